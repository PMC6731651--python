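"""Genomic compartments: named interval sets with set algebra.

A compartment is a named collection of half-open 0-based intervals
(BED convention).  Unscored compartments are merged and sorted on
construction; scored compartments (hotspot tiers, covariate tracks) must be
non-overlapping, since merging intervals with different scores has no
well-defined semantics.  Set operations are delegated to pyranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pyranges as pr

from . import io as msio

IntervalLike = Union[pd.DataFrame, Iterable[tuple]]


def _as_frame(intervals: IntervalLike) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        df = intervals.copy()
    else:
        rows = list(intervals)
        if rows and len(rows[0]) == 4:
            df = pd.DataFrame(rows, columns=["contig", "start", "end", "score"])
        else:
            df = pd.DataFrame(rows, columns=["contig", "start", "end"])
    if df.empty:
        cols = ["contig", "start", "end"] + (
            ["score"] if "score" in df.columns else []
        )
        return pd.DataFrame(columns=cols)
    df["contig"] = df["contig"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


class CompartmentSet:
    """A named set of genomic intervals, optionally scored."""

    def __init__(self, name: str, intervals: IntervalLike = (), merge: bool = True):
        df = _as_frame(intervals)
        if not df.empty and (df["start"] >= df["end"]).any():
            raise ValueError(f"compartment {name!r}: start must be < end")
        self.name = name
        self.scored = "score" in df.columns
        if self.scored:
            df = df.sort_values(["contig", "start"], kind="mergesort")
            df = df.reset_index(drop=True)
            nxt = df["start"].shift(-1)
            same = df["contig"] == df["contig"].shift(-1)
            if bool((same & (nxt < df["end"])).any()):
                raise ValueError(
                    f"scored compartment {name!r} has overlapping intervals"
                )
            self.df = df[["contig", "start", "end", "score"]]
        else:
            if merge and not df.empty:
                merged = self._to_pr(df).merge()
                df = self._from_pr(merged)
            else:
                df = df.sort_values(["contig", "start"], kind="mergesort")
                df = df.reset_index(drop=True)
            self.df = df[["contig", "start", "end"]]

    # -- conversion helpers -------------------------------------------------

    @staticmethod
    def _to_pr(df: pd.DataFrame) -> pr.PyRanges:
        return pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": df["contig"].astype(str),
                    "Start": df["start"],
                    "End": df["end"],
                }
            )
        )

    @staticmethod
    def _from_pr(ranges: pr.PyRanges) -> pd.DataFrame:
        if ranges.empty:
            return pd.DataFrame(columns=["contig", "start", "end"])
        df = ranges.df
        out = pd.DataFrame(
            {
                "contig": df["Chromosome"].astype(str),
                "start": df["Start"].astype(np.int64),
                "end": df["End"].astype(np.int64),
            }
        )
        return out.sort_values(["contig", "start"], kind="mergesort").reset_index(
            drop=True
        )

    @property
    def pyranges(self) -> pr.PyRanges:
        return self._to_pr(self.df)

    # -- basic properties ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def empty(self) -> bool:
        return self.df.empty

    @property
    def total_length(self) -> int:
        if self.df.empty:
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    @property
    def contigs(self) -> list[str]:
        return sorted(self.df["contig"].unique())

    def intervals(self) -> list[tuple]:
        cols = ["contig", "start", "end"] + (["score"] if self.scored else [])
        return [tuple(row) for row in self.df[cols].itertuples(index=False)]

    def scores(self) -> np.ndarray:
        if not self.scored:
            raise ValueError(f"compartment {self.name!r} has no scores")
        return self.df["score"].to_numpy(dtype=float)

    def drop_scores(self, name: Optional[str] = None) -> "CompartmentSet":
        return CompartmentSet(name or self.name, self.df[["contig", "start", "end"]])

    # -- set algebra ----------------------------------------------------------

    def intersect(self, other: "CompartmentSet", name: Optional[str] = None) -> "CompartmentSet":
        if self.empty or other.empty:
            return CompartmentSet(name or self.name, ())
        res = self.pyranges.merge().intersect(other.pyranges.merge())
        return CompartmentSet(name or self.name, self._from_pr(res))

    def subtract(self, other: "CompartmentSet", name: Optional[str] = None) -> "CompartmentSet":
        if self.empty or other.empty:
            return CompartmentSet(name or self.name, self.df[["contig", "start", "end"]])
        res = self.pyranges.merge().subtract(other.pyranges.merge())
        return CompartmentSet(name or self.name, self._from_pr(res))

    def union(self, other: "CompartmentSet", name: Optional[str] = None) -> "CompartmentSet":
        both = pd.concat(
            [self.df[["contig", "start", "end"]], other.df[["contig", "start", "end"]]],
            ignore_index=True,
        )
        return CompartmentSet(name or self.name, both)

    def complement(
        self, extent: Mapping[str, int], name: Optional[str] = None
    ) -> "CompartmentSet":
        """Everything in ``extent`` (contig -> length) not covered by self."""
        full = CompartmentSet(
            name or f"not-{self.name}",
            [(c, 0, L) for c, L in extent.items()],
        )
        return full.subtract(self, name=name or f"not-{self.name}")

    # -- queries --------------------------------------------------------------

    def contains(self, contigs: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based positions, matched by contig."""
        contigs = np.asarray(contigs, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(len(positions), dtype=bool)
        for contig, sub in self.df.groupby("contig", sort=False):
            mask = contigs == contig
            if not mask.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            pos = positions[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos[ok] < ends[idx[ok]]
            out[mask] = ok
        return out

    def interval_index(self, contigs: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Row index in ``self.df`` containing each position, or -1."""
        contigs = np.asarray(contigs, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), -1, dtype=np.int64)
        for contig, sub in self.df.groupby("contig", sort=False):
            mask = contigs == contig
            if not mask.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            rows = sub.index.to_numpy()
            pos = positions[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos[ok] < ends[idx[ok]]
            res = np.full(len(pos), -1, dtype=np.int64)
            res[ok] = rows[idx[ok]]
            out[mask] = res
        return out

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_bed(cls, path: Union[str, Path], name: Optional[str] = None) -> "CompartmentSet":
        return cls(name or Path(path).stem, msio.read_bed(path))

    @classmethod
    def from_bedgraph(cls, path: Union[str, Path], name: Optional[str] = None) -> "CompartmentSet":
        return cls(name or Path(path).stem, msio.read_bedgraph(path))

    def to_bed(self, path: Union[str, Path]) -> None:
        msio.write_bed(self.df, path)

    def to_bedgraph(self, path: Union[str, Path]) -> None:
        if not self.scored:
            raise ValueError("bedGraph output requires scores")
        msio.write_bedgraph(self.df, path)

    def __repr__(self) -> str:  # pragma: no cover
        kind = "scored " if self.scored else ""
        return (
            f"CompartmentSet({self.name!r}, {len(self)} {kind}intervals, "
            f"{self.total_length} bp)"
        )


# ---------------------------------------------------------------------------
# Derived partitions
# ---------------------------------------------------------------------------


def tile_windows(
    extent: Mapping[str, int], width: int, name: str = "windows"
) -> CompartmentSet:
    """Tile each contig with fixed-width windows.

    The final partial window on each contig is retained; partial windows can
    be recognised by ``end - start < width``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rows = []
    for contig, length in extent.items():
        for start in range(0, length, width):
            rows.append((contig, start, min(start + width, length)))
    out = CompartmentSet(name, rows, merge=False)
    return out


def bin_by_score(
    scored: CompartmentSet,
    edges: Optional[Sequence[float]] = None,
    n_bins: Optional[int] = None,
    names: Optional[Sequence[str]] = None,
) -> list[CompartmentSet]:
    """Partition a scored compartment into bins by score.

    Threshold mode (``edges=(low, high)``): two bins with closed
    inequalities, score <= low and score >= high; the middle is discarded.
    This matches the late (score <= -0.5) / early (score >= 0.5)
    replication-timing split.

    Quantile mode (``n_bins=k``): k bins with edges at length-weighted score
    quantiles, so each bin holds about the same number of base pairs.
    """
    scores = scored.scores()
    df = scored.df
    if edges is not None:
        if n_bins is not None:
            raise ValueError("give either edges or n_bins, not both")
        if len(edges) != 2 or not edges[0] < edges[1]:
            raise ValueError("threshold mode takes two increasing edges")
        low, high = float(edges[0]), float(edges[1])
        groups = [df[scores <= low], df[scores >= high]]
        labels = list(names) if names else [
            f"{scored.name}_le_{low:g}",
            f"{scored.name}_ge_{high:g}",
        ]
    elif n_bins is not None:
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
        inner = weighted_quantiles(
            scores, lengths, np.arange(1, n_bins) / n_bins
        )
        # values equal to an inner edge fall in the lower bin, so tied
        # score tiers round-trip exactly
        assign = np.searchsorted(inner, scores, side="left")
        groups = [df[assign == b] for b in range(n_bins)]
        labels = list(names) if names else [
            f"{scored.name}_q{b + 1}" for b in range(n_bins)
        ]
    else:
        raise ValueError("either edges or n_bins is required")
    return [
        CompartmentSet(label, grp.reset_index(drop=True))
        for label, grp in zip(labels, groups)
    ]


def weighted_quantiles(
    values: np.ndarray, weights: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Quantiles of ``values`` under ``weights``, by inverse weighted CDF."""
    order = np.argsort(values, kind="mergesort")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cdf = np.cumsum(w) / w.sum()
    idx = np.searchsorted(cdf, probs, side="left")
    return v[np.minimum(idx, len(v) - 1)]


def window_means(
    track: CompartmentSet, windows: CompartmentSet
) -> np.ndarray:
    """Base-pair-weighted mean track score over each window.

    Windows with no overlapping track segment get NaN.
    """
    scores = track.scores()
    out = np.full(len(windows), np.nan)
    tdf = track.df
    for contig, wsub in windows.df.groupby("contig", sort=False):
        tsub = tdf[tdf["contig"] == contig]
        if tsub.empty:
            continue
        tstart = tsub["start"].to_numpy()
        tend = tsub["end"].to_numpy()
        tscore = scores[tsub.index.to_numpy()]
        for row in wsub.itertuples():
            lo = np.searchsorted(tend, row.start, side="right")
            hi = np.searchsorted(tstart, row.end, side="left")
            if hi <= lo:
                continue
            seg_lo = np.maximum(tstart[lo:hi], row.start)
            seg_hi = np.minimum(tend[lo:hi], row.end)
            overlap = (seg_hi - seg_lo).astype(float)
            total = overlap.sum()
            if total > 0:
                out[row.Index] = float(
                    np.dot(overlap, tscore[lo:hi]) / total
                )
    return out
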