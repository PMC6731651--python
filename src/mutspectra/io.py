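"""File formats and the in-memory genome container.

FASTA is read through pyfaidx and VCF through pysam; VCF, BED, bedGraph and
the package's TSV tables are written as plain text so that identical inputs
produce byte-identical outputs.

Variant callsets are held as a pandas DataFrame with one row per derived
allele (multiallelic sites contribute several rows at the same position):

    contig  str     pos  int (1-based)   ref  uint8   alt  uint8
    ac      int     an   int

``ref``/``alt`` use the catalog base encoding (A=0, C=1, G=2, T=3).
"""

from __future__ import annotations

import io as _io
from collections.abc import Mapping
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .catalog import N_CODE, decode, encode

OBS_COLUMNS = ["contig", "pos", "ref", "alt", "ac", "an"]


class Genome(Mapping):
    """Reference (or ancestral) sequences as encoded uint8 arrays by contig."""

    def __init__(self, sequences: Mapping[str, Union[str, np.ndarray]]):
        self._seqs: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            if isinstance(seq, str):
                arr = encode(seq)
            else:
                arr = np.asarray(seq, dtype=np.uint8)
            self._seqs[str(name)] = arr

    def __getitem__(self, contig: str) -> np.ndarray:
        return self._seqs[contig]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def extent(self) -> dict[str, int]:
        """Contig name -> length in bp."""
        return {name: len(seq) for name, seq in self._seqs.items()}

    def sequence(self, contig: str) -> str:
        return decode(self._seqs[contig])

    def reverse_complement(self) -> "Genome":
        out = {}
        for name, seq in self._seqs.items():
            rc = seq[::-1].copy()
            ok = rc < 4
            rc[ok] = 3 - rc[ok]
            out[name] = rc
        return Genome(out)

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: Union[str, Path], width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                s = decode(seq)
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: Union[str, Path]) -> pd.DataFrame:
    """Read a VCF with AC/AN INFO fields into the observation frame.

    Each ALT allele becomes one row.  Records whose REF or ALT is not a
    single A/C/G/T base are kept with code 4 so that downstream
    classification can log them as skipped rather than silently drop them.
    """
    import pysam

    rows: list[tuple] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            if "AN" not in info or "AC" not in info:
                raise ValueError(
                    f"record {rec.contig}:{rec.pos} lacks AC/AN INFO fields"
                )
            an = int(info["AN"])
            acs = info["AC"]
            if not isinstance(acs, tuple):
                acs = (acs,)
            ref = rec.ref or ""
            for alt, ac in zip(rec.alts or (), acs):
                rcode = int(encode(ref)[0]) if len(ref) == 1 else N_CODE
                acode = int(encode(alt)[0]) if len(alt) == 1 else N_CODE
                rows.append((rec.contig, rec.pos, rcode, acode, int(ac), an))
    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return df.astype(
        {"pos": np.int64, "ref": np.uint8, "alt": np.uint8, "ac": np.int64, "an": np.int64}
    )


def write_vcf(
    obs: pd.DataFrame, path: Union[str, Path], extent: Optional[Mapping[str, int]] = None
) -> None:
    """Write observation rows as a sorted VCF 4.2 with AC/AN INFO fields.

    Rows sharing (contig, pos) are merged into one multiallelic record.
    """
    df = obs.sort_values(["contig", "pos", "alt"], kind="mergesort")
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Derived allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">',
    ]
    if extent:
        for name, length in extent.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    buf = _io.StringIO()
    buf.write("\n".join(lines) + "\n")
    for (contig, pos), grp in df.groupby(["contig", "pos"], sort=False):
        ref = "ACGTN"[int(grp["ref"].iloc[0])]
        alts = ",".join("ACGTN"[a] for a in grp["alt"])
        acs = ",".join(str(int(a)) for a in grp["ac"])
        an = int(grp["an"].iloc[0])
        buf.write(f"{contig}\t{int(pos)}\t.\t{ref}\t{alts}\t.\t.\tAC={acs};AN={an}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------


def read_bed(path: Union[str, Path]) -> pd.DataFrame:
    """Read 3- or 5-column BED into (contig, start, end[, score])."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name", "score"][: _ncols(path)],
    )
    keep = ["contig", "start", "end"] + (["score"] if "score" in df else [])
    return df[keep]


def _ncols(path: Union[str, Path]) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                return len(line.rstrip("\n").split("\t"))
    return 3


def write_bed(df: pd.DataFrame, path: Union[str, Path]) -> None:
    out = df.copy()
    if "score" in out.columns:
        out["name"] = "."
        out = out[["contig", "start", "end", "name", "score"]]
    else:
        out = out[["contig", "start", "end"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: Union[str, Path]) -> pd.DataFrame:
    """Read a 4-column bedGraph into (contig, start, end, score)."""
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "score"],
    )


def write_bedgraph(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[["contig", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# TSV tables with a parameter comment block
# ---------------------------------------------------------------------------


def write_table(
    df: pd.DataFrame,
    path: Union[str, Path],
    params: Optional[Mapping[str, object]] = None,
    index: bool = True,
) -> None:
    """Write a result table as TSV preceded by '# key=value' comment lines."""
    with open(path, "w") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: Union[str, Path], index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
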