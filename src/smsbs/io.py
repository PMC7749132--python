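"""File formats: FASTA references, FASTQ reads, TSV spot tables, TIFF stacks.

Reads carry no meaningful per-base quality (the instrument reports none), so
FASTQ qualities are a constant Q40 placeholder; read IDs encode FOV, anchor
and pixel position so every read stays spatially traceable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .basecall import CalledRead
from .chemistry import BASES, ReferenceSet
from .simulate import SPOT_COLUMNS

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_fastq",
    "write_spots",
    "read_spots",
    "write_images_tiff",
    "read_images_tiff",
]

# IUPAC ambiguity code -> deterministic concrete base (first of the set)
_IUPAC_FIRST = {
    "R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A", "U": "T",
}


def read_fasta(path, strict: bool = False) -> ReferenceSet:
    """Read a reference FASTA.

    Lowercase is uppercased.  Ambiguity codes are rejected when ``strict``;
    otherwise each is expanded to a deterministic concrete base (the first of
    its IUPAC set, e.g. V → A).
    """
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(BASES)
        if bad:
            if strict or not bad.issubset(_IUPAC_FIRST):
                raise ValueError(
                    f"reference {rec.id!r} contains non-ACGT characters {sorted(bad)!r}"
                )
            seq = "".join(_IUPAC_FIRST.get(c, c) for c in seq)
        if rec.id in entries:
            raise ValueError(f"duplicate reference id {rec.id!r}")
        entries[rec.id] = seq
    return ReferenceSet(entries)


def write_fasta(refs: ReferenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in refs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: list[CalledRead], path, quality_char: str = "I") -> None:
    """Write reads as FASTQ with constant placeholder quality (Q40).

    Length-0 reads are skipped (FASTQ cannot represent them usefully).
    """
    with open(path, "w") as fh:
        for r in reads:
            if r.length == 0:
                continue
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{quality_char * r.length}\n")


def read_fastq(path) -> list[CalledRead]:
    """Read a FASTQ written by :func:`write_fastq` back into reads.

    Flow provenance is not stored in FASTQ, so ``base_provenance`` is empty
    and ``stopped_at_quad`` is 0 on round-trip.
    """
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fov, anchor, x, y = CalledRead.parse_read_id(rec.id)
        reads.append(
            CalledRead(
                anchor_id=anchor,
                fov_id=fov,
                x_px=x,
                y_px=y,
                seq=str(rec.seq).upper(),
                base_provenance=[],
                stopped_at_quad=0,
            )
        )
    return reads


def write_spots(spots: pd.DataFrame, path) -> None:
    cols = [c for c in SPOT_COLUMNS if c in spots.columns]
    spots.to_csv(path, sep="\t", index=False, columns=cols)


def read_spots(path) -> pd.DataFrame:
    """Read a spot table TSV, reporting malformed rows by line number."""
    df = pd.read_csv(path, sep="\t")
    required = [c for c in SPOT_COLUMNS if c != "molecule_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot table {path} missing columns {missing}")
    for col in ("fov_id", "quad", "flow", "x_px", "y_px"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() | (coerced != coerced.round())]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            lines = [int(i) + 2 for i in bad[:5]]
            raise ValueError(
                f"spot table {path}: non-integer {col!r} at line(s) {lines}"
            )
        df[col] = coerced.astype(int)
    if "molecule_id" in df.columns:
        df["molecule_id"] = pd.to_numeric(df["molecule_id"], errors="coerce").fillna(-1).astype(int)
    bad_phase = df.index[~df.phase.isin(["incorporation", "post_cleave"])]
    if len(bad_phase):
        lines = [int(i) + 2 for i in bad_phase[:5]]
        raise ValueError(f"spot table {path}: unknown phase at line(s) {lines}")
    return df


def write_images_tiff(images: dict, path) -> list:
    """Write rendered images as a multi-page TIFF; returns the page order."""
    import tifffile

    keys = sorted(images)
    stack = np.stack([images[k] for k in keys]).astype(np.float32)
    tifffile.imwrite(str(path), stack)
    return keys


def read_images_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
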