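"""Barcode identification by local alignment with Karlin–Altschul e-values.

Reads are short (typically 5–40 nt) and error-prone, so identification uses
full Smith–Waterman local alignment of every read against every reference
barcode, plus-strand only, and converts the best score S into an e-value

    E = K · m · n · exp(-λ·S)

with m the read length and n the summed reference length.  A read is
identified when the best-scoring reference is unique and E falls below the
threshold (0.01 for multi-barcode panels; 0.1 when the reference holds a
single barcode).  The same machinery flags byproduct reads (TSO/primer
artifacts) and drives Monte-Carlo multiplexing-capacity estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basecall import CalledRead
from .chemistry import BASES, ReferenceSet, reverse_complement

__all__ = [
    "ScoringScheme",
    "Alignment",
    "IdentificationResult",
    "CapacityCurve",
    "ReadModel",
    "local_align",
    "sw_score",
    "evalue",
    "identify_reads",
    "default_byproduct_reference",
    "flag_byproducts",
    "capacity_curve",
    "estimate_multiplex_capacity",
    "UNIDENTIFIED",
]

UNIDENTIFIED = "UNIDENTIFIED"

#: Template-switching oligo (DNA form) and RT/PCR primer — the dominant
#: library-prep byproduct sources.
TSO = "AAGCAGTGGTATCAACGCAGAGTACGGG"
PCR_PRIMER = "AAGCAGTGGTATCAACGCAGAGT"


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores and Karlin–Altschul parameters.

    Defaults are the classic +1/−2 nucleotide scheme with affine gaps (first
    gap base −2, each extension −1) and the standard ungapped λ, K for +1/−2,
    used here as an approximation for the gapped statistics.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -2
    gap_extend: int = -1
    lam: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_SCORING = ScoringScheme()


def sw_score(query: str, subject: str, scoring: ScoringScheme = DEFAULT_SCORING) -> int:
    """Smith–Waterman local alignment score (affine gaps), score only.

    A gap of length L scores ``gap_open + (L-1) * gap_extend``.
    """
    m, n = len(query), len(subject)
    if m == 0 or n == 0:
        return 0
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    NEG = -(10**9)
    prev_h = [0] * (n + 1)
    prev_e = [NEG] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        h = [0] * (n + 1)
        e = [NEG] * (n + 1)
        f = NEG
        ph = prev_h
        pe = prev_e
        hj1 = 0  # h[j-1]
        for j in range(1, n + 1):
            e[j] = max(ph[j] + go, pe[j] + ge)
            f = max(hj1 + go, f + ge)
            diag = ph[j - 1] + (ma if qi == subject[j - 1] else mi)
            v = diag
            if e[j] > v:
                v = e[j]
            if f > v:
                v = f
            if v < 0:
                v = 0
            h[j] = v
            hj1 = v
            if v > best:
                best = v
        prev_h, prev_e = h, e
    return best


@dataclass
class Alignment:
    """A local alignment with per-column detail.

    ``columns`` lists (query_index, subject_index) pairs, with ``None`` on
    the gapped side; indices are 0-based.  Spans are half-open.
    """

    score: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    columns: list[tuple[int | None, int | None]]
    matches: int
    mismatches: int
    insertions: int  # query bases absent from subject
    deletions: int  # subject bases absent from query

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def identity(self) -> float:
        return self.matches / self.n_columns if self.columns else 0.0


def local_align(
    query: str, subject: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> Alignment:
    """Smith–Waterman local alignment with affine gaps and traceback.

    Deterministic traceback: ties prefer the diagonal, then up (gap in
    subject), then left (gap in query); the start cell is the first maximum
    in row-major order.  Empty query or subject yields a score-0 empty
    alignment.
    """
    m, n = len(query), len(subject)
    empty = Alignment(0, (0, 0), (0, 0), [], 0, 0, 0, 0)
    if m == 0 or n == 0:
        return empty
    ma, mi = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i - 1, j] + go, E[i - 1, j] + ge)
            F[i, j] = max(H[i, j - 1] + go, F[i, j - 1] + ge)
            diag = H[i - 1, j - 1] + (ma if qi == subject[j - 1] else mi)
            H[i, j] = max(0, diag, E[i, j], F[i, j])
    score = int(H.max())
    if score == 0:
        return empty
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    cols: list[tuple[int | None, int | None]] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            v = H[i, j]
            if v == 0:
                break
            diag = H[i - 1, j - 1] + (ma if query[i - 1] == subject[j - 1] else mi)
            if v == diag:
                cols.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif v == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in subject: consume query base (up)
            cols.append((i - 1, None))
            if E[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
        else:  # gap in query: consume subject base (left)
            cols.append((None, j - 1))
            if F[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
    cols.reverse()
    qidx = [c[0] for c in cols if c[0] is not None]
    sidx = [c[1] for c in cols if c[1] is not None]
    matches = sum(
        1
        for qi_, sj in cols
        if qi_ is not None and sj is not None and query[qi_] == subject[sj]
    )
    mismatches = sum(
        1
        for qi_, sj in cols
        if qi_ is not None and sj is not None and query[qi_] != subject[sj]
    )
    insertions = sum(1 for qi_, sj in cols if sj is None)
    deletions = sum(1 for qi_, sj in cols if qi_ is None)
    return Alignment(
        score=score,
        query_span=(min(qidx), max(qidx) + 1) if qidx else (0, 0),
        subject_span=(min(sidx), max(sidx) + 1) if sidx else (0, 0),
        columns=cols,
        matches=matches,
        mismatches=mismatches,
        insertions=insertions,
        deletions=deletions,
    )


def evalue(
    score: float, query_len: int, total_ref_len: int, scoring: ScoringScheme = DEFAULT_SCORING
) -> float:
    """Karlin–Altschul e-value E = K·m·n·exp(-λS)."""
    if query_len < 1 or total_ref_len < 1:
        raise ValueError("query_len and total_ref_len must be >= 1")
    return scoring.K * query_len * total_ref_len * math.exp(-scoring.lam * score)


@dataclass
class IdentificationResult:
    read_id: str
    fov_id: int
    best_ref_id: str  # reference name, or UNIDENTIFIED
    score: int
    evalue: float


def _best_hit(
    seq: str, refs: ReferenceSet, scoring: ScoringScheme
) -> tuple[str | None, int, float, bool]:
    """Best reference for one sequence: (name, score, evalue, unique)."""
    total_n = refs.total_length
    best_name, best_score, unique = None, 0, True
    for name, ref in refs.items():
        s = sw_score(seq, ref, scoring)
        if s > best_score:
            best_name, best_score, unique = name, s, True
        elif s == best_score and best_name is not None and name != best_name:
            unique = False
    if best_name is None or not seq:
        return None, 0, math.inf, False
    return best_name, best_score, evalue(best_score, len(seq), total_n, scoring), unique


def identify_reads(
    reads: list[CalledRead],
    refs: ReferenceSet,
    threshold: float = 0.01,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> tuple[list[IdentificationResult], pd.DataFrame]:
    """Identify each read against a barcode reference set.

    A read is identified as the unique best-scoring barcode when its e-value
    is below ``threshold``; score ties and weak hits are UNIDENTIFIED.
    Returns the per-read results and a per-(FOV, barcode) count table with an
    UNIDENTIFIED column.
    """
    if len(refs) == 0:
        raise ValueError("reference set must be non-empty")
    results: list[IdentificationResult] = []
    for read in reads:
        name, score, ev, unique = _best_hit(read.seq, refs, scoring)
        identified = name is not None and unique and ev < threshold
        results.append(
            IdentificationResult(
                read_id=read.read_id,
                fov_id=read.fov_id,
                best_ref_id=name if identified else UNIDENTIFIED,
                score=score,
                evalue=ev,
            )
        )
    counts = (
        pd.DataFrame(
            {"fov_id": [r.fov_id for r in results], "barcode": [r.best_ref_id for r in results]}
        )
        .groupby(["fov_id", "barcode"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[*refs.names, UNIDENTIFIED], fill_value=0)
    )
    return results, counts


def default_byproduct_reference() -> ReferenceSet:
    """Predicted byproduct reference: TSO, its reverse complement, the
    RT/PCR primer, and their concatemers."""
    entries = {
        "TSO": TSO,
        "TSO_rc": reverse_complement(TSO),
        "PCR_primer": PCR_PRIMER,
        "TSO_x2": TSO * 2,
        "TSO_rc_x2": reverse_complement(TSO) * 2,
        "PCR_primer_x2": PCR_PRIMER * 2,
    }
    return ReferenceSet(entries)


def flag_byproducts(
    reads: list[CalledRead],
    byproduct_refs: ReferenceSet | None = None,
    threshold: float = 0.01,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> dict[str, bool]:
    """Flag reads whose best byproduct-reference e-value beats ``threshold``.

    An empty byproduct set flags nothing.
    """
    if byproduct_refs is None:
        byproduct_refs = default_byproduct_reference()
    flags: dict[str, bool] = {}
    for read in reads:
        if len(byproduct_refs) == 0 or not read.seq:
            flags[read.read_id] = False
            continue
        _, _, ev, _ = _best_hit(read.seq, byproduct_refs, scoring)
        flags[read.read_id] = ev < threshold
    return flags


# ---------------------------------------------------------------------------
# multiplexing-capacity Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadModel:
    """Read-level generative model for capacity simulations.

    Reads are prefixes of their source barcode with normally distributed
    length (clipped to [1, barcode length]) and independent per-base errors
    split among substitutions, insertions and deletions.
    """

    mean_length: float = 15.4
    sd_length: float = 5.9
    error_rate: float = 0.05
    sub_frac: float = 1 / 3
    ins_frac: float = 1 / 3  # remainder is deletions

    def sample_read(self, source: str, rng: np.random.Generator) -> str:
        L = int(np.clip(round(rng.normal(self.mean_length, self.sd_length)), 1, len(source)))
        out: list[str] = []
        for b in source[:L]:
            if rng.random() < self.error_rate:
                u = rng.random()
                if u < self.sub_frac:
                    others = BASES.replace(b, "")
                    out.append(others[int(rng.integers(3))])
                elif u < self.sub_frac + self.ins_frac:
                    out.append(BASES[int(rng.integers(4))] + b)
                # else: deletion — emit nothing
            else:
                out.append(b)
        return "".join(out) or source[0]


def _random_barcode(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@dataclass
class CapacityCurve:
    """False-positive/correct/unidentified rates vs reference size."""

    rates: pd.DataFrame  # columns: k, false_positive_rate, correct_rate, unidentified_rate
    threshold: float  # FP-rate tolerance
    max_k_below_threshold: int


def capacity_curve(
    read_model: ReadModel,
    sizes: list[int],
    n_reads: int = 100,
    barcode_len: int = 15,
    threshold: float = 0.01,
    seed: int = 0,
    evalue_threshold: float = 0.1,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> CapacityCurve:
    """False-positive rate of identification as the reference grows.

    Reads are simulated from one designated source barcode; for each
    reference size ``k`` the reference holds the source plus ``k - 1`` random
    decoys, and the false-positive rate is the fraction of reads identified
    as a non-source barcode.  ``threshold`` is the FP-rate tolerance defining
    ``max_k_below_threshold`` ("negligible" false positives).
    """
    rng = np.random.default_rng(seed)
    kmax = max(sizes)
    source = _random_barcode(barcode_len, rng)
    decoys: list[str] = []
    while len(decoys) < kmax - 1:
        d = _random_barcode(barcode_len, rng)
        if d != source and d not in decoys:
            decoys.append(d)
    reads = [read_model.sample_read(source, rng) for _ in range(n_reads)]
    rows = []
    for k in sorted(sizes):
        names = {"source": source}
        names.update({f"decoy_{i}": d for i, d in enumerate(decoys[: k - 1])})
        refs = ReferenceSet(names)
        fp = correct = unid = 0
        for seq in reads:
            name, _, ev, unique = _best_hit(seq, refs, scoring)
            if name is None or not unique or ev >= evalue_threshold:
                unid += 1
            elif name == "source":
                correct += 1
            else:
                fp += 1
        rows.append(
            (k, fp / n_reads, correct / n_reads, unid / n_reads)
        )
    rates = pd.DataFrame(
        rows, columns=["k", "false_positive_rate", "correct_rate", "unidentified_rate"]
    )
    ok = rates[rates.false_positive_rate <= threshold]
    max_k = int(ok.k.max()) if len(ok) else 0
    return CapacityCurve(rates=rates, threshold=threshold, max_k_below_threshold=max_k)


def _wilson(successes: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def estimate_multiplex_capacity(
    n_targets: int,
    barcode_len: int = 15,
    read_model: ReadModel = ReadModel(),
    n_reads: int = 200,
    seed: int = 0,
    evalue_threshold: float = 0.1,
    scoring: ScoringScheme = DEFAULT_SCORING,
    work_budget: int = 5_000_000,
) -> dict:
    """Monte-Carlo identification rates for an ``n_targets``-plex panel.

    Draws ``n_targets`` random barcodes, simulates reads from uniformly
    chosen sources under ``read_model``, identifies each read against the
    full panel and reports correct/incorrect/unidentified rates with Wilson
    95% intervals.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if n_targets * n_reads > work_budget:
        warnings.warn(
            f"alignment work n_targets*n_reads = {n_targets * n_reads} exceeds "
            f"budget {work_budget}; consider reducing n_reads",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    barcodes: dict[str, str] = {}
    while len(barcodes) < n_targets:
        b = _random_barcode(barcode_len, rng)
        if b not in barcodes.values():
            barcodes[f"T_{len(barcodes)}"] = b
    refs = ReferenceSet(barcodes)
    names = refs.names
    correct = incorrect = unid = 0
    for _ in range(n_reads):
        src = names[int(rng.integers(n_targets))]
        seq = read_model.sample_read(refs[src], rng)
        name, _, ev, unique = _best_hit(seq, refs, scoring)
        if name is None or not unique or ev >= evalue_threshold:
            unid += 1
        elif name == src:
            correct += 1
        else:
            incorrect += 1
    out = {}
    for label, c in (("correct", correct), ("incorrect", incorrect), ("unidentified", unid)):
        lo, hi = _wilson(c, n_reads)
        out[f"{label}_rate"] = c / n_reads
        out[f"{label}_ci"] = (lo, hi)
    out["n_reads"] = n_reads
    out["n_targets"] = n_targets
    return out
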