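"""Run-level analytics: extension traces, stop/pause statistics, accuracy,
elongation-model fitting, count correlations and group comparisons.

The elongation model summarises a run by two parameters: a per-quad survival
probability ``s`` (the chance a molecule keeps extending into the next quad;
full stops, e.g. surface detachment, remove it) and a rate ``r`` of
nucleotides gained per active quad.  The expected read length after Q quads
is then

    L(Q) = r * s * (1 - s**Q) / (1 - s)        (L(Q) = r*Q when s = 1)

i.e. ``r`` times the expected number of active quads.  The model captures
the observed saturation of mean read length with cycle number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .basecall import CalledRead
from .identify import DEFAULT_SCORING, ScoringScheme, local_align

__all__ = [
    "TraceSet",
    "StopPauseStats",
    "AccuracyReport",
    "ElongationFit",
    "extension_traces",
    "stop_pause_stats",
    "accuracy_report",
    "expected_length",
    "simulate_elongation_mc",
    "fit_elongation",
    "count_correlation",
    "compare_lengths",
    "effective_sample_fraction",
]


# ---------------------------------------------------------------------------
# extension traces and stop/pause statistics
# ---------------------------------------------------------------------------

@dataclass
class TraceSet:
    """Per-read cumulative extension traces.

    ``traces[i, q]`` is read i's called length after quad q (column 0 is the
    pre-sequencing state, always 0); traces are non-decreasing and end at the
    read length.
    """

    traces: np.ndarray  # (n_reads, n_quads + 1)
    read_ids: list[str]
    groups: list[str]
    n_quads: int

    def group_stats(self) -> pd.DataFrame:
        """Mean and s.d. trace per group (one row per group × quad)."""
        rows = []
        arr = self.traces
        for g in sorted(set(self.groups)):
            sel = arr[[i for i, gg in enumerate(self.groups) if gg == g]]
            for q in range(self.n_quads + 1):
                rows.append((g, q, float(sel[:, q].mean()), float(sel[:, q].std())))
        return pd.DataFrame(rows, columns=["group", "quad", "mean", "sd"])


def extension_traces(
    reads: list[CalledRead],
    n_quads: int,
    groups: dict[str, str] | None = None,
) -> TraceSet:
    """Cumulative incorporations per quad for every read.

    ``groups`` maps read_id → group label (e.g. "identified"/"unidentified"
    or an anchoring condition); unmapped reads get group "all".
    """
    groups = groups or {}
    traces = np.zeros((len(reads), n_quads + 1), dtype=int)
    ids, labels = [], []
    for i, r in enumerate(reads):
        per_quad = np.zeros(n_quads + 1, dtype=int)
        for q, _ in r.base_provenance:
            if q <= n_quads:
                per_quad[q] += 1
        traces[i] = np.cumsum(per_quad)
        ids.append(r.read_id)
        labels.append(groups.get(r.read_id, "all"))
    return TraceSet(traces=traces, read_ids=ids, groups=labels, n_quads=n_quads)


@dataclass
class StopPauseStats:
    """Stop-quad histogram and pause frequency of a trace set.

    ``stop_histogram[q]`` is the fraction of reads whose last incorporation
    was in quad q (q = 0: no incorporation at all); the bin at the final quad
    counts reads that were still extending at the end of the run — whether
    they would have stopped afterwards is unobservable.  The pause frequency
    is the fraction of blank quads among quads up to and including the stop
    quad, averaged over reads that incorporated at least once.
    """

    stop_histogram: np.ndarray  # (n_quads + 1,), sums to 1
    reached_last_fraction: float
    pause_frequency: float
    n_reads: int


def stop_pause_stats(traces: TraceSet, n_quads: int | None = None) -> StopPauseStats:
    n_quads = traces.n_quads if n_quads is None else n_quads
    arr = traces.traces
    if len(arr) == 0:
        return StopPauseStats(np.zeros(n_quads + 1), 0.0, 0.0, 0)
    incs = np.diff(arr, axis=1) > 0  # (n_reads, n_quads)
    stop = np.where(
        incs.any(axis=1), n_quads - np.argmax(incs[:, ::-1], axis=1), 0
    )
    hist = np.bincount(stop, minlength=n_quads + 1).astype(float)
    hist /= hist.sum()
    pauses = []
    for i in range(len(arr)):
        if stop[i] >= 1:
            blanks = int((~incs[i, : stop[i]]).sum())
            pauses.append(blanks / stop[i])
    return StopPauseStats(
        stop_histogram=hist,
        reached_last_fraction=float((stop == n_quads).mean()),
        pause_frequency=float(np.mean(pauses)) if pauses else 0.0,
        n_reads=len(arr),
    )


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Alignment-based per-base accuracy with error decomposition.

    ``context`` is a 4×4 table of second-base error rates in consecutive
    called-base pairs, stratified by (first called base, second called base);
    entries are rates, NaN where the pair was never observed.
    """

    error_rate: float
    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float
    n_aligned_columns: int
    n_reads: int
    context: pd.DataFrame

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error_rate


def accuracy_report(
    reads: list[CalledRead],
    sources: dict[str, str],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> AccuracyReport:
    """Align each read to its source sequence and pool error counts.

    ``sources`` maps read_id → source sequence (the molecule's synthesis
    track in truth mode, or the identified barcode in reference mode); reads
    without a source (e.g. unidentified) are skipped.  The error rate is
    (mismatches + insertions + deletions) / aligned columns.  The context
    table stratifies second-base errors of consecutive called-base pairs by
    the preceding called base.
    """
    bases = "ACGT"
    mm = ins = dele = cols = 0
    n_used = 0
    pair_err = np.zeros((4, 4))
    pair_n = np.zeros((4, 4))
    for r in reads:
        src = sources.get(r.read_id)
        if src is None or not r.seq:
            continue
        aln = local_align(r.seq, src, scoring)
        if aln.n_columns == 0:
            continue
        n_used += 1
        mm += aln.mismatches
        ins += aln.insertions
        dele += aln.deletions
        cols += aln.n_columns
        # per-read-base error class within the aligned span
        err_of: dict[int, bool] = {}
        for qi, sj in aln.columns:
            if qi is None:
                continue
            err_of[qi] = sj is None or r.seq[qi] != src[sj]
        for p in sorted(err_of):
            if p - 1 in err_of:
                b1, b2 = bases.index(r.seq[p - 1]), bases.index(r.seq[p])
                pair_n[b1, b2] += 1
                if err_of[p]:
                    pair_err[b1, b2] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        context = pd.DataFrame(
            np.where(pair_n > 0, pair_err / np.maximum(pair_n, 1), np.nan),
            index=list(bases),
            columns=list(bases),
        )
    total_err = mm + ins + dele
    return AccuracyReport(
        error_rate=total_err / cols if cols else 0.0,
        mismatch_rate=mm / cols if cols else 0.0,
        insertion_rate=ins / cols if cols else 0.0,
        deletion_rate=dele / cols if cols else 0.0,
        n_aligned_columns=cols,
        n_reads=n_used,
        context=context,
    )


# ---------------------------------------------------------------------------
# elongation model
# ---------------------------------------------------------------------------

def expected_length(Q, r: float, s: float):
    """Closed-form mean read length L(Q) = r·s·(1−s^Q)/(1−s); r·Q at s = 1."""
    Q = np.asarray(Q, dtype=float)
    if s == 1.0:
        out = r * Q
    else:
        out = r * s * (1.0 - s**Q) / (1.0 - s)
    return float(out) if out.ndim == 0 else out


def simulate_elongation_mc(
    r: float, s: float, n_quads: int, n_molecules: int = 50_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo mean read length under the survival model.

    Each molecule survives into the next quad with probability ``s`` and
    gains ``r`` nt per active quad.  Returns (mean, standard error), a
    cross-check of :func:`expected_length`.
    """
    rng = np.random.default_rng(seed)
    if s == 1.0:
        active = np.full(n_molecules, n_quads)
    else:
        # quads survived = (geometric trials to first failure) - 1
        active = np.minimum(rng.geometric(1.0 - s, size=n_molecules) - 1, n_quads)
    lengths = r * active
    return float(lengths.mean()), float(lengths.std(ddof=1) / np.sqrt(n_molecules))


@dataclass
class ElongationFit:
    r: float
    s: float
    predictions: dict[int, float]
    residuals: dict[int, float]


def fit_elongation(mean_lengths: dict[int, float]) -> ElongationFit:
    """Fit (r, s) of the elongation model to mean lengths per quad count.

    With exactly two points (Q1, L1), (Q2, L2) the fit is exact: the ratio
    L2/L1 = (1 − s^Q2)/(1 − s^Q1) pins ``s`` (closed form when Q2 = 2·Q1,
    otherwise a bracketed root), and L1 then gives ``r``.  With more points a
    bounded least-squares fit is used.  A single point is rejected as
    non-identifiable.
    """
    pts = sorted((int(q), float(v)) for q, v in mean_lengths.items())
    if len(pts) < 2:
        raise ValueError("at least 2 (Q, mean length) points are required")
    qs = np.array([p[0] for p in pts], dtype=float)
    ls = np.array([p[1] for p in pts], dtype=float)
    if len(pts) == 2:
        (q1, l1), (q2, l2) = pts
        ratio = l2 / l1
        if ratio >= q2 / q1:  # at or beyond the linear (s = 1) limit
            s = 1.0
        elif q2 == 2 * q1:
            s = (ratio - 1.0) ** (1.0 / q1)
        else:
            f = lambda s_: l1 * (1 - s_**q2) - l2 * (1 - s_**q1)
            s = float(optimize.brentq(f, 1e-9, 1 - 1e-12))
        r = l1 / q1 if s == 1.0 else l1 * (1 - s) / (s * (1 - s**q1))
    else:
        def model(q, r_, s_):
            s_ = min(s_, 1.0 - 1e-12)
            return r_ * s_ * (1 - s_**q) / (1 - s_)

        p0 = (ls[0] / qs[0] * 1.5, 0.95)
        (r, s), _ = optimize.curve_fit(
            model, qs, ls, p0=p0, bounds=([1e-9, 1e-9], [np.inf, 1.0]), maxfev=10_000
        )
        r, s = float(r), float(s)
    preds = {int(q): expected_length(q, r, s) for q in qs}
    resid = {int(q): float(l - preds[int(q)]) for q, l in zip(qs, ls)}
    return ElongationFit(r=r, s=s, predictions=preds, residuals=resid)


# ---------------------------------------------------------------------------
# correlations, group tests, worked fractions
# ---------------------------------------------------------------------------

def count_correlation(
    counts_a: dict[str, int], counts_b: dict[str, int], log_transform: bool = False
) -> float:
    """Pearson correlation of per-barcode counts between two runs.

    Requires identical key sets with at least 3 keys; ``log_transform``
    compares log10(count + 1) instead of raw counts.
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("count tables must share the same barcode keys")
    keys = sorted(counts_a)
    if len(keys) < 3:
        raise ValueError("need at least 3 shared barcodes")
    a = np.array([counts_a[k] for k in keys], dtype=float)
    b = np.array([counts_b[k] for k in keys], dtype=float)
    if log_transform:
        a, b = np.log10(a + 1), np.log10(b + 1)
    return float(stats.pearsonr(a, b).statistic)


def compare_lengths(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test on read-length samples.

    Normal approximation with tie correction; returns (U of group_a,
    p-value).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def effective_sample_fraction(*fractions: float) -> float:
    """Overall sampled fraction as the product of stage-wise fractions
    (e.g. loaded amount × scanned area)."""
    out = 1.0
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fractions must be in (0, 1]")
        out *= f
    return out
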