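"""Traces, stop/pause statistics, accuracy, elongation fit, correlations."""

import numpy as np
import pytest

import smsbs as s

from conftest import reads_from_truth, truth_sources


def _read(prov, n_quads=6, rid="fov0_a0_x0_y0"):
    fov, anchor, x, y = s.CalledRead.parse_read_id(rid)
    return s.CalledRead(
        anchor_id=anchor, fov_id=fov, x_px=x, y_px=y,
        seq="A" * len(prov), base_provenance=prov,
        stopped_at_quad=prov[-1][0] if prov else 0,
    )


class TestExtensionTraces:
    def test_one_incorporation_per_quad(self):
        r = _read([(q, 1) for q in range(1, 7)])
        ts = s.extension_traces([r], 6)
        assert ts.traces[0].tolist() == [0, 1, 2, 3, 4, 5, 6]

    def test_pause_plateaus_then_resumes(self):
        r = _read([(1, 1), (3, 1), (4, 1)])
        ts = s.extension_traces([r], 4)
        assert ts.traces[0].tolist() == [0, 1, 1, 2, 3]

    def test_identical_traces_have_zero_sd(self):
        reads = [_read([(1, 1), (2, 1)], rid=f"fov0_a{i}_x0_y0") for i in range(5)]
        ts = s.extension_traces([reads[0]] + reads[1:], 3)
        stats_df = ts.group_stats()
        assert (stats_df.sd == 0).all()
        assert stats_df[stats_df.quad == 2]["mean"].iloc[0] == 2


class TestStopPauseStats:
    def test_common_stop_quad_concentrates_histogram(self):
        reads = [
            _read([(q, 1) for q in range(1, 7)], rid=f"fov0_a{i}_x0_y0")
            for i in range(4)
        ]
        ts = s.extension_traces(reads, 10)
        st = s.stop_pause_stats(ts)
        assert st.stop_histogram[6] == 1.0
        assert st.stop_histogram.sum() == pytest.approx(1.0)

    def test_read_active_at_last_quad_counts_as_reached(self):
        r = _read([(q, 1) for q in range(1, 9)])
        st = s.stop_pause_stats(s.extension_traces([r], 8))
        assert st.reached_last_fraction == 1.0

    def test_reached_last_complements_cumulative_stops(self, noisy_pipeline):
        ts = s.extension_traces(noisy_pipeline["kept"], 24)
        st = s.stop_pause_stats(ts)
        assert st.stop_histogram.sum() == pytest.approx(1.0)
        assert st.reached_last_fraction == pytest.approx(
            1.0 - st.stop_histogram[:-1].sum()
        )

    def test_empty_input(self):
        st = s.stop_pause_stats(s.extension_traces([], 5))
        assert st.n_reads == 0 and st.pause_frequency == 0.0


def test_pause_frequency_recovers_planted_rate():
    """Simulated p_pause = 0.1 with no other error sources is recovered as a
    measured pause frequency of 0.10 +- 0.02 (5,000 molecules)."""
    refs = s.make_barcode_library(5, 60, seed=21)
    cfg = s.RunConfig(
        n_fovs=1, density=5000, fov_size_px=1024, n_quads=24, p_pause=0.10,
        p_dark=0, p_mis=0, p_detach=0, p_cleavefail=0, nonspecific_rate=0,
        drift=s.DriftModel(max_abs_px=0), seed=33,
    )
    sim = s.simulate_run(cfg, refs)
    ts = s.extension_traces(reads_from_truth(sim), 24)
    st = s.stop_pause_stats(ts)
    assert st.pause_frequency == pytest.approx(0.10, abs=0.02)


def _planted_error_reads(n_reads=100, length=120, error_rate=0.05, seed=0):
    """Reads over long sources with independent planted errors, so terminal
    clipping by the local alignment is negligible."""
    rng = np.random.default_rng(seed)
    model = s.ReadModel(
        mean_length=length - 10, sd_length=0, error_rate=error_rate
    )
    reads, sources = [], {}
    for i in range(n_reads):
        src = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
        seq = model.sample_read(src, rng)
        r = _read([(j + 1, 1) for j in range(len(seq))], rid=f"fov0_a{i}_x0_y0")
        r.seq = seq
        reads.append(r)
        sources[r.read_id] = src
    return reads, sources


class TestAccuracyReport:
    def test_noise_free_reads_have_full_accuracy(self, clean_run):
        sim, _ = clean_run
        reads = reads_from_truth(sim)
        sources = {r.read_id: m.track.needed for r, m in
                   zip(reads, sim.molecules)}
        rep = s.accuracy_report(reads, sources)
        assert rep.error_rate == 0.0
        assert rep.accuracy == 1.0

    def test_recovers_planted_five_percent_error(self):
        """A planted 5% per-base error rate is reported as ~95% accuracy
        (within one point, ~10,000 aligned bases)."""
        reads, sources = _planted_error_reads(error_rate=0.05, seed=1)
        rep = s.accuracy_report(reads, sources)
        assert rep.n_aligned_columns >= 10_000
        assert rep.accuracy == pytest.approx(0.95, abs=0.01)

    def test_context_matrix_uniform_when_errors_context_free(self):
        """With context-free planted errors, the off-diagonal dinucleotide
        classes share one rate (the query-base error rate: substitutions +
        insertions, i.e. 2/3 of the planted total); same-base classes can
        only read lower, because gap placement inside a homopolymer is
        ambiguous and the aligner's consistent choice hides second-base
        errors there."""
        reads, sources = _planted_error_reads(
            n_reads=200, error_rate=0.05, seed=2
        )
        rep = s.accuracy_report(reads, sources)
        off = [
            rep.context.loc[b1, b2]
            for b1 in "ACGT"
            for b2 in "ACGT"
            if b1 != b2
        ]
        m = np.mean(off)
        n = 200 * 100 / 16  # approx pairs per class
        band = 5 * np.sqrt(m * (1 - m) / n)
        assert m == pytest.approx(2 / 3 * 0.05, abs=0.01)
        for rate in off:
            assert abs(rate - m) < band
        for b in "ACGT":
            assert rep.context.loc[b, b] <= m + band

    def test_truth_mode_matches_event_log_within_alignment_ambiguity(
        self, noisy_pipeline
    ):
        """The alignment-based error estimate agrees with an independent
        event-log count (errors within the best-scoring event window, i.e.
        what a local alignment can observe) to within 0.5% absolute."""
        kept = noisy_pipeline["kept"]
        mols = truth_sources(noisy_pipeline["sim"], kept)
        sources = {rid: m.track.needed for rid, m in mols.items()}
        rep = s.accuracy_report(kept, sources)

        err = cols = 0
        for r in kept:
            m = mols.get(r.read_id)
            if m is None:
                continue
            vals, is_err = [], []
            prev_dark = False
            for e in m.event_log:
                if e.fate == "incorp":
                    vals.append(1); is_err.append(False); prev_dark = False
                elif e.fate == "dark":
                    vals.append(-1 if prev_dark else -2)
                    is_err.append(True); prev_dark = True
                elif e.fate in ("mis_sub", "mis_ins"):
                    vals.append(-2); is_err.append(True); prev_dark = False
            best, cur, start, span = 0, 0, 0, (0, 0)
            for i, v in enumerate(vals):
                cur += v
                if cur <= 0:
                    cur, start = 0, i + 1
                elif cur > best:
                    best, span = cur, (start, i + 1)
            a, b = span
            err += sum(is_err[a:b])
            cols += b - a
        assert cols > 0
        assert rep.error_rate == pytest.approx(err / cols, abs=0.005)


class TestElongationFit:
    def test_two_point_calibration(self):
        fit = s.fit_elongation({6: 8.1, 12: 13.7})
        assert fit.s == pytest.approx(0.94034, abs=1e-4)
        # the fit reproduces both calibration points exactly
        assert s.expected_length(6, fit.r, fit.s) == pytest.approx(8.1, abs=1e-9)
        assert s.expected_length(12, fit.r, fit.s) == pytest.approx(13.7, abs=1e-9)

    def test_multi_point_self_consistency(self):
        r, sv = 2.0, 0.95
        pts = {q: s.expected_length(q, r, sv) for q in (4, 8, 12, 16, 20, 24)}
        fit = s.fit_elongation(pts)
        assert fit.r == pytest.approx(r, rel=0.01)
        assert fit.s == pytest.approx(sv, rel=0.01)

    def test_linear_limit(self):
        assert s.expected_length(10, 1.5, 1.0) == pytest.approx(15.0)
        fit = s.fit_elongation({5: 7.5, 10: 15.0})
        assert fit.s == 1.0
        assert fit.r == pytest.approx(1.5)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            s.fit_elongation({6: 8.1})


def test_mc_elongation_matches_closed_form():
    mean, se = s.simulate_elongation_mc(1.66487, 0.940344, 6, 50_000, seed=5)
    assert abs(mean - s.expected_length(6, 1.66487, 0.940344)) < 3 * se


class TestCountCorrelation:
    def test_identical_vectors(self):
        c = {f"B{i}": i + 1 for i in range(10)}
        assert s.count_correlation(c, dict(c)) == pytest.approx(1.0)

    def test_anti_ordered_affine_vectors(self):
        a = {f"B{i}": i for i in range(10)}
        b = {f"B{i}": 100 - 3 * i for i in range(10)}
        assert s.count_correlation(a, b) == pytest.approx(-1.0)

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            s.count_correlation({"A": 1, "B": 2, "C": 3}, {"A": 1, "B": 2, "D": 3})

    def test_replicate_runs_correlate_strongly(self):
        """Two seeded replicate simulations of the same 30-barcode sample
        (a shared, unequal loading stoichiometry) at matched depth give
        per-barcode counts with Pearson r > 0.85."""
        refs = s.make_barcode_library(30, 25, seed=11)
        weights = np.random.default_rng(77).lognormal(0, 0.8, size=30)
        counts = []
        for seed in (101, 202):
            cfg = s.RunConfig(
                n_fovs=2, density=400, n_quads=24, nonspecific_rate=0,
                drift=s.DriftModel(max_abs_px=0), seed=seed,
            )
            sim = s.simulate_run(cfg, refs, weights=weights)
            reads = reads_from_truth(sim)
            kept, _ = s.filter_reads(reads, 5)
            results, _ = s.identify_reads(kept, refs, 0.01)
            c = {n: 0 for n in refs.names}
            for r in results:
                if r.best_ref_id != "UNIDENTIFIED":
                    c[r.best_ref_id] += 1
            counts.append(c)
        assert s.count_correlation(*counts) > 0.85


class TestCompareLengths:
    def test_identical_samples_are_not_distinguished(self):
        a = list(range(10, 40))
        u, p = s.compare_lengths(a, list(a))
        assert p > 0.9

    def test_shifted_samples_are_separated(self):
        rng = np.random.default_rng(3)
        a = rng.normal(15, 3, 200)
        u, p = s.compare_lengths(a, a + 10)
        assert p < 1e-10

    def test_u_statistic_matches_pairwise_count(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.integers(0, 15, size=rng.integers(3, 21))
            b = rng.integers(0, 15, size=rng.integers(3, 21))
            u, _ = s.compare_lengths(a, b)
            brute = sum(
                1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
            )
            assert u == pytest.approx(brute)
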