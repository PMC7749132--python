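"""Local alignment, e-values, identification, byproducts, capacity."""

import functools
import math

import numpy as np
import pytest
from scipy import stats

import smsbs as s
from smsbs.identify import PCR_PRIMER, _best_hit, default_byproduct_reference


def _read(seq, rid="fov0_a0_x0_y0"):
    fov, anchor, x, y = s.CalledRead.parse_read_id(rid)
    return s.CalledRead(
        anchor_id=anchor, fov_id=fov, x_px=x, y_px=y, seq=seq,
        base_provenance=[(i + 1, 1) for i in range(len(seq))],
        stopped_at_quad=len(seq),
    )


def oracle_score(q, sub, scoring=s.ScoringScheme()):
    """Independent affine-gap local-alignment score: memoized recursion over
    (i, j, state) with state H (aligned), E (gap in subject), F (gap in
    query); the answer is the max of the H-state over all cell pairs."""

    @functools.lru_cache(maxsize=None)
    def best_end(i, j, state):
        # best score of an alignment path ending at (i, j) in `state`
        if state == "H":
            sc = scoring.match if q[i] == sub[j] else scoring.mismatch
            prev = 0
            if i > 0 and j > 0:
                prev = max(
                    0,
                    best_end(i - 1, j - 1, "H"),
                    best_end(i - 1, j - 1, "E"),
                    best_end(i - 1, j - 1, "F"),
                )
            return prev + sc
        if state == "E":  # consumed q[i], gap in subject
            opts = []
            if i > 0:
                opts.append(best_end(i - 1, j, "H") + scoring.gap_open)
                opts.append(best_end(i - 1, j, "E") + scoring.gap_extend)
            return max(opts, default=-(10**9))
        opts = []  # F: consumed sub[j], gap in query
        if j > 0:
            opts.append(best_end(i, j - 1, "H") + scoring.gap_open)
            opts.append(best_end(i, j - 1, "F") + scoring.gap_extend)
        return max(opts, default=-(10**9))

    best = 0
    for i in range(len(q)):
        for j in range(len(sub)):
            best = max(best, best_end(i, j, "H"))
    return best


class TestLocalAlign:
    def test_identical_15mers_score_15(self):
        seq = "ACGTACGTACGTACG"
        aln = s.local_align(seq, seq)
        assert aln.score == 15
        assert aln.identity == 1.0
        assert aln.query_span == (0, 15)

    def test_single_mismatch_beats_clipping(self):
        a = "ACGTACGAACGTACG"
        b = a[:7] + "C" + a[8:]
        aln = s.local_align(a, b)
        assert aln.score == 12  # 14 matches - 2
        assert aln.mismatches == 1

    def test_empty_query_scores_zero(self):
        assert s.local_align("", "ACGT").score == 0
        assert s.local_align("ACGT", "").score == 0

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            q = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 21)))
            sub = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 21)))
            want = oracle_score(q, sub)
            assert s.sw_score(q, sub) == want
            assert s.local_align(q, sub).score == want


class TestEvalue:
    def test_formula_value(self):
        assert s.evalue(15, 15, 750) == pytest.approx(2.4e-5, rel=0.02)

    def test_linear_in_reference_length(self):
        assert s.evalue(10, 20, 1000) == pytest.approx(2 * s.evalue(10, 20, 500))

    def test_monotone_decreasing_in_score(self):
        evs = [s.evalue(S, 20, 750) for S in range(0, 40, 5)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert evs[-1] < 1e-15


class TestIdentifyReads:
    def test_exact_read_identified(self):
        refs = s.make_barcode_library(30, 25, seed=1)
        name = refs.names[4]
        results, counts = s.identify_reads([_read(refs[name])], refs, 0.01)
        assert results[0].best_ref_id == name
        assert counts.loc[0, name] == 1

    def test_score_tie_is_unidentified(self):
        refs = s.ReferenceSet({"X": "ACGTACGTACGTACG", "Y": "ACGTACGTACGTACT"})
        # read matches both on the first 14 bases equally
        results, _ = s.identify_reads([_read("ACGTACGTACGTAC")], refs, 0.01)
        assert results[0].best_ref_id == "UNIDENTIFIED"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            s.identify_reads([_read("ACGT")], s.ReferenceSet({}), 0.01)

    def test_noisy_reads_identified_as_their_source(self):
        """Reads from barcode #7 with 5% per-base error and length >= 15 are
        nearly always identified as #7 and never as another barcode."""
        refs = s.make_barcode_library(30, 25, seed=1)
        src = refs.names[7]
        model = s.ReadModel(mean_length=20, sd_length=3, error_rate=0.05)
        rng = np.random.default_rng(7)
        reads = []
        i = 0
        while len(reads) < 100:
            seq = model.sample_read(refs[src], rng)
            if len(seq) >= 15:
                reads.append(_read(seq, f"fov0_a{i}_x0_y0"))
                i += 1
        results, _ = s.identify_reads(reads, refs, 0.01)
        as_src = sum(r.best_ref_id == src for r in results)
        as_other = sum(
            r.best_ref_id not in (src, "UNIDENTIFIED") for r in results
        )
        assert as_src >= 95
        assert as_other == 0

    def test_error_free_library_identification_is_complete(self):
        """Every error-free full-length read of a min-Hamming-8 library is
        identified at threshold 0.01."""
        refs = s.make_barcode_library(30, 25, seed=9, min_pairwise_hamming=8)
        reads = [_read(seq, f"fov0_a{i}_x0_y0") for i, seq in enumerate(refs.sequences)]
        results, _ = s.identify_reads(reads, refs, 0.01)
        assert all(r.best_ref_id == n for r, n in zip(results, refs.names))


class TestByproducts:
    def test_read_containing_primer_flagged(self):
        flags = s.flag_byproducts([_read("TT" + PCR_PRIMER + "AC")])
        assert all(flags.values())

    def test_random_dissimilar_read_unflagged(self):
        flags = s.flag_byproducts([_read("ATCGATTGCCAGTCGCAGGT")])
        assert not any(flags.values())

    def test_empty_byproduct_set_flags_nothing(self):
        flags = s.flag_byproducts([_read(PCR_PRIMER)], s.ReferenceSet({}))
        assert not any(flags.values())


class TestCapacity:
    def test_single_reference_has_no_false_positives(self):
        curve = s.capacity_curve(s.ReadModel(), sizes=[1], n_reads=30, seed=1)
        assert curve.rates.false_positive_rate.iloc[0] == 0.0

    def test_error_free_full_length_reads_never_misassigned(self):
        model = s.ReadModel(mean_length=15, sd_length=0, error_rate=0.0)
        curve = s.capacity_curve(model, sizes=[1, 10, 50], n_reads=30, seed=2)
        assert (curve.rates.false_positive_rate == 0).all()

    def test_fp_rate_nondecreasing_in_reference_size(self):
        """Spearman correlation between reference size and FP rate is
        non-negative in expectation over 20 seeds."""
        model = s.ReadModel(mean_length=12, sd_length=3, error_rate=0.10)
        sizes = [1, 5, 15, 40, 80]
        fp = np.zeros(len(sizes))
        for sd in range(20):
            curve = s.capacity_curve(model, sizes=sizes, n_reads=25, seed=sd)
            fp += curve.rates.sort_values("k").false_positive_rate.to_numpy()
        rho = stats.spearmanr(sizes, fp).statistic
        assert rho >= 0

    def test_fp_rate_decreases_with_barcode_length(self):
        model = s.ReadModel(mean_length=30, sd_length=5, error_rate=0.10)
        def mean_fp(blen):
            vals = []
            for sd in range(10):
                c = s.capacity_curve(
                    model, sizes=[60], n_reads=25, barcode_len=blen, seed=sd
                )
                vals.append(c.rates.false_positive_rate.iloc[0])
            return np.mean(vals)
        assert mean_fp(8) >= mean_fp(20)


class TestMultiplexCapacity:
    def test_single_target_never_incorrect(self):
        out = s.estimate_multiplex_capacity(1, n_reads=50, seed=3)
        assert out["incorrect_rate"] == 0.0
        assert out["correct_rate"] == pytest.approx(1 - out["unidentified_rate"])

    def test_long_barcodes_and_no_errors_identify_perfectly(self):
        model = s.ReadModel(mean_length=30, sd_length=0, error_rate=0.0)
        out = s.estimate_multiplex_capacity(
            20, barcode_len=30, read_model=model, n_reads=50, seed=4
        )
        assert out["correct_rate"] == 1.0

    def test_budget_warning(self):
        with pytest.warns(UserWarning):
            s.estimate_multiplex_capacity(
                10, n_reads=10, seed=5, work_budget=10
            )
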