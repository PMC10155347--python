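"""Read scoring, normalization, dual-threshold classification and ROC,
checked against independent brute-force reimplementations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylotype import (
    ReadMethylProfile,
    ReadSimSpec,
    ValidationError,
    classify_read,
    classify_sample,
    normalize_score,
    roc_sweep,
    score_read,
    simulate_reads,
)


def _read(calls, read_id="r", chrom="chrS"):
    positions = [p for p, _ in calls]
    start = min(positions) if positions else 0
    end = max(positions) + 1 if positions else 1
    return ReadMethylProfile(read_id, chrom, start, end, calls)


def brute_force_score(read, reference):
    """Independent oracle: literal per-site evaluation of the branch rule."""
    contributions = []
    for pos, m in read.calls:
        key = (read.chrom, pos)
        if key not in reference:
            continue
        mp = reference[key]
        contributions.append(mp if m == 1 else 100.0 - mp)
    if not contributions:
        return None, 0
    return sum(contributions) / len(contributions), len(contributions)


class TestScoreRead:
    def test_hand_computed_branch_formula(self):
        # m=[1,0,1] at m'=[80,30,90] -> (80 + 70 + 90)/3 = 80.0
        read = _read([(10, 1), (20, 0), (30, 1)])
        ref = {("chrS", 10): 80.0, ("chrS", 20): 30.0, ("chrS", 30): 90.0}
        f, n = score_read(read, ref)
        assert f == pytest.approx(80.0)
        assert n == 3

    @pytest.mark.parametrize("m,mp,expected", [(1, 100.0, 100.0), (0, 100.0, 0.0)])
    def test_perfect_match_and_mismatch(self, m, mp, expected):
        f, n = score_read(_read([(10, m)]), {("chrS", 10): mp})
        assert (f, n) == (expected, 1)

    def test_read_with_no_reference_sites_skipped(self):
        f, n = score_read(_read([(10, 1)]), {("chrS", 99): 50.0})
        assert (f, n) == (None, 0)

    def test_linearity_over_disjoint_site_sets(self):
        ref = {("chrS", p): float(5 * p % 101) for p in range(1, 40)}
        a = _read([(p, p % 2) for p in range(1, 20)])
        b = _read([(p, p % 2) for p in range(20, 40)])
        both = _read([(p, p % 2) for p in range(1, 40)])
        fa, na = score_read(a, ref)
        fb, nb = score_read(b, ref)
        fboth, nboth = score_read(both, ref)
        assert nboth == na + nb
        assert fboth == pytest.approx((fa * na + fb * nb) / (na + nb))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 1),
                      st.floats(0, 100)),
            min_size=1, max_size=30,
            unique_by=lambda t: t[0],
        )
    )
    def test_matches_brute_force_on_random_reads(self, triples):
        triples = sorted(triples)
        read = _read([(p, m) for p, m, _ in triples])
        ref = {("chrS", p): mp for p, _, mp in triples}
        f, n = score_read(read, ref)
        f_oracle, n_oracle = brute_force_score(read, ref)
        assert n == n_oracle
        assert f == pytest.approx(f_oracle)


class TestNormalizeAndClassify:
    def test_symmetry_at_equal_scores(self):
        assert normalize_score(42.0, 42.0) == pytest.approx(0.5)

    def test_ratio_arithmetic(self):
        assert normalize_score(90.0, 10.0) == pytest.approx(0.9)

    def test_zero_denominator_undefined(self):
        assert normalize_score(0.0, 0.0) is None

    @pytest.mark.parametrize(
        "p,expected",
        [(0.05, "immune"), (0.95, "tumor"), (0.9, "unclassified"),
         (0.1, "unclassified"), (0.5, "unclassified")],
    )
    def test_dual_threshold_strict_boundaries(self, p, expected):
        assert classify_read(p, 0.1, 0.9) == expected

    def test_thresholds_out_of_order_rejected(self):
        with pytest.raises(ValidationError):
            classify_read(0.5, 0.9, 0.1)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        ps = rng.random(500)
        tumor_counts = [
            sum(classify_read(p, 0.1, ct) == "tumor" for p in ps)
            for ct in [0.5, 0.7, 0.9, 0.99]
        ]
        assert tumor_counts == sorted(tumor_counts, reverse=True)
        immune_counts = [
            sum(classify_read(p, it, 0.9) == "immune" for p in ps)
            for it in [0.4, 0.2, 0.1, 0.01]
        ]
        assert immune_counts == sorted(immune_counts, reverse=True)


class TestClassifySample:
    def test_swapping_references_flips_p(self, realistic_sites, realistic_refs):
        tumor, _, _ = realistic_refs
        reads, _ = simulate_reads(tumor, ReadSimSpec(n_reads=100, seed=8))
        scores_fwd, _ = classify_sample(reads, realistic_sites)
        swapped = realistic_sites.rename(
            columns={"pct_tumor": "pct_immune", "pct_immune": "pct_tumor"}
        )
        scores_rev, _ = classify_sample(reads, swapped)
        for a, b in zip(scores_fwd, scores_rev):
            if a.p is None:
                assert b.p is None
            else:
                assert b.p == pytest.approx(1.0 - a.p)

    def test_separable_reads_all_true_origin(self, separable_refs, separable_sites):
        tumor, immune, _ = separable_refs
        t_reads, _ = simulate_reads(tumor, ReadSimSpec(n_reads=200, seed=1))
        i_reads, _ = simulate_reads(immune, ReadSimSpec(n_reads=200, seed=2))
        t_scores, t_summary = classify_sample(t_reads, separable_sites)
        i_scores, i_summary = classify_sample(i_reads, separable_sites)
        assert t_summary.n_tumor == t_summary.n_scored
        assert i_summary.n_immune == i_summary.n_scored
        assert t_summary.tumor_read_fraction == 1.0
        assert i_summary.tumor_read_fraction == 0.0

    def test_summary_matches_brute_force_recount(self, realistic_refs,
                                                 realistic_sites):
        tumor, immune, _ = realistic_refs
        t_reads, _ = simulate_reads(tumor, ReadSimSpec(n_reads=500, seed=31))
        i_reads, _ = simulate_reads(immune, ReadSimSpec(n_reads=500, seed=32))
        reads = t_reads + i_reads
        scores, summary = classify_sample(reads, realistic_sites)

        ref_t = {
            (c, int(p)): float(v)
            for c, p, v in zip(realistic_sites["chrom"],
                               realistic_sites["pos"],
                               realistic_sites["pct_tumor"])
        }
        ref_i = {
            (c, int(p)): float(v)
            for c, p, v in zip(realistic_sites["chrom"],
                               realistic_sites["pos"],
                               realistic_sites["pct_immune"])
        }
        counts = {"tumor": 0, "immune": 0, "unclassified": 0, "skipped": 0}
        for read in reads:
            ft, nt = brute_force_score(read, ref_t)
            fi, _ = brute_force_score(read, ref_i)
            if ft is None or ft + fi == 0:
                counts["skipped"] += 1
            else:
                p = ft / (ft + fi)
                if p < 0.1:
                    counts["immune"] += 1
                elif p > 0.9:
                    counts["tumor"] += 1
                else:
                    counts["unclassified"] += 1
        assert summary.n_tumor == counts["tumor"]
        assert summary.n_immune == counts["immune"]
        assert summary.n_unclassified == counts["unclassified"]
        assert summary.n_total - summary.n_scored == counts["skipped"]

    def test_empty_site_table_rejected(self):
        empty = pd.DataFrame(
            columns=["chrom", "pos", "pct_tumor", "pct_immune",
                     "cov_tumor", "cov_immune"]
        )
        with pytest.raises(ValidationError):
            classify_sample([_read([(10, 1)])], empty)


class TestExpectedScoreIdentity:
    def test_self_match_closed_form(self, realistic_refs, realistic_sites):
        # E[f_self] = mean over covered sites of (m'^2 + (100-m')^2)/100
        tumor, _, _ = realistic_refs
        reads, _ = simulate_reads(tumor, ReadSimSpec(n_reads=20_000, seed=13))
        ref_t = {
            (c, int(p)): float(v)
            for c, p, v in zip(realistic_sites["chrom"],
                               realistic_sites["pos"],
                               realistic_sites["pct_tumor"])
        }
        fs, expected_site_scores = [], []
        for read in reads:
            f, n = score_read(read, ref_t)
            if f is None:
                continue
            fs.append((f, n))
            for pos, _ in read.calls:
                mp = ref_t.get((read.chrom, pos))
                if mp is not None:
                    expected_site_scores.append(
                        (mp**2 + (100.0 - mp) ** 2) / 100.0
                    )
        # compare site-weighted empirical mean against the closed form
        total_sites = sum(n for _, n in fs)
        empirical = sum(f * n for f, n in fs) / total_sites
        closed_form = np.mean(expected_site_scores)
        assert empirical == pytest.approx(closed_form, abs=1.0)


class TestRocSweep:
    def _scores_and_truth(self, reads, sites, truth_frames):
        scores, _ = classify_sample(reads, sites)
        truth = pd.concat(truth_frames, ignore_index=True)
        return scores, truth

    def test_separable_auc_is_exactly_one(self, separable_refs, separable_sites):
        tumor, immune, _ = separable_refs
        t_reads, t_truth = simulate_reads(tumor, ReadSimSpec(n_reads=300, seed=41))
        i_reads, i_truth = simulate_reads(immune, ReadSimSpec(n_reads=300, seed=42))
        scores, truth = self._scores_and_truth(
            t_reads + i_reads, separable_sites, [t_truth, i_truth]
        )
        result = roc_sweep(scores, truth)
        assert result.auc_stringent == 1.0
        assert all(v == 1.0 for v in result.auc.values())

    def test_permuted_labels_auc_near_half(self, realistic_refs, realistic_sites):
        tumor, immune, _ = realistic_refs
        t_reads, t_truth = simulate_reads(tumor, ReadSimSpec(n_reads=1000, seed=51))
        i_reads, i_truth = simulate_reads(immune, ReadSimSpec(n_reads=1000, seed=52))
        scores, truth = self._scores_and_truth(
            t_reads + i_reads, realistic_sites, [t_truth, i_truth]
        )
        rng = np.random.default_rng(7)
        truth = truth.assign(origin=rng.permutation(truth["origin"].to_numpy()))
        result = roc_sweep(scores, truth)
        assert result.auc_stringent == pytest.approx(0.5, abs=0.06)

    def test_grid_matches_confusion_matrix_oracle(self, realistic_refs,
                                                  realistic_sites):
        tumor, immune, _ = realistic_refs
        t_reads, t_truth = simulate_reads(tumor, ReadSimSpec(n_reads=400, seed=61))
        i_reads, i_truth = simulate_reads(immune, ReadSimSpec(n_reads=400, seed=62))
        scores, truth = self._scores_and_truth(
            t_reads + i_reads, realistic_sites, [t_truth, i_truth]
        )
        immune_grid = [0.1, 0.3]
        cancer_grid = [0.6, 0.9]
        result = roc_sweep(scores, truth, immune_grid, cancer_grid)
        origin = dict(zip(truth["read_id"], truth["origin"]))
        for row in result.grid.itertuples():
            tp = fn = tn = fp = 0
            for s in scores:
                if s.p is None:
                    continue
                call = ("tumor" if s.p > row.cancer_threshold
                        else "immune" if s.p < row.immune_threshold
                        else None)
                if call is None:
                    continue
                truth_label = origin[s.read_id]
                if truth_label == "tumor":
                    tp += call == "tumor"
                    fn += call == "immune"
                else:
                    tn += call == "immune"
                    fp += call == "tumor"
            assert row.sensitivity == pytest.approx(tp / (tp + fn))
            assert row.specificity == pytest.approx(tn / (tn + fp))

    def test_missing_truth_label_rejected(self, separable_sites, separable_refs):
        tumor, _, _ = separable_refs
        reads, _ = simulate_reads(tumor, ReadSimSpec(n_reads=5, seed=1))
        scores, _ = classify_sample(reads, separable_sites)
        with pytest.raises(ValidationError, match="truth"):
            roc_sweep(scores, pd.DataFrame({"read_id": [], "origin": []}))
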