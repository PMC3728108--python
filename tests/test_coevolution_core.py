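"""Covariation statistic: divergence times, site vectors, correlations, null."""

import math

import numpy as np
import pytest

from coevnet import coevolution_core as cc
from coevnet import synthetic_data as sd
from coevnet.io_formats import Alignment, Phylogeny


def aln_of(*rows, ids=None, alphabet="protein"):
    ids = ids or tuple(f"s{k}" for k in range(len(rows)))
    return Alignment(ids=tuple(ids), rows=tuple(rows), alphabet=alphabet)


class TestDivergenceTimes:
    def test_patristic_branch_sum(self):
        aln = aln_of("ACDE", "ACDF", ids=("A", "B"))
        tree = Phylogeny.from_newick("(A:0.1,B:0.2);")
        t = cc.divergence_times(aln, "patristic", tree=tree)
        assert t.matrix[0, 1] == pytest.approx(0.3)
        assert t.mode == "patristic"

    def test_poisson_closed_form(self):
        # 1 mismatch over 10 columns -> p = 0.1 -> t = -ln(0.9)
        aln = aln_of("AAAAAAAAAA", "AAAAAAAAAC")
        t = cc.divergence_times(aln, "poisson_protein")
        assert t.matrix[0, 1] == pytest.approx(-math.log(0.9))

    def test_identical_cds_floored(self):
        aln = aln_of("MA", "MA")
        cds = aln_of("ATGGCT", "ATGGCT", alphabet="dna")
        t = cc.divergence_times(aln, "li_ks", cds=cds)
        assert t.pair_times()[0] == pytest.approx(t.floor)

    def test_li_ks_positive_for_synonymous_changes(self):
        tree = sd.simulate_tree(6, 0.3, seed=3)
        aln, _ = sd.evolve_alignment(tree, 40, seed=4)
        cds = sd.emit_cds(aln, seed=5, synonymous_divergence=0.3)
        t = cc.divergence_times(aln, "li_ks", cds=cds)
        off_diag = t.matrix[np.triu_indices(aln.n_sequences, k=1)]
        assert (off_diag >= 0).all()
        assert off_diag.max() > 0

    def test_symmetry_and_zero_diagonal(self):
        aln = aln_of("ACDEFG", "ACDEFH", "ACDEHH")
        t = cc.divergence_times(aln, "poisson_protein")
        assert np.allclose(t.matrix, t.matrix.T)
        assert np.allclose(np.diag(t.matrix), 0)

    def test_saturated_pair_replaced_by_max(self):
        # complete mismatch -> p = 1 -> -ln(0) undefined -> matrix max
        aln = aln_of("AAAA", "CCCC", "AAAC")
        t = cc.divergence_times(aln, "poisson_protein")
        assert ("s0", "s1") in t.saturated_pairs
        finite_max = -math.log(1 - 0.75)  # s1 vs s2, the largest finite entry
        assert t.matrix[0, 1] == pytest.approx(finite_max)


class TestSiteVector:
    def test_invariant_column_centers_to_zero(self):
        aln = aln_of("AA", "AA", "AA")
        t = cc.divergence_times(aln, "poisson_protein")
        v = cc.site_vector(aln, 1, t)
        assert np.allclose(v.values, 0.0)

    def test_single_pair_centers_to_zero(self):
        aln = aln_of("A", "A")
        t = cc.divergence_times(aln, "poisson_protein")
        v = cc.site_vector(aln, 1, t)
        assert v.values[0] == pytest.approx(0.0)

    def test_hand_arithmetic_three_sequences(self):
        # residues A,A,S; B(A,A)=4, B(A,S)=1 -> raw (4,1,1), mean 2 ->
        # centered (2,-1,-1); divergence times all equal so the centered
        # pattern survives up to the common scale
        aln = aln_of("AC", "AC", "SC")
        n = 3
        times = cc.DivergenceMatrix(
            ids=aln.ids, matrix=np.ones((n, n)) - np.eye(n), mode="patristic"
        )
        v = cc.site_vector(aln, 1, times)
        assert np.allclose(v.values, [2.0, -1.0, -1.0])

    def test_gapped_pairs_masked(self):
        aln = aln_of("A-", "AC", "SC")
        t = cc.divergence_times(aln, "poisson_protein")
        v = cc.site_vector(aln, 2, t)
        # pairs: (s0,s1) and (s0,s2) involve the gap row at column 2
        assert np.isnan(v.values[0]) and np.isnan(v.values[1])
        assert np.isfinite(v.values[2])


class TestPairCorrelation:
    def test_self_is_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        r, reason = cc.pair_correlation(v, v)
        assert r == pytest.approx(1.0)
        assert reason is None

    def test_negated_is_minus_one(self):
        v = np.array([1.0, 2.0, 3.0])
        r, _ = cc.pair_correlation(v, -v)
        assert r == pytest.approx(-1.0)

    def test_hand_pearson(self):
        r, _ = cc.pair_correlation(
            np.array([2.0, -1.0, -1.0]), np.array([-1.0, 2.0, -1.0])
        )
        assert r == pytest.approx(-0.5)

    def test_constant_vector_skipped(self):
        r, reason = cc.pair_correlation(
            np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])
        )
        assert math.isnan(r)
        assert reason == "zero variance"

    def test_insufficient_overlap_skipped(self):
        x = np.array([1.0, 2.0, np.nan, np.nan])
        y = np.array([1.0, np.nan, 2.0, np.nan])
        r, reason = cc.pair_correlation(x, y)
        assert reason == "insufficient overlap"

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r_xy, _ = cc.pair_correlation(x, y)
        r_yx, _ = cc.pair_correlation(y, x)
        r_scaled, _ = cc.pair_correlation(3.7 * x, 3.7 * y)
        assert r_xy == pytest.approx(r_yx)
        assert r_xy == pytest.approx(r_scaled)


class TestCorrelationMatrixConsistency:
    def test_matches_pairwise_on_gapped_data(self):
        rng = np.random.default_rng(2)
        V = rng.normal(size=(6, 30))
        V[rng.random(size=V.shape) < 0.15] = np.nan
        R = cc.correlation_matrix(V)
        for i in range(6):
            for j in range(i + 1, 6):
                r, reason = cc.pair_correlation(V[i], V[j])
                if reason is None:
                    assert R[i, j] == pytest.approx(r, abs=1e-10)

    def test_row_pair_matches_matrix(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(8, 25))
        ii = np.array([0, 1, 2, 5])
        jj = np.array([3, 4, 6, 7])
        R = cc.correlation_matrix(V)
        r = cc.row_pair_correlations(V, ii, jj)
        for k in range(4):
            assert r[k] == pytest.approx(R[ii[k], jj[k]], abs=1e-10)


class TestTimeScalingInvariance:
    def test_correlations_invariant_to_time_rescaling(self, neutral_dataset):
        aln, tree, times = neutral_dataset
        scaled = cc.DivergenceMatrix(
            ids=times.ids, matrix=3.0 * times.matrix, mode=times.mode,
            floor=3.0 * times.floor,
        )
        V1, _ = cc.site_vector_matrix(aln, times)
        V2, _ = cc.site_vector_matrix(aln, scaled)
        iu = np.triu_indices(40, k=1)
        r1 = cc.row_pair_correlations(V1[:40], iu[0], iu[1])
        r2 = cc.row_pair_correlations(V2[:40], iu[0], iu[1])
        both = np.isfinite(r1) & np.isfinite(r2)
        assert np.allclose(r1[both], r2[both], atol=1e-9)


class TestNullModel:
    def test_quantile_with_outlier(self):
        samples = np.sort(np.array([0.0] * 999 + [0.9]))
        null = cc.NullModel(samples=samples, n_sim_alignments=1, seed=0)
        assert null.threshold(0.001) == pytest.approx(0.9)

    def test_median_of_symmetric_sample(self):
        rng = np.random.default_rng(4)
        samples = np.sort(rng.normal(scale=0.2, size=10001))
        null = cc.NullModel(samples=samples, n_sim_alignments=1, seed=0)
        assert abs(null.threshold(0.5)) < 0.02

    def test_threshold_monotone_in_alpha(self, small_null):
        alphas = [0.5, 0.1, 0.01, 0.001]
        thresholds = [small_null.threshold(a) for a in alphas]
        assert thresholds == sorted(thresholds)

    def test_same_seed_identical(self, neutral_dataset):
        aln, tree, times = neutral_dataset
        n1 = cc.build_null(aln, tree, times, 3, 5000, seed=42)
        n2 = cc.build_null(aln, tree, times, 3, 5000, seed=42)
        assert np.array_equal(n1.samples, n2.samples)

    def test_addone_exceedance(self):
        null = cc.NullModel(
            samples=np.sort(np.linspace(0, 1, 999)), n_sim_alignments=1, seed=0
        )
        p = null.exceedance_p(2.0)  # above all samples
        assert p == pytest.approx(1.0 / 1000)

    def test_randomized_tie_break_reproducible(self, small_null):
        r = np.array([0.5, 0.9, 1.0])
        p1 = small_null.exceedance_p(r, rng=np.random.default_rng(5))
        p2 = small_null.exceedance_p(r, rng=np.random.default_rng(5))
        assert np.array_equal(p1, p2)


class TestDetection:
    def test_duplicated_columns_detected(self, neutral_dataset, small_null):
        """Two duplicated non-constant columns are flagged at alpha=0.001."""
        aln, tree, times = neutral_dataset
        # duplicate a variable multi-state column onto another position
        arr = aln.to_char_array()
        counts = [len(set(arr[:, c])) for c in range(aln.length)]
        src = int(np.argmax(counts))
        dst = src + 1 if src + 1 < aln.length else src - 1
        rows = [
            r[:dst] + r[src] + r[dst + 1 :] for r in aln.rows
        ]
        aln2 = Alignment(aln.ids, tuple(rows))
        res = cc.detect_intra(aln2, times, 0.001, small_null, seed=6)
        key = (min(src, dst) + 1, max(src, dst) + 1)
        hit = [r for r in res if (r.site_a, r.site_b) == key]
        assert len(hit) == 1
        assert hit[0].r == pytest.approx(1.0)
        assert hit[0].significant

    def test_invariant_column_skipped(self, neutral_dataset, small_null):
        aln, tree, times = neutral_dataset
        rows = ["A" + r[1:] for r in aln.rows]
        aln2 = Alignment(aln.ids, tuple(rows))
        res = cc.detect_intra(aln2, times, 0.001, small_null, seed=7)
        first_col = [r for r in res if r.site_a == 1]
        assert all(r.skip_reason == "zero variance" for r in first_col)
        assert not any(r.significant for r in first_col)

    def test_inter_requires_paired_rows(self, neutral_dataset, small_null):
        aln, tree, times = neutral_dataset
        other = Alignment(aln.ids[:-1], aln.rows[:-1])
        with pytest.raises(ValueError, match="paired"):
            cc.detect_inter(aln, other, times, 0.001, small_null)

    def test_cross_protein_planted_pair_detected(self):
        tree = sd.simulate_tree(30, 0.5, seed=20)
        aln_a, aln_b, _ = sd.evolve_protein_pair(
            tree, 50, 50,
            cross_planted=[sd.PlantedPair(7, 13, 1.0)],
            seed=21,
        )
        combined = Alignment(
            aln_a.ids,
            tuple(a + b for a, b in zip(aln_a.rows, aln_b.rows)),
        )
        times = cc.divergence_times(combined, "patristic", tree=tree)
        null = cc.build_null(combined, tree, times, 10, 20_000, seed=22)
        res = cc.detect_inter(aln_a, aln_b, times, 0.001, null, seed=23)
        hit = [r for r in res if (r.site_a, r.site_b) == (7, 13)]
        assert len(hit) == 1
        assert hit[0].significant
        assert hit[0].r == pytest.approx(1.0)
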