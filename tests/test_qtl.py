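"""Tests for HMM genotype probabilities, imputation and LOD scans."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import cssqtl as c
from cssqtl.data import F2_PRIOR, MISSING, GenotypeMatrix
from cssqtl.qtl import (
    QtlScan,
    _ScanKernel,
    _transition_matrix,
    build_grid,
    genotype_probabilities,
    impute_genotypes,
    lod_support_interval,
)
from cssqtl.sim import haldane_recombination_fraction


def _enumerate_posterior(calls, grid_cm, marker_cols, error_rate=0.0):
    """Brute-force hidden-state posterior over a small grid by enumeration."""
    P = len(grid_cm)
    trans = [
        _transition_matrix(float(haldane_recombination_fraction(grid_cm[i + 1] - grid_cm[i])))
        for i in range(P - 1)
    ]
    post = np.zeros((P, 3))
    total = 0.0
    for states in product(range(3), repeat=P):
        pr = F2_PRIOR[states[0]]
        for i in range(P - 1):
            pr *= trans[i][states[i], states[i + 1]]
        for pos, col in enumerate(marker_cols):
            if col is None:
                continue
            obs = calls[col]
            if obs == MISSING:
                continue
            pr *= (1 - error_rate) if states[pos] == obs else error_rate / 2
        total += pr
        for pos in range(P):
            post[pos, states[pos]] += pr
    return post / total


class TestGenotypeProbabilities:
    def test_typed_marker_is_certain(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 20, seed=0, missing_rate=0.0)
        probs = genotype_probabilities(geno, step_cm=2.0, error_rate=0.0)
        marker_pos = probs.grid.marker_col >= 0
        for p_idx in np.where(marker_pos)[0]:
            col = probs.grid.marker_col[p_idx]
            for i in range(20):
                triple = probs.probs[i, p_idx]
                assert triple[geno.calls[i, col]] == pytest.approx(1.0, abs=1e-9)

    def test_untyped_individual_gets_f2_prior(self, small_map):
        calls = np.full((1, small_map.n_markers), MISSING, dtype=np.int8)
        geno = GenotypeMatrix(["i1"], small_map, calls)
        probs = genotype_probabilities(geno, step_cm=1.0)
        np.testing.assert_allclose(probs.probs[0], np.tile(F2_PRIOR, (probs.grid.n_positions, 1)),
                                   atol=1e-12)

    def test_midpoint_between_opposite_homozygotes(self, two_marker_map):
        geno = GenotypeMatrix(["i1"], two_marker_map, np.array([[0, 2]], dtype=np.int8))
        probs = genotype_probabilities(geno, step_cm=10.0, error_rate=0.0)
        oracle = _enumerate_posterior(geno.calls[0], probs.grid.positions_cm,
                                      [0, None, 1])
        assert np.abs(probs.probs[0] - oracle).max() < 1e-12

    @pytest.mark.parametrize("g1,g2", list(product([0, 1, 2, MISSING], repeat=2)))
    def test_forward_backward_matches_enumeration(self, two_marker_map, g1, g2):
        geno = GenotypeMatrix(["i1"], two_marker_map,
                              np.array([[g1, g2]], dtype=np.int8))
        probs = genotype_probabilities(geno, step_cm=5.0, error_rate=0.002)
        cols = [c if c >= 0 else None for c in probs.grid.marker_col]
        oracle = _enumerate_posterior(geno.calls[0], probs.grid.positions_cm, cols,
                                      error_rate=0.002)
        assert np.abs(probs.probs[0] - oracle).max() < 1e-12

    def test_pseudomarker_spacing(self, small_map):
        grid = build_grid(small_map, step_cm=0.7)
        gaps = np.diff(grid.positions_cm)
        assert gaps.max() <= 0.7 + 1e-12

    def test_probabilities_sum_to_one(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 50, seed=1, missing_rate=0.3)
        probs = genotype_probabilities(geno, step_cm=1.0)
        np.testing.assert_allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)


class TestImputation:
    def test_complete_data_draws_equal_observations(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 30, seed=2, missing_rate=0.0)
        probs = genotype_probabilities(geno, step_cm=1000.0, error_rate=0.0)
        imp = impute_genotypes(probs, 5, seed=0)
        for d in range(5):
            assert (imp.draws[d] == geno.calls).all()

    def test_marginal_frequencies_match_probabilities(self, two_marker_map):
        geno = GenotypeMatrix(["i1"], two_marker_map, np.array([[0, 2]], dtype=np.int8))
        probs = genotype_probabilities(geno, step_cm=10.0, error_rate=0.0)
        imp = impute_genotypes(probs, 10_000, seed=3)
        mid = 1  # pseudomarker between the two markers
        freq = np.bincount(imp.draws[:, 0, mid], minlength=3) / 10_000
        np.testing.assert_allclose(freq, probs.probs[0, mid], atol=0.02)

    def test_same_seed_identical(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 20, seed=4, missing_rate=0.2)
        probs = genotype_probabilities(geno)
        a = impute_genotypes(probs, 8, seed=11)
        b = impute_genotypes(probs, 8, seed=11)
        assert (a.draws == b.draws).all()

    def test_draws_respect_linkage(self, two_marker_map):
        """Draws must come from the joint chain, not independent marginals:
        with both flanking markers missing, adjacent tightly-linked positions
        should almost always agree within a draw."""
        mm = c.MarkerMap(two_marker_map.table.assign(position_cm=[0.0, 1.0]))
        geno = GenotypeMatrix(["i1"], mm, np.array([[MISSING, MISSING]], dtype=np.int8))
        probs = genotype_probabilities(geno, step_cm=1.0)
        imp = impute_genotypes(probs, 2_000, seed=5)
        agree = (imp.draws[:, 0, 0] == imp.draws[:, 0, -1]).mean()
        assert agree > 0.95  # r(1 cM) ~ 0.0099; independence would give ~0.375


def _direct_lod(y, calls):
    """Two-degree-of-freedom least-squares LOD at each marker."""
    n = len(y)
    yc = y - y.mean()
    rss0 = (yc**2).sum()
    out = []
    for j in range(calls.shape[1]):
        X = np.column_stack([
            np.ones(n), calls[:, j] - 1.0, (calls[:, j] == 1).astype(float)
        ])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = ((y - X @ beta) ** 2).sum()
        out.append(0.5 * n * np.log10(rss0 / rss1))
    return np.array(out)


class TestScan:
    def test_matches_direct_least_squares(self, small_map):
        for seed in range(3):
            geno = c.simulate_f2_genotypes(small_map, 60, seed=seed, missing_rate=0.0)
            rng = np.random.default_rng(100 + seed)
            y = rng.standard_normal(60) + 0.8 * (geno.calls[:, 7] - 1.0)
            probs = genotype_probabilities(geno, step_cm=1000.0, error_rate=0.0)
            imp = impute_genotypes(probs, 1, seed=seed)
            scan = c.scan_trait(y, imp)
            oracle = _direct_lod(y, geno.calls)
            assert np.abs(scan.lod - oracle).max() < 1e-8

    def test_null_trait_lod_stays_low(self, small_map):
        max_lods, mean_lods = [], []
        for seed in range(300):
            geno = c.simulate_f2_genotypes(small_map, 100, seed=seed, missing_rate=0.0)
            y = np.random.default_rng(500 + seed).standard_normal(100)
            probs = genotype_probabilities(geno, step_cm=1000.0, error_rate=0.0)
            imp = impute_genotypes(probs, 1, seed=seed)
            scan = c.scan_trait(y, imp)
            max_lods.append(scan.peak_lod)
            mean_lods.append(scan.lod.mean())
        assert np.median(max_lods) < 2.0
        assert np.mean(mean_lods) < 0.5

    def test_perfect_fit_capped(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 60, seed=6, missing_rate=0.0)
        y = (geno.calls[:, 4] - 1.0).astype(float)
        probs = genotype_probabilities(geno, step_cm=1000.0, error_rate=0.0)
        imp = impute_genotypes(probs, 1, seed=0)
        scan = c.scan_trait(y, imp)
        assert scan.peak_lod == 50.0
        assert scan.peak_index == 4

    def test_affine_invariance(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 50, seed=7, missing_rate=0.05)
        rng = np.random.default_rng(7)
        y = rng.standard_normal(50) + (geno.true_calls[:, 3] - 1.0)
        probs = genotype_probabilities(geno)
        imp = impute_genotypes(probs, 16, seed=1)
        kernel = _ScanKernel(imp)
        a = kernel.lod(y)
        b = kernel.lod(2.0 * y + 3.0)
        assert np.abs(a - b).max() < 1e-9

    def test_constant_trait_rejected(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 20, seed=8)
        probs = genotype_probabilities(geno)
        imp = impute_genotypes(probs, 2, seed=0)
        with pytest.raises(ValueError, match="zero-variance"):
            c.scan_trait(np.ones(20), imp)

    def test_imputation_draw_count_convergence(self, small_map):
        """LOD with 128 vs 512 draws agrees on nearly all positions."""
        close = 0
        total = 0
        for seed in range(20):
            geno = c.simulate_f2_genotypes(small_map, 60, seed=seed, missing_rate=0.1)
            rng = np.random.default_rng(900 + seed)
            y = rng.standard_normal(60) + 0.8 * (geno.true_calls[:, 7] - 1.0)
            probs = genotype_probabilities(geno, step_cm=2.0)
            lod128 = c.scan_trait(y, impute_genotypes(probs, 128, seed=1)).lod
            lod512 = c.scan_trait(y, impute_genotypes(probs, 512, seed=2)).lod
            close += (np.abs(lod128 - lod512) < 0.05).sum()
            total += len(lod128)
        assert close / total >= 0.95


class TestSupportInterval:
    def _scan(self, lods):
        n = len(lods)
        return QtlScan("t", np.arange(1, n + 1) * 1000, np.arange(n, dtype=float),
                       np.asarray(lods, dtype=float))

    def test_worked_example(self):
        scan = self._scan([0.2, 1.0, 1.61, 0.9, 0.4])
        assert lod_support_interval(scan, drop=1.0) == (2000, 4000)

    def test_flat_curve_spans_everything(self):
        scan = self._scan([1.0, 1.0, 1.0, 1.0])
        assert lod_support_interval(scan, drop=1.0) == (1000, 4000)

    def test_zero_drop_is_peak_alone(self):
        scan = self._scan([0.2, 1.0, 1.61, 0.9, 0.4])
        assert lod_support_interval(scan, drop=0.0) == (3000, 3000)

    def test_interval_contains_peak(self, small_map):
        geno = c.simulate_f2_genotypes(small_map, 60, seed=9, missing_rate=0.0)
        rng = np.random.default_rng(9)
        y = rng.standard_normal(60) + (geno.calls[:, 10] - 1.0)
        probs = genotype_probabilities(geno, step_cm=2.0, error_rate=0.0)
        imp = impute_genotypes(probs, 8, seed=0)
        scan = c.scan_trait(y, imp)
        lo, hi = scan.support_interval
        assert lo <= scan.peak_position_bp <= hi


@pytest.fixture(scope="module")
def perm_setup(small_map):
    geno = c.simulate_f2_genotypes(small_map, 60, seed=10, missing_rate=0.0)
    probs = genotype_probabilities(geno, step_cm=1000.0, error_rate=0.0)
    imp = impute_genotypes(probs, 1, seed=0)
    y = np.random.default_rng(10).standard_normal(60)
    return y, imp


class TestPermutationThreshold:

    def test_same_seed_identical(self, perm_setup):
        y, imp = perm_setup
        a = c.permutation_threshold(y, imp, n_perm=100, alpha=0.05, seed=1)
        b = c.permutation_threshold(y, imp, n_perm=100, alpha=0.05, seed=1)
        assert a == b

    def test_alpha_near_one_approaches_minimum(self, perm_setup):
        y, imp = perm_setup
        thr, maxima = c.permutation_threshold(y, imp, n_perm=200, alpha=0.999,
                                              seed=2, return_maxima=True)
        assert maxima.min() <= thr <= np.partition(maxima, 1)[1]

    def test_threshold_decreases_with_alpha(self, perm_setup):
        y, imp = perm_setup
        t5 = c.permutation_threshold(y, imp, n_perm=200, alpha=0.05, seed=3)
        t50 = c.permutation_threshold(y, imp, n_perm=200, alpha=0.5, seed=3)
        assert t50 <= t5

    def test_validation(self, perm_setup):
        y, imp = perm_setup
        with pytest.raises(ValueError, match="n_perm"):
            c.permutation_threshold(y, imp, n_perm=50)
        with pytest.raises(ValueError, match="alpha"):
            c.permutation_threshold(y, imp, n_perm=100, alpha=1.5)


class TestEqtlScan:
    def test_fdr_target_one_flags_everything_above_grid_minimum(self, tiny_dataset):
        expr = c.preprocess(tiny_dataset.expression)
        sub = expr.subset_probes(expr.probes[:40])
        mapper = c.F2IntervalMapper(tiny_dataset.genotypes, step_cm=1000.0,
                                    n_draws=2, seed=0)
        res = mapper.fit_expression(sub, n_perm=50, fdr_target=1.0, seed=0)
        assert res.records["significant"].all()

    def test_null_expression_yields_no_significant_probes(self, small_map):
        import cssqtl.sim as sim

        n_sig = []
        for seed in range(3):
            probes = [f"P{i}" for i in range(200)]
            ann = pd.DataFrame(
                {"gene_symbol": probes, "chromosome": "5",
                 "start_bp": np.arange(200) * 1000 + 1, "snp_in_probe": 0},
                index=pd.Index(probes, name="probe_id"),
            )
            truth = sim.TruthSpec(
                qtl_position_cm=14.0, additive_effect=0.0,
                annotation=ann, noise_sd=1.0,
            )
            geno = c.simulate_f2_genotypes(small_map, 40, seed=seed, missing_rate=0.0)
            expr = c.preprocess(sim.simulate_expression(geno, truth, seed=seed),
                                alpha=0.999)
            mapper = c.F2IntervalMapper(geno, step_cm=2.0, n_draws=2, seed=seed)
            res = mapper.fit_expression(expr, n_perm=100, fdr_target=0.01, seed=seed)
            n_sig.append(int(res.records["significant"].sum()))
        assert np.mean(n_sig) <= 0.5

    def test_planted_cis_gene_recovered(self, tiny_dataset):
        ds = tiny_dataset
        expr = c.preprocess(ds.expression)
        mapper = c.F2IntervalMapper(ds.genotypes, step_cm=2.0, n_draws=4, seed=0)
        res = mapper.fit_expression(expr, n_perm=100, fdr_target=0.01, seed=0)
        rec = res.records.set_index("probe")
        cand = ds.candidate_probe
        assert rec.loc[cand, "significant"]
        truth_bp = ds.truth.annotation.loc[cand, "start_bp"]
        assert abs(rec.loc[cand, "peak_bp"] - truth_bp) < 25_000_000  # ~15 cM
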