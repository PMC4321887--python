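"""Permutation machinery, centering decomposition, grids, analyses."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prfcohort import (
    CohortConfig,
    build_grid,
    center_by_group,
    eccentricity_resolved_analysis,
    fixed_eccentricity_analysis,
    fwe_correct,
    generate_cohort,
    measure_thresholds,
    permutation_pvalue,
    spearman_rho,
)
from prfcohort.psychophysics import PsychometricObserver, threshold_positions


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0
        assert spearman_rho([1, 2, 3, 4], [5, 4, 3, 2]) == -1.0

    def test_tied_data_matches_hand_ranking(self):
        # x ranks: 1, 2.5, 2.5, 4, 5, 6; y ranks: 2, 1, 4, 4, 4, 6
        # Pearson on those average ranks = 0.8008534347238067
        x = [1, 2, 2, 3, 4, 5]
        y = [2, 1, 3, 3, 3, 4]
        assert spearman_rho(x, y) == pytest.approx(
            0.8008534347238067, rel=1e-12
        )

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="rank variance"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_length_checks(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestPermutationPvalue:
    def test_exhaustive_extreme_case(self):
        # perfectly monotone n=6: only identity and reversal reach |rho|=1
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 4, 6, 8, 10, 12]
        rho, p = permutation_pvalue(x, y)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(2 / 720)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rho, p = permutation_pvalue(x, y)
        # independent brute-force enumeration
        null = [
            spearman_rho(x, np.asarray(y)[list(perm)])
            for perm in itertools.permutations(range(6))
        ]
        expect = np.mean(np.abs(null) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expect, rel=1e-12)

    def test_sampled_within_binomial_ci_of_exhaustive(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x, y = rng.normal(size=6), rng.normal(size=6)
            _, p_ex = permutation_pvalue(x, y)
            _, p_mc = permutation_pvalue(
                x, y, n_perm=4000, rng=rng, exhaustive_if_small=False
            )
            se = np.sqrt(p_ex * (1 - p_ex) / 4000)
            assert abs(p_mc - p_ex) < 4 * se + 1e-3

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(300):
            x, y = rng.normal(size=10), rng.normal(size=10)
            _, p = permutation_pvalue(x, y, n_perm=199, rng=rng)
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_small_nperm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_pvalue(
                np.arange(10.0), np.arange(10.0), n_perm=50,
                rng=0, exhaustive_if_small=False,
            )

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3], [1, 2, 3])


class TestFWE:
    def _pairs(self, rng, k, n=12):
        return [
            (f"m{i}", rng.normal(size=n), rng.normal(size=n))
            for i in range(k)
        ]

    def test_family_of_one_equals_raw(self):
        rng = np.random.default_rng(4)
        res = fwe_correct(self._pairs(rng, 1), n_perm=499, rng=5)
        assert res[0].p_fwe == res[0].p_raw

    def test_duplicated_member_does_not_change_its_p(self):
        rng = np.random.default_rng(5)
        pairs = self._pairs(rng, 3)
        a = fwe_correct(pairs, n_perm=499, rng=6)
        b = fwe_correct(pairs + [pairs[0]], n_perm=499, rng=6)
        assert b[0].p_fwe == a[0].p_fwe

    def test_fwe_dominates_raw(self):
        rng = np.random.default_rng(6)
        res = fwe_correct(self._pairs(rng, 6), n_perm=499, rng=7)
        assert all(r.p_fwe >= r.p_raw for r in res)
        assert all(0 < r.p_raw <= 1 and r.p_fwe <= 1 for r in res)

    def test_heterogeneous_n_supported(self):
        rng = np.random.default_rng(7)
        pairs = [
            ("a", rng.normal(size=10), rng.normal(size=10)),
            ("b", rng.normal(size=20), rng.normal(size=20)),
        ]
        res = fwe_correct(pairs, n_perm=299, rng=8)
        assert {r.n for r in res} == {10, 20}

    def test_strong_effect_survives_correction(self):
        rng = np.random.default_rng(8)
        x = np.arange(20.0)
        pairs = [("signal", x, x + rng.normal(0, 1, 20))]
        pairs += self._pairs(rng, 5, n=20)
        res = fwe_correct(pairs, n_perm=999, rng=9)
        assert res[0].p_fwe < 0.05


class TestCenterByGroup:
    def test_group_means_become_zero(self):
        v = [1.0, 2.0, 3.0, 10.0, 20.0]
        g = ["a", "a", "a", "b", "b"]
        out = center_by_group(v, g)
        assert out[:3].mean() == pytest.approx(0.0)
        assert out[3:].mean() == pytest.approx(0.0)

    def test_constant_within_groups_gives_zeros(self):
        out = center_by_group([5, 5, 7, 7], ["a", "a", "b", "b"])
        assert np.allclose(out, 0.0)

    def test_removes_exactly_the_group_variance_component(self):
        # additive two-factor layout: y = a_i + b_j; centering by i must
        # leave exactly the b component (ANOVA decomposition oracle)
        a = np.array([0.0, 1.0, 2.0, 5.0])
        b = np.array([0.0, 10.0, 20.0])
        y = (a[:, None] + b[None, :]).ravel()
        labels = np.repeat(np.arange(4), 3)
        centered = center_by_group(y, labels)
        expect = np.tile(b - b.mean(), 4)
        assert np.allclose(centered, expect)

    def test_centered_correlation_equals_pooled_within_group(self):
        rng = np.random.default_rng(9)
        g = np.repeat(np.arange(5), 8)
        x = rng.normal(size=40) + 3.0 * g
        y = rng.normal(size=40) - 2.0 * g
        cx, cy = center_by_group(x, g), center_by_group(y, g)
        # brute-force pooled within-group correlation
        dx, dy = [], []
        for k in range(5):
            sel = g == k
            dx.append(x[sel] - x[sel].mean())
            dy.append(y[sel] - y[sel].mean())
        dx, dy = np.concatenate(dx), np.concatenate(dy)
        pooled = dx @ dy / np.sqrt((dx @ dx) * (dy @ dy))
        got = cx @ cy / np.sqrt((cx @ cx) * (cy @ cy))
        assert got == pytest.approx(pooled, rel=1e-12)


def _threshold_maps(cohort, seed=0):
    rngs = np.random.SeedSequence(seed).spawn(len(cohort.observers))
    return {
        pid: measure_thresholds(
            cohort.observers[pid], rng=np.random.default_rng(s),
            participant_id=pid,
        )
        for pid, s in zip(sorted(cohort.observers), rngs)
    }


class TestFixedEccentricityAnalysis:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(
            CohortConfig(areas=("V1",), n_vertices=1500, seed=31)
        )

    @pytest.fixture(scope="class")
    def result(self, cohort):
        maps = _threshold_maps(cohort, seed=31)
        areas = {a.participant_id: a.surface_area["V1"]
                 for a in cohort.anatomy}
        return fixed_eccentricity_analysis(
            cohort.vertices, maps, areas, n_perm=999, rng=1
        )

    def test_table_is_participants_by_positions(self, result):
        assert len(result.table) == 120  # 20 participants x 6 positions
        assert result.n_excluded == 0

    def test_planted_signs_recovered(self, result):
        by = result.by_pair()
        assert by["width~threshold"].rho > 0
        assert by["width~thickness"].rho > 0
        assert by["width~area"].rho < 0
        assert by["threshold~thickness"].rho > 0
        assert by["threshold~area"].rho < 0
        for pair in ("width~threshold", "width~thickness", "width~area"):
            assert by[pair].p_fwe < 0.05

    def test_intra_inter_variants_sign_match_total(self, result):
        by = result.by_pair()
        for var, tot in [
            ("width~threshold_intra", "width~threshold"),
            ("width~threshold_inter", "width~threshold"),
            ("width~thickness_intra", "width~thickness"),
            ("width~thickness_inter", "width~thickness"),
        ]:
            assert np.sign(by[var].rho) == np.sign(by[tot].rho)

    def test_null_generator_controls_false_positives(self):
        cfg = dataclasses.replace(
            CohortConfig(areas=("V1",), n_vertices=600, seed=33),
            beta_thickness=0.0, beta_area=0.0, area_slope_coupling=0.0,
            slope_rel_sd=0.0, threshold_beta_thickness=0.0,
            threshold_beta_area=0.0,
        )
        cohort = generate_cohort(cfg)
        maps = _threshold_maps(cohort, seed=33)
        areas = {a.participant_id: a.surface_area["V1"]
                 for a in cohort.anatomy}
        res = fixed_eccentricity_analysis(
            cohort.vertices, maps, areas, n_perm=499, rng=2
        )
        n_sig = sum(r.p_fwe < 0.05 for r in res.results)
        assert n_sig <= 2
        assert max(abs(r.rho) for r in res.results) < 0.45


class TestBuildGrid:
    def test_single_vertex_cells_equal_raw_values(self):
        v = pd.DataFrame(
            {
                "participant_id": ["P1", "P1", "P2", "P2"],
                "eccentricity": [1.0, 5.0, 1.0, 5.0],
                "thickness": [2.0, 2.1, 2.2, 2.3],
                "true_sigma": [0.3, 0.9, 0.4, 1.0],
            }
        )
        grid = build_grid(v, "true_sigma", n_ecc_bins=2)
        assert grid.means.loc["P1"].dropna().tolist() == [0.3, 0.9]
        assert grid.counts.to_numpy().sum() == 4

    def test_cell_means_match_brute_force_groupby(self, small_cohort):
        v = small_cohort.vertices[small_cohort.vertices.area == "V1"]
        grid = build_grid(v, "true_sigma", n_ecc_bins=5)
        edges = grid.ecc_edges
        for pid in v.participant_id.unique():
            sel = v[v.participant_id == pid]
            for j in range(5):
                lo, hi = edges[j], edges[j + 1]
                if j == 0:
                    m = sel[(sel.eccentricity >= lo)
                            & (sel.eccentricity <= hi)]
                else:
                    m = sel[(sel.eccentricity > lo)
                            & (sel.eccentricity <= hi)]
                cell = grid.means.loc[pid].iloc[j]
                if len(m):
                    assert cell == pytest.approx(m.true_sigma.mean(),
                                                 rel=1e-9)
                else:
                    assert np.isnan(cell)

    def test_thickness_axis_uses_01mm_bins(self, small_cohort):
        grid = build_grid(
            small_cohort.vertices, "true_sigma", axis2="thickness"
        )
        centers = np.array(sorted(grid.means.index))
        # populated bins sit on a 0.1 mm lattice (empty bins are dropped)
        offsets = (centers - centers[0]) / 0.1
        assert np.allclose(offsets, np.round(offsets), atol=1e-6)
        assert np.diff(centers).min() == pytest.approx(0.1, abs=1e-6)

    def test_empty_selection_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            build_grid(small_cohort.vertices.iloc[:0], "true_sigma")


class TestEccentricityResolved:
    def test_exact_linear_values_fit_perfectly(self):
        rng = np.random.default_rng(10)
        rows = []
        slopes = {"P1": 0.10, "P2": 0.15, "P3": 0.20, "P4": 0.25}
        for pid, s in slopes.items():
            ecc = rng.uniform(0.25, 7.2, 500)
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "eccentricity": ecc,
                        "thickness": 2.25,
                        "true_sigma": 0.2 + s * ecc,
                    }
                )
            )
        v = pd.concat(rows, ignore_index=True)
        grid = build_grid(v, "true_sigma", n_ecc_bins=8)
        # anatomy chosen so that slope decreases with it
        anatomy = {"P1": 4.0, "P2": 3.0, "P3": 2.0, "P4": 1.0}
        res = eccentricity_resolved_analysis(grid, anatomy, n_perm=499,
                                             rng=3)
        for pid, s in slopes.items():
            assert res.fits[pid].r2 > 0.999
            assert res.fits[pid].slope == pytest.approx(s, rel=0.02)
        assert res.by_pair()["slope~anatomy"].rho == -1.0

    def test_planted_area_coupling_recovered(self):
        cohort = generate_cohort(
            CohortConfig(areas=("V1",), n_vertices=1500, seed=41)
        )
        areas = {a.participant_id: a.surface_area["V1"]
                 for a in cohort.anatomy}
        grid = build_grid(cohort.vertices, "true_sigma", area="V1")
        res = eccentricity_resolved_analysis(grid, areas, n_perm=999, rng=4)
        by = res.by_pair()
        assert by["slope~anatomy"].rho < 0
        assert by["slope~anatomy"].p_fwe < 0.05
        assert by["intercept~anatomy"].rho < 0

    def test_per_ecc_bin_thickness_correlations_positive(self):
        cohort = generate_cohort(
            CohortConfig(areas=("V1",), n_vertices=1500, seed=42)
        )
        grid = build_grid(cohort.vertices, "true_sigma", axis2="thickness",
                          area="V1")
        res = eccentricity_resolved_analysis(grid, n_perm=499, rng=5)
        bins = [r for r in res.results if r.family == "per_ecc_bin"]
        assert len(bins) >= 5
        assert np.mean([r.rho > 0 for r in bins]) >= 0.9

    def test_participant_grid_requires_anatomy(self, small_cohort):
        grid = build_grid(small_cohort.vertices, "true_sigma", area="V1")
        with pytest.raises(ValueError, match="anatomy_values"):
            eccentricity_resolved_analysis(grid)
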