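import numpy as np
import pytest

import scnet
from scnet import (
    CohortConfig,
    ContrastSpec,
    DensityGrid,
    PlantedEffect,
    Subcase,
    enumerate_subcases,
    fdr_correct,
    generate_cohort,
    observed_contrast,
    permutation_null,
    pvalues,
    run_contrast,
    significance_report,
    significant_view,
)
from scnet.errors import ConfigurationError
from scnet.inference import significance_tier
from scnet.pipeline import build_group_tables, effective_grid, residualize_cohort

GRID = DensityGrid(0.2, 0.5, 0.05)


def _tiny_tables(seed, planted=(), n_cortical=10):
    cfg = CohortConfig(
        n_hc=20,
        n_et=20,
        n_cortical=n_cortical,
        n_noncortical=0,
        planted_effects=planted,
        seed=seed,
    )
    resid = residualize_cohort(generate_cohort(cfg))
    return {g: build_group_tables(resid, g) for g in ("HC", "ET_pre", "ET_post")}


class TestSubcases:
    def test_full_enumeration_is_fifteen(self):
        subs = enumerate_subcases()
        assert len(subs) == 15
        assert sum(s.kind == "same" for s in subs) == 9
        assert sum(s.kind == "cross" for s in subs) == 6
        assert len({s.label for s in subs}) == 15

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ConfigurationError):
            Subcase("same", "CT", "in_degree")
        with pytest.raises(ConfigurationError):
            Subcase("cross", ("CT", "MC"), "degree")


class TestObservedContrast:
    def test_self_contrast_is_zero(self):
        tabs = _tiny_tables(1)
        sc = [Subcase("same", "CT", "degree"), Subcase("cross", ("CT", "MC"), "out_degree")]
        deltas = observed_contrast(tabs["HC"], tabs["HC"], sc, GRID)
        for v in deltas.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_antisymmetry(self):
        tabs = _tiny_tables(2)
        sc = [Subcase("same", "MC", "degree")]
        d_ab = observed_contrast(tabs["HC"], tabs["ET_pre"], sc, GRID)
        d_ba = observed_contrast(tabs["ET_pre"], tabs["HC"], sc, GRID)
        np.testing.assert_allclose(d_ab["MC.degree"], -d_ba["MC.degree"], atol=1e-12)

    def test_planted_regions_rank_top_by_degree_delta(self):
        """A planted coupling boost puts its regions at the top of the degree contrast."""
        planted_idx = (1, 5, 8)
        hits = 0
        for rep in range(10):
            tabs = _tiny_tables(
                100 + rep,
                planted=(PlantedEffect("ET_pre", "MC", planted_idx, 4.0),),
                n_cortical=12,
            )
            deltas = observed_contrast(
                tabs["ET_pre"], tabs["ET_post"], [Subcase("same", "MC", "degree")], GRID
            )["MC.degree"]
            top5 = set(np.argsort(-deltas)[:5])
            hits += sum(r in top5 for r in planted_idx)
        assert hits >= 0.8 * 10 * len(planted_idx)


class TestPermutationNull:
    def test_identity_assignment_reproduces_observed(self):
        tabs = _tiny_tables(3)
        sc = [Subcase("same", "CT", "degree")]
        spec = ContrastSpec("c", "HC", "ET_pre", n_permutations=1, seed=0)
        n_a = tabs["HC"].n_subjects
        n_b = tabs["ET_pre"].n_subjects
        identity = [(np.arange(n_a), np.arange(n_a, n_a + n_b))]
        null = permutation_null(tabs["HC"], tabs["ET_pre"], spec, sc, GRID, assignments=identity)
        observed = observed_contrast(tabs["HC"], tabs["ET_pre"], sc, GRID)
        np.testing.assert_allclose(null["CT.degree"][0], observed["CT.degree"], atol=1e-12)

    def test_seeded_determinism(self):
        tabs = _tiny_tables(4)
        sc = [Subcase("same", "CT", "degree")]
        spec = ContrastSpec("c", "HC", "ET_pre", n_permutations=20, seed=9)
        n1 = permutation_null(tabs["HC"], tabs["ET_pre"], spec, sc, GRID)
        n2 = permutation_null(tabs["HC"], tabs["ET_pre"], spec, sc, GRID)
        np.testing.assert_array_equal(n1["CT.degree"], n2["CT.degree"])

    def test_swapped_groups_negate_null_under_fixed_assignments(self, rng):
        tabs = _tiny_tables(5)
        sc = [Subcase("same", "CT", "degree")]
        spec = ContrastSpec("c", "HC", "ET_pre", n_permutations=5, seed=0)
        n = tabs["HC"].n_subjects + tabs["ET_pre"].n_subjects
        assigns = []
        for _ in range(5):
            perm = rng.permutation(n)
            assigns.append((perm[: tabs["HC"].n_subjects], perm[tabs["HC"].n_subjects :]))
        fwd = permutation_null(tabs["HC"], tabs["ET_pre"], spec, sc, GRID, assignments=assigns)
        rev_assigns = [(b, a) for a, b in assigns]
        # same pooled rows, reversed roles
        rev = permutation_null(tabs["HC"], tabs["ET_pre"], spec, sc, GRID, assignments=rev_assigns)
        np.testing.assert_allclose(fwd["CT.degree"], -rev["CT.degree"], atol=1e-12)

    def test_paired_swap_requires_equal_sizes(self):
        tabs = _tiny_tables(6)
        spec = ContrastSpec("c", "HC", "ET_pre", n_permutations=2, seed=0, shuffle_scheme="paired_swap")
        cfg = CohortConfig(n_hc=10, n_et=20, n_cortical=10, n_noncortical=0, seed=6)
        resid = residualize_cohort(generate_cohort(cfg))
        t = {g: build_group_tables(resid, g) for g in ("HC", "ET_pre")}
        with pytest.raises(ConfigurationError):
            permutation_null(t["HC"], t["ET_pre"], spec, [Subcase("same", "CT", "degree")], GRID)


class TestPValues:
    def test_add_one_bound(self):
        obs = np.array([10.0])
        null = np.array([[1.0], [2.0], [3.0], [-4.0], [5.0], [-6.0], [7.0]])
        assert pvalues(obs, null)[0] == pytest.approx(1 / 8)

    def test_zero_observed_gives_p_one(self):
        obs = np.array([0.0])
        null = np.array([[1.0], [-2.0], [3.0]])
        assert pvalues(obs, null)[0] == 1.0

    def test_two_sided_on_magnitude(self):
        obs = np.array([-10.0])
        null = np.array([[1.0], [2.0], [3.0]])
        assert pvalues(obs, null)[0] == pytest.approx(1 / 4)


class TestFDR:
    def test_all_equal_ps(self):
        q = fdr_correct(np.full(5, 0.03))
        np.testing.assert_allclose(q, 0.03)

    def test_bh_step_up_worked_example(self):
        q = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, 0.04)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        q = fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestReport:
    def _results(self, seed=7):
        tabs = _tiny_tables(seed)
        spec = ContrastSpec("HC_minus_ETpre", "HC", "ET_pre", n_permutations=30, seed=1)
        sc = [Subcase("same", p, "degree") for p in ("CT", "MC")]
        return run_contrast(tabs["HC"], tabs["ET_pre"], spec, GRID, subcases=sc)

    def test_report_structure_and_sorting(self):
        results = self._results()
        rep = significance_report(results)
        assert len(rep) == 2 * 10
        assert list(rep.columns) == [
            "region", "property", "metric", "contrast", "delta_auc", "p", "q", "tier",
        ]
        assert np.all(np.diff(rep["q"].to_numpy()) >= -1e-12)

    def test_pooled_fdr_spans_subcases(self):
        results = self._results()
        pooled = np.concatenate([r.p for r in results])
        q_expected = fdr_correct(pooled)
        q_got = np.concatenate([r.q for r in results])
        np.testing.assert_allclose(q_got, q_expected)

    def test_significant_view_filters(self):
        results = self._results()
        rep = significance_report(results)
        sig = significant_view(rep, alpha=0.5)
        assert (sig["q"] < 0.5).all()
        empty = significant_view(rep, alpha=1e-9)
        assert len(empty) == 0 and len(rep) == 20

    def test_tier_labels(self):
        assert significance_tier(0.0005) == "alpha2"
        assert significance_tier(0.005) == "alpha1"
        assert significance_tier(0.5) == "ns"


def test_contrast_spec_validation():
    with pytest.raises(ConfigurationError):
        ContrastSpec("c", "A", "A")
    with pytest.raises(ConfigurationError):
        ContrastSpec("c", "A", "B", n_permutations=0)
    with pytest.raises(ConfigurationError):
        ContrastSpec("c", "A", "B", shuffle_scheme="bogus")
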