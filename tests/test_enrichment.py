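"""KS testing, Benjamini-Yekutieli adjustment, and enrichment calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from ipfa.annotation_io import FeatureAnnotation, FeatureCatalog
from ipfa.enrichment import (
    EnrichmentConfig,
    adjust_benjamini_yekutieli,
    classify_enrichment,
    ks_two_sample,
    run_enrichment,
    _ks_d_numerator,
)
from ipfa.errors import ValidationError


def brute_force_ks_d(group, background):
    """Independent oracle: sup of |ECDF difference| over pooled points."""
    n, m = len(group), len(background)
    best = 0.0
    for x in list(group) + list(background):
        fg = sum(1 for v in group if v <= x) / n
        fb = sum(1 for v in background if v <= x) / m
        best = max(best, abs(fg - fb))
    return best


class TestKSStatistic:
    def test_identical_multisets_give_zero_d_unit_p(self):
        d, p = ks_two_sample([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports_give_d_one(self):
        d, _ = ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == 1.0

    def test_worked_example(self):
        d, _ = ks_two_sample([1, 2], [1, 2, 3, 4])
        assert d == 0.5  # at x=2: 1.0 vs 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])

    @given(
        g=st.lists(st.integers(0, 4), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 4), min_size=1, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_d_matches_brute_force_oracle(self, g, b):
        d, _ = ks_two_sample(g, b)
        assert d == pytest.approx(brute_force_ks_d(g, b), abs=1e-12)

    def test_d_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = rng.normal(size=rng.integers(2, 40))
            b = rng.normal(size=rng.integers(2, 40))
            d, _ = ks_two_sample(g, b)
            assert d == pytest.approx(scipy.stats.ks_2samp(g, b).statistic, abs=1e-12)


class TestKSPValues:
    def test_exact_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n, m = rng.integers(2, 12, 2)
            vals = rng.permutation(np.arange(200.0))[: n + m]
            g, b = vals[:n], vals[n:]
            _, p = ks_two_sample(g, b, method="exact_small_n")
            ref = scipy.stats.ks_2samp(g, b, method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-9)

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n, m = rng.integers(1, 6, 2)
            vals = rng.integers(0, 3, n + m).astype(float)
            g, b = vals[:n], vals[n:]
            d_num = _ks_d_numerator(g, b)
            pooled = np.concatenate([g, b])
            hits = total = 0
            for idx in itertools.combinations(range(n + m), n):
                mask = np.zeros(n + m, bool)
                mask[list(idx)] = True
                total += 1
                hits += _ks_d_numerator(pooled[mask], pooled[~mask]) >= d_num
            _, p = ks_two_sample(g, b, method="exact_small_n")
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_permutation_agrees_with_exact_conditional(self):
        g = np.array([0.1, 0.5, 0.5, 1.2])
        b = np.array([0.5, 0.9, 1.2, 1.7, 2.0])
        _, p_exact = ks_two_sample(g, b, method="exact_small_n")
        _, p_perm = ks_two_sample(
            g, b, method="permutation", permutation_rounds=20_000, rng=11
        )
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_perm - p_exact) < 4 * se + 1e-4

    def test_asymptotic_used_for_large_samples(self):
        rng = np.random.default_rng(9)
        g, b = rng.normal(size=60), rng.normal(0.5, size=200)
        _, p_auto = ks_two_sample(g, b, method="auto")
        _, p_asym = ks_two_sample(g, b, method="asymptotic")
        assert p_auto == p_asym


def by_oracle(p):
    """Closed-form BY step-up: p(i) * m * c(m) / i, monotone, clipped."""
    p = np.asarray(p, float)
    m = len(p)
    cm = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m * cm / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        assert adjust_benjamini_yekutieli([0.02])[0] == pytest.approx(0.02)

    def test_two_p_closed_form(self):
        # c(2)=1.5: 0.01*2*1.5/1 = 0.03, 0.04*2*1.5/2 = 0.06
        adj = adjust_benjamini_yekutieli([0.01, 0.04])
        assert adj == pytest.approx([0.03, 0.06])

    def test_all_ones_stay_one(self):
        assert (adjust_benjamini_yekutieli([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(adjust_benjamini_yekutieli(p), by_oracle(p), atol=1e-12)

    def test_at_least_benjamini_hochberg(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(22)
        for _ in range(50):
            p = rng.random(rng.integers(2, 40))
            by = adjust_benjamini_yekutieli(p)
            bh = multipletests(p, method="fdr_bh")[1]
            assert (by >= bh - 1e-12).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(23)
        p = rng.random(15)
        perm = rng.permutation(15)
        assert np.allclose(
            adjust_benjamini_yekutieli(p)[perm], adjust_benjamini_yekutieli(p[perm])
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_benjamini_yekutieli([0.5, 1.5])


class TestClassification:
    @pytest.mark.parametrize(
        "p_adj,median_group,median_all,expected",
        [
            (0.01, 0.3, 0.0, True),
            (0.20, 0.3, 0.0, False),  # not significant
            (0.01, -0.2, 0.0, False),  # depleted, not enriched
        ],
    )
    def test_two_part_rule(self, p_adj, median_group, median_all, expected):
        df = pd.DataFrame(
            [
                {
                    "p_raw": p_adj / 2,
                    "p_adj": p_adj,
                    "median_group": median_group,
                    "median_all": median_all,
                }
            ]
        )
        out = classify_enrichment(df, EnrichmentConfig())
        assert bool(out["enriched"].iloc[0]) is expected

    def test_raw_p_threshold_mode(self):
        df = pd.DataFrame(
            [{"p_raw": 0.03, "p_adj": 0.2, "median_group": 1.0, "median_all": 0.0}]
        )
        cfg = EnrichmentConfig(apply_adjustment_to_threshold=False)
        assert bool(classify_enrichment(df, cfg)["enriched"].iloc[0])


def _catalog(features: dict) -> FeatureCatalog:
    anns = [
        FeatureAnnotation(pid, "PTM", name)
        for name, pids in features.items()
        for pid in pids
    ]
    return FeatureCatalog(anns)


def _ratio_series(n=40, seed=0, shift_idx=(), shift=0.0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 0.5, n)
    vals[list(shift_idx)] += shift
    return pd.Series(vals, index=[f"p{i}" for i in range(n)])


class TestRunEnrichment:
    def test_carriers_equal_background_not_enriched(self):
        ratios = _ratio_series()
        cat = _catalog({"mod X": list(ratios.index)})
        res = run_enrichment(cat, ratios)
        assert len(res) == 1
        assert res["D"].iloc[0] == 0.0 and not res["enriched"].iloc[0]

    def test_identical_carrier_sets_identical_statistics(self):
        ratios = _ratio_series()
        carriers = [f"p{i}" for i in range(8)]
        cat = _catalog({"mod A": carriers, "mod B": carriers})
        res = run_enrichment(cat, ratios)
        a = res[res["name"] == "mod A"].iloc[0]
        b = res[res["name"] == "mod B"].iloc[0]
        for col in ("D", "p_raw", "p_adj", "median_group"):
            assert a[col] == b[col]

    def test_planted_shift_is_flagged(self):
        ratios = _ratio_series(n=300, seed=4, shift_idx=range(25), shift=1.5)
        cat = _catalog(
            {
                "planted": [f"p{i}" for i in range(25)],
                "null": [f"p{i}" for i in range(100, 125)],
            }
        )
        res = run_enrichment(cat, ratios).set_index("name")
        assert bool(res.loc["planted", "enriched"])
        assert not bool(res.loc["null", "enriched"])

    def test_depleted_shift_not_flagged_despite_significance(self):
        ratios = _ratio_series(n=300, seed=4, shift_idx=range(25), shift=-1.5)
        cat = _catalog({"depleted": [f"p{i}" for i in range(25)]})
        res = run_enrichment(cat, ratios)
        assert res["p_adj"].iloc[0] < 0.05
        assert not res["enriched"].iloc[0]

    def test_groups_below_min_size_skipped(self):
        ratios = _ratio_series()
        cat = _catalog({"tiny": ["p0", "p1", "p2", "p3"]})
        assert len(run_enrichment(cat, ratios, EnrichmentConfig(min_group_size=5))) == 0

    def test_empty_catalog_gives_empty_frame(self):
        res = run_enrichment(_catalog({}), _ratio_series())
        assert len(res) == 0 and "enriched" in res.columns

    def test_enlarging_alpha_never_unflags(self):
        ratios = _ratio_series(n=200, seed=8, shift_idx=range(20), shift=0.8)
        cat = _catalog(
            {f"mod {j}": [f"p{i}" for i in range(j, j + 15)] for j in range(0, 60, 10)}
        )
        flags = {}
        for alpha in (0.01, 0.05, 0.2):
            res = run_enrichment(cat, ratios, EnrichmentConfig(alpha=alpha))
            flags[alpha] = set(res.loc[res["enriched"], "name"])
        assert flags[0.01] <= flags[0.05] <= flags[0.2]

    def test_background_exclusion_mode(self):
        ratios = _ratio_series(n=100, seed=2, shift_idx=range(10), shift=2.0)
        cat = _catalog({"mod X": [f"p{i}" for i in range(10)]})
        res = run_enrichment(
            cat, ratios, EnrichmentConfig(background_mode="all_excluding_carriers")
        )
        # carriers removed from background -> D is 1 for a 2-sigma shift
        assert res["D"].iloc[0] > 0.9

    def test_results_sorted_by_p_adj_then_name(self):
        ratios = _ratio_series(n=200, seed=6, shift_idx=range(15), shift=1.0)
        cat = _catalog(
            {
                "strong": [f"p{i}" for i in range(15)],
                "weak a": [f"p{i}" for i in range(50, 65)],
                "weak b": [f"p{i}" for i in range(50, 65)],
            }
        )
        res = run_enrichment(cat, ratios)
        assert list(res["p_adj"]) == sorted(res["p_adj"])
        ties = res[res["p_adj"].duplicated(keep=False)]
        for _, sub in ties.groupby("p_adj"):
            assert list(sub["name"]) == sorted(sub["name"])
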