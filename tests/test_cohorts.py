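import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabograd import cohorts
from metabograd.io import MetaboliteMatrix, SampleMetadata
from metabograd.synth import generate_cohort


def brute_force_mann_whitney(a, b):
    """Independent oracle: U by direct pair counting, p by enumerating every
    assignment of the pooled values to groups."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)

    def u_stat(x, y):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi in x for yi in y
        )

    u_obs = u_stat(a, b)
    pooled = np.concatenate([a, b])
    centre = n1 * n2 / 2
    dev = abs(u_obs - centre)
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - centre) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_complete_separation(self):
        u, p, auc = cohorts.mann_whitney([1, 2, 3], [4, 5, 6])
        assert auc == 0.0
        assert u == 0.0

    def test_identical_groups(self):
        u, p, auc = cohorts.mann_whitney([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        assert auc == 0.5

    @pytest.mark.parametrize("n1,n2,tied", [
        (3, 4, False), (4, 4, True), (8, 8, False), (2, 7, True), (5, 6, True),
    ])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2, tied):
        rng = np.random.default_rng(n1 * 10 + n2 + tied)
        if tied:
            a = rng.integers(0, 4, n1).astype(float)
            b = rng.integers(0, 4, n2).astype(float)
        else:
            a, b = rng.normal(size=n1), rng.normal(0.8, 1, n2)
        u, p, _ = cohorts.mann_whitney(a, b)
        u_oracle, p_oracle = brute_force_mann_whitney(a, b)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_p_and_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=9), rng.normal(0.5, 1, 7)
        u1, p1, auc1 = cohorts.mann_whitney(a, b)
        u2, p2, auc2 = cohorts.mann_whitney(np.exp(a), np.exp(b))
        assert (u1, p1, auc1) == pytest.approx((u2, p2, auc2))

    def test_batch_matches_scalar_asymptotic(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(30, 6))
        b = rng.normal(0.4, 1, size=(25, 6))
        u, p, auc = cohorts.batch_mann_whitney(a, b)
        from scipy import stats
        for j in range(6):
            ref = stats.mannwhitneyu(a[:, j], b[:, j],
                                     alternative="two-sided",
                                     method="asymptotic")
            assert p[j] == pytest.approx(float(ref.pvalue))
            assert auc[j] == pytest.approx(u[j] / (30 * 25))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cohorts.mann_whitney([], [1.0])


class TestBonferroni:
    def test_printed_bound_at_324_metabolites(self):
        assert cohorts.bonferroni_threshold(0.05, 324) == pytest.approx(
            1.54e-4, rel=5e-3)

    def test_single_test_keeps_alpha(self):
        assert cohorts.bonferroni_threshold(0.05, 1) == 0.05

    def test_threshold_times_m_is_alpha(self):
        for m in (1, 17, 324, 1000):
            assert cohorts.bonferroni_threshold(0.05, m) * m == pytest.approx(0.05)


class TestDiscoveryReplication:
    def test_passing_metabolites_have_concordant_directions(self, small_config):
        matrix, meta, _, _ = generate_cohort(small_config)
        from metabograd.preprocess import impute_min_detected
        screen = cohorts.discovery_replication(impute_min_detected(matrix), meta)
        passing = screen[screen["passes"]]
        assert len(passing) > 0
        assert (passing["direction_disc"] == passing["direction_rep"]).all()

    def test_planted_effects_dominate_passes(self, small_config):
        cfg = dataclasses.replace(small_config, effect_up_range=(2.0, 2.0),
                                  effect_down_range=(2.0, 2.0))
        matrix, meta, _, truth = generate_cohort(cfg)
        from metabograd.preprocess import impute_min_detected
        screen = cohorts.discovery_replication(impute_min_detected(matrix), meta)
        passing = set(screen.index[screen["passes"]])
        planted = set(truth.affected["CTEPH_vs_HC"])
        assert len(passing - planted) <= 1
        assert len(planted & passing) / len(planted) > 0.8

    def test_missing_cohort_label_errors(self, small_config):
        matrix, meta, _, _ = generate_cohort(small_config)
        md = meta.data.copy()
        md.loc[md["cohort"] == "replication", "cohort"] = "none"
        with pytest.raises(ValueError, match="replication"):
            cohorts.discovery_replication(matrix, SampleMetadata(data=md))


def _confounded_dataset(n=120, seed=0):
    """Group difference wholly driven by an age imbalance."""
    rng = np.random.default_rng(seed)
    age = np.r_[rng.normal(45, 6, n // 2), rng.normal(70, 6, n // 2)]
    y = 0.08 * (age - 55) + rng.normal(0, 0.5, n)
    ids = [f"s{i}" for i in range(n)]
    matrix = MetaboliteMatrix(
        data=pd.DataFrame({"m1": y}, index=ids), scale_tag="zscore")
    meta = SampleMetadata(data=pd.DataFrame({
        "subject_id": ids,
        "group": ["HC"] * (n // 2) + ["CTEPH"] * (n // 2),
        "cohort": "none", "batch": "b0", "timepoint": "none", "site": "none",
        "age": age,
        "sex_female": rng.integers(0, 2, n).astype(float),
    }, index=ids))
    return matrix, meta


class TestConfounderAdjustment:
    def test_age_driven_difference_not_significant_after_adjustment(self):
        matrix, meta = _confounded_dataset()
        # unadjusted: the groups differ strongly
        hc = meta.samples_where(group="HC")
        ct = meta.samples_where(group="CTEPH")
        _, p_raw, _ = cohorts.mann_whitney(matrix.data.loc[ct, "m1"],
                                           matrix.data.loc[hc, "m1"])
        assert p_raw < 1e-6
        adj = cohorts.confounder_adjust(matrix, meta, ["m1"])
        assert not adj.loc["m1", "significant"]

    def test_true_group_effect_survives_adjustment(self):
        matrix, meta = _confounded_dataset(seed=1)
        rng = np.random.default_rng(2)
        y = matrix.data["m1"].to_numpy() + np.where(
            meta.data["group"] == "CTEPH", 1.5, 0.0)
        matrix = MetaboliteMatrix(
            data=pd.DataFrame({"m1": y}, index=matrix.data.index),
            scale_tag="zscore")
        adj = cohorts.confounder_adjust(matrix, meta, ["m1"])
        assert adj.loc["m1", "significant"]
        assert adj.loc["m1", "beta_group"] == pytest.approx(1.5, abs=0.4)

    def test_hc_missing_assays_assumed_preserved(self, small_config):
        matrix, meta, _, _ = generate_cohort(small_config)
        X = cohorts.build_design(meta, "CTEPH", "HC")
        md = meta.data.loc[X.index]
        hc_rows = X[md["group"] == "HC"]
        assert (hc_rows["preserved_renal"] == 1.0).all()
        assert (hc_rows["preserved_liver"] == 1.0).all()
        assert md.loc[hc_rows.index, "creatinine"].isna().all()

    def test_too_few_complete_cases_skipped(self, caplog):
        matrix, meta = _confounded_dataset(n=8)
        with caplog.at_level("WARNING"):
            adj = cohorts.confounder_adjust(matrix, meta, ["m1"])
        assert len(adj) == 0


def _screen_frame(passes: dict) -> pd.DataFrame:
    return pd.DataFrame({"passes": pd.Series(passes)})


def _adj_frame(sig: dict) -> pd.DataFrame:
    return pd.DataFrame({"significant": pd.Series(sig)})


class TestTierClassification:
    def test_all_criteria_gives_top_tier(self):
        tiers = cohorts.tier_classify(
            _screen_frame({"x": True}), _adj_frame({"x": True}),
            _adj_frame({"x": True}), _adj_frame({"x": True}),
            _adj_frame({"x": True}),
        )
        assert tiers["x"] == "vs_all_including_IPAH"

    def test_failed_replication_is_none_regardless(self):
        tiers = cohorts.tier_classify(
            _screen_frame({"x": False}), _adj_frame({"x": True}),
            _adj_frame({"x": True}), _adj_frame({"x": True}),
            _adj_frame({"x": True}),
        )
        assert tiers["x"] == "none"

    def test_hc_dc_but_not_cted(self):
        tiers = cohorts.tier_classify(
            _screen_frame({"x": True}), _adj_frame({"x": True}),
            _adj_frame({"x": True}), _adj_frame({"x": False}),
            _adj_frame({"x": True}),
        )
        assert tiers["x"] == "vs_HC_DC"

    def test_tier_counts_nested_monotone(self, small_config):
        """|vs_all| <= |vs_HC_DC_CTED or higher| <= |vs_HC_DC or higher|."""
        rng = np.random.default_rng(3)
        mets = [f"m{i}" for i in range(40)]
        screen = _screen_frame({m: bool(rng.random() < 0.8) for m in mets})
        frames = [_adj_frame({m: bool(rng.random() < 0.6) for m in mets})
                  for _ in range(4)]
        tiers = cohorts.tier_classify(screen, *frames)
        order = ["vs_HC_only", "vs_HC_DC", "vs_HC_DC_CTED",
                 "vs_all_including_IPAH"]
        counts = [int((tiers == t).sum()) for t in order]
        cumulative = np.cumsum(counts[::-1])  # top tier downward
        assert (np.diff(cumulative) >= 0).all()
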