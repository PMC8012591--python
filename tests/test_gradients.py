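import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabograd import gradients
from metabograd.io import MetaboliteAnnotation, MetaboliteMatrix, SampleMetadata


class TestBenjaminiHochberg:
    def test_hand_step_up_example(self):
        adj = gradients.benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert gradients.benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_all_identical_unchanged(self):
        adj = gradients.benjamini_hochberg([0.04] * 7)
        assert np.allclose(adj, 0.04)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        adj = gradients.benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_step_up_implementation(self, seed):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 400))
        adj = gradients.benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref, atol=1e-12)


def _trisite_dataset(n_subj=40, offsets=None, seed=0, noise=0.3):
    """Hand-built tri-site data: met columns get fixed site offsets
    (svc, pa, art) added to a per-subject random level."""
    rng = np.random.default_rng(seed)
    offsets = offsets or {}
    mets = sorted(offsets) or ["m0"]
    rows, meta_rows = [], []
    for i in range(n_subj):
        level = {m: rng.normal(0, 1) for m in mets}
        for site_idx, site in enumerate(("SVC", "PA", "ART")):
            rows.append([
                level[m] + offsets.get(m, (0, 0, 0))[site_idx]
                + rng.normal(0, noise)
                for m in mets
            ])
            meta_rows.append((f"subj{i}", site))
    ids = [f"t{i}" for i in range(len(rows))]
    matrix = MetaboliteMatrix(
        data=pd.DataFrame(rows, index=ids, columns=mets), scale_tag="zscore")
    subj, sites = zip(*meta_rows)
    meta = SampleMetadata(data=pd.DataFrame({
        "subject_id": subj, "group": "CTEPH", "cohort": "gradient",
        "batch": "b0", "timepoint": "none", "site": sites,
    }, index=pd.Index(ids, name="sample_id")))
    return matrix, meta


class TestSiteGradients:
    def test_planted_svc_pa_offset_found_only_there(self):
        matrix, meta = _trisite_dataset(
            n_subj=60,
            offsets={"hit": (0.0, 0.6, 0.6), "null": (0.0, 0.0, 0.0)},
        )
        table = gradients.site_gradients(matrix, meta)
        assert bool(table.loc[("hit", "SVC_PA"), "significant"])
        assert not bool(table.loc[("hit", "PA_ART"), "significant"])
        assert not table.xs("null", level="metabolite_id")["significant"].any()
        assert table.loc[("hit", "SVC_PA"), "median_difference"] == pytest.approx(
            0.6, abs=0.15)

    def test_tri_gradient_metabolite_significant_in_all_three(self):
        """A metabolite rising SVC->PA and PA->ART shows all three
        gradients, the closing ART->SVC difference included."""
        matrix, meta = _trisite_dataset(
            n_subj=60, offsets={"kg": (0.0, 0.5, 1.0)})
        table = gradients.site_gradients(matrix, meta)
        sub = table.xs("kg", level="metabolite_id")
        assert sub["significant"].all()
        assert sub.loc["ART_SVC", "median_difference"] < 0

    def test_cycle_of_mean_differences_sums_to_zero(self):
        matrix, meta = _trisite_dataset(
            n_subj=30, offsets={"m0": (0.0, 0.4, 0.9)})
        md = meta.data.reset_index()
        means = {}
        for pair, up, down in gradients.SITE_PAIR_ORDER:
            u = md[md["site"] == up].set_index("subject_id")["sample_id"]
            d = md[md["site"] == down].set_index("subject_id")["sample_id"]
            d = d.reindex(u.index)
            means[pair] = float(
                (matrix.data.loc[d, "m0"].to_numpy()
                 - matrix.data.loc[u, "m0"].to_numpy()).mean())
        assert sum(means.values()) == pytest.approx(0.0, abs=1e-12)

    def test_permuting_sites_within_subject_destroys_signal(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(10):
            matrix, meta = _trisite_dataset(
                n_subj=60, offsets={"hit": (0.0, 0.6, 0.6)}, seed=rep)
            md = meta.data.copy()
            for subj, block in md.groupby("subject_id"):
                md.loc[block.index, "site"] = rng.permutation(
                    block["site"].to_numpy())
            table = gradients.site_gradients(matrix, SampleMetadata(data=md))
            hits += int(table["significant"].any())
        assert hits <= 2

    def test_too_few_pairs_skipped(self, caplog):
        matrix, meta = _trisite_dataset(n_subj=3)
        with pytest.raises(ValueError):
            gradients.site_gradients(matrix, meta)


def hypergeom_two_sided_p(k, K, n, N):
    """Oracle: two-sided Fisher p as the hypergeometric-tail mass of all
    tables at most as probable as the observed one."""
    rv = stats.hypergeom(N, K, n)
    support = np.arange(max(0, n + K - N), min(K, n) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(k) * (1 + 1e-9)].sum())


def _gradient_table(sig_sets, detected):
    rows = []
    for pair, sig in sig_sets.items():
        for met in detected:
            rows.append({"metabolite_id": met, "site_pair": pair,
                         "n_pairs": 40, "median_difference": 0.0,
                         "p_value": 0.01 if met in sig else 0.9,
                         "p_adjusted": 0.01 if met in sig else 0.9,
                         "significant": met in sig})
    return pd.DataFrame(rows).set_index(["metabolite_id", "site_pair"])


def _annotation(pathway_of):
    df = pd.DataFrame({
        "subpathway": pd.Series(pathway_of),
        "superpathway": "SP",
        "identity_confirmed": True,
        "xenobiotic": False,
    })
    df.index.name = "metabolite_id"
    return MetaboliteAnnotation(data=df)


class TestPathwayEnrichment:
    def test_fully_significant_pathway_hits_hypergeometric_floor(self):
        """Pathway of 5, all significant, nothing else significant in a
        background of 100: p = 1/C(100,5)."""
        detected = [f"m{i}" for i in range(100)]
        pathway_of = {m: ("target" if i < 5 else f"other{i % 8}")
                      for i, m in enumerate(detected)}
        table = _gradient_table({"SVC_PA": set(detected[:5])}, detected)
        out = gradients.pathway_enrichment(table, _annotation(pathway_of))
        row = out[out["pathway"] == "target"].iloc[0]
        from math import comb
        assert row["p_value"] == pytest.approx(1 / comb(100, 5))

    def test_no_significant_metabolites_all_p_one(self):
        detected = [f"m{i}" for i in range(40)]
        pathway_of = {m: f"p{i % 4}" for i, m in enumerate(detected)}
        table = _gradient_table({"SVC_PA": set()}, detected)
        out = gradients.pathway_enrichment(table, _annotation(pathway_of))
        assert (out["p_value"] == 1.0).all()

    def test_small_pathways_excluded(self):
        detected = [f"m{i}" for i in range(20)]
        pathway_of = {m: ("tiny" if i < 3 else "big")
                      for i, m in enumerate(detected)}
        table = _gradient_table({"SVC_PA": set(detected[:6])}, detected)
        out = gradients.pathway_enrichment(table, _annotation(pathway_of),
                                           min_size=4)
        assert "tiny" not in set(out["pathway"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hypergeometric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(20, 200))
        detected = [f"m{i}" for i in range(N)]
        K = int(rng.integers(4, N // 2))
        pathway_of = {m: ("inset" if i < K else "rest")
                      for i, m in enumerate(detected)}
        n_sig = int(rng.integers(0, N))
        sig = set(rng.choice(detected, size=n_sig, replace=False))
        k = len(sig & set(detected[:K]))
        table = _gradient_table({"PA_ART": sig}, detected)
        out = gradients.pathway_enrichment(table, _annotation(pathway_of))
        row = out[out["pathway"] == "inset"].iloc[0]
        assert row["p_value"] == pytest.approx(
            hypergeom_two_sided_p(k, K, n_sig, N), rel=1e-6)
        assert row["k_significant"] == k


class TestRelevanceNetwork:
    def test_duplicated_column_gives_perfect_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        matrix = MetaboliteMatrix(data=pd.DataFrame(
            {"a": x, "b": x.copy(), "c": rng.normal(size=50)},
            index=[f"s{i}" for i in range(50)]), scale_tag="zscore")
        g = gradients.relevance_network(matrix)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["rho"] == pytest.approx(1.0)
        assert not g.has_edge("a", "c")

    def test_independent_noise_gives_no_edges_at_gradient_cohort_size(self):
        rng = np.random.default_rng(1)
        matrix = MetaboliteMatrix(data=pd.DataFrame(
            rng.normal(size=(258, 30)),
            index=[f"s{i}" for i in range(258)],
            columns=[f"m{i}" for i in range(30)]), scale_tag="zscore")
        g = gradients.relevance_network(matrix)
        assert g.number_of_edges() == 0

    def test_edge_list_matches_brute_force_scan(self):
        """Edges equal an exhaustive all-pairs Spearman scan at a lower
        threshold (so some edges exist)."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=(40, 4))
        cols = {}
        for j in range(12):
            src = base[:, j % 4]
            cols[f"m{j}"] = src + rng.normal(0, 0.4, 40)
        matrix = MetaboliteMatrix(
            data=pd.DataFrame(cols, index=[f"s{i}" for i in range(40)]),
            scale_tag="zscore")
        g = gradients.relevance_network(matrix, rho_threshold=0.6)
        expected = set()
        names = list(cols)
        for a, b in itertools.combinations(names, 2):
            rho = stats.spearmanr(cols[a], cols[b]).statistic
            if rho > 0.6:
                expected.add(frozenset((a, b)))
        assert {frozenset(e) for e in g.edges} == expected

    def test_components_labelled(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        matrix = MetaboliteMatrix(data=pd.DataFrame(
            {"a": x, "b": x + rng.normal(0, 0.01, 30),
             "c": rng.normal(size=30)},
            index=[f"s{i}" for i in range(30)]), scale_tag="zscore")
        g = gradients.relevance_network(matrix)
        assert g.nodes["a"]["component"] == g.nodes["b"]["component"]
        assert g.nodes["c"]["component"] != g.nodes["a"]["component"]


class TestClinicalCorrelations:
    def _dataset(self):
        rng = np.random.default_rng(4)
        n = 30
        walk = rng.uniform(100, 500, n)
        ids = [f"s{i}" for i in range(n)]
        matrix = MetaboliteMatrix(data=pd.DataFrame({
            "mono": np.sqrt(walk),          # monotone in walk distance
            "noise": rng.normal(size=n),
        }, index=ids), scale_tag="zscore")
        meta = SampleMetadata(data=pd.DataFrame({
            "subject_id": ids, "group": "CTEPH", "cohort": "gradient",
            "batch": "b0", "timepoint": "none", "site": "none",
            "walk_distance": walk,
        }, index=pd.Index(ids, name="sample_id")))
        return matrix, meta

    def test_monotone_function_gives_rho_one(self):
        matrix, meta = self._dataset()
        out = gradients.clinical_correlations(matrix, meta,
                                              variables=("walk_distance",))
        row = out[out["metabolite_id"] == "mono"].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_classical_rank_formula_oracle_no_ties(self):
        """rho on a 10-sample fixture equals 1 - 6*sum(d^2)/(n(n^2-1))."""
        matrix, meta = self._dataset()
        sub = matrix.data.iloc[:10]
        walk = meta.data["walk_distance"].iloc[:10]
        rx = stats.rankdata(sub["noise"])
        ry = stats.rankdata(walk)
        d2 = ((rx - ry) ** 2).sum()
        expected = 1 - 6 * d2 / (10 * 99)
        out = gradients.clinical_correlations(
            MetaboliteMatrix(data=sub, scale_tag="zscore"),
            SampleMetadata(data=meta.data.iloc[:10]),
            variables=("walk_distance",))
        row = out[out["metabolite_id"] == "noise"].iloc[0]
        assert row["rho"] == pytest.approx(expected, abs=1e-12)

    def test_missing_variable_column_skipped(self):
        matrix, meta = self._dataset()
        out = gradients.clinical_correlations(matrix, meta,
                                              variables=("mrap",))
        assert out.empty
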