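"""Multi-site arteriovenous gradient analysis and downstream summaries.

Paired Wilcoxon tests of metabolite abundance between anatomical sampling
sites (superior vena cava -> pulmonary artery -> radial artery), with
Benjamini-Hochberg FDR control within each site pair; Fisher's-exact
pathway enrichment over the detected-metabolite background; an undirected
relevance network linking metabolites with Spearman rho above a threshold;
and Spearman correlations of metabolites with clinical severity variables.

Sign convention: gradients are reported downstream minus upstream along the
flow direction SVC -> PA -> ART, so the SVC_PA gradient is PA minus SVC,
PA_ART is ART minus PA, and the closing ART_SVC difference is SVC minus ART.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import MetaboliteAnnotation, MetaboliteMatrix, SampleMetadata

log = logging.getLogger(__name__)

#: (pair label, upstream site, downstream site)
SITE_PAIR_ORDER = (
    ("SVC_PA", "SVC", "PA"),
    ("PA_ART", "PA", "ART"),
    ("ART_SVC", "ART", "SVC"),
)

MIN_PAIRS = 5


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR-adjusted p-values (monotone, adjusted >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _paired_site_values(matrix, metadata, upstream, downstream):
    """Aligned (upstream, downstream) value frames over shared subjects."""
    md = metadata.data
    up = md[md["site"] == upstream].reset_index().set_index("subject_id")
    down = md[md["site"] == downstream].reset_index().set_index("subject_id")
    shared = up.index.intersection(down.index)
    sample_col = md.index.name or "index"
    up_ids = up.loc[shared, sample_col]
    down_ids = down.loc[shared, sample_col]
    return (
        matrix.data.loc[up_ids].set_axis(shared, axis=0),
        matrix.data.loc[down_ids].set_axis(shared, axis=0),
    )


def site_gradients(
    matrix: MetaboliteMatrix,
    metadata: SampleMetadata,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired Wilcoxon gradient table, one row per metabolite x site pair.

    The effect is the median within-subject downstream-minus-upstream
    difference; FDR adjustment runs within each site pair across
    metabolites.  Pairs with fewer than 5 complete subjects are skipped.
    """
    frames = []
    for pair, upstream, downstream in SITE_PAIR_ORDER:
        up_vals, down_vals = _paired_site_values(matrix, metadata,
                                                 upstream, downstream)
        n_pairs = len(up_vals)
        if n_pairs < MIN_PAIRS:
            log.warning("skipping %s: only %d complete pairs", pair, n_pairs)
            continue
        diffs = down_vals.to_numpy(dtype=float) - up_vals.to_numpy(dtype=float)
        pvals = np.ones(diffs.shape[1])
        nonzero = np.abs(diffs).sum(axis=0) > 0
        if nonzero.any():
            with np.errstate(invalid="ignore"):
                res = stats.wilcoxon(
                    diffs[:, nonzero], zero_method="wilcox",
                    alternative="two-sided", method="approx", axis=0,
                )
            p_nonzero = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
            p_nonzero[~np.isfinite(p_nonzero)] = 1.0
            pvals[nonzero] = p_nonzero
        adj = benjamini_hochberg(pvals)
        frames.append(pd.DataFrame({
            "metabolite_id": matrix.data.columns,
            "site_pair": pair,
            "n_pairs": n_pairs,
            "median_difference": np.median(diffs, axis=0),
            "p_value": pvals,
            "p_adjusted": adj,
            "significant": adj < fdr_alpha,
        }))
    if not frames:
        raise ValueError("no site pair has enough complete subject pairs")
    return pd.concat(frames, ignore_index=True).set_index(
        ["metabolite_id", "site_pair"]
    )


def pathway_enrichment(
    gradient_table: pd.DataFrame,
    annotation: MetaboliteAnnotation,
    min_size: int = 4,
    level: str = "subpathway",
) -> pd.DataFrame:
    """Fisher's-exact pathway enrichment of significant-gradient metabolites.

    For each site pair, tests each pathway with >= ``min_size`` detected
    members using a two-sided 2x2 Fisher's exact test with all detected
    metabolites as background.
    """
    ann = annotation.data
    rows = []
    for pair in gradient_table.index.get_level_values("site_pair").unique():
        sub = gradient_table.xs(pair, level="site_pair")
        detected = sub.index
        sig = set(sub.index[sub["significant"]])
        pathways = ann.reindex(detected)[level].dropna()
        n_sig, n_det = len(sig), len(detected)
        for pathway, members in pathways.groupby(pathways):
            mets = set(members.index)
            K = len(mets)
            if K < min_size:
                continue
            k = len(mets & sig)
            table = [[k, n_sig - k], [K - k, n_det - K - (n_sig - k)]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append({
                "site_pair": pair, "pathway": pathway,
                "k_significant": k, "pathway_size": K,
                "n_significant": n_sig, "n_detected": n_det,
                "p_value": float(p),
            })
    return pd.DataFrame(rows)


def relevance_network(
    matrix: MetaboliteMatrix,
    metabolites=None,
    rho_threshold: float = 0.9,
    use_absolute: bool = False,
) -> nx.Graph:
    """Undirected graph linking metabolites with Spearman rho above threshold.

    The threshold is strict (rho > threshold on the signed correlation by
    default; ``use_absolute`` switches to |rho|).  Nodes carry a
    ``component`` label; edges carry their ``rho``.
    """
    cols = list(metabolites) if metabolites is not None else list(matrix.data.columns)
    sub = matrix.data[cols].to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(cols)
    if len(cols) >= 2:
        rho = stats.spearmanr(sub, axis=0).statistic
        rho = np.atleast_2d(rho)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = abs(rho[i, j]) if use_absolute else rho[i, j]
                if r > rho_threshold:
                    g.add_edge(cols[i], cols[j], rho=float(rho[i, j]))
    for label, component in enumerate(nx.connected_components(g)):
        for node in component:
            g.nodes[node]["component"] = label
    return g


def clinical_correlations(
    matrix: MetaboliteMatrix,
    metadata: SampleMetadata,
    variables=("mrap", "cardiac_output", "walk_distance"),
    metabolites=None,
) -> pd.DataFrame:
    """Spearman correlation of each metabolite with each clinical variable.

    Clinical variables are rank-normalised (rank-based inverse normal)
    first; Spearman's rho is invariant to this, so it only standardises
    reporting scales.  Samples missing a variable are dropped pairwise.
    """
    cols = list(metabolites) if metabolites is not None else list(matrix.data.columns)
    md = metadata.data.reindex(matrix.data.index)
    rows = []
    for var in variables:
        if var not in md.columns:
            continue
        v = pd.to_numeric(md[var], errors="coerce")
        ok = v.notna()
        if ok.sum() < 3:
            continue
        ranks = stats.rankdata(v[ok])
        normed = stats.norm.ppf(ranks / (ok.sum() + 1))
        for met in cols:
            x = matrix.data.loc[ok, met].to_numpy(dtype=float)
            keep = np.isfinite(x)
            if keep.sum() < 3:
                continue
            rho, p = stats.spearmanr(x[keep], normed[keep])
            rows.append({
                "metabolite_id": met, "variable": var,
                "rho": float(rho), "p_value": float(p),
                "n": int(keep.sum()),
            })
    return pd.DataFrame(rows)
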