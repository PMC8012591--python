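"""Metabolite response to pulmonary endarterectomy (PEA).

Two-stage screen: an unpaired Mann-Whitney comparison of independent
pre-surgery vs post-surgery patient groups (Bonferroni over the tested
panel), then a paired Wilcoxon signed-rank validation in subjects sampled
both before and after surgery, restricted to stage-1 hits.  For each
validated metabolite the percent of the baseline perturbation (relative to
healthy controls) corrected by surgery is reported, and hits whose
direction of change disagrees between the two designs are flagged as
probable false positives.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import batch_mann_whitney, bonferroni_threshold
from .io import MetaboliteMatrix, SampleMetadata

log = logging.getLogger(__name__)

_EXACT_PAIR_LIMIT = 25


def wilcoxon_signed_rank(pre, post) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    Zero differences are dropped (Wilcoxon convention; count logged).  The
    p-value is exact for <= 25 informative pairs without tied absolute
    differences, otherwise a tie-corrected normal approximation.  Returns
    ``(W, p)`` with W the smaller of the positive/negative rank sums.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must pair one-to-one")
    d = post - pre
    n_zero = int((d == 0).sum())
    if n_zero:
        log.debug("dropping %d zero differences", n_zero)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= _EXACT_PAIR_LIMIT and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method)
    p = float(res.pvalue)
    return float(res.statistic), (1.0 if np.isnan(p) else p)


class PercentCorrection(NamedTuple):
    """Fraction of the pre-surgery perturbation removed after surgery."""

    percent: float   # clamped to [-100, 200] for reporting
    raw: float       # unclamped value
    defined: bool    # False when the baseline perturbation is negligible


def percent_correction(pre_z, post_z) -> PercentCorrection:
    """100 * (median(pre) - median(post)) / median(pre) on the HC z-scale.

    Values must be healthy-control-referenced z-scores (HC centre 0), so
    100% means a full return to healthy-control level.  The statistic is
    undefined when the baseline perturbation |median(pre)| < 0.1 sd.
    """
    pre_z = np.asarray(pre_z, dtype=float)
    post_z = np.asarray(post_z, dtype=float)
    if pre_z.size == 0 or post_z.size == 0:
        raise ValueError("percent_correction needs non-empty inputs")
    med_pre = float(np.median(pre_z))
    med_post = float(np.median(post_z))
    if abs(med_pre) < 0.1:
        return PercentCorrection(np.nan, np.nan, False)
    raw = 100.0 * (med_pre - med_post) / med_pre
    return PercentCorrection(float(np.clip(raw, -100.0, 200.0)), raw, True)


def _split_subjects(metadata: SampleMetadata):
    """(unpaired pre ids, unpaired post ids, paired (pre id, post id) list)."""
    md = metadata.data
    pea = md[md["timepoint"].isin(["pre_PEA", "post_PEA"])]
    pivot = pea.reset_index().pivot_table(
        index="subject_id", columns="timepoint", values=pea.index.name or "index",
        aggfunc="first",
    )
    have_pre = pivot.get("pre_PEA")
    have_post = pivot.get("post_PEA")
    if have_pre is None or have_post is None:
        raise ValueError("need both pre_PEA and post_PEA samples")
    both = pivot.index[have_pre.notna() & have_post.notna()]
    only_pre = pivot.index[have_pre.notna() & have_post.isna()]
    only_post = pivot.index[have_pre.isna() & have_post.notna()]
    pairs = [(pivot.loc[s, "pre_PEA"], pivot.loc[s, "post_PEA"]) for s in both]
    return (
        [pivot.loc[s, "pre_PEA"] for s in only_pre],
        [pivot.loc[s, "post_PEA"] for s in only_post],
        pairs,
    )


def pea_screen(
    matrix: MetaboliteMatrix,
    metadata: SampleMetadata,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-stage PEA response screen; one row per stage-1 hit.

    Stage 1: unpaired Mann-Whitney, Bonferroni over tested metabolites.
    Stage 2: paired Wilcoxon on stage-1 hits, with a nominal p < 0.05 flag
    and a Benjamini-Hochberg FDR < 0.05 flag over the stage-1 hits.
    ``consistent`` is False when the unpaired and paired directions of
    change disagree (probable false positive).
    """
    from .gradients import benjamini_hochberg

    pre_ids, post_ids, pairs = _split_subjects(metadata)
    if not pre_ids or not post_ids:
        raise ValueError("stage 1 needs independent pre and post groups")
    mets = matrix.data.columns
    a = matrix.data.loc[post_ids].to_numpy(dtype=float)
    b = matrix.data.loc[pre_ids].to_numpy(dtype=float)
    _, p1, _ = batch_mann_whitney(a, b)
    bound = bonferroni_threshold(alpha, len(mets))
    hits = np.flatnonzero(p1 < bound)
    direction_unpaired = np.where(
        np.median(a, axis=0) >= np.median(b, axis=0), "up", "down"
    )

    pre_mat = matrix.data.loc[[p for p, _ in pairs]].to_numpy(dtype=float)
    post_mat = matrix.data.loc[[q for _, q in pairs]].to_numpy(dtype=float)
    rows = []
    for j in hits:
        w, p2 = wilcoxon_signed_rank(pre_mat[:, j], post_mat[:, j])
        med_diff = float(np.median(post_mat[:, j] - pre_mat[:, j]))
        dpair = "up" if med_diff >= 0 else "down"
        pc = percent_correction(pre_mat[:, j], post_mat[:, j])
        rows.append({
            "metabolite_id": mets[j],
            "p_unpaired": float(p1[j]),
            "p_paired": p2,
            "direction_unpaired": direction_unpaired[j],
            "direction_paired": dpair,
            "consistent": direction_unpaired[j] == dpair,
            "percent_correction": pc.percent,
            "percent_correction_raw": pc.raw,
            "correction_defined": pc.defined,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=[
            "p_unpaired", "p_paired", "p_paired_adj", "nominal",
            "fdr_significant", "direction_unpaired", "direction_paired",
            "consistent", "percent_correction", "percent_correction_raw",
            "correction_defined",
        ])
    table = table.set_index("metabolite_id")
    table["p_paired_adj"] = benjamini_hochberg(table["p_paired"].to_numpy())
    table["nominal"] = table["p_paired"] < 0.05
    table["fdr_significant"] = table["p_paired_adj"] < 0.05
    return table
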