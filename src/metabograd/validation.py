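"""Simulation studies that characterise the pipeline's operating behaviour.

Each function runs the relevant analysis stage on freshly generated
synthetic cohorts with planted (or null) truth and scores the outcome
against the generator's ledger: family-wise error under a global null,
p-value calibration of the paired test, recovery of planted disease
effects, of post-surgery correction fractions and of site gradients.
These are the package's own power/calibration checks; they are exercised
by the test suite and by ``scripts/acceptance.py``.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from . import cohorts as _cohorts
from . import gradients as _gradients
from . import pea as _pea
from . import preprocess as _pre
from . import synth as _synth


def _null_config(seed: int) -> _synth.SynthConfig:
    """Global-null study at the main-study discovery/replication scale."""
    return _synth.SynthConfig(
        seed=seed, m_metabolites=300, fraction_affected=0.0,
        n_twin_pairs=0, fraction_gradient=0.0,
        # comparator arms are not used by the cascade; keep them minimal
        n_dc=5, n_cted=5, n_ipah=5,
    )


def fwer_null_cascade(n_reps: int = 50, seed: int = 0) -> float:
    """Family-wise false-positive rate of the two-cohort Bonferroni cascade
    under a global null (no planted effects), over ``n_reps`` studies.

    The cascade tests m=300 metabolites in discovery (108 vs 58) and
    replication (92 vs 63) cohorts; a study counts as a family-wise error
    if any metabolite passes both screens with a consistent direction.
    """
    hits = 0
    for r in range(n_reps):
        cfg = _null_config(int(np.random.default_rng([seed, r]).integers(2**31)))
        matrix, meta, _, _ = _synth.generate_cohort(cfg)
        imputed = _pre.impute_min_detected(matrix)
        screen = _cohorts.discovery_replication(imputed, meta)
        hits += int(screen["passes"].any())
    return hits / n_reps


def wilcoxon_null_uniformity(
    n_sims: int = 1000, n_pairs: int = 40, seed: int = 0
) -> float:
    """KS-test p-value for uniformity of paired Wilcoxon p-values under an
    antisymmetric null (differences symmetric about zero)."""
    rng = np.random.default_rng([seed, 7])
    pvals = np.empty(n_sims)
    for i in range(n_sims):
        d = rng.standard_t(df=5, size=n_pairs)  # symmetric, heavy-tailed
        _, pvals[i] = _pea.wilcoxon_signed_rank(np.zeros(n_pairs), d)
    return float(stats.kstest(pvals, "uniform").pvalue)


def _recovery_config(seed: int) -> _synth.SynthConfig:
    """Planted 1.5-sd effects, confounders at 1/50 of the disease effect,
    ~100 cases / 60 controls per cohort."""
    return _synth.SynthConfig(
        seed=seed, m_metabolites=300, fraction_affected=0.15,
        effect_up_range=(1.5, 1.5), effect_down_range=(1.5, 1.5),
        age_effect_ratio=50.0, sex_effect_ratio=50.0,
        n_twin_pairs=0,
        n_cteph_discovery=100, n_cteph_replication=100,
        n_hc_discovery=60, n_hc_replication=60,
        n_dc=5, n_cted=5, n_ipah=5,
    )


def effect_recovery(n_reps: int = 50, seed: int = 0) -> tuple[float, float]:
    """(mean sensitivity, mean false positives per run) of the
    discovery/replication cascade on planted 1.5-sd effects."""
    sens, fps = [], []
    for r in range(n_reps):
        cfg = _recovery_config(
            int(np.random.default_rng([seed, 11, r]).integers(2**31))
        )
        matrix, meta, _, truth = _synth.generate_cohort(cfg)
        imputed = _pre.impute_min_detected(matrix)
        screen = _cohorts.discovery_replication(imputed, meta)
        planted = set(truth.affected["CTEPH_vs_HC"])
        passing = set(screen.index[screen["passes"]])
        sens.append(len(planted & passing) / len(planted))
        fps.append(len(passing - planted))
    return float(np.mean(sens)), float(np.mean(fps))


def correction_recovery(n_reps: int = 50, seed: int = 0) -> dict:
    """Recovery of planted percent-correction fractions (0.15-1.0).

    Returns a dict with the mean signed error, the mean absolute error and
    the largest absolute mean error across four planted-fraction bins, all
    in percentage points.  Bias (the binned means) is the calibration
    quantity; the per-metabolite absolute error reflects 43-pair sampling
    noise.
    """
    cfg_base = dict(
        m_metabolites=300, fraction_affected=0.15,
        frac_corrected=1.0, correction_range=(0.15, 1.0),
        n_inconsistent=0, n_twin_pairs=0,
    )
    planted, recovered = [], []
    for r in range(n_reps):
        cfg = _synth.SynthConfig(
            seed=int(np.random.default_rng([seed, 13, r]).integers(2**31)),
            **cfg_base,
        )
        matrix, meta, truth = _synth.generate_paired_pea(cfg)
        imputed = _pre.impute_min_detected(matrix)
        params = _pre.fit_boxcox(imputed)
        bc = _pre.apply_boxcox(imputed, params)
        hc = meta.samples_where(group="HC")
        z, _ = _pre.zscore_to_reference(bc, hc)
        _, _, pairs = _pea._split_subjects(meta)
        pre_mat = z.data.loc[[p for p, _ in pairs]]
        post_mat = z.data.loc[[q for _, q in pairs]]
        for met, f in truth.correction_fractions.items():
            if met not in z.data.columns:
                continue
            pc = _pea.percent_correction(pre_mat[met], post_mat[met])
            if pc.defined:
                planted.append(100.0 * f)
                recovered.append(pc.percent)
    planted = np.asarray(planted)
    errors = np.asarray(recovered) - planted
    edges = np.linspace(15.0, 100.0, 5)
    bin_means = [
        errors[(planted >= lo) & (planted <= hi)].mean()
        for lo, hi in zip(edges[:-1], edges[1:])
        if ((planted >= lo) & (planted <= hi)).any()
    ]
    return {
        "mean_signed_error": float(errors.mean()),
        "mean_abs_error": float(np.abs(errors).mean()),
        "max_abs_binned_error": float(np.max(np.abs(bin_means))),
        "n_scored": int(len(errors)),
    }


def gradient_sensitivity(n_reps: int = 50, seed: int = 0,
                         fdr_alpha: float = 0.05) -> float:
    """Fraction of planted site gradients (0.2-0.45 sd at 86 subjects)
    flagged at FDR < ``fdr_alpha`` by the paired gradient analysis."""
    found = total = 0
    for r in range(n_reps):
        cfg = _synth.SynthConfig(
            seed=int(np.random.default_rng([seed, 17, r]).integers(2**31)),
            m_metabolites=300, n_twin_pairs=0,
            gradient_range=(0.2, 0.45),
        )
        matrix, meta, truth = _synth.generate_trisite(cfg)
        imputed = _pre.impute_min_detected(matrix)
        params = _pre.fit_boxcox(imputed)
        bc = _pre.apply_boxcox(imputed, params)
        z, _ = _pre.zscore_to_reference(bc, bc.sample_ids)
        table = _gradients.site_gradients(z, meta, fdr_alpha=fdr_alpha)
        for pair, planted in truth.site_gradients.items():
            for met, offset in planted.items():
                if abs(offset) < 0.2 or met not in z.data.columns:
                    continue
                total += 1
                if bool(table.loc[(met, pair), "significant"]):
                    found += 1
    return found / total
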