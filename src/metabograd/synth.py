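"""Synthetic plasma-metabolomics cohorts with planted ground truth.

The generator emulates the statistical structure an untargeted LC-MS plasma
study of pulmonary hypertension rests on: log-normal semi-quantitative
intensities with subpathway correlation blocks, group effects planted on the
log scale in units of each metabolite's log-sd, covariate (age/sex) effects
much smaller than disease effects, additive batch shifts, and left-censoring
at a per-metabolite limit of detection.  Three designs are covered:

* a case/control cohort with discovery and replication arms plus disease
  comparator groups (``generate_cohort``),
* a surgery arm with unpaired pre/post groups and paired pre/post subjects
  whose post values move back toward the healthy mean by a planted
  correction fraction (``generate_paired_pea``),
* a tri-site arm with three samples per subject (superior vena cava,
  pulmonary artery, radial artery) sharing a subject random effect, with
  planted site-to-site offsets (``generate_trisite``).

Every planted parameter is recorded in a :class:`TruthLedger` so recovery
tests can score the pipeline against the truth.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MetaboliteAnnotation, MetaboliteMatrix, SampleMetadata

SITE_PAIRS = ("SVC_PA", "PA_ART", "ART_SVC")

_SUPERPATHWAYS = (
    "Lipid", "Amino Acid", "Nucleotide", "Carbohydrate",
    "Energy", "Cofactors and Vitamins", "Peptide", "Xenobiotics",
)


@dataclasses.dataclass
class SynthConfig:
    """Knobs of the synthetic study; defaults mirror the main-study scale."""

    seed: int = 0
    # metabolite panel
    m_metabolites: int = 375
    n_subpathways: int = 40
    frac_xenobiotic: float = 0.06
    frac_poorly_detected: float = 0.08
    lod_quantile: float = 0.005
    lod_quantile_poor: float = 0.15
    intra_subpathway_rho: float = 0.3
    # structurally related near-duplicate species (isomers, co-regulated
    # lipids) whose profiles correlate almost perfectly
    n_twin_pairs: int = 8
    twin_rho: float = 0.97
    # planted disease effects (units: per-metabolite log-sd)
    fraction_affected: float = 0.17
    effect_up_range: tuple = (0.84, 2.0)
    effect_down_range: tuple = (0.33, 1.53)
    prob_effect_up: float = 0.55
    frac_shared_ipah: float = 0.8
    frac_shared_dc: float = 0.15
    frac_shared_cted: float = 0.25
    # covariate interference
    frac_age_affected: float = 0.3
    frac_sex_affected: float = 0.3
    age_effect_ratio: float = 75.0
    sex_effect_ratio: float = 2.35
    # batches
    batch_count: int = 3
    batch_sd: float = 0.2
    # case/control cohort sizes
    n_hc_discovery: int = 58
    n_hc_replication: int = 63
    n_dc: int = 132
    n_cted: int = 63
    n_ipah: int = 433
    n_cteph_discovery: int = 108
    n_cteph_replication: int = 92
    # surgery arm
    n_paired: int = 43
    n_pre_unpaired: int = 64
    n_post_unpaired: int = 82
    frac_corrected: float = 0.6
    correction_range: tuple = (0.15, 1.0)
    n_inconsistent: int = 1
    subject_share: float = 0.5
    # tri-site arm
    n_trisite_cteph: int = 68
    n_trisite_ipah: int = 18
    fraction_gradient: float = 0.55
    gradient_range: tuple = (0.2, 0.45)
    site_subject_sd: float = 0.8
    site_noise_sd: float = 0.35
    clinical_coupling: float = 0.35

    def __post_init__(self) -> None:
        for name in (
            "m_metabolites", "n_subpathways", "batch_count",
            "n_hc_discovery", "n_hc_replication", "n_dc", "n_cted", "n_ipah",
            "n_cteph_discovery", "n_cteph_replication",
            "n_paired", "n_pre_unpaired", "n_post_unpaired",
            "n_trisite_cteph", "n_trisite_ipah",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lod_quantile", "lod_quantile_poor"):
            q = getattr(self, name)
            if not 0 <= q < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 <= self.fraction_affected <= 1:
            raise ValueError("fraction_affected must lie in [0, 1]")


@dataclasses.dataclass
class TruthLedger:
    """Planted parameters of one synthetic study, for recovery scoring."""

    affected: dict            # comparison -> {metabolite: delta (sd units)}
    confounder_effects: dict  # covariate -> {metabolite: beta (sd units)}
    batch_offsets: dict       # batch label -> {metabolite: offset (sd units)}
    correction_fractions: dict  # metabolite -> fraction in [0, 1]
    inconsistent: list        # metabolites with opposite unpaired/paired shifts
    site_gradients: dict      # site pair -> {metabolite: offset (sd units)}
    pathway_assignments: dict  # metabolite -> [subpathway, superpathway]
    seed: int = 0

    def __post_init__(self) -> None:
        for met, f in self.correction_fractions.items():
            if not 0 <= f <= 1:
                raise ValueError(f"correction fraction for {met} outside [0,1]")
        for comp, d in self.affected.items():
            for met, delta in d.items():
                if not np.isfinite(delta):
                    raise ValueError(f"non-finite effect for {met} in {comp}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# metabolite panel (shared across the three designs for a given seed)
# ---------------------------------------------------------------------------

def _build_panel(config: SynthConfig) -> dict:
    """Deterministic per-metabolite parameters derived from config.seed."""
    rng = np.random.default_rng([config.seed, 101])
    m = config.m_metabolites
    ids = np.array([f"M{i:04d}" for i in range(1, m + 1)])

    # pathway assignment: ~n_subpathways subpathways in 8 superpathways;
    # xenobiotics get their own superpathway
    n_sub = max(2, config.n_subpathways)
    sub_super = rng.integers(0, len(_SUPERPATHWAYS) - 1, size=n_sub)
    subpathway_idx = rng.integers(0, n_sub, size=m)
    xeno = rng.random(m) < config.frac_xenobiotic
    subpathways = np.array([f"subpathway_{k:02d}" for k in subpathway_idx])
    superpathways = np.array([_SUPERPATHWAYS[sub_super[k]] for k in subpathway_idx])
    subpathways[xeno] = "xenobiotic_chemicals"
    superpathways[xeno] = "Xenobiotics"
    confirmed = rng.random(m) > 0.15

    mu = rng.normal(7.0, 1.0, size=m)          # baseline log-intensity
    sd = rng.uniform(0.5, 1.5, size=m)         # per-metabolite log-sd
    poorly = rng.random(m) < config.frac_poorly_detected
    lod_q = np.where(poorly, config.lod_quantile_poor, config.lod_quantile)

    # planted CTEPH-vs-HC effects among non-xenobiotic, well-detected panel
    eligible = np.flatnonzero(~xeno & ~poorly)
    n_aff = int(round(config.fraction_affected * m))
    if 0 < config.fraction_affected and n_aff < 1:
        warnings.warn("fraction_affected * m < 1; planting no effects")
    n_aff = min(n_aff, eligible.size)
    affected_idx = rng.choice(eligible, size=n_aff, replace=False)
    delta = np.zeros(m)
    up = rng.random(n_aff) < config.prob_effect_up
    delta[affected_idx[up]] = rng.uniform(*config.effect_up_range, size=int(up.sum()))
    delta[affected_idx[~up]] = -rng.uniform(
        *config.effect_down_range, size=int((~up).sum())
    )

    shared_ipah = np.zeros(m, bool)
    shared_dc = np.zeros(m, bool)
    shared_cted = np.zeros(m, bool)
    shared_ipah[affected_idx] = rng.random(n_aff) < config.frac_shared_ipah
    shared_dc[affected_idx] = rng.random(n_aff) < config.frac_shared_dc
    shared_cted[affected_idx] = rng.random(n_aff) < config.frac_shared_cted

    # covariate effects, small relative to the disease effect
    mean_abs = np.abs(delta[affected_idx]).mean() if n_aff else 1.2
    beta_age = np.zeros(m)
    beta_sex = np.zeros(m)
    age_hit = rng.random(m) < config.frac_age_affected
    sex_hit = rng.random(m) < config.frac_sex_affected
    beta_age[age_hit] = rng.choice([-1, 1], size=int(age_hit.sum())) * (
        mean_abs / config.age_effect_ratio
    )
    beta_sex[sex_hit] = rng.choice([-1, 1], size=int(sex_hit.sum())) * (
        mean_abs / config.sex_effect_ratio
    )

    batch_off = rng.normal(0, config.batch_sd, size=(config.batch_count, m))

    # post-surgery correction fractions for a subset of affected metabolites
    frac = np.zeros(m)
    corrected = affected_idx[rng.random(n_aff) < config.frac_corrected]
    frac[corrected] = rng.uniform(*config.correction_range, size=corrected.size)
    n_inc = min(config.n_inconsistent, corrected.size)
    inconsistent = rng.choice(corrected, size=n_inc, replace=False)

    # site gradients (cumulative along flow SVC -> PA -> ART)
    n_grad = int(round(config.fraction_gradient * m))
    n_grad = min(n_grad, eligible.size)
    grad_idx = rng.choice(eligible, size=n_grad, replace=False)
    g_svc_pa = np.zeros(m)
    g_pa_art = np.zeros(m)
    which = rng.integers(0, 3, size=n_grad)  # 0: SVC_PA, 1: PA_ART, 2: both
    signs = rng.choice([-1, 1], size=n_grad)
    mags = rng.uniform(*config.gradient_range, size=n_grad)
    mags2 = rng.uniform(*config.gradient_range, size=n_grad)
    for k, j in enumerate(grad_idx):
        if which[k] in (0, 2):
            g_svc_pa[j] = signs[k] * mags[k]
        if which[k] in (1, 2):
            g_pa_art[j] = signs[k] * mags2[k]

    # twin pairs: structurally related species sharing planted parameters
    # and almost all of their biological/technical variation
    twin_of = np.full(m, -1)
    n_tw = min(config.n_twin_pairs, eligible.size // 2)
    if n_tw > 0:
        # half the twin primaries sit in the gradient set: correlated
        # clusters of related species are concentrated among metabolites
        # with tissue gradients
        n_from_grad = min(n_tw // 2, grad_idx.size)
        primaries = list(rng.choice(grad_idx, size=n_from_grad, replace=False))
        rest = np.setdiff1d(eligible, primaries)
        primaries += list(rng.choice(rest, size=n_tw - n_from_grad, replace=False))
        partners = rng.choice(
            np.setdiff1d(eligible, primaries), size=n_tw, replace=False
        )
        for a, b in zip(primaries, partners):
            twin_of[b] = a
            delta[b] = delta[a]
            for arr in (shared_ipah, shared_dc, shared_cted):
                arr[b] = arr[a]
            frac[b] = frac[a]
            g_svc_pa[b] = g_svc_pa[a]
            g_pa_art[b] = g_pa_art[a]
            subpathways[b] = subpathways[a]
            superpathways[b] = superpathways[a]
        affected_idx = np.flatnonzero(delta != 0)

    return {
        "ids": ids, "mu": mu, "sd": sd, "xeno": xeno, "poorly": poorly,
        "lod_q": lod_q, "subpathways": subpathways,
        "superpathways": superpathways, "confirmed": confirmed,
        "subpathway_idx": subpathway_idx, "delta": delta,
        "affected_idx": affected_idx, "shared_ipah": shared_ipah,
        "shared_dc": shared_dc, "shared_cted": shared_cted,
        "beta_age": beta_age, "beta_sex": beta_sex, "batch_off": batch_off,
        "correction_frac": frac, "inconsistent": ids[inconsistent].tolist(),
        "g_svc_pa": g_svc_pa, "g_pa_art": g_pa_art,
        "twin_of": twin_of, "twin_rho": config.twin_rho,
    }


def _annotation(panel) -> MetaboliteAnnotation:
    df = pd.DataFrame(
        {
            "subpathway": panel["subpathways"],
            "superpathway": panel["superpathways"],
            "identity_confirmed": panel["confirmed"],
            "xenobiotic": panel["xeno"],
        },
        index=pd.Index(panel["ids"], name="metabolite_id"),
    )
    return MetaboliteAnnotation(data=df)


def _ledger(config, panel, include=("cohort", "pea", "trisite")) -> TruthLedger:
    ids = panel["ids"]
    delta = panel["delta"]
    aff = panel["affected_idx"]

    def effects(mask):
        return {ids[j]: float(delta[j]) for j in aff if mask[j]}

    affected = {}
    if "cohort" in include or "pea" in include:
        affected["CTEPH_vs_HC"] = {ids[j]: float(delta[j]) for j in aff}
    if "cohort" in include:
        affected["CTEPH_vs_DC"] = effects(~panel["shared_dc"])
        affected["CTEPH_vs_CTED"] = effects(~panel["shared_cted"])
        affected["CTEPH_vs_IPAH_HPAH"] = effects(~panel["shared_ipah"])
    grads = {}
    if "trisite" in include:
        g1, g2 = panel["g_svc_pa"], panel["g_pa_art"]
        grads["SVC_PA"] = {ids[j]: float(g1[j]) for j in range(len(ids)) if g1[j]}
        grads["PA_ART"] = {ids[j]: float(g2[j]) for j in range(len(ids)) if g2[j]}
        g3 = -(g1 + g2)
        grads["ART_SVC"] = {
            ids[j]: float(g3[j]) for j in range(len(ids)) if g1[j] or g2[j]
        }
    corrections = {}
    inconsistent = []
    if "pea" in include:
        corrections = {
            ids[j]: float(panel["correction_frac"][j])
            for j in aff
            if panel["correction_frac"][j] > 0
        }
        inconsistent = list(panel["inconsistent"])
    return TruthLedger(
        affected=affected,
        confounder_effects={
            "age": {ids[j]: float(b) for j, b in enumerate(panel["beta_age"]) if b},
            "sex": {ids[j]: float(b) for j, b in enumerate(panel["beta_sex"]) if b},
        },
        batch_offsets={
            f"batch_{b}": {ids[j]: float(v) for j, v in enumerate(row)}
            for b, row in enumerate(panel["batch_off"])
        },
        correction_fractions=corrections,
        inconsistent=inconsistent,
        site_gradients=grads,
        pathway_assignments={
            ids[j]: [panel["subpathways"][j], panel["superpathways"][j]]
            for j in range(len(ids))
        },
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# sample-level machinery
# ---------------------------------------------------------------------------

_COVARIATE_PROFILES = {
    # group: (age mean, age sd, P(female), P(european), creatinine median,
    #         bilirubin median, clinical medians (mrap, mpap, pvr, co, 6mwd))
    "HC": (51, 12, 0.64, 0.55, np.nan, np.nan, None),
    "DC": (59, 14, 0.68, 0.43, 71, 9, (6, 20, 1.7, 4.8, 387)),
    "CTED": (60, 13, 0.43, 0.66, 78, 9, (6, 20, 1.8, 5.2, 387)),
    "IPAH_HPAH": (54, 15, 0.70, 0.83, 83, 11, (9, 53, 11.1, 3.8, 336)),
    "CTEPH": (67, 11, 0.48, 0.75, 86, 12, (9, 43, 8.0, 3.9, 260)),
}

_DRUG_PROBS = {
    # group: (pde5i, era, anticoagulant, loop diuretic, statin)
    "HC": (0, 0, 0, 0, 0),
    "DC": (0, 0, 0.33, 0.18, 0.30),
    "CTED": (0.02, 0, 0.84, 0.08, 0.22),
    "IPAH_HPAH": (0.65, 0.54, 0.67, 0.53, 0.26),
    "CTEPH": (0.38, 0.25, 0.95, 0.47, 0.40),
}

DRUG_COLUMNS = ("drug_pde5i", "drug_era", "drug_anticoagulant",
                "drug_diuretic", "drug_statin")


def _draw_covariates(rng, groups: np.ndarray) -> pd.DataFrame:
    n = len(groups)
    out = pd.DataFrame(index=range(n))
    age = np.empty(n)
    female = np.empty(n)
    european = np.empty(n)
    creat = np.full(n, np.nan)
    bili = np.full(n, np.nan)
    clin = {k: np.full(n, np.nan) for k in
            ("mrap", "mpap", "pvr", "cardiac_output", "walk_distance")}
    drugs = {c: np.zeros(n) for c in DRUG_COLUMNS}
    for g in np.unique(groups):
        sel = groups == g
        k = int(sel.sum())
        a_mu, a_sd, p_f, p_e, cr, bl, clinical = _COVARIATE_PROFILES[g]
        age[sel] = np.clip(rng.normal(a_mu, a_sd, k), 18, 90)
        female[sel] = (rng.random(k) < p_f).astype(float)
        european[sel] = (rng.random(k) < p_e).astype(float)
        if np.isfinite(cr):
            creat[sel] = np.exp(rng.normal(np.log(cr), 0.25, k))
        if np.isfinite(bl):
            bili[sel] = np.exp(rng.normal(np.log(bl), 0.4, k))
        if clinical is not None:
            mrap, mpap, pvr, co, mwd = clinical
            clin["mrap"][sel] = np.clip(rng.normal(mrap, 3.5, k), 0, None)
            clin["mpap"][sel] = np.clip(rng.normal(mpap, 10, k), 8, None)
            clin["pvr"][sel] = np.clip(rng.normal(pvr, 3.0, k), 0.3, None)
            clin["cardiac_output"][sel] = np.clip(rng.normal(co, 1.0, k), 1.5, None)
            clin["walk_distance"][sel] = np.clip(rng.normal(mwd, 110, k), 0, None)
        for col, p in zip(DRUG_COLUMNS, _DRUG_PROBS[g]):
            drugs[col][sel] = (rng.random(k) < p).astype(float)
    out["age"] = age
    out["sex_female"] = female
    out["ethnicity_european"] = european
    out["bmi"] = np.clip(rng.normal(27.5, 4.5, n), 16, 55)
    out["creatinine"] = creat
    out["bilirubin"] = bili
    for col in DRUG_COLUMNS:
        out[col] = drugs[col]
    for col, v in clin.items():
        out[col] = v
    return out


def _base_noise(rng, n, panel, rho) -> np.ndarray:
    """Subpathway-block-correlated standard noise, n x m.

    Twin metabolites share almost all of their partner's variation."""
    m = len(panel["ids"])
    n_sub = panel["subpathway_idx"].max() + 1
    block = rng.normal(size=(n, n_sub))[:, panel["subpathway_idx"]]
    eps = rng.normal(size=(n, m))
    return _mix_twins(np.sqrt(rho) * block + np.sqrt(1 - rho) * eps, panel)


def _mix_twins(noise: np.ndarray, panel) -> np.ndarray:
    """Blend each twin's standard noise with its partner's."""
    r = panel["twin_rho"]
    for b in np.flatnonzero(panel["twin_of"] >= 0):
        a = panel["twin_of"][b]
        noise[..., b] = r * noise[..., a] + np.sqrt(1 - r * r) * noise[..., b]
    return noise


def _censor(rng_unused, values: np.ndarray, lod_q: np.ndarray) -> np.ndarray:
    """Left-censor each metabolite below its empirical detection quantile."""
    out = values.copy()
    for j in range(values.shape[1]):
        if lod_q[j] <= 0:
            continue
        lod = np.quantile(values[:, j], lod_q[j])
        out[values[:, j] < lod, j] = np.nan
    return out


def _assemble(panel, log_values, sample_ids) -> MetaboliteMatrix:
    df = pd.DataFrame(
        np.exp(log_values),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=panel["ids"],
    )
    return MetaboliteMatrix(data=df, scale_tag="raw")


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_cohort(config: SynthConfig):
    """Case/control study: discovery + replication CTEPH vs HC, plus DC,
    CTED and IPAH/HPAH comparator groups.

    Returns ``(matrix, metadata, annotation, truth)``.
    """
    panel = _build_panel(config)
    rng = np.random.default_rng([config.seed, 202])
    blocks = [
        ("HC", "discovery", config.n_hc_discovery),
        ("HC", "replication", config.n_hc_replication),
        ("CTEPH", "discovery", config.n_cteph_discovery),
        ("CTEPH", "replication", config.n_cteph_replication),
        ("DC", "none", config.n_dc),
        ("CTED", "none", config.n_cted),
        ("IPAH_HPAH", "none", config.n_ipah),
    ]
    groups = np.concatenate([[g] * n for g, _, n in blocks])
    cohorts = np.concatenate([[c] * n for _, c, n in blocks])
    n = len(groups)
    covs = _draw_covariates(rng, groups)
    batches = rng.integers(0, config.batch_count, size=n)

    sd = panel["sd"]
    x = panel["mu"] + sd * _base_noise(rng, n, panel, config.intra_subpathway_rho)
    # disease effects
    delta = panel["delta"] * sd
    x[groups == "CTEPH"] += delta
    x[groups == "IPAH_HPAH"] += delta * panel["shared_ipah"]
    x[groups == "DC"] += delta * panel["shared_dc"]
    x[groups == "CTED"] += delta * panel["shared_cted"]
    # covariate effects (age standardised to the all-sample scale)
    age_z = (covs["age"].to_numpy() - 55.0) / 15.0
    x += np.outer(age_z, panel["beta_age"] * sd)
    x += np.outer(covs["sex_female"].to_numpy(), panel["beta_sex"] * sd)
    # batch shifts
    x += panel["batch_off"][batches] * sd
    x = _censor(rng, x, panel["lod_q"])

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    meta = pd.DataFrame(
        {
            "subject_id": [f"subj_{i:04d}" for i in range(1, n + 1)],
            "group": groups,
            "cohort": cohorts,
            "batch": [f"batch_{b}" for b in batches],
            "timepoint": "none",
            "site": "none",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta = pd.concat([meta, covs.set_index(meta.index)], axis=1)
    return (
        _assemble(panel, x, sample_ids),
        SampleMetadata(data=meta),
        _annotation(panel),
        _ledger(config, panel, include=("cohort",)),
    )


def generate_paired_pea(config: SynthConfig):
    """Surgery arm: healthy controls, independent pre/post groups and paired
    pre/post subjects.  Post values move toward the healthy mean by the
    planted correction fraction.

    Returns ``(matrix, metadata, truth)``; the annotation is shared with the
    cohort design (same seed) via :func:`generate_cohort` or
    :func:`annotation_for`.
    """
    panel = _build_panel(config)
    rng = np.random.default_rng([config.seed, 303])
    sd = panel["sd"]
    delta = panel["delta"] * sd
    frac = panel["correction_frac"]
    inconsistent = set(panel["inconsistent"])
    inc_mask = np.isin(panel["ids"], list(inconsistent))
    rho = config.intra_subpathway_rho

    rows, meta_rows = [], []
    n_hc = config.n_hc_discovery
    hc = panel["mu"] + sd * _base_noise(rng, n_hc, panel, rho)
    for i in range(n_hc):
        rows.append(hc[i])
        meta_rows.append((f"hc_{i:03d}", "HC", "none", "none"))

    pre_u = panel["mu"] + delta + sd * _base_noise(
        rng, config.n_pre_unpaired, panel, rho
    )
    for i in range(config.n_pre_unpaired):
        rows.append(pre_u[i])
        meta_rows.append((f"unp_pre_{i:03d}", "CTEPH", "pre_PEA", "none"))

    post_shift = (1 - frac) * delta
    # the planted inconsistent metabolite moves further up in the unpaired
    # post group but down in the paired subjects
    post_shift_unpaired = np.where(inc_mask, delta + 0.8 * sd, post_shift)
    post_u = panel["mu"] + post_shift_unpaired + sd * _base_noise(
        rng, config.n_post_unpaired, panel, rho
    )
    for i in range(config.n_post_unpaired):
        rows.append(post_u[i])
        meta_rows.append((f"unp_post_{i:03d}", "CTEPH", "post_PEA", "none"))

    share = config.subject_share
    subj_sd = sd * np.sqrt(share)
    resid_sd = sd * np.sqrt(1 - share)
    post_shift_paired = np.where(inc_mask, delta - 0.8 * sd, post_shift)
    for i in range(config.n_paired):
        a = rng.normal(0, 1, size=len(sd)) * subj_sd
        pre = panel["mu"] + delta + a + resid_sd * rng.normal(size=len(sd))
        post = (
            panel["mu"] + post_shift_paired + a
            + resid_sd * rng.normal(size=len(sd))
        )
        rows.append(pre)
        meta_rows.append((f"pair_{i:03d}", "CTEPH", "pre_PEA", "paired"))
        rows.append(post)
        meta_rows.append((f"pair_{i:03d}", "CTEPH", "post_PEA", "paired"))

    x = _censor(rng, np.vstack(rows), panel["lod_q"])
    sample_ids = [f"P{i:04d}" for i in range(1, len(rows) + 1)]
    subj, grp, tp, _tag = zip(*meta_rows)
    groups = np.array(grp)
    covs = _draw_covariates(rng, groups)
    meta = pd.DataFrame(
        {
            "subject_id": subj,
            "group": groups,
            "cohort": "none",
            "batch": "batch_0",
            "timepoint": tp,
            "site": "none",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta = pd.concat([meta, covs.set_index(meta.index)], axis=1)
    return (
        _assemble(panel, x, sample_ids),
        SampleMetadata(data=meta),
        _ledger(config, panel, include=("pea",)),
    )


def generate_trisite(config: SynthConfig):
    """Tri-site arm: three samples per subject (SVC, PA, ART) with a shared
    subject random effect and planted cumulative site offsets along the flow
    direction SVC -> PA -> ART.

    Returns ``(matrix, metadata, truth)``.
    """
    panel = _build_panel(config)
    rng = np.random.default_rng([config.seed, 404])
    sd = panel["sd"]
    m = len(sd)
    delta = panel["delta"] * sd
    cum = {
        "SVC": np.zeros(m),
        "PA": panel["g_svc_pa"] * sd,
        "ART": (panel["g_svc_pa"] + panel["g_pa_art"]) * sd,
    }
    n_subj = config.n_trisite_cteph + config.n_trisite_ipah
    subj_groups = np.array(
        ["CTEPH"] * config.n_trisite_cteph + ["IPAH_HPAH"] * config.n_trisite_ipah
    )
    order = rng.permutation(n_subj)
    subj_groups = subj_groups[order]

    severity = rng.normal(size=n_subj)
    kappa = config.clinical_coupling
    aff_mask = np.zeros(m)
    aff_mask[panel["affected_idx"]] = 1.0

    rows, meta_rows = [], []
    for i in range(n_subj):
        g = subj_groups[i]
        base = panel["mu"].copy()
        base = base + delta * (1.0 if g == "CTEPH" else panel["shared_ipah"])
        subj_scale = config.site_subject_sd
        resid = np.sqrt(max(subj_scale**2 - kappa**2, 0.0))
        a = sd * (
            kappa * severity[i] * aff_mask * np.sign(panel["delta"])
            + resid * _mix_twins(rng.normal(size=m), panel) * aff_mask
            + subj_scale * _mix_twins(rng.normal(size=m), panel) * (1 - aff_mask)
        )
        for site in ("SVC", "PA", "ART"):
            e = config.site_noise_sd * sd * _mix_twins(rng.normal(size=m), panel)
            rows.append(base + a + cum[site] + e)
            meta_rows.append((f"tri_{i:03d}", g, site))

    x = _censor(rng, np.vstack(rows), panel["lod_q"])
    sample_ids = [f"T{i:04d}" for i in range(1, len(rows) + 1)]
    subj, grp, sites = zip(*meta_rows)
    meta = pd.DataFrame(
        {
            "subject_id": subj,
            "group": grp,
            "cohort": "gradient",
            "batch": "batch_0",
            "timepoint": "none",
            "site": sites,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    # clinical severity variables at the subject level, repeated per sample
    sev = np.repeat(severity, 3)
    meta["age"] = np.repeat(np.clip(rng.normal(64, 12, n_subj), 18, 90), 3)
    meta["mrap"] = np.clip(8 + 3.0 * sev + rng.normal(0, 1.5, 3 * n_subj), 0, None)
    meta["cardiac_output"] = np.clip(
        4.6 - 0.8 * sev + rng.normal(0, 0.5, 3 * n_subj), 1.5, None
    )
    meta["walk_distance"] = np.clip(
        352 - 80 * sev + rng.normal(0, 40, 3 * n_subj), 0, None
    )
    return (
        _assemble(panel, x, sample_ids),
        SampleMetadata(data=meta),
        _ledger(config, panel, include=("trisite",)),
    )


def annotation_for(config: SynthConfig) -> MetaboliteAnnotation:
    """The metabolite annotation shared by all designs at this seed."""
    return _annotation(_build_panel(config))


def full_truth(config: SynthConfig) -> TruthLedger:
    """Truth ledger covering all three designs at this seed."""
    return _ledger(config, _build_panel(config))
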