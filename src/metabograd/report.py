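"""End-to-end pipeline orchestration, overlap sets and the run manifest.

``run_pipeline`` exercises every stage on synthetic cohorts with planted
ground truth: preprocessing, the discovery/replication differential cascade
with confounder adjustment and specificity tiers, ROC evaluation of the
tiered markers, the two-stage surgery-response screen, and the tri-site
gradient analysis with enrichment, relevance network and clinical
correlations.  All tables are written as CSV next to a JSON manifest that
records the configuration, the seed, library versions, the named analysis
decisions, and a hash of every output, so an identical configuration and
seed reproduces the run byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from . import cohorts as _cohorts
from . import gradients as _gradients
from . import pea as _pea
from . import preprocess as _pre
from . import roc as _roc
from . import synth as _synth
from .io import write_table

ANALYSIS_DECISIONS = {
    "imputation": "minimum detected level per metabolite, before Box-Cox",
    "detection_filter": "nonxenobiotic and detected in >=95% of samples",
    "boxcox_grid": "lambda in [-2, 2] step 0.1, per-metabolite profile ML",
    "zscore_reference": "healthy-control group (all samples when absent)",
    "quantile_normalisation": "after z-scoring, across all samples",
    "replication_rule": "Bonferroni alpha/m in both cohorts + shared direction",
    "confounders": "binary preserved renal (<75 umol/L creatinine) and liver "
                   "(<21 umol/L bilirubin) indicators; complete-case",
    "roc_cutoff": "Youden's J, ties toward higher sensitivity",
    "roc_ci": "DeLong variance, normal quantiles, truncated to [0, 1]",
    "pea_stage1": "Bonferroni over tested metabolites, unpaired groups",
    "pea_stage2": "Benjamini-Hochberg FDR < 0.05 over stage-1 hits",
    "gradient_sign": "downstream minus upstream along flow SVC -> PA -> ART",
    "gradient_fdr": "Benjamini-Hochberg within site pair across metabolites",
    "network_threshold": "Spearman rho > 0.9, signed (not absolute)",
}


@dataclasses.dataclass
class OverlapSummary:
    """Named metabolite sets with all pairwise and triple intersections."""

    sets: dict          # name -> sorted member list
    intersections: dict  # "A&B" / "A&B&C" -> sorted member list

    def counts(self) -> dict:
        out = {name: len(m) for name, m in self.sets.items()}
        out.update({name: len(m) for name, m in self.intersections.items()})
        return out

    def to_json(self, path) -> None:
        payload = {
            "sets": self.sets,
            "intersections": self.intersections,
            "counts": self.counts(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def overlap_sets(named_sets: dict) -> OverlapSummary:
    """Exact set algebra over named metabolite sets, deterministic order."""
    sets = {name: sorted(set(members)) for name, members in named_sets.items()}
    inter = {}
    names = sorted(sets)
    for r in (2, 3):
        for combo in itertools.combinations(names, r):
            common = set(sets[combo[0]])
            for name in combo[1:]:
                common &= set(sets[name])
            inter["&".join(combo)] = sorted(common)
    return OverlapSummary(sets=sets, intersections=inter)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: _synth.SynthConfig,
    out_dir,
    alpha: float = 0.05,
    quantile_normalise_last: bool = True,
) -> dict:
    """Generate the three synthetic designs and run every analysis stage.

    Returns a dict of in-memory results and writes all tables plus
    ``manifest.json`` under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- case/control arm -------------------------------------------------
    matrix, meta, ann, truth_cohort = _synth.generate_cohort(config)
    hc_ids = meta.samples_where(group="HC")
    z, bc_params, ref_stats = _pre.standard_chain(
        matrix, ann, hc_ids, quantile_normalise_last=quantile_normalise_last
    )
    screen = _cohorts.discovery_replication(z, meta, "CTEPH", "HC", alpha=alpha)
    passing = list(screen.index[screen["passes"]])
    adj_hc = _cohorts.confounder_adjust(z, meta, passing, "CTEPH", "HC", alpha)
    robust = list(adj_hc.index[adj_hc["significant"]]) if len(adj_hc) else []
    adj_comp = {}
    for comparator in ("DC", "CTED", "IPAH_HPAH"):
        adj_comp[comparator] = _cohorts.confounder_adjust(
            z, meta, robust, "CTEPH", comparator, alpha
        )
    tiers = _cohorts.tier_classify(
        screen, adj_hc, adj_comp["DC"], adj_comp["CTED"], adj_comp["IPAH_HPAH"]
    )
    differential = screen.copy()
    differential["adjusted_p_HC"] = adj_hc["p_group"].reindex(differential.index)
    differential["tier"] = tiers

    roc_markers = list(tiers.index[tiers.isin(
        ["vs_HC_DC_CTED", "vs_all_including_IPAH"]
    )])
    roc_table = _roc.evaluate_markers(z, meta, roc_markers, "CTEPH", ("HC", "DC"))

    # ---- surgery arm ------------------------------------------------------
    pea_matrix, pea_meta, truth_pea = _synth.generate_paired_pea(config)
    hc_pea = pea_meta.samples_where(group="HC")
    z_pea, _, _ = _pre.standard_chain(
        pea_matrix, ann, hc_pea, quantile_normalise_last=quantile_normalise_last
    )
    pea_table = _pea.pea_screen(z_pea, pea_meta, alpha=alpha)

    # ---- tri-site arm -----------------------------------------------------
    tri_matrix, tri_meta, truth_tri = _synth.generate_trisite(config)
    z_tri, _, _ = _pre.standard_chain(
        tri_matrix, ann, tri_matrix.sample_ids,
        quantile_normalise_last=quantile_normalise_last,
    )
    grad_table = _gradients.site_gradients(z_tri, tri_meta, fdr_alpha=alpha)
    enrichment = _gradients.pathway_enrichment(grad_table, ann)
    sig_by_pair = {
        pair: set(grad_table.xs(pair, level="site_pair").pipe(
            lambda t: t.index[t["significant"]]
        ))
        for pair in grad_table.index.get_level_values("site_pair").unique()
    }
    grad_mets = sorted(set().union(*sig_by_pair.values())) if sig_by_pair else []
    network = _gradients.relevance_network(z_tri, grad_mets)
    clinical = _gradients.clinical_correlations(z_tri, tri_meta,
                                                metabolites=grad_mets)

    # ---- overlaps ---------------------------------------------------------
    overlaps = overlap_sets({
        "CTEPH_associated": robust,
        "PEA_responsive": list(
            pea_table.index[pea_table["nominal"] & pea_table["consistent"]]
        ) if len(pea_table) else [],
        "gradient_SVC_PA": sorted(sig_by_pair.get("SVC_PA", set())),
        "gradient_PA_ART": sorted(sig_by_pair.get("PA_ART", set())),
        "gradient_ART_SVC": sorted(sig_by_pair.get("ART_SVC", set())),
    })

    # ---- write artefacts --------------------------------------------------
    files = {
        "differential_table.csv": differential,
        "confounder_adjusted_HC.csv": adj_hc,
        "roc_records.csv": roc_table,
        "pea_records.csv": pea_table,
        "gradient_table.csv": grad_table,
        "pathway_enrichment.csv": enrichment,
        "clinical_correlations.csv": clinical,
        "boxcox_params.csv": bc_params.table,
        "reference_stats.csv": ref_stats.table,
    }
    for name, df in files.items():
        write_table(df, out / name)
    edges = pd.DataFrame(
        [(u, v, d["rho"]) for u, v, d in network.edges(data=True)],
        columns=["metabolite_a", "metabolite_b", "rho"],
    )
    edges.to_csv(out / "network_edges.csv", index=False)
    nx.write_graphml(network, out / "network.graphml")
    overlaps.to_json(out / "overlap_summary.json")
    truth_cohort.to_json(out / "truth_cohort.json")
    truth_pea.to_json(out / "truth_pea.json")
    truth_tri.to_json(out / "truth_trisite.json")

    manifest = _manifest(config, alpha, quantile_normalise_last, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return {
        "differential": differential,
        "adjusted_hc": adj_hc,
        "tiers": tiers,
        "roc": roc_table,
        "pea": pea_table,
        "gradients": grad_table,
        "enrichment": enrichment,
        "network": network,
        "clinical": clinical,
        "overlaps": overlaps,
        "truth": {
            "cohort": truth_cohort, "pea": truth_pea, "trisite": truth_tri,
        },
        "manifest": manifest,
    }


def _manifest(config, alpha, qn_last, out: Path) -> dict:
    import numpy, pandas, scipy

    from . import __version__

    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.name != "manifest.json"
    }
    return {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "alpha": alpha,
        "quantile_normalise_last": qn_last,
        "decisions": ANALYSIS_DECISIONS,
        "versions": {
            "metabograd": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "outputs": outputs,
    }
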