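"""Pipeline orchestration and the co-IP interactor GSEA workflow.

``run_pipeline`` executes the full synthetic study end to end — simulate,
preprocess, ratiometric enrichment, combined-experiment stress analysis,
transcript/protein integration — into a run directory with per-stage TSV/JSON
outputs, a machine-readable summary, and a parameter log. ``run_coip_gsea``
ranks an interactor differential table and runs preranked GSEA with a
normalized-enrichment-score report filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genesets import GeneSetCollection, write_gmt, write_rnk
from .io_preprocess import (
    filter_valid_values,
    impute_downshift,
    median_normalize,
)
from .omics_integration import assign_quadrants, pair_features, quadrant_ora
from .proximity_enrichment import ratiometric_enrichment, scatter_table
from .stats_core import pca_scores, preranked_gsea
from .stress_shift import combine_experiments, gate_muscle_expressed, stress_volcano
from .synthdata import (
    SimConfig,
    simulate_gene_sets,
    simulate_paired_omics,
    simulate_proximity_experiment,
    simulate_stress_experiment,
)

__all__ = ["RunConfig", "run_coip_gsea", "run_pipeline"]

_KNOWN_KEYS = {
    "alpha",
    "fold_threshold_log2",
    "gate_mode",
    "min_valid",
    "valid_scope",
    "impute_width",
    "impute_downshift",
    "impute_per_sample",
    "gsea_n_perm",
    "gsea_p_weight",
    "nes_cutoff",
    "omics_filter_mode",
    "ora_q_cutoff",
    "seed",
    "sim",
}


@dataclass
class RunConfig:
    """Parameters for an end-to-end run; unknown keys are rejected."""

    alpha: float = 0.05
    fold_threshold_log2: float = 1.0
    gate_mode: str = "either"
    min_valid: int = 3
    valid_scope: str = "any_group"
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    impute_per_sample: bool = True
    gsea_n_perm: int = 200
    gsea_p_weight: float = 1.0
    nes_cutoff: float = 0.5
    omics_filter_mode: str = "transcript_significant"
    ora_q_cutoff: float = 0.05
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim is not None:
            cfg.sim = SimConfig.from_dict(sim) if isinstance(sim, dict) else sim
        else:
            cfg.sim.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _KNOWN_KEYS if k != "sim"}
        d["sim"] = self.sim.to_dict()
        return d


def run_coip_gsea(
    interactor_table: pd.DataFrame,
    sets: GeneSetCollection,
    nes_cutoff: float = 0.5,
    n_perm: int = 1000,
    seed: int | None = None,
    rank_metric: str = "log2fc",
    p_weight: float = 1.0,
    both_directions: bool = True,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA on a co-immunoprecipitation interactor table.

    ``interactor_table`` needs columns id, log2fc and (for the signed-p
    metric) pvalue. The ranking metric is the signed log2 fold change by
    default, or sign(log2fc) * -log10(p) with ``rank_metric="signed_logp"``.
    Rows are filtered to NES >= nes_cutoff; with ``both_directions`` the
    symmetric negative tail (NES <= -nes_cutoff) is reported as well. Output
    is ranked by NES, descending.
    """
    table = interactor_table.copy()
    if "id" not in table.columns or "log2fc" not in table.columns:
        raise ValueError("interactor table needs 'id' and 'log2fc' columns")
    if rank_metric == "log2fc":
        metric = table["log2fc"].astype(float)
    elif rank_metric == "signed_logp":
        if "pvalue" not in table.columns:
            raise ValueError("signed_logp metric needs a 'pvalue' column")
        p = table["pvalue"].astype(float).clip(lower=1e-300)
        metric = np.sign(table["log2fc"].astype(float)) * (-np.log10(p))
    else:
        raise ValueError(f"unknown rank_metric: {rank_metric!r}")
    if not np.isfinite(metric).all():
        raise ValueError("ranking metric must be finite for every id")
    ranked = pd.DataFrame({"id": table["id"].astype(str), "score": metric})
    result = preranked_gsea(
        ranked, sets, p_weight=p_weight, n_perm=n_perm, seed=seed, min_size=min_size
    )
    if len(result) == 0:
        raise ValueError("no gene set overlaps the ranked ids at min_size")
    keep = result["nes"] >= nes_cutoff
    if both_directions:
        keep |= result["nes"] <= -nes_cutoff
    return result[keep].reset_index(drop=True)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full synthetic study and write per-stage outputs.

    Stages run in dependency order; a failure aborts with the stage name in
    the exception. Returns the summary dict that is also written as
    ``summary.json``. All randomness derives from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config": config.to_dict()}
    log_lines = [f"proxistress {__version__}", f"config: {json.dumps(config.to_dict(), sort_keys=True)}"]

    def stage(name):
        log_lines.append(f"stage: {name}")

    try:
        stage("simulate")
        sim = config.sim
        nonstress, ns_design, truth = simulate_proximity_experiment(sim)
        stress, st_design, _ = simulate_stress_experiment(sim)
        truth.to_tsv(outdir / "ground_truth.tsv")
        ns_design.to_tsv(outdir / "design_nonstress.tsv")
        st_design.to_tsv(outdir / "design_stress.tsv")

        stage("preprocess")
        ns_norm = median_normalize(nonstress)
        st_norm = median_normalize(stress)
        ns_filt, ns_excl = filter_valid_values(
            ns_norm, ns_design, min_valid=config.min_valid, scope=config.valid_scope
        )
        st_filt, st_excl = filter_valid_values(
            st_norm, st_design, min_valid=config.min_valid, scope=config.valid_scope
        )
        ns_imp = impute_downshift(
            ns_filt,
            width=config.impute_width,
            downshift=config.impute_downshift,
            per_sample=config.impute_per_sample,
            seed=config.seed + 1,
        )
        st_imp = impute_downshift(
            st_filt,
            width=config.impute_width,
            downshift=config.impute_downshift,
            per_sample=config.impute_per_sample,
            seed=config.seed + 2,
        )

        stage("enrich")
        enr = ratiometric_enrichment(
            ns_imp, ns_design, alpha=config.alpha, exclusions=ns_excl
        )
        enr.table.to_csv(outdir / "enrichment.tsv", sep="\t")
        scatter_table(enr).to_csv(outdir / "enrichment_scatter.tsv", sep="\t", index=False)

        stage("stress-shift")
        combined = combine_experiments(ns_imp, st_imp, ns_design, st_design)
        scores, evr = pca_scores(combined.matrix.values, n_components=2)
        scores.assign(explained_1=evr[0], explained_2=evr[1]).to_csv(
            outdir / "pca_scores.tsv", sep="\t"
        )
        gate = gate_muscle_expressed(
            combined, fold_threshold_log2=config.fold_threshold_log2, mode=config.gate_mode
        )
        volcano = stress_volcano(combined, gate, alpha=config.alpha)
        gate.to_csv(outdir / "gate.tsv", sep="\t")
        volcano.to_csv(outdir / "stress_volcano.tsv", sep="\t")
        _write_json(combined.overlap, outdir / "overlap.json")

        stage("integrate")
        omics = simulate_paired_omics(sim)
        pairs = pair_features(omics.transcript_de, omics.protein_de)
        quad, quad_summary = assign_quadrants(
            pairs, filter_mode=config.omics_filter_mode, alpha=config.alpha
        )
        quad.to_csv(outdir / "quadrants.tsv", sep="\t")
        _write_json(quad_summary, outdir / "quadrant_summary.json")

        stage("ora")
        universe = list(pairs.index)
        up_ids = omics.truth.index[omics.truth["quadrant"] == "both_up"]
        sets = simulate_gene_sets(
            universe,
            n_sets=10,
            planted_members=up_ids,
            seed=config.seed + 3,
        )
        write_gmt(sets, outdir / "gene_sets.gmt")
        ora_table = quadrant_ora(
            quad, "both_up", sets, q_cutoff=config.ora_q_cutoff
        )
        ora_table.to_csv(outdir / "ora_both_up.tsv", sep="\t", index=False)

        stage("gsea")
        ranked = enr.table.loc[enr.table["exclusion_reason"].isna()]
        rnk = pd.DataFrame(
            {"id": ranked.index, "score": ranked["log2fc_i_vs_iii"]}
        ).reset_index(drop=True)
        write_rnk(rnk, outdir / "enrichment.rnk")
        prox_sets = simulate_gene_sets(
            list(rnk["id"]),
            n_sets=6,
            planted_members=truth.members("PROXIMITY_TRUE"),
            seed=config.seed + 4,
        )
        gsea_table = run_coip_gsea(
            rnk.rename(columns={"score": "log2fc"}),
            prox_sets,
            nes_cutoff=config.nes_cutoff,
            n_perm=config.gsea_n_perm,
            seed=config.seed + 5,
            p_weight=config.gsea_p_weight,
        )
        gsea_table.drop(columns=["leading_edge"]).to_csv(
            outdir / "gsea.tsv", sep="\t", index=False
        )
    except Exception as exc:  # annotate with the failing stage
        failed = log_lines[-1].removeprefix("stage: ")
        (outdir / "run.log").write_text("\n".join(log_lines + [f"FAILED: {exc}"]) + "\n")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    summary.update(
        {
            "n_tested": enr.summary["n_tested"],
            "n_enriched_vs_neg": enr.summary["n_vs_neg"],
            "n_enriched_vs_muscle": enr.summary["n_vs_muscle"],
            "n_enriched_both": enr.summary["n_both"],
            "n_excluded_nonstress": int(len(ns_excl)),
            "overlap": combined.overlap,
            "n_gated": int(gate["passes_gate"].sum()),
            "n_stress_significant": int(volcano["significant"].sum()),
            "quadrants": quad_summary,
            "pca_explained_variance": [float(v) for v in evr],
            "n_gsea_sets_reported": int(len(gsea_table)),
        }
    )
    _write_json(summary, outdir / "summary.json")
    log_lines.append("done")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
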