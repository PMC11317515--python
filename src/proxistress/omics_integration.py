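"""Transcript/protein concordance: pairing, quadrant calls, per-quadrant ORA.

Paired differential tables (one per assay: feature id, log2 fold change,
p-value) are joined on feature id. Features passing the chosen filter — the
transcript OR the protein significant at alpha, regardless of the other
assay — are placed into one of four quadrants by the signs of the two fold
changes: concordant up, concordant down, or one of the two discordant
classes. Quadrant proportions are reported as percentages of the assigned
features, and each quadrant's members can be tested for gene-set
over-representation against the paired-feature universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats_core
from .genesets import GeneSetCollection

__all__ = ["pair_features", "assign_quadrants", "quadrant_ora", "QUADRANTS"]

QUADRANTS = ("both_up", "both_down", "tx_up_prot_down", "tx_down_prot_up")


def _check_de_table(table: pd.DataFrame, label: str) -> pd.DataFrame:
    required = {"id", "log2fc", "pvalue"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{label} table missing columns: {sorted(missing)}")
    out = table[["id", "log2fc", "pvalue"]].copy()
    out["id"] = out["id"].astype(str)
    if out["id"].duplicated().any():
        dupes = out["id"][out["id"].duplicated()].unique()
        raise ValueError(f"{label} table has duplicate ids: {list(dupes[:5])}")
    return out


def pair_features(
    transcript_table: pd.DataFrame,
    protein_table: pd.DataFrame,
    id_map: pd.DataFrame | dict | None = None,
) -> pd.DataFrame:
    """Inner-join transcript and protein differential tables on feature id.

    ``id_map`` optionally translates protein ids to transcript ids (dict or
    two-column DataFrame protein_id -> transcript_id); the identity map is
    the default. Many-to-many maps are rejected. Unmatched counts are stored
    in ``result.attrs["unmatched"]``.
    """
    tx = _check_de_table(transcript_table, "transcript")
    prot = _check_de_table(protein_table, "protein")
    if id_map is not None:
        if isinstance(id_map, dict):
            mapping = pd.Series({str(k): str(v) for k, v in id_map.items()})
        else:
            mapping = pd.Series(
                id_map.iloc[:, 1].astype(str).to_numpy(),
                index=id_map.iloc[:, 0].astype(str),
            )
        if mapping.index.duplicated().any() or mapping.duplicated().any():
            bad = list(mapping.index[mapping.index.duplicated()])[:5]
            raise ValueError(f"ambiguous many-to-many id mapping (e.g. {bad})")
        prot = prot.copy()
        prot["id"] = prot["id"].map(mapping)
        prot = prot[prot["id"].notna()]
    pairs = tx.merge(
        prot, on="id", how="inner", suffixes=("_transcript", "_protein")
    ).rename(
        columns={
            "log2fc_transcript": "transcript_log2fc",
            "pvalue_transcript": "transcript_p",
            "log2fc_protein": "protein_log2fc",
            "pvalue_protein": "protein_p",
        }
    )
    pairs = pairs.set_index("id")
    pairs.attrs["unmatched"] = {
        "transcripts_only": int(len(tx) - len(pairs)),
        "proteins_only": int(len(prot) - len(pairs)),
        "n_pairs": int(len(pairs)),
    }
    return pairs


def assign_quadrants(
    pairs: pd.DataFrame,
    filter_mode: str = "transcript_significant",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Filter paired features and classify them into sign quadrants.

    A feature is included when the filtering assay's p-value is <= alpha,
    regardless of the other assay's significance. Quadrants come from the
    signs of the two log2 fold changes; features with an exactly zero fold
    change in either assay stay "unassigned" and are excluded from the
    proportions, which are percentages of the assigned features and sum to
    100.
    """
    if filter_mode not in ("transcript_significant", "protein_significant"):
        raise ValueError(f"unknown filter_mode: {filter_mode!r}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    out = pairs.copy()
    p_col = "transcript_p" if filter_mode == "transcript_significant" else "protein_p"
    included = out[p_col] <= alpha
    out["included_by"] = np.where(included, filter_mode, "neither")

    tx = out["transcript_log2fc"]
    prot = out["protein_log2fc"]
    quadrant = np.select(
        [
            included & (tx > 0) & (prot > 0),
            included & (tx < 0) & (prot < 0),
            included & (tx > 0) & (prot < 0),
            included & (tx < 0) & (prot > 0),
        ],
        QUADRANTS,
        default="unassigned",
    )
    out["quadrant"] = quadrant
    assigned = out["quadrant"] != "unassigned"
    n_assigned = int(assigned.sum())
    proportions = {
        q: (100.0 * float((out["quadrant"] == q).sum()) / n_assigned)
        if n_assigned
        else np.nan
        for q in QUADRANTS
    }
    summary = {
        "filter_mode": filter_mode,
        "alpha": alpha,
        "n_pairs": int(len(out)),
        "n_filtered": int(included.sum()),
        "n_assigned": n_assigned,
        "proportions_pct": proportions,
    }
    return out, summary


def quadrant_ora(
    pairs: pd.DataFrame,
    quadrant: str,
    sets: GeneSetCollection,
    universe_mode: str = "all_pairs",
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Gene-set over-representation for the members of one quadrant.

    ``universe_mode`` picks the background: every paired feature
    ("all_pairs") or only those passing the significance filter
    ("filtered_pairs"). Rows are reported when the hypergeometric p is
    <= 0.05 and the BH q is <= ``q_cutoff`` (0.01 is conventional for
    transcript-filtered runs, 0.05 for protein-filtered runs).
    """
    if "quadrant" not in pairs.columns:
        raise ValueError("run assign_quadrants first")
    if universe_mode not in ("all_pairs", "filtered_pairs"):
        raise ValueError(f"unknown universe_mode: {universe_mode!r}")
    selection = list(pairs.index[pairs["quadrant"] == quadrant])
    if not selection:
        empty = pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p_hyper", "enrichment_ratio", "q_bh"]
        )
        empty.attrs["warning"] = f"quadrant {quadrant!r} is empty"
        return empty
    if universe_mode == "all_pairs":
        universe = list(pairs.index)
    else:
        universe = list(pairs.index[pairs["quadrant"] != "unassigned"])
    table = stats_core.ora(selection, universe, sets)
    keep = (table["p_hyper"] <= 0.05) & (table["q_bh"] <= q_cutoff)
    filtered = table[keep].sort_values("q_bh", kind="stable").reset_index(drop=True)
    filtered.attrs["skipped_sets"] = table.attrs.get("skipped_sets", [])
    filtered.attrs["n_tested_sets"] = int(len(table))
    return filtered
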