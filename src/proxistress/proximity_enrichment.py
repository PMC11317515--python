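"""Ratiometric enrichment of bait-proximal proteins against two controls.

Each protein is compared in bait proximity (i) versus the no-ligase negative
control (iii) and versus the free-ligase cytosolic reference (ii). A protein
counts as enriched in a comparison when its BH-adjusted two-sided t-test
p-value is at or below alpha AND its mean log2 difference is positive
("enriched in proximity" is directional); proteins enriched in both
comparisons are the ratiometric hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, Role, SampleDesign
from .stats_core import ZeroVarianceError, bh_adjust, two_sample_ttest

__all__ = ["EnrichmentResult", "ratiometric_enrichment", "scatter_table"]


@dataclass
class EnrichmentResult:
    """Per-protein enrichment table plus summary counts.

    ``table`` columns: log2fc_i_vs_iii, p_i_vs_iii, q_i_vs_iii,
    log2fc_i_vs_ii, p_i_vs_ii, q_i_vs_ii, enriched_vs_neg,
    enriched_vs_muscle, enriched_both, exclusion_reason.
    """

    table: pd.DataFrame
    summary: dict


def _group_values(
    matrix: IntensityMatrix, design: SampleDesign, role: Role
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = [s for s in design.samples_for(role) if s in matrix.sample_names]
    observed = matrix.observed_mask()[cols]
    return matrix.values[cols], observed


def pick_test_values(
    values: pd.Series, observed: pd.Series, min_obs: int
) -> np.ndarray:
    """Values entering a group's t-test: observed if enough, else imputed too.

    Imputation exists to keep low-abundance proteins testable; where real
    observations suffice (>= min_obs) they are used alone so that imputation
    noise cannot distort a well-observed comparison.
    """
    obs = values[observed].dropna()
    if obs.size >= min_obs:
        return obs.to_numpy()
    return values.dropna().to_numpy()


def ratiometric_enrichment(
    matrix: IntensityMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    equal_var: bool = True,
    min_per_group: int = 2,
    exclusions: pd.Series | None = None,
) -> EnrichmentResult:
    """Two-control ratiometric test of every protein.

    The matrix should be preprocessed (normalized and either imputed or
    valid-value filtered). Proteins with fewer than ``min_per_group``
    available values in any of the three groups, or with a degenerate
    zero-variance comparison, are excluded with a reason and carry no flags.
    ``exclusions`` lets the caller pass through upstream filtering reasons so
    excluded proteins still appear in the output table.

    BH adjustment runs separately within each comparison over the tested
    proteins, so each comparison has its own q-values out of the same
    denominator.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    design.require_roles(
        [Role.FUSION_PROXIMITY, Role.FREE_LIGASE, Role.NEG_CONTROL], min_per_group
    )
    g_i, o_i = _group_values(matrix, design, Role.FUSION_PROXIMITY)
    g_ii, o_ii = _group_values(matrix, design, Role.FREE_LIGASE)
    g_iii, o_iii = _group_values(matrix, design, Role.NEG_CONTROL)

    index = matrix.protein_ids
    cols = {
        "log2fc_i_vs_iii": np.nan,
        "p_i_vs_iii": np.nan,
        "q_i_vs_iii": np.nan,
        "log2fc_i_vs_ii": np.nan,
        "p_i_vs_ii": np.nan,
        "q_i_vs_ii": np.nan,
    }
    table = pd.DataFrame(cols, index=index)
    table["exclusion_reason"] = pd.Series(pd.NA, index=index, dtype=object)

    for pid in index:
        a = pick_test_values(g_i.loc[pid], o_i.loc[pid], min_per_group)
        b = pick_test_values(g_iii.loc[pid], o_iii.loc[pid], min_per_group)
        c = pick_test_values(g_ii.loc[pid], o_ii.loc[pid], min_per_group)
        if min(a.size, b.size, c.size) < min_per_group:
            table.loc[pid, "exclusion_reason"] = "insufficient_valid_values"
            continue
        try:
            res_neg = two_sample_ttest(a, b, equal_var=equal_var)
            res_mus = two_sample_ttest(a, c, equal_var=equal_var)
        except ZeroVarianceError:
            table.loc[pid, "exclusion_reason"] = "zero_variance"
            continue
        table.loc[pid, "log2fc_i_vs_iii"] = res_neg.estimate
        table.loc[pid, "p_i_vs_iii"] = res_neg.p
        table.loc[pid, "log2fc_i_vs_ii"] = res_mus.estimate
        table.loc[pid, "p_i_vs_ii"] = res_mus.p

    tested = table["exclusion_reason"].isna()
    if tested.sum() >= 2:
        table.loc[tested, "q_i_vs_iii"] = bh_adjust(
            table.loc[tested, "p_i_vs_iii"].to_numpy()
        )
        table.loc[tested, "q_i_vs_ii"] = bh_adjust(
            table.loc[tested, "p_i_vs_ii"].to_numpy()
        )
    else:
        # degenerate: too few tests for a meaningful FDR; pass p through
        table.loc[tested, "q_i_vs_iii"] = table.loc[tested, "p_i_vs_iii"]
        table.loc[tested, "q_i_vs_ii"] = table.loc[tested, "p_i_vs_ii"]

    table["enriched_vs_neg"] = (
        tested
        & (table["q_i_vs_iii"] <= alpha)
        & (table["log2fc_i_vs_iii"] > 0)
    )
    table["enriched_vs_muscle"] = (
        tested & (table["q_i_vs_ii"] <= alpha) & (table["log2fc_i_vs_ii"] > 0)
    )
    table["enriched_both"] = table["enriched_vs_neg"] & table["enriched_vs_muscle"]

    if exclusions is not None:
        for pid, reason in exclusions.items():
            if pid not in table.index:
                row = {c: np.nan for c in cols}
                row["exclusion_reason"] = reason
                row["enriched_vs_neg"] = False
                row["enriched_vs_muscle"] = False
                row["enriched_both"] = False
                table.loc[pid] = row

    summary = {
        "n_total": int(len(table)),
        "n_tested": int(tested.sum()),
        "n_vs_neg": int(table["enriched_vs_neg"].sum()),
        "n_vs_muscle": int(table["enriched_vs_muscle"].sum()),
        "n_both": int(table["enriched_both"].sum()),
        "alpha": alpha,
    }
    return EnrichmentResult(table=table, summary=summary)


def scatter_table(
    result: EnrichmentResult,
    annotations: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Export rows for the two-axis enrichment scatter.

    x = log2fc of proximity vs free ligase (ii), y = log2fc of proximity vs
    negative control (iii); one row per tested protein with its enrichment
    category and optional external annotation labels.
    """
    table = result.table
    tested = table["exclusion_reason"].isna()
    out = pd.DataFrame(
        {
            "protein_id": table.index[tested],
            "x_log2fc_i_vs_ii": table.loc[tested, "log2fc_i_vs_ii"].to_numpy(),
            "y_log2fc_i_vs_iii": table.loc[tested, "log2fc_i_vs_iii"].to_numpy(),
        }
    )
    category = np.where(
        table.loc[tested, "enriched_both"],
        "enriched_both",
        np.where(
            table.loc[tested, "enriched_vs_neg"],
            "enriched_vs_neg",
            np.where(
                table.loc[tested, "enriched_vs_muscle"],
                "enriched_vs_muscle",
                "not_enriched",
            ),
        ),
    )
    out["category"] = category
    if annotations is not None:
        ann = pd.Series(annotations)
        out["annotation"] = ann.reindex(out["protein_id"]).to_numpy()
    return out.reset_index(drop=True)
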