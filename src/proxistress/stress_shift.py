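"""Combined-experiment stress-shift analysis.

Two proximity pull-down experiments — one at rest (roles i, ii, iii) and one
under induced mechanical stress (roles iv, v) — are intersected on their
detected proteins. A fold-change gate on the non-stress arm keeps proteins
that are at least 2-fold enriched in bait proximity (i) or in the
tissue-cytosol reference (ii) over the negative control (iii): these are the
muscle-expressed candidates whose movement toward or away from the bait under
stress is then scored by a t-test of (iv) versus (v) with BH correction over
the gated set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import Batch, IntensityMatrix, Role, SampleDesign
from .proximity_enrichment import pick_test_values
from .stats_core import ZeroVarianceError, bh_adjust, two_sample_ttest

__all__ = [
    "CombinedExperiment",
    "combine_experiments",
    "gate_muscle_expressed",
    "stress_volcano",
]


@dataclass
class CombinedExperiment:
    """Shared-protein matrix across the two experiments, with batch labels."""

    matrix: IntensityMatrix
    design: SampleDesign
    overlap: dict  # n_nonstress, n_stress, n_shared, overlap_pct


def combine_experiments(
    nonstress: IntensityMatrix,
    stress: IntensityMatrix,
    nonstress_design: SampleDesign,
    stress_design: SampleDesign,
) -> CombinedExperiment:
    """Intersect two experiments on their detected proteins.

    Detection means presence in the matrix as handed in (i.e. after whatever
    valid-value filtering each experiment received). The overlap percentage
    is 100 * n_shared / n_stress — the share of stress-experiment detections
    already seen in the non-stress experiment.
    """
    shared = nonstress.protein_ids.intersection(stress.protein_ids)
    n_nonstress = int(nonstress.n_proteins)
    n_stress = int(stress.n_proteins)
    if len(shared) == 0:
        raise ValueError("empty intersection between experiments")
    a = nonstress.subset_proteins(shared)
    b = stress.subset_proteins(shared)
    dup = a.sample_names.intersection(b.sample_names)
    if len(dup):
        raise ValueError(f"sample name collision between experiments: {list(dup[:5])}")
    values = pd.concat([a.values, b.values], axis=1)
    imputed = None
    if a.imputed is not None and b.imputed is not None:
        imputed = pd.concat([a.imputed, b.imputed], axis=1)
    matrix = IntensityMatrix(values=values, gene_names=a.gene_names, imputed=imputed)
    design = nonstress_design.concat(stress_design)
    design.validate_against(matrix)
    overlap = {
        "n_nonstress": n_nonstress,
        "n_stress": n_stress,
        "n_shared": int(len(shared)),
        "overlap_pct": 100.0 * len(shared) / n_stress,
    }
    return CombinedExperiment(matrix=matrix, design=design, overlap=overlap)


def gate_muscle_expressed(
    combined: CombinedExperiment,
    fold_threshold_log2: float = 1.0,
    mode: str = "either",
) -> pd.DataFrame:
    """Fold-change gate for muscle-expressed proteins.

    Uses group means only (no p-value), per the "at least 2-fold positively
    enriched" rule: passes_gate is true when the mean log2 difference of (i)
    over (iii) reaches the threshold OR (mode="either") / AND (mode="both")
    the mean log2 difference of (ii) over (iii) does. Means are taken over
    the non-stress batch samples of the combined matrix.

    Returns a DataFrame with gate_log2fc_i_vs_iii, gate_log2fc_ii_vs_iii and
    passes_gate per protein.
    """
    if mode not in ("either", "both"):
        raise ValueError(f"mode must be 'either' or 'both', got {mode!r}")
    design = combined.design
    matrix = combined.matrix
    cols_i = design.samples_for(Role.FUSION_PROXIMITY, Batch.NONSTRESS)
    cols_ii = design.samples_for(Role.FREE_LIGASE, Batch.NONSTRESS)
    cols_iii = design.samples_for(Role.NEG_CONTROL, Batch.NONSTRESS)
    for cols, label in ((cols_i, "i"), (cols_ii, "ii"), (cols_iii, "iii")):
        if not cols:
            raise ValueError(f"gate role ({label}) missing from the non-stress arm")
    mean_i = matrix.values[cols_i].mean(axis=1, skipna=True)
    mean_ii = matrix.values[cols_ii].mean(axis=1, skipna=True)
    mean_iii = matrix.values[cols_iii].mean(axis=1, skipna=True)
    fc_i = mean_i - mean_iii
    fc_ii = mean_ii - mean_iii
    pass_i = fc_i >= fold_threshold_log2
    pass_ii = fc_ii >= fold_threshold_log2
    passes = (pass_i | pass_ii) if mode == "either" else (pass_i & pass_ii)
    passes &= fc_i.notna() & fc_ii.notna()
    return pd.DataFrame(
        {
            "gate_log2fc_i_vs_iii": fc_i,
            "gate_log2fc_ii_vs_iii": fc_ii,
            "passes_gate": passes.fillna(False).astype(bool),
        }
    )


def stress_volcano(
    combined: CombinedExperiment,
    gated: pd.DataFrame | pd.Index,
    alpha: float = 0.05,
    equal_var: bool = True,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Score movement toward/away from the bait under stress.

    For every gated protein: log2_ratio = mean(iv) - mean(v), a two-sided
    t-test p, and BH q computed over the gated proteins only. significant
    means q <= alpha; direction is "toward" the bait for positive ratios and
    "away" for negative ones.

    ``gated`` is either the gate table from :func:`gate_muscle_expressed`
    (its passes_gate column selects proteins) or an explicit protein index.
    """
    if isinstance(gated, pd.DataFrame):
        gate_table = gated
        gated_ids = gated.index[gated["passes_gate"]]
    else:
        gate_table = None
        gated_ids = pd.Index(gated)
    if len(gated_ids) == 0:
        raise ValueError("gated set is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    design = combined.design
    matrix = combined.matrix
    cols_iv = design.samples_for(Role.STRESS_PLUS_ATR)
    cols_v = design.samples_for(Role.STRESS_MINUS_ATR)
    if len(cols_iv) < min_per_group or len(cols_v) < min_per_group:
        raise ValueError("roles iv and v each need >= 2 samples")

    observed = matrix.observed_mask()
    rows = []
    for pid in gated_ids:
        a = pick_test_values(
            matrix.values.loc[pid, cols_iv], observed.loc[pid, cols_iv], min_per_group
        )
        b = pick_test_values(
            matrix.values.loc[pid, cols_v], observed.loc[pid, cols_v], min_per_group
        )
        row = {
            "protein_id": pid,
            "log2_ratio_iv_vs_v": np.nan,
            "p_iv_vs_v": np.nan,
            "exclusion_reason": pd.NA,
        }
        if min(a.size, b.size) < min_per_group:
            row["exclusion_reason"] = "insufficient_valid_values"
        else:
            try:
                res = two_sample_ttest(a, b, equal_var=equal_var)
            except ZeroVarianceError:
                row["exclusion_reason"] = "zero_variance"
            else:
                row["log2_ratio_iv_vs_v"] = res.estimate
                row["p_iv_vs_v"] = res.p
        rows.append(row)
    table = pd.DataFrame(rows).set_index("protein_id")
    tested = table["exclusion_reason"].isna()
    table["q_iv_vs_v"] = np.nan
    if tested.sum() >= 2:
        table.loc[tested, "q_iv_vs_v"] = bh_adjust(
            table.loc[tested, "p_iv_vs_v"].to_numpy()
        )
    else:
        table.loc[tested, "q_iv_vs_v"] = table.loc[tested, "p_iv_vs_v"]
    table["significant"] = tested & (table["q_iv_vs_v"] <= alpha)
    table["direction"] = np.where(
        table["significant"] & (table["log2_ratio_iv_vs_v"] > 0),
        "toward",
        np.where(
            table["significant"] & (table["log2_ratio_iv_vs_v"] < 0), "away", "none"
        ),
    )
    if gate_table is not None:
        table = table.join(
            gate_table.loc[gated_ids, ["gate_log2fc_i_vs_iii", "gate_log2fc_ii_vs_iii"]]
        )
        table["passes_gate"] = True
    return table
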