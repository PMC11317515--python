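"""Reading protein-group tables and Perseus-style LFQ preprocessing.

The expected input is a MaxQuant proteinGroups.txt-style TSV with one row per
protein group, "LFQ intensity <sample>" columns, and "+"-flagged decoy rows
(Reverse, Potential contaminant, Only identified by site). Preprocessing
follows the standard label-free workflow: drop decoys, log2-transform, treat
zero/empty as missing, median-center samples, filter on valid values per
design group, and impute remaining missing values from a downshifted normal
distribution (missing-not-at-random model for low-abundance dropout).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, SampleDesign

__all__ = [
    "read_protein_groups",
    "write_protein_groups",
    "median_normalize",
    "filter_valid_values",
    "impute_downshift",
]

DECOY_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")
DEFAULT_LFQ_PREFIX = "LFQ intensity "


def read_protein_groups(
    path,
    lfq_prefix: str = DEFAULT_LFQ_PREFIX,
    filter_decoys: bool = True,
) -> IntensityMatrix:
    """Read a proteinGroups-style TSV into a log2 :class:`IntensityMatrix`.

    Raw intensities of 0, empty cells, and "NaN" are treated as missing
    (MaxQuant writes 0 when a protein was not quantified in a sample).
    Sample names are the LFQ column names with ``lfq_prefix`` stripped.
    """
    raw = pd.read_csv(path, sep="\t", dtype={c: str for c in DECOY_COLUMNS})
    if "Protein IDs" not in raw.columns:
        raise ValueError(f"{path}: missing 'Protein IDs' column")
    lfq_cols = [c for c in raw.columns if c.startswith(lfq_prefix)]
    if not lfq_cols:
        raise ValueError(f"{path}: no columns with prefix {lfq_prefix!r}")
    if filter_decoys:
        keep = pd.Series(True, index=raw.index)
        for col in DECOY_COLUMNS:
            if col in raw.columns:
                keep &= raw[col].fillna("") != "+"
        raw = raw[keep]
    ids = raw["Protein IDs"].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()
        raise ValueError(f"{path}: duplicate protein ids: {list(dupes[:5])}")
    intensities = raw[lfq_cols].apply(pd.to_numeric, errors="coerce")
    intensities = intensities.where(intensities > 0)  # 0 and negatives -> NaN
    values = np.log2(intensities)
    values.index = pd.Index(ids, name="protein_id")
    values.columns = [c[len(lfq_prefix):] for c in lfq_cols]
    gene_names = None
    if "Gene names" in raw.columns:
        gene_names = raw["Gene names"].astype(str)
        gene_names.index = values.index
    return IntensityMatrix(values=values, gene_names=gene_names)


def write_protein_groups(
    matrix: IntensityMatrix,
    path,
    lfq_prefix: str = DEFAULT_LFQ_PREFIX,
) -> None:
    """Write an :class:`IntensityMatrix` back to proteinGroups-style TSV.

    Log2 values are exponentiated; missing cells are written as 0, matching
    the MaxQuant convention read by :func:`read_protein_groups`.
    """
    linear = np.exp2(matrix.values)
    linear = linear.fillna(0.0)
    out = pd.DataFrame(
        {
            "Protein IDs": matrix.protein_ids,
            "Gene names": (
                matrix.gene_names.to_numpy()
                if matrix.gene_names is not None
                else matrix.protein_ids
            ),
            "Reverse": "",
            "Potential contaminant": "",
            "Only identified by site": "",
        }
    )
    for col in matrix.sample_names:
        out[f"{lfq_prefix}{col}"] = linear[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Center each sample so its median observed log2 intensity is 0."""
    medians = matrix.values.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = list(medians.index[medians.isna()])
        raise ValueError(f"samples with no observed values: {empty[:5]}")
    out = matrix.copy()
    out.values = out.values - medians
    return out


def filter_valid_values(
    matrix: IntensityMatrix,
    design: SampleDesign,
    min_valid: int = 3,
    scope: str = "any_group",
    groups: list | None = None,
) -> tuple[IntensityMatrix, pd.Series]:
    """Keep proteins with enough observed values per design group.

    Parameters
    ----------
    min_valid
        Minimum observed (non-missing, non-imputed) values required.
    scope
        "any_group": keep the protein if any group reaches ``min_valid``;
        "each_group": require every group to reach it.
    groups
        Roles to consider (defaults to all roles in the design). Groups are
        formed by (role, batch).

    Returns the filtered matrix and a per-protein exclusion-reason Series for
    the dropped proteins ("no_valid_values" when nothing was observed at all,
    otherwise "insufficient_valid_values").
    """
    if scope not in ("any_group", "each_group"):
        raise ValueError(f"unknown scope: {scope!r}")
    design.validate_against(matrix)
    observed = matrix.observed_mask()
    group_cols: list[list[str]] = []
    table = design.table.loc[design.table.index.intersection(matrix.sample_names)]
    if groups is not None:
        wanted = {str(getattr(g, "value", g)) for g in groups}
        table = table[table["role"].isin(wanted)]
    for (_, _), sub in table.groupby(["role", "batch"], sort=True):
        cols = [s for s in sub.index if s in observed.columns]
        if not cols:
            raise ValueError("design group with no matrix samples")
        group_cols.append(cols)
    if not group_cols:
        raise ValueError("no design groups to filter on")
    for cols in group_cols:
        if min_valid > len(cols):
            raise ValueError(
                f"min_valid={min_valid} exceeds group size {len(cols)}"
            )
    counts = pd.DataFrame(
        {i: observed[cols].sum(axis=1) for i, cols in enumerate(group_cols)}
    )
    if scope == "any_group":
        keep = (counts >= min_valid).any(axis=1)
    else:
        keep = (counts >= min_valid).all(axis=1)
    dropped = matrix.protein_ids[~keep]
    total_obs = observed.sum(axis=1)
    reasons = pd.Series(
        np.where(total_obs.loc[dropped] == 0, "no_valid_values", "insufficient_valid_values"),
        index=dropped,
        name="exclusion_reason",
        dtype=object,
    )
    return matrix.subset_proteins(matrix.protein_ids[keep]), reasons


def impute_downshift(
    matrix: IntensityMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    per_sample: bool = True,
    seed: int | None = None,
) -> IntensityMatrix:
    """Replace missing values with draws from a downshifted normal.

    For each unit (one sample column if ``per_sample``, else the whole
    matrix) with observed mean ``m`` and SD ``s``, missing cells are drawn
    from Normal(m - downshift*s, (width*s)^2). These are the canonical
    Perseus defaults for modelling low-abundance dropout. Observed cells are
    never altered; imputed cells are recorded in the ``imputed`` mask.
    """
    out = matrix.copy()
    rng = np.random.default_rng(seed)
    values = out.values
    missing = values.isna()
    imputed = pd.DataFrame(False, index=values.index, columns=values.columns)
    if not missing.to_numpy().any():
        out.imputed = imputed
        return out

    def impute_unit(col_values: np.ndarray, miss: np.ndarray) -> np.ndarray:
        observed = col_values[~miss]
        if observed.size < 2:
            raise ValueError("imputation unit has < 2 observed values")
        m = observed.mean()
        s = observed.std(ddof=1)
        draws = rng.normal(m - downshift * s, width * s, size=int(miss.sum()))
        filled = col_values.copy()
        filled[miss] = draws
        return filled

    if per_sample:
        for col in values.columns:
            miss = missing[col].to_numpy()
            if miss.any():
                values[col] = impute_unit(values[col].to_numpy(), miss)
                imputed.loc[miss, col] = True
    else:
        flat = values.to_numpy().ravel()
        miss = missing.to_numpy().ravel()
        filled = impute_unit(flat, miss)
        values.loc[:, :] = filled.reshape(values.shape)
        imputed.loc[:, :] = missing
    out.values = values
    out.imputed = imputed
    return out
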