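"""Synthetic data with the statistical structure the analysis assumes.

Every downstream stage of the package is testable offline against data
generated here, with ground-truth labels for each planted signal class:

PROXIMITY_TRUE        elevated in bait proximity (i) over both the free-ligase
                      reference (ii) and the negative control (iii)
MUSCLE_CYTO           elevated in (i) and (ii) over (iii) — tissue-expressed
                      background labelled by both ligases
ENDOGENOUS_BACKGROUND equal mean across all roles (endogenously biotinylated
                      or bead-binding proteins)
STRESS_SHIFT_IN/OUT   muscle-level baseline plus a positive/negative shift of
                      the stress (iv) over non-stress (v) proximity signal
NULL                  no planted effect anywhere

The intensity model is log-normal LFQ behaviour: per-protein baseline
~ Normal(base_mean, base_sd) on the log2 scale, replicate noise
~ Normal(0, noise_sd), and missing-not-at-random dropout with
logit p(missing) = dropout_slope * (dropout_midpoint - intensity).
Stress-shift classes carry muscle-level enrichment in the non-stress
experiment so that planted stress candidates fall inside the 2-fold
muscle gate, as in the combined-experiment design they emulate.

Default sizes echo the scale of the study this pipeline targets: 1709
proteins, 4 replicates per condition, 34 proximity-true / 77 muscle /
6+6 stress-shift proteins (so 123 gate-true proteins carrying 12 stress
candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .matrix import Batch, IntensityMatrix, Role, SampleDesign
from .stats_core import two_sample_ttest

__all__ = [
    "ProteinClass",
    "QuadrantClass",
    "SimConfig",
    "GroundTruth",
    "PairedOmics",
    "simulate_proximity_experiment",
    "simulate_stress_experiment",
    "simulate_paired_omics",
    "simulate_gene_sets",
]


class ProteinClass(str, Enum):
    PROXIMITY_TRUE = "PROXIMITY_TRUE"
    MUSCLE_CYTO = "MUSCLE_CYTO"
    ENDOGENOUS_BACKGROUND = "ENDOGENOUS_BACKGROUND"
    STRESS_SHIFT_IN = "STRESS_SHIFT_IN"
    STRESS_SHIFT_OUT = "STRESS_SHIFT_OUT"
    NULL = "NULL"


class QuadrantClass(str, Enum):
    BOTH_UP = "both_up"
    BOTH_DOWN = "both_down"
    TX_UP_PROT_DOWN = "tx_up_prot_down"
    TX_DOWN_PROT_UP = "tx_down_prot_up"
    NULL = "null"


@dataclass
class SimConfig:
    """Generative parameters; all effects and scales are log2 units."""

    n_proteins: int = 1709
    n_replicates: int = 4
    # planted-class fractions (remainder is NULL)
    frac_proximity_true: float = 34 / 1709
    frac_muscle_background: float = 77 / 1709
    frac_endogenous_background: float = 0.10
    frac_stress_shift_in: float = 6 / 1709
    frac_stress_shift_out: float = 6 / 1709
    # planted log2 effects
    effect_proximity: float = 3.0
    effect_muscle: float = 2.0
    effect_stress: float = 2.0
    # intensity model
    base_mean: float = 26.0
    base_sd: float = 2.0
    noise_sd: float = 0.5
    # MNAR dropout: logit p(missing) = slope * (midpoint - intensity);
    # slope <= 0 disables dropout entirely
    dropout_midpoint: float = 22.0
    dropout_slope: float = 1.0
    # additive log2 offset of the stress experiment relative to non-stress
    batch_shift: float = 0.5
    # paired transcript/protein simulation
    frac_concordant_up: float = 0.05
    frac_concordant_down: float = 0.05
    frac_discordant_tx_up: float = 0.03
    frac_discordant_tx_down: float = 0.03
    effect_omics: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        fracs = [
            self.frac_proximity_true,
            self.frac_muscle_background,
            self.frac_endogenous_background,
            self.frac_stress_shift_in,
            self.frac_stress_shift_out,
        ]
        if any(f < 0 for f in fracs):
            raise ValueError("class fractions must be nonnegative")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError(f"class fractions sum to {sum(fracs):.3f} > 1")
        quad = [
            self.frac_concordant_up,
            self.frac_concordant_down,
            self.frac_discordant_tx_up,
            self.frac_discordant_tx_down,
        ]
        if any(f < 0 for f in quad):
            raise ValueError("quadrant fractions must be nonnegative")
        if sum(quad) > 1 + 1e-12:
            raise ValueError(f"quadrant fractions sum to {sum(quad):.3f} > 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("base_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-protein class labels and true log2 effects per comparison."""

    table: pd.DataFrame  # index protein_id; class + true_log2fc_* columns

    def members(self, cls: ProteinClass | str) -> pd.Index:
        label = getattr(cls, "value", cls)
        return self.table.index[self.table["class"] == label]

    def class_counts(self) -> pd.Series:
        return self.table["class"].value_counts()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def _protein_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i + 1:06d}" for i in range(n)], name="protein_id")


def _assign_classes(config: SimConfig) -> pd.Series:
    """Deterministic class assignment shared by both experiments.

    Counts are rounded from the fractions (so planted proportions are exact),
    then positions are shuffled with a stream derived only from the seed —
    the same config therefore yields the same class for each protein id in
    the proximity and the stress experiment.
    """
    n = config.n_proteins
    spec = [
        (ProteinClass.PROXIMITY_TRUE, config.frac_proximity_true),
        (ProteinClass.MUSCLE_CYTO, config.frac_muscle_background),
        (ProteinClass.ENDOGENOUS_BACKGROUND, config.frac_endogenous_background),
        (ProteinClass.STRESS_SHIFT_IN, config.frac_stress_shift_in),
        (ProteinClass.STRESS_SHIFT_OUT, config.frac_stress_shift_out),
    ]
    counts = [int(round(f * n)) for _, f in spec]
    if sum(counts) > n:
        raise ValueError("rounded class counts exceed n_proteins")
    labels = []
    for (cls, _), c in zip(spec, counts):
        labels.extend([cls.value] * c)
    labels.extend([ProteinClass.NULL.value] * (n - len(labels)))
    rng = np.random.default_rng([config.seed, 0])
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return pd.Series(labels, index=_protein_ids(n), name="class")


_TRUTH_COLUMNS = [
    "true_log2fc_i_vs_iii",
    "true_log2fc_i_vs_ii",
    "true_log2fc_ii_vs_iii",
    "true_log2fc_iv_vs_v",
]


def _true_effects(classes: pd.Series, config: SimConfig) -> pd.DataFrame:
    eff = pd.DataFrame(0.0, index=classes.index, columns=_TRUTH_COLUMNS)
    prox = classes == ProteinClass.PROXIMITY_TRUE.value
    muscle_like = classes.isin(
        [
            ProteinClass.MUSCLE_CYTO.value,
            ProteinClass.STRESS_SHIFT_IN.value,
            ProteinClass.STRESS_SHIFT_OUT.value,
        ]
    )
    eff.loc[prox, "true_log2fc_i_vs_iii"] = config.effect_proximity
    eff.loc[prox, "true_log2fc_i_vs_ii"] = config.effect_proximity
    eff.loc[muscle_like, "true_log2fc_i_vs_iii"] = config.effect_muscle
    eff.loc[muscle_like, "true_log2fc_ii_vs_iii"] = config.effect_muscle
    eff.loc[
        classes == ProteinClass.STRESS_SHIFT_IN.value, "true_log2fc_iv_vs_v"
    ] = config.effect_stress
    eff.loc[
        classes == ProteinClass.STRESS_SHIFT_OUT.value, "true_log2fc_iv_vs_v"
    ] = -config.effect_stress
    return eff


def _role_offsets(classes: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Mean log2 offset from the per-protein baseline for each role."""
    offs = pd.DataFrame(
        0.0, index=classes.index, columns=[r.value for r in Role]
    )
    prox = classes == ProteinClass.PROXIMITY_TRUE.value
    offs.loc[prox, Role.FUSION_PROXIMITY.value] = config.effect_proximity
    muscle_like = classes.isin(
        [
            ProteinClass.MUSCLE_CYTO.value,
            ProteinClass.STRESS_SHIFT_IN.value,
            ProteinClass.STRESS_SHIFT_OUT.value,
        ]
    )
    offs.loc[muscle_like, Role.FUSION_PROXIMITY.value] = config.effect_muscle
    offs.loc[muscle_like, Role.FREE_LIGASE.value] = config.effect_muscle
    # stress arm: both iv and v are bait-proximity samples, so every class
    # keeps its proximity-level baseline there; the stress effect moves iv
    shift_in = classes == ProteinClass.STRESS_SHIFT_IN.value
    shift_out = classes == ProteinClass.STRESS_SHIFT_OUT.value
    base_prox = offs[Role.FUSION_PROXIMITY.value]
    offs[Role.STRESS_PLUS_ATR.value] = base_prox
    offs[Role.STRESS_MINUS_ATR.value] = base_prox
    offs.loc[shift_in, Role.STRESS_PLUS_ATR.value] += config.effect_stress
    offs.loc[shift_out, Role.STRESS_PLUS_ATR.value] -= config.effect_stress
    return offs


def _apply_dropout(
    values: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    if config.dropout_slope <= 0:
        return values
    logit = config.dropout_slope * (config.dropout_midpoint - values.to_numpy())
    p_miss = 1.0 / (1.0 + np.exp(-logit))
    drop = rng.random(values.shape) < p_miss
    return values.mask(pd.DataFrame(drop, index=values.index, columns=values.columns))


def _simulate_experiment(
    config: SimConfig,
    roles: Sequence[Role],
    batch: Batch,
    stream_offset: int,
    extra_shift: float = 0.0,
) -> tuple[IntensityMatrix, SampleDesign, GroundTruth]:
    config.validate()
    classes = _assign_classes(config)
    offsets = _role_offsets(classes, config)
    # the per-protein baseline is a property of the protein, shared across
    # experiments; noise and dropout streams are experiment-specific
    rng_baseline = np.random.default_rng([config.seed, 1])
    rng_noise = np.random.default_rng([config.seed, stream_offset + 1])
    rng_dropout = np.random.default_rng([config.seed, stream_offset + 2])
    baseline = rng_baseline.normal(
        config.base_mean, config.base_sd, size=config.n_proteins
    )
    columns: dict[str, np.ndarray] = {}
    records: dict[str, tuple[Role, Batch, int]] = {}
    for role in roles:
        role_mean = baseline + offsets[role.value].to_numpy() + extra_shift
        for rep in range(1, config.n_replicates + 1):
            name = f"{role.value}_r{rep}"
            noise = rng_noise.normal(0.0, config.noise_sd, size=config.n_proteins)
            columns[name] = role_mean + noise
            records[name] = (role, batch, rep)
    values = pd.DataFrame(columns, index=classes.index)
    values = _apply_dropout(values, config, rng_dropout)
    matrix = IntensityMatrix(values=values)
    design = SampleDesign.from_records(records)
    truth = GroundTruth(
        pd.concat([classes, _true_effects(classes, config)], axis=1)
    )
    return matrix, design, truth


def simulate_proximity_experiment(
    config: SimConfig,
    roles: Iterable[Role | str] | None = None,
) -> tuple[IntensityMatrix, SampleDesign, GroundTruth]:
    """Non-stress proximity pull-down: roles (i), (ii), (iii)."""
    wanted = (
        [Role.from_label(r) for r in roles]
        if roles is not None
        else [Role.FUSION_PROXIMITY, Role.FREE_LIGASE, Role.NEG_CONTROL]
    )
    required = {Role.FUSION_PROXIMITY, Role.FREE_LIGASE, Role.NEG_CONTROL}
    if not required.issubset(wanted):
        missing = sorted(r.value for r in required - set(wanted))
        raise ValueError(f"proximity experiment requires roles {missing}")
    return _simulate_experiment(config, wanted, Batch.NONSTRESS, stream_offset=1)


def simulate_stress_experiment(
    config: SimConfig,
    roles: Iterable[Role | str] | None = None,
) -> tuple[IntensityMatrix, SampleDesign, GroundTruth]:
    """Stress-arm proximity pull-down: roles (iv), (v), with a batch offset.

    Protein ids and class labels are shared with
    :func:`simulate_proximity_experiment` for the same config, so the
    intersection of the two experiments is meaningful.
    """
    wanted = (
        [Role.from_label(r) for r in roles]
        if roles is not None
        else [Role.STRESS_PLUS_ATR, Role.STRESS_MINUS_ATR]
    )
    required = {Role.STRESS_PLUS_ATR, Role.STRESS_MINUS_ATR}
    if not required.issubset(wanted):
        missing = sorted(r.value for r in required - set(wanted))
        raise ValueError(f"stress experiment requires roles {missing}")
    return _simulate_experiment(
        config, wanted, Batch.STRESS, stream_offset=11, extra_shift=config.batch_shift
    )


@dataclass
class PairedOmics:
    """Replicate-level and differential tables for paired transcript/protein data."""

    transcript_values: pd.DataFrame  # features x (ctrl_r*, trt_r*) log2
    protein_values: pd.DataFrame
    transcript_de: pd.DataFrame  # columns id, log2fc, pvalue
    protein_de: pd.DataFrame
    truth: pd.DataFrame  # index feature id; quadrant + true effects


def _de_table(values: pd.DataFrame) -> pd.DataFrame:
    ctrl_cols = [c for c in values.columns if c.startswith("ctrl_")]
    trt_cols = [c for c in values.columns if c.startswith("trt_")]
    rows = []
    for fid, row in values.iterrows():
        res = two_sample_ttest(row[trt_cols].to_numpy(), row[ctrl_cols].to_numpy())
        rows.append({"id": fid, "log2fc": res.estimate, "pvalue": res.p})
    return pd.DataFrame(rows)


def simulate_paired_omics(config: SimConfig) -> PairedOmics:
    """Paired transcript/protein measurements with planted quadrant structure.

    Each feature carries a true (transcript, protein) log2 effect pair whose
    signs define its quadrant. Replicate tables (control vs treated,
    ``n_replicates`` each) are generated for both assays on the log2 scale;
    differential tables are then produced by the package's own two-sample
    t-test, which stands in for the external count-model DE stage that real
    transcript tables would come from.
    """
    config.validate()
    n = config.n_proteins
    ids = pd.Index([f"G{i + 1:06d}" for i in range(n)], name="feature_id")
    spec = [
        (QuadrantClass.BOTH_UP, config.frac_concordant_up, +1, +1),
        (QuadrantClass.BOTH_DOWN, config.frac_concordant_down, -1, -1),
        (QuadrantClass.TX_UP_PROT_DOWN, config.frac_discordant_tx_up, +1, -1),
        (QuadrantClass.TX_DOWN_PROT_UP, config.frac_discordant_tx_down, -1, +1),
    ]
    counts = [int(round(f * n)) for _, f, _, _ in spec]
    if sum(counts) > n:
        raise ValueError("quadrant fractions exceed 1 after rounding")
    labels, tx_sign, prot_sign = [], [], []
    for (cls, _, st, sp), c in zip(spec, counts):
        labels.extend([cls.value] * c)
        tx_sign.extend([st] * c)
        prot_sign.extend([sp] * c)
    pad = n - len(labels)
    labels.extend([QuadrantClass.NULL.value] * pad)
    tx_sign.extend([0] * pad)
    prot_sign.extend([0] * pad)
    rng = np.random.default_rng([config.seed, 21])
    perm = rng.permutation(n)
    truth = pd.DataFrame(
        {
            "quadrant": np.array(labels, dtype=object)[perm],
            "true_tx_log2fc": np.array(tx_sign, dtype=float)[perm]
            * config.effect_omics,
            "true_prot_log2fc": np.array(prot_sign, dtype=float)[perm]
            * config.effect_omics,
        },
        index=ids,
    )

    def build_values(effects: np.ndarray, stream: int) -> pd.DataFrame:
        rng_b = np.random.default_rng([config.seed, stream])
        rng_n = np.random.default_rng([config.seed, stream + 1])
        base = rng_b.normal(config.base_mean, config.base_sd, size=n)
        cols = {}
        for rep in range(1, config.n_replicates + 1):
            cols[f"ctrl_r{rep}"] = base + rng_n.normal(0, config.noise_sd, n)
        for rep in range(1, config.n_replicates + 1):
            cols[f"trt_r{rep}"] = base + effects + rng_n.normal(0, config.noise_sd, n)
        return pd.DataFrame(cols, index=ids)

    tx_values = build_values(truth["true_tx_log2fc"].to_numpy(), 22)
    prot_values = build_values(truth["true_prot_log2fc"].to_numpy(), 24)
    return PairedOmics(
        transcript_values=tx_values,
        protein_values=prot_values,
        transcript_de=_de_table(tx_values),
        protein_de=_de_table(prot_values),
        truth=truth,
    )


def simulate_gene_sets(
    universe: Iterable[str],
    n_sets: int = 20,
    planted_members: Iterable[str] | None = None,
    planted_fraction: float = 1.0,
    decoy_size: int = 20,
    seed: int | None = None,
    planted_name: str = "planted_set",
) -> GeneSetCollection:
    """One planted set enriched for a ground-truth class plus uniform decoys.

    ``planted_members`` are the ids of the class to enrich for (e.g. the
    PROXIMITY_TRUE proteins); ``planted_fraction`` of them (rounded) are
    included in the planted set. Decoy sets are uniform draws of
    ``decoy_size`` ids from the universe without replacement.
    """
    universe = list(dict.fromkeys(str(u) for u in universe))
    if not universe:
        raise ValueError("empty universe")
    if decoy_size > len(universe):
        raise ValueError("decoy_size exceeds universe size")
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    if planted_members is not None:
        members = [str(m) for m in planted_members if str(m) in set(universe)]
        n_take = int(round(planted_fraction * len(members)))
        take = list(rng.choice(members, size=n_take, replace=False)) if n_take else []
        coll.add(planted_name, sorted(take), "planted signal set")
    n_decoys = n_sets - (1 if planted_members is not None else 0)
    for i in range(max(n_decoys, 0)):
        decoy = rng.choice(universe, size=decoy_size, replace=False)
        coll.add(f"decoy_{i + 1:03d}", sorted(decoy), "uniform decoy set")
    return coll
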