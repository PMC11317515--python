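"""In-memory containers for label-free quantification (LFQ) data.

The central object is :class:`IntensityMatrix`, a proteins x samples table of
log2 LFQ intensities in which missing observations are encoded as NaN, plus an
optional boolean mask recording which cells were filled in by imputation.
:class:`SampleDesign` maps each sample column to its experimental role, batch,
and replicate index.

Sample roles follow the five-arm proximity-labeling design:

i    bait-fusion ligase (proteins biotinylated in bait proximity)
ii   free ligase expressed in the same tissue (spatial reference / cytosolic
     background)
iii  no-ligase negative control (endogenous biotinylation, bead binders)
iv   bait proximity under mechanical stress (light pulses + cofactor)
v    bait proximity without functional channel (no cofactor; non-stress arm of
     the stress experiment)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["Role", "Batch", "IntensityMatrix", "SampleDesign"]


class Role(str, Enum):
    """Sample role in the proximity-labeling design (legend labels i-v)."""

    FUSION_PROXIMITY = "i"
    FREE_LIGASE = "ii"
    NEG_CONTROL = "iii"
    STRESS_PLUS_ATR = "iv"
    STRESS_MINUS_ATR = "v"

    @classmethod
    def from_label(cls, label: "str | Role") -> "Role":
        if isinstance(label, Role):
            return label
        return cls(str(label))


class Batch(str, Enum):
    """Experiment batch: the two pull-down experiments that get combined."""

    NONSTRESS = "nonstress_expt"
    STRESS = "stress_expt"

    @classmethod
    def from_label(cls, label: "str | Batch") -> "Batch":
        if isinstance(label, Batch):
            return label
        return cls(str(label))


@dataclass
class IntensityMatrix:
    """Proteins x samples matrix of log2 intensities.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = protein ids, columns = sample
        names. Missing observations are NaN.
    gene_names
        Optional per-protein gene symbols, aligned with ``values.index``.
    imputed
        Optional boolean DataFrame (same shape) marking cells whose value was
        drawn by imputation rather than observed.
    """

    values: pd.DataFrame
    gene_names: pd.Series | None = None
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate protein ids: {list(dupes[:5])}")
        if self.gene_names is not None:
            self.gene_names = self.gene_names.reindex(self.values.index)
        if self.imputed is not None:
            if self.imputed.shape != self.values.shape:
                raise ValueError("imputed mask shape does not match values")
            self.imputed = self.imputed.astype(bool)

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_names(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where no value is available (neither observed nor imputed)."""
        return self.values.isna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> pd.DataFrame:
        """True where the value was actually measured (not missing, not imputed)."""
        obs = self.values.notna()
        if self.imputed is not None:
            obs &= ~self.imputed
        return obs

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            values=self.values.copy(),
            gene_names=None if self.gene_names is None else self.gene_names.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )

    def subset_proteins(self, ids: Iterable[str]) -> "IntensityMatrix":
        ids = pd.Index(ids)
        return IntensityMatrix(
            values=self.values.loc[ids],
            gene_names=None if self.gene_names is None else self.gene_names.loc[ids],
            imputed=None if self.imputed is None else self.imputed.loc[ids],
        )

    def subset_samples(self, names: Iterable[str]) -> "IntensityMatrix":
        names = list(names)
        return IntensityMatrix(
            values=self.values[names],
            gene_names=self.gene_names,
            imputed=None if self.imputed is None else self.imputed[names],
        )


@dataclass
class SampleDesign:
    """Maps sample names to (role, batch, replicate).

    Stored as a DataFrame indexed by sample name with columns
    ``role`` (Role value, "i".."v"), ``batch`` and ``replicate`` (int).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"role", "batch", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample names in design")
        self.table = self.table.copy()
        self.table["role"] = [Role.from_label(r).value for r in self.table["role"]]
        self.table["batch"] = [Batch.from_label(b).value for b in self.table["batch"]]
        self.table["replicate"] = self.table["replicate"].astype(int)

    @classmethod
    def from_records(
        cls, records: Mapping[str, tuple[str | Role, str | Batch, int]]
    ) -> "SampleDesign":
        rows = {
            name: {
                "role": Role.from_label(role).value,
                "batch": Batch.from_label(batch).value,
                "replicate": rep,
            }
            for name, (role, batch, rep) in records.items()
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    @property
    def sample_names(self) -> pd.Index:
        return self.table.index

    def roles(self) -> set[Role]:
        return {Role(r) for r in self.table["role"].unique()}

    def samples_for(
        self, role: str | Role, batch: str | Batch | None = None
    ) -> list[str]:
        role = Role.from_label(role).value
        mask = self.table["role"] == role
        if batch is not None:
            mask &= self.table["batch"] == Batch.from_label(batch).value
        return list(self.table.index[mask])

    def require_roles(self, roles: Iterable[str | Role], min_samples: int = 2) -> None:
        """Raise if any requested role is absent or has too few samples."""
        for role in roles:
            samples = self.samples_for(role)
            if len(samples) < min_samples:
                raise ValueError(
                    f"role {Role.from_label(role).value!r} has "
                    f"{len(samples)} samples; need >= {min_samples}"
                )

    def subset(self, sample_names: Iterable[str]) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(sample_names)])

    def concat(self, other: "SampleDesign") -> "SampleDesign":
        overlap = self.table.index.intersection(other.table.index)
        if len(overlap):
            raise ValueError(f"overlapping sample names: {list(overlap[:5])}")
        return SampleDesign(pd.concat([self.table, other.table]))

    def validate_against(self, matrix: IntensityMatrix) -> None:
        missing = matrix.sample_names.difference(self.table.index)
        if len(missing):
            raise ValueError(f"samples without design entry: {list(missing[:5])}")

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", index_col="sample"))
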