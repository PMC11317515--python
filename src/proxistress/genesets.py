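"""Gene set collections and the flat text formats that carry them.

GMT: one set per line, tab-separated — name, description, member ids.
RNK: two tab-separated columns — id, ranking metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "read_rnk", "write_rnk"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions.

    Member lists preserve insertion order and are deduplicated on
    construction; set semantics (intersection with a universe) are applied at
    test time by the callers.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            seen: dict[str, None] = dict.fromkeys(str(m) for m in members)
            cleaned[name] = list(seen)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate set name: {name!r}")
        self.sets[name] = list(dict.fromkeys(str(m) for m in members))
        self.descriptions[name] = description

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        universe = set(universe)
        return GeneSetCollection(
            sets={
                name: [m for m in members if m in universe]
                for name, members in self.sets.items()
            },
            descriptions=dict(self.descriptions),
        )

    def write_gmt(self, path) -> None:
        write_gmt(self, path)


def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: GMT line needs name, description, members")
        name, description, *members = fields
        coll.add(name, [m for m in members if m], description)
    return coll


def write_gmt(collection: GeneSetCollection | Mapping[str, Iterable[str]], path) -> None:
    if isinstance(collection, GeneSetCollection):
        items = collection.sets.items()
        descriptions = collection.descriptions
    else:
        items = collection.items()
        descriptions = {}
    lines = [
        "\t".join([name, descriptions.get(name, "")] + list(members))
        for name, members in items
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_rnk(path) -> pd.DataFrame:
    """Read a two-column ranked list (id, score); no header expected."""
    table = pd.read_csv(path, sep="\t", header=None, names=["id", "score"], comment="#")
    table["id"] = table["id"].astype(str)
    table["score"] = table["score"].astype(float)
    return table


def write_rnk(table: pd.DataFrame, path) -> None:
    """Write (id, score) pairs as a headerless RNK file."""
    table.iloc[:, :2].to_csv(path, sep="\t", header=False, index=False)
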