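"""Kinase group/family catalog.

The kinome is organised hierarchically: groups (TK, CMGC, CAMK, AGC, ...)
contain families (EGFR, Jak, GSK, ...), and a family has ``M_f`` member
kinases.  Family-level inhibitor labels are defined against this catalog:
a compound is an active family inhibitor when it inhibits at least half of
the ``M_f`` members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["CatalogEntry", "FamilyCatalog", "read_catalog_csv", "write_catalog_csv"]


@dataclass(frozen=True)
class CatalogEntry:
    """One kinase family: its group, members, and structure availability."""

    group: str
    family: str
    members: tuple[str, ...]
    has_structure: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.has_structure):
            raise ValueError(
                f"family {self.family!r}: members and has_structure lengths differ"
            )
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"family {self.family!r}: duplicate member kinase ids")

    @property
    def m_f(self) -> int:
        """Number of member kinases (the M_f of the family-labeling rule)."""
        return len(self.members)

    @property
    def any_structure(self) -> bool:
        return any(self.has_structure)


@dataclass
class FamilyCatalog:
    """Ordered collection of :class:`CatalogEntry` with unique kinase ids."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            for k in entry.members:
                if k in seen:
                    raise ValueError(f"kinase id {k!r} appears in more than one family")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def families(self) -> list[str]:
        return [e.family for e in self.entries]

    @property
    def kinase_ids(self) -> list[str]:
        return [k for e in self.entries for k in e.members]

    def family_of(self, kinase_id: str) -> str | None:
        for e in self.entries:
            if kinase_id in e.members:
                return e.family
        return None

    def entry(self, family: str) -> CatalogEntry:
        for e in self.entries:
            if e.family == family:
                return e
        raise KeyError(f"no family named {family!r} in catalog")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": e.group,
                "family": e.family,
                "kinase_id": k,
                "has_structure": s,
            }
            for e in self.entries
            for k, s in zip(e.members, e.has_structure)
        ]
        return pd.DataFrame(rows, columns=["group", "family", "kinase_id", "has_structure"])


def write_catalog_csv(catalog: FamilyCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, index=False)


def read_catalog_csv(path: str | Path) -> FamilyCatalog:
    """Read a catalog table (group, family, kinase_id, has_structure rows)."""
    df = pd.read_csv(path)
    required = {"group", "family", "kinase_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog file {path}: missing columns {sorted(missing)}")
    if "has_structure" not in df.columns:
        df["has_structure"] = True
    entries = []
    for (group, family), sub in df.groupby(["group", "family"], sort=False):
        entries.append(
            CatalogEntry(
                group=str(group),
                family=str(family),
                members=tuple(str(k) for k in sub["kinase_id"]),
                has_structure=tuple(bool(s) for s in sub["has_structure"]),
            )
        )
    return FamilyCatalog(entries)
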