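"""Curation of kinase-compound bioactivity into family-inhibitor datasets.

The pipeline mirrors common practice for assembling QSAR-ready sets from
heterogeneous assay sources:

1. each measurement is labeled positive or negative against a source-specific
   activity threshold (IC50 < 500 nM, or pKi > 6.3 — strict inequalities);
2. replicate measurements of one kinase-compound pair are resolved by voting:
   the pair is *active* when more than 80% of its records are positive,
   *inactive* when fewer than 20% are, and discarded as *ambiguous* otherwise;
3. per-kinase active/inactive compound sets are assembled from the calls;
4. a compound becomes an *active family inhibitor* (label 1) for a kinase
   family when it is active against at least half of the family's M_f
   members, and an inactive family inhibitor (label 0) otherwise, provided it
   has at least one non-ambiguous call against some member;
5. families are kept for modelling when they have >= 250 labeled inhibitors,
   >= 2 member kinases, and (optionally) at least one member with a crystal
   structure.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CatalogEntry, FamilyCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "ASSAY_IC50",
    "ASSAY_PKI",
    "IC50_THRESHOLD_NM",
    "PKI_THRESHOLD",
    "BioactivityRecord",
    "ActivityCall",
    "FamilyDataset",
    "label_record",
    "vote_pair",
    "vote_all_pairs",
    "build_kinase_sets",
    "label_family_inhibitors",
    "select_families",
    "summarize_families",
    "summary_from_counts",
    "read_bioactivity_table",
    "write_bioactivity_csv",
    "chembl_prefilter",
]

ASSAY_IC50 = "IC50"
ASSAY_PKI = "pKi"

IC50_THRESHOLD_NM = 500.0  # IC50 strictly below this (nM) is a positive record
PKI_THRESHOLD = 6.3  # pKi strictly above this is a positive record

ACTIVE_VOTE_FRACTION = 0.8  # strictly more than 80% positive -> active pair
INACTIVE_VOTE_FRACTION = 0.2  # strictly less than 20% positive -> inactive pair


@dataclass(frozen=True)
class BioactivityRecord:
    """A single measured assay value for one kinase-compound pair.

    ``assay_type`` selects the unit dialect: ``IC50`` values are molar
    concentrations in nM, ``pKi`` values are unitless negative log constants.
    """

    compound_id: str
    kinase_id: str
    assay_type: str
    value: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.assay_type not in (ASSAY_IC50, ASSAY_PKI):
            raise ValueError(
                f"unknown assay_type {self.assay_type!r} "
                f"(expected {ASSAY_IC50!r} or {ASSAY_PKI!r})"
            )
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite bioactivity value for {self.compound_id!r}")
        if self.assay_type == ASSAY_IC50 and self.value <= 0:
            raise ValueError(
                f"IC50 must be positive, got {self.value} for {self.compound_id!r}"
            )


@dataclass(frozen=True)
class ActivityCall:
    """The voted activity of one kinase-compound pair."""

    compound_id: str
    kinase_id: str
    call: Literal["active", "inactive", "ambiguous"]
    n_records: int
    positive_fraction: float


@dataclass
class FamilyDataset:
    """Binary family-inhibitor labels for the compounds tested on one family.

    ``provenance`` maps each compound to ``(n_active_members, n_called_members)``:
    how many family members it was called active on, and how many it has any
    non-ambiguous call against.
    """

    entry: CatalogEntry
    compound_ids: list[str]
    labels: np.ndarray
    provenance: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.compound_ids):
            raise ValueError("labels must be a 1-D array aligned with compound_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("family labels must be binary")

    @property
    def family(self) -> str:
        return self.entry.family

    @property
    def group(self) -> str:
        return self.entry.group

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    @property
    def n_inactive(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    @property
    def total(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"compound_id": self.compound_ids, "label": self.labels})


def label_record(record: BioactivityRecord) -> bool:
    """Return True when the record is positive under its source's threshold.

    IC50 records are positive strictly below 500 nM; pKi records strictly
    above 6.3.  Values exactly at a threshold are negative.
    """
    if record.assay_type == ASSAY_IC50:
        return record.value < IC50_THRESHOLD_NM
    if record.assay_type == ASSAY_PKI:
        return record.value > PKI_THRESHOLD
    raise ValueError(f"unknown assay_type {record.assay_type!r}")


def vote_pair(records: Sequence[BioactivityRecord]) -> ActivityCall:
    """Resolve replicate records of one kinase-compound pair by voting.

    The pair is called active when its positive fraction strictly exceeds
    0.8, inactive when strictly below 0.2, ambiguous otherwise (including
    exactly 0.8 or 0.2).
    """
    if not records:
        raise ValueError("vote_pair requires at least one record")
    pairs = {(r.compound_id, r.kinase_id) for r in records}
    if len(pairs) != 1:
        raise ValueError(f"vote_pair received records for multiple pairs: {sorted(pairs)}")
    positives = sum(label_record(r) for r in records)
    fraction = positives / len(records)
    if fraction > ACTIVE_VOTE_FRACTION:
        call = "active"
    elif fraction < INACTIVE_VOTE_FRACTION:
        call = "inactive"
    else:
        call = "ambiguous"
    compound_id, kinase_id = next(iter(pairs))
    return ActivityCall(compound_id, kinase_id, call, len(records), fraction)


def vote_all_pairs(records: Iterable[BioactivityRecord]) -> list[ActivityCall]:
    """Group records by (compound, kinase) pair and vote each pair."""
    grouped: dict[tuple[str, str], list[BioactivityRecord]] = defaultdict(list)
    for r in records:
        grouped[(r.compound_id, r.kinase_id)].append(r)
    return [vote_pair(rs) for rs in grouped.values()]


def build_kinase_sets(
    calls: Sequence[ActivityCall],
) -> dict[str, tuple[set[str], set[str]]]:
    """Map each kinase to its (active, inactive) compound sets.

    Ambiguous calls contribute to neither set but still register the kinase.
    Duplicate calls for one pair are an error: votes must be pre-aggregated.
    """
    seen: set[tuple[str, str]] = set()
    sets: dict[str, tuple[set[str], set[str]]] = {}
    for call in calls:
        key = (call.compound_id, call.kinase_id)
        if key in seen:
            raise ValueError(f"duplicate activity call for pair {key}")
        seen.add(key)
        active, inactive = sets.setdefault(call.kinase_id, (set(), set()))
        if call.call == "active":
            active.add(call.compound_id)
        elif call.call == "inactive":
            inactive.add(call.compound_id)
    return sets


def label_family_inhibitors(
    kinase_sets: Mapping[str, tuple[set[str], set[str]]],
    catalog: FamilyCatalog,
    family_threshold: Literal["ceil", "floor"] = "ceil",
    inactive_scope: Literal["tested", "all"] = "tested",
) -> list[FamilyDataset]:
    """Assign binary family-inhibitor labels from per-kinase activity sets.

    A compound is labeled 1 for a family when the number of members it is
    called active on reaches half of M_f; with odd M_f the default "ceil"
    threshold requires at least ceil(M_f/2) members (2 of 3).  The
    denominator is always M_f: members without calls count as not inhibited.

    ``inactive_scope`` controls which compounds enter a family's dataset with
    label 0: "tested" (default) admits only compounds with at least one
    non-ambiguous call against a member; "all" admits every compound with a
    call against any catalog kinase.
    """
    if family_threshold not in ("ceil", "floor"):
        raise ValueError(f"family_threshold must be 'ceil' or 'floor', got {family_threshold!r}")
    if inactive_scope not in ("tested", "all"):
        raise ValueError(f"inactive_scope must be 'tested' or 'all', got {inactive_scope!r}")

    catalog_kinases = set(catalog.kinase_ids)
    for kinase_id in kinase_sets:
        if kinase_id not in catalog_kinases:
            logger.warning("kinase %r not in catalog; its calls are skipped", kinase_id)

    all_called: set[str] = set()
    for active, inactive in kinase_sets.values():
        all_called |= active | inactive

    datasets = []
    for entry in catalog:
        if family_threshold == "ceil":
            needed = math.ceil(entry.m_f / 2)
        else:
            needed = max(1, math.floor(entry.m_f / 2))
        n_active_on: dict[str, int] = defaultdict(int)
        n_called_on: dict[str, int] = defaultdict(int)
        for kinase_id in entry.members:
            active, inactive = kinase_sets.get(kinase_id, (set(), set()))
            for c in active:
                n_active_on[c] += 1
                n_called_on[c] += 1
            for c in inactive:
                n_called_on[c] += 1
        if inactive_scope == "tested":
            universe = sorted(n_called_on)
        else:
            universe = sorted(all_called)
        labels = np.array(
            [1 if n_active_on[c] >= needed else 0 for c in universe], dtype=int
        )
        provenance = {c: (n_active_on[c], n_called_on[c]) for c in universe}
        datasets.append(FamilyDataset(entry, list(universe), labels, provenance))
    return datasets


def select_families(
    datasets: Sequence[FamilyDataset],
    min_total: int = 250,
    min_kinases: int = 2,
    require_structure: bool = True,
) -> list[FamilyDataset]:
    """Keep families with enough labeled inhibitors, members, and structures."""
    kept = []
    for ds in datasets:
        if ds.total < min_total:
            continue
        if ds.entry.m_f < min_kinases:
            continue
        if require_structure and not ds.entry.any_structure:
            continue
        kept.append(ds)
    return kept


def summarize_families(datasets: Sequence[FamilyDataset]) -> pd.DataFrame:
    """Tabulate per-family counts and the active/inactive ratio."""
    rows = [
        (ds.group, ds.family, ds.entry.m_f, ds.n_active, ds.n_inactive)
        for ds in datasets
    ]
    return summary_from_counts(rows)


def summary_from_counts(
    rows: Iterable[tuple[str, str, int, int, int]],
) -> pd.DataFrame:
    """Build the family summary table from (group, family, M_f, n_active,
    n_inactive) tuples.

    ``ratio`` is n_active / n_inactive rounded to two decimals, with
    ``inf`` when a family has no inactives.
    """
    out = []
    for group, family, m_f, n_active, n_inactive in rows:
        ratio = math.inf if n_inactive == 0 else round(n_active / n_inactive, 2)
        out.append(
            {
                "group": group,
                "family": family,
                "m_f": m_f,
                "n_active": n_active,
                "n_inactive": n_inactive,
                "total": n_active + n_inactive,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(
        out, columns=["group", "family", "m_f", "n_active", "n_inactive", "total", "ratio"]
    )


# ---------------------------------------------------------------------------
# I/O


def write_bioactivity_csv(records: Iterable[BioactivityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "kinase_id": r.kinase_id,
                "assay_type": r.assay_type,
                "value": r.value,
                "source": r.source,
            }
            for r in records
        ],
        columns=["compound_id", "kinase_id", "assay_type", "value", "source"],
    )
    df.to_csv(path, index=False)


def chembl_prefilter(
    df: pd.DataFrame,
    relation_col: str = "standard_relation",
    assay_rel_col: str = "assay_relationship",
    confidence_col: str = "confidence_score",
) -> pd.DataFrame:
    """Apply ChEMBL-style row filters when the corresponding columns exist.

    Keeps rows with an exact '=' activity relation, binding ('B') assay
    relationship, and the maximum assay confidence score of 9.  Columns
    absent from the table are simply not filtered on.
    """
    mask = pd.Series(True, index=df.index)
    if relation_col in df.columns:
        mask &= df[relation_col].astype(str).str.strip() == "="
    if assay_rel_col in df.columns:
        mask &= df[assay_rel_col].astype(str).str.strip() == "B"
    if confidence_col in df.columns:
        mask &= pd.to_numeric(df[confidence_col], errors="coerce") == 9
    return df[mask]


def read_bioactivity_table(
    path: str | Path,
    sep: str | None = None,
    apply_chembl_filters: bool = False,
) -> list[BioactivityRecord]:
    """Read bioactivity records from a CSV/TSV table.

    Required columns: compound_id, kinase_id, assay_type, value; optional:
    source.  ``sep=None`` sniffs the delimiter.  With
    ``apply_chembl_filters=True``, ChEMBL-style quality columns (relation,
    assay relationship, confidence score) are used to drop low-confidence
    rows before parsing.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"compound_id", "kinase_id", "assay_type", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bioactivity table {path}: missing columns {sorted(missing)}")
    if apply_chembl_filters:
        df = chembl_prefilter(df)
    if "source" not in df.columns:
        df["source"] = ""
    return [
        BioactivityRecord(
            compound_id=str(row.compound_id),
            kinase_id=str(row.kinase_id),
            assay_type=str(row.assay_type),
            value=float(row.value),
            source=str(row.source),
        )
        for row in df.itertuples(index=False)
    ]
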