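"""Synthetic kinome bioactivity generator with planted driver moieties.

The generator emulates the statistical shape of a curated kinase-family
bioactivity compendium so the whole pipeline — curation, classification,
Shapley attribution, moiety tagging — can be exercised with known ground
truth:

* a kinome of ``n_groups`` groups, each with ``families_per_group`` families
  of 2-4 member kinases;
* compounds encoded directly as binary feature vectors, each bit i.i.d.
  Bernoulli(background_prevalence) — driver moieties are no more prevalent
  than the rest, they act only through activity;
* a logistic activity model per kinase-compound pair:
  ``p = sigmoid(intercept + driver_effect * k)`` where ``k`` counts the
  drivers of that kinase's family (common + group-level + family-specific)
  present in the compound;
* replicated measurements per tested pair, mixed between IC50-type (nM) and
  pKi-type records, whose values fall on the active or inactive side of the
  curation thresholds according to the pair's Bernoulli(p) activity state,
  flipped with probability ``label_noise``.

Randomness is hierarchical: every compound and every pair derives its own
stream from the one spec seed, so enlarging ``n_compounds`` leaves the
records of earlier compounds untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .catalog import CatalogEntry, FamilyCatalog
from .curation import ASSAY_IC50, ASSAY_PKI, BioactivityRecord
from .featurization import FeatureMatrix

__all__ = ["SyntheticSpec", "generate_kinome", "generate_compounds", "simulate_bioactivity"]

_STREAM_KINOME = 1
_STREAM_COMPOUNDS = 2
_STREAM_BIOACTIVITY = 3


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the synthetic study; serves as ground truth.

    Driver ids are 1-based feature indices.  ``common_driver_ids`` raise
    activity for every family; ``group_driver_ids`` (keyed by group name) for
    the families of one group; ``specific_driver_ids`` (keyed by family name)
    for a single family.  The three tiers must not overlap.
    """

    n_groups: int = 4
    families_per_group: int = 2
    kinases_per_family: int | tuple[int, int] = (2, 4)
    n_compounds: int = 1000
    n_features: int = 238
    background_prevalence: float = 0.15
    common_driver_ids: tuple[int, ...] = ()
    group_driver_ids: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    specific_driver_ids: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    driver_effect: float = 6.0
    intercept: float = -3.0
    replicate_range: tuple[int, int] = (1, 3)
    assay_mix: float = 0.5
    label_noise: float = 0.0
    coverage: float = 1.0
    seed: int = 0

    # -- structure helpers ---------------------------------------------------

    @property
    def group_names(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_groups)]

    @property
    def family_names(self) -> list[str]:
        return [
            f"G{i + 1}F{j + 1}"
            for i in range(self.n_groups)
            for j in range(self.families_per_group)
        ]

    def drivers_for(self, group: str, family: str) -> tuple[int, ...]:
        """All driver feature ids acting on one family, sorted."""
        ids = set(self.common_driver_ids)
        ids |= set(self.group_driver_ids.get(group, ()))
        ids |= set(self.specific_driver_ids.get(family, ()))
        return tuple(sorted(ids))

    def validate(self) -> None:
        for name in ("n_groups", "families_per_group", "n_compounds", "n_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        kpf = self.kinases_per_family
        lo, hi = (kpf, kpf) if isinstance(kpf, int) else kpf
        if lo < 2 or hi < lo:
            raise ValueError(
                f"kinases_per_family must be >= 2 (and min <= max), got {kpf!r}"
            )
        for name in ("background_prevalence", "assay_mix", "label_noise", "coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        rlo, rhi = self.replicate_range
        if rlo < 1 or rhi < rlo:
            raise ValueError(f"replicate_range must satisfy 1 <= min <= max, got {self.replicate_range}")
        tiers: list[tuple[str, set[int]]] = [("common_driver_ids", set(self.common_driver_ids))]
        tiers += [(f"group_driver_ids[{g}]", set(ids)) for g, ids in self.group_driver_ids.items()]
        tiers += [(f"specific_driver_ids[{f}]", set(ids)) for f, ids in self.specific_driver_ids.items()]
        for name, ids in tiers:
            if not ids <= set(range(1, self.n_features + 1)):
                raise ValueError(f"{name} contains ids outside [1..{self.n_features}]")
        common = set(self.common_driver_ids)
        pooled_specific: set[int] = set()
        for fam, ids in self.specific_driver_ids.items():
            sids = set(ids)
            if sids & common:
                raise ValueError(f"specific_driver_ids[{fam}] overlaps common_driver_ids")
            if sids & pooled_specific:
                raise ValueError(f"specific_driver_ids[{fam}] overlaps another family's drivers")
            pooled_specific |= sids
        for grp, ids in self.group_driver_ids.items():
            gids = set(ids)
            if gids & common:
                raise ValueError(f"group_driver_ids[{grp}] overlaps common_driver_ids")
            if gids & pooled_specific:
                raise ValueError(f"group_driver_ids[{grp}] overlaps family-specific drivers")

    @classmethod
    def with_default_drivers(
        cls,
        n_common: int = 2,
        n_group: int = 2,
        n_specific: int = 3,
        **kwargs,
    ) -> "SyntheticSpec":
        """Build a spec whose driver tiers occupy consecutive feature ids.

        Features 1..n_common are common drivers, the next blocks are
        group-level then family-specific drivers, the rest is background.
        """
        spec = cls(**kwargs)
        next_id = 1
        common = tuple(range(next_id, next_id + n_common))
        next_id += n_common
        group_ids = {}
        for g in spec.group_names:
            group_ids[g] = tuple(range(next_id, next_id + n_group))
            next_id += n_group
        specific = {}
        for f in spec.family_names:
            specific[f] = tuple(range(next_id, next_id + n_specific))
            next_id += n_specific
        if next_id - 1 > spec.n_features:
            raise ValueError(
                f"driver layout needs {next_id - 1} features but n_features={spec.n_features}"
            )
        spec = replace(
            spec,
            common_driver_ids=common,
            group_driver_ids=group_ids,
            specific_driver_ids=specific,
        )
        spec.validate()
        return spec


def generate_kinome(spec: SyntheticSpec) -> FamilyCatalog:
    """Deterministically generate the group/family/kinase catalog."""
    spec.validate()
    rng = _rng(spec.seed, _STREAM_KINOME)
    kpf = spec.kinases_per_family
    lo, hi = (kpf, kpf) if isinstance(kpf, int) else kpf
    entries = []
    kinase_counter = 0
    for i, group in enumerate(spec.group_names):
        for j in range(spec.families_per_group):
            family = f"{group}F{j + 1}"
            n_members = int(rng.integers(lo, hi + 1))
            members = tuple(
                f"K{kinase_counter + m + 1:04d}" for m in range(n_members)
            )
            kinase_counter += n_members
            entries.append(
                CatalogEntry(
                    group=group,
                    family=family,
                    members=members,
                    has_structure=tuple(True for _ in members),
                )
            )
    return FamilyCatalog(entries)


def generate_compounds(spec: SyntheticSpec) -> FeatureMatrix:
    """Sample the n_compounds x n_features binary matrix.

    Every bit — driver or not — is Bernoulli(background_prevalence): planted
    drivers influence activity, not prevalence.  Each compound has its own
    seed stream, so the first k rows are identical for any n_compounds >= k.
    """
    spec.validate()
    rows = np.empty((spec.n_compounds, spec.n_features), dtype=np.uint8)
    for c in range(spec.n_compounds):
        rng = _rng(spec.seed, _STREAM_COMPOUNDS, c)
        rows[c] = rng.random(spec.n_features) < spec.background_prevalence
    compound_ids = [f"C{c + 1:05d}" for c in range(spec.n_compounds)]
    feature_ids = [f"f-{j + 1}" for j in range(spec.n_features)]
    return FeatureMatrix(compound_ids, feature_ids, rows)


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def simulate_bioactivity(
    catalog: FamilyCatalog,
    features: FeatureMatrix,
    spec: SyntheticSpec,
) -> list[BioactivityRecord]:
    """Emit replicated IC50/pKi records for every tested kinase-compound pair.

    For each pair, the latent activity state is Bernoulli(p) with
    ``p = sigmoid(intercept + driver_effect * n_drivers_present)`` counting
    the drivers of the kinase's family.  Each replicate record reports a
    value on the matching side of the curation threshold — log-uniform IC50
    on (10, 500) nM for actives and (500, 50000) nM for inactives, or pKi
    uniform on (6.3, 9) / (3, 6.3) — with its side flipped with probability
    ``label_noise``.
    """
    spec.validate()
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if features.n_compounds == 0:
        raise ValueError("feature matrix is empty")

    records: list[BioactivityRecord] = []
    bits = features.bits
    for c, compound_id in enumerate(features.compound_ids):
        rng = _rng(spec.seed, _STREAM_BIOACTIVITY, c)
        for entry in catalog:
            drivers = spec.drivers_for(entry.group, entry.family)
            n_present = int(bits[c, [d - 1 for d in drivers]].sum()) if drivers else 0
            p = _sigmoid(spec.intercept + spec.driver_effect * n_present)
            for kinase_id in entry.members:
                # draws below happen unconditionally so that record streams
                # stay aligned whatever the coverage mask does
                tested = rng.random() < spec.coverage
                active = rng.random() < p
                n_rep = int(rng.integers(spec.replicate_range[0], spec.replicate_range[1] + 1))
                for _ in range(n_rep):
                    is_ic50 = rng.random() < spec.assay_mix
                    flipped = rng.random() < spec.label_noise
                    positive = active != flipped
                    u = rng.random()
                    if is_ic50:
                        lo, hi = (10.0, 500.0) if positive else (500.0, 50000.0)
                        value = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
                        # keep strictly inside the open interval
                        value = min(max(value, lo * 1.0000001), hi * 0.9999999)
                        assay = ASSAY_IC50
                    else:
                        lo, hi = (6.3, 9.0) if positive else (3.0, 6.3)
                        value = lo + u * (hi - lo)
                        value = min(max(value, lo + 1e-9), hi - 1e-9)
                        assay = ASSAY_PKI
                    if tested:
                        records.append(
                            BioactivityRecord(
                                compound_id=compound_id,
                                kinase_id=kinase_id,
                                assay_type=assay,
                                value=float(value),
                                source="synthetic",
                            )
                        )
    return records
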