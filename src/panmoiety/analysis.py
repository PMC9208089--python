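"""Downstream statistics over per-family importance profiles.

Validates and organises what the attribution stage produced: per-feature
odds ratios from the 2x2 presence-vs-activity table (with Haldane-Anscombe
correction), the Pearson correlation between importance scores and odds
ratios over the selected features, hierarchical clustering of families by
their importance profiles (1 - Pearson r distance, average linkage),
tagging of moieties as common to most families versus specific to one, and
the average occurrence percentage of a moiety group in a ligand set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .explanation import ImportanceProfile
from .featurization import FeatureMatrix

__all__ = [
    "OddsRatioTable",
    "FamilyImportanceMatrix",
    "MoietyGrouping",
    "odds_ratios",
    "importance_or_correlation",
    "build_importance_matrix",
    "cluster_families",
    "tag_moieties",
    "occurrence_percentage",
]


@dataclass
class OddsRatioTable:
    """Per-feature 2x2 association between presence and activity label.

    Cells per feature: a = active with feature, b = active without,
    c = inactive with, d = inactive without.  ``odds_ratio = (a*d)/(b*c)``;
    when any cell is zero, 0.5 is added to all four cells of that feature
    (Haldane-Anscombe) and ``correction_used`` is flagged.
    """

    feature_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    odds_ratio: np.ndarray
    correction_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "d": self.d,
                "odds_ratio": self.odds_ratio,
                "correction_used": self.correction_used,
            }
        )

    def ratio_for(self, feature_id: str) -> float:
        return float(self.odds_ratio[self.feature_ids.index(feature_id)])


def odds_ratios(features: FeatureMatrix, labels: np.ndarray) -> OddsRatioTable:
    """Odds ratio of each moiety's presence between active and inactive sets."""
    labels = np.asarray(labels)
    if labels.shape[0] != features.n_compounds:
        raise ValueError("labels length does not match the feature matrix")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    act = labels == 1
    if not act.any() or act.all():
        raise ValueError("both classes must be present to compute odds ratios")
    bits = features.bits.astype(float)
    a = bits[act].sum(axis=0)
    b = act.sum() - a
    c = bits[~act].sum(axis=0)
    d = (~act).sum() - c
    needs = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a_, b_, c_, d_ = (np.where(needs, v + 0.5, v) for v in (a, b, c, d))
    ratio = (a_ * d_) / (b_ * c_)
    return OddsRatioTable(
        feature_ids=list(features.feature_ids),
        a=a, b=b, c=c, d=d,
        odds_ratio=ratio,
        correction_used=needs,
    )


def importance_or_correlation(
    profile: ImportanceProfile,
    ors: OddsRatioTable,
    subset: Sequence[str] | None = None,
) -> float:
    """Pearson r between importance scores and odds ratios over a feature subset.

    Default subset is the profile's selected features; at least 3 features
    with variance in both vectors are required.
    """
    if subset is None:
        subset = profile.selected
    subset = list(subset)
    if len(subset) < 3:
        raise ValueError(f"need >= 3 features to correlate, got {len(subset)}")
    s_index = {f: i for i, f in enumerate(profile.feature_ids)}
    o_index = {f: i for i, f in enumerate(ors.feature_ids)}
    missing = [f for f in subset if f not in s_index or f not in o_index]
    if missing:
        raise KeyError(f"features missing from profile or odds-ratio table: {missing[:5]}")
    x = np.array([profile.scores[s_index[f]] for f in subset])
    y = np.array([ors.odds_ratio[o_index[f]] for f in subset])
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation inputs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in importance scores or odds ratios")
    r, _ = pearsonr(x, y)
    return float(r)


@dataclass
class FamilyImportanceMatrix:
    """Families x union-of-selected-features score matrix."""

    families: list[str]
    feature_union: list[str]
    scores: np.ndarray  # (n_families, n_union_features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.families, columns=self.feature_union)


def build_importance_matrix(
    profiles: Sequence[ImportanceProfile],
) -> FamilyImportanceMatrix:
    """Union the families' selected features and tabulate their scores.

    Union order is first-seen across profiles (each profile's selection in
    its own rank order).  Every feature is scored in every family, so no
    cell is missing.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two family profiles")
    spaces = {tuple(p.feature_ids) for p in profiles}
    if len(spaces) != 1:
        raise ValueError("profiles have mismatched feature spaces")
    union: list[str] = []
    seen: set[str] = set()
    for p in profiles:
        for f in p.selected:
            if f not in seen:
                seen.add(f)
                union.append(f)
    index = {f: i for i, f in enumerate(profiles[0].feature_ids)}
    scores = np.array([[p.scores[index[f]] for f in union] for p in profiles])
    return FamilyImportanceMatrix(
        families=[p.family for p in profiles],
        feature_union=union,
        scores=scores,
    )


def cluster_families(
    matrix: FamilyImportanceMatrix, method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerate families on correlation distance between score profiles.

    Distance between two families is 1 - Pearson r of their score vectors
    over the union features (range [0, 2]).  Returns the scipy linkage
    matrix and the family order used (sorted by name so ties break
    deterministically).
    """
    if len(matrix.families) < 2:
        raise ValueError("need at least two families to cluster")
    order = sorted(range(len(matrix.families)), key=lambda i: matrix.families[i])
    names = [matrix.families[i] for i in order]
    rows = matrix.scores[order]
    for name, row in zip(names, rows):
        if np.std(row) == 0:
            raise ValueError(f"family {name!r} has a constant importance profile")
    corr = np.corrcoef(rows)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    return Z, names


@dataclass
class MoietyGrouping:
    """Partition of the selected-feature union into common / specific / rest."""

    common: list[str]
    specific: dict[str, list[str]]
    remainder: list[str]
    n_selected_in: dict[str, int] = field(default_factory=dict)


def tag_moieties(
    matrix: FamilyImportanceMatrix,
    profiles: Sequence[ImportanceProfile],
    common_min_families: int | None = None,
    specific_max_families: int = 1,
) -> MoietyGrouping:
    """Tag union features as common, family-specific, or remainder.

    A feature is *common* when selected in at least ``common_min_families``
    families (default: 75% of them, rounded up), and *specific* to a family
    when selected there and in at most ``specific_max_families`` families in
    total.  Everything else in the union is remainder.
    """
    n_families = len(profiles)
    if common_min_families is None:
        common_min_families = int(np.ceil(0.75 * n_families))
    counts = {f: 0 for f in matrix.feature_union}
    for p in profiles:
        for f in p.selected:
            if f in counts:
                counts[f] += 1
    common = [f for f in matrix.feature_union if counts[f] >= common_min_families]
    specific: dict[str, list[str]] = {}
    claimed: set[str] = set(common)
    for p in profiles:
        fam_specific = [
            f
            for f in p.selected
            if f not in claimed and counts[f] <= specific_max_families
        ]
        specific[p.family] = fam_specific
        claimed |= set(fam_specific)
    remainder = [f for f in matrix.feature_union if f not in claimed]
    return MoietyGrouping(
        common=common, specific=specific, remainder=remainder, n_selected_in=counts
    )


def occurrence_percentage(
    ligand_features: FeatureMatrix, group: Sequence[str]
) -> float:
    """Average percentage of ligands containing each moiety of a group.

    For every moiety in the group, compute 100 x (fraction of ligands whose
    bit is set) and return the mean over the group.
    """
    group = list(group)
    if not group:
        raise ValueError("moiety group is empty")
    if ligand_features.n_compounds == 0:
        raise ValueError("ligand set is empty")
    index = {f: i for i, f in enumerate(ligand_features.feature_ids)}
    missing = [f for f in group if f not in index]
    if missing:
        raise KeyError(f"moieties absent from the ligand feature matrix: {missing[:5]}")
    cols = [index[f] for f in group]
    per_moiety = 100.0 * ligand_features.bits[:, cols].mean(axis=0)
    return float(per_moiety.mean())
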