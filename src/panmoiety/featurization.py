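"""Binary moiety fingerprints for compounds.

Each compound is encoded as a 238-bit presence/absence vector over a moiety
dictionary: 204 functional-group features in the style of the Checkmol
descriptor set, plus 34 ring moieties grouped by their typical interaction
type with the kinase ATP site (electrostatic, hydrogen-bonding,
hydrogen-bonding+vdW, vdW).  Matching is by SMARTS substructure search;
dictionary entries without a working SMARTS (named placeholders for
functional groups only the external Checkmol program perceives) always
contribute a 0 bit and can instead be supplied through a precomputed matrix
loaded with :func:`load_feature_matrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_CLASSES",
    "MoietyEntry",
    "MoietyDictionary",
    "FeatureMatrix",
    "load_moiety_dictionary",
    "featurize_compound",
    "build_feature_matrix",
    "load_feature_matrix",
    "write_feature_matrix",
]

INTERACTION_CLASSES = (
    "electrostatic",
    "hydrogen-bonding",
    "hydrogen-bonding+vdW",
    "vdW",
    "unclassified",
)


@dataclass(frozen=True)
class MoietyEntry:
    feature_id: str
    name: str
    smarts: str | None
    interaction_class: str


class MoietyDictionary:
    """Ordered, validated collection of moiety definitions."""

    def __init__(self, entries: Sequence[MoietyEntry]):
        from rdkit import Chem

        ids = [e.feature_id for e in entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate feature ids in moiety dictionary: {sorted(dupes)}")
        self.entries: list[MoietyEntry] = list(entries)
        self._patterns = []
        for e in self.entries:
            if e.interaction_class not in INTERACTION_CLASSES:
                raise ValueError(
                    f"entry {e.feature_id}: unknown interaction class {e.interaction_class!r}"
                )
            if e.smarts is None:
                self._patterns.append(None)
                continue
            pat = Chem.MolFromSmarts(e.smarts)
            if pat is None:
                raise ValueError(f"entry {e.feature_id} ({e.name}): malformed SMARTS {e.smarts!r}")
            self._patterns.append(pat)
        self._index = {e.feature_id: i for i, e in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, feature_id: str) -> MoietyEntry:
        return self.entries[self._index[feature_id]]

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def pattern(self, feature_id: str):
        return self._patterns[self._index[feature_id]]

    @property
    def patterns(self):
        return list(self._patterns)


def load_moiety_dictionary(path: str | Path | None = None) -> MoietyDictionary:
    """Load a moiety dictionary from TSV (feature_id, name, smarts,
    interaction_class); with no path, load the bundled 238-entry default."""
    if path is None:
        source = resources.files("panmoiety.data") / "moieties.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"feature_id", "name", "smarts", "interaction_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"moiety dictionary: missing columns {sorted(missing)}")
    entries = [
        MoietyEntry(
            feature_id=str(r.feature_id),
            name=str(r.name),
            smarts=(str(r.smarts) or None),
            interaction_class=str(r.interaction_class),
        )
        for r in df.itertuples(index=False)
    ]
    return MoietyDictionary(entries)


@dataclass
class FeatureMatrix:
    """Binary compound-by-feature matrix with aligned id lists."""

    compound_ids: list[str]
    feature_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.bits.shape != (len(self.compound_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.bits.shape} inconsistent with "
                f"{len(self.compound_ids)} compounds x {len(self.feature_ids)} features"
            )
        bad = ~np.isin(self.bits, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at compound {self.compound_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r}: {self.bits[r, c]!r}"
            )
        self.bits = self.bits.astype(np.uint8)
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids in feature matrix")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids in feature matrix")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.compound_ids, columns=self.feature_ids)

    def subset(self, compound_ids: Sequence[str]) -> "FeatureMatrix":
        """Row-subset in the given order (compounds must all be present)."""
        index = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in compound_ids if c not in index]
        if missing:
            raise KeyError(f"compounds absent from feature matrix: {missing[:5]}")
        rows = [index[c] for c in compound_ids]
        return FeatureMatrix(list(compound_ids), list(self.feature_ids), self.bits[rows])


_null_smarts_warned: set[int] = set()


def _warn_null_smarts(dictionary: MoietyDictionary) -> None:
    """Warn once per dictionary object about entries that cannot match."""
    if id(dictionary) in _null_smarts_warned:
        return
    nulls = [e.feature_id for e, p in zip(dictionary.entries, dictionary.patterns) if p is None]
    if nulls:
        logger.warning(
            "dictionary has %d entries without SMARTS (e.g. %s); their bits are 0 — "
            "supply a precomputed matrix to populate them",
            len(nulls),
            nulls[0],
        )
    _null_smarts_warned.add(id(dictionary))


def featurize_compound(smiles: str, dictionary: MoietyDictionary) -> np.ndarray:
    """Encode one SMILES as a presence/absence vector over the dictionary.

    The molecule is parsed and sanitized once (RDKit canonical aromaticity),
    so the result is independent of the input atom ordering.  Entries with no
    SMARTS yield 0 with a warning.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    bits = np.zeros(len(dictionary), dtype=np.uint8)
    _warn_null_smarts(dictionary)
    for j, (entry, pattern) in enumerate(zip(dictionary.entries, dictionary.patterns)):
        if pattern is None:
            continue
        if mol.HasSubstructMatch(pattern):
            bits[j] = 1
    return bits


def build_feature_matrix(
    compounds: Sequence[tuple[str, str]], dictionary: MoietyDictionary
) -> FeatureMatrix:
    """Featurize (compound_id, smiles) pairs; rows keep input order.

    Compounds whose SMILES fail to parse are dropped with a logged error
    rather than aborting the whole matrix.
    """
    ids = [c for c, _ in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("compound ids must be unique")
    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    for compound_id, smiles in compounds:
        try:
            rows.append(featurize_compound(smiles, dictionary))
        except ValueError as exc:
            logger.error("compound %r dropped: %s", compound_id, exc)
            continue
        kept_ids.append(compound_id)
    bits = np.vstack(rows) if rows else np.zeros((0, len(dictionary)), dtype=np.uint8)
    return FeatureMatrix(kept_ids, dictionary.feature_ids, bits)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("compound_id").to_csv(path)


def load_feature_matrix(
    path: str | Path, expected_ids: Sequence[str] | None = None
) -> FeatureMatrix:
    """Load a binary matrix (rows=compounds, header=feature ids) from CSV.

    When ``expected_ids`` is given, the file's feature columns must match it
    exactly, in order.
    """
    df = pd.read_csv(path, index_col=0)
    feature_ids = [str(c) for c in df.columns]
    if expected_ids is not None:
        expected = [str(c) for c in expected_ids]
        if feature_ids != expected:
            extra = sorted(set(feature_ids) - set(expected))
            missing = sorted(set(expected) - set(feature_ids))
            raise ValueError(
                f"feature columns differ from expected: missing={missing[:10]}, "
                f"unexpected={extra[:10]}, order_mismatch="
                f"{feature_ids != expected and not missing and not extra}"
            )
    return FeatureMatrix([str(i) for i in df.index], feature_ids, df.to_numpy())
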