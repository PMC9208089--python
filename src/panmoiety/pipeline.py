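"""End-to-end orchestration: curate -> featurize -> train -> explain -> analyze.

The pipeline runs either on synthetic data (a :class:`SyntheticSpec` with
planted driver moieties, the self-contained test bed) or on user-supplied
tables (bioactivity CSV + catalog CSV + a feature matrix or SMILES list).
Every stage is seeded from the one pipeline seed; rerunning a config
reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import analysis as an
from . import classifier as clf
from . import curation as cur
from . import explanation as ex
from . import featurization as feat
from . import synthetic as syn
from .catalog import FamilyCatalog, read_catalog_csv, write_catalog_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one declarative object.

    Exactly one input mode must be configured: ``synthetic`` or the file
    trio (``bioactivity_csv`` + ``catalog_csv`` + ``features_csv`` or
    ``smiles_csv``).
    """

    # inputs
    synthetic: syn.SyntheticSpec | None = None
    bioactivity_csv: str | None = None
    catalog_csv: str | None = None
    features_csv: str | None = None
    smiles_csv: str | None = None
    moiety_dictionary: str | None = None

    # curation
    family_threshold: str = "ceil"
    inactive_scope: str = "tested"
    min_total: int = 250
    min_kinases: int = 2
    require_structure: bool = True

    # classifier
    hidden_sizes: tuple[int, ...] = (1024, 768, 512, 256)
    dropout_rate: float = 0.2
    batch_norm: bool = True
    n_repeats: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10

    # explanation
    n_permutations: int = 6
    background_size: int = 100
    max_explain_samples: int = 500
    models_to_explain: int = 2

    # analysis
    z_threshold: float = 1.96
    top_k: int = 15
    common_min_families: int | None = None
    specific_max_families: int = 1

    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.synthetic is not None:
            self.synthetic.validate()
            return
        if not (self.bioactivity_csv and self.catalog_csv):
            raise ValueError(
                "config needs either a synthetic spec or bioactivity_csv + catalog_csv"
            )
        if not (self.features_csv or self.smiles_csv):
            raise ValueError("file-mode config needs features_csv or smiles_csv")
        for name in ("bioactivity_csv", "catalog_csv", "features_csv", "smiles_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} points to a missing file: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise ValueError(f"config file {path} is not a mapping")
        raw = dict(raw)
        spec = raw.pop("synthetic", None)
        if spec is not None:
            for key in ("kinases_per_family", "replicate_range"):
                if key in spec and isinstance(spec[key], list):
                    spec[key] = tuple(spec[key])
            for key in ("common_driver_ids",):
                if key in spec:
                    spec[key] = tuple(spec[key])
            for key in ("group_driver_ids", "specific_driver_ids"):
                if key in spec:
                    spec[key] = {k: tuple(v) for k, v in spec[key].items()}
            spec = syn.SyntheticSpec(**spec)
        if "hidden_sizes" in raw:
            raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=spec, **raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 — re-raise with stage context
                raise PipelineError(name, exc) from exc
            logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec = config.synthetic
        catalog = syn.generate_kinome(spec)
        features = syn.generate_compounds(spec)
        records = syn.simulate_bioactivity(catalog, features, spec)
        return catalog, features, records
    catalog = read_catalog_csv(config.catalog_csv)
    records = cur.read_bioactivity_table(config.bioactivity_csv)
    if config.features_csv:
        features = feat.load_feature_matrix(config.features_csv)
    else:
        import pandas as pd

        dictionary = feat.load_moiety_dictionary(config.moiety_dictionary)
        smiles = pd.read_csv(config.smiles_csv)
        compounds = list(zip(smiles["compound_id"].astype(str), smiles["smiles"]))
        features = feat.build_feature_matrix(compounds, dictionary)
    return catalog, features, records


@_stage("curation")
def _curate(config: PipelineConfig, catalog, records):
    calls = cur.vote_all_pairs(records)
    kinase_sets = cur.build_kinase_sets(calls)
    datasets = cur.label_family_inhibitors(
        kinase_sets,
        catalog,
        family_threshold=config.family_threshold,
        inactive_scope=config.inactive_scope,
    )
    selected = cur.select_families(
        datasets,
        min_total=config.min_total,
        min_kinases=config.min_kinases,
        require_structure=config.require_structure,
    )
    summary = cur.summarize_families(selected)
    return selected, summary


def _choose_explained(y: np.ndarray, limit: int, rng: np.random.Generator) -> np.ndarray:
    """Class-stratified subset of row indices to explain (keeps both classes)."""
    n = len(y)
    if n <= limit:
        return np.arange(n)
    act = np.flatnonzero(y == 1)
    inact = np.flatnonzero(y == 0)
    n_act = max(1, min(len(act), round(limit * len(act) / n)))
    n_inact = max(1, limit - n_act)
    take_act = rng.choice(act, size=min(n_act, len(act)), replace=False)
    take_inact = rng.choice(inact, size=min(n_inact, len(inact)), replace=False)
    return np.sort(np.concatenate([take_act, take_inact]))


def run_full_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return (and optionally write) the report bundle."""
    config.validate()
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    catalog, features, records = _load_inputs(config)
    datasets, summary = _curate(config, catalog, records)
    if not datasets:
        raise PipelineError("curation", ValueError("no family passed the selection criteria"))

    model_spec = clf.ModelSpec(
        n_inputs=features.n_features,
        hidden_sizes=config.hidden_sizes,
        dropout_rate=config.dropout_rate,
        batch_norm=config.batch_norm,
    )

    metrics: dict[str, dict] = {}
    profiles: list[ex.ImportanceProfile] = []
    correlations: dict[str, float] = {}
    occurrence: dict[str, dict[str, float]] = {}

    for fam_idx, ds in enumerate(datasets):
        fam_seed = int((seeds[0] + 7919 * fam_idx) % (2**31))
        sub = features.subset(ds.compound_ids)
        X = sub.bits.astype(float)
        y = ds.labels

        try:
            cfg = clf.TrainConfig(
                n_repeats=config.n_repeats,
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                max_epochs=config.max_epochs,
                patience=config.patience,
                seed=fam_seed,
            )
            result = clf.repeat_experiments(X, y, cfg, model_spec)
        except Exception as exc:
            raise PipelineError(f"train[{ds.family}]", exc) from exc
        metrics[ds.family] = {
            "group": ds.group,
            "mean": result.mean,
            "std": result.std,
        }

        try:
            rng = np.random.default_rng(int(seeds[1]) + fam_idx)
            shap_cfg = ex.ShapConfig(
                background=ex.marginal_background(X, config.background_size, rng),
                n_permutations=config.n_permutations,
                seed=int(seeds[2]) + fam_idx,
            )
            explained = _choose_explained(y, config.max_explain_samples, rng)
            models = result.models[: max(1, config.models_to_explain)]
            expl = ex.explain_dataset(models, X[explained], shap_cfg, dtype=np.float32)
            profile = ex.importance_scores(
                expl, y[explained], feature_ids=sub.feature_ids, family=ds.family
            )
            ex.select_top_features(
                profile, z_threshold=config.z_threshold, top_k=config.top_k
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"explain[{ds.family}]", exc) from exc
        profiles.append(profile)

        try:
            # ORs over the same compounds the attributions were computed on,
            # so the two statistics see identical presence frequencies
            explained_fm = feat.FeatureMatrix(
                [sub.compound_ids[i] for i in explained],
                sub.feature_ids,
                sub.bits[explained],
            )
            ors = an.odds_ratios(explained_fm, y[explained])
            correlations[ds.family] = an.importance_or_correlation(profile, ors)
        except ValueError as exc:
            logger.warning("no SHAP-vs-OR correlation for %s: %s", ds.family, exc)
            correlations[ds.family] = float("nan")
        metrics[ds.family]["shap_or_pearson_r"] = correlations[ds.family]

    try:
        matrix = an.build_importance_matrix(profiles)
        Z, order = an.cluster_families(matrix)
        grouping = an.tag_moieties(
            matrix,
            profiles,
            common_min_families=config.common_min_families,
            specific_max_families=config.specific_max_families,
        )
    except Exception as exc:
        raise PipelineError("analysis", exc) from exc

    for ds, profile in zip(datasets, profiles):
        actives = [c for c, l in zip(ds.compound_ids, ds.labels) if l == 1]
        if not actives:
            continue
        ligands = features.subset(actives)
        fam_occ: dict[str, float] = {}
        for name, group in (
            ("common", grouping.common),
            ("top15", profile.selected),
            ("specific", grouping.specific.get(ds.family, [])),
            ("remainder", grouping.remainder),
        ):
            if group:
                fam_occ[name] = an.occurrence_percentage(ligands, group)
        occurrence[ds.family] = fam_occ

    bundle: dict[str, Any] = {
        "summary": summary,
        "metrics": metrics,
        "profiles": {p.family: p for p in profiles},
        "importance_matrix": matrix,
        "linkage": Z,
        "family_order": order,
        "grouping": grouping,
        "correlations": correlations,
        "occurrence": occurrence,
        "datasets": datasets,
        "features": features,
        "catalog": catalog,
        "seed": config.seed,
    }
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict[str, Any], config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["summary"].to_csv(out / "family_summary.csv", index=False)
    write_catalog_csv(bundle["catalog"], out / "catalog.csv")
    with open(out / "metrics.json", "w") as fh:
        json.dump(bundle["metrics"], fh, indent=2, allow_nan=True)
    bundle["importance_matrix"].to_frame().rename_axis("family").to_csv(
        out / "importance_matrix.csv"
    )
    for family, profile in bundle["profiles"].items():
        df = {
            "feature_id": profile.feature_ids,
            "score": profile.scores,
            "z_score": profile.z_scores,
        }
        import pandas as pd

        pd.DataFrame(df).to_csv(out / f"importance_{family}.csv", index=False)
    grouping = bundle["grouping"]
    with open(out / "moiety_grouping.json", "w") as fh:
        json.dump(
            {
                "common": grouping.common,
                "specific": grouping.specific,
                "remainder": grouping.remainder,
            },
            fh,
            indent=2,
        )
    with open(out / "clustering.json", "w") as fh:
        json.dump(
            {
                "linkage": np.asarray(bundle["linkage"]).tolist(),
                "family_order": bundle["family_order"],
            },
            fh,
            indent=2,
        )
    with open(out / "occurrence.json", "w") as fh:
        json.dump(bundle["occurrence"], fh, indent=2)
    for ds in bundle["datasets"]:
        ds.to_frame().to_csv(out / f"dataset_{ds.family}.csv", index=False)
    logger.info("report bundle written to %s", out)
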