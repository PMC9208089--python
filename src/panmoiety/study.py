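"""The bundled synthetic benchmark study.

A fixed, fully seeded study emulating the shape of the curated kinase
compendium: four kinase groups of two families each (2-4 kinases per
family), 1,000 compounds over 60 binary moiety features, with two common
drivers shared by all families, one driver per group, and three
family-specific drivers per family.  Effects are saturated (activity is
exactly the OR of a family's drivers) and label noise is zero, so planted
ground truth is recoverable and every pipeline stage can be held to it.
"""

from __future__ import annotations

from .pipeline import PipelineConfig
from .synthetic import SyntheticSpec

__all__ = ["benchmark_spec", "benchmark_config"]


def benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """The synthetic benchmark's generator settings (see module docstring)."""
    return SyntheticSpec.with_default_drivers(
        n_common=2,
        n_group=1,
        n_specific=3,
        n_groups=4,
        families_per_group=2,
        kinases_per_family=(2, 4),
        n_compounds=1000,
        n_features=60,
        background_prevalence=0.25,
        driver_effect=100.0,
        intercept=-50.0,
        label_noise=0.0,
        seed=seed,
    )


def benchmark_config(seed: int = 0, outdir: str | None = None) -> PipelineConfig:
    """Pipeline settings sized for a single-CPU run of the benchmark.

    Five repeat networks of two hidden layers (64, 32) per family;
    attributions from six antithetic permutations over a 100-row marginal
    background, on a 500-compound stratified subset, averaged over two
    repeat models.
    """
    return PipelineConfig(
        synthetic=benchmark_spec(seed),
        hidden_sizes=(64, 32),
        n_repeats=5,
        max_epochs=60,
        patience=8,
        n_permutations=6,
        background_size=100,
        max_explain_samples=500,
        models_to_explain=2,
        seed=seed,
        outdir=outdir,
    )
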