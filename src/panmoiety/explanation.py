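"""Shapley-value attribution and the class-contrast importance score.

A trained classifier ``f`` is explained per compound by an additive model

    f(x) = phi_0 + sum_j phi_j

where ``phi_j`` is the Shapley value of feature ``j``: its average marginal
contribution over all feature coalitions, weighted by |S|!(M-|S|-1)!/M!.
The value function is the interventional expectation: for a coalition S,
features outside S are replaced by the corresponding values of each
background sample and the predictions averaged; ``phi_0`` is the mean model
output over the background.

Two estimators are provided:

* :func:`shapley_exact` — full 2^M subset enumeration, the oracle for small
  M (default cap 12 features);
* :func:`shapley_sampled` — the permutation Monte-Carlo estimator.  For each
  sampled feature ordering the marginal contributions telescope from
  phi_0 to f(x), so the efficiency identity holds *exactly* for any number
  of permutations; averaging over permutations drives each phi_j to its
  exact value.

Per-family feature importance contrasts the two label classes
(mean phi_j over active compounds minus mean over inactive ones); features
are selected when their importance z-score across the feature axis exceeds
1.96, keeping at most the top 15 by score.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ShapConfig",
    "ShapExplanation",
    "ImportanceProfile",
    "shapley_exact",
    "shapley_sampled",
    "explain_dataset",
    "importance_scores",
    "select_top_features",
    "marginal_background",
]

ModelFn = Callable[[np.ndarray], np.ndarray]


def marginal_background(
    X: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Product-of-marginals background: each column's empirical prevalence,
    independent of the others.

    Column j of the returned matrix contains ``round(size * mean(X[:, j]))``
    ones in seeded random row positions.  Compared with a plain row
    subsample this removes two nuisance terms from interventional masking:
    the binomial noise of a small subsample's column means, and the
    subsample's accidental feature co-occurrence.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D array")
    if size < 1:
        raise ValueError("background size must be >= 1")
    p = X.mean(axis=0)
    bg = np.zeros((size, X.shape[1]))
    for j in range(X.shape[1]):
        ones = int(round(size * p[j]))
        col = np.zeros(size)
        col[:ones] = 1.0
        bg[:, j] = rng.permutation(col)
    return bg


@dataclass
class ShapConfig:
    """Attribution settings: background reference set, sampling effort, seed."""

    background: np.ndarray
    n_permutations: int = 200
    seed: int = 0
    max_exact_features: int = 12

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.ndim != 2 or self.background.shape[0] == 0:
            raise ValueError("background must be a non-empty 2-D array")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ShapExplanation:
    """Per-sample attribution matrix and the shared base value phi_0."""

    phi0: float
    phi: np.ndarray  # (n_samples, n_features)
    predictions: np.ndarray | None = None


def _subset_weights(m: int) -> np.ndarray:
    """w[s] = s! (m-s-1)! / m! for coalition sizes s = 0..m-1."""
    fact = [math.factorial(k) for k in range(m + 1)]
    return np.array([fact[s] * fact[m - s - 1] / fact[m] for s in range(m)])


def shapley_exact(
    model_fn: ModelFn, x: np.ndarray, cfg: ShapConfig
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by full coalition enumeration.

    Feasible only for small feature counts; raises beyond
    ``cfg.max_exact_features`` with a pointer to the sampling estimator.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    if m > cfg.max_exact_features:
        raise ValueError(
            f"{m} features exceeds max_exact_features={cfg.max_exact_features}; "
            "use shapley_sampled for larger models"
        )
    bg = cfg.background
    if bg.shape[1] != m:
        raise ValueError("background feature dimension does not match x")
    n_subsets = 1 << m
    # masks[s, j] — feature j present in coalition s
    masks = ((np.arange(n_subsets)[:, None] >> np.arange(m)) & 1).astype(bool)
    # hybrids: coalition features from x, the rest from each background row
    hybrids = np.where(masks[:, None, :], x[None, None, :], bg[None, :, :])
    preds = np.asarray(model_fn(hybrids.reshape(-1, m)), dtype=float)
    v = preds.reshape(n_subsets, bg.shape[0]).mean(axis=1)
    sizes = masks.sum(axis=1)
    w = _subset_weights(m)
    phi = np.zeros(m)
    for j in range(m):
        bit = 1 << j
        without = np.flatnonzero(~masks[:, j])
        phi[j] = np.sum(w[sizes[without]] * (v[without | bit] - v[without]))
    return phi, float(v[0])


def _sample_permutations(
    m: int, n: int, rng: np.random.Generator, antithetic: bool = False
) -> np.ndarray:
    """Draw n feature orderings; with ``antithetic`` each odd ordering is the
    reverse of its predecessor, which cancels much of the position bias of
    the truncated permutation average."""
    if not antithetic:
        return np.stack([rng.permutation(m) for _ in range(n)])
    out = np.empty((n, m), dtype=np.int64)
    for i in range(0, n, 2):
        p = rng.permutation(m)
        out[i] = p
        if i + 1 < n:
            out[i + 1] = p[::-1]
    return out


def shapley_sampled(
    model_fn: ModelFn,
    x: np.ndarray,
    cfg: ShapConfig,
    permutations: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Permutation Monte-Carlo estimate of the Shapley values of one sample.

    A precomputed permutation matrix may be supplied (as
    :func:`explain_dataset` does, so identical samples get identical phi);
    otherwise ``cfg.n_permutations`` orderings are drawn from ``cfg.seed``.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    bg = cfg.background
    if bg.shape[1] != m:
        raise ValueError("background feature dimension does not match x")
    if permutations is None:
        rng = np.random.default_rng(cfg.seed)
        permutations = _sample_permutations(m, cfg.n_permutations, rng)
    phi = np.zeros(m)
    for perm in permutations:
        # prefix masks: row k has the first k features of the ordering present
        masks = np.zeros((m + 1, m), dtype=bool)
        masks[1:] = np.cumsum(np.eye(m, dtype=bool)[perm], axis=0)
        hybrids = np.where(masks[:, None, :], x[None, None, :], bg[None, :, :])
        preds = np.asarray(model_fn(hybrids.reshape(-1, m)), dtype=float)
        v = preds.reshape(m + 1, bg.shape[0]).mean(axis=1)
        phi[perm] += np.diff(v)
    phi /= len(permutations)
    phi0 = float(np.asarray(model_fn(bg), dtype=float).mean())
    return phi, phi0


def _row_seed(cfg_seed: int, row: np.ndarray) -> np.random.SeedSequence:
    """Content-keyed seed: identical rows get identical permutation draws."""
    digest = hashlib.blake2b(np.ascontiguousarray(row).tobytes(), digest_size=8).digest()
    return np.random.SeedSequence((int(cfg_seed), int.from_bytes(digest, "little")))


def explain_dataset(
    models,
    X: np.ndarray,
    cfg: ShapConfig,
    chunk_rows: int = 200_000,
    dtype=np.float64,
) -> ShapExplanation:
    """Permutation-SHAP for every row of a feature matrix.

    ``models`` is a single predictor or a list (e.g. the repeat-trained
    networks); attributions are computed per model and averaged.  Each
    sample's permutation set is seeded from ``cfg.seed`` and a hash of the
    sample's own feature values: duplicate rows therefore receive identical
    attributions, while distinct rows draw independent orderings so the
    finite-permutation bias of the estimator decorrelates across the
    dataset instead of pushing every sample's phi the same way.

    ``dtype`` controls the precision of the masked-prediction batches;
    float32 roughly halves memory traffic at ~1e-6 cost in phi, which the
    downstream class-contrast scores cannot resolve anyway.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    m = X.shape[1]
    if cfg.background.shape[1] != m:
        raise ValueError(
            f"background has {cfg.background.shape[1]} features, data has {m}"
        )
    model_list = models if isinstance(models, (list, tuple)) else [models]
    fns = [mdl.predict_proba if hasattr(mdl, "predict_proba") else mdl for mdl in model_list]

    n_perm = cfg.n_permutations
    # per-sample permutations and prefix masks, shared across models
    perms = np.empty((X.shape[0], n_perm, m), dtype=np.int64)
    for s in range(X.shape[0]):
        rng = np.random.default_rng(_row_seed(cfg.seed, X[s]))
        perms[s] = _sample_permutations(m, n_perm, rng, antithetic=True)
    eye = np.eye(m, dtype=bool)
    masks = np.zeros((X.shape[0], n_perm, m + 1, m), dtype=bool)
    masks[:, :, 1:, :] = np.cumsum(eye[perms], axis=2)
    masks = masks.reshape(X.shape[0], n_perm * (m + 1), m)

    bg = cfg.background.astype(dtype)
    nb = bg.shape[0]
    rows_per_sample = n_perm * (m + 1) * nb
    samples_per_chunk = max(1, chunk_rows // rows_per_sample)
    Xd = X.astype(dtype)

    phi = np.zeros((X.shape[0], m))
    phi0 = 0.0
    preds = np.zeros(X.shape[0])
    for fn in fns:
        phi0 += float(np.asarray(fn(bg), dtype=float).mean())
        preds += np.asarray(fn(X), dtype=float)
        for start in range(0, X.shape[0], samples_per_chunk):
            stop = min(start + samples_per_chunk, X.shape[0])
            xs = Xd[start:stop]
            # (n_chunk, P*(m+1), nb, m): coalition bits from x, rest from bg
            hybrids = np.where(
                masks[start:stop, :, None, :], xs[:, None, None, :], bg[None, None, :, :]
            )
            p = np.asarray(fn(hybrids.reshape(-1, m)), dtype=float)
            v = p.reshape(len(xs), n_perm, m + 1, nb).mean(axis=3)
            contrib = np.diff(v, axis=2)  # (n_chunk, P, m) in permutation order
            scattered = np.zeros_like(contrib)
            np.put_along_axis(scattered, perms[start:stop], contrib, axis=2)
            phi[start:stop] += scattered.sum(axis=1)
    phi /= n_perm * len(fns)
    phi0 /= len(fns)
    preds /= len(fns)
    return ShapExplanation(phi0=phi0, phi=phi, predictions=preds)


@dataclass
class ImportanceProfile:
    """Per-feature class-contrast importance for one kinase family.

    ``scores[j]`` is the mean Shapley value of feature j over active
    compounds minus the mean over inactive compounds; ``z_scores``
    standardize the scores across the feature axis.
    """

    family: str
    feature_ids: list[str]
    scores: np.ndarray
    z_scores: np.ndarray
    n_active: int
    n_inactive: int
    selected: list[str] = field(default_factory=list)


def importance_scores(
    expl: ShapExplanation,
    labels: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    family: str = "",
) -> ImportanceProfile:
    """Contrast mean attributions between active and inactive compounds."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if labels.shape[0] != expl.phi.shape[0]:
        raise ValueError("labels length does not match the attribution matrix")
    act = labels == 1
    if not act.any() or act.all():
        raise ValueError("both classes must be present to contrast attributions")
    scores = expl.phi[act].mean(axis=0) - expl.phi[~act].mean(axis=0)
    sd = scores.std()
    if sd == 0.0:
        z = np.full_like(scores, np.nan)
    else:
        z = (scores - scores.mean()) / sd
    if feature_ids is None:
        feature_ids = [f"f-{j + 1}" for j in range(scores.size)]
    return ImportanceProfile(
        family=family,
        feature_ids=list(feature_ids),
        scores=scores,
        z_scores=z,
        n_active=int(act.sum()),
        n_inactive=int((~act).sum()),
    )


def select_top_features(
    profile: ImportanceProfile,
    z_threshold: float = 1.96,
    top_k: int = 15,
) -> list[str]:
    """Features with z above threshold, ranked by score, capped at top_k.

    Ties in score break deterministically by feature id.  The selection is
    stored on the profile and returned.
    """
    if np.isnan(profile.z_scores).all():
        raise ValueError(
            f"importance scores for family {profile.family!r} have zero variance; "
            "z-scores are undefined"
        )
    passing = [
        (profile.scores[j], profile.feature_ids[j])
        for j in range(len(profile.feature_ids))
        if profile.z_scores[j] > z_threshold
    ]
    passing.sort(key=lambda t: (-t[0], t[1]))
    selected = [fid for _, fid in passing[:top_k]]
    profile.selected = selected
    return selected
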