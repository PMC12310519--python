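"""Inference-quality diagnostics.

Posterior shrinkage and z-score quantify, per parameter, how much an
inferred posterior learned from the data and how far its mean sits from the
ground truth.  Simulation-based calibration (SBC) checks the *distributional*
correctness of an inference procedure: ranks of ground-truth parameters
within their own posteriors must be uniform, tested here with one-sample
Kolmogorov-Smirnov statistics.  The classifier two-sample test (C2ST)
measures distinguishability of two sample sets as cross-validated classifier
accuracy (0.5 = indistinguishable).  The posterior dispersion index (PDI) is
a repo-local normalization of posterior spread: posterior standard deviation
divided by the prior interval width (1/sqrt(12) ~ 0.289 when the posterior
equals the uniform prior).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import kstest
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .inference import BatchResult, N_PARAMS, PosteriorSamples, PriorBox, sample_prior

__all__ = [
    "SBCResult",
    "C2STResult",
    "shrinkage",
    "posterior_zscore",
    "run_sbc",
    "c2st",
    "pdi",
]


def shrinkage(prior_var: np.ndarray, post_var: np.ndarray) -> np.ndarray:
    """Posterior shrinkage ``s = 1 - sigma^2_post / sigma^2_prior``.

    0 when the posterior is as wide as the prior (nothing learned), 1 for a
    point mass.  For a uniform prior on [a, b] use variance (b - a)^2 / 12.
    """
    prior_var = np.asarray(prior_var, dtype=float)
    post_var = np.asarray(post_var, dtype=float)
    if np.any(prior_var <= 0):
        raise ValueError("prior variance must be positive")
    if np.any(post_var < 0):
        raise ValueError("posterior variance must be non-negative")
    return 1.0 - post_var / prior_var


def posterior_zscore(
    mu_post: np.ndarray, sigma_post: np.ndarray, theta_true: np.ndarray
) -> np.ndarray:
    """Absolute posterior z-score ``|mu_post - theta_true| / sigma_post``."""
    sigma_post = np.asarray(sigma_post, dtype=float)
    if np.any(sigma_post <= 0):
        raise ValueError("posterior standard deviation must be positive")
    return np.abs((np.asarray(mu_post, dtype=float) - np.asarray(theta_true, dtype=float)) / sigma_post)


@dataclass
class SBCResult:
    """Rank statistics of ground-truth parameters within their posteriors."""

    ranks: np.ndarray  # (M, 7) integers in [0, L]
    M: int
    L: int
    ks_stats: np.ndarray  # per parameter
    p_values: np.ndarray  # per parameter
    n_failed: int = 0


def run_sbc(
    prior: PriorBox,
    simulator: Callable[[np.ndarray, int | np.random.Generator], BatchResult],
    infer_fn: Callable[[np.ndarray, int], np.ndarray],
    M: int = 100,
    L: int = 100,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> SBCResult:
    """Simulation-based calibration of an inference procedure.

    For each of ``M`` prior draws theta: simulate an observation, call
    ``infer_fn(observation_summary, seed) -> (>=L, 7) posterior draws``, and
    record the rank of theta among the first ``L`` draws per parameter.  A
    calibrated procedure yields uniform ranks; uniformity is tested per
    parameter with a one-sample KS test of ``(rank + 0.5) / (L + 1)`` against
    U(0, 1).
    """
    if M < 50 or L < 50:
        raise ValueError("need M >= 50 and L >= 50 for a meaningful KS test")
    rng = np.random.default_rng(seed)
    thetas = sample_prior(prior, M, rng)
    ranks = []
    kept_thetas = []
    n_failed = 0
    for i, theta in enumerate(thetas):
        try:
            batch = simulator(theta[None, :], rng)
            if len(batch.summaries) == 0:
                raise RuntimeError("simulation failed")
            draws = np.asarray(infer_fn(batch.summaries[0], seed + i))[:L]
            if draws.shape != (L, N_PARAMS):
                raise RuntimeError(f"infer_fn returned shape {draws.shape}")
        except (RuntimeError, np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        ranks.append((draws < theta[None, :]).sum(axis=0))
        kept_thetas.append(theta)
    if n_failed > max_failure_rate * M:
        raise RuntimeError(f"inference failed on {n_failed}/{M} SBC draws (> {max_failure_rate:.0%})")
    rank_arr = np.array(ranks, dtype=int)
    # Continuity correction maps the discrete ranks into (0, 1).
    u = (rank_arr + 0.5) / (L + 1.0)
    ks = [kstest(u[:, j], "uniform") for j in range(N_PARAMS)]
    return SBCResult(
        ranks=rank_arr,
        M=len(rank_arr),
        L=L,
        ks_stats=np.array([k.statistic for k in ks]),
        p_values=np.array([k.pvalue for k in ks]),
        n_failed=n_failed,
    )


@dataclass
class C2STResult:
    """Cross-validated classifier two-sample test accuracy."""

    accuracy: float
    fold_sd: float
    fold_accuracies: np.ndarray

    def __float__(self) -> float:
        return self.accuracy


def c2st(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
) -> C2STResult:
    """Classifier two-sample test between two sample sets.

    A small feed-forward classifier is trained to distinguish the sets on
    standardized features; the statistic is its ``n_folds``-fold
    cross-validated accuracy.  0.5 means the sets are indistinguishable,
    1.0 perfectly separable.  The larger set is subsampled to equal counts.
    """
    a = np.atleast_2d(np.asarray(samples_a, dtype=float))
    b = np.atleast_2d(np.asarray(samples_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("sample sets must share dimensionality")
    m = min(len(a), len(b))
    if m < 100:
        raise ValueError(f"need at least 100 samples per set, got {m}")
    rng = np.random.default_rng(seed)
    a = a[rng.choice(len(a), m, replace=False)]
    b = b[rng.choice(len(b), m, replace=False)]
    x = np.vstack([a, b])
    y = np.concatenate([np.zeros(m), np.ones(m)])
    clf = make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=(10 * x.shape[1],),
            max_iter=300,
            random_state=seed,
        ),
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        scores = cross_val_score(clf, x, y, cv=cv, scoring="accuracy")
    return C2STResult(
        accuracy=float(scores.mean()),
        fold_sd=float(scores.std()),
        fold_accuracies=scores,
    )


def pdi(samples: PosteriorSamples | np.ndarray, prior: PriorBox) -> np.ndarray:
    """Posterior dispersion index: posterior SD / prior interval width.

    A repo-local definition: 0 for a point mass, 1/sqrt(12) ~ 0.289 when the
    posterior equals the uniform prior.  Invariant to affine
    reparameterization of any single parameter (both SD and width rescale).
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if len(draws) < 100:
        raise ValueError("need >= 100 posterior draws")
    return draws.std(axis=0) / prior.width
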