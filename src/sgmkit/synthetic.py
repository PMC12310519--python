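"""Synthetic inputs: geometric connectomes, noisy spectra, age-structured cohorts.

Everything the pipeline consumes can be generated here without downloads.
The connectome generator emulates the gross geometry of a template structural
connectome: regions scattered in a brain-sized sphere, connection weights
decaying exponentially with Euclidean distance (with log-normal jitter),
thresholded to a target density and guaranteed connected.  The cohort
generator plants known developmental trajectories — parameters drifting
linearly in log10 age with between-subject jitter — so that the end-to-end
recovery suite has ground truth: rising long-range coupling and conduction
speed, falling excitatory gain, rising inhibitory gain, and shortening
neural time constants, all inside the physiological box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .connectome import Connectome
from .forward import (
    LOWER_BOUNDS,
    PARAM_NAMES,
    UPPER_BOUNDS,
    FrequencyGrid,
    SGMParameters,
    network_response,
)

__all__ = [
    "TrajectorySpec",
    "SyntheticCohort",
    "make_connectome",
    "make_cohort",
    "add_observation_noise",
    "default_trajectory",
]


def make_connectome(
    n_regions: int,
    seed: int = 0,
    density: float = 0.3,
    length_scale_mm: float = 60.0,
    sphere_diameter_mm: float = 140.0,
) -> Connectome:
    """Random geometric connectome inside a brain-sized sphere.

    ``n_regions`` points are placed uniformly in a sphere of the given
    diameter; distances are Euclidean (mm); weights decay as
    ``exp(-d / length_scale)`` with multiplicative log-normal jitter, are
    thresholded to the target edge density, symmetrized, and zero on the
    diagonal.  Connectivity is guaranteed by re-adding edges along a random
    spanning order when thresholding disconnects the graph.
    """
    if n_regions < 4:
        raise ValueError("need at least 4 regions")
    rng = np.random.default_rng(seed)
    radius = sphere_diameter_mm / 2.0
    # Uniform in the ball: direction times radius * U^(1/3).
    vec = rng.normal(size=(n_regions, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    pts = vec * radius * rng.uniform(0.0, 1.0, size=(n_regions, 1)) ** (1.0 / 3.0)
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(dist, 0.0)

    jitter = rng.lognormal(mean=0.0, sigma=0.4, size=(n_regions, n_regions))
    jitter = np.sqrt(jitter * jitter.T)  # symmetric jitter
    weights = np.exp(-dist / length_scale_mm) * jitter
    np.fill_diagonal(weights, 0.0)

    # Keep the strongest `density` fraction of off-diagonal pairs.
    iu = np.triu_indices(n_regions, k=1)
    vals = weights[iu]
    n_keep = max(int(round(density * vals.size)), n_regions - 1)
    thresh = np.sort(vals)[::-1][n_keep - 1]
    mask = np.zeros_like(weights, dtype=bool)
    mask[iu] = vals >= thresh
    mask |= mask.T
    weights = np.where(mask, weights, 0.0)

    # Guarantee connectivity along a random spanning order.
    n_comp, _ = connected_components(csr_matrix(weights > 0), directed=False)
    if n_comp > 1:
        order = rng.permutation(n_regions)
        for a, b in zip(order[:-1], order[1:]):
            if weights[a, b] == 0:
                w = np.exp(-dist[a, b] / length_scale_mm)
                weights[a, b] = weights[b, a] = w

    labels = [f"region_{i:03d}" for i in range(n_regions)]
    return Connectome(labels=labels, weights=weights, distances=dist)


def add_observation_noise(
    psd: np.ndarray, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Multiplicative log-normal observation noise, independent per bin.

    Each bin is multiplied by ``exp(eps)`` with ``eps ~ N(0, sigma^2)``, so
    the output stays strictly positive and the expected *log* power equals
    the noiseless log power.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    psd = np.asarray(psd, dtype=float)
    if np.any(psd <= 0):
        raise ValueError("psd must be strictly positive")
    if sigma == 0:
        return psd.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return psd * np.exp(rng.normal(0.0, sigma, size=psd.shape))


@dataclass(frozen=True)
class TrajectorySpec:
    """Planted developmental trajectories of the seven model parameters.

    For each parameter: value at age 1 year (``intercept``), drift per decade
    of log10 age (``slope``) and between-subject jitter SD (``subject_sd``).
    Subject values are clipped to stay a 2%-of-range margin inside the
    physiological bounds.
    """

    intercepts: dict[str, float]
    slopes: dict[str, float]
    subject_sds: dict[str, float]
    clip_margin: float = 0.02

    def theta_for_ages(self, ages_years: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        log_age = np.log10(np.asarray(ages_years, dtype=float))
        n = log_age.size
        theta = np.empty((n, len(PARAM_NAMES)))
        margin = self.clip_margin * (UPPER_BOUNDS - LOWER_BOUNDS)
        for j, name in enumerate(PARAM_NAMES):
            vals = (
                self.intercepts[name]
                + self.slopes[name] * log_age
                + rng.normal(0.0, self.subject_sds[name], size=n)
            )
            theta[:, j] = np.clip(vals, LOWER_BOUNDS[j] + margin[j], UPPER_BOUNDS[j] - margin[j])
        return theta


def default_trajectory() -> TrajectorySpec:
    """Default planted trends over a 1-day-to-30-years cohort.

    Long-range coupling and conduction speed rise with age, excitatory gain
    falls (so the excitatory:inhibitory ratio declines), inhibitory gain
    rises, both neural time constants shorten, and the graph time constant is
    age-flat.  Magnitudes are chosen so every trajectory stays strictly
    inside the physiological box over the full age range.
    """
    return TrajectorySpec(
        intercepts={
            "tau_e": 0.018,
            "tau_i": 0.015,
            "alpha": 0.50,
            "speed": 7.0,
            "g_ei": 10.0,
            "g_ii": 10.0,
            "tau_g": 0.15,
        },
        slopes={
            "tau_e": -0.002,
            "tau_i": -0.002,
            "alpha": 0.10,
            "speed": 1.5,
            "g_ei": -1.5,
            "g_ii": 1.5,
            "tau_g": 0.0,
        },
        subject_sds={
            "tau_e": 0.001,
            "tau_i": 0.001,
            "alpha": 0.04,
            "speed": 0.5,
            "g_ei": 0.7,
            "g_ii": 0.7,
            "tau_g": 0.02,
        },
    )


@dataclass
class SyntheticCohort:
    """Age-structured cohort with full ground truth retained."""

    subject_ids: list[str]
    ages_years: np.ndarray
    true_theta: np.ndarray  # (n, 7)
    noiseless_psd: np.ndarray  # (n, F)
    observed_psd: np.ndarray  # (n, F)
    grid: FrequencyGrid
    connectome: Connectome
    spec: TrajectorySpec
    noise_sigma: float
    seed: int


def make_cohort(
    n_subjects: int,
    conn: Connectome,
    grid: FrequencyGrid,
    spec: TrajectorySpec | None = None,
    age_range: tuple[float, float] = (1.0 / 365.25, 30.0),
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a cohort of subjects with known parameter trajectories.

    Ages are log-uniform over ``age_range`` (so neonates are well
    represented); each subject's parameters follow the trajectory spec; their
    global SGM spectrum is simulated and observed under multiplicative
    log-normal noise of width ``noise_sigma``.
    """
    spec = spec or default_trajectory()
    rng = np.random.default_rng(seed)
    ages = 10 ** rng.uniform(np.log10(age_range[0]), np.log10(age_range[1]), size=n_subjects)
    theta = spec.theta_for_ages(ages, rng)

    margin = spec.clip_margin * (UPPER_BOUNDS - LOWER_BOUNDS)
    at_bound = np.any(
        (theta <= LOWER_BOUNDS + margin) | (theta >= UPPER_BOUNDS - margin), axis=1
    )
    if at_bound.mean() > 0.05:
        warnings.warn(
            f"{int(at_bound.sum())}/{n_subjects} subjects clipped at parameter bounds",
            stacklevel=2,
        )

    clean = np.empty((n_subjects, len(grid)))
    for i in range(n_subjects):
        clean[i] = network_response(conn, SGMParameters.from_array(theta[i]), grid).global_psd
    observed = add_observation_noise(clean, noise_sigma, rng) if noise_sigma else clean.copy()

    return SyntheticCohort(
        subject_ids=[f"sub_{i:04d}" for i in range(n_subjects)],
        ages_years=ages,
        true_theta=theta,
        noiseless_psd=clean,
        observed_psd=observed,
        grid=grid,
        connectome=conn,
        spec=spec,
        noise_sigma=noise_sigma,
        seed=seed,
    )
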