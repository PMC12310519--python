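"""Population-level statistics over per-subject parameter estimates.

Given per-subject posterior point estimates of the model parameters and the
subjects' ages, this module quantifies developmental trajectories: Pearson
correlations of each parameter against log10 age, cross-validated degree-2
polynomial regression for age (or spectral-feature) prediction, a
predicted-vs-observed regression convention for evaluating prediction bias,
Breusch-Pagan heteroskedasticity testing of the residuals, and
Jensen-Shannon spectral-divergence contrasts between coupling regimes and
connectomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import chi2, pearsonr
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .connectome import Connectome
from .features import normalize_to_distribution
from .forward import FrequencyGrid, SGMParameters, network_response
from .inference import PriorBox, sample_prior

__all__ = [
    "CohortTable",
    "age_correlation",
    "cv_regression",
    "CVRegressionResult",
    "predicted_vs_observed",
    "breusch_pagan",
    "jsh_divergence",
    "regime_contrast",
    "RegimeContrast",
]


@dataclass
class CohortTable:
    """One row per subject: id, age in years, parameter estimates, features.

    Ages must be strictly positive (a one-day-old is 1/365.25 years) and ids
    unique — each subject contributes a single EEG measurement.
    """

    df: pd.DataFrame
    id_column: str = "subject_id"
    age_column: str = "age_years"

    def __post_init__(self) -> None:
        df = self.df
        for col in (self.id_column, self.age_column):
            if col not in df.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        if df[self.id_column].duplicated().any():
            dup = df[self.id_column][df[self.id_column].duplicated()].iloc[0]
            raise ValueError(f"duplicated subject id {dup!r}")
        if (df[self.age_column] <= 0).any():
            raise ValueError("ages must be strictly positive (years)")
        self.df = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def log_age(self) -> np.ndarray:
        return np.log10(self.df[self.age_column].to_numpy(dtype=float))


def age_correlation(cohort: CohortTable, column: str) -> tuple[float, float, int]:
    """Pearson correlation of a cohort column against log10 age (years).

    Returns ``(r, two-sided p, n)``.
    """
    if cohort.n < 10:
        raise ValueError("need at least 10 subjects")
    y = cohort.df[column].to_numpy(dtype=float)
    x = cohort.log_age
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in age or column")
    r, p = pearsonr(x, y)
    return float(r), float(p), cohort.n


def _poly_design(x: np.ndarray, degree: int, interactions: bool) -> np.ndarray:
    """Per-feature polynomial expansion; pairwise products only on request."""
    cols = [x**d for d in range(1, degree + 1)]
    if interactions and x.shape[1] > 1:
        n_feat = x.shape[1]
        for i in range(n_feat):
            for j in range(i + 1, n_feat):
                cols.append((x[:, i] * x[:, j])[:, None])
    return np.hstack(cols)


@dataclass
class CVRegressionResult:
    adj_r2: float
    r2: float
    mse: float
    predictions: pd.DataFrame  # per subject: observed, predicted (model scale and natural scale)
    n_features: int
    target_transform: str | None


def cv_regression(
    cohort: CohortTable,
    feature_columns: list[str],
    target_column: str,
    degree: int = 2,
    k: int = 10,
    seed: int = 0,
    interactions: bool = False,
    target_transform: str | None = "auto",
) -> CVRegressionResult:
    """k-fold cross-validated polynomial regression of a cohort target.

    A degree-``degree`` per-feature polynomial expansion (no cross-feature
    interaction terms unless ``interactions=True``) is fitted by ordinary
    least squares inside each training fold; out-of-fold predictions are
    pooled and scored.  When the target is an age column (or
    ``target_transform="log10"``), the model operates on log10 years and the
    natural-scale predictions are reported alongside.  Adjusted R^2 is
    ``1 - (1 - R^2)(n - 1)/(n - p - 1)`` with ``p`` expanded features.
    """
    n = cohort.n
    if n < 3 * k:
        raise ValueError(f"need n >= 3k subjects (n={n}, k={k})")
    x = cohort.df[feature_columns].to_numpy(dtype=float)
    y_raw = cohort.df[target_column].to_numpy(dtype=float)
    if target_transform == "auto":
        target_transform = "log10" if target_column == cohort.age_column else None
    if target_transform == "log10":
        if np.any(y_raw <= 0):
            raise ValueError("log10 target requires positive values")
        y = np.log10(y_raw)
    elif target_transform is None:
        y = y_raw.copy()
    else:
        raise ValueError(f"unknown target transform {target_transform!r}")

    design = _poly_design(x, degree, interactions)
    p = design.shape[1]
    if n - p - 1 <= 0:
        raise ValueError("too many expanded features for the sample size")

    oof = np.full(n, np.nan)
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in cv.split(design):
        model = LinearRegression().fit(design[train_idx], y[train_idx])
        oof[test_idx] = model.predict(design[test_idx])
    ss_res = float(np.sum((y - oof) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in the regression target")
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    mse = ss_res / n

    pred_df = pd.DataFrame(
        {
            cohort.id_column: cohort.df[cohort.id_column],
            "observed": y,
            "predicted": oof,
        }
    )
    if target_transform == "log10":
        pred_df["observed_natural"] = y_raw
        pred_df["predicted_natural"] = 10.0**oof
    return CVRegressionResult(
        adj_r2=adj_r2,
        r2=r2,
        mse=mse,
        predictions=pred_df,
        n_features=p,
        target_transform=target_transform,
    )


def predicted_vs_observed(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float, float]:
    """OLS of observed (y) on predicted (x): returns (slope, intercept, R^2).

    With this axis convention an unbiased predictor gives slope 1 and
    intercept 0.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if np.std(pred) == 0:
        raise ValueError("zero variance in predictions")
    slope, intercept = np.polyfit(pred, obs, 1)
    resid = obs - (slope * pred + intercept)
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / float(ss_tot) if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def breusch_pagan(residuals: np.ndarray, design: np.ndarray) -> tuple[float, float]:
    """Breusch-Pagan Lagrange-multiplier test for heteroskedasticity.

    Squared residuals are regressed on the (constant-augmented) design; the
    statistic is ``LM = n R^2_aux`` with a chi-squared null on as many
    degrees of freedom as there are predictors.  Returns ``(LM, p)``.
    """
    residuals = np.asarray(residuals, dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != residuals.shape[0]:
        design = design.T
    n, n_pred = design.shape
    if n != residuals.shape[0] or n <= n_pred + 1:
        raise ValueError("degenerate design for Breusch-Pagan test")
    z = np.column_stack([np.ones(n), design])
    u2 = residuals**2
    coef, *_ = np.linalg.lstsq(z, u2, rcond=None)
    fitted = z @ coef
    ss_tot = float(np.sum((u2 - u2.mean()) ** 2))
    if ss_tot == 0:  # constant residuals: no heteroskedasticity signal at all
        return 0.0, 1.0
    r2_aux = 1.0 - float(np.sum((u2 - fitted) ** 2)) / ss_tot
    lm = n * r2_aux
    return float(lm), float(chi2.sf(lm, df=n_pred))


def jsh_divergence(p: np.ndarray, q: np.ndarray, tol: float = 1e-6) -> float:
    """Base-2 Jensen-Shannon divergence between two probability vectors.

    0 iff the distributions coincide, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > tol:
            raise ValueError(f"{name} is not normalized (sum = {v.sum():.8f})")
    d = float(jensenshannon(p, q, base=2.0) ** 2)
    return min(max(d, 0.0), 1.0)


@dataclass
class RegimeContrast:
    """Spectral-divergence contrast of coupling regimes vs connectome choice."""

    jsh_alpha: float  # weak-vs-strong alpha divergence, averaged over connectomes
    jsh_connectome: float  # connectome-A-vs-B divergence, averaged over regimes
    difference: float  # jsh_alpha - jsh_connectome
    p_value: float  # permutation p for difference > 0
    jsh_alpha_per_connectome: tuple[float, float]
    jsh_connectome_per_regime: tuple[float, float]
    n_draws: int
    n_permutations: int


def _mean_distribution(spectra: np.ndarray) -> np.ndarray:
    return normalize_to_distribution(spectra.mean(axis=0))


def _contrast_stat(spectra: np.ndarray, conn_lab: np.ndarray, reg_lab: np.ndarray):
    means = {
        (c, r): _mean_distribution(spectra[(conn_lab == c) & (reg_lab == r)])
        for c in (0, 1)
        for r in (0, 1)
    }
    jsh_a = tuple(jsh_divergence(means[(c, 0)], means[(c, 1)]) for c in (0, 1))
    jsh_c = tuple(jsh_divergence(means[(0, r)], means[(1, r)]) for r in (0, 1))
    return jsh_a, jsh_c, float(np.mean(jsh_a) - np.mean(jsh_c))


def regime_contrast(
    conn_a: Connectome,
    conn_b: Connectome,
    grid: FrequencyGrid | None = None,
    n_draws: int = 1000,
    weak: tuple[float, float] = (0.1, 0.3),
    strong: tuple[float, float] = (0.7, 0.9),
    seed: int = 0,
    n_permutations: int = 1000,
    prior: PriorBox | None = None,
) -> RegimeContrast:
    """Contrast the spectral effect of coupling strength against connectome choice.

    For each coupling regime, ``n_draws`` parameter sets are drawn from the
    physiological prior with the long-range coupling restricted to the regime
    band, and the *same* draws are simulated on both connectomes (a paired
    design, so an identical-connectome contrast is exactly zero).  The mean
    global spectra per connectome-regime cell are normalized to distributions
    and compared with Jensen-Shannon divergence.  The reported statistic is
    (regime effect) - (connectome effect); its permutation p-value shuffles
    the regime and connectome labels jointly across all realizations.
    """
    grid = grid or FrequencyGrid.default()
    prior = prior or PriorBox.default()
    rng = np.random.default_rng(seed)

    spectra = []
    conn_lab = []
    reg_lab = []
    for ri, band in enumerate((weak, strong)):
        thetas = sample_prior(prior, n_draws, rng)
        thetas[:, 2] = rng.uniform(band[0], band[1], n_draws)
        for ci, conn in enumerate((conn_a, conn_b)):
            for t in thetas:
                g = network_response(conn, SGMParameters.from_array(t), grid).global_psd
                spectra.append(normalize_to_distribution(g))
                conn_lab.append(ci)
                reg_lab.append(ri)
    spectra = np.array(spectra)
    conn_lab = np.array(conn_lab)
    reg_lab = np.array(reg_lab)

    jsh_a, jsh_c, diff = _contrast_stat(spectra, conn_lab, reg_lab)

    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(spectra))
        _, _, d = _contrast_stat(spectra, conn_lab[perm], reg_lab[perm])
        if d >= diff:
            count += 1
    p = (1 + count) / (1 + n_permutations)

    return RegimeContrast(
        jsh_alpha=float(np.mean(jsh_a)),
        jsh_connectome=float(np.mean(jsh_c)),
        difference=diff,
        p_value=p,
        jsh_alpha_per_connectome=jsh_a,
        jsh_connectome_per_regime=jsh_c,
        n_draws=n_draws,
        n_permutations=n_permutations,
    )
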