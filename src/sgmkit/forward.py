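"""Closed-form spectral graph model (SGM) of whole-brain spectra.

The SGM is a linear, Fourier-domain model of macroscopic neural activity on a
structural connectome.  Local excitatory-inhibitory dynamics in each region
are summarized by gamma-shaped transfer functions; long-range propagation is
governed by a *complex* graph Laplacian whose phase factors encode axonal
conduction delays.  For a structural weight matrix ``C`` with degree vector
``deg`` and inter-region delays ``tau_jk = d_jk / speed`` the model is

    C(w)  = diag(1/deg) . [ c_jk exp(-i w tau_jk) ]
    L(w)  = I - alpha C(w)
    X(w)  = ( i w I + F(w)/tau_G . L(w) )^-1  H_local(w) P(w)

with gamma filter ``F(w) = (1/tau^2) / (i w + 1/tau)^2`` evaluated at the
graph time constant ``tau_G``, a spatially homogeneous local transfer
``H_local(w)`` and white driving noise ``P(w)``.  Writing
``T(w) = (i w I + F(w)/tau_G . L(w))^-1 H_local(w)`` for the network transfer
matrix, the driving noise is *uncorrelated* across regions, so the modelled
power spectrum is the diagonal of the output spectral density
``T(w) T(w)^H``: ``psd_j(w) = sum_k |T_jk(w)|^2``.  The complex response
``x = T(w) p`` to a deterministic drive vector ``p`` (default all ones) is
also exposed; it is the quantity the closed-form limit checks and the
direct-vs-eigenmode oracle operate on, in addition to the PSD itself.

Seven parameters control the model: local excitatory/inhibitory time
constants ``tau_e, tau_i`` (s), global coupling ``alpha``, conduction speed
``S`` (m/s), excitatory/inhibitory gains ``G_EI, G_II`` and the graph time
constant ``tau_G`` (s).  Their admissible bounds are the physiological box
used throughout this package (see ``PARAM_BOUNDS``).

Two equivalent evaluation routes are provided: a per-frequency linear solve
(``method="direct"``) and an eigenmode expansion over the Laplacian spectrum
(``method="eigen"``).  The direct solve is the ground truth; the modal route
must match it to numerical precision, which is enforced in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .connectome import Connectome, degree_vector

__all__ = [
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "LOWER_BOUNDS",
    "UPPER_BOUNDS",
    "SGMParameters",
    "FrequencyGrid",
    "SpectralResponse",
    "complex_connectivity",
    "complex_laplacian",
    "gamma_filter",
    "local_transfer",
    "network_response",
    "global_psd_db",
]

#: Canonical parameter order used by every array interface in the package.
PARAM_NAMES: tuple[str, ...] = ("tau_e", "tau_i", "alpha", "speed", "g_ei", "g_ii", "tau_g")

#: Physiological bounds per parameter (lower, upper), canonical order.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_e": (0.001, 0.03),
    "tau_i": (0.001, 0.03),
    "alpha": (0.01, 1.0),
    "speed": (0.5, 15.0),
    "g_ei": (1.0, 20.0),
    "g_ii": (1.0, 20.0),
    "tau_g": (0.01, 0.3),
}

LOWER_BOUNDS = np.array([PARAM_BOUNDS[p][0] for p in PARAM_NAMES])
UPPER_BOUNDS = np.array([PARAM_BOUNDS[p][1] for p in PARAM_NAMES])


@dataclass(frozen=True)
class SGMParameters:
    """The seven-parameter vector of the spectral graph model.

    All units: time constants in seconds, conduction speed in m/s, coupling
    and gains dimensionless.  In ``bounded`` mode (the default) construction
    rejects values outside the physiological box; unbounded mode still
    requires strict positivity.
    """

    tau_e: float
    tau_i: float
    alpha: float
    speed: float
    g_ei: float
    g_ii: float
    tau_g: float
    bounded: bool = True

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and strictly positive, got {v}")
            if self.bounded:
                lo, hi = PARAM_BOUNDS[name]
                if not (lo <= v <= hi):
                    raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray, bounded: bool = True) -> "SGMParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (7,):
            raise ValueError(f"expected a length-7 parameter vector, got shape {theta.shape}")
        return cls(*theta.tolist(), bounded=bounded)

    @classmethod
    def midpoint(cls) -> "SGMParameters":
        """Midpoint of the physiological box."""
        return cls.from_array((LOWER_BOUNDS + UPPER_BOUNDS) / 2.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly positive, strictly increasing evaluation frequencies (Hz)."""

    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("frequency grid must be a 1-D array of length >= 2")
        if f[0] <= 0:
            raise ValueError("minimum frequency must be > 0 (the response is evaluated off omega = 0)")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs_hz", f)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies ``2 pi f`` in rad/s."""
        return 2.0 * np.pi * self.freqs_hz

    def __len__(self) -> int:
        return self.freqs_hz.size

    @classmethod
    def default(cls, fmin: float = 0.5, fmax: float = 50.0, n_bins: int = 100) -> "FrequencyGrid":
        """100 linearly spaced bins over 0.5-50 Hz (avoids the omega=0 singularity)."""
        return cls(np.linspace(fmin, fmax, n_bins))


@dataclass(frozen=True)
class SpectralResponse:
    """Model output on a frequency grid.

    ``psd`` is the regional power under independent unit-variance white noise
    driving every region (the diagonal of ``T T^H`` for the network transfer
    matrix ``T``); ``global_psd`` is its mean across regions.  ``x`` is the
    complex response ``T p`` to the deterministic drive vector passed to
    :func:`network_response` (all ones by default) and is used by the
    analytic-limit and linearity checks.
    """

    x: np.ndarray  # (n_regions, n_freqs) complex, response to the drive vector
    psd: np.ndarray  # (n_regions, n_freqs) power under uncorrelated white drive
    global_psd: np.ndarray  # region mean of psd
    grid: FrequencyGrid
    params: SGMParameters


def gamma_filter(omega: float | np.ndarray, tau: float) -> complex | np.ndarray:
    """Gamma-shaped linear filter ``F(w) = (1/tau^2) / (i w + 1/tau)^2``.

    Its magnitude is ``1 / (1 + (w tau)^2)``: unity at DC, monotonically
    decreasing with frequency.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    omega = np.asarray(omega, dtype=float)
    out = (1.0 / tau**2) / (1j * omega + 1.0 / tau) ** 2
    return out if out.ndim else complex(out)


def delay_matrix(conn: Connectome, speed: float) -> np.ndarray:
    """Conduction delays in seconds: distances (mm) * 1e-3 / speed (m/s).

    This is the single place where the mm -> s unit conversion happens.
    """
    if speed <= 0:
        raise ValueError(f"conduction speed must be positive, got {speed}")
    return conn.distances * 1e-3 / speed


def complex_connectivity(conn: Connectome, omega: float, speed: float) -> np.ndarray:
    """Degree-normalized complex connectivity ``C(w)`` at one angular frequency.

    ``C(w) = diag(1/deg) [ c_jk exp(-i w tau_jk) ]`` with delays from
    :func:`delay_matrix`.  At ``omega = 0`` this reduces to the row-normalized
    weight matrix.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    tau = delay_matrix(conn, speed)
    deg = degree_vector(conn).deg
    return (conn.weights * np.exp(-1j * omega * tau)) / deg[:, None]


def complex_laplacian(c_omega: np.ndarray, alpha: float) -> np.ndarray:
    """Complex graph Laplacian ``L(w) = I - alpha C(w)``."""
    c_omega = np.asarray(c_omega)
    if c_omega.ndim != 2 or c_omega.shape[0] != c_omega.shape[1]:
        raise ValueError("C(omega) must be square")
    return np.eye(c_omega.shape[0]) - alpha * c_omega


def local_transfer(
    grid: FrequencyGrid, params: SGMParameters, g_ee: float = 1.0
) -> np.ndarray:
    """Spatially homogeneous local excitatory-inhibitory transfer ``H_local(w)``.

    Two gamma filters ``F_e(w; tau_e)`` and ``F_i(w; tau_i)`` are coupled in a
    feedback loop: ``G_EI`` is the excitatory-inhibitory loop gain, ``G_II``
    the inhibitory self-gain, and the excitatory self-gain is fixed at 1.
    The returned vector (one value per grid frequency) is the sum of the
    excitatory and inhibitory population transfer functions of that loop.

    The algebraic form is pluggable: :func:`network_response` accepts any
    callable with this signature, and every downstream contract (finite,
    nonzero on the grid for bounded parameters) is checked here.
    """
    w = grid.omega
    te, ti = params.tau_e, params.tau_i
    gei, gii = params.g_ei, params.g_ii
    fe = gamma_filter(w, te)
    fi = gamma_filter(w, ti)

    cross_e = 1.0 + (fe * fi * gei) / (te * (1j * w + fi * gii / ti))
    h_e = cross_e / (1j * w + (fe * g_ee / te) * cross_e)
    cross_i = 1.0 - (fe * fi * gei) / (ti * (1j * w + fe * g_ee / te))
    h_i = cross_i / (1j * w + (fi * gii / ti) * cross_i)
    h = h_e + h_i

    if not np.all(np.isfinite(h)) or np.any(h == 0):
        raise FloatingPointError(
            f"H_local is non-finite or zero on the grid for parameters {params.to_array()}"
        )
    return h


def _batched_laplacian(conn: Connectome, params: SGMParameters, grid: FrequencyGrid) -> np.ndarray:
    """Stack of ``L(w)`` over the whole grid, shape (F, n, n)."""
    tau = delay_matrix(conn, params.speed)
    deg = degree_vector(conn).deg
    phases = np.exp(-1j * grid.omega[:, None, None] * tau[None, :, :])
    c_w = (conn.weights[None, :, :] * phases) / deg[None, :, None]
    return np.eye(conn.n)[None, :, :] - params.alpha * c_w


def network_response(
    conn: Connectome,
    params: SGMParameters,
    grid: FrequencyGrid,
    method: str = "direct",
    drive: np.ndarray | None = None,
    local_model: Callable[[FrequencyGrid, SGMParameters], np.ndarray] = local_transfer,
) -> SpectralResponse:
    """Evaluate the SGM network frequency response on a grid.

    Parameters
    ----------
    method : {"direct", "eigen"}
        ``direct`` inverts ``(i w I + F(w)/tau_G L(w))`` by a batched solve
        per frequency.  ``eigen`` expands the same operator over the
        eigenmodes ``L(w) = U diag(lambda) U^-1``:
        ``T = sum_i u_i u~_i H_local / (i w + lambda_i F(w)/tau_G)`` with
        ``u~_i`` the rows of ``U^-1``.  Both routes agree to numerical
        precision on ``x`` and ``psd``; direct is the oracle.
    drive : (n,) array, optional
        Deterministic drive vector for the ``x`` output; defaults to all
        ones.  ``x`` is linear in this vector.  The PSD models uncorrelated
        unit white noise in every region and does not depend on ``drive``.
    local_model : callable, optional
        Alternative local transfer implementation with the
        :func:`local_transfer` signature.
    """
    n, n_f = conn.n, len(grid)
    p_vec = np.ones(n) if drive is None else np.asarray(drive, dtype=float)
    if p_vec.shape != (n,):
        raise ValueError(f"drive must have shape ({n},)")
    h_local = local_model(grid, params)
    f_g = gamma_filter(grid.omega, params.tau_g) / params.tau_g  # (F,)
    lap = _batched_laplacian(conn, params, grid)  # (F, n, n)
    i_w = 1j * grid.omega  # (F,)

    if method == "direct":
        a = i_w[:, None, None] * np.eye(n)[None, :, :] + f_g[:, None, None] * lap
        try:
            t_fw = np.linalg.inv(a) * h_local[:, None, None]  # (F, n, n) transfer matrix
        except np.linalg.LinAlgError as exc:
            for k in range(n_f):
                try:
                    np.linalg.inv(a[k])
                except np.linalg.LinAlgError:
                    raise np.linalg.LinAlgError(
                        f"singular SGM system at f = {grid.freqs_hz[k]:.3f} Hz "
                        f"for parameters {params.to_array()}"
                    ) from exc
            raise
    elif method == "eigen":
        try:
            lam, u = np.linalg.eig(lap)  # (F, n), (F, n, n)
            u_inv = np.linalg.inv(u)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"eigendecomposition failure for parameters {params.to_array()}"
            ) from exc
        denom = i_w[:, None] + f_g[:, None] * lam  # (F, n)
        t_fw = np.einsum("fij,fj,fjk->fik", u, h_local[:, None] / denom, u_inv)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'direct' or 'eigen'")

    if not np.all(np.isfinite(t_fw)):
        raise FloatingPointError(
            f"non-finite SGM response for parameters {params.to_array()}"
        )
    x = np.einsum("fij,j->if", t_fw, p_vec)  # (n, F) coherent response
    psd = (np.abs(t_fw) ** 2).sum(axis=2).T  # (n, F) incoherent-drive power
    return SpectralResponse(x=x, psd=psd, global_psd=psd.mean(axis=0), grid=grid, params=params)


def global_psd_db(resp: SpectralResponse) -> np.ndarray:
    """Global-mean PSD in decibels, ``10 log10`` of the region-mean power."""
    g = resp.global_psd
    if np.any(g <= 0):
        k = int(np.flatnonzero(g <= 0)[0])
        raise ValueError(f"non-positive global power at bin {k} (f = {resp.grid.freqs_hz[k]} Hz)")
    return 10.0 * np.log10(g)
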