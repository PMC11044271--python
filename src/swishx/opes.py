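"""OPES MultiThermal expanded-ensemble bias on the potential energy.

The bias makes a single run sample a multicanonical ensemble spanning a
temperature range [T_min, T_max].  With a grid of temperatures T_j (uniform
in inverse temperature beta_j) and expansion shifts

    du_j(U) = (beta_j - beta) * U ,

the bias at update n is

    V_n(U) = -(1/beta) * ln[ (1/N_T) * sum_j exp(-du_j(U) + beta_j * dF_n(T_j)) ]

and the free-energy differences are estimated iteratively from the biased
samples by self-normalized importance weighting,

    dF_n(T_j) = -(1/beta_j) * ln[ sum_k w_k exp(-du_j(U_k)) / sum_k w_k ],
    w_k = exp(+beta * V_{n-1}(U_k)) .

dF(T_j) converges to -(1/beta_j) * ln(Z(beta_j)/Z(beta)), the normalization
each expansion term needs; dF at T_j = T is identically zero.  All
exponentials go through log-sum-exp; accumulators live in log space.
k_B = 1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from . import _kernels

__all__ = [
    "ExpansionGrid",
    "make_temperature_grid",
    "delta_u",
    "OpesMultiThermal",
    "bias_energy",
    "bias_force_factor",
    "update_estimates",
    "reweight_observable",
    "run_opes_harmonic",
    "harmonic_delta_f",
]


@dataclass(frozen=True)
class ExpansionGrid:
    """Temperature grid of the expanded ensemble (uniform in beta)."""

    T: float
    T_min: float
    T_max: float
    temperatures: np.ndarray

    @property
    def betas(self) -> np.ndarray:
        return 1.0 / self.temperatures

    @property
    def beta(self) -> float:
        return 1.0 / self.T

    @property
    def n_T(self) -> int:
        return len(self.temperatures)


def make_temperature_grid(
    T: float,
    T_min: float,
    T_max: float,
    n_T: Union[int, str] = "auto",
    calibration_U: Optional[np.ndarray] = None,
    max_auto: int = 200,
) -> ExpansionGrid:
    """Build the expansion grid, uniform in beta with both endpoints included.

    ``n_T="auto"`` grows the grid until the canonical energy distributions of
    neighboring grid points overlap: |<U>_{j+1} - <U>_j| <= 2*sigma_U, with
    means and fluctuations estimated by reweighting a short unbiased
    calibration sample of U drawn at the thermostat temperature T.
    """
    if not (0 < T_min <= T_max):
        raise ValueError("require 0 < T_min <= T_max")
    if not (T_min <= T <= T_max):
        raise ValueError(f"thermostat T={T} outside [{T_min}, {T_max}]")
    if T_min == T_max:
        if n_T not in (1, "auto"):
            raise ValueError("degenerate range needs n_T = 1")
        return ExpansionGrid(T, T_min, T_max, np.array([T_min]))

    def uniform_beta(n: int) -> np.ndarray:
        betas = np.linspace(1.0 / T_max, 1.0 / T_min, n)
        return np.sort(1.0 / betas)

    if n_T == "auto":
        if calibration_U is None:
            raise ValueError("n_T='auto' requires calibration_U samples")
        U = np.asarray(calibration_U, dtype=float)
        beta = 1.0 / T
        for n in range(2, max_auto + 1):
            temps = uniform_beta(n)
            ok = True
            means = np.empty(n)
            sds = np.empty(n)
            for j, Tj in enumerate(temps):
                logw = -(1.0 / Tj - beta) * U
                logw -= logsumexp(logw)
                w = np.exp(logw)
                mu = float(np.sum(w * U))
                means[j] = mu
                sds[j] = float(np.sqrt(max(np.sum(w * (U - mu) ** 2), 1e-300)))
            for j in range(n - 1):
                if abs(means[j + 1] - means[j]) > 2.0 * min(sds[j], sds[j + 1]):
                    ok = False
                    break
            if ok:
                return ExpansionGrid(T, T_min, T_max, temps)
        raise RuntimeError("auto grid did not converge below max_auto points")

    n_T = int(n_T)
    if n_T < 1:
        raise ValueError("n_T must be >= 1")
    if n_T == 1:
        raise ValueError("n_T = 1 with T_min < T_max is ambiguous; pass the range as degenerate")
    return ExpansionGrid(T, T_min, T_max, uniform_beta(n_T))


def delta_u(U, j: int, grid: ExpansionGrid):
    """Expansion shift du_j(U) = (beta_j - beta) * U (dimensionless)."""
    if not (0 <= j < grid.n_T):
        raise IndexError("grid index out of range")
    return (grid.betas[j] - grid.beta) * np.asarray(U, dtype=float)


@dataclass
class OpesMultiThermal:
    """Running bias state: log-space weight accumulators and dF estimates.

    ``update_stride`` is bookkeeping for callers that refresh the estimates
    every so many engine steps; the bias is piecewise constant in between.
    """

    grid: ExpansionGrid
    update_stride: int = 500
    n_samples: int = 0
    n_updates: int = 0
    log_sum_w: float = -np.inf
    log_sum_w_expdu: np.ndarray = None
    deltaF: np.ndarray = None

    def __post_init__(self):
        if self.log_sum_w_expdu is None:
            self.log_sum_w_expdu = np.full(self.grid.n_T, -np.inf)
        if self.deltaF is None:
            self.deltaF = np.zeros(self.grid.n_T)

    # --- bias -------------------------------------------------------------
    def bias_energy(self, U: float) -> float:
        return bias_energy(U, self.grid, self)

    def bias_force_factor(self, U: float) -> float:
        return bias_force_factor(U, self.grid, self)

    @property
    def beta_j_deltaF(self) -> np.ndarray:
        """beta_j * dF_j, the array the kernels consume."""
        return self.grid.betas * self.deltaF

    # --- estimator --------------------------------------------------------
    def update(self, U_samples: np.ndarray, V_samples: np.ndarray) -> None:
        update_estimates(self, U_samples, V_samples)


def _log_terms(U: float, grid: ExpansionGrid, state: Optional[OpesMultiThermal]):
    if not np.isfinite(U):
        raise ValueError("non-finite potential energy")
    bj = grid.betas
    bjdF = np.zeros(grid.n_T) if state is None else bj * state.deltaF
    return -(bj - grid.beta) * U + bjdF


def bias_energy(U: float, grid: ExpansionGrid, state: Optional[OpesMultiThermal]) -> float:
    """V(U); identically zero for the single-member expansion at T_1 = T."""
    a = _log_terms(U, grid, state)
    return float(-(logsumexp(a) - np.log(grid.n_T)) / grid.beta)


def bias_force_factor(U: float, grid: ExpansionGrid, state: Optional[OpesMultiThermal]) -> float:
    """dV/dU, bounded in [min_j (beta_j-beta)/beta, max_j (beta_j-beta)/beta]."""
    a = _log_terms(U, grid, state)
    a = a - np.max(a)
    w = np.exp(a)
    return float(np.sum(w * (grid.betas - grid.beta)) / (np.sum(w) * grid.beta))


def update_estimates(
    state: OpesMultiThermal, U_samples: np.ndarray, V_samples: np.ndarray
) -> OpesMultiThermal:
    """Accumulate one batch of biased samples and refresh dF(T_j).

    The importance weights w_k = exp(beta * V_{k}) unbias each sample with
    the bias that was acting when it was drawn.
    """
    U = np.atleast_1d(np.asarray(U_samples, dtype=float))
    V = np.atleast_1d(np.asarray(V_samples, dtype=float))
    if U.size == 0:
        raise ValueError("empty sample batch")
    if U.shape != V.shape:
        raise ValueError("U and V sample shapes differ")
    beta = state.grid.beta
    logw = beta * V
    if not np.any(np.isfinite(logw)):
        raise ValueError("all-zero importance weights")
    state.log_sum_w = float(np.logaddexp(state.log_sum_w, logsumexp(logw)))
    # log sum of w_k * exp(-du_j(U_k)) per grid point
    du = (state.grid.betas[:, None] - beta) * U[None, :]
    batch = logsumexp(logw[None, :] - du, axis=1)
    state.log_sum_w_expdu = np.logaddexp(state.log_sum_w_expdu, batch)
    state.deltaF = -(state.log_sum_w_expdu - state.log_sum_w) / state.grid.betas
    state.n_samples += U.size
    state.n_updates += 1
    if not np.all(np.isfinite(state.deltaF)):
        raise RuntimeError("non-finite free-energy estimates")
    return state


def reweight_observable(
    U: np.ndarray,
    V: np.ndarray,
    observable: np.ndarray,
    grid: ExpansionGrid,
    target_T: float,
    ess_floor: float = 50.0,
):
    """Self-normalized importance estimate of <O> at a target temperature.

    Weights are exp(beta*V - (beta_t - beta)*U).  Returns (value, ess,
    ess_warning); the warning flags an effective sample size below the floor.
    """
    if not (grid.T_min <= target_T <= grid.T_max):
        raise ValueError("target temperature outside the expansion range")
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    obs = np.asarray(observable, dtype=float)
    beta_t = 1.0 / target_T
    logw = grid.beta * V - (beta_t - grid.beta) * U
    logw = logw - logsumexp(logw)
    w = np.exp(logw)
    value = float(np.sum(w * obs))
    ess = float(1.0 / np.sum(w * w))
    return value, ess, ess < ess_floor


# ---------------------------------------------------------------------------
# analytic calibration system: 1-D harmonic well


def harmonic_delta_f(grid: ExpansionGrid, k_spring: float = 1.0) -> np.ndarray:
    """Analytic dF(T_j) for the 1-D harmonic well, the estimator's limit.

    Z(beta) = sqrt(2*pi/(beta*k)) gives
    dF(T_j) = -(1/beta_j) ln(Z_j/Z) = -(T_j/2) ln(T_j/T).
    """
    Tj = grid.temperatures
    return -(Tj / 2.0) * np.log(Tj / grid.T)


def run_opes_harmonic(
    grid: ExpansionGrid,
    n_steps: int = 1_000_000,
    k_spring: float = 1.0,
    dt: float = 0.05,
    gamma: float = 1.0,
    update_stride: int = 500,
    seed: int = 0,
    bias: bool = True,
):
    """Biased BAOAB run on U = k x^2 / 2 with on-the-fly dF updates.

    Returns (state, U_series, V_series).  The first ``update_stride`` steps
    run with the zero-dF bias; estimates refresh every stride thereafter.
    """
    rng = np.random.default_rng(seed)
    state = OpesMultiThermal(grid=grid, update_stride=update_stride)
    x = float(rng.standard_normal()) * np.sqrt(grid.T / k_spring)
    v = float(rng.standard_normal()) * np.sqrt(grid.T)
    u_all = np.empty(n_steps)
    v_all = np.empty(n_steps)
    done = 0
    while done < n_steps:
        seg = min(update_stride, n_steps - done)
        noise = rng.standard_normal(seg)
        u_out = np.empty(seg)
        v_out = np.empty(seg)
        x, v = _kernels.baoab_harmonic_opes(
            x, v, k_spring, dt, gamma, grid.T,
            bias, grid.beta, grid.betas, state.beta_j_deltaF,
            noise, u_out, v_out,
        )
        u_all[done : done + seg] = u_out
        v_all[done : done + seg] = v_out
        if bias:
            state.update(u_out, v_out)
        done += seg
    return state, u_all, v_all
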