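"""Circular-error statistics and mixture models of continuous-report memory.

Responses on a circular report dimension are summarized by the signed
reproduction error ``x = wrap(response - target)``.  Two generative models
of the error distribution are implemented:

standard mixture (uniform + von Mises)
    ``f(x; g, sigma) = (1 - g) * phi(x, k(sigma)) + g / (2*pi)``
    where ``g`` is the guess rate (weight of the memoryless uniform
    component) and ``phi`` a von Mises density centred on zero whose
    concentration ``k`` encodes the memory precision ``sigma``.

swap model (uniform + target + non-targets)
    ``f(x; g, sigma, beta) = g / (2*pi) + (1 - g - beta) * phi(x, k)
    + (beta / m) * sum_i phi(x_i, k)``
    where ``beta`` is the swap rate, ``m`` the number of non-probed items
    and ``x_i`` the error relative to non-target ``i``.

Angles are degrees at the interface and radians internally; densities are
per radian so both pdfs integrate to one around the circle.  The
sigma <-> kappa mapping is the wrapped-normal approximation
``Rbar = exp(-sigma_rad**2 / 2)``, ``kappa = A1inv(Rbar)`` with
``A1(kappa) = I1(kappa) / I0(kappa)``, the convention used throughout the
continuous-report modeling literature.  Fitting is maximum likelihood with
multi-start Nelder-Mead on transformed (unconstrained) parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import i0e, i1e
from scipy.stats import vonmises

__all__ = [
    "SD_MIN",
    "SD_MAX",
    "StandardMixtureFit",
    "SwapFit",
    "wrap",
    "abs_error",
    "sd_to_kappa",
    "kappa_to_sd",
    "standard_pdf",
    "swap_pdf",
    "fit_standard",
    "fit_swap",
    "simulate_standard",
    "simulate_swap",
    "summarize",
]

SD_MIN = 0.5  # degrees; fitting bounds on the circular SD
SD_MAX = 100.0
_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class StandardMixtureFit:
    g: float
    sd: float
    kappa: float
    loglik: float
    n: int


@dataclass(frozen=True)
class SwapFit:
    g: float
    beta: float
    sd: float
    kappa: float
    loglik: float
    n: int
    m: int


# ---------------------------------------------------------------------------
# angle arithmetic
# ---------------------------------------------------------------------------

def wrap(angle):
    """Wrap angle(s) in degrees into the signed interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angle must be finite")
    wrapped = a - 360.0 * np.ceil((a - 180.0) / 360.0)
    return float(wrapped) if np.isscalar(angle) else wrapped


def abs_error(target, response):
    """Absolute circular error |wrap(response - target)|, in [0, 180]."""
    diff = wrap(np.asarray(response, dtype=float) - np.asarray(target, dtype=float))
    return np.abs(diff) if isinstance(diff, np.ndarray) else abs(diff)


# ---------------------------------------------------------------------------
# sigma <-> kappa
# ---------------------------------------------------------------------------

def _a1(kappa: np.ndarray) -> np.ndarray:
    """Mean resultant length A1(kappa) = I1(kappa)/I0(kappa), overflow-safe."""
    k = np.asarray(kappa, dtype=float)
    return np.where(k > 0, i1e(k) / np.where(k > 0, i0e(k), 1.0), 0.0)


def _a1_inv(r: float) -> float:
    """Invert A1 by the standard piecewise seed plus Newton refinement."""
    if r >= 1.0:
        return float("inf")
    if r <= 0.0:
        return 0.0
    # Fisher/Banerjee seed
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    for _ in range(30):
        a = float(_a1(k))
        # dA1/dk = 1 - A1/k - A1^2
        deriv = 1.0 - a / k - a * a
        step = (a - r) / deriv
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * max(1.0, k):
            k = k_new
            break
        k = k_new
    return float(k)


def sd_to_kappa(sd: float) -> float:
    """Concentration for a circular SD in degrees (wrapped-normal mapping)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    sigma = math.radians(sd)
    rbar = math.exp(-(sigma**2) / 2.0)
    return _a1_inv(rbar)


def kappa_to_sd(kappa: float) -> float:
    """Circular SD in degrees for a von Mises concentration."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return float("inf")
    rbar = float(_a1(kappa))
    return math.degrees(math.sqrt(-2.0 * math.log(rbar)))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _validate_gb(g: float, beta: float = 0.0) -> None:
    if not (0.0 <= g <= 1.0) or beta < 0.0 or g + beta > 1.0 + 1e-12:
        raise ValueError(f"invalid mixture weights g={g}, beta={beta}")


def standard_pdf(x, g: float, sd: float):
    """Standard-mixture density (per radian) at signed error(s) x in degrees."""
    _validate_gb(g)
    kappa = sd_to_kappa(sd)
    xr = np.radians(np.asarray(x, dtype=float))
    dens = (1.0 - g) * vonmises.pdf(xr, kappa) + g / _TWO_PI
    return float(dens) if np.isscalar(x) else dens


def swap_pdf(x, nontarget_offsets, g: float, beta: float, sd: float):
    """Swap-model density (per radian) at signed error(s) x in degrees.

    ``nontarget_offsets`` holds, per trial, the signed circular positions of
    the non-probed items relative to the target (degrees); the density of a
    swap response to item i is a von Mises centred on that offset.
    """
    _validate_gb(g, beta)
    kappa = sd_to_kappa(sd)
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    offsets = np.atleast_2d(np.asarray(nontarget_offsets, dtype=float))
    if offsets.shape[0] == 1 and x_arr.shape[0] > 1:
        offsets = np.broadcast_to(offsets, (x_arr.shape[0], offsets.shape[1]))
    if beta > 0 and offsets.shape[1] == 0:
        raise ValueError("beta > 0 requires at least one non-target offset")
    xr = np.radians(x_arr)
    dens = g / _TWO_PI + (1.0 - g - beta) * vonmises.pdf(xr, kappa)
    if offsets.shape[1] > 0:
        m = offsets.shape[1]
        swap_x = np.radians(x_arr[:, None] - offsets)
        dens = dens + (beta / m) * vonmises.pdf(swap_x, kappa).sum(axis=1)
    return float(dens[0]) if np.isscalar(x) else dens


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _sigmoid(u: float) -> float:
    if u >= 0:
        return 1.0 / (1.0 + math.exp(-u))
    e = math.exp(u)
    return e / (1.0 + e)


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1.0 - 1e-6)
    return math.log(p / (1.0 - p))


def _sd_from_u(u: float) -> float:
    return SD_MIN + (SD_MAX - SD_MIN) * _sigmoid(u)


def _u_from_sd(sd: float) -> float:
    return _logit((min(max(sd, SD_MIN + 1e-3), SD_MAX - 1e-3) - SD_MIN) / (SD_MAX - SD_MIN))


_START_G = (0.05, 0.25, 0.5, 0.75, 0.95)
_START_SD = (15.0, 45.0)


def fit_standard(errors, min_n: int = 20) -> StandardMixtureFit:
    """Maximum-likelihood fit of the standard mixture to signed errors.

    Runs Nelder-Mead from a grid of starting points over (g, sd) on
    logit-transformed coordinates so the box constraints g in [0, 1],
    sd in [SD_MIN, SD_MAX] hold implicitly; returns the best optimum.
    """
    x = np.asarray(errors, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} errors, got {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("all errors identical; fit is at the precision boundary")
    xr = np.radians(wrap(x))
    cos_x = np.cos(xr)

    def nll(params) -> float:
        g = _sigmoid(params[0])
        kappa = sd_to_kappa(_sd_from_u(params[1]))
        # log von Mises via exp-scaled Bessel to stay finite at large kappa
        log_vm = kappa * (cos_x - 1.0) - math.log(_TWO_PI * float(i0e(kappa)))
        dens = (1.0 - g) * np.exp(log_vm) + g / _TWO_PI
        return -float(np.sum(np.log(dens)))

    best = None
    for g0 in _START_G:
        for sd0 in _START_SD:
            res = minimize(
                nll,
                x0=[_logit(g0), _u_from_sd(sd0)],
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
    g_hat = _sigmoid(best.x[0])
    sd_hat = _sd_from_u(best.x[1])
    return StandardMixtureFit(
        g=g_hat,
        sd=sd_hat,
        kappa=sd_to_kappa(sd_hat),
        loglik=-best.fun,
        n=int(x.size),
    )


def fit_swap(errors, nontarget_offsets, min_n: int = 50) -> SwapFit:
    """Maximum-likelihood fit of the swap model.

    ``nontarget_offsets`` is an (n, m) array of per-trial non-target
    positions relative to the target (degrees).  The weights (g, beta) are
    kept on the simplex g + beta <= 1 by a stick-breaking transform.
    """
    x = np.asarray(errors, dtype=float)
    offsets = np.atleast_2d(np.asarray(nontarget_offsets, dtype=float))
    if offsets.shape[0] == 1 and x.size > 1:
        offsets = np.broadcast_to(offsets, (x.size, offsets.shape[1]))
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} errors, got {x.size}")
    if offsets.shape[1] < 1:
        raise ValueError("swap model needs at least one non-target per trial")
    m = offsets.shape[1]
    xr = np.radians(wrap(x))
    swap_xr = np.radians(wrap(x[:, None] - offsets))
    cos_x = np.cos(xr)
    cos_swap = np.cos(swap_xr)

    def nll(params) -> float:
        g = _sigmoid(params[0])
        beta = (1.0 - g) * _sigmoid(params[1])
        kappa = sd_to_kappa(_sd_from_u(params[2]))
        log_norm = math.log(_TWO_PI * float(i0e(kappa)))
        vm_target = np.exp(kappa * (cos_x - 1.0) - log_norm)
        vm_swap = np.exp(kappa * (cos_swap - 1.0) - log_norm).sum(axis=1)
        dens = g / _TWO_PI + (1.0 - g - beta) * vm_target + (beta / m) * vm_swap
        return -float(np.sum(np.log(dens)))

    best = None
    for g0 in (0.05, 0.3, 0.6):
        for b0 in (0.05, 0.3):
            for sd0 in _START_SD:
                res = minimize(
                    nll,
                    x0=[_logit(g0), _logit(b0 / (1.0 - g0)), _u_from_sd(sd0)],
                    method="Nelder-Mead",
                    options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 3000},
                )
                if best is None or res.fun < best.fun:
                    best = res
    g_hat = _sigmoid(best.x[0])
    beta_hat = (1.0 - g_hat) * _sigmoid(best.x[1])
    sd_hat = _sd_from_u(best.x[2])
    return SwapFit(
        g=g_hat,
        beta=beta_hat,
        sd=sd_hat,
        kappa=sd_to_kappa(sd_hat),
        loglik=-best.fun,
        n=int(x.size),
        m=m,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_standard(n: int, g: float, sd: float, seed=None) -> np.ndarray:
    """Draw n signed errors (degrees) from the standard mixture."""
    _validate_gb(g)
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = _rng(seed)
    kappa = sd_to_kappa(sd)
    guess = rng.random(n) < g
    draws = np.degrees(rng.vonmises(0.0, kappa, size=n))
    draws[guess] = rng.uniform(-180.0, 180.0, size=int(guess.sum()))
    return wrap(draws)


def simulate_swap(
    n: int, g: float, beta: float, sd: float, nontarget_offsets, seed=None
) -> np.ndarray:
    """Draw n signed errors from the swap model.

    ``nontarget_offsets`` is (n, m) or (m,) broadcast to all trials; on a
    swap trial the response centres on one non-target chosen uniformly.
    """
    _validate_gb(g, beta)
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = _rng(seed)
    offsets = np.atleast_2d(np.asarray(nontarget_offsets, dtype=float))
    if offsets.shape[0] == 1:
        offsets = np.broadcast_to(offsets, (n, offsets.shape[1]))
    if offsets.shape[0] != n:
        raise ValueError("nontarget_offsets must broadcast to n trials")
    m = offsets.shape[1]
    if beta > 0 and m < 1:
        raise ValueError("beta > 0 requires non-target offsets")
    kappa = sd_to_kappa(sd)
    u = rng.random(n)
    noise = np.degrees(rng.vonmises(0.0, kappa, size=n))
    errors = noise.copy()  # target component
    is_guess = u < g
    is_swap = (~is_guess) & (u < g + beta)
    errors[is_guess] = rng.uniform(-180.0, 180.0, size=int(is_guess.sum()))
    if is_swap.any():
        which = rng.integers(0, m, size=int(is_swap.sum()))
        errors[is_swap] = offsets[is_swap, which] + noise[is_swap]
    return wrap(errors)


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def summarize(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive error summaries of a reproduction-trial table.

    Computes the mean absolute error per participant and condition, then the
    across-participant mean and SD: by set size, by serial position of the
    probed item within set size 2, and by block crossed with set size.
    """
    required = {
        "participant_id",
        "block",
        "set_size",
        "serial_position",
        "target_deg",
        "response_deg",
    }
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df = trials.copy()
    df["abs_error"] = abs_error(df["target_deg"].values, df["response_deg"].values)

    def across_participants(group_cols: list[str]) -> pd.DataFrame:
        per_p = (
            df.groupby(["participant_id", *group_cols])["abs_error"]
            .mean()
            .reset_index()
        )
        out = (
            per_p.groupby(group_cols)["abs_error"]
            .agg(mean_abs_error="mean", sd_across_participants="std")
            .reset_index()
        )
        return out

    by_set_size = across_participants(["set_size"])
    ss2 = df[df["set_size"] == 2]
    if ss2.empty:
        by_serial = pd.DataFrame(
            columns=["serial_position", "mean_abs_error", "sd_across_participants"]
        )
    else:
        by_serial = (
            ss2.groupby(["participant_id", "serial_position"])["abs_error"]
            .mean()
            .reset_index()
            .groupby("serial_position")["abs_error"]
            .agg(mean_abs_error="mean", sd_across_participants="std")
            .reset_index()
        )
    by_block = across_participants(["block", "set_size"])
    return {
        "by_set_size": by_set_size,
        "by_serial_position_ss2": by_serial,
        "by_block": by_block,
    }
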