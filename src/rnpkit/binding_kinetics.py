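"""1:1 Langmuir binding kinetics: sensorgram simulation and global fitting.

The pseudo-first-order model for a surface-binding experiment: an analyte
at constant concentration C binds an immobilized ligand with association
rate k_on (1/(M s)) and dissociation rate k_off (1/s). During analyte
injection the response follows

    R(t) = R_eq (1 - exp(-(k_on C + k_off) t)),   R_eq = R_max C / (C + K_D)

and after switching to buffer at t_switch it decays as

    R(t) = R(t_switch) exp(-k_off (t - t_switch)),

with K_D = k_off / k_on the equilibrium dissociation constant. Fitting is
a global nonlinear least squares over all concentrations jointly, sharing
one (k_on, k_off, R_max) triple — the standard one-to-one analysis of a
dilution series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "Sensorgram",
    "simulate_sensorgram",
    "fit_one_to_one",
    "dissociation_constant",
    "FitResult",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures with banker's rounding.

    Floating-point noise beyond ~7 significant digits is stripped first so
    that an analytically exact half (e.g. 2.25e-9 to 2 s.f.) resolves by
    round-half-to-even rather than by its binary representation.
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    if x == 0:
        return 0.0
    d = Decimal(f"{x:.{sig + 4}e}")
    exp = d.adjusted()
    mantissa = d.scaleb(-exp).quantize(
        Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_HALF_EVEN
    )
    return float(mantissa.scaleb(exp))


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of a 1:1 interaction plus the surface capacity R_max."""

    k_on: float   # 1/(M s)
    k_off: float  # 1/s
    R_max: float  # response units

    def __post_init__(self):
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")
        if self.k_off < 0:
            raise ValueError("k_off must be nonnegative")
        if self.R_max <= 0:
            raise ValueError("R_max must be positive")

    @property
    def K_D(self) -> float:
        """Equilibrium dissociation constant k_off/k_on, in M."""
        return self.k_off / self.k_on


def dissociation_constant(params: KineticParams) -> float:
    """K_D = k_off / k_on (M). Zero when the complex never dissociates."""
    return params.k_off / params.k_on


@dataclass
class Sensorgram:
    """One response curve: association up to ``t_switch``, dissociation after."""

    analyte_concentration: float  # M
    times: np.ndarray             # s, strictly increasing
    responses: np.ndarray         # response units
    t_switch: float               # s

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.shape != self.responses.shape:
            raise ValueError("times and responses must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.times[0] <= self.t_switch <= self.times[-1]:
            raise ValueError("t_switch must lie within the time range")


def _model_response(
    params: KineticParams, conc: float, times: np.ndarray, t_switch: float
) -> np.ndarray:
    k_obs = params.k_on * conc + params.k_off
    r_eq = params.R_max * conc / (conc + params.K_D)
    assoc = r_eq * (1.0 - np.exp(-k_obs * times))
    r_switch = r_eq * (1.0 - np.exp(-k_obs * t_switch))
    dissoc = r_switch * np.exp(-params.k_off * (times - t_switch))
    return np.where(times <= t_switch, assoc, dissoc)


def simulate_sensorgram(
    params: KineticParams,
    conc: float,
    times: np.ndarray,
    t_switch: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Sensorgram:
    """Simulate a two-phase sensorgram from the closed-form 1:1 model.

    Additive iid Gaussian noise of standard deviation ``noise_sd`` response
    units is applied when nonzero; the ``seed`` makes it reproducible.
    """
    if conc <= 0:
        raise ValueError("analyte concentration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    times = np.asarray(times, dtype=float)
    responses = _model_response(params, conc, times, t_switch)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        responses = responses + rng.normal(0.0, noise_sd, size=times.shape)
    return Sensorgram(conc, times, responses, t_switch)


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    params: KineticParams
    param_sd: dict[str, float]      # 1-sigma from residual-scaled covariance
    rss: float                      # residual sum of squares
    rmse: float
    n_points: int

    @property
    def K_D(self) -> float:
        return self.params.K_D

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k_on": self.params.k_on,
            "k_off": self.params.k_off,
            "R_max": self.params.R_max,
            "K_D": self.params.K_D,
            "sd": self.param_sd,
            "rss": self.rss,
            "rmse": self.rmse,
            "n_points": self.n_points,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _initial_guess(curves: Sequence[Sensorgram]) -> KineticParams:
    """Feature-based starting point: R_max from the peak response, k_off from
    a log-linear fit of the dissociation tail, k_on from the apparent
    association rate of the highest-concentration curve."""
    r_max0 = 1.2 * max(c.responses.max() for c in curves)
    if r_max0 <= 0:
        r_max0 = 1.0

    # k_off: pool log-responses of dissociation phases (positive values only)
    slopes = []
    for c in curves:
        mask = (c.times > c.t_switch) & (c.responses > 0)
        if mask.sum() >= 3:
            t = c.times[mask] - c.t_switch
            y = np.log(c.responses[mask])
            slope = np.polyfit(t, y, 1)[0]
            if slope < 0:
                slopes.append(-slope)
    k_off0 = float(np.median(slopes)) if slopes else 1e-3

    # k_on from the association of the highest-concentration curve
    top = max(curves, key=lambda c: c.analyte_concentration)
    mask = top.times <= top.t_switch
    t, r = top.times[mask], top.responses[mask]
    r_eq_est = max(r.max() * 1.05, 1e-12)
    frac = np.clip(1.0 - r / r_eq_est, 1e-6, 1.0)
    k_obs = -np.polyfit(t, np.log(frac), 1)[0] if len(t) >= 3 else 1e-2
    k_on0 = max((k_obs - k_off0) / top.analyte_concentration, 1e-2)
    return KineticParams(k_on0, max(k_off0, 1e-12), r_max0)


def fit_one_to_one(
    curves: Sequence[Sensorgram],
    init: Optional[KineticParams] = None,
) -> FitResult:
    """Global 1:1 fit of (k_on, k_off, R_max) shared across all curves.

    Nonlinear least squares in log-parameter space (positivity without
    constraints). Per-parameter 1-sigma uncertainties come from the
    residual-variance-scaled Gauss-Newton covariance. Raises on
    non-convergence, warns when the data carry no signal.
    """
    if not curves:
        raise ValueError("need at least one sensorgram")
    if all(np.ptp(c.responses) < 1e-12 for c in curves):
        warnings.warn("flat sensorgram(s): the fit is ill-conditioned")
    if init is None:
        init = _initial_guess(curves)

    def unpack(x: np.ndarray) -> KineticParams:
        return KineticParams(np.exp(x[0]), np.exp(x[1]), np.exp(x[2]))

    def residuals(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        return np.concatenate(
            [
                _model_response(p, c.analyte_concentration, c.times, c.t_switch)
                - c.responses
                for c in curves
            ]
        )

    x0 = np.log([init.k_on, max(init.k_off, 1e-15), init.R_max])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=20000)
    if not sol.success:
        raise RuntimeError(
            f"kinetic fit did not converge (final residual {np.sum(sol.fun**2):.3g})"
        )
    params = unpack(sol.x)
    n = len(sol.fun)
    rss = float(np.sum(sol.fun**2))
    dof = max(n - 3, 1)
    s2 = rss / dof
    try:
        jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
        log_sd = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0, None))
    except np.linalg.LinAlgError:
        log_sd = np.full(3, np.nan)
    # delta method: sd(p) = p * sd(log p)
    values = np.array([params.k_on, params.k_off, params.R_max])
    sd = dict(zip(("k_on", "k_off", "R_max"), values * log_sd))
    sd["K_D"] = params.K_D * float(np.hypot(log_sd[0], log_sd[1]))
    return FitResult(params, sd, rss, float(np.sqrt(rss / n)), n)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def write_sensorgram_csv(curves: Sequence[Sensorgram], path: str | Path) -> None:
    frames = []
    for i, c in enumerate(curves):
        frames.append(
            pd.DataFrame(
                {
                    "curve": i,
                    "time": c.times,
                    "response": c.responses,
                    "concentration": c.analyte_concentration,
                    "phase": np.where(c.times <= c.t_switch, "association",
                                      "dissociation"),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_sensorgram_csv(path: str | Path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    curves = []
    for _i, sub in df.groupby("curve", sort=True):
        assoc = sub[sub["phase"] == "association"]
        t_switch = float(assoc["time"].max()) if len(assoc) else float(sub["time"].min())
        curves.append(
            Sensorgram(
                float(sub["concentration"].iloc[0]),
                sub["time"].to_numpy(),
                sub["response"].to_numpy(),
                t_switch,
            )
        )
    return curves
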