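"""Kelvin-Voigt fitting of laser-ablation vertex-recoil traces.

After ablating a cell junction, the separation of the flanking tricellular
vertices relaxes as the step response of a spring and dashpot in parallel:

    d(t) = d0 + D * (1 - exp(-k t)),   t >= 0

with pre-ablation baseline ``d0``, recoil amplitude ``D`` and relaxation
rate ``k`` (elasticity-to-viscosity ratio, 1/s).  The initial recoil
velocity, the tension proxy, is d'(0) = D * k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConvergenceError, ValidationError

K_BOUNDS = (1e-4, 10.0)  # plausible relaxation-rate range, 1/s


@dataclass
class RecoilTrace:
    """A tracked vertex-vertex distance trace around a junction ablation.

    ``time_s`` is seconds from ablation (t = 0 at the ablation frame);
    negative times are pre-ablation baseline frames.  Requires strictly
    increasing times, >= 5 post-ablation points and >= 1 pre-ablation point.
    """

    time_s: np.ndarray
    distance: np.ndarray
    group: str = ""
    trace_id: object = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if self.time_s.shape != self.distance.shape:
            raise ValidationError("time and distance lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValidationError(
                f"trace {self.trace_id}: timestamps not strictly increasing"
            )
        if np.sum(self.time_s >= 0) < 5:
            raise ValidationError(
                f"trace {self.trace_id}: fewer than 5 post-ablation points"
            )
        if np.sum(self.time_s < 0) < 1:
            raise ValidationError(
                f"trace {self.trace_id}: no pre-ablation baseline point"
            )

    @property
    def baseline(self) -> float:
        """Mean pre-ablation separation."""
        return float(self.distance[self.time_s < 0].mean())


@dataclass
class KelvinVoigtFit:
    """Fitted Kelvin-Voigt parameters for one recoil trace."""

    baseline_distance: float
    asymptote_gain: float  # D, total recoil amplitude
    rate_k: float  # 1/s
    residual_rms: float
    converged: bool = True
    negative_amplitude: bool = False
    group: str = ""
    trace_id: object = None

    @property
    def initial_recoil(self) -> float:
        """Initial recoil velocity d'(0) = D * k (distance per second)."""
        return self.asymptote_gain * self.rate_k


def _model(t, D, k, d0):
    return d0 + D * (1.0 - np.exp(-k * t))


def fit_kelvin_voigt(trace: RecoilTrace, fit_baseline: bool = False) -> KelvinVoigtFit:
    """Nonlinear least-squares Kelvin-Voigt fit of one recoil trace.

    By default the baseline ``d0`` is fixed to the pre-ablation mean and
    only (D, k) are fitted; with ``fit_baseline=True``, ``d0`` is a third
    free parameter.  Deterministic: initial guesses are derived from the
    trace (D from the total rise, k from the half-rise time) and ``k`` is
    bounded to ``[1e-4, 10]`` 1/s.

    Raises :class:`ConvergenceError` carrying best-so-far parameters if the
    optimiser fails; a negative fitted amplitude is flagged, not raised
    (junction under compression or failed ablation).
    """
    post = trace.time_s >= 0
    t = trace.time_s[post]
    d = trace.distance[post]
    d0 = trace.baseline

    rise = float(d[-1] - d[0])
    d_guess = rise if rise != 0 else 1e-6
    half_level = d[0] + 0.5 * rise
    crossed = np.nonzero((d - half_level) * np.sign(d_guess) >= 0)[0]
    t_half = t[crossed[0]] if crossed.size and t[crossed[0]] > 0 else (t[-1] or 1.0)
    k_guess = float(np.clip(1.0 / t_half, *K_BOUNDS))

    try:
        if fit_baseline:
            popt, _ = curve_fit(
                _model,
                t,
                d,
                p0=[d_guess, k_guess, d0],
                bounds=([-np.inf, K_BOUNDS[0], -np.inf], [np.inf, K_BOUNDS[1], np.inf]),
                maxfev=20_000,
            )
            D, k, d0_fit = popt
        else:
            popt, _ = curve_fit(
                lambda tt, D, k: _model(tt, D, k, d0),
                t,
                d,
                p0=[d_guess, k_guess],
                bounds=([-np.inf, K_BOUNDS[0]], [np.inf, K_BOUNDS[1]]),
                maxfev=20_000,
            )
            D, k = popt
            d0_fit = d0
    except RuntimeError as exc:
        raise ConvergenceError(
            f"Kelvin-Voigt fit did not converge for trace {trace.trace_id}: {exc}",
            state={"D": d_guess, "k": k_guess, "d0": d0},
        ) from exc

    resid = d - _model(t, D, k, d0_fit)
    return KelvinVoigtFit(
        baseline_distance=float(d0_fit),
        asymptote_gain=float(D),
        rate_k=float(k),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=True,
        negative_amplitude=bool(D < 0),
        group=trace.group,
        trace_id=trace.trace_id,
    )


def fits_to_frame(fits) -> pd.DataFrame:
    """Tabulate fits in the output CSV dialect."""
    return pd.DataFrame(
        [
            {
                "trace_id": f.trace_id,
                "group": f.group,
                "d0": f.baseline_distance,
                "D": f.asymptote_gain,
                "k": f.rate_k,
                "initial_recoil": f.initial_recoil,
                "residual_rms": f.residual_rms,
                "converged": f.converged,
            }
            for f in fits
        ]
    )


def initial_recoil_summary(fits) -> pd.DataFrame:
    """Per-group mean +/- SEM of initial recoil velocity (and k).

    SEM is reported as NaN for single-fit groups.  Empty groups simply do
    not appear; raw values are available via :func:`fits_to_frame`.
    """
    df = fits_to_frame(fits)
    if df.empty:
        raise ValueError("no fits to summarise")

    def _sem(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    rows = []
    for group, grp in df.groupby("group", sort=True):
        rows.append(
            {
                "group": group,
                "n": len(grp),
                "initial_recoil_mean": float(grp["initial_recoil"].mean()),
                "initial_recoil_sem": _sem(grp["initial_recoil"].to_numpy()),
                "k_mean": float(grp["k"].mean()),
                "k_sem": _sem(grp["k"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)
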