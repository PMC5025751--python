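"""ATPase-cycle kinetics: transient fits, actin activation, and head gating.

The measured cycle transitions of myosin X (per second, from stopped-flow and
steady-state assays) and a minimal gated two-head model that links them to
motility.  The pyrene-actin-monitored transition is the slowest cycle step
(~19 s^-1 per head on single filaments) and is accelerated to ~34 s^-1 for
the dimer on fascin bundles; phosphate release (max ~108 s^-1) and mantADP
release (~60 s^-1) are too fast to limit the cycle.  In the dimer the bound
rear head gates the lead head — with strict gating each head completes one
cycle per two cycle times, halving the per-head steady-state ATPase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticRates",
    "GatingModel",
    "ExponentialTransient",
    "TransientResults",
    "ActinActivation",
    "ActivationResults",
    "fit_exponential",
    "fit_actin_dependence",
    "gated_per_head_rate",
    "predict_velocity",
    "velocity_ratio",
]


@dataclass(frozen=True)
class KineticRates:
    """Measured rate constants of the myosin X cycle (s^-1)."""

    k_pi_max_per_s: float = 108.0
    k_pyrene_filament_per_s: float = 19.0
    k_pyrene_bundle_per_s: float = 34.0
    k_mantadp_per_s: float = 60.0
    atpase_s1_per_head: float = 19.0
    atpase_hmm_per_head: float = 9.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    def rate_limiting(self, track: str = "filament") -> float:
        """Slowest cycle transition on the given track."""
        pyrene = (
            self.k_pyrene_bundle_per_s
            if track == "bundle"
            else self.k_pyrene_filament_per_s
        )
        return min(self.k_pi_max_per_s, self.k_mantadp_per_s, pyrene)


@dataclass(frozen=True)
class GatingModel:
    """Fraction of lead-head cycles stalled until the rear head detaches."""

    gating_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gating_efficiency <= 1.0:
            raise ValueError("gating_efficiency must be in [0, 1]")


def gated_per_head_rate(monomer_rate: float, g: GatingModel | float) -> float:
    """Per-head steady-state ATPase of the gated dimer.

    With strict gating the two heads alternate, so each head waits one full
    partner cycle between its own cycles: per-head rate = monomer_rate / 2.
    Without gating each head cycles independently at the monomer rate.  The
    waiting time interpolates linearly in the gating efficiency, so the rate
    is monomer_rate / (1 + g).
    """
    if monomer_rate <= 0:
        raise ValueError("monomer_rate must be positive")
    eff = g.gating_efficiency if isinstance(g, GatingModel) else float(g)
    if not 0.0 <= eff <= 1.0:
        raise ValueError("gating efficiency must be in [0, 1]")
    return monomer_rate / (1.0 + eff)


def predict_velocity(
    mean_forward_step_nm: float, k_limiting_per_s: float, coupling: float = 1.0
) -> float:
    """Velocity (nm/s) = step size x rate-limiting rate x steps-per-event."""
    if mean_forward_step_nm <= 0 or k_limiting_per_s <= 0 or coupling < 0:
        raise ValueError("step and rate must be positive, coupling >= 0")
    return mean_forward_step_nm * k_limiting_per_s * coupling


def velocity_ratio(
    k_bundle: float, k_filament: float, d_bundle: float = 1.0, d_filament: float = 1.0
) -> float:
    """Predicted bundle/filament velocity ratio from rate and step ratios."""
    return (k_bundle / k_filament) * (d_bundle / d_filament)


# ------------------------------------------------------------- transient fits
@dataclass(frozen=True)
class TransientResults:
    """Multi-exponential decay fit; rates sorted descending."""

    amplitudes: tuple[float, ...]
    rates_per_s: tuple[float, ...]
    offset: float
    residual_ss: float
    success: bool

    @property
    def params(self) -> list[tuple[float, float]]:
        return list(zip(self.amplitudes, self.rates_per_s))

    def summary(self) -> str:
        lines = [f"Exponential transient fit ({len(self.rates_per_s)} phases, "
                 f"success = {self.success}):"]
        for a, k in self.params:
            lines.append(f"  amplitude = {a:8.4f}   k = {k:8.3f} /s")
        lines.append(f"  offset = {self.offset:.4f}, residual SS = {self.residual_ss:.4g}")
        return "\n".join(lines)


class ExponentialTransient:
    """Sum-of-decaying-exponentials model of a stopped-flow record."""

    def __init__(self, times_s, signal):
        self.t = np.asarray(times_s, dtype=float).ravel()
        self.y = np.asarray(signal, dtype=float).ravel()
        if self.t.size != self.y.size or self.t.size < 5:
            raise ValueError("times and signal must align, length >= 5")

    def fit(self, n_exp: int = 1, fit_offset: bool = False) -> TransientResults:
        """Nonlinear least-squares fit of ``sum_i A_i exp(-k_i t)`` (+offset)."""
        if n_exp not in (1, 2):
            raise ValueError("n_exp must be 1 or 2")
        t, y = self.t, self.y
        span = y[: max(3, t.size // 10)].mean() - y[-max(3, t.size // 10):].mean()
        if span <= 0:
            # signal does not decay; flag failure with a null fit
            return TransientResults((0.0,) * n_exp, (np.nan,) * n_exp,
                                    float(y.mean()), float(((y - y.mean()) ** 2).sum()),
                                    False)
        t_half = t[np.argmin(np.abs((y - y[-1]) - span / 2))]
        k0 = np.log(2) / max(t_half, t[1] if t[0] == 0 else t[0])

        if n_exp == 1:
            if fit_offset:
                f = lambda t, a, k, c: a * np.exp(-k * t) + c
                p0 = [span, k0, y[-1]]
            else:
                f = lambda t, a, k: a * np.exp(-k * t)
                p0 = [span, k0]
        else:
            if fit_offset:
                f = lambda t, a1, k1, a2, k2, c: (a1 * np.exp(-k1 * t)
                                                  + a2 * np.exp(-k2 * t) + c)
                p0 = [span / 2, k0 * 3, span / 2, k0 / 3, y[-1]]
            else:
                f = lambda t, a1, k1, a2, k2: a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)
                p0 = [span / 2, k0 * 3, span / 2, k0 / 3]
        try:
            popt, _ = curve_fit(f, t, y, p0=p0, maxfev=20000)
        except RuntimeError:
            return TransientResults((np.nan,) * n_exp, (np.nan,) * n_exp, np.nan,
                                    np.nan, False)
        resid = float(((y - f(t, *popt)) ** 2).sum())
        if fit_offset:
            offset = float(popt[-1])
            popt = popt[:-1]
        else:
            offset = 0.0
        amps = popt[0::2]
        rates = popt[1::2]
        order = np.argsort(rates)[::-1]
        return TransientResults(tuple(float(a) for a in amps[order]),
                                tuple(float(k) for k in rates[order]),
                                offset, resid, bool(np.all(rates > 0)))


def fit_exponential(times_s, signal, n_exp: int = 1) -> TransientResults:
    """Functional wrapper around :meth:`ExponentialTransient.fit`."""
    return ExponentialTransient(times_s, signal).fit(n_exp=n_exp)


# --------------------------------------------------------- actin dependence
@dataclass(frozen=True)
class ActivationResults:
    """Hyperbolic actin-activation fit, k_obs = k_max [A] / (K_half + [A])."""

    k_max_per_s: float
    k_half_um: float
    k_max_se: float
    saturating: bool

    def summary(self) -> str:
        warn = "" if self.saturating else "  (data do not saturate; wide confidence)"
        return (f"Actin activation: k_max = {self.k_max_per_s:.2f} +/- "
                f"{self.k_max_se:.2f} /s, K_half = {self.k_half_um:.2f} uM{warn}")


class ActinActivation:
    """Hyperbolic dependence of an observed rate on actin concentration."""

    def __init__(self, actin_um, k_obs_per_s):
        self.conc = np.asarray(actin_um, dtype=float).ravel()
        self.k_obs = np.asarray(k_obs_per_s, dtype=float).ravel()
        if self.conc.size != self.k_obs.size or self.conc.size < 4:
            raise ValueError("need >= 4 (concentration, rate) pairs")

    def fit(self) -> ActivationResults:
        def f(a, kmax, khalf):
            return kmax * a / (khalf + a)

        kmax0 = float(self.k_obs.max())
        p0 = [kmax0 * 1.2, max(float(np.median(self.conc)) / 4, 1e-3)]
        popt, pcov = curve_fit(f, self.conc, self.k_obs, p0=p0,
                               bounds=([1e-9, 0.0], [np.inf, np.inf]),
                               maxfev=20000)
        kmax, khalf = float(popt[0]), float(popt[1])
        se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.inf
        # saturating if the largest concentration reaches ~80% of k_max
        saturating = bool(self.conc.max() >= 4.0 * khalf or se < 0.2 * kmax)
        return ActivationResults(kmax, khalf, se, saturating)


def fit_actin_dependence(actin_um, k_obs_per_s) -> ActivationResults:
    """Functional wrapper around :meth:`ActinActivation.fit`."""
    return ActinActivation(actin_um, k_obs_per_s).fit()
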