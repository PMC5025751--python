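"""Generative models for stepping traces, runs and kinetic transients.

Everything downstream (step finding, mixture fitting, run-length fitting,
transient fitting) is tested against data produced here, so the generators
mirror the assays: FIONA-style position-vs-time traces are piecewise-constant
signals with exponentially (or Erlang-2) distributed dwells, signed step sizes
drawn from a Gaussian mixture, Gaussian localization noise at a finite frame
rate; processive runs terminate at random giving truncated-exponential run
lengths; stopped-flow records are sums of decaying exponentials plus noise.

All randomness flows through :func:`numpy.random.default_rng`; passing the
same seed reproduces outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MixtureSpec",
    "TraceParams",
    "StepTrace",
    "RunSet",
    "sample_steps",
    "simulate_trace",
    "simulate_runs",
    "simulate_transient",
    "FL_SINGLE",
    "FL_BUNDLE",
    "HMM_SINGLE",
    "HMM_BUNDLE",
    "HMM_BUNDLE_SPLIT_BACKWARD",
    "N_OBSERVED",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Signed step-size distribution as a univariate Gaussian mixture.

    ``components`` is a sequence of (weight, mean_nm, sd_nm); negative means
    are backward steps.  Weights must be positive and sum to 1; a zero sd is
    allowed for degenerate (deterministic) components.
    """

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(m), float(s)) for w, m, s in self.components)
        object.__setattr__(self, "components", comps)
        w = np.array([c[0] for c in comps])
        s = np.array([c[2] for c in comps])
        if len(comps) == 0:
            raise ValueError("mixture needs at least one component")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if np.any(s < 0):
            raise ValueError("sd_nm must be >= 0")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    @property
    def mean(self) -> float:
        """Analytic mixture mean."""
        return float(np.dot(self.weights, self.means))


# Step-size mixtures measured for the two constructs on the two tracks.
# Component means/sds are the fitted values; the observed histograms are
# dominated by forward steps, so forward components share the non-backward
# mass equally and backward steps carry 30% where no finer split is known.
FL_SINGLE = MixtureSpec(((0.3, -26.0, 15.0), (0.7, 36.0, 14.0)))
FL_BUNDLE = MixtureSpec(
    (
        (0.3, -33.0, 14.0),
        (0.7 / 3, 19.0, 7.0),
        (0.7 / 3, 38.0, 7.0),
        (0.7 / 3, 52.0, 5.0),
    )
)
HMM_SINGLE = MixtureSpec(((0.3, -33.0, 15.0), (0.7, 39.0, 13.0)))
HMM_BUNDLE = MixtureSpec(
    ((0.25, -28.0, 18.0), (0.25, 17.0, 6.0), (0.25, 40.0, 9.0), (0.25, 57.0, 2.0))
)
#: Variant with the backward population split in two, as resolved for the
#: zippered dimer on bundles.
HMM_BUNDLE_SPLIT_BACKWARD = MixtureSpec(
    (
        (0.125, -49.0, 6.0),
        (0.125, -20.0, 11.0),
        (0.25, 17.0, 6.0),
        (0.25, 40.0, 9.0),
        (0.25, 57.0, 2.0),
    )
)

#: Step counts of the measured datasets, for matched-size synthetic draws.
N_OBSERVED = {
    "fl_single": 214,
    "fl_bundle": 393,
    "hmm_single": 238,
    "hmm_bundle": 178,
}


@dataclass(frozen=True)
class TraceParams:
    """Acquisition and kinetic parameters of a simulated stepping trace."""

    frame_rate_hz: float = 50.0
    noise_sd_nm: float = 3.0
    k_step_per_s: float = 2.0
    n_steps: int | None = 20
    duration_s: float | None = None
    p_detach: float = 0.0
    dwell: Literal["exponential", "erlang2"] = "exponential"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.k_step_per_s <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")
        if not 0 <= self.p_detach <= 1:
            raise ValueError("p_detach must be in [0, 1]")
        if self.n_steps is None and self.duration_s is None:
            raise ValueError("give n_steps or duration_s")


@dataclass
class StepTrace:
    """A sampled position trace with its generating ground truth."""

    times_s: np.ndarray
    positions_nm: np.ndarray
    true_step_times: np.ndarray
    true_step_sizes: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.positions_nm):
            raise ValueError("times and positions must align")
        if len(self.true_step_times) != len(self.true_step_sizes):
            raise ValueError("ground-truth arrays must align")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class RunSet:
    """Processive runs: length, duration and velocity per run."""

    run_lengths_um: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        self.run_lengths_um = np.asarray(self.run_lengths_um, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if np.any(self.run_lengths_um <= 0) or np.any(self.durations_s <= 0):
            raise ValueError("run lengths and durations must be positive")

    @property
    def velocities_um_per_s(self) -> np.ndarray:
        return self.run_lengths_um / self.durations_s

    def __len__(self) -> int:
        return len(self.run_lengths_um)


def sample_steps(
    mix: MixtureSpec, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. signed step sizes (nm) from a Gaussian mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mix.components), size=n, p=mix.weights)
    return rng.normal(mix.means[comp], mix.sds[comp])


def _draw_dwells(tp: TraceParams, n: int, rng: np.random.Generator) -> np.ndarray:
    mean = 1.0 / tp.k_step_per_s
    if tp.dwell == "erlang2":
        # two sequential exponential phases with the same total mean
        return rng.exponential(mean / 2.0, size=(n, 2)).sum(axis=1)
    return rng.exponential(mean, size=n)


def simulate_trace(tp: TraceParams, mix: MixtureSpec) -> StepTrace:
    """Simulate one FIONA-style stepping trace.

    Dwells are i.i.d. Exponential (or Erlang-2), step increments come from
    ``mix``, and the piecewise-constant position is sampled at the frame rate
    with Gaussian localization noise.  If ``duration_s`` is too short for a
    single dwell the trace comes back with ``empty=True``.
    """
    rng = np.random.default_rng(tp.seed)
    if tp.n_steps is not None:
        n = tp.n_steps
        dwells = _draw_dwells(tp, n + 1, rng)
        if tp.p_detach > 0:
            survive = rng.random(n) >= tp.p_detach
            if not survive.all():
                n = int(np.argmin(survive)) + 1
                dwells = dwells[: n + 1]
        step_times = np.cumsum(dwells[:-1])[:n]
        duration = step_times[-1] + dwells[n] if n else dwells[0]
    else:
        duration = float(tp.duration_s)
        dwells = []
        t = 0.0
        while True:
            d = float(_draw_dwells(tp, 1, rng)[0])
            if t + d > duration:
                break
            t += d
            dwells.append(t)
            if tp.p_detach > 0 and rng.random() < tp.p_detach:
                break
        step_times = np.asarray(dwells)
        n = len(step_times)

    sizes = sample_steps(mix, n, rng) if n else np.empty(0)
    n_frames = max(int(np.floor(duration * tp.frame_rate_hz)) + 1, 2)
    times = np.arange(n_frames) / tp.frame_rate_hz
    levels = np.concatenate([[0.0], np.cumsum(sizes)])
    pos = levels[np.searchsorted(step_times, times, side="right")]
    if tp.noise_sd_nm > 0:
        pos = pos + rng.normal(0.0, tp.noise_sd_nm, size=n_frames)
    return StepTrace(times, pos, step_times, sizes, empty=(n == 0))


def simulate_runs(
    lambda_um: float,
    x0_um: float,
    n: int,
    seed: int | np.random.Generator | None = None,
    *,
    step_nm: float = 36.0,
    k_step_per_s: float = 8.7,
) -> RunSet:
    """Simulate processive runs with truncated-exponential lengths.

    Run lengths are ``x0 + Exponential(lambda)`` — the form recovered when
    only runs longer than the detection floor ``x0`` are scored.  Durations
    are built from the stepping kinetics (length/step exponential dwells at
    ``k_step_per_s``) so that velocities are consistent with the lengths.
    """
    if lambda_um < 0 or x0_um < 0:
        raise ValueError("lambda_um and x0_um must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = x0_um + rng.exponential(lambda_um, size=n) if lambda_um > 0 else (
        np.full(n, x0_um)
    )
    n_steps = np.maximum(np.round(lengths * 1000.0 / step_nm).astype(int), 1)
    # sum of k exponential dwells == Gamma(k, 1/rate)
    durations = rng.gamma(shape=n_steps, scale=1.0 / k_step_per_s)
    return RunSet(lengths, durations)


def simulate_transient(
    rates: Sequence[tuple[float, float]],
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sum of decaying exponentials, amplitude * exp(-k t), plus noise."""
    if not rates:
        raise ValueError("rates must be non-empty")
    t = np.asarray(t_grid, dtype=float)
    y = np.zeros_like(t)
    for amp, k in rates:
        if k <= 0:
            raise ValueError("rate constants must be positive")
        y = y + amp * np.exp(-k * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return y
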