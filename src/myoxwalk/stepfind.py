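"""Step detection in position-vs-time traces.

Greedy chi-square step fitter with counter-fit model selection, in the style
long used for molecular-motor traces: steps are inserted one at a time at the
location that maximally reduces the residual sum of squares, and the number
of steps is chosen by comparing each fit against a "counter-fit" whose steps
are deliberately placed mid-plateau.  The quality factor

    S(k) = chi2_counterfit(k) / chi2_fit(k)

peaks at the true step count: under-fitting leaves real steps inside plateaus
(raising chi2_fit), while over-fitting makes the counter-fit as good as the
fit (driving S toward 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import StepTrace

__all__ = ["StepFitResult", "find_steps"]


@dataclass
class StepFitResult:
    """Detected steps for one trace."""

    step_indices: np.ndarray  # frame index of the first frame after each step
    step_times_s: np.ndarray
    plateau_levels_nm: np.ndarray
    step_sizes_nm: np.ndarray
    residual_ss: float
    quality: dict[int, float] | None  # counter-fit quality factor per step count
    n_steps: int

    def __post_init__(self) -> None:
        if len(self.step_sizes_nm) != max(len(self.plateau_levels_nm) - 1, 0):
            raise ValueError("sizes/levels mismatch")

    def summary(self) -> str:
        lines = [
            f"Step fit: {self.n_steps} steps, residual SS = {self.residual_ss:.3g}"
        ]
        for t, s in zip(self.step_times_s, self.step_sizes_nm):
            lines.append(f"  t = {t:8.3f} s   step = {s:+7.2f} nm")
        return "\n".join(lines)


class _Segments:
    """O(1) residual sums of squares over segments via prefix sums."""

    def __init__(self, y: np.ndarray):
        self.y = y
        self.c1 = np.concatenate([[0.0], np.cumsum(y)])
        self.c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(self, a: int, b: int) -> float:
        n = b - a
        if n <= 0:
            return 0.0
        s = self.c1[b] - self.c1[a]
        return float(self.c2[b] - self.c2[a] - s * s / n)

    def sse_total(self, bounds: np.ndarray) -> float:
        return sum(self.sse(a, b) for a, b in zip(bounds[:-1], bounds[1:]))

    def mean(self, a: int, b: int) -> float:
        return float((self.c1[b] - self.c1[a]) / (b - a))

    def best_split(self, a: int, b: int, min_dwell: int):
        """Best single changepoint in [a, b) keeping both parts >= min_dwell."""
        lo, hi = a + min_dwell, b - min_dwell
        if hi < lo:
            return None
        s = np.arange(lo, hi + 1)
        nl = s - a
        nr = b - s
        suml = self.c1[s] - self.c1[a]
        sumr = self.c1[b] - self.c1[s]
        sse_split = (
            self.c2[b]
            - self.c2[a]
            - suml * suml / nl
            - sumr * sumr / nr
        )
        i = int(np.argmin(sse_split))
        reduction = self.sse(a, b) - float(sse_split[i])
        return int(s[i]), reduction


def _counterfit_bounds(bounds: np.ndarray) -> np.ndarray:
    """Counter-fit changepoints: the midpoints of the fit's plateaus."""
    mids = (bounds[:-1] + bounds[1:]) // 2
    inner = mids[(mids > bounds[0]) & (mids < bounds[-1])]
    return np.concatenate([[bounds[0]], np.unique(inner), [bounds[-1]]])


def find_steps(
    trace: StepTrace | np.ndarray,
    max_steps: int | None = None,
    min_dwell_frames: int = 2,
) -> StepFitResult:
    """Detect steps in a trace by greedy chi-square fitting.

    Parameters
    ----------
    trace : StepTrace or array
        The sampled positions; a bare array is treated as sampled at 1 Hz.
    max_steps : int, optional
        Cap on the number of candidate steps; defaults to the largest count
        the minimum-dwell constraint permits (at most 500).
    min_dwell_frames : int
        Minimum plateau length in frames.
    """
    if isinstance(trace, StepTrace):
        y = np.asarray(trace.positions_nm, dtype=float)
        times = np.asarray(trace.times_s, dtype=float)
    else:
        y = np.asarray(trace, dtype=float)
        times = np.arange(len(y), dtype=float)
    n = len(y)
    if n < 2 * min_dwell_frames:
        raise ValueError("trace shorter than twice the minimum dwell")

    seg = _Segments(y)
    if seg.sse(0, n) <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        # flat trace: no steps, quality undefined
        return StepFitResult(
            np.empty(0, dtype=int),
            np.empty(0),
            np.array([seg.mean(0, n)]),
            np.empty(0),
            seg.sse(0, n),
            None,
            0,
        )

    cap = n // (2 * min_dwell_frames)
    if max_steps is not None:
        cap = min(cap, max_steps)
    cap = min(cap, 500)

    bounds = [0, n]
    best_cache: dict[tuple[int, int], tuple[int, float] | None] = {}
    history: list[np.ndarray] = []
    total_sse = seg.sse(0, n)
    for _ in range(cap):
        best = None
        for a, b in zip(bounds[:-1], bounds[1:]):
            key = (a, b)
            if key not in best_cache:
                best_cache[key] = seg.best_split(a, b, min_dwell_frames)
            cand = best_cache[key]
            if cand is not None and (best is None or cand[1] > best[1]):
                best = cand
        if best is None or best[1] <= 1e-12 * max(total_sse, 1e-30):
            break
        split, _ = best
        bounds = sorted(bounds + [split])
        history.append(np.array(bounds))

    # counter-fit quality per candidate step count
    quality: dict[int, float] = {}
    for bnds in history:
        k = len(bnds) - 2
        chi_fit = seg.sse_total(bnds)
        chi_counter = seg.sse_total(_counterfit_bounds(bnds))
        quality[k] = float(np.inf) if chi_fit <= 0 else chi_counter / chi_fit

    if not quality:
        return StepFitResult(
            np.empty(0, dtype=int),
            np.empty(0),
            np.array([seg.mean(0, n)]),
            np.empty(0),
            seg.sse(0, n),
            None,
            0,
        )

    best_s = max(quality.values())
    k_best = min(k for k, s in quality.items() if s == best_s)
    bnds = history[k_best - 1]
    levels = np.array([seg.mean(a, b) for a, b in zip(bnds[:-1], bnds[1:])])
    idx = bnds[1:-1]
    return StepFitResult(
        step_indices=idx,
        step_times_s=times[idx],
        plateau_levels_nm=levels,
        step_sizes_nm=np.diff(levels),
        residual_ss=seg.sse_total(bnds),
        quality=quality,
        n_steps=k_best,
    )
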