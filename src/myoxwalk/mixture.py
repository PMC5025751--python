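"""Signed step-size distributions: Gaussian-mixture fitting and K selection.

The observed step-size histograms mix forward and backward populations, so
they are fit as univariate Gaussian mixtures by expectation-maximization
(best of several restarts), with the number of components chosen by k-fold
cross-validation on held-out log-likelihood.  Components are always reported
sorted by mean, so backward components (negative means) come first.

The estimator follows the ``Model(data).fit() -> Results`` idiom::

    res = StepMixture(steps).fit(k=2, seed=0)
    print(res.summary())
    sel = StepMixture(steps).select_k(range(1, 7), seed=0)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import KFold

__all__ = [
    "StepMixture",
    "StepMixtureResults",
    "CVSelection",
    "fit_gaussian_mixture",
    "select_k_cv",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _component_logpdf(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * (z * z + _LOG_2PI) - np.log(sds)[None, :]


@dataclass
class CVSelection:
    """Cross-validation curve and the selected component count."""

    k_range: tuple[int, ...]
    cv_loglik: np.ndarray  # mean held-out log-likelihood per observation
    k_selected: int
    folds_used: int

    def summary(self) -> str:
        lines = [f"CV selection over K = {list(self.k_range)} ({self.folds_used}-fold)"]
        for k, ll in zip(self.k_range, self.cv_loglik):
            mark = " <-- selected" if k == self.k_selected else ""
            lines.append(f"  K = {k}: held-out loglik/obs = {ll: .4f}{mark}")
        return "\n".join(lines)


class StepMixtureResults:
    """Fitted K-component Gaussian mixture.

    Attributes
    ----------
    weights_, means_, sds_ : ndarray
        Component parameters, sorted by mean.
    loglik : float
        Log-likelihood at the fitted parameters.
    loglik_path : ndarray
        Per-iteration log-likelihood of the winning EM run (non-decreasing).
    converged : bool
    n_restarts_used : int
    degenerate : bool
        True if every restart ended with a vanishing-mass component.
    """

    def __init__(self, model, weights, means, sds, loglik, loglik_path, converged,
                 n_restarts_used, degenerate):
        order = np.argsort(means)
        self.model = model
        self.k = len(means)
        self.weights_ = np.asarray(weights)[order]
        self.means_ = np.asarray(means)[order]
        self.sds_ = np.asarray(sds)[order]
        self.loglik = float(loglik)
        self.loglik_path = np.asarray(loglik_path)
        self.converged = bool(converged)
        self.n_restarts_used = int(n_restarts_used)
        self.degenerate = bool(degenerate)

    @property
    def params(self) -> list[tuple[float, float, float]]:
        return list(zip(self.weights_, self.means_, self.sds_))

    @property
    def nobs(self) -> int:
        return len(self.model.steps)

    def logpdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lp = _component_logpdf(x, self.means_, self.sds_) + np.log(self.weights_)
        return logsumexp(lp, axis=1)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        comp = rng.choice(self.k, size=n, p=self.weights_ / self.weights_.sum())
        return rng.normal(self.means_[comp], self.sds_[comp])

    @property
    def bic(self) -> float:
        n_par = 3 * self.k - 1
        return n_par * np.log(self.nobs) - 2.0 * self.loglik

    def summary(self) -> str:
        lines = [
            f"Gaussian mixture fit: K = {self.k}, N = {self.nobs}, "
            f"loglik = {self.loglik:.3f}, converged = {self.converged}",
            "  comp    weight    mean (nm)    sd (nm)",
        ]
        for i, (w, m, s) in enumerate(self.params):
            lines.append(f"  {i:>4}    {w:6.3f}    {m:9.2f}    {s:7.2f}")
        return "\n".join(lines)

    def plot(self, ax=None, bins=30):
        """Histogram of the data with the fitted density and its components."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.steps
        ax.hist(x, bins=bins, density=True, alpha=0.4, color="grey")
        grid = np.linspace(x.min() - 10, x.max() + 10, 400)
        ax.plot(grid, self.pdf(grid), "k-", lw=1.5)
        for w, m, s in self.params:
            ax.plot(grid, w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi)),
                    "--", lw=1)
        ax.set_xlabel("step size (nm)")
        ax.set_ylabel("density")
        return ax


class StepMixture:
    """Univariate Gaussian-mixture model of signed step sizes."""

    def __init__(self, steps):
        self.steps = np.asarray(steps, dtype=float).ravel()
        if self.steps.size < 2:
            raise ValueError("need at least two observations")

    @classmethod
    def from_dataframe(cls, df, column: str = "step_nm") -> "StepMixture":
        return cls(df[column].to_numpy())

    # ------------------------------------------------------------------ EM
    def _init_params(self, k: int, n_restarts: int, rng: np.random.Generator):
        """Initial (weights, means, sds), batched over restarts.

        Restart 0 puts means at data quantiles; the rest draw means from the
        data itself.
        """
        x = self.steps
        means = np.empty((n_restarts, k))
        means[0] = np.quantile(x, (np.arange(k) + 0.5) / k)
        for r in range(1, n_restarts):
            means[r] = rng.choice(x, size=k, replace=False)
        sds = np.full((n_restarts, k), max(x.std(), 1.0) / max(np.sqrt(k), 1.0))
        weights = np.full((n_restarts, k), 1.0 / k)
        return weights, means, sds

    def _em_batched(self, weights, means, sds, tol, sd_floor, max_iter):
        """Run EM on all restarts at once (axis 0 = restart).

        Returns final (weights, means, sds, loglik) per restart plus the
        per-iteration log-likelihood path of each restart (nan-padded after
        convergence) and convergence flags.
        """
        x = self.steps
        n = x.size
        nr = weights.shape[0]
        paths = np.full((nr, max_iter + 1), np.nan)
        prev = np.full(nr, -np.inf)
        ll = np.full(nr, -np.inf)
        active = np.ones(nr, dtype=bool)
        xc = x[None, :, None]  # (1, n, 1)
        for it in range(max_iter):
            act = np.flatnonzero(active)
            w_a, m_a, s_a = weights[act], means[act], sds[act]
            # E-step in the log domain (manual max-shift logsumexp)
            lp = (
                -0.5 * (((xc - m_a[:, None, :]) / s_a[:, None, :]) ** 2 + _LOG_2PI)
                - np.log(s_a)[:, None, :]
                + np.log(w_a)[:, None, :]
            )
            mx = lp.max(axis=2, keepdims=True)
            sumexp = np.exp(lp - mx).sum(axis=2, keepdims=True)
            norm = (mx + np.log(sumexp))[:, :, 0]  # (n_active, n)
            ll_new = norm.sum(axis=1)
            ll[act] = ll_new
            paths[act, it] = ll_new
            done = ll_new - prev[act] < tol * np.maximum(np.abs(ll_new), 1.0)
            active[act[done]] = False
            if not active.any():
                break
            prev[act] = ll_new
            # M-step for the restarts that have not converged
            keep = ~done
            sub = act[keep]
            resp = np.exp(lp[keep] - norm[keep][:, :, None])
            nk = np.maximum(resp.sum(axis=1), 1e-300)  # (n_keep, k)
            weights[sub] = nk / n
            means[sub] = (resp * xc).sum(axis=1) / nk
            var = (resp * (xc - means[sub][:, None, :]) ** 2).sum(axis=1) / nk
            sds[sub] = np.maximum(np.sqrt(var), sd_floor)
        converged = ~active
        degenerate = (weights < 1.0 / n).any(axis=1)
        return weights, means, sds, ll, paths, converged, degenerate

    def fit(
        self,
        k: int,
        n_restarts: int = 10,
        tol: float = 1e-8,
        sd_floor: float = 1.0,
        max_iter: int = 500,
        seed=None,
    ) -> StepMixtureResults:
        """Fit a K-component mixture by EM, best of ``n_restarts`` starts.

        Restart 0 initializes means at data quantiles; later restarts draw
        means from the data.  A component whose weight falls below 1/N is
        flagged degenerate and that run is not allowed to win unless every
        run degenerates.  ``sd_floor`` (nm) guards against collapse onto a
        single observation.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        if self.steps.size < 3 * k:
            raise ValueError(f"need at least {3 * k} observations for k={k}")
        rng = np.random.default_rng(seed)
        w0, m0, s0 = self._init_params(k, n_restarts, rng)
        w, m, s, ll, paths, conv, degen = self._em_batched(
            w0, m0, s0, tol, sd_floor, max_iter
        )
        # degenerate runs (vanishing-mass component) only win if all are
        clean = ~degen
        pool = np.flatnonzero(clean) if clean.any() else np.arange(n_restarts)
        r = pool[np.argmax(ll[pool])]
        path = paths[r][~np.isnan(paths[r])]
        return StepMixtureResults(
            self, w[r], m[r], s[r], ll[r], path, conv[r], n_restarts, degen[r]
        )

    # ------------------------------------------------------- model selection
    def select_k(
        self,
        k_range=range(1, 7),
        folds: int = 5,
        seed=None,
        n_restarts: int = 10,
        **fit_kw,
    ) -> CVSelection:
        """Choose K by k-fold cross-validated held-out log-likelihood.

        Ties break toward the smaller K.  With very few observations the
        fold count is reduced to keep every fold non-empty, and K values the
        training folds cannot support (fewer than 3*K points) are dropped;
        both adjustments warn.
        """
        k_range = tuple(sorted(k_range))
        n = self.steps.size
        if folds > n:
            folds = max(2, n // 2)
            warnings.warn(f"more folds than observations; reducing to {folds} folds")
        train_size = (n * (folds - 1)) // folds
        feasible = tuple(k for k in k_range if 3 * k <= train_size)
        if not feasible:
            raise ValueError("too few observations for any candidate K")
        if feasible != k_range:
            warnings.warn(
                f"training folds hold {train_size} points; reducing candidate "
                f"K to {list(feasible)}"
            )
            k_range = feasible
        rng = np.random.default_rng(seed)
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        fold_seeds = rng.integers(2**31 - 1, size=(folds, len(k_range)))
        heldout = np.zeros(len(k_range))
        for f, (tr, te) in enumerate(kf.split(self.steps)):
            train = StepMixture(self.steps[tr])
            for j, k in enumerate(k_range):
                res = train.fit(k, n_restarts=n_restarts,
                                seed=int(fold_seeds[f, j]), **fit_kw)
                heldout[j] += res.logpdf(self.steps[te]).sum()
        heldout /= n
        k_selected = k_range[int(np.argmax(heldout))]  # first max -> smallest K
        return CVSelection(k_range, heldout, k_selected, folds)


def fit_gaussian_mixture(steps, k, n_restarts=10, tol=1e-8, sd_floor=1.0,
                         seed=None) -> StepMixtureResults:
    """Functional wrapper around :meth:`StepMixture.fit`."""
    return StepMixture(steps).fit(k, n_restarts=n_restarts, tol=tol,
                                  sd_floor=sd_floor, seed=seed)


def select_k_cv(steps, k_range=range(1, 7), folds=5, seed=None, **kw) -> CVSelection:
    """Functional wrapper around :meth:`StepMixture.select_k`."""
    return StepMixture(steps).select_k(k_range, folds=folds, seed=seed, **kw)
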