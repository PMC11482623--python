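"""Estimation of sequential NTA kinetics from band-fraction time courses.

The estimator is a bounded nonlinear least-squares fit of the closed-form
chain model (:mod:`rtswitch.kinetics`) jointly to all species trajectories,
with a deterministic multistart grid so that no hand initialization is ever
needed.  The public surface follows the Model / Results convention:

>>> model = SequentialKineticsModel(timecourse, n_steps=3)
>>> res = model.fit()
>>> res.k, res.a, res.rss
>>> res = res.bootstrap(n_boot=200, seed=1)   # residual-resampling SEs
>>> print(res.summary())

Rates are searched in log10 space for conditioning; bounds on the natural
scale are k in (1e-6, 1e3) min^-1 and a in (1e-3, 1].
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import KineticModel, TimeCourse, fraction_trajectories

__all__ = [
    "SequentialKineticsModel",
    "KineticFitResults",
    "fit_sequential",
    "select_n_steps",
    "bootstrap_se",
]

_LOGK_BOUNDS = (-6.0, 3.0)     # log10 of (1e-6, 1e3) min^-1
_A_BOUNDS = (1e-3, 1.0)
_GRID_K = (0.01, 0.1, 1.0)     # per-step rate starts, min^-1
_GRID_A = (0.5, 1.0)           # shared reactive-fraction starts
_RSS_EARLY_STOP = 1e-14        # a start this good cannot be improved meaningfully
_RSS_FLOOR_PER_POINT = 1e-12   # AICc floor; keeps noiseless comparisons sane


def _predict(theta: np.ndarray, n_steps: int, times: np.ndarray,
             n_cols: int) -> np.ndarray:
    """Model fractions padded/collapsed to the observed column count."""
    k = 10.0 ** theta[:n_steps]
    a = theta[n_steps:]
    f = fraction_trajectories(KineticModel(k, a), times)
    if n_cols == n_steps + 1:
        return f
    if n_cols > n_steps + 1:  # higher species never produced by this model
        pad = np.zeros((f.shape[0], n_cols - n_steps - 1))
        return np.hstack([f, pad])
    # fewer observed columns: everything at or beyond the last observed
    # species co-migrates in the terminal column
    out = f[:, : n_cols - 1]
    tail = f[:, n_cols - 1 :].sum(axis=1, keepdims=True)
    return np.hstack([out, tail])


class KineticFitResults:
    """Point estimates, uncertainties and diagnostics of a sequential fit."""

    def __init__(self, model, kinetic_model, rss, converged, n_starts_used,
                 k_se=None, a_se=None, n_boot=0, n_boot_dropped=0):
        self.model = model                   # the SequentialKineticsModel
        self.kinetic_model = kinetic_model   # point-estimate KineticModel
        self.rss = float(rss)
        self.converged = bool(converged)
        self.n_starts_used = int(n_starts_used)
        self.k_se = k_se
        self.a_se = a_se
        self.n_boot = int(n_boot)
        self.n_boot_dropped = int(n_boot_dropped)

    # -- convenience accessors -------------------------------------------
    @property
    def k(self) -> np.ndarray:
        return self.kinetic_model.k

    @property
    def a(self) -> np.ndarray:
        return self.kinetic_model.a

    @property
    def n_steps(self) -> int:
        return self.kinetic_model.n_steps

    def fittedvalues(self) -> np.ndarray:
        tc = self.model.timecourse
        return _predict(
            np.concatenate([np.log10(self.k), self.a]),
            self.n_steps, tc.times, tc.n_species,
        )

    def resid(self) -> np.ndarray:
        return self.model.timecourse.fractions - self.fittedvalues()

    def aicc(self) -> float:
        """Small-sample-corrected AIC under i.i.d. Gaussian residuals."""
        n = self.model.timecourse.fractions.size
        p = 2 * self.n_steps
        rss = max(self.rss, n * _RSS_FLOOR_PER_POINT)
        aic = n * np.log(rss / n) + 2 * p
        if n - p - 1 > 0:
            aic += 2 * p * (p + 1) / (n - p - 1)
        return float(aic)

    # -- uncertainty ------------------------------------------------------
    def bootstrap(self, n_boot: int = 200, seed: int = 0) -> "KineticFitResults":
        """Residual-resampling bootstrap standard errors.

        Residuals are pooled over all cells, resampled with replacement onto
        the fitted surface, and each pseudo-dataset is refit warm-started at
        the point estimate.  Non-convergent refits are dropped and counted;
        more than 20 % drops flags the result as not converged.
        """
        if n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        tc = self.model.timecourse
        fitted = self.fittedvalues()
        resid = (tc.fractions - fitted).ravel()
        rng = np.random.default_rng(seed)
        x0 = np.concatenate([np.log10(self.k), self.a])
        lo = np.concatenate(
            [np.full(self.n_steps, _LOGK_BOUNDS[0]),
             np.full(self.n_steps, _A_BOUNDS[0])])
        hi = np.concatenate(
            [np.full(self.n_steps, _LOGK_BOUNDS[1]),
             np.full(self.n_steps, _A_BOUNDS[1])])
        ks, As = [], []
        dropped = 0
        for _ in range(n_boot):
            draw = rng.choice(resid, size=resid.size, replace=True)
            pseudo = fitted + draw.reshape(fitted.shape)

            def fun(theta, data=pseudo):
                return (_predict(theta, self.n_steps, tc.times,
                                 tc.n_species) - data).ravel()

            sol = least_squares(fun, x0, bounds=(lo, hi), method="trf")
            if not sol.success:
                dropped += 1
                continue
            ks.append(10.0 ** sol.x[: self.n_steps])
            As.append(sol.x[self.n_steps :])
        if not ks:
            raise RuntimeError("every bootstrap refit failed to converge")
        k_se = np.std(np.array(ks), axis=0, ddof=1)
        a_se = np.std(np.array(As), axis=0, ddof=1)
        flagged = dropped > 0.2 * n_boot
        return KineticFitResults(
            self.model, self.kinetic_model, self.rss,
            self.converged and not flagged, self.n_starts_used,
            k_se=k_se, a_se=a_se, n_boot=n_boot, n_boot_dropped=dropped,
        )

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Sequential NTA kinetics fit",
            "=" * 46,
            f"n_steps:        {self.n_steps}",
            f"observations:   {self.model.timecourse.fractions.size}",
            f"rss:            {self.rss:.6g}",
            f"converged:      {self.converged}",
            f"starts used:    {self.n_starts_used}",
        ]
        if self.n_boot:
            lines.append(
                f"bootstrap:      {self.n_boot} resamples "
                f"({self.n_boot_dropped} dropped)")
        lines.append("-" * 46)
        lines.append(f"{'step':>4} {'k (min^-1)':>12} {'se(k)':>10} "
                     f"{'a':>8} {'se(a)':>10}")
        for i in range(self.n_steps):
            kse = f"{self.k_se[i]:.3g}" if self.k_se is not None else "-"
            ase = f"{self.a_se[i]:.3g}" if self.a_se is not None else "-"
            lines.append(
                f"{i + 1:>4} {self.k[i]:>12.4g} {kse:>10} "
                f"{self.a[i]:>8.4g} {ase:>10}")
        return "\n".join(lines)

    def to_json(self) -> str:
        obj = {
            "n_steps": self.n_steps,
            "k": self.k.tolist(),
            "a": self.a.tolist(),
            "k_se": None if self.k_se is None else self.k_se.tolist(),
            "a_se": None if self.a_se is None else self.a_se.tolist(),
            "rss": self.rss,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "n_boot": self.n_boot,
            "n_boot_dropped": self.n_boot_dropped,
        }
        return json.dumps(obj, indent=2)

    def plot_fit(self, ax=None):
        """Overlay observed fractions and the fitted trajectories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tc = self.model.timecourse
        grid = np.linspace(tc.times[0], tc.times[-1], 200)
        smooth = _predict(
            np.concatenate([np.log10(self.k), self.a]),
            self.n_steps, grid, tc.n_species)
        for i in range(tc.n_species):
            line, = ax.plot(grid, smooth[:, i], label=f"+{i}" if i else "primer")
            ax.plot(tc.times, tc.fractions[:, i], "o",
                    color=line.get_color(), ms=4)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("species fraction")
        ax.legend()
        return ax


class SequentialKineticsModel:
    """Nonlinear least-squares model for the sequential NTA chain.

    Parameters
    ----------
    timecourse : TimeCourse
        Observed species fractions over time.
    n_steps : int
        Number of addition steps to fit (1-3).
    """

    def __init__(self, timecourse: TimeCourse, n_steps: int):
        if n_steps not in (1, 2, 3):
            raise ValueError("n_steps must be 1, 2 or 3")
        if timecourse.times.size < 2 * n_steps + 1:
            raise ValueError(
                f"need at least {2 * n_steps + 1} time points to fit "
                f"{2 * n_steps} parameters")
        self.timecourse = timecourse
        self.n_steps = n_steps

    @classmethod
    def from_dataframe(cls, df, n_steps: int, label: str = ""):
        """Build from a DataFrame with time_min and f0, f1, ... columns."""
        fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        fcols.sort(key=lambda c: int(c[1:]))
        tc = TimeCourse(df["time_min"].to_numpy(), df[fcols].to_numpy(),
                        label=label)
        return cls(tc, n_steps)

    @classmethod
    def from_csv(cls, path, n_steps: int, label: str = ""):
        return cls(TimeCourse.from_csv(path, label=label), n_steps)

    # ---------------------------------------------------------------------
    def _starts(self, init_strategy: str, x0, seed: int):
        n = self.n_steps
        if init_strategy == "user":
            if x0 is None:
                raise ValueError("init_strategy='user' requires x0=(k, a)")
            k0, a0 = x0
            yield np.concatenate([np.log10(np.asarray(k0, dtype=float)),
                                  np.asarray(a0, dtype=float)])
            return
        if init_strategy != "grid":
            raise ValueError(f"unknown init_strategy {init_strategy!r}")
        for ks in itertools.product(_GRID_K, repeat=n):
            for a0 in _GRID_A:
                yield np.concatenate(
                    [np.log10(ks), np.full(n, a0)])

    def fit(self, init_strategy: str = "grid", x0=None,
            seed: int = 0) -> KineticFitResults:
        """Bounded least squares over all species trajectories jointly.

        Multistarts from a fixed deterministic grid (rates crossed per step,
        shared reactive-fraction start); if every grid start fails, 20 seeded
        jitter starts are tried before flagging non-convergence.
        """
        tc = self.timecourse
        n = self.n_steps
        data = tc.fractions
        lo = np.concatenate([np.full(n, _LOGK_BOUNDS[0]),
                             np.full(n, _A_BOUNDS[0])])
        hi = np.concatenate([np.full(n, _LOGK_BOUNDS[1]),
                             np.full(n, _A_BOUNDS[1])])

        def fun(theta):
            return (_predict(theta, n, tc.times, tc.n_species) - data).ravel()

        best = None
        n_used = 0
        any_success = False
        starts = list(self._starts(init_strategy, x0, seed))
        for theta0 in starts:
            n_used += 1
            sol = least_squares(fun, theta0, bounds=(lo, hi), method="trf")
            any_success = any_success or sol.success
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
            if best is not None and 2 * best.cost < _RSS_EARLY_STOP:
                break
        if best is None:
            # seeded jitter fallback: log-uniform rates, uniform fractions
            rng = np.random.default_rng(seed)
            for _ in range(20):
                n_used += 1
                theta0 = np.concatenate([
                    rng.uniform(-3, 1, size=n),
                    rng.uniform(0.3, 1.0, size=n)])
                sol = least_squares(fun, theta0, bounds=(lo, hi), method="trf")
                if sol.success and (best is None or sol.cost < best.cost):
                    best = sol
        if best is None:
            # never silently succeed: return a flagged result at the last sol
            km = KineticModel(10.0 ** sol.x[:n], np.clip(sol.x[n:], 1e-3, 1.0))
            return KineticFitResults(self, km, 2 * sol.cost, False, n_used)
        km = KineticModel(10.0 ** best.x[:n], best.x[n:])
        return KineticFitResults(self, km, 2 * best.cost, True, n_used)


# -- thin functional surface ------------------------------------------------

def fit_sequential(tc: TimeCourse, n_steps: int, init_strategy: str = "grid",
                   seed: int = 0, x0=None) -> KineticFitResults:
    """Fit the n-step sequential model to a time course (grid multistart)."""
    return SequentialKineticsModel(tc, n_steps).fit(
        init_strategy=init_strategy, x0=x0, seed=seed)


def select_n_steps(tc: TimeCourse, max_steps: int = 3, seed: int = 0) -> int:
    """Pick the chain length by small-sample-corrected AIC, ties to fewer."""
    if max_steps not in (1, 2, 3):
        raise ValueError("max_steps must be 1, 2 or 3")
    best_order, best_aicc = None, np.inf
    for m in range(1, max_steps + 1):
        res = fit_sequential(tc, m, seed=seed)
        crit = res.aicc()
        if crit < best_aicc - 1e-12:  # strict improvement required
            best_order, best_aicc = m, crit
    return best_order


def bootstrap_se(tc: TimeCourse, n_steps: int, n_boot: int = 200,
                 seed: int = 0) -> KineticFitResults:
    """Fit then attach residual-resampling bootstrap standard errors."""
    res = fit_sequential(tc, n_steps, seed=seed)
    return res.bootstrap(n_boot=n_boot, seed=seed)
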