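"""Parameter inference for the active nematic tube model.

The public surface follows the model/results idiom: :class:`TubeModel`
binds observation data (replicate radius series, order parameters, cell
areas) to the forward model; :meth:`TubeModel.fit` minimizes the weighted
sum of squared residuals by multi-start local optimization and returns a
:class:`TubeFitResults` carrying estimates, diagnostics, an optional
residual-resampling bootstrap and a ``summary()`` table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .params import (ModelParams, NoiseSpec, PressureProtocol,
                     ParameterError, step_protocol)
from .synthetic import SyntheticDataset, generate_observations
from .tube import (IntegrationError, LaplaceInstabilityError, integrate_tube)

__all__ = ["TubeModel", "TubeFitResults", "fit_model",
           "bootstrap_uncertainty", "recovery_experiment", "DEFAULT_FREE"]

#: Parameters free by default; zeta0 is always closed by the initial
#: Laplace balance and never fitted.
DEFAULT_FREE = ("gamma", "beta", "q0", "Ka", "mu", "tau", "lam", "alpha", "kd")

_BAD_RESIDUAL = 1e3


class FitError(RuntimeError):
    pass


@dataclass
class _Series:
    """One observable: times, values (replicate mean), weight sigma and the
    optional replicate-level values."""
    t: np.ndarray
    y: np.ndarray
    sigma: float
    reps: Optional[np.ndarray] = None  # (n_rep, n_t)


class TubeModel:
    """Weighted least-squares model of tube observations.

    Parameters
    ----------
    data : dict
        Mapping of observable name to ``(t, y, sigma[, reps])`` tuples for
        any of ``"R"`` (R/R0), ``"q"``, ``"Q"``, ``"a"`` (a/a0).
    protocol : PressureProtocol
        Pressure protocol the data were recorded under.
    params_init : ModelParams
        Starting parameter set; fixed parameters keep these values.
    free : sequence of str
        Names of free parameters (subset of DEFAULT_FREE).
    """

    def __init__(self, data: Dict[str, tuple], protocol: PressureProtocol,
                 params_init: Optional[ModelParams] = None,
                 free: Sequence[str] = DEFAULT_FREE,
                 rtol: float = 1e-6):
        if "R" not in data:
            raise FitError("radius series is required")
        unknown = set(free) - set(DEFAULT_FREE)
        if unknown:
            raise FitError(f"unknown free parameters: {sorted(unknown)}")
        if "q" not in data and {"beta", "q0"} & set(free):
            warnings.warn(
                "beta/q0 free without q observations: the nematic coupling "
                "is structurally weakly identifiable", RuntimeWarning)
        self.series: Dict[str, _Series] = {}
        for name, tup in data.items():
            t, y, sigma = tup[:3]
            reps = tup[3] if len(tup) > 3 else None
            self.series[name] = _Series(np.asarray(t, float),
                                        np.asarray(y, float), float(sigma),
                                        None if reps is None
                                        else np.asarray(reps, float))
        self.protocol = protocol
        self.params_init = (params_init or ModelParams()).with_zeta0_closure(
            protocol.dP0)
        self.free = tuple(free)
        self.rtol = rtol
        self._t_union = np.unique(np.concatenate(
            [s.t for s in self.series.values()]))
        self._index = {name: np.searchsorted(self._t_union, s.t)
                       for name, s in self.series.items()}

    # -- construction helpers -------------------------------------------
    @classmethod
    def from_dataset(cls, ds: SyntheticDataset,
                     params_init: Optional[ModelParams] = None,
                     free: Sequence[str] = DEFAULT_FREE,
                     rtol: float = 1e-6) -> "TubeModel":
        """Bind a synthetic observation set (replicate means + per-observable
        weights from its NoiseSpec)."""
        ns = ds.noise
        rn = max(ns.n_replicates, 1)
        data = {
            "R": (ds.t_radius, ds.radius_rel_mean,
                  max(ns.sd_R_rel, 1e-4) / np.sqrt(rn), ds.radius_rel),
            "q": (ds.t_obs, ds.q_obs, max(ns.sd_q, 1e-4)),
            "Q": (ds.t_obs, ds.Q_obs, max(ns.sd_Q, 1e-4)),
            "a": (ds.t_obs, ds.a_obs_mean,
                  max(ns.sd_area_rel, 1e-4) / np.sqrt(rn), ds.a_obs),
        }
        return cls(data, ds.protocol,
                   params_init=params_init or ds.params, free=free,
                   rtol=rtol)

    # -- parameter vector mapping ---------------------------------------
    def _to_params(self, theta: np.ndarray) -> ModelParams:
        kw = {}
        for name, v in zip(self.free, np.exp(theta)):
            kw[name] = float(v)
        p = self.params_init.replace(zeta0=None, **kw)
        return p.with_zeta0_closure(self.protocol.dP0)

    def _theta0(self) -> np.ndarray:
        return np.log([getattr(self.params_init, n) for n in self.free])

    def _bounds(self, width: float = np.log(30.0)):
        t0 = self._theta0()
        lo, hi = t0 - width, t0 + width
        for i, n in enumerate(self.free):
            if n == "q0":
                hi[i] = min(hi[i], np.log(0.499))
            if n == "lam":
                hi[i] = min(hi[i], np.log(200.0))
        return lo, hi

    # -- forward prediction and residuals -------------------------------
    def predict(self, params: ModelParams) -> Dict[str, np.ndarray]:
        traj = integrate_tube(self.protocol, params, self._t_union,
                              rtol=self.rtol, check_laplace=False,
                              max_rhs_calls=20_000)
        if traj.terminated_early or traj.t.size < self._t_union.size:
            raise LaplaceInstabilityError("trajectory truncated")
        out = {}
        for name, idx in self._index.items():
            if name == "R":
                out[name] = traj.R[idx] / params.R0
            elif name == "q":
                out[name] = traj.q[idx]
            elif name == "Q":
                out[name] = traj.Q[idx]
            elif name == "a":
                out[name] = traj.a_rel[idx]
        return out

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        try:
            params = self._to_params(theta)
            pred = self.predict(params)
        except (ParameterError, IntegrationError, LaplaceInstabilityError,
                ValueError):
            n = sum(s.t.size for s in self.series.values())
            return np.full(n, _BAD_RESIDUAL)
        chunks = [(pred[name] - s.y) / s.sigma
                  for name, s in self.series.items()]
        r = np.concatenate(chunks)
        return np.where(np.isfinite(r), r, _BAD_RESIDUAL)

    def objective(self, theta: np.ndarray) -> float:
        """Weighted sum of squared residuals."""
        return float(np.sum(self.residuals(theta) ** 2))

    # -- fitting ---------------------------------------------------------
    def fit(self, n_starts: int = 32, seed: int = 0, n_polish: int = 4,
            start_width: float = np.log(10.0)) -> "TubeFitResults":
        """Multi-start weighted least squares.

        ``n_starts`` candidate starting points are drawn log-uniformly
        within a factor ``exp(start_width)`` of the initial parameters (the
        initial point itself is always a candidate); the ``n_polish`` best
        candidates are polished with a trust-region least-squares solver
        and the best optimum is returned.  The reported objective never
        exceeds the objective of any start.
        """
        rng = np.random.default_rng(seed)
        t0 = self._theta0()
        starts = [t0]
        lo, hi = self._bounds()
        for _ in range(max(n_starts - 1, 0)):
            th = t0 + rng.uniform(-start_width, start_width, size=t0.size)
            starts.append(np.clip(th, lo, hi))
        screened = [(self.objective(th), i) for i, th in enumerate(starts)]
        screened.sort(key=lambda x: x[0])
        best_theta, best_obj = starts[screened[0][1]], screened[0][0]
        n_evals = len(starts)
        converged = False
        for _, i in screened[:max(n_polish, 1)]:
            try:
                sol = least_squares(self.residuals, starts[i],
                                    bounds=self._bounds(), method="trf",
                                    x_scale="jac", xtol=1e-10, ftol=1e-10,
                                    max_nfev=60)
            except Exception:
                continue
            obj = 2.0 * sol.cost
            n_evals += sol.nfev
            if obj < best_obj:
                best_obj, best_theta = obj, sol.x
                converged = converged or sol.success
        params = self._to_params(best_theta)
        estimates = {n: getattr(params, n) for n in self.free}
        fixed = tuple(n for n in DEFAULT_FREE if n not in self.free)
        return TubeFitResults(
            model=self, params=params, estimates=estimates,
            residual=best_obj, n_starts=n_starts, seed=seed,
            converged=converged, fixed=fixed, n_evals=n_evals,
        )


@dataclass
class TubeFitResults:
    """Best-fit parameters with diagnostics and bootstrap uncertainty."""

    model: TubeModel
    params: ModelParams
    estimates: Dict[str, float]
    residual: float
    n_starts: int
    seed: int
    converged: bool
    fixed: Tuple[str, ...]
    n_evals: int = 0
    stderr: Optional[Dict[str, float]] = None
    n_boot: int = 0

    @property
    def K(self) -> float:
        """Derived short-time modulus mu/tau (N/m)."""
        return self.params.K

    def bootstrap(self, n_boot: int = 200, seed: int = 0) -> "TubeFitResults":
        """Residual-resampling bootstrap.

        Replicate deviations from the fitted curves are resampled with
        replacement per observable (whole replicates where the data are
        replicated, per-time residuals otherwise), the synthetic data are
        refitted from the best-fit point, and the standard deviation of the
        bootstrap estimates is reported as the standard error.
        """
        rng = np.random.default_rng(seed)
        pred = self.model.predict(self.params)
        boots = {n: [] for n in self.model.free}
        n_ok = 0
        for _ in range(n_boot):
            data = {}
            for name, s in self.model.series.items():
                mu = pred[name]
                if s.reps is not None:
                    dev = s.reps - mu[None, :]
                    pick = rng.integers(0, dev.shape[0], size=dev.shape[0])
                    y = mu + dev[pick].mean(axis=0)
                    data[name] = (s.t, y, s.sigma, mu[None, :] + dev[pick])
                else:
                    dev = s.y - mu
                    y = mu + rng.choice(dev, size=dev.size, replace=True)
                    data[name] = (s.t, y, s.sigma)
            m = TubeModel(data, self.model.protocol,
                          params_init=self.params, free=self.model.free,
                          rtol=self.model.rtol)
            try:
                sol = least_squares(m.residuals, m._theta0(),
                                    bounds=m._bounds(), method="trf",
                                    x_scale="jac", xtol=1e-8, ftol=1e-8,
                                    max_nfev=40)
            except Exception:
                continue
            if not sol.success:
                continue
            pb = m._to_params(sol.x)
            for n in self.model.free:
                boots[n].append(getattr(pb, n))
            n_ok += 1
        if n_boot and n_ok < 0.5 * n_boot:
            warnings.warn(f"only {n_ok}/{n_boot} bootstrap refits converged",
                          RuntimeWarning)
        self.stderr = {n: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
                       for n, v in boots.items()}
        self.boot_samples = {n: np.asarray(v) for n, v in boots.items()}
        self.n_boot = n_ok
        return self

    def conf_int(self, level: float = 0.95) -> Dict[str, tuple]:
        """Percentile bootstrap intervals (requires .bootstrap())."""
        if not getattr(self, "boot_samples", None):
            raise FitError("run .bootstrap() first")
        a = 100 * (1 - level) / 2
        return {n: tuple(np.percentile(v, [a, 100 - a]))
                for n, v in self.boot_samples.items() if v.size}

    def summary(self) -> str:
        lines = ["Active nematic tube model — weighted least squares",
                 f"free parameters: {', '.join(self.free_names)}",
                 f"weighted SSR: {self.residual:.4g}   "
                 f"starts: {self.n_starts}   converged: {self.converged}",
                 f"{'param':>8} {'estimate':>12} {'boot SE':>12}"]
        for n in self.free_names:
            se = (self.stderr or {}).get(n)
            se_s = f"{se:12.4g}" if se is not None and np.isfinite(se) else "           -"
            lines.append(f"{n:>8} {self.estimates[n]:12.5g} {se_s}")
        lines.append(f"{'K=mu/tau':>8} {self.K:12.5g} "
                     f"{'(derived)':>12}")
        return "\n".join(lines)

    @property
    def free_names(self):
        return list(self.model.free)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "K_mu_over_tau": self.K,
            "stderr": self.stderr,
            "residual": self.residual,
            "n_starts": self.n_starts,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "converged": self.converged,
            "fixed": list(self.fixed),
        }


def fit_model(dataset, free: Sequence[str] = DEFAULT_FREE,
              p_init: Optional[ModelParams] = None, n_starts: int = 32,
              seed: int = 0, **kw) -> TubeFitResults:
    """Fit the tube model to a SyntheticDataset (or a prepared data dict)."""
    if isinstance(dataset, SyntheticDataset):
        model = TubeModel.from_dataset(dataset, params_init=p_init, free=free)
    else:
        raise FitError("pass a SyntheticDataset or construct TubeModel directly")
    return model.fit(n_starts=n_starts, seed=seed, **kw)


def bootstrap_uncertainty(fit: TubeFitResults, n_boot: int = 200,
                          seed: int = 0) -> TubeFitResults:
    """Attach residual-resampling bootstrap standard errors to a fit."""
    if not fit.converged:
        warnings.warn("bootstrapping a fit that did not formally converge",
                      RuntimeWarning)
    return fit.bootstrap(n_boot=n_boot, seed=seed)


def _derived(estimates: Dict[str, float], K: float, name: str) -> float:
    if name == "K":
        return K
    if name == "inv_lam_min":
        return 60.0 / estimates["lam"]
    return estimates[name]


def recovery_experiment(p_true: ModelParams, ns: NoiseSpec, n_trials: int,
                        seed: int = 0, *, protocol: PressureProtocol = None,
                        free: Sequence[str] = DEFAULT_FREE,
                        n_starts: int = 32, n_boot: int = 0,
                        extra: Sequence[str] = ("K", "inv_lam_min")) -> pd.DataFrame:
    """Generate-and-refit experiment measuring estimator bias and RMSE.

    Each trial generates a fresh synthetic dataset at ``p_true`` (seeds
    derived from ``seed``), fits it, and the table reports per-parameter
    bias, RMSE and (when ``n_boot > 0``) nominal-95% bootstrap coverage.
    Derived rows: ``K = mu/tau`` and ``inv_lam_min`` (the elongation
    relaxation time 1/lambda in minutes, the scale on which it is
    reported); statistics are taken over the derived per-trial values.
    """
    rows = {n: [] for n in list(free) + list(extra)}
    cover = {n: [] for n in rows}
    for i in range(n_trials):
        trial_seed = int(seed) * 1000 + i + 1
        ds = generate_observations(p_true, protocol,
                                   ns.replace(seed=trial_seed))
        fit = fit_model(ds, free=free, p_init=p_true,
                        n_starts=n_starts, seed=trial_seed)
        if n_boot:
            fit.bootstrap(n_boot=n_boot, seed=trial_seed)
            ci = fit.conf_int()
        for n in rows:
            val = _derived(fit.estimates, fit.K, n)
            rows[n].append(val)
            if n_boot and n in (ci or {}):
                lo, hi = ci[n]
                truth = _derived({m: getattr(p_true, m) for m in free},
                                 p_true.K, n)
                cover[n].append(lo <= truth <= hi)
    p_true = p_true.with_zeta0_closure((protocol or step_protocol()).dP0)
    recs = []
    for n, vals in rows.items():
        truth = _derived({m: getattr(p_true, m) for m in free}, p_true.K, n)
        vals = np.asarray(vals)
        recs.append({
            "parameter": n, "truth": truth,
            "median": float(np.median(vals)),
            "bias": float(vals.mean() - truth),
            "rmse": float(np.sqrt(np.mean((vals - truth) ** 2))),
            "coverage": (float(np.mean(cover[n])) if cover[n] else np.nan),
            "n_trials": n_trials,
        })
    return pd.DataFrame(recs)
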