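"""Fitting the proliferation model to labeling data.

The cost is a replicate-SD-weighted squared deviation,

    chi(theta) = sum_i (d_i - m_i)^2 / sigma_i^2,

over the ten observations of a group, with model predictions m_i and
data d_i on a common (BrdU-comparable) scale: raw CldU/IdU ratios are
multiplied by the detection scale eta, and values already stored with
the conventional 3-fold rescaling by eta/3.  Sampling targets
``exp(-level * chi)`` where ``level`` in (0, 1] tempers the cost; the
untempered posterior is the level-1.0 chain.

``parallel_tempering_fit`` runs ten tempered random-walk Metropolis
chains (levels 0.1 .. 1.0) with replica-exchange swaps every 20 steps to
locate the global cost minimum, then a single untempered production
chain started from the optimum for posterior means and SDs.

``model_probability`` holds the quiescent:active ratio f fixed (the
model index), runs the tempered chains *without* swaps, and estimates
the log-evidence by thermodynamic integration of the temperature-averaged
cost over the ladder (trapezoidal rule).  ``evidence_profile`` normalizes
those evidences over a grid of f values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import StudyDataset
from .kinetics import PARAM_NAMES, ModelParameters

__all__ = [
    "DEFAULT_BOUNDS",
    "PRINTED_SCALE",
    "FitConfig",
    "FitResult",
    "EvidenceProfile",
    "CostFunction",
    "cost",
    "parallel_tempering_fit",
    "model_probability",
    "evidence_profile",
]

#: Box constraints enclosing plausible physiology (days / per-day units).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "f": (0.0, 200.0),
    "r0": (0.0, 1.0),
    "t_rise": (-5.0, 30.0),
    "t_fall": (-5.0, 30.0),
    "tau_rise": (0.05, 20.0),
    "tau_fall": (0.05, 20.0),
    "eta": (0.5, 10.0),
}

#: Conventional detection rescaling already applied to stored CldU/IdU values.
PRINTED_SCALE = 3.0

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


class _Geometry:
    """Precomputed quadrature layout for one set of observations.

    Splits the experiment time axis at every protocol knot (window edges,
    measure days, the shared origin), lays 16-point Gauss-Legendre panels
    of at most 0.5 d on each piece, and exposes a vectorized map from a
    parameter matrix (one row per chain) to predicted labeling ratios in
    percent.
    """

    def __init__(self, cells, max_panel: float = 0.5):
        cells = [
            (o.protocol, o.analog) if hasattr(o, "protocol") else tuple(o)
            for o in cells
        ]
        knots = set()
        for proto, analog in cells:
            a, b = proto.window(analog)
            knots.update((a, b, proto.measure_day))
        self.origin = min(knots)
        knots.add(self.origin)
        self.knots = np.array(sorted(knots))
        nodes, weights, panel_end_knot = [], [], []
        for k in range(len(self.knots) - 1):
            a, b = self.knots[k], self.knots[k + 1]
            n_sub = max(1, int(np.ceil((b - a) / max_panel)))
            edges = np.linspace(a, b, n_sub + 1)
            for j in range(n_sub):
                half = 0.5 * (edges[j + 1] - edges[j])
                mid = 0.5 * (edges[j + 1] + edges[j])
                nodes.append(mid + half * _GL_NODES)
                weights.append(half * _GL_WEIGHTS)
                panel_end_knot.append(k + 1)
        self.nodes = np.concatenate(nodes)
        w = np.concatenate(weights)
        # W[k] accumulates int r ds from the origin up to knot k.
        n_knots = len(self.knots)
        W = np.zeros((n_knots, len(self.nodes)))
        for p, k_end in enumerate(panel_end_knot):
            sl = slice(p * 16, (p + 1) * 16)
            W[k_end:, sl] = w[sl]
        self.W = W
        idx = {t: i for i, t in enumerate(self.knots)}
        self.ia = np.array([idx[p.window(a)[0]] for p, a in cells])
        self.ib = np.array([idx[p.window(a)[1]] for p, a in cells])
        self.im = np.array([idx[p.measure_day] for p, a in cells])

    def predict_many(self, theta: np.ndarray) -> np.ndarray:
        """Predicted ratios in percent; theta is (n_chains, 7)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        f = theta[:, 0:1]
        r0 = theta[:, 1:2]
        t_rise, t_fall = theta[:, 2:3], theta[:, 3:4]
        tau_rise, tau_fall = theta[:, 4:5], theta[:, 5:6]
        t = self.nodes[None, :]
        with np.errstate(over="ignore"):
            rate = r0 / (
                (1.0 + np.exp(-(t - t_rise) / tau_rise))
                * (1.0 + np.exp((t - t_fall) / tau_fall))
            )
        cum = rate @ self.W.T  # (n_chains, n_knots)
        n_active = np.exp(-cum)
        labeled = 2.0 * (n_active[:, self.ia] - n_active[:, self.ib])
        total = f + 2.0 - n_active[:, self.im]
        return 100.0 * labeled / total

    def predict(self, params: ModelParameters) -> np.ndarray:
        return self.predict_many(params.to_array()[None, :])[0]


class CostFunction:
    """Weighted squared-deviation cost for one dataset.

    ``sigma_min`` floors the (scaled) replicate SDs, in percentage
    points, to keep weights finite; pass ``None`` to forbid zero SDs
    outright.
    """

    def __init__(self, dataset: StudyDataset, sigma_min: float | None = 0.1):
        self.dataset = dataset
        self.geometry = _Geometry(dataset)
        self.sigma_min = sigma_min
        self._mean = np.array([o.mean_ratio for o in dataset])
        self._sd = np.array([o.sd_ratio for o in dataset])
        # eta exponent: 0 for BrdU, 1 for raw CldU/IdU; printed values
        # already carry PRINTED_SCALE, so they rescale by eta/3.
        self._eta_factor_base = np.array(
            [
                1.0 if o.analog == "BrdU"
                else (1.0 / PRINTED_SCALE if o.scale_applied else 1.0)
                for o in dataset
            ]
        )
        self._is_dual = np.array([o.analog != "BrdU" for o in dataset])
        if sigma_min is None and np.any(self._sd == 0.0):
            raise ValueError(
                "zero replicate SD present; set sigma_min to floor the weights"
            )

    def _scaled_data(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        factor = np.where(self._is_dual, self._eta_factor_base * eta, 1.0)
        d = self._mean * factor
        s = self._sd * factor
        if self.sigma_min is not None:
            s = np.maximum(s, self.sigma_min)
        return d, s

    def many(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        m = self.geometry.predict_many(theta)
        d, s = self._scaled_data(theta[:, 6:7])
        return np.sum(((d - m) / s) ** 2, axis=1)

    def __call__(self, params: ModelParameters) -> float:
        return float(self.many(params.to_array()[None, :])[0])

    def predictions(self, params: ModelParameters) -> np.ndarray:
        """Model ratios (percent, BrdU-comparable scale) at ``params``."""
        return self.geometry.predict(params)


def cost(params: ModelParameters, dataset: StudyDataset, sigma_min: float | None = 0.1) -> float:
    """chi = sum_i (d_i - m_i)^2 / sigma_i^2 for one parameter set."""
    return CostFunction(dataset, sigma_min=sigma_min)(params)


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    The default ladder is ten levels 0.1 .. 1.0 (spacing 0.1), with
    replica-exchange swap attempts every 20 steps during equilibration
    and a single untempered production chain for posterior statistics.
    """

    temperatures: tuple[float, ...] = tuple(round(0.1 * k, 10) for k in range(1, 11))
    swap_interval: int = 20
    n_equilibration: int = 200_000
    n_production: int = 100_000
    proposal_scales: dict | None = None
    bounds: dict | None = None
    seed: int = 0
    eta_policy: str = "fixed"  # "fixed" | "free"
    eta_fixed: float = 3.0
    sigma_min: float | None = 0.1
    adapt_interval: int = 500
    thin: int | None = None
    n_replicas: int = 4

    def __post_init__(self) -> None:
        ladder = np.asarray(self.temperatures, dtype=float)
        if ladder.ndim != 1 or len(ladder) < 1 or np.any(np.diff(ladder) <= 0):
            raise ValueError("temperature ladder must be strictly increasing")
        if self.swap_interval < 1:
            raise ValueError("swap_interval must be >= 1")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.eta_policy not in ("fixed", "free"):
            raise ValueError("eta_policy must be 'fixed' or 'free'")
        for name, (lo, hi) in self.resolved_bounds().items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lo < hi")

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        out = dict(DEFAULT_BOUNDS)
        if self.bounds:
            out.update({k: tuple(v) for k, v in self.bounds.items()})
        return out

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "temperatures" in raw:
            raw["temperatures"] = tuple(raw["temperatures"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperatures"] = list(self.temperatures)
        return d


@dataclass
class FitResult:
    """Outcome of a parallel-tempering fit."""

    best_params: ModelParameters
    best_cost: float
    posterior_mean: dict[str, float]
    posterior_sd: dict[str, float]
    acceptance_rates: np.ndarray
    swap_rate: float
    predicted_ratios: np.ndarray
    seed: int
    free_names: tuple[str, ...]
    samples: np.ndarray  # thinned production samples, full 7-column order
    warnings: list[str] = field(default_factory=list)

    def sample_parameters(self) -> list[ModelParameters]:
        return [ModelParameters.from_array(row) for row in self.samples]

    def to_dict(self) -> dict:
        return {
            "best_params": dict(zip(PARAM_NAMES, self.best_params.to_array())),
            "best_cost": self.best_cost,
            "posterior_mean": self.posterior_mean,
            "posterior_sd": self.posterior_sd,
            "acceptance_rates": list(np.asarray(self.acceptance_rates, dtype=float)),
            "swap_rate": self.swap_rate,
            "predicted_ratios": list(np.asarray(self.predicted_ratios, dtype=float)),
            "seed": self.seed,
            "free_names": list(self.free_names),
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def chain_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(PARAM_NAMES))


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold proposals back into the box (reflecting boundaries)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def _free_indices(config: FitConfig, f_fixed: float | None) -> list[int]:
    names = list(PARAM_NAMES[:6])
    if f_fixed is not None:
        names.remove("f")
    if config.eta_policy == "free":
        names.append("eta")
    return [PARAM_NAMES.index(n) for n in names]


def swap_probability(level_i: float, level_j: float, cost_i: float, cost_j: float) -> float:
    """Replica-exchange acceptance probability for two tempered chains."""
    log_p = (level_i - level_j) * (cost_i - cost_j)
    return 1.0 if log_p >= 0 else float(np.exp(log_p))


#: Parameters random-walked on a log scale (positive scale parameters).
_LOG_WALK = ("tau_rise", "tau_fall")


class _Sampler:
    """Vectorized ensemble of tempered random-walk Metropolis chains.

    ``levels`` may concatenate several independent copies of the ladder
    (``replica_size`` chains each); swaps are attempted within each copy
    only.  The tau time scales are proposed with a log-normal walk (with
    the corresponding Hastings factor), which explores sharp-onset
    solutions near the lower tau bound far better than a linear walk.
    """

    def __init__(
        self,
        costfn: CostFunction,
        config: FitConfig,
        levels: np.ndarray,
        rng: np.random.Generator,
        f_fixed: float | None = None,
        replica_size: int | None = None,
    ):
        self.costfn = costfn
        self.config = config
        self.levels = np.asarray(levels, dtype=float)
        self.rng = rng
        self.replica_size = replica_size or len(self.levels)
        self.free = np.array(_free_indices(config, f_fixed))
        self.log_dims = np.array(
            [i for i in self.free if PARAM_NAMES[i] in _LOG_WALK]
        )
        self.lin_dims = np.array(
            [i for i in self.free if PARAM_NAMES[i] not in _LOG_WALK]
        )
        bounds = config.resolved_bounds()
        self.lo = np.array([bounds[n][0] for n in PARAM_NAMES])
        self.hi = np.array([bounds[n][1] for n in PARAM_NAMES])
        n_chains = len(self.levels)

        def draw(n):
            t = self.lo + (self.hi - self.lo) * rng.uniform(size=(n, len(PARAM_NAMES)))
            if config.eta_policy == "fixed":
                t[:, 6] = config.eta_fixed
            if f_fixed is not None:
                t[:, 0] = f_fixed
            return t

        theta = draw(n_chains)
        chi = costfn.many(theta)
        for _ in range(100):
            bad = ~np.isfinite(chi)
            if not bad.any():
                break
            theta[bad] = draw(int(bad.sum()))
            chi = costfn.many(theta)
        if not np.all(np.isfinite(chi)):
            raise RuntimeError("could not find finite-cost starting points")
        self.theta = theta
        self.chi = chi
        base = config.proposal_scales or {}
        default_scale = []
        for n in PARAM_NAMES:
            lo, hi = bounds[n]
            if n in base:
                default_scale.append(base[n])
            elif n in _LOG_WALK:
                default_scale.append(0.1 * (np.log(hi) - np.log(lo)))
            else:
                default_scale.append(0.1 * (hi - lo))
        self.scales = np.tile(np.array(default_scale), (n_chains, 1))
        self.best_theta = theta[np.argmin(chi)].copy()
        self.best_chi = float(np.min(chi))
        self.accept_count = np.zeros(n_chains)
        self.window_accept = np.zeros(n_chains)
        self.swap_attempts = 0
        self.swap_accepts = 0
        self.steps_done = 0
        # optional correlated proposal: Cholesky factor of the empirical
        # parameter covariance in transformed (log-tau) coordinates, with
        # a per-chain scalar step multiplier
        self.chol: np.ndarray | None = None
        self.step = np.ones(n_chains)

    def _to_transformed(self, theta: np.ndarray) -> np.ndarray:
        y = theta[:, self.free].copy()
        for k, dim in enumerate(self.free):
            if dim in self.log_dims:
                y[:, k] = np.log(y[:, k])
        return y

    def transformed_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.lo[self.free].copy()
        hi = self.hi[self.free].copy()
        for k, dim in enumerate(self.free):
            if dim in self.log_dims:
                lo[k], hi[k] = np.log(lo[k]), np.log(hi[k])
        return lo, hi

    def _propose(self, n_chains: int):
        """Random-walk proposal; returns (theta', log Hastings ratio)."""
        prop = self.theta.copy()
        hastings = np.zeros(n_chains)
        lin, logd = self.lin_dims, self.log_dims
        if self.chol is not None:
            y = self._to_transformed(self.theta)
            z = self.rng.standard_normal((n_chains, y.shape[1]))
            jump = (z @ self.chol.T) * self.step[:, None]
            t_lo, t_hi = self.transformed_bounds()
            y_new = _reflect(y + jump, t_lo, t_hi)
            for k, dim in enumerate(self.free):
                if dim in self.log_dims:
                    prop[:, dim] = np.exp(y_new[:, k])
                    hastings += y_new[:, k] - y[:, k]
                else:
                    prop[:, dim] = y_new[:, k]
            return prop, hastings
        if lin.size:
            jump = self.rng.standard_normal((n_chains, lin.size)) * self.scales[:, lin]
            prop[:, lin] = _reflect(self.theta[:, lin] + jump, self.lo[lin], self.hi[lin])
        if logd.size:
            y = np.log(self.theta[:, logd])
            jump = self.rng.standard_normal((n_chains, logd.size)) * self.scales[:, logd]
            y_new = _reflect(y + jump, np.log(self.lo[logd]), np.log(self.hi[logd]))
            prop[:, logd] = np.exp(y_new)
            # log-normal walk on a uniform-in-x target: q(x|x')/q(x'|x) = x'/x
            hastings = np.sum(y_new - y, axis=1)
        return prop, hastings

    def run(
        self,
        n_steps: int,
        adapt: bool,
        swaps: bool,
        record: bool = False,
        record_cost: bool = False,
        record_multi: np.ndarray | None = None,
        record_stride: int = 5,
    ):
        cfg = self.config
        n_chains, n_par = self.theta.shape
        n_replicas = n_chains // self.replica_size
        trace = np.empty((n_steps, n_par)) if record else None
        cost_trace = np.empty((n_steps, n_chains)) if record_cost else None
        multi = (
            np.empty((n_steps // record_stride, len(record_multi), n_par))
            if record_multi is not None
            else None
        )
        window = 0
        for step in range(n_steps):
            prop, hastings = self._propose(n_chains)
            chi_prop = self.costfn.many(prop)
            logu = np.log(self.rng.uniform(size=n_chains))
            ok = logu < -self.levels * (chi_prop - self.chi) + hastings
            ok &= np.isfinite(chi_prop)
            self.theta[ok] = prop[ok]
            self.chi[ok] = chi_prop[ok]
            self.accept_count += ok
            self.window_accept += ok
            window += 1
            i_best = int(np.argmin(self.chi))
            if self.chi[i_best] < self.best_chi:
                self.best_chi = float(self.chi[i_best])
                self.best_theta = self.theta[i_best].copy()
            if swaps and self.replica_size > 1 and (step + 1) % cfg.swap_interval == 0:
                for r in range(n_replicas):
                    base = r * self.replica_size
                    i, j = base + self.rng.choice(
                        self.replica_size, size=2, replace=False
                    )
                    self.swap_attempts += 1
                    p = swap_probability(
                        self.levels[i], self.levels[j], self.chi[i], self.chi[j]
                    )
                    if self.rng.uniform() < p:
                        self.swap_accepts += 1
                        self.theta[[i, j]] = self.theta[[j, i]]
                        self.chi[[i, j]] = self.chi[[j, i]]
            if adapt and (step + 1) % cfg.adapt_interval == 0:
                rate = self.window_accept / window
                factor = np.where(rate > 0.4, 1.25, np.where(rate < 0.2, 0.8, 1.0))
                if self.chol is not None:
                    self.step *= factor
                else:
                    self.scales *= factor[:, None]
                    self.scales[:, self.lin_dims] = np.minimum(
                        self.scales[:, self.lin_dims],
                        (self.hi - self.lo)[None, self.lin_dims],
                    )
                self.window_accept[:] = 0.0
                window = 0
            if record:
                trace[step] = self.theta[-1]  # coldest level is last
            if record_cost:
                cost_trace[step] = self.chi
            if multi is not None and (step + 1) % record_stride == 0:
                idx = (step + 1) // record_stride - 1
                if idx < len(multi):
                    multi[idx] = self.theta[record_multi]
            self.steps_done += 1
        if multi is not None:
            return trace, cost_trace, multi
        return trace, cost_trace


def _polish(costfn: CostFunction, theta0: np.ndarray, free: np.ndarray,
            lo: np.ndarray, hi: np.ndarray, maxfev: int = 4000):
    """Deterministic simplex polish of the tempered-search optimum."""
    from scipy import optimize

    def fun(x):
        th = theta0.copy()
        th[free] = np.clip(x, lo[free], hi[free])
        return costfn.many(th[None, :])[0]

    res = optimize.minimize(
        fun,
        theta0[free],
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-8, "fatol": 1e-10},
    )
    theta = theta0.copy()
    theta[free] = np.clip(res.x, lo[free], hi[free])
    return theta, float(costfn.many(theta[None, :])[0])


def _split_half_warning(values: np.ndarray, label: str) -> str | None:
    half = len(values) // 2
    if half < 10:
        return None
    a, b = values[:half], values[half:]
    pooled = np.sqrt(0.5 * (a.var() + b.var())) + 1e-12
    if abs(a.mean() - b.mean()) > 0.5 * pooled:
        return (
            f"{label}: split-half means differ "
            f"({a.mean():.3g} vs {b.mean():.3g}); chain may not be converged"
        )
    return None


def parallel_tempering_fit(
    dataset: StudyDataset,
    config: FitConfig | None = None,
    f_fixed: float | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit the model by parallel tempering, then sample the posterior.

    Equilibration runs ``n_replicas`` independent copies of the tempered
    ladder with swaps and proposal adaptation to locate the global cost
    minimum.  Production restarts one ladder from the optimum (swaps on,
    adaptation off); the untempered level-1.0 chain supplies the
    posterior means and SDs.  Bit-for-bit reproducible given
    ``config.seed``.
    """
    config = config or FitConfig()
    costfn = CostFunction(dataset, sigma_min=config.sigma_min)
    rng = rng or np.random.default_rng(config.seed)
    ladder = np.asarray(config.temperatures, dtype=float)
    levels = np.tile(ladder, config.n_replicas)
    sampler = _Sampler(
        costfn, config, levels, rng, f_fixed=f_fixed, replica_size=len(ladder)
    )
    n_first = (2 * config.n_equilibration) // 3
    sampler.run(n_first, adapt=True, swaps=True)
    # record the cold chain of every replica over the late equilibration
    # to estimate the posterior covariance for the production proposals
    cold_idx = np.arange(1, config.n_replicas + 1) * len(ladder) - 1
    _, _, late = sampler.run(
        config.n_equilibration - n_first,
        adapt=True,
        swaps=True,
        record_multi=cold_idx,
    )
    acceptance = sampler.accept_count / max(1, sampler.steps_done)
    swap_rate = sampler.swap_accepts / max(1, sampler.swap_attempts)

    # deterministic simplex polish of the search optimum
    free_idx = np.array(_free_indices(config, f_fixed))
    bounds_arr = config.resolved_bounds()
    lo_arr = np.array([bounds_arr[n][0] for n in PARAM_NAMES])
    hi_arr = np.array([bounds_arr[n][1] for n in PARAM_NAMES])
    polished, polished_chi = _polish(costfn, sampler.best_theta, free_idx, lo_arr, hi_arr)
    if np.isfinite(polished_chi) and polished_chi < sampler.best_chi:
        sampler.best_theta = polished
        sampler.best_chi = polished_chi

    # Production: one tempered ladder restarted from the optimum, swaps
    # kept on (replica exchange preserves the per-level marginals), with
    # posterior statistics read off the untempered level-1.0 chain.
    # Proposals are correlated Gaussian jumps shaped by the empirical
    # covariance of the late-equilibration cold chains (log scale for the
    # tau parameters), with per-chain step multipliers tuned during a
    # short discarded warmup.
    cold = _Sampler(costfn, config, ladder, rng, f_fixed=f_fixed)
    cold.theta[:] = sampler.best_theta
    cold.chi[:] = costfn.many(cold.theta)
    cold.scales[:] = sampler.scales[-len(ladder):]
    cold.best_theta = sampler.best_theta.copy()
    cold.best_chi = sampler.best_chi
    pooled = late.reshape(-1, late.shape[-1])
    y = cold._to_transformed(pooled)
    d_free = y.shape[1]
    cov = np.cov(y, rowvar=False) if len(y) > 2 * d_free else np.eye(d_free)
    cov = np.atleast_2d(cov)
    t_lo, t_hi = cold.transformed_bounds()
    jitter = 1e-12 + 1e-6 * np.mean((t_hi - t_lo) ** 2)
    try:
        cold.chol = np.linalg.cholesky(cov + jitter * np.eye(d_free))
    except np.linalg.LinAlgError:
        cold.chol = np.diag(t_hi - t_lo) * 0.05
    cold.step[:] = 2.38 / np.sqrt(d_free)
    n_warm = min(max(config.adapt_interval, config.n_production // 5), 5000)
    cold.run(n_warm, adapt=True, swaps=True)
    trace, cost_trace = cold.run(
        config.n_production, adapt=False, swaps=True, record=True, record_cost=True
    )

    free = _free_indices(config, f_fixed)
    names = tuple(PARAM_NAMES[i] for i in free)
    posterior_mean = {n: float(trace[:, i].mean()) for n, i in zip(names, free)}
    posterior_sd = {n: float(trace[:, i].std(ddof=1)) for n, i in zip(names, free)}
    warn_msgs = []
    msg = _split_half_warning(cost_trace[:, -1], "production cost")
    if msg:
        warn_msgs.append(msg)

    best = ModelParameters.from_array(cold.best_theta)
    thin = config.thin or max(1, config.n_production // 5000)
    result = FitResult(
        best_params=best,
        best_cost=cold.best_chi,
        posterior_mean=posterior_mean,
        posterior_sd=posterior_sd,
        acceptance_rates=acceptance,
        swap_rate=float(swap_rate),
        predicted_ratios=costfn.predictions(best),
        seed=config.seed,
        free_names=names,
        samples=trace[::thin].copy(),
        warnings=warn_msgs,
    )
    for m in warn_msgs:
        warnings.warn(m, stacklevel=2)
    return result


def model_probability(
    dataset: StudyDataset,
    f_fixed: float,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Log model evidence for the model indexed by a fixed f.

    Runs the tempered chains without replica exchange, averages the cost
    at each ladder level over the measurement phase, and integrates
    d(log Z)/d(level) = -<chi> across the ladder by the trapezoidal
    rule.  The constant prior-volume term is omitted; it is common to
    every f and cancels in normalized profiles.
    """
    config = config or FitConfig()
    costfn = CostFunction(dataset, sigma_min=config.sigma_min)
    rng = rng or np.random.default_rng(config.seed)
    levels = np.asarray(config.temperatures, dtype=float)
    sampler = _Sampler(costfn, config, levels, rng, f_fixed=f_fixed)
    burn = max(config.adapt_interval, config.n_equilibration // 2)
    sampler.run(burn, adapt=True, swaps=False)
    _, cost_trace = sampler.run(
        config.n_production, adapt=False, swaps=False, record_cost=True
    )
    avg_cost = cost_trace.mean(axis=0)
    msg = _split_half_warning(cost_trace[:, -1], f"evidence chains (f={f_fixed:g})")
    if msg:
        warnings.warn(msg, stacklevel=2)
    return float(-np.trapezoid(avg_cost, levels))


@dataclass(frozen=True)
class EvidenceProfile:
    """Model probability as a function of the fixed quiescent:active ratio."""

    f_grid: np.ndarray
    log_evidence: np.ndarray
    normalized_probability: np.ndarray

    @property
    def mode(self) -> float:
        return float(self.f_grid[int(np.argmax(self.normalized_probability))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f": self.f_grid,
                "log_evidence": self.log_evidence,
                "probability": self.normalized_probability,
            }
        )


def evidence_profile(
    dataset: StudyDataset,
    f_grid: Sequence[float],
    config: FitConfig | None = None,
) -> EvidenceProfile:
    """Normalized model probabilities over a grid of fixed f values."""
    f_grid = np.asarray(list(f_grid), dtype=float)
    if f_grid.size == 0:
        raise ValueError("f_grid must be non-empty")
    if np.any(f_grid < 0):
        raise ValueError("f values must be non-negative")
    config = config or FitConfig()
    log_ev = np.empty_like(f_grid)
    for i, f in enumerate(f_grid):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        )
        log_ev[i] = model_probability(dataset, float(f), config, rng=rng)
    shifted = log_ev - log_ev.max()
    prob = np.exp(shifted)
    prob /= prob.sum()
    return EvidenceProfile(f_grid=f_grid, log_evidence=log_ev, normalized_probability=prob)
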