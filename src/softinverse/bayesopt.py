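"""Gradient-free batch Bayesian optimization with a random-forest surrogate.

The optimizer follows the batch-sequential efficient-global-optimization
pattern: an initial space-filling design is evaluated, a random forest is fit
to the (configuration, loss) archive, and each iteration proposes a batch of
q candidates, the i-th maximizing the moment-generating-function (MGF)
acquisition under its own temperature t_i drawn from Lognormal(0, 1).  Large
temperatures reward predictive uncertainty (exploration), small ones reward
low predicted loss (exploitation); at t = 0 the criterion reduces exactly to
the probability of improvement.  The acquisition is maximized by a
(μ+λ) evolution strategy with self-adaptive Gaussian mutation, run in
encoded coordinates.

Encodings: each search dimension is either ``linear`` or ``log10``; moduli
spanning many decades are searched in log10 space.  Internally every
dimension is scaled to [0, 1].

Losses are modelled on a log10 scale (a strictly monotone transform, so the
argmin is unchanged); this resolves the many-decade dynamic range of
squared-deformation losses near and far from the optimum far better than the
raw scale, and the MGF temperature then acts on comparable magnitudes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc

log = logging.getLogger(__name__)

__all__ = [
    "SearchSpace",
    "Dimension",
    "Configuration",
    "SurrogatePrediction",
    "OptimizerConfig",
    "ConvergenceHistory",
    "ForestSurrogate",
    "fit_surrogate",
    "InsufficientDataError",
    "mgf_acquisition",
    "log_mgf_acquisition",
    "sample_temperature",
    "propose_batch",
    "optimize",
]

_LOSS_FLOOR = 1e-300  # additive floor inside log10 so an exact zero loss is finite


class InsufficientDataError(ValueError):
    """Surrogate fitting requires at least two evaluated points."""


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    encoding: str = "linear"  # "linear" | "log10"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: need lower < upper")
        if self.encoding not in ("linear", "log10"):
            raise ValueError(f"{self.name}: unknown encoding {self.encoding!r}")
        if self.encoding == "log10" and self.lower <= 0.0:
            raise ValueError(f"{self.name}: log10 encoding needs positive bounds")


@dataclass
class SearchSpace:
    """Ordered collection of bounded, encoded search dimensions."""

    dimensions: list

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("search space must have >= 1 dimension")

    @property
    def names(self):
        return [d.name for d in self.dimensions]

    @property
    def n_dim(self) -> int:
        return len(self.dimensions)

    def encode(self, values: np.ndarray) -> np.ndarray:
        """Physical values (…, d) -> unit-cube coordinates (…, d)."""
        values = np.asarray(values, dtype=float)
        out = np.empty_like(values)
        for j, dim in enumerate(self.dimensions):
            v = values[..., j]
            if dim.encoding == "log10":
                lo, hi = np.log10(dim.lower), np.log10(dim.upper)
                out[..., j] = (np.log10(v) - lo) / (hi - lo)
            else:
                out[..., j] = (v - dim.lower) / (dim.upper - dim.lower)
        return out

    def decode(self, unit: np.ndarray) -> np.ndarray:
        """Unit-cube coordinates (…, d) -> physical values (…, d)."""
        unit = np.asarray(unit, dtype=float)
        out = np.empty_like(unit)
        for j, dim in enumerate(self.dimensions):
            z = unit[..., j]
            if dim.encoding == "log10":
                lo, hi = np.log10(dim.lower), np.log10(dim.upper)
                out[..., j] = 10.0 ** (lo + z * (hi - lo))
            else:
                out[..., j] = dim.lower + z * (dim.upper - dim.lower)
        return out

    def as_dict(self, values) -> dict:
        return dict(zip(self.names, np.asarray(values, dtype=float)))


@dataclass
class Configuration:
    """A decision vector in both unit-encoded and physical coordinates."""

    encoded: np.ndarray
    values: np.ndarray
    names: list

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


@dataclass
class SurrogatePrediction:
    mean: np.ndarray
    variance: np.ndarray


@dataclass
class OptimizerConfig:
    """Loop parameters: batch size q, initial design n0, evaluation budget N.

    ``budget`` counts objective evaluations (initial design included); with
    ``budget == n_initial`` only the space-filling design is evaluated.  The
    temperature mode is ``"sampled"`` (t ~ Lognormal(0,1), one per batch
    member) or ``"fixed"`` (t = ``t_fixed`` for every member).
    """

    batch_size: int = 8
    n_initial: int | None = None  # default 2 d + 2
    budget: int = 100
    seed: int = 0
    t_mode: str = "sampled"
    t_fixed: float = 2.0
    n_jobs: int = 1
    convergence_tol: float = 0.0  # absolute loss threshold for early stop

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size q must be >= 1")
        if self.n_initial is not None and self.n_initial < 2:
            raise ValueError("initial design needs >= 2 points")
        if self.t_mode not in ("sampled", "fixed"):
            raise ValueError(f"unknown temperature mode {self.t_mode!r}")


@dataclass
class ConvergenceHistory:
    """Archive of evaluated configurations with the best-so-far trace."""

    X: np.ndarray  # encoded coordinates (n, d)
    values: np.ndarray  # physical coordinates (n, d)
    losses: np.ndarray  # raw losses (n,)
    best_so_far: np.ndarray  # non-increasing trace (n,)
    temperatures: np.ndarray  # acquisition temperature per point (nan = initial)
    iterations: np.ndarray  # batch index per point (0 = initial design)
    names: list = field(default_factory=list)

    @property
    def best_index(self) -> int:
        return int(np.nanargmin(self.losses))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "iteration", self.iterations)
        df["loss"] = self.losses
        df["temperature"] = self.temperatures
        df["best_so_far"] = self.best_so_far
        return df


class ForestSurrogate:
    """Random-forest surrogate with tree-spread predictive variance.

    100 bootstrapped trees; the predictive mean is the forest mean and the
    empirical variance s²(x) is the variance of the individual tree
    predictions, floored at (1e-12)² to keep the acquisition finite.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0):
        from sklearn.ensemble import RandomForestRegressor

        self._rf = RandomForestRegressor(
            n_estimators=n_trees, bootstrap=True, random_state=int(seed) % (2**32)
        )
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ForestSurrogate":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < 2 or len(np.unique(y)) < 1:
            raise InsufficientDataError("need at least 2 evaluated points")
        self._rf.fit(X, y)
        # cache per-tree leaf values so prediction is a single apply() pass
        self._leaf_values = [
            t.tree_.value[:, 0, 0] for t in self._rf.estimators_
        ]
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> SurrogatePrediction:
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float32)
        leaves = self._rf.apply(X)  # (n, n_trees)
        per_tree = np.empty((len(self._leaf_values), len(X)))
        for i, vals in enumerate(self._leaf_values):
            per_tree[i] = vals[leaves[:, i]]
        return SurrogatePrediction(
            mean=per_tree.mean(axis=0), variance=per_tree.var(axis=0)
        )


def fit_surrogate(X, losses, seed: int = 0, n_trees: int = 100) -> ForestSurrogate:
    """Fit the random-forest surrogate on (encoded X, transformed losses)."""
    return ForestSurrogate(n_trees=n_trees, seed=seed).fit(X, losses)


def sample_temperature(rng: np.random.Generator, size=None):
    """Acquisition temperature t ~ Lognormal(0, 1) (median 1, mean e^0.5)."""
    return rng.lognormal(mean=0.0, sigma=1.0, size=size)


def log_mgf_acquisition(mean, sd, loss_min, t):
    """log of the MGF acquisition (numerically safe form).

    M(x, t) = Φ((L_min − L̂′)/s) · exp((L_min − L̂ − 1)t + s²t²/2),
    L̂′ = L̂ − s²t.  Evaluated as log Φ + exponent; sd is floored at 1e-12.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.maximum(np.asarray(sd, dtype=float), 1e-12)
    t = float(t)
    z = (loss_min - (mean - sd**2 * t)) / sd
    expo = (loss_min - mean - 1.0) * t + 0.5 * sd**2 * t**2
    return norm.logcdf(z) + np.clip(expo, -1e300, 700.0)


def mgf_acquisition(prediction: SurrogatePrediction, loss_min: float, t: float):
    """MGF acquisition on the natural scale (may underflow to 0 for poor x)."""
    lm = log_mgf_acquisition(
        prediction.mean, np.sqrt(prediction.variance), loss_min, t
    )
    with np.errstate(over="ignore"):
        return np.exp(lm)


def _transform_losses(losses: np.ndarray) -> tuple[np.ndarray, float]:
    """log10 loss transform with +inf (failed evaluations) mapped above max."""
    y = np.log10(np.maximum(losses, 0.0) + _LOSS_FLOOR)
    finite = np.isfinite(y)
    if not finite.all():
        ceil = y[finite].max() if finite.any() else 0.0
        y = np.where(finite, y, ceil + 2.0)
    return y, float(y.min())


def propose_batch(
    surrogate: ForestSurrogate,
    space: SearchSpace,
    q: int,
    loss_min: float,
    rng: np.random.Generator,
    temperatures=None,
    X_archive=None,
    y_archive=None,
    n_parents: int = 4,
    n_offspring: int = 28,
    n_generations: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Propose q encoded configurations maximizing the MGF acquisition.

    The i-th batch member maximizes M(·, t_i) with its own temperature using
    a (μ+λ) evolution strategy with self-adaptive per-dimension step sizes.
    All q strategies run in lockstep so the forest is queried once per
    generation.  Parents are seeded with the best archived points (when
    given) plus uniform random points.  Proposals that exactly duplicate an
    archived point are re-mutated once, then accepted.

    Returns (proposals (q, d) encoded, temperatures (q,)).
    """
    d = space.n_dim
    if temperatures is None:
        temperatures = sample_temperature(rng, size=q)
    temperatures = np.asarray(temperatures, dtype=float)

    mu_p, lam_o = n_parents, n_offspring
    tau = 1.0 / np.sqrt(2.0 * d)

    # initial parents: best archive points + uniform random.  The archive
    # seeds start with step sizes set by the incumbent's distance to the
    # nearest point of meaningfully different objective value, so local
    # refinement keeps pace with the resolved structure of the landscape (a
    # self-shrinking trust region that cannot collapse onto near-duplicate
    # re-evaluations of the incumbent).
    P = rng.random((q, mu_p, d))
    sig = np.full((q, mu_p, d), 0.1)
    seed_sig = np.full(d, 0.1)
    if X_archive is not None and len(X_archive) > 1 and y_archive is not None:
        Xa = np.asarray(X_archive)
        ya = np.asarray(y_archive)
        order = np.argsort(ya)
        k = min(2, len(order))
        y_best = ya[order[0]]
        spread = float(ya.max() - y_best)
        distinct = (ya - y_best) > max(1e-12, 1e-3 * spread)
        if distinct.any():
            dist = np.linalg.norm(Xa[distinct] - Xa[order[0]], axis=1)
            seed_sig = np.full(d, float(np.clip(dist.min(), 1e-9, 0.1)))
        for i in range(q):
            P[i, :k] = Xa[order[:k]]
            sig[i, :k] = seed_sig

    def acq(points):  # points (q, m, d) -> (q, m)
        flat = points.reshape(-1, d)
        pred = surrogate.predict(flat)
        vals = np.empty(len(flat))
        sdev = np.sqrt(pred.variance)
        for i in range(q):
            sl = slice(i * points.shape[1], (i + 1) * points.shape[1])
            vals[sl] = log_mgf_acquisition(
                pred.mean[sl], sdev[sl], loss_min, temperatures[i]
            )
        return vals.reshape(points.shape[:2])

    fP = acq(P)
    for _ in range(n_generations):
        idx = rng.integers(0, mu_p, size=(q, lam_o))
        take = np.take_along_axis  # parent selection per member
        par = take(P, idx[..., None], axis=1)
        psig = take(sig, idx[..., None], axis=1)
        csig = psig * np.exp(tau * rng.standard_normal((q, lam_o, d)))
        csig = np.clip(csig, 1e-9, 0.5)
        child = np.clip(par + csig * rng.standard_normal((q, lam_o, d)), 0.0, 1.0)
        fC = acq(child)
        allP = np.concatenate([P, child], axis=1)
        allS = np.concatenate([sig, csig], axis=1)
        allF = np.concatenate([fP, fC], axis=1)
        sel = np.argsort(-allF, axis=1)[:, :mu_p]
        P = take(allP, sel[..., None], axis=1)
        sig = take(allS, sel[..., None], axis=1)
        fP = take(allF, sel, axis=1)
    best = P[:, 0, :].copy()
    if X_archive is not None and len(X_archive) > 1 and q >= 2:
        # one batch member performs multi-scale local search around the
        # incumbent: a piecewise-constant forest cannot extrapolate a
        # descending trend past the sampled cluster, so this member supplies
        # that evidence at a radius drawn log-uniformly between the local
        # refinement scale and a tenth of the range
        Xa_all = np.asarray(X_archive)
        incumbent = Xa_all[int(np.argmin(np.asarray(y_archive)))]
        lo = max(float(seed_sig[0]), 1e-9)
        radius = np.exp(rng.uniform(np.log(lo), np.log(0.1)))
        best[q - 1] = np.clip(
            incumbent + radius * rng.standard_normal(d), 0.0, 1.0
        )
    if X_archive is not None and len(X_archive):
        Xa = np.asarray(X_archive)
        for i in range(q):
            if np.any(np.all(np.isclose(Xa, best[i], atol=1e-15), axis=1)):
                # duplicate of an evaluated point: re-mutate once at the local
                # refinement scale so it still probes the incumbent's region
                best[i] = np.clip(
                    best[i] + 0.5 * seed_sig * rng.standard_normal(d), 0.0, 1.0
                )
    return best, temperatures


def optimize(
    objective,
    space: SearchSpace,
    config: OptimizerConfig,
) -> tuple[Configuration, ConvergenceHistory]:
    """Run the batch surrogate-optimization loop (random-forest + MGF infill).

    ``objective`` maps a dict {dimension name: physical value} to a scalar
    loss; an exception inside it is recorded as +inf and the run continues.
    Batch members may be evaluated concurrently (``config.n_jobs``); results
    are identical to sequential evaluation for a deterministic objective.
    Stops when the budget is exhausted or the best loss falls to
    ``config.convergence_tol`` or below.
    """
    rng = np.random.default_rng(config.seed)
    d = space.n_dim
    n0 = config.n_initial if config.n_initial is not None else 2 * d + 2
    if config.budget < n0:
        raise ValueError("budget must cover the initial design (budget >= n0)")

    sampler = qmc.LatinHypercube(d=d, seed=int(rng.integers(2**31)))
    X = sampler.random(n=n0)
    rf_seed = int(rng.integers(2**31))

    def evaluate(batch_encoded):
        vals = space.decode(batch_encoded)
        results = []
        if config.n_jobs > 1:
            from joblib import Parallel, delayed

            def safe(v):
                try:
                    return float(objective(space.as_dict(v)))
                except Exception as e:  # noqa: BLE001 - must survive solver failures
                    warnings.warn(f"objective failed ({e}); recording +inf")
                    return np.inf

            results = Parallel(n_jobs=config.n_jobs)(delayed(safe)(v) for v in vals)
        else:
            for v in vals:
                try:
                    results.append(float(objective(space.as_dict(v))))
                except Exception as e:  # noqa: BLE001
                    warnings.warn(f"objective failed ({e}); recording +inf")
                    results.append(np.inf)
        return np.asarray(results, dtype=float), vals

    losses, values = evaluate(X)
    temps = np.full(n0, np.nan)
    iters = np.zeros(n0, dtype=int)

    iteration = 0
    while len(losses) < config.budget and np.nanmin(losses) > config.convergence_tol:
        iteration += 1
        y, y_min = _transform_losses(losses)
        surrogate = fit_surrogate(X, y, seed=rf_seed)
        q = min(config.batch_size, config.budget - len(losses))
        if config.t_mode == "fixed":
            t_batch = np.full(q, config.t_fixed)
            sample_temperature(rng, size=q)  # keep the stream aligned across modes
        else:
            t_batch = sample_temperature(rng, size=q)
        proposals, t_batch = propose_batch(
            surrogate, space, q, y_min, rng,
            temperatures=t_batch, X_archive=X, y_archive=y,
        )
        new_losses, new_values = evaluate(proposals)
        X = np.vstack([X, proposals])
        values = np.vstack([values, new_values])
        losses = np.concatenate([losses, new_losses])
        temps = np.concatenate([temps, t_batch])
        iters = np.concatenate([iters, np.full(q, iteration, dtype=int)])
        log.info(
            "iteration %d: best loss %.6e after %d evaluations",
            iteration, float(np.nanmin(losses)), len(losses),
        )

    best_trace = np.minimum.accumulate(np.where(np.isfinite(losses), losses, np.inf))
    hist = ConvergenceHistory(
        X=X, values=values, losses=losses, best_so_far=best_trace,
        temperatures=temps, iterations=iters, names=space.names,
    )
    b = hist.best_index
    best = Configuration(encoded=X[b], values=values[b], names=space.names)
    return best, hist
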