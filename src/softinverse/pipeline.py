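"""End-to-end inverse identification: observation -> (M*, P*, S*).

Wires the forward solver, abnormality labelling, and the batch Bayesian
optimizer into the recovery of material moduli M, abnormality position P and
shape S that jointly minimize the deformation mismatch

    L = ‖D − D̂‖²,

the squared Euclidean norm over the flattened keypoint trajectory arrays
(observed D vs simulated D̂).  Each benchmark case exposes several
"unknown sets": the free parameters of the search; everything else is fixed
at its known value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from softinverse import bayesopt
from softinverse.bayesopt import ConvergenceHistory, OptimizerConfig, SearchSpace

__all__ = [
    "ObservedDeformation",
    "RecoveryResult",
    "deformation_loss",
    "relative_error",
    "simulate_candidate",
    "run_inverse",
]


@dataclass
class ObservedDeformation:
    """Keypoint trajectory array D (steps, keypoints, components), mm.

    ``provenance`` is "synthetic" (generated by the package's own forward
    solver — the inverse-crime benchmark mode) or "external".
    """

    data: np.ndarray
    provenance: str = "synthetic"
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("observation must be (steps, keypoints, components)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("observation contains non-finite values")


@dataclass
class RecoveryResult:
    """Outcome of an inverse run with truth-relative errors when available."""

    case_name: str
    estimates: dict
    final_loss: float
    history: ConvergenceHistory
    errors: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)
    preset: str = "desk"


def deformation_loss(observed: np.ndarray, simulated: np.ndarray) -> float:
    """Squared Euclidean mismatch over all steps/keypoints/components."""
    D = np.asarray(observed, dtype=float)
    Dh = np.asarray(simulated, dtype=float)
    if D.shape != Dh.shape:
        raise ValueError(f"shape mismatch: observed {D.shape} vs simulated {Dh.shape}")
    return float(np.sum((D - Dh) ** 2))


def relative_error(estimate: float, truth: float) -> float:
    """|estimate − truth| / |truth| (undefined at truth = 0)."""
    if truth == 0.0:
        raise ZeroDivisionError("relative error undefined for zero truth")
    return abs(estimate - truth) / abs(truth)


def _align_steps(D: np.ndarray, n_steps: int) -> np.ndarray:
    """Linear interpolation in load fraction when step counts disagree."""
    have = D.shape[0] - 1
    if have == n_steps:
        return D
    warnings.warn(
        f"observation has {have} steps, solver uses {n_steps}; "
        "interpolating linearly in load fraction"
    )
    f_have = np.linspace(0.0, 1.0, have + 1)
    f_want = np.linspace(0.0, 1.0, n_steps + 1)
    flat = D.reshape(have + 1, -1)
    out = np.empty((n_steps + 1, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(f_want, f_have, flat[:, j])
    return out.reshape((n_steps + 1,) + D.shape[1:])


def simulate_candidate(case, params: dict, preset: str = "desk") -> np.ndarray:
    """Forward-simulate one parameter configuration and extract D̂.

    ``case`` is a :class:`softinverse.cases.CaseDefinition`; ``params`` maps
    parameter names to physical values (missing ones fall back to the case's
    fixed/truth values).  Solver failure is propagated as an exception; the
    optimizer records it as +inf loss.
    """
    return case.simulate(params, preset=preset)


def run_inverse(
    case,
    observed: ObservedDeformation,
    optimizer: OptimizerConfig,
    unknowns=None,
    preset: str = "desk",
    loss_mode: str = "trajectory",
) -> RecoveryResult:
    """Recover the case's unknown parameters from an observed deformation.

    ``case`` is a CaseDefinition or a registered case name.  ``unknowns``
    defaults to the case's own unknown set.  ``loss_mode`` is "trajectory"
    (all load steps; default) or "final" (last step only).  Relative errors
    vs the case's ground truth are computed for every free parameter, on the
    linear (physical) scale.
    """
    if isinstance(case, str):
        from softinverse.cases import get_case

        case = get_case(case)
    if optimizer.budget < 1:
        raise ValueError("optimizer budget must be >= 1")
    if unknowns is None:
        unknowns = case.unknowns
    if not unknowns:
        raise ValueError("unknown set must be non-empty")
    space = SearchSpace([case.bounds[name] for name in unknowns])

    D = _align_steps(observed.data, case.n_steps(preset))
    if loss_mode == "final":
        D_cmp = D[-1:]
    elif loss_mode == "trajectory":
        D_cmp = D
    else:
        raise ValueError(f"unknown loss mode {loss_mode!r}")

    tol = 1e-12 * (1.0 + float(np.sum(D**2)))
    cfg = OptimizerConfig(
        batch_size=optimizer.batch_size,
        n_initial=optimizer.n_initial,
        budget=optimizer.budget,
        seed=optimizer.seed,
        t_mode=optimizer.t_mode,
        t_fixed=optimizer.t_fixed,
        n_jobs=optimizer.n_jobs,
        convergence_tol=max(optimizer.convergence_tol, tol),
    )

    def objective(p: dict) -> float:
        Dh = case.simulate(p, preset=preset)
        if loss_mode == "final":
            Dh = Dh[-1:]
        return deformation_loss(D_cmp, Dh)

    best, history = bayesopt.optimize(objective, space, cfg)

    estimates = dict(case.fixed_values(unknowns))
    estimates.update(best.as_dict())
    if hasattr(case, "canonicalize"):
        estimates = case.canonicalize(estimates)
    errors = {}
    for name in unknowns:
        truth = case.truth.get(name)
        if truth not in (None, 0.0):
            errors[name] = relative_error(estimates[name], truth)
    derived = case.derived_quantities(estimates)
    return RecoveryResult(
        case_name=case.name,
        estimates=estimates,
        final_loss=float(history.best_so_far[-1]),
        history=history,
        errors=errors,
        derived=derived,
        preset=preset,
    )
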