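"""Survey-driven calibration of susceptibilities and innate opinions.

A five-point Likert willingness item is mapped to probability classes of
width 0.2 (class ``j`` covers ``(0.2(j-1), 0.2j]``, with 0 in class 1).
Survey marginals ``f_1..f_5`` fix the class sizes on the network via
largest-remainder rounding; each agent draws a target steady-state
probability ``p*_i`` uniformly in its class band.  Calibration then seeks
susceptibilities ``lambda`` and innate probabilities ``p(0)`` so that the
steady state ``p_bar`` of the dynamics best matches ``p*`` in least
squares, subject to

* ``0 <= p_i(0) <= 1``,
* ``0 <= lambda_i <= 1`` with mean susceptibility exactly ``rho``,
* class retention: ``p_bar_i`` stays in the band of ``p*_i``
  (strict lower bound closed by a small ``eps``),
* ``p_bar`` being the steady state of the dynamics.

Algorithm
---------
The program is solved by an exact reduction rather than by alternating
descent.  For a candidate steady state ``p_bar`` define the neighborhood
averages ``s = W p_bar``.  Eliminating ``p(0)`` from the stationarity
relation ``(1 - lambda_i) p_i(0) = p_bar_i - lambda_i s_i`` shows that a
consistent ``p_i(0)`` in ``[0, 1]`` exists iff

.. math:: 0 \\le \\lambda_i \\le U_i(\\bar p) =
          \\min\\{1,\\; (1-\\bar p_i)/(1-s_i),\\; \\bar p_i/s_i\\},

so the whole feasibility content of the program collapses to the single
scalar constraint ``sum_i U_i(p_bar) >= rho * n``.  Calibration therefore
minimizes ``||p_bar - p*||^2`` over ``p_bar`` in the (box) class bands
subject to that one constraint; ``lambda`` is then chosen by
water-filling ``lambda_i = min(U_i, theta)`` with ``theta`` set so the
mean is exactly ``rho``, and ``p(0)`` follows in closed form.  When the
targets are themselves a reachable steady state the projection is the
identity and the objective is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from vaxwill.graph_model import SocialNetwork
from vaxwill.opinion_dynamics import AgentParameters, steady_state

__all__ = [
    "SurveyMarginals",
    "CalibrationTarget",
    "CalibrationResult",
    "CLASS_EDGES",
    "class_of_probability",
    "class_band",
    "assign_classes",
    "sample_targets",
    "make_targets",
    "calibrate",
    "find_max_rho",
]

N_CLASSES = 5
#: class-band edges 0, 0.2, ..., 1.0
CLASS_EDGES = np.linspace(0.0, 1.0, N_CLASSES + 1)
#: closure of the strict lower band bound, and the feasibility tolerance
BAND_EPS = 1e-6
FEAS_TOL = 1e-6
#: susceptibilities are capped just below 1 so p(0) stays well conditioned
LAMBDA_CAP = 1.0 - 1e-6


# ---------------------------------------------------------------------- #
# survey marginals and targets
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SurveyMarginals:
    """Fractions of respondents per Likert class, summing to one."""

    fractions: np.ndarray

    def __post_init__(self):
        f = np.ascontiguousarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if f.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} class fractions, got {f.shape}")
        if np.any(f < 0):
            raise ValueError("class fractions must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {f.sum()!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurveyMarginals":
        """Read a 5-row CSV with columns (likert_point, fraction)."""
        df = pd.read_csv(path)
        df = df.sort_values(df.columns[0])
        return cls(fractions=df[df.columns[1]].to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"likert_point": np.arange(1, N_CLASSES + 1), "fraction": self.fractions}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationTarget:
    """Per-agent class labels and target steady-state probabilities."""

    class_labels: np.ndarray
    p_star: np.ndarray

    def __post_init__(self):
        labels = np.ascontiguousarray(self.class_labels, dtype=np.int64)
        p_star = np.ascontiguousarray(self.p_star, dtype=float)
        object.__setattr__(self, "class_labels", labels)
        object.__setattr__(self, "p_star", p_star)
        if labels.shape != p_star.shape:
            raise ValueError("class_labels and p_star must have equal length")
        if np.any((labels < 1) | (labels > N_CLASSES)):
            raise ValueError("class labels must lie in 1..5")
        if np.any(p_star < 0) or np.any(p_star > 1):
            raise ValueError("targets must lie in [0, 1]")
        lo = CLASS_EDGES[labels - 1]
        hi = CLASS_EDGES[labels]
        ok = (p_star <= hi) & ((p_star > lo) | (labels == 1))
        if not np.all(ok):
            raise ValueError("some p_star values fall outside their class band")

    @property
    def n(self) -> int:
        return self.p_star.size

    @property
    def class_ranges(self) -> list[tuple[float, float]]:
        return [(CLASS_EDGES[j - 1], CLASS_EDGES[j]) for j in range(1, N_CLASSES + 1)]


def class_of_probability(p) -> np.ndarray:
    """Likert class of a probability: band ``(0.2(j-1), 0.2j]``, 0 -> 1.

    Values within 1e-9 of a band edge are snapped to it first, so a
    steady state computed to sit exactly on an edge classifies stably
    under floating-point roundoff.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    j = np.ceil(p * N_CLASSES - 1e-9 * N_CLASSES).astype(np.int64)
    return np.clip(j, 1, N_CLASSES)


def class_band(class_labels) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper band edges for the given class labels."""
    j = np.asarray(class_labels, dtype=np.int64)
    return CLASS_EDGES[j - 1], CLASS_EDGES[j]


def assign_classes(marginals: SurveyMarginals, n: int, seed: int) -> np.ndarray:
    """Seeded random class labels with largest-remainder class sizes.

    Class counts ``c_j`` round ``f_j * n`` so that ``sum c_j = n`` and
    ``|c_j - f_j n| < 1``; labels are distributed over agents by a seeded
    uniform permutation.
    """
    if n < 1:
        raise ValueError("need at least one agent")
    quota = marginals.fractions * n
    counts = np.floor(quota).astype(np.int64)
    short = n - counts.sum()
    # largest fractional remainders get the leftover units; ties -> low class
    order = np.lexsort((np.arange(N_CLASSES), -(quota - counts)))
    counts[order[:short]] += 1
    labels_sorted = np.repeat(np.arange(1, N_CLASSES + 1), counts)
    rng = np.random.default_rng(seed)
    return labels_sorted[rng.permutation(n)]


def sample_targets(class_labels: np.ndarray, seed: int) -> np.ndarray:
    """Draw ``p*_i`` uniformly in the class band of agent ``i`` (seeded)."""
    labels = np.asarray(class_labels, dtype=np.int64)
    if np.any((labels < 1) | (labels > N_CLASSES)):
        raise ValueError("class labels must lie in 1..5")
    lo, hi = class_band(labels)
    rng = np.random.default_rng(seed)
    return lo + (hi - lo) * rng.random(labels.size)


def make_targets(marginals: SurveyMarginals, n: int, seed: int) -> CalibrationTarget:
    """Convenience: classes and targets from one master seed."""
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    labels = assign_classes(marginals, n, np.random.default_rng(s1))
    p_star = sample_targets(labels, np.random.default_rng(s2))
    return CalibrationTarget(class_labels=labels, p_star=p_star)


# ---------------------------------------------------------------------- #
# calibration result
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the constrained least-squares calibration."""

    params: AgentParameters
    p_bar: np.ndarray
    p_star: np.ndarray
    objective: float
    rho: float
    feasible: bool
    diagnostics: dict = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent": np.arange(self.p_bar.size),
                "lambda": self.params.lam,
                "p0": self.params.p0,
                "p_bar": self.p_bar,
                "p_star": self.p_star,
                "class": class_of_probability(self.p_star),
            }
        )

    def summary(self) -> dict:
        return {
            "objective": self.objective,
            "rho": self.rho,
            "feasible": self.feasible,
            "max_residual": self.diagnostics["max_residual"],
            "mean_lambda": float(self.params.lam.mean()),
        }


# ---------------------------------------------------------------------- #
# the reduction: feasible-susceptibility caps
# ---------------------------------------------------------------------- #
def _lambda_caps(p_bar: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Per-agent upper bound ``U_i`` on lambda consistent with ``p_bar``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        from_upper = np.where(s < 1.0, (1.0 - p_bar) / (1.0 - s), np.inf)
        from_lower = np.where(s > 0.0, p_bar / s, np.inf)
    return np.minimum(LAMBDA_CAP, np.minimum(from_upper, from_lower))


def _caps_and_grad(
    p_bar: np.ndarray, net: SocialNetwork
) -> tuple[float, np.ndarray]:
    """``sum_i U_i(p_bar)`` and its (sub)gradient in ``p_bar``."""
    s = net.W @ p_bar
    with np.errstate(divide="ignore", invalid="ignore"):
        b_upper = np.where(s < 1.0, (1.0 - p_bar) / (1.0 - s), np.inf)
        b_lower = np.where(s > 0.0, p_bar / s, np.inf)
    U = np.minimum(LAMBDA_CAP, np.minimum(b_upper, b_lower))
    # active branch per agent: 0 = cap, 1 = upper ratio, 2 = lower ratio
    branch = np.where(
        U >= LAMBDA_CAP, 0, np.where(b_upper <= b_lower, 1, 2)
    )
    diag = np.zeros_like(p_bar)
    through_s = np.zeros_like(p_bar)
    up = branch == 1
    lo = branch == 2
    diag[up] = -1.0 / (1.0 - s[up])
    through_s[up] = (1.0 - p_bar[up]) / (1.0 - s[up]) ** 2
    diag[lo] = 1.0 / s[lo]
    through_s[lo] = -p_bar[lo] / s[lo] ** 2
    grad = diag + net.W.T @ through_s
    return float(U.sum()), grad


def _waterfill(caps: np.ndarray, target_sum: float) -> np.ndarray:
    """Choose ``lambda = min(caps, theta)`` with ``sum lambda = target_sum``.

    If the caps cannot carry the target, returns the caps themselves
    (the deficit shows up as a mean-susceptibility residual).
    """
    total = caps.sum()
    if target_sum >= total:
        return caps.copy()
    lo_t, hi_t = 0.0, float(caps.max())
    for _ in range(100):
        mid = 0.5 * (lo_t + hi_t)
        if np.minimum(caps, mid).sum() < target_sum:
            lo_t = mid
        else:
            hi_t = mid
    lam = np.minimum(caps, hi_t)
    # exact final adjustment on the uncapped entries
    free = lam < caps - 1e-12
    n_free = int(free.sum())
    if n_free:
        lam[free] += (target_sum - lam.sum()) / n_free
        lam = np.minimum(np.maximum(lam, 0.0), caps)
    return lam


def _recover_parameters(
    p_bar: np.ndarray, net: SocialNetwork, rho: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Water-filled ``lambda`` and closed-form ``p(0)`` for a steady state.

    Returns ``(lambda, p0, p0_box_violation)``; the violation is how far
    the un-clipped ``p(0)`` left ``[0, 1]`` (zero when ``p_bar`` is
    exactly consistent).
    """
    s = net.W @ p_bar
    caps = _lambda_caps(p_bar, s)
    lam = _waterfill(caps, rho * p_bar.size)
    p0 = (p_bar - lam * s) / (1.0 - lam)
    violation = float(max(np.max(p0 - 1.0, initial=0.0), np.max(-p0, initial=0.0)))
    return lam, np.clip(p0, 0.0, 1.0), violation


# ---------------------------------------------------------------------- #
# calibrate
# ---------------------------------------------------------------------- #
def calibrate(
    net: SocialNetwork,
    p_star: np.ndarray | CalibrationTarget,
    rho: float,
    seed: int = 0,
    restarts: int = 5,
    band_eps: float = BAND_EPS,
    warm_starts: Sequence[np.ndarray] | None = None,
) -> CalibrationResult:
    """Fit ``lambda`` and ``p(0)`` to survey targets at mean susceptibility ``rho``.

    Never raises on infeasibility: the result carries ``feasible=False``
    together with the maximal constraint violation in ``diagnostics``.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly between 0 and 1")
    if isinstance(p_star, CalibrationTarget):
        p_star = p_star.p_star
    p_star = np.ascontiguousarray(p_star, dtype=float)
    if p_star.size != net.n:
        raise ValueError("p_star length must equal the number of agents")
    if np.any(p_star < 0) or np.any(p_star > 1):
        raise ValueError("targets must lie in [0, 1]")

    labels = class_of_probability(p_star)
    lo, hi = class_band(labels)
    # close the strict lower band bound; class 1 includes 0 by convention
    lo_closed = np.where(labels == 1, 0.0, lo + band_eps)
    target = np.clip(p_star, lo_closed, hi)
    need = rho * net.n

    trace: list[float] = []

    def objective_of(p_bar: np.ndarray) -> float:
        return float(np.sum((p_bar - p_star) ** 2))

    # Fast path: the (band-projected) targets are themselves feasible.
    g_target, _ = _caps_and_grad(target, net)
    if g_target >= need:
        p_bar_sol = target
        trace.append(objective_of(target))
        solver_info = {"path": "direct", "nit": 0}
    else:
        p_bar_sol, solver_info = _constrained_projection(
            net, target, lo_closed, hi, need, seed, restarts, trace,
            warm_starts=warm_starts,
        )

    lam, p0, p0_violation = _recover_parameters(p_bar_sol, net, rho)
    params = AgentParameters(lam=lam, p0=p0)
    p_bar = steady_state(net, params)

    band_violation = float(
        np.max(np.maximum(lo_closed - p_bar, p_bar - hi), initial=0.0)
    )
    mean_violation = float(abs(lam.mean() - rho))
    consistency = float(np.max(np.abs(p_bar - p_bar_sol)))
    residuals = {
        "band": band_violation,
        "p0_box": p0_violation,
        "mean_lambda": mean_violation,
        "steady_state": consistency,
    }
    max_residual = max(residuals.values())
    feasible = max_residual < FEAS_TOL
    objective = objective_of(p_bar)
    if not trace or objective < trace[-1]:
        trace.append(objective)
    return CalibrationResult(
        params=params,
        p_bar=p_bar,
        p_star=p_star,
        objective=objective,
        rho=rho,
        feasible=feasible,
        diagnostics={
            "residuals": residuals,
            "max_residual": max_residual,
            "objective_trace": trace,
            "solver": solver_info,
        },
    )


def _band_flat_start(target: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Global mean projected into each agent's band.

    ``U_i = 1`` exactly when ``p_bar_i`` equals its neighborhood average,
    so a maximally flat profile is the natural high-feasibility start.
    """
    return np.clip(np.full_like(target, target.mean()), lo, hi)


def _constrained_projection(
    net: SocialNetwork,
    target: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    need: float,
    seed: int,
    restarts: int,
    trace: list[float],
    warm_starts: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, dict]:
    """Minimize ``||p_bar - target||^2`` s.t. ``sum U(p_bar) >= need``.

    The single scalar constraint is handled by Lagrange-multiplier
    continuation: for a multiplier ``mu`` the box-constrained subproblem
    ``min ||x - target||^2 - mu * sum U(x)`` is solved with L-BFGS-B,
    and ``mu`` is driven up by doubling until the constraint holds, then
    refined by bisection so the solution sits on the constraint surface.
    """
    rng = np.random.default_rng(seed)
    n = net.n
    bounds = list(zip(lo, hi))
    # candidates pass if the susceptibility budget shortfall, spread over
    # the population, stays well inside the feasibility tolerance
    slack_tol = 0.25 * FEAS_TOL * n

    def caps_sum(x):
        g, _ = _caps_and_grad(x, net)
        return g

    def solve_penalized(mu, x0):
        def fun_jac(x):
            g, grad = _caps_and_grad(x, net)
            f = float(np.sum((x - target) ** 2)) - mu * g
            return f, 2.0 * (x - target) - mu * grad

        res = minimize(
            fun_jac, x0, jac=True, bounds=bounds, method="L-BFGS-B",
            options={"maxiter": 300},
        )
        return res.x

    starts = [_band_flat_start(target, lo, hi)]
    if warm_starts is not None:
        starts.extend(np.clip(w, lo, hi) for w in warm_starts)
    for _ in range(max(restarts - len(starts), 0)):
        starts.append(lo + (hi - lo) * rng.random(n))

    best_x, best_obj = None, np.inf
    most_feasible_x, most_feasible_g = target, caps_sum(target)
    n_solves = 0
    for x0 in starts:
        x, mu = x0, 0.125
        mu_lo, mu_hi = 0.0, None
        for _ in range(50):
            x = solve_penalized(mu, x)
            n_solves += 1
            g = caps_sum(x)
            if g > most_feasible_g:
                most_feasible_x, most_feasible_g = x, g
            if g >= need - slack_tol:
                mu_hi = mu
                break
            mu_lo, mu = mu, 2.0 * mu
        if mu_hi is None:
            continue  # constraint unreachable along this path
        incumbent, inc_obj = x, float(np.sum((x - target) ** 2))
        for _ in range(30):
            mid = 0.5 * (mu_lo + mu_hi)
            x = solve_penalized(mid, incumbent)
            n_solves += 1
            g = caps_sum(x)
            if g >= need - slack_tol:
                mu_hi = mid
                obj = float(np.sum((x - target) ** 2))
                if obj < inc_obj:
                    incumbent, inc_obj = x, obj
            else:
                mu_lo = mid
        if inc_obj < best_obj:
            best_x, best_obj = incumbent, inc_obj
            trace.append(inc_obj if not trace else min(trace[-1], inc_obj))

    if best_x is None:
        return most_feasible_x, {
            "path": "infeasible",
            "slack": float(most_feasible_g - need),
            "n_solves": n_solves,
        }
    return best_x, {"path": "multiplier-continuation", "n_solves": n_solves}


# ---------------------------------------------------------------------- #
# largest feasible mean susceptibility
# ---------------------------------------------------------------------- #
def find_max_rho(
    net: SocialNetwork,
    p_star: np.ndarray | CalibrationTarget,
    resolution: float = 0.01,
    seed: int = 0,
    restarts: int = 3,
) -> float:
    """Largest grid value of ``rho`` at which calibration is feasible.

    A direct maximization of ``sum_i U_i(p_bar)`` over the class bands
    gives an estimate of the feasibility frontier; the grid is then
    scanned downward from just above it, and the returned value is
    re-verified by a full :func:`calibrate` call.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(p_star, CalibrationTarget):
        p_star = p_star.p_star
    p_star = np.ascontiguousarray(p_star, dtype=float)
    labels = class_of_probability(p_star)
    lo, hi = class_band(labels)
    lo_closed = np.where(labels == 1, 0.0, lo + BAND_EPS)
    target = np.clip(p_star, lo_closed, hi)

    def neg_caps(x):
        g, grad = _caps_and_grad(x, net)
        return -g, -grad

    best_val, best_x = -np.inf, None
    rng = np.random.default_rng(seed)
    starts = [target, _band_flat_start(target, lo_closed, hi)]
    for _ in range(max(restarts - 2, 0)):
        starts.append(lo_closed + (hi - lo_closed) * rng.random(net.n))
    for x0 in starts:
        res = minimize(
            neg_caps,
            x0,
            jac=True,
            bounds=list(zip(lo_closed, hi)),
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if -res.fun > best_val:
            best_val, best_x = -res.fun, res.x

    rho_ub = best_val / net.n
    grid = np.round(np.arange(resolution, 1.0, resolution), 10)
    candidates = grid[grid <= min(rho_ub + 2 * resolution, grid[-1])][::-1]
    for rho in candidates:
        result = calibrate(
            net, p_star, float(rho), seed=seed, restarts=restarts,
            warm_starts=None if best_x is None else [best_x],
        )
        if result.feasible:
            return float(rho)
    raise ValueError(
        "no feasible rho on the grid; the class structure may be too "
        "dispersed for any positive mean susceptibility — consider coarser "
        "classes or different targets"
    )
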