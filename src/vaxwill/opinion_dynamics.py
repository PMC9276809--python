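"""Friedkin-Johnsen willingness dynamics and their steady state.

Each agent updates its vaccination probability as a convex combination of
the neighborhood average (weight ``lambda_i``, the *susceptibility*) and
its innate probability (weight ``1 - lambda_i``, the *stubbornness*):

.. math:: p(k+1) = \\Lambda W p(k) + (I_n - \\Lambda)\\,p(0).

Whenever at least one agent is not fully susceptible
(:math:`\\Lambda \\ne I_n`) and the graph is connected with self-loops,
the spectral radius of :math:`\\Lambda W` is below one and the dynamics
converge geometrically to the unique fixed point

.. math:: \\bar p = (I_n - \\Lambda W)^{-1}(I_n - \\Lambda)\\,p(0),

computed here by a sparse direct solve rather than an explicit inverse.
An agent with ``lambda_i = 0`` is a *zealot*: its probability never moves
while it keeps influencing its neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from vaxwill.graph_model import SocialNetwork

__all__ = [
    "AgentParameters",
    "OpinionState",
    "SingularDynamicsError",
    "fj_step",
    "steady_state",
    "iterate_to_steady_state",
    "save_agent_vector",
    "load_agent_vector",
]

#: convergence tolerance (infinity norm) for the fixed-point iteration
ITERATION_TOL = 1e-12
#: iteration cap; geometric convergence makes this generous
MAX_ITERATIONS = 10**6


class SingularDynamicsError(ValueError):
    """Raised when every agent is fully susceptible (``Lambda == I``)."""


@dataclass(frozen=True)
class AgentParameters:
    """Per-agent susceptibilities and innate vaccination probabilities."""

    lam: np.ndarray
    p0: np.ndarray

    def __post_init__(self):
        lam = np.ascontiguousarray(self.lam, dtype=float)
        p0 = np.ascontiguousarray(self.p0, dtype=float)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "p0", p0)
        if lam.ndim != 1 or p0.ndim != 1 or lam.shape != p0.shape:
            raise ValueError("lam and p0 must be 1-D vectors of equal length")
        for name, v in (("lam", lam), ("p0", p0)):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if np.all(lam >= 1.0):
            raise SingularDynamicsError(
                "all susceptibilities equal 1: at least one agent must have "
                "lambda_i < 1 for the dynamics to admit a unique steady state"
            )

    @property
    def n(self) -> int:
        return self.lam.size


@dataclass(frozen=True)
class OpinionState:
    """Vector of current vaccination probabilities at step ``k``."""

    p: np.ndarray
    k: int = 0

    def __post_init__(self):
        p = np.ascontiguousarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.ndim != 1:
            raise ValueError("p must be a 1-D vector")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.k < 0:
            raise ValueError("step index must be nonnegative")


def _check_dims(net: SocialNetwork, params: AgentParameters, p: np.ndarray) -> None:
    if params.n != net.n or p.size != net.n:
        raise ValueError(
            f"dimension mismatch: network has n={net.n}, "
            f"parameters n={params.n}, state n={p.size}"
        )


def fj_step(
    state: OpinionState, net: SocialNetwork, params: AgentParameters
) -> OpinionState:
    """One synchronous Friedkin-Johnsen update.

    Every output entry is a convex combination of entries of ``state.p``
    and ``params.p0``, so probabilities remain in ``[0, 1]`` exactly.
    """
    _check_dims(net, params, state.p)
    p_next = params.lam * (net.W @ state.p) + (1.0 - params.lam) * params.p0
    return OpinionState(p=p_next, k=state.k + 1)


def steady_state(net: SocialNetwork, params: AgentParameters) -> np.ndarray:
    """Unique fixed point ``(I - Lambda W)^{-1} (I - Lambda) p(0)``.

    Solved as the sparse linear system ``(I - Lambda W) p = (I - Lambda) p(0)``.
    """
    _check_dims(net, params, params.p0)
    if np.all(params.lam >= 1.0):
        raise SingularDynamicsError(
            "Lambda equals the identity: at least one agent must have "
            "lambda_i < 1"
        )
    n = net.n
    A = sp.eye_array(n, format="csr") - sp.csr_array(
        net.W.multiply(params.lam[:, None])
    )
    b = (1.0 - params.lam) * params.p0
    p_bar = spsolve(A.tocsc(), b)
    # roundoff can leave values a few ulp outside the box
    return np.clip(p_bar, 0.0, 1.0)


def iterate_to_steady_state(
    net: SocialNetwork,
    params: AgentParameters,
    p_init: np.ndarray | None = None,
    tol: float = ITERATION_TOL,
    max_iter: int = MAX_ITERATIONS,
) -> np.ndarray:
    """Fixed-point iteration of the dynamics until the update stalls.

    Serves as an independent cross-check of :func:`steady_state`; the
    iteration contracts geometrically at rate ``spectral_radius(Lambda W)``.
    """
    p = params.p0.copy() if p_init is None else np.asarray(p_init, dtype=float)
    _check_dims(net, params, p)
    state = OpinionState(p=p, k=0)
    for _ in range(max_iter):
        nxt = fj_step(state, net, params)
        if np.max(np.abs(nxt.p - state.p)) < tol:
            return nxt.p
        state = nxt
    raise RuntimeError(
        f"fixed-point iteration did not reach tol={tol} in {max_iter} steps"
    )


# ---------------------------------------------------------------------- #
# serialization: two-column CSV (agent, value)
# ---------------------------------------------------------------------- #
def save_agent_vector(values: np.ndarray, path: str | Path, name: str = "value") -> None:
    pd.DataFrame({"agent": np.arange(len(values)), name: values}).to_csv(
        path, index=False
    )


def load_agent_vector(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    df = df.sort_values(df.columns[0])
    return df[df.columns[1]].to_numpy(dtype=float)
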