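"""Influencer campaigns: targeted and mass opinion steering.

A campaign is modeled as a virtual influencer node with fixed vaccination
probability ``p_l`` (1 for a pro-vaccine campaign, 0 for an anti-vaccine
one) wired to a fraction ``phi`` of the agents.  A targeted agent shifts a
weight ``alpha`` of its social-pressure term from its neighborhood onto
the influencer, giving the modified dynamics

.. math:: p(k+1) = \\Lambda\\big((I_n - \\alpha\\Delta) W p(k)
          + \\alpha\\,\\delta\\,p_l\\big) + (I_n - \\Lambda)\\,p(0),

with ``delta`` the 0/1 target indicator and ``Delta = diag(delta)``.  The
campaign's *overall effort* is ``eta = alpha * phi``; effort sweeps fix
``alpha = 1`` and vary ``phi = eta`` for targeted strategies, while the
mass campaign wires everyone (``phi = 1``) at per-head effort
``alpha = eta``.

The innate anchor ``p(0)`` for a campaign run is the calibrated baseline
steady state (opinions are taken as consolidated by campaign time), so
campaign effects are measured against the no-campaign fixed point under
that anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from vaxwill.graph_model import SocialNetwork
from vaxwill.opinion_dynamics import (
    AgentParameters,
    OpinionState,
    SingularDynamicsError,
)

__all__ = [
    "STRATEGIES",
    "CampaignSpec",
    "round_half_up",
    "select_targets",
    "targeted_spec",
    "mass_spec",
    "campaign_step",
    "campaign_steady_state",
]

#: targeted selection rules plus the mass baseline
STRATEGIES = ("mass", "degree", "antivax-neighbors", "susceptibility")
#: agents whose baseline probability falls in the lowest Likert band
ANTIVAX_BAND_UPPER = 0.2


def round_half_up(x: float) -> int:
    """Deterministic half-up rounding for target counts."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class CampaignSpec:
    """Who is targeted and how hard.

    ``delta`` is the 0/1 target indicator, ``alpha`` the effort per
    targeted individual, ``phi`` the targeted fraction and ``p_l`` the
    influencer's fixed vaccination probability.
    """

    delta: np.ndarray
    alpha: float
    phi: float
    p_l: float
    strategy: str = "mass"

    def __post_init__(self):
        delta = np.ascontiguousarray(self.delta, dtype=float)
        object.__setattr__(self, "delta", delta)
        if not np.all(np.isin(delta, (0.0, 1.0))):
            raise ValueError("delta must be a 0/1 indicator vector")
        for name, v in (("alpha", self.alpha), ("phi", self.phi), ("p_l", self.p_l)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; valid: {STRATEGIES}"
            )
        expected = round_half_up(self.phi * delta.size)
        if int(delta.sum()) != expected:
            raise ValueError(
                f"delta selects {int(delta.sum())} agents but phi={self.phi} "
                f"requires {expected}"
            )

    @property
    def eta(self) -> float:
        """Overall campaign effort ``alpha * phi``."""
        return self.alpha * self.phi


def select_targets(
    strategy: str,
    phi: float,
    net: SocialNetwork,
    params: AgentParameters | None = None,
    p_bar: np.ndarray | None = None,
) -> np.ndarray:
    """Target indicator for ``round(phi * n)`` agents under a strategy.

    * ``degree`` — most connected agents (self-loops excluded from the
      degree; they are uniform and carry no ranking information);
    * ``antivax-neighbors`` — non-antivax agents ranked by their number
      of antivax neighbors, where *antivax* means a baseline probability
      in the lowest Likert band ``[0, 0.2]``;
    * ``susceptibility`` — most susceptible agents (largest ``lambda``);
    * ``mass`` — everyone (requires ``phi = 1``).

    Ties are broken by the lowest agent index, so selections are
    deterministic and invariant under relabeling of the input file.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; valid: {STRATEGIES}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    n = net.n
    m = round_half_up(phi * n)
    delta = np.zeros(n)
    if strategy == "mass":
        if m != n:
            raise ValueError("the mass strategy requires phi = 1")
        return np.ones(n)
    if m == 0:
        return delta

    if strategy == "degree":
        key = net.degrees.astype(float)
        pool = np.arange(n)
    elif strategy == "susceptibility":
        if params is None:
            raise ValueError("susceptibility strategy needs agent parameters")
        key = params.lam
        pool = np.arange(n)
    else:  # antivax-neighbors
        if p_bar is None:
            raise ValueError("antivax-neighbors strategy needs the baseline p_bar")
        antivax = np.asarray(p_bar) <= ANTIVAX_BAND_UPPER
        adj = net.adjacency.astype(float)
        counts = adj @ antivax.astype(float) - antivax.astype(float)  # no self
        key = counts
        pool = np.flatnonzero(~antivax)
        if pool.size < m:
            # not enough non-antivax agents: fill up from the excluded pool
            extra = np.flatnonzero(antivax)
            pool = np.concatenate([pool, extra])

    # stable sort: descending key, ties by lowest index
    order = pool[np.argsort(-key[pool], kind="stable")]
    delta[order[:m]] = 1.0
    return delta


def targeted_spec(
    strategy: str,
    eta: float,
    net: SocialNetwork,
    params: AgentParameters,
    p_bar: np.ndarray,
    p_l: float = 1.0,
) -> CampaignSpec:
    """Sweep convention for targeted strategies: ``alpha = 1, phi = eta``."""
    delta = select_targets(strategy, eta, net, params=params, p_bar=p_bar)
    return CampaignSpec(delta=delta, alpha=1.0, phi=eta, p_l=p_l, strategy=strategy)


def mass_spec(eta: float, net: SocialNetwork, p_l: float = 1.0) -> CampaignSpec:
    """Sweep convention for the mass campaign: ``phi = 1, alpha = eta``."""
    delta = select_targets("mass", 1.0, net)
    return CampaignSpec(delta=delta, alpha=eta, phi=1.0, p_l=p_l, strategy="mass")


def _check_dims(net: SocialNetwork, params: AgentParameters, spec: CampaignSpec):
    if params.n != net.n or spec.delta.size != net.n:
        raise ValueError(
            f"dimension mismatch: network n={net.n}, parameters n={params.n}, "
            f"delta n={spec.delta.size}"
        )


def campaign_step(
    state: OpinionState,
    net: SocialNetwork,
    params: AgentParameters,
    spec: CampaignSpec,
) -> OpinionState:
    """One synchronous update of the influencer-augmented dynamics.

    With ``alpha = 0`` this reduces exactly to the plain
    Friedkin-Johnsen step.  Targeted agents blend their social term with
    the influencer's ``p_l``; every entry stays a convex combination of
    probabilities, hence in ``[0, 1]``.
    """
    _check_dims(net, params, spec)
    if state.p.size != net.n:
        raise ValueError("state dimension does not match the network")
    social = net.W @ state.p
    blended = (1.0 - spec.alpha * spec.delta) * social + (
        spec.alpha * spec.p_l
    ) * spec.delta
    p_next = params.lam * blended + (1.0 - params.lam) * params.p0
    return OpinionState(p=p_next, k=state.k + 1)


def campaign_steady_state(
    net: SocialNetwork, params: AgentParameters, spec: CampaignSpec
) -> np.ndarray:
    """Fixed point of the campaign dynamics via a sparse direct solve.

    Solves ``(I - Lambda (I - alpha Delta) W) p = alpha p_l Lambda delta
    + (I - Lambda) p(0)``; the system matrix is an M-matrix perturbation
    with spectral radius of the iteration below one whenever some agent
    has ``lambda_i < 1``, so the solve is well posed.
    """
    _check_dims(net, params, spec)
    if np.all(params.lam >= 1.0):
        raise SingularDynamicsError(
            "Lambda equals the identity: at least one agent must have "
            "lambda_i < 1"
        )
    n = net.n
    row_scale = params.lam * (1.0 - spec.alpha * spec.delta)
    A = sp.eye_array(n, format="csr") - sp.csr_array(
        net.W.multiply(row_scale[:, None])
    )
    b = spec.alpha * spec.p_l * params.lam * spec.delta + (1.0 - params.lam) * params.p0
    p_bar = spsolve(A.tocsc(), b)
    return np.clip(p_bar, 0.0, 1.0)
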