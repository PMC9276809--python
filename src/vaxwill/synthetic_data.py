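"""Synthetic networks, survey marginals and calibration fixtures.

These generators stand in for the two external inputs of the analysis —
a real friendship network and a Likert willingness survey — so that the
whole pipeline runs and is testable without downloads.  Three network
families are provided: a homogeneous random graph, a heavy-tailed
preferential-attachment graph (on which degree-based targeting is
meaningfully different from mass targeting) and a small-world ring.
Survey profiles emulate the qualitative shapes such willingness items
produce: a polarized population, and a hesitant middle with a small
strongly-opposed minority.

``make_selfconsistent_fixture`` builds calibration problems whose
targets are, by construction, an exactly reachable steady state with
known ground-truth parameters — the parameter-recovery harness for the
calibration solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from vaxwill.calibration import (
    CalibrationTarget,
    SurveyMarginals,
    class_of_probability,
)
from vaxwill.graph_model import SocialNetwork
from vaxwill.opinion_dynamics import AgentParameters, steady_state

__all__ = [
    "NETWORK_KINDS",
    "SURVEY_PROFILES",
    "make_network",
    "make_survey",
    "make_selfconsistent_fixture",
]

NETWORK_KINDS = ("homogeneous-random", "preferential-attachment", "small-world")

#: built-in Likert marginal profiles (fractions for classes 1..5)
SURVEY_PROFILES = {
    "uniform": (0.2, 0.2, 0.2, 0.2, 0.2),
    "polarized": (0.35, 0.12, 0.06, 0.12, 0.35),
    "hesitant-middle": (0.06, 0.27, 0.30, 0.27, 0.10),
}

_MAX_RETRIES = 20
#: keep ground-truth steady states this far from class boundaries
_BOUNDARY_MARGIN = 1e-3


def make_network(
    kind: str, n: int, mean_degree: float, seed: int
) -> SocialNetwork:
    """Connected undirected graph with self-loops of a given family.

    Parameters
    ----------
    kind:
        ``"homogeneous-random"`` (Erdos-Renyi), ``"preferential-attachment"``
        (Barabasi-Albert, heavy-tailed degrees) or ``"small-world"``
        (Watts-Strogatz ring rewiring).
    n:
        Requested number of agents (at least 10).  For the random graph
        the largest connected component is extracted, so the realized
        size can be slightly smaller.
    mean_degree:
        Target average non-self-loop degree (at least 2).
    """
    if kind not in NETWORK_KINDS:
        raise ValueError(f"unknown network kind {kind!r}; valid: {NETWORK_KINDS}")
    if n < 10:
        raise ValueError("need n >= 10")
    if mean_degree < 2:
        raise ValueError("need mean_degree >= 2")
    ss = np.random.SeedSequence(seed)
    for attempt_seed in ss.generate_state(_MAX_RETRIES) >> 1:  # keep below 2^31
        g = _generate(kind, n, mean_degree, int(attempt_seed))
        if g.number_of_nodes() < max(10, int(0.75 * n)):
            continue
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = [(mapping[u], mapping[v]) for u, v in g.edges() if u != v]
        return SocialNetwork.from_edges(edges, n=g.number_of_nodes())
    raise RuntimeError(
        f"could not generate a connected {kind} graph of ~{n} nodes "
        f"in {_MAX_RETRIES} attempts"
    )


def _generate(kind: str, n: int, mean_degree: float, seed: int) -> nx.Graph:
    if kind == "homogeneous-random":
        p = min(1.0, mean_degree / (n - 1))
        g = nx.fast_gnp_random_graph(n, p, seed=seed)
        nodes = max(nx.connected_components(g), key=len)
        return g.subgraph(nodes).copy()
    if kind == "preferential-attachment":
        m = max(1, int(round(mean_degree / 2)))
        return nx.barabasi_albert_graph(n, m, seed=seed)
    # small-world: k must be even and >= 2
    k = max(2, 2 * int(round(mean_degree / 2)))
    return nx.connected_watts_strogatz_graph(n, k, p=0.1, seed=seed)


def make_survey(
    profile: str | tuple | list | np.ndarray, seed: int = 0
) -> SurveyMarginals:
    """Likert marginals from a named profile or explicit fractions.

    Explicit fractions are returned verbatim (after validation).  The
    ``seed`` argument is accepted for interface uniformity with the other
    generators; the built-in profiles are deterministic.
    """
    if isinstance(profile, str):
        if profile not in SURVEY_PROFILES:
            raise ValueError(
                f"unknown survey profile {profile!r}; valid: "
                f"{sorted(SURVEY_PROFILES)}"
            )
        fractions = np.array(SURVEY_PROFILES[profile], dtype=float)
    else:
        fractions = np.asarray(profile, dtype=float)
    return SurveyMarginals(fractions=fractions)


def _mean_adjusted(raw: np.ndarray, mean: float, lo: float, hi: float) -> np.ndarray:
    """Shift-and-clip ``raw`` into ``[lo, hi]`` with an exact mean.

    The shift is found by bisection (the clipped mean is monotone in the
    shift); a final affine correction on the unclipped entries makes the
    mean exact to machine precision.
    """
    target = mean * raw.size
    t_lo, t_hi = lo - raw.max(), hi - raw.min()
    for _ in range(200):
        mid = 0.5 * (t_lo + t_hi)
        if np.clip(raw + mid, lo, hi).sum() < target:
            t_lo = mid
        else:
            t_hi = mid
    out = np.clip(raw + t_hi, lo, hi)
    free = (out > lo + 1e-12) & (out < hi - 1e-12)
    n_free = int(free.sum())
    if n_free:
        out[free] += (target - out.sum()) / n_free
    return np.clip(out, lo, hi)


def make_selfconsistent_fixture(
    net: SocialNetwork, rho: float, seed: int
) -> tuple[CalibrationTarget, AgentParameters]:
    """Calibration targets that are a reachable steady state by construction.

    Ground-truth susceptibilities are drawn with mean exactly ``rho``
    (within machine precision) and innate probabilities away from the
    extremes of ``[0, 1]``; the implied steady state is nudged off class
    boundaries — re-solving for consistent innate probabilities — so that
    the strict lower band bound of the calibration program is satisfiable
    with a comfortable margin.  The returned targets ``p*`` equal the
    ground-truth steady state exactly, so calibration at the same ``rho``
    has a zero-objective feasible point.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = net.n
    lam_cap = 0.98  # keep (1 - lambda)^{-1} well conditioned
    raw = rng.random(n)
    lam = _mean_adjusted(raw, rho, 0.0, lam_cap)
    # innate probabilities away from the box edges so that the boundary
    # nudge below never pushes p(0) outside [0, 1]
    p0 = 0.02 + 0.96 * rng.random(n)
    params = AgentParameters(lam=lam, p0=p0)
    p_bar = steady_state(net, params)

    for _ in range(10):
        nudged = _nudge_off_boundaries(p_bar)
        if nudged is None:
            break
        # back-solve the innate probabilities that realize the nudged
        # steady state exactly: (1 - lam) p0 = (I - Lambda W) p_bar
        s = net.W @ nudged
        p0 = np.clip((nudged - lam * s) / (1.0 - lam), 0.0, 1.0)
        params = AgentParameters(lam=lam, p0=p0)
        p_bar = steady_state(net, params)

    labels = class_of_probability(p_bar)
    target = CalibrationTarget(class_labels=labels, p_star=p_bar)
    return target, params


def _nudge_off_boundaries(p_bar: np.ndarray) -> np.ndarray | None:
    """Move entries within the margin of a class edge inward, or None."""
    edges = np.round(p_bar * 5.0) / 5.0
    near = np.abs(p_bar - edges) < _BOUNDARY_MARGIN
    near &= (edges > 0.0) | (p_bar < edges)  # 0 and 1 handled by clip below
    if not np.any(near):
        return None
    out = p_bar.copy()
    shift = np.where(p_bar >= edges, 1.0, -1.0) * 2.0 * _BOUNDARY_MARGIN
    out[near] = np.clip(
        edges[near] + shift[near], _BOUNDARY_MARGIN, 1.0 - _BOUNDARY_MARGIN
    )
    return out
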