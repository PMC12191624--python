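"""Small binary causal Bayes nets with logistic conditional probability tables.

A :class:`CausalNetwork` is a directed acyclic graph over named binary
variables whose links carry a *polarity*: generative links make the effect
more likely, inhibitory links make it less likely.  Given a
:class:`Parameterization`, the exact joint distribution over all ``2**n``
system states is computed by enumeration (the networks of interest have
three or four variables, so exact inference is cheap), and any conditional
probability query can then be answered by summing states.

State indexing convention
-------------------------
A system state assigns 0/1 to every variable.  States map to integers
``0 .. 2**n - 1`` with the **first declared variable as the most significant
bit**, so for variable order ``(X, YA, YB, Z)`` the state written ``1111``
is index 15 and ``1000`` (only X present) is index 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

GENERATIVE = "generative"
INHIBITORY = "inhibitory"

__all__ = [
    "GENERATIVE",
    "INHIBITORY",
    "CausalNetwork",
    "Parameterization",
    "Query",
    "JointDistribution",
    "cpd_prob",
    "joint_distribution",
    "conditional_query",
    "normative_predictions",
]


@dataclass(frozen=True)
class CausalNetwork:
    """A DAG over binary variables with signed (generative/inhibitory) links.

    Parameters
    ----------
    variables:
        Ordered variable names.  Order fixes the state-index convention
        (first variable = most significant bit).
    links:
        ``(source, target, polarity)`` triples, polarity one of
        ``"generative"`` or ``"inhibitory"``.
    """

    variables: tuple[str, ...]
    links: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(
            self, "links", tuple((s, t, p) for s, t, p in self.links)
        )
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        if len(self.variables) > 16:
            raise ValueError("exact enumeration supports at most 16 variables")
        seen = set()
        for s, t, p in self.links:
            if s not in self.variables or t not in self.variables:
                raise ValueError(f"link ({s},{t}) references undeclared variable")
            if p not in (GENERATIVE, INHIBITORY):
                raise ValueError(f"unknown polarity {p!r}")
            if (s, t) in seen:
                raise ValueError(f"duplicate link ({s},{t})")
            seen.add((s, t))
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((s, t) for s, t, _ in self.links)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network must be acyclic")

    # -- structural helpers -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def n_states(self) -> int:
        return 1 << self.n

    def index_of(self, variable: str) -> int:
        return self.variables.index(variable)

    def parents(self, variable: str) -> tuple[str, ...]:
        return tuple(s for s, t, _ in self.links if t == variable)

    def roots(self) -> tuple[str, ...]:
        targets = {t for _, t, _ in self.links}
        return tuple(v for v in self.variables if v not in targets)

    def in_links(self, variable: str) -> tuple[tuple[str, str, str], ...]:
        return tuple(l for l in self.links if l[1] == variable)

    def has_inhibitory(self) -> bool:
        return any(p == INHIBITORY for _, _, p in self.links)

    # -- state <-> index ----------------------------------------------------

    def state_to_index(self, bits: Sequence[int]) -> int:
        if len(bits) != self.n:
            raise ValueError("state length must equal variable count")
        idx = 0
        for b in bits:
            idx = (idx << 1) | int(b)
        return idx

    def index_to_state(self, index: int) -> tuple[int, ...]:
        return tuple((index >> (self.n - 1 - i)) & 1 for i in range(self.n))

    def state_string(self, index: int) -> str:
        return "".join(str(b) for b in self.index_to_state(index))

    def states_matrix(self) -> np.ndarray:
        """(2**n, n) array of 0/1 assignments, row ``s`` = state ``s``."""
        shifts = np.arange(self.n - 1, -1, -1)
        return (np.arange(self.n_states)[:, None] >> shifts) & 1


@dataclass(frozen=True)
class Parameterization:
    """Numerical parameters of a network's logistic CPDs.

    ``root_priors`` are direct probabilities in (0, 1) (the root-cause
    base rate, e.g. ``wX``).  ``link_weights`` and ``exo_weights`` enter a
    logistic: for a non-root variable ``V`` with parents coded +1 when
    present and -1 when absent,

        p(V=1 | parents) = 1 / (1 + exp(-(sum_j w_j c_j + w_exo))).

    Generative links must have weight >= 0 and inhibitory links <= 0.
    """

    root_priors: Mapping[str, float]
    link_weights: Mapping[tuple[str, str], float]
    exo_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "root_priors", dict(self.root_priors))
        object.__setattr__(self, "link_weights", dict(self.link_weights))
        object.__setattr__(self, "exo_weights", dict(self.exo_weights))
        for v, p in self.root_priors.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"root prior for {v} must lie strictly in (0,1)")

    @classmethod
    def shared(
        cls,
        network: CausalNetwork,
        root_prior: float,
        w_gen: float,
        w_exo: float,
        w_inh: float | None = None,
    ) -> "Parameterization":
        """Build the tied parameterization used throughout the experiments:
        one prior for every root, one weight for all generative links, one
        for all inhibitory links, one exogenous weight shared by all
        non-root variables."""
        if w_gen < 0:
            raise ValueError("generative weight must be >= 0")
        if w_inh is not None and w_inh > 0:
            raise ValueError("inhibitory weight must be <= 0")
        lw: dict[tuple[str, str], float] = {}
        for s, t, p in network.links:
            if p == GENERATIVE:
                lw[(s, t)] = w_gen
            else:
                if w_inh is None:
                    raise ValueError("network has inhibitory links but w_inh not given")
                lw[(s, t)] = w_inh
        roots = network.roots()
        return cls(
            root_priors={r: root_prior for r in roots},
            link_weights=lw,
            exo_weights={v: w_exo for v in network.variables if v not in roots},
        )

    def validate_for(self, network: CausalNetwork) -> None:
        for r in network.roots():
            if r not in self.root_priors:
                raise ValueError(f"missing root prior for {r}")
        for s, t, p in network.links:
            if (s, t) not in self.link_weights:
                raise ValueError(f"missing weight for link ({s},{t})")
            w = self.link_weights[(s, t)]
            if p == GENERATIVE and w < 0:
                raise ValueError(f"generative link ({s},{t}) has negative weight")
            if p == INHIBITORY and w > 0:
                raise ValueError(f"inhibitory link ({s},{t}) has positive weight")
        for v in network.variables:
            if v not in network.roots() and v not in self.exo_weights:
                raise ValueError(f"missing exogenous weight for {v}")


@dataclass(frozen=True)
class Query:
    """A conditional probability query p(target = 1 | evidence)."""

    target: str
    evidence: tuple[tuple[str, int], ...] = ()
    id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        ev = tuple(sorted((v, int(b)) for v, b in dict(self.evidence).items()))
        object.__setattr__(self, "evidence", ev)
        if any(v == self.target for v, _ in ev):
            raise ValueError("query target cannot appear in its evidence")
        if not self.id:
            object.__setattr__(self, "id", self.default_id())

    def default_id(self) -> str:
        if self.evidence:
            ev = ",".join(f"{v}={b}" for v, b in self.evidence)
            return f"p({self.target}=1|{ev})"
        return f"p({self.target}=1)"

    @property
    def evidence_dict(self) -> dict[str, int]:
        return dict(self.evidence)


@dataclass(frozen=True)
class JointDistribution:
    """Probability vector over the ``2**n`` system states of a network."""

    network: CausalNetwork
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (self.network.n_states,):
            raise ValueError("probability vector length must be 2**n")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


def _logistic(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def cpd_prob(
    network: CausalNetwork,
    variable: str,
    parent_assignment: Mapping[str, int],
    params: Parameterization,
) -> float:
    """p(variable = 1 | parents), one entry of the variable's CPD.

    Roots return their prior.  Non-roots use the logistic form with parents
    coded +1 (present) / -1 (absent); multiple parents contribute additively
    inside the logistic.
    """
    parents = set(network.parents(variable))
    given = set(parent_assignment)
    if given != parents:
        raise ValueError(
            f"parent assignment for {variable} must cover exactly {sorted(parents)}, "
            f"got {sorted(given)}"
        )
    if not parents:
        return float(params.root_priors[variable])
    z = float(params.exo_weights[variable])
    for s, t, _ in network.in_links(variable):
        c = 1.0 if parent_assignment[s] else -1.0
        z += params.link_weights[(s, t)] * c
    return float(_logistic(z))


def joint_distribution(
    network: CausalNetwork, params: Parameterization
) -> JointDistribution:
    """Exact joint p(state) = product of per-variable CPDs, by enumeration."""
    params.validate_for(network)
    states = network.states_matrix()  # (N, n) of 0/1
    code = 2.0 * states - 1.0  # +1 / -1 coding
    roots = set(network.roots())
    probs = np.ones(network.n_states)
    for j, v in enumerate(network.variables):
        if v in roots:
            p1 = np.full(network.n_states, params.root_priors[v])
        else:
            z = np.full(network.n_states, float(params.exo_weights[v]))
            for s, t, _ in network.in_links(v):
                z += params.link_weights[(s, t)] * code[:, network.index_of(s)]
            p1 = _logistic(z)
        probs *= np.where(states[:, j] == 1, p1, 1.0 - p1)
    probs /= probs.sum()  # enumeration is exact; guard rounding at 1e-16 scale
    return JointDistribution(network, probs)


def _query_masks(
    network: CausalNetwork, query: Query
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over states: (evidence & target=1, evidence)."""
    states = network.states_matrix()
    ev_mask = np.ones(network.n_states, dtype=bool)
    for v, b in query.evidence:
        ev_mask &= states[:, network.index_of(v)] == b
    tgt_mask = ev_mask & (states[:, network.index_of(query.target)] == 1)
    return tgt_mask, ev_mask


def conditional_query(
    joint: JointDistribution,
    query: Query,
    zero_mass_fallback: float = 0.5,
) -> float:
    """p(target=1 | evidence) from a joint by summing matching states.

    If the evidence has zero probability mass (possible only for degenerate
    sampled joints, never the exact joint), returns ``zero_mass_fallback``.
    """
    net = joint.network
    for v in [query.target, *[v for v, _ in query.evidence]]:
        if v not in net.variables:
            raise ValueError(f"query references unknown variable {v}")
    tgt_mask, ev_mask = _query_masks(net, query)
    denom = float(joint.probs[ev_mask].sum())
    if denom == 0.0:
        return float(zero_mass_fallback)
    return float(joint.probs[tgt_mask].sum() / denom)


def normative_predictions(
    network: CausalNetwork,
    params: Parameterization,
    battery: Iterable[Query],
) -> np.ndarray:
    """Exact-model answers to every query in the battery, in battery order."""
    joint = joint_distribution(network, params)
    return np.array([conditional_query(joint, q) for q in battery])
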