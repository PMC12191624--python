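"""The mutation sampler: biased-start, length-limited MCMC over system states.

The model assumes that people answer conditional probability queries by
sampling network states with a Metropolis-Hastings walk on the hypercube
lattice (the "mutation" move flips a single variable) and reading the
query off the empirical state frequencies.  Two resource assumptions turn
this from a normative approximation into a psychological model:

1. **Short chains.** Only a handful of samples are taken (chain length
   ``lambda_``, typically 10-40), so the visited-state frequencies retain
   the bias of where the chain started.
2. **Prototype starts.** Sampling commences at *prototype* states — full
   assignments qualitatively consistent with every causal link (equal
   values across a generative link, opposite across an inhibitory one),
   ignoring direction and strength.  When no assignment satisfies every
   link (e.g. a structure mixing generative and inhibitory paths to the
   same variable), there is no prototype and the start is unbiased
   (uniform over all states).

Rather than averaging noisy simulated chains, predictions are computed as
the exact *occupancy distribution*: the average of the chain's state
distribution over its first L steps, which is the expectation of the
sampled frequencies.  A seeded stochastic simulator is also provided for
studies of within-subject response variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .networks import (
    GENERATIVE,
    CausalNetwork,
    JointDistribution,
    Parameterization,
    Query,
    conditional_query,
    joint_distribution,
)

__all__ = [
    "PrototypeSet",
    "SamplerSettings",
    "NoPrototypesError",
    "derive_prototypes",
    "transition_matrix",
    "occupancy_distribution",
    "start_distribution",
    "sampler_predictions",
    "simulate_chain",
]


class NoPrototypesError(ValueError):
    """Raised when prototype starts are requested for a network without
    prototypes; use ``start_mode='uniform'`` for such networks."""


@dataclass(frozen=True)
class PrototypeSet:
    """The set of prototype state indices of a network (possibly empty)."""

    network: CausalNetwork
    indices: tuple[int, ...]

    def as_strings(self) -> tuple[str, ...]:
        return tuple(self.network.state_string(i) for i in self.indices)

    def __len__(self) -> int:
        return len(self.indices)

    def __bool__(self) -> bool:
        return bool(self.indices)


@dataclass(frozen=True)
class SamplerSettings:
    """Chain length and start-state policy of the mutation sampler.

    ``lambda_`` is the chain length (number of samples, counting the start
    state); non-integer values interpolate linearly between the two
    adjacent integer-length occupancies, which keeps model predictions
    continuous in ``lambda_`` during fitting.
    """

    lambda_: float = 17.5
    start_mode: Literal["prototypes", "uniform", "custom"] = "prototypes"
    custom_start: np.ndarray | None = None
    zero_mass_fallback: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_) or self.lambda_ < 1:
            raise ValueError("lambda_ must be finite and >= 1")
        if self.start_mode == "custom":
            if self.custom_start is None:
                raise ValueError("custom start mode requires a distribution")
            s = np.asarray(self.custom_start, dtype=float)
            if np.any(s < 0) or abs(s.sum() - 1.0) > 1e-9:
                raise ValueError("custom start must be a normalized distribution")
            object.__setattr__(self, "custom_start", s)


def derive_prototypes(network: CausalNetwork) -> PrototypeSet:
    """Enumerate the states qualitatively consistent with every link.

    A state is a prototype iff for every link the two endpoint values are
    equal (generative link) or unequal (inhibitory link).  Causal direction
    and link strength are deliberately ignored — this is the reasoner's
    superficial, qualitative analysis.  The set may be empty.
    """
    states = network.states_matrix()
    ok = np.ones(network.n_states, dtype=bool)
    for s, t, p in network.links:
        a = states[:, network.index_of(s)]
        b = states[:, network.index_of(t)]
        ok &= (a == b) if p == GENERATIVE else (a != b)
    return PrototypeSet(network, tuple(int(i) for i in np.nonzero(ok)[0]))


def transition_matrix(joint: JointDistribution) -> np.ndarray:
    """Metropolis-Hastings transition matrix targeting the joint.

    Proposal: flip one of the ``n`` variables, chosen uniformly (prob 1/n
    each).  Acceptance: ``min(1, pi(s')/pi(s))``; rejected proposals stay
    put.  Returned matrix ``T`` is **column-stochastic**: ``T[s', s]`` is
    the probability of moving to ``s'`` from ``s``, so distributions evolve
    as ``v_next = T @ v``.  T satisfies detailed balance w.r.t. the joint.
    """
    pi = joint.probs
    if np.any(pi <= 0):
        raise ValueError("transition matrix requires a strictly positive joint")
    n = joint.network.n
    N = joint.network.n_states
    idx = np.arange(N)
    T = np.zeros((N, N))
    for i in range(n):
        flipped = idx ^ (1 << (n - 1 - i))
        acc = np.minimum(1.0, pi[flipped] / pi) / n
        T[flipped, idx] += acc
    T[idx, idx] += 1.0 - T.sum(axis=0)
    return T


def occupancy_distribution(
    T: np.ndarray, start: np.ndarray, lambda_: float
) -> np.ndarray:
    """Expected visited-state frequencies of a chain of length ``lambda_``.

    For integer L this is ``(1/L) * sum_{t=0}^{L-1} T^t @ start`` — the
    start state counts as the first sample, so L = 1 returns the start
    distribution itself (the model's resource-starved limit).  Non-integer
    ``lambda_`` interpolates linearly between the floor- and ceiling-length
    results.
    """
    if lambda_ < 1:
        raise ValueError("chain length must be >= 1")
    start = np.asarray(start, dtype=float)
    lo = int(np.floor(lambda_))
    hi = int(np.ceil(lambda_))
    v = start.copy()
    acc = start.copy()
    occ_lo = None
    for t in range(1, hi):
        if t == lo:
            occ_lo = acc / lo
        v = T @ v
        acc += v
    occ_hi = acc / hi
    if hi == lo:
        return occ_hi
    if occ_lo is None:  # lo == hi - 1 and loop never hit t == lo (lo == hi-1 < 1 impossible; guard anyway)
        occ_lo = occ_hi
    frac = lambda_ - lo
    return (1.0 - frac) * occ_lo + frac * occ_hi


def start_distribution(
    network: CausalNetwork, settings: SamplerSettings
) -> np.ndarray:
    """The chain's start-state distribution under the settings' policy."""
    N = network.n_states
    if settings.start_mode == "uniform":
        return np.full(N, 1.0 / N)
    if settings.start_mode == "custom":
        return settings.custom_start.copy()
    protos = derive_prototypes(network)
    if not protos:
        raise NoPrototypesError(
            "network has no prototype states; use start_mode='uniform' "
            "(the no-prototype variant of the model)"
        )
    start = np.zeros(N)
    start[list(protos.indices)] = 1.0 / len(protos)
    return start


def sampler_predictions(
    network: CausalNetwork,
    params: Parameterization,
    settings: SamplerSettings,
    battery: Iterable[Query],
) -> np.ndarray:
    """Mutation-sampler answers to a query battery.

    Computes the exact occupancy distribution of the finite MH chain and
    answers every query from it, in battery order.  Short chains started at
    prototypes yield systematically distorted conditionals — the model's
    account of Markov violations.
    """
    joint = joint_distribution(network, params)
    T = transition_matrix(joint)
    start = start_distribution(network, settings)
    occ = occupancy_distribution(T, start, settings.lambda_)
    sampled = JointDistribution(network, occ / occ.sum())
    return np.array(
        [conditional_query(sampled, q, settings.zero_mass_fallback) for q in battery]
    )


def simulate_chain(
    network: CausalNetwork,
    params: Parameterization,
    settings: SamplerSettings,
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Simulate one stochastic MH trajectory (state indices, length
    ``n_samples``, start state included).

    The deterministic occupancy computation is what model predictions use;
    this simulator exists for studying within-subject response variability,
    where each query answer comes from a fresh short chain.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    joint = joint_distribution(network, params)
    pi = joint.probs
    n = network.n
    start = start_distribution(network, settings)
    state = int(rng.choice(network.n_states, p=start))
    traj = np.empty(n_samples, dtype=np.int64)
    traj[0] = state
    flips = rng.integers(0, n, size=n_samples - 1)
    accepts = rng.random(n_samples - 1)
    for k in range(n_samples - 1):
        proposal = state ^ (1 << (n - 1 - int(flips[k])))
        if accepts[k] < min(1.0, pi[proposal] / pi[state]):
            state = proposal
        traj[k + 1] = state
    return traj
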