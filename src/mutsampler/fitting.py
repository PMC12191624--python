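"""Per-subject least-squares fitting of the three candidate models.

Each subject's 32 ratings (0-100) are fit by minimizing the sum of squared
error between ratings and 100x the model's predicted probabilities, for
three model variants:

* ``normative`` — exact causal-graphical-model predictions;
* ``ms_prototypes`` — mutation sampler started at the network's prototype
  states;
* ``ms_noprototypes`` — mutation sampler started uniformly at random.

All generative links share one strength parameter ``wgen`` and all
non-root variables one exogenous weight ``wexo``; networks with an
inhibitory link add ``winh``.  Sampler variants add the chain length
``lambda_``, fitted on the log scale so that the search treats 2 -> 4 and
25 -> 50 as comparable moves.  Parameter counts are therefore 3 or 4 for
the normative model and 4 or 5 for the sampler variants.

Models are compared per subject by the least-squares AIC,
``n*ln(SSE/n) + 2*(p+1)``; lower is better.  The optimizer is a seeded
multi-start bounded Nelder-Mead search, so refits with the same seed are
bit-identical.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .battery import QueryBattery
from .networks import GENERATIVE, CausalNetwork
from .sampler import NoPrototypesError, derive_prototypes

__all__ = [
    "VARIANTS",
    "DEFAULT_BOUNDS",
    "ModelSpec",
    "FitResult",
    "DiamondPredictor",
    "fit_subject",
    "aic",
    "geometric_mean_lambda",
    "condition_model_specs",
    "compare_models",
]

VARIANTS = ("normative", "ms_prototypes", "ms_noprototypes")

#: Search bounds; lambda_ is searched as ln(lambda_) within ln([1, 100]).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "wX": (0.01, 0.99),
    "wgen": (0.0, 5.0),
    "winh": (-5.0, 0.0),
    "wexo": (-5.0, 5.0),
    "lambda_": (1.0, 100.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: variant plus its free parameters for a network.

    ``assumed_prototypes`` lets the prototype variant be fit with an
    imposed start set (state strings such as ``("0000", "1111")``) on a
    network whose own prototype set is empty — the comparison run for the
    inhibitory conditions, where the question is precisely whether
    subjects behave as if those all-generative prototypes applied.
    """

    variant: str
    network: CausalNetwork
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    assumed_prototypes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if (
            self.variant == "ms_prototypes"
            and self.assumed_prototypes is None
            and not derive_prototypes(self.network)
        ):
            raise NoPrototypesError(
                "ms_prototypes cannot be fit to a network without prototypes; "
                "pass assumed_prototypes to impose a start set"
            )

    def start_distribution(self) -> np.ndarray | None:
        """Explicit start distribution, or None to use the variant default."""
        if self.assumed_prototypes is None:
            return None
        start = np.zeros(self.network.n_states)
        for s in self.assumed_prototypes:
            start[self.network.state_to_index([int(b) for b in s])] = 1.0
        return start / start.sum()

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["wX", "wgen"]
        if self.network.has_inhibitory():
            names.append("winh")
        names.append("wexo")
        if self.variant != "normative":
            names.append("lambda_")
        return tuple(names)

    @property
    def p(self) -> int:
        return len(self.param_names)


@dataclass(frozen=True)
class FitResult:
    """Best parameters and fit measures for one subject under one spec."""

    variant: str
    params: dict[str, float]
    sse: float
    n: int
    r: float
    aic: float
    n_params: int


class DiamondPredictor:
    """Vectorized predictions for a fixed (network, battery) pair.

    Precomputes the state lattice, the per-variable +-1 parent codes split
    by link polarity, the single-flip neighbor table for the MH proposal,
    and the query evidence/target masks, so that one prediction costs a
    handful of small matrix operations.  Used heavily inside the fitting
    loop; works for any network with one root, not just the diamond.
    """

    def __init__(self, network: CausalNetwork, battery: QueryBattery):
        roots = network.roots()
        if len(roots) != 1:
            raise ValueError("tied-parameter predictor requires exactly one root")
        self.network = network
        self.battery = battery
        self.n = network.n
        self.N = network.n_states
        states = network.states_matrix()
        code = 2.0 * states - 1.0
        self.root_col = network.index_of(roots[0])
        self.root_bits = states[:, self.root_col].astype(float)
        nonroots = [v for v in network.variables if v != roots[0]]
        G = np.zeros((self.N, len(nonroots)))
        I = np.zeros((self.N, len(nonroots)))
        S = np.zeros((self.N, len(nonroots)))
        for j, v in enumerate(nonroots):
            S[:, j] = code[:, network.index_of(v)]
            for s, t, p in network.in_links(v):
                col = code[:, network.index_of(s)]
                if p == GENERATIVE:
                    G[:, j] += col
                else:
                    I[:, j] += col
        self._G, self._I, self._S = G, I, S
        idx = np.arange(self.N)
        self._flips = np.array(
            [idx ^ (1 << (self.n - 1 - i)) for i in range(self.n)]
        )
        M0 = np.zeros((len(battery), self.N))
        M1 = np.zeros((len(battery), self.N))
        for qi, q in enumerate(battery):
            ev = np.ones(self.N, dtype=bool)
            for v, b in q.evidence:
                ev &= states[:, network.index_of(v)] == b
            M0[qi] = ev
            M1[qi] = ev & (states[:, network.index_of(q.target)] == 1)
        self._M0, self._M1 = M0, M1
        protos = derive_prototypes(network)
        self._proto_start = None
        if protos:
            ps = np.zeros(self.N)
            ps[list(protos.indices)] = 1.0 / len(protos)
            self._proto_start = ps
        self._uniform_start = np.full(self.N, 1.0 / self.N)

    def joint(self, wX: float, wgen: float, winh: float, wexo: float) -> np.ndarray:
        z = wexo + wgen * self._G + winh * self._I
        p = 1.0 / (1.0 + np.exp(-z * self._S))
        probs = p.prod(axis=1) * np.where(self.root_bits == 1.0, wX, 1.0 - wX)
        return probs / probs.sum()

    def occupancy(self, pi: np.ndarray, start: np.ndarray, lam: float) -> np.ndarray:
        T = np.zeros((self.N, self.N))
        idx = np.arange(self.N)
        for i in range(self.n):
            f = self._flips[i]
            T[f, idx] += np.minimum(1.0, pi[f] / pi) / self.n
        T[idx, idx] += 1.0 - T.sum(axis=0)
        lo = int(math.floor(lam))
        hi = int(math.ceil(lam))
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
        frac = lam - lo
        return (1.0 - frac) * occ_lo + frac * occ_hi

    def predict(
        self,
        variant: str,
        wX: float,
        wgen: float,
        wexo: float,
        winh: float = 0.0,
        lambda_: float = 1.0,
        zero_mass_fallback: float = 0.5,
        start: np.ndarray | None = None,
    ) -> np.ndarray:
        """Predicted probabilities for every battery query."""
        pi = self.joint(wX, wgen, winh, wexo)
        if variant == "normative":
            dist = pi
        else:
            if start is None:
                if variant == "ms_prototypes":
                    if self._proto_start is None:
                        raise NoPrototypesError("network has no prototypes")
                    start = self._proto_start
                elif variant == "ms_noprototypes":
                    start = self._uniform_start
                else:
                    raise ValueError(f"unknown variant {variant!r}")
            dist = self.occupancy(pi, start, lambda_)
        num = self._M1 @ dist
        den = self._M0 @ dist
        return np.where(den > 0, num / np.maximum(den, 1e-300), zero_mass_fallback)

    def predict_spec(self, spec: ModelSpec, params: Mapping[str, float]) -> np.ndarray:
        return self.predict(
            spec.variant,
            wX=params["wX"],
            wgen=params["wgen"],
            wexo=params["wexo"],
            winh=params.get("winh", 0.0),
            lambda_=params.get("lambda_", 1.0),
            start=spec.start_distribution(),
        )


def aic(sse: float, n: int, p: int) -> float:
    """Least-squares AIC: ``n*ln(SSE/n) + 2*(p+1)`` (natural log).

    A perfect fit (SSE = 0) returns -inf with a warning; in practice rating
    noise keeps SSE positive.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sse < 0:
        raise ValueError("SSE must be non-negative")
    if sse == 0:
        warnings.warn("SSE is exactly 0; AIC is -inf (perfect fit)")
        return float("-inf")
    return n * math.log(sse / n) + 2.0 * (p + 1)


def geometric_mean_lambda(lambdas: Sequence[float]) -> float:
    """exp(mean(ln lambda)): the average chain length on the log scale,
    appropriate because fitted chain lengths are strongly right-skewed."""
    arr = np.asarray(lambdas, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one lambda")
    if np.any(arr <= 0):
        raise ValueError("all lambdas must be positive")
    return float(np.exp(np.mean(np.log(arr))))


def _start_points(
    spec: ModelSpec, rng: np.random.Generator, n_starts: int
) -> np.ndarray:
    """Fixed seeded start set: one canonical start plus uniform draws in the
    (internal, log-lambda) box."""
    lows, highs = [], []
    canonical = []
    canon = {"wX": 0.6, "wgen": 0.5, "winh": -0.4, "wexo": 0.45, "lambda_": 16.0}
    for name in spec.param_names:
        lo, hi = spec.bounds[name]
        if name == "lambda_":
            lo, hi = math.log(lo), math.log(hi)
            canonical.append(math.log(canon[name]))
        else:
            canonical.append(canon[name])
        lows.append(lo)
        highs.append(hi)
    lows = np.array(lows)
    highs = np.array(highs)
    draws = rng.uniform(lows, highs, size=(max(n_starts - 1, 0), len(lows)))
    return np.vstack([np.array(canonical)[None, :], draws])


def fit_subject(
    ratings: Mapping[str, float],
    spec: ModelSpec,
    battery: QueryBattery,
    seed: int = 0,
    n_starts: int = 20,
    maxfev: int = 400,
    predictor: DiamondPredictor | None = None,
) -> FitResult:
    """Fit one model spec to one subject's ratings by least squares.

    ``ratings`` maps query ids (a subset of the battery) to 0-100
    responses.  The objective is ``sum((100*prediction - rating)**2)``
    over the rated queries, minimized by ``n_starts`` bounded Nelder-Mead
    runs from a fixed seeded start set; the best run is returned.
    """
    if predictor is None:
        predictor = DiamondPredictor(spec.network, battery)
    ids = list(battery.ids)
    rated = [i for i, qid in enumerate(ids) if qid in ratings]
    if len(rated) < spec.p + 2:
        raise ValueError(
            f"need at least {spec.p + 2} rated queries to fit {spec.p} parameters, "
            f"got {len(rated)}"
        )
    y = np.array([float(ratings[ids[i]]) for i in rated])
    rated = np.array(rated)
    names = spec.param_names
    lam_pos = names.index("lambda_") if "lambda_" in names else None

    def unpack(theta: np.ndarray) -> dict[str, float]:
        d = dict(zip(names, theta))
        if lam_pos is not None:
            d["lambda_"] = math.exp(theta[lam_pos])
        return d

    def objective(theta: np.ndarray) -> float:
        d = unpack(theta)
        preds = predictor.predict_spec(spec, d)[rated]
        resid = 100.0 * preds - y
        return float(resid @ resid)

    bounds = []
    for name in names:
        lo, hi = spec.bounds[name]
        if name == "lambda_":
            lo, hi = math.log(lo), math.log(hi)
        bounds.append((lo, hi))
    rng = np.random.default_rng(seed)
    starts = _start_points(spec, rng, n_starts)
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)
    preds = predictor.predict_spec(spec, params)[rated]
    resid = 100.0 * preds - y
    sse = float(resid @ resid)
    if np.std(preds) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(100.0 * preds, y)[0, 1])
    else:
        r = 0.0
    return FitResult(
        variant=spec.variant,
        params=params,
        sse=sse,
        n=len(y),
        r=r,
        aic=aic(sse, len(y), spec.p),
        n_params=spec.p,
    )


def condition_model_specs(
    network: CausalNetwork,
    variants: Sequence[str] = VARIANTS,
) -> dict[str, ModelSpec]:
    """ModelSpecs for a condition's network, one per requested variant.

    On networks with no prototype states of their own, the prototype
    variant is built with the all-generative start set (all-present /
    all-absent) imposed, mirroring the model-comparison design for the
    inhibitory conditions.
    """
    specs: dict[str, ModelSpec] = {}
    for v in variants:
        if v == "ms_prototypes" and not derive_prototypes(network):
            ones = "1" * network.n
            zeros = "0" * network.n
            specs[v] = ModelSpec(v, network, assumed_prototypes=(zeros, ones))
        else:
            specs[v] = ModelSpec(v, network)
    return specs


def compare_models(
    fits: Mapping[str, Mapping[str, FitResult]],
) -> dict[str, dict]:
    """Summarize per-subject fits of >= 2 specs over one subject group.

    ``fits`` maps variant -> {subject_id -> FitResult}; all variants must
    cover the same subjects.  Returns, per variant: mean parameters with
    standard errors, mean R, mean AIC, geometric-mean chain length (if
    fitted), and the percentage of subjects for which that variant has the
    lowest AIC (exact ties split equally).
    """
    variants = list(fits)
    if len(variants) < 2:
        raise ValueError("need at least two model specs to compare")
    subjects = sorted(fits[variants[0]])
    for v in variants[1:]:
        if sorted(fits[v]) != subjects:
            raise ValueError("all specs must be fitted to the same subjects")
    best_share = {v: 0.0 for v in variants}
    for s in subjects:
        aics = {v: fits[v][s].aic for v in variants}
        lo = min(aics.values())
        winners = [v for v, a in aics.items() if a == lo]
        for w in winners:
            best_share[w] += 1.0 / len(winners)
    out: dict[str, dict] = {}
    for v in variants:
        results = [fits[v][s] for s in subjects]
        pnames = list(results[0].params)
        summary = {
            "mean_params": {},
            "se_params": {},
            "mean_R": float(np.mean([f.r for f in results])),
            "mean_AIC": float(np.mean([f.aic for f in results])),
            "pct_best": 100.0 * best_share[v] / len(subjects),
            "n_subjects": len(subjects),
        }
        for name in pnames:
            vals = np.array([f.params[name] for f in results])
            if name == "lambda_":
                summary["mean_params"][name] = geometric_mean_lambda(vals)
                logs = np.log(vals)
                summary["se_params"][name] = float(
                    np.std(logs, ddof=1) / math.sqrt(len(vals))
                ) if len(vals) > 1 else 0.0
            else:
                summary["mean_params"][name] = float(vals.mean())
                summary["se_params"][name] = float(
                    np.std(vals, ddof=1) / math.sqrt(len(vals))
                ) if len(vals) > 1 else 0.0
        out[v] = summary
    return out
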