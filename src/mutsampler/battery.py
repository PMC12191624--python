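"""Query batteries and the Markov-violation summary statistic.

The experiment presents each subject with 32 conditional probability
queries about a four-variable "diamond" network X -> {YA, YB} -> Z.  The
12 *Markov queries* probe whether YA and YB are treated as independent
given their common cause X (they normatively are: X screens them off, and
the collider Z is never part of the evidence).  The remaining 20 queries
exercise other inferences over the same network; their exact membership
is configurable, since only the Markov subset enters the headline
statistic.

Sign convention
---------------
``markov_violation_score`` is the mean over the four (target Y, value of
X) cells of

    value(p(Yi=1 | X=x, Yj=1)) - value(p(Yi=1 | X=x, Yj=0)),

i.e. *present minus absent*.  A **positive** score means the screened-off
variable's presence raised the judged probability — the classic positive
Markov violation.  The normative model scores exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .networks import CausalNetwork, Query

__all__ = [
    "QueryBattery",
    "markov_battery",
    "default_battery_32",
    "markov_violation_score",
    "markov_violation_from_predictions",
]


@dataclass(frozen=True)
class QueryBattery:
    """An ordered list of queries with stable, unique string ids."""

    network: CausalNetwork
    queries: tuple[Query, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "queries", tuple(self.queries))
        ids = [q.id for q in self.queries]
        if len(set(ids)) != len(ids):
            raise ValueError("query ids must be unique")
        for q in self.queries:
            for v in [q.target, *[v for v, _ in q.evidence]]:
                if v not in self.network.variables:
                    raise ValueError(f"query {q.id} references unknown variable {v}")

    def __len__(self) -> int:
        return len(self.queries)

    def __iter__(self):
        return iter(self.queries)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(q.id for q in self.queries)

    def by_id(self, query_id: str) -> Query:
        for q in self.queries:
            if q.id == query_id:
                return q
        raise KeyError(query_id)


def markov_battery(
    network: CausalNetwork, x_var: str, y_pair: tuple[str, str]
) -> QueryBattery:
    """The 12 queries probing independence of the Y pair given X.

    For each ordered pair (Yi, Yj) and each x in {0, 1}, in display order
    Yj-absent, Yj-unknown, Yj-present:
    p(Yi=1|X=x,Yj=0), p(Yi=1|X=x), p(Yi=1|X=x,Yj=1).
    """
    ya, yb = y_pair
    for v in (x_var, ya, yb):
        if v not in network.variables:
            raise ValueError(f"{v} is not a network variable")
    for y in (ya, yb):
        if x_var not in network.parents(y):
            raise ValueError(f"{x_var} must be a direct cause of {y}")
    queries = []
    for yi, yj in ((ya, yb), (yb, ya)):
        for x in (0, 1):
            queries.append(Query(yi, ((x_var, x), (yj, 0))))
            queries.append(Query(yi, ((x_var, x),)))
            queries.append(Query(yi, ((x_var, x), (yj, 1))))
    return QueryBattery(network, tuple(queries))


def default_battery_32(
    network: CausalNetwork,
    x_var: str = "X",
    y_pair: tuple[str, str] = ("YA", "YB"),
    z_var: str = "Z",
    extra_queries: Sequence[Query] | None = None,
) -> QueryBattery:
    """The full 32-query battery for the diamond network.

    The 12 Markov queries come first, followed by 20 further conditional
    probability queries over the same four variables (predictive and
    diagnostic inferences involving Z).  Pass ``extra_queries`` to replace
    the default non-Markov block, e.g. to mirror a particular deposited
    query set.
    """
    ya, yb = y_pair
    mk = markov_battery(network, x_var, y_pair)
    if extra_queries is not None:
        extras = tuple(extra_queries)
    else:
        extras = []
        for a, b in product((0, 1), repeat=2):  # p(Z|YA,YB): collider, both parents
            extras.append(Query(z_var, ((ya, a), (yb, b))))
        for y in (ya, yb):  # diagnostic: effect -> root
            for v in (0, 1):
                extras.append(Query(x_var, ((y, v),)))
        for y in (ya, yb):  # diagnostic: terminal effect -> mediator
            for z in (0, 1):
                extras.append(Query(y, ((z_var, z),)))
        for z in (0, 1):  # root <- terminal, both directions
            extras.append(Query(x_var, ((z_var, z),)))
        for x in (0, 1):
            extras.append(Query(z_var, ((x_var, x),)))
        for y in (ya, yb):  # mediator -> terminal
            for v in (0, 1):
                extras.append(Query(z_var, ((y, v),)))
        extras = tuple(extras)
    return QueryBattery(network, mk.queries + extras)


def _markov_cells(
    x_var: str, y_pair: tuple[str, str]
) -> list[tuple[str, str, str]]:
    """(present-id, absent-id) pairs for the four (Yi, x) cells."""
    ya, yb = y_pair
    cells = []
    for yi, yj in ((ya, yb), (yb, ya)):
        for x in (0, 1):
            present = Query(yi, ((x_var, x), (yj, 1))).id
            absent = Query(yi, ((x_var, x), (yj, 0))).id
            cells.append((yi, present, absent))
    return cells


def markov_violation_score(
    values: Mapping[str, float],
    battery: QueryBattery,
    x_var: str = "X",
    y_pair: tuple[str, str] = ("YA", "YB"),
) -> float:
    """Mean (Yj present) - (Yj absent) difference over the four Markov cells.

    ``values`` maps query ids to judgments or predictions on the 0-100
    scale.  Positive scores are positive Markov violations.  Queries in
    the battery outside the eight conditioned Markov queries are ignored.
    """
    battery_ids = set(battery.ids)
    diffs = []
    for _, present, absent in _markov_cells(x_var, y_pair):
        if present not in battery_ids or absent not in battery_ids:
            raise ValueError(f"battery lacks Markov query pair ({present}, {absent})")
        if present not in values or absent not in values:
            raise ValueError(f"values lack Markov query pair ({present}, {absent})")
        diffs.append(float(values[present]) - float(values[absent]))
    return float(np.mean(diffs))


def markov_violation_from_predictions(
    predictions: Sequence[float],
    battery: QueryBattery,
    x_var: str = "X",
    y_pair: tuple[str, str] = ("YA", "YB"),
) -> float:
    """Score model predictions (probabilities), rescaled x100 to the rating
    scale first so model and human scores are directly comparable."""
    values = {q.id: 100.0 * p for q, p in zip(battery.queries, predictions)}
    return markov_violation_score(values, battery, x_var, y_pair)
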