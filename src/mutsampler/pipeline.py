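"""End-to-end analysis steps over a ratings table.

Glue between the ratings dialect and the core modules: compute
per-subject Markov-violation scores, run the group-level statistics, fit
every applicable model variant to every subject, and assemble the
condition-by-model summary tables.  Both the command-line interface and
reproduction scripts drive these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .battery import default_battery_32
from .fitting import (
    DiamondPredictor,
    FitResult,
    compare_models,
    condition_model_specs,
    fit_subject,
)
from .fixtures import CONDITIONS, network_for_condition
from .stats import condition_summary
from .synth import subject_scores

__all__ = [
    "cohort_scores",
    "score_statistics",
    "fit_cohort",
    "fits_to_frame",
    "fit_summaries",
]


def cohort_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Markov-violation scores, one row per subject."""
    frames = []
    for condition, grp in ratings.groupby("condition", sort=True):
        battery = default_battery_32(network_for_condition(condition))
        frames.append(subject_scores(grp, battery))
    return pd.concat(frames, ignore_index=True)


def score_statistics(scores: pd.DataFrame) -> dict:
    """ANOVA, per-condition t-tests, and Bayes factors of the scores."""
    groups = {
        c: scores.loc[scores.condition == c, "score"].to_numpy()
        for c in CONDITIONS
        if (scores.condition == c).any()
    }
    return condition_summary(groups)


def fit_cohort(
    ratings: pd.DataFrame,
    seed: int = 0,
    n_starts: int = 20,
    maxfev: int = 400,
    variants: tuple[str, ...] = ("normative", "ms_prototypes", "ms_noprototypes"),
) -> dict[str, dict[str, dict[str, FitResult]]]:
    """Fit every applicable variant to every subject.

    Returns ``{condition: {variant: {subject_id: FitResult}}}``.  For
    networks with an empty prototype set, ``ms_prototypes`` is dropped
    from that condition's variant list (there is nothing for it to start
    from).
    """
    out: dict[str, dict[str, dict[str, FitResult]]] = {}
    for condition, grp in ratings.groupby("condition", sort=True):
        network = network_for_condition(condition)
        battery = default_battery_32(network)
        predictor = DiamondPredictor(network, battery)
        specs = condition_model_specs(network, variants)
        cond_variants = list(specs)
        fits: dict[str, dict[str, FitResult]] = {v: {} for v in cond_variants}
        for sid, sub in grp.groupby("subject_id", sort=True):
            values = dict(zip(sub["query_id"], sub["rating"]))
            for v in cond_variants:
                fits[v][sid] = fit_subject(
                    values,
                    specs[v],
                    battery,
                    seed=seed,
                    n_starts=n_starts,
                    maxfev=maxfev,
                    predictor=predictor,
                )
        out[condition] = fits
    return out


def fits_to_frame(fits: dict[str, dict[str, dict[str, FitResult]]]) -> pd.DataFrame:
    """Flatten nested fits to one row per subject x variant, with a
    ``best`` flag marking the lowest-AIC variant per subject."""
    rows = []
    for condition, by_variant in fits.items():
        subjects = sorted(next(iter(by_variant.values())))
        for sid in subjects:
            aics = {v: by_variant[v][sid].aic for v in by_variant}
            lo = min(aics.values())
            for v, res in by_variant.items():
                f = res[sid]
                rows.append(
                    {
                        "subject_id": sid,
                        "condition": condition,
                        "variant": v,
                        "wX": f.params.get("wX", np.nan),
                        "wgen": f.params.get("wgen", np.nan),
                        "winh": f.params.get("winh", np.nan),
                        "wexo": f.params.get("wexo", np.nan),
                        "lambda_": f.params.get("lambda_", np.nan),
                        "sse": f.sse,
                        "n": f.n,
                        "r": f.r,
                        "aic": f.aic,
                        "best": f.aic == lo,
                    }
                )
    return pd.DataFrame(rows)


def fit_summaries(fits: dict[str, dict[str, dict[str, FitResult]]]) -> dict:
    """Per-condition model-comparison summaries (mean parameters, R, AIC,
    percent of subjects best fit)."""
    return {
        condition: compare_models(by_variant)
        for condition, by_variant in fits.items()
        if len(by_variant) >= 2
    }
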