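"""Synthetic subject cohorts with the statistical structure of the study.

The real experiment assigns each subject to one of three between-subject
conditions (Generative, YA-Inhibitory, YB-Inhibitory), crossed with a
cover-story domain label, and collects their ratings of the 32-query
battery on a 0-100 slider.  The generator emulates this: each synthetic
subject is a draw of true model parameters, a generating model variant
(normative / sampler with prototypes / sampler without), deterministic
model predictions for every query, and truncated-Gaussian response noise
clipped to the slider range.

By default Generative-condition subjects are generated by the sampler
*with* prototypes and the Inhibitory-condition subjects by the sampler
*without* (the networks have no prototypes), so a default cohort exhibits
the study's signature pattern: positive Markov violations only in the
Generative condition.  Parameter ranges bracket the fitted group averages
reported for this paradigm (root prior around 0.6-0.7, generative
strengths around 0.5-0.8, chain lengths in the teens to thirties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import QueryBattery, default_battery_32, markov_violation_score
from .fitting import (
    DiamondPredictor,
    FitResult,
    condition_model_specs,
    fit_subject,
)
from .fixtures import CONDITIONS, network_for_condition
from .networks import CausalNetwork, Parameterization
from .sampler import derive_prototypes

__all__ = [
    "DOMAINS",
    "SubjectSpec",
    "ExperimentConfig",
    "generate_subject",
    "generate_experiment",
    "subject_scores",
    "recovery_experiment",
]

#: Cover-story domain labels (a between-subject factor with no modeled effect).
DOMAINS = ("economics", "meteorology", "sociology")


@dataclass(frozen=True)
class SubjectSpec:
    """Ground truth for one synthetic subject."""

    subject_id: str
    condition: str
    variant: str  # generating model: normative | ms_prototypes | ms_noprototypes
    wX: float
    wgen: float
    wexo: float
    winh: float | None = None
    lambda_: float | None = None
    noise_sd: float = 10.0
    domain: str = "economics"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Cohort layout and parameter-sampling ranges.

    Defaults follow the study's design: 56 Generative and 28 + 28
    Inhibitory subjects (112 total), domains assigned in rotation, true
    parameters drawn uniformly from ranges that bracket the group-level
    fitted values, chain length log-uniform on [8, 40], and response
    noise with sd 10 rating points.
    """

    subjects_per_condition: dict[str, int] = field(
        default_factory=lambda: {
            "Generative": 56,
            "YA-Inhibitory": 28,
            "YB-Inhibitory": 28,
        }
    )
    #: generating model per condition; None entries fall back to the
    #: condition's natural variant (prototypes where they exist).
    variant_by_condition: dict[str, str] = field(
        default_factory=lambda: {
            "Generative": "ms_prototypes",
            "YA-Inhibitory": "ms_noprototypes",
            "YB-Inhibitory": "ms_noprototypes",
        }
    )
    wX_range: tuple[float, float] = (0.4, 0.8)
    wgen_range: tuple[float, float] = (0.2, 1.0)
    winh_range: tuple[float, float] = (-1.0, -0.2)
    wexo_range: tuple[float, float] = (0.0, 1.0)
    lambda_log_range: tuple[float, float] = (8.0, 40.0)
    noise_sd: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("wX_range", self.wX_range),
            ("wgen_range", self.wgen_range),
            ("winh_range", self.winh_range),
            ("wexo_range", self.wexo_range),
            ("lambda_log_range", self.lambda_log_range),
        ):
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing interval")
        if self.lambda_log_range[0] < 1:
            raise ValueError("chain lengths below 1 are not meaningful")


def _true_params(spec: SubjectSpec, network: CausalNetwork) -> Parameterization:
    return Parameterization.shared(
        network, spec.wX, spec.wgen, spec.wexo, w_inh=spec.winh
    )


def generate_subject(
    spec: SubjectSpec,
    network: CausalNetwork,
    battery: QueryBattery,
    predictor: DiamondPredictor | None = None,
) -> pd.DataFrame:
    """Ratings rows for one subject: clip(100*prediction + N(0, sd), 0, 100).

    Deterministic given ``spec.seed``.  Requesting the prototype-start
    generating model for a network without prototypes raises.
    """
    if spec.variant == "ms_prototypes" and not derive_prototypes(network):
        raise ValueError(
            f"subject {spec.subject_id}: ms_prototypes generator requested for a "
            "network with no prototype states"
        )
    if predictor is None:
        predictor = DiamondPredictor(network, battery)
    preds = predictor.predict(
        spec.variant,
        wX=spec.wX,
        wgen=spec.wgen,
        wexo=spec.wexo,
        winh=spec.winh or 0.0,
        lambda_=spec.lambda_ or 1.0,
    )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(preds)) if spec.noise_sd else 0.0
    ratings = np.clip(100.0 * preds + noise, 0.0, 100.0)
    return pd.DataFrame(
        {
            "subject_id": spec.subject_id,
            "condition": spec.condition,
            "domain": spec.domain,
            "query_id": list(battery.ids),
            "target": [q.target for q in battery],
            "evidence": [
                ",".join(f"{v}={b}" for v, b in q.evidence) for q in battery
            ],
            "rating": ratings,
        }
    )


def _draw_subject_specs(config: ExperimentConfig) -> list[SubjectSpec]:
    rng = np.random.default_rng(config.master_seed)
    specs = []
    counter = 0
    for condition in CONDITIONS:
        n_subj = config.subjects_per_condition.get(condition, 0)
        variant = config.variant_by_condition[condition]
        network = network_for_condition(condition)
        has_inh = network.has_inhibitory()
        for i in range(n_subj):
            lo, hi = config.lambda_log_range
            spec = SubjectSpec(
                subject_id=f"S{counter:03d}",
                condition=condition,
                variant=variant,
                wX=float(rng.uniform(*config.wX_range)),
                wgen=float(rng.uniform(*config.wgen_range)),
                wexo=float(rng.uniform(*config.wexo_range)),
                winh=float(rng.uniform(*config.winh_range)) if has_inh else None,
                lambda_=float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                if variant != "normative"
                else None,
                noise_sd=config.noise_sd,
                domain=DOMAINS[counter % len(DOMAINS)],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            specs.append(spec)
            counter += 1
    return specs


def generate_experiment(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, list[SubjectSpec]]:
    """Generate a full cohort; returns (ratings table, true subject specs).

    Byte-identical output under a fixed master seed: per-subject seeds and
    parameters are expanded deterministically from it.
    """
    specs = _draw_subject_specs(config)
    frames = []
    predictors: dict[str, DiamondPredictor] = {}
    for spec in specs:
        if spec.condition not in predictors:
            net = network_for_condition(spec.condition)
            predictors[spec.condition] = DiamondPredictor(
                net, default_battery_32(net)
            )
        pred = predictors[spec.condition]
        frames.append(generate_subject(spec, pred.network, pred.battery, pred))
    ratings = pd.concat(frames, ignore_index=True)
    return ratings, specs


def subject_scores(ratings: pd.DataFrame, battery: QueryBattery) -> pd.DataFrame:
    """Per-subject Markov-violation scores from a ratings table.

    Returns one row per subject with columns (subject_id, condition, score).
    """
    rows = []
    for (sid, cond), grp in ratings.groupby(["subject_id", "condition"], sort=True):
        values = dict(zip(grp["query_id"], grp["rating"]))
        rows.append(
            {
                "subject_id": sid,
                "condition": cond,
                "score": markov_violation_score(values, battery),
            }
        )
    return pd.DataFrame(rows)


def recovery_experiment(
    config: ExperimentConfig,
    fit_seed: int = 0,
    n_starts: int = 20,
    maxfev: int = 400,
    variants: tuple[str, ...] = ("normative", "ms_prototypes", "ms_noprototypes"),
) -> dict:
    """Generate a cohort, fit every model to every subject, and report how
    well the generating model and its parameters are recovered.

    The report gives, per condition: the fraction of subjects whose
    generating variant attains the lowest AIC (model-recovery rate) and,
    for sampler-generated subjects, bias and RMSE of the recovered
    parameters (chain length on the log scale, reported as a ratio).
    """
    ratings, specs = generate_experiment(config)
    spec_by_id = {s.subject_id: s for s in specs}
    report: dict = {"conditions": {}, "config_master_seed": config.master_seed}
    for condition in CONDITIONS:
        n_subj = config.subjects_per_condition.get(condition, 0)
        if n_subj == 0:
            continue
        network = network_for_condition(condition)
        battery = default_battery_32(network)
        predictor = DiamondPredictor(network, battery)
        model_specs = condition_model_specs(network, variants)
        cond_variants = list(model_specs)
        fits: dict[str, dict[str, FitResult]] = {v: {} for v in cond_variants}
        cond_ids = [s.subject_id for s in specs if s.condition == condition]
        for sid in cond_ids:
            grp = ratings[ratings.subject_id == sid]
            values = dict(zip(grp["query_id"], grp["rating"]))
            for v in cond_variants:
                fits[v][sid] = fit_subject(
                    values,
                    model_specs[v],
                    battery,
                    seed=fit_seed,
                    n_starts=n_starts,
                    maxfev=maxfev,
                    predictor=predictor,
                )
        recovered = 0.0
        wX_err, lam_ratio = [], []
        for sid in cond_ids:
            truth = spec_by_id[sid]
            aics = {v: fits[v][sid].aic for v in cond_variants}
            lo = min(aics.values())
            winners = [v for v, a in aics.items() if a == lo]
            if truth.variant in winners:
                recovered += 1.0 / len(winners)
            best_own = fits[truth.variant][sid]
            wX_err.append(best_own.params["wX"] - truth.wX)
            if truth.lambda_ is not None:
                lam_ratio.append(best_own.params["lambda_"] / truth.lambda_)
        wX_err = np.array(wX_err)
        entry = {
            "n_subjects": len(cond_ids),
            "generating_variant": config.variant_by_condition[condition],
            "model_recovery_rate": recovered / len(cond_ids),
            "wX_bias": float(wX_err.mean()),
            "wX_rmse": float(np.sqrt((wX_err**2).mean())),
            "wX_median_abs_error": float(np.median(np.abs(wX_err))),
        }
        if lam_ratio:
            lr = np.log(np.array(lam_ratio))
            entry["lambda_log_bias"] = float(lr.mean())
            entry["lambda_median_ratio"] = float(np.exp(np.median(lr)))
        report["conditions"][condition] = entry
        report.setdefault("fits", {})[condition] = fits
    return report
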