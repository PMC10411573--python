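"""Leave-one-environment-out evaluation and accuracy metrics.

Each environment serves once as the full testing set while the
remaining environments train the model. Accuracy is summarized per
(trait, environment) group by:

- APC: Pearson correlation between observed and predicted values,
  averaged over groups;
- Best10 / Best20: percentage of the truly top 10% / 20% of lines
  (ranked by observed value, most to least favorable) recovered among
  the same number of top-ranked predicted lines;
- NRMSE: root mean squared error divided by |mean(observed)| of the
  group (range normalization available as an option).

Relative gains between models are percentages of the reference value,
with the challenger in the denominator for lower-is-better metrics so
that error reductions beyond half show up as gains above 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import M1_GE, M1_NO_GE, fit_m1
from .diffmethod import run_m2
from .relmatrices import GenomicRelMatrix
from .solver import SolverOptions
from .tables import validate_phenotypes

logger = logging.getLogger(__name__)

MODELS = (M1_NO_GE, M1_GE, "M2")
METRICS = ("apc", "best10", "best20", "nrmse")
HIGHER_IS_BETTER = {"apc": True, "best10": True, "best20": True, "nrmse": False}


@dataclass
class EvalOptions:
    """Evaluation settings.

    ``trait_direction`` maps trait -> +1 (larger observed value is more
    favorable, e.g. yield) or -1 (smaller is more favorable, e.g. a
    1-5 disease severity scale). Unlisted traits default to +1.
    """

    solver: SolverOptions = field(default_factory=SolverOptions)
    nrmse_norm: str = "mean"  # "mean" | "range"
    trait_direction: dict = field(default_factory=dict)
    fractions: tuple[float, float] = (0.10, 0.20)

    def direction(self, trait) -> int:
        return int(self.trait_direction.get(trait, 1))


@dataclass
class MetricReport:
    """Tidy per-group metric values plus averaging and gain helpers."""

    per_env: pd.DataFrame  # columns: trait, env, model, metric, value

    def by_trait(self) -> pd.DataFrame:
        """Mean over environments within each (trait, model, metric)."""
        return (
            self.per_env.groupby(["trait", "model", "metric"], sort=False)["value"]
            .mean()
            .reset_index()
        )

    def overall(self) -> pd.DataFrame:
        """Mean over environments within trait, then over traits."""
        bt = self.by_trait()
        return (
            bt.groupby(["model", "metric"], sort=False)["value"].mean().reset_index()
        )

    def gains(self, challenger: str = "M2") -> pd.DataFrame:
        """Relative gain of ``challenger`` over every other model, per metric,
        computed on the overall averages."""
        ov = self.overall().pivot(index="metric", columns="model", values="value")
        rows = []
        for metric in ov.index:
            for ref in ov.columns:
                if ref == challenger or challenger not in ov.columns:
                    continue
                gain = relative_gain(
                    ov.at[metric, challenger],
                    ov.at[metric, ref],
                    higher_is_better=HIGHER_IS_BETTER.get(metric, True),
                )
                rows.append(
                    {
                        "metric": metric,
                        "challenger": challenger,
                        "reference": ref,
                        "gain_pct": gain,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.per_env.to_csv(path, index=False)


def loeo_split(phenos: pd.DataFrame) -> list[tuple]:
    """One fold per environment, in input order: (target, training envs)."""
    _, envs, _ = validate_phenotypes(phenos, min_envs=2)
    return [(e, [o for o in envs if o != e]) for e in envs]


def pearson_correlation(observed, predicted) -> float:
    """Plain Pearson r; NaN (with a warning) when either side is constant."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted lengths differ")
    if len(observed) < 3:
        raise ValueError("need at least 3 records for a correlation")
    if np.std(observed) == 0.0 or np.std(predicted) == 0.0:
        logger.warning("constant vector in a correlation group; reporting NaN")
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1])


def pearson_apc(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(trait, env, model) Pearson correlation of observed vs predicted."""
    rows = []
    for (trait, env, model), grp in results.groupby(
        ["trait", "env", "model"], sort=False
    ):
        rows.append(
            {
                "trait": trait,
                "env": env,
                "model": model,
                "metric": "apc",
                "value": pearson_correlation(grp["observed"], grp["predicted"]),
            }
        )
    return pd.DataFrame(rows)


def top_capture(
    observed, predicted, fraction: float, lines=None, direction: int = 1
) -> float:
    """Percentage of truly top lines recovered by the predicted ranking.

    k = round(fraction * J), at least 1; ties are broken by line
    identifier order so the selection is deterministic. ``direction``
    +1 ranks larger values as more favorable, -1 smaller.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    observed = np.asarray(observed, dtype=float) * direction
    predicted = np.asarray(predicted, dtype=float) * direction
    J = len(observed)
    if J < int(np.ceil(1.0 / fraction)):
        raise ValueError(
            f"group of {J} lines is too small for fraction {fraction}"
        )
    if lines is None:
        lines = np.arange(J)
    lines = np.asarray(lines, dtype=object)
    k = max(int(round(fraction * J)), 1)
    # stable two-key ordering: favorability descending, then line id
    order_obs = np.lexsort((lines, -observed))
    order_pred = np.lexsort((lines, -predicted))
    top_obs = set(lines[order_obs[:k]])
    top_pred = set(lines[order_pred[:k]])
    return 100.0 * len(top_obs & top_pred) / k


def nrmse(observed, predicted, norm: str = "mean") -> float:
    """RMSE normalized by |mean(observed)| (or the observed range)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if norm == "mean":
        denom = abs(float(np.mean(observed)))
        if denom == 0.0:
            raise ValueError(
                "observed group mean is zero; use range normalization "
                "(norm='range') instead"
            )
    elif norm == "range":
        denom = float(np.max(observed) - np.min(observed))
        if denom == 0.0:
            raise ValueError("observed group has zero range")
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    return rmse / denom


def relative_gain(challenger: float, reference: float, higher_is_better: bool) -> float:
    """Percent improvement of the challenger over the reference.

    For lower-is-better metrics the challenger sits in the denominator,
    so halving the error reads as a 100% gain.
    """
    if higher_is_better:
        if reference == 0.0:
            logger.warning("zero reference metric; gain undefined")
            return float("nan")
        return 100.0 * (challenger - reference) / abs(reference)
    if challenger == 0.0:
        logger.warning("zero challenger metric; gain undefined")
        return float("nan")
    return 100.0 * (reference - challenger) / abs(challenger)


def metrics_for_group(
    grp: pd.DataFrame, options: EvalOptions, trait
) -> dict[str, float]:
    """All four metrics for one (trait, env, model) prediction group."""
    obs = grp["observed"].to_numpy(float)
    pred = grp["predicted"].to_numpy(float)
    lines = grp["line"].to_numpy(object)
    direction = options.direction(trait)
    f10, f20 = options.fractions
    return {
        "apc": pearson_correlation(obs, pred),
        "best10": top_capture(obs, pred, f10, lines=lines, direction=direction),
        "best20": top_capture(obs, pred, f20, lines=lines, direction=direction),
        "nrmse": nrmse(obs, pred, norm=options.nrmse_norm),
    }


def evaluate_all(
    phenos: pd.DataFrame,
    G: GenomicRelMatrix,
    models=MODELS,
    options: EvalOptions | None = None,
) -> MetricReport:
    """Run every requested model through full leave-one-environment-out
    prediction, for every trait, and assemble the metric report."""
    options = options or EvalOptions()
    models = list(models)
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}; choose from {MODELS}")
    _, envs, traits = validate_phenotypes(phenos, min_envs=2)
    predictions = collect_predictions(phenos, G, models, options)
    rows = []
    for (trait, env, model), grp in predictions.groupby(
        ["trait", "env", "model"], sort=False
    ):
        for metric, value in metrics_for_group(grp, options, trait).items():
            rows.append(
                {
                    "trait": trait,
                    "env": env,
                    "model": model,
                    "metric": metric,
                    "value": value,
                }
            )
    return MetricReport(per_env=pd.DataFrame(rows))


def collect_predictions(
    phenos: pd.DataFrame,
    G: GenomicRelMatrix,
    models=MODELS,
    options: EvalOptions | None = None,
) -> pd.DataFrame:
    """LOEO predictions for all folds, traits, and requested models."""
    options = options or EvalOptions()
    _, envs, traits = validate_phenotypes(phenos, min_envs=2)
    out = []
    for trait in traits:
        for target, _training in loeo_split(phenos):
            for model in models:
                if model == M1_GE:
                    res = fit_m1(
                        phenos, G, target, include_ge=True, trait=trait,
                        options=options.solver,
                    )
                elif model == M1_NO_GE:
                    res = fit_m1(
                        phenos, G, target, include_ge=False, trait=trait,
                        options=options.solver,
                    )
                elif model == "M2":
                    res = run_m2(phenos, G, target, trait, options=options.solver)
                else:  # pragma: no cover - guarded in evaluate_all
                    raise ValueError(f"unknown model {model!r}")
                out.append(res)
    return pd.concat(out, ignore_index=True)
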