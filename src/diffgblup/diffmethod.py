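"""The difference-response predictor for tested lines in untested
environments.

Instead of training on the raw phenotype, the method trains a GBLUP on
pairwise between-environment differences of each line,

    d_(i,i',j) = y_ij - y_i'j,

which cancels environment main effects shared by a line across two
environments and thereby shrinks the distribution mismatch between
training environments and an unseen target environment. Differences
involving the target environment are masked, predicted by a
line-effect GBLUP (intercept + genomic kernel), and the target
phenotypes are reconstructed as an ensemble over the I-1 training
environments:

    yhat_tj = 1/(I-1) * sum_i' (y_i'j + s * dhat)

where s = +1 when the target is the first member of the pair and -1
when it is the second (the difference then estimates y_i' - y_t).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .relmatrices import GenomicRelMatrix
from .solver import KernelSpec, SolverOptions, fit_lmm, predict_masked
from .tables import pivot_trait, prediction_frame, validate_phenotypes

FRAME_COLUMNS = ("obs", "line", "env_i", "env_iprime", "y_i", "y_iprime", "d")


@dataclass
class DifferenceFrame:
    """The stacked pairwise-difference table.

    ``frame`` has one block of J rows per unordered environment pair,
    blocks in ``pair_order``; within a block, lines keep their input
    order. ``d`` is NaN on rows masked for prediction.
    """

    frame: pd.DataFrame
    pair_order: list[tuple]

    @property
    def n_lines(self) -> int:
        return self.frame["line"].nunique()

    @property
    def environments(self) -> list:
        seen: dict = {}
        for a, b in self.pair_order:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        return list(seen)

    @property
    def masked(self) -> np.ndarray:
        return self.frame["d"].isna().to_numpy()

    def to_csv(self, path) -> None:
        """Export mirroring the stacked layout; NA rendered as empty field."""
        self.frame.to_csv(path, index=False, na_rep="")


def enumerate_pairs(envs) -> list[tuple]:
    """All C(I, 2) unordered environment pairs, in input order.

    Pairs are emitted lexicographically by (first index, second index),
    so each pair's first element occurs earlier in the input ordering.
    """
    envs = list(envs)
    if len(set(envs)) != len(envs):
        raise ValueError("duplicate environment identifiers")
    if len(envs) < 2:
        raise ValueError("need at least 2 environments to form pairs")
    return list(combinations(envs, 2))


def build_difference_frame(
    phenos: pd.DataFrame, trait, min_envs: int = 3
) -> DifferenceFrame:
    """Stack the per-pair difference blocks for one trait.

    Requires a balanced table with at least three environments (two
    would leave no training pairs once one environment is masked).
    """
    validate_phenotypes(phenos, min_envs=2)
    wide = pivot_trait(phenos, trait)
    envs = list(wide.columns)
    lines = list(wide.index)
    if len(envs) < min_envs:
        raise ValueError(
            f"the difference method assumes at least {min_envs} environments, "
            f"found {len(envs)}"
        )
    pairs = enumerate_pairs(envs)
    blocks = []
    obs0 = 1
    for ei, ep in pairs:
        yi = wide[ei].to_numpy(dtype=float)
        yp = wide[ep].to_numpy(dtype=float)
        blocks.append(
            pd.DataFrame(
                {
                    "obs": np.arange(obs0, obs0 + len(lines)),
                    "line": lines,
                    "env_i": ei,
                    "env_iprime": ep,
                    "y_i": yi,
                    "y_iprime": yp,
                    "d": yi - yp,
                }
            )
        )
        obs0 += len(lines)
    frame = pd.concat(blocks, ignore_index=True)
    return DifferenceFrame(frame=frame, pair_order=pairs)


def mask_for_target_env(diff: DifferenceFrame, target_env) -> DifferenceFrame:
    """NA out the difference response wherever the target environment
    appears; those rows form the testing set, the rest the training set."""
    envs = diff.environments
    if target_env not in envs:
        raise ValueError(f"target environment {target_env!r} not in the frame")
    frame = diff.frame.copy()
    hit = (frame["env_i"] == target_env) | (frame["env_iprime"] == target_env)
    frame.loc[hit, "d"] = np.nan
    return DifferenceFrame(frame=frame, pair_order=list(diff.pair_order))


def fit_difference_model(
    diff: DifferenceFrame,
    G: GenomicRelMatrix,
    options: SolverOptions | None = None,
    fixed_components: dict[str, float] | None = None,
) -> np.ndarray:
    """Fit d = mu + g_j + e on unmasked rows and predict the masked ones.

    The line effect carries covariance sigma2_g G through the line
    incidence of the stacked frame; the returned vector holds dhat for
    the masked rows in frame order.
    """
    frame = diff.frame
    d = frame["d"].to_numpy(dtype=float)
    masked = np.isnan(d)
    if not (~masked).any():
        raise ValueError("difference frame has no training rows")
    ix = G.index_of(frame["line"])
    Kg = G.values[np.ix_(ix, ix)]
    fit = fit_lmm(
        d,
        [KernelSpec("line", Kg)],
        options=options,
        fixed_components=fixed_components,
    )
    return predict_masked(fit, masked)


def ensemble_predictions(
    diff: DifferenceFrame,
    d_hat: np.ndarray,
    target_env,
    trait="trait",
    observed: np.ndarray | None = None,
) -> pd.DataFrame:
    """Reconstruct target-environment phenotypes from predicted
    differences, averaging the I-1 pair-wise reconstructions per line."""
    frame = diff.frame
    masked = diff.masked
    d_hat = np.asarray(d_hat, dtype=float)
    envs = diff.environments
    n_envs = len(envs)
    lines = list(pd.unique(frame["line"]))
    expected = len(lines) * (n_envs - 1)
    if int(masked.sum()) != expected:
        raise ValueError(
            f"{int(masked.sum())} masked rows; expected J*(I-1) = {expected} "
            f"for a single target environment"
        )
    if len(d_hat) != expected:
        raise ValueError(
            f"d_hat has length {len(d_hat)}, expected J*(I-1) = {expected}"
        )
    sub = frame.loc[masked, ["line", "env_i", "env_iprime", "y_i", "y_iprime"]].copy()
    sub["d_hat"] = d_hat
    is_first = sub["env_i"] == target_env
    is_second = sub["env_iprime"] == target_env
    if not (is_first | is_second).all():
        raise ValueError("masked rows must all involve the target environment")
    # known phenotype of the non-target environment, plus the signed
    # predicted difference pointing from it to the target
    term = np.where(
        is_first,
        sub["y_iprime"].to_numpy(float) + sub["d_hat"].to_numpy(float),
        sub["y_i"].to_numpy(float) - sub["d_hat"].to_numpy(float),
    )
    sub = sub.assign(term=term)
    per_line = sub.groupby("line", sort=False)["term"].mean()
    per_line = per_line.reindex(lines)
    obs_vals = (
        np.asarray(observed, dtype=float)
        if observed is not None
        else np.full(len(lines), np.nan)
    )
    return prediction_frame(
        lines, target_env, trait, obs_vals, per_line.to_numpy(), "M2"
    )


def run_m2(
    phenos: pd.DataFrame,
    G: GenomicRelMatrix,
    target_env,
    trait,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """End-to-end difference-response prediction of one environment."""
    diff = build_difference_frame(phenos, trait)
    masked_frame = mask_for_target_env(diff, target_env)
    d_hat = fit_difference_model(masked_frame, G, options=options)
    wide = pivot_trait(phenos, trait)
    observed = wide[target_env].to_numpy(dtype=float)
    return ensemble_predictions(
        masked_frame, d_hat, target_env, trait=trait, observed=observed
    )
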