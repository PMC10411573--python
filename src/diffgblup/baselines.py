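"""Conventional multi-environment GBLUP predictors.

The model is

    y_ij = mu + L_i + g_j + gL_ij + e_ij

with random environment effects L ~ N(0, sigma2_L H), genomic line
effects g ~ N(0, sigma2_g G), and (optionally) the separable
genotype-by-environment term gL ~ N(0, sigma2_gL H (.) Z_g G Z_g').
With H built purely from environment incidence, an unseen target
environment has zero covariance with every training observation, so
its environment and interaction BLUPs are zero and the prediction for
line j reduces to mu + g_j (plus nothing the target environment could
inform). That blindness to environment-level novelty is exactly what
the difference-response method is designed to sidestep.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .relmatrices import GenomicRelMatrix, env_relationship, interaction_kernel
from .solver import KernelSpec, SolverOptions, fit_lmm, predict_masked
from .tables import pivot_trait, prediction_frame, validate_phenotypes

M1_GE = "M1_GE"
M1_NO_GE = "M1_NO_GE"


def fit_m1(
    phenos: pd.DataFrame,
    G: GenomicRelMatrix,
    target_env,
    include_ge: bool = True,
    trait=None,
    options: SolverOptions | None = None,
    fixed_components: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Train on all environments except ``target_env`` and predict every
    line there.

    The observation index covers all (line, env) cells; responses at
    the target environment are masked and recovered from the fitted
    conditional mean. ``include_ge`` toggles the interaction kernel
    (model tags M1_GE / M1_NO_GE).
    """
    lines, envs, traits = validate_phenotypes(phenos, min_envs=2)
    if target_env not in envs:
        raise ValueError(f"target environment {target_env!r} not in the table")
    if len(envs) < 3:
        raise ValueError("need at least 2 training environments besides the target")
    if trait is None:
        if len(traits) != 1:
            raise ValueError(f"specify one of the traits {traits}")
        trait = traits[0]
    wide = pivot_trait(phenos, trait)
    envs = list(wide.columns)
    lines = list(wide.index)

    # env-major observation order: all lines of E1, then E2, ...
    env_labels = np.repeat(envs, len(lines))
    line_labels = np.tile(lines, len(envs))
    y = wide.to_numpy(dtype=float).T.reshape(-1).copy()
    observed_target = wide[target_env].to_numpy(dtype=float)
    target_mask = env_labels == target_env
    y[target_mask] = np.nan

    H = env_relationship(env_labels, scale=1.0)
    ix = G.index_of(line_labels)
    Kg = G.values[np.ix_(ix, ix)]
    kernels = [KernelSpec("env", H.values), KernelSpec("line", Kg)]
    if include_ge:
        kernels.append(KernelSpec("ge", interaction_kernel(H, line_labels, G)))
    fit = fit_lmm(y, kernels, options=options, fixed_components=fixed_components)
    predicted = predict_masked(fit, target_mask)
    model = M1_GE if include_ge else M1_NO_GE
    return prediction_frame(lines, target_env, trait, observed_target, predicted, model)
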