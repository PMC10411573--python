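"""Simulation studies exercising the predictors end to end.

These drivers define the package's reference study conditions: balanced
trials generated from the additive multi-environment model with
variance components (sigma2_L, sigma2_g, sigma2_gL, sigma2) =
(1, 1, 0.25, 0.5) in trait-units squared, a marker panel of several
hundred loci, and — for the non-stationarity study — a deterministic
mean shift of two residual standard deviations applied to one
designated environment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import evaluate_all
from .relmatrices import env_relationship, interaction_kernel, vanraden_grm
from .solver import KernelSpec, SolverOptions, fit_lmm
from .synthetic import SimConfig, simulate_markers, simulate_trial

BASE_VARIANCES = dict(var_env=1.0, var_g=1.0, var_ge=0.25, var_e=0.5)


def _derive_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 100_003 + 7 * index + 1) % (2**31 - 1))


def variance_recovery_study(
    n_seeds: int = 20,
    J: int = 300,
    I: int = 4,
    p: int = 400,
    base_seed: int = 0,
    variances: dict | None = None,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Fit the full four-component model to its own generative output.

    Returns one row per seed with the REML estimates of
    (var_env, var_g, var_ge, var_e); the generating values are in the
    DataFrame ``attrs``.
    """
    variances = dict(variances or BASE_VARIANCES)
    rows = []
    for i in range(n_seeds):
        cfg = SimConfig(J=J, I=I, p=p, seed=_derive_seed(base_seed, i), **variances)
        markers = simulate_markers(cfg)
        G = vanraden_grm(markers)
        phenos, _ = simulate_trial(markers, cfg)
        wide = phenos.pivot(index="line", columns="env", values="value")
        lines = list(markers.line_ids)
        envs = cfg.env_ids
        env_labels = np.repeat(envs, J)
        line_labels = np.tile(lines, I)
        y = np.concatenate([wide.loc[lines, e].to_numpy() for e in envs])
        H = env_relationship(env_labels)
        ix = G.index_of(line_labels)
        Kg = G.values[np.ix_(ix, ix)]
        fit = fit_lmm(
            y,
            [
                KernelSpec("env", H.values),
                KernelSpec("line", Kg),
                KernelSpec("ge", interaction_kernel(H, line_labels, G)),
            ],
            options=options,
        )
        comp = fit.components
        rows.append(
            {
                "seed": cfg.seed,
                "var_env": comp.kernel_vars["env"],
                "var_g": comp.kernel_vars["line"],
                "var_ge": comp.kernel_vars["ge"],
                "var_e": comp.residual,
                "converged": fit.converged,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["truth"] = variances
    return out


def _loeo_overall(phenos, G, models, options=None) -> dict:
    report = evaluate_all(phenos, G, models=models, options=options)
    ov = report.overall().pivot(index="metric", columns="model", values="value")
    return {
        f"{metric}_{model}": float(ov.at[metric, model])
        for metric in ov.index
        for model in ov.columns
    }


def shift_study(
    n_seeds: int = 30,
    J: int = 200,
    I: int = 4,
    p: int = 500,
    shift_resid_sds: float = 2.0,
    base_seed: int = 0,
    models: tuple = ("M1_GE", "M2"),
) -> pd.DataFrame:
    """Full-LOEO comparison under a deterministic environment-mean shift.

    One environment (E1) receives a mean offset of ``shift_resid_sds``
    residual standard deviations, creating the train/test distribution
    mismatch of a non-stationary environment. Each row holds one
    seed's across-environment average metrics per model.
    """
    shift = shift_resid_sds * float(np.sqrt(BASE_VARIANCES["var_e"]))
    rows = []
    for i in range(n_seeds):
        cfg = SimConfig(
            J=J, I=I, p=p, seed=_derive_seed(base_seed, i),
            shift=shift, shift_env=0, **BASE_VARIANCES,
        )
        markers = simulate_markers(cfg)
        G = vanraden_grm(markers)
        phenos, _ = simulate_trial(markers, cfg)
        rows.append({"seed": cfg.seed, **_loeo_overall(phenos, G, list(models))})
    return pd.DataFrame(rows)


def stationary_study(
    n_seeds: int = 20,
    J: int = 200,
    I: int = 4,
    p: int = 500,
    base_seed: int = 0,
    models: tuple = ("M1_NO_GE", "M2"),
) -> pd.DataFrame:
    """Full-LOEO comparison with zero shift and zero G-by-E interaction:
    the regime where the difference predictor and the plain GBLUP should
    agree closely."""
    variances = dict(BASE_VARIANCES, var_ge=0.0)
    rows = []
    for i in range(n_seeds):
        cfg = SimConfig(
            J=J, I=I, p=p, seed=_derive_seed(base_seed, i), shift=0.0, **variances
        )
        markers = simulate_markers(cfg)
        G = vanraden_grm(markers)
        phenos, _ = simulate_trial(markers, cfg)
        rows.append({"seed": cfg.seed, **_loeo_overall(phenos, G, list(models))})
    return pd.DataFrame(rows)
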