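"""Validation and reshaping of long-format phenotype tables.

A phenotype table is a tidy DataFrame with columns
``line, env, trait, value`` that is *balanced* per trait: every line
is observed exactly once in every environment. Line and environment
orderings are taken from first appearance in the table, which keeps
every downstream construction deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PHENO_COLUMNS = ("line", "env", "trait", "value")


def validate_phenotypes(
    phenos: pd.DataFrame, min_envs: int = 2
) -> tuple[list, list, list]:
    """Check table layout and balance; return (lines, envs, traits) in
    first-appearance order."""
    missing_cols = [c for c in PHENO_COLUMNS if c not in phenos.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns {missing_cols}")
    lines = list(pd.unique(phenos["line"]))
    envs = list(pd.unique(phenos["env"]))
    traits = list(pd.unique(phenos["trait"]))
    if len(envs) < min_envs:
        raise ValueError(
            f"need at least {min_envs} environments, found {len(envs)}"
        )
    dup = phenos.duplicated(subset=["line", "env", "trait"], keep=False)
    if dup.any():
        offenders = (
            phenos.loc[dup, ["line", "env", "trait"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValueError(
            "duplicate (line, env, trait) records: " + ", ".join(map(str, offenders))
        )
    counts = phenos.groupby("trait", sort=False).size()
    for trait, k in counts.items():
        if k != len(lines) * len(envs):
            present = set(
                map(
                    tuple,
                    phenos.loc[phenos["trait"] == trait, ["line", "env"]].values,
                )
            )
            absent = [
                (l, e) for l in lines for e in envs if (l, e) not in present
            ]
            raise ValueError(
                f"unbalanced table for trait {trait!r}: missing cells {absent[:5]}"
                + ("..." if len(absent) > 5 else "")
            )
    return lines, envs, traits


def pivot_trait(phenos: pd.DataFrame, trait) -> pd.DataFrame:
    """Lines x environments value matrix for one trait.

    Rows and columns follow first appearance in the table; a missing
    (line, env) cell raises.
    """
    sub = phenos[phenos["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in the phenotype table")
    lines = list(pd.unique(sub["line"]))
    envs = list(pd.unique(sub["env"]))
    wide = sub.pivot(index="line", columns="env", values="value")
    wide = wide.reindex(index=lines, columns=envs)
    if wide.isna().any().any():
        miss = [
            (l, e)
            for l in lines
            for e in envs
            if pd.isna(wide.at[l, e])
        ]
        raise ValueError(f"missing (line, env) cells for trait {trait!r}: {miss[:5]}")
    return wide


def balanced_from_values(values_by_env: dict, lines=None, trait="trait") -> pd.DataFrame:
    """Build a balanced long-format table from {env: per-line values}."""
    envs = list(values_by_env)
    n = len(next(iter(values_by_env.values())))
    if lines is None:
        lines = [f"g{j + 1}" for j in range(n)]
    records = [
        (line, env, trait, float(values_by_env[env][j]))
        for env in envs
        for j, line in enumerate(lines)
    ]
    return pd.DataFrame(records, columns=list(PHENO_COLUMNS))


def prediction_frame(
    lines, env, trait, observed, predicted, model: str
) -> pd.DataFrame:
    """Assemble a tidy prediction record for one target environment."""
    out = pd.DataFrame(
        {
            "line": list(lines),
            "env": env,
            "trait": trait,
            "observed": np.asarray(observed, dtype=float),
            "predicted": np.asarray(predicted, dtype=float),
            "model": model,
        }
    )
    if not np.isfinite(out["predicted"]).all():
        raise ValueError(f"non-finite predictions produced by model {model}")
    return out
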