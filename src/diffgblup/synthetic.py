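"""Simulation of marker panels and balanced multi-environment trials.

The phenotype generator follows the additive multi-environment model

    y_ij = mu + L_i + g_j + gL_ij + e_ij

with a marker-derived genetic value g, environment main effects L,
separable genotype-by-environment deviations gL (environment-specific
marker effects), and i.i.d. residuals. A deterministic mean ``shift``
can be added to one designated environment to create the train/test
distribution mismatch that arises from non-stationary environments —
the scenario the difference-response predictor is designed to survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmatrices import MarkerMatrix


@dataclass
class SimConfig:
    """Parameters of one simulated multi-environment trial.

    Variances are in squared trait units; ``shift`` (trait units) is a
    deterministic offset added to the environment at index
    ``shift_env`` on top of its random main effect.
    """

    J: int = 100  # lines
    I: int = 4  # environments
    p: int = 500  # markers
    maf_range: tuple[float, float] = (0.05, 0.5)
    mu: float = 10.0
    var_env: float = 1.0  # sigma2_L
    var_g: float = 1.0  # sigma2_g
    var_ge: float = 0.25  # sigma2_gL
    var_e: float = 0.5  # sigma2 (residual)
    shift: float = 0.0
    shift_env: int = 0
    seed: int = 0
    trait: str = "sim_trait"

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError("J must be >= 2")
        if self.I < 3:
            raise ValueError("I must be >= 3")
        if self.p < 10:
            raise ValueError("p must be >= 10")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )
        for name in ("var_env", "var_g", "var_ge", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.shift_env < self.I:
            raise ValueError("shift_env must index an environment")

    @property
    def env_ids(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.I)]

    @property
    def line_ids(self) -> list[str]:
        width = len(str(self.J))
        return [f"L{j + 1:0{width}d}" for j in range(self.J)]


@dataclass
class TrialTruth:
    """Ground-truth effects of one simulated trial, for recovery tests.

    ``genetic_value[t]`` is the environment-specific genetic signal
    g_j + gL_ij (what an ideal genomic predictor could recover in
    environment t); ``env_effects`` includes the deterministic shift.
    """

    env_ids: list[str]
    line_ids: list[str]
    mu: float
    env_effects: np.ndarray  # (I,)
    line_effects: np.ndarray  # (J,)
    ge_effects: np.ndarray  # (I, J)
    config: SimConfig = field(repr=False, default=None)

    def genetic_value(self, env: str) -> np.ndarray:
        i = self.env_ids.index(env)
        return self.line_effects + self.ge_effects[i]

    def to_dict(self) -> dict:
        return {
            "env_ids": list(self.env_ids),
            "line_ids": list(self.line_ids),
            "mu": self.mu,
            "env_effects": self.env_effects.tolist(),
            "line_effects": self.line_effects.tolist(),
            "ge_effects": self.ge_effects.tolist(),
        }


def simulate_markers(config: SimConfig) -> MarkerMatrix:
    """Draw a panel of independent biallelic markers.

    Allele frequencies are uniform on ``maf_range`` and dosages are
    binomial(2, freq) per line (Hardy-Weinberg sampling, no linkage).
    """
    rng = np.random.default_rng(config.seed)
    freqs = rng.uniform(*config.maf_range, size=config.p)
    dosages = rng.binomial(2, freqs, size=(config.J, config.p)).astype(float)
    width = len(str(config.p))
    marker_ids = [f"M{k + 1:0{width}d}" for k in range(config.p)]
    return MarkerMatrix(
        line_ids=np.array(config.line_ids, dtype=object),
        marker_ids=np.array(marker_ids, dtype=object),
        dosages=dosages,
    )


def simulate_trial(
    markers: MarkerMatrix, config: SimConfig
) -> tuple[pd.DataFrame, TrialTruth]:
    """Generate one balanced trial from a marker panel.

    Returns the long-format phenotype table (line, env, trait, value)
    and the true effect record. Marker effects for the main genetic
    value and for each environment's G-by-E deviation are drawn as
    N(0, var / (2 sum_k p_k q_k)), so realized variances match the
    configured components in expectation and the simulated G-by-E
    covariance is separable — attainable by the Hadamard kernel the
    fitted model assumes.
    """
    if np.isnan(markers.dosages).any():
        raise ValueError("simulate_trial needs a complete (imputed) marker panel")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    J, I = markers.n_lines, config.I
    if J != config.J:
        raise ValueError(f"marker panel has {J} lines but config.J = {config.J}")
    p_freq = markers.dosages.mean(axis=0) / 2.0
    sum_pq = float(np.sum(p_freq * (1.0 - p_freq)))
    if sum_pq <= 0:
        raise ValueError("all markers monomorphic; cannot scale genetic effects")
    W = markers.dosages - 2.0 * p_freq

    def genetic(var: float) -> np.ndarray:
        if var == 0.0:
            return np.zeros(J)
        w = rng.normal(0.0, np.sqrt(var / (2.0 * sum_pq)), size=markers.n_markers)
        return W @ w

    g = genetic(config.var_g)
    gL = np.vstack([genetic(config.var_ge) for _ in range(I)])
    L = rng.normal(0.0, np.sqrt(config.var_env), size=I) if config.var_env else np.zeros(I)
    L = L.astype(float)
    L[config.shift_env] += config.shift
    eps = (
        rng.normal(0.0, np.sqrt(config.var_e), size=(I, J))
        if config.var_e
        else np.zeros((I, J))
    )

    env_ids = config.env_ids
    line_ids = list(markers.line_ids)
    records = []
    for i, env in enumerate(env_ids):
        values = config.mu + L[i] + g + gL[i] + eps[i]
        for j, line in enumerate(line_ids):
            records.append((line, env, config.trait, values[j]))
    phenos = pd.DataFrame(records, columns=["line", "env", "trait", "value"])
    truth = TrialTruth(
        env_ids=env_ids,
        line_ids=line_ids,
        mu=config.mu,
        env_effects=L,
        line_effects=g,
        ge_effects=gL,
        config=config,
    )
    return phenos, truth
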