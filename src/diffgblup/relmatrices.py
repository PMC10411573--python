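"""Marker quality control and relationship-kernel construction.

Builds the three covariance structures of the multi-environment GBLUP
model: the genomic relationship matrix ``G`` (VanRaden method 1), the
environmental relationship matrix ``H`` derived from the environment
incidence design, and their Hadamard interaction kernel used for
genotype-by-environment effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: relative ridge added to the GRM diagonal so Gram matrices stay PSD
#: under finite precision
GRM_RIDGE = 1e-8


class EmptyPanelError(ValueError):
    """All markers were removed by quality control."""


@dataclass
class MarkerMatrix:
    """A panel of J lines x p biallelic markers, dosage-coded 0/1/2.

    Missing genotypes are stored as NaN in ``dosages``.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray  # (J, p) float, NaN marks a missing call
    #: True once missing calls have been replaced by (fractional) column
    #: means; integer dosage coding is then no longer enforced
    imputed: bool = False

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        J, p = self.n_lines, self.n_markers
        if J < 2:
            raise ValueError(f"need at least 2 lines, got {J}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if self.dosages.shape != (J, p):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{J} lines x {p} markers"
            )
        if len(set(self.line_ids)) != J:
            raise ValueError("line identifiers must be unique")
        if len(set(self.marker_ids)) != p:
            raise ValueError("marker identifiers must be unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if self.imputed:
            if vals.size and (vals.min() < 0.0 or vals.max() > 2.0):
                raise ValueError("imputed dosages must lie in [0, 2]")
        elif not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals) - {0.0, 1.0, 2.0})
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)


@dataclass
class GenomicRelMatrix:
    """VanRaden genomic relationship matrix over a set of lines."""

    line_ids: np.ndarray
    values: np.ndarray  # (J, J), symmetric PSD

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        J = len(self.line_ids)
        if self.values.shape != (J, J):
            raise ValueError("GRM must be square over the line set")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    def index_of(self, labels) -> np.ndarray:
        """Row/column positions of ``labels``; unknown labels raise."""
        pos = {lid: k for k, lid in enumerate(self.line_ids)}
        try:
            return np.array([pos[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"line {exc.args[0]!r} not present in the GRM") from None


@dataclass
class EnvRelMatrix:
    """Block-structured environmental relationship matrix H = X_L X_L' / scale."""

    env_labels: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    scale: float = 1.0

    @property
    def n_obs(self) -> int:
        return len(self.env_labels)


def filter_markers(
    markers: MarkerMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.15,
) -> MarkerMatrix:
    """Drop markers with too many missing calls or too little variation.

    A marker is retained when its missing fraction is <= ``missing_max``
    and its minor allele frequency, computed from non-missing dosages as
    min(pbar, 1 - pbar) with pbar = mean(dosage)/2, is >= ``maf_min``.
    Marker order is preserved and the operation is idempotent.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must lie in [0, 0.5), got {maf_min}")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError(f"missing_max must lie in [0, 1], got {missing_max}")
    miss_frac = markers.missing_mask.mean(axis=0)
    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(markers.dosages, axis=0) / 2.0
    maf = np.fmin(pbar, 1.0 - pbar)
    keep = (miss_frac <= missing_max) & (maf >= maf_min) & ~np.isnan(maf)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("marker QC removed %d of %d markers", n_drop, markers.n_markers)
    if not keep.any():
        raise EmptyPanelError(
            "marker QC removed every marker (empty panel); relax maf_min or missing_max"
        )
    return MarkerMatrix(
        line_ids=markers.line_ids,
        marker_ids=markers.marker_ids[keep],
        dosages=markers.dosages[:, keep],
        imputed=markers.imputed,
    )


def impute_mean(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing dosages by each marker's mean non-missing dosage."""
    dos = markers.dosages.copy()
    miss = np.isnan(dos)
    if not miss.any():
        return MarkerMatrix(
            markers.line_ids, markers.marker_ids, dos, imputed=markers.imputed
        )
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = markers.marker_ids[all_missing]
        raise ValueError(f"markers with no observed genotypes: {list(bad)}")
    col_mean = np.nanmean(dos, axis=0)
    dos[miss] = np.broadcast_to(col_mean, dos.shape)[miss]
    return MarkerMatrix(markers.line_ids, markers.marker_ids, dos, imputed=True)


def vanraden_grm(markers: MarkerMatrix, ridge: float = GRM_RIDGE) -> GenomicRelMatrix:
    """VanRaden method-1 GRM: G = WW' / (2 sum_k p_k (1 - p_k)).

    W is the dosage matrix centered by twice the allele frequency p_k
    (column mean dosage / 2). Markers fixed for one allele have a zero
    centered column and zero p(1-p), so they drop out of both numerator
    and denominator. A small relative ridge keeps G positive
    semi-definite under finite precision.
    """
    dos = markers.dosages
    if np.isnan(dos).any():
        raise ValueError("GRM requires a complete panel; impute missing dosages first")
    p = dos.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError(
            "all markers are monomorphic: the VanRaden denominator 2*sum(p(1-p)) is zero"
        )
    W = dos - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    if ridge:
        G = G + ridge * float(np.mean(np.diag(G))) * np.eye(len(G))
    return GenomicRelMatrix(line_ids=markers.line_ids, values=G)


def env_relationship(env_labels, scale: float = 1.0) -> EnvRelMatrix:
    """Environmental relationship H = X_L X_L' / scale from the one-hot
    environment incidence X_L: entry (a, b) is 1/scale when observations
    a and b share an environment and 0 otherwise.

    Any positive ``scale`` is absorbed by the corresponding variance
    component during fitting, so predictions do not depend on it.
    """
    env_labels = np.asarray(list(env_labels), dtype=object)
    if env_labels.size == 0:
        raise ValueError("env_relationship needs at least one observation")
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    same = env_labels[:, None] == env_labels[None, :]
    values = same.astype(float) / scale
    return EnvRelMatrix(env_labels=env_labels, values=values, scale=scale)


def interaction_kernel(
    H: EnvRelMatrix, line_labels, G: GenomicRelMatrix
) -> np.ndarray:
    """Hadamard genotype-by-environment kernel H (.) Z_g G Z_g'.

    Entry (a, b) equals H_ab * G[line(a), line(b)]: genomic relatedness
    restricted to pairs of observations sharing an environment.
    """
    line_labels = list(line_labels)
    if len(line_labels) != H.n_obs:
        raise ValueError(
            f"{len(line_labels)} line labels for {H.n_obs} observations"
        )
    ix = G.index_of(line_labels)
    return H.values * G.values[np.ix_(ix, ix)]
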