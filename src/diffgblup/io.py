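"""Readers and writers for genotype/phenotype CSV, VCF, configs and reports.

Formats
-------
- genotype CSV: first column ``line``, remaining columns one marker
  each, entries 0/1/2 or empty for a missing call;
- phenotype CSV: long format with header ``line,env,trait,value``;
  the value field may be empty or "NA" for a missing record;
- VCF (optional, read-only via cyvcf2): biallelic SNPs converted to
  alt-allele dosage; multi-allelic records are skipped with a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .relmatrices import MarkerMatrix
from .tables import PHENO_COLUMNS, validate_phenotypes

logger = logging.getLogger(__name__)


def read_phenotypes(path, validate: bool = True) -> pd.DataFrame:
    """Load and validate a long-format phenotype CSV."""
    df = pd.read_csv(
        path,
        dtype={"line": str, "env": str, "trait": str},
        na_values=["NA", ""],
        keep_default_na=False,
    )
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype CSV lacks columns {missing}")
    bad = df[~df["value"].apply(lambda v: pd.isna(v) or _is_number(v))]
    if len(bad):
        first = bad.index[0] + 2  # header + 1-based
        raise ValueError(f"{path}: malformed value field at line {first}")
    df["value"] = pd.to_numeric(df["value"])
    if validate:
        validate_phenotypes(df, min_envs=1)
    return df


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos.to_csv(path, index=False, na_rep="NA")


def wide_to_long(wide: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Convert a lines x environments table to the long phenotype format."""
    long = wide.reset_index(names="line").melt(
        id_vars="line", var_name="env", value_name="value"
    )
    long["trait"] = trait
    return long[list(PHENO_COLUMNS)]


def read_genotypes(path, fmt: str = "csv") -> MarkerMatrix:
    """Read a marker panel from CSV or VCF."""
    if fmt == "csv":
        return _read_genotypes_csv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unsupported genotype format {fmt!r}")


def _read_genotypes_csv(path) -> MarkerMatrix:
    df = pd.read_csv(path, dtype={0: str}, na_values=["NA", ""], keep_default_na=False)
    if df.columns[0] != "line":
        raise ValueError(f"{path}: first genotype column must be 'line'")
    lines = df["line"].to_numpy(object)
    markers = df.columns[1:].to_numpy(object)
    dosages = df.iloc[:, 1:].apply(pd.to_numeric).to_numpy(dtype=float)
    ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"{path}: invalid dosage {dosages[i, j]!r} for line {lines[i]!r}, "
            f"marker {markers[j]!r} (expected 0/1/2 or empty)"
        )
    return MarkerMatrix(line_ids=lines, marker_ids=markers, dosages=dosages)


def _read_genotypes_vcf(path) -> MarkerMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        name = var.ID or f"{var.CHROM}:{var.POS}"
        marker_ids.append(name)
        columns.append(dosage)
    if n_skipped:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped)
    if not columns:
        raise ValueError(f"{path}: no biallelic SNP records found")
    return MarkerMatrix(
        line_ids=np.array(samples, dtype=object),
        marker_ids=np.array(marker_ids, dtype=object),
        dosages=np.column_stack(columns),
    )


def write_genotypes(markers: MarkerMatrix, path) -> None:
    df = pd.DataFrame(markers.dosages, columns=markers.marker_ids)
    df.insert(0, "line", markers.line_ids)

    def _fmt(v):
        if pd.isna(v):
            return ""
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    for col in markers.marker_ids:
        df[col] = df[col].map(_fmt)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-serializable)."""

    genotype_path: str = ""
    phenotype_path: str = ""
    output_dir: str = "results"
    traits: list = field(default_factory=list)  # empty -> all traits
    models: list = field(default_factory=lambda: ["M1_NO_GE", "M1_GE", "M2"])
    fitter: str = "reml"
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    maf_min: float = 0.05
    missing_max: float = 0.15
    nrmse_norm: str = "mean"
    trait_direction: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not cfg.models:
            raise ValueError("config must request at least one model")
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def write_metrics(report, out_dir) -> tuple[Path, Path]:
    """Serialize a MetricReport as tidy CSV plus a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "metrics.csv"
    report.per_env.to_csv(csv_path, index=False)
    summary = {
        "overall": report.overall().to_dict(orient="records"),
        "by_trait": report.by_trait().to_dict(orient="records"),
        "gains_vs_M2": report.gains("M2").to_dict(orient="records"),
    }
    json_path = out_dir / "metrics_summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return csv_path, json_path


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
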