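"""Shared fixtures: tiny marker panels and balanced phenotype tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from diffgblup import GenomicRelMatrix, MarkerMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_markers() -> MarkerMatrix:
    """3 lines x 3 markers, fully observed, mixed frequencies."""
    return MarkerMatrix(
        line_ids=np.array(["g1", "g2", "g3"], dtype=object),
        marker_ids=np.array(["m1", "m2", "m3"], dtype=object),
        dosages=np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0], [1.0, 1.0, 1.0]]),
    )


@pytest.fixture
def identity_grm() -> GenomicRelMatrix:
    """Unrelated-lines relationship matrix for three lines."""
    return GenomicRelMatrix(
        line_ids=np.array(["g1", "g2", "g3"], dtype=object),
        values=np.eye(3),
    )


def balanced_table(values_by_env: dict, lines=None, trait="yield") -> pd.DataFrame:
    """Build a balanced long-format table from env -> per-line values."""
    from diffgblup.tables import balanced_from_values

    return balanced_from_values(values_by_env, lines=lines, trait=trait)


@pytest.fixture
def toy_phenos() -> pd.DataFrame:
    """J=3 lines in I=3 environments with distinct values."""
    return balanced_table(
        {"E1": (1.0, 2.0, 3.0), "E2": (2.5, 1.5, 3.5), "E3": (0.5, 2.0, 1.0)}
    )
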