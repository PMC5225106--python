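import numpy as np
import pandas as pd
import pytest

from metabnet.io import NormalizedTable, PeakTable
from metabnet.simulate import (
    CorrelationBlock,
    CorrelationSpec,
    DesignSpec,
    EffectSpec,
    generate_peak_table,
    study_preset,
)


@pytest.fixture(scope="session")
def small_peak_table() -> PeakTable:
    """4 samples x 3 features plus ribitol, hand-set values."""
    intensities = pd.DataFrame(
        {
            "sucrose": [10.0, 20.0, 8.0, 16.0],
            "glucose": [4.0, 8.0, 3.0, 6.0],
            "proline": [1.0, 2.0, 1.5, 3.0],
            "ribitol": [2.0, 4.0, 1.0, 2.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    intensities.index.name = "sample_id"
    metadata = pd.DataFrame(
        {
            "genotype": ["WT", "WT", "adh1", "adh1"],
            "condition": ["CK", "S", "CK", "S"],
            "timepoint": ["t2h", "t2h", "t2h", "t2h"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return PeakTable(intensities=intensities, metadata=metadata)


@pytest.fixture(scope="session")
def study_table():
    """Seeded table from the study-like preset (72 samples, 263 features)."""
    design, effects, corr = study_preset()
    return generate_peak_table(design, effects, corr, seed=11)


@pytest.fixture(scope="session")
def flat_design() -> DesignSpec:
    """Single-cell design: one genotype/condition/timepoint."""
    return DesignSpec(
        genotypes=("G",), conditions=("C",), timepoints=("T",),
        replicates=12, n_features=26, n_annotated=0,
    )


def make_normalized(values: np.ndarray, metadata: pd.DataFrame | None = None,
                    feature_prefix: str = "f") -> NormalizedTable:
    """Wrap a raw samples x features array as a NormalizedTable."""
    n, p = values.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    frame = pd.DataFrame(values, index=idx,
                         columns=[f"{feature_prefix}{j}" for j in range(p)])
    if metadata is None:
        metadata = pd.DataFrame(
            {"genotype": "G", "condition": "C", "timepoint": "T",
             "replicate": range(1, n + 1)},
            index=idx,
        )
    return NormalizedTable(values=frame, metadata=metadata)
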