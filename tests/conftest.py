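import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from panelqc import ControlSpec, ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 probes x 2 samples with counts [[1,2],[3,4],[5,6]]."""
    return ExpressionMatrix(
        probe_ids=("P1", "P2", "P3"),
        sample_ids=("A", "B"),
        counts=np.array([[1, 2], [3, 4], [5, 6]]),
    )


@pytest.fixture
def panel_matrix() -> ExpressionMatrix:
    """18 probes (4 POS + 4 ANT + 10 genes) x 4 samples, deterministic counts."""
    rng = np.random.default_rng(11)
    probes = tuple(
        [f"POS{i}" for i in range(1, 5)]
        + [f"ANT{i}" for i in range(1, 5)]
        + [f"GENE{i}" for i in range(1, 11)]
    )
    counts = rng.integers(1, 1000, size=(18, 4))
    return ExpressionMatrix(probes, ("S1", "S2", "S3", "S4"), counts)


@pytest.fixture
def panel_controls(panel_matrix) -> ControlSpec:
    return ControlSpec(
        positive_ids=frozenset(p for p in panel_matrix.probe_ids if p.startswith("POS")),
        negative_ids=frozenset(p for p in panel_matrix.probe_ids if p.startswith("ANT")),
    )


def random_panel_matrix(rng: np.random.Generator, n_probes: int = 10, n_samples: int = 6):
    """Random small matrix with 2 positive and 2 negative control probes.

    Every sample is guaranteed a positive library size.
    """
    n_genes = n_probes - 4
    probes = tuple(
        ["POS1", "POS2", "ANT1", "ANT2"] + [f"GENE{i}" for i in range(1, n_genes + 1)]
    )
    counts = rng.integers(0, 60, size=(n_probes, n_samples))
    counts[4, :] += 1  # keep library sizes positive
    matrix = ExpressionMatrix(probes, tuple(f"S{j}" for j in range(n_samples)), counts)
    controls = ControlSpec(
        positive_ids=frozenset({"POS1", "POS2"}), negative_ids=frozenset({"ANT1", "ANT2"})
    )
    return matrix, controls
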