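import numpy as np
import pytest

from stagenet.core import ExpressionMatrix, GeneAnnotation, MIRankedEdgeList, StageLabels
from stagenet.simulate import make_study_config, generate_cohort


@pytest.fixture
def tiny_matrix():
    """2 genes x 2 samples with known values."""
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0]]), ["gA", "gB"], ["s1", "s2"]
    )


@pytest.fixture
def toy_annotation():
    return GeneAnnotation(
        {"g1": "chr1", "g2": "1", "g3": "2", "g4": "chr2", "g5": "X"}
    )


@pytest.fixture
def toy_labels():
    mapping = {}
    for ph in ("control", "tumor"):
        for j in range(3):
            mapping[f"{ph}_{j}"] = ph
    return StageLabels(mapping, control="control")


def ranked_edges(records):
    return MIRankedEdgeList.from_records(records)


@pytest.fixture(scope="session")
def demo_cohort():
    """One small planted cohort shared by read-only tests."""
    cfg = make_study_config(
        11, samples_per_phenotype=40, module_size=10, n_noise_genes=42,
        include_shared_modules=True,
    )
    matrix, annotation, labels, truth = generate_cohort(cfg)
    return cfg, matrix, annotation, labels, truth
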