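import numpy as np
import pytest

from pieglyph import (
    Embedding,
    ExpressionMatrix,
    FixtureSpec,
    GeneGroup,
    GeneListSpec,
    generate_fixture,
)

# the two tumor-class biomarker panels used throughout the docs/tests:
# 8 class-1 genes and 4 class-2 genes (12 total)
CLASS1_GENES = ("EIF1B", "FXR1", "ID2", "LMCD1", "LTA4H", "MTUS1", "ROBO1", "SATB1")
CLASS2_GENES = ("CDH1", "ECM1", "HTR2B", "RRAB31")


@pytest.fixture
def toy_matrix():
    """3 cells x 2 genes with values {{1,0},{2,2},{0,5}}."""
    return ExpressionMatrix(
        cell_ids=("c1", "c2", "c3"),
        gene_ids=("GA", "GB"),
        values=np.array([[1.0, 0.0], [2.0, 2.0], [0.0, 5.0]]),
    )


@pytest.fixture
def toy_embedding():
    return Embedding(
        cell_ids=("c1", "c2", "c3"),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]),
    )


@pytest.fixture
def toy_spec():
    return GeneListSpec(
        groups=(GeneGroup(name="g", genes=("GA", "GB"), color_rule="viridis"),)
    )


@pytest.fixture
def biomarker_spec():
    return GeneListSpec(
        groups=(
            GeneGroup(name="class1", genes=CLASS1_GENES, color_rule="winter"),
            GeneGroup(name="class2", genes=CLASS2_GENES, color_rule="autumn"),
        )
    )


@pytest.fixture(scope="session")
def fixture_dataset():
    """Default 3-cluster, 300-cell synthetic dataset (seed fixed)."""
    return generate_fixture(FixtureSpec(seed=42))


def write_gene_list(path, genes):
    path.write_text("\n".join(genes) + "\n", encoding="utf-8")
    return path
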