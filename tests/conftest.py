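import numpy as np
import pandas as pd
import pytest

from screpurpose.reference import DrugReference
from screpurpose.signatures import CellTable, ClusterSignature


@pytest.fixture
def toy_cells() -> CellTable:
    rows = []
    for i in range(75):
        rows.append((f"d{i}", "S1", "disease", "C1", "T cell"))
    for i in range(25):
        rows.append((f"e{i}", "S1", "disease", "C2", "B cell"))
    for i in range(40):
        rows.append((f"c{i}", "S1", "control", "C1", "T cell"))
    for i in range(10):
        rows.append((f"k{i}", "S1", "control", "C2", "B cell"))
    return CellTable(
        pd.DataFrame(rows, columns=["cell_id", "sample_id", "condition", "cluster_id", "cell_type"])
    )


@pytest.fixture
def toy_signature() -> ClusterSignature:
    table = pd.DataFrame(
        {
            "gene": ["G1", "G2", "G3", "G4", "G5"],
            "logFC": [2.0, -1.0, 1.0, 0.5, -2.5],
            "p": [0.001, 0.01, 0.08, 0.3, 0.002],
            "adj_p": [0.01, 0.04, 0.2, 0.5, 0.01],
        }
    )
    return ClusterSignature("C1", 75, table)


def random_reference(
    rng: np.random.Generator,
    n_genes: int = 20,
    n_drugs: int = 4,
    instances_per_drug: int = 2,
    tissues: tuple[str, ...] = ("breast", "lung"),
) -> DrugReference:
    genes = [f"G{i + 1}" for i in range(n_genes)]
    cols, meta = [], []
    for d in range(n_drugs):
        for j in range(instances_per_drug):
            cols.append(rng.permutation(n_genes) + 1)
            meta.append(
                (f"D{d + 1}_i{j + 1}", f"D{d + 1}", f"CL{j + 1}",
                 tissues[(d + j) % len(tissues)])
            )
    meta = pd.DataFrame(meta, columns=["instance_id", "drug", "cell_line", "tissue"])
    return DrugReference(genes, np.column_stack(cols), meta)


@pytest.fixture
def small_reference() -> DrugReference:
    return random_reference(np.random.default_rng(42))
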