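import numpy as np
import pandas as pd
import pytest

from priorselect.datatypes import DrugAnnotation, GeneSetCollection, OmicsDataset
from priorselect.synthetic import SyntheticConfig, generate


def tiny_config(**overrides) -> SyntheticConfig:
    """A small but structurally complete generator config for fast tests."""
    base = dict(
        n_cell_lines=60,
        n_genes=200,
        n_mutation_genes=30,
        n_cnv_segments=12,
        n_pathways=6,
        pathway_size_range=(5, 15),
        n_signatures=5,
        signature_size_range=(4, 8),
        n_tissues=4,
        n_drugs=8,
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate(tiny_config())


@pytest.fixture
def toy_dataset():
    """Hand-built 6-line dataset: 4 genes, 2 mutation genes, 2 segments, 2 tissues."""
    lines = [f"L{i}" for i in range(6)]
    rng = np.random.default_rng(42)
    expression = pd.DataFrame(
        rng.normal(7, 1, size=(6, 4)), index=lines, columns=["BRAF", "KRAS", "TP53", "EGFR"]
    )
    mutation = pd.DataFrame(
        [[1, 0], [0, 0], [1, 1], [0, 0], [0, 1], [1, 0]],
        index=lines, columns=["BRAF", "TP53"],
    )
    cnv = pd.DataFrame(
        [[0, 1], [1, 0], [0, 0], [1, 1], [0, 0], [0, 1]],
        index=lines, columns=["SEG1", "SEG2"],
    )
    segment_genes = {"SEG1": frozenset({"BRAF", "KRAS", "TP53"}), "SEG2": frozenset({"EGFR"})}
    tissue = pd.Series(["lung", "lung", "skin", "skin", "lung", "skin"], index=lines)
    return OmicsDataset(
        expression=expression, mutation=mutation, cnv=cnv,
        segment_genes=segment_genes, tissue=tissue,
    )


@pytest.fixture
def braf_drug():
    return DrugAnnotation(drug_id="DRUG1", targets=frozenset({"BRAF"}), target_pathway="MAPK")


@pytest.fixture
def toy_pathways():
    return GeneSetCollection(
        sets={"P1": ["BRAF", "KRAS"], "P2": ["TP53"], "P3": ["EGFR", "KRAS"]},
        kind="pathway",
    )
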