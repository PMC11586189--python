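import numpy as np
import pandas as pd
import pytest

from hydrodeg import AbundanceTable, parse_lineage


@pytest.fixture
def counts_table() -> AbundanceTable:
    """Small mixed-lineage counts table used across community tests."""
    data = pd.DataFrame(
        {
            "asv1": [10.0, 5.0],
            "asv2": [0.0, 15.0],
            "asv3": [30.0, 20.0],
            "asv4": [4.0, 1.0],
            "asv5": [6.0, 9.0],
        },
        index=["s1", "s2"],
    )
    lineages = {
        "asv1": parse_lineage("Bacteria;Pseudomonadota;Alphaproteobacteria;"
                              "Sphingomonadales;Sphingomonadaceae;Sphingomonas"),
        "asv2": parse_lineage("Bacteria;Pseudomonadota;Alphaproteobacteria;"
                              "Sphingomonadales;Sphingomonadaceae;Sphingomonas"),
        "asv3": parse_lineage("Bacteria;Bacillota;Bacilli;Bacillales;Bacillaceae"),
        "asv4": parse_lineage("Eukarya;Streptophyta"),
        "asv5": parse_lineage("Bacteria;Cyanobacteria;Cyanobacteriia;"
                              "Chloroplast"),
    }
    return AbundanceTable(data=data, mode="counts", lineage_of=lineages,
                          sample_meta={"s1": {"season": "spring"},
                                       "s2": {"season": "autumn"}})


def random_counts_table(rng: np.random.Generator, n_samples=4, n_taxa=8):
    """Counts table with random lineages, some unclassified below family."""
    data = pd.DataFrame(
        rng.integers(0, 50, size=(n_samples, n_taxa)).astype(float) + 1.0,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    lineages = {}
    for j in range(n_taxa):
        fam = f"Fam{j % 3}"
        genus = f";Genus{j % 5}" if rng.random() < 0.7 else ""
        lineages[f"t{j}"] = parse_lineage(
            f"Bacteria;Phy{j % 2};Cls{j % 2};Ord{j % 3};{fam}{genus}"
        )
    return AbundanceTable(data=data, mode="counts", lineage_of=lineages)
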