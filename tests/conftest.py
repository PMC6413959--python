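"""Shared fixtures: tiny pedigrees, maps and genotype sets built in memory."""

import numpy as np
import pandas as pd
import pytest

from pedsel import GeneticMap, GenotypeMatrix, pedigree_from_text
from pedsel.synthetic import SyntheticConfig, make_founders, make_map, make_pedigree

TRIO_TEXT = "entry\tparent1\tparent2\nP1\t\t\nP2\t\t\nC\tP1\tP2\n"


@pytest.fixture
def trio():
    """Two founders and one cross."""
    return pedigree_from_text(TRIO_TEXT)


@pytest.fixture
def sib_pedigree():
    """Two founders with two sibling progeny of the same cross."""
    return pedigree_from_text(
        "entry\tparent1\tparent2\nP1\t\t\nP2\t\t\nA\tP1\tP2\nB\tP1\tP2\n"
    )


def unlinked_map(n_markers: int) -> GeneticMap:
    """One marker per chromosome: all loci segregate independently."""
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(n_markers)],
                "chrom": [f"c{i}" for i in range(n_markers)],
                "pos": np.zeros(n_markers),
            }
        )
    )


def two_marker_map(d_cm: float) -> GeneticMap:
    """Two markers ``d_cm`` apart on one chromosome."""
    return GeneticMap(
        pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "1"], "pos": [0.0, d_cm]})
    )


@pytest.fixture
def small_synthetic():
    """A compact neutral breeding scenario shared across modules."""
    cfg = SyntheticConfig(
        n_chromosomes=5,
        markers_per_chromosome=8,
        n_founders=10,
        generations=3,
        crosses_per_generation=8,
        selfing_generations=4,
        seed=11,
    )
    gmap = make_map(cfg)
    founders, freqs = make_founders(cfg.n_founders, gmap, seed=cfg.seed)
    ped = make_pedigree(cfg)
    return cfg, gmap, founders, ped


def geno(rows: dict[str, list[float]], markers=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {line: dosages}."""
    lines = list(rows)
    arr = np.array([rows[l] for l in lines], dtype=float)
    if markers is None:
        markers = [f"m{i}" for i in range(arr.shape[1])]
    return GenotypeMatrix(arr, lines, markers)
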