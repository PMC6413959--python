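"""Gene dropping: forward simulation of multilocus genotypes through a pedigree.

Founder alleles descend through the pedigree under Mendelian 50:50
transmission.  Gametes are formed chromosome by chromosome with map-based
recombination under Haldane's mapping function (no crossover interference):
between adjacent markers d cM apart the parental strand switches with
probability r = (1 - exp(-2 d / 100)) / 2, the starting strand is uniform,
and chromosomes assort independently.  Each non-founder receives one gamete
from each parent and is then taken through a single-seed-descent selfing
chain (default 7 generations) to mimic inbred variety development.

Diploid genotypes are (2, L) arrays of allele codes {0, 1}; -1 marks a
missing allele (missing founder calls propagate as missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, GeneticMap
from .errors import ConfigurationError
from .pedigree import Pedigree

__all__ = [
    "simulate_meiosis",
    "self_line",
    "gene_drop",
    "ensemble",
    "SimulationEnsemble",
    "diploid_from_dosage",
    "dosage_from_diploid",
]

MISSING = -1


def simulate_meiosis(
    parent: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw one gamete (length-L allele vector) from a (2, L) diploid parent.

    The strand indicator is the running parity of per-marker switch events:
    probability 0.5 at the first marker of every chromosome (uniform start,
    independent chromosomes) and the Haldane recombination fraction of the
    inter-marker distance elsewhere.  Markers at identical positions never
    recombine.
    """
    parent = np.asarray(parent)
    if parent.shape != (2, gmap.n_markers):
        raise ConfigurationError(
            f"parent genotype shape {parent.shape} does not match map "
            f"({gmap.n_markers} markers)"
        )
    switches = rng.random(gmap.n_markers) < gmap.switch_probs()
    strand = np.cumsum(switches) % 2
    return parent[strand, np.arange(gmap.n_markers)]


def self_line(
    genotype: np.ndarray, generations: int, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Single-seed descent: each generation draws two independent gametes."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    g = np.asarray(genotype)
    for _ in range(generations):
        g = np.stack([simulate_meiosis(g, gmap, rng), simulate_meiosis(g, gmap, rng)])
    return g


def diploid_from_dosage(
    dosage: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Expand a dosage vector to a (2, L) diploid.

    Dosage 0 -> (0,0), 2 -> (1,1), NaN -> missing.  A heterozygous call (1)
    is resolved to a random homozygote, reflecting that pedigree founders are
    near-inbred and a residual het call is ambiguous about which allele the
    seed stock actually fixed; resolution is re-drawn per call of this
    function (i.e. per replicate).
    """
    dosage = np.asarray(dosage, dtype=float)
    out = np.full((2, dosage.size), MISSING, dtype=np.int8)
    out[:, dosage == 0] = 0
    out[:, dosage == 2] = 1
    het = np.flatnonzero(dosage == 1)
    if het.size:
        if rng is None:
            rng = np.random.default_rng()
        out[:, het] = rng.integers(0, 2, size=het.size).astype(np.int8)
    return out


def dosage_from_diploid(genotype: np.ndarray) -> np.ndarray:
    """Collapse a (2, L) diploid to dosages; any missing allele -> NaN."""
    g = np.asarray(genotype)
    d = g.sum(axis=0).astype(float)
    d[(g == MISSING).any(axis=0)] = np.nan
    return d


def gene_drop(
    ped: Pedigree,
    founder_genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    selfing_generations: int = 7,
    seed: int | None = None,
    targets=None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Simulate one realisation of descent through the whole pedigree.

    Every pedigree founder must be genotyped (its dosages are looked up in
    ``founder_genotypes`` on the map's marker set); an unknown parent slot
    transmits a fully missing gamete.  Each non-founder is built as the F1 of
    its parents' realised genotypes followed by ``selfing_generations`` of
    single-seed descent.  Pass ``selfing_generations=0`` when the pedigree is
    already augmented with explicit selfing entries.

    Deterministic given ``seed``.  Returns dosages for ``targets`` (default:
    all entries) on the map's marker order.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    markers = gmap.markers
    founder_view = founder_genotypes.subset_markers(
        [m for m in markers if m in founder_genotypes._marker_idx]
    )
    if founder_view.n_markers != len(markers):
        missing = set(markers) - set(founder_genotypes.markers)
        raise ConfigurationError(
            f"founder genotypes lack {len(missing)} map markers, e.g. "
            f"{sorted(missing)[:3]}"
        )
    if targets is None:
        targets = ped.ids
    else:
        targets = list(targets)
        for t in targets:
            ped.entry(t)

    realised: dict[str, np.ndarray] = {}
    for eid in ped.topological_order():
        p1, p2 = ped.parents(eid)
        if p1 is None and p2 is None:
            try:
                dos = founder_view.row(eid)
            except KeyError:
                raise ConfigurationError(
                    f"founder {eid!r} has no genotypes"
                ) from None
            realised[eid] = diploid_from_dosage(dos, rng)
            continue
        gametes = []
        for pid in (p1, p2):
            if pid is None:
                gametes.append(np.full(len(markers), MISSING, dtype=np.int8))
            else:
                gametes.append(simulate_meiosis(realised[pid], gmap, rng))
        geno = np.stack(gametes)
        realised[eid] = self_line(geno, selfing_generations, gmap, rng)

    dosage = np.stack([dosage_from_diploid(realised[t]) for t in targets])
    return GenotypeMatrix(dosage, targets, markers)


@dataclass
class SimulationEnsemble:
    """A collection of independent gene-drop replicates with seed provenance."""

    replicates: list[GenotypeMatrix]
    seeds: list[int]
    config: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.replicates)

    def dosage_stack(self) -> np.ndarray:
        """(n_replicates, n_lines, n_markers) dosage array."""
        return np.stack([r.dosage for r in self.replicates])


def ensemble(
    n_sims: int,
    ped: Pedigree,
    founder_genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    selfing_generations: int = 7,
    base_seed: int = 0,
    targets=None,
) -> SimulationEnsemble:
    """Run ``n_sims`` independent gene drops; replicate i uses seed
    ``base_seed + i`` and is reproducible in isolation."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    seeds = [int(base_seed) + i for i in range(n_sims)]
    reps = [
        gene_drop(ped, founder_genotypes, gmap, selfing_generations, seed=s,
                  targets=targets)
        for s in seeds
    ]
    return SimulationEnsemble(
        replicates=reps,
        seeds=seeds,
        config={
            "selfing_generations": selfing_generations,
            "n_markers": gmap.n_markers,
            "base_seed": int(base_seed),
        },
    )
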