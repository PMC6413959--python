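"""Synthetic breeding data with known ground truth.

Generates the three inputs every pipeline stage needs — a multi-generation
crossing pedigree of inbred lines, fully homozygous founder genotypes at
biallelic loci, and a 21-chromosome centimorgan map — plus genotypes bred
under an explicit, tunable selection regime.  Selection is modelled as
best-of-k truncation on an additive QTL score within each cross: each cross
produces ``k_selection`` independent selfed progeny and only the
highest-scoring one enters the pedigree, the simplest mechanism that
produces distorted parental contributions, local diversity loss and
conserved linkage blocks.  ``k_selection = 1`` is exactly neutral gene
dropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .containers import GenotypeMatrix, GeneticMap
from .errors import ConfigurationError
from .genedrop import (
    MISSING,
    diploid_from_dosage,
    dosage_from_diploid,
    gene_drop,
    self_line,
    simulate_meiosis,
)
from .pedigree import Pedigree, PedigreeEntry

__all__ = [
    "SyntheticConfig",
    "make_map",
    "make_founders",
    "make_pedigree",
    "breed_with_selection",
    "write_synthetic_dataset",
    "TruthRecord",
]

_WHEAT_CHROMS = [f"{n}{s}" for n in range(1, 8) for s in "ABD"]


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic breeding scenario.

    QTLs are given as (chromosome label, cM position, additive effect);
    each is attached to the nearest mapped marker.  ``k_selection`` is the
    number of progeny screened per cross, of which the top scorer is kept
    (1 = no selection).
    """

    n_chromosomes: int = 21
    chromosome_lengths: tuple[float, ...] | None = None  # default: 150-330 cM spread
    markers_per_chromosome: int = 10
    n_founders: int = 20
    generations: int = 3            # pedigree depth including the founder generation
    crosses_per_generation: int = 10
    selfing_generations: int = 7
    founder_freq: tuple[float, float] | float = (0.1, 0.9)
    qtl: tuple[tuple[str, float, float], ...] = ()
    k_selection: int = 1
    base_year: int = 1990
    years_per_generation: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chromosomes", "markers_per_chromosome", "n_founders",
                     "generations", "crosses_per_generation", "k_selection"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.selfing_generations < 0:
            raise ConfigurationError("selfing_generations must be >= 0")
        if self.chromosome_lengths is not None:
            self.chromosome_lengths = tuple(float(x) for x in self.chromosome_lengths)
            if len(self.chromosome_lengths) != self.n_chromosomes:
                raise ConfigurationError("one length per chromosome required")

    @property
    def chrom_labels(self) -> list[str]:
        if self.n_chromosomes == 21:
            return list(_WHEAT_CHROMS)
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def lengths(self) -> np.ndarray:
        if self.chromosome_lengths is not None:
            return np.asarray(self.chromosome_lengths)
        if self.n_chromosomes == 1:
            return np.array([240.0])
        return np.linspace(150.0, 330.0, self.n_chromosomes)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "qtl" in data:
            data["qtl"] = tuple(tuple(q) for q in data["qtl"])
        return cls(**data)


def make_map(cfg: SyntheticConfig) -> GeneticMap:
    """Random marker placement: uniform positions per chromosome, sorted.

    Deterministic given ``cfg.seed``.  A zero-length chromosome puts all its
    markers at 0 cM (complete linkage).
    """
    rng = np.random.default_rng(cfg.seed)
    import pandas as pd

    rows = []
    for label, length in zip(cfg.chrom_labels, cfg.lengths()):
        pos = np.sort(rng.uniform(0.0, length, size=cfg.markers_per_chromosome))
        for k, p in enumerate(pos):
            rows.append({"marker": f"{label}_m{k + 1}", "chrom": label, "pos": p})
    return GeneticMap(pd.DataFrame(rows))


def make_founders(
    n: int,
    gmap: GeneticMap,
    freq_spec=None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Fully homozygous founder lines with per-marker reference frequencies.

    ``freq_spec`` may be a scalar, a per-marker array, or None for the
    default Uniform(0.1, 0.9) draw per marker.  Returns the genotypes and
    the realised reference-allele frequencies (ground truth).
    """
    rng = np.random.default_rng(seed)
    L = gmap.n_markers
    if freq_spec is None:
        freqs = rng.uniform(0.1, 0.9, size=L)
    else:
        freqs = np.broadcast_to(np.asarray(freq_spec, dtype=float), (L,)).copy()
    dosage = 2.0 * (rng.random((n, L)) < freqs)
    lines = [f"F{i + 1:03d}" for i in range(n)]
    g = GenotypeMatrix(dosage, lines, gmap.markers)
    return g, g.allele_freq()


def make_pedigree(cfg: SyntheticConfig) -> Pedigree:
    """Multi-generation crossing pedigree with year/country attributes.

    Generation 0 holds ``n_founders`` founders; each later generation adds
    ``crosses_per_generation`` entries whose two distinct parents are drawn
    at random from the previous generation.  Years increase per generation
    (so cutoff-year subsetting is exercised); countries cycle over a small
    set.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    countries = ["UK", "FR", "DE", "US"]
    ped = Pedigree()
    prev = []
    for i in range(cfg.n_founders):
        eid = f"F{i + 1:03d}"
        ped.add_entry(
            PedigreeEntry(
                eid,
                year=cfg.base_year,
                country=countries[i % len(countries)],
                is_landrace=(i % 5 == 0),
            )
        )
        prev.append(eid)
    for gen in range(1, cfg.generations):
        current = []
        year = cfg.base_year + gen * cfg.years_per_generation
        for j in range(cfg.crosses_per_generation):
            eid = f"G{gen}_{j + 1:03d}"
            p1, p2 = rng.choice(prev, size=2, replace=False)
            ped.add_entry(
                PedigreeEntry(
                    eid, parent1=str(p1), parent2=str(p2), year=year,
                    country=countries[int(rng.integers(len(countries)))],
                )
            )
            current.append(eid)
        prev = current
    return ped


@dataclass
class TruthRecord:
    """Ground truth of a selection-bred dataset."""

    qtl_markers: list[str]
    qtl_chrom: list[str]
    qtl_pos: list[float]
    effects: list[float]
    k_selection: int
    favoured_allele: int = 1  # positive effect favours the reference allele


def _resolve_qtl(cfg: SyntheticConfig, gmap: GeneticMap) -> TruthRecord:
    markers, chroms, poss, effects = [], [], [], []
    for chrom, pos, effect in cfg.qtl:
        chrom = str(chrom)
        on_chrom = np.flatnonzero(gmap.chrom == chrom)
        if on_chrom.size == 0:
            raise ConfigurationError(f"QTL chromosome {chrom!r} not on map")
        cpos = gmap.pos[on_chrom]
        if pos < 0 or pos > cpos.max():
            raise ConfigurationError(
                f"QTL position {pos} cM outside chromosome {chrom} "
                f"(0..{cpos.max():.1f} cM)"
            )
        nearest = on_chrom[np.argmin(np.abs(cpos - pos))]
        markers.append(gmap.markers[nearest])
        chroms.append(chrom)
        poss.append(float(gmap.pos[nearest]))
        effects.append(float(effect))
    return TruthRecord(markers, chroms, poss, effects, cfg.k_selection)


def breed_with_selection(
    cfg: SyntheticConfig,
    ped: Pedigree,
    founders: GenotypeMatrix,
    gmap: GeneticMap,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Drop genotypes through the pedigree with best-of-k within-cross selection.

    For each non-founder cross, ``cfg.k_selection`` independent selfed
    progeny are simulated and the one with the highest additive QTL score
    (sum of effect x dosage at the QTL markers; ties keep the first) becomes
    the entry's genotype and the parent of downstream crosses.  With
    ``k_selection = 1`` this is byte-identical to
    :func:`pedsel.genedrop.gene_drop` run with ``seed = cfg.seed``.
    """
    truth = _resolve_qtl(cfg, gmap)
    if cfg.k_selection == 1:
        g = gene_drop(ped, founders, gmap, cfg.selfing_generations, seed=cfg.seed)
        return g, truth
    rng = np.random.default_rng(cfg.seed)
    qtl_idx = np.array([gmap.marker_index(m) for m in truth.qtl_markers], dtype=int)
    eff = np.array(truth.effects)

    def score(geno: np.ndarray) -> float:
        d = dosage_from_diploid(geno[:, qtl_idx]) if qtl_idx.size else np.array([])
        return float(np.nansum(eff * d)) if d.size else 0.0

    realised: dict[str, np.ndarray] = {}
    for eid in ped.topological_order():
        p1, p2 = ped.parents(eid)
        if p1 is None and p2 is None:
            realised[eid] = diploid_from_dosage(founders.row(eid), rng)
            continue
        best = None
        best_score = -np.inf
        for _ in range(cfg.k_selection):
            gametes = []
            for pid in (p1, p2):
                if pid is None:
                    gametes.append(np.full(gmap.n_markers, MISSING, dtype=np.int8))
                else:
                    gametes.append(simulate_meiosis(realised[pid], gmap, rng))
            cand = self_line(np.stack(gametes), cfg.selfing_generations, gmap, rng)
            s = score(cand)
            if s > best_score:
                best, best_score = cand, s
        realised[eid] = best
    dosage = np.stack([dosage_from_diploid(realised[i]) for i in ped.ids])
    return GenotypeMatrix(dosage, ped.ids, gmap.markers), truth


def write_synthetic_dataset(cfg: SyntheticConfig, outdir) -> dict:
    """Generate and write a complete dataset: pedigree, map, genotypes, truth.

    Writes ``pedigree.tsv``, ``map.tsv``, ``genotypes.tsv`` and
    ``truth.json`` under ``outdir`` and returns the paths.
    """
    import dataclasses
    import json
    from pathlib import Path

    from .pedigree import write_pedigree

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmap = make_map(cfg)
    founders, _ = make_founders(cfg.n_founders, gmap, freq_spec=cfg.founder_freq
                                if np.isscalar(cfg.founder_freq) else None,
                                seed=cfg.seed)
    ped = make_pedigree(cfg)
    genotypes, truth = breed_with_selection(cfg, ped, founders, gmap)
    paths = {
        "pedigree": outdir / "pedigree.tsv",
        "map": outdir / "map.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_pedigree(ped, paths["pedigree"])
    gmap.write_tsv(paths["map"])
    genotypes.write_tsv(paths["genotypes"])
    paths["truth"].write_text(
        json.dumps(dataclasses.asdict(truth), indent=2) + "\n"
    )
    return paths
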