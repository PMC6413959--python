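"""Cross-pedigree selection scan via allelic-diversity deviations.

Genotyped varieties released before a cutoff year act as simulation
founders; descendants whose complete ancestry lies inside that founder pool
and that were released after the cutoff are the scan targets.  Gene-dropping
the founder genotypes through the connecting pedigree yields, per marker, a
null distribution of allelic diversity D = 1 - sum(p_i^2) among the targets;
markers whose observed diversity deviates by more than a set number of
simulated standard deviations (default 5, roughly a Bonferroni p = 0.001
for ~2,000 markers) are flagged as candidate selection signals — diversity
loss under directional selection, gain under balancing-style selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GeneticMap
from .errors import ConfigurationError
from .genedrop import SimulationEnsemble
from .pedigree import Pedigree

__all__ = [
    "FounderSubset",
    "DiversityScan",
    "build_founder_subset",
    "allelic_diversity",
    "diversity_scan",
]


@dataclass
class FounderSubset:
    """Founder pool, eligible descendants and scan targets."""

    founders: list[str]
    eligible_descendants: list[str]
    targets: list[str]
    cutoff_year: int


def build_founder_subset(
    ped: Pedigree, genotyped_ids, cutoff_year: int = 2000
) -> FounderSubset:
    """Partition the pedigree around a release-year cutoff.

    Founders: genotyped entries released before ``cutoff_year``.  Eligible
    descendants: entries all of whose ancestor paths terminate inside the
    founder set (both parents known, each a founder or itself eligible) —
    no ancestry outside the founder gene pool.  Targets: eligible
    descendants that are genotyped and released in or after the cutoff year.
    """
    genotyped = set(genotyped_ids)
    founders = [
        e.id
        for e in ped.entries.values()
        if e.id in genotyped and e.year is not None and e.year < cutoff_year
    ]
    if not founders:
        raise ConfigurationError(
            f"no genotyped entries released before {cutoff_year}"
        )
    founder_set = set(founders)
    eligible: list[str] = []
    eligible_set: set[str] = set()
    for eid in ped.topological_order():
        if eid in founder_set:
            continue
        e = ped.entry(eid)
        if e.parent1 is None or e.parent2 is None:
            continue
        if all(p in founder_set or p in eligible_set for p in (e.parent1, e.parent2)):
            eligible.append(eid)
            eligible_set.add(eid)
    targets = [
        i
        for i in eligible
        if i in genotyped
        and ped.entry(i).year is not None
        and ped.entry(i).year >= cutoff_year
    ]
    return FounderSubset(founders, eligible, targets, cutoff_year)


def allelic_diversity(freqs) -> float:
    """Allelic diversity D = 1 - sum(p_i^2) of an allele-frequency vector.

    The probability that two randomly drawn alleles differ; at most 0.5 for
    a biallelic locus.  Frequencies must be non-negative and sum to 1
    (tolerance 1e-8).
    """
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("allele frequencies must be >= 0")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))


def _diversity_per_marker(g: GenotypeMatrix) -> np.ndarray:
    """Biallelic D per marker from target allele frequencies.

    Frequencies come from dosages over non-missing calls (heterozygotes
    contribute one count to each allele): D = 2 p (1 - p).
    """
    p = g.allele_freq()
    return 2.0 * p * (1.0 - p)


@dataclass
class DiversityScan:
    """Per-marker observed vs simulated allelic diversity."""

    table: pd.DataFrame            # marker, [chrom, pos], d_obs, sim_mean, sim_sd, z, flag
    sd_threshold: float
    mean_d_obs: float
    mean_d_sim: float
    zero_sd_markers: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flag"] != ""]

    def report_table(self) -> pd.DataFrame:
        """Flagged markers as chromosome / position / marker / signed SD deviation."""
        cols = [c for c in ("chrom", "pos", "marker", "z") if c in self.table.columns]
        out = self.flagged.loc[:, cols].rename(columns={"z": "sd_deviation"})
        return out.reset_index(drop=True)


def diversity_scan(
    observed: GenotypeMatrix,
    ens: SimulationEnsemble,
    sd_threshold: float = 5.0,
    gmap: GeneticMap | None = None,
) -> DiversityScan:
    """Compare observed target diversity to the gene-dropped null per marker.

    z = (D_obs - mean_sim) / sd_sim; markers with z <= -threshold are
    flagged ``"loss"`` and z >= +threshold ``"gain"``.  Markers whose
    simulated SD is zero get no z and are listed on ``zero_sd_markers``.
    Note the SD comes from the ensemble (often only ~100 replicates), so the
    +-5 SD rule is an approximation to Bonferroni p = 0.001, not an exact
    test.
    """
    if not ens.replicates:
        raise ConfigurationError("empty simulation ensemble")
    rep0 = ens.replicates[0]
    if rep0.markers != observed.markers:
        raise ConfigurationError("ensemble and observed marker sets differ")
    sim_targets = [i for i in rep0.lines if i in set(observed.lines)]
    if len(sim_targets) != len(observed.lines):
        raise ConfigurationError("ensemble lines do not cover observed targets")

    d_obs = _diversity_per_marker(observed)
    d_sim = np.stack(
        [_diversity_per_marker(r.subset_lines(sim_targets)) for r in ens.replicates]
    )
    sim_mean = d_sim.mean(axis=0)
    sim_sd = d_sim.std(axis=0, ddof=1) if ens.n > 1 else np.zeros_like(sim_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d_obs - sim_mean) / sim_sd
    zero_sd = sim_sd == 0
    z[zero_sd] = np.nan
    flag = np.where(z <= -sd_threshold, "loss", np.where(z >= sd_threshold, "gain", ""))
    flag[zero_sd] = ""
    data = {"marker": observed.markers}
    if gmap is not None:
        idx = [gmap.marker_index(m) for m in observed.markers]
        data["chrom"] = gmap.chrom[idx]
        data["pos"] = gmap.pos[idx]
    data.update(d_obs=d_obs, sim_mean=sim_mean, sim_sd=sim_sd, z=z, flag=flag)
    table = pd.DataFrame(data)
    return DiversityScan(
        table=table,
        sd_threshold=sd_threshold,
        mean_d_obs=float(np.nanmean(d_obs)),
        mean_d_sim=float(np.nanmean(sim_mean)),
        zero_sd_markers=[m for m, s in zip(observed.markers, zero_sd) if s],
    )
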