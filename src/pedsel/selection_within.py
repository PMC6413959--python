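"""Within-cross selection test on simplex families.

A simplex family is a genotyped trio: two parents and one derived progeny
line.  Under drift alone the progeny shares on average half its genome with
each parent; breeder selection during the inbreeding generations pulls the
progeny toward the superior parent.  The test compares the observed
proportion of alleles shared with the maximally related parent against an
empirical null built by gene-dropping an F1 of two fully polymorphic inbred
parents through the selfing chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GeneticMap
from .errors import InsufficientDataError
from .genedrop import self_line

__all__ = [
    "SimplexFamily",
    "SharingResult",
    "SharingNull",
    "FamilyTestReport",
    "parental_sharing",
    "null_sharing_distribution",
    "test_simplex_families",
]


@dataclass(frozen=True)
class SimplexFamily:
    """Two genotyped parents and their one genotyped progeny line."""

    progeny: str
    parent1: str
    parent2: str

    def __post_init__(self):
        if self.parent1 == self.parent2:
            raise ValueError(f"parents of {self.progeny!r} must be distinct")


@dataclass
class SharingResult:
    prop_parent1: float
    prop_parent2: float
    max_prop: float
    n_markers: int


def parental_sharing(
    family: SimplexFamily, g: GenotypeMatrix, polymorphic_only: bool = False
) -> SharingResult:
    """Proportion of the progeny genome shared with each parent.

    Per marker the sharing with a parent is (shared allele count)/2, i.e.
    1 - |dosage difference|/2; the proportion is the mean over markers
    jointly non-missing in all three lines.  By default markers where the
    two parents carry the same allele are included (genome-proportion
    reading); ``polymorphic_only`` restricts to markers polymorphic between
    the parents, where sharing with one parent is sharing against the other.
    """
    try:
        prog = g.row(family.progeny)
        par1 = g.row(family.parent1)
        par2 = g.row(family.parent2)
    except KeyError as exc:
        raise InsufficientDataError(str(exc)) from None
    keep = np.isfinite(prog) & np.isfinite(par1) & np.isfinite(par2)
    if polymorphic_only:
        keep &= par1 != par2
    if not keep.any():
        raise InsufficientDataError(
            f"family {family.progeny!r}: no usable markers"
        )
    s1 = float(np.mean(1.0 - np.abs(prog[keep] - par1[keep]) / 2.0))
    s2 = float(np.mean(1.0 - np.abs(prog[keep] - par2[keep]) / 2.0))
    return SharingResult(s1, s2, max(s1, s2), int(keep.sum()))


@dataclass
class SharingNull:
    """Empirical null of the max-parent sharing proportion.

    ``samples`` holds one max-parent proportion per gene-drop simulation;
    ``thresholds`` maps each p-level to the empirical (1 - p) quantile.
    """

    samples: np.ndarray
    thresholds: dict[float, float]
    n_markers: int
    selfing: int

    def threshold(self, p: float) -> float:
        return self.thresholds[p]


def null_sharing_distribution(
    gmap: GeneticMap,
    n_markers: int | None = None,
    selfing: int = 7,
    n_sims: int = 1000,
    seed: int = 0,
    p_levels=(0.01, 0.001),
) -> SharingNull:
    """Simulate the no-selection null of max-parent allele sharing.

    The two simulated parents are fully inbred and opposite homozygotes at
    every locus, so the F1 is completely heterozygous; each replicate takes
    the F1 through ``selfing`` generations of single-seed descent with
    map-based recombination and records the proportion of alleles shared
    with the better-shared parent.  Thresholds are empirical (1 - p)
    quantiles of that distribution.
    """
    if n_markers is not None:
        if n_markers > gmap.n_markers:
            raise ValueError("n_markers exceeds map size")
        gmap = gmap.subset(gmap.markers[:n_markers])
    for p in p_levels:
        if n_sims < 1.0 / p:
            warnings.warn(
                f"n_sims={n_sims} < 1/p for p={p}; quantile estimate unstable",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    L = gmap.n_markers
    f1 = np.stack([np.ones(L, dtype=np.int8), np.zeros(L, dtype=np.int8)])
    samples = np.empty(n_sims)
    for i in range(n_sims):
        geno = self_line(f1, selfing, gmap, rng)
        d = geno.sum(axis=0)  # dosage of parent-1 allele
        s1 = np.mean(1.0 - np.abs(d - 2) / 2.0)
        s2 = np.mean(1.0 - d / 2.0)
        samples[i] = max(s1, s2)
    thresholds = {p: float(np.quantile(samples, 1.0 - p)) for p in p_levels}
    return SharingNull(samples=samples, thresholds=thresholds,
                       n_markers=L, selfing=selfing)


@dataclass
class FamilyTestReport:
    """Per-family sharing results with null exceedance flags and a summary."""

    table: pd.DataFrame
    excluded: list[tuple[SimplexFamily, str]]
    n_families: int
    exceedance: dict[float, int]       # p-level -> families above threshold
    exceedance_fraction: dict[float, float]
    median_max_prop: float
    max_parent_tally: pd.Series        # parent id -> times it was the max parent

    def summary(self) -> str:
        lines = [f"{self.n_families} simplex families tested"]
        for p, k in self.exceedance.items():
            lines.append(
                f"  p <= {p}: {k}/{self.n_families} "
                f"({100 * self.exceedance_fraction[p]:.1f}%) above threshold"
            )
        lines.append(f"  median max-parent sharing: {self.median_max_prop:.3f}")
        return "\n".join(lines)


def test_simplex_families(
    families,
    g: GenotypeMatrix,
    null: SharingNull,
    polymorphic_only: bool = False,
) -> FamilyTestReport:
    """Score every simplex family against the gene-dropping null.

    Families whose trio cannot be scored (ungenotyped member, no usable
    markers) are excluded and listed with the reason.  The max-parent tally
    counts, for each parent id, how often it was the more-shared parent —
    the summary used to spot systematically favoured parents.
    """
    rows = []
    excluded: list[tuple[SimplexFamily, str]] = []
    tally: dict[str, int] = {}
    p_levels = sorted(null.thresholds, reverse=True)
    for fam in families:
        try:
            res = parental_sharing(fam, g, polymorphic_only=polymorphic_only)
        except InsufficientDataError as exc:
            excluded.append((fam, str(exc)))
            continue
        max_parent = fam.parent1 if res.prop_parent1 >= res.prop_parent2 else fam.parent2
        tally[max_parent] = tally.get(max_parent, 0) + 1
        row = {
            "progeny": fam.progeny,
            "parent1": fam.parent1,
            "parent2": fam.parent2,
            "prop_parent1": res.prop_parent1,
            "prop_parent2": res.prop_parent2,
            "max_prop": res.max_prop,
            "max_parent": max_parent,
            "n_markers": res.n_markers,
        }
        for p in p_levels:
            row[f"exceeds_p{p:g}"] = res.max_prop > null.thresholds[p]
        rows.append(row)
    if not rows:
        raise InsufficientDataError("no scoreable simplex families")
    table = pd.DataFrame(rows)
    n = len(table)
    exceedance = {p: int(table[f"exceeds_p{p:g}"].sum()) for p in p_levels}
    return FamilyTestReport(
        table=table,
        excluded=excluded,
        n_families=n,
        exceedance=exceedance,
        exceedance_fraction={p: exceedance[p] / n for p in p_levels},
        median_max_prop=float(np.quantile(table["max_prop"], 0.5)),
        max_parent_tally=pd.Series(tally, dtype=int).sort_values(ascending=False),
    )


def read_families(path, sep: str = "\t") -> list[SimplexFamily]:
    """Read a families file with columns progeny, parent1, parent2."""
    frame = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in frame.columns]
    frame.columns = cols
    return [
        SimplexFamily(str(r["progeny"]), str(r["parent1"]), str(r["parent2"]))
        for _, r in frame.iterrows()
    ]
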