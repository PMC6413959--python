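"""Linkage disequilibrium: pairwise R², decay curves and observed-vs-simulated
difference profiles.

LD between two markers is the squared Pearson correlation of their dosage
vectors across lines (so it is invariant to allele relabelling).  Decay
along each chromosome is summarised by a loess fit of R² against genetic
distance, and compressed into the distance at which the fitted curve first
falls to a reference level (default R² = 0.15).  Comparing observed LD to a
gene-dropped null ensemble isolates the component attributable to selection:
elevated short-range ΔR² indicates conserved haplotype blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import GenotypeMatrix, GeneticMap
from .errors import ConfigurationError
from .genedrop import SimulationEnsemble

__all__ = [
    "LDMatrix",
    "DecayCurve",
    "maf_filter",
    "pairwise_r2",
    "ld_decay_fit",
    "distance_at_r2",
    "decay_summary",
    "ld_difference_profile",
    "ensemble_mean_r2",
]


def maf_filter(g: GenotypeMatrix, min_maf: float = 0.2) -> GenotypeMatrix:
    """Keep markers with minor-allele frequency strictly above ``min_maf``
    (computed over non-missing calls)."""
    maf = g.maf()
    keep = [m for m, f in zip(g.markers, maf) if np.isfinite(f) and f > min_maf]
    return g.subset_markers(keep)


@dataclass
class LDMatrix:
    """Pairwise R² with genetic distances.

    ``r2`` and ``dist`` are square marker-by-marker arrays; distance is inf
    for inter-chromosomal pairs.  Pairs with fewer than 3 jointly observed
    lines have NaN R².
    """

    markers: list[str]
    r2: np.ndarray
    dist: np.ndarray
    chrom: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def pairs(self) -> pd.DataFrame:
        """Long-format upper-triangle pair table."""
        iu = np.triu_indices(self.n_markers, k=1)
        m = np.asarray(self.markers)
        return pd.DataFrame(
            {
                "marker1": m[iu[0]],
                "marker2": m[iu[1]],
                "r2": self.r2[iu],
                "dist": self.dist[iu],
                "same_chrom": np.isfinite(self.dist[iu]),
            }
        )


def pairwise_r2(g: GenotypeMatrix, gmap: GeneticMap) -> LDMatrix:
    """Squared Pearson correlation of dosages for every marker pair.

    Correlations use pairwise-complete lines; a pair with fewer than 3 joint
    observations is set to NaN.  Distances come from the map; markers on
    different chromosomes get infinite distance.
    """
    if g.n_markers < 2:
        raise ConfigurationError("need at least two markers")
    for m in g.markers:
        if m not in gmap._marker_idx:
            raise ConfigurationError(f"marker {m!r} missing from map")
    frame = g.to_frame()
    r = frame.corr(min_periods=3).to_numpy()
    r2 = r**2
    np.fill_diagonal(r2, 1.0)
    idx = [gmap.marker_index(m) for m in g.markers]
    sub = GeneticMap(gmap.frame.iloc[sorted(idx)])
    # reorder to g's marker order
    order = [sub.marker_index(m) for m in g.markers]
    pos = sub.pos[order]
    chrom = sub.chrom[order]
    dist = np.abs(pos[:, None] - pos[None, :])
    dist[chrom[:, None] != chrom[None, :]] = np.inf
    return LDMatrix(markers=list(g.markers), r2=r2, dist=dist, chrom=chrom)


@dataclass
class DecayCurve:
    """Loess-smoothed R² as a function of cM distance on one chromosome."""

    chrom: str
    grid: np.ndarray
    values: np.ndarray
    span: float
    n_pairs: int

    def evaluate(self, d) -> np.ndarray:
        return np.interp(d, self.grid, self.values)


def ld_decay_fit(
    ld: LDMatrix,
    span: float = 0.75,
    grid_step: float = 1.0,
    min_pairs: int = 10,
) -> dict[str, DecayCurve]:
    """Per-chromosome loess fit of R² on genetic distance.

    Locally weighted linear regression with tricube weights, no robustness
    iterations, ``span`` as the fraction of points in each local window,
    evaluated on a 0..max-distance grid with ``grid_step`` cM steps.
    Chromosomes with fewer than ``min_pairs`` intra-chromosomal pairs are
    skipped with a warning.  Deterministic for identical input.
    """
    pairs = ld.pairs()
    intra = pairs[pairs["same_chrom"] & np.isfinite(pairs["r2"])]
    marker_chrom = dict(zip(ld.markers, ld.chrom))
    curves: dict[str, DecayCurve] = {}
    for chrom in dict.fromkeys(ld.chrom):
        sel = intra[intra["marker1"].map(marker_chrom) == chrom]
        if len(sel) < min_pairs:
            warnings.warn(
                f"chromosome {chrom}: only {len(sel)} pairs, skipping loess fit",
                stacklevel=2,
            )
            continue
        x = sel["dist"].to_numpy()
        y = sel["r2"].to_numpy()
        fitted = sm.nonparametric.lowess(y, x, frac=span, it=0, return_sorted=True)
        fx, fy = fitted[:, 0], fitted[:, 1]
        # average duplicated x before interpolation onto the grid
        ux, inv = np.unique(fx, return_inverse=True)
        uy = np.bincount(inv, weights=fy) / np.bincount(inv)
        grid = np.arange(0.0, x.max() + grid_step, grid_step)
        values = np.interp(grid, ux, uy)
        curves[str(chrom)] = DecayCurve(
            chrom=str(chrom), grid=grid, values=values, span=span, n_pairs=len(sel)
        )
    return curves


def distance_at_r2(curve: DecayCurve, level: float = 0.15) -> float | None:
    """Genetic distance at which the fitted curve first falls to ``level``.

    First downward crossing, linearly interpolated between grid points;
    ``None`` when the curve never reaches the level in range (reported as
    not-reached rather than raised).
    """
    v = curve.values
    if v[0] <= level:
        return float(curve.grid[0])
    below = np.flatnonzero(v <= level)
    if below.size == 0:
        return None
    i = below[0]
    x0, x1 = curve.grid[i - 1], curve.grid[i]
    y0, y1 = v[i - 1], v[i]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - level) / (y0 - y1) * (x1 - x0))


def _subgenome(chrom: str) -> str | None:
    """Wheat-style subgenome letter from labels like '3B'; None otherwise."""
    tail = chrom.lstrip("0123456789")
    return tail if len(tail) == 1 and tail.isalpha() else None


def decay_summary(
    obs_curves: dict[str, DecayCurve],
    sim_curves: dict[str, DecayCurve] | None = None,
    level: float = 0.15,
) -> pd.DataFrame:
    """Per-chromosome table of the distance at which LD falls to ``level``.

    Rows per chromosome, then per subgenome mean (when chromosome labels
    carry a subgenome letter, e.g. 1A..7D) and an overall mean; columns for
    observed and, if given, simulated curves.  Not-reached crossings are NaN
    and excluded from means.
    """
    rows = []
    for chrom, c in obs_curves.items():
        row = {"group": chrom, "level": level, "obs_cM": distance_at_r2(c, level)}
        if sim_curves is not None and chrom in sim_curves:
            row["sim_cM"] = distance_at_r2(sim_curves[chrom], level)
        rows.append(row)
    table = pd.DataFrame(rows)
    value_cols = [c for c in ("obs_cM", "sim_cM") if c in table.columns]
    extra = []
    subg = {g["group"]: _subgenome(g["group"]) for _, g in table.iterrows()}
    if all(v is not None for v in subg.values()) and table.shape[0] > 1:
        for letter in sorted(set(subg.values())):
            sel = table[[subg[g] == letter for g in table["group"]]]
            extra.append(
                {"group": f"subgenome_{letter}", "level": level,
                 **{c: sel[c].mean() for c in value_cols}}
            )
    extra.append(
        {"group": "overall", "level": level,
         **{c: table[c].mean() for c in value_cols}}
    )
    return pd.concat([table, pd.DataFrame(extra)], ignore_index=True)


def ensemble_mean_r2(ens: SimulationEnsemble, gmap: GeneticMap,
                     markers=None) -> LDMatrix:
    """Replicate-averaged LD of a simulated ensemble.

    R² is computed per replicate and then averaged across replicates (more
    stable than pooling genotypes).  ``markers`` restricts to a subset, e.g.
    the observed post-MAF-filter panel.
    """
    acc = None
    count = None
    base = None
    for rep in ens.replicates:
        view = rep.subset_markers(markers) if markers is not None else rep
        ldm = pairwise_r2(view, gmap)
        if acc is None:
            acc = np.zeros_like(ldm.r2)
            count = np.zeros_like(ldm.r2)
            base = ldm
        ok = np.isfinite(ldm.r2)
        acc[ok] += ldm.r2[ok]
        count += ok
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, acc / np.maximum(count, 1), np.nan)
    return LDMatrix(markers=base.markers, r2=mean, dist=base.dist, chrom=base.chrom)


@dataclass
class LDDifferenceProfile:
    """Observed-minus-simulated LD by genetic-distance bin."""

    table: pd.DataFrame          # bin_low, bin_high, mean_obs, mean_sim, delta, n_pairs
    inter_chrom_obs: float
    inter_chrom_sim: float

    @property
    def inter_chrom_delta(self) -> float:
        return self.inter_chrom_obs - self.inter_chrom_sim


def ld_difference_profile(
    obs: LDMatrix,
    sim: LDMatrix,
    bin_width: float = 5.0,
    max_dist: float | None = None,
) -> LDDifferenceProfile:
    """Bin intra-chromosomal pairs by distance and contrast mean obs vs sim R².

    ``sim`` is typically the replicate-averaged null from
    :func:`ensemble_mean_r2` on the same marker panel.  The inter-chromosome
    means give the long-range baseline (the dashed reference line of a
    difference-vs-distance plot).  Empty bins are omitted.
    """
    if obs.markers != sim.markers:
        raise ConfigurationError("observed and simulated marker sets differ")
    iu = np.triu_indices(obs.n_markers, k=1)
    d = obs.dist[iu]
    ro = obs.r2[iu]
    rs = sim.r2[iu]
    ok = np.isfinite(ro) & np.isfinite(rs)
    inter = ~np.isfinite(d) & ok
    intra = np.isfinite(d) & ok
    if max_dist is None:
        max_dist = d[intra].max() if intra.any() else 0.0
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = intra & (d >= lo) & (d < hi)
        if not sel.any():
            continue
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "mean_obs": float(ro[sel].mean()),
                "mean_sim": float(rs[sel].mean()),
                "delta": float(ro[sel].mean() - rs[sel].mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    return LDDifferenceProfile(
        table=pd.DataFrame(rows),
        inter_chrom_obs=float(ro[inter].mean()) if inter.any() else np.nan,
        inter_chrom_sim=float(rs[inter].mean()) if inter.any() else np.nan,
    )


def ld_matrix_export(obs: LDMatrix, sim: LDMatrix) -> pd.DataFrame:
    """Square marker-by-marker frame: observed R² above the diagonal,
    simulated below, 1 on the diagonal (heat-map export)."""
    if obs.markers != sim.markers:
        raise ConfigurationError("observed and simulated marker sets differ")
    out = np.triu(obs.r2, k=1) + np.tril(sim.r2, k=-1)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=obs.markers, columns=obs.markers)
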