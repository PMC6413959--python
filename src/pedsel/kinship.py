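"""Pedigree- and marker-based kinship, marker thinning, matrix comparison
and pedigree/seed-stock error flagging.

Pedigree kinship is the probability of identity by descent between random
alleles of two lines, computed by the classical tabular recursion with one
crop-specific convention: every founder is taken as fully inbred (F = 1,
self-kinship 1), because pedigree founders here are inbred varieties or
landrace selections, not outbred individuals.  Under that convention two
fully inbred sibling lines from a cross of unrelated founders have kinship
0.5 and any fully inbred line has self-kinship 1.

Marker kinship is plain identity-by-state allele sharing, chosen over an
allele-frequency-weighted genomic relationship because frequency estimation
is ill-posed in a structured collection of inbred lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, GeneticMap, KinshipMatrix
from .errors import InsufficientDataError
from .pedigree import Pedigree, ancestors

__all__ = [
    "pedigree_kinship",
    "ibs_kinship",
    "thin_markers",
    "compare_kinship",
    "flag_pedigree_errors",
    "ComparisonReport",
    "FlaggedLine",
]


def pedigree_kinship(ped: Pedigree, targets=None) -> KinshipMatrix:
    """Expected-IBD kinship matrix from the pedigree recursion.

    Works on any acyclic pedigree (typically one augmented with selfing
    generations).  The recursion, run in topological order over the ancestor
    closure of ``targets``:

    * founder f: phi(f, f) = 1 (fully inbred), phi(f, g) = 0 for g != f;
    * non-founder j with parents (p, q):
      phi(i, j) = (phi(i, p) + phi(i, q)) / 2 for any earlier i, and
      phi(j, j) = (1 + phi(p, q)) / 2;
    * an unknown parent slot contributes 0 to both formulas, i.e. behaves as
      a unique, unrelated, fully inbred founder.

    Returns the matrix restricted to ``targets`` (default: all entries).
    """
    if targets is None:
        targets = ped.ids
    else:
        targets = list(targets)
        for t in targets:
            ped.entry(t)  # KeyError on unknown id

    relevant: set[str] = set()
    for t in targets:
        if t not in relevant:
            relevant.add(t)
            relevant.update(ancestors(ped, t))
    order = [i for i in ped.topological_order() if i in relevant]
    idx = {i: k for k, i in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for j, jid in enumerate(order):
        p1, p2 = ped.parents(jid)
        i1 = idx[p1] if p1 is not None else -1
        i2 = idx[p2] if p2 is not None else -1
        if i1 < 0 and i2 < 0:
            K[j, j] = 1.0
            continue
        a = K[:j, i1] if i1 >= 0 else 0.0
        b = K[:j, i2] if i2 >= 0 else 0.0
        K[:j, j] = 0.5 * (a + b)
        K[j, :j] = K[:j, j]
        kpp = K[i1, i2] if (i1 >= 0 and i2 >= 0) else 0.0
        K[j, j] = 0.5 * (1.0 + kpp)
    sel = [idx[t] for t in targets]
    return KinshipMatrix(K[np.ix_(sel, sel)], targets, source="pedigree")


def ibs_kinship(g: GenotypeMatrix, min_overlap: int = 100) -> KinshipMatrix:
    """Identity-by-state allele-sharing kinship.

    Per marker the sharing between dosages a, b is 1 - |a - b| / 2 (1 for
    identical homozygotes, 0.5 when the dosages differ by one, 0 for opposite
    homozygotes); K(i, j) averages this over markers non-missing in both
    lines.  The diagonal is 1 by convention.  Pairs with no jointly observed
    marker get NaN; pairs below ``min_overlap`` jointly observed markers are
    recorded on ``low_overlap`` (list of (i, j, count)) and emit a warning.
    """
    if g.n_markers < 1:
        raise InsufficientDataError("need at least one marker")
    X = g.dosage
    obs = np.isfinite(X)
    n = g.n_lines
    K = np.ones((n, n))
    counts = obs.astype(np.int64) @ obs.T.astype(np.int64)
    for i in range(n):
        diff = np.abs(X[i] - X)  # (n, m), NaN where either missing
        share = 1.0 - diff / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            K[i] = np.nanmean(share, axis=1)
    K[counts == 0] = np.nan
    np.fill_diagonal(K, 1.0)
    km = KinshipMatrix(K, g.lines, source="marker")
    iu = np.triu_indices(n, k=1)
    low = counts[iu] < min_overlap
    km.low_overlap = [
        (g.lines[i], g.lines[j], int(c))
        for i, j, c in zip(iu[0][low], iu[1][low], counts[iu][low])
    ]
    if km.low_overlap:
        warnings.warn(
            f"{len(km.low_overlap)} line pairs share fewer than "
            f"{min_overlap} jointly observed markers",
            stacklevel=2,
        )
    return km


def thin_markers(
    g: GenotypeMatrix,
    r_abs_threshold: float = 0.75,
    genetic_map: GeneticMap | None = None,
    drop_colocated: bool = False,
) -> GenotypeMatrix:
    """Greedy keep-first thinning of correlated markers.

    Markers are visited in map order (or input order without a map); a marker
    is dropped if its absolute Pearson correlation with any already-kept
    marker exceeds ``r_abs_threshold``.  Monomorphic markers have undefined
    correlation and are retained but never compared.  With ``drop_colocated``
    a marker mapping to the exact position of a kept marker is also dropped
    (used before the cross-pedigree diversity scan).
    """
    if genetic_map is not None:
        order = [m for m in genetic_map.markers if m in set(g.markers)]
        order += [m for m in g.markers if m not in set(order)]
    else:
        order = list(g.markers)
    frame = g.to_frame()
    corr = frame.corr().abs()  # pairwise-complete; NaN for monomorphic
    kept: list[str] = []
    kept_pos: set[tuple[str, float]] = set()
    for m in order:
        r = corr.loc[m, kept] if kept else pd.Series(dtype=float)
        if (r > r_abs_threshold).any():
            continue
        if drop_colocated and genetic_map is not None and m in genetic_map._marker_idx:
            i = genetic_map.marker_index(m)
            key = (str(genetic_map.chrom[i]), float(genetic_map.pos[i]))
            if key in kept_pos:
                continue
            kept_pos.add(key)
        kept.append(m)
    kept_in_input_order = [m for m in g.markers if m in set(kept)]
    return g.subset_markers(kept_in_input_order)


@dataclass
class ComparisonReport:
    """Pedigree-vs-marker kinship comparison over shared off-diagonal pairs."""

    correlation: float
    p_value: float
    n_pairs: int
    pairs: pd.DataFrame  # id1, id2, pedigree, marker, residual, std_residual
    slope: float
    intercept: float


def compare_kinship(
    kp: KinshipMatrix, km: KinshipMatrix, drop_zero_pedigree: bool = True
) -> ComparisonReport:
    """Pearson correlation between pedigree and marker kinship matrices.

    Pairs with pedigree kinship exactly 0 (no known common ancestor) are
    excluded by default, since for them the pedigree is uninformative.
    Residuals are taken from the least-squares line of marker on pedigree
    kinship and standardised by a robust scale (1.4826 x median absolute
    deviation), so that the gross outliers the flagging step looks for do
    not mask themselves by inflating the scale estimate.
    """
    common = [i for i in kp.ids if i in set(km.ids)]
    if len(common) < 2:
        raise InsufficientDataError("need at least two shared line ids")
    a = kp.subset(common).values
    b = km.subset(common).values
    iu = np.triu_indices(len(common), k=1)
    ped_v = a[iu]
    mar_v = b[iu]
    keep = np.isfinite(ped_v) & np.isfinite(mar_v)
    if drop_zero_pedigree:
        keep &= ped_v != 0.0
    if keep.sum() < 3:
        raise InsufficientDataError("fewer than 3 comparable kinship pairs")
    ped_v, mar_v = ped_v[keep], mar_v[keep]
    ids1 = np.array(common)[iu[0][keep]]
    ids2 = np.array(common)[iu[1][keep]]
    r, p = stats.pearsonr(ped_v, mar_v)
    slope, intercept = np.polyfit(ped_v, mar_v, 1)
    resid = mar_v - (slope * ped_v + intercept)
    sd = float(stats.median_abs_deviation(resid, scale="normal"))
    if not np.isfinite(sd) or sd == 0:
        sd = resid.std(ddof=2) if len(resid) > 2 else np.nan
    std_resid = resid / sd if sd and np.isfinite(sd) and sd > 0 else np.zeros_like(resid)
    pairs = pd.DataFrame(
        {
            "id1": ids1,
            "id2": ids2,
            "pedigree": ped_v,
            "marker": mar_v,
            "residual": resid,
            "std_residual": std_resid,
        }
    )
    return ComparisonReport(
        correlation=float(r),
        p_value=float(p),
        n_pairs=int(keep.sum()),
        pairs=pairs,
        slope=float(slope),
        intercept=float(intercept),
    )


@dataclass
class FlaggedLine:
    """A line whose marker kinships deviate from pedigree expectation."""

    id: str
    n_extreme: int
    n_pairs: int
    fraction: float
    nearest_relatives: list[str] = field(default_factory=list)


def flag_pedigree_errors(
    report: ComparisonReport,
    ped: Pedigree | None = None,
    sd_cutoff: float = 4.0,
    min_fraction: float = 0.25,
) -> list[FlaggedLine]:
    """Flag lines with a disproportionate share of extreme residuals.

    A pair is extreme when |standardised residual| > ``sd_cutoff``; a line is
    flagged when more than ``min_fraction`` of its pairs are extreme.  Both
    cutoffs are heuristics for manual review (a genotype/pedigree swap makes
    most of a line's pairs extreme), not significance tests.  When a pedigree
    is supplied, each flag is annotated with the line's parents and children.
    """
    pairs = report.pairs
    flagged: list[FlaggedLine] = []
    all_ids = pd.unique(pd.concat([pairs["id1"], pairs["id2"]]))
    extreme = pairs["std_residual"].abs() > sd_cutoff
    for lid in all_ids:
        mask = (pairs["id1"] == lid) | (pairs["id2"] == lid)
        n = int(mask.sum())
        n_ext = int((mask & extreme).sum())
        if n == 0:
            continue
        frac = n_ext / n
        if frac > min_fraction:
            relatives: list[str] = []
            if ped is not None and lid in ped:
                relatives = list(ped.entry(lid).known_parents())
                relatives += sorted(ped.graph.successors(lid))
            flagged.append(FlaggedLine(str(lid), n_ext, n, frac, relatives))
    flagged.sort(key=lambda f: -f.fraction)
    return flagged
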