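"""MAF filtering, pairwise R², loess decay curves and difference profiles."""

import numpy as np
import pandas as pd
import pytest

from pedsel import (
    GeneticMap,
    GenotypeMatrix,
    decay_summary,
    distance_at_r2,
    ensemble_mean_r2,
    ld_decay_fit,
    ld_difference_profile,
    maf_filter,
    pairwise_r2,
)
from pedsel.genedrop import SimulationEnsemble, gene_drop, ensemble
from pedsel.ld import DecayCurve, ld_matrix_export
from conftest import geno


def linear_map(n, chrom="1", step=1.0, start=0.0):
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(n)],
                "chrom": [chrom] * n,
                "pos": start + step * np.arange(n),
            }
        )
    )


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------


def test_maf_filter_drops_fixed_keeps_balanced():
    g = geno({"a": [2, 2, 2], "b": [2, 0, 2], "c": [2, 0, 0], "d": [2, 2, 0]})
    # m0 fixed (maf 0), m1 maf 0.25, m2 maf 0.5
    out = maf_filter(g, min_maf=0.2)
    assert out.markers == ["m1", "m2"]


def test_maf_filter_is_strict():
    g = geno({"a": [2], "b": [2], "c": [2], "d": [0], "e": [0]})  # maf 0.4
    assert maf_filter(g, min_maf=0.4).markers == []
    assert maf_filter(g, min_maf=0.39).markers == ["m0"]


# ---------------------------------------------------------------------------
# pairwise R^2
# ---------------------------------------------------------------------------


def test_duplicated_and_swapped_marker_give_r2_one():
    rng = np.random.default_rng(0)
    col = rng.integers(0, 3, 30).astype(float)
    g = GenotypeMatrix(np.c_[col, col, 2 - col], [f"l{i}" for i in range(30)],
                       ["m0", "m1", "m2"])
    ld = pairwise_r2(g, linear_map(3))
    assert ld.r2[0, 1] == pytest.approx(1.0)
    assert ld.r2[0, 2] == pytest.approx(1.0)  # allele-label swap is sign-invariant


def test_too_few_joint_observations_gives_nan():
    g = geno(
        {
            "a": [2, np.nan],
            "b": [0, np.nan],
            "c": [2, np.nan],
            "d": [np.nan, 0],
            "e": [np.nan, 2],
        }
    )
    ld = pairwise_r2(g, linear_map(2))
    assert np.isnan(ld.r2[0, 1])


def test_inter_chromosome_pairs_have_infinite_distance():
    g = geno({"a": [2, 0, 0], "b": [0, 2, 2], "c": [2, 2, 0], "d": [0, 0, 2]})
    gmap = GeneticMap(
        pd.DataFrame(
            {"marker": ["m0", "m1", "m2"], "chrom": ["1", "1", "2"],
             "pos": [0.0, 5.0, 0.0]}
        )
    )
    ld = pairwise_r2(g, gmap)
    assert ld.dist[0, 1] == 5.0
    assert np.isinf(ld.dist[0, 2])


def test_r2_invariant_to_line_order():
    rng = np.random.default_rng(1)
    dos = rng.integers(0, 3, size=(25, 6)).astype(float)
    lines = [f"l{i}" for i in range(25)]
    g = GenotypeMatrix(dos, lines, [f"m{i}" for i in range(6)])
    ld0 = pairwise_r2(g, linear_map(6))
    perm = rng.permutation(25)
    g2 = g.subset_lines([lines[i] for i in perm])
    ld1 = pairwise_r2(g2, linear_map(6))
    assert np.allclose(ld0.r2, ld1.r2, equal_nan=True)


def test_unlinked_marker_mean_r2_near_null_expectation():
    # E[r^2] ~ 1/(n-1) for independent markers over n lines
    rng = np.random.default_rng(9)
    n, reps = 40, 300
    vals = []
    for _ in range(reps):
        a = rng.binomial(2, 0.5, n).astype(float)
        b = rng.binomial(2, 0.5, n).astype(float)
        if a.std() == 0 or b.std() == 0:
            continue
        vals.append(np.corrcoef(a, b)[0, 1] ** 2)
    mean = np.mean(vals)
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(mean - 1.0 / (n - 1)) < 3 * se


# ---------------------------------------------------------------------------
# decay curves
# ---------------------------------------------------------------------------


def test_constant_r2_fits_flat_curve():
    n = 12
    g = geno({f"l{i}": list(np.zeros(n)) for i in range(4)},
             markers=[f"m{i}" for i in range(n)])
    ld = pairwise_r2(g, linear_map(n, step=3.0))
    ld.r2[:] = 0.4  # force constant off-diagonal R^2
    np.fill_diagonal(ld.r2, 1.0)
    curve = ld_decay_fit(ld, span=0.75)["1"]
    assert np.allclose(curve.values, 0.4, atol=1e-8)


def test_known_exponential_decay_recovered():
    rng = np.random.default_rng(4)
    n = 40
    gmap = linear_map(n, step=2.0)
    pos = gmap.pos
    d = np.abs(pos[:, None] - pos[None, :])
    r2 = np.exp(-d / 20.0) + rng.normal(0, 0.01, size=(n, n))
    r2 = np.clip((r2 + r2.T) / 2, 0, 1)
    np.fill_diagonal(r2, 1.0)
    from pedsel.ld import LDMatrix

    ld = LDMatrix(markers=gmap.markers, r2=r2, dist=d, chrom=gmap.chrom)
    curve = ld_decay_fit(ld, span=0.3)["1"]
    grid = np.arange(5.0, 60.0, 5.0)
    truth = np.exp(-grid / 20.0)
    assert np.max(np.abs(curve.evaluate(grid) - truth)) < 0.05


def test_decay_fit_deterministic():
    rng = np.random.default_rng(2)
    dos = rng.integers(0, 3, size=(30, 10)).astype(float)
    g = GenotypeMatrix(dos, [f"l{i}" for i in range(30)],
                       [f"m{i}" for i in range(10)])
    gmap = linear_map(10, step=4.0)
    c1 = ld_decay_fit(pairwise_r2(g, gmap))["1"]
    c2 = ld_decay_fit(pairwise_r2(g, gmap))["1"]
    assert np.array_equal(c1.values, c2.values)


def test_sparse_chromosome_skipped_with_warning():
    g = geno({"a": [2, 0], "b": [0, 2], "c": [2, 2], "d": [0, 0]})
    with pytest.warns(UserWarning, match="skipping"):
        curves = ld_decay_fit(pairwise_r2(g, linear_map(2)), min_pairs=10)
    assert curves == {}


# ---------------------------------------------------------------------------
# distance at reference LD
# ---------------------------------------------------------------------------


def test_distance_at_level_closed_form_inversion():
    grid = np.arange(0.0, 120.0, 1.0)
    curve = DecayCurve("1", grid, np.exp(-grid / 20.0), span=0.75, n_pairs=100)
    d = distance_at_r2(curve, level=0.15)
    assert d == pytest.approx(-20.0 * np.log(0.15), abs=0.1)  # ~37.9 cM


def test_flat_curve_never_reaches_level():
    grid = np.arange(0.0, 50.0, 1.0)
    curve = DecayCurve("1", grid, np.full_like(grid, 0.5), span=0.75, n_pairs=10)
    assert distance_at_r2(curve, level=0.15) is None


def test_decay_summary_reproducible_from_chromosome_values():
    grid = np.arange(0.0, 100.0, 1.0)
    curves_obs = {
        "1A": DecayCurve("1A", grid, np.exp(-grid / 20.0), 0.75, 50),
        "1B": DecayCurve("1B", grid, np.exp(-grid / 10.0), 0.75, 50),
        "2A": DecayCurve("2A", grid, np.exp(-grid / 30.0), 0.75, 50),
    }
    table = decay_summary(curves_obs, level=0.15)
    per_chrom = table.set_index("group").loc[["1A", "1B", "2A"], "obs_cM"]
    overall = table.set_index("group").loc["overall", "obs_cM"]
    assert overall == pytest.approx(per_chrom.mean())
    sub_a = table.set_index("group").loc["subgenome_A", "obs_cM"]
    assert sub_a == pytest.approx(per_chrom[["1A", "2A"]].mean())


# ---------------------------------------------------------------------------
# observed vs simulated difference profile
# ---------------------------------------------------------------------------


def _ld_setup(seed=0):
    from pedsel import Pedigree, PedigreeEntry
    from pedsel.synthetic import make_founders

    n = 30
    gmap = GeneticMap(
        pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(n)],
                "chrom": np.repeat(["1", "2", "3"], 10),
                "pos": np.tile(np.arange(10) * 8.0, 3),
            }
        )
    )
    founders, _ = make_founders(8, gmap, freq_spec=0.5, seed=seed)
    ped = Pedigree([PedigreeEntry(f) for f in founders.lines])
    rng = np.random.default_rng(seed)
    targets = []
    for i in range(12):
        p1, p2 = rng.choice(founders.lines, 2, replace=False)
        ped.add_entry(PedigreeEntry(f"T{i}", str(p1), str(p2)))
        targets.append(f"T{i}")
    return gmap, founders, ped, targets


def test_profile_of_replicate_against_ensemble_is_near_zero():
    gmap, founders, ped, targets = _ld_setup()
    ens = ensemble(25, ped, founders, gmap, selfing_generations=3, base_seed=10,
                   targets=targets)
    obs = gene_drop(ped, founders, gmap, selfing_generations=3, seed=500,
                    targets=targets)
    sim = ensemble_mean_r2(ens, gmap)
    prof = ld_difference_profile(pairwise_r2(obs, gmap), sim, bin_width=20.0)
    assert np.abs(prof.table["delta"]).max() < 0.15
    assert abs(prof.inter_chrom_delta) < 0.05


def test_matrix_export_obs_above_sim_below():
    gmap, founders, ped, targets = _ld_setup(seed=2)
    obs = gene_drop(ped, founders, gmap, selfing_generations=2, seed=3,
                    targets=targets)
    sim = gene_drop(ped, founders, gmap, selfing_generations=2, seed=4,
                    targets=targets)
    lo = pairwise_r2(obs, gmap)
    ls = pairwise_r2(sim, gmap)
    mat = ld_matrix_export(lo, ls)
    assert mat.iloc[0, 1] == pytest.approx(lo.r2[0, 1])
    assert mat.iloc[1, 0] == pytest.approx(ls.r2[1, 0])
    assert mat.iloc[2, 2] == 1.0


def test_profile_requires_matching_markers():
    gmap, founders, ped, targets = _ld_setup(seed=3)
    obs = gene_drop(ped, founders, gmap, selfing_generations=1, seed=1,
                    targets=targets)
    lo = pairwise_r2(obs, gmap)
    ls = pairwise_r2(obs.subset_markers(obs.markers[:10]), gmap)
    from pedsel import ConfigurationError

    with pytest.raises(ConfigurationError):
        ld_difference_profile(lo, ls)
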