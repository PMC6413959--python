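"""Pedigree and IBS kinship, thinning, comparison and error flagging."""

import numpy as np
import pandas as pd
import pytest

from pedsel import (
    GenotypeMatrix,
    InsufficientDataError,
    Pedigree,
    PedigreeEntry,
    augment_selfing,
    compare_kinship,
    flag_pedigree_errors,
    ibs_kinship,
    pedigree_kinship,
    thin_markers,
)
from conftest import geno


# ---------------------------------------------------------------------------
# independent oracle: single-locus IBD gene dropping with founder labels
# ---------------------------------------------------------------------------


def ibd_kinship_mc(ped, pairs, n_sims=20000, seed=0):
    """Monte-Carlo IBD kinship, independent of the tabular recursion.

    Each founder gets ONE allele label on both chromosomes (fully inbred);
    an unknown parent slot transmits a unique private label.  A child draws
    one random allele from each parent.  The kinship estimate for (a, b) is
    the mean over simulations of the fraction of the four cross-line allele
    pairs that share a label.  Returns {pair: (estimate, standard_error)}.
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    labels = {}
    next_label = 0
    for eid in order:
        p1, p2 = ped.parents(eid)
        if p1 is None and p2 is None:
            lab = np.full(n_sims, next_label)
            next_label += 1
            labels[eid] = np.stack([lab, lab])
            continue
        alleles = []
        for pid in (p1, p2):
            if pid is None:
                alleles.append(np.full(n_sims, next_label))
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_sims)
                alleles.append(labels[pid][pick, np.arange(n_sims)])
        labels[eid] = np.stack(alleles)
    out = {}
    for a, b in pairs:
        la, lb = labels[a], labels[b]
        share = np.zeros(n_sims)
        for i in range(2):
            for j in range(2):
                share += la[i] == lb[j]
        share /= 4.0
        out[(a, b)] = (share.mean(), share.std(ddof=1) / np.sqrt(n_sims))
    return out


def random_crossing_pedigree(n_founders, n_crosses, seed, single_parent=False):
    rng = np.random.default_rng(seed)
    ped = Pedigree([PedigreeEntry(f"F{i}") for i in range(n_founders)])
    pool = ped.ids[:]
    for i in range(n_crosses):
        p1, p2 = rng.choice(pool, 2, replace=False)
        ped.add_entry(PedigreeEntry(f"X{i}", str(p1), str(p2)))
        pool.append(f"X{i}")
    if single_parent:
        ped.add_entry(PedigreeEntry("SP", str(pool[-1]), None))
    return ped


# ---------------------------------------------------------------------------
# pedigree kinship
# ---------------------------------------------------------------------------


def test_founder_self_kinship_is_one(trio):
    k = pedigree_kinship(trio)
    assert k.get("P1", "P1") == 1.0
    assert k.get("P1", "P2") == 0.0


def test_selfed_sibling_lines_have_kinship_half(sib_pedigree):
    aug = augment_selfing(sib_pedigree, 7)
    k = pedigree_kinship(aug, targets=["A", "B"])
    assert k.get("A", "B") == pytest.approx(0.5, abs=1e-12)


def test_seven_generation_selfed_self_kinship(sib_pedigree):
    # phi_n = (1 + phi_{n-1}) / 2 with phi_0 = 0.5 gives 1 - 2**-8 after 7 selfings
    aug = augment_selfing(sib_pedigree, 7)
    k = pedigree_kinship(aug, targets=["A"])
    assert k.get("A", "A") == pytest.approx(1.0 - 2.0**-8, abs=1e-12)


def test_unknown_parent_side_acts_as_unrelated_founder():
    ped = Pedigree([PedigreeEntry("P"), PedigreeEntry("C", "P", None)])
    k = pedigree_kinship(ped)
    assert k.get("C", "C") == 0.5  # (1 + phi(P, unknown)) / 2
    assert k.get("C", "P") == 0.5  # (phi(P,P) + phi(unknown,P)) / 2


def test_kinship_matches_monte_carlo_ibd_oracle():
    ped = random_crossing_pedigree(6, 8, seed=5, single_parent=True)
    assert len(ped) <= 30
    ids = ped.ids
    rng = np.random.default_rng(1)
    pairs = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(6)]
    pairs += [("SP", "SP"), ("X7", "X7")]
    mc = ibd_kinship_mc(ped, pairs, n_sims=20000, seed=2)
    k = pedigree_kinship(ped)
    for (a, b), (est, se) in mc.items():
        assert abs(k.get(a, b) - est) <= 3 * max(se, 1e-4), (a, b)


def test_kinship_with_nonancestor_never_exceeds_self_kinship():
    ped = random_crossing_pedigree(5, 10, seed=9)
    k = pedigree_kinship(ped)
    v = k.values
    assert (v <= np.diag(v)[:, None] + 1e-12).all()


def test_unknown_target_raises(trio):
    with pytest.raises(KeyError):
        pedigree_kinship(trio, targets=["nope"])


# ---------------------------------------------------------------------------
# IBS kinship
# ---------------------------------------------------------------------------


def test_ibs_identical_and_opposite_lines():
    g = geno({"a": [2, 0, 2], "b": [2, 0, 2], "c": [0, 2, 0]})
    k = ibs_kinship(g, min_overlap=1)
    assert k.get("a", "b") == 1.0
    assert k.get("a", "c") == 0.0
    assert k.get("a", "a") == 1.0


def test_ibs_hand_computed_sharing():
    # (2,2) -> 1, (2,0) -> 0, (1,2) -> 0.5 => mean 0.5
    g = geno({"a": [2, 2, 1], "b": [2, 0, 2]})
    k = ibs_kinship(g, min_overlap=1)
    assert k.get("a", "b") == pytest.approx(0.5)


def test_ibs_missing_handling_and_zero_overlap():
    g = geno({"a": [2, np.nan], "b": [np.nan, 0]})
    with pytest.warns(UserWarning):
        k = ibs_kinship(g, min_overlap=1)
    assert np.isnan(k.get("a", "b"))
    assert k.get("a", "a") == 1.0


def test_ibs_invariant_to_marker_order_and_allele_swap():
    rng = np.random.default_rng(3)
    dos = rng.integers(0, 3, size=(6, 30)).astype(float)
    g = GenotypeMatrix(dos, [f"l{i}" for i in range(6)], [f"m{j}" for j in range(30)])
    k0 = ibs_kinship(g, min_overlap=1).values
    perm = rng.permutation(30)
    g_perm = g.subset_markers([g.markers[i] for i in perm])
    assert np.allclose(ibs_kinship(g_perm, min_overlap=1).values, k0)
    swapped = dos.copy()
    swapped[:, :10] = 2 - swapped[:, :10]  # relabel alleles at 10 markers
    g_swap = GenotypeMatrix(swapped, g.lines, g.markers)
    assert np.allclose(ibs_kinship(g_swap, min_overlap=1).values, k0)


# ---------------------------------------------------------------------------
# marker thinning
# ---------------------------------------------------------------------------


def test_thin_removes_one_of_identical_pair():
    g = geno({"a": [0, 0, 2], "b": [2, 2, 0], "c": [2, 2, 2], "d": [0, 0, 0]})
    out = thin_markers(g, r_abs_threshold=0.75)
    assert out.markers == ["m0", "m2"]  # m1 duplicates m0; keep-first


def test_thin_keeps_uncorrelated_markers():
    rng = np.random.default_rng(0)
    dos = rng.integers(0, 3, size=(60, 5)).astype(float)
    g = GenotypeMatrix(dos, [f"l{i}" for i in range(60)], [f"m{j}" for j in range(5)])
    frame = g.to_frame()
    assert frame.corr().abs().to_numpy()[np.triu_indices(5, 1)].max() < 0.75
    assert thin_markers(g).markers == g.markers


def test_thin_greedy_matches_stated_pattern():
    # |r|(1,2) > thr, |r|(1,3) and |r|(2,3) small -> keep {1, 3}
    rng = np.random.default_rng(7)
    m1 = rng.integers(0, 3, 200).astype(float)
    noise = rng.normal(size=200)
    m2 = np.clip(np.round(m1 + 0.3 * noise), 0, 2)
    m3 = rng.integers(0, 3, 200).astype(float)
    g = GenotypeMatrix(np.c_[m1, m2, m3], [f"l{i}" for i in range(200)],
                       ["m1", "m2", "m3"])
    corr = g.to_frame().corr().abs()
    assert corr.loc["m1", "m2"] > 0.75
    assert corr.loc["m1", "m3"] < 0.75 and corr.loc["m2", "m3"] < 0.75
    out = thin_markers(g, 0.75)
    assert out.markers == ["m1", "m3"]
    # no retained pair exceeds the threshold (brute-force property)
    kept_corr = out.to_frame().corr().abs().to_numpy()
    assert kept_corr[np.triu_indices(len(out.markers), 1)].max() <= 0.75


def test_thin_retains_monomorphic_markers():
    g = geno({"a": [2, 2], "b": [2, 0], "c": [2, 2]})  # m0 monomorphic
    assert thin_markers(g).markers == ["m0", "m1"]


# ---------------------------------------------------------------------------
# comparison and error flagging
# ---------------------------------------------------------------------------


def _pedigree_and_kinships(seed=4, n_founders=8, n_crosses=20):
    ped = random_crossing_pedigree(n_founders, n_crosses, seed=seed)
    kp = pedigree_kinship(ped)
    return ped, kp


def test_compare_identical_matrices_gives_r_one():
    _, kp = _pedigree_and_kinships()
    kp2 = type(kp)(kp.values.copy(), kp.ids, source="marker")
    rep = compare_kinship(kp, kp2)
    assert rep.correlation == pytest.approx(1.0)


def test_compare_to_noise_gives_small_r():
    _, kp = _pedigree_and_kinships()
    rng = np.random.default_rng(12)
    noise = rng.random((kp.n, kp.n))
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 1.0)
    km = type(kp)(noise, kp.ids, source="marker")
    rep = compare_kinship(kp, km)
    n = rep.n_pairs
    assert abs(rep.correlation) < 4 / np.sqrt(n)


def test_compare_r_invariant_to_affine_rescaling():
    _, kp = _pedigree_and_kinships()
    rng = np.random.default_rng(5)
    vals = kp.values * 0.4 + 0.55 + 0
    km = type(kp)(vals, kp.ids, source="marker")
    base = compare_kinship(kp, km).correlation
    km2 = type(kp)(vals * 3.0 - 0.2, kp.ids, source="marker")
    assert compare_kinship(kp, km2).correlation == pytest.approx(base)


def test_compare_requires_three_pairs():
    from pedsel import KinshipMatrix

    k = KinshipMatrix(np.eye(2), ["a", "b"])
    with pytest.raises(InsufficientDataError):
        compare_kinship(k, KinshipMatrix(np.eye(2), ["a", "b"], "marker"))


def _marker_kinship_from_pedigree(ped, kp, seed=0, noise=0.02):
    """Marker-like kinship: pedigree kinship plus small symmetric noise."""
    rng = np.random.default_rng(seed)
    n = kp.n
    eps = rng.normal(0, noise, size=(n, n))
    eps = (eps + eps.T) / 2
    vals = np.clip(kp.values + eps, 0, 1)
    np.fill_diagonal(vals, 1.0)
    return type(kp)(vals, kp.ids, source="marker")


def test_flagging_clean_data_is_empty():
    ped, kp = _pedigree_and_kinships()
    km = _marker_kinship_from_pedigree(ped, kp)
    rep = compare_kinship(kp, km)
    assert flag_pedigree_errors(rep, ped) == []


def test_swapped_line_is_flagged():
    ped, kp = _pedigree_and_kinships()
    km = _marker_kinship_from_pedigree(ped, kp)
    vals = km.values.copy()
    ids = km.ids
    # swap one line's marker kinships with an unrelated line's row/column
    i, j = ids.index("X10"), ids.index("F0")
    vals[[i, j], :] = vals[[j, i], :]
    vals[:, [i, j]] = vals[:, [j, i]]
    np.fill_diagonal(vals, 1.0)
    km_bad = type(kp)(vals, ids, source="marker")
    rep = compare_kinship(kp, km_bad)
    flagged = flag_pedigree_errors(rep, ped)
    assert "X10" in {f.id for f in flagged}


def test_mutually_mislabelled_pair_both_flagged():
    # two-population construction: two pedigree clusters, labels of one line
    # in each cluster exchanged in the marker data
    ped = Pedigree([PedigreeEntry(f"A{i}") for i in range(4)]
                   + [PedigreeEntry(f"B{i}") for i in range(4)])
    for i in range(6):
        ped.add_entry(PedigreeEntry(f"AX{i}", f"A{i % 4}", f"A{(i + 1) % 4}"))
        ped.add_entry(PedigreeEntry(f"BX{i}", f"B{i % 4}", f"B{(i + 1) % 4}"))
    kp = pedigree_kinship(ped)
    km = _marker_kinship_from_pedigree(ped, kp, seed=8)
    vals = km.values.copy()
    ids = km.ids
    i, j = ids.index("AX0"), ids.index("BX0")
    vals[[i, j], :] = vals[[j, i], :]
    vals[:, [i, j]] = vals[:, [j, i]]
    np.fill_diagonal(vals, 1.0)
    rep = compare_kinship(kp, type(kp)(vals, ids, source="marker"))
    flagged = {f.id for f in flag_pedigree_errors(rep, ped)}
    assert {"AX0", "BX0"} <= flagged


def test_flag_annotates_nearest_relatives():
    ped, kp = _pedigree_and_kinships()
    km = _marker_kinship_from_pedigree(ped, kp)
    vals = km.values.copy()
    i = km.ids.index("X5")
    rng = np.random.default_rng(3)
    vals[i, :] = rng.random(kp.n)
    vals[:, i] = vals[i, :]
    np.fill_diagonal(vals, 1.0)
    rep = compare_kinship(kp, type(kp)(vals, km.ids, source="marker"))
    flagged = flag_pedigree_errors(rep, ped)
    target = [f for f in flagged if f.id == "X5"]
    assert target and set(ped.entry("X5").known_parents()) <= set(
        target[0].nearest_relatives
    )
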