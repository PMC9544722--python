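"""Pedigree container, pruning, summaries and relatedness structures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedfit as pf
from pedfit.pedigree import PedigreeError

from conftest import random_pedigree


# ---------------------------------------------------------------------------
# reading & validation
# ---------------------------------------------------------------------------


def test_read_pedigree_roundtrip(tmp_path, trio_ped):
    path = tmp_path / "ped.tsv"
    pf.write_pedigree(trio_ped, path)
    ped = pf.read_pedigree(path)
    assert ped == trio_ped
    assert ped.n_founders == 2


def test_read_is_order_invariant(tmp_path):
    a = tmp_path / "a.csv"
    b = tmp_path / "b.csv"
    a.write_text("id,dam,sire,cohort\nm,NA,NA,1\nf,NA,NA,1\nkid,f,m,2\n")
    b.write_text("id,dam,sire,cohort\nkid,f,m,2\nm,NA,NA,1\nf,NA,NA,1\n")
    pa, pb = pf.read_pedigree(a), pf.read_pedigree(b)
    assert sorted(pa.ids) == sorted(pb.ids)
    # child after both parents in both cases
    for ped in (pa, pb):
        k = ped.index_of("kid")
        assert k > ped.index_of("m") and k > ped.index_of("f")


def test_unlisted_parent_becomes_founder_with_warning(tmp_path):
    path = tmp_path / "ped.csv"
    path.write_text("id,dam,sire\nkid,mum,dad\nmum,NA,NA\n")
    with pytest.warns(UserWarning, match="founder"):
        ped = pf.read_pedigree(path)
    assert "dad" in ped
    assert ped.dam[ped.index_of("dad")] == -1


def test_duplicate_id_raises():
    with pytest.raises(PedigreeError, match="dup"):
        pf.Pedigree(["dup", "dup"], [None, None], [None, None])


def test_cycle_raises_and_names_a_cycle():
    with pytest.raises(PedigreeError, match="cycle"):
        pf.Pedigree(["a", "b"], ["b", "a"], [None, None])


def test_missing_sentinels(tmp_path):
    path = tmp_path / "ped.csv"
    path.write_text("animal,mother,father\nx,0,*\ny,x,NA\n")
    ped = pf.read_pedigree(path)
    assert ped.is_founder[ped.index_of("x")]
    assert ped.dam[ped.index_of("y")] == ped.index_of("x")


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def test_prune_keeps_full_ancestor_chain():
    ids = ["a", "b", "c", "d", "e"]
    ped = pf.Pedigree(ids, [None, "a", "b", "c", "d"], [None] * 5)
    pruned = pf.prune_to_phenotyped(ped, ["e"])
    assert sorted(pruned.ids) == ids


def test_prune_drops_childless_unphenotyped_sibling(sib_ped):
    pruned = pf.prune_to_phenotyped(sib_ped, ["c1"])
    assert "c2" not in pruned
    assert "h1" not in pruned
    assert {"f1", "f2", "c1"} == set(pruned.ids)


def test_prune_empty_or_unknown_raises(trio_ped):
    with pytest.raises(PedigreeError):
        pf.prune_to_phenotyped(trio_ped, [])
    with pytest.raises(PedigreeError):
        pf.prune_to_phenotyped(trio_ped, ["ghost"])


def _ancestor_closure(ped, keep):
    out = set()

    def up(i):
        if i in out:
            return
        out.add(i)
        for p in (ped.dam[i], ped.sire[i]):
            if p >= 0:
                up(p)

    for i in keep:
        up(ped.index_of(i))
    return {ped.ids[i] for i in out}


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), pick=st.integers(1, 10))
def test_prune_matches_recursive_ancestor_closure_and_is_idempotent(seed, pick):
    ped = random_pedigree(seed, n=50)
    rng = np.random.default_rng(seed + 1)
    pheno = list(rng.choice(ped.ids, size=pick, replace=False))
    pruned = pf.prune_to_phenotyped(ped, pheno)
    assert set(pruned.ids) == _ancestor_closure(ped, pheno)
    again = pf.prune_to_phenotyped(pruned, pheno)
    assert again == pruned


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_summary_counts_trio_family():
    ped = pf.Pedigree(
        ["m", "f", "a", "b", "c"],
        [None, None, "f", "f", "f"],
        [None, None, "m", "m", "m"],
    )
    s = pf.summarize(ped)
    assert s.n_paternities == 3 and s.n_maternities == 3
    # C(3,2) = 3 pairs for each sib category
    assert s.n_fullsib_pairs == 3
    assert s.n_paternal_halfsib_pairs_incl_full == 3
    assert s.n_maternal_halfsib_pairs_incl_full == 3
    assert s.max_depth == 2


def test_summary_founders_only():
    ped = pf.Pedigree(["x", "y"], [None, None], [None, None])
    s = pf.summarize(ped)
    assert s.n_records == 2 and s.max_depth == 1
    assert s.n_paternities == s.n_fullsib_pairs == 0


def _brute_force_counts(ped):
    full = pat = mat = 0
    n = len(ped)
    for i in range(n):
        for j in range(i + 1, n):
            same_sire = ped.sire[i] >= 0 and ped.sire[i] == ped.sire[j]
            same_dam = ped.dam[i] >= 0 and ped.dam[i] == ped.dam[j]
            pat += same_sire
            mat += same_dam
            full += same_sire and same_dam
    return full, pat, mat


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_summary_matches_brute_force_pair_enumeration(seed):
    ped = random_pedigree(seed, n=80, p_known=0.85)
    s = pf.summarize(ped)
    full, pat, mat = _brute_force_counts(ped)
    assert s.n_fullsib_pairs == full
    assert s.n_paternal_halfsib_pairs_incl_full == pat
    assert s.n_maternal_halfsib_pairs_incl_full == mat
    assert s.n_fullsib_pairs <= min(pat, mat)


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------


def test_relationship_founders_identity():
    ped = pf.Pedigree(["a", "b", "c"], [None] * 3, [None] * 3)
    rs = pf.additive_relationship(ped, dense=True)
    assert np.allclose(rs.dense_A(), np.eye(3))
    assert np.allclose(rs.F, 0)


def test_relationship_classic_coefficients(sib_ped):
    rs = pf.additive_relationship(sib_ped, dense=True)
    A = rs.dense_A()
    ix = sib_ped.index_of
    assert A[ix("f1"), ix("c1")] == pytest.approx(0.5)  # parent-offspring
    assert A[ix("c1"), ix("c2")] == pytest.approx(0.5)  # full sibs
    assert A[ix("c1"), ix("h1")] == pytest.approx(0.25)  # half sibs


def test_fullsib_mating_inbreeding():
    ped = pf.Pedigree(
        ["a", "b", "s1", "s2", "k"],
        [None, None, "a", "a", "s1"],
        [None, None, "b", "b", "s2"],
    )
    rs = pf.additive_relationship(ped, dense=True)
    k = ped.index_of("k")
    assert rs.F[k] == pytest.approx(0.25)
    assert rs.dense_A()[k, k] == pytest.approx(1.25)


def _kinship_recursive(ped):
    """Independent oracle: Malecot kinship by recursion over pedigree paths."""
    from functools import lru_cache

    dam, sire = ped.dam, ped.sire

    @lru_cache(maxsize=None)
    def phi(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + phi(sire[i], dam[i]))
        if j > i:
            i, j = j, i
        return 0.5 * (phi(dam[i], j) + phi(sire[i], j))

    n = len(ped)
    return np.array([[2.0 * phi(i, j) for j in range(n)] for i in range(n)])


@pytest.mark.parametrize("seed", [1, 5, 11])
def test_tabular_A_equals_kinship_recursion(seed):
    ped = random_pedigree(seed, n=20, p_known=0.9)
    A = pf.additive_relationship(ped, dense=True).dense_A()
    # 2x kinship equals the numerator relationship matrix, diagonal included
    assert np.allclose(A, _kinship_recursive(ped), atol=1e-12)


@pytest.mark.parametrize("seed", [2, 9])
def test_sparse_inverse_times_dense_A_is_identity(seed):
    ped = random_pedigree(seed, n=200, p_known=0.85)
    rs = pf.additive_relationship(ped, dense=True)
    prod = rs.A_inv @ rs.dense_A()
    assert np.abs(prod - np.eye(len(ped))).max() < 1e-8


def test_inbreeding_matches_dense_diagonal(rand_ped):
    rs = pf.additive_relationship(rand_ped, dense=True)
    assert np.allclose(1.0 + rs.F, np.diag(rs.dense_A()))
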