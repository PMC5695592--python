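"""Morphometric pipeline: standardization, binning, MDI/PDI, rank ANOVA, DFA."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg

from morphopop import morpho
from morphopop.datamodel import CategoricalMatrix, TraitMatrix


def make_traits(values, pops=None, chars=None):
    values = np.asarray(values, dtype=float)
    n, c = values.shape
    return TraitMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        population_ids=pops or ["A"] * n,
        characters=chars or [f"ch{j}" for j in range(c)],
        values=values,
    )


def make_categorical(states, pops, n_states=None):
    states = np.asarray(states, dtype=np.int64)
    n, c = states.shape
    return CategoricalMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        population_ids=pops,
        characters=[f"ch{j}" for j in range(c)],
        states=states,
        n_states=np.asarray(n_states if n_states is not None else states.max(axis=0)),
    )


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------


def test_standardize_column():
    t = make_traits([[2.0], [4.0], [6.0]])
    std, params = morpho.standardize(t)
    assert abs(std.values.mean()) < 1e-9
    assert abs(std.values.std(ddof=1) - 1.0) < 1e-9
    # value equal to the column mean maps to zero
    assert std.values[1, 0] == 0.0


def test_standardize_params_reapply_bit_identical():
    rng = np.random.default_rng(0)
    t = make_traits(rng.normal(10, 3, size=(20, 4)))
    std, params = morpho.standardize(t)
    again = params.apply(t)
    assert np.array_equal(std.values, again.values)


def test_standardize_flags_zero_sd_character():
    t = make_traits(np.column_stack([np.arange(5.0), np.full(5, 7.0)]),
                    chars=["ok", "flat"])
    std, params = morpho.standardize(t)
    assert params.degenerate == ["flat"]
    assert std.characters == ["ok"]


# ---------------------------------------------------------------------------
# Sturges rule and categorization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n,k", [(1, 1), (2, 2), (16, 5), (100, 8)])
def test_sturges_classes(n, k):
    assert morpho.sturges_classes(n) == k


def test_sturges_rejects_nonpositive():
    with pytest.raises(ValueError):
        morpho.sturges_classes(0)


def test_categorize_hand_example():
    t = make_traits([[0.0], [1.0], [2.0], [3.0]])
    c = morpho.categorize(t, n_classes=3)
    assert list(c.states[:, 0]) == [1, 1, 2, 3]


def test_categorize_constant_column_single_class():
    t = make_traits([[5.0], [5.0], [5.0]])
    c = morpho.categorize(t)
    assert c.n_states[0] == 1
    assert set(c.states[:, 0]) == {1}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=40)
)
def test_categorize_total_single_class_assignment(vals):
    """Every scored value maps to exactly one class in 1..k (no gaps/overlaps)."""
    t = make_traits(np.asarray(vals)[:, None])
    c = morpho.categorize(t)
    k = int(c.n_states[0])
    assert ((c.states[:, 0] >= 1) & (c.states[:, 0] <= k)).all()
    # min goes to class 1, max to class k
    lo, hi = np.argmin(vals), np.argmax(vals)
    assert c.states[lo, 0] == 1
    assert c.states[hi, 0] == k


# ---------------------------------------------------------------------------
# MDI
# ---------------------------------------------------------------------------


def test_mdi_uniform_four_states():
    states = np.array([[1], [2], [3], [4]])
    c = make_categorical(states, ["A"] * 4, n_states=[4])
    res = morpho.mdi(c)
    assert res.per_group["A"] == pytest.approx(0.75)


def test_mdi_monomorphic_zero():
    c = make_categorical(np.array([[2], [2], [2]]), ["A"] * 3, n_states=[3])
    assert morpho.mdi(c).per_group["A"] == 0.0


def test_mdi_group_mean_over_characters():
    # char 1: diversities chosen to hit 0.5; char 2: 0.3 via brute-force counts
    # char1 states: two states at 0.5/0.5 -> 1 - 0.5 = 0.5
    # char2: proportions; pick counts giving sum p^2 = 0.7 is impossible with
    # tiny n, so verify against a direct brute-force count instead
    states = np.array([[1, 1], [1, 1], [2, 1], [2, 2]])
    c = make_categorical(states, ["A"] * 4)
    res = morpho.mdi(c)
    d1 = 1 - (0.5**2 + 0.5**2)
    d2 = 1 - ((3 / 4) ** 2 + (1 / 4) ** 2)
    assert res.per_group["A"] == pytest.approx((d1 + d2) / 2)


def test_mdi_missing_cells_excluded():
    states = np.array([[1], [2], [0], [0]])  # 0 = missing
    c = make_categorical(states, ["A"] * 4, n_states=[2])
    assert morpho.mdi(c).per_group["A"] == pytest.approx(0.5)


def test_mdi_all_missing_group_errors():
    states = np.array([[1], [0]])
    c = make_categorical(states, ["A", "B"], n_states=[2])
    with pytest.raises(ValueError, match="B"):
        morpho.mdi(c)


def test_mdi_bounds_and_uniform_maximum():
    """MDI <= 1 - 1/s, maximized by uniform state frequencies (grid search)."""
    s = 4
    best = -1.0
    for counts in itertools.product(range(1, 6), repeat=s):
        p = np.array(counts) / sum(counts)
        best = max(best, 1.0 - (p**2).sum())
    assert best <= 1 - 1 / s + 1e-12
    uniform = 1.0 - s * (1.0 / s) ** 2
    assert uniform == pytest.approx(1 - 1 / s)
    assert best <= uniform + 1e-12


def test_units_invariance_of_standardize_categorize_mdi():
    rng = np.random.default_rng(8)
    vals = rng.normal(20, 5, size=(30, 2))
    pops = ["A"] * 15 + ["B"] * 15
    t1 = make_traits(vals, pops=pops)
    t2 = make_traits(vals * np.array([2.54, 1000.0]) + np.array([5.0, -3.0]), pops=pops)
    m1 = morpho.mdi(morpho.categorize(morpho.standardize(t1)[0]))
    m2 = morpho.mdi(morpho.categorize(morpho.standardize(t2)[0]))
    assert np.allclose(m1.per_group.values, m2.per_group.values)


def test_mdi_lower_for_narrow_covariance_groups():
    """Groups drawn from a narrower trait covariance have lower median MDI."""
    from morphopop.simulate import simulate_traits
    from conftest import make_design

    diffs = []
    for rep in range(20):
        d = make_design(n_pops=2, n=25, seed=300 + rep)
        d.populations[1].management = "cultivated"
        d.characters = ["c1", "c2", "c3"]
        d.trait_means = {
            ("sp", "wild"): np.array([10.0, 5.0, 2.0]),
            ("sp", "cultivated"): np.array([10.0, 5.0, 2.0]),
        }
        d.trait_cov = {
            ("sp", "wild"): np.diag([4.0, 4.0, 4.0]),         # wide
            ("sp", "cultivated"): np.diag([0.25, 0.25, 0.25]),  # narrow
        }
        t = simulate_traits(d)
        std, _ = morpho.standardize(t)
        res = morpho.mdi(morpho.categorize(std))
        diffs.append(res.per_group["P2"] - res.per_group["P1"])
    assert np.median(diffs) < 0


# ---------------------------------------------------------------------------
# PDI
# ---------------------------------------------------------------------------


def test_pdi_identical_profiles_zero():
    states = np.array([[1], [2], [1], [2]])
    c = make_categorical(states, ["A", "A", "B", "B"], n_states=[2])
    assert morpho.pdi(c)[("A", "B")] == pytest.approx(0.0, abs=1e-12)


def test_pdi_hand_computed_nei():
    # group A freqs (0.5, 0.5), group B (1, 0):
    # Jxy = 0.5, Jx = 0.5, Jy = 1 -> D = -ln(0.5/sqrt(0.5)) = 0.346574
    states = np.array([[1], [2], [1], [1]])
    c = make_categorical(states, ["A", "A", "B", "B"], n_states=[2])
    expected = -math.log(0.5 / math.sqrt(0.5))
    assert morpho.pdi(c)[("A", "B")] == pytest.approx(expected, abs=1e-9)


def test_pdi_no_shared_state_infinite_flagged():
    states = np.array([[1], [1], [2], [2]])
    c = make_categorical(states, ["A", "A", "B", "B"], n_states=[2])
    d = morpho.pdi(c)
    assert d.infinite_pairs() == [("A", "B")]


def test_pdi_invariant_to_state_relabeling():
    rng = np.random.default_rng(3)
    states = rng.integers(1, 4, size=(40, 3))
    pops = ["A"] * 20 + ["B"] * 20
    c1 = make_categorical(states, pops, n_states=[3, 3, 3])
    perm = np.array([0, 3, 1, 2])  # relabel 1->3, 2->1, 3->2
    c2 = make_categorical(perm[states], pops, n_states=[3, 3, 3])
    assert morpho.pdi(c1)[("A", "B")] == pytest.approx(
        morpho.pdi(c2)[("A", "B")], abs=1e-12
    )


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def test_kw_identical_groups_h_zero():
    t = make_traits([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]],
                    pops=["A"] * 3 + ["B"] * 3)
    res = morpho.kruskal_wallis(t)
    assert res.table["H"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_kw_brute_force_oracle():
    # groups [1,2,3] vs [10,11,12]: ranks 1..6, no ties
    # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 = 3.857142...
    t = make_traits([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]],
                    pops=["A"] * 3 + ["B"] * 3)
    res = morpho.kruskal_wallis(t)
    ranks = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    N = 6
    H = 12.0 / (N * (N + 1)) * (
        3 * (ranks[:3].mean() - (N + 1) / 2) ** 2
        + 3 * (ranks[3:].mean() - (N + 1) / 2) ** 2
    )
    assert res.table["H"].iloc[0] == pytest.approx(H, abs=1e-9)


@pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: -1.0 / (1 + np.exp(-x))])
def test_kw_invariant_under_monotone_transform(transform):
    rng = np.random.default_rng(1)
    base = rng.normal(size=(24, 1))
    pops = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
    h1 = morpho.kruskal_wallis(make_traits(base, pops=pops)).table["H"].iloc[0]
    h2 = morpho.kruskal_wallis(make_traits(transform(base), pops=pops)).table["H"].iloc[0]
    assert h1 == pytest.approx(h2, abs=1e-9)


def test_kw_letters_consistency():
    """Groups sharing no letter must be significantly different."""
    rng = np.random.default_rng(4)
    vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(0.2, 1, 15),
                           rng.normal(8, 1, 15)])
    pops = ["A"] * 15 + ["B"] * 15 + ["C"] * 15
    res = morpho.kruskal_wallis(make_traits(vals[:, None], pops=pops))
    letters = res.letters["ch0"]
    pmat = res.pairwise_p["ch0"]
    for g1, g2 in itertools.combinations(letters, 2):
        if not set(letters[g1]) & set(letters[g2]):
            assert pmat.loc[g1, g2] <= res.alpha


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


def test_lda_identical_means_wilks_near_one():
    rng = np.random.default_rng(6)
    vals = rng.normal(0, 1, size=(60, 3))
    pops = ["A"] * 30 + ["B"] * 30
    res = morpho.lda(make_traits(vals, pops=pops))
    assert res.wilks_lambda > 0.8


def test_lda_eigenvalues_match_dense_oracle():
    rng = np.random.default_rng(7)
    centers = np.array([[0, 0, 0], [3, 1, -1], [-2, 2, 1]], dtype=float)
    vals = np.concatenate([rng.normal(c, 1.0, size=(20, 3)) for c in centers])
    pops = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
    t = make_traits(vals, pops=pops)
    res = morpho.lda(t)
    # independent oracle: eigenvalues of Sw^-1 Sb via dense solver
    X = vals
    grand = X.mean(axis=0)
    Sw = np.zeros((3, 3))
    Sb = np.zeros((3, 3))
    for gname in ("A", "B", "C"):
        sel = X[np.asarray(pops) == gname]
        mu = sel.mean(axis=0)
        Sw += (sel - mu).T @ (sel - mu)
        Sb += len(sel) * np.outer(mu - grand, mu - grand)
    ref = np.sort(np.real(linalg.eigvals(np.linalg.inv(Sw) @ Sb)))[::-1][:2]
    np.testing.assert_allclose(res.eigenvalues, ref, atol=1e-8)


def test_lda_confusion_rows_sum_to_class_sizes():
    rng = np.random.default_rng(9)
    vals = np.concatenate([rng.normal(0, 1, (12, 2)), rng.normal(4, 1, (18, 2))])
    pops = ["A"] * 12 + ["B"] * 18
    res = morpho.lda(make_traits(vals, pops=pops))
    assert res.confusion.sum(axis=1).tolist() == [12, 18]
    assert res.explained.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# trait_cluster
# ---------------------------------------------------------------------------


def test_trait_cluster_two_groups_half_distance():
    t = make_traits([[0.0], [0.0], [4.0], [4.0]], pops=["A", "A", "B", "B"])
    tree = morpho.trait_cluster(t)
    tips = {x.name: x for x in tree.tips()}
    assert tips["A"].length == pytest.approx(2.0)
    assert tips["B"].length == pytest.approx(2.0)


def test_trait_cluster_duplicate_group_zero_join():
    t = make_traits([[0.0], [0.0], [9.0]], pops=["A", "A2", "B"])
    tree = morpho.trait_cluster(t)
    join = tree.lca(["A", "A2"])
    tip = [x for x in join.tips() if x.name == "A"][0]
    assert tip.length == pytest.approx(0.0)
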