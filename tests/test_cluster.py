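"""UPGMA, bootstrap supports, admixture sampler, Evanno, label alignment,
and AMOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from morphopop import cluster, popgen
from morphopop.datamodel import DistanceMatrix, GenotypeMatrix
from morphopop.simulate import simulate_genotypes
from conftest import make_design


def dm(labels, mat):
    return DistanceMatrix(list(labels), np.asarray(mat, dtype=float))


def cophenetic(tree, labels):
    """Leaf-to-leaf distances implied by the ultrametric tree (2x MRCA height)."""
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            node = tree.lca([labels[i], labels[j]])
            # MRCA height = distance from the node down to any tip
            h = node.distance(next(iter(node.tips())))
            out[i, j] = out[j, i] = 2 * h
    return out


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def test_upgma_two_leaves():
    tree = cluster.upgma(dm("AB", [[0, 4], [4, 0]]))
    for tip in tree.tips():
        assert tip.length == pytest.approx(2.0)


def test_upgma_hand_agglomeration():
    tree = cluster.upgma(dm("ABC", [[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
    ab = tree.lca(["A", "B"])
    assert next(iter(ab.tips())).length == pytest.approx(1.0)
    # root height 4: C branch length = 4
    c = [t for t in tree.tips() if t.name == "C"][0]
    assert c.length == pytest.approx(4.0)


def test_upgma_ultrametric_on_random_matrices():
    rng = np.random.default_rng(2)
    for n in (4, 6, 9):
        m = rng.random((n, n)) + 0.1
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(n)]
        tree = cluster.upgma(dm(labels, m))
        depths = [tree.distance(tip) for tip in tree.tips()]
        assert max(depths) - min(depths) < 1e-9


@pytest.mark.parametrize("n", [4, 5, 6])
def test_upgma_matches_scipy_average_linkage(n):
    """Cophenetic distances equal scipy's average-linkage cophenet (oracle)."""
    rng = np.random.default_rng(n)
    for _ in range(10):
        m = rng.random((n, n)) + 0.05
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(n)]
        tree = cluster.upgma(dm(labels, m))
        ours = cophenetic(tree, labels)
        Z = hierarchy.average(squareform(m, checks=False))
        ref = squareform(hierarchy.cophenet(Z))
        np.testing.assert_allclose(ours, ref, atol=1e-9)


def test_upgma_deterministic_tie_break():
    m = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
    t1 = cluster.upgma(dm("ABC", m))
    t2 = cluster.upgma(dm("CBA", np.asarray(m)))
    assert {x.name for x in t1.lca(["A", "B"]).tips()} == \
        {x.name for x in t2.lca(["A", "B"]).tips()}


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def nei_dist(g):
    return popgen.nei_distance(popgen.allele_frequencies(g))


def test_bootstrap_identical_loci_full_support():
    d = make_design(n_pops=4, n=15, F=0.3, n_loci=1, seed=51)
    g = simulate_genotypes(d)
    g5 = GenotypeMatrix(
        list(g.individual_ids), list(g.population_ids),
        [f"L{j}" for j in range(5)], np.repeat(g.alleles, 5, axis=1),
    )
    tree = cluster.bootstrap_tree(g5, nei_dist, n_boot=50, seed=3)
    supports = [n.support for n in tree.non_tips() if getattr(n, "support", None) is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_zero_reps_plain_tree():
    d = make_design(n_pops=3, n=10, F=0.3, n_loci=5, seed=52)
    g = simulate_genotypes(d)
    tree = cluster.bootstrap_tree(g, nei_dist, n_boot=0)
    assert all(getattr(n, "support", None) is None for n in tree.non_tips())


# ---------------------------------------------------------------------------
# admixture MCMC
# ---------------------------------------------------------------------------


def test_admixture_k1_trivial():
    d = make_design(n_pops=2, n=8, F=0.2, n_loci=4, seed=53)
    g = simulate_genotypes(d)
    res = cluster.admixture_mcmc(g, K=1, burn_in=20, n_iter=50, seed=1)
    assert np.allclose(res.Q.values, 1.0)
    assert np.isfinite(res.ln_prob)


def test_admixture_rows_sum_to_one_and_deterministic():
    d = make_design(n_pops=2, n=10, F=0.3, n_loci=6, seed=54)
    g = simulate_genotypes(d)
    r1 = cluster.admixture_mcmc(g, K=2, burn_in=50, n_iter=150, seed=5)
    r2 = cluster.admixture_mcmc(g, K=2, burn_in=50, n_iter=150, seed=5)
    assert np.allclose(r1.Q.values.sum(axis=1), 1.0, atol=1e-9)
    assert np.array_equal(r1.Q.values, r2.Q.values)
    assert r1.ln_prob == r2.ln_prob


def test_admixture_recovers_two_clusters():
    d = make_design(n_pops=2, n=20, F=0.3, n_loci=10, seed=55)
    g = simulate_genotypes(d)
    res = cluster.admixture_mcmc(g, K=2, burn_in=200, n_iter=600, seed=2,
                                 freq_model="correlated")
    q = res.Q.values
    members = np.array([0] * 20 + [1] * 20)
    # majority cluster of each population should be distinct and strong
    m0 = q[members == 0].mean(axis=0)
    m1 = q[members == 1].mean(axis=0)
    assert m0.argmax() != m1.argmax()
    assert q.max(axis=1).mean() > 0.9


def test_admixture_k_zero_rejected():
    d = make_design(n_pops=2, n=5, seed=56)
    g = simulate_genotypes(d)
    with pytest.raises(ValueError):
        cluster.admixture_mcmc(g, K=0)


def test_admixture_order_equivariance_after_alignment():
    """Reversing individual order yields the same memberships (up to label
    permutation and Monte-Carlo tolerance)."""
    d = make_design(n_pops=2, n=15, F=0.35, n_loci=10, seed=57)
    g = simulate_genotypes(d)
    perm = list(range(g.n_individuals))[::-1]
    g2 = GenotypeMatrix(
        [g.individual_ids[i] for i in perm],
        [g.population_ids[i] for i in perm],
        list(g.loci),
        g.alleles[perm],
    )
    r1 = cluster.admixture_mcmc(g, K=2, burn_in=200, n_iter=600, seed=3)
    r2 = cluster.admixture_mcmc(g2, K=2, burn_in=200, n_iter=600, seed=4)
    q2 = r2.Q.loc[r1.Q.index]  # re-sort rows to original order
    r2b = cluster.ClusterRunResult(
        K=2, Q=q2, ln_prob=r2.ln_prob, lnl_trace=r2.lnl_trace,
        cluster_freqs=r2.cluster_freqs, seed=r2.seed,
        burn_in=r2.burn_in, n_iter=r2.n_iter)
    aligned, _ = cluster.align_labels([r1, r2b])
    assert np.abs(aligned[0].values - aligned[1].values).max() < 0.15


# ---------------------------------------------------------------------------
# Evanno
# ---------------------------------------------------------------------------


def fake_run(K, lnp):
    return cluster.ClusterRunResult(
        K=K, Q=pd.DataFrame(np.ones((2, K)) / K), ln_prob=lnp,
        lnl_trace=np.array([lnp]), cluster_freqs=[], seed=0,
        burn_in=0, n_iter=0)


def test_evanno_direct_arithmetic():
    means = {1: -100.0, 2: -50.0, 3: -48.0, 4: -47.0}
    runs = []
    for k, m in means.items():
        runs += [fake_run(k, m - 0.5 * np.sqrt(2)), fake_run(k, m + 0.5 * np.sqrt(2))]
    # each K has two runs at mean +- sqrt(2)/2 -> sd = 1 exactly
    ev = cluster.evanno(runs)
    assert ev.loc[2, "delta_k"] == pytest.approx(48.0)
    assert ev.attrs["best_k_delta"] == 2


def test_evanno_linear_lnp_zero_delta():
    runs = []
    for k in range(1, 5):
        runs += [fake_run(k, -10.0 * k - 0.1), fake_run(k, -10.0 * k + 0.1)]
    ev = cluster.evanno(runs)
    assert ev["delta_k"].dropna().max() == pytest.approx(0.0, abs=1e-9)


def test_evanno_zero_sd_flagged_nan():
    runs = []
    for k in (1, 2, 3):
        runs += [fake_run(k, -10.0 * k), fake_run(k, -10.0 * k)]
    ev = cluster.evanno(runs)
    assert np.isnan(ev.loc[2, "delta_k"])


def test_evanno_requires_consecutive_ks():
    runs = [fake_run(1, -1), fake_run(1, -2), fake_run(3, -1), fake_run(3, -2)]
    with pytest.raises(ValueError):
        cluster.evanno(runs)


# ---------------------------------------------------------------------------
# label alignment
# ---------------------------------------------------------------------------


def test_align_recovers_column_swap():
    rng = np.random.default_rng(10)
    q = rng.dirichlet(np.ones(3), size=12)
    ids = [f"i{k}" for k in range(12)]
    r1 = cluster.ClusterRunResult(3, pd.DataFrame(q, index=ids), -1.0,
                                  np.array([-1.0]), [], 0, 0, 0)
    swap = [2, 0, 1]
    r2 = cluster.ClusterRunResult(3, pd.DataFrame(q[:, swap], index=ids), -1.0,
                                  np.array([-1.0]), [], 0, 0, 0)
    aligned, perms = cluster.align_labels([r1, r2])
    np.testing.assert_allclose(aligned[1].values, q)
    # self-alignment is the identity
    aligned_self, perms_self = cluster.align_labels([r1, r1])
    assert perms_self[1] == (0, 1, 2)


def test_align_greedy_equals_exhaustive_k3():
    rng = np.random.default_rng(11)
    for _ in range(20):
        q1 = rng.dirichlet(np.ones(3), size=15)
        q2 = rng.dirichlet(np.ones(3), size=15)
        ids = [f"i{k}" for k in range(15)]
        r1 = cluster.ClusterRunResult(3, pd.DataFrame(q1, index=ids), -1.0,
                                      np.array([-1.0]), [], 0, 0, 0)
        r2 = cluster.ClusterRunResult(3, pd.DataFrame(q2, index=ids), -1.0,
                                      np.array([-1.0]), [], 0, 0, 0)
        _, p_ex = cluster.align_labels([r1, r2], exhaustive_max_k=8)
        _, p_gr = cluster.align_labels([r1, r2], exhaustive_max_k=0)
        # greedy should match the exhaustive optimum on easy random instances
        sim = cluster._column_similarity(q1, q2)
        score_ex = sum(sim[k, p_ex[1][k]] for k in range(3))
        score_gr = sum(sim[k, p_gr[1][k]] for k in range(3))
        assert score_gr <= score_ex + 1e-12


def test_align_mismatched_k_rejected():
    r1 = fake_run(2, -1.0)
    r2 = fake_run(3, -1.0)
    with pytest.raises(ValueError):
        cluster.align_labels([r1, r2])


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def test_amova_maximal_case():
    g = GenotypeMatrix(
        [f"i{k}" for k in range(8)],
        ["A"] * 4 + ["B"] * 4,
        ["L1"],
        np.array([[[100, 100]]] * 4 + [[[104, 104]]] * 4),
    )
    res = cluster.amova(g, n_perm=0)
    assert res.phi_st == pytest.approx(1.0)
    assert res.table.loc["among_populations", "percent_of_variation"] == pytest.approx(100.0)


def brute_force_two_level(x, pops):
    """Independent expected-mean-squares computation for one locus."""
    x = np.asarray(x, dtype=float)
    pops = np.asarray(pops)
    N = len(x)
    labels = sorted(set(pops))
    P = len(labels)
    grand = x.mean()
    ssw = sum(((x[pops == p] - x[pops == p].mean()) ** 2).sum() for p in labels)
    ssa = sum(len(x[pops == p]) * (x[pops == p].mean() - grand) ** 2 for p in labels)
    ms_w = ssw / (N - P)
    ms_a = ssa / (P - 1)
    n_p = np.array([np.sum(pops == p) for p in labels], dtype=float)
    nc = (N - (n_p**2).sum() / N) / (P - 1)
    sigma_a = (ms_a - ms_w) / nc
    return sigma_a, ms_w


def test_amova_brute_force_oracle():
    rng = np.random.default_rng(12)
    sizes = rng.integers(98, 112, size=(6, 1, 2)) * 2
    g = GenotypeMatrix([f"i{k}" for k in range(6)],
                       ["A", "A", "B", "B", "B", "C"], ["L1"], sizes)
    res = cluster.amova(g, n_perm=0)
    copies = sizes.reshape(6, 2)
    x = copies.ravel().astype(float)
    pops = np.repeat(["A", "A", "B", "B", "B", "C"], 2)
    sigma_a, sigma_w = brute_force_two_level(x, pops)
    assert res.table.loc["among_populations", "variance_component"] == pytest.approx(sigma_a, abs=1e-9)
    assert res.table.loc["within_populations", "variance_component"] == pytest.approx(sigma_w, abs=1e-9)


def test_amova_percentages_sum_and_components_sum():
    d = make_design(n_pops=6, n=12, F=0.25, n_loci=5, seed=61)
    g = simulate_genotypes(d)
    groups = {f"P{i + 1}": ("G1" if i < 3 else "G2") for i in range(6)}
    res = cluster.amova(g, groups=groups, n_perm=0)
    assert res.table.loc["total", "percent_of_variation"] == pytest.approx(100.0, abs=0.05)
    comps = res.table["variance_component"]
    assert comps.iloc[:-1].sum() == pytest.approx(comps.loc["total"], abs=1e-12)


def test_amova_shift_invariance():
    d = make_design(n_pops=4, n=10, F=0.3, n_loci=3, seed=62)
    g = simulate_genotypes(d)
    res1 = cluster.amova(g, n_perm=0)
    g2 = GenotypeMatrix(
        list(g.individual_ids), list(g.population_ids), list(g.loci),
        np.where(g.alleles > 0, g.alleles + 50, g.alleles),
    )
    res2 = cluster.amova(g2, n_perm=0)
    assert res1.phi_st == pytest.approx(res2.phi_st, abs=1e-12)


def test_amova_permutation_detects_structure():
    d = make_design(n_pops=4, n=15, F=0.3, n_loci=8, seed=63)
    g = simulate_genotypes(d)
    res = cluster.amova(g, n_perm=99, seed=1)
    assert res.p_values["phi_st"] <= 0.05


def test_percentages_from_components():
    pct = cluster.percentages_from_components([1.0, 1.0, 2.0])
    np.testing.assert_allclose(pct, [25.0, 25.0, 50.0])
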