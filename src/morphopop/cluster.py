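"""Distance-based and Bayesian clustering, and hierarchical AMOVA.

* :func:`upgma` — deterministic average-linkage agglomeration with
  cluster-size weighting and lexicographic tie-breaking, returning an
  ultrametric :class:`skbio.TreeNode`.
* :func:`bootstrap_tree` — resamples loci (or characters) with
  replacement, recomputes the distance + UPGMA tree, and reports the
  fraction of replicates containing each original bipartition.
* :func:`admixture_mcmc` — Gibbs sampler for the admixture model: each
  individual's genome is a mixture over K clusters with Dirichlet(alpha)
  proportions Q, cluster allele frequencies get conjugate Dirichlet
  updates (optionally an F-model prior around empirical frequencies),
  and alpha moves by random-walk Metropolis.
* :func:`evanno` — the second-difference Delta-K statistic over runs.
* :func:`align_labels` — CLUMPP-style column permutation matching.
* :func:`amova` — two- or three-level analysis of molecular variance at
  the gene-copy level with squared allele-size differences (the stepwise
  mutation model distance, giving R_ST-type statistics), with permutation
  significance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import TreeNode

from .datamodel import MISSING, CategoricalMatrix, DistanceMatrix, GenotypeMatrix

__all__ = [
    "upgma",
    "bootstrap_tree",
    "admixture_mcmc",
    "ClusterRunResult",
    "evanno",
    "align_labels",
    "amova",
    "AmovaResult",
    "percentages_from_components",
]


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (cluster-size weighted) agglomeration.

    Deterministic: equal-distance candidate pairs are broken by the
    lexicographically smallest (leaf-label) pair.  The returned tree is
    ultrametric; node heights are half the merge distances.
    """
    if not np.isfinite(d.values).all():
        raise ValueError("upgma requires finite distances")
    if (d.values < 0).any():
        raise ValueError("upgma requires non-negative distances")
    n = len(d.labels)
    if n < 2:
        raise ValueError("upgma needs >= 2 leaves")
    # active clusters: key -> (node, size, height, sort_key)
    active: dict[int, tuple[TreeNode, int, float, str]] = {}
    for i, label in enumerate(d.labels):
        active[i] = (TreeNode(name=label), 1, 0.0, label)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), val in dist.items():
            if i not in active or j not in active:
                continue
            ki = min(active[i][3], active[j][3])
            kj = max(active[i][3], active[j][3])
            cand = (val, ki, kj, i, j)
            if best is None or cand < best:
                best = cand
        val, _, _, i, j = best
        node_i, size_i, h_i, key_i = active[i]
        node_j, size_j, h_j, key_j = active[j]
        height = val / 2.0
        node_i.length = height - h_i
        node_j.length = height - h_j
        parent = TreeNode(children=[node_i, node_j])
        new_key = min(key_i, key_j)
        # weighted average distances to the merged cluster
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (
                size_i * dik + size_j * djk
            ) / (size_i + size_j)
        del active[i], active[j]
        active[next_id] = (parent, size_i + size_j, height, new_key)
        next_id += 1
    root = next(iter(active.values()))[0]
    root.length = None
    return root


def _clades(tree: TreeNode) -> set[frozenset]:
    """Leaf-name sets of internal nodes (excluding root and trivial clades)."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(all_tips):
            out.add(clade)
    return out


def bootstrap_tree(
    data,
    distance,
    n_boot: int = 1000,
    seed: int | None = None,
) -> TreeNode:
    """UPGMA tree with bootstrap supports from resampling loci/characters.

    ``data`` is a :class:`GenotypeMatrix` (resampled over loci) or
    :class:`CategoricalMatrix` (over characters); ``distance`` maps such a
    matrix to a :class:`DistanceMatrix`.  Supports are percentages of
    replicates whose UPGMA tree contains each original internal clade,
    stored as ``node.support``.  ``n_boot=0`` returns the plain tree.
    """
    tree = upgma(distance(data))
    if n_boot == 0:
        return tree
    if isinstance(data, GenotypeMatrix):
        n_cols = data.n_loci
        take = data.subset_loci
    elif isinstance(data, CategoricalMatrix):
        n_cols = len(data.characters)

        def take(idx):
            idx = list(idx)
            return CategoricalMatrix(
                individual_ids=list(data.individual_ids),
                population_ids=list(data.population_ids),
                characters=[f"{data.characters[i]}__{k}" for k, i in enumerate(idx)],
                states=data.states[:, idx].copy(),
                n_states=data.n_states[idx].copy(),
                bin_edges=[data.bin_edges[i] for i in idx] if data.bin_edges else [],
            )
    else:
        raise TypeError(f"unsupported data type {type(data)!r}")
    if n_cols < 2:
        raise ValueError("bootstrap needs >= 2 loci/characters")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {clade: 0 for clade in _clades(tree)}
    for _ in range(n_boot):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_tree = upgma(distance(take(idx)))
        rep_clades = _clades(rep_tree)
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if clade in counts:
            node.support = 100.0 * counts[clade] / n_boot
    return tree


# ---------------------------------------------------------------------------
# Admixture-model Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class ClusterRunResult:
    """One MCMC run at a fixed K."""

    K: int
    Q: pd.DataFrame                      # posterior-mean membership, rows sum to 1
    ln_prob: float                       # LnP(K): mean - var/2 of loglik trace
    lnl_trace: np.ndarray
    cluster_freqs: list[np.ndarray]      # per locus (K, n_alleles) posterior means
    seed: int | None
    burn_in: int
    n_iter: int
    freq_model: str = "independent"
    alpha_trace: np.ndarray | None = None


def _encode(x) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    """Integer-recode data as (n, L, ploidy) allele indices, -1 = missing."""
    if isinstance(x, GenotypeMatrix):
        n, L = x.n_individuals, x.n_loci
        codes = np.full((n, L, 2), -1, dtype=np.int64)
        allele_lists = []
        for l in range(L):
            vals = np.unique(x.alleles[:, l, :][x.alleles[:, l, :] != MISSING])
            lookup = {int(v): k for k, v in enumerate(vals)}
            allele_lists.append(vals)
            for c in (0, 1):
                col = x.alleles[:, l, c]
                codes[:, l, c] = [lookup.get(int(v), -1) for v in col]
        return codes, allele_lists, list(x.individual_ids)
    if isinstance(x, CategoricalMatrix):
        n, L = len(x.individual_ids), len(x.characters)
        codes = np.full((n, L, 1), -1, dtype=np.int64)
        allele_lists = []
        for l in range(L):
            allele_lists.append(np.arange(1, int(x.n_states[l]) + 1))
            col = x.states[:, l]
            codes[:, l, 0] = np.where(col > 0, col - 1, -1)
        return codes, allele_lists, list(x.individual_ids)
    raise TypeError(f"unsupported data type {type(x)!r}")


def _sample_categorical(rng, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw from an (m, K) unnormalized probability array."""
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return (u[:, None] >= cum).sum(axis=1)


def admixture_mcmc(
    x,
    K: int,
    burn_in: int = 5000,
    n_iter: int = 50_000,
    seed: int | None = None,
    freq_model: str = "independent",
    F_prior: float = 0.05,
    alpha_init: float = 1.0,
    alpha_max: float = 10.0,
    thin: int = 1,
) -> ClusterRunResult:
    """Gibbs sampler for the admixture model at fixed K.

    Data are diploid genotypes (two copies per locus) or a haploid
    categorical-morphology matrix (each character one state per
    individual).  ``freq_model='correlated'`` uses the F-model Dirichlet
    prior around empirical overall frequencies (fixed strength
    ``F_prior``); ``'independent'`` uses a flat Dirichlet(1) prior.
    LnP(K) is the standard estimate mean(L) - var(L)/2 of the per-sweep
    log-likelihood.  Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if freq_model not in ("independent", "correlated"):
        raise ValueError(f"unknown freq_model {freq_model!r}")
    codes, allele_lists, ids = _encode(x)
    n, L, ploidy = codes.shape
    rng = np.random.default_rng(seed)

    # per-locus prior on cluster frequencies
    priors = []
    for l in range(L):
        J = len(allele_lists[l])
        obs = codes[:, l, :].ravel()
        obs = obs[obs >= 0]
        emp = (np.bincount(obs, minlength=J) + 0.5) / (len(obs) + 0.5 * J)
        if freq_model == "correlated":
            priors.append(emp * (1.0 - F_prior) / F_prior)
        else:
            priors.append(np.ones(J))

    P = [
        np.stack([rng.dirichlet(priors[l]) for _ in range(K)]) for l in range(L)
    ]  # per locus (K, J)
    Q = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
    Z = [np.zeros((n, ploidy), dtype=np.int64) for _ in range(L)]
    alpha = alpha_init

    present = [codes[:, l, :] >= 0 for l in range(L)]  # (n, ploidy) masks

    total = burn_in + n_iter
    q_sum = np.zeros((n, K))
    p_sum = [np.zeros_like(P[l]) for l in range(L)]
    lnl_kept = []
    alpha_kept = []
    n_kept = 0
    log_q_sum_const = 0.0  # updated each sweep for the alpha move

    for sweep in range(total):
        # --- Z | Q, P and allele counts for P update
        counts_q = np.zeros((n, K))
        loglik = 0.0
        for l in range(L):
            mask = present[l]
            idx_i, idx_c = np.nonzero(mask)
            a = codes[idx_i, l, idx_c]
            probs = Q[idx_i] * P[l][:, a].T  # (m, K)
            loglik += float(np.log(probs.sum(axis=1) + 1e-300).sum())
            if K > 1:
                z = _sample_categorical(rng, probs)
            else:
                z = np.zeros(len(a), dtype=np.int64)
            Z[l][idx_i, idx_c] = z
            np.add.at(counts_q, (idx_i, z), 1.0)
            # P update counts
            J = P[l].shape[1]
            cnt = np.zeros((K, J))
            np.add.at(cnt, (z, a), 1.0)
            gam = rng.gamma(priors[l][None, :] + cnt)
            P[l] = gam / gam.sum(axis=1, keepdims=True)
        # --- Q | Z
        if K > 1:
            gam = rng.gamma(alpha + counts_q)
            Q = gam / gam.sum(axis=1, keepdims=True)
            Q = np.clip(Q, 1e-12, None)
            Q /= Q.sum(axis=1, keepdims=True)
            # --- alpha | Q (random-walk Metropolis, uniform prior (0, alpha_max))
            prop = alpha + rng.normal(0.0, 0.25)
            if 0.0 < prop < alpha_max:
                slq = float(np.log(Q).sum())
                def _logp(a_):
                    return n * (gammaln(K * a_) - K * gammaln(a_)) + (a_ - 1.0) * slq
                if math.log(rng.random() + 1e-300) < _logp(prop) - _logp(alpha):
                    alpha = prop
        else:
            Q = np.ones((n, 1))
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            q_sum += Q
            for l in range(L):
                p_sum[l] += P[l]
            lnl_kept.append(loglik)
            alpha_kept.append(alpha)
            n_kept += 1

    q_mean = q_sum / n_kept
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    lnl = np.asarray(lnl_kept)
    ln_prob = float(lnl.mean() - lnl.var() / 2.0)
    return ClusterRunResult(
        K=K,
        Q=pd.DataFrame(q_mean, index=ids, columns=[f"C{k + 1}" for k in range(K)]),
        ln_prob=ln_prob,
        lnl_trace=lnl,
        cluster_freqs=[p_sum[l] / n_kept for l in range(L)],
        seed=seed,
        burn_in=burn_in,
        n_iter=n_iter,
        freq_model=freq_model,
        alpha_trace=np.asarray(alpha_kept),
    )


# ---------------------------------------------------------------------------
# Evanno Delta-K
# ---------------------------------------------------------------------------


def evanno(runs: list[ClusterRunResult]) -> pd.DataFrame:
    """Evanno table: Delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / SD(LnP(K)).

    Needs >= 3 consecutive K values with >= 2 runs each.  Delta-K at a K
    where the run SD is zero is NaN (flagged, not infinite).  The result
    also carries ``best_k_lnp`` (argmax of mean LnP) and
    ``best_k_delta`` (argmax of Delta-K) in ``DataFrame.attrs``.
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.ln_prob)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("evanno needs >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("evanno needs >= 2 runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lprime = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lsec = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = lsec / sd[k] if sd[k] > 0 else np.nan
        else:
            lsec, dk = np.nan, np.nan
        rows.append(
            {"K": k, "n_runs": len(by_k[k]), "mean_lnp": mean[k], "sd_lnp": sd[k],
             "lprime": lprime, "lsecond_abs": lsec, "delta_k": dk}
        )
    out = pd.DataFrame(rows).set_index("K")
    out.attrs["best_k_lnp"] = int(max(ks, key=lambda k: mean[k]))
    valid = out["delta_k"].dropna()
    out.attrs["best_k_delta"] = int(valid.idxmax()) if len(valid) else None
    return out


# ---------------------------------------------------------------------------
# Label alignment (CLUMPP-style)
# ---------------------------------------------------------------------------


def _column_similarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of columns (0 where degenerate)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    sim = a.T @ b
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, sim / denom, 0.0)
    return sim


def align_labels(
    runs: list[ClusterRunResult], exhaustive_max_k: int = 8
) -> tuple[list[pd.DataFrame], list[tuple[int, ...]]]:
    """Permute cluster columns of each run to best match the first run.

    Maximizes the summed column correlation; exhaustive over permutations
    for K <= ``exhaustive_max_k``, greedy (best unused column per
    reference column) above.  Returns aligned Q matrices and the applied
    permutations (perm[k] = source column of aligned column k).
    """
    if not runs:
        return [], []
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must share K")
    ref = runs[0].Q.values
    aligned, perms = [runs[0].Q.copy()], [tuple(range(K))]
    for run in runs[1:]:
        if list(run.Q.index) != list(runs[0].Q.index):
            raise ValueError("runs must cover the same individuals")
        sim = _column_similarity(ref, run.Q.values)
        if K <= exhaustive_max_k:
            best, best_score = None, -np.inf
            for perm in itertools.permutations(range(K)):
                score = sum(sim[k, perm[k]] for k in range(K))
                if score > best_score:
                    best, best_score = perm, score
        else:
            used, best = set(), []
            for k in range(K):
                order = np.argsort(sim[k])[::-1]
                pick = next(int(j) for j in order if j not in used)
                used.add(pick)
                best.append(pick)
            best = tuple(best)
        q = run.Q.values[:, list(best)]
        aligned.append(
            pd.DataFrame(q, index=run.Q.index, columns=runs[0].Q.columns)
        )
        perms.append(best)
    return aligned, perms


# ---------------------------------------------------------------------------
# AMOVA (stepwise mutation model / R_ST)
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition with permutation significance."""

    table: pd.DataFrame          # level x (df, SS, variance, percent)
    phi_st: float                # (among components) / total
    phi_ct: float | None         # among groups / total (three-level only)
    phi_sc: float | None         # among pops / (pops + within)
    p_values: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0
    seed: int | None = None


def percentages_from_components(components) -> np.ndarray:
    """Percentage of variation per level: component / sum(components) * 100."""
    comps = np.asarray(components, dtype=float)
    return comps / comps.sum() * 100.0


def _amova_components(
    values: list[np.ndarray], pop_idx: list[np.ndarray], group_of: np.ndarray | None
):
    """Summed-over-loci variance components at the gene-copy level.

    values[l]: allele sizes of typed copies at locus l; pop_idx[l]: the
    population index of each copy.  group_of maps population index ->
    group index (None = two-level design).  Returns (ss, df, components)
    arrays ordered top level first.
    """
    n_levels = 2 if group_of is None else 3
    ss = np.zeros(n_levels)
    df = np.zeros(n_levels)
    comps = np.zeros(n_levels)
    for x, pidx in zip(values, pop_idx):
        N = len(x)
        pops, inv = np.unique(pidx, return_inverse=True)
        P = len(pops)
        if N == 0 or P < 2:
            continue
        n_p = np.bincount(inv).astype(float)
        sum_p = np.bincount(inv, weights=x)
        mean_p = sum_p / n_p
        grand = x.mean()
        ssw = float(((x - mean_p[inv]) ** 2).sum())
        if group_of is None:
            ssa = float((n_p * (mean_p - grand) ** 2).sum())
            df_a, df_w = P - 1, N - P
            ms_w = ssw / df_w if df_w > 0 else 0.0
            nc = (N - (n_p**2).sum() / N) / (P - 1)
            ms_a = ssa / df_a
            sigma_a = (ms_a - ms_w) / nc if nc > 0 else 0.0
            ss += (ssa, ssw)
            df += (df_a, df_w)
            comps += (sigma_a, ms_w)
        else:
            g_of = group_of[pops]
            groups = np.unique(g_of)
            G = len(groups)
            if G < 2:
                continue
            g_inv = np.searchsorted(groups, g_of)
            N_g = np.bincount(g_inv, weights=n_p)
            sum_g = np.bincount(g_inv, weights=sum_p)
            mean_g = sum_g / N_g
            ss_ap = float((n_p * (mean_p - mean_g[g_inv]) ** 2).sum())
            ss_ag = float((N_g * (mean_g - grand) ** 2).sum())
            df_ag, df_ap, df_w = G - 1, P - G, N - P
            ms_w = ssw / df_w if df_w > 0 else 0.0
            ms_ap = ss_ap / df_ap if df_ap > 0 else 0.0
            ms_ag = ss_ag / df_ag
            sum_np2_over_Ng = float(
                np.bincount(g_inv, weights=n_p**2) @ (1.0 / N_g)
            )
            n1 = (N - sum_np2_over_Ng) / (P - G) if P > G else 0.0
            n2 = (sum_np2_over_Ng - (n_p**2).sum() / N) / (G - 1)
            n3 = (N - (N_g**2).sum() / N) / (G - 1)
            sigma_b = (ms_ap - ms_w) / n1 if n1 > 0 else 0.0
            sigma_a = (ms_ag - ms_w - n2 * sigma_b) / n3 if n3 > 0 else 0.0
            ss += (ss_ag, ss_ap, ssw)
            df += (df_ag, df_ap, df_w)
            comps += (sigma_a, sigma_b, ms_w)
    return ss, df, comps


def amova(
    g: GenotypeMatrix,
    groups: dict[str, str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA under the stepwise mutation model (squared allele-size distances).

    Works at the gene-copy level per locus, summing sums of squares and
    variance components over loci — the R_ST analogue of F-statistics.
    ``groups`` maps population label -> group label for the three-level
    (among groups / among populations within groups / within populations)
    design; None gives the two-level design.  Significance by permuting
    individuals among populations (and, for the group level, populations
    among groups).
    """
    pops = g.populations
    if len(pops) < 2:
        raise ValueError("amova needs >= 2 populations")
    pop_index = {p: i for i, p in enumerate(pops)}
    ind_pop = np.array([pop_index[p] for p in g.population_ids])
    group_of = None
    level_names = ["among_populations", "within_populations"]
    if groups is not None:
        glabels = sorted(set(groups.values()))
        gindex = {x: i for i, x in enumerate(glabels)}
        group_of = np.array([gindex[groups[p]] for p in pops])
        level_names = ["among_groups", "among_populations", "within_populations"]
        counts = np.bincount(group_of, minlength=len(glabels))
        if (counts < 2).any():
            singles = [glabels[i] for i in np.nonzero(counts < 2)[0]]
            level_names[0] = "among_groups(single-population group: flagged)"
            # still computable, but the group component is confounded
            _ = singles

    def extract(ind_pop_vec: np.ndarray):
        values, pidx = [], []
        for l in range(g.n_loci):
            geno = g.alleles[:, l, :]
            typed = geno[:, 0] != MISSING
            x = geno[typed].ravel().astype(float)
            p = np.repeat(ind_pop_vec[typed], 2)
            values.append(x)
            pidx.append(p)
        return values, pidx

    values, pidx = extract(ind_pop)
    ss, df, comps = _amova_components(values, pidx, group_of)
    total = comps.sum()
    if total > 0:
        pct = percentages_from_components(comps)
        phi_st = float(comps[:-1].sum() / total)
    else:  # degenerate data (e.g. all sizes identical)
        pct = np.full_like(comps, np.nan)
        phi_st = np.nan
    phi_ct = phi_sc = None
    if group_of is not None and total > 0:
        phi_ct = float(comps[0] / total)
        denom = comps[1] + comps[2]
        phi_sc = float(comps[1] / denom) if denom > 0 else np.nan

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits_st = 0
        hits_ct = 0
        for _ in range(n_perm):
            perm_pop = ind_pop[rng.permutation(len(ind_pop))]
            v2, p2 = extract(perm_pop)
            _, _, c2 = _amova_components(v2, p2, group_of)
            t2 = c2.sum()
            stat = c2[:-1].sum() / t2 if t2 > 0 else -np.inf
            if stat >= phi_st - 1e-12:
                hits_st += 1
            if group_of is not None:
                perm_groups = group_of[rng.permutation(len(group_of))]
                _, _, c3 = _amova_components(values, pidx, perm_groups)
                t3 = c3.sum()
                stat3 = c3[0] / t3 if t3 > 0 else -np.inf
                if stat3 >= (phi_ct if phi_ct is not None else np.inf) - 1e-12:
                    hits_ct += 1
        p_values["phi_st"] = (1 + hits_st) / (1 + n_perm)
        if group_of is not None:
            p_values["phi_ct"] = (1 + hits_ct) / (1 + n_perm)

    table = pd.DataFrame(
        {
            "df": df,
            "sum_of_squares": ss,
            "variance_component": comps,
            "percent_of_variation": pct,
        },
        index=level_names,
    )
    table.loc["total"] = [df.sum(), ss.sum(), comps.sum(), 100.0]
    return AmovaResult(
        table=table,
        phi_st=phi_st,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        p_values=p_values,
        n_perm=n_perm,
        seed=seed,
    )
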