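"""Phenotype pipeline: standardization, Sturges categorization, diversity
and differentiation indices, rank ANOVA, discriminant analysis and
trait-based clustering.

The Morphological Diversity Index (MDI) is a Simpson-type heterogeneity
index over Sturges-binned character states: per character
1 - sum_i p_i^2 where p_i is the proportion of plants in the group showing
the i-th state, averaged (unweighted) over characters.  The Phenotypic
Differentiation Index (PDI) applies Nei's (1972) standard genetic distance
to the character-state frequency profiles, treating each character as a
locus and each Sturges class as an allele.
"""

from __future__ import annotations

import itertools
import logging
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datamodel import (
    CategoricalMatrix,
    DistanceMatrix,
    StandardizationParams,
    TraitMatrix,
)

log = logging.getLogger(__name__)

__all__ = [
    "standardize",
    "sturges_classes",
    "categorize",
    "mdi",
    "pdi",
    "kruskal_wallis",
    "lda",
    "trait_cluster",
    "select_characters",
]


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize(t: TraitMatrix) -> tuple[TraitMatrix, StandardizationParams]:
    """Z-score each character: Y0 = (Y - a)/b with a the mean, b the SD.

    Characters with zero spread are excluded (flagged on the returned
    params and logged), never silently dropped.  The params can be re-
    applied to new data via :meth:`StandardizationParams.apply`.
    """
    a = np.nanmean(t.values, axis=0)
    b = np.nanstd(t.values, axis=0, ddof=1)
    keep = b > 0
    dropped = [c for c, k in zip(t.characters, keep) if not k]
    if dropped:
        log.warning("standardize: zero-SD characters excluded: %s", dropped)
    params = StandardizationParams(
        characters=[c for c, k in zip(t.characters, keep) if k],
        a=a[keep],
        b=b[keep],
        degenerate=dropped,
    )
    return params.apply(t), params


# ---------------------------------------------------------------------------
# Sturges categorization
# ---------------------------------------------------------------------------


def sturges_classes(n: int) -> int:
    """Sturges' rule: k = ceil(1 + log2(n))."""
    if n < 1:
        raise ValueError("sturges_classes requires n >= 1")
    return math.ceil(1.0 + math.log2(n))


def categorize(
    t: TraitMatrix,
    characters: list[str] | None = None,
    n_classes: int | None = None,
) -> CategoricalMatrix:
    """Bin characters into Sturges classes shared across all populations.

    Per character: k = sturges_classes(number of scored individuals),
    equal-width bins spanning the pooled [min, max]; values on an interior
    edge go to the lower bin, the maximum goes to class k.  Constant
    characters collapse to a single class (s = 1, logged).  Missing cells
    stay missing (state 0).  ``n_classes`` overrides k for every character
    (used in tests and hand-constructed examples).
    """
    chars = list(characters) if characters is not None else list(t.characters)
    idx = [t.characters.index(c) for c in chars]
    n_ind = t.n_individuals
    states = np.zeros((n_ind, len(chars)), dtype=np.int64)
    n_states = np.zeros(len(chars), dtype=np.int64)
    edges_list: list[np.ndarray] = []
    for j, col in enumerate(idx):
        v = t.values[:, col]
        scored = ~np.isnan(v)
        vals = v[scored]
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            log.warning("categorize: constant character %r -> single class", chars[j])
            k = 1
            edges = np.array([lo, hi])
            states[scored, j] = 1
        else:
            k = n_classes if n_classes is not None else sturges_classes(len(vals))
            edges = np.linspace(lo, hi, k + 1)
            # interior edges inclusive on the lower side; max -> class k
            s = np.searchsorted(edges[1:-1], vals, side="left") + 1
            states[scored, j] = s
        n_states[j] = k
        edges_list.append(edges)
    return CategoricalMatrix(
        individual_ids=list(t.individual_ids),
        population_ids=list(t.population_ids),
        characters=chars,
        states=states,
        n_states=n_states,
        bin_edges=edges_list,
    )


# ---------------------------------------------------------------------------
# MDI
# ---------------------------------------------------------------------------


@dataclass
class MDIResult:
    """Per-group MDI with per-character diversities and state counts."""

    per_group: pd.Series                       # group -> MDI
    per_character: pd.DataFrame                # group x character diversity
    sum_p2: pd.DataFrame                       # group x character sum(p_i^2)
    n_individuals: pd.Series                   # group -> n


def _state_frequencies(
    c: CategoricalMatrix, member: np.ndarray, j: int
) -> np.ndarray | None:
    col = c.states[member, j]
    col = col[col > 0]
    if col.size == 0:
        return None
    counts = np.bincount(col, minlength=int(c.n_states[j]) + 1)[1:]
    return counts / counts.sum()


def _resolve_grouping(labels, obj) -> list[str]:
    if isinstance(labels, str):
        if labels == "population":
            return list(obj.population_ids)
        raise ValueError(f"unknown grouping {labels!r}")
    labels = list(labels)
    if len(labels) != len(obj.individual_ids):
        raise ValueError("grouping must give one label per individual")
    return labels


def mdi(c: CategoricalMatrix, grouping="population") -> MDIResult:
    """Morphological Diversity Index per group.

    Per character: 1 - sum_i p_i^2 over state proportions within the
    group (missing cells excluded from the denominators); the group MDI
    is the unweighted mean over characters scored in that group.
    """
    labels = _resolve_grouping(grouping, c)
    groups = list(dict.fromkeys(labels))
    arr = np.asarray(labels)
    div = pd.DataFrame(index=groups, columns=c.characters, dtype=float)
    sp2 = pd.DataFrame(index=groups, columns=c.characters, dtype=float)
    n_ind = {}
    for gname in groups:
        member = arr == gname
        n_ind[gname] = int(member.sum())
        any_scored = False
        for j, ch in enumerate(c.characters):
            p = _state_frequencies(c, member, j)
            if p is None:
                continue
            any_scored = True
            s2 = float((p**2).sum())
            sp2.loc[gname, ch] = s2
            div.loc[gname, ch] = 1.0 - s2
        if not any_scored:
            raise ValueError(f"group {gname!r} has no scored cells")
    return MDIResult(
        per_group=div.mean(axis=1, skipna=True).rename("MDI"),
        per_character=div,
        sum_p2=sp2,
        n_individuals=pd.Series(n_ind, name="n"),
    )


# ---------------------------------------------------------------------------
# PDI
# ---------------------------------------------------------------------------


def pdi(
    c: CategoricalMatrix, grouping="population", unbiased: bool = False
) -> DistanceMatrix:
    """Phenotypic Differentiation Index between groups.

    Nei's standard distance D = -ln(Jxy / sqrt(Jx * Jy)) on character-state
    frequencies, with the J terms summed over characters.  Groups sharing
    no state at any character get an infinite distance (flagged on the
    returned matrix).  ``unbiased`` switches to the Nei 1978 small-sample
    J terms.
    """
    labels = _resolve_grouping(grouping, c)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("pdi needs >= 2 groups")
    arr = np.asarray(labels)
    profiles: dict[str, list[np.ndarray | None]] = {}
    counts: dict[str, list[int]] = {}
    for gname in groups:
        member = arr == gname
        profiles[gname] = [
            _state_frequencies(c, member, j) for j in range(len(c.characters))
        ]
        counts[gname] = [
            int((c.states[member, j] > 0).sum()) for j in range(len(c.characters))
        ]
    n = len(groups)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jx = jy = jxy = 0.0
            for ch in range(len(c.characters)):
                x, y = profiles[groups[i]][ch], profiles[groups[j]][ch]
                if x is None or y is None:
                    continue
                if unbiased:
                    nx = 2 * counts[groups[i]][ch]
                    ny = 2 * counts[groups[j]][ch]
                    jx += (nx * (x**2).sum() - 1) / (nx - 1) if nx > 1 else (x**2).sum()
                    jy += (ny * (y**2).sum() - 1) / (ny - 1) if ny > 1 else (y**2).sum()
                else:
                    jx += (x**2).sum()
                    jy += (y**2).sum()
                jxy += (x * y).sum()
            if jxy <= 0:
                d[i, j] = d[j, i] = np.inf
            else:
                d[i, j] = d[j, i] = max(0.0, -math.log(jxy / math.sqrt(jx * jy)))
    return DistanceMatrix(groups, d, statistic="PDI")


# ---------------------------------------------------------------------------
# Kruskal–Wallis rank ANOVA with Dunn/Bonferroni letters
# ---------------------------------------------------------------------------


@dataclass
class RankAnovaResult:
    """Per-character H statistics with multiple-comparison letter codes."""

    table: pd.DataFrame                        # character x (H, df, p)
    letters: dict[str, dict[str, str]]         # character -> group -> letters
    pairwise_p: dict[str, pd.DataFrame]        # character -> group x group p
    alpha: float = 0.05


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray, groups: list[str]):
    """Dunn-type z tests on mid-ranks with tie correction; Bonferroni-adjusted."""
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks = {gname: ranks[labels == gname].mean() for gname in groups}
    sizes = {gname: int((labels == gname).sum()) for gname in groups}
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pmat = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
    for g1, g2 in itertools.combinations(groups, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
        pmat.loc[g1, g2] = pmat.loc[g2, g1] = p
    return pmat, mean_ranks


def _compact_letters(pmat: pd.DataFrame, order: list[str], alpha: float) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different."""
    nsd = {
        (g1, g2)
        for g1, g2 in itertools.combinations(order, 2)
        if pmat.loc[g1, g2] > alpha
    }

    def compatible(gname, group_set):
        return all(
            (min(gname, other), max(gname, other)) in nsd or gname == other
            for other in group_set
        )

    sets: list[set] = []
    for gname in order:
        placed = False
        for s in sets:
            if compatible(gname, s):
                s.add(gname)
                placed = True
        if not placed:
            sets.append({gname})
    # guarantee every non-significant pair shares a letter
    for g1, g2 in nsd:
        if not any(g1 in s and g2 in s for s in sets):
            sets.append({g1, g2})
    # drop redundant subsets
    sets = [s for s in sets if not any(s < other for other in sets)]
    letters = {gname: "" for gname in order}
    for letter, s in zip(string.ascii_uppercase, sets):
        for gname in s:
            letters[gname] += letter
    return letters


def kruskal_wallis(
    t: TraitMatrix, grouping="population", alpha: float = 0.05
) -> RankAnovaResult:
    """One-way ANOVA on ranks per character, with Dunn/Bonferroni letters.

    H is the tie-corrected Kruskal–Wallis statistic with a chi-square
    p-value on (groups - 1) df; all-identical values give H = 0, p = 1.
    """
    labels = np.asarray(_resolve_grouping(grouping, t))
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    rows, letters, pairwise = [], {}, {}
    for j, ch in enumerate(t.characters):
        v = t.values[:, j]
        scored = ~np.isnan(v)
        vj, lj = v[scored], labels[scored]
        samples = [vj[lj == gname] for gname in groups if (lj == gname).size]
        samples = [s for s in samples if len(s) > 0]
        df = len(samples) - 1
        if np.unique(vj).size < 2:
            H, p = 0.0, 1.0
        else:
            H, p = stats.kruskal(*samples)
        rows.append({"character": ch, "H": float(H), "df": df, "p": float(p)})
        pmat, mean_ranks = _dunn_pairwise(vj, lj, groups)
        order = sorted(groups, key=lambda gname: mean_ranks[gname])
        letters[ch] = _compact_letters(pmat, order, alpha)
        pairwise[ch] = pmat
    return RankAnovaResult(
        table=pd.DataFrame(rows).set_index("character"),
        letters=letters,
        pairwise_p=pairwise,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Discriminant function analysis
# ---------------------------------------------------------------------------


@dataclass
class LdaResult:
    scores: pd.DataFrame                 # individuals x DF axes
    explained: np.ndarray                # fraction of discriminating variance per axis
    loadings: pd.DataFrame               # characters x DF axes
    eigenvalues: np.ndarray
    wilks_lambda: float
    wilks_chi2: float
    wilks_p: float
    confusion: pd.DataFrame              # a-priori class x assigned class
    percent_correct: pd.Series           # per class, leave-one-out
    classes: list[str] = field(default_factory=list)

    @property
    def total_percent_correct(self) -> float:
        return 100.0 * np.trace(self.confusion.values) / self.confusion.values.sum()


def lda(
    t: TraitMatrix, classes="population", n_axes: int | None = None
) -> LdaResult:
    """Canonical discriminant analysis of (standardized) traits.

    Solves the generalized eigenproblem Sb v = lambda Sw v of between- vs
    within-class scatter.  Reports per-axis explained-variance fractions,
    Wilks' Lambda = prod 1/(1+lambda_j) with its chi-square approximation,
    and a leave-one-out reclassification by nearest class centroid in
    discriminant space.  A singular within-class scatter is ridge-
    regularized (logged).
    """
    labels = np.asarray(_resolve_grouping(classes, t))
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("lda needs >= 2 classes")
    X = t.values
    if np.isnan(X).any():
        raise ValueError("lda requires complete data; impute or drop first")
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for gname in groups:
        sel = X[labels == gname]
        mu = sel.mean(axis=0)
        dev = sel - mu
        Sw += dev.T @ dev
        dmu = (mu - grand)[:, None]
        Sb += len(sel) * (dmu @ dmu.T)
    # regularize if Sw is singular
    if np.linalg.matrix_rank(Sw) < p:
        eps = 1e-8 * max(np.trace(Sw) / p, 1.0)
        log.warning("lda: singular within-class scatter, ridge epsilon %.3g", eps)
        Sw = Sw + eps * np.eye(p)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    max_axes = min(len(groups) - 1, p)
    lam = np.clip(evals[:max_axes], 0.0, None)
    k = n_axes if n_axes is not None else max_axes
    k = min(k, max_axes)
    W = evecs[:, :k]
    lam_k = lam[:k]
    explained = lam_k / lam.sum() if lam.sum() > 0 else np.zeros(k)

    wilks = float(np.prod(1.0 / (1.0 + lam)))
    gsize = len(groups)
    chi2 = -(n - 1 - (p + gsize) / 2.0) * math.log(max(wilks, 1e-300))
    dof = p * (gsize - 1)
    wilks_p = float(stats.chi2.sf(chi2, dof))

    scores = (X - grand) @ W
    axis_names = [f"DF{i + 1}" for i in range(k)]

    # leave-one-out reclassification by nearest class centroid in DF space
    assigned = []
    sums = {gname: scores[labels == gname].sum(axis=0) for gname in groups}
    sizes = {gname: int((labels == gname).sum()) for gname in groups}
    for i in range(n):
        best, best_d = None, np.inf
        for gname in groups:
            m, s = sizes[gname], sums[gname]
            if labels[i] == gname:
                if m == 1:
                    continue
                cen = (s - scores[i]) / (m - 1)
            else:
                cen = s / m
            dist = float(((scores[i] - cen) ** 2).sum())
            if dist < best_d:
                best, best_d = gname, dist
        assigned.append(best)
    confusion = pd.crosstab(
        pd.Series(labels, name="a_priori"), pd.Series(assigned, name="assigned")
    ).reindex(index=groups, columns=groups, fill_value=0)
    correct = pd.Series(
        {
            gname: 100.0 * confusion.loc[gname, gname] / max(sizes[gname], 1)
            for gname in groups
        },
        name="percent_correct",
    )
    return LdaResult(
        scores=pd.DataFrame(scores, index=t.individual_ids, columns=axis_names),
        explained=np.asarray(explained),
        loadings=pd.DataFrame(W, index=t.characters, columns=axis_names),
        eigenvalues=lam_k,
        wilks_lambda=wilks,
        wilks_chi2=float(chi2),
        wilks_p=wilks_p,
        confusion=confusion,
        percent_correct=correct,
        classes=groups,
    )


# ---------------------------------------------------------------------------
# Character selection helper and trait clustering
# ---------------------------------------------------------------------------


def select_characters(
    anova: RankAnovaResult,
    lda_result: LdaResult,
    alpha: float = 0.05,
    top_loadings: int = 10,
) -> list[str]:
    """Helper filter: significant characters plus top-|loading| ones on DF1/DF2.

    Never applied implicitly — the categorical matrix is always built from
    an explicit character list chosen by the caller.
    """
    sig = set(anova.table.index[anova.table["p"] <= alpha])
    axes = [c for c in ("DF1", "DF2") if c in lda_result.loadings.columns]
    mag = lda_result.loadings[axes].abs().max(axis=1)
    top = set(mag.sort_values(ascending=False).head(top_loadings).index)
    return [c for c in anova.table.index if c in (sig | top)]


def trait_cluster(t: TraitMatrix, grouping="population"):
    """UPGMA tree on Euclidean distances between group mean trait vectors."""
    from .cluster import upgma

    labels = np.asarray(_resolve_grouping(grouping, t))
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("trait_cluster needs >= 2 groups")
    means = np.stack(
        [np.nanmean(t.values[labels == gname], axis=0) for gname in groups]
    )
    n = len(groups)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.linalg.norm(means[i] - means[j]))
    return upgma(DistanceMatrix(groups, d, statistic="euclidean"))
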