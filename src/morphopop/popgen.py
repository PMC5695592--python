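"""Microsatellite diversity and differentiation statistics.

Implements gene-counting allele frequencies, per-population diversity
summaries (NA, NE, H_O, H_E, UH_E), an EM estimator of null-allele
frequency under Hardy–Weinberg, Weir–Cockerham variance-components
F-statistics with an ENA-style null-allele correction, Nei (1972) standard
distance and the Cavalli-Sforza & Edwards chord distance (with INA
correction), a Monte-Carlo exact Hardy–Weinberg test, and the algebraic
demographic conversions Ne = Theta/(4 mu) and Nm = Theta*M/4.

Notation: for allele u at a locus scored in r populations with n_i typed
individuals, p_i its frequency and h_i the observed frequency of
heterozygotes carrying u in population i, the Weir–Cockerham components
are

    a = (nbar/nc) * [s2 - (pbar(1-pbar) - s2*(r-1)/r - hbar/4) / (nbar-1)]
    b = (nbar/(nbar-1)) * [pbar(1-pbar) - s2*(r-1)/r - hbar*(2nbar-1)/(4nbar)]
    c = hbar/2

and theta = sum(a) / sum(a+b+c) over alleles and loci (ratio of sums).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import MISSING, DistanceMatrix, GenotypeMatrix

__all__ = [
    "AlleleFrequencyTable",
    "allele_frequencies",
    "diversity",
    "null_allele_em",
    "fst",
    "fis",
    "nei_distance",
    "chord_distance",
    "hwe_test",
    "theta_from_he_smm",
    "ne_from_theta",
    "nm_from_theta_m",
]

TWO_SQRT2_OVER_PI = 2.0 * math.sqrt(2.0) / math.pi


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Per population x locus allele-size frequencies by gene counting.

    ``freq[(pop, locus)]`` maps allele size -> frequency among typed gene
    copies; ``n_typed[(pop, locus)]`` is the number of typed individuals N
    (2N gene copies).  When null-allele estimation was requested,
    ``null_r[(pop, locus)]`` holds the EM estimate r and the visible
    frequencies in ``freq`` are rescaled so that the full vector
    (visible..., r) sums to 1.
    """

    populations: list[str]
    loci: list[str]
    freq: dict[tuple[str, str], dict[int, float]]
    n_typed: dict[tuple[str, str], int]
    null_r: dict[tuple[str, str], float] = field(default_factory=dict)

    def alleles_at(self, locus: str) -> list[int]:
        out: set[int] = set()
        for pop in self.populations:
            out.update(self.freq.get((pop, locus), {}))
        return sorted(out)

    def vector(self, pop: str, locus: str, alleles: list[int]) -> np.ndarray:
        f = self.freq.get((pop, locus), {})
        return np.array([f.get(a, 0.0) for a in alleles])


def allele_frequencies(
    g: GenotypeMatrix, estimate_nulls: bool = False
) -> AlleleFrequencyTable:
    """Gene-counting allele frequencies; missing genotypes excluded.

    With ``estimate_nulls=True`` the EM null-allele estimator is run for
    every population x locus cell with enough data and the returned
    frequencies are the EM-adjusted ones (visible + null summing to 1).
    """
    freq: dict[tuple[str, str], dict[int, float]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    null_r: dict[tuple[str, str], float] = {}
    any_typed = {pop: False for pop in g.populations}
    for pop in g.populations:
        mask = g.population_mask(pop)
        sub = g.alleles[mask]
        for l, locus in enumerate(g.loci):
            copies = sub[:, l, :].ravel()
            copies = copies[copies != MISSING]
            if copies.size == 0:
                continue  # cell flagged absent by omission
            any_typed[pop] = True
            vals, counts = np.unique(copies, return_counts=True)
            total = counts.sum()
            freq[(pop, locus)] = {
                int(v): c / total for v, c in zip(vals, counts)
            }
            n_typed[(pop, locus)] = int(total // 2)
    for pop, ok in any_typed.items():
        if not ok:
            raise ValueError(f"population {pop!r} has zero typed copies at every locus")
    table = AlleleFrequencyTable(
        populations=g.populations, loci=list(g.loci), freq=freq, n_typed=n_typed
    )
    if estimate_nulls:
        for pop in g.populations:
            for locus in g.loci:
                if (pop, locus) not in freq:
                    continue
                try:
                    r, p_vis, _ = null_allele_em(g, locus, pop, return_freqs=True)
                except ValueError:
                    continue
                null_r[(pop, locus)] = r
                table.freq[(pop, locus)] = p_vis
        table.null_r = null_r
    return table


# ---------------------------------------------------------------------------
# Diversity summary
# ---------------------------------------------------------------------------


def diversity(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-population diversity summary: NA, NE, H_O, H_E, UH_E.

    Per locus: NA = number of observed alleles; NE = 1/sum(p^2);
    H_O = fraction of heterozygotes among typed individuals;
    H_E = 1 - sum(p^2); UH_E = 2N/(2N-1) * H_E with N typed individuals.
    Population values are means over loci with standard errors.
    """
    rows = []
    for pop in g.populations:
        mask = g.population_mask(pop)
        sub = g.alleles[mask]
        na, ne, ho, he, uhe = [], [], [], [], []
        for l in range(g.n_loci):
            geno = sub[:, l, :]
            typed = geno[:, 0] != MISSING
            n = int(typed.sum())
            if n == 0:
                continue
            copies = geno[typed].ravel()
            vals, counts = np.unique(copies, return_counts=True)
            p = counts / counts.sum()
            sum_p2 = float((p**2).sum())
            na.append(len(vals))
            ne.append(1.0 / sum_p2)
            ho.append(float((geno[typed, 0] != geno[typed, 1]).mean()))
            he_l = 1.0 - sum_p2
            he.append(he_l)
            uhe.append((2 * n / (2 * n - 1)) * he_l if n > 1 else np.nan)
        if not na:
            raise ValueError(f"population {pop!r} has no typed loci")

        def _mean_se(x):
            x = np.asarray(x, dtype=float)
            x = x[~np.isnan(x)]
            se = x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else np.nan
            return x.mean(), se

        stats = {}
        for name, vec in (("NA", na), ("NE", ne), ("Ho", ho), ("He", he), ("uHe", uhe)):
            m, se = _mean_se(vec)
            stats[name] = m
            stats[name + "_se"] = se
        rows.append({"population": pop, "n_loci": len(na), **stats})
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Null-allele EM
# ---------------------------------------------------------------------------


def _em_null(
    het_counts: dict[tuple[int, int], int],
    hom_counts: dict[int, int],
    n_blank: int,
    tol: float = 1e-8,
    max_iter: int = 10_000,
):
    """EM for one null allele under HWE on visible genotype counts.

    Genotype classes: visible heterozygote (i, j), visible homozygote i
    (true homozygote i/i or null heterozygote i/null), blank (null/null).
    Returns (r, visible allele freqs dict, converged, loglik trace).
    """
    alleles = sorted(set(hom_counts) | {a for pair in het_counts for a in pair})
    N = sum(het_counts.values()) + sum(hom_counts.values()) + n_blank
    if N == 0:
        raise ValueError("no individuals")
    # init: uniform over visible alleles, small null
    p = {a: 1.0 / (len(alleles) + 1) for a in alleles}
    r = 1.0 / (len(alleles) + 1)
    loglik = []
    converged = False
    for _ in range(max_iter):
        # E-step: expected gene-copy counts
        copies = {a: 0.0 for a in alleles}
        null_copies = 2.0 * n_blank
        for (i, j), c in het_counts.items():
            copies[i] += c
            copies[j] += c
        for i, c in hom_counts.items():
            denom = p[i] + 2.0 * r
            w_true = p[i] / denom if denom > 0 else 1.0
            copies[i] += c * (2.0 * w_true + (1.0 - w_true))  # 2 copies if true hom, 1 if i/null
            null_copies += c * (1.0 - w_true)
        total = 2.0 * N
        new_p = {a: copies[a] / total for a in alleles}
        new_r = null_copies / total
        # observed-data log-likelihood (multinomial over classes)
        ll = 0.0
        for (i, j), c in het_counts.items():
            ll += c * math.log(max(2.0 * new_p[i] * new_p[j], 1e-300))
        for i, c in hom_counts.items():
            ll += c * math.log(max(new_p[i] ** 2 + 2.0 * new_p[i] * new_r, 1e-300))
        if n_blank:
            ll += n_blank * math.log(max(new_r**2, 1e-300))
        loglik.append(ll)
        delta = abs(new_r - r)
        p, r = new_p, new_r
        if delta < tol:
            converged = True
            break
    return r, p, converged, loglik


def null_allele_em(
    g: GenotypeMatrix,
    locus: str,
    population: str,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    return_freqs: bool = False,
    return_trace: bool = False,
):
    """EM estimate of the null-allele frequency r for one population x locus.

    Blank (missing) genotypes are attributed to null homozygotes, visible
    homozygotes are apportioned between true homozygotes and visible/null
    heterozygotes under HWE.  Returns ``(r, converged)`` by default.
    """
    l = g.loci.index(locus)
    mask = g.population_mask(population)
    geno = g.alleles[mask][:, l, :]
    typed = geno[:, 0] != MISSING
    if int(typed.sum()) < 5:
        raise ValueError(
            f"null_allele_em needs >= 5 typed individuals at {population}/{locus}"
        )
    het_counts: dict[tuple[int, int], int] = {}
    hom_counts: dict[int, int] = {}
    for a, b in geno[typed]:
        if a == b:
            hom_counts[int(a)] = hom_counts.get(int(a), 0) + 1
        else:
            key = (int(min(a, b)), int(max(a, b)))
            het_counts[key] = het_counts.get(key, 0) + 1
    n_blank = int((~typed).sum())
    r, p, converged, trace = _em_null(het_counts, hom_counts, n_blank, tol, max_iter)
    if return_freqs:
        return r, {int(a): v for a, v in p.items()}, converged
    if return_trace:
        return r, converged, trace
    return r, converged


# ---------------------------------------------------------------------------
# Weir–Cockerham F-statistics
# ---------------------------------------------------------------------------


def _wc_components_locus(
    p: np.ndarray, h: np.ndarray, n: np.ndarray, exclude: np.ndarray | None = None
):
    """Per-allele (a, b, c) sums for one locus.

    p: (r, A) allele frequencies per population, h: (r, A) observed
    heterozygote frequencies involving each allele, n: (r,) typed
    individuals.  ``exclude`` marks allele columns left out of the sums
    (the ENA treatment of the estimated null allele).
    """
    r = len(n)
    nbar = n.mean()
    if r < 2 or nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    A = p.shape[1]
    asum = bsum = csum = 0.0
    for u in range(A):
        if exclude is not None and exclude[u]:
            continue
        pbar = (n * p[:, u]).sum() / (r * nbar)
        s2 = (n * (p[:, u] - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h[:, u]).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        asum += a
        bsum += b
        csum += c
    return asum, bsum, csum


def _locus_pop_arrays(g: GenotypeMatrix, l: int, pops: list[str]):
    """(p, h, n) arrays for locus l over populations with >= 1 typed individual."""
    alleles = np.unique(g.alleles[:, l, :][g.alleles[:, l, :] != MISSING])
    used_pops, p_rows, h_rows, ns = [], [], [], []
    for pop in pops:
        mask = g.population_mask(pop)
        geno = g.alleles[mask][:, l, :]
        typed = geno[:, 0] != MISSING
        n = int(typed.sum())
        if n == 0:
            continue
        geno = geno[typed]
        copies = geno.ravel()
        p = np.array([(copies == a).sum() for a in alleles]) / (2 * n)
        is_het = geno[:, 0] != geno[:, 1]
        h = np.array(
            [((geno == a).any(axis=1) & is_het).sum() for a in alleles]
        ) / n
        used_pops.append(pop)
        p_rows.append(p)
        h_rows.append(h)
        ns.append(n)
    return alleles, used_pops, np.array(p_rows), np.array(h_rows), np.array(ns, dtype=float)


def _ena_arrays(g: GenotypeMatrix, l: int, used: list[str], alleles: np.ndarray):
    """EM-reconstructed (p, h, n) arrays with the null allele appended.

    Per population the EM estimate of the null frequency r becomes the
    last allele column (visible frequencies sum to 1 - r), observed
    heterozygosities are augmented by the expected visible/null
    heterozygotes the EM attributes to apparent homozygotes, and blank
    genotypes count as null homozygotes (n = all individuals).
    """
    A = len(alleles)
    p = np.zeros((len(used), A + 1))
    h = np.zeros((len(used), A + 1))
    n = np.zeros(len(used))
    col = {int(a): k for k, a in enumerate(alleles)}
    for k, pop in enumerate(used):
        mask = g.population_mask(pop)
        geno = g.alleles[mask][:, l, :]
        typed = geno[:, 0] != MISSING
        n_all = len(geno)
        n[k] = n_all
        het_counts: dict[tuple[int, int], int] = {}
        hom_counts: dict[int, int] = {}
        for a_, b_ in geno[typed]:
            if a_ == b_:
                hom_counts[int(a_)] = hom_counts.get(int(a_), 0) + 1
            else:
                key = (int(min(a_, b_)), int(max(a_, b_)))
                het_counts[key] = het_counts.get(key, 0) + 1
        n_blank = int((~typed).sum())
        if int(typed.sum()) >= 5:
            r, p_vis, _, _ = _em_null(het_counts, hom_counts, n_blank)
        else:  # too little data: no correction for this cell
            copies = geno[typed].ravel()
            vals, counts = np.unique(copies, return_counts=True)
            p_vis = {int(v): c / counts.sum() for v, c in zip(vals, counts)}
            r = 0.0
        for a_, freq in p_vis.items():
            p[k, col[a_]] = freq
        p[k, -1] = r
        exp_null_het = 0.0
        for a_, c_ in hom_counts.items():
            pa = p_vis.get(a_, 0.0)
            e = c_ * (2.0 * r / (pa + 2.0 * r)) if (pa + 2.0 * r) > 0 else 0.0
            h[k, col[a_]] += e
            exp_null_het += e
        for (a_, b_), c_ in het_counts.items():
            h[k, col[a_]] += c_
            h[k, col[b_]] += c_
        h[k, -1] = exp_null_het
        h[k] /= max(n_all, 1)
    return p, h, n


@dataclass
class FStatResult:
    """Multi-locus theta with per-locus values and bootstrap-over-loci CI."""

    theta: float
    per_locus: dict[str, float]
    ci: tuple[float, float] | None
    correction: str
    n_boot: int
    seed: int | None
    components: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def fst(
    g: GenotypeMatrix,
    correction: str = "none",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> FStatResult:
    """Weir–Cockerham theta over all populations, optionally ENA-corrected.

    Under ``correction='ena'`` the EM-estimated null-allele frequency is
    appended as an extra allele per locus x population (visible
    frequencies rescaled to sum to 1 - r) and that allele is excluded
    from the numerator/denominator sums.  The 95% CI is a percentile
    bootstrap over loci (absent with a single locus).
    """
    if correction not in ("none", "ena"):
        raise ValueError(f"unknown correction {correction!r}")
    pops = g.populations
    if len(pops) < 2:
        raise ValueError("fst needs >= 2 populations")
    components: dict[str, tuple[float, float, float]] = {}
    for l, locus in enumerate(g.loci):
        alleles, used, p, h, n = _locus_pop_arrays(g, l, pops)
        if len(used) < 2 or len(alleles) < 2:
            continue
        exclude = None
        if correction == "ena":
            p, h, n = _ena_arrays(g, l, used, alleles)
            exclude = np.zeros(len(alleles) + 1, dtype=bool)
            exclude[-1] = True
        a, b, c = _wc_components_locus(p, h, n, exclude=exclude)
        if a + b + c != 0:
            components[locus] = (a, b, c)
    if not components:
        raise ValueError("no informative loci for fst")
    per_locus = {
        loc: (a / (a + b + c) if (a + b + c) > 0 else np.nan)
        for loc, (a, b, c) in components.items()
    }
    # multi-locus ratio of sums; per spec, loci with non-positive
    # denominators are dropped from the ratio
    num = sum(a for (a, b, c) in components.values() if (a + b + c) > 0)
    den = sum(a + b + c for (a, b, c) in components.values() if (a + b + c) > 0)
    theta = num / den
    ci = None
    if len(components) >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        loci = list(components)
        reps = np.empty(n_boot)
        abc = np.array([components[loc] for loc in loci])  # (L, 3)
        idx = rng.integers(0, len(loci), size=(n_boot, len(loci)))
        for bI in range(n_boot):
            sel = abc[idx[bI]]
            denom = sel.sum(axis=1)
            keep = denom > 0
            reps[bI] = sel[keep, 0].sum() / denom[keep].sum() if keep.any() else np.nan
        reps = reps[~np.isnan(reps)]
        ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return FStatResult(
        theta=float(theta),
        per_locus=per_locus,
        ci=ci,
        correction=correction,
        n_boot=n_boot,
        seed=seed,
        components=components,
    )


def fis(g: GenotypeMatrix) -> pd.Series:
    """Per-population multi-locus Weir–Cockerham f (inbreeding coefficient).

    Uses the within-population (b, c) variance components with
    f = 1 - sum(c)/sum(b + c) over alleles and loci.  Monomorphic
    populations yield NaN (undefined).
    """
    out = {}
    for pop in g.populations:
        mask = g.population_mask(pop)
        bsum = csum = 0.0
        informative = False
        for l in range(g.n_loci):
            geno = g.alleles[mask][:, l, :]
            typed = geno[:, 0] != MISSING
            n = int(typed.sum())
            if n < 2:
                continue
            geno = geno[typed]
            alleles = np.unique(geno)
            if len(alleles) < 2:
                continue
            informative = True
            copies = geno.ravel()
            is_het = geno[:, 0] != geno[:, 1]
            for a in alleles:
                p = (copies == a).sum() / (2 * n)
                h = (((geno == a).any(axis=1)) & is_het).sum() / n
                b = (n / (n - 1)) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
                bsum += b
                csum += h / 2.0
        if not informative or (bsum + csum) == 0:
            out[pop] = np.nan
        else:
            out[pop] = 1.0 - csum / (bsum + csum)
    return pd.Series(out, name="fis")


# ---------------------------------------------------------------------------
# Genetic distances
# ---------------------------------------------------------------------------


def nei_distance(f: AlleleFrequencyTable, unbiased: bool = False) -> DistanceMatrix:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx * Jy)).

    J terms are summed over loci before taking the ratio (Nei 1972).
    With ``unbiased=True`` the within-population J terms use the Nei 1978
    small-sample correction (2N sum(p^2) - 1)/(2N - 1).  Pairs sharing no
    allele at any locus get an infinite distance (flagged, not capped).
    """
    pops = f.populations
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jx = jy = jxy = 0.0
            shared_loci = [
                loc for loc in f.loci
                if (pops[i], loc) in f.freq and (pops[j], loc) in f.freq
            ]
            if not shared_loci:
                raise ValueError(f"populations {pops[i]} and {pops[j]} share no typed locus")
            for loc in shared_loci:
                alleles = sorted(
                    set(f.freq[(pops[i], loc)]) | set(f.freq[(pops[j], loc)])
                )
                x = f.vector(pops[i], loc, alleles)
                y = f.vector(pops[j], loc, alleles)
                if unbiased:
                    nx = f.n_typed[(pops[i], loc)]
                    ny = f.n_typed[(pops[j], loc)]
                    jx += (2 * nx * (x**2).sum() - 1) / (2 * nx - 1)
                    jy += (2 * ny * (y**2).sum() - 1) / (2 * ny - 1)
                else:
                    jx += (x**2).sum()
                    jy += (y**2).sum()
                jxy += (x * y).sum()
            if jxy <= 0:
                d[i, j] = d[j, i] = np.inf
            else:
                d[i, j] = d[j, i] = max(
                    0.0, -math.log(jxy / math.sqrt(jx * jy))
                )
    return DistanceMatrix(list(pops), d, statistic="nei_D")


def chord_distance(f: AlleleFrequencyTable, correction: str = "none") -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance.

    Per locus d_l = (2*sqrt(2)/pi) * sqrt(1 - sum_i sqrt(x_i y_i)); the
    multi-locus value is sqrt(sum_l d_l^2 / L).  Under ``correction='ina'``
    the EM-estimated null allele (``f.null_r``) is included as an
    additional shared allele in the sum sqrt(x*y).
    """
    if correction not in ("none", "ina"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "ina" and not f.null_r:
        raise ValueError("INA correction requires a table built with estimate_nulls=True")
    pops = f.populations
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = []
            for loc in f.loci:
                if (pops[i], loc) not in f.freq or (pops[j], loc) not in f.freq:
                    continue
                alleles = sorted(
                    set(f.freq[(pops[i], loc)]) | set(f.freq[(pops[j], loc)])
                )
                x = f.vector(pops[i], loc, alleles)
                y = f.vector(pops[j], loc, alleles)
                cos = float(np.sqrt(x * y).sum())
                if correction == "ina":
                    rx = f.null_r.get((pops[i], loc), 0.0)
                    ry = f.null_r.get((pops[j], loc), 0.0)
                    cos += math.sqrt(rx * ry)
                dl = TWO_SQRT2_OVER_PI * math.sqrt(max(0.0, 1.0 - min(cos, 1.0)))
                d2.append(dl**2)
            if not d2:
                raise ValueError(f"populations {pops[i]} and {pops[j]} share no typed locus")
            d[i, j] = d[j, i] = math.sqrt(sum(d2) / len(d2))
    return DistanceMatrix(list(pops), d, statistic="chord_DC")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Monte Carlo)
# ---------------------------------------------------------------------------


def _log_prob_genotype_array(geno: np.ndarray) -> float:
    """log P(genotype array | allele counts) under HWE (Levene's formula)."""
    n = len(geno)
    copies = geno.ravel()
    vals, allele_counts = np.unique(copies, return_counts=True)
    # genotype counts
    keys, het = {}, 0
    for a, b in geno:
        k = (min(a, b), max(a, b))
        keys[k] = keys.get(k, 0) + 1
        if a != b:
            het += 1
    logp = (
        gammaln(n + 1)
        + gammaln(allele_counts + 1).sum()
        + het * math.log(2.0)
        - gammaln(2 * n + 1)
        - sum(gammaln(c + 1) for c in keys.values())
    )
    return float(logp)


def hwe_test(
    g: GenotypeMatrix,
    locus: str,
    population: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo exact test of Hardy–Weinberg at one population x locus.

    The observed genotype array's conditional probability given the allele
    counts is compared with arrays obtained by randomly re-pairing the
    observed gene copies; p = (1 + #{perm <= obs}) / (1 + n_perm).
    """
    l = g.loci.index(locus)
    mask = g.population_mask(population)
    geno = g.alleles[mask][:, l, :]
    geno = geno[geno[:, 0] != MISSING]
    if len(geno) < 5:
        raise ValueError(f"hwe_test needs >= 5 typed individuals at {population}/{locus}")
    if len(np.unique(geno)) < 2:
        return 1.0
    obs = _log_prob_genotype_array(geno)
    rng = np.random.default_rng(seed)
    copies = geno.ravel().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(copies)
        perm = copies.reshape(-1, 2)
        if _log_prob_genotype_array(perm) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Demographic conversions
# ---------------------------------------------------------------------------


def theta_from_he_smm(he: float) -> float:
    """Moment estimate of Theta = 4*Ne*mu from expected heterozygosity
    under the stepwise mutation model: H = 1 - 1/sqrt(1 + 2*Theta)."""
    if not 0 <= he < 1:
        raise ValueError("expected heterozygosity must be in [0, 1)")
    return ((1.0 / (1.0 - he)) ** 2 - 1.0) / 2.0


def ne_from_theta(theta: float, mu: float = 5e-4) -> float:
    """Effective population size Ne = Theta / (4 mu)."""
    if mu <= 0:
        raise ValueError("mutation rate mu must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / (4.0 * mu)


def nm_from_theta_m(theta: float, M: float) -> float:
    """Migrants per generation Nm = Theta * M / 4 (M = m/mu scaled migration)."""
    if theta < 0 or M < 0:
        raise ValueError("theta and M must be non-negative")
    return theta * M / 4.0
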