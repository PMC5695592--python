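"""Synthetic genotype and trait data with the structure the analyses assume.

The genotype generator is a two-level F-model.  Each locus has an ancestral
pool of allele sizes (by default 8 sizes spaced 2 bp apart, the dinucleotide
repeat convention) with Dirichlet-drawn ancestral frequencies.  Optional
cluster pools diverge from the ancestral pool with drift parameter
``F_cluster`` (frequencies ~ Dirichlet(p * (1-F)/F), the Balding–Nichols
parameterization), and each population diverges from its parent pool with
its own ``F``.  With no clusters and a single shared pool this is the plain
one-level F-model; F -> 0 is handled as the limit (frequencies equal to the
parent pool).

Diploid genotypes are random unions of gametes.  Null alleles act per
allele copy: with the configured per-locus x per-population null frequency
an allele copy is a non-amplifying null, so a null/visible heterozygote is
recorded as a visible homozygote and null/null as a missing genotype.
Clonal individuals are exact copies of the *latent* genotype (including
null states) of a previously sampled individual in the same population,
mimicking vegetatively propagated (cultivated) stands.

Traits are multivariate normal around species-x-management group means.
The default design emulates a study of 24 agave populations (16 of a wild
species with managed and cultivated stands, 4 of a second wild species, 4
of an exclusively cultivated domesticate), 19-30 individuals per
population, 10 microsatellite loci and 23 vegetative characters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MISSING, GenotypeMatrix, TraitMatrix

__all__ = [
    "PopulationDesign",
    "SimDesign",
    "default_design",
    "simulate_genotypes",
    "simulate_traits",
]

_F_EPS = 1e-9


@dataclass
class PopulationDesign:
    """One population in a simulation design."""

    name: str
    species: str
    management: str  # wild | managed | cultivated
    n: int
    F: float
    clonality: float = 0.0
    cluster: str | None = None  # ancestral-pool group; None = root pool


@dataclass
class SimDesign:
    populations: list[PopulationDesign]
    n_loci: int = 10
    n_alleles: int = 8
    allele_spacing: int = 2
    allele_base_size: int = 100
    ancestral_alpha: float = 1.0
    cluster_F: dict[str, float] = field(default_factory=dict)
    #: (n_populations, n_loci) per-copy null-allele frequency
    null_freq: np.ndarray | None = None
    #: if True, the null allele joins the parent pool at the configured
    #: frequency and drifts with the population's F like any allele (its
    #: realized per-population frequency then varies around the configured
    #: value); if False the configured value is applied exactly
    null_drift: bool = False
    characters: list[str] = field(default_factory=list)
    #: group key (species, management) -> mean vector over characters
    trait_means: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    trait_cov: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    trait_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.null_freq is None:
            self.null_freq = np.zeros((len(self.populations), self.n_loci))
        self.null_freq = np.asarray(self.null_freq, dtype=float)

    def validate(self) -> None:
        for p in self.populations:
            if not 0.0 <= p.F < 1.0:
                raise ValueError(f"population {p.name}: F must be in [0, 1), got {p.F}")
            if p.n < 2:
                raise ValueError(f"population {p.name}: sample size must be >= 2")
            if not 0.0 <= p.clonality <= 1.0:
                raise ValueError(f"population {p.name}: clonality must be in [0, 1]")
            if p.cluster is not None and p.cluster not in self.cluster_F:
                raise ValueError(f"population {p.name}: unknown cluster {p.cluster!r}")
        for c, F in self.cluster_F.items():
            if not 0.0 <= F < 1.0:
                raise ValueError(f"cluster {c}: F must be in [0, 1), got {F}")
        if self.null_freq.shape != (len(self.populations), self.n_loci):
            raise ValueError(
                f"null_freq shape {self.null_freq.shape} != "
                f"({len(self.populations)}, {self.n_loci})"
            )
        if ((self.null_freq < 0) | (self.null_freq >= 1)).any():
            raise ValueError("null-allele frequencies must be in [0, 1)")
        for key, cov in self.trait_cov.items():
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError(f"trait covariance for {key} is not symmetric")
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-8 * max(1.0, abs(w).max()):
                raise ValueError(
                    f"trait covariance for {key} is not positive semidefinite"
                )

    def group_of(self, pop: PopulationDesign) -> tuple[str, str]:
        return (pop.species, pop.management)


def _dirichlet_around(rng: np.random.Generator, parent: np.ndarray, F: float) -> np.ndarray:
    """Draw frequencies around ``parent`` under the F-model; F -> 0 is the limit case."""
    if F < _F_EPS:
        return parent.copy()
    alpha = parent * (1.0 - F) / F
    # Dirichlet with tiny alphas can produce exact zeros; clip for stability
    return rng.dirichlet(np.maximum(alpha, 1e-6))


def simulate_genotypes(
    design: SimDesign, seed: int | None = None, return_freqs: bool = False
):
    """Draw a :class:`GenotypeMatrix` under the (two-level) F-model.

    Deterministic given ``seed`` (defaults to ``design.seed``).  With
    ``return_freqs=True`` also returns the drawn ancestral and
    per-population visible-allele frequencies, for provenance records and
    parameter-recovery tests.
    """
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    L, A = design.n_loci, design.n_alleles

    sizes = np.array(
        [
            design.allele_base_size + 10 * l * design.allele_spacing
            + design.allele_spacing * np.arange(A)
            for l in range(L)
        ]
    )  # (L, A), loci occupy disjoint size ranges
    p_anc = np.stack(
        [rng.dirichlet(np.full(A, design.ancestral_alpha)) for _ in range(L)]
    )  # (L, A)
    cluster_pools: dict[str, np.ndarray] = {}
    for cname in design.cluster_F:  # insertion order: deterministic
        cluster_pools[cname] = np.stack(
            [_dirichlet_around(rng, p_anc[l], design.cluster_F[cname]) for l in range(L)]
        )

    ids, pops = [], []
    allele_rows = []
    pop_freqs: dict[str, np.ndarray] = {}
    for pi, pop in enumerate(design.populations):
        parent = cluster_pools[pop.cluster] if pop.cluster is not None else p_anc

        # latent genotypes: allele index 0..A-1 visible, A = null
        latent = np.empty((pop.n, L, 2), dtype=np.int64)
        p_pop = np.empty((L, A))
        for l in range(L):
            r = design.null_freq[pi, l]
            if design.null_drift and r > 0:
                parent_ext = np.append(parent[l] * (1.0 - r), r)
                p_ext = _dirichlet_around(rng, parent_ext, pop.F)
            else:
                p_vis = _dirichlet_around(rng, parent[l], pop.F)
                p_ext = np.append(p_vis * (1.0 - r), r)
            p_ext = p_ext / p_ext.sum()
            p_pop[l] = p_ext[:-1] / max(p_ext[:-1].sum(), 1e-300)
            latent[:, l, :] = rng.choice(A + 1, size=(pop.n, 2), p=p_ext)
        pop_freqs[pop.name] = p_pop
        # clone replacement: copy the latent genotype of an earlier individual
        clone_u = rng.random(pop.n)
        for i in range(1, pop.n):
            if clone_u[i] < pop.clonality:
                latent[i] = latent[rng.integers(0, i)]

        rendered = np.full((pop.n, L, 2), MISSING, dtype=np.int64)
        for l in range(L):
            g = latent[:, l, :]
            is_null = g == A
            both_null = is_null.all(axis=1)
            one_null = is_null.any(axis=1) & ~both_null
            ok = ~is_null.any(axis=1)
            rendered[ok, l, 0] = sizes[l][g[ok, 0]]
            rendered[ok, l, 1] = sizes[l][g[ok, 1]]
            if one_null.any():
                vis = np.where(is_null[one_null, 0], g[one_null, 1], g[one_null, 0])
                rendered[one_null, l, 0] = sizes[l][vis]
                rendered[one_null, l, 1] = sizes[l][vis]
        allele_rows.append(rendered)
        ids.extend(f"{pop.name}_{i + 1:03d}" for i in range(pop.n))
        pops.extend([pop.name] * pop.n)

    g = GenotypeMatrix(
        individual_ids=ids,
        population_ids=pops,
        loci=[f"L{l + 1:02d}" for l in range(L)],
        alleles=np.concatenate(allele_rows, axis=0),
    )
    if return_freqs:
        return g, {"ancestral": p_anc, "sizes": sizes, "populations": pop_freqs}
    return g


def simulate_traits(
    design: SimDesign, g: GenotypeMatrix | None = None, seed: int | None = None
) -> TraitMatrix:
    """Draw multivariate-normal traits around species x management group means.

    If ``g`` is given, traits are drawn for exactly its individuals (same
    ids, same order); otherwise individuals are enumerated from the design.
    Negative draws for the strictly positive characters are truncated at
    ``design.trait_floor``.
    """
    design.validate()
    if not design.characters:
        raise ValueError("design has no trait characters")
    rng = np.random.default_rng(
        (design.seed if seed is None else seed) + 1_000_003
    )
    by_name = {p.name: p for p in design.populations}
    if g is not None:
        ids = list(g.individual_ids)
        pops = list(g.population_ids)
    else:
        ids, pops = [], []
        for p in design.populations:
            ids.extend(f"{p.name}_{i + 1:03d}" for i in range(p.n))
            pops.extend([p.name] * p.n)

    C = len(design.characters)
    values = np.empty((len(ids), C))
    for i, popname in enumerate(pops):
        pop = by_name[popname]
        key = design.group_of(pop)
        mean = np.asarray(design.trait_means[key], dtype=float)
        cov = np.asarray(design.trait_cov[key], dtype=float)
        values[i] = rng.multivariate_normal(mean, cov, method="svd")
    values = np.maximum(values, design.trait_floor)
    return TraitMatrix(
        individual_ids=ids,
        population_ids=pops,
        characters=list(design.characters),
        values=values,
        management={p.name: p.management for p in design.populations},
    )


# ---------------------------------------------------------------------------
# Default design: 24 populations, 3 species, 3 management classes
# ---------------------------------------------------------------------------

#: 23 vegetative characters (lengths in cm, TEE10 a count, plus ratios).
DEFAULT_CHARACTERS = [
    "GPL", "SL", "D1", "D2", "LL", "LW", "LL_LW", "LL_SL", "TTL", "TTW",
    "TTL_TTW", "TTL_LL", "TEE10", "LTEE1", "LTEE2", "LTEE1_LL", "LTEE2_LL",
    "WTEE1", "WTEE2", "LTEE1_WTEE1", "LTEE2_WTEE2", "DTEE", "DTEE_LL",
]

# Group means and standard errors of the study-scale magnitude, per
# species x management group, in DEFAULT_CHARACTERS order.  Columns:
# (speciesA wild, speciesA managed, speciesA cultivated, domesticate
# cultivated, speciesB wild, speciesB cultivated).
_TRAIT_TABLE = {
    "GPL": ((119.031, 3.873), (162.200, 4.541), (148.327, 2.962), (201.150, 4.128), (98.025, 3.782), (124.325, 2.719)),
    "SL": ((44.765, 1.355), (45.800, 2.213), (47.008, 1.407), (56.763, 1.809), (35.250, 0.923), (47.550, 1.734)),
    "D1": ((216.190, 6.724), (246.750, 8.097), (199.990, 5.560), (305.890, 6.576), (164.100, 4.871), (189.980, 4.441)),
    "D2": ((214.378, 6.565), (249.000, 6.515), (203.092, 5.372), (297.563, 6.499), (163.275, 5.141), (183.700, 4.148)),
    "LL": ((93.707, 2.796), (119.018, 3.286), (106.385, 2.220), (161.195, 3.399), (70.413, 2.798), (82.765, 2.329)),
    "LW": ((15.744, 0.453), (20.333, 0.646), (20.861, 0.383), (20.715, 0.361), (25.625, 0.660), (30.923, 0.768)),
    "LL_LW": ((6.099, 0.149), (5.959, 0.245), (5.187, 0.112), (8.030, 0.272), (2.780, 0.095), (2.710, 0.080)),
    "LL_SL": ((2.154, 0.057), (2.696, 0.124), (2.453, 0.087), (2.998, 0.081), (2.043, 0.084), (1.816, 0.078)),
    "TTL": ((3.457, 0.066), (3.151, 0.134), (4.039, 0.086), (4.850, 0.130), (3.567, 0.101), (4.073, 0.134)),
    "TTW": ((0.571, 0.014), (0.671, 0.032), (0.732, 0.017), (0.749, 0.023), (0.473, 0.019), (0.668, 0.033)),
    "TTL_TTW": ((6.305, 0.160), (4.784, 0.186), (5.756, 0.160), (6.943, 0.282), (7.781, 0.244), (6.799, 0.532)),
    "TTL_LL": ((0.040, 0.002), (0.027, 0.001), (0.039, 0.001), (0.031, 0.001), (0.056, 0.005), (0.050, 0.002)),
    "TEE10": ((6.243, 0.223), (6.250, 0.260), (5.138, 0.193), (4.663, 0.163), (13.325, 0.962), (8.450, 0.786)),
    "LTEE1": ((0.580, 0.016), (0.535, 0.047), (0.752, 0.020), (1.738, 0.232), (1.202, 0.055), (1.338, 0.072)),
    "LTEE2": ((0.300, 0.015), (0.360, 0.030), (0.390, 0.020), (0.390, 0.023), (0.410, 0.046), (0.490, 0.044)),
    "LTEE1_LL": ((0.007, 0.001), (0.005, 0.001), (0.007, 0.001), (0.011, 0.001), (0.020, 0.003), (0.017, 0.001)),
    "LTEE2_LL": ((0.040, 0.002), (0.027, 0.001), (0.039, 0.001), (0.031, 0.001), (0.056, 0.005), (0.050, 0.002)),
    "WTEE1": ((0.817, 0.022), (0.966, 0.054), (1.065, 0.031), (3.098, 0.399), (1.738, 0.090), (2.107, 0.174)),
    "WTEE2": ((0.430, 0.023), (0.580, 0.027), (0.570, 0.036), (0.560, 0.038), (0.450, 0.057), (0.610, 0.042)),
    "LTEE1_WTEE1": ((0.724, 0.015), (0.546, 0.032), (0.725, 0.016), (0.610, 0.030), (0.713, 0.029), (0.686, 0.030)),
    "LTEE2_WTEE2": ((0.750, 0.027), (0.620, 0.039), (0.760, 0.031), (0.680, 0.033), (0.950, 0.033), (0.810, 0.044)),
    "DTEE": ((1.003, 0.056), (0.774, 0.071), (1.214, 0.081), (4.450, 0.760), (0.306, 0.042), (0.777, 0.118)),
    "DTEE_LL": ((0.011, 0.001), (0.007, 0.001), (0.012, 0.001), (0.026, 0.004), (0.005, 0.001), (0.010, 0.001)),
}

# SEs in the source tables are over ~36+ plants per group; per-individual
# SD is taken as SE * 6 (documented in the methods note).
_SD_FROM_SE = 6.0

_GROUP_COLS = {
    ("speciesA", "wild"): 0,
    ("speciesA", "managed"): 1,
    ("speciesA", "cultivated"): 2,
    ("domesticate", "cultivated"): 3,
    ("speciesB", "wild"): 4,
    ("speciesB", "cultivated"): 5,
}


def _default_populations() -> list[PopulationDesign]:
    sizes = [25, 22, 28, 19, 30, 24, 27, 21, 26, 23, 29, 20, 25, 22, 28, 19, 30, 24, 27, 21, 26, 23, 29, 20]
    specs = (
        # name, species, management, F, clonality
        [("WPIE", "speciesA", "wild", 0.10, 0.0),
         ("WCUA", "speciesA", "wild", 0.10, 0.0),
         ("WPR", "speciesA", "wild", 0.10, 0.0),
         ("WICU", "speciesA", "wild", 0.10, 0.0),
         ("WPB", "speciesA", "wild", 0.10, 0.0),
         ("WSAH2", "speciesA", "wild", 0.12, 0.0),
         ("MSAH1", "speciesA", "managed", 0.10, 0.05),
         ("M1", "speciesA", "managed", 0.10, 0.05),
         ("M2", "speciesA", "managed", 0.10, 0.05),
         ("CROC1", "speciesA", "cultivated", 0.12, 0.2),
         ("CROC2", "speciesA", "cultivated", 0.12, 0.2),
         ("CROC3", "speciesA", "cultivated", 0.12, 0.2),
         ("CTC", "speciesA", "cultivated", 0.12, 0.2),
         ("CSAH1", "speciesA", "cultivated", 0.12, 0.2),
         ("CSAH2", "speciesA", "cultivated", 0.12, 0.2),
         ("CLH", "speciesA", "cultivated", 0.12, 0.2),
         ("CCOR", "domesticate", "cultivated", 0.25, 0.5),
         ("CNAH", "domesticate", "cultivated", 0.25, 0.5),
         ("CTSI", "domesticate", "cultivated", 0.25, 0.5),
         ("CANG", "domesticate", "cultivated", 0.25, 0.5),
         ("WLL", "speciesB", "wild", 0.08, 0.0),
         ("WRP", "speciesB", "wild", 0.08, 0.0),
         ("CP1", "speciesB", "cultivated", 0.08, 0.2),
         ("CP2", "speciesB", "cultivated", 0.08, 0.2)]
    )
    return [
        PopulationDesign(name=n, species=s, management=m, n=sz, F=F,
                         clonality=c, cluster=s)
        for (n, s, m, F, c), sz in zip(specs, sizes)
    ]


def default_design(seed: int = 0) -> SimDesign:
    """The bundled 24-population / 3-species / 3-management design."""
    pops = _default_populations()
    null_freq = np.zeros((len(pops), 10))
    for pi, p in enumerate(pops):
        if p.species == "speciesA":
            null_freq[pi, 0] = 0.15  # emulates nulls at one locus in most pops
            null_freq[pi, 1] = 0.12
        elif p.species == "domesticate" and p.name != "CANG":
            null_freq[pi, 2] = 0.15
        elif p.species == "speciesB":
            null_freq[pi, 3] = 0.15
    means, covs = {}, {}
    for key, col in _GROUP_COLS.items():
        mu = np.array([_TRAIT_TABLE[c][col][0] for c in DEFAULT_CHARACTERS])
        sd = np.array([_TRAIT_TABLE[c][col][1] for c in DEFAULT_CHARACTERS]) * _SD_FROM_SE
        means[key] = mu
        covs[key] = np.diag(sd**2)
    return SimDesign(
        populations=pops,
        n_loci=10,
        cluster_F={"speciesA": 0.15, "domesticate": 0.35, "speciesB": 0.30},
        null_freq=null_freq,
        characters=list(DEFAULT_CHARACTERS),
        trait_means=means,
        trait_cov=covs,
        seed=seed,
    )


def design_provenance(design: SimDesign) -> dict:
    """JSON-serializable record of all design parameters."""
    return {
        "seed": design.seed,
        "n_loci": design.n_loci,
        "n_alleles": design.n_alleles,
        "allele_spacing": design.allele_spacing,
        "cluster_F": dict(design.cluster_F),
        "populations": [
            {
                "name": p.name, "species": p.species, "management": p.management,
                "n": p.n, "F": p.F, "clonality": p.clonality, "cluster": p.cluster,
            }
            for p in design.populations
        ],
        "null_freq": design.null_freq.tolist(),
        "characters": list(design.characters),
        "trait_means": {f"{s}/{m}": v.tolist() for (s, m), v in design.trait_means.items()},
    }


def write_provenance(design: SimDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design_provenance(design), fh, indent=1)
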