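"""Shared domain containers for the morphometric + microsatellite pipeline.

Two kinds of raw data flow through the pipeline:

* diploid codominant microsatellite genotypes — allele fragment sizes in
  integer base pairs, two copies per individual per locus, with an explicit
  missing marker (untyped locus);
* continuous morphological characters (lengths in cm, counts) measured on
  the same or different individuals, each individual belonging to one
  population with a management class (wild / managed / cultivated).

Derived containers hold Sturges-binned categorical character states,
symmetric labelled distance matrices, and per-character standardization
parameters.  Trees are represented as :class:`skbio.TreeNode`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Internal missing-allele sentinel (GenAlEx files use 0, STRUCTURE -9).
MISSING = -1

MANAGEMENT_CLASSES = ("wild", "managed", "cultivated")


class FormatError(ValueError):
    """A file does not follow its declared layout."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele sizes (bp).

    ``alleles`` has shape (n_individuals, n_loci, 2) with integer allele
    sizes and :data:`MISSING` for untyped copies.  Both copies of a
    genotype are either typed or missing, never mixed.
    """

    individual_ids: list[str]
    population_ids: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if len(self.population_ids) != n:
            raise ValueError("one population label per individual required")
        a, b = self.alleles[..., 0], self.alleles[..., 1]
        half_missing = (a == MISSING) ^ (b == MISSING)
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise ValueError(
                f"genotype {self.individual_ids[i]} x {self.loci[l]} has one "
                "typed and one missing allele copy"
            )
        typed = a != MISSING
        if (self.alleles[typed.nonzero()] <= 0).any():
            raise ValueError("typed allele sizes must be strictly positive")
        if len(set(self.individual_ids)) != n:
            dupes = {x for x in self.individual_ids if self.individual_ids.count(x) > 1}
            raise FormatError(f"duplicated individual ids: {sorted(dupes)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance (file) order."""
        return list(dict.fromkeys(self.population_ids))

    def population_mask(self, pop: str) -> np.ndarray:
        return np.asarray([p == pop for p in self.population_ids])

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype is untyped."""
        return self.alleles[..., 0] == MISSING

    def subset_loci(self, locus_indices) -> "GenotypeMatrix":
        idx = list(locus_indices)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            population_ids=list(self.population_ids),
            loci=[self.loci[i] for i in idx],
            alleles=self.alleles[:, idx, :].copy(),
        )


@dataclass
class TraitMatrix:
    """Individuals x continuous morphological characters.

    ``management`` maps each population label to one of
    :data:`MANAGEMENT_CLASSES`; ``values`` is (n_individuals, n_characters)
    float with NaN for missing measurements.
    """

    individual_ids: list[str]
    population_ids: list[str]
    characters: list[str]
    values: np.ndarray
    management: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, c = len(self.individual_ids), len(self.characters)
        if self.values.shape != (n, c):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {c})")
        if len(self.population_ids) != n:
            raise ValueError("one population label per individual required")
        if np.isinf(self.values).any():
            raise ValueError("trait values must be finite")
        for pop, cls in self.management.items():
            if cls not in MANAGEMENT_CLASSES:
                raise ValueError(f"unknown management class {cls!r} for {pop!r}")
        # no character entirely missing within a population
        for pop in self.populations:
            mask = self.population_mask(pop)
            all_nan = np.isnan(self.values[mask]).all(axis=0)
            if all_nan.any():
                j = int(np.argmax(all_nan))
                raise ValueError(
                    f"character {self.characters[j]!r} entirely missing in "
                    f"population {pop!r}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.population_ids))

    def population_mask(self, pop: str) -> np.ndarray:
        return np.asarray([p == pop for p in self.population_ids])

    def management_labels(self) -> list[str]:
        """Per-individual management class (requires ``management`` filled)."""
        return [self.management[p] for p in self.population_ids]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.individual_ids, columns=self.characters)
        df.insert(0, "population", self.population_ids)
        return df


@dataclass
class StandardizationParams:
    """Per-character location/scale: a = mean, b = standard deviation.

    Characters with zero spread (b == 0) are listed in ``degenerate`` and
    excluded from ``characters`` rather than silently dropped.
    """

    characters: list[str]
    a: np.ndarray
    b: np.ndarray
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (self.b > 0).all():
            raise ValueError("retained characters must have b > 0")

    def apply(self, t: TraitMatrix) -> TraitMatrix:
        """Standardize ``t`` with these stored parameters (reusable on new data)."""
        cols = [t.characters.index(c) for c in self.characters]
        vals = (t.values[:, cols] - self.a) / self.b
        return TraitMatrix(
            individual_ids=list(t.individual_ids),
            population_ids=list(t.population_ids),
            characters=list(self.characters),
            values=vals,
            management=dict(t.management),
        )


@dataclass
class CategoricalMatrix:
    """Individuals x characters in discrete Sturges classes (1..s_c).

    ``states`` is integer (n, c) with 0 for missing; ``n_states`` gives s_c
    per character and ``bin_edges`` records the class boundaries used, so
    the categorization is reproducible.
    """

    individual_ids: list[str]
    population_ids: list[str]
    characters: list[str]
    states: np.ndarray
    n_states: np.ndarray
    bin_edges: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.n_states = np.asarray(self.n_states, dtype=np.int64)
        if (self.n_states < 1).any():
            raise ValueError("each character needs s_c >= 1")
        bad = (self.states < 0) | (self.states > self.n_states[None, :])
        if bad.any():
            raise ValueError("states must lie in 0 (missing) .. s_c")

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.population_ids))

    def population_mask(self, pop: str) -> np.ndarray:
        return np.asarray([p == pop for p in self.population_ids])


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal.

    ``statistic`` names what the entries are (``"PDI"``, ``"nei_D"``,
    ``"chord_DC"``, ``"fst"``, ``"euclidean"``).  Infinite entries (e.g.
    Nei D with no shared states) are permitted but flagged via
    :meth:`infinite_pairs`.
    """

    labels: list[str]
    values: np.ndarray
    statistic: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("square matrix required")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if (self.values[finite] < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def infinite_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isinf(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)
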