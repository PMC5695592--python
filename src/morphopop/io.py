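"""Readers and writers for the standard file formats the pipeline touches.

Supported formats:

* GenAlEx codominant CSV (diploid microsatellite genotypes; 0 = missing)
* STRUCTURE two-rows-per-individual input (-9 = missing)
* TSV trait tables (individual, population, [management,] characters...)
* PHYLIP square distance matrices
* Newick trees (via scikit-bio), with bootstrap supports as internal-node
  labels or in square brackets

Every reader/writer pair is a lossless round trip; readers reject malformed
files with errors that name the offending row/column.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .datamodel import (
    MISSING,
    CategoricalMatrix,
    DistanceMatrix,
    FormatError,
    GenotypeMatrix,
    TraitMatrix,
)

# ---------------------------------------------------------------------------
# GenAlEx codominant CSV
# ---------------------------------------------------------------------------


def read_genalex(path) -> GenotypeMatrix:
    """Read a GenAlEx codominant genotype CSV.

    Layout: row 1 = n_loci, n_samples, n_pops, per-population sizes;
    row 2 = title / population names (ignored); row 3 = header with the
    locus names in every other column starting at column 3; then one row
    per individual: sample id, population, two allele columns per locus.
    0 encodes a missing allele.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 4:
        raise FormatError(f"{path}: GenAlEx file needs >= 4 rows")
    head = rows[0]
    try:
        n_loci = int(head[0])
        n_samples = int(head[1])
        n_pops = int(head[2])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad GenAlEx header row: {head!r}") from exc
    header = rows[2]
    loci = [header[2 + 2 * l].strip() for l in range(n_loci)]
    if any(not name for name in loci):
        raise FormatError(f"{path}: empty locus name in header row 3")

    data = [r for r in rows[3:] if any(cell.strip() for cell in r)]
    if len(data) != n_samples:
        raise FormatError(
            f"{path}: declared {n_samples} samples but found {len(data)} data rows"
        )
    ids, pops = [], []
    alleles = np.full((n_samples, n_loci, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(data):
        row = [c.strip() for c in row]
        # trailing empty cells from spreadsheet export are tolerated
        while row and row[-1] == "":
            row.pop()
        n_allele_cols = len(row) - 2
        if n_allele_cols != 2 * n_loci:
            raise FormatError(
                f"{path}: row {i + 4} ({row[0] if row else '?'}) has "
                f"{n_allele_cols} allele columns, expected {2 * n_loci}"
            )
        ids.append(row[0])
        pops.append(row[1])
        for l in range(n_loci):
            a, b = row[2 + 2 * l], row[3 + 2 * l]
            try:
                a, b = int(a), int(b)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: row {i + 4}, locus {loci[l]}: non-integer allele "
                    f"({a!r}, {b!r})"
                ) from exc
            if (a == 0) != (b == 0):
                raise FormatError(
                    f"{path}: row {i + 4}, locus {loci[l]}: half-missing genotype"
                )
            if a != 0:
                alleles[i, l] = (a, b)
    g = GenotypeMatrix(ids, pops, loci, alleles)
    if len(g.populations) != n_pops:
        raise FormatError(
            f"{path}: declared {n_pops} populations but found {len(g.populations)}"
        )
    return g


def write_genalex(g: GenotypeMatrix, path, title: str = "morphopop export") -> None:
    pops = g.populations
    sizes = [sum(p == pop for p in g.population_ids) for pop in pops]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([g.n_loci, g.n_individuals, len(pops), *sizes])
        w.writerow([title, "", *pops])
        header = ["Sample", "Pop"]
        for locus in g.loci:
            header += [locus, ""]
        w.writerow(header)
        for i, (ind, pop) in enumerate(zip(g.individual_ids, g.population_ids)):
            row = [ind, pop]
            for l in range(g.n_loci):
                a, b = g.alleles[i, l]
                row += [0, 0] if a == MISSING else [int(a), int(b)]
            w.writerow(row)


# ---------------------------------------------------------------------------
# STRUCTURE two-row format
# ---------------------------------------------------------------------------


def write_structure(g: GenotypeMatrix, path) -> None:
    """Write STRUCTURE input: two rows per individual, -9 = missing.

    Columns: individual id, integer population code (1-based in file
    order), then one allele column per locus.
    """
    pop_code = {p: k + 1 for k, p in enumerate(g.populations)}
    with open(path, "w") as fh:
        fh.write("\t".join(g.loci) + "\n")
        for i, (ind, pop) in enumerate(zip(g.individual_ids, g.population_ids)):
            for copy in (0, 1):
                row = [ind, str(pop_code[pop])]
                for l in range(g.n_loci):
                    a = g.alleles[i, l, copy]
                    row.append("-9" if a == MISSING else str(int(a)))
                fh.write("\t".join(row) + "\n")


def read_structure(path) -> GenotypeMatrix:
    """Read the two-row STRUCTURE files written by :func:`write_structure`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    loci = lines[0].split("\t")
    body = [ln.split("\t") for ln in lines[1:]]
    if len(body) % 2:
        raise FormatError(f"{path}: odd number of data rows for diploid data")
    ids, pops = [], []
    alleles = np.full((len(body) // 2, len(loci), 2), MISSING, dtype=np.int64)
    for i in range(0, len(body), 2):
        r0, r1 = body[i], body[i + 1]
        if r0[0] != r1[0]:
            raise FormatError(
                f"{path}: rows {i + 2}/{i + 3} pair ids {r0[0]!r} and {r1[0]!r}"
            )
        if len(r0) != len(loci) + 2 or len(r1) != len(loci) + 2:
            raise FormatError(f"{path}: row for {r0[0]!r} has wrong column count")
        ids.append(r0[0])
        pops.append(r0[1])
        for l in range(len(loci)):
            a, b = int(r0[2 + l]), int(r1[2 + l])
            if (a == -9) != (b == -9):
                raise FormatError(f"{path}: half-missing genotype for {r0[0]!r}")
            if a != -9:
                alleles[i // 2, l] = (a, b)
    return GenotypeMatrix(ids, pops, loci, alleles)


# ---------------------------------------------------------------------------
# Trait TSV
# ---------------------------------------------------------------------------

_META_COLS = ("individual", "population", "management")


def read_traits(path) -> TraitMatrix:
    """Read a TSV trait table.

    Columns: ``individual``, ``population``, optional ``management``,
    then one numeric column per character.  Empty cells are missing (NaN).
    """
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        rows = [r for r in reader if any(c.strip() for c in r)]
    lowered = [h.strip().lower() for h in header]
    if lowered[:2] != ["individual", "population"]:
        raise FormatError(
            f"{path}: first two columns must be 'individual' and 'population'"
        )
    has_mgmt = len(lowered) > 2 and lowered[2] == "management"
    first_char = 3 if has_mgmt else 2
    characters = header[first_char:]
    ids, pops, mgmt = [], [], {}
    values = np.full((len(rows), len(characters)), np.nan)
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {i + 2} has {len(row)} columns, expected {len(header)}"
            )
        ids.append(row[0])
        pops.append(row[1])
        if has_mgmt:
            mgmt[row[1]] = row[2]
        for j, cell in enumerate(row[first_char:]):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2}, "
                    f"column {characters[j]!r}"
                ) from exc
    return TraitMatrix(ids, pops, characters, values, management=mgmt)


def write_traits(t: TraitMatrix, path) -> None:
    has_mgmt = bool(t.management)
    with open(path, "w") as fh:
        header = ["individual", "population"]
        if has_mgmt:
            header.append("management")
        fh.write("\t".join(header + t.characters) + "\n")
        for i, (ind, pop) in enumerate(zip(t.individual_ids, t.population_ids)):
            row = [ind, pop]
            if has_mgmt:
                row.append(t.management[pop])
            for v in t.values[i]:
                row.append("" if np.isnan(v) else repr(float(v)))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix
# ---------------------------------------------------------------------------


def write_phylip_dist(d: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(d.labels)}\n")
        for label, row in zip(d.labels, d.values):
            name = label[:10].ljust(10)
            fh.write(name + "  " + "  ".join(repr(float(x)) for x in row) + "\n")


def read_phylip_dist(path, statistic: str = "") -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    if len(lines) - 1 != n:
        raise FormatError(f"{path}: declared {n} taxa but found {len(lines) - 1} rows")
    labels, values = [], np.zeros((n, n))
    for i, ln in enumerate(lines[1:]):
        name = ln[:10].strip()
        fields = ln[10:].split()
        if len(fields) != n:
            raise FormatError(f"{path}: row {i + 2} has {len(fields)} entries, expected {n}")
        labels.append(name)
        values[i] = [float(x) for x in fields]
    return DistanceMatrix(labels, values, statistic=statistic)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def write_newick(tree: TreeNode, path, support_style: str = "label") -> None:
    """Write a tree as Newick.

    ``support_style='label'`` puts bootstrap supports (if present as
    ``node.support``) in the internal-node label position; ``'bracket'``
    appends them in square-bracket comments after the branch length.
    """
    if support_style == "label":
        buf = _io.StringIO()
        tree.write(buf, format="newick")  # skbio emits node.support as label
        Path(path).write_text(buf.getvalue())
        return
    if support_style != "bracket":
        raise ValueError(f"unknown support_style {support_style!r}")
    t = tree.copy()
    supports = []
    for node in t.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None and node.length is not None:
            supports.append((f":{node.length:g}", f":{node.length:g}[{sup:g}]"))
        node.support = None
    buf = _io.StringIO()
    t.write(buf, format="newick")
    text = buf.getvalue()
    for old, new in supports:
        text = text.replace(old, new, 1)
    Path(path).write_text(text)


def read_newick(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tree.assign_supports()  # internal-node labels -> node.support
    return tree


# ---------------------------------------------------------------------------
# Categorical matrix TSV (pipeline intermediate)
# ---------------------------------------------------------------------------


def write_categorical(c: CategoricalMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["individual", "population"] + c.characters) + "\n")
        fh.write(
            "\t".join(["#n_states", ""] + [str(int(s)) for s in c.n_states]) + "\n"
        )
        for i, (ind, pop) in enumerate(zip(c.individual_ids, c.population_ids)):
            fh.write(
                "\t".join([ind, pop] + [str(int(s)) for s in c.states[i]]) + "\n"
            )
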