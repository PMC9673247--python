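"""Orthogroup tables: parsing, single-copy filtering, expression joins,
and presence/absence (Venn) summaries.

Cross-species expression comparison is only meaningful between genes with a
one-to-one correspondence in every species, so analysis is restricted to
*orthogenes*: orthogroups containing exactly one gene in each species.
Orthogroups with paralogs (more than one gene in any species) or missing
species are dropped.  The orthogene keeps the orthogroup ID as its row
identifier, with a sidecar map back to each species' gene IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = [
    "OrthogroupTable",
    "read_orthogroups",
    "write_orthogroups",
    "filter_single_copy",
    "join_expression",
    "presence_venn",
]


@dataclass
class OrthogroupTable:
    """orthogroup_id -> (species -> gene list), with a fixed species order."""

    species_list: list[str]
    groups: dict[str, dict[str, list[str]]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            og: {sp: ", ".join(genes.get(sp, [])) for sp in self.species_list}
            for og, genes in self.groups.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index", columns=self.species_list)
        df.index.name = "Orthogroup"
        return df


def _split_genes(cell: str) -> list[str]:
    cell = cell.strip()
    if not cell:
        return []
    return [g.strip() for g in cell.split(",") if g.strip()]


def read_orthogroups(path, species_columns: list[str] | None = None) -> OrthogroupTable:
    """Parse an orthogroup TSV (header ``Orthogroup\\t<sp1>\\t<sp2>...``).

    Cells hold comma(+space)-separated gene lists; empty cells mean the
    species is absent from the orthogroup.  ``species_columns`` restricts
    parsing to the named columns (extra non-species columns, e.g. from
    hierarchical orthogroup variants, are then ignored).

    Raises
    ------
    ValueError
        On ragged rows or duplicate orthogroup IDs, citing the line number.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2:
            raise ValueError("orthogroup table needs an ID column plus species columns")
        all_species = cols[1:]
        if species_columns is None:
            species = list(all_species)
        else:
            unknown = [s for s in species_columns if s not in all_species]
            if unknown:
                raise ValueError(f"species columns not in table header: {unknown}")
            species = list(species_columns)
        col_idx = {sp: all_species.index(sp) + 1 for sp in species}
        groups: dict[str, dict[str, list[str]]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ValueError(
                    f"line {lineno}: expected {len(cols)} columns, found {len(fields)}"
                )
            og = fields[0].strip()
            if og in groups:
                raise ValueError(f"line {lineno}: duplicate orthogroup ID {og!r}")
            groups[og] = {sp: _split_genes(fields[col_idx[sp]]) for sp in species}
    for og, genes in groups.items():
        for sp, glist in genes.items():
            if len(set(glist)) != len(glist):
                raise ValueError(f"orthogroup {og}: duplicate gene IDs within {sp}")
    return OrthogroupTable(species_list=species, groups=groups)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def filter_single_copy(table: OrthogroupTable, species_list: list[str] | None = None) -> OrthogroupTable:
    """Keep exactly the orthogroups with one gene in every listed species.

    This single predicate implements both the removal of orthogroups with
    paralogs and the restriction to universally present groups.  Output
    order follows the input table (deterministic); applying the filter twice
    is the identity.
    """
    if species_list is None:
        species_list = table.species_list
    unknown = [s for s in species_list if s not in table.species_list]
    if unknown:
        raise ValueError(f"unknown species: {unknown}")
    kept = {
        og: {sp: genes[sp] for sp in species_list}
        for og, genes in table.groups.items()
        if all(len(genes.get(sp, [])) == 1 for sp in species_list)
    }
    return OrthogroupTable(species_list=list(species_list), groups=kept)


def orthogene_map(table: OrthogroupTable) -> pd.DataFrame:
    """Single-copy table as a DataFrame: one gene ID per species column."""
    bad = [
        og
        for og, genes in table.groups.items()
        if any(len(genes.get(sp, [])) != 1 for sp in table.species_list)
    ]
    if bad:
        raise ValueError(f"not a single-copy table; offending orthogroups: {bad[:5]}")
    return pd.DataFrame(
        {
            sp: [table.groups[og][sp][0] for og in table.groups]
            for sp in table.species_list
        },
        index=pd.Index(list(table.groups), name="orthogroup_id"),
    )


def join_expression(
    orthoset: OrthogroupTable,
    matrices: dict[str, ExpressionMatrix],
    proxy: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Join per-species counts into one orthogene-by-all-samples matrix.

    Parameters
    ----------
    orthoset : OrthogroupTable
        A single-copy table (one gene per species per orthogroup).
    matrices : dict
        species -> ExpressionMatrix with that species' samples.
    proxy : dict, optional
        species -> species whose gene IDs index its count rows; used when
        two species were quantified against one reference annotation (e.g.
        wild tomato reads mapped to the cultivated tomato genome, so one set
        of gene IDs represents both).

    Count values are carried over bit-exactly; no normalization happens
    here.  Missing gene IDs raise with the offending IDs listed.
    """
    proxy = proxy or {}
    gmap = orthogene_map(orthoset)
    blocks = []
    metas = []
    for sp in sorted(matrices):
        expr = matrices[sp]
        id_species = proxy.get(sp, sp)
        if id_species not in gmap.columns:
            raise ValueError(f"species {id_species!r} not in orthogroup table")
        wanted = gmap[id_species].tolist()
        idx = expr.gene_ids.get_indexer(wanted)
        missing = [g for g, i in zip(wanted, idx) if i < 0]
        if missing:
            raise KeyError(
                f"gene IDs missing from {sp} counts: {missing[:10]}"
                + (" ..." if len(missing) > 10 else "")
            )
        blocks.append(expr.counts[idx])
        metas.append(expr.samples)
    joint = np.concatenate(blocks, axis=1)
    meta = pd.concat(metas, ignore_index=True)
    return ExpressionMatrix(gmap.index.copy(), meta, joint)


def presence_venn(
    table: OrthogroupTable,
    species_list: list[str] | None = None,
    single_copy_only: bool = False,
) -> dict[frozenset, int]:
    """Count orthogroups by the exact subset of species they occupy.

    With ``single_copy_only=True`` an orthogroup counts toward a species
    only when it has exactly one gene there (per-genus orthogene semantics).
    Region counts over all nonempty subsets sum to the number of orthogroups
    with at least one occupied listed species.
    """
    if species_list is None:
        species_list = table.species_list
    counts: dict[frozenset, int] = {}
    for genes in table.groups.values():
        if single_copy_only:
            present = frozenset(sp for sp in species_list if len(genes.get(sp, [])) == 1)
        else:
            present = frozenset(sp for sp in species_list if genes.get(sp, []))
        if present:
            counts[present] = counts.get(present, 0) + 1
    return counts
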