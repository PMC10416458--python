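"""Gene-level homology weights, top-u truncation, ranks and back-ranks.

The protein matrix ``V`` is projected onto genes: the weight of a gene pair
is the maximum normalized weight over all protein pairs encoded by the two
genes, ``W(X, Y) = max{ w(x, y) : x ∈ X, y ∈ Y }``.  For each gene X and
each species A (including X's own species), only the ``u`` highest-weight
homologs passing the weight and E-value thresholds are retained — the
"table of homologs".  Each retained entry is annotated with its *rank*
(position of the target in the query's per-species list) and *back-rank*
(position of the query in the target's reciprocal list, or infinity when
the query did not survive truncation on the other side).  A bidirectional
best hit (BBH) is exactly rank = back-rank = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from .scores import SparseScoreMatrix

__all__ = [
    "GeneRecord",
    "HomologEntry",
    "HomologTable",
    "gene_weight",
    "gene_pair_stats",
    "build_homolog_table",
    "assign_ranks",
]

ProteinFilter = Callable[[str, str], bool]


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with 1-based inclusive genomic coordinates."""

    gene_id: str
    species_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    protein_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass
class HomologEntry:
    """One row of the table of homologs."""

    query_gene: str
    query_species: str
    target_gene: str
    target_species: str
    weight: float
    e_value: float
    raw_score: float
    rank: int = 0
    back_rank: float = math.inf  # inf when the query is absent from the reciprocal list


def gene_pair_stats(X: GeneRecord, Y: GeneRecord, V: SparseScoreMatrix,
                    protein_filter: Optional[ProteinFilter] = None,
                    ) -> Tuple[float, float, float]:
    """(weight, e_value, raw_score) of a gene pair under max projection.

    The weight and raw score are the maxima over qualifying protein pairs;
    the E-value reported is that of the maximum-weight pair (smallest E on
    ties).  Returns (0, inf, 0) when no cell exists between any isoforms.
    """
    best_w = 0.0
    best_e = math.inf
    best_raw = 0.0
    found = False
    for x in X.protein_ids:
        for y in Y.protein_ids:
            if protein_filter is not None and not protein_filter(x, y):
                continue
            cell = V.cell(x, y)
            if cell is None or cell.normalized_weight is None:
                continue
            found = True
            w = cell.normalized_weight
            if w > best_w or (w == best_w and cell.e_value < best_e):
                best_w = w
                best_e = cell.e_value
            if cell.raw_score > best_raw:
                best_raw = cell.raw_score
    if not found:
        return 0.0, math.inf, 0.0
    return best_w, best_e, best_raw


def gene_weight(X: GeneRecord, Y: GeneRecord, V: SparseScoreMatrix,
                protein_filter: Optional[ProteinFilter] = None) -> float:
    """W(X, Y): maximum normalized protein-pair weight between two genes."""
    if not X.protein_ids or not Y.protein_ids:
        raise ValueError("gene_weight requires genes with at least one protein")
    return gene_pair_stats(X, Y, V, protein_filter)[0]


def _entry_sort_key(e: HomologEntry) -> Tuple[float, float, str]:
    # descending weight, then ascending E-value, then target gene id:
    # deterministic ranks and symmetric BBH under the symmetric W
    return (-e.weight, e.e_value, e.target_gene)


class HomologTable:
    """Top-u homolog lists per (query gene, target species), with ranks."""

    def __init__(self, genes: Iterable[GeneRecord], u: int):
        if u < 1:
            raise ValueError("u must be at least 1")
        self.u = u
        self.genes: Dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self.genes[g.gene_id] = g
        self.buckets: Dict[Tuple[str, str], List[HomologEntry]] = {}

    def bucket(self, query_gene: str, target_species: str) -> List[HomologEntry]:
        return self.buckets.get((query_gene, target_species), [])

    def entry(self, query_gene: str, target_gene: str) -> Optional[HomologEntry]:
        tg = self.genes.get(target_gene)
        if tg is None:
            return None
        for e in self.bucket(query_gene, tg.species_id):
            if e.target_gene == target_gene:
                return e
        return None

    def species(self) -> List[str]:
        return sorted({g.species_id for g in self.genes.values()})

    def genes_of_species(self, species_id: str) -> List[GeneRecord]:
        return [g for g in self.genes.values() if g.species_id == species_id]

    # -- interchange format ------------------------------------------------
    HEADER = ("query_gene", "query_species", "target_gene", "target_species",
              "weight", "e_value", "raw_score", "rank", "back_rank")

    def to_tsv(self, path: str | Path) -> None:
        """Write the table in its TSV interchange format (sorted, stable)."""
        with Path(path).open("w") as fh:
            fh.write("\t".join(self.HEADER) + "\n")
            for key in sorted(self.buckets):
                for e in self.buckets[key]:
                    back = "inf" if math.isinf(e.back_rank) else str(int(e.back_rank))
                    fh.write("\t".join([
                        e.query_gene, e.query_species, e.target_gene,
                        e.target_species, f"{e.weight:.6g}", f"{e.e_value:.6g}",
                        f"{e.raw_score:.6g}", str(e.rank), back]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, genes: Iterable[GeneRecord],
                 u: int) -> "HomologTable":
        table = cls(genes, u)
        with Path(path).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls.HEADER:
                raise ValueError(f"{path}: unexpected homolog-table header {header}")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                e = HomologEntry(
                    query_gene=f[0], query_species=f[1], target_gene=f[2],
                    target_species=f[3], weight=float(f[4]), e_value=float(f[5]),
                    raw_score=float(f[6]), rank=int(f[7]),
                    back_rank=math.inf if f[8] == "inf" else float(f[8]))
                table.buckets.setdefault((e.query_gene, e.target_species), []).append(e)
        for bucket in table.buckets.values():
            bucket.sort(key=_entry_sort_key)
        return table


def build_homolog_table(genes: Iterable[GeneRecord], V: SparseScoreMatrix,
                        u: int = 3, weight_min: float = 0.07,
                        e_value_max: float = 1e-7,
                        protein_filter: Optional[ProteinFilter] = None,
                        ) -> HomologTable:
    """Project V onto genes and truncate to the top-u homologs per species.

    An entry qualifies when its weight is strictly above ``weight_min`` and
    its E-value strictly below ``e_value_max`` (defaults 0.07 and 1e-7).
    The gene's own-species bucket keeps paralogs but never the gene itself.
    Ranks and back-ranks are assigned before returning.
    """
    table = HomologTable(genes, u)
    by_species: Dict[str, List[GeneRecord]] = {}
    for g in table.genes.values():
        by_species.setdefault(g.species_id, []).append(g)

    # restrict candidate targets to genes sharing at least one V cell:
    # enumerate via the protein->gene map instead of all gene pairs
    gene_of_protein: Dict[str, str] = {}
    for g in table.genes.values():
        for pid in g.protein_ids:
            gene_of_protein[pid] = g.gene_id
    candidates: Dict[str, set] = {}
    for (x, y) in V.cells:
        gx = gene_of_protein.get(x)
        gy = gene_of_protein.get(y)
        if gx is None or gy is None or gx == gy:
            continue
        candidates.setdefault(gx, set()).add(gy)

    for X in table.genes.values():
        per_species: Dict[str, List[HomologEntry]] = {}
        for gy in candidates.get(X.gene_id, ()):
            Y = table.genes[gy]
            w, e, raw = gene_pair_stats(X, Y, V, protein_filter)
            if w > weight_min and e < e_value_max:
                per_species.setdefault(Y.species_id, []).append(HomologEntry(
                    query_gene=X.gene_id, query_species=X.species_id,
                    target_gene=Y.gene_id, target_species=Y.species_id,
                    weight=w, e_value=e, raw_score=raw))
        for sp, entries in per_species.items():
            entries.sort(key=_entry_sort_key)
            table.buckets[(X.gene_id, sp)] = entries[:u]

    return assign_ranks(table)


def assign_ranks(table: HomologTable) -> HomologTable:
    """Assign 1-based ranks and back-ranks to every entry of the table.

    Rank is the entry's position in its (query, target-species) bucket;
    back-rank is the query's position in the target's bucket over the
    query's species, or infinity when absent there.  A BBH pair has
    rank = back-rank = 1 in both directions.
    """
    position: Dict[Tuple[str, str], int] = {}
    for (qg, _sp), entries in table.buckets.items():
        for i, e in enumerate(entries, start=1):
            e.rank = i
            position[(qg, e.target_gene)] = i
    for entries in table.buckets.values():
        for e in entries:
            e.back_rank = position.get((e.target_gene, e.query_gene), math.inf)
    return table
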