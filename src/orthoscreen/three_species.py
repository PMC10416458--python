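"""The three-species exclusion filter.

A reference gene X that has no ortholog in the upper species may still be
"reachable" there through a lower-species intermediate: X has an ortholog
X* in some fish, and X* in turn has an ortholog X*′ in an upper species.
Such a chain means X cannot safely be considered eliminated in the upper
species.  The chain is tested at several neighborhood radii (default 1, 2
and 5 Mbp); for each radius the gene gets flag 1 if *no* chain exists
(condition holds) and 0 if one does (condition broken).  Genes whose flags
are 0 at every radius are excluded; the survivors form the final list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Mapping, Sequence, Tuple

from .homology import GeneRecord, HomologTable
from .orthology import GenomeIndex, Parameters, call_presence

__all__ = ["ThreeSpeciesFlags", "three_species_flags", "apply_final_filter"]

DEFAULT_RADII: Tuple[int, ...] = (1_000_000, 2_000_000, 5_000_000)


@dataclass
class ThreeSpeciesFlags:
    """Per-radius chain flags for one reference gene.

    ``flags[i]`` is 1 when the three-species condition holds at
    ``radii[i]`` (no reference → fish → upper ortholog chain), 0 when it is
    broken there.
    """

    gene: str
    radii: Tuple[int, ...]
    flags: Tuple[int, ...]

    @property
    def excluded(self) -> bool:
        return all(f == 0 for f in self.flags)


def three_species_flags(X: GeneRecord, fish_species: Sequence[str],
                        upper_species: Sequence[str], table: HomologTable,
                        index: GenomeIndex, params: Parameters,
                        radii: Sequence[int] = DEFAULT_RADII,
                        ) -> ThreeSpeciesFlags:
    """Test the reference → fish → upper ortholog chain at each radius.

    Both links of the chain are evaluated with the same radius; the fish
    intermediate plays the reference role in the second link (its own
    neighborhood hosts the backward check's alternative search).  The flag
    for a radius is 0 iff some fish ortholog of X has an ortholog in some
    upper species at that radius.  Species iteration order cannot change
    the outcome (the chain test is existential).
    """
    flags: List[int] = []
    for r in radii:
        p_r = replace(params, radius=r)
        broken = False
        for fsp in fish_species:
            call = call_presence(X, fsp, table, index, p_r)
            if not call.present:
                continue
            Xstar = table.genes[call.ortholog]
            for usp in upper_species:
                chain = call_presence(Xstar, usp, table, index, p_r)
                if chain.present:
                    broken = True
                    break
            if broken:
                break
        flags.append(0 if broken else 1)
    return ThreeSpeciesFlags(gene=X.gene_id, radii=tuple(radii),
                             flags=tuple(flags))


def apply_final_filter(list4_genes: Sequence[GeneRecord],
                       flags: Mapping[str, ThreeSpeciesFlags],
                       ) -> List[GeneRecord]:
    """Drop genes whose chain flags are 0 at every radius.

    A gene with at least one flag equal to 1 is retained.  Genes with no
    fish ortholog at any radius have every flag 1 (vacuously no chain) and
    are always retained.
    """
    out: List[GeneRecord] = []
    for g in list4_genes:
        f = flags.get(g.gene_id)
        if f is None:
            raise KeyError(f"no three-species flags computed for {g.gene_id!r}")
        if not f.excluded:
            out.append(g)
    return out
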