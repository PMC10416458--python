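import math
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # sw_oracle importable

from orthoscreen.homology import GeneRecord, HomologEntry, HomologTable, assign_ranks
from orthoscreen.orthology import Parameters
from orthoscreen.screening import SpeciesGroup, SpeciesGroupConfig
from orthoscreen.simulate import SimConfig, simulate_dataset


def mkgene(gene_id, species, slot, seq_id="chr1", spacing=1_000_000,
           span=10_000, strand="+", proteins=None):
    """A gene occupying slot*spacing .. slot*spacing+span-1 (1-based)."""
    start = 1 + slot * spacing
    return GeneRecord(gene_id=gene_id, species_id=species, seq_id=seq_id,
                      start=start, end=start + span - 1, strand=strand,
                      protein_ids=tuple(proteins or (f"{gene_id}_p1",)))


def table_from_weights(genes, weights, u=3, weight_min=0.0,
                       e_value_max=math.inf):
    """Hand-built homolog table from a symmetric gene-pair weight map.

    ``weights``: {(gene_a, gene_b): weight} or {(a, b): (weight, raw_score)};
    each unordered pair listed once.  E-values are derived monotonically from
    the weight so tie-breaks behave as in the real pipeline.
    """
    by_id = {g.gene_id: g for g in genes}
    table = HomologTable(genes, u)
    sym = {}
    for (a, b), val in weights.items():
        w, raw = val if isinstance(val, tuple) else (val, val * 100.0)
        sym[(a, b)] = (w, raw)
        sym[(b, a)] = (w, raw)
    for (a, b), (w, raw) in sym.items():
        if not (w > weight_min):
            continue
        e = math.exp(-10.0 * w)
        if not (e < e_value_max):
            continue
        A, B = by_id[a], by_id[b]
        table.buckets.setdefault((a, B.species_id), []).append(HomologEntry(
            query_gene=a, query_species=A.species_id, target_gene=b,
            target_species=B.species_id, weight=w, e_value=e, raw_score=raw))
    for key, entries in list(table.buckets.items()):
        entries.sort(key=lambda e: (-e.weight, e.e_value, e.target_gene))
        table.buckets[key] = entries[:u]
    return assign_ranks(table)


def groups_for(sim_config: SimConfig) -> SpeciesGroupConfig:
    return SpeciesGroupConfig(
        groups=tuple(SpeciesGroup(g.name, tuple(g.species), g.role)
                     for g in sim_config.groups),
        reference=sim_config.reference)


@pytest.fixture(scope="session")
def clean_dataset():
    """Paralog-free, low-divergence, unshuffled dataset with planted losses."""
    cfg = SimConfig(
        seed=11, genes_per_genome=40, divergence=0.08,
        loss_events=(
            (("g0004", "g0012"), ("placentals",)),
            (("g0020",), ("reptiles", "birds", "primitive_mammals", "placentals")),
        ))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_params():
    return Parameters()
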