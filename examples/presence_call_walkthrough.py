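"""Anatomy of one presence call: forward check, backward check, verdict.

Builds a miniature two-species world by hand: reference gene x with
neighbor y, and in the target species a candidate xp with neighbor yp.
A reference paralog U closer to xp sits in the same neighborhood, so the
candidate is rejected under λ = 0 but survives once λ exceeds the weight
margin — the knob that separates "a strictly closer alternative exists"
from "too close to call".
"""

from orthoscreen.homology import GeneRecord, HomologEntry, HomologTable, assign_ranks
from orthoscreen.orthology import GenomeIndex, Parameters, call_presence

MBP = 1_000_000


def gene(gid, species, slot):
    start = 1 + slot * MBP
    return GeneRecord(gene_id=gid, species_id=species, seq_id="chr1",
                      start=start, end=start + 9_999, strand="+",
                      protein_ids=(f"{gid}_p",))


genes = [gene("x", "R", 0), gene("y", "R", 1), gene("U", "R", 2),
         gene("xp", "A", 0), gene("yp", "A", 1)]
weights = {("x", "xp"): 0.80, ("U", "xp"): 0.90, ("y", "yp"): 0.95}

table = HomologTable(genes, u=3)
by_id = {g.gene_id: g for g in genes}
for (a, b), w in list(weights.items()) + [((b, a), w) for (a, b), w in weights.items()]:
    A, B = by_id[a], by_id[b]
    table.buckets.setdefault((a, B.species_id), []).append(HomologEntry(
        query_gene=a, query_species=A.species_id, target_gene=b,
        target_species=B.species_id, weight=w, e_value=1e-20, raw_score=w * 100))
for bucket in table.buckets.values():
    bucket.sort(key=lambda e: (-e.weight, e.e_value, e.target_gene))
assign_ranks(table)

index = GenomeIndex(genes)
for lam in (0.0, 0.15):
    call = call_presence(by_id["x"], "A", table, index, Parameters(lam=lam))
    print(f"λ = {lam}: gene x is {call.status} in species A")
    if call.present:
        print(f"  ortholog {call.ortholog}, witnesses {call.witnesses}")
    for rej in call.rejected_candidates:
        print(f"  rejected {rej['candidate']}: {rej['reason']}"
              + (f" (alternative {rej['alternative']}, margin "
                 f"{rej['margin']:.2f})" if "alternative" in rej else ""))
# At λ=0 the paralog U (weight 0.90 vs 0.80, margin 0.10 > 0) rejects the
# candidate; at λ=0.15 the margin no longer clears the bar and xp is kept.
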