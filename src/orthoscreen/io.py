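"""Readers and writers for the package's file formats.

Proteomes travel as FASTA with the header convention
``>protein_id gene=<gene_id> species=<species_id>``; gene annotations as a
flat TSV (one row per gene, protein ids comma-separated) or GFF3; the DE
table, homolog table, presence matrix and gene lists as TSV.  All writers
emit rows in a deterministic order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de_integration import DERecord
from .homology import GeneRecord
from .orthology import PresenceCall
from .scores import ProteinRecord

__all__ = [
    "read_fasta", "write_fasta",
    "read_annotations_tsv", "write_annotations_tsv", "read_annotations_gff3",
    "write_de_table",
    "write_presence_matrix", "read_presence_matrix", "write_evidence_json",
]


# -- proteomes ---------------------------------------------------------------

def read_fasta(path: str | Path, species_id: Optional[str] = None,
               ) -> List[ProteinRecord]:
    """Read a proteome FASTA.

    Headers carry ``gene=`` and ``species=`` key-value tags; a
    ``species_id`` argument overrides (or supplies) the species tag.
    """
    records: List[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(part.split("=", 1) for part in rec.description.split()[1:]
                    if "=" in part)
        gene = tags.get("gene")
        sp = species_id or tags.get("species")
        if gene is None or sp is None:
            raise ValueError(
                f"{path}: header {rec.description!r} lacks gene=/species= tags")
        records.append(ProteinRecord(protein_id=rec.id, gene_id=gene,
                                     species_id=sp, sequence=str(rec.seq)))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id} gene={p.gene_id} species={p.species_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


# -- annotations -------------------------------------------------------------

_ANN_HEADER = ("gene_id", "species_id", "seq_id", "start", "end", "strand",
               "protein_ids")


def write_annotations_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_ANN_HEADER) + "\n")
        for g in sorted(genes, key=lambda g: (g.species_id, g.seq_id, g.start,
                                              g.gene_id)):
            fh.write("\t".join([g.gene_id, g.species_id, g.seq_id,
                                str(g.start), str(g.end), g.strand,
                                ",".join(g.protein_ids)]) + "\n")


def read_annotations_tsv(path: str | Path) -> List[GeneRecord]:
    genes: List[GeneRecord] = []
    with Path(path).open() as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != _ANN_HEADER:
            raise ValueError(f"{path}: unexpected annotation header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_ANN_HEADER):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(_ANN_HEADER)} columns, got {len(f)}")
            genes.append(GeneRecord(
                gene_id=f[0], species_id=f[1], seq_id=f[2], start=int(f[3]),
                end=int(f[4]), strand=f[5],
                protein_ids=tuple(p for p in f[6].split(",") if p)))
    return genes


def read_annotations_gff3(path: str | Path, species_id: str) -> List[GeneRecord]:
    """Read gene annotations from GFF3 (gene features with ID; CDS features
    carrying protein_id, or mRNA IDs as a fallback protein mapping)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: List[GeneRecord] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        protein_ids: List[str] = []
        for child in db.children(feat, featuretype="CDS"):
            pid = child.attributes.get("protein_id", [None])[0]
            if pid and pid not in protein_ids:
                protein_ids.append(pid)
        if not protein_ids:
            for child in db.children(feat, featuretype="mRNA"):
                mid = child.attributes.get("ID", [None])[0]
                if mid and mid not in protein_ids:
                    protein_ids.append(mid)
        genes.append(GeneRecord(
            gene_id=gene_id, species_id=species_id, seq_id=feat.seqid,
            start=feat.start, end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            protein_ids=tuple(protein_ids)))
    return genes


# -- DE table ----------------------------------------------------------------

def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tcontrast\tlogFC\tFDR\n")
        for r in sorted(records, key=lambda r: (r.gene_id, r.contrast)):
            fh.write(f"{r.gene_id}\t{r.contrast}\t{r.logFC:.6g}\t{r.FDR:.6g}\n")


# -- presence matrix ---------------------------------------------------------

def write_presence_matrix(calls: Mapping[Tuple[str, str], PresenceCall],
                          path: str | Path) -> None:
    """Presence TSV: one row per (reference gene, species)."""
    with Path(path).open("w") as fh:
        fh.write("ref_gene\tspecies\tstatus\tortholog\n")
        for key in sorted(calls):
            c = calls[key]
            fh.write(f"{c.ref_gene}\t{c.species}\t{c.status}\t{c.ortholog or ''}\n")


def read_presence_matrix(path: str | Path) -> Dict[Tuple[str, str], PresenceCall]:
    calls: Dict[Tuple[str, str], PresenceCall] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["ref_gene", "species", "status", "ortholog"]:
            raise ValueError(f"{path}: unexpected presence-matrix header")
        for line in fh:
            g, sp, status, orth = line.rstrip("\n").split("\t")
            calls[(g, sp)] = PresenceCall(ref_gene=g, species=sp, status=status,
                                          ortholog=orth or None)
    return calls


def write_evidence_json(calls: Mapping[Tuple[str, str], PresenceCall],
                        path: str | Path) -> None:
    """Audit sidecar: witnesses and rejection traces per call."""
    payload = {}
    for (g, sp) in sorted(calls):
        c = calls[(g, sp)]
        payload[f"{g}|{sp}"] = {
            "status": c.status,
            "ortholog": c.ortholog,
            "witnesses": [list(w) for w in c.witnesses],
            "rejected_candidates": c.rejected_candidates,
        }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
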