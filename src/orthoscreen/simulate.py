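"""Synthetic multi-species gene sets with planted orthology and losses.

The generator lays an ancestral set of random peptide genes on chromosomes
at fixed spacing, then derives each extant species independently (a star
phylogeny): planted per-group gene losses, optional tandem paralog
duplications with extra divergence, per-site amino-acid substitutions at a
configurable rate, and optional local gene-order shuffles.  Every emitted
gene is tracked in a truth table, so downstream presence calls, group
counts and final lists can be checked against ground truth.

The module also houses an *independent* brute-force re-implementation of
the presence/absence decision (:func:`oracle_presence`) that shares only
the pairwise aligner with the main pipeline: all protein pairs are aligned
exhaustively, homolog lists are fully sorted and truncated from scratch,
and witnesses and backward alternatives are enumerated without any of the
pipeline's indexing shortcuts.  It refuses datasets large enough that the
exhaustive enumeration would be meaningless as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np

from .de_integration import DERecord
from .homology import GeneRecord
from .scores import ProteinRecord, align_raw_score, surrogate_evalue

__all__ = [
    "SimGroup",
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_dataset",
    "simulate_de_table",
    "oracle_presence",
]

# Amino acids ordered as in BLOSUM62, with their background frequencies
# (Robinson & Robinson composition, as used by protein search tools).
_AA = "ARNDCQEGHILKMFPSTWYV"
_AA_FREQ = np.array([
    0.07805, 0.05129, 0.04487, 0.05364, 0.01925, 0.04264, 0.06295, 0.07377,
    0.02199, 0.05142, 0.09019, 0.05744, 0.02243, 0.03856, 0.05203, 0.07120,
    0.05841, 0.01330, 0.03216, 0.06441,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def _blosum62_substitution_rows() -> np.ndarray:
    """Substitution distribution per source residue: P(b | a) ∝ exp(score),
    excluding the identity, over the BLOSUM62 row of a."""
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    n = len(_AA)
    rows = np.zeros((n, n))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            if i != j:
                rows[i, j] = math.exp(float(m[a][b]))
        rows[i] /= rows[i].sum()
    return rows


_SUB_ROWS = _blosum62_substitution_rows()
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


@dataclass(frozen=True)
class SimGroup:
    """A species group of the simulated study design."""

    name: str
    role: str  # "lower" | "middle" | "upper"
    species: Tuple[str, ...]


def _default_groups() -> Tuple[SimGroup, ...]:
    # A desk-scale mirror of a lost-gene screen's study design: a
    # well-annotated lower-group reference, sibling lower species (the
    # "fish"), middle taxa, and upper taxa in which losses are sought.
    return (
        SimGroup("fish", "lower", ("fish1", "fish2")),
        SimGroup("amphibians", "lower", ("ref",)),
        SimGroup("reptiles", "middle", ("rep1",)),
        SimGroup("birds", "middle", ("bird1",)),
        SimGroup("primitive_mammals", "middle", ("pmam1",)),
        SimGroup("placentals", "upper", ("plac1", "plac2")),
    )


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of the synthetic dataset.

    ``loss_events`` plants losses: each (gene ids, group names) pair removes
    those ancestral genes from every species of the named groups.
    ``divergence`` is the per-site substitution probability on each species'
    branch from the ancestor; ``duplication_rate`` the per-gene, per-species
    probability of a tandem paralog (which receives
    ``paralog_extra_divergence`` additional substitutions);
    ``synteny_shuffle_rate`` the per-adjacent-slot probability of a local
    order swap.  Genes sit every ``intergenic_spacing`` bp, so a 5 Mbp
    neighborhood radius spans about ten neighbors at the default spacing.
    """

    groups: Tuple[SimGroup, ...] = field(default_factory=_default_groups)
    reference: str = "ref"
    genes_per_genome: int = 60
    n_chromosomes: int = 2
    peptide_length: int = 50
    loss_events: Tuple[Tuple[Tuple[str, ...], Tuple[str, ...]], ...] = ()
    duplication_rate: float = 0.0
    divergence: float = 0.1
    paralog_extra_divergence: float = 0.1
    synteny_shuffle_rate: float = 0.0
    intergenic_spacing: int = 1_000_000
    gene_span: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("duplication_rate", self.duplication_rate),
                           ("divergence", self.divergence),
                           ("paralog_extra_divergence", self.paralog_extra_divergence),
                           ("synteny_shuffle_rate", self.synteny_shuffle_rate)):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.genes_per_genome < 1:
            raise ValueError("genes_per_genome must be >= 1")
        species = [sp for g in self.groups for sp in g.species]
        if len(species) != len(set(species)):
            raise ValueError("species groups overlap")
        if self.reference not in species:
            raise ValueError(f"reference {self.reference!r} not in any group")

    def species(self) -> List[str]:
        return [sp for g in self.groups for sp in g.species]

    def groups_of_species(self, sp: str) -> SimGroup:
        for g in self.groups:
            if sp in g.species:
                return g
        raise KeyError(sp)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    # ancestral gene -> species -> emitted ortholog gene id (None = lost)
    ortholog_map: Dict[str, Dict[str, Optional[str]]]
    # (species, paralog gene id) -> ancestral parent gene
    paralogs: Dict[Tuple[str, str], str]
    # group name -> set of ancestral genes planted as lost there
    planted_losses: Dict[str, Set[str]]

    def lost_in_species(self, anc_gene: str, species: str) -> bool:
        return self.ortholog_map[anc_gene][species] is None


@dataclass
class SimDataset:
    """A simulated dataset: proteomes, annotations and their truth."""

    config: SimConfig
    proteins: List[ProteinRecord]
    annotations: Dict[str, List[GeneRecord]]
    truth: SimTruth

    def all_genes(self) -> List[GeneRecord]:
        return [g for sp in sorted(self.annotations) for g in self.annotations[sp]]

    def reference_genes(self) -> List[GeneRecord]:
        return list(self.annotations[self.config.reference])

    def n_species(self) -> int:
        return len(self.annotations)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_AA), size=length, p=_AA_FREQ)
    return "".join(_AA[i] for i in idx)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.nonzero(hits)[0]:
        a = _AA_INDEX[out[i]]
        out[i] = _AA[rng.choice(len(_AA), p=_SUB_ROWS[a])]
    return "".join(out)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate proteomes + annotations with planted orthology and losses.

    Deterministic given ``config.seed``: two runs with the same config
    produce identical records in identical order.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species()

    # ancestral genome
    anc_ids = [f"g{i:04d}" for i in range(config.genes_per_genome)]
    anc_seq = {gid: _random_peptide(rng, config.peptide_length) for gid in anc_ids}
    per_chrom = math.ceil(config.genes_per_genome / config.n_chromosomes)
    anc_slot: Dict[str, Tuple[str, int]] = {}
    for i, gid in enumerate(anc_ids):
        chrom = f"chr{i // per_chrom + 1}"
        anc_slot[gid] = (chrom, i % per_chrom)

    # planted losses: group -> set of ancestral genes
    planted: Dict[str, Set[str]] = {g.name: set() for g in config.groups}
    known_groups = set(planted)
    for gene_set, group_set in config.loss_events:
        for gid in gene_set:
            if gid not in anc_seq:
                raise ValueError(f"loss event references unknown gene {gid!r}")
        for grp in group_set:
            if grp not in known_groups:
                raise ValueError(f"loss event references unknown group {grp!r}")
            planted[grp].update(gene_set)

    ortholog_map: Dict[str, Dict[str, Optional[str]]] = {
        gid: {} for gid in anc_ids}
    paralogs: Dict[Tuple[str, str], str] = {}
    proteins: List[ProteinRecord] = []
    annotations: Dict[str, List[GeneRecord]] = {}

    for sp in species:
        group = config.groups_of_species(sp)
        lost = planted[group.name]
        entries: List[Tuple[str, int, float, str, str]] = []  # chrom, slot, sub-slot, gene, anc
        for gid in anc_ids:
            if gid in lost:
                ortholog_map[gid][sp] = None
                continue
            gene_id = f"{sp}_{gid}"
            ortholog_map[gid][sp] = gene_id
            chrom, slot = anc_slot[gid]
            entries.append((chrom, slot, 0.0, gene_id, gid))
            if rng.random() < config.duplication_rate:
                dup_id = f"{sp}_{gid}_dup"
                paralogs[(sp, dup_id)] = gid
                entries.append((chrom, slot, 0.5, dup_id, gid))

        # local order shuffles: swap adjacent retained slots
        entries.sort(key=lambda t: (t[0], t[1], t[2]))
        if config.synteny_shuffle_rate > 0:
            i = 0
            while i < len(entries) - 1:
                same_chrom = entries[i][0] == entries[i + 1][0]
                if same_chrom and rng.random() < config.synteny_shuffle_rate:
                    entries[i], entries[i + 1] = entries[i + 1], entries[i]
                    i += 2
                else:
                    i += 1

        genes: List[GeneRecord] = []
        pos_counter: Dict[str, int] = {}
        for chrom, _slot, sub, gene_id, gid in entries:
            k = pos_counter.get(chrom, 0)
            pos_counter[chrom] = k + 1
            start = 1 + k * config.intergenic_spacing
            end = start + config.gene_span - 1
            seq = _mutate(anc_seq[gid], config.divergence, rng)
            if sub > 0:  # paralog copy diverges further
                seq = _mutate(seq, config.paralog_extra_divergence, rng)
            pid = f"{gene_id}_p1"
            proteins.append(ProteinRecord(
                protein_id=pid, gene_id=gene_id, species_id=sp, sequence=seq))
            genes.append(GeneRecord(
                gene_id=gene_id, species_id=sp, seq_id=chrom, start=start,
                end=end, strand="+" if rng.random() < 0.5 else "-",
                protein_ids=(pid,)))
        annotations[sp] = genes

    truth = SimTruth(ortholog_map=ortholog_map, paralogs=paralogs,
                     planted_losses=planted)
    return SimDataset(config=config, proteins=proteins,
                      annotations=annotations, truth=truth)


def simulate_de_table(dataset: SimDataset,
                      de_events: Mapping[str, float],
                      seed: int = 0,
                      contrast: str = "t0_vs_t1") -> List[DERecord]:
    """Emit a DE table for the reference species' genes.

    ``de_events`` maps ancestral gene ids to planted logFC values; those
    genes get a strongly significant record (FDR ~ 1e-6..1e-3), all other
    reference genes get a clearly non-significant one (FDR ≥ 0.2).
    """
    rng = np.random.default_rng(seed)
    ref = dataset.config.reference
    records: List[DERecord] = []
    for gid in sorted(dataset.truth.ortholog_map):
        gene_id = dataset.truth.ortholog_map[gid].get(ref)
        if gene_id is None:
            continue
        if gid in de_events:
            fdr = 10 ** rng.uniform(-6, -3)
            records.append(DERecord(gene_id=gene_id, contrast=contrast,
                                    logFC=float(de_events[gid]), FDR=fdr))
        else:
            fdr = rng.uniform(0.2, 1.0)
            logfc = rng.uniform(-0.5, 0.5)
            records.append(DERecord(gene_id=gene_id, contrast=contrast,
                                    logFC=float(logfc), FDR=float(fdr)))
    return records


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_GENES = 300
_ORACLE_MAX_SPECIES = 8


def oracle_presence(dataset: SimDataset, params,
                    e_value_cut: float = 0.1,
                    normalization: str = "mean",
                    ) -> Dict[Tuple[str, str], str]:
    """Exhaustive re-derivation of presence calls, independent of the
    pipeline's data structures.

    Returns (reference gene id, species) -> "present" | "absent".  Shares
    only :func:`align_raw_score`/:func:`surrogate_evalue` with the main
    implementation; everything else — matrix construction, symmetrization,
    weight projection, truncation, ranks, witness search, backward
    alternatives — is recomputed here by plain enumeration.  Refuses
    datasets beyond ~300 genes × 8 species.
    """
    cfg = dataset.config
    if cfg.genes_per_genome > _ORACLE_MAX_GENES or dataset.n_species() > _ORACLE_MAX_SPECIES:
        raise ValueError("dataset too large for the brute-force oracle")

    prots = dataset.proteins
    db_len = sum(len(p.sequence) for p in prots)

    # raw scores, all ordered pairs (score symmetric; compute once)
    raw: Dict[Tuple[str, str], float] = {}
    ev: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(prots):
        for b in prots[i:]:
            s = align_raw_score(a.sequence, b.sequence)
            e_ab = surrogate_evalue(s, len(a.sequence), db_len)
            e_ba = surrogate_evalue(s, len(b.sequence), db_len)
            self_pair = a.protein_id == b.protein_id
            if self_pair or e_ab <= e_value_cut:
                raw[(a.protein_id, b.protein_id)] = s
                ev[(a.protein_id, b.protein_id)] = e_ab
            if not self_pair and e_ba <= e_value_cut:
                raw[(b.protein_id, a.protein_id)] = s
                ev[(b.protein_id, a.protein_id)] = e_ba

    # symmetrize: max score / min E over the two directions; fill empties
    pids = [p.protein_id for p in prots]
    for x in pids:
        for y in pids:
            if x >= y:
                continue
            have_xy = (x, y) in raw
            have_yx = (y, x) in raw
            if not have_xy and not have_yx:
                continue
            s = max(raw.get((x, y), -math.inf), raw.get((y, x), -math.inf))
            e = min(ev.get((x, y), math.inf), ev.get((y, x), math.inf))
            raw[(x, y)] = raw[(y, x)] = s
            ev[(x, y)] = ev[(y, x)] = e

    def weight(x: str, y: str) -> float:
        if (x, y) not in raw:
            return 0.0
        sxx = raw.get((x, x), 0.0)
        syy = raw.get((y, y), 0.0)
        if sxx <= 0 or syy <= 0:
            return 0.0
        if normalization == "mean":
            return 2.0 * raw[(x, y)] / (sxx + syy)
        if normalization == "min":
            return raw[(x, y)] / min(sxx, syy)
        return raw[(x, y)] / max(sxx, syy)

    genes: Dict[str, GeneRecord] = {g.gene_id: g
                                    for sp in dataset.annotations
                                    for g in dataset.annotations[sp]}

    def gene_stats(X: GeneRecord, Y: GeneRecord) -> Tuple[float, float, float]:
        best_w, best_e, best_raw = 0.0, math.inf, 0.0
        found = False
        for x in X.protein_ids:
            for y in Y.protein_ids:
                if (x, y) not in raw:
                    continue
                found = True
                w = weight(x, y)
                if w > best_w or (w == best_w and ev[(x, y)] < best_e):
                    best_w, best_e = w, ev[(x, y)]
                best_raw = max(best_raw, raw[(x, y)])
        return (best_w, best_e, best_raw) if found else (0.0, math.inf, 0.0)

    # full homolog lists, truncated to top-u per (gene, species)
    all_genes = sorted(genes.values(), key=lambda g: g.gene_id)
    bucket: Dict[Tuple[str, str], List[Tuple[float, float, float, str]]] = {}
    for X in all_genes:
        for Y in all_genes:
            if X.gene_id == Y.gene_id:
                continue
            w, e, s = gene_stats(X, Y)
            if w > params.weight_min and e < params.e_value_max:
                bucket.setdefault((X.gene_id, Y.species_id), []).append(
                    (w, e, s, Y.gene_id))
    for key in bucket:
        bucket[key].sort(key=lambda t: (-t[0], t[1], t[3]))
        bucket[key] = bucket[key][:params.u]

    rank_of: Dict[Tuple[str, str], int] = {}
    for (qg, _sp), entries in bucket.items():
        for i, (_w, _e, _s, tg) in enumerate(entries, start=1):
            rank_of[(qg, tg)] = i

    def is_bbh(y: str, yp: str) -> bool:
        return rank_of.get((y, yp)) == 1 and rank_of.get((yp, y)) == 1

    def beta_ok(y: str, yp: str) -> bool:
        r = rank_of.get((y, yp))
        if r is None:
            return False
        if params.beta_condition == "bbh":
            return r == 1 and rank_of.get((yp, y)) == 1
        if params.beta_condition == "best-hit":
            return r == 1
        if params.beta_condition.startswith("top:"):
            return r <= int(params.beta_condition.split(":", 1)[1])
        raise ValueError(params.beta_condition)

    def neighbors(X: GeneRecord, radius: int) -> List[GeneRecord]:
        out = []
        for g in genes.values():
            if g.species_id != X.species_id or g.seq_id != X.seq_id:
                continue
            if g.gene_id == X.gene_id:
                continue
            if g.end >= X.start - radius and g.start <= X.end + radius:
                out.append(g)
        return out

    def synteny(X: GeneRecord, Xp: GeneRecord) -> bool:
        rX = params.radius_for(X.species_id)
        rXp = params.radius_for(Xp.species_id)
        near_X = neighbors(X, rX)
        near_Xp = {g.gene_id for g in neighbors(Xp, rXp)}
        pairs = []
        for Y in near_X:
            for (w, _e, _s, tg) in bucket.get((Y.gene_id, Xp.species_id), []):
                if tg == Xp.gene_id or tg not in near_Xp:
                    continue
                if beta_ok(Y.gene_id, tg):
                    pairs.append((w, Y.gene_id, tg))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_l: Set[str] = set()
        used_r: Set[str] = set()
        n = 0
        for _w, y, yp in pairs:
            if y in used_l or yp in used_r:
                continue
            used_l.add(y)
            used_r.add(yp)
            n += 1
            if n >= params.witnesses_required:
                return True
        return False

    def present(X: GeneRecord, sp: str) -> bool:
        for (w_XXp, _e, s_XXp, xp_id) in bucket.get((X.gene_id, sp), []):
            Xp = genes[xp_id]
            if not synteny(X, Xp):
                continue
            rejected = False
            for (w_XpU, _e2, s_XpU, u_id) in bucket.get((xp_id, X.species_id), []):
                if u_id == X.gene_id:
                    continue
                if params.backward_variant == "difference":
                    closer = (w_XpU - w_XXp) > params.lam
                else:
                    closer = s_XXp > 0 and (s_XpU / s_XXp) > params.lambda1
                if closer and synteny(genes[u_id], Xp):
                    rejected = True
                    break
            if not rejected:
                return True
        return False

    ref = cfg.reference
    calls: Dict[Tuple[str, str], str] = {}
    for X in dataset.annotations[ref]:
        for sp in cfg.species():
            if sp == ref:
                continue
            calls[(X.gene_id, sp)] = "present" if present(X, sp) else "absent"
    return calls
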