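"""Protein-pair score matrix: alignment, normalization, symmetrization.

The screen's similarity primitive is the optimal local (Smith–Waterman)
alignment score of two protein sequences under BLOSUM62 with affine gap
penalties (open 11, extend 1).  Raw scores are normalized to a dimensionless
homology weight

    w(x, y) = 2 s(x, y) / [s(x, x) + s(y, y)]

which is 1 for identical sequences and usually lies in [0, 1], though it can
slightly exceed 1 for unusual alignments; it is never clamped.  All pairwise
scores live in a sparse matrix ``V`` whose absent cells mean "no hit": raw
score 0, E-value infinity.  ``V`` is symmetrized (max score, min E-value per
unordered pair) before any downstream use.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ALPHABET",
    "ProteinRecord",
    "ScoreCell",
    "SparseScoreMatrix",
    "align_raw_score",
    "surrogate_evalue",
    "normalize_score",
    "build_protein_matrix",
    "load_score_table",
    "symmetrize_matrix",
]

#: The 20 standard amino acids plus the ambiguity code X.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_VALID_SEQ = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")

# Karlin–Altschul parameters for gapped BLOSUM62 (open 11 / extend 1), used
# by the monotone surrogate E-value of the built-in aligner path.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its gene and species of origin."""

    protein_id: str
    gene_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - AMINO_ALPHABET)
            raise ValueError(
                f"protein {self.protein_id!r}: non-amino-acid characters {bad}"
            )


@dataclass
class ScoreCell:
    """Raw alignment score and E-value for one directed protein pair."""

    raw_score: float
    e_value: float
    normalized_weight: Optional[float] = None


class SparseScoreMatrix:
    """Sparse all-vs-all protein score matrix (``V``).

    Cells are keyed by ordered ``(query_protein_id, target_protein_id)``
    pairs.  A missing cell semantically carries raw score 0 and E-value
    infinity.  Within-species pairs (including self pairs, needed for
    normalization) are first-class cells.
    """

    def __init__(self, proteins: Iterable[ProteinRecord]):
        self.proteins: Dict[str, ProteinRecord] = {}
        for p in proteins:
            if p.protein_id in self.proteins:
                raise ValueError(f"duplicate protein id {p.protein_id!r}")
            self.proteins[p.protein_id] = p
        self.cells: Dict[Tuple[str, str], ScoreCell] = {}
        self._symmetric = False

    # -- basic access ------------------------------------------------------
    def cell(self, x: str, y: str) -> Optional[ScoreCell]:
        return self.cells.get((x, y))

    def raw(self, x: str, y: str) -> float:
        c = self.cells.get((x, y))
        return c.raw_score if c is not None else 0.0

    def evalue(self, x: str, y: str) -> float:
        c = self.cells.get((x, y))
        return c.e_value if c is not None else math.inf

    def weight(self, x: str, y: str) -> float:
        c = self.cells.get((x, y))
        if c is None or c.normalized_weight is None:
            return 0.0
        return c.normalized_weight

    def set_cell(self, x: str, y: str, cell: ScoreCell) -> None:
        if x not in self.proteins or y not in self.proteins:
            missing = x if x not in self.proteins else y
            raise KeyError(f"protein id {missing!r} not in proteome set")
        self.cells[(x, y)] = cell

    def species_of(self, protein_id: str) -> str:
        return self.proteins[protein_id].species_id

    def __len__(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _make_aligner(gap_open: int = 11, gap_extend: int = 1,
                  matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # affine gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def align_raw_score(x: ProteinRecord | str, y: ProteinRecord | str,
                    aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Optimal local alignment score of two protein sequences.

    BLOSUM62, affine gaps (open 11, extend 1).  Symmetric in its arguments.
    Scores below 0 (no positive-scoring local alignment) are reported as 0.
    """
    sx = x.sequence if isinstance(x, ProteinRecord) else x
    sy = y.sequence if isinstance(y, ProteinRecord) else y
    for s in (sx, sy):
        if not s:
            raise ValueError("cannot align an empty sequence")
        if not _VALID_SEQ.match(s):
            bad = sorted(set(s) - AMINO_ALPHABET)
            raise ValueError(f"non-amino-acid characters in sequence: {bad}")
    if aligner is None:
        aligner = _DEFAULT_ALIGNER
    return float(aligner.score(sx, sy))


def surrogate_evalue(raw_score: float, query_len: int, db_len: int) -> float:
    """Monotone surrogate E-value for a raw score from the built-in aligner.

    A Karlin–Altschul-style estimate E = K·m·n·exp(−λ·S) with the gapped
    BLOSUM62 parameters (λ=0.267, K=0.041).  It is *not* numerically
    identical to BLAST's E-value (no length corrections, no sum statistics)
    but is strictly decreasing in the raw score at fixed lengths, which is
    all that thresholding and ranking downstream require.
    """
    return _KA_K * query_len * db_len * math.exp(-_KA_LAMBDA * raw_score)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_score(s_xy: float, s_xx: float, s_yy: float,
                    mode: str = "mean") -> float:
    """Normalized homology weight of a protein pair.

    ``mode`` selects the denominator: ``"mean"`` (default) gives
    2·s(x,y)/[s(x,x)+s(y,y)]; ``"min"`` and ``"max"`` divide by the smaller
    or larger self-score instead.  No clamping is applied.
    """
    if s_xx <= 0 or s_yy <= 0:
        raise ValueError("self-scores must be positive for normalization")
    if mode == "mean":
        return 2.0 * s_xy / (s_xx + s_yy)
    if mode == "min":
        return s_xy / min(s_xx, s_yy)
    if mode == "max":
        return s_xy / max(s_xx, s_yy)
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _dedup_sequences(proteins: Mapping[str, ProteinRecord]) -> Tuple[Dict[str, List[str]], Dict[str, str]]:
    """Group protein ids by identical sequence.

    Returns (sequence -> list of protein ids, protein id -> representative id).
    Identical proteins are aligned once and their cells re-expanded to every
    copy afterwards.
    """
    by_seq: Dict[str, List[str]] = {}
    for pid, rec in proteins.items():
        by_seq.setdefault(rec.sequence, []).append(pid)
    rep_of: Dict[str, str] = {}
    for pids in by_seq.values():
        rep = pids[0]
        for pid in pids:
            rep_of[pid] = rep
    return by_seq, rep_of


def build_protein_matrix(proteomes: Iterable[ProteinRecord],
                         e_value_cut: float = 0.1,
                         source: str = "aligner",
                         score_table: Optional[str | Path] = None,
                         aligner: Optional[Align.PairwiseAligner] = None,
                         ) -> SparseScoreMatrix:
    """Build the sparse all-vs-all protein score matrix ``V``.

    ``source="aligner"`` aligns every protein pair (within and across
    species) with the built-in local aligner, deduplicating identical
    sequences first, and keeps a cell whenever its surrogate E-value is at
    most ``e_value_cut``.  Self cells are always kept (they anchor the
    normalization).  ``source="precomputed"`` instead loads a TSV of
    ``query_protein  target_protein  raw_score  e_value`` rows produced by
    an external search tool and applies the same E-value cut.

    The returned matrix is *not* yet symmetrized and carries no normalized
    weights; call :func:`symmetrize_matrix` next.
    """
    V = SparseScoreMatrix(proteomes)
    species = {p.species_id for p in V.proteins.values()}
    if len(species) < 2:
        raise ValueError("need proteomes from at least two species")

    if source == "precomputed":
        if score_table is None:
            raise ValueError("source='precomputed' requires score_table")
        load_score_table(V, score_table, e_value_cut=e_value_cut)
        return V
    if source != "aligner":
        raise ValueError(f"unknown source {source!r}")

    by_seq, rep_of = _dedup_sequences(V.proteins)
    reps = [pids[0] for pids in by_seq.values()]
    seqs = {rep: V.proteins[rep].sequence for rep in reps}
    db_len = sum(len(p.sequence) for p in V.proteins.values())

    rep_cells: Dict[Tuple[str, str], ScoreCell] = {}
    for i, rx in enumerate(reps):
        sx = seqs[rx]
        for ry in reps[i:]:
            sy = seqs[ry]
            s = align_raw_score(sx, sy, aligner)
            e_xy = surrogate_evalue(s, len(sx), db_len)
            e_yx = surrogate_evalue(s, len(sy), db_len)
            self_pair = rx == ry
            if self_pair or e_xy <= e_value_cut:
                rep_cells[(rx, ry)] = ScoreCell(s, e_xy)
            if not self_pair and e_yx <= e_value_cut:
                rep_cells[(ry, rx)] = ScoreCell(s, e_yx)

    # re-expand deduplicated cells to every identical copy; the self-cell
    # exemption from the E-value cut applies only to true self pairs
    copies = {rep: pids for pids in by_seq.values() for rep in [pids[0]]}
    for (rx, ry), cell in rep_cells.items():
        for px in copies[rx]:
            for py in copies[ry]:
                if px != py and cell.e_value > e_value_cut:
                    continue
                V.cells[(px, py)] = ScoreCell(cell.raw_score, cell.e_value)
    # self cells for every copy (the rep loop only covers rep-rep)
    for pids in by_seq.values():
        rep = pids[0]
        c = rep_cells[(rep, rep)]
        for pid in pids:
            V.cells[(pid, pid)] = ScoreCell(c.raw_score, c.e_value)
    return V


def load_score_table(V: SparseScoreMatrix, path: str | Path,
                     e_value_cut: float = 0.1) -> None:
    """Load precomputed hits (query, target, raw_score, e_value TSV) into V.

    Matches the tabular output convention of protein search tools
    (`qseqid sseqid score evalue`).  Self hits are kept regardless of the
    E-value cut.  Unknown protein ids raise.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            q, t, s, e = parts[0], parts[1], float(parts[2]), float(parts[3])
            for pid in (q, t):
                if pid not in V.proteins:
                    raise KeyError(f"{path}:{lineno}: protein id {pid!r} not in proteomes")
            if q == t or e <= e_value_cut:
                V.cells[(q, t)] = ScoreCell(s, e)


def symmetrize_matrix(V: SparseScoreMatrix,
                      normalization: str = "mean") -> SparseScoreMatrix:
    """Symmetrize ``V`` in place and (re)compute normalized weights.

    For every unordered pair with at least one cell present, both directed
    cells receive the larger raw score and the smaller E-value; a single
    empty direction is filled from the other.  Weights are then recomputed
    from the symmetrized raw scores, so the operation is idempotent.
    Proteins lacking a positive self-score get weight 0 against everything.
    """
    for (x, y) in list(V.cells.keys()):
        if x >= y:
            continue
        a = V.cells.get((x, y))
        b = V.cells.get((y, x))
        if a is None and b is None:
            continue
        raw = max(c.raw_score for c in (a, b) if c is not None)
        ev = min(c.e_value for c in (a, b) if c is not None)
        V.cells[(x, y)] = ScoreCell(raw, ev)
        V.cells[(y, x)] = ScoreCell(raw, ev)
    # catch pairs present only in the (y, x) > (x, y) direction
    for (x, y) in list(V.cells.keys()):
        if x > y and (y, x) not in V.cells:
            c = V.cells[(x, y)]
            V.cells[(y, x)] = ScoreCell(c.raw_score, c.e_value)

    for (x, y), cell in V.cells.items():
        s_xx = V.raw(x, x)
        s_yy = V.raw(y, y)
        if s_xx > 0 and s_yy > 0:
            cell.normalized_weight = normalize_score(
                cell.raw_score, s_xx, s_yy, mode=normalization)
        else:
            cell.normalized_weight = 0.0
    V._symmetric = True
    return V
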