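"""Independent quadratic-space Smith–Waterman (Gotoh) oracle.

A deliberately naive affine-gap local-alignment DP used only to cross-check
the package's aligner backend.  A gap of length k costs open + k * extend
(BLAST convention), so the first gap residue costs open + extend.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local alignment score, straightforward O(n·m) Gotoh DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    first = gap_open + gap_extend  # cost of opening a gap of length 1
    # H: best ending in a match/mismatch; E: gap in b (insertion in a);
    # F: gap in a.  Local: floor at 0 applies to H only.
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            sub = float(_B62[a[i - 1]][b[j - 1]])
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
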