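"""Differential-expression table consumption and list intersection.

The DE statistics themselves (exact tests, GLMs, normalization) are the
business of edgeR/DESeq2-class tools; this module consumes their output —
a TSV of (gene, contrast, logFC, FDR) rows — filters it into the DE gene
list by an FDR ceiling and an effect-size floor θ = |logFC|, and intersects
the result with the loss screen's gene list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

__all__ = ["DERecord", "load_de_table", "filter_de", "intersect_lists"]

REQUIRED_COLUMNS = ("gene_id", "contrast", "logFC", "FDR")


@dataclass(frozen=True)
class DERecord:
    """One differential-expression test result for a gene and contrast."""

    gene_id: str
    contrast: str
    logFC: float  # binary-log fold change
    FDR: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.FDR <= 1.0):
            raise ValueError(
                f"{self.gene_id}/{self.contrast}: FDR {self.FDR} outside [0, 1]")


def load_de_table(path: str | Path) -> List[DERecord]:
    """Load a DE table (TSV with gene_id, contrast, logFC, FDR columns).

    Malformed rows are reported with their line numbers; a header-only file
    yields an empty list.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contrast": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: List[DERecord] = []
    errors: List[str] = []
    seen: Set[Tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            rec = DERecord(gene_id=str(row.gene_id), contrast=str(row.contrast),
                           logFC=float(row.logFC), FDR=float(row.FDR))
        except (TypeError, ValueError) as exc:
            errors.append(f"{path}:{i}: {exc}")
            continue
        key = (rec.gene_id, rec.contrast)
        if key in seen:
            errors.append(f"{path}:{i}: duplicate (gene, contrast) {key}")
            continue
        seen.add(key)
        records.append(rec)
    if errors:
        raise ValueError("malformed DE rows:\n" + "\n".join(errors))
    return records


def filter_de(records: Iterable[DERecord], fdr_max: float = 0.01,
              theta_min: float = 0.0,
              glm_records: Optional[Iterable[DERecord]] = None,
              ) -> Dict[str, float]:
    """Select DE genes: FDR strictly below ``fdr_max`` and |logFC| at least
    ``theta_min`` in at least one contrast.

    Returns gene → logFC of the gene's maximum-|logFC| qualifying record.
    If a second table from an independent model is supplied
    (``glm_records``), a gene must qualify in both (per gene, not per
    contrast) to be kept.
    """
    if not (0.0 < fdr_max <= 1.0):
        raise ValueError("fdr_max must be in (0, 1]")
    if theta_min < 0:
        raise ValueError("theta_min must be non-negative")

    def best_hits(recs: Iterable[DERecord]) -> Dict[str, float]:
        best: Dict[str, float] = {}
        for r in recs:
            if r.FDR < fdr_max and abs(r.logFC) >= theta_min:
                if r.gene_id not in best or abs(r.logFC) > abs(best[r.gene_id]):
                    best[r.gene_id] = r.logFC
        return best

    hits = best_hits(records)
    if glm_records is not None:
        confirmed = best_hits(glm_records)
        hits = {g: fc for g, fc in hits.items() if g in confirmed}
    return hits


def intersect_lists(loss_genes: Sequence[str],
                    de_genes: Dict[str, float],
                    ) -> Tuple[List[Tuple[str, float]], int, int]:
    """Genes common to the loss list and the DE list.

    Returns (rows, n_up, n_down) where rows are (gene, logFC) in descending
    logFC order (upregulated first) and the counts partition the rows by
    logFC sign.  Zero logFC counts as neither up nor down.
    """
    common = [g for g in loss_genes if g in de_genes]
    rows = sorted(((g, de_genes[g]) for g in common),
                  key=lambda t: (-t[1], t[0]))
    n_up = sum(1 for _g, fc in rows if fc > 0)
    n_down = sum(1 for _g, fc in rows if fc < 0)
    return rows, n_up, n_down
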