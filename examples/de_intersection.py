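"""Filtering a differential-expression table and intersecting lists.

Writes a small DE table, filters it at FDR < 0.01 with an effect-size
floor θ = |logFC| ≥ 1, and intersects the survivors with a loss list.
"""

import tempfile
from pathlib import Path

from orthoscreen import filter_de, intersect_lists, load_de_table

table = """gene_id\tcontrast\tlogFC\tFDR
geneA\tt0_vs_6h\t3.2\t0.0004
geneA\t6h_vs_24h\t-1.1\t0.2
geneB\tt0_vs_6h\t-2.4\t0.002
geneC\tt0_vs_6h\t0.6\t0.001
geneD\tt0_vs_6h\t4.0\t0.05
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "de.tsv"
    path.write_text(table)
    records = load_de_table(path)

de_genes = filter_de(records, fdr_max=0.01, theta_min=1.0)
print("DE genes (FDR < 0.01, |logFC| >= 1):", de_genes)
# geneC fails the effect-size floor, geneD the FDR cut; geneA reports its
# strongest qualifying contrast (+3.2).

loss_list = ["geneA", "geneB", "geneX"]
rows, n_up, n_down = intersect_lists(loss_list, de_genes)
print("lost AND differentially expressed:", rows)
print(f"{n_up} upregulated, {n_down} downregulated")
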