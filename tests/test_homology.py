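"""Gene-level weight projection, top-u truncation, ranks and back-ranks."""

import math
import random

import pytest

from orthoscreen.homology import HomologTable, build_homolog_table, gene_weight
from orthoscreen.scores import ProteinRecord, build_protein_matrix, symmetrize_matrix
from conftest import mkgene, table_from_weights
from sw_oracle import sw_score

AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestGeneWeight:
    def _fake_V(self, weights):
        """Minimal stand-in matrix exposing cell lookups."""
        from orthoscreen.scores import ScoreCell, SparseScoreMatrix

        prots = {}
        for (x, y) in weights:
            for pid in (x, y):
                prots.setdefault(pid, ProteinRecord(pid, f"g_{pid}", "sp", "MKVLA"))
        V = SparseScoreMatrix(prots.values())
        for (x, y), (w, e) in weights.items():
            V.cells[(x, y)] = ScoreCell(raw_score=w * 100, e_value=e,
                                        normalized_weight=w)
        return V

    def test_max_over_isoform_pairs(self):
        V = self._fake_V({("x1", "y1"): (0.4, 1e-9), ("x2", "y1"): (0.7, 1e-12)})
        X = mkgene("gx", "sp1", 0, proteins=["x1", "x2"])
        Y = mkgene("gy", "sp2", 0, proteins=["y1"])
        assert gene_weight(X, Y, V) == pytest.approx(0.7)

    def test_single_isoform_equals_protein_weight(self):
        V = self._fake_V({("x1", "y1"): (0.42, 1e-9)})
        X = mkgene("gx", "sp1", 0, proteins=["x1"])
        Y = mkgene("gy", "sp2", 0, proteins=["y1"])
        assert gene_weight(X, Y, V) == pytest.approx(0.42)

    def test_no_cells_gives_zero(self):
        V = self._fake_V({("a", "b"): (0.5, 1e-9)})
        X = mkgene("gx", "sp1", 0, proteins=["a"])
        Y = mkgene("gy", "sp2", 0, proteins=["zz"])
        V.proteins["zz"] = ProteinRecord("zz", "gy", "sp2", "MKVLA")
        assert gene_weight(X, Y, V) == 0.0

    def test_protein_filter_hook(self):
        V = self._fake_V({("x1", "y1"): (0.4, 1e-9), ("x2", "y1"): (0.7, 1e-12)})
        X = mkgene("gx", "sp1", 0, proteins=["x1", "x2"])
        Y = mkgene("gy", "sp2", 0, proteins=["y1"])
        no_x2 = lambda x, y: x != "x2"
        assert gene_weight(X, Y, V, protein_filter=no_x2) == pytest.approx(0.4)


class TestTopU:
    def test_top_u_truncation(self):
        genes = [mkgene("q", "R", 0)] + [mkgene(f"t{i}", "A", i) for i in range(5)]
        weights = {("q", f"t{i}"): w
                   for i, w in enumerate([0.9, 0.8, 0.5, 0.3, 0.1])}
        table = table_from_weights(genes, weights, u=3)
        bucket = table.bucket("q", "A")
        assert [e.target_gene for e in bucket] == ["t0", "t1", "t2"]
        assert [e.weight for e in bucket] == [0.9, 0.8, 0.5]

    def test_weight_threshold_is_strict(self):
        # an entry at exactly the minimum weight is excluded
        prots = [ProteinRecord("x1", "gx", "R", "MKVLAHEAGAWGHEE"),
                 ProteinRecord("y1", "gy", "A", "MKVLAHEAGAWGHEE")]
        V = build_protein_matrix(prots, e_value_cut=10)
        symmetrize_matrix(V)
        genes = [mkgene("gx", "R", 0, proteins=["x1"]),
                 mkgene("gy", "A", 0, proteins=["y1"])]
        w = V.weight("x1", "y1")  # == 1.0
        at_exact = build_homolog_table(genes, V, u=3, weight_min=w,
                                       e_value_max=math.inf)
        assert at_exact.bucket("gx", "A") == []
        below = build_homolog_table(genes, V, u=3, weight_min=w - 1e-9,
                                    e_value_max=math.inf)
        assert [e.target_gene for e in below.bucket("gx", "A")] == ["gy"]

    def test_u_must_be_positive(self):
        with pytest.raises(ValueError):
            HomologTable([], u=0)

    def test_bucket_cardinality_never_exceeds_u(self, clean_dataset):
        from orthoscreen.scores import build_protein_matrix, symmetrize_matrix

        ds = clean_dataset
        V = symmetrize_matrix(build_protein_matrix(ds.proteins))
        for u in (1, 2, 3):
            table = build_homolog_table(ds.all_genes(), V, u=u)
            assert all(len(b) <= u for b in table.buckets.values())

    def test_threshold_monotonicity(self, clean_dataset):
        # raising weight_min never adds entries
        ds = clean_dataset
        V = symmetrize_matrix(build_protein_matrix(ds.proteins))
        loose = build_homolog_table(ds.all_genes(), V, u=3, weight_min=0.07)
        tight = build_homolog_table(ds.all_genes(), V, u=3, weight_min=0.3)
        loose_pairs = {(e.query_gene, e.target_gene)
                       for b in loose.buckets.values() for e in b}
        tight_pairs = {(e.query_gene, e.target_gene)
                       for b in tight.buckets.values() for e in b}
        assert tight_pairs <= loose_pairs

    def test_own_species_bucket_keeps_paralogs_not_self(self):
        genes = [mkgene("a", "R", 0), mkgene("a_dup", "R", 1),
                 mkgene("b", "A", 0)]
        weights = {("a", "a_dup"): 0.8, ("a", "b"): 0.9, ("a_dup", "b"): 0.7}
        table = table_from_weights(genes, weights, u=3)
        own = table.bucket("a", "R")
        assert [e.target_gene for e in own] == ["a_dup"]


class TestRanks:
    def test_mutual_best_hits_are_bbh(self):
        genes = [mkgene("x", "R", 0), mkgene("y", "A", 0),
                 mkgene("z", "A", 1)]
        table = table_from_weights(genes, {("x", "y"): 0.9, ("x", "z"): 0.5})
        e = table.entry("x", "y")
        assert (e.rank, e.back_rank) == (1, 1)
        back = table.entry("y", "x")
        assert (back.rank, back.back_rank) == (1, 1)

    def test_back_rank_infinite_when_reciprocal_list_lacks_query(self):
        # y's bucket over R is saturated by closer paralogs, dropping x
        genes = ([mkgene("x", "R", 0)]
                 + [mkgene(f"p{i}", "R", i + 1) for i in range(3)]
                 + [mkgene("y", "A", 0)])
        weights = {("x", "y"): 0.3}
        for i in range(3):
            weights[(f"p{i}", "y")] = 0.8 - 0.1 * i
        table = table_from_weights(genes, weights, u=3)
        e = table.entry("x", "y")
        assert e.rank == 1  # x's only homolog in A
        assert math.isinf(e.back_rank)

    def test_ranks_match_recomputed_sort(self):
        rng = random.Random(3)
        genes = [mkgene(f"r{i}", "R", i) for i in range(6)] + \
                [mkgene(f"a{i}", "A", i) for i in range(6)]
        weights = {}
        for i in range(6):
            for j in range(6):
                if rng.random() < 0.7:
                    weights[(f"r{i}", f"a{j}")] = round(rng.random(), 3)
        table = table_from_weights(genes, weights, u=3)
        for (qg, sp), bucket in table.buckets.items():
            expected = sorted(bucket, key=lambda e: (-e.weight, e.e_value,
                                                     e.target_gene))
            assert [e.target_gene for e in bucket] == \
                   [e.target_gene for e in expected]
            assert [e.rank for e in bucket] == list(range(1, len(bucket) + 1))

    def test_bbh_symmetry_everywhere(self, clean_dataset):
        ds = clean_dataset
        V = symmetrize_matrix(build_protein_matrix(ds.proteins))
        table = build_homolog_table(ds.all_genes(), V, u=3)
        for bucket in table.buckets.values():
            for e in bucket:
                if e.rank == 1 and e.back_rank == 1:
                    mirror = table.entry(e.target_gene, e.query_gene)
                    assert mirror is not None
                    assert (mirror.rank, mirror.back_rank) == (1, 1)


class TestOracleEquivalence:
    def test_table_matches_brute_force_enumeration(self):
        """Top-u buckets equal an exhaustive sort-all-pairs enumeration."""
        rng = random.Random(17)
        prots, genes = [], []
        for sp in ("R", "A", "B"):
            for i in range(8):
                seq = "".join(rng.choice(AAS) for _ in range(45))
                pid = f"{sp}{i}_p"
                prots.append(ProteinRecord(pid, f"{sp}{i}", sp, seq))
                genes.append(mkgene(f"{sp}{i}", sp, i, proteins=[pid]))
        # relatives: copy some sequences with light mutation
        for k in range(4):
            src = prots[k]
            seq = list(src.sequence)
            for pos in rng.sample(range(45), 5):
                seq[pos] = rng.choice(AAS)
            pid = f"A_rel{k}_p"
            prots.append(ProteinRecord(pid, f"A_rel{k}", "A", "".join(seq)))
            genes.append(mkgene(f"A_rel{k}", "A", 10 + k, proteins=[pid]))

        cut, u, wmin, emax = 0.1, 2, 0.07, 1e-7
        V = symmetrize_matrix(build_protein_matrix(prots, e_value_cut=cut))
        table = build_homolog_table(genes, V, u=u, weight_min=wmin,
                                    e_value_max=emax)

        # independent enumeration from raw sequences
        from orthoscreen.scores import surrogate_evalue
        db_len = sum(len(p.sequence) for p in prots)
        raw, ev = {}, {}
        for p in prots:
            for q in prots:
                s = sw_score(p.sequence, q.sequence)
                e_pq = surrogate_evalue(s, len(p.sequence), db_len)
                if p.protein_id == q.protein_id or e_pq <= cut:
                    raw[(p.protein_id, q.protein_id)] = s
                    ev[(p.protein_id, q.protein_id)] = e_pq
        # symmetrize
        for (x, y) in list(raw):
            if (y, x) in raw:
                s = max(raw[(x, y)], raw[(y, x)])
                e = min(ev[(x, y)], ev[(y, x)])
            else:
                s, e = raw[(x, y)], ev[(x, y)]
            raw[(x, y)] = raw[(y, x)] = s
            ev[(x, y)] = ev[(y, x)] = e
        gmap = {g.gene_id: g for g in genes}
        expected = {}
        for X in genes:
            per_sp = {}
            for Y in genes:
                if Y.gene_id == X.gene_id:
                    continue
                x, y = X.protein_ids[0], Y.protein_ids[0]
                if (x, y) not in raw:
                    continue
                w = 2 * raw[(x, y)] / (raw[(x, x)] + raw[(y, y)])
                if w > wmin and ev[(x, y)] < emax:
                    per_sp.setdefault(Y.species_id, []).append(
                        (-w, ev[(x, y)], Y.gene_id))
            for sp, lst in per_sp.items():
                lst.sort()
                expected[(X.gene_id, sp)] = [t[2] for t in lst[:u]]
        actual = {key: [e.target_gene for e in bucket]
                  for key, bucket in table.buckets.items()}
        assert actual == expected


class TestInterchange:
    def test_tsv_round_trip(self, tmp_path, clean_dataset):
        ds = clean_dataset
        V = symmetrize_matrix(build_protein_matrix(ds.proteins))
        table = build_homolog_table(ds.all_genes(), V, u=3)
        p = tmp_path / "table.tsv"
        table.to_tsv(p)
        loaded = HomologTable.from_tsv(p, ds.all_genes(), u=3)
        assert set(loaded.buckets) == set(table.buckets)
        for key in table.buckets:
            a = [(e.target_gene, e.rank, e.back_rank) for e in table.buckets[key]]
            b = [(e.target_gene, e.rank, e.back_rank) for e in loaded.buckets[key]]
            assert a == b
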