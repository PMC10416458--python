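"""Forward/backward checks and presence calls."""

import dataclasses

import pytest

from orthoscreen.orthology import (
    GenomeIndex,
    Parameters,
    backward_check,
    call_presence,
    forward_check,
    neighborhood_genes,
)
from conftest import groups_for, mkgene, table_from_weights

MBP = 1_000_000


class TestNeighborhood:
    def test_within_radius_included(self):
        x = mkgene("x", "R", 0)            # 1..10000
        near = mkgene("n", "R", 4)         # 4.9 Mbp away < 5 Mbp
        idx = GenomeIndex([x, near])
        assert [g.gene_id for g in neighborhood_genes(x, 5 * MBP, idx)] == ["n"]

    def test_boundary_intersection_inclusive(self):
        x = mkgene("x", "R", 0)  # ends at 10_000
        r = 2 * MBP
        touch = dataclasses.replace(mkgene("t", "R", 0),
                                    start=x.end + r, end=x.end + r + 9_999)
        beyond = dataclasses.replace(mkgene("b", "R", 0),
                                     start=x.end + r + 1, end=x.end + r + 10_000)
        idx = GenomeIndex([x, touch, beyond])
        ids = [g.gene_id for g in neighborhood_genes(x, r, idx)]
        assert "t" in ids and "b" not in ids

    def test_other_scaffold_excluded(self):
        x = mkgene("x", "R", 0, seq_id="chr1")
        other = mkgene("o", "R", 0, seq_id="chr2")
        idx = GenomeIndex([x, other])
        assert neighborhood_genes(x, 5 * MBP, idx) == []

    def test_focal_gene_excluded(self):
        x = mkgene("x", "R", 0)
        idx = GenomeIndex([x])
        assert neighborhood_genes(x, 5 * MBP, idx) == []


def _witness_world(witness_slot_A=1, extra_weights=None, u=3):
    """R: x(0), y(1); A: xp(0), yp(witness_slot_A).  (x, xp) candidate at
    0.8; (y, yp) mutual best at 0.9."""
    genes = [mkgene("x", "R", 0), mkgene("y", "R", 1),
             mkgene("xp", "A", 0), mkgene("yp", "A", witness_slot_A)]
    weights = {("x", "xp"): 0.8, ("y", "yp"): 0.9}
    if extra_weights:
        for (a, b), w in extra_weights.items():
            for g in {a, b} - {g.gene_id for g in genes}:
                raise AssertionError(f"unknown gene {g}")
            weights[(a, b)] = w
    table = table_from_weights(genes, weights, u=u)
    index = GenomeIndex(genes)
    by_id = {g.gene_id: g for g in genes}
    return table, index, by_id


class TestForwardCheck:
    def test_single_bbh_witness_passes(self):
        table, index, g = _witness_world()
        ok, pairs = forward_check(g["x"], g["xp"], table, index, Parameters())
        assert ok and pairs == [("y", "yp")]

    def test_witness_outside_radius_fails(self):
        # witness partner sits 6 Mbp from xp with a 5 Mbp radius
        table, index, g = _witness_world(witness_slot_A=6)
        ok, pairs = forward_check(g["x"], g["xp"], table, index, Parameters())
        assert not ok and pairs == []

    def test_non_bbh_witness_fails_under_default_beta(self):
        # yp prefers a far-away decoy over y, so (y, yp) is rank 2 from
        # yp's side and the only in-window witness pair is not BBH
        genes = [mkgene("x", "R", 0), mkgene("y", "R", 1),
                 mkgene("decoy", "R", 0, seq_id="chr2"),
                 mkgene("xp", "A", 0), mkgene("yp", "A", 1)]
        weights = {("x", "xp"): 0.8, ("y", "yp"): 0.6, ("decoy", "yp"): 0.9}
        table = table_from_weights(genes, weights, u=3)
        index = GenomeIndex(genes)
        by_id = {g.gene_id: g for g in genes}
        e = table.entry("y", "yp")
        assert (e.rank, e.back_rank) == (1, 2)  # not BBH
        ok, _ = forward_check(by_id["x"], by_id["xp"], table, index, Parameters())
        assert not ok

    def test_top_k_beta_relaxation(self):
        genes = [mkgene("x", "R", 0), mkgene("y", "R", 1),
                 mkgene("decoy", "R", 20, seq_id="chr2"),
                 mkgene("xp", "A", 0), mkgene("yp", "A", 1)]
        # decoy outranks y for yp but is on another scaffold (no witness use)
        weights = {("x", "xp"): 0.8, ("y", "yp"): 0.6, ("decoy", "yp"): 0.9}
        table = table_from_weights(genes, weights, u=3)
        index = GenomeIndex(genes)
        by_id = {g.gene_id: g for g in genes}
        strict = forward_check(by_id["x"], by_id["xp"], table, index,
                               Parameters(beta_condition="bbh"))[0]
        relaxed = forward_check(by_id["x"], by_id["xp"], table, index,
                                Parameters(beta_condition="top:2"))[0]
        assert not strict and relaxed

    def test_witness_gene_used_once_per_side(self):
        # one witness on R's side cannot satisfy a 2-witness requirement
        table, index, g = _witness_world()
        params = Parameters(witnesses_required=2)
        ok, pairs = forward_check(g["x"], g["xp"], table, index, params)
        assert not ok and len(pairs) == 1

    def test_two_witnesses(self):
        genes = [mkgene("x", "R", 0), mkgene("y", "R", 1), mkgene("z", "R", 2),
                 mkgene("xp", "A", 0), mkgene("yp", "A", 1), mkgene("zp", "A", 2)]
        weights = {("x", "xp"): 0.8, ("y", "yp"): 0.9, ("z", "zp"): 0.85}
        table = table_from_weights(genes, weights, u=3)
        index = GenomeIndex(genes)
        by_id = {g.gene_id: g for g in genes}
        ok, pairs = forward_check(by_id["x"], by_id["xp"], table, index,
                                  Parameters(witnesses_required=2))
        assert ok and sorted(pairs) == [("y", "yp"), ("z", "zp")]

    def test_non_candidate_pair_raises(self):
        table, index, g = _witness_world()
        with pytest.raises(ValueError):
            forward_check(g["x"], g["yp"], table, index, Parameters())

    def test_radius_monotonicity(self):
        # a pass at radius r implies a pass at any larger radius
        for slot in (1, 3, 5, 8):
            table, index, g = _witness_world(witness_slot_A=slot)
            passed = []
            for r in (1, 2, 5, 10):
                ok, _ = forward_check(g["x"], g["xp"], table, index,
                                      Parameters(radius=r * MBP))
                passed.append(ok)
            assert passed == sorted(passed)  # non-decreasing in r


def _backward_world():
    """R: x(0), y(1), U(2); A: xp(0), yp(1).  U is closer to xp than x is
    and shares witness (y, yp) through its own neighborhood."""
    genes = [mkgene("x", "R", 0), mkgene("y", "R", 1), mkgene("U", "R", 2),
             mkgene("xp", "A", 0), mkgene("yp", "A", 1)]
    weights = {("x", "xp"): 0.8, ("U", "xp"): 0.9, ("y", "yp"): 0.95}
    table = table_from_weights(genes, weights, u=3)
    index = GenomeIndex(genes)
    by_id = {g.gene_id: g for g in genes}
    return table, index, by_id


class TestBackwardCheck:
    def test_no_alternative_accepts(self):
        table, index, g = _witness_world()
        accepted, U, _ = backward_check(g["x"], g["xp"], table, index,
                                        Parameters())
        assert accepted and U is None

    def test_closer_syntenic_alternative_rejects_at_lambda_zero(self):
        table, index, g = _backward_world()
        accepted, U, margin = backward_check(g["x"], g["xp"], table, index,
                                             Parameters(lam=0.0))
        assert not accepted and U == "U"
        assert margin == pytest.approx(0.1)

    def test_lambda_threshold_saves_candidate(self):
        table, index, g = _backward_world()
        accepted, U, _ = backward_check(g["x"], g["xp"], table, index,
                                        Parameters(lam=0.15))
        assert accepted and U is None

    def test_exact_tie_never_rejects(self):
        genes = [mkgene("x", "R", 0), mkgene("y", "R", 1), mkgene("U", "R", 2),
                 mkgene("xp", "A", 0), mkgene("yp", "A", 1)]
        weights = {("x", "xp"): 0.8, ("U", "xp"): 0.8, ("y", "yp"): 0.95}
        table = table_from_weights(genes, weights, u=3)
        index = GenomeIndex(genes)
        by_id = {g.gene_id: g for g in genes}
        accepted, _, _ = backward_check(by_id["x"], by_id["xp"], table, index,
                                        Parameters(lam=0.0))
        assert accepted  # margin 0 is not > 0

    def test_non_syntenic_alternative_does_not_reject(self):
        # U is closer but isolated on another scaffold: no witnesses
        genes = [mkgene("x", "R", 0), mkgene("y", "R", 1),
                 mkgene("U", "R", 0, seq_id="chr2"),
                 mkgene("xp", "A", 0), mkgene("yp", "A", 1)]
        weights = {("x", "xp"): 0.8, ("U", "xp"): 0.9, ("y", "yp"): 0.95}
        table = table_from_weights(genes, weights, u=3)
        index = GenomeIndex(genes)
        by_id = {g.gene_id: g for g in genes}
        accepted, _, _ = backward_check(by_id["x"], by_id["xp"], table, index,
                                        Parameters())
        assert accepted

    def test_quotient_variant(self):
        table, index, g = _backward_world()
        # raw scores in the fixture are weight*100: 90 vs 80, quotient 1.125
        rejected_at = Parameters(backward_variant="quotient", lambda1=1.05)
        accepted_at = Parameters(backward_variant="quotient", lambda1=1.2)
        assert not backward_check(g["x"], g["xp"], table, index, rejected_at)[0]
        assert backward_check(g["x"], g["xp"], table, index, accepted_at)[0]


class TestCallPresence:
    def test_second_candidate_wins_when_first_lacks_synteny(self):
        genes = [mkgene("x", "R", 0), mkgene("y", "R", 1),
                 mkgene("c1", "A", 0, seq_id="chr2"),  # better weight, no synteny
                 mkgene("c2", "A", 0), mkgene("yp", "A", 1)]
        weights = {("x", "c1"): 0.9, ("x", "c2"): 0.8, ("y", "yp"): 0.95}
        table = table_from_weights(genes, weights, u=3)
        index = GenomeIndex(genes)
        by_id = {g.gene_id: g for g in genes}
        call = call_presence(by_id["x"], "A", table, index, Parameters())
        assert call.present and call.ortholog == "c2"
        assert call.rejected_candidates[0]["candidate"] == "c1"

    def test_all_candidates_rejected_means_absent(self):
        table, index, g = _backward_world()
        call = call_presence(g["x"], "A", table, index, Parameters(lam=0.0))
        assert not call.present and call.ortholog is None
        assert call.rejected_candidates[0]["reason"] == "closer_alternative"

    def test_empty_bucket_means_absent(self):
        genes = [mkgene("x", "R", 0), mkgene("z", "A", 0)]
        table = table_from_weights(genes, {}, u=3)
        index = GenomeIndex(genes)
        call = call_presence(genes[0], "A", table, index, Parameters())
        assert call.status == "absent"

    def test_lambda_monotonicity_per_call(self):
        table, index, g = _backward_world()
        statuses = []
        lam = 0.0
        while lam <= 0.6:
            call = call_presence(g["x"], "A", table, index, Parameters(lam=lam))
            statuses.append(call.present)
            lam = round(lam + 0.03, 5)
        assert statuses == sorted(statuses)  # absent -> present, never back


class TestPlantedRecovery:
    def test_clean_simulation_fully_recovered(self, clean_dataset):
        """On a paralog-free, low-divergence, unshuffled dataset every
        planted loss is absent and every retained ortholog present."""
        from orthoscreen.pipeline import PipelineConfig, run_pipeline

        ds = clean_dataset
        cfg = PipelineConfig(groups=groups_for(ds.config))
        res = run_pipeline(ds.proteins, ds.annotations, [], cfg)
        truth = ds.truth
        ref = ds.config.reference
        for anc, per_sp in truth.ortholog_map.items():
            ref_gene = per_sp.get(ref)
            if ref_gene is None:
                continue
            for sp, target in per_sp.items():
                if sp == ref:
                    continue
                call = res.calls[(ref_gene, sp)]
                if target is None:
                    assert not call.present, (anc, sp)
                else:
                    assert call.present and call.ortholog == target, (anc, sp)
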