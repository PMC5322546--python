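import networkx as nx
import pytest

import lecdup
from lecdup.annotation_io import GeneModel, GenomeAnnotation, SimilarityHit
from lecdup.dup_classifier import (
    GTDPair,
    assemble_calls,
    call_gtd,
    call_td_alpha,
    find_tandem_arrays,
    polarize_gtd,
)
from lecdup.molevol import align_codons
from lecdup.synteny import OhnologPair


def annotation(ranks_strands, chrom="chr1", species="s"):
    genes = [
        GeneModel(gid, chrom, 100 * r, 100 * r + 50, strand, r, cds_length=30, species=species)
        for gid, r, strand in ranks_strands
    ]
    return GenomeAnnotation(species, genes)


def hit(q, s, e=1e-40):
    return SimilarityHit(q, s, 90.0, 100, e, 200.0)


class TestTandemArrays:
    def test_three_adjacent_homologs_form_one_array(self):
        ann = annotation([("gA", 0, "+"), ("gB", 1, "+"), ("gC", 2, "+")])
        arrays = find_tandem_arrays(ann, [hit("gA", "gB"), hit("gB", "gC")])
        assert len(arrays) == 1
        assert arrays[0].members == ["gA", "gB", "gC"]

    def test_eleven_spacers_is_out_ten_is_in(self):
        rows = [("gA", 0, "+")] + [(f"f{i}", i, "+") for i in range(1, 12)] + [("gB", 12, "+")]
        ann = annotation(rows)
        assert find_tandem_arrays(ann, [hit("gA", "gB")]) == []  # 11 spacers
        rows = [("gA", 0, "+")] + [(f"f{i}", i, "+") for i in range(1, 11)] + [("gB", 11, "+")]
        ann = annotation(rows)
        arrays = find_tandem_arrays(ann, [hit("gA", "gB")])  # 10 spacers
        assert len(arrays) == 1

    def test_bridged_members_share_one_array(self):
        # gA..gB 10 spacers via middle member gM: one array of 3
        rows = (
            [("gA", 0, "+"), ("gM", 6, "+"), ("gB", 12, "+")]
            + [(f"f{i}", r, "+") for i, r in enumerate([1, 2, 3, 4, 5, 7, 8, 9, 10, 11])]
        )
        ann = annotation(rows)
        arrays = find_tandem_arrays(ann, [hit("gA", "gM"), hit("gM", "gB")])
        assert [a.members for a in arrays] == [["gA", "gM", "gB"]]

    @pytest.mark.parametrize(
        "strands,expected",
        [
            (("+", "+"), "head_to_tail"),
            (("-", "-"), "head_to_tail"),
            (("-", "+"), "head_to_head"),
            (("+", "-"), "tail_to_tail"),
        ],
    )
    def test_adjacent_pair_orientation_labels(self, strands, expected):
        ann = annotation([("gA", 0, strands[0]), ("gB", 1, strands[1])])
        [arr] = find_tandem_arrays(ann, [hit("gA", "gB")])
        assert arr.pair_orientations == [expected]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_networkx_connected_components(self, trial):
        import numpy as np

        rng = np.random.default_rng(2000 + trial)
        n = 30
        ann = annotation([(f"g{i}", i, "+") for i in range(n)])
        hits = []
        g = nx.Graph()
        for _ in range(25):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            hits.append(hit(f"g{i}", f"g{j}"))
            if abs(int(i) - int(j)) - 1 <= 10:
                g.add_edge(f"g{i}", f"g{j}")
        arrays = find_tandem_arrays(ann, hits, max_spacers=10)
        got = {frozenset(a.members) for a in arrays}
        want = {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}
        assert got == want

    def test_planted_simulator_arrays_recovered_exactly(self, default_sim, default_classification):
        got = {frozenset(a.members) for a in default_classification.tandem_arrays}
        want = {frozenset(a) for a in default_sim.truth.tandem_arrays}
        assert got == want


class TestCallGTD:
    def test_distant_pair_with_no_other_explanation_is_gtd(self):
        genes = ["gA", "gB", "gC"]
        pairs = call_gtd(genes, [hit("gA", "gB", 1e-60), hit("gB", "gA", 1e-60)], [], [])
        assert {(p.transposed_gene, p.partner_gene) for p in pairs} == {("gA", "gB"), ("gB", "gA")}

    def test_tandem_neighbor_is_not_a_gtd_partner(self):
        ann = annotation([("gA", 0, "+"), ("gB", 1, "+")])
        arrays = find_tandem_arrays(ann, [hit("gA", "gB")])
        assert call_gtd(["gA", "gB"], [hit("gA", "gB", 1e-60)], [], arrays) == []

    def test_weak_hits_above_threshold_ignored(self):
        assert call_gtd(["gA", "gB"], [hit("gA", "gB", 1e-20)], [], [], e_max=1e-30) == []

    def test_chained_tandem_ohnolog_relations_suppress_gtd(self):
        # gA tandem with gB; gB ohnolog of gC: gA-gC is explained through
        # the chain, not a transposition
        ann = annotation([("gA", 0, "+"), ("gB", 1, "+")])
        arrays = find_tandem_arrays(ann, [hit("gA", "gB")])
        ohno = [OhnologPair("gB", "gC", 0, True)]
        got = call_gtd(["gA", "gB", "gC"], [hit("gA", "gC", 1e-60)], ohno, arrays)
        assert got == []

    def test_no_pair_connects_tandem_or_ohnolog_partners(self, default_sim, default_classification):
        res = default_classification
        arrays = {frozenset(a.members) for a in res.tandem_arrays}
        ohno = {frozenset((p.gene_a, p.gene_b)) for p in res.ohnolog_pairs}
        for gp in res.gtd_pairs:
            pair = frozenset((gp.transposed_gene, gp.partner_gene))
            assert pair not in ohno
            assert not any(pair <= arr for arr in arrays)

    def test_simulator_gtd_f1_meets_floor(self):
        tp = fp = fn = 0
        for seed in range(1, 6):
            out = lecdup.simulate(seed=seed)
            res = lecdup.classify_genome(out.annotation, out.hits)
            pred = res.label_set("gtd")
            tp += len(pred & out.truth.gtd)
            fp += len(pred - out.truth.gtd)
            fn += len(out.truth.gtd - pred)
        p, r = tp / (tp + fp), tp / (tp + fn)
        assert 2 * p * r / (p + r) >= 0.75


class TestPolarizeGTD:
    def _models(self, cds_t, cds_p, exons_t=(), exons_p=()):
        return {
            "t": GeneModel("t", "chr1", 0, 5000, "+", 0, cds_length=cds_t, exon_lengths=exons_t),
            "p": GeneModel("p", "chr2", 0, 5000, "+", 0, cds_length=cds_p, exon_lengths=exons_p),
        }

    def test_all_criteria_agreeing_vote_4_0(self):
        pair = GTDPair("t", "p", 1e-60)
        # partner: 1 indel of 3bp, CDS 900; transposed: 2 indels, max 30bp, CDS 720
        aligned_p = "AAA" * 250 + "---" * 50
        aligned_t = "AAA" * 100 + "---" * 10 + "AAA" * 100 + "---" * 90
        polarize_gtd(
            pair, aligned_t, aligned_p,
            self._models(720, 900, exons_t=(360, 360), exons_p=(450, 450)),
        )
        assert pair.polarization == "partner_ancestral"
        assert len(pair.votes) == 4
        assert all(v == "partner" for v in pair.votes.values())

    def test_identical_copies_unresolved(self):
        pair = GTDPair("t", "p", 1e-60)
        polarize_gtd(pair, "ATGAAA", "ATGAAA", self._models(6, 6))
        assert pair.polarization == "unresolved"

    def test_unaligned_input_raises(self):
        with pytest.raises(ValueError, match="unaligned"):
            polarize_gtd(GTDPair("t", "p", 1e-60), "AAA", "AAAAAA", self._models(3, 6))

    def test_simulated_polarization_accuracy(self):
        tot = correct = 0
        for seed in range(1, 6):
            out = lecdup.simulate(seed=seed)
            gm = {g.gene_id: g for g in out.annotation}
            for pair in out.truth.gtd_pairs:
                a, b = sorted(pair)
                novel = a if out.sim.genes[a].origin == "gtd_copy" else b
                anc = b if novel == a else a
                gp = GTDPair(novel, anc, 1e-60)
                aln_t, aln_p = align_codons(out.sequences[novel], out.sequences[anc])
                polarize_gtd(gp, aln_t, aln_p, gm)
                tot += 1
                correct += gp.polarization == "partner_ancestral"
        assert correct / tot >= 0.8


class TestTDAlpha:
    def _arrays(self):
        ann = annotation([("gA", 0, "+"), ("gB", 1, "+")])
        return find_tandem_arrays(ann, [hit("gA", "gB")])

    def test_tandem_member_with_ohnolog_is_td_alpha(self):
        ohno = [OhnologPair("gA", "gX", 0, True, epoch="alpha")]
        genes, report = call_td_alpha(self._arrays(), ohno, epoch_filter="alpha")
        assert genes == {"gA", "gB"}  # the copy belongs with its ohnolog source
        assert report == [("gA", "gX", 0)]
        strict, _ = call_td_alpha(self._arrays(), ohno, epoch_filter="alpha", semantics="gene")
        assert strict == {"gA"}

    def test_tandem_without_ohnolog_is_not_td_alpha(self):
        genes, _ = call_td_alpha(self._arrays(), [], epoch_filter="any")
        assert genes == set()

    def test_epoch_filter_excludes_other_epochs(self):
        ohno = [OhnologPair("gA", "gX", 0, True, epoch="beta")]
        assert call_td_alpha(self._arrays(), ohno, epoch_filter="alpha")[0] == set()
        assert call_td_alpha(self._arrays(), ohno, epoch_filter="any")[0] == {"gA", "gB"}

    def test_simulator_td_alpha_recovered_exactly(self):
        for seed in range(1, 6):
            out = lecdup.simulate(seed=seed)
            res = lecdup.classify_genome(out.annotation, out.hits)
            assert res.td_alpha_genes == out.truth.td_alpha


class TestAssembleCalls:
    def test_triple_membership_counts_once_in_triple_cell(self):
        ann = annotation([("gA", 0, "+"), ("gB", 1, "+")])
        arrays = find_tandem_arrays(ann, [hit("gA", "gB")])
        ohno = [OhnologPair("gA", "gX", 0, True)]
        gtd = [GTDPair("gA", "gY", 1e-60)]
        calls, venn = assemble_calls(["gA", "gB", "gX", "gY"], arrays, ohno, gtd)
        assert calls["gA"].labels == {"tandem", "ohnolog", "gtd"}
        assert venn[frozenset({"tandem", "ohnolog", "gtd"})] == 1

    def test_empty_inputs_make_everyone_singleton(self):
        calls, venn = assemble_calls(["a", "b"], [], [], [])
        assert all(c.singleton for c in calls.values())
        assert venn == {}

    def test_missing_partner_is_hard_error(self):
        with pytest.raises(KeyError):
            assemble_calls(["gA"], [], [OhnologPair("gA", "gZ", 0, True)], [])

    def test_venn_cells_match_inclusion_exclusion(self, rng):
        genes = [f"g{i}" for i in range(50)]
        sets = {
            m: set(rng.choice(genes, size=rng.integers(5, 20), replace=False))
            for m in ("tandem", "ohnolog", "gtd")
        }
        # feed label sets through fabricated inputs
        ann = annotation([(g, i, "+") for i, g in enumerate(genes)], chrom="chr1")
        tandem_list = sorted(sets["tandem"], key=lambda g: int(g[1:]))
        arrays = []
        if len(tandem_list) >= 2:
            from lecdup.dup_classifier import TandemArray

            arrays = [TandemArray(0, "chr1", tandem_list, [])]
        ohno = [OhnologPair(g, g, 0, True) for g in sets["ohnolog"]]
        gtd = [GTDPair(g, g, 1e-60) for g in sets["gtd"]]
        calls, venn = assemble_calls(genes, arrays, ohno, gtd)
        total_nonsingleton = sum(1 for c in calls.values() if not c.singleton)
        assert sum(venn.values()) == total_nonsingleton
        for cell, count in venn.items():
            want = sum(
                1 for g in genes
                if {m for m in sets if g in sets[m]} == set(cell)
            )
            assert count == want
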