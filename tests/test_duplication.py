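"""Tandem/segmental calling and homolog grouping."""

import numpy as np
import pytest

from mybkit import duplication as dup
from mybkit.models import GeneModel, PairHit


def model(gid, chrom="1A", start=1000, end=2000, strand="+", cds_len=None):
    m = GeneModel(gid, chrom, start, end, strand, [(start, end)])
    if cds_len:
        m.cds_sequence = "A" * cds_len
    return m


def hit(q, s, identity=95.0, length=900, evalue=1e-30):
    return PairHit(q, s, identity, length, evalue=evalue)


class TestPairwiseAlign:
    def test_identical_sequences(self):
        h = dup.pairwise_align("ACGTACGT", "ACGTACGT")
        assert h.pct_identity == 100.0
        assert h.aln_length == 8

    def test_single_mismatch_75_percent(self):
        h = dup.pairwise_align("ACGT", "ACGA")
        assert h.pct_identity == pytest.approx(75.0)

    def test_symmetry(self):
        a, b = "MKVLANNNWQRP", "MKVANNWQKP"
        assert dup.pairwise_align(a, b).pct_identity == pytest.approx(
            dup.pairwise_align(b, a).pct_identity
        )

    def test_protein_mode_uses_blosum(self):
        h = dup.pairwise_align("MKVLW", "MKVLW")
        assert h.score > 5  # BLOSUM62 self-scores exceed +1/match

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dup.pairwise_align("", "ACGT")


class TestIngestPairhits:
    ROW = "g1\tg2\t97.5\t800\t20\t0\t1\t800\t1\t800\t1e-50\t1450.0\n"

    def test_field_mapping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW)
        (h,) = dup.ingest_pairhits(p)
        assert (h.query_id, h.subject_id) == ("g1", "g2")
        assert h.pct_identity == 97.5
        assert h.aln_length == 800
        assert h.evalue == pytest.approx(1e-50)
        assert h.query_range == (1, 800)

    def test_self_hit_dropped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("g1\tg1\t100\t800\t0\t0\t1\t800\t1\t800\t0.0\t1500\n" + self.ROW)
        assert len(dup.ingest_pairhits(p)) == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert dup.ingest_pairhits(p) == []

    def test_wrong_columns_named_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW + "only\tthree\tcols\n")
        with pytest.raises(ValueError, match=":2"):
            dup.ingest_pairhits(p)


class TestCallTandem:
    def _adjacent_models(self):
        return [
            model("a", start=1000, end=2000, cds_len=900),
            model("b", start=2500, end=3500, cds_len=900),
            model("c", start=9000, end=9900, cds_len=900),
        ]

    def test_adjacent_pair_called(self):
        clusters = dup.call_tandem([hit("a", "b")], self._adjacent_models(), {"a", "b", "c"})
        assert [c.members for c in clusters] == [["a", "b"]]

    def test_intervening_gene_blocks_pair(self):
        models = [
            model("a", start=1000, end=2000, cds_len=900),
            model("x", start=2100, end=2400),  # any annotated gene counts
            model("b", start=2500, end=3500, cds_len=900),
        ]
        assert dup.call_tandem([hit("a", "b")], models, {"a", "b"}) == []

    def test_low_identity_rejected(self):
        clusters = dup.call_tandem(
            [hit("a", "b", identity=75.0)], self._adjacent_models(), {"a", "b"}
        )
        assert clusters == []

    def test_weak_evalue_rejected(self):
        clusters = dup.call_tandem(
            [hit("a", "b", evalue=1e-5)], self._adjacent_models(), {"a", "b"}
        )
        assert clusters == []

    def test_short_alignment_rejected(self):
        clusters = dup.call_tandem(
            [hit("a", "b", length=500)], self._adjacent_models(), {"a", "b"}
        )
        assert clusters == []  # 500 < 0.8 * 900

    def test_coverage_uses_longer_gene(self):
        models = [
            model("a", start=1000, end=2000, cds_len=600),
            model("b", start=2500, end=3500, cds_len=1200),
        ]
        assert dup.call_tandem([hit("a", "b", length=700)], models, {"a", "b"}) == []

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            dup.call_tandem([hit("a", "zz")], self._adjacent_models(), {"a", "zz"})

    def test_score_path_when_no_evalue(self):
        h = PairHit("a", "b", 95.0, 900, evalue=None, score=800.0)
        clusters = dup.call_tandem([h], self._adjacent_models(), {"a", "b"})
        assert len(clusters) == 1
        weak = PairHit("a", "b", 95.0, 900, evalue=None, score=10.0)
        assert dup.call_tandem([weak], self._adjacent_models(), {"a", "b"}) == []

    def test_hit_order_invariance_and_disjoint(self):
        models = [
            model(f"g{i}", start=1000 + 1500 * i, end=2000 + 1500 * i, cds_len=900)
            for i in range(6)
        ]
        fam = {m.gene_id for m in models}
        hits = [hit("g0", "g1"), hit("g1", "g2"), hit("g4", "g5")]
        rng = np.random.default_rng(0)
        base = dup.call_tandem(hits, models, fam)
        assert [c.members for c in base] == [["g0", "g1", "g2"], ["g4", "g5"]]
        for _ in range(5):
            shuffled = [hits[i] for i in rng.permutation(len(hits))]
            again = dup.call_tandem(shuffled, models, fam)
            assert [c.members for c in again] == [c.members for c in base]
        seen = set()
        for c in base:
            assert not (set(c.members) & seen)
            seen |= set(c.members)

    def test_loosened_criteria_reduce_to_adjacency_components(self):
        """Brute-force oracle: with thresholds disabled, clusters are exactly
        the connected runs of adjacent family genes with any hit."""
        rng = np.random.default_rng(3)
        models = [
            model(f"g{i}", start=1000 + 1200 * i, end=2000 + 1200 * i, cds_len=600)
            for i in range(20)
        ]
        fam = {m.gene_id for m in models}
        hits = []
        linked = set()
        for i in range(19):
            if rng.random() < 0.4:
                hits.append(hit(f"g{i}", f"g{i + 1}", identity=50.0, length=1, evalue=1.0))
                linked.add((i, i + 1))
        got = dup.call_tandem(
            hits, models, fam, coverage=0.0, min_identity=0.0, max_evalue=np.inf
        )
        # oracle: merge adjacent link runs by brute force
        expected = []
        run = []
        for i in range(19):
            if (i, i + 1) in linked:
                if not run:
                    run = [i]
                run.append(i + 1)
            else:
                if run:
                    expected.append([f"g{j}" for j in run])
                run = []
        if run:
            expected.append([f"g{j}" for j in run])
        assert [c.members for c in got] == expected

    def test_planted_clusters_recovered(self, small_genome):
        cfg, bundle, truth = small_genome
        fam = set(truth.family_genes())
        by_id = {m.gene_id: m for m in bundle.models}
        pos = dup._positional_index(bundle.models)
        by_chrom = {}
        for gid, (chrom, rank) in pos.items():
            by_chrom.setdefault(chrom, {})[rank] = gid
        hits = []
        for chrom, ranks in by_chrom.items():
            for r in sorted(ranks)[:-1]:
                a, b = ranks[r], ranks[r + 1]
                if a in fam and b in fam:
                    hits.append(
                        dup.pairwise_align(
                            by_id[a].cds_sequence, by_id[b].cds_sequence, id_a=a, id_b=b
                        )
                    )
        clusters = dup.call_tandem(hits, bundle.models, fam)
        got = {frozenset(c.members) for c in clusters}
        want = {frozenset(c) for c in truth.tandem_clusters}
        assert got == want


class TestCallSegmental:
    def _planted(self, small_genome):
        cfg, bundle, truth = small_genome
        fam = set(truth.family_genes())
        by_id = {m.gene_id: m for m in bundle.models}
        prot = {g: by_id[g].protein_sequence for g in sorted(fam)}
        hits = [
            dup.pairwise_align(prot[a], prot[b], id_a=a, id_b=b)
            for a, b in dup.candidate_pairs(prot)
        ]
        return cfg, bundle, truth, fam, hits

    def test_planted_block_recovered(self, small_genome):
        cfg, bundle, truth, fam, hits = self._planted(small_genome)
        blocks = dup.call_segmental(
            hits, bundle.models, fam, min_span=cfg.segmental_span // 2
        )
        assert truth.segmental_blocks
        for planted in truth.segmental_blocks:
            want = set(zip(planted["a_members"], planted["b_members"]))
            matched = any(
                len(want & {tuple(sorted(a)) for a in _norm(b.anchors)})
                >= 0.8 * len(want)
                for b in blocks
            )
            assert matched, planted

    def test_span_threshold_blocks(self, small_genome):
        cfg, bundle, truth, fam, hits = self._planted(small_genome)
        assert (
            dup.call_segmental(hits, bundle.models, fam, min_span=10 * cfg.segmental_span)
            == []
        )

    def test_reversed_order_not_chained(self):
        # two anchors with region-B order inverted but no strand flip
        models = [
            model("a1", "1A", 1000, 2000, "+"),
            model("a2", "1A", 20_000, 21_000, "+"),
            model("b1", "2A", 50_000, 51_000, "+"),
            model("b2", "2A", 30_000, 31_000, "+"),
        ]
        hits = [hit("a1", "b1"), hit("a2", "b2")]
        fam = {"a1", "a2", "b1", "b2"}
        assert dup.call_segmental(hits, models, fam, min_span=5_000) == []

    def test_flipped_orientation_descending_ok(self):
        models = [
            model("a1", "1A", 1000, 2000, "+"),
            model("a2", "1A", 20_000, 21_000, "+"),
            model("b1", "2A", 50_000, 51_000, "-"),
            model("b2", "2A", 30_000, 31_000, "-"),
        ]
        hits = [hit("a1", "b1"), hit("a2", "b2")]
        fam = {"a1", "a2", "b1", "b2"}
        blocks = dup.call_segmental(hits, models, fam, min_span=5_000, chain_gap=50_000)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 2

    def test_tandem_pairs_excluded(self):
        models = [
            model("a", "1A", 1000, 2000),
            model("b", "1A", 2500, 3500),
        ]
        assert dup.call_segmental([hit("a", "b")], models, {"a", "b"}, min_span=100) == []


def _norm(anchors):
    return [tuple(a) for a in anchors]


class TestHomologGroups:
    def test_planted_triads_recovered(self, small_genome):
        cfg, bundle, truth = small_genome
        fam = set(truth.family_genes())
        by_id = {m.gene_id: m for m in bundle.models}
        prot = {g: by_id[g].protein_sequence for g in sorted(fam)}
        hits = [
            dup.pairwise_align(prot[a], prot[b], id_a=a, id_b=b)
            for a, b in dup.candidate_pairs(prot)
        ]
        groups, fraction = dup.find_homolog_groups(hits, bundle.models, fam)
        got = {frozenset(g.members.values()) for g in groups if g.completeness == 3}
        want = {frozenset(t) for t in truth.triads}
        assert want <= got
        expected_fraction = 3 * len(truth.triads) / len(fam)
        assert fraction == pytest.approx(expected_fraction, abs=0.1)

    def test_isolated_gene_is_singleton(self):
        models = [model("solo", "3B", 100, 1100)]
        groups, fraction = dup.find_homolog_groups([], models, {"solo"}, subgenomes={"A", "B", "D"})
        assert len(groups) == 1
        assert groups[0].completeness == 1
        assert fraction == 0.0

    def test_unlabeled_chromosome_rejected(self):
        models = [model("g1", "scaffold_1", 100, 1100)]
        with pytest.raises(ValueError, match="subgenome"):
            dup.find_homolog_groups([], models, {"g1"})
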