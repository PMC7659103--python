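"""Repeat detection, merging, classification and naming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mybkit import family
from mybkit.models import DomainHit, GeneModel, ProteinRecord, RepeatArchitecture
from mybkit.simulate import DEFAULT_REPEAT_CONSENSUS

CONS = DEFAULT_REPEAT_CONSENSUS
PSSM = family.build_pssm(CONS)


def protein(seq, pid="p1", gid="g1"):
    return ProteinRecord(pid, gid, seq)


class TestScanRepeats:
    def test_exact_match_found_at_planted_offset(self):
        seq = "M" * 10 + CONS + "A" * 20
        hits = family.scan_repeats(protein(seq), PSSM)
        best = max(hits, key=lambda h: h.score)
        assert (best.start, best.end) == (11, 62)
        # the consensus itself realizes the per-column maximum
        max_score = PSSM.max(axis=1).sum()
        assert best.score == pytest.approx(max_score)

    def test_short_protein_empty(self):
        assert family.scan_repeats(protein("MKV"), PSSM) == []

    def test_minus_inf_threshold_reports_every_window(self):
        seq = "A" * 80
        hits = family.scan_repeats(protein(seq), PSSM, bit_threshold=-np.inf)
        assert len(hits) == 80 - 52 + 1

    def test_random_protein_false_positive_rate(self):
        rng = np.random.default_rng(42)
        aas = family.ALPHABET
        windows = hits = 0
        for i in range(2000):
            seq = "".join(aas[j] for j in rng.integers(0, 20, size=200))
            got = family.scan_repeats(protein(seq, pid=f"r{i}"), PSSM)
            hits += len(got)
            windows += 200 - 52 + 1
        assert hits / windows < 1e-3

    def test_noisy_repeat_still_detected(self):
        rng = np.random.default_rng(0)
        from mybkit.simulate.genome import _noisy_repeat

        for seed in range(20):
            rep = _noisy_repeat(rng, CONS, 0.1)
            seq = "MSTART" + rep + "ENDSEQ".replace("B", "A")
            hits = family.scan_repeats(protein(seq), PSSM)
            assert any(h.start == 7 for h in hits)


class TestMergeAndClassify:
    def test_overlap_merged(self):
        hits = [DomainHit("p", 10, 61, 5.0), DomainHit("p", 40, 91, 5.0)]
        arch = family.merge_hits(hits)
        assert arch.repeats == [(10, 91)]

    def test_disjoint_kept(self):
        hits = [DomainHit("p", 10, 61, 5.0), DomainHit("p", 70, 121, 5.0)]
        arch = family.merge_hits(hits, min_separation=5)
        assert arch.repeat_count == 2

    def test_gap_below_separation_merged(self):
        hits = [DomainHit("p", 10, 61, 5.0), DomainHit("p", 65, 116, 5.0)]
        assert family.merge_hits(hits, min_separation=5).repeat_count == 1

    def test_empty_hits(self):
        arch = family.merge_hits([], gene_id="g")
        assert arch.repeat_count == 0
        assert arch.family_class == "none"

    def test_multi_protein_hits_rejected(self):
        with pytest.raises(ValueError):
            family.merge_hits([DomainHit("a", 1, 5, 1.0), DomainHit("b", 1, 5, 1.0)])

    @given(
        st.lists(
            st.tuples(st.integers(1, 300), st.integers(0, 60)), min_size=0, max_size=15
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_merge_idempotent(self, intervals):
        hits = [DomainHit("p", s, s + w, 1.0) for s, w in intervals]
        once = family.merge_hits(hits)
        again = family.merge_hits(
            [DomainHit("p", a, b, 1.0) for a, b in once.repeats]
        )
        assert once.repeats == again.repeats

    @pytest.mark.parametrize(
        "count,expected",
        [(0, "none"), (1, "1R"), (2, "2R"), (3, "3R"), (4, "4R"), (5, "none")],
    )
    def test_classification_map(self, count, expected):
        arch = RepeatArchitecture("g", [(i * 60 + 1, i * 60 + 52) for i in range(count)])
        assert family.classify_family(arch) == expected


class TestDedupe:
    def _model(self, gid, tid, cds_len):
        return GeneModel(gid, "1A", 1, cds_len, "+", [(1, cds_len)], transcript_id=tid)

    def test_longest_cds_wins(self):
        models = [self._model("g1", "t1", 900), self._model("g1", "t2", 750)]
        prots = [protein("A" * 300, "t1", "g1"), protein("A" * 250, "t2", "g1")]
        reps = family.dedupe_transcripts(prots, models)
        assert [r.protein_id for r in reps] == ["t1"]

    def test_tie_breaks_lexicographically(self):
        models = [self._model("g1", "t2", 300), self._model("g1", "t1", 300)]
        prots = [protein("A" * 100, "t2", "g1"), protein("A" * 100, "t1", "g1")]
        assert family.dedupe_transcripts(prots, models)[0].protein_id == "t1"

    def test_single_isoform_unchanged(self):
        models = [self._model("g1", "t1", 300)]
        prots = [protein("MKV" * 33 + "M", "t1", "g1")]
        reps = family.dedupe_transcripts(prots, models)
        assert len(reps) == 1 and reps[0].sequence == prots[0].sequence

    def test_orphan_protein_rejected(self):
        with pytest.raises(ValueError, match="no parent gene"):
            family.dedupe_transcripts([protein("AAA", "t1", "gX")], [])


class TestDomtblout:
    HEADER = "#" + " header\n#---\n"

    def _row(self, target="p1", ifrom=10, ito=61, ieval="1e-20", score="55.2"):
        cols = [
            target, "-", "200", "QUERY", "PF00000.1", "52", "1e-30", "60.0", "0.1",
            "1", "2", "1e-22", ieval, score, "0.1", "1", "52",
            str(ifrom + 1), str(ito - 1), str(ifrom), str(ito), "0.95", "desc here",
        ]
        return " ".join(cols) + "\n"

    def test_field_mapping(self, tmp_path):
        p = tmp_path / "h.domtblout"
        p.write_text(self.HEADER + self._row())
        (hit,) = family.ingest_domtblout(p)
        assert (hit.start, hit.end) == (10, 61)
        assert hit.evalue == pytest.approx(1e-20)
        assert hit.score == pytest.approx(55.2)

    def test_comments_only(self, tmp_path):
        p = tmp_path / "h.domtblout"
        p.write_text(self.HEADER)
        assert family.ingest_domtblout(p) == []

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "h.domtblout"
        p.write_text(self._row(ifrom=61, ito=10))
        with pytest.raises(ValueError, match=":1"):
            family.ingest_domtblout(p)

    def test_dual_path_agreement_on_clean_genome(self, clean_genome, tmp_path):
        """PSSM scan and domtblout ingest agree on repeat counts when the
        table is written from the planted (noise-free) architecture."""
        cfg, bundle, truth = clean_genome
        lines = [self.HEADER]
        for m in bundle.models:
            for a, b in truth.genes[m.gene_id]["repeats"]:
                lines.append(self._row(target=m.gene_id, ifrom=a, ito=b))
        p = tmp_path / "planted.domtblout"
        p.write_text("".join(lines))
        by_protein = {}
        for hit in family.ingest_domtblout(p):
            by_protein.setdefault(hit.protein_id, []).append(hit)
        pssm = family.build_pssm(cfg.repeat_consensus)
        for m in bundle.models:
            scanned = family.merge_hits(
                family.scan_repeats(
                    ProteinRecord(m.gene_id, m.gene_id, m.protein_sequence), pssm
                ),
                gene_id=m.gene_id,
            )
            ingested = family.merge_hits(by_protein.get(m.gene_id, []), gene_id=m.gene_id)
            assert scanned.repeat_count == ingested.repeat_count, m.gene_id


class TestAssignNames:
    def test_chromosome_order(self):
        members = [
            ("g1", "2R", "1A", 500),
            ("g2", "2R", "1B", 100),
            ("g3", "2R", "2A", 50),
        ]
        named = {m.gene_id: m.assigned_name for m in family.assign_names(members)}
        assert named == {"g1": "TaMYB1", "g2": "TaMYB2", "g3": "TaMYB3"}

    def test_separate_series_per_class(self):
        members = [
            ("a", "3R", "1A", 10),
            ("b", "2R", "1A", 20),
            ("c", "3R", "2B", 5),
            ("d", "1R", "3D", 9),
        ]
        names = {m.gene_id: m.assigned_name for m in family.assign_names(members, "X")}
        assert names == {"a": "X3R1", "b": "X1", "c": "X3R2", "d": "X1R1"}

    def test_tie_broken_by_gene_id(self):
        members = [("gB", "2R", "1A", 100), ("gA", "2R", "1A", 100)]
        named = family.assign_names(members)
        assert [m.gene_id for m in named] == ["gA", "gB"]

    def test_unplaced_appended_in_input_order(self):
        members = [
            ("u2", "2R", "scaffold_9", 5),
            ("g1", "2R", "7D", 10),
            ("u1", "2R", "ctg00", 1),
        ]
        named = family.assign_names(members)
        assert [m.gene_id for m in named] == ["g1", "u2", "u1"]

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            family.assign_names([("g", "2R", "1A", 1), ("g", "2R", "1B", 2)])

    def test_permutation_stable(self):
        rng = np.random.default_rng(2)
        members = [
            (f"g{i}", "2R", f"{1 + i % 7}{'ABD'[i % 3]}", int(rng.integers(1, 10_000)))
            for i in range(25)
        ]
        base = {m.gene_id: m.assigned_name for m in family.assign_names(members)}
        for _ in range(5):
            shuffled = [members[i] for i in rng.permutation(len(members))]
            again = {m.gene_id: m.assigned_name for m in family.assign_names(shuffled)}
            assert again == base
        assert len(set(base.values())) == len(base)  # bijection


class TestRecovery:
    def test_classification_recovery_across_seeds(self):
        from mybkit.simulate import SyntheticGenomeConfig, generate_genome

        tp = fp = fn = 0
        for seed in range(3):
            cfg = SyntheticGenomeConfig(
                chromosome_length=100_000,
                n_family_genes=25,
                n_background_genes=40,
                n_tandem_clusters=1,
                n_segmental_blocks=0,
                repeat_noise=0.1,
                seed=100 + seed,
            )
            bundle, truth = generate_genome(cfg)
            pssm = family.build_pssm(cfg.repeat_consensus)
            for m in bundle.models:
                arch = family.merge_hits(
                    family.scan_repeats(
                        ProteinRecord(m.gene_id, m.gene_id, m.protein_sequence), pssm
                    ),
                    gene_id=m.gene_id,
                )
                true_cls = truth.genes[m.gene_id]["family_class"]
                if arch.family_class == "none" and true_cls == "none":
                    continue
                if arch.family_class == true_cls:
                    tp += 1
                elif true_cls == "none":
                    fp += 1
                else:
                    fn += 1
        assert fp == 0
        assert tp / (tp + fn) >= 0.99
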