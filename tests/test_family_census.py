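import random

import pytest

from famexpand.family_census import (ClusterCall, ProteinRecord,
                                     apply_min_length, call_orf, census,
                                     cluster_isoforms, intervals_conflict,
                                     pairwise_nt_identity, resolve_gene_units,
                                     select_family_transcripts)
from famexpand.seqio import SequenceRecord
from famexpand.synthetic_data import _reverse_translate
from famexpand.translated_search import AlignmentHit
from oracles import min_chain_oracle

AA_NO_M = "ARNDCQEGHILKFPSTWYV"  # avoids stray internal start codons


def protein_without_internal_met(rng, length):
    body = rng.integers(0, len(AA_NO_M), size=length - 1)
    return "M" + "".join(AA_NO_M[i] for i in body)


def mutate_evenly(seq, n_mut, shift=0):
    """Substitute n_mut positions at even spacing through the interior, so a
    local aligner cannot trim its way past the target identity."""
    arr = list(seq)
    span = len(seq) - 20
    for k in range(n_mut):
        p = 10 + shift + (k * span) // n_mut
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


def hit_for(tid, subject, frame=1, qs=1, qe=100, ss=1, se=100, bits=200.0,
            qlen=300, sid_bits=None):
    return AlignmentHit(query_id=tid, subject_id=subject, frame=frame,
                        q_aa_start=qs, q_aa_end=qe, s_start=ss, s_end=se,
                        bit_score=bits, e_value=1e-40, identity=0.95,
                        q_nongap=qe - qs + 1, aligned_cols=qe - qs + 1,
                        mismatches=0, gap_opens=0, q_len_nt=qlen)


class TestSelection:
    ANN = {
        "P1": ProteinRecord("P1", "M" * 10, family="CYP6", clan="CYP3",
                            description="cytochrome P450 6BQ"),
        "P2": ProteinRecord("P2", "M" * 10, family="CatL", clan="",
                            description="cysteine peptidase cathepsin-L"),
        "P3": ProteinRecord("P3", "M" * 10, family="Actin", clan="",
                            description="actin-related protein"),
    }

    def test_keyword_routing(self):
        top = {"a": hit_for("a", "P1"), "b": hit_for("b", "P2"),
               "c": hit_for("c", "P3")}
        sel = select_family_transcripts(top, self.ANN)
        assert sel["P450"] == ["a"]
        assert sel["cathepsin"] == ["b"]

    def test_double_keyword_match_selects_once(self):
        top = {"b": hit_for("b", "P2")}
        sel = select_family_transcripts(top, self.ANN)
        assert sel["cathepsin"] == ["b"]

    def test_overlapping_keyword_groups_rejected(self):
        with pytest.raises(ValueError, match="share"):
            select_family_transcripts(
                {}, self.ANN, {"a": ["p450"], "b": ["P450"]})

    def test_missing_annotation_raises(self):
        with pytest.raises(KeyError, match="P9"):
            select_family_transcripts({"x": hit_for("x", "P9")}, self.ANN)


class TestMinLength:
    def test_boundary_249_vs_250(self):
        ts = [SequenceRecord("short", "A" * 249),
              SequenceRecord("ok", "A" * 250)]
        kept = apply_min_length(ts)
        assert [t.id for t in kept] == ["ok"]

    def test_empty_and_idempotent(self):
        assert apply_min_length([]) == []
        ts = [SequenceRecord("x", "A" * 300)]
        assert apply_min_length(apply_min_length(ts)) == ts


class TestIsoformClustering:
    @pytest.fixture()
    def base_seq(self, rng):
        return "".join(rng.choice(list("ACGT"), size=600))

    def test_96_percent_merged_94_percent_split(self, base_seq):
        t96 = mutate_evenly(base_seq, 24)   # 4% divergence
        t94 = mutate_evenly(base_seq, 36)   # 6% divergence
        a = SequenceRecord("a", base_seq)
        assert len(cluster_isoforms([a, SequenceRecord("b", t96)])) == 1
        assert len(cluster_isoforms([a, SequenceRecord("b", t94)])) == 2

    def test_single_linkage_chain(self, base_seq):
        b = mutate_evenly(base_seq, 24)            # a~b 96%
        c = mutate_evenly(b, 24, shift=5)          # b~c 96%, a~c ~92%
        ia, _ = pairwise_nt_identity(base_seq, c)
        assert ia < 0.95  # a and c are NOT directly linkable
        clusters = cluster_isoforms([SequenceRecord("a", base_seq),
                                     SequenceRecord("b", b),
                                     SequenceRecord("c", c)])
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_reverse_complement_isoform_detected(self, base_seq):
        from famexpand.translated_search import reverse_complement
        iso = reverse_complement(mutate_evenly(base_seq, 12))
        clusters = cluster_isoforms([SequenceRecord("a", base_seq),
                                     SequenceRecord("b", iso)])
        assert len(clusters) == 1

    def test_low_coverage_not_linked(self, base_seq):
        # identical subsequence, but only 40% of the shorter sequence
        piece = base_seq[:240] + "".join(
            "TGCA"[(i * 7) % 4] for i in range(360))
        clusters = cluster_isoforms([SequenceRecord("a", base_seq),
                                     SequenceRecord("b", piece)])
        assert len(clusters) == 2

    def test_representative_is_longest_then_lexicographic(self, base_seq):
        t2 = mutate_evenly(base_seq, 12) + "ACGTAC"
        clusters = cluster_isoforms([SequenceRecord("z", base_seq),
                                     SequenceRecord("b", t2)])
        assert clusters[0][0].id == "b"  # longer wins


class TestCallOrf:
    @pytest.fixture()
    def gene(self, rng):
        prot = protein_without_internal_met(rng, 100)
        cds = _reverse_translate(rng, prot)
        return prot, cds

    def test_full_cds_is_complete(self, gene):
        prot, cds = gene
        tr = SequenceRecord("t", cds)
        orf = call_orf(tr, hit_for("t", "P", qs=1, qe=100, qlen=len(cds)))
        assert orf.status == "complete"
        assert orf.has_start and orf.has_stop

    def test_internal_fragment_is_truncated(self, gene):
        prot, cds = gene
        frag = cds[60:240]  # codon-aligned interior, no ATG, no stop
        tr = SequenceRecord("t", frag)
        orf = call_orf(tr, hit_for("t", "P", qs=1, qe=60, qlen=len(frag)))
        assert orf.status == "truncated"
        assert not orf.has_start and not orf.has_stop

    def test_start_without_stop_is_truncated(self, gene):
        prot, cds = gene
        no_stop = cds[:-3]
        tr = SequenceRecord("t", no_stop)
        orf = call_orf(tr, hit_for("t", "P", qs=1, qe=100, qlen=len(no_stop)))
        assert orf.has_start and not orf.has_stop
        assert orf.status == "truncated"

    def test_stop_inside_hit_interval_cannot_be_complete(self, gene):
        prot, cds = gene
        # corrupt codon 50 into TAA: premature stop inside the aligned region
        broken = cds[:147] + "TAA" + cds[150:]
        tr = SequenceRecord("t", broken)
        orf = call_orf(tr, hit_for("t", "P", qs=1, qe=100, qlen=len(broken)))
        assert orf.status == "truncated"

    def test_frame_inconsistent_raises(self, gene):
        prot, cds = gene
        with pytest.raises(ValueError):
            call_orf(SequenceRecord("t", "AC"),
                     hit_for("t", "P", frame=3, qs=1, qe=10))


class TestResolveGeneUnits:
    def call(self, iid, interval, complete=False):
        return ClusterCall(iid, interval, complete)

    def test_disjoint_truncated_fragments_merge(self):
        units = resolve_gene_units([self.call("a", (1, 100)),
                                    self.call("b", (150, 250))])
        assert len(units) == 1 and sorted(units[0]) == ["a", "b"]

    def test_overlapping_truncated_fragments_split(self):
        units = resolve_gene_units([self.call("a", (1, 120)),
                                    self.call("b", (100, 220))])
        assert len(units) == 2

    def test_three_interval_worked_example(self):
        units = resolve_gene_units([self.call("a", (1, 80)),
                                    self.call("b", (90, 160)),
                                    self.call("c", (140, 230))])
        assert len(units) == 2

    def test_complete_orfs_always_distinct(self):
        units = resolve_gene_units([self.call("a", (1, 100), complete=True),
                                    self.call("b", (150, 250), complete=True),
                                    self.call("c", (300, 400))])
        assert len(units) == 3

    def test_small_overlap_below_tolerance_ignored(self):
        # 10-aa overlap between two ~100-aa intervals: below min(15, 10%)
        units = resolve_gene_units([self.call("a", (1, 100)),
                                    self.call("b", (95, 200))])
        assert len(units) == 1

    def test_min_overlap_one_gives_literal_any_overlap(self):
        units = resolve_gene_units([self.call("a", (1, 100)),
                                    self.call("b", (100, 200))],
                                   min_overlap=1)
        assert len(units) == 2

    def test_matches_exhaustive_minimum_on_random_groups(self):
        pyrng = random.Random(42)

        def conflict(x, y):
            return intervals_conflict(x, y, 15, 0.10)

        for _ in range(300):
            n = pyrng.randint(1, 6)
            ivs = []
            for _ in range(n):
                s = pyrng.randint(1, 400)
                ivs.append((s, s + pyrng.randint(5, 250)))
            calls = [self.call(f"c{i}", iv) for i, iv in enumerate(ivs)]
            assert len(resolve_gene_units(calls)) == \
                min_chain_oracle(ivs, conflict)


def build_reference(rng, families):
    proteome = []
    genes = {}
    for fam in families:
        prot = protein_without_internal_met(rng, 120)
        proteome.append(ProteinRecord(
            id=f"{fam}_REF", seq=prot, family=fam, clan="CYP3",
            description=f"cytochrome P450 {fam}"))
        genes[fam] = (prot, _reverse_translate(rng, prot))
    return proteome, genes


class TestCensus:
    def test_isoforms_plus_second_subject_gives_two_genes(self, rng):
        proteome, genes = build_reference(rng, ["CYP6", "CYP9"])
        cds1 = genes["CYP6"][1]
        cds2 = genes["CYP9"][1]
        iso = mutate_evenly(cds1, round(0.03 * len(cds1)))
        ts = [SequenceRecord("A", cds1), SequenceRecord("B", iso),
              SequenceRecord("C", cds2)]
        res = census(ts, proteome)
        counts = {fc.family: fc.gene_count for fc in res.family_counts}
        assert counts == {"CYP6": 1, "CYP9": 1}
        tcounts = {fc.family: fc.transcript_count for fc in res.family_counts}
        assert tcounts == {"CYP6": 2, "CYP9": 1}

    def test_fragments_merge_and_complete_orf_stays_separate(self, rng):
        # one gene seen as two non-overlapping truncated fragments, plus a
        # complete-ORF transcript of a paralogous gene hitting the same
        # subject and overlapping both fragments -> 2 genes
        prot = protein_without_internal_met(rng, 360)
        cds = _reverse_translate(rng, prot)
        proteome = [ProteinRecord("CYP6_REF", prot, family="CYP6",
                                  clan="CYP3",
                                  description="cytochrome P450 CYP6")]
        paralog = list(prot)
        for p in range(2, 360, 7):  # ~14% aa divergence, keeps top hit
            paralog[p] = "A" if paralog[p] != "A" else "G"
        full = _reverse_translate(rng, "".join(paralog))
        frag1 = cds[0:300]          # aa 1-100
        frag2 = cds[3 * 150:]       # aa 151-360 + stop
        ts = [SequenceRecord("full", full), SequenceRecord("f1", frag1),
              SequenceRecord("f2", frag2)]
        res = census(ts, proteome)
        (fc,) = res.family_counts
        assert fc.gene_count == 2  # complete unit + merged fragment pair
        merged = [u for u in res.gene_units if len(u) == 2]
        assert len(merged) == 1

    def test_provenance_every_selected_transcript_in_one_cluster(
            self, tiny_dataset):
        res = census(tiny_dataset.transcripts, tiny_dataset.proteome)
        counted = [t for c in res.clusters for t in c.member_transcripts]
        assert len(counted) == len(set(counted))
        in_ledger = set(res.ledger.transcript_id) - {""}
        assert set(counted) <= in_ledger

    def test_gene_count_bounds(self, tiny_dataset):
        res = census(tiny_dataset.transcripts, tiny_dataset.proteome)
        for fc in res.family_counts:
            assert 1 <= fc.gene_count <= fc.transcript_count
        n_units = len(res.gene_units)
        assert n_units <= len(res.clusters)
        subjects = {c.subject_id for c in res.clusters}
        assert n_units >= len(subjects)

    def test_adding_new_subject_transcript_is_monotone(self, rng):
        proteome, genes = build_reference(rng, ["CYP6", "CYP9"])
        ts = [SequenceRecord("A", genes["CYP6"][1])]
        res1 = census(ts, proteome)
        ts.append(SequenceRecord("B", genes["CYP9"][1]))
        res2 = census(ts, proteome)
        total1 = sum(fc.gene_count for fc in res1.family_counts)
        total2 = sum(fc.gene_count for fc in res2.family_counts)
        assert total2 == total1 + 1

    def test_unannotated_subject_raises(self, rng):
        proteome, genes = build_reference(rng, ["CYP6"])
        bad = [p for p in proteome]
        ts = [SequenceRecord("A", genes["CYP6"][1])]
        hits = [hit_for("A", "MYSTERY", qlen=len(ts[0].seq))]
        with pytest.raises(KeyError, match="MYSTERY"):
            census(ts, bad, hits=hits)
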