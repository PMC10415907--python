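import numpy as np
import pytest

import retrokit as rk
from retrokit.retroscan import (
    NoCanonicalStartError,
    ParentCandidate,
    RetroWindow,
    assess_intron_loss,
    assign_parent,
    detect_cds_integrity,
    extract_window,
    find_polya_signal,
    find_polya_tail,
    find_tsd,
    scan_retrogene,
    translate,
    verify_tsd,
)
from retrokit.seqio import CoordinateError, GeneLocus, SequenceRecord


def make_locus(start, end, strand="+", contig="c", lid="L1"):
    return GeneLocus(
        locus_id=lid, species="s", contig=contig, start=start, end=end,
        strand=strand, gene_name="IFITM_X", exon_count=1,
    )


class TestExtractWindow:
    def test_plus_strand_arithmetic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = SequenceRecord(id="c", residues=seq)
        w = extract_window(genome, make_locus(100, 220), up=200, down=400)
        assert w.upstream == seq[0:100]
        assert w.body == seq[100:220]
        assert w.downstream == seq[220:620]

    def test_minus_strand_swaps_and_reverse_complements(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = SequenceRecord(id="c", residues=seq)
        w = extract_window(genome, make_locus(400, 520, strand="-"), up=200, down=400)
        rc = lambda s: SequenceRecord(id="x", residues=s).reverse_complement().residues
        assert w.upstream == rc(seq[520:720])
        assert w.body == rc(seq[400:520])
        assert w.downstream == rc(seq[0:400])

    def test_edge_truncation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        genome = SequenceRecord(id="c", residues=seq)
        w = extract_window(genome, make_locus(50, 150))
        assert len(w.upstream) == 50
        assert len(w.downstream) == 150

    def test_locus_outside_contig_is_an_error(self):
        genome = SequenceRecord(id="c", residues="ACGT" * 10)
        with pytest.raises(CoordinateError):
            extract_window(genome, make_locus(10, 100))


class TestPolyASignalAndTail:
    def test_first_hexamer_position(self):
        w = RetroWindow("L", "", "ATGTAA", "GGTTAATAAACCC")
        assert find_polya_signal(w) == 4

    def test_absent_signal_is_none(self):
        w = RetroWindow("L", "", "ATGTAA", "GGGGCCCCTTTT")
        assert find_polya_signal(w) is None

    def test_tail_found_after_signal_gap(self):
        w = RetroWindow("L", "", "ATGTAA", "CCCAATAAA" + "GC" + "A" * 12 + "GGGG")
        sp = find_polya_signal(w)
        assert sp == 3
        assert find_polya_tail(w, sp) == sp + 8

    def test_no_tail_within_gap_limit(self):
        w = RetroWindow("L", "", "ATGTAA", "AATAAA" + "GCGT" * 30 + "A" * 20)
        assert find_polya_tail(w, 0, max_gap_to_signal=50) is None

    def test_tail_without_signal_searches_whole_downstream(self):
        w = RetroWindow("L", "", "ATGTAA", "GCGTGC" + "A" * 10 + "CCC")
        assert find_polya_tail(w, None) == 6


class TestFindTsd:
    def test_constructed_direct_repeat_recovered(self):
        tsd = "CATTAGCG"
        up = "G" * 150 + tsd + "GTCCTCGG"  # TSD then a UTR remnant
        down = "CCGGTCGG" + "A" * 20 + tsd + "TCTCTGGC" + "G" * 60
        w = RetroWindow("L", up, "ATGTAA", down)
        t = find_tsd(w, tail_start=8)
        assert t is not None
        assert (t.sequence, t.length, t.mismatches) == (tsd, 8, 0)
        assert t.upstream_pos == 150
        assert t.downstream_pos == 28
        assert verify_tsd(w, t)

    def test_no_shared_kmer_near_boundaries_is_none(self):
        w = RetroWindow("L", "G" * 200, "ATGTAA", "C" * 10 + "A" * 15 + "T" * 100)
        assert find_tsd(w, tail_start=10) is None

    def test_mismatch_budget_is_respected(self, mut1_world):
        cfg, genome, loci, truth = mut1_world
        by_id = {l.locus_id: l for l in loci}
        checked = 0
        for ins in truth.insertions[:50]:
            w = extract_window(genome, by_id[ins.locus_id])
            sp = find_polya_signal(w)
            ts = find_polya_tail(w, sp)
            if ts is None:
                continue
            t = find_tsd(w, ts)
            if t is not None:
                assert verify_tsd(w, t)
                checked += 1
        assert checked > 30


class TestCdsIntegrity:
    def test_premature_stop_reported_with_expected_length(self):
        assert detect_cds_integrity("ATGTAA", expected_aa_len=5) == (2, False)

    def test_clean_short_cds_is_full(self):
        assert detect_cds_integrity("ATGAAATGA", expected_aa_len=2) == (None, True)

    def test_terminal_stop_is_not_premature_without_expectation(self):
        assert detect_cds_integrity("ATGAAATGA") == (None, True)

    def test_missing_terminal_stop_fails_full_cds(self):
        assert detect_cds_integrity("ATGAAAAAA") == (None, False)

    def test_non_atg_start_raises(self):
        with pytest.raises(NoCanonicalStartError):
            detect_cds_integrity("TTGAAATGA")

    def test_agrees_with_codon_by_codon_oracle(self, rng):
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(50):
            n = int(rng.integers(4, 40))
            body = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * n))
            body = body[: 3 * (len(body) // 3)]
            aa = translate(body)
            oracle = aa.find("*") + 1 or None  # 1-based first stop codon
            got, _ = detect_cds_integrity(body, expected_aa_len=None)
            n_codons = len(body) // 3
            expect = oracle if (oracle is not None and oracle < n_codons) else None
            assert got == expect


class TestIntronLoss:
    def _parent(self, rng):
        cds = "ATG" + "".join(
            rng.choice(["AAA", "GAA", "CTG", "GGC", "TGC", "CCA"], size=120)
        ) + "TGA"
        utr5 = "".join(rng.choice(list("ACGT"), size=50))
        utr3 = "".join(rng.choice(list("ACGT"), size=60))
        mrna = utr5 + cds + utr3
        ex1 = len(utr5) + 180
        return mrna, [ex1, len(mrna) - ex1], cds

    def test_spliced_copy_scores_yes(self, rng):
        mrna, exons, cds = self._parent(rng)
        rec = SequenceRecord(id="p", residues=mrna)
        assert assess_intron_loss(cds, rec, exons) == "yes"

    def test_retained_intron_scores_no(self, rng):
        mrna, exons, cds = self._parent(rng)
        rec = SequenceRecord(id="p", residues=mrna)
        insert_at = exons[0] - 50  # junction position within the CDS
        intron = "GT" + "".join(rng.choice(list("ACGT"), size=296)) + "AG"
        body = cds[:insert_at] + intron + cds[insert_at:]
        assert assess_intron_loss(body, rec, exons) == "no"

    def test_inconsistent_exon_lengths_raise(self, rng):
        mrna, exons, cds = self._parent(rng)
        rec = SequenceRecord(id="p", residues=mrna)
        with pytest.raises(ValueError):
            assess_intron_loss(cds, rec, [10, 20])

    def test_simulated_retrocopies_all_lose_introns(self, small_world):
        cfg, genome, loci, truth = small_world
        by_id = {l.locus_id: l for l in loci}
        for ins in truth.insertions:
            w = extract_window(genome, by_id[ins.locus_id])
            parent = truth.parents[ins.parent_id]
            assert (
                assess_intron_loss(w.body, SequenceRecord(id="p", residues=parent.mrna),
                                   parent.exon_lengths)
                == "yes"
            )


class TestAssignParent:
    def _candidates(self, rng, n=2):
        cands = []
        base = "ATG" + "".join(rng.choice(list("ACGT"), size=300))
        for i in range(n):
            seq = list(base)
            for j in range(len(seq)):
                if rng.random() < 0.05 * i:
                    seq[j] = rng.choice([c for c in "ACGT" if c != seq[j]])
            mrna = "".join(rng.choice(list("ACGT"), size=60)) + "".join(seq) + "".join(
                rng.choice(list("ACGT"), size=60)
            )
            cands.append(
                ParentCandidate(
                    mrna=SequenceRecord(id=f"P{i + 1}", residues=mrna),
                    cds_start=60, cds_end=60 + len(base),
                )
            )
        return cands

    def test_identical_query_wins_with_recency(self, rng):
        cands = self._candidates(rng)
        c0 = cands[0]
        w = RetroWindow(
            "L",
            upstream="G" * 30 + c0.mrna.residues[:60],
            body=c0.mrna.residues[60:-60],
            downstream=c0.mrna.residues[-60:] + "A" * 20 + "G" * 30,
        )
        pa = assign_parent(w, cands)
        assert pa.best_parent_id == "P1"
        assert pa.margin > 0
        assert pa.recency_flag

    def test_tie_breaks_to_lexicographically_first_id(self, rng):
        cands = self._candidates(rng, n=1)
        twin = ParentCandidate(
            mrna=SequenceRecord(id="A0", residues=cands[0].mrna.residues),
            cds_start=cands[0].cds_start, cds_end=cands[0].cds_end,
        )
        c0 = cands[0]
        w = RetroWindow(
            "L", upstream=c0.mrna.residues[:60],
            body=c0.mrna.residues[60:-60], downstream=c0.mrna.residues[-60:],
        )
        pa = assign_parent(w, cands + [twin])
        assert pa.best_parent_id == "A0"
        assert pa.margin == 0

    def test_empty_candidate_list_rejected(self):
        w = RetroWindow("L", "G" * 10, "ATGTAA", "C" * 10)
        with pytest.raises(ValueError):
            assign_parent(w, [])

    def test_truth_parent_recovered_under_mutation(self, mut1_world):
        # 3 paralogs at ~5% divergence, copies carrying 1% mutations
        cfg, genome, loci, truth = mut1_world
        by_id = {l.locus_id: l for l in loci}
        cands = [p.candidate() for p in truth.parents.values()]
        subset = truth.insertions[:100]
        correct = sum(
            assign_parent(extract_window(genome, by_id[i.locus_id]), cands).best_parent_id
            == i.parent_id
            for i in subset
        )
        assert correct / len(subset) >= 0.95


class TestScanRetrogene:
    def test_fields_equal_standalone_detectors(self, small_world):
        cfg, genome, loci, truth = small_world
        by_id = {l.locus_id: l for l in loci}
        ins = truth.insertions[0]
        w = extract_window(genome, by_id[ins.locus_id])
        rep = scan_retrogene(w, truth.parents[ins.parent_id].candidate())
        sp = find_polya_signal(w)
        ts = find_polya_tail(w, sp)
        assert rep.polya_signal_pos == sp
        assert rep.polya_tail_start == ts
        assert rep.tsd == find_tsd(w, ts)

    def test_clean_copy_is_retrogene_mutated_copy_is_retropseudogene(self, small_world):
        cfg, genome, loci, truth = small_world
        by_id = {l.locus_id: l for l in loci}
        seen = set()
        for ins in truth.insertions:
            w = extract_window(genome, by_id[ins.locus_id])
            rep = scan_retrogene(w, truth.parents[ins.parent_id].candidate())
            want = "retropseudogene" if ins.premature_stop else "retrogene"
            assert rep.verdict == want
            seen.add(want)
        assert seen == {"retrogene", "retropseudogene"}

    def test_intact_prosimian_style_copy_reports_all_hallmarks(self, rng):
        # synthetic stand-in for an intact lemur-lineage retrogene record:
        # all four insertion hallmarks present, no premature stop
        cfg = rk.SimConfig(seed=424201, genome_len=60_000, n_insertions=1,
                           nonsense_probability=0.0, truncation_probability=0.0)
        genome, loci, truth = rk.simulate_genome(cfg)
        ins = truth.insertions[0]
        w = extract_window(genome, [l for l in loci if l.locus_id == ins.locus_id][0])
        rep = scan_retrogene(w, truth.parents[ins.parent_id].candidate())
        assert rep.lacks_intron == "yes"
        assert rep.polya_signal_pos is not None
        assert rep.polya_tail_start is not None
        assert rep.tsd is not None
        assert rep.premature_stop_codon_index is None
        assert rep.full_cds
        assert rep.verdict == "retrogene"
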