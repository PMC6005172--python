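import pytest

from hgtscreen.blast_scores import SimilarityHit, TaxonClass, TaxonClassMap, TaxonRecord
from hgtscreen.screening import (
    CandidateBranch,
    GeneModel,
    check_splice_sites,
    classify_candidate,
    gene_models_from_gff3,
    rbh_presence_matrix,
    reciprocal_best_hits,
    screen_close_relatives,
    select_phylo_taxa,
)


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestCheckSpliceSites:
    def test_plus_strand_canonical(self):
        # exons 1-10 and 21-30; intron 11-20 reads GT......AG
        seq = "A" * 10 + "GT" + "C" * 6 + "AG" + "T" * 10
        model = GeneModel("g", "scf", "+", ((1, 10), (21, 30)))
        rep = check_splice_sites(model, {"scf": seq})
        assert rep.n_introns == 1
        assert rep.per_intron == [("GT", "AG", True)]

    def test_plus_strand_noncanonical(self):
        seq = "A" * 10 + "CA" + "C" * 6 + "TT" + "T" * 10
        model = GeneModel("g", "scf", "+", ((1, 10), (21, 30)))
        rep = check_splice_sites(model, {"scf": seq})
        assert rep.per_intron == [("CA", "TT", False)]

    def test_minus_strand_canonical_after_reverse_complement(self):
        # forward-strand intron reading CT......AC is GT..AG on the minus
        # strand (hand reverse-complement of the fixture)
        seq = "A" * 10 + "CT" + "G" * 6 + "AC" + "T" * 10
        model = GeneModel("g", "scf", "-", ((1, 10), (21, 30)))
        rep = check_splice_sites(model, {"scf": seq})
        assert rep.per_intron == [("GT", "AG", True)]

    def test_single_exon_gene_has_empty_report(self):
        model = GeneModel("g", "scf", "+", ((1, 30),))
        rep = check_splice_sites(model, {"scf": "A" * 30})
        assert rep.n_introns == 0 and rep.per_intron == []

    def test_exon_outside_scaffold_rejected(self):
        model = GeneModel("g", "scf", "+", ((1, 10), (21, 50)))
        with pytest.raises(ValueError, match="bounds"):
            check_splice_sites(model, {"scf": "A" * 30})

    def test_tiny_intron_rejected(self):
        model = GeneModel("g", "scf", "+", ((1, 10), (13, 30)))
        with pytest.raises(ValueError, match="intron"):
            check_splice_sites(model, {"scf": "A" * 30})

    def test_strand_symmetry(self):
        """A gene model lifted to the opposite strand of the
        reverse-complemented scaffold yields the identical report."""
        seq = "ACGTACGTAC" + "GT" + "ACGTAC" + "AG" + "TTGCAGGCAT"
        n = len(seq)
        fwd = GeneModel("g", "scf", "+", ((1, 10), (21, 30)))
        # mirror coordinates: position p -> n - p + 1
        mirrored_exons = tuple(
            sorted((n - e + 1, n - s + 1) for s, e in fwd.exons)
        )
        rev = GeneModel("g", "scf", "-", mirrored_exons)
        rep_fwd = check_splice_sites(fwd, {"scf": seq})
        rep_rev = check_splice_sites(rev, {"scf": _revcomp(seq)})
        assert rep_fwd.per_intron == rep_rev.per_intron

    def test_gff3_gene_models_parsed(self):
        gff = (
            "##gff-version 3\n"
            "scf1\tsrc\tgene\t1\t30\t.\t+\t.\tID=g1\n"
            "scf1\tsrc\texon\t1\t10\t.\t+\t.\tID=g1.e1;Parent=g1\n"
            "scf1\tsrc\texon\t21\t30\t.\t+\t.\tID=g1.e2;Parent=g1\n"
        )
        models = gene_models_from_gff3(gff)
        assert len(models) == 1
        assert models[0].exons == ((1, 10), (21, 30))
        assert models[0].strand == "+"


def _hits(rows):
    out = []
    ranks = {}
    for q, s, e, b in rows:
        ranks[q] = ranks.get(q, 0) + 1
        out.append(SimilarityHit(q, s, e, b, ranks[q]))
    return out


class TestReciprocalBestHits:
    def test_symmetric_pair_found(self):
        ab = _hits([("a1", "b1", 1e-50, 200.0)])
        ba = _hits([("b1", "a1", 1e-48, 190.0)])
        assert reciprocal_best_hits(ab, ba) == [("a1", "b1")]

    def test_asymmetric_best_rejected(self):
        ab = _hits([("a1", "b1", 1e-50, 200.0)])
        ba = _hits([("b1", "a2", 1e-60, 250.0), ("b1", "a1", 1e-48, 190.0)])
        assert reciprocal_best_hits(ab, ba) == []

    def test_cutoff_excludes_weak_best(self):
        ab = _hits([("a1", "b1", 0.5, 30.0)])
        ba = _hits([("b1", "a1", 0.5, 30.0)])
        assert reciprocal_best_hits(ab, ba, evalue_cutoff=0.1) == []

    def test_swap_transposes_pairs(self):
        ab = _hits([("a1", "b1", 1e-50, 200.0), ("a2", "b2", 1e-30, 100.0)])
        ba = _hits([("b1", "a1", 1e-48, 190.0), ("b2", "a2", 1e-28, 95.0)])
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        assert sorted((b, a) for a, b in fwd) == rev

    def test_presence_matrix(self):
        ab = _hits([("q1", "s1", 1e-50, 200.0)])
        ba = _hits([("s1", "q1", 1e-50, 200.0)])
        frame = rbh_presence_matrix(["q1", "q2"], {"spX": (ab, ba)})
        assert bool(frame.loc["q1", "spX"]) is True
        assert bool(frame.loc["q2", "spX"]) is False


def _close_relative_map():
    cmap = TaxonClassMap()
    cmap.add("choano1", TaxonRecord("Monosiga brevicollis",
                                    TaxonClass.EUK_NONMETAZOAN,
                                    "Choanoflagellatea", genus="Monosiga"))
    cmap.add("bac1", TaxonRecord("Escherichia coli", TaxonClass.BACTERIA,
                                 "Proteobacteria", genus="Escherichia"))
    return cmap


class TestScreenCloseRelatives:
    def test_top_choanoflagellate_hit_flags_gene(self):
        hits = _hits([("g", "choano1", 1e-40, 150.0), ("g", "bac1", 1e-30, 120.0)])
        assert screen_close_relatives(hits, _close_relative_map()) is True

    def test_second_rank_close_relative_does_not_flag(self):
        hits = _hits([("g", "bac1", 1e-50, 200.0), ("g", "choano1", 1e-40, 150.0)])
        assert screen_close_relatives(hits, _close_relative_map()) is False

    def test_no_hit_below_cutoff_not_flagged(self):
        hits = _hits([("g", "choano1", 5.0, 20.0)])
        assert screen_close_relatives(hits, _close_relative_map()) is False

    def test_empty_hits_rejected(self):
        with pytest.raises(ValueError):
            screen_close_relatives([], _close_relative_map())


def _selection_map(n_bact=15):
    cmap = TaxonClassMap()
    for i in range(n_bact):
        cmap.add(
            f"b{i}",
            TaxonRecord(f"Bacterium {i}", TaxonClass.BACTERIA, "P",
                        genus=f"Genus{i}"),
        )
    return cmap


class TestSelectPhyloTaxa:
    def test_caps_at_per_group(self):
        cmap = _selection_map(12)
        hits = _hits([("g", f"b{i}", 10 ** -(50 - i), 100.0) for i in range(12)])
        sel = select_phylo_taxa(hits, cmap, per_group=10)
        assert len(sel) == 10
        assert sel == [f"b{i}" for i in range(10)]

    def test_same_genus_skipped(self):
        cmap = _selection_map(3)
        # second subject shares the first one's genus
        cmap.add("b1", TaxonRecord("Bacterium 1b", TaxonClass.BACTERIA, "P",
                                   genus="Genus0"))
        hits = _hits([("g", "b0", 1e-50, 100.0), ("g", "b1", 1e-45, 90.0),
                      ("g", "b2", 1e-40, 80.0)])
        sel = select_phylo_taxa(hits, cmap, per_group=10)
        assert sel == ["b0", "b2"]

    def test_must_include_without_hit_is_omitted(self):
        cmap = _selection_map(2)
        hits = _hits([("g", "b0", 1e-50, 100.0), ("g", "b1", 1e-45, 90.0)])
        sel = select_phylo_taxa(
            hits, cmap, per_group=10, must_include=["Homo sapiens"]
        )
        assert sel == ["b0", "b1"]

    def test_genus_unique_within_group(self):
        cmap = _selection_map(8)
        for i in range(8):
            cmap.add(f"dup{i}", TaxonRecord(f"Bacterium {i} redux",
                                            TaxonClass.BACTERIA, "P",
                                            genus=f"Genus{i % 4}"))
        rows = [("g", f"b{i}", 10 ** -(60 - i), 100.0) for i in range(8)]
        rows += [("g", f"dup{i}", 10 ** -(40 - i), 90.0) for i in range(8)]
        sel = select_phylo_taxa(_hits(rows), cmap, per_group=6)
        genera = [cmap[s].genus for s in sel]
        assert len(genera) == len(set(genera))
        assert len(sel) <= 6

    def test_fungi_and_eukaryotes_separate_groups(self):
        cmap = TaxonClassMap()
        cmap.add("f1", TaxonRecord("Fungus one", TaxonClass.EUK_NONMETAZOAN,
                                   "Ascomycota", genus="FgA", is_fungus=True))
        cmap.add("e1", TaxonRecord("Alga one", TaxonClass.EUK_NONMETAZOAN,
                                   "Rhodophyta", genus="AlA"))
        hits = _hits([("g", "f1", 1e-30, 90.0), ("g", "e1", 1e-20, 70.0)])
        sel = select_phylo_taxa(hits, cmap, per_group=1)
        assert set(sel) == {"f1", "e1"}


class TestClassifyCandidate:
    @pytest.mark.parametrize(
        "n_animal,n_non,expected",
        [
            (0, 15, CandidateBranch.NO_ANIMAL_HITS_HGT),
            (1, 15, CandidateBranch.TOO_FEW_ANIMAL_HITS_DISCARD),
            (2, 15, CandidateBranch.TOO_FEW_ANIMAL_HITS_DISCARD),
            (3, 15, CandidateBranch.PHYLO_TEST),
            (10, 15, CandidateBranch.PHYLO_TEST),
        ],
    )
    def test_branching_rule(self, n_animal, n_non, expected):
        assert classify_candidate(n_animal, n_non) == expected

    def test_no_hits_at_all_rejected(self):
        with pytest.raises(ValueError):
            classify_candidate(0, 0)
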