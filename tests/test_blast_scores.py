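import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtscreen.blast_scores import (
    SimilarityHit,
    TaxonClass,
    TaxonClassMap,
    TaxonRecord,
    alien_index,
    best_hits_by_class,
    candidate_filter,
    hgt_index,
    parse_similarity_table,
    score_genes,
)


def _line(query, subject, evalue, bits):
    return "\t".join(
        [query, subject, "90.0", "100", "5", "0", "1", "100", "1", "100",
         str(evalue), str(bits)]
    )


def _map(entries):
    cmap = TaxonClassMap()
    for subject, klass, phylum in entries:
        cmap.add(subject, TaxonRecord(subject, TaxonClass(klass), phylum))
    return cmap


class TestTaxonClassMap:
    def test_tsv_loading_and_closed_label_set(self):
        cmap = TaxonClassMap.from_tsv(
            "s1\tMETAZOAN\tChordata\tHomo sapiens\tHomo\n"
            "s2\tbacteria\tProteobacteria\n"
        )
        assert cmap["s1"].genus == "Homo"
        assert cmap["s2"].taxon_class is TaxonClass.BACTERIA
        with pytest.raises(ValueError, match="unknown taxon class"):
            TaxonClassMap.from_tsv("s3\tVIRUS\tNone\n")

    def test_json_loading(self):
        cmap = TaxonClassMap.from_json(
            '{"s1": {"class": "EUK_NONMETAZOAN", "phylum": "Rhodophyta",'
            ' "organism": "Chondrus crispus", "fungus": false}}'
        )
        assert cmap["s1"].phylum == "Rhodophyta"
        assert not cmap["s1"].is_fungus


class TestParseSimilarityTable:
    def test_empty_stream_gives_empty_list(self):
        assert parse_similarity_table("") == []

    def test_single_line_parsed_with_rank_one(self):
        hits = parse_similarity_table(_line("q1", "s1", "1e-30", "120"))
        assert len(hits) == 1
        h = hits[0]
        assert (h.query, h.subject, h.evalue, h.bitscore, h.rank) == (
            "q1", "s1", 1e-30, 120.0, 1
        )

    def test_ranks_increase_per_query_in_file_order(self):
        text = "\n".join(
            [_line("q1", "a", "1e-5", "50"), _line("q2", "b", "1e-6", "60"),
             _line("q1", "c", "1e-7", "70")]
        )
        hits = parse_similarity_table(text)
        assert [(h.query, h.rank) for h in hits] == [("q1", 1), ("q2", 1), ("q1", 2)]

    @pytest.mark.parametrize(
        "bad",
        ["q1\ts1\tonly-three-cols", _line("q1", "s1", "not-a-number", "120")],
    )
    def test_malformed_line_raises_with_line_number(self, bad):
        text = _line("q0", "s0", "1e-5", "40") + "\n" + bad
        with pytest.raises(ValueError, match="line 2"):
            parse_similarity_table(text)


class TestBestHitsByClass:
    def test_all_hits_in_self_phylum_excluded(self):
        cmap = _map([("s1", "METAZOAN", "Ctenophora"), ("s2", "BACTERIA", "Ctenophora")])
        hits = [
            SimilarityHit("q", "s1", 1e-9, 50, 1),
            SimilarityHit("q", "s2", 1e-20, 90, 2),
        ]
        bm, bn, n_m, n_n = best_hits_by_class(hits, cmap, "Ctenophora")
        assert bm is None and bn is None and n_m == 0 and n_n == 0

    def test_lowest_evalue_wins_per_class(self):
        cmap = _map([("m1", "METAZOAN", "Chordata"), ("m2", "METAZOAN", "Chordata"),
                     ("b1", "BACTERIA", "Proteobacteria")])
        hits = [
            SimilarityHit("q", "m1", 1e-5, 40, 1),
            SimilarityHit("q", "m2", 1e-9, 60, 2),
            SimilarityHit("q", "b1", 1e-3, 30, 3),
        ]
        bm, bn, n_m, n_n = best_hits_by_class(hits, cmap, "Ctenophora")
        assert bm.subject == "m2" and bn.subject == "b1"
        assert (n_m, n_n) == (2, 1)

    def test_evalue_tie_broken_by_higher_bitscore(self):
        # frozen by hand: equal E-values, 130 bits beats 100 bits
        cmap = _map([("m1", "METAZOAN", "Chordata"), ("m2", "METAZOAN", "Mollusca")])
        hits = [
            SimilarityHit("q", "m1", 1e-9, 100, 1),
            SimilarityHit("q", "m2", 1e-9, 130, 2),
        ]
        bm, _, _, _ = best_hits_by_class(hits, cmap, "Ctenophora")
        assert bm.subject == "m2"

    def test_unmapped_subject_skipped(self, caplog):
        cmap = _map([("m1", "METAZOAN", "Chordata")])
        hits = [SimilarityHit("q", "mystery", 1e-30, 200, 1),
                SimilarityHit("q", "m1", 1e-5, 40, 2)]
        bm, bn, _, _ = best_hits_by_class(hits, cmap, "Ctenophora")
        assert bm.subject == "m1" and bn is None


class TestAlienIndex:
    def test_equal_evalues_give_zero(self):
        assert alien_index(1e-10, 1e-10) == 0.0

    def test_missing_animal_hit_value(self):
        # no animal hit substitutes E = 1: AI = ln(1) - ln(1e-30) = 30 ln 10
        assert alien_index(None, 1e-30) == pytest.approx(30 * math.log(10), rel=1e-6)

    def test_missing_nonanimal_hit_value(self):
        assert alien_index(1e-50, None) == pytest.approx(-50 * math.log(10), rel=1e-6)

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            alien_index(-1e-5, 1e-5)

    @given(
        em=st.floats(min_value=1e-180, max_value=1.0),
        en=st.floats(min_value=1e-180, max_value=1.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetry(self, em, en):
        assert alien_index(em, en) == pytest.approx(-alien_index(en, em), abs=1e-9)

    @given(
        em=st.floats(min_value=1e-150, max_value=1.0),
        en=st.floats(min_value=1e-150, max_value=1.0),
        factor=st.floats(min_value=1e-10, max_value=1.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_nonanimal_evalue(self, em, en, factor):
        # improving (shrinking) the non-animal E-value never lowers the index
        assert alien_index(em, en * factor) >= alien_index(em, en) - 1e-12


class TestHgtIndex:
    @pytest.mark.parametrize(
        "nb,mb,expected", [(200, 200, 0), (250, 100, 150), (None, 120, -120)]
    )
    def test_bitscore_difference(self, nb, mb, expected):
        assert hgt_index(nb, mb) == expected


class TestCandidateFilter:
    def _gene(self, name, ai):
        return score_genes([], TaxonClassMap(), "X") or None  # unused helper

    def test_strictly_greater_than_threshold(self):
        from hgtscreen.blast_scores import ScoredGene

        genes = [
            ScoredGene("a", 1, 1, 0, 0, alien_index=46.0),
            ScoredGene("b", 1, 1, 0, 0, alien_index=45.0),
            ScoredGene("c", 1, 1, 0, 0, alien_index=10.0),
        ]
        kept = candidate_filter(genes)
        assert [g.gene for g in kept] == ["a"]

    def test_empty_input(self):
        assert candidate_filter([]) == []

    def test_boundary_values_all_excluded(self):
        from hgtscreen.blast_scores import ScoredGene

        genes = [ScoredGene(str(i), 1, 1, 0, 0, alien_index=45.0) for i in range(3)]
        assert candidate_filter(genes) == []


def _brute_force_best(hits, cmap, self_phylum, metazoan):
    pool = []
    for h in hits:
        rec = cmap.get(h.subject)
        if rec is None or rec.phylum == self_phylum:
            continue
        if (rec.taxon_class is TaxonClass.METAZOAN) == metazoan:
            pool.append(h)
    if not pool:
        return None
    return min(pool, key=lambda h: (h.evalue, -h.bitscore, h.rank))


def test_scoring_agrees_with_exhaustive_rescan():
    """Random tables: per-class best hits and indices match a brute-force
    re-scan of every hit."""
    rng = np.random.default_rng(42)
    classes = list(TaxonClass)
    phyla = ["P1", "P2", "Self"]
    cmap = TaxonClassMap()
    subjects = [f"s{i}" for i in range(40)]
    for s in subjects:
        cmap.add(
            s,
            TaxonRecord(
                s,
                classes[rng.integers(0, 4)],
                phyla[rng.integers(0, 3)],
            ),
        )
    for trial in range(50):
        hits = []
        ranks = {}
        for _ in range(rng.integers(1, 30)):
            q = f"g{rng.integers(0, 3)}"
            ranks[q] = ranks.get(q, 0) + 1
            hits.append(
                SimilarityHit(
                    q,
                    subjects[rng.integers(0, len(subjects))],
                    float(10.0 ** rng.uniform(-100, 1)),
                    float(rng.uniform(20, 500)),
                    ranks[q],
                )
            )
        for sg in score_genes(hits, cmap, "Self"):
            mine = [h for h in hits if h.query == sg.gene]
            bm = _brute_force_best(mine, cmap, "Self", metazoan=True)
            bn = _brute_force_best(mine, cmap, "Self", metazoan=False)
            assert sg.best_meta_evalue == (None if bm is None else bm.evalue)
            assert sg.best_nonmeta_evalue == (None if bn is None else bn.evalue)
            expected_ai = alien_index(
                None if bm is None else bm.evalue,
                None if bn is None else bn.evalue,
            )
            assert sg.alien_index == pytest.approx(expected_ai, abs=1e-12)
            assert sg.hgt_index == pytest.approx(
                hgt_index(
                    None if bn is None else bn.bitscore,
                    None if bm is None else bm.bitscore,
                ),
                abs=1e-12,
            )
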