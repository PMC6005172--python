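"""Contamination and provenance screens around the phylogenetic core.

Four orthogonal lines of evidence distinguish genuine horizontal
transfers from contaminants or vertically inherited genes:

* splice sites — spliceosomal (U2) introns with GT donors and AG acceptors
  only occur in eukaryotic genes, so intron-bearing candidates are not
  bacterial contamination;
* reciprocal best hits across independently collected transcriptomes —
  the same contaminant is unlikely to recur in every dataset;
* close-relative screen — candidates whose top database hit is a
  choanoflagellate or filasterean may simply be vertically inherited genes
  lost elsewhere in animals;
* hit-count triage — candidates lacking animal hits are transfers by
  absence, candidates with only one or two animal hits are discarded as
  untestable, the rest proceed to tree building with a genus-deduplicated
  taxon sample.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .blast_scores import SimilarityHit, TaxonClass, TaxonClassMap, _better

__all__ = [
    "GeneModel",
    "SpliceReport",
    "CandidateBranch",
    "read_genome_fasta",
    "gene_models_from_gff3",
    "check_splice_sites",
    "splice_report_frame",
    "reciprocal_best_hits",
    "screen_close_relatives",
    "select_phylo_taxa",
    "classify_candidate",
    "rbh_presence_matrix",
    "DEFAULT_CLOSE_RELATIVE_GROUPS",
]

DEFAULT_CLOSE_RELATIVE_GROUPS = frozenset({"Choanoflagellatea", "Filasterea"})


@dataclass(frozen=True)
class GeneModel:
    """A gene model: ordered exons on a scaffold (1-based inclusive)."""

    gene: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene}: gene model needs at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError(
                    f"{self.gene}: exons must be sorted and non-overlapping"
                )
            if end < start:
                raise ValueError(f"{self.gene}: exon end before start")
            prev_end = end

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class SpliceReport:
    """Donor/acceptor dinucleotides per intron, in transcript orientation."""

    gene: str
    n_introns: int
    per_intron: list[tuple[str, str, bool]]  # (donor, acceptor, canonical)

    @property
    def all_canonical(self) -> bool:
        return all(c for _, _, c in self.per_intron)


class CandidateBranch:
    """Triage outcomes for an alien-index candidate after the database
    re-search."""

    NO_ANIMAL_HITS_HGT = "NO_ANIMAL_HITS_HGT"
    TOO_FEW_ANIMAL_HITS_DISCARD = "TOO_FEW_ANIMAL_HITS_DISCARD"
    PHYLO_TEST = "PHYLO_TEST"


# ---------------------------------------------------------------------------
# gene models and splice sites
# ---------------------------------------------------------------------------
def read_genome_fasta(handle: IO[str] | str) -> dict[str, str]:
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def gene_models_from_gff3(handle: IO[str] | str) -> list[GeneModel]:
    """Parse gene models from GFF3 text (gene features with exon children).

    Coordinates stay 1-based inclusive as in GFF3.  Exons are attached to
    their ``Parent`` gene (directly or through an mRNA feature).
    """
    import gffutils

    text = handle.read() if hasattr(handle, "read") else handle
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(
            GeneModel(gene.id, gene.seqid, gene.strand, tuple(exons))
        )
    return models


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def check_splice_sites(model: GeneModel, genome: Mapping[str, str]) -> SpliceReport:
    """Classify each intron's splice dinucleotides as U2-canonical (GT..AG).

    Introns are the inter-exon gaps read in transcript orientation: on the
    minus strand the donor is the reverse complement of the intron's last
    two genomic bases and the acceptor of its first two.
    """
    if model.scaffold not in genome:
        raise KeyError(f"scaffold {model.scaffold!r} not in genome")
    seq = genome[model.scaffold]
    if model.exons[-1][1] > len(seq) or model.exons[0][0] < 1:
        raise ValueError(f"{model.gene}: exon outside scaffold bounds")
    introns = []
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        istart, iend = e1 + 1, s2 - 1
        if iend - istart + 1 < 4:
            raise ValueError(f"{model.gene}: intron shorter than 4 bases")
        introns.append((istart, iend))
    if model.strand == "-":
        introns = introns[::-1]
    per_intron = []
    for istart, iend in introns:
        if model.strand == "+":
            donor = seq[istart - 1 : istart + 1]
            acceptor = seq[iend - 2 : iend]
        else:
            donor = _revcomp(seq[iend - 2 : iend])
            acceptor = _revcomp(seq[istart - 1 : istart + 1])
        canonical = donor.upper() == "GT" and acceptor.upper() == "AG"
        per_intron.append((donor.upper(), acceptor.upper(), canonical))
    return SpliceReport(model.gene, len(per_intron), per_intron)


def splice_report_frame(reports: Iterable[SpliceReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for i, (donor, acceptor, canonical) in enumerate(r.per_intron, start=1):
            rows.append(
                {"gene": r.gene, "intron": i, "donor": donor,
                 "acceptor": acceptor, "canonical": canonical}
            )
        if r.n_introns == 0:
            rows.append(
                {"gene": r.gene, "intron": 0, "donor": "", "acceptor": "",
                 "canonical": None}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------
def _best_per_query(
    hits: Iterable[SimilarityHit], evalue_cutoff: float
) -> dict[str, SimilarityHit]:
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.evalue > evalue_cutoff:
            continue
        cur = best.get(h.query)
        best[h.query] = h if cur is None else _better(cur, h)
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[SimilarityHit],
    hits_ba: Iterable[SimilarityHit],
    evalue_cutoff: float = 0.1,
) -> list[tuple[str, str]]:
    """Pairs (a, b) that are each other's best hit in both directions.

    Best = lowest E-value, ties broken by higher bitscore then earlier
    rank; hits above the E-value cutoff never participate.
    """
    best_ab = _best_per_query(hits_ab, evalue_cutoff)
    best_ba = _best_per_query(hits_ba, evalue_cutoff)
    pairs = []
    for a, hit in best_ab.items():
        b = hit.subject
        back = best_ba.get(b)
        if back is not None and back.subject == a:
            pairs.append((a, b))
    return sorted(pairs)


def rbh_presence_matrix(
    queries: Sequence[str],
    tables: Mapping[str, tuple[Iterable[SimilarityHit], Iterable[SimilarityHit]]],
    evalue_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Presence/absence of each query across several transcriptomes,
    scored by reciprocal best hits (rows: queries, columns: datasets)."""
    data = {}
    for species, (ab, ba) in tables.items():
        pairs = dict(reciprocal_best_hits(ab, ba, evalue_cutoff))
        data[species] = [q in pairs for q in queries]
    return pd.DataFrame(data, index=list(queries))


# ---------------------------------------------------------------------------
# close-relative and taxon-selection screens
# ---------------------------------------------------------------------------
def screen_close_relatives(
    hits: Sequence[SimilarityHit],
    class_map: TaxonClassMap,
    flagged_groups: frozenset[str] | set[str] = DEFAULT_CLOSE_RELATIVE_GROUPS,
    evalue_cutoff: float = 0.1,
) -> bool:
    """True (remove from contention) iff the top-ranked hit passing the
    E-value cutoff belongs to a flagged protistan lineage.

    With the query taxon possibly sister to all other animals, a best hit
    in Choanoflagellatea or Filasterea is compatible with vertical
    inheritance plus loss, so such candidates are not called transfers.
    """
    if not hits:
        raise ValueError("empty hit list")
    for h in sorted(hits, key=lambda x: x.rank):
        if h.evalue > evalue_cutoff:
            continue
        rec = class_map.get(h.subject)
        if rec is None:
            continue
        return rec.phylum in flagged_groups
    return False


def _selection_group(rec) -> str:
    if rec.taxon_class is TaxonClass.METAZOAN:
        return "animals"
    if rec.taxon_class is TaxonClass.BACTERIA:
        return "bacteria"
    if rec.taxon_class is TaxonClass.ARCHAEA:
        return "archaea"
    return "fungi" if rec.is_fungus else "eukaryotes"


def select_phylo_taxa(
    hits: Sequence[SimilarityHit],
    class_map: TaxonClassMap,
    per_group: int = 10,
    evalue_cutoff: float = 0.1,
    must_include: Sequence[str] = (),
) -> list[str]:
    """Subjects for tree building: the top hits per domain group, one per
    genus, plus the best hit of each must-include organism.

    Groups (bacteria / archaea / non-fungal non-metazoan eukaryotes /
    fungi / animals) are walked in hit-rank order; a subject whose genus
    was already taken within its group is skipped; each group stops at
    ``per_group``.  Must-include organisms contribute their single best
    hit (within the cutoff) if not already selected.
    """
    selected: list[str] = []
    taken_genus: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for h in sorted(hits, key=lambda x: x.rank):
        if h.evalue > evalue_cutoff:
            continue
        rec = class_map.get(h.subject)
        if rec is None or h.subject in selected:
            continue
        group = _selection_group(rec)
        if counts.get(group, 0) >= per_group:
            continue
        if rec.genus in taken_genus.get(group, set()):
            continue
        selected.append(h.subject)
        taken_genus.setdefault(group, set()).add(rec.genus)
        counts[group] = counts.get(group, 0) + 1
    for organism in must_include:
        best = None
        for h in hits:
            if h.evalue > evalue_cutoff:
                continue
            rec = class_map.get(h.subject)
            if rec is None or rec.organism != organism:
                continue
            best = h if best is None else _better(best, h)
        if best is not None and best.subject not in selected:
            selected.append(best.subject)
    return selected


def classify_candidate(n_animal_hits: int, n_nonanimal_hits: int) -> str:
    """Triage a candidate by its animal-hit count at the E-value cutoff.

    No animal hits at all (with at least one non-animal hit) is itself
    evidence of transfer; one or two animal hits are too few to build a
    trustworthy tree and may be contamination, so the gene is discarded;
    three or more proceed to phylogenetic testing.
    """
    if n_animal_hits < 0 or n_nonanimal_hits < 0:
        raise ValueError("hit counts must be non-negative")
    if n_animal_hits == 0 and n_nonanimal_hits == 0:
        raise ValueError("candidate with no hits at all cannot be classified")
    if n_animal_hits == 0:
        return CandidateBranch.NO_ANIMAL_HITS_HGT
    if n_animal_hits <= 2:
        return CandidateBranch.TOO_FEW_ANIMAL_HITS_DISCARD
    return CandidateBranch.PHYLO_TEST
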