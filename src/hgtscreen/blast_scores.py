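"""Alien-index and HGT-index scoring of BLAST-style similarity tables.

The screen asks, for every query gene of an animal genome: is its best
database hit to a non-animal sequence dramatically better than its best hit
to any animal?  The alien index (AI) quantifies this as the log-scale gap
between the best animal and best non-animal E-values; the HGT index is the
analogous gap in bit scores.  Genes with AI above a threshold (45 by
default) become horizontal-gene-transfer candidates for downstream
phylogenetic confirmation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

import pandas as pd

__all__ = [
    "TaxonClass",
    "TaxonRecord",
    "TaxonClassMap",
    "SimilarityHit",
    "ScoredGene",
    "parse_similarity_table",
    "best_hits_by_class",
    "alien_index",
    "hgt_index",
    "score_genes",
    "candidate_filter",
    "scores_to_frame",
    "AI_EPSILON",
    "DEFAULT_AI_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Offset added to E-values before taking logs so that E = 0 stays finite.
AI_EPSILON = 1e-200

#: Candidate screen keeps genes with alien index strictly above this value.
DEFAULT_AI_THRESHOLD = 45.0


class TaxonClass(str, Enum):
    """Closed set of domain-level classes used to split hits."""

    BACTERIA = "BACTERIA"
    ARCHAEA = "ARCHAEA"
    EUK_NONMETAZOAN = "EUK_NONMETAZOAN"
    METAZOAN = "METAZOAN"

    @property
    def is_metazoan(self) -> bool:
        return self is TaxonClass.METAZOAN


@dataclass(frozen=True)
class TaxonRecord:
    """Organism-level annotation for one database subject."""

    organism: str
    taxon_class: TaxonClass
    phylum: str
    genus: str = ""
    is_fungus: bool = False


class TaxonClassMap:
    """Mapping from subject identifier to organism / class / phylum labels.

    Every identifier maps to exactly one record and the class label set is
    closed: unknown labels are rejected at load time.
    """

    def __init__(self, entries: Mapping[str, TaxonRecord] | None = None):
        self._entries: dict[str, TaxonRecord] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, subject: str) -> bool:
        return subject in self._entries

    def __getitem__(self, subject: str) -> TaxonRecord:
        return self._entries[subject]

    def get(self, subject: str) -> TaxonRecord | None:
        return self._entries.get(subject)

    def add(self, subject: str, record: TaxonRecord) -> None:
        self._entries[subject] = record

    def items(self):
        return self._entries.items()

    @staticmethod
    def _coerce_class(label: str) -> TaxonClass:
        try:
            return TaxonClass(label.strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown taxon class label {label!r}; expected one of "
                f"{[c.value for c in TaxonClass]}"
            ) from None

    @classmethod
    def from_tsv(cls, handle: IO[str] | str) -> "TaxonClassMap":
        """Load a 3+-column TSV: subject id, class, phylum[, organism[, genus[, fungus]]]."""
        if isinstance(handle, str):
            import io

            handle = io.StringIO(handle)
        entries: dict[str, TaxonRecord] = {}
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"taxon map line {lineno}: expected >= 3 columns")
            subject, klass, phylum = parts[0], parts[1], parts[2]
            organism = parts[3] if len(parts) > 3 else subject
            genus = parts[4] if len(parts) > 4 else organism.split()[0]
            fungus = len(parts) > 5 and parts[5].strip().lower() in {"1", "true", "yes"}
            entries[subject] = TaxonRecord(
                organism=organism,
                taxon_class=cls._coerce_class(klass),
                phylum=phylum,
                genus=genus,
                is_fungus=fungus,
            )
        return cls(entries)

    @classmethod
    def from_json(cls, handle: IO[str] | str) -> "TaxonClassMap":
        data = json.load(handle) if hasattr(handle, "read") else json.loads(handle)
        entries = {}
        for subject, rec in data.items():
            entries[subject] = TaxonRecord(
                organism=rec.get("organism", subject),
                taxon_class=cls._coerce_class(rec["class"]),
                phylum=rec["phylum"],
                genus=rec.get("genus", rec.get("organism", subject).split()[0]),
                is_fungus=bool(rec.get("fungus", False)),
            )
        return cls(entries)


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a tabular similarity search (BLAST outfmt-6 dialect)."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    rank: int  # 1-based file order within the query

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query}->{self.subject}")
        if self.bitscore < 0:
            raise ValueError(f"negative bit score for {self.query}->{self.subject}")


@dataclass
class ScoredGene:
    """Per-gene best-hit summary with alien and HGT indices."""

    gene: str
    best_meta_evalue: float | None
    best_nonmeta_evalue: float | None
    best_meta_bits: float | None
    best_nonmeta_bits: float | None
    alien_index: float = 0.0
    hgt_index: float = 0.0
    n_meta_hits: int = 0
    n_nonmeta_hits: int = 0

    @property
    def is_candidate(self) -> bool:
        return self.alien_index > DEFAULT_AI_THRESHOLD


def parse_similarity_table(stream: IO[str] | str | Iterable[str]) -> list[SimilarityHit]:
    """Parse tabular similarity output (outfmt-6: 12+ tab-separated columns).

    Hits are preserved in file order; ``rank`` is assigned 1..n per query.
    Malformed lines (wrong column count, non-numeric evalue/bitscore) raise
    a ``ValueError`` naming the line number.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    hits: list[SimilarityHit] = []
    ranks: dict[str, int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ValueError(
                f"similarity table line {lineno}: expected >= 12 tab-separated "
                f"columns, got {len(parts)}"
            )
        query, subject = parts[0], parts[1]
        try:
            evalue = float(parts[10])
            bitscore = float(parts[11])
        except ValueError:
            raise ValueError(
                f"similarity table line {lineno}: non-numeric evalue/bitscore"
            ) from None
        ranks[query] = ranks.get(query, 0) + 1
        hits.append(
            SimilarityHit(
                query=query,
                subject=subject,
                evalue=evalue,
                bitscore=bitscore,
                rank=ranks[query],
            )
        )
    return hits


def _better(a: SimilarityHit, b: SimilarityHit) -> SimilarityHit:
    """Lower E-value wins; ties broken by higher bitscore, then earlier rank."""
    if a.evalue != b.evalue:
        return a if a.evalue < b.evalue else b
    if a.bitscore != b.bitscore:
        return a if a.bitscore > b.bitscore else b
    return a if a.rank < b.rank else b


def best_hits_by_class(
    hits: Iterable[SimilarityHit],
    class_map: TaxonClassMap,
    self_phylum: str,
) -> tuple[SimilarityHit | None, SimilarityHit | None, int, int]:
    """Best metazoan and non-metazoan hits for one query's hit list.

    Hits whose subject phylum equals ``self_phylum`` are excluded from both
    classes so the query organism's own phylum cannot mask a transfer.
    Subjects missing from the map are skipped with a logged warning.

    Returns ``(best_meta, best_nonmeta, n_meta, n_nonmeta)`` with ``None``
    standing in for an empty class.
    """
    best_meta: SimilarityHit | None = None
    best_nonmeta: SimilarityHit | None = None
    n_meta = n_nonmeta = 0
    for hit in hits:
        record = class_map.get(hit.subject)
        if record is None:
            logger.warning("subject %s not in taxon map; skipped", hit.subject)
            continue
        if record.phylum == self_phylum:
            continue
        if record.taxon_class.is_metazoan:
            n_meta += 1
            best_meta = hit if best_meta is None else _better(best_meta, hit)
        else:
            n_nonmeta += 1
            best_nonmeta = hit if best_nonmeta is None else _better(best_nonmeta, hit)
    return best_meta, best_nonmeta, n_meta, n_nonmeta


def alien_index(
    best_meta_evalue: float | None, best_nonmeta_evalue: float | None
) -> float:
    """AI = ln(E_meta + eps) - ln(E_nonmeta + eps), eps = 1e-200.

    A missing hit substitutes E = 1 (the worst plausible hit), keeping the
    index finite and directionally correct.  Positive AI favours non-animal
    origin.
    """
    e_meta = 1.0 if best_meta_evalue is None else best_meta_evalue
    e_nonmeta = 1.0 if best_nonmeta_evalue is None else best_nonmeta_evalue
    if e_meta < 0 or e_nonmeta < 0:
        raise ValueError("E-values must be non-negative")
    return math.log(e_meta + AI_EPSILON) - math.log(e_nonmeta + AI_EPSILON)


def hgt_index(best_nonmeta_bits: float | None, best_meta_bits: float | None) -> float:
    """Difference between the highest non-animal and animal bit scores.

    A missing hit substitutes a bit score of 0.
    """
    nb = 0.0 if best_nonmeta_bits is None else best_nonmeta_bits
    mb = 0.0 if best_meta_bits is None else best_meta_bits
    return nb - mb


def score_genes(
    hits: Iterable[SimilarityHit],
    class_map: TaxonClassMap,
    self_phylum: str,
) -> list[ScoredGene]:
    """Score every query present in ``hits``; queries kept in first-seen order."""
    by_query: dict[str, list[SimilarityHit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query, []).append(hit)
    scored = []
    for gene, gene_hits in by_query.items():
        bm, bn, n_meta, n_nonmeta = best_hits_by_class(gene_hits, class_map, self_phylum)
        scored.append(
            ScoredGene(
                gene=gene,
                best_meta_evalue=None if bm is None else bm.evalue,
                best_nonmeta_evalue=None if bn is None else bn.evalue,
                best_meta_bits=None if bm is None else bm.bitscore,
                best_nonmeta_bits=None if bn is None else bn.bitscore,
                alien_index=alien_index(
                    None if bm is None else bm.evalue,
                    None if bn is None else bn.evalue,
                ),
                hgt_index=hgt_index(
                    None if bn is None else bn.bitscore,
                    None if bm is None else bm.bitscore,
                ),
                n_meta_hits=n_meta,
                n_nonmeta_hits=n_nonmeta,
            )
        )
    return scored


def candidate_filter(
    scored: Iterable[ScoredGene], ai_threshold: float = DEFAULT_AI_THRESHOLD
) -> list[ScoredGene]:
    """Retain genes with alien index strictly greater than the threshold.

    The HGT index is reported but never filtered on.  Output sorted by
    descending alien index (gene id breaks exact ties, for determinism).
    """
    kept = [g for g in scored if g.alien_index > ai_threshold]
    kept.sort(key=lambda g: (-g.alien_index, g.gene))
    return kept


def scores_to_frame(
    scored: Iterable[ScoredGene], ai_threshold: float = DEFAULT_AI_THRESHOLD
) -> pd.DataFrame:
    """Tabulate scores as the per-gene TSV-ready report."""
    rows = []
    for g in scored:
        rows.append(
            {
                "gene": g.gene,
                "best_meta_evalue": g.best_meta_evalue,
                "best_nonmeta_evalue": g.best_nonmeta_evalue,
                "best_meta_bits": g.best_meta_bits,
                "best_nonmeta_bits": g.best_nonmeta_bits,
                "alien_index": g.alien_index,
                "hgt_index": g.hgt_index,
                "n_meta_hits": g.n_meta_hits,
                "n_nonmeta_hits": g.n_nonmeta_hits,
                "candidate": g.alien_index > ai_threshold,
            }
        )
    return pd.DataFrame(rows)
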