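"""Ground-truthed synthetic fixtures for every pipeline stage.

Real transfer detection needs a query genome, curated sequence databases
and a developmental RNA-seq timecourse; none of those are shippable, so
this module fabricates small datasets whose truth is known by
construction: gene trees where the query was grafted into a bacterial or
eukaryotic donor clade (or kept with the animals), similarity tables whose
E-values follow a Karlin-Altschul-shaped map from sequence identity,
negative-binomial expression timecourses with stereotyped developmental
profiles, and intron-bearing gene models with controlled splice-site
canonicality.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .blast_scores import SimilarityHit, TaxonClass, TaxonClassMap, TaxonRecord
from .expression import ExpressionMatrix
from .phylo_engine import AMINO_ACIDS, Alignment, SubstitutionModel, simulate_alignment
from .tree_ops import PhyloTree

__all__ = [
    "ScenarioKind",
    "Scenario",
    "simulate_scenario",
    "synthesize_similarity_table",
    "synthesize_expression",
    "synthesize_gene_models",
    "EXPRESSION_PROFILES",
]


class ScenarioKind(str, Enum):
    HGT_FROM_BACTERIA = "HGT_FROM_BACTERIA"
    HGT_FROM_EUK = "HGT_FROM_EUK"
    VERTICAL = "VERTICAL"
    CONTAMINATION = "CONTAMINATION"


@dataclass
class Scenario:
    """One simulated gene history with everything the pipeline consumes."""

    kind: ScenarioKind
    true_tree: PhyloTree
    alignment: Alignment
    query: str
    class_map: TaxonClassMap
    contaminant_leaves: frozenset[str] = field(default_factory=frozenset)

    @property
    def metazoan_leaves(self) -> frozenset[str]:
        """Leaves labeled metazoan in the class map (excluding the query)."""
        return frozenset(
            leaf
            for leaf, _ in self.class_map.items()
            if self.class_map[leaf].taxon_class is TaxonClass.METAZOAN
            and leaf != self.query
        )


def _random_clade_newick(labels, rng, bl_mean):
    """Random coalescent-style joins with exponential branch lengths;
    returns (newick fragment without trailing length, stem handled by caller)."""
    nodes = [(lab, 0.0) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, _), (nb, _) = nodes[i], nodes[j]
        la = rng.exponential(bl_mean)
        lb = rng.exponential(bl_mean)
        joined = f"({na}:{la:.6f},{nb}:{lb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((joined, 0.0))
    return nodes[0][0]


def simulate_scenario(
    kind: ScenarioKind | str,
    n_bacteria: int = 4,
    n_euk: int = 3,
    n_metazoa: int = 4,
    n_sites: int = 300,
    divergence_scale: float = 1.0,
    seed: int = 0,
    n_contaminants: int = 2,
    model: SubstitutionModel | None = None,
) -> Scenario:
    """Simulate a gene history of the requested kind and its alignment.

    A three-clade backbone (bacteria, non-metazoan eukaryotes, metazoans)
    is built by random joins with exponential branch lengths scaled by
    ``divergence_scale``; the query is grafted inside the donor clade for
    the transfer kinds, inside the metazoan clade for VERTICAL, and for
    CONTAMINATION the gene is a bacterial transfer while ``n_contaminants``
    bacterial leaves are (mis)labeled metazoan in the class map.
    Deterministic under the seed.
    """
    kind = ScenarioKind(kind)
    if min(n_bacteria, n_euk, n_metazoa) < 2:
        raise ValueError("each clade needs at least 2 taxa")
    if n_sites < 50:
        raise ValueError("n_sites must be >= 50")
    rng = np.random.default_rng(seed)
    model = model or SubstitutionModel()
    query = "QUERY_CTENO"
    bac = [f"BAC_{i:02d}" for i in range(n_bacteria)]
    euk = [f"EUK_{i:02d}" for i in range(n_euk)]
    met = [f"MET_{i:02d}" for i in range(n_metazoa)]

    inner = 0.12 * divergence_scale  # within-clade joins
    stem = 0.45 * divergence_scale  # clade stems
    graft = 0.05 * divergence_scale  # query attachment branch

    if kind is ScenarioKind.VERTICAL:
        donor_labels = None
        met_labels = met + [query]
        bac_labels, euk_labels = bac, euk
    elif kind is ScenarioKind.HGT_FROM_EUK:
        euk_labels = euk + [query]
        bac_labels, met_labels = bac, met
    else:  # HGT_FROM_BACTERIA and CONTAMINATION
        bac_labels = bac + [query]
        euk_labels, met_labels = euk, met

    def clade(labels, has_query):
        if has_query:
            # graft the query onto a random clade member with a short branch
            # so the placement signal is unambiguous
            members = [x for x in labels if x != query]
            host = members[int(rng.integers(0, len(members)))]
            rest = [x for x in members if x != host]
            pair = f"({host}:{graft:.6f},{query}:{graft:.6f})"
            return _random_clade_newick([pair] + rest, rng, inner)
        return _random_clade_newick(labels, rng, inner)

    bac_nwk = clade(bac_labels, query in bac_labels)
    euk_nwk = clade(euk_labels, query in euk_labels)
    met_nwk = clade(met_labels, query in met_labels)
    newick = (
        f"({bac_nwk}:{stem:.6f},{euk_nwk}:{stem:.6f},{met_nwk}:{stem:.6f});"
    )

    contaminants: frozenset[str] = frozenset()
    if kind is ScenarioKind.CONTAMINATION:
        if n_contaminants > n_bacteria - 1:
            raise ValueError("not enough bacterial leaves to relabel")
        picked = rng.choice(n_bacteria, size=n_contaminants, replace=False)
        contaminants = frozenset(bac[i] for i in sorted(picked))

    entries: dict[str, TaxonRecord] = {}
    for i, leaf in enumerate(bac):
        klass = (
            TaxonClass.METAZOAN if leaf in contaminants else TaxonClass.BACTERIA
        )
        phylum = f"BacPhylum{i % 3}" if klass is TaxonClass.BACTERIA else "Mislabeled"
        entries[leaf] = TaxonRecord(leaf, klass, phylum, genus=f"Bacgen{i}")
    for i, leaf in enumerate(euk):
        entries[leaf] = TaxonRecord(
            leaf, TaxonClass.EUK_NONMETAZOAN, f"EukPhylum{i % 3}", genus=f"Eukgen{i}"
        )
    for i, leaf in enumerate(met):
        entries[leaf] = TaxonRecord(
            leaf, TaxonClass.METAZOAN, f"MetPhylum{i % 3}", genus=f"Metgen{i}"
        )
    entries[query] = TaxonRecord(query, TaxonClass.METAZOAN, "Ctenophora", genus="Query")
    class_map = TaxonClassMap(entries)

    leaf_classes = {
        leaf: entries[leaf].taxon_class.value for leaf in entries
    }
    tree = PhyloTree.from_newick(newick, leaf_classes=leaf_classes, query=query)
    aln = simulate_alignment(tree, model, n_sites, rng)
    return Scenario(
        kind=kind,
        true_tree=tree,
        alignment=aln,
        query=query,
        class_map=class_map,
        contaminant_leaves=contaminants,
    )


def synthesize_similarity_table(
    scenario: Scenario,
    seed: int = 0,
    bits_per_identity: float = 2.0,
    db_size: float = 1e8,
    bit_noise_sd: float = 1.0,
) -> list[SimilarityHit]:
    """Similarity hits of the query against every other scenario sequence.

    Bit scores follow a Karlin-Altschul-shaped map from pairwise identity
    (bits = lambda * identity * n_sites, plus a little Gaussian noise) and
    E-values are ``m * n * 2**-bits`` clamped to [1e-180, 10].  The exact
    constants are fixture conventions, not biological claims.
    """
    rng = np.random.default_rng(seed)
    q = scenario.alignment.sequences[scenario.query]
    m = scenario.alignment.n_sites
    rows = []
    for sid, seq in scenario.alignment.sequences.items():
        if sid == scenario.query:
            continue
        ok = [(a, b) for a, b in zip(q, seq) if a in AMINO_ACIDS and b in AMINO_ACIDS]
        identity = (
            sum(1 for a, b in ok if a == b) / len(ok) if ok else 0.0
        )
        bits = max(0.0, bits_per_identity * identity * m + rng.normal(0.0, bit_noise_sd))
        evalue = float(np.clip(m * db_size * 2.0 ** (-bits), 1e-180, 10.0))
        rows.append((sid, evalue, bits))
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    return [
        SimilarityHit(
            query=scenario.query, subject=sid, evalue=ev, bitscore=round(b, 1),
            rank=i + 1,
        )
        for i, (sid, ev, b) in enumerate(rows)
    ]


# ---------------------------------------------------------------------------
# expression timecourses
# ---------------------------------------------------------------------------
EXPRESSION_PROFILES = ("maternal", "zygotic_spike", "cyclic", "silent")


def _profile_mean_tpm(profile: str, hours: np.ndarray) -> np.ndarray:
    """Stereotyped developmental mean-expression shapes, in tpm units.

    maternal: deposited transcript decaying from fertilization;
    zygotic_spike: bump during tentacle morphogenesis (~9-12 hpf);
    cyclic: sinusoid through development (cell-cycle-like);
    silent: background noise well below the expressed threshold.
    """
    if profile == "maternal":
        return 120.0 * np.exp(-hours / 4.0)
    if profile == "zygotic_spike":
        return 150.0 * np.exp(-0.5 * ((hours - 10.5) / 1.5) ** 2)
    if profile == "cyclic":
        return 8.0 + 6.0 * np.sin(2.0 * np.pi * hours / 6.0)
    if profile == "silent":
        return np.full_like(hours, 0.4)
    raise ValueError(f"unknown expression profile {profile!r}")


def synthesize_expression(
    profiles: dict[str, str],
    n_timepoints: int = 25,
    reps_per_tp: int = 3,
    seed: int = 0,
    dispersion: float = 0.2,
    library_size: float = 5e5,
    n_background: int = 250,
) -> ExpressionMatrix:
    """Negative-binomial counts for a developmental timecourse.

    ``profiles`` maps gene id -> profile kind.  Background genes with flat
    expression fill the library so that tpm normalization reproduces the
    designed profile means.  Deterministic under the seed.
    """
    if reps_per_tp < 1:
        raise ValueError("reps_per_tp must be >= 1")
    for g, p in profiles.items():
        if p not in EXPRESSION_PROFILES:
            raise ValueError(f"unknown expression profile {p!r} for gene {g}")
    rng = np.random.default_rng(seed)
    hours = np.round(np.linspace(0.0, 20.0, n_timepoints), 3)
    samples, meta_rows = [], []
    for t_i, h in enumerate(hours):
        for rep in range(1, reps_per_tp + 1):
            samples.append(f"t{t_i:02d}_r{rep}")
            meta_rows.append({"sample": samples[-1], "time_point": h, "replicate": rep})
    genes = list(profiles) + [f"BG_{i:03d}" for i in range(n_background)]
    bg_tpm = (1e6 - 2000.0) / max(n_background, 1)
    mean_tpm = np.zeros((len(genes), len(samples)))
    for gi, g in enumerate(profiles):
        prof = np.repeat(_profile_mean_tpm(profiles[g], hours), reps_per_tp)
        mean_tpm[gi] = prof
    mean_tpm[len(profiles):] = bg_tpm

    mean_counts = mean_tpm * (library_size / 1e6)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, 1.0, size=mean_counts.shape) * dispersion * mean_counts
    counts = rng.poisson(lam).astype(float)
    cdf = pd.DataFrame(counts, index=genes, columns=samples)
    mdf = pd.DataFrame(meta_rows).set_index("sample")
    return ExpressionMatrix(cdf, mdf)


# ---------------------------------------------------------------------------
# gene models with controlled splice sites
# ---------------------------------------------------------------------------
_NONCANONICAL_DONORS = ("CA", "AT", "GA", "TC")
_NONCANONICAL_ACCEPTORS = ("TT", "CC", "GC", "AA")


def synthesize_gene_models(
    n_genes: int = 6,
    introns_per_gene: int = 2,
    canonical_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, str], str, pd.DataFrame]:
    """Random scaffolds with embedded multi-exon genes on both strands.

    Each intron is made U2-canonical (GT..AG in transcript orientation)
    with probability ``canonical_fraction``.  Returns (genome, GFF3 text,
    truth table with one row per intron).
    """
    if not 0.0 <= canonical_fraction <= 1.0:
        raise ValueError("canonical_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    gff = io.StringIO()
    gff.write("##gff-version 3\n")
    truth_rows = []
    for gi in range(n_genes):
        scaffold = f"scf{gi:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(30, 80))
        seq = list(rng.choice(bases, size=pos - 1))
        exons = []
        intron_truth = []
        n_exons = introns_per_gene + 1
        for e in range(n_exons):
            elen = int(rng.integers(50, 150))
            exons.append((pos, pos + elen - 1))
            seq.extend(rng.choice(bases, size=elen))
            pos += elen
            if e < n_exons - 1:
                ilen = int(rng.integers(60, 140))
                intron = list(rng.choice(bases, size=ilen))
                canonical = bool(rng.random() < canonical_fraction)
                if strand == "+":
                    donor = "GT" if canonical else _NONCANONICAL_DONORS[
                        int(rng.integers(0, len(_NONCANONICAL_DONORS)))
                    ]
                    acceptor = "AG" if canonical else _NONCANONICAL_ACCEPTORS[
                        int(rng.integers(0, len(_NONCANONICAL_ACCEPTORS)))
                    ]
                    intron[0], intron[1] = donor[0], donor[1]
                    intron[-2], intron[-1] = acceptor[0], acceptor[1]
                else:
                    # transcript orientation is right-to-left on the genome
                    donor = "GT" if canonical else _NONCANONICAL_DONORS[
                        int(rng.integers(0, len(_NONCANONICAL_DONORS)))
                    ]
                    acceptor = "AG" if canonical else _NONCANONICAL_ACCEPTORS[
                        int(rng.integers(0, len(_NONCANONICAL_ACCEPTORS)))
                    ]
                    # revcomp(GT) = AC at the genomic end; revcomp(AG) = CT at start
                    rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    intron[-2], intron[-1] = rc[donor[1]], rc[donor[0]]
                    intron[0], intron[1] = rc[acceptor[1]], rc[acceptor[0]]
                seq.extend(intron)
                pos += ilen
                intron_truth.append(canonical)
        seq.extend(rng.choice(bases, size=int(rng.integers(30, 80))))
        genome[scaffold] = "".join(seq)
        gene_id = f"gene{gi:03d}"
        gstart, gend = exons[0][0], exons[-1][1]
        gff.write(
            f"{scaffold}\tsynthetic\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\t"
            f"ID={gene_id}\n"
        )
        # transcript-order intron indices for the truth table
        order = (
            range(len(intron_truth))
            if strand == "+"
            else range(len(intron_truth) - 1, -1, -1)
        )
        for out_i, src_i in enumerate(order, start=1):
            truth_rows.append(
                {"gene": gene_id, "intron": out_i, "canonical": intron_truth[src_i]}
            )
        for ei, (es, ee) in enumerate(exons, start=1):
            gff.write(
                f"{scaffold}\tsynthetic\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                f"ID={gene_id}.e{ei};Parent={gene_id}\n"
            )
    truth = pd.DataFrame(truth_rows)
    return genome, gff.getvalue(), truth
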