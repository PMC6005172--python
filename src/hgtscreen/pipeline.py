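"""End-to-end orchestration of the detection-and-confirmation flow.

Stages, in order: alien-index scoring of similarity hits; candidate
triage by animal-hit counts; tree inference; contaminant pruning toward
animal monophyly (discarding candidates with more than ``max_prune``
disruptors); SOWH and dual AU topology tests against the
metazoan-constraint tree; the combined significance rule; the
close-relative screen; and optional expression / splice-site /
reciprocal-best-hit annexes.  Every per-gene decision is recorded with the
rule that produced it, and all randomness derives from one top-level seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _mlcore as core
from .blast_scores import (
    DEFAULT_AI_THRESHOLD,
    SimilarityHit,
    TaxonClass,
    TaxonClassMap,
    score_genes,
)
from .hypothesis_tests import (
    DEFAULT_AU_SCALES,
    au_test,
    combined_decision,
    likelihood_proportions,
    sowh_test,
)
from .phylo_engine import (
    Alignment,
    SubstitutionModel,
    _from_array_tree,
    site_log_likelihood_matrix,
)
from .screening import (
    CandidateBranch,
    classify_candidate,
    screen_close_relatives,
)
from .synthetic_data import Scenario, synthesize_similarity_table
from .tree_ops import (
    PhyloTree,
    dedupe_trees,
    is_monophyletic,
    prune_to_monophyly,
    shuffle_clades_of_three,
)

__all__ = ["PipelineParams", "GeneRecord", "PipelineReport", "run_scenario",
           "run_scenarios", "bootstrap_trees"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunable thresholds; defaults follow the published screen."""

    ai_threshold: float = DEFAULT_AI_THRESHOLD  # candidate iff AI > 45
    evalue_cutoff: float = 0.1
    max_prune: int = 2
    alpha: float = 0.05
    expression_threshold: float = 100.0
    n_bootstrap_trees: int = 100
    n_shuffled_trees: int = 100
    sowh_replicates: int = 99
    au_replicates: int = 10_000
    au_scales: tuple = DEFAULT_AU_SCALES
    seed: int = 0
    #: run the phylogenetic stage even for genes failing the alien-index
    #: screen (useful for probing the confirmation stage in isolation)
    skip_ai_screen: bool = False


@dataclass
class GeneRecord:
    """Per-gene pipeline outcome (one row of the final report)."""

    gene: str
    alien_index: float = float("nan")
    hgt_index: float = float("nan")
    candidate: bool = False
    branch: str | None = None
    pruned_leaves: list[str] = field(default_factory=list)
    prune_discarded: bool = False
    sowh_p: float | None = None
    au_p_bootstrap: float | None = None
    au_p_manual: float | None = None
    delta_lnl: float | None = None
    close_relative_flagged: bool = False
    confirmed: bool = False
    expression_score: float | None = None
    expressed: bool | None = None
    n_canonical_introns: int | None = None
    n_introns: int | None = None
    likelihood_proportions: dict | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class PipelineReport:
    records: list[GeneRecord]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = asdict(r)
            d["pruned_leaves"] = ",".join(r.pruned_leaves)
            d["notes"] = "; ".join(r.notes)
            d.pop("likelihood_proportions")
            rows.append(d)
        return pd.DataFrame(rows).set_index("gene")

    def to_json(self) -> str:
        return json.dumps([asdict(r) for r in self.records], indent=2)

    def proportions_long_table(self) -> pd.DataFrame:
        """Long-format likelihood proportions (gene, tree_class, proportion),
        ready for violin plots of suboptimal-tree spread per gene."""
        rows = []
        for r in self.records:
            props = r.likelihood_proportions
            if not props:
                continue
            rows.append({"gene": r.gene, "tree_class": "best",
                         "proportion": props["best"]})
            rows.append({"gene": r.gene, "tree_class": "constrained",
                         "proportion": props["constrained"]})
            for x in props["suboptimal"]:
                rows.append({"gene": r.gene, "tree_class": "suboptimal",
                             "proportion": x})
        return pd.DataFrame(rows, columns=["gene", "tree_class", "proportion"])


def bootstrap_trees(
    aln: Alignment,
    model: SubstitutionModel,
    n_trees: int,
    seed: int,
) -> list[PhyloTree]:
    """Nonparametric bootstrap trees: resample alignment columns with
    replacement and rerun a (fast-setting) ML search per replicate."""
    rng = np.random.default_rng(seed)
    order = sorted(aln.ids())
    base = np.array([list(aln.sequences[k]) for k in order])
    out = []
    for _ in range(n_trees):
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep = Alignment({k: "".join(base[i, cols]) for i, k in enumerate(order)})
        enc = rep.encode(order)
        lp = core.leaf_partials(enc)
        if len(order) <= 7:
            at, _ = core.exhaustive_search(
                lp, enc, model, refine_top=1, refine_passes=4, screen_top=30
            )
        else:
            at, _ = core.nni_search(
                lp, enc, model, None, max_sweeps=2, screen_passes=1,
                refine_passes=3,
            )
        out.append(_from_array_tree(at, order))
    return out


def _hit_counts_at_cutoff(
    hits: Sequence[SimilarityHit],
    class_map: TaxonClassMap,
    self_phylum: str,
    cutoff: float,
) -> tuple[int, int]:
    n_animal = n_nonanimal = 0
    for h in hits:
        rec = class_map.get(h.subject)
        if rec is None or h.evalue > cutoff or rec.phylum == self_phylum:
            continue
        if rec.taxon_class is TaxonClass.METAZOAN:
            n_animal += 1
        else:
            n_nonanimal += 1
    return n_animal, n_nonanimal


def run_scenario(
    scenario: Scenario,
    params: PipelineParams | None = None,
    model: SubstitutionModel | None = None,
    hits: Sequence[SimilarityHit] | None = None,
    seed: int | None = None,
) -> GeneRecord:
    """Run the full flow for one (synthetic) gene scenario.

    The similarity table is synthesized from the scenario unless supplied;
    the query phylum is taken from the scenario's class map.  Deterministic
    for a fixed seed.
    """
    params = params or PipelineParams()
    model = model or SubstitutionModel()
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_hits, s_boot, s_shuffle, s_sowh, s_au1, s_au2 = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    ]
    query = scenario.query
    self_phylum = scenario.class_map[query].phylum
    if hits is None:
        hits = synthesize_similarity_table(scenario, seed=s_hits)
    rec = GeneRecord(gene=query)

    scored = score_genes(hits, scenario.class_map, self_phylum)
    if not scored:
        rec.notes.append("no scoreable hits")
        return rec
    sg = scored[0]
    rec.alien_index = sg.alien_index
    rec.hgt_index = sg.hgt_index
    rec.candidate = sg.alien_index > params.ai_threshold
    if not rec.candidate and not params.skip_ai_screen:
        rec.notes.append(f"alien index {sg.alien_index:.1f} <= {params.ai_threshold}")
        return rec

    n_animal, n_nonanimal = _hit_counts_at_cutoff(
        hits, scenario.class_map, self_phylum, params.evalue_cutoff
    )
    rec.branch = classify_candidate(n_animal, n_nonanimal)
    if rec.branch == CandidateBranch.TOO_FEW_ANIMAL_HITS_DISCARD:
        rec.notes.append(f"only {n_animal} animal hits at E <= {params.evalue_cutoff}")
        return rec

    rec.close_relative_flagged = screen_close_relatives(
        list(hits), scenario.class_map, evalue_cutoff=params.evalue_cutoff
    )

    if rec.branch == CandidateBranch.NO_ANIMAL_HITS_HGT:
        # absence from all animals is itself the evidence; no trees to build
        rec.confirmed = not rec.close_relative_flagged
        rec.notes.append("no animal hits: transfer confirmed without topology tests")
        return rec

    # --- phylogenetic stage -------------------------------------------
    aln = scenario.alignment
    group = set(scenario.metazoan_leaves)
    order = sorted(aln.ids())
    enc = aln.encode(order)
    lp = core.leaf_partials(enc)
    if len(order) <= 7:
        at, _ = core.exhaustive_search(lp, enc, model)
    else:
        at, _ = core.nni_search(lp, enc, model, None)
    ml_tree = _from_array_tree(at, order)

    if is_monophyletic(ml_tree, group | {query}):
        # the candidate forms a clade with all other animals: vertical
        # inheritance explains the data, so it is ruled out without tests
        rec.notes.append("forms a clade with all other animals; ruled out")
        return rec

    if not is_monophyletic(ml_tree, group):
        prune_res = prune_to_monophyly(
            ml_tree, group, protected={query}, max_prune=params.max_prune
        )
        if not prune_res.success:
            rec.prune_discarded = True
            rec.notes.append(
                f"more than {params.max_prune} taxa disrupt animal monophyly"
            )
            return rec
        rec.pruned_leaves = prune_res.removed_leaves
        if prune_res.removed_leaves:
            rec.notes.append(
                "pruned putative contaminants: " + ",".join(prune_res.removed_leaves)
            )
            group -= set(prune_res.removed_leaves)
            aln = Alignment(
                {k: v for k, v in aln.sequences.items()
                 if k not in set(prune_res.removed_leaves)}
            )

    sowh = sowh_test(
        aln, group, query, model, n_reps=params.sowh_replicates, seed=s_sowh
    )
    rec.sowh_p = sowh.p_value
    rec.delta_lnl = sowh.delta_observed

    best_tree, con_tree = sowh.ml_tree, sowh.constrained_tree
    boots = dedupe_trees(
        bootstrap_trees(aln, model, params.n_bootstrap_trees, s_boot)
    )
    shuffled = shuffle_clades_of_three(
        best_tree, params.n_shuffled_trees, seed=s_shuffle
    )

    def au_against(subopt, au_seed):
        labeled = [("ml_best", best_tree), ("constraint", con_tree)]
        labeled += [(f"sub_{i:03d}", t) for i, t in enumerate(subopt)]
        mat = site_log_likelihood_matrix(labeled, aln, model)
        return au_test(
            mat, "constraint", scales=params.au_scales,
            n_rep=params.au_replicates, seed=au_seed,
        ), mat

    au_boot, boot_mat = au_against(boots, s_au1)
    au_man, _ = au_against(shuffled, s_au2)
    rec.au_p_bootstrap = au_boot.p_value
    rec.au_p_manual = au_man.p_value

    decision = combined_decision(
        sowh.p_value, au_boot.p_value, au_man.p_value, alpha=params.alpha
    )
    rec.confirmed = decision.confirmed and not rec.close_relative_flagged
    if rec.close_relative_flagged:
        rec.notes.append("top hit from a close protistan relative; removed")

    sub_lnls = [float(boot_mat.values[i].sum()) for i in range(2, len(boot_mat.labels))]
    if sub_lnls:
        rec.likelihood_proportions = likelihood_proportions(
            float(boot_mat.values[0].sum()), float(boot_mat.values[1].sum()), sub_lnls
        )
    return rec


def run_scenarios(
    scenarios: Iterable[Scenario],
    params: PipelineParams | None = None,
    model: SubstitutionModel | None = None,
) -> PipelineReport:
    """Run the pipeline over several scenarios, spawning per-gene seeds
    from the top-level seed."""
    params = params or PipelineParams()
    records = []
    for i, sc in enumerate(scenarios):
        rec = run_scenario(sc, params, model, seed=params.seed + 7919 * (i + 1))
        rec.gene = f"{sc.kind.value}_{i:03d}"
        records.append(rec)
    return PipelineReport(records)
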