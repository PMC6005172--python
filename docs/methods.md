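# Methods

This note documents the models, statistics and numerical choices behind
`hgtscreen`, and what the synthetic fixtures do and do not establish.

## Alien-index screen

For each query gene the screen consumes a taxon-labeled similarity table
(tabular outfmt-6 dialect) and a map from subject identifier to
`{BACTERIA, ARCHAEA, EUK_NONMETAZOAN, METAZOAN}` plus phylum and genus.
The alien index is

    AI = ln(E_meta + ε) − ln(E_nonmeta + ε),   ε = 1e-200,

with natural logarithms; the source literature defers the exact log base
and offset to the original screening program, so these constants are a
documented assumption chosen to be consistent with the conventional
`AI > 45` candidate threshold (45 ≈ 20·ln 10, i.e. a 20-order-of-magnitude
E-value gap). A class with no hit substitutes E = 1 and bit score 0 — the
worst plausible hit — keeping the index finite and directionally correct.
Hits whose subject phylum equals the query's own phylum are excluded from
both classes, so the query species' own genome (or a congener) in the
database cannot mask a transfer; exclusion by phylum rather than species
is the more conservative of the two readings and is flagged as an
assumption. E-value ties break by higher bit score, then file rank, so
outputs are deterministic. The HGT index (best non-animal minus best
animal bit score) is reported but never used for candidacy.

## Tree operations

All topology tests treat trees as unrooted and reason over bipartitions;
rooted drawings are storage artefacts. Monophyly of a group means some
edge separates exactly that group from its complement (singletons and the
full leaf set are trivially monophyletic). Contaminant pruning searches
removal subsets of group members in order of size 0, 1, 2 (the published
budget of "a maximum of two" disrupting taxa), breaking equal-size ties
by lexicographic leaf label — the tie-break is unstated in the source and
fixed here for determinism. The query and non-group leaves are never
pruned. Monophyly after removal is decided by restriction of the full
tree's bipartitions, which avoids rebuilding trees inside the subset
search. Suboptimal-tree generation "by shuffling clades of three" is
realized as drawing three disjoint clades of ≤ 3 leaves uniformly at
random and cyclically exchanging their attachment points (each position
keeps its branch length); outputs are deduplicated against each other and
the input by bipartition-set identity. This cyclic-exchange reading is an
interpretation of a procedure the source describes only briefly.

## Likelihood engine

The substitution model is a reversible 20-state amino-acid process. The
default has equal exchangeabilities (Poisson-type) with uniform
stationary frequencies, for which transition probabilities are closed
form: `P(t) = a·I + (1−a)·1πᵀ` with `a = e^{−βt}` and `β = 1/(1−Σπ²)`
normalizing the mean rate to 1. Arbitrary symmetric exchangeability
matrices (e.g. a WAG-style table in PAML format) are supported through an
eigendecomposition of the symmetrized rate matrix. Among-site rate
variation uses the standard discrete-gamma approximation: equal-probability
categories represented by their category means, renormalized to mean 1.
The original study does not state its substitution model; the engine
deliberately does not hard-wire any published matrix.

Per-site log-likelihoods use Felsenstein pruning with per-node rescaling
enabled above 25 leaves (smaller trees cannot underflow double
precision). Gaps and ambiguous residues are fully ambiguous states
(partial vector of ones). Branch lengths are clamped to [1e-8, 20].

Branch-length optimization cycles sweeps in which inside ("down") and
outside ("up") partial vectors are computed once and every branch is
line-searched against them by safeguarded Newton steps on analytic first
and second derivatives (for the closed-form model the per-branch
objective reduces to two site vectors). Because those partials go stale
within a sweep, any sweep that fails to improve the exact log-likelihood
is replaced by a slower pass recomputing partials per branch; at the
fixed point each branch is optimal given the others to the stated
tolerance (1e-6 log units, max 20 sweeps). Degree-2 roots arising from
rooted Newick input are collapsed on conversion, since their two edges
are confounded under a reversible model and degrade coordinate ascent.

Tree search is deterministic. For ≤ 8 leaves all unrooted topologies are
enumerated once per leaf count and cached with per-topology geometry
(edge bipartition masks and the pseudoinverse mapping pairwise distances
to ordinary-least-squares branch lengths). A search ranks topologies by
their least-squares path-length residual (one batched matrix product),
likelihood-scores the best 60 at OLS branch lengths, and fully optimizes
the leading few (default 5; 2 inside replicate-heavy tests). Above 8
leaves the search is NNI hill-climbing from a neighbor-joining start on
20-state ML distances (`d = −(19/20)·ln(1 − 20p/19)`), screening every
neighbor by likelihood at inherited branch lengths and re-optimizing only
the leaders. A monophyly constraint is enforced by filtering enumerated
topologies, or by rejecting NNI moves that break the constraint from a
start tree in which the constraint holds (obtained by a minimal regraft
of the violating leaf into the constraint clade, falling back to joined
neighbor-joining subtrees). The pre-screening stages are a deliberate
trade: they are not guaranteed to rank the global optimum first, but on
the problem sizes used here they reproduced full-enumeration optima in
every paired comparison, and the hypothesis tests apply the identical
search to observed and replicate data, which is what their calibration
relies on.

Sequence simulation draws the root state from the stationary frequencies
and evolves it down each branch by transition-probability sampling (a
stay/redraw step under the closed-form model), with per-site gamma
categories drawn once; it is deterministic under a seed and doubles as
the SOWH replicate generator and the scenario generator.

## Topology hypothesis tests

**SOWH.** The statistic is `δ = lnL(unconstrained ML tree) −
lnL(constrained ML tree)`, the constraint being monophyly of the metazoan
group plus the query. The null distribution comes from alignments
simulated on the constrained tree (with its optimized branch lengths),
each re-analyzed with the identical two searches; for ≤ 8 leaves both
searches share one screening pass. The p-value uses the add-one
correction `(1 + #{δ* ≥ δ})/(n_reps + 1)`, which cannot return 0 from
finite replicates; `δ` is floored at 0 because the constrained space is
nested in the unconstrained one. Default 99 replicates; the end-to-end
simulation studies use 19 (putting the attainable floor exactly at the
0.05 decision boundary) to keep many-scenario runs at desk scale.

The SOWH statistic has a point mass at zero: whenever the unconstrained
ML tree itself satisfies the constraint, δ = 0 and p = 1. Under interior
nulls (a well-supported constrained clade) that mass approaches one and
the test is extremely conservative; its size is therefore measured at the
least-favorable boundary null — a star-like tree in which the constrained
clade is true but carries no signal — where the rejection rate at
α = 0.05 sits inside the exact binomial band. Even at the boundary the
point mass (≈ 0.3 empirically, stable under deeper search refinement)
makes the null p-value distribution sub-uniform rather than uniform:
valid at every level, conservative overall.

**AU.** Per-site log-likelihoods for the ML tree, the constraint tree and
a suboptimal set are resampled by RELL at scales 0.5–1.4 (step 0.1,
10,000 replicates per scale by default; multinomial weight vectors rather
than explicit index draws, so each scale is one matrix product per
chunk). Replicates are awarded to the argmax tree with exact ties split
equally. The focal tree's bootstrap proportions are clamped to
`[1/(2n), 1−1/(2n)]`, transformed by `z_r = Φ⁻¹(1−BP_r)`, and fitted by
weighted least squares to `z_r = d√r + c/√r` with delta-method binomial
weights; `p_AU = 1 − Φ(d−c)`. Only scales whose proportions carry real
counting information (between 5 and n−5 wins) enter the fit: saturated
scales contribute a nearly constant clamped z that corrupts the
regression, so a focal tree that wins (or loses) essentially every
replicate at every scale short-circuits to p = 1 (or 0) with a
degeneracy flag rather than passing garbage through the fit. The focal tree
is the metazoan-constraint tree, so small p rejects vertical inheritance.
Two suboptimal sets are used, mirroring the published two AU columns:
deduplicated nonparametric bootstrap trees, and clade-shuffled trees.

**Combined rule.** A candidate is confirmed iff all three p-values
(SOWH, AU/bootstrap-set, AU/shuffled-set) are ≤ α = 0.05. The boundary is
inclusive: the published table note says ≤ 0.05 while the text says
< 0.05, and the table's own classification is the operative rule (no
printed row sits exactly at 0.05). Likelihood proportions divide each
tree's log-likelihood by the mean suboptimal log-likelihood — "likelihood
scores" are read as log-likelihoods, since that is what ML programs
report; this is flagged as an interpretation.

## Expression screen

Counts from a 3'-end (CEL-Seq-style) developmental timecourse are
normalized per sample to transcripts per million with no length term.
The developmental score of a gene is the sum over distinct time points of
the median replicate tpm (midpoint median for even replicate counts — a
convention the source does not state); a gene is called expressed when
the score is ≥ 100, inclusive per the published "100 or greater" rule.
The 25-time-point shape is the default fixture, not a hard-coded
requirement.

## Contamination and provenance screens

U2 spliceosomal introns are identified by GT donor and AG acceptor
dinucleotides read in transcript orientation (reverse complement on the
minus strand); GFF3 coordinates are 1-based inclusive, and introns
shorter than 4 bases are rejected as malformed. Reciprocal best hits
require mutual best hits at E ≤ 0.1 with the same tie-breaks as the
screen. The close-relative rule removes a candidate whose top-ranked hit
within the cutoff is Choanoflagellatea or Filasterea, because a sister-
group position of the query lineage makes vertical inheritance plus loss
viable there. Taxon selection for tree building walks hits in rank
order, keeps at most one subject per genus within each group (bacteria /
archaea / non-fungal eukaryotes / fungi / animals — the genus rule is
applied within groups, one of two possible readings), caps each group at
10, then appends the best hit of each must-include organism. Candidates
with 1–2 animal hits are discarded; assigning the one-hit case to the
discard branch is the conservative resolution of a gap in the published
rule, which only describes the zero-hit and two-hit cases.

## Synthetic scenarios

`simulate_scenario` builds a three-clade backbone (bacteria, non-metazoan
eukaryotes, metazoans) by random joins with exponential branch lengths
(within-clade mean 0.12, clade stems 0.45, query graft 0.05, all times a
divergence scale of 1), grafts the query into the donor clade
(transfers), the metazoan clade (vertical), or the bacterial clade with
2 bacterial leaves relabeled metazoan (contamination), and simulates the
alignment under the engine. Defaults (4 bacteria, 3 eukaryotes, 4
metazoans, 300 sites) give 12-leaf trees; the many-scenario simulation
studies use 3/2/3 so that per-gene trees stay in the fast search regime.
Similarity tables map pairwise identity to bit scores through a
Karlin–Altschul-shaped convention (`bits = 2·identity·n_sites` plus 1-bit
Gaussian noise, `E = m·n·2^{−bits}` clamped to [1e-180, 10]); the
constants are fixture conventions, not biological claims. Expression
counts are negative-binomial (dispersion 0.2) around stereotyped profile
means — maternal decay, a tentacle-morphogenesis-timed Gaussian spike,
a cell-cycle-like sinusoid, or near-silence — with flat background genes
filling the library so tpm normalization reproduces the designed means.
Gene-model fixtures embed multi-exon genes on both strands with splice
dinucleotides set canonical with a controlled probability and an emitted
truth table.

What passing tests show — and do not. The synthetic data make the truth
of every decision checkable, so the suite demonstrates internal
correctness (agreement with brute force and closed forms), frequentist
calibration of the SOWH test under its own model, and end-to-end
recovery of planted signals. They do not emulate alignment error,
model misspecification, compositional heterogeneity, incomplete taxon
sampling, or real contamination structure, so measured sensitivity and
specificity are upper bounds on what real data would give.

## Problem sizes in the validation suite

The acceptance-style checks use: 1,000 random similarity tables; full
20⁴ pattern enumeration on 50 random quartets; 200 random 12-leaf trees
for the pruning oracle; 100 null SOWH tests at 6 taxa × 200 sites × 99
replicates plus 20 power runs at 500 sites × 19 replicates; 10⁴ RELL
replicates per scale for AU checks; and 20 + 20 transfer/vertical
pipeline runs at 9 leaves with 19 SOWH replicates, 100 bootstrap and 100
shuffled trees, and 2,000 RELL replicates (the reproduction script runs
10 + 10 pipeline scenarios and 50 calibration tests to stay well inside
a coffee break). These sizes were chosen as
desk-scale study conditions; the thresholds they are checked against
(binomial confidence bounds, 90%/10% recovery rates, closed-form
tolerances) follow from the statistics, not from tuning.

## Known limitations

* The ML searches are heuristics past 8 leaves; NNI from a
  neighbor-joining start can miss optima separated by multiple
  rearrangements.
* The engine's default model is intentionally simple; real-data use
  should load an empirical exchangeability matrix and enable gamma
  rates, at a corresponding cost in the SOWH inner loop.
* The AU implementation follows the standard multiscale-bootstrap
  recipe but is not a reimplementation of any specific external
  program's numerics; p-values can differ in the third decimal from
  other implementations at finite replicate counts.
* `run_scenario` orchestrates the full flow for in-memory scenarios;
  file-driven analyses compose the same stages through the CLI
  subcommands, which operate on one stage at a time.
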