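"""Protein likelihood engine: pruning log-likelihoods, branch-length
optimization, small-scale ML tree search, and alignment simulation.

The model is a reversible 20-state amino-acid substitution process.  By
default every exchangeability is equal (a Poisson-type model, optionally
with non-uniform stationary frequencies), for which transition
probabilities are closed-form; an arbitrary symmetric exchangeability
matrix (e.g. a WAG-style table read from a PAML-format file) is supported
through an eigendecomposition.  Among-site rate variation uses the
standard discrete-gamma approximation (equal-probability categories,
category means).

Searches are deterministic: for up to 7 leaves all unrooted topologies are
enumerated, scored at least-squares branch lengths, and the leaders are
fully optimized; larger problems use NNI hill-climbing from a
neighbor-joining start.  A monophyly constraint restricts the admissible
topologies, which is how metazoan-constraint (null) trees are produced.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import _mlcore as core
from .tree_ops import PhyloTree

__all__ = [
    "AMINO_ACIDS",
    "Alignment",
    "SubstitutionModel",
    "SiteLogLikMatrix",
    "site_log_likelihoods",
    "total_log_likelihood",
    "optimize_branch_lengths",
    "ml_search",
    "simulate_alignment",
    "site_log_likelihood_matrix",
]

#: Canonical residue order used by the engine (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AMBIGUOUS = set("-XBZJUO?*.")


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------
class Alignment:
    """An amino-acid multiple sequence alignment (equal-length sequences).

    Residues outside the 20 canonical amino acids (gaps, X, etc.) are kept
    but treated as fully ambiguous by the likelihood machinery.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("alignment has no sequences")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        self.n_sites = lengths.pop()
        if len(self.sequences) != len(sequences):
            raise ValueError("duplicate sequence ids")
        for sid, seq in self.sequences.items():
            bad = set(seq) - set(AMINO_ACIDS) - _AMBIGUOUS
            if bad:
                raise ValueError(f"sequence {sid}: unknown residues {sorted(bad)}")

    def __len__(self):
        return len(self.sequences)

    def ids(self) -> list[str]:
        return list(self.sequences)

    def encode(self, order: Sequence[str]) -> np.ndarray:
        """Integer matrix (len(order), n_sites); 0-19 residues, 20 ambiguous."""
        enc = np.empty((len(order), self.n_sites), dtype=np.int64)
        for row, sid in enumerate(order):
            seq = self.sequences[sid]
            enc[row] = [_AA_INDEX.get(ch, core.GAP) for ch in seq]
        return enc

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_fasta(cls, handle: IO[str] | str) -> "Alignment":
        if isinstance(handle, str):
            handle = io.StringIO(handle)
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
        return cls(seqs)

    @classmethod
    def from_phylip(cls, handle: IO[str] | str) -> "Alignment":
        if isinstance(handle, str):
            handle = io.StringIO(handle)
        aln = AlignIO.read(handle, "phylip-relaxed")
        return cls({rec.id: str(rec.seq) for rec in aln})

    def to_fasta(self, handle: IO[str]) -> None:
        for sid, seq in self.sequences.items():
            handle.write(f">{sid}\n{seq}\n")

    def to_phylip(self, handle: IO[str]) -> None:
        handle.write(f" {len(self)} {self.n_sites}\n")
        for sid, seq in self.sequences.items():
            handle.write(f"{sid}  {seq}\n")


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------
class SubstitutionModel:
    """Reversible amino-acid substitution model with optional discrete gamma.

    Parameters
    ----------
    exchangeabilities:
        Symmetric non-negative 20x20 matrix, or ``None`` for the default
        equal-exchangeability (Poisson-type) model.
    frequencies:
        Stationary frequencies (20-simplex); uniform by default.
    gamma_shape:
        Shape of the gamma rate distribution, or ``None`` for rate
        homogeneity.
    n_rate_categories:
        Number of discrete gamma categories (used only with a shape).
    """

    def __init__(
        self,
        exchangeabilities: np.ndarray | None = None,
        frequencies: np.ndarray | None = None,
        gamma_shape: float | None = None,
        n_rate_categories: int = 4,
    ):
        n = core.N_STATES
        if frequencies is None:
            pi = np.full(n, 1.0 / n)
        else:
            pi = np.asarray(frequencies, dtype=float)
            if pi.shape != (n,) or np.any(pi < 0):
                raise ValueError("frequencies must be 20 non-negative values")
            if abs(pi.sum() - 1.0) > 1e-8:
                raise ValueError("frequencies must sum to 1")
            pi = pi / pi.sum()
        self.frequencies = pi
        self.closed_form = exchangeabilities is None
        if gamma_shape is not None and gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self.gamma_shape = gamma_shape
        self.n_rate_categories = int(n_rate_categories) if gamma_shape else 1
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")
        self.category_rates = self._discrete_gamma_rates()

        if self.closed_form:
            # F81-style closed form: P(t) = a I + (1 - a) 1 pi^T,
            # a = exp(-beta t), beta chosen so the mean rate is 1.
            self.beta = 1.0 / (1.0 - float(pi @ pi))
            self.exchangeabilities = None
        else:
            S = np.asarray(exchangeabilities, dtype=float)
            if S.shape != (n, n) or np.any(S < 0):
                raise ValueError("exchangeabilities must be a non-negative 20x20 matrix")
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError("exchangeabilities must be symmetric")
            self.exchangeabilities = S
            Q = S * pi[None, :]
            np.fill_diagonal(Q, 0.0)
            Q[np.diag_indices(n)] = -Q.sum(axis=1)
            mu = -float(pi @ np.diag(Q))
            Q /= mu
            sqp = np.sqrt(pi)
            B_sym = (sqp[:, None] * Q) / sqp[None, :]
            lam, U = np.linalg.eigh((B_sym + B_sym.T) / 2.0)
            self.eigenvalues = lam
            A = U / sqp[:, None]
            B = U.T * sqp[None, :]
            self._A = A
            self._B = B
            self.eigbasis_left = A.T
            self.eigbasis_right = B

    def _discrete_gamma_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        a = self.gamma_shape
        k = self.n_rate_categories
        bounds = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        bounds = np.concatenate([[0.0], bounds, [np.inf]])
        # mean of each equal-probability slice of Gamma(a, rate a)
        upper = gammainc(a + 1.0, a * bounds[1:])
        lower = gammainc(a + 1.0, a * bounds[:-1])
        rates = k * (upper - lower)
        return rates / rates.mean()

    # -- matrices --------------------------------------------------------
    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t): row-stochastic transition-probability matrix."""
        n = core.N_STATES
        if self.closed_form:
            a = np.exp(-self.beta * rate * t)
            return a * np.eye(n) + (1.0 - a) * np.tile(self.frequencies, (n, 1))
        return self._A @ (np.exp(self.eigenvalues * rate * t)[:, None] * self._B)

    # fast partial-likelihood transfers used by the pruning core
    def transfer(self, X: np.ndarray, t: float) -> np.ndarray:
        if self.closed_form:
            a = np.exp(-self.beta * t)
            return a * X + (1.0 - a) * (self.frequencies @ X)
        return self._A @ (np.exp(self.eigenvalues * t)[:, None] * (self._B @ X))

    def transfer_T(self, X: np.ndarray, t: float) -> np.ndarray:
        if self.closed_form:
            a = np.exp(-self.beta * t)
            return a * X + (1.0 - a) * self.frequencies[:, None] * X.sum(axis=0)
        return self._B.T @ (np.exp(self.eigenvalues * t)[:, None] * (self._A.T @ X))

    @classmethod
    def from_paml(
        cls,
        handle: IO[str] | str,
        use_file_frequencies: bool = True,
        gamma_shape: float | None = None,
        n_rate_categories: int = 4,
    ) -> "SubstitutionModel":
        """Load a PAML-format rate matrix file (lower-triangular
        exchangeabilities followed by a frequency line)."""
        text = handle.read() if hasattr(handle, "read") else handle
        values = [float(x) for x in text.split()]
        n = core.N_STATES
        n_tri = n * (n - 1) // 2
        if len(values) < n_tri:
            raise ValueError("not enough values for a 20-state PAML matrix")
        S = np.zeros((n, n))
        it = iter(values[:n_tri])
        for i in range(1, n):
            for j in range(i):
                S[i, j] = S[j, i] = next(it)
        freqs = None
        if use_file_frequencies and len(values) >= n_tri + n:
            freqs = np.array(values[n_tri:n_tri + n])
            freqs = freqs / freqs.sum()
        return cls(S, freqs, gamma_shape, n_rate_categories)


# ---------------------------------------------------------------------------
# per-site log-likelihood matrix (trees x sites)
# ---------------------------------------------------------------------------
@dataclass
class SiteLogLikMatrix:
    """Per-site log-likelihoods for a set of trees over one alignment."""

    labels: list[str]
    values: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match tree labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("site log-likelihoods must be finite")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate tree labels")

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    def to_tsv(self, handle: IO[str]) -> None:
        for label, row in zip(self.labels, self.values):
            handle.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, handle: IO[str] | str) -> "SiteLogLikMatrix":
        if isinstance(handle, str):
            handle = io.StringIO(handle)
        labels, rows = [], []
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if not rows:
            raise ValueError("empty site log-likelihood table")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("rows have unequal site counts")
        return cls(labels, np.array(rows))


# ---------------------------------------------------------------------------
# PhyloTree <-> array conversion
# ---------------------------------------------------------------------------
def _to_array_tree(tree: PhyloTree, order: Sequence[str]) -> core.ArrayTree:
    index = {label: i for i, label in enumerate(order)}
    n_leaves = len(order)
    dtree = tree.dendropy_tree
    node_ids: dict[int, int] = {}
    next_internal = n_leaves
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in index:
                raise ValueError(f"leaf {label!r} has no sequence")
            node_ids[id(node)] = index[label]
        else:
            node_ids[id(node)] = next_internal
            next_internal += 1
    n_nodes = next_internal
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    lengths = np.zeros(n_nodes)
    for node in dtree.preorder_node_iter():
        v = node_ids[id(node)]
        if node.parent_node is not None:
            p = node_ids[id(node.parent_node)]
            parent[v] = p
            children[p].append(v)
            lengths[v] = node.edge.length if node.edge.length is not None else 0.0
    root = node_ids[id(dtree.seed_node)]
    # collapse a degree-2 root: the two root edges are confounded (only
    # their sum matters under a reversible model), which degrades the
    # per-edge optimizer; splice them into one edge
    if len(children[root]) == 2:
        c1, c2 = children[root]
        if c1 < n_leaves <= c2:
            c1, c2 = c2, c1
        if c1 >= n_leaves:
            children[root] = []
            parent[c1] = -1
            parent[c2] = c1
            children[c1].append(c2)
            lengths[c2] += lengths[c1]
            lengths[c1] = 0.0
            root = c1
    return core.ArrayTree(n_leaves, parent, children, lengths, root)


def _from_array_tree(
    at: core.ArrayTree,
    order: Sequence[str],
    leaf_classes: dict[str, str] | None = None,
    query: str | None = None,
) -> PhyloTree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    nodes: dict[int, dendropy.Node] = {}
    for v in at.preorder:
        node = dtree.seed_node if v == at.root else dendropy.Node()
        if v < at.n_leaves:
            node.taxon = taxa.new_taxon(order[v])
        if v != at.root:
            node.edge.length = float(at.lengths[v])
            nodes[int(at.parent[v])].add_child(node)
        nodes[v] = node
    return PhyloTree(dtree, leaf_classes, query)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------
def _prepare(tree: PhyloTree, aln: Alignment):
    order = sorted(tree.leaf_labels())
    missing = set(order) - set(aln.sequences)
    if missing:
        raise ValueError(f"leaves without sequences: {sorted(missing)}")
    at = _to_array_tree(tree, order)
    enc = aln.encode(order)
    lp = core.leaf_partials(enc)
    return at, lp


def site_log_likelihoods(
    tree: PhyloTree, aln: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihoods by pruning (gamma category average when on)."""
    at, lp = _prepare(tree, aln)
    return core.site_logliks(at, lp, model)


def total_log_likelihood(
    tree: PhyloTree, aln: Alignment, model: SubstitutionModel
) -> float:
    return float(site_log_likelihoods(tree, aln, model).sum())


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_passes: int = 20,
) -> PhyloTree:
    """Return a copy of the tree with coordinate-wise ML branch lengths.

    Branches are cycled until the total log-likelihood improves by less
    than ``tol`` or ``max_passes`` sweeps are exhausted; lengths are
    clamped to [1e-8, 20].
    """
    order = sorted(tree.leaf_labels())
    at, lp = _prepare(tree, aln)
    core.optimize_branches(at, lp, model, tol=tol, max_passes=max_passes)
    return _from_array_tree(at, order, tree.leaf_classes, tree.query)


def ml_search(
    aln: Alignment,
    model: SubstitutionModel,
    constraint: Iterable[str] | None = None,
    refine_top: int = 5,
) -> PhyloTree:
    """Maximum-likelihood tree search, optionally constrained.

    With 7 or fewer sequences every unrooted topology is enumerated (those
    violating the constraint are filtered out), scored at least-squares
    branch lengths, and the leading ``refine_top`` are fully optimized.
    Larger problems use NNI hill-climbing from a neighbor-joining start
    (a grafted start when the constraint is not already monophyletic),
    rejecting moves that break the constraint.  Deterministic.
    """
    order = sorted(aln.ids())
    if len(order) < 3:
        raise ValueError("tree search needs at least 3 sequences")
    cmask = None
    if constraint is not None:
        cset = set(constraint)
        unknown = cset - set(order)
        if unknown:
            raise ValueError(f"constraint taxa not in alignment: {sorted(unknown)}")
        cmask = 0
        for i, label in enumerate(order):
            if label in cset:
                cmask |= 1 << i
    enc = aln.encode(order)
    lp = core.leaf_partials(enc)
    if len(order) <= 7:
        at, _ = core.exhaustive_search(lp, enc, model, cmask, refine_top=refine_top)
    else:
        at, _ = core.nni_search(lp, enc, model, cmask)
    return _from_array_tree(at, order)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.Generator,
) -> Alignment:
    """Simulate an alignment along the tree under the model.

    The root state is drawn from the stationary frequencies and evolved
    down every branch by transition-probability sampling; with gamma on,
    each site draws its rate category once.  Deterministic under a fixed
    seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = sorted(tree.leaf_labels())
    at = _to_array_tree(tree, order)
    pi = model.frequencies
    ncat = len(model.category_rates)
    site_rates = np.ones(n_sites)
    if ncat > 1:
        cats = rng.integers(0, ncat, size=n_sites)
        site_rates = model.category_rates[cats]
    states = np.empty((at.n_nodes, n_sites), dtype=np.int64)
    states[at.root] = rng.choice(core.N_STATES, size=n_sites, p=pi)
    for v in at.preorder:
        if v == at.root:
            continue
        p = at.parent[v]
        t = at.lengths[v]
        if model.closed_form:
            a = np.exp(-model.beta * t * site_rates)
            stay = rng.random(n_sites) < a
            redraw = rng.choice(core.N_STATES, size=n_sites, p=pi)
            states[v] = np.where(stay, states[p], redraw)
        else:
            states[v] = states[p]
            for r in np.unique(site_rates):
                P = model.transition_matrix(t, rate=r)
                sel = site_rates == r
                for s in range(core.N_STATES):
                    mask = sel & (states[p] == s)
                    k = int(mask.sum())
                    if k:
                        states[v][mask] = rng.choice(core.N_STATES, size=k, p=P[s])
    seqs = {
        label: "".join(AMINO_ACIDS[s] for s in states[i])
        for i, label in enumerate(order)
    }
    return Alignment(seqs)


def site_log_likelihood_matrix(
    trees: Sequence[tuple[str, PhyloTree]],
    aln: Alignment,
    model: SubstitutionModel,
) -> SiteLogLikMatrix:
    """Stack per-site log-likelihoods for several trees over one alignment."""
    labels = [label for label, _ in trees]
    rows = [site_log_likelihoods(tree, aln, model) for _, tree in trees]
    return SiteLogLikMatrix(labels, np.vstack(rows))
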