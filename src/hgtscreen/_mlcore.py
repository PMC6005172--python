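"""Array-based likelihood internals: pruning, branch optimization, search.

Trees are flattened to parent-pointer arrays so the per-site pruning
recursion and the per-edge branch-length objective are pure vectorized
numpy.  For the default equal-exchangeability model the transition
probabilities have the closed form ``P(t) = a I + (1-a) 1 pi^T`` with
``a = exp(-beta t)``, so transferring a partial-likelihood block across an
edge is one scaled add plus one dot product; general reversible models go
through a cached eigendecomposition.

Everything here is private to the package; the public surface lives in
:mod:`hgtscreen.phylo_engine`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

N_STATES = 20
GAP = 20  # encoding for gap / unknown: fully ambiguous

MIN_BL = 1e-8
MAX_BL = 20.0


# ---------------------------------------------------------------------------
# array tree
# ---------------------------------------------------------------------------
class ArrayTree:
    """Rooted array representation of a (conceptually unrooted) tree.

    Leaves are nodes ``0..n_leaves-1``; internals follow.  ``lengths[v]`` is
    the branch above ``v`` (towards the parent); the root has no branch.
    Under a reversible model the likelihood does not depend on where the
    root was placed.
    """

    __slots__ = ("n_leaves", "n_nodes", "parent", "children", "lengths",
                 "postorder", "preorder", "root")

    def __init__(self, n_leaves, parent, children, lengths, root):
        self.n_leaves = n_leaves
        self.n_nodes = len(parent)
        self.parent = parent
        self.children = children
        self.lengths = lengths
        self.root = root
        self._compute_orders()

    def _compute_orders(self):
        post = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                post.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        self.postorder = post
        self.preorder = post[::-1]

    @classmethod
    def from_edges(cls, edges, lengths, n_leaves, root=None):
        """Build from an undirected edge list ``[(u, v), ...]``.

        Node ids must be 0..n_nodes-1 with leaves first.  ``lengths`` is a
        parallel list of branch lengths.  The tree is rooted at ``root``
        (default: the highest-numbered internal node).
        """
        n_nodes = max(max(u, v) for u, v in edges) + 1
        adj = {i: [] for i in range(n_nodes)}
        elen = {}
        for (u, v), ln in zip(edges, lengths):
            adj[u].append(v)
            adj[v].append(u)
            elen[frozenset((u, v))] = ln
        if root is None:
            root = n_nodes - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        blen = np.zeros(n_nodes)
        children = [[] for _ in range(n_nodes)]
        stack = [root]
        seen = {root}
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    children[u].append(v)
                    blen[v] = elen[frozenset((u, v))]
                    stack.append(v)
        return cls(n_leaves, parent, children, blen, root)

    def to_edges(self):
        edges, lengths = [], []
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                edges.append((int(p), int(v)))
                lengths.append(float(self.lengths[v]))
        return edges, lengths

    def copy(self):
        t = ArrayTree.__new__(ArrayTree)
        t.n_leaves = self.n_leaves
        t.n_nodes = self.n_nodes
        t.parent = self.parent.copy()
        t.children = [list(c) for c in self.children]
        t.lengths = self.lengths.copy()
        t.root = self.root
        t.postorder = self.postorder
        t.preorder = self.preorder
        return t

    def leaf_masks(self):
        """Bitmask of leaves below each node (leaf i contributes bit i)."""
        masks = np.zeros(self.n_nodes, dtype=object)
        for v in self.postorder:
            if v < self.n_leaves:
                masks[v] = 1 << v
            else:
                m = 0
                for c in self.children[v]:
                    m |= masks[c]
                masks[v] = m
        return masks


def leaf_partials(enc):
    """One-hot (ambiguity-aware) partials, shape (n_leaves, 20, n_sites)."""
    n_leaves, ns = enc.shape
    L = np.zeros((n_leaves, N_STATES, ns))
    site_idx = np.arange(ns)
    for i in range(n_leaves):
        known = enc[i] < N_STATES
        L[i, enc[i][known], site_idx[known]] = 1.0
        L[i, :, ~known] = 1.0
    return L


# ---------------------------------------------------------------------------
# pruning passes
# ---------------------------------------------------------------------------
#: Rescale partials only beyond this leaf count; float64 cannot underflow
#: on smaller trees given non-negative transfer outputs.
_RESCALE_LEAVES = 25


def down_pass(at, lp, model, rate):
    """Conditional likelihoods of each subtree, with per-site log rescaling.

    Returns ``(D, S)``: ``D[v]`` is the (20, n_sites) partial at node ``v``
    and ``S[v]`` the per-site log scale factored out of it.
    """
    ns = lp.shape[2]
    rescale = at.n_leaves > _RESCALE_LEAVES
    D = np.empty((at.n_nodes, N_STATES, ns))
    S = np.zeros((at.n_nodes, ns))
    for v in at.postorder:
        if v < at.n_leaves:
            D[v] = lp[v]
            continue
        acc = None
        s = None
        for c in at.children[v]:
            m = model.transfer(D[c], at.lengths[c] * rate)
            acc = m if acc is None else acc * m
            if rescale:
                s = S[c] if s is None else s + S[c]
        if rescale:
            mx = acc.max(axis=0)
            mx[mx <= 0.0] = 1.0
            acc /= mx
            S[v] = s + np.log(mx)
        D[v] = acc
    return D, S


def up_pass(at, D, S, model, rate):
    """Outside partials: ``Rpre[v]`` is the likelihood of all data outside
    the subtree of ``v`` conditioned on the state at v's *parent*, with the
    root frequencies folded in; ``SR[v]`` its log scale.

    For any non-root ``v`` the per-site likelihood factors as
    ``sum_ij Rpre[v][i] P_ij(t_v) D[v][j]`` (times ``exp(SR[v] + S[v])``),
    which is what the per-edge branch-length objective consumes.
    """
    ns = D.shape[2]
    rescale = at.n_leaves > _RESCALE_LEAVES
    Rpre = np.empty_like(D)
    SR = np.zeros((at.n_nodes, ns))
    R = np.empty_like(D)
    SRR = np.zeros((at.n_nodes, ns))
    R[at.root] = model.frequencies[:, None]
    SRR[at.root] = 0.0
    for u in at.preorder:
        if u < at.n_leaves:
            continue
        cs = at.children[u]
        msgs = [model.transfer(D[c], at.lengths[c] * rate) for c in cs]
        for i, v in enumerate(cs):
            acc = R[u]
            s = SRR[u]
            for j, c in enumerate(cs):
                if j == i:
                    continue
                acc = acc * msgs[j]
                if rescale:
                    s = s + S[c]
            if acc is R[u]:
                acc = acc.copy()
            if rescale:
                mx = acc.max(axis=0)
                mx[mx <= 0.0] = 1.0
                acc /= mx
                SR[v] = s + np.log(mx)
            Rpre[v] = acc
            R[v] = model.transfer_T(acc, at.lengths[v] * rate)
            SRR[v] = SR[v]
    return Rpre, SR


def site_logliks(at, lp, model):
    """Per-site log-likelihoods (category-averaged when gamma is on)."""
    ns = lp.shape[2]
    rates = model.category_rates
    per_cat = np.empty((len(rates), ns))
    pi = model.frequencies
    for k, r in enumerate(rates):
        D, S = down_pass(at, lp, model, r)
        root_like = pi @ D[at.root]
        per_cat[k] = np.log(np.maximum(root_like, 1e-300)) + S[at.root]
    if len(rates) == 1:
        return per_cat[0]
    m = per_cat.max(axis=0)
    return m + np.log(np.mean(np.exp(per_cat - m), axis=0))


def total_loglik(at, lp, model):
    return float(site_logliks(at, lp, model).sum())


# ---------------------------------------------------------------------------
# branch-length optimization
# ---------------------------------------------------------------------------
def _edge_objective(model, cat_data, rates):
    """Return fdf(t) = (lnL, dlnL/dt, d2lnL/dt2) for one branch length.

    ``cat_data[k]`` holds the per-category site-wise pieces prepared by the
    caller; the closed-form model needs only two site vectors per category.
    Per-site scale constants cancel in the derivative ratios, so only the
    total constant is added back to the value.
    """
    ncat = len(rates)

    if model.closed_form:
        beta = model.beta

        if ncat > 1:
            consts = np.array([cd[2] for cd in cat_data])
            cmax = consts.max(axis=0)
            cat_w = np.exp(consts - cmax)  # per-category per-site weights

        def fdf(t):
            if ncat == 1:
                u, w, const = cat_data[0]
                br = beta * rates[0]
                a = np.exp(-br * t)
                L = a * u + (1.0 - a) * w
                dL = -br * a * (u - w)
                d2L = br * br * a * (u - w)
                const_total = const.sum()
            else:
                L = dL = d2L = 0.0
                for k, r in enumerate(rates):
                    u, w, _ = cat_data[k]
                    br = beta * r
                    a = np.exp(-br * t)
                    wk = cat_w[k]
                    L = L + wk * (a * u + (1.0 - a) * w)
                    dL = dL + wk * (-br * a * (u - w))
                    d2L = d2L + wk * (br * br * a * (u - w))
                const_total = cmax.sum() - len(cmax) * np.log(ncat)
            L = np.maximum(L, 1e-300)
            g = dL / L
            f = np.log(L).sum() + const_total
            return f, g.sum(), (d2L / L - g * g).sum()

        return fdf

    lam = model.eigenvalues

    if ncat > 1:
        consts = np.array([cd[1] for cd in cat_data])
        cmax = consts.max(axis=0)
        cat_w = np.exp(consts - cmax)

    def fdf(t):
        if ncat == 1:
            c, const = cat_data[0]
            lr = lam * rates[0]
            e = np.exp(lr * t)
            L = e @ c
            dL = (lr * e) @ c
            d2L = (lr * lr * e) @ c
            const_total = const.sum()
        else:
            L = dL = d2L = 0.0
            for k, r in enumerate(rates):
                c, _ = cat_data[k]
                lr = lam * r
                e = np.exp(lr * t)
                wk = cat_w[k]
                L = L + wk * (e @ c)
                dL = dL + wk * ((lr * e) @ c)
                d2L = d2L + wk * ((lr * lr * e) @ c)
            const_total = cmax.sum() - len(cmax) * np.log(ncat)
        L = np.maximum(L, 1e-300)
        g = dL / L
        f = np.log(L).sum() + const_total
        return f, g.sum(), (d2L / L - g * g).sum()

    return fdf


def _maximize_branch(fdf, t0, tol=1e-8, max_iter=20):
    """Safeguarded Newton maximization of a branch-length objective on
    [MIN_BL, MAX_BL]; falls back to bisection steps when Newton misbehaves."""
    t = float(np.clip(t0, MIN_BL, MAX_BL))
    f, g, h = fdf(t)
    lo, hi = MIN_BL, MAX_BL
    for _ in range(max_iter):
        # maintain a bracket from the gradient sign
        if g > 0:
            lo = t
        else:
            hi = t
        if h < 0:
            step = -g / h
            t_new = t + step
        else:
            t_new = 0.5 * (lo + hi)
        if not (lo <= t_new <= hi):
            t_new = 0.5 * (lo + hi)
        if abs(t_new - t) < tol:
            t = t_new
            break
        f_new, g_new, h_new = fdf(t_new)
        if f_new < f - 1e-12:
            # overshoot: bisect toward the bracket instead
            t_new = 0.5 * (lo + hi)
            f_new, g_new, h_new = fdf(t_new)
            if f_new < f - 1e-12:
                break
        t, f, g, h = t_new, f_new, g_new, h_new
        if abs(g) < 1e-10:
            break
    return float(np.clip(t, MIN_BL, MAX_BL))


def _edge_cat_data(model, Rpre_v, SR_v, D_v, S_v):
    const = SR_v + S_v
    if model.closed_form:
        u = (Rpre_v * D_v).sum(axis=0)
        w = Rpre_v.sum(axis=0) * (model.frequencies @ D_v)
        return (u, w, const)
    c = (model.eigbasis_left @ Rpre_v) * (model.eigbasis_right @ D_v)
    return (c, const)


def _optimize_edge(at, lp, model, rates, v):
    """Line-search one branch length against freshly computed partials."""
    all_cat = []
    for r in rates:
        D, S = down_pass(at, lp, model, r)
        Rpre, SR = up_pass(at, D, S, model, r)
        all_cat.append((D, S, Rpre, SR))
    cat_data = [
        _edge_cat_data(model, Rpre[v], SR[v], D[v], S[v])
        for (D, S, Rpre, SR) in all_cat
    ]
    fdf = _edge_objective(model, cat_data, rates)
    at.lengths[v] = _maximize_branch(fdf, at.lengths[v])


def optimize_branches(at, lp, model, tol=1e-6, max_passes=20):
    """Cycle branch-length sweeps until the total lnL stops improving.

    Fast sweeps compute inside/outside partials once and line-search every
    branch against them; because those partials go stale within a sweep,
    any sweep that fails to improve is replaced by a slower exact
    coordinate pass (fresh partials per branch), so the fixed point has
    every branch optimal given the others.  Lengths are clamped to
    [1e-8, 20].  Returns the final total lnL (tree modified in place).
    """
    rates = model.category_rates
    best = total_loglik(at, lp, model)
    if not np.isfinite(best):
        raise ValueError("non-finite likelihood at starting branch lengths")
    edges = [v for v in at.postorder if v != at.root]
    did_exact = False
    for _ in range(max_passes):
        prev_lengths = at.lengths.copy()
        all_cat = []
        for r in rates:
            D, S = down_pass(at, lp, model, r)
            Rpre, SR = up_pass(at, D, S, model, r)
            all_cat.append((D, S, Rpre, SR))
        for v in edges:
            cat_data = [
                _edge_cat_data(model, Rpre[v], SR[v], D[v], S[v])
                for (D, S, Rpre, SR) in all_cat
            ]
            fdf = _edge_objective(model, cat_data, rates)
            at.lengths[v] = _maximize_branch(fdf, at.lengths[v])
        new = total_loglik(at, lp, model)
        if not np.isfinite(new):
            raise ValueError("non-finite likelihood during branch optimization")
        if new < best - 1e-12:
            # stale sweep overshot (e.g. oscillation on tiny trees): revert
            # and fall back to exact coordinate moves with fresh partials
            at.lengths = prev_lengths
            if did_exact:
                break
            for v in edges:
                _optimize_edge(at, lp, model, rates, v)
            new = total_loglik(at, lp, model)
            did_exact = True
            if new - best < tol:
                best = max(new, best)
                break
            best = new
            continue
        if new - best < tol:
            # converged: lengths barely moved, so the sweep's partials were
            # essentially fresh and each branch is optimal given the others
            best = new
            break
        best = new
    return best


# ---------------------------------------------------------------------------
# distances, neighbor joining
# ---------------------------------------------------------------------------
def ml_pairwise_distances(enc):
    """20-state (Jukes-Cantor-style) ML distances between all sequence pairs:
    d = -(19/20) ln(1 - 20/19 p), with p the proportion of differing sites."""
    n, ns = enc.shape
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        ok = (enc[i] < N_STATES) & (enc[j] < N_STATES)
        if ok.sum() == 0:
            p = 0.5
        else:
            p = float((enc[i][ok] != enc[j][ok]).mean())
        p = min(p, 0.94)
        dist = -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * p)
        d[i, j] = d[j, i] = max(dist, MIN_BL)
    return d


def neighbor_joining(dist):
    """Deterministic NJ; returns (edges, lengths, n_leaves) of an unrooted
    binary tree with leaves 0..n-1 (ties broken by lowest pair index)."""
    n = dist.shape[0]
    if n == 2:
        return [(0, 1)], [max(dist[0, 1], MIN_BL)], n
    active = list(range(n))
    D = {(i, j): dist[i, j] for i in range(n) for j in range(n) if i != j}
    next_id = n
    edges, lengths = [], []
    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        u = next_id
        next_id += 1
        dij = D[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        edges.append((i, u))
        lengths.append(max(li, MIN_BL))
        edges.append((j, u))
        lengths.append(max(lj, MIN_BL))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[(i, k)] + D[(j, k)] - dij)
            D[(u, k)] = D[(k, u)] = max(duk, MIN_BL)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    edges.append((i, j))
    lengths.append(max(D[(i, j)], MIN_BL))
    return edges, lengths, n


# ---------------------------------------------------------------------------
# topology enumeration (exhaustive search for small leaf counts)
# ---------------------------------------------------------------------------
@dataclass
class Topology:
    """One enumerated unrooted topology plus cached geometry helpers."""

    atree: ArrayTree
    edge_nodes: list  # non-root nodes, one per edge, fixed order
    edge_masks: list  # leaf bitmask below each edge (same order)
    path_matrix: np.ndarray  # (n_pairs, n_edges) leaf-path indicators
    ols_pinv: np.ndarray  # maps the pairwise-distance vector to OLS lengths
    pairs: list  # leaf pairs in the order ols_pinv expects


_TOPOLOGY_CACHE: dict[int, list[Topology]] = {}
_STACK_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _enumerate_edge_lists(n):
    """All unrooted leaf-labeled topologies on n leaves via leaf insertion."""
    trees = [([(0, n), (1, n), (2, n)], n + 1)]
    for leaf in range(3, n):
        new = []
        for edges, next_id in trees:
            for idx in range(len(edges)):
                u, v = edges[idx]
                w = next_id
                e2 = edges[:idx] + edges[idx + 1:] + [(u, w), (w, v), (leaf, w)]
                new.append((e2, next_id + 1))
        trees = new
    return [e for e, _ in trees]


def enumerate_topologies(n):
    """Cached list of all (2n-5)!! unrooted topologies on n leaves."""
    if n in _TOPOLOGY_CACHE:
        return _TOPOLOGY_CACHE[n]
    out = []
    pairs = list(combinations(range(n), 2))
    for edges in _enumerate_edge_lists(n):
        at = ArrayTree.from_edges(edges, [0.1] * len(edges), n)
        masks = at.leaf_masks()
        edge_nodes = [v for v in range(at.n_nodes) if at.parent[v] >= 0]
        edge_masks = [int(masks[v]) for v in edge_nodes]
        A = np.zeros((len(pairs), len(edge_nodes)))
        for pi_, (a, b) in enumerate(pairs):
            for ei, m in enumerate(edge_masks):
                inside = bool(m >> a & 1)
                if inside != bool(m >> b & 1):
                    A[pi_, ei] = 1.0
        ols_pinv = np.linalg.pinv(A)
        out.append(Topology(at, edge_nodes, edge_masks, A, ols_pinv, pairs))
    _TOPOLOGY_CACHE[n] = out
    return out


def _ls_residuals(n, dvec):
    """Squared OLS path-length residual of every topology for one distance
    vector (batched; used to pre-rank topologies before likelihood work)."""
    if n not in _STACK_CACHE:
        topos = enumerate_topologies(n)
        A = np.stack([t.path_matrix for t in topos])  # (T, n_pairs, n_edges)
        P = np.stack([t.ols_pinv for t in topos])
        _STACK_CACHE[n] = (A, P)
    A, P = _STACK_CACHE[n]
    b = np.einsum("tep,p->te", P, dvec)
    pred = np.einsum("tpe,te->tp", A, b)
    return ((pred - dvec) ** 2).sum(axis=1)


def mask_satisfies_constraint(edge_masks, cmask, full_mask):
    """True iff some edge splits off exactly the constrained leaf set."""
    k = bin(cmask).count("1")
    n = bin(full_mask).count("1")
    if k <= 1 or k >= n - 1:
        return True
    comp = full_mask ^ cmask
    for m in edge_masks:
        if m == cmask or m == comp:
            return True
    return False


_CONSTRAINT_CACHE: dict[tuple[int, int], list[int]] = {}


def constrained_topology_indices(n, cmask):
    """Indices of enumerated n-leaf topologies where cmask is monophyletic
    (cached; the same constraint recurs across bootstrap replicates)."""
    key = (n, cmask)
    if key not in _CONSTRAINT_CACHE:
        full_mask = (1 << n) - 1
        _CONSTRAINT_CACHE[key] = [
            ti for ti, topo in enumerate(enumerate_topologies(n))
            if mask_satisfies_constraint(topo.edge_masks, cmask, full_mask)
        ]
    return _CONSTRAINT_CACHE[key]


def ols_lengths(topo, dvec):
    b = topo.ols_pinv @ dvec
    return np.clip(b, 1e-6, MAX_BL)


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------
def _screen_candidates(topos, indices, dvec, lp, model):
    """Likelihood-score the given topology indices at OLS branch lengths."""
    scored = []
    for ti in indices:
        topo = topos[ti]
        at = topo.atree.copy()
        b = ols_lengths(topo, dvec)
        for ei, v in enumerate(topo.edge_nodes):
            at.lengths[v] = b[ei]
        scored.append((total_loglik(at, lp, model), ti, at))
    scored.sort(key=lambda x: (-x[0], x[1]))
    return scored


def _refine(cands, lp, model, refine_top, refine_passes, tol):
    best_at, best_lnl = None, -np.inf
    for _lnl0, _ti, at in cands[:refine_top]:
        at2 = at.copy()
        lnl = optimize_branches(at2, lp, model, tol=tol, max_passes=refine_passes)
        if lnl > best_lnl:
            best_lnl, best_at = lnl, at2
    return best_at, best_lnl


def exhaustive_search(lp, enc, model, cmask=None, refine_top=5,
                      refine_passes=8, tol=1e-6, screen_top=60):
    """Exhaustive-enumeration search: every topology is ranked by its
    least-squares path-length residual, the best ``screen_top`` are scored
    by likelihood at OLS branch lengths, and the leading ``refine_top``
    are fully optimized.  Returns (ArrayTree, lnL).  Deterministic."""
    n = enc.shape[0]
    topos = enumerate_topologies(n)
    full_mask = (1 << n) - 1
    dist = ml_pairwise_distances(enc)
    dvec = np.array([dist[a, b] for a, b in combinations(range(n), 2)])
    if cmask is None:
        indices = list(range(len(topos)))
    else:
        indices = constrained_topology_indices(n, cmask)
        if not indices:
            raise ValueError("no topology satisfies the constraint")
    if len(indices) > screen_top:
        res = _ls_residuals(n, dvec)
        indices = sorted(indices, key=lambda ti: (res[ti], ti))[:screen_top]
    scored = _screen_candidates(topos, indices, dvec, lp, model)
    return _refine(scored, lp, model, refine_top, refine_passes, tol)


def exhaustive_delta(lp, enc, model, cmask, refine_top=2, refine_passes=8,
                     tol=1e-6, screen_top=60):
    """Unconstrained and constrained optima from one shared screening pass.

    Used by the parametric-bootstrap topology test, where both searches
    are needed for every replicate: topologies are pre-ranked by
    least-squares residual, the leaders (plus the constraint-satisfying
    leaders) are likelihood-scored at OLS branch lengths, and the top
    ``refine_top`` of each pool are optimized.  Returns
    ``(best_at, best_lnl, con_at, con_lnl)``; the unconstrained optimum is
    floored at the constrained one (the constrained space is nested).
    """
    n = enc.shape[0]
    topos = enumerate_topologies(n)
    full_mask = (1 << n) - 1
    dist = ml_pairwise_distances(enc)
    dvec = np.array([dist[a, b] for a, b in combinations(range(n), 2)])
    con_all = constrained_topology_indices(n, cmask)
    if not con_all:
        raise ValueError("no topology satisfies the constraint")
    free = list(range(len(topos)))
    if len(free) > screen_top or len(con_all) > screen_top:
        res = _ls_residuals(n, dvec)
        free = sorted(free, key=lambda ti: (res[ti], ti))[:screen_top]
        con_all = sorted(con_all, key=lambda ti: (res[ti], ti))[:screen_top]
    pool = sorted(set(free) | set(con_all))
    scored = _screen_candidates(topos, pool, dvec, lp, model)
    con_set = set(con_all)
    con_scored = [s for s in scored if s[1] in con_set]
    free_scored = [s for s in scored if s[1] in set(free)]
    con_at, con_lnl = _refine(con_scored, lp, model, refine_top,
                              refine_passes, tol)
    best_at, best_lnl = _refine(free_scored, lp, model, refine_top,
                                refine_passes, tol)
    if con_lnl > best_lnl:
        best_at, best_lnl = con_at, con_lnl
    return best_at, best_lnl, con_at, con_lnl


def _edge_list_masks(edges, n_leaves):
    at = ArrayTree.from_edges(edges, [0.1] * len(edges), n_leaves)
    masks = at.leaf_masks()
    return [int(masks[v]) for v in range(at.n_nodes) if at.parent[v] >= 0]


def _nni_neighbors(edges, lengths, n_leaves):
    """All NNI rearrangements of an unrooted binary tree (edge-list form)."""
    adj = {}
    elen = {}
    for (u, v), ln in zip(edges, lengths):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
        elen[frozenset((u, v))] = ln
    out = []
    for (u, v) in edges:
        if u < n_leaves or v < n_leaves:
            continue
        u_nb = [x for x in adj[u] if x != v]
        v_nb = [x for x in adj[v] if x != u]
        b = u_nb[1]
        for c in v_nb:
            new_edges, new_lengths = [], []
            for (x, y), ln in zip(edges, lengths):
                s = frozenset((x, y))
                if s == frozenset((u, b)):
                    new_edges.append((u, c))
                    new_lengths.append(elen[frozenset((v, c))])
                elif s == frozenset((v, c)):
                    new_edges.append((v, b))
                    new_lengths.append(elen[frozenset((u, b))])
                else:
                    new_edges.append((x, y))
                    new_lengths.append(ln)
            out.append((new_edges, new_lengths))
    return out


def _graft_constraint_start(dist, cidx):
    """NJ start tree in which the constrained leaf set is monophyletic:
    join an NJ tree of the group with an NJ tree of its complement."""
    n = dist.shape[0]
    rest = [i for i in range(n) if i not in cidx]
    cidx = sorted(cidx)

    def subtree(idxs, offset):
        if len(idxs) == 1:
            return [], [], idxs[0], offset
        sub = dist[np.ix_(idxs, idxs)]
        edges, lengths, _ = neighbor_joining(sub)
        remap = {}
        nxt = offset
        out_edges = []
        for (a, b) in edges:
            pair = []
            for x in (a, b):
                if x < len(idxs):
                    pair.append(idxs[x])
                else:
                    if x not in remap:
                        remap[x] = nxt
                        nxt += 1
                    pair.append(remap[x])
            out_edges.append(tuple(pair))
        # subdivide the last-joined edge to create an attachment point
        u, v = out_edges[-1]
        ln = lengths[-1]
        hub = nxt
        nxt += 1
        out_edges = out_edges[:-1] + [(u, hub), (hub, v)]
        out_lengths = lengths[:-1] + [ln / 2, ln / 2]
        return out_edges, out_lengths, hub, nxt

    nxt = n
    e1, l1, h1, nxt = subtree(cidx, nxt)
    e2, l2, h2, nxt = subtree(rest, nxt)
    edges = e1 + e2 + [(h1, h2)]
    lengths = l1 + l2 + [0.5]
    return edges, lengths


def regraft_to_satisfy(edges, lengths, n_leaves, cmask):
    """Minimal edit making ``cmask`` monophyletic: find a leaf of the
    constraint whose removal leaves the rest of the constraint as a clade,
    prune it and reattach it onto that clade's stem edge.  Returns
    ``(edges, lengths)`` or ``None`` if no single-leaf regraft works."""
    masks_at = ArrayTree.from_edges(edges, lengths, n_leaves)
    node_masks = masks_at.leaf_masks()
    full_mask = (1 << n_leaves) - 1
    edge_masks = {}
    for v in range(masks_at.n_nodes):
        if masks_at.parent[v] >= 0:
            edge_masks[v] = int(node_masks[v])
    for leaf in range(n_leaves):
        if not (cmask >> leaf) & 1:
            continue
        rest = cmask ^ (1 << leaf)
        if bin(rest).count("1") < 2:
            continue
        stem = None
        for v, m in edge_masks.items():
            mm = m if not (m >> leaf) & 1 else (full_mask ^ m)
            if mm == rest:
                stem = v
                break
        if stem is None:
            continue
        # prune the leaf: remove it and splice out its degree-2 neighbor
        adj = {}
        elen = {}
        for (u, v), ln in zip(edges, lengths):
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
            elen[frozenset((u, v))] = ln
        hub = adj[leaf][0]
        others = [x for x in adj[hub] if x != leaf]
        if len(others) != 2:
            continue
        a, b = others
        new_edges, new_lengths = [], []
        drop = {frozenset((leaf, hub)), frozenset((hub, a)), frozenset((hub, b))}
        for (u, v), ln in zip(edges, lengths):
            if frozenset((u, v)) in drop:
                continue
            new_edges.append((u, v))
            new_lengths.append(ln)
        new_edges.append((a, b))
        new_lengths.append(elen[frozenset((hub, a))] + elen[frozenset((hub, b))])
        # reattach on the stem edge of the remaining constraint clade
        p = int(masks_at.parent[stem])
        stem_pair = frozenset((stem, p))
        if stem_pair in drop or stem_pair not in {frozenset(e) for e in new_edges}:
            # stem edge itself was spliced; attach to the edge (a, b)
            stem_pair = frozenset((a, b))
        su, sv = tuple(stem_pair)
        half = elen.get(stem_pair, 0.2) / 2.0
        out_e, out_l = [], []
        for (u, v), ln in zip(new_edges, new_lengths):
            if frozenset((u, v)) == stem_pair:
                continue
            out_e.append((u, v))
            out_l.append(ln)
        out_e += [(su, hub), (hub, sv), (hub, leaf)]
        out_l += [max(half, MIN_BL), max(half, MIN_BL), 0.1]
        if mask_satisfies_constraint(
            _edge_list_masks(out_e, n_leaves), cmask, full_mask
        ):
            return out_e, out_l
    return None


def nni_search(lp, enc, model, cmask=None, max_sweeps=10, refine_passes=8,
               screen_passes=3, screen_top=3, tol=1e-6, start=None):
    """NNI hill-climbing from a neighbor-joining (or supplied) start tree.

    Each sweep scores every admissible NNI neighbor by likelihood at its
    inherited branch lengths, then re-optimizes only the leading
    ``screen_top`` candidates; the first that beats the incumbent is
    accepted.  Moves breaking the constraint bipartition are rejected.
    Returns (ArrayTree, lnL).  Deterministic.
    """
    n = enc.shape[0]
    full_mask = (1 << n) - 1
    dist = ml_pairwise_distances(enc)
    if start is not None:
        edges, lengths = start
    else:
        edges, lengths, _ = neighbor_joining(dist)
    if cmask is not None and not mask_satisfies_constraint(
        _edge_list_masks(edges, n), cmask, full_mask
    ):
        regrafted = regraft_to_satisfy(edges, lengths, n, cmask)
        if regrafted is not None:
            edges, lengths = regrafted
        else:
            cidx = [i for i in range(n) if cmask >> i & 1]
            edges, lengths = _graft_constraint_start(dist, cidx)

    at = ArrayTree.from_edges(edges, lengths, n)
    best = optimize_branches(at, lp, model, tol=1e-4, max_passes=refine_passes)
    best_edges, best_lengths = at.to_edges()
    for _ in range(max_sweeps):
        cands = []
        for ne, nl in _nni_neighbors(best_edges, best_lengths, n):
            if cmask is not None and not mask_satisfies_constraint(
                _edge_list_masks(ne, n), cmask, full_mask
            ):
                continue
            cand_at = ArrayTree.from_edges(ne, nl, n)
            cands.append((total_loglik(cand_at, lp, model), ne, nl, cand_at))
        cands.sort(key=lambda x: -x[0])
        improved = False
        for _lnl0, ne, nl, cand_at in cands[:screen_top]:
            cand = optimize_branches(
                cand_at, lp, model, tol=1e-4, max_passes=screen_passes
            )
            if cand > best + tol:
                best = cand
                at = cand_at
                best_edges, best_lengths = at.to_edges()
                improved = True
                break
        if not improved:
            break
    final = optimize_branches(at, lp, model, tol=tol, max_passes=refine_passes)
    return at, final
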