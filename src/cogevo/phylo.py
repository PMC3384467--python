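"""Maximum-likelihood protein phylogenetics under WAG+F.

The inference pipeline mirrors classical ML protein tree building with
uniform rates across sites: columns containing gaps or missing data are
deleted entirely, equilibrium frequencies are re-estimated from the data
(the "+F" step), pairwise distances are maximum-likelihood estimates under
the resulting reversible model, a neighbor-joining tree provides the
starting topology, and a nearest-neighbour-interchange hill climb under the
Felsenstein pruning likelihood refines it.  Branch lengths around each
candidate rearrangement are re-optimised by coordinate-wise scalar
optimisation using cached directional partial likelihoods, so a full NNI
sweep stays cheap even for ~30-taxon alignments.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MISSING_CODE, CogAlignment
from .substitution import SubstitutionModel, wag_f
from .tree import PhyloTree

__all__ = [
    "complete_deletion",
    "empirical_frequencies",
    "ml_pairwise_distance",
    "distance_matrix",
    "nj_tree",
    "tree_log_likelihood",
    "nni_search",
    "infer_tree",
]

#: Bracket for all scalar branch-length optimisations (subs/site).
BRANCH_MIN = 1e-9
BRANCH_MAX = 10.0

_FREQ_FLOOR = 1e-6


class EmptyAlignmentError(ValueError):
    """Raised when complete deletion leaves no alignment columns."""


def complete_deletion(aln: CogAlignment) -> CogAlignment:
    """Remove every column containing a gap or missing symbol in any member."""
    if len(aln) == 0:
        raise ValueError("empty alignment")
    enc = aln.encoded()
    keep = np.all(enc != MISSING_CODE, axis=0)
    if not keep.any():
        raise EmptyAlignmentError(
            f"no columns survive complete deletion in {aln.cog_id}")
    cols = np.flatnonzero(keep)
    seqs = ["".join(s[c] for c in cols) for s in aln.seqs]
    return CogAlignment(aln.cog_id, list(aln.ids), seqs, dict(aln.taxon_of))


def empirical_frequencies(aln: CogAlignment) -> np.ndarray:
    """Observed amino-acid frequencies with zero counts floored at 1e-6."""
    enc = aln.encoded()
    residues = enc[enc != MISSING_CODE]
    if residues.size == 0:
        raise ValueError(f"no residues in alignment {aln.cog_id}")
    counts = np.bincount(residues, minlength=20).astype(float)
    pi = counts / counts.sum()
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def _encode_one(seq: str) -> np.ndarray:
    from .wag_data import AA_INDEX
    table = np.full(128, MISSING_CODE, dtype=np.int8)
    for a, i in AA_INDEX.items():
        table[ord(a)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _pair_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ok = (x != MISSING_CODE) & (y != MISSING_CODE)
    if not ok.any():
        raise ValueError("no comparable sites between sequences")
    idx = x[ok].astype(np.int64) * 20 + y[ok]
    return np.bincount(idx, minlength=400).reshape(20, 20).astype(float)


def ml_pairwise_distance(seq_i: str, seq_j: str, model: SubstitutionModel,
                         t_max: float = BRANCH_MAX, full: bool = False):
    """ML evolutionary distance between two aligned sequences.

    Maximises ``sum_sites log(pi_x * P(t)[x, y])`` over ``t in [0, t_max]``.
    With ``full=True`` returns ``(distance, saturated)`` where the flag marks
    an optimum at the upper bound.
    """
    if len(seq_i) != len(seq_j):
        raise ValueError("sequences must have equal aligned length")
    x, y = _encode_one(seq_i), _encode_one(seq_j)
    counts = _pair_counts(x, y)
    if counts.sum() == np.trace(counts):  # identical on comparable sites
        return (0.0, False) if full else 0.0
    log_pi = np.log(model.frequencies)

    def neg_ll(t: float) -> float:
        p = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            term = log_pi[:, None] + np.log(np.maximum(p, 1e-300))
        return -float(np.sum(counts * term))

    res = minimize_scalar(neg_ll, bounds=(0.0, t_max), method="bounded",
                          options={"xatol": 1e-8})
    t_hat = float(res.x)
    saturated = t_hat > t_max - 1e-3
    return (t_hat, saturated) if full else t_hat


def distance_matrix(aln: CogAlignment, model: SubstitutionModel
                    ) -> tuple[list[str], np.ndarray]:
    """All pairwise ML distances; returns (member ids, symmetric matrix)."""
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_pairwise_distance(
                aln.seqs[i], aln.seqs[j], model)
    return list(aln.ids), d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: np.ndarray, labels: list[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative estimated branch lengths are clamped to zero.  Ties in the NJ
    criterion break on the smallest (i, j) index pair, which makes the
    construction deterministic.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels disagree")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    tree = PhyloTree()
    nodes = [tree.add_node(lab) for lab in labels]
    d = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        iu = np.triu_indices(m, k=1)
        q_upper = np.full_like(q, np.inf)
        q_upper[iu] = q[iu]
        i_loc, j_loc = np.unravel_index(int(np.argmin(q_upper)), q.shape)
        i, j = active[i_loc], active[j_loc]

        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        li = min(max(li, 0.0), max(dij, 0.0))
        lj = max(dij - li, 0.0)
        u = tree.add_node()
        tree.add_edge(nodes[i], u, li)
        tree.add_edge(nodes[j], u, lj)

        # distances from the new node to the remaining actives
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[-1, k] = d[k, -1] = max(
                0.5 * (d[i, k] + d[j, k] - dij), 0.0)
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    # resolve the final three around a central node
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    center = tree.add_node()
    tree.add_edge(nodes[a], center, max(0.5 * (dab + dac - dbc), 0.0))
    tree.add_edge(nodes[b], center, max(0.5 * (dab + dbc - dac), 0.0))
    tree.add_edge(nodes[c], center, max(0.5 * (dac + dbc - dab), 0.0))
    return tree


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

class _Pruner:
    """Directional partial likelihoods (messages) on an unrooted tree.

    ``message(u, v)`` is the likelihood of the data in the subtree on the
    ``u`` side of edge (u, v), conditional on the state at ``u``, excluding
    the (u, v) edge itself.  Messages are scaled per site; the log of the
    scale is carried separately.
    """

    def __init__(self, tree: PhyloTree, aln: CogAlignment,
                 model: SubstitutionModel):
        tree_names = set(tree.leaf_names)
        aln_names = set(aln.ids)
        if tree_names != aln_names:
            raise ValueError(
                "tree leaves and alignment members differ: "
                f"{sorted(tree_names ^ aln_names)[:5]} ...")
        self.tree = tree
        self.model = model
        enc = aln.encoded()
        self.n_sites = enc.shape[1]
        self.leaf_partials: dict[int, np.ndarray] = {}
        for row, sid in enumerate(aln.ids):
            node = tree.node_of(sid)
            part = np.zeros((self.n_sites, 20))
            codes = enc[row]
            miss = codes == MISSING_CODE
            part[miss, :] = 1.0
            ok = ~miss
            part[np.flatnonzero(ok), codes[ok].astype(int)] = 1.0
            self.leaf_partials[node] = part
        self._memo: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._pcache: dict[float, np.ndarray] = {}

    def invalidate(self) -> None:
        self._memo.clear()

    def _p(self, t: float) -> np.ndarray:
        p = self._pcache.get(t)
        if p is None:
            p = self.model.transition_matrix(t)
            self._pcache[t] = p
        return p

    def message(self, u: int, v: int) -> tuple[np.ndarray, np.ndarray]:
        key = (u, v)
        got = self._memo.get(key)
        if got is not None:
            return got
        # iterative postorder to avoid deep recursion
        order: list[tuple[int, int]] = []
        stack = [(u, v)]
        while stack:
            a, b = stack.pop()
            order.append((a, b))
            for w in self.tree.adj[a]:
                if w != b and (w, a) not in self._memo:
                    stack.append((w, a))
        for a, b in reversed(order):
            if (a, b) in self._memo:
                continue
            if self.tree.is_leaf(a):
                self._memo[(a, b)] = (self.leaf_partials[a],
                                      np.zeros(self.n_sites))
                continue
            part = np.ones((self.n_sites, 20))
            scale = np.zeros(self.n_sites)
            for w, t in self.tree.adj[a].items():
                if w == b:
                    continue
                sub, sub_scale = self._memo[(w, a)]
                part = part * (sub @ self._p(t).T)
                scale = scale + sub_scale
            mx = part.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            part = part / mx[:, None]
            scale = scale + np.log(mx)
            self._memo[(a, b)] = (part, scale)
        return self._memo[(u, v)]

    def edge_log_likelihood(self, u: int, v: int, t: float | None = None
                            ) -> float:
        fu, su = self.message(u, v)
        fv, sv = self.message(v, u)
        if t is None:
            t = self.tree.adj[u][v]
        site = np.einsum("a,sa,sa->s", self.model.frequencies, fu,
                         fv @ self._p(t).T)
        return float(np.sum(np.log(np.maximum(site, 1e-300)) + su + sv))

    def log_likelihood(self) -> float:
        u, v, _ = self.tree.edges()[0]
        return self.edge_log_likelihood(u, v)


def tree_log_likelihood(tree: PhyloTree, aln: CogAlignment,
                        model: SubstitutionModel) -> float:
    """Felsenstein-pruning log-likelihood of an unrooted tree.

    The virtual root is placed on an arbitrary edge; under a reversible
    model the value is independent of that choice.
    """
    return _Pruner(tree, aln, model).log_likelihood()


# ---------------------------------------------------------------------------
# NNI hill climbing
# ---------------------------------------------------------------------------

def _local_log_likelihood(model, msgs, lengths, pcache):
    """logL of the quartet arrangement around one internal edge.

    ``msgs`` = [(F, scale)] for the four adjacent subtrees (A, B | C, D);
    ``lengths`` = [tA, tB, tC, tD, t_uv].
    """
    def p(t):
        got = pcache.get(t)
        if got is None:
            got = model.transition_matrix(t)
            pcache[t] = got
        return got

    (fa, sa), (fb, sb), (fc, sc), (fd, sd) = msgs
    ta, tb, tc, td, tuv = lengths
    hu = (fa @ p(ta).T) * (fb @ p(tb).T)
    hv = (fc @ p(tc).T) * (fd @ p(td).T)
    site = np.einsum("a,sa,sa->s", model.frequencies, hu, hv @ p(tuv).T)
    return float(np.sum(np.log(np.maximum(site, 1e-300)) + sa + sb + sc + sd))


def _optimise_local(model, msgs, lengths, pcache, n_passes: int = 2):
    """Coordinate-wise branch-length optimisation of the 5 local lengths."""
    lengths = list(lengths)
    for _ in range(n_passes):
        for k in range(5):
            def obj(t, k=k):
                trial = lengths[:k] + [t] + lengths[k + 1:]
                return -_local_log_likelihood(model, msgs, trial, pcache)
            res = minimize_scalar(obj, bounds=(BRANCH_MIN, BRANCH_MAX),
                                  method="bounded", options={"xatol": 1e-5})
            lengths[k] = float(res.x)
    return lengths, _local_log_likelihood(model, msgs, lengths, pcache)


def nni_search(start: PhyloTree, aln: CogAlignment, model: SubstitutionModel,
               max_rounds: int = 5) -> PhyloTree:
    """Nearest-neighbour-interchange hill climb from a starting tree.

    Each internal edge is scanned in deterministic order; the current and
    both swapped quartet arrangements are scored with the five local branch
    lengths re-optimised, and strict improvements are accepted immediately.
    Stops at a local optimum or after ``max_rounds`` sweeps.  The returned
    tree's likelihood is never below the start tree's.
    """
    tree = start.copy()
    if max_rounds <= 0:
        return tree
    pruner = _Pruner(tree, aln, model)
    pcache: dict[float, np.ndarray] = {}

    for _ in range(max_rounds):
        improved = False
        for u, v in sorted(tree.internal_edges()):
            if v not in tree.adj.get(u, {}):
                continue  # edge list went stale after an accepted swap
            if tree.degree(u) != 3 or tree.degree(v) != 3:
                continue  # only binary rearrangements
            a, b = [w for w in tree.adj[u] if w != v]
            c, d = [w for w in tree.adj[v] if w != u]
            msgs = {w: pruner.message(w, anchor)
                    for w, anchor in ((a, u), (b, u), (c, v), (d, v))}
            base_lengths = [tree.adj[u][a], tree.adj[u][b],
                            tree.adj[v][c], tree.adj[v][d], tree.adj[u][v]]
            arrangements = [
                ((a, b, c, d), base_lengths),
                ((a, c, b, d), [base_lengths[0], base_lengths[2],
                                base_lengths[1], base_lengths[3],
                                base_lengths[4]]),
                ((a, d, c, b), [base_lengths[0], base_lengths[3],
                                base_lengths[2], base_lengths[1],
                                base_lengths[4]]),
            ]
            best = None
            for idx, (quartet, lens) in enumerate(arrangements):
                m = [msgs[w] for w in quartet]
                opt_lens, ll = _optimise_local(model, m, lens, pcache)
                if best is None or ll > best[0] + 1e-9:
                    best = (ll, idx, quartet, opt_lens)
            _, idx, quartet, opt_lens = best
            qa, qb, qc, qd = quartet
            # rewire to the winning arrangement and apply its lengths
            for w in (a, b):
                tree.remove_edge(u, w)
            for w in (c, d):
                tree.remove_edge(v, w)
            tree.remove_edge(u, v)
            tree.add_edge(u, qa, opt_lens[0])
            tree.add_edge(u, qb, opt_lens[1])
            tree.add_edge(v, qc, opt_lens[2])
            tree.add_edge(v, qd, opt_lens[3])
            tree.add_edge(u, v, opt_lens[4])
            pruner.invalidate()
            if idx != 0:
                improved = True
        if not improved:
            break
    return tree


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def infer_tree(aln: CogAlignment, model: SubstitutionModel | None = None,
               nni_rounds: int = 1) -> PhyloTree:
    """Filter, estimate +F frequencies, build NJ start tree, NNI-refine.

    With ``model=None`` the WAG exchangeabilities are combined with
    frequencies estimated from the filtered alignment (WAG+F).
    """
    filtered = complete_deletion(aln)
    if model is None:
        model = wag_f(empirical_frequencies(filtered))
    ids, d = distance_matrix(filtered, model)
    tree = nj_tree(d, ids)
    if nni_rounds > 0:
        tree = nni_search(tree, filtered, model, max_rounds=nni_rounds)
    return tree
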