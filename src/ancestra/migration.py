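"""Population-splits-and-migrations graph inference from ancestry allele counts.

A fitted admixture model yields, per ancestry, pseudo-counts of alternate
and reference alleles (proportion sums x 2, times frequencies, rounded).
Allele frequencies deviate from their across-ancestry mean by drift
accumulated along a rooted binary tree; the centered frequency covariance
is the sufficient statistic.  A Gaussian composite likelihood on its
entries, with block-jackknife standard errors, scores candidate graphs.
Migration edges let a lineage inherit a fixed proportion w of its alleles
from a second lineage; branch lengths enter the model covariance linearly,
so for a fixed topology and migration weights they are refit by
non-negative least squares.  The fitter follows the original protocol:
random leaf input orders, greedy edge addition from m = 0 upward, a
stopping rule on the sign of the composite log-likelihood, and a
majority-rule bootstrap consensus tree.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from ._tree import Node
from ._util import child_rng, child_seed

__all__ = [
    "AlleleCountTable",
    "MigrationGraphModel",
    "MigrationGraphResults",
    "ConsensusTree",
    "ancestry_allele_counts",
    "frequency_covariance",
    "fit_tree",
    "fit_migration_graph",
    "stopping_rule",
    "consensus_tree",
    "replicate_runs",
    "bootstrap_trees",
]


# ---------------------------------------------------------------------------
# Allele counts
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountTable:
    """Per-ancestry total allele counts and per-marker alt/ref counts."""

    labels: list[str]
    N: np.ndarray  # K total allele counts
    alt: np.ndarray  # K x m
    ref: np.ndarray  # K x m

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        if np.any(self.alt < 0) or np.any(self.ref < 0) or np.any(self.N <= 0):
            raise ValueError("allele counts must be non-negative with positive totals")
        if not np.all(self.alt + self.ref == self.N[:, None]):
            raise ValueError("alt + ref must equal N at every marker")

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def n_markers(self) -> int:
        return self.alt.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.alt / self.N[:, None]

    def write(self, path, compress: bool = True) -> None:
        """Write in the TreeMix input dialect (header; 'ref,alt' per cell)."""
        opener = gzip.open if compress else open
        with opener(path, "wt", encoding="utf-8", newline="\n") as fh:
            fh.write(" ".join(self.labels) + "\n")
            for j in range(self.n_markers):
                fh.write(
                    " ".join(f"{self.ref[k, j]},{self.alt[k, j]}" for k in range(self.K))
                    + "\n"
                )


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def ancestry_allele_counts(
    Q: np.ndarray,
    F: np.ndarray,
    labels: list[str] | None = None,
    extra_profiles: dict[str, tuple[np.ndarray, int]] | None = None,
) -> AlleleCountTable:
    """Convert a fitted admixture model to ancestry-specific allele counts.

    Total count per ancestry N_k = round(2 * sum_i q_ik); alternate count
    per marker = round(N_k * f_kj); reference = N_k - alt (rounding N first
    and deriving ref by subtraction keeps alt + ref = N exact).
    ``extra_profiles`` appends externally supplied ancestries as
    label -> (frequency vector, total allele count N).
    """
    Q = np.asarray(Q, float)
    F = np.asarray(F, float)
    K = Q.shape[1]
    labels = list(labels) if labels is not None else [f"comp{k + 1}" for k in range(K)]
    N = _round_half_away(2.0 * Q.sum(axis=0)).astype(np.int64)
    keep = N > 0
    if not keep.all():
        dropped = [labels[k] for k in range(K) if not keep[k]]
        warnings.warn(f"dropping ancestries with zero allele count: {dropped}")
    labels = [labels[k] for k in range(K) if keep[k]]
    N = N[keep]
    F = F[keep]
    alt = _round_half_away(N[:, None] * F).astype(np.int64)
    if extra_profiles:
        for label, (freq, n_extra) in extra_profiles.items():
            freq = np.asarray(freq, float)
            labels.append(label)
            N = np.append(N, int(n_extra))
            alt = np.vstack([alt, _round_half_away(int(n_extra) * freq).astype(np.int64)])
    ref = N[:, None] - alt
    return AlleleCountTable(labels, N, alt, ref)


# ---------------------------------------------------------------------------
# Frequency covariance
# ---------------------------------------------------------------------------

def frequency_covariance(counts: AlleleCountTable, block_size: int = 500):
    """Centered allele-frequency covariance with sampling-noise correction.

    Per marker, deviations x_kj = f_kj - mean_k(f_kj); W_hat averages the
    outer products over markers and subtracts the centered expectation of
    binomial sampling noise (diag f(1-f)/N_k, conjugated by the centering
    projection).  Standard errors by block jackknife over contiguous marker
    blocks.
    """
    if counts.K < 2:
        raise ValueError("need at least 2 ancestries")
    m = counts.n_markers
    if m < 2:
        raise ValueError("need at least 2 markers for a standard error")
    f = counts.frequencies()
    K = counts.K
    C = np.eye(K) - np.ones((K, K)) / K
    x = C @ f
    raw = np.einsum("kj,lj->jkl", x, x)  # per-marker outer products
    noise_diag = f * (1 - f) / counts.N[:, None]
    noise = np.einsum("kj,ka,kb->jab", noise_diag, C, C)
    per_marker = raw - noise
    W_hat = per_marker.mean(axis=0)
    bs = max(1, min(block_size, m // 2)) if m >= 2 else 1
    starts = np.arange(0, m, bs)
    nb = len(starts)
    if nb < 2:
        bs = m // 2
        starts = np.arange(0, m, bs)
        nb = len(starts)
    total = per_marker.sum(axis=0)
    jack = np.empty((nb, K, K))
    for i, s in enumerate(starts):
        blk = per_marker[s : s + bs]
        jack[i] = (total - blk.sum(axis=0)) / (m - blk.shape[0])
    jbar = jack.mean(axis=0)
    se = np.sqrt((nb - 1) / nb * ((jack - jbar) ** 2).sum(axis=0))
    se = np.maximum(se, 1e-12)
    return W_hat, se


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------

def _skbio_to_node(sknode) -> Node:
    node = Node(sknode.name, sknode.length or 0.0)
    for child in sknode.children:
        node.add_child(_skbio_to_node(child))
    return node


def _reroot_on_leaf_edge(tree: Node, leaf_name: str) -> Node:
    """Root an (effectively unrooted) tree on the pendant edge of a leaf."""
    # adjacency over the existing nodes
    adj: dict[int, list[tuple[Node, float]]] = {}
    nodes: dict[int, Node] = {}
    for n in tree.traverse():
        nodes[id(n)] = n
        adj.setdefault(id(n), [])
        for c in n.children:
            adj[id(n)].append((c, c.length))
            adj.setdefault(id(c), []).append((n, c.length))
    leaf = tree.find(leaf_name)
    if leaf.parent is None:
        raise ValueError("cannot root on the current root")
    (peer, plen) = next((p, l) for p, l in adj[id(leaf)] if p is leaf.parent)

    def build(old: Node, came_from: Node | None, length: float) -> Node:
        new = Node(old.name, length)
        for nbr, l in adj[id(old)]:
            if nbr is came_from:
                continue
            new.add_child(build(nbr, old, l))
        return new

    root = Node(None, 0.0)
    root.add_child(build(leaf, peer, plen / 2.0))
    root.add_child(build(peer, leaf, plen / 2.0))
    # suppress any unifurcation left at the former root
    for n in list(root.traverse()):
        if n.parent is not None and len(n.children) == 1:
            child = n.children[0]
            child.length += n.length
            sibs = n.parent.children
            sibs[sibs.index(n)] = child
            child.parent = n.parent
    return root


def _tree_distance_design(tree: Node, labels: list[str]):
    """Pairwise-path design matrix over branches for distance fitting."""
    branch_nodes = [n for n in tree.traverse() if n.parent is not None]
    index = {id(n): i for i, n in enumerate(branch_nodes)}
    leaf_paths = {}
    for leaf in tree.leaves():
        path = set()
        n = leaf
        while n.parent is not None:
            path.add(index[id(n)])
            n = n.parent
        leaf_paths[leaf.name] = path
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            sym = leaf_paths[labels[a]] ^ leaf_paths[labels[b]]
            row = np.zeros(len(branch_nodes))
            row[list(sym)] = 1.0
            rows.append(row)
    return np.array(rows), branch_nodes


def fit_tree(
    W_hat: np.ndarray,
    labels: list[str],
    root_label: str,
    leaf_order: list[int] | None = None,
) -> Node:
    """Neighbor-joining topology from covariance-implied distances.

    Distances d_ab = W_aa + W_bb - 2 W_ab; the topology comes from NJ (tie
    breaks follow the supplied leaf input order), the tree is rooted on the
    pendant edge of ``root_label``, and branch lengths are refit by
    non-negative least squares against d.
    """
    if root_label not in labels:
        raise KeyError(f"unknown root label {root_label!r}")
    K = len(labels)
    diag = np.diag(W_hat)
    d = diag[:, None] + diag[None, :] - 2.0 * W_hat
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0
    order = list(range(K)) if leaf_order is None else list(leaf_order)
    perm_labels = [labels[i] for i in order]
    if K == 2:
        tree = Node(None, 0.0)
        other = [l for l in labels if l != root_label][0]
        tree.add_child(Node(root_label, d[0, 1] / 2.0))
        tree.add_child(Node(other, d[0, 1] / 2.0))
        return tree
    dm = DistanceMatrix(d[np.ix_(order, order)], ids=perm_labels)
    unrooted = _skbio_to_node(_skbio_nj(dm))
    tree = _reroot_on_leaf_edge(unrooted, root_label)
    # refit branch lengths against the distance matrix
    X, branch_nodes = _tree_distance_design(tree, labels)
    y = d[np.triu_indices(K, k=1)]
    lengths, _ = optimize.nnls(X, y)
    for n, l in zip(branch_nodes, lengths):
        n.length = float(l)
    return tree


# ---------------------------------------------------------------------------
# Graph model: covariance from paths, migration edges, composite likelihood
# ---------------------------------------------------------------------------

def _clade(node: Node) -> tuple[str, ...]:
    return tuple(sorted(node.leaf_names()))


def _ancestry_weights(tree: Node, migrations: list[tuple[Node, Node, float]]):
    """Per-leaf branch inheritance weights under the migration mixture.

    Returns (U, branch_nodes): U[k, b] is the weight with which leaf k's
    frequency deviation accumulates the drift on branch b.  A migration
    (source, target, w) makes the target node inherit (1-w) via its parent
    branch and w from the source lineage.
    """
    branch_nodes = [n for n in tree.traverse() if n.parent is not None]
    index = {id(n): i for i, n in enumerate(branch_nodes)}
    mig = {id(t): (s, w) for s, t, w in migrations}
    memo: dict[int, dict[int, float]] = {}

    def weights(node: Node) -> dict[int, float]:
        if node.parent is None:
            return {}
        if id(node) in memo:
            return memo[id(node)]
        own = dict(weights(node.parent))
        b = index[id(node)]
        own[b] = own.get(b, 0.0) + 1.0
        if id(node) in mig:
            src, w = mig[id(node)]
            out: dict[int, float] = {k: (1.0 - w) * v for k, v in own.items()}
            for k, v in weights(src).items():
                out[k] = out.get(k, 0.0) + w * v
        else:
            out = own
        memo[id(node)] = out
        return out

    leaves = tree.leaves()
    U = np.zeros((len(leaves), len(branch_nodes)))
    for i, leaf in enumerate(leaves):
        for b, v in weights(leaf).items():
            U[i, b] = v
    return U, branch_nodes, [leaf.name for leaf in leaves]


def _composite_design(tree, migrations, labels):
    """Design matrix mapping branch lengths to centered covariance entries."""
    U, branch_nodes, leaf_names = _ancestry_weights(tree, migrations)
    # reorder rows to the label order of W_hat
    perm = [leaf_names.index(l) for l in labels]
    U = U[perm]
    K = len(labels)
    C = np.eye(K) - np.ones((K, K)) / K
    CU = C @ U  # K x n_branches
    iu = np.triu_indices(K)
    X = np.empty((len(iu[0]), U.shape[1]))
    for b in range(U.shape[1]):
        outer = np.outer(CU[:, b], CU[:, b])
        X[:, b] = outer[iu]
    return X, branch_nodes, iu


def _fit_lengths_ll(W_hat, se, tree, migrations, labels):
    """NNLS branch lengths and the composite log-likelihood they achieve."""
    X, branch_nodes, iu = _composite_design(tree, migrations, labels)
    y = W_hat[iu]
    wts = 1.0 / se[iu]
    lengths, _ = optimize.nnls(X * wts[:, None], y * wts)
    fit = X @ lengths
    ll = float(stats.norm.logpdf(y, loc=fit, scale=se[iu]).sum())
    return lengths, branch_nodes, ll


@dataclass
class MigrationGraphResults:
    """A fitted splits-and-migrations graph."""

    tree: Node
    migration_edges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    loglik: float
    m_events: int
    labels: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Migration graph fit",
            "===================",
            f"ancestries:            {len(self.labels)}",
            f"migration events:      {self.m_events}",
            f"composite loglik:      {self.loglik:.4f}",
            f"tree: {self.tree.to_newick()}",
        ]
        for src, tgt, w in self.migration_edges:
            lines.append(f"  migration {'+'.join(src)} -> {'+'.join(tgt)}  w = {w:.3f}")
        return "\n".join(lines)

    def write(self, prefix) -> None:
        with open(f"{prefix}.nwk", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.tree.to_newick() + "\n")
        with open(f"{prefix}.migrations.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("source_clade\ttarget_clade\tweight\n")
            for src, tgt, w in self.migration_edges:
                fh.write(f"{'+'.join(src)}\t{'+'.join(tgt)}\t{w:.6f}\n")


class MigrationGraphModel:
    """Splits-and-migrations graph model over a frequency covariance.

    Construct from an ``AlleleCountTable`` (covariance and SEs are computed
    by block jackknife) or directly from (W_hat, se, labels) via
    ``from_covariance``.
    """

    def __init__(self, counts: AlleleCountTable, block_size: int = 500):
        self.labels = list(counts.labels)
        self.W_hat, self.se = frequency_covariance(counts, block_size=block_size)
        self.counts = counts

    @classmethod
    def from_covariance(cls, W_hat, se, labels) -> "MigrationGraphModel":
        obj = cls.__new__(cls)
        obj.labels = list(labels)
        obj.W_hat = np.asarray(W_hat, float)
        obj.se = np.asarray(se, float)
        obj.counts = None
        return obj

    # -- fitting ------------------------------------------------------------

    def fit(self, m_events: int = 0, root_label: str | None = None,
            order_seed: int = 0, w_grid=None) -> MigrationGraphResults:
        """Greedy graph fit with ``m_events`` migration edges.

        Starts from an NJ tree built on a random leaf input order, then
        adds edges one at a time, each chosen (over all valid ordered node
        pairs and a weight grid, with a bounded 1-D polish of the best
        weight) to maximally increase the composite log-likelihood; branch
        lengths are refit by non-negative least squares after each step.
        """
        K = len(self.labels)
        if m_events > K * (K - 1) // 2:
            raise ValueError("m_events exceeds the number of ancestry pairs")
        root_label = root_label or self.labels[0]
        rng = child_rng(order_seed, "leaf-order")
        order = list(rng.permutation(K))
        tree = fit_tree(self.W_hat, self.labels, root_label, leaf_order=order)
        migrations: list[tuple[Node, Node, float]] = []
        lengths, branch_nodes, ll = _fit_lengths_ll(
            self.W_hat, self.se, tree, migrations, self.labels
        )
        if w_grid is None:
            w_grid = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
        for _ in range(m_events):
            best = None
            nodes = [n for n in tree.traverse() if n.parent is not None]
            targeted = {id(t) for _, t, _ in migrations}
            for src in nodes:
                src_line = {id(a) for a in src.ancestors()} | {id(src)}
                src_sub = {id(n) for n in src.traverse()}
                for tgt in nodes:
                    if tgt is src or id(tgt) in targeted:
                        continue
                    # no ancestor-descendant pairs (would create a cycle)
                    if id(tgt) in src_line or id(tgt) in src_sub:
                        continue
                    for w in w_grid:
                        cand = migrations + [(src, tgt, float(w))]
                        _, _, cll = _fit_lengths_ll(
                            self.W_hat, self.se, tree, cand, self.labels
                        )
                        if best is None or cll > best[0]:
                            best = (cll, src, tgt, float(w))
            if best is None:
                warnings.warn("no valid migration edge candidates remain")
                break
            _, src, tgt, w0 = best

            def neg_ll(w):
                cand = migrations + [(src, tgt, float(w))]
                return -_fit_lengths_ll(self.W_hat, self.se, tree, cand, self.labels)[2]

            res = optimize.minimize_scalar(
                neg_ll, bounds=(1e-3, 0.999), method="bounded",
                options={"xatol": 1e-3},
            )
            w_star = float(res.x) if -res.fun >= best[0] else w0
            migrations.append((src, tgt, w_star))
            lengths, branch_nodes, new_ll = _fit_lengths_ll(
                self.W_hat, self.se, tree, migrations, self.labels
            )
            if new_ll < ll - 1e-9:
                warnings.warn("migration edge did not improve the composite likelihood")
            ll = new_ll
        for n, l in zip(branch_nodes, lengths):
            n.length = float(l)
        edges = [(_clade(s), _clade(t), w) for s, t, w in migrations]
        return MigrationGraphResults(tree, edges, ll, len(edges), self.labels)

    def fit_range(self, m_max: int = 6, root_label: str | None = None,
                  n_orders: int = 100, seed: int = 0):
        """Best fit over random input orders for each m in 0..m_max.

        Returns (results_by_m, chosen_m) applying the sign-based stopping
        rule to the best composite log-likelihoods.
        """
        results = []
        for m in range(m_max + 1):
            summary = replicate_runs(self, m, root_label=root_label,
                                     n_orders=n_orders, seed=child_seed(seed, f"m{m}"))
            results.append(summary)
        lls = [r["best"].loglik for r in results]
        chosen = stopping_rule(lls)
        return results, chosen


# functional surface ---------------------------------------------------------

def fit_migration_graph(W_hat, se, labels, m_events: int, root_label: str,
                        order_seed: int = 0) -> MigrationGraphResults:
    model = MigrationGraphModel.from_covariance(W_hat, se, labels)
    return model.fit(m_events=m_events, root_label=root_label, order_seed=order_seed)


def stopping_rule(loglik_by_m: list[float], log=None) -> int:
    """Largest m with non-positive log-likelihoods before the first positive.

    Given best composite log-likelihoods for m = 0, 1, 2, ..., returns the
    largest m such that every value at index <= m is <= 0 and the next (if
    present) is > 0.  If no value is positive, the last index is returned
    with a note; if the first value is already positive, 0 is returned with
    a warning.
    """
    if not loglik_by_m:
        raise ValueError("empty log-likelihood list")
    if loglik_by_m[0] > 0:
        warnings.warn("log-likelihood already positive at m=0; rule degenerate")
        return 0
    for m, ll in enumerate(loglik_by_m):
        if ll > 0:
            return m - 1
    if log is not None:
        log("no positive log-likelihood observed; returning the largest m")
    return len(loglik_by_m) - 1


def replicate_runs(model: MigrationGraphModel, m_events: int,
                   root_label: str | None = None, n_orders: int = 100,
                   seed: int = 0) -> dict:
    """Fit with many random leaf input orders; summarize distinct outcomes.

    The outcome key of a run is its (topology bipartitions, migration
    attachment clades) pair; frequencies are reported as percentages and
    the best-likelihood graph is returned.
    """
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    outcomes: dict = {}
    best = None
    for i in range(n_orders):
        res = model.fit(m_events=m_events, root_label=root_label,
                        order_seed=child_seed(seed, f"order-{i}"))
        key = (
            tuple(sorted(map(tuple, res.tree.bipartitions()))),
            tuple(sorted((s, t) for s, t, _ in res.migration_edges)),
        )
        outcomes.setdefault(key, []).append(res)
        if best is None or res.loglik > best.loglik:
            best = res
    return {
        "best": best,
        "outcome_percentages": {
            key: 100.0 * len(v) / n_orders for key, v in outcomes.items()
        },
        "runs": n_orders,
    }


# ---------------------------------------------------------------------------
# Bootstrap consensus
# ---------------------------------------------------------------------------

def bootstrap_trees(counts: AlleleCountTable, root_label: str, n_boot: int = 100,
                    block_size: int = 500, seed: int = 0) -> list[Node]:
    """Trees from marker-block bootstrap replicates of the count table."""
    m = counts.n_markers
    bs = max(1, min(block_size, m // 2))
    starts = np.arange(0, m, bs)
    blocks = [np.arange(s, min(s + bs, m)) for s in starts]
    rng = child_rng(seed, "tree-bootstrap")
    trees = []
    for _ in range(n_boot):
        chosen = rng.integers(len(blocks), size=len(blocks))
        idx = np.concatenate([blocks[c] for c in chosen])
        rep = AlleleCountTable(counts.labels, counts.N, counts.alt[:, idx],
                               counts.ref[:, idx])
        W, _ = frequency_covariance(rep, block_size=block_size)
        trees.append(fit_tree(W, counts.labels, root_label))
    return trees


@dataclass
class ConsensusTree:
    """Strict-majority consensus topology with per-clade support."""

    tree: Node
    support: dict[tuple[str, ...], float]  # clade -> percent in (50, 100]


def consensus_tree(trees: list[Node]) -> ConsensusTree:
    """Majority-rule consensus over rooted trees on one leaf set.

    Clades (leaf sets below internal nodes) appearing in strictly more than
    half of the trees are retained with their percentage support; strict
    majority guarantees pairwise compatibility, and the retained clades are
    nested into a tree.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    leafset = frozenset(trees[0].leaf_names())
    counts: dict[frozenset, int] = {}
    for t in trees:
        if frozenset(t.leaf_names()) != leafset:
            raise ValueError("trees have different leaf sets")
        seen = set()
        for n in t.traverse():
            if n is t or n.is_leaf:
                continue
            clade = frozenset(n.leaf_names())
            if len(clade) < len(leafset):
                seen.add(clade)
        for clade in seen:
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    kept = {c: 100.0 * k / n for c, k in counts.items() if k > n / 2}
    # nest clades, largest first
    root = Node(None, 0.0)
    clade_node = {leafset: root}
    for clade in sorted(kept, key=len, reverse=True):
        parent = min(
            (c for c in clade_node if clade < c), key=len
        )
        clade_node[clade] = clade_node[parent].add_child(Node(None, 0.0))
    for leaf in sorted(leafset):
        parent = min((c for c in clade_node if leaf in c), key=len)
        clade_node[parent].add_child(Node(leaf, 0.0))
    return ConsensusTree(root, {tuple(sorted(c)): v for c, v in kept.items()})
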