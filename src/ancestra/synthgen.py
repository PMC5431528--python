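"""Synthetic genotype data with tree-structured ancestral allele frequencies.

The generator emulates the statistical structure the downstream analysis
assumes: K latent ancestries whose allele-frequency vectors evolve from a
common root along a rooted binary tree by Balding-Nichols drift, individuals
with Dirichlet-distributed admixture proportions grouped into labelled
samples, optional planted migration (frequency-mixing) events, missing
genotypes completely at random, and ancestry-concordant language labels with
optional language-replacement noise.

Balding-Nichols drift: a child frequency on a branch with drift ``c`` is
drawn from Beta(f(1-c)/c, (1-f)(1-c)/c) where ``f`` is the parent frequency,
so E[child] = f and Var[child] = c f(1-f); ``c`` equals the expected F_ST
between child and parent populations.  Frequencies fixed at 0 or 1 propagate
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._tree import Node, parse_newick
from ._util import child_rng
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "TrueModel",
    "SyntheticTruth",
    "simulate_frequency_tree",
    "plant_migration",
    "simulate_admixed_genotypes",
    "simulate_language_labels",
]


@dataclass
class TrueModel:
    """Ground-truth generative model: tree, leaf frequencies, migrations."""

    tree: Node | None
    ancestry_labels: list[str]
    ancestral_freqs: np.ndarray  # K x m, in [0, 1]
    migrations: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.ancestral_freqs.shape[0]

    @property
    def n_markers(self) -> int:
        return self.ancestral_freqs.shape[1]

    def freq(self, label: str) -> np.ndarray:
        return self.ancestral_freqs[self.ancestry_labels.index(label)]

    def write_tree(self, path) -> None:
        if self.tree is None:
            raise ValueError("single-ancestry model has no tree")
        Path(path).write_text(self.tree.to_newick() + "\n", encoding="utf-8")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated genotype matrix."""

    true_Q: np.ndarray  # n x K, rows sum to 1
    sample_map: dict[str, str]  # individual -> sample label
    language_map: dict[str, str] | None
    model: TrueModel
    seed: int

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ids = list(self.sample_map)
        pd.DataFrame(self.true_Q, index=ids, columns=self.model.ancestry_labels).to_csv(
            outdir / "true_Q.tsv", sep="\t"
        )
        with open(outdir / "sample_map.tsv", "w", encoding="utf-8", newline="\n") as fh:
            for k, v in self.sample_map.items():
                fh.write(f"{k}\t{v}\n")
        if self.language_map is not None:
            with open(outdir / "language_map.tsv", "w", encoding="utf-8", newline="\n") as fh:
                for k, v in self.language_map.items():
                    fh.write(f"{k}\t{v}\n")
        if self.model.tree is not None:
            self.model.write_tree(outdir / "tree.nwk")


def _default_tree(K: int, drift: float) -> Node:
    """Balanced-ish rooted binary tree over leaves A1..AK, uniform drift."""
    nodes = [Node(f"A{i + 1}", drift) for i in range(K)]
    nxt = K + 1
    while len(nodes) > 1:
        merged = []
        for i in range(0, len(nodes) - 1, 2):
            parent = Node(None, drift)
            parent.add_child(nodes[i])
            parent.add_child(nodes[i + 1])
            merged.append(parent)
            nxt += 1
        if len(nodes) % 2:
            merged.append(nodes[-1])
        nodes = merged
    root = nodes[0]
    root.length = 0.0
    return root


def _bn_draw(f: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols perturbation of a frequency vector along one branch."""
    if c < 0:
        raise ValueError("negative drift")
    if c == 0:
        return f.copy()
    out = f.copy()
    interior = (f > 0) & (f < 1)  # fixed frequencies propagate unchanged
    fi = f[interior]
    a = fi * (1 - c) / c
    b = (1 - fi) * (1 - c) / c
    out[interior] = rng.beta(a, b)
    return out


def simulate_frequency_tree(
    K: int,
    m: int,
    tree_spec: str | Node | None = None,
    drift: float = 0.05,
    root_freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> TrueModel:
    """Simulate per-ancestry allele frequencies along a drift tree.

    Parameters
    ----------
    K, m : number of ancestries and markers.
    tree_spec : newick string or Node with branch lengths as drift amounts;
        leaf names are the ancestry labels.  ``None`` builds a balanced
        binary tree over ``A1..AK`` with uniform ``drift`` per branch.
    root_freq_range : support of the uniform root-frequency distribution,
        mimicking an ascertained panel of common variants.
    """
    if K < 1 or m < 1:
        raise ValueError("K and m must be >= 1")
    rng = child_rng(seed, "freq-tree")
    lo, hi = root_freq_range
    root_freq = rng.uniform(lo, hi, size=m)
    if K == 1:
        return TrueModel(None, ["A1"], root_freq[None, :].copy())
    if tree_spec is None:
        tree = _default_tree(K, drift)
    elif isinstance(tree_spec, Node):
        tree = tree_spec.copy()
    else:
        tree = parse_newick(tree_spec)
    leaves = tree.leaves()
    if len(leaves) != K:
        raise ValueError(f"tree has {len(leaves)} leaves, expected K={K}")
    if K > 2 and not tree.is_binary():
        raise ValueError("tree_spec must be a rooted binary tree")
    for n in tree.traverse():
        if n.length < 0:
            raise ValueError("negative drift on a branch")
    freqs: dict[int, np.ndarray] = {id(tree): root_freq}
    for node in tree.traverse():
        if node is tree:
            continue
        freqs[id(node)] = _bn_draw(freqs[id(node.parent)], node.length, rng)
    labels = [leaf.name for leaf in leaves]
    F = np.vstack([freqs[id(leaf)] for leaf in leaves])
    return TrueModel(tree, labels, F)


def plant_migration(model: TrueModel, source: str, target: str, w: float) -> TrueModel:
    """Mix a fraction ``w`` of the source ancestry's frequencies into the target.

    The target's frequency vector becomes ``(1-w)*target + w*source`` per
    marker, emulating a single admixture pulse between two lineages.
    """
    if not 0 <= w <= 1:
        raise ValueError("w must lie in [0, 1]")
    if source == target:
        raise ValueError("source and target must differ")
    for label in (source, target):
        if label not in model.ancestry_labels:
            raise KeyError(f"unknown ancestry {label!r}")
    F = model.ancestral_freqs.copy()
    si = model.ancestry_labels.index(source)
    ti = model.ancestry_labels.index(target)
    F[ti] = (1 - w) * F[ti] + w * F[si]
    return TrueModel(
        model.tree,
        list(model.ancestry_labels),
        F,
        model.migrations + [(source, target, w)],
    )


def simulate_admixed_genotypes(
    model: TrueModel,
    samples: list[tuple[str, int, np.ndarray]],
    missing_rate: float = 0.002,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw admixed individuals and their genotypes from the true model.

    ``samples`` lists (label, n individuals, Dirichlet concentration vector
    of length K).  Each individual's admixture row q ~ Dirichlet(alpha); the
    genotype at marker j ~ Binomial(2, sum_k q_k f_kj); entries are then set
    missing independently at ``missing_rate``.
    """
    if not samples:
        raise ValueError("empty sample list")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    K, m = model.K, model.n_markers
    rng = child_rng(seed, "genotypes")
    q_rows, ids, sample_map = [], [], {}
    for label, n, alpha in samples:
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != (K,) or np.any(alpha <= 0):
            raise ValueError(f"sample {label!r}: concentration must be positive length-K")
        q = rng.dirichlet(alpha, size=n)
        for i in range(n):
            iid = f"{label}_{i + 1}"
            ids.append(iid)
            sample_map[iid] = label
        q_rows.append(q)
    Q = np.vstack(q_rows)
    # rounding can push q @ f a hair outside [0, 1]
    P = np.clip(Q @ model.ancestral_freqs, 0.0, 1.0)
    G = rng.binomial(2, P).astype(np.int8)
    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = MISSING
    marker_ids = [f"snp{j + 1}" for j in range(m)]
    gmat = GenotypeMatrix(G, ids, marker_ids)
    truth = SyntheticTruth(Q, sample_map, None, model, seed)
    return gmat, truth


def simulate_language_labels(
    truth: SyntheticTruth,
    family_of_ancestry: dict[str, str] | None = None,
    replacement_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Assign each sample the language family of its majority ancestry.

    With probability ``replacement_rate`` a sample's label is swapped to a
    different family drawn uniformly from the remaining families, emulating
    language replacement.  The resulting map (sample -> family) is also
    stored on ``truth.language_map``.
    """
    labels = truth.model.ancestry_labels
    if family_of_ancestry is None:
        family_of_ancestry = {a: f"fam_{a}" for a in labels}
    samples = sorted(set(truth.sample_map.values()))
    ids = list(truth.sample_map)
    rng = child_rng(seed, "language")
    families = sorted(set(family_of_ancestry.values()))
    lang: dict[str, str] = {}
    for s in samples:
        rows = [i for i, iid in enumerate(ids) if truth.sample_map[iid] == s]
        if not rows:
            raise ValueError(f"sample {s!r} has no individuals")
        mean_q = truth.true_Q[rows].mean(axis=0)
        fam = family_of_ancestry[labels[int(np.argmax(mean_q))]]
        if replacement_rate > 0 and rng.random() < replacement_rate:
            others = [f for f in families if f != fam]
            if others:
                fam = others[rng.integers(len(others))]
        lang[s] = fam
    truth.language_map = lang
    return lang
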