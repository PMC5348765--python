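"""Distance-based phylogenetic grouping.

Poisson-corrected protein distances, Saitou-Nei neighbor joining with a
deterministic lexicographic tie-break, column-resampling bootstrap with
per-bipartition support, monophyly tests on the unrooted bipartition
criterion, and the clustering rule that splits RT-free individual aRNH
loci into reference-linked clades versus novel clades.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .mining import make_protein_aligner

logger = logging.getLogger(__name__)

D_MAX = 10.0  # cap for saturated (p >= 1 - e^-d_max) distances


def protein_distance(a: str, b: str, d_max: float = D_MAX) -> float:
    """Poisson-corrected distance d = -ln(1 - p) between two rows of an
    alignment, with p the mismatch proportion over columns where neither
    sequence is gapped. Saturated pairs are capped at ``d_max``."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    comparable = mismatch = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            mismatch += 1
    if comparable == 0:
        raise ValueError("zero comparable columns")
    p = mismatch / comparable
    if p >= 1.0 - math.exp(-d_max):
        logger.debug("distance saturated (p=%.3f), capped at %.1f", p, d_max)
        return d_max
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_alignment(cls, labels: Sequence[str], rows: Sequence[str],
                       d_max: float = D_MAX) -> "DistanceMatrix":
        """Poisson-corrected distances with pairwise deletion, vectorized;
        agrees with :func:`protein_distance` pair by pair."""
        mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
        mat = mat.reshape(len(rows), -1)
        gap = mat == ord("-")
        comparable = (~gap[:, None, :] & ~gap[None, :, :])
        n_comp = comparable.sum(axis=2)
        if np.any(n_comp[~np.eye(len(rows), dtype=bool)] == 0):
            raise ValueError("zero comparable columns")
        mismatch = ((mat[:, None, :] != mat[None, :, :]) & comparable).sum(axis=2)
        p = mismatch / np.maximum(n_comp, 1)
        saturated = p >= 1.0 - math.exp(-d_max)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(saturated, d_max, -np.log(np.clip(1.0 - p, 1e-300, 1.0)))
        np.fill_diagonal(values, 0.0)
        return cls(list(labels), values)


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaf_names()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted tree represented with a trifurcating root."""

    root: TreeNode

    def leaves(self) -> frozenset[str]:
        return self.root.leaf_names()

    def edges(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """(child node, leaf set below it) for every edge."""
        out = []

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                out.append((child, child.leaf_names()))
                walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Nontrivial bipartitions, keyed by the canonical side (the side
        not containing the lexicographically first leaf)."""
        all_leaves = self.leaves()
        ref = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}
        for node, side in self.edges():
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            canon = side if ref not in side else all_leaves - side
            out[canon] = node
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode, length: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.6g}"

        return fmt(self.root, None) + ";"


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Deterministic: candidate pairs with equal Q are resolved by the
    lexicographically smallest (label, label) pair, where an internal
    node inherits the smallest leaf label of its cluster. Negative branch
    length estimates are clamped to zero (logged at debug level).
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    order = sorted(range(n), key=lambda i: matrix.labels[i])
    keys = [matrix.labels[i] for i in order]
    nodes = [TreeNode(name=matrix.labels[i]) for i in order]
    D = matrix.values[np.ix_(order, order)].copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - (r[:, None] + r[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ii, jj = np.where(Q == qmin)
        best = None
        for a, b in zip(ii, jj):
            i, j = (int(a), int(b)) if a < b else (int(b), int(a))
            cand = (tuple(sorted((keys[i], keys[j]))), i, j)
            if best is None or cand < best:
                best = cand
        _, i, j = best
        li = clamp(D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(D[i, j] - D[i, j] / 2 - (r[i] - r[j]) / (2 * (m - 2)))
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_row = np.array([
            max(0.0, (D[i, k] + D[j, k] - D[i, j]) / 2)
            for k in range(m) if k not in (i, j)
        ])
        keep = [k for k in range(m) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.vstack([np.hstack([D, new_row[:, None]]),
                       np.hstack([new_row, [0.0]])])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = clamp((dab + dac - dbc) / 2)
    lb = clamp((dab + dbc - dac) / 2)
    lc = clamp((dac + dbc - dab) / 2)
    return PhyloTree(TreeNode(children=[(a, la), (b, lb), (c, lc)]))


def bootstrap_support(
    labels: Sequence[str],
    rows: Sequence[str],
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    d_max: float = D_MAX,
) -> PhyloTree:
    """NJ tree from a multiple alignment with column-resampling bootstrap.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each original bipartition is the percentage of replicate trees that
    contain it. With ``n_reps=0`` supports are left absent.
    """
    if len(labels) < 3:
        raise ValueError("bootstrap needs >= 3 rows")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    tree = nj_tree(DistanceMatrix.from_alignment(labels, rows))
    if n_reps <= 0:
        return tree
    bips = tree.bipartitions()
    counts = {b: 0 for b in bips}
    mat = np.array([list(r) for r in rows])
    length = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = ["".join(row) for row in mat[:, cols]]
        try:
            rep_tree = nj_tree(DistanceMatrix.from_alignment(labels, resampled, d_max))
        except ValueError:  # a pair with zero comparable columns
            continue
        rep_bips = set(rep_tree.bipartitions())
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
    for b, node in bips.items():
        node.support = 100.0 * counts[b] / n_reps
    return tree


def is_monophyletic(tree: PhyloTree, taxa: Iterable[str]) -> bool:
    """True iff some edge bipartition splits exactly ``taxa`` from the rest
    (unrooted criterion). Singletons and the full leaf set are trivially
    monophyletic."""
    subset = frozenset(taxa)
    leaves = tree.leaves()
    if not subset:
        raise ValueError("empty taxa subset")
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown leaf label(s): {sorted(unknown)}")
    if len(subset) == 1 or subset == leaves:
        return True
    for _, side in tree.edges():
        if side == subset or leaves - side == subset:
            return True
    return False


# ---------------------------------------------------------------------------
# Multiple alignment (center-star) and individual-aRNH clustering
# ---------------------------------------------------------------------------


def center_star_msa(sequences: Mapping[str, str]) -> tuple[list[str], list[str]]:
    """Deterministic center-star multiple alignment.

    The center is the sequence with the highest total pairwise alignment
    score (ties to the lexicographically first label); every other sequence
    is aligned to the center globally and the pairwise gaps are merged on
    center coordinates. Adequate for the substitution-dominated families
    this package simulates; not a general-purpose aligner.
    """
    labels = sorted(sequences)
    if len(labels) == 1:
        return labels, [sequences[labels[0]]]
    aligner = make_protein_aligner("global")
    totals = {lab: 0.0 for lab in labels}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            s = aligner.score(sequences[la], sequences[lb])
            totals[la] += s
            totals[lb] += s
    center = max(labels, key=lambda l: (totals[l], l))
    center_seq = sequences[center]
    L = len(center_seq)
    aligned_at: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    max_ins = [0] * (L + 1)
    for lab in labels:
        if lab == center:
            continue
        al = aligner.align(center_seq, sequences[lab])[0]
        gc, go = al[0], al[1]
        at = ["-"] * L
        ins = [""] * (L + 1)
        ci = 0
        for x, y in zip(gc, go):
            if x == "-":
                ins[ci] += y
            else:
                at[ci] = y
                ci += 1
        aligned_at[lab] = at
        inserts[lab] = ins
        for slot in range(L + 1):
            max_ins[slot] = max(max_ins[slot], len(ins[slot]))
    rows = []
    for lab in labels:
        parts = []
        if lab == center:
            for slot in range(L):
                parts.append("-" * max_ins[slot])
                parts.append(center_seq[slot])
            parts.append("-" * max_ins[L])
        else:
            at, ins = aligned_at[lab], inserts[lab]
            for slot in range(L):
                parts.append(ins[slot].ljust(max_ins[slot], "-"))
                parts.append(at[slot])
            parts.append(ins[L].ljust(max_ins[L], "-"))
        rows.append("".join(parts))
    return labels, rows


def cluster_individual_arnh(
    individuals: Mapping[str, str],
    references: Mapping[str, str | Sequence[str]],
    support_threshold: float = 60.0,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[str, str]:
    """Clade labels for RT-free individual aRNH proteins.

    All individuals are placed on an NJ tree together with the per-group
    retrotransposon aRNH references. Each individual takes the group of the
    smallest well-supported clade (bootstrap >= ``support_threshold``) that
    joins it with references of a single group — the "remnant of group X"
    call. Individuals without such a clade found a novel clade label
    (novel-1, novel-2, ...): unassigned individuals are pooled when they
    are mutually closer than either is to any reference.
    """
    if len(individuals) < 1:
        raise ValueError("need at least one individual sequence")
    ref_seqs: dict[str, str] = {}
    ref_group: dict[str, str] = {}
    for group, seqs in references.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        for i, s in enumerate(seqs):
            lab = f"ref|{group}|{i}"
            ref_seqs[lab] = s
            ref_group[lab] = group
    pool = {**dict(individuals), **ref_seqs}
    labels, rows = center_star_msa(pool)
    dm = DistanceMatrix.from_alignment(labels, rows)
    index = {lab: i for i, lab in enumerate(labels)}
    tree = bootstrap_support(labels, rows, n_reps=n_reps, seed=seed)
    bips = tree.bipartitions()
    leaves = tree.leaves()

    def edge_sides_containing(leaf: str):
        sides = []
        for canon, node in bips.items():
            side = canon if leaf in canon else leaves - canon
            sides.append((len(side), sorted(side)[0], side, node))
        sides.sort(key=lambda t: (t[0], t[1]))
        return sides

    def nearest_reference_distance(lab: str) -> float:
        i = index[lab]
        return min(dm.values[i, index[r]] for r in ref_seqs)

    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    for lab in sorted(individuals):
        call = None
        # the smallest well-supported clade around the individual that
        # carries references is decisive: one group -> remnant of that
        # group; several groups -> no significant clustering (novel)
        for _, _, side, node in edge_sides_containing(lab):
            support = node.support if node.support is not None else 100.0
            if support < support_threshold:
                continue
            groups = {ref_group[m] for m in side if m in ref_group}
            if not groups:
                continue
            if len(groups) == 1:
                call = next(iter(groups))
            break
        if call is None:
            unassigned.append(lab)
        else:
            assignments[lab] = call

    # pool novel individuals that are closer to each other than to any ref
    parent = {lab: lab for lab in unassigned}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, la in enumerate(unassigned):
        for lb in unassigned[i + 1:]:
            d = dm.values[index[la], index[lb]]
            if d < min(nearest_reference_distance(la), nearest_reference_distance(lb)):
                parent[find(la)] = find(lb)
    clusters: dict[str, list[str]] = {}
    for lab in unassigned:
        clusters.setdefault(find(lab), []).append(lab)
    for k, root in enumerate(sorted(clusters, key=lambda r: min(clusters[r])), start=1):
        for lab in clusters[root]:
            assignments[lab] = f"novel-{k}"
    return assignments
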