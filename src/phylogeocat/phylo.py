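"""Distance-based phylogenetics: Jukes-Cantor distances, neighbor-joining
trees, site-resampling bootstrap supports and reciprocal-monophyly checks.

Trees are handled as dendropy objects; Newick is the exchange format, with
bootstrap percentages stored as internal node labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import MissingPolicy, SequenceAlignment, used_columns
from .structure import DistanceMatrix


class SaturationError(ValueError):
    """A pairwise p-distance reached the Jukes-Cantor domain bound 3/4."""


class InsufficientTaxaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Distances


def p_distance_matrix(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> np.ndarray:
    mask = used_columns(aln, missing_policy)
    arr = aln.to_array()[:, mask]
    L = arr.shape[1]
    n = aln.n
    p = np.zeros((n, n))
    for i in range(n):
        d = (arr[i] != arr[i + 1 :]).sum(axis=1) / L
        p[i, i + 1 :] = d
        p[i + 1 :, i] = d
    return p


def jukes_cantor_matrix(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> DistanceMatrix:
    """Jukes-Cantor distance d = -(3/4)·ln(1 - 4p/3).

    Raises :class:`SaturationError` naming the first offending pair when
    any p-distance is >= 0.75.
    """
    p = p_distance_matrix(aln, missing_policy)
    if (p >= 0.75).any():
        i, j = np.argwhere(p >= 0.75)[0]
        raise SaturationError(
            f"p-distance {p[i, j]:.3f} >= 0.75 between "
            f"{aln.ids[i]!r} and {aln.ids[j]!r}; Jukes-Cantor undefined"
        )
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(aln.ids), values=d, units="substitutions/site")


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted (or outgroup-rooted) tree with optional supports."""

    tree: dendropy.Tree
    clamped_branches: int = 0

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_names(self) -> set[str]:
        return {l.taxon.label for l in self.tree.leaf_node_iter()}


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Saitou & Nei neighbor joining with the standard Q-criterion.

    Ties in Q minimisation break deterministically toward the pair whose
    (label, label) tuple sorts first. Negative branch lengths are clamped
    to zero with the deficit moved onto the sibling branch (flagged via
    ``clamped_branches``).
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise InsufficientTaxaError("NJ requires >= 3 taxa")
    d = dist.values.astype(float).copy()
    # node -> newick fragment
    frag = {i: labels[i] for i in range(len(labels))}
    active = list(range(len(labels)))
    key = {i: labels[i] for i in range(len(labels))}
    clamped = 0

    def pair_lengths(vi: float, vj: float) -> tuple[float, float, int]:
        nonlocal clamped
        c = 0
        if vi < 0:
            vj += vi  # move deficit to the adjacent branch
            vi = 0.0
            c += 1
        if vj < 0:
            vi += vj
            vj = 0.0
            c += 1
        return max(vi, 0.0), max(vj, 0.0), c

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                q = (r - 2) * sub[a, b] - R[a] - R[b]
                tie = tuple(sorted((key[active[a]], key[active[b]])))
                cand = (q, tie, a, b)
                if best is None or cand < best:
                    best = cand
        _, _, a, b = best
        i, j = active[a], active[b]
        vi = 0.5 * sub[a, b] + (R[a] - R[b]) / (2.0 * (r - 2))
        vj = sub[a, b] - vi
        vi, vj, c = pair_lengths(vi, vj)
        clamped += c
        # new node distances
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for c_idx in active:
            if c_idx in (i, j):
                continue
            d[new, c_idx] = d[c_idx, new] = 0.5 * (d[i, c_idx] + d[j, c_idx] - d[i, j])
        frag[new] = f"({frag[i]}:{vi:.10f},{frag[j]}:{vj:.10f})"
        key[new] = min(key[i], key[j])
        active = [x for x in active if x not in (i, j)] + [new]

    # final three-point formulas
    x, y, z = active
    vx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    vy = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    vz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    lens = []
    for v in (vx, vy, vz):
        if v < 0:
            clamped += 1
            v = 0.0
        lens.append(v)
    newick = (
        f"({frag[x]}:{lens[0]:.10f},{frag[y]}:{lens[1]:.10f},{frag[z]}:{lens[2]:.10f});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return PhyloTree(tree=tree, clamped_branches=clamped)


# ---------------------------------------------------------------------------
# Bootstrap


def _bipartitions(tree: dendropy.Tree, all_taxa: frozenset[str]) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as canonical frozensets."""
    out: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(leaves) < len(all_taxa) - 1:
            other = frozenset(all_taxa - leaves)
            out.add(min(leaves, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(
    aln: SequenceAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    missing_policy: MissingPolicy = "complete-deletion",
) -> tuple[PhyloTree, int]:
    """Site-resampling bootstrap on the NJ tree.

    Returns the point-estimate tree with percent support written on
    internal nodes, plus the count of replicates skipped because a
    resample hit Jukes-Cantor saturation.
    """
    point = nj_tree(jukes_cantor_matrix(aln, missing_policy))
    all_taxa = frozenset(aln.ids)
    target = _bipartitions(point.tree, all_taxa)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    mask = used_columns(aln, missing_policy)
    cols = np.flatnonzero(mask)
    arr = aln.to_array()
    skipped = 0
    used = 0
    for _ in range(n_reps):
        pick = rng.choice(cols, size=len(cols), replace=True)
        rep_arr = arr[:, pick]
        rep = SequenceAlignment(
            tuple((sid, "".join(row)) for sid, row in zip(aln.ids, rep_arr))
        )
        try:
            rep_tree = nj_tree(jukes_cantor_matrix(rep, "strict"))
        except SaturationError:
            skipped += 1
            continue
        used += 1
        rep_bps = _bipartitions(rep_tree.tree, all_taxa)
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    for node in point.tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(leaves) < len(all_taxa) - 1:
            other = frozenset(all_taxa - leaves)
            bp = min(leaves, other, key=lambda s: (len(s), sorted(s)))
            node.label = f"{100.0 * hits[bp] / max(used, 1):.0f}"
    return PhyloTree(tree=point.tree, clamped_branches=point.clamped_branches), skipped


def support_values(tree: PhyloTree) -> dict[frozenset, float]:
    """Map canonical bipartition -> percent support from node labels."""
    all_taxa = frozenset(l.taxon.label for l in tree.tree.leaf_node_iter())
    out = {}
    for node in tree.tree.preorder_internal_node_iter():
        if node.label is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(leaves) < len(all_taxa) - 1:
            other = frozenset(all_taxa - leaves)
            bp = min(leaves, other, key=lambda s: (len(s), sorted(s)))
            out[bp] = float(node.label)
    return out


# ---------------------------------------------------------------------------
# Monophyly


def is_reciprocally_monophyletic(
    tree: PhyloTree, partition: list[set[str]], outgroup: str
) -> bool:
    """True iff every set of the ingroup partition is a clade on the
    outgroup-rooted tree."""
    names = tree.leaf_names()
    if outgroup not in names:
        raise KeyError(f"outgroup {outgroup!r} not among leaves")
    t = tree.tree.clone(depth=1)
    og = t.find_node_with_taxon_label(outgroup)
    t.to_outgroup_position(og, update_bipartitions=False)
    t.is_rooted = True
    for group in partition:
        taxa = [t.taxon_namespace.get_taxon(name) for name in sorted(group)]
        if any(x is None for x in taxa):
            raise KeyError(f"labels missing from tree: {sorted(group)}")
        mrca = t.mrca(taxa=taxa)
        clade = {l.taxon.label for l in mrca.leaf_iter()}
        if clade != set(group):
            return False
    return True
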