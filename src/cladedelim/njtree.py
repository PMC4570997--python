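"""Neighbor-joining trees from K2P distances, bootstrap supports, monophyly
checks, and a simplified strict-clock node-age estimator.

NJ follows the standard Q-criterion agglomeration with the Studier–Keppler
distance update; ties on Q are broken by merging the pair whose subtrees
contain the lexicographically smallest tip labels, which makes the output
deterministic. Negative branch lengths are retained internally (preserving
additivity) and floored at zero only for display.

The age estimator is deliberately simple: it linearizes mean between-group
K2P distances against a single calibration split under a strict molecular
clock. It is a transparent first-order tool, not a replacement for relaxed-
clock Bayesian dating, and the two can differ substantially when rates vary
among lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix, distance_matrix
from .seqio import Alignment
from .delimit import Partition


class _NjNode:
    __slots__ = ("children", "rep", "newick")

    def __init__(self, rep: str, newick: str):
        self.rep = rep  # lexicographically smallest tip label in subtree
        self.newick = newick


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def nj_newick(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string (unrooted; trifurcating root)."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 labels for NJ")
    if np.isnan(dm.d).any():
        raise ValueError(f"undefined distances for pairs: {dm.undefined_pairs[:5]}")
    D = dm.d.astype(float).copy()
    nodes = [_NjNode(lab, lab) for lab in dm.labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # deterministic tie-break: smallest (rep_i, rep_j) pair among minima
        cands = np.argwhere(Q <= qmin + 1e-15)
        best = None
        for a, b in cands:
            if a >= b:
                continue
            key = tuple(sorted((nodes[active[a]].rep, nodes[active[b]].rep)))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        vi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        vj = dij - vi
        ni, nj_ = nodes[i], nodes[j]
        first, second = ((ni, vi), (nj_, vj))
        if nj_.rep < ni.rep:
            first, second = second, first
        new = _NjNode(
            min(ni.rep, nj_.rep),
            f"({first[0].newick}:{_fmt(first[1])},{second[0].newick}:{_fmt(second[1])})",
        )
        # Studier–Keppler update: distances from the new node
        knew = len(nodes)
        newrow = np.zeros(knew + 1)
        for c in active:
            if c in (i, j):
                continue
            newrow[c] = 0.5 * (D[i, c] + D[j, c] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[knew, : knew] = newrow[:knew]
        D[:knew, knew] = newrow[:knew]
        nodes.append(new)
        active = [c for c in active if c not in (i, j)] + [knew]
    # resolve the final three nodes around a central trifurcation
    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    trio = sorted(zip((nodes[a], nodes[b], nodes[c]), (va, vb, vc)), key=lambda t: t[0].rep)
    inner = ",".join(f"{nd.newick}:{_fmt(v)}" for nd, v in trio)
    return f"({inner});"


def nj(dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Neighbor-joining tree as a dendropy Tree (unrooted)."""
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree.get(
        data=nj_newick(dm),
        schema="newick",
        taxon_namespace=taxon_namespace,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return tree


def display_newick(tree: dendropy.Tree, floor_negative: bool = True) -> str:
    """Newick for display: negative branch lengths floored at zero."""
    t = tree.clone(depth=1)
    if floor_negative:
        for e in t.edges():
            if e.length is not None and e.length < 0:
                e.length = 0.0
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def _canon(mask: int, full: int) -> int:
    """Orientation-free bipartition key: the lesser of a side and its complement."""
    mask &= full
    return min(mask, (~mask) & full)


def _nontrivial_bitmasks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    full = tree.taxon_namespace.all_taxa_bitmask()
    out = set()
    for b in tree.bipartition_encoding:
        if b.is_trivial():
            continue
        out.add(_canon(int(b.leafset_bitmask), full))
    return out


def bootstrap(
    alignment: Alignment, replicates: int = 500, seed: int | None = None
) -> tuple[dendropy.Tree, int]:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement per replicate from one seeded
    stream (replicate r consumes the r-th block of draws, so results do not
    depend on execution order). A replicate whose resampled matrix contains
    an undefined distance is skipped. Supports (percent of kept replicates
    containing each internal bipartition) are written to internal node
    labels of the full-data NJ tree. Returns ``(tree, replicates_used)``.
    """
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    base_dm = distance_matrix(alignment)
    base = nj(base_dm, ns)
    L = alignment.length
    enc = alignment.encoded()
    counts: dict[int, int] = {}
    used = 0
    draws = rng.integers(0, L, size=(replicates, L))
    for r in range(replicates):
        cols = draws[r]
        rep_aln = _ResampledAlignment(enc[:, cols], alignment.ids)
        dm = distance_matrix(rep_aln)
        if np.isnan(dm.d).any():
            continue
        used += 1
        for bm in _nontrivial_bitmasks(nj(dm, ns)):
            counts[bm] = counts.get(bm, 0) + 1
    base.encode_bipartitions()
    full = ns.all_taxa_bitmask()
    for edge in base.preorder_edge_iter():
        b = edge.bipartition
        if b is None or b.is_trivial():
            continue
        node = edge.head_node
        if node.is_leaf():
            continue
        pct = 100.0 * counts.get(_canon(int(b.leafset_bitmask), full), 0) / max(used, 1)
        node.label = f"{pct:.0f}"
    return base, used


class _ResampledAlignment:
    """Duck-typed alignment over a pre-encoded matrix (bootstrap internals)."""

    def __init__(self, enc: np.ndarray, ids: list[str]):
        self._enc = enc
        self.ids = ids

    def __len__(self) -> int:
        return self._enc.shape[0]

    def encoded(self) -> np.ndarray:
        return self._enc


def check_monophyly(tree: dendropy.Tree, tips: set[str], outgroup: set[str]) -> bool:
    """True iff ``tips`` forms exactly one clade after rooting on ``outgroup``."""
    t = tree.clone(depth=1)
    t.is_rooted = True  # rooting on the outgroup is the point of the check
    names = {lf.taxon.label for lf in t.leaf_node_iter()}
    if not set(tips) <= names:
        raise ValueError(f"tips not in tree: {sorted(set(tips) - names)}")
    if not set(outgroup) <= names:
        raise ValueError(f"outgroup not in tree: {sorted(set(outgroup) - names)}")
    og_mrca = t.mrca(taxon_labels=sorted(outgroup))
    if og_mrca is t.seed_node:
        og_mrca = t.mrca(taxon_labels=sorted(names - set(outgroup)))
    t.reroot_at_edge(og_mrca.edge, update_bipartitions=False)
    mrca = t.mrca(taxon_labels=sorted(tips))
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == set(tips)


@dataclass
class CalibratedAges:
    """Strict-clock split ages (million years) linearized on one calibration."""

    rate: float  # substitutions/site/MY along a single lineage
    calibration_age: float
    pair_ages: dict[tuple[str, str], float]  # (group_a, group_b) sorted -> age

    def age(self, group_a: str, group_b: str) -> float:
        return self.pair_ages[tuple(sorted((group_a, group_b)))]


def _mean_between(dm: DistanceMatrix, ids_a: list[str], ids_b: list[str]) -> float:
    ia = [dm.labels.index(x) for x in ids_a]
    ib = [dm.labels.index(x) for x in ids_b]
    vals = dm.d[np.ix_(ia, ib)]
    return float(np.nanmean(vals))


def calibrated_ages(
    dm: DistanceMatrix,
    groups: Partition,
    calibration_split: tuple[set[str], set[str]],
    calibration_age: float,
) -> CalibratedAges:
    """Date every between-group split by linear scaling against a calibration.

    The per-lineage rate is r = D_cal / (2 T_cal), with D_cal the mean
    between-side K2P distance of the calibration split; any other split is
    aged as mean-between-distance / (2 r). Scale-invariant in the distances.
    """
    side_a, side_b = (set(calibration_split[0]), set(calibration_split[1]))
    if side_a & side_b:
        raise ValueError("calibration sides must be disjoint")
    members = groups.groups()
    for g in side_a | side_b:
        if g not in members:
            raise ValueError(f"unknown group in calibration split: {g}")
    ids_a = [i for g in sorted(side_a) for i in members[g]]
    ids_b = [i for g in sorted(side_b) for i in members[g]]
    d_cal = _mean_between(dm, ids_a, ids_b)
    if not d_cal > 0:
        raise ValueError("calibration split has zero mean distance")
    rate = d_cal / (2.0 * calibration_age)
    ages: dict[tuple[str, str], float] = {}
    gl = sorted(members)
    for i, ga in enumerate(gl):
        for gb in gl[i + 1 :]:
            d = _mean_between(dm, members[ga], members[gb])
            ages[(ga, gb)] = d / (2.0 * rate)
    return CalibratedAges(rate, calibration_age, ages)
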