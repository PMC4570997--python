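"""OTU delimitation: refined single linkage (RESL-style) and barcode-gap
partitioning (ABGD-style), plus multi-method concordance.

Two delimitation routes are implemented over a precomputed K2P distance
matrix:

* ``resl`` — three phases: single-linkage clustering at a fixed threshold
  (2.2% by default), Markov clustering (MCL) within each coarse cluster to
  test finer structure at several inflation values, and selection among the
  candidate partitions by mean silhouette width.
* ``abgd_partition`` — for each prior maximal intraspecific distance P,
  locate the barcode gap in the sorted pairwise distances (first position
  above P where the jump exceeds X times the local mean slope), split at
  the gap, and optionally recurse within the resulting groups.

Both are also exposed as scikit-learn-compatible clusterers
(:class:`ReslClusterer`, :class:`AbgdPartitioner`) that ``fit`` precomputed
distance matrices and expose ``labels_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score

from .distances import DistanceMatrix

#: Default prior maximal intraspecific distances swept by the ABGD route
#: (the standard geometric grid between Pmin=0.001 and Pmax=0.1).
DEFAULT_P_SWEEP = (0.001, 0.0017, 0.0028, 0.0077, 0.0129, 0.0215, 0.0359, 0.1)


@dataclass
class Partition:
    """Assignment of every sequence to exactly one OTU."""

    assignment: dict[str, str]
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not v for v in self.assignment.values()):
            raise ValueError("OTU labels must be non-empty")

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, ids) -> np.ndarray:
        """Integer labels in the order of ``ids`` (for ARI etc.)."""
        uniq = {g: i for i, g in enumerate(dict.fromkeys(self.assignment[i] for i in ids))}
        return np.array([uniq[self.assignment[i]] for i in ids])

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, g in self.assignment.items():
            out.setdefault(g, []).append(sid)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\totu\n")
            for sid in self.assignment:
                fh.write(f"{sid}\t{self.assignment[sid]}\n")


def _partition_from_components(labels, comp, method, params) -> Partition:
    """Deterministic OTU names: components ordered by their smallest member id."""
    members: dict[int, list[str]] = {}
    for lab, c in zip(labels, comp):
        members.setdefault(int(c), []).append(lab)
    order = sorted(members.values(), key=lambda ms: min(ms))
    width = max(2, len(str(len(order))))
    assignment = {}
    for k, ms in enumerate(order, start=1):
        name = f"OTU_{k:0{width}d}"
        for m in ms:
            assignment[m] = name
    return Partition(assignment, method, params)


@dataclass
class ReslConfig:
    """Parameters of the three-phase refined-single-linkage clusterer."""

    linkage_threshold: float = 0.022
    inflation_values: tuple[float, ...] = (1.4, 2.0, 2.8, 4.0)
    similarity_scale: float = 0.03
    max_mcl_iterations: int = 200
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 < self.linkage_threshold < 1:
            raise ValueError("linkage_threshold must be in (0, 1)")
        if any(i <= 1 for i in self.inflation_values):
            raise ValueError("inflation values must be > 1")


@dataclass
class AbgdConfig:
    """Parameters of the barcode-gap partitioner."""

    Pmin: float = 0.001
    Pmax: float = 0.1
    X: float = 1.5
    metric: str = "K2P"  # K2P | JC (which distance matrix was supplied)
    steps: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.Pmin < self.Pmax < 1:
            raise ValueError("need 0 < Pmin < Pmax < 1")
        if self.X <= 0:
            raise ValueError("X must be > 0")

    def sweep(self) -> list[float]:
        grid = [p for p in DEFAULT_P_SWEEP if self.Pmin <= p <= self.Pmax]
        for endpoint in (self.Pmin, self.Pmax):
            if endpoint not in grid:
                grid.append(endpoint)
        return sorted(grid)


# ---------------------------------------------------------------------------
# phase 1: single linkage


def single_linkage(dm: DistanceMatrix, threshold: float) -> Partition:
    """Connected components of the graph linking pairs with d < threshold.

    The inequality is strict; undefined (NaN) distances never create links.
    """
    d = dm.d
    adj = (d < threshold) & ~np.isnan(d)
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    return _partition_from_components(dm.labels, comp, "single_linkage", {"threshold": threshold})


# ---------------------------------------------------------------------------
# phase 2: Markov clustering within coarse clusters


def _mcl(sim: np.ndarray, inflation: float, max_iter: int, tol: float) -> np.ndarray:
    """Run MCL on a similarity matrix; returns component labels.

    Expansion is matrix squaring; inflation is entrywise power followed by
    column renormalization; iteration stops at flow convergence. Clusters
    are read from the converged flow in the standard way: attractors are
    nodes with positive diagonal flow; each attractor claims the support of
    its row; clusters sharing an attractor merge; a node claimed by several
    clusters (a perfectly balanced bridge) goes to the first.
    """
    M = sim.astype(float).copy()
    colsum = M.sum(axis=0)
    colsum[colsum == 0] = 1.0
    M /= colsum
    for _ in range(max_iter):
        M2 = M @ M
        M2 = np.power(M2, inflation)
        M2[M2 < 1e-12] = 0.0
        colsum = M2.sum(axis=0)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.abs(M2 - M).max() < tol:
            M = M2
            break
        M = M2
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > 1e-6]
    if not attractors:  # non-convergent flow: keep the component whole
        return np.zeros(n, dtype=int)
    # merge attractor rows that share an attractor
    clusters: list[set[int]] = []
    for a in attractors:
        support = set(np.nonzero(M[a] > 1e-8)[0]) | {a}
        merged = False
        for cl in clusters:
            if cl & support & set(attractors):
                cl |= support
                merged = True
                break
        if not merged:
            clusters.append(support)
    comp = np.full(n, -1, dtype=int)
    for ci, cl in enumerate(clusters):
        for node in sorted(cl):
            if comp[node] == -1:
                comp[node] = ci
    # orphans (no attractor claimed them): attach to their strongest column
    for i in range(n):
        if comp[i] == -1:
            comp[i] = comp[int(np.argmax(M[:, i]))]
    return comp


def _similarity(dsub: np.ndarray, scale: float) -> np.ndarray:
    """Distance -> similarity transform used inside MCL.

    s_ij = max(0, 1 - d_ij/scale); NaN distances get zero similarity;
    self-loops set to each column's maximum off-diagonal similarity (or 1).
    """
    with np.errstate(invalid="ignore"):
        s = np.maximum(0.0, 1.0 - dsub / scale)
    s[np.isnan(dsub)] = 0.0
    np.fill_diagonal(s, 0.0)
    loop = s.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(s, loop)
    return s


def mcl_refine(
    dm: DistanceMatrix, coarse: Partition, config: ReslConfig | None = None
) -> list[Partition]:
    """Candidate refinements of a coarse partition by MCL at each inflation.

    Every candidate refines ``coarse``: MCL runs inside each coarse cluster
    only, so clusters are never merged across coarse boundaries. The
    unrefined coarse partition is always included as the first candidate.
    """
    config = config or ReslConfig()
    candidates = [Partition(dict(coarse.assignment), "resl_coarse", {"inflation": None})]
    index = {lab: i for i, lab in enumerate(dm.labels)}
    for inflation in config.inflation_values:
        assignment: dict[str, str] = {}
        for gname, members in coarse.groups().items():
            if len(members) == 1:
                assignment[members[0]] = f"{gname}"
                continue
            gi = [index[m] for m in members]
            sim = _similarity(dm.d[np.ix_(gi, gi)], config.similarity_scale)
            comp = _mcl(sim, inflation, config.max_mcl_iterations, config.tolerance)
            for m, c in zip(members, comp):
                assignment[m] = f"{gname}.{c}"
        # renumber deterministically
        comp_ids = {g: i for i, g in enumerate(dict.fromkeys(assignment.values()))}
        part = _partition_from_components(
            list(assignment), [comp_ids[assignment[m]] for m in assignment],
            "resl_mcl", {"inflation": inflation},
        )
        candidates.append(part)
    return candidates


# ---------------------------------------------------------------------------
# phase 3: silhouette selection


def silhouette_widths(dm: DistanceMatrix, partition: Partition) -> np.ndarray:
    """Per-sequence silhouette width s(i) on the (unsquared) distances.

    a(i) = mean distance to own OTU, b(i) = smallest mean distance to
    another OTU; s(i) = (b-a)/max(a,b). Members of singleton OTUs score 0,
    and a single-OTU partition scores 0 everywhere.
    """
    labels = partition.labels_for(dm.labels)
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) == 1:
        return np.zeros(n)
    d = np.where(np.isnan(dm.d), np.nanmax(dm.d[~np.isnan(dm.d)], initial=1.0), dm.d)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            continue
        a = d[i, own & (np.arange(n) != i)].mean()
        b = min(d[i, labels == g].mean() for g in uniq if g != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def silhouette_select(candidates: list[Partition], dm: DistanceMatrix) -> Partition:
    """Pick the candidate partition with the highest mean silhouette width.

    Ties keep the earliest candidate (so the coarse partition wins ties
    against its refinements).
    """
    if not candidates:
        raise ValueError("no candidate partitions")
    best, best_score = candidates[0], -np.inf
    for cand in candidates:
        score = float(silhouette_widths(dm, cand).mean())
        if score > best_score + 1e-12:
            best, best_score = cand, score
    return best


def resl(dm: DistanceMatrix, config: ReslConfig | None = None) -> Partition:
    """Three-phase refined single linkage: linkage -> MCL -> silhouette."""
    config = config or ReslConfig()
    coarse = single_linkage(dm, config.linkage_threshold)
    candidates = mcl_refine(dm, coarse, config)
    chosen = silhouette_select(candidates, dm)
    return Partition(dict(chosen.assignment), "resl", {"config": config, "phase": chosen.method})


# ---------------------------------------------------------------------------
# ABGD-style barcode-gap partitioning


def _find_gap(sorted_d: np.ndarray, prior_p: float, X: float) -> float | None:
    """Locate the barcode gap in sorted pairwise distances.

    Scans jumps whose upper shoulder lies above prior_p (the prior maximal
    intraspecific distance); the gap is the first jump d[k+1] - d[k]
    exceeding X times the largest spacing expected from the local spacing
    rate. The local rate is the mean of the nonzero successive differences
    over the preceding window (10% of the pair count, at least 5 pairs;
    tied ranks carry no slope information), and the expected extreme of m
    such spacings is rate * (ln m + 0.5772) — without this extreme-value
    yardstick every noisy dataset contains a "gap", since the maximum of m
    exponential spacings routinely exceeds the mean severalfold. Returns
    the split distance (midpoint of the jump) or None when no significant
    gap exists.
    """
    n = len(sorted_d)
    if n < 3 or len(np.unique(sorted_d)) < 3:
        return None
    window = max(5, int(0.1 * n))
    diffs = np.diff(sorted_d)
    for k in range(len(diffs)):
        if sorted_d[k + 1] <= prior_p or diffs[k] <= 0:
            continue
        local = diffs[max(0, k - window) : k]
        local = local[local > 0]
        if len(local) < 5:  # widen to all preceding spacings if the window is tie-heavy
            local = diffs[:k]
            local = local[local > 0]
        if len(local) == 0:
            # a jump off a pure tie plateau separates two discrete modes
            if k >= 2:
                return float((sorted_d[k] + sorted_d[k + 1]) / 2)
            continue
        if len(local) < 5 and k < 5:
            continue  # too few observations below to call a gap
        rate = float(np.mean(local))
        extreme = rate * max(1.0, np.log(len(local)) + 0.5772)
        if diffs[k] > X * extreme:
            return float((sorted_d[k] + sorted_d[k + 1]) / 2)
    return None


def _split_at(dm: DistanceMatrix, threshold: float) -> list[list[str]]:
    d = dm.d
    adj = (d < threshold) & ~np.isnan(d)
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    out: dict[int, list[str]] = {}
    for lab, c in zip(dm.labels, comp):
        out.setdefault(int(c), []).append(lab)
    return list(out.values())


def _recursive_split(dm: DistanceMatrix, members: list[str], prior_p: float, X: float) -> list[list[str]]:
    sub = dm.submatrix(members)
    vals = sub.condensed()
    vals = np.sort(vals[~np.isnan(vals)])
    gap = _find_gap(vals, prior_p, X)
    if gap is None:
        return [members]
    parts = _split_at(sub, gap)
    if len(parts) == 1:
        return [members]
    out: list[list[str]] = []
    for p in parts:
        out.extend(_recursive_split(dm, p, prior_p, X) if len(p) > 2 else [p])
    return out


def abgd_partition(dm: DistanceMatrix, config: AbgdConfig | None = None) -> list[dict]:
    """Initial and recursive barcode-gap partitions over the prior-P sweep.

    For each prior maximal intraspecific distance P: the initial partition
    links pairs below the detected gap distance; the recursive partition
    re-applies gap detection inside each group until no further significant
    gap is found. With no detectable gap everything is one OTU.
    """
    config = config or AbgdConfig()
    vals = dm.condensed()
    vals = np.sort(vals[~np.isnan(vals)])
    results = []
    for prior_p in config.sweep():
        gap = _find_gap(vals, prior_p, config.X)
        if gap is None:
            comp = [0] * len(dm.labels)
            initial = _partition_from_components(
                dm.labels, comp, "abgd_initial", {"P": prior_p, "X": config.X}
            )
            recursive = Partition(dict(initial.assignment), "abgd_recursive", dict(initial.params))
        else:
            groups = _split_at(dm, gap)
            comp = {lab: k for k, g in enumerate(groups) for lab in g}
            initial = _partition_from_components(
                dm.labels, [comp[lab] for lab in dm.labels],
                "abgd_initial", {"P": prior_p, "X": config.X, "gap": gap},
            )
            rec_groups: list[list[str]] = []
            for g in groups:
                rec_groups.extend(_recursive_split(dm, g, prior_p, config.X) if len(g) > 2 else [g])
            rcomp = {lab: k for k, g in enumerate(rec_groups) for lab in g}
            recursive = _partition_from_components(
                dm.labels, [rcomp[lab] for lab in dm.labels],
                "abgd_recursive", {"P": prior_p, "X": config.X, "gap": gap},
            )
        results.append({"P": prior_p, "initial": initial, "recursive": recursive})
    return results


# ---------------------------------------------------------------------------
# concordance


def concordance_table(partitions: dict[str, Partition]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OTU counts per method plus pairwise adjusted Rand indices.

    All partitions must cover the same id set. Returns ``(counts, ari)``
    where ``counts`` has one row per method and ``ari`` is the symmetric
    method-by-method agreement matrix.
    """
    methods = list(partitions)
    idsets = {m: frozenset(partitions[m].assignment) for m in methods}
    if len(set(idsets.values())) > 1:
        raise ValueError("partitions cover different id sets")
    ids = sorted(idsets[methods[0]])
    counts = pd.DataFrame(
        {"n_otus": [partitions[m].n_otus for m in methods]}, index=methods
    )
    ari = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for j, mj in enumerate(methods[i + 1 :], start=i + 1):
            score = adjusted_rand_score(
                partitions[mi].labels_for(ids), partitions[mj].labels_for(ids)
            )
            ari.iloc[i, j] = ari.iloc[j, i] = score
    return counts, ari


# ---------------------------------------------------------------------------
# scikit-learn estimator surface


def _as_square(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("X must be a square precomputed distance matrix")
    return X


def _dm_from_array(X) -> DistanceMatrix:
    n = X.shape[0]
    width = len(str(n))
    labels = [f"s{i:0{width}d}" for i in range(n)]
    return DistanceMatrix(labels, X, np.ones_like(X, dtype=int))


class ReslClusterer(ClusterMixin, BaseEstimator):
    """Refined-single-linkage OTU clusterer over precomputed distances.

    scikit-learn-compatible: ``fit(X)`` with X a square K2P distance matrix
    sets ``labels_`` (integer OTU labels) and ``n_otus_``.
    """

    def __init__(
        self,
        linkage_threshold: float = 0.022,
        inflation_values: tuple[float, ...] = (1.4, 2.0, 2.8, 4.0),
        similarity_scale: float = 0.03,
        max_mcl_iterations: int = 200,
        tolerance: float = 1e-8,
    ):
        self.linkage_threshold = linkage_threshold
        self.inflation_values = inflation_values
        self.similarity_scale = similarity_scale
        self.max_mcl_iterations = max_mcl_iterations
        self.tolerance = tolerance

    def fit(self, X, y=None):
        X = _as_square(X)
        dm = _dm_from_array(X)
        cfg = ReslConfig(
            self.linkage_threshold,
            tuple(self.inflation_values),
            self.similarity_scale,
            self.max_mcl_iterations,
            self.tolerance,
        )
        part = resl(dm, cfg)
        self.partition_ = part
        self.labels_ = part.labels_for(dm.labels)
        self.n_otus_ = part.n_otus
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class AbgdPartitioner(ClusterMixin, BaseEstimator):
    """Barcode-gap OTU partitioner over precomputed distances.

    ``fit(X)`` runs gap detection at the prior ``P`` (initial or recursive
    mode) and sets ``labels_``. Use :func:`abgd_partition` for a full sweep.
    """

    def __init__(self, P: float = 0.0077, X: float = 1.5, mode: str = "recursive"):
        self.P = P
        self.X = X
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in ("initial", "recursive"):
            raise ValueError("mode must be 'initial' or 'recursive'")
        Xd = _as_square(X)
        dm = _dm_from_array(Xd)
        vals = dm.condensed()
        vals = np.sort(vals[~np.isnan(vals)])
        gap = _find_gap(vals, self.P, self.X)
        if gap is None:
            part = _partition_from_components(
                dm.labels, [0] * len(dm.labels), f"abgd_{self.mode}", {"P": self.P}
            )
        else:
            groups = _split_at(dm, gap)
            if self.mode == "recursive":
                rec: list[list[str]] = []
                for g in groups:
                    rec.extend(_recursive_split(dm, g, self.P, self.X) if len(g) > 2 else [g])
                groups = rec
            comp = {lab: k for k, g in enumerate(groups) for lab in g}
            part = _partition_from_components(
                dm.labels, [comp[lab] for lab in dm.labels],
                f"abgd_{self.mode}", {"P": self.P, "gap": gap},
            )
        self.partition_ = part
        self.labels_ = part.labels_for(dm.labels)
        self.n_otus_ = part.n_otus
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
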