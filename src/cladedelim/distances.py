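"""Kimura 2-parameter distances with pairwise deletion, and their summaries.

The K2P model separates transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) and estimates the per-site substitution
distance as

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Pairwise deletion means a column enters the comparison for a pair only when
both members carry a plain A/C/G/T there; gaps, N and IUPAC ambiguity codes
are treated as missing. Saturated pairs (a log argument <= 0) and pairs with
no comparable sites yield an undefined distance (NaN) that is excluded from
all summaries but tracked for QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import Alignment, SequenceRecord, _ENCODE

_PURINE = np.array([True, False, True, False])  # A, C, G, T -> A/G purines


def _encode(seq) -> np.ndarray:
    if isinstance(seq, SequenceRecord):
        return seq.encoded()
    if isinstance(seq, np.ndarray):
        return seq
    return _ENCODE[np.frombuffer(str(seq).upper().encode("ascii"), dtype=np.uint8)]


def k2p_counts(seq_a, seq_b) -> tuple[int, int, int]:
    """Classify comparable columns of a pair: (comparable, transitions, transversions)."""
    a, b = _encode(seq_a), _encode(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned lengths")
    mask = (a >= 0) & (b >= 0)
    m = int(mask.sum())
    diff = mask & (a != b)
    same_class = _PURINE[a * diff] == _PURINE[b * diff]  # valid only where diff
    ts = int((diff & same_class).sum())
    tv = int(diff.sum()) - ts
    return m, ts, tv


def k2p(seq_a, seq_b) -> tuple[float, int]:
    """K2P distance for one pair under pairwise deletion.

    Returns ``(distance, comparable_sites)``; the distance is NaN when no
    sites are comparable or the estimator saturates.
    """
    m, ts, tv = k2p_counts(seq_a, seq_b)
    if m == 0:
        return float("nan"), 0
    p, q = ts / m, tv / m
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return float("nan"), m
    return -0.5 * np.log(w1) - 0.25 * np.log(w2), m


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair comparable-site counts."""

    labels: list[str]
    d: np.ndarray  # (n, n) float, NaN where undefined
    sites: np.ndarray  # (n, n) int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.triu(np.isnan(self.d), k=1))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (NaN pairs included)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]

    def max(self) -> float:
        return float(np.nanmax(self.condensed())) if len(self) > 1 else 0.0

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.labels.index(i) for i in ids]
        return DistanceMatrix(
            [self.labels[i] for i in idx],
            self.d[np.ix_(idx, idx)],
            self.sites[np.ix_(idx, idx)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        d = df.to_numpy(dtype=float)
        return cls(list(df.index.astype(str)), d, np.zeros_like(d, dtype=int))


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs K2P distances under pairwise deletion (vectorized)."""
    if len(alignment) < 2:
        raise ValueError("need >= 2 records")
    enc = alignment.encoded()
    n = enc.shape[0]
    valid = enc >= 0
    purine = np.zeros_like(enc, dtype=bool)
    purine[valid] = _PURINE[enc[valid]]
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        mask = valid[i] & valid[i + 1 :]
        m = mask.sum(axis=1)
        diff = mask & (enc[i] != enc[i + 1 :])
        ts = (diff & (purine[i] == purine[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(m > 0, ts / np.maximum(m, 1), np.nan)
            q = np.where(m > 0, tv / np.maximum(m, 1), np.nan)
            w1, w2 = 1 - 2 * p - q, 1 - 2 * q
            row = np.where(
                (w1 > 0) & (w2 > 0), -0.5 * np.log(np.abs(w1)) - 0.25 * np.log(np.abs(w2)), np.nan
            )
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
        sites[i, i + 1 :] = m
        sites[i + 1 :, i] = m
    np.fill_diagonal(sites, enc.shape[1])
    return DistanceMatrix(list(alignment.ids), d, sites)


@dataclass
class DistanceHistogram:
    """Binned pairwise-distance distribution with its empty ("gap") intervals."""

    bin_edges: np.ndarray
    counts: np.ndarray
    empty_intervals: list[tuple[float, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:], "count": self.counts}
        )


def histogram(
    dm: DistanceMatrix, bin_width: float = 0.005, min_empty_bins: int = 2
) -> DistanceHistogram:
    """Histogram of defined pairwise distances and its internal empty intervals.

    An empty interval (candidate barcode gap) is a run of at least
    ``min_empty_bins`` consecutive empty bins strictly inside the observed
    distance range; requiring two bins avoids single-bin binning artifacts.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = dm.condensed()
    vals = vals[~np.isnan(vals)]
    hi = max(vals.max(), bin_width) if len(vals) else bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    empties: list[tuple[float, float]] = []
    run = 0
    nz = np.nonzero(counts)[0]
    lo_bin, hi_bin = (nz[0], nz[-1]) if len(nz) else (0, -1)
    for b in range(lo_bin, hi_bin + 1):
        if counts[b] == 0:
            run += 1
        else:
            if run >= min_empty_bins:
                empties.append((float(edges[b - run]), float(edges[b])))
            run = 0
    return DistanceHistogram(edges, counts, empties)


@dataclass
class GroupDistanceSummary:
    """Per-group maximum intra-group distance and nearest-neighbour distances."""

    table: pd.DataFrame  # index=group; columns: n, max_intra, nn_group, nn_distance


def group_summary(dm: DistanceMatrix, partition) -> GroupDistanceSummary:
    """Maximum intra-group and nearest-neighbour inter-group K2P distances.

    ``partition`` maps sequence id -> group label (a mapping or a
    delimitation Partition). Singleton groups report max_intra as NaN.
    """
    assignment = getattr(partition, "assignment", partition)
    missing = [lab for lab in dm.labels if lab not in assignment]
    if missing:
        raise ValueError(f"partition does not cover labels: {missing[:5]}")
    groups = sorted(set(assignment.values()))
    idx = {g: [i for i, lab in enumerate(dm.labels) if assignment[lab] == g] for g in groups}
    rows = []
    for g in groups:
        gi = idx[g]
        sub = dm.d[np.ix_(gi, gi)]
        iu = np.triu_indices(len(gi), k=1)
        max_intra = float(np.nanmax(sub[iu])) if len(gi) > 1 else float("nan")
        nn_group, nn_d = None, float("inf")
        for h in groups:
            if h == g:
                continue
            between = dm.d[np.ix_(gi, idx[h])]
            if np.all(np.isnan(between)):
                continue
            m = float(np.nanmin(between))
            if m < nn_d:
                nn_group, nn_d = h, m
        rows.append(
            {
                "group": g,
                "n": len(gi),
                "max_intra": max_intra,
                "nn_group": nn_group,
                "nn_distance": nn_d if nn_group is not None else float("nan"),
            }
        )
    return GroupDistanceSummary(pd.DataFrame(rows).set_index("group"))
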