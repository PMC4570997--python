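"""Host–parasite divergence comparison.

Compares mitochondrial divergence (COI/cytb K2P) between parasitic lice
and their primate hosts: pairwise divergences across a taxon panel,
amino-acid substitution counts under the appropriate mitochondrial genetic
code (invertebrate for lice, vertebrate for hosts), and parasite/host rate
ratios. Sequences are compared over a shared gene window; host mitogenome
records can be sliced to the window by best ungapped local match against a
reference gene sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import k2p
from .seqio import Alignment, SequenceRecord, translation_qc

#: Accessions excluded by default (known contaminant record).
DEFAULT_EXCLUSIONS = ("AY316793",)

#: NCBI genetic-code table per role.
GENETIC_CODE = {"parasite": 5, "host": 2}  # invertebrate / vertebrate mito


@dataclass
class PanelEntry:
    taxon: str
    accessions: dict[str, str]  # gene -> accession id
    role: str  # host | parasite

    def __post_init__(self) -> None:
        if self.role not in ("host", "parasite"):
            raise ValueError(f"role must be host or parasite, got {self.role!r}")


@dataclass
class TaxonPanel:
    """Named taxa with accessions and host/parasite roles."""

    entries: list[PanelEntry] = field(default_factory=list)
    windows: dict[str, int] = field(default_factory=lambda: {"COI": 658, "cytb": 294})
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS

    @classmethod
    def from_json(cls, path: str | Path) -> "TaxonPanel":
        spec = json.loads(Path(path).read_text())
        entries = [
            PanelEntry(t, dict(e["accessions"]), e["role"]) for t, e in spec["taxa"].items()
        ]
        return cls(entries, spec.get("windows", {"COI": 658, "cytb": 294}),
                   tuple(spec.get("exclusions", DEFAULT_EXCLUSIONS)))

    def role_of(self, taxon: str) -> str:
        for e in self.entries:
            if e.taxon == taxon:
                return e.role
        raise KeyError(taxon)


def slice_to_window(sequence: str, reference: str) -> str:
    """Extract the reference-gene window from a longer record.

    Scans every ungapped offset and returns the window maximizing exact
    A/C/G/T matches to the reference (first best on ties — deterministic).
    """
    seq = sequence.upper().replace("-", "")
    ref = reference.upper().replace("-", "")
    if len(seq) < len(ref):
        raise ValueError("sequence shorter than reference window")
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    best_off, best_score = 0, -1
    for off in range(len(s) - len(r) + 1):
        score = int((s[off : off + len(r)] == r).sum())
        if score > best_score:
            best_off, best_score = off, score
    return seq[best_off : best_off + len(r)]


def panel_divergences(alignment: Alignment, percent: bool = True) -> pd.DataFrame:
    """All pairwise K2P distances among panel sequences (pairwise deletion).

    Returns a symmetric taxon-by-taxon table; values in percent by default
    (1-decimal presentation is left to the caller). Saturated/uncomparable
    pairs are NaN.
    """
    ids = alignment.ids
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = k2p(alignment[i].sequence, alignment[j].sequence)
            out[i, j] = out[j, i] = d * 100 if percent else d
    return pd.DataFrame(out, index=ids, columns=ids)


def aa_substitution_count(
    alignment: Alignment, genetic_code: int = 5, frame: int = 1
) -> tuple[int, list[int]]:
    """Number of amino-acid positions with >= 2 distinct residues.

    All sequences are translated in the given frame with the given NCBI
    table; a frame containing internal stop codons is an error (run the
    translation QC first to pick a clean frame). Positions where any
    sequence has an undetermined residue (X) are ignored.
    """
    proteins = []
    for rec in alignment:
        rep = translation_qc(rec, genetic_code=genetic_code, frame=frame)
        if rep["stop_codons"] > 0:
            raise ValueError(
                f"record {rec.id!r} has internal stop codons in frame {frame}; "
                "check the reading frame with translation_qc"
            )
        proteins.append(rep["protein"])
    length = min(len(p) for p in proteins)
    variable = []
    for pos in range(length):
        residues = {p[pos] for p in proteins} - {"X"}
        if len(residues) > 1:
            variable.append(pos)
    return len(variable), variable


def rate_ratio(parasite_distance: float, host_distance: float) -> float:
    """Parasite/host divergence ratio; undefined when the host distance is 0."""
    if host_distance == 0:
        raise ValueError("host distance is zero: ratio undefined")
    return parasite_distance / host_distance


def panel_report(
    lice: Alignment, hosts: Alignment, pairs: list[tuple[tuple[str, str], tuple[str, str]]]
) -> pd.DataFrame:
    """Rate-ratio table for matched (parasite pair, host pair) comparisons.

    ``pairs`` lists ((louse_a, louse_b), (host_a, host_b)) id tuples; each
    row reports both K2P divergences (percent) and their ratio.
    """
    lice_d = panel_divergences(lice)
    host_d = panel_divergences(hosts)
    rows = []
    for (la, lb), (ha, hb) in pairs:
        pd_ = lice_d.loc[la, lb]
        hd_ = host_d.loc[ha, hb]
        rows.append({
            "parasite_pair": f"{la}/{lb}", "host_pair": f"{ha}/{hb}",
            "parasite_divergence_pct": pd_, "host_divergence_pct": hd_,
            "ratio": rate_ratio(pd_, hd_) if hd_ else float("nan"),
        })
    return pd.DataFrame(rows)
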