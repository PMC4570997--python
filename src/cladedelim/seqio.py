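"""Sequence I/O and quality control for mitochondrial barcode datasets.

Reads FASTA alignments with per-sequence metadata (country, population,
clade label), and applies the QC steps used upstream of distance analysis:
minimum-length filtering, trimming to the commonly covered window,
translation checks against the invertebrate mitochondrial code, and
flagging of grossly divergent (contaminant) sequences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: Characters allowed in input sequences (IUPAC DNA + gap).
DNA_ALPHABET = set("ACGTRYSWKMBDHVN-")

#: Nucleotide -> small-int code; anything not plain A/C/G/T maps to -1 and is
#: treated as missing under pairwise deletion.
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.array(list("ACGT"))


@dataclass
class SequenceRecord:
    """One aligned DNA sequence plus its specimen metadata."""

    id: str
    sequence: str
    gene: str | None = None  # "COI" or "cytb"
    country: str | None = None
    population: str | None = None
    clade_label: str | None = None
    source: str = "study"  # study | genbank | simulated

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")

    @property
    def ungapped_length(self) -> int:
        """Number of unambiguous A/C/G/T positions (gaps and N/ambiguity excluded)."""
        s = self.sequence.upper()
        return sum(1 for c in s if c in "ACGT")

    def encoded(self) -> np.ndarray:
        """int8 encoding: A,C,G,T -> 0..3; anything else -> -1 (missing)."""
        return _ENCODE[np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)]


@dataclass
class Alignment:
    """An ordered collection of equal-length sequence records."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate id(s): {dups}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def length(self) -> int:
        """Alignment width in columns."""
        return len(self.records[0].sequence) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def encoded(self) -> np.ndarray:
        """(n, length) int8 matrix; -1 marks gaps/ambiguity/N."""
        return np.vstack([r.encoded() for r in self.records])

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = set(ids)
        return Alignment([r for r in self.records if r.id in keep])


# ---------------------------------------------------------------------------
# reading / writing


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a metadata TSV with header ``id gene country population clade``."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["id"]] = row
    return out


def read_fasta(
    path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    aligned: bool = True,
    source: str = "study",
) -> Alignment | list[SequenceRecord]:
    """Read FASTA records, optionally joining a metadata TSV keyed by id.

    The metadata join is left-outer: records without metadata keep ``None``
    fields; metadata rows without a matching sequence are collected in the
    report attribute ``read_fasta.unmatched`` of the returned object (a list
    attached as ``alignment.unmatched_metadata`` is avoided to keep the type
    simple — unmatched ids are simply ignored after being computed).

    Parameters
    ----------
    aligned:
        If True (default) return an :class:`Alignment` (equal lengths
        enforced); otherwise return a plain list of records.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    meta = read_metadata(metadata_path) if metadata_path else {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id: {rec.id!r}")
        seen.add(rec.id)
        row = meta.get(rec.id, {})
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                gene=row.get("gene") or None,
                country=row.get("country") or None,
                population=row.get("population") or None,
                clade_label=row.get("clade") or None,
                source=source,
            )
        )
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    if aligned:
        return Alignment(records)
    return records


def write_fasta(records: Alignment | Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA, preserving order and ids."""
    recs = list(records)
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_metadata(records: Alignment | Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "gene", "country", "population", "clade"])
        for r in records:
            w.writerow([r.id, r.gene or "", r.country or "", r.population or "", r.clade_label or ""])


# ---------------------------------------------------------------------------
# QC operations


def filter_min_length(
    records: Alignment | Sequence[SequenceRecord], min_len: int = 500
) -> list[SequenceRecord]:
    """Keep records whose ungapped length exceeds ``min_len`` (strict).

    Mirrors barcode-compliance filtering where only sequences longer than
    500 bp enter the analysis. Order-preserving; never adds records.
    """
    return [r for r in records if r.ungapped_length > min_len]


def trim_to_overlap(alignment: Alignment, min_coverage: float = 1.0) -> Alignment:
    """Trim leading/trailing columns whose non-gap coverage is below threshold.

    Only the 5'/3' flanks are removed: internal low-coverage columns are kept.
    ``min_coverage`` is the fraction of records that must have a non-gap,
    non-N character in a column for it to anchor the retained window.
    """
    if not alignment.records:
        raise ValueError("empty alignment")
    enc = alignment.encoded()
    coverage = (enc >= 0).mean(axis=0)
    ok = coverage >= min_coverage
    if not ok.any():
        raise ValueError("no overlapping region: every column is below coverage")
    first, last = int(np.argmax(ok)), int(len(ok) - 1 - np.argmax(ok[::-1]))
    if first == 0 and last == alignment.length - 1:
        return alignment
    trimmed = [replace(r, sequence=r.sequence[first : last + 1]) for r in alignment.records]
    return Alignment(trimmed)


#: NCBI translation table ids accepted by translation_qc.
_KNOWN_TABLES = {1, 2, 5}


def detect_frame(sequence: str, genetic_code: int = 5) -> int:
    """Pick the reading frame (1, 2 or 3) minimizing in-frame stop codons."""
    best, best_stops = 1, None
    for frame in (1, 2, 3):
        rep = translation_qc(sequence, genetic_code=genetic_code, frame=frame)
        if best_stops is None or rep["stop_codons"] < best_stops:
            best, best_stops = frame, rep["stop_codons"]
    return best


def translation_qc(
    record: SequenceRecord | str, genetic_code: int = 5, frame: int = 1
) -> dict:
    """Check a coding sequence for internal stop codons and gaps.

    Translates with the requested NCBI table (default 5, invertebrate
    mitochondrial) in the given frame; a trailing (terminal) stop is not
    counted. Gaps anywhere in the sequence fail QC.
    """
    if genetic_code not in _KNOWN_TABLES:
        raise ValueError(f"unknown genetic code table id: {genetic_code}")
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    seq = seq.upper()
    internal_gaps = seq.count("-")
    coding = seq.replace("-", "")[frame - 1 :]
    coding = coding[: len(coding) - len(coding) % 3]
    if len(coding) < 3:
        raise ValueError("fewer than 3 ungapped bases in chosen frame")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stops = 0
    n_codons = len(coding) // 3
    for k in range(n_codons):
        codon = coding[3 * k : 3 * k + 3]
        if codon in table.stop_codons and k < n_codons - 1:
            stops += 1
    aa = str(Seq(coding).translate(table=genetic_code))
    return {
        "ok": stops == 0 and internal_gaps == 0,
        "stop_codons": stops,
        "internal_gaps": internal_gaps,
        "protein": aa,
        "frame": frame,
    }


def flag_contaminants(
    alignment: Alignment, references: Alignment, max_divergence: float = 0.30
) -> list[dict]:
    """Flag sequences far more divergent from every reference than conspecifics can be.

    A record is flagged when its minimum K2P distance to any reference
    exceeds ``max_divergence`` (default 0.30 — far above intraspecific
    maxima, far below a cross-family contaminant). Records with no
    comparable sites against any reference are flagged as ``uncomparable``.
    """
    from .distances import k2p

    flagged = []
    for rec in alignment:
        best = None
        for ref in references:
            d, sites = k2p(rec.sequence, ref.sequence)
            if sites > 0 and d == d:  # defined
                best = d if best is None else min(best, d)
        if best is None:
            flagged.append({"id": rec.id, "reason": "uncomparable", "min_distance": None})
        elif best > max_divergence:
            flagged.append({"id": rec.id, "reason": "divergent", "min_distance": best})
    return flagged
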