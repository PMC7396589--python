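"""Reference sets of mature small-RNA sequences.

Mature miRNAs are ~19-26 nt and piRNAs ~24-30 nt, i.e. shorter than the
sequencing reads that carry them, which is what makes exact read-containment
counting possible.  References come from miRBase/piRNAdb-style FASTA (RNA
alphabet); on load they are uppercased, U is mapped to T, and any record with
remaining non-ACGT characters (ambiguity codes) is excluded, because exact
matching can never succeed through an ambiguous base.

Distinct ids sharing an identical mature sequence (multi-locus families) are
all kept and recorded as duplicate groups; downstream counting credits each id
identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._io import PathLike, open_text

log = logging.getLogger(__name__)

#: Expected mature-sequence length bounds (nt) per biotype. Out-of-bounds
#: lengths are warned about, never rejected.
BIOTYPE_BOUNDS: dict[str, tuple[int, int]] = {"miRNA": (19, 26), "piRNA": (24, 30)}

_VALID_ALPHABET = frozenset("ACGT")
_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ReferenceRecord:
    """One validated mature small-RNA sequence (DNA alphabet, uppercase)."""

    id: str
    sequence: str
    biotype: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reference record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"reference {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"reference {self.id!r}: invalid characters {sorted(bad)}"
            )


@dataclass
class ReferenceSet:
    """An ordered, id-unique collection of reference records."""

    records: list[ReferenceRecord]
    biotype_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(BIOTYPE_BOUNDS)
    )
    #: (id, reason) pairs for records dropped during loading.
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate reference id {rec.id!r}")
            seen.add(rec.id)
            if rec.biotype not in self.biotype_bounds:
                raise ValueError(
                    f"reference {rec.id!r}: biotype {rec.biotype!r} has no "
                    f"length bounds"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def by_id(self) -> dict[str, ReferenceRecord]:
        return {r.id: r for r in self.records}

    def sequences(self) -> dict[str, str]:
        """Mapping id -> sequence, in record order."""
        return {r.id: r.sequence for r in self.records}

    @property
    def duplicate_groups(self) -> list[list[str]]:
        """Groups (size >= 2) of ids whose sequences are identical."""
        by_seq: dict[str, list[str]] = {}
        for rec in self.records:
            by_seq.setdefault(rec.sequence, []).append(rec.id)
        return [ids for ids in by_seq.values() if len(ids) > 1]

    def duplicate_group_labels(self) -> dict[str, str]:
        """id -> duplicate-group label ("dupN"); singletons map to "-"."""
        labels = {r.id: "-" for r in self.records}
        for n, group in enumerate(self.duplicate_groups, start=1):
            for fid in group:
                labels[fid] = f"dup{n}"
        return labels


def load_reference_fasta(path: PathLike, biotype: str) -> ReferenceSet:
    """Load a mature-sequence FASTA (plain or gzipped) into a ReferenceSet.

    The first whitespace-delimited header token becomes the id (miRBase-style
    headers carry accessions after the name; the remainder is kept as a
    free-text description).  Sequences are uppercased and U->T mapped; records
    still containing non-ACGT characters are excluded and logged.  Lengths
    outside the biotype's expected bounds only produce warnings.

    Raises ``ValueError`` on a duplicate id or when no valid record remains.
    """
    if biotype not in BIOTYPE_BOUNDS:
        raise ValueError(
            f"unknown biotype {biotype!r}; expected one of {sorted(BIOTYPE_BOUNDS)}"
        )
    lo, hi = BIOTYPE_BOUNDS[biotype]
    records: list[ReferenceRecord] = []
    excluded: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open_text(path) as handle:
        for header, raw_seq in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            if not parts:
                raise ValueError(f"{path}: FASTA entry with empty header")
            fid = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if fid in seen:
                raise ValueError(f"{path}: duplicate reference id {fid!r}")
            seen.add(fid)
            seq = raw_seq.upper().replace("U", "T")
            bad = set(seq) - _VALID_ALPHABET
            if bad or not seq:
                reason = (
                    f"non-ACGT characters {sorted(bad)}" if bad else "empty sequence"
                )
                log.warning("excluding reference %s: %s", fid, reason)
                excluded.append((fid, reason))
                continue
            if not lo <= len(seq) <= hi:
                log.warning(
                    "reference %s: length %d outside expected %s range %d-%d",
                    fid, len(seq), biotype, lo, hi,
                )
            records.append(
                ReferenceRecord(id=fid, sequence=seq, biotype=biotype, description=desc)
            )
    if not records:
        raise ValueError(f"{path}: no valid {biotype} records after filtering")
    return ReferenceSet(records=records, excluded=excluded)


def merge_reference_sets(sets: Iterable[ReferenceSet]) -> ReferenceSet:
    """Concatenate reference sets (e.g. miRNA + piRNA); ids must stay unique."""
    records: list[ReferenceRecord] = []
    bounds: dict[str, tuple[int, int]] = {}
    excluded: list[tuple[str, str]] = []
    for rs in sets:
        records.extend(rs.records)
        bounds.update(rs.biotype_bounds)
        excluded.extend(rs.excluded)
    return ReferenceSet(records=records, biotype_bounds=bounds, excluded=excluded)


def write_canonical_fasta(refset: ReferenceSet, path: PathLike) -> None:
    """Write the set back out as DNA-alphabet FASTA (id + description headers)."""
    with open_text(path, "wt") as out:
        for rec in refset:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            out.write(f"{header}\n{rec.sequence}\n")


def write_reference_report(refset: ReferenceSet, path: PathLike) -> dict[str, int]:
    """Write a per-record TSV (id, length, biotype, duplicate group).

    Returns record counts by biotype.
    """
    labels = refset.duplicate_group_labels()
    counts: dict[str, int] = {}
    with open_text(path, "wt") as out:
        out.write("id\tlength\tbiotype\tduplicate_group\n")
        for rec in refset:
            out.write(f"{rec.id}\t{rec.length}\t{rec.biotype}\t{labels[rec.id]}\n")
            counts[rec.biotype] = counts.get(rec.biotype, 0) + 1
    return counts
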