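"""FASTQ preprocessing: 3' adapter removal, Q20 3'-end trimming, length filter.

Small-RNA library inserts (19-30 nt) are much shorter than the read length, so
nearly every read runs into the 3' sequencing adapter; removal is required
before length-based filtering but is optional for containment counting itself
(an intact adapter does not disturb exact substring matching of the insert).

The quality step trims low-quality 3' tails with the standard partial-sum rule
(the BWA/cutadapt ``-q`` algorithm) at a default cutoff of Q20, and reads
shorter than 15 nt after trimming are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._io import PathLike, open_text

log = logging.getLogger(__name__)

#: Illumina TruSeq small-RNA 3' adapter ("RA3").
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_PHRED_OFFSET = 33


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with Phred+33 qualities."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )
        if any(not ("!" <= c <= "~") for c in self.quality):
            raise ValueError(f"read {self.id!r}: quality outside printable ASCII")

    def phred(self) -> list[int]:
        return [ord(c) - _PHRED_OFFSET for c in self.quality]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TrimConfig:
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 3
    max_error_rate: float = 0.1
    quality_cutoff: int = 20
    min_length: int = 15
    #: If True, replace 3' quality trimming by a mean-read-quality drop rule
    #: (reads with mean Phred < cutoff are discarded whole).
    mean_quality_filter: bool = False

    def __post_init__(self) -> None:
        if not self.adapter or set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must be a non-empty ACGT string")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")
        if self.quality_cutoff < 0:
            raise ValueError("quality_cutoff must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class TrimStats:
    reads_in: int = 0
    reads_out: int = 0
    adapter_trimmed: int = 0
    dropped_short: int = 0

    def check(self) -> None:
        assert self.reads_in == self.reads_out + self.dropped_short
        assert self.adapter_trimmed <= self.reads_in

    def as_json(self) -> str:
        return json.dumps(self.__dict__)


def quality_trim_3prime(read: ReadRecord, cutoff: int) -> ReadRecord:
    """Trim the 3' end by the partial-sum rule.

    Scanning from the 3' end, accumulate ``cutoff - q_i``; the read is cut at
    the position where the running sum is maximal and positive (ties broken
    toward the 3' end, i.e. minimal trimming).  If the sum never becomes
    positive the read is returned unchanged.  May return an empty read; the
    length filter deals with that downstream.
    """
    q = read.phred()
    running = 0
    best = 0
    cut = len(q)
    for i in range(len(q) - 1, -1, -1):
        running += cutoff - q[i]
        if running > best:
            best = running
            cut = i
    if best <= 0:
        return read
    return ReadRecord(read.id, read.sequence[:cut], read.quality[:cut])


def find_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> Optional[int]:
    """Leftmost start of a 3' adapter occurrence, or None.

    A position ``p`` matches when the read suffix starting at ``p`` aligns to
    an adapter prefix of length ``L = min(len(adapter), len(read) - p)`` with
    ``L >= min_overlap`` and at most ``floor(max_error_rate * L)`` Hamming
    mismatches (no indels).  N in the read always counts as a mismatch.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(sequence)
    alen = len(adapter)
    for p in range(0, n - min_overlap + 1):
        L = min(alen, n - p)
        allowed = int(max_error_rate * L)
        mismatches = 0
        window = sequence[p : p + L]
        ok = True
        for a, b in zip(window, adapter):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return p
    return None


def trim_read(
    read: ReadRecord, config: TrimConfig
) -> tuple[Optional[ReadRecord], bool]:
    """Adapter-trim then quality-trim one read.

    Trimming iterates to a fixpoint: cutting at an adapter (or trimming a
    low-quality tail) can expose a new terminal adapter fragment, which would
    otherwise survive a single pass.  Each cut strictly shortens the read and
    quality trimming is idempotent, so the loop terminates, and no surviving
    read ends in anything matching the adapter under the overlap/error rules.

    Returns ``(trimmed_read, adapter_found)``; ``trimmed_read`` is None when
    the result falls below ``config.min_length`` (or, in mean-quality mode,
    when the mean Phred score is below the cutoff).
    """
    adapter_found = False
    changed = True
    while changed:
        changed = False
        pos = find_adapter(
            read.sequence, config.adapter, config.min_overlap, config.max_error_rate
        )
        while pos is not None:
            adapter_found = True
            read = ReadRecord(read.id, read.sequence[:pos], read.quality[:pos])
            pos = find_adapter(
                read.sequence, config.adapter, config.min_overlap,
                config.max_error_rate,
            )
        if not config.mean_quality_filter:
            trimmed = quality_trim_3prime(read, config.quality_cutoff)
            if len(trimmed) != len(read):
                read = trimmed
                changed = True
    if config.mean_quality_filter:
        q = read.phred()
        if q and sum(q) / len(q) < config.quality_cutoff:
            return None, adapter_found
    if len(read) < config.min_length:
        return None, adapter_found
    return read, adapter_found


def iter_fastq(path: PathLike) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (plain or gzipped) as validated ReadRecords.

    Malformed records (length mismatch, truncation) raise ValueError carrying
    the 1-based record index.
    """
    with open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            index += 1
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record {index}: {exc}")
            try:
                yield ReadRecord(title.split(None, 1)[0], seq.upper(), qual)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed FASTQ record {index}: {exc}")


def write_fastq(records, path: PathLike) -> int:
    """Write ReadRecords as FASTQ; returns the number written."""
    n = 0
    with open_text(path, "wt") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def process_fastq(
    in_path: PathLike, out_path: PathLike, config: TrimConfig | None = None
) -> TrimStats:
    """Trim a whole FASTQ file, preserving input order; returns TrimStats."""
    config = config or TrimConfig()
    stats = TrimStats()
    with open_text(out_path, "wt") as out:
        for rec in iter_fastq(in_path):
            stats.reads_in += 1
            trimmed, adapter_found = trim_read(rec, config)
            if adapter_found:
                stats.adapter_trimmed += 1
            if trimmed is None:
                stats.dropped_short += 1
                continue
            out.write(f"@{trimmed.id}\n{trimmed.sequence}\n+\n{trimmed.quality}\n")
            stats.reads_out += 1
    stats.check()
    log.info("trim stats: %s", stats.as_json())
    return stats
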