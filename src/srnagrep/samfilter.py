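"""SAM alignment filtering and per-reference counting.

For the aligner-based quantification route, alignments to a small-RNA
transcriptome are kept only when the read is mapped with at least 18 aligned
bases — the CIGAR match length, i.e. the summed lengths of M (and the =/X
operations some aligners emit in place of M).  This is a *total aligned
length* reading of the 18M threshold: a literal single-token reading would
absurdly drop perfect 19M-30M alignments.

Each read counts at most once per reference: secondary (0x100) and
supplementary (0x800) records are excluded by default.  Only the SAM text
columns qname/flag/rname/cigar are consulted; transcriptome references are
the features themselves so coordinates are irrelevant.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import IO, Iterable, Optional, Union

from ._io import PathLike, open_text

CIGAR_OPS = frozenset("MIDNSHP=X")
_MATCH_OPS = frozenset("M=X")
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL = re.compile(r"^(?:\d+[MIDNSHP=X])+$")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

#: list of (op, length) pairs; None is the unaligned marker ("*").
Cigar = Optional[list[tuple[str, int]]]


def parse_cigar(text: str) -> Cigar:
    """Strict run-length CIGAR parse; "*" yields the unaligned marker None."""
    if text == "*":
        return None
    if not text or not _CIGAR_FULL.match(text):
        raise ValueError(f"malformed CIGAR string {text!r}")
    ops = [(op, int(length)) for length, op in _CIGAR_TOKEN.findall(text)]
    if any(length < 1 for _, length in ops):
        raise ValueError(f"zero-length CIGAR operation in {text!r}")
    return ops


def format_cigar(cigar: Cigar) -> str:
    if cigar is None:
        return "*"
    return "".join(f"{length}{op}" for op, length in cigar)


def matched_length(cigar: Cigar) -> int:
    """Total aligned bases: summed lengths of M, = and X operations."""
    if cigar is None:
        return 0
    return sum(length for op, length in cigar if op in _MATCH_OPS)


def keep_alignment(
    flag: int,
    cigar: Cigar,
    min_matched: int = 18,
    count_secondary: bool = False,
) -> bool:
    """Filter rule: mapped, primary (unless ``count_secondary``), and at
    least ``min_matched`` aligned bases."""
    if flag & FLAG_UNMAPPED:
        return False
    if not count_secondary and flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
        return False
    return matched_length(cigar) >= min_matched


def counts_from_sam(
    sam: Union[PathLike, IO[str], Iterable[str]],
    min_matched: int = 18,
    count_secondary: bool = False,
) -> Counter:
    """Per-reference counts of kept alignments from SAM text.

    Headers (@ lines) are tolerated but not required.  An unparseable
    alignment line raises ValueError with its 1-based line number.
    """
    if isinstance(sam, (str, bytes)) or hasattr(sam, "__fspath__"):
        with open_text(sam) as handle:
            return counts_from_sam(handle, min_matched, count_secondary)
    counts: Counter = Counter()
    for lineno, line in enumerate(sam, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ValueError(
                f"SAM line {lineno}: expected >= 11 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            flag = int(fields[1])
            cigar = parse_cigar(fields[5])
        except ValueError as exc:
            raise ValueError(f"SAM line {lineno}: {exc}")
        rname = fields[2]
        if keep_alignment(flag, cigar, min_matched, count_secondary):
            counts[rname] += 1
    return counts
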