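"""Exact read-containment counting of mature small RNAs.

The quantification unit is *read containment*: a read is counted for a
reference exactly when the complete mature sequence occurs in the read as a
contiguous, mismatch-free substring.  Because mature miRNAs (19-26 nt) and
piRNAs (24-30 nt) are shorter than the 75-150 nt reads, a sequenced insert
carries the whole mature sequence, and exact substring search is a complete
(if deliberately conservative) alignment criterion: no mismatches, no indels,
no seed heuristics.

Two independent implementations are provided:

* :class:`ExactMatcher` — an Aho-Corasick failure-link automaton over all
  reference sequences; one linear pass per read regardless of the number of
  patterns.  This is the production path.
* :func:`naive_count_oracle` — the literal brute force (double loop with a
  substring scan per read x reference), kept as an independent oracle; it
  shares no code with the automaton.

Semantics shared by both: a read containing a reference k >= 1 times counts
once for that reference; a read containing several distinct references counts
once for each; N never matches any base.
"""

from __future__ import annotations

from collections import Counter, deque
from typing import Iterable, Mapping

from ._io import PathLike
from .reference import ReferenceSet, reverse_complement
from .trim import iter_fastq


class ExactMatcher:
    """Multi-pattern exact substring matcher over reference sequences.

    Parameters
    ----------
    patterns :
        Mapping of feature id -> sequence (ACGT, uppercase).  Distinct ids may
        share a sequence; each matching read credits every such id.
    rc_mode :
        When True, a read also matches a feature if it contains the reverse
        complement of the feature's sequence.  Off by default: small-RNA
        library prep preserves insert orientation.
    """

    def __init__(self, patterns: Mapping[str, str], rc_mode: bool = False):
        if not patterns:
            raise ValueError("cannot build a matcher from an empty pattern set")
        for fid, seq in patterns.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"pattern {fid!r} is not a non-empty ACGT string")
        self.rc_mode = rc_mode
        self.feature_ids = list(patterns)
        # pattern string -> ids credited when it is found
        by_seq: dict[str, set[str]] = {}
        for fid, seq in patterns.items():
            by_seq.setdefault(seq, set()).add(fid)
            if rc_mode:
                by_seq.setdefault(reverse_complement(seq), set()).add(fid)
        self._build(by_seq)

    def _build(self, by_seq: Mapping[str, set[str]]) -> None:
        # trie with goto transitions keyed by byte value
        goto: list[dict[int, int]] = [{}]
        out: list[frozenset[str]] = [frozenset()]
        for seq, ids in by_seq.items():
            state = 0
            for byte in seq.encode("ascii"):
                nxt = goto[state].get(byte)
                if nxt is None:
                    nxt = len(goto)
                    goto[state][byte] = nxt
                    goto.append({})
                    out.append(frozenset())
                state = nxt
            out[state] = out[state] | ids
        # breadth-first failure links; outputs inherited along them
        fail = [0] * len(goto)
        queue: deque[int] = deque()
        for state in goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for byte, nxt in goto[state].items():
                queue.append(nxt)
                f = fail[state]
                while f and byte not in goto[f]:
                    f = fail[f]
                fail[nxt] = goto[f].get(byte, 0) if goto[f].get(byte, 0) != nxt else 0
                if out[fail[nxt]]:
                    out[nxt] = out[nxt] | out[fail[nxt]]
        self._goto = goto
        self._fail = fail
        self._out = out

    @classmethod
    def from_reference_set(
        cls, refset: ReferenceSet, rc_mode: bool = False
    ) -> "ExactMatcher":
        return cls(refset.sequences(), rc_mode=rc_mode)

    def match(self, read_sequence: str) -> set[str]:
        """Set of feature ids whose sequence is contained in the read.

        Set semantics: each id appears at most once regardless of occurrence
        multiplicity.  Characters outside ACGT (e.g. N) reset the automaton
        and can never participate in a match.
        """
        goto = self._goto
        fail = self._fail
        out = self._out
        state = 0
        found: set[str] = set()
        for byte in read_sequence.encode("ascii"):
            nxt = goto[state].get(byte)
            while nxt is None and state:
                state = fail[state]
                nxt = goto[state].get(byte)
            state = nxt if nxt is not None else 0
            o = out[state]
            if o:
                found.update(o)
        return found

    # keep the dict-like alias the rest of the package uses
    __call__ = match


def count_reads(
    reads: Iterable[str], matcher: ExactMatcher
) -> tuple[Counter, int]:
    """Count read containment over an iterable of read sequences.

    Returns ``(per-feature Counter, number of reads processed)``; a read
    matching k features increments k counters.
    """
    counts: Counter = Counter({fid: 0 for fid in matcher.feature_ids})
    n = 0
    match = matcher.match
    for seq in reads:
        n += 1
        for fid in match(seq):
            counts[fid] += 1
    return counts, n


def count_fastq(path: PathLike, matcher: ExactMatcher) -> tuple[Counter, int]:
    """Count read containment over one FASTQ file (one sample column)."""
    return count_reads((rec.sequence for rec in iter_fastq(path)), matcher)


def naive_count_oracle(
    reads: Iterable[str], patterns: Mapping[str, str] | ReferenceSet
) -> Counter:
    """Literal brute-force containment counting (independent oracle).

    Double loop: for every read, for every reference, a plain substring scan.
    Deliberately shares no code with :class:`ExactMatcher`.
    """
    if isinstance(patterns, ReferenceSet):
        patterns = patterns.sequences()
    counts: Counter = Counter({fid: 0 for fid in patterns})
    for read in reads:
        for fid, seq in patterns.items():
            if seq in read:
                counts[fid] += 1
    return counts
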