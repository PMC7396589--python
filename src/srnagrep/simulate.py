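"""Synthetic small-RNA sequencing libraries with exact ground truth.

The generator emulates the structure of pooled serum-exosome small-RNA
libraries: two strains/groups x 5 pooled samples, each library a fixed number
of reads; each feature read is a complete mature reference sequence followed
by the 3' sequencing adapter and random filler, truncated or padded to a
uniform-random read length of 75-150 nt; the remaining reads are background.

The ground truth is *exact* by construction: background reads are
rejection-sampled so that they contain no reference as a substring, and every
feature read is rejection-sampled so that it contains no reference other than
its own.  With ``error_rate == 0`` this makes exact-containment counts equal
the truth table cell by cell; with substitution errors, observed counts can
only fall below the truth (an error that would *create* a foreign containment
match triggers a re-draw).

Per-sample library sizes are fixed (sequencing-depth constraint): counts are
drawn multinomially over the feature/background expected proportions, which
slightly attenuates realized fold changes relative to the injected values.
With dispersion ``phi > 0`` extra between-sample variability is added by
gamma-weighting the proportions (a negative-binomial draw conditioned on the
fixed total), so the conservation invariant column-sum + background ==
lib_size always holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._io import PathLike, open_text
from .counts import write_count_table
from .diffexpr import CASE, CONTROL, SampleDesign, write_design
from .reference import ReferenceRecord, ReferenceSet, BIOTYPE_BOUNDS
from .trim import DEFAULT_ADAPTER

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_QUAL34 = chr(33 + 34)  # constant Q34 qualities

_MAX_TRIES = 1000


@dataclass
class SimConfig:
    seed: int = 17
    n_per_group: int = 5
    references: Optional[ReferenceSet] = None  # None: random miRNA-like set
    n_features: int = 200                      # used when references is None
    baseline_props: Optional[np.ndarray] = None  # None: log-uniform draw
    background_fraction: float = 0.1
    lib_size: int = 50_000
    dispersion: float = 0.0
    injected_lfc: dict[str, float] = field(default_factory=dict)
    read_len_range: tuple[int, int] = (75, 150)
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.lib_size <= 0:
            raise ValueError("lib_size must be positive")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        lo, hi = self.read_len_range
        if not (40 <= lo <= hi <= 300):
            raise ValueError("read_len_range must lie within [40, 300]")


@dataclass
class SimTruth:
    """Ground-truth reads generated per feature per sample."""

    counts: pd.DataFrame          # features x samples, int
    background: pd.Series         # per-sample background read count
    design: SampleDesign
    config: SimConfig
    references: Optional[ReferenceSet] = None  # resolved set actually used

    def check(self) -> None:
        totals = self.counts.sum(axis=0) + self.background
        assert (totals == self.config.lib_size).all()


def random_reference_set(
    rng: np.random.Generator,
    n: int,
    biotype: str = "miRNA",
    prefix: str = "sim-mir-",
) -> ReferenceSet:
    """Random mature-like references, screened against substring nesting.

    Sequences are unique, within the biotype's length bounds, and no sequence
    is a substring of another — the screening that makes simulator ground
    truth exact.
    """
    lo, hi = BIOTYPE_BOUNDS[biotype]
    seqs: list[str] = []
    tries = 0
    while len(seqs) < n:
        tries += 1
        if tries > _MAX_TRIES * max(n, 1):
            raise RuntimeError("could not generate a nesting-free reference set")
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        if any(seq in s or s in seq for s in seqs):
            continue
        seqs.append(seq)
    records = [
        ReferenceRecord(id=f"{prefix}{i + 1}", sequence=s, biotype=biotype)
        for i, s in enumerate(seqs)
    ]
    return ReferenceSet(records=records)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _resolve(config: SimConfig) -> tuple[ReferenceSet, np.ndarray]:
    """References and baseline proportions, drawn from the seed if absent."""
    ss = np.random.SeedSequence([config.seed, 0xA11CE])
    rng = np.random.default_rng(ss)
    refs = config.references
    if refs is None:
        refs = random_reference_set(rng, config.n_features)
    props = config.baseline_props
    if props is None:
        # log-uniform abundances over ~3 decades, a generic skewed profile
        raw = 10.0 ** rng.uniform(-3, 0, size=len(refs))
        props = raw / raw.sum() * (1.0 - config.background_fraction)
    else:
        props = np.asarray(props, dtype=float)
        if props.size != len(refs) or (props < 0).any() or props.sum() > 1 + 1e-9:
            raise ValueError(
                "baseline_props must be non-negative, one per feature, sum <= 1"
            )
    max_ref = max(r.length for r in refs)
    if config.read_len_range[0] < max_ref + 1:
        raise ValueError(
            f"read_len_range minimum {config.read_len_range[0]} must exceed the "
            f"longest reference ({max_ref} nt)"
        )
    return refs, props


def _sample_names(config: SimConfig) -> SampleDesign:
    samples = [f"{CONTROL}_{i + 1}" for i in range(config.n_per_group)] + [
        f"{CASE}_{i + 1}" for i in range(config.n_per_group)
    ]
    group = {s: (CASE if s.startswith(CASE) else CONTROL) for s in samples}
    return SampleDesign(sample_ids=samples, group=group)


def draw_true_counts(config: SimConfig) -> SimTruth:
    """Draw the ground-truth count matrix (deterministic under the seed).

    Expected feature weights are ``lib_size * prop_f * 2**lfc_f`` in the case
    group (lfc 0 in control) plus the background remainder, renormalized per
    sample so each library totals exactly ``lib_size``.
    """
    refs, props = _resolve(config)
    design = _sample_names(config)
    fids = refs.ids
    lfc = np.array([config.injected_lfc.get(f, 0.0) for f in fids])
    bg_weight = max(0.0, 1.0 - props.sum())
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0457]))
    cols = {}
    background = {}
    for sample in design.sample_ids:
        w = props * (np.exp2(lfc) if design.group[sample] == CASE else 1.0)
        w = np.append(w, bg_weight)
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            gam = rng.gamma(shape, w[:-1] / shape)
            w = np.append(gam, w[-1])
        pvec = w / w.sum()
        draw = rng.multinomial(config.lib_size, pvec)
        cols[sample] = draw[:-1]
        background[sample] = int(draw[-1])
    counts = pd.DataFrame(cols, index=pd.Index(fids, name="feature_id"), dtype=np.int64)
    truth = SimTruth(
        counts=counts,
        background=pd.Series(background, name="background"),
        design=design,
        config=config,
        references=refs,
    )
    truth.check()
    return truth


def _feature_read(
    rng: np.random.Generator,
    refseq: str,
    all_seqs: list[str],
    config: SimConfig,
) -> str:
    """One read containing ``refseq`` and no other reference."""
    lo, hi = config.read_len_range
    core = refseq + config.adapter
    for _ in range(_MAX_TRIES):
        length = int(rng.integers(lo, hi + 1))
        if len(core) >= length:
            seq = core[:length]
        else:
            seq = core + _random_seq(rng, length - len(core))
        if config.error_rate > 0:
            seq = _apply_errors(rng, seq, config.error_rate)
        if any(s in seq for s in all_seqs if s != refseq):
            continue
        return seq
    raise RuntimeError("feature-read rejection sampling exceeded the retry cap")


def _background_read(
    rng: np.random.Generator, all_seqs: list[str], config: SimConfig
) -> str:
    """One read containing no reference at all."""
    lo, hi = config.read_len_range
    for _ in range(_MAX_TRIES):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        if config.error_rate > 0:
            seq = _apply_errors(rng, seq, config.error_rate)
        if any(s in seq for s in all_seqs):
            continue
        return seq
    raise RuntimeError("background-read rejection sampling exceeded the retry cap")


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size:
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def synthesize_reads(
    truth: SimTruth, out_dir: PathLike, gzip_output: bool = True
) -> dict[str, Path]:
    """Write one FASTQ per sample realizing the truth counts.

    Deterministic given the config seed.  Qualities are constant Q34.
    """
    config = truth.config
    refs: ReferenceSet = truth.references or _resolve(config)[0]
    all_seqs = [r.sequence for r in refs]
    seq_of = refs.sequences()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    paths: dict[str, Path] = {}
    for sidx, sample in enumerate(truth.design.sample_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xF00D, sidx])
        )
        path = out_dir / f"{sample}{suffix}"
        n = 0
        with open_text(path, "wt") as out:
            col = truth.counts[sample]
            for fid in truth.counts.index:
                refseq = seq_of[fid]
                for _ in range(int(col[fid])):
                    n += 1
                    seq = _feature_read(rng, refseq, all_seqs, config)
                    out.write(f"@{sample}:{n} {fid}\n{seq}\n+\n{_QUAL34 * len(seq)}\n")
            for _ in range(int(truth.background[sample])):
                n += 1
                seq = _background_read(rng, all_seqs, config)
                out.write(
                    f"@{sample}:{n} background\n{seq}\n+\n{_QUAL34 * len(seq)}\n"
                )
        assert n == config.lib_size
        paths[sample] = path
    return paths


@dataclass
class SimExperiment:
    fastq_paths: dict[str, Path]
    truth: SimTruth
    truth_path: Path
    design_path: Path


def simulate_experiment(
    config: SimConfig, out_dir: PathLike, gzip_output: bool = True
) -> SimExperiment:
    """Full simulated experiment: FASTQs + truth table + design TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = draw_true_counts(config)
    paths = synthesize_reads(truth, out_dir, gzip_output=gzip_output)
    truth_path = out_dir / "truth_counts.tsv"
    write_count_table(truth.counts, truth_path)
    design_path = out_dir / "design.tsv"
    write_design(truth.design, design_path)
    return SimExperiment(
        fastq_paths=paths, truth=truth, truth_path=truth_path,
        design_path=design_path,
    )
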