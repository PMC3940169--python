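"""Quality-control cascade for stripped amplicon reads.

The 250PE cascade, in fixed order and pair-synchronized throughout
(discarding either mate discards the pair):

1. sliding-window truncation: cut a read immediately before the first
   30 bp window (step 1) whose mean phred falls below 20;
2. fractional-length pair filter: a pair is dropped when either mate kept
   less than 75% of its pre-trim length (strict inequality);
3. consecutive low-quality truncation: cut before the first run of three
   or more bases each below the low-quality threshold;
4. ambiguity filter: any non-ACGT base call drops the pair;
5. minimum length: both mates must keep at least 150 bases (inclusive).

The 300PE path deliberately applies no quality trimming before overlap
assembly — merging itself corrects errors — and only the ambiguity and
minimum-length filters apply to the merged product.

Every trimming operation returns a prefix of its input; interior bases are
never edited, and qualities are carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .fastq import ReadPair

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class QCParams:
    window: int = 30
    window_mean_q: float = 20.0
    retain_fraction: float = 0.75
    low_q_run: int = 3
    low_q_threshold: int = 20  # QIIME's historical default of 3 is a valid preset
    min_len: int = 150
    allow_n: bool = False

    def __post_init__(self):
        if self.window < 1 or self.low_q_run < 1 or self.min_len < 1:
            raise ValueError("window, low_q_run and min_len must be positive")
        if not 0.0 < self.retain_fraction <= 1.0:
            raise ValueError("retain_fraction must lie in (0, 1]")


def sliding_window_trim(seq: str, qual: np.ndarray, params: QCParams) -> tuple[str, np.ndarray]:
    """Truncate before the start of the first failing mean-quality window.

    Windows of ``params.window`` bases advance one base at a time. Any read
    — input or truncation survivor — shorter than one window is judged as a
    single whole-read window, which keeps the operation idempotent.
    """
    q = np.asarray(qual, dtype=float)
    n = len(q)
    w = params.window
    cut = n
    if n >= w:
        csum = np.concatenate(([0.0], np.cumsum(q)))
        means = (csum[w:] - csum[:-w]) / w
        bad = np.flatnonzero(means < params.window_mean_q)
        if len(bad):
            cut = int(bad[0])
    if 0 < cut < w and q[:cut].mean() < params.window_mean_q:
        cut = 0
    return seq[:cut], qual[:cut]


def consecutive_low_q_trim(seq: str, qual: np.ndarray, params: QCParams) -> tuple[str, np.ndarray]:
    """Truncate before the first run of >= low_q_run consecutive low bases."""
    q = np.asarray(qual)
    low = q < params.low_q_threshold
    if len(low) < params.low_q_run or not low.any():
        return seq, qual
    run = 0
    for i, flag in enumerate(low):
        run = run + 1 if flag else 0
        if run == params.low_q_run:
            cut = i - params.low_q_run + 1
            return seq[:cut], qual[:cut]
    return seq, qual


def pair_length_filter(
    pair: ReadPair, original_lengths: tuple[int, int], params: QCParams
) -> bool:
    """Keep the pair only if BOTH mates retain >= retain_fraction of their
    pre-trim length ("less than 75%" is a strict discard)."""
    o1, o2 = original_lengths
    return not (
        len(pair.seq1) < params.retain_fraction * o1
        or len(pair.seq2) < params.retain_fraction * o2
    )


def ambiguity_filter(seq: str) -> bool:
    """Keep iff the sequence contains only A/C/G/T after case normalization."""
    return not set(seq.upper()) - _ACGT


def min_length_filter(seq: str, params: QCParams) -> bool:
    """Keep iff length >= min_len (150 bp boundary is inclusive)."""
    return len(seq) >= params.min_len


@dataclass
class QCReport:
    """Telescoping per-stage accounting: input of stage i+1 == kept of stage i."""

    stages: list[dict] = field(default_factory=list)
    per_sample: dict[str, int] = field(default_factory=dict)
    final_lengths_r1: list[int] = field(default_factory=list)
    final_lengths_r2: list[int] = field(default_factory=list)
    run_id: str | None = None

    @property
    def pairs_in(self) -> int:
        return self.stages[0]["in"] if self.stages else 0

    @property
    def pairs_out(self) -> int:
        return self.stages[-1]["kept"] if self.stages else 0

    def add_stage(self, name: str, n_in: int, kept: int) -> None:
        if self.stages and self.stages[-1]["kept"] != n_in:
            raise AssertionError("QC stage counts do not telescope")
        self.stages.append({"stage": name, "in": n_in, "kept": kept, "removed": n_in - kept})

    def check(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            assert prev["kept"] == cur["in"], "QC stage counts do not telescope"
        for s in self.stages:
            assert s["in"] - s["kept"] == s["removed"]

    def length_summary(self) -> pd.DataFrame:
        rows = []
        for mate, lens in (("R1", self.final_lengths_r1), ("R2", self.final_lengths_r2)):
            arr = np.asarray(lens, dtype=float)
            rows.append(
                {
                    "mate": mate,
                    "n": len(arr),
                    "median": float(np.median(arr)) if len(arr) else 0.0,
                    "mean": float(arr.mean()) if len(arr) else 0.0,
                    "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def _trim_pair(pair: ReadPair, fn, params: QCParams) -> ReadPair:
    s1, q1 = fn(pair.seq1, pair.qual1, params)
    s2, q2 = fn(pair.seq2, pair.qual2, params)
    return replace(pair, seq1=s1, qual1=q1, seq2=s2, qual2=q2, state="trimmed")


def qc_pipeline_250(
    pairs: Iterable[ReadPair],
    params: QCParams = QCParams(),
    sample_of: dict[str, str] | None = None,
) -> tuple[list[ReadPair], QCReport]:
    """Run the full 250PE cascade over stripped pairs.

    Stage order is fixed: window trim -> 75% pair filter -> consecutive
    low-quality trim -> ambiguity filter -> 150 bp minimum. The report
    telescopes; per-sample post-QC counts are filled when ``sample_of``
    maps read ids to sample ids.
    """
    report = QCReport()
    pairs = list(pairs)
    n0 = len(pairs)

    trimmed: list[tuple[ReadPair, tuple[int, int]]] = []
    for p in pairs:
        orig = (len(p.seq1), len(p.seq2))
        trimmed.append((_trim_pair(p, sliding_window_trim, params), orig))
    report.add_stage("sliding_window_trim", n0, len(trimmed))

    kept = [(p, o) for p, o in trimmed if pair_length_filter(p, o, params)]
    report.add_stage("pair_length_filter", len(trimmed), len(kept))

    low_trimmed = [_trim_pair(p, consecutive_low_q_trim, params) for p, _ in kept]
    report.add_stage("consecutive_low_q_trim", len(kept), len(low_trimmed))

    unambiguous = [
        p for p in low_trimmed if ambiguity_filter(p.seq1) and ambiguity_filter(p.seq2)
    ]
    report.add_stage("ambiguity_filter", len(low_trimmed), len(unambiguous))

    final = [
        p
        for p in unambiguous
        if min_length_filter(p.seq1, params) and min_length_filter(p.seq2, params)
    ]
    report.add_stage("min_length_filter", len(unambiguous), len(final))

    for p in final:
        report.final_lengths_r1.append(len(p.seq1))
        report.final_lengths_r2.append(len(p.seq2))
        if sample_of is not None:
            sid = sample_of.get(p.id)
            if sid is not None:
                report.per_sample[sid] = report.per_sample.get(sid, 0) + 1
    report.check()
    return final, report


def qc_pipeline_300(
    pairs: Iterable[ReadPair], params: QCParams = QCParams()
) -> tuple[list[ReadPair], QCReport]:
    """300PE pre-merge path: pass sequences through bit-identical.

    No quality trimming happens before assembly; the ambiguity and minimum-
    length filters are applied to the merged product (see
    ``filter_merged``), not here.
    """
    out = list(pairs)
    report = QCReport()
    report.add_stage("passthrough", len(out), len(out))
    for p in out:
        report.final_lengths_r1.append(len(p.seq1))
        report.final_lengths_r2.append(len(p.seq2))
    report.check()
    return out, report


def filter_merged(
    seqs: Iterable[tuple[str, str, np.ndarray]], params: QCParams = QCParams()
) -> tuple[list[tuple[str, str, np.ndarray]], QCReport]:
    """Post-merge filters for the 300PE path: ambiguity then minimum length."""
    report = QCReport()
    items = list(seqs)
    n0 = len(items)
    unamb = [t for t in items if ambiguity_filter(t[1])]
    report.add_stage("ambiguity_filter", n0, len(unamb))
    final = [t for t in unamb if min_length_filter(t[1], params)]
    report.add_stage("min_length_filter", len(unamb), len(final))
    report.check()
    return final, report
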