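"""Paired-read resolution: overlap detection, consensus merging, stitching.

A V3-V4 amplicon of ~469 bp leaves ~90 bp of true overlap between 300 bp
mates — enough for confident assembly with error correction — while 250 bp
mates overlap by at most ~30 bp after prefix removal and are usually just
concatenated. Both behaviours live here:

* 300PE: ``assemble_300`` finds the best overlap of mate 1 against the
  reverse-complemented mate 2 and builds an error-corrected consensus;
  pairs with no acceptable overlap are rejected and counted.
* 250PE: ``resolve_250`` merges when an acceptable overlap exists and
  otherwise stitches the mates end-to-end (mate 1 + revcomp mate 2) with
  the junction position recorded for downstream splitting.

Overlap scoring is exhaustive over candidate lengths: every overlap length
from ``min_overlap`` up to the shorter mate is scored by Hamming mismatch
ratio; the minimum ratio wins, ties going to the longer overlap, and the
winner is accepted only if its ratio is at most ``max_mismatch_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .fastq import ReadPair


@dataclass(frozen=True)
class OverlapResult:
    overlap_len: int
    mismatches: int
    accepted: bool

    @property
    def mismatch_ratio(self) -> float:
        return self.mismatches / self.overlap_len if self.overlap_len else 0.0


@dataclass
class MergedRead:
    """One resolved pair: either a consensus merge or an end-to-end stitch."""

    id: str
    sequence: str
    qualities: np.ndarray
    provenance: str  # merged | stitched
    junction: int | None = None  # stitch junction (0-based, = len(mate 1))
    overlap_len: int | None = None

    def header_comment(self) -> str:
        if self.provenance == "stitched":
            return f"provenance=stitched junction={self.junction}"
        return f"provenance=merged overlap={self.overlap_len}"


def find_overlap(
    mate1_seq: str,
    mate2_seq: str,
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.25,
) -> OverlapResult | None:
    """Best suffix(mate1)/prefix(revcomp(mate2)) overlap, or None.

    All overlap lengths in [min_overlap, min(len1, len2)] are scored; the
    smallest mismatch ratio wins with ties broken toward the longest
    overlap. Returns None when even the best ratio exceeds the threshold.
    """
    rc2 = revcomp(mate2_seq)
    n1, n2 = len(mate1_seq), len(rc2)
    max_len = min(n1, n2)
    if max_len < min_overlap:
        return None
    a = np.frombuffer(mate1_seq.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(rc2.encode("ascii"), dtype=np.uint8)
    best: tuple[float, int, int] | None = None  # (ratio, -len, mismatches)
    for olen in range(min_overlap, max_len + 1):
        mm = int((a[n1 - olen :] != b[:olen]).sum())
        ratio = mm / olen
        key = (ratio, -olen)
        if best is None or key < best[:2]:
            best = (ratio, -olen, mm)
    ratio, neg_len, mm = best
    if ratio > max_mismatch_ratio:
        return None
    return OverlapResult(overlap_len=-neg_len, mismatches=mm, accepted=True)


def merge_consensus(pair: ReadPair, overlap: OverlapResult) -> MergedRead:
    """Collapse an overlapping pair into one error-corrected consensus.

    Non-overlap flanks are copied verbatim. Within the overlap, agreeing
    bases keep the higher of the two qualities; disagreeing positions take
    the higher-quality base with quality |q1 - q2| — low residual quality
    marks an unresolved conflict.
    """
    if not overlap.accepted:
        raise ValueError("merge_consensus requires an accepted overlap")
    rc2 = revcomp(pair.seq2)
    rq2 = pair.qual2[::-1].copy()
    n1 = len(pair.seq1)
    olen = overlap.overlap_len
    left_seq, left_q = pair.seq1[: n1 - olen], pair.qual1[: n1 - olen]
    right_seq, right_q = rc2[olen:], rq2[olen:]
    s1 = np.frombuffer(pair.seq1[n1 - olen :].encode("ascii"), dtype=np.uint8)
    s2 = np.frombuffer(rc2[:olen].encode("ascii"), dtype=np.uint8)
    q1 = pair.qual1[n1 - olen :].astype(np.int16)
    q2 = rq2[:olen].astype(np.int16)
    take1 = q1 >= q2
    cons = np.where(take1, s1, s2)
    agree = s1 == s2
    cq = np.where(agree, np.maximum(q1, q2), np.abs(q1 - q2))
    merged_seq = left_seq + cons.tobytes().decode("ascii") + right_seq
    merged_q = np.concatenate([left_q, cq.astype(np.int16), right_q])
    assert len(merged_seq) == len(pair.seq1) + len(pair.seq2) - olen
    return MergedRead(
        id=pair.id,
        sequence=merged_seq,
        qualities=merged_q,
        provenance="merged",
        overlap_len=olen,
    )


def stitch(pair: ReadPair) -> MergedRead:
    """Concatenate mate 1 and reverse-complemented mate 2 end-to-end."""
    seq = pair.seq1 + revcomp(pair.seq2)
    qual = np.concatenate([pair.qual1, pair.qual2[::-1]])
    return MergedRead(
        id=pair.id,
        sequence=seq,
        qualities=qual.astype(np.int16),
        provenance="stitched",
        junction=len(pair.seq1),
    )


@dataclass(frozen=True)
class PairingParams:
    min_overlap: int = 10
    max_mismatch_ratio: float = 0.25


def resolve_250(pair: ReadPair, params: PairingParams = PairingParams()) -> MergedRead:
    """250PE rule: consensus-merge when the mates overlap, else stitch."""
    ov = find_overlap(pair.seq1, pair.seq2, params.min_overlap, params.max_mismatch_ratio)
    if ov is not None:
        return merge_consensus(pair, ov)
    return stitch(pair)


def assemble_300(pair: ReadPair, params: PairingParams = PairingParams()) -> MergedRead | None:
    """300PE rule: consensus-merge, or None (rejected) without overlap."""
    ov = find_overlap(pair.seq1, pair.seq2, params.min_overlap, params.max_mismatch_ratio)
    if ov is None:
        return None
    return merge_consensus(pair, ov)


def pairing_stats(results: list[MergedRead | None]) -> dict:
    """Provenance accounting: merged/stitched/rejected counts and length stats."""
    merged = sum(1 for r in results if r is not None and r.provenance == "merged")
    stitched = sum(1 for r in results if r is not None and r.provenance == "stitched")
    rejected = sum(1 for r in results if r is None)
    lengths = np.array([len(r.sequence) for r in results if r is not None], dtype=float)
    return {
        "total": len(results),
        "merged": merged,
        "stitched": stitched,
        "rejected": rejected,
        "length_mean": float(lengths.mean()) if len(lengths) else 0.0,
        "length_sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
    }
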