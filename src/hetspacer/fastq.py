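"""Streaming paired FASTQ I/O (phred+33 only).

Reading goes through pysam's FastxFile, which handles plain and gzipped
files; records are validated and re-exposed as ReadPair objects carrying
integer phred vectors. Nothing here buffers whole files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pysam

MAX_PHRED = 60  # phred+33 chars '!'..']'; anything above flags +64 encoding


@dataclass
class ReadPair:
    """One mate pair with per-base qualities and processing state."""

    id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray
    state: str = "raw"  # raw | stripped | trimmed
    comment: str = ""

    def __post_init__(self):
        self.qual1 = np.asarray(self.qual1, dtype=np.int16)
        self.qual2 = np.asarray(self.qual2, dtype=np.int16)
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")
        for q in (self.qual1, self.qual2):
            if len(q) and (q.min() < 0 or q.max() > MAX_PHRED):
                raise ValueError(
                    f"read {self.id!r}: phred values outside [0, {MAX_PHRED}] "
                    "(is this phred+33?)"
                )
        if self.state not in ("raw", "stripped", "trimmed"):
            raise ValueError(f"bad state {self.state!r}")

    def with_state(self, state: str) -> "ReadPair":
        return replace(self, state=state)


def _decode_qual(qual_str: str, rid: str) -> np.ndarray:
    q = np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    if len(q) and (q.min() < 0 or q.max() > MAX_PHRED):
        raise ValueError(
            f"read {rid!r}: quality characters outside the phred+33 range "
            f"'!'..'{chr(33 + MAX_PHRED)}' (phred+64 input?)"
        )
    return q


def _strip_mate_suffix(name: str) -> str:
    for suf in ("/1", "/2"):
        if name.endswith(suf):
            return name[:-2]
    return name


def read_paired_fastq(path1, path2) -> Iterator[ReadPair]:
    """Stream lockstep ReadPairs from two FASTQ files.

    Raises on mate-count mismatch, malformed records, phred+64-looking
    qualities, or read-id disagreement, always naming the record number.
    """
    with pysam.FastxFile(str(path1)) as fh1, pysam.FastxFile(str(path2)) as fh2:
        recno = 0
        it1, it2 = iter(fh1), iter(fh2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            recno += 1
            if r1 is None or r2 is None:
                short = path1 if r1 is None else path2
                raise ValueError(f"record {recno}: {short} has fewer records than its mate")
            if r1.quality is None or r2.quality is None:
                raise ValueError(f"record {recno}: not FASTQ (missing qualities)")
            n1, n2 = _strip_mate_suffix(r1.name), _strip_mate_suffix(r2.name)
            if n1 != n2:
                raise ValueError(f"record {recno}: id mismatch {r1.name!r} vs {r2.name!r}")
            yield ReadPair(
                id=n1,
                seq1=r1.sequence.upper(),
                seq2=r2.sequence.upper(),
                qual1=_decode_qual(r1.quality, n1),
                qual2=_decode_qual(r2.quality, n2),
            )


def _open_out(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


class FastqPairWriter:
    """Write mate 1 / mate 2 records to a pair of (optionally gzipped) files."""

    def __init__(self, path1, path2):
        self._fh1 = _open_out(path1)
        self._fh2 = _open_out(path2)
        self.count = 0

    def write(self, pair: ReadPair) -> None:
        comment = f" {pair.comment}" if pair.comment else ""
        for fh, seq, qual in ((self._fh1, pair.seq1, pair.qual1), (self._fh2, pair.seq2, pair.qual2)):
            fh.write(f"@{pair.id}{comment}\n{seq}\n+\n{encode_qual(qual)}\n")
        self.count += 1

    def close(self) -> None:
        self._fh1.close()
        self._fh2.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class FastqWriter:
    """Write single-end (merged/stitched) records."""

    def __init__(self, path):
        self._fh = _open_out(path)
        self.count = 0

    def write(self, rid: str, seq: str, qual: np.ndarray, comment: str = "") -> None:
        c = f" {comment}" if comment else ""
        self._fh.write(f"@{rid}{c}\n{seq}\n+\n{encode_qual(qual)}\n")
        self.count += 1

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def encode_qual(q: np.ndarray) -> str:
    return (np.asarray(q, dtype=np.uint8) + 33).tobytes().decode("ascii")
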