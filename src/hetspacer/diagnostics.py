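"""Per-cycle composition/quality diagnostics and run-level summaries.

These are the numeric views that show whether a pooled library is base-
balanced cycle by cycle — the property the in-line index + heterogeneity
spacer design exists to create. Low per-cycle diversity in early MiSeq
cycles breaks cluster identification and phasing calibration, so the
quantity of interest is how far each cycle's base fractions sit from the
ideal 0.25 each.

All figures derive from the serialized matrices; the numeric artifact, not
any plot, is the test surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASE_COLS = ["A", "C", "G", "T", "N"]


@dataclass
class BaseCompositionMatrix:
    """Per-cycle fractions of A/C/G/T/N across a read set or predicted design.

    ``fractions`` is indexed by 1-based cycle with columns A, C, G, T, N;
    each row sums to 1 over the reads (or probability mass) still extending
    to that cycle. ``n_reads`` holds the per-cycle denominator.
    """

    fractions: pd.DataFrame
    n_reads: np.ndarray

    def __post_init__(self):
        if list(self.fractions.columns) != BASE_COLS:
            raise ValueError(f"columns must be {BASE_COLS}")
        self.n_reads = np.asarray(self.n_reads, dtype=float)
        if len(self.n_reads) != len(self.fractions):
            raise ValueError("n_reads length != number of cycles")
        rows = self.fractions.to_numpy().sum(axis=1)
        live = self.n_reads > 0
        if not np.allclose(rows[live], 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1 +/- 1e-9")

    @property
    def n_cycles(self) -> int:
        return len(self.fractions)

    def to_tsv(self, path) -> None:
        out = self.fractions.copy()
        out["n_reads"] = self.n_reads
        out.to_csv(path, sep="\t", index_label="cycle")

    @classmethod
    def from_tsv(cls, path) -> "BaseCompositionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cycle")
        return cls(df[BASE_COLS], df["n_reads"].to_numpy())


def base_composition(reads: list[str], n_cycles: int) -> BaseCompositionMatrix:
    """Observed fraction of each base at each cycle.

    Reads shorter than a cycle are excluded from that cycle's denominator.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not reads:
        raise ValueError("base_composition: empty read set")
    counts = np.zeros((n_cycles, len(BASE_COLS)), dtype=float)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASE_COLS):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    for seq in reads:
        arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][:n_cycles]
        if (arr < 0).any():
            bad = sorted(set(seq.upper()) - set(BASE_COLS))
            raise ValueError(f"unexpected characters in read: {bad}")
        np.add.at(counts, (np.arange(len(arr)), arr), 1.0)
    n_reads = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_reads[:, None] > 0, counts / n_reads[:, None], 0.0)
    df = pd.DataFrame(frac, columns=BASE_COLS, index=pd.RangeIndex(1, n_cycles + 1, name="cycle"))
    return BaseCompositionMatrix(df, n_reads)


def quality_profile(quals: list[np.ndarray]) -> pd.Series:
    """Mean phred quality per cycle over reads extending to that cycle."""
    if not quals:
        raise ValueError("quality_profile: empty input")
    n_cycles = max(len(q) for q in quals)
    total = np.zeros(n_cycles)
    count = np.zeros(n_cycles)
    for q in quals:
        q = np.asarray(q, dtype=float)
        total[: len(q)] += q
        count[: len(q)] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.Series(mean, index=pd.RangeIndex(1, n_cycles + 1, name="cycle"), name="mean_q")


def balance_score(matrix: BaseCompositionMatrix, cycles: range | None = None) -> float:
    """Max over the given cycles and the four real bases of |fraction - 0.25|.

    0 means perfectly balanced; 0.75 is the point-mass worst case. Cycles
    are 1-based; defaults to every cycle with a non-zero denominator.
    """
    frac = matrix.fractions[["A", "C", "G", "T"]].to_numpy()
    live = matrix.n_reads > 0
    mask = live.copy()
    if cycles is not None:
        sel = np.zeros(matrix.n_cycles, dtype=bool)
        idx = np.asarray(list(cycles)) - 1
        if (idx < 0).any() or (idx >= matrix.n_cycles).any():
            raise ValueError("cycles out of range for matrix")
        sel[idx] = True
        mask &= sel
    if not mask.any():
        raise ValueError("no assessed cycle has reads")
    return float(np.abs(frac[mask] - 0.25).max())


@dataclass
class RunSummary:
    """Consolidated run-level statistics row for one run/pool."""

    run_id: str
    total_pairs: int
    pairs_after_qc: int
    reads_after_qc: tuple[int, int]
    median_length: tuple[float, float]
    mean_length: tuple[float, float]
    sd_length: tuple[float, float]
    assembled: int | None = None
    assembled_pct: float | None = None

    def to_dict(self) -> dict:
        d = {
            "run_id": self.run_id,
            "total_pairs": self.total_pairs,
            "pairs_after_qc": self.pairs_after_qc,
            "reads_after_qc_r1": self.reads_after_qc[0],
            "reads_after_qc_r2": self.reads_after_qc[1],
            "median_length_r1": self.median_length[0],
            "median_length_r2": self.median_length[1],
            "mean_length_r1": self.mean_length[0],
            "mean_length_r2": self.mean_length[1],
            "sd_length_r1": self.sd_length[0],
            "sd_length_r2": self.sd_length[1],
        }
        if self.assembled is not None:
            d["assembled"] = self.assembled
            d["assembled_pct"] = self.assembled_pct
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunSummary":
        return cls(
            run_id=d["run_id"],
            total_pairs=int(d["total_pairs"]),
            pairs_after_qc=int(d["pairs_after_qc"]),
            reads_after_qc=(int(d["reads_after_qc_r1"]), int(d["reads_after_qc_r2"])),
            median_length=(float(d["median_length_r1"]), float(d["median_length_r2"])),
            mean_length=(float(d["mean_length_r1"]), float(d["mean_length_r2"])),
            sd_length=(float(d["sd_length_r1"]), float(d["sd_length_r2"])),
            assembled=int(d["assembled"]) if "assembled" in d else None,
            assembled_pct=float(d["assembled_pct"]) if "assembled_pct" in d else None,
        )


def run_summary(demux_report, qc_report, pairing_stats=None, run_id: str = "run") -> RunSummary:
    """Consolidate stage reports into one run-level summary.

    ``demux_report`` and ``qc_report`` must come from the same run; if both
    carry a run id they must agree. Lengths are computed from the post-QC
    reads recorded in the QC report.
    """
    for rep in (demux_report, qc_report):
        rid = getattr(rep, "run_id", None)
        if rid is not None and rid != run_id:
            raise ValueError(f"mismatched run ids: {rid!r} != {run_id!r}")
    len1 = np.asarray(qc_report.final_lengths_r1, dtype=float)
    len2 = np.asarray(qc_report.final_lengths_r2, dtype=float)

    def stats(x):
        if len(x) == 0:
            return 0.0, 0.0, 0.0
        return float(np.median(x)), float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    med1, mean1, sd1 = stats(len1)
    med2, mean2, sd2 = stats(len2)
    assembled = assembled_pct = None
    if pairing_stats is not None:
        assembled = int(pairing_stats.get("merged", 0))
        total = int(pairing_stats.get("total", 0))
        assembled_pct = 100.0 * assembled / total if total else 0.0
    return RunSummary(
        run_id=run_id,
        total_pairs=demux_report.total_pairs,
        pairs_after_qc=qc_report.pairs_out,
        reads_after_qc=(len(len1), len(len2)),
        median_length=(med1, med2),
        mean_length=(mean1, mean2),
        sd_length=(sd1, sd2),
        assembled=assembled,
        assembled_pct=assembled_pct,
    )
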