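"""Index-set, spacer-set and sample-layout design for phase-staggered
dual-indexed amplicon libraries.

The architecture being designed: every amplification primer carries, in
sequencing order, a flow-cell linker (never sequenced in-line), a 12 bp
sample index, a 0-7 bp heterogeneity spacer, and the gene-specific primer.
Reads therefore open with 12 index cycles whose base composition is set by
the chosen index set, followed by spacer cycles that stagger the conserved
primer bases across 8 distinct offsets. A 24-forward x 24-reverse index
design addresses 576 samples.

Index selection is a greedy build on the balance objective

    balance_deviation = max over cycles 1..12 and bases of |freq - 0.25|

subject to a minimum pairwise Hamming distance, with seeded random restarts
and a pairwise-swap polish; the spacer set is searched under the constraint
that spacer length stays recoverable from sequence alone (no spacer+primer
string may be a prefix of another).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import BASES, IUPAC
from .diagnostics import BASE_COLS, BaseCompositionMatrix
from .samplesheet import (
    INDEX_LEN,
    MAX_SPACER_LEN,
    SampleRow,
    SampleSheet,
    validate_index,
    validate_primer,
    validate_spacer,
)

#: Standard V3-V4 gene primers (341F / 805R), 17 and 21 bp.
DEFAULT_PRIMER_FWD = "CCTACGGGNGGCWGCAG"
DEFAULT_PRIMER_REV = "GACTACHVGGGTATCTAATCC"

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Spacer:
    """A 0-7 bp heterogeneity spacer."""

    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", validate_spacer(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerConstruct:
    """One amplification primer: linker + index + spacer + gene primer.

    The linker sits upstream of the sequencing start; the in-line sequenced
    prefix of a read from this construct is index + spacer + gene_primer.
    """

    linker: str
    index: str
    spacer: Spacer
    gene_primer: str
    orientation: str

    def __post_init__(self):
        object.__setattr__(self, "index", validate_index(self.index))
        object.__setattr__(self, "gene_primer", validate_primer(self.gene_primer))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")

    @property
    def sequenced_prefix(self) -> str:
        return self.index + self.spacer.sequence + self.gene_primer

    @property
    def full_sequence(self) -> str:
        return self.linker + self.sequenced_prefix


def build_primer_construct(linker, index, spacer, gene_primer, orientation) -> PrimerConstruct:
    if isinstance(spacer, str):
        spacer = Spacer(spacer)
    return PrimerConstruct(linker, index, spacer, gene_primer, orientation)


@dataclass
class IndexSet:
    """A chosen set of 12 bp indices with its design metrics."""

    members: list[str]
    min_pairwise_hamming: int
    balance_deviation: float

    def __post_init__(self):
        self.members = [validate_index(m) for m in self.members]
        if len(set(self.members)) != len(self.members):
            raise ValueError("index set members must be unique")
        if not 0.0 <= self.balance_deviation <= 0.75 + 1e-12:
            raise ValueError("balance_deviation out of [0, 0.75]")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def _encode_indices(indices: list[str]) -> np.ndarray:
    """(n, 12) integer-coded index matrix."""
    return np.array([[_BASE_IDX[b] for b in s] for s in indices], dtype=np.int8)


def _onehot(codes: np.ndarray) -> np.ndarray:
    """(n, 12, 4) one-hot tensor."""
    return np.eye(4)[codes]


def balance_deviation(indices: list[str]) -> float:
    """Max over cycles 1-12 and bases of |frequency - 0.25| for a set."""
    oh = _onehot(_encode_indices(indices))
    freq = oh.mean(axis=0)
    return float(np.abs(freq - 0.25).max())


def _pairwise_hamming(codes: np.ndarray) -> np.ndarray:
    return (codes[:, None, :] != codes[None, :, :]).sum(axis=2)


def min_pairwise_hamming(indices: list[str]) -> int:
    codes = _encode_indices(indices)
    d = _pairwise_hamming(codes)
    n = len(indices)
    if n < 2:
        return INDEX_LEN
    return int(d[np.triu_indices(n, k=1)].min())


def design_index_set(
    candidates: list[str],
    k: int,
    min_hamming: int = 3,
    seed: int = 0,
    n_restarts: int = 32,
) -> IndexSet:
    """Pick ``k`` indices from ``candidates`` with pairwise Hamming distance
    >= ``min_hamming``, minimizing the per-cycle balance deviation.

    Greedy forward construction (ties broken by lexicographic order) from
    seeded starting points — some with randomized near-best choices — then a
    local-search polish exchanging one or two members at a time. With the
    default min_hamming of 3, any single sequencing error in an index is
    uniquely correctable.
    """
    candidates = [validate_index(c) for c in candidates]
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate indices must be unique")
    if len(candidates) < k:
        raise ValueError(f"need at least k={k} candidates, got {len(candidates)}")
    if k % 4 != 0:
        warnings.warn(
            f"k={k} is not a multiple of 4: a balance deviation of 0 is unattainable",
            stacklevel=2,
        )
    order = np.array(sorted(range(len(candidates)), key=lambda i: candidates[i]))
    cand = [candidates[i] for i in order]  # lexicographic order for tie-breaks
    codes = _encode_indices(cand)
    oh = _onehot(codes)  # (n, 12, 4)
    dist = _pairwise_hamming(codes)
    compat = dist >= min_hamming
    n = len(cand)
    rng = np.random.default_rng(seed)

    def objective(sel: list[int]) -> float:
        freq = oh[sel].mean(axis=0)
        return float(np.abs(freq - 0.25).max())

    def greedy(start: int, noisy: bool = False) -> list[int] | None:
        sel = [start]
        ok = compat[start].copy()
        ok[start] = False
        counts = oh[start].copy()
        while len(sel) < k:
            avail = np.flatnonzero(ok)
            if len(avail) == 0:
                return None
            m = len(sel) + 1
            objs = np.abs((counts[None] + oh[avail]) / m - 0.25).max(axis=(1, 2))
            if noisy:
                near = avail[objs <= objs.min() + 0.05]
                best = int(rng.choice(near))
            else:
                # lexicographic tie-break: candidates sorted, argmin takes first
                best = int(avail[int(np.argmin(objs))])
            sel.append(best)
            counts += oh[best]
            ok &= compat[best]
            ok[best] = False
        return sel

    # 2-swap moves are quadratic in the free pool; cap the work per pass
    use_two_swap = k * k * (n - k) * (n - k) <= 300_000

    def polish(sel: list[int]) -> list[int]:
        sel = list(sel)
        improved = True
        while improved:
            improved = False
            cur = objective(sel)
            for pos in range(k):
                others = [s for i, s in enumerate(sel) if i != pos]
                ok = np.logical_and.reduce(compat[others]) if others else np.ones(n, bool)
                ok[sel] = False
                for cand_i in np.flatnonzero(ok):
                    trial = others + [int(cand_i)]
                    if objective(trial) < cur - 1e-12:
                        sel = trial
                        cur = objective(sel)
                        improved = True
                        break
                if improved:
                    break
            if improved or not use_two_swap:
                continue
            for p1, p2 in itertools.combinations(range(k), 2):
                others = [s for i, s in enumerate(sel) if i not in (p1, p2)]
                ok = np.logical_and.reduce(compat[others]) if others else np.ones(n, bool)
                ok[sel] = False
                free = np.flatnonzero(ok)
                for c1, c2 in itertools.combinations(free, 2):
                    if not compat[c1, c2]:
                        continue
                    trial = others + [int(c1), int(c2)]
                    if objective(trial) < cur - 1e-12:
                        sel = trial
                        cur = objective(sel)
                        improved = True
                        break
                if improved:
                    break
        return sel

    best_sel, best_obj = None, np.inf

    def consider(sel):
        nonlocal best_sel, best_obj
        if sel is None:
            return
        sel = polish(sel)
        obj = objective(sel)
        key = (obj, tuple(sorted(cand[i] for i in sel)))
        if best_sel is None or key < (best_obj, tuple(sorted(cand[i] for i in best_sel))):
            best_sel, best_obj = sel, obj

    for s in range(min(n, n_restarts)):
        consider(greedy(s))
        if best_obj <= 1e-12:
            break
    if best_obj > 1e-12:
        for _ in range(n_restarts):
            consider(greedy(int(rng.integers(n)), noisy=True))
            if best_obj <= 1e-12:
                break
    if best_sel is None:
        raise ValueError(
            f"infeasible: no {k}-subset of {n} candidates has pairwise "
            f"Hamming distance >= {min_hamming}"
        )
    members = sorted(cand[i] for i in best_sel)
    return IndexSet(
        members=members,
        min_pairwise_hamming=min_pairwise_hamming(members),
        balance_deviation=best_obj,
    )


def _iupac_compatible(a: str, b: str) -> bool:
    """True when two IUPAC strings could describe the same concrete sequence
    over their common positions (a no longer than b)."""
    return all(set(IUPAC[x]) & set(IUPAC[y]) for x, y in zip(a.upper(), b.upper()))


def spacer_prefix_conflict(short: str, long: str, gene_primer: str) -> bool:
    """Would ``short``+primer be indistinguishable from a prefix of
    ``long``+primer in a real read?

    Checked under IUPAC compatibility, so a degenerate primer base conflicts
    with any base in its expansion. This is the condition that makes spacer
    length recoverable from sequence alone.
    """
    a = short + gene_primer
    b = long + gene_primer
    if len(a) > len(b):
        raise ValueError("short spacer must not be longer than long spacer")
    return _iupac_compatible(a, b[: len(a)])


def _spacer_block_deviation(spacers: list[str]) -> float:
    """Balance deviation of the pooled spacer block, averaged over cycles.

    At spacer cycle m only samples whose spacer extends past m contribute.
    The per-cycle score is the max base deviation from 0.25; cycles are
    averaged rather than maxed because the deepest cycle is always served
    by a single spacer and would otherwise saturate the objective.
    """
    max_len = max((len(s) for s in spacers), default=0)
    if max_len == 0:
        return 0.0
    per_cycle = []
    for m in range(max_len):
        contrib = [s[m] for s in spacers if len(s) > m]
        if not contrib:
            continue
        per_cycle.append(
            max(abs(contrib.count(b) / len(contrib) - 0.25) for b in BASES)
        )
    return float(np.mean(per_cycle)) if per_cycle else 0.0


def design_spacer_set(
    lengths=range(MAX_SPACER_LEN + 1),
    gene_primer: str = DEFAULT_PRIMER_FWD,
    seed: int = 0,
    n_restarts: int = 16,
) -> list[Spacer]:
    """One spacer per requested length, mutually prefix-distinguishable.

    For every pair of spacers the shorter spacer + primer must not be a
    prefix (under IUPAC matching) of the longer spacer + primer; otherwise
    the spacer length could not be recovered from the read. Among feasible
    sets, a seeded randomized search minimizes the balance deviation of the
    pooled spacer block.
    """
    lengths = sorted(set(int(x) for x in lengths))
    if any(l < 0 or l > MAX_SPACER_LEN for l in lengths):
        raise ValueError(f"spacer lengths must lie in [0, {MAX_SPACER_LEN}]")
    gene_primer = validate_primer(gene_primer)
    rng = np.random.default_rng(seed)

    def candidates_for(length: int) -> list[str]:
        if length == 0:
            return [""]
        if length <= 4:
            return ["".join(p) for p in itertools.product(BASES, repeat=length)]
        # sample without exhaustive enumeration at longer lengths
        picks = {
            "".join(BASES[i] for i in rng.integers(4, size=length)) for _ in range(1024)
        }
        return sorted(picks)

    best: list[str] | None = None
    best_dev = np.inf
    for _ in range(n_restarts):
        chosen: list[str] = []
        for length in lengths:
            cands = candidates_for(length)
            rng.shuffle(cands)
            scored: list[tuple[float, str]] = []
            for c in cands:
                ok = True
                for prev in chosen:
                    lo, hi = sorted((prev, c), key=len)
                    if len(lo) == len(hi):
                        ok = lo != hi
                    else:
                        ok = not spacer_prefix_conflict(lo, hi, gene_primer)
                    if not ok:
                        break
                if ok:
                    scored.append((_spacer_block_deviation(chosen + [c]), c))
            if not scored:
                raise ValueError(
                    f"no feasible spacer of length {length} for primer {gene_primer!r}"
                )
            scored.sort(key=lambda t: (t[0], t[1]))
            chosen.append(scored[0][1])
        dev = _spacer_block_deviation(chosen)
        if dev < best_dev - 1e-12:
            best, best_dev = chosen, dev
    assert best is not None
    return [Spacer(s) for s in best]


def assign_samples(
    sample_ids: list[str],
    fwd_set: IndexSet,
    rev_set: IndexSet,
    spacers: list[Spacer],
    seed: int = 0,
    gene_primer_fwd: str = DEFAULT_PRIMER_FWD,
    gene_primer_rev: str = DEFAULT_PRIMER_REV,
) -> SampleSheet:
    """Lay out samples on the fwd x rev index grid with balanced spacers.

    Every sample gets a unique (fwd, rev) index pair and the same spacer
    length on both mates, cycled through the spacer set so per-length counts
    differ by at most 1. Pairs follow a diagonal (Latin-square) walk of the
    grid so that each forward and each reverse index is used as evenly as
    possible even when only part of the grid is populated — a random subset
    of cells would concentrate some indices and ruin the per-cycle balance
    the index set was optimized for. The seed permutes index labels, not
    the walk, so layouts stay balanced and deterministic.
    """
    n = len(sample_ids)
    kf, kr = len(fwd_set), len(rev_set)
    capacity = kf * kr
    if n > capacity:
        raise ValueError(
            f"too many samples: {n} requested but {kf}x{kr} "
            f"indices address only {capacity}"
        )
    if len(set(sample_ids)) != n:
        raise ValueError("sample ids must be unique")
    if not spacers:
        raise ValueError("need at least one spacer")
    rng = np.random.default_rng(seed)
    fwd = [fwd_set.members[i] for i in rng.permutation(kf)]
    rev = [rev_set.members[i] for i in rng.permutation(kr)]
    spacer_sorted = sorted(spacers, key=lambda s: s.length)
    rows = []
    for t, sid in enumerate(sample_ids):
        block, i = divmod(t, kf)
        f = fwd[i]
        r = rev[(i + block) % kr]
        sp = spacer_sorted[t % len(spacer_sorted)]
        rows.append(SampleRow(sid, f, r, sp.sequence, sp.sequence))
    return SampleSheet(rows=rows, gene_primer_fwd=gene_primer_fwd, gene_primer_rev=gene_primer_rev)


def predicted_cycle_composition(
    sheet: SampleSheet,
    template_pool: list[str],
    n_cycles: int,
) -> BaseCompositionMatrix:
    """Expected per-cycle base fractions for mate 1 of a pooled run.

    Assumes equal sample abundance and, past the primer, templates drawn
    uniformly from ``template_pool``. Cycles 1-12 are determined by the
    indices; from cycle 13 each sample contributes its spacer, then the
    gene primer (degenerate codes spread uniformly over their expansion),
    then the template mix — offset per sample by its spacer length, which
    is what staggers the conserved primer bases across cycles.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if len(sheet) == 0:
        raise ValueError("predicted_cycle_composition: empty sample sheet")
    weights = np.zeros((n_cycles, len(BASE_COLS)))
    col = {b: i for i, b in enumerate(BASE_COLS)}
    n_templates = len(template_pool)
    w_sample = 1.0 / len(sheet)
    for row in sheet:
        prefix = row.fwd_index + row.fwd_spacer
        for c, b in enumerate(prefix[:n_cycles]):
            weights[c, col[b]] += w_sample
        off = len(prefix)
        for j, p in enumerate(sheet.gene_primer_fwd):
            c = off + j
            if c >= n_cycles:
                break
            expansion = IUPAC[p]
            for b in expansion:
                weights[c, col[b]] += w_sample / len(expansion)
        off += len(sheet.gene_primer_fwd)
        if n_templates:
            w_tmpl = w_sample / n_templates
            for tmpl in template_pool:
                for j, b in enumerate(tmpl[: max(0, n_cycles - off)]):
                    weights[off + j, col[b.upper()]] += w_tmpl
    totals = weights.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(totals[:, None] > 0, weights / np.maximum(totals[:, None], 1e-300), 0.0)
    df = pd.DataFrame(frac, columns=BASE_COLS, index=pd.RangeIndex(1, n_cycles + 1, name="cycle"))
    return BaseCompositionMatrix(df, totals)
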