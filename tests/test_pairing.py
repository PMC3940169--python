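"""Overlap detection, consensus merging and stitching."""

import numpy as np
import pytest

import hetspacer as hs
from hetspacer._seq import revcomp


def oracle_find_overlap(seq1, seq2, min_overlap=10, max_ratio=0.25):
    """Exhaustive offset scan with plain string comparisons."""
    rc2 = revcomp(seq2)
    best = None
    for olen in range(min_overlap, min(len(seq1), len(rc2)) + 1):
        tail = seq1[len(seq1) - olen :]
        head = rc2[:olen]
        mm = sum(x != y for x, y in zip(tail, head))
        ratio = mm / olen
        if best is None or (ratio, -olen) < (best[0], -best[1]):
            best = (ratio, olen, mm)
    if best is None or best[0] > max_ratio:
        return None
    return best[1], best[2]


def make_overlapping_pair(rng, left=80, olen=90, right=85, err=0.0):
    """True amplicon fragment read from both ends with a known overlap."""
    total = left + olen + right
    frag = "".join("ACGT"[i] for i in rng.integers(4, size=total))
    r1 = frag[: left + olen]
    r2 = revcomp(frag[left:])
    if err > 0:
        r1 = _mutate(r1, rng, err)
        r2 = _mutate(r2, rng, err)
    q = np.full(len(r1), 35)
    return hs.ReadPair("p", r1, r2, q, np.full(len(r2), 35)), frag, olen


def _mutate(seq, rng, rate):
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        chars[i] = "ACGT"[(("ACGT".index(chars[i])) + 1 + rng.integers(3)) % 4]
    return "".join(chars)


class TestFindOverlap:
    def test_identical_sequences_full_overlap(self):
        seq = "ACGTTGCAACGTTGCA" * 5
        ov = hs.find_overlap(seq, revcomp(seq))
        assert ov.overlap_len == len(seq) and ov.mismatches == 0

    def test_true_90bp_overlap_recovered_with_2pct_errors(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            pair, _, olen = make_overlapping_pair(rng, err=0.02)
            ov = hs.find_overlap(pair.seq1, pair.seq2)
            if ov is not None and ov.overlap_len == olen:
                hits += 1
        assert hits >= 48  # occasional error placement can shift the optimum

    def test_unrelated_sequences_rejected(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = "".join("ACGT"[i] for i in rng.integers(4, size=150))
            b = "".join("ACGT"[i] for i in rng.integers(4, size=150))
            assert hs.find_overlap(a, b) is None

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equivalence_with_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(250):
            if rng.random() < 0.5:
                pair, _, _ = make_overlapping_pair(
                    rng,
                    left=int(rng.integers(0, 40)),
                    olen=int(rng.integers(12, 80)),
                    right=int(rng.integers(0, 40)),
                    err=float(rng.random() * 0.1),
                )
                a, b = pair.seq1, pair.seq2
            else:
                a = "".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(15, 120)))
                b = "".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(15, 120)))
            got = hs.find_overlap(a, b)
            want = oracle_find_overlap(a, b)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.overlap_len, got.mismatches) == want

    def test_too_short_for_min_overlap(self):
        assert hs.find_overlap("ACGTA", "ACGTA") is None


class TestMergeConsensus:
    def _pair(self, s1, s2, q1, q2):
        return hs.ReadPair("m", s1, s2, np.asarray(q1), np.asarray(q2))

    def test_agreement_takes_max_quality(self):
        frag = "ACGTACGTACGTACGTACGT"
        r1, r2 = frag, revcomp(frag)
        pair = self._pair(r1, r2, np.full(20, 30), np.full(20, 35))
        ov = hs.find_overlap(r1, r2)
        merged = hs.merge_consensus(pair, ov)
        assert merged.sequence == frag
        assert (merged.qualities == 35).all()

    def test_disagreement_takes_higher_base_with_quality_difference(self):
        # 20-base overlap; one disagreeing position in the middle
        frag = "ACGTACGTACGTACGTACGT"
        r1 = frag[:10] + "A" + frag[11:]
        r2 = revcomp(frag)
        q1 = np.full(20, 35)
        q2 = np.full(20, 20)
        pair = self._pair(r1, r2, q1, q2)
        ov = hs.find_overlap(r1, r2, min_overlap=10, max_mismatch_ratio=0.25)
        merged = hs.merge_consensus(pair, ov)
        assert merged.sequence[10] == "A"  # mate 1 wins at Q35 vs Q20
        assert merged.qualities[10] == 15  # |35 - 20|

    def test_merged_length_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pair, frag, olen = make_overlapping_pair(
                rng,
                left=int(rng.integers(5, 60)),
                olen=int(rng.integers(15, 90)),
                right=int(rng.integers(5, 60)),
            )
            ov = hs.find_overlap(pair.seq1, pair.seq2)
            merged = hs.merge_consensus(pair, ov)
            assert len(merged.sequence) == len(pair.seq1) + len(pair.seq2) - ov.overlap_len

    def test_error_free_merge_reproduces_fragment(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pair, frag, _ = make_overlapping_pair(rng)
            merged = hs.assemble_300(pair)
            assert merged.sequence == frag

    def test_260_259_mates_with_90_overlap_merge_to_429(self):
        rng = np.random.default_rng(9)
        frag = "".join("ACGT"[i] for i in rng.integers(4, size=429))
        r1 = frag[:260]
        r2 = revcomp(frag[429 - 259 :])
        q = np.full(260, 35)
        pair = hs.ReadPair("x", r1, r2, q, q[:259])
        merged = hs.assemble_300(pair)
        assert len(merged.sequence) == 260 + 259 - 90 == 429


class TestStitch:
    def test_two_10_base_mates_stitch_to_20_with_junction(self):
        p = hs.ReadPair("s", "ACGTACGTAC", "TTTTTTTTTT", np.full(10, 30), np.full(10, 12))
        out = hs.stitch(p)
        assert len(out.sequence) == 20
        assert out.junction == 10
        assert out.sequence == "ACGTACGTAC" + "AAAAAAAAAA"
        assert list(out.qualities) == [30] * 10 + [12] * 10
        assert "junction=10" in out.header_comment()

    def test_revcomp_involution(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = "".join("ACGT"[i] for i in rng.integers(4, size=40))
            b = "".join("ACGT"[i] for i in rng.integers(4, size=35))
            qa, qb = np.full(40, 30), np.full(35, 25)
            fwd = hs.stitch(hs.ReadPair("f", a, b, qa, qb))
            swapped = hs.stitch(hs.ReadPair("r", b, a, qb, qa))
            assert swapped.sequence == revcomp(fwd.sequence)


class TestResolve:
    def test_250pe_full_length_pairs_are_stitched(self, clean_run_250, sheet8):
        pairs, truth, _ = clean_run_250
        by_id = {r.read_id: r for r in truth.itertuples()}
        stitched = merged = 0
        for p in pairs[:100]:
            row = sheet8.get(by_id[p.id].sample_id)
            s = hs.strip_prefix(p, row, sheet8.gene_primer_fwd, sheet8.gene_primer_rev)
            out = hs.resolve_250(s)
            if out.provenance == "stitched":
                stitched += 1
            else:
                merged += 1
        # 469 bp amplicon leaves no true overlap for 250 bp mates
        assert stitched + merged == 100
        assert stitched >= 95

    def test_overlapping_short_amplicon_is_merged(self):
        rng = np.random.default_rng(13)
        pair, frag, _ = make_overlapping_pair(rng, left=40, olen=60, right=40)
        out = hs.resolve_250(pair)
        assert out.provenance == "merged"
        assert out.sequence == frag

    def test_provenance_counts_conserve(self, clean_run_250, sheet8):
        pairs, truth, _ = clean_run_250
        by_id = {r.read_id: r for r in truth.itertuples()}
        results = []
        for p in pairs[:60]:
            row = sheet8.get(by_id[p.id].sample_id)
            s = hs.strip_prefix(p, row, sheet8.gene_primer_fwd, sheet8.gene_primer_rev)
            results.append(hs.resolve_250(s))
        stats = hs.pairing.pairing_stats(results)
        assert stats["merged"] + stats["stitched"] + stats["rejected"] == stats["total"]

    def test_stitched_junction_carries_no_primer(self, clean_run_250, sheet8):
        pairs, truth, _ = clean_run_250
        by_id = {r.read_id: r for r in truth.itertuples()}
        pf, pr = sheet8.gene_primer_fwd, sheet8.gene_primer_rev
        for p in pairs[:30]:
            row = sheet8.get(by_id[p.id].sample_id)
            s = hs.strip_prefix(p, row, pf, pr)
            out = hs.stitch(s)
            window = out.sequence[max(0, out.junction - 25) : out.junction + 25]
            assert "CCTACGGG" not in window  # fwd primer core
            assert revcomp("GACTAC") not in window[:25]


class TestAssemble300:
    def test_error_free_run_fully_assembled(self, clean_run_300, sheet8):
        pairs, truth, _ = clean_run_300
        by_id = {r.read_id: r for r in truth.itertuples()}
        n = ok = 0
        for p in pairs[:150]:
            row = sheet8.get(by_id[p.id].sample_id)
            s = hs.strip_prefix(p, row, sheet8.gene_primer_fwd, sheet8.gene_primer_rev)
            n += 1
            if hs.assemble_300(s) is not None:
                ok += 1
        assert ok == n

    def test_noisy_run_assembles_at_least_90pct(self, sheet8, templates):
        cfg = hs.SimConfig(seed=31, read_length=300, reads_per_sample=40,
                           contaminant_fraction=0.0)
        pairs, truth = hs.simulate_run(sheet8, templates, cfg)
        by_id = {r.read_id: r for r in truth.itertuples()}
        n = ok = 0
        lengths = []
        for p in pairs:
            row = sheet8.get(by_id[p.id].sample_id)
            try:
                s = hs.strip_prefix(p, row, sheet8.gene_primer_fwd, sheet8.gene_primer_rev)
            except hs.demux.PrimerMismatch:
                continue
            n += 1
            m = hs.assemble_300(s)
            if m is not None:
                ok += 1
                lengths.append(len(m.sequence))
        assert ok / n >= 0.90
        # assembled length sits at amplicon minus both primers (431 bp)
        assert abs(np.median(lengths) - 431) <= 2
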