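"""Sample sheets: the demultiplexing contract.

A sheet maps each sample to its forward/reverse 12 bp in-line index and its
forward/reverse heterogeneity spacer, plus the run-level gene primers. The
on-disk format is a QIIME-mapping-style TSV with columns

    SampleID  BarcodeSequenceFwd  BarcodeSequenceRev  SpacerFwd  SpacerRev
    LinkerPrimerSequence  ReversePrimer

where the primer columns repeat the run-level primers on every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import BASES, IUPAC

INDEX_LEN = 12
MAX_SPACER_LEN = 7

_COLUMNS = [
    "SampleID",
    "BarcodeSequenceFwd",
    "BarcodeSequenceRev",
    "SpacerFwd",
    "SpacerRev",
    "LinkerPrimerSequence",
    "ReversePrimer",
]


def validate_index(seq: str) -> str:
    """Check a 12 bp in-line index: exact length, unambiguous bases."""
    seq = seq.upper()
    if len(seq) != INDEX_LEN:
        raise ValueError(f"index must be {INDEX_LEN} bp, got {len(seq)}: {seq!r}")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"index contains ambiguous bases {sorted(bad)}: {seq!r}")
    return seq


def validate_spacer(seq: str) -> str:
    """Check a heterogeneity spacer: 0-7 bp, unambiguous bases."""
    seq = seq.upper()
    if len(seq) > MAX_SPACER_LEN:
        raise ValueError(f"spacer longer than {MAX_SPACER_LEN} bp: {seq!r}")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"spacer contains ambiguous bases {sorted(bad)}: {seq!r}")
    return seq


def validate_primer(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("gene primer must be non-empty")
    bad = set(seq) - set(IUPAC)
    if bad:
        raise ValueError(f"primer contains non-IUPAC characters {sorted(bad)}: {seq!r}")
    return seq


@dataclass(frozen=True)
class SampleRow:
    sample_id: str
    fwd_index: str
    rev_index: str
    fwd_spacer: str
    rev_spacer: str

    def __post_init__(self):
        object.__setattr__(self, "fwd_index", validate_index(self.fwd_index))
        object.__setattr__(self, "rev_index", validate_index(self.rev_index))
        object.__setattr__(self, "fwd_spacer", validate_spacer(self.fwd_spacer))
        object.__setattr__(self, "rev_spacer", validate_spacer(self.rev_spacer))


@dataclass
class SampleSheet:
    """Sample -> (indices, spacers) mapping plus run-level gene primers."""

    rows: list[SampleRow]
    gene_primer_fwd: str
    gene_primer_rev: str
    _by_barcode: dict[str, SampleRow] = field(init=False, repr=False)

    def __post_init__(self):
        self.gene_primer_fwd = validate_primer(self.gene_primer_fwd)
        self.gene_primer_rev = validate_primer(self.gene_primer_rev)
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        pairs = [(r.fwd_index, r.rev_index) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (fwd_index, rev_index) pairs in sheet")
        self._by_barcode = {r.fwd_index + r.rev_index: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def get(self, sample_id: str) -> SampleRow:
        for r in self.rows:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def exact_lookup(self, barcode: str) -> SampleRow | None:
        """O(1) lookup of a 24 bp dual barcode with zero mismatches."""
        return self._by_barcode.get(barcode)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(_COLUMNS) + "\n")
            for r in self.rows:
                fh.write(
                    "\t".join(
                        [
                            r.sample_id,
                            r.fwd_index,
                            r.rev_index,
                            r.fwd_spacer,
                            r.rev_spacer,
                            self.gene_primer_fwd,
                            self.gene_primer_rev,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def read(cls, path) -> "SampleSheet":
        """Strict parser: header must name exactly the expected columns."""
        rows: list[SampleRow] = []
        primers: set[tuple[str, str]] = set()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").lstrip("#")
            cols = header.split("\t")
            if cols != _COLUMNS:
                raise ValueError(
                    f"bad sample sheet header: expected {_COLUMNS}, got {cols}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != len(_COLUMNS):
                    raise ValueError(
                        f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(parts)}"
                    )
                sid, fidx, ridx, fsp, rsp, pf, pr = parts
                rows.append(SampleRow(sid, fidx, ridx, fsp, rsp))
                primers.add((pf.upper(), pr.upper()))
        if len(primers) > 1:
            raise ValueError(f"sheet mixes primer pairs: {sorted(primers)}")
        if not primers:
            raise ValueError("empty sample sheet")
        pf, pr = primers.pop()
        return cls(rows=rows, gene_primer_fwd=pf, gene_primer_rev=pr)
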