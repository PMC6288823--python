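"""Custom FASTQ filtering, masking, splitting, and barcode demultiplexing.

The filtering pipeline applies, in order:

1. discard reads containing an adapter fragment (any exact substring of
   length ≥ ``adapter_min_match`` of the forward/reverse adapter or their
   reverse complements);
2. discard reads containing a run of ≥ ``polyn_min`` N bases (checked on the
   raw read, before masking);
3. mask bases with Phred quality ≤ ``qual_mask_max`` to N;
4. trim leading and trailing Ns;
5. if two internal Ns are separated by fewer than ``split_gap_max`` non-N
   bases, excise the region between and including both Ns, split the read,
   and keep the longest piece (5' piece on ties);
6. discard reads with fewer than ``min_end_nonn`` contiguous non-N bases at
   either end, or shorter than ``min_len``.

Demultiplexing assigns a read to a library when its barcode prefix equals
the library barcode or differs from it by exactly one substitution
(a change to N counts as a substitution); prefixes matching zero or more
than one library are routed to ``undetermined``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadQCConfig:
    """Thresholds of the filtering pipeline (defaults follow the study design:
    50 bp single-end reads, Phred+33)."""

    polyn_min: int = 15
    qual_mask_max: int = 20
    min_len: int = 30
    min_end_nonn: int = 10
    split_gap_max: int = 20
    adapter_seqs: tuple[str, ...] = ()
    adapter_min_match: int = 12
    barcodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("polyn_min", "qual_mask_max", "min_len",
                     "min_end_nonn", "split_gap_max", "adapter_min_match"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        codes = list(self.barcodes.values())
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) < 3:
                    warnings.warn(
                        f"barcodes {a} and {b} are within Hamming distance 2; "
                        "single-mismatch demultiplexing may be ambiguous")

    def adapter_kmers(self) -> set[str]:
        k = self.adapter_min_match
        kmers: set[str] = set()
        for a in self.adapter_seqs:
            for s in (a, _revcomp(a)):
                kmers.update(s[i:i + k] for i in range(len(s) - k + 1))
        return kmers


@dataclass
class FilterOutcome:
    read_id: str | None
    fate: str                  # kept | discarded | split-kept
    reason: str                # clean | adapter | polyN | split | short | end_n
    final_sequence: str
    final_quals: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.fate == "discarded" and self.final_sequence:
            raise ValueError("discarded reads carry no sequence")


def _mask_low_quality(seq: str, quals: Sequence[int], threshold: int) -> str:
    return "".join("N" if q <= threshold else b for b, q in zip(seq, quals))


def _split_on_close_ns(seq: str, quals: Sequence[int],
                       gap_max: int) -> tuple[str, Sequence[int], bool]:
    """Excise every maximal cluster of ≥2 Ns whose neighbours are separated
    by < gap_max non-N bases, then keep the longest remaining piece."""
    n_pos = [i for i, b in enumerate(seq) if b == "N"]
    if len(n_pos) < 2:
        return seq, quals, False
    clusters: list[list[int]] = [[n_pos[0]]]
    for p in n_pos[1:]:
        if p - clusters[-1][-1] - 1 < gap_max:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    spans = [(c[0], c[-1]) for c in clusters if len(c) >= 2]
    if not spans:
        return seq, quals, False
    pieces: list[tuple[int, int]] = []
    cursor = 0
    for s, e in spans:
        if s > cursor:
            pieces.append((cursor, s))
        cursor = e + 1
    if cursor < len(seq):
        pieces.append((cursor, len(seq)))
    if not pieces:
        return "", [], True
    best = max(pieces, key=lambda p: (p[1] - p[0], -p[0]))  # longest; 5' on ties
    return seq[best[0]:best[1]], list(quals[best[0]:best[1]]), True


def filter_read(seq: str, quals: Sequence[int], config: ReadQCConfig,
                read_id: str | None = None) -> FilterOutcome:
    """Apply the full filtering pipeline to one read.  ``quals`` are Phred
    scores aligned with ``seq``."""
    if len(seq) != len(quals):
        raise ValueError("sequence and quality lengths differ")
    seq = seq.upper()

    kmers = config.adapter_kmers()
    if kmers:
        k = config.adapter_min_match
        if any(seq[i:i + k] in kmers for i in range(len(seq) - k + 1)):
            return FilterOutcome(read_id, "discarded", "adapter", "")

    if "N" * config.polyn_min in seq:
        return FilterOutcome(read_id, "discarded", "polyN", "")

    masked = _mask_low_quality(seq, quals, config.qual_mask_max)
    start = len(masked) - len(masked.lstrip("N"))
    stop = len(masked.rstrip("N"))
    if stop <= start:
        return FilterOutcome(read_id, "discarded", "short", "")
    trimmed, tquals = masked[start:stop], list(quals[start:stop])

    final, fquals, was_split = _split_on_close_ns(trimmed, tquals, config.split_gap_max)

    if len(final) < config.min_len:
        return FilterOutcome(read_id, "discarded", "short", "")
    m = config.min_end_nonn
    if "N" in final[:m] or "N" in final[-m:]:
        return FilterOutcome(read_id, "discarded", "end_n", "")
    fate = "split-kept" if was_split else "kept"
    reason = "split" if was_split else "clean"
    return FilterOutcome(read_id, fate, reason, final, tuple(fquals))


# ---------------------------------------------------------------------------
# demultiplexing

def _matches_single_change(prefix: str, barcode: str) -> bool:
    """True if prefix equals the barcode or differs by exactly one
    substitution (an N at the differing position counts)."""
    mismatches = sum(a != b for a, b in zip(prefix, barcode))
    return mismatches <= 1


def demultiplex(reads: Iterable[tuple[str, str, Sequence[int]]],
                barcodes: dict[str, str], strip_barcode: bool = True
                ) -> tuple[dict[str, list[tuple[str, str, list[int]]]], pd.Series]:
    """Assign reads to libraries by barcode prefix.

    Returns ``(per_library, stats)``: a dict mapping each library label (plus
    ``"undetermined"``) to its reads, and per-library read counts.  Reads
    whose prefix matches zero or ≥2 library codes under the single-change
    rule go to ``undetermined``.
    """
    if not barcodes:
        raise ValueError("at least one barcode is required")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have equal length")
    bc_len = lengths.pop()
    out: dict[str, list[tuple[str, str, list[int]]]] = {lib: [] for lib in barcodes}
    out["undetermined"] = []
    for read_id, seq, quals in reads:
        if len(seq) < bc_len:
            raise ValueError(f"{read_id}: read shorter than the barcode")
        prefix = seq[:bc_len].upper()
        hits = [lib for lib, bc in barcodes.items()
                if _matches_single_change(prefix, bc)]
        if len(hits) == 1:
            lib = hits[0]
            if strip_barcode:
                out[lib].append((read_id, seq[bc_len:], list(quals[bc_len:])))
            else:
                out[lib].append((read_id, seq, list(quals)))
        else:
            out["undetermined"].append((read_id, seq, list(quals)))
    stats = pd.Series({lib: len(v) for lib, v in out.items()}, name="reads")
    return out, stats


# ---------------------------------------------------------------------------
# FASTQ I/O and the end-to-end QC driver

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, sequence, phred qualities) from a Phred+33 FASTQ file."""
    from Bio import SeqIO
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])


def run_qc(reads: Iterable[tuple[str, str, Sequence[int]]],
           config: ReadQCConfig) -> tuple[dict[str, list[FilterOutcome]], pd.DataFrame]:
    """Demultiplex then filter; returns per-library outcomes and a tidy
    per-read outcome table.  Conservation holds: every input read appears
    exactly once (assigned, undetermined, or discarded)."""
    per_lib, _ = demultiplex(reads, config.barcodes)
    outcomes: dict[str, list[FilterOutcome]] = {}
    rows = []
    for lib, lib_reads in per_lib.items():
        outcomes[lib] = []
        for read_id, seq, quals in lib_reads:
            if lib == "undetermined":
                oc = FilterOutcome(read_id, "undetermined", "barcode", "")
            else:
                oc = filter_read(seq, quals, config, read_id=read_id)
            outcomes[lib].append(oc)
            rows.append((read_id, lib, oc.fate, oc.reason, len(oc.final_sequence)))
    table = pd.DataFrame(rows, columns=["read_id", "library", "fate", "reason",
                                        "final_length"])
    return outcomes, table
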