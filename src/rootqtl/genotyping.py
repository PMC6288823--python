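"""Chimeric reference construction and introgression verification from reads.

For each IL a *chimeric* transcriptome is built: the recurrent parent's
sequence everywhere except for genes inside the donor introgression, which
take the donor sequence.  Allele-informative reads — those occurring as an
exact substring of exactly one gene in exactly one parent — are tallied per
gene, and the per-gene donor fraction is used to infer introgression
boundaries, which can then be compared with the expected intervals.

Alignment is by exact-substring unique assignment, which at gene resolution
is equivalent to unique read mapping for error-free synthetic reads; users
with real alignments can supply per-gene allele counts in the same table
schema to :func:`infer_introgressions`.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synthetic_data import GeneAnnotation, IntrogressionLine


# ---------------------------------------------------------------------------
# FASTA helpers

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# chimeric references

def splice_chimeric_transcriptome(recurrent: Mapping[str, str],
                                  donor: Mapping[str, str],
                                  il: IntrogressionLine,
                                  genes: Sequence[GeneAnnotation]
                                  ) -> tuple[dict[str, str], list[str]]:
    """Per-gene chimera: genes whose midpoint lies inside a donor interval
    take the donor sequence, all others the recurrent sequence.

    Returns ``(sequences, boundary_genes)``; boundary genes straddle an
    introgression edge (they overlap an interval without being contained in
    it) and their expression counts are suspect.
    """
    out: dict[str, str] = {}
    boundary: list[str] = []
    for g in genes:
        if g.gene_id not in recurrent or g.gene_id not in donor:
            raise KeyError(f"gene {g.gene_id} missing from a parental reference")
        inside = il.contains_gene(g)
        out[g.gene_id] = donor[g.gene_id] if inside else recurrent[g.gene_id]
        for chrom, s, e in il.intervals:
            if chrom == g.chrom and g.start < e and s < g.end:     # overlaps
                if not (s <= g.start and g.end <= e):              # not contained
                    boundary.append(g.gene_id)
                break
    return out, boundary


# ---------------------------------------------------------------------------
# allele assignment

class _SubstringIndex:
    """Occurrence search over a set of gene sequences via one concatenated
    string with separators, so a query can never span two genes."""

    def __init__(self, seqs: Mapping[str, str]):
        self.gene_ids = list(seqs)
        parts, offsets, pos = [], [], 0
        for gid in self.gene_ids:
            offsets.append(pos)
            parts.append(seqs[gid])
            pos += len(seqs[gid]) + 1
        self.offsets = offsets
        self.concat = "#".join(parts)

    def occurrences(self, query: str, limit: int = 2) -> list[str]:
        """Gene ids of up to ``limit`` occurrences of ``query``."""
        hits: list[str] = []
        start = 0
        while len(hits) < limit:
            i = self.concat.find(query, start)
            if i < 0:
                break
            gi = bisect.bisect_right(self.offsets, i) - 1
            hits.append(self.gene_ids[gi])
            start = i + 1
        return hits


@dataclass
class AlleleCounts:
    """Per-gene tallies of uniquely assigned and ambiguous reads."""

    table: pd.DataFrame          # index gene_id; recurrent, donor, ambiguous
    unmapped: int = 0

    def __post_init__(self) -> None:
        if (self.table[["recurrent", "donor", "ambiguous"]].to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def assign_allele_counts(reads: Iterable[str | tuple],
                         recurrent: Mapping[str, str],
                         donor: Mapping[str, str]) -> AlleleCounts:
    """Count, per gene, reads uniquely matching one parent.

    A read counts for a parent when it occurs as an exact substring of
    exactly one gene in exactly one parent; a read found in both parents or
    in more than one gene is ambiguous (tallied under the gene of its first
    occurrence); a read found nowhere is unmapped.
    """
    if set(recurrent) != set(donor):
        raise KeyError("the two parental references must cover the same genes")
    idx_rec = _SubstringIndex(recurrent)
    idx_don = _SubstringIndex(donor)
    counts = pd.DataFrame(0, index=pd.Index(list(recurrent), name="gene_id"),
                          columns=["recurrent", "donor", "ambiguous"])
    unmapped = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        hits_r = idx_rec.occurrences(seq)
        hits_d = idx_don.occurrences(seq)
        total = len(hits_r) + len(hits_d)
        if total == 0:
            unmapped += 1
        elif total == 1:
            if hits_r:
                counts.loc[hits_r[0], "recurrent"] += 1
            else:
                counts.loc[hits_d[0], "donor"] += 1
        else:
            gene = hits_r[0] if hits_r else hits_d[0]
            counts.loc[gene, "ambiguous"] += 1
    return AlleleCounts(counts, unmapped)


# ---------------------------------------------------------------------------
# introgression inference

@dataclass
class InferredIntrogression:
    intervals: list[tuple[str, int, int]]
    boundary_genes: list[str] = field(default_factory=list)
    per_gene: pd.DataFrame | None = None   # donor_fraction, informative, call


def infer_introgressions(counts: AlleleCounts, genes: Sequence[GeneAnnotation],
                         min_reads: int = 10, donor_cutoff: float = 0.9
                         ) -> InferredIntrogression:
    """Call donor segments from per-gene allele counts.

    A gene with ≥ ``min_reads`` informative (uniquely assigned) reads is
    called *donor* when its donor fraction ≥ ``donor_cutoff``, otherwise
    *recurrent*; genes below ``min_reads`` are no-calls.  Consecutive donor
    calls are merged, bridging single-gene no-call gaps; each inferred
    interval spans the first to the last donor gene.
    """
    tab = counts.table
    rows = []
    for g in genes:
        rec = int(tab.loc[g.gene_id, "recurrent"]) if g.gene_id in tab.index else 0
        don = int(tab.loc[g.gene_id, "donor"]) if g.gene_id in tab.index else 0
        informative = rec + don
        if informative < min_reads:
            call, frac = "nocall", float("nan")
        else:
            frac = don / informative
            call = "donor" if frac >= donor_cutoff else "recurrent"
        rows.append((g.gene_id, g.chrom, g.start, g.end, informative, frac, call))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                           "informative", "donor_fraction", "call"]
                            ).set_index("gene_id")

    intervals: list[tuple[str, int, int]] = []
    flagged: list[str] = []
    for chrom, grp in per_gene.groupby("chrom", sort=True):
        calls = list(grp["call"])
        ids = list(grp.index)
        # bridge single-gene no-call gaps between donor calls
        for i in range(1, len(calls) - 1):
            if calls[i] == "nocall" and calls[i - 1] == "donor" and calls[i + 1] == "donor":
                calls[i] = "donor"
        run_start = None
        for i, c in enumerate(calls + ["recurrent"]):   # sentinel flushes last run
            if c == "donor" and run_start is None:
                run_start = i
            elif c != "donor" and run_start is not None:
                first, last = ids[run_start], ids[i - 1]
                intervals.append((chrom, int(grp.loc[first, "start"]),
                                  int(grp.loc[last, "end"])))
                flagged.extend([first, last])
                run_start = None
    return InferredIntrogression(intervals, flagged, per_gene)


def concordance(inferred: InferredIntrogression, expected: IntrogressionLine,
                genes: Sequence[GeneAnnotation]) -> dict:
    """Compare inferred donor intervals with the expected introgression.

    Intervals are matched by overlap; boundary offsets are reported in genes
    (inferred boundary gene index − expected boundary gene index, left and
    right).  Unmatched expected intervals are *missed*; unmatched inferred
    intervals are *extra*.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    def covered_idx(chrom: str, s: int, e: int) -> list[int]:
        return [i for i, g in enumerate(by_chrom.get(chrom, []))
                if s <= g.midpoint < e]

    matched, offsets = [], []
    used_inferred = set()
    missed = []
    for exp in expected.intervals:
        chrom, es, ee = exp
        hit = None
        for j, inf in enumerate(inferred.intervals):
            if j in used_inferred:
                continue
            ic, is_, ie = inf
            if ic == chrom and is_ < ee and es < ie:
                hit = j
                break
        if hit is None:
            missed.append(exp)
            continue
        used_inferred.add(hit)
        matched.append((exp, inferred.intervals[hit]))
        exp_genes = covered_idx(chrom, es, ee)
        inf_genes = covered_idx(*inferred.intervals[hit])
        if exp_genes and inf_genes:
            offsets.append((inf_genes[0] - exp_genes[0], inf_genes[-1] - exp_genes[-1]))
        else:
            offsets.append((None, None))
    extra = [iv for j, iv in enumerate(inferred.intervals) if j not in used_inferred]
    return {"matched": matched, "missed": missed, "extra": extra,
            "boundary_offsets": offsets}


# ---------------------------------------------------------------------------
# BED / TSV I/O

def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        rows.append((parts[0], int(parts[1]), int(parts[2]),
                     parts[3] if len(parts) > 3 else ""))
    return rows


def write_allele_counts(counts: AlleleCounts, path: str | Path) -> None:
    counts.table.to_csv(path, sep="\t")


def read_allele_counts(path: str | Path) -> AlleleCounts:
    return AlleleCounts(pd.read_csv(path, sep="\t", index_col="gene_id"))
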