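"""Genomic bins from introgression overlaps, fine-mapping by IL exclusion,
and the trait-consistency candidate-gene test.

A *bin* is a maximal genomic segment covered by a constant set of IL
introgressions (its *signature*); bins partition the union of all donor
segments and are the unit of QTL localization in an IL population.  A bin
is a *candidate* for a trait when at least one trait-significant IL covers
it and no non-significant IL does — nested sub-ILs thereby carve a wide
significant interval down to a narrow causal candidate.

Within candidate bins, a gene survives the trait-consistency test when it
is significantly differentially expressed (vs the recurrent parent) in at
least ``min_ils`` of the trait-significant ILs covering its bin, with the
same direction of expression change in all of them, and with a minimum mean
normalized count; survivors are ranked by the squared Pearson correlation
of per-genotype mean expression with per-genotype mean trait.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import GeneAnnotation, IntrogressionLine

logger = logging.getLogger(__name__)


@dataclass
class Bin:
    """A maximal segment with a constant coverage signature."""

    bin_id: str
    chrom: str
    start: int
    end: int
    signature: frozenset[str]
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty bin")
        if not self.signature:
            raise ValueError("a bin must be covered by at least one IL")


def _chrom_letter(index: int) -> str:
    letters = string.ascii_uppercase
    if index < len(letters):
        return letters[index]
    return letters[index // len(letters) - 1] + letters[index % len(letters)]


def compute_bins(panel: Sequence[IntrogressionLine],
                 genes: Sequence[GeneAnnotation] = ()) -> list[Bin]:
    """Partition the union of all introgressions into maximal
    constant-signature bins.

    All interval breakpoints on a chromosome delimit atomic segments; each
    segment's signature is the set of ILs covering it; consecutive segments
    with identical signatures merge.  Genes attach to the bin containing
    their midpoint.  Bin ids follow a ``d-<chrom><letter>`` scheme, lettered
    left to right per chromosome.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for il in panel:
        for chrom, s, e in il.intervals:
            by_chrom.setdefault(chrom, []).append((s, e, il.il_id))
    bins: list[Bin] = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        points = sorted({p for s, e, _ in ivs for p in (s, e)})
        segments: list[tuple[int, int, frozenset[str]]] = []
        for s, e in zip(points, points[1:]):
            sig = frozenset(il for is_, ie, il in ivs if is_ <= s and e <= ie)
            if not sig:
                continue
            if segments and segments[-1][2] == sig and segments[-1][1] == s:
                segments[-1] = (segments[-1][0], e, sig)
            else:
                segments.append((s, e, sig))
        cnum = chrom.removeprefix("chr")
        for i, (s, e, sig) in enumerate(segments):
            gene_ids = tuple(g.gene_id for g in genes
                             if g.chrom == chrom and s <= g.midpoint < e)
            bins.append(Bin(f"d-{cnum}{_chrom_letter(i)}", chrom, s, e, sig, gene_ids))
    return bins


def bin_of_gene(bins: Sequence[Bin], gene_id: str) -> Bin | None:
    for b in bins:
        if gene_id in b.genes:
            return b
    return None


# ---------------------------------------------------------------------------
# fine-mapping

@dataclass
class BinTraitCall:
    bin_id: str
    status: str                     # candidate | excluded
    supporting_sig_ils: frozenset[str] = frozenset()
    excluding_nonsig_ils: frozenset[str] = frozenset()


def fine_map(bins: Sequence[Bin], sig_ils: set[str],
             nonsig_ils: set[str]) -> list[BinTraitCall]:
    """Call candidate bins by significant-IL support and non-significant-IL
    exclusion.

    A bin is a candidate when its signature intersects ``sig_ils`` and
    contains no member of ``nonsig_ils``; within a nested sub-IL family this
    reduces to the intersection of the significant introgressions minus the
    union of the non-significant ones.
    """
    if sig_ils & nonsig_ils:
        raise ValueError("significant and non-significant IL sets must be disjoint")
    calls = []
    for b in bins:
        support = b.signature & sig_ils
        exclude = b.signature & nonsig_ils
        status = "candidate" if support and not exclude else "excluded"
        calls.append(BinTraitCall(b.bin_id, status, frozenset(support),
                                  frozenset(exclude)))
    return calls


# ---------------------------------------------------------------------------
# trait-consistency candidate-gene test

@dataclass
class CandidateGene:
    gene_id: str
    bin_id: str
    n_supporting_ils: int
    direction: str                  # positive | negative association with trait
    mean_norm: float
    r2: float | None = None
    r2_sign: int = 0


def consistency_test(de_by_il: Mapping[str, pd.DataFrame],
                     trait_effects: pd.DataFrame,
                     bins: Sequence[Bin],
                     bin_calls: Sequence[BinTraitCall] | None = None,
                     min_ils: int = 2, min_mean: float = 5.0,
                     alpha: float = 0.01) -> list[CandidateGene]:
    """Genes in candidate bins whose expression change is consistent with
    the trait.

    ``de_by_il`` maps IL id → its DE table (per-gene q, log2FC, mean_norm);
    ``trait_effects`` is the per-genotype trait-model table (effect,
    significant).  For each gene of a candidate bin, the trait-significant
    ILs of its bin's signature are collected; the gene survives when it is
    DE (q ≤ alpha) in at least ``min_ils`` of them, the sign of log2FC is
    identical across all those DE calls, and its mean normalized count
    reaches ``min_mean``.  The association direction is positive when
    expression and trait move the same way relative to the reference.
    """
    sig_ils = set(trait_effects.index[trait_effects["significant"]])
    if bin_calls is None:
        nonsig = set(trait_effects.index) - sig_ils
        bin_calls = fine_map(bins, sig_ils, nonsig & {il for b in bins
                                                      for il in b.signature})
    candidate_bins = {c.bin_id for c in bin_calls if c.status == "candidate"}
    bins_by_id = {b.bin_id: b for b in bins}
    out: list[CandidateGene] = []
    for bin_id in sorted(candidate_bins):
        b = bins_by_id[bin_id]
        covering_sig = sorted(b.signature & sig_ils)
        for gene_id in b.genes:
            de_hits = []
            for il in covering_sig:
                de = de_by_il.get(il)
                if de is None or gene_id not in de.index:
                    continue
                row = de.loc[gene_id]
                if row["q"] <= alpha:
                    de_hits.append((il, float(row["log2FC"]), float(row["mean_norm"])))
            if len(de_hits) < min_ils:
                continue
            signs = {np.sign(fc) for _, fc, _ in de_hits}
            if len(signs) != 1 or 0 in signs:
                continue
            mean_norm = float(np.mean([mn for _, _, mn in de_hits]))
            if mean_norm < min_mean:
                continue
            expr_sign = signs.pop()
            trait_signs = {np.sign(trait_effects.loc[il, "effect"]) for il, _, _ in de_hits}
            if len(trait_signs) != 1:
                continue
            direction = "positive" if expr_sign == trait_signs.pop() else "negative"
            out.append(CandidateGene(gene_id, bin_id, len(de_hits), direction, mean_norm))
    return out


def rank_candidates(expr_means: pd.Series, trait_means: pd.Series
                    ) -> tuple[float, int]:
    """Squared Pearson correlation of per-genotype mean expression with
    per-genotype mean trait, with the sign of the slope retained.

    Returns ``(r2, sign)``; constant inputs yield ``(nan, 0)``.
    """
    common = expr_means.index.intersection(trait_means.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genotypes with both values")
    x = expr_means.loc[common].to_numpy(dtype=float)
    y = trait_means.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 0
    r = float(stats.pearsonr(x, y).statistic)
    return r * r, int(np.sign(r))


def attach_rankings(candidates: Sequence[CandidateGene],
                    de_by_il: Mapping[str, pd.DataFrame],
                    trait_effects: pd.DataFrame,
                    reference_id: str, n_reps_hint: int | None = None
                    ) -> list[CandidateGene]:
    """Fill each candidate's expression–trait R² from per-genotype summed
    normalized counts (reference plus the covering significant ILs)."""
    for cand in candidates:
        expr, trait = {}, {}
        for il, de in de_by_il.items():
            if cand.gene_id not in de.index or il not in trait_effects.index:
                continue
            row = de.loc[cand.gene_id]
            expr[il] = float(row["norm_sum_il"])
            trait[il] = float(trait_effects.loc[il, "effect"])
            expr[reference_id] = float(row["norm_sum_ref"])
            trait[reference_id] = 0.0
        if len(expr) >= 3:
            r2, sign = rank_candidates(pd.Series(expr), pd.Series(trait))
            cand.r2, cand.r2_sign = r2, sign
    return candidates


def bins_to_bed(bins: Sequence[Bin]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.start, b.end, b.bin_id, ",".join(sorted(b.signature)))
         for b in bins],
        columns=["chrom", "start", "end", "bin_id", "signature"])
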