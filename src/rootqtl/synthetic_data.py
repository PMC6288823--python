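"""Generators for every input the pipeline consumes, with recorded ground truth.

The generators emulate the statistical structure of an introgression-line
(IL) eQTL study: a panel of genotypes each carrying one donor genomic
segment on a recurrent background, negative-binomial RNA-seq counts with
planted cis effects inside introgressions and trans effects elsewhere,
seedling root-angle traits with crossed random effects for germination age
and plating date, saturating tip-angle responses to a 90° rotation, and
barcoded single-end FASTQ reads with planted contamination whose filtering
fate is known by construction.

Every generator is deterministic for a fixed seed, and every planted effect
is recorded in a :class:`SimTruth` ledger so downstream recovery can be
scored without re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .root_traits import DT_MINUTES, N_TIMEPOINTS, TipAngleSeries

_BASES = np.array(list("ACGT"))

# Plate-holder geometry: 7 holders (A..G), 12 pair-slots each, 2 plate
# positions (sides A/B) per slot.
N_HOLDERS = 7
SLOTS_PER_HOLDER = 12
PLATE_CAPACITY = N_HOLDERS * SLOTS_PER_HOLDER * 2  # 168 plate positions


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval; coordinates are 0-based half-open base pairs."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class Genome:
    """Gene annotations plus the two parental allele sequences per gene.

    ``snp_positions`` records, per gene, the 0-based offsets at which the
    donor sequence was made to differ from the recurrent one — the only
    positions at which alleles are distinguishable.
    """

    genes: list[GeneAnnotation]
    recurrent_seqs: dict[str, str]
    donor_seqs: dict[str, str]
    snp_positions: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        by_chrom: dict[str, list[GeneAnnotation]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            for a, b in zip(gs, gs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping/unsorted genes on {chrom}")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def genes_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(g.gene_id, g.chrom, g.start, g.end) for g in self.genes],
            columns=["gene_id", "chrom", "start", "end"],
        )
        return df.set_index("gene_id")

    def chrom_length(self, chrom: str) -> int:
        return max(g.end for g in self.genes if g.chrom == chrom)


@dataclass(frozen=True)
class IntrogressionLine:
    """A genotype carrying one or more donor genomic segments on the
    recurrent background."""

    il_id: str
    intervals: tuple[tuple[str, int, int], ...]
    parent_ids: tuple[str, str] = ("M82", "PENN")  # (recurrent, donor)

    def __post_init__(self) -> None:
        for chrom, s, e in self.intervals:
            if e <= s:
                raise ValueError(f"{self.il_id}: empty interval on {chrom}")
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            per_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.il_id}: overlapping intervals on {chrom}")

    def contains(self, chrom: str, pos: float) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in self.intervals)

    def contains_gene(self, gene: GeneAnnotation) -> bool:
        """Gene membership is decided by the interval midpoint."""
        return self.contains(gene.chrom, gene.midpoint)


@dataclass
class SimTruth:
    """Ledger of every planted effect, sufficient to score recovery."""

    cis_effects: dict[str, float] = field(default_factory=dict)
    trans_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    causal_gene: str | None = None
    trait_effects: dict[str, float] = field(default_factory=dict)
    dispersions: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dispersions.values()):
            raise ValueError("dispersions must be > 0")
        if self.causal_gene is not None and not self.cis_effects.get(self.causal_gene):
            raise ValueError("the causal gene must carry a nonzero cis effect")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["trans_effects"] = {f"{il}::{g}": v for (il, g), v in self.trans_effects.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        payload["trans_effects"] = {
            tuple(k.split("::")): v for k, v in payload["trans_effects"].items()
        }
        return cls(**payload)


@dataclass
class PlateLayout:
    """Randomized assignment of genotypes to plate-holder positions."""

    assignments: dict[str, tuple[str, int, str, str]]  # plate_id -> (holder, slot, side, genotype)
    empty_positions: int

    def __post_init__(self) -> None:
        positions = [(h, s, side) for h, s, side, _ in self.assignments.values()]
        if len(set(positions)) != len(positions):
            raise ValueError("a plate position was assigned twice")
        if len(positions) + self.empty_positions != PLATE_CAPACITY:
            raise ValueError("plates + empty positions must equal capacity")

    @property
    def n_plates(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(pid, h, s, side, g) for pid, (h, s, side, g) in self.assignments.items()],
            columns=["plate_id", "holder", "slot", "side", "genotype"],
        )


@dataclass
class CountMatrix:
    """Raw gene × sample counts plus gene positions and sample metadata."""

    counts: pd.DataFrame                # genes × samples, integers
    genes: pd.DataFrame                 # index gene_id; chrom, start, end
    samples: pd.DataFrame               # index sample; genotype, replicate

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.genes.index):
            raise ValueError("counts rows must match the gene table")
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("counts columns must match the sample table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def subset_genotypes(self, genotypes: Sequence[str]) -> "CountMatrix":
        keep = self.samples["genotype"].isin(genotypes)
        return CountMatrix(self.counts.loc[:, keep.to_numpy()],
                           self.genes, self.samples.loc[keep.to_numpy()])


# ---------------------------------------------------------------------------
# genome and panel

def make_genome(n_chrom: int, genes_per_chrom: int, gene_len: int = 500,
                seed: int = 0, snps_per_gene: int = 4,
                spacing: int | None = None) -> Genome:
    """Simulate a transcriptome with evenly spaced genes and two parental
    alleles per gene.

    The donor allele differs from the recurrent one at ``snps_per_gene``
    evenly spaced positions within each gene (planted SNPs); everywhere else
    the two alleles are identical, so only reads overlapping a SNP are
    allele-informative.
    """
    if n_chrom < 1 or genes_per_chrom < 2 or gene_len < 1:
        raise ValueError("n_chrom ≥ 1, genes_per_chrom ≥ 2, gene_len ≥ 1 required")
    rng = np.random.default_rng(seed)
    spacing = gene_len if spacing is None else spacing
    snp_pos = tuple(
        int(gene_len * (j + 1) / (snps_per_gene + 1)) for j in range(snps_per_gene)
    )
    genes, rec, don, snps = [], {}, {}, {}
    for c in range(1, n_chrom + 1):
        chrom = f"chr{c}"
        for i in range(genes_per_chrom):
            gid = f"g{c:02d}{i:04d}"
            start = i * (gene_len + spacing)
            genes.append(GeneAnnotation(gid, chrom, start, start + gene_len))
            seq = rng.choice(_BASES, size=gene_len)
            donor = seq.copy()
            for p in snp_pos:
                alt = [b for b in "ACGT" if b != seq[p]]
                donor[p] = alt[int(rng.integers(3))]
            rec[gid] = "".join(seq)
            don[gid] = "".join(donor)
            snps[gid] = snp_pos
    return Genome(genes, rec, don, snps)


def make_il_panel(genome: Genome, n_ils: int, overlap_frac: float = 0.25,
                  n_subils: int = 0, subil_parent_index: int | None = None,
                  seed: int = 0,
                  parent_ids: tuple[str, str] = ("M82", "PENN")) -> list[IntrogressionLine]:
    """Tile each chromosome with overlapping donor introgressions.

    Adjacent ILs on a chromosome overlap by ``overlap_frac`` of their length,
    so multi-IL bins exist.  ``n_subils`` nested sub-ILs (strict
    sub-intervals anchored at the parent's left end, of growing extent) are
    added inside one parent IL, emulating the nested sub-line families used
    for fine-mapping.
    """
    if n_ils < 2:
        raise ValueError("n_ils must be ≥ 2")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    chroms = sorted({g.chrom for g in genome.genes})
    # distribute main ILs over chromosomes as evenly as possible
    base, extra = divmod(n_ils, len(chroms))
    counts = [base + (1 if i < extra else 0) for i in range(len(chroms))]
    panel: list[IntrogressionLine] = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        length = genome.chrom_length(chrom)
        if k == 1:
            segs = [(0, length)]
        else:
            # k segments of length L covering [0, length) with pairwise overlap o·L
            seg_len = length / (1 + (k - 1) * (1 - overlap_frac))
            step = seg_len * (1 - overlap_frac)
            segs = [(int(round(i * step)), int(round(i * step + seg_len))) for i in range(k)]
            segs[-1] = (segs[-1][0], length)
        cnum = chrom.removeprefix("chr")
        for i, (s, e) in enumerate(segs, start=1):
            panel.append(IntrogressionLine(f"IL{cnum}-{i}", ((chrom, s, e),),
                                           parent_ids=parent_ids))
    if n_subils:
        idx = subil_parent_index if subil_parent_index is not None else len(panel) // 2
        parent = panel[idx]
        chrom, s, e = parent.intervals[0]
        span = e - s
        # nested, left-anchored, strictly inside the parent
        fracs = np.linspace(0.3, 0.6, n_subils)
        for j, f in enumerate(fracs, start=1):
            sub_end = s + max(1, int(round(span * f)))
            panel.append(IntrogressionLine(f"{parent.il_id}-{j}",
                                           ((chrom, s, min(sub_end, e - 1)),),
                                           parent_ids=parent_ids))
    return panel


# ---------------------------------------------------------------------------
# expression counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + disp·mean²; disp→0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    disp = np.broadcast_to(np.asarray(disp, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = disp < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        r = 1.0 / disp[~tiny]
        p = r / (r + mean[~tiny])
        out[~tiny] = rng.negative_binomial(r, p)
    return out


def simulate_expression(panel: Sequence[IntrogressionLine], genome: Genome,
                        truth: SimTruth, n_reps: int = 3,
                        lib_size_cv: float = 0.1, base_mean_log: float = np.log(60.0),
                        base_mean_sd: float = 0.8, seed: int = 0,
                        reference_id: str | None = None,
                        base_mean_overrides: Mapping[str, float] | None = None
                        ) -> CountMatrix:
    """Negative-binomial counts for the reference parent and every IL.

    Per gene g and sample s, counts ~ NB(mean_g · lib_s · 2^effect, disp_g).
    Cis effects from the truth ledger apply only when the gene lies inside
    the sample genotype's introgression; trans effects apply per
    (il_id, gene_id) pair regardless of position.  Baseline means are
    lognormal (defaults emulate per-gene coverage of a multiplexed 50 bp
    single-end root-tip library); ``base_mean_overrides`` pins chosen genes
    to fixed baselines.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be ≥ 2")
    rng = np.random.default_rng(seed)
    gene_ids = genome.gene_ids
    base_mean = np.exp(rng.normal(base_mean_log, base_mean_sd, size=len(gene_ids)))
    if base_mean_overrides:
        for i, gid in enumerate(gene_ids):
            if gid in base_mean_overrides:
                base_mean[i] = base_mean_overrides[gid]
    disp = np.array([truth.dispersions.get(g, 0.01) for g in gene_ids])

    ref = reference_id or (panel[0].parent_ids[0] if panel else "M82")
    genotypes: list[tuple[str, IntrogressionLine | None]] = [(ref, None)]
    genotypes += [(il.il_id, il) for il in panel]

    cols, meta, data = [], [], []
    for geno, il in genotypes:
        effect = np.zeros(len(gene_ids))
        if il is not None:
            for i, g in enumerate(genome.genes):
                if il.contains_gene(g):
                    effect[i] += truth.cis_effects.get(g.gene_id, 0.0)
                effect[i] += truth.trans_effects.get((il.il_id, g.gene_id), 0.0)
        for rep in range(1, n_reps + 1):
            lib = float(np.exp(rng.normal(0.0, lib_size_cv)))
            mean = base_mean * lib * np.power(2.0, effect)
            data.append(_nb_draw(rng, mean, disp))
            cols.append(f"{geno}_r{rep}")
            meta.append((geno, rep))
    counts = pd.DataFrame(np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"),
                          columns=cols)
    samples = pd.DataFrame(meta, columns=["genotype", "replicate"],
                           index=pd.Index(cols, name="sample"))
    return CountMatrix(counts, genome.genes_frame(), samples)


# ---------------------------------------------------------------------------
# seedling traits

def genotype_trait_shift(il: IntrogressionLine | None, genome: Genome,
                         truth: SimTruth) -> float:
    """Sum of planted trait effects carried by a genotype (the effect of a
    gene is carried when the genotype's introgression contains it)."""
    if il is None:
        return 0.0
    shift = 0.0
    by_id = {g.gene_id: g for g in genome.genes}
    for gid, eff in truth.trait_effects.items():
        gene = by_id.get(gid)
        if gene is not None and il.contains_gene(gene):
            shift += eff
    return shift


def simulate_trait(panel: Sequence[IntrogressionLine], genome: Genome,
                   truth: SimTruth, n_seedlings: int = 35, baseline: float = 25.0,
                   sd_germ_age: float = 2.0, sd_plate_date: float = 2.0,
                   sd_resid: float = 6.0, collide_shift: float = 4.0,
                   collide_rate: float = 0.15, germ_age_levels: Sequence[int] = (3, 4, 5),
                   plate_date_levels: Sequence[str] = ("D1", "D2", "D3", "D4"),
                   seed: int = 0, reference_id: str | None = None) -> pd.DataFrame:
    """Seedling root-angle records for the reference and every IL.

    trait = baseline + Σ planted effects carried by the genotype
          + u[germAge] + u[plateDate] + collide_shift·1[collide] + ε,
    with crossed random intercepts drawn i.i.d. N(0, sd) per factor level and
    ε ~ N(0, sd_resid).  Default sizes emulate ~35 traceable roots per
    genotype accumulated over four replicate growth cycles; the parents,
    plated on twice the plates of any IL, get twice the seedlings.
    """
    if n_seedlings < 2:
        raise ValueError("need at least 2 seedlings per genotype")
    if min(sd_germ_age, sd_plate_date, sd_resid) < 0:
        raise ValueError("standard deviations must be ≥ 0")
    rng = np.random.default_rng(seed)
    u_germ = {lv: rng.normal(0.0, sd_germ_age) for lv in germ_age_levels}
    u_plate = {lv: rng.normal(0.0, sd_plate_date) for lv in plate_date_levels}
    ref = reference_id or (panel[0].parent_ids[0] if panel else "M82")
    genotypes: list[tuple[str, IntrogressionLine | None]] = [(ref, None)]
    genotypes += [(il.il_id, il) for il in panel]
    rows = []
    for geno, il in genotypes:
        shift = genotype_trait_shift(il, genome, truth)
        n_here = 2 * n_seedlings if il is None else n_seedlings
        for i in range(n_here):
            ga = germ_age_levels[int(rng.integers(len(germ_age_levels)))]
            pd_ = plate_date_levels[int(rng.integers(len(plate_date_levels)))]
            collide = bool(rng.random() < collide_rate)
            along = bool(rng.random() < collide_rate / 2)
            trait = (baseline + shift + u_germ[ga] + u_plate[pd_]
                     + (collide_shift if collide else 0.0)
                     + rng.normal(0.0, sd_resid))
            rows.append((geno, i + 1, trait, ga, pd_, collide, along))
    return pd.DataFrame(rows, columns=["genotype", "replicate", "trait",
                                       "germAge", "plateDate", "collide", "along"])


# ---------------------------------------------------------------------------
# tip-angle kinetics

def simulate_tip_angle_series(response_params: Mapping[str, tuple[float, float, float]],
                              n_roots: int = 20, noise_sd: float = 1.0,
                              a0_sd: float = 8.0, seed: int = 0) -> list[TipAngleSeries]:
    """Saturating-exponential tip-angle responses after a 90° rotation.

    ``response_params`` maps genotype → (rate per min, amplitude °, lag min);
    angle(t) = a0 + amplitude·(1 − exp(−rate·max(0, t − lag))) + noise, with
    the starting angle a0 drawn N(0, a0_sd) so both "through" (a0 > 0) and
    "away" (a0 < 0) rotation classes occur, as when plates are rotated
    blindly with respect to each root's established angle.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(N_TIMEPOINTS) * DT_MINUTES
    out = []
    for geno, (rate, amplitude, lag) in response_params.items():
        if rate < 0 or amplitude < 0:
            raise ValueError("rate and amplitude must be ≥ 0")
        for i in range(n_roots):
            a0 = rng.normal(0.0, a0_sd)
            angles = a0 + amplitude * (1.0 - np.exp(-rate * np.maximum(0.0, t - lag)))
            angles = angles + rng.normal(0.0, noise_sd, size=N_TIMEPOINTS)
            s = TipAngleSeries(angles, root_id=f"{geno}_root{i + 1}", genotype=geno)
            s.rotation_class = "through" if a0 >= 0 else "away"
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# reads

@dataclass
class ContaminationConfig:
    """Per-read probabilities of planted contamination classes.

    ``lowq_rate`` reads receive low-quality (Phred ≤ 20) bases in one of
    three patterns — isolated interior bases (read survives masked), a close
    interior pair (read is split), or a long tail (surviving fragment too
    short) — chosen uniformly.
    """

    adapter_rate: float = 0.0
    polyn_rate: float = 0.0
    lowq_rate: float = 0.0
    short_rate: float = 0.0

    def __post_init__(self) -> None:
        total = self.adapter_rate + self.polyn_rate + self.lowq_rate + self.short_rate
        if total > 1.0 + 1e-9:
            raise ValueError("contamination rates must sum to ≤ 1")


DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_HI_Q = 40
_LO_Q = 10


def _random_clean_seq(rng: np.random.Generator, length: int,
                      forbidden_kmers: set[str], k: int) -> str:
    while True:
        seq = "".join(rng.choice(_BASES, size=length))
        if not any(seq[i:i + k] in forbidden_kmers for i in range(len(seq) - k + 1)):
            return seq


def simulate_reads(genome: Genome, genotype: IntrogressionLine | None,
                   barcode: str, n_reads: int,
                   contamination: ContaminationConfig | None = None,
                   read_len: int = 50, seed: int = 0,
                   adapter: str = DEFAULT_ADAPTER,
                   adapter_min_match: int = 12) -> tuple[list[tuple[str, str, list[int]]], pd.DataFrame]:
    """Barcoded single-end reads from a genotype's chimeric transcriptome.

    Reads are drawn uniformly over genes and start positions; genes inside
    the genotype's introgression yield the donor allele, all others the
    recurrent allele (``genotype=None`` simulates the recurrent parent).
    Each read's expected filtering fate under the QC rules is decided at
    construction time and recorded in the returned truth table.

    Returns ``(records, truth)`` where each record is
    ``(read_id, sequence_with_barcode_prefix, phred_qualities)``.
    """
    if not barcode:
        raise ValueError("barcode must be non-empty")
    contamination = contamination or ContaminationConfig()
    rng = np.random.default_rng(seed)
    # k-mers whose presence triggers the adapter rule — avoided in clean reads
    from .read_qc import _revcomp  # shared helper; avoids drift between modules
    k = adapter_min_match
    adapter_kmers = set()
    for a in (adapter, _revcomp(adapter)):
        adapter_kmers.update(a[i:i + k] for i in range(len(a) - k + 1))

    genes = genome.genes
    records, truth_rows = [], []
    classes = np.array(["adapter", "polyN", "lowq", "short", "clean"])
    probs = np.array([contamination.adapter_rate, contamination.polyn_rate,
                      contamination.lowq_rate, contamination.short_rate, 0.0])
    probs[-1] = 1.0 - probs.sum()
    lowq_patterns = ("isolated", "pair", "tail")

    for i in range(n_reads):
        read_id = f"read{i:06d}"
        gene = genes[int(rng.integers(len(genes)))]
        allele = "donor" if (genotype is not None and genotype.contains_gene(gene)) else "recurrent"
        source = genome.donor_seqs if allele == "donor" else genome.recurrent_seqs
        cls = classes[int(rng.choice(len(classes), p=probs))]

        length = read_len
        if cls == "short":
            length = int(rng.integers(15, 30))  # below the 30-base minimum
        max_start = len(source[gene.gene_id]) - length
        start = int(rng.integers(max_start + 1))
        seq = source[gene.gene_id][start:start + length]
        if any(seq[j:j + k] in adapter_kmers for j in range(len(seq) - k + 1)):
            # an accidental adapter hit in genomic sequence would change the
            # fate; replace with a screened random sequence (vanishingly rare)
            seq = _random_clean_seq(rng, length, adapter_kmers, k)
        quals = [_HI_Q] * length
        fate, reason = "kept", "clean"

        if cls == "adapter":
            frag_len = int(rng.integers(adapter_min_match, len(adapter) + 1))
            frag = adapter[:frag_len]
            pos = int(rng.integers(length - frag_len + 1))
            seq = seq[:pos] + frag + seq[pos + frag_len:]
            fate, reason = "discarded", "adapter"
        elif cls == "polyN":
            run = int(rng.integers(15, 21))
            pos = int(rng.integers(length - run + 1))
            seq = seq[:pos] + "N" * run + seq[pos + run:]
            quals = [_HI_Q] * length
            fate, reason = "discarded", "polyN"
        elif cls == "short":
            fate, reason = "discarded", "short"
        elif cls == "lowq":
            pattern = lowq_patterns[int(rng.integers(3))]
            if pattern == "isolated":
                # one masked interior base, ≥10 from each end: read survives
                pos = int(rng.integers(12, length - 12))
                quals[pos] = _LO_Q
                fate, reason = "kept", "lowq-masked"
            elif pattern == "pair":
                # two masked bases < 20 apart: the region is excised and the
                # longest fragment (here the 3' one, ≥ 30 bases) is kept
                p1 = 5
                p2 = p1 + int(rng.integers(2, 8))
                quals[p1] = quals[p2] = _LO_Q
                fate, reason = "split-kept", "split"
            else:
                # low-quality tail: post-trim length < 30
                tail = int(rng.integers(length - 29 + 1, length - 10))
                for p in range(length - tail, length):
                    quals[p] = _LO_Q
                fate, reason = "discarded", "short"

        full_seq = barcode + seq
        full_quals = [_HI_Q] * len(barcode) + quals
        records.append((read_id, full_seq, full_quals))
        truth_rows.append((read_id, barcode, gene.gene_id, allele, fate, reason))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "source_library", "source_gene",
                                              "source_allele", "expected_fate", "reason"])
    return records, truth


def write_fastq(records: Sequence[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    """Write (id, seq, phred) records as a Phred+33 FASTQ file."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seqrecs = []
    for rid, seq, quals in records:
        r = SeqRecord(Seq(seq), id=rid, description="")
        r.letter_annotations["phred_quality"] = list(quals)
        seqrecs.append(r)
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fastq")


def write_parent_fastas(genome: Genome, recurrent_path: str | Path,
                        donor_path: str | Path) -> None:
    """Emit the two parental transcriptomes as FASTA (one record per gene)."""
    from .genotyping import write_fasta
    write_fasta(genome.recurrent_seqs, recurrent_path)
    write_fasta(genome.donor_seqs, donor_path)


def write_panel_bed(panel: Sequence[IntrogressionLine], path: str | Path) -> None:
    """BED (0-based half-open) of every IL's donor intervals."""
    with open(path, "w") as fh:
        for il in panel:
            for chrom, s, e in il.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{il.il_id}\n")


# ---------------------------------------------------------------------------
# plate layout

def make_plate_layout(genotypes: Sequence[str], parent_ids: tuple[str, str],
                      seed: int = 0) -> PlateLayout:
    """Randomly assign genotypes to plate-holder positions.

    Seven holders (A–G) each hold 12 pairs of back-to-back plates (sides
    A/B), 168 plate positions in all.  Each genotype occupies both sides of
    one pair-slot (2 plates); each parent occupies two pair-slots (4
    plates).  79 genotypes including the two parents therefore need 162
    plates, leaving 6 empty positions.
    """
    rng = np.random.default_rng(seed)
    slot_demand: list[str] = []
    for g in genotypes:
        slot_demand.extend([g, g] if g in parent_ids else [g])
    n_positions = 2 * len(slot_demand)
    if n_positions > PLATE_CAPACITY:
        raise ValueError(
            f"{n_positions} plate positions requested but capacity is {PLATE_CAPACITY}")
    all_slots = [(h, s) for h in "ABCDEFG" for s in range(1, SLOTS_PER_HOLDER + 1)]
    order = rng.permutation(len(all_slots))
    assignments: dict[str, tuple[str, int, str, str]] = {}
    for geno_i, slot_i in zip(range(len(slot_demand)), order):
        geno = slot_demand[geno_i]
        holder, slot = all_slots[slot_i]
        for side in ("A", "B"):
            assignments[f"{holder}{slot}{side}"] = (holder, slot, side, geno)
    return PlateLayout(assignments, PLATE_CAPACITY - n_positions)


# ---------------------------------------------------------------------------
# the default study scenario

@dataclass
class Scenario:
    """A complete synthetic study: genome, IL panel, and truth ledger."""

    genome: Genome
    panel: list[IntrogressionLine]
    truth: SimTruth
    reference_id: str = "M82"
    base_mean_overrides: dict[str, float] = field(default_factory=dict)

    @property
    def causal_gene(self) -> str:
        assert self.truth.causal_gene is not None
        return self.truth.causal_gene


def default_scenario(seed: int = 0, n_genes: int = 2000, n_main_ils: int = 27,
                     n_subils: int = 3, causal_log2fc: float = 1.5,
                     causal_trait_shift: float = 8.0,
                     background_cis_frac: float = 0.05,
                     n_trans_hotspots: int = 2) -> Scenario:
    """The default end-to-end study: 30 ILs (27 tiling + 3 nested sub-ILs),
    2000 genes, one causal cis gene driving the trait.

    The causal gene sits in the overlap of the sub-IL family's parent and
    its right-hand neighbour, beyond the reach of the nested sub-ILs — so
    the sub-ILs carry no trait effect and act as excluders during
    fine-mapping, mirroring how nested sub-lines narrow a candidate bin.
    Background cis effects (±1 log2FC on a fraction of in-introgression
    genes) and two trans hotspots make the DE landscape non-trivial.
    """
    rng = np.random.default_rng(seed)
    genome = make_genome(2, n_genes // 2, gene_len=500, seed=int(rng.integers(2**31)))
    # place the sub-IL family mid-way along chromosome 1
    n_chr1 = (n_main_ils + 1) // 2
    parent_index = n_chr1 // 2
    panel = make_il_panel(genome, n_main_ils, overlap_frac=0.25, n_subils=n_subils,
                          subil_parent_index=parent_index,
                          seed=int(rng.integers(2**31)))
    parent_il = panel[parent_index]
    neighbour = panel[parent_index + 1]
    sub_ends = [iv[2] for il in panel if il.il_id.startswith(parent_il.il_id + "-")
                for iv in il.intervals]
    max_sub_end = max(sub_ends) if sub_ends else parent_il.intervals[0][1]
    chrom, p_start, p_end = parent_il.intervals[0]
    _, nb_start, _ = neighbour.intervals[0]
    lo = max(nb_start, max_sub_end)
    candidates = [g for g in genome.genes
                  if g.chrom == chrom and lo <= g.midpoint < p_end]
    if not candidates:
        raise RuntimeError("panel geometry left no room for a causal gene")
    causal = candidates[len(candidates) // 2]

    # biological CV ~10% (dispersion ~0.01): homozygous inbred lines, each
    # library pooling root-tip segments from 7–14 seedlings
    dispersions = {g: float(np.exp(rng.normal(np.log(0.01), 0.3)))
                   for g in genome.gene_ids}
    cis: dict[str, float] = {causal.gene_id: causal_log2fc}
    covered = [g for g in genome.genes if any(il.contains_gene(g) for il in panel)]
    n_bg = int(background_cis_frac * len(covered))
    for g in rng.choice(len(covered), size=n_bg, replace=False):
        gid = covered[int(g)].gene_id
        if gid != causal.gene_id:
            cis[gid] = float(rng.choice([-1.0, 1.0]))
    trans: dict[tuple[str, str], float] = {}
    hot_ils = rng.choice(len(panel), size=min(n_trans_hotspots, len(panel)), replace=False)
    for hi in hot_ils:
        il = panel[int(hi)]
        targets = rng.choice(len(genome.genes), size=20, replace=False)
        for t in targets:
            gene = genome.genes[int(t)]
            if not il.contains_gene(gene):
                trans[(il.il_id, gene.gene_id)] = float(rng.choice([-1.0, 1.0]))

    truth = SimTruth(cis_effects=cis, trans_effects=trans,
                     causal_gene=causal.gene_id,
                     trait_effects={causal.gene_id: causal_trait_shift},
                     dispersions=dispersions, seed=seed)
    # the causal gene is a solidly expressed transcript: a gene this pipeline
    # can find must clear the mean-count floor of the consistency test
    overrides = {causal.gene_id: 100.0}
    return Scenario(genome, panel, truth, base_mean_overrides=overrides)
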