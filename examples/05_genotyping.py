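"""Verifying an introgression from allele-informative reads.

Builds the chimeric transcriptome of one IL (donor sequence inside the
introgression, recurrent elsewhere), simulates reads from it, assigns each
read to a parent by unique exact match, infers the introgression from
per-gene donor fractions, and compares the inferred boundaries with the
expected interval.
"""

from rootqtl import genotyping as gt, synthetic_data as sd

genome = sd.make_genome(n_chrom=1, genes_per_chrom=40, gene_len=300, seed=6)
il = sd.IntrogressionLine("IL1-2", (("chr1", genome.genes[12].start,
                                     genome.genes[24].end),))

chimera, boundary = gt.splice_chimeric_transcriptome(
    genome.recurrent_seqs, genome.donor_seqs, il, genome.genes)
n_donor = sum(chimera[g.gene_id] == genome.donor_seqs[g.gene_id]
              for g in genome.genes)
print(f"chimeric reference: {n_donor} donor genes of {len(genome.genes)}; "
      f"boundary-straddling genes flagged: {boundary or 'none'}")

records, _ = sd.simulate_reads(genome, il, barcode="A", n_reads=6000, seed=6)
reads = [seq[1:] for _, seq, _ in records]           # strip the barcode
counts = gt.assign_allele_counts(reads, genome.recurrent_seqs, genome.donor_seqs)
print(f"reads uniquely assigned: recurrent={counts.table['recurrent'].sum()}, "
      f"donor={counts.table['donor'].sum()}, "
      f"ambiguous (no SNP covered)={counts.table['ambiguous'].sum()}")

inferred = gt.infer_introgressions(counts, genome.genes, min_reads=10)
report = gt.concordance(inferred, il, genome.genes)
print(f"inferred intervals: {inferred.intervals}")
print(f"expected interval:  {list(il.intervals)}")
print(f"boundary offsets (genes): {report['boundary_offsets']}")
print("Offsets of (0, 0) mean both introgression boundaries were recovered"
      " at gene resolution.")
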