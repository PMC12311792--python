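#!/usr/bin/env python
"""Generate the study's inputs: toy genome, DPC fragment libraries for every
genotype/condition/replicate, repeat-locus read sets, and qPCR Ct tables.

Everything downstream (02-05) reads the files this script writes, so the
whole analysis can be reproduced from one seed.
"""

import argparse
from pathlib import Path

from dpcseq import genomic_io as gio
from dpcseq.simulate import (
    SimulationConfig,
    TREATMENT_LABELS,
    build_toy_genome,
    simulate_dpc_fragments,
    simulate_qpcr_ct,
    simulate_repeat_reads,
    substream,
)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/simulated_inputs"))
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed)
    outdir = args.out
    outdir.mkdir(parents=True, exist_ok=True)

    genome = build_toy_genome(config)
    gio.write_bed(genome.segmentation.intervals, outdir / "segmentation.bed")
    gio.write_gene_table(genome.genes, outdir / "genes.tsv")
    gio.write_fasta(genome.repeat_reference.to_fasta_dict(), outdir / "repeat_reference.fa")
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    print(f"genome: {genome.segmentation.genome_size:,} b over "
          f"{len(genome.chrom_sizes)} chromosomes, "
          f"{len(genome.segmentation.state_set)} chromatin states, "
          f"{len(genome.genes)} genes")

    n_frag = 0
    for genotype in config.genotypes:
        for condition in TREATMENT_LABELS:
            for rep in range(config.n_replicates):
                frags = simulate_dpc_fragments(genome, config, condition, genotype, rep)
                gio.write_bed(frags.to_intervals(),
                              outdir / f"fragments_{genotype}_{condition}_{rep}.bed")
                n_frag += frags.total_count
    print(f"fragments: {n_frag:,} across {len(config.genotypes)} genotypes x "
          f"{len(TREATMENT_LABELS)} conditions x {config.n_replicates} replicates")

    n_reads = 0
    for condition in ("T", "R"):
        for rep in range(config.n_replicates):
            reads = simulate_repeat_reads(genome.repeat_reference, config, condition, rep)
            gio.write_fastq(((r.name, r.seq) for r in reads.reads),
                            outdir / f"repeat_reads_{condition}_{rep}.fastq")
            n_reads += len(reads)
    print(f"repeat-locus reads: {n_reads:,} ({config.repeat_read_length} b, "
          f"error rate {config.repeat_error_rate})")

    records = []
    for genotype in config.genotypes:
        frac = config.quintile_removal[genotype]["Q4"]
        ct_seed = int(substream(config.seed, "qpcr", genotype).integers(2**31))
        records.extend(simulate_qpcr_ct(frac, 5, config.ct_noise_sd, ct_seed,
                                        base_ct=config.ct_base_cycle, genotype=genotype))
    gio.write_ct_csv(records, outdir / "ct_table.csv")
    print(f"qPCR: {len(records)} Ct replicate pairs "
          f"({', '.join(config.genotypes)}) -> {outdir / 'ct_table.csv'}")


if __name__ == "__main__":
    main()
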