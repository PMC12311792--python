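#!/usr/bin/env python
"""Is DPC removal transcription-coupled? TSS metaprofiles by expression stratum.

Builds CPM tracks from the fragment BEDs written by 01, stratifies genes
into Q0 (silent) and Q1-Q4 (expressed rank groups), and computes
TSS-centered mean-signal curves for T and R conditions per genotype, plus
the position-wise WT-vs-mutant -log10 p curves for Q0 and Q4.

Expected picture: T curves coincide across strata; after recovery the WT
signal drops in proportion to transcription (Q4 lowest), XPA-KO drops less,
CSB-KO barely at all; the WT-vs-XPA-KO significance curve rises near the
TSS for Q4 but stays flat for Q0.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dpcseq import genomic_io as gio
from dpcseq.metaprofile import (
    assign_quintiles,
    cpm_normalize,
    positionwise_compare,
    quintile_profiles,
    tss_matrix,
)
from dpcseq.simulate import SimulationConfig, substream


def load_track(inputs, genotype, condition, rep, chrom_sizes):
    intervals = gio.read_bed(inputs / f"fragments_{genotype}_{condition}_{rep}.bed")
    frags = type("F", (), {"fragments": [(iv.chrom, iv.start, iv.end)
                                         for iv in intervals]})()
    return cpm_normalize(frags, chrom_sizes, bin_size=10)


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--inputs", type=Path, default=Path("results/simulated_inputs"))
    parser.add_argument("--out", type=Path, default=Path("results/tss_metaprofiles"))
    parser.add_argument("--seed", type=int, default=1,
                        help="Seed of the run that produced the inputs.")
    parser.add_argument("--window", type=int, default=20_000)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(seed=args.seed)
    genes = gio.read_gene_table(args.inputs / "genes.tsv")
    segmentation = gio.ChromatinSegmentation(gio.read_bed(args.inputs / "segmentation.bed"))
    chrom_sizes = segmentation.chrom_sizes
    assignment = assign_quintiles(
        genes, seed=int(substream(args.seed, "quintiles").integers(2**31))
    )
    print("stratum sizes:",
          {s: len(g) for s, g in assignment.strata.items()},
          f"({len(assignment.excluded)} genes with 0<FPKM<0.1 excluded)")

    half = args.window // 10
    tss_slice = slice(half, half + 100)  # first 1 kb downstream
    matrices = {}
    curves = {}
    for genotype in config.genotypes:
        for condition in ("T", "R"):
            for rep in range(config.n_replicates):
                track = load_track(args.inputs, genotype, condition, rep, chrom_sizes)
                m = tss_matrix(track, genes, window=args.window)
                matrices[(genotype, condition, rep)] = m
                for stratum, (curve, _n) in quintile_profiles(m, assignment).items():
                    curves[f"{genotype}:{condition}:{rep}:{stratum}"] = curve
    pd.DataFrame(curves).to_csv(args.out / "stratum_curves.tsv", sep="\t", index=False)

    print("\npercent signal loss (T->R) over the first 1 kb downstream of the TSS:")
    for genotype in config.genotypes:
        losses = {}
        for stratum in ("Q0", "Q1", "Q2", "Q3", "Q4"):
            t = np.mean([curves[f"{genotype}:T:{r}:{stratum}"][tss_slice].mean()
                         for r in range(config.n_replicates)])
            r_ = np.mean([curves[f"{genotype}:R:{r}:{stratum}"][tss_slice].mean()
                          for r in range(config.n_replicates)])
            losses[stratum] = 100 * (1 - r_ / t)
        print(f"  {genotype:8s} " +
              " ".join(f"{s}={v:6.1f}%" for s, v in losses.items()))

    print("\nposition-wise WT vs mutant (R condition), -log10 p near the TSS:")
    rows = {}
    for genotype in [g for g in config.genotypes if g != "WT"]:
        wt = [matrices[("WT", "R", r)] for r in range(config.n_replicates)]
        mut = [matrices[(genotype, "R", r)] for r in range(config.n_replicates)]
        for stratum in ("Q0", "Q4"):
            curve = positionwise_compare(wt, mut, stratum, assignment, direction="less")
            rows[f"WT_vs_{genotype}:{stratum}"] = curve
            near = curve[half - 100: half + 100]
            print(f"  WT vs {genotype:8s} {stratum}: mean {near.mean():5.2f}, "
                  f"max {near.max():5.2f}")
    pd.DataFrame(rows).to_csv(args.out / "positionwise_neglog10p.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
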