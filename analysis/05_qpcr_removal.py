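#!/usr/bin/env python
"""Locus-specific removal by qPCR: percent removal per genotype with paired
one-tailed tests against the wild type.

Reads the Ct table written by 01 (five replicate T/R cycle-threshold pairs
per genotype at a highly transcribed locus), applies the percent-removal
transform per replicate with the negative-shift discard rule, and tests
whether each repair-deficient genotype removes less than WT.
"""

import argparse
from pathlib import Path

import pandas as pd

from dpcseq import genomic_io as gio
from dpcseq.removal_stats import paired_one_tailed_t, summarize_removal


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--inputs", type=Path, default=Path("results/simulated_inputs"))
    parser.add_argument("--out", type=Path, default=Path("results/qpcr_removal"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    records = gio.read_ct_csv(args.inputs / "ct_table.csv")
    by_genotype = {}
    for rec in records:
        by_genotype.setdefault(rec.genotype, []).append(rec)

    results = {g: summarize_removal(recs) for g, recs in by_genotype.items()}
    wt = results.get("WT")
    rows = []
    print("percent DPC removal at the transcribed locus (mean +/- SEM):")
    for genotype, res in results.items():
        p_vs_wt = None
        if wt is not None and genotype != "WT" and \
                len(res.percent_per_replicate) == len(wt.percent_per_replicate) >= 2:
            p_vs_wt = paired_one_tailed_t(
                wt.percent_per_replicate, res.percent_per_replicate, direction="less"
            ).p
        rows.append({
            "locus": res.locus, "genotype": genotype,
            "n_retained": len(res.percent_per_replicate),
            "n_discarded": res.discarded_replicates,
            "mean_percent": round(res.mean, 1) if res.mean is not None else None,
            "sem": round(res.sem, 2) if res.sem is not None else None,
            "p_less_than_WT": round(p_vs_wt, 4) if p_vs_wt is not None else None,
        })
        p_str = f", p(<WT)={p_vs_wt:.4f}" if p_vs_wt is not None else ""
        print(f"  {genotype:8s} {res.mean:5.1f}% +/- {res.sem:.1f} "
              f"(n={len(res.percent_per_replicate)}, "
              f"discarded={res.discarded_replicates}{p_str})")
    pd.DataFrame(rows).to_csv(args.out / "removal_summary.csv", index=False)


if __name__ == "__main__":
    main()
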