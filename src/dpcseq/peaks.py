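"""DPC-enriched region calling and chromatin-state fold enrichment.

Peaks are broad regions where binned coverage exceeds a fold threshold over
a control track (or over the genome-wide mean when no control is supplied).
The caller here is a deliberately simple threshold/merge/min-width scheme —
the scientific quantity of interest is not the peak boundaries but the
downstream fold-enrichment statistic:

    enrichment(state) = (overlap_bases(state, peaks) / state_bases(state))
                        / (peak_bases / genome_bases)

which equals 1 for a state hit exactly in proportion to its genomic share,
and the Spearman correlation of peak signals across chromatin tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from dpcseq.genomic_io import ChromatinSegmentation, GenomicInterval
from dpcseq.metaprofile import CoverageTrack
from dpcseq.removal_stats import paired_one_tailed_t


@dataclass
class PeakList:
    """Sorted, non-overlapping called regions for one condition/replicate."""

    peaks: list[GenomicInterval]
    condition: str | None = None
    replicate: int | None = None

    def __post_init__(self):
        by_chrom: dict[str, int] = {}
        order: list[str] = []
        for pk in self.peaks:
            if pk.chrom not in by_chrom:
                by_chrom[pk.chrom] = -1
                order.append(pk.chrom)
            if pk.start < by_chrom[pk.chrom]:
                raise ValueError(
                    f"peaks overlap or are unsorted on {pk.chrom} at {pk.start}"
                )
            by_chrom[pk.chrom] = pk.end

    def total_bases(self) -> int:
        return sum(len(pk) for pk in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome; labels dropped."""
    merged: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom], key=lambda iv: iv.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def overlap_bases(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> int:
    """Base-pair overlap between two interval sets, double-covered bases in
    either set counted once (both sets are merged first)."""
    total = 0
    a_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(list(a)):
        a_by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in merge_intervals(list(b)):
        for other in a_by_chrom.get(iv.chrom, []):
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if hi > lo:
                total += hi - lo
    return total


def call_broad_peaks(
    treatment: CoverageTrack,
    control: CoverageTrack | None = None,
    min_fold: float = 2.0,
    merge_gap: int = 1000,
    min_width: int = 200,
    condition: str | None = None,
    replicate: int | None = None,
) -> PeakList:
    """Flag bins with treatment >= min_fold x reference, merge nearby runs,
    drop short ones.

    The reference is the control track's bin value when a control is given,
    otherwise the genome-wide mean of the treatment track (background
    assumed uniform). Flagged runs separated by less than ``merge_gap``
    bases are merged; merged runs shorter than ``min_width`` are dropped.
    """
    if control is not None:
        if control.bin_size != treatment.bin_size:
            raise ValueError(
                f"bin size mismatch: {treatment.bin_size} vs {control.bin_size}"
            )
        if set(control.values) != set(treatment.values) or any(
            len(control.values[c]) != len(treatment.values[c]) for c in treatment.values
        ):
            raise ValueError("treatment and control tracks are on different bin grids")
    bs = treatment.bin_size
    peaks: list[GenomicInterval] = []
    global_mean = treatment.global_mean()
    for chrom in treatment.values:
        vals = treatment.values[chrom]
        ref = control.values[chrom] if control is not None else global_mean
        flagged = vals >= min_fold * ref
        if not np.any(flagged):
            continue
        # runs of flagged bins
        idx = np.flatnonzero(flagged)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        run_ends = np.concatenate((idx[breaks], [idx[-1]])) + 1  # exclusive bins
        runs = [(s * bs, min(e * bs, treatment.chrom_sizes[chrom]))
                for s, e in zip(run_starts, run_ends)]
        # merge runs closer than merge_gap
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        peaks.extend(
            GenomicInterval(chrom, s, e) for s, e in merged if e - s >= min_width
        )
    return PeakList(peaks, condition=condition, replicate=replicate)


def fold_enrichment(
    peaks: PeakList, segmentation: ChromatinSegmentation
) -> pd.Series:
    """Per-state fold enrichment of peak coverage.

    For each state s: (bases in s and in peaks / bases in s) divided by
    (peak bases / genome bases). States with zero bases in the segmentation
    are reported as missing (NaN), never as zero. An empty peak list yields
    NaN throughout (the normalizer is undefined).
    """
    states = sorted(segmentation.state_set)
    state_bases = segmentation.state_bases()
    genome = segmentation.genome_size
    peak_bases = peaks.total_bases()
    merged_peaks = merge_intervals(peaks.peaks)
    state_ivs: dict[str, list[GenomicInterval]] = {s: [] for s in states}
    for iv in segmentation.intervals:
        state_ivs[iv.label].append(iv)
    values = {}
    for s in states:
        if state_bases[s] == 0 or peak_bases == 0:
            values[s] = np.nan
            continue
        ov = overlap_bases(state_ivs[s], merged_peaks)
        values[s] = (ov / state_bases[s]) / (peak_bases / genome)
    return pd.Series(values, name="fold_enrichment")


def enrichment_matrix(
    peak_lists: Mapping[tuple[str, int], PeakList],
    segmentation: ChromatinSegmentation,
) -> pd.DataFrame:
    """States x (condition, replicate) fold-enrichment grid."""
    cols = {}
    for (condition, replicate), pl in sorted(peak_lists.items()):
        cols[(condition, replicate)] = fold_enrichment(pl, segmentation)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["condition", "replicate"])
    return df


def compare_state_enrichment(
    matrix: pd.DataFrame, cond_a: str, cond_b: str, direction: str = "greater"
) -> pd.Series:
    """Per-state one-tailed p-values comparing two conditions' enrichments.

    Replicates are paired by index; ``direction="greater"`` tests
    cond_b > cond_a within each state (e.g. T > C for formation), ``"less"``
    tests cond_b < cond_a (e.g. R < T for removal).
    """
    a = matrix[cond_a]
    b = matrix[cond_b]
    if list(a.columns) != list(b.columns):
        raise ValueError(
            f"replicates unpaired between {cond_a} and {cond_b}: "
            f"{list(a.columns)} vs {list(b.columns)}"
        )
    if a.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    pvals = {}
    for state in matrix.index:
        pvals[state] = paired_one_tailed_t(
            a.loc[state].to_numpy(), b.loc[state].to_numpy(), direction=direction
        ).p
    return pd.Series(pvals, name=f"p_{cond_b}_{direction}_{cond_a}")


def peak_signal_correlation(
    peaks: PeakList,
    tracks: Mapping[str, CoverageTrack],
    sample_size: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation matrix of per-peak mean signals across tracks.

    ``sample_size`` peaks are drawn without replacement from the seeded
    stream (all peaks when None or when fewer are available, with a notice).
    Ties are handled by average ranks (scipy's convention). Pairs where
    either signal vector has zero variance are reported as NaN.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to correlate")
    chosen = list(peaks.peaks)
    if sample_size is not None and sample_size < len(chosen):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(chosen), size=sample_size, replace=False)
        chosen = [chosen[i] for i in sorted(idx)]
    elif sample_size is not None and sample_size > len(chosen):
        import logging

        logging.getLogger(__name__).info(
            "sample_size %d exceeds peak count %d; using all peaks",
            sample_size,
            len(chosen),
        )
    names = list(tracks)
    signals = np.array(
        [
            [tracks[name].mean_signal(pk.chrom, pk.start, pk.end) for pk in chosen]
            for name in names
        ]
    )
    n = len(names)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(signals[i]) == 0 or np.ptp(signals[j]) == 0:
                rho = np.nan
            else:
                rho = sps.spearmanr(signals[i], signals[j]).statistic
            corr[i, j] = corr[j, i] = rho
    return pd.DataFrame(corr, index=names, columns=names)
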