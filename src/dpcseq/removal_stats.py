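"""Locus-level DPC removal from qPCR cycle thresholds, and the shared
statistical machinery (paired one-tailed t-test, SEM aggregation).

The central quantity is percent DPC removal derived from the cycle-threshold
shift between material harvested immediately after treatment (T) and after a
recovery period (R):

    dCt = Ct_R - Ct_T
    percent removal = (1 - 0.5**dCt) * 100

A positive dCt means less crosslinked template survived recovery, i.e. DPCs
were removed. Replicate experiments with negative dCt are discarded (they
indicate more template after recovery than before, a failed experiment), and
the discarded count is always reported so data loss is visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CtRecord:
    """Paired qPCR cycle thresholds for one replicate experiment at one locus."""

    locus: str
    genotype: str
    replicate: int
    ct_T: float
    ct_R: float

    def __post_init__(self):
        for name in ("ct_T", "ct_R"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_R - self.ct_T


@dataclass(frozen=True)
class RemovalResult:
    """Percent-removal summary over replicates of one locus/genotype."""

    locus: str
    genotype: str
    percent_per_replicate: tuple[float, ...]
    discarded_replicates: int
    mean: float | None
    sem: float | None


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int
    degenerate: bool = False


def percent_removal(record: CtRecord) -> float | None:
    """Percent DPC removal for one replicate, or ``None`` if discarded.

    Returns ``(1 - 0.5**dCt) * 100`` for dCt >= 0; replicates with negative
    dCt are discarded per the assay's QC rule.
    """
    dct = record.delta_ct
    if not math.isfinite(dct):
        raise ValueError(f"non-finite delta Ct for {record.locus} rep {record.replicate}")
    if dct < 0:
        return None
    return (1.0 - 0.5 ** dct) * 100.0


def summarize_removal(records: Sequence[CtRecord]) -> RemovalResult:
    """Apply the percent-removal transform per replicate, discard negatives,
    and aggregate mean and SEM over the retained replicates.

    All records must share locus and genotype; transformation happens per
    replicate *before* averaging, consistent with the per-experiment discard
    rule.
    """
    if not records:
        raise ValueError("no Ct records to summarize")
    loci = {r.locus for r in records}
    genos = {r.genotype for r in records}
    if len(loci) > 1 or len(genos) > 1:
        raise ValueError(f"mixed loci/genotypes in one summary: {loci}, {genos}")
    retained = []
    discarded = 0
    for rec in records:
        pct = percent_removal(rec)
        if pct is None:
            discarded += 1
        else:
            retained.append(pct)
    if retained:
        mean, sem, _ = aggregate(retained)
    else:
        mean = sem = None
    return RemovalResult(
        locus=records[0].locus,
        genotype=records[0].genotype,
        percent_per_replicate=tuple(retained),
        discarded_replicates=discarded,
        mean=mean,
        sem=sem,
    )


def ddct_fold_change(
    ct_target_cond: float,
    ct_housekeeping_cond: float,
    ct_target_ref: float,
    ct_housekeeping_ref: float,
) -> float:
    """Expression fold change by the 2^-ddCt method.

    dCt = target - housekeeping within each sample; ddCt = dCt(condition) -
    dCt(reference); fold change = 2**(-ddCt). Assumes perfect doubling per
    cycle for both amplicons.
    """
    for v in (ct_target_cond, ct_housekeeping_cond, ct_target_ref, ct_housekeeping_ref):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    dct_cond = ct_target_cond - ct_housekeeping_cond
    dct_ref = ct_target_ref - ct_housekeeping_ref
    return 2.0 ** (-(dct_cond - dct_ref))


def paired_one_tailed_t(
    x: Sequence[float], y: Sequence[float], direction: str
) -> TTestResult:
    """Paired one-tailed t-test on replicate pairs.

    ``direction`` is the alternative hypothesis: ``"greater"`` tests y > x,
    ``"less"`` tests y < x. The statistic is t = mean(d) / (sd(d)/sqrt(n))
    with d = y - x and the n-1 sd denominator, referred to Student's t with
    n-1 degrees of freedom.

    Degenerate case (all differences identical): if the shared difference is
    zero the data carry no evidence either way and p = 1 is returned with the
    ``degenerate`` flag; if it is non-zero the p-value limit in the matching
    direction is 0 (1 in the opposite direction), also flagged.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"unpaired replicates: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 replicate pairs")
    d = y - x
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(t=0.0, p=1.0, df=df, degenerate=True)
        sign_ok = (md > 0) == (direction == "greater")
        return TTestResult(
            t=math.copysign(math.inf, md), p=0.0 if sign_ok else 1.0, df=df, degenerate=True
        )
    t = md / (sd / math.sqrt(n))
    if direction == "greater":
        p = float(sps.t.sf(t, df))
    else:
        p = float(sps.t.cdf(t, df))
    return TTestResult(t=t, p=p, df=df)


def aggregate(values: Sequence[float]) -> tuple[float, float | None, int]:
    """Arithmetic mean, SEM (sd with n-1 denominator over sqrt n), and n.

    SEM is ``None`` at n = 1 (undefined, not zero).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty value list")
    mean = float(np.mean(arr))
    if arr.size == 1:
        return mean, None, 1
    sem = float(np.std(arr, ddof=1) / math.sqrt(arr.size))
    return mean, sem, int(arr.size)
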