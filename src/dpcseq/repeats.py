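"""Removal efficiency at repetitive loci via a reconstructed reference.

Repetitive genes (the rDNA analogue here) cannot be quantified against a
standard annotation because short reads do not map uniquely. Instead, a
reconstructed reference is built from one canonical repeat sequence plus
panels of non-transcribed (Q0) and highly transcribed (Q4) control genes.
Reads are hard-trimmed to their first 50 bp, counted only when they match a
reference sequence with zero mismatches, and the Relative Removal Efficiency
(RRE) of a group is the ratio of filtered read counts in the treated (T)
library over the recovered (R) library, averaged over replicates. RRE ~ 1
means no preferential removal at that group; RRE > 1 means DPCs were
preferentially removed during recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dpcseq.genomic_io import NUCLEOTIDES
from dpcseq.removal_stats import aggregate, paired_one_tailed_t

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RepeatReference:
    """Canonical repeat plus named control-gene panels.

    ``canonical_name``/``canonical_seq`` hold the repeat unit (the study
    analogue is the 13,357 b 45S pre-rRNA); ``control_groups`` maps a group
    label (``Q0_controls``, ``Q4_controls``) to its named sequences.
    Sequence names must be unique across the whole reference.
    """

    canonical_name: str
    canonical_seq: str
    control_groups: dict[str, dict[str, str]] = field(default_factory=dict)
    repeat_group: str = "repeat"

    def __post_init__(self):
        names = [self.canonical_name]
        for seqs in self.control_groups.values():
            names.extend(seqs)
        if len(names) != len(set(names)):
            raise ValueError("sequence names must be unique across the reference")
        for name, seq in self.iter_sequences():
            if not seq:
                raise ValueError(f"empty sequence {name!r}")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise ValueError(f"non-nucleotide characters {sorted(bad)} in {name!r}")

    def iter_sequences(self):
        yield self.canonical_name, self.canonical_seq
        for seqs in self.control_groups.values():
            yield from seqs.items()

    @property
    def groups(self) -> dict[str, dict[str, str]]:
        """All target groups, the canonical repeat included as its own group."""
        out = {self.repeat_group: {self.canonical_name: self.canonical_seq}}
        out.update(self.control_groups)
        return out

    def group_of(self, target: str) -> str:
        if target == self.canonical_name:
            return self.repeat_group
        for group, seqs in self.control_groups.items():
            if target in seqs:
                return group
        raise KeyError(f"unknown target {target!r}")

    def to_fasta_dict(self) -> dict[str, str]:
        return dict(self.iter_sequences())


@dataclass(frozen=True)
class Read:
    name: str
    seq: str
    source: str | None = None  # target of origin when simulated, for truth checks


@dataclass
class ReadSet:
    reads: list[Read]
    condition: str | None = None
    replicate: int | None = None

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class MatchCounts:
    """Outcome of mismatch-free counting: per-target and per-group tallies.

    ``matched + ambiguous + unmatched`` always equals the number of reads
    counted, so no read is silently lost.
    """

    per_target: dict[str, int]
    per_group: dict[str, int]
    ambiguous: int
    unmatched: int

    @property
    def matched(self) -> int:
        return sum(self.per_group.values())

    @property
    def total(self) -> int:
        return self.matched + self.ambiguous + self.unmatched


@dataclass
class RREEntry:
    group: str
    counts_T: tuple[int, ...]
    counts_R: tuple[int, ...]
    rre_per_replicate: tuple[float, ...]
    rre_mean: float
    sem: float | None
    replicate_n: int


def hardtrim_reads(reads: ReadSet, keep: int = 50) -> tuple[ReadSet, int]:
    """Keep only the first ``keep`` bases from the 5' end of every read.

    Reads shorter than ``keep`` are dropped; the drop count is returned so
    the filter's cost is visible. The 5' prefix is used because it is the
    least error-prone part of a sequencing read.
    """
    if keep < 1:
        raise ValueError(f"keep must be >= 1, got {keep}")
    kept = []
    dropped = 0
    for read in reads.reads:
        if len(read.seq) < keep:
            dropped += 1
        else:
            kept.append(Read(read.name, read.seq[:keep], read.source))
    return ReadSet(kept, reads.condition, reads.replicate), dropped


def _build_kmer_index(
    reference: RepeatReference, k: int, include_revcomp: bool
) -> dict[str, frozenset[str]]:
    """Map every k-mer occurring in the reference (and optionally its reverse
    complement) to the set of target names containing it."""
    index: dict[str, set[str]] = {}
    for name, seq in reference.iter_sequences():
        strands = [seq]
        if include_revcomp:
            strands.append(reverse_complement(seq))
        for strand_seq in strands:
            for i in range(len(strand_seq) - k + 1):
                index.setdefault(strand_seq[i : i + k], set()).add(name)
    return {kmer: frozenset(names) for kmer, names in index.items()}


def exact_match_count(
    reads: ReadSet, reference: RepeatReference, include_revcomp: bool = True
) -> MatchCounts:
    """Count reads matching each reference target with zero mismatches.

    A read counts for target t iff it occurs as an exact substring of t's
    sequence (or, with ``include_revcomp``, of its reverse complement — real
    libraries are unstranded). A read whose exact matches span more than one
    target *group* is discarded as ambiguous, in the spirit of
    unique-mapping filters; multi-target hits within one group are fine and
    are attributed to the lexicographically first target. Reads matching
    nothing are unmatched.

    Reads must all have the same length (hard-trim first); reads with indels
    or any substitution relative to the reference simply fail to match.
    """
    if not any(True for _ in reference.iter_sequences()):
        raise ValueError("reference is empty")
    per_target = {name: 0 for name, _ in reference.iter_sequences()}
    per_group = {group: 0 for group in reference.groups}
    ambiguous = 0
    unmatched = 0
    if not reads.reads:
        return MatchCounts(per_target, per_group, ambiguous, unmatched)
    lengths = {len(r.seq) for r in reads.reads}
    if len(lengths) != 1:
        raise ValueError(f"reads must be trimmed to a uniform length, got {sorted(lengths)}")
    k = lengths.pop()
    for name, seq in reference.iter_sequences():
        if k > len(seq):
            raise ValueError(
                f"read length {k} exceeds target {name!r} length {len(seq)}"
            )
    index = _build_kmer_index(reference, k, include_revcomp)
    for read in reads.reads:
        targets = index.get(read.seq)
        if not targets:
            unmatched += 1
            continue
        groups = {reference.group_of(t) for t in targets}
        if len(groups) > 1:
            ambiguous += 1
            continue
        per_group[groups.pop()] += 1
        per_target[min(targets)] += 1
    return MatchCounts(per_target, per_group, ambiguous, unmatched)


def compute_rre(
    group: str, counts_T: Sequence[int], counts_R: Sequence[int]
) -> RREEntry:
    """Relative Removal Efficiency for one group: per-replicate T/R count
    ratio, then the arithmetic mean over replicates, with SEM."""
    if len(counts_T) != len(counts_R):
        raise ValueError(
            f"unpaired replicates for {group}: {len(counts_T)} T vs {len(counts_R)} R"
        )
    if not counts_T:
        raise ValueError(f"no replicates for group {group}")
    for i, c_r in enumerate(counts_R):
        if c_r == 0:
            raise ZeroDivisionError(
                f"RRE undefined for group {group}: zero R count in replicate {i}"
            )
    ratios = tuple(t / r for t, r in zip(counts_T, counts_R))
    mean, sem, n = aggregate(ratios)
    return RREEntry(
        group=group,
        counts_T=tuple(counts_T),
        counts_R=tuple(counts_R),
        rre_per_replicate=ratios,
        rre_mean=mean,
        sem=sem,
        replicate_n=n,
    )


def rre_report(
    entries: Mapping[str, RREEntry],
    repeat_group: str = "repeat",
    q0_group: str = "Q0_controls",
    q4_group: str = "Q4_controls",
):
    """Compare group RREs: Q4 controls vs Q0 controls (expected significant
    when removal is transcription-coupled) and repeat vs Q0 controls
    (expected non-significant when the repeat escapes that pathway).

    Returns a pandas DataFrame of group means/SEMs and a dict of one-tailed
    paired p-values over per-replicate RREs.
    """
    import pandas as pd

    for g in (repeat_group, q0_group, q4_group):
        if g not in entries:
            raise ValueError(f"group {g!r} missing from RRE results")
    ns = {e.replicate_n for e in entries.values()}
    if len(ns) != 1:
        raise ValueError(f"groups have differing replicate structure: {ns}")
    table = pd.DataFrame(
        [
            {
                "group": e.group,
                "rre_mean": e.rre_mean,
                "sem": e.sem,
                "n": e.replicate_n,
                "rre_per_replicate": ",".join(format(r, ".6g") for r in e.rre_per_replicate),
            }
            for e in entries.values()
        ]
    ).set_index("group")
    pvals = {
        "Q4_gt_Q0": paired_one_tailed_t(
            entries[q0_group].rre_per_replicate,
            entries[q4_group].rre_per_replicate,
            direction="greater",
        ).p,
        "repeat_gt_Q0": paired_one_tailed_t(
            entries[q0_group].rre_per_replicate,
            entries[repeat_group].rre_per_replicate,
            direction="greater",
        ).p,
    }
    return table, pvals
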