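"""CPM coverage tracks, expression strata and TSS-centered metaprofiles.

Fragment coverage is binned (10 bp by default) and normalized to counts per
million mapped fragments (CPM), so libraries of different depth are
comparable. Genes are stratified by expression into Q0 (FPKM = 0, sampled)
and Q1-Q4 (equal-size rank groups of genes with FPKM >= 0.1, lowest to
highest; genes with 0 < FPKM < 0.1 are excluded and reported). Signal
matrices are anchored at each gene's transcription start site and oriented
in the direction of transcription, the standard metagene layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dpcseq.genomic_io import GeneModel
from dpcseq.removal_stats import paired_one_tailed_t

STRATA = ("Q0", "Q1", "Q2", "Q3", "Q4")
FPKM_THRESHOLD = 0.1


@dataclass
class CoverageTrack:
    """Fixed-bin CPM-normalized coverage over a genome.

    ``values[chrom][i]`` is the CPM value of bin ``[i*bin_size,
    (i+1)*bin_size)``; the final bin may be truncated at the chromosome end.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    total_fragments: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.chrom_sizes:
            self.chrom_sizes = {
                c: len(v) * self.bin_size for c, v in self.values.items()
            }
        for chrom, vals in self.values.items():
            if np.any(vals < 0):
                raise ValueError(f"negative coverage values on {chrom}")

    def global_mean(self) -> float:
        return float(np.mean(np.concatenate(list(self.values.values()))))

    def mean_signal(self, chrom: str, start: int, end: int) -> float:
        """Mean bin value over ``[start, end)``, bins weighted equally."""
        vals = self.values[chrom]
        lo = max(0, start // self.bin_size)
        hi = min(len(vals), -(-end // self.bin_size))
        if hi <= lo:
            return 0.0
        return float(np.mean(vals[lo:hi]))


def cpm_normalize(
    fragment_set, chrom_sizes: Mapping[str, int], bin_size: int = 10
) -> CoverageTrack:
    """Binned CPM coverage from a fragment set.

    Each fragment contributes its full span: every bin it overlaps is
    incremented by one (full-insert coverage, no read-end extension needed
    because fragments carry both ends). Bin value = overlapping-fragment
    count x 1e6 / total fragments, making the track depth-invariant.
    """
    fragments = fragment_set.fragments
    if not fragments:
        raise ValueError("cannot CPM-normalize an empty fragment set")
    counts = {
        chrom: np.zeros(-(-size // bin_size), dtype=np.float64)
        for chrom, size in chrom_sizes.items()
    }
    for chrom, start, end in fragments:
        arr = counts[chrom]
        lo = start // bin_size
        hi = min(len(arr), -(-end // bin_size))
        arr[lo:hi] += 1.0
    total = len(fragments)
    values = {chrom: arr * (1e6 / total) for chrom, arr in counts.items()}
    return CoverageTrack(
        bin_size=bin_size,
        values=values,
        total_fragments=total,
        chrom_sizes=dict(chrom_sizes),
    )


@dataclass
class QuintileAssignment:
    """Gene -> expression stratum mapping with the per-stratum member lists.

    The field keeps the study's "quintile" naming although Q1-Q4 are rank
    quartiles of the expressed genes and Q0 is a sample of silent genes.
    """

    stratum_of: dict[str, str]
    strata: dict[str, list[str]]
    excluded: list[str]  # genes with 0 < fpkm < threshold

    def genes_in(self, stratum: str) -> list[str]:
        return self.strata.get(stratum, [])


def assign_quintiles(
    genes: Sequence[GeneModel],
    q0_sample_size: int | None = None,
    seed: int = 0,
) -> QuintileAssignment:
    """Stratify genes by expression into Q0 and Q1-Q4.

    Genes with FPKM >= 0.1 are ranked ascending (ties broken by gene id for
    determinism) and split into four groups whose sizes differ by at most
    one: Q1 holds the lowest-expressed, Q4 the highest. Genes with FPKM = 0
    form the Q0 pool, down-sampled to ``q0_sample_size`` with the seeded
    stream (all of them when ``None``). Genes with 0 < FPKM < 0.1 fall in
    neither stratum; they are excluded and listed in the return value.
    """
    if not genes:
        raise ValueError("no genes to stratify")
    expressed = sorted(
        (g for g in genes if g.fpkm >= FPKM_THRESHOLD), key=lambda g: (g.fpkm, g.gene_id)
    )
    zeroes = sorted((g.gene_id for g in genes if g.fpkm == 0.0))
    excluded = sorted(g.gene_id for g in genes if 0.0 < g.fpkm < FPKM_THRESHOLD)
    if not expressed:
        raise ValueError(f"no genes with FPKM >= {FPKM_THRESHOLD}; cannot build strata")
    rng = np.random.default_rng(seed)
    if q0_sample_size is not None and q0_sample_size < len(zeroes):
        q0 = sorted(rng.choice(zeroes, size=q0_sample_size, replace=False).tolist())
    else:
        q0 = zeroes
    # np.array_split puts the larger groups first; assign lowest ranks to Q1
    chunks = np.array_split(np.array([g.gene_id for g in expressed], dtype=object), 4)
    strata = {"Q0": list(q0)}
    for i, chunk in enumerate(chunks, start=1):
        strata[f"Q{i}"] = chunk.tolist()
    stratum_of = {gid: s for s, gids in strata.items() for gid in gids}
    return QuintileAssignment(stratum_of=stratum_of, strata=strata, excluded=excluded)


@dataclass
class MetaMatrix:
    """Genes x bins signal matrix spanning +/- ``window`` around each TSS.

    Rows of minus-strand genes are stored reversed, so columns always run
    upstream -> downstream in the direction of transcription. Rows that
    would extend past a chromosome edge are zero-padded and the gene is
    flagged.
    """

    values: np.ndarray  # shape (n_genes, 2*window/bin_size)
    gene_ids: list[str]
    bin_size: int
    window: int
    flagged_genes: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def offsets(self) -> np.ndarray:
        """Bin-start offsets relative to the TSS, in transcription direction."""
        return np.arange(-self.window, self.window, self.bin_size)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def tss_matrix(
    track: CoverageTrack, genes: Sequence[GeneModel], window: int = 20_000
) -> MetaMatrix:
    """Signal matrix of ``track`` over ``[tss - window, tss + window)`` per gene.

    ``window`` must be a multiple of the track's bin size. TSS positions are
    snapped to their containing bin. Unknown chromosomes raise.
    """
    bs = track.bin_size
    if window % bs != 0:
        raise ValueError(f"window {window} must be a multiple of bin size {bs}")
    half = window // bs
    n_cols = 2 * half
    values = np.zeros((len(genes), n_cols))
    flagged = []
    for i, gene in enumerate(genes):
        if gene.chrom not in track.values:
            raise KeyError(f"chromosome {gene.chrom!r} not in track")
        vals = track.values[gene.chrom]
        center = gene.tss // bs
        lo, hi = center - half, center + half
        src_lo, src_hi = max(0, lo), min(len(vals), hi)
        row = np.zeros(n_cols)
        row[src_lo - lo : src_hi - lo] = vals[src_lo:src_hi]
        if lo < 0 or hi > len(vals):
            flagged.append(gene.gene_id)
        if gene.strand == "-":
            row = row[::-1]
        values[i] = row
    return MetaMatrix(
        values=values,
        gene_ids=[g.gene_id for g in genes],
        bin_size=bs,
        window=window,
        flagged_genes=flagged,
    )


def quintile_profiles(
    matrix: MetaMatrix, assignment: QuintileAssignment
) -> dict[str, tuple[np.ndarray, int]]:
    """Column-wise mean signal per expression stratum.

    Returns ``{stratum: (curve, n_genes)}``; strata with no member rows are
    omitted. Matrix rows whose gene is not in the assignment are skipped.
    """
    idx_of = {gid: i for i, gid in enumerate(matrix.gene_ids)}
    out = {}
    for stratum in STRATA:
        rows = [idx_of[g] for g in assignment.genes_in(stratum) if g in idx_of]
        if not rows:
            continue
        out[stratum] = (matrix.values[rows].mean(axis=0), len(rows))
    return out


def positionwise_compare(
    matrices_a: Sequence[MetaMatrix],
    matrices_b: Sequence[MetaMatrix],
    stratum: str,
    assignment: QuintileAssignment,
    direction: str = "less",
) -> np.ndarray:
    """Per-column -log10 p comparing two replicate groups within one stratum.

    At each bin position the stratum mean is computed per replicate on each
    side, and the replicate-paired one-tailed t-test is applied. The default
    direction ``"less"`` tests a < b at each column — e.g. with a = WT and
    b = a repair-deficient genotype after recovery, lower WT signal means
    more removal, so small p flags positions of genotype-dependent repair.
    """
    if len(matrices_a) != len(matrices_b):
        raise ValueError(
            f"replicate count mismatch: {len(matrices_a)} vs {len(matrices_b)}"
        )
    if len(matrices_a) < 2:
        raise ValueError("need >= 2 replicates per side")

    def stratum_means(matrices):
        curves = []
        for m in matrices:
            idx_of = {gid: i for i, gid in enumerate(m.gene_ids)}
            rows = [idx_of[g] for g in assignment.genes_in(stratum) if g in idx_of]
            if not rows:
                raise ValueError(f"stratum {stratum!r} has no genes in a matrix")
            curves.append(m.values[rows].mean(axis=0))
        return np.vstack(curves)  # replicates x columns

    means_a = stratum_means(matrices_a)
    means_b = stratum_means(matrices_b)
    n_cols = means_a.shape[1]
    # direction "less" per spec convention tests a < b, i.e. b - a > 0
    flipped = "greater" if direction == "less" else "less"
    logp = np.empty(n_cols)
    for j in range(n_cols):
        res = paired_one_tailed_t(means_a[:, j], means_b[:, j], direction=flipped)
        logp[j] = -np.log10(max(res.p, 1e-300))
    return logp
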