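"""Synthetic-data generator for the DPC-seq pipeline.

Generates every input the analysis needs — an annotated toy genome with an
18-state chromatin segmentation, a gene table spanning silent to highly
expressed genes, condition-tagged DPC fragment sets, repeat-locus reads, and
qPCR cycle thresholds — under an explicit formation/removal model:

* Untreated control (C) fragments fall uniformly across the genome at a
  state-independent baseline rate (steady-state DPCs are essentially evenly
  distributed).
* Treated (T) fragments fall with per-chromatin-state Poisson intensities,
  highest in bivalent/Polycomb and actively transcribed states, emulating
  preferential crosslink formation in accessible, transcription-associated
  chromatin.
* Recovered (R) fragments are an independent T-like draw thinned by removal:
  a fragment overlapping a gene in expression stratum q of genotype g
  survives with probability 1 - quintile_removal[g][q], so removal is
  transcription-coupled and genotype-dependent. Intergenic fragments are
  thinned at the genotype's non-transcribed baseline.

All randomness flows from a master seed through a documented splitting rule
(CRC32 of string tags into numpy SeedSequence spawn keys), so the same
config and seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from dpcseq.genomic_io import ChromatinSegmentation, GeneModel, GenomicInterval
from dpcseq.metaprofile import STRATA, assign_quintiles
from dpcseq.removal_stats import CtRecord
from dpcseq.repeats import Read, ReadSet, RepeatReference, reverse_complement

TREATMENT_LABELS = ("C", "T", "R")

#: 18-state chromatin model labels (ChromHMM-style naming).
CHROMATIN_STATES_18 = (
    "TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk", "ZNF/Rpts",
    "Het", "TssBiv", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

#: Expected T-condition fragments per kilobase, per state. Highest for
#: Polycomb-repressed and bivalent states, elevated for strong transcription,
#: weak enhancers and ZNF/repeats, lowest for quiescent chromatin — the
#: qualitative formation pattern formaldehyde produces.
DEFAULT_FORMATION_INTENSITY = {
    "TssA": 4.0, "TssFlnk": 3.5, "TssFlnkU": 3.5, "TssFlnkD": 3.5,
    "Tx": 5.0, "TxWk": 3.0, "EnhG1": 3.5, "EnhG2": 3.5,
    "EnhA1": 4.0, "EnhA2": 4.0, "EnhWk": 4.5, "ZNF/Rpts": 4.5,
    "Het": 1.5, "TssBiv": 7.0, "EnhBiv": 6.5, "ReprPC": 8.0,
    "ReprPCWk": 5.0, "Quies": 1.2,
}

#: Removal fraction during the recovery window at highly transcribed (Q4)
#: loci, per genotype, with a transcription-independent baseline of 0.10.
#: WT and GG-NER-deficient XPC-KO remove efficiently; XPA-KO (core NER)
#: partially; CSB-KO (TC-NER initiation) is reduced to baseline.
DEFAULT_TRANSCRIBED_REMOVAL = {
    "WT": 0.72,
    "XPA-KO": 0.40,
    "XPC-KO": 0.72,
    "CSB-KO": 0.10,
}
DEFAULT_BASELINE_REMOVAL = 0.10


def default_quintile_removal(
    transcribed: Mapping[str, float] | None = None,
    baseline: float = DEFAULT_BASELINE_REMOVAL,
) -> dict[str, dict[str, float]]:
    """Per-genotype removal fractions per expression stratum: baseline at Q0,
    the genotype's transcribed value at Q4, linear in between."""
    transcribed = dict(transcribed or DEFAULT_TRANSCRIBED_REMOVAL)
    out = {}
    for genotype, top in transcribed.items():
        out[genotype] = {
            stratum: baseline + (top - baseline) * i / 4
            for i, stratum in enumerate(STRATA)
        }
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults defining the
    simulated conditions (see docs/methods.md for rationale)."""

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    n_states: int = 18
    state_formation_intensity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FORMATION_INTENSITY)
    )
    baseline_intensity: float = 0.5  # C-condition fragments per kb
    quintile_removal: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_quintile_removal
    )
    fragment_length_range: tuple[int, int] = (200, 500)
    n_replicates: int = 3
    seed: int = 0
    ct_noise_sd: float = 0.15
    ct_base_cycle: float = 22.0
    reprogrammable_genes: frozenset[str] = frozenset()
    # TSS-proximal removal shaping: 0 = uniform thinning over the gene body
    # (the default contract); > 0 scales the thinning probability by a weight
    # decaying linearly from 1 at the TSS to 0 at this distance downstream.
    tss_decay_bp: int = 0
    # genome layout
    block_length_range: tuple[int, int] = (2_000, 15_000)
    gene_length_range: tuple[int, int] = (3_000, 12_000)
    gene_gap_range: tuple[int, int] = (1_000, 8_000)
    p_zero_fpkm: float = 0.30
    p_subthreshold_fpkm: float = 0.05
    # repeat locus
    repeat_name: str = "rRNA_45S"
    repeat_length: int = 13_357
    n_control_genes: int = 100
    control_gene_length: int = 2_000
    repeat_read_length: int = 150
    repeat_read_depth: float = 200.0  # expected reads per target per library
    repeat_error_rate: float = 0.001
    repeat_removal: Mapping[str, float] = field(
        default_factory=lambda: {"repeat": 0.10, "Q0_controls": 0.10, "Q4_controls": 0.72}
    )

    def __post_init__(self):
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if self.baseline_intensity < 0:
            raise ValueError("baseline_intensity must be >= 0")
        for state, lam in self.state_formation_intensity.items():
            if lam < 0:
                raise ValueError(f"formation intensity for {state!r} must be >= 0")
        if len(self.state_formation_intensity) != self.n_states:
            raise ValueError(
                f"state_formation_intensity has {len(self.state_formation_intensity)} "
                f"states, config says n_states={self.n_states}"
            )
        for genotype, fracs in self.quintile_removal.items():
            for stratum, frac in fracs.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"removal fraction {frac} for {genotype}/{stratum} outside [0, 1]"
                    )
        lo, hi = self.fragment_length_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad fragment_length_range {self.fragment_length_range}")
        for group, frac in self.repeat_removal.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"repeat removal {frac} for {group!r} outside [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(self.quintile_removal)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.state_formation_intensity)

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("fragment_length_range", "block_length_range",
                    "gene_length_range", "gene_gap_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "reprogrammable_genes" in d:
            d["reprogrammable_genes"] = frozenset(d["reprogrammable_genes"])
        return cls(**d)


def substream(seed: int, *tags) -> np.random.Generator:
    """Derive an independent random stream from a master seed and string tags.

    Tags are hashed with CRC32 into a numpy ``SeedSequence`` spawn key, so
    streams for different (condition, genotype, replicate, purpose)
    combinations never collide and never depend on call order.
    """
    key = tuple(zlib.crc32(str(t).encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class FragmentSet:
    """Condition-, replicate- and genotype-tagged DPC fragment intervals."""

    fragments: list[tuple[str, int, int]]
    condition: str
    replicate: int
    genotype: str

    def __post_init__(self):
        if self.condition not in TREATMENT_LABELS:
            raise ValueError(f"condition must be one of {TREATMENT_LABELS}")
        for chrom, start, end in self.fragments:
            if not 0 <= start < end:
                raise ValueError(f"bad fragment [{start}, {end}) on {chrom}")

    @property
    def total_count(self) -> int:
        return len(self.fragments)

    def to_intervals(self) -> list[GenomicInterval]:
        name = f"{self.condition}:{self.replicate}:{self.genotype}"
        return [GenomicInterval(c, s, e, name) for c, s, e in self.fragments]


@dataclass
class ToyGenome:
    """Everything the pipeline consumes: segmentation, genes, repeat reference."""

    segmentation: ChromatinSegmentation
    genes: list[GeneModel]
    repeat_reference: RepeatReference

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.segmentation.chrom_sizes


def build_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Generate the annotated toy genome for one configuration.

    The segmentation partitions each chromosome exactly into labeled state
    blocks (every one of the ``n_states`` labels is guaranteed to occur);
    genes are placed non-overlapping with random strands and an FPKM mix
    spanning silent (FPKM = 0), sub-threshold and expressed; the repeat
    reference holds one canonical repeat plus Q0/Q4 control panels.
    """
    states = list(config.states)
    chrom_sizes = _chromosome_sizes(config)

    # --- segmentation ---------------------------------------------------
    rng = substream(config.seed, "segmentation")
    lo, hi = config.block_length_range
    intervals: list[GenomicInterval] = []
    state_cycle: list[str] = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        while pos < size:
            if not state_cycle:
                state_cycle = list(states)
                rng.shuffle(state_cycle)
            length = int(rng.integers(lo, hi + 1))
            end = min(pos + length, size)
            intervals.append(GenomicInterval(chrom, pos, end, state_cycle.pop()))
            pos = end
    if len(intervals) < config.n_states:
        raise ValueError(
            f"genome of {config.genome_length} b yields only {len(intervals)} "
            f"state blocks; cannot place all {config.n_states} states — "
            "increase genome_length or shrink block_length_range"
        )
    segmentation = ChromatinSegmentation(intervals, frozenset(states))

    # --- genes ----------------------------------------------------------
    rng = substream(config.seed, "genes")
    genes: list[GeneModel] = []
    g_lo, g_hi = config.gene_length_range
    gap_lo, gap_hi = config.gene_gap_range
    idx = 0
    for chrom, size in chrom_sizes.items():
        pos = int(rng.integers(gap_lo, gap_hi + 1))
        while True:
            length = int(rng.integers(g_lo, g_hi + 1))
            if pos + length >= size - gap_lo:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            tss = pos if strand == "+" else pos + length - 1
            genes.append(
                GeneModel(f"gene_{idx:04d}", chrom, strand, tss, length,
                          _draw_fpkm(rng, config))
            )
            idx += 1
            pos += length + int(rng.integers(gap_lo, gap_hi + 1))
    n_expressed = sum(g.fpkm >= 0.1 for g in genes)
    n_zero = sum(g.fpkm == 0.0 for g in genes)
    if n_expressed < 8 or n_zero < 2:
        raise ValueError(
            f"genome too short to place the requested gene strata: got "
            f"{n_expressed} expressed and {n_zero} silent genes; need >= 8 "
            "expressed and >= 2 silent — increase genome_length"
        )

    # --- repeat reference -------------------------------------------------
    rng = substream(config.seed, "repeat_reference")
    canonical = _random_sequence(rng, config.repeat_length)
    control_groups = {}
    for group in ("Q0_controls", "Q4_controls"):
        control_groups[group] = {
            f"{group[:2]}_ctrl_{i:03d}": _random_sequence(rng, config.control_gene_length)
            for i in range(config.n_control_genes)
        }
    reference = RepeatReference(config.repeat_name, canonical, control_groups)

    return ToyGenome(segmentation, genes, reference)


def _chromosome_sizes(config: SimulationConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    sizes = {f"chr{i + 1}": base for i in range(config.n_chromosomes)}
    sizes[f"chr{config.n_chromosomes}"] += config.genome_length % config.n_chromosomes
    return sizes


def _draw_fpkm(rng: np.random.Generator, config: SimulationConfig) -> float:
    u = rng.random()
    if u < config.p_zero_fpkm:
        return 0.0
    if u < config.p_zero_fpkm + config.p_subthreshold_fpkm:
        return float(rng.uniform(0.01, 0.099))
    # expressed: log-uniform over ~3.5 decades, 0.1 to ~500 FPKM
    return float(10 ** rng.uniform(-1.0, 2.7))


def toggle_expression(
    genes: Sequence[GeneModel], gene_ids, repressed_fpkm: float = 0.0
) -> list[GeneModel]:
    """Repress (or re-set) expression of selected genes — the in-silico
    analogue of reprogramming transcription with dexamethasone."""
    gene_ids = set(gene_ids)
    unknown = gene_ids - {g.gene_id for g in genes}
    if unknown:
        raise KeyError(f"unknown gene ids: {sorted(unknown)}")
    return [
        GeneModel(g.gene_id, g.chrom, g.strand, g.tss, g.length, repressed_fpkm)
        if g.gene_id in gene_ids
        else g
        for g in genes
    ]


# --------------------------------------------------------------------------
# DPC fragments


def simulate_dpc_fragments(
    genome: ToyGenome,
    config: SimulationConfig,
    condition: str,
    genotype: str = "WT",
    replicate: int = 0,
) -> FragmentSet:
    """Draw one replicate's DPC fragment set for a condition and genotype.

    C: Poisson(baseline_intensity x kb) fragments placed uniformly per
    chromosome. T: Poisson(state intensity x block kb) per segmentation
    block, uniform within the block. R: an independent T-like draw thinned
    fragment-by-fragment — survival probability 1 - removal fraction of the
    overlapped gene's stratum (non-transcribed baseline when intergenic).
    Fragment lengths are uniform over ``fragment_length_range``. Every draw
    comes from the (condition, genotype, replicate)-specific seeded stream.
    """
    if condition not in TREATMENT_LABELS:
        raise ValueError(f"condition must be one of {TREATMENT_LABELS}, got {condition!r}")
    if genotype not in config.quintile_removal:
        raise KeyError(
            f"genotype {genotype!r} has no removal parameters; "
            f"known: {list(config.quintile_removal)}"
        )
    rng = substream(config.seed, "fragments", condition, genotype, replicate)
    chrom_sizes = genome.chrom_sizes
    if condition == "C":
        fragments = _draw_uniform_fragments(rng, chrom_sizes, config)
    else:
        fragments = _draw_state_fragments(rng, genome, config)
        if condition == "R":
            fragments = _thin_fragments(rng, fragments, genome, config, genotype)
    return FragmentSet(fragments, condition, replicate, genotype)


def _fragment_at(rng, chrom: str, lo: int, hi: int, chrom_len: int,
                 config: SimulationConfig) -> tuple[str, int, int]:
    flo, fhi = config.fragment_length_range
    length = int(rng.integers(flo, fhi + 1))
    start = int(rng.integers(lo, hi))
    start = min(start, chrom_len - length)  # keep full length inside the chromosome
    start = max(start, 0)
    return (chrom, start, start + length)


def _draw_uniform_fragments(rng, chrom_sizes, config) -> list[tuple[str, int, int]]:
    fragments = []
    for chrom, size in chrom_sizes.items():
        n = rng.poisson(config.baseline_intensity * size / 1000.0)
        for _ in range(n):
            fragments.append(_fragment_at(rng, chrom, 0, size, size, config))
    return fragments


def _draw_state_fragments(rng, genome: ToyGenome, config) -> list[tuple[str, int, int]]:
    chrom_sizes = genome.chrom_sizes
    fragments = []
    for block in genome.segmentation.intervals:
        lam = config.state_formation_intensity[block.label] * len(block) / 1000.0
        n = rng.poisson(lam)
        size = chrom_sizes[block.chrom]
        for _ in range(n):
            fragments.append(
                _fragment_at(rng, block.chrom, block.start, block.end, size, config)
            )
    return fragments


def _thin_fragments(rng, fragments, genome: ToyGenome, config, genotype: str):
    """Independent per-fragment survival under the genotype's removal model."""
    removal = config.quintile_removal[genotype]
    baseline = removal.get("Q0", 0.0)
    assignment = assign_quintiles(genome.genes, seed=int(substream(
        config.seed, "quintiles").integers(2**31)))
    # per-chromosome sorted gene arrays for overlap lookup
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genome.genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    starts = {c: np.array([g.start for g in gs]) for c, gs in by_chrom.items()}
    survivors = []
    for chrom, fstart, fend in fragments:
        gene = _overlapping_gene(by_chrom.get(chrom, []), starts.get(chrom), fstart, fend)
        if gene is None:
            p_remove = baseline
        else:
            stratum = assignment.stratum_of.get(gene.gene_id)
            p_remove = removal.get(stratum, baseline) if stratum else baseline
            if config.tss_decay_bp > 0:
                mid = (fstart + fend) // 2
                d = (mid - gene.tss) if gene.strand == "+" else (gene.tss - mid)
                weight = max(0.0, 1.0 - max(d, 0) / config.tss_decay_bp)
                p_remove *= weight
        if rng.random() >= p_remove:
            survivors.append((chrom, fstart, fend))
    return survivors


def _overlapping_gene(genes, gene_starts, fstart, fend):
    """First gene overlapping [fstart, fend); genes are non-overlapping so
    checking the insertion neighborhood suffices."""
    if not genes:
        return None
    i = int(np.searchsorted(gene_starts, fend))
    for j in (i - 1, i):
        if 0 <= j < len(genes):
            g = genes[j]
            if g.start < fend and fstart < g.end:
                return g
    return None


# --------------------------------------------------------------------------
# Repeat-locus reads


def simulate_repeat_reads(
    reference: RepeatReference,
    config: SimulationConfig,
    condition: str,
    replicate: int = 0,
    abundances: Mapping[str, float] | None = None,
) -> ReadSet:
    """Draw sequencing reads from the repeat reference targets.

    Per-target read counts are Poisson with mean ``abundances[target]``
    (default: ``repeat_read_depth``, scaled for the R condition by 1 minus
    the group's removal fraction). Reads start uniformly within the target,
    come from either strand, and carry substitution errors at
    ``repeat_error_rate`` per base. Each read records its target of origin
    for truth-based testing.
    """
    if condition not in ("T", "R"):
        raise ValueError(f"repeat reads exist for T/R conditions, got {condition!r}")
    rlen = config.repeat_read_length
    for name, seq in reference.iter_sequences():
        if rlen > len(seq):
            raise ValueError(
                f"read length {rlen} exceeds target {name!r} length {len(seq)}"
            )
    if abundances is None:
        abundances = {}
        for group, seqs in reference.groups.items():
            survive = 1.0
            if condition == "R":
                survive = 1.0 - config.repeat_removal.get(group, 0.0)
            for name in seqs:
                abundances[name] = config.repeat_read_depth * survive
    rng = substream(config.seed, "repeat_reads", condition, replicate)
    reads: list[Read] = []
    seqs = reference.to_fasta_dict()
    for target in sorted(abundances):
        seq = seqs[target]
        n = rng.poisson(abundances[target])
        for i in range(n):
            start = int(rng.integers(0, len(seq) - rlen + 1))
            read_seq = seq[start : start + rlen]
            if rng.random() < 0.5:
                read_seq = reverse_complement(read_seq)
            read_seq = _inject_errors(rng, read_seq, config.repeat_error_rate)
            reads.append(Read(f"{condition}:{replicate}:{target}:{i}", read_seq, target))
    return ReadSet(reads, condition=condition, replicate=replicate)


_OTHER_BASES = {b: "ACGT".replace(b, "") for b in "ACGT"}


def _inject_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for pos in positions:
        base = out[pos]
        if base in _OTHER_BASES:  # N stays N
            out[pos] = _OTHER_BASES[base][int(rng.integers(3))]
    return "".join(out)


def _random_sequence(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


# --------------------------------------------------------------------------
# qPCR cycle thresholds


def simulate_qpcr_ct(
    true_removal_fraction: float,
    n_replicates: int,
    noise_sd: float,
    seed: int,
    base_ct: float = 22.0,
    locus: str = "IL1B",
    genotype: str = "WT",
) -> list[CtRecord]:
    """Forward model of the DPC-selective qPCR assay.

    When a fraction f of crosslinked template is removed during recovery,
    the surviving template is (1 - f) of the treated sample, which shifts
    the recovery cycle threshold by -log2(1 - f) cycles. Each replicate
    draws Ct_T around ``base_ct`` and Ct_R = Ct_T - log2(1 - f) plus
    Gaussian noise of sd ``noise_sd``, so the downstream percent-removal
    transform recovers 100 f on average.
    """
    if not 0.0 <= true_removal_fraction < 1.0:
        raise ValueError(
            f"true_removal_fraction must be in [0, 1), got {true_removal_fraction} "
            "(at 1 the Ct shift is undefined)"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    shift = -math.log2(1.0 - true_removal_fraction)
    records = []
    for rep in range(n_replicates):
        ct_t = base_ct + float(rng.normal(0.0, noise_sd))
        ct_r = ct_t + shift + float(rng.normal(0.0, noise_sd))
        records.append(CtRecord(locus, genotype, rep, ct_t, ct_r))
    return records
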