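"""End-to-end study orchestration: simulate -> peaks -> enrich -> profile ->
repeat RRE -> qPCR, from a single config and master seed.

Every stage writes its outputs in the standard formats and immediately
re-reads them, so any file that reaches disk is a valid instance of its
declared format. All analysis outputs are deterministic given (config,
seed); wall-clock timestamps appear only in the run manifest, which is
therefore the one file excluded from byte-identity comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from dpcseq import genomic_io as gio
from dpcseq import metaprofile as mp
from dpcseq import peaks as pk
from dpcseq import removal_stats as rs
from dpcseq import repeats as rp
from dpcseq import simulate as sim

log = logging.getLogger("dpcseq.pipeline")


def config_hash(config: sim.SimulationConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _config_dict(config: sim.SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["reprogrammable_genes"] = sorted(d["reprogrammable_genes"])
    return d


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_formation_removal_study(
    config: sim.SimulationConfig,
    outdir,
    genotypes: Sequence[str] | None = None,
    enrichment_genotype: str = "WT",
    tss_flank: int = 1_000,
) -> dict:
    """Genome-wide formation/removal analysis on simulated data.

    Simulates C/T/R fragment sets for each genotype and replicate, then
    computes per-state fold-enrichment matrices with C-vs-T and T-vs-R
    paired tests, TSS metaprofiles per expression stratum, position-wise
    comparisons of each mutant genotype against the first genotype, and a
    summary of headline statistics (T/C induction ratio, per-stratum percent
    signal loss over the first ``tss_flank`` bases downstream of the TSS).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes = list(genotypes or config.genotypes)
    summary: dict = {"seed": config.seed, "config_hash": config_hash(config)}

    genome = sim.build_toy_genome(config)
    gio.write_bed(genome.segmentation.intervals, outdir / "segmentation.bed")
    gio.write_gene_table(genome.genes, outdir / "genes.tsv")
    # stage-boundary re-read checks
    gio.ChromatinSegmentation(gio.read_bed(outdir / "segmentation.bed"))
    genes = gio.read_gene_table(outdir / "genes.tsv")
    chrom_sizes = genome.chrom_sizes

    assignment = mp.assign_quintiles(
        genes, seed=int(sim.substream(config.seed, "quintiles").integers(2**31))
    )
    summary["stratum_sizes"] = {s: len(g) for s, g in assignment.strata.items()}
    summary["excluded_genes"] = len(assignment.excluded)

    # --- simulate fragments and build tracks -----------------------------
    tracks: dict[tuple[str, str, int], mp.CoverageTrack] = {}
    counts: dict[tuple[str, str, int], int] = {}
    try:
        for genotype in genotypes:
            for condition in sim.TREATMENT_LABELS:
                for rep in range(config.n_replicates):
                    frags = sim.simulate_dpc_fragments(
                        genome, config, condition, genotype, rep
                    )
                    path = outdir / f"fragments_{genotype}_{condition}_{rep}.bed"
                    gio.write_bed(frags.to_intervals(), path)
                    gio.read_bed(path)
                    counts[(genotype, condition, rep)] = frags.total_count
                    tracks[(genotype, condition, rep)] = mp.cpm_normalize(
                        frags, chrom_sizes, bin_size=10
                    )
                    log.info(
                        "simulated %s/%s rep %d: %d fragments",
                        genotype, condition, rep, frags.total_count,
                    )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", exc)

    g0 = genotypes[0]
    tc_ratios = [
        counts[(g0, "T", r)] / counts[(g0, "C", r)] for r in range(config.n_replicates)
    ]
    summary["t_over_c_induction"] = {
        "per_replicate": [round(r, 3) for r in tc_ratios],
        "mean": round(float(np.mean(tc_ratios)), 3),
    }

    # --- peaks and chromatin-state enrichment ----------------------------
    try:
        eg = enrichment_genotype if enrichment_genotype in genotypes else g0
        peak_lists = {}
        for condition in sim.TREATMENT_LABELS:
            for rep in range(config.n_replicates):
                peak_lists[(condition, rep)] = pk.call_broad_peaks(
                    tracks[(eg, condition, rep)], condition=condition, replicate=rep
                )
        matrix = pk.enrichment_matrix(peak_lists, genome.segmentation)
        matrix.to_csv(outdir / "enrichment_matrix.tsv", sep="\t")
        pvals = {}
        if config.n_replicates >= 2:
            pvals["T_greater_C"] = pk.compare_state_enrichment(
                matrix, "C", "T", direction="greater"
            ).round(6).to_dict()
            pvals["R_less_T"] = pk.compare_state_enrichment(
                matrix, "T", "R", direction="less"
            ).round(6).to_dict()
            _dump_json(pvals, outdir / "state_pvalues.json")
        summary["enrichment_genotype"] = eg
        summary["state_pvalues"] = pvals
    except Exception as exc:
        raise StageError("enrichment", exc)

    # --- TSS metaprofiles and per-stratum removal ------------------------
    try:
        window = _profile_window(config)
        flank_bins = tss_flank // 10
        half = window // 10
        matrices: dict[tuple[str, str, int], mp.MetaMatrix] = {}
        for key, track in tracks.items():
            matrices[key] = mp.tss_matrix(track, genes, window=window)
        profiles = {
            key: mp.quintile_profiles(matrix, assignment)
            for key, matrix in matrices.items()
        }
        sl = slice(half, half + flank_bins)  # first tss_flank b downstream of the TSS
        stratum_removal: dict[str, dict[str, float]] = {}
        for genotype in genotypes:
            per_stratum = {}
            for stratum in mp.STRATA:
                t_sig, r_sig = [], []
                for rep in range(config.n_replicates):
                    prof_t = profiles[(genotype, "T", rep)]
                    prof_r = profiles[(genotype, "R", rep)]
                    if stratum not in prof_t:
                        continue
                    t_sig.append(float(prof_t[stratum][0][sl].mean()))
                    r_sig.append(float(prof_r[stratum][0][sl].mean()))
                if t_sig and np.mean(t_sig) > 0:
                    per_stratum[stratum] = round(
                        100.0 * (1.0 - float(np.mean(r_sig)) / float(np.mean(t_sig))), 2
                    )
            stratum_removal[genotype] = per_stratum
        summary["stratum_percent_signal_loss"] = stratum_removal
        _write_profiles(outdir, matrices, assignment, genotypes, config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("metaprofile", exc)

    # --- position-wise genotype comparison --------------------------------
    try:
        if config.n_replicates >= 2 and len(genotypes) > 1:
            compare = {}
            for genotype in genotypes[1:]:
                mats_a = [matrices[(g0, "R", r)] for r in range(config.n_replicates)]
                mats_b = [matrices[(genotype, "R", r)] for r in range(config.n_replicates)]
                for stratum in ("Q0", "Q4"):
                    curve = mp.positionwise_compare(
                        mats_a, mats_b, stratum, assignment, direction="less"
                    )
                    compare[f"{g0}_vs_{genotype}_{stratum}"] = {
                        "max_neglog10_p": round(float(curve.max()), 4),
                        "tss_neglog10_p": round(float(curve[half]), 4),
                    }
                    np.savetxt(
                        outdir / f"neglog10p_{g0}_vs_{genotype}_{stratum}.tsv",
                        curve, fmt="%.6g",
                    )
            summary["positionwise"] = compare
    except Exception as exc:
        raise StageError("positionwise", exc)

    _dump_json(summary, outdir / "formation_removal_summary.json")
    return summary


def _profile_window(config: sim.SimulationConfig) -> int:
    # 20 kb flanks as in the study design, shrunk for small toy chromosomes
    smallest = min(sim._chromosome_sizes(config).values())
    return min(20_000, max(1_000, (smallest // 4) // 10 * 10))


def _write_profiles(outdir, matrices, assignment, genotypes, config) -> None:
    import pandas as pd

    rows = {}
    for (genotype, condition, rep), matrix in matrices.items():
        profs = mp.quintile_profiles(matrix, assignment)
        for stratum, (curve, _n) in profs.items():
            rows[f"{genotype}:{condition}:{rep}:{stratum}"] = curve
    pd.DataFrame(rows).to_csv(outdir / "stratum_profiles.tsv", sep="\t", index=False)


def run_repeat_study(config: sim.SimulationConfig, outdir) -> dict:
    """Repeat-locus removal analysis: simulate T/R reads per replicate, hard
    trim to 50 b, count mismatch-free matches per group, and compute RREs
    with the Q4-vs-Q0 and repeat-vs-Q0 comparisons."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = sim.build_toy_genome(config)
    reference = genome.repeat_reference
    gio.write_fasta(reference.to_fasta_dict(), outdir / "repeat_reference.fa")
    gio.read_fasta(outdir / "repeat_reference.fa")

    try:
        counts: dict[str, dict[str, list[int]]] = {
            g: {"T": [], "R": []} for g in reference.groups
        }
        dropped_total = 0
        for rep in range(config.n_replicates):
            for condition in ("T", "R"):
                reads = sim.simulate_repeat_reads(reference, config, condition, rep)
                path = outdir / f"reads_{condition}_{rep}.fastq"
                gio.write_fastq(((r.name, r.seq) for r in reads.reads), path)
                gio.read_fastq(path)
                trimmed, dropped = rp.hardtrim_reads(reads, keep=50)
                dropped_total += dropped
                mc = rp.exact_match_count(trimmed, reference)
                for group in reference.groups:
                    counts[group][condition].append(mc.per_group[group])
        entries = {
            group: rp.compute_rre(group, c["T"], c["R"]) for group, c in counts.items()
        }
        table, pvals = rp.rre_report(entries)
        table.to_csv(outdir / "rre_table.tsv", sep="\t")
        result = {
            "seed": config.seed,
            "config_hash": config_hash(config),
            "rre_mean": {g: round(e.rre_mean, 4) for g, e in entries.items()},
            "rre_sem": {g: (round(e.sem, 4) if e.sem is not None else None)
                        for g, e in entries.items()},
            "pvalues": {k: round(v, 6) for k, v in pvals.items()},
            "dropped_short_reads": dropped_total,
        }
        _dump_json(result, outdir / "rre_summary.json")
        return result
    except StageError:
        raise
    except Exception as exc:
        raise StageError("repeat_rre", exc)


def run_qpcr_study(
    config: sim.SimulationConfig,
    outdir,
    n_replicates: int = 5,
    reference_genotype: str = "WT",
) -> dict:
    """Locus-specific qPCR analysis: simulate Ct pairs per genotype at a
    highly transcribed locus using each genotype's Q4 removal fraction, then
    recover percent removal and test each mutant against the reference
    genotype (one-tailed, mutant removes less)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records_all = []
    results = {}
    for genotype in config.genotypes:
        frac = config.quintile_removal[genotype]["Q4"]
        seed = int(sim.substream(config.seed, "qpcr", genotype).integers(2**31))
        records = sim.simulate_qpcr_ct(
            frac, n_replicates, config.ct_noise_sd, seed,
            base_ct=config.ct_base_cycle, genotype=genotype,
        )
        records_all.extend(records)
        res = rs.summarize_removal(records)
        results[genotype] = {
            "true_fraction": frac,
            "mean_percent_removal": round(res.mean, 2) if res.mean is not None else None,
            "sem": round(res.sem, 3) if res.sem is not None else None,
            "n_retained": len(res.percent_per_replicate),
            "n_discarded": res.discarded_replicates,
        }
    gio.write_ct_csv(records_all, outdir / "ct_table.csv")
    gio.read_ct_csv(outdir / "ct_table.csv")
    summary = {"seed": config.seed, "per_genotype": results}
    _dump_json(summary, outdir / "qpcr_summary.json")
    return summary


def run_all(config: sim.SimulationConfig, outdir) -> dict:
    """Full study: formation/removal, repeat RRE, and qPCR analyses, plus a
    run manifest (config hash, seed, stage outputs, timestamps)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report = {
        "formation_removal": run_formation_removal_study(config, outdir / "formation_removal"),
        "repeat_rre": run_repeat_study(config, outdir / "repeat_rre"),
        "qpcr": run_qpcr_study(config, outdir / "qpcr"),
    }
    _dump_json(report, outdir / "report.json")
    manifest = {
        "config": _config_dict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "outputs": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
        "started": t0,
        "finished": time.time(),
    }
    _dump_json(manifest, outdir / "manifest.json")
    return report
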