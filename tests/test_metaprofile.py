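import numpy as np
import pytest

from dpcseq.genomic_io import GeneModel
from dpcseq.metaprofile import (
    CoverageTrack,
    assign_quintiles,
    cpm_normalize,
    positionwise_compare,
    quintile_profiles,
    tss_matrix,
)
from dpcseq.simulate import (
    SimulationConfig,
    build_toy_genome,
    simulate_dpc_fragments,
    substream,
)


class _Frags:
    def __init__(self, fragments):
        self.fragments = fragments


def test_cpm_value_is_count_scaled_to_million():
    # 1,000 fragments, one bin overlapped by 5 of them -> CPM 5,000
    frags = [("chr1", 5000, 5300)] * 5 + [("chr1", 100_000 + 400 * i, 100_300 + 400 * i)
                                          for i in range(995)]
    track = cpm_normalize(_Frags(frags), {"chr1": 600_000}, bin_size=10)
    assert track.total_fragments == 1000
    assert track.values["chr1"][500] == pytest.approx(5 / 1000 * 1e6)


def test_fragment_increments_exactly_its_bins():
    track = cpm_normalize(_Frags([("chr1", 1000, 1300)]), {"chr1": 10_000}, bin_size=10)
    assert int(np.count_nonzero(track.values["chr1"])) == 30
    assert track.values["chr1"][100:130].tolist() == [1e6] * 30


def test_cpm_is_depth_invariant():
    frags = [("chr1", 0, 250), ("chr1", 700, 1000)]
    single = cpm_normalize(_Frags(frags), {"chr1": 2000}, bin_size=10)
    doubled = cpm_normalize(_Frags(frags * 2), {"chr1": 2000}, bin_size=10)
    np.testing.assert_allclose(single.values["chr1"], doubled.values["chr1"])


def test_cpm_conservation_identity(small_genome, small_config):
    """Sum of bin counts equals the sum over fragments of bins overlapped."""
    frags = simulate_dpc_fragments(small_genome, small_config, "T", "WT", 0)
    track = cpm_normalize(frags, small_genome.chrom_sizes, bin_size=10)
    total_bin_counts = sum(
        v.sum() * track.total_fragments / 1e6 for v in track.values.values()
    )
    expected = sum(
        -(-e // 10) - s // 10 for _c, s, e in frags.fragments
    )
    assert total_bin_counts == pytest.approx(expected)


def test_empty_fragment_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        cpm_normalize(_Frags([]), {"chr1": 100})


def _gene(i, fpkm, chrom="chr1", strand="+", tss=10_000, length=1000):
    return GeneModel(f"g{i}", chrom, strand, tss, length, fpkm)


def test_quintile_threshold_rules():
    genes = [_gene(0, 0.0), _gene(1, 0.05), _gene(2, 0.1), _gene(3, 1.0),
             _gene(4, 2.0), _gene(5, 5.0)]
    a = assign_quintiles(genes)
    assert a.stratum_of["g0"] == "Q0"
    assert "g1" not in a.stratum_of and a.excluded == ["g1"]
    assert a.stratum_of["g2"] == "Q1"
    assert a.stratum_of["g5"] == "Q4"


def test_eight_expressed_genes_split_two_per_group():
    genes = [_gene(i, 0.1 * (i + 1)) for i in range(8)]
    a = assign_quintiles(genes)
    assert [len(a.genes_in(f"Q{i}")) for i in (1, 2, 3, 4)] == [2, 2, 2, 2]
    assert set(a.genes_in("Q1")) == {"g0", "g1"}  # fpkm 0.1, 0.2
    assert set(a.genes_in("Q4")) == {"g6", "g7"}  # fpkm 0.7, 0.8


def test_group_sizes_differ_by_at_most_one():
    genes = [_gene(i, 0.1 + i) for i in range(11)]
    a = assign_quintiles(genes)
    sizes = [len(a.genes_in(f"Q{i}")) for i in (1, 2, 3, 4)]
    assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 11


def test_q0_sampling_is_seeded():
    genes = [_gene(i, 0.0) for i in range(20)] + [_gene(99, 1.0)]
    a1 = assign_quintiles(genes, q0_sample_size=5, seed=3)
    a2 = assign_quintiles(genes, q0_sample_size=5, seed=3)
    a3 = assign_quintiles(genes, q0_sample_size=5, seed=4)
    assert a1.genes_in("Q0") == a2.genes_in("Q0")
    assert len(a3.genes_in("Q0")) == 5
    assert a1.genes_in("Q0") != a3.genes_in("Q0")


def test_no_expressed_genes_rejected():
    with pytest.raises(ValueError, match="FPKM"):
        assign_quintiles([_gene(0, 0.0)])


def _uniform_track(v, n_bins=4000, chrom="chr1", bin_size=10):
    return CoverageTrack(bin_size=bin_size,
                         values={chrom: np.full(n_bins, float(v))},
                         total_fragments=100)


def test_tss_matrix_shape_and_uniform_fill():
    genes = [_gene(0, 1.0, tss=20_000), _gene(1, 2.0, tss=25_000)]
    m = tss_matrix(_uniform_track(7.0, n_bins=5000), genes, window=20_000)
    assert m.values.shape == (2, 4000)  # 40 kb / 10 b bins
    assert np.all(m.values == 7.0)


def test_tss_matrix_strand_mirror_symmetry():
    vals = np.zeros(1000)
    vals[480:520] = np.arange(40, dtype=float)  # asymmetric bump
    track = CoverageTrack(10, {"chr1": vals}, 10)
    plus = GeneModel("p", "chr1", "+", 5000, 500, 1.0)
    minus = GeneModel("m", "chr1", "-", 5000, 500, 1.0)
    m = tss_matrix(track, [plus, minus], window=1000)
    np.testing.assert_allclose(m.row("p"), m.row("m")[::-1])


def test_tss_matrix_edge_rows_zero_padded_and_flagged():
    genes = [_gene(0, 1.0, tss=100)]
    m = tss_matrix(_uniform_track(3.0, n_bins=1000), genes, window=2000)
    assert m.flagged_genes == ["g0"]
    row = m.row("g0")
    assert np.all(row[:190] == 0.0) and np.all(row[190:] == 3.0)


def test_tss_matrix_unknown_chromosome_and_bad_window():
    genes = [_gene(0, 1.0, chrom="chrX")]
    with pytest.raises(KeyError, match="chrX"):
        tss_matrix(_uniform_track(1.0), genes, window=1000)
    with pytest.raises(ValueError, match="multiple"):
        tss_matrix(_uniform_track(1.0), [_gene(0, 1.0)], window=1005)


def test_quintile_profiles_are_member_means():
    genes = [_gene(0, 0.0, tss=20_000), _gene(1, 1.0, tss=25_000), _gene(2, 9.0, tss=30_000)]
    a = assign_quintiles(genes)
    track = _uniform_track(1.0, n_bins=10_000)
    m = tss_matrix(track, genes, window=1000)
    m.values[0, :] = 1.0
    m.values[1, :] = 1.0
    m.values[2, :] = 3.0
    profs = quintile_profiles(m, a)
    assert profs["Q0"][0] == pytest.approx(np.ones(200)) and profs["Q0"][1] == 1
    # single-gene stratum curve equals that gene's row (g2 ranks into Q2 here)
    np.testing.assert_allclose(profs["Q2"][0], m.values[2])
    assert "Q4" not in profs  # empty strata are omitted, not zero-filled
    # arithmetic-mean check: rows (1,...) and (3,...) average to (2,...)
    stacked = np.vstack([m.values[1], m.values[2]]).mean(axis=0)
    assert stacked == pytest.approx(np.full(200, 2.0))


def test_positionwise_identical_replicates_give_zero_curve():
    genes = [_gene(0, 1.0, tss=20_000), _gene(1, 0.0, tss=30_000)]
    a = assign_quintiles(genes)
    track = _uniform_track(2.0, n_bins=10_000)
    mats = [tss_matrix(track, genes, window=1000) for _ in range(2)]
    curve = positionwise_compare(mats, mats, "Q1", a, direction="less")
    assert np.all(curve == 0.0)


def test_positionwise_constant_offset_beats_half():
    genes = [_gene(0, 1.0, tss=20_000)]
    a = assign_quintiles(genes)
    lo = [tss_matrix(_uniform_track(1.0 + 0.01 * r, 10_000), genes, 1000) for r in range(3)]
    hi = [tss_matrix(_uniform_track(2.0 + 0.01 * r, 10_000), genes, 1000) for r in range(3)]
    curve = positionwise_compare(lo, hi, "Q1", a, direction="less")
    pvals = 10.0 ** (-curve)
    assert np.all(pvals < 0.5)


def test_positionwise_replicate_mismatch_rejected():
    genes = [_gene(0, 1.0, tss=20_000)]
    a = assign_quintiles(genes)
    m = tss_matrix(_uniform_track(1.0, 10_000), genes, 1000)
    with pytest.raises(ValueError, match="mismatch"):
        positionwise_compare([m, m], [m], "Q1", a)


def _wt_recovery_profiles(seed, n_replicates=2):
    cfg = SimulationConfig(seed=seed, genome_length=1_000_000, n_chromosomes=2,
                           n_replicates=n_replicates,
                           repeat_length=500, n_control_genes=0, control_gene_length=200)
    genome = build_toy_genome(cfg)
    assignment = assign_quintiles(
        genome.genes, seed=int(substream(cfg.seed, "quintiles").integers(2**31))
    )
    curves = {}
    for rep in range(n_replicates):
        frags = simulate_dpc_fragments(genome, cfg, "R", "WT", rep)
        track = cpm_normalize(frags, genome.chrom_sizes, bin_size=10)
        m = tss_matrix(track, genome.genes, window=2000)
        for stratum, (curve, _n) in quintile_profiles(m, assignment).items():
            curves.setdefault(stratum, []).append(curve)
    return {s: np.mean(np.vstack(cs), axis=0) for s, cs in curves.items()}


def test_wt_recovery_strata_are_graded_at_tss():
    """After recovery, transcription-graded removal orders the stratum means
    Q4 < Q3 < Q2 < Q1 downstream of the TSS in a majority of simulations."""
    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        profs = _wt_recovery_profiles(300 + seed)
        # mean over the first 1 kb downstream of the TSS (columns 200..300)
        tss_means = {s: profs[s][200:300].mean() for s in ("Q1", "Q2", "Q3", "Q4")}
        if tss_means["Q4"] < tss_means["Q3"] < tss_means["Q2"] < tss_means["Q1"]:
            wins += 1
    assert wins > n_seeds / 2


def test_t_condition_strata_overlap():
    """Formation is transcription-independent, so T-condition stratum curves
    coincide up to sampling noise (Q4-to-Q0 TSS signal ratio near 1)."""
    cfg = SimulationConfig(seed=17, genome_length=1_000_000, repeat_length=500,
                           n_control_genes=0, control_gene_length=200)
    genome = build_toy_genome(cfg)
    assignment = assign_quintiles(
        genome.genes, seed=int(substream(cfg.seed, "quintiles").integers(2**31))
    )
    ratios = []
    for rep in range(3):
        frags = simulate_dpc_fragments(genome, cfg, "T", "WT", rep)
        track = cpm_normalize(frags, genome.chrom_sizes, bin_size=10)
        profs = quintile_profiles(tss_matrix(track, genome.genes, 2000), assignment)
        ratios.append(profs["Q4"][0][150:250].mean() / profs["Q0"][0][150:250].mean())
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.35)
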