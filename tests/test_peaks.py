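import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dpcseq.genomic_io import ChromatinSegmentation, GenomicInterval
from dpcseq.metaprofile import CoverageTrack, cpm_normalize
from dpcseq.peaks import (
    PeakList,
    call_broad_peaks,
    compare_state_enrichment,
    enrichment_matrix,
    fold_enrichment,
    merge_intervals,
    overlap_bases,
    peak_signal_correlation,
)
from dpcseq.simulate import build_toy_genome, simulate_dpc_fragments


def _track(values, bin_size=10, chrom="chr1"):
    arr = np.asarray(values, dtype=float)
    return CoverageTrack(bin_size=bin_size, values={chrom: arr}, total_fragments=1000,
                         chrom_sizes={chrom: len(arr) * bin_size})


def test_flat_track_yields_no_peaks():
    assert len(call_broad_peaks(_track([3.0] * 100))) == 0


def test_single_plateau_yields_one_spanning_peak():
    vals = np.ones(200)
    vals[50:100] = 5.0  # 5x the background over 500 b
    peaks = call_broad_peaks(_track(vals), min_fold=2.0, merge_gap=100, min_width=200)
    assert len(peaks) == 1
    (pk,) = peaks.peaks
    assert (pk.start, pk.end) == (500, 1000)


def test_nearby_runs_merge_and_match_bin_scan_oracle():
    vals = np.ones(300)
    vals[20:40] = 10.0
    vals[60:90] = 10.0  # gap of 200 b < merge_gap
    vals[200:230] = 10.0  # far away: own peak
    track = _track(vals)
    peaks = call_broad_peaks(track, min_fold=2.0, merge_gap=500, min_width=100)
    assert [(p.start, p.end) for p in peaks.peaks] == [(200, 900), (2000, 2300)]
    # exhaustive bin-scan oracle: every flagged bin is inside a peak
    threshold = 2.0 * track.global_mean()
    for i, v in enumerate(vals):
        inside = any(p.start <= i * 10 < p.end for p in peaks.peaks)
        if v >= threshold:
            assert inside


def test_control_track_grid_mismatch_rejected():
    with pytest.raises(ValueError, match="bin size"):
        call_broad_peaks(_track([1.0] * 10), control=_track([1.0] * 10, bin_size=20))


def _toy_segmentation():
    # 1,000 b genome: state A = 100 b, state B = 900 b
    return ChromatinSegmentation(
        [GenomicInterval("chr1", 0, 100, "A"), GenomicInterval("chr1", 100, 1000, "B")]
    )


def test_fold_enrichment_direct_arithmetic():
    seg = _toy_segmentation()
    # peaks: 20 b inside A + 30 b inside B = 50 b total
    peaks = PeakList([GenomicInterval("chr1", 80, 100), GenomicInterval("chr1", 500, 530)])
    fe = fold_enrichment(peaks, seg)
    assert fe["A"] == pytest.approx((20 / 100) / (50 / 1000))  # = 4.0
    assert fe["A"] == pytest.approx(4.0)
    assert fe["B"] == pytest.approx((30 / 900) / (50 / 1000))


def test_fold_enrichment_saturation_and_disjoint():
    seg = _toy_segmentation()
    tiling = PeakList([GenomicInterval("chr1", 0, 1000)])
    assert fold_enrichment(tiling, seg).tolist() == pytest.approx([1.0, 1.0])
    disjoint = PeakList([GenomicInterval("chr1", 200, 250)])
    assert fold_enrichment(disjoint, seg)["A"] == 0.0


def test_fold_enrichment_zero_base_state_is_missing_not_zero():
    seg = ChromatinSegmentation(
        [GenomicInterval("chr1", 0, 1000, "A")], state_set=frozenset({"A", "Z"})
    )
    fe = fold_enrichment(PeakList([GenomicInterval("chr1", 0, 100)]), seg)
    assert np.isnan(fe["Z"]) and fe["A"] == pytest.approx(1.0)


def test_state_weighted_mean_enrichment_is_one():
    """Exact identity: sum_s state_bases * enrichment = genome * peak share."""
    seg = _toy_segmentation()
    peaks = PeakList([GenomicInterval("chr1", 50, 120), GenomicInterval("chr1", 700, 900)])
    fe = fold_enrichment(peaks, seg)
    bases = seg.state_bases()
    weighted = sum(bases[s] * fe[s] for s in fe.index)
    assert weighted == pytest.approx(seg.genome_size)


def test_uniform_random_peaks_have_unit_mean_enrichment():
    seg = _toy_segmentation()
    rng = np.random.default_rng(0)
    per_state = {"A": [], "B": []}
    for _ in range(50):
        starts = np.sort(rng.choice(990, size=5, replace=False))
        ivs = merge_intervals([GenomicInterval("chr1", int(s), int(s) + 10) for s in starts])
        fe = fold_enrichment(PeakList(ivs), seg)
        for s in per_state:
            per_state[s].append(fe[s])
    for s, vals in per_state.items():
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(1.0, abs=3 * se)


def test_fold_enrichment_matches_per_base_oracle(small_genome, small_config):
    """Exact agreement with naive per-base membership counting."""
    frags = simulate_dpc_fragments(small_genome, small_config, "T", "WT", 0)
    track = cpm_normalize(frags, small_genome.chrom_sizes, bin_size=10)
    peaks = call_broad_peaks(track)
    seg = small_genome.segmentation
    fe = fold_enrichment(peaks, seg)
    # naive: paint state and peak membership base-by-base
    state_of = {c: np.empty(size, dtype=object) for c, size in seg.chrom_sizes.items()}
    for iv in seg.intervals:
        state_of[iv.chrom][iv.start:iv.end] = iv.label
    in_peak = {c: np.zeros(size, dtype=bool) for c, size in seg.chrom_sizes.items()}
    for pk in peaks.peaks:
        in_peak[pk.chrom][pk.start:pk.end] = True
    genome = seg.genome_size
    peak_bases = sum(a.sum() for a in in_peak.values())
    for state in seg.state_set:
        sb = sum((state_of[c] == state).sum() for c in state_of)
        ov = sum(((state_of[c] == state) & in_peak[c]).sum() for c in state_of)
        naive = (ov / sb) / (peak_bases / genome)
        assert fe[state] == pytest.approx(naive, abs=1e-12)


def test_t_enrichment_ranks_recover_formation_intensities():
    """Across seeds, T-condition per-state enrichment rank-orders like the
    configured formation intensity vector."""
    from dpcseq.simulate import SimulationConfig

    rhos = []
    for seed in range(10):
        cfg = SimulationConfig(seed=100 + seed)
        genome = build_toy_genome(cfg)
        frags = simulate_dpc_fragments(genome, cfg, "T", "WT", 0)
        track = cpm_normalize(frags, genome.chrom_sizes, bin_size=10)
        peaks = call_broad_peaks(track, min_fold=1.5, merge_gap=200, min_width=100)
        fe = fold_enrichment(peaks, genome.segmentation).dropna()
        intensities = [cfg.state_formation_intensity[s] for s in fe.index]
        rhos.append(sps.spearmanr(intensities, fe.to_numpy()).statistic)
    assert np.mean(rhos) >= 0.9


def test_compare_state_enrichment():
    states = ["A", "B"]
    cols = pd.MultiIndex.from_product([["C", "T"], [0, 1, 2]],
                                      names=["condition", "replicate"])
    matrix = pd.DataFrame(
        [[1.0, 1.1, 0.9, 2.0, 2.2, 1.8], [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]],
        index=states, columns=cols,
    )
    p_up = compare_state_enrichment(matrix, "C", "T", direction="greater")
    assert p_up["A"] < 0.05
    assert p_up["B"] == 1.0  # identical replicate vectors: degenerate convention
    p_down = compare_state_enrichment(matrix, "C", "T", direction="less")
    assert p_down["A"] > 0.5


def test_enrichment_matrix_shape(small_genome, small_config):
    frags = {
        (c, r): simulate_dpc_fragments(small_genome, small_config, c, "WT", r)
        for c in ("C", "T") for r in range(2)
    }
    peak_lists = {
        key: call_broad_peaks(
            cpm_normalize(f, small_genome.chrom_sizes), condition=key[0], replicate=key[1]
        )
        for key, f in frags.items()
    }
    m = enrichment_matrix(peak_lists, small_genome.segmentation)
    assert m.shape == (18, 4)
    assert list(m.columns.names) == ["condition", "replicate"]


def test_spearman_monotone_and_antitone():
    rng = np.random.default_rng(1)
    vals = rng.random(400)
    a = _track(vals)
    b = _track(2 * vals)
    c = _track(-vals + 5)
    peaks = PeakList([GenomicInterval("chr1", i * 40, i * 40 + 30) for i in range(100)])
    corr = peak_signal_correlation(peaks, {"a": a, "b": b, "c": c})
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert np.allclose(np.diag(corr), 1.0)


def test_spearman_with_ties_matches_rank_enumeration_oracle():
    x = np.array([1.0, 2.0, 2.0, 3.0, 1.0, 4.0])
    y = np.array([0.5, 0.5, 2.0, 2.0, 1.0, 3.0])
    a = _track(x)
    b = _track(y)
    peaks = PeakList([GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(6)])
    corr = peak_signal_correlation(peaks, {"a": a, "b": b})

    def average_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = np.mean(np.arange(i, j + 1) + 1)
            i = j + 1
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_signal_reported_missing():
    peaks = PeakList([GenomicInterval("chr1", i * 10, (i + 1) * 10) for i in range(5)])
    corr = peak_signal_correlation(
        peaks, {"flat": _track([2.0] * 5), "var": _track([1, 2, 3, 4, 5.0])}
    )
    assert np.isnan(corr.loc["flat", "var"])


def test_peak_list_rejects_overlaps():
    with pytest.raises(ValueError, match="overlap"):
        PeakList([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)])


def test_overlap_bases_counts_double_covered_once():
    a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
    b = [GenomicInterval("chr1", 80, 200)]
    assert overlap_bases(a, b) == 70  # merged a = [0,150): overlap [80,150)
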