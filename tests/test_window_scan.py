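"""Window grid arithmetic, the rescan oracle for window means, null-CI
behavior, and region-calling semantics."""

from __future__ import annotations

import numpy as np
import pytest

from bsascan.bsa_index import IndexedVariant, apply_filters
from bsascan.variant_io import GeneModel, PooledVariant
from bsascan.window_scan import (
    ScanConfig,
    WindowStat,
    call_regions,
    make_windows,
    null_ci,
    scan_track,
    window_means,
)


def _cfg(**kw) -> ScanConfig:
    return ScanConfig(**kw)


class TestMakeWindows:
    def test_forced_arithmetic_4mb(self):
        cfg = _cfg(window_size=2_000_000, step_size=10_000)
        wins = make_windows({"c": 4_000_000}, cfg)
        assert len(wins) == 400
        assert wins[0] == ("c", 1, 2_000_000)
        assert wins[200] == ("c", 2_000_001, 4_000_000)  # the 201st window
        assert wins[-1] == ("c", 3_990_001, 4_000_000)

    def test_chromosome_shorter_than_window(self):
        cfg = _cfg(window_size=2_000_000, step_size=500_000)
        wins = make_windows({"c": 1_500_000}, cfg)
        assert all(end == 1_500_000 for _, _, end in wins)
        assert [s for _, s, _ in wins] == [1, 500_001, 1_000_001]

    def test_step_equals_window_tiles(self):
        cfg = _cfg(window_size=100, step_size=100)
        wins = make_windows({"c": 1000}, cfg)
        assert len(wins) == 10
        for (_, s1, e1), (_, s2, _) in zip(wins, wins[1:]):
            assert s2 == e1 + 1

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 0}, _cfg())


def _random_indexed(n=300, length=1_000_000, seed=0, vclass="SNP"):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
    out = []
    for p in pos:
        dh, dl = rng.integers(10, 60), rng.integers(10, 60)
        ah, al = rng.integers(0, dh + 1), rng.integers(0, dl + 1)
        ref, alt = ("A", "G") if vclass == "SNP" else ("A", "AT")
        v = PooledVariant(chrom="c", pos=int(p), ref_allele=ref, alt_allele=alt,
                          ad_high=(int(dh - ah), int(ah)), ad_low=(int(dl - al), int(al)))
        out.append(IndexedVariant.from_variant(v))
    return out


def test_window_means_match_rescan_oracle():
    """Per-window means equal a brute-force rescan over all variants."""
    indexed = _random_indexed(n=400, seed=2)
    cfg = _cfg(window_size=100_000, step_size=25_000, min_variants_per_window=5)
    wins = make_windows({"c": 1_000_000}, cfg)
    stats = window_means(wins, indexed, "SNP", cfg)
    for (chrom, start, end), stat in zip(wins, stats):
        members = [iv for iv in indexed if start <= iv.pos <= end]
        assert stat.n_variants == len(members)
        if members:
            assert stat.mean_delta == pytest.approx(np.mean([iv.delta for iv in members]))
            assert stat.mean_index_high == pytest.approx(np.mean([iv.index_high for iv in members]))
            assert stat.mean_index_low == pytest.approx(np.mean([iv.index_low for iv in members]))
        else:
            assert np.isnan(stat.mean_delta)
            assert not stat.reliable


def test_simple_window_mean_and_empty_flag():
    ivs = []
    for pos, d in [(100, 0.2), (200, 0.4), (300, 0.9)]:
        ah = int(round(d * 10))
        v = PooledVariant(chrom="c", pos=pos, ref_allele="A", alt_allele="G",
                          ad_high=(10 - ah, ah), ad_low=(10, 0))
        ivs.append(IndexedVariant.from_variant(v))
    cfg = _cfg(window_size=500, step_size=500, min_variants_per_window=1)
    stats = window_means([("c", 1, 500), ("c", 501, 1000)], ivs, "SNP", cfg)
    assert stats[0].mean_delta == pytest.approx(0.5)
    assert stats[1].n_variants == 0 and not stats[1].reliable


def _fixed_depth_indexed(n, depth=40, alt_frac=0.5, seed=0, spacing=1000):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ah = rng.binomial(depth, alt_frac)
        al = rng.binomial(depth, alt_frac)
        v = PooledVariant(chrom="c", pos=1 + i * spacing, ref_allele="A", alt_allele="G",
                          ad_high=(depth - ah, int(ah)), ad_low=(depth - al, int(al)))
        out.append(IndexedVariant.from_variant(v))
    return out


class TestNullCI:
    def test_ci_width_shrinks_with_depth_reads_only(self):
        """Reads-only null: scaling depths x1000 collapses the CI width."""
        win = [("c", 1, 100_000)]
        widths = {}
        for scale in (1, 1000):
            ivs = []
            for i in range(30):
                d = 40 * scale
                v = PooledVariant(chrom="c", pos=1 + i * 1000, ref_allele="A", alt_allele="G",
                                  ad_high=(d // 2, d // 2), ad_low=(d // 2, d // 2))
                ivs.append(IndexedVariant.from_variant(v))
            cfg = _cfg(null_reps=2000, rng_seed=1, pool_size=None)
            (ci,) = null_ci(win, ivs, cfg, vclass="SNP")
            lo, hi = ci[0.95]
            widths[scale] = hi - lo
        assert widths[1000] < widths[1] / 10

    def test_symmetric_null_about_zero(self):
        """|low + high| < 0.02 at 10,000 reps, depth 40, 50 variants."""
        ivs = _fixed_depth_indexed(50, depth=40, alt_frac=0.5, seed=3)
        cfg = _cfg(null_reps=10_000, rng_seed=7)
        (ci,) = null_ci([("c", 1, 100_000)], ivs, cfg, vclass="SNP")
        lo, hi = ci[0.95]
        assert lo <= 0.0 <= hi
        assert abs(lo + hi) < 0.02

    def test_single_variant_wider_than_fifty(self):
        cfg = _cfg(null_reps=4000, rng_seed=5)
        one = _fixed_depth_indexed(1, depth=4, alt_frac=0.5, seed=1)
        fifty = _fixed_depth_indexed(50, depth=4, alt_frac=0.5, seed=2)
        (ci1,) = null_ci([("c", 1, 100_000)], one, cfg, vclass="SNP")
        (ci50,) = null_ci([("c", 1, 100_000)], fifty, cfg, vclass="SNP")
        lo1, hi1 = ci1[0.95]
        lo50, hi50 = ci50[0.95]
        assert -1.0 <= lo1 <= hi1 <= 1.0
        assert hi1 - lo1 > hi50 - lo50

    def test_seeded_reproducibility(self):
        ivs = _random_indexed(n=100, seed=9)
        cfg = _cfg(window_size=200_000, step_size=100_000, null_reps=500, rng_seed=11)
        wins = make_windows({"c": 1_000_000}, cfg)
        a = null_ci(wins, ivs, cfg, vclass="SNP")
        b = null_ci(wins, ivs, cfg, vclass="SNP")
        assert a == b

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            _cfg(null_reps=0)


def _stat(chrom, start, end, delta, vclass="SNP", reliable=True, ci=None):
    return WindowStat(
        chrom=chrom, start=start, end=end, vclass=vclass, n_variants=20,
        mean_index_high=0.5 + delta / 2, mean_index_low=0.5 - delta / 2,
        mean_delta=delta, reliable=reliable,
        ci=ci if ci is not None else {0.95: (-0.1, 0.1)},
    )


class TestCallRegions:
    def test_grid_mismatch_rejected(self):
        cfg = _cfg()
        a = [_stat("c", 1, 100, 0.0)]
        b = [_stat("c", 2, 101, 0.0, vclass="InDel")]
        with pytest.raises(ValueError, match="grid"):
            call_regions(a, b, None, cfg)

    def test_single_track_significance_mode_semantics(self):
        cfg = _cfg()
        snp = [_stat("c", 1, 100, 0.95)]
        indel = [_stat("c", 1, 100, 0.10, vclass="InDel")]
        assert call_regions(snp, indel, None, cfg) == []
        cfg_any = _cfg(require_both_tracks=False)
        regions = call_regions(snp, indel, None, cfg_any)
        assert len(regions) == 1 and regions[0].supported_by == frozenset({"SNP"})

    def test_threshold_and_ci_must_both_hold_in_default_mode(self):
        cfg = _cfg()
        # over threshold but inside a wide CI -> not significant
        snp = [_stat("c", 1, 100, 0.95, ci={0.95: (-0.99, 0.99)})]
        indel = [_stat("c", 1, 100, 0.95, vclass="InDel", ci={0.95: (-0.99, 0.99)})]
        assert call_regions(snp, indel, None, cfg) == []
        cfg_thr = _cfg(significance_mode="threshold")
        assert len(call_regions(snp, indel, None, cfg_thr)) == 1

    def test_merge_and_gene_attachment(self):
        cfg = _cfg()
        snp = [_stat("c", 1, 200, 0.95), _stat("c", 101, 300, 0.96), _stat("c", 900, 1000, 0.0)]
        indel = [
            _stat("c", 1, 200, 0.93, vclass="InDel"),
            _stat("c", 101, 300, 0.92, vclass="InDel"),
            _stat("c", 900, 1000, 0.0, vclass="InDel"),
        ]
        genes = [
            GeneModel("inA", "c", "+", 120, 250, ((120, 250),)),
            GeneModel("out", "c", "+", 500, 700, ((500, 700),)),
        ]
        regions = call_regions(snp, indel, genes, cfg)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1, 300)
        assert r.peak_delta == pytest.approx(0.96)
        assert r.genes == ("inA",)
        assert r.supported_by == frozenset({"SNP", "InDel"})

    def test_merging_associative_across_chromosomes(self):
        """Calling on concatenated chromosomes equals per-chromosome calls."""
        cfg = _cfg()
        snp1 = [_stat("c1", 1, 200, 0.95), _stat("c1", 101, 300, 0.96)]
        snp2 = [_stat("c2", 1, 200, 0.97)]
        ind1 = [_stat("c1", 1, 200, 0.95, vclass="InDel"), _stat("c1", 101, 300, 0.96, vclass="InDel")]
        ind2 = [_stat("c2", 1, 200, 0.97, vclass="InDel")]
        combined = call_regions(snp1 + snp2, ind1 + ind2, None, cfg)
        separate = call_regions(snp1, ind1, None, cfg) + call_regions(snp2, ind2, None, cfg)
        assert combined == sorted(separate, key=lambda r: (r.chrom, r.start))

    def test_unreliable_windows_never_called(self):
        cfg = _cfg()
        snp = [_stat("c", 1, 100, 0.99, reliable=False)]
        indel = [_stat("c", 1, 100, 0.99, vclass="InDel", reliable=False)]
        assert call_regions(snp, indel, None, cfg) == []


def test_scan_track_ci_shortcut_matches_full_for_region_calling():
    """Restricting CIs to above-threshold windows leaves AND-mode region
    calls identical to computing CIs everywhere."""
    rng = np.random.default_rng(21)
    ivs = _random_indexed(n=250, seed=21)
    # inject a strong divergent block so at least one window passes threshold
    strong = []
    for i in range(30):
        v = PooledVariant(chrom="c", pos=500_000 + i * 1_000, ref_allele="A", alt_allele="G",
                          ad_high=(1, 39), ad_low=(39, 1))
        strong.append(IndexedVariant.from_variant(v))
    ivs = sorted(ivs + strong, key=lambda x: x.pos)
    cfg = _cfg(window_size=100_000, step_size=50_000, null_reps=800,
               rng_seed=2, min_variants_per_window=5, delta_threshold=0.5)
    wins = make_windows({"c": 1_000_000}, cfg)
    full_s = scan_track(wins, ivs, "SNP", cfg, rng=np.random.default_rng(1))
    fast_s = scan_track(wins, ivs, "SNP", cfg, rng=np.random.default_rng(1),
                        ci_windows="above-threshold")
    dummy_i = [  # mirror the SNP track so the AND requirement can pass
        WindowStat(w.chrom, w.start, w.end, "InDel", w.n_variants,
                   w.mean_index_high, w.mean_index_low, w.mean_delta,
                   w.reliable, w.truncated, w.ci)
        for w in full_s
    ]
    dummy_i_fast = [
        WindowStat(w.chrom, w.start, w.end, "InDel", w.n_variants,
                   w.mean_index_high, w.mean_index_low, w.mean_delta,
                   w.reliable, w.truncated, w.ci)
        for w in fast_s
    ]
    full = call_regions(full_s, dummy_i, None, cfg)
    fast = call_regions(fast_s, dummy_i_fast, None, cfg)
    assert [(r.chrom, r.start, r.end) for r in full] == [(r.chrom, r.start, r.end) for r in fast]
    assert full  # the injected block is actually called
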