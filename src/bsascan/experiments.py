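"""Reproducible study-condition runs on the synthetic generator.

These helpers bundle the standard evaluation scenarios: scanning one
simulated cohort under the default extreme-pool design (with or without a
causal locus), and measuring the empirical coverage of the window null
confidence intervals on a causal-free cohort.

Problem sizes follow the generator defaults (1525 accessions, pools of 49,
~40x depth, 10 Mb chromosomes at one variant per 10 kb); the calibration
run uses non-overlapping windows so the outside-CI fraction is averaged
over effectively independent windows, and depth-only filtering, because
the index-based filters condition retained sites on the very statistic
the null resamples.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np

from .bsa_index import FilterConfig, apply_filters
from .synthetic_data import (
    SimulationConfig,
    chrom_lengths,
    select_pools,
    simulate_cohort,
    simulate_pooled_reads,
)
from .window_scan import ScanConfig, call_regions, make_windows, scan_track

__all__ = ["scan_single_cohort", "null_ci_calibration"]


def scan_single_cohort(
    seed: int,
    causal: bool = True,
    null_reps: int = 1000,
    sim_overrides: Mapping | None = None,
    scan_overrides: Mapping | None = None,
) -> dict:
    """Simulate one cohort, scan both tracks, call regions.

    Returns the genome-wide max-|Δ| window, whether it contains the causal
    site, and whether a called candidate region does.  CIs are evaluated
    for threshold-passing windows, which leaves default threshold-AND-CI
    region calling unchanged.
    """
    sim = SimulationConfig(rng_seed=seed, **(sim_overrides or {}))
    if not causal:
        sim = replace(sim, causal_sites=())
    cohort = simulate_cohort(sim)
    pools = select_pools(cohort, n_pool=sim.n_pool)
    variants, truth = simulate_pooled_reads(cohort, pools, sim)
    indexed, report = apply_filters(variants, FilterConfig())

    scan_cfg = ScanConfig(null_reps=null_reps, rng_seed=seed,
                          pool_size=sim.n_pool, **(scan_overrides or {}))
    windows = make_windows(chrom_lengths(sim), scan_cfg)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    snp = scan_track(windows, indexed, "SNP", scan_cfg, rng=rng,
                     ci_windows="above-threshold")
    indel = scan_track(windows, indexed, "InDel", scan_cfg, rng=rng,
                       ci_windows="above-threshold")
    regions = call_regions(snp, indel, None, scan_cfg)

    out = {
        "n_retained": report.retained,
        "n_regions": len(regions),
        "regions": [(r.chrom, r.start, r.end, r.peak_delta) for r in regions],
        "best_window": None,
        "best_window_contains_causal": False,
        "region_contains_causal": False,
    }
    reliable = [w for w in snp if w.reliable and np.isfinite(w.mean_delta)]
    if reliable:
        best = max(reliable, key=lambda w: abs(w.mean_delta))
        out["best_window"] = (best.chrom, best.start, best.end, best.mean_delta)
    if causal:
        causal_row = truth.loc[truth.is_causal].iloc[0]
        c_chrom, c_pos = str(causal_row.chrom), int(causal_row.pos)
        if out["best_window"] is not None:
            bc, bs, be, _ = out["best_window"]
            out["best_window_contains_causal"] = bc == c_chrom and bs <= c_pos <= be
        out["region_contains_causal"] = any(
            r.chrom == c_chrom and r.start <= c_pos <= r.end for r in regions
        )
    return out


def null_ci_calibration(
    seed: int,
    n_chromosomes: int = 12,
    window_size: int = 200_000,
    null_reps: int = 10_000,
    level: float = 0.95,
) -> dict:
    """Empirical coverage of the window null CI on a causal-free cohort.

    Non-overlapping windows of ``window_size`` over ``n_chromosomes``
    default-sized chromosomes; depth-only variant filtering; SNP track.
    Returns the number of reliable windows and the fraction of them whose
    observed mean Δ falls outside the CI at ``level``.
    """
    sim = SimulationConfig(
        rng_seed=seed, causal_sites=(), n_chromosomes=n_chromosomes,
        n_variants=n_chromosomes * 1000,
    )
    cohort = simulate_cohort(sim)
    pools = select_pools(cohort, n_pool=sim.n_pool)
    variants, _ = simulate_pooled_reads(cohort, pools, sim)
    depth_only = FilterConfig(min_index=0.0, drop_equal_genotypes=False)
    indexed, _ = apply_filters(variants, depth_only)

    scan_cfg = ScanConfig(
        window_size=window_size, step_size=window_size,
        ci_levels=(level,), null_reps=null_reps, rng_seed=seed,
        pool_size=sim.n_pool,
    )
    windows = make_windows(chrom_lengths(sim), scan_cfg)
    stats = scan_track(windows, indexed, "SNP", scan_cfg,
                       rng=np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1]))
    reliable = [w for w in stats if w.reliable and level in w.ci]
    outside = sum(w.outside_ci(level) for w in reliable)
    return {
        "n_windows": len(windows),
        "n_reliable": len(reliable),
        "outside_fraction": outside / len(reliable) if reliable else float("nan"),
    }
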