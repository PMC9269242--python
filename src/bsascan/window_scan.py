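"""Sliding-window aggregation of Δ(index) with a simulated null.

Windows (default 2 Mb, stepped every 10 kb) average the per-variant pool
indices and Δ.  Because read depth varies site to site, the null spread of
a window mean is depth-dependent; confidence intervals therefore come from
a Monte-Carlo two-stage resampling null of "no allele-frequency divergence
between pools".  At each member site, with p̂ the pooled alternate read
fraction across both bulks: (1) each bulk's true alternate frequency is
redrawn as the mean of 2·pool_size allele copies sampled at p̂ — finite
bulks of m accessions fluctuate around the population frequency with
variance p(1-p)/2m even without linkage; (2) alternate read counts are
redrawn as Binomial(observed pool depth, bulk frequency).  Omitting stage
1 (``pool_size=None``) gives a reads-only null that understates the null
spread for small bulks.  Candidate regions are merged runs of windows
significant in both the SNP and the InDel track.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bsa_index import IndexedVariant
from .variant_io import GeneModel

__all__ = [
    "ScanConfig",
    "WindowStat",
    "CandidateRegion",
    "make_windows",
    "window_means",
    "null_ci",
    "scan_track",
    "call_regions",
    "windows_to_frame",
]


@dataclass
class ScanConfig:
    """Window geometry, null-simulation and region-calling parameters."""

    window_size: int = 2_000_000
    step_size: int = 10_000
    ci_levels: tuple[float, ...] = (0.95, 0.99)
    null_reps: int = 10_000
    delta_threshold: float = 0.90
    min_variants_per_window: int = 10
    rng_seed: int | None = None
    significance_mode: str = "both"   # "threshold" | "ci" | "both"
    require_both_tracks: bool = True
    ci_scope: str = "per-window"      # "per-window" | "genome-wide"
    pool_size: int | None = 49        # accessions per bulk; None = reads-only null

    def __post_init__(self) -> None:
        if self.step_size > self.window_size:
            raise ValueError("step_size must be <= window_size")
        if self.step_size < 1 or self.window_size < 1:
            raise ValueError("window and step sizes must be positive")
        if not all(0 < lv < 1 for lv in self.ci_levels):
            raise ValueError("ci levels must be in (0, 1)")
        if not 0 < self.delta_threshold <= 1:
            raise ValueError("delta_threshold must be in (0, 1]")
        if self.null_reps < 1:
            raise ValueError("null_reps must be positive")
        if self.significance_mode not in {"threshold", "ci", "both"}:
            raise ValueError("significance_mode must be 'threshold', 'ci' or 'both'")
        if self.ci_scope not in {"per-window", "genome-wide"}:
            raise ValueError("ci_scope must be 'per-window' or 'genome-wide'")


@dataclass(frozen=True)
class WindowStat:
    """One sliding-window record for one variant-class track."""

    chrom: str
    start: int
    end: int
    vclass: str
    n_variants: int
    mean_index_high: float
    mean_index_low: float
    mean_delta: float
    reliable: bool
    truncated: bool = False
    ci: dict[float, tuple[float, float]] = field(default_factory=dict, compare=False)

    def outside_ci(self, level: float) -> bool:
        if level not in self.ci or not self.reliable:
            return False
        lo, hi = self.ci[level]
        return self.mean_delta < lo or self.mean_delta > hi


@dataclass(frozen=True)
class CandidateRegion:
    """Merged above-threshold interval supported by both variant tracks."""

    chrom: str
    start: int
    end: int
    peak_delta: float
    supported_by: frozenset[str]
    genes: tuple[str, ...] = ()


def make_windows(
    chrom_lengths: Mapping[str, int], config: ScanConfig
) -> list[tuple[str, int, int]]:
    """Window grid: starts at 1, 1+step, ...; a window exists whenever its
    start is within the chromosome; tail windows are truncated at the end."""
    windows: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"{chrom}: non-positive length {length}")
        start = 1
        while start <= length:
            windows.append((chrom, start, min(start + config.window_size - 1, length)))
            start += config.step_size
    return windows


def _track_arrays(
    variants: Sequence[IndexedVariant], vclass: str
) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome sorted arrays for one variant class."""
    by_chrom: dict[str, list[IndexedVariant]] = {}
    for iv in variants:
        if iv.vclass == vclass:
            by_chrom.setdefault(iv.chrom, []).append(iv)
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda v: v.pos)
        out[chrom] = {
            "pos": np.array([v.pos for v in ivs], dtype=np.int64),
            "ih": np.array([v.index_high for v in ivs]),
            "il": np.array([v.index_low for v in ivs]),
            "delta": np.array([v.delta for v in ivs]),
            "dh": np.array([v.depth_high for v in ivs], dtype=np.int64),
            "dl": np.array([v.depth_low for v in ivs], dtype=np.int64),
            "ah": np.array([v.variant.ad_high[1] for v in ivs], dtype=np.int64),
            "al": np.array([v.variant.ad_low[1] for v in ivs], dtype=np.int64),
        }
    return out


def window_means(
    windows: Sequence[tuple[str, int, int]],
    indexed_variants: Sequence[IndexedVariant],
    vclass: str,
    config: ScanConfig | None = None,
) -> list[WindowStat]:
    """Arithmetic window means of index_high, index_low and Δ for one class.

    Windows with fewer than ``min_variants_per_window`` members are flagged
    unreliable (their means are NaN when empty).
    """
    cfg = config or ScanConfig()
    arrays = _track_arrays(indexed_variants, vclass)
    chrom_max = {c: int(a["pos"].max()) if a["pos"].size else 0 for c, a in arrays.items()}
    stats: list[WindowStat] = []
    for chrom, start, end in windows:
        arr = arrays.get(chrom)
        if arr is None or arr["pos"].size == 0:
            n, mh, ml, md = 0, float("nan"), float("nan"), float("nan")
        else:
            i0 = int(np.searchsorted(arr["pos"], start, side="left"))
            i1 = int(np.searchsorted(arr["pos"], end, side="right"))
            n = i1 - i0
            if n == 0:
                mh = ml = md = float("nan")
            else:
                mh = float(arr["ih"][i0:i1].mean())
                ml = float(arr["il"][i0:i1].mean())
                md = float(arr["delta"][i0:i1].mean())
        stats.append(
            WindowStat(
                chrom=chrom, start=start, end=end, vclass=vclass, n_variants=n,
                mean_index_high=mh, mean_index_low=ml, mean_delta=md,
                reliable=n >= cfg.min_variants_per_window,
                truncated=end - start + 1 < cfg.window_size,
            )
        )
    return stats


def null_ci(
    windows: Sequence[tuple[str, int, int]] | Sequence[WindowStat],
    indexed_variants: Sequence[IndexedVariant],
    config: ScanConfig,
    vclass: str | None = None,
    rng: np.random.Generator | None = None,
) -> list[dict[float, tuple[float, float]]]:
    """Per-window CI bounds of the window-mean Δ under the resampling null.

    Returns one ``{level: (low, high)}`` dict per window, aligned with the
    input.  With ``ci_scope = "genome-wide"`` the bounds are quantiles of
    the per-replicate maximum |window mean Δ| over all windows, applied
    symmetrically to every window.
    """
    if config.null_reps < 1:
        raise ValueError("null_reps must be >= 1")
    if windows and isinstance(windows[0], WindowStat):
        if vclass is None:
            vclass = windows[0].vclass
        grid = [(w.chrom, w.start, w.end) for w in windows]
    else:
        grid = list(windows)  # type: ignore[arg-type]
        if vclass is None:
            raise ValueError("vclass required when windows are bare tuples")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    arrays = _track_arrays(indexed_variants, vclass)
    R = config.null_reps

    # replicate window-mean deltas, assembled per chromosome
    win_by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _, _) in enumerate(grid):
        win_by_chrom.setdefault(chrom, []).append(i)

    out: list[dict[float, tuple[float, float]]] = [{} for _ in grid]
    levels = tuple(config.ci_levels)
    probs = np.array([q for lv in levels for q in ((1 - lv) / 2, 1 - (1 - lv) / 2)])

    gw_max: np.ndarray | None = None  # per-replicate genome-wide max |mean Δ|
    gw_windows: list[int] = []
    for chrom, win_idx in win_by_chrom.items():
        arr = arrays.get(chrom)
        if arr is None or arr["pos"].size == 0:
            continue
        n = arr["pos"].size
        p_hat = (arr["ah"] + arr["al"]) / (arr["dh"] + arr["dl"])
        bounds = np.array(
            [
                (np.searchsorted(arr["pos"], grid[i][1], side="left"),
                 np.searchsorted(arr["pos"], grid[i][2], side="right"))
                for i in win_idx
            ],
            dtype=np.int64,
        )
        counts = bounds[:, 1] - bounds[:, 0]
        occupied = counts > 0
        sums = np.zeros((len(win_idx), R))
        chunk = max(1, int(2e7) // max(n, 1))
        done = 0
        m = config.pool_size
        while done < R:
            r = min(chunk, R - done)
            if m is not None:
                # stage 1: bulk composition — each pool's true ALT frequency
                # is the mean of 2m sampled allele copies at frequency p̂
                q_h = rng.binomial(2 * m, p_hat[:, None], size=(n, r)) / (2 * m)
                q_l = rng.binomial(2 * m, p_hat[:, None], size=(n, r)) / (2 * m)
            else:
                q_h = q_l = np.broadcast_to(p_hat[:, None], (n, r))
            # stage 2: read sampling at the observed depths
            alt_h = rng.binomial(arr["dh"][:, None], q_h, size=(n, r))
            alt_l = rng.binomial(arr["dl"][:, None], q_l, size=(n, r))
            delta = alt_h / arr["dh"][:, None] - alt_l / arr["dl"][:, None]
            prefix = np.vstack([np.zeros((1, r)), np.cumsum(delta, axis=0)])
            sums[:, done:done + r] = prefix[bounds[:, 1]] - prefix[bounds[:, 0]]
            done += r
        means = sums[occupied] / counts[occupied, None]
        if config.ci_scope == "genome-wide":
            if means.size:
                chrom_max = np.abs(means).max(axis=0)
                gw_max = chrom_max if gw_max is None else np.maximum(gw_max, chrom_max)
                gw_windows.extend(int(i) for i, occ in zip(win_idx, occupied) if occ)
            continue
        if means.size:
            qs = np.quantile(means, probs, axis=1)  # (2*levels, occupied windows)
            for j, i in enumerate(int(i) for i, occ in zip(win_idx, occupied) if occ):
                out[i] = {
                    lv: (float(qs[2 * li, j]), float(qs[2 * li + 1, j]))
                    for li, lv in enumerate(levels)
                }

    if config.ci_scope == "genome-wide" and gw_max is not None:
        bounds_gw = {
            lv: (-float(np.quantile(gw_max, lv)), float(np.quantile(gw_max, lv)))
            for lv in levels
        }
        for i in gw_windows:
            out[i] = dict(bounds_gw)
    return out


def scan_track(
    windows: Sequence[tuple[str, int, int]],
    indexed_variants: Sequence[IndexedVariant],
    vclass: str,
    config: ScanConfig,
    rng: np.random.Generator | None = None,
    with_ci: bool = True,
    ci_windows: str = "all",
) -> list[WindowStat]:
    """Window means plus null CIs for one variant-class track.

    ``ci_windows="above-threshold"`` restricts the Monte-Carlo null to
    windows whose |mean Δ| already reaches the association threshold — a
    shortcut that leaves threshold-AND-CI region calling unchanged, since
    sub-threshold windows cannot become significant in that mode.
    """
    stats = window_means(windows, indexed_variants, vclass, config)
    if not with_ci:
        return stats
    if ci_windows == "all":
        cis = null_ci(windows, indexed_variants, config, vclass=vclass, rng=rng)
        return [replace(s, ci=c) for s, c in zip(stats, cis)]
    if ci_windows != "above-threshold":
        raise ValueError("ci_windows must be 'all' or 'above-threshold'")
    pick = [
        i for i, s in enumerate(stats)
        if s.reliable and np.isfinite(s.mean_delta)
        and abs(s.mean_delta) >= config.delta_threshold
    ]
    if pick:
        sub = [(stats[i].chrom, stats[i].start, stats[i].end) for i in pick]
        cis = null_ci(sub, indexed_variants, config, vclass=vclass, rng=rng)
        stats = list(stats)
        for i, c in zip(pick, cis):
            stats[i] = replace(stats[i], ci=c)
    return stats


def _significant(stat: WindowStat, config: ScanConfig) -> bool:
    if not stat.reliable or not np.isfinite(stat.mean_delta):
        return False
    over_threshold = abs(stat.mean_delta) >= config.delta_threshold
    level = config.ci_levels[0]
    outside = stat.outside_ci(level)
    if config.significance_mode == "threshold":
        return over_threshold
    if config.significance_mode == "ci":
        return outside
    return over_threshold and outside


def call_regions(
    snp_windows: Sequence[WindowStat],
    indel_windows: Sequence[WindowStat],
    gene_models: Sequence[GeneModel] | None,
    config: ScanConfig,
) -> list[CandidateRegion]:
    """Merge significant windows into candidate regions.

    Both tracks must be computed on the identical window grid.  In the
    default mode a window contributes only if significant in both the SNP
    and the InDel track; overlapping significant windows merge, and genes
    overlapping the merged interval are attached.
    """
    grid_snp = [(w.chrom, w.start, w.end) for w in snp_windows]
    grid_indel = [(w.chrom, w.start, w.end) for w in indel_windows]
    if grid_snp != grid_indel:
        raise ValueError("SNP and InDel tracks are on different window grids")

    flagged: list[tuple[str, int, int, float, frozenset[str]]] = []
    for ws, wi in zip(snp_windows, indel_windows):
        sig_s = _significant(ws, config)
        sig_i = _significant(wi, config)
        if config.require_both_tracks:
            ok = sig_s and sig_i
        else:
            ok = sig_s or sig_i
        if ok:
            support = frozenset(
                t for t, sig in (("SNP", sig_s), ("InDel", sig_i)) if sig
            )
            flagged.append((ws.chrom, ws.start, ws.end, ws.mean_delta, support))

    regions: list[CandidateRegion] = []
    for chrom in dict.fromkeys(f[0] for f in flagged):
        chrom_wins = sorted(f for f in flagged if f[0] == chrom)
        current: list[tuple[str, int, int, float, frozenset[str]]] = []
        for win in chrom_wins:
            if current and win[1] <= current[-1][2] + 1:
                current.append(win)
            else:
                if current:
                    regions.append(_merge(current, gene_models))
                current = [win]
        if current:
            regions.append(_merge(current, gene_models))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _merge(
    wins: list[tuple[str, int, int, float, frozenset[str]]],
    gene_models: Sequence[GeneModel] | None,
) -> CandidateRegion:
    chrom = wins[0][0]
    start = min(w[1] for w in wins)
    end = max(w[2] for w in wins)
    peak = max((w[3] for w in wins), key=abs)
    support = frozenset().union(*(w[4] for w in wins))
    genes: tuple[str, ...] = ()
    if gene_models:
        genes = tuple(
            g.gene_id
            for g in sorted(gene_models, key=lambda g: (g.chrom, g.tx_start))
            if g.chrom == chrom and g.overlaps(start, end)
        )
    return CandidateRegion(
        chrom=chrom, start=start, end=end, peak_delta=peak,
        supported_by=support, genes=genes,
    )


def windows_to_frame(stats: Sequence[WindowStat], level: float | None = None) -> pd.DataFrame:
    """Window TSV layout: coordinates, n, means, Δ and CI bounds."""
    rows = []
    for s in stats:
        lv = level if level is not None else (min(s.ci) if s.ci else None)
        lo, hi = s.ci.get(lv, (float("nan"), float("nan"))) if lv else (float("nan"), float("nan"))
        rows.append(
            (s.chrom, s.start, s.end, s.vclass, s.n_variants, s.reliable,
             s.mean_index_high, s.mean_index_low, s.mean_delta, lo, hi)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "vclass", "n", "reliable",
                 "mean_index_high", "mean_index_low", "mean_delta", "ci_low", "ci_high"],
    )
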