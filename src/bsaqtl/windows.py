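"""Sliding-window smoothing, null-simulation confidence bands, per-method
region calling, and the four-method intersection that defines the QTL.

Windows are 1-based closed bp intervals starting at 1 + j*step; at the
defaults (2000-kb windows, 20-kb step) each site contributes to 100
overlapping windows.  Windows holding fewer than a minimum number of sites
are merged into the next window (cascading, coordinates expanding to the
union); a trailing sparse window merges backward into the last retained one.

Significance is assessed against empirical quantiles of the statistics
under the no-QTL null, obtained by simulating bulk composition
(k F2 genotypes per bulk at 1:2:1) and Poisson/binomial read sampling,
tabulated per depth class.  Δ(SNP-index) is judged two-sided, the other
three statistics one-sided upper (Fisher on the −log10 p scale).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from bsaqtl._util import STREAM_NULLBAND, require, stream_rng
from bsaqtl.stats import fisher_two_tailed, g_statistic_array

METHODS = ("delta", "ed", "g", "fisher")

_UNIT_SCALE = {"bp": 1.0, "kb": 1e3, "Mb": 1e6}
_UNIT_DECIMALS = {"bp": 0, "kb": 1, "Mb": 2}


@dataclass(frozen=True)
class Region:
    """Maximal run of significant windows for one method."""

    method: str
    chrom: str
    start: int
    end: int
    peak: float
    peak_pos: int
    n_windows: int = 0


@dataclass(frozen=True)
class QTLCall:
    """Intersection interval supported by the required methods."""

    chrom: str
    start: int
    end: int
    methods: tuple[str, ...]
    peaks: dict = field(default_factory=dict, hash=False, compare=False)

    def length(self, unit: str = "Mb", decimals: int | None = None) -> float:
        return region_length(self.start, self.end, unit, decimals)


# ---------------------------------------------------------------------------
# windows


def window_starts_containing(pos: int, window: int, step: int) -> np.ndarray:
    """Start coordinates of every window whose closed interval contains ``pos``."""
    require(window > 0 and step > 0, "window and step must be positive")
    require(step <= window, "step > window would leave gaps between windows")
    j_lo = max(0, math.ceil((pos - window) / step))
    j_hi = (pos - 1) // step
    return 1 + step * np.arange(j_lo, j_hi + 1)


def assign_windows(
    positions: Sequence[int], window: int, step: int, chrom_length: int | None = None
) -> pd.DataFrame:
    """Window grid over one chromosome with per-window member-site ranges.

    Returns a frame with columns start, end, lo, hi, n_snps where [lo, hi)
    indexes the sorted position array.  Windows are generated while their
    start lies within the chromosome (or the last site when the length is
    unknown); ends are capped at the chromosome end.
    """
    require(window > 0 and step > 0, "window and step must be positive")
    if step > window:
        raise ValueError("step > window would leave gaps that drop sites")
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    limit = int(chrom_length) if chrom_length else (int(pos[-1]) if pos.size else 0)
    if limit <= 0:
        return pd.DataFrame(columns=["start", "end", "lo", "hi", "n_snps"])
    starts = np.arange(1, limit + 1, step, dtype=np.int64)
    ends = np.minimum(starts + window - 1, limit)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    return pd.DataFrame(dict(start=starts, end=ends, lo=lo, hi=hi, n_snps=hi - lo))


def merge_sparse_windows(windows: pd.DataFrame, min_snps: int) -> pd.DataFrame:
    """Cascade windows with fewer than ``min_snps`` member sites into the next.

    Coordinates and member ranges expand to the union; a trailing sparse
    window merges backward into the last retained window.  A chromosome
    whose sites cannot reach the minimum yields no windows.
    """
    require(min_snps >= 1, "min_snps must be >= 1")
    kept: list[list[int]] = []
    pending: list[int] | None = None
    for row in windows.itertuples(index=False):
        cur = [row.start, row.end, row.lo, row.hi]
        if pending is not None:
            cur = [min(pending[0], cur[0]), max(pending[1], cur[1]), min(pending[2], cur[2]), max(pending[3], cur[3])]
            pending = None
        if cur[3] - cur[2] < min_snps:
            pending = cur
        else:
            kept.append(cur)
    if pending is not None and kept:
        last = kept[-1]
        kept[-1] = [min(last[0], pending[0]), max(last[1], pending[1]), min(last[2], pending[2]), max(last[3], pending[3])]
    out = pd.DataFrame(kept, columns=["start", "end", "lo", "hi"])
    out["n_snps"] = out["hi"] - out["lo"]
    return out


def window_profile(
    site_stats: pd.DataFrame,
    window: int = 2_000_000,
    step: int = 20_000,
    min_snps: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window mean statistic profile over all chromosomes.

    Means are arithmetic over member sites (a merged window averages the
    union of its sites, not the mean of means); Fisher p-values are
    summarised as the mean of −log10(p).
    """
    frames = []
    for chrom, sub in site_stats.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        win = assign_windows(pos, window, step, length)
        win = merge_sparse_windows(win, min_snps)
        if win.empty:
            continue
        csum = {}
        for col, series in (
            ("delta", sub["delta"]),
            ("ed", sub["ed"]),
            ("g", sub["g"]),
            ("neglog_p", -np.log10(sub["fisher_p"])),
            ("depth", (sub["depth_t"].to_numpy() + sub["depth_s"].to_numpy()) / 2.0),
        ):
            csum[col] = np.concatenate([[0.0], np.cumsum(np.asarray(series, float))])
        lo = win["lo"].to_numpy()
        hi = win["hi"].to_numpy()
        n = (hi - lo).astype(float)
        data = dict(chrom=chrom, start=win["start"], end=win["end"], n_snps=win["n_snps"])
        for col in ("delta", "ed", "g", "neglog_p", "depth"):
            data[f"mean_{col}"] = (csum[col][hi] - csum[col][lo]) / n
        frames.append(pd.DataFrame(data))
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_snps", "mean_delta", "mean_ed", "mean_g", "mean_neglog_p", "mean_depth"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# null confidence bands


@dataclass
class ConfidenceBand:
    """Empirical null quantiles per depth class, statistic and level."""

    bulk_size: int
    levels: tuple[float, ...]
    quantiles: dict  # depth_class -> stat -> level -> value
    n_rep: int = 0

    @property
    def depth_classes(self) -> list[int]:
        return sorted(self.quantiles)

    def threshold(self, stat: str, level: float, depth: float) -> float:
        cls = min(self.depth_classes, key=lambda c: abs(c - depth))
        return self.quantiles[cls][stat][level]


def simulate_null_thresholds(
    bulk_size: int,
    depth: float,
    n_rep: int = 10_000,
    levels: Sequence[float] = (0.95, 0.99),
    depth_classes: Sequence[int] | None = None,
    statistics: Sequence[str] = METHODS,
    ed_exponent: int = 1,
    seed: int = 0,
) -> ConfidenceBand:
    """Null quantiles of the four statistics under no-QTL bulk sampling.

    Per replicate and bulk: k F2 genotypes at 1:2:1 (equivalently a
    Binomial(2k, 1/2) tolerant-allele count), bulk frequency p, site depth
    Poisson(depth class), tolerant reads Binomial(depth, p).  Quantiles are
    two-sided for Δ (tabulated on |Δ|), upper for ED, G and −log10 p.
    """
    require(bulk_size > 0 and depth > 0 and n_rep > 0, "k, depth and replicates must be positive")
    if n_rep < 1000:
        warnings.warn("fewer than 1000 null replicates gives unstable quantiles", stacklevel=2)
    rng = stream_rng(seed, STREAM_NULLBAND)
    classes = [int(round(depth))] if depth_classes is None else sorted({int(c) for c in depth_classes})
    quantiles: dict[int, dict[str, dict[float, float]]] = {}
    two_k = 2 * bulk_size
    for cls in classes:
        p_t = rng.binomial(two_k, 0.5, size=n_rep) / two_k
        p_s = rng.binomial(two_k, 0.5, size=n_rep) / two_k
        dep_t = rng.poisson(cls, size=n_rep)
        dep_s = rng.poisson(cls, size=n_rep)
        ok = (dep_t > 0) & (dep_s > 0)
        a = rng.binomial(dep_t, p_t)
        c = rng.binomial(dep_s, p_s)
        a, c, dep_t, dep_s = a[ok], c[ok], dep_t[ok], dep_s[ok]
        delta = a / dep_t - c / dep_s
        per_stat: dict[str, dict[float, float]] = {}
        if "delta" in statistics:
            per_stat["delta"] = {lv: float(np.quantile(np.abs(delta), lv)) for lv in levels}
        if "ed" in statistics:
            ed = (math.sqrt(2.0) * np.abs(delta)) ** ed_exponent
            per_stat["ed"] = {lv: float(np.quantile(ed, lv)) for lv in levels}
        if "g" in statistics:
            g = g_statistic_array(a, dep_t - a, c, dep_s - c)
            per_stat["g"] = {lv: float(np.quantile(g, lv)) for lv in levels}
        if "fisher" in statistics:
            neglog = np.array(
                [
                    -math.log10(fisher_two_tailed((int(ai), int(ti - ai)), (int(ci), int(si - ci))))
                    for ai, ti, ci, si in zip(a, dep_t, c, dep_s)
                ]
            )
            per_stat["fisher"] = {lv: float(np.quantile(neglog, lv)) for lv in levels}
        quantiles[cls] = per_stat
    return ConfidenceBand(bulk_size=bulk_size, levels=tuple(levels), quantiles=quantiles, n_rep=n_rep)


def delta_null_sd_infinite_depth(bulk_size: int) -> float:
    """Normal-theory SD of Δ(SNP-index) under the null at infinite depth.

    Each bulk frequency is a Binomial(2k, 1/2)/2k mean, so
    Var(Δ) = 2 · 1/(8k) and the two-sided 99% bound is ≈ 2.576·√(2/(8k)).
    """
    return math.sqrt(2.0 / (8.0 * bulk_size))


# ---------------------------------------------------------------------------
# region calling


_WINDOW_STAT = {"delta": "mean_delta", "ed": "mean_ed", "g": "mean_g", "fisher": "mean_neglog_p"}


def call_regions(
    profile: pd.DataFrame,
    band: ConfidenceBand,
    level: float = 0.99,
    methods: Sequence[str] = METHODS,
    max_gap: int = 0,
) -> list[Region]:
    """Maximal runs of consecutive supra-threshold windows, per method.

    A window is significant for a method when its mean statistic exceeds the
    null band at ``level`` for the window's mean depth (|mean_delta| for Δ).
    Runs separated by more than ``max_gap`` sub-threshold windows split into
    separate regions (default: no gap bridging).
    """
    require(level in band.levels, f"band was not tabulated at level {level}")
    regions: list[Region] = []
    for chrom, sub in profile.groupby("chrom", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        for method in methods:
            col = _WINDOW_STAT[method]
            values = sub[col].to_numpy(float)
            judged = np.abs(values) if method == "delta" else values
            thr = np.array([band.threshold(method, level, d) for d in sub["mean_depth"]])
            exceed = judged > thr
            idx = np.nonzero(exceed)[0]
            if idx.size == 0:
                continue
            runs: list[list[int]] = [[int(idx[0])]]
            for i in idx[1:]:
                if i - runs[-1][-1] <= max_gap + 1:
                    runs[-1].append(int(i))
                else:
                    runs.append([int(i)])
            for run in runs:
                rows = sub.iloc[run]
                j = int(np.argmax(np.abs(rows[col].to_numpy(float))))
                peak_row = rows.iloc[j]
                regions.append(
                    Region(
                        method=method,
                        chrom=str(chrom),
                        start=int(rows["start"].min()),
                        end=int(rows["end"].max()),
                        peak=float(peak_row[col]),
                        peak_pos=int((peak_row["start"] + peak_row["end"]) // 2),
                        n_windows=len(run),
                    )
                )
    return regions


def intersect_methods(
    regions: Iterable[Region], required: Sequence[str] = METHODS
) -> list[QTLCall]:
    """Overlap-consistent tuples of per-method regions and their intersections.

    For every combination of one region per required method on the same
    chromosome whose intervals mutually overlap, the call interval is the
    intersection of all of them.  A chromosome missing any required method
    yields no call there.
    """
    require(len(required) >= 2, "need at least two methods to intersect")
    from itertools import product

    by_chrom: dict[str, dict[str, list[Region]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, {}).setdefault(r.method, []).append(r)
    calls: list[QTLCall] = []
    seen = set()
    for chrom, per_method in sorted(by_chrom.items()):
        if any(m not in per_method for m in required):
            continue
        for combo in product(*(per_method[m] for m in required)):
            start = max(r.start for r in combo)
            end = min(r.end for r in combo)
            if start > end:
                continue
            key = (chrom, start, end)
            if key in seen:
                continue
            seen.add(key)
            calls.append(
                QTLCall(
                    chrom=chrom,
                    start=start,
                    end=end,
                    methods=tuple(required),
                    peaks={r.method: (r.peak, r.peak_pos, r.start, r.end) for r in combo},
                )
            )
    return calls


def region_length(
    start: int, end: int, unit: str = "bp", decimals: int | None = None
) -> float:
    """Interval length as end − start scaled to bp/kb/Mb.

    Plain subtraction (not +1) matches how genomic interval sizes are
    conventionally printed; default rounding is 1 decimal for kb and 2
    for Mb.
    """
    require(end >= start, "end must be >= start")
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown unit {unit!r}")
    dec = _UNIT_DECIMALS[unit] if decimals is None else decimals
    return round((end - start) / _UNIT_SCALE[unit], dec)


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    """Table-style report of per-method regions (Method, Chr, Start, End, Peak)."""
    return pd.DataFrame(
        [
            dict(
                method=r.method,
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                peak=r.peak,
                peak_pos=r.peak_pos,
                n_windows=r.n_windows,
            )
            for r in regions
        ]
    )
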