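"""The four per-site bulk-segregant association statistics.

All statistics operate on the 2x2 read-count table of one variant site:

              tolerant allele   other allele
    T bulk          a                b
    S bulk          c                d

* SNP-index of a bulk: fraction of its reads carrying the tolerant
  parent's allele; Δ(SNP-index) = index(T) − index(S).
* Euclidean distance: sqrt of the summed squared allele-frequency
  differences between bulks; for a biallelic site ED = √2·|Δ|.
* G statistic: likelihood-ratio statistic 2·Σ n·ln(n/n̂) against
  row/column independence (natural log; 0·ln 0 ≡ 0).
* Fisher's exact test: two-sided p by hypergeometric enumeration with
  exact integer arithmetic (all tables at fixed margins whose
  probability is ≤ that of the observed table).
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from bsaqtl.variants import Variant


def snp_index(ad: tuple[int, int]) -> float:
    """Fraction of reads carrying the tolerant parent's allele; NaN at depth 0."""
    total = ad[0] + ad[1]
    if total <= 0:
        return float("nan")
    return ad[0] / total


def delta_snp_index(ad_t: tuple[int, int], ad_s: tuple[int, int]) -> float:
    """SNP-index difference between tolerant and sensitive bulks."""
    return snp_index(ad_t) - snp_index(ad_s)


def euclidean_distance(ad_t: tuple[int, int], ad_s: tuple[int, int], exponent: int = 1) -> float:
    """Allele-frequency Euclidean distance between bulks, raised to ``exponent``.

    Raw ED = sqrt(Σ over alleles (f_T − f_S)²); for a biallelic site this is
    √2·|f_T − f_S|.  ``exponent`` > 1 (typically 2) sharpens peaks for plotting.
    """
    if exponent < 1:
        raise ValueError("exponent must be >= 1")
    ft, fs = snp_index(ad_t), snp_index(ad_s)
    raw = math.sqrt(2.0) * abs(ft - fs)
    return raw ** exponent


def g_statistic(ad_t: tuple[int, int], ad_s: tuple[int, int]) -> float:
    """Likelihood-ratio G on the 2x2 bulk-by-allele table (0 on a zero margin)."""
    obs = np.array([[ad_t[0], ad_t[1]], [ad_s[0], ad_s[1]]], float)
    return float(_g_from_table(obs))


def _g_from_table(obs: np.ndarray) -> float:
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0
    expected = np.outer(rows, cols) / n
    mask = obs > 0
    return 2.0 * float((obs[mask] * np.log(obs[mask] / expected[mask])).sum())


def g_statistic_array(a, b, c, d) -> np.ndarray:
    """Vectorised G over parallel count arrays."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        def term(o, r, col):
            e = r * col / n
            t = o * np.log(o / e)
            return np.where(o > 0, t, 0.0)

        g = 2.0 * (term(a, r1, c1) + term(b, r1, c2) + term(c, r2, c1) + term(d, r2, c2))
    degenerate = (n == 0) | (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    return np.where(degenerate, 0.0, g)


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # integer table weights share the denominator C(n, c1): exact comparison
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / math.comb(n, c1)


def fisher_two_tailed(ad_t: tuple[int, int], ad_s: tuple[int, int]) -> float:
    """Exact two-sided Fisher p for the bulk-by-allele table.

    Enumerates every table with the observed margins using exact integer
    weights, summing the probabilities of tables no more probable than the
    observed one.  A zero margin carries no information and returns 1.
    """
    a, b = int(ad_t[0]), int(ad_t[1])
    c, d = int(ad_s[0]), int(ad_s[1])
    if min(a, b, c, d) < 0:
        raise ValueError("negative read counts")
    return _fisher_cached(a, b, c, d)


def compute_site_stats(
    variants: Sequence[Variant], ed_exponent: int = 1
) -> pd.DataFrame:
    """Evaluate all four statistics at every site with reads in both bulks.

    Sites where either bulk has zero depth are excluded (their statistics are
    undefined); the returned frame carries one row per retained site with
    columns chrom, pos, ref, alt, parent alleles, tolerant-first depths,
    snp_index_t, snp_index_s, delta, ed, g, fisher_p, depth_t, depth_s,
    plus ``n_excluded`` in ``DataFrame.attrs``.
    """
    rows = [v for v in variants if v.dp_t > 0 and v.dp_s > 0]
    n_excluded = len(variants) - len(rows)
    if not rows:
        df = pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "parent_t", "parent_s",
                "ad_t_tol", "ad_t_other", "ad_s_tol", "ad_s_other",
                "snp_index_t", "snp_index_s", "delta", "ed", "g", "fisher_p",
                "depth_t", "depth_s",
            ]
        )
        df.attrs["n_excluded"] = n_excluded
        return df
    at = np.array([v.ad_t for v in rows], float)
    as_ = np.array([v.ad_s for v in rows], float)
    idx_t = at[:, 0] / at.sum(axis=1)
    idx_s = as_[:, 0] / as_.sum(axis=1)
    delta = idx_t - idx_s
    ed = (math.sqrt(2.0) * np.abs(delta)) ** ed_exponent
    g = g_statistic_array(at[:, 0], at[:, 1], as_[:, 0], as_[:, 1])
    fisher = np.array([fisher_two_tailed(v.ad_t, v.ad_s) for v in rows])
    df = pd.DataFrame(
        dict(
            chrom=[v.chrom for v in rows],
            pos=[v.pos for v in rows],
            ref=[v.ref for v in rows],
            alt=[v.alt for v in rows],
            parent_t=[v.parent_t_allele for v in rows],
            parent_s=[v.parent_s_allele for v in rows],
            ad_t_tol=at[:, 0].astype(int),
            ad_t_other=at[:, 1].astype(int),
            ad_s_tol=as_[:, 0].astype(int),
            ad_s_other=as_[:, 1].astype(int),
            snp_index_t=idx_t,
            snp_index_s=idx_s,
            delta=delta,
            ed=ed,
            g=g,
            fisher_p=fisher,
            depth_t=at.sum(axis=1).astype(int),
            depth_s=as_.sum(axis=1).astype(int),
        )
    )
    df.attrs["n_excluded"] = n_excluded
    return df
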