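"""Fine-mapping stage: marker selection, genetic-map estimation and a
Haley–Knott single-QTL scan with permutation LOD thresholds.

Markers are coded A (sensitive-parent homozygote), H (heterozygote),
B (tolerant-parent homozygote).  Adjacent-marker recombination fractions
are estimated by maximum likelihood for F2 codominant markers and turned
into centimorgans with Kosambi's map function, the convention for rice
linkage maps.  The scan regresses the trait on expected additive and
dominance dosages given the flanking markers (Haley–Knott regression),
with LOD = (n/2)·log10(RSS0/RSS1) and PVE = 100·(1 − RSS1/RSS0); the
additive effect is signed so that a positive value means the tolerant
parent's allele raises the trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from bsaqtl._util import STREAM_PERMUTATION, require, stream_rng

MISSING = -1
CODE_OF = {"A": 0, "H": 1, "B": 2, "-": MISSING}
LETTER_OF = {0: "A", 1: "H", 2: "B", MISSING: "-"}


@dataclass
class MarkerGenotypes:
    """Line × marker genotype matrix with physical marker coordinates."""

    line_ids: list[str]
    marker_ids: list[str]
    chrom: str
    positions_bp: np.ndarray  # physical bp per marker, ascending
    codes: np.ndarray  # (n_lines, n_markers) int8 in {0,1,2,-1}

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        require(self.codes.shape == (len(self.line_ids), len(self.marker_ids)), "shape mismatch")
        require(bool(np.all(np.diff(self.positions_bp) > 0)), "marker positions must increase")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        require(not bad.any(), "genotype codes must be A/H/B/missing")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("line_id\t" + "\t".join(self.marker_ids) + "\n")
            for i, lid in enumerate(self.line_ids):
                fh.write(lid + "\t" + "\t".join(LETTER_OF[int(c)] for c in self.codes[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str, chrom: str, positions_bp: Sequence[int]) -> "MarkerGenotypes":
        df = pd.read_csv(path, sep="\t", dtype=str).set_index("line_id")
        codes = np.vectorize(CODE_OF.get)(df.to_numpy())
        return cls(
            line_ids=df.index.tolist(),
            marker_ids=df.columns.tolist(),
            chrom=chrom,
            positions_bp=np.asarray(positions_bp),
            codes=codes,
        )


@dataclass
class GeneticMap:
    """Marker positions in cM (anchored at 0), with unlinked-marker flags."""

    marker_ids: list[str]
    chrom: str
    positions_cm: np.ndarray
    positions_bp: np.ndarray
    recomb_fractions: np.ndarray  # between adjacent markers, len n-1
    unlinked: list[str] = field(default_factory=list)

    def cm_of_bp(self, bp: float) -> float:
        """Physical → genetic coordinate by linear interpolation between markers."""
        return float(np.interp(bp, self.positions_bp, self.positions_cm))

    def bp_of_cm(self, cm: float) -> float:
        return float(np.interp(cm, self.positions_cm, self.positions_bp))


def kosambi_cm(r: float) -> float:
    """Kosambi map distance (cM) for a recombination fraction r."""
    require(0 <= r < 0.5, "r must lie in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))

def kosambi_r(cm: float) -> float:
    """Inverse Kosambi: recombination fraction for a map distance in cM."""
    return 0.5 * math.tanh(cm / 50.0)


# ---------------------------------------------------------------------------
# marker selection


def select_fine_markers(
    site_stats: pd.DataFrame,
    effects: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    delta_min: float = 0.48,
    n_markers: int = 27,
) -> pd.DataFrame:
    """Non-synonymous, supra-threshold SNPs spread evenly across the interval.

    Candidates are non-synonymous SNPs inside [start, end] with
    Δ(SNP-index) > ``delta_min``; ``n_markers`` of them are picked by greedy
    max–min physical spacing (both interval extremes first, then repeatedly
    the candidate farthest from everything already chosen).  If fewer
    candidates qualify than requested, all are returned.
    """
    require(end >= start, "empty interval")
    merged = site_stats.merge(effects[["chrom", "pos", "classification"]], on=["chrom", "pos"])
    qual = merged[
        (merged["chrom"] == chrom)
        & (merged["pos"] >= start)
        & (merged["pos"] <= end)
        & (merged["delta"] > delta_min)
        & (merged["classification"] == "non-synonymous")
    ].sort_values("pos")
    positions = qual["pos"].to_numpy()
    if positions.size <= n_markers:
        return qual.reset_index(drop=True)
    chosen = [0, positions.size - 1]
    remaining = set(range(1, positions.size - 1))
    while len(chosen) < n_markers and remaining:
        best, best_gap = None, -1.0
        for i in sorted(remaining):
            gap = min(abs(positions[i] - positions[j]) for j in chosen)
            if gap > best_gap:
                best, best_gap = i, gap
        chosen.append(best)
        remaining.discard(best)
    return qual.iloc[sorted(chosen)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# map estimation


def _joint_probs(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities of two F2 loci at recombination r."""
    gametes = [((0, 0), (1 - r) / 2), ((1, 1), (1 - r) / 2), ((0, 1), r / 2), ((1, 0), r / 2)]
    p = np.zeros((3, 3))
    for (a1, b1), f1 in gametes:
        for (a2, b2), f2 in gametes:
            p[a1 + a2, b1 + b2] += f1 * f2
    return p


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    ok = (g1 != MISSING) & (g2 != MISSING)
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1[ok], g2[ok]), 1)
    return counts


def _mle_r(counts: np.ndarray) -> float:
    def nll(r: float) -> float:
        p = np.clip(_joint_probs(r), 1e-300, None)
        return -float((counts * np.log(p)).sum())

    res = minimize_scalar(nll, bounds=(1e-6, 0.5 - 1e-6), method="bounded")
    return float(res.x)


def estimate_map(geno: MarkerGenotypes) -> GeneticMap:
    """ML recombination fractions between adjacent markers → Kosambi cM map.

    Adjacent pairs whose estimated fraction reaches 0.5 are flagged
    unlinked (the fraction is capped just below 0.5 so the map stays
    finite).  The first marker anchors the map at 0 cM.
    """
    n_lines, n_markers = geno.codes.shape
    require(n_markers >= 2, "need at least two markers")
    require(n_lines >= 30, "need at least 30 lines for a stable map")
    rs = np.empty(n_markers - 1)
    unlinked = []
    for i in range(n_markers - 1):
        r = _mle_r(_pair_counts(geno.codes[:, i], geno.codes[:, i + 1]))
        if r >= 0.499:
            unlinked.append(geno.marker_ids[i + 1])
            r = 0.499
        rs[i] = r
    cm = np.concatenate([[0.0], np.cumsum([kosambi_cm(r) for r in rs])])
    return GeneticMap(
        marker_ids=list(geno.marker_ids),
        chrom=geno.chrom,
        positions_cm=cm,
        positions_bp=geno.positions_bp.copy(),
        recomb_fractions=rs,
        unlinked=unlinked,
    )


# ---------------------------------------------------------------------------
# Haley–Knott scan



def _transition(r: float) -> np.ndarray:
    """F2 genotype transition matrix between two loci at recombination r."""
    return np.array(
        [
            [(1 - r) ** 2, 2 * r * (1 - r), r**2],
            [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
            [r**2, 2 * r * (1 - r), (1 - r) ** 2],
        ]
    )


def _geno_probs_at(
    codes_l: np.ndarray, codes_r: np.ndarray, d_left_cm: float, d_right_cm: float
) -> tuple[np.ndarray, np.ndarray]:
    """P(QTL genotype | flanking genotypes) per line, plus a validity mask.

    Lines missing either flanking genotype are masked out at this position.
    """
    t1 = _transition(kosambi_r(d_left_cm))
    t2 = _transition(kosambi_r(d_right_cm))
    ok = (codes_l != MISSING) & (codes_r != MISSING)
    probs = np.zeros((codes_l.size, 3))
    l = codes_l[ok]
    rr = codes_r[ok]
    w = t1[l] * t2[:, rr].T  # (m, 3): P(mL→q) · P(q→mR)
    w = w / w.sum(axis=1, keepdims=True)
    probs[ok] = w
    return probs, ok


def _scan_design(probs: np.ndarray) -> np.ndarray:
    """Design columns [x, z]: expected dosage−1 and heterozygote probability."""
    x = probs[:, 2] - probs[:, 0]
    z = probs[:, 1]
    return np.column_stack([x, z])


def _fit_position(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float, float]:
    """(LOD, PVE%, additive, dominance) of the trait on one position's design."""
    n = y.size
    ybar = y - y.mean()
    rss0 = float(ybar @ ybar)
    if rss0 == 0:
        return 0.0, 0.0, 0.0, 0.0
    X = np.column_stack([np.ones(n), design])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss1 = float(resid @ resid)
    rss1 = min(rss1, rss0)
    lod = (n / 2.0) * math.log10(rss0 / max(rss1, 1e-300))
    pve = 100.0 * (1.0 - rss1 / rss0)
    return lod, pve, float(coef[1]), float(coef[2])


def _grid(gmap: GeneticMap, step_cm: float) -> list[tuple[float, int, int]]:
    """Scan positions: (cM, left marker index, right marker index)."""
    out = []
    cm = gmap.positions_cm
    for i in range(len(cm) - 1):
        pos = cm[i]
        while pos < cm[i + 1] - 1e-9:
            out.append((float(pos), i, i + 1))
            pos += step_cm
    out.append((float(cm[-1]), len(cm) - 2, len(cm) - 1))
    return out


def interval_mapping(
    geno: MarkerGenotypes,
    phen: Mapping[str, float] | pd.Series,
    gmap: GeneticMap,
    step_cm: float = 0.5,
) -> pd.DataFrame:
    """Haley–Knott scan along the map at ``step_cm`` resolution.

    Returns one row per grid position with LOD, PVE (%), the additive effect
    (positive ⇔ tolerant allele raises the trait), the dominance effect and
    the flanking marker ids.  Lines without a phenotype, or missing a
    flanking genotype, are dropped at that position only.
    """
    phen = pd.Series(phen)
    has_phen = np.array([lid in phen.index for lid in geno.line_ids])
    require(has_phen.mean() >= 0.9, "phenotypes missing for more than 10% of genotyped lines")
    y_full = np.array([phen.get(lid, np.nan) for lid in geno.line_ids])
    rows = []
    for pos_cm, i, j in _grid(gmap, step_cm):
        probs, ok = _geno_probs_at(
            geno.codes[:, i],
            geno.codes[:, j],
            pos_cm - gmap.positions_cm[i],
            gmap.positions_cm[j] - pos_cm,
        )
        use = ok & ~np.isnan(y_full)
        lod, pve, add, dom = _fit_position(y_full[use], _scan_design(probs[use]))
        rows.append(
            dict(
                pos_cm=pos_cm,
                lod=lod,
                pve=pve,
                additive=add,
                dominance=dom,
                left_marker=gmap.marker_ids[i],
                right_marker=gmap.marker_ids[j],
                n=int(use.sum()),
            )
        )
    return pd.DataFrame(rows)


def permutation_threshold(
    geno: MarkerGenotypes,
    phen: Mapping[str, float] | pd.Series,
    gmap: GeneticMap,
    n_perm: int = 1000,
    alpha: float = 0.01,
    step_cm: float = 0.5,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotypes are shuffled across lines ``n_perm`` times (seeded); the
    threshold is the empirical (1−alpha) critical value of the
    per-permutation maximum LOD (see :func:`empirical_threshold`).
    """
    require(n_perm >= 100, "need at least 100 permutations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    phen = pd.Series(phen)
    y_full = np.array([phen.get(lid, np.nan) for lid in geno.line_ids])
    phenotyped = ~np.isnan(y_full)
    codes = geno.codes[phenotyped]
    y0 = y_full[phenotyped]
    rng = stream_rng(seed, STREAM_PERMUTATION)
    Y = np.empty((y0.size, n_perm))
    for p in range(n_perm):
        Y[:, p] = rng.permutation(y0)
    max_lod = np.zeros(n_perm)
    for pos_cm, i, j in _grid(gmap, step_cm):
        probs, use = _geno_probs_at(
            codes[:, i],
            codes[:, j],
            pos_cm - gmap.positions_cm[i],
            gmap.positions_cm[j] - pos_cm,
        )
        design = _scan_design(probs)
        Xc = np.column_stack([np.ones(int(use.sum())), design[use]])
        q, _ = np.linalg.qr(Xc)
        Ym = Y[use]
        rss0 = (Ym**2).sum(axis=0) - Ym.sum(axis=0) ** 2 / use.sum()
        proj = q.T @ Ym
        rss1 = np.maximum((Ym**2).sum(axis=0) - (proj**2).sum(axis=0), 1e-300)
        rss1 = np.minimum(rss1, np.maximum(rss0, 1e-300))
        lod = (use.sum() / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1)
        max_lod = np.maximum(max_lod, lod)
    return empirical_threshold(max_lod, alpha)


def empirical_threshold(max_lods: Sequence[float], alpha: float) -> float:
    """Critical value from a list of permutation maximum LODs.

    Uses the order statistic at 0-based index ceil(n·(1−alpha)) of the
    sorted values (capped at the largest), a conservative convention under
    which the empirical exceedance probability is at most alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    x = np.sort(np.asarray(max_lods, float))
    k = min(x.size - 1, math.ceil(x.size * (1.0 - alpha)))
    return float(x[k])


def call_qtl(
    scan: pd.DataFrame,
    threshold: float,
    lod_min: float = 3.0,
    trait: str = "SR",
) -> pd.DataFrame:
    """Peaks of the LOD profile with 1-LOD support intervals.

    Local maxima with LOD ≥ ``lod_min`` are reported; those also exceeding
    the permutation ``threshold`` are flagged significant, the rest are kept
    as flagged secondary peaks.  Ties at equal LOD resolve to the leftmost
    position.  The support interval extends from the peak to the nearest
    positions where the LOD has dropped by 1.
    """
    require(not scan.empty, "empty scan")
    cutoff = max(threshold, lod_min)
    lod = scan["lod"].to_numpy()
    pos = scan["pos_cm"].to_numpy()
    peaks = []
    for i in range(lod.size):
        left = lod[i - 1] if i > 0 else -np.inf
        right = lod[i + 1] if i < lod.size - 1 else -np.inf
        if lod[i] >= lod_min and lod[i] > left and lod[i] >= right:
            peaks.append(i)
    rows = []
    for i in peaks:
        target = lod[i] - 1.0
        l = i
        while l > 0 and lod[l - 1] >= target:
            l -= 1
        r = i
        while r < lod.size - 1 and lod[r + 1] >= target:
            r += 1
        row = scan.iloc[i]
        add = float(row["additive"])
        rows.append(
            dict(
                trait=trait,
                pos_cm=float(row["pos_cm"]),
                lod=float(row["lod"]),
                pve=float(row["pve"]),
                additive=add,
                dominance=float(row["dominance"]),
                left_ci=float(pos[l]),
                right_ci=float(pos[r]),
                significant=bool(lod[i] >= cutoff),
                contributing_parent="tolerant" if add >= 0 else "sensitive",
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "trait", "pos_cm", "lod", "pve", "additive", "dominance",
            "left_ci", "right_ci", "significant", "contributing_parent",
        ],
    )
    return out.sort_values("lod", ascending=False).reset_index(drop=True)
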