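"""Differentially methylated region (DMR) detection.

Autocorrelation-corrected combination of per-probe p-values, in the
style of the sliding-window combined-p-value approach widely used on
methylation arrays:

1.  The spatial autocorrelation of the association signal is estimated
    from the data: p-values are mapped to z = Phi^-1(1 - p) and, for
    every pair of probes on the same chromosome within ``max_dist``
    bases, the Pearson correlation of the paired z's is computed per
    distance bin.
2.  Each probe's p-value is smoothed by a Stouffer-Liptak combination
    of all probes within a +/- ``window_bp`` window, using the binned
    ACF as the correlation model: combined z = sum(z_i) / sqrt(sum_ij
    C_ij).
3.  Candidate regions seed at probes with smoothed p below ``seed_p``
    and extend bidirectionally over probes below ``extend_p`` separated
    by at most ``max_gap_bp``; overlapping candidates merge.
4.  Each region is re-scored by Stouffer-Liptak over its members'
    *original* p-values and Sidak-adjusted for the number of
    region-sized windows among all tested bases:
    p_adj = 1 - (1 - p_region)^(tested_bp / region_bp).

The shipped region filter keeps regions with Sidak-adjusted p < 0.001
and at least three member CpGs.  Combination is one-sided on
association strength (1 - p); the sign of the mean delta-beta over
members is reported separately and mixed-direction regions are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "ACFEstimate",
    "DMRRecord",
    "estimate_acf",
    "stouffer_liptak",
    "smooth_pvalues",
    "find_regions",
    "score_regions",
    "run_dmr",
]

P_FLOOR = 1e-300
P_CEIL = 1 - 1e-16


@dataclass
class ACFEstimate:
    """Binned distance-decay of signal correlation.

    ``bins`` are half-open intervals (lo, hi]; bin 1 starts at distance
    1 bp.  Bins with fewer than ``min_pairs`` probe pairs get
    correlation 0 and are flagged.
    """

    bins: list[tuple[int, int]]
    correlations: np.ndarray
    pair_counts: np.ndarray
    flagged_bins: list[int] = field(default_factory=list)

    def corr_at(self, dist: int) -> float:
        """Correlation for a probe pair at the given distance (0 beyond
        the last bin)."""
        for (lo, hi), c in zip(self.bins, self.correlations):
            if lo < dist <= hi:
                return float(c)
        return 0.0


def _p_to_z(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, P_CEIL)
    return stats.norm.isf(p)  # Phi^-1(1 - p)


def estimate_acf(
    p: np.ndarray,
    positions: pd.DataFrame,
    max_dist: int = 500,
    bin_width: int = 50,
    min_pairs: int = 30,
) -> ACFEstimate:
    """Distance-binned Pearson correlation of z-scores.

    ``positions`` has columns ``chrom`` and ``pos`` aligned to ``p``;
    pairs are formed within chromosomes and pooled across them.
    """
    z = _p_to_z(p)
    edges = list(range(0, max_dist + bin_width, bin_width))
    bins = [(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    nb = len(bins)
    cnt = np.zeros(nb)
    sx = np.zeros(nb)
    sy = np.zeros(nb)
    sxx = np.zeros(nb)
    syy = np.zeros(nb)
    sxy = np.zeros(nb)

    frame = pd.DataFrame(
        {"chrom": positions["chrom"].to_numpy(), "pos": positions["pos"].to_numpy(),
         "z": z}
    )
    for _, sub in frame.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        zz = sub["z"].to_numpy()
        n = pos.size
        j0 = 0
        for i in range(n):
            j = i + 1
            while j < n and pos[j] - pos[i] <= max_dist:
                d = pos[j] - pos[i]
                if d >= 1:
                    b = min((d - 1) // bin_width, nb - 1)
                    cnt[b] += 1
                    sx[b] += zz[i]
                    sy[b] += zz[j]
                    sxx[b] += zz[i] ** 2
                    syy[b] += zz[j] ** 2
                    sxy[b] += zz[i] * zz[j]
                j += 1
    corr = np.zeros(nb)
    flagged = []
    for b in range(nb):
        if cnt[b] < min_pairs:
            flagged.append(b)
            continue
        n = cnt[b]
        cov = sxy[b] / n - (sx[b] / n) * (sy[b] / n)
        vx = sxx[b] / n - (sx[b] / n) ** 2
        vy = syy[b] / n - (sy[b] / n) ** 2
        if vx <= 0 or vy <= 0:
            flagged.append(b)
            continue
        corr[b] = np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0)
    return ACFEstimate(bins=bins, correlations=corr, pair_counts=cnt,
                       flagged_bins=flagged)


def _nearest_pd(C: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clip non-positive eigenvalues; returns (repaired, was_repaired)."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() > eps:
        return C, False
    vals = np.clip(vals, eps, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    return R, True


def stouffer_liptak(p: np.ndarray, corr: np.ndarray | None = None) -> float:
    """Correlation-corrected Stouffer combination of p-values.

    z_i = Phi^-1(1 - p_i); combined z = sum(z) / sqrt(sum_ij C_ij);
    combined p = 1 - Phi(combined z).  With the identity correlation
    this is the classical Stouffer method; a single p is returned
    unchanged.  Non-positive-definite correlation matrices are repaired
    by eigenvalue clipping.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    k = p.size
    if k == 1:
        return float(p[0])
    if corr is None:
        corr = np.eye(k)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValidationError("correlation matrix shape mismatch")
    corr, _ = _nearest_pd(corr)
    z = _p_to_z(p)
    denom = corr.sum()
    if denom <= 0:
        denom = k
    z_comb = z.sum() / np.sqrt(denom)
    return float(stats.norm.sf(z_comb))


def smooth_pvalues(
    p: np.ndarray,
    positions: pd.DataFrame,
    acf: ACFEstimate,
    window_bp: int = 500,
) -> np.ndarray:
    """Sliding-window Stouffer-Liptak smoothing of per-probe p-values.

    For each probe, all probes on the same chromosome within
    +/- ``window_bp`` are combined with correlations looked up from the
    ACF bins.  Isolated probes keep their original p.
    """
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    frame = pd.DataFrame(
        {"chrom": positions["chrom"].to_numpy(), "pos": positions["pos"].to_numpy()}
    )
    frame["row"] = np.arange(len(frame))
    # precompute bin lookup as array over distance for speed
    max_d = acf.bins[-1][1] if acf.bins else 0
    corr_by_dist = np.zeros(max_d + 1)
    for (lo, hi), c in zip(acf.bins, acf.correlations):
        corr_by_dist[lo + 1 : hi + 1] = c
    for _, sub in frame.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        rows = sub["row"].to_numpy()
        n = pos.size
        lo_idx = np.searchsorted(pos, pos - window_bp, side="left")
        hi_idx = np.searchsorted(pos, pos + window_bp, side="right")
        for i in range(n):
            a, b = lo_idx[i], hi_idx[i]
            if b - a == 1:
                out[rows[i]] = p[rows[i]]
                continue
            idx = rows[a:b]
            dmat = np.abs(pos[a:b][:, None] - pos[a:b][None, :])
            C = np.where(
                dmat == 0, 1.0,
                corr_by_dist[np.clip(dmat, 0, max_d)],
            )
            out[rows[i]] = stouffer_liptak(p[idx], C)
    return out


def find_regions(
    smoothed_p: np.ndarray,
    positions: pd.DataFrame,
    seed_p: float = 0.01,
    extend_p: float = 0.05,
    max_gap_bp: int = 500,
) -> list[dict]:
    """Candidate intervals from smoothed p-values.

    A region starts at a probe with smoothed p < ``seed_p`` and extends
    bidirectionally over probes with smoothed p < ``extend_p`` whose
    gaps are <= ``max_gap_bp``; overlapping candidates are merged.
    Returns dicts with chrom, start, end (1-based inclusive) and member
    row indices (genomic order).
    """
    sp = np.asarray(smoothed_p, dtype=float)
    frame = pd.DataFrame(
        {"chrom": positions["chrom"].to_numpy(), "pos": positions["pos"].to_numpy()}
    )
    frame["row"] = np.arange(len(frame))
    regions: list[dict] = []
    for chrom, sub in frame.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        rows = sub["row"].to_numpy()
        ext = sp[rows] < extend_p
        seed = sp[rows] < seed_p
        n = pos.size
        i = 0
        while i < n:
            if not ext[i]:
                i += 1
                continue
            # maximal run of extendable probes with small gaps
            j = i
            while j + 1 < n and ext[j + 1] and pos[j + 1] - pos[j] <= max_gap_bp:
                j += 1
            if seed[i : j + 1].any():
                regions.append(
                    dict(
                        chrom=chrom,
                        start=int(pos[i]),
                        end=int(pos[j]),
                        rows=list(rows[i : j + 1]),
                    )
                )
            i = j + 1
    return regions


@dataclass
class DMRRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_probes: int
    probe_ids: list[str]
    p_region: float
    p_sidak: float
    mean_delta_beta: float
    mixed_direction: bool


def _tested_bp(positions: pd.DataFrame, max_gap_bp: int = 500) -> int:
    """Total bases covered by tested probes: per probe, the distance to
    its next neighbour capped at ``max_gap_bp`` (minimum footprint 1)."""
    total = 0
    for _, sub in positions.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size == 0:
            continue
        gaps = np.minimum(np.diff(pos), max_gap_bp)
        total += int(gaps.sum()) + 1  # last probe contributes 1 bp
    return total


def score_regions(
    candidates: list[dict],
    p: np.ndarray,
    positions: pd.DataFrame,
    acf: ACFEstimate,
    probe_ids: list[str] | None = None,
    delta_beta: np.ndarray | None = None,
    genome_bp_tested: int | None = None,
    max_gap_bp: int = 500,
    sidak_alpha: float = 0.001,
    min_probes: int = 3,
) -> list[DMRRecord]:
    """Region-level combined and Sidak-adjusted p-values with filters.

    Each candidate is scored by Stouffer-Liptak over its members'
    original p-values (ACF correlations) and Sidak-adjusted with
    exponent tested_bp / region_bp.  Records pass when p_sidak <
    ``sidak_alpha`` and n_probes >= ``min_probes``.
    """
    p = np.asarray(p, dtype=float)
    pos_all = positions["pos"].to_numpy()
    if genome_bp_tested is None:
        genome_bp_tested = _tested_bp(positions, max_gap_bp)
    max_d = acf.bins[-1][1] if acf.bins else 0
    corr_by_dist = np.zeros(max_d + 1)
    for (lo, hi), c in zip(acf.bins, acf.correlations):
        corr_by_dist[lo + 1 : hi + 1] = c
    records: list[DMRRecord] = []
    for cand in candidates:
        rows = np.asarray(cand["rows"], dtype=int)
        rp = p[rows]
        rpos = pos_all[rows]
        order = np.argsort(rpos)
        rows, rp, rpos = rows[order], rp[order], rpos[order]
        dmat = np.abs(rpos[:, None] - rpos[None, :])
        C = np.where(dmat == 0, 1.0, corr_by_dist[np.clip(dmat, 0, max_d)])
        p_region = stouffer_liptak(rp, C)
        region_bp = max(int(rpos[-1] - rpos[0]), 1)
        exponent = genome_bp_tested / region_bp
        p_region_c = min(max(p_region, P_FLOOR), P_CEIL)
        # log1p form keeps precision for tiny p * huge exponent
        p_sidak = -np.expm1(exponent * np.log1p(-p_region_c))
        db = float("nan")
        mixed = False
        if delta_beta is not None:
            dbs = np.asarray(delta_beta, dtype=float)[rows]
            db = float(np.nanmean(dbs))
            signs = np.sign(dbs[~np.isnan(dbs)])
            mixed = bool((signs > 0).any() and (signs < 0).any())
        if p_sidak < sidak_alpha and rows.size >= min_probes:
            records.append(
                DMRRecord(
                    chrom=str(cand["chrom"]),
                    start=int(rpos[0]),
                    end=int(rpos[-1]),
                    n_probes=int(rows.size),
                    probe_ids=(
                        [probe_ids[r] for r in rows] if probe_ids is not None else []
                    ),
                    p_region=float(p_region),
                    p_sidak=float(p_sidak),
                    mean_delta_beta=db,
                    mixed_direction=mixed,
                )
            )
    records.sort(key=lambda r: r.p_sidak)
    return records


def run_dmr(
    p: pd.Series,
    annotation_frame: pd.DataFrame,
    delta_beta: pd.Series | None = None,
    max_dist: int = 500,
    bin_width: int = 50,
    window_bp: int = 500,
    seed_p: float = 0.01,
    extend_p: float = 0.05,
    max_gap_bp: int = 500,
    sidak_alpha: float = 0.001,
    min_probes: int = 3,
) -> tuple[list[DMRRecord], ACFEstimate]:
    """Full DMR stage from per-probe p-values and genomic positions.

    ``annotation_frame`` is indexed by probe id with columns chrom/pos;
    only probes present in both inputs are used.
    """
    probes = [pid for pid in p.index if pid in annotation_frame.index]
    if not probes:
        raise ValidationError("no probes shared between p-values and annotation")
    sub = annotation_frame.loc[probes, ["chrom", "pos"]]
    order = np.lexsort((sub["pos"].to_numpy(), sub["chrom"].to_numpy()))
    probes = [probes[i] for i in order]
    sub = sub.iloc[order]
    pv = p.loc[probes].to_numpy(dtype=float)
    keep = ~np.isnan(pv)
    probes = [pid for pid, k in zip(probes, keep) if k]
    sub = sub.loc[probes]
    pv = pv[keep]
    acf = estimate_acf(pv, sub, max_dist=max_dist, bin_width=bin_width)
    smoothed = smooth_pvalues(pv, sub, acf, window_bp=window_bp)
    cands = find_regions(smoothed, sub, seed_p=seed_p, extend_p=extend_p,
                         max_gap_bp=max_gap_bp)
    db = delta_beta.loc[probes].to_numpy(dtype=float) if delta_beta is not None else None
    records = score_regions(
        cands, pv, sub, acf,
        probe_ids=probes,
        delta_beta=db,
        max_gap_bp=max_gap_bp,
        sidak_alpha=sidak_alpha,
        min_probes=min_probes,
    )
    return records, acf
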