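"""Quality control and probe filtering.

Filters follow the standard blood-array EWAS recipe: samples with more
than 5% of probes failing detection (p > 0.05) are dropped; probes
failing in more than 10% of samples are removed; probes flagged for SNP
overlap, cross-hybridization or sex-chromosome location are masked; and
probes whose beta distribution is bi- or tri-modal (genotype-like
clusters, typically caused by polymorphisms in the probe body) are
excluded by one-dimensional density clustering.  "More than" thresholds
are strict inequalities, so a sample failing at exactly 5.0% is kept.

Individual detection-failed values are set to missing before any
downstream stage; all later computations are pairwise-complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import BetaMatrix, CpGAnnotation, DetectionPMatrix, ValidationError

__all__ = [
    "QCReport",
    "drop_failed_samples",
    "mask_probes_by_detection",
    "apply_blacklist",
    "flag_multimodal_probes",
    "mask_failed_values",
    "beta_to_m",
    "m_to_beta",
    "run_qc",
]


@dataclass
class QCReport:
    """Bookkeeping of what each filter removed.

    Counts reconcile per axis: probes in = probes surviving + removed by
    detection + blacklist + multimodal; likewise for samples.
    """

    n_probes_in: int = 0
    n_samples_in: int = 0
    n_probes_removed_detection: int = 0
    n_probes_removed_blacklist: int = 0
    n_probes_removed_multimodal: int = 0
    n_samples_removed: int = 0
    surviving_probes: list[str] = field(default_factory=list)
    surviving_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "n_probes_in": self.n_probes_in,
            "n_samples_in": self.n_samples_in,
            "n_probes_removed_detection": self.n_probes_removed_detection,
            "n_probes_removed_blacklist": self.n_probes_removed_blacklist,
            "n_probes_removed_multimodal": self.n_probes_removed_multimodal,
            "n_samples_removed": self.n_samples_removed,
            "n_probes_out": len(self.surviving_probes),
            "n_samples_out": len(self.surviving_samples),
        }
        return d


def drop_failed_samples(
    detp: DetectionPMatrix,
    alpha: float = 0.05,
    max_sample_fail_frac: float = 0.05,
) -> list[str]:
    """Samples whose fraction of detection-failed probes is tolerable.

    A probe call fails when its detection p exceeds ``alpha``; a sample
    is removed when its failing fraction is strictly greater than
    ``max_sample_fail_frac``.  Returns the kept sample ids, in order.
    """
    if detp.shape[0] == 0 or detp.shape[1] == 0:
        raise ValidationError("empty detection p-value matrix")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    vals = detp.values
    fail_frac = np.nanmean(vals > alpha, axis=0)
    keep = fail_frac <= max_sample_fail_frac
    return [s for s, k in zip(detp.sample_ids, keep) if k]


def mask_probes_by_detection(
    detp: DetectionPMatrix,
    alpha: float = 0.05,
    max_probe_fail_frac: float = 0.10,
) -> list[str]:
    """Probes reliable in enough samples (failing fraction <= threshold)."""
    vals = detp.values
    fail_frac = np.nanmean(vals > alpha, axis=1)
    keep = fail_frac <= max_probe_fail_frac
    return [p for p, k in zip(detp.probe_ids, keep) if k]


def apply_blacklist(betas: BetaMatrix, annotation: CpGAnnotation) -> BetaMatrix:
    """Remove probes flagged for SNP overlap, cross-hybridization or sex
    chromosomes.  A probe with several flags set is removed (and counted)
    once."""
    bad = set(annotation.blacklisted())
    keep = [p for p in betas.probe_ids if p not in bad]
    if not keep:
        raise ValidationError("blacklist removed every probe")
    return betas.select_probes(keep)


def _cluster_1d(values: np.ndarray, eps: float, min_samples: int) -> list[np.ndarray]:
    """Density clusters of sorted 1-D values: maximal runs whose
    consecutive gaps are <= eps, keeping runs with >= min_samples points
    (the 1-D specialization of DBSCAN's reachability)."""
    v = np.sort(values)
    if v.size == 0:
        return []
    breaks = np.nonzero(np.diff(v) > eps)[0]
    clusters = np.split(v, breaks + 1)
    return [c for c in clusters if c.size >= min_samples]


def flag_multimodal_probes(
    betas: BetaMatrix,
    min_cluster_frac: float = 0.10,
    min_separation: float = 0.25,
    eps: float = 0.05,
) -> list[str]:
    """Probes whose beta values form >= 2 well-separated density clusters.

    Per probe, non-missing betas are density-clustered in one dimension
    (neighborhood radius ``eps``, minimum neighborhood count
    ``max(3, ceil(0.05 n))``).  The probe is flagged multimodal when at
    least two clusters each hold >= ``min_cluster_frac`` of the samples
    and their medians are >= ``min_separation`` apart on the beta scale.
    Probes with fewer than 5 non-missing values are never flagged.
    """
    flagged: list[str] = []
    vals = betas.values
    for i, probe in enumerate(betas.probe_ids):
        row = vals[i]
        row = row[~np.isnan(row)]
        n = row.size
        if n < 5:
            continue
        min_samples = max(3, math.ceil(0.05 * n))
        clusters = _cluster_1d(row, eps, min_samples)
        big = [c for c in clusters if c.size >= min_cluster_frac * n]
        if len(big) < 2:
            continue
        medians = sorted(float(np.median(c)) for c in big)
        if any(b - a >= min_separation for a, b in zip(medians, medians[1:])):
            flagged.append(probe)
    return flagged


def mask_failed_values(
    betas: BetaMatrix, detp: DetectionPMatrix, alpha: float = 0.05
) -> BetaMatrix:
    """Set individual detection-failed beta values to missing."""
    sub = detp.data.loc[betas.probe_ids, betas.sample_ids]
    failed = sub.to_numpy() > alpha
    return BetaMatrix(betas.data.where(~failed))


def beta_to_m(beta, epsilon: float = 1e-6):
    """Logit-2 transform M = log2(b / (1 - b)) with clipping to
    [epsilon, 1 - epsilon] so boundary betas stay finite."""
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1 - epsilon)
    return np.log2(b / (1 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (away from the clipped boundary)."""
    x = np.power(2.0, np.asarray(m, dtype=float))
    return x / (1 + x)


def run_qc(
    betas: BetaMatrix,
    detp: DetectionPMatrix,
    annotation: CpGAnnotation,
    detection_alpha: float = 0.05,
    max_sample_fail_frac: float = 0.05,
    max_probe_fail_frac: float = 0.10,
    multimodal_min_cluster_frac: float = 0.10,
    multimodal_min_separation: float = 0.25,
    multimodal_eps: float = 0.05,
) -> tuple[BetaMatrix, QCReport]:
    """Full QC: failed samples, unreliable probes, blacklist, multimodal.

    Filter order matches the narrative of a standard preprocessing
    report; the detection and blacklist filters commute.
    """
    report = QCReport(n_probes_in=betas.shape[0], n_samples_in=betas.shape[1])

    kept_samples = drop_failed_samples(detp, detection_alpha, max_sample_fail_frac)
    report.n_samples_removed = betas.shape[1] - len(kept_samples)
    betas = betas.select_samples(kept_samples)
    detp = detp.select_samples(kept_samples)

    kept_probes = mask_probes_by_detection(detp, detection_alpha, max_probe_fail_frac)
    report.n_probes_removed_detection = betas.shape[0] - len(kept_probes)
    betas = betas.select_probes(kept_probes)
    detp = detp.select_probes(kept_probes)

    betas = mask_failed_values(betas, detp, detection_alpha)

    n_before = betas.shape[0]
    betas = apply_blacklist(betas, annotation)
    report.n_probes_removed_blacklist = n_before - betas.shape[0]

    multimodal = set(
        flag_multimodal_probes(
            betas,
            min_cluster_frac=multimodal_min_cluster_frac,
            min_separation=multimodal_min_separation,
            eps=multimodal_eps,
        )
    )
    report.n_probes_removed_multimodal = len(multimodal)
    betas = betas.select_probes([p for p in betas.probe_ids if p not in multimodal])

    report.surviving_probes = list(betas.probe_ids)
    report.surviving_samples = list(betas.sample_ids)
    return betas, report
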