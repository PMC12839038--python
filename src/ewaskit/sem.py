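"""Stochastic epigenetic mutations (SEMs), burden models, epivariations.

A SEM is an extreme methylation value at a single CpG in a single
subject: outside the control-population fences

    [Q1 - k * IQR, Q3 + k * IQR],   IQR = Q3 - Q1,  k = 3 by default,

with Q1/Q3 the 25th/75th percentiles of the control betas at that probe
(linear-interpolation quantile convention).  A subject's SEM burden is
the count of probes at which it falls outside the fences, split into
hypo- (below) and hyper-methylated (above) calls.

Burden is modeled on the log10(n + 1) scale; subjects whose transformed
burden lies outside mean +/- 3 SD are excluded as technical outliers
before an OLS regression of burden on group, age, sex and cell-type
fractions.

An epivariation is a gene-level enrichment of same-direction SEMs in one
subject: at least ``min_run`` genomically consecutive CpGs of the gene
called in the same direction, with a binomial enrichment p-value against
the subject's genome-wide SEM rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import BetaMatrix, CpGAnnotation, SampleSheet, ValidationError

__all__ = [
    "SEMReferenceRanges",
    "SEMProfile",
    "BurdenModelResult",
    "compute_reference_ranges",
    "call_sems",
    "model_burden",
    "call_epivariations",
    "group_specific_epivariations",
]


@dataclass
class SEMReferenceRanges:
    """Per-probe control fences: q1, q3, iqr, lo, hi."""

    data: pd.DataFrame  # index probe_id; columns q1, q3, iqr, lo, hi
    n_controls: int
    k: float
    skipped_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = self.data
        if ((d["lo"] > d["q1"] + 1e-12) | (d["q1"] > d["q3"] + 1e-12)).any():
            raise ValidationError("fence ordering violated")


@dataclass
class SEMProfile:
    """Sparse SEM calls plus per-sample burden totals."""

    calls: pd.DataFrame  # columns probe_id, sample_id, direction
    totals: pd.DataFrame  # index sample_id; n_sem, n_hypo, n_hyper
    probe_ids: list[str]  # probes that were scored (the calling universe)

    def __post_init__(self) -> None:
        t = self.totals
        if ((t["n_hypo"] + t["n_hyper"]) != t["n_sem"]).any():
            raise ValidationError("burden totals do not reconcile")


def compute_reference_ranges(
    betas_controls: BetaMatrix, k: float = 3.0, min_n: int = 8
) -> SEMReferenceRanges:
    """Control-derived fences per probe.

    Probes with fewer than ``min_n`` non-missing control values are
    skipped (listed in ``skipped_probes``) rather than given unstable
    fences.
    """
    if betas_controls.shape[1] == 0:
        raise ValidationError("no control samples")
    vals = betas_controls.values
    n_ok = (~np.isnan(vals)).sum(axis=1)
    enough = n_ok >= min_n
    skipped = [p for p, e in zip(betas_controls.probe_ids, enough) if not e]
    vals_ok = vals[enough]
    with np.errstate(all="ignore"):
        q1 = np.nanquantile(vals_ok, 0.25, axis=1)
        q3 = np.nanquantile(vals_ok, 0.75, axis=1)
    iqr = q3 - q1
    frame = pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lo": q1 - k * iqr,
            "hi": q3 + k * iqr,
        },
        index=betas_controls.probe_ids[enough],
    )
    return SEMReferenceRanges(
        data=frame,
        n_controls=betas_controls.shape[1],
        k=k,
        skipped_probes=skipped,
    )


def call_sems(betas_all: BetaMatrix, ranges: SEMReferenceRanges) -> SEMProfile:
    """Score every sample against the control fences.

    Strict inequalities: beta < lo is a hypomethylated SEM, beta > hi a
    hypermethylated one; missing values are never called.
    """
    probes = [p for p in betas_all.probe_ids if p in ranges.data.index]
    B = betas_all.data.loc[probes].to_numpy(dtype=float)
    lo = ranges.data.loc[probes, "lo"].to_numpy()[:, None]
    hi = ranges.data.loc[probes, "hi"].to_numpy()[:, None]
    with np.errstate(invalid="ignore"):
        hypo = B < lo
        hyper = B > hi
    samples = list(betas_all.sample_ids)
    rows = []
    pi, si = np.nonzero(hypo)
    rows.extend(
        {"probe_id": probes[i], "sample_id": samples[j], "direction": "hypo"}
        for i, j in zip(pi, si)
    )
    pi, si = np.nonzero(hyper)
    rows.extend(
        {"probe_id": probes[i], "sample_id": samples[j], "direction": "hyper"}
        for i, j in zip(pi, si)
    )
    calls = pd.DataFrame(rows, columns=["probe_id", "sample_id", "direction"])
    totals = pd.DataFrame(
        {
            "n_hypo": hypo.sum(axis=0),
            "n_hyper": hyper.sum(axis=0),
        },
        index=betas_all.sample_ids,
    )
    totals["n_sem"] = totals["n_hypo"] + totals["n_hyper"]
    return SEMProfile(calls=calls, totals=totals[["n_sem", "n_hypo", "n_hyper"]],
                      probe_ids=probes)


def call_sems_leave_one_out(
    betas_all: BetaMatrix,
    control_ids: list[str],
    k: float = 3.0,
    min_n: int = 8,
) -> SEMProfile:
    """SEM calls with leave-one-out fences for the control samples.

    Each control is scored against fences built from the other controls,
    so controls and cases are equally out-of-sample and the burden
    comparison is not biased by in-sample quantile fitting.  Cases are
    scored against the all-controls fences.
    """
    ctrl = betas_all.select_samples(control_ids)
    case_ids = [s for s in betas_all.sample_ids if s not in set(control_ids)]
    parts: list[SEMProfile] = []
    if case_ids:
        ranges = compute_reference_ranges(ctrl, k=k, min_n=min_n)
        parts.append(call_sems(betas_all.select_samples(case_ids), ranges))
    for cid in control_ids:
        others = [s for s in control_ids if s != cid]
        ranges_i = compute_reference_ranges(
            ctrl.select_samples(others), k=k, min_n=min_n
        )
        parts.append(call_sems(betas_all.select_samples([cid]), ranges_i))
    calls = pd.concat([p.calls for p in parts], ignore_index=True)
    totals = pd.concat([p.totals for p in parts]).loc[betas_all.sample_ids]
    probes = sorted({p for part in parts for p in part.probe_ids})
    return SEMProfile(calls=calls, totals=totals, probe_ids=probes)


@dataclass
class BurdenModelResult:
    burden_kind: str  # total | hypo | hyper
    excluded_samples: list[str]
    coefficients: pd.DataFrame  # index term; coef, se, t, p, ci_lo, ci_hi
    n_used: int


def _burden_design(sheet: SampleSheet, cell_fractions=None) -> pd.DataFrame:
    X = pd.DataFrame(index=sheet.sample_ids)
    X["group"] = sheet.case_mask().astype(float)
    X["age"] = sheet.data["age"].astype(float)
    X["sex"] = (sheet.data["sex"] == "M").astype(float)
    if cell_fractions is not None:
        # drop one cell type (the first) for identifiability
        frac = cell_fractions.data.loc[sheet.sample_ids]
        for ct in frac.columns[1:]:
            X[f"frac_{ct}"] = frac[ct].to_numpy()
    return X


def model_burden(
    profile: SEMProfile,
    sheet: SampleSheet,
    cell_fractions=None,
    outlier_sd: float = 3.0,
) -> dict[str, BurdenModelResult]:
    """Covariate-adjusted burden regression for total/hypo/hyper burdens.

    Burden is log10(n + 1)-transformed; samples outside mean +/- 3 SD of
    the transformed burden (computed over all samples) are excluded,
    then OLS: log-burden ~ group + age + sex + cell fractions.
    """
    results: dict[str, BurdenModelResult] = {}
    X_all = _burden_design(sheet, cell_fractions)
    for kind, col in (("total", "n_sem"), ("hypo", "n_hypo"), ("hyper", "n_hyper")):
        y = np.log10(profile.totals.loc[sheet.sample_ids, col].astype(float) + 1.0)
        mu, sd = y.mean(), y.std(ddof=1)
        if sd > 0:
            keep = (y - mu).abs() <= outlier_sd * sd
        else:
            keep = pd.Series(True, index=y.index)
        excluded = list(y.index[~keep])
        if keep.sum() < 10:
            raise ValidationError(
                f"{kind} burden: fewer than 10 samples after outlier exclusion"
            )
        X = sm.add_constant(X_all.loc[keep], has_constant="add")
        fit = sm.OLS(y[keep], X).fit()
        ci = fit.conf_int(alpha=0.05)
        coefs = pd.DataFrame(
            {
                "coef": fit.params,
                "se": fit.bse,
                "t": fit.tvalues,
                "p": fit.pvalues,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
            }
        )
        results[kind] = BurdenModelResult(
            burden_kind=kind,
            excluded_samples=excluded,
            coefficients=coefs,
            n_used=int(keep.sum()),
        )
    return results


def call_epivariations(
    profile: SEMProfile,
    annotation: CpGAnnotation,
    min_run: int = 3,
) -> pd.DataFrame:
    """Gene-level epivariation calls per sample.

    Within each gene, the gene's scored CpGs are put in genomic order; a
    sample carries an epivariation of the gene when >= ``min_run``
    consecutive CpGs are all SEM-called in the same direction.  The
    enrichment p is the binomial upper tail P(X >= k_sem) with n = CpGs
    in the gene and success rate = that sample's genome-wide SEM rate.

    Returns a table with columns gene, sample_id, direction,
    n_sem_cpgs_in_gene, n_cpgs_in_gene, enrichment_p.
    """
    ann = annotation.data
    if ann["pos"].isna().any():
        raise ValidationError("annotation missing positions")
    universe = [p for p in profile.probe_ids if p in ann.index]
    n_universe = len(universe)
    # gene -> probes in genomic order
    gene_probes: dict[str, list[tuple[str, int]]] = {}
    sub = ann.loc[universe]
    for pid, row in sub.iterrows():
        for g in row["genes"]:
            gene_probes.setdefault(g, []).append((pid, int(row["pos"])))
    for g in gene_probes:
        gene_probes[g].sort(key=lambda t: t[1])

    # sample -> probe -> direction
    calls_by_sample: dict[str, dict[str, str]] = {}
    for _, r in profile.calls.iterrows():
        calls_by_sample.setdefault(r["sample_id"], {})[r["probe_id"]] = r["direction"]

    rows = []
    for sample, probe_dir in calls_by_sample.items():
        n_sem_total = int(profile.totals.loc[sample, "n_sem"])
        rate = n_sem_total / n_universe if n_universe else 0.0
        for gene, plist in gene_probes.items():
            dirs = [probe_dir.get(pid) for pid, _ in plist]
            best = _longest_same_direction_run(dirs)
            if best is None or best[1] < min_run:
                continue
            direction = best[0]
            k_sem = sum(1 for d in dirs if d is not None)
            n_gene = len(plist)
            p_enr = float(stats.binom.sf(k_sem - 1, n_gene, rate)) if rate > 0 else 0.0
            rows.append(
                dict(gene=gene, sample_id=sample, direction=direction,
                     n_sem_cpgs_in_gene=k_sem, n_cpgs_in_gene=n_gene,
                     enrichment_p=p_enr)
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "sample_id", "direction", "n_sem_cpgs_in_gene",
                 "n_cpgs_in_gene", "enrichment_p"],
    )


def _longest_same_direction_run(dirs: list[str | None]) -> tuple[str, int] | None:
    """(direction, length) of the longest run of identical non-None calls."""
    best: tuple[str, int] | None = None
    cur_dir, cur_len = None, 0
    for d in dirs:
        if d is not None and d == cur_dir:
            cur_len += 1
        else:
            cur_dir, cur_len = d, 1 if d is not None else 0
        if cur_dir is not None and (best is None or cur_len > best[1]):
            best = (cur_dir, cur_len)
    return best


def group_specific_epivariations(
    calls: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """Per-gene carrier counts and group exclusivity of epivariations.

    Exclusivity is ``case-only`` / ``control-only`` / ``shared``; the
    direction summary is ``all hypomethylated`` / ``all hypermethylated``
    / ``mixed``.
    """
    ctrl_g, case_g = sheet.groups
    group_of = sheet.data["group"]
    rows = []
    if calls.empty:
        return pd.DataFrame(
            columns=["gene", "n_case", "n_control", "exclusivity", "direction_summary"]
        ).set_index("gene")
    for gene, sub in calls.groupby("gene"):
        grp = group_of.loc[sub["sample_id"]].to_numpy()
        n_case = int((grp == case_g).sum())
        n_control = int((grp == ctrl_g).sum())
        if n_case and not n_control:
            excl = "case-only"
        elif n_control and not n_case:
            excl = "control-only"
        else:
            excl = "shared"
        dirs = set(sub["direction"])
        if dirs == {"hypo"}:
            dsum = "all hypomethylated"
        elif dirs == {"hyper"}:
            dsum = "all hypermethylated"
        else:
            dsum = "mixed"
        rows.append(
            dict(gene=gene, n_case=n_case, n_control=n_control,
                 exclusivity=excl, direction_summary=dsum)
        )
    return pd.DataFrame(rows).set_index("gene")
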