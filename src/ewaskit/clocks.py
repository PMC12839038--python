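"""Coefficient-driven epigenetic clocks and age-acceleration testing.

A clock is a linear predictor over CpG betas — ``score = intercept +
sum_j w_j * beta_j`` — optionally passed through the piecewise
log-linear age transform used by pan-tissue clocks calibrated on
children and adults:

    age = (1 + a) * exp(y) - 1      for y < 0
    age = (1 + a) * y + a           for y >= 0

with ``a`` the adult-age knot (default 20 years).

Age acceleration is anchored on the control group: an OLS regression of
predicted on chronological age is fitted within controls only, then
applied to the whole cohort; a sample's acceleration is its residual
from that control-calibrated line.  Group differences in residuals are
tested per clock (two-sided Welch t) with Benjamini-Hochberg correction
across clocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, SampleSheet, ValidationError
from .stats import bh_adjust

__all__ = [
    "ClockModel",
    "AccelerationResult",
    "apply_clock",
    "fit_acceleration",
    "compare_acceleration_multi",
    "horvath_age_transform",
    "horvath_age_inverse",
    "read_clock",
    "write_clock",
]


@dataclass
class ClockModel:
    name: str
    intercept: float
    weights: dict[str, float]  # probe id -> coefficient
    output_transform: str = "identity"  # or "horvath_age"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("clock weight map is empty")
        if self.output_transform not in ("identity", "horvath_age"):
            raise ValidationError(
                f"unknown output transform {self.output_transform!r}"
            )
        if self.output_transform == "horvath_age" and self.adult_age <= 0:
            raise ValidationError("adult_age must be positive")


def horvath_age_transform(y, adult_age: float = 20.0):
    """Map the linear clock score to years (piecewise log-linear)."""
    y = np.asarray(y, dtype=float)
    a = adult_age
    return np.where(y < 0, (1 + a) * np.exp(y) - 1, (1 + a) * y + a)


def horvath_age_inverse(age, adult_age: float = 20.0):
    """Inverse of :func:`horvath_age_transform` on both branches."""
    age = np.asarray(age, dtype=float)
    a = adult_age
    return np.where(age < a, np.log((age + 1) / (1 + a)), (age - a) / (1 + a))


def apply_clock(
    betas: BetaMatrix,
    clock: ClockModel,
    missing_policy: str = "mean",
    min_probe_frac: float = 0.5,
) -> pd.Series:
    """Predicted age per sample from a coefficient-driven clock.

    Clock probes absent from the matrix (or missing in a sample) are
    imputed by the cohort mean beta of that probe when ``missing_policy``
    is ``"mean"``; policy ``"error"`` refuses any absence.  Fewer than
    ``min_probe_frac`` of the clock's probes present is always an error.
    """
    probes = [p for p in clock.weights if p in set(betas.probe_ids)]
    n_missing = len(clock.weights) - len(probes)
    if len(probes) < min_probe_frac * len(clock.weights):
        raise ValidationError(
            f"clock {clock.name!r}: {n_missing} of {len(clock.weights)} "
            f"probes absent (need >= {min_probe_frac:.0%} present)"
        )
    if missing_policy == "error" and n_missing:
        raise ValidationError(
            f"clock {clock.name!r}: {n_missing} probes absent"
        )
    if missing_policy not in ("error", "mean"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")

    sub = betas.data.loc[probes]
    # impute per-probe cohort mean for missing cells
    filled = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    if filled.isna().any().any():
        raise ValidationError("clock probe missing in every sample")
    w = np.array([clock.weights[p] for p in probes])
    score = clock.intercept + filled.to_numpy(dtype=float).T @ w
    if clock.output_transform == "horvath_age":
        score = horvath_age_transform(score, clock.adult_age)
    return pd.Series(score, index=betas.sample_ids, name=clock.name)


@dataclass
class AccelerationResult:
    clock: str
    slope: float  # control regression predicted ~ age
    intercept: float
    predicted: pd.Series  # per-sample predicted age (years)
    residuals: pd.Series  # per-sample control-anchored acceleration
    mean_diff: float  # case - control mean residual
    ci_lo: float
    ci_hi: float
    t: float
    p: float
    q: float = field(default=np.nan)


def fit_acceleration(predicted: pd.Series, sheet: SampleSheet) -> AccelerationResult:
    """Control-anchored age acceleration for one clock.

    OLS of predicted on chronological age in controls only; residuals
    for every sample against that line; Welch t-test of case vs control
    residuals.  Control residuals average zero by the least-squares
    property.
    """
    pred = predicted.loc[sheet.sample_ids]
    age = sheet.data["age"].astype(float)
    ctrl_g, case_g = sheet.groups
    cmask = sheet.group_mask(ctrl_g)
    if cmask.sum() < 3:
        raise ValidationError("need >= 3 controls with age")
    age_c = age.to_numpy()[cmask]
    if np.var(age_c) == 0:
        raise ValidationError("zero age variance among controls")
    slope, intercept = np.polyfit(age_c, pred.to_numpy()[cmask], 1)
    resid = pred - (intercept + slope * age)
    r_case = resid.to_numpy()[sheet.group_mask(case_g)]
    r_ctrl = resid.to_numpy()[cmask]
    t_res = stats.ttest_ind(r_case, r_ctrl, equal_var=False)
    se = np.sqrt(r_case.var(ddof=1) / len(r_case) + r_ctrl.var(ddof=1) / len(r_ctrl))
    df = t_res.df
    half = stats.t.ppf(0.975, df) * se if se > 0 else 0.0
    diff = float(r_case.mean() - r_ctrl.mean())
    return AccelerationResult(
        clock=str(predicted.name),
        slope=float(slope),
        intercept=float(intercept),
        predicted=pred,
        residuals=resid,
        mean_diff=diff,
        ci_lo=diff - half,
        ci_hi=diff + half,
        t=float(t_res.statistic),
        p=float(t_res.pvalue),
    )


def compare_acceleration_multi(results: list[AccelerationResult]) -> pd.DataFrame:
    """BH correction across clocks; returns the per-clock summary table."""
    if not results:
        raise ValidationError("no clock results")
    q = bh_adjust(np.array([r.p for r in results]))
    rows = []
    for r, qi in zip(results, q):
        r.q = float(qi)
        rows.append(
            dict(clock=r.clock, slope=r.slope, intercept=r.intercept,
                 mean_diff=r.mean_diff, ci_lo=r.ci_lo, ci_hi=r.ci_hi,
                 t=r.t, p=r.p, q=r.q)
        )
    return pd.DataFrame(rows).set_index("clock")


def read_clock(path) -> ClockModel:
    """Clock coefficient CSV: '#key=value' metadata lines (name,
    intercept, transform, adult_age) then probe_id,weight rows."""
    meta: dict[str, str] = {}
    weights: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            elif not line.startswith("probe_id"):
                pid, _, w = line.partition(",")
                weights[pid.strip()] = float(w)
    return ClockModel(
        name=meta.get("name", "clock"),
        intercept=float(meta.get("intercept", 0.0)),
        weights=weights,
        output_transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


def write_clock(clock: ClockModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={clock.name}\n")
        fh.write(f"#intercept={clock.intercept!r}\n")
        fh.write(f"#transform={clock.output_transform}\n")
        fh.write(f"#adult_age={clock.adult_age!r}\n")
        fh.write("probe_id,weight\n")
        for pid, w in clock.weights.items():
            fh.write(f"{pid},{w!r}\n")
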