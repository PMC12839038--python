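"""Differentially methylated position (DMP) analysis.

Per-probe linear models with empirical-Bayes variance moderation, an
empirical-null correction of the resulting z-scores, genomic-inflation
diagnostics, BH-FDR and two-tier effect-size filtering.

The stages are:

1.  Per-probe OLS of beta on a design (group + covariates); the group
    contrast, its unscaled standard error and the residual variance are
    extracted.
2.  Variance moderation by the classical empirical-Bayes shrinkage
    scheme: the residual variances are modeled as scaled-inverse-chi^2
    draws around a prior variance s0^2 with prior df d0, estimated by
    moment matching on log s^2 (digamma/trigamma equations); posterior
    variances s~^2 = (d0*s0^2 + df*s^2)/(d0 + df) give moderated t.
3.  Empirical-null correction: a three-component Gaussian mixture is
    fitted to the z-scores by Gibbs sampling; the dominant (largest
    weight) component is the null, whose posterior-mean location (bias)
    and scale (inflation) re-standardize every z.
4.  Genomic inflation factor lambda = median(z^2) / median(chi^2_1) as
    a calibration diagnostic, before and after correction.
5.  BH-FDR and tier assignment: a probe is a stringent DMP when
    q < 0.001 and |delta-beta| > 0.1, a relaxed DMP when q < 0.05 and
    |delta-beta| > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import BetaMatrix, SampleSheet, ValidationError
from .stats import bh_adjust

__all__ = [
    "ProbeModelFit",
    "ModerationFit",
    "EmpiricalNullFit",
    "fit_probe_models",
    "moderate_variances",
    "empirical_null_adjust",
    "genomic_inflation",
    "bh_adjust",
    "call_dmps",
    "build_design",
    "run_dmp",
    "CHI2_1_MEDIAN",
]

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = 0.4549364231195724


@dataclass
class ProbeModelFit:
    """Per-probe OLS results for the group contrast."""

    coef: pd.Series  # group coefficient, modeled scale
    se: pd.Series  # ordinary standard error
    unscaled_se: pd.Series  # sqrt([(X'X)^-1]_gg), per-probe
    s2: pd.Series  # residual variance
    df: pd.Series  # residual degrees of freedom


@dataclass
class ModerationFit:
    d0: float  # prior degrees of freedom (may be inf)
    s0_2: float  # prior variance
    s2_post: pd.Series  # posterior (shrunk) variances
    t: pd.Series  # moderated t statistics
    df_total: pd.Series  # residual df + d0
    p: pd.Series  # two-sided p from moderated t
    no_shrinkage: bool = False  # all s2 identical -> d0 = inf convention


@dataclass
class EmpiricalNullFit:
    bias: float  # null-component location
    inflation: float  # null-component scale
    weights: np.ndarray  # posterior-mean component weights
    means: np.ndarray
    sds: np.ndarray
    z_adjusted: pd.Series
    p_adjusted: pd.Series
    lambda_before: float
    lambda_after: float
    seed: int | None = None


def build_design(
    sheet: SampleSheet,
    cell_fractions=None,
    include_age: bool = True,
    include_sex: bool = True,
) -> pd.DataFrame:
    """Default design: intercept + group + age + sex + cell fractions
    (first cell type dropped for identifiability)."""
    X = pd.DataFrame(index=sheet.sample_ids)
    X["intercept"] = 1.0
    X["group"] = sheet.case_mask().astype(float)
    if include_age:
        X["age"] = sheet.data["age"].astype(float)
    if include_sex:
        X["sex"] = (sheet.data["sex"] == "M").astype(float)
    if cell_fractions is not None:
        frac = cell_fractions.data.loc[sheet.sample_ids]
        for ct in frac.columns[1:]:
            X[f"frac_{ct}"] = frac[ct].to_numpy()
    return X


def fit_probe_models(
    Y: BetaMatrix,
    design: pd.DataFrame,
    contrast: str = "group",
) -> ProbeModelFit:
    """Per-probe OLS of the response on the design matrix.

    Probes with missing values are fitted on their complete rows
    (pairwise-complete); a probe needs at least rank + 2 observations.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = design.loc[Y.sample_ids].to_numpy(dtype=float)
    cols = list(design.columns)
    if contrast not in cols:
        raise ValidationError(f"contrast column {contrast!r} not in design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of offending columns by greedy scan
        bad = []
        seen: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, seen + [j]]
            if np.linalg.matrix_rank(trial) == len(seen):
                bad.append(cols[j])
            else:
                seen.append(j)
        raise ValidationError(f"design is rank deficient; collinear columns: {bad}")
    g = cols.index(contrast)
    n, p = X.shape
    B = Y.values  # probes x samples
    has_missing = np.isnan(B).any(axis=1)

    coef = np.full(B.shape[0], np.nan)
    se = np.full(B.shape[0], np.nan)
    use = np.full(B.shape[0], np.nan)
    s2 = np.full(B.shape[0], np.nan)
    dfree = np.full(B.shape[0], np.nan)

    # complete-case probes: one shared projection
    comp = ~has_missing
    if comp.any():
        XtX_inv = np.linalg.inv(X.T @ X)
        H = X @ XtX_inv  # n x p
        Bc = B[comp]
        coefs_all = Bc @ H  # probes x p
        resid = Bc - coefs_all @ X.T
        rss = (resid**2).sum(axis=1)
        df_c = n - p
        s2_c = rss / df_c
        u = np.sqrt(XtX_inv[g, g])
        coef[comp] = coefs_all[:, g]
        s2[comp] = s2_c
        dfree[comp] = df_c
        use[comp] = u
        se[comp] = np.sqrt(s2_c) * u

    if has_missing.any():
        for i in np.nonzero(has_missing)[0]:
            y = B[i]
            ok = ~np.isnan(y)
            if ok.sum() < p + 2:
                continue  # left NaN: too few observations
            Xi = X[ok]
            if np.linalg.matrix_rank(Xi) < p:
                continue
            XtX_inv = np.linalg.inv(Xi.T @ Xi)
            b = XtX_inv @ (Xi.T @ y[ok])
            r = y[ok] - Xi @ b
            df_i = ok.sum() - p
            s2_i = float(r @ r) / df_i
            coef[i] = b[g]
            s2[i] = s2_i
            dfree[i] = df_i
            use[i] = np.sqrt(XtX_inv[g, g])
            se[i] = np.sqrt(s2_i) * use[i]

    idx = Y.probe_ids
    return ProbeModelFit(
        coef=pd.Series(coef, index=idx),
        se=pd.Series(se, index=idx),
        unscaled_se=pd.Series(use, index=idx),
        s2=pd.Series(s2, index=idx),
        df=pd.Series(dfree, index=idx),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(fits: ProbeModelFit) -> ModerationFit:
    """Empirical-Bayes shrinkage of residual variances.

    Moment matching on e = log(s^2): under the scaled-inverse-chi^2
    model, e - digamma(df/2) + log(df/2) has mean log(s0^2) +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2) above
    trigamma(df/2); d0 follows by inverting the trigamma function.
    """
    ok = fits.s2.notna() & (fits.s2 > 0)
    s2 = fits.s2[ok].to_numpy()
    df = fits.df[ok].to_numpy()
    if s2.size < 10:
        raise ValidationError("need >= 10 probes with positive variance")
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    e_bar = e.mean()
    ev = (e - e_bar) @ (e - e_bar) / (e.size - 1)
    excess = ev - special.polygamma(1, df / 2).mean()
    no_shrinkage = False
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_bar))
        no_shrinkage = bool(np.allclose(s2, s2[0]))
    else:
        d0 = 2 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2) - np.log(d0 / 2)))

    s2_all = fits.s2.to_numpy()
    df_all = fits.df.to_numpy()
    if no_shrinkage:
        # degenerate case: all sample variances identical
        s2_post = s2_all.copy()
        df_total = df_all.copy()
    elif np.isinf(d0):
        s2_post = np.full_like(s2_all, s0_2)
        s2_post[np.isnan(s2_all)] = np.nan
        df_total = np.full_like(df_all, np.inf)
        df_total[np.isnan(df_all)] = np.nan
    else:
        s2_post = (d0 * s0_2 + df_all * s2_all) / (d0 + df_all)
        df_total = df_all + d0
    t = fits.coef.to_numpy() / (fits.unscaled_se.to_numpy() * np.sqrt(s2_post))
    p = 2 * stats.t.sf(np.abs(t), df_total)
    idx = fits.s2.index
    return ModerationFit(
        d0=float(d0),
        s0_2=s0_2,
        s2_post=pd.Series(s2_post, index=idx),
        t=pd.Series(t, index=idx),
        df_total=pd.Series(df_total, index=idx),
        p=pd.Series(p, index=idx),
        no_shrinkage=no_shrinkage,
    )


def genomic_inflation(z) -> float:
    """Genomic inflation factor lambda = median(z^2) / median(chi^2_1)."""
    z = np.asarray(z, dtype=float)
    z = z[~np.isnan(z)]
    if z.size < 100:
        raise ValidationError("need >= 100 z-scores for lambda")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def _gibbs_mixture(
    z: np.ndarray,
    rng: np.random.Generator,
    n_iter: int,
    burn_in: int,
) -> tuple[float, float, np.ndarray, np.ndarray, np.ndarray]:
    """Three-component Gaussian-mixture Gibbs sampler.

    The null is identified per retained iteration as the component with
    the largest weight; its location/scale posterior means are the bias
    and inflation estimates.  Priors are weakly informative and
    data-centred (so the fit is equivariant under shifts of z): the
    candidate null is centred at the median, the two signal components
    at median -/+ 3 robust SDs.
    """
    n = z.size
    med = np.median(z)
    mad_sd = 1.4826 * np.median(np.abs(z - med))
    if mad_sd == 0:
        mad_sd = max(z.std(), 1e-3)
    mu0 = np.array([med, med - 3 * mad_sd, med + 3 * mad_sd])
    tau2 = np.full(3, (5 * mad_sd) ** 2)  # prior variance on locations
    a0, b0 = 2.0, mad_sd**2  # inverse-gamma prior on variances
    alpha = np.ones(3)  # Dirichlet prior on weights

    mu = mu0.copy()
    sig2 = np.full(3, mad_sd**2)
    pi = np.array([0.9, 0.05, 0.05])

    keep = n_iter - burn_in
    sum_bias = 0.0
    sum_infl = 0.0
    sum_pi = np.zeros(3)
    sum_mu = np.zeros(3)
    sum_sd = np.zeros(3)

    u = np.empty(n)
    for it in range(n_iter):
        # responsibilities (log-space for stability)
        logp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * np.pi * sig2)[None, :]
            - (z[:, None] - mu[None, :]) ** 2 / (2 * sig2)[None, :]
        )
        logp -= logp.max(axis=1, keepdims=True)
        w = np.exp(logp)
        w /= w.sum(axis=1, keepdims=True)
        # sample assignments
        rng.random(out=u)
        c0 = w[:, 0]
        c1 = c0 + w[:, 1]
        assign = (u > c0).astype(np.int8) + (u > c1).astype(np.int8)

        nk = np.bincount(assign, minlength=3).astype(float)
        sz = np.bincount(assign, weights=z, minlength=3)
        szz = np.bincount(assign, weights=z * z, minlength=3)
        pi = rng.dirichlet(alpha + nk)
        # location given scale (conjugate normal)
        post_var = 1.0 / (nk / sig2 + 1.0 / tau2)
        post_mean = post_var * (sz / sig2 + mu0 / tau2)
        mu = rng.normal(post_mean, np.sqrt(post_var))
        # scale given location (conjugate inverse-gamma)
        ss = szz - 2 * mu * sz + nk * mu**2
        sig2 = 1.0 / rng.gamma(a0 + nk / 2.0, 1.0 / (b0 + np.clip(ss, 0, None) / 2.0))
        if it >= burn_in:
            null_k = int(np.argmax(pi))
            sum_bias += mu[null_k]
            sum_infl += np.sqrt(sig2[null_k])
            sum_pi += pi
            sum_mu += mu
            sum_sd += np.sqrt(sig2)

    return (
        sum_bias / keep,
        sum_infl / keep,
        sum_pi / keep,
        sum_mu / keep,
        sum_sd / keep,
    )


def empirical_null_adjust(
    z: pd.Series | np.ndarray,
    seed: int | None = 0,
    n_iter: int = 5000,
    burn_in: int = 2000,
) -> EmpiricalNullFit:
    """Estimate and remove bias/inflation of test statistics.

    Fits a three-component Gaussian mixture to the z-scores by Gibbs
    sampling; the dominant component is the empirical null, with
    posterior-mean location ``bias`` and scale ``inflation``.  Adjusted
    z = (z - bias) / inflation, two-sided p from the standard normal.
    """
    if burn_in >= n_iter:
        raise ValidationError("burn_in must be smaller than n_iter")
    idx = z.index if isinstance(z, pd.Series) else None
    zv = np.asarray(z, dtype=float)
    if not np.isfinite(zv).all():
        raise ValidationError("non-finite z-scores present")
    rng = np.random.default_rng(seed)
    bias, infl, pi, mu, sd = _gibbs_mixture(zv, rng, n_iter, burn_in)
    z_adj = (zv - bias) / infl
    p_adj = 2 * stats.norm.sf(np.abs(z_adj))
    return EmpiricalNullFit(
        bias=float(bias),
        inflation=float(infl),
        weights=pi,
        means=mu,
        sds=sd,
        z_adjusted=pd.Series(z_adj, index=idx),
        p_adjusted=pd.Series(p_adj, index=idx),
        lambda_before=genomic_inflation(zv),
        lambda_after=genomic_inflation(z_adj),
        seed=seed,
    )


def delta_beta(betas: BetaMatrix, sheet: SampleSheet) -> pd.Series:
    """Per-probe group mean difference of beta (case - control),
    pairwise-complete."""
    B = betas.data.loc[:, sheet.sample_ids].to_numpy(dtype=float)
    case = sheet.case_mask()
    with np.errstate(all="ignore"):
        db = np.nanmean(B[:, case], axis=1) - np.nanmean(B[:, ~case], axis=1)
    return pd.Series(db, index=betas.probe_ids, name="delta_beta")


def call_dmps(
    q: pd.Series,
    dbeta: pd.Series,
    stringent: tuple[float, float] = (0.001, 0.1),
    relaxed: tuple[float, float] = (0.05, 0.05),
) -> pd.Series:
    """Tier labels per probe: the highest tier whose q and |delta-beta|
    thresholds are both met, else 'none'."""
    q_s, d_s = stringent
    q_r, d_r = relaxed
    ad = dbeta.abs()
    tier = pd.Series("none", index=q.index, dtype=object)
    tier[(q < q_r) & (ad > d_r)] = "relaxed"
    tier[(q < q_s) & (ad > d_s)] = "stringent"
    tier[q.isna() | dbeta.isna()] = "none"
    return tier


def run_dmp(
    betas: BetaMatrix,
    sheet: SampleSheet,
    cell_fractions=None,
    include_age: bool = True,
    include_sex: bool = True,
    seed: int | None = 0,
    n_iter: int = 5000,
    burn_in: int = 2000,
    empirical_null: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full DMP stage: fits, moderation, empirical-null, FDR, tiers.

    Returns the per-probe table (delta_beta, t, z, p, q, tier) and a
    diagnostics dict (lambda before/after, bias, inflation, d0, s0^2).
    """
    design = build_design(sheet, cell_fractions, include_age, include_sex)
    fits = fit_probe_models(betas, design)
    mod = moderate_variances(fits)
    ok = mod.t.notna()
    # moderated t -> z through matched tail probabilities
    t_ok = mod.t[ok]
    df_ok = mod.df_total[ok]
    with np.errstate(all="ignore"):
        tail = stats.t.sf(np.abs(t_ok.to_numpy()), df_ok.to_numpy())
        tail = np.clip(tail, 1e-300, 0.5)
        z = np.sign(t_ok.to_numpy()) * stats.norm.isf(tail)
    z = pd.Series(z, index=t_ok.index)
    diagnostics: dict = {"d0": mod.d0, "s0_2": mod.s0_2}
    if empirical_null:
        nf = empirical_null_adjust(z, seed=seed, n_iter=n_iter, burn_in=burn_in)
        p_final = nf.p_adjusted
        z_final = nf.z_adjusted
        diagnostics.update(
            bias=nf.bias,
            inflation=nf.inflation,
            lambda_before=nf.lambda_before,
            lambda_after=nf.lambda_after,
        )
    else:
        z_final = z
        p_final = pd.Series(2 * stats.norm.sf(np.abs(z.to_numpy())), index=z.index)
        diagnostics.update(lambda_before=genomic_inflation(z), lambda_after=None)
    q = pd.Series(bh_adjust(p_final.to_numpy()), index=p_final.index)
    db = delta_beta(betas, sheet)
    table = pd.DataFrame(
        {
            "delta_beta": db,
            "coef": fits.coef,
            "t": mod.t,
            "z": z_final.reindex(betas.probe_ids),
            "p": p_final.reindex(betas.probe_ids),
            "q": q.reindex(betas.probe_ids),
        },
        index=betas.probe_ids,
    )
    table["tier"] = call_dmps(table["q"], table["delta_beta"])
    return table, diagnostics
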