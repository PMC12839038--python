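"""Synthetic case-control methylation cohorts with ground truth.

The generator emulates the statistical structure of a blood EWAS
cohort: two groups of ~20 subjects aged 60-87 with balanced sex; probe
baseline means drawn from a three-component beta mixture (modes near
0.1, 0.5 and 0.9, weights 0.45/0.10/0.45 — the familiar bimodal
marginal density of array betas); Gaussian within-probe noise on the
beta scale, clipped to [0, 1]; convex cell-type mixtures over a
purified reference panel; probes with a linear age trend driving a
synthetic clock; injected single-probe group shifts (DMPs), clustered
correlated shifts (DMRs), rare per-subject outliers (epimutations) and
bimodal genotype-like probes; missing values; and detection p-values
with a controllable failure rate.

Everything injected is recorded in a :class:`TruthSet` so recovery can
be tested downstream.  The same seed always reproduces the same bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clocks import ClockModel
from .deconvolution import BLOOD12, ReferenceProfiles
from .io import (
    BetaMatrix,
    CpGAnnotation,
    DetectionPMatrix,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "SyntheticCohort",
    "generate_cohort",
    "inject_group_shift",
    "inject_epimutations",
    "simulate_cell_mixture",
    "simulate_reference_profiles",
]

N_CHROMS = 22


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the target study design: 20 cases / 20 controls,
    ages 60-87, twelve blood cell types, beta-scale noise SD 0.03.
    """

    n_probes: int = 50_000
    n_per_group: tuple[int, int] = (20, 20)
    age_range: tuple[float, float] = (60.0, 87.0)
    dirichlet_alpha: tuple[float, ...] = (
        40.0, 2.0, 0.5, 6.0, 1.5, 1.5, 6.0, 6.0, 2.5, 2.5, 4.0, 1.5,
    )  # loosely blood-like: neutrophil-dominated
    n_dmp: int = 200
    dmp_delta: float = 0.10
    n_dmr: int = 5
    dmr_size: int = 5
    dmr_delta: float = 0.15
    dmr_spacing_bp: int = 50
    epimutation_rate: float = 5.0  # expected outlier probes per subject
    epimutation_shift: float = 0.4
    n_bimodal: int = 50
    n_deconv_probes: int = 600
    n_clock_probes: int = 200
    missing_rate: float = 0.002
    detection_fail_rate: float = 0.002
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_probes, self.n_dmp, self.n_dmr, self.dmr_size,
            self.n_bimodal, self.n_deconv_probes, self.n_clock_probes,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("counts must be >= 0")
        if not 0 < self.dmp_delta < 1 or not 0 < self.epimutation_shift < 1:
            raise ValidationError("dmp_delta and epimutation_shift must be in (0,1)")
        for rate in (self.missing_rate, self.detection_fail_rate):
            if not 0 <= rate <= 1:
                raise ValidationError("rates must be in [0, 1]")
        reserved = (
            self.n_dmr * self.dmr_size + self.n_dmp + self.n_bimodal
            + self.n_deconv_probes + self.n_clock_probes
        )
        if reserved > self.n_probes:
            raise ValidationError(
                f"injected/special probes ({reserved}) exceed n_probes "
                f"({self.n_probes})"
            )


@dataclass
class TruthSet:
    """Ground truth of everything the generator injected."""

    dmp_probes: dict[str, float] = field(default_factory=dict)  # probe -> delta
    dmr_intervals: list[dict] = field(default_factory=list)
    epimutations: list[tuple[str, str, str]] = field(default_factory=list)
    # (probe, sample, direction)
    cell_fractions: pd.DataFrame | None = None  # samples x cell types
    clock_ages: pd.Series | None = None  # chronological ages
    bimodal_probes: list[str] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    """Full generated bundle; iterable as the canonical 5-tuple."""

    betas: BetaMatrix
    detp: DetectionPMatrix
    sheet: SampleSheet
    annotation: CpGAnnotation
    truth: TruthSet
    reference: ReferenceProfiles | None = None
    clock: ClockModel | None = None

    def __iter__(self):
        return iter((self.betas, self.detp, self.sheet, self.annotation, self.truth))


def simulate_reference_profiles(
    n_probes: int = 600,
    cell_types: tuple[str, ...] = BLOOD12,
    seed: int = 0,
    probe_ids: list[str] | None = None,
) -> ReferenceProfiles:
    """Purified cell-type profiles over deconvolution-informative probes.

    Values are drawn from a U-shaped beta distribution so most probes
    discriminate strongly between cell types, as selected reference
    libraries do.
    """
    rng = np.random.default_rng(seed)
    vals = rng.beta(0.3, 0.3, size=(n_probes, len(cell_types)))
    if probe_ids is None:
        probe_ids = [f"ref{i:05d}" for i in range(n_probes)]
    return ReferenceProfiles(
        pd.DataFrame(vals, index=probe_ids, columns=list(cell_types))
    )


def simulate_cell_mixture(
    reference: ReferenceProfiles,
    alpha: tuple[float, ...] | np.ndarray,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Convex mixtures of the reference columns plus beta-scale noise.

    Fractions are Dirichlet(alpha) per sample; betas = R @ w + noise,
    clipped to [0, 1].  Returns the beta matrix and the true fractions.
    """
    alpha = np.asarray(alpha, dtype=float)
    k = reference.data.shape[1]
    if alpha.size != k:
        raise ValidationError(
            f"alpha has {alpha.size} entries for {k} cell types"
        )
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(alpha, size=n_samples)  # samples x cell types
    R = reference.data.to_numpy(dtype=float)
    B = R @ W.T
    if noise_sd > 0:
        B = B + rng.normal(0.0, noise_sd, size=B.shape)
    B = np.clip(B, 0.0, 1.0)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    betas = BetaMatrix(
        pd.DataFrame(B, index=reference.probe_ids, columns=samples)
    )
    fractions = pd.DataFrame(W, index=samples, columns=reference.cell_types)
    return betas, fractions


def inject_group_shift(
    betas: BetaMatrix,
    probes: list[str],
    group_mask: np.ndarray,
    delta: float,
) -> BetaMatrix:
    """Shift the case-group betas at the listed probes by +delta, clipped.

    delta = 0 is the identity; unknown probes raise.
    """
    if not 0 <= delta < 1:
        raise ValidationError("delta must be in [0, 1)")
    unknown = [p for p in probes if p not in betas.data.index]
    if unknown:
        raise ValidationError(f"unknown probes: {unknown[:5]}")
    if delta == 0 or not probes:
        return betas
    data = betas.data.copy()
    arr = data.loc[probes].to_numpy(dtype=float)
    arr[:, np.asarray(group_mask, dtype=bool)] += delta
    data.loc[probes] = np.clip(arr, 0.0, 1.0)
    return BetaMatrix(data)


def inject_epimutations(
    betas: BetaMatrix,
    rate: float,
    shift: float,
    seed: int = 0,
    eligible_probes: list[str] | None = None,
) -> tuple[BetaMatrix, list[tuple[str, str, str]]]:
    """Displace Poisson(rate) random probes per subject by +/- shift.

    The direction is chosen away from the nearer boundary (a probe with
    mean beta above 0.5 is shifted down) so the displaced value is not
    lost to clipping; each (probe, sample, direction) is recorded.
    """
    rng = np.random.default_rng(seed)
    data = betas.data.copy()
    probes = eligible_probes if eligible_probes is not None else list(data.index)
    if not probes:
        return betas, []
    probe_means = data.loc[probes].mean(axis=1)
    coords: list[tuple[str, str, str]] = []
    arr = data.to_numpy(dtype=float)
    row_of = {p: i for i, p in enumerate(data.index)}
    col_of = {s: j for j, s in enumerate(data.columns)}
    for sample in data.columns:
        k = rng.poisson(rate)
        if k == 0:
            continue
        k = min(k, len(probes))
        chosen = rng.choice(len(probes), size=k, replace=False)
        for ci in chosen:
            probe = probes[ci]
            direction = "hypo" if probe_means.iloc[ci] > 0.5 else "hyper"
            sgn = -1.0 if direction == "hypo" else 1.0
            i, j = row_of[probe], col_of[sample]
            arr[i, j] = np.clip(arr[i, j] + sgn * shift, 0.0, 1.0)
            coords.append((probe, sample, direction))
    out = pd.DataFrame(arr, index=data.index, columns=data.columns)
    return BetaMatrix(out), coords


def _probe_layout(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Assign probes to chromosomes/positions/genes and reserve the
    special probe classes (DMR clusters, DMPs, bimodal, deconvolution,
    clock)."""
    n = cfg.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]

    # blocks: DMR clusters first, then singletons
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    roles = np.array(["background"] * n, dtype=object)

    dmr_members: list[list[int]] = []
    idx = 0
    blocks: list[list[int]] = []
    for _ in range(cfg.n_dmr):
        members = list(range(idx, idx + cfg.dmr_size))
        dmr_members.append(members)
        blocks.append(members)
        idx += cfg.dmr_size
    singles = list(range(idx, n))
    blocks.extend([[i] for i in singles])
    # scatter cluster blocks among the singletons
    perm = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in perm]

    # scatter blocks across chromosomes; inter-block gaps far exceed the
    # smoothing window so blocks are spatially independent
    per_chrom = int(np.ceil(len(blocks) / N_CHROMS))
    b = 0
    for c in range(N_CHROMS):
        cursor = 10_000
        for _ in range(per_chrom):
            if b >= len(blocks):
                break
            block = blocks[b]
            for j, pi in enumerate(block):
                chrom[pi] = f"chr{c + 1}"
                pos[pi] = cursor + j * cfg.dmr_spacing_bp
            cursor = int(pos[block[-1]]) + int(rng.integers(2_000, 20_000))
            b += 1

    # roles for the reserved classes (all among singleton probes)
    cursorlist = singles.copy()
    rng.shuffle(cursorlist)
    take = 0

    def grab(count: int) -> list[int]:
        nonlocal take
        sel = cursorlist[take : take + count]
        take += count
        return sel

    deconv_idx = grab(cfg.n_deconv_probes)
    clock_idx = grab(cfg.n_clock_probes)
    bimodal_idx = grab(cfg.n_bimodal)
    dmp_idx = grab(cfg.n_dmp)
    roles[deconv_idx] = "deconv"
    roles[clock_idx] = "clock"
    roles[bimodal_idx] = "bimodal"
    roles[dmp_idx] = "dmp"
    for members in dmr_members:
        roles[members] = "dmr"

    # genes: consecutive probes (genomic order) grouped ~8 per gene,
    # with occasional intergenic probes
    order = np.lexsort((pos, chrom))
    genes = np.empty(n, dtype=object)
    gene_no = 0
    i = 0
    while i < len(order):
        size = int(rng.integers(4, 13))
        members = order[i : i + size]
        if rng.random() < 0.15:
            for m in members:
                genes[m] = ()
        else:
            name = f"GENE{gene_no:05d}"
            gene_no += 1
            for m in members:
                genes[m] = (name,)
        i += size

    # blacklist flags on a small fraction of background probes
    flags = {
        "snp_overlap": np.zeros(n, dtype=bool),
        "cross_hybridizing": np.zeros(n, dtype=bool),
        "sex_chromosome": np.zeros(n, dtype=bool),
    }
    bg = np.nonzero(roles == "background")[0]
    for name, frac in (("snp_overlap", 0.01), ("cross_hybridizing", 0.005)):
        sel = rng.choice(bg, size=int(frac * n), replace=False)
        flags[name][sel] = True

    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "genes": genes,
            "role": roles,
            **flags,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    layout = {
        "dmr_members": dmr_members,
        "deconv_idx": deconv_idx,
        "clock_idx": clock_idx,
        "bimodal_idx": bimodal_idx,
        "dmp_idx": dmp_idx,
    }
    return frame, layout


def _baseline_means(n: int, rng: np.random.Generator) -> np.ndarray:
    """Three-component beta mixture with modes ~0.1 / 0.5 / 0.9."""
    comp = rng.choice(3, size=n, p=[0.45, 0.10, 0.45])
    means = np.empty(n)
    means[comp == 0] = rng.beta(3, 20, size=(comp == 0).sum())
    means[comp == 1] = rng.beta(10, 10, size=(comp == 1).sum())
    means[comp == 2] = rng.beta(20, 3, size=(comp == 2).sum())
    return means


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic bundle with ground truth.

    Deterministic under a fixed config (including seed): calling twice
    yields identical matrices, sheets, annotation and truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_ctrl, n_case = cfg.n_per_group
    n_samples = n_ctrl + n_case
    samples = [f"S{i:03d}" for i in range(n_samples)]
    groups = ["control"] * n_ctrl + ["case"] * n_case
    # balanced sex by construction within each group
    sexes = ["M", "F"] * (n_ctrl // 2) + ["M"] * (n_ctrl % 2)
    sexes += ["F", "M"] * (n_case // 2) + ["F"] * (n_case % 2)
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n_samples)
    sheet = SampleSheet(
        pd.DataFrame(
            {"group": groups, "age": np.round(ages, 1), "sex": sexes},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    ages = sheet.data["age"].to_numpy(dtype=float)

    ann_frame, layout = _probe_layout(cfg, rng)
    probe_ids = list(ann_frame.index)
    n = cfg.n_probes

    means = _baseline_means(n, rng)
    B = np.clip(
        means[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n, n_samples)),
        0.0, 1.0,
    )

    truth = TruthSet(clock_ages=pd.Series(ages, index=samples, name="age"))

    # cell-mixture probes
    reference = None
    if cfg.n_deconv_probes:
        didx = np.asarray(layout["deconv_idx"], dtype=int)
        ref_vals = rng.beta(0.3, 0.3, size=(len(didx), len(cfg.dirichlet_alpha)))
        cell_types = list(BLOOD12[: len(cfg.dirichlet_alpha)])
        if len(cell_types) < len(cfg.dirichlet_alpha):
            cell_types += [
                f"CT{i}" for i in range(len(cell_types), len(cfg.dirichlet_alpha))
            ]
        reference = ReferenceProfiles(
            pd.DataFrame(
                ref_vals, index=[probe_ids[i] for i in didx], columns=cell_types
            )
        )
        W = rng.dirichlet(np.asarray(cfg.dirichlet_alpha), size=n_samples)
        B[didx, :] = np.clip(
            ref_vals @ W.T + rng.normal(0.0, cfg.noise_sd, size=(len(didx), n_samples)),
            0.0, 1.0,
        )
        truth.cell_fractions = pd.DataFrame(W, index=samples, columns=cell_types)

    # clock probes: linear age trend; weights invert the trend exactly
    clock = None
    if cfg.n_clock_probes:
        cidx = np.asarray(layout["clock_idx"], dtype=int)
        slopes = rng.uniform(0.002, 0.008, size=len(cidx)) * rng.choice(
            [-1.0, 1.0], size=len(cidx)
        )
        anchors = rng.uniform(0.25, 0.75, size=len(cidx))
        age_mid = float(np.mean(cfg.age_range))
        B[cidx, :] = np.clip(
            anchors[:, None]
            + slopes[:, None] * (ages[None, :] - age_mid)
            + rng.normal(0.0, cfg.noise_sd, size=(len(cidx), n_samples)),
            0.0, 1.0,
        )
        wts = slopes / (slopes @ slopes)
        intercept = age_mid - float(wts @ anchors)
        clock = ClockModel(
            name="synthclock",
            intercept=intercept,
            weights={probe_ids[i]: float(w) for i, w in zip(cidx, wts)},
            output_transform="identity",
        )

    # bimodal probes: two clusters >= 0.5 apart, 50/50 assignment
    if cfg.n_bimodal:
        bidx = np.asarray(layout["bimodal_idx"], dtype=int)
        lo_c = rng.uniform(0.05, 0.30, size=len(bidx))
        hi_c = lo_c + rng.uniform(0.50, 0.65, size=len(bidx))
        assign = rng.random(size=(len(bidx), n_samples)) < 0.5
        centers = np.where(assign, hi_c[:, None], lo_c[:, None])
        B[bidx, :] = np.clip(
            centers + rng.normal(0.0, 0.02, size=centers.shape), 0.0, 1.0
        )
        truth.bimodal_probes = [probe_ids[i] for i in bidx]

    case_mask = np.array([g == "case" for g in groups])

    # DMPs: single-probe group shifts, direction with room before clipping
    dmp_idx = np.asarray(layout["dmp_idx"], dtype=int)
    for i in dmp_idx:
        sgn = -1.0 if means[i] > 0.5 else 1.0
        B[i, case_mask] = np.clip(B[i, case_mask] + sgn * cfg.dmp_delta, 0.0, 1.0)
        truth.dmp_probes[probe_ids[i]] = sgn * cfg.dmp_delta

    # DMRs: clustered shifts, one direction per region
    for members in layout["dmr_members"]:
        sgn = -1.0 if means[members].mean() > 0.5 else 1.0
        for i in members:
            B[i, case_mask] = np.clip(
                B[i, case_mask] + sgn * cfg.dmr_delta, 0.0, 1.0
            )
        truth.dmr_intervals.append(
            dict(
                chrom=str(ann_frame["chrom"].iloc[members[0]]),
                start=int(ann_frame["pos"].iloc[members].min()),
                end=int(ann_frame["pos"].iloc[members].max()),
                probes=[probe_ids[i] for i in members],
                delta=sgn * cfg.dmr_delta,
            )
        )

    # epimutations: rare per-subject outliers on clean background probes
    flagged = ann_frame[
        ["snp_overlap", "cross_hybridizing", "sex_chromosome"]
    ].any(axis=1).to_numpy()
    background = ann_frame["role"].to_numpy() == "background"
    eligible = np.nonzero(background & ~flagged)[0].tolist()
    if cfg.epimutation_rate > 0 and eligible:
        epi_seed = int(rng.integers(0, 2**31 - 1))
        bm = BetaMatrix(pd.DataFrame(B, index=probe_ids, columns=samples))
        bm, coords = inject_epimutations(
            bm,
            cfg.epimutation_rate,
            cfg.epimutation_shift,
            seed=epi_seed,
            eligible_probes=[probe_ids[i] for i in eligible],
        )
        B = bm.values
        truth.epimutations = coords

    # missingness and detection failures avoid injected coordinates so
    # the recorded truth stays observable
    col_of = {s: j for j, s in enumerate(samples)}
    row_of = {p: i for i, p in enumerate(probe_ids)}
    injected = np.zeros((n, n_samples), dtype=bool)
    for p, s, _ in truth.epimutations:
        injected[row_of[p], col_of[s]] = True
    for p in truth.dmp_probes:
        injected[row_of[p], :] = True
    for iv in truth.dmr_intervals:
        for p in iv["probes"]:
            injected[row_of[p], :] = True

    if cfg.missing_rate > 0:
        miss = (rng.random(size=B.shape) < cfg.missing_rate) & ~injected
        B = B.copy()
        B[miss] = np.nan

    detp = rng.uniform(0.0, 0.01, size=B.shape)
    if cfg.detection_fail_rate > 0:
        fail = (rng.random(size=B.shape) < cfg.detection_fail_rate) & ~injected
        detp[fail] = rng.uniform(0.06, 1.0, size=int(fail.sum()))

    betas = BetaMatrix(pd.DataFrame(B, index=probe_ids, columns=samples))
    detp_m = DetectionPMatrix(pd.DataFrame(detp, index=probe_ids, columns=samples))
    annotation = CpGAnnotation(ann_frame.drop(columns=["role"]))
    return SyntheticCohort(
        betas=betas,
        detp=detp_m,
        sheet=sheet,
        annotation=annotation,
        truth=truth,
        reference=reference,
        clock=clock,
    )
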