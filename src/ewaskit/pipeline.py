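"""End-to-end pipeline orchestration.

Stages run in the fixed order qc -> deconvolution -> clocks -> sem ->
dmp -> dmr -> ora, each reading the previous stage's in-memory objects
and writing its own artifacts under the output directory.  A single
global seed is fanned out to per-stage sub-seeds through a counter-based
scheme (stage index mixed into a SeedSequence), so toggling one stage
never shifts another stage's randomness.  The run report echoes every
parameter actually applied plus the key diagnostics, and regenerates
identically from the same inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clocks as clocks_mod
from . import deconvolution as deconv_mod
from . import dmp as dmp_mod
from . import dmr as dmr_mod
from . import ora as ora_mod
from . import qc as qc_mod
from . import sem as sem_mod
from .io import (
    BetaMatrix,
    align_to_sheet,
    read_annotation,
    read_beta_matrix,
    read_detection_p_matrix,
    read_gene_sets,
    read_sample_sheet,
    write_bed,
    ValidationError,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "simulate_command",
           "stage_seed"]

STAGES = ("qc", "deconvolve", "clocks", "sem", "dmp", "dmr", "ora")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage sub-seed from the global seed (counter-based)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Paths, per-stage parameters and toggles for a full run."""

    beta_path: str = ""
    detp_path: str = ""
    sheet_path: str = ""
    annotation_path: str = ""
    reference_path: str = ""
    clock_paths: list[str] = field(default_factory=list)
    gene_sets_path: str = ""
    out_dir: str = "results"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    qc: dict[str, Any] = field(
        default_factory=lambda: dict(
            detection_alpha=0.05,
            max_sample_fail_frac=0.05,
            max_probe_fail_frac=0.10,
            multimodal_min_cluster_frac=0.10,
            multimodal_min_separation=0.25,
            multimodal_eps=0.05,
        )
    )
    sem: dict[str, Any] = field(
        default_factory=lambda: dict(k=3.0, min_n=8, outlier_sd=3.0, min_run=3,
                                     leave_one_out=False)
    )
    dmp: dict[str, Any] = field(
        default_factory=lambda: dict(
            n_iter=5000, burn_in=2000, empirical_null=True,
            include_age=True, include_sex=True, use_cell_fractions=True,
        )
    )
    dmr: dict[str, Any] = field(
        default_factory=lambda: dict(
            max_dist=500, bin_width=50, window_bp=500, seed_p=0.01,
            extend_p=0.05, max_gap_bp=500, sidak_alpha=0.001, min_probes=3,
        )
    )
    ora: dict[str, Any] = field(
        default_factory=lambda: dict(min_set=5, max_set=2000)
    )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValidationError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, dict):
                current.update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunReport:
    seed: int
    stages_run: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)
            fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, log=print) -> RunReport:
    """Execute the configured stages in order; see module docstring."""
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    import ewaskit

    report = RunReport(
        seed=cfg.seed,
        parameters=dict(qc=cfg.qc, sem=cfg.sem, dmp=cfg.dmp, dmr=cfg.dmr,
                        ora=cfg.ora),
        versions=dict(
            ewaskit=ewaskit.__version__,
            numpy=np.__version__,
            pandas=pd.__version__,
        ),
    )
    for key in ("beta_path", "detp_path", "sheet_path", "annotation_path",
                "reference_path", "gene_sets_path"):
        path = getattr(cfg, key)
        if path:
            if not os.path.exists(path):
                raise ValidationError(f"{key} does not exist: {path}")
            report.input_digests[key] = _digest(path)

    log(f"[pipeline] seed={cfg.seed} out={cfg.out_dir}")
    sheet = read_sample_sheet(cfg.sheet_path)
    betas = align_to_sheet(read_beta_matrix(cfg.beta_path), sheet)
    detp = align_to_sheet(read_detection_p_matrix(cfg.detp_path), sheet)
    annotation = read_annotation(cfg.annotation_path)

    def outp(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    # ---- qc
    if cfg.stages.get("qc", True):
        log(f"[qc] detection alpha={cfg.qc['detection_alpha']} "
            f"sample fail >{cfg.qc['max_sample_fail_frac']:.0%} "
            f"probe fail >{cfg.qc['max_probe_fail_frac']:.0%} "
            f"multimodal eps={cfg.qc['multimodal_eps']} "
            f"min_cluster_frac={cfg.qc['multimodal_min_cluster_frac']} "
            f"min_separation={cfg.qc['multimodal_min_separation']}")
        betas, qc_report = qc_mod.run_qc(betas, detp, annotation, **cfg.qc)
        sheet = sheet.select(list(betas.sample_ids))
        with open(outp("qc_report.json"), "w") as fh:
            json.dump(qc_report.to_dict(), fh, indent=2)
            fh.write("\n")
        report.diagnostics["qc"] = qc_report.to_dict()
        report.stages_run.append("qc")

    fractions = None
    # ---- deconvolution
    if cfg.stages.get("deconvolve", True) and cfg.reference_path:
        reference = deconv_mod.read_reference_profiles(cfg.reference_path)
        fractions = deconv_mod.estimate_fractions(betas, reference)
        comparison = deconv_mod.compare_fractions(fractions, sheet)
        fractions.data.to_csv(outp("cell_fractions.tsv"), sep="\t",
                              index_label="sample_id")
        comparison.to_csv(outp("cell_comparison.tsv"), sep="\t")
        report.diagnostics["deconvolve"] = dict(
            n_cell_types=int(fractions.data.shape[1]),
            min_q=float(comparison["q"].min()),
        )
        report.stages_run.append("deconvolve")
        log(f"[deconvolve] {fractions.data.shape[1]} cell types, "
            f"min q = {comparison['q'].min():.3g}")

    # ---- clocks
    if cfg.stages.get("clocks", True) and cfg.clock_paths:
        results = []
        for path in cfg.clock_paths:
            clock = clocks_mod.read_clock(path)
            predicted = clocks_mod.apply_clock(betas, clock)
            results.append(clocks_mod.fit_acceleration(predicted, sheet))
        table = clocks_mod.compare_acceleration_multi(results)
        table.to_csv(outp("clock_acceleration.tsv"), sep="\t")
        report.diagnostics["clocks"] = dict(
            n_clocks=len(results), min_q=float(table["q"].min())
        )
        report.stages_run.append("clocks")
        log(f"[clocks] {len(results)} clocks, min q = {table['q'].min():.3g}")

    # ---- sem
    if cfg.stages.get("sem", True):
        ctrl_ids = [s for s, g in zip(sheet.sample_ids, sheet.data["group"])
                    if g == sheet.groups[0]]
        if cfg.sem.get("leave_one_out", False):
            profile = sem_mod.call_sems_leave_one_out(
                betas, ctrl_ids, k=cfg.sem["k"], min_n=cfg.sem["min_n"]
            )
        else:
            ranges = sem_mod.compute_reference_ranges(
                betas.select_samples(ctrl_ids), k=cfg.sem["k"],
                min_n=cfg.sem["min_n"]
            )
            profile = sem_mod.call_sems(betas, ranges)
        burden = sem_mod.model_burden(
            profile, sheet, fractions, outlier_sd=cfg.sem["outlier_sd"]
        )
        epiv = sem_mod.call_epivariations(profile, annotation,
                                          min_run=cfg.sem["min_run"])
        summary = sem_mod.group_specific_epivariations(epiv, sheet)
        profile.calls.to_csv(outp("sem_calls.tsv"), sep="\t", index=False)
        profile.totals.to_csv(outp("sem_burden.tsv"), sep="\t",
                              index_label="sample_id")
        epiv.to_csv(outp("epivariations.tsv"), sep="\t", index=False)
        summary.to_csv(outp("epivariation_genes.tsv"), sep="\t")
        group_p = {k: float(v.coefficients.loc["group", "p"])
                   for k, v in burden.items()}
        report.diagnostics["sem"] = dict(
            k=cfg.sem["k"],
            burden_group_p=group_p,
            n_epivariated_genes=int(summary.shape[0]),
            excluded=burden["total"].excluded_samples,
        )
        report.stages_run.append("sem")
        log(f"[sem] fences k={cfg.sem['k']}, burden group p={group_p['total']:.3g}, "
            f"{summary.shape[0]} epivariated genes")

    # ---- dmp
    dmp_table = None
    if cfg.stages.get("dmp", True):
        pars = cfg.dmp
        dmp_table, diag = dmp_mod.run_dmp(
            betas, sheet,
            cell_fractions=fractions if pars.get("use_cell_fractions", True) else None,
            include_age=pars.get("include_age", True),
            include_sex=pars.get("include_sex", True),
            seed=stage_seed(cfg.seed, "dmp"),
            n_iter=pars["n_iter"],
            burn_in=pars["burn_in"],
            empirical_null=pars.get("empirical_null", True),
        )
        ann = annotation.data.reindex(dmp_table.index)
        out = dmp_table.copy()
        out.insert(0, "chrom", ann["chrom"])
        out.insert(1, "pos", ann["pos"])
        out.insert(2, "genes", [";".join(g) if isinstance(g, tuple) else ""
                                for g in ann["genes"]])
        out.to_csv(outp("dmp_table.tsv"), sep="\t", index_label="probe_id")
        with open(outp("dmp_diagnostics.json"), "w") as fh:
            json.dump(diag, fh, indent=2, default=_jsonable)
            fh.write("\n")
        report.diagnostics["dmp"] = dict(
            **{k: v for k, v in diag.items()},
            n_stringent=int((dmp_table["tier"] == "stringent").sum()),
            n_relaxed=int((dmp_table["tier"] != "none").sum()),
            thresholds="stringent: q<0.001 & |db|>0.1; relaxed: q<0.05 & |db|>0.05",
        )
        report.stages_run.append("dmp")
        log(f"[dmp] lambda before/after = {diag.get('lambda_before'):.3f}/"
            f"{(diag.get('lambda_after') or float('nan')):.3f}, "
            f"bias={diag.get('bias', float('nan')):.3f}, "
            f"inflation={diag.get('inflation', float('nan')):.3f}")

    # ---- dmr
    if cfg.stages.get("dmr", True):
        if dmp_table is None:
            raise ValidationError("dmr stage requires the dmp stage")
        pars = cfg.dmr
        records, acf = dmr_mod.run_dmr(
            dmp_table["p"].dropna(),
            annotation.data,
            delta_beta=dmp_table["delta_beta"],
            **pars,
        )
        rows = [
            dict(chrom=r.chrom, start=r.start, end=r.end, n_probes=r.n_probes,
                 p_region=r.p_region, p_sidak=r.p_sidak,
                 mean_delta_beta=r.mean_delta_beta,
                 mixed_direction=r.mixed_direction,
                 probes=";".join(r.probe_ids))
            for r in records
        ]
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_probes", "p_region",
                           "p_sidak", "mean_delta_beta", "mixed_direction",
                           "probes"]
        ).to_csv(outp("dmr_table.tsv"), sep="\t", index=False)
        write_bed(
            [dict(chrom=r.chrom, start=r.start, end=r.end,
                  name=f"DMR{i + 1}", score=min(int(-np.log10(max(r.p_sidak, 1e-30))
                                                    * 100), 1000))
             for i, r in enumerate(records)],
            outp("dmr_regions.bed"),
        )
        report.diagnostics["dmr"] = dict(
            n_regions=len(records),
            acf_correlations=acf.correlations.tolist(),
            filter=f"p_sidak<{pars['sidak_alpha']} & n_probes>={pars['min_probes']}",
        )
        report.stages_run.append("dmr")
        log(f"[dmr] {len(records)} regions pass "
            f"p_sidak<{pars['sidak_alpha']} with >= {pars['min_probes']} CpGs")

    # ---- ora
    if cfg.stages.get("ora", True) and cfg.gene_sets_path:
        if dmp_table is None:
            raise ValidationError("ora stage requires the dmp stage")
        sets = read_gene_sets(cfg.gene_sets_path)
        ann = annotation.data.reindex(dmp_table.index)
        universe = sorted(
            {g for genes in ann["genes"].dropna() for g in genes}
        )
        hits = dmp_table.index[dmp_table["tier"] != "none"]
        query = sorted(
            {g for genes in ann.loc[hits, "genes"].dropna() for g in genes}
        )
        table = ora_mod.run_ora(query, sets, universe, **cfg.ora)
        table.to_csv(outp("ora_table.tsv"), sep="\t")
        report.diagnostics["ora"] = dict(
            n_query=len(query), n_universe=len(universe),
            n_sets_tested=int(table.shape[0]),
            min_q=float(table["q"].min()) if len(table) else None,
        )
        report.stages_run.append("ora")
        log(f"[ora] {len(query)} query genes vs {table.shape[0]} sets")

    report.to_json(outp("run_report.json"))
    return report


def simulate_command(
    sim_config, out_dir: str, n_gene_sets: int = 20, write_gmt: bool = True
) -> dict[str, str]:
    """Generate a synthetic bundle and write it in pipeline formats.

    Returns the mapping of artifact names to paths.  Besides the five
    canonical inputs this writes the reference profiles, the synthetic
    clock and (optionally) a GMT of gene sets sampled from the
    annotation so the ORA stage can run end to end.
    """
    from . import synthetic
    from .io import (GeneSetCollection, write_annotation, write_gene_sets,
                     write_matrix, write_sample_sheet)

    os.makedirs(out_dir, exist_ok=True)
    cohort = synthetic.generate_cohort(sim_config)
    paths = {
        "beta_path": os.path.join(out_dir, "betas.tsv"),
        "detp_path": os.path.join(out_dir, "detection_p.tsv"),
        "sheet_path": os.path.join(out_dir, "samples.tsv"),
        "annotation_path": os.path.join(out_dir, "annotation.tsv"),
    }
    write_matrix(cohort.betas, paths["beta_path"])
    write_matrix(cohort.detp, paths["detp_path"])
    write_sample_sheet(cohort.sheet, paths["sheet_path"])
    write_annotation(cohort.annotation, paths["annotation_path"])
    if cohort.reference is not None:
        paths["reference_path"] = os.path.join(out_dir, "reference.tsv")
        deconv_mod.write_reference_profiles(cohort.reference,
                                            paths["reference_path"])
    if cohort.clock is not None:
        paths["clock_path"] = os.path.join(out_dir, "clock_synth.csv")
        clocks_mod.write_clock(cohort.clock, paths["clock_path"])
    if write_gmt:
        rng = np.random.default_rng(sim_config.seed + 1)
        genes = sorted(
            {g for gg in cohort.annotation.data["genes"] for g in gg}
        )
        sets = {}
        for i in range(n_gene_sets):
            size = int(rng.integers(10, 60))
            members = tuple(rng.choice(genes, size=min(size, len(genes)),
                                       replace=False))
            sets[f"SET{i:03d}"] = (f"synthetic set {i}", members)
        paths["gene_sets_path"] = os.path.join(out_dir, "gene_sets.gmt")
        write_gene_sets(GeneSetCollection(sets), paths["gene_sets_path"])
    # truth for downstream evaluation
    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(
            dict(
                dmp_probes=cohort.truth.dmp_probes,
                dmr_intervals=cohort.truth.dmr_intervals,
                epimutations=cohort.truth.epimutations,
            ),
            fh, indent=2, default=_jsonable,
        )
        fh.write("\n")
    paths["truth_path"] = truth_path
    return paths
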