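import numpy as np
import pandas as pd
import pytest

from ewaskit.io import BetaMatrix, DetectionPMatrix, SampleSheet, CpGAnnotation
from ewaskit.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 5,000-probe 20/20 cohort with all effect classes injected."""
    return generate_cohort(SimConfig(n_probes=5_000, seed=101))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no injected effects of any kind."""
    cfg = SimConfig(
        n_probes=3_000, seed=202, n_dmp=0, n_dmr=0, epimutation_rate=0.0,
        n_bimodal=0,
    )
    return generate_cohort(cfg)


@pytest.fixture
def tiny_sheet():
    frame = pd.DataFrame(
        {
            "group": ["control"] * 10 + ["case"] * 10,
            "age": np.linspace(60, 85, 20),
            "sex": ["M", "F"] * 10,
        },
        index=pd.Index([f"S{i:02d}" for i in range(20)], name="sample_id"),
    )
    return SampleSheet(frame)


def make_beta(values, probe_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    frame.index.name = "probe_id"
    return BetaMatrix(frame)


def make_detp(values, probe_ids=None, sample_ids=None) -> DetectionPMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(values.shape[1])]
    return DetectionPMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))


def make_annotation(rows) -> CpGAnnotation:
    """rows: list of dicts with probe_id, chrom, pos, genes, flags."""
    frame = pd.DataFrame(rows).set_index("probe_id")
    if "genes" not in frame.columns:
        frame["genes"] = [()] * len(frame)
    for flag in CpGAnnotation.FLAGS:
        if flag not in frame.columns:
            frame[flag] = False
        frame[flag] = [bool(v) and not pd.isna(v) for v in frame[flag]]
    return CpGAnnotation(frame)
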