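import numpy as np
import pandas as pd
import pytest

from ewaskit import sem
from ewaskit.io import SampleSheet, ValidationError
from conftest import make_annotation, make_beta


def _sheet(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return SampleSheet(
        pd.DataFrame(
            {"group": ["control"] * n + ["case"] * n,
             "age": rng.uniform(60, 87, 2 * n).round(1),
             "sex": ["M", "F"] * n},
            index=pd.Index([f"S{i:03d}" for i in range(2 * n)],
                           name="sample_id"),
        )
    )


class TestReferenceRanges:
    def test_worked_example_linear_interpolation(self):
        vals = np.arange(0.10, 0.25, 0.02)[None, :]
        bm = make_beta(vals)
        r = sem.compute_reference_ranges(bm).data.iloc[0]
        assert r["q1"] == pytest.approx(0.135)
        assert r["q3"] == pytest.approx(0.205)
        assert r["iqr"] == pytest.approx(0.07)
        assert r["lo"] == pytest.approx(-0.075)
        assert r["hi"] == pytest.approx(0.415)

    def test_constant_probe_collapses_fences(self):
        bm = make_beta(np.full((1, 10), 0.42))
        r = sem.compute_reference_ranges(bm).data.iloc[0]
        assert r["iqr"] == 0
        assert r["lo"] == r["hi"] == 0.42

    def test_fences_monotone_in_k(self):
        rng = np.random.default_rng(0)
        bm = make_beta(rng.random((20, 15)))
        r1 = sem.compute_reference_ranges(bm, k=1).data
        r3 = sem.compute_reference_ranges(bm, k=3).data
        pos_iqr = r1["iqr"] > 0
        assert (r3.loc[pos_iqr, "lo"] < r1.loc[pos_iqr, "lo"]).all()
        assert (r3.loc[pos_iqr, "hi"] > r1.loc[pos_iqr, "hi"]).all()

    def test_low_coverage_probe_skipped(self):
        vals = np.full((2, 10), 0.5)
        vals[0, 3:] = np.nan  # 3 non-missing < min_n=8
        bm = make_beta(vals)
        r = sem.compute_reference_ranges(bm)
        assert r.skipped_probes == [bm.probe_ids[0]]
        assert list(r.data.index) == [bm.probe_ids[1]]

    def test_no_controls_rejected(self):
        bm = make_beta(np.empty((3, 0)))
        with pytest.raises(ValidationError):
            sem.compute_reference_ranges(bm)


class TestCallSems:
    def _fixture(self):
        # evenly spaced rows: every value provably inside its own fences
        offsets = np.linspace(0.3, 0.6, 5)[:, None]
        vals = offsets + np.linspace(0.0, 0.05, 12)[None, :]
        bm = make_beta(vals)
        ranges = sem.compute_reference_ranges(bm)
        return bm, ranges

    def test_all_inside_fences_gives_zero_burden(self):
        bm, ranges = self._fixture()
        prof = sem.call_sems(bm, ranges)
        assert (prof.totals["n_sem"] == 0).all()

    def test_value_just_above_hi_called_hyper(self):
        bm, ranges = self._fixture()
        vals = bm.values.copy()
        hi = ranges.data.iloc[2]["hi"]
        vals[2, 4] = min(hi + 0.01, 1.0)
        bm2 = make_beta(vals, probe_ids=list(bm.probe_ids),
                        sample_ids=list(bm.sample_ids))
        prof = sem.call_sems(bm2, ranges)
        assert prof.totals.loc[bm.sample_ids[4], "n_hyper"] == 1
        assert prof.totals["n_sem"].sum() == 1
        call = prof.calls.iloc[0]
        assert call["direction"] == "hyper"
        assert call["probe_id"] == bm.probe_ids[2]

    def test_value_at_fence_not_called_strict(self):
        bm, ranges = self._fixture()
        vals = bm.values.copy()
        vals[1, 0] = ranges.data.iloc[1]["hi"]
        bm2 = make_beta(vals, probe_ids=list(bm.probe_ids),
                        sample_ids=list(bm.sample_ids))
        prof = sem.call_sems(bm2, ranges)
        assert prof.totals["n_sem"].sum() == 0

    def test_missing_values_never_called(self):
        bm, ranges = self._fixture()
        vals = bm.values.copy()
        vals[0, 0] = np.nan
        bm2 = make_beta(vals, probe_ids=list(bm.probe_ids),
                        sample_ids=list(bm.sample_ids))
        prof = sem.call_sems(bm2, ranges)
        assert prof.totals["n_sem"].sum() == 0

    def test_widening_k_never_increases_burden(self):
        rng = np.random.default_rng(2)
        bm = make_beta(np.clip(rng.normal(0.5, 0.05, (200, 30)), 0, 1))
        ctrl = bm.select_samples(list(bm.sample_ids[:15]))
        burden = {}
        for k in (1.0, 2.0, 3.0):
            prof = sem.call_sems(bm, sem.compute_reference_ranges(ctrl, k=k))
            burden[k] = prof.totals["n_sem"]
        assert (burden[2.0] <= burden[1.0]).all()
        assert (burden[3.0] <= burden[2.0]).all()

    def test_injected_epimutations_fully_recovered(self, small_cohort):
        betas, _, sheet, _, truth = small_cohort
        ctrl = [s for s, g in zip(sheet.sample_ids, sheet.data["group"])
                if g == "control"]
        ranges = sem.compute_reference_ranges(betas.select_samples(ctrl))
        prof = sem.call_sems(betas, ranges)
        called = {(p, s, d) for p, s, d in
                  zip(prof.calls["probe_id"], prof.calls["sample_id"],
                      prof.calls["direction"])}
        assert set(map(tuple, truth.epimutations)) <= called


class TestBurdenModel:
    def _profile(self, totals, sample_ids):
        frame = pd.DataFrame(
            {"n_sem": totals, "n_hypo": np.asarray(totals) // 2,
             "n_hyper": np.asarray(totals) - np.asarray(totals) // 2},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return sem.SEMProfile(
            calls=pd.DataFrame(columns=["probe_id", "sample_id", "direction"]),
            totals=frame[["n_sem", "n_hypo", "n_hyper"]],
            probe_ids=[],
        )

    def test_null_burden_group_coefficient_near_zero(self):
        sheet = _sheet(seed=3)
        big_t = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            totals = rng.poisson(200, 40)
            res = sem.model_burden(self._profile(totals, sheet.sample_ids),
                                   sheet)
            big_t += abs(res["total"].coefficients.loc["group", "t"]) >= 2
        assert big_t <= 10

    def test_tripled_case_burden_detected(self):
        sheet = _sheet(seed=4)
        rng = np.random.default_rng(4)
        totals = rng.poisson(200, 40)
        totals[20:] *= 3
        res = sem.model_burden(self._profile(totals, sheet.sample_ids), sheet)
        row = res["total"].coefficients.loc["group"]
        assert row["coef"] > 0
        assert row["p"] < 0.01

    def test_extreme_outlier_excluded(self):
        sheet = _sheet(seed=5)
        rng = np.random.default_rng(5)
        totals = rng.poisson(200, 40)
        totals[7] = 200 * 100
        res = sem.model_burden(self._profile(totals, sheet.sample_ids), sheet)
        assert sheet.sample_ids[7] in res["total"].excluded_samples
        assert res["total"].n_used == 39

    def test_cell_fraction_covariates_enter_design(self):
        from ewaskit.deconvolution import BLOOD12, CellFractions

        sheet = _sheet(seed=6)
        rng = np.random.default_rng(6)
        w = rng.dirichlet(np.ones(12), 40)
        fr = CellFractions(pd.DataFrame(w, index=sheet.sample_ids,
                                        columns=list(BLOOD12)))
        totals = rng.poisson(150, 40)
        res = sem.model_burden(self._profile(totals, sheet.sample_ids),
                               sheet, cell_fractions=fr)
        terms = list(res["total"].coefficients.index)
        # 11 fraction terms (one dropped) + const, group, age, sex
        assert sum(t.startswith("frac_") for t in terms) == 11


class TestEpivariations:
    def _ann(self):
        rows = []
        for i in range(6):
            rows.append(dict(probe_id=f"cg{i}", chrom="chr1", pos=100 + 10 * i,
                             genes=("GENEA",)))
        for i in range(3):
            rows.append(dict(probe_id=f"cgb{i}", chrom="chr2", pos=500 + 10 * i,
                             genes=("GENEB",)))
        return make_annotation(rows)

    def _profile(self, call_rows, n_sem_by_sample):
        calls = pd.DataFrame(call_rows,
                             columns=["probe_id", "sample_id", "direction"])
        samples = sorted(n_sem_by_sample)
        totals = pd.DataFrame(
            {
                "n_sem": [n_sem_by_sample[s] for s in samples],
                "n_hypo": [n_sem_by_sample[s] for s in samples],
                "n_hyper": [0] * len(samples),
            },
            index=pd.Index(samples, name="sample_id"),
        )
        probe_ids = [f"cg{i}" for i in range(6)] + [f"cgb{i}" for i in range(3)]
        return sem.SEMProfile(calls=calls, totals=totals, probe_ids=probe_ids)

    def test_three_consecutive_same_direction_called(self):
        rows = [(f"cg{i}", "S1", "hypo") for i in (1, 2, 3)]
        prof = self._profile(rows, {"S1": 3})
        calls = sem.call_epivariations(prof, self._ann())
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["gene"] == "GENEA" and row["direction"] == "hypo"
        assert row["n_sem_cpgs_in_gene"] == 3
        assert row["n_cpgs_in_gene"] == 6
        assert 0 < row["enrichment_p"] < 1

    def test_two_sems_below_min_run_not_called(self):
        rows = [(f"cg{i}", "S1", "hypo") for i in (1, 2)]
        prof = self._profile(rows, {"S1": 2})
        assert len(sem.call_epivariations(prof, self._ann())) == 0

    def test_mixed_direction_run_not_called(self):
        rows = [("cg1", "S1", "hypo"), ("cg2", "S1", "hyper"),
                ("cg3", "S1", "hypo")]
        prof = self._profile(rows, {"S1": 3})
        assert len(sem.call_epivariations(prof, self._ann())) == 0

    def test_non_adjacent_sems_not_called(self):
        rows = [("cg0", "S1", "hypo"), ("cg2", "S1", "hypo"),
                ("cg4", "S1", "hypo")]
        prof = self._profile(rows, {"S1": 3})
        assert len(sem.call_epivariations(prof, self._ann())) == 0

    def test_calls_invariant_to_probe_storage_order(self):
        rows = [(f"cg{i}", "S1", "hypo") for i in (3, 1, 2)]  # shuffled
        prof = self._profile(rows, {"S1": 3})
        calls = sem.call_epivariations(prof, self._ann())
        assert len(calls) == 1


class TestGroupSpecificEpivariations:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "sample_id", "direction",
                           "n_sem_cpgs_in_gene", "n_cpgs_in_gene",
                           "enrichment_p"],
        )

    def test_case_only_gene_labeled(self):
        sheet = _sheet()
        case_ids = list(sheet.sample_ids[20:22])
        calls = self._calls([("G1", s, "hypo", 3, 6, 0.01) for s in case_ids])
        out = sem.group_specific_epivariations(calls, sheet)
        assert out.loc["G1", "exclusivity"] == "case-only"
        assert out.loc["G1", "n_case"] == 2
        assert out.loc["G1", "direction_summary"] == "all hypomethylated"

    def test_shared_gene_labeled(self):
        sheet = _sheet()
        calls = self._calls(
            [("G1", sheet.sample_ids[0], "hyper", 3, 6, 0.01),
             ("G1", sheet.sample_ids[25], "hypo", 3, 6, 0.01)]
        )
        out = sem.group_specific_epivariations(calls, sheet)
        assert out.loc["G1", "exclusivity"] == "shared"
        assert out.loc["G1", "direction_summary"] == "mixed"

    def test_empty_calls_give_empty_summary(self):
        sheet = _sheet()
        out = sem.group_specific_epivariations(self._calls([]), sheet)
        assert out.empty


class TestLeaveOneOut:
    def test_loo_removes_in_sample_advantage(self):
        # with plain fences controls are in-sample and carry less burden;
        # LOO scoring should equalize the group means on null data
        rng = np.random.default_rng(9)
        bm = make_beta(np.clip(0.5 + rng.normal(0, 0.03, (3000, 40)), 0, 1),
                       sample_ids=[f"S{i:03d}" for i in range(40)])
        ctrl = [f"S{i:03d}" for i in range(20)]
        plain = sem.call_sems(
            bm, sem.compute_reference_ranges(bm.select_samples(ctrl))
        )
        loo = sem.call_sems_leave_one_out(bm, ctrl)
        plain_gap = (plain.totals["n_sem"][20:].mean()
                     - plain.totals["n_sem"][:20].mean())
        loo_gap = (loo.totals["n_sem"][20:].mean()
                   - loo.totals["n_sem"][:20].mean())
        assert plain_gap > 2 * max(abs(loo_gap), 1e-9)
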