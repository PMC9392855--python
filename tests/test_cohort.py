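"""Synthetic cohort generator: determinism, calibration, back-solve
consistency, and CSV / spec-config round-trips."""

import dataclasses
import warnings

import numpy as np
import pytest

import modrer as m
from modrer.pipeline import index_change_frame

CALIBRATED = ("ph", "paco2", "scvo2", "lactate", "mod_rer")


def zero_change_spec(seed=0) -> m.CohortSpec:
    spec = m.CohortSpec(seed=seed)
    return dataclasses.replace(
        spec,
        indices={
            name: dataclasses.replace(
                cal, change=dataclasses.replace(cal.change, fail_sd=0.0, success_sd=0.0)
            )
            for name, cal in spec.indices.items()
        },
    )


class TestDeterminism:
    def test_same_seed_same_cohort_csv_bytes(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        m.write_cohort_csv(m.generate_cohort(m.CohortSpec(seed=11)), a)
        m.write_cohort_csv(m.generate_cohort(m.CohortSpec(seed=11)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        c1 = m.generate_cohort(m.CohortSpec(seed=1))
        c2 = m.generate_cohort(m.CohortSpec(seed=2))
        assert c1.to_dataframe().equals(c2.to_dataframe()) is False

    def test_null_cohort_deterministic(self):
        df1 = m.generate_null_cohort(m.CohortSpec(seed=3)).to_dataframe()
        df2 = m.generate_null_cohort(m.CohortSpec(seed=3)).to_dataframe()
        assert df1.equals(df2)


class TestStructure:
    def test_sizes_and_linkage(self, default_cohort):
        assert len(default_cohort) == 71
        patients = {t.patient_id for t in default_cohort}
        assert len(patients) == 51
        # repeat trials belong to patients whose first trial failed
        first_outcome = {}
        for t in default_cohort.trials[:51]:
            first_outcome[t.patient_id] = t.failed
        for t in default_cohort.trials[51:]:
            assert first_outcome[t.patient_id]

    def test_panels_satisfy_invariants_without_warnings(self):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            cohort = m.generate_cohort(m.CohortSpec(seed=23))
        for t in cohort:
            assert t.pre.pao2 - t.pre.pcvo2 >= 5.0
            assert t.post.scvo2 < t.post.sao2

    def test_hemoglobin_can_be_omitted(self):
        spec = dataclasses.replace(m.CohortSpec(seed=5), include_hemoglobin=False)
        cohort = m.generate_cohort(spec)
        assert all(t.pre.hemoglobin is None for t in cohort)


class TestCalibration:
    def test_zero_variance_changes_equal_group_means(self):
        cohort = m.generate_cohort(zero_change_spec(seed=2))
        frame = index_change_frame(cohort)
        ev = frame["event"].to_numpy()
        spec = m.CohortSpec()
        for name in CALIBRATED:
            chg = frame[f"{name}_change"].to_numpy()
            cal = spec.indices[name].change
            assert chg[ev == 1] == pytest.approx(cal.fail_mean, abs=1e-9)
            assert chg[ev == 0] == pytest.approx(cal.success_mean, abs=1e-9)

    def test_failure_fraction_calibrated(self):
        rng = np.random.default_rng(31)
        fractions = [
            m.generate_cohort(m.CohortSpec(), rng).n_failures / 71 for _ in range(200)
        ]
        se = np.sqrt(0.451 * 0.549 / (200 * 71))
        assert np.mean(fractions) == pytest.approx(32 / 71, abs=4 * se)

    def test_index_change_means_calibrated(self):
        """Group-wise mean Mod-RER changes track the generative parameters."""
        rng = np.random.default_rng(17)
        fail_changes, succ_changes = [], []
        for _ in range(60):
            frame = index_change_frame(m.generate_cohort(m.CohortSpec(), rng))
            ev = frame["event"].to_numpy()
            chg = frame["mod_rer_change"].to_numpy()
            fail_changes.extend(chg[ev == 1])
            succ_changes.extend(chg[ev == 0])
        se_f = 59.57 / np.sqrt(len(fail_changes))
        se_s = 63.69 / np.sqrt(len(succ_changes))
        assert np.mean(fail_changes) == pytest.approx(54.77, abs=4 * se_f)
        assert np.mean(succ_changes) == pytest.approx(3.32, abs=4 * se_s)

    def test_back_solved_panels_reproduce_mod_rer_distribution(self):
        """Derived Mod-RER values are exactly pcvco2/(pao2-pcvo2) and the
        pre draws follow the calibrated truncated normal (whose mean sits
        above the untruncated 1.25/1.14 because of the positivity floor)."""
        from scipy.stats import truncnorm

        cohort = m.generate_cohort(m.CohortSpec(n_trials=2000, n_patients=2000, seed=13))
        frame = index_change_frame(cohort)
        ev = frame["event"].to_numpy()
        pre = frame["mod_rer_pre"].to_numpy()
        for t, v in zip(cohort, pre):
            assert v == pytest.approx(
                t.pre.pcvco2 / (t.pre.pao2 - t.pre.pcvo2), abs=1e-9
            )
        cal = m.CohortSpec().indices["mod_rer"].pre
        for mask, mu, sd in [
            (ev == 1, cal.fail_mean, cal.fail_sd),
            (ev == 0, cal.success_mean, cal.success_sd),
        ]:
            a, b = (cal.lo - mu) / sd, (cal.hi - mu) / sd
            expected = truncnorm.mean(a, b, mu, sd)
            se = truncnorm.std(a, b, mu, sd) / np.sqrt(mask.sum())
            assert pre[mask].mean() == pytest.approx(expected, abs=4 * se)

    def test_auc_monotone_in_effect_size(self):
        """Raising the fail-group change mean raises the expected AUC."""
        aucs = []
        for mean in (0.0, 30.0, 60.0, 120.0):
            spec = m.CohortSpec(n_trials=600, n_patients=600, seed=19)
            spec = dataclasses.replace(
                spec,
                indices={
                    **spec.indices,
                    "mod_rer": dataclasses.replace(
                        spec.indices["mod_rer"],
                        change=dataclasses.replace(
                            spec.indices["mod_rer"].change, fail_mean=mean
                        ),
                    ),
                },
            )
            frame = index_change_frame(m.generate_cohort(spec))
            auc, _, _ = m.auc_delong(
                frame["mod_rer_change"].to_numpy(), frame["event"].to_numpy()
            )
            aucs.append(auc)
        assert aucs == sorted(aucs)


class TestNullCohort:
    def test_null_auc_centred_on_half(self):
        rng = np.random.default_rng(41)
        aucs = []
        for _ in range(100):
            frame = index_change_frame(m.generate_null_cohort(m.CohortSpec(), rng))
            auc, _, _ = m.auc_delong(
                frame["mod_rer_change"].to_numpy(), frame["event"].to_numpy()
            )
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


class TestIO:
    def test_cohort_csv_round_trip(self, default_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        m.write_cohort_csv(default_cohort, path)
        back = m.read_cohort_csv(path)
        for a, b in zip(default_cohort, back):
            assert a.trial_id == b.trial_id and a.outcome == b.outcome
            assert a.pre.scvo2 == pytest.approx(b.pre.scvo2, rel=1e-9)
            assert a.post.pcvco2 == pytest.approx(b.post.pcvco2, rel=1e-9)

    def test_percent_saturations_normalised_on_read(self, default_cohort, tmp_path):
        path = tmp_path / "pct.csv"
        df = default_cohort.to_dataframe()
        for col in ("pre_sao2", "pre_scvo2", "post_sao2", "post_scvo2"):
            df[col] = df[col] * 100  # percent, as clinical tables print them
        df.to_csv(path, index=False)
        back = m.read_cohort_csv(path)
        assert back.trials[0].pre.scvo2 == pytest.approx(
            default_cohort.trials[0].pre.scvo2, rel=1e-9
        )

    def test_malformed_csv_names_the_problem(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("trial_id,outcome\nT1,fail\n")
        with pytest.raises(ValueError, match="missing required columns"):
            m.read_cohort_csv(path)

    def test_empty_csv_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("\n")
        with pytest.raises(Exception):
            m.read_cohort_csv(path)

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_spec_config_round_trip(self, tmp_path, suffix):
        spec = dataclasses.replace(m.CohortSpec(seed=99), n_trials=40, n_patients=30)
        path = tmp_path / f"spec{suffix}"
        m.write_spec(spec, path)
        assert m.read_spec(path) == spec

    def test_spec_round_trip_preserves_generation(self, tmp_path):
        spec = m.CohortSpec(seed=77)
        path = tmp_path / "spec.yaml"
        m.write_spec(spec, path)
        df1 = m.generate_cohort(spec).to_dataframe()
        df2 = m.generate_cohort(m.read_spec(path)).to_dataframe()
        assert df1.equals(df2)


class TestSpecValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            m.CohortSpec(failure_probability=1.5)

    def test_more_patients_than_trials_rejected(self):
        with pytest.raises(ValueError):
            m.CohortSpec(n_trials=10, n_patients=20)

    def test_infeasible_backsolve_errors(self):
        spec = m.CohortSpec(seed=1)
        bad = dataclasses.replace(
            spec,
            indices={
                **spec.indices,
                "ph": dataclasses.replace(
                    spec.indices["ph"],
                    # every post value forced outside the physiologic window
                    change=m.GroupNormal(400.0, 0.0, 400.0, 0.0),
                ),
            },
            max_resample=5,
        )
        from modrer.cohort import BacksolveError

        with pytest.raises(BacksolveError):
            m.generate_cohort(bad)
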