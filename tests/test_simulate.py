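import math

import numpy as np
import pandas as pd
import pytest

from anginatrial.blinding import blinding_index
from anginatrial.simulate import (
    Patient,
    TrialConfig,
    block_randomize,
    generate_blinding_responses,
    generate_trial,
    inject_overrides,
    simulate_daily_episodes,
    simulate_medication_protocol,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_per_arm", 0),
            ("pre_days", 0),
            ("followup_days", 0),
            ("baseline_daily_rate_mean", -0.1),
            ("frailty_dispersion", -1.0),
            ("pci_rate_ratio", 0.0),
            ("pci_rate_ratio", 1.5),
            ("contact_threshold", 0.0),
            ("med_attenuation", 1.2),
            ("missing_day_prob", 1.0),
            ("override_probs", (0.6, 0.6, 0.0)),
        ],
    )
    def test_invalid_parameter_named_in_error(self, field, value):
        with pytest.raises(ValueError) as err:
            TrialConfig(**{field: value})
        token = field if field != "override_probs" else "override_probs"
        assert token in str(err.value) or "probabilit" in str(err.value)


def test_seed_determinism():
    cfg = TrialConfig(n_per_arm=20, seed=42)
    a = generate_trial(cfg)
    b = generate_trial(cfg)
    pd.testing.assert_frame_equal(a.patients, b.patients)
    pd.testing.assert_frame_equal(a.diary, b.diary)
    pd.testing.assert_frame_equal(a.endpoints, b.endpoints)
    pd.testing.assert_frame_equal(a.blinding, b.blinding)


def test_block_randomization_balance():
    rng = np.random.default_rng(0)
    arms = block_randomize(300, rng)
    n_pci = int(np.sum(arms == "PCI"))
    assert abs(n_pci - 150) <= 8  # at most half the largest block
    assert set(arms) == {"PCI", "placebo"}


def test_null_effect_gives_equal_arm_episode_means():
    cfg = TrialConfig(
        n_per_arm=500, seed=1, pci_rate_ratio=1.0, override_probs=(0, 0, 0)
    )
    ds = generate_trial(cfg)
    fu = ds.diary[ds.diary.day >= 1].merge(ds.patients, on="patient_id")
    means = fu.groupby("arm").episodes.mean()
    # patient-level means are overdispersed; compare on 3 cluster s.e.
    per_patient = fu.groupby(["arm", "patient_id"]).episodes.mean()
    se = per_patient.groupby("arm").std() / np.sqrt(cfg.n_per_arm)
    assert abs(means["PCI"] - means["placebo"]) < 3 * np.hypot(*se)


def test_rate_ratio_reproduced_in_followup_means():
    """Without medication feedback the arm ratio matches pci_rate_ratio."""
    cfg = TrialConfig(
        n_per_arm=2000, seed=2, pci_rate_ratio=0.43,
        contact_threshold=math.inf, override_probs=(0, 0, 0),
        missing_day_prob=0.0,
    )
    ds = generate_trial(cfg)
    fu = ds.diary[ds.diary.day >= 1].merge(ds.patients, on="patient_id")
    means = fu.groupby("arm").episodes.mean()
    ratio = means["PCI"] / means["placebo"]
    assert ratio == pytest.approx(0.43, abs=0.03)


class TestDailyEpisodes:
    def test_zero_frailty_means_zero_episodes(self):
        patient = Patient(id=0, arm="placebo", frailty=0.0)
        cfg = TrialConfig()
        rng = np.random.default_rng(0)
        assert all(
            simulate_daily_episodes(patient, d, cfg, 0, rng) == 0
            for d in (-5, 1, 50)
        )

    def test_law_of_large_numbers_on_daily_mean(self):
        cfg = TrialConfig(baseline_daily_rate_mean=0.7)
        patient = Patient(id=0, arm="placebo", frailty=1.0)
        rng = np.random.default_rng(8)
        n = 100_000
        draws = [simulate_daily_episodes(patient, -1, cfg, 0, rng) for _ in range(n)]
        se = np.sqrt(0.7 / n)
        assert np.mean(draws) == pytest.approx(0.7, abs=3 * se)

    def test_pci_scales_post_randomization_rate(self):
        cfg = TrialConfig(pci_rate_ratio=0.43)
        pci = Patient(id=0, arm="PCI", frailty=1.0)
        rng = np.random.default_rng(9)
        n = 50_000
        pre = np.mean([simulate_daily_episodes(pci, -1, cfg, 0, rng) for _ in range(n)])
        post = np.mean([simulate_daily_episodes(pci, 1, cfg, 0, rng) for _ in range(n)])
        assert post / pre == pytest.approx(0.43, abs=0.04)


class TestMedicationProtocol:
    def _diary(self, episodes, units):
        return pd.DataFrame({"episodes": episodes, "med_units": units})

    def test_no_symptoms_no_medication(self):
        cfg = TrialConfig()
        diary = self._diary([0.0] * 20, [0] * 20)
        assert simulate_medication_protocol(diary, cfg) == 0

    def test_persistent_symptoms_saturate_at_maximum(self):
        cfg = TrialConfig(contact_threshold=0.5, max_med_units=4)
        units = 0
        history_e, history_u = [], []
        for _ in range(84):
            history_e.append(5.0)
            history_u.append(units)
            units = simulate_medication_protocol(
                self._diary(history_e, history_u), cfg
            )
        assert units == 4
        assert max(history_u) == 4

    def test_infinite_threshold_never_escalates(self):
        cfg = TrialConfig(contact_threshold=math.inf)
        diary = self._diary([50.0] * 30, [0] * 30)
        assert simulate_medication_protocol(diary, cfg) == 0

    def test_never_decrements_and_resets_at_randomization(self):
        ds = generate_trial(TrialConfig(n_per_arm=30, seed=3, contact_threshold=0.3))
        for _, sub in ds.diary.groupby("patient_id"):
            fu = sub[sub.day >= 1].sort_values("day")
            assert (np.diff(fu.med_units) >= 0).all()
            assert fu.med_units.iloc[0] == 0  # pre-phase medication stopped


class TestOverrides:
    def test_zero_probabilities_leave_dataset_unchanged(self):
        ds = generate_trial(TrialConfig(n_per_arm=25, seed=4, override_probs=(0, 0, 0)))
        assert (ds.diary.override == "none").all()

    def test_certain_death_truncates_every_diary(self):
        ds = generate_trial(TrialConfig(n_per_arm=25, seed=5, override_probs=(0, 0, 1.0)))
        deaths = ds.diary[ds.diary.override == "death"]
        assert set(deaths.patient_id) == set(ds.patients.patient_id)
        for pid, sub in ds.diary.groupby("patient_id"):
            death_day = sub.loc[sub.override == "death", "day"].item()
            assert sub.day.max() == death_day

    def test_event_counts_match_binomial_expectation(self):
        """Probabilities (1/300, 10/300, 0) give ~1 unblinding and ~10 ACS
        per 300 patients."""
        totals = {"unblinding": 0, "acs": 0, "death": 0}
        reps = 12
        for s in range(reps):
            ds = generate_trial(
                TrialConfig(n_per_arm=150, seed=100 + s,
                            override_probs=(1 / 300, 10 / 300, 0.0))
            )
            counts = ds.diary.override.value_counts()
            for k in totals:
                totals[k] += int(counts.get(k, 0))
        assert totals["death"] == 0
        # Poisson-scale tolerance around expectations 12 and 120
        assert abs(totals["unblinding"] - reps) < 4 * np.sqrt(reps)
        assert abs(totals["acs"] - 10 * reps) < 4 * np.sqrt(10 * reps)


def test_every_randomized_patient_had_presymptoms(small_trial):
    pre = small_trial.diary[small_trial.diary.day < 0]
    totals = pre.groupby("patient_id").episodes.sum()
    assert (totals >= 1).all()
    assert set(totals.index) == set(small_trial.patients.patient_id)


class TestBlindingResponses:
    def test_all_dont_know(self):
        arms = np.array(["PCI"] * 40 + ["placebo"] * 40)
        tables = generate_blinding_responses(
            arms, {"PCI": 0.0, "placebo": 0.0}, 1.0, np.random.default_rng(0)
        )
        for arm, t in tables.items():
            assert t.dont_know == 40
            assert blinding_index(t)[0] == 0.0

    def test_certain_correct_guessing(self):
        arms = np.array(["PCI"] * 30 + ["placebo"] * 30)
        tables = generate_blinding_responses(
            arms, {"PCI": 1.0, "placebo": 1.0}, 0.0, np.random.default_rng(1)
        )
        for t in tables.values():
            assert blinding_index(t)[0] == 1.0

    def test_symmetric_probabilities_center_index_at_zero(self):
        arms = np.array(["PCI"] * 4000 + ["placebo"] * 4000)
        tables = generate_blinding_responses(
            arms, {"PCI": 0.25, "placebo": 0.25}, 0.5, np.random.default_rng(2)
        )
        for t in tables.values():
            bi, lo, hi = blinding_index(t)
            assert lo <= 0.0 <= hi
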