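"""Synthetic placebo-controlled angina trial generator.

Emulates the design whose analysis this package implements: a two-week
pre-randomization symptom assessment phase on no antianginal
medication, 1:1 block randomization of ~150 patients per arm to
intervention (PCI) or placebo, and a 12-week blinded follow-up with
daily symptom diaries.  Daily angina counts are overdispersed via a
patient-level gamma frailty multiplying a Poisson rate (a negative-
binomial marginal); assignment to PCI multiplies the post-
randomization rate by ``pci_rate_ratio``.  Antianginal medication is
initiated and uptitrated by a deterministic contact rule — one unit
step whenever the trailing weekly episode mean exceeds a threshold —
and all medication started pre-randomization stops on the day of
randomization.  Rare clinical events (unblinding for intolerable
angina, acute coronary syndrome, death) occur independently per patient
at a uniform random follow-up day; death truncates the diary.  Diary
days go missing completely at random at the observed per-day
completeness of such smartphone diaries (~99.7%).

All randomness flows from a single seeded generator, so a config fully
determines the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blinding import BlindingTable

ARMS = ("PCI", "placebo")
_BLOCK_SIZES = (8, 10, 12, 14, 16)


@dataclass(frozen=True)
class TrialConfig:
    """Generative parameters for one synthetic trial.

    Defaults reproduce the trial's reported conditions: ~150 patients
    per arm, 14 pre-randomization days, 84 follow-up days, a placebo
    daily episode rate of 0.7 with a PCI rate ratio of 0.43 (daily
    means 0.3 vs 0.7), override probabilities matching 1 unblinding and
    10 acute coronary syndromes per ~300 patients with no deaths, and
    0.3% missing diary days.
    """

    n_per_arm: int = 150
    pre_days: int = 14
    followup_days: int = 84
    baseline_daily_rate_mean: float = 0.7
    frailty_dispersion: float = 1.0
    pci_rate_ratio: float = 0.43
    contact_threshold: float = 2.5
    max_med_units: int = 4
    med_attenuation: float = 0.85
    override_probs: tuple[float, float, float] = (1 / 300, 10 / 300, 0.0)
    missing_day_prob: float = 0.003
    endpoint_missing_prob: float = 0.12
    correct_guess_prob: float = 0.20
    dont_know_prob: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if self.pre_days < 1:
            raise ValueError(
                f"pre_days must be >= 1 (randomization requires a symptomatic "
                f"assessment phase), got {self.pre_days}"
            )
        if self.followup_days < 1:
            raise ValueError(f"followup_days must be >= 1, got {self.followup_days}")
        if self.baseline_daily_rate_mean <= 0:
            raise ValueError(
                f"baseline_daily_rate_mean must be > 0, got {self.baseline_daily_rate_mean}"
            )
        if self.frailty_dispersion < 0:
            raise ValueError(
                f"frailty_dispersion must be >= 0, got {self.frailty_dispersion}"
            )
        if not 0 < self.pci_rate_ratio <= 1:
            raise ValueError(
                f"pci_rate_ratio must be in (0, 1], got {self.pci_rate_ratio}"
            )
        if self.contact_threshold <= 0:
            raise ValueError(
                f"contact_threshold must be > 0, got {self.contact_threshold}"
            )
        if not 0 < self.med_attenuation <= 1:
            raise ValueError(
                f"med_attenuation must be in (0, 1], got {self.med_attenuation}"
            )
        if self.max_med_units < 0:
            raise ValueError(f"max_med_units must be >= 0, got {self.max_med_units}")
        probs = list(self.override_probs) + [
            self.missing_day_prob,
            self.endpoint_missing_prob,
            self.correct_guess_prob,
            self.dont_know_prob,
        ]
        for p in probs:
            if not 0 <= p <= 1:
                raise ValueError(f"probabilities must be in [0, 1], got {p}")
        if sum(self.override_probs) > 1:
            raise ValueError("override_probs must sum to at most 1")
        if self.missing_day_prob >= 1:
            raise ValueError("missing_day_prob must be < 1")
        if self.correct_guess_prob + self.dont_know_prob > 1:
            raise ValueError("correct_guess_prob + dont_know_prob must be <= 1")


@dataclass
class Patient:
    """One randomized patient."""

    id: int
    arm: str
    frailty: float
    baseline_covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DailyDiaryRecord:
    """One patient-day: the atomic observation of the trial.

    ``day`` is negative pre-randomization and 1..followup_days during
    follow-up; ``episodes`` is NaN on missing diary days.
    """

    patient_id: int
    day: int
    episodes: float
    med_units: int
    override: str = "none"


@dataclass
class TrialDataset:
    """All tables of one simulated (or imported) trial."""

    config: TrialConfig
    patients: pd.DataFrame  # patient_id, arm, frailty
    diary: pd.DataFrame  # patient_id, day, episodes, med_units, override
    endpoints: pd.DataFrame  # patient_id, arm, baseline_*/followup_* columns
    blinding: pd.DataFrame  # respondent, timepoint, arm, guess counts


def block_randomize(n_total: int, rng: np.random.Generator) -> np.ndarray:
    """1:1 assignment in shuffled blocks of random size 8-16.

    The sequence is trimmed to ``n_total``, so arm totals can differ by
    at most half a block.
    """
    arms: list[str] = []
    while len(arms) < n_total:
        size = int(rng.choice(_BLOCK_SIZES))
        block = ["PCI"] * (size // 2) + ["placebo"] * (size // 2)
        rng.shuffle(block)
        arms.extend(block)
    return np.array(arms[:n_total])


def _daily_rate(config: TrialConfig, frailty, med_units, pci: np.ndarray | bool,
                post_randomization: bool):
    rate = config.baseline_daily_rate_mean * frailty
    rate = rate * config.med_attenuation ** np.asarray(med_units, dtype=float)
    if post_randomization:
        rate = rate * np.where(pci, config.pci_rate_ratio, 1.0)
    return rate


def simulate_daily_episodes(
    patient: Patient,
    day: int,
    config: TrialConfig,
    med_units: int = 0,
    rng: np.random.Generator | None = None,
) -> int:
    """Draw one day's angina episode count for one patient.

    The conditional distribution is Poisson with mean
    ``baseline_rate * frailty * attenuation^med_units``, times the PCI
    rate ratio after randomization; marginally over the gamma frailty
    this is negative binomial.
    """
    rng = rng if rng is not None else np.random.default_rng()
    rate = _daily_rate(
        config, patient.frailty, med_units, patient.arm == "PCI", day > 0
    )
    return int(rng.poisson(rate))


def simulate_medication_protocol(diary_so_far, config: TrialConfig) -> int:
    """Medication units for the next day under the contact rule.

    ``diary_so_far`` holds the current phase's records (any object with
    ``episodes`` and ``med_units`` fields, or a DataFrame with those
    columns).  If the mean episode count over the trailing seven
    observed days exceeds ``contact_threshold``, the dose steps up one
    unit toward ``max_med_units``; it never steps down within a phase.
    """
    if isinstance(diary_so_far, pd.DataFrame):
        episodes = diary_so_far["episodes"].to_numpy(dtype=float)
        current = int(diary_so_far["med_units"].iloc[-1]) if len(diary_so_far) else 0
    else:
        records = list(diary_so_far)
        episodes = np.array([r.episodes for r in records], dtype=float)
        current = int(records[-1].med_units) if records else 0
    if len(episodes) == 0:
        return 0
    window = episodes[-7:]
    window = window[~np.isnan(window)]
    if len(window) and window.mean() > config.contact_threshold:
        return min(current + 1, config.max_med_units)
    return current


def _simulate_phase(
    rng: np.random.Generator,
    config: TrialConfig,
    frailty: np.ndarray,
    pci: np.ndarray,
    n_days: int,
    post_randomization: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Episode and medication matrices (n_patients x n_days) for one phase.

    Medication starts at zero at the phase start (the protocol stops
    all pre-randomization antianginals on the day of randomization) and
    follows the vectorized contact rule day by day.
    """
    n = len(frailty)
    episodes = np.zeros((n, n_days))
    meds = np.zeros((n, n_days), dtype=np.int64)
    current = np.zeros(n, dtype=np.int64)
    for d in range(n_days):
        if d > 0:
            window = episodes[:, max(0, d - 7) : d]
            escalate = window.mean(axis=1) > config.contact_threshold
            current = np.minimum(
                current + escalate.astype(np.int64), config.max_med_units
            )
        meds[:, d] = current
        rate = _daily_rate(config, frailty, current, pci, post_randomization)
        episodes[:, d] = rng.poisson(rate)
    return episodes, meds


def _draw_frailty(rng: np.random.Generator, config: TrialConfig, n: int) -> np.ndarray:
    d = config.frailty_dispersion
    if d == 0:
        return np.ones(n)
    # gamma with mean 1 and variance d
    return rng.gamma(shape=1.0 / d, scale=d, size=n)


def inject_overrides(
    dataset: TrialDataset,
    config: TrialConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TrialDataset:
    """Assign at most one clinical override event per patient.

    Event type follows ``override_probs`` (unblinding, acs, death,
    mutually exclusive) and the event day is uniform over follow-up.
    A death removes all subsequent diary records.
    """
    config = config or dataset.config
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    diary = dataset.diary.copy()
    pu, pa, pd_ = config.override_probs
    for pid in dataset.patients["patient_id"]:
        u = rng.uniform()
        if u < pu:
            kind = "unblinding"
        elif u < pu + pa:
            kind = "acs"
        elif u < pu + pa + pd_:
            kind = "death"
        else:
            continue
        day = int(rng.integers(1, config.followup_days + 1))
        mask = (diary["patient_id"] == pid) & (diary["day"] == day)
        if not mask.any():
            continue
        diary.loc[mask, "override"] = kind
        if kind == "death":
            drop = (diary["patient_id"] == pid) & (diary["day"] > day)
            diary = diary[~drop]
    dataset.diary = diary.reset_index(drop=True)
    return dataset


def generate_blinding_responses(
    arms: np.ndarray,
    correct_guess_prob_by_arm: dict[str, float],
    dont_know_prob: float,
    rng: np.random.Generator | None = None,
) -> dict[str, BlindingTable]:
    """Simulate 5-category treatment guesses and tabulate them per arm.

    Each respondent guesses their assigned arm with the arm's
    ``correct_guess_prob``, answers "don't know" with
    ``dont_know_prob``, and otherwise guesses the other arm; sure and
    unsure guesses are equally likely within each direction.
    """
    rng = rng if rng is not None else np.random.default_rng()
    tables = {}
    for arm in ARMS:
        n = int(np.sum(arms == arm))
        pc = correct_guess_prob_by_arm[arm]
        pdk = dont_know_prob
        if pc + pdk > 1:
            raise ValueError("correct and don't-know probabilities exceed 1")
        pi = 1 - pc - pdk
        counts = rng.multinomial(n, [pc / 2, pc / 2, pdk, pi / 2, pi / 2])
        tables[arm] = BlindingTable(*[int(c) for c in counts])
    return tables


def _blinding_frame(
    rng: np.random.Generator, config: TrialConfig, arms: np.ndarray
) -> pd.DataFrame:
    rows = []
    for respondent in ("patient", "staff"):
        for timepoint in ("randomization", "followup"):
            tables = generate_blinding_responses(
                arms,
                {a: config.correct_guess_prob for a in ARMS},
                config.dont_know_prob,
                rng,
            )
            for arm, t in tables.items():
                rows.append(
                    {
                        "respondent": respondent,
                        "timepoint": timepoint,
                        "arm": arm,
                        "correct_sure": t.correct_sure,
                        "correct_unsure": t.correct_unsure,
                        "dont_know": t.dont_know,
                        "incorrect_unsure": t.incorrect_unsure,
                        "incorrect_sure": t.incorrect_sure,
                    }
                )
    return pd.DataFrame(rows)


def _simulate_endpoints(
    rng: np.random.Generator, config: TrialConfig, arms: np.ndarray, frailty: np.ndarray
) -> pd.DataFrame:
    """Endpoint-level Gaussian/ordinal draws with arm effects.

    These emulate the marginal behaviour of the trial's secondary
    endpoints (treadmill seconds, questionnaire scores, CCS class,
    quality-of-life utility, stress-echo ischemia score); they are
    drawn at the endpoint level rather than derived mechanistically.
    """
    n = len(arms)
    pci = arms == "PCI"
    sev = np.log(np.clip(frailty, 0.05, None))  # shared severity driver

    base_tread = np.clip(rng.normal(590, 160, n) - 40 * sev, 60, None)
    fu_tread = base_tread + np.where(pci, 110, 50) + rng.normal(0, 150, n)

    base_saq = np.clip(rng.normal(55, 16, n) - 8 * sev, 0, 100)
    fu_saq = np.clip(base_saq + np.where(pci, 35, 15) + rng.normal(0, 15, n), 0, 100)

    base_eq = np.clip(rng.normal(0.70, 0.16, n) - 0.05 * sev, -0.2, 1.0)
    fu_eq = np.clip(base_eq + np.where(pci, 0.12, 0.03) + rng.normal(0, 0.10, n), -0.2, 1.0)

    base_ccs = rng.choice([1, 2, 3, 4], size=n, p=[0.02, 0.55, 0.41, 0.02])
    fu_ccs = np.where(
        pci,
        rng.choice([0, 1, 2, 3, 4], size=n, p=[0.45, 0.30, 0.15, 0.08, 0.02]),
        rng.choice([0, 1, 2, 3, 4], size=n, p=[0.20, 0.25, 0.30, 0.20, 0.05]),
    )

    base_echo = np.clip(rng.normal(2.6, 1.5, n) + 0.5 * sev, 0, None)
    fu_echo = np.clip(
        0.25 * base_echo + np.where(pci, 0.1, 1.2) + rng.normal(0, 0.9, n), 0, None
    )

    miss = rng.uniform(size=(2, n)) < config.endpoint_missing_prob
    fu_tread = np.where(miss[0], np.nan, fu_tread)
    fu_echo = np.where(miss[1], np.nan, fu_echo)

    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "arm": arms,
            "baseline_treadmill_seconds": base_tread,
            "followup_treadmill_seconds": fu_tread,
            "baseline_saq_angina_frequency": base_saq,
            "followup_saq_angina_frequency": fu_saq,
            "baseline_eq5d_index": base_eq,
            "followup_eq5d_index": fu_eq,
            "baseline_ccs_class": base_ccs,
            "followup_ccs_class": fu_ccs,
            "baseline_stress_echo_score": base_echo,
            "followup_stress_echo_score": fu_echo,
        }
    )


def generate_trial(config: TrialConfig) -> TrialDataset:
    """Simulate one complete trial dataset.

    Deterministic given ``config.seed``.  Patients whose simulated
    pre-randomization phase contains no angina episode do not meet the
    randomization criterion and are redrawn (the trial withdrew
    asymptomatic patients before randomization).
    """
    rng = np.random.default_rng(config.seed)
    n_total = 2 * config.n_per_arm
    arms = block_randomize(n_total, rng)
    pci = arms == "PCI"
    frailty = _draw_frailty(rng, config, n_total)

    pre_ep, pre_med = _simulate_phase(
        rng, config, frailty, pci, config.pre_days, post_randomization=False
    )
    # redraw asymptomatic patients until every retained patient qualifies
    for _ in range(1000):
        bad = pre_ep.sum(axis=1) < 1
        if not bad.any():
            break
        idx = np.where(bad)[0]
        frailty[idx] = _draw_frailty(rng, config, len(idx))
        new_ep, new_med = _simulate_phase(
            rng, config, frailty[idx], pci[idx], config.pre_days, False
        )
        pre_ep[idx] = new_ep
        pre_med[idx] = new_med
    else:
        raise RuntimeError("could not generate symptomatic pre-randomization phases")

    fu_ep, fu_med = _simulate_phase(
        rng, config, frailty, pci, config.followup_days, post_randomization=True
    )

    # assemble long diary; MCAR missing diary days
    n_days = config.pre_days + config.followup_days
    days = np.concatenate(
        [np.arange(-config.pre_days, 0), np.arange(1, config.followup_days + 1)]
    )
    episodes = np.concatenate([pre_ep, fu_ep], axis=1).astype(float)
    meds = np.concatenate([pre_med, fu_med], axis=1)
    missing = rng.uniform(size=episodes.shape) < config.missing_day_prob
    # never blank the whole pre-phase: keep the first symptomatic day
    first_sym = np.argmax(pre_ep >= 1, axis=1)
    missing[np.arange(n_total), first_sym] = False
    episodes[missing] = np.nan

    diary = pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(n_total), n_days),
            "day": np.tile(days, n_total),
            "episodes": episodes.ravel(),
            "med_units": meds.ravel(),
            "override": "none",
        }
    )
    patients = pd.DataFrame(
        {"patient_id": np.arange(n_total), "arm": arms, "frailty": frailty}
    )
    endpoints = _simulate_endpoints(rng, config, arms, frailty)
    blinding = _blinding_frame(rng, config, arms)

    dataset = TrialDataset(
        config=config,
        patients=patients,
        diary=diary,
        endpoints=endpoints,
        blinding=blinding,
    )
    return inject_overrides(dataset, config, rng)
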