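"""Plain-text readers and writers for trial tables.

A trial lives in a directory of four tab-separated tables plus a YAML
config sidecar::

    patients.tsv   patient_id  arm  frailty
    diary.tsv      patient_id  day  episodes  med_units  override
    endpoints.tsv  patient_id  arm  baseline_* / followup_* ...
    blinding.tsv   respondent  timepoint  arm  <guess counts>
    config.yaml    generative parameters (round-trippable)

Real data in the same schema can be read back with
:func:`read_trial`; ``write_trial`` then ``read_trial`` is the
identity on valid tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .simulate import TrialConfig, TrialDataset

_REQUIRED = {
    "patients.tsv": ["patient_id", "arm", "frailty"],
    "diary.tsv": ["patient_id", "day", "episodes", "med_units", "override"],
    "endpoints.tsv": ["patient_id", "arm"],
    "blinding.tsv": [
        "respondent",
        "timepoint",
        "arm",
        "correct_sure",
        "correct_unsure",
        "dont_know",
        "incorrect_unsure",
        "incorrect_sure",
    ],
}


def write_trial(dataset: TrialDataset, directory) -> Path:
    """Write all trial tables and the config sidecar to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        "patients.tsv": dataset.patients,
        "diary.tsv": dataset.diary,
        "endpoints.tsv": dataset.endpoints,
        "blinding.tsv": dataset.blinding,
    }
    for name, frame in tables.items():
        frame.to_csv(directory / name, sep="\t", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(dataset.config), fh, sort_keys=True)
    return directory


def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / name
    if not path.exists():
        raise FileNotFoundError(f"missing trial table: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED[name] if c not in frame.columns]
    if missing:
        raise ValueError(f"{name}: missing required column(s) {missing}")
    return frame


def read_trial(directory) -> TrialDataset:
    """Read a trial directory written by :func:`write_trial`."""
    directory = Path(directory)
    config_path = directory / "config.yaml"
    if not config_path.exists():
        raise FileNotFoundError(f"missing trial config: {config_path}")
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if "override_probs" in raw:
        raw["override_probs"] = tuple(raw["override_probs"])
    config = TrialConfig(**raw)
    return TrialDataset(
        config=config,
        patients=_read_table(directory, "patients.tsv"),
        diary=_read_table(directory, "diary.tsv"),
        endpoints=_read_table(directory, "endpoints.tsv"),
        blinding=_read_table(directory, "blinding.tsv"),
    )


def write_scores(scores: pd.DataFrame, path) -> Path:
    """Write the per-patient score table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(path, sep="\t", index=False)
    return path
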