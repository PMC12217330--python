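"""WAV, CSV and JSON interchange.

The CSV schema is the interchange contract between the acoustics and
statistics layers: one row per subject × state, one column per canonical
biomarker name, so either half of the package can be used on its own.
WAV files follow the naming convention ``{subject}_{state}_{task}.wav``
(optionally ``..._{task}{repeat}.wav`` for repeated tasks).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from levospeech.acoustics import FEATURE_NAMES, Waveform
from levospeech.synthgen import RATE, PairedCohortTable

logger = logging.getLogger(__name__)

_WAV_RE = re.compile(r"(?P<subject>.+)_(?P<state>OFF|ON|HC)_(?P<task>phon|ddk|text)(?P<rep>\d*)\.wav$")

CLINICAL_COLUMNS = [
    *[f"updrs3_{i:02d}" for i in range(1, 19)],
    "updrs3_total", "updrs3_no_tremor", "updrs3_brady", "updrs3_rigidity",
    "updrs3_axial", "updrs3_tremor", "marconi_axial", "updrs1", "updrs2", "updrs4",
]
DEMOGRAPHIC_COLUMNS = ["age", "gender", "language", "moca", "disease_duration"]


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write 16-bit PCM RIFF WAV."""
    samples = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(str(path), int(w.rate), (samples * 32767.0).astype(np.int16))


def read_wav(path: str | Path, task: str) -> Waveform:
    """Read a RIFF PCM WAV; resample to the 48 kHz analysis rate if needed."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    if rate != RATE:
        from math import gcd

        g = gcd(int(RATE), int(rate))
        data = resample_poly(data, int(RATE) // g, int(rate) // g)
        logger.info("resampled %s from %d Hz to %d Hz", path, rate, int(RATE))
    return Waveform(samples=data, rate=RATE, task=task)


def scan_wav_dir(audio_dir: str | Path) -> dict[tuple[str, str], dict[str, list[Path]]]:
    """Group WAV paths by (subject, state) -> task -> ordered repeat paths."""
    out: dict[tuple[str, str], dict[str, list[Path]]] = {}
    for path in sorted(Path(audio_dir).glob("*.wav")):
        m = _WAV_RE.match(path.name)
        if not m:
            logger.warning("skipping unrecognized WAV name %s", path.name)
            continue
        key = (m["subject"], m["state"])
        out.setdefault(key, {}).setdefault(m["task"], []).append(path)
    return out


def write_features_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Feature table with subject/state metadata and the 16 canonical columns."""
    cols = ["subject", "state"] + [c for c in FEATURE_NAMES if c in frame.columns]
    frame.loc[:, cols].to_csv(path, index=False)


def cohort_to_frames(table: PairedCohortTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort table into (features, clinical) long-format frames."""
    rows_f, rows_c = [], []
    for state, feats, clin in (
        ("OFF", table.features_off, table.clinical_off),
        ("ON", table.features_on, table.clinical_on),
    ):
        f = feats.copy()
        f.insert(0, "subject", [f"pd{i:03d}" for i in feats.index])
        f.insert(1, "state", state)
        rows_f.append(f)
        c = clin.copy()
        c = pd.concat([c, table.demographics], axis=1)
        c.insert(0, "subject", [f"pd{i:03d}" for i in clin.index])
        c.insert(1, "state", state)
        rows_c.append(c)
    if table.hc_features is not None:
        f = table.hc_features.copy()
        f.insert(0, "subject", [f"hc{i:03d}" for i in table.hc_features.index])
        f.insert(1, "state", "HC")
        rows_f.append(f)
        c = table.hc_covariates.copy()
        c.insert(0, "subject", [f"hc{i:03d}" for i in table.hc_covariates.index])
        c.insert(1, "state", "HC")
        rows_c.append(c)
    return (
        pd.concat(rows_f, ignore_index=True),
        pd.concat(rows_c, ignore_index=True),
    )


def write_cohort_csv(
    table: PairedCohortTable, features_path: str | Path, clinical_path: str | Path
) -> None:
    features, clinical = cohort_to_frames(table)
    features.to_csv(features_path, index=False)
    clinical.to_csv(clinical_path, index=False)


def read_cohort_csv(
    features_path: str | Path, clinical_path: str | Path
) -> PairedCohortTable:
    """Rebuild a cohort table from the long-format CSV pair."""
    features = pd.read_csv(features_path)
    clinical = pd.read_csv(clinical_path)
    for frame, path in ((features, features_path), (clinical, clinical_path)):
        if not {"subject", "state"} <= set(frame.columns):
            raise ValueError(f"{path}: need 'subject' and 'state' columns")

    def split(frame: pd.DataFrame, state: str) -> pd.DataFrame:
        part = frame[frame["state"] == state].set_index("subject").drop(columns="state")
        return part.sort_index()

    f_off, f_on = split(features, "OFF"), split(features, "ON")
    c_off, c_on = split(clinical, "OFF"), split(clinical, "ON")
    missing = set(f_off.index) ^ set(f_on.index)
    if missing:
        raise ValueError(f"subjects without both states: {sorted(missing)}")
    feat_cols = [c for c in FEATURE_NAMES if c in f_off.columns]
    demo = c_off[[c for c in DEMOGRAPHIC_COLUMNS if c in c_off.columns]]
    clin_cols = [c for c in c_off.columns if c not in DEMOGRAPHIC_COLUMNS]

    hc_features = hc_cov = None
    if (features["state"] == "HC").any():
        hc_features = split(features, "HC")[feat_cols]
        hc_cov = split(clinical, "HC")
    return PairedCohortTable(
        features_off=f_off[feat_cols],
        features_on=f_on[feat_cols],
        clinical_off=c_off[clin_cols],
        clinical_on=c_on[clin_cols],
        demographics=demo,
        hc_features=hc_features,
        hc_covariates=hc_cov,
    )


def write_truth_json(table: PairedCohortTable, path: str | Path) -> None:
    """Ground-truth sidecar: latent responses and planted loadings."""
    if table.truth is None:
        raise ValueError("cohort table carries no ground truth")
    truth = table.truth
    payload = {
        "D": list(np.asarray(truth["D"], dtype=float)),
        "K": list(np.asarray(truth["K"], dtype=float)),
        "planted_hypo": truth["planted_hypo"],
        "planted_hyper": truth["planted_hyper"],
        "spec": {
            k: v for k, v in vars(truth["spec"]).items()
            if isinstance(v, (int, float, str, dict, list, tuple, type(None)))
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def write_report_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    return str(obj)
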