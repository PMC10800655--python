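"""Assembly of the labeled observation table.

One row per (subject, phase, quadrant) analysis window; 57 feature columns
(12 EEG + 9 HRV + 2 BVP + 17 GSR + 8 RESP + 9 pupil) plus metadata. For the
full 22-subject cohort this is 264 rows, 12 per subject. Extractor failures
never drop a row: the affected cells are NaN and the failure is recorded in
the ``flags`` column.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardio, eda, eeg, pupil, resp
from .protocol import Quadrant, analysis_windows
from .synthetic import MONTAGE, RecordingSet

__all__ = [
    "FEATURE_NAMES",
    "METADATA_COLUMNS",
    "extract_window",
    "assemble",
    "split_by_subject",
    "save_table",
    "load_table",
]

HRV_FEATURE_NAMES = tuple(f"hrv_{f}" for f in cardio.HRV_FIELDS)
BVP_FEATURE_NAMES = ("bvp_vp", "bvp_pat")

FEATURE_NAMES: tuple[str, ...] = (
    eeg.EEG_FEATURE_NAMES
    + HRV_FEATURE_NAMES
    + BVP_FEATURE_NAMES
    + eda.GSR_FEATURE_NAMES
    + resp.RESP_FEATURE_NAMES
    + pupil.PUPIL_FEATURE_NAMES
)
assert len(FEATURE_NAMES) == 57

METADATA_COLUMNS = ("subject_id", "phase", "session", "valence_half", "quadrant", "flags")


def extract_window(rec: RecordingSet, window) -> dict:
    """Run all six extractors on one analysis window of one recording."""
    feats: dict[str, float] = {name: np.nan for name in FEATURE_NAMES}
    flags: list[str] = []

    def attempt(fn, tag):
        try:
            return fn()
        except Exception as exc:  # failures become flagged missing cells
            flags.append(f"{tag}:{type(exc).__name__}")
            return None

    eeg_out = attempt(
        lambda: eeg.eeg_feature_vector(rec.slice("EEG", window), rec.rates["EEG"], MONTAGE),
        "eeg")
    if eeg_out:
        feats.update(eeg_out)

    ecg_slice = rec.slice("ECG", window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beats = attempt(lambda: cardio.detect_r_peaks(ecg_slice, rec.rates["ECG"]), "rpeaks")
    if beats is not None and len(beats) >= 14:
        hrv = attempt(lambda: cardio.fit_ig_pointprocess(beats), "hrv")
        if hrv:
            flags.extend(hrv.flags)
            feats.update({f"hrv_{k}": v for k, v in hrv.as_dict().items()})
        bvp_out = attempt(
            lambda: cardio.bvp_fiducials(rec.slice("BVP", window), rec.rates["BVP"], beats),
            "bvp")
        if bvp_out:
            fid, _ = bvp_out
            bf = cardio.bvp_features(fid, beats)
            flags.extend(bf.flags)
            feats["bvp_vp"], feats["bvp_pat"] = bf.vp, bf.pat
    else:
        flags.append("too_few_beats")

    gsr_out = attempt(
        lambda: eda.gsr_feature_vector(rec.slice("GSR", window), rec.rates["GSR"]), "gsr")
    if gsr_out:
        g, gflags = gsr_out
        feats.update(g)
        flags.extend(gflags)

    if beats is not None and len(beats) >= 2:
        resp_out = attempt(
            lambda: resp.resp_feature_vector(
                rec.slice("RESP", window), rec.rates["RESP"],
                cardio.BeatSeries(beats.r_times)), "resp")
        if resp_out:
            r, rflags = resp_out
            feats.update(r)
            flags.extend(rflags)

    pupil_out = attempt(
        lambda: pupil.pupil_feature_vector(
            pupil.PupilTrace(rec.slice("PUPIL_L", window), rec.slice("PUPIL_R", window),
                             rec.rates["PUPIL_L"])), "pupil")
    if pupil_out:
        p, pflags = pupil_out
        feats.update(p)
        flags.extend(pflags)

    return {
        "subject_id": rec.subject_id,
        "phase": window.phase.value,
        "session": window.session.value,
        "valence_half": window.valence_half.value,
        "quadrant": window.quadrant.value,
        "flags": ";".join(flags),
        **feats,
    }


def assemble(recordings: list[RecordingSet]) -> pd.DataFrame:
    """Build the observation table: one row per labeled 45 s window.

    A2/A3 windows carry no class label and are excluded. Column order is the
    frozen registry order.
    """
    rows = []
    for rec in recordings:
        for w in analysis_windows(rec.timeline):
            if w.phase != rec.phase:
                continue
            rows.append(extract_window(rec, w))
    df = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))
    return df


def split_by_subject(
    table: pd.DataFrame, n_test_subjects: int = 7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leakage-guarded split: every row of a subject lands on one side only."""
    subjects = np.array(sorted(table["subject_id"].unique()))
    if n_test_subjects >= len(subjects):
        raise ValueError("n_test_subjects must be smaller than the cohort")
    rng = np.random.default_rng(seed)
    test_subjects = set(rng.choice(subjects, size=n_test_subjects, replace=False))
    is_test = table["subject_id"].isin(test_subjects)
    return table[~is_test].copy(), table[is_test].copy()


FLOAT_FORMAT = "%.17g"  # exact binary round-trip


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the table as CSV plus a JSON schema sidecar."""
    path = Path(path)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    schema = {
        "metadata_columns": list(METADATA_COLUMNS),
        "feature_columns": list(FEATURE_NAMES),
        "float_format": FLOAT_FORMAT,
        "registry_sizes": {"eeg": 12, "hrv": 9, "bvp": 2, "gsr": 17, "resp": 8, "pupil": 9},
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))


def load_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True, float_precision="round_trip")
    df["flags"] = df["flags"].fillna("")
    return df


def class_counts(table: pd.DataFrame) -> pd.Series:
    """Rows per quadrant (balanced designs give equal counts)."""
    labeled = [q.value for q in Quadrant if q is not Quadrant.NONE]
    return table["quadrant"].value_counts().reindex(labeled).fillna(0).astype(int)
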