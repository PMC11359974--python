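"""CSV/YAML readers and writers for trial traces, manifests and reports.

Trace files are plain comma-separated text with a header row: ``time_s``
(seconds, uniform step), ``force_n`` (newtons) and optionally ``emg_v``
(volts) — the form any lab acquisition export (e.g. Spike2) converts to
trivially. A study is a directory of trace files plus a YAML manifest
mapping each file to its (subject, session, trial) identifiers.

Report rounding follows the conventions of published reliability tables:
ICC and CI to 2 decimals, SEM to 2 significant figures, SEM% to the
nearest integer, session summaries as mean±SD.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .reliability import ReliabilityResult
from .types import SignalTrace, StudyDataset, TrialRecording, Units

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_manifest",
    "write_study",
    "load_study",
    "report_records",
    "report_frame",
    "write_report",
]

MAX_JITTER_FRACTION = 0.01

TIME_COL = "time_s"
FORCE_COL = "force_n"
EMG_COL = "emg_v"


def read_trial_csv(
    path: str | Path,
    *,
    subject_id: str,
    session: int,
    trial: int,
) -> TrialRecording:
    """Read one trial's traces from CSV.

    The sampling rate is inferred from the median time step; time steps
    deviating from it by more than 1% raise a non-uniform-sampling error.
    A missing ``emg_v`` column yields a recording without EMG; a missing
    ``force_n`` column is an error.
    """
    df = pd.read_csv(path)
    if TIME_COL not in df.columns:
        raise ValueError(f"{path}: missing {TIME_COL!r} column")
    if FORCE_COL not in df.columns:
        raise ValueError(f"{path}: missing {FORCE_COL!r} column")
    t = df[TIME_COL].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: time must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > MAX_JITTER_FRACTION * step:
        raise ValueError(f"{path}: non-uniform sampling (jitter beyond 1% of the median step)")
    rate = 1.0 / step

    force = SignalTrace(df[FORCE_COL].to_numpy(dtype=float), rate, Units.NEWTON)
    emg = None
    if EMG_COL in df.columns:
        emg = SignalTrace(df[EMG_COL].to_numpy(dtype=float), rate, Units.VOLT)
    return TrialRecording(subject_id=subject_id, session=session, trial=trial, force=force, emg=emg)


def write_trial_csv(trial: TrialRecording, path: str | Path) -> None:
    """Write one trial's traces to CSV (full float precision, round-trip safe)."""
    cols = {TIME_COL: trial.force.times_s, FORCE_COL: trial.force.samples}
    if trial.emg is not None:
        cols[EMG_COL] = trial.emg.samples
    pd.DataFrame(cols).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[dict]:
    """Load a YAML manifest: a list of {file, subject, session, trial} entries."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["trials"] if isinstance(doc, dict) else doc
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"{path}: manifest must list at least one trial")
    for e in entries:
        missing = {"file", "subject", "session", "trial"} - set(e)
        if missing:
            raise ValueError(f"{path}: manifest entry missing keys {sorted(missing)}")
    return entries


def write_study(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write every trial to ``out_dir`` as CSV plus a ``manifest.yaml``.

    Returns the manifest path. File names encode the identifiers
    (``<subject>_s<session>_t<trial>.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in dataset.trials:
        fname = f"{trial.subject_id}_s{trial.session}_t{trial.trial}.csv"
        write_trial_csv(trial, out_dir / fname)
        entries.append(
            {
                "file": fname,
                "subject": trial.subject_id,
                "session": trial.session,
                "trial": trial.trial,
            }
        )
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"trials": entries, "meta": dataset.manifest.get("study_params", {})}, fh)
    return manifest_path


def load_study(manifest_path: str | Path) -> StudyDataset:
    """Load a full study from its manifest; file paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    entries = read_manifest(manifest_path)
    trials = [
        read_trial_csv(
            manifest_path.parent / e["file"],
            subject_id=str(e["subject"]),
            session=int(e["session"]),
            trial=int(e["trial"]),
        )
        for e in entries
    ]
    return StudyDataset(trials=trials, manifest={"source": str(manifest_path)})


# --- report serialization ---------------------------------------------------


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def report_records(results: Sequence[ReliabilityResult]) -> list[dict]:
    """Rounded numeric report rows (shared by the CSV and JSON writers)."""
    if len(results) == 0:
        raise ValueError("cannot write an empty report")
    records = []
    for r in results:
        records.append(
            {
                "outcome": r.outcome_name,
                "aggregation": r.aggregation.value,
                "n": r.n,
                "mean_session1": float(f"{r.mean_session1:.4g}"),
                "sd_session1": float(f"{r.sd_session1:.4g}"),
                "mean_session2": float(f"{r.mean_session2:.4g}"),
                "sd_session2": float(f"{r.sd_session2:.4g}"),
                "icc": round(r.icc, 2),
                "ci_low": round(r.ci_low, 2),
                "ci_high": round(r.ci_high, 2),
                "sem": _round_sig(r.sem, 2),
                "sem_pct": int(round(r.sem_pct)),
                "class_point": r.class_point.value,
                "class_lower": r.class_lower.value,
                "log_transformed": bool(r.log_transformed),
            }
        )
    return records


def _fmt_num(x: float) -> str:
    return f"{x:.4g}"


def report_frame(results: Sequence[ReliabilityResult]) -> pd.DataFrame:
    """Human-readable report table in the style of published Table-1 layouts."""
    rows = []
    for rec in report_records(results):
        rows.append(
            {
                "outcome": rec["outcome"],
                "aggregation": rec["aggregation"],
                "n": rec["n"],
                "session1_mean_sd": f"{_fmt_num(rec['mean_session1'])}±{_fmt_num(rec['sd_session1'])}",
                "session2_mean_sd": f"{_fmt_num(rec['mean_session2'])}±{_fmt_num(rec['sd_session2'])}",
                "icc_ci": f"{rec['icc']:.2f} [{rec['ci_low']:.2f}, {rec['ci_high']:.2f}]",
                "sem": f"{rec['sem']:g}",
                "sem_pct": str(rec["sem_pct"]),
                "classification": f"{rec['class_point']} ({rec['class_lower']})",
                "log_transformed": str(rec["log_transformed"]).lower(),
            }
        )
    return pd.DataFrame(rows)


def write_report(
    results: Sequence[ReliabilityResult],
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write the reliability report as display CSV and numeric JSON.

    When ``json_path`` is omitted it defaults to the CSV path with a
    ``.json`` suffix. Both carry identical (rounded) numeric content.
    """
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path is not None else csv_path.with_suffix(".json")
    report_frame(results).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(report_records(results), fh, indent=2)
        fh.write("\n")
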