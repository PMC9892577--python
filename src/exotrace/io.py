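"""File round-trips: traces, event tables, FASTA sequences, reference bundles.

Traces travel either as two-column tabular text (time_s, current_nA)
with a ``# key: value`` metadata header, or as an ``.npz`` container
holding the same arrays plus the ground truth.  Event tables are TSV.
All dwell times are stored in seconds and currents in nA.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .fingerprint import FingerprintClassifier
from .models import CurrentTrace, GroundTruth, ReadTruth, validate_sequence

EVENT_COLUMNS = ["state", "start_s", "dwell_s", "mean_current_nA"]


class FileFormatError(ValueError):
    """Malformed input file, with a line-numbered diagnostic."""


# -- traces -----------------------------------------------------------------

def write_trace_tsv(trace: CurrentTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate!r}\n")
        for k, v in trace.metadata.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_s\tcurrent_nA\n")
        np.savetxt(fh, np.column_stack([trace.times, trace.currents]),
                   fmt="%.9g", delimiter="\t")


def read_trace_tsv(path: str | Path) -> CurrentTrace:
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                break
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # locate the offending line for the user
        _diagnose_lines(path, expected_cols=2)
        raise FileFormatError(f"{path}: {exc}") from exc
    if not {"time_s", "current_nA"} <= set(df.columns):
        raise FileFormatError(
            f"{path}, line {header_lines + 1}: expected columns "
            f"time_s, current_nA; got {list(df.columns)}")
    if df[["time_s", "current_nA"]].isna().any().any():
        _diagnose_lines(path, expected_cols=2)
        raise FileFormatError(f"{path}: unparseable numeric values")
    fs = float(meta.pop("sampling_rate_hz", 0)) or None
    times = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        steps = np.diff(times)
        if steps.size and np.ptp(steps) > 1e-9 * steps.mean():
            raise FileFormatError(f"{path}: non-uniform time grid")
        fs = 1.0 / steps.mean() if steps.size else 1.0
    return CurrentTrace(df["current_nA"].to_numpy(dtype=float), fs, meta)


def _diagnose_lines(path: Path, expected_cols: int) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != expected_cols:
                raise FileFormatError(
                    f"{path}, line {i}: expected {expected_cols} "
                    f"tab-separated fields, got {line!r}")


def write_trace_npz(path: str | Path, trace: CurrentTrace,
                    truth: GroundTruth | None = None) -> None:
    """Binary container with the trace arrays and optional ground truth."""
    payload = {
        "currents": trace.currents,
        "sampling_rate": np.array(trace.sampling_rate),
        "metadata_json": np.array(json.dumps(trace.metadata, default=str)),
    }
    if truth is not None:
        payload.update(
            state_path=truth.state_path,
            event_boundaries=truth.event_boundaries,
            event_states=truth.event_states,
            read_bases=np.array(["".join(r.step_bases) for r in truth.reads]),
            read_spans=np.array([[r.start_sample, r.end_sample]
                                 for r in truth.reads], dtype=np.int64
                                ).reshape(-1, 2),
        )
    np.savez_compressed(path, **payload)


def read_trace_npz(path: str | Path
                   ) -> tuple[CurrentTrace, GroundTruth | None]:
    with np.load(path, allow_pickle=False) as z:
        trace = CurrentTrace(z["currents"], float(z["sampling_rate"]),
                             json.loads(str(z["metadata_json"])))
        truth = None
        if "state_path" in z:
            reads = [ReadTruth(list(bases), int(span[0]), int(span[1]))
                     for bases, span in zip(z["read_bases"], z["read_spans"])]
            truth = GroundTruth(z["state_path"], z["event_boundaries"],
                                z["event_states"], reads)
    return trace, truth


# -- event tables -----------------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {sorted(missing)}")
    sort_cols = [c for c in ("read_id", "start_s") if c in df.columns]
    return df.sort_values(sort_cols, kind="stable").reset_index(drop=True)


# -- sequences --------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id; T is mapped to U with a warning."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if "T" in raw.upper():
            warnings.warn(f"{path}:{rec.id}: DNA alphabet detected; "
                          "mapping T -> U")
        out[rec.id] = validate_sequence(raw)
    if not out:
        raise FileFormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


# -- reference library ------------------------------------------------------

def write_reference_bundle(path: str | Path,
                           classifier: FingerprintClassifier,
                           obs_by_base: dict[str, pd.DataFrame]) -> None:
    """Self-describing bundle: raw reference observations + grid metadata."""
    grid = classifier.library_.grid
    payload = {"grid_json": np.array(json.dumps(vars(grid))),
               "margin_threshold": np.array(classifier.margin_threshold),
               "metric": np.array(classifier.metric)}
    for base, obs in obs_by_base.items():
        payload[f"obs_{base}"] = obs[["dwell", "current"]].to_numpy(float)
    np.savez_compressed(path, **payload)


def read_reference_bundle(path: str | Path
                          ) -> tuple[FingerprintClassifier,
                                     dict[str, pd.DataFrame]]:
    from .fingerprint import FingerprintGrid
    with np.load(path, allow_pickle=False) as z:
        grid = FingerprintGrid(**json.loads(str(z["grid_json"])))
        clf = FingerprintClassifier(metric=str(z["metric"]),
                                    margin_threshold=float(z["margin_threshold"]),
                                    grid=grid)
        obs_by_base = {}
        X_all, y_all = [], []
        for key in z.files:
            if key.startswith("obs_"):
                base = key[4:]
                arr = z[key]
                obs_by_base[base] = pd.DataFrame(
                    {"dwell": arr[:, 0], "current": arr[:, 1]})
                X_all.append(arr)
                y_all.extend([base] * arr.shape[0])
    clf.fit(np.vstack(X_all), np.array(y_all))
    return clf, obs_by_base
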