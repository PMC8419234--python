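"""Reading and writing recordings and cohort artifacts.

Recordings travel as EDF (one file per subject) with a JSON sidecar holding
channel labels, the ROI definition and the generator seed; cohort targets
as CSV and ground truth as JSON.  EDF reading goes through MNE.  Writing
uses a minimal EDF encoder implemented here, since no installed library
exports EDF; the encoding is round-trip checked against MNE's reader in the
test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PreprocessError, RawRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise PreprocessError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path: str | Path, *,
              patient: str = "X", recording: str = "eeg2tms") -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    Requires an integer sampling rate and an integer number of seconds.
    Quantisation to the per-channel 16-bit physical range costs < 0.01 μV
    on typical amplitudes.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise PreprocessError("EDF writer needs an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise PreprocessError("EDF writer needs a whole number of seconds")
    n_records = rec.n_samples // fs
    n_sig = rec.n_channels

    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmins[flat] -= 0.5
    pmaxs[flat] += 0.5

    header = b"".join([
        _ascii_field(0, 8),
        _ascii_field(patient, 80),
        _ascii_field(recording, 80),
        _ascii_field("01.01.01", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(256 * (n_sig + 1), 8),
        _ascii_field("", 44),
        _ascii_field(n_records, 8),
        _ascii_field(1, 8),
        _ascii_field(n_sig, 4),
    ])
    sig_header = b"".join([
        b"".join(_ascii_field(lab, 16) for lab in rec.channel_labels),
        b"".join(_ascii_field("AgAgCl electrode", 80) for _ in range(n_sig)),
        b"".join(_ascii_field("uV", 8) for _ in range(n_sig)),
        b"".join(_ascii_field(f"{p:.8g}"[:8], 8) for p in pmins),
        b"".join(_ascii_field(f"{p:.8g}"[:8], 8) for p in pmaxs),
        b"".join(_ascii_field(_DIG_MIN, 8) for _ in range(n_sig)),
        b"".join(_ascii_field(_DIG_MAX, 8) for _ in range(n_sig)),
        b"".join(_ascii_field("", 80) for _ in range(n_sig)),
        b"".join(_ascii_field(fs, 8) for _ in range(n_sig)),
        b"".join(_ascii_field("", 32) for _ in range(n_sig)),
    ])
    # re-read the (precision-limited) header values so writer and reader
    # agree on the scaling
    pmins = np.array([float(f"{p:.8g}"[:8]) for p in pmins])
    pmaxs = np.array([float(f"{p:.8g}"[:8]) for p in pmaxs])
    scale = (pmaxs - pmins) / (_DIG_MAX - _DIG_MIN)
    digital = np.round(
        (rec.data - pmins[:, None]) / scale[:, None] + _DIG_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF file into a RawRecording (μV) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds volts
    return RawRecording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))


def write_cohort(
    recordings, targets: pd.DataFrame, truth, config, out_dir: str | Path
) -> Path:
    """Write a simulated cohort: per-subject EDF + JSON sidecar, targets
    CSV, ground-truth JSON, and the generator config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roi = list(config.roi_labels())
    for rec, subject in zip(recordings, truth.subjects):
        stem = out_dir / subject.subject_id
        write_edf(rec, stem.with_suffix(".edf"), recording=subject.subject_id)
        sidecar = {
            "subject_id": subject.subject_id,
            "channel_labels": list(rec.channel_labels),
            "sampling_rate": rec.sampling_rate,
            "roi": roi,
            "seed": config.seed,
        }
        stem.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )
    targets.to_csv(out_dir / "targets.csv")
    truth_doc = {
        "subjects": [
            {
                "subject_id": s.subject_id,
                "band_factors": s.band_factors,
                "alpha2_power": s.alpha2_power,
                "latent": s.latent,
                "coupling_density": s.coupling_density,
                "active_members": list(s.active_members),
                "artifact_epochs": list(s.artifact_epochs),
                "rmt_true": s.rmt_true,
                "amt_true": s.amt_true,
            }
            for s in truth.subjects
        ],
        "coupling_adjacency": {
            band: adj.tolist() for band, adj in truth.coupling_adjacency.items()
        },
    }
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth_doc, indent=1, sort_keys=True)
    )
    return out_dir


def read_cohort(data_dir: str | Path) -> tuple[list[RawRecording], pd.DataFrame]:
    """Read a cohort directory (per-subject EDFs + targets.csv)."""
    data_dir = Path(data_dir)
    targets = pd.read_csv(data_dir / "targets.csv", index_col="subject_id")
    recordings = []
    for sid in targets.index:
        recordings.append(read_edf(data_dir / f"{sid}.edf"))
    return recordings, targets
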