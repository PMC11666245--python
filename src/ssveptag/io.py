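"""Portable recording format and format bridges.

A recording is stored as a ``.npy`` array container (channels x samples,
32-bit float, microvolts) next to a JSON sidecar with the sampling rate,
channel labels, condition-onset events and session metadata.  EDF import via
mne is provided as the single standard-format bridge; a minimal 16-bit EDF
writer exists solely to build synthetic round-trip fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import Recording

SIDE_CAR_FIELDS = ("sampling_rate", "channel_labels", "events")


def write_recording(recording: Recording, path) -> Path:
    """Write ``<path>.npy`` + ``<path>.json``; returns the sidecar path."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.save(base.with_suffix(".npy"), recording.data.astype(np.float32))
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "events": [[int(s), str(lab)] for s, lab in recording.events],
        "meta": _jsonable(recording.meta),
    }
    out = base.with_suffix(".json")
    with open(out, "w") as f:
        json.dump(sidecar, f, indent=1)
    return out


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`; the sidecar is
    validated against the array shape."""
    base = Path(path)
    npy, side = base.with_suffix(".npy"), base.with_suffix(".json")
    if not npy.exists() or not side.exists():
        raise FileNotFoundError(f"missing {npy} or {side}")
    data = np.load(npy).astype(float)
    with open(side) as f:
        sc = json.load(f)
    for fld in SIDE_CAR_FIELDS:
        if fld not in sc:
            raise ValueError(f"sidecar missing required field: {fld!r}")
    if len(sc["channel_labels"]) != data.shape[0]:
        raise ValueError(
            "sidecar field 'channel_labels' does not match the matrix: "
            f"{len(sc['channel_labels'])} labels vs {data.shape[0]} rows")
    events = [(int(s), lab) for s, lab in sc["events"]]
    return Recording(data, float(sc["sampling_rate"]), sc["channel_labels"],
                     events, sc.get("meta", {}))


def import_edf(path, events: list | None = None) -> Recording:
    """Import a continuous EDF file via mne (converted to microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                     events or [], {"source": str(path)})


def write_edf_synthetic(recording: Recording, path) -> Path:
    """Minimal EDF writer for synthetic fixtures (16-bit, one data record per
    second).  Not a general-purpose exporter."""
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF fixture writer needs an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_rec = recording.n_samples // fs
    data = recording.data[:, : n_rec * fs]
    pmax = max(np.max(np.abs(data)), 1.0)
    pmin = -pmax
    dmax, dmin = 32767, -32768
    scaled = np.clip(
        (data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin, dmin, dmax
    ).astype("<i2")

    def pad(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("synthetic", 80), pad("synthetic fixture", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 + 256 * n_ch, 8), pad("", 44), pad(n_rec, 8), pad(1, 8),
        pad(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(pad(c, 16) for c in recording.channel_labels),
        b"".join(pad("EEG", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{pmin:.1f}", 8) for _ in range(n_ch)),
        b"".join(pad(f"{pmax:.1f}", 8) for _ in range(n_ch)),
        b"".join(pad(dmin, 8) for _ in range(n_ch)),
        b"".join(pad(dmax, 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(fs, 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as f:
        f.write(hdr + sig)
        for r in range(n_rec):
            f.write(scaled[:, r * fs:(r + 1) * fs].tobytes())
    return path
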