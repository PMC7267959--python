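"""Readers and writers for matrices, layouts, epoched recordings and EDF.

On-disk conventions:
- connectivity matrices: tab-delimited text with a channel-label header row
  and column, optional ``# key=value`` comment lines for metadata;
- sensor layouts: whitespace-delimited ``label x y z region`` rows;
- epoched recordings: NumPy ``.npz`` containers holding the epoch array,
  sampling rate, labels and layout, so a recording round-trips standalone;
- EDF import (optional, requires mne): a continuous EDF is segmented into
  consecutive fixed-length epochs. A minimal EDF writer is included for
  generating fixtures and demos (16-bit EDF, one data record per second);
  it is not a general-purpose exporter.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .connectivity import ConnectivityMatrix
from .exceptions import FormatError, InvalidArgumentError
from .synthetic import Recording, SensorLayout

_SYM_TOL = 1e-9


def write_matrix(m: ConnectivityMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# band={m.band}\n# n_epochs_used={m.n_epochs_used}\n")
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for lab, row in zip(m.labels, m.wpli):
            fh.write(lab + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    meta = {}
    rows, row_labels = [], []
    header = None
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if header is None:
            if parts[0] != "label":
                raise FormatError(f"{path}: expected 'label' header row")
            header = parts[1:]
            continue
        row_labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if header is None:
        raise FormatError(f"{path}: empty matrix file")
    if row_labels != header:
        raise FormatError(f"{path}: row labels do not match column labels")
    w = np.asarray(rows, dtype=float)
    if w.shape[0] != w.shape[1]:
        raise FormatError(f"{path}: matrix is not square")
    if not np.allclose(w, w.T, atol=_SYM_TOL):
        raise FormatError(f"{path}: matrix asymmetric beyond tolerance {_SYM_TOL}")
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(wpli=w, band=meta.get("band", "unknown"),
                              labels=tuple(header),
                              n_epochs_used=int(meta.get("n_epochs_used", 0)))


def write_layout(layout: SensorLayout, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("label\tx\ty\tz\tregion\n")
        for lab, pos, reg in zip(layout.labels, layout.positions, layout.region):
            fh.write(f"{lab}\t{pos[0]:.6f}\t{pos[1]:.6f}\t{pos[2]:.6f}\t{reg}\n")


def read_layout(path) -> SensorLayout:
    labels, pos, region = [], [], []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts or (i == 0 and parts[0] == "label"):
            continue
        if len(parts) < 4:
            raise FormatError(f"{path}: layout row needs label x y z [region]")
        labels.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
        region.append(parts[4] if len(parts) > 4 else "central")
    return SensorLayout(labels=tuple(labels), positions=np.asarray(pos),
                        region=tuple(region))


def write_epochs(recording: Recording, path) -> None:
    np.savez(
        Path(path), epochs=recording.epochs, fs=recording.fs,
        subject_id=recording.subject_id,
        labels=np.asarray(recording.layout.labels),
        positions=recording.layout.positions,
        region=np.asarray(recording.layout.region),
    )


def read_epochs(path) -> Recording:
    with np.load(Path(path), allow_pickle=False) as z:
        layout = SensorLayout(labels=tuple(str(s) for s in z["labels"]),
                              positions=z["positions"],
                              region=tuple(str(s) for s in z["region"]))
        return Recording(subject_id=str(z["subject_id"]), epochs=z["epochs"],
                         fs=float(z["fs"]), layout=layout)


# --- EDF ------------------------------------------------------------------

def write_edf_minimal(recording: Recording, path, physical_unit: str = "uV") -> None:
    """Write a recording as a minimal 16-bit EDF file (fixtures/demos only).

    Epochs are concatenated into a continuous signal; one data record per
    second. Values are linearly quantised to int16 over the per-channel
    physical range, so a round trip is exact only to that quantisation.
    """
    fs = recording.fs
    if fs != int(fs):
        raise InvalidArgumentError("minimal EDF writer needs an integer sampling rate")
    fs = int(fs)
    data = np.concatenate(list(recording.epochs), axis=1)  # (n_ch, total)
    n_ch, total = data.shape
    if total % fs:
        raise InvalidArgumentError("total duration must be an integer number of seconds")
    n_rec = total // fs
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.where(pmax - pmin > 0, pmax - pmin, 1.0)
    dmin, dmax = -32768, 32767
    dig = np.round((data - pmin[:, None]) / span[:, None] * (dmax - dmin) + dmin).astype("<i2")

    def pad(s, n):
        b = str(s).encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 * (n_ch + 1), 8), pad("", 44), pad(n_rec, 8), pad(1, 8), pad(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(pad(lab, 16) for lab in recording.layout.labels),
        b"".join(pad("EEG", 80) for _ in range(n_ch)),
        b"".join(pad(physical_unit, 8) for _ in range(n_ch)),
        b"".join(pad(f"{v:.6g}", 8) for v in pmin),
        b"".join(pad(f"{v:.6g}", 8) for v in pmax),
        b"".join(pad(dmin, 8) for _ in range(n_ch)),
        b"".join(pad(dmax, 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(fs, 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ])
    with Path(path).open("wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            chunk = dig[:, r * fs:(r + 1) * fs]
            fh.write(struct.pack(f"<{n_ch * fs}h", *chunk.reshape(-1)))


def read_edf(path, layout: SensorLayout, epoch_duration: float = 2.0,
             subject_id: str | None = None) -> Recording:
    """Import an EDF recording (requires mne) and segment it into epochs."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for EEG-typed channels
    fs = float(raw.info["sfreq"])
    n_samp = int(round(epoch_duration * fs))
    n_epochs = data.shape[1] // n_samp
    if n_epochs < 1:
        raise FormatError(f"{path}: shorter than one epoch")
    if data.shape[0] != layout.n_channels:
        raise FormatError(f"{path}: channel count does not match layout")
    epochs = data[:, : n_epochs * n_samp].reshape(layout.n_channels, n_epochs, n_samp)
    return Recording(subject_id=subject_id or Path(path).stem,
                     epochs=np.transpose(epochs, (1, 0, 2)), fs=fs, layout=layout)
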