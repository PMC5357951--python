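"""Reading and writing multi-lead ECG records.

Two on-disk representations are supported:

* a minimal subset of the PhysioNet WFDB format — a ``.hea`` header plus a
  format-16 (little-endian int16) ``.dat`` signal file, with per-signal
  gain/baseline/units metadata;
* a comma-separated text file with a mandatory header row of lead names and
  one numeric column per lead, voltages in mV.

The in-memory container is :class:`ECGRecord`: a float matrix of voltages in
mV, one row per time sample and one column per lead, plus the sample rate and
the ordered lead names.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ECGRecord",
    "ECGFormatError",
    "FRONTAL_LEADS",
    "canonical_lead",
    "read_wfdb",
    "read_delimited",
    "select_leads",
    "write_record",
]

#: Canonical frontal-plane limb leads in conventional order.
FRONTAL_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")

_CANONICAL = {name.lower(): name for name in FRONTAL_LEADS}


class ECGFormatError(ValueError):
    """A file does not conform to the expected record format."""


def canonical_lead(name: str) -> str:
    """Normalize a lead label: canonical casing for the six frontal leads
    (case-insensitive, so the ``avF`` spelling variant is accepted), other
    labels stripped but otherwise untouched."""
    return _CANONICAL.get(name.strip().lower(), name.strip())


@dataclass
class ECGRecord:
    """Multi-lead voltage time series.

    Parameters
    ----------
    sample_rate_hz
        Sampling rate of every lead, in Hz. Must be positive.
    lead_names
        Ordered, unique lead labels; one per column of ``voltages``.
    voltages
        Array of shape ``(n_samples, n_leads)`` holding voltages in mV.
    """

    sample_rate_hz: float
    lead_names: list[str]
    voltages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim == 1:
            self.voltages = self.voltages[:, None]
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be a 2-D samples x leads array")
        self.lead_names = [canonical_lead(n) for n in self.lead_names]
        if len(self.lead_names) != self.voltages.shape[1]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.voltages.shape[1]} voltage columns"
            )
        if len(set(n.lower() for n in self.lead_names)) != len(self.lead_names):
            raise ValueError(f"duplicate lead names: {self.lead_names}")
        if not (self.sample_rate_hz > 0 and math.isfinite(self.sample_rate_hz)):
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if not np.all(np.isfinite(self.voltages)):
            raise ValueError("voltages contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_leads(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's voltage trace by (case-insensitive) label."""
        want = canonical_lead(name).lower()
        for i, label in enumerate(self.lead_names):
            if label.lower() == want:
                return self.voltages[:, i]
        raise KeyError(
            f"lead {name!r} not in record; available leads: {self.lead_names}"
        )


# ---------------------------------------------------------------------------
# WFDB subset: header (.hea) + format-16 signal file (.dat)

_UNIT_TO_MV = {"mv": 1.0, "uv": 1e-3, "muv": 1e-3, "millivolt": 1.0}

# gain, optional "(baseline)", mandatory "/units", e.g. "1000(0)/mV"
_GAIN_RE = re.compile(r"^([0-9.eE+-]+)(?:\(([-0-9]+)\))?/(\w+)$")


def read_wfdb(record_path: str | Path) -> ECGRecord:
    """Read a WFDB record (header + format-16 signal file) into an ECGRecord.

    ``record_path`` may be the record name, with or without the ``.hea``
    extension. All leads present in the record are returned in header order;
    raw ADC counts are converted to mV with each signal's gain and baseline.
    Signals without explicit voltage units in the header are rejected —
    guessing units would silently corrupt the downstream amplitude mapping.
    """
    path = Path(record_path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise ECGFormatError(f"WFDB header not found: {hea}")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    try:
        head = lines[0].split()
        n_sig = int(head[1])
        fs = float(head[2])
        n_samples = int(head[3])
    except (IndexError, ValueError) as exc:
        raise ECGFormatError(f"malformed WFDB header line in {hea}: {lines[0]!r}") from exc
    if len(lines) < 1 + n_sig:
        raise ECGFormatError(f"{hea} declares {n_sig} signals but lists {len(lines) - 1}")

    dat_names: list[str] = []
    gains = np.empty(n_sig)
    baselines = np.empty(n_sig)
    unit_scale = np.empty(n_sig)
    lead_names: list[str] = []
    for i, ln in enumerate(lines[1 : 1 + n_sig]):
        fields = ln.split()
        if len(fields) < 3:
            raise ECGFormatError(f"malformed signal line in {hea}: {ln!r}")
        dat_names.append(fields[0])
        if fields[1] != "16":
            raise ECGFormatError(
                f"unsupported WFDB signal format {fields[1]!r} in {hea} (only 16)"
            )
        m = _GAIN_RE.match(fields[2])
        if not m or m.group(3).lower() not in _UNIT_TO_MV:
            raise ECGFormatError(
                f"signal {i} in {hea} lacks usable gain/units metadata: {fields[2]!r}"
            )
        gains[i] = float(m.group(1))
        baselines[i] = int(m.group(2)) if m.group(2) is not None else 0
        unit_scale[i] = _UNIT_TO_MV[m.group(3).lower()]
        lead_names.append(fields[-1])
        if gains[i] <= 0:
            raise ECGFormatError(f"non-positive gain for signal {i} in {hea}")

    if len(set(dat_names)) != 1:
        raise ECGFormatError(f"{hea}: multi-file records are not supported")
    dat = hea.parent / dat_names[0]
    if not dat.exists():
        raise IOError(f"WFDB signal file not found: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_samples * n_sig:
        raise IOError(
            f"{dat}: expected {n_samples * n_sig} samples ({n_samples} x {n_sig}), "
            f"found {raw.size}"
        )
    adc = raw.reshape(n_samples, n_sig).astype(float)
    voltages = (adc - baselines) / gains * unit_scale
    return ECGRecord(sample_rate_hz=fs, lead_names=lead_names, voltages=voltages)


def _write_wfdb(record: ECGRecord, path: Path, gain: float = 1000.0) -> None:
    """Write header + format-16 signal file. ``gain`` sets the quantization:
    the stored resolution is 1/gain mV per ADC count."""
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    dat = hea.with_suffix(".dat")
    adc = np.rint(record.voltages * gain)
    if np.any(np.abs(adc) > 32767):
        raise ValueError(
            f"voltages exceed int16 range at gain {gain}; reduce gain or amplitude"
        )
    adc = adc.astype("<i2")
    checksums = adc.astype(np.int64).sum(axis=0) & 0xFFFF
    checksums = np.where(checksums >= 0x8000, checksums - 0x10000, checksums)
    lines = [f"{hea.stem} {record.n_leads} {record.sample_rate_hz:g} {record.n_samples}"]
    for i, name in enumerate(record.lead_names):
        first = int(adc[0, i])
        lines.append(
            f"{dat.name} 16 {gain:g}(0)/mV 16 0 {first} {int(checksums[i])} 0 {name}"
        )
    hea.write_text("\n".join(lines) + "\n")
    adc.tofile(dat)


# ---------------------------------------------------------------------------
# Delimited text: CSV, "." decimal, mandatory header row

def read_delimited(path: str | Path, sample_rate_hz: float) -> ECGRecord:
    """Read a comma-separated voltage table (header row of lead names, one
    numeric mV column per lead). Trailing blank lines are tolerated; ragged
    rows and non-numeric cells are errors that name the offending row."""
    path = Path(path)
    text = path.read_text()
    rows = [ln for ln in text.splitlines()]
    while rows and not rows[-1].strip():
        rows.pop()
    if not rows:
        raise ECGFormatError(f"{path}: empty file")
    header = [c.strip() for c in rows[0].split(",")]
    if any(not c for c in header):
        raise ECGFormatError(f"{path}: empty lead name in header row")
    n_cols = len(header)
    data = np.empty((len(rows) - 1, n_cols))
    for r, ln in enumerate(rows[1:], start=2):
        cells = ln.split(",")
        if len(cells) != n_cols:
            raise ECGFormatError(
                f"{path}: row {r} has {len(cells)} cells, expected {n_cols}"
            )
        try:
            data[r - 2] = [float(c) for c in cells]
        except ValueError as exc:
            raise ECGFormatError(f"{path}: non-numeric cell in row {r}: {ln!r}") from exc
    return ECGRecord(sample_rate_hz=sample_rate_hz, lead_names=header, voltages=data)


def _write_delimited(record: ECGRecord, path: Path) -> None:
    header = ",".join(record.lead_names)
    # repr-precision floats so the CSV round-trips bit-exactly
    np.savetxt(path, record.voltages, fmt="%.17g", delimiter=",",
               header=header, comments="")


# ---------------------------------------------------------------------------

def select_leads(record: ECGRecord, wanted: list[str] | tuple[str, ...]) -> ECGRecord:
    """Return a record with exactly the ``wanted`` leads, in the wanted order.

    Matching is case-insensitive (``avF`` selects ``aVF``). Unknown labels
    raise a KeyError naming the missing lead and listing what is available.
    """
    idx = []
    lower = [n.lower() for n in record.lead_names]
    for name in wanted:
        key = canonical_lead(name).lower()
        if key not in lower:
            raise KeyError(
                f"lead {name!r} not in record; available leads: {record.lead_names}"
            )
        idx.append(lower.index(key))
    return ECGRecord(
        sample_rate_hz=record.sample_rate_hz,
        lead_names=[record.lead_names[i] for i in idx],
        voltages=record.voltages[:, idx].copy(),
    )


def write_record(record: ECGRecord, path: str | Path, format: str = "delimited") -> None:
    """Write a record so that the matching reader reproduces it.

    ``format="delimited"`` writes CSV (lossless); ``format="wfdb"`` writes a
    header + int16 signal file quantized at 0.001 mV. Zero-sample records are
    refused.
    """
    if record.n_samples == 0:
        raise ValueError("refusing to write a record with 0 samples")
    path = Path(path)
    if format == "delimited":
        _write_delimited(record, path)
    elif format == "wfdb":
        _write_wfdb(record, path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'wfdb' or 'delimited'")
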