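"""Reading, writing and preprocessing of multi-lead ECG records.

Supports two on-disk dialects:

* WFDB ``.hea``/``.dat`` pairs, read-only, restricted to format-16
  (little-endian int16) signals — the format used by the PhysioNet
  Challenge-2011 and noise-stress-test records.
* A plain CSV dialect (read/write): a ``# fs=<Hz>`` comment line, a header
  row of lead names, then one row per sample with one column per lead.

Amplitudes are standardized to millivolts on read.
"""

from __future__ import annotations

import csv
import io
import struct
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ECGRecord",
    "NormalizationParams",
    "ECGParseError",
    "read_record",
    "write_record",
    "mapminmax_normalize",
    "split_leads",
    "detect_empty_leads",
]

VALID_LABELS = ("acceptable", "unacceptable", "indeterminate")


class ECGParseError(ValueError):
    """A record file could not be parsed; the message names the bad field."""


@dataclass
class ECGRecord:
    """A sampled multi-lead ECG waveform.

    Attributes
    ----------
    samples : ndarray, shape (n_leads, n)
        Per-lead amplitudes in mV.
    fs : float
        Sampling rate in Hz, strictly positive.
    lead_names : list of str
        Ordered lead labels, one per row of ``samples``.
    label : str or None
        Optional quality label: acceptable / unacceptable / indeterminate.
    record_id : str
        Identifier, by convention the source file stem.
    """

    samples: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=list)
    label: Optional[str] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_leads, n) array")
        if self.samples.shape[1] < 1:
            raise ValueError("record must contain at least one sample per lead")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.lead_names:
            self.lead_names = [f"lead{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.lead_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.samples.shape[0]} sample rows"
            )
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class NormalizationParams:
    """Target range of the min-max affine rescaling; defaults to (-1, +1)."""

    ymin: float = -1.0
    ymax: float = 1.0

    def __post_init__(self) -> None:
        if not self.ymax > self.ymin:
            raise ValueError("ymax must exceed ymin")


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------


def read_record(path: str | Path, format: Optional[str] = None) -> ECGRecord:
    """Read an ECG record from ``path`` in the ``wfdb`` or ``csv`` dialect.

    When ``format`` is omitted it is inferred from the file suffix
    (``.hea`` -> wfdb, ``.csv`` -> csv).
    """
    path = Path(path)
    if format is None:
        format = {"hea": "wfdb", "csv": "csv"}.get(path.suffix.lstrip("."), "")
    if format == "wfdb":
        return _read_wfdb(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown record format {format!r}")


def write_record(record: ECGRecord, path: str | Path, format: str = "csv") -> None:
    """Write ``record`` so that :func:`read_record` recovers it exactly.

    Only the CSV dialect is writable. Sample values are emitted with
    ``repr``-level precision, so the round trip is bit-equal for doubles.
    """
    if format != "csv":
        raise ValueError(f"unsupported write format {format!r}")
    path = Path(path)
    buf = io.StringIO()
    header = f"# fs={record.fs!r}"
    if record.label is not None:
        header += f" label={record.label}"
    buf.write(header + "\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(record.lead_names)
    for row in record.samples.T:
        writer.writerow([repr(float(v)) for v in row])
    path.write_text(buf.getvalue())


def _read_csv(path: Path) -> ECGRecord:
    if not path.exists():
        raise FileNotFoundError(path)
    fs = None
    label = None
    lines = path.read_text().splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            data_start = i
            break
        for tok in line.lstrip("#").split():
            key, _, value = tok.partition("=")
            if key == "fs":
                try:
                    fs = float(value)
                except ValueError:
                    raise ECGParseError(f"{path}: malformed fs value {value!r}")
            elif key == "label":
                label = value
    if fs is None:
        raise ECGParseError(f"{path}: missing '# fs=' header comment")
    rows = list(csv.reader(lines[data_start:]))
    rows = [r for r in rows if r]
    if not rows:
        raise ECGParseError(f"{path}: no header row of lead names")
    lead_names = [c.strip() for c in rows[0]]
    n_leads = len(lead_names)
    data = np.empty((len(rows) - 1, n_leads))
    for i, row in enumerate(rows[1:]):
        line_no = data_start + i + 2  # 1-based, counting comments and header
        if len(row) != n_leads:
            raise ECGParseError(
                f"{path}: row {line_no} has {len(row)} columns, expected {n_leads}"
            )
        try:
            data[i] = [float(v) for v in row]
        except ValueError as exc:
            raise ECGParseError(f"{path}: row {line_no}: {exc}")
    if data.shape[0] == 0:
        raise ECGParseError(f"{path}: record contains no samples")
    return ECGRecord(
        samples=data.T,
        fs=fs,
        lead_names=lead_names,
        label=label,
        record_id=path.stem,
    )


def _read_wfdb(path: Path) -> ECGRecord:
    """Minimal WFDB reader: single-segment records, format-16 signals only."""
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 2:
        raise ECGParseError(f"{hea}: malformed record line {lines[0]!r}")
    record_name = head[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except ValueError as exc:
        raise ECGParseError(f"{hea}: record line: {exc}")
    if len(lines) - 1 < n_sig:
        raise ECGParseError(
            f"{hea}: header declares {n_sig} signals but lists {len(lines) - 1}"
        )

    sig_files: list[str] = []
    gains = np.empty(n_sig)
    baselines = np.empty(n_sig)
    lead_names: list[str] = []
    for k in range(n_sig):
        fields = lines[1 + k].split()
        if len(fields) < 2:
            raise ECGParseError(f"{hea}: signal line {k}: too few fields")
        sig_files.append(fields[0])
        if fields[1].split("+")[0] != "16":
            raise ECGParseError(
                f"{hea}: signal {k}: unsupported storage format {fields[1]!r} "
                "(only format 16 is supported)"
            )
        gain_field = fields[2] if len(fields) > 2 else "200"
        gain_field = gain_field.split("/")[0]  # strip units suffix
        if "(" in gain_field:  # gain(baseline)
            gain_s, base_s = gain_field.rstrip(")").split("(")
        else:
            gain_s, base_s = gain_field, "0"
        try:
            gains[k] = float(gain_s) or 200.0
            baselines[k] = float(base_s)
        except ValueError as exc:
            raise ECGParseError(f"{hea}: signal {k}: gain field: {exc}")
        lead_names.append(fields[-1] if len(fields) > 8 else f"sig{k}")

    if len(set(sig_files)) != 1:
        raise ECGParseError(f"{hea}: multi-file signal groups are not supported")
    dat = hea.parent / sig_files[0]
    if not dat.exists():
        raise FileNotFoundError(dat)
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if n_samples and raw.size != n_samples * n_sig:
        raise ECGParseError(
            f"{dat}: expected {n_samples * n_sig} int16 values, found {raw.size}"
        )
    adc = raw.reshape(-1, n_sig).T.astype(float)
    samples = (adc - baselines[:, None]) / gains[:, None]  # -> mV
    return ECGRecord(
        samples=samples, fs=fs, lead_names=lead_names, record_id=record_name
    )


def write_wfdb_format16(
    samples_mv: np.ndarray,
    fs: float,
    path: str | Path,
    lead_names: Optional[Sequence[str]] = None,
    gain: float = 200.0,
) -> None:
    """Write a format-16 WFDB pair (testing aid for the reader)."""
    path = Path(path)
    samples_mv = np.atleast_2d(np.asarray(samples_mv, dtype=float))
    n_sig, n = samples_mv.shape
    if lead_names is None:
        lead_names = [f"sig{k}" for k in range(n_sig)]
    adc = np.clip(np.rint(samples_mv * gain), -32768, 32767).astype("<i2")
    dat_name = path.stem + ".dat"
    with open(path.with_suffix(".hea"), "w") as fh:
        fh.write(f"{path.stem} {n_sig} {fs:g} {n}\n")
        for k in range(n_sig):
            fh.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {lead_names[k]}\n")
    interleaved = adc.T.reshape(-1)
    path.with_suffix(".dat").write_bytes(
        struct.pack(f"<{interleaved.size}h", *interleaved.tolist())
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def mapminmax_normalize(
    x: Sequence[float] | np.ndarray,
    params: NormalizationParams = NormalizationParams(),
) -> np.ndarray:
    """Affinely rescale ``x`` so its minimum maps to ymin and maximum to ymax.

    ``y = (ymax - ymin) * (x - xmin) / (xmax - xmin) + ymin``

    Raises
    ------
    ValueError
        If ``x`` contains non-finite values or all elements are equal
        (the map's denominator vanishes).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        raise ValueError("cannot normalize a constant sequence (xmax == xmin)")
    return (params.ymax - params.ymin) * (x - xmin) / (xmax - xmin) + params.ymin


def split_leads(record: ECGRecord) -> list[ECGRecord]:
    """Split a multi-lead record into one single-lead record per lead.

    The record-level quality label is propagated to every lead as a
    provisional label; lead order is preserved.
    """
    out = []
    for k, name in enumerate(record.lead_names):
        out.append(
            ECGRecord(
                samples=record.samples[k : k + 1].copy(),
                fs=record.fs,
                lead_names=[name],
                label=record.label,
                record_id=f"{record.record_id}_{name}" if record.record_id else name,
            )
        )
    return out


def _longest_flat_run(x: np.ndarray, eps: float) -> int:
    """Length of the longest window whose values fit in a band of half-width eps.

    Two-pointer sweep with monotonic deques; a window [i, j] qualifies iff
    max(x[i:j+1]) - min(x[i:j+1]) <= 2 * eps, i.e. every sample lies within
    eps of the band centre.
    """
    maxd: deque[int] = deque()
    mind: deque[int] = deque()
    best = 0
    left = 0
    for right in range(x.size):
        while maxd and x[maxd[-1]] <= x[right]:
            maxd.pop()
        maxd.append(right)
        while mind and x[mind[-1]] >= x[right]:
            mind.pop()
        mind.append(right)
        while x[maxd[0]] - x[mind[0]] > 2 * eps:
            if maxd[0] == left:
                maxd.popleft()
            if mind[0] == left:
                mind.popleft()
            left += 1
        best = max(best, right - left + 1)
    return best


def detect_empty_leads(
    record: ECGRecord,
    flat_fraction_threshold: float = 0.95,
    eps: Optional[float] = None,
) -> list[bool]:
    """Flag leads that are flat (or saturated) over most of their duration.

    A lead is empty when its longest run of consecutive samples lying within
    ``eps`` of a constant covers at least ``flat_fraction_threshold`` of the
    lead. ``eps`` defaults to 1e-4 of the lead's amplitude range (1e-6 mV
    for a fully degenerate lead). Invariant to DC offsets by construction.
    """
    if not 0 < flat_fraction_threshold <= 1:
        raise ValueError("flat_fraction_threshold must lie in (0, 1]")
    flags = []
    for x in record.samples:
        rng = float(x.max() - x.min())
        lead_eps = eps if eps is not None else (1e-4 * rng if rng > 0 else 1e-6)
        run = _longest_flat_run(x, lead_eps)
        flags.append(run >= flat_fraction_threshold * x.size)
    return flags
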