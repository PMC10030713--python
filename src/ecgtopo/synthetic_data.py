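"""Synthetic ECG and noise generation, SNR mixing, and dataset construction.

Emulates a noise-stress-test setting without downloads: quasi-periodic
P-QRS-T waveforms plus four contaminant classes — baseline wander (``bw``),
electrode-motion artifact (``em``), muscle artifact (``ma``) and white
``gaussian`` noise — mixed into clean traces at a controlled SNR
(default -10 dB, i.e. noise power ten times signal power).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from ecgtopo.ecg_io import ECGRecord, detect_empty_leads, read_record

__all__ = [
    "NOISE_KINDS",
    "DEFAULT_SNR_DB",
    "NoiseSpec",
    "ManifestEntry",
    "DatasetManifest",
    "generate_clean_ecg",
    "generate_noise",
    "load_nstdb_noise",
    "mix_at_snr",
    "plan_noise_allocation",
    "build_dataset",
]

NOISE_KINDS = ("bw", "em", "ma", "gaussian")
DEFAULT_SNR_DB = -10.0
#: bw : em : ma get equal shares, gaussian half a share.
DEFAULT_ALLOCATION_WEIGHTS = {"bw": 2.0, "em": 2.0, "ma": 2.0, "gaussian": 1.0}

# P, Q, R, S, T deflections as (offset from R peak [s], amplitude [mV], width [s])
_PQRST = (
    (-0.20, 0.15, 0.025),
    (-0.05, -0.12, 0.010),
    (0.00, 1.00, 0.011),
    (0.045, -0.20, 0.010),
    (0.30, 0.30, 0.045),
)


@dataclass(frozen=True)
class NoiseSpec:
    """One contaminant draw: kind, target mixing SNR in dB, and RNG seed."""

    kind: str
    snr_db: float = DEFAULT_SNR_DB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; choose from {NOISE_KINDS}")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass(frozen=True)
class ManifestEntry:
    record_id: str
    source: str  # clean | corrupted
    noise_kind: Optional[str]
    label: str


@dataclass
class DatasetManifest:
    """Bookkeeping for a built dataset: per-record provenance and class counts."""

    entries: list[ManifestEntry] = field(default_factory=list)
    n_empty_removed: int = 0

    @property
    def counts_by_class(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.label] = counts.get(e.label, 0) + 1
        return counts

    def validate(self) -> None:
        kinds_by_id: dict[str, str] = {}
        for e in self.entries:
            if e.noise_kind is None:
                continue
            base = e.record_id
            if base in kinds_by_id and kinds_by_id[base] != e.noise_kind:
                raise ValueError(f"record {base} assigned two noise kinds")
            kinds_by_id[base] = e.noise_kind
        if sum(self.counts_by_class.values()) != len(self.entries):
            raise AssertionError("class counts do not sum to entry count")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_empty_removed": self.n_empty_removed,
            "counts_by_class": self.counts_by_class,
            "entries": [
                {
                    "record_id": e.record_id,
                    "source": e.source,
                    "noise_kind": e.noise_kind,
                    "label": e.label,
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_clean_ecg(
    duration_s: float,
    fs: float,
    heart_rate_bpm: float = 72.0,
    seed: int = 0,
    record_id: str = "synthetic",
) -> ECGRecord:
    """Generate a single-lead quasi-periodic ECG trace.

    Each beat is a sum of five Gaussians (P, Q, R, S, T deflections) centred
    on R peaks whose intervals are jittered around 60/heart_rate. The output
    is deterministic for a given seed and labelled ``acceptable``.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if not 30.0 <= heart_rate_bpm <= 220.0:
        raise ValueError(f"heart_rate_bpm {heart_rate_bpm} outside [30, 220]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    rr_mean = 60.0 / heart_rate_bpm
    # small amplitude/width modulation per beat keeps the trace quasi-periodic
    r_time = rr_mean * rng.uniform(0.3, 0.9)
    while r_time < duration_s + 0.4:
        amp_mod = 1.0 + 0.05 * rng.standard_normal()
        lo = max(0, int((r_time - 0.45) * fs))
        hi = min(n, int((r_time + 0.55) * fs) + 1)
        if hi > lo:
            dt = t[lo:hi] - r_time
            for off, amp, width in _PQRST:
                x[lo:hi] += amp * amp_mod * np.exp(-0.5 * ((dt - off) / width) ** 2)
        r_time += rr_mean * (1.0 + 0.04 * rng.standard_normal())
    return ECGRecord(
        samples=x[None, :],
        fs=fs,
        lead_names=["I"],
        label="acceptable",
        record_id=record_id,
    )


def generate_noise(spec: NoiseSpec, duration_s: float, fs: float) -> np.ndarray:
    """Generate one contaminant trace, unit RMS, deterministic given the spec.

    bw       random-phase sinusoids below 0.5 Hz plus a slow random walk
    ma       band-limited (5-100 Hz) coloured noise
    em       bw component + ma component + sparse step/spike artifacts
    gaussian white normal noise
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * fs))
    kind = spec.kind
    if kind == "gaussian":
        x = rng.standard_normal(n)
    elif kind == "bw":
        x = _baseline_wander(rng, n, fs)
    elif kind == "ma":
        x = _muscle_noise(rng, n, fs)
    elif kind == "em":
        x = (
            0.8 * _baseline_wander(rng, n, fs)
            + 0.5 * _muscle_noise(rng, n, fs)
            + _electrode_steps(rng, n, fs)
        )
    else:  # pragma: no cover - NoiseSpec already validates
        raise ValueError(f"unknown noise kind {kind!r}")
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _baseline_wander(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    x = np.zeros(n)
    for _ in range(5):
        f = rng.uniform(0.05, 0.45)
        x += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    walk = np.cumsum(rng.standard_normal(n)) / np.sqrt(n)
    return x + walk


def _muscle_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    white = rng.standard_normal(n)
    hi = min(100.0, 0.45 * fs)
    lo = min(5.0, 0.5 * hi)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, white)


def _electrode_steps(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    x = np.zeros(n)
    for _ in range(rng.poisson(3) + 1):
        start = rng.integers(0, n)
        length = int(rng.uniform(0.05, 0.5) * fs)
        x[start : min(n, start + max(length, 1))] += rng.uniform(-3, 3)
    return x


def load_nstdb_noise(path: str | Path, duration_s: float, fs: float) -> np.ndarray:
    """Load a real noise-stress-test WFDB record, first lead, leading segment.

    Raises if the record is shorter than requested or sampled at a different
    rate (no resampling is performed).
    """
    rec = read_record(path, format="wfdb")
    if rec.fs != fs:
        raise ValueError(f"noise record fs {rec.fs} != requested {fs}")
    n = int(round(duration_s * fs))
    if rec.n_samples < n:
        raise ValueError("noise record shorter than requested duration")
    return rec.samples[0, :n].copy()


# ---------------------------------------------------------------------------
# Mixing and allocation
# ---------------------------------------------------------------------------


def mix_at_snr(
    clean: np.ndarray, noise: np.ndarray, snr_db: float = DEFAULT_SNR_DB
) -> np.ndarray:
    """Return ``clean + c * noise`` with ``c`` set so the segment-level SNR of
    the added component, ``10 log10(P_clean / P_scaled_noise)``, equals
    ``snr_db``. Powers are mean squared amplitudes over the whole segment.
    """
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ValueError("clean and noise must have equal lengths")
    p_clean = np.mean(clean**2)
    p_noise = np.mean(noise**2)
    if p_clean == 0:
        raise ValueError("clean signal has zero power")
    if p_noise == 0:
        raise ValueError("noise has zero power")
    c = np.sqrt(p_clean / (p_noise * 10.0 ** (snr_db / 10.0)))
    return clean + c * noise


def plan_noise_allocation(
    n_signals: int, weights: dict[str, float]
) -> dict[str, int]:
    """Split ``n_signals`` among noise kinds proportionally to ``weights``.

    Integerized by the largest-remainder method, so the counts always sum to
    ``n_signals`` and each deviates from exact proportionality by < 1.
    """
    if n_signals < 0:
        raise ValueError("n_signals must be nonnegative")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    kinds = list(weights)
    quotas = np.array([n_signals * weights[k] / total for k in kinds])
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    for i in np.argsort(-remainders, kind="stable")[: n_signals - counts.sum()]:
        counts[i] += 1
    return dict(zip(kinds, counts.tolist()))


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------


def build_dataset(
    clean_records: Sequence[ECGRecord],
    labeled_unacceptable_records: Sequence[ECGRecord],
    allocation_weights: Optional[dict[str, float]] = None,
    snr_db: float = DEFAULT_SNR_DB,
    seed: int = 0,
    n_corrupt: Optional[int] = None,
    flat_fraction_threshold: float = 0.95,
) -> tuple[DatasetManifest, list[ECGRecord]]:
    """Build a labelled acceptable/unacceptable dataset.

    Steps: (1) drop empty-lead records from the unacceptable pool; (2) pick
    ``n_corrupt`` acceptable records uniformly at random, make a noise-added
    copy of each (exactly one noise kind per record, counts planned by
    :func:`plan_noise_allocation`) and label the copies unacceptable;
    (3) emit every record with a manifest. Originals of corrupted records
    stay in the acceptable class.

    ``n_corrupt`` defaults to whatever balances the two classes (capped at
    the clean pool size).
    """
    if allocation_weights is None:
        allocation_weights = dict(DEFAULT_ALLOCATION_WEIGHTS)
    rng = np.random.default_rng(seed)

    retained_unacceptable = []
    n_removed = 0
    for rec in labeled_unacceptable_records:
        if any(detect_empty_leads(rec, flat_fraction_threshold)):
            n_removed += 1
        else:
            retained_unacceptable.append(rec)

    if n_corrupt is None:
        n_corrupt = max(0, min(len(clean_records), len(clean_records) - len(retained_unacceptable)))
    if n_corrupt > len(clean_records):
        raise ValueError(
            f"cannot corrupt {n_corrupt} records from a pool of {len(clean_records)}"
        )
    allocation = plan_noise_allocation(n_corrupt, allocation_weights)
    kind_sequence = [k for k, c in allocation.items() for _ in range(c)]
    chosen = rng.choice(len(clean_records), size=n_corrupt, replace=False)
    rng.shuffle(kind_sequence)

    manifest = DatasetManifest(n_empty_removed=n_removed)
    records: list[ECGRecord] = []

    for rec in clean_records:
        records.append(rec)
        manifest.entries.append(
            ManifestEntry(rec.record_id, "clean", None, "acceptable")
        )
    for rec in retained_unacceptable:
        records.append(rec)
        manifest.entries.append(
            ManifestEntry(rec.record_id, "clean", None, "unacceptable")
        )
    for idx, kind in zip(chosen, kind_sequence):
        src = clean_records[idx]
        spec = NoiseSpec(kind=kind, snr_db=snr_db, seed=int(rng.integers(2**31)))
        noise = generate_noise(spec, src.duration_seconds, src.fs)
        corrupted = ECGRecord(
            samples=mix_at_snr(src.samples[0], noise, snr_db)[None, :],
            fs=src.fs,
            lead_names=list(src.lead_names),
            label="unacceptable",
            record_id=f"{src.record_id}__{kind}",
        )
        records.append(corrupted)
        manifest.entries.append(
            ManifestEntry(corrupted.record_id, "corrupted", kind, "unacceptable")
        )
    manifest.validate()
    return manifest, records
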