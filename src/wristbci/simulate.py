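"""Synthetic 128-channel EEG with ground truth for every pipeline stage.

The generator emulates the cue-paced isometric wrist paradigm: per trial a
GetReady / StartMoving / HoldMovement / Stop marker quadruple at 0 / 2000 /
5000 / 8000 ms, one of the four movement classes (RH-WE, RH-WF, LH-WE,
LH-WF), and a 12,000 ms analysis window from −3000 to +9000 ms.

Cortical activity is modelled as band-limited noise sources at the seven
ROI scalp positions, mixed to the electrodes with isotropic Gaussian
distance-decay gains g = exp(−d²/2λ²) (λ ≈ 2.5 cm) — a deliberately
simple stand-in for volume conduction that preserves what the pipeline
consumes: focal topographies and class-dependent band power.  During the
force ramp and hold (S2–S3) a source's power is (1 + δ)× larger for its
configured classes than for the others.  On top of the sources sit pink
(1/f) background noise, common 50 Hz line interference, frontal biphasic
blink transients and lateral high-frequency EMG bursts.

Everything is a pure function of the config's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import CLASS_LABELS, ContinuousRecording, EventStream
from .montage import Montage, load_default_montage, roi_coordinates, \
    scalp_distance_cm
from .preprocess import STAGE_TIMES_MS

__all__ = ["SourceSpec", "SimConfig", "GroundTruth", "generate",
           "spectral_audit"]

_BAND_RANGES = {"delta-theta": (1.0, 7.0), "mu-beta": (7.0, 35.0),
                "low-gamma": (35.0, 49.0), "high-gamma": (51.0, 90.0)}


@dataclass(frozen=True)
class SourceSpec:
    """One cortical source: where, which band, and which classes it favours.

    ``delta`` is the relative S2–S3 band-power difference: power is
    (1 + delta) × baseline for trials of the *boost_classes* and baseline
    otherwise.
    """

    roi: str
    band: str
    delta: float = 0.0
    boost_classes: tuple = ()
    rms_uv: float = 10.0

    def band_range(self) -> tuple:
        return _BAND_RANGES[self.band]


def default_sources() -> tuple:
    """Study-like source layout: contralateral mu–beta lateralisation for
    the hand contrast, a weaker high-gamma extension/flexion contrast in
    prefrontal cortex, and neutral midline activity."""
    return (
        SourceSpec("l-M1-H", "mu-beta", 0.5, ("RH-WE", "RH-WF")),
        SourceSpec("r-M1-H", "mu-beta", 0.5, ("LH-WE", "LH-WF")),
        SourceSpec("l-PFC", "high-gamma", 0.25, ("RH-WE", "LH-WE")),
        SourceSpec("r-PFC", "high-gamma", 0.25, ("RH-WF", "LH-WF")),
        SourceSpec("SMA", "delta-theta", 0.0),
    )


@dataclass
class SimConfig:
    """Study conditions for one synthetic participant."""

    seed: int = 0
    trials_per_class: int = 200         # per movement per hand
    fs: float = 500.0
    stage_times_ms: dict = field(default_factory=lambda: dict(STAGE_TIMES_MS))
    sources: tuple = field(default_factory=default_sources)
    montage: Montage | None = None      # None = packaged 128-channel 10-5
    mixing_lambda_cm: float = 2.5
    pink_rms_uv: float = 10.0
    line_amp_uv: float = 2.0
    blink_rate_hz: float = 0.1
    blink_amp_uv: float = 100.0
    emg_rate_hz: float = 0.05
    emg_amp_uv: float = 25.0
    inter_trial_spacing_ms: float = 13000.0

    def __post_init__(self):
        if self.trials_per_class < 2:
            raise ValueError("need at least 2 trials per class")
        for src in self.sources:
            if src.delta < 0:
                raise ValueError("effect size delta must be >= 0")
        st = self.stage_times_ms
        if not (0 == st["GetReady"] < st["StartMoving"] < st["HoldMovement"]
                < st["Stop"]):
            raise ValueError("infeasible stage schedule")
        if self.inter_trial_spacing_ms < st["Stop"] + 1000.0 + 3000.0:
            raise ValueError("trial windows would overlap at this spacing")


@dataclass
class GroundTruth:
    """What was planted: sources, gains, artifact times, labels."""

    labels: np.ndarray
    getready_times_ms: np.ndarray
    sources: list            # dicts: spec fields + gains + nearest electrode
    blink_times_ms: np.ndarray
    emg_times_ms: np.ndarray
    seed: int

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "seed": int(self.seed),
            "labels": [str(l) for l in self.labels],
            "getready_times_ms": self.getready_times_ms.tolist(),
            "blink_times_ms": self.blink_times_ms.tolist(),
            "emg_times_ms": self.emg_times_ms.tolist(),
            "sources": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in s.items()} for s in self.sources
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


# ---------------------------------------------------------------------------

def _pink_noise(rng, n_channels, n_samples, fs, rms):
    """1/f-power background noise, per channel, scaled to *rms* µV."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    spec *= shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x


def _band_noise(rng, n_samples, fs, lo, hi):
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n_samples)
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _smoothstep_envelope(n_samples, i0, i1, ramp):
    """0→1→0 envelope over [i0, i1) with cosine ramps of *ramp* samples."""
    env = np.zeros(n_samples)
    env[i0:i1] = 1.0
    r = min(ramp, (i1 - i0) // 2)
    if r > 0:
        t = 0.5 - 0.5 * np.cos(np.pi * np.arange(r) / r)
        env[i0:i0 + r] = t
        env[i1 - r:i1] = t[::-1]
    return env


def _gains(montage: Montage, target_unit: np.ndarray, lambda_cm: float):
    d = scalp_distance_cm(montage.positions, target_unit,
                          montage.head_radius_mm)
    return np.exp(-d ** 2 / (2.0 * lambda_cm ** 2))


def _blink_waveform(fs):
    """300 ms biphasic deflection (positive then negative lobe)."""
    n = int(round(0.3 * fs))
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.hanning(n)


def generate(config: SimConfig) -> tuple[ContinuousRecording, GroundTruth]:
    """Synthesise one participant's continuous recording plus ground truth."""
    rng = np.random.default_rng(config.seed)
    montage = config.montage or load_default_montage()
    fs = config.fs
    n_cls = config.trials_per_class
    labels = np.repeat(np.asarray(CLASS_LABELS, dtype=object), n_cls)
    rng.shuffle(labels)
    n_trials = len(labels)

    spacing = config.inter_trial_spacing_ms
    lead_ms = 4000.0
    getready = lead_ms + spacing * np.arange(n_trials)
    stop_off = config.stage_times_ms["Stop"]
    total_ms = getready[-1] + stop_off + 1000.0 + 1000.0
    n_samples = int(round(total_ms * fs / 1000.0))

    signal = _pink_noise(rng, len(montage), n_samples, fs, config.pink_rms_uv)

    # 50 Hz line interference, common waveform, per-channel gain spread
    if config.line_amp_uv > 0:
        t = np.arange(n_samples) / fs
        phase = rng.uniform(0, 2 * np.pi)
        gains = config.line_amp_uv * rng.uniform(0.8, 1.2, len(montage))
        signal += gains[:, None] * np.sin(2 * np.pi * 50.0 * t + phase)

    rois = roi_coordinates(load_default_montage())
    s2_ms = config.stage_times_ms["StartMoving"]
    s3_end_ms = config.stage_times_ms["Stop"]
    truth_sources = []
    for spec in config.sources:
        lo, hi = spec.band_range()
        base = _band_noise(rng, n_samples, fs, lo, hi) * spec.rms_uv
        envelope = np.ones(n_samples)
        for t_gr, lab in zip(getready, labels):
            if spec.delta > 0 and lab in spec.boost_classes:
                i0 = int(round((t_gr + s2_ms) * fs / 1000.0))
                i1 = int(round((t_gr + s3_end_ms) * fs / 1000.0))
                ramp = int(round(0.2 * fs))
                bump = _smoothstep_envelope(n_samples, i0, i1, ramp)
                envelope += (np.sqrt(1.0 + spec.delta) - 1.0) * bump
        src = base * envelope
        g = _gains(montage, rois.loc[spec.roi].to_numpy(float),
                   config.mixing_lambda_cm)
        signal += g[:, None] * src[None, :]
        truth_sources.append({
            "roi": spec.roi, "band": spec.band, "delta": spec.delta,
            "boost_classes": list(spec.boost_classes),
            "rms_uv": spec.rms_uv, "gains": g,
            "nearest_electrode": montage.labels[int(np.argmax(g))],
        })

    # frontal blinks
    blink_times = _poisson_times(rng, config.blink_rate_hz, total_ms)
    if len(blink_times):
        anchor = _frontmost(montage)
        g = _gains(montage, anchor, 3.0)
        wf = _blink_waveform(fs) * config.blink_amp_uv
        _add_events(signal, g, wf, blink_times, fs)

    # lateral EMG bursts (50–90 Hz, 500 ms, random side)
    emg_times = _poisson_times(rng, config.emg_rate_hz, total_ms)
    if len(emg_times):
        left, right = _most_lateral(montage)
        n_burst = int(round(0.5 * fs))
        env = np.hanning(n_burst)
        for t_ms in emg_times:
            burst = _band_noise(rng, n_burst, fs, 50.0, min(90.0, fs / 2 - 5))
            wf = burst * env * config.emg_amp_uv
            side = left if rng.random() < 0.5 else right
            g = _gains(montage, side, 2.0)
            _add_events(signal, g, wf, [t_ms], fs)

    records = []
    for t_gr, lab in zip(getready, labels):
        for marker, off in STAGE_TIMES_MS.items():
            records.append((t_gr + config.stage_times_ms[marker], marker, lab))
    events = EventStream.from_records(records)
    rec = ContinuousRecording(signal, fs, montage, events)
    truth = GroundTruth(labels, getready, truth_sources,
                        np.asarray(blink_times), np.asarray(emg_times),
                        config.seed)
    return rec, truth


def _poisson_times(rng, rate_hz, total_ms):
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * total_ms / 1000.0)
    return np.sort(rng.uniform(500.0, total_ms - 1000.0, n))


def _frontmost(montage: Montage) -> np.ndarray:
    try:
        return montage.position("Fpz")
    except KeyError:
        return montage.positions[int(np.argmax(montage.positions[:, 1]))]


def _most_lateral(montage: Montage):
    x = montage.positions[:, 0]
    return montage.positions[int(np.argmin(x))], montage.positions[int(np.argmax(x))]


def _add_events(signal, gains, waveform, times_ms, fs):
    n = signal.shape[1]
    for t_ms in times_ms:
        i0 = int(round(t_ms * fs / 1000.0))
        i1 = min(i0 + len(waveform), n)
        if i0 >= n:
            continue
        signal[:, i0:i1] += gains[:, None] * waveform[: i1 - i0][None, :]


# ---------------------------------------------------------------------------

def spectral_audit(rec: ContinuousRecording, truth: GroundTruth,
                   config: SimConfig) -> pd.DataFrame:
    """Verify planted class contrasts at the electrodes.

    For every source with δ > 0, measures the S2–S3 band power of its
    nearest electrode per trial and reports the boost-class vs other-class
    power ratio (expected ≈ 1 + δ, diluted by background noise); also
    counts planted blink/EMG events whose anchor-electrode amplitude
    stands out from the background.
    """
    fs = rec.fs
    s2 = config.stage_times_ms["StartMoving"]
    s3e = config.stage_times_ms["Stop"]
    rows = []
    for src in truth.sources:
        if src["delta"] <= 0:
            continue
        ch = rec.montage.index(src["nearest_electrode"])
        lo, hi = _BAND_RANGES[src["band"]]
        powers = []
        for t_gr in truth.getready_times_ms:
            i0 = int(round((t_gr + s2) * fs / 1000.0))
            i1 = int(round((t_gr + s3e) * fs / 1000.0))
            seg = rec.signal[ch, i0:i1]
            f, p = sps.welch(seg, fs=fs, nperseg=min(512, len(seg)))
            m = (f >= lo) & (f < hi)
            powers.append(np.trapezoid(p[m], f[m]))
        powers = np.asarray(powers)
        boost = np.isin(truth.labels, src["boost_classes"])
        ratio = float(powers[boost].mean() / powers[~boost].mean())
        rows.append((src["roi"], src["band"], src["delta"],
                     src["nearest_electrode"], ratio,
                     int(boost.sum()), int((~boost).sum())))
    audit = pd.DataFrame(rows, columns=["roi", "band", "delta",
                                        "electrode", "power_ratio",
                                        "n_boost", "n_other"])
    audit.attrs["n_blinks_detected"] = _count_detected(
        rec, truth.blink_times_ms, _frontmost(rec.montage), 0.3)
    audit.attrs["n_emg_detected"] = _count_detected(
        rec, truth.emg_times_ms, _most_lateral(rec.montage)[0], 0.5)
    audit.attrs["n_blinks_planted"] = len(truth.blink_times_ms)
    audit.attrs["n_emg_planted"] = len(truth.emg_times_ms)
    return audit


def _count_detected(rec, times_ms, anchor, dur_s):
    if len(times_ms) == 0:
        return 0
    g = _gains(rec.montage, anchor, 3.0)
    ch = int(np.argmax(g))
    x = rec.signal[ch]
    rms = np.sqrt(np.mean(x ** 2))
    n = 0
    for t_ms in times_ms:
        i0 = int(round(t_ms * rec.fs / 1000.0))
        i1 = min(i0 + int(dur_s * rec.fs), len(x))
        if i0 < len(x) and np.max(np.abs(x[i0:i1])) > 3.0 * rms:
            n += 1
    return n
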