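"""Pre-processing: quality screening, segmentation, baseline, broadband
filtering, ICA artifact removal and assembly of the three analysis datasets.

Each trial covers 12,000 ms: from 3,000 ms before the GetReady cue to
1,000 ms after the Stop cue, with t = 0 at GetReady.  The four stages are
S1 get-ready [0, 2000), S2 force ramp [2000, 5000), S3 isometric hold
[5000, 8000) and S4 rest [8000, 9000].

The three analysis datasets are the right-vs-left investigation (RLI: all
trials, labelled by hand) and the extension-vs-flexion investigations
(EFI-RH / EFI-LH: one hand each, labelled WE vs WF).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ContinuousRecording
from .montage import Montage

__all__ = [
    "STAGE_TIMES_MS",
    "TrialSet",
    "ArtifactReport",
    "DatasetBundle",
    "detect_noisy_channels",
    "segment_trials",
    "baseline_correct",
    "broadband_filter",
    "flag_artifact_ics",
    "remove_ics_and_reconstruct",
    "build_datasets",
]

logger = logging.getLogger(__name__)

#: Nominal cue offsets within a trial (ms from GetReady).
STAGE_TIMES_MS = {"GetReady": 0.0, "StartMoving": 2000.0,
                  "HoldMovement": 5000.0, "Stop": 8000.0}

TRIAL_PRE_MS = 3000.0     # trial starts this long before GetReady
TRIAL_POST_STOP_MS = 1000.0   # and ends this long after Stop


@dataclass
class TrialSet:
    """trials × channels × samples tensor (µV) with per-trial class labels."""

    data: np.ndarray
    labels: np.ndarray          # one class label per trial
    fs: float
    montage: Montage
    t_start_ms: float = -TRIAL_PRE_MS
    stage_times_ms: dict = field(default_factory=lambda: dict(STAGE_TIMES_MS))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel axis does not match montage")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_samples) / self.fs * 1000.0

    def sample_of(self, t_ms: float) -> int:
        """Index of the first sample at or after time *t_ms*."""
        return int(np.ceil((t_ms - self.t_start_ms) * self.fs / 1000.0 - 1e-9))

    def select(self, mask) -> "TrialSet":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask], labels=self.labels[mask])

    def with_labels(self, labels) -> "TrialSet":
        return replace(self, data=self.data, labels=np.asarray(labels))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype("<f4"))
            f.create_dataset("labels", data=np.array(
                [str(l) for l in self.labels], dtype=h5py.string_dtype()))
            f.create_dataset("montage_labels", data=np.array(
                self.montage.labels, dtype=h5py.string_dtype()))
            f.create_dataset("montage_positions", data=self.montage.positions)
            f.attrs.update(fs=self.fs, t_start_ms=self.t_start_ms,
                           head_radius_mm=self.montage.head_radius_mm,
                           stage_times=json.dumps(self.stage_times_ms))

    @classmethod
    def from_hdf5(cls, path) -> "TrialSet":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()].astype(float)
            labels = np.array([l.decode() for l in f["labels"][()]],
                              dtype=object)
            mlabels = tuple(l.decode() for l in f["montage_labels"][()])
            montage = Montage(mlabels, f["montage_positions"][()],
                              float(f.attrs["head_radius_mm"]))
            return cls(data, labels, float(f.attrs["fs"]), montage,
                       float(f.attrs["t_start_ms"]),
                       json.loads(f.attrs["stage_times"]))


@dataclass
class ArtifactReport:
    """Per-IC artifact flags with the diagnostic scores behind them."""

    flags: np.ndarray                 # 'EOG' | 'EMG' | 'none' per IC
    scores: pd.DataFrame              # diagnostic indices per IC
    thresholds: dict

    @property
    def flagged(self) -> np.ndarray:
        return np.flatnonzero(self.flags != "none")


@dataclass
class DatasetBundle:
    """The three analysis datasets with binary labels."""

    rli: TrialSet        # RH vs LH, movements bundled
    efi_rh: TrialSet     # WE vs WF, right hand
    efi_lh: TrialSet     # WE vs WF, left hand

    def __post_init__(self):
        if self.rli.n_trials != self.efi_rh.n_trials + self.efi_lh.n_trials:
            raise ValueError("RLI trial count must equal EFI-RH + EFI-LH")

    def items(self):
        return [("rli", self.rli), ("efi-rh", self.efi_rh),
                ("efi-lh", self.efi_lh)]


# ---------------------------------------------------------------------------

def detect_noisy_channels(rec: ContinuousRecording, threshold_uv: float = 100.0,
                          fraction: float = 0.05) -> list[str]:
    """Channels whose |amplitude| exceeds *threshold_uv* (default 100 µV,
    the typical maximum of scalp EEG) on more than *fraction* of samples."""
    exceed = (np.abs(rec.signal) > threshold_uv).mean(axis=1)
    return [lab for lab, frac in zip(rec.montage.labels, exceed)
            if frac > fraction]


def segment_trials(rec: ContinuousRecording) -> TrialSet:
    """Cut the continuous recording into cue-locked 12,000 ms trials.

    One trial per GetReady marker, spanning [GetReady − 3000 ms,
    Stop + 1000 ms].  Trials without a Stop before the next GetReady, trials
    whose window leaves the recording, and trials of non-nominal length are
    skipped with a warning.
    """
    ev = rec.events.frame
    n_expected = int(round((TRIAL_PRE_MS + STAGE_TIMES_MS["Stop"]
                            + TRIAL_POST_STOP_MS) * rec.fs / 1000.0))
    gr_idx = np.flatnonzero(ev["marker"].to_numpy() == "GetReady")
    trials, labels = [], []
    for k, i in enumerate(gr_idx):
        t_gr = float(ev["time_ms"].iloc[i])
        nxt = ev["time_ms"].iloc[gr_idx[k + 1]] if k + 1 < len(gr_idx) else np.inf
        block = ev.iloc[i:][(ev["time_ms"].iloc[i:] < nxt)]
        stops = block[block["marker"] == "Stop"]
        if stops.empty:
            warnings.warn(f"GetReady at {t_gr:.0f} ms has no matching Stop; "
                          "trial skipped")
            continue
        t_stop = float(stops["time_ms"].iloc[0])
        start = int(round((t_gr - TRIAL_PRE_MS) * rec.fs / 1000.0))
        stop = int(round((t_stop + TRIAL_POST_STOP_MS) * rec.fs / 1000.0))
        if start < 0 or stop > rec.n_samples:
            warnings.warn(f"trial at {t_gr:.0f} ms exceeds recording bounds; "
                          "dropped")
            continue
        if stop - start != n_expected:
            warnings.warn(f"trial at {t_gr:.0f} ms spans {stop - start} "
                          f"samples, expected {n_expected}; dropped")
            continue
        trials.append(rec.signal[:, start:stop])
        labels.append(ev["label"].iloc[i])
    data = (np.stack(trials) if trials
            else np.empty((0, rec.n_channels, n_expected)))
    return TrialSet(data, np.asarray(labels, dtype=object), rec.fs, rec.montage)


def baseline_correct(ts: TrialSet) -> TrialSet:
    """Subtract the per-trial, per-channel mean over [−3000, 0) ms."""
    if ts.t_start_ms > -TRIAL_PRE_MS + 1e-9:
        raise ValueError("time axis does not cover the baseline interval")
    i0 = ts.sample_of(-TRIAL_PRE_MS)
    i1 = ts.sample_of(0.0)
    base = ts.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return replace(ts, data=ts.data - base)


def _apply_filtfilt_sos(sos, data):
    return sps.sosfiltfilt(sos, data, axis=-1)


def broadband_filter(ts: TrialSet, hp_hz: float = 0.5, lp_hz: float = 99.0,
                     notch_hz: float = 50.0, notch_bw_hz: float = 2.0,
                     order: int = 4) -> TrialSet:
    """Zero-phase cascade: Butterworth high-pass 0.5 Hz (DC shifts),
    low-pass 99 Hz (high-frequency noise) and a 2nd-order 49–51 Hz notch
    (AC line noise)."""
    nyq = ts.fs / 2.0
    if lp_hz >= nyq:
        raise ValueError(f"low-pass corner {lp_hz} Hz requires a sampling "
                         f"rate above {2 * lp_hz} Hz")
    hp = sps.butter(order, hp_hz, btype="highpass", fs=ts.fs, output="sos")
    lp = sps.butter(order, lp_hz, btype="lowpass", fs=ts.fs, output="sos")
    b, a = sps.iirnotch(notch_hz, notch_hz / notch_bw_hz, fs=ts.fs)
    out = _apply_filtfilt_sos(hp, ts.data)
    out = _apply_filtfilt_sos(lp, out)
    out = sps.filtfilt(b, a, out, axis=-1)
    return replace(ts, data=out)


# ---------------------------------------------------------------------------
# artifact IC screening

#: Electrodes count as frontal when their unit-y (front) coordinate exceeds
#: this; as lateral/edge when |unit-x| exceeds the second value.
_FRONTAL_Y = 0.55
_EDGE_X = 0.72

DEFAULT_ARTIFACT_THRESHOLDS = {
    "frontal_focality": 0.45,
    "low_freq_fraction": 0.55,
    "edge_focality": 0.45,
    "high_freq_fraction": 0.55,
}


def _topography_mass_fraction(column: np.ndarray, region_mask: np.ndarray):
    w = np.abs(column)
    total = w.sum()
    if total == 0:
        return 0.0
    return float(w[region_mask].sum() / total)


def _power_fraction(act: np.ndarray, fs: float, band: tuple) -> float:
    """Fraction of total PSD power inside *band*, Welch estimate."""
    x = act.reshape(-1)
    nper = min(1024, x.size)
    f, p = sps.welch(x, fs=fs, nperseg=nper)
    total = np.trapezoid(p, f)
    if total == 0:
        return 0.0
    lo, hi = band
    m = (f >= lo) & (f < hi)
    return float(np.trapezoid(p[m], f[m]) / total)


def flag_artifact_ics(decomp, montage: Montage,
                      thresholds: dict | None = None) -> ArtifactReport:
    """Automated screen for ocular and myogenic components.

    EOG components show frontally concentrated topographies with power
    dominated by low frequencies (< 5 Hz); EMG components show narrow
    lateral topographies at the head's edge with broadband power above
    30 Hz.  A component is flagged when both indices of a pair exceed
    their thresholds; if both pairs fire, the larger margin wins.
    """
    thr = dict(DEFAULT_ARTIFACT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    pos = montage.positions
    frontal = pos[:, 1] > _FRONTAL_Y
    edge = np.abs(pos[:, 0]) > _EDGE_X
    n_comp = decomp.mixing.shape[1]
    rows = []
    flags = []
    for ic in range(n_comp):
        col = decomp.mixing[:, ic]
        act = decomp.activations[:, ic, :]
        ff = _topography_mass_fraction(col, frontal)
        ef = _topography_mass_fraction(col, edge)
        lf = _power_fraction(act, decomp.fs, (0.0, 5.0))
        hf = _power_fraction(act, decomp.fs, (30.0, decomp.fs / 2.0))
        rows.append((ff, lf, ef, hf))
        eog = ff > thr["frontal_focality"] and lf > thr["low_freq_fraction"]
        emg = ef > thr["edge_focality"] and hf > thr["high_freq_fraction"]
        if eog and emg:
            eog_margin = min(ff - thr["frontal_focality"],
                             lf - thr["low_freq_fraction"])
            emg_margin = min(ef - thr["edge_focality"],
                             hf - thr["high_freq_fraction"])
            flags.append("EOG" if eog_margin >= emg_margin else "EMG")
        elif eog:
            flags.append("EOG")
        elif emg:
            flags.append("EMG")
        else:
            flags.append("none")
    scores = pd.DataFrame(rows, columns=["frontal_focality",
                                         "low_freq_fraction",
                                         "edge_focality",
                                         "high_freq_fraction"])
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("non-finite artifact diagnostics")
    return ArtifactReport(np.asarray(flags, dtype=object), scores, thr)


def remove_ics_and_reconstruct(ts: TrialSet, decomp,
                               report: ArtifactReport) -> TrialSet:
    """Zero flagged components and rebuild channel data from the rest."""
    flagged = set(report.flagged.tolist())
    n_comp = decomp.mixing.shape[1]
    keep = [i for i in range(n_comp) if i not in flagged]
    if not keep:
        raise ValueError("all components flagged as artifacts; nothing left "
                         "to reconstruct from")
    return replace(ts, data=decomp.reconstruct(keep))


# ---------------------------------------------------------------------------

def build_datasets(ts: TrialSet, trials_per_class: int | None = None
                   ) -> DatasetBundle:
    """Assemble the RLI and the two EFI datasets from labelled trials.

    *trials_per_class* optionally caps each movement class (first trials
    kept) to mirror a fixed-size protocol; default keeps all trials.
    """
    labels = np.asarray([str(l) for l in ts.labels], dtype=object)
    if trials_per_class is not None:
        keep = np.zeros(len(labels), dtype=bool)
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)[:trials_per_class]
            keep[idx] = True
        ts = ts.select(keep)
        labels = labels[keep]
    hand = np.array([l.split("-")[0] for l in labels], dtype=object)
    movement = np.array([l.split("-")[1] for l in labels], dtype=object)
    rli = ts.with_labels(hand)
    efi_rh = ts.select(hand == "RH").with_labels(movement[hand == "RH"])
    efi_lh = ts.select(hand == "LH").with_labels(movement[hand == "LH"])
    for name, sub in (("EFI-RH", efi_rh), ("EFI-LH", efi_lh)):
        if sub.n_trials == 0:
            warnings.warn(f"{name} dataset is empty (no trials for that hand)")
    return DatasetBundle(rli, efi_rh, efi_lh)
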