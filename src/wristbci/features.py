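"""Time–frequency band-power features from single-trial IC activations.

During the isometric hold (t = 5000…8000 ms) a 300 ms window slides in
100 ms steps (28 windows).  Each window's FFT power spectrum is split into
contiguous 2.9 Hz bins tiling the analysis band upward from F_LOWER, and
the summed power in each (window, bin) cell is one feature.

At 500 Hz a 300 ms window holds 150 samples, so the FFT resolution
(3.33 Hz) is coarser than the 2.9 Hz bins: each FFT frequency is assigned
to the unique bin containing it, and a bin that receives no FFT frequency
yields a structural zero feature.  The feature-count law
|features| = n_windows × n_bins is kept exact either way.  An optional
``pad_factor`` zero-pads the FFT to refine the frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .ica import BandDefinition

__all__ = [
    "FeatureIndexMap",
    "FeatureTable",
    "build_index_map",
    "extract_features",
]

#: Defaults of the sliding-window scheme (ms / Hz).
T_START_MS = 5000.0
T_END_MS = 8000.0
WINDOW_MS = 300.0
STEP_MS = 100.0
BIN_WIDTH_HZ = 2.9


@dataclass(frozen=True)
class FeatureIndexMap:
    """Ordered (window, frequency-bin) grid behind a feature vector.

    Feature order is window-major: all bins of window 0, then window 1, …
    """

    band: BandDefinition
    window_starts_ms: np.ndarray
    window_ms: float
    bin_edges_hz: np.ndarray      # n_bins + 1 edges, half-open [low, high)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts_ms)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_hz) - 1

    @property
    def n_features(self) -> int:
        return self.n_windows * self.n_bins

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, t0 in enumerate(self.window_starts_ms):
            for b in range(self.n_bins):
                rows.append((w, float(t0), b,
                             float(self.bin_edges_hz[b]),
                             float(self.bin_edges_hz[b + 1])))
        return pd.DataFrame(rows, columns=["window", "window_start_ms",
                                           "bin", "bin_low_hz", "bin_high_hz"])


def build_index_map(band: BandDefinition, t_start_ms: float = T_START_MS,
                    t_end_ms: float = T_END_MS, window_ms: float = WINDOW_MS,
                    step_ms: float = STEP_MS,
                    bin_width_hz: float = BIN_WIDTH_HZ) -> FeatureIndexMap:
    """Sliding-window / frequency-bin grid for one analysis band.

    n_windows = floor((t_end − t_start − window)/step) + 1 (28 with the
    defaults); bins of width *bin_width_hz* tile upward from the band's
    lower edge, discarding any leftover narrower than one bin.
    """
    span = t_end_ms - t_start_ms
    if window_ms > span:
        raise ValueError(f"window of {window_ms} ms exceeds the "
                         f"{span} ms analysis range")
    n_windows = int(np.floor((span - window_ms) / step_ms)) + 1
    starts = t_start_ms + step_ms * np.arange(n_windows)
    n_bins = int(np.floor((band.f_upper - band.f_lower) / bin_width_hz))
    if n_bins < 1:
        raise ValueError(f"band {band.name!r} is narrower than one "
                         f"{bin_width_hz} Hz bin")
    edges = band.f_lower + bin_width_hz * np.arange(n_bins + 1)
    return FeatureIndexMap(band, starts, window_ms, edges)


@dataclass
class FeatureTable:
    """trials × features matrix of summed spectral power (µV²)."""

    values: np.ndarray
    index_map: FeatureIndexMap
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be trials x features")
        if self.values.shape[1] != self.index_map.n_features:
            raise ValueError(
                f"{self.values.shape[1]} feature columns but the index map "
                f"describes {self.index_map.n_features}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_trials(self, mask) -> "FeatureTable":
        mask = np.asarray(mask)
        labels = None if self.labels is None else self.labels[mask]
        return FeatureTable(self.values[mask], self.index_map, labels)

    def to_frame(self) -> pd.DataFrame:
        meta = self.index_map.to_frame()
        cols = [f"w{int(r.window):02d}_b{int(r.bin):02d}"
                for r in meta.itertuples(index=False)]
        df = pd.DataFrame(self.values, columns=cols)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            if self.labels is not None:
                f.create_dataset("labels", data=np.array(
                    [str(l) for l in self.labels], dtype=h5py.string_dtype()))
            self.index_map.to_frame().to_records(index=False)
            f.attrs["band"] = self.index_map.band.name


def extract_features(activations: np.ndarray, index_map: FeatureIndexMap,
                     fs: float, *, t0_ms: float = -3000.0,
                     labels=None, pad_factor: int = 1) -> FeatureTable:
    """Band-power features for one IC's single-trial activations.

    *activations* is trials × samples; *t0_ms* is the trial time of its
    first sample.  Per window, the power spectrum (squared FFT magnitude,
    one-sided, DC excluded, rectangular taper) is summed within each
    frequency bin of *index_map*.
    """
    act = np.atleast_2d(np.asarray(activations, dtype=float))
    n_trials, n_samples = act.shape
    n_win_samp = int(round(index_map.window_ms * fs / 1000.0))
    n_fft = n_win_samp * pad_factor
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    edges = index_map.bin_edges_hz
    # assign each non-DC FFT frequency to its bin, -1 = outside the band
    bin_of = np.searchsorted(edges, freqs, side="right") - 1
    bin_of[(freqs < edges[0]) | (freqs >= edges[-1])] = -1
    bin_of[0] = -1  # DC excluded
    n_bins = index_map.n_bins

    out = np.zeros((n_trials, index_map.n_features))
    valid = bin_of >= 0
    for w, t_ms in enumerate(index_map.window_starts_ms):
        i0 = int(round((t_ms - t0_ms) * fs / 1000.0))
        if i0 < 0 or i0 + n_win_samp > n_samples:
            raise ValueError(
                f"window at {t_ms} ms falls outside the trial samples"
            )
        seg = act[:, i0:i0 + n_win_samp]
        spec = np.fft.rfft(seg, n=n_fft, axis=1)
        power = np.abs(spec) ** 2
        sums = np.zeros((n_trials, n_bins))
        np.add.at(sums.T, bin_of[valid], power[:, valid].T)
        out[:, w * n_bins:(w + 1) * n_bins] = sums
    return FeatureTable(out, index_map, labels)
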