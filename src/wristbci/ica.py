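"""Band-specific ICA decomposition, component topographies and ROI matching.

The full 1–90 Hz spectrum is split into four passbands — delta–theta
(1–7 Hz), mu–beta (7–35 Hz), low gamma (35–49 Hz) and high gamma
(51–90 Hz) — and each band-filtered dataset is decomposed with extended
Infomax ICA into as many components as the data's numerical rank.
Average-referenced 128-channel data has rank 127, hence 127 components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import griddata

from .montage import Montage, roi_coordinates, scalp_distance_cm
from .preprocess import DatasetBundle, TrialSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "ICADecomposition",
    "Topography",
    "bandpass_filter",
    "bandpass_decompose",
    "ica_decompose",
    "make_topography",
    "match_roi",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named passband with lower and upper frequency limits in Hz."""

    name: str
    f_lower: float
    f_upper: float

    def __post_init__(self):
        if not self.f_lower < self.f_upper:
            raise ValueError("F_LOWER must be below F_UPPER")


#: The four analysis bands covering 1–90 Hz.
DEFAULT_BANDS = (
    BandDefinition("delta-theta", 1.0, 7.0),
    BandDefinition("mu-beta", 7.0, 35.0),
    BandDefinition("low-gamma", 35.0, 49.0),
    BandDefinition("high-gamma", 51.0, 90.0),
)


def bandpass_filter(ts: TrialSet, band: BandDefinition,
                    order: int = 4) -> TrialSet:
    """Zero-phase Butterworth bandpass restricted to *band*."""
    nyq = ts.fs / 2.0
    if band.f_upper >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_upper} Hz is not below "
            f"the Nyquist frequency {nyq} Hz"
        )
    sos = sps.butter(order, (band.f_lower, band.f_upper), btype="bandpass",
                     fs=ts.fs, output="sos")
    return replace(ts, data=sps.sosfiltfilt(sos, ts.data, axis=-1))


def bandpass_decompose(bundle: DatasetBundle,
                       bands=DEFAULT_BANDS) -> dict:
    """Filter every analysis dataset into every band.

    Returns ``{(dataset_name, band_name): TrialSet}``: with the default
    four bands and three datasets, 12 band-filtered datasets (4 for the
    RLI, 8 for the two EFIs).
    """
    out = {}
    for ds_name, ts in bundle.items():
        for band in bands:
            out[(ds_name, band.name)] = bandpass_filter(ts, band)
    return out


# ---------------------------------------------------------------------------
# ICA

@dataclass
class ICADecomposition:
    """Unmixing/mixing matrices with per-trial component activations.

    ``mixing @ unmixing`` is the identity on the retained subspace; the
    component count equals the numerical rank of the (optionally
    average-referenced) input.
    """

    unmixing: np.ndarray        # components x channels
    mixing: np.ndarray          # channels x components
    activations: np.ndarray     # trials x components x samples
    channel_means: np.ndarray   # per-channel mean removed before unmixing
    fs: float
    seed: int
    n_iter: int
    band: str = ""
    dataset: str = ""

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def reconstruct(self, components=None) -> np.ndarray:
        """trials × channels × samples rebuilt from (a subset of) components."""
        if components is None:
            components = np.arange(self.n_components)
        components = np.asarray(components)
        mix = self.mixing[:, components]
        out = np.einsum("ck,tks->tcs", mix, self.activations[:, components, :])
        return out + self.channel_means[None, :, None]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("unmixing", "mixing", "activations", "channel_means"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs.update(fs=self.fs, seed=self.seed, n_iter=self.n_iter,
                           band=self.band, dataset=self.dataset)

    @classmethod
    def from_hdf5(cls, path) -> "ICADecomposition":
        with h5py.File(path, "r") as f:
            kw = {name: f[name][()] for name in
                  ("unmixing", "mixing", "activations", "channel_means")}
            kw.update(fs=float(f.attrs["fs"]), seed=int(f.attrs["seed"]),
                      n_iter=int(f.attrs["n_iter"]),
                      band=str(f.attrs["band"]), dataset=str(f.attrs["dataset"]))
        return cls(**kw)


def ica_decompose(ts: TrialSet, seed: int, *, average_reference: bool = True,
                  max_iter: int = 512, tol: float = 1e-7,
                  max_fit_samples: int | None = None,
                  rank_tol: float = 1e-7) -> ICADecomposition:
    """Extended-Infomax decomposition of trials concatenated along time.

    The data are optionally average-referenced (rank n_channels − 1, the
    route to 127 components from 128 channels), centred, reduced to their
    numerical rank by PCA whitening, and rotated by extended Infomax
    (:func:`mne.preprocessing.infomax`).  Deterministic for a fixed seed.

    *max_fit_samples* fits the decomposition on an evenly spaced subset of
    time points (activations are still computed for every sample) — the
    standard economy for long recordings.
    """
    from mne.preprocessing import infomax

    data = ts.data
    if average_reference:
        data = data - data.mean(axis=1, keepdims=True)
    n_trials, n_chan, n_samp = data.shape
    X = np.ascontiguousarray(data.transpose(1, 0, 2).reshape(n_chan, -1))
    means = X.mean(axis=1)
    Xc = X - means[:, None]

    fit = Xc
    if max_fit_samples is not None and Xc.shape[1] > max_fit_samples:
        idx = np.linspace(0, Xc.shape[1] - 1, max_fit_samples).astype(int)
        fit = Xc[:, idx]

    # PCA whitening to numerical rank
    U, s, _ = np.linalg.svd(fit, full_matrices=False)
    rank = int(np.sum(s > s[0] * rank_tol))
    n_fit = fit.shape[1]
    whitener = (U[:, :rank] / (s[:rank] / np.sqrt(n_fit - 1))).T  # rank x chan
    Z = whitener @ fit

    W, n_iter = infomax(Z.T, extended=True, max_iter=max_iter, w_change=tol,
                        rng=np.random.default_rng(seed), return_n_iter=True,
                        verbose="error")
    if not np.all(np.isfinite(W)):
        raise RuntimeError(
            f"Infomax ICA diverged (non-finite weights after {n_iter} "
            f"iterations, rank {rank})"
        )
    unmixing = W @ whitener                      # rank x channels
    mixing = np.linalg.pinv(unmixing)            # channels x rank
    acts = (unmixing @ Xc).reshape(rank, n_trials, n_samp)
    acts = np.ascontiguousarray(acts.transpose(1, 0, 2))
    return ICADecomposition(unmixing, mixing, acts, means, ts.fs,
                            seed=seed, n_iter=int(n_iter))


# ---------------------------------------------------------------------------
# topographies and ROI matching

def _azimuthal_xy(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of unit vectors from the vertex."""
    x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
    r = np.arccos(np.clip(z, -1.0, 1.0))
    rho = np.hypot(x, y)
    scale = np.where(rho > 1e-12, r / np.where(rho > 1e-12, rho, 1.0), 0.0)
    return np.column_stack([x * scale, y * scale])


@dataclass
class Topography:
    """A component's per-electrode weights with an interpolated scalp map."""

    weights: np.ndarray
    montage: Montage
    grid_x: np.ndarray = field(repr=False)
    grid_y: np.ndarray = field(repr=False)
    grid_map: np.ndarray = field(repr=False)
    peak_position: np.ndarray | None   # 3-D unit vector, None if undefined
    peak_label: str | None
    focality: float

    @property
    def defined(self) -> bool:
        return self.peak_position is not None

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = ax.pcolormesh(self.grid_x, self.grid_y, self.grid_map,
                          shading="auto", **kwargs)
        xy = _azimuthal_xy(self.montage.positions)
        ax.scatter(xy[:, 0], xy[:, 1], s=4, c="k")
        ax.set_aspect("equal")
        return m


def make_topography(decomp_or_weights, ic: int | None = None,
                    montage: Montage | None = None,
                    grid_size: int = 67) -> Topography:
    """Interpolated 2-D scalp map of one component's mixing column.

    Accepts either an :class:`ICADecomposition` plus component index, or a
    raw per-electrode weight vector.  The peak is the electrode of maximum
    absolute weight; a perfectly uniform column has focality 0 and an
    undefined peak.
    """
    if ic is None and montage is None:
        raise TypeError("montage required")
    if hasattr(decomp_or_weights, "mixing"):
        weights = np.asarray(decomp_or_weights.mixing[:, ic], float)
    else:
        weights = np.asarray(decomp_or_weights, float)
    if len(weights) != len(montage):
        raise ValueError("weight vector does not match montage size")
    xy = _azimuthal_xy(montage.positions)
    lim = np.abs(xy).max() * 1.05
    gx, gy = np.meshgrid(np.linspace(-lim, lim, grid_size),
                         np.linspace(-lim, lim, grid_size))
    grid = griddata(xy, weights, (gx, gy), method="linear")

    absw = np.abs(weights)
    n = len(absw)
    total = absw.sum()
    if total == 0:
        focality = 0.0
    else:
        focality = float((n * absw.max() / total - 1.0) / (n - 1))
    if focality < 1e-12:  # uniform (or zero) column: no meaningful peak
        peak_pos, peak_label = None, None
    else:
        i = int(np.argmax(absw))
        peak_pos, peak_label = montage.positions[i], montage.labels[i]
    return Topography(weights, montage, gx, gy, grid, peak_pos, peak_label,
                      focality)


def match_roi(topo: Topography, rois: pd.DataFrame | None = None,
              radius_cm: float = 3.0,
              head_radius_mm: float | None = None) -> list[str]:
    """ROIs whose scalp position lies within *radius_cm* of the topography
    peak, ordered by distance (ties by name).  Undefined peak → empty."""
    if not topo.defined:
        return []
    if rois is None:
        rois = roi_coordinates()
    if head_radius_mm is None:
        head_radius_mm = topo.montage.head_radius_mm
    d = scalp_distance_cm(rois.to_numpy(float), topo.peak_position,
                          head_radius_mm)
    order = sorted((float(di), name) for di, name in zip(d, rois.index)
                   if di <= radius_cm)
    return [name for _, name in order]
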