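"""Electrode geometry: the 128-channel 10-5 montage and cortical ROI anchors.

The montage ships as a static table of unit-sphere positions (head frame:
x right, y front, z up) for a fixed 128-label subset of the 10-5 placement
system.  Scalp distances are measured along the sphere surface (great-circle
arc length scaled by the head radius), which is the natural metric for
comparing component topographies with ROI positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "ROI_NAMES",
    "load_default_montage",
    "read_montage_tsv",
    "roi_coordinates",
    "scalp_distance_cm",
]

#: Default head radius used to convert angular distances to centimetres.
DEFAULT_HEAD_RADIUS_MM = 95.0

#: The seven cortical regions of interest: hand area of primary motor cortex
#: (M1-H), ventral premotor cortex (PMv) and prefrontal cortex (PFC)
#: bilaterally, plus the midline supplementary motor area (SMA).
ROI_NAMES = ("r-M1-H", "l-M1-H", "r-PMv", "l-PMv", "r-PFC", "l-PFC", "SMA")

# Scalp anchors for each lateral ROI pair (left electrode, right electrode)
# and the midline SMA.  M1-H lies under C3/C4, PMv under FC5/FC6, PFC under
# AF3/AF4 and SMA under FCz.
_ROI_ANCHORS = {
    "M1-H": ("C3", "C4"),
    "PMv": ("FC5", "FC6"),
    "PFC": ("AF3", "AF4"),
    "SMA": ("FCz", None),
}


@dataclass(frozen=True)
class Montage:
    """Electrode labels with unit-sphere 3-D head-frame coordinates."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) unit vectors
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("electrode coordinates must be unit-norm (1e-6)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Position of *label* in the montage; raises on unknown labels."""
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(
                f"unknown electrode label {label!r}; montage has "
                f"{len(self)} configured labels"
            ) from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def subset(self, labels) -> "Montage":
        """Montage restricted to *labels* (order preserved)."""
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx], self.head_radius_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.positions, columns=["x", "y", "z"],
            index=pd.Index(self.labels, name="label"),
        )


def read_montage_tsv(path) -> Montage:
    """Read a montage from a TSV of (label, x, y, z) rows."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["label", "x", "y", "z"])
    return Montage(tuple(df["label"]), df[["x", "y", "z"]].to_numpy(float))


def write_montage_tsv(montage: Montage, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
    return path


def load_default_montage() -> Montage:
    """The packaged 128-electrode 10-5 montage."""
    ref = resources.files("wristbci.data") / "montage_1005_128.tsv"
    with resources.as_file(ref) as path:
        return read_montage_tsv(path)


def scalp_distance_cm(u: np.ndarray, v: np.ndarray,
                      head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM):
    """Great-circle scalp distance between unit vectors, in centimetres.

    Broadcasts over leading axes of *u*.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    cosang = np.clip((u * v).sum(axis=-1), -1.0, 1.0)
    return np.arccos(cosang) * head_radius_mm / 10.0


def _mirror(p: np.ndarray) -> np.ndarray:
    """Reflect a head-frame point across the sagittal (midline) plane."""
    q = p.copy()
    q[..., 0] = -q[..., 0]
    return q


def roi_coordinates(montage: Montage | None = None) -> pd.DataFrame:
    """Scalp positions of the seven ROIs as unit vectors.

    Lateral ROI pairs are exactly mirror-symmetric about the midline: each
    pair is built by symmetrising its left/right electrode anchors, and the
    SMA anchor is projected onto the midline plane.

    Returns a DataFrame indexed by ROI name with columns x, y, z.
    """
    if montage is None:
        montage = load_default_montage()
    rows = {}
    for roi, (left, right) in _ROI_ANCHORS.items():
        if right is None:  # midline ROI
            p = montage.position(left).copy()
            p[0] = 0.0
            rows["SMA"] = p / np.linalg.norm(p)
            continue
        pl = montage.position(left)
        pr = montage.position(right)
        # symmetrise: average the left anchor with the mirrored right anchor
        l_sym = 0.5 * (pl + _mirror(pr))
        l_sym /= np.linalg.norm(l_sym)
        rows[f"l-{roi}"] = l_sym
        rows[f"r-{roi}"] = _mirror(l_sym)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["x", "y", "z"])
    return df.loc[list(ROI_NAMES)]
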