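"""Shared data containers: fluorescence trace matrices and ROI sets.

A :class:`TraceMatrix` is the in-memory currency of the whole pipeline: a
time x channel array of fluorescence values, either raw camera units
(``kind="raw"``) or dimensionless dF/F (``kind="dff"``), together with the
sampling rate and channel labels.  CSV round-trip uses a ``time_s`` column
followed by one column per channel.

A :class:`RoiSet` holds named pixel masks (brain regions or single neurons)
used both to render synthetic movies and to extract traces from image stacks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, ParameterError

#: Canonical anterior-to-posterior ordering of the six imaged brain regions.
REGIONS = ("pallium", "habenula", "neuropil", "spv", "cerebellum", "hindbrain")

#: Twelve bilateral region channels in anterior-to-posterior order.
REGION_CHANNELS = tuple(f"{r}_{s}" for r in REGIONS for s in ("left", "right"))


def region_of(label: str) -> str:
    """Strip the hemisphere suffix from a bilateral channel label."""
    base = label.rsplit("_", 1)[0]
    return base


@dataclass
class TraceMatrix:
    """Time x channel fluorescence matrix with sampling metadata.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_channels)
        Fluorescence samples. Raw traces are in camera units; dF/F traces are
        dimensionless.
    fps : float
        Sampling rate in Hz.
    labels : sequence of str
        One unique label per channel, in column order.
    kind : {"raw", "dff"}
        Whether the values are raw fluorescence or baseline-normalized dF/F.
    """

    values: np.ndarray
    fps: float
    labels: list[str]
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("trace values must be 2-D (time x channel)")
        if not np.isfinite(self.values).all():
            raise InputError("trace values contain NaN or infinity")
        if not self.fps > 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.values.shape[1]:
            raise InputError(
                f"{len(self.labels)} labels for {self.values.shape[1]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise InputError("channel labels must be unique")
        if self.kind not in ("raw", "dff"):
            raise ParameterError(f"kind must be 'raw' or 'dff', got {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        """Epoch length in seconds (n_frames / fps)."""
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        try:
            j = self.labels.index(label)
        except ValueError:
            raise InputError(f"no channel labeled {label!r}") from None
        return self.values[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, kind: str = "raw") -> "TraceMatrix":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise InputError("trace CSV must have a 'time_s' first column")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise InputError("trace CSV needs at least two samples")
        fps = 1.0 / float(np.median(np.diff(t)))
        labels = [c for c in df.columns if c != "time_s"]
        return cls(df[labels].to_numpy(dtype=float), fps=fps, labels=labels, kind=kind)


@dataclass
class Roi:
    """A single region of interest: an integer label and a boolean pixel mask.

    Coordinates are 0-based, row-major (row, col). ``side`` is "left", "right"
    or "n/a" (single neurons).
    """

    label: int
    name: str
    mask: np.ndarray
    side: str = "n/a"
    scale_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise InputError(f"ROI {self.label}: mask must be a nonempty 2-D mask")
        if self.side not in ("left", "right", "n/a"):
            raise ParameterError(f"ROI {self.label}: bad side {self.side!r}")
        if not self.scale_um_per_px > 0:
            raise ParameterError(f"ROI {self.label}: scale must be positive")

    @property
    def centroid(self) -> tuple[float, float]:
        """Mask centroid as (row, col) in pixels."""
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())

    @property
    def channel_label(self) -> str:
        return self.name if self.side == "n/a" else f"{self.name}_{self.side}"


@dataclass
class RoiSet:
    """An ordered collection of disjoint ROIs sharing one frame geometry."""

    rois: list[Roi] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rois:
            raise InputError("RoiSet must contain at least one ROI")
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise InputError("ROI labels must be unique")
        shapes = {r.mask.shape for r in self.rois}
        if len(shapes) > 1:
            raise InputError("all ROI masks must share the same frame shape")
        cover = np.zeros(self.rois[0].mask.shape, dtype=np.int32)
        for r in self.rois:
            cover += r.mask
        if (cover > 1).any():
            raise ParameterError("ROI masks overlap; overlapping pixels are ambiguous")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.rois[0].mask.shape

    @property
    def channel_labels(self) -> list[str]:
        return [r.channel_label for r in self.rois]

    def centroids(self) -> np.ndarray:
        """(n_rois, 2) array of (row, col) centroids in pixels."""
        return np.array([r.centroid for r in self.rois], dtype=float)

    def to_label_image(self) -> np.ndarray:
        img = np.zeros(self.frame_shape, dtype=np.int32)
        for r in self.rois:
            img[r.mask] = r.label
        return img

    @classmethod
    def from_label_image(cls, label_img: np.ndarray, table: list[dict]) -> "RoiSet":
        """Build from a label image plus a JSON-style table of ROI metadata.

        ``table`` rows carry ``label``, ``name`` and optionally ``side`` and
        ``scale_um_per_px``.
        """
        label_img = np.asarray(label_img)
        rois = []
        for row in table:
            lab = int(row["label"])
            mask = label_img == lab
            rois.append(
                Roi(
                    label=lab,
                    name=str(row["name"]),
                    mask=mask,
                    side=str(row.get("side", "n/a")),
                    scale_um_per_px=float(row.get("scale_um_per_px", 1.0)),
                )
            )
        return cls(rois)
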