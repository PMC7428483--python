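"""Signal conditioning and spherical-ROI time-series extraction.

The conditioning steps mirror a minimal resting/task fMRI pipeline operating
on data already in MNI space: the first volumes of a run are dropped to let
magnetization reach equilibrium, and slow scanner drifts are removed with a
zero-phase high-pass filter (0.01 Hz by default at TR = 3 s).  ROI series
are unweighted voxel means over 10 mm-diameter spheres centered on a node
coordinate table.  Motion correction, slice timing, spatial normalization
and smoothing are out of scope; inputs are assumed corrected and normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal

DEFAULT_TR_S = 3.0
DEFAULT_DROP_VOLUMES = 5
DEFAULT_HIGHPASS_HZ = 0.01
DEFAULT_ROI_RADIUS_MM = 5.0  # 10 mm diameter spheres


@dataclass
class RoiTimeSeriesMatrix:
    """A volumes x nodes signal matrix with its repetition time.

    ``data[t, j]`` is node ``j``'s representative signal at volume ``t``.
    """

    data: np.ndarray
    tr_seconds: float = DEFAULT_TR_S
    node_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D volumes x nodes matrix")
        if self.data.shape[0] < 2:
            raise ValueError("at least 2 volumes required")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.node_ids is None:
            self.node_ids = tuple(f"n{j}" for j in range(self.data.shape[1]))
        else:
            self.node_ids = tuple(str(n) for n in self.node_ids)
            if len(self.node_ids) != self.data.shape[1]:
                raise ValueError("node_ids must match the number of columns")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class Parcellation:
    """Node table: id, MNI coordinate (mm) and functional network label."""

    table: pd.DataFrame  # columns: node_id, x, y, z, network

    REQUIRED = ("node_id", "x", "y", "z", "network")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"parcellation table lacks columns {missing}")
        ids = self.table["node_id"].astype(str)
        if ids.duplicated().any():
            raise ValueError("node ids must be unique")
        if (self.table["network"].astype(str).str.len() == 0).any():
            raise ValueError("network labels must be non-empty")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self.table["node_id"].astype(str))

    @property
    def networks(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["network"].astype(str).unique()))

    def members(self, label: str) -> np.ndarray:
        """Row indices of the nodes carrying ``label``."""
        mask = (self.table["network"].astype(str) == label).to_numpy()
        if not mask.any():
            raise KeyError(f"network label {label!r} not present")
        return np.flatnonzero(mask)

    def coordinates(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class Volume4D:
    """A 4-D intensity array with an affine mapping voxel indices to MNI mm."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = DEFAULT_TR_S

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.data.shape[3] < 6:
            raise ValueError("at least 6 time points required")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @classmethod
    def from_nifti(cls, path, tr_seconds: float | None = None) -> "Volume4D":
        img = nib.load(str(path))
        tr = tr_seconds
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else DEFAULT_TR_S
        return cls(np.asarray(img.get_fdata()), img.affine, tr)

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr_seconds))
        nib.save(img, str(path))


def drop_initial_volumes(ts, k: int = DEFAULT_DROP_VOLUMES):
    """Remove the first ``k`` time points (non-equilibrium magnetization)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if isinstance(ts, RoiTimeSeriesMatrix):
        if k >= ts.n_volumes:
            raise ValueError(f"cannot drop {k} of {ts.n_volumes} volumes")
        return RoiTimeSeriesMatrix(ts.data[k:], ts.tr_seconds, ts.node_ids)
    if isinstance(ts, Volume4D):
        if k >= ts.n_volumes:
            raise ValueError(f"cannot drop {k} of {ts.n_volumes} volumes")
        return Volume4D(ts.data[..., k:], ts.affine, ts.tr_seconds)
    raise TypeError("expected RoiTimeSeriesMatrix or Volume4D")


def highpass_filter(
    ts: RoiTimeSeriesMatrix,
    cutoff_hz: float = DEFAULT_HIGHPASS_HZ,
    order: int = 2,
) -> RoiTimeSeriesMatrix:
    """Zero-phase Butterworth high-pass per node, removing slow drifts.

    Applied forward and backward (``filtfilt``) so no phase is introduced;
    the DC component is removed exactly, so filtered columns have mean ~= 0.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz for TR "
            f"{ts.tr_seconds} s"
        )
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=1.0 / ts.tr_seconds, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return RoiTimeSeriesMatrix(filtered, ts.tr_seconds, ts.node_ids)


def extract_roi_timeseries(
    vol: Volume4D,
    parc: Parcellation,
    radius_mm: float = DEFAULT_ROI_RADIUS_MM,
) -> RoiTimeSeriesMatrix:
    """Mean signal over voxels strictly within ``radius_mm`` of each node.

    Voxel membership uses voxel-center coordinates; spheres of neighboring
    nodes may overlap, in which case shared voxels contribute to both.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    nx, ny, nz, nt = vol.data.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    centers_mm = vox @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    flat = vol.data.reshape(-1, nt)

    coords = parc.coordinates()
    out = np.empty((nt, len(parc)))
    for j, (node_id, c) in enumerate(zip(parc.node_ids, coords)):
        d2 = np.sum((centers_mm - c) ** 2, axis=1)
        inside = d2 < radius_mm**2
        if not inside.any():
            raise ValueError(
                f"ROI {node_id!r} at {tuple(c)} captures no voxels "
                f"(radius {radius_mm} mm)"
            )
        out[:, j] = flat[inside].mean(axis=0)
    return RoiTimeSeriesMatrix(out, vol.tr_seconds, parc.node_ids)


def read_roi_tsv(path) -> RoiTimeSeriesMatrix:
    """Read a TSV with node-id header and one row per volume.

    Commented header lines of the form ``# key=value`` carry metadata;
    ``tr_seconds`` is honored.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    tr = float(meta.get("tr_seconds", DEFAULT_TR_S))
    return RoiTimeSeriesMatrix(
        frame.to_numpy(dtype=float), tr, tuple(frame.columns)
    )


def write_roi_tsv(ts: RoiTimeSeriesMatrix, path, **metadata) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tr_seconds={ts.tr_seconds}\n")
        for key, value in metadata.items():
            fh.write(f"# {key}={value}\n")
        pd.DataFrame(ts.data, columns=list(ts.node_ids)).to_csv(
            fh, sep="\t", index=False, float_format="%.6g"
        )
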