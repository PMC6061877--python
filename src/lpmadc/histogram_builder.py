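"""Paired ADC histograms and conventional per-tumor summary parameters.

Diffusion-weighted MRI yields a per-voxel apparent diffusion coefficient
(ADC, mm^2/s).  For each tumor the voxelwise ADC values observed at baseline
(t = 0 h) and at a follow-up scan (t = 72 h) are binned into a single B x 2
histogram — one axis ADC, the other time — which is the unit of analysis for
the linear Poisson model.  This module converts raw multi-b diffusion signals
into ADC values, builds those paired histograms under a shared binning
scheme, and computes the three conventional summary parameters (volume
change, mean-ADC change, IQR change) used by the t-test benchmark arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered time labels: first scan (pre-treatment) and follow-up scan.
TIME_LEVELS = ("baseline", "post")

#: Hours after treatment corresponding to each time level.
TIME_HOURS = {"baseline": 0.0, "post": 72.0}


@dataclass(frozen=True)
class BinningScheme:
    """Shared ADC binning: strictly increasing edges plus ordered time labels.

    Bins are half-open ``[lo, hi)``; the last bin is closed so the upper
    edge is countable.  The same scheme must be shared by every tumor in a
    study so that histogram cells are comparable across tumors.
    """

    adc_edges: np.ndarray
    time_levels: tuple[str, str] = TIME_LEVELS

    def __post_init__(self) -> None:
        edges = np.asarray(self.adc_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("adc_edges must be a 1-D vector of length B+1 with B >= 2")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("adc_edges must be strictly increasing")
        if len(self.time_levels) != 2:
            raise ValueError("exactly two time levels are required")
        object.__setattr__(self, "adc_edges", edges)
        object.__setattr__(self, "time_levels", tuple(self.time_levels))

    @property
    def n_bins(self) -> int:
        return self.adc_edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.adc_edges[:-1] + self.adc_edges[1:])

    @classmethod
    def uniform(cls, n_bins: int = 64, adc_min: float = 0.0,
                adc_max: float = 3.0e-3) -> "BinningScheme":
        """Default scheme: 64 uniform bins spanning [0, 3.0e-3] mm^2/s."""
        return cls(np.linspace(adc_min, adc_max, n_bins + 1))

    def to_dict(self) -> dict:
        return {"adc_edges": self.adc_edges.tolist(),
                "time_levels": list(self.time_levels)}

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(np.asarray(d["adc_edges"], dtype=float),
                   tuple(d["time_levels"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinningScheme):
            return NotImplemented
        return (self.time_levels == other.time_levels
                and np.array_equal(self.adc_edges, other.adc_edges))


@dataclass
class PairedHistogram:
    """B x 2 integer count array for one tumor (ADC bins x time points)."""

    counts: np.ndarray
    tumor_id: str
    binning: BinningScheme

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("counts must have shape (B, 2)")
        if counts.shape[0] != self.binning.n_bins:
            raise ValueError("counts rows must match the binning scheme")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("histogram counts must be integers")
            counts = rounded.astype(np.int64)
        self.counts = counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def column_totals(self) -> np.ndarray:
        """Number of voxels at each time point."""
        return self.counts.sum(axis=0)


@dataclass
class SummaryParams:
    """Conventional per-tumor change parameters for the t-test benchmark arm.

    ``volume_source`` records whether the volumes came from caliper ellipsoid
    measurements or from voxel counts; the percentile convention used for the
    IQR is linear interpolation (numpy's default, type 7).
    """

    volume_change: float
    mean_adc_change: float
    iqr_change: float
    volume_source: str = "caliper"
    tumor_id: str = ""


def compute_adc(signals, b_values) -> tuple[float, float]:
    """Monoexponential diffusion fit S(b) = S0 * exp(-b * D) by log-linear OLS.

    Parameters
    ----------
    signals : array-like of positive floats
        Measured signal at each diffusion weighting.  Rows with non-positive
        signal are rejected with a logged diagnostic.
    b_values : array-like of non-negative floats, s/mm^2
        Diffusion weightings; at least two distinct values must survive
        filtering.

    Returns
    -------
    (s0, adc) : tuple of floats
        ``s0`` is the extrapolated signal at b = 0 and ``adc`` the apparent
        diffusion coefficient D in mm^2/s.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("signals and b_values must be 1-D and equally long")
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    ok = s > 0
    if not np.all(ok):
        logger.warning("compute_adc: rejecting %d row(s) with non-positive signal",
                       int((~ok).sum()))
        s, b = s[ok], b[ok]
    if np.unique(b).size < 2:
        raise ValueError("at least two distinct b-values are required")
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return float(np.exp(intercept)), float(-slope)


def ellipsoid_volume(l: float, w: float, d: float) -> float:
    """Caliper tumor volume V = (pi/6) * L * W * D in mm^3."""
    if l <= 0 or w <= 0 or d <= 0:
        raise ValueError("ellipsoid dimensions must be positive")
    return float(np.pi / 6.0 * l * w * d)


def _bin_indices(adc: np.ndarray, binning: BinningScheme) -> np.ndarray:
    edges = binning.adc_edges
    out_of_range = (adc < edges[0]) | (adc > edges[-1])
    if np.any(out_of_range):
        logger.warning("%d ADC value(s) outside [%g, %g]; clipped into edge bins",
                       int(out_of_range.sum()), edges[0], edges[-1])
    idx = np.searchsorted(edges, adc, side="right") - 1
    return np.clip(idx, 0, binning.n_bins - 1)


def build_paired_histogram(voxels: pd.DataFrame, binning: BinningScheme,
                           tumor_id: str | None = None) -> PairedHistogram:
    """Bin one tumor's voxel table into a B x 2 paired histogram.

    ``voxels`` needs columns ``time`` and ``adc`` (a ``tumor_id`` column is
    used to infer the label when ``tumor_id`` is not given).  Bins are
    half-open with the last bin closed; out-of-range ADC values are clipped
    into the first/last bin with a warning so that voxel counts are conserved.
    """
    if voxels.empty:
        raise ValueError("empty voxel set")
    if tumor_id is None:
        ids = voxels["tumor_id"].unique() if "tumor_id" in voxels else []
        if len(ids) != 1:
            raise ValueError("tumor_id must be given when the table is not single-tumor")
        tumor_id = str(ids[0])
    adc = voxels["adc"].to_numpy(dtype=float)
    if np.any(adc < 0):
        raise ValueError(f"tumor {tumor_id}: negative ADC values in input")
    counts = np.zeros((binning.n_bins, 2), dtype=np.int64)
    for t, level in enumerate(binning.time_levels):
        sel = voxels["time"] == level
        if not sel.any():
            raise ValueError(f"tumor {tumor_id}: no voxels at time point {level!r}")
        idx = _bin_indices(adc[sel.to_numpy()], binning)
        np.add.at(counts[:, t], idx, 1)
    return PairedHistogram(counts, tumor_id, binning)


def summary_params(h0, h1, vol0: float = 0.0, vol1: float = 0.0,
                   volume_source: str = "caliper",
                   tumor_id: str = "") -> SummaryParams:
    """Per-tumor conventional changes between baseline and post voxel sets.

    ``h0`` and ``h1`` are the raw voxel ADC values at the two time points;
    volumes are supplied separately (caliper or voxel-count derived).
    """
    a0 = np.asarray(h0, dtype=float)
    a1 = np.asarray(h1, dtype=float)
    if a0.size == 0 or a1.size == 0:
        raise ValueError("empty voxel set")
    iqr = lambda a: float(np.percentile(a, 75) - np.percentile(a, 25))
    return SummaryParams(
        volume_change=float(vol1 - vol0),
        mean_adc_change=float(a1.mean() - a0.mean()),
        iqr_change=iqr(a1) - iqr(a0),
        volume_source=volume_source,
        tumor_id=tumor_id,
    )


def histogram_adc_values(hist: PairedHistogram, time_index: int) -> np.ndarray:
    """Expand one histogram column into ADC values at bin centers."""
    return np.repeat(hist.binning.centers, hist.counts[:, time_index])


def summary_from_histogram(hist: PairedHistogram, vol0: float | None = None,
                           vol1: float | None = None,
                           voxel_volume: float = 1.0) -> SummaryParams:
    """Conventional summary computed from binned counts (bin-center values).

    When volumes are not supplied they default to voxel count x voxel volume
    at each time point, with the source recorded as ``voxel_count``.
    """
    n0, n1 = hist.column_totals
    source = "caliper"
    if vol0 is None or vol1 is None:
        vol0, vol1 = n0 * voxel_volume, n1 * voxel_volume
        source = "voxel_count"
    return summary_params(histogram_adc_values(hist, 0),
                          histogram_adc_values(hist, 1),
                          vol0, vol1, volume_source=source,
                          tumor_id=hist.tumor_id)


def voxels_from_nifti(adc_path, mask_path, tumor_id: str, time: str) -> pd.DataFrame:
    """Read an ADC map + binary mask (NIfTI) into voxel-table rows."""
    import nibabel as nib  # optional dependency

    adc = np.asanyarray(nib.load(str(adc_path)).dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if adc.shape != mask.shape:
        raise ValueError("ADC map and mask shapes differ")
    values = adc[mask]
    return pd.DataFrame({"tumor_id": tumor_id, "time": time, "adc": values})
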