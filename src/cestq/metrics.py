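"""Asymmetry contrasts, pH-weighted mapping and ROI histogram features.

MTR asymmetry at offset x is (Z(−x) − Z(+x)) / M0; at 3.5 ppm it is the
conventional amide-weighted MTR_3.5, at 3.0 ppm it is the amine-proton
pH-weighted contrast. A four-parameter sigmoid relates the 3.0-ppm
asymmetry to nominal pH when calibration constants are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core import RoiMask, ZSpectrumVolume

__all__ = [
    "PhCalibration",
    "HistogramFeatures",
    "mtr_asym",
    "ph_weighted_map",
    "ph_from_asym",
    "extract_histogram_features",
    "features_to_records",
]

FEATURE_NAMES = ("mean", "median", "p10", "p25", "p75", "p90")


def _z_at(zspec: ZSpectrumVolume, ppm: float) -> np.ndarray:
    """Z at one offset: exact schedule point when present, else spline."""
    offsets = zspec.offsets_ppm
    hit = np.flatnonzero(np.isclose(offsets, ppm, atol=1e-9))
    if hit.size:
        return zspec.values[..., hit[0]]
    if ppm > offsets.max() or ppm < offsets.min():
        raise ValueError(f"offset {ppm} ppm outside the sampled range")
    order = np.argsort(offsets)
    out = np.zeros(zspec.spatial_shape)
    for idx in np.argwhere(zspec.mask):
        tidx = tuple(idx)
        out[tidx] = CubicSpline(offsets[order], zspec.values[tidx][order])(ppm)
    return out


def mtr_asym(zspec: ZSpectrumVolume, ppm: float, m0: float = 1.0) -> np.ndarray:
    """MTR asymmetry map (Z(−ppm) − Z(+ppm)) / M0.

    On normalized Z-spectra M0 = 1. A CEST pool on the positive side
    (amide, amine) makes the value positive; NOE on the negative side makes
    it negative.
    """
    if ppm <= 0:
        raise ValueError("ppm must be positive")
    out = (_z_at(zspec, -ppm) - _z_at(zspec, ppm)) / m0
    out[~zspec.mask] = np.nan
    return out


def ph_weighted_map(zspec: ZSpectrumVolume) -> np.ndarray:
    """pH-weighted contrast: the MTR asymmetry at 3.0 ppm.

    The amine-proton asymmetry at 3.0 ppm tracks tissue acidity; the
    default output is the raw contrast (small signed Z-unit values), not
    pH, since a sigmoid calibration requires constants no scanner-agnostic
    default can supply.
    """
    return mtr_asym(zspec, 3.0)


@dataclass(frozen=True)
class PhCalibration:
    """Sigmoid calibration  asym(pH) = α + (β − α) / (1 + 10^E).

    ``exponent_form`` selects E = δ·(κ − pH) (default reading) or
    E = δ·κ·pH (literal reading of the printed expression); both are
    strictly monotone in pH and invert uniquely.
    """

    alpha: float
    beta: float
    delta_slope: float
    kappa: float
    exponent_form: str = "kappa_minus_ph"

    def __post_init__(self):
        if self.beta <= self.alpha:
            raise ValueError("beta must exceed alpha")
        if self.delta_slope == 0:
            raise ValueError("delta_slope must be nonzero")
        if self.exponent_form not in ("kappa_minus_ph", "kappa_times_ph"):
            raise ValueError("unknown exponent_form")

    def evaluate(self, ph):
        ph = np.asarray(ph, dtype=float)
        if self.exponent_form == "kappa_minus_ph":
            e = self.delta_slope * (self.kappa - ph)
        else:
            e = self.delta_slope * self.kappa * ph
        return self.alpha + (self.beta - self.alpha) / (1.0 + 10.0 ** e)


def ph_from_asym(asym_value: float, cal: PhCalibration) -> float:
    """Invert the sigmoid calibration; ``asym_value`` must lie strictly
    inside (alpha, beta), otherwise the value is out of calibration."""
    a = float(asym_value)
    if not (cal.alpha < a < cal.beta):
        raise ValueError(f"asymmetry {a} outside the open calibration range "
                         f"({cal.alpha}, {cal.beta})")
    e = np.log10((cal.beta - cal.alpha) / (a - cal.alpha) - 1.0)
    if cal.exponent_form == "kappa_minus_ph":
        return float(cal.kappa - e / cal.delta_slope)
    return float(e / (cal.delta_slope * cal.kappa))


@dataclass(frozen=True)
class HistogramFeatures:
    """Six ROI summary statistics of one metric map."""

    metric: str
    mean: float
    median: float
    p10: float
    p25: float
    p75: float
    p90: float
    n_voxels: int

    def __post_init__(self):
        if not (self.p10 <= self.p25 <= self.median <= self.p75 <= self.p90):
            raise ValueError("percentiles are not monotone")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


def extract_histogram_features(metric_map: np.ndarray, roi: RoiMask,
                               metric: str = "metric",
                               min_voxels: int = 10) -> HistogramFeatures:
    """Mean, median and 10/25/75/90th percentiles over in-ROI voxels.

    Flagged voxels (NaN in the map, e.g. non-converged fits) are excluded
    before the statistics; percentiles use linear interpolation between
    order statistics.
    """
    vals = np.asarray(metric_map, dtype=float)[roi.voxels]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_voxels:
        raise ValueError(f"ROI '{roi.label}' has {vals.size} usable voxels "
                         f"(< {min_voxels})")
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    return HistogramFeatures(metric=metric, mean=float(vals.mean()),
                             median=float(p50), p10=float(p10), p25=float(p25),
                             p75=float(p75), p90=float(p90),
                             n_voxels=int(vals.size))


def features_to_records(subject_id: str, group: str | None,
                        features: list[HistogramFeatures]) -> list[dict]:
    """Long-format rows (one per metric) for a per-subject feature table."""
    rows = []
    for f in features:
        row = {"subject_id": subject_id, "metric": f.metric}
        if group is not None:
            row["group"] = group
        row.update(f.as_dict())
        row["n_voxels"] = f.n_voxels
        rows.append(row)
    return rows
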