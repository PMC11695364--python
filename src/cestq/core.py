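"""Core domain types for CEST Z-spectrum quantification.

A CEST acquisition saturates at a sequence of frequency offsets (in ppm
relative to water) and the Z-spectrum is the saturated image normalized by
a fully relaxed reference image, Z(Δω) = S_sat(Δω) / S0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MT_BACKGROUND_OFFSETS",
    "WATER_BACKGROUND_OFFSETS",
    "OffsetSchedule",
    "AcquisitionParams",
    "RoiMask",
    "ZSpectrumVolume",
    "build_default_offset_schedule",
    "normalize_to_zspectrum",
]

#: Absolute offsets (ppm) assumed to be influenced only by the semisolid MT pool.
MT_BACKGROUND_OFFSETS = (10.0, 15.0, 20.0, 25.0, 30.0, 100.0)
#: Absolute offsets (ppm) assumed to be influenced only by direct water saturation.
WATER_BACKGROUND_OFFSETS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class OffsetSchedule:
    """Ordered saturation frequency offsets with the normalization frame.

    Parameters
    ----------
    offsets_ppm
        Saturation offsets in acquisition order, in ppm from water.
    reference_index
        Index of the fully-relaxed (S0) frame within ``offsets_ppm``, or
        ``None`` when S0 was acquired separately.
    """

    offsets_ppm: tuple[float, ...]
    reference_index: int | None = None

    def __post_init__(self):
        arr = np.asarray(self.offsets_ppm, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("offsets must be finite")
        object.__setattr__(self, "offsets_ppm", tuple(float(v) for v in arr))
        if self.reference_index is not None:
            if not 0 <= self.reference_index < len(self.offsets_ppm):
                raise ValueError("reference_index out of range")

    def __len__(self) -> int:
        return len(self.offsets_ppm)

    @property
    def sampled_offsets(self) -> np.ndarray:
        """Offsets contributing Z-spectrum samples (reference frame excluded)."""
        arr = np.asarray(self.offsets_ppm, dtype=float)
        if self.reference_index is None:
            return arr
        return np.delete(arr, self.reference_index)

    def background_indices(self) -> np.ndarray:
        """Indices (into the sampled offsets) used by the 2-pool background fit.

        Only the MT-range and water-range offsets are assumed free of CEST
        contributions; every other offset is disregarded by the background fit.
        """
        sampled = self.sampled_offsets
        wanted = np.concatenate([MT_BACKGROUND_OFFSETS, WATER_BACKGROUND_OFFSETS])
        sel = np.isin(np.round(np.abs(sampled), 6), np.round(wanted, 6))
        return np.flatnonzero(sel)


@dataclass(frozen=True)
class AcquisitionParams:
    """Saturation parameters needed beyond the offset list.

    ``pulse_duration_s`` feeds the Fourier bandwidth of the water-line
    plateau, BW = (1 / t_pulse) * (gamma / 2π)⁻¹-scaled to ppm by the caller.
    """

    saturation_power_uT: float = 0.9
    saturation_duration_ms: float = 3000.0
    pulse_duration_s: float | None = None
    gyromagnetic_factor_MHz_per_T: float = 42.577
    field_strength_T: float = 3.0

    def __post_init__(self):
        for name in ("saturation_power_uT", "saturation_duration_ms",
                     "gyromagnetic_factor_MHz_per_T", "field_strength_T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pulse_duration_s is not None and self.pulse_duration_s <= 0:
            raise ValueError("pulse_duration_s must be strictly positive")

    def plateau_bandwidth_ppm(self) -> float:
        """Water-line plateau bandwidth in ppm.

        The Fourier width of the saturation pulse is 1/t_pulse in Hz;
        dividing by the Larmor frequency (γ/2π · B0, in MHz → Hz/ppm)
        expresses it in ppm. Returns 0 (standard Lorentzian) when the pulse
        duration is unset, with a warning, because the printed bandwidth
        expression does not resolve to unambiguous units.
        """
        if self.pulse_duration_s is None:
            warnings.warn("pulse duration unset; water-line plateau bandwidth "
                          "defaults to 0 (standard Lorentzian)", stacklevel=2)
            return 0.0
        hz_per_ppm = self.gyromagnetic_factor_MHz_per_T * self.field_strength_T
        return (1.0 / self.pulse_duration_s) / hz_per_ppm


@dataclass
class RoiMask:
    """A labelled boolean region of interest."""

    label: str
    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if not self.voxels.any():
            raise ValueError(f"ROI '{self.label}' is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class ZSpectrumVolume:
    """Per-voxel normalized Z-spectra.

    ``values`` has shape ``spatial_shape + (n_sampled_offsets,)`` and holds
    Z = S_sat/S0 (dimensionless). ``mask`` selects valid voxels;
    ``b0_map_ppm`` (optional) is a per-voxel static-field offset.
    """

    values: np.ndarray
    schedule: OffsetSchedule
    mask: np.ndarray
    b0_map_ppm: np.ndarray | None = None
    n_excluded_s0: int = 0
    #: voxels with any Z outside the [-0.2, 1.5] plausibility band (flag only)
    out_of_band: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.schedule.sampled_offsets)
        if self.values.shape[-1] != n:
            raise ValueError(
                f"spectral depth {self.values.shape[-1]} does not match the "
                f"{n} sampled offsets of the schedule")
        if self.mask.shape != self.values.shape[:-1]:
            raise ValueError("mask shape does not match spatial shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite Z values inside mask")
        if self.out_of_band is None:
            band = (self.values < -0.2) | (self.values > 1.5)
            self.out_of_band = band.any(axis=-1) & self.mask

    @property
    def offsets_ppm(self) -> np.ndarray:
        return self.schedule.sampled_offsets

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[:-1]

    def masked_spectra(self) -> np.ndarray:
        """Return spectra of in-mask voxels as an (n_voxels, n_offsets) array."""
        return self.values[self.mask]


def build_default_offset_schedule() -> OffsetSchedule:
    """The 64-entry acquisition schedule.

    Offsets in order: 0, then ± pairs in 0.25-ppm steps out to ±5 ppm, ±
    pairs in 0.5-ppm steps from ±5.5 to ±7.5 ppm, the MT-range pairs ±10,
    ±15, ±20, ±25, ±30, ±100 ppm, and finally +300 ppm, which is so far off
    resonance that saturation is negligible and the frame serves as S0.
    """
    offsets: list[float] = [0.0]
    for v in np.arange(0.25, 5.0 + 1e-9, 0.25):
        offsets += [float(v), float(-v)]
    for v in np.arange(5.5, 7.5 + 1e-9, 0.5):
        offsets += [float(v), float(-v)]
    for v in (10.0, 15.0, 20.0, 25.0, 30.0, 100.0):
        offsets += [v, -v]
    offsets.append(300.0)
    return OffsetSchedule(tuple(offsets), reference_index=len(offsets) - 1)


def normalize_to_zspectrum(saturated_stack: np.ndarray,
                           s0_image: np.ndarray | None,
                           schedule: OffsetSchedule,
                           mask: RoiMask | np.ndarray | None = None,
                           ) -> ZSpectrumVolume:
    """Normalize a saturated image stack to a Z-spectrum volume.

    Parameters
    ----------
    saturated_stack
        Shape ``spatial + (n,)``. When ``s0_image`` is given, ``n`` must
        equal the number of non-reference offsets; otherwise ``n`` must
        equal the full schedule length and S0 is taken from the reference
        frame inside the stack.
    s0_image
        Fully relaxed reference image, or ``None`` to use the in-stack
        reference frame.
    mask
        Optional ROI restricting normalization. Voxels whose S0 is zero or
        negative are excluded from the output mask; their count is recorded
        on the returned volume and reported with a warning.
    """
    stack = np.asarray(saturated_stack, dtype=float)
    n_sampled = len(schedule.sampled_offsets)
    if s0_image is None:
        if schedule.reference_index is None:
            raise ValueError("schedule has no reference frame and no s0 given")
        if stack.shape[-1] != len(schedule):
            raise ValueError(
                f"stack depth {stack.shape[-1]} != schedule length "
                f"{len(schedule)} (required to extract the in-stack S0)")
        s0 = stack[..., schedule.reference_index]
        stack = np.delete(stack, schedule.reference_index, axis=-1)
    else:
        if stack.shape[-1] != n_sampled:
            raise ValueError(
                f"stack depth {stack.shape[-1]} != {n_sampled} non-reference offsets")
        s0 = np.asarray(s0_image, dtype=float)

    if mask is None:
        m = np.ones(stack.shape[:-1], dtype=bool)
    else:
        m = mask.voxels if isinstance(mask, RoiMask) else np.asarray(mask, bool)
        if m.shape != stack.shape[:-1]:
            raise ValueError("mask shape does not match image shape")
        m = m.copy()

    bad = (s0 <= 0) & m
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxel(s) with non-positive S0 excluded from mask",
                      stacklevel=2)
        m &= ~bad

    with np.errstate(divide="ignore", invalid="ignore"):
        z = stack / s0[..., None]
    z[~m] = 0.0
    return ZSpectrumVolume(z, _sampled_only(schedule), m, n_excluded_s0=n_bad)


def _sampled_only(schedule: OffsetSchedule) -> OffsetSchedule:
    """Schedule restricted to its sampled offsets (reference dropped)."""
    if schedule.reference_index is None:
        return schedule
    return OffsetSchedule(tuple(schedule.sampled_offsets), reference_index=None)
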