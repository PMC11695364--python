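"""Motion correction, tensor denoising and B0 correction of Z-spectra.

The static field B0 varies smoothly over the brain, shifting every voxel's
Z-spectrum along the offset axis. The water resonance position from a
preliminary 2-pool (water + MT) fit serves as a surrogate B0 map; a
spline-interpolated spectrum minimum is available as an alternative.
Spectra are then re-sampled on the shifted grid to re-center water at
0 ppm before quantitative fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from skimage.registration import phase_cross_correlation

from .core import ZSpectrumVolume
from .lorentzian import FitOptions, fit_background

__all__ = [
    "B0Map",
    "register_subpixel",
    "denoise_mlsvd",
    "estimate_b0_two_pool",
    "estimate_b0_spline_minimum",
    "apply_b0_correction",
]


@dataclass
class B0Map:
    """Per-voxel static-field offset in ppm."""

    shift_ppm: np.ndarray
    method: str
    flagged: np.ndarray
    bound_ppm: float = 1.0

    def __post_init__(self):
        self.shift_ppm = np.asarray(self.shift_ppm, dtype=float)
        over = np.abs(self.shift_ppm) > self.bound_ppm
        self.flagged = np.asarray(self.flagged, bool) | over


def register_subpixel(stack: np.ndarray, reference_frame_index: int,
                      upsample_factor: int = 100,
                      min_correlation: float = 0.1
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Translate every frame onto the reference frame at subpixel precision.

    In-plane translation only (single-slice data), estimated by upsampled
    phase correlation. Frames that are constant or essentially uncorrelated
    with the reference (pure noise) are left untouched with a warning.

    Returns the corrected stack and the per-frame (dy, dx) shifts applied.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 frames to register")
    ref = stack[..., reference_frame_index]
    out = stack.copy()
    shifts = np.zeros((n, 2))
    for i in range(n):
        if i == reference_frame_index:
            continue
        frame = stack[..., i]
        if frame.std() == 0 or ref.std() == 0:
            warnings.warn(f"frame {i}: constant image, shift set to (0, 0)",
                          stacklevel=2)
            continue
        r = np.corrcoef(frame.ravel(), ref.ravel())[0, 1]
        if abs(r) < min_correlation:
            warnings.warn(f"frame {i}: correlation with reference {r:.2f} below "
                          f"{min_correlation}, shift set to (0, 0)", stacklevel=2)
            continue
        # normalization=None: plain cross-correlation. The default phase
        # normalization whitens the spectrum and is unreliable on smooth,
        # band-limited images such as MR magnitude data.
        shift, _err, _ = phase_cross_correlation(ref, frame,
                                                 upsample_factor=upsample_factor,
                                                 normalization=None)
        shifts[i] = shift
        out[..., i] = ndimage.shift(frame, shift, order=3, mode="nearest")
    return out, shifts


def _auto_rank(s: np.ndarray, shape: tuple[int, int]) -> int:
    """Keep singular values above the estimated noise bulk edge.

    For an m×n i.i.d.-noise matrix the singular values fall in
    [σ(√n−√m), σ(√n+√m)] (Marchenko–Pastur support). The smallest observed
    singular value bounds σ from above via σ̂ = s_min/(√n−√m); components
    below the upper edge σ̂(√m+√n) are treated as noise. On (near)
    noise-free data s_min is at numerical-rank level, so essentially all
    structure is kept.
    """
    m, n = min(shape), max(shape)
    if shape[0] < 32 or m == n:
        # too few singular values to locate a noise bulk reliably
        return shape[0]
    sigma_hat = s[-1] / (np.sqrt(n) - np.sqrt(m))
    edge = sigma_hat * (np.sqrt(n) + np.sqrt(m))
    keep = int(np.sum(s > edge))
    return max(keep, 1)


def _energy_rank(s: np.ndarray, fraction: float) -> int:
    e = np.cumsum(s ** 2) / np.sum(s ** 2)
    return int(np.searchsorted(e, fraction) + 1)


def denoise_mlsvd(stack: np.ndarray,
                  rank: tuple[int, ...] | None = None,
                  energy_fraction: float | None = None) -> np.ndarray:
    """Truncated multilinear (higher-order) SVD denoising of an image stack.

    The (x, y, offset) tensor is projected onto the leading left singular
    subspaces of each mode unfolding. Ranks come from, in order of
    precedence: an explicit per-mode ``rank`` tuple, an ``energy_fraction``
    (smallest rank retaining that fraction of squared singular-value
    energy per mode), or a noise-adaptive tail rule (default).
    """
    x = np.asarray(stack, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3-mode (x, y, offset) tensor")
    if rank is not None:
        if len(rank) != 3:
            raise ValueError("rank must have one entry per mode")
        for r, nmode in zip(rank, x.shape):
            if r > nmode:
                raise ValueError(f"rank {r} exceeds mode size {nmode}")
    out = x
    for mode in range(3):
        unf = np.moveaxis(out, mode, 0).reshape(out.shape[mode], -1)
        u, s, _ = np.linalg.svd(unf, full_matrices=False)
        if rank is not None:
            r = rank[mode]
        elif energy_fraction is not None:
            r = _energy_rank(s, energy_fraction)
        else:
            r = _auto_rank(s, unf.shape)
        proj = u[:, :r] @ (u[:, :r].T @ unf)
        out = np.moveaxis(proj.reshape((out.shape[mode],)
                                       + tuple(np.delete(out.shape, mode))),
                          0, mode)
    return out


def estimate_b0_two_pool(zspec: ZSpectrumVolume,
                         options: FitOptions | None = None,
                         bound_ppm: float = 1.0) -> B0Map:
    """B0 from the water-line position of the per-voxel 2-pool background fit.

    The fit is restricted to the MT-range and water-range background
    offsets; all other offsets are disregarded. Non-convergent voxels are
    flagged and fall back to 0 ppm.
    """
    shift = np.zeros(zspec.spatial_shape)
    flagged = np.zeros(zspec.spatial_shape, bool)
    offsets = zspec.offsets_ppm
    for idx in np.argwhere(zspec.mask):
        tidx = tuple(idx)
        try:
            bg = fit_background(zspec.values[tidx], offsets, options)
        except Exception:
            flagged[tidx] = True
            continue
        if not bg.converged:
            flagged[tidx] = True
            continue
        shift[tidx] = bg.water.position
    return B0Map(shift, "two_pool_fit", flagged, bound_ppm)


def estimate_b0_spline_minimum(zspec: ZSpectrumVolume,
                               search_ppm: float = 1.0,
                               grid_step_ppm: float = 0.001,
                               fit_window_ppm: float = 2.0,
                               bound_ppm: float = 1.0) -> B0Map:
    """B0 as the argmin of a cubic-spline interpolation of Z near water.

    Requires dense offset coverage of [−1, 1] ppm. When several grid points
    tie for the minimum, the one nearest 0 ppm is taken and the voxel is
    flagged.
    """
    offsets = zspec.offsets_ppm
    near = offsets[np.abs(offsets) <= search_ppm]
    if near.size < 5 or near.max() < search_ppm - 0.3 or near.min() > -search_ppm + 0.3:
        raise ValueError("offsets do not cover the water region densely")
    sel = np.abs(offsets) <= fit_window_ppm
    order = np.argsort(offsets[sel])
    xs = offsets[sel][order]
    grid = np.arange(-search_ppm, search_ppm + grid_step_ppm / 2, grid_step_ppm)
    shift = np.zeros(zspec.spatial_shape)
    flagged = np.zeros(zspec.spatial_shape, bool)
    for idx in np.argwhere(zspec.mask):
        tidx = tuple(idx)
        cs = CubicSpline(xs, zspec.values[tidx][sel][order])
        vals = cs(grid)
        vmin = vals.min()
        ties = np.flatnonzero(vals <= vmin + 1e-15)
        if ties.size > 1 and np.ptp(grid[ties]) > grid_step_ppm * 1.5:
            flagged[tidx] = True
        shift[tidx] = grid[ties[np.argmin(np.abs(grid[ties]))]]
    return B0Map(shift, "spline_minimum", flagged, bound_ppm)


def apply_b0_correction(zspec: ZSpectrumVolume, b0map: B0Map) -> ZSpectrumVolume:
    """Re-sample each voxel's spectrum at Δω + b0 to re-center water at 0.

    Cubic-spline interpolation on the sorted offset grid; query points
    falling outside the sampled range use spline extrapolation and the
    voxel is flagged in ``b0_map_ppm``-carrying metadata (count reported).
    """
    offsets = zspec.offsets_ppm
    order = np.argsort(offsets)
    xs = offsets[order]
    if not np.all(np.isfinite(b0map.shift_ppm)):
        raise ValueError("B0 map contains non-finite shifts")
    out = zspec.values.copy()
    n_extra = 0
    for idx in np.argwhere(zspec.mask):
        tidx = tuple(idx)
        d = b0map.shift_ppm[tidx]
        if d == 0.0:
            continue
        query = offsets + d
        if query.max() > xs[-1] or query.min() < xs[0]:
            n_extra += 1
        cs = CubicSpline(xs, zspec.values[tidx][order])
        out[tidx] = cs(query)
    if n_extra:
        warnings.warn(f"{n_extra} voxel(s) required extrapolation beyond the "
                      "sampled offset range during B0 correction", stacklevel=2)
    corrected = ZSpectrumVolume(out, zspec.schedule, zspec.mask.copy(),
                                b0_map_ppm=b0map.shift_ppm.copy(),
                                n_excluded_s0=zspec.n_excluded_s0)
    corrected.n_extrapolated = n_extra
    return corrected
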