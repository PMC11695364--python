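"""Synthetic CEST phantoms and cohorts with known ground truth.

The generator is the same 5-pool Lorentzian forward model the analysis
assumes (it deliberately does not simulate Bloch–McConnell exchange
dynamics): per-voxel Z-spectra are c − ΣL_pool evaluated on the acquisition
offset grid, with a smooth polynomial B0 field, optional per-frame in-plane
motion, and Gaussian or Rician noise on the saturated images. Cohorts add
group-level shifts of pool amplitudes and lognormal between-subject
variability, emulating the statistical structure of a two-group patient
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import OffsetSchedule, RoiMask, build_default_offset_schedule
from .lorentzian import LorentzianLine, eval_standard_line, eval_water_line

__all__ = [
    "TissueClass",
    "PhantomConfig",
    "CohortConfig",
    "PhantomResult",
    "SubjectData",
    "default_tissue_classes",
    "simulate_zspectrum",
    "generate_phantom",
    "generate_cohort",
    "cohort_truth_features",
]

CEST_POOLS = ("amide", "amine", "noe")
ALL_POOLS = ("ds", "mt", "amide", "amine", "noe")


@dataclass(frozen=True)
class TissueClass:
    """Pool parameters of one tissue type (amplitudes in Z units, ppm widths)."""

    label: str
    pools: dict[str, LorentzianLine]
    c: float = 1.0

    def __post_init__(self):
        missing = set(ALL_POOLS) - set(self.pools)
        if missing:
            raise ValueError(f"tissue {self.label!r} missing pools {sorted(missing)}")
        total = sum(l.amplitude for l in self.pools.values())
        if not 0.0 <= total < 1.2:
            raise ValueError(f"pool amplitudes of {self.label!r} sum to {total:.3f}, "
                             "outside the plausible [0, 1.2) band")


def default_tissue_classes() -> tuple[TissueClass, ...]:
    """Tumor / edema / normal-appearing white matter defaults.

    Amplitudes are chosen so downstream DS, MT and amide histogram values
    land in clinically reported ranges at 3 T (DS ≈ 0.78–0.80, MT ≈
    0.10–0.17, amide ≈ 0.04–0.06); they are conveniences for testing, not
    claims about tissue.
    """
    def cls(label, ds, mt, amide, amine, noe, gw=2.0):
        return TissueClass(label, {
            "ds": LorentzianLine(ds, gw, 0.0),
            "mt": LorentzianLine(mt, 40.0, -1.0),
            "amide": LorentzianLine(amide, 1.5, 3.5),
            "amine": LorentzianLine(amine, 1.8, 2.0),
            "noe": LorentzianLine(noe, 3.0, -3.5),
        })
    return (
        cls("tumor", ds=0.80, mt=0.14, amide=0.055, amine=0.020, noe=0.055),
        cls("edema", ds=0.84, mt=0.11, amide=0.045, amine=0.018, noe=0.048),
        cls("normal", ds=0.78, mt=0.16, amide=0.040, amine=0.015, noe=0.050),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic phantom slice.

    ``b0_field`` is ``"none"``, ``"quadratic"`` (second-order polynomial
    scaled to ``b0_max_ppm`` peak amplitude, a typical 3 T shim scale) or a
    dict of 2-D polynomial coefficients ``{(i, j): coeff}`` over normalized
    coordinates in [−1, 1]. ``jitter`` is the relative half-width of the
    uniform per-voxel variation of pool amplitudes and widths (biological
    heterogeneity). ``noise_sd`` is the noise standard deviation as a
    fraction of S0 on the saturated images.
    """

    grid_shape: tuple[int, int] = (24, 24)
    tissue_classes: tuple[TissueClass, ...] = field(default_factory=default_tissue_classes)
    b0_field: str | dict = "none"
    b0_max_ppm: float = 0.5
    motion_shifts_px: tuple[tuple[float, float], ...] | None = None
    noise_sd: float = 0.0
    noise_model: str = "gaussian"
    jitter: float = 0.10
    s0_value: float = 1000.0
    plateau_bw: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter must be in [0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Two-group (or more) cohort structure.

    ``group_effects`` maps a group label to additive shifts of pool
    amplitudes in every tissue class (e.g. ``{"wt": {"amide": 0.015}}``);
    ``group_effects_mul`` applies multiplicative factors the same way.
    ``between_subject_sd`` is the lognormal sigma of per-subject,
    per-pool amplitude multipliers; these random effects apply to the
    CEST solute pools (amide, amine, NOE) only.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {"g1": 10, "g2": 10})
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    group_effects_mul: dict[str, dict[str, float]] = field(default_factory=dict)
    between_subject_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2")
        for d in (self.group_effects, self.group_effects_mul):
            for g, eff in d.items():
                if not all(np.isfinite(list(eff.values()))):
                    raise ValueError("group effects must be finite")


def simulate_zspectrum(pools: dict[str, LorentzianLine], schedule,
                       b0_shift_ppm: float = 0.0, plateau_bw: float = 0.0,
                       c: float = 1.0) -> np.ndarray:
    """Noise-free forward model Z(Δω) = c − Σ L_pool(Δω − b0).

    The water pool ("ds") carries the plateau bandwidth; every other pool
    is a standard Lorentzian. A static-field offset shifts all lines
    together.
    """
    if isinstance(schedule, OffsetSchedule):
        offsets = schedule.sampled_offsets
    else:
        offsets = np.asarray(schedule, dtype=float)
    dw = offsets - b0_shift_ppm
    z = np.full(dw.shape, float(c))
    for name, line in pools.items():
        if name == "ds":
            z = z - eval_water_line(dw, replace(line, plateau_bw=plateau_bw))
        else:
            z = z - eval_standard_line(dw, line)
    return z


@dataclass
class PhantomResult:
    """Saturated stack (full schedule incl. reference frame), S0, masks, truth."""

    stack: np.ndarray
    s0: np.ndarray
    schedule: OffsetSchedule
    mask: np.ndarray
    masks: dict[str, RoiMask]
    truth: dict
    config: PhantomConfig


def _b0_map(config: PhantomConfig) -> np.ndarray:
    ny, nx = config.grid_shape
    v, u = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij")
    if config.b0_field == "none":
        return np.zeros(config.grid_shape)
    if config.b0_field == "quadratic":
        raw = 0.4 * u + 0.3 * v + 0.5 * u * v + 0.6 * u**2 - 0.4 * v**2
    else:
        raw = np.zeros(config.grid_shape)
        for (i, j), cij in config.b0_field.items():
            raw = raw + cij * u**int(i) * v**int(j)
        return raw  # explicit coefficients taken literally
    return raw / np.max(np.abs(raw)) * config.b0_max_ppm


def _class_map(config: PhantomConfig) -> np.ndarray:
    """Concentric layout: central tumor disk, edema ring, normal background."""
    ny, nx = config.grid_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot((yy - (ny - 1) / 2) / ny, (xx - (nx - 1) / 2) / nx)
    cmap = np.full(config.grid_shape, min(2, len(config.tissue_classes) - 1), dtype=int)
    if len(config.tissue_classes) > 1:
        cmap[r < 0.38] = 1
    cmap[r < 0.22] = 0
    return cmap


def generate_phantom(config: PhantomConfig) -> PhantomResult:
    """Deterministically synthesize one phantom from its config and seed."""
    rng = np.random.default_rng(config.seed)
    schedule = build_default_offset_schedule()
    offsets = schedule.sampled_offsets
    ny, nx = config.grid_shape
    cmap = _class_map(config)
    b0 = _b0_map(config)

    amp_truth = {p: np.zeros(config.grid_shape) for p in ALL_POOLS}
    wid_truth = {p: np.zeros(config.grid_shape) for p in ALL_POOLS}
    z_clean = np.zeros((ny, nx, offsets.size))
    for iy in range(ny):
        for ix in range(nx):
            tc = config.tissue_classes[cmap[iy, ix]]
            pools = {}
            for p, line in tc.pools.items():
                ja = 1 + config.jitter * rng.uniform(-1, 1)
                jw = 1 + config.jitter * rng.uniform(-1, 1)
                pools[p] = replace(line, amplitude=line.amplitude * ja,
                                   width=line.width * jw)
                amp_truth[p][iy, ix] = pools[p].amplitude
                wid_truth[p][iy, ix] = pools[p].width
            z_clean[iy, ix] = simulate_zspectrum(
                pools, offsets, b0_shift_ppm=b0[iy, ix],
                plateau_bw=config.plateau_bw, c=tc.c)

    # derived noise-free asymmetry truth (M0 = 1 on normalized spectra)
    def z_at(ppm):
        idx = int(np.argmin(np.abs(offsets - ppm)))
        return z_clean[..., idx]
    truth_mtr35 = z_at(-3.5) - z_at(3.5)
    truth_asym30 = z_at(-3.0) - z_at(3.0)

    s0 = np.full(config.grid_shape, config.s0_value)
    stack = np.empty((ny, nx, len(schedule)))
    sampled_ix = [i for i in range(len(schedule)) if i != schedule.reference_index]
    for k, i in enumerate(sampled_ix):
        stack[..., i] = z_clean[..., k] * s0
    stack[..., schedule.reference_index] = s0

    if config.motion_shifts_px is not None:
        for i, (dy, dx) in enumerate(config.motion_shifts_px):
            stack[..., i] = ndimage.shift(stack[..., i], (dy, dx), order=3,
                                          mode="nearest")

    if config.noise_sd > 0:
        sd = config.noise_sd * config.s0_value
        if config.noise_model == "gaussian":
            stack = stack + rng.normal(0, sd, stack.shape)
        else:
            stack = np.hypot(stack + rng.normal(0, sd, stack.shape),
                             rng.normal(0, sd, stack.shape))

    masks = {}
    for i, tc in enumerate(config.tissue_classes):
        sel = cmap == i
        if sel.any():
            masks[tc.label] = RoiMask(tc.label, sel)
    truth = {
        "amplitude": amp_truth, "width": wid_truth, "b0_ppm": b0,
        "mtr35": truth_mtr35, "mtrasym30": truth_asym30,
        "class_map": cmap,
        "class_labels": tuple(tc.label for tc in config.tissue_classes),
        "z_clean": z_clean,
    }
    return PhantomResult(stack=stack, s0=s0, schedule=schedule,
                         mask=np.ones(config.grid_shape, bool), masks=masks,
                         truth=truth, config=config)


@dataclass
class SubjectData:
    subject_id: str
    group: str
    phantom: PhantomResult | None
    #: per-pool subject-level mean tumor amplitudes (ground truth)
    truth_amplitudes: dict[str, float]
    seed: int


def _subject_tissue_classes(base: tuple[TissueClass, ...], group: str,
                            cfg: CohortConfig, rng: np.random.Generator
                            ) -> tuple[tuple[TissueClass, ...], dict[str, float]]:
    add = cfg.group_effects.get(group, {})
    mul = cfg.group_effects_mul.get(group, {})
    # Subject-level random effects act on the small CEST solute pools only;
    # water and MT amplitudes vary far less across subjects than solute
    # concentrations do, and scaling them lognormally would routinely push
    # the pool-amplitude sum out of the physical band.
    # Truncated lognormal (±2.5 sigma): biological between-subject variation
    # is bounded, and unbounded tails would occasionally produce tissue with
    # an unphysical pool-amplitude sum.
    factors = {p: float(np.exp(np.clip(rng.normal(0.0, cfg.between_subject_sd),
                                       -2.5 * cfg.between_subject_sd,
                                       2.5 * cfg.between_subject_sd)))
               if p in CEST_POOLS else 1.0
               for p in ALL_POOLS}
    out = []
    tumor_amp = {}
    for tc in base:
        pools = {}
        for p, line in tc.pools.items():
            a = (line.amplitude + add.get(p, 0.0)) * mul.get(p, 1.0) * factors[p]
            pools[p] = replace(line, amplitude=max(a, 0.0))
        out.append(TissueClass(tc.label, pools, tc.c))
        if tc.label == base[0].label:
            tumor_amp = {p: pools[p].amplitude for p in ALL_POOLS}
    return tuple(out), tumor_amp


def generate_cohort(cohort: CohortConfig, phantom: PhantomConfig,
                    images: bool = True) -> list[SubjectData]:
    """Draw a multi-subject cohort; each subject is one phantom slice.

    Group effects shift the ground-truth pool amplitudes of every tissue
    class; subject-level lognormal random effects are applied on top. With
    ``images=False`` only the subject-level ground truth is drawn (fast
    path for statistical calibration studies).
    """
    ss = np.random.SeedSequence(cohort.seed)
    subjects: list[SubjectData] = []
    labels = sorted(cohort.n_per_group)
    child_seeds = ss.spawn(sum(cohort.n_per_group.values()))
    k = 0
    for g in labels:
        for i in range(cohort.n_per_group[g]):
            sseed = int(child_seeds[k].generate_state(1)[0] % (2**31 - 1))
            k += 1
            rng = np.random.default_rng(sseed)
            classes, tumor_amp = _subject_tissue_classes(
                phantom.tissue_classes, g, cohort, rng)
            ph = None
            if images:
                ph = generate_phantom(replace(phantom, tissue_classes=classes,
                                              seed=sseed))
            subjects.append(SubjectData(subject_id=f"{g}_{i:03d}", group=g,
                                        phantom=ph, truth_amplitudes=tumor_amp,
                                        seed=sseed))
    return subjects


def cohort_truth_features(subjects: list[SubjectData], pool: str = "amide"
                          ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Ground-truth subject feature vector, binary labels and group order.

    Returns the per-subject truth amplitude of ``pool`` in the first tissue
    class (tumor), labels coded 0/1 by sorted group name, and the sorted
    group names. This is the oracle feature set against which pipeline-
    derived features are compared.
    """
    groups = sorted({s.group for s in subjects})
    if len(groups) != 2:
        raise ValueError("truth features require exactly two groups")
    x = np.array([s.truth_amplitudes[pool] for s in subjects])
    y = np.array([groups.index(s.group) for s in subjects])
    return x, y, groups
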