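"""Synthetic AD-vs-control glucoCEST cohorts.

Generates, from a seeded specification, everything the analysis stages
consume: dynamic CEST series (7 infusion timepoints x 61 offsets, with B0
field, noise and parametric brain/hippocampus/cortex ROI geometry), paired
six-direction DWI sets, and a per-animal hippocampal myo-inositol value tied
to the animal's true glucoCEST enhancement through a linear link.

Voxel MTRasym targets are converted into full Z-spectra by the
Bloch-McConnell forward model: a per-scheme library of spectra is simulated
over a glucose-concentration grid, the concentration reaching each target is
found on the (monotone) concentration -> MTRasym curve, and the voxel
spectrum is interpolated between the bracketing simulations.  Because
MTRasym is a linear functional of the spectrum, the interpolated spectrum
hits its target exactly, so a noise-free cohort is recovered exactly by the
processing pipeline.

Group effects follow the study design being emulated: n = 6 + 6, a
piecewise-linear uptake curve rising to a plateau of 0.03 (delta MTRasym)
for controls that then holds steady, and a lower-plateau curve for the AD
group that declines late in the infusion, with its minimum at the 40-min
timepoint; a normal animal-level random effect (sd 0.005) acts on both the
baseline level and the plateau.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.interpolate import CubicSpline

from .bloch import simulate_zspectrum
from .dti import DEFAULT_BVECS, DiffusionSet, tensor_from_elements
from .gce import TIMEPOINTS, CestSeries
from .pools import SaturationScheme, glucose_invivo_system, invivo_scheme
from .zspec import B0Map, mtr_asym_at

__all__ = [
    "CohortSpec",
    "CohortSpecError",
    "AnimalData",
    "Cohort",
    "SpectrumLibrary",
    "make_rois",
    "b0_field_map",
    "generate_animal",
    "generate_cohort",
    "sample_cohort_frame",
    "gce_population_moments",
    "mi_sigma_for_r2",
    "axisymmetric_tensor",
]


class CohortSpecError(ValueError):
    """The cohort specification is internally inconsistent or unreachable."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    MTRasym quantities are dimensionless (fractions, not percent); the
    uptake curves give the group-mean change from baseline at the seven
    infusion timepoints (0, 10, 20, 30, 40 min infusion; +10, +20 min post).
    """

    n_per_group: int = 6
    grid: tuple[int, int] = (32, 32)
    baseline_mtr: tuple[tuple[str, float], ...] = (("control", 0.05), ("ad", 0.05))
    uptake_curve: tuple[tuple[str, tuple[float, ...]], ...] = (
        ("control", (0.0, 0.015, 0.025, 0.030, 0.030, 0.030, 0.030)),
        ("ad", (0.0, 0.008, 0.012, 0.004, -0.006, -0.003, -0.001)),
    )
    animal_sd: float = 0.005        # sd of the per-animal plateau effect
    baseline_sd: float = 0.005      # sd of the per-animal baseline effect
    noise_sigma: float = 0.002      # additive Gaussian sd on z images
    b0_field: tuple[float, ...] = (0.0,)   # Hz; 2-D polynomial coefficients
    scheme: SaturationScheme = field(default_factory=invivo_scheme)
    glucose_ph: float = 7.4
    # myo-inositol link: mI = alpha + beta * GCE + N(0, sigma); sigma=None
    # derives the noise sd that makes the population R^2 equal mi_target_r2.
    mi_alpha: float = 4.0           # mM
    mi_beta: float = 40.0           # mM per GCE unit
    mi_sigma: float | None = None
    mi_target_r2: float = 0.626
    # DWI ground truth (brain tissue)
    dwi_adc: float = 0.8e-3         # mm^2/s
    dwi_fa: float = 0.3
    dwi_bval: float = 1031.0        # s/mm^2
    dwi_noise_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise CohortSpecError("n_per_group must be >= 2")
        if self.noise_sigma < 0 or self.animal_sd < 0 or self.baseline_sd < 0:
            raise CohortSpecError("noise/effect sds must be >= 0")
        for g, curve in self.uptake_curve:
            if len(curve) != len(TIMEPOINTS):
                raise CohortSpecError(f"uptake curve for {g!r} needs {len(TIMEPOINTS)} values")
            if curve[0] != 0.0:
                raise CohortSpecError("uptake_curve must be 0 at baseline")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.uptake_curve)

    def baseline(self, group: str) -> float:
        return dict(self.baseline_mtr)[group]

    def curve(self, group: str) -> np.ndarray:
        return np.asarray(dict(self.uptake_curve)[group], dtype=float)

    def plateau(self, group: str) -> float:
        return float(np.max(self.curve(group)))

    def gce_true(self, group: str) -> float:
        """Group-mean true GCE: mean of the 40-min and post-10 deltas."""
        c = self.curve(group)
        return float(0.5 * (c[4] + c[5]))

    def resolved_mi_sigma(self) -> float:
        if self.mi_sigma is not None:
            return self.mi_sigma
        return mi_sigma_for_r2(self, self.mi_target_r2)


# --------------------------------------------------------------- geometry --


def _ellipse(grid, cy, cx, ry, rx):
    ny, nx = grid
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((yy + 0.5 - cy) / ry) ** 2 + ((xx + 0.5 - cx) / rx) ** 2 <= 1.0


def make_rois(grid: tuple[int, int]) -> dict[str, np.ndarray]:
    """Parametric brain / bilateral hippocampus / parietal cortex masks."""
    ny, nx = grid
    brain = _ellipse(grid, 0.5 * ny, 0.5 * nx, 0.40 * ny, 0.45 * nx)
    rois = {"total_brain": brain}
    rois["hippocampus_L"] = _ellipse(grid, 0.58 * ny, 0.34 * nx, 0.10 * ny, 0.09 * nx) & brain
    rois["hippocampus_R"] = _ellipse(grid, 0.58 * ny, 0.66 * nx, 0.10 * ny, 0.09 * nx) & brain
    rois["parietal_cortex_L"] = _ellipse(grid, 0.26 * ny, 0.32 * nx, 0.09 * ny, 0.12 * nx) & brain
    rois["parietal_cortex_R"] = _ellipse(grid, 0.26 * ny, 0.68 * nx, 0.09 * ny, 0.12 * nx) & brain
    for name, m in rois.items():
        if not np.any(m):
            raise CohortSpecError(f"ROI {name!r} is empty on grid {grid}")
    return rois


def b0_field_map(coeffs: tuple[float, ...], grid: tuple[int, int]) -> np.ndarray:
    """Smooth polynomial B0 field (Hz) on normalized [-1, 1] coordinates.

    Basis order: 1, x, y, x^2, y^2, xy (truncated to ``len(coeffs)``).
    """
    ny, nx = grid
    y = np.linspace(-1, 1, ny)[:, None] * np.ones((1, nx))
    x = np.linspace(-1, 1, nx)[None, :] * np.ones((ny, 1))
    basis = [np.ones_like(x), x, y, x**2, y**2, x * y]
    if len(coeffs) > len(basis):
        raise CohortSpecError(f"at most {len(basis)} b0_field coefficients supported")
    out = np.zeros((ny, nx))
    for c, b in zip(coeffs, basis):
        out += c * b
    return out


# ---------------------------------------------------- spectrum generation --

_CONC_GRID = np.concatenate([[0.0], np.geomspace(2.0, 900.0, 26)])
_library_cache: dict = {}


class SpectrumLibrary:
    """Maps MTRasym(0.9 ppm) targets to full Z-spectra for one scheme.

    Spectra are simulated on a fixed glucose-concentration grid; a target is
    reached by linear interpolation between the two bracketing simulations
    on the monotone concentration -> MTRasym curve.  MTRasym is linear in
    the spectrum, so the interpolated spectrum attains the target exactly.
    """

    def __init__(self, scheme: SaturationScheme, ph: float = 7.4,
                 delta_ppm: float = 0.9):
        self.scheme = scheme
        self.delta_ppm = delta_ppm
        spectra = [
            simulate_zspectrum(glucose_invivo_system(c, ph), scheme)
            for c in _CONC_GRID
        ]
        mtr = np.array([mtr_asym_at(s, delta_ppm) for s in spectra])
        # keep the strictly increasing prefix (effect saturates at high conc)
        keep = 1 + int(np.argmax(np.diff(mtr) <= 0)) if np.any(np.diff(mtr) <= 0) else mtr.size
        self.conc = _CONC_GRID[:keep]
        self.mtr = mtr[:keep]
        self.z = np.stack([s.z for s in spectra[:keep]])   # (n_conc, n_off)
        self.offsets_hz = spectra[0].offsets_hz
        self.larmor = scheme.larmor_hz_per_ppm

    @property
    def ceiling(self) -> float:
        return float(self.mtr[-1])

    def spectrum_for_target(self, target: float) -> np.ndarray:
        """Z-spectrum whose MTRasym(0.9 ppm) equals ``target``."""
        if not np.isfinite(target) or target < 0:
            raise CohortSpecError(f"MTRasym target must be finite and >= 0, got {target!r}")
        if target > self.ceiling:
            raise CohortSpecError(
                f"MTRasym target {target:.4f} exceeds the achievable ceiling "
                f"{self.ceiling:.4f} for this scheme"
            )
        i = int(np.clip(np.searchsorted(self.mtr, target) - 1, 0, self.mtr.size - 2))
        w = (target - self.mtr[i]) / (self.mtr[i + 1] - self.mtr[i])
        return (1.0 - w) * self.z[i] + w * self.z[i + 1]


def get_library(scheme: SaturationScheme, ph: float = 7.4) -> SpectrumLibrary:
    """Process-wide cache of spectrum libraries keyed by scheme and pH."""
    key = (scheme, ph)
    if key not in _library_cache:
        _library_cache[key] = SpectrumLibrary(scheme, ph)
    return _library_cache[key]


# ------------------------------------------------------ animal generation --


@dataclass
class AnimalData:
    animal_id: str
    group: str
    series: CestSeries
    dwi: DiffusionSet | None
    mi: float
    truth: dict


def axisymmetric_tensor(adc: float, fa: float) -> np.ndarray:
    """Unique elements of a z-axial tensor with given mean diffusivity and FA."""
    if not 0 <= fa < 1:
        raise ValueError("fa must be in [0, 1)")
    delta = fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))
    lam_par = adc * (1 + 2 * delta)
    lam_perp = adc * (1 - delta)
    return np.array([lam_perp, lam_perp, lam_par, 0.0, 0.0, 0.0])


def _assemble_stack(
    library: SpectrumLibrary,
    targets: dict[str, float],
    region_masks: dict[str, np.ndarray],
    shift_hz: np.ndarray,
) -> np.ndarray:
    """Per-offset image with each region carrying its target spectrum.

    A nonzero B0 field displaces the measured spectrum: the stored signal at
    offset d is the true spectrum evaluated at d - shift.
    """
    off = library.offsets_hz
    grid = shift_hz.shape
    stack = np.zeros(grid + (off.size,))
    flat_shift = shift_hz.reshape(-1)
    for region, mask in region_masks.items():
        z_true = library.spectrum_for_target(targets[region])
        m = mask.reshape(-1)
        if not np.any(m):
            continue
        s = flat_shift[m]
        if np.all(s == 0.0):
            stack.reshape(-1, off.size)[m] = z_true
        else:
            cs = CubicSpline(off, z_true)
            stack.reshape(-1, off.size)[m] = cs(off[None, :] - s[:, None])
    return stack


def generate_animal(
    spec: CohortSpec,
    group: str,
    animal_id: str,
    rng: np.random.Generator,
    include_dwi: bool = True,
    library: SpectrumLibrary | None = None,
) -> AnimalData:
    """One synthetic animal: CEST series, DWI set and myo-inositol value.

    All ground-truth parameters are recorded in ``truth``.  The CEST, DWI
    and metabolite noise streams are split from ``rng`` so that skipping the
    DWI set does not perturb the other draws.
    """
    if group not in spec.groups:
        raise CohortSpecError(f"unknown group {group!r}; spec has {spec.groups}")
    if library is None:
        library = get_library(spec.scheme, spec.glucose_ph)
    rng_cest, rng_dwi, rng_mi = rng.spawn(3)

    baseline = spec.baseline(group) + rng_cest.normal(0.0, spec.baseline_sd)
    plateau_g = spec.plateau(group)
    plateau_i = plateau_g + rng_cest.normal(0.0, spec.animal_sd)
    scale = plateau_i / plateau_g
    curve_i = scale * spec.curve(group)
    if baseline + np.max(curve_i) > library.ceiling or baseline + np.min(curve_i) < 0:
        raise CohortSpecError(
            f"animal {animal_id!r}: MTRasym targets "
            f"[{baseline + np.min(curve_i):.4f}, {baseline + np.max(curve_i):.4f}] "
            "outside the achievable range"
        )

    rois = make_rois(spec.grid)
    shift = b0_field_map(spec.b0_field, spec.grid)
    brain = rois["total_brain"]
    regions = {"brain": brain, "background": ~brain}

    stacks, s0_images = {}, {}
    for (label, _), delta in zip(TIMEPOINTS, curve_i):
        targets = {"brain": baseline + delta, "background": 0.0}
        stack = _assemble_stack(library, targets, regions, shift)
        if spec.noise_sigma > 0:
            stack += rng_cest.normal(0.0, spec.noise_sigma, size=stack.shape)
        s0 = np.ones(spec.grid)
        if spec.noise_sigma > 0:
            s0 += rng_cest.normal(0.0, spec.noise_sigma, size=s0.shape)
        stacks[label] = stack
        s0_images[label] = s0

    series = CestSeries(
        stacks=stacks,
        s0_images=s0_images,
        offsets_hz=library.offsets_hz.copy(),
        rois=rois,
        b0=B0Map(shift.copy()),
        larmor_hz_per_ppm=library.larmor,
    )

    dwi = None
    if include_dwi:
        d6 = axisymmetric_tensor(spec.dwi_adc, spec.dwi_fa)
        D = tensor_from_elements(d6)
        atten = np.exp(-spec.dwi_bval * np.einsum("id,de,ie->i", DEFAULT_BVECS, D, DEFAULT_BVECS))
        s0_d = np.where(brain, 1.0, 0.0)
        dwi_img = s0_d[..., None] * atten[None, None, :]
        if spec.dwi_noise_sigma > 0:
            dwi_img = dwi_img + rng_dwi.normal(0.0, spec.dwi_noise_sigma, dwi_img.shape)
            s0_d = s0_d + rng_dwi.normal(0.0, spec.dwi_noise_sigma, s0_d.shape)
        dwi = DiffusionSet(s0_d, dwi_img, DEFAULT_BVECS.copy(), spec.dwi_bval)

    gce_true = scale * spec.gce_true(group)
    mi = spec.mi_alpha + spec.mi_beta * gce_true + rng_mi.normal(0.0, spec.resolved_mi_sigma())

    truth = {
        "animal_id": animal_id,
        "group": group,
        "baseline_mtr": float(baseline),
        "plateau": float(plateau_i),
        "scale": float(scale),
        "uptake_curve": [float(v) for v in curve_i],
        "gce_true": float(gce_true),
        "mi": float(mi),
        "dwi_adc": spec.dwi_adc,
        "dwi_fa": spec.dwi_fa,
    }
    return AnimalData(animal_id, group, series, dwi, float(mi), truth)


@dataclass
class Cohort:
    spec: CohortSpec
    animals: tuple[AnimalData, ...]

    @property
    def manifest(self) -> dict:
        return {
            "spec": _spec_to_jsonable(self.spec),
            "animals": [a.truth for a in self.animals],
        }


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = {}
    for f in fields(spec):
        v = getattr(spec, f.name)
        if isinstance(v, SaturationScheme):
            v = {
                "B1_uT": v.B1_uT,
                "t_sat": v.t_sat,
                "TR": v.TR,
                "offsets_hz": list(v.offsets_hz),
                "ref_offset_hz": v.ref_offset_hz,
                "larmor_hz_per_ppm": v.larmor_hz_per_ppm,
            }
        d[f.name] = v
    return json.loads(json.dumps(d))  # normalize tuples -> lists


def spec_from_jsonable(d: dict) -> CohortSpec:
    """Rebuild a CohortSpec from a truth-manifest dictionary."""
    d = dict(d)
    d["grid"] = tuple(d["grid"])
    d["baseline_mtr"] = tuple((g, v) for g, v in d["baseline_mtr"])
    d["uptake_curve"] = tuple((g, tuple(c)) for g, c in d["uptake_curve"])
    d["b0_field"] = tuple(d["b0_field"])
    s = d["scheme"]
    d["scheme"] = SaturationScheme(
        s["B1_uT"], s["t_sat"], s["TR"], tuple(s["offsets_hz"]),
        s["ref_offset_hz"], s["larmor_hz_per_ppm"],
    )
    return CohortSpec(**d)


def generate_cohort(
    spec: CohortSpec,
    out_dir=None,
    force: bool = False,
    include_dwi: bool = True,
) -> Cohort:
    """Generate ``n_per_group`` animals per group from ``spec.seed``.

    With ``out_dir`` the cohort is also written to disk (NIfTI stacks, ROI
    label maps, DWI, sidecars, metabolite table and truth manifest); an
    existing non-empty directory is refused unless ``force`` is set.
    """
    rng = np.random.default_rng(spec.seed)
    library = get_library(spec.scheme, spec.glucose_ph)
    animals = []
    for group in spec.groups:
        for i in range(spec.n_per_group):
            aid = f"{group}_{i + 1:02d}"
            animals.append(
                generate_animal(spec, group, aid, rng, include_dwi, library)
            )
    cohort = Cohort(spec, tuple(animals))
    if out_dir is not None:
        from .io import write_cohort

        write_cohort(cohort, out_dir, force=force)
    return cohort


# ------------------------------------------------------- tabular sampling --


def sample_cohort_frame(
    spec: CohortSpec, rng: np.random.Generator, n_per_group: int | None = None
):
    """Animal-level true GCE and mI draws without image synthesis.

    Uses the same distributions the image pathway realizes (plateau random
    effect scaling the group uptake curve; linear mI link), for statistical
    tests that do not need the imaging stack.
    """
    import pandas as pd

    n = n_per_group if n_per_group is not None else spec.n_per_group
    sigma = spec.resolved_mi_sigma()
    rows = []
    for group in spec.groups:
        m_g = spec.gce_true(group)
        p_g = spec.plateau(group)
        for i in range(n):
            scale = 1.0 + rng.normal(0.0, spec.animal_sd) / p_g
            gce = scale * m_g
            mi = spec.mi_alpha + spec.mi_beta * gce + rng.normal(0.0, sigma)
            rows.append({"animal": f"{group}_{i + 1:02d}", "group": group,
                         "gce": gce, "mi": mi})
    return pd.DataFrame(rows)


def gce_population_moments(spec: CohortSpec) -> tuple[float, float]:
    """Mean and variance of true GCE under the equal-weight group mixture."""
    means, variances = [], []
    for group in spec.groups:
        m_g = spec.gce_true(group)
        p_g = spec.plateau(group)
        means.append(m_g)
        variances.append((m_g * spec.animal_sd / p_g) ** 2)
    means = np.asarray(means)
    mean = float(np.mean(means))
    var = float(np.mean(variances) + np.mean((means - mean) ** 2))
    return mean, var


def mi_sigma_for_r2(spec: CohortSpec, r2: float) -> float:
    """Noise sd making the population R^2 of the mI ~ GCE link equal ``r2``."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    _, var = gce_population_moments(spec)
    signal_var = spec.mi_beta**2 * var
    return float(np.sqrt(signal_var * (1.0 - r2) / r2))
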