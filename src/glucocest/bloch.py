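"""Multi-pool Bloch-McConnell simulation of CW-CEST experiments.

The magnetization of water plus N dilute solute pools evolves under

    dM/dt = A M + b,

where A stacks, per pool, transverse relaxation, off-resonance precession at
``2*pi*(delta_i*larmor - offset_rf)``, the CW saturation field omega1 about x,
longitudinal relaxation, and first-order two-site exchange with water obeying
detailed balance (water -> solute rate f_s * k_s, solute -> water rate k_s).
The affine system is solved exactly over each interval via the matrix
exponential: M(t) = M_ss + expm(A t) (M0 - M_ss) with M_ss = -A^{-1} b.

One repetition of the acquisition is modeled as

    readout (magnetization spoiled to zero)
      -> free recovery for TR - t_sat
      -> CW saturation for t_sat at the offset of interest
      -> readout of water Mz,

iterated to its periodic steady state.  The reference signal S0 is produced
by the same cycle with saturation applied at the far off-resonance reference
offset, and the Z-spectrum is the ratio of the two readouts.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .pools import (
    PoolSystem,
    SaturationScheme,
    exchange_rate_at_ph,
    load_defaults,
)
from .zspec import ZSpectrum, mtr_asym_at

__all__ = [
    "SimulationError",
    "simulate_zspectrum",
    "steady_state_zspectrum",
    "sweep",
    "SweepResult",
    "phantom_image",
    "PhantomImage",
    "bloch_mcconnell_matrix",
]

SWEEPABLE = ("concentration", "ph", "B1_uT", "t_sat", "TR")

_MAX_CYCLES = 10
_CYCLE_TOL = 1e-8


class SimulationError(RuntimeError):
    """The linearized system is too stiff / ill-conditioned to solve reliably."""


def bloch_mcconnell_matrix(
    system: PoolSystem, offset_hz: float, omega1: float, larmor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (A, b) for the coupled system in the RF rotating frame.

    State ordering is [Mx, My, Mz] per pool, water first.  b carries the
    R1*M0 longitudinal recovery terms (water M0 = 1, solute M0 = f_s).
    """
    pools = (system.water, *system.solutes)
    n = len(pools)
    fracs = [1.0] + [system.fraction(p) for p in pools[1:]]
    k_to_water = [0.0] + [p.k_exch for p in pools[1:]]
    k_water_out = sum(f * k for f, k in zip(fracs[1:], k_to_water[1:]))

    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    for i, p in enumerate(pools):
        dw = 2.0 * np.pi * (p.delta_ppm * larmor - offset_hz)
        R1, R2 = 1.0 / p.T1, 1.0 / p.T2
        k_out = k_water_out if i == 0 else k_to_water[i]
        j = 3 * i
        A[j, j] = -(R2 + k_out)
        A[j, j + 1] = -dw
        A[j + 1, j] = dw
        A[j + 1, j + 1] = -(R2 + k_out)
        A[j + 1, j + 2] = omega1
        A[j + 2, j + 1] = -omega1
        A[j + 2, j + 2] = -(R1 + k_out)
        b[j + 2] = R1 * fracs[i]
        if i > 0:
            # exchange coupling with water, componentwise
            for c in range(3):
                A[c, j + c] += k_to_water[i]          # solute -> water
                A[j + c, c] += fracs[i] * k_to_water[i]  # water -> solute
    return A, b


def _steady_state(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e14:
        raise SimulationError(
            f"Bloch-McConnell matrix is ill-conditioned (cond ~ {cond:.2e}); "
            "check exchange rates and relaxation times"
        )
    return np.linalg.solve(A, -b)


@dataclass
class _CyclePropagator:
    """Cached affine propagators for one repetition at a fixed offset."""

    P_rec: np.ndarray | None
    M_rec: np.ndarray | None
    P_sat: np.ndarray
    M_sat: np.ndarray

    def run(self) -> float:
        """Water Mz at readout, iterating the cycle to periodic steady state."""
        n = self.P_sat.shape[0]
        prev = None
        sig = 0.0
        for _ in range(_MAX_CYCLES):
            M = np.zeros(n)  # post-readout: fully spoiled
            if self.P_rec is not None:
                M = self.M_rec + self.P_rec @ (M - self.M_rec)
            M = self.M_sat + self.P_sat @ (M - self.M_sat)
            # magnitude detection: on-resonance nutation can leave a small
            # negative Mz transient, which a magnitude image cannot carry
            sig = abs(float(M[2]))
            if prev is not None and abs(sig - prev) < _CYCLE_TOL:
                break
            prev = sig
        return sig


def _make_propagator(
    system: PoolSystem,
    scheme: SaturationScheme,
    offset_hz: float,
    rec: tuple[np.ndarray, np.ndarray] | None,
) -> _CyclePropagator:
    A, b = bloch_mcconnell_matrix(system, offset_hz, scheme.omega1, scheme.larmor_hz_per_ppm)
    M_sat = _steady_state(A, b)
    P_sat = expm(A * scheme.t_sat)
    if not (np.all(np.isfinite(P_sat)) and np.all(np.isfinite(M_sat))):
        raise SimulationError("non-finite propagator; system too stiff")
    P_rec = M_rec = None
    if rec is not None:
        P_rec, M_rec = rec
    return _CyclePropagator(P_rec, M_rec, P_sat, M_sat)


def _recovery_propagator(
    system: PoolSystem, scheme: SaturationScheme
) -> tuple[np.ndarray, np.ndarray] | None:
    t_rec = scheme.TR - scheme.t_sat
    if t_rec <= 0:
        return None
    A, b = bloch_mcconnell_matrix(system, 0.0, 0.0, scheme.larmor_hz_per_ppm)
    return expm(A * t_rec), _steady_state(A, b)


def simulate_zspectrum(system: PoolSystem, scheme: SaturationScheme) -> ZSpectrum:
    """Forward-simulate the Z-spectrum of ``system`` under ``scheme``.

    Returns Ssat/S0 per offset, with S0 generated by the identical
    saturation-readout cycle at the reference offset.
    """
    rec = _recovery_propagator(system, scheme)
    s0 = _make_propagator(system, scheme, scheme.ref_offset_hz, rec).run()
    if s0 <= 0:
        raise SimulationError("non-positive reference signal")
    offsets = np.sort(scheme.offsets_array())
    z = np.empty(offsets.size)
    for i, off in enumerate(offsets):
        z[i] = _make_propagator(system, scheme, off, rec).run() / s0
    if not np.all(np.isfinite(z)):
        raise SimulationError("non-finite Z-spectrum values")
    return ZSpectrum(offsets, z, scheme.larmor_hz_per_ppm)


def steady_state_zspectrum(system: PoolSystem, scheme: SaturationScheme) -> ZSpectrum:
    """Algebraic CW steady state (t_sat -> infinity limit of the cycle).

    Solves the linear fixed point A M = -b directly at every offset; used as
    the closed-form long-saturation limit of :func:`simulate_zspectrum`.
    """
    larmor = scheme.larmor_hz_per_ppm
    A, b = bloch_mcconnell_matrix(system, scheme.ref_offset_hz, scheme.omega1, larmor)
    s0 = abs(float(_steady_state(A, b)[2]))
    offsets = np.sort(scheme.offsets_array())
    z = np.empty(offsets.size)
    for i, off in enumerate(offsets):
        A, b = bloch_mcconnell_matrix(system, off, scheme.omega1, larmor)
        z[i] = abs(float(_steady_state(A, b)[2])) / s0
    return ZSpectrum(offsets, z, larmor)


# ------------------------------------------------------------------ sweep --


@dataclass
class SweepResult:
    """Aligned results of a one-parameter sweep."""

    parameter: str
    values: tuple[float, ...]
    spectra: tuple[ZSpectrum, ...]
    mtr_asym: tuple[float, ...]
    delta_ppm: float

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "mtr_asym": self.mtr_asym})


def sweep(
    system: PoolSystem,
    scheme: SaturationScheme,
    parameter: str,
    values,
    delta_ppm: float = 0.9,
    solute: str = "glucose",
    ph_ref: float | None = None,
) -> SweepResult:
    """Simulate a series varying one parameter, all others held fixed.

    ``parameter`` is one of ``concentration`` (mM of ``solute``, converted
    through its per-molecule proton count), ``ph`` (rescales the solute
    exchange rate with the base-catalysed model from ``ph_ref``), ``B1_uT``,
    ``t_sat`` (the recovery interval TR - t_sat is held fixed, so TR moves
    with t_sat) or ``TR``.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; use one of {SWEEPABLE}")
    d = load_defaults()
    spectra, asyms = [], []
    for v in values:
        sys_v, sch_v = system, scheme
        if parameter == "concentration":
            pool = system.solute(solute)
            per_mol = (
                d["glucose"]["protons_per_molecule"]
                if solute == "glucose"
                else d["metabolites"][solute]["protons_per_molecule"]
            )
            sys_v = system.replace_solute(
                solute, replace(pool, proton_conc=float(v) * per_mol)
            )
        elif parameter == "ph":
            # the template system is assumed to be parameterized at ph_ref
            pool = system.solute(solute)
            ref = ph_ref if ph_ref is not None else d["glucose"]["ph_ref"]
            sys_v = system.replace_solute(
                solute,
                replace(pool, k_exch=exchange_rate_at_ph(pool.k_exch, float(v), ref)),
            )
        elif parameter == "B1_uT":
            sch_v = replace(scheme, B1_uT=float(v))
        elif parameter == "t_sat":
            t_rec = scheme.TR - scheme.t_sat
            sch_v = replace(scheme, t_sat=float(v), TR=float(v) + t_rec)
        elif parameter == "TR":
            sch_v = replace(scheme, TR=float(v))
        spec = simulate_zspectrum(sys_v, sch_v)
        spectra.append(spec)
        asyms.append(mtr_asym_at(spec, delta_ppm))
    return SweepResult(
        parameter,
        tuple(float(v) for v in values),
        tuple(spectra),
        tuple(asyms),
        delta_ppm,
    )


# ---------------------------------------------------------------- phantom --


@dataclass
class PhantomImage:
    """Rendered multi-tube phantom: per-offset image stack plus tube masks."""

    stack: np.ndarray            # (ny, nx, n_offsets), z values
    s0_image: np.ndarray         # (ny, nx), all ones (stack already normalized)
    offsets_hz: np.ndarray
    tube_masks: tuple[np.ndarray, ...]
    spectra: tuple[ZSpectrum, ...]
    larmor_hz_per_ppm: float


def phantom_image(
    systems,
    layout,
    scheme: SaturationScheme,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    grid: tuple[int, int] = (64, 64),
    background: PoolSystem | None = None,
) -> PhantomImage:
    """Render circular tubes carrying simulated Z-spectra on a water background.

    ``layout`` is a sequence of (cx, cy, radius) in pixel units aligned with
    ``systems``.  Additive Gaussian noise of sd ``noise_sigma`` (z units) is
    applied per voxel per offset.
    """
    systems = tuple(systems)
    layout = tuple(layout)
    if len(systems) != len(layout):
        raise ValueError("systems and layout must have equal length")
    ny, nx = grid
    for cx, cy, r in layout:
        if r <= 0:
            raise ValueError("tube radius must be positive")
        if cx - r < 0 or cx + r > nx or cy - r < 0 or cy + r > ny:
            raise ValueError(f"tube at ({cx}, {cy}) r={r} exceeds the {grid} grid")
    for i in range(len(layout)):
        for j in range(i + 1, len(layout)):
            xi, yi, ri = layout[i]
            xj, yj, rj = layout[j]
            if np.hypot(xi - xj, yi - yj) < ri + rj:
                raise ValueError(f"tubes {i} and {j} overlap")

    if background is None:
        ref_water = systems[0].water if systems else None
        from .pools import water_pool

        background = PoolSystem(water=ref_water or water_pool("phantom"))
    bg_spec = simulate_zspectrum(background, scheme)
    offsets = bg_spec.offsets_hz
    stack = np.broadcast_to(bg_spec.z, (ny, nx, offsets.size)).copy()

    yy, xx = np.mgrid[0:ny, 0:nx]
    masks, spectra = [], []
    for (cx, cy, r), system in zip(layout, systems):
        mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r**2
        spec = simulate_zspectrum(system, scheme)
        stack[mask] = spec.z
        masks.append(mask)
        spectra.append(spec)

    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sigma > 0")
        stack = stack + rng.normal(0.0, noise_sigma, size=stack.shape)
    return PhantomImage(
        stack,
        np.ones((ny, nx)),
        offsets,
        tuple(masks),
        tuple(spectra),
        scheme.larmor_hz_per_ppm,
    )
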