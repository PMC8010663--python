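"""Shared independent oracles and constructors for the test suite."""
from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.integrate import solve_ivp

from glucocest.bloch import bloch_mcconnell_matrix
from glucocest.zspec import ZSpectrum


def ode_saturation_signal(
    system, scheme, offset_hz, rtol=1e-9, atol=1e-12
) -> float:
    """Water |Mz| at readout via stiff (Radau) integration instead of expm.

    Independently integrates the same spoiled -> recovery -> CW-saturation
    cycle; serves as the evolution oracle for the matrix-exponential
    propagator.  The far off-resonance reference leg is excluded (its fast
    precession makes time stepping intractable), so callers compare signal
    *ratios*, in which the common reference cancels.
    """
    n_states = 3 * (1 + len(system.solutes))
    larmor = scheme.larmor_hz_per_ppm

    def run(A, b, M0, t_end):
        sol = solve_ivp(
            lambda _t, m: A @ m + b,
            (0.0, t_end),
            M0,
            method="Radau",
            rtol=rtol,
            atol=atol,
            jac=lambda _t, _m: A,
        )
        return sol.y[:, -1]

    M = np.zeros(n_states)
    t_rec = scheme.TR - scheme.t_sat
    if t_rec > 0:
        A_rec, b_rec = bloch_mcconnell_matrix(system, 0.0, 0.0, larmor)
        M = run(A_rec, b_rec, M, t_rec)
    A, b = bloch_mcconnell_matrix(system, offset_hz, scheme.omega1, larmor)
    M = run(A, b, M, scheme.t_sat)
    return abs(float(M[2]))  # magnitude detection, matching the implementation


def shifted_measurement(system, scheme, shift_hz) -> ZSpectrum:
    """Forward-inject a B0 shift: acquire with the RF grid displaced.

    A water resonance sitting at ``shift_hz`` is physically equivalent to
    saturating at ``offset - shift`` while labeling the sample grid
    nominally; the returned spectrum carries the nominal offsets.
    """
    from glucocest.bloch import simulate_zspectrum

    sch = replace(scheme, offsets_hz=tuple(o - shift_hz for o in scheme.offsets_hz))
    spec = simulate_zspectrum(system, sch)
    return ZSpectrum(
        np.sort(np.asarray(scheme.offsets_hz, dtype=float)),
        spec.z,
        scheme.larmor_hz_per_ppm,
    )


def linear_mtr_stack(value, offsets_hz, grid, larmor, level=0.8):
    """Stack with exact voxelwise MTRasym(0.9 ppm) == ``value``.

    z is linear in offset; cubic splines reproduce linear data exactly, so
    z(-d) - z(+d) carries no interpolation error.
    """
    off = np.asarray(offsets_hz, dtype=float)
    d_hz = 0.9 * larmor
    z = level - (value / (2.0 * d_hz)) * off
    ny, nx = grid
    return np.broadcast_to(z, (ny, nx, off.size)).copy()
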