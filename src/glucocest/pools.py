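"""Spin pools, pool systems and saturation schemes.

These types parameterize the Bloch-McConnell forward model: each exchanging
proton species is a :class:`Pool` with a chemical shift relative to water, an
exchangeable-proton concentration, an exchange rate to water and its own
relaxation times.  A :class:`PoolSystem` couples one water pool to any number
of dilute solute pools; a :class:`SaturationScheme` describes the
continuous-wave presaturation block of the acquisition (amplitude, duration,
repetition time, offset grid and unsaturated reference offset).

Default physical parameters (relaxation times, exchange rates, proton
multiplicities) live in ``data/defaults.yaml`` and are the single frozen
parameter set used throughout the package.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "Pool",
    "PoolSystem",
    "SaturationScheme",
    "exchange_rate_at_ph",
    "load_defaults",
    "larmor_hz_per_ppm",
    "glucose_pool",
    "metabolite_pool",
    "water_pool",
    "glucose_phantom_system",
    "glucose_invivo_system",
    "metabolite_phantom_system",
    "phantom_scheme",
    "invivo_scheme",
]


@lru_cache(maxsize=1)
def load_defaults() -> dict:
    """Return the frozen default parameter table (parsed defaults.yaml)."""
    text = resources.files("glucocest").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def larmor_hz_per_ppm() -> float:
    """Hz-per-ppm conversion at the default field strength (7 T -> ~298 Hz/ppm)."""
    d = load_defaults()
    return d["field_T"] * d["gamma_hz_per_uT"]


def exchange_rate_at_ph(k_ref: float, ph: float, ph_ref: float) -> float:
    """Base-catalysed exchange rate at ``ph`` given the rate at ``ph_ref``.

    Hydroxyl-proton exchange is dominated by OH- catalysis in the
    physiological range, so the rate scales with the hydroxide concentration:
    ``k = k_ref * 10**(ph - ph_ref)``.

    Parameters
    ----------
    k_ref : reference exchange rate (1/s), must be positive and finite.
    ph, ph_ref : pH of interest and pH at which ``k_ref`` was specified.
    """
    for name, v in (("k_ref", k_ref), ("ph", ph), ("ph_ref", ph_ref)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if k_ref <= 0:
        raise ValueError(f"k_ref must be positive, got {k_ref!r}")
    return k_ref * 10.0 ** (ph - ph_ref)


@dataclass(frozen=True)
class Pool:
    """One exchanging proton species.

    Parameters
    ----------
    name : label ("water", "glucose", ...).
    delta_ppm : chemical shift relative to water (ppm).
    proton_conc : exchangeable-proton concentration (mM).
    k_exch : exchange rate of this pool's protons to water (1/s); 0 for water.
    T1, T2 : longitudinal / transverse relaxation times (s).
    """

    name: str
    delta_ppm: float
    proton_conc: float
    k_exch: float
    T1: float
    T2: float

    def __post_init__(self) -> None:
        if self.proton_conc < 0:
            raise ValueError(f"proton_conc must be >= 0, got {self.proton_conc}")
        if self.k_exch < 0:
            raise ValueError(f"k_exch must be >= 0, got {self.k_exch}")
        if not self.T1 > 0 or not self.T2 > 0:
            raise ValueError("T1 and T2 must be positive")
        if self.T2 > self.T1:
            raise ValueError(f"T2 ({self.T2}) must not exceed T1 ({self.T1})")


@dataclass(frozen=True)
class PoolSystem:
    """Water pool plus dilute solute pools.

    ``water_proton_conc`` is the proton concentration of pure water (mM) used
    to convert solute proton concentrations into equilibrium magnetization
    fractions f_s = proton_conc / water_proton_conc.
    """

    water: Pool
    solutes: tuple[Pool, ...] = ()
    water_proton_conc: float = 111000.0
    temperature_label: str = "room temperature"

    def __post_init__(self) -> None:
        object.__setattr__(self, "solutes", tuple(self.solutes))
        if self.water.delta_ppm != 0.0:
            raise ValueError("water pool must sit at delta_ppm = 0")
        if any(p.name == "water" for p in self.solutes):
            raise ValueError("exactly one water pool allowed")
        if self.water_proton_conc <= 0:
            raise ValueError("water_proton_conc must be positive")
        for p in self.solutes:
            if self.fraction(p) >= 0.2:
                raise ValueError(
                    f"solute pool {p.name!r} is not dilute "
                    f"(fraction {self.fraction(p):.3f} >= 0.2)"
                )

    def fraction(self, pool: Pool) -> float:
        """Equilibrium magnetization fraction of a solute pool."""
        return pool.proton_conc / self.water_proton_conc

    def solute(self, name: str) -> Pool:
        for p in self.solutes:
            if p.name == name:
                return p
        raise KeyError(f"no solute pool named {name!r}")

    def replace_solute(self, name: str, new_pool: Pool) -> "PoolSystem":
        found = False
        solutes = []
        for p in self.solutes:
            if p.name == name:
                solutes.append(new_pool)
                found = True
            else:
                solutes.append(p)
        if not found:
            raise KeyError(f"no solute pool named {name!r}")
        return replace(self, solutes=tuple(solutes))


@dataclass(frozen=True)
class SaturationScheme:
    """Continuous-wave presaturation block of one repetition.

    ``ref_offset_hz`` is the far off-resonance offset at which the reference
    (S0) image is acquired with the same timing; it must lie well outside the
    sampled offset range so the water pool is essentially unsaturated.
    """

    B1_uT: float
    t_sat: float
    TR: float
    offsets_hz: tuple[float, ...]
    ref_offset_hz: float = 10000.0
    larmor_hz_per_ppm: float = field(default_factory=larmor_hz_per_ppm)

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets_hz", tuple(float(o) for o in self.offsets_hz))
        if self.B1_uT <= 0:
            raise ValueError("B1_uT must be positive")
        if not 0 < self.t_sat <= self.TR:
            raise ValueError(f"need 0 < t_sat <= TR, got t_sat={self.t_sat}, TR={self.TR}")
        if len(self.offsets_hz) == 0:
            raise ValueError("offsets_hz must be non-empty")
        max_off = max(abs(o) for o in self.offsets_hz)
        if abs(self.ref_offset_hz) < 5 * max_off:
            raise ValueError(
                "ref_offset_hz must be far outside the offset range "
                f"(|ref| >= 5 x {max_off:g} Hz)"
            )

    @property
    def omega1(self) -> float:
        """Saturation amplitude in rad/s: 2*pi*gamma*B1."""
        return 2.0 * math.pi * load_defaults()["gamma_hz_per_uT"] * self.B1_uT

    def offsets_array(self) -> np.ndarray:
        return np.asarray(self.offsets_hz, dtype=float)


# ---------------------------------------------------------------- presets --


def water_pool(kind: str = "phantom") -> Pool:
    """Default water pool ('phantom' = PBS/agarose, 'invivo' = brain)."""
    w = load_defaults()["water"][kind]
    return Pool("water", 0.0, 0.0, 0.0, w["T1_s"], w["T2_s"])


def glucose_pool(conc_mM: float, ph: float = 7.4) -> Pool:
    """Effective single hydroxyl pool for D-glucose at ``conc_mM`` and ``ph``."""
    g = load_defaults()["glucose"]
    k = exchange_rate_at_ph(g["k_exch_ref_s"], ph, g["ph_ref"])
    return Pool(
        "glucose",
        g["delta_ppm"],
        conc_mM * g["protons_per_molecule"],
        k,
        g["T1_s"],
        g["T2_s"],
    )


def metabolite_pool(name: str, conc_mM: float) -> Pool:
    """Preset metabolite pool (creatine, glutamate, gaba, choline)."""
    if name == "glucose":
        return glucose_pool(conc_mM)
    table = load_defaults()["metabolites"]
    if name not in table:
        raise KeyError(f"no preset for metabolite {name!r}")
    m = table[name]
    return Pool(
        name,
        m["delta_ppm"],
        conc_mM * m["protons_per_molecule"],
        m["k_exch_s"],
        m["T1_s"],
        m["T2_s"],
    )


def glucose_phantom_system(conc_mM: float, ph: float = 7.4) -> PoolSystem:
    """PBS/agarose glucose tube system used by the phantom experiments."""
    return PoolSystem(
        water=water_pool("phantom"),
        solutes=(glucose_pool(conc_mM, ph),),
        water_proton_conc=load_defaults()["water_proton_conc_mM"],
    )


def glucose_invivo_system(conc_mM: float, ph: float = 7.4) -> PoolSystem:
    """Brain-tissue water plus a glucose pool (used by the cohort generator)."""
    return PoolSystem(
        water=water_pool("invivo"),
        solutes=(glucose_pool(conc_mM, ph),),
        water_proton_conc=load_defaults()["water_proton_conc_mM"],
        temperature_label="in vivo, 37 C",
    )


def metabolite_phantom_system(name: str, conc_mM: float) -> PoolSystem:
    return PoolSystem(
        water=water_pool("phantom"),
        solutes=(metabolite_pool(name, conc_mM),),
        water_proton_conc=load_defaults()["water_proton_conc_mM"],
    )


def _offset_grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(start + i * step for i in range(n))


def phantom_scheme(
    B1_uT: float = 1.5, t_sat: float = 5.0, TR: float = 5.04
) -> SaturationScheme:
    """Phantom acquisition: offsets -1500..+1500 Hz step 30, reference 10 kHz."""
    return SaturationScheme(B1_uT, t_sat, TR, _offset_grid(-1500, 1500, 30))


def invivo_scheme(
    B1_uT: float = 1.5, t_sat: float = 5.0, TR: float = 6.0
) -> SaturationScheme:
    """In vivo acquisition: offsets -900..+900 Hz step 30, reference 10 kHz."""
    return SaturationScheme(B1_uT, t_sat, TR, _offset_grid(-900, 900, 30))
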