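"""Readers, writers and configuration for the on-disk interchange layout.

Images travel as uncompressed NIfTI (offset / direction dimension on the 4th
axis) with JSON sidecar manifests naming offsets, timepoints and provenance;
tables are CSV; simulator and cohort configuration is YAML.  Every artifact
written carries the metadata (seed, config hash, package version) needed to
re-derive it.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dti import DiffusionSet
from .gce import CestSeries
from .pools import (
    Pool,
    PoolSystem,
    SaturationScheme,
    glucose_invivo_system,
    glucose_phantom_system,
    metabolite_phantom_system,
    larmor_hz_per_ppm,
    water_pool,
)
from .zspec import B0Map, ZSpectrum

__all__ = [
    "ManifestError",
    "write_series",
    "read_series",
    "write_cohort",
    "read_cohort",
    "write_diffusion",
    "read_diffusion",
    "write_zspectrum_csv",
    "read_zspectrum_csv",
    "load_config",
    "system_from_config",
    "scheme_from_config",
    "cohort_spec_from_config",
    "config_hash",
]

FORMAT_VERSION = 1


class ManifestError(ValueError):
    """A sidecar manifest is missing, inconsistent or names absent files."""


def _nifti_write(path: Path, data: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))
    nib.save(img, str(path))


def _nifti_read(path: Path) -> np.ndarray:
    if not path.exists():
        raise ManifestError(f"referenced image file does not exist: {path}")
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(seed=None, config=None) -> dict:
    p = {"package_version": __version__, "format_version": FORMAT_VERSION}
    if seed is not None:
        p["seed"] = int(seed)
    if config is not None:
        p["config_hash"] = config_hash(config)
    return p


# ----------------------------------------------------------- CEST series --


def write_series(series: CestSeries, out_dir, seed=None, config=None) -> Path:
    """Write one animal's dynamic CEST series plus sidecar manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ny, nx = series.grid
    files: dict = {"stacks": {}, "s0": {}}
    for label in series.labels:
        fn = f"cest_{label}.nii"
        _nifti_write(out / fn, series.stacks[label].reshape(ny, nx, 1, -1))
        files["stacks"][label] = fn
        fn0 = f"s0_{label}.nii"
        _nifti_write(out / fn0, series.s0_images[label])
        files["s0"][label] = fn0
    roi_names = sorted(series.rois)
    _nifti_write(
        out / "rois.nii",
        np.stack([series.rois[n] for n in roi_names], axis=-1).reshape(
            ny, nx, 1, len(roi_names)
        ),
    )
    files["rois"] = "rois.nii"
    if series.b0 is not None:
        _nifti_write(out / "b0.nii", series.b0.shift_hz)
        _nifti_write(out / "b0_valid.nii", series.b0.valid_mask.astype(float))
        files["b0"] = "b0.nii"
        files["b0_valid"] = "b0_valid.nii"
    manifest = {
        "offsets_hz": [float(o) for o in series.offsets_hz],
        "timepoints": [[t, m] for t, m in series.timepoints],
        "larmor_hz_per_ppm": series.larmor_hz_per_ppm,
        "roi_names": roi_names,
        "files": files,
        "provenance": _provenance(seed, config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_series(animal_dir) -> CestSeries:
    """Load a CEST series written by :func:`write_series`.

    Raises :class:`ManifestError` naming the offending field when the
    sidecar is inconsistent with the image files.
    """
    d = Path(animal_dir)
    mpath = d / "manifest.json"
    if not mpath.exists():
        raise ManifestError(f"missing manifest.json in {d}")
    m = json.loads(mpath.read_text())
    for key in ("offsets_hz", "timepoints", "larmor_hz_per_ppm", "files"):
        if key not in m:
            raise ManifestError(f"manifest field {key!r} is missing")
    offsets = np.asarray(m["offsets_hz"], dtype=float)
    stacks, s0s = {}, {}
    for label, _minutes in m["timepoints"]:
        stack = _nifti_read(d / m["files"]["stacks"][label])
        stack = stack.reshape(stack.shape[0], stack.shape[1], -1)
        if stack.shape[-1] != offsets.size:
            raise ManifestError(
                f"offsets_hz length {offsets.size} does not match stack depth "
                f"{stack.shape[-1]} for timepoint {label!r}"
            )
        stacks[label] = stack
        s0s[label] = _nifti_read(d / m["files"]["s0"][label])
    rois = {}
    if "rois" in m["files"]:
        roi_img = _nifti_read(d / m["files"]["rois"])
        roi_img = roi_img.reshape(roi_img.shape[0], roi_img.shape[1], -1)
        names = m.get("roi_names", [])
        if roi_img.shape[-1] != len(names):
            raise ManifestError("roi_names does not match rois.nii channels")
        rois = {n: roi_img[..., i] > 0.5 for i, n in enumerate(names)}
    b0 = None
    if "b0" in m["files"]:
        b0 = B0Map(
            _nifti_read(d / m["files"]["b0"]),
            _nifti_read(d / m["files"]["b0_valid"]) > 0.5
            if "b0_valid" in m["files"]
            else None,
        )
    return CestSeries(
        stacks=stacks,
        s0_images=s0s,
        offsets_hz=offsets,
        rois=rois,
        b0=b0,
        timepoints=tuple((t, float(mn)) for t, mn in m["timepoints"]),
        larmor_hz_per_ppm=float(m["larmor_hz_per_ppm"]),
    )


# ------------------------------------------------------------------- DWI --


def write_diffusion(ds: DiffusionSet, out_dir, prefix: str = "dwi") -> Path:
    """FSL-dialect DWI layout: 4-D NIfTI (S0 first) + bvec/bval text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ny, nx = ds.s0_image.shape
    vol = np.concatenate([ds.s0_image[..., None], ds.dwi_images], axis=-1)
    _nifti_write(out / f"{prefix}.nii", vol.reshape(ny, nx, 1, 7))
    bvec = np.column_stack([np.zeros(3), ds.bvecs.T])  # 3 rows x 7 cols
    np.savetxt(out / f"{prefix}.bvec", bvec, fmt="%.8f")
    np.savetxt(out / f"{prefix}.bval", np.r_[0.0, np.full(6, ds.bval)][None, :], fmt="%.1f")
    return out


def read_diffusion(dwi_path, bvec_path, bval_path) -> DiffusionSet:
    vol = _nifti_read(Path(dwi_path))
    vol = vol.reshape(vol.shape[0], vol.shape[1], -1)
    if vol.shape[-1] != 7:
        raise ManifestError(f"expected 7 volumes (S0 + 6 directions), got {vol.shape[-1]}")
    bvec = np.loadtxt(bvec_path)
    bval = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    if bvec.shape != (3, 7) or bval.size != 7:
        raise ManifestError("bvec must be 3x7 and bval length 7 (FSL dialect)")
    return DiffusionSet(vol[..., 0], vol[..., 1:], bvec[:, 1:].T, float(bval[1]))


# ---------------------------------------------------------------- cohort --


def write_cohort(cohort, out_dir, force: bool = False) -> Path:
    """Write a generated cohort: per-animal directories + truth manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.manifest["spec"]
    rows = []
    for a in cohort.animals:
        adir = out / a.animal_id
        write_series(a.series, adir, seed=cohort.spec.seed, config=cfg)
        if a.dwi is not None:
            write_diffusion(a.dwi, adir)
        rows.append({"animal": a.animal_id, "group": a.group, "mi": a.mi})
    pd.DataFrame(rows).to_csv(out / "metabolites.csv", index=False)
    (out / "cohort_manifest.json").write_text(json.dumps(cohort.manifest, indent=1))
    return out


def read_cohort(cohort_dir):
    """Load a written cohort: (records, metabolite table, manifest).

    ``records`` is a list of ``(animal_id, group, CestSeries)`` in manifest
    order, directly consumable by :func:`glucocest.gce.cohort_table`.
    """
    d = Path(cohort_dir)
    mpath = d / "cohort_manifest.json"
    if not mpath.exists():
        raise ManifestError(f"missing cohort_manifest.json in {d}")
    manifest = json.loads(mpath.read_text())
    table = pd.read_csv(d / "metabolites.csv")
    records = []
    for truth in manifest["animals"]:
        aid, group = truth["animal_id"], truth["group"]
        records.append((aid, group, read_series(d / aid)))
    return records, table, manifest


# ---------------------------------------------------------------- tables --


def write_zspectrum_csv(spec: ZSpectrum, path) -> None:
    pd.DataFrame({"offset_hz": spec.offsets_hz, "z": spec.z}).to_csv(path, index=False)


def read_zspectrum_csv(path, larmor: float | None = None) -> ZSpectrum:
    df = pd.read_csv(path)
    for col in ("offset_hz", "z"):
        if col not in df.columns:
            raise ManifestError(f"Z-spectrum CSV is missing column {col!r}")
    return ZSpectrum(
        df["offset_hz"].to_numpy(),
        df["z"].to_numpy(),
        larmor if larmor is not None else larmor_hz_per_ppm(),
    )


# ---------------------------------------------------------------- config --


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ManifestError("config file must contain a YAML mapping")
    return cfg


def system_from_config(cfg: dict) -> PoolSystem:
    """Build a PoolSystem from the ``system`` section of a config mapping.

    Either a preset (``glucose_phantom`` / ``glucose_invivo`` /
    ``metabolite``) with its parameters, or an explicit water + pools list.
    """
    sec = cfg.get("system")
    if sec is None:
        raise ManifestError("config is missing the 'system' section")
    preset = sec.get("preset")
    if preset == "glucose_phantom":
        return glucose_phantom_system(sec.get("concentration_mM", 25.0), sec.get("ph", 7.4))
    if preset == "glucose_invivo":
        return glucose_invivo_system(sec.get("concentration_mM", 25.0), sec.get("ph", 7.4))
    if preset == "metabolite":
        return metabolite_phantom_system(sec["metabolite"], sec.get("concentration_mM", 10.0))
    if preset is not None:
        raise ManifestError(f"unknown system preset {preset!r}")
    w = sec.get("water", {})
    water = (
        Pool("water", 0.0, 0.0, 0.0, w["T1_s"], w["T2_s"])
        if w
        else water_pool(sec.get("water_kind", "phantom"))
    )
    pools = tuple(
        Pool(
            p["name"],
            p["delta_ppm"],
            p["proton_conc_mM"],
            p["k_exch_s"],
            p["T1_s"],
            p["T2_s"],
        )
        for p in sec.get("pools", [])
    )
    return PoolSystem(water=water, solutes=pools)


def scheme_from_config(cfg: dict) -> SaturationScheme:
    sec = cfg.get("scheme")
    if sec is None:
        raise ManifestError("config is missing the 'scheme' section")
    off = sec.get("offsets_hz")
    if isinstance(off, dict):
        start, stop, step = off["start"], off["stop"], off["step"]
        n = int(round((stop - start) / step)) + 1
        offsets = tuple(start + i * step for i in range(n))
    elif isinstance(off, (list, tuple)):
        offsets = tuple(float(o) for o in off)
    else:
        raise ManifestError("scheme.offsets_hz must be a list or {start, stop, step}")
    kwargs = {}
    if "ref_offset_hz" in sec:
        kwargs["ref_offset_hz"] = sec["ref_offset_hz"]
    if "larmor_hz_per_ppm" in sec:
        kwargs["larmor_hz_per_ppm"] = sec["larmor_hz_per_ppm"]
    return SaturationScheme(sec["B1_uT"], sec["t_sat"], sec["TR"], offsets, **kwargs)


def cohort_spec_from_config(cfg: dict, seed: int | None = None):
    """CohortSpec from the ``cohort`` config section (defaults elsewhere)."""
    from .synth import CohortSpec

    sec = dict(cfg.get("cohort", {}))
    if "grid" in sec:
        sec["grid"] = tuple(sec["grid"])
    if "b0_field" in sec:
        sec["b0_field"] = tuple(sec["b0_field"])
    if "baseline_mtr" in sec:
        sec["baseline_mtr"] = tuple((g, float(v)) for g, v in dict(sec["baseline_mtr"]).items())
    if "uptake_curve" in sec:
        sec["uptake_curve"] = tuple(
            (g, tuple(float(x) for x in c)) for g, c in dict(sec["uptake_curve"]).items()
        )
    if "scheme" in cfg:
        sec["scheme"] = scheme_from_config(cfg)
    if seed is not None:
        sec["seed"] = seed
    return CohortSpec(**sec)
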