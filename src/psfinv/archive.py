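"""HDF5 model archive: save/load every PSF parameterization losslessly.

Layout: one group per model kind (``zernike``, ``pupil_image``, ``voxel``,
``iab4pi``, ``field_dependent``) with named float64 datasets, plus an
``optics`` group of the optical configuration and root attributes for the
format version and the random seed. Loading reproduces bit-identical arrays.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .forward import FieldDependentModel, IAB4PiModel, VoxelPSF
from .pupil import ComplexPupil, OpticalConfig

__all__ = ["save_model", "load_model", "ARCHIVE_VERSION"]

ARCHIVE_VERSION = 1


def _write_optics(f, cfg: OpticalConfig):
    g = f.create_group("optics")
    for fld in dataclasses.fields(cfg):
        g.attrs[fld.name] = getattr(cfg, fld.name)


def _read_optics(f) -> OpticalConfig | None:
    if "optics" not in f:
        return None
    a = f["optics"].attrs
    return OpticalConfig(**{k: (int(v) if k in ("roi_size", "oversample")
                                else float(v))
                            for k, v in a.items()})


def save_model(model, path, config: OpticalConfig | None = None,
               seed: int | None = None, extra: dict | None = None):
    """Write a PSF model to an HDF5 archive."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = ARCHIVE_VERSION
        f.attrs["software"] = "psfinv"
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if config is not None:
            _write_optics(f, config)
        if isinstance(model, ComplexPupil):
            kind = "zernike" if model.coeff_phase is not None else "pupil_image"
            g = f.create_group(kind)
            g.create_dataset("magnitude", data=model.magnitude)
            g.create_dataset("phase", data=model.phase)
            if model.coeff_phase is not None:
                g.create_dataset("coeff_phase", data=model.coeff_phase)
            if model.coeff_magnitude is not None:
                g.create_dataset("coeff_magnitude", data=model.coeff_magnitude)
            if model.aperture is not None:
                g.create_dataset("aperture",
                                 data=model.aperture.astype(np.uint8))
            g.attrs["magnitude_mode"] = model.magnitude_mode
        elif isinstance(model, VoxelPSF):
            g = f.create_group("voxel")
            g.create_dataset("values", data=model.values)
            g.attrs["z_step"] = model.z_step
            g.attrs["pixel_size"] = model.pixel_size
            g.attrs["oversample"] = model.oversample
        elif isinstance(model, IAB4PiModel):
            g = f.create_group("iab4pi")
            for name in ("I", "A", "B"):
                g.create_dataset(name, data=getattr(model, name))
            g.attrs["k"] = model.k
            g.attrs["phi0"] = model.phi0
            g.attrs["z_step"] = model.z_step
            if model.channel_phases is not None:
                g.create_dataset("channel_phases", data=model.channel_phases)
        elif isinstance(model, FieldDependentModel):
            g = f.create_group("field_dependent")
            g.create_dataset("maps", data=model.maps)
            g.attrs["map_pitch"] = model.map_pitch
            g.create_dataset("modes", data=np.asarray(model.modes, int))
        else:
            raise TypeError(f"cannot archive model of type {type(model)!r}")
        if extra:
            ge = f.create_group("extra")
            for k, v in extra.items():
                ge.create_dataset(k, data=np.asarray(v))


def load_model(path):
    """Read a model archive; returns (model, OpticalConfig or None)."""
    with h5py.File(path, "r") as f:
        ver = int(f.attrs.get("format_version", -1))
        if ver != ARCHIVE_VERSION:
            raise ValueError(
                f"archive format version {ver} != supported {ARCHIVE_VERSION}")
        cfg = _read_optics(f)
        for kind in ("zernike", "pupil_image"):
            if kind in f:
                g = f[kind]
                for req in ("magnitude", "phase"):
                    if req not in g:
                        raise KeyError(f"archive missing dataset {kind}/{req}")
                ap = (np.asarray(g["aperture"]).astype(bool)
                      if "aperture" in g else None)
                return ComplexPupil(
                    magnitude=np.asarray(g["magnitude"]),
                    phase=np.asarray(g["phase"]),
                    coeff_phase=(np.asarray(g["coeff_phase"])
                                 if "coeff_phase" in g else None),
                    coeff_magnitude=(np.asarray(g["coeff_magnitude"])
                                     if "coeff_magnitude" in g else None),
                    magnitude_mode=str(g.attrs.get("magnitude_mode",
                                                   "constant")),
                    aperture=ap), cfg
        if "voxel" in f:
            g = f["voxel"]
            if "values" not in g:
                raise KeyError("archive missing dataset voxel/values")
            return VoxelPSF(values=np.asarray(g["values"]),
                            z_step=float(g.attrs["z_step"]),
                            pixel_size=float(g.attrs["pixel_size"]),
                            oversample=int(g.attrs["oversample"])), cfg
        if "iab4pi" in f:
            g = f["iab4pi"]
            return IAB4PiModel(
                I=np.asarray(g["I"]), A=np.asarray(g["A"]),
                B=np.asarray(g["B"]), k=float(g.attrs["k"]),
                phi0=float(g.attrs["phi0"]), z_step=float(g.attrs["z_step"]),
                channel_phases=(np.asarray(g["channel_phases"])
                                if "channel_phases" in g else None)), cfg
        if "field_dependent" in f:
            g = f["field_dependent"]
            return FieldDependentModel(
                maps=np.asarray(g["maps"]),
                map_pitch=float(g.attrs["map_pitch"]),
                modes=[tuple(nm) for nm in np.asarray(g["modes"])]), cfg
    raise KeyError("archive contains no recognized model group")
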