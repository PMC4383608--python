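"""File formats: float32 TIFF for images, HDF5 for sinograms, YAML for
configuration and JSON for reports."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .grid import ProjectionGeometry, Sinogram
from .solver import PICCSConfig, SolveReport
from .transforms import TransformChoice

__all__ = [
    "write_image",
    "read_image",
    "write_sinogram",
    "read_sinogram",
    "write_report",
    "config_to_yaml",
    "config_from_yaml",
]


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_sinogram(path: str | Path, sino: Sinogram) -> None:
    with h5py.File(str(path), "w") as f:
        ds = f.create_dataset("values", data=sino.values)
        f.create_dataset("angles", data=np.asarray(sino.geometry.angles))
        ds.attrs["n_detector_bins"] = sino.geometry.n_detector_bins
        ds.attrs["detector_spacing"] = sino.geometry.detector_spacing
        ds.attrs["sigma"] = sino.sigma


def read_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(str(path), "r") as f:
        values = f["values"][()]
        angles = tuple(float(a) for a in f["angles"][()])
        geom = ProjectionGeometry(
            angles,
            int(f["values"].attrs["n_detector_bins"]),
            float(f["values"].attrs["detector_spacing"]),
        )
        return Sinogram(geom, values, float(f["values"].attrs["sigma"]))


def write_report(path: str | Path, report: SolveReport) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def config_to_yaml(path: str | Path, cfg: PICCSConfig) -> None:
    d = asdict(cfg)
    d["t2"] = {"name": cfg.t2.name, "wavelet_levels": cfg.t2.wavelet_levels}
    Path(path).write_text(yaml.safe_dump(d))


def config_from_yaml(path: str | Path) -> PICCSConfig:
    d = yaml.safe_load(Path(path).read_text())
    t2 = d.pop("t2", {})
    return PICCSConfig(t2=TransformChoice(**t2), **d)
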