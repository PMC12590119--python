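"""File formats: PNG/CSV images with sidecar geometry, maps, tables, results.

PNG (8-bit grayscale, linear [-1, 1] -> [0, 255]) is for inspection; CSV
numeric grids are the lossless interchange.  Geometry travels in a sidecar
JSON next to the image ({extent_deg, pixels_per_degree}; {mm_per_pixel} for
orientation maps).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cortical import OrientationMap
from .fitting import FitResult
from .percept import FilterSet, GratingParams, ImageField

__all__ = [
    "write_image_png",
    "read_image_png",
    "write_image_csv",
    "read_image_csv",
    "write_orientation_map",
    "read_orientation_map",
    "write_fit_result",
    "read_fit_result",
    "read_csf_table",
    "write_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_geometry(path: Path, field: ImageField) -> None:
    _sidecar(path).write_text(
        json.dumps(
            {"extent_deg": field.extent_deg, "pixels_per_degree": field.pixels_per_degree},
            sort_keys=True,
        )
    )


def _read_geometry(path: Path) -> dict:
    return json.loads(_sidecar(path).read_text())


def write_image_png(field: ImageField, path: str | Path) -> None:
    path = Path(path)
    scaled = np.clip((field.values + 1.0) * 127.5, 0, 255).astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(path)
    _write_geometry(path, field)


def read_image_png(path: str | Path) -> ImageField:
    path = Path(path)
    meta = _read_geometry(path)
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    values = arr / 127.5 - 1.0
    return ImageField(values, meta["extent_deg"], meta["pixels_per_degree"])


def write_image_csv(field: ImageField, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, field.values, delimiter=",")
    _write_geometry(path, field)


def read_image_csv(path: str | Path) -> ImageField:
    path = Path(path)
    meta = _read_geometry(path)
    values = np.loadtxt(path, delimiter=",")
    return ImageField(values, meta["extent_deg"], meta["pixels_per_degree"])


def write_orientation_map(omap: OrientationMap, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, omap.preferred_orientation, delimiter=",")
    _sidecar(path).write_text(
        json.dumps({"mm_per_pixel": omap.mm_per_pixel, "provenance": omap.provenance},
                   sort_keys=True)
    )


def read_orientation_map(path: str | Path) -> OrientationMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    grid = np.loadtxt(path, delimiter=",")
    return OrientationMap(grid, meta["mm_per_pixel"], meta.get("provenance", "file"))


def write_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), sort_keys=True, indent=1))


def read_fit_result(path: str | Path) -> FitResult:
    data = json.loads(Path(path).read_text())
    filters = [
        GratingParams(
            orientation=f["orientation"],
            spatial_frequency=f["spatial_frequency"],
            phase=f["phase"],
            duty_constant=f["duty_constant"],
            saturation_threshold=f["saturation_threshold"],
            amblyopia_constant=f["amblyopia_constant"],
        )
        for f in data["filters"]
    ]
    weights = np.array([f["weight"] for f in data["filters"]])
    stim = data.get("stimulus")
    stim_params = (
        None
        if stim is None
        else GratingParams(stim["orientation"], stim["spatial_frequency"], stim["phase"])
    )
    return FitResult(
        filter_set=FilterSet(filters, weights),
        final_nlpd=data["final_nlpd"],
        nlpd_trace=data["nlpd_trace"],
        n_filters_used=data["n_filters_used"],
        converged=data["converged"],
        threshold_used=data["threshold_used"],
        stimulus=stim_params,
    )


def read_csf_table(path: str | Path) -> pd.DataFrame:
    """CSF CSV with columns eye, sf_cpd, sensitivity."""
    df = pd.read_csv(path)
    missing = {"eye", "sf_cpd", "sensitivity"} - set(df.columns)
    if missing:
        raise ValueError(f"CSF table missing columns: {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    """Byte-stable JSON (sorted keys) for reports and manifests."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")
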