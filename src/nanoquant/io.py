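"""TIFF + JSON-sidecar readers and writers.

Movies and height maps travel as 32-bit-float TIFF (multi-page for time
series, time as the leading axis) with a ``<name>.json`` sidecar carrying the
physical calibration; decay images are 3-D TIFF with the time axis leading
and the bin width in the sidecar.  Ground-truth manifests are written by the
generators as ``<name>.truth.json`` (see :mod:`nanoquant.manifest`).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import AFMImage, DecayImage, GelImage, MovieStack


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(path: str | Path, movie: MovieStack) -> Path:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {
                "pixel_size_nm": movie.pixel_size_nm,
                "frame_interval_s": movie.frame_interval_s,
                "injection_frame": movie.injection_frame,
            }
        )
    )
    return path


def read_movie(path: str | Path) -> MovieStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return MovieStack(frames=tifffile.imread(path), **meta)


def write_afm_image(path: str | Path, img: AFMImage) -> Path:
    path = Path(path)
    tifffile.imwrite(path, img.heights.astype(np.float32))
    _sidecar(path).write_text(json.dumps({"pixel_size_nm": img.pixel_size_nm}))
    return path


def read_afm_image(path: str | Path) -> AFMImage:
    path = Path(path)
    if path.suffix.lower() in {".txt", ".dat"}:
        raise ValueError("use read_afm_matrix for plain-text height maps")
    meta = json.loads(_sidecar(path).read_text())
    return AFMImage(heights=tifffile.imread(path), **meta)


def read_afm_matrix(path: str | Path, pixel_size_nm: float) -> AFMImage:
    """Read a whitespace-delimited plain-text height matrix (nm units)."""
    return AFMImage(heights=np.loadtxt(path), pixel_size_nm=pixel_size_nm)


def write_decay_image(path: str | Path, img: DecayImage) -> Path:
    path = Path(path)
    tifffile.imwrite(path, img.histograms.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps({"bin_width_ns": img.bin_width_ns, "frequency_hz": img.frequency_hz})
    )
    return path


def read_decay_image(path: str | Path) -> DecayImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return DecayImage(histograms=tifffile.imread(path), **meta)


def write_gel_image(path: str | Path, img: GelImage) -> Path:
    path = Path(path)
    tifffile.imwrite(path, img.values.astype(np.float32))
    _sidecar(path).write_text(json.dumps({"saturation_level": img.saturation_level}))
    return path


def read_gel_image(path: str | Path) -> GelImage:
    path = Path(path)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return GelImage(values=tifffile.imread(path).astype(float), **meta)
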