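"""File I/O: spectra as two-column CSV, masks as 0/1 text, results as JSON.

Dialects are fixed (comma separator, dot decimal, LF line endings) regardless
of locale.  Spectrum metadata travels in ``# key=value`` comment lines at the
top of the file and round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .hadamard import MaskSet
from .phantom import Spectrum, WavelengthGrid

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_mask_set",
    "write_mask_set",
    "load_config",
]

_HEADER = "wavelength_nm,intensity"


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum at full (repr) precision with metadata comment lines."""
    lines = []
    meta = dict(spectrum.metadata)
    if spectrum.label:
        meta["label"] = spectrum.label
    if spectrum.excitation_intensity is not None:
        meta["excitation_intensity"] = repr(spectrum.excitation_intensity)
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    lines.append(_HEADER)
    for wl, y in zip(spectrum.wavelengths, spectrum.intensities):
        lines.append(f"{float(wl)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column spectrum CSV; wavelengths must be strictly increasing."""
    meta: dict = {}
    wavelengths: list[float] = []
    intensities: list[float] = []
    saw_header = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if not saw_header:
            if line.replace(" ", "") != _HEADER:
                raise ValueError(f"malformed header {line!r}; expected {_HEADER!r}")
            saw_header = True
            continue
        cells = line.split(",")
        if len(cells) != 2:
            raise ValueError(f"expected 2 cells, got {line!r}")
        try:
            wavelengths.append(float(cells[0]))
            intensities.append(float(cells[1]))
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in line {line!r}") from exc
    if not saw_header:
        raise ValueError("missing header line")
    wl = np.asarray(wavelengths)
    if wl.size < 2:
        raise ValueError("spectrum needs at least 2 rows")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), int(wl.size))
    if not np.allclose(grid.centers, wl, rtol=0, atol=1e-6):
        raise ValueError("wavelengths are not uniformly spaced")
    label = meta.pop("label", "")
    exc_raw = meta.pop("excitation_intensity", None)
    return Spectrum(
        grid=grid,
        intensities=np.asarray(intensities),
        label=label,
        excitation_intensity=float(exc_raw) if exc_raw is not None else None,
        metadata=meta,
    )


def write_mask_set(mask_set: MaskSet, path) -> None:
    """Delimited 0/1 matrix with a one-line JSON header comment."""
    header = json.dumps(
        {
            "scheme": mask_set.scheme,
            "n_channels": mask_set.n_channels,
            "decode_rule": mask_set.decode_rule,
        }
    )
    rows = [",".join(str(int(v)) for v in row) for row in mask_set.matrix]
    Path(path).write_text("# " + header + "\n" + "\n".join(rows) + "\n", newline="\n")


def read_mask_set(path) -> MaskSet:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ValueError("mask file must start with a JSON header comment")
    header = json.loads(lines[0].lstrip("#").strip())
    matrix = np.array([[int(v) for v in ln.split(",")] for ln in lines[1:]], dtype=np.int8)
    return MaskSet(
        matrix=matrix,
        scheme=header["scheme"],
        n_channels=int(header["n_channels"]),
        decode_rule=header.get("decode_rule", ""),
    )


def load_config(path) -> dict:
    """Load a YAML (or JSON -- a YAML subset) config mapping."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
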