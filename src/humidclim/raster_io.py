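"""Integer quantization, GeoTIFF export and dataset packaging.

Layers are stored as 16-bit signed integers: temperature-related variables
(BIO1-BIO11) are multiplied by 10 (so 0.1 degC resolution) and the humidity
variables (BIO12-BIO19) by 100 000 (1e-5 kg/kg resolution), with
half-away-from-zero rounding and -32768 as the nodata sentinel. Values whose
scaled magnitude exceeds the int16 range raise instead of wrapping.

File and folder names follow the convention
``resolution_version_decade_BIOn.tif`` with resolutions ``10m``, ``5m`` and
``2_5m``, versions ``min``/``mean``/``max`` and decades ``80s``/``90s``/
``00s`` — e.g. ``10m_min_00s_BIO1.tif`` inside folder ``10m_min_00s``.

GeoTIFFs are single-band int16 in geographic WGS84 coordinates, north-up,
with ModelPixelScale/ModelTiepoint geo-tags, an EPSG:4326 GeoKey directory
and a GDAL-style nodata tag, written with ``tifffile``.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .bioclim import VARIABLE_INFO, VARIABLE_NAMES, BioclimSet
from .grids import GridSpec

_INT_LIMITS = {"int16": 32767, "int32": 2147483647}

__all__ = [
    "QuantizationRule",
    "QuantizationOverflowError",
    "LayerName",
    "quantize",
    "dequantize",
    "render_name",
    "parse_name",
    "write_geotiff",
    "read_geotiff",
    "package_decade",
    "resolution_token",
]

NODATA_INT16 = -32768
INT16_MAX = 32767

RESOLUTION_TOKENS = ("10m", "5m", "2_5m")
VERSION_TOKENS = ("min", "mean", "max")
DECADE_TOKENS = ("80s", "90s", "00s")

_TOKEN_BY_ARCMIN = {10.0: "10m", 10: "10m", 5.0: "5m", 5: "5m", 2.5: "2_5m"}


class QuantizationOverflowError(ValueError):
    """A scaled value fell outside the int16 range."""


def resolution_token(resolution) -> str:
    """Map a resolution in arc-minutes (10, 5, 2.5) to its name token."""
    if isinstance(resolution, str):
        if resolution not in RESOLUTION_TOKENS:
            raise ValueError(f"unknown resolution token {resolution!r}")
        return resolution
    try:
        return _TOKEN_BY_ARCMIN[resolution]
    except KeyError:
        raise ValueError(f"no naming token for resolution {resolution!r} arc-min") from None


@dataclass(frozen=True)
class QuantizationRule:
    """How one variable is packed into a fixed-point integer raster.

    BIO15 defaults to int32: a coefficient of variation in percent times
    100 000 exceeds the int16 range for any realistic humidity field, while
    every other variable fits comfortably in 16 bits.
    """

    variable_id: str
    scale_factor: int = field(default=None)  # type: ignore[assignment]
    nodata: int = NODATA_INT16
    dtype: str = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.variable_id not in VARIABLE_NAMES:
            raise ValueError(f"unknown variable {self.variable_id!r}")
        expected = VARIABLE_INFO[self.variable_id]["scale_factor"]
        if self.scale_factor is None:
            object.__setattr__(self, "scale_factor", expected)
        elif self.scale_factor != expected:
            raise ValueError(
                f"{self.variable_id} uses scale factor {expected}, got {self.scale_factor}"
            )
        if self.dtype is None:
            object.__setattr__(self, "dtype", "int32" if self.variable_id == "BIO15" else "int16")
        if self.dtype not in _INT_LIMITS:
            raise ValueError(f"dtype must be one of {sorted(_INT_LIMITS)}")


def quantize(layer: np.ndarray, rule: QuantizationRule) -> np.ndarray:
    """``round_half_away(value * scale_factor)`` as integer; NaN -> nodata."""
    layer = np.asarray(layer, dtype=float)
    scaled = layer * rule.scale_factor
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    finite = np.isfinite(rounded)
    limit = _INT_LIMITS[rule.dtype]
    over = finite & (np.abs(rounded) > limit)
    if over.any():
        cell = tuple(int(i) for i in np.argwhere(over)[0])
        raise QuantizationOverflowError(
            f"{rule.variable_id}: scaled value {rounded[cell]:.0f} at cell {cell} "
            f"exceeds {rule.dtype} range"
        )
    return np.where(finite, rounded, rule.nodata).astype(rule.dtype)


def dequantize(layer: np.ndarray, rule: QuantizationRule) -> np.ndarray:
    """Inverse of :func:`quantize` up to half a quantum; nodata -> NaN."""
    layer = np.asarray(layer)
    out = layer.astype(float) / rule.scale_factor
    return np.where(layer == rule.nodata, np.nan, out)


@dataclass(frozen=True)
class LayerName:
    """The four-token layer naming convention."""

    resolution: str
    version: str
    decade: str
    variable: str

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTION_TOKENS:
            raise ValueError(f"resolution must be one of {RESOLUTION_TOKENS}")
        if self.version not in VERSION_TOKENS:
            raise ValueError(f"version must be one of {VERSION_TOKENS}")
        if self.decade not in DECADE_TOKENS:
            raise ValueError(f"decade must be one of {DECADE_TOKENS}")
        if self.variable not in VARIABLE_NAMES:
            raise ValueError(f"variable must be one of BIO1..BIO19")

    def render(self) -> str:
        return f"{self.resolution}_{self.version}_{self.decade}_{self.variable}.tif"

    @property
    def folder(self) -> str:
        return f"{self.resolution}_{self.version}_{self.decade}"

    @classmethod
    def parse(cls, name: str) -> "LayerName":
        stem = name[:-4] if name.endswith(".tif") else name
        parts = stem.split("_")
        if len(parts) < 4:
            raise ValueError(f"cannot parse layer name {name!r}")
        variable, decade, version = parts[-1], parts[-2], parts[-3]
        resolution = "_".join(parts[:-3])
        return cls(resolution=resolution, version=version, decade=decade, variable=variable)


def render_name(name: LayerName) -> str:
    return name.render()


def parse_name(s: str) -> LayerName:
    return LayerName.parse(s)


# ---------------------------------------------------------------- GeoTIFF IO

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeys: geographic model, pixel-is-area raster, EPSG:4326 datum
_GEO_KEYS = (
    1, 1, 0, 3,          # version 1.1, 3 keys follow
    1024, 0, 1, 2,       # GTModelType = geographic
    1025, 0, 1, 1,       # GTRasterType = PixelIsArea
    2048, 0, 1, 4326,    # GeographicType = WGS84
)


def write_geotiff(layer: np.ndarray, grid: GridSpec, path, nodata: int = NODATA_INT16) -> None:
    """Write a quantized integer layer as a north-up WGS84 GeoTIFF."""
    layer = np.asarray(layer)
    if layer.dtype not in (np.int16, np.int32):
        raise ValueError("write_geotiff expects a quantized int16/int32 layer")
    if layer.shape != grid.shape:
        raise ValueError(f"layer shape {layer.shape} != grid shape {grid.shape}")
    nodata_ascii = f"{nodata}\x00".encode("ascii")
    extratags = [
        (_TAG_PIXEL_SCALE, 12, 3, (grid.lon_step, grid.lat_step, 0.0)),
        (_TAG_TIEPOINT, 12, 6, (0.0, 0.0, 0.0, grid.west_edge, grid.north_edge, 0.0)),
        (_TAG_GEO_KEYS, 3, len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, 2, len(nodata_ascii), nodata_ascii),
    ]
    tifffile.imwrite(str(path), layer, photometric="minisblack", extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridSpec, int]:
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns ``(array, grid, nodata)``; the grid is reconstructed from the
    geo-tags (edge-registered, north-up).
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError:
            raise ValueError(f"{path}: missing georeferencing tags") from None
        nodata = NODATA_INT16
        if _TAG_GDAL_NODATA in tags:
            nodata = int(float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00")))
    west, north = float(tie[3]), float(tie[4])
    grid = GridSpec(
        n_rows=arr.shape[0],
        n_cols=arr.shape[1],
        lat_step=float(sy),
        lon_step=float(sx),
        lat_origin=north,
        lon_origin=west,
        registration="edge",
    )
    return arr, grid, nodata


def package_decade(
    sets: dict,
    decade: str,
    version: str,
    out_dir,
    make_zip: bool = False,
) -> list[Path]:
    """Write one folder of 19 GeoTIFFs per resolution; optionally zip each.

    ``sets`` maps a resolution (arc-minutes or token) to a
    :class:`~humidclim.bioclim.BioclimSet`. Returns the folder (or zip)
    paths created.
    """
    if decade not in DECADE_TOKENS:
        raise ValueError(f"decade must be one of {DECADE_TOKENS}")
    if version not in VERSION_TOKENS:
        raise ValueError(f"version must be one of {VERSION_TOKENS}")
    if not sets:
        raise ValueError("no resolution sets given")
    out_dir = Path(out_dir)
    created: list[Path] = []
    for resolution, bset in sets.items():
        if not isinstance(bset, BioclimSet):
            raise TypeError("sets values must be BioclimSet instances")
        missing = [v for v in VARIABLE_NAMES if v not in bset.layers]
        if missing:
            raise ValueError(f"incomplete set for {resolution}: missing {missing}")
        token = resolution_token(resolution)
        folder = out_dir / f"{token}_{version}_{decade}"
        folder.mkdir(parents=True, exist_ok=True)
        for var in VARIABLE_NAMES:
            rule = QuantizationRule(variable_id=var)
            q = quantize(bset.layers[var], rule)
            name = LayerName(resolution=token, version=version, decade=decade, variable=var)
            write_geotiff(q, bset.grid, folder / name.render(), nodata=rule.nodata)
        if make_zip:
            zip_path = folder.with_suffix(".zip")
            with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
                for f in sorted(folder.iterdir()):
                    zf.write(f, arcname=f"{folder.name}/{f.name}")
            created.append(zip_path)
        else:
            created.append(folder)
    return created
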