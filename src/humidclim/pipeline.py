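"""End-to-end orchestration: hourly files -> decadal GeoTIFF folders.

The full chain is: read hourly NetCDF -> per-year monthly climatologies ->
19 annual bioclim layers per humidity version -> ecological rescale ->
decadal mean -> spline downscaling to the requested resolutions -> integer
quantization -> named GeoTIFF folders.
"""

from __future__ import annotations

from pathlib import Path

from .bioclim import (
    BioclimSet,
    annual_bioclim,
    apply_ecological_rescale,
    decadal_mean,
)
from .climatology import MonthlyClimatology
from .downscale import SplineParams, downscale_set
from .ingest import build_year_climatology, read_hourly_netcdf
from .raster_io import package_decade

__all__ = ["DECADES", "build_decade_set", "run_build"]

#: decade labels partitioning the 1981-2010 span
DECADES = {
    "80s": tuple(range(1981, 1991)),
    "90s": tuple(range(1991, 2001)),
    "00s": tuple(range(2001, 2011)),
}


def build_decade_set(
    climatologies: list[MonthlyClimatology],
    version: str,
    decade_label: str,
    cv_offset: float = 0.0,
) -> BioclimSet:
    """Annual bioclim -> rescale -> decadal mean for one humidity version."""
    annuals = [
        apply_ecological_rescale(annual_bioclim(clim, version=version, cv_offset=cv_offset))
        for clim in climatologies
    ]
    return decadal_mean(annuals, period=decade_label)


def run_build(
    input_paths,
    decade: str,
    versions=("min", "mean", "max"),
    resolutions=(10.0, 5.0, 2.5),
    out_dir="bioclim_out",
    cv_offset: float = 0.0,
    spline: SplineParams = SplineParams(),
    extent=None,
    years=None,
    make_zip: bool = False,
    min_coverage: float = 0.9,
) -> list[Path]:
    """Run the whole pipeline for one decade; returns created folder paths.

    ``years`` defaults to the decade's ten calendar years; pass a shorter
    list to process partial data.
    """
    if decade not in DECADES:
        raise ValueError(f"decade must be one of {tuple(DECADES)}")
    years = list(years) if years is not None else list(DECADES[decade])
    cube = read_hourly_netcdf(input_paths)
    climatologies = [
        build_year_climatology(cube, year, min_coverage=min_coverage) for year in years
    ]
    del cube  # the hourly fields dominate memory; not needed past this point
    created: list[Path] = []
    for version in versions:
        decadal = build_decade_set(climatologies, version, decade, cv_offset=cv_offset)
        # one resolution at a time: the finest grid dominates peak memory
        for res in resolutions:
            by_res = downscale_set(decadal, resolutions=(res,), params=spline, extent=extent)
            created += package_decade(by_res, decade, version, out_dir, make_zip=make_zip)
    return created
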