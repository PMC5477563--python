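# humidclim

Bioclimatic predictor layers (BIO1–BIO19) from **hourly gridded 2 m
temperature and specific humidity**, with a specific-humidity moisture axis
in place of precipitation — for ecologists building species distribution
models (SDMs) in regions that ground-station interpolations cover poorly
(high latitudes, Antarctica, high altitudes), and for anyone who needs a
reproducible pipeline from reanalysis-style hourly fields to packaged
GeoTIFF climate layers.

## What it computes

From hourly fields T(t; φ, λ) in Kelvin and q(t; φ, λ) in kg water / kg air
on a regular latitude–longitude grid:

1. **Monthly climatologies** — per cell and calendar month *m*:
   tmin_m / tmax_m (extremes of all hourly temperatures, °C) and
   hmin_m / hmean_m / hmax_m (min / mean / max of hourly humidity).
2. **19 bioclimatic variables** per year, in three humidity **versions**
   (V_min, V_mean, V_max — which monthly humidity summary serves as the
   moisture series). Temperature variables follow the classic definitions,
   e.g. BIO1 = mean of monthly (tmin+tmax)/2, BIO4 = 100·σ(monthly means),
   BIO7 = BIO5 − BIO6, BIO3 = 100·BIO2/BIO7. "Quarters" are the 12 cyclic
   3-month windows; the wettest quarter maximises the moisture sum, the
   warmest the mean temperature, ties to the earliest start.
3. **Ecological rescaling** — because humidity is intensive, the annual and
   quarterly *sums* are converted to means: BIO12/12, BIO16–BIO19/3.
4. **Decadal means** (80s = 1981–1990, 90s = 1991–2000, 00s = 2001–2010).
5. **Downscaling** by local regularized thin-plate splines to 10, 5 and 2.5
   arc-minutes.
6. **Integer GeoTIFF export** — ×10 for BIO1–BIO11 (0.1 °C), ×100 000 for
   BIO12–BIO19 (10⁻⁵ kg/kg), folder/file names like
   `10m_min_00s/10m_min_00s_BIO1.tif`.
7. **Validation statistics** — station collocation (Pearson r, OLS of the
   gridded series on the station, R², residual interquartile range as the
   bias scalar, per-month residual summaries) and buffer-zone raster
   comparison (1/3-square-degree buffers, Tukey-fence outlier maps,
   latitude-weighted outlier area fractions).

A seeded synthetic-data generator (seasonal + diurnal temperature cycles,
temperature-coupled humidity, linearly related noisy stations) makes every
stage testable without downloading any real reanalysis product.

## Worked example

```python
import humidclim as hc

clim = hc.gen_monthly_climatology("toy-seasonal")   # a mid-latitude cell
bset = hc.apply_ecological_rescale(hc.annual_bioclim(clim, version="mean"))
for name in ("BIO1", "BIO4", "BIO5", "BIO6", "BIO7", "BIO12", "BIO15"):
    print(name, round(float(bset[name][0, 0]), 4))
```

prints

```
BIO1 9.4583
BIO4 916.6908
BIO5 29.0
BIO6 -8.0
BIO7 37.0
BIO12 0.0055
BIO15 52.7639
```

i.e. an annual mean of 9.46 °C, strong seasonality (σ of monthly means
≈ 9.2 °C, stored ×100), a 37 °C annual range (exactly BIO5 − BIO6), an
annual mean specific humidity of 5.5 g/kg and a humidity seasonality (CV)
of ≈ 53 %. The scripts in `examples/` walk through each capability —
cube generation and ingest, the three-version variable table, downscaling +
GeoTIFF export, and station validation — each printing the numbers it
computes and what they mean.

A thin CLI wraps the same library calls:

```sh
humidclim build --input hourly_2001.nc ... --decade 00s \
    --versions min,mean,max --resolutions 10,5,2.5 --out layers/
humidclim validate stations --cube hourly.nc --stations station.csv
humidclim validate rasters --raster-a x.tif --raster-b y.tif --stations s.csv
```

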