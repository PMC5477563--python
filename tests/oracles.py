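"""Independent brute-force oracle for the 19 bioclim variables.

Written directly from the variable definitions with explicit Python loops
and no code shared with the package: the vectorized implementation is
checked against this, not the other way round.
"""

import math

NAN = float("nan")


def bioclim_oracle(tmin, tmax, moisture, cv_offset=0.0, rescaled=False):
    """All 19 variables for one cell from 12-month lists.

    Returns a dict BIO1..BIO19. ``rescaled=True`` applies the ecological
    rescaling (BIO12/12, BIO16..19/3) at the end.
    """
    assert len(tmin) == len(tmax) == len(moisture) == 12
    tavg = [(tmin[m] + tmax[m]) / 2.0 for m in range(12)]

    out = {}
    out["BIO1"] = sum(tavg) / 12.0
    out["BIO2"] = sum(tmax[m] - tmin[m] for m in range(12)) / 12.0
    mean_t = out["BIO1"]
    out["BIO4"] = math.sqrt(sum((t - mean_t) ** 2 for t in tavg) / 11.0) * 100.0
    out["BIO5"] = max(tmax)
    out["BIO6"] = min(tmin)
    out["BIO7"] = out["BIO5"] - out["BIO6"]
    out["BIO3"] = 100.0 * out["BIO2"] / out["BIO7"] if out["BIO7"] != 0 else NAN

    # the 12 cyclic three-month windows
    wsum_moist = []
    wmean_tavg = []
    for start in range(12):
        months = [start % 12, (start + 1) % 12, (start + 2) % 12]
        wsum_moist.append(sum(moisture[m] for m in months))
        wmean_tavg.append(sum(tavg[m] for m in months) / 3.0)

    def argext(values, biggest):
        best = 0
        for i in range(1, 12):
            if (values[i] > values[best]) if biggest else (values[i] < values[best]):
                best = i
        return best

    wet = argext(wsum_moist, True)
    dry = argext(wsum_moist, False)
    warm = argext(wmean_tavg, True)
    cold = argext(wmean_tavg, False)

    out["BIO8"] = wmean_tavg[wet]
    out["BIO9"] = wmean_tavg[dry]
    out["BIO10"] = max(wmean_tavg)
    out["BIO11"] = min(wmean_tavg)

    out["BIO12"] = sum(moisture)
    out["BIO13"] = max(moisture)
    out["BIO14"] = min(moisture)
    shifted = [m + cv_offset for m in moisture]
    mean_s = sum(shifted) / 12.0
    if mean_s != 0:
        sd_s = math.sqrt(sum((v - mean_s) ** 2 for v in shifted) / 11.0)
        out["BIO15"] = 100.0 * sd_s / mean_s
    else:
        out["BIO15"] = NAN
    out["BIO16"] = wsum_moist[wet]
    out["BIO17"] = wsum_moist[dry]
    out["BIO18"] = wsum_moist[warm]
    out["BIO19"] = wsum_moist[cold]

    if rescaled:
        out["BIO12"] /= 12.0
        for name in ("BIO16", "BIO17", "BIO18", "BIO19"):
            out[name] /= 3.0
    return out
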