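"""Shared simulation helpers for the test suite: a single synthetic
city x subperiod with a known cumulative exposure-lag-response surface."""

import numpy as np
import pandas as pd

from heatattrib.dlnm import ExposureBasisSpec, LagBasisSpec


def simulate_city_subperiod(seed, rr99=1.30, n_years=5, phi=1.0,
                             baseline=40.0, lag_max=10):
    """One synthetic city x subperiod with a known cumulative surface."""
    from heatattrib.synthetic import true_cumulative_curve, _lag_weights

    rng = np.random.default_rng(seed)
    frames = []
    for y in range(2000, 2000 + n_years):
        dates = pd.date_range(f"{y}-05-22", f"{y}-09-30")
        doy = dates.dayofyear.to_numpy(dtype=float)
        seasonal = 18.0 + 4.0 * np.cos(2 * np.pi * (doy - 201) / 365.25)
        eps = rng.normal(0, 1.7, len(dates))
        for i in range(1, len(eps)):
            eps[i] += 0.7 * eps[i - 1]
        frames.append(pd.DataFrame({
            "city": "c", "date": dates, "tmean": seasonal + eps
        }))
    temps = pd.concat(frames, ignore_index=True)
    warm = temps[pd.to_datetime(temps["date"]).dt.month.isin((6, 7, 8, 9))]
    exposure = ExposureBasisSpec.from_temperatures(warm["tmean"].to_numpy())
    theta, mmt, cmin = true_cumulative_curve(
        exposure, warm["tmean"].to_numpy(), rr99
    )
    lag = LagBasisSpec(max_lag=lag_max)
    w = _lag_weights(lag, 1.5)

    deaths_frames = []
    for y in range(2000, 2000 + n_years):
        season = temps[
            (temps["date"] >= pd.Timestamp(y, 5, 22))
            & (temps["date"] <= pd.Timestamp(y, 9, 30))
        ]
        x = season["tmean"].to_numpy()
        delta = exposure.transform(x) @ theta - cmin
        D = np.zeros_like(x)
        for l in range(lag_max + 1):
            if l == 0:
                D += w[0] * delta
            else:
                D[l:] += w[l] * delta[:-l]
        keep = season["date"] >= pd.Timestamp(y, 6, 1)
        lam = baseline * np.exp(D[keep.to_numpy()])
        if phi <= 1.0:
            deaths = rng.poisson(lam)
        else:
            r = lam / (phi - 1.0)
            deaths = rng.negative_binomial(r, r / (r + lam))
        deaths_frames.append(pd.DataFrame({
            "city": "c", "date": season["date"][keep].to_numpy(),
            "deaths": deaths,
        }))
    deaths = pd.concat(deaths_frames, ignore_index=True)
    x99 = float(np.percentile(warm["tmean"], 99.0))
    true_logrr99 = float(
        (exposure.transform(np.array([x99])) @ theta)[0] - cmin
    )
    return temps, deaths, exposure, theta, true_logrr99, x99, mmt
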