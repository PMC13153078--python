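"""Synthetic field-trial generator: plot design, LPN values, canopy spectra.

Emulates a rice nitrogen-rate trial: six N rates (0-187.5 kg/hm^2) x five
replicate plots, five leaf subsamples per plot (150 samples), and 224-band
canopy reflectance over 400-1000 nm whose red-edge position shifts with
leaf protein nitrogen (LPN, % dry mass), so that red-edge/chlorophyll
indices carry the signal.

The LPN response to fertilizer rate is a saturating Michaelis-Menten
curve plus Gaussian subsample noise.  Reflectance is a two-regime mixture:
a visible regime (green peak, red chlorophyll-absorption trough) and a
near-infrared plateau, blended by a logistic red-edge whose inflection
moves from 700 nm toward 715 nm as canopy chlorophyll (proxied by LPN)
increases.  This is a statistical emulator, not radiative transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_RATES = (0.0, 37.5, 75.0, 112.5, 150.0, 187.5)


class DesignError(ValueError):
    """Invalid experimental design (e.g. negative fertilizer rate)."""


class ParameterError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class PlotDesign:
    """One field plot: treatment label, fertilizer rate, replicate index."""

    plot_id: str
    treatment: str
    n_rate: float  # kg/hm^2
    replicate: int

    def __post_init__(self) -> None:
        if self.n_rate < 0:
            raise DesignError(f"negative N rate {self.n_rate} for plot {self.plot_id}")


@dataclass(frozen=True)
class LpnModelParams:
    """Saturating LPN response to nitrogen rate.

    lpn(rate) = l0 + (lmax - l0) * rate / (k_half + rate) + eps,
    eps ~ Normal(0, sigma^2), clipped at 0.

    Defaults span roughly 1.2-3.2 % dry mass over the default rates, so an
    RMSE on the order of 0.2 % is a meaningful error scale.
    """

    l0: float = 1.2  # baseline LPN, % dry mass
    lmax: float = 4.0  # asymptotic LPN, % dry mass
    k_half: float = 75.0  # half-saturation N rate, kg/hm^2
    sigma: float = 0.15  # subsample noise s.d., % dry mass

    def __post_init__(self) -> None:
        if not (self.lmax > self.l0 > 0):
            raise ParameterError(f"require lmax > l0 > 0, got l0={self.l0}, lmax={self.lmax}")
        if self.k_half <= 0:
            raise ParameterError(f"k_half must be positive, got {self.k_half}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be nonnegative, got {self.sigma}")

    def mean_lpn(self, rate: float) -> float:
        return self.l0 + (self.lmax - self.l0) * rate / (self.k_half + rate)


@dataclass(frozen=True)
class SensorModel:
    """Imaging-spectrometer band layout and noise: 224 bands, 400-1000 nm."""

    lambda_min: float = 400.0
    lambda_max: float = 1000.0
    n_bands: int = 224
    noise_sd: float = 0.02  # multiplicative reflectance noise s.d.

    def __post_init__(self) -> None:
        if self.lambda_min >= self.lambda_max:
            raise ParameterError("lambda_min must be below lambda_max")
        if self.n_bands < 2:
            raise ParameterError("need at least 2 bands")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.lambda_min, self.lambda_max, self.n_bands)


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed reflectance vector."""

    wavelengths: np.ndarray  # nm, strictly ascending
    reflectance: np.ndarray  # unitless, in [0, 1]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)
        if wl.ndim != 1 or r.shape != wl.shape:
            raise ParameterError("wavelengths and reflectance must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ParameterError("wavelengths must be strictly ascending")
        if np.any(~np.isfinite(r)):
            raise ParameterError("reflectance contains non-finite values")
        if np.any(r < 0) or np.any(r > 1):
            raise ParameterError("reflectance must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class SpectrumShapeParams:
    """Constants of the generative reflectance model; all configurable.

    The chlorophyll proxy c = clamp(lpn / lpn_scale, 0, 1) drives:
    red-edge inflection re_base + re_shift*c; NIR plateau nir_base +
    nir_gain*c; a green peak at 550 nm damped by c; and a red
    absorption trough at 670 nm deepening with c.
    """

    lpn_scale: float = 4.0  # matches LpnModelParams.lmax default
    re_base: float = 700.0
    re_shift: float = 15.0
    re_width: float = 10.0
    nir_base: float = 0.40
    nir_gain: float = 0.10
    vis_floor: float = 0.05
    green_amp: float = 0.06
    green_center: float = 550.0
    green_width: float = 25.0
    green_damp: float = 0.6
    red_amp: float = 0.035
    red_center: float = 670.0
    red_width: float = 20.0
    vis_min: float = 0.01


def generate_design(
    rates: tuple[float, ...] | list[float] = DEFAULT_N_RATES,
    replicates: int = 5,
) -> list[PlotDesign]:
    """Build the full-factorial plot layout: one plot per (rate, replicate).

    Treatments are labeled N1..Nk in ascending-rate order of the given
    rates; plot ids are deterministic ``P01``, ``P02``, ...
    """
    if replicates < 0:
        raise DesignError(f"replicates must be nonnegative, got {replicates}")
    if replicates == 0:
        return []
    if len(rates) == 0:
        raise DesignError("rates must be non-empty")
    if any(r < 0 for r in rates):
        raise DesignError("N rates must be nonnegative")
    order = np.argsort(rates, kind="stable")
    plots: list[PlotDesign] = []
    pid = 0
    for rank, idx in enumerate(order):
        for rep in range(1, replicates + 1):
            pid += 1
            plots.append(
                PlotDesign(
                    plot_id=f"P{pid:02d}",
                    treatment=f"N{rank + 1}",
                    n_rate=float(rates[idx]),
                    replicate=rep,
                )
            )
    return plots


def simulate_lpn(
    design: list[PlotDesign],
    params: LpnModelParams = LpnModelParams(),
    subsamples_per_plot: int = 5,
    seed: int = 0,
    plot_sigma: float = 0.0,
) -> pd.DataFrame:
    """Draw per-subsample LPN values for every plot in the design.

    Returns a DataFrame with columns sample_id, plot_id, treatment, n_rate,
    lpn (% dry mass).  ``plot_sigma`` adds an optional plot-level random
    effect (off by default); subsample noise s.d. is ``params.sigma``.
    """
    if subsamples_per_plot < 1:
        raise ParameterError("subsamples_per_plot must be >= 1")
    if plot_sigma < 0:
        raise ParameterError("plot_sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for plot in design:
        mu = params.mean_lpn(plot.n_rate)
        plot_effect = rng.normal(0.0, plot_sigma) if plot_sigma > 0 else 0.0
        for sub in range(1, subsamples_per_plot + 1):
            eps = rng.normal(0.0, params.sigma) if params.sigma > 0 else 0.0
            lpn = max(0.0, mu + plot_effect + eps)
            rows.append(
                {
                    "sample_id": f"{plot.plot_id}_S{sub}",
                    "plot_id": plot.plot_id,
                    "treatment": plot.treatment,
                    "n_rate": plot.n_rate,
                    "lpn": lpn,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "plot_id", "treatment", "n_rate", "lpn"])


def _mean_reflectance(
    wavelengths: np.ndarray, lpn: float, shape: SpectrumShapeParams
) -> np.ndarray:
    """Noise-free reflectance curve for a given LPN."""
    c = float(np.clip(lpn / shape.lpn_scale, 0.0, 1.0))
    lam = wavelengths
    lam_re = shape.re_base + shape.re_shift * c
    s = 1.0 / (1.0 + np.exp(-(lam - lam_re) / shape.re_width))
    r_nir = shape.nir_base + shape.nir_gain * c
    green = shape.green_amp * np.exp(-((lam - shape.green_center) ** 2) / (2 * shape.green_width**2))
    red = shape.red_amp * np.exp(-((lam - shape.red_center) ** 2) / (2 * shape.red_width**2))
    r_vis = shape.vis_floor + green * (1.0 - shape.green_damp * c) - red * c
    r_vis = np.maximum(r_vis, shape.vis_min)
    return r_nir * s + r_vis * (1.0 - s)


def simulate_spectrum(
    lpn: float,
    sensor: SensorModel = SensorModel(),
    seed: int = 0,
    shape: SpectrumShapeParams = SpectrumShapeParams(),
) -> Spectrum:
    """Simulate one canopy reflectance spectrum for a given LPN value.

    Multiplicative noise Normal(1, noise_sd^2) per band; result clipped to
    [0, 1].
    """
    if lpn < 0:
        raise ParameterError(f"lpn must be nonnegative, got {lpn}")
    wl = sensor.wavelengths
    r = _mean_reflectance(wl, lpn, shape)
    if sensor.noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r * rng.normal(1.0, sensor.noise_sd, size=r.shape)
    return Spectrum(wavelengths=wl, reflectance=np.clip(r, 0.0, 1.0))


def simulate_dataset(
    rates: tuple[float, ...] | list[float] = DEFAULT_N_RATES,
    replicates: int = 5,
    subsamples_per_plot: int = 5,
    params: LpnModelParams = LpnModelParams(),
    sensor: SensorModel = SensorModel(),
    shape: SpectrumShapeParams = SpectrumShapeParams(),
    seed: int = 0,
    plot_sigma: float = 0.0,
) -> tuple[pd.DataFrame, list[Spectrum]]:
    """Full synthetic campaign: samples table plus one spectrum per sample.

    Spectrum seeds are derived deterministically from ``seed`` so the whole
    dataset is reproducible from one integer.
    """
    design = generate_design(rates, replicates)
    samples = simulate_lpn(design, params, subsamples_per_plot, seed=seed, plot_sigma=plot_sigma)
    seed_rng = np.random.default_rng(seed + 1)
    spectra = [
        simulate_spectrum(lpn, sensor, seed=int(seed_rng.integers(0, 2**31 - 1)), shape=shape)
        for lpn in samples["lpn"].to_numpy()
    ]
    return samples, spectra


def band_name(wavelength: float) -> str:
    """Column name for a raw band, e.g. ``B_670.40``."""
    return f"B_{wavelength:.2f}"


def spectra_to_frame(samples: pd.DataFrame, spectra: list[Spectrum]) -> pd.DataFrame:
    """Wide CSV layout: sample_id plus one column per band center."""
    if len(samples) != len(spectra):
        raise ParameterError("samples and spectra length mismatch")
    if spectra:
        wl = spectra[0].wavelengths
        cols = [band_name(w) for w in wl]
        mat = np.vstack([s.reflectance for s in spectra])
        out = pd.DataFrame(mat, columns=cols)
    else:
        out = pd.DataFrame()
    out.insert(0, "sample_id", samples["sample_id"].to_numpy())
    return out
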