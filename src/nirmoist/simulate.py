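"""Synthetic NIR spectra with moisture-dependent absorption structure.

Dried-seaweed (nori) spectra in the 900-1650 nm short-wave NIR window are
emulated as a sum of Gaussian absorption bands whose amplitudes couple
linearly to moisture mass fraction, plus per-sample multiplicative and
additive scatter and i.i.d. instrument noise:

    A_i(lam) = (1 + a_i) * sum_b [amp_b + c_b * m_i/100] * g_b(lam) + b_i + eps

with ``g_b`` a unit-height Gaussian centred on the band, ``a_i``/``b_i``
per-sample scatter draws and ``eps`` channel noise.  The default band set
places the O-H first-overtone water band near 1430 nm (moisture-coupled),
the C-H second-overtone carbohydrate band near 1180 nm, and a weaker
polysaccharide-water interaction band near 1375 nm.

Moisture values are drawn from a truncated normal whose defaults match a
commercial dried-nori calibration set: mean 10.18 %, SD 2.78 %, range
4.37-14.84 % (mass fraction, percent).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbsorptionBand",
    "GeneratorConfig",
    "SpectraSet",
    "DEFAULT_BANDS",
    "generate_moisture",
    "generate_spectra",
    "generate_dataset",
    "write_spectra",
    "read_spectra",
]

MOISTURE_COLUMN = "moisture_percent"


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption band.

    Parameters
    ----------
    center_nm : float
        Band centre in nm.
    width_nm : float
        Gaussian SD in nm; must be positive.
    base_amplitude : float
        Moisture-independent absorbance at the band centre.
    moisture_coupling : float
        Absorbance added per unit moisture *mass fraction* (moisture percent
        divided by 100).  Zero for moisture-independent bands.
    """

    center_nm: float
    width_nm: float
    base_amplitude: float
    moisture_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError(f"width_nm must be > 0, got {self.width_nm}")
        if self.base_amplitude < 0:
            raise ValueError(f"base_amplitude must be >= 0, got {self.base_amplitude}")


#: O-H first overtone (water, moisture-coupled), C-H second overtone
#: (carbohydrate backbone), and polysaccharide-water interaction band.
DEFAULT_BANDS: tuple[AbsorptionBand, ...] = (
    AbsorptionBand(center_nm=1430.0, width_nm=45.0, base_amplitude=0.25, moisture_coupling=2.2),
    AbsorptionBand(center_nm=1180.0, width_nm=35.0, base_amplitude=0.28, moisture_coupling=0.0),
    AbsorptionBand(center_nm=1365.0, width_nm=18.0, base_amplitude=0.08, moisture_coupling=0.5),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic spectra generator.

    The wavelength grid is ``n_channels`` evenly spaced points over
    ``[lambda_start_nm, lambda_end_nm]``.  The default channel count of 125
    matches the model input dimension used throughout the package; the
    acquisition geometry (900-1650 nm at a 3.0 nm interval) would give 251
    points, and both are supported through ``n_channels``.
    """

    n_samples: int = 380
    lambda_start_nm: float = 900.0
    lambda_end_nm: float = 1650.0
    n_channels: int = 125
    moisture_mean: float = 10.18
    moisture_sd: float = 2.78
    moisture_min: float = 4.37
    moisture_max: float = 14.84
    bands: tuple[AbsorptionBand, ...] = DEFAULT_BANDS
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.lambda_start_nm < self.lambda_end_nm:
            raise ValueError(
                f"lambda_start_nm ({self.lambda_start_nm}) must be < "
                f"lambda_end_nm ({self.lambda_end_nm})"
            )
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if not self.moisture_min < self.moisture_max:
            raise ValueError(
                f"moisture_min ({self.moisture_min}) must be < moisture_max "
                f"({self.moisture_max})"
            )
        if not self.moisture_min <= self.moisture_mean <= self.moisture_max:
            raise ValueError("moisture_mean must lie within [moisture_min, moisture_max]")
        for name in ("moisture_sd", "scatter_slope_sd", "scatter_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def wavelength_grid(self) -> np.ndarray:
        return np.linspace(self.lambda_start_nm, self.lambda_end_nm, self.n_channels)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SpectraSet:
    """Absorbance matrix plus wavelength grid and optional moisture vector.

    The universal payload between pipeline stages.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    moisture: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but there "
                f"are {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.wavelengths)) or not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite values in spectra")
        if self.moisture is not None:
            self.moisture = np.asarray(self.moisture, dtype=float)
            if self.moisture.shape != (self.absorbance.shape[0],):
                raise ValueError(
                    f"moisture length {self.moisture.size} does not match "
                    f"{self.absorbance.shape[0]} samples"
                )
            if not np.all(np.isfinite(self.moisture)):
                raise ValueError("non-finite moisture values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]


def _substreams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent child streams for moisture, scatter and noise.

    One shared seed drives all three, so any stage can be regenerated in
    isolation without replaying the others.
    """
    moisture_ss, scatter_ss, noise_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(moisture_ss),
        np.random.default_rng(scatter_ss),
        np.random.default_rng(noise_ss),
    )


def generate_moisture(config: GeneratorConfig) -> np.ndarray:
    """Draw moisture values (percent) from a truncated normal.

    Values are drawn from N(moisture_mean, moisture_sd) truncated to
    [moisture_min, moisture_max]; ``moisture_sd = 0`` degenerates to a
    constant vector at the mean.  Reproducible for a fixed seed.
    """
    rng, _, _ = _substreams(config.seed)
    if config.moisture_sd == 0:
        return np.full(config.n_samples, config.moisture_mean)

    # Asymmetric truncation shifts the mean of a truncated normal away from
    # the location parameter, so the location is re-centred (by root finding)
    # until the truncated distribution's mean equals moisture_mean; the
    # configured mean then really is the expected value of the draw.
    def truncated_mean(loc: float) -> float:
        a = (config.moisture_min - loc) / config.moisture_sd
        b = (config.moisture_max - loc) / config.moisture_sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=config.moisture_sd)

    from scipy.optimize import brentq

    span = config.moisture_max - config.moisture_min
    loc = brentq(
        lambda m: truncated_mean(m) - config.moisture_mean,
        config.moisture_min - span, config.moisture_max + span, xtol=1e-10,
    )
    a = (config.moisture_min - loc) / config.moisture_sd
    b = (config.moisture_max - loc) / config.moisture_sd
    return stats.truncnorm.rvs(
        a, b, loc=loc, scale=config.moisture_sd,
        size=config.n_samples, random_state=rng,
    )


def generate_spectra(moisture: np.ndarray, config: GeneratorConfig) -> SpectraSet:
    """Build an absorbance matrix for given moisture values (percent).

    Clean spectra are sums of Gaussian bands with moisture-coupled
    amplitudes; per-sample multiplicative scatter ``(1 + a_i)``, additive
    offset ``b_i`` and i.i.d. Gaussian channel noise are then applied.
    """
    moisture = np.asarray(moisture, dtype=float)
    if moisture.ndim != 1:
        raise ValueError("moisture must be a one-dimensional vector")
    if np.any((moisture < 0) | (moisture > 100)):
        raise ValueError("moisture values must lie in [0, 100] percent")

    _, scatter_rng, noise_rng = _substreams(config.seed)
    lam = config.wavelength_grid()
    n = moisture.size

    clean = np.zeros((n, lam.size))
    frac = moisture / 100.0  # percent -> mass fraction where amplitudes couple
    for band in config.bands:
        shape = np.exp(-((lam - band.center_nm) ** 2) / (2.0 * band.width_nm**2))
        amp = band.base_amplitude + band.moisture_coupling * frac
        clean += amp[:, None] * shape[None, :]

    slope = scatter_rng.normal(0.0, config.scatter_slope_sd, size=n) if config.scatter_slope_sd else np.zeros(n)
    offset = scatter_rng.normal(0.0, config.scatter_offset_sd, size=n) if config.scatter_offset_sd else np.zeros(n)
    absorbance = (1.0 + slope)[:, None] * clean + offset[:, None]
    if config.noise_sd:
        absorbance = absorbance + noise_rng.normal(0.0, config.noise_sd, size=absorbance.shape)

    return SpectraSet(wavelengths=lam, absorbance=absorbance, moisture=moisture)


def generate_dataset(config: GeneratorConfig) -> SpectraSet:
    """Moisture draw plus spectra in one call."""
    return generate_spectra(generate_moisture(config), config)


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV: header row = wavelengths in nm, one row per
    sample, optional final column ``moisture_percent``."""
    columns = [repr(float(w)) for w in spectra.wavelengths]  # shortest round-trip repr
    frame = pd.DataFrame(spectra.absorbance, columns=columns)
    if spectra.moisture is not None:
        frame[MOISTURE_COLUMN] = spectra.moisture
    frame.to_csv(path, index=False)


def read_spectra(path) -> SpectraSet:
    """Read a spectral CSV written by :func:`write_spectra`.

    Raises
    ------
    ValueError
        On non-numeric or missing cells (named by row and column), on
        unsorted wavelength headers, or on ragged rows.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ValueError(f"malformed spectra file {path}: {exc}") from exc

    moisture = None
    if MOISTURE_COLUMN in frame.columns:
        moisture = frame.pop(MOISTURE_COLUMN).to_numpy()

    try:
        wavelengths = np.array([float(c) for c in frame.columns])
    except ValueError as exc:
        raise ValueError(
            f"non-numeric wavelength header in {path}: {exc}"
        ) from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError(f"wavelength header in {path} is not strictly increasing")

    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        row, col = bad[0]
        raise ValueError(
            f"non-numeric or missing cell in {path} at data row {row}, "
            f"column '{frame.columns[col]}'"
        )
    if moisture is not None:
        moisture = pd.to_numeric(pd.Series(moisture), errors="coerce").to_numpy()
        bad_m = np.argwhere(~np.isfinite(moisture))
        if bad_m.size:
            raise ValueError(
                f"non-numeric or missing cell in {path} at data row "
                f"{bad_m[0][0]}, column '{MOISTURE_COLUMN}'"
            )
    return SpectraSet(wavelengths=wavelengths, absorbance=values, moisture=moisture)
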