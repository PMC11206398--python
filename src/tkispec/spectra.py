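"""UV-Vis spectrum construction and peak-shift analysis.

Excited-state calculations deliver a *stick spectrum*: a list of
(wavelength, oscillator strength) pairs. A smooth absorption profile is
obtained by giving each stick a Gaussian band in the **energy** domain with
area proportional to its oscillator strength, then sampling the sum on a
uniform wavelength grid. Total integrated intensity over energy is therefore
proportional to the sum of oscillator strengths.

The principal absorption maximum (λmax) is read off the sticks directly, not
off the broadened curve: it is the longest-wavelength transition whose
oscillator strength clears a threshold (default f >= 0.5, the rule used to
tabulate the principal band of the quinazoline series). The crystal-pose
spectral shift is Δλmax = λ_crystal − λ_cal; a negative value (crystal band
at shorter wavelength) is a blue shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ensembles import StickSpectrum
from .errors import (
    GridMismatchError,
    NoQualifyingTransitionError,
    ValidationError,
)

__all__ = [
    "EV_NM",
    "DEFAULT_FWHM_EV",
    "DEFAULT_GRID",
    "BroadenedSpectrum",
    "PeakShiftRecord",
    "broaden",
    "lambda_max",
    "peak_shift",
    "difference_spectrum",
    "band_onset",
    "provisional_peaks",
]

#: Photon energy-wavelength product: E [eV] = EV_NM / λ [nm].
EV_NM = 1239.841984

#: Default Gaussian band full width at half maximum, eV.
DEFAULT_FWHM_EV = 0.333

#: Default wavelength grid (min nm, max nm, step nm).
DEFAULT_GRID = (180.0, 350.0, 0.1)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BroadenedSpectrum:
    """Absorbance sampled on a strictly increasing uniform wavelength grid.

    ``absorbance`` may be negative only for difference spectra (flagged via
    ``provenance['kind']``); ordinary broadened spectra are non-negative.
    """

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.shape != ab.shape:
            raise ValidationError("wavelength and absorbance lengths differ")
        if len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")

    @property
    def step_nm(self) -> float:
        return float(self.wavelength_nm[1] - self.wavelength_nm[0])

    def argmax_nm(self) -> float:
        return float(self.wavelength_nm[int(np.argmax(self.absorbance))])

    def integral_over_energy(self) -> float:
        """Integral of absorbance over photon energy (eV), by trapezoid."""
        energy = EV_NM / self.wavelength_nm
        order = np.argsort(energy)
        return float(np.trapezoid(self.absorbance[order], energy[order]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "absorbance": self.absorbance}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PeakShiftRecord:
    """Principal-band shift between a crystal pose and the global minimum."""

    substituent: str
    lambda_cal_nm: float
    lambda_crystal_nm: float
    delta_lambda_nm: float
    shift_class: str  # "blue" | "red" | "none"

    def __post_init__(self):
        expected = self.lambda_crystal_nm - self.lambda_cal_nm
        if self.delta_lambda_nm != expected:
            raise ValidationError("delta_lambda must equal lambda_crystal - lambda_cal")


def broaden(
    stick: StickSpectrum,
    fwhm_eV: float = DEFAULT_FWHM_EV,
    grid: tuple[float, float, float] = DEFAULT_GRID,
) -> BroadenedSpectrum:
    """Convolve a stick spectrum with Gaussian bands in the energy domain.

    Each excitation at wavelength λ_k contributes a Gaussian centred at
    E_k = EV_NM/λ_k with standard deviation σ = FWHM/2.3548 and **area** equal
    to its oscillator strength, so the energy-domain integral of the result
    equals Σf (up to grid truncation). The sum is sampled at the energies of
    the uniform nm grid.

    Raises on an empty stick list; if the grid excludes every stick the
    result is a zero spectrum and ``provenance['warning']`` is set.
    """
    if fwhm_eV <= 0:
        raise ValidationError(f"fwhm_eV must be > 0, got {fwhm_eV}")
    lo, hi, step = grid
    if not (lo < hi and step > 0):
        raise ValidationError(f"invalid grid {grid}")
    if len(stick.states) == 0:  # pragma: no cover - StickSpectrum forbids this
        raise ValidationError("empty stick spectrum")

    wl = np.arange(lo, hi + 0.5 * step, step)
    energy = EV_NM / wl
    sigma = fwhm_eV * _FWHM_TO_SIGMA
    centers = EV_NM / stick.wavelengths
    strengths = stick.oscillator_strengths
    # (n_grid, n_sticks) Gaussian evaluation; stick counts are small (~30)
    gauss = np.exp(-0.5 * ((energy[:, None] - centers[None, :]) / sigma) ** 2)
    absorb = gauss @ (strengths / (sigma * np.sqrt(2.0 * np.pi)))

    provenance = {
        "owner_label": stick.owner_label,
        "kind": "broadened",
        "fwhm_eV": fwhm_eV,
        "grid": tuple(grid),
    }
    in_range = (stick.wavelengths >= lo) & (stick.wavelengths <= hi)
    if not np.any(in_range):
        provenance["warning"] = "grid excludes all sticks"
    return BroadenedSpectrum(wl, absorb, provenance)


def lambda_max(
    stick: StickSpectrum,
    f_threshold: float = 0.5,
    window: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Principal absorption band: longest-wavelength state with f >= threshold.

    ``window`` optionally restricts the search to a (min nm, max nm)
    interval. If two qualifying states share the maximal wavelength the one
    with larger oscillator strength wins. When no state qualifies a
    :class:`NoQualifyingTransitionError` is raised — never a silent fallback
    to a weaker band.

    Returns
    -------
    (wavelength_nm, oscillator_strength)
    """
    candidates = [
        s
        for s in stick.states
        if s.oscillator_strength >= f_threshold
        and (window is None or window[0] <= s.wavelength_nm <= window[1])
    ]
    if not candidates:
        where = f" in window {window}" if window else ""
        raise NoQualifyingTransitionError(
            f"{stick.owner_label!r}: no transition with f >= {f_threshold}{where}"
        )
    best = max(candidates, key=lambda s: (s.wavelength_nm, s.oscillator_strength))
    return best.wavelength_nm, best.oscillator_strength


def peak_shift(
    lambda_cal_nm: float, lambda_crystal_nm: float, substituent: str = ""
) -> PeakShiftRecord:
    """Δλmax = λ_crystal − λ_cal with its blue/red classification."""
    if lambda_cal_nm <= 0 or lambda_crystal_nm <= 0:
        raise ValidationError("wavelengths must be positive")
    delta = lambda_crystal_nm - lambda_cal_nm
    if delta < 0:
        cls = "blue"
    elif delta > 0:
        cls = "red"
    else:
        cls = "none"
    return PeakShiftRecord(
        substituent=substituent,
        lambda_cal_nm=lambda_cal_nm,
        lambda_crystal_nm=lambda_crystal_nm,
        delta_lambda_nm=delta,
        shift_class=cls,
    )


def difference_spectrum(
    a: BroadenedSpectrum, b: BroadenedSpectrum
) -> BroadenedSpectrum:
    """Pointwise ``a - b`` on an identical grid (no implicit resampling)."""
    if a.wavelength_nm.shape != b.wavelength_nm.shape or not np.allclose(
        a.wavelength_nm, b.wavelength_nm, rtol=0, atol=1e-12
    ):
        raise GridMismatchError("difference_spectrum requires identical wavelength grids")
    return BroadenedSpectrum(
        a.wavelength_nm.copy(),
        a.absorbance - b.absorbance,
        {
            "kind": "difference",
            "minuend": a.provenance.get("owner_label"),
            "subtrahend": b.provenance.get("owner_label"),
        },
    )


def band_onset(spec: BroadenedSpectrum, fraction_of_max: float = 0.02) -> float:
    """Absorption onset: shortest wavelength where A first exceeds a fraction of max.

    Scans from short to long wavelength; the onset criterion (default 2% of
    the maximum) is a package parameter, configurable per analysis.
    """
    if not (0 < fraction_of_max < 1):
        raise ValidationError("fraction_of_max must lie in (0, 1)")
    peak = float(np.max(spec.absorbance))
    if peak <= 0:
        raise ValidationError("band_onset is undefined for an all-zero spectrum")
    above = spec.absorbance > fraction_of_max * peak
    idx = int(np.argmax(above))
    if not above[idx]:  # pragma: no cover - peak > 0 guarantees a crossing
        raise ValidationError("no onset crossing found")
    return float(spec.wavelength_nm[idx])


def provisional_peaks(
    spec: BroadenedSpectrum, min_fraction_of_max: float = 0.05
) -> list[float]:
    """Local maxima of the broadened curve (3-point discrete test).

    Congested short-wavelength bands overlap heavily, so these positions are
    *provisional* peak readings, not resolved transitions; tiny bumps below
    ``min_fraction_of_max`` of the global maximum are ignored.
    """
    a = spec.absorbance
    floor = min_fraction_of_max * float(np.max(a))
    interior = np.arange(1, len(a) - 1)
    is_peak = (a[interior] > a[interior - 1]) & (a[interior] >= a[interior + 1])
    keep = interior[is_peak & (a[interior] >= floor)]
    return [float(spec.wavelength_nm[i]) for i in keep]
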