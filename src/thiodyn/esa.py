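"""Excited-state absorption spectra from stick data.

Electronic-structure calculations deliver, for each excited-state
minimum, a list of vertical transitions (energy, oscillator strength).
A band spectrum is obtained by placing a Gaussian of fixed energy-domain
FWHM (0.7 eV by default) on every stick with amplitude proportional to
its oscillator strength, and a measured transient spectrum is then
interpreted as a non-negative linear combination of such component
bands, the weights giving the per-cent contribution of each state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core import EV_NM

__all__ = [
    "StickSpectrum",
    "BandSpectrum",
    "CombinationFit",
    "broaden",
    "fit_combination",
    "read_sticks",
    "write_sticks",
    "write_band",
    "read_band",
]

DEFAULT_FWHM_EV = 0.7


@dataclass(frozen=True)
class StickSpectrum:
    """Vertical transitions of one electronic state."""

    state_label: str
    transitions: tuple[tuple[float, float], ...]  # (energy eV, oscillator strength)

    def __post_init__(self) -> None:
        for energy, f in self.transitions:
            if energy <= 0:
                raise ValueError(f"transition energy must be positive, got {energy}")
            if f < 0:
                raise ValueError(f"oscillator strength must be >= 0, got {f}")


@dataclass
class BandSpectrum:
    """A broadened absorption band sampled on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensity: np.ndarray
    state_label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity vectors must match")
        if np.any(self.intensity < 0):
            raise ValueError("band intensity must be non-negative")

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelengths[np.argmax(self.intensity)])


@dataclass
class CombinationFit:
    weights: np.ndarray  # >= 0, one per component
    percent: np.ndarray  # 100 * w / sum(w)
    residual_rms: float
    component_labels: tuple[str, ...] = ()


def broaden(
    sticks: StickSpectrum,
    fwhm_eV: float = DEFAULT_FWHM_EV,
    grid: np.ndarray | None = None,
) -> BandSpectrum:
    """Gaussian-broaden a stick spectrum onto a wavelength grid.

    Broadening acts in the energy domain with constant width
    sigma_E = fwhm / (2 sqrt(2 ln 2)):
    I(lambda) = sum_k f_k exp(-(E(lambda) - E_k)^2 / (2 sigma_E^2)),
    then the band is simply sampled at the grid wavelengths.  No
    dE/dlambda Jacobian is applied, i.e. the spectrum is treated as a
    function of energy re-plotted against wavelength; an empty stick
    list yields the zero spectrum.
    """
    if fwhm_eV <= 0:
        raise ValueError("fwhm must be positive")
    if grid is None:
        grid = np.arange(300.0, 750.0 + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    energies = EV_NM / grid
    sigma = fwhm_eV / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    intensity = np.zeros_like(grid)
    for e_k, f_k in sticks.transitions:
        intensity += f_k * np.exp(-((energies - e_k) ** 2) / (2.0 * sigma**2))
    return BandSpectrum(grid, intensity, sticks.state_label)


def fit_combination(
    components: list[BandSpectrum], target: np.ndarray
) -> CombinationFit:
    """Non-negative least-squares decomposition of a transient spectrum.

    Solves min || sum_i w_i comp_i - target ||^2 with w_i >= 0 (spectra
    add like populations of absorbers, so negative weights are
    unphysical) and reports each weight as a percentage of the total.
    """
    if not components:
        raise ValueError("at least one component is required")
    target = np.asarray(target, dtype=float)
    grid = components[0].wavelengths
    for comp in components:
        if comp.wavelengths.shape != grid.shape or not np.allclose(
            comp.wavelengths, grid
        ):
            raise ValueError("all components must share the target's grid")
    if target.shape != grid.shape:
        raise ValueError("target must be sampled on the component grid")
    A = np.column_stack([c.intensity for c in components])
    weights, rnorm = optimize.nnls(A, target)
    total = weights.sum()
    percent = 100.0 * weights / total if total > 0 else np.zeros_like(weights)
    return CombinationFit(
        weights=weights,
        percent=percent,
        residual_rms=float(rnorm / np.sqrt(len(target))),
        component_labels=tuple(c.state_label for c in components),
    )


def write_sticks(sticks: list[StickSpectrum], path) -> None:
    rows = [
        {"state_label": s.state_label, "energy_eV": e, "oscillator_strength": f}
        for s in sticks
        for e, f in s.transitions
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_sticks(path) -> list[StickSpectrum]:
    df = pd.read_csv(path)
    out = []
    for label, grp in df.groupby("state_label", sort=False):
        out.append(
            StickSpectrum(
                str(label),
                tuple(
                    (float(e), float(f))
                    for e, f in zip(grp["energy_eV"], grp["oscillator_strength"])
                ),
            )
        )
    return out


def write_band(band: BandSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": band.wavelengths, "intensity": band.intensity}
    ).to_csv(path, index=False, float_format="%.10g")


def read_band(path, state_label: str = "") -> BandSpectrum:
    df = pd.read_csv(path)
    return BandSpectrum(
        df["wavelength_nm"].to_numpy(float), df["intensity"].to_numpy(float), state_label
    )
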