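"""Synthetic inputs with known ground truth.

The experimental transient-absorption maps and the ab initio stick
spectra behind the 2-thiocytosine study are not deposited, so every
input of the analysis chain is emulated here with the statistical
structure the analysis assumes: broadband dA maps built from the
two-step sequential model (lifetimes 210/480 fs, 200 fs IRF), probe
chirp, Gaussian noise and a masked pump-overtone window; stochastic
jump-trajectory ensembles on the relaxation scheme S2 -> S1 -> {T2, T1}
-> T1 with the simulation-derived rate constants; and fixture stick
spectra at the published band positions with declared (invented)
oscillator strengths honouring the 10-fold npi*/pipi* intensity ratio.

All generators are pure functions of (config, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from .core import EV_NM
from .esa import StickSpectrum
from .populations import JumpEnsemble, simulate_jump_ensemble
from .tas import (
    DASet,
    IRFModel,
    SequentialModel,
    SpectroTemporalMap,
    chirp_polynomial,
    emg_profile,
    sequential_profiles,
)

__all__ = [
    "TASGenConfig",
    "generate_tas",
    "generate_trajectory_ensemble",
    "default_markov_rates",
    "fixture_sticks",
    "default_delay_grid",
]

#: Gaussian band parameters (centre nm, sigma nm, amplitude mOD) for the
#: three decay-associated spectra of the synthetic map.  These shapes are
#: declared fixtures emulating the reported band positions (UV band near
#: 355 nm on the intermediate component, visible band near 525 nm on the
#: offset, a broad featureless initial component); they are not digitised
#: from any figure.
DEFAULT_DAS_SHAPES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "A": ((450.0, 150.0, 0.6), (550.0, 100.0, 0.4)),
    "B": ((355.0, 30.0, 2.0), (581.0, 50.0, 0.8)),
    "C": ((525.0, 60.0, 1.6), (420.0, 45.0, 0.4)),
}


def default_delay_grid() -> np.ndarray:
    """Pump-probe delay axis: 20 fs steps from -1 ps to +1 ps, then 40
    log-spaced points out to 5 ps (emulating typical acquisition)."""
    lin = np.arange(-1000.0, 1000.0, 20.0)
    log = np.geomspace(1000.0, 5000.0, 41)
    return np.unique(np.concatenate([lin, log]))


@dataclass
class TASGenConfig:
    wl_min: float = 320.0  # nm
    wl_max: float = 710.0
    wl_step: float = 2.0
    delays: np.ndarray = field(default_factory=default_delay_grid)  # fs
    tau1: float = 210.0  # fs
    tau2: float = 480.0  # fs
    irf_fwhm: float = 200.0  # fs
    t0: float = 0.0  # fs, common time zero after chirp correction
    das_shapes: dict = field(default_factory=lambda: dict(DEFAULT_DAS_SHAPES))
    chirp_coeffs: tuple[float, ...] = (250.0, -0.7, 0.0005)  # fs per nm^m
    noise_sd: float = 0.05  # mOD
    mask_window: tuple[float, float] = (600.0, 632.0)  # nm, pump overtone
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_step <= 0 or self.noise_sd < 0 or self.irf_fwhm <= 0:
            raise ValueError("grid steps, widths and noise sd must be positive")
        self.delays = np.asarray(self.delays, dtype=float)
        if self.delays.size < 10 or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delay grid must be increasing with >= 10 points")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_min, self.wl_max + self.wl_step / 2, self.wl_step)


def _das_from_shapes(shapes: dict, wavelengths: np.ndarray) -> DASet:
    spectra = []
    labels = tuple(shapes.keys())
    for label in labels:
        spec = np.zeros_like(wavelengths)
        for center, sigma, amp in shapes[label]:
            spec += amp * np.exp(-((wavelengths - center) ** 2) / (2.0 * sigma**2))
        spectra.append(spec)
    return DASet(labels, np.vstack(spectra))


def generate_tas(config: TASGenConfig) -> tuple[SpectroTemporalMap, dict]:
    """Synthesize a broadband dA map plus its ground-truth record.

    The map is the bilinear sequential model with the chirp applied
    analytically (each wavelength's kinetics evaluated with its own time
    zero t0 + chirp(lambda)), iid Gaussian noise added, and the
    pump-overtone window masked.  The ground truth carries the DAS, the
    lifetimes, the IRF, the chirp polynomial and the seed.
    """
    wl = config.wavelengths
    das = _das_from_shapes(config.das_shapes, wl)
    model = SequentialModel(config.tau1, config.tau2)
    shift = chirp_polynomial(wl, config.chirp_coeffs)
    amplitudes = np.empty((wl.size, config.delays.size))
    for i in range(wl.size):
        irf_i = IRFModel(config.irf_fwhm, config.t0 + shift[i])
        profiles = np.vstack(sequential_profiles(model, irf_i, config.delays))
        amplitudes[i] = das.spectra[:, i] @ profiles
    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        amplitudes = amplitudes + rng.normal(0.0, config.noise_sd, amplitudes.shape)
    mask = np.zeros(amplitudes.shape, dtype=bool)
    lo, hi = config.mask_window
    mask[(wl >= lo) & (wl <= hi), :] = True
    smap = SpectroTemporalMap(wl, config.delays, amplitudes, mask)
    truth = {
        "das": das,
        "tau1": config.tau1,
        "tau2": config.tau2,
        "irf_fwhm": config.irf_fwhm,
        "t0": config.t0,
        "chirp_coeffs": tuple(config.chirp_coeffs),
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return smap, truth


def default_markov_rates() -> dict:
    """The packaged rate file of the relaxation scheme (fs^-1).

    The S2 state depopulates with the simulation-derived 160 fs lifetime
    (mostly to S1, with a minor direct S2->T2 branch), S1 undergoes
    intersystem crossing with the ~250 fs average time constant split
    between T2 (faster) and T1, and T2->T1 internal conversion follows
    on the ~480 fs scale.
    """
    with resources.files("thiodyn.data").joinpath("markov_rates.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


def generate_trajectory_ensemble(
    rates=None,
    n_traj: int = 137,
    t_max: float = 1000.0,
    seed: int = 0,
) -> JumpEnsemble:
    """Event-driven jump trajectories on the relaxation rate graph.

    ``rates`` defaults to the packaged file (see
    :func:`default_markov_rates`); pass either ``{(src, dst): rate}`` or
    ``[(src, dst, rate)]`` to override.  Reproducible under ``seed``.
    """
    if rates is None:
        spec = default_markov_rates()
        triples = [(r["from"], r["to"], float(r["rate"])) for r in spec["rates"]]
        initial = spec.get("initial_state")
    else:
        triples = rates
        initial = None
    return simulate_jump_ensemble(triples, n_traj, t_max, seed, initial)


def fixture_sticks() -> list[StickSpectrum]:
    """Approximate excited-state absorption sticks for testing.

    Band positions follow the reported values (1pipi* at 363 nm; 3pipi*
    at 441 and 546 nm; the two npi* states at 333/576 and 333/574 nm);
    the oscillator strengths are invented fixtures with the npi* bands
    set to one tenth of the pipi* bands.
    """
    def ev(nm: float) -> float:
        return EV_NM / nm

    return [
        StickSpectrum("1pipi*", ((ev(363.0), 1.0),)),
        StickSpectrum("3pipi*", ((ev(441.0), 0.8), (ev(546.0), 0.7))),
        StickSpectrum("1npi*", ((ev(333.0), 0.1), (ev(576.0), 0.07))),
        StickSpectrum("3npi*", ((ev(333.0), 0.1), (ev(574.0), 0.07))),
    ]
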