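"""Global/target analysis of broadband transient-absorption maps.

A pump-probe experiment on 2-thiocytosine delivers a difference-absorbance
map dA(lambda, t) in mOD.  The dynamics during the first picoseconds are
described by a two-step sequential kinetic scheme A -> B -> C where C is a
non-decaying offset (the long-lived triplet): the concentration profiles
are exponentials convolved with a Gaussian instrument response function
(IRF), and every wavelength shares the same lifetimes while carrying its
own amplitudes.  The fit therefore separates into a small nonlinear part
(tau1, tau2, t0) and a conditionally linear part (the decay-associated
spectra, DAS), solved here by variable projection.

All times are fs, wavelengths nm, amplitudes mOD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "SpectroTemporalMap",
    "IRFModel",
    "SequentialModel",
    "DASet",
    "GlobalFitResult",
    "emg_profile",
    "sequential_profiles",
    "compose_map",
    "chirp_correct",
    "apply_chirp",
    "global_fit",
    "kinetic_trace",
    "read_map",
    "write_map",
]

_DEGENERATE_DK = 1e-12  # fs^-1; below this the equal-lifetime limit is used


@dataclass
class SpectroTemporalMap:
    """A dA(lambda, t) matrix with axes and an exclusion mask.

    ``amplitudes`` has shape (n_wavelengths, n_delays); ``mask`` is the
    same shape with True marking points excluded from every fit (e.g.
    the pump-overtone window blocked in the experiment).
    """

    wavelengths: np.ndarray  # nm, strictly increasing
    delays: np.ndarray  # fs, strictly increasing
    amplitudes: np.ndarray  # mOD, (n_wl, n_t)
    mask: np.ndarray | None = None  # bool, True = excluded

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.amplitudes.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delay axis must be strictly increasing")
        expected = (self.wavelengths.size, self.delays.size)
        if self.amplitudes.shape != expected:
            raise ValueError(
                f"amplitudes shape {self.amplitudes.shape} does not match axes {expected}"
            )
        if self.mask.shape != expected:
            raise ValueError("mask shape does not match amplitudes")

    def copy(self) -> "SpectroTemporalMap":
        return SpectroTemporalMap(
            self.wavelengths.copy(),
            self.delays.copy(),
            self.amplitudes.copy(),
            self.mask.copy(),
        )


@dataclass(frozen=True)
class IRFModel:
    """Gaussian instrument response: FWHM and time zero (both fs)."""

    fwhm: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"IRF fwhm must be positive, got {self.fwhm}")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SequentialModel:
    """Two-lifetime sequential scheme A --tau1--> B --tau2--> C."""

    tau1: float
    tau2: float
    has_offset: bool = True

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("lifetimes must be positive")


@dataclass
class DASet:
    """Decay-associated spectra: one amplitude spectrum per component.

    Component C is the constant offset of the sequential scheme.
    """

    component_labels: tuple[str, ...]
    spectra: np.ndarray  # (n_components, n_wavelengths), mOD

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape[0] != len(self.component_labels):
            raise ValueError("one spectrum per component label required")


@dataclass
class GlobalFitResult:
    model: SequentialModel
    das: DASet
    irf: IRFModel
    residual_rms: float
    lifetime_uncertainties: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)
    cost: float = float("nan")
    n_points: int = 0


def emg_profile(rate: float, irf: IRFModel, delays: np.ndarray) -> np.ndarray:
    """Exponential decay exp(-k (t-t0)) H(t-t0) convolved with the IRF.

    Uses the exponentially-modified-Gaussian closed form in its
    numerically stable scaled-erfc expression
    c(t) = 1/2 * erfcx(z) * exp(-(t-t0)^2 / (2 sigma^2)),
    z = (t0 - t + k sigma^2) / (sigma sqrt(2)),
    which is algebraically identical to
    1/2 exp(-k(t-t0) + k^2 sigma^2/2) erfc(z) but free of overflow.
    For ``rate == 0`` this is the IRF-convolved step.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    sigma = irf.sigma
    t = np.asarray(delays, dtype=float)
    tau = t - irf.t0
    z = (-tau + rate * sigma**2) / (sigma * np.sqrt(2.0))
    # two stable branches: erfcx kills the overflow of the plain
    # exponential prefactor for z > 0 (early times), while for z <= 0
    # (late times, where erfcx itself overflows) the plain form is safe
    # because its exponent -k tau + k^2 sigma^2/2 is then non-positive
    pos = z > 0
    out = np.empty_like(z)
    out[pos] = 0.5 * special.erfcx(z[pos]) * np.exp(
        -(tau[pos] ** 2) / (2.0 * sigma**2)
    )
    a = -rate * tau[~pos] + 0.5 * rate**2 * sigma**2
    out[~pos] = 0.5 * np.exp(a) * special.erfc(z[~pos])
    return out


def _emg_degenerate_b(rate: float, irf: IRFModel, delays: np.ndarray) -> np.ndarray:
    # Equal-lifetime limit of the intermediate: k t e^{-kt} H(t) (x) Gaussian,
    # written with erfcx to avoid cancellation.
    sigma = irf.sigma
    tau = np.asarray(delays, dtype=float) - irf.t0
    z = (-tau + rate * sigma**2) / (sigma * np.sqrt(2.0))
    gauss = np.exp(-(tau**2) / (2.0 * sigma**2))
    out = np.empty_like(z)
    pos = z > 0
    out[pos] = rate * gauss[pos] * (
        0.5 * (tau[pos] - rate * sigma**2) * special.erfcx(z[pos])
        + sigma / np.sqrt(2.0 * np.pi)
    )
    a = -rate * tau[~pos] + 0.5 * rate**2 * sigma**2
    out[~pos] = rate * (
        0.5 * (tau[~pos] - rate * sigma**2) * np.exp(a) * special.erfc(z[~pos])
        + sigma / np.sqrt(2.0 * np.pi) * gauss[~pos]
    )
    return out


def sequential_profiles(
    model: SequentialModel, irf: IRFModel, delays: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRF-convolved concentration profiles (c_A, c_B, c_C).

    c_A + c_B + c_C equals the IRF-convolved step exactly, so the offset
    component C absorbs everything that has not decayed.  The degenerate
    tau1 == tau2 case switches to the analytic t-weighted limit.
    """
    k1 = 1.0 / model.tau1
    k2 = 1.0 / model.tau2
    step = emg_profile(0.0, irf, delays)
    c_a = emg_profile(k1, irf, delays)
    if abs(k1 - k2) < _DEGENERATE_DK:
        c_b = _emg_degenerate_b(k1, irf, delays)
    else:
        c_b = k1 / (k1 - k2) * (emg_profile(k2, irf, delays) - c_a)
    c_c = step - c_a - c_b
    return c_a, c_b, c_c


def compose_map(
    das: DASet,
    profiles: tuple[np.ndarray, ...],
    wavelengths: np.ndarray,
    delays: np.ndarray,
) -> SpectroTemporalMap:
    """Bilinear model: amplitudes[i, j] = sum_comp DAS[comp, i] c_comp[j]."""
    prof = np.vstack(profiles)
    if das.spectra.shape[0] != prof.shape[0]:
        raise ValueError("number of DAS components does not match profiles")
    if das.spectra.shape[1] != len(wavelengths):
        raise ValueError("DAS wavelength dimension does not match axis")
    if prof.shape[1] != len(delays):
        raise ValueError("profile delay dimension does not match axis")
    amplitudes = das.spectra.T @ prof
    return SpectroTemporalMap(np.asarray(wavelengths), np.asarray(delays), amplitudes)


def chirp_polynomial(wavelengths: np.ndarray, chirp_coeffs) -> np.ndarray:
    """t0(lambda) = sum_m a_m lambda^m, lambda in nm, result in fs."""
    coeffs = np.asarray(chirp_coeffs, dtype=float)
    return np.polynomial.polynomial.polyval(np.asarray(wavelengths, float), coeffs)


def chirp_correct(
    smap: SpectroTemporalMap, chirp_coeffs
) -> SpectroTemporalMap:
    """Undo probe group-velocity dispersion.

    Each wavelength's trace is resampled at t + t0(lambda) so that time
    zero becomes common to all wavelengths; points that fall outside the
    recorded delay window are masked.  A zero polynomial is the identity.
    """
    t0 = chirp_polynomial(smap.wavelengths, chirp_coeffs)
    if np.all(t0 == 0.0):
        return smap.copy()
    out = smap.copy()
    t = smap.delays
    for i, shift in enumerate(t0):
        ts = t + shift
        out.amplitudes[i] = np.interp(ts, t, smap.amplitudes[i])
        # a corrected point is bad if either neighbour it interpolates
        # between was masked, or if it left the recorded window
        frac_masked = np.interp(ts, t, smap.mask[i].astype(float))
        out.mask[i] = (frac_masked > 1e-12) | (ts < t[0]) | (ts > t[-1])
    return out


def apply_chirp(smap: SpectroTemporalMap, chirp_coeffs) -> SpectroTemporalMap:
    """Impose dispersion (inverse of :func:`chirp_correct`), by resampling
    each trace at t - t0(lambda)."""
    neg = -np.asarray(chirp_coeffs, dtype=float)
    return chirp_correct(smap, neg)


def _solve_das(
    profiles: np.ndarray, amplitudes: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Conditionally-linear DAS solve, one masked least-squares per row."""
    n_comp = profiles.shape[0]
    n_wl = amplitudes.shape[0]
    das = np.zeros((n_comp, n_wl))
    full = ~mask.any(axis=1)
    if full.any():
        # common design matrix for rows without masked points
        sol, *_ = np.linalg.lstsq(profiles.T, amplitudes[full].T, rcond=None)
        das[:, full] = sol
    for i in np.nonzero(~full)[0]:
        keep = ~mask[i]
        if keep.sum() < n_comp:
            continue
        sol, *_ = np.linalg.lstsq(profiles.T[keep], amplitudes[i, keep], rcond=None)
        das[:, i] = sol
    return das


_COMPONENT_LABELS = ("A", "B", "C")


def _model_matrices(theta, base_irf, model_template, delays):
    tau1, tau2, t0 = theta
    irf = IRFModel(base_irf.fwhm, t0)
    model = SequentialModel(tau1, tau2, model_template.has_offset)
    c_a, c_b, c_c = sequential_profiles(model, irf, delays)
    if model.has_offset:
        profiles = np.vstack([c_a, c_b, c_c])
    else:
        profiles = np.vstack([c_a, c_b])
    return model, irf, profiles


def global_fit(
    smap: SpectroTemporalMap,
    init: SequentialModel,
    irf: IRFModel,
    fix_irf: bool = True,
    tau_bounds: tuple[float, float] = (5.0, 1e5),
    t0_bounds: tuple[float, float] = (-300.0, 300.0),
    n_starts: int = 3,
) -> GlobalFitResult:
    """Variable-projection global fit of the sequential model.

    The nonlinear parameters are (tau1, tau2, t0); at every trial point
    the DAS are the exact masked linear-least-squares solution, so the
    optimiser only ever sees the projected residual.  The IRF width is
    held fixed (``fix_irf=True``, the default) at the value supplied,
    following the usual practice of determining it from a solvent
    coherence signal.  Three starts log-spaced around the initial
    lifetimes guard against the shallow slow-lifetime direction; ties
    are broken by lowest residual, then lowest tau1.  The fit is
    deterministic for identical inputs.
    """
    if not fix_irf:
        raise NotImplementedError("only a fixed IRF width is supported")
    unmasked_cols = (~smap.mask).any(axis=0).sum()
    unmasked_rows = (~smap.mask).any(axis=1).sum()
    if unmasked_rows < 2 or unmasked_cols < 10:
        raise ValueError("need >= 2 unmasked wavelengths and >= 10 unmasked delays")

    mask = smap.mask
    weights = (~mask).astype(float)
    n_points = int(weights.sum())

    def residual(theta):
        _, _, profiles = _model_matrices(theta, irf, init, smap.delays)
        das = _solve_das(profiles, smap.amplitudes, mask)
        r = (das.T @ profiles - smap.amplitudes) * weights
        return r.ravel()

    lo = np.array([tau_bounds[0], tau_bounds[0], t0_bounds[0]])
    hi = np.array([tau_bounds[1], tau_bounds[1], t0_bounds[1]])
    best = None
    for factor in np.logspace(-0.3, 0.3, n_starts):
        x0 = np.clip(
            [init.tau1 * factor, init.tau2 * factor, irf.t0], lo * 1.001, hi * 0.999
        )
        sol = optimize.least_squares(
            residual, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
        )
        key = (round(sol.cost, 12), round(sol.x[0], 9))
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]

    model, fit_irf, profiles = _model_matrices(sol.x, irf, init, smap.delays)
    das = DASet(_COMPONENT_LABELS[: profiles.shape[0]], _solve_das(profiles, smap.amplitudes, mask))
    rms = float(np.sqrt(2.0 * sol.cost / max(n_points, 1)))

    flags: list[str] = []
    for name, tau in (("tau1", model.tau1), ("tau2", model.tau2)):
        if tau < tau_bounds[0] * 1.01 or tau > tau_bounds[1] * 0.99:
            flags.append(f"{name}_at_bound")
    if not sol.success:
        flags.append("did_not_converge")

    # linearised 1-sigma errors on (tau1, tau2) from the projected Jacobian
    unc = None
    try:
        J = sol.jac
        dof = max(n_points - J.shape[1] - das.spectra.size, 1)
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        unc = (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])))
    except np.linalg.LinAlgError:
        flags.append("singular_covariance")

    return GlobalFitResult(
        model=model,
        das=das,
        irf=fit_irf,
        residual_rms=rms,
        lifetime_uncertainties=unc,
        flags=flags,
        cost=float(sol.cost),
        n_points=n_points,
    )


def replicate_uncertainty(fits: list[GlobalFitResult]) -> tuple[float, float]:
    """Lifetime uncertainty as twice the standard deviation over repeated
    independent fits (the convention used when several experiments are
    analysed separately)."""
    t1 = np.array([f.model.tau1 for f in fits])
    t2 = np.array([f.model.tau2 for f in fits])
    return 2.0 * float(np.std(t1, ddof=1)), 2.0 * float(np.std(t2, ddof=1))


def kinetic_trace(
    smap: SpectroTemporalMap, wavelength: float, fit: GlobalFitResult
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and fitted trace at the nearest recorded wavelength.

    Masked observations are returned as NaN; the fitted vector is the
    bilinear model restricted to that wavelength.
    """
    lo, hi = smap.wavelengths[0], smap.wavelengths[-1]
    if not (lo <= wavelength <= hi):
        raise ValueError(f"wavelength {wavelength} nm outside [{lo}, {hi}]")
    i = int(np.argmin(np.abs(smap.wavelengths - wavelength)))
    if smap.mask[i].all():
        raise ValueError(f"trace at {smap.wavelengths[i]} nm is fully masked")
    observed = np.where(smap.mask[i], np.nan, smap.amplitudes[i])
    _, _, profiles = _model_matrices(
        (fit.model.tau1, fit.model.tau2, fit.irf.t0), fit.irf, fit.model, smap.delays
    )
    fitted = fit.das.spectra[:, i] @ profiles
    return observed, fitted


def write_map(smap: SpectroTemporalMap, path) -> None:
    """Write as delimited text: first row wavelengths (nm), first column
    delays (fs), cells mOD; masked cells become NaN."""
    values = np.where(smap.mask, np.nan, smap.amplitudes)
    df = pd.DataFrame(values.T, index=smap.delays, columns=smap.wavelengths)
    df.index.name = "delay_fs"
    df.to_csv(path, float_format="%.10g")


def read_map(path) -> SpectroTemporalMap:
    df = pd.read_csv(path, index_col=0)
    wavelengths = df.columns.to_numpy(dtype=float)
    delays = df.index.to_numpy(dtype=float)
    amplitudes = df.to_numpy(dtype=float).T
    mask = np.isnan(amplitudes)
    amplitudes = np.nan_to_num(amplitudes)
    return SpectroTemporalMap(wavelengths, delays, amplitudes, mask)
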