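"""Few-mode vibronic coupling models with spin-orbit coupling.

The electronic landscape of 2-thiocytosine near the Franck-Condon region
involves five spin-free states -- S0, the sulfur lone-pair singlet
1npi*, the bright 1pipi*, and the corresponding triplets 3npi* and
3pipi* -- whose minima, conical intersections and singlet-triplet
crossing points all cluster around 3 eV.  This module represents such a
landscape as a linear vibronic coupling (LVC) model on a handful of
dimensionless effective normal modes:

    H_aa(q) = E_a + sum_i kappa_ai q_i + sum_i (omega_i/2 + gamma_ai) q_i^2
    H_ab(q) = lambda0_ab + sum_i lambda_abi q_i      (same multiplicity)

with constant (Condon) spin-orbit couplings between singlets and triplet
sublevels.  The model's stationary and crossing points are located
numerically and calibrated against the packaged table of reference
energies, so that dynamics run on it inherits the printed energetics
even though the effective coordinates are abstract.

Units: energies eV, SOC magnitudes cm^-1 (converted at build time),
coordinates and momenta dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import optimize

from .core import CM1_PER_EV, CriticalPointTable, load_critical_points

__all__ = [
    "ElectronicState",
    "InterstateCoupling",
    "SpinOrbitCoupling",
    "VibronicModel",
    "CalibrationEntry",
    "CalibrationReport",
    "CalibrationError",
    "CalibrationTemplate",
    "spinfree_hamiltonian",
    "spinfree_hamiltonian_batch",
    "total_hamiltonian",
    "expand_spinfree",
    "locate_critical_points",
    "calibrate_model",
    "load_model",
    "save_model",
    "load_2tc_model",
    "load_toy_model",
]

GAP_TOL_EV = 1e-4  # crossing-seam convergence gap
CALIBRATION_TOL_EV = 0.05


@dataclass(frozen=True)
class ElectronicState:
    """One diabatic electronic state of the model."""

    label: str
    multiplicity: int  # 1 or 3
    energy: float  # vertical energy at q = 0, eV
    kappa: tuple[float, ...]  # intrastate gradients, eV per unit q
    quad: tuple[float, ...] | None = None  # quadratic shifts gamma, eV


@dataclass(frozen=True)
class InterstateCoupling:
    """Diabatic coupling between two same-multiplicity states.

    ``mode is None`` denotes a coordinate-independent (constant)
    coupling; otherwise the coupling is ``strength * q[mode]``.
    """

    state_a: str
    state_b: str
    mode: int | None
    strength: float  # eV (or eV per unit q when mode is set)


@dataclass(frozen=True)
class SpinOrbitCoupling:
    """Constant SOC between a singlet and the three sublevels of a triplet.

    ``magnitude`` is the Frobenius norm of the 1x3 singlet-triplet block
    in cm^-1; ``pattern`` is a unit-norm complex 3-vector distributing it
    over the ms = -1, 0, +1 sublevels.
    """

    singlet: str
    triplet: str
    magnitude: float  # cm^-1
    pattern: tuple[complex, complex, complex] = (
        1.0 / np.sqrt(2.0),
        0.0,
        1.0 / np.sqrt(2.0),
    )


@dataclass
class VibronicModel:
    frequencies: np.ndarray  # eV, one per mode
    states: list[ElectronicState]
    couplings: list[InterstateCoupling] = field(default_factory=list)
    soc: list[SpinOrbitCoupling] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ValueError("mode frequencies must be positive")
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        mult = {s.label: s.multiplicity for s in self.states}
        for s in self.states:
            if s.multiplicity not in (1, 3):
                raise ValueError("multiplicity must be 1 (singlet) or 3 (triplet)")
            if len(s.kappa) != self.n_modes:
                raise ValueError(f"state {s.label}: kappa has wrong length")
            if s.quad is not None and len(s.quad) != self.n_modes:
                raise ValueError(f"state {s.label}: quad has wrong length")
        for c in self.couplings:
            if mult[c.state_a] != mult[c.state_b]:
                raise ValueError(
                    "interstate couplings are only allowed between states "
                    "of the same multiplicity"
                )
        for s in self.soc:
            if mult[s.singlet] != 1 or mult[s.triplet] != 3:
                raise ValueError("SOC entries must pair a singlet with a triplet")
            norm = np.linalg.norm(np.asarray(s.pattern, dtype=complex))
            if abs(norm - 1.0) > 1e-10:
                raise ValueError(
                    f"SOC sublevel pattern must have unit norm, got {norm}"
                )

    # -- bookkeeping -----------------------------------------------------

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    @property
    def n_el(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    @property
    def n_singlets(self) -> int:
        return sum(1 for s in self.states if s.multiplicity == 1)

    @property
    def n_triplets(self) -> int:
        return sum(1 for s in self.states if s.multiplicity == 3)

    @property
    def n_dim(self) -> int:
        """Total spin dimension: n_singlets + 3 * n_triplets."""
        return self.n_singlets + 3 * self.n_triplets

    def state(self, label: str) -> ElectronicState:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def state_index(self, label: str) -> int:
        return self.labels.index(label)

    def spin_expansion(self) -> np.ndarray:
        """Electronic index of each component of the spin-expanded basis.

        Singlets come first in state order, then each triplet
        contributes three consecutive sublevels (ms = -1, 0, +1).
        """
        idx = [i for i, s in enumerate(self.states) if s.multiplicity == 1]
        for i, s in enumerate(self.states):
            if s.multiplicity == 3:
                idx.extend([i, i, i])
        return np.asarray(idx, dtype=int)

    def multiplicity_of_dim(self) -> np.ndarray:
        exp = self.spin_expansion()
        return np.asarray([self.states[i].multiplicity for i in exp], dtype=int)


# -- Hamiltonian construction --------------------------------------------


def spinfree_hamiltonian_batch(
    model: VibronicModel, Q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Diabatic spin-free potential matrix and gradient for a batch of
    geometries.

    ``Q`` has shape (..., n_modes); returns ``H`` of shape
    (..., n_el, n_el) in eV and ``grad`` of shape
    (..., n_modes, n_el, n_el) with the exact analytic derivatives.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[-1] != model.n_modes:
        raise ValueError(f"expected {model.n_modes} modes, got {Q.shape[-1]}")
    batch = Q.shape[:-1]
    n = model.n_el
    m = model.n_modes
    H = np.zeros(batch + (n, n))
    grad = np.zeros(batch + (m, n, n))
    omega = model.frequencies
    for a, s in enumerate(model.states):
        kappa = np.asarray(s.kappa)
        curv = omega / 2.0 + (np.asarray(s.quad) if s.quad is not None else 0.0)
        H[..., a, a] = s.energy + Q @ kappa + (Q**2) @ curv
        grad[..., :, a, a] = kappa + 2.0 * curv * Q
    for c in model.couplings:
        a = model.state_index(c.state_a)
        b = model.state_index(c.state_b)
        if c.mode is None:
            val = np.full(batch, c.strength)
        else:
            val = c.strength * Q[..., c.mode]
            grad[..., c.mode, a, b] += c.strength
            grad[..., c.mode, b, a] += c.strength
        H[..., a, b] += val
        H[..., b, a] += val
    return H, grad


def spinfree_hamiltonian(
    model: VibronicModel, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Single-geometry wrapper around :func:`spinfree_hamiltonian_batch`."""
    return spinfree_hamiltonian_batch(model, np.asarray(q, dtype=float))


def expand_spinfree(model: VibronicModel, H_el: np.ndarray) -> np.ndarray:
    """Expand an electronic matrix to the spin basis (triplet sublevels
    degenerate in the spin-free part)."""
    exp = model.spin_expansion()
    mult = model.multiplicity_of_dim()
    H = np.asarray(H_el)[..., exp[:, None], exp[None, :]].copy()
    # a triplet couples to itself and to other triplets only diagonally
    # in ms; off-diagonal sublevel pairs of the spin-free part vanish
    sub = np.zeros(model.n_dim, dtype=int)
    pos = 0
    for i, s in enumerate(model.states):
        if s.multiplicity == 1:
            pos += 1
    k = pos
    for s in model.states:
        if s.multiplicity == 3:
            sub[k : k + 3] = [0, 1, 2]
            k += 3
    both_trip = (mult[:, None] == 3) & (mult[None, :] == 3)
    ms_diff = sub[:, None] != sub[None, :]
    H[..., both_trip & ms_diff] = 0.0
    return H


def soc_matrix(model: VibronicModel) -> np.ndarray:
    """Constant spin-orbit block of the total Hamiltonian (eV, complex)."""
    n = model.n_dim
    H = np.zeros((n, n), dtype=complex)
    exp = model.spin_expansion()
    # first expanded position of each electronic state
    first = {}
    for pos, el in enumerate(exp):
        first.setdefault(int(el), pos)
    for s in model.soc:
        i = first[model.state_index(s.singlet)]
        j0 = first[model.state_index(s.triplet)]
        mag_ev = s.magnitude / CM1_PER_EV
        for ms, pat in enumerate(s.pattern):
            H[i, j0 + ms] += mag_ev * pat
            H[j0 + ms, i] += np.conj(mag_ev * pat)
    return H


def total_hamiltonian(model: VibronicModel, H_el: np.ndarray) -> np.ndarray:
    """Total electronic + spin-orbit Hamiltonian in the spin basis.

    ``H_el`` is the diabatic spin-free matrix (n_el x n_el, possibly
    batched); the result is complex Hermitian of spin dimension
    n_singlets + 3 n_triplets, whose singlet-triplet blocks carry
    Frobenius norm equal to the configured SOC magnitudes.
    """
    return expand_spinfree(model, H_el).astype(complex) + soc_matrix(model)


# -- critical-point location ---------------------------------------------


def _block_indices(model: VibronicModel, multiplicity: int) -> np.ndarray:
    return np.asarray(
        [i for i, s in enumerate(model.states) if s.multiplicity == multiplicity]
    )


def _adiabatic_by_character(model: VibronicModel, q: np.ndarray, label: str):
    """Energy, gradient and character weight of the adiabatic spin-free
    state with the largest weight on diabatic state ``label``."""
    H, grad = spinfree_hamiltonian(model, q)
    s = model.state(label)
    block = _block_indices(model, s.multiplicity)
    sub = H[np.ix_(block, block)]
    w, v = np.linalg.eigh(sub)
    pos = int(np.where(block == model.state_index(label))[0][0])
    k = int(np.argmax(np.abs(v[pos, :]) ** 2))
    vec = v[:, k]
    g_sub = grad[:, block[:, None], block[None, :]]
    g = np.einsum("a,iab,b->i", vec, g_sub, vec)
    return float(w[k]), g, float(np.abs(v[pos, k]) ** 2)


def _diabatic_minimum(model: VibronicModel, label: str) -> np.ndarray:
    s = model.state(label)
    curv = model.frequencies + 2.0 * (
        np.asarray(s.quad) if s.quad is not None else np.zeros(model.n_modes)
    )
    if np.any(curv <= 0):
        raise ValueError(f"state {label} has a non-positive quadratic part")
    return -np.asarray(s.kappa) / curv


def _minimize_surface(model: VibronicModel, label: str, x0: np.ndarray):
    def fun(q):
        e, g, _ = _adiabatic_by_character(model, q, label)
        return e, g

    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            options={"ftol": 1e-14, "gtol": 1e-10})
    return res.x, float(res.fun), bool(res.success)


def _crossing_search(model: VibronicModel, label_a: str, label_b: str,
                     x0: np.ndarray, max_cycles: int = 14):
    """Minimum-energy point on the seam between the adiabatic surfaces
    carrying the two characters, by a squared-gap penalty ramped x10 per
    cycle until the gap closes below ``GAP_TOL_EV``."""
    sigma = 10.0
    x = np.asarray(x0, dtype=float)
    gap = np.inf
    for _ in range(max_cycles):
        def fun(q, sigma=sigma):
            ea, ga, _ = _adiabatic_by_character(model, q, label_a)
            eb, gb, _ = _adiabatic_by_character(model, q, label_b)
            d = ea - eb
            f = 0.5 * (ea + eb) + sigma * d * d
            g = 0.5 * (ga + gb) + 2.0 * sigma * d * (ga - gb)
            return f, g

        res = optimize.minimize(fun, x, jac=True, method="L-BFGS-B",
                                options={"ftol": 1e-14, "gtol": 1e-10})
        x = res.x
        ea, _, _ = _adiabatic_by_character(model, x, label_a)
        eb, _, _ = _adiabatic_by_character(model, x, label_b)
        gap = abs(ea - eb)
        if gap < GAP_TOL_EV:
            return x, 0.5 * (ea + eb), True
        sigma *= 10.0
    ea, _, _ = _adiabatic_by_character(model, x, label_a)
    eb, _, _ = _adiabatic_by_character(model, x, label_b)
    return x, 0.5 * (ea + eb), False


@dataclass
class CalibrationEntry:
    label: str
    target_energy_eV: float
    model_energy_eV: float
    abs_error_eV: float
    converged: bool = True


@dataclass
class CalibrationReport:
    entries: list[CalibrationEntry]

    def get(self, label: str) -> CalibrationEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def max_abs_error(self) -> float:
        return max(e.abs_error_eV for e in self.entries)

    def offenders(self, tol: float = CALIBRATION_TOL_EV) -> list[CalibrationEntry]:
        return [e for e in self.entries if e.abs_error_eV > tol or not e.converged]


def locate_critical_points(
    model: VibronicModel, table: CriticalPointTable | None = None
) -> CalibrationReport:
    """Locate the landscape's stationary and crossing points and compare
    them with the reference table.

    Minima are found by gradient descent on the adiabatic spin-free
    surface carrying each state's diabatic character (started from the
    diabatic minimum); conical intersections and MECPs by the penalty
    seam search; Franck-Condon points are vertical energies at q = 0.
    The barrier entry measures the minimum-energy S0 crossing seam with
    the named excited state relative to that state's minimum, and its
    error is the shortfall below the reference lower bound.  All
    energies are reported relative to the located S0 minimum.
    """
    if table is None:
        table = load_critical_points()
    s0_label = None
    for s in model.states:
        if s.multiplicity == 1 and abs(s.energy) < 1e-9:
            s0_label = s.label
            break
    if s0_label is None:
        s0_label = min(
            (s for s in model.states if s.multiplicity == 1), key=lambda s: s.energy
        ).label
    _, e_s0, _ = _minimize_surface(model, s0_label, _diabatic_minimum(model, s0_label))

    minima: dict[str, float] = {}
    entries: list[CalibrationEntry] = []
    # pass 1: minima (other entries may refer to them)
    for cp in table:
        if cp.kind != "minimum":
            continue
        label = cp.states[0]
        _, e, ok = _minimize_surface(model, label, _diabatic_minimum(model, label))
        minima[label] = e - e_s0
        entries.append(
            CalibrationEntry(cp.label, cp.energy_eV, e - e_s0,
                            abs(e - e_s0 - cp.energy_eV), ok)
        )
    for cp in table:
        if cp.kind == "minimum":
            continue
        if cp.kind == "FC-point":
            e, _, _ = _adiabatic_by_character(
                model, np.zeros(model.n_modes), cp.states[0]
            )
            e -= e_s0
            entries.append(
                CalibrationEntry(cp.label, cp.energy_eV, e, abs(e - cp.energy_eV))
            )
        elif cp.kind in ("CoIn", "MECP"):
            a, b = cp.states
            x0 = 0.5 * (_diabatic_minimum(model, a) + _diabatic_minimum(model, b))
            _, e, ok = _crossing_search(model, a, b, x0)
            e -= e_s0
            entries.append(
                CalibrationEntry(cp.label, cp.energy_eV, e, abs(e - cp.energy_eV), ok)
            )
        elif cp.kind == "barrier":
            exc, gs = cp.states  # e.g. 1npi* / S0
            x0 = 0.5 * _diabatic_minimum(model, exc)
            _, e_seam, ok = _crossing_search(model, exc, gs, x0)
            ref_min = minima.get(exc)
            if ref_min is None:
                _, e_m, _ = _minimize_surface(
                    model, exc, _diabatic_minimum(model, exc)
                )
                ref_min = e_m - e_s0
            barrier = (e_seam - e_s0) - ref_min
            err = max(0.0, cp.energy_eV - barrier) if cp.bound == "ge" else abs(
                barrier - cp.energy_eV
            )
            entries.append(CalibrationEntry(cp.label, cp.energy_eV, barrier, err, ok))
        else:
            raise ValueError(f"unknown critical-point kind {cp.kind!r}")
    return CalibrationReport(entries)


# -- calibration ----------------------------------------------------------


class CalibrationError(RuntimeError):
    def __init__(self, offenders: list[CalibrationEntry]):
        self.offenders = offenders
        msg = "; ".join(
            f"{e.label}: model {e.model_energy_eV:.3f} eV vs target "
            f"{e.target_energy_eV:.3f} eV (|err| {e.abs_error_eV:.3f})"
            for e in offenders
        )
        super().__init__(f"calibration missed targets: {msg}")


@dataclass
class CalibrationTemplate:
    """A model plus the names of its free parameters.

    Parameter names are ``<label>.energy``, ``<label>.kappa<i>`` or
    ``<label>.quad<i>``; everything else is held fixed.
    """

    model: VibronicModel
    free_parameters: list[str]

    def get_vector(self) -> np.ndarray:
        return np.asarray([self._get(p) for p in self.free_parameters])

    def with_vector(self, x: np.ndarray) -> VibronicModel:
        states = {s.label: s for s in self.model.states}
        for name, val in zip(self.free_parameters, x):
            label, fld = name.split(".", 1)
            s = states[label]
            if fld == "energy":
                states[label] = replace(s, energy=float(val))
            elif fld.startswith("kappa"):
                i = int(fld[5:])
                kappa = list(s.kappa)
                kappa[i] = float(val)
                states[label] = replace(s, kappa=tuple(kappa))
            elif fld.startswith("quad"):
                i = int(fld[4:])
                quad = list(s.quad or (0.0,) * self.model.n_modes)
                quad[i] = float(val)
                states[label] = replace(s, quad=tuple(quad))
            else:
                raise ValueError(f"unknown parameter field {fld!r}")
        new_states = [states[s.label] for s in self.model.states]
        return VibronicModel(
            self.model.frequencies.copy(),
            new_states,
            list(self.model.couplings),
            list(self.model.soc),
        )

    def _get(self, name: str) -> float:
        label, fld = name.split(".", 1)
        s = self.model.state(label)
        if fld == "energy":
            return s.energy
        if fld.startswith("kappa"):
            return s.kappa[int(fld[5:])]
        if fld.startswith("quad"):
            return (s.quad or (0.0,) * self.model.n_modes)[int(fld[4:])]
        raise ValueError(f"unknown parameter field {fld!r}")


def calibrate_model(
    table: CriticalPointTable,
    template: CalibrationTemplate,
    tol: float = CALIBRATION_TOL_EV,
) -> VibronicModel:
    """Least-squares adjust the template's free parameters so that
    :func:`locate_critical_points` reproduces every reference energy.

    The optimisation is deterministic (derivative-free residuals with a
    fixed start taken from the template).  If any equality target is
    missed by more than ``tol`` (or the barrier bound violated by more
    than ``tol``), :class:`CalibrationError` lists the offenders.
    """

    def residuals(x):
        model = template.with_vector(x)
        report = locate_critical_points(model, table)
        out = []
        for cp, entry in zip(table, report.entries_in_table_order(table)):
            if cp.bound == "ge":
                out.append(max(0.0, cp.energy_eV - entry.model_energy_eV))
            else:
                out.append(entry.model_energy_eV - cp.energy_eV)
        return np.asarray(out)

    x0 = template.get_vector()
    if np.max(np.abs(residuals(x0))) < 1e-10:
        return template.with_vector(x0)  # already exact: no-op
    sol = optimize.least_squares(residuals, x0, diff_step=1e-3, xtol=1e-12)
    model = template.with_vector(sol.x)
    report = locate_critical_points(model, table)
    offenders = report.offenders(tol)
    if offenders:
        raise CalibrationError(offenders)
    return model


def _entries_in_table_order(self: CalibrationReport, table: CriticalPointTable):
    return [self.get(cp.label) for cp in table]


CalibrationReport.entries_in_table_order = _entries_in_table_order


# -- serialization --------------------------------------------------------


def _model_to_dict(model: VibronicModel) -> dict:
    return {
        "frequencies": [float(w) for w in model.frequencies],
        "states": [
            {
                "label": s.label,
                "multiplicity": s.multiplicity,
                "energy": float(s.energy),
                "kappa": [float(k) for k in s.kappa],
                **(
                    {"quad": [float(g) for g in s.quad]}
                    if s.quad is not None
                    else {}
                ),
            }
            for s in model.states
        ],
        "couplings": [
            {
                "states": [c.state_a, c.state_b],
                "mode": c.mode,
                "strength": float(c.strength),
            }
            for c in model.couplings
        ],
        "soc": [
            {
                "singlet": s.singlet,
                "triplet": s.triplet,
                "magnitude_cm1": float(s.magnitude),
                "pattern": [[float(np.real(p)), float(np.imag(p))] for p in s.pattern],
            }
            for s in model.soc
        ],
    }


def _model_from_dict(d: dict) -> VibronicModel:
    states = [
        ElectronicState(
            label=s["label"],
            multiplicity=int(s["multiplicity"]),
            energy=float(s["energy"]),
            kappa=tuple(float(k) for k in s["kappa"]),
            quad=tuple(float(g) for g in s["quad"]) if "quad" in s else None,
        )
        for s in d["states"]
    ]
    couplings = [
        InterstateCoupling(
            c["states"][0],
            c["states"][1],
            None if c["mode"] is None else int(c["mode"]),
            float(c["strength"]),
        )
        for c in d.get("couplings", [])
    ]
    soc = [
        SpinOrbitCoupling(
            s["singlet"],
            s["triplet"],
            float(s["magnitude_cm1"]),
            tuple(complex(p[0], p[1]) for p in s["pattern"]),
        )
        for s in d.get("soc", [])
    ]
    return VibronicModel(np.asarray(d["frequencies"], float), states, couplings, soc)


def save_model(model: VibronicModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> VibronicModel:
    with open(path, "r", encoding="utf-8") as fh:
        return _model_from_dict(yaml.safe_load(fh))


def _load_packaged(name: str) -> VibronicModel:
    from importlib import resources

    with resources.files("thiodyn.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        return _model_from_dict(yaml.safe_load(fh))


def load_2tc_model() -> VibronicModel:
    """The shipped calibrated 2-thiocytosine model (three effective
    modes, five spin-free states, printed-average SOC magnitudes)."""
    return _load_packaged("2tc_model.yaml")


def load_toy_model(name: str) -> VibronicModel:
    """Pedagogical 1D toys: ``"avoided_crossing"`` (two linear diabats
    with constant coupling, the Landau-Zener workhorse) or
    ``"harmonic_crossing"`` (two crossing harmonic surfaces)."""
    if name not in ("avoided_crossing", "harmonic_crossing"):
        raise KeyError(name)
    return _load_packaged(f"toy_{name}.yaml")
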