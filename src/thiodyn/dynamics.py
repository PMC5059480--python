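"""Trajectory surface hopping with spin-orbit coupling.

Nuclear dynamics runs on the *diagonal* (spin-mixed) surfaces obtained
by diagonalizing the total electronic + spin-orbit Hamiltonian of a
:class:`~thiodyn.vibronic.VibronicModel` at every geometry.  The
electronic wavefunction is propagated by local diabatization -- the
overlap matrix between consecutive eigenbases replaces explicit
nonadiabatic coupling vectors -- with fewest-switches hopping, uniform
momentum rescaling on accepted hops, rejection of energetically
frustrated hops, and an energy-based decoherence correction.

Initial conditions are drawn from the harmonic ground-state Wigner
distribution (per-mode variance 1/2 in both the dimensionless position
and momentum).  Working units: energy eV, time fs, hbar = 0.6582119569
eV fs; the dimensionless mode momenta relate to velocities by
v_i = omega_i p_i / hbar, giving kinetic energy sum_i (omega_i/2) p_i^2.

The propagator is vectorized over the trajectory ensemble: all
trajectories advance in lock-step through batched diagonalizations,
which is what makes ensembles of 10^4 short trajectories (for the
Landau-Zener validation) affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HBAR_EV_FS, HARTREE_EV
from .vibronic import (
    VibronicModel,
    soc_matrix,
    spinfree_hamiltonian_batch,
)

__all__ = [
    "InitialCondition",
    "EnsembleSpec",
    "Ensemble",
    "Trajectory",
    "wigner_sample",
    "select_initial_state",
    "electronic_step",
    "hop_decision",
    "decoherence_correct",
    "spinfree_class_weights",
    "run_trajectory",
    "run_ensemble",
    "OverlapDiagnosticsError",
]

DEFAULT_DECOHERENCE_C = 0.1 * HARTREE_EV  # eV; the customary 0.1 hartree
ENERGY_DRIFT_LIMIT = 0.1  # eV; beyond this a trajectory is flagged invalid


class OverlapDiagnosticsError(RuntimeError):
    """Raised when the step overlap matrix is near-singular, i.e. a
    state flip between steps went undetected."""


@dataclass(frozen=True)
class InitialCondition:
    q: np.ndarray
    p: np.ndarray
    initial_state: str  # spin-free diabatic state label


@dataclass(frozen=True)
class EnsembleSpec:
    n_traj: int
    t_max: float = 1000.0  # fs
    dt_nuclear: float = 0.5  # fs
    dt_electronic: float = 0.02  # fs
    seed: int = 0
    decoherence_C: float | None = DEFAULT_DECOHERENCE_C  # eV; None disables

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        ratio = self.dt_nuclear / self.dt_electronic
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                "dt_nuclear / dt_electronic must be a positive integer"
            )

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt_nuclear / self.dt_electronic))


# -- sampling -------------------------------------------------------------


def wigner_sample(
    model: VibronicModel, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` phase-space points from the ground-state harmonic
    Wigner distribution: independent Gaussians with mean 0 and variance
    1/2 per mode in both q and p.  Bit-reproducible under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(0.5)
    q = rng.normal(0.0, scale, size=(n, model.n_modes))
    p = rng.normal(0.0, scale, size=(n, model.n_modes))
    return q, p


def _singlet_excitations(model: VibronicModel, Q: np.ndarray):
    """Adiabatic spin-free singlet excitation energies and the dominant
    diabatic character of each excited adiabat, per geometry."""
    H, _ = spinfree_hamiltonian_batch(model, Q)
    sing = np.asarray(
        [i for i, s in enumerate(model.states) if s.multiplicity == 1]
    )
    sub = H[..., sing[:, None], sing[None, :]]
    w, v = np.linalg.eigh(sub)
    exc = w[..., 1:] - w[..., :1]  # energy above the lowest singlet adiabat
    char = sing[np.argmax(np.abs(v[..., :, 1:]) ** 2, axis=-2)]
    return exc, char


def select_initial_state(
    model: VibronicModel,
    sample: tuple[np.ndarray, np.ndarray],
    excitation_window: tuple[float, float],
    seed: int,
    state_weights: dict[str, float] | None = None,
) -> list[tuple[int, str]]:
    """Pick initial electronic states for sampled geometries.

    For each geometry, the excited singlet adiabats whose vertical
    excitation energy falls inside ``excitation_window`` are candidates;
    the sample is accepted with probability proportional to the summed
    oscillator-strength surrogate weights (capped at 1) and the state is
    then chosen with probability proportional to its weight.  Returns
    ``(sample_index, diabatic_label)`` pairs for the accepted samples.
    """
    lo, hi = excitation_window
    if hi <= lo:
        raise ValueError("excitation window must have positive width")
    q, _ = sample
    q = np.atleast_2d(q)
    if state_weights is None:
        state_weights = {
            s.label: 1.0 for s in model.states if s.multiplicity == 1 and s.energy > 0
        }
    exc, char = _singlet_excitations(model, q)
    rng = np.random.default_rng(seed)
    accepted: list[tuple[int, str]] = []
    for i in range(q.shape[0]):
        cands = []
        for k in range(exc.shape[1]):
            label = model.states[char[i, k]].label
            w = state_weights.get(label, 0.0)
            if lo <= exc[i, k] <= hi and w > 0:
                cands.append((label, w))
        if not cands:
            continue
        total = sum(w for _, w in cands)
        if rng.random() > min(total, 1.0):
            continue
        u = rng.random() * total
        acc = 0.0
        for label, w in cands:
            acc += w
            if u <= acc:
                accepted.append((i, label))
                break
    return accepted


# -- electronic propagation ----------------------------------------------


def lowdin_orthonormalize(S: np.ndarray) -> np.ndarray:
    """Closest unitary to ``S`` (batched): U Sigma V^dag -> U V^dag.

    When ``S`` is already unitary to rounding (the usual case here,
    being a product of eigenvector matrices) the SVD is skipped.
    """
    St = np.conj(np.swapaxes(S, -1, -2))
    eye = np.eye(S.shape[-1])
    if np.abs(St @ S - eye).max() < 1e-10:
        return S
    u, _, vh = np.linalg.svd(S)
    return u @ vh


def _expm2(H: np.ndarray, dt: float) -> np.ndarray:
    """exp(-i H dt / hbar) for batched 2x2 Hermitian ``H`` via the Pauli
    closed form (exact, no diagonalization)."""
    a0 = 0.5 * (H[..., 0, 0] + H[..., 1, 1]).real
    bz = 0.5 * (H[..., 0, 0] - H[..., 1, 1]).real
    boff = H[..., 0, 1]  # = bx - i by
    bnorm = np.sqrt(bz**2 + np.abs(boff) ** 2)
    theta = bnorm * dt / HBAR_EV_FS
    cos = np.cos(theta)
    sinc = np.where(bnorm > 0, np.sin(theta) / np.maximum(bnorm, 1e-300), dt / HBAR_EV_FS)
    phase = np.exp(-1j * a0 * dt / HBAR_EV_FS)
    out = np.empty(H.shape, dtype=complex)
    out[..., 0, 0] = phase * (cos - 1j * sinc * bz)
    out[..., 0, 1] = phase * (-1j * sinc * boff)
    out[..., 1, 0] = phase * (-1j * sinc * np.conj(boff))
    out[..., 1, 1] = phase * (cos + 1j * sinc * bz)
    return out


def electronic_step(
    c: np.ndarray,
    H1: np.ndarray,
    H2: np.ndarray,
    overlap: np.ndarray,
    dt: float,
    n_substeps: int,
    check_determinant: bool = True,
    return_propagator: bool = False,
):
    """Local-diabatization propagation of electronic coefficients over
    one nuclear step.

    ``H1``/``H2`` are the Hamiltonians in the running representation at
    the step's start and end and ``overlap`` the eigenbasis overlap
    matrix between the two geometries.  The overlap is Loewdin-
    orthonormalized, the end-point Hamiltonian transformed into the
    frozen (locally diabatic) basis, and the Schroedinger equation
    integrated in ``n_substeps`` midpoint exponentials of the linearly
    interpolated Hamiltonian; finally the coefficients are rotated into
    the new basis.  The scheme is exactly norm-conserving.  All
    arguments may carry leading batch dimensions.  With
    ``return_propagator=True`` the unitary step propagator R (such that
    c_new = R c_old) is returned alongside, for the hopping formula.
    """
    S = lowdin_orthonormalize(np.asarray(overlap, dtype=complex))
    if check_determinant:
        det = np.abs(np.linalg.det(overlap))
        if np.any(det < 1e-3):
            raise OverlapDiagnosticsError(
                f"near-singular step overlap (min |det| = {det.min():.2e}); "
                "a state flip between steps was probably missed"
            )
    H1 = np.asarray(H1, dtype=complex)
    M = S @ np.asarray(H2, dtype=complex) @ np.conj(np.swapaxes(S, -1, -2))
    dt_sub = dt / n_substeps
    two_level = H1.shape[-1] == 2
    Z = np.broadcast_to(
        np.eye(H1.shape[-1], dtype=complex), H1.shape
    ).copy()
    for k in range(n_substeps):
        x = (k + 0.5) / n_substeps
        H = (1.0 - x) * H1 + x * M
        if two_level:
            Z = _expm2(H, dt_sub) @ Z
        else:
            w, v = np.linalg.eigh(H)
            phase = np.exp(-1j * w * dt_sub / HBAR_EV_FS)
            expH = np.einsum("...ij,...j,...kj->...ik", v, phase, np.conj(v))
            Z = expH @ Z
    R = np.conj(np.swapaxes(S, -1, -2)) @ Z
    c_new = np.einsum("...ij,...j->...i", R, np.asarray(c, dtype=complex))
    if return_propagator:
        return c_new, R
    return c_new


def hop_decision(
    active_old: np.ndarray,
    active_new: np.ndarray,
    c_old: np.ndarray,
    c_new: np.ndarray,
    R: np.ndarray,
    u: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fewest-switches hopping probabilities over one nuclear step, in
    the propagator-resolved (flux-partition) form used with local
    diabatization.

    ``c_old`` lives in the eigenbasis at the step's start (active index
    ``active_old``), ``c_new`` in the eigenbasis at its end (the same
    physical surface carries the overlap-tracked index ``active_new``),
    and ``R`` is the full step propagator, c_new = R c_old.  The
    probability of leaving the active state a is its fractional
    population loss 1 - |c_a(t+dt)|^2/|c_a(t)|^2; it is distributed over
    target states k in proportion to the interference terms
    Re[c_k*(t+dt) R_ka c_a(t)], which resolve how much of the loss
    actually flowed into each k (the denominator
    |c_a(t)|^2 - Re[c_a*(t+dt) R_aa c_a(t)] normalises the partition).
    Negative contributions are clipped, so every probability lies in
    [0, 1] and their sum is at most 1.  ``u`` holds one uniform variate
    per trajectory; the returned target equals ``active_new`` where no
    hop is drawn.  Stationary populations give all-zero probabilities; a
    monotonic transfer into a single target receives exactly the
    fractional population loss.
    """
    B, n = c_old.shape
    idx = np.arange(B)
    ca_old = c_old[idx, active_old]
    p_old = np.abs(ca_old) ** 2
    p_new = np.abs(c_new[idx, active_new]) ** 2
    loss = np.clip(1.0 - p_new / np.maximum(p_old, 1e-300), 0.0, 1.0)
    flow = (np.conj(c_new) * R[idx, :, active_old] * ca_old[:, None]).real
    flow = np.clip(flow, 0.0, None)
    flow[idx, active_new] = 0.0
    den = p_old - (
        np.conj(c_new[idx, active_new]) * R[idx, active_new, active_old] * ca_old
    ).real
    total = flow.sum(axis=1)
    norm = np.where(den > 1e-300, den, np.maximum(total, 1e-300))
    probs = loss[:, None] * flow / np.maximum(norm, 1e-300)[:, None]
    probs = np.clip(probs, 0.0, 1.0)
    # the partition may not exceed the total leaving probability
    scale = np.minimum(1.0, loss / np.maximum(probs.sum(axis=1), 1e-300))
    probs = probs * scale[:, None]
    cum = np.cumsum(probs, axis=1)
    target = active_new.copy()
    hop = u[:, None] < cum
    has_hop = hop.any(axis=1)
    target[has_hop] = np.argmax(hop[has_hop], axis=1)
    return probs, target


def decoherence_correct(
    c: np.ndarray,
    energies: np.ndarray,
    active: np.ndarray,
    kinetic_energy: np.ndarray,
    dt: float,
    C: float,
) -> np.ndarray:
    """Energy-based decoherence: damp every non-active amplitude with
    time constant tau_k = hbar/|E_k - E_active| * (1 + C/E_kin) and
    rescale the active amplitude to restore unit norm.  A vanishing gap
    means no damping for that state."""
    B, n = c.shape
    idx = np.arange(B)
    gap = np.abs(energies - energies[idx, active][:, None])
    ekin = np.maximum(kinetic_energy, 1e-12)[:, None]
    with np.errstate(divide="ignore"):
        rate = gap / (HBAR_EV_FS * (1.0 + C / ekin))
    damp = np.exp(-dt * rate)
    out = c * damp
    out[idx, active] = c[idx, active]
    p_act = np.abs(c[idx, active]) ** 2
    p_other = (np.abs(out) ** 2).sum(axis=1) - p_act
    scale = np.sqrt(np.maximum(1.0 - p_other, 0.0) / np.maximum(p_act, 1e-300))
    out[idx, active] = c[idx, active] * scale
    return out


# -- the propagator -------------------------------------------------------


def _expand_batch(model: VibronicModel, A: np.ndarray) -> np.ndarray:
    """Expand (..., n_el, n_el) electronic matrices to the spin basis."""
    exp = model.spin_expansion()
    out = A[..., exp[:, None], exp[None, :]].copy()
    mult = model.multiplicity_of_dim()
    sub = np.zeros(model.n_dim, dtype=int)
    k = model.n_singlets
    for s in model.states:
        if s.multiplicity == 3:
            sub[k : k + 3] = [0, 1, 2]
            k += 3
    bad = (mult[:, None] == 3) & (mult[None, :] == 3) & (sub[:, None] != sub[None, :])
    out[..., bad] = 0.0
    return out


def spinfree_class_weights(model: VibronicModel, H_el: np.ndarray, u: np.ndarray):
    """Weights |<spin-free adiabat | u>|^2 of diagonal-state vectors,
    with triplet sublevels pooled, plus the class energies.

    Classes are ordered [S0..S_{ns-1}, T1..T_{nt}] by energy within each
    multiplicity block at the given geometry.
    """
    sing = np.asarray([i for i, s in enumerate(model.states) if s.multiplicity == 1])
    trip = np.asarray([i for i, s in enumerate(model.states) if s.multiplicity == 3])
    ns, nt = len(sing), len(trip)
    B = H_el.shape[0]
    weights = np.zeros((B, ns + nt))
    Hs = H_el[..., sing[:, None], sing[None, :]]
    ws, vs = np.linalg.eigh(Hs)
    # singlet components of u sit first in the expanded basis
    u_s = u[..., :ns]
    amp = np.einsum("...ps,...p->...s", np.conj(vs), u_s)
    weights[:, :ns] = np.abs(amp) ** 2
    if nt:
        Ht = H_el[..., trip[:, None], trip[None, :]]
        wt, vt = np.linalg.eigh(Ht)
        u_t = u[..., ns:].reshape(B, nt, 3)
        amp_t = np.einsum("...ps,...pm->...sm", np.conj(vt), u_t)
        weights[:, ns:] = (np.abs(amp_t) ** 2).sum(axis=-1)
    return weights


@dataclass
class Ensemble:
    """Lock-step trajectory ensemble with per-step logs.

    Arrays are indexed (trajectory, time, ...); ``class_index`` holds
    the spin-free class (energetic ordering, triplet sublevels pooled)
    assigned to the active diagonal state at each step.
    """

    model: VibronicModel
    spec: EnsembleSpec
    times: np.ndarray  # (T,)
    q: np.ndarray  # (B, T, n_modes)
    p: np.ndarray  # (B, T, n_modes)
    active: np.ndarray  # (B, T) diagonal-state index
    coeff_pops: np.ndarray  # (B, T, n_dim)
    class_index: np.ndarray  # (B, T)
    class_labels: list[str]
    total_energy: np.ndarray  # (B, T) eV
    active_energy: np.ndarray  # (B, T) eV
    n_frustrated: np.ndarray  # (B,)
    n_hops: np.ndarray  # (B,)
    invalid: np.ndarray  # (B,) bool: energy drift beyond the limit
    max_norm_error: float = 0.0
    max_drift_between_hops: np.ndarray | None = None  # (B,) eV
    n_class_ties: int = 0
    initial_labels: list[str] = field(default_factory=list)

    @property
    def n_traj(self) -> int:
        return self.active.shape[0]

    def trajectory(self, i: int) -> "Trajectory":
        return Trajectory(self, i)


class Trajectory:
    """A single-trajectory view into an :class:`Ensemble`."""

    def __init__(self, ensemble: Ensemble, index: int = 0):
        self._e = ensemble
        self._i = index

    def __getattr__(self, name):
        val = getattr(self._e, name)
        if isinstance(val, np.ndarray) and val.ndim >= 1 and val.shape[0] == self._e.n_traj:
            return val[self._i]
        return val


def _class_labels(model: VibronicModel) -> list[str]:
    ns = model.n_singlets
    nt = model.n_triplets
    return [f"S{i}" for i in range(ns)] + [f"T{i + 1}" for i in range(nt)]


def _initial_electronic(model, H_el, Hs_soc, labels):
    """Diagonal-basis energies/vectors plus initial coefficients and
    active states for requested diabatic start labels."""
    exp_H = _expand_batch(model, H_el).astype(complex) + Hs_soc
    E, U = np.linalg.eigh(exp_H)
    B = H_el.shape[0]
    n = model.n_dim
    psi = np.zeros((B, n), dtype=complex)
    sing = [i for i, s in enumerate(model.states) if s.multiplicity == 1]
    trip = [i for i, s in enumerate(model.states) if s.multiplicity == 3]
    for b, label in enumerate(labels):
        el = model.state_index(label)
        s = model.state(label)
        if s.multiplicity == 1:
            block = np.asarray(sing)
            sub = H_el[b][np.ix_(block, block)]
            w, v = np.linalg.eigh(sub)
            pos = int(np.where(block == el)[0][0])
            k = int(np.argmax(np.abs(v[pos]) ** 2))
            psi[b, : len(sing)] = v[:, k]
        else:
            block = np.asarray(trip)
            sub = H_el[b][np.ix_(block, block)]
            w, v = np.linalg.eigh(sub)
            pos = int(np.where(block == el)[0][0])
            k = int(np.argmax(np.abs(v[pos]) ** 2))
            # put the whole amplitude in the ms = 0 sublevel
            vec = np.zeros((len(trip), 3), dtype=complex)
            vec[:, 1] = v[:, k]
            psi[b, len(sing):] = vec.reshape(-1)
    c = np.einsum("bji,bj->bi", np.conj(U), psi)
    active = np.argmax(np.abs(c) ** 2, axis=1)
    return E, U, c, active


def run_ensemble(
    model: VibronicModel,
    spec: EnsembleSpec,
    excitation_window: tuple[float, float] | None = None,
    initial_state: str | None = None,
    state_weights: dict[str, float] | None = None,
    initial_conditions: list[InitialCondition] | None = None,
    check_overlap: bool = False,
) -> Ensemble:
    """Propagate a surface-hopping ensemble.

    Initial conditions come either from ``initial_conditions`` (explicit
    list, e.g. for scattering setups) or from Wigner sampling with the
    start state fixed by ``initial_state`` or chosen per geometry via
    ``excitation_window``/``state_weights``.  Trajectory ``i`` consumes
    the dedicated random stream ``spec.seed + i`` for its hopping
    decisions, so ensembles are reproducible and single trajectories
    coincide with ensemble members.  Trajectories whose total energy
    drifts by more than 0.1 eV from the value at the last hop are
    flagged invalid; an ensemble with more than 20% invalid
    trajectories raises.
    """
    B = spec.n_traj
    m = model.n_modes
    if initial_conditions is not None:
        if len(initial_conditions) != B:
            raise ValueError("need one InitialCondition per trajectory")
        Q = np.array([ic.q for ic in initial_conditions], dtype=float)
        P = np.array([ic.p for ic in initial_conditions], dtype=float)
        labels = [ic.initial_state for ic in initial_conditions]
    else:
        q_all, p_all = wigner_sample(model, max(4 * B, B), spec.seed)
        if initial_state is not None:
            Q, P = q_all[:B], p_all[:B]
            labels = [initial_state] * B
        else:
            if excitation_window is None:
                raise ValueError(
                    "provide initial_state, excitation_window or explicit "
                    "initial_conditions"
                )
            pairs = select_initial_state(
                model, (q_all, p_all), excitation_window, spec.seed, state_weights
            )
            if len(pairs) < B:
                raise ValueError(
                    f"only {len(pairs)} of {q_all.shape[0]} sampled geometries "
                    "were accepted; widen the window or sample more"
                )
            pairs = pairs[:B]
            Q = q_all[[i for i, _ in pairs]]
            P = p_all[[i for i, _ in pairs]]
            labels = [lab for _, lab in pairs]

    omega = model.frequencies
    mass = HBAR_EV_FS**2 / omega  # so that T = 1/2 m v^2 with v = omega p / hbar
    V = omega * P / HBAR_EV_FS
    dt = spec.dt_nuclear
    n_steps = int(round(spec.t_max / dt))
    times = np.arange(n_steps + 1) * dt
    n = model.n_dim
    Hsoc = soc_matrix(model)

    # per-trajectory hop random streams (seed + i), one draw per step
    u_hop = np.empty((B, n_steps))
    for i in range(B):
        u_hop[i] = np.random.default_rng(spec.seed + i).random(n_steps)

    H_el, grad_el = spinfree_hamiltonian_batch(model, Q)
    E, U, c, active = _initial_electronic(model, H_el, Hsoc, labels)

    idxB = np.arange(B)

    def diag_grad(grad_el, U, act):
        G = _expand_batch(model, grad_el)  # (B, m, n, n)
        u_act = U[idxB, :, act]  # (B, n)
        g = np.einsum("bp,bipq,bq->bi", np.conj(u_act), G, u_act)
        return g.real

    g = diag_grad(grad_el, U, active)
    accel = -g / mass

    # logs
    log_q = np.empty((B, n_steps + 1, m))
    log_p = np.empty((B, n_steps + 1, m))
    log_active = np.empty((B, n_steps + 1), dtype=int)
    log_pops = np.empty((B, n_steps + 1, n))
    log_cls = np.empty((B, n_steps + 1), dtype=int)
    log_E = np.empty((B, n_steps + 1))
    log_Eact = np.empty((B, n_steps + 1))
    n_frustrated = np.zeros(B, dtype=int)
    n_hops = np.zeros(B, dtype=int)
    max_norm_err = 0.0
    n_ties = 0

    def kinetic(V):
        return 0.5 * (mass * V**2).sum(axis=1)

    def log_step(j, Q, V, active, c, E, H_el):
        log_q[:, j] = Q
        log_p[:, j] = HBAR_EV_FS * V / omega
        log_active[:, j] = active
        log_pops[:, j] = np.abs(c) ** 2
        u_act = U[idxB, :, active]
        w = spinfree_class_weights(model, H_el, u_act)
        top2 = np.sort(w, axis=1)[:, -2:]
        nonlocal n_ties
        if w.shape[1] > 1:
            n_ties += int(((top2[:, 1] - top2[:, 0]) < 1e-6).sum())
        log_cls[:, j] = np.argmax(w, axis=1)
        e_act = E[idxB, active]
        log_Eact[:, j] = e_act
        log_E[:, j] = kinetic(V) + e_act

    log_step(0, Q, V, active, c, E, H_el)
    e_ref = log_E[:, 0].copy()  # total energy at the last accepted hop
    max_drift = np.zeros(B)

    for step in range(n_steps):
        V_half = V + 0.5 * dt * accel
        Q_new = Q + dt * V_half
        H_el_n, grad_el_n = spinfree_hamiltonian_batch(model, Q_new)
        Hs_n = _expand_batch(model, H_el_n).astype(complex) + Hsoc
        E_n, U_n = np.linalg.eigh(Hs_n)
        S = np.conj(np.swapaxes(U, -1, -2)) @ U_n
        # follow the active surface through trivial crossings
        track = np.argmax(np.abs(S[idxB, active, :]) ** 2, axis=1)

        c_new, R = electronic_step(
            c, np.zeros((B, n, n)) + E[:, :, None] * np.eye(n),
            np.zeros((B, n, n)) + E_n[:, :, None] * np.eye(n),
            S, dt, spec.n_substeps, check_determinant=check_overlap,
            return_propagator=True,
        )
        max_norm_err = max(
            max_norm_err,
            float(np.abs((np.abs(c_new) ** 2).sum(axis=1) - 1.0).max()),
        )

        # the active surface's identity at the new geometry is the
        # overlap-tracked index; the hopping flux is resolved through the
        # step propagator, so basis reorderings cause no spurious hops
        _, target = hop_decision(active, track, c, c_new, R, u_hop[:, step])

        g_new = diag_grad(grad_el_n, U_n, track)
        V_new = V_half + 0.5 * dt * (-g_new / mass)

        wants_hop = target != track
        if wants_hop.any():
            ekin = kinetic(V_new)
            e_from = E_n[idxB, track]
            e_to = E_n[idxB, target]
            avail = ekin + e_from - e_to
            ok = wants_hop & (avail >= 0.0)
            frustrated = wants_hop & ~ok
            n_frustrated += frustrated.astype(int)
            if ok.any():
                scale = np.ones(B)
                scale[ok] = np.sqrt(avail[ok] / np.maximum(ekin[ok], 1e-300))
                V_new = V_new * scale[:, None]
                track = np.where(ok, target, track)
                n_hops += ok.astype(int)
                g_new2 = diag_grad(grad_el_n, U_n, track)
                g_new = np.where(ok[:, None], g_new2, g_new)
                e_ref = np.where(
                    ok, kinetic(V_new) + E_n[idxB, track], e_ref
                )

        if spec.decoherence_C is not None:
            c_new = decoherence_correct(
                c_new, E_n, track, kinetic(V_new), dt, spec.decoherence_C
            )

        # the energy reference resets at every active-surface identity
        # change: accepted hops conserve energy by construction of the
        # rescaling, while a diabatic relabel through a narrow avoided
        # crossing legitimately shifts the total by the local gap (the
        # trivial-crossing problem); in between, drift is integrator error
        changed = track != active
        Q, V, accel = Q_new, V_new, -g_new / mass
        H_el, E, U, c, active = H_el_n, E_n, U_n, c_new, track
        log_step(step + 1, Q, V, active, c, E, H_el)
        drift = np.abs(log_E[:, step + 1] - e_ref)
        max_drift = np.maximum(max_drift, np.where(changed, 0.0, drift))
        e_ref = np.where(changed, log_E[:, step + 1], e_ref)

    finite = np.isfinite(log_E).all(axis=1) & np.isfinite(max_drift)
    invalid = ~finite | (max_drift > ENERGY_DRIFT_LIMIT)
    ens = Ensemble(
        model=model,
        spec=spec,
        times=times,
        q=log_q,
        p=log_p,
        active=log_active,
        coeff_pops=log_pops,
        class_index=log_cls,
        class_labels=_class_labels(model),
        total_energy=log_E,
        active_energy=log_Eact,
        n_frustrated=n_frustrated,
        n_hops=n_hops,
        invalid=invalid,
        max_norm_error=max_norm_err,
        max_drift_between_hops=max_drift,
        n_class_ties=n_ties,
        initial_labels=list(labels),
    )
    if invalid.mean() > 0.2:
        raise RuntimeError(
            f"{invalid.sum()} of {B} trajectories exceeded the "
            f"{ENERGY_DRIFT_LIMIT} eV energy-drift limit"
        )
    return ens


def run_trajectory(
    model: VibronicModel, ic: InitialCondition, spec: EnsembleSpec
) -> Trajectory:
    """Propagate a single trajectory (an ensemble of one)."""
    one = EnsembleSpec(
        n_traj=1,
        t_max=spec.t_max,
        dt_nuclear=spec.dt_nuclear,
        dt_electronic=spec.dt_electronic,
        seed=spec.seed,
        decoherence_C=spec.decoherence_C,
    )
    ens = run_ensemble(model, one, initial_conditions=[ic])
    return ens.trajectory(0)
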