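"""Electronic-state populations, lifetimes, and the kinetic-scheme surrogate.

Surface-hopping ensembles are analysed in the spin-free basis: at every
step the active diagonal state is assigned to the spin-free class
(S0, S1, ..., T1, T2, ... in energetic order, triplet sublevels pooled)
with the largest eigenvector weight, and class fractions are averaged
over trajectories.  Lifetimes come from (delayed) monoexponential fits
with bootstrap confidence intervals over trajectories.  The same
containers also serve a continuous-time Markov surrogate of the
three-step relaxation scheme S2 -> S1 -> {T2, T1} -> T1, simulated
exactly (event-driven) and solved deterministically through the master
equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "PopulationSeries",
    "JumpEnsemble",
    "LifetimeFit",
    "classify_populations",
    "fit_population_decay",
    "markov_scheme",
    "simulate_jump_ensemble",
    "master_equation",
    "triplet_yield",
    "write_population_series",
    "read_population_series",
]


@dataclass
class PopulationSeries:
    """Class populations vs time, plus (optionally) the per-trajectory
    class occupancy that generated them (needed for bootstrapping)."""

    times: np.ndarray  # fs, (T,)
    populations: np.ndarray  # (n_classes, T), columns sum to 1
    class_labels: list[str]
    n_traj: int
    trajectory_classes: np.ndarray | None = None  # (n_traj, T) int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        if self.populations.shape != (len(self.class_labels), self.times.size):
            raise ValueError("populations shape must be (n_classes, n_times)")

    def population(self, label: str) -> np.ndarray:
        return self.populations[self.class_labels.index(label)]


@dataclass
class JumpEnsemble:
    """Event-driven jump trajectories on a discrete state graph."""

    states: list[str]
    # per trajectory: list of (time fs, state index) starting with (0, s0)
    jumps: list[list[tuple[float, int]]]
    t_max: float

    @property
    def n_traj(self) -> int:
        return len(self.jumps)

    def occupancy(self, times: np.ndarray) -> np.ndarray:
        """State index of every trajectory at each requested time."""
        times = np.asarray(times, dtype=float)
        out = np.empty((self.n_traj, times.size), dtype=int)
        for i, traj in enumerate(self.jumps):
            jt = np.asarray([t for t, _ in traj])
            js = np.asarray([s for _, s in traj])
            pos = np.searchsorted(jt, times, side="right") - 1
            out[i] = js[np.clip(pos, 0, len(js) - 1)]
        return out


@dataclass
class LifetimeFit:
    tau: float  # fs
    t_delay: float  # fs
    amplitude: float
    ci_95: tuple[float, float] | None = None  # bootstrap over trajectories


def classify_populations(
    ensemble,
    times: np.ndarray | None = None,
    merge: dict[str, str] | None = None,
) -> PopulationSeries:
    """Class fractions over time for a surface-hopping
    :class:`~thiodyn.dynamics.Ensemble` or a :class:`JumpEnsemble`.

    For hopping ensembles the per-step class assignment (largest
    spin-free weight of the active diagonal state, deterministic
    tie-break towards the lower class index) was recorded during
    propagation; here the indicator fractions are averaged over
    trajectories.  ``merge`` folds classes together (e.g. a short-lived
    S3 merged into S2) before averaging.
    """
    if isinstance(ensemble, JumpEnsemble):
        if times is None:
            raise ValueError("a time grid is required for a JumpEnsemble")
        cls = ensemble.occupancy(times)
        labels = list(ensemble.states)
        t = np.asarray(times, dtype=float)
    else:
        t = ensemble.times if times is None else np.asarray(times)
        if times is None:
            cls = ensemble.class_index
        else:
            pos = np.searchsorted(ensemble.times, t)
            if not np.allclose(ensemble.times[pos], t):
                raise ValueError("all trajectories must share the time grid")
            cls = ensemble.class_index[:, pos]
        labels = list(ensemble.class_labels)
    if merge:
        remap = np.arange(len(labels))
        for src, dst in merge.items():
            remap[labels.index(src)] = labels.index(dst)
        cls = remap[cls]
        keep = sorted(set(remap.tolist()))
        cls = np.searchsorted(keep, cls)
        labels = [labels[k] for k in keep]
    n_cls = len(labels)
    pops = np.stack([(cls == k).mean(axis=0) for k in range(n_cls)])
    return PopulationSeries(t, pops, labels, cls.shape[0], trajectory_classes=cls)


def _exp_model(theta, t, kind):
    A, td, tau = theta
    x = np.maximum(t - td, 0.0) / tau
    decay = A * np.exp(-x)
    return decay if kind == "decay" else A - decay


def _fit_exp(t, p, kind, delayed):
    A0 = float(p.max()) if kind == "decay" else float(p[-1])
    A0 = max(A0, 1e-6)
    # crude 1/e crossing for the initial lifetime
    ref = A0 / np.e
    series = p if kind == "decay" else A0 - p
    below = np.nonzero(series < ref)[0]
    tau0 = float(t[below[0]]) if below.size else float(t[-1] / 2)
    tau0 = max(tau0, float(t[1] - t[0]))
    x0 = np.array([A0, 0.0, tau0])
    lo = np.array([0.0, 0.0, 1e-3])
    hi = np.array([1.5, t[-1] / 2 if delayed else 1e-9, np.inf])
    x0 = np.clip(x0, lo, hi if delayed else [1.5, 0.0, np.inf])

    def resid(theta):
        return _exp_model(theta, t, kind) - p

    sol = optimize.least_squares(resid, x0, bounds=(lo, np.maximum(hi, lo + 1e-12)))
    return sol.x


def fit_population_decay(
    series: PopulationSeries,
    class_label: str,
    kind: str = "decay",
    delayed: bool = True,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> LifetimeFit:
    """Monoexponential lifetime of one population class.

    Fits p(t) = A exp(-max(t - t_d, 0)/tau) (``kind="decay"``) or its
    complement A (1 - exp(...)) (``kind="rise"``) by least squares; the
    onset t_d can be frozen at zero with ``delayed=False``.  When the
    series carries per-trajectory occupancies, a seeded bootstrap over
    trajectories (default 200 resamples) yields a 95% confidence
    interval on tau.
    """
    if kind not in ("decay", "rise"):
        raise ValueError("kind must be 'decay' or 'rise'")
    p = series.population(class_label)
    if p.max() <= 0:
        raise ValueError(f"population of class {class_label} is identically zero")
    if np.ptp(p) < 1e-12:
        raise ValueError(f"population of class {class_label} is flat; tau is not identifiable")
    t = series.times
    A, td, tau = _fit_exp(t, p, kind, delayed)

    ci = None
    if series.trajectory_classes is not None and n_bootstrap > 0:
        k = series.class_labels.index(class_label)
        ind = (series.trajectory_classes == k).astype(float)
        rng = np.random.default_rng(seed)
        B = ind.shape[0]
        taus = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.integers(0, B, size=B)
            pb = ind[pick].mean(axis=0)
            try:
                taus[b] = _fit_exp(t, pb, kind, delayed)[2]
            except Exception:
                taus[b] = np.nan
        taus = taus[np.isfinite(taus)]
        if taus.size >= 10:
            ci = (
                float(np.percentile(taus, 2.5)),
                float(np.percentile(taus, 97.5)),
            )
    return LifetimeFit(tau=float(tau), t_delay=float(td), amplitude=float(A), ci_95=ci)


# -- Markov surrogate -----------------------------------------------------


def _normalize_rates(rates) -> tuple[list[str], list[tuple[int, int, float]]]:
    """Accept {(src, dst): rate} or [(src, dst, rate)]; preserve order."""
    triples = []
    if isinstance(rates, dict):
        items = [(a, b, r) for (a, b), r in rates.items()]
    else:
        items = [tuple(x) for x in rates]
    states: list[str] = []
    for a, b, r in items:
        if r < 0:
            raise ValueError(f"rate {a}->{b} is negative")
        for s in (a, b):
            if s not in states:
                states.append(s)
    for a, b, r in items:
        triples.append((states.index(a), states.index(b), float(r)))
    return states, triples


def simulate_jump_ensemble(
    rates, n_traj: int, t_max: float, seed: int, initial_state: str | None = None
) -> JumpEnsemble:
    """Exact (event-driven) stochastic simulation of the rate graph:
    exponential waiting times, branching by rate ratio."""
    states, triples = _normalize_rates(rates)
    s0 = states.index(initial_state) if initial_state is not None else 0
    out_rates: list[list[tuple[int, float]]] = [[] for _ in states]
    for a, b, r in triples:
        if r > 0:
            out_rates[a].append((b, r))
    rng = np.random.default_rng(seed)
    jumps = []
    for _ in range(n_traj):
        t = 0.0
        s = s0
        traj = [(0.0, s)]
        while out_rates[s]:
            total = sum(r for _, r in out_rates[s])
            t += rng.exponential(1.0 / total)
            if t >= t_max:
                break
            u = rng.random() * total
            acc = 0.0
            for dst, r in out_rates[s]:
                acc += r
                if u <= acc:
                    s = dst
                    break
            traj.append((t, s))
        jumps.append(traj)
    return JumpEnsemble(states, jumps, t_max)


def master_equation(
    rates, times: np.ndarray, initial_state: str | None = None
) -> PopulationSeries:
    """Deterministic solution dp/dt = K p on a uniform grid, via the
    matrix exponential of the generator over one grid spacing."""
    states, triples = _normalize_rates(rates)
    n = len(states)
    K = np.zeros((n, n))
    for a, b, r in triples:
        K[b, a] += r
        K[a, a] -= r
    times = np.asarray(times, dtype=float)
    dts = np.diff(times)
    if dts.size and np.ptp(dts) > 1e-9:
        raise ValueError("master_equation expects a uniform time grid")
    p = np.zeros(n)
    p[states.index(initial_state) if initial_state is not None else 0] = 1.0
    pops = np.empty((n, times.size))
    pops[:, 0] = p
    if dts.size:
        P = linalg.expm(K * dts[0])
        for j in range(1, times.size):
            p = P @ p
            pops[:, j] = p
    return PopulationSeries(times, pops, states, n_traj=0)


def markov_scheme(
    rates,
    n_traj: int,
    t_max: float,
    seed: int,
    grid_dt: float = 5.0,
    initial_state: str | None = None,
) -> tuple[PopulationSeries, PopulationSeries]:
    """Stochastic and deterministic solutions of a kinetic scheme.

    Returns ``(stochastic, deterministic)`` population series on the
    same uniform grid; the stochastic one carries per-trajectory
    occupancies for bootstrapping.  All-zero rates simply freeze the
    initial populations.
    """
    times = np.arange(0.0, t_max + grid_dt / 2, grid_dt)
    ens = simulate_jump_ensemble(rates, n_traj, t_max, seed, initial_state)
    stoch = classify_populations(ens, times)
    det = master_equation(rates, times, initial_state)
    return stoch, det


def triplet_yield(series: PopulationSeries, t: float) -> float:
    """Total triplet population p_T1 + p_T2 + ... at time ``t`` (nearest
    grid point; ``t`` must lie inside the grid)."""
    if not (series.times[0] <= t <= series.times[-1]):
        raise ValueError(f"t = {t} fs outside the population grid")
    j = int(np.argmin(np.abs(series.times - t)))
    total = 0.0
    for k, label in enumerate(series.class_labels):
        if label.startswith("T"):
            total += series.populations[k, j]
    return float(total)


def write_population_series(series: PopulationSeries, path) -> None:
    df = pd.DataFrame(series.populations.T, columns=series.class_labels)
    df.insert(0, "time_fs", series.times)
    df.to_csv(path, index=False, float_format="%.10g")


def read_population_series(path, n_traj: int = 0) -> PopulationSeries:
    df = pd.read_csv(path)
    labels = [c for c in df.columns if c != "time_fs"]
    return PopulationSeries(
        df["time_fs"].to_numpy(float),
        df[labels].to_numpy(float).T,
        labels,
        n_traj,
    )
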