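"""Environment-mediated consumer-resource model (ECRM) simulation.

The community obeys

    dx_i/dt = x_i ( sum_a G_ia R_a - d_x )
    dR_a/dt = K_a(t) - ( d_R + sum_i r_ia x_i ) R_a

with an explicitly time-dependent external supply K_a(t) that models
environmental fluctuations.  Two drive families are supported:

* sinusoidal, K_a(t) = K_a0 + A_a sin(w_a t - phi_a), the idealization of
  periodic forcing (diurnal cycles, feeding schedules);
* Ornstein-Uhlenbeck, K_a(t) = K_a0 + Q_a(t) with
  dQ_a/dt = -w_a Q_a + A_a w_a eta_a(t), a stochastic drive whose
  stationary variance is A_a^2 w_a / 2 and whose autocorrelation decays
  as exp(-w_a tau).

Abundance series are analyzed as log z scores,
s_i(t) = (log x_i(t) - mean) / sd, so only relative fluctuations matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from ._integrate import rk4_chunk
from ._rng import substream
from .network import ResourceNetwork

__all__ = [
    "DriveSpec",
    "SimParams",
    "Trajectory",
    "ZScoreSeries",
    "make_sinusoidal_drive",
    "make_ou_drive",
    "simulate",
    "sample_series",
    "log_zscore",
    "save_trajectory_tsv",
    "save_trajectory_hdf5",
    "load_trajectory_hdf5",
]


@dataclass(frozen=True)
class DriveSpec:
    """Per-resource supply fluctuation parameters.

    ``kind`` is "sinusoidal" or "ou".  All vectors have length M.  For OU
    drives ``frequency`` is the relaxation rate and ``seed`` selects the
    noise realization; ``phase`` is only meaningful for sinusoids.
    """

    kind: str
    base_supply: np.ndarray
    amplitude: np.ndarray
    frequency: np.ndarray
    phase: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoidal", "ou"):
            raise ValueError(f"unknown drive kind {self.kind!r}")
        for name in ("base_supply", "amplitude", "frequency"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        m = self.base_supply.shape[0]
        if self.amplitude.shape != (m,) or self.frequency.shape != (m,):
            raise ValueError("base_supply, amplitude, frequency must share length M")
        if np.any(self.base_supply < 0) or np.any(self.amplitude < 0):
            raise ValueError("base supply and amplitude must be non-negative")
        if np.any(self.frequency <= 0):
            raise ValueError("frequencies must be positive")
        if self.kind == "sinusoidal":
            phase = np.zeros(m) if self.phase is None else np.atleast_1d(np.asarray(self.phase, dtype=float))
            if phase.shape != (m,):
                raise ValueError("phase must have length M")
            object.__setattr__(self, "phase", phase)

    @property
    def n_resources(self) -> int:
        return self.base_supply.shape[0]

    @classmethod
    def sinusoidal(
        cls,
        n_resources: int,
        omega: float | tuple[float, float],
        base_supply: float = 1.0,
        amplitude: float | None = None,
        seed: int = 0,
    ) -> "DriveSpec":
        """Sinusoidal drive; scalar ``omega`` is shared, a (lo, hi) tuple
        samples per-resource frequencies log-uniformly on [lo, hi].
        Phases are uniform on [0, 2 pi).  Default amplitude is half the
        base supply."""
        rng = substream(seed, "drive", "sinusoidal")
        if np.isscalar(omega):
            freq = np.full(n_resources, float(omega))
        else:
            lo, hi = omega
            freq = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_resources))
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n_resources)
        amp = 0.5 * base_supply if amplitude is None else amplitude
        return cls(
            kind="sinusoidal",
            base_supply=np.full(n_resources, float(base_supply)),
            amplitude=np.full(n_resources, float(amp)),
            frequency=freq,
            phase=phase,
            seed=seed,
        )

    @classmethod
    def ou(
        cls,
        n_resources: int,
        omega: float = 1.0,
        base_supply: float = 1.0,
        amplitude: float | None = None,
        seed: int = 0,
    ) -> "DriveSpec":
        """Ornstein-Uhlenbeck drive with a common relaxation rate."""
        amp = 0.5 * base_supply if amplitude is None else amplitude
        return cls(
            kind="ou",
            base_supply=np.full(n_resources, float(base_supply)),
            amplitude=np.full(n_resources, float(amp)),
            frequency=np.full(n_resources, float(omega)),
            seed=seed,
        )


@dataclass(frozen=True)
class SimParams:
    """Integration and sampling parameters.

    ``burn_in`` defaults to ten species turnover times (10 / d_x), rounded
    up to the integrator grid, and is discarded before sampling.
    """

    t_final: float = 20000.0
    death_rate_species: float = 0.3
    depletion_rate_resource: float = 0.5
    integrator_step: float = 0.01
    burn_in: float | None = None
    sampling_interval: float = 1.0
    x0: np.ndarray | float = 1.0
    r0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.t_final <= 0 or self.integrator_step <= 0 or self.sampling_interval <= 0:
            raise ValueError("t_final, integrator_step, sampling_interval must be positive")
        if self.death_rate_species <= 0 or self.depletion_rate_resource <= 0:
            raise ValueError("death and depletion rates must be positive")
        if self.sampling_interval < self.integrator_step:
            raise ValueError("sampling_interval must be >= integrator_step")

    def resolved_burn_in_steps(self) -> int:
        burn = self.burn_in
        if burn is None:
            burn = 10.0 / self.death_rate_species
        if burn < 0:
            raise ValueError("burn_in must be non-negative")
        return int(np.ceil(burn / self.integrator_step - 1e-9))


@dataclass
class Trajectory:
    """Sampled states: times (T,), abundances (N, T), resources (M, T),
    and the realized drive (M, T).  ``n_floor_events`` counts integrator
    steps where a resource was floored at zero."""

    times: np.ndarray
    abundances: np.ndarray
    resources: np.ndarray
    drive_realization: np.ndarray
    n_floor_events: int = 0

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass
class ZScoreSeries:
    """Per-species z scores of log abundance (rows mean 0, sd 1)."""

    scores: np.ndarray
    source_means: np.ndarray
    source_sds: np.ndarray

    @property
    def n_species(self) -> int:
        return self.scores.shape[0]

    @property
    def n_times(self) -> int:
        return self.scores.shape[1]


def make_sinusoidal_drive(spec: DriveSpec, times: np.ndarray) -> np.ndarray:
    """Evaluate K_a(t) = K_a0 + A_a sin(w_a t - phi_a) at the given times."""
    if spec.kind != "sinusoidal":
        raise ValueError("spec.kind must be 'sinusoidal'")
    t = np.asarray(times, dtype=float)
    return (
        spec.base_supply[:, None]
        + spec.amplitude[:, None] * np.sin(spec.frequency[:, None] * t[None, :] - spec.phase[:, None])
    )


def _ou_innovation_sd(amplitude: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    # exact discretization: Q_{n+1} = e^(-w dt) Q_n + eps,
    # eps ~ N(0, (A^2 w / 2)(1 - e^(-2 w dt)))
    return np.sqrt(0.5 * amplitude**2 * omega * (1.0 - np.exp(-2.0 * omega * dt)))


def _ou_extend(
    spec: DriveSpec, q_last: np.ndarray, n_steps: int, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Continue the OU deviation Q by ``n_steps`` steps; returns (M, n_steps)."""
    decay = np.exp(-spec.frequency * dt)
    sd = _ou_innovation_sd(spec.amplitude, spec.frequency, dt)
    noise = sd[:, None] * rng.standard_normal((spec.n_resources, n_steps))
    # AR(1) recursion Q_{n+1} = decay * Q_n + noise_n via lfilter, seeded
    # with the carried state.
    out = np.empty((spec.n_resources, n_steps))
    for a in range(spec.n_resources):
        zi = np.array([decay[a] * q_last[a]])
        out[a], _ = lfilter([1.0], [1.0, -decay[a]], noise[a], zi=zi)
    return out


def make_ou_drive(spec: DriveSpec, dt: float, t_final: float) -> np.ndarray:
    """Realize the OU drive on a uniform grid 0, dt, ..., t_final.

    Uses the exact discretization of the OU update; Q starts at 0.
    Returns K values with shape (M, n_steps + 1).
    """
    if spec.kind != "ou":
        raise ValueError("spec.kind must be 'ou'")
    n_steps = int(round(t_final / dt))
    rng = substream(spec.seed, "drive", "ou")
    q = np.zeros((spec.n_resources, n_steps + 1))
    if n_steps > 0:
        q[:, 1:] = _ou_extend(spec, q[:, 0], n_steps, dt, rng)
    return spec.base_supply[:, None] + q


_CHUNK_STEPS = 50_000


def simulate(network: ResourceNetwork, drive: DriveSpec, params: SimParams) -> Trajectory:
    """Integrate the ECRM and return samples at ``params.sampling_interval``.

    Species are integrated in log space (structurally positive); the
    burn-in window is discarded and sampled times restart at 0.  Given
    the same (network, drive, params) the output is bit-for-bit
    reproducible.
    """
    n, m = network.n_species, network.n_resources
    if drive.n_resources != m:
        raise ValueError("drive length does not match the number of resources")
    dt = params.integrator_step
    keep_every = int(round(params.sampling_interval / dt))
    if abs(keep_every * dt - params.sampling_interval) > 1e-9 * params.sampling_interval:
        raise ValueError("sampling_interval must be an integer multiple of integrator_step")

    n_burn = params.resolved_burn_in_steps()
    n_main = int(round(params.t_final / dt))
    n_keep = n_main // keep_every + 1

    x0 = np.broadcast_to(np.asarray(params.x0, dtype=float), (n,)).copy()
    if np.any(x0 <= 0):
        raise ValueError("initial abundances must be strictly positive")
    u = np.log(x0)
    if params.r0 is None:
        r_state = drive.base_supply / params.depletion_rate_resource
    else:
        r_state = np.broadcast_to(np.asarray(params.r0, dtype=float), (m,)).copy()
    if np.any(r_state < 0):
        raise ValueError("initial resources must be non-negative")
    r_state = r_state.astype(float).copy()

    gain = np.ascontiguousarray(network.gain)
    uptake = np.ascontiguousarray(network.uptake)

    out_x = np.empty((n_keep, n))
    out_r = np.empty((n_keep, m))
    drive_samples = np.empty((n_keep, m))

    is_ou = drive.kind == "ou"
    rng = substream(drive.seed, "drive", "ou") if is_ou else None
    q_last = np.zeros(m) if is_ou else None

    def stage_values(step0: int, n_steps: int):
        """Drive at RK4 stage times for steps step0..step0+n_steps-1, plus
        the per-step start values (for storing the realization)."""
        nonlocal q_last
        if is_ou:
            q_new = _ou_extend(drive, q_last, n_steps, dt, rng)
            starts = drive.base_supply[:, None] + np.concatenate([q_last[:, None], q_new[:, :-1]], axis=1)
            q_last = q_new[:, -1].copy()
            k3 = np.repeat(starts, 3, axis=1)  # piecewise constant over each step
        else:
            t0 = step0 * dt
            stage_t = t0 + dt * (np.repeat(np.arange(n_steps), 3) + np.tile([0.0, 0.5, 1.0], n_steps))
            k3 = make_sinusoidal_drive(drive, stage_t)
            starts = k3[:, 0::3]
        return np.ascontiguousarray(k3), starts

    n_floor = 0
    # burn-in: integrate without recording
    step = 0
    while step < n_burn:
        nb = min(_CHUNK_STEPS, n_burn - step)
        k3, _ = stage_values(step, nb)
        _, nf = rk4_chunk(
            u, r_state, gain, uptake,
            params.death_rate_species, params.depletion_rate_resource,
            k3, dt, n_burn + n_main + 1, out_x, out_r, 0, 0,
        )
        n_floor += nf
        step += nb

    # main phase: record initial state then integrate in chunks
    out_x[0] = np.exp(u)
    out_r[0] = r_state
    pos = 1
    step = 0
    chunk = max((_CHUNK_STEPS // keep_every) * keep_every, keep_every)
    while step < n_main:
        nb = min(chunk, n_main - step)
        k3, starts = stage_values(n_burn + step, nb)
        if is_ou:
            # record the piecewise-constant drive at sample steps in this chunk
            g = np.arange(0, n_main + 1, keep_every)
            here = g[(g >= step) & (g < step + nb)]
            drive_samples[here // keep_every, :] = starts[:, here - step].T
        pos, nf = rk4_chunk(
            u, r_state, gain, uptake,
            params.death_rate_species, params.depletion_rate_resource,
            k3, dt, keep_every, out_x, out_r, pos, step,
        )
        n_floor += nf
        step += nb

    times = np.arange(n_keep) * params.sampling_interval
    if is_ou:
        if n_main % keep_every == 0:
            drive_samples[n_keep - 1, :] = drive.base_supply + q_last
    else:
        drive_samples[:, :] = make_sinusoidal_drive(drive, n_burn * dt + times).T

    if not (np.all(np.isfinite(out_x)) and np.all(np.isfinite(out_r))):
        raise FloatingPointError("non-finite state encountered during integration")
    if n_floor > 0:
        warnings.warn(
            f"resource concentration floored at zero in {n_floor} integrator steps "
            "(negative supply excursions)",
            RuntimeWarning,
        )
    return Trajectory(
        times=times,
        abundances=out_x.T.copy(),
        resources=out_r.T.copy(),
        drive_realization=drive_samples.T.copy(),
        n_floor_events=n_floor,
    )


def save_trajectory_tsv(traj: Trajectory, path) -> None:
    """Wide TSV: one row per series (species, resource, drive) over time."""
    import pandas as pd

    n, m = traj.abundances.shape[0], traj.resources.shape[0]
    rows = np.vstack([traj.abundances, traj.resources, traj.drive_realization])
    index = (
        [f"x_{i}" for i in range(n)]
        + [f"R_{a}" for a in range(m)]
        + [f"K_{a}" for a in range(m)]
    )
    pd.DataFrame(rows, index=index, columns=traj.times).to_csv(path, sep="\t")


def save_trajectory_hdf5(traj: Trajectory, path, metadata: dict | None = None) -> None:
    """HDF5 export with a metadata block (e.g. config hash and seed)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("abundances", data=traj.abundances)
        fh.create_dataset("resources", data=traj.resources)
        fh.create_dataset("drive_realization", data=traj.drive_realization)
        fh.attrs["n_floor_events"] = traj.n_floor_events
        for key, value in (metadata or {}).items():
            fh.attrs[key] = value


def load_trajectory_hdf5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as fh:
        return Trajectory(
            times=fh["times"][:],
            abundances=fh["abundances"][:],
            resources=fh["resources"][:],
            drive_realization=fh["drive_realization"][:],
            n_floor_events=int(fh.attrs.get("n_floor_events", 0)),
        )


def sample_series(traj: Trajectory, sampling_interval: float) -> np.ndarray:
    """Subsample stored abundances at a coarser interval.

    ``sampling_interval`` must be an integer multiple of the stored grid
    spacing; returns an (N, T') matrix with T' = floor(span / dt) + 1.
    """
    grid = traj.sampling_interval
    if grid <= 0:
        raise ValueError("trajectory has fewer than two samples")
    ratio = sampling_interval / grid
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"sampling interval {sampling_interval} is not a multiple of the stored grid {grid}"
        )
    return traj.abundances[:, :: int(round(ratio))]


def log_zscore(abundances: np.ndarray) -> ZScoreSeries:
    """Log-transform then z-score each species' series.

    Requires strictly positive abundances (the metrics are defined on
    gap-free, zero-free series) and non-constant rows.
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 2:
        raise ValueError("abundances must be a 2-D species x time matrix")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("abundances must be finite and strictly positive")
    logs = np.log(x)
    means = logs.mean(axis=1)
    sds = logs.std(axis=1)  # population sd so that C_ii(0) = 1 exactly
    if np.any(sds == 0):
        bad = np.where(sds == 0)[0].tolist()
        raise ValueError(f"constant series (zero variance) for species rows {bad}")
    scores = (logs - means[:, None]) / sds[:, None]
    return ZScoreSeries(scores=scores, source_means=means, source_sds=sds)
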