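"""Synthetic data with the statistical structure the pipeline assumes.

Generators for the three kinds of inputs the analyses consume:

* doubly stochastic spike trains whose spike-count autocorrelation is (up
  to the zero-lag drop and rectification) a known mixture of exponentials:
  the rate is r(t) = max(0, r0 + sum_i a_i y_i(t)) with independent
  unit-variance OU processes y_i of time constant tau_i, and spikes are an
  inhomogeneous Poisson process. With this convention the count
  autocorrelation beyond lag 0 is a mixture of exp(-t/tau_i) with weights
  proportional to a_i^2, so the planted signal-to-noise is set directly by
  the modulation amplitudes (kept small, sum(a_i) <= 0.5 r0 by default, so
  rectification distortion stays negligible);

* trial tables with the statistics of a blocked two-alternative detection
  task — side-prior blocks of 20-100 trials at 20/80% or 80/20% right
  probability, contrasts in {100, 25, 12.5, 6, 0}%, choice correlated with
  the stimulus at a configurable accuracy, deterministic reward — plus
  task-modulated spike trains with planted multiplicative rate effects and
  optional block-correlated slow rate drift (the confound the
  block-restricted permutation null exists to absorb);

* spatially smooth voxel feature fields (spectrally synthesised Gaussian
  random fields) with a planted linear map from features to log10
  timescales, for validating the anatomy regression and its surrogate
  test.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .anatomy import VoxelGrid, NeuronPlacements
from .selectivity import DEFAULT_WINDOWS, TrialTable
from .spikes import SpikeTrain
from .tails import sample_power_law

__all__ = [
    "MultiscaleRateSpec",
    "PopulationSpec",
    "gen_multiscale_spike_train",
    "gen_population",
    "gen_trial_table",
    "gen_task_spike_train",
    "gen_voxel_world",
    "DEFAULT_DURATION",
]

#: Default recording duration in seconds (10-minute spontaneous period).
DEFAULT_DURATION = 600.0

_SIM_DT = 0.001  # rate-process grid, seconds

CONTRAST_LEVELS = (100.0, 25.0, 12.5, 6.0, 0.0)


@dataclass(frozen=True)
class MultiscaleRateSpec:
    """Doubly stochastic rate: r0 plus OU modulations (tau_i, a_i).

    ``components`` are (timescale seconds, amplitude Hz) pairs; each
    amplitude multiplies a stationary unit-variance OU process.
    """

    base_rate: float = 50.0
    components: tuple = ((0.05, 12.5), (0.5, 12.5))
    duration: float = DEFAULT_DURATION
    seed: int = 0

    def __post_init__(self):
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        for tau, _ in self.components:
            if tau <= 0:
                raise ValueError("component timescales must be positive")


def _ou_path(tau: float, n: int, dt: float, rng) -> np.ndarray:
    """Stationary unit-variance OU samples via the exact AR(1) recursion."""
    rho = np.exp(-dt / tau)
    s = np.sqrt(1.0 - rho ** 2)
    y0 = rng.standard_normal()  # stationary start
    noise = s * rng.standard_normal(n)
    y, _ = lfilter([1.0], [1.0, -rho], noise, zi=np.array([rho * y0]))
    return y


def _spikes_from_rate(rate: np.ndarray, dt: float, rng) -> np.ndarray:
    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(counts.size), counts)
    times = (idx + rng.random(idx.size)) * dt
    return np.sort(times)


def gen_multiscale_spike_train(spec: MultiscaleRateSpec,
                               unit_id="synthetic") -> tuple:
    """Spike train with a planted mixture-of-exponentials count AC.

    Returns ``(train, info)`` where ``info`` reports the fraction of time
    the rate was rectified at zero (a warning-level distortion above 20%).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / _SIM_DT))
    rate = np.full(n, spec.base_rate)
    for tau, amp in spec.components:
        if amp != 0:
            rate = rate + amp * _ou_path(tau, n, _SIM_DT, rng)
    rectified = float(np.mean(rate < 0))
    rate = np.clip(rate, 0.0, None)
    times = _spikes_from_rate(rate, _SIM_DT, rng)
    train = SpikeTrain(unit_id=unit_id, spike_times=times,
                       duration=spec.duration)
    return train, {"rectified_fraction": rectified,
                   "warn_rectified": rectified > 0.20}


@dataclass(frozen=True)
class PopulationSpec:
    """Population of units with planted per-neuron timescales.

    ``timescale_law`` is ("power_law", gamma, theta) or ("fixed", taus).
    Each neuron gets a single OU rate component at its planted timescale
    with amplitude ``modulation_fraction * base_rate``.
    """

    n_neurons: int = 500
    timescale_law: tuple = ("power_law", 2.0, 0.2)
    base_rate: float = 20.0
    modulation_fraction: float = 0.5
    duration: float = DEFAULT_DURATION
    seed: int = 0


def gen_population(spec: PopulationSpec) -> tuple:
    """Spike trains with planted timescales plus a ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    law = spec.timescale_law
    if law[0] == "power_law":
        _, gamma, theta = law
        taus = sample_power_law(gamma, theta, spec.n_neurons,
                                rng.integers(2 ** 31))
    elif law[0] == "fixed":
        taus = np.asarray(law[1], dtype=float)
        if taus.size != spec.n_neurons:
            raise ValueError("fixed law must list one tau per neuron")
    else:
        raise ValueError(f"unknown timescale law: {law[0]}")
    trains = []
    for i, tau in enumerate(taus):
        sub = MultiscaleRateSpec(
            base_rate=spec.base_rate,
            components=((float(tau),
                         spec.modulation_fraction * spec.base_rate),),
            duration=spec.duration, seed=int(rng.integers(2 ** 31)))
        train, _ = gen_multiscale_spike_train(sub, unit_id=f"unit{i:04d}")
        trains.append(train)
    truth = pd.DataFrame({"unit_id": [t.unit_id for t in trains],
                          "tau_true": taus})
    return trains, truth


def gen_trial_table(n_trials: int = 400, block_len_range=(20, 100),
                    p_side=(0.2, 0.8), contrasts=CONTRAST_LEVELS,
                    accuracy: float = 0.8, trial_spacing: float = 3.0,
                    seed=None) -> TrialTable:
    """Blocked task trial table.

    Blocks alternate between a right-biased and a left-biased side prior
    (right-stimulus probability ``p_side[1]`` and ``p_side[0]``), with
    block lengths uniform over ``block_len_range``. Choice equals the
    stimulus side with probability ``accuracy``; reward is deterministic
    given correctness. Event times are laid out at ``trial_spacing``
    seconds per trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = block_len_range
    block_id = np.empty(n_trials, dtype=np.int64)
    p_right = np.empty(n_trials)
    b, start = 0, 0
    right_block = bool(rng.integers(2))
    while start < n_trials:
        length = int(rng.integers(lo, hi + 1))
        stop = min(start + length, n_trials)
        block_id[start:stop] = b
        p_right[start:stop] = p_side[1] if right_block else p_side[0]
        right_block = not right_block
        b += 1
        start = stop
    right = rng.random(n_trials) < p_right
    side = np.where(right, "right", "left")
    correct = rng.random(n_trials) < accuracy
    choice = np.where(correct, side,
                      np.where(right, "left", "right"))
    reward = choice == side
    contrast = rng.choice(contrasts, size=n_trials)
    t0 = 1.0 + np.arange(n_trials) * trial_spacing
    rt = rng.uniform(0.2, 0.5, n_trials)
    df = pd.DataFrame({
        "stimulus_side": side, "contrast": contrast, "choice": choice,
        "reward": reward, "block_id": block_id,
        "stimulus_onset": t0, "movement_onset": t0 + rt,
        "feedback_onset": t0 + rt + 0.05,
    })
    return TrialTable(df)


def gen_task_spike_train(table: TrialTable, base_rate: float = 10.0,
                         effects: dict | None = None,
                         drift_tau: float | None = None,
                         drift_amp: float = 0.0,
                         unit_id="task-unit", seed=None) -> SpikeTrain:
    """Session-long spike train with planted task-variable rate effects.

    ``effects`` maps a task variable to a multiplicative rate factor
    applied in that variable's default count window on V1 trials (V1 is
    the first sorted label value, as in the selectivity test). With
    ``drift_tau``/``drift_amp`` set, the log-rate carries a slow OU drift
    — temporally correlated with the block structure but independent of
    the trial labels given time.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    n = int(np.ceil((table.df["feedback_onset"].max() + 2.0) / _SIM_DT))
    duration = n * _SIM_DT
    log_gain = np.zeros(n)
    if drift_tau is not None and drift_amp > 0:
        log_gain += drift_amp * _ou_path(drift_tau, n, _SIM_DT, rng)
    rate = base_rate * np.exp(log_gain)
    for variable, factor in effects.items():
        event_col, (a, bnd) = DEFAULT_WINDOWS[variable]
        labels = table.variable_labels(variable)
        events = np.asarray(table.df[event_col], dtype=float)
        for ev in events[labels]:
            i0 = int(np.floor((ev + a) / _SIM_DT))
            i1 = int(np.ceil((ev + bnd) / _SIM_DT))
            rate[max(i0, 0):min(i1, n)] *= factor
    times = _spikes_from_rate(rate, _SIM_DT, rng)
    return SpikeTrain(unit_id=unit_id, spike_times=times, duration=duration)


def gen_voxel_world(dims=(8, 8, 8), n_features: int = 10,
                    smoothness: float = 1.5, signal_beta=1.0,
                    noise_sd: float = 0.3, neurons_per_voxel: int = 3,
                    tau_median: float = 0.3, seed=None) -> tuple:
    """Smooth voxel feature fields with a planted linear timescale map.

    Features are Gaussian random fields synthesised spectrally with a
    power-law amplitude falloff |k|^(-smoothness) (larger = smoother),
    standardized per feature. Per-neuron log10 timescales are
    X @ beta + log10(tau_median) + N(0, noise_sd). ``signal_beta`` may be
    a scalar (applied to the first feature) or a length-n_features vector.

    Returns ``(grid, placements, truth)`` where ``truth`` records beta and
    the planted signal fraction var(X beta) / var(y).
    """
    if any(d < 4 for d in dims):
        raise ValueError("dims must be at least 4 in every direction")
    rng = np.random.default_rng(seed)
    nx, ny, nz = dims
    k = [np.fft.fftfreq(d) * d for d in dims]
    kk = np.sqrt(k[0][:, None, None] ** 2 + k[1][None, :, None] ** 2
                 + k[2][None, None, :] ** 2)
    with np.errstate(divide="ignore"):
        amp = np.where(kk > 0, kk ** (-smoothness), 0.0)
    fields = np.empty((*dims, n_features))
    for a in range(n_features):
        white = rng.standard_normal(dims)
        f = np.real(np.fft.ifftn(np.fft.fftn(white) * amp))
        f = (f - f.mean()) / max(f.std(), 1e-12)
        fields[..., a] = f
    grid = VoxelGrid(fields=fields)

    beta = np.zeros(n_features)
    sb = np.asarray(signal_beta, dtype=float)
    if sb.ndim == 0:
        beta[0] = float(sb)
    else:
        if sb.size != n_features:
            raise ValueError("signal_beta must be scalar or n_features long")
        beta = sb
    n_neurons = grid.n_voxels * neurons_per_voxel
    voxel_idx = np.repeat(np.arange(grid.n_voxels), neurons_per_voxel)
    signal = grid.features[voxel_idx] @ beta
    log_tau = (np.log10(tau_median) + signal
               + noise_sd * rng.standard_normal(n_neurons))
    placements = NeuronPlacements(
        unit_ids=np.array([f"v{idx}n{m}" for m, idx in enumerate(voxel_idx)]),
        voxel_indices=voxel_idx, tau_eff=10.0 ** log_tau)
    var_sig = float(np.var(signal))
    truth = {"beta": beta,
             "signal_fraction": var_sig / (var_sig + noise_sd ** 2)}
    return grid, placements, truth
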