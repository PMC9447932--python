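"""Synthetic trial sequences, observers, voxels, and spiking populations.

Everything downstream of raw data acquisition is testable against this
module: it generates (a) trial tables with the orientation-sequence and
timing statistics of the delayed discrimination task, (b) binary CW/CCW
responses from observers whose bias follows a DoG curve or an
encoder-decoder readout, (c) orientation-tuned voxel time series built by
convolving tuned event amplitudes with an HRF (optionally attenuated by a
fraction of the previous trial's response, emulating adaptation), and
(d) Poisson spike counts from the adapted population model.  Ground-truth
quantities are always returned alongside the simulated data so every
analysis stage has an oracle.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd

from .circular import wrap_ori
from .hrf_glm import canonical_hrf
from .population_model import AdaptationParams, PopulationModel, population_response
from .psychometrics import GUESS_RATE, dog, response_probability

__all__ = [
    "TimingConfig",
    "ObserverSpec",
    "SyntheticVoxelSpec",
    "VoxelDataset",
    "gen_trial_sequence",
    "add_history",
    "gen_observer_responses",
    "gen_voxel_timeseries",
    "trial_patterns",
    "gen_population_spikes",
    "save_trials",
    "load_trials",
]

TRIAL_COLUMNS = ["orientation", "probe_offset", "response", "onset", "delay",
                 "iti", "block_id", "prev_orientation", "delta"]

#: 22.5-deg-spaced bin centers avoiding cardinals and obliques
BINNED_CENTERS = 11.25 + 22.5 * np.arange(8)
#: jitter half-width around each bin center (deg)
BINNED_JITTER = 5.0
#: bin centers nearest the obliques (45/135) and the cardinals (0/90)
_OBLIQUE_BINS = np.array([33.75, 56.25, 123.75, 146.25])
_CARDINAL_BINS = np.array([11.25, 78.75, 101.25, 168.75])


@dataclasses.dataclass(frozen=True)
class TimingConfig:
    """Trial timing (s): defaults mirror the scanner task."""

    stim_duration: float = 1.0
    delays: tuple = (5.0, 7.0, 9.0)  # sample-to-probe delay, drawn uniformly
    iti_range: tuple = (5.0, 9.0)  # uniform inter-trial interval


@dataclasses.dataclass(frozen=True)
class ObserverSpec:
    """Simulated observer for the binary discrimination task.

    ``bias`` is the serial-dependence bias mu(Delta-theta): either
    ``("dog", A, w)`` or any callable mapping Delta-theta (deg) to bias
    (deg), e.g. an interpolated encoder-decoder bias curve.  ``bias=None``
    means unbiased.  ``sigma`` is the encoding SD (deg); ``guess_rate`` the
    fixed lapse probability.
    """

    bias: object = None
    sigma: float = 5.0
    guess_rate: float = GUESS_RATE
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError("guess_rate must lie in [0, 1)")

    def bias_at(self, delta):
        delta = np.asarray(delta, dtype=float)
        if self.bias is None:
            return np.zeros_like(delta)
        if callable(self.bias):
            return np.asarray(self.bias(delta), dtype=float)
        kind, *params = self.bias
        if kind == "dog":
            return dog(delta, *params)
        raise ValueError(f"unknown bias source {kind!r}")


def gen_trial_sequence(n_blocks, trials_per_block, mode="uniform", seed=0,
                       probe_offset=4.5, timing: TimingConfig | None = None
                       ) -> pd.DataFrame:
    """Generate a trial table with the task's orientation-sequence statistics.

    ``mode="uniform"``: each block's orientations are a random permutation of
    a grid linearly spaced across 180 deg with a per-block random phase
    offset (sorted successive differences all equal 180/trials_per_block).
    ``mode="binned"``: orientations jitter (+-5 deg, uniform) around
    22.5-deg-spaced centers offset by 11.25 deg, ordered so a near-oblique
    stimulus is always followed by a near-cardinal one.  Probe offsets have
    magnitude ``probe_offset`` with random sign; a ``(lo, hi)`` tuple draws
    a per-block magnitude uniformly from that range (emulating the per-block
    difficulty titration).  Timing fields are drawn from the configured
    ranges and onsets accumulate across the session.
    """
    if trials_per_block < 2:
        raise ValueError("trials_per_block must be >= 2")
    if mode not in ("uniform", "binned"):
        raise ValueError(f"unknown sequence mode {mode!r}; expected 'uniform' "
                         "or 'binned'")
    timing = timing or TimingConfig()
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for b in range(n_blocks):
        if mode == "uniform":
            phase = rng.uniform(0.0, 180.0 / trials_per_block)
            oris = (phase + np.arange(trials_per_block)
                    * 180.0 / trials_per_block) % 180.0
            rng.shuffle(oris)
        else:
            oris = np.empty(trials_per_block)
            for i in range(trials_per_block):
                pool = _OBLIQUE_BINS if i % 2 == 0 else _CARDINAL_BINS
                center = rng.choice(pool)
                oris[i] = (center + rng.uniform(-BINNED_JITTER,
                                                BINNED_JITTER)) % 180.0
        delays = rng.choice(timing.delays, size=trials_per_block)
        itis = rng.uniform(*timing.iti_range, size=trials_per_block)
        signs = rng.choice([-1.0, 1.0], size=trials_per_block)
        if np.iterable(probe_offset):
            lo, hi = probe_offset
            block_offset = rng.uniform(lo, hi)
        else:
            block_offset = probe_offset
        for i in range(trials_per_block):
            rows.append({"orientation": oris[i],
                         "probe_offset": signs[i] * block_offset,
                         "response": None, "onset": t, "delay": delays[i],
                         "iti": itis[i], "block_id": b})
            t += timing.stim_duration + delays[i] + itis[i]
    return add_history(pd.DataFrame(rows))


def add_history(trials: pd.DataFrame) -> pd.DataFrame:
    """Derive prev_orientation and delta = wrap(theta_prev - theta_n).

    History is computed within block (runs are independent); the first trial
    of each block has NaN history.
    """
    trials = trials.copy()
    prev = trials.groupby("block_id")["orientation"].shift(1)
    trials["prev_orientation"] = prev
    delta = wrap_ori(prev.to_numpy(dtype=float)
                     - trials["orientation"].to_numpy(dtype=float))
    trials["delta"] = np.where(prev.isna(), np.nan, delta)
    return trials


def gen_observer_responses(trials: pd.DataFrame,
                           spec: ObserverSpec) -> pd.DataFrame:
    """Fill the response column by inverting the binary response model.

    Per trial, P(CW) = g/2 + (1-g) * Phi((probe_offset - mu(Delta)) / sigma)
    with mu from the observer's bias source (0 where Delta is undefined).
    """
    if trials["probe_offset"].isna().any():
        raise ValueError("probe offsets must be populated before generating "
                         "responses")
    trials = trials.copy()
    delta = trials["delta"].to_numpy(dtype=float)
    mu = np.where(np.isnan(delta), 0.0, spec.bias_at(np.nan_to_num(delta)))
    p_cw = response_probability(trials["probe_offset"].to_numpy(dtype=float),
                                mu, spec.sigma, spec.guess_rate)
    rng = np.random.default_rng(spec.seed)
    trials["response"] = np.where(rng.uniform(size=len(trials)) < p_cw,
                                  "cw", "ccw")
    return trials


# ---------------------------------------------------------------------------
# Voxel simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SyntheticVoxelSpec:
    """Orientation-tuned voxel population with HRF dynamics.

    ``adaptation_fraction`` attenuates each trial's stimulus-evoked amplitude
    by that fraction of the previous trial's (realized) amplitude, per voxel,
    within block.  ``hrf`` may be a tap series; None uses the canonical
    double-gamma kernel sampled at TR over ``n_taps`` taps.
    """

    n_voxels: int = 32
    tuning_kappa: float = 2.0
    hrf: object = None
    noise_sd: float = 2.0
    adaptation_fraction: float = 0.40
    tr: float = 0.8
    n_taps: int = 30
    probe_gain: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.adaptation_fraction < 1.0:
            raise ValueError("adaptation_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def centers(self):
        return np.arange(self.n_voxels) * (180.0 / self.n_voxels)

    def kernel(self):
        if self.hrf is None:
            return canonical_hrf(self.tr, self.n_taps)
        return np.asarray(self.hrf, dtype=float)

    def tuned_amplitude(self, theta):
        """Peak-1 von Mises amplitude of every voxel to orientation(s) theta."""
        theta = np.asarray(theta, dtype=float)
        d = np.deg2rad(2.0 * (theta[..., None] - self.centers))
        return np.exp(self.tuning_kappa * (np.cos(d) - 1.0))


@dataclasses.dataclass
class VoxelDataset:
    """TR x voxel time series plus everything needed to analyse it."""

    data: np.ndarray  # (n_trs, n_voxels)
    tr: float
    stim_onsets: np.ndarray  # TR indices
    probe_onsets: np.ndarray  # TR indices
    block_bounds: list  # (start, stop) TR pairs, half-open
    trials: pd.DataFrame
    truth_stim_amps: np.ndarray  # (n_trials, n_voxels) ground truth
    truth_probe_amps: np.ndarray
    hrf_kernel: np.ndarray

    @property
    def orientations(self):
        return self.trials["orientation"].to_numpy(dtype=float)

    @property
    def delta(self):
        return self.trials["delta"].to_numpy(dtype=float)


def gen_voxel_timeseries(trials: pd.DataFrame, spec: SyntheticVoxelSpec,
                         seed=0) -> VoxelDataset:
    """Simulate orientation-tuned voxel responses to the task sequence.

    Per voxel: tuned amplitudes for each stimulus (at the trial orientation)
    and probe (at orientation + probe offset) event, stimulus amplitudes
    optionally attenuated by ``adaptation_fraction`` x the previous trial's
    realized amplitude (within block), each event convolved with the HRF
    kernel on the TR grid, summed, plus white Gaussian noise.  Event onsets
    are snapped to the TR grid; the snapped indices are stored on the
    returned dataset.
    """
    rng = np.random.default_rng(seed)
    kernel = spec.kernel()
    onset_s = trials["onset"].to_numpy(dtype=float)
    stim_dur = 1.0  # probe follows stimulus offset + delay
    probe_s = onset_s + stim_dur + trials["delay"].to_numpy(dtype=float)
    stim_idx = np.rint(onset_s / spec.tr).astype(int)
    probe_idx = np.rint(probe_s / spec.tr).astype(int)
    n_trs = int(probe_idx.max() + len(kernel) + int(10.0 / spec.tr))
    if np.any(stim_idx >= n_trs) or np.any(probe_idx >= n_trs):
        raise ValueError("event onset beyond the simulated series length")

    theta = trials["orientation"].to_numpy(dtype=float)
    theta_probe = (theta + trials["probe_offset"].to_numpy(dtype=float)) % 180.0
    amp_stim = spec.tuned_amplitude(theta)
    amp_probe = spec.probe_gain * spec.tuned_amplitude(theta_probe)

    if spec.adaptation_fraction > 0:
        block = trials["block_id"].to_numpy()
        adapted = amp_stim.copy()
        for i in range(1, len(trials)):
            if block[i] == block[i - 1]:
                adapted[i] = amp_stim[i] - spec.adaptation_fraction * adapted[i - 1]
        amp_stim = adapted

    impulses = np.zeros((n_trs, spec.n_voxels))
    np.add.at(impulses, stim_idx, amp_stim)
    np.add.at(impulses, probe_idx, amp_probe)
    from scipy.signal import fftconvolve
    data = fftconvolve(impulses, kernel[:, None], axes=0)[:n_trs]
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    blocks = trials["block_id"].to_numpy()
    bounds = []
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        lo = stim_idx[idx[0]]
        hi = n_trs if b == blocks.max() else stim_idx[
            np.flatnonzero(blocks == b + 1)[0]]
        bounds.append((int(lo), int(hi)))

    return VoxelDataset(data=data, tr=spec.tr, stim_onsets=stim_idx,
                        probe_onsets=probe_idx, block_bounds=bounds,
                        trials=trials.reset_index(drop=True),
                        truth_stim_amps=amp_stim, truth_probe_amps=amp_probe,
                        hrf_kernel=kernel)


def trial_patterns(dataset: VoxelDataset, start_s=4.8, n_trs=4) -> np.ndarray:
    """Trial x voxel activity: average of ``n_trs`` TRs starting ``start_s``
    after each stimulus onset (default 4.8-8.0 s, the analysis window)."""
    first = dataset.stim_onsets + int(round(start_s / dataset.tr))
    rows = first[:, None] + np.arange(n_trs)
    rows = np.clip(rows, 0, dataset.data.shape[0] - 1)
    return dataset.data[rows].mean(axis=1)


def gen_population_spikes(trials: pd.DataFrame, model: PopulationModel,
                          adapt: AdaptationParams | None = None, seed=0
                          ) -> np.ndarray:
    """Trial x unit Poisson spike counts from the (adapted) population model.

    The expected rate of each unit is the adapted tuning-curve response to the
    trial's orientation given the previous orientation; trials without history
    use the unadapted profile.
    """
    rng = np.random.default_rng(seed)
    theta = trials["orientation"].to_numpy(dtype=float)
    prev = trials["prev_orientation"].to_numpy(dtype=float)
    counts = np.empty((len(trials), model.n_units), dtype=int)
    for i in range(len(trials)):
        tp = None if np.isnan(prev[i]) else prev[i]
        rates = population_response(theta[i], tp, model,
                                    adapt if tp is not None else None)
        if np.any(rates < 0):
            raise ValueError("negative expected rate")
        counts[i] = rng.poisson(rates)
    return counts


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

def save_trials(trials: pd.DataFrame, path):
    trials.to_csv(path, index=False)


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return add_history(df) if "delta" not in df.columns else df


def save_voxels(dataset: VoxelDataset, prefix):
    """Write a voxel dataset as data CSV + trials CSV + JSON sidecar."""
    prefix = pathlib.Path(prefix)
    np.savetxt(prefix.with_suffix(".data.csv"), dataset.data, delimiter=",")
    save_trials(dataset.trials, prefix.with_suffix(".trials.csv"))
    meta = {"tr": dataset.tr,
            "stim_onsets": dataset.stim_onsets.tolist(),
            "probe_onsets": dataset.probe_onsets.tolist(),
            "block_bounds": [list(b) for b in dataset.block_bounds]}
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def load_voxels(prefix) -> VoxelDataset:
    prefix = pathlib.Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.loadtxt(prefix.with_suffix(".data.csv"), delimiter=",")
    trials = load_trials(prefix.with_suffix(".trials.csv"))
    nt = len(trials)
    return VoxelDataset(data=data, tr=meta["tr"],
                        stim_onsets=np.array(meta["stim_onsets"]),
                        probe_onsets=np.array(meta["probe_onsets"]),
                        block_bounds=[tuple(b) for b in meta["block_bounds"]],
                        trials=trials,
                        truth_stim_amps=np.full((nt, data.shape[1]), np.nan),
                        truth_probe_amps=np.full((nt, data.shape[1]), np.nan),
                        hrf_kernel=np.array([]))
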