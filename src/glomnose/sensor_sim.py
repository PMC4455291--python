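"""Synthetic drifting gas-sensor-array simulator.

Emulates the statistical structure of a 4-class x 4-replica metal-oxide
sensor array probed with five volatile compounds: class-specific selectivity,
replica gain spread, a slow cross-class-correlated baseline random walk
("drift"), abrupt correlated baseline steps at episode boundaries ("jumps"),
i.i.d. read-out noise, and injectable sensor faults (dropout / random output).

All responses live on a normalized, dimensionless scale in [0, 1]
(the raw read-out of such sensors is a resistance change, dR, per exposure;
the simulator works directly on the normalized scale the downstream network
expects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StimulusSchedule",
    "SensorArrayModel",
    "ResponseMatrix",
    "FaultSpec",
    "make_training_schedule",
    "make_testing_schedule",
    "concat_schedules",
    "simulate_responses",
    "apply_fault",
    "correlation_matrix",
    "default_model",
    "DEFAULT_TRAINING_COUNTS",
    "DEFAULT_TESTING_EPISODES",
]

#: per-stimulus presentation counts of the training phase
DEFAULT_TRAINING_COUNTS = [40, 50, 20, 20, 20]

#: episodic testing phase: (stimulus_id, n_repetitions) per episode, in
#: presentation order.  Per-stimulus totals are [25, 60, 75, 188, 358]
#: (706 samples); episode lengths are irregular on purpose.
DEFAULT_TESTING_EPISODES = [
    (5, 45), (2, 12), (4, 30), (1, 6), (3, 18), (5, 40), (4, 25),
    (2, 20), (5, 50), (3, 25), (4, 40), (1, 9), (5, 38), (2, 8),
    (4, 35), (3, 12), (5, 42), (2, 15), (4, 28), (1, 10), (5, 35),
    (3, 20), (4, 30), (2, 5), (5, 48), (5, 60),
]


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered sequence of stimulus presentations.

    Each entry pairs a stimulus id (1-based) with an episode id.  The
    interleaved training phase carries episode id 0 for every entry; testing
    episodes (id >= 1) each contain repetitions of a single stimulus.
    """

    stimulus_ids: np.ndarray
    episode_ids: np.ndarray
    n_stimuli: int

    def __post_init__(self):
        sid = np.asarray(self.stimulus_ids, dtype=int)
        eid = np.asarray(self.episode_ids, dtype=int)
        object.__setattr__(self, "stimulus_ids", sid)
        object.__setattr__(self, "episode_ids", eid)
        if sid.shape != eid.shape or sid.ndim != 1:
            raise ValueError("stimulus_ids and episode_ids must be equal-length 1-D")
        if sid.size:
            if sid.min() < 1 or sid.max() > self.n_stimuli:
                raise ValueError(f"stimulus ids must lie in [1, {self.n_stimuli}]")
            if np.any(np.diff(eid) < 0):
                raise ValueError("episode ids must be non-decreasing")
            for ep in np.unique(eid):
                if ep >= 1 and len(np.unique(sid[eid == ep])) > 1:
                    raise ValueError(f"episode {ep} mixes several stimuli")

    def __len__(self) -> int:
        return self.stimulus_ids.size

    @property
    def entries(self) -> list[tuple[int, int]]:
        return list(zip(self.stimulus_ids.tolist(), self.episode_ids.tolist()))


def make_training_schedule(counts, seed: int, n_stimuli: int | None = None) -> StimulusSchedule:
    """Seeded random interleaving with exactly ``counts[s]`` presentations of
    stimulus ``s+1``, all in episode 0 (rapid irregular training sequence)."""
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise ValueError("presentation counts must be non-negative")
    n_stimuli = len(counts) if n_stimuli is None else n_stimuli
    labels = np.repeat(np.arange(1, len(counts) + 1), counts)
    rng = np.random.default_rng(seed)
    labels = rng.permutation(labels)
    return StimulusSchedule(labels, np.zeros(labels.size, dtype=int), n_stimuli)


def make_testing_schedule(episodes, first_episode_id: int = 1,
                          n_stimuli: int | None = None) -> StimulusSchedule:
    """Concatenate single-stimulus episodes; episode ids increment from
    ``first_episode_id``."""
    episodes = list(episodes)
    for stim, reps in episodes:
        if reps < 1:
            raise ValueError(f"episode of stimulus {stim} has {reps} repetitions (need >= 1)")
    if n_stimuli is None:
        n_stimuli = max((s for s, _ in episodes), default=0)
    sids, eids = [], []
    for offset, (stim, reps) in enumerate(episodes):
        sids.extend([stim] * reps)
        eids.extend([first_episode_id + offset] * reps)
    return StimulusSchedule(np.array(sids, dtype=int), np.array(eids, dtype=int), n_stimuli)


def concat_schedules(a: StimulusSchedule, b: StimulusSchedule) -> StimulusSchedule:
    """Join two schedules (e.g. training then testing) into one stream."""
    if a.n_stimuli != b.n_stimuli:
        raise ValueError("schedules disagree on the number of stimuli")
    return StimulusSchedule(
        np.concatenate([a.stimulus_ids, b.stimulus_ids]),
        np.concatenate([a.episode_ids, b.episode_ids]),
        a.n_stimuli,
    )


@dataclass(frozen=True)
class SensorArrayModel:
    """Generative model of the sensor array.

    selectivity[c, s] is the clean mean response of class ``c+1`` to stimulus
    ``s+1`` on the normalized [0, 1] scale.  Per-replica multiplicative gains
    and per-replica selectivity-shape perturbations (sd
    ``replica_selectivity_sd``, manufacturing spread between nominally
    identical sensors) are drawn once; each class carries a Gaussian baseline
    random walk whose
    increments are correlated across classes via ``class_drift_correlation``;
    with probability ``jump_prob`` a correlated baseline step of sd
    ``jump_sd`` is added at each episode boundary (shared by all replicas of a
    class); ``noise_sd`` is i.i.d. per reading.  Outputs are clipped to [0,1].
    """

    selectivity: np.ndarray
    n_classes: int = 4
    replicas_per_class: int = 4
    replica_gain_sd: float = 0.10
    replica_selectivity_sd: float = 0.0
    drift_step_sd: float = 0.0025
    class_drift_correlation: np.ndarray | None = None
    jump_prob: float = 0.7
    jump_sd: float = 0.035
    noise_sd: float = 0.01
    noise_spread: float = 1.0

    def __post_init__(self):
        sel = np.asarray(self.selectivity, dtype=float)
        object.__setattr__(self, "selectivity", sel)
        if sel.shape[0] != self.n_classes:
            raise ValueError("selectivity must have one row per sensor class")
        if sel.min() < 0 or sel.max() > 1:
            raise ValueError("selectivity entries must lie in [0, 1]")
        if self.class_drift_correlation is None:
            object.__setattr__(self, "class_drift_correlation", np.eye(self.n_classes))
        corr = np.asarray(self.class_drift_correlation, dtype=float)
        object.__setattr__(self, "class_drift_correlation", corr)
        if corr.shape != (self.n_classes, self.n_classes):
            raise ValueError("drift correlation matrix has wrong shape")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("drift correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("drift correlation must be positive semidefinite")
        for name in ("replica_gain_sd", "replica_selectivity_sd", "drift_step_sd",
                     "jump_sd", "noise_sd", "noise_spread"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if not 0 <= self.jump_prob <= 1:
            raise ValueError("jump_prob must lie in [0, 1]")

    @property
    def n_stimuli(self) -> int:
        return self.selectivity.shape[1]

    @property
    def n_channels(self) -> int:
        return self.n_classes * self.replicas_per_class


#: Default 4x5 selectivity: stimulus 1 is well separated (the one compound the
#: array distinguishes cleanly); stimuli 2-5 overlap across classes.
_DEFAULT_SELECTIVITY = np.array(
    [
        [0.90, 0.50, 0.46, 0.50, 0.46],
        [0.20, 0.58, 0.46, 0.52, 0.48],
        [0.30, 0.46, 0.56, 0.48, 0.58],
        [0.15, 0.48, 0.58, 0.60, 0.44],
    ]
)

#: Classes 2 and 4 highly correlated, class 3 moderately so, class 1 weakly.
_DEFAULT_CORR = np.array(
    [
        [1.0, 0.3, 0.3, 0.3],
        [0.3, 1.0, 0.5, 0.8],
        [0.3, 0.5, 1.0, 0.5],
        [0.3, 0.8, 0.5, 1.0],
    ]
)


def default_model(**overrides) -> SensorArrayModel:
    """The default drift benchmark array model (see docs/methods.md)."""
    kw = dict(selectivity=_DEFAULT_SELECTIVITY.copy(),
              class_drift_correlation=_DEFAULT_CORR.copy())
    kw.update(overrides)
    return SensorArrayModel(**kw)


@dataclass
class ResponseMatrix:
    """Time-ordered table of sensor outputs.

    values: samples x channels, normalized responses in [0, 1] (faulty
    channels may carry exact zeros).  Channels are ordered class-major:
    channel c*Q + q is replica q of class c+1.
    """

    values: np.ndarray
    labels: np.ndarray
    episode_ids: np.ndarray
    channel_class: np.ndarray
    sample_index: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.episode_ids = np.asarray(self.episode_ids, dtype=int)
        self.channel_class = np.asarray(self.channel_class, dtype=int)
        self.sample_index = np.asarray(self.sample_index, dtype=int)
        n, m = self.values.shape
        if not (self.labels.size == self.episode_ids.size == self.sample_index.size == n):
            raise ValueError("per-sample arrays must match the number of rows")
        if self.channel_class.size != m:
            raise ValueError("channel_class must have one entry per channel")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")
        if n > 1 and np.any(np.diff(self.sample_index) <= 0):
            raise ValueError("sample_index must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(self.values.copy(), self.labels.copy(),
                              self.episode_ids.copy(), self.channel_class.copy(),
                              self.sample_index.copy())

    def slice_index(self, start: int, stop: int) -> "ResponseMatrix":
        """Rows with start <= sample_index < stop."""
        sel = (self.sample_index >= start) & (self.sample_index < stop)
        return ResponseMatrix(self.values[sel], self.labels[sel],
                              self.episode_ids[sel], self.channel_class.copy(),
                              self.sample_index[sel])


@dataclass(frozen=True)
class FaultSpec:
    """One faulty channel over a half-open sample-index window.

    ``dropout`` forces the channel to 0 (dead sensor); ``random`` replaces it
    with i.i.d. Uniform(0, 1) draws (mean 0.5, spanning the response scale).
    """

    channel: int
    start: int
    stop: int
    mode: str

    def __post_init__(self):
        if self.mode not in ("dropout", "random"):
            raise ValueError(f"unknown fault mode {self.mode!r}")
        if self.start > self.stop:
            raise ValueError("fault window must satisfy start <= stop")


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    """Square root of a PSD correlation matrix (eigen-based; tolerates
    semidefinite inputs where Cholesky would fail)."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_responses(model: SensorArrayModel, schedule: StimulusSchedule,
                       seed: int) -> ResponseMatrix:
    """Generate a ResponseMatrix for ``schedule`` under ``model``.

    value[t, (c, q)] = clip_[0,1]( selectivity[c, s(t)] * g_q + h[c, q, s(t)]
                                   + b_c(t) + jump_c(t) + eps )
    with per-replica gains g, fixed per-replica selectivity perturbations h,
    correlated class random walk b, correlated episode-boundary jumps, and
    i.i.d. noise eps.  Deterministic given seed.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    if model.n_stimuli < int(schedule.stimulus_ids.max()):
        raise ValueError("schedule uses stimuli the model does not define")
    rng = np.random.default_rng(seed)
    n = len(schedule)
    C, Q = model.n_classes, model.replicas_per_class
    fac = _corr_factor(model.class_drift_correlation)

    gains = 1.0 + rng.normal(0.0, 1.0, size=(C, Q)) * model.replica_gain_sd
    shapes = rng.normal(0.0, 1.0, size=(C, Q, model.n_stimuli)) \
        * model.replica_selectivity_sd
    # individual sensors differ in read-out noise (log-normal spread)
    noise_scale = np.exp(rng.normal(0.0, 1.0, size=C * Q) * model.noise_spread)

    steps = rng.normal(size=(n, C)) @ fac.T * model.drift_step_sd
    steps[0] = 0.0  # the walk starts at zero offset
    drift = np.cumsum(steps, axis=0)

    boundaries = np.flatnonzero(np.diff(schedule.episode_ids) != 0) + 1
    jump_hits = rng.random(boundaries.size) < model.jump_prob
    jump_vecs = rng.normal(size=(boundaries.size, C)) @ fac.T * model.jump_sd
    jump = np.zeros((n, C))
    for t, hit, vec in zip(boundaries, jump_hits, jump_vecs):
        if hit:
            jump[t:] += vec

    noise = rng.normal(0.0, 1.0, size=(n, C * Q)) * (model.noise_sd * noise_scale)

    s_idx = schedule.stimulus_ids - 1
    clean = model.selectivity[:, s_idx].T  # n x C
    pert = shapes[:, :, s_idx].transpose(2, 0, 1)  # n x C x Q
    values = (clean[:, :, None] * gains[None, :, :] + pert
              + drift[:, :, None] + jump[:, :, None]).reshape(n, C * Q) + noise
    values = np.clip(values, 0.0, 1.0)

    channel_class = np.repeat(np.arange(1, C + 1), Q)
    return ResponseMatrix(values, schedule.stimulus_ids.copy(),
                          schedule.episode_ids.copy(), channel_class,
                          np.arange(n))


def apply_fault(data: ResponseMatrix, fault: FaultSpec, seed: int) -> ResponseMatrix:
    """Copy ``data`` with the fault injected; only the (channel, window)
    rectangle changes."""
    if not 0 <= fault.channel < data.n_channels:
        raise ValueError(f"channel {fault.channel} outside [0, {data.n_channels})")
    out = data.copy()
    sel = (data.sample_index >= fault.start) & (data.sample_index < fault.stop)
    k = int(sel.sum())
    if k == 0:
        warnings.warn("fault window does not overlap the data; returned unchanged",
                      stacklevel=2)
        return out
    if fault.mode == "dropout":
        out.values[sel, fault.channel] = 0.0
    else:
        rng = np.random.default_rng(seed)
        out.values[sel, fault.channel] = rng.uniform(0.0, 1.0, size=k)
    return out


def correlation_matrix(data: ResponseMatrix) -> np.ndarray:
    """Pearson correlation between channel columns (NaN for constant
    channels)."""
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = data.values
    const = np.ptp(x, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[const, :] = np.nan
    corr[:, const] = np.nan
    np.fill_diagonal(corr, np.where(const, np.nan, 1.0))
    return corr
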