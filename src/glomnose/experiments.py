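"""End-to-end experiment drivers.

Pipelines compared on one simulated (or user-supplied) sensor stream:

* ``run_plsda_baseline``        — PLS-DA directly on the 16 normalized channels
* ``run_class_average_baseline``— PLS-DA on the 4 per-class channel means
* ``run_network_pipeline``      — glomerular network pre-processing, PLS-DA on
  the L mitral-cell outputs, averaged over repeated random initializations
* ``run_fault_sweep``           — classification during a fault of each sensor
  in turn, with and without the network
* ``run_fault_dynamics_study``  — matched-seed no-fault / dropout / random
  passes recording the weight and output dynamics around a fault window

Training and testing are simulated as one continuous stream (the drift random
walk does not reset between phases) and split by sample index.  Faults are
injected into the normalized test stream: the fault modes (dead sensor r = 0,
random r with mean 0.5) are statements about the normalized response scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import sensor_sim as ss
from .glomerular import LearningRates, init_network, process_sequence
from .plsda import ClassificationReport, classify, confusion, fit_plsda, select_ncomp
from .sensor_sim import FaultSpec, ResponseMatrix

__all__ = [
    "NormalizerStats",
    "ExperimentConfig",
    "SweepResult",
    "normalize_fit",
    "normalize_apply",
    "make_benchmark",
    "run_plsda_baseline",
    "run_class_average_baseline",
    "run_network_pipeline",
    "run_fault_sweep",
    "run_fault_dynamics_study",
    "trial_seeds",
]


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizerStats:
    """Per-channel affine map fitted on training data (robust 1%/99%
    percentiles); application clips to [0, 1]."""

    lo: np.ndarray
    hi: np.ndarray


def normalize_fit(train: ResponseMatrix, lo_pct: float = 1.0,
                  hi_pct: float = 99.0) -> NormalizerStats:
    if train.n_samples == 0:
        raise ValueError("training data must be non-empty")
    lo = np.percentile(train.values, lo_pct, axis=0)
    hi = np.percentile(train.values, hi_pct, axis=0)
    flat = hi <= lo
    if np.any(flat):
        warnings.warn(
            f"constant channels {np.flatnonzero(flat).tolist()}: unit-scale fallback",
            stacklevel=2)
        hi = np.where(flat, lo + 1.0, hi)
    return NormalizerStats(lo, hi)


def normalize_apply(stats: NormalizerStats, data: ResponseMatrix) -> ResponseMatrix:
    out = data.copy()
    out.values = np.clip((data.values - stats.lo) / (stats.hi - stats.lo), 0.0, 1.0)
    return out


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one benchmark run."""

    # simulator
    training_counts: list = field(default_factory=lambda: list(ss.DEFAULT_TRAINING_COUNTS))
    testing_episodes: list = field(default_factory=lambda: [list(e) for e in ss.DEFAULT_TESTING_EPISODES])
    model_overrides: dict = field(default_factory=dict)
    # network
    L: int = 4
    f_density: float = 0.5
    rates: LearningRates = field(default_factory=LearningRates)
    # classifier
    n_components: int | str = 4   # or "auto" for CV + one-SE selection
    autoscale: bool = False
    # trials & fault
    n_trials: int = 100
    fault_channel: int = 3
    fault_start: int = 400
    fault_stop: int = 520
    fault_mode: str = "dropout"
    master_seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if isinstance(self.rates, dict):
            self.rates = LearningRates(**self.rates)

    def model(self) -> ss.SensorArrayModel:
        return ss.default_model(**self.model_overrides)


def trial_seeds(master_seed: int, n_trials: int) -> np.ndarray:
    """Documented seed-splitting scheme: one child stream per trial."""
    seq = np.random.SeedSequence(master_seed)
    return np.array([int(c.generate_state(1)[0] % (2 ** 31)) for c in seq.spawn(n_trials)])


def make_benchmark(cfg: ExperimentConfig) -> tuple[ResponseMatrix, ResponseMatrix]:
    """Simulate the default drift benchmark and split it into the interleaved
    training phase and the episodic testing phase.

    The two phases come from one continuous simulation so drift and jumps
    carry over from training into testing.
    """
    model = cfg.model()
    train_sched = ss.make_training_schedule(cfg.training_counts, seed=cfg.master_seed,
                                            n_stimuli=model.n_stimuli)
    test_sched = ss.make_testing_schedule([tuple(e) for e in cfg.testing_episodes],
                                          first_episode_id=1,
                                          n_stimuli=model.n_stimuli)
    full = ss.concat_schedules(train_sched, test_sched)
    data = ss.simulate_responses(model, full, seed=cfg.master_seed)
    n_train = len(train_sched)
    return data.slice_index(0, n_train), data.slice_index(n_train, data.n_samples)


def _resolve_ncomp(cfg: ExperimentConfig, X: np.ndarray, labels: np.ndarray) -> int:
    bound = min(X.shape[0] - 1, X.shape[1])
    if cfg.n_components == "auto":
        return select_ncomp(X, labels, max_components=bound if bound < 8 else
                            len(np.unique(labels)), seed=cfg.master_seed,
                            autoscale=cfg.autoscale)
    return min(int(cfg.n_components), bound)


# --------------------------------------------------------------------------
# pipeline variants
# --------------------------------------------------------------------------

def _prepare(train: ResponseMatrix, test: ResponseMatrix):
    stats = normalize_fit(train)
    return normalize_apply(stats, train), normalize_apply(stats, test)


def run_plsda_baseline(train: ResponseMatrix, test: ResponseMatrix,
                       cfg: ExperimentConfig) -> ClassificationReport:
    """PLS-DA on the raw (normalized) sensor channels, no network."""
    tr, te = _prepare(train, test)
    a = _resolve_ncomp(cfg, tr.values, tr.labels)
    model = fit_plsda(tr.values, tr.labels, a, autoscale=cfg.autoscale)
    pred = classify(model, te.values)
    return confusion(te.labels, pred, int(max(tr.labels.max(), te.labels.max())))


def _class_average(data: ResponseMatrix) -> np.ndarray:
    classes = np.unique(data.channel_class)
    return np.column_stack([
        data.values[:, data.channel_class == c].mean(axis=1) for c in classes])


def run_class_average_baseline(train: ResponseMatrix, test: ResponseMatrix,
                               cfg: ExperimentConfig) -> ClassificationReport:
    """PLS-DA on the per-class channel means (4 inputs instead of 16)."""
    tr, te = _prepare(train, test)
    Xtr, Xte = _class_average(tr), _class_average(te)
    a = _resolve_ncomp(cfg, Xtr, tr.labels)
    model = fit_plsda(Xtr, tr.labels, a, autoscale=cfg.autoscale)
    pred = classify(model, Xte)
    return confusion(te.labels, pred, int(max(tr.labels.max(), te.labels.max())))


@dataclass
class NetworkPipelineResult:
    report: ClassificationReport          # mean confusion over trials
    per_trial_ccr: np.ndarray
    mean_ccr: float


def _network_trial(tr: ResponseMatrix, te: ResponseMatrix, cfg: ExperimentConfig,
                   seed: int, test_faults=None):
    """One random initialization: adapt through training, fit PLS-DA on the
    recorded MC outputs, keep adapting through the test stream, classify."""
    net = init_network(L=cfg.L, N=tr.n_channels, f_density=cfg.f_density,
                       seed=seed, rates=cfg.rates)
    net, trace_tr = process_sequence(net, tr, adapt=True)
    a = min(int(cfg.n_components) if cfg.n_components != "auto" else cfg.L,
            trace_tr.mc_outputs.shape[1], tr.n_samples - 1)
    model = fit_plsda(trace_tr.mc_outputs, tr.labels, a, autoscale=cfg.autoscale)
    net, trace_te = process_sequence(net, te, adapt=True, faults=test_faults,
                                     fault_seed=seed)
    pred = classify(model, trace_te.mc_outputs)
    return pred, trace_te


def run_network_pipeline(train: ResponseMatrix, test: ResponseMatrix,
                         cfg: ExperimentConfig) -> NetworkPipelineResult:
    """Network + PLS-DA, averaged over ``cfg.n_trials`` random initial
    conditions (new random weights each trial, same data)."""
    tr, te = _prepare(train, test)
    S = int(max(tr.labels.max(), te.labels.max()))
    seeds = trial_seeds(cfg.master_seed, cfg.n_trials)
    ccrs, confusions = [], []
    for seed in seeds:
        pred, _ = _network_trial(tr, te, cfg, seed)
        rep = confusion(te.labels, pred, S)
        ccrs.append(rep.ccr)
        confusions.append(rep.confusion)
    mean_conf = np.mean(confusions, axis=0)
    ccrs = np.array(ccrs)
    rowsum = mean_conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pce = np.where(rowsum > 0, 1.0 - np.diag(mean_conf) / rowsum, np.nan)
    report = ClassificationReport(mean_conf, float(ccrs.mean()), pce,
                                  np.arange(1, S + 1))
    return NetworkPipelineResult(report, ccrs, float(ccrs.mean()))


# --------------------------------------------------------------------------
# fault experiments
# --------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-sensor classification rates during a fault, for both pipeline
    variants, plus their no-fault references."""

    fault_mode: str
    plsda_ccr: np.ndarray          # n_channels
    network_ccr: np.ndarray        # n_channels, trial-averaged
    plsda_reference: float
    network_reference: float
    per_trial_network_ccr: np.ndarray  # n_channels x n_trials


def _window_mask(data: ResponseMatrix, start: int, stop: int) -> np.ndarray:
    return (data.sample_index >= start) & (data.sample_index < stop)


def run_fault_sweep(train: ResponseMatrix, test: ResponseMatrix,
                    cfg: ExperimentConfig, mode: str | None = None) -> SweepResult:
    """Inject the configured fault into each sensor in turn and score both
    pipelines on the fault-window samples only."""
    mode = cfg.fault_mode if mode is None else mode
    tr, te = _prepare(train, test)
    S = int(max(tr.labels.max(), te.labels.max()))
    win = _window_mask(te, cfg.fault_start, cfg.fault_stop)
    if not win.any():
        warnings.warn("fault window covers no test samples", stacklevel=2)
    n_ch = te.n_channels
    seeds = trial_seeds(cfg.master_seed, cfg.n_trials)

    # direct PLS-DA: fit once on clean training data
    a = _resolve_ncomp(cfg, tr.values, tr.labels)
    base_model = fit_plsda(tr.values, tr.labels, a, autoscale=cfg.autoscale)
    base_ref = float(np.mean(classify(base_model, te.values[win]) == te.labels[win])) \
        if win.any() else float("nan")
    plsda_ccr = np.empty(n_ch)
    for ch in range(n_ch):
        faulty = ss.apply_fault(te, FaultSpec(ch, cfg.fault_start, cfg.fault_stop, mode),
                                seed=cfg.master_seed + ch)
        pred = classify(base_model, faulty.values[win])
        plsda_ccr[ch] = np.mean(pred == te.labels[win]) if win.any() else np.nan

    # network variant: training pass shared across sensors within a trial
    net_ccr = np.zeros((n_ch, cfg.n_trials))
    net_ref = np.zeros(cfg.n_trials)
    for ti, seed in enumerate(seeds):
        net0 = init_network(L=cfg.L, N=n_ch, f_density=cfg.f_density,
                            seed=int(seed), rates=cfg.rates)
        net0, trace_tr = process_sequence(net0, tr, adapt=True)
        a_net = min(int(cfg.n_components) if cfg.n_components != "auto" else cfg.L,
                    cfg.L, tr.n_samples - 1)
        model = fit_plsda(trace_tr.mc_outputs, tr.labels, a_net,
                          autoscale=cfg.autoscale)
        _, trace_clean = process_sequence(net0.copy(), te, adapt=True)
        pred = classify(model, trace_clean.mc_outputs[win])
        net_ref[ti] = np.mean(pred == te.labels[win]) if win.any() else np.nan
        for ch in range(n_ch):
            fs = FaultSpec(ch, cfg.fault_start, cfg.fault_stop, mode)
            _, trace = process_sequence(net0.copy(), te, adapt=True, faults=[fs],
                                        fault_seed=cfg.master_seed + ch)
            pred = classify(model, trace.mc_outputs[win])
            net_ccr[ch, ti] = np.mean(pred == te.labels[win]) if win.any() else np.nan

    return SweepResult(mode, plsda_ccr, net_ccr.mean(axis=1), base_ref,
                       float(net_ref.mean()), net_ccr)


@dataclass
class FaultDynamicsResult:
    """Matched-seed traces of the no-fault / dropout / random passes around a
    single fault window, for the glomerulus owning the faulty channel."""

    channel: int
    start: int
    stop: int
    sample_index: np.ndarray
    c_faulty: dict       # mode -> c[i, channel] trajectory
    d_faulty: dict
    mc_output: dict      # mode -> m[i] trajectory
    c_survivors: dict    # mode -> mean over surviving branches of c[i, :]


def run_fault_dynamics_study(train: ResponseMatrix, test: ResponseMatrix,
                             cfg: ExperimentConfig) -> FaultDynamicsResult:
    """Three passes with identical weights and data, differing only in the
    fault mode on the configured channel/window."""
    tr, te = _prepare(train, test)
    ch = cfg.fault_channel
    net0 = init_network(L=cfg.L, N=tr.n_channels, f_density=cfg.f_density,
                        seed=cfg.master_seed, rates=cfg.rates)
    net0, _ = process_sequence(net0, tr, adapt=True)
    glom = int(np.flatnonzero(net0.class_mask[:, ch] == 1)[0])
    survivors = (net0.class_mask[glom] == 1) & (np.arange(net0.N) != ch)

    out = FaultDynamicsResult(ch, cfg.fault_start, cfg.fault_stop,
                              te.sample_index.copy(), {}, {}, {}, {})
    for mode in ("none", "dropout", "random"):
        faults = None if mode == "none" else \
            [FaultSpec(ch, cfg.fault_start, cfg.fault_stop, mode)]
        _, trace = process_sequence(net0.copy(), te, adapt=True, faults=faults,
                                    record_weights=True, record_branches=True,
                                    fault_seed=cfg.master_seed)
        out.c_faulty[mode] = trace.c_trace[:, glom, ch]
        out.d_faulty[mode] = trace.d_trace[:, glom, ch]
        out.mc_output[mode] = trace.mc_outputs[:, glom]
        out.c_survivors[mode] = trace.c_trace[:, glom, survivors].mean(axis=1)
    return out
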