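"""Adaptive multi-compartment glomerular network.

The circuit mirrors the input layer of the olfactory bulb.  Each of L
glomerular units bundles one mitral cell (MC) and one periglomerular (PG)
cell.  Sensor channel j drives branch j of the MCs through excitatory weights
c[i, j] (nonzero only for the unit's own sensor class — replicas of one class
converge onto one glomerulus) and drives subcompartment k of every PG cell
through weights d[i, k] (PG cells see all channels).  A PG subcompartment
potential p[i, k] = d[i, k] * r[k] multiplicatively inhibits MC branches via
fixed coefficients f[i, j, k]:

    m[i, j] = c[i, j] * r[j] * prod_k (1 - f[i, j, k] * p[i, k])
    m[i]    = sum_j m[i, j]

Weights adapt on-line with a local, nonlinear Hebbian rule: a saturating
growth term driven by the local subcompartment drive and a quadratic decay,

    dc[i, j] = gamma_a * m[i, j] * (1 - c[i, j]) - gamma_b * c[i, j]**2
    dd[i, k] = delta_a * r[k]    * (1 - d[i, k]) - delta_b * d[i, k]**2

The quadratic decay gives the characteristic fast-then-slow decay of a
deprived synapse (under r = 0 both rules reduce to pure quadratic decay) and
lets small weights persist far longer than a linear decay would, so a
connection can recover when its sensor comes back.  f is fixed (no adaptation
rule for the inhibitory synapses).

The PG growth term uses the subcompartment's afferent signal r[k] rather
than its own potential p[i, k] = d[i, k] * r[k]: with the stated rates
(delta_b ~ 1.26) the self-referential form is degenerate — d = 0 is
absorbing and any d above ~0.8 crashes to zero within one step, silencing
the periglomerular pathway permanently.  The self-referential variant
remains available through ``LearningRates.d_drive = "potential"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .sensor_sim import FaultSpec, ResponseMatrix

__all__ = [
    "LearningRates",
    "GlomerularNetwork",
    "NetworkTrace",
    "default_class_mask",
    "init_network",
    "pg_potentials",
    "mc_branch_potentials",
    "mc_outputs",
    "update_weights",
    "process_sequence",
    "disinhibition_check",
]


@dataclass(frozen=True)
class LearningRates:
    """Synaptic learning speeds (dimensionless, per presentation) and the
    drive of the PG growth term ("input": the afferent signal r_k, default;
    "potential": the subcompartment potential p_ik)."""

    gamma_a: float = 5 * 10 ** -0.7
    gamma_b: float = 10 ** -0.7
    delta_a: float = 10 ** -0.6
    delta_b: float = 5 * 10 ** -0.6
    d_drive: str = "input"

    def __post_init__(self):
        for name in ("gamma_a", "gamma_b", "delta_a", "delta_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_drive not in ("input", "potential"):
            raise ValueError("d_drive must be 'input' or 'potential'")


def default_class_mask(L: int = 4, N: int = 16) -> np.ndarray:
    """Contiguous class mask: sensors [i*N//L, (i+1)*N//L) belong to unit i."""
    if N % L:
        raise ValueError("N must be a multiple of L for the default mask")
    q = N // L
    mask = np.zeros((L, N), dtype=int)
    for i in range(L):
        mask[i, i * q:(i + 1) * q] = 1
    return mask


@dataclass
class GlomerularNetwork:
    """Network state: excitatory weights c, PG weights d, fixed inhibition f.

    Invariants kept at all times: 0 <= c, d <= 1; 0 <= f <= 0.1; c is exactly
    zero off the class mask; f rows for non-existent branches are zero.
    """

    L: int
    N: int
    class_mask: np.ndarray
    c: np.ndarray
    d: np.ndarray
    f: np.ndarray
    rates: LearningRates = field(default_factory=LearningRates)

    def __post_init__(self):
        self.class_mask = np.asarray(self.class_mask, dtype=int)
        self.c = np.asarray(self.c, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.class_mask.shape != (self.L, self.N):
            raise ValueError("class_mask must be L x N")
        if self.c.shape != (self.L, self.N) or self.d.shape != (self.L, self.N):
            raise ValueError("c and d must be L x N")
        if self.f.shape != (self.L, self.N, self.N):
            raise ValueError("f must be L x N x N")
        if np.any((self.class_mask != 0) & (self.class_mask != 1)):
            raise ValueError("class_mask must be binary")
        if np.any(self.c[self.class_mask == 0] != 0):
            raise ValueError("masked-out c entries must be exactly zero")
        if self.c.min() < 0 or self.c.max() > 1 or self.d.min() < 0 or self.d.max() > 1:
            raise ValueError("c and d must lie in [0, 1]")
        if self.f.min() < 0 or self.f.max() > 0.1 + 1e-15:
            raise ValueError("f must lie in [0, 0.1]")

    def copy(self) -> "GlomerularNetwork":
        # f is immutable over time, share it
        return GlomerularNetwork(self.L, self.N, self.class_mask, self.c.copy(),
                                 self.d.copy(), self.f, self.rates)

    # --- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "L": self.L, "N": self.N,
            "class_mask": self.class_mask.tolist(),
            "c": self.c.tolist(), "d": self.d.tolist(), "f": self.f.tolist(),
            "rates": {"gamma_a": self.rates.gamma_a, "gamma_b": self.rates.gamma_b,
                      "delta_a": self.rates.delta_a, "delta_b": self.rates.delta_b,
                      "d_drive": self.rates.d_drive},
        })

    @classmethod
    def from_json(cls, text: str) -> "GlomerularNetwork":
        obj = json.loads(text)
        return cls(obj["L"], obj["N"], np.array(obj["class_mask"]),
                   np.array(obj["c"]), np.array(obj["d"]), np.array(obj["f"]),
                   LearningRates(**obj["rates"]))


@dataclass
class NetworkTrace:
    """Per-sample record of a processed stream."""

    mc_outputs: np.ndarray                    # samples x L
    sample_index: np.ndarray                  # samples
    branch_potentials: np.ndarray | None = None   # samples x L x N
    c_trace: np.ndarray | None = None             # samples x L x N (pre-update)
    d_trace: np.ndarray | None = None


def init_network(L: int = 4, N: int = 16, class_mask: np.ndarray | None = None,
                 f_density: float = 0.5, seed: int = 0,
                 rates: LearningRates | None = None) -> GlomerularNetwork:
    """Random initial state.

    c ~ U(0,1) on masked-in entries (zero elsewhere); d ~ U(0,1) everywhere
    (PG cells listen to every channel); f ~ U(0, 0.1) masked by independent
    Bernoulli(f_density) draws, zeroed where the MC branch does not exist.
    """
    if class_mask is None:
        class_mask = default_class_mask(L, N)
    class_mask = np.asarray(class_mask, dtype=int)
    if class_mask.shape != (L, N):
        raise ValueError("class_mask must be L x N")
    if np.any(class_mask.sum(axis=1) == 0):
        raise ValueError("every glomerular unit needs at least one sensor")
    if np.any(class_mask.sum(axis=0) != 1):
        raise ValueError("every sensor must belong to exactly one class")
    if not 0 <= f_density <= 1:
        raise ValueError("f_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    c = rng.uniform(0.0, 1.0, size=(L, N)) * class_mask
    d = rng.uniform(0.0, 1.0, size=(L, N))
    f = rng.uniform(0.0, 0.1, size=(L, N, N))
    f *= rng.random(size=(L, N, N)) < f_density
    f *= class_mask[:, :, None]  # no inhibition onto a branch that does not exist
    return GlomerularNetwork(L, N, class_mask, c, d, f,
                             rates if rates is not None else LearningRates())


def _check_input(net: GlomerularNetwork, r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (net.N,):
        raise ValueError(f"expected a length-{net.N} response vector")
    if not np.all(np.isfinite(r)) or r.min() < -1e-12 or r.max() > 1 + 1e-12:
        raise ValueError("responses must be finite and normalized to [0, 1]")
    return np.clip(r, 0.0, 1.0)


def pg_potentials(net: GlomerularNetwork, r: np.ndarray) -> np.ndarray:
    """p[i, k] = d[i, k] * r[k]."""
    r = _check_input(net, r)
    return net.d * r[None, :]


def mc_branch_potentials(net: GlomerularNetwork, r: np.ndarray,
                         p: np.ndarray) -> np.ndarray:
    """m[i, j] = c[i, j] * r[j] * prod_k (1 - f[i, j, k] * p[i, k])."""
    r = _check_input(net, r)
    factors = 1.0 - net.f * p[:, None, :]
    if factors.min() < 0:
        raise RuntimeError("negative inhibition factor: f/p outside their boxes")
    return net.c * r[None, :] * np.prod(factors, axis=2)


def mc_outputs(m_branch: np.ndarray) -> np.ndarray:
    """m[i] = sum_j m[i, j]."""
    m_branch = np.asarray(m_branch, dtype=float)
    if not np.all(np.isfinite(m_branch)) or m_branch.min() < 0:
        raise ValueError("branch potentials must be finite and non-negative")
    return m_branch.sum(axis=1)


def update_weights(net: GlomerularNetwork, r: np.ndarray, m_branch: np.ndarray,
                   p: np.ndarray) -> GlomerularNetwork:
    """One plasticity step; returns a new network (f shared, unchanged)."""
    g = net.rates
    r = np.asarray(r, dtype=float)
    dc = g.gamma_a * m_branch * (1.0 - net.c) - g.gamma_b * net.c ** 2
    d_drive = p if g.d_drive == "potential" else np.broadcast_to(r, net.d.shape)
    dd = g.delta_a * d_drive * (1.0 - net.d) - g.delta_b * net.d ** 2
    if not (np.all(np.isfinite(dc)) and np.all(np.isfinite(dd))):
        raise FloatingPointError("non-finite weight update")
    c = np.clip(net.c + dc, 0.0, 1.0) * net.class_mask
    d = np.clip(net.d + dd, 0.0, 1.0)
    return GlomerularNetwork(net.L, net.N, net.class_mask, c, d, net.f, net.rates)


def process_sequence(net: GlomerularNetwork, data: ResponseMatrix,
                     adapt: bool = True,
                     faults: list[FaultSpec] | None = None,
                     record_branches: bool = False,
                     record_weights: bool = False,
                     fault_seed: int = 0) -> tuple[GlomerularNetwork, NetworkTrace]:
    """Run the stream through the network sample by sample.

    Per sample: apply active faults to r, compute the forward pass with the
    *current* weights, record the outputs, then (if ``adapt``) update the
    weights.  Recording before updating means a downstream classifier always
    sees pre-update responses.
    """
    if data.n_channels != net.N:
        raise ValueError(f"data has {data.n_channels} channels, network expects {net.N}")
    if faults:
        from .sensor_sim import apply_fault
        for i, fs in enumerate(faults):
            data = apply_fault(data, fs, seed=fault_seed + i)
    n = data.n_samples
    trace_m = np.empty((n, net.L))
    trace_b = np.empty((n, net.L, net.N)) if record_branches else None
    trace_c = np.empty((n, net.L, net.N)) if record_weights else None
    trace_d = np.empty((n, net.L, net.N)) if record_weights else None
    net = net.copy()
    for t in range(n):
        r = data.values[t]
        p = pg_potentials(net, r)
        mb = mc_branch_potentials(net, r, p)
        trace_m[t] = mb.sum(axis=1)
        if record_branches:
            trace_b[t] = mb
        if record_weights:
            trace_c[t] = net.c
            trace_d[t] = net.d
        if adapt:
            net = update_weights(net, r, mb, p)
    return net, NetworkTrace(trace_m, data.sample_index.copy(), trace_b,
                             trace_c, trace_d)


def disinhibition_check(net: GlomerularNetwork, r: np.ndarray, k: int) -> np.ndarray:
    """Branch-potential change caused by silencing channel ``k`` at fixed
    weights: m[i, j](r with r_k = 0) - m[i, j](r), for branches j != k.

    Column k of the returned L x N matrix is set to 0 (that branch loses its
    own drive; the disinhibition statement concerns the *other* branches).
    Every returned entry is >= 0: removing an inhibitory factor can only
    increase a product of terms in (0, 1].
    """
    r = _check_input(net, r)
    if not 0 <= k < net.N:
        raise ValueError("channel out of range")
    m0 = mc_branch_potentials(net, r, pg_potentials(net, r))
    r2 = r.copy()
    r2[k] = 0.0
    m1 = mc_branch_potentials(net, r2, pg_potentials(net, r2))
    delta = m1 - m0
    delta[:, k] = 0.0
    return delta
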