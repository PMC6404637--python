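"""Network structure: populations, random connectivity, weight classes, delays.

The model is a recurrent network of leaky integrate-and-fire neurons split into
``p`` item-selective excitatory populations (Es1..Esp, each ``f*N_E`` neurons),
one non-selective excitatory population (Ens, the remaining ``(1-p*f)*N_E``
neurons) and one inhibitory population (I).  Every ordered pair of distinct
neurons is connected independently with probability ``c``.  E->E synapses carry
one of three static efficacies: the potentiated value ``J_p`` within a
selective population, the baseline ``J_b`` between different selective
populations, and a gamma-mixture of the two (``J_p`` with probability
``gamma``) for connections involving the non-selective population.  E->I, I->E
and I->I efficacies are fixed scalars.  Only E->E synapses are dynamic
(short-term facilitation/depression); their presynaptic state (u, x) lives on
the presynaptic neuron, shared across all of its outgoing E->E synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NetworkSpec",
    "PopulationLayout",
    "SynapseTable",
    "build_layout",
    "sample_connectivity",
]

#: weight-class codes stored per synapse
EE_POTENTIATED, EE_BASELINE, EI, IE, II = 0, 1, 2, 3, 4
CLASS_NAMES = {
    EE_POTENTIATED: "EE_potentiated",
    EE_BASELINE: "EE_baseline",
    EI: "EI",
    IE: "IE",
    II: "II",
}


@dataclass(frozen=True)
class NetworkSpec:
    """All structural, cellular, synaptic and short-term-plasticity parameters.

    Defaults are the desk-scale reference network: the full-size model scaled
    to N_E=2000, N_I=500 with the connection probability raised to c=0.8 so
    that the mean in-degree (2000) matches the full-size network.  Use
    :meth:`paper_scale` for the original sizes.

    Per-class values (theta, V_r, tau_m, mu_ext, sigma_ext) are (E, I) pairs
    in mV / ms.
    """

    N_E: int = 2000
    N_I: int = 500
    p: int = 5
    f: float = 0.10
    c: float = 0.80
    gamma: float = 0.10
    J_b: float = 0.10
    J_p: float = 0.45
    J_EI: float = 0.135
    J_IE: float = 0.25
    J_II: float = 0.20
    theta: tuple[float, float] = (20.0, 20.0)
    V_r: tuple[float, float] = (16.0, 13.0)
    tau_m: tuple[float, float] = (15.0, 10.0)
    tau_arp: float = 2.0
    mu_ext: tuple[float, float] = (23.8, 21.0)
    sigma_ext: tuple[float, float] = (1.0, 1.0)
    U: float = 0.20
    X: float = 1.00
    tau_u: float = 1500.0
    tau_x: float = 200.0
    delay_range: tuple[float, float] = (0.0, 1.0)
    #: weight-class rule for Ens->Es connections: gamma-mixture like Ens->Ens
    #: (True) or pure baseline (False).  The mixture is the package default.
    ens_to_es_mixture: bool = True

    def __post_init__(self) -> None:
        if self.N_E <= 0 or self.N_I <= 0:
            raise ValueError("N_E and N_I must be positive")
        if not 0 < self.f * self.p <= 1:
            raise ValueError(f"need 0 < f*p <= 1, got f*p={self.f * self.p}")
        fn = self.f * self.N_E
        if abs(fn - round(fn)) > 1e-9:
            raise ValueError(f"f*N_E must be integral, got f={self.f} * N_E={self.N_E} = {fn}")
        if not 0 <= self.c <= 1:
            raise ValueError(f"connection probability c must be in [0, 1], got {self.c}")
        if not 0 <= self.gamma <= 1:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0 < self.U <= 1:
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        if self.X <= 0:
            raise ValueError("X must be positive")
        for name in ("tau_arp", "tau_u", "tau_x"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for tm in self.tau_m:
            if tm <= 0:
                raise ValueError("membrane time constants must be positive")
        for vr, th in zip(self.V_r, self.theta):
            if vr >= th:
                raise ValueError(f"reset potential {vr} must lie below threshold {th}")
        for j in (self.J_b, self.J_p, self.J_EI, self.J_IE, self.J_II):
            if j < 0:
                raise ValueError("synaptic efficacies must be non-negative")
        lo, hi = self.delay_range
        if not 0 <= lo < hi:
            raise ValueError(f"invalid delay range {self.delay_range}")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def es_size(self) -> int:
        return round(self.f * self.N_E)

    @classmethod
    def paper_scale(cls, **overrides) -> "NetworkSpec":
        """The full-size configuration (8000 E / 2000 I, c=0.2)."""
        return cls(N_E=8000, N_I=2000, c=0.20, **overrides)

    def with_(self, **overrides) -> "NetworkSpec":
        return replace(self, **overrides)


@dataclass(frozen=True)
class PopulationLayout:
    """Index ranges partitioning [0, N_E + N_I) into Es1..Esp, Ens, I."""

    labels: tuple[str, ...]
    starts: tuple[int, ...]
    stops: tuple[int, ...]

    def range_of(self, label: str) -> tuple[int, int]:
        i = self.labels.index(label)
        return self.starts[i], self.stops[i]

    def slice_of(self, label: str) -> slice:
        lo, hi = self.range_of(label)
        return slice(lo, hi)

    def size_of(self, label: str) -> int:
        lo, hi = self.range_of(label)
        return hi - lo

    @property
    def es_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l.startswith("Es"))

    def label_of(self, idx: int) -> str:
        for label, lo, hi in zip(self.labels, self.starts, self.stops):
            if lo <= idx < hi:
                return label
        raise IndexError(f"neuron index {idx} outside layout")

    def membership(self) -> np.ndarray:
        """Array of population labels, one per neuron index."""
        n = self.stops[-1]
        out = np.empty(n, dtype=object)
        for label, lo, hi in zip(self.labels, self.starts, self.stops):
            out[lo:hi] = label
        return out


def build_layout(spec: NetworkSpec) -> PopulationLayout:
    """Partition neuron indices into p selective populations, Ens and I.

    Selective populations occupy the first ``p * f * N_E`` excitatory indices
    in consecutive blocks; the remaining excitatory indices form Ens (possibly
    empty when ``p*f == 1``); inhibitory neurons follow.
    """
    es = spec.es_size
    labels: list[str] = []
    starts: list[int] = []
    stops: list[int] = []
    pos = 0
    for k in range(spec.p):
        labels.append(f"Es{k + 1}")
        starts.append(pos)
        stops.append(pos + es)
        pos += es
    labels.append("Ens")
    starts.append(pos)
    stops.append(spec.N_E)
    labels.append("I")
    starts.append(spec.N_E)
    stops.append(spec.N)
    return PopulationLayout(tuple(labels), tuple(starts), tuple(stops))


@dataclass
class SynapseTable:
    """Sparse connectivity in CSR-by-presynaptic-neuron form.

    ``indptr[j]:indptr[j+1]`` addresses the outgoing synapses of neuron ``j``
    in ``targets`` / ``weights`` / ``delay_steps`` / ``weight_class``.
    ``weights`` holds the static efficacy J_ij in mV (before any dopamine
    scaling); ``delay_steps`` the transmission delay in integration steps
    (>= 1).  ``u`` and ``x`` are the per-presynaptic-excitatory-neuron
    short-term-plasticity state used to initialize a simulation.
    """

    indptr: np.ndarray
    targets: np.ndarray
    weights: np.ndarray
    delay_steps: np.ndarray
    weight_class: np.ndarray
    dt: float
    N_E: int
    N_I: int
    u: np.ndarray = field(default=None)  # type: ignore[assignment]
    x: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_synapses(self) -> int:
        return int(self.targets.size)

    @property
    def max_delay_steps(self) -> int:
        return int(self.delay_steps.max()) if self.n_synapses else 1

    def scaled_weights(self, A_EE: float, A_EI: float) -> np.ndarray:
        """Apply dopamine scaling factors: A_EE multiplies all E->E classes,
        A_EI multiplies E->I; I->E and I->I are never scaled."""
        w = self.weights.astype(np.float64, copy=True)
        ee = (self.weight_class == EE_POTENTIATED) | (self.weight_class == EE_BASELINE)
        w[ee] *= A_EE
        w[self.weight_class == EI] *= A_EI
        return w

    def to_frame(self) -> pd.DataFrame:
        """Flat per-connection table (pre, post, class, J, delay_ms)."""
        pre = np.repeat(np.arange(self.indptr.size - 1), np.diff(self.indptr))
        return pd.DataFrame(
            {
                "pre": pre.astype(np.int64),
                "post": self.targets.astype(np.int64),
                "class": [CLASS_NAMES[int(cl)] for cl in self.weight_class],
                "J": self.weights.astype(float),
                "delay_ms": self.delay_steps.astype(float) * self.dt,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_connectivity(
    spec: NetworkSpec,
    layout: PopulationLayout,
    seed: int,
    dt: float = 0.1,
) -> SynapseTable:
    """Draw the random connectivity and assign weight classes and delays.

    Each ordered pair (j -> i), j != i, is connected independently with
    probability ``c``.  Delays are uniform on ``delay_range`` and quantized
    *up* to the integration grid (minimum one step) so causality is strict.
    E->E dynamic state is initialized at the baselines (u=U, x=X).
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    N, N_E = spec.N, spec.N_E

    # per-neuron population code: 0..p-1 selective, p = Ens, p+1 = I
    pop_code = np.empty(N, dtype=np.int32)
    for k, label in enumerate(layout.labels):
        pop_code[layout.slice_of(label)] = k
    ens_code = spec.p

    indptr = np.zeros(N + 1, dtype=np.int64)
    tg_rows: list[np.ndarray] = []
    wt_rows: list[np.ndarray] = []
    cl_rows: list[np.ndarray] = []

    lo_d, hi_d = spec.delay_range
    for j in range(N):
        tgt = np.flatnonzero(rng.random(N) < spec.c).astype(np.int32)
        tgt = tgt[tgt != j]
        indptr[j + 1] = indptr[j] + tgt.size
        cls = np.empty(tgt.size, dtype=np.int8)
        w = np.empty(tgt.size, dtype=np.float64)
        post_exc = tgt < N_E
        if j < N_E:  # excitatory presynaptic
            cls[~post_exc] = EI
            w[~post_exc] = spec.J_EI
            pe = np.flatnonzero(post_exc)
            jc = pop_code[j]
            tc = pop_code[tgt[pe]]
            if jc < spec.p:
                same = tc == jc
                other_sel = (tc < spec.p) & ~same
                to_ens = tc == ens_code
            else:  # presynaptic in Ens
                same = np.zeros(pe.size, dtype=bool)
                other_sel = (
                    np.zeros(pe.size, dtype=bool) if spec.ens_to_es_mixture else tc < spec.p
                )
                to_ens = ~other_sel
            # gamma-mixture block: Es->Ens, Ens->Ens and (by default) Ens->Es
            mix = to_ens
            pot = rng.random(pe.size) < spec.gamma
            c_ee = np.where(same | (mix & pot), EE_POTENTIATED, EE_BASELINE).astype(np.int8)
            cls[pe] = c_ee
            w[pe] = np.where(c_ee == EE_POTENTIATED, spec.J_p, spec.J_b)
        else:  # inhibitory presynaptic
            cls[post_exc] = IE
            w[post_exc] = spec.J_IE
            cls[~post_exc] = II
            w[~post_exc] = spec.J_II
        tg_rows.append(tgt)
        wt_rows.append(w)
        cl_rows.append(cls)

    targets = np.concatenate(tg_rows) if tg_rows else np.empty(0, dtype=np.int32)
    weights = np.concatenate(wt_rows) if wt_rows else np.empty(0)
    classes = np.concatenate(cl_rows) if cl_rows else np.empty(0, dtype=np.int8)

    n_syn = targets.size
    raw = rng.uniform(lo_d, hi_d, size=n_syn)
    delay_steps = np.maximum(1, np.ceil(raw / dt - 1e-12)).astype(np.int32)

    u0 = np.full(N_E, spec.U)
    x0 = np.full(N_E, spec.X)
    return SynapseTable(
        indptr=indptr,
        targets=targets,
        weights=weights,
        delay_steps=delay_steps,
        weight_class=classes,
        dt=dt,
        N_E=N_E,
        N_I=spec.N_I,
        u=u0,
        x=x0,
    )
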