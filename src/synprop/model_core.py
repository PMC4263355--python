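"""Single-neuron dynamics: membrane, synaptic kernels and the nonlinear dendrite.

The neuron is a conductance-based leaky integrate-and-fire unit.  Synaptic
inputs cause transient conductance changes shaped as a difference of two
exponentials, normalized so that an input of strength ``eps`` (in nS)
produces a peak conductance of exactly ``eps``.

In the *non-additive* coupling mode each neuron carries an extra nonlinear
dendrite: if the summed excitatory input arriving within a short integration
window exceeds a dendritic threshold, an all-or-none stereotyped current
pulse is injected into the soma after a fixed latency, after which the
dendrite is refractory.  Only excitatory input counts towards the dendritic
threshold; inhibition acts solely at the soma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseKernel",
    "DendriteParams",
    "NeuronState",
    "conductance_kernel",
    "kernel_peak_time",
    "kernel_norm_const",
    "kernel_integral",
    "balanced_inhibitory_strength",
    "balance_ratio",
    "dendritic_current",
    "update_dendrite",
    "step_membrane",
]


# --------------------------------------------------------------------------- #
# parameter containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class NeuronParams:
    """Membrane constants of a leaky integrate-and-fire neuron.

    Units: capacitance pF, conductance nS, potentials mV, times ms.
    """

    C_m: float = 400.0       #: membrane capacitance (pF)
    g_L: float = 25.0        #: leak conductance (nS)
    E_L: float = -65.0       #: leak/equilibrium potential (mV)
    V_theta: float = -50.0   #: somatic spike threshold (mV)
    V_reset: float = -65.0   #: reset potential (mV)
    t_ref: float = 3.0       #: absolute refractory period (ms)

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if not self.V_reset < self.V_theta:
            raise ValueError("V_reset must lie below V_theta")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_L (ms)."""
        return self.C_m / self.g_L


@dataclass(frozen=True)
class SynapseKernel:
    """Difference-of-exponentials conductance time course.

    The peak of the kernel is normalized to 1, so an input of strength
    ``eps`` yields a peak conductance ``eps``.
    """

    tau_rise: float = 0.5    #: rise time constant (ms)
    tau_decay: float = 2.0   #: decay time constant (ms)
    E_rev: float = 0.0       #: reversal potential (mV)

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")

    @property
    def t_peak(self) -> float:
        return kernel_peak_time(self.tau_rise, self.tau_decay)

    @property
    def norm_const(self) -> float:
        return kernel_norm_const(self.tau_rise, self.tau_decay)


@dataclass(frozen=True)
class DendriteParams:
    """Constants of the nonlinear (dendritic-spike generating) dendrite."""

    window: float = 2.0       #: integration window length (ms)
    threshold: float = 8.65   #: dendritic threshold on summed peak conductance (nS)
    cap: float = 17.3         #: maximal conductance change counted within one window (nS)
    latency: float = 2.7      #: delay from threshold crossing to somatic current onset (ms)
    amps: tuple[float, float, float] = (6.0, 3.0, 1.5)   #: current prefactors (nA)
    taus: tuple[float, float, float] = (0.5, 1.0, 2.0)   #: decay time constants (ms)
    t_ref_d: float = 5.0      #: dendritic refractory period (ms)

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.cap < self.threshold:
            raise ValueError("cap must be at least the dendritic threshold")
        if self.latency < 0:
            raise ValueError("latency must be non-negative")
        if self.t_ref_d < self.window:
            raise ValueError("dendritic refractory period must cover the window")
        if any(a < 0 for a in self.amps):
            raise ValueError("current prefactors must be positive")
        if any(t <= 0 for t in self.taus):
            raise ValueError("current time constants must be positive")


@dataclass
class NeuronState:
    """Mutable per-neuron integration state (reference implementation)."""

    V: float
    t: float = 0.0
    t_last_spike: float = -np.inf
    t_last_dspike: float = -np.inf
    window_buffer: list = field(default_factory=list)     #: [(arrival time, strength)]
    pending_currents: list = field(default_factory=list)  #: scheduled current onset times


# --------------------------------------------------------------------------- #
# synaptic kernel
# --------------------------------------------------------------------------- #

@lru_cache(maxsize=None)
def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the kernel maximum (ms)."""
    return (tau_decay * tau_rise / (tau_decay - tau_rise)) * math.log(tau_decay / tau_rise)


@lru_cache(maxsize=None)
def kernel_norm_const(tau_rise: float, tau_decay: float) -> float:
    """Normalization constant setting the kernel peak to 1."""
    tp = kernel_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def kernel_integral(kernel: SynapseKernel) -> float:
    """Time integral of the unit-peak kernel (ms); used for mean-drive estimates."""
    return kernel.norm_const * (kernel.tau_decay - kernel.tau_rise)


def conductance_kernel(t_since_arrival, kernel: SynapseKernel):
    """Unit-peak conductance time course; 0 for negative times.

    Accepts scalars or arrays and is a total function of time.
    """
    t = np.asarray(t_since_arrival, dtype=float)
    out = np.where(
        t >= 0,
        kernel.norm_const
        * (np.exp(-np.clip(t, 0, None) / kernel.tau_decay)
           - np.exp(-np.clip(t, 0, None) / kernel.tau_rise)),
        0.0,
    )
    if np.isscalar(t_since_arrival):
        return float(out)
    return out


# --------------------------------------------------------------------------- #
# excitation/inhibition balance
# --------------------------------------------------------------------------- #

def _psp_peak(eps: float, kernel: SynapseKernel, neuron: NeuronParams,
              dt: float = 0.01, t_max: float = 50.0) -> float:
    """Peak deviation of the membrane potential from rest after a single input."""
    n = int(round(t_max / dt))
    V = neuron.E_L
    extremum = 0.0
    t = 0.0
    for _ in range(n):
        g = eps * conductance_kernel(t, kernel)
        g_tot = neuron.g_L + g
        V_inf = (neuron.g_L * neuron.E_L + g * kernel.E_rev) / g_tot
        V = V_inf + (V - V_inf) * math.exp(-g_tot * dt / neuron.C_m)
        t += dt
        dev = V - neuron.E_L
        if abs(dev) > abs(extremum):
            extremum = dev
    return extremum


@lru_cache(maxsize=None)
def balance_ratio(neuron: NeuronParams, kernel_ex: SynapseKernel,
                  kernel_in: SynapseKernel, reference_eps: float = 1.0) -> float:
    """Ratio ``alpha`` such that an inhibitory input of strength
    ``alpha * reference_eps`` produces a hyperpolarization from rest whose
    peak magnitude equals the peak depolarization of an excitatory input of
    strength ``reference_eps``.

    Determined numerically, once per parameter set (cached).
    """
    if not (kernel_in.E_rev < neuron.E_L < kernel_ex.E_rev):
        raise ValueError("reversal potentials must bracket the resting potential")
    target = _psp_peak(reference_eps, kernel_ex, neuron)
    if target <= 0:
        raise ValueError("excitatory input produced no depolarization")

    from scipy.optimize import brentq

    def f(alpha: float) -> float:
        return abs(_psp_peak(alpha * reference_eps, kernel_in, neuron)) - target

    lo, hi = 1e-6, 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket the balance ratio")
    return float(brentq(f, lo, hi, xtol=1e-6))


def balanced_inhibitory_strength(eps_ex: float, neuron: NeuronParams,
                                 kernel_ex: SynapseKernel, kernel_in: SynapseKernel,
                                 reference_eps: float = 1.0) -> float:
    """Inhibitory strength balancing an excitatory input of strength ``eps_ex``.

    The balance ratio is computed at a fixed reference strength so that the
    returned value is exactly linear in ``eps_ex``.
    """
    if eps_ex < 0:
        raise ValueError("eps_ex must be non-negative")
    if eps_ex == 0:
        return 0.0
    return balance_ratio(neuron, kernel_ex, kernel_in, reference_eps) * eps_ex


# --------------------------------------------------------------------------- #
# nonlinear dendrite
# --------------------------------------------------------------------------- #

def dendritic_current(t_since_onset, dendrite: DendriteParams):
    """Stereotyped dendritic-spike current (nA); 0 for negative times.

    The waveform is independent of the input that triggered it (all-or-none).
    """
    t = np.asarray(t_since_onset, dtype=float)
    tc = np.clip(t, 0, None)
    val = sum(a * np.exp(-tc / tau) for a, tau in zip(dendrite.amps, dendrite.taus))
    out = np.where(t >= 0, val, 0.0)
    if np.isscalar(t_since_onset):
        return float(out)
    return out


def update_dendrite(state: NeuronState, event: tuple[float, float],
                    dendrite: DendriteParams):
    """Register an excitatory event on the nonlinear dendrite.

    Returns the somatic current onset time if the event completes a
    suprathreshold window, else ``None``.  Events arriving while the
    dendrite is refractory still cause their ordinary conductance change
    (handled by the caller) but neither count towards nor trigger a
    dendritic spike.
    """
    t, strength = event
    if t < state.t_last_dspike + dendrite.t_ref_d:
        return None
    # evict events that left the trailing window (t - window, t]
    state.window_buffer = [(ti, si) for ti, si in state.window_buffer
                           if ti > t - dendrite.window]
    state.window_buffer.append((t, strength))
    raw = sum(s for _, s in state.window_buffer)
    counted = min(raw, dendrite.cap)
    if counted >= dendrite.threshold:
        state.t_last_dspike = t
        state.window_buffer.clear()
        onset = t + dendrite.latency
        state.pending_currents.append(onset)
        return onset
    return None


# --------------------------------------------------------------------------- #
# membrane integration (reference, single neuron)
# --------------------------------------------------------------------------- #

def step_membrane(state: NeuronState, dt: float, conductances: tuple[float, float],
                  external_current: float, neuron: NeuronParams,
                  kernel_ex: SynapseKernel, kernel_in: SynapseKernel,
                  dendrite: DendriteParams | None = None):
    """Advance the membrane by one step of the exponential-Euler scheme.

    Conductances are held constant over the step.  Returns ``True`` if a
    somatic spike was emitted during the step.  During somatic
    refractoriness the potential is clamped at ``V_reset``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g_ex, g_in = conductances
    t_new = state.t + dt
    if state.t < state.t_last_spike + neuron.t_ref:
        state.V = neuron.V_reset
        state.t = t_new
        return False
    I = external_current
    if dendrite is not None and state.pending_currents:
        for onset in state.pending_currents:
            I += dendritic_current(state.t - onset, dendrite)
        horizon = 20.0 * max(dendrite.taus)
        state.pending_currents = [o for o in state.pending_currents
                                  if state.t - o < horizon]
    g_tot = neuron.g_L + g_ex + g_in
    # I is in nA; conductance * potential terms are nS * mV = pA
    V_inf = (neuron.g_L * neuron.E_L + g_ex * kernel_ex.E_rev
             + g_in * kernel_in.E_rev + 1e3 * I) / g_tot
    state.V = V_inf + (state.V - V_inf) * math.exp(-g_tot * dt / neuron.C_m)
    state.t = t_new
    if state.V >= neuron.V_theta:
        state.V = neuron.V_reset
        state.t_last_spike = t_new
        return True
    return False
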