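"""External drive: homogeneous Poisson background and oscillatory input from a
virtual source population.

The oscillatory drive is produced by ``n_osc`` virtual neurons each spiking
once per cycle, with Gaussian within-cycle jitter.  Every source spike is
delivered to every network neuron independently: excitatory with probability
``p_deliver_ex`` and inhibitory with probability ``p_deliver_in``; the
inhibitory strength is scaled by the unbalance factor ``g`` (g = 1 balanced,
g < 1 net depolarizing, g > 1 net hyperpolarizing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import rng as _rng
from .model_core import NeuronParams, SynapseKernel, balance_ratio

__all__ = [
    "BackgroundSpec", "OscillationSpec", "ExternalEvents",
    "generate_background", "generate_oscillation", "oscillation_source_spikes",
    "effective_mean_drive",
]


@dataclass(frozen=True)
class BackgroundSpec:
    """Independent excitatory/inhibitory Poisson spike trains per neuron."""

    rate_ex: float = 1.0    #: kHz
    rate_in: float = 1.0    #: kHz
    eps_ex: float = 1.0     #: nS
    eps_in: float = 6.626   #: nS (approximately balanced for standard parameters)

    def __post_init__(self):
        if self.rate_ex < 0 or self.rate_in < 0:
            raise ValueError("rates must be non-negative")
        if self.eps_ex < 0 or self.eps_in < 0:
            raise ValueError("strengths must be non-negative")

    @classmethod
    def balanced(cls, rate: float, eps_ex: float, neuron: NeuronParams,
                 kernel_ex: SynapseKernel, kernel_in: SynapseKernel
                 ) -> "BackgroundSpec":
        alpha = balance_ratio(neuron, kernel_ex, kernel_in)
        return cls(rate_ex=rate, rate_in=rate, eps_ex=eps_ex,
                   eps_in=alpha * eps_ex)


@dataclass(frozen=True)
class OscillationSpec:
    """Oscillatory virtual-population input."""

    n_osc: int = 0             #: virtual population size
    nu_stim: float = 180.0     #: oscillation frequency (Hz)
    sigma_osc: float = 0.5     #: within-cycle spike-time jitter (ms)
    p_deliver_ex: float = 0.25
    p_deliver_in: float = 0.25
    eps_ex: float = 0.2        #: nS
    eps_in: float = 1.325      #: nS (balanced partner of eps_ex before scaling)
    unbalance_g: float = 1.0   #: inhibition scaling factor
    phase: float = 0.0         #: time of the first cycle centre (ms)

    def __post_init__(self):
        if self.n_osc < 0:
            raise ValueError("n_osc must be non-negative")
        if self.nu_stim <= 0:
            raise ValueError("nu_stim must be positive")
        if not (0 <= self.p_deliver_ex <= 1 and 0 <= self.p_deliver_in <= 1):
            raise ValueError("delivery probabilities must lie in [0, 1]")
        if self.unbalance_g <= 0:
            raise ValueError("unbalance factor must be positive")

    @property
    def period(self) -> float:
        """Oscillation period (ms)."""
        return 1000.0 / self.nu_stim

    def with_frequency(self, nu: float) -> "OscillationSpec":
        return replace(self, nu_stim=nu)

    @classmethod
    def balanced(cls, n_osc: int, nu_stim: float, eps_ex: float,
                 neuron: NeuronParams, kernel_ex: SynapseKernel,
                 kernel_in: SynapseKernel, **kw) -> "OscillationSpec":
        alpha = balance_ratio(neuron, kernel_ex, kernel_in)
        return cls(n_osc=n_osc, nu_stim=nu_stim, eps_ex=eps_ex,
                   eps_in=alpha * eps_ex, **kw)


@dataclass
class ExternalEvents:
    """Flat record of external synaptic events (times in ms)."""

    neuron: np.ndarray     #: target neuron ids
    time: np.ndarray
    sign: np.ndarray       #: +1 excitatory, -1 inhibitory
    strength: np.ndarray   #: nS

    def __len__(self):
        return len(self.time)

    @classmethod
    def empty(cls) -> "ExternalEvents":
        z = np.empty(0)
        return cls(z.astype(np.int64), z.copy(), z.astype(np.int64), z.copy())

    @classmethod
    def concatenate(cls, streams) -> "ExternalEvents":
        streams = list(streams)
        return cls(*(np.concatenate([getattr(s, f) for s in streams])
                     for f in ("neuron", "time", "sign", "strength")))

    def to_csv(self, path: str | Path):
        pd.DataFrame({
            "neuron": self.neuron, "time_ms": self.time,
            "sign": np.where(self.sign > 0, "E", "I"),
            "strength_nS": self.strength,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExternalEvents":
        df = pd.read_csv(path)
        return cls(df["neuron"].to_numpy(np.int64),
                   df["time_ms"].to_numpy(float),
                   np.where(df["sign"].to_numpy() == "E", 1, -1).astype(np.int64),
                   df["strength_nS"].to_numpy(float))


# --------------------------------------------------------------------------- #
# generation
# --------------------------------------------------------------------------- #

def generate_background(spec: BackgroundSpec, n_neurons: int, duration: float,
                        seed: int) -> ExternalEvents:
    """Independent homogeneous Poisson event streams for every neuron."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng.stream(seed, "background")
    neuron_l, time_l, sign_l, eps_l = [], [], [], []
    for sign, rate, eps in ((1, spec.rate_ex, spec.eps_ex),
                            (-1, spec.rate_in, spec.eps_in)):
        if rate == 0:
            continue
        counts = rng.poisson(rate * duration, size=n_neurons)
        total = int(counts.sum())
        neuron_l.append(np.repeat(np.arange(n_neurons), counts))
        time_l.append(rng.uniform(0, duration, size=total))
        sign_l.append(np.full(total, sign, dtype=np.int64))
        eps_l.append(np.full(total, eps))
    if not neuron_l:
        return ExternalEvents.empty()
    ev = ExternalEvents(np.concatenate(neuron_l), np.concatenate(time_l),
                        np.concatenate(sign_l), np.concatenate(eps_l))
    order = np.argsort(ev.time, kind="stable")
    return ExternalEvents(ev.neuron[order], ev.time[order], ev.sign[order],
                          ev.strength[order])


def oscillation_source_spikes(spec: OscillationSpec, duration: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Source-population spike times on [0, duration).

    Cycle centres sit at ``phase + k * period``; Gaussian tails are not
    truncated at cycle boundaries (events falling outside the simulated
    interval are discarded).
    """
    if spec.n_osc == 0:
        return np.empty(0)
    centers = np.arange(spec.phase, duration, spec.period)
    times = rng.normal(loc=np.repeat(centers, spec.n_osc), scale=spec.sigma_osc)
    times = times[(times >= 0) & (times < duration)]
    return np.sort(times)


def generate_oscillation(spec: OscillationSpec, n_neurons: int, duration: float,
                         seed: int) -> ExternalEvents:
    """Explicit per-neuron delivery events of the oscillatory drive.

    Every (source spike, target, sign) delivery is drawn independently, so a
    single source spike can deliver both an excitatory and an inhibitory
    event to the same target.
    """
    if duration < spec.period:
        raise ValueError("duration must cover at least one oscillation period")
    rng = _rng.stream(seed, "oscillation")
    src_times = oscillation_source_spikes(spec, duration, rng)
    if len(src_times) == 0:
        return ExternalEvents.empty()
    neuron_l, time_l, sign_l, eps_l = [], [], [], []
    for sign, p, eps in ((1, spec.p_deliver_ex, spec.eps_ex),
                         (-1, spec.p_deliver_in,
                          spec.unbalance_g * spec.eps_in)):
        if p == 0 or eps == 0:
            continue
        mask = rng.random((len(src_times), n_neurons)) < p
        ii, jj = np.nonzero(mask)
        neuron_l.append(jj.astype(np.int64))
        time_l.append(src_times[ii])
        sign_l.append(np.full(len(ii), sign, dtype=np.int64))
        eps_l.append(np.full(len(ii), eps))
    if not neuron_l:
        return ExternalEvents.empty()
    ev = ExternalEvents(np.concatenate(neuron_l), np.concatenate(time_l),
                        np.concatenate(sign_l), np.concatenate(eps_l))
    order = np.argsort(ev.time, kind="stable")
    return ExternalEvents(ev.neuron[order], ev.time[order], ev.sign[order],
                          ev.strength[order])


def effective_mean_drive(spec: OscillationSpec) -> tuple[float, float]:
    """Time-averaged delivered input per neuron and sign (nS * spikes / s).

    Used to construct the matched constant current for the
    additive-equivalence experiment.
    """
    src_rate = spec.n_osc * spec.nu_stim  # source spikes per second
    ex = src_rate * spec.p_deliver_ex * spec.eps_ex
    inh = src_rate * spec.p_deliver_in * spec.unbalance_g * spec.eps_in
    return ex, inh
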