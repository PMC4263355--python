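"""Standard parameter set and flat config-file I/O.

The default values form a self-consistent hippocampal-like operating point:
a fluctuation-driven, balanced ground state with sparse spontaneous firing,
dendritic spikes triggered by synchronous input within a ~2 ms window, and a
natural layer-to-layer propagation frequency in the fast-ripple range.

All values can be overridden from a flat YAML or JSON mapping whose keys
match the attribute names below (units: pF, nS, mV, ms, kHz).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .model_core import DendriteParams, NeuronParams, SynapseKernel

__all__ = ["StandardParams", "standard_params", "load_params", "dump_params"]


@dataclass(frozen=True)
class StandardParams:
    """Flat view of the standard parameter set."""

    # membrane
    C_m: float = 400.0
    g_L: float = 25.0
    E_L: float = -65.0
    V_theta: float = -50.0
    V_reset: float = -65.0
    t_ref: float = 3.0
    # synaptic kernels (same time constants for both transmitter types)
    tau_rise_ex: float = 0.5
    tau_decay_ex: float = 2.0
    tau_rise_in: float = 0.5
    tau_decay_in: float = 2.0
    E_ex: float = 0.0
    E_in: float = -75.0
    # nonlinear dendrite
    dendrite_window: float = 2.0
    dendrite_threshold: float = 8.65
    dendrite_cap: float = 17.3
    dendrite_latency: float = 2.7
    dendrite_amp1: float = 6.0
    dendrite_amp2: float = 3.0
    dendrite_amp3: float = 1.5
    dendrite_tau1: float = 0.5
    dendrite_tau2: float = 1.0
    dendrite_tau3: float = 2.0
    dendrite_t_ref: float = 5.0
    # network
    p_ex: float = 0.05
    p_in: float = 0.05
    delay: float = 2.0
    # homogeneous Poisson background (rates in kHz)
    bg_rate_ex: float = 1.0
    bg_rate_in: float = 1.0
    bg_eps_ex: float = 1.0
    # detector
    det_window: float = 3.0
    det_max_shift: float = 10.0
    det_chance_const: float = 0.01
    det_snr_min: float = 3.0
    det_control_interval: float = 3000.0
    # integration
    dt: float = 0.1

    # ------------------------------------------------------------------ #
    def neuron(self) -> NeuronParams:
        return NeuronParams(C_m=self.C_m, g_L=self.g_L, E_L=self.E_L,
                            V_theta=self.V_theta, V_reset=self.V_reset,
                            t_ref=self.t_ref)

    def kernel_ex(self) -> SynapseKernel:
        return SynapseKernel(tau_rise=self.tau_rise_ex,
                             tau_decay=self.tau_decay_ex, E_rev=self.E_ex)

    def kernel_in(self) -> SynapseKernel:
        return SynapseKernel(tau_rise=self.tau_rise_in,
                             tau_decay=self.tau_decay_in, E_rev=self.E_in)

    def dendrite(self) -> DendriteParams:
        return DendriteParams(
            window=self.dendrite_window, threshold=self.dendrite_threshold,
            cap=self.dendrite_cap, latency=self.dendrite_latency,
            amps=(self.dendrite_amp1, self.dendrite_amp2, self.dendrite_amp3),
            taus=(self.dendrite_tau1, self.dendrite_tau2, self.dendrite_tau3),
            t_ref_d=self.dendrite_t_ref)


def standard_params(**overrides) -> StandardParams:
    """The standard parameter set, with optional keyword overrides."""
    return StandardParams(**overrides)


def load_params(path: str | Path) -> StandardParams:
    """Load a flat YAML or JSON parameter file; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    valid = set(StandardParams.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return StandardParams(**data)


def dump_params(params: StandardParams, path: str | Path) -> None:
    path = Path(path)
    data = asdict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
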