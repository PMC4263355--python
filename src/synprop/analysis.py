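"""Analysis layer: pulse-propagation detection, response curves, the binomial
iterated map with fixed-point/bifurcation analysis, and the higher-level
scans (critical coupling, resonance, locking, gating).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

from .network_gen import DelayModel, NetworkSpec, build_network
from .params import StandardParams
from .sim_engine import SimulationConfig, SpikeRecord, probe_response, run
from .stimuli import BackgroundSpec, OscillationSpec

__all__ = [
    "DetectorConfig", "LayerDetection", "PulseTrace", "detect_propagation",
    "propagation_frequency", "ResponseCurve", "estimate_response_curve",
    "IteratedMap", "build_map", "tangent_bifurcation",
    "PropagationSetup", "propagation_trial", "natural_frequency",
    "find_resonance", "critical_coupling_sim", "resonance_scan",
    "lock_ratio", "gating_experiment",
]


# --------------------------------------------------------------------------- #
# pulse detection
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class DetectorConfig:
    window: float = 3.0            #: count window length (ms)
    max_shift: float = 10.0         #: maximal lag of a pulse behind its predecessor (ms)
    chance_const: float = 0.01     #: chance-level probability constant
    snr_min: float = 3.0           #: minimal signal-to-noise ratio
    control_interval: float = 3000.0  #: control interval length (ms)
    shift_resolution: float = 0.1  #: lag search grid (ms)

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.chance_const < 1:
            raise ValueError("chance_const must lie in (0, 1)")
        if self.snr_min <= 0:
            raise ValueError("snr_min must be positive")


@dataclass
class LayerDetection:
    layer: int            #: 1-based layer index
    chi: int              #: maximal window count
    t: float | None       #: pulse centre time (ms)
    noise_level: int      #: chance-level count
    snr: float
    success: bool


@dataclass
class PulseTrace:
    t0: float
    layers: list[LayerDetection]
    max_successful_layer: int   #: highest k with layers 2..k all successful

    def pulse_times(self) -> list[float]:
        """Centre times of the initiated pulse and all successful layers."""
        times = [self.t0]
        for d in self.layers:
            if not d.success:
                break
            times.append(d.t)
        return times


def noise_level(control_times: np.ndarray, window: float, chance_const: float,
                control_duration: float, resolution: float = 0.1) -> int:
    """Minimal count whose occurrence probability in a sliding window of the
    control interval is at most ``chance_const``.

    The probability is estimated empirically over all window positions.
    """
    times = np.sort(np.asarray(control_times, dtype=float))
    starts = np.arange(0.0, max(control_duration - window, resolution), resolution)
    counts = (np.searchsorted(times, starts + window)
              - np.searchsorted(times, starts))
    max_c = int(counts.max()) if len(counts) else 0
    hist = np.bincount(counts, minlength=max_c + 2)
    tail = np.cumsum(hist[::-1])[::-1] / max(len(counts), 1)
    for lam in range(1, max_c + 2):
        if tail[lam] <= chance_const:
            return lam
    return max_c + 1


def detect_propagation(record: SpikeRecord, layers, t0: float,
                       detector: DetectorConfig, control: SpikeRecord,
                       control_duration: float | None = None) -> PulseTrace:
    """Track the synchronous pulse layer by layer.

    ``layers`` is a list of neuron-id arrays, the first entry being the
    initiated layer.  ``control`` holds spikes of an interval with identical
    stimulation but no initiated pulse (times relative to the start of the
    control interval).  Layer ``k`` (1-based) is successful iff its
    signal-to-noise ratio ``chi_k / lambda_k`` reaches ``snr_min`` and all
    previous layers were successful.
    """
    if control is None or control.N == 0:
        raise ValueError("control record required")
    if control_duration is None:
        control_duration = detector.control_interval
    half = detector.window / 2.0
    shifts = np.arange(0.0, detector.max_shift + 1e-9, detector.shift_resolution)

    out: list[LayerDetection] = []
    t_prev = t0
    chain_alive = True
    max_ok = 1
    for k, members in enumerate(layers[1:], start=2):
        lam = noise_level(control.subset(members).time, detector.window,
                          detector.chance_const, control_duration)
        det = LayerDetection(layer=k, chi=0, t=None, noise_level=lam,
                             snr=0.0, success=False)
        if chain_alive and t_prev is not None:
            times = np.sort(record.subset(members).time)
            centers = t_prev + shifts
            counts = (np.searchsorted(times, centers + half)
                      - np.searchsorted(times, centers - half))
            best = int(np.argmax(counts))       # ties -> smallest shift
            chi = int(counts[best])
            det.chi = chi
            if chi > 0:
                c = centers[best]
                in_win = times[(times >= c - half) & (times < c + half)]
                det.t = float(np.mean(in_win))
            det.snr = chi / lam
            det.success = det.snr >= detector.snr_min and det.t is not None
        if det.success:
            max_ok = k
            t_prev = det.t
        else:
            chain_alive = False
            t_prev = None
        out.append(det)
    return PulseTrace(t0=t0, layers=out, max_successful_layer=max_ok)


def propagation_frequency(trace: PulseTrace) -> float:
    """Inverse of the mean interval between consecutive pulses (Hz)."""
    times = trace.pulse_times()
    if len(times) < 3:
        raise ValueError("need at least 3 successful layers")
    return 1000.0 / float(np.mean(np.diff(times)))


# --------------------------------------------------------------------------- #
# response curve and iterated map
# --------------------------------------------------------------------------- #

@dataclass
class ResponseCurve:
    """Estimated probability of spiking within the response window after a
    compound synchronous input, on a grid of input strengths."""

    strengths: np.ndarray
    probs: np.ndarray
    n_trials: int
    window: float = 10.0

    def __post_init__(self):
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def ci_halfwidth(self) -> np.ndarray:
        """95% normal-approximation half-widths."""
        p = self.probs
        return 1.96 * np.sqrt(np.maximum(p * (1 - p), 0.25 / self.n_trials)
                              / self.n_trials)

    def interp(self, g):
        """Linear interpolation; constant extrapolation beyond the grid."""
        return np.interp(g, self.strengths, self.probs)

    @classmethod
    def from_step(cls, threshold: float, high: float, strengths,
                  low: float = 0.0, n_trials: int = 10**6) -> "ResponseCurve":
        """Idealized step response (analysis/testing aid)."""
        s = np.asarray(strengths, dtype=float)
        return cls(s, np.where(s >= threshold, high, low), n_trials)


def estimate_response_curve(strength_grid, mode: str, n_trials: int,
                            background: BackgroundSpec | None, seed: int,
                            params: StandardParams | None = None, *,
                            window: float = 10.0,
                            oscillation: OscillationSpec | None = None
                            ) -> ResponseCurve:
    """Monte-Carlo estimate of the single-neuron response probability."""
    if n_trials < 100:
        raise ValueError("need at least 100 trials per strength")
    if params is None:
        params = StandardParams()
    probs, _ = probe_response(strength_grid, n_trials, mode, params,
                              background, seed, window=window,
                              oscillation=oscillation)
    return ResponseCurve(np.asarray(strength_grid, dtype=float), probs,
                         n_trials, window=window)


@dataclass
class IteratedMap:
    """Layer-to-layer map of the expected number of synchronously spiking
    neurons: the binomial input mixture evaluated through the single-neuron
    response curve, continuously interpolated between integer occupancies."""

    w: int
    p: float
    eps_ff: float
    xi: np.ndarray          #: integer grid 0..w
    values: np.ndarray      #: G(xi) on the grid
    _spline: PchipInterpolator = field(repr=False, default=None)
    fixed_points: list = field(default_factory=list)  #: [(xi*, stable)]

    def G(self, x):
        return np.clip(self._spline(np.clip(x, 0, self.w)), 0.0, self.w)

    def dG(self, x):
        return self._spline.derivative()(np.clip(x, 0, self.w))

    def iterate(self, x0: float, n: int) -> np.ndarray:
        out = np.empty(n + 1)
        out[0] = x0
        for i in range(n):
            out[i + 1] = float(self.G(out[i]))
        return out

    @property
    def n_fixed_points(self) -> int:
        return len(self.fixed_points)


def _find_fixed_points(gmap: IteratedMap, tol: float = 1e-9):
    w = gmap.w
    grid = np.linspace(0.0, w, 4001)
    f = gmap.G(grid) - grid
    roots: list[float] = []
    if abs(f[0]) < 1e-6:
        roots.append(0.0)
    sign = np.sign(f)
    for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
        r = optimize.brentq(lambda x: float(gmap.G(x)) - x,
                            grid[i], grid[i + 1], xtol=tol)
        roots.append(float(r))
    # dedupe
    uniq: list[float] = []
    for r in roots:
        if not uniq or abs(r - uniq[-1]) > 1e-4 * max(w, 1):
            uniq.append(r)
    return [(r, bool(abs(gmap.dG(r)) < 1.0)) for r in uniq]


def build_map(curve: ResponseCurve, w: int, p: float, eps_ff: float
              ) -> IteratedMap:
    """Construct the iterated map from a response curve.

    For an integer number ``xi`` of synchronously spiking neurons in the
    previous layer, the number of inputs a neuron receives is binomial
    ``(xi, p)`` and each input carries ``eps_ff``; the expected number of
    responders is ``w * E[p_hat(k * eps_ff)]``.  Non-integer ``xi`` is
    handled by monotone interpolation of the integer-grid values.
    """
    if w < 1 or not 0 < p <= 1:
        raise ValueError("invalid layer size or connection probability")
    k_max = int(stats.binom.ppf(1 - 1e-9, w, p))
    if curve.strengths.max() < min(k_max * eps_ff, w * eps_ff) - 1e-9:
        # constant extrapolation is only safe if the curve has saturated
        tail = curve.probs[curve.strengths >= 0.8 * curve.strengths.max()]
        if tail.size < 2 or np.ptp(tail) > 5e-3:
            raise ValueError("response curve does not cover the needed strengths")
    xi = np.arange(w + 1)
    ks = np.arange(w + 1)
    phat = curve.interp(ks * eps_ff)
    values = np.empty(w + 1)
    for x in xi:
        pmf = stats.binom.pmf(ks[:x + 1], x, p)
        values[x] = w * float(pmf @ phat[:x + 1])
    spline = PchipInterpolator(xi, values)
    gmap = IteratedMap(w=w, p=p, eps_ff=eps_ff, xi=xi, values=values,
                       _spline=spline)
    gmap.fixed_points = _find_fixed_points(gmap)
    return gmap


def tangent_bifurcation(curve: ResponseCurve, w: int, p: float,
                        eps_lo: float, eps_hi: float,
                        tol: float = 1e-3) -> float:
    """Critical coupling where two additional fixed points appear.

    Bisects on the number of fixed points (1 below, 3 above).  Raises if the
    bracket does not straddle the transition.
    """
    n_lo = build_map(curve, w, p, eps_lo).n_fixed_points
    n_hi = build_map(curve, w, p, eps_hi).n_fixed_points
    if not (n_lo == 1 and n_hi >= 3):
        raise ValueError(
            f"bracket does not straddle the bifurcation (counts {n_lo}, {n_hi})")
    while eps_hi - eps_lo > tol:
        mid = 0.5 * (eps_lo + eps_hi)
        if build_map(curve, w, p, mid).n_fixed_points >= 3:
            eps_hi = mid
        else:
            eps_lo = mid
    return 0.5 * (eps_lo + eps_hi)


# --------------------------------------------------------------------------- #
# propagation experiments
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PropagationSetup:
    """Everything needed to run one pulse-propagation trial."""

    spec: NetworkSpec
    delay_model: DelayModel
    params: StandardParams
    background: BackgroundSpec
    mode: str = "non_additive"
    burn_in: float = 200.0
    prop_window: float = 150.0
    detector: DetectorConfig = DetectorConfig()
    control_interval: float = 400.0
    #: oscillation cycle-centre lead relative to the first layer-2 arrival (ms)
    phase_lead: float = 0.5
    #: delay used to anchor the oscillation phase (default: delay-model mean)
    phase_anchor_delay: float | None = None
    injected_current: float = 0.0
    ffn_delay_models: tuple | None = None

    def duration(self) -> float:
        return self.burn_in + self.control_interval + self.prop_window


def propagation_trial(setup: PropagationSetup, eps_ff: float,
                      oscillation: OscillationSpec | None, seed: int,
                      initiate: bool = True, ffn: int = 0):
    """Run one trial and detect propagation.

    The interval before the pulse (after burn-in) serves as the control for
    the noise level; the pulse is initiated afterwards, phase-aligned with
    the oscillation.  Returns ``(trace, record, net, t0)``.
    """
    spec = replace(setup.spec, eps_ff=eps_ff)
    net = build_network(spec, setup.delay_model, seed,
                        ffn_delay_models=list(setup.ffn_delay_models)
                        if setup.ffn_delay_models else None)
    t0 = setup.burn_in + setup.control_interval
    osc = oscillation
    if osc is not None and osc.n_osc > 0:
        # put a cycle centre slightly ahead of the first arrival at layer 2
        anchor = (setup.phase_anchor_delay if setup.phase_anchor_delay
                  is not None else setup.delay_model.mean)
        target = t0 + anchor - setup.phase_lead
        osc = replace(osc, phase=target % osc.period)
    cfg = SimulationConfig(dt=setup.params.dt, duration=setup.duration(),
                           mode=setup.mode, seed=seed)
    forced = None
    if initiate:
        first = net.layer_members(0, 0)
        forced = (first, np.full(len(first), t0))
    inj = None
    if setup.injected_current:
        inj = np.full(net.N, setup.injected_current)
    rec = run(net, cfg, setup.params, background=setup.background,
              oscillation=osc, forced_spikes=forced, injected_currents=inj)
    layers = net.layers(ffn=ffn, L=spec.L)
    ctrl = rec.subset(np.concatenate(layers))
    mask = (ctrl.time >= setup.burn_in) & (ctrl.time < t0)
    control = SpikeRecord(ctrl.neuron[mask], ctrl.time[mask] - setup.burn_in,
                          rec.N)
    trace = detect_propagation(rec, layers, t0, setup.detector, control,
                               control_duration=setup.control_interval)
    return trace, rec, net, t0


def _spontaneous_full_propagation(setup: PropagationSetup, eps_ff: float,
                                  oscillation: OscillationSpec | None,
                                  seed: int) -> bool:
    """Does the control (no initiated pulse) already 'propagate' to the final
    layer?  Marks the pathological regime."""
    trace, _, _, _ = propagation_trial(setup, eps_ff, oscillation, seed,
                                       initiate=False)
    return trace.max_successful_layer >= setup.spec.L


def natural_frequency(setup: PropagationSetup, eps_ff: float, seed: int = 0,
                      n_trials: int = 3) -> float:
    """Propagation frequency of the unstimulated FFN at coupling ``eps_ff``
    (supercritical), averaged over trials."""
    freqs = []
    for i in range(n_trials):
        trace, _, _, _ = propagation_trial(setup, eps_ff, None, seed + i)
        if trace.max_successful_layer >= min(setup.spec.L, 4):
            freqs.append(propagation_frequency(trace))
    if not freqs:
        raise RuntimeError("no propagation at the given coupling")
    return float(np.mean(freqs))


def find_resonance(setup: PropagationSetup, eps_ff: float,
                   oscillation: OscillationSpec, nu_candidates,
                   seed: int = 0, n_trials: int = 2) -> float:
    """Pick the stimulation frequency with the deepest propagation from a
    candidate list (coarse resonance search)."""
    best_nu, best_depth = None, -1
    for nu in sorted(nu_candidates):
        osc = oscillation.with_frequency(float(nu))
        depths = []
        for i in range(n_trials):
            trace, _, _, _ = propagation_trial(setup, eps_ff, osc,
                                               seed + 101 * i)
            depths.append(trace.max_successful_layer)
        d = float(np.median(depths))
        # ties resolved towards the highest frequency: near the top of the
        # locking band the hop period stays feasible for strong couplings too
        if d >= best_depth:
            best_depth, best_nu = d, float(nu)
    return best_nu


def critical_coupling_sim(setup: PropagationSetup,
                          oscillation: OscillationSpec | None,
                          n_trials: int, seed: int,
                          eps_lo: float, eps_hi: float, *,
                          success_frac: float = 0.5,
                          tol: float = 0.05) -> dict:
    """Bisect the critical feed-forward coupling.

    Success at a coupling means the initiated pulse is detected up to the
    final layer in at least ``success_frac`` of trials.  Also reports the
    smallest tested coupling at which the control shows spontaneous full
    propagation (pathological bound), if any.
    """
    L = setup.spec.L

    def succeeds(eps: float) -> tuple[bool, bool]:
        # one spontaneous-propagation (pathological) probe per coupling
        if _spontaneous_full_propagation(setup, eps, oscillation, seed + 17):
            return False, True
        ok = 0
        for i in range(n_trials):
            trace, _, _, _ = propagation_trial(setup, eps, oscillation,
                                               seed + 1000 * i)
            if trace.max_successful_layer >= L:
                ok += 1
        return ok >= math.ceil(success_frac * n_trials), False

    lo_ok, lo_patho = succeeds(eps_lo)
    hi_ok, hi_patho = succeeds(eps_hi)
    if lo_patho and hi_patho:
        raise RuntimeError("pathological activity throughout the bracket")
    if lo_ok or not hi_ok:
        raise ValueError("bracket does not contain the transition "
                         f"(lo={lo_ok}, hi={hi_ok})")
    eps_patho = None
    history = [(eps_lo, lo_ok), (eps_hi, hi_ok)]
    while eps_hi - eps_lo > tol:
        mid = 0.5 * (eps_lo + eps_hi)
        ok, patho = succeeds(mid)
        history.append((mid, ok))
        if patho and eps_patho is None:
            eps_patho = mid
        if ok:
            eps_hi = mid
        else:
            eps_lo = mid
    return {"eps_crit": 0.5 * (eps_lo + eps_hi), "eps_patho": eps_patho,
            "history": history}


def lock_ratio(nu_prop: float, nu_stim: float, max_int: int = 4,
               rel_tol: float = 0.02) -> tuple[int, int] | None:
    """Rational ratio n:m (n, m <= max_int) matching nu_prop/nu_stim within
    ``rel_tol``, or None."""
    ratio = nu_prop / nu_stim
    best = None
    for m in range(1, max_int + 1):
        for n in range(1, max_int + 1):
            if math.gcd(n, m) != 1:
                continue
            err = abs(ratio - n / m) / (n / m)
            if err <= rel_tol and (best is None or err < best[2]):
                best = (n, m, err)
    return (best[0], best[1]) if best else None


def resonance_scan(setup: PropagationSetup, oscillation: OscillationSpec,
                   nu_grid, n_trials: int, seed: int,
                   eps_ff: float) -> list[dict]:
    """Propagation depth, frequency and locking over stimulation frequencies."""
    if len(list(nu_grid)) == 0:
        raise ValueError("nu_grid must be non-empty")
    rows = []
    for nu in nu_grid:
        osc = oscillation.with_frequency(float(nu))
        depths, freqs = [], []
        for i in range(n_trials):
            trace, _, _, _ = propagation_trial(setup, eps_ff, osc,
                                               seed + 101 * i)
            depths.append(trace.max_successful_layer)
            if trace.max_successful_layer >= 4:
                freqs.append(propagation_frequency(trace))
        nu_prop = float(np.median(freqs)) if freqs else None
        ratio = lock_ratio(nu_prop, float(nu)) if nu_prop else None
        rows.append({"nu_stim": float(nu),
                     "max_layer": float(np.median(depths)),
                     "nu_prop": nu_prop, "lock": ratio})
    return rows


def gating_experiment(setup: PropagationSetup, eps_ff: float,
                      oscillation: OscillationSpec | None, seed: int,
                      n_trials: int = 1) -> dict:
    """Per-FFN propagation depth in a multi-FFN network sharing layer 1."""
    if setup.spec.n_ffn < 2 or not setup.spec.share_first_layer:
        raise ValueError("gating needs >= 2 FFNs sharing the first layer")
    depths = {f: [] for f in range(setup.spec.n_ffn)}
    for i in range(n_trials):
        s = seed + 1000 * i
        trace0, rec, net, t0 = propagation_trial(setup, eps_ff, oscillation,
                                                 s, ffn=0)
        for f in range(setup.spec.n_ffn):
            if f == 0:
                trace = trace0
            else:
                layers = net.layers(ffn=f, L=setup.spec.L)
                ctrl = rec.subset(np.concatenate(layers))
                mask = (ctrl.time >= setup.burn_in) & (ctrl.time < t0)
                control = SpikeRecord(ctrl.neuron[mask],
                                      ctrl.time[mask] - setup.burn_in, rec.N)
                trace = detect_propagation(rec, layers, t0, setup.detector,
                                           control,
                                           control_duration=setup.control_interval)
            depths[f].append(trace.max_successful_layer)
    return {f: float(np.median(v)) for f, v in depths.items()}
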