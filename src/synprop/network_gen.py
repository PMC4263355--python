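"""Network construction: random recurrent graphs with embedded feed-forward
subnetworks, and per-edge conduction-delay models.

Feed-forward subnetworks (FFNs) are "naturally occurring": in recurrent mode
no edge is added, the already existing excitatory edges between consecutive
layers are merely strengthened.  In isolated mode only the consecutive-layer
excitatory edges are generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rng as _rng

__all__ = [
    "DelayModel", "HomogeneousDelay", "UniformDelay", "LognormalDelay",
    "HippocampalDelay", "lognormal_std", "hippocampal_delay_density",
    "NetworkSpec", "NetworkRealization", "build_network", "sample_delays",
]


# --------------------------------------------------------------------------- #
# delay models
# --------------------------------------------------------------------------- #

class DelayModel:
    """Base class; subclasses implement i.i.d. sampling of positive delays."""

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    @property
    def mean(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class HomogeneousDelay(DelayModel):
    d0: float = 2.0

    def __post_init__(self):
        if self.d0 <= 0:
            raise ValueError("delay must be positive")

    def sample(self, n, rng):
        return np.full(n, self.d0)

    @property
    def mean(self):
        return self.d0


@dataclass(frozen=True)
class UniformDelay(DelayModel):
    """Delays drawn uniformly from an interval of given width centred on d_mean."""

    d_mean: float
    width: float

    def __post_init__(self):
        if self.width < 0 or self.d_mean - self.width / 2 <= 0:
            raise ValueError("uniform delay support must be positive")

    def sample(self, n, rng):
        return rng.uniform(self.d_mean - self.width / 2,
                           self.d_mean + self.width / 2, size=n)

    @property
    def mean(self):
        return self.d_mean


@dataclass(frozen=True)
class LognormalDelay(DelayModel):
    """Log-normal delays parameterized by the distribution *mode*.

    The underlying location parameter is ``mu = ln(mode) + sigma**2`` so the
    density maximum stays at ``mode`` as the width parameter grows.
    """

    mode: float
    sigma: float

    def __post_init__(self):
        if self.mode <= 0 or self.sigma < 0:
            raise ValueError("invalid log-normal parameters")

    @property
    def mu(self) -> float:
        return math.log(self.mode) + self.sigma**2

    def sample(self, n, rng):
        if self.sigma == 0:
            return np.full(n, self.mode)
        return rng.lognormal(mean=self.mu, sigma=self.sigma, size=n)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        s, mu = self.sigma, self.mu
        out[pos] = (np.exp(-((np.log(t[pos]) - mu) ** 2) / (2 * s**2))
                    / (t[pos] * s * math.sqrt(2 * math.pi)))
        return out

    @property
    def mean(self):
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def std(self):
        return lognormal_std(self.mode, self.sigma)


def lognormal_std(mode: float, sigma: float) -> float:
    """Closed-form standard deviation of the mode-parameterized log-normal."""
    return mode * math.exp(1.5 * sigma**2) * math.sqrt(math.expm1(sigma**2))


@dataclass(frozen=True)
class HippocampalDelay(DelayModel):
    """Distance-based delays: axonal (two uniform points on a square patch)
    plus an independent uniform dendritic contribution."""

    side_length: float = 500.0        #: patch side (µm)
    velocity: float = 350.0           #: axonal conduction velocity (µm/ms)
    dendritic_range: tuple[float, float] = (0.5, 1.5)  #: (ms, ms)

    def __post_init__(self):
        a, b = self.dendritic_range
        if self.side_length < 0 or self.velocity <= 0 or not 0 <= a <= b:
            raise ValueError("invalid hippocampal delay parameters")
        if a + self.side_length == 0:
            raise ValueError("degenerate model with zero delays")

    def sample(self, n, rng):
        p1 = rng.uniform(0, self.side_length, size=(n, 2))
        p2 = rng.uniform(0, self.side_length, size=(n, 2))
        dist = np.hypot(*(p1 - p2).T)
        a, b = self.dendritic_range
        return dist / self.velocity + rng.uniform(a, b, size=n)

    @property
    def mean(self):
        # mean distance on a square of side S is S * c with c ≈ 0.5214
        c = (2 + math.sqrt(2) + 5 * math.asinh(1)) / 15
        a, b = self.dendritic_range
        return self.side_length * c / self.velocity + (a + b) / 2


def _square_distance_pdf(t):
    """Density of the distance between two uniform points on the unit square."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m1 = (t >= 0) & (t <= 1)
    out[m1] = 2 * t[m1] * (t[m1] ** 2 - 4 * t[m1] + math.pi)
    m2 = (t > 1) & (t <= math.sqrt(2))
    tt = t[m2]
    r = np.sqrt(tt**2 - 1)
    out[m2] = 2 * tt * (4 * r - (tt**2 + 2 - math.pi) - 4 * np.arctan(r))
    return out


class HippocampalDelayDensity:
    """Analytic density/CDF of the hippocampal delay model."""

    def __init__(self, side_length: float, velocity: float,
                 dendritic_range: tuple[float, float], grid_points: int = 8001):
        if side_length < 0 or velocity <= 0:
            raise ValueError("invalid parameters")
        a, b = dendritic_range
        if not 0 <= a <= b:
            raise ValueError("invalid dendritic range")
        self.side_length = side_length
        self.velocity = velocity
        self.dendritic_range = (a, b)
        d_ax_max = math.sqrt(2) * side_length / velocity
        self.support = (a, d_ax_max + b)
        # cumulative of the axonal-delay density on a dense grid
        if side_length > 0:
            tau = np.linspace(0, d_ax_max, grid_points)
            scale = side_length / velocity  # d_ax = scale * unit-square distance
            pdf_ax = _square_distance_pdf(tau / scale) / scale
            cdf_ax = np.concatenate([[0.0], np.cumsum(
                0.5 * (pdf_ax[1:] + pdf_ax[:-1]) * np.diff(tau))])
            cdf_ax /= cdf_ax[-1]
            self._tau, self._cdf_ax = tau, cdf_ax
        else:
            self._tau, self._cdf_ax = None, None

    def _F_ax(self, t):
        t = np.asarray(t, dtype=float)
        if self._tau is None:
            return (t >= 0).astype(float)
        return np.interp(t, self._tau, self._cdf_ax, left=0.0, right=1.0)

    def pdf(self, t):
        """Density of axonal + dendritic delay (ms^-1)."""
        t = np.asarray(t, dtype=float)
        a, b = self.dendritic_range
        if b == a:
            if self._tau is None:
                raise ValueError("fully degenerate delay model has no density")
            scale = self.side_length / self.velocity
            return _square_distance_pdf((t - a) / scale) / scale
        return (self._F_ax(t - a) - self._F_ax(t - b)) / (b - a)

    def cdf(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a, b = self.dendritic_range
        if self._tau is None:
            return np.clip((t - a) / max(b - a, 1e-300), 0.0, 1.0)
        # integrate the pdf numerically up to each query point
        hi = self.support[1]
        grid = np.linspace(self.support[0] - 1e-9, hi + 1e-9, 4001)
        p = self.pdf(grid)
        c = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(grid))])
        c = np.clip(c / c[-1], 0, 1)
        return np.interp(t, grid, c, left=0.0, right=1.0)


def hippocampal_delay_density(side_length: float, velocity: float,
                              dendritic_range: tuple[float, float]
                              ) -> HippocampalDelayDensity:
    """Analytic delay density of :class:`HippocampalDelay`."""
    return HippocampalDelayDensity(side_length, velocity, dendritic_range)


def sample_delays(delay_model: DelayModel, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. delays (ms) from the given model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = delay_model.sample(n, _rng.stream(seed, "delays"))
    if np.any(out <= 0):
        raise ValueError("delay model produced non-positive delays")
    return out


# --------------------------------------------------------------------------- #
# network specification and realization
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the random network with embedded FFN(s)."""

    N: int                       #: total neuron count
    L: int                       #: FFN layers
    w: int                       #: neurons per layer
    eps_ff: float                #: feed-forward peak conductance (nS)
    p_ex: float = 0.05           #: excitatory connection probability
    p_in: float = 0.05           #: inhibitory connection probability
    eps: float = 0.0             #: recurrent excitatory strength (nS)
    eps_in: float = 0.0          #: inhibitory strength (nS)
    isolated: bool = True        #: isolated FFN vs recurrent embedding
    n_ffn: int = 1               #: number of embedded FFNs
    share_first_layer: bool = False

    def __post_init__(self):
        if not (0 <= self.p_ex <= 1 and 0 <= self.p_in <= 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        if self.L < 1 or self.w < 1 or self.n_ffn < 1:
            raise ValueError("L, w, n_ffn must be positive")
        if self.eps_ff < self.eps:
            raise ValueError("feed-forward strength must be >= recurrent strength")
        need = self.group_count * self.w
        if need > self.N:
            raise ValueError("FFN groups exceed network size")

    @property
    def group_count(self) -> int:
        if self.share_first_layer:
            return 1 + self.n_ffn * (self.L - 1)
        return self.n_ffn * self.L


@dataclass
class NetworkRealization:
    """Concrete directed network with per-edge strengths and delays."""

    N: int
    exc_src: np.ndarray
    exc_dst: np.ndarray
    exc_strength: np.ndarray
    exc_delay: np.ndarray
    inh_src: np.ndarray
    inh_dst: np.ndarray
    inh_strength: np.ndarray
    inh_delay: np.ndarray
    #: per-neuron (ffn index, layer index); -1 where unassigned
    ffn_index: np.ndarray = field(default=None)
    layer_index: np.ndarray = field(default=None)

    def layer_members(self, ffn: int, layer: int) -> np.ndarray:
        mask = (self.layer_index == layer) & (
            (self.ffn_index == ffn) | (self.ffn_index == -2))
        return np.flatnonzero(mask)

    def layers(self, ffn: int = 0, L: int | None = None) -> list[np.ndarray]:
        if L is None:
            L = int(self.layer_index.max()) + 1
        return [self.layer_members(ffn, k) for k in range(L)]

    # ------------------------------ I/O ------------------------------- #
    def to_csv(self, edges_path: str | Path, layers_path: str | Path | None = None):
        df = pd.DataFrame({
            "source": np.concatenate([self.exc_src, self.inh_src]),
            "target": np.concatenate([self.exc_dst, self.inh_dst]),
            "sign": ["E"] * len(self.exc_src) + ["I"] * len(self.inh_src),
            "strength_nS": np.concatenate([self.exc_strength, self.inh_strength]),
            "delay_ms": np.concatenate([self.exc_delay, self.inh_delay]),
        })
        df.to_csv(edges_path, index=False)
        if layers_path is not None:
            sel = self.layer_index >= 0
            pd.DataFrame({
                "neuron": np.flatnonzero(sel),
                "ffn": self.ffn_index[sel],
                "layer": self.layer_index[sel],
            }).to_csv(layers_path, index=False)

    @classmethod
    def from_csv(cls, edges_path: str | Path, layers_path: str | Path | None = None,
                 N: int | None = None) -> "NetworkRealization":
        df = pd.read_csv(edges_path)
        if N is None:
            N = int(max(df["source"].max(), df["target"].max())) + 1
        e = df[df["sign"] == "E"]
        i = df[df["sign"] == "I"]
        ffn_index = np.full(N, -1, dtype=np.int64)
        layer_index = np.full(N, -1, dtype=np.int64)
        if layers_path is not None:
            ldf = pd.read_csv(layers_path)
            ffn_index[ldf["neuron"].to_numpy()] = ldf["ffn"].to_numpy()
            layer_index[ldf["neuron"].to_numpy()] = ldf["layer"].to_numpy()
        return cls(
            N=N,
            exc_src=e["source"].to_numpy(np.int64),
            exc_dst=e["target"].to_numpy(np.int64),
            exc_strength=e["strength_nS"].to_numpy(float),
            exc_delay=e["delay_ms"].to_numpy(float),
            inh_src=i["source"].to_numpy(np.int64),
            inh_dst=i["target"].to_numpy(np.int64),
            inh_strength=i["strength_nS"].to_numpy(float),
            inh_delay=i["delay_ms"].to_numpy(float),
            ffn_index=ffn_index, layer_index=layer_index)


# --------------------------------------------------------------------------- #
# construction
# --------------------------------------------------------------------------- #

def _er_edges(N: int, p: float, rng: np.random.Generator):
    """Directed Erdős–Rényi edges without self-loops."""
    if p == 0:
        return (np.empty(0, np.int64),) * 2
    src_list, dst_list = [], []
    for i in range(N):
        mask = rng.random(N) < p
        mask[i] = False
        tgt = np.flatnonzero(mask)
        src_list.append(np.full(len(tgt), i, dtype=np.int64))
        dst_list.append(tgt.astype(np.int64))
    return np.concatenate(src_list), np.concatenate(dst_list)


def _assign_layers(spec: NetworkSpec, rng: np.random.Generator):
    """Random, disjoint layer assignment.  Returns (ffn_index, layer_index).

    A shared first layer is tagged with ffn index -2.
    """
    ffn_index = np.full(spec.N, -1, dtype=np.int64)
    layer_index = np.full(spec.N, -1, dtype=np.int64)
    chosen = rng.choice(spec.N, size=spec.group_count * spec.w, replace=False)
    pos = 0
    if spec.share_first_layer:
        first = chosen[pos:pos + spec.w]; pos += spec.w
        ffn_index[first] = -2   # shared among all FFNs
        layer_index[first] = 0
        for f in range(spec.n_ffn):
            for k in range(1, spec.L):
                grp = chosen[pos:pos + spec.w]; pos += spec.w
                ffn_index[grp] = f
                layer_index[grp] = k
    else:
        for f in range(spec.n_ffn):
            for k in range(spec.L):
                grp = chosen[pos:pos + spec.w]; pos += spec.w
                ffn_index[grp] = f
                layer_index[grp] = k
    return ffn_index, layer_index


def _consecutive_pair_mask(src, dst, ffn_index, layer_index, ffn: int):
    """Mask of edges running between consecutive layers of the given FFN."""
    fs, fd = ffn_index[src], ffn_index[dst]
    ls, ld = layer_index[src], layer_index[dst]
    src_in = (fs == ffn) | (fs == -2)
    dst_in = (fd == ffn) | (fd == -2)
    return src_in & dst_in & (ls >= 0) & (ld == ls + 1)


def build_network(spec: NetworkSpec, delay_model: DelayModel, seed: int,
                  ffn_delay_models: list[DelayModel] | None = None
                  ) -> NetworkRealization:
    """Build a network realization.

    ``ffn_delay_models`` optionally overrides the delay model for the
    feed-forward edges of each FFN (used in gating experiments where the
    FFNs have distinct mean delays and hence distinct resonance
    frequencies).  Deterministic given ``seed``.
    """
    topo = _rng.stream(seed, "topology")
    dly = _rng.stream(seed, "delays")
    ffn_index, layer_index = _assign_layers(spec, topo)

    if spec.isolated:
        src_list, dst_list = [], []
        for f in range(spec.n_ffn):
            for k in range(spec.L - 1):
                pre = np.flatnonzero(((ffn_index == f) | (ffn_index == -2))
                                     & (layer_index == k))
                post = np.flatnonzero((ffn_index == f) & (layer_index == k + 1))
                mask = topo.random((len(pre), len(post))) < spec.p_ex
                ii, jj = np.nonzero(mask)
                src_list.append(pre[ii])
                dst_list.append(post[jj])
        exc_src = np.concatenate(src_list) if src_list else np.empty(0, np.int64)
        exc_dst = np.concatenate(dst_list) if dst_list else np.empty(0, np.int64)
        exc_strength = np.full(len(exc_src), spec.eps_ff, dtype=float)
        inh_src = inh_dst = np.empty(0, np.int64)
    else:
        exc_src, exc_dst = _er_edges(spec.N, spec.p_ex, topo)
        inh_src, inh_dst = _er_edges(spec.N, spec.p_in, topo)
        exc_strength = np.full(len(exc_src), spec.eps, dtype=float)
        for f in range(spec.n_ffn):
            mask = _consecutive_pair_mask(exc_src, exc_dst, ffn_index,
                                          layer_index, f)
            exc_strength[mask] = spec.eps_ff
    inh_strength = np.full(len(inh_src), spec.eps_in, dtype=float)

    # ------------------------------ delays ---------------------------- #
    if isinstance(delay_model, HippocampalDelay) and delay_model.side_length > 0:
        coords = dly.uniform(0, delay_model.side_length, size=(spec.N, 2))
        a, b = delay_model.dendritic_range

        def _hippo(src, dst):
            dist = np.hypot(*(coords[src] - coords[dst]).T) if len(src) else np.empty(0)
            return dist / delay_model.velocity + dly.uniform(a, b, size=len(src))

        exc_delay = _hippo(exc_src, exc_dst)
        inh_delay = _hippo(inh_src, inh_dst)
    else:
        exc_delay = delay_model.sample(len(exc_src), dly)
        inh_delay = delay_model.sample(len(inh_src), dly)

    if ffn_delay_models is not None:
        if len(ffn_delay_models) != spec.n_ffn:
            raise ValueError("need one delay model per FFN")
        for f, model in enumerate(ffn_delay_models):
            mask = _consecutive_pair_mask(exc_src, exc_dst, ffn_index,
                                          layer_index, f)
            exc_delay[mask] = model.sample(int(mask.sum()), dly)

    if (len(exc_delay) and exc_delay.min() <= 0) or \
       (len(inh_delay) and inh_delay.min() <= 0):
        raise ValueError("delay model produced non-positive delays")

    return NetworkRealization(
        N=spec.N, exc_src=exc_src, exc_dst=exc_dst,
        exc_strength=exc_strength, exc_delay=exc_delay,
        inh_src=inh_src, inh_dst=inh_dst,
        inh_strength=inh_strength, inh_delay=inh_delay,
        ffn_index=ffn_index, layer_index=layer_index)
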