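"""Distance-dependent wiring on a periodic square lattice.

Neurons live on a 1 mm^2 square sheet with periodic boundaries (distances use
the minimum-image convention).  Each neuron receives exactly K = round(eps*N)
recurrent synapses; sources are drawn with acceptance probability
``exp(-r^2 / (2 sigma_c^2))`` of the source-target distance r, so the accepted
distance distribution is proportional to ``P(r) * exp(-r^2 / 2 sigma_c^2)``,
where P(r) is the density of the distance between two uniformly placed points
on the periodic square.

Six named scenarios fix the (eps, sigma_c) pair; axonal delays grow linearly
with distance on top of a fixed synaptic latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import SynapseParams

__all__ = [
    "LatticeGeometry",
    "ConnectivityParams",
    "ScenarioSpec",
    "DelayParams",
    "SynapseTable",
    "SCENARIOS",
    "pair_distance",
    "gaussian_profile",
    "radial_density",
    "normalized_connection_density",
    "sample_in_connections",
    "compute_delay",
    "build_synapse_table",
]

MAX_REJECTION_ATTEMPTS = 1_000_000


@dataclass(frozen=True)
class LatticeGeometry:
    """Periodic square sheet of side ``L`` mm with per-neuron positions."""

    L: float
    positions: np.ndarray  # shape (N, 2), coordinates in [0, L)
    periodic: bool = True

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.L <= 0:
            raise ValueError("lattice side must be positive")
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if np.any(pos < 0) or np.any(pos >= self.L):
            raise ValueError("all coordinates must lie in [0, L)")

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    @classmethod
    def uniform_random(cls, n: int, rng: np.random.Generator, L: float = 1.0):
        return cls(L=L, positions=rng.uniform(0.0, L, size=(n, 2)))

    @classmethod
    def regular_grid(cls, n: int, L: float = 1.0) -> "LatticeGeometry":
        """Deterministic near-square grid layout (testing aid)."""
        side = int(np.ceil(np.sqrt(n)))
        xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        pos = np.stack([xs.ravel(), ys.ravel()], axis=1)[:n] * (L / side)
        return cls(L=L, positions=pos.astype(float))


@dataclass(frozen=True)
class ScenarioSpec:
    """Named connectivity scenario: percentages of local arborization density
    (eps) and lateral Gaussian spread (sigma_c)."""

    name: str
    epsilon_pct: float
    sigma_c_pct: float

    @property
    def epsilon(self) -> float:
        return self.epsilon_pct / 100.0

    @property
    def sigma_c_frac(self) -> float:
        return self.sigma_c_pct / 100.0


SCENARIOS: dict[str, ScenarioSpec] = {
    "A-1": ScenarioSpec("A-1", 1.0, 9.0),
    "A-2": ScenarioSpec("A-2", 1.0, 10.0),
    "B-1": ScenarioSpec("B-1", 9.0, 1.0),
    "B-2": ScenarioSpec("B-2", 10.0, 1.0),
    "B-3": ScenarioSpec("B-3", 19.0, 1.0),
    "B-4": ScenarioSpec("B-4", 20.0, 1.0),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None


@dataclass(frozen=True)
class ConnectivityParams:
    """Wiring parameters for one network realization."""

    epsilon: float
    sigma_c: float  # fraction of L
    N: int
    n_exc: int
    n_inh: int

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 0.21:
            raise ValueError("epsilon must lie in (0, 0.21]")
        if not 0 < self.sigma_c <= 0.10:
            raise ValueError("sigma_c must lie in (0, 0.10]")
        if self.n_exc + self.n_inh != self.N:
            raise ValueError("n_exc + n_inh must equal N")

    @property
    def K(self) -> int:
        return round(self.epsilon * self.N)

    @classmethod
    def from_scenario(cls, scenario: ScenarioSpec, N: int) -> "ConnectivityParams":
        # 4:1 excitatory:inhibitory split
        n_inh = N // 5
        return cls(
            epsilon=scenario.epsilon,
            sigma_c=scenario.sigma_c_frac,
            N=N,
            n_exc=N - n_inh,
            n_inh=n_inh,
        )


@dataclass(frozen=True)
class DelayParams:
    """Linear distance-dependent delay: d = d_syn + r / v."""

    v: float = 0.5  # m/s
    d_syn: float = 0.2  # ms

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("propagation speed must be positive")
        if self.d_syn < 0:
            raise ValueError("synaptic delay must be non-negative")


@dataclass(frozen=True)
class SynapseTable:
    """Flat synapse list: (source, target, weight nS, delay ms, is_inhibitory)."""

    source: np.ndarray
    target: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    is_inhibitory: np.ndarray
    K: int = field(default=0)

    def __len__(self) -> int:
        return int(self.source.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.source,
                "target": self.target,
                "weight_nS": self.weight,
                "delay_ms": self.delay,
                "is_inhibitory": self.is_inhibitory,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, K: int = 0) -> "SynapseTable":
        return cls(
            source=df["source"].to_numpy(np.int64),
            target=df["target"].to_numpy(np.int64),
            weight=df["weight_nS"].to_numpy(float),
            delay=df["delay_ms"].to_numpy(float),
            is_inhibitory=df["is_inhibitory"].to_numpy(bool),
            K=K,
        )

    def validate(self) -> None:
        n_targets = np.unique(self.target).size
        counts = np.bincount(self.target)
        if self.K and not np.all(counts[np.unique(self.target)] == self.K):
            raise ValueError("in-degree differs from K for some target")
        if np.any(self.source == self.target):
            raise ValueError("self-connections are not allowed")
        pairs = self.source.astype(np.int64) * (self.target.max() + 1) + self.target
        if np.unique(pairs).size != len(self):
            raise ValueError("duplicate (source, target) pairs present")
        del n_targets


def pair_distance(i_pos, j_pos, geom: LatticeGeometry) -> float:
    """Euclidean distance under the minimum-image convention (mm)."""
    a = np.asarray(i_pos, dtype=float)
    b = np.asarray(j_pos, dtype=float)
    if np.any(a < 0) or np.any(a >= geom.L) or np.any(b < 0) or np.any(b >= geom.L):
        raise ValueError("coordinates must lie inside the lattice [0, L)")
    d = np.abs(a - b)
    if geom.periodic:
        d = np.minimum(d, geom.L - d)
    return float(np.sqrt(np.sum(d * d, axis=-1)))


def _distances_to(target: int, geom: LatticeGeometry) -> np.ndarray:
    """Minimum-image distances from every neuron to ``target``."""
    d = np.abs(geom.positions - geom.positions[target])
    if geom.periodic:
        d = np.minimum(d, geom.L - d)
    return np.sqrt(np.einsum("ij,ij->i", d, d))


def gaussian_profile(r, sigma_c: float):
    """Connection acceptance probability exp(-r^2 / (2 sigma_c^2))."""
    if sigma_c <= 0:
        raise ValueError("sigma_c must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-(r**2) / (2.0 * sigma_c**2))
    return float(out) if out.ndim == 0 else out


def radial_density(r, geom: LatticeGeometry):
    """Density of the pair distance on the periodic square (per mm).

    Piecewise: 2*pi*r/L^2 up to L/2, then the wrapped-corner branch
    r*(2*pi - 8*arccos(L/(2r)))/L^2 up to the maximal distance L*sqrt(2)/2,
    zero beyond.  Integrates to 1.
    """
    L = geom.L
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = np.zeros_like(r)
    near = r <= L / 2
    out[near] = 2.0 * np.pi * r[near] / L**2
    far = (r > L / 2) & (r <= L * np.sqrt(2) / 2)
    if np.any(far):
        rf = r[far]
        out[far] = rf * (2.0 * np.pi - 8.0 * np.arccos(L / (2.0 * rf))) / L**2
    return float(out[0]) if scalar else out


def normalized_connection_density(
    r, sigma_c: float, epsilon: float, geom: LatticeGeometry
):
    """Accepted-distance density scaled to integrate to ``epsilon``.

    The raw accepted-distance shape is P(r) * exp(-r^2 / 2 sigma_c^2); with a
    fixed in-degree K = eps*N the realized connection fraction is eps, so the
    density is normalized to that mass.
    """
    from scipy.integrate import quad

    rmax = geom.L * np.sqrt(2) / 2

    def shape(x):
        return radial_density(x, geom) * gaussian_profile(x, sigma_c)

    mass, _ = quad(shape, 0.0, rmax, limit=200)
    r = np.asarray(r, dtype=float)
    out = epsilon * radial_density(r, geom) * gaussian_profile(r, sigma_c) / mass
    return float(out) if np.ndim(out) == 0 else out


def sample_in_connections(
    target: int,
    candidates: np.ndarray,
    K: int,
    sigma_c: float,
    geom: LatticeGeometry,
    rng: np.random.Generator,
    method: str = "keys",
) -> np.ndarray:
    """Draw K distinct presynaptic sources for ``target``.

    Candidates are accepted with probability ``exp(-r^2 / 2 sigma_c^2)``;
    repeated rejection until K distinct sources are accepted is equivalent to
    successive weighted sampling without replacement, implemented here with
    the exponential-key trick (``method='keys'``, the fast default).  A
    literal rejection loop (``method='rejection'``) is kept for small cases
    and distribution cross-checks; it errors out after a bounded number of
    attempts when sigma_c is pathologically small.
    """
    candidates = np.asarray(candidates, dtype=np.int64)
    candidates = candidates[candidates != target]
    if K == 0:
        return np.empty(0, dtype=np.int64)
    if K >= geom.n:
        raise ValueError("K must be smaller than the network size")
    if K > candidates.size:
        raise ValueError("not enough candidates to reach in-degree K")

    r = _distances_to(target, geom)[candidates]
    w = gaussian_profile(r, sigma_c)

    if method == "keys":
        positive = w > 0
        if np.count_nonzero(positive) < K:
            raise RuntimeError(
                f"acceptance stalled: only {np.count_nonzero(positive)} candidates "
                f"have non-zero acceptance for sigma_c={sigma_c}"
            )
        keys = np.full(candidates.size, np.inf)
        with np.errstate(over="ignore"):  # denormal weights overflow to inf keys
            keys[positive] = rng.exponential(size=int(positive.sum())) / w[positive]
        chosen = candidates[np.argpartition(keys, K - 1)[:K]]
        return np.sort(chosen)

    if method == "rejection":
        chosen: set[int] = set()
        for _ in range(MAX_REJECTION_ATTEMPTS):
            idx = rng.integers(candidates.size)
            if rng.random() < w[idx]:
                chosen.add(int(candidates[idx]))
                if len(chosen) == K:
                    return np.sort(np.fromiter(chosen, dtype=np.int64))
        raise RuntimeError(
            f"rejection sampling stalled after {MAX_REJECTION_ATTEMPTS} attempts "
            f"(target={target}, sigma_c={sigma_c}, K={K})"
        )

    raise ValueError(f"unknown sampling method {method!r}")


def compute_delay(r, dp: DelayParams):
    """Propagation delay in ms for distance r in mm (v in m/s => r/v in ms)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = dp.d_syn + r / dp.v
    return float(out) if out.ndim == 0 else out


def build_synapse_table(
    scenario: ScenarioSpec,
    cp: ConnectivityParams,
    geom: LatticeGeometry,
    dp: DelayParams,
    sp: SynapseParams,
    rng: np.random.Generator,
) -> SynapseTable:
    """Wire the whole network for one scenario.

    Every neuron receives exactly K synapses; a source's weight and sign
    follow its fixed class (ids < n_exc are excitatory, the rest inhibitory).
    """
    N = cp.N
    K = cp.K
    all_ids = np.arange(N, dtype=np.int64)
    sources = np.empty((N, K), dtype=np.int64)
    delays = np.empty((N, K), dtype=float)
    for tgt in range(N):
        src = sample_in_connections(tgt, all_ids, K, cp.sigma_c, geom, rng)
        sources[tgt] = src
        d = np.abs(geom.positions[src] - geom.positions[tgt])
        if geom.periodic:
            d = np.minimum(d, geom.L - d)
        delays[tgt] = compute_delay(np.sqrt(np.einsum("ij,ij->i", d, d)), dp)

    src_flat = sources.ravel()
    tgt_flat = np.repeat(all_ids, K)
    inhibitory = src_flat >= cp.n_exc
    weights = np.where(inhibitory, sp.g_inh, sp.g_exc)
    return SynapseTable(
        source=src_flat,
        target=tgt_flat,
        weight=weights.astype(float),
        delay=delays.ravel(),
        is_inhibitory=inhibitory,
        K=K,
    )
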