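"""Full-network rate simulator for attractor networks with overlapping engrams.

Neurons follow Wilson-Cowan rate dynamics

    tau dr_i/dt = -r_i + phi(h_i),

with a sigmoidal transfer function phi(h) = r_max / (1 + exp(-b (h - h0)))
and Hopfield-Tsodyks couplings for sparse binary patterns,

    w_ij = A / (N gamma (1-gamma)) * sum_mu (xi_i^mu - gamma)(xi_j^mu - gamma).

Everything here is integrated in *dimensionless* units: time in units of
1/r_max, currents in units of A*r_max, rates in units of r_max.  The two
parameters that matter for the dynamics are then the rescaled steepness
b_hat = b*A*r_max and the rescaled threshold h0_hat = h0/(A*r_max);
``TransferParams`` converts between the dimensional and dimensionless
descriptions.

Optional ingredients: neuron-specific adaptation (a hyperpolarizing current
theta_i with first-order kinetics), a global inhibitory feedback
-J0(t)/(gamma N) * sum_j r_j whose strength can be modulated periodically
(the clock that drives association chains), random dilution of the weight
matrix with 1/d compensation, and heterogeneous per-neuron f-I curves.

The retrieval readout is the similarity (overlap)

    m^mu = 1/(N gamma (1-gamma) r_max) * sum_j (xi_j^mu - gamma) r_j,

which is ~1 when engram mu is retrieved and ~0 at rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import expit

from .patterns import PatternEnsemble

__all__ = [
    "TransferParams",
    "AdaptationParams",
    "OscillatoryInhibition",
    "ConstantInhibition",
    "HeterogeneityParams",
    "NetworkParams",
    "StimulusEvent",
    "StimulusSchedule",
    "SimulationTrace",
    "build_couplings",
    "transfer_phi",
    "similarity",
    "simulate",
    "nondimensionalize",
    "dimensionalize",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class TransferParams:
    """Dimensional f-I curve parameters.

    A : overall coupling strength (current * time); b : steepness
    (1/current); h0 : firing threshold (current); r_max : maximal rate
    (1/time).  The dimensionless combinations are b_hat = b*A*r_max and
    h0_hat = h0/(A*r_max).
    """

    A: float
    b: float
    h0: float
    r_max: float

    def __post_init__(self):
        if self.r_max <= 0 or self.A <= 0:
            raise ValueError("A and r_max must be positive")
        if self.b < 0:
            raise ValueError("steepness b must be non-negative")

    @property
    def b_hat(self) -> float:
        return self.b * self.A * self.r_max

    @property
    def h0_hat(self) -> float:
        return self.h0 / (self.A * self.r_max)

    @classmethod
    def from_dimensionless(
        cls, b_hat: float, h0_hat: float, r_max: float = 40.0, A: float = 1.0
    ) -> "TransferParams":
        """Pick dimensional (b, h0) reproducing (b_hat, h0_hat) for given A, r_max."""
        return cls(A=A, b=b_hat / (A * r_max), h0=h0_hat * A * r_max, r_max=r_max)


def nondimensionalize(transfer: TransferParams, tau: float) -> dict:
    """Map dimensional parameters to the dimensionless ones used internally.

    Time is measured in units of 1/r_max and currents in units of A*r_max:
    b_hat = b*A*r_max, h0_hat = h0/(A*r_max), tau_hat = tau*r_max.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return {
        "b_hat": transfer.b_hat,
        "h0_hat": transfer.h0_hat,
        "tau_hat": tau * transfer.r_max,
    }


def dimensionalize(
    b_hat: float, h0_hat: float, tau_hat: float, r_max: float, A: float = 1.0
) -> tuple[TransferParams, float]:
    """Inverse of :func:`nondimensionalize` for a chosen (A, r_max)."""
    if r_max <= 0 or A <= 0:
        raise ValueError("A and r_max must be positive")
    tp = TransferParams.from_dimensionless(b_hat, h0_hat, r_max=r_max, A=A)
    return tp, tau_hat / r_max


@dataclass
class AdaptationParams:
    """Neuron-specific adaptation: tau_theta dtheta/dt = -theta + theta0 + D_theta r."""

    tau_theta_hat: float
    D_theta_hat: float
    theta0: float = 0.0

    def __post_init__(self):
        if self.tau_theta_hat <= 0:
            raise ValueError("tau_theta must be positive")


@dataclass
class OscillatoryInhibition:
    """Sinusoidal modulation of the global inhibition strength J0(t).

    J0(t) = (Jmax-Jmin)/2 * sin(2 pi t / T - pi/2) + (Jmax+Jmin)/2,
    i.e. J0 starts at Jmin, peaks at t = T/2 and returns to Jmin at t = T.
    """

    J_min: float = 0.7
    J_max: float = 1.2
    period_hat: float = 25.0

    def __post_init__(self):
        if self.J_min > self.J_max:
            raise ValueError("J_min must not exceed J_max")
        if self.period_hat <= 0:
            raise ValueError("inhibition period must be positive")

    def value(self, t: float) -> float:
        return 0.5 * (self.J_max - self.J_min) * np.sin(
            2.0 * np.pi * t / self.period_hat - np.pi / 2.0
        ) + 0.5 * (self.J_max + self.J_min)


@dataclass
class ConstantInhibition:
    J0: float = 0.5

    def value(self, t: float) -> float:
        return self.J0


@dataclass
class HeterogeneityParams:
    """Gaussian per-neuron minimal/maximal rates, in units of mu_max.

    mu_min, sigma_min, mu_max, sigma_max are dimensional rates; internally
    everything is normalized by mu_max.  Draws violating
    r_max_i > r_min_i >= 0 are rejected and redrawn.
    """

    mu_min: float = 0.0
    sigma_min: float = 4.0
    mu_max: float = 40.0
    sigma_max: float = 4.0


@dataclass
class NetworkParams:
    """Dimensionless simulation parameters (time unit 1/r_max, current unit A*r_max)."""

    b_hat: float = 100.0
    h0_hat: float = 0.25
    tau_hat: float = 1.0
    heaviside: bool = False
    adaptation: AdaptationParams | None = None
    inhibition: OscillatoryInhibition | ConstantInhibition | None = None
    dilution: float = 1.0
    exclude_self: bool = False
    heterogeneity: HeterogeneityParams | None = None

    def __post_init__(self):
        if not 0.0 < self.dilution <= 1.0:
            raise ValueError("dilution d must be in (0, 1]")
        if self.tau_hat <= 0:
            raise ValueError("tau must be positive")


# --------------------------------------------------------------------------
# stimulation
# --------------------------------------------------------------------------

@dataclass
class StimulusEvent:
    """Constant input of given dimensionless amplitude to a pattern's neurons
    (or to an explicit neuron mask) during [t_on, t_off)."""

    t_on: float
    t_off: float
    amplitude: float
    pattern: int | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.t_off < self.t_on or self.t_on < 0:
            raise ValueError("stimulus window must satisfy 0 <= t_on <= t_off")
        if not np.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        if (self.pattern is None) == (self.mask is None):
            raise ValueError("specify exactly one of pattern index or neuron mask")


@dataclass
class StimulusSchedule:
    events: list[StimulusEvent] = field(default_factory=list)

    def current(self, t: float, ensemble: PatternEnsemble) -> np.ndarray | None:
        """External input vector at time t; None when no event is active."""
        I = None
        for ev in self.events:
            if ev.t_on <= t < ev.t_off:
                if I is None:
                    I = np.zeros(ensemble.N)
                if ev.pattern is not None:
                    I[ensemble.patterns[ev.pattern]] += ev.amplitude
                else:
                    I[ev.mask] += ev.amplitude
        return I


# --------------------------------------------------------------------------
# couplings
# --------------------------------------------------------------------------

class FactoredCoupling:
    """Low-rank (pattern-space) coupling for full connectivity.

    For d = 1 the recurrent input is exactly
    h_i = sum_mu (xi_i^mu - gamma) m^mu, so no N x N matrix is needed.
    Excluding self-interaction subtracts the diagonal w_ii r_i term.
    """

    def __init__(self, ensemble: PatternEnsemble, exclude_self: bool = False):
        N, P = ensemble.N, ensemble.n_patterns
        rows = np.concatenate(ensemble.patterns) if P else np.array([], dtype=int)
        cols = np.concatenate(
            [np.full(len(idx), mu) for mu, idx in enumerate(ensemble.patterns)]
        ) if P else np.array([], dtype=int)
        self.S = sparse.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(N, P)
        )
        self.ST = self.S.T.tocsr()
        self.gamma = ensemble.gamma
        self.N = N
        self.P = P
        self.norm = 1.0 / (N * ensemble.gamma * (1.0 - ensemble.gamma))
        self.exclude_self = exclude_self
        if exclude_self:
            # w_ii = sum_mu (xi_i^mu - gamma)^2 / (N gamma (1-gamma))
            counts = np.asarray(self.S.sum(axis=1)).ravel()
            self.w_diag = self.norm * (
                counts * (1.0 - self.gamma) ** 2
                + (P - counts) * self.gamma**2
            )
        else:
            self.w_diag = None

    def overlaps(self, r: np.ndarray) -> np.ndarray:
        return self.norm * (self.ST @ r - self.gamma * r.sum())

    def input(self, r: np.ndarray) -> np.ndarray:
        m = self.overlaps(r)
        h = self.S @ m - self.gamma * m.sum()
        if self.exclude_self:
            h = h - self.w_diag * r
        return h

    def dense(self) -> np.ndarray:
        """Materialize the equivalent dense weight matrix (tests only)."""
        xi = self.S.toarray() - self.gamma
        W = self.norm * xi @ xi.T
        if self.exclude_self:
            np.fill_diagonal(W, 0.0)
        return W


class DenseCoupling:
    """Explicit (possibly diluted) weight matrix with 1/d compensation.

    w_ij = d_ij/(d N gamma (1-gamma)) * sum_mu (xi_i^mu - gamma)(xi_j^mu - gamma)
    with d_ij ~ Bernoulli(d).  Memory is O(N^2); intended for N up to a few
    thousand.
    """

    _MAX_N = 6000

    def __init__(
        self,
        ensemble: PatternEnsemble,
        dilution: float = 1.0,
        exclude_self: bool = False,
        seed: int = 0,
    ):
        N = ensemble.N
        if N > self._MAX_N:
            raise MemoryError(
                f"explicit weight matrix requested for N={N} > {self._MAX_N}; "
                "use the factored representation (d=1) or a smaller network"
            )
        xi = ensemble.to_dense().astype(float) - ensemble.gamma
        W = xi @ xi.T / (N * ensemble.gamma * (1.0 - ensemble.gamma))
        if dilution < 1.0:
            rng = np.random.default_rng(seed)
            mask = rng.random((N, N)) < dilution
            W = W * mask / dilution
        if exclude_self:
            np.fill_diagonal(W, 0.0)
        self.W = W
        self.gamma = ensemble.gamma
        self.norm = 1.0 / (N * ensemble.gamma * (1.0 - ensemble.gamma))
        self.ST = sparse.csr_matrix(
            (ensemble.to_dense().T > 0).astype(float)
        )
        self.N = N

    def overlaps(self, r: np.ndarray) -> np.ndarray:
        return self.norm * (self.ST @ r - self.gamma * r.sum())

    def input(self, r: np.ndarray) -> np.ndarray:
        return self.W @ r

    def dense(self) -> np.ndarray:
        return self.W


def build_couplings(
    ensemble: PatternEnsemble,
    dilution: float = 1.0,
    exclude_self: bool = False,
    seed: int = 0,
):
    """Coupling representation for the given ensemble.

    Full connectivity uses the factored pattern-space form (mathematically
    identical to the explicit matrix, no N^2 memory); dilution requires the
    explicit Bernoulli-masked matrix.
    """
    if dilution >= 1.0:
        return FactoredCoupling(ensemble, exclude_self=exclude_self)
    return DenseCoupling(
        ensemble, dilution=dilution, exclude_self=exclude_self, seed=seed
    )


# --------------------------------------------------------------------------
# transfer function and similarity
# --------------------------------------------------------------------------

def transfer_phi(
    h: np.ndarray,
    b_hat: float,
    h0_hat: float,
    heaviside: bool = False,
    r_min: np.ndarray | float = 0.0,
    r_max: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Dimensionless transfer function, optionally heterogeneous.

    phi(h) = r_min + (r_max - r_min) * sigmoid(b_hat (h - h0_hat)); the
    Heaviside flag gives the b -> infinity limit with strict threshold
    (phi = r_max for h > h0, r_min otherwise).
    """
    h = np.asarray(h, dtype=float)
    if heaviside:
        s = (h > h0_hat).astype(float)
    else:
        s = expit(b_hat * (h - h0_hat))
    return r_min + (r_max - r_min) * s


def similarity(rates: np.ndarray, ensemble: PatternEnsemble, mu: int) -> float:
    """Overlap m^mu of a dimensionless rate vector with pattern mu."""
    if not 0.0 < ensemble.gamma < 1.0:
        raise ValueError("similarity undefined for gamma in {0, 1}")
    g = ensemble.gamma
    idx = ensemble.patterns[mu]
    return float(
        (rates[idx].sum() - g * rates.sum()) / (ensemble.N * g * (1.0 - g))
    )


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Time series output of :func:`simulate` (all dimensionless)."""

    t: np.ndarray
    m: np.ndarray                      # (T, P) overlaps
    J0: np.ndarray | None = None
    theta_mean: np.ndarray | None = None
    rates: np.ndarray | None = None    # decimated snapshots (T_r, N)
    rates_t: np.ndarray | None = None

    def retrieval_events(self, threshold: float = 0.5) -> list[dict]:
        """Contiguous episodes with m^mu above threshold: onset/offset/peak."""
        events = []
        for mu in range(self.m.shape[1]):
            above = self.m[:, mu] > threshold
            edges = np.flatnonzero(np.diff(above.astype(int)))
            starts = list(edges[~above[edges]] + 1)
            stops = list(edges[above[edges]] + 1)
            if above[0]:
                starts.insert(0, 0)
            if above[-1]:
                stops.append(len(above))
            for s0, s1 in zip(starts, stops):
                events.append({
                    "pattern": mu,
                    "onset": float(self.t[s0]),
                    "offset": float(self.t[min(s1, len(self.t) - 1)]),
                    "peak_m": float(self.m[s0:s1, mu].max()),
                })
        return sorted(events, key=lambda e: e["onset"])


def _initial_rates(init, ensemble: PatternEnsemble) -> np.ndarray:
    if isinstance(init, np.ndarray):
        return init.astype(float).copy()
    if init == "rest" or init is None:
        return np.zeros(ensemble.N)
    if isinstance(init, tuple) and init[0] == "pattern":
        r = np.zeros(ensemble.N)
        r[ensemble.patterns[init[1]]] = 1.0
        return r
    raise ValueError(f"unrecognized initial condition {init!r}")


def simulate(
    ensemble: PatternEnsemble,
    params: NetworkParams,
    schedule: StimulusSchedule | None = None,
    init="rest",
    duration: float = 20.0,
    dt: float = 0.1,
    seed: int = 0,
    record_rates: bool = False,
    record_every: int = 1,
) -> SimulationTrace:
    """Forward-Euler integration of the full rate network (dimensionless).

    ``init`` is "rest" (all rates zero), ("pattern", mu) (rates r_max on
    engram mu's neurons — "initialized to retrieve" the memory), or an
    explicit rate vector.  Overlaps m^mu(t) are recorded every
    ``record_every`` steps; raw rates optionally as decimated snapshots.

    Raises RuntimeError on numerical divergence; warns when dt > tau/5.
    """
    if dt > params.tau_hat / 5.0:
        warnings.warn(
            f"dt={dt} exceeds tau/5={params.tau_hat / 5:.3g}; "
            "Euler integration may be inaccurate", stacklevel=2
        )
    N = ensemble.N
    gamma = ensemble.gamma
    coupling = build_couplings(
        ensemble, dilution=params.dilution,
        exclude_self=params.exclude_self, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    het = params.heterogeneity
    if het is not None:
        scale = het.mu_max
        r_min_i = rng.normal(het.mu_min / scale, het.sigma_min / scale, N)
        r_max_i = rng.normal(1.0, het.sigma_max / scale, N)
        bad = (r_min_i < 0) | (r_max_i <= r_min_i)
        while bad.any():
            r_min_i[bad] = rng.normal(het.mu_min / scale, het.sigma_min / scale,
                                      bad.sum())
            r_max_i[bad] = rng.normal(1.0, het.sigma_max / scale, bad.sum())
            bad = (r_min_i < 0) | (r_max_i <= r_min_i)
        h0_i = params.h0_hat * (r_max_i - r_min_i)
        span = r_max_i - r_min_i
    else:
        r_min_i = 0.0
        r_max_i = 1.0
        h0_i = params.h0_hat
        span = None

    r = _initial_rates(init, ensemble)
    theta = np.zeros(N) if params.adaptation else None
    if params.adaptation and params.adaptation.theta0:
        theta += params.adaptation.theta0

    n_steps = int(round(duration / dt))
    rec_idx = np.arange(0, n_steps + 1, record_every)
    t_rec = rec_idx * dt
    m_rec = np.empty((rec_idx.size, ensemble.n_patterns))
    J_rec = np.empty(rec_idx.size) if params.inhibition else None
    th_rec = np.empty(rec_idx.size) if theta is not None else None
    snapshots, snap_t = [], []
    rec_ptr = 0

    for step in range(n_steps + 1):
        t = step * dt
        # effective rates entering recurrence/readout (heterogeneous rescale)
        r_eff = (np.clip((r - r_min_i) / span, 0.0, None)
                 if span is not None else r)
        if rec_ptr < rec_idx.size and step == rec_idx[rec_ptr]:
            m_rec[rec_ptr] = coupling.overlaps(r_eff)
            if J_rec is not None:
                J_rec[rec_ptr] = params.inhibition.value(t)
            if th_rec is not None:
                th_rec[rec_ptr] = theta.mean()
            if record_rates and rec_ptr % 10 == 0:
                snapshots.append(r.copy())
                snap_t.append(t)
            rec_ptr += 1
        if step == n_steps:
            break

        h = coupling.input(r_eff)
        if theta is not None:
            h = h - theta
        if params.inhibition is not None:
            h = h - params.inhibition.value(t) / gamma * r_eff.mean()
        if schedule is not None:
            I = schedule.current(t, ensemble)
            if I is not None:
                h = h + I
        phi = transfer_phi(
            h, params.b_hat, h0_i, heaviside=params.heaviside,
            r_min=r_min_i, r_max=r_max_i,
        )
        r = r + dt / params.tau_hat * (-r + phi)
        if theta is not None:
            ad = params.adaptation
            theta = theta + dt / ad.tau_theta_hat * (
                -theta + ad.theta0 + ad.D_theta_hat * r
            )
        if not np.isfinite(r).all():
            raise RuntimeError(
                f"simulation diverged at t={t:.3f} "
                f"(max |r|={np.abs(r[np.isfinite(r)]).max() if np.isfinite(r).any() else np.nan})"
            )

    return SimulationTrace(
        t=t_rec, m=m_rec, J0=J_rec, theta_mean=th_rec,
        rates=np.array(snapshots) if snapshots else None,
        rates_t=np.array(snap_t) if snap_t else None,
    )
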