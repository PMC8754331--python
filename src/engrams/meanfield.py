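"""Mean-field theory of retrieval in networks with overlapping engrams.

In the large-N limit the network dynamics closes on the overlaps m^mu of the
retrieved (correlated) patterns.  Neurons split into 2^n sub-populations by
their joint selectivity x = (x^1..x^n) to the n correlated patterns, with
joint probabilities P_x; the mean-field input of population x is

    h_x = sum_nu (x^nu - gamma) m^nu + I_x - theta_x - (J0/gamma) <r>
          + sqrt(alpha R) z  (+ self-interaction correction),

where z ~ N(0,1) captures the quenched noise of the non-retrieved
"background" patterns, whose mean squared overlap R = p/(1-q)^2 is solved
self-consistently from q = <phi'(h)> and p = <phi^2(h)>.  The overlap
dynamics is tau dm^mu/dt = -m^mu + F_mu(m) with

    F_mu(m) = sum_x P_x (x^mu - gamma)/(gamma(1-gamma)) <phi(h_x)>_z .

At zero load (alpha = 0) the Gaussian integrals collapse and the equations
are exact.  Fixed points are found by multi-start root solving, classified
by the Jacobian, and continued in the pattern correlation C to locate the
saddle-node bifurcations that bound the admissible range of shared-neuron
fractions: c_max where the single-retrieval states merge with their saddles
and disappear, and (with global inhibition) c_min where a stable symmetric
state appears.  The b -> infinity (Heaviside) limit admits closed forms and
exact fixed-point enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import erfc, expit

from .patterns import fraction_to_pearson, group_joint_probabilities, pearson_to_fraction

__all__ = [
    "MeanFieldParams",
    "FixedPoint",
    "BifurcationResult",
    "MeanField",
    "mf_rhs",
    "solve_self_consistent_R",
    "scan_R_grid",
    "background_R_correction",
    "sherman_morrison_inverse",
    "find_fixed_points",
    "jacobian_stability",
    "phase_plane",
    "extract_c_max",
    "extract_c_min_symmetric",
    "analytic_cmax_bound",
    "heaviside_second_overlap",
    "zero_sparsity_fixed_points",
    "extract_cmax_zero_sparsity",
    "mf_dynamics_adaptation",
    "chain_correlation_bounds",
    "min_stimulation_curve",
]

_STAB_TOL = 1e-6


# --------------------------------------------------------------------------
# parameters and result containers
# --------------------------------------------------------------------------

@dataclass
class MeanFieldParams:
    """Configuration of the mean-field reduction.

    gamma : engram sparsity.
    C : Pearson correlation among the n_corr retrieved patterns
        (equicorrelated; c = C(1-gamma)+gamma).
    n_corr : number of tracked correlated patterns (1-4 closed form).
    alpha : memory load P/N (P/M when diluted); 0 makes the theory exact.
    b_hat, h0_hat : rescaled steepness and threshold of the f-I curve.
    heaviside : force the b -> infinity limit; None switches automatically
        for b_hat > 1000 (erfc closed forms / exact enumeration).
    J0 : constant global-inhibition strength, or None.
    exclude_self : apply the self-interaction exclusion correction.
    background_C, background_group : pairwise correlation and group size of
        the *background* patterns (R correction); 0 means independent.
    quad_nodes : Gauss-Hermite node count for the Gaussian integrals.
    """

    gamma: float = 0.002
    C: float = 0.0
    n_corr: int = 2
    alpha: float = 0.0
    b_hat: float = 100.0
    h0_hat: float = 0.25
    heaviside: bool | None = None
    J0: float | None = None
    exclude_self: bool = False
    background_C: float = 0.0
    background_group: int = 2
    quad_nodes: int = 101
    R_max: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0,1), got {self.gamma}")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 1 <= self.n_corr <= 4:
            raise ValueError("closed forms available for 1-4 correlated patterns")
        if self.heaviside is None:
            # steep sigmoids are numerically indistinguishable from a step
            self.heaviside = self.b_hat > 1000

    @property
    def c(self) -> float:
        return pearson_to_fraction(self.C, self.gamma)


@dataclass
class FixedPoint:
    """A mean-field equilibrium with its stability classification."""

    m: np.ndarray
    stability: str                 # stable | saddle | unstable | marginal
    eigenvalues: np.ndarray | None = None
    R: float = 0.0
    mean_rate: float = 0.0         # <r> (drives the global inhibition)
    residual: float = 0.0

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class BifurcationResult:
    """Outcome of a bifurcation scan in the pattern correlation C."""

    found: bool
    C_crit: float | None
    c_crit: float | None
    kind: str                      # "c_max" | "c_min" | ...
    grid_step: float
    C_grid: np.ndarray | None = None
    loci: list | None = None       # per grid C: list of (m-projection, stability)
    note: str = ""


# --------------------------------------------------------------------------
# background-pattern correlation corrections
# --------------------------------------------------------------------------

def sherman_morrison_inverse(D: float, qC: float, p_group: int) -> np.ndarray:
    """Closed-form inverse of M = D*I - qC*(ones - I) (size p_group).

    Writing M = a*I - b*J with a = D + qC, b = qC and J the all-ones
    matrix, the Sherman-Morrison formula gives
    M^-1 = I/a + b/(a*(a - p_group*b)) * J.  Singular when
    D = (p_group - 1) qC.
    """
    a = D + qC
    b = qC
    denom = a * (a - p_group * b)
    if abs(a) < 1e-14 or abs(a - p_group * b) < 1e-14:
        raise ValueError(
            f"singular background matrix: D={D}, qC={qC}, group={p_group}"
        )
    g = p_group
    return np.eye(g) / a + (b / denom) * np.ones((g, g))


def background_R_correction(
    p: float, q: float, C_background: float, group_size: int | None = 2
) -> float:
    """Effective mean squared background overlap R with correlated background.

    Background patterns correlated pairwise (or in disjoint groups of
    ``group_size``) with Pearson C couple their overlap amplitudes through
    the linear system M m = B with M = (1-q) I - qC (ones - I).  The
    effective R entering the retrieval equations is

        R_eff = p * tr(K M^-1 K M^-1) / group_size,

    K being the correlation matrix (1 on the diagonal, C off it), which for
    C = 0 reduces to the standard R = p/(1-q)^2.  ``group_size=None``
    represents *all* background patterns sharing the same correlation; the
    resulting noise variance grows like P^2/N and diverges in the mean-field
    limit, so that case is rejected rather than evaluated.
    """
    D = 1.0 - q
    if group_size is None:
        if C_background > 0:
            raise ValueError(
                "all-pattern correlation C>0: background noise scales as "
                "P^2/N and diverges for N -> infinity at fixed load alpha"
            )
        return p / D**2
    if group_size < 2:
        raise ValueError("group_size must be >= 2 (or None for all patterns)")
    if C_background == 0.0:
        return p / D**2
    g = group_size
    C = C_background
    Minv = sherman_morrison_inverse(D, q * C, g)
    K = np.full((g, g), C)
    np.fill_diagonal(K, 1.0)
    A = K @ Minv
    return float(p * np.trace(A @ A) / g)


def background_pair_R(p: float, q: float, C: float) -> float:
    """Closed form of the pairwise-correlated background R (group of 2):

    R = p [D^2 + q^2 C^2 + 4 D q C^2 + D^2 C^2 + q^2 C^4] / (D^2 - (qC)^2)^2,
    D = 1 - q.  Equals the general group formula at group_size = 2.
    """
    D = 1.0 - q
    num = D**2 + q**2 * C**2 + 4 * D * q * C**2 + D**2 * C**2 + q**2 * C**4
    return p * num / (D**2 - (q * C) ** 2) ** 2


# --------------------------------------------------------------------------
# the evaluator
# --------------------------------------------------------------------------

class MeanField:
    """Evaluator of the mean-field right-hand side and its equilibria."""

    def __init__(self, params: MeanFieldParams):
        self.params = params
        n = params.n_corr
        g = params.gamma
        self.states = np.array(
            list(itertools.product((0.0, 1.0), repeat=n))
        )  # (2^n, n), x[0] slowest bit; order irrelevant as long as consistent
        self.P = self._joint_probs()
        self.Xc = self.states - g
        self.coef = self.Xc / (g * (1.0 - g))
        if params.alpha > 0 and not params.heaviside:
            x, w = np.polynomial.hermite.hermgauss(params.quad_nodes)
            self.z = np.sqrt(2.0) * x
            self.w = w / np.sqrt(np.pi)
        else:
            self.z = self.w = None

    def _joint_probs(self) -> np.ndarray:
        p = self.params
        probs = group_joint_probabilities(p.gamma, p.C, p.n_corr)
        # group_joint_probabilities orders bit0 fastest; re-order to match
        # itertools.product (bit0 slowest)
        n = p.n_corr
        order = [
            sum(((i >> (n - 1 - k)) & 1) << k for k in range(n))
            for i in range(2**n)
        ]
        return probs[order]

    # -- transfer -----------------------------------------------------------
    def _phi(self, h):
        p = self.params
        if p.heaviside:
            return (np.asarray(h) > p.h0_hat).astype(float)
        return expit(p.b_hat * (np.asarray(h) - p.h0_hat))

    def _dphi(self, h):
        p = self.params
        if p.heaviside:
            raise ValueError("phi' is a Dirac delta in the Heaviside limit")
        s = self._phi(h)
        return p.b_hat * s * (1.0 - s)

    def _pop_averages(self, base: np.ndarray, sigma: float):
        """Per-population <phi>, plus aggregated q = <phi'> and p = <phi^2>.

        ``base`` is the z-free part of the input of each population; sigma
        the background-noise standard deviation sqrt(alpha R).
        """
        prm = self.params
        if sigma == 0.0:
            r = self._phi(base)
            pval = float(self.P @ r**2)
            qval = float(self.P @ self._dphi(base)) if not prm.heaviside else 0.0
            return r, qval, pval
        if prm.heaviside:
            arg = (prm.h0_hat - base) / sigma
            r = 0.5 * erfc(arg / np.sqrt(2.0))
            pval = float(self.P @ r)  # phi^2 = phi for a 0/1 step
            dens = np.exp(-0.5 * arg**2) / (np.sqrt(2.0 * np.pi) * sigma)
            qval = float(self.P @ dens)
            return r, qval, pval
        h = base[:, None] + sigma * self.z[None, :]
        phi = expit(prm.b_hat * (h - prm.h0_hat))
        r = phi @ self.w
        pval = float(self.P @ ((phi**2) @ self.w))
        qval = float(self.P @ ((prm.b_hat * phi * (1 - phi)) @ self.w))
        return r, qval, pval

    # -- input assembly with inner self-consistencies ------------------------
    def _raw_inputs(self, m, I=None, theta=None) -> np.ndarray:
        m = np.atleast_1d(np.asarray(m, dtype=float))
        base = self.Xc @ m
        if I is not None:
            base = base + self.states @ np.asarray(I, dtype=float)
        if theta is not None:
            base = base - np.asarray(theta, dtype=float)
        return base

    def _self_corrected(self, base, q):
        """Self-interaction exclusion: h -> h + q alpha phi(h)/(1-q), solved
        population-wise by fixed-point iteration on the mean input (the
        first-order-in-z approximation); in the Heaviside limit the
        correction is the constant alpha/2."""
        prm = self.params
        if not prm.exclude_self or prm.alpha == 0.0:
            return base
        if prm.heaviside:
            return base + prm.alpha / 2.0
        h = base.copy()
        for _ in range(200):
            h_new = base + q * prm.alpha * self._phi(h) / (1.0 - q)
            if np.max(np.abs(h_new - h)) < 1e-12:
                return h_new
            h = 0.5 * h + 0.5 * h_new
        raise RuntimeError("self-interaction recursion did not converge")

    def _solve_populations(self, raw, J0, sigma, q_guess=0.0):
        """Population rates with global inhibition and self-interaction.

        With inhibition the mean rate u = sum_x P_x <r_x> feeds back into
        every input as -(J0/gamma) u; the map u -> sum P r(u) is strictly
        decreasing, so the unique root is found with brentq.
        Returns (r_x, q, p, u).
        """
        prm = self.params
        q = q_guess

        def rates_at(u):
            base = raw - (J0 / prm.gamma) * u if J0 is not None else raw
            base = self._self_corrected(base, q)
            return self._pop_averages(base, sigma)

        if J0 is None:
            if prm.exclude_self and prm.alpha > 0 and not prm.heaviside:
                # q enters its own correction: iterate the (q, h) pair
                for _ in range(100):
                    r, q_new, pval = rates_at(0.0)
                    if abs(q_new - q) < 1e-12:
                        q = q_new
                        break
                    q = 0.5 * q + 0.5 * q_new
                r, q, pval = rates_at(0.0)
                return r, q, pval, float(self.P @ r)
            r, q, pval = rates_at(0.0)
            return r, q, pval, float(self.P @ r)

        def g(u):
            r, _, _ = rates_at(u)
            return float(self.P @ r) - u

        lo, hi = 0.0, 1.0
        glo = g(lo)
        if glo <= 0.0:
            u = 0.0
        else:
            while g(hi) > 0 and hi < 16:
                hi *= 2.0
            u = optimize.brentq(g, lo, hi, xtol=1e-13)
        r, q, pval = rates_at(u)
        return r, q, pval, u

    # -- background self-consistency -----------------------------------------
    def solve_R(self, m, I=None, theta=None, J0=None, R0=0.0,
                damping=0.5, tol=1e-11, max_iter=500):
        """Self-consistent mean squared background overlap R at state m.

        Damped fixed-point iteration R <- (1-d) R + d R_map(p(R), q(R));
        returns None when no solution is found in [0, R_max * 4] (the
        fixed-point scan then skips the state).
        """
        prm = self.params
        if prm.alpha == 0.0:
            return 0.0
        raw = self._raw_inputs(m, I, theta)
        R = R0
        for _ in range(max_iter):
            sigma = np.sqrt(prm.alpha * max(R, 0.0))
            _, q, pval, _ = self._solve_populations(raw, J0, sigma)
            if q >= 1.0:
                return None
            try:
                R_new = background_R_correction(
                    pval, q, prm.background_C, prm.background_group
                )
            except ValueError:
                return None
            if not np.isfinite(R_new) or R_new > 4.0 * max(prm.R_max, 1.0):
                return None
            if abs(R_new - R) < tol:
                return float(R_new)
            R = (1.0 - damping) * R + damping * R_new
        return None

    # -- the right-hand side --------------------------------------------------
    def equilibrium_quantities(self, m, I=None, theta=None, J0=None, R=None):
        """Population rates r_x plus (q, p, R, u) at overlap state m."""
        prm = self.params
        if J0 is None and prm.J0 is not None:
            J0 = prm.J0
        raw = self._raw_inputs(m, I, theta)
        if prm.alpha == 0.0:
            sigma = 0.0
            R = 0.0
        else:
            if R is None:
                R = self.solve_R(m, I, theta, J0)
                if R is None:
                    raise RuntimeError(
                        f"no self-consistent background R at m={np.asarray(m)}"
                    )
            sigma = np.sqrt(prm.alpha * R)
        r, q, pval, u = self._solve_populations(raw, J0, sigma)
        return {"r": r, "q": q, "p": pval, "R": R, "u": u}

    def rhs(self, m, I=None, theta=None, J0=None, R=None) -> np.ndarray:
        """dm/dt = -m + F(m) of the closed overlap dynamics."""
        m = np.atleast_1d(np.asarray(m, dtype=float))
        eq = self.equilibrium_quantities(m, I, theta, J0, R)
        F = (self.P * eq["r"]) @ self.coef
        return -m + F

    # -- Jacobian and stability ------------------------------------------------
    def jacobian(self, m, I=None, theta=None, J0=None) -> np.ndarray:
        """Jacobian of the overlap dynamics at m.

        Analytic at zero load with a smooth transfer (including the implicit
        derivative of the inhibition feedback); central finite differences of
        the full RHS otherwise.
        """
        prm = self.params
        m = np.atleast_1d(np.asarray(m, dtype=float))
        if J0 is None and prm.J0 is not None:
            J0 = prm.J0
        if prm.alpha == 0.0 and not prm.heaviside:
            eq = self.equilibrium_quantities(m, I, theta, J0)
            base = self._raw_inputs(m, I, theta)
            if J0 is not None:
                base = base - (J0 / prm.gamma) * eq["u"]
            dphi = self._dphi(base)
            w = self.P * dphi
            if J0 is not None:
                S = float(w.sum())
                s_vec = w @ self.Xc                      # (n,)
                du = s_vec / (1.0 + (J0 / prm.gamma) * S)
                dbase = self.Xc - (J0 / prm.gamma) * du[None, :]
            else:
                dbase = self.Xc
            J = self.coef.T @ (w[:, None] * dbase) - np.eye(len(m))
            return J
        # finite differences (background R re-solved at each displacement)
        n = len(m)
        J = np.zeros((n, n))
        h = 1e-6
        for j in range(n):
            dm = np.zeros(n)
            dm[j] = h
            J[:, j] = (self.rhs(m + dm, I, theta, J0) -
                       self.rhs(m - dm, I, theta, J0)) / (2 * h)
        return J

    def classify(self, m, I=None, theta=None, J0=None):
        J = self.jacobian(m, I, theta, J0)
        ev = np.linalg.eigvals(J)
        re = ev.real
        if np.all(re < -_STAB_TOL):
            label = "stable"
        elif np.all(re > _STAB_TOL):
            label = "unstable"
        elif np.any(re > _STAB_TOL) and np.any(re < -_STAB_TOL):
            label = "saddle"
        else:
            label = "marginal"
        return label, ev

    # -- fixed points -----------------------------------------------------------
    def _default_seeds(self):
        n = self.params.n_corr
        C = self.params.C
        pts = list(itertools.product((0.0, 0.45, 1.0), repeat=n))
        if n >= 2:
            extra = [
                np.eye(n)[k] + C * (1 - np.eye(n)[k]) for k in range(n)
            ]
            pts += [tuple(e) for e in extra]
            pts += [tuple(np.full(n, v)) for v in (0.05, 0.2, 0.9)]
        return [np.array(p, dtype=float) for p in pts]

    def find_fixed_points(
        self, I=None, J0=None, seeds=None, residual_tol=1e-8, dedupe_tol=5e-4,
    ) -> list[FixedPoint]:
        """All equilibria reachable from the seed set, deduplicated and
        classified.  Heaviside zero-load mode enumerates the finitely many
        self-consistent population-activation configurations instead (the
        transfer is piecewise constant, so every consistent point is a
        stable plateau)."""
        prm = self.params
        if prm.heaviside and prm.alpha == 0.0:
            return self._heaviside_fixed_points(I=I, J0=J0)
        if seeds is None:
            seeds = self._default_seeds()
        found: list[FixedPoint] = []
        for s in seeds:
            try:
                sol = optimize.root(
                    lambda mm: self.rhs(mm, I=I, J0=J0), s,
                    method="hybr", options={"xtol": 1e-12},
                )
            except RuntimeError:
                continue
            if not sol.success:
                continue
            m = sol.x
            if np.any(m < -0.35) or np.any(m > 1.35):
                continue
            res = float(np.max(np.abs(self.rhs(m, I=I, J0=J0))))
            if res > residual_tol:
                continue
            if any(np.max(np.abs(m - f.m)) < dedupe_tol for f in found):
                continue
            label, ev = self.classify(m, I=I, J0=J0)
            eq = self.equilibrium_quantities(m, I=I, J0=J0)
            found.append(FixedPoint(
                m=m, stability=label, eigenvalues=ev,
                R=eq["R"], mean_rate=eq["u"], residual=res,
            ))
        return sorted(found, key=lambda f: tuple(np.round(f.m, 6)))

    def _heaviside_fixed_points(self, I=None, J0=None) -> list[FixedPoint]:
        prm = self.params
        if J0 is None and prm.J0 is not None:
            J0 = prm.J0
        n_pop = len(self.P)
        out = []
        for bits in itertools.product((0.0, 1.0), repeat=n_pop):
            s = np.array(bits)
            m = (self.P * s) @ self.coef
            u = float(self.P @ s)
            base = self._raw_inputs(m, I)
            if J0 is not None:
                base = base - (J0 / prm.gamma) * u
            if prm.exclude_self and prm.alpha > 0:
                base = base + prm.alpha / 2.0
            margin = base - prm.h0_hat
            want = margin > 0
            if np.array_equal(want.astype(float), s):
                label = ("marginal" if np.min(np.abs(margin)) < 1e-9
                         else "stable")
                if any(np.max(np.abs(m - f.m)) < 1e-9 for f in out):
                    continue
                out.append(FixedPoint(
                    m=m, stability=label, eigenvalues=None,
                    R=0.0, mean_rate=u, residual=0.0,
                ))
        return sorted(out, key=lambda f: tuple(np.round(f.m, 9)))


# --------------------------------------------------------------------------
# module-level operation surface
# --------------------------------------------------------------------------

def mf_rhs(m, params: MeanFieldParams, I=None, theta=None, J0=None):
    """dm/dt of the closed mean-field overlap dynamics (convenience)."""
    return MeanField(params).rhs(m, I=I, theta=theta, J0=J0)


def solve_self_consistent_R(m, params: MeanFieldParams, I=None, J0=None):
    """Self-consistent R (with q, p) at overlap state m; None if absent."""
    mf = MeanField(params)
    R = mf.solve_R(m, I=I, J0=J0)
    if R is None:
        return None
    eq = mf.equilibrium_quantities(m, I=I, J0=J0, R=R)
    return {"R": R, "q": eq["q"], "p": eq["p"]}


def scan_R_grid(
    m, params: MeanFieldParams, resolution: int = 1000,
    correction_constant: float = 1.0, I=None, J0=None,
):
    """Grid-scan acceptance of R values (the paper's procedure): accept
    R_val when |R_val - R_reconstructed| < correction_constant * step with
    step = R_max/resolution.  Returns the accepted R values."""
    mf = MeanField(params)
    step = params.R_max / resolution
    grid = np.linspace(0.0, params.R_max, resolution + 1)
    raw = mf._raw_inputs(m, I)
    accepted = []
    for R_val in grid:
        sigma = np.sqrt(params.alpha * R_val)
        _, q, pval, _ = mf._solve_populations(raw, J0, sigma)
        if q >= 1.0:
            continue
        R_rec = background_R_correction(
            pval, q, params.background_C, params.background_group
        )
        if abs(R_val - R_rec) < correction_constant * step:
            accepted.append(R_val)
    return np.array(accepted)


def find_fixed_points(params: MeanFieldParams, I=None, J0=None, **kw):
    return MeanField(params).find_fixed_points(I=I, J0=J0, **kw)


def jacobian_stability(m, params: MeanFieldParams, I=None, J0=None):
    """Eigenvalues and stability class of the Jacobian at m."""
    mf = MeanField(params)
    label, ev = mf.classify(m, I=I, J0=J0)
    return {"eigenvalues": ev, "stability": label,
            "jacobian": mf.jacobian(m, I=I, J0=J0)}


def analytic_cmax_bound(gamma: float, h0_hat: float) -> float:
    """Upper bound c_max^0 = gamma + (1-gamma) h0_hat (b -> inf, alpha=0,
    gamma -> 0 closed form; bounds c_max for any finite steepness)."""
    if not 0.0 < gamma <= 1.0 or h0_hat < 0:
        raise ValueError("gamma in (0,1], h0_hat >= 0 required")
    return gamma + (1.0 - gamma) * h0_hat


# --------------------------------------------------------------------------
# phase plane
# --------------------------------------------------------------------------

def phase_plane(
    params: MeanFieldParams, bounds=(-0.2, 1.2), n_grid: int = 201,
    I=None, J0=None,
):
    """Nullclines and flow field of the two-pattern overlap dynamics.

    Returns dict with the meshgrid, the two RHS components, and the
    m1-/m2-nullcline polylines (zero contours).
    """
    if params.n_corr != 2:
        raise ValueError("phase plane is defined for the two-pattern mode")
    mf = MeanField(params)
    xs = np.linspace(bounds[0], bounds[1], n_grid)
    M1, M2 = np.meshgrid(xs, xs)
    U = np.empty_like(M1)
    V = np.empty_like(M2)
    for i in range(n_grid):
        for j in range(n_grid):
            d = mf.rhs(np.array([M1[i, j], M2[i, j]]), I=I, J0=J0)
            U[i, j], V[i, j] = d
    from matplotlib.figure import Figure

    fig = Figure()
    ax = fig.add_subplot()
    nulls = []
    for Z in (U, V):
        cs = ax.contour(M1, M2, Z, levels=[0.0])
        segs = cs.allsegs[0] if cs.allsegs else []
        nulls.append([np.asarray(s) for s in segs])
    return {
        "m1": M1, "m2": M2, "dm1": U, "dm2": V,
        "nullclines_m1": nulls[0], "nullclines_m2": nulls[1],
    }


# --------------------------------------------------------------------------
# bifurcation extraction
# --------------------------------------------------------------------------

def _has_single_retrieval(params: MeanFieldParams, J0=None,
                          m1_min=0.55, gap_min=0.08) -> bool:
    """Does a stable single-retrieval state (m1 high, m2 well below) exist?"""
    mf = MeanField(params)
    if params.heaviside and params.alpha == 0.0:
        fps = mf._heaviside_fixed_points(J0=J0)
        return any(
            f.is_stable and f.m[0] > m1_min and f.m[0] - f.m[1] > gap_min
            for f in fps
        )
    C = params.C
    seeds = [np.array([1.0, C]), np.array([1.0, 0.0]),
             np.array([0.95, min(C + 0.05, 0.9)])]
    for s in seeds:
        try:
            sol = optimize.root(lambda mm: mf.rhs(mm, J0=J0), s,
                                method="hybr", options={"xtol": 1e-12})
        except RuntimeError:
            continue
        if not sol.success:
            continue
        m = sol.x
        if np.max(np.abs(mf.rhs(m, J0=J0))) > 1e-8:
            continue
        if m[0] > m1_min and m[0] - m[1] > gap_min:
            label, _ = mf.classify(m, J0=J0)
            if label == "stable":
                return True
    return False


def _has_symmetric_state(params: MeanFieldParams, J0=None,
                         m_min=0.5, sym_tol=0.01) -> bool:
    """Does a stable symmetric state m1 = m2 >= m_min exist?"""
    mf = MeanField(params)
    if params.heaviside and params.alpha == 0.0:
        fps = mf._heaviside_fixed_points(J0=J0)
        return any(
            f.is_stable and abs(f.m[0] - f.m[1]) < sym_tol and f.m[0] > m_min
            for f in fps
        )
    for v in (1.0, 0.9, 0.7, 0.5, 0.3, 0.15):
        s = np.array([v, v])
        try:
            sol = optimize.root(lambda mm: mf.rhs(mm, J0=J0), s,
                                method="hybr", options={"xtol": 1e-12})
        except RuntimeError:
            continue
        if not sol.success or np.max(np.abs(mf.rhs(sol.x, J0=J0))) > 1e-8:
            continue
        m = sol.x
        if abs(m[0] - m[1]) < sym_tol and m[0] > m_min:
            label, _ = mf.classify(m, J0=J0)
            if label == "stable":
                return True
    return False


def _bisect_C(predicate, C_lo, C_hi, coarse, refine):
    """Largest C with predicate True, assuming True at C_lo, False at C_hi."""
    lo, hi = C_lo, C_hi
    while hi - lo > coarse:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            lo = mid
        else:
            hi = mid
    while hi - lo > refine:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def extract_c_max(
    params: MeanFieldParams, J0=None, C_hi=None,
    coarse: float = 1e-3, refine: float = 1e-4, scan_grid=None,
) -> BifurcationResult:
    """Largest shared fraction preserving separate retrieval.

    Continues the single-retrieval fixed point in the correlation C and
    bisects on its existence; the disappearance is the saddle-node where
    the retrieval state merges with its companion saddle.  Without global
    inhibition, C_max <= h0_hat (the analytic bound), which brackets the
    search.  Returns a not-found result when no single-retrieval state
    exists even for weakly correlated patterns (resting-state-only region).
    """
    def pred(C):
        return _has_single_retrieval(replace(params, C=C), J0=J0)

    C_lo = 1e-4
    if not pred(C_lo):
        return BifurcationResult(
            found=False, C_crit=None, c_crit=None, kind="c_max",
            grid_step=refine, note="no single-retrieval state at any C",
        )
    if C_hi is None:
        C_hi = min(1.0, params.h0_hat + 0.02) if J0 is None else 0.98
    while pred(C_hi):
        if C_hi >= 0.999:
            return BifurcationResult(
                found=True, C_crit=1.0, c_crit=1.0, kind="c_max",
                grid_step=refine,
                note="single retrieval persists to C = 1",
            )
        C_hi = min(1.0, C_hi + 0.1)
    C_max = _bisect_C(pred, C_lo, C_hi, coarse, refine)
    loci = C_grid = None
    if scan_grid is not None:
        C_grid = np.asarray(scan_grid)
        loci = []
        for C in C_grid:
            fps = MeanField(replace(params, C=C)).find_fixed_points(J0=J0)
            loci.append([(f.m.copy(), f.stability) for f in fps])
    return BifurcationResult(
        found=True, C_crit=C_max,
        c_crit=pearson_to_fraction(C_max, params.gamma),
        kind="c_max", grid_step=refine, C_grid=C_grid, loci=loci,
        note="saddle-node disappearance of the single-retrieval states",
    )


def extract_c_min_symmetric(
    params: MeanFieldParams, J0=None, C_hi: float = 0.9,
    coarse: float = 1e-3, refine: float = 1e-4, m_min: float = 0.5,
) -> BifurcationResult:
    """Smallest shared fraction with a stable symmetric double-retrieval
    state (the c_min of the globally-inhibited network)."""
    def pred(C):
        return _has_symmetric_state(replace(params, C=C), J0=J0, m_min=m_min)

    if not pred(C_hi):
        return BifurcationResult(
            found=False, C_crit=None, c_crit=None, kind="c_min",
            grid_step=refine, note=f"no symmetric state up to C={C_hi}",
        )
    C_lo = 1e-4
    if pred(C_lo):
        C_min = C_lo
    else:
        # predicate is True above the threshold: bisect on the complement
        C_min = _bisect_C(lambda C: not pred(C), C_lo, C_hi, coarse, refine)
    return BifurcationResult(
        found=True, C_crit=C_min,
        c_crit=pearson_to_fraction(C_min, params.gamma),
        kind="c_min", grid_step=refine,
        note="appearance of the stable symmetric double-retrieval state",
    )


# --------------------------------------------------------------------------
# Heaviside / zero-sparsity analytic limit
# --------------------------------------------------------------------------

def zero_sparsity_fixed_points(C: float, h0_hat: float, I=(0.0, 0.0)):
    """Fixed points of the two-pattern dynamics in the b -> inf, alpha = 0,
    gamma -> 0 limit.

    Only three neuron populations survive the limit: selective to both
    patterns (weight C), to pattern 1 only, or to pattern 2 only (weight
    1-C each), with F1 = C Theta(m1+m2+I1+I2-h0) + (1-C) Theta(m1+I1-h0)
    and symmetrically for F2.  All self-consistent activation patterns are
    enumerated exactly.
    """
    if not 0.0 <= C <= 1.0 or h0_hat <= 0.0:
        raise ValueError("need C in [0,1] and h0_hat > 0")
    I1, I2 = I
    out = []
    for s11, s10, s01 in itertools.product((0.0, 1.0), repeat=3):
        m1 = C * s11 + (1.0 - C) * s10
        m2 = C * s11 + (1.0 - C) * s01
        h11 = m1 + m2 + I1 + I2
        h10 = m1 + I1
        h01 = m2 + I2
        want = (float(h11 > h0_hat), float(h10 > h0_hat), float(h01 > h0_hat))
        if want == (s11, s10, s01):
            m = np.array([m1, m2])
            if any(np.max(np.abs(m - f.m)) < 1e-12 for f in out):
                continue
            out.append(FixedPoint(m=m, stability="stable", residual=0.0))
    return sorted(out, key=lambda f: tuple(np.round(f.m, 12)))


def heaviside_second_overlap(C: float, h0_hat: float) -> float:
    """Second overlap m2 of the retrieval state (m1 = 1) in the b -> inf,
    gamma -> 0, alpha = 0 limit: m2 = C for C < h0_hat; no single-retrieval
    state exists for C >= h0_hat (raises)."""
    fps = zero_sparsity_fixed_points(C, h0_hat)
    for f in fps:
        if f.m[0] > 0.999 and f.m[1] < f.m[0] - 1e-9:
            return float(f.m[1])
    raise ValueError(
        f"no single-retrieval state at C={C} (C_max = h0_hat = {h0_hat})"
    )


def extract_cmax_zero_sparsity(h0_hat: float, refine: float = 1e-10) -> float:
    """Numerically extracted C_max in the analytic limit; converges to h0_hat."""
    def pred(C):
        try:
            heaviside_second_overlap(C, h0_hat)
            return True
        except ValueError:
            return False

    if not pred(1e-12):
        return 0.0
    return _bisect_C(pred, 1e-12, 1.0, 1e-3, refine)


# --------------------------------------------------------------------------
# adaptation + oscillatory inhibition (quasi-static dynamics)
# --------------------------------------------------------------------------

def mf_dynamics_adaptation(
    params: MeanFieldParams,
    J0_schedule,
    duration: float,
    tau_theta_hat: float = 45.0,
    D_theta_hat: float = 0.1,
    theta0: float = 0.0,
    tau_hat: float = 1.0,
    dt: float = 0.25,
    m_init=None,
    relax_dt: float = 0.2,
    relax_tol: float = 1e-7,
    max_relax: int = 4000,
):
    """Quasi-static mean-field dynamics with adaptation and modulated J0.

    Exploits the time-scale separation tau << T_J0 < tau_theta: at each
    outer step the overlaps are relaxed to their quasi-equilibrium given the
    frozen per-population adaptation theta_x and the current inhibition
    J0(t); theta_x is then advanced by one Euler step of
    tau_theta dtheta/dt = -theta + theta0 + D_theta r_x.

    ``J0_schedule`` is any object with .value(t) (e.g. OscillatoryInhibition)
    or a plain callable.  Returns dict of trajectories.
    """
    mf = MeanField(params)
    n_pop = len(mf.P)
    schedule = J0_schedule.value if hasattr(J0_schedule, "value") else J0_schedule
    m = (np.array([1.0] + [params.C] * (params.n_corr - 1))
         if m_init is None else np.asarray(m_init, dtype=float).copy())
    theta = np.full(n_pop, theta0)
    n_steps = int(round(duration / dt))
    traj = {
        "t": np.arange(n_steps + 1) * dt,
        "m": np.empty((n_steps + 1, params.n_corr)),
        "theta": np.empty((n_steps + 1, n_pop)),
        "J0": np.empty(n_steps + 1),
        "r": np.empty((n_steps + 1, n_pop)),
    }
    for step in range(n_steps + 1):
        t = step * dt
        J0 = float(schedule(t))
        for _ in range(max_relax):
            dm = mf.rhs(m, theta=theta, J0=J0)
            m = m + relax_dt / tau_hat * dm
            if np.max(np.abs(dm)) < relax_tol:
                break
        else:
            raise RuntimeError(
                f"overlap relaxation did not converge at t={t:.2f} "
                f"(m={m}, J0={J0:.3f})"
            )
        eq = mf.equilibrium_quantities(m, theta=theta, J0=J0)
        traj["m"][step] = m
        traj["theta"][step] = theta
        traj["J0"][step] = J0
        traj["r"][step] = eq["r"]
        theta = theta + dt / tau_theta_hat * (
            -theta + theta0 + D_theta_hat * eq["r"]
        )
    return traj


def chain_correlation_bounds(
    params: MeanFieldParams, J_min: float = 0.7, J_max: float = 1.2,
    coarse: float = 2e-3, refine: float = 5e-4,
) -> dict:
    """Admissible shared-fraction range [c_min', c_max'] for association
    chains under oscillatory inhibition (adaptation frozen at theta = 0).

    c_max': largest c with both single-retrieval states at J0 = J_min
    (needed so concepts can be retrieved separately in the low-inhibition
    phase).  c_min': smallest c with a stable transition state
    m1 = m2 > 0 at J0 = J_max (needed to bridge between concepts in the
    high-inhibition phase); it exceeds chance level for sparse patterns.
    """
    res_max = extract_c_max(params, J0=J_min, coarse=coarse, refine=refine)

    def pred_transition(C):
        p = replace(params, C=C)
        mf = MeanField(p)
        rest = None
        try:
            sol = optimize.root(lambda mm: mf.rhs(mm, J0=J_max),
                                np.zeros(2), method="hybr",
                                options={"xtol": 1e-12})
            if sol.success:
                rest = sol.x
        except RuntimeError:
            pass
        for v in (0.02, 0.05, 0.1, C, 0.2, 0.4):
            if v <= 0:
                continue
            try:
                sol = optimize.root(lambda mm: mf.rhs(mm, J0=J_max),
                                    np.array([v, v]), method="hybr",
                                    options={"xtol": 1e-12})
            except RuntimeError:
                continue
            if not sol.success or np.max(np.abs(mf.rhs(sol.x, J0=J_max))) > 1e-8:
                continue
            m = sol.x
            if abs(m[0] - m[1]) > 0.005 or m[0] < 0.005:
                continue
            if rest is not None and np.max(np.abs(m - rest)) < 0.005:
                continue
            label, _ = mf.classify(m, J0=J_max)
            if label == "stable":
                return True
        return False

    C_hi = 0.9
    if not pred_transition(C_hi):
        c_min_prime = None
    elif pred_transition(1e-4):
        c_min_prime = pearson_to_fraction(1e-4, params.gamma)
    else:
        C_min = _bisect_C(lambda C: not pred_transition(C),
                          1e-4, C_hi, coarse, refine)
        c_min_prime = pearson_to_fraction(C_min, params.gamma)
    return {
        "c_min_prime": c_min_prime,
        "c_max_prime": res_max.c_crit if res_max.found else None,
        "J_min": J_min, "J_max": J_max,
    }


# --------------------------------------------------------------------------
# minimal stimulation curve
# --------------------------------------------------------------------------

def min_stimulation_curve(
    params: MeanFieldParams, c_grid, I_max: float = 0.8,
    tol: float = 2e-3, horizon: float = 80.0, dt: float = 0.1,
) -> np.ndarray:
    """Minimal sustained stimulus I2 that recalls pattern 2 when pattern 1
    is retrieved, as a function of the shared fraction c.

    For each c the flow is integrated from the single-retrieval state with
    constant input I2 to pattern 2; success means m2 > 0.5 at the horizon.
    Above c_max no stimulation is needed (returns 0).
    """
    out = np.empty(len(c_grid))
    for i, c in enumerate(c_grid):
        C = fraction_to_pearson(c, params.gamma)
        p = replace(params, C=C)
        mf = MeanField(p)
        sol = optimize.root(lambda mm: mf.rhs(mm), np.array([1.0, C]),
                            method="hybr", options={"xtol": 1e-12})
        start = sol.x if sol.success else np.array([1.0, C])
        label, _ = mf.classify(start)
        single = (sol.success and label == "stable"
                  and start[0] - start[1] > 0.08)
        if not single:
            out[i] = 0.0
            continue

        def recalls(I2):
            m = start.copy()
            for _ in range(int(horizon / dt)):
                m = m + dt * mf.rhs(m, I=(0.0, I2))
            return m[1] > 0.5

        if recalls(0.0):
            out[i] = 0.0
            continue
        lo, hi = 0.0, I_max
        if not recalls(hi):
            out[i] = np.nan
            continue
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if recalls(mid):
                hi = mid
            else:
                lo = mid
        out[i] = 0.5 * (lo + hi)
    return out
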