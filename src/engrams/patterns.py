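"""Sparse binary memory engrams with prescribed pairwise overlap.

A memory engram ("pattern") is the subset of neurons whose joint persistent
activity encodes one concept.  Patterns are binary vectors xi^mu in {0,1}^N
with sparsity gamma = P(xi_i^mu = 1).  Two associated engrams share a
fraction ``c`` of their neurons, i.e. P(xi^nu = 1 | xi^mu = 1) = c; chance
level is c = gamma.  The shared fraction is related to the Pearson
correlation coefficient C between the two binary patterns by

    c = C * (1 - gamma) + gamma.

This module provides four construction algorithms for subgroups of K
mutually overlapping patterns:

``generate_parent_correlated``
    copy/flip model: each pattern equals a common parent bit with
    probability epsilon, giving an equicorrelated group (used by the
    mean-field theory for 3 and 4 correlated patterns).
``generate_hierarchical``
    hierarchical generative model: a parent of sparsity lambda = gamma/c;
    children copy parent ones with probability c and are never active
    where the parent is silent.
``generate_indicator``
    indicator-neuron model: a small set of indicator neurons joins every
    pattern with probability 1 - epsilon while any other neuron joins
    with probability Omega; we impose epsilon = Omega (self-consistent).
``generate_iterative``
    non-hierarchical iterative model with exact integer counts:
    round(gamma*N) active neurons per pattern, pairwise intersections
    topped up to exactly round(gamma*c*N) (counting pre-existing
    intersections first).

The first three are probabilistic (Bernoulli) constructions with the target
statistics holding in expectation; the iterative model enforces exact counts
and is the only one that is not derived from a parent pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PatternEnsemble",
    "CorrelationSpec",
    "fraction_to_pearson",
    "pearson_to_fraction",
    "solve_parent_parameters",
    "parent_forward_maps",
    "joint_probability",
    "indicator_parameters",
    "generate_parent_correlated",
    "generate_hierarchical",
    "generate_indicator",
    "generate_iterative",
    "generate_iterative_groups",
    "generate_subgroup",
    "group_joint_probabilities",
    "hierarchical_response_distribution",
    "indicator_response_distribution",
    "ensemble_statistics",
]


# --------------------------------------------------------------------------
# correlation bookkeeping
# --------------------------------------------------------------------------

def fraction_to_pearson(c: float, gamma: float) -> float:
    """Convert a shared-neuron fraction ``c`` to the Pearson coefficient C.

    Inverts the identity c = C*(1-gamma) + gamma.  ``c`` must lie in
    [gamma, 1]: a shared fraction below chance level corresponds to a
    negative correlation, which the pattern constructions cannot produce.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0,1), got {gamma}")
    if c < gamma - 1e-12 or c > 1.0 + 1e-12:
        raise ValueError(
            f"shared fraction c={c} outside [gamma={gamma}, 1]; "
            "c < gamma would require negative correlation"
        )
    return float((c - gamma) / (1.0 - gamma))


def pearson_to_fraction(C: float, gamma: float) -> float:
    """Shared fraction c = C*(1-gamma) + gamma for Pearson coefficient C."""
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0,1), got {gamma}")
    if C < -1e-12 or C > 1.0 + 1e-12:
        raise ValueError(f"Pearson C={C} outside [0, 1]")
    return float(C * (1.0 - gamma) + gamma)


@dataclass
class CorrelationSpec:
    """Resolved parameters tying together the equivalent descriptions of
    a group of correlated patterns.

    Attributes
    ----------
    gamma : sparsity of each pattern.
    pearson_C : Pearson correlation coefficient between any two patterns.
    shared_fraction_c : conditional sharing probability, c = C(1-gamma)+gamma.
    parent_lambda, epsilon : copy/flip parent-model parameters (Eq. 96-style
        inversion); pattern bit equals the parent bit with probability
        epsilon, the parent has sparsity lambda.
    lambda_ind, omega : indicator-model parameters (only set when solved).
    """

    gamma: float
    pearson_C: float
    shared_fraction_c: float
    parent_lambda: float | None = None
    epsilon: float | None = None
    lambda_ind: float | None = None
    omega: float | None = None

    def __post_init__(self):
        c = pearson_to_fraction(self.pearson_C, self.gamma)
        if abs(c - self.shared_fraction_c) > 1e-9:
            raise ValueError(
                f"inconsistent spec: c={self.shared_fraction_c} but "
                f"C={self.pearson_C}, gamma={self.gamma} imply c={c}"
            )
        for name in ("parent_lambda", "epsilon", "lambda_ind", "omega"):
            v = getattr(self, name)
            if v is not None and not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0,1]")

    @classmethod
    def from_shared_fraction(cls, gamma: float, c: float) -> "CorrelationSpec":
        return cls(gamma=gamma, pearson_C=fraction_to_pearson(c, gamma),
                   shared_fraction_c=c)

    @classmethod
    def from_pearson(cls, gamma: float, C: float) -> "CorrelationSpec":
        return cls(gamma=gamma, pearson_C=C,
                   shared_fraction_c=pearson_to_fraction(C, gamma))


# --------------------------------------------------------------------------
# parent copy/flip model
# --------------------------------------------------------------------------

def parent_forward_maps(lam: float, eps: float) -> tuple[float, float]:
    """Forward maps (C, gamma) of the copy/flip parent construction.

    A parent pattern of sparsity ``lam`` is copied bit-wise with
    probability ``eps`` (flipped with probability 1-eps).  The resulting
    children have sparsity gamma = lam*eps + (1-lam)*(1-eps) and pairwise
    Pearson correlation C = lam*(1-lam)*(2 eps - 1)^2 / (gamma*(1-gamma)).
    """
    g = lam * eps + (1.0 - lam) * (1.0 - eps)
    if g <= 0.0 or g >= 1.0:
        return float("nan"), g
    C = lam * (1.0 - lam) * (2.0 * eps - 1.0) ** 2 / (g * (1.0 - g))
    return C, g


def solve_parent_parameters(
    C: float, gamma: float, *, tol: float = 1e-8, return_all: bool = False
):
    """Solve the copy/flip parent parameters (lambda, epsilon) for (C, gamma).

    epsilon satisfies the cubic

        2 e^3 - 3 e^2 + [1 + 2 g(1-g)(1-C)] e - g(1-g)(1-C) = 0

    and lambda = (gamma + eps - 1)/(2 eps - 1).  Of the up-to-three real
    roots with lambda, eps in [0,1] we return the one with eps < 1/2 when
    available (the copy-dominant branch); all admissible roots are exposed
    via ``return_all=True``.

    Raises
    ------
    ValueError : if no real root yields admissible (lambda, eps) whose
        forward maps reproduce (C, gamma) to ``tol``.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0,1), got {gamma}")
    if not -1e-12 <= C <= 1.0 + 1e-12:
        raise ValueError(f"Pearson C={C} outside [0,1]")
    G = gamma * (1.0 - gamma) * (1.0 - C)
    roots = np.roots([2.0, -3.0, 1.0 + 2.0 * G, -G])
    admissible: list[tuple[float, float]] = []
    for r in roots:
        if abs(r.imag) > 1e-10:
            continue
        eps = float(r.real)
        if not -1e-10 <= eps <= 1.0 + 1e-10:
            continue
        eps = min(max(eps, 0.0), 1.0)
        if abs(2.0 * eps - 1.0) < 1e-9:
            # degenerate branch: children are fair coins regardless of the
            # parent, only consistent with gamma = 1/2 and C = 0
            if abs(gamma - 0.5) < 1e-9 and abs(C) < 1e-9:
                admissible.append((0.5, eps))
            continue
        lam = (gamma + eps - 1.0) / (2.0 * eps - 1.0)
        if not -1e-10 <= lam <= 1.0 + 1e-10:
            continue
        lam = min(max(lam, 0.0), 1.0)
        C_fwd, g_fwd = parent_forward_maps(lam, eps)
        if np.isnan(C_fwd):
            # fully degenerate parent (children constant); only C undefined
            if abs(C) < tol:
                C_fwd = 0.0
            else:
                continue
        if abs(C_fwd - C) < tol and abs(g_fwd - gamma) < tol:
            admissible.append((lam, eps))
    if not admissible:
        raise ValueError(
            f"no admissible parent parameters in [0,1] for C={C}, gamma={gamma}"
        )
    admissible.sort(key=lambda le: le[1])  # smallest eps first
    if return_all:
        return admissible
    for lam, eps in admissible:
        if eps < 0.5:
            return lam, eps
    return admissible[0]


def joint_probability(lam: float, eps: float, x) -> float:
    """Joint selectivity probability P_{x1..xn} of the copy/flip model.

    P = lam * eps^a (1-eps)^b + (1-lam) * eps^b (1-eps)^a with a the number
    of ones in ``x`` and b = n - a; invariant under permutation of x.
    """
    if not (0.0 <= lam <= 1.0 and 0.0 <= eps <= 1.0):
        raise ValueError("lam and eps must be in [0,1]")
    x = np.asarray(x)
    if not np.isin(x, (0, 1)).all():
        raise ValueError(f"selectivity vector must be binary, got {x!r}")
    a = int(x.sum())
    b = x.size - a
    return float(lam * eps**a * (1 - eps) ** b + (1 - lam) * eps**b * (1 - eps) ** a)


def group_joint_probabilities(gamma: float, C: float, n: int) -> np.ndarray:
    """Joint probabilities P_x over all x in {0,1}^n for an equicorrelated
    group of ``n`` patterns with sparsity gamma and pairwise Pearson C.

    For n = 2 the closed form P11 = gamma^2 + gamma(1-gamma) C (etc.) is
    used; for n >= 3 the copy/flip parent parameters are solved and the
    permutation-invariant product form applied.  Rows are ordered by the
    binary code of x (x[0] the fastest-varying bit is column 0).
    """
    states = np.array(
        [[(i >> k) & 1 for k in range(n)] for i in range(2**n)], dtype=float
    )
    if n == 1:
        probs = np.array([1 - gamma, gamma])
    elif n == 2:
        P11 = gamma**2 + gamma * (1 - gamma) * C
        P10 = gamma * (1 - gamma) * (1 - C)
        P00 = (1 - gamma) ** 2 + gamma * (1 - gamma) * C
        lookup = {(0, 0): P00, (1, 0): P10, (0, 1): P10, (1, 1): P11}
        probs = np.array([lookup[tuple(int(v) for v in s)] for s in states])
    else:
        if C == 0.0:
            probs = np.prod(
                np.where(states == 1, gamma, 1 - gamma), axis=1
            )
        else:
            lam, eps = solve_parent_parameters(C, gamma)
            probs = np.array([joint_probability(lam, eps, s) for s in states])
    return probs


# --------------------------------------------------------------------------
# indicator model parameters
# --------------------------------------------------------------------------

def indicator_parameters(
    gamma: float, c: float, *, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[float, float]:
    """Solve the indicator-model parameters (lambda_ind, epsilon = Omega).

    lambda_ind = (c*gamma - gamma^2) / ((1-eps)^2 - 2*gamma*(1-eps) + c*gamma)
    guarantees the pairwise sharing c*gamma = lam*(1-eps)^2 + (1-lam)*Omega^2,
    with Omega = (gamma - lam*(1-eps)) / (1-lam) fixing the sparsity.  The
    additional constraint eps = Omega is imposed by 1-D fixed-point
    iteration on eps.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0,1), got {gamma}")
    if c < gamma:
        raise ValueError(f"c={c} below chance level gamma={gamma}")
    eps = gamma  # Omega is near gamma for sparse patterns
    for _ in range(max_iter):
        denom = (1 - eps) ** 2 - 2 * gamma * (1 - eps) + c * gamma
        lam = (c * gamma - gamma**2) / denom
        if not 0.0 <= lam < 1.0:
            raise ValueError(
                f"no self-consistent indicator solution: lambda_ind={lam} "
                f"outside [0,1) for gamma={gamma}, c={c}"
            )
        omega = (gamma - lam * (1 - eps)) / (1 - lam)
        if not 0.0 <= omega <= 1.0:
            raise ValueError(
                f"no self-consistent indicator solution: Omega={omega} "
                f"outside [0,1] for gamma={gamma}, c={c}"
            )
        if abs(omega - eps) < tol:
            return float(lam), float(omega)
        eps = omega
    raise ValueError(
        f"indicator fixed-point iteration did not converge for gamma={gamma}, c={c}"
    )


# --------------------------------------------------------------------------
# the ensemble container
# --------------------------------------------------------------------------

@dataclass
class PatternEnsemble:
    """A set of binary patterns over N neurons, stored as index sets.

    ``patterns[mu]`` is the sorted array of neuron indices active in
    pattern mu (gamma*N ~ 200 of N ~ 1e5, so index sets are the natural
    representation; a dense matrix is materialized on demand).
    ``subgroups`` partitions pattern indices into associated groups that
    share the target fraction ``target_c``; patterns outside any subgroup
    are mutually independent.
    """

    N: int
    patterns: list[np.ndarray]
    gamma: float
    subgroups: list[list[int]] = field(default_factory=list)
    target_c: float | None = None
    seed: int | None = None
    algorithm: str = ""

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def to_dense(self) -> np.ndarray:
        """Dense binary selectivity matrix, neurons x patterns."""
        xi = np.zeros((self.N, self.n_patterns), dtype=np.int8)
        for mu, idx in enumerate(self.patterns):
            xi[idx, mu] = 1
        return xi

    def sparsity(self) -> np.ndarray:
        return np.array([len(idx) / self.N for idx in self.patterns])

    def shared_count(self, mu: int, nu: int) -> int:
        return int(np.intersect1d(self.patterns[mu], self.patterns[nu]).size)

    def response_counts(self) -> np.ndarray:
        """Number of patterns each neuron belongs to (length N)."""
        counts = np.zeros(self.N, dtype=np.int64)
        for idx in self.patterns:
            counts[idx] += 1
        return counts

    def distinct_active(self, pattern_indices=None) -> int:
        """Number of neurons active in >= 1 of the given patterns."""
        if pattern_indices is None:
            pattern_indices = range(self.n_patterns)
        all_idx = np.concatenate([self.patterns[mu] for mu in pattern_indices])
        return int(np.unique(all_idx).size)

    # -- serialization ------------------------------------------------------
    def save_npz(self, path) -> None:
        lengths = np.array([len(p) for p in self.patterns])
        flat = (np.concatenate(self.patterns) if self.patterns
                else np.array([], dtype=np.int64))
        np.savez_compressed(
            path,
            selectivity_indices=flat,
            pattern_lengths=lengths,
            N=self.N,
            gamma=self.gamma,
            subgroups=np.array(
                [np.array(g) for g in self.subgroups], dtype=object
            ) if self.subgroups else np.array([], dtype=object),
            target_c=np.nan if self.target_c is None else self.target_c,
            seed=-1 if self.seed is None else self.seed,
            algorithm=self.algorithm,
        )

    @classmethod
    def load_npz(cls, path) -> "PatternEnsemble":
        with np.load(path, allow_pickle=True) as f:
            offsets = np.concatenate([[0], np.cumsum(f["pattern_lengths"])])
            flat = f["selectivity_indices"]
            patterns = [
                np.asarray(flat[offsets[i]: offsets[i + 1]], dtype=np.int64)
                for i in range(len(f["pattern_lengths"]))
            ]
            target_c = float(f["target_c"])
            seed = int(f["seed"])
            return cls(
                N=int(f["N"]),
                patterns=patterns,
                gamma=float(f["gamma"]),
                subgroups=[list(g) for g in f["subgroups"]],
                target_c=None if np.isnan(target_c) else target_c,
                seed=None if seed < 0 else seed,
                algorithm=str(f["algorithm"]),
            )


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent substreams so adding patterns never perturbs earlier ones."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_parent_correlated(
    N: int, gamma: float, C: float, n_corr: int, n_independent: int = 0,
    seed: int = 0,
) -> PatternEnsemble:
    """Copy/flip parent model: ``n_corr`` mutually correlated patterns with
    pairwise Pearson C, plus independent Bernoulli(gamma) background patterns.
    """
    if C == 0.0:
        lam, eps = gamma, 1.0  # children literally copy an independent parent
    else:
        lam, eps = solve_parent_parameters(C, gamma)
    rngs = _spawn_rngs(seed, 1 + n_corr + n_independent)
    parent = rngs[0].random(N) < lam
    patterns = []
    for mu in range(n_corr):
        if C == 0.0:
            active = rngs[1 + mu].random(N) < gamma
        else:
            keep = rngs[1 + mu].random(N) < eps
            active = np.where(keep, parent, ~parent)
        patterns.append(np.flatnonzero(active).astype(np.int64))
    for j in range(n_independent):
        active = rngs[1 + n_corr + j].random(N) < gamma
        patterns.append(np.flatnonzero(active).astype(np.int64))
    return PatternEnsemble(
        N=N, patterns=patterns, gamma=gamma,
        subgroups=[list(range(n_corr))] if n_corr > 1 else [],
        target_c=pearson_to_fraction(C, gamma), seed=seed,
        algorithm="parent",
    )


def generate_hierarchical(
    N: int, gamma: float, c: float, K: int, seed: int = 0,
) -> PatternEnsemble:
    """Hierarchical generative model for one subgroup of K patterns.

    Parent sparsity lambda = gamma/c (requires c >= gamma); each pattern
    activates a parent neuron with probability c and never activates a
    non-parent neuron.  Response-count statistics follow
    ``hierarchical_response_distribution``.
    """
    if c < gamma:
        raise ValueError(
            f"c={c} < gamma={gamma} gives parent sparsity lambda > 1"
        )
    lam = gamma / c
    rngs = _spawn_rngs(seed, 1 + K)
    parent_idx = np.flatnonzero(rngs[0].random(N) < lam)
    patterns = []
    for mu in range(K):
        keep = rngs[1 + mu].random(parent_idx.size) < c
        patterns.append(np.sort(parent_idx[keep]).astype(np.int64))
    return PatternEnsemble(
        N=N, patterns=patterns, gamma=gamma,
        subgroups=[list(range(K))], target_c=c, seed=seed,
        algorithm="hierarchical",
    )


def generate_indicator(
    N: int, gamma: float, c: float, K: int, seed: int = 0,
) -> PatternEnsemble:
    """Indicator-neuron model for one subgroup of K patterns.

    Indicator neurons (sparsity lambda_ind) join each pattern with
    probability 1-eps; all other neurons join with probability Omega = eps.
    Expected active count per pattern is gamma*N.
    """
    lam_ind, eps = indicator_parameters(gamma, c)
    rngs = _spawn_rngs(seed, 1 + K)
    is_ind = rngs[0].random(N) < lam_ind
    patterns = []
    for mu in range(K):
        u = rngs[1 + mu].random(N)
        active = np.where(is_ind, u < 1.0 - eps, u < eps)
        patterns.append(np.flatnonzero(active).astype(np.int64))
    return PatternEnsemble(
        N=N, patterns=patterns, gamma=gamma,
        subgroups=[list(range(K))], target_c=c, seed=seed,
        algorithm="indicator",
    )


def generate_iterative(
    N: int, gamma: float, c: float, K: int, seed: int = 0,
) -> PatternEnsemble:
    """Iterative overlap-generating model (non-hierarchical, exact counts).

    Every pattern has exactly round(gamma*N) active neurons.  Each new
    pattern mu is compared against the earlier patterns in descending index
    order; for each earlier pattern nu the intersection is topped up to
    round(gamma*c*N) shared neurons, counting neurons already shared through
    previous comparisons first.  The remainder is drawn from the pool of
    never-used ("untouched") neurons.  For large K late patterns can exceed
    the pairwise target (the known excess of this construction).
    """
    n_active = int(round(gamma * N))
    n_shared = int(round(gamma * c * N))
    if n_shared > n_active:
        raise ValueError(f"target shared count {n_shared} exceeds engram size {n_active}")
    rngs = _spawn_rngs(seed, K)
    untouched = np.ones(N, dtype=bool)
    member = np.zeros(N, dtype=bool)  # scratch: membership of pattern under construction
    patterns: list[np.ndarray] = []
    for mu in range(K):
        member[:] = False
        n_cur = 0
        for nu in range(mu - 1, -1, -1):  # descending index order
            prev = patterns[nu]
            existing = int(member[prev].sum())
            need = n_shared - existing
            if need > 0:
                candidates = prev[~member[prev]]
                take = rngs[mu].choice(candidates, size=need, replace=False)
                member[take] = True
                n_cur += need
        fill = n_active - n_cur
        if fill < 0:
            # overshoot can only come from target inconsistencies
            raise ValueError(
                f"pattern {mu}: shared-neuron targets exceed engram size "
                f"(K={K}, gamma={gamma}, c={c}, N={N})"
            )
        pool = np.flatnonzero(untouched & ~member)
        if fill > pool.size:
            raise ValueError(
                f"untouched pool exhausted at pattern {mu} "
                f"(K={K}, gamma={gamma}, c={c}, N={N})"
            )
        take = rngs[mu].choice(pool, size=fill, replace=False)
        member[take] = True
        idx = np.flatnonzero(member)
        patterns.append(idx.astype(np.int64))
        untouched[idx] = False
    return PatternEnsemble(
        N=N, patterns=patterns, gamma=gamma,
        subgroups=[list(range(K))], target_c=c, seed=seed,
        algorithm="iterative",
    )


def generate_iterative_groups(
    N: int, gamma: float, c: float, subgroups: list[list[int]],
    n_patterns: int | None = None, seed: int = 0,
) -> PatternEnsemble:
    """Iterative construction with an explicit subgroup structure.

    Patterns within the same subgroup share round(gamma*c*N) neurons
    pairwise (a pattern may belong to several subgroups, e.g. a person
    associated with two contexts); pairs not sharing a subgroup get no
    topped-up overlap.  Top-up neurons are drawn preferentially from
    neurons exclusive to the compared pattern, so the pairwise shared sets
    are kept disjoint whenever capacity allows (the Venn-diagram overlap
    structure); higher-order intersections arise only when exclusive
    neurons run out.  Pattern indices in ``subgroups`` refer to positions
    0..n_patterns-1; patterns not named in any subgroup are independent
    exact-count draws.
    """
    if n_patterns is None:
        n_patterns = max((i for g in subgroups for i in g), default=-1) + 1
    n_active = int(round(gamma * N))
    n_shared = int(round(gamma * c * N))
    associated = np.zeros((n_patterns, n_patterns), dtype=bool)
    for g in subgroups:
        for mu in g:
            for nu in g:
                if mu != nu:
                    associated[mu, nu] = True
    rngs = _spawn_rngs(seed, n_patterns)
    untouched = np.ones(N, dtype=bool)
    member = np.zeros(N, dtype=bool)
    usage = np.zeros(N, dtype=np.int32)   # in how many patterns so far
    patterns: list[np.ndarray] = []
    for mu in range(n_patterns):
        member[:] = False
        n_cur = 0
        for nu in range(mu - 1, -1, -1):
            if not associated[mu, nu]:
                continue
            prev = patterns[nu]
            existing = int(member[prev].sum())
            need = n_shared - existing
            if need > 0:
                candidates = prev[~member[prev]]
                exclusive = candidates[usage[candidates] == 1]
                if exclusive.size >= need:
                    take = rngs[mu].choice(exclusive, size=need, replace=False)
                else:
                    rest = rngs[mu].choice(
                        candidates[usage[candidates] > 1],
                        size=need - exclusive.size, replace=False)
                    take = np.concatenate([exclusive, rest])
                member[take] = True
                n_cur += need
        fill = n_active - n_cur
        pool = np.flatnonzero(untouched & ~member)
        if fill < 0 or fill > pool.size:
            raise ValueError(
                f"infeasible subgroup structure at pattern {mu} "
                f"(gamma={gamma}, c={c}, N={N})"
            )
        take = rngs[mu].choice(pool, size=fill, replace=False)
        member[take] = True
        idx = np.flatnonzero(member)
        patterns.append(idx.astype(np.int64))
        untouched[idx] = False
        usage[idx] += 1
    return PatternEnsemble(
        N=N, patterns=patterns, gamma=gamma,
        subgroups=[list(g) for g in subgroups], target_c=c, seed=seed,
        algorithm="iterative-groups",
    )


GENERATORS = {
    "parent": generate_parent_correlated,
    "hierarchical": generate_hierarchical,
    "indicator": generate_indicator,
    "iterative": generate_iterative,
}


def generate_subgroup(
    algorithm: str, N: int, gamma: float, c: float, K: int, seed: int = 0,
) -> PatternEnsemble:
    """Dispatch a subgroup construction by algorithm name.

    ``algorithm`` is one of 'parent', 'hierarchical', 'indicator',
    'iterative'; for 'parent' the shared fraction is converted to Pearson C.
    """
    if algorithm == "parent":
        return generate_parent_correlated(
            N, gamma, fraction_to_pearson(c, gamma), n_corr=K, seed=seed
        )
    if algorithm not in GENERATORS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return GENERATORS[algorithm](N, gamma, c, K, seed)


# --------------------------------------------------------------------------
# response-count distributions
# --------------------------------------------------------------------------

def hierarchical_response_distribution(gamma: float, c: float, K: int) -> np.ndarray:
    """P(neuron responds to exactly k of K patterns), hierarchical model.

    P_K(k) = binom(K,k) * lambda * c^k (1-c)^(K-k) + (1-lambda) * delta_k0
    with lambda = gamma/c.
    """
    if c < gamma:
        raise ValueError(f"c={c} < gamma={gamma} gives parent sparsity lambda > 1")
    lam = gamma / c
    k = np.arange(K + 1)
    pk = lam * stats.binom.pmf(k, K, c)
    pk[0] += 1.0 - lam
    return pk


def indicator_response_distribution(gamma: float, c: float, K: int) -> np.ndarray:
    """P(neuron responds to exactly k of K patterns), indicator model.

    Two-component binomial mixture: indicator neurons (weight lambda_ind)
    respond Binom(K, 1-eps); non-indicators respond Binom(K, Omega=eps).
    The mean is K*gamma by construction.
    """
    lam_ind, eps = indicator_parameters(gamma, c)
    k = np.arange(K + 1)
    return lam_ind * stats.binom.pmf(k, K, 1.0 - eps) + (
        1.0 - lam_ind
    ) * stats.binom.pmf(k, K, eps)


# --------------------------------------------------------------------------
# empirical statistics
# --------------------------------------------------------------------------

def ensemble_statistics(ensemble: PatternEnsemble) -> dict:
    """Exact empirical statistics of an ensemble.

    Returns a dict with per-pattern sparsity, the pairwise shared-fraction
    matrix (intersection divided by the mean engram size of the pair; 1 on
    the diagonal), the pairwise shared counts, a plug-in Pearson-correlation
    estimate, and per-neuron response counts.  Pairs involving an empty
    pattern have undefined shared fraction, reported as 0 with
    ``undefined_pairs`` flagging them.
    """
    P = ensemble.n_patterns
    sizes = np.array([len(p) for p in ensemble.patterns], dtype=float)
    shared = np.zeros((P, P), dtype=np.int64)
    for mu in range(P):
        for nu in range(mu, P):
            s = (len(ensemble.patterns[mu]) if mu == nu
                 else ensemble.shared_count(mu, nu))
            shared[mu, nu] = shared[nu, mu] = s
    mean_size = 0.5 * (sizes[:, None] + sizes[None, :])
    undefined = mean_size == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(undefined, 0.0, shared / np.where(undefined, 1.0, mean_size))
    sp = sizes / ensemble.N
    p11 = shared / ensemble.N
    var = sp * (1.0 - sp)
    denom = np.sqrt(np.outer(var, var))
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(
            bad, 0.0, (p11 - np.outer(sp, sp)) / np.where(bad, 1.0, denom)
        )
    return {
        "sparsity": sp,
        "shared_counts": shared,
        "shared_fraction": frac,
        "pearson": pearson,
        "response_counts": ensemble.response_counts(),
        "undefined_pairs": undefined,
    }
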