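"""Virtual experiments: how many concepts does a single neuron respond to?

Human-MTL recordings show neurons responding to several concepts
("multi-responsive" neurons, e.g. five or more).  To compare the pattern
construction algorithms against that observation without the recordings
themselves, we emulate the experimental design with *synthetic session
structures*: each session contributes a number of responsive neurons and a
list of cluster sizes (groups of associated stimuli).  A virtual experiment
then builds, per session, one subgroup of patterns per cluster with a given
algorithm, samples responsive neurons (active in at least one pattern) until
the session's count is matched, and accumulates the distribution of
per-neuron response counts.  Non-responsive neurons are ignored, mirroring
the experimental under-sampling of silent units.

The closed-form counterpart combines per-subgroup response-count
distributions P_K(k) into a session mixture over responsive neurons
(assuming disjoint subgroups) and weights sessions by their responsive-
neuron counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .patterns import (
    generate_subgroup,
    hierarchical_response_distribution,
    indicator_response_distribution,
)

__all__ = [
    "SessionStructure",
    "ResponseDistribution",
    "synth_sessions",
    "virtual_experiment",
    "session_mixture",
    "theory_session_mixture",
]


@dataclass
class SessionStructure:
    """One recording session: responsive-neuron count and cluster sizes."""

    session_id: int
    n_responsive: int
    cluster_sizes: list[int]

    def __post_init__(self):
        if self.n_responsive <= 0:
            raise ValueError("n_responsive must be a positive integer")
        if any(k <= 0 for k in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive integers")


@dataclass
class ResponseDistribution:
    """Probability of responding to exactly k concepts (k >= 1), with the
    across-run mean and standard deviation of a virtual experiment."""

    k: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_runs: int
    algorithm: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "mean_prob": self.mean, "sd": self.sd}
        )

    def mass_at_least(self, k0: int) -> float:
        return float(self.mean[self.k >= k0].sum())


# defaults sized like the human-MTL experiment: ~100 sessions totalling
# ~4000 responsive neurons, clusters of associated stimuli mostly small
# with occasional large groups
_DEFAULT_SIZE_WEIGHTS = {1: 0.55, 2: 0.25, 4: 0.15, 16: 0.05}


def synth_sessions(
    n_sessions: int = 100,
    mean_responsive: float = 40.7,
    mean_clusters: float = 8.0,
    size_weights: dict | None = None,
    seed: int = 0,
    N: int | None = None,
    gamma: float | None = None,
) -> list[SessionStructure]:
    """Reproducible synthetic session list standing in for the real design.

    Responsive counts are Poisson(mean_responsive) (>= 1) and the number of
    clusters Poisson(mean_clusters) (>= 1) with sizes drawn from
    ``size_weights``.  When N and gamma are given, configurations whose
    total pattern budget could exhaust the neuron pool are rejected.
    """
    weights = size_weights or _DEFAULT_SIZE_WEIGHTS
    sizes = np.array(list(weights.keys()))
    probs = np.array(list(weights.values()), dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    sessions = []
    for s in range(n_sessions):
        n_resp = max(1, int(rng.poisson(mean_responsive)))
        n_clusters = max(1, int(rng.poisson(mean_clusters)))
        cs = [int(v) for v in rng.choice(sizes, size=n_clusters, p=probs)]
        if N is not None and gamma is not None:
            budget = sum(cs) * round(gamma * N)
            if budget > 0.5 * N:
                raise ValueError(
                    f"session {s}: cluster sizes {cs} need ~{budget} neurons, "
                    f"exceeding half of the N={N} pool"
                )
        sessions.append(SessionStructure(s, n_resp, cs))
    return sessions


def virtual_experiment(
    sessions: list[SessionStructure],
    algorithm: str,
    N: int = 100_000,
    gamma: float = 0.002,
    c: float = 0.04,
    n_runs: int = 40,
    seed: int = 0,
) -> ResponseDistribution:
    """Run the virtual experiment for one construction algorithm.

    Per run and session: build one subgroup per cluster (all subgroups in
    the same N-neuron pool, so cross-subgroup sharing occurs by chance as
    in the real network), count per-neuron pattern memberships, and sample
    the session's responsive neurons uniformly without replacement among
    neurons responding to >= 1 pattern.  Counts are histogrammed over
    k = 1..max cluster size (chance cross-subgroup collisions above the
    support are clipped into the top bin) and normalized per run.
    """
    k_max = max(max(s.cluster_sizes) for s in sessions)
    root = np.random.SeedSequence([seed, 2025])
    run_seeds = root.spawn(n_runs)
    hists = np.zeros((n_runs, k_max))
    for run, rs in enumerate(run_seeds):
        rng = np.random.default_rng(rs)
        counts_hist = np.zeros(k_max)
        for sess in sessions:
            counts = np.zeros(N, dtype=np.int32)
            for K in sess.cluster_sizes:
                sub_seed = int(rng.integers(2**31 - 1))
                ens = generate_subgroup(algorithm, N, gamma, c, K, seed=sub_seed)
                for idx in ens.patterns:
                    counts[idx] += 1
            responsive = np.flatnonzero(counts > 0)
            if responsive.size < sess.n_responsive:
                raise RuntimeError(
                    f"session {sess.session_id}: only {responsive.size} "
                    f"responsive neurons available, {sess.n_responsive} requested"
                )
            picked = rng.choice(responsive, size=sess.n_responsive,
                                replace=False)
            kvals = np.minimum(counts[picked], k_max)
            counts_hist += np.bincount(kvals, minlength=k_max + 1)[1:]
        hists[run] = counts_hist / counts_hist.sum()
    return ResponseDistribution(
        k=np.arange(1, k_max + 1),
        mean=hists.mean(axis=0),
        sd=hists.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(k_max),
        n_runs=n_runs,
        algorithm=algorithm,
    )


def session_mixture(
    dists_by_size: dict[int, np.ndarray],
    sessions: list[SessionStructure],
) -> np.ndarray:
    """Closed-form responsive-neuron mixture over sessions.

    ``dists_by_size[K]`` is the full response-count distribution P_K(k),
    k = 0..K, of one subgroup of size K (must sum to 1).  Assuming strictly
    disjoint subgroups, a responsive neuron of session s responds to k
    concepts with probability

        Psi_s(k) = sum_j P_{K_j}(k) / sum_j zeta_j,   zeta_j = 1 - P_{K_j}(0),

    and sessions combine weighted by their responsive-neuron counts:
    Psi_final(k) = sum_s N_s Psi_s(k) / sum_s N_s.  Returns Psi_final over
    k = 1..max K.
    """
    for K, pk in dists_by_size.items():
        pk = np.asarray(pk)
        if len(pk) != K + 1:
            raise ValueError(f"distribution for K={K} must have length K+1")
        if abs(pk.sum() - 1.0) > 1e-8 or (pk < -1e-12).any():
            raise ValueError(f"distribution for K={K} is not normalized")
    k_max = max(max(s.cluster_sizes) for s in sessions)
    total_resp = sum(s.n_responsive for s in sessions)
    psi_final = np.zeros(k_max)
    for sess in sessions:
        num = np.zeros(k_max)
        zeta_sum = 0.0
        for K in sess.cluster_sizes:
            pk = np.asarray(dists_by_size[K], dtype=float)
            num[: K] += pk[1: K + 1]
            zeta_sum += 1.0 - pk[0]
        psi_s = num / zeta_sum
        psi_final += sess.n_responsive * psi_s
    return psi_final / total_resp


def theory_session_mixture(
    sessions: list[SessionStructure],
    gamma: float,
    c: float,
    model: str = "hierarchical",
) -> np.ndarray:
    """Psi_final built from the closed-form per-subgroup distributions."""
    dist_fn = {
        "hierarchical": hierarchical_response_distribution,
        "indicator": indicator_response_distribution,
    }[model]
    sizes = sorted({K for s in sessions for K in s.cluster_sizes})
    dists = {K: dist_fn(gamma, c, K) for K in sizes}
    return session_mixture(dists, sessions)
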