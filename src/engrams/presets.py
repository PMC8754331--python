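"""Preset scenarios: end-to-end runs of the paper-style experiments.

Each preset is a plain function returning a dict of computed results, so it
can be called from the library, from tests, or through the command line.
All stochastic presets take an explicit seed.  Times are dimensionless
(units of 1/r_max; with r_max = 40 Hz one unit is 25 ms).
"""

from __future__ import annotations

import numpy as np

from . import meanfield as mfm
from . import multiresponse as mr
from . import network as nw
from . import patterns as pt

__all__ = [
    "retrieval_protocol",
    "association_chain",
    "context_disentangling",
    "subgroup_sizes",
    "multiresponse_comparison",
    "bifurcation_fig1",
    "chain_bounds_preset",
    "PRESETS",
]


def retrieval_protocol(
    N: int = 10_000, gamma: float = 0.002, c: float = 0.1,
    b_hat: float = 100.0, h0_hat: float = 0.25,
    I_strong: float = 0.3, I_weak: float = 0.1,
    stim_window: float = 4.8,   # 120 ms at r_max = 40 Hz
    duration: float = 25.0, dt: float = 0.05, seed: int = 0,
) -> dict:
    """Two-engram retrieval protocol: strong cue to concept 1, then a weak
    cue to concept 2, in both the full network and the mean-field theory.

    Patterns are built with the exact-count iterative generator so that the
    finite-size network matches the theory (at gamma*N ~ 20 neurons per
    engram, Bernoulli sparsity fluctuations would dominate the overlaps).
    Returns both trajectories and their maximal discrepancy away from the
    stimulus edges.
    """
    C = pt.fraction_to_pearson(c, gamma)
    ens = pt.generate_iterative(N, gamma, c, K=2, seed=seed)
    params = nw.NetworkParams(b_hat=b_hat, h0_hat=h0_hat)
    t1_on, t1_off = 2.0, 2.0 + stim_window
    t2_on, t2_off = 12.0, 12.0 + stim_window
    sched = nw.StimulusSchedule([
        nw.StimulusEvent(t1_on, t1_off, I_strong, pattern=0),
        nw.StimulusEvent(t2_on, t2_off, I_weak, pattern=1),
    ])
    trace = nw.simulate(ens, params, schedule=sched, init="rest",
                        duration=duration, dt=dt, seed=seed)

    mf = mfm.MeanField(mfm.MeanFieldParams(
        gamma=gamma, C=C, b_hat=b_hat, h0_hat=h0_hat))

    def I_of_t(t):
        return (I_strong if t1_on <= t < t1_off else 0.0,
                I_weak if t2_on <= t < t2_off else 0.0)

    m = np.zeros(2)
    ms = [m.copy()]
    for k in range(int(round(duration / dt))):
        m = m + dt * mf.rhs(m, I=I_of_t(k * dt))
        ms.append(m.copy())
    m_mf = np.array(ms)

    mask = np.ones(len(trace.t), bool)
    for edge in (t1_on, t1_off, t2_on, t2_off):
        mask &= np.abs(trace.t - edge) > 1.5
    return {
        "t": trace.t,
        "m_sim": trace.m,
        "m_mf": m_mf,
        "max_discrepancy": float(np.abs(trace.m - m_mf)[mask].max()),
        "c": c, "C": C,
    }


def association_chain(
    N: int = 10_000, gamma: float = 0.002, c: float = 0.2,
    subgroup_p: int = 4, P_total: int = 16,
    tau_theta_hat: float = 45.0, D_theta_hat: float = 0.1,
    J_min: float = 0.7, J_max: float = 1.2, period_hat: float = 25.0,
    duration: float = 150.0, dt: float = 0.1, seed: int = 0,
    heaviside: bool = True,
) -> dict:
    """Association-chain simulation: a subgroup of ``subgroup_p`` engrams
    sharing fraction c, adaptation plus oscillatory inhibition, network
    initialized on one subgroup member.

    Returns the retrieval sequence (pattern index per retrieval episode).
    Chains require c above chance; rerun with c = gamma to see disruption.
    """
    if c <= gamma:
        C = 0.0
    else:
        C = pt.fraction_to_pearson(c, gamma)
    ens = pt.generate_parent_correlated(
        N, gamma, C, n_corr=subgroup_p,
        n_independent=P_total - subgroup_p, seed=seed,
    )
    params = nw.NetworkParams(
        b_hat=100.0, h0_hat=0.0, heaviside=heaviside,
        adaptation=nw.AdaptationParams(tau_theta_hat, D_theta_hat),
        inhibition=nw.OscillatoryInhibition(J_min, J_max, period_hat),
    )
    trace = nw.simulate(ens, params, init=("pattern", 0),
                        duration=duration, dt=dt, seed=seed)
    who = np.where(trace.m.max(axis=1) > 0.6, trace.m.argmax(axis=1), -1)
    episodes = []
    for i in range(1, len(who)):
        if who[i] != who[i - 1] and who[i] >= 0:
            episodes.append((float(trace.t[i]), int(who[i])))
    return {
        "t": trace.t, "m": trace.m, "J0": trace.J0,
        "episodes": episodes,
        "retrieved_patterns": sorted({p for _, p in episodes}),
        "subgroup": list(range(subgroup_p)),
    }


def context_disentangling(
    context: str = "C1", N: int = 20_000, gamma: float = 0.002,
    C: float = 0.1, b_hat: float = 100.0, h0_hat: float = 0.25,
    I_weak: float = 0.02, I_strong: float = 1.0,
    duration: float = 16.0, dt: float = 0.05, seed: int = 0,
) -> dict:
    """Context stimulation disentangles two memories sharing a person.

    Five concepts are stored: persons P0, P1, P2 and contexts C1, C2, with
    two overlapping subgroups {P0, P1, C1} and {P0, P2, C2} (within-group
    Pearson correlation C; pairwise-disjoint shared sets as in the
    iterative construction).  P1 and P2 receive a weak ambiguous cue
    throughout; P0 is strongly stimulated first, then the chosen context.
    Stimulating C1 recalls P1 but not P2; C2 the reverse.

    The readout follows shortly after the context window: the context-driven
    recall cascade takes ~2 tau, while the weak ambiguous cue alone drives a
    much slower drift of the person overlaps through their intermediate-rate
    shared neurons, so the discrimination is temporal as well as structural.

    Pattern order: 0=P0, 1=P1, 2=C1, 3=P2, 4=C2.
    """
    if context not in ("C1", "C2"):
        raise ValueError("context must be 'C1' or 'C2'")
    c = pt.pearson_to_fraction(C, gamma)
    ens = pt.generate_iterative_groups(
        N, gamma, c, subgroups=[[0, 1, 2], [0, 3, 4]], seed=seed,
    )
    ctx_idx = 2 if context == "C1" else 4
    sched = nw.StimulusSchedule([
        nw.StimulusEvent(0.0, duration, I_weak, pattern=1),   # P1
        nw.StimulusEvent(0.0, duration, I_weak, pattern=3),   # P2
        nw.StimulusEvent(2.0, 6.8, I_strong, pattern=0),      # P0
        nw.StimulusEvent(9.0, 13.8, I_strong, pattern=ctx_idx),
    ])
    params = nw.NetworkParams(b_hat=b_hat, h0_hat=h0_hat)
    trace = nw.simulate(ens, params, schedule=sched, init="rest",
                        duration=duration, dt=dt, seed=seed)
    m_final = trace.m[-1]
    return {
        "t": trace.t, "m": trace.m,
        "labels": ["P0", "P1", "C1", "P2", "C2"],
        "context": context,
        "m_final": m_final,
        "P1_recalled": bool(m_final[1] > 0.5),
        "P2_recalled": bool(m_final[3] > 0.5),
    }


def subgroup_sizes(
    N: int = 100_000, gamma: float = 0.002, c: float = 0.04,
    K: int = 16, n_seeds: int = 40, seed: int = 0,
) -> dict:
    """Expected number of distinct neurons recruited by a subgroup of K
    engrams, per construction algorithm (mean over seeds), plus the
    hierarchical closed form lambda*N*(1 - (1-c)^K)."""
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(seed).spawn(n_seeds)]
    out = {}
    for algo in ("hierarchical", "indicator", "iterative"):
        sizes = [
            pt.generate_subgroup(algo, N, gamma, c, K, seed=s).distinct_active()
            for s in seeds
        ]
        out[algo] = {"mean": float(np.mean(sizes)), "sd": float(np.std(sizes))}
    lam = gamma / c
    out["hierarchical_closed_form"] = float(
        lam * N * (1.0 - (1.0 - c) ** K)
    )
    return out


def multiresponse_comparison(
    n_sessions: int = 100, N: int = 100_000, gamma: float = 0.002,
    c: float = 0.04, n_runs: int = 40, seed: int = 0,
    mean_responsive: float = 40.7,
) -> dict:
    """Virtual-experiment response-count distributions for the three
    algorithms on the same synthetic sessions, plus the closed-form session
    mixtures for the two hierarchical models."""
    sessions = mr.synth_sessions(
        n_sessions=n_sessions, mean_responsive=mean_responsive,
        seed=seed, N=N, gamma=gamma,
    )
    dists = {
        algo: mr.virtual_experiment(
            sessions, algo, N=N, gamma=gamma, c=c, n_runs=n_runs, seed=seed)
        for algo in ("hierarchical", "indicator", "iterative")
    }
    theory = {
        model: mr.theory_session_mixture(sessions, gamma, c, model=model)
        for model in ("hierarchical", "indicator")
    }
    return {"sessions": sessions, "distributions": dists, "theory": theory}


def bifurcation_fig1(
    gamma: float = 0.002, b_hat: float = 100.0, h0_hat: float = 0.25,
    alpha: float = 0.0, scan: bool = False,
) -> dict:
    """c_max extraction in the reference regime, optionally with the full
    fixed-point loci versus C for the bifurcation diagram."""
    params = mfm.MeanFieldParams(
        gamma=gamma, C=0.0, b_hat=b_hat, h0_hat=h0_hat, alpha=alpha)
    grid = np.linspace(0.0, min(1.0, h0_hat + 0.02), 45) if scan else None
    res = mfm.extract_c_max(params, scan_grid=grid)
    return {"result": res, "c_max": res.c_crit, "C_max": res.C_crit,
            "bound": mfm.analytic_cmax_bound(gamma, h0_hat)}


def chain_bounds_preset(
    gamma: float = 0.002, b_hat: float = 50.0, h0_hat: float = 0.0,
    J_min: float = 0.7, J_max: float = 1.2,
) -> dict:
    """Admissible [c_min', c_max'] range for association chains under
    oscillatory inhibition (adaptation frozen), S2-figure regime."""
    params = mfm.MeanFieldParams(
        gamma=gamma, C=0.0, b_hat=b_hat, h0_hat=h0_hat)
    return mfm.chain_correlation_bounds(params, J_min=J_min, J_max=J_max)


PRESETS = {
    "fig1c_retrieval": retrieval_protocol,
    "fig4_chain": association_chain,
    "fig8_context": context_disentangling,
    "fig6b_sizes": subgroup_sizes,
    "fig6a_multiresponse": multiresponse_comparison,
    "fig9_bifurcation": bifurcation_fig1,
    "fig5_chain_bounds": chain_bounds_preset,
}
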