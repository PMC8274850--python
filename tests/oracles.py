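"""Independent oracles used by the test suite.

These deliberately avoid the code paths they are used to check: the
frontier oracle tests dominance from its definition (pairwise mixes), and
the cohort oracle integrates the disease process deterministically rather
than simulating it.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def brute_force_efficient(points) -> set[str]:
    """Efficient set straight from the definition of (extended) dominance.

    A point is inefficient if a single other point weakly dominates it
    (with a strict part, or an exact tie broken toward the smaller label),
    or if a convex combination of two other points attains its QALY level
    at strictly lower cost.
    """
    efficient = set()
    for p in points:
        dominated = False
        for q in points:
            if q is p:
                continue
            if q.cost <= p.cost and q.qaly >= p.qaly:
                if q.cost < p.cost or q.qaly > p.qaly or q.label < p.label:
                    dominated = True
                    break
        if not dominated:
            for q in points:
                if dominated:
                    break
                for r in points:
                    if q is p or r is p or q is r:
                        continue
                    if not (q.qaly < p.qaly < r.qaly):
                        continue
                    lam = (p.qaly - q.qaly) / (r.qaly - q.qaly)
                    mix_cost = q.cost + lam * (r.cost - q.cost)
                    if mix_cost < p.cost - 1e-9 * max(1.0, abs(p.cost)):
                        dominated = True
                        break
        if not dominated:
            efficient.add(p.label)
    return efficient


def _progression_kinetics(params, grid):
    """P(lesion has turned clinical) and P(lesion has caused death) by time
    since onset, from the lesion-level continuous-time Markov chain."""
    k = len(params.precursor_states)
    m = len(params.stage_distribution)
    # states: 0..k-1 precursors, k preclinical, k+1..k+m clinical stages,
    # k+m+1 dead of cancer, k+m+2 stalled benign
    n = k + m + 3
    Q = np.zeros((n, n))
    for j in range(k):
        out = 1.0 / params.dwell_means[j]
        Q[j, j] = -out
        Q[j, k] += out * params.p_malignant[j]
        if j + 1 < k:
            Q[j, j + 1] += out * (1.0 - params.p_malignant[j])
        else:
            Q[j, n - 1] += out * (1.0 - params.p_malignant[j])
    out = 1.0 / params.sojourn_mean
    Q[k, k] = -out
    for s in range(m):
        Q[k, k + 1 + s] = out * params.stage_distribution[s]
        Q[k + 1 + s, k + 1 + s] = -1.0 / params.cancer_survival_means[s]
        Q[k + 1 + s, k + m + 1] = 1.0 / params.cancer_survival_means[s]

    p0 = np.zeros(n)
    p0[0] = 1.0
    sol = solve_ivp(
        lambda _t, p: Q.T @ p,
        (0.0, grid[-1]),
        p0,
        t_eval=grid,
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    p = sol.y
    q_clinical = p[k + 1 : k + m + 1].sum(axis=0) + p[k + m + 1]
    q_dead = p[k + m + 1]
    return q_clinical, q_dead


def cohort_expectation(params, life_table, entry_age=20.0, step=0.05):
    """Deterministic lifetime clinical-cancer incidence and mortality.

    Lesion onsets form a non-homogeneous Poisson process; each onset
    independently becomes clinical (or lethal) within u years with the
    kinetics above, so the number of lesions clinical by age a is Poisson
    with mean Lambda(a) = int mu(s) q(a - s) ds.  Marginalizing over the
    other-cause death age D (conditional on survival to entry):

        P(diagnosed in life) = E_D[1 - exp(-Lambda_clin(D))]
        P(dies of cancer)    = E_D[1 - exp(-Lambda_dead(D))]

    Valid for entry at or before the first possible onset age, so that no
    conditioning on being cancer-free at entry is needed.
    """
    a_max = life_table.max_age
    grid = np.arange(0.0, a_max + step / 2, step)
    q_clin, q_dead = _progression_kinetics(params, grid)
    idx = np.minimum(grid.astype(int), len(params.onset_rates) - 1)
    mu = params.onset_rates[idx]

    lam_clin = np.convolve(mu, q_clin)[: len(grid)] * step
    lam_dead = np.convolve(mu, q_dead)[: len(grid)] * step

    s_cond = life_table.survival_at(grid) / life_table.survival_at(entry_age)
    s_cond = np.clip(s_cond, 0.0, 1.0)
    s_cond[grid < entry_age] = 1.0
    dens = -np.gradient(s_cond, grid)

    p_diag = np.trapezoid(dens * (1.0 - np.exp(-lam_clin)), grid)
    p_dead = np.trapezoid(dens * (1.0 - np.exp(-lam_dead)), grid)
    # residual mass clamped to the last table age
    tail = s_cond[-1]
    p_diag += tail * (1.0 - np.exp(-lam_clin[-1]))
    p_dead += tail * (1.0 - np.exp(-lam_dead[-1]))
    return float(p_diag), float(p_dead)


def grid_search_wls(series, alphas, betas):
    """Coarse grid argmin of the weighted SSE for the exponential form."""
    best = (np.inf, None, None)
    for a in alphas:
        resid = series.values[None, :] - a * np.exp(
            np.asarray(betas)[:, None] * series.ages[None, :]
        )
        sse = (series.weights[None, :] * resid**2).sum(axis=1)
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (float(sse[j]), float(a), float(betas[j]))
    return best
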