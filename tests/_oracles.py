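"""Exact enumeration oracles for the bootstrap variance of the HT total.

Each function enumerates the full outcome space of one bootstrap procedure
on a small sample and returns the exact bootstrap variance, written
independently of the package's replicate generators (plain probability
arithmetic over explicitly listed outcomes).
"""

from itertools import combinations, product

import numpy as np

from svyboot import ht_total


def _var_from_mixture(terms):
    """terms: iterable of (prob, cond_mean, cond_var) -> total variance."""
    e1 = sum(p * m for p, m, _ in terms)
    e2 = sum(p * (v + m * m) for p, m, v in terms)
    return e2 - e1 * e1


def enum_rao_wu_var(sample) -> float:
    """Exact variance of the rescaled-bootstrap HT total by full enumeration."""
    n, N = sample.n, sample.N
    f1 = n / N
    Mbar0 = sample.M0 / N
    ybar = ht_total(sample) / sample.M0
    a = np.sqrt(n * (1.0 - f1) / (n - 1.0))

    # per original psu: the exact (mean, variance) of one bootstrap slot's
    # contribution, over its with-replacement element draws
    slot_mv = []
    for j in range(n):
        mj, Mj = int(sample.m[j]), float(sample.M[j])
        ts = sample.that[j] / Mbar0
        b = np.sqrt(mj * f1 * (1.0 - mj / Mj) / (mj - 1.0))
        w = N * Mbar0 / (n * mj)
        vals = []
        for draws in product(range(mj), repeat=mj):
            ystar = sample.y[j][list(draws)]
            pv = ybar + a * (ts - ybar) + b * (Mj * ystar / Mbar0 - ts)
            vals.append(w * pv.sum())
        vals = np.array(vals)
        slot_mv.append((vals.mean(), vals.var()))

    terms = []
    for P in product(range(n), repeat=n):
        p = (1.0 / n) ** n
        mean = sum(slot_mv[j][0] for j in P)
        var = sum(slot_mv[j][1] for j in P)
        terms.append((p, mean, var))
    return _var_from_mixture(terms)


def enum_preston_var(sample, n_prime: int, m_prime) -> float:
    """Exact variance of the Preston weighted HT total."""
    n, N = sample.n, sample.N
    f1 = n / N
    m_prime = np.asarray(m_prime, dtype=int)
    lam1 = np.sqrt(n_prime * (1.0 - f1) / (n - n_prime))
    lam2 = np.sqrt(m_prime * f1 * (1.0 - sample.pi2) / (sample.m - m_prime))

    psu_subsets = list(combinations(range(n), n_prime))
    elem_subsets = [list(combinations(range(int(mi)), int(mp))) for mi, mp in zip(sample.m, m_prime)]
    outcomes = []
    for psel in psu_subsets:
        for esel in product(*elem_subsets):
            tot = 0.0
            for i in range(n):
                di = 1.0 if i in psel else 0.0
                mi, mpi = int(sample.m[i]), int(m_prime[i])
                for k in range(mi):
                    dk = 1.0 if k in esel[i] else 0.0
                    adj = (
                        1.0
                        + lam1 * ((n / n_prime) * di - 1.0)
                        + lam2[i] * np.sqrt(n / n_prime) * di * ((mi / mpi) * dk - 1.0)
                    )
                    tot += adj * sample.y[i][k] / (sample.pi1[i] * sample.pi2[i])
            outcomes.append(tot)
    return float(np.var(outcomes))


def enum_mirror_match_var(sample, n_prime: int, m_prime: int, k1: int) -> float:
    """Exact mirror-match variance; k1 and all k2i must be integers."""
    n, N = sample.n, sample.N
    nstar = k1 * n_prime

    occ_mv = []  # per original psu: (mean, var) of one occurrence's total
    for j in range(n):
        mj, Mj = int(sample.m[j]), float(sample.M[j])
        f2 = mj / Mj
        f2s = m_prime / mj
        k2 = N * mj * (1.0 - f2s) / (nstar * m_prime * (1.0 - f2))
        assert abs(k2 - round(k2)) < 1e-9, "pick a fixture with integer k2"
        k2 = int(round(k2))
        mstar = k2 * m_prime
        w = (N / nstar) * (Mj / mstar)
        vals = []
        subsets = list(combinations(range(mj), m_prime))
        for draws in product(subsets, repeat=k2):
            s = sum(sample.y[j][list(d)].sum() for d in draws)
            vals.append(w * s)
        vals = np.array(vals)
        occ_mv.append((vals.mean(), vals.var()))

    group_subsets = list(combinations(range(n), n_prime))
    terms = []
    for groups in product(group_subsets, repeat=k1):
        p = (1.0 / len(group_subsets)) ** k1
        occ = [j for g in groups for j in g]
        mean = sum(occ_mv[j][0] for j in occ)
        var = sum(occ_mv[j][1] for j in occ)
        terms.append((p, mean, var))
    return _var_from_mixture(terms)


def enum_bwo_var(sample, plan) -> float:
    """Exact modified-BWO variance, including both randomization layers."""
    n = sample.n
    nu = plan.nu
    v_support = [(plan.v_lo, 1.0 - plan.q1)]
    if plan.q1 > 0:
        v_support.append((plan.v_lo + 1, plan.q1))

    terms = []
    for v, pv in v_support:
        if pv == 0:
            continue
        u_lo, q2 = plan.u_lo[v], plan.q2[v]
        # per original psu: exact (mean, second moment) of one selected
        # pseudo-psu's HT contribution under the u-mixture
        psu_mv = {}
        for j in range(n):
            Mpj = int(plan.Mp[j])
            sub_terms = []
            for u, pu in ((int(u_lo[j]), 1.0 - q2[j]), (min(int(u_lo[j]) + 1, Mpj), q2[j])):
                if pu == 0:
                    continue
                w = (nu / v) * (Mpj / u)
                vals = np.array(
                    [w * plan.values[j][list(c)].sum() for c in combinations(range(Mpj), u)]
                )
                sub_terms.append((pu, vals.mean(), vals.var()))
            e1 = sum(p * m for p, m, _ in sub_terms)
            e2 = sum(p * (vv + m * m) for p, m, vv in sub_terms)
            psu_mv[j] = (e1, e2 - e1 * e1)
        for subset in combinations(range(nu), v):
            p = pv / len(list(combinations(range(nu), v)))
            js = [t % n for t in subset]
            mean = sum(psu_mv[j][0] for j in js)
            var = sum(psu_mv[j][1] for j in js)
            terms.append((p, mean, var))
    return _var_from_mixture(terms)
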