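"""Seven bootstrap variance procedures for two-stage samples.

All methods share one replicate-generating interface: given a realized
:class:`~svyboot.designs.TwoStageSample`, a weighted point estimator and a
:class:`MethodConfig`, they return a :class:`ReplicateSet` of B bootstrap
point estimates whose spread estimates the design variance.

Under SRSWOR at both stages, four of the procedures (rescaled Rao-Wu,
mirror-match, the modified without-replacement pseudo-population bootstrap,
and the Preston bootstrap-weight scheme) are calibrated so that the bootstrap
variance of the HT *total* equals the textbook variance estimator exactly;
the Bernoulli bootstrap matches it through its keep/replace probabilities.
The Rao-Wu-Yue bootstrap-weight scheme and the Chauvet pseudo-population
double bootstrap also cover unequal-probability (IPPS) first stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import TwoStageSample, ipps_randomized_systematic, srswor
from .estimators import ht_total

__all__ = [
    "MethodConfig",
    "ReplicateSet",
    "bootstrap_variance",
    "rao_wu",
    "mirror_match",
    "mirror_match_k1",
    "bwo_sitter",
    "plan_bwo",
    "bernoulli",
    "bernoulli_probs",
    "preston",
    "preston_lambdas",
    "rwy",
    "chauvet",
    "run_method",
    "export_replicate_weights",
    "METHODS",
]


@dataclass
class MethodConfig:
    """Bootstrap method identifier plus tuning constants.

    ``n_prime`` / ``m_prime`` override the per-method defaults where a
    resample size applies; ``A_ppb`` / ``B_ppb`` are the outer/inner counts
    of the Chauvet double bootstrap.
    """

    method: str = ""
    B: int = 500
    n_prime: int | None = None
    m_prime: int | None = None
    A_ppb: int = 10
    B_ppb: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")


@dataclass
class ReplicateSet:
    """B bootstrap point estimates (and, for weight methods, weights)."""

    estimates: np.ndarray
    method: str
    replicate_weights: np.ndarray | None = None  # (B, L) over sample.flat order
    groups: np.ndarray | None = None  # outer-iteration label per replicate

    B: int = field(init=False)

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=np.float64)
        self.B = len(self.estimates)


def bootstrap_variance(reps: ReplicateSet | np.ndarray) -> float:
    """Monte Carlo bootstrap variance (B-1 denominator).

    For grouped replicates (Chauvet outer iterations) this is the mean over
    groups of the within-group replicate variances.
    """
    if isinstance(reps, ReplicateSet):
        est, groups = reps.estimates, reps.groups
    else:
        est, groups = np.asarray(reps, dtype=np.float64), None
    if len(est) < 2:
        raise ValueError("need at least two replicates")
    if groups is None:
        return float(np.var(est, ddof=1))
    vs = []
    for g in np.unique(groups):
        block = est[groups == g]
        if len(block) < 2:
            raise ValueError("need at least two replicates per outer iteration")
        vs.append(np.var(block, ddof=1))
    return float(np.mean(vs))


def _rng_from(cfg: MethodConfig, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(cfg.seed)


def _rand_round(x: float, rng: np.random.Generator) -> int:
    """Randomize between the bracketing integers with exact expectation."""
    a = int(np.floor(x))
    return a + int(rng.random() < (x - a))


def _require_srswor(sample: TwoStageSample, method: str) -> None:
    if sample.design != "srswor":
        raise ValueError(f"{method} requires SRSWOR at the first stage")


def _rect(sample: TwoStageSample):
    """(n, m) value matrix when every psu has the same subsample size."""
    if len(set(sample.m.tolist())) == 1:
        return np.vstack(sample.y)
    return None


# ---------------------------------------------------------------------------
# Rao-Wu rescaled bootstrap
# ---------------------------------------------------------------------------


def rao_wu(sample, estimator, cfg: MethodConfig | None = None, rng=None) -> ReplicateSet:
    """Rescaled bootstrap: SRSWR of psus and elements, scale applied to y.

    Pseudo-values recentre the resampled data around the estimated mean so
    that for the HT total the bootstrap variance reproduces the textbook
    estimator.  Because the rescaling acts on y-values, the method is meant
    for smooth statistics; requesting a non-smooth one raises a warning and
    proceeds (its documented failure mode).
    """
    cfg = cfg or MethodConfig(method="rao_wu")
    rng = _rng_from(cfg, rng)
    _require_srswor(sample, "rao_wu")
    n = sample.n
    if n < 2:
        raise ValueError("rao_wu needs n >= 2")
    if np.any(sample.m < 2):
        raise ValueError("rao_wu needs m_i >= 2 in every sampled psu")
    if not getattr(estimator, "smooth", True):
        warnings.warn(
            "the rescaled bootstrap is not valid for non-smooth statistics "
            "such as quantiles; results will be severely biased",
            UserWarning,
            stacklevel=2,
        )
    B = cfg.B
    f1 = sample.f1
    Mbar0 = sample.M0 / sample.N
    ybar_hat = ht_total(sample) / sample.M0
    a = np.sqrt(n * (1.0 - f1) / (n - 1.0))

    Y = _rect(sample)
    if Y is not None:
        m = int(sample.m[0])
        P = rng.integers(0, n, size=(B, n))
        E = rng.integers(0, m, size=(B, n, m))
        ystar = Y[P[..., None], E]  # (B, n, m)
        Ms = sample.M[P].astype(float)
        ts = sample.that[P] / Mbar0  # t_hat_i*/Mbar0, (B, n)
        f2s = m / Ms
        b = np.sqrt(m * f1 * (1.0 - f2s) / (m - 1.0))
        pseudo = (
            ybar_hat
            + a * (ts - ybar_hat)[..., None]
            + b[..., None] * (Ms[..., None] * ystar / Mbar0 - ts[..., None])
        )
        W = np.full_like(pseudo, sample.N * Mbar0 / (n * m))
        est = estimator.batch(pseudo.reshape(B, -1), W.reshape(B, -1))
        return ReplicateSet(est, "rao_wu")

    out = np.empty(B)
    for bi in range(B):
        vals, wts = [], []
        for j in rng.integers(0, n, size=n):
            mj = int(sample.m[j])
            Mj = float(sample.M[j])
            pick = rng.integers(0, mj, size=mj)
            ystar = sample.y[j][pick]
            ts = sample.that[j] / Mbar0
            bj = np.sqrt(mj * f1 * (1.0 - mj / Mj) / (mj - 1.0))
            pv = ybar_hat + a * (ts - ybar_hat) + bj * (Mj * ystar / Mbar0 - ts)
            vals.append(pv)
            wts.append(np.full(mj, sample.N * Mbar0 / (n * mj)))
        out[bi] = estimator(np.concatenate(vals), np.concatenate(wts))
    return ReplicateSet(out, "rao_wu")


# ---------------------------------------------------------------------------
# mirror-match bootstrap
# ---------------------------------------------------------------------------


def mirror_match_k1(n: int, f1: float, n_prime: int) -> float:
    """Number of concatenated subsample draws: k1 = n(1-f1*)/(n'(1-f1))."""
    f1s = n_prime / n
    return n * (1.0 - f1s) / (n_prime * (1.0 - f1))


def mirror_match(sample, estimator, cfg: MethodConfig | None = None, rng=None) -> ReplicateSet:
    """Mirror-match bootstrap: small SRSWOR subsamples replicated to scale.

    Each replicate concatenates k1 independent SRSWOR draws of n' psus
    (k1 = n(1-f1*)/(n'(1-f1)), f1* = n'/n) and, within every drawn psu,
    k2i independent SRSWOR draws of m_i' elements
    (k2i = N m_i (1-f2i*)/(n* m_i' (1-f2i))).  Non-integer k's are randomized
    between bracketing integers.  Estimates use same-form HT weights
    (N/n*)(M_i/m_i*).
    """
    cfg = cfg or MethodConfig(method="mirror_match")
    rng = _rng_from(cfg, rng)
    _require_srswor(sample, "mirror_match")
    n, N = sample.n, sample.N
    f1 = n / N
    n_prime = cfg.n_prime if cfg.n_prime is not None else max(1, int(np.rint(f1 * n)))
    if not (1 <= n_prime < n):
        raise ValueError(f"need 1 <= n' < n, got n'={n_prime}")
    if cfg.m_prime is not None:
        m_prime = np.full(n, int(cfg.m_prime))
    else:
        m_prime = np.maximum(1, np.rint(sample.pi2 * sample.m).astype(int))
    m_prime = np.minimum(m_prime, sample.m - 1)
    if np.any(m_prime < 1):
        raise ValueError("need 1 <= m_i' < m_i in every psu")
    k1 = mirror_match_k1(n, f1, n_prime)
    f2s = m_prime / sample.m
    out = np.empty(cfg.B)
    for bi in range(cfg.B):
        k1r = _rand_round(k1, rng)
        draws = [rng.choice(n, size=n_prime, replace=False) for _ in range(k1r)]
        occ = np.concatenate(draws) if draws else np.empty(0, dtype=int)
        nstar = len(occ)  # = k1r * n_prime
        vals, wts = [], []
        for j in occ:
            mj, Mj = int(sample.m[j]), float(sample.M[j])
            mpj = int(m_prime[j])
            if sample.pi2[j] >= 1.0:  # census second stage: no within-psu noise
                picks = np.arange(mj)
            else:
                k2 = N * mj * (1.0 - f2s[j]) / (nstar * mpj * (1.0 - sample.pi2[j]))
                k2r = max(1, _rand_round(k2, rng))
                picks = np.concatenate(
                    [rng.choice(mj, size=mpj, replace=False) for _ in range(k2r)]
                )
            vals.append(sample.y[j][picks])
            wts.append(np.full(len(picks), (N / nstar) * (Mj / len(picks))))
        out[bi] = estimator(np.concatenate(vals), np.concatenate(wts))
    return ReplicateSet(out, "mirror_match")


# ---------------------------------------------------------------------------
# modified without-replacement (BWO) pseudo-population bootstrap
# ---------------------------------------------------------------------------


@dataclass
class _BwoPlan:
    """Pseudo-population and randomized resample sizes for the BWO bootstrap."""

    k1: int
    nu: int  # pseudo-population psu count = k1 * n
    k2: np.ndarray  # per-psu replication of elements
    Mp: np.ndarray  # pseudo-psu sizes k2_i * m_i
    values: list[np.ndarray]  # tiled element values per distinct psu
    v_lo: int  # first-stage resample size bracket
    q1: float  # P(v = v_lo + 1)
    u_lo: dict[int, np.ndarray]  # per realized v: per-psu element bracket
    q2: dict[int, np.ndarray]  # per realized v: P(u = u_lo + 1)


def plan_bwo(sample: TwoStageSample, k1: int | None = None, max_k1: int = 4096) -> _BwoPlan:
    """Solve the variance-matching contract for the modified BWO constants.

    The pseudo-population replicates each sampled psu k1 times and each
    sampled element k2i = round(M_i/m_i) times.  Real-valued resample sizes
    (n', m_i') are then solved so that the exact SRSWOR/SRSWOR bootstrap
    variance of the HT total on the pseudo-population equals the textbook
    estimator on the original sample, and realized by randomization between
    bracketing integers with mixing probabilities exact on the 1/n' and
    1/m_i' - 1/M_i' scales (so the match holds in expectation, exactly).
    """
    n, N = sample.n, sample.N
    if n < 2:
        raise ValueError("bwo_sitter needs n >= 2")
    f1 = n / N
    k2 = np.maximum(1, np.rint(sample.M / sample.m)).astype(int)
    Mp = k2 * sample.m
    values = [np.tile(yi, int(k)) for yi, k in zip(sample.y, k2)]
    tprime = np.array([k * yi.sum() for yi, k in zip(sample.y, k2)], dtype=float)
    # pseudo-psu element variance (denominator Mp - 1)
    syi2 = np.array([np.var(yi, ddof=1) if len(yi) > 1 else 0.0 for yi in sample.y])
    Syp2 = np.where(Mp > 1, k2 * (sample.m - 1) * syi2 / np.maximum(Mp - 1, 1), 0.0)

    st2 = float(np.var(sample.that, ddof=1))
    T1 = N * N * (1.0 - f1) * st2 / n
    T2 = (N / n) * sample.M.astype(float) ** 2 * (1.0 - sample.pi2) * syi2 / sample.m

    candidates = [int(k1)] if k1 is not None else None
    if candidates is None:
        k0 = max(1, int(np.rint(1.0 / f1)))
        candidates = []
        k = k0
        while k <= max_k1:
            candidates.append(k)
            k = max(k + 1, int(k * 2))
    last_err = "no candidate k1 tried"
    for k1c in candidates:
        nu = k1c * n
        St2p = k1c * float(np.sum((tprime - tprime.mean()) ** 2)) / (nu - 1)
        if St2p <= 0:
            if T1 > 0:
                last_err = "pseudo-population psu totals are constant but T1 > 0"
                continue
            v_lo, q1 = max(1, int(np.rint(f1 * nu))), 0.0
        else:
            h = T1 / (nu * nu * St2p) + 1.0 / nu
            if h > 1.0 or h < 1.0 / nu:
                last_err = f"k1={k1c}: first-stage target 1/n'={h:.4g} infeasible"
                continue
            v_lo = int(np.floor(1.0 / h))
            v_lo = min(v_lo, nu - 1)
            q1 = (1.0 / v_lo - h) / (1.0 / v_lo - 1.0 / (v_lo + 1))
            q1 = min(max(q1, 0.0), 1.0)
        u_lo, q2 = {}, {}
        feasible = True
        for v in ({v_lo} if q1 == 0.0 else {v_lo, v_lo + 1}):
            ul = np.empty(sample.n, dtype=int)
            qq = np.zeros(sample.n)
            for i in range(sample.n):
                denom = nu * k1c * float(Mp[i]) ** 2 * Syp2[i]
                if denom <= 0 or T2[i] <= 0:
                    ul[i], qq[i] = int(sample.m[i]), 0.0
                    continue
                G = v * T2[i] / denom
                gmax = 1.0 - 1.0 / Mp[i]
                if G > gmax + 1e-12:
                    feasible = False
                    last_err = f"k1={k1c}: psu {i} needs m'<1 (target {G:.4g})"
                    break
                u0 = 1.0 / (G + 1.0 / Mp[i])
                a2 = max(1, min(int(np.floor(u0)), int(Mp[i]) - 1))
                g_a = 1.0 / a2 - 1.0 / Mp[i]
                g_b = 1.0 / (a2 + 1) - 1.0 / Mp[i]
                qq[i] = min(max((g_a - G) / (g_a - g_b), 0.0), 1.0)
                ul[i] = a2
            if not feasible:
                break
            u_lo[v], q2[v] = ul, qq
        if feasible:
            return _BwoPlan(
                k1=k1c, nu=nu, k2=k2, Mp=Mp, values=values,
                v_lo=v_lo, q1=q1, u_lo=u_lo, q2=q2,
            )
    raise ValueError(f"no feasible modified-BWO constants found: {last_err}")


def bwo_sitter(sample, estimator, cfg: MethodConfig | None = None, rng=None) -> ReplicateSet:
    """Modified without-replacement pseudo-population (BWO) bootstrap.

    Builds a pseudo-population by whole-number replication of the sampled
    psus and elements, then redraws SRSWOR/SRSWOR samples from it with
    resample sizes randomized so that the bootstrap variance of the HT total
    matches the textbook estimator exactly (see :func:`plan_bwo`).
    """
    cfg = cfg or MethodConfig(method="bwo_sitter")
    rng = _rng_from(cfg, rng)
    _require_srswor(sample, "bwo_sitter")
    plan = plan_bwo(sample, k1=cfg.n_prime)
    n = sample.n
    out = np.empty(cfg.B)
    for bi in range(cfg.B):
        v = plan.v_lo + int(rng.random() < plan.q1)
        sel = rng.choice(plan.nu, size=v, replace=False) % n  # pseudo-psu -> original
        ul, qq = plan.u_lo[v], plan.q2[v]
        vals, wts = [], []
        for j in sel:
            Mpj = int(plan.Mp[j])
            u = min(ul[j] + int(rng.random() < qq[j]), Mpj)
            pick = rng.choice(Mpj, size=u, replace=False)
            vals.append(plan.values[j][pick])
            wts.append(np.full(u, (plan.nu / v) * (Mpj / u)))
        out[bi] = estimator(np.concatenate(vals), np.concatenate(wts))
    return ReplicateSet(out, "bwo_sitter")


# ---------------------------------------------------------------------------
# Bernoulli bootstrap
# ---------------------------------------------------------------------------


def bernoulli_probs(sample: TwoStageSample) -> tuple[float, np.ndarray]:
    """Keep probabilities (p1, p2i) of the Bernoulli bootstrap.

    Solved from the requirement that the bootstrap variance of the HT total
    equal the textbook estimator:
    p1 = 1 - (1-f1) / (2(1-1/n)),  p2i = 1 - f1(1-f2i) / (2 p1 (1-1/m_i)).
    """
    n = sample.n
    f1 = sample.f1
    p1 = 1.0 - (1.0 - f1) / (2.0 * (1.0 - 1.0 / n))
    p2 = 1.0 - f1 * (1.0 - sample.pi2) / (2.0 * p1 * (1.0 - 1.0 / sample.m))
    if not (0.0 <= p1 <= 1.0) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("Bernoulli bootstrap keep-probabilities fall outside [0, 1]")
    return float(p1), p2


def bernoulli(sample, estimator, cfg: MethodConfig | None = None, rng=None) -> ReplicateSet:
    """Bernoulli bootstrap: keep-or-replace resampling at both stages.

    Each replicate draws a donor pool of n-1 with-replacement psus, keeps
    each original psu with probability p1 (replacing it by a random donor
    otherwise), and inside every kept psu applies the same device to the
    elements with donor pools of size m_i - 1 and probability p2i.  The
    resulting sample has the original shape and reuses the original weights.
    """
    cfg = cfg or MethodConfig(method="bernoulli")
    rng = _rng_from(cfg, rng)
    _require_srswor(sample, "bernoulli")
    n = sample.n
    if n < 2 or np.any(sample.m < 2):
        raise ValueError("bernoulli needs n >= 2 and m_i >= 2")
    p1, p2 = bernoulli_probs(sample)
    N = sample.N
    out = np.empty(cfg.B)
    for bi in range(cfg.B):
        donors = rng.integers(0, n, size=n - 1)
        keep = rng.random(n) < p1
        vals, wts = [], []
        for i in range(n):
            if keep[i]:
                mi = int(sample.m[i])
                e_donors = rng.integers(0, mi, size=mi - 1)
                ekeep = rng.random(mi) < p2[i]
                yv = sample.y[i].copy()
                repl = ~ekeep
                if repl.any():
                    yv[repl] = sample.y[i][e_donors[rng.integers(0, mi - 1, size=int(repl.sum()))]]
                j, vj = i, yv
            else:
                j = int(donors[rng.integers(0, n - 1)])
                vj = sample.y[j]
            vals.append(vj)
            wts.append(np.full(len(vj), (N / n) * (sample.M[j] / sample.m[j])))
        out[bi] = estimator(np.concatenate(vals), np.concatenate(wts))
    return ReplicateSet(out, "bernoulli")


# ---------------------------------------------------------------------------
# Preston bootstrap weights
# ---------------------------------------------------------------------------


def preston_lambdas(n: int, f1: float, n_prime: int, m, f2, m_prime):
    """Rescaling constants lambda1 and lambda2i of the Preston weights."""
    lam1 = float(np.sqrt(n_prime * (1.0 - f1) / (n - n_prime)))
    m = np.asarray(m, dtype=float)
    m_prime = np.asarray(m_prime, dtype=float)
    lam2 = np.sqrt(m_prime * f1 * (1.0 - np.asarray(f2, dtype=float)) / (m - m_prime))
    return lam1, lam2


def preston(sample, estimator, cfg: MethodConfig | None = None, rng=None) -> ReplicateSet:
    """Preston bootstrap-weight scheme (half-sample subsampling).

    Per replicate, SRSWOR indicators delta_i (n' of n psus) and delta_ik
    (m_i' of m_i elements inside selected psus) define element weights

        w_ik* = {1 + lambda1 (n/n' delta_i - 1)
                   + lambda2i sqrt(n/n') delta_i (m_i/m_i' delta_ik - 1)}
                / (pi_i pi_{k|i}),

    with lambda1 = sqrt(n'(1-f1)/(n-n')) and
    lambda2i = sqrt(m_i' f1 (1-f2i)/(m_i-m_i')).  Defaults n' = floor(n/2),
    m_i' = floor(m_i/2) keep the weights non-negative.
    """
    cfg = cfg or MethodConfig(method="preston")
    rng = _rng_from(cfg, rng)
    _require_srswor(sample, "preston")
    n, N = sample.n, sample.N
    f1 = n / N
    n_prime = cfg.n_prime if cfg.n_prime is not None else n // 2
    if not (1 <= n_prime < n):
        raise ValueError(f"need 1 <= n' < n, got n'={n_prime}")
    if np.any(sample.m < 2):
        raise ValueError("preston needs m_i >= 2 in every sampled psu")
    if cfg.m_prime is not None:
        m_prime = np.full(n, int(cfg.m_prime))
    else:
        m_prime = sample.m // 2
    if np.any((m_prime < 1) | (m_prime >= sample.m)):
        raise ValueError("need 1 <= m_i' < m_i in every psu")
    lam1, lam2 = preston_lambdas(n, f1, n_prime, sample.m, sample.pi2, m_prime)
    base_w = [np.full(int(mi), 1.0 / (a * b)) for mi, a, b in zip(sample.m, sample.pi1, sample.pi2)]

    B = cfg.B
    Y = _rect(sample)
    if Y is not None and len(set(m_prime.tolist())) == 1:
        m, mp = int(sample.m[0]), int(m_prime[0])
        ranks1 = np.argsort(rng.random((B, n)), axis=1)
        delta = np.zeros((B, n))
        np.put_along_axis(delta, ranks1[:, :n_prime], 1.0, axis=1)
        ranks2 = np.argsort(rng.random((B, n, m)), axis=2)
        delta2 = np.zeros((B, n, m))
        np.put_along_axis(delta2, ranks2[..., :mp], 1.0, axis=2)
        adj = (
            1.0
            + lam1 * ((n / n_prime) * delta - 1.0)[..., None]
            + lam2[None, :, None]
            * np.sqrt(n / n_prime)
            * delta[..., None]
            * ((m / mp) * delta2 - 1.0)
        )
        W = adj * np.vstack(base_w)[None, ...]
        Yfull = np.broadcast_to(Y[None, ...], W.shape)
        est = estimator.batch(Yfull.reshape(B, -1), W.reshape(B, -1))
        return ReplicateSet(est, "preston", replicate_weights=W.reshape(B, -1))

    out = np.empty(B)
    Wout = np.empty((B, int(sample.m.sum())))
    yflat = np.concatenate(sample.y)
    for bi in range(B):
        di = np.zeros(n)
        di[rng.choice(n, size=n_prime, replace=False)] = 1.0
        wparts = []
        for i in range(n):
            mi, mpi = int(sample.m[i]), int(m_prime[i])
            dk = np.zeros(mi)
            dk[rng.choice(mi, size=mpi, replace=False)] = 1.0
            adj = (
                1.0
                + lam1 * ((n / n_prime) * di[i] - 1.0)
                + lam2[i] * np.sqrt(n / n_prime) * di[i] * ((mi / mpi) * dk - 1.0)
            )
            wparts.append(adj * base_w[i])
        wrow = np.concatenate(wparts)
        Wout[bi] = wrow
        out[bi] = estimator(yflat, wrow)
    return ReplicateSet(out, "preston", replicate_weights=Wout)


# ---------------------------------------------------------------------------
# Rao-Wu-Yue bootstrap weights
# ---------------------------------------------------------------------------


def rwy(sample, estimator, cfg: MethodConfig | None = None, rng=None) -> ReplicateSet:
    """Rao-Wu-Yue bootstrap weights: SRSWR of n' psus, scale on the weights.

    w_ik* = {1 + sqrt(n'/(n-1)) (n n_i*/n' - 1)} / (pi_i pi_{k|i}) with n_i*
    the psu multiplicities of n' with-replacement draws.  Valid for smooth
    and non-smooth statistics; n' <= n-1 keeps the weights non-negative
    (default n' = n-1).
    """
    cfg = cfg or MethodConfig(method="rwy")
    rng = _rng_from(cfg, rng)
    n = sample.n
    if n < 2:
        raise ValueError("rwy needs n >= 2")
    n_prime = cfg.n_prime if cfg.n_prime is not None else n - 1
    if not (1 <= n_prime <= n - 1):
        raise ValueError(
            f"n'={n_prime} outside (0, n-1]: bootstrap weights could go negative"
        )
    B = cfg.B
    counts = rng.multinomial(n_prime, np.full(n, 1.0 / n), size=B)
    factor = 1.0 + np.sqrt(n_prime / (n - 1.0)) * ((n / n_prime) * counts - 1.0)
    base_w = np.concatenate(
        [np.full(int(mi), 1.0 / (a * b)) for mi, a, b in zip(sample.m, sample.pi1, sample.pi2)]
    )
    psu_of = np.repeat(np.arange(n), sample.m)
    W = factor[:, psu_of] * base_w[None, :]
    yflat = np.concatenate(sample.y)
    if hasattr(estimator, "batch"):
        est = estimator.batch(np.broadcast_to(yflat, W.shape), W)
    else:
        est = np.array([estimator(yflat, wrow) for wrow in W])
    return ReplicateSet(np.asarray(est), "rwy", replicate_weights=W)


# ---------------------------------------------------------------------------
# Chauvet pseudo-population double bootstrap
# ---------------------------------------------------------------------------


def _choice_wor(rng: np.random.Generator, N: int, k: int) -> np.ndarray:
    """Fast SRSWOR indices for small k: rejection first, fallback choice."""
    if k * k < N:
        for _ in range(8):
            pick = rng.integers(0, N, size=k)
            if len(np.unique(pick)) == k:
                return pick
    return rng.choice(N, size=k, replace=False)


def chauvet(sample, estimator, cfg: MethodConfig | None = None, rng=None) -> ReplicateSet:
    """Chauvet pseudo-population bootstrap (outer/inner double loop).

    Each outer iteration rebuilds a pseudo-population: every sampled element
    is duplicated round(1/pi_{k|i}) times within its psu, every psu pair is
    duplicated floor(1/pi_i) times and completed by Poisson sampling with
    probabilities 1/pi_i - floor(1/pi_i).  Inner replicates redraw the
    original first-stage design from the pseudo-population; within each
    selected pseudo-psu the second-stage bootstrap uses SRSWOR from the
    duplicated elements with probability pi_i and the original subsample
    otherwise.  The variance estimate averages the inner replicate variances
    over the outer iterations (use :func:`bootstrap_variance` on the grouped
    result).
    """
    cfg = cfg or MethodConfig(method="chauvet")
    rng = _rng_from(cfg, rng)
    if cfg.A_ppb < 1 or cfg.B_ppb < 2:
        raise ValueError("need A_ppb >= 1 and B_ppb >= 2")
    n = sample.n
    c = np.floor(1.0 / sample.pi1).astype(int)
    frac = 1.0 / sample.pi1 - c

    est = np.empty(cfg.A_ppb * cfg.B_ppb)
    groups = np.repeat(np.arange(cfg.A_ppb), cfg.B_ppb)
    for a in range(cfg.A_ppb):
        # within-psu pseudo-populations: floor(1/pi_{k|i}) copies of every
        # element, completed to the exact cluster size M_i by giving one
        # extra copy to a without-replacement draw of elements (redrawn per
        # outer iteration), so sum_k copies = M_i
        Ui, Mstar = [], np.empty(n, dtype=int)
        for i in range(n):
            mi, Mi = int(sample.m[i]), int(sample.M[i])
            base = Mi // mi
            extra = Mi - base * mi
            counts = np.full(mi, base)
            if extra:
                counts[rng.choice(mi, size=extra, replace=False)] += 1
            Ui.append(np.repeat(sample.y[i], counts))
            Mstar[i] = Mi
        copies = c + (rng.random(n) < frac).astype(int)
        psu_of = np.repeat(np.arange(n), copies)
        Nstar = len(psu_of)
        if Nstar < n:
            raise ValueError("pseudo-population smaller than the bootstrap sample size")
        if sample.design == "ipps":
            sizes = Mstar[psu_of].astype(float)
            pi_b_all = n * sizes / sizes.sum()
            if np.any(pi_b_all > 1):
                raise ValueError("certainty unit in the bootstrap first stage")
        else:
            pi_b_all = np.full(Nstar, n / Nstar)
        for b in range(cfg.B_ppb):
            if sample.design == "ipps":
                sel = ipps_randomized_systematic(Mstar[psu_of].astype(float), n, rng)
            else:
                sel = _choice_wor(rng, Nstar, n)
            vals, wts = [], []
            for copy_idx in sel:
                j = int(psu_of[copy_idx])
                if rng.random() < sample.pi1[j]:
                    pick = _choice_wor(rng, int(Mstar[j]), int(sample.m[j]))
                    vj = Ui[j][pick]
                else:
                    vj = sample.y[j]
                vals.append(vj)
                wts.append(
                    np.full(len(vj), (Mstar[j] / sample.m[j]) / pi_b_all[copy_idx])
                )
            est[a * cfg.B_ppb + b] = estimator(np.concatenate(vals), np.concatenate(wts))
    return ReplicateSet(est, "chauvet", groups=groups)


METHODS = {
    "rao_wu": rao_wu,
    "mirror_match": mirror_match,
    "bwo_sitter": bwo_sitter,
    "bernoulli": bernoulli,
    "preston": preston,
    "rwy": rwy,
    "chauvet": chauvet,
}


def run_method(sample, estimator, cfg: MethodConfig, rng=None) -> ReplicateSet:
    """Dispatch a bootstrap method by its ``cfg.method`` name."""
    try:
        fn = METHODS[cfg.method]
    except KeyError:
        raise ValueError(f"unknown bootstrap method {cfg.method!r}") from None
    return fn(sample, estimator, cfg, rng)


def export_replicate_weights(sample: TwoStageSample, reps: ReplicateSet, path) -> None:
    """Write a bootstrap-weights file: one row per element, w and w_1..w_B."""
    if reps.replicate_weights is None:
        raise ValueError(f"method {reps.method!r} does not produce replicate weights")
    keys = [
        f"{sample.psu_index[i]}:{k}"
        for i in range(sample.n)
        for k in sample.elem_index[i]
    ]
    _, w = sample.flat()
    df = pd.DataFrame({"elem_key": keys, "w": w})
    for b in range(reps.B):
        df[f"w_{b + 1}"] = reps.replicate_weights[b]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
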