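"""Point and analytic variance estimators for two-stage samples.

The Horvitz-Thompson (HT) total weights each sampled element by the inverse
of its overall inclusion probability.  Its design variance admits a general
double-sum estimator requiring joint inclusion probabilities, a textbook
closed form under SRSWOR at both stages, a first-term-only simplification,
and the customary with-replacement approximation.  More general parameters
(mean, distribution function, quantiles) are defined through weighted
estimating equations and solved here; quantiles use the left-continuous
inverse of the weighted CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .designs import TwoStageSample

__all__ = [
    "VarianceEstimate",
    "EstimatingFunction",
    "ef_mean",
    "ef_cdf",
    "ef_quantile",
    "HTTotal",
    "WeightedQuantile",
    "ht_total",
    "var_general",
    "var_srswor_textbook",
    "var_simplified",
    "var_with_replacement",
    "srswor_joint_matrices",
    "weighted_quantile",
    "solve_estimating_equation",
    "linearization_variance_median",
    "t_interval",
]


@dataclass
class VarianceEstimate:
    value: float
    method: str
    degrees_of_freedom: int

    def __float__(self) -> float:
        return float(self.value)

    @property
    def se(self) -> float:
        return float(np.sqrt(max(self.value, 0.0)))


# ---------------------------------------------------------------------------
# point estimators
# ---------------------------------------------------------------------------


class HTTotal:
    """HT total as a weighted-estimator callable: sum_k w_k y_k."""

    smooth = True
    name = "total"

    def __call__(self, y: np.ndarray, w: np.ndarray) -> float:
        return float(np.sum(np.asarray(w) * np.asarray(y)))

    def batch(self, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
        """Row-wise evaluation over (B, L) arrays of values and weights."""
        return (Y * W).sum(axis=1)


class WeightedQuantile:
    """Weighted tau-quantile: smallest y with weighted CDF mass >= tau."""

    smooth = False
    name = "quantile"

    def __init__(self, tau: float = 0.5):
        if not (0.0 < tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        self.tau = tau

    def __call__(self, y: np.ndarray, w: np.ndarray) -> float:
        return weighted_quantile(y, w, self.tau)

    def batch(self, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
        order = np.argsort(Y, axis=1, kind="stable")
        Ys = np.take_along_axis(Y, order, axis=1)
        Ws = np.take_along_axis(W, order, axis=1)
        cw = np.cumsum(Ws, axis=1)
        thresh = self.tau * cw[:, -1]
        idx = (cw >= thresh[:, None]).argmax(axis=1)
        return Ys[np.arange(len(Ys)), idx]


def weighted_quantile(y, w, tau: float) -> float:
    """Left-continuous inverse of the weighted CDF at tau."""
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty sample")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    order = np.argsort(y, kind="stable")
    cw = np.cumsum(w[order])
    total = cw[-1]
    if total <= 0:
        raise ValueError("weights sum to zero")
    idx = int(np.searchsorted(cw, tau * total, side="left"))
    return float(y[order][min(idx, y.size - 1)])


def ht_total(sample: TwoStageSample) -> float:
    """HT estimator of the population total: sum_i t_hat_i / pi_i."""
    return float(np.sum(sample.that / sample.pi1))


# ---------------------------------------------------------------------------
# analytic variance estimators
# ---------------------------------------------------------------------------


def srswor_joint_matrices(sample: TwoStageSample):
    """Delta_ij/pi_ij matrices for SRSWOR at both stages.

    Returns the (n, n) first-stage matrix and a list of (m_i, m_i)
    within-psu matrices, for use with :func:`var_general`.
    """
    def _ratio_matrix(N: int, n: int) -> np.ndarray:
        pi = n / N
        if n == N:
            return np.zeros((n, n))
        pij = n * (n - 1) / (N * (N - 1))
        off = (pij - pi * pi) / pij
        diag = (pi - pi * pi) / pi
        A = np.full((n, n), off)
        np.fill_diagonal(A, diag)
        return A

    first = _ratio_matrix(sample.N, sample.n)
    second = [_ratio_matrix(int(Mi), int(mi)) for Mi, mi in zip(sample.M, sample.m)]
    return first, second


def var_general(
    sample: TwoStageSample,
    delta_over_pi_1: np.ndarray | None,
    delta_over_pi_2: list[np.ndarray] | None = None,
) -> VarianceEstimate:
    """General double-sum variance estimator of the HT total.

    ``delta_over_pi_1[i, j]`` must hold Delta_ij / pi_ij for the selected
    psus, and ``delta_over_pi_2[i]`` the within-psu analogue
    Delta_{kl|i} / pi_{kl|i}.  Raises when joint probabilities are missing.
    """
    if delta_over_pi_1 is None or delta_over_pi_2 is None:
        raise ValueError(
            "joint inclusion probabilities unavailable: design not supported "
            "by the general variance estimator"
        )
    a = sample.that / sample.pi1
    first = float(a @ np.asarray(delta_over_pi_1) @ a)
    second = 0.0
    for i in range(sample.n):
        z = sample.y[i] / sample.pi2[i]
        Vi = float(z @ np.asarray(delta_over_pi_2[i]) @ z)
        second += Vi / sample.pi1[i]
    return VarianceEstimate(first + second, "general", sample.n - 1)


def var_srswor_textbook(sample: TwoStageSample) -> VarianceEstimate:
    """Textbook variance estimator under SRSWOR/SRSWOR.

    N^2 (1 - n/N) s_t^2 / n + (N/n) sum_i M_i^2 (1 - m_i/M_i) s_yi^2 / m_i,
    with s_t^2 the between-psu variance of the t_hat_i and s_yi^2 the
    within-psu element variance.
    """
    n, N = sample.n, sample.N
    if n < 2:
        raise ValueError("s_t^2 undefined for n < 2")
    f1 = n / N
    st2 = float(np.var(sample.that, ddof=1))
    first = N * N * (1.0 - f1) * st2 / n
    second = 0.0
    for Mi, mi, yi in zip(sample.M, sample.m, sample.y):
        f2 = mi / Mi
        if f2 < 1.0:
            if mi < 2:
                raise ValueError("s_yi^2 undefined for m_i < 2 with f2i < 1")
            syi2 = float(np.var(yi, ddof=1))
            second += Mi * Mi * (1.0 - f2) * syi2 / mi
    second *= N / n
    return VarianceEstimate(first + second, "textbook", n - 1)


def var_simplified(
    sample: TwoStageSample, delta_over_pi_1: np.ndarray | None
) -> VarianceEstimate:
    """First-stage double sum only; its bias is always negative."""
    if delta_over_pi_1 is None:
        raise ValueError("joint inclusion probabilities unavailable")
    a = sample.that / sample.pi1
    value = float(a @ np.asarray(delta_over_pi_1) @ a)
    return VarianceEstimate(value, "simplified", sample.n - 1)


def var_with_replacement(sample: TwoStageSample) -> VarianceEstimate:
    """With-replacement variance approximation (PPSWR form).

    (1/(n(n-1))) sum_i (t_hat_i / p_i - t_hat_wr)^2 with
    t_hat_wr = (1/n) sum_i t_hat_i / p_i.
    """
    if np.any(sample.p1 <= 0):
        raise ValueError("single-draw probabilities must be positive")
    n = sample.n
    if n < 2:
        raise ValueError("with-replacement variance undefined for n < 2")
    z = sample.that / sample.p1
    zbar = z.mean()
    value = float(np.sum((z - zbar) ** 2) / (n * (n - 1)))
    return VarianceEstimate(value, "with_replacement", n - 1)


# ---------------------------------------------------------------------------
# estimating equations
# ---------------------------------------------------------------------------


@dataclass
class EstimatingFunction:
    """u(y; theta) defining a parameter through sum_k w_k u(y_k; theta) = 0."""

    u: Callable[[np.ndarray, float], np.ndarray]
    smooth: bool
    tau: float | None = None
    name: str = "custom"


def ef_mean() -> EstimatingFunction:
    return EstimatingFunction(u=lambda y, t: y - t, smooth=True, name="mean")


def ef_cdf(t: float) -> EstimatingFunction:
    return EstimatingFunction(
        u=lambda y, theta: (y <= t).astype(float) - theta, smooth=True, name="cdf"
    )


def ef_quantile(tau: float) -> EstimatingFunction:
    return EstimatingFunction(
        u=lambda y, theta: (y <= theta).astype(float) - tau,
        smooth=False,
        tau=tau,
        name="quantile",
    )


def solve_estimating_equation(sample: TwoStageSample, ef: EstimatingFunction) -> float:
    """Root of the weighted sample estimating equation.

    Smooth u: bisection on an auto-expanded bracket (u is non-increasing in
    theta for the built-ins).  Quantile u: the weighted left-inverse CDF.
    """
    y, w = sample.flat()
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not ef.smooth and ef.tau is not None:
        return weighted_quantile(y, w, ef.tau)

    def g(theta: float) -> float:
        return float(np.sum(w * ef.u(y, theta)))

    lo, hi = float(np.min(y)) - 1.0, float(np.max(y)) + 1.0
    for _ in range(80):
        if g(lo) * g(hi) <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
    else:
        raise ValueError("no sign change found for the estimating function")
    from scipy.optimize import brentq

    return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-10))


def linearization_variance_median(
    sample: TwoStageSample, tau: float = 0.5
) -> VarianceEstimate:
    """Woodruff-type linearization variance for the weighted tau-quantile.

    Applies the design variance estimator to z_ik = I(y_ik <= theta_hat) - tau,
    scales by M0^2, and divides by a squared Gaussian-kernel density estimate
    at theta_hat (Silverman bandwidth on the weighted sample).
    """
    theta = solve_estimating_equation(sample, ef_quantile(tau))
    z = [(yi <= theta).astype(float) - tau for yi in sample.y]
    zsample = TwoStageSample(
        design=sample.design,
        psu_index=sample.psu_index,
        M=sample.M,
        m=sample.m,
        y=z,
        elem_index=sample.elem_index,
        pi1=sample.pi1,
        p1=sample.p1,
        N=sample.N,
        M0=sample.M0,
    )
    if sample.design == "srswor":
        vz = var_srswor_textbook(zsample).value
    else:
        vz = var_with_replacement(zsample).value
    v_u = vz / sample.M0**2

    y, w = sample.flat()
    wsum = w.sum()
    mu = float(np.sum(w * y) / wsum)
    sd = float(np.sqrt(np.sum(w * (y - mu) ** 2) / wsum))
    q75 = weighted_quantile(y, w, 0.75)
    q25 = weighted_quantile(y, w, 0.25)
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError(
            "degenerate density estimate: the sampled y-values have no spread; "
            "the quantile variance cannot be linearized"
        )
    h = 0.9 * spread * y.size ** (-0.2)
    dens = float(np.sum(w * np.exp(-0.5 * ((theta - y) / h) ** 2)) / (wsum * h * np.sqrt(2 * np.pi)))
    if dens <= 0:
        raise ValueError("degenerate density estimate at the quantile")
    return VarianceEstimate(v_u / dens**2, "linearization", sample.n - 1)


def t_interval(theta_hat: float, se: float, df: int, level: float = 0.95):
    """theta_hat +/- t_{(1+level)/2, df} * se; returns (lo, hi)."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if se < 0:
        raise ValueError("se must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    tq = float(stats.t.ppf(0.5 * (1.0 + level), df))
    return (theta_hat - tq * se, theta_hat + tq * se)
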