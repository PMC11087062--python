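"""Sampling primitives and the two-stage sample selector.

First-stage designs: simple random sampling without replacement (SRSWOR) and
randomized systematic inclusion-probability-proportional-to-size sampling
(IPPS).  The second stage is SRSWOR of ``m_i`` elements within each selected
psu, independent across psus.  The selector records every inclusion
probability the estimators need: pi_i, the single-draw probabilities p_i used
by the with-replacement variance formula, and pi_{k|i} = m_i / M_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .population import FinitePopulation

__all__ = [
    "srswor",
    "srswr",
    "poisson_sample",
    "ipps_randomized_systematic",
    "FirstStageDesign",
    "first_stage_design",
    "TwoStageSample",
    "draw_two_stage",
    "write_sample",
    "read_sample",
]


def srswor(N: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly distributed n-subset of {0..N-1} (pi_i = n/N)."""
    if not (1 <= n <= N):
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    return np.sort(rng.choice(N, size=n, replace=False))


def srswr(N: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. uniform draws from {0..N-1}, multiplicities kept."""
    if N < 1 or n < 1:
        raise ValueError("N and n must be >= 1")
    return rng.integers(0, N, size=n)


def poisson_sample(probs: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli inclusions: indices of the selected units."""
    p = np.asarray(probs, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    return np.flatnonzero(rng.random(p.shape) < p)


def ipps_randomized_systematic(
    sizes: Sequence[float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Fixed-size IPPS sample via randomized systematic selection.

    The units are first placed in uniformly random order (this is what makes
    every pair of units jointly selectable), then a systematic pass on the
    cumulated pi_i = n * size_i / sum(sizes) scale with a uniform random start
    picks exactly n units with first-order inclusion probability pi_i.
    """
    x = np.asarray(sizes, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("size measures must be positive")
    N = len(x)
    if not (1 <= n <= N):
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    pi = n * x / x.sum()
    if np.any(pi > 1 + 1e-12):
        bad = int(np.argmax(pi))
        raise ValueError(
            f"unit {bad} has inclusion probability {pi[bad]:.4f} > 1 "
            "(certainty unit; not auto-resolved)"
        )
    perm = rng.permutation(N)
    c = np.cumsum(pi[perm])
    u = rng.uniform(0.0, 1.0)
    points = u + np.arange(n)
    idx = np.searchsorted(c, points, side="left")
    idx = np.minimum(idx, N - 1)  # guard against cumsum round-off at the top
    return np.sort(perm[idx])


@dataclass
class FirstStageDesign:
    """First-stage design spec: kind, n, per-unit pi_i and single-draw p_i."""

    kind: str  # "srswor" | "ipps"
    n: int
    pi: np.ndarray  # (N,) first-order inclusion probabilities, sum == n
    p: np.ndarray  # (N,) single-draw probabilities, sum == 1

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.kind not in ("srswor", "ipps"):
            raise ValueError(f"unknown first-stage design {self.kind!r}")
        if not np.isclose(self.pi.sum(), self.n):
            raise ValueError("first-order inclusion probabilities must sum to n")
        if np.any(self.pi <= 0) or np.any(self.pi > 1 + 1e-12):
            raise ValueError("pi_i must lie in (0, 1]")

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        N = len(self.pi)
        if self.kind == "srswor":
            return srswor(N, self.n, rng)
        return ipps_randomized_systematic(self.p, self.n, rng)


def first_stage_design(kind: str, pop: FinitePopulation, n: int) -> FirstStageDesign:
    """Build the first-stage design for a population.

    For IPPS the size measure is the cluster size M_i, so p_i = M_i / M0 and
    pi_i = n * p_i.
    """
    N = pop.N
    if kind == "srswor":
        pi = np.full(N, n / N)
        p = np.full(N, 1.0 / N)
    elif kind == "ipps":
        p = pop.psu_sizes / pop.M0
        pi = n * p
        if np.any(pi > 1):
            raise ValueError("IPPS certainty unit: some n*M_i/M0 > 1")
    else:
        raise ValueError(f"unknown first-stage design {kind!r}")
    return FirstStageDesign(kind=kind, n=n, pi=pi, p=p)


@dataclass
class TwoStageSample:
    """A realized two-stage sample with all design quantities populated."""

    design: str  # first-stage kind
    psu_index: np.ndarray  # (n,) population indices of selected psus
    M: np.ndarray  # (n,) psu sizes M_i
    m: np.ndarray  # (n,) subsample sizes m_i
    y: list[np.ndarray]  # per-psu sampled values, len m_i each
    elem_index: list[np.ndarray]  # per-psu within-psu element ids
    pi1: np.ndarray  # (n,) first-stage inclusion probs of selected psus
    p1: np.ndarray  # (n,) single-draw probs of selected psus
    N: int
    M0: int

    n: int = field(init=False)
    pi2: np.ndarray = field(init=False)  # (n,) second-stage pi_{k|i} = m_i/M_i
    that: np.ndarray = field(init=False)  # (n,) psu-total estimates t_hat_i

    def __post_init__(self) -> None:
        self.psu_index = np.asarray(self.psu_index, dtype=np.int64)
        self.M = np.asarray(self.M, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        self.pi1 = np.asarray(self.pi1, dtype=np.float64)
        self.p1 = np.asarray(self.p1, dtype=np.float64)
        self.y = [np.asarray(v, dtype=np.float64) for v in self.y]
        self.n = len(self.psu_index)
        if np.any(self.m > self.M) or np.any(self.m < 1):
            raise ValueError("need 1 <= m_i <= M_i for every selected psu")
        for ids in self.elem_index:
            if len(np.unique(ids)) != len(ids):
                raise ValueError("within-psu element ids must be distinct")
        self.pi2 = self.m / self.M
        self.that = np.array([(Mi / mi) * yi.sum() for Mi, mi, yi in zip(self.M, self.m, self.y)])

    @property
    def f1(self) -> float:
        return self.n / self.N

    @property
    def f2(self) -> np.ndarray:
        return self.pi2

    def element_weights(self) -> list[np.ndarray]:
        """Design weights w_k = (pi_i * pi_{k|i})^{-1} per psu."""
        return [np.full(int(mi), 1.0 / (a * b)) for mi, a, b in zip(self.m, self.pi1, self.pi2)]

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All sampled y-values and their design weights, flattened."""
        return np.concatenate(self.y), np.concatenate(self.element_weights())


def draw_two_stage(
    pop: FinitePopulation,
    first: FirstStageDesign,
    m: int | Sequence[int] | Callable[[int], int],
    rng: np.random.Generator,
) -> TwoStageSample:
    """Select a two-stage sample: ``first`` at stage one, SRSWOR at stage two.

    ``m`` may be a constant, a per-psu-index sequence, or a callable
    ``m(M_i) -> m_i``.
    """
    sel = first.draw(rng)
    M = pop.psu_sizes[sel]
    if callable(m):
        m_i = np.array([int(m(int(Mi))) for Mi in M])
    elif np.isscalar(m):
        m_i = np.full(len(sel), int(m))
    else:
        m_i = np.asarray(m, dtype=np.int64)[sel]
    if np.any(m_i > M):
        bad = int(np.argmax(m_i > M))
        raise ValueError(f"m_i={m_i[bad]} exceeds M_i={M[bad]} in psu {sel[bad]}")
    y, ids = [], []
    for j, i in enumerate(sel):
        pick = srswor(int(M[j]), int(m_i[j]), rng)
        ids.append(pick)
        y.append(pop.y[i][pick])
    return TwoStageSample(
        design=first.kind,
        psu_index=sel,
        M=M,
        m=m_i,
        y=y,
        elem_index=ids,
        pi1=first.pi[sel],
        p1=first.p[sel],
        N=pop.N,
        M0=pop.M0,
    )


def write_sample(sample: TwoStageSample, path) -> None:
    """Serialize a realized sample as headered delimited text.

    A single comment line records the design-level constants; the body has
    one row per sampled element with all per-psu design quantities repeated.
    """
    import pandas as pd

    rows = []
    for i in range(sample.n):
        for k, yv in zip(sample.elem_index[i], sample.y[i]):
            rows.append(
                {
                    "psu_id": int(sample.psu_index[i]),
                    "elem_id": int(k),
                    "y": yv,
                    "M_i": int(sample.M[i]),
                    "m_i": int(sample.m[i]),
                    "pi_i": sample.pi1[i],
                    "p_i": sample.p1[i],
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# design={sample.design} N={sample.N} M0={sample.M0}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_sample(path) -> TwoStageSample:
    """Read a sample written by :func:`write_sample`."""
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("sample file missing the design header line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    psu_index, M, m, pi1, p1, y, ids = [], [], [], [], [], [], []
    for pid, grp in df.groupby("psu_id", sort=True):
        psu_index.append(int(pid))
        M.append(int(grp["M_i"].iloc[0]))
        m.append(int(grp["m_i"].iloc[0]))
        pi1.append(float(grp["pi_i"].iloc[0]))
        p1.append(float(grp["p_i"].iloc[0]))
        y.append(grp["y"].to_numpy(dtype=float))
        ids.append(grp["elem_id"].to_numpy(dtype=int))
    return TwoStageSample(
        design=meta["design"],
        psu_index=np.array(psu_index),
        M=np.array(M),
        m=np.array(m),
        y=y,
        elem_index=ids,
        pi1=np.array(pi1),
        p1=np.array(p1),
        N=int(meta["N"]),
        M0=int(meta["M0"]),
    )
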