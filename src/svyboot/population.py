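"""Clustered finite populations and their target parameters.

A population is a set of N primary sampling units (psus, i.e. clusters) of
sizes ``M_1..M_N`` holding the study variable ``y``.  The synthetic generator
draws cluster sizes from a (zero-truncated) Poisson distribution and y-values
from a one-way random-effects model

    y_ij = 10 + x_i + eps_ij,
    x_i ~ N(0, rho/(1-rho)),   eps_ij ~ N(M_i, 1),

so that ``rho`` controls the intraclass correlation of the cluster effect.
Note the element-level errors are centred at the cluster size ``M_i``; a
``mean_zero_errors`` switch recentres them at zero for users who prefer the
classical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FinitePopulation",
    "generate_population",
    "population_total",
    "population_quantile",
    "write_population",
    "read_population",
]


@dataclass
class FinitePopulation:
    """A clustered universe of elements.

    Attributes
    ----------
    psu_sizes : (N,) int array of cluster sizes M_i (all >= 1).
    y : list of N float arrays; ``y[i]`` holds the M_i element values of psu i.
    rho : intraclass parameter used to generate the population (0 if unknown).
    """

    psu_sizes: np.ndarray
    y: list[np.ndarray]
    rho: float = 0.0

    N: int = field(init=False)
    M0: int = field(init=False)
    psu_totals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.psu_sizes = np.asarray(self.psu_sizes, dtype=np.int64)
        if self.psu_sizes.ndim != 1 or len(self.psu_sizes) == 0:
            raise ValueError("psu_sizes must be a non-empty 1-d sequence")
        if np.any(self.psu_sizes < 1):
            raise ValueError("every psu must contain at least one element")
        self.y = [np.asarray(v, dtype=np.float64) for v in self.y]
        if len(self.y) != len(self.psu_sizes):
            raise ValueError("y must hold one value array per psu")
        for i, (m, v) in enumerate(zip(self.psu_sizes, self.y)):
            if len(v) != m:
                raise ValueError(f"psu {i}: len(y[{i}])={len(v)} != M_i={m}")
        self.N = int(len(self.psu_sizes))
        self.M0 = int(self.psu_sizes.sum())
        self.psu_totals = np.array([v.sum() for v in self.y])

    def all_values(self) -> np.ndarray:
        """All M0 element values as one flat array."""
        return np.concatenate(self.y) if self.y else np.empty(0)


def generate_population(
    N: int,
    mean_psu_size: float,
    rho: float,
    seed: int | np.random.SeedSequence,
    *,
    mean_zero_errors: bool = False,
) -> FinitePopulation:
    """Generate a clustered population from the random-effects model.

    Cluster sizes are Poisson(``mean_psu_size``) with zero draws redrawn
    (an empty cluster is meaningless), the cluster effect has variance
    ``rho/(1-rho)`` and element errors are N(M_i, 1) unless
    ``mean_zero_errors`` recentres them.  Deterministic given ``seed``;
    the stream order is sizes, then cluster effects, then errors.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if mean_psu_size <= 0:
        raise ValueError("mean_psu_size must be positive")
    rng = np.random.default_rng(seed)

    sizes = rng.poisson(mean_psu_size, size=N)
    while np.any(sizes == 0):  # zero-truncation by redraw
        zero = sizes == 0
        sizes[zero] = rng.poisson(mean_psu_size, size=int(zero.sum()))
    sizes = sizes.astype(np.int64)

    sd_x = np.sqrt(rho / (1.0 - rho))
    x = rng.normal(0.0, sd_x, size=N) if sd_x > 0 else np.zeros(N)

    y = []
    for i in range(N):
        eps_mean = 0.0 if mean_zero_errors else float(sizes[i])
        eps = rng.normal(eps_mean, 1.0, size=int(sizes[i]))
        y.append(10.0 + x[i] + eps)
    return FinitePopulation(psu_sizes=sizes, y=y, rho=rho)


def population_total(pop: FinitePopulation) -> float:
    """The census total t_y = sum_i sum_k y_ik."""
    return float(pop.psu_totals.sum())


def population_quantile(pop: FinitePopulation, tau: float) -> float:
    """Finite-population tau-quantile: smallest y with CDF mass >= tau.

    Uses the left-continuous inverse of the population CDF; ties are kept
    as data.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    values = np.sort(pop.all_values())
    if values.size == 0:
        raise ValueError("empty population")
    # smallest index with (idx+1)/M0 >= tau
    idx = int(np.ceil(tau * values.size)) - 1
    return float(values[max(idx, 0)])


def write_population(pop: FinitePopulation, path) -> None:
    """Write a population as headered delimited text (psu_id, elem_id, y)."""
    psu_id = np.repeat(np.arange(pop.N), pop.psu_sizes)
    elem_id = np.concatenate([np.arange(m) for m in pop.psu_sizes])
    df = pd.DataFrame({"psu_id": psu_id, "elem_id": elem_id, "y": pop.all_values()})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_population(path, rho: float = 0.0) -> FinitePopulation:
    """Read a population written by :func:`write_population`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("psu_id", "elem_id", "y"):
        if col not in df.columns:
            raise ValueError(f"population file missing column {col!r}")
    y = []
    sizes = []
    for _, grp in df.groupby("psu_id", sort=True):
        grp = grp.sort_values("elem_id")
        y.append(grp["y"].to_numpy(dtype=np.float64))
        sizes.append(len(grp))
    return FinitePopulation(psu_sizes=np.array(sizes), y=y, rho=rho)
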