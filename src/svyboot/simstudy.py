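"""Monte Carlo comparison harness for the variance estimators.

Repeatedly draws two-stage samples from a fixed synthetic population,
computes the HT total and the weighted median together with every requested
variance estimator, and aggregates four metrics per (parameter, method)
cell: percent relative bias of the variance estimator against the Monte
Carlo variance of the point estimator, percent coefficient of variation of
the variance estimator, coverage rate of t-based confidence intervals
(n - 1 degrees of freedom), and their average length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population import FinitePopulation, generate_population, population_total, population_quantile
from .designs import first_stage_design, draw_two_stage
from .estimators import (
    HTTotal,
    WeightedQuantile,
    ht_total,
    linearization_variance_median,
    var_srswor_textbook,
    var_with_replacement,
    weighted_quantile,
)
from .bootstrap import MethodConfig, bootstrap_variance, run_method

__all__ = [
    "SimulationConfig",
    "mc_relative_bias",
    "mc_cv",
    "coverage_and_length",
    "run_cell",
    "run_study",
    "write_tables",
    "ANALYTIC_METHODS",
    "method_menu",
]

ANALYTIC_METHODS = ("textbook", "linearization")
_BOOT_SRSWOR = ("rao_wu", "mirror_match", "bwo_sitter", "bernoulli", "preston", "rwy", "chauvet")
_BOOT_IPPS = ("rwy", "chauvet")


def method_menu(design: str) -> tuple[str, ...]:
    """Variance procedures admissible under a first-stage design."""
    if design == "srswor":
        return ANALYTIC_METHODS + _BOOT_SRSWOR
    if design == "ipps":
        return ANALYTIC_METHODS + _BOOT_IPPS
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def mc_relative_bias(var_estimates: Sequence[float], mc_variance: float) -> float:
    """100 * (mean(var_estimates) - mc_variance) / mc_variance."""
    if mc_variance <= 0:
        raise ValueError("mc_variance must be positive")
    v = np.asarray(var_estimates, dtype=np.float64)
    return float(100.0 * (v.mean() - mc_variance) / mc_variance)


def mc_cv(var_estimates: Sequence[float]) -> float:
    """100 * SD(var_estimates) / mean(var_estimates)."""
    v = np.asarray(var_estimates, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("need at least two estimates")
    mu = v.mean()
    if mu <= 0:
        raise ValueError("mean of the variance estimates must be positive")
    return float(100.0 * np.std(v, ddof=1) / mu)


def coverage_and_length(
    point_estimates, se_estimates, truth: float, df: int, level: float = 0.95
) -> tuple[float, float]:
    """Percent of t-intervals containing the truth, and their mean length."""
    if df < 1:
        raise ValueError("df must be >= 1")
    pts = np.asarray(point_estimates, dtype=np.float64)
    ses = np.asarray(se_estimates, dtype=np.float64)
    if pts.shape != ses.shape:
        raise ValueError("point and se arrays must be aligned")
    tq = float(stats.t.ppf(0.5 * (1.0 + level), df))
    cover = (pts - tq * ses <= truth) & (truth <= pts + tq * ses)
    return float(100.0 * cover.mean()), float(np.mean(2.0 * tq * ses))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Grid and sizes of the Monte Carlo study.

    Defaults are the study conditions: N = 200 psus of mean size 50,
    intraclass parameter rho in {0.1, 0.3}, n in {10, 40} (first-stage
    fractions 5% and 20%), m_i = 5, K = 3000 samples and B = 500 bootstrap
    replicates (A = 10 outer, B = 50 inner for the pseudo-population double
    bootstrap).  ``reduced`` switches to K = 500, B = 200 for quick runs.
    """

    N: int = 200
    mean_psu_size: float = 50.0
    rho: tuple[float, ...] = (0.1, 0.3)
    designs: tuple[str, ...] = ("srswor", "ipps")
    n: tuple[int, ...] = (10, 40)
    m: int = 5
    K: int = 3000
    methods: tuple[str, ...] | None = None  # None = full menu per design
    B: int = 500
    A_ppb: int = 10
    B_ppb: int = 50
    level: float = 0.95
    seed: int = 20220606
    reduced: bool = False
    # The study variable is y_ij = 10 + x_i + eps_ij with eps_ij ~ N(0, 1).
    # (The generator also supports errors centred at the cluster size, but
    # that variant inflates cluster totals quadratically in M_i and is not
    # the model behind the reference results; see docs/methods.md.)
    mean_zero_errors: bool = True

    def __post_init__(self) -> None:
        for key in ("rho", "designs", "n"):
            v = getattr(self, key)
            if not isinstance(v, tuple):
                setattr(self, key, tuple(v) if isinstance(v, (list, set)) else (v,))
        if self.methods is not None and not isinstance(self.methods, tuple):
            self.methods = tuple(self.methods)
        if any(ni >= self.N for ni in self.n):
            raise ValueError("every n must be smaller than N")
        for d in self.designs:
            if d not in ("srswor", "ipps"):
                raise ValueError(f"unknown design {d!r}")
        if self.reduced:
            self.K = min(self.K, 500)
            self.B = min(self.B, 200)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def study_population(cfg: SimulationConfig, rho: float) -> FinitePopulation:
    """The fixed population for one rho, reproducible from the master seed.

    Regenerates (with a perturbed seed) in the vanishingly unlikely event
    that some cluster is smaller than the subsample size m.
    """
    idx = cfg.rho.index(rho) if rho in cfg.rho else -1
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0, max(idx, 0)))
    pop = generate_population(
        cfg.N, cfg.mean_psu_size, rho, ss, mean_zero_errors=cfg.mean_zero_errors
    )
    tries = 0
    while np.any(pop.psu_sizes < cfg.m):
        tries += 1
        ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0, max(idx, 0), tries))
        pop = generate_population(
            cfg.N, cfg.mean_psu_size, rho, ss, mean_zero_errors=cfg.mean_zero_errors
        )
    return pop


# ---------------------------------------------------------------------------
# one simulation cell
# ---------------------------------------------------------------------------

_PARAM_TRUTH = {"total": population_total, "median": lambda p: population_quantile(p, 0.5)}


def _variance_for(sample, method: str, parameter: str, cfg: SimulationConfig, rng) -> float:
    if method == "textbook":
        if parameter == "median":
            raise ValueError("use 'linearization' for the median's analytic row")
        est = var_srswor_textbook(sample) if sample.design == "srswor" else var_with_replacement(sample)
        return est.value
    if method == "linearization":
        if parameter == "total":
            raise ValueError("'linearization' applies to the median")
        return linearization_variance_median(sample).value
    estimator = HTTotal() if parameter == "total" else WeightedQuantile(0.5)
    mc = MethodConfig(method=method, B=cfg.B, A_ppb=cfg.A_ppb, B_ppb=cfg.B_ppb)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", UserWarning)
        reps = run_method(sample, estimator, mc, rng)
    return bootstrap_variance(reps)


def run_cell(
    pop: FinitePopulation,
    design: str,
    n: int,
    m: int,
    tasks: Sequence[tuple[str, str]],
    cfg: SimulationConfig,
    seed_seq: np.random.SeedSequence,
) -> list[dict]:
    """Run K Monte Carlo samples for one (design, n) cell.

    ``tasks`` is a list of (method, parameter) pairs; returns one metrics
    dict per task with keys rb_pct, cv_pct, coverage_pct, avg_length.
    """
    menu = method_menu(design)
    for method, parameter in tasks:
        if method not in menu:
            raise ValueError(f"method {method!r} not available under design {design!r}")
        if parameter not in _PARAM_TRUTH:
            raise ValueError(f"unknown parameter {parameter!r}")
    first = first_stage_design(design, pop, n)
    K = cfg.K
    children = seed_seq.spawn(K)
    points = {"total": np.empty(K), "median": np.empty(K)}
    vhat = {t: np.empty(K) for t in tasks}
    method_idx = {name: i for i, name in enumerate(ANALYTIC_METHODS + _BOOT_SRSWOR)}
    for k in range(K):
        child = children[k]
        rng = np.random.default_rng(child)
        sample = draw_two_stage(pop, first, m, rng)
        points["total"][k] = ht_total(sample)
        y, w = sample.flat()
        points["median"][k] = weighted_quantile(y, w, 0.5)
        for t in tasks:
            # independent stream per (replicate, method, parameter) so cell
            # metrics do not depend on the order methods are evaluated in
            tss = np.random.SeedSequence(
                entropy=child.entropy,
                spawn_key=child.spawn_key
                + (1 + method_idx[t[0]], 0 if t[1] == "total" else 1),
            )
            vhat[t][k] = _variance_for(sample, t[0], t[1], cfg, np.random.default_rng(tss))
    out = []
    for t in tasks:
        method, parameter = t
        truth = _PARAM_TRUTH[parameter](pop)
        pts = points[parameter]
        v_mc = float(np.var(pts, ddof=1))
        ses = np.sqrt(np.maximum(vhat[t], 0.0))
        cov, length = coverage_and_length(pts, ses, truth, n - 1, cfg.level)
        out.append(
            {
                "method": method,
                "parameter": parameter,
                "design": design,
                "n": n,
                "f1": n / pop.N,
                "rho": pop.rho,
                "rb_pct": mc_relative_bias(vhat[t], v_mc),
                "cv_pct": mc_cv(vhat[t]),
                "coverage_pct": cov,
                "avg_length": length,
                "mc_variance": v_mc,
                "mean_vhat": float(vhat[t].mean()),
                "K": K,
            }
        )
    return out


def run_study(cfg: SimulationConfig) -> pd.DataFrame:
    """Full grid: rho x design x n, all admissible (method, parameter) pairs."""
    rows = []
    for ri, rho in enumerate(cfg.rho):
        pop = study_population(cfg, rho)
        for di, design in enumerate(cfg.designs):
            menu = method_menu(design)
            methods = cfg.methods if cfg.methods is not None else menu
            for mth in methods:
                if mth not in menu:
                    raise ValueError(
                        f"method {mth!r} is not admissible under design {design!r}"
                    )
            tasks = []
            for mth in methods:
                if mth == "textbook":
                    tasks.append((mth, "total"))
                elif mth == "linearization":
                    tasks.append((mth, "median"))
                elif mth == "rao_wu":
                    tasks.extend([(mth, "total"), (mth, "median")])
                else:
                    tasks.extend([(mth, "total"), (mth, "median")])
            for ni, n in enumerate(cfg.n):
                ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, ri, di, ni))
                rows.extend(run_cell(pop, design, n, cfg.m, tasks, cfg, ss))
    return pd.DataFrame(rows)


def write_tables(results: pd.DataFrame, out_dir) -> None:
    """One delimited file per metric plus a combined long-format file."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results_long.tsv", sep="\t", index=False)
    for metric in ("rb_pct", "cv_pct", "coverage_pct", "avg_length"):
        cols = ["method", "parameter", "design", "rho", "f1", metric]
        results[cols].rename(columns={metric: "value"}).to_csv(
            out / f"{metric}.tsv", sep="\t", index=False
        )
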