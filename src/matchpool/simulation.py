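"""Monte Carlo study: distributed 1:M matched data and pooled-vs-unpooled fits.

The generator emulates a multi-node matched case-control study nested in
a cohort.  Disease status follows a logistic model with a per-stratum
intercept alpha_i (matching factors absorbed), a per-node intercept
nu_k, a confidential log-normal exposure U, an independent binary
exposure X, a confounder Z1 correlated with log U, and a continuous
effect modifier Z2 interacting with U:

    logit Pr(D=1) = alpha_i + nu_k + beta*U + gamma*X
                    + delta*Z1 + omega*Z2 + vartheta*U*Z2

Each matched set is built by rejection: subjects are drawn from the
covariate model until one case and M controls accrue, emulating
risk-set sampling within a stratum.  Node intercepts are assigned so
baseline prevalence decreases with node size (the smallest node has the
highest baseline prevalence).

The default configuration is the reference study design: 1020 matched
sets over 5 nodes of 120/180/180/240/300 sets, M = 10 controls per
case, (beta, gamma, delta, omega, vartheta) = (0.3, 0.2, 0.15, 0.09,
0.05), alpha_i ~ Normal(-3, 2^2), corr(Z1, log U) = 0.35, X prevalence
0.4, and within-node pool sizes 4, 6 and 10 compared against the
unpooled analysis over 500 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import clogit
from .matched_data import (
    MatchedStratum,
    ModelSpec,
    SubjectRecord,
    interaction,
    main,
)
from .pooling import PoolPolicy, aggregate_pools, plan_pools

__all__ = [
    "PARAM_NAMES",
    "SimulationConfig",
    "AnalysisCells",
    "SimulationSummary",
    "StratumGenerationError",
    "paper_design",
    "study_model_spec",
    "simulate_dataset",
    "run_study",
]

PARAM_NAMES = ("beta", "gamma", "delta", "omega", "vartheta")


class StratumGenerationError(RuntimeError):
    """Rejection sampling failed to assemble a stratum within the cap."""


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters and design sizes for one simulation study."""

    true_params: tuple[float, float, float, float, float] = (0.3, 0.2, 0.15, 0.09, 0.05)
    node_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "node1": 120,
            "node2": 180,
            "node3": 180,
            "node4": 240,
            "node5": 300,
        }
    )
    M: int = 10
    alpha_mean: float = -3.0
    alpha_sd: float = 2.0
    corr_z1_logu: float = 0.35
    x_prevalence: float = 0.4
    n_reps: int = 500
    poolsizes: tuple[int, ...] = (4, 6, 10)
    base_seed: int = 20170907
    max_resamples: int = 200

    def __post_init__(self) -> None:
        if not -1.0 < self.corr_z1_logu < 1.0:
            raise ValueError("correlation must lie in (-1, 1)")
        if not 0.0 < self.x_prevalence < 1.0:
            raise ValueError("x_prevalence must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if len(self.true_params) != len(PARAM_NAMES):
            raise ValueError(f"true_params must have {len(PARAM_NAMES)} entries")

    @property
    def n_strata(self) -> int:
        return sum(self.node_sizes.values())


def paper_design(**overrides) -> SimulationConfig:
    """The reference study configuration; override fields by keyword."""
    return SimulationConfig(**overrides)


def study_model_spec() -> ModelSpec:
    """Terms of the analysis model: U, X, Z1, Z2 and the U x Z2 interaction."""
    return ModelSpec(
        [main("u"), main("x"), main("z1"), main("z2"), interaction("u", "z2")]
    )


# ---------------------------------------------------------------------------
# dataset generation


def _assign_node_intercepts(
    node_sizes: Mapping[str, int], rng: np.random.Generator
) -> dict[str, float]:
    """Standard-normal node intercepts, decreasing with node size."""
    names = list(node_sizes)
    order = sorted(names, key=lambda k: (node_sizes[k], k))  # ascending size
    nus = np.sort(rng.standard_normal(len(names)))[::-1]  # descending value
    return {name: float(nu) for name, nu in zip(order, nus)}


def _draw_subjects(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Covariates (u, x, z1, z2) and linear-predictor offsets for n subjects."""
    rho = config.corr_z1_logu
    logu = rng.standard_normal(n)
    z1 = rho * logu + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    u = np.exp(logu)
    x = (rng.random(n) < config.x_prevalence).astype(float)
    z2 = rng.standard_normal(n)
    b, g, d, w, t = config.true_params
    lp = b * u + g * x + d * z1 + w * z2 + t * u * z2
    return u, x, z1, z2, lp


def _simulate_stratum(
    stratum_id: str,
    node_id: str,
    nu: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> MatchedStratum:
    """Draw subjects under one stratum intercept until 1 case + M controls."""
    M = config.M
    for _ in range(config.max_resamples):
        alpha = rng.normal(config.alpha_mean, config.alpha_sd)
        base = alpha + nu
        # expected draws: ~1/p for the case; batch accordingly, capped
        p0 = float(expit(base))
        batch = int(np.clip((M + 4) / max(p0, 1e-4), M + 8, 20_000))
        case_cov: tuple[float, float, float, float] | None = None
        controls: list[tuple[float, float, float, float]] = []
        drawn = 0
        while drawn < 200_000:
            u, x, z1, z2, lp = _draw_subjects(batch, config, rng)
            d = rng.random(batch) < expit(base + lp)
            for i in range(batch):
                if d[i]:
                    if case_cov is None:
                        case_cov = (u[i], x[i], z1[i], z2[i])
                else:
                    if len(controls) < M:
                        controls.append((u[i], x[i], z1[i], z2[i]))
                if case_cov is not None and len(controls) == M:
                    break
            drawn += batch
            if case_cov is not None and len(controls) == M:
                members = []
                for is_case, cov in ((1, case_cov), *((0, c) for c in controls)):
                    members.append(
                        SubjectRecord(
                            node_id=node_id,
                            stratum_id=stratum_id,
                            is_case=is_case,
                            covariates={
                                "u": cov[0],
                                "x": cov[1],
                                "z1": cov[2],
                                "z2": cov[3],
                            },
                        )
                    )
                return MatchedStratum(
                    stratum_id=stratum_id,
                    node_id=node_id,
                    case=members[0],
                    controls=tuple(members[1:]),
                )
        # pathological intercept (case essentially never occurs at this
        # alpha): resample the stratum intercept and retry
    raise StratumGenerationError(
        f"stratum {stratum_id!r}: no case within draw cap after "
        f"{config.max_resamples} intercept resamples (node {node_id!r}, nu={nu:.3f})"
    )


def simulate_dataset(
    config: SimulationConfig, rep_seed: int | np.random.SeedSequence
) -> list[MatchedStratum]:
    """One replicate: validated matched strata across all nodes."""
    rng = np.random.default_rng(rep_seed)
    nus = _assign_node_intercepts(config.node_sizes, rng)
    strata: list[MatchedStratum] = []
    counter = 0
    for node_id, n_node in config.node_sizes.items():
        for _ in range(n_node):
            counter += 1
            strata.append(
                _simulate_stratum(f"s{counter:05d}", node_id, nus[node_id], config, rng)
            )
    return strata


# ---------------------------------------------------------------------------
# study runner


@dataclass(frozen=True)
class AnalysisCells:
    """Replicate-level results of one analysis (unpooled or one pool size)."""

    label: str
    estimates: np.ndarray  # (n_converged, 5)
    model_ses: np.ndarray  # (n_converged, 5)
    covered: np.ndarray  # (n_converged, 5) bool, truth inside the 95% Wald CI
    n_converged: int

    @property
    def mean_estimate(self) -> np.ndarray:
        if self.n_converged == 0:
            return np.full(len(PARAM_NAMES), np.nan)
        return self.estimates.mean(axis=0)

    @property
    def emp_se(self) -> np.ndarray:
        # the SD over replicates needs at least two of them
        if self.n_converged < 2:
            return np.full(len(PARAM_NAMES), np.nan)
        return self.estimates.std(axis=0, ddof=1)

    @property
    def model_se(self) -> np.ndarray:
        if self.n_converged == 0:
            return np.full(len(PARAM_NAMES), np.nan)
        return self.model_ses.mean(axis=0)

    @property
    def coverage(self) -> np.ndarray:
        if self.n_converged == 0:
            return np.full(len(PARAM_NAMES), np.nan)
        return self.covered.mean(axis=0)


@dataclass(frozen=True)
class SimulationSummary:
    config: SimulationConfig
    analyses: tuple[AnalysisCells, ...]

    def cells(self, label: str) -> AnalysisCells:
        for a in self.analyses:
            if a.label == label:
                return a
        raise KeyError(label)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: (parameter x statistic) rows, one column per analysis."""
        rows = []
        for pname, truth in zip(PARAM_NAMES, self.config.true_params):
            i = PARAM_NAMES.index(pname)
            for stat in ("Estimate", "EmpSE", "ModelSE", "Coverage"):
                row: dict[str, object] = {
                    "parameter": pname,
                    "truth": truth,
                    "statistic": stat,
                }
                for a in self.analyses:
                    v = {
                        "Estimate": a.mean_estimate,
                        "EmpSE": a.emp_se,
                        "ModelSE": a.model_se,
                        "Coverage": a.coverage,
                    }[stat][i]
                    row[a.label] = v
                rows.append(row)
        return pd.DataFrame(rows)


def _fit_once(cl_strata, truth: np.ndarray):
    """(estimates, SEs, coverage flags) or None when not converged."""
    try:
        res = clogit.fit(cl_strata, term_names=PARAM_NAMES)
    except clogit.NonIdentifiableError:
        return None
    if not res.converged:
        return None
    ci = clogit.wald_ci(res, 0.95)
    covered = (ci[:, 0] <= truth) & (truth <= ci[:, 1])
    return res.estimates, res.standard_errors, covered


def run_study(config: SimulationConfig) -> SimulationSummary:
    """Replicated comparison of unpooled vs within-node pooled analyses.

    Per replicate: simulate a dataset, fit the individual-level model,
    then for each pool size plan within-node pools (single pool size,
    leftovers excluded), aggregate, and fit the pooled model.  Replicates
    where a fit fails to converge are dropped from that analysis's cells
    and reflected in ``n_converged``.
    """
    spec = study_model_spec()
    truth = np.asarray(config.true_params)
    labels = ["unpooled"] + [f"g={g}" for g in config.poolsizes]
    acc: dict[str, list] = {lab: [] for lab in labels}

    root = np.random.SeedSequence(config.base_seed)
    rep_seeds = root.spawn(config.n_reps)
    for rep, rep_ss in enumerate(rep_seeds):
        data_ss, pool_ss = rep_ss.spawn(2)
        strata = simulate_dataset(config, data_ss)
        out = _fit_once(clogit.strata_from_matched(strata, spec), truth)
        if out is not None:
            acc["unpooled"].append(out)
        for g, g_ss in zip(config.poolsizes, pool_ss.spawn(len(config.poolsizes))):
            seed = int(g_ss.generate_state(1)[0] & 0x7FFFFFFF)
            policy = PoolPolicy(mode="single_g_exclude", g=g, seed=seed)
            plan = plan_pools(strata, policy)
            pooled = aggregate_pools(strata, plan, spec)
            out = _fit_once(clogit.strata_from_pooled(pooled), truth)
            if out is not None:
                acc[f"g={g}"].append(out)

    analyses = []
    for lab in labels:
        rows = acc[lab]
        p = len(PARAM_NAMES)
        est = np.array([r[0] for r in rows]).reshape(-1, p)
        ses = np.array([r[1] for r in rows]).reshape(-1, p)
        cov = np.array([r[2] for r in rows]).reshape(-1, p).astype(bool)
        analyses.append(
            AnalysisCells(
                label=lab,
                estimates=est,
                model_ses=ses,
                covered=cov,
                n_converged=len(rows),
            )
        )
    return SimulationSummary(config=config, analyses=tuple(analyses))
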