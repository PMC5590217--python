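"""Within-node, outcome-stratified pool planning and covariate aggregation.

Each data-holding node partitions its matched strata into pools of size
``g`` and releases, per pool, only the summed case design row and the M
position-wise summed control design rows.  The resulting pooled strata
feed the same conditional logistic likelihood as individual-level data;
because interaction and transform columns are evaluated per subject
before summation, pooled models with effect modifiers remain valid.

Three planning modes are provided:

``single_g_exclude``
    one pool size per node; within each node the ``n mod g`` leftover
    strata are excluded (randomly, via the seeded permutation tail).
``mixed_g``
    two pool sizes ``g`` and ``g_alt``; each node's count is decomposed
    as ``a*g + b*g_alt`` to minimize exclusions.
``cross_node``
    pools may span nodes.  This reproduces unstratified pooling for
    comparison only; it would require secure summation in practice and
    the plan is flagged non-private.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matched_data import (
    MatchedStratum,
    ModelSpec,
    build_design_row,
)

__all__ = [
    "PoolPolicy",
    "Pool",
    "PoolPlan",
    "PooledStratum",
    "PrivacyFinding",
    "PrivacyAuditReport",
    "plan_pools",
    "aggregate_pools",
    "privacy_audit",
]

MODES = ("single_g_exclude", "mixed_g", "cross_node")


@dataclass(frozen=True)
class PoolPolicy:
    """How strata are grouped into pools.

    ``g`` is the primary pool size; ``g_alt`` a secondary size used only
    by ``mixed_g``.  ``seed`` drives the within-node permutation and the
    within-stratum control shuffle, making plans reproducible.
    """

    mode: str = "single_g_exclude"
    g: int = 2
    g_alt: int | None = None
    seed: int = 0
    shuffle_controls: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.g < 1:
            raise ValueError("pool size g must be >= 1")
        if self.g_alt is not None:
            if self.g_alt < 1:
                raise ValueError("g_alt must be >= 1")
            if self.g_alt == self.g:
                raise ValueError("g_alt must differ from g")
        if self.mode == "mixed_g" and self.g_alt is None:
            raise ValueError("mixed_g mode requires g_alt")


@dataclass(frozen=True)
class Pool:
    pool_id: str
    node_id: str  # "*" for cross-node pools
    member_stratum_ids: tuple[str, ...]

    @property
    def g(self) -> int:
        return len(self.member_stratum_ids)


@dataclass(frozen=True)
class PoolPlan:
    pools: tuple[Pool, ...]
    excluded_strata: tuple[str, ...]
    policy: PoolPolicy
    non_private: bool = False

    @property
    def n_pools(self) -> int:
        return len(self.pools)


@dataclass(frozen=True)
class PooledStratum:
    """Aggregate design rows of one pool: one 'case' row, M 'control' rows.

    ``case_aggregate[t]`` is the sum of term t over the pool's g cases;
    ``control_aggregates[j][t]`` the sum over the g position-(j+1)
    controls.  Structurally identical to an individual matched stratum,
    so it drops into the conditional logistic likelihood unchanged.
    """

    pool_id: str
    node_id: str
    g: int
    case_aggregate: np.ndarray
    control_aggregates: tuple[np.ndarray, ...]

    @property
    def m(self) -> int:
        return len(self.control_aggregates)


def _mixed_decomposition(n: int, g: int, g_alt: int) -> tuple[int, int]:
    """Counts (a, b) with a*g + b*g_alt <= n maximizing coverage, then a."""
    best = (0, 0)
    best_cov = -1
    for a in range(n // g, -1, -1):
        b = (n - a * g) // g_alt
        cov = a * g + b * g_alt
        if cov > best_cov:
            best_cov = cov
            best = (a, b)
    return best


def plan_pools(strata: Sequence[MatchedStratum], policy: PoolPolicy) -> PoolPlan:
    """Randomly partition strata into pools according to ``policy``.

    Within each node (or globally for ``cross_node``) the strata are
    permuted with a seeded generator and sliced into consecutive pools;
    leftover strata at the tail of the permutation are excluded.
    """
    rng = np.random.default_rng(policy.seed)
    pools: list[Pool] = []
    excluded: list[str] = []

    if policy.mode == "cross_node":
        ids = [s.stratum_id for s in strata]
        perm = [ids[i] for i in rng.permutation(len(ids))]
        n_pools = len(perm) // policy.g
        for k in range(n_pools):
            members = tuple(perm[k * policy.g : (k + 1) * policy.g])
            pools.append(Pool(pool_id=f"pool{k + 1}", node_id="*", member_stratum_ids=members))
        excluded.extend(perm[n_pools * policy.g :])
        return PoolPlan(tuple(pools), tuple(excluded), policy, non_private=True)

    # group by node, preserving first-seen node order
    by_node: dict[str, list[str]] = {}
    for s in strata:
        by_node.setdefault(s.node_id, []).append(s.stratum_id)

    counter = 0
    for node_id, ids in by_node.items():
        # g=1 partitions into singletons whatever the permutation; keep
        # input order so that g=1 pooling is an exact identity
        if policy.g == 1 and policy.mode == "single_g_exclude":
            perm = list(ids)
        else:
            perm = [ids[i] for i in rng.permutation(len(ids))]
        n = len(perm)
        if policy.mode == "single_g_exclude":
            sizes = [policy.g] * (n // policy.g)
            if policy.g > n:
                import warnings

                warnings.warn(
                    f"pool size g={policy.g} exceeds node {node_id!r} size {n}; "
                    "node fully excluded",
                    stacklevel=2,
                )
        else:  # mixed_g
            a, b = _mixed_decomposition(n, policy.g, policy.g_alt)
            sizes = [policy.g] * a + [policy.g_alt] * b
        pos = 0
        for size in sizes:
            counter += 1
            members = tuple(perm[pos : pos + size])
            pools.append(Pool(pool_id=f"pool{counter}", node_id=node_id, member_stratum_ids=members))
            pos += size
        excluded.extend(perm[pos:])

    return PoolPlan(tuple(pools), tuple(excluded), policy)


def aggregate_pools(
    strata: Sequence[MatchedStratum],
    plan: PoolPlan,
    spec: ModelSpec,
) -> list[PooledStratum]:
    """Sum design rows within each planned pool.

    The case aggregate sums the member cases' design rows; the j-th
    control aggregate sums the member strata's position-j controls.
    Controls within each stratum are exchangeable given matching, so by
    default their positions are shuffled once (seeded from the plan's
    policy seed) before position-wise summation; pools of size 1 keep
    the stored order so that g=1 pooling is an exact identity.
    """
    by_id = {s.stratum_id: s for s in strata}
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence([plan.policy.seed, 0x5D]).generate_state(1)
    )

    out: list[PooledStratum] = []
    for pool in plan.pools:
        case_agg: np.ndarray | None = None
        ctrl_aggs: list[np.ndarray] | None = None
        for sid in pool.member_stratum_ids:
            try:
                s = by_id[sid]
            except KeyError:
                raise ValueError(f"plan references unknown stratum {sid!r}") from None
            controls = list(s.controls)
            if plan.policy.shuffle_controls and pool.g > 1:
                controls = [controls[i] for i in shuffle_rng.permutation(len(controls))]
            case_row = build_design_row(s.case, spec)
            ctrl_rows = [build_design_row(c, spec) for c in controls]
            if case_agg is None:
                case_agg = case_row
                ctrl_aggs = ctrl_rows
            else:
                if len(ctrl_rows) != len(ctrl_aggs):
                    raise ValueError(
                        f"stratum {sid!r} has {len(ctrl_rows)} controls; pool "
                        f"{pool.pool_id!r} expects {len(ctrl_aggs)}"
                    )
                case_agg = case_agg + case_row
                ctrl_aggs = [a + r for a, r in zip(ctrl_aggs, ctrl_rows)]
        out.append(
            PooledStratum(
                pool_id=pool.pool_id,
                node_id=pool.node_id,
                g=pool.g,
                case_aggregate=case_agg,
                control_aggregates=tuple(ctrl_aggs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# disclosure audit


@dataclass(frozen=True)
class PrivacyFinding:
    """One fully disclosive aggregate: a binary term summing to 0 or g."""

    pool_id: str
    node_id: str
    role: str  # "case" or "control"
    position: int  # 0 for case, 1..M for controls
    term: str
    aggregate: float
    g: int


@dataclass(frozen=True)
class PrivacyAuditReport:
    findings: tuple[PrivacyFinding, ...]
    counts_per_node: dict[str, int] = field(default_factory=dict)

    @property
    def n_findings(self) -> int:
        return len(self.findings)


def privacy_audit(
    pooled: Iterable[PooledStratum],
    spec: ModelSpec,
    binary_terms: set[int],
) -> PrivacyAuditReport:
    """Flag aggregates that reveal every member's value of a binary term.

    A 0/1-coded term whose pool aggregate equals 0 or g discloses that
    all g members share the same value -- the degenerate case that makes
    small pools of all-binary covariates unsafe.  Aggregates strictly
    between 0 and g stay ambiguous and are not flagged.
    """
    names = spec.term_names
    findings: list[PrivacyFinding] = []
    counts: dict[str, int] = {}
    for ps in pooled:
        rows = [("case", 0, ps.case_aggregate)] + [
            ("control", j + 1, agg) for j, agg in enumerate(ps.control_aggregates)
        ]
        for role, position, agg in rows:
            for t in binary_terms:
                v = float(agg[t])
                if v == 0.0 or v == float(ps.g):
                    findings.append(
                        PrivacyFinding(
                            pool_id=ps.pool_id,
                            node_id=ps.node_id,
                            role=role,
                            position=position,
                            term=names[t],
                            aggregate=v,
                            g=ps.g,
                        )
                    )
                    counts[ps.node_id] = counts.get(ps.node_id, 0) + 1
    return PrivacyAuditReport(tuple(findings), counts)
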