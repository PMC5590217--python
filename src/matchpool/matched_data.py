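"""Data model for distributed matched case-control datasets.

A dataset is a flat list of subject records, each tagged with the node
(data-holding site) and matched stratum it belongs to.  Every stratum
contains exactly one case and a fixed number ``M`` of matched controls
(a 1:M matched design).  Model terms -- main effects, elementwise
transforms and pairwise interactions -- are evaluated *per subject* to
produce design rows; this per-subject evaluation order is what makes
downstream aggregation of interaction terms valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SubjectRecord",
    "MatchedStratum",
    "TermDef",
    "main",
    "transform",
    "interaction",
    "ModelSpec",
    "DesignConfig",
    "MalformedStratumError",
    "InconsistentDesignError",
    "MissingDataError",
    "validate_dataset",
    "build_design_row",
    "design_matrix",
]


# ---------------------------------------------------------------------------
# errors


class MalformedStratumError(ValueError):
    """A stratum does not contain exactly one case."""


class InconsistentDesignError(ValueError):
    """The number of controls per case varies across strata."""


class MissingDataError(ValueError):
    """A subject lacks a covariate value present elsewhere in the dataset."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: site, matched stratum, outcome and covariates.

    ``is_case`` must be 0 or 1; binary covariates are coded 0/1 by
    convention (the privacy audit relies on this coding).
    """

    node_id: str
    stratum_id: str
    is_case: int
    covariates: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.is_case not in (0, 1):
            raise ValueError(f"is_case must be 0 or 1, got {self.is_case!r}")


@dataclass(frozen=True)
class MatchedStratum:
    """One case plus its M matched controls, all from the same node.

    Control order is the input-file order; position-wise pooling
    consumes these positions 1..M.
    """

    stratum_id: str
    node_id: str
    case: SubjectRecord
    controls: tuple[SubjectRecord, ...]

    @property
    def m(self) -> int:
        return len(self.controls)

    def members(self) -> list[SubjectRecord]:
        return [self.case, *self.controls]


# --- model terms -----------------------------------------------------------

_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "log": math.log,
    "square": lambda x: x * x,
}


@dataclass(frozen=True)
class TermDef:
    """One column of the linear predictor.

    kind ``main``      -> the covariate itself
    kind ``transform`` -> f(covariate), f in {log, square} or a custom callable
    kind ``interaction`` -> product of two covariates, computed per subject
    """

    kind: str
    name: str
    name_b: str | None = None
    function: str | None = None
    custom: Callable[[float], float] | None = field(default=None, compare=False)

    @property
    def label(self) -> str:
        if self.kind == "main":
            return self.name
        if self.kind == "transform":
            return f"{self.function}({self.name})"
        return f"{self.name}:{self.name_b}"

    def evaluate(self, cov: Mapping[str, float]) -> float:
        try:
            x = cov[self.name]
        except KeyError:
            raise MissingDataError(f"covariate {self.name!r} absent") from None
        if self.kind == "main":
            return float(x)
        if self.kind == "transform":
            if self.function == "log" and x <= 0:
                raise ValueError(
                    f"log transform of non-positive value {x!r} for {self.name!r}"
                )
            f = self.custom if self.function == "custom" else _TRANSFORMS[self.function]
            return float(f(x))
        # interaction: per-subject product -- never a product of sums
        try:
            y = cov[self.name_b]
        except KeyError:
            raise MissingDataError(f"covariate {self.name_b!r} absent") from None
        return float(x) * float(y)


def main(name: str) -> TermDef:
    return TermDef(kind="main", name=name)


def transform(name: str, function: str, custom: Callable[[float], float] | None = None) -> TermDef:
    if function not in ("log", "square", "custom"):
        raise ValueError(f"unknown transform {function!r}")
    if function == "custom" and custom is None:
        raise ValueError("custom transform requires a callable")
    return TermDef(kind="transform", name=name, function=function, custom=custom)


def interaction(name_a: str, name_b: str) -> TermDef:
    return TermDef(kind="interaction", name=name_a, name_b=name_b)


@dataclass(frozen=True)
class ModelSpec:
    """Ordered list of terms defining the linear predictor."""

    terms: tuple[TermDef, ...]

    def __init__(self, terms: Sequence[TermDef]):
        terms = tuple(terms)
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate terms in model specification")
        object.__setattr__(self, "terms", terms)

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def term_names(self) -> list[str]:
        return [t.label for t in self.terms]

    def referenced_covariates(self) -> set[str]:
        names: set[str] = set()
        for t in self.terms:
            names.add(t.name)
            if t.name_b is not None:
                names.add(t.name_b)
        return names

    @staticmethod
    def parse(text: str | Sequence[str]) -> "ModelSpec":
        """Parse a compact term syntax: ``u``, ``log(u)``, ``square(u)``, ``u:z2``.

        Accepts a comma-separated string or a sequence of term strings.
        """
        if isinstance(text, str):
            parts = [p.strip() for p in text.split(",") if p.strip()]
        else:
            parts = [p.strip() for p in text]
        terms = []
        for p in parts:
            if ":" in p:
                a, b = p.split(":", 1)
                terms.append(interaction(a.strip(), b.strip()))
            elif p.endswith(")") and "(" in p:
                fn, arg = p[:-1].split("(", 1)
                terms.append(transform(arg.strip(), fn.strip()))
            else:
                terms.append(main(p))
        return ModelSpec(terms)


@dataclass(frozen=True)
class DesignConfig:
    """Controls per case and the per-node stratum counts of a study design."""

    M: int
    node_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if any(n < 0 for n in self.node_sizes.values()):
            raise ValueError("node sizes must be non-negative")

    @property
    def n_strata(self) -> int:
        return sum(self.node_sizes.values())


# ---------------------------------------------------------------------------
# operations


def validate_dataset(records: Iterable[SubjectRecord]) -> list[MatchedStratum]:
    """Group subject records into validated matched strata.

    Records are grouped by ``stratum_id``; each group must hold exactly
    one case, all groups must share the same number of controls M, and
    every record must carry the same covariate names.  Control order
    within a stratum is the input order.
    """
    records = list(records)
    if not records:
        raise ValueError("empty dataset")

    key_set = frozenset(records[0].covariates)
    for r in records:
        if frozenset(r.covariates) != key_set:
            missing = key_set.symmetric_difference(r.covariates)
            raise MissingDataError(
                f"subject in stratum {r.stratum_id!r} has mismatched covariates: "
                f"{sorted(missing)}"
            )

    groups: dict[str, list[SubjectRecord]] = {}
    for r in records:
        groups.setdefault(r.stratum_id, []).append(r)

    strata: list[MatchedStratum] = []
    m_common: int | None = None
    for sid, members in groups.items():
        cases = [r for r in members if r.is_case == 1]
        controls = [r for r in members if r.is_case == 0]
        if len(cases) != 1:
            raise MalformedStratumError(
                f"stratum {sid!r} has {len(cases)} cases (expected exactly 1)"
            )
        if not controls:
            raise MalformedStratumError(f"stratum {sid!r} has no controls")
        node_ids = {r.node_id for r in members}
        if len(node_ids) != 1:
            raise MalformedStratumError(
                f"stratum {sid!r} spans nodes {sorted(node_ids)}"
            )
        if m_common is None:
            m_common = len(controls)
        elif len(controls) != m_common:
            raise InconsistentDesignError(
                f"stratum {sid!r} has {len(controls)} controls, others have {m_common}"
            )
        strata.append(
            MatchedStratum(
                stratum_id=sid,
                node_id=cases[0].node_id,
                case=cases[0],
                controls=tuple(controls),
            )
        )
    return strata


def build_design_row(subject: SubjectRecord, spec: ModelSpec) -> np.ndarray:
    """Evaluate the model terms for one subject.

    Interaction and transform columns are computed from this subject's
    own covariates before any aggregation, which is what makes pooled
    interaction terms sums of per-subject products.
    """
    return np.array([t.evaluate(subject.covariates) for t in spec.terms], dtype=float)


def design_matrix(strata: Sequence[MatchedStratum], spec: ModelSpec) -> np.ndarray:
    """Stacked design rows, shape (n_strata, M+1, p); index 0 is the case."""
    if not strata:
        raise ValueError("no strata")
    m = strata[0].m
    out = np.empty((len(strata), m + 1, spec.p), dtype=float)
    for i, s in enumerate(strata):
        if s.m != m:
            raise InconsistentDesignError("strata differ in number of controls")
        out[i, 0] = build_design_row(s.case, spec)
        for j, c in enumerate(s.controls, start=1):
            out[i, j] = build_design_row(c, spec)
    return out
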