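import numpy as np
import pytest

from matchpool import (
    MatchedStratum,
    ModelSpec,
    SubjectRecord,
    interaction,
    main,
)


def make_subject(node, stratum, is_case, **cov):
    return SubjectRecord(node_id=node, stratum_id=stratum, is_case=is_case, covariates=cov)


def make_stratum(node, sid, case_cov, control_covs):
    """Build one matched stratum from covariate dicts."""
    case = make_subject(node, sid, 1, **case_cov)
    controls = tuple(make_subject(node, sid, 0, **c) for c in control_covs)
    return MatchedStratum(stratum_id=sid, node_id=node, case=case, controls=controls)


def random_strata(rng, n_strata=20, m=2, p=2, node="n1", prefix="s"):
    """Random matched strata with covariates c0..c(p-1) ~ N(0,1)."""
    names = [f"c{i}" for i in range(p)]
    out = []
    for i in range(n_strata):
        case = {k: rng.normal() for k in names}
        ctrls = [{k: rng.normal() for k in names} for _ in range(m)]
        out.append(make_stratum(node, f"{prefix}{i}", case, ctrls))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def toy_nodes_433():
    """Three nodes holding 4, 3 and 3 matched sets (1:3 matching)."""
    rng = np.random.default_rng(7)
    strata = []
    k = 0
    for node, n in (("node1", 4), ("node2", 3), ("node3", 3)):
        for _ in range(n):
            k += 1
            strata.append(
                make_stratum(
                    node,
                    f"s{k}",
                    {"u": rng.normal(), "x": float(rng.integers(2))},
                    [{"u": rng.normal(), "x": float(rng.integers(2))} for _ in range(3)],
                )
            )
    return strata


@pytest.fixture
def spec_u():
    return ModelSpec([main("u")])


@pytest.fixture
def spec_ux():
    return ModelSpec([main("u"), main("x")])


@pytest.fixture
def spec_uz2_inter():
    return ModelSpec([main("u"), main("z2"), interaction("u", "z2")])
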