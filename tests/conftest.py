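import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_spec(rng, J, M, sojourn_family="gamma", emission_family="norm"):
    """Random valid HSMM specification for oracle-based tests."""
    from hsmmseg import EmissionModel, HSMMSpec, SojournModel

    if sojourn_family == "nonparametric":
        params = []
        for _ in range(J):
            d = rng.random(M) + 0.05
            params.append({"d": d / d.sum()})
    elif sojourn_family == "gamma":
        params = [
            {"shape": rng.uniform(0.5, 5.0), "scale": rng.uniform(0.3, 3.0)} for _ in range(J)
        ]
    elif sojourn_family == "poisson":
        params = [{"rate": rng.uniform(0.0, 4.0)} for _ in range(J)]
    elif sojourn_family == "geometric":
        params = [{"p": rng.uniform(0.1, 0.9)} for _ in range(J)]
    else:
        params = [
            {"size": rng.uniform(0.5, 5.0), "prob": rng.uniform(0.2, 0.8)} for _ in range(J)
        ]
    sojourn = SojournModel(sojourn_family, M, params)
    if emission_family == "norm":
        em = EmissionModel(
            "norm", 1, [{"mean": rng.normal(0, 2), "sd": rng.uniform(0.5, 2)} for _ in range(J)]
        )
    else:
        em = EmissionModel("pois", 1, [{"rate": rng.uniform(0.5, 8)} for _ in range(J)])
    pi = rng.dirichlet(np.ones(J))
    A = np.zeros((J, J))
    for i in range(J):
        if J > 1:
            off = rng.dirichlet(np.ones(J - 1))
            A[i, [k for k in range(J) if k != i]] = off
    return HSMMSpec(J, pi, A, em, sojourn, M)
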