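import numpy as np
import pytest

from otbiomon import GeneratorConfig, generate_surveys, load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    """Tidy three-epoch site index table packaged with the library."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def synthetic_surveys():
    return generate_surveys(GeneratorConfig(seed=11, n_sites=12))


# ---------------------------------------------------------------------------
# Independent oracles. These deliberately avoid the library's own code paths:
# the exceedance probability is computed by numerical quadrature over scipy
# frozen distributions, the Wilcoxon p by full enumeration of sign patterns,
# and the Holm flags by a literal transcription of the step-down rule.
# ---------------------------------------------------------------------------

def scipy_dist(family: str, params: dict):
    from scipy import stats

    if family == "log_logistic":
        return stats.fisk(c=params["beta"], scale=params["alpha"])
    if family == "pareto":
        return stats.pareto(b=params["a"], scale=params["x_m"])
    raise ValueError(family)


def exceedance_probability_quadrature(mtc_family, mtc_params, pnetc_family, pnetc_params):
    """P(MTC/PNETC >= 1) for independent draws, by 1-D quadrature.

    Substituting u = F_PNETC(y) gives the bounded, well-scaled integral
    P = ∫₀¹ S_MTC(F_PNETC⁻¹(u)) du.
    """
    from scipy import integrate

    mtc = scipy_dist(mtc_family, mtc_params)
    pnetc = scipy_dist(pnetc_family, pnetc_params)

    def integrand(u):
        return mtc.sf(pnetc.ppf(u))

    value, err = integrate.quad(integrand, 0.0, 1.0, limit=400)
    assert err < 1e-8
    return value


def exact_wilcoxon_p(x, y):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns of the
    observed |differences| (midranks, zeros dropped)."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(y, float) - np.asarray(x, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    stat_obs = abs(w_obs - mu)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= stat_obs - 1e-12:
            count += 1
    return count / 2**n


def brute_force_holm(p_values, alpha=0.05):
    """Step-down rule, literally: sort ascending, p_(i) is significant iff
    p_(j) <= alpha / (m - j + 1) for every j <= i (stop at first failure)."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):  # i is 0-based, rule's j = i + 1
        if p[idx] <= alpha / (m - i):
            flags[idx] = True
        else:
            break
    return flags
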