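import numpy as np
import pytest

from minibloom import ecomodel as em
from minibloom import io_cli


@pytest.fixture(scope="session")
def table1():
    return io_cli.load_table1()


@pytest.fixture(scope="session")
def default_traits():
    return em.default_traits()


@pytest.fixture(scope="session")
def factorial_results(default_traits):
    """The four 40-day factorial runs (nutrient × control), shared across
    the suite since each takes a couple of seconds."""
    out = {}
    for nc in ("HCNC", "LCNC"):
        for cc in ("LCC", "HCC"):
            ex = em.ExperimentSpec(nutrient_condition=nc, control_condition=cc)
            out[(nc, cc)] = em.run(ex, traits=default_traits)
    return out


@pytest.fixture(scope="session")
def mortality_sweep(default_traits, factorial_results):
    """Final R-vs-C2 biomass margin as a function of the R mortality rate
    under the high-nutrient condition, endpoints reused from the factorial
    runs."""
    margins = {}
    names = default_traits.names
    i_r, i_c2 = names.index("R"), names.index("C2")

    def margin(res):
        row = res.biomass_C[-1]
        return float(row[i_r] - row[i_c2])

    margins[0.10] = margin(factorial_results[("HCNC", "LCC")])
    margins[0.25] = margin(factorial_results[("HCNC", "HCC")])
    for r in (0.15, 0.20):
        ex = em.ExperimentSpec(nutrient_condition="HCNC", r_mortality_override=r)
        margins[r] = margin(em.run(ex, traits=default_traits))
    return margins


def _random_strategist(rng, name, strategy, uses_silicon):
    qmin_n = rng.uniform(0.02, 0.08)
    qmin_p = rng.uniform(0.001, 0.004)
    qmin_si = rng.uniform(0.02, 0.08)
    kwargs = {}
    if uses_silicon:
        kwargs = dict(K_Si=rng.uniform(0.2, 3.0), Qmin_Si=qmin_si,
                      Qmax_Si=qmin_si * rng.uniform(1.5, 4.0))
    return em.StrategistTraits(
        name=name, strategy=strategy, uses_silicon=uses_silicon,
        mu_max=rng.uniform(0.2, 2.5),
        alpha_chl=rng.uniform(0.5, 8.0),
        theta_max=rng.uniform(0.01, 0.08),
        K_NO3=rng.uniform(0.1, 3.0),
        K_PO4=rng.uniform(0.01, 0.2),
        K_DOM=rng.uniform(0.2, 3.0),
        Qmin_N=qmin_n, Qmax_N=qmin_n * rng.uniform(1.5, 4.0),
        Qmin_P=qmin_p, Qmax_P=qmin_p * rng.uniform(1.5, 4.0),
        m=rng.uniform(0.0, 0.4),
        exud_frac=rng.uniform(0.0, 0.3),
        **kwargs,
    )


@pytest.fixture(scope="session")
def trait_sampler():
    """Callable drawing a random admissible four-strategist trait table."""

    def sample(rng):
        return em.TraitsTable([
            _random_strategist(rng, "SS", "SS", False),
            _random_strategist(rng, "C1", "C1", False),
            _random_strategist(rng, "C2", "C2", True),
            _random_strategist(rng, "R", "R", True),
        ])

    return sample


@pytest.fixture
def random_state_factory(trait_sampler):
    """Callable building a randomized admissible state for given traits."""

    def build(rng, traits):
        n = len(traits)
        c = rng.uniform(0.01, 5.0, size=n)
        qn = rng.uniform(traits.Qmin_N, traits.Qmax_N)
        qp = rng.uniform(traits.Qmin_P, traits.Qmax_P)
        qsi = np.where(traits.uses_silicon,
                       rng.uniform(np.maximum(traits.Qmin_Si, 1e-6),
                                   np.maximum(traits.Qmax_Si, 2e-6)), 0.0)
        theta = rng.uniform(0.2, 1.0, size=n) * traits.theta_max
        return em.CommunityState(
            C=c, N=qn * c, P=qp * c, Si=qsi * c,
            Chl=theta * c * em.GRAMS_C_PER_MOL,
            BC=rng.uniform(0, 1), BN=rng.uniform(0, 0.2), BP=rng.uniform(0, 0.02),
            NO3=rng.uniform(0, 10), PO4=rng.uniform(0, 0.5),
            SiOH4=rng.uniform(0, 10),
            DOC=rng.uniform(0, 5), DON=rng.uniform(0, 1), DOP=rng.uniform(0, 0.1),
            dBSi=rng.uniform(0, 2), time=rng.uniform(0, 2),
        )

    return build
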