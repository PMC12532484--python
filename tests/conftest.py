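import pytest

import extbeta as eb


@pytest.fixture(scope="session")
def extinction_table():
    """CS+ extinction trials for a small simulated cohort (exact unit ratings)."""
    tab = eb.simulate_study(15, seed=321, phases=("extinction",))
    return eb.filter_extinction_cs_plus(tab)


@pytest.fixture(scope="session")
def small_fit(extinction_table):
    """A quick ordered beta baseline fit used by several comparison tests."""
    return eb.fit_model(
        extinction_table,
        eb.ModelSpec.named("baseline"),
        settings=eb.SamplerSettings(chains=2, warmup=300, draws=300),
        seed=7,
        check_convergence=False,
    )


@pytest.fixture(scope="session")
def small_linear_fit(extinction_table):
    return eb.fit_model(
        extinction_table,
        eb.ModelSpec.named("linear"),
        settings=eb.SamplerSettings(chains=2, warmup=300, draws=300),
        seed=7,
        check_convergence=False,
    )


# deterministic hypothesis runs: examples are derived from a fixed seed so the
# suite behaves identically across machines and re-runs
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
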