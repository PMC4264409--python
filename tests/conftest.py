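import warnings

import pytest

# statsmodels emits convergence chatter on small simulated datasets and
# arviz warns about its ongoing refactor; neither is actionable here.
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def exp1_default():
    """One full-size complexity-design dataset (52 participants, 28 items),
    shared across tests that only read it."""
    from cuemem.generate import GeneratorParams, generate_exp1

    return generate_exp1(GeneratorParams(seed=20_260_925))


@pytest.fixture(scope="session")
def exp1_small_residualized():
    """A trimmed + residualized 20-participant dataset for region fits."""
    from cuemem.generate import GeneratorParams, generate_exp1
    from cuemem.pipeline import residualize, trim

    df = generate_exp1(GeneratorParams(n_participants=20, seed=7))
    trimmed, _ = trim(df)
    return residualize(trimmed).data
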