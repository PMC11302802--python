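import pytest

from fmrisk import CheckCounts, default_detectability_table, default_occurrence_table


@pytest.fixture(scope="session")
def o_table():
    return default_occurrence_table()


@pytest.fixture(scope="session")
def d_table():
    return default_detectability_table()


@pytest.fixture()
def dose_calc_counts():
    """Dose-calculation-error counts: caught 8x at the initial check and 2x at
    the first weekly check over 2358 plans, two QC layers."""
    return CheckCounts(fm_id="fm36", n1=8, n2=2, n_plans=2358, n_layers=2)
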