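import pandas as pd
import pytest

from psycea import calibrated_spec, generate_cohort, load_sf6d_tariff, load_sf12_weights, load_unit_costs


@pytest.fixture(scope="session")
def unit_costs():
    return load_unit_costs()


@pytest.fixture(scope="session")
def weights():
    return load_sf12_weights()


@pytest.fixture(scope="session")
def tariff():
    return load_sf6d_tariff()


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One calibrated synthetic cohort (85 clients) shared across tests."""
    return generate_cohort(calibrated_spec(seed=7))


def make_utilization(rows):
    """Utilization table from (client_id, period, service_item, units, amount_eur) tuples."""
    return pd.DataFrame(
        rows, columns=["client_id", "period", "service_item", "units", "amount_eur"]
    )


def make_clients(last_visits: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        {"client_id": list(last_visits), "last_observed_visit": list(last_visits.values())}
    )
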