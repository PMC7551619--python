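import pytest

from threshpanel.core_data import (
    ConcentrationSeries,
    DiscriminationDataset,
    PreferenceDataset,
)

TRIANGLE_LEVELS = (0.2, 2.0, 20.0, 200.0, 2000.0)
PREFERENCE_LEVELS = (3.75, 7.5, 37.5, 75.0, 375.0, 750.0)


@pytest.fixture
def triangle_series():
    return ConcentrationSeries(TRIANGLE_LEVELS)


@pytest.fixture
def preference_series():
    return ConcentrationSeries(PREFERENCE_LEVELS)


@pytest.fixture
def small_discrimination(triangle_series):
    return DiscriminationDataset(
        series=triangle_series,
        records={
            "P01": (False, False, False, True, True),
            "P02": (True, True, True, True, True),
            "P03": (True, False, True, False, False),
        },
        condition="orthonasal",
    )


@pytest.fixture
def small_preference(preference_series):
    return PreferenceDataset(
        series=preference_series,
        records={
            "P01": ("spike", "blank", "blank", "blank", "blank", "blank"),
            "P02": ("blank", "spike", "spike", "spike", "spike", "spike"),
            "P03": ("spike", "blank", "spike", "blank", "spike", "blank"),
        },
    )
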