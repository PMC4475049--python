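import numpy as np
import pandas as pd
import pytest

from thermopair import DevelopmentObservation, SpeciesRecord


def make_obs(points, species="sp1", stage="egg_to_adult", pop="pop1", study="st1"):
    """DevelopmentObservation list from (temperature, days) tuples."""
    return [
        DevelopmentObservation(
            species_id=species,
            population_id=pop,
            study_id=study,
            stage=stage,
            temperature=t,
            development_time=d,
        )
        for t, d in points
    ]


def make_species(
    species_id,
    invasive,
    genus="G",
    family="F",
    order="O",
    continent="Europe",
    ldt=10.0,
    set_dd=300.0,
    **kw,
):
    return SpeciesRecord(
        species_id=species_id,
        order=order,
        family=family,
        genus=genus,
        continent=continent,
        invasive=invasive,
        ldt=ldt,
        set_dd=set_dd,
        **kw,
    )


@pytest.fixture
def exact_line_obs():
    """Rates exactly on r = 0.01 (T - 10) at four temperatures."""
    return make_obs([(t, 1.0 / (0.01 * (t - 10))) for t in (15, 20, 25, 30)])


@pytest.fixture
def species_long_table():
    """Balanced two-group table with known group structure for mixed models."""
    rng = np.random.default_rng(42)
    orders = np.repeat([f"O{i}" for i in range(5)], 40)
    families = np.repeat([f"F{i}" for i in range(20)], 10)
    status = np.tile([0, 1], 100)
    value = (
        10.0
        + 1.5 * status
        + rng.normal(0, 1.0, 5)[np.repeat(np.arange(5), 40)]
        + rng.normal(0, 1.2, 20)[np.repeat(np.arange(20), 10)]
        + rng.normal(0, 2.0, 200)
    )
    return pd.DataFrame(
        {"value": value, "status": status, "order": orders, "family": families}
    )
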