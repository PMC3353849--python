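import dataclasses

import numpy as np
import pytest

import cardiocea as cc
from cardiocea.synthetic_data import AGE_MAX, AGE_MIN, EVENTS, IncidenceTable


@pytest.fixture(scope="session")
def params():
    """Packaged tables with the default synthetic baseline incidence."""
    ps = cc.load_parameter_set()
    return ps.replace(baseline_rates=cc.generate_baseline_rates())


@pytest.fixture
def male70():
    return cc.PatientProfile(sex="male", start_age=70)


def flat_incidence(**rates) -> IncidenceTable:
    """Age- and sex-constant incidence table; unspecified events get rate 0."""
    n = AGE_MAX - AGE_MIN + 1
    table = {}
    for sex in ("male", "female"):
        for event in EVENTS:
            table[(sex, event)] = np.full(n, float(rates.get(event, 0.0)))
    return IncidenceTable(table)


def all_fixed(ps: cc.ParameterSet) -> cc.ParameterSet:
    """Copy of a parameter set with every uncertainty spec set to fixed."""
    fixed = cc.DistributionSpec("fixed")
    return ps.replace(
        first_year=tuple(dataclasses.replace(r, spec=fixed) for r in ps.first_year),
        later_year=tuple(dataclasses.replace(r, spec=fixed) for r in ps.later_year),
        effects=tuple(dataclasses.replace(r, spec=fixed) for r in ps.effects),
        costs=tuple(dataclasses.replace(r, spec=fixed) for r in ps.costs),
    )
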