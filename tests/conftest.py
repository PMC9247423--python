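import pandas as pd
import pytest

import certadjust as ca
from certadjust.records import AGE_GROUPS, Cohort, DeathRecord


@pytest.fixture(scope="session")
def taxonomy():
    return ca.CauseTaxonomy.default()


@pytest.fixture(scope="session")
def std():
    return ca.StandardPopulation.synthetic_default()


def make_record(
    record_id="r1",
    year=2006,
    sex="male",
    age_group="85-89",
    part1=("F03",),
    part2=(),
    ucod="F03",
):
    return DeathRecord(
        record_id=record_id,
        year=year,
        sex=sex,
        age_group=age_group,
        part1_codes=list(part1),
        part2_codes=list(part2),
        ucod_code=ucod,
    )


@pytest.fixture
def mixed_cohort():
    """10 records: 4 dementia-MCOD, 6 without any dementia code."""
    recs = [
        make_record("d1", part1=["F03"], ucod="F03"),
        make_record("d2", part1=["I21"], part2=["G30"], ucod="I21"),
        make_record("d3", part1=["G30", "J18"], ucod="G30"),
        make_record("d4", part2=["F01"], part1=["I63"], ucod="F01"),
        make_record("n1", part1=["I21"], ucod="I21"),
        make_record("n2", part1=["C80"], ucod="C80"),
        make_record("n3", part1=["J18"], ucod="J18"),
        make_record("n4", part1=["I63"], part2=["E11"], ucod="I63"),
        make_record("n5", part1=["R99"], ucod="R99"),
        make_record("n6", part1=["N39"], ucod="N39"),
    ]
    return Cohort(records=recs, country_label="fixture")


@pytest.fixture(scope="session")
def small_sim(std):
    """A small (~4k records) flat-truth study shared across tests."""
    cfg = ca.preset("flat_truth", seed=123)
    cfg.population_scale *= 0.04
    cohort, pop, truth = ca.generate_cohort(cfg)
    return cfg, cohort, pop, truth


@pytest.fixture(scope="session")
def small_run(small_sim, std):
    cfg, cohort, pop, truth = small_sim
    results = ca.run_adjustment(cohort, pop, std, taxonomy=cfg.taxonomy())
    return cfg, cohort, pop, truth, results
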