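"""Shared fixtures: full-size synthetic study runs, computed once per session."""

import numpy as np
import pytest

from aadfe import dfestats, pool_by_type, synthetic
from aadfe.ingest import ORDERED_PAIRS
from aadfe.selection import LambdaMatrix


@pytest.fixture(scope="session")
def fitness_recovery():
    """Full-circle run: 380 types, ~1000 obs/type, known lambda*."""
    lm = synthetic.gen_lambda_matrix(101)
    scenario = synthetic.SyntheticScenario(lambda_star=lm, seed=101)
    dfes, long, dropped = pool_by_type(synthetic.gen_scenario_assays(scenario))
    reports, aggregate = dfestats.summarize_all(dfes, seed=102)
    return {
        "lambda_star": lm,
        "dfes": dfes,
        "reports": reports,
        "aggregate": aggregate,
        "dropped": dropped,
        "n_records": len(long),
    }


@pytest.fixture(scope="session")
def null_battery():
    """All-uniform scenario (every lambda* = 0), full test battery."""
    lm = LambdaMatrix({p: 0.0 for p in ORDERED_PAIRS}, "null")
    scenario = synthetic.SyntheticScenario(lambda_star=lm, seed=201)
    dfes, _, _ = pool_by_type(synthetic.gen_scenario_assays(scenario))
    reports, aggregate = dfestats.summarize_all(dfes, seed=202)
    return {"reports": reports, "aggregate": aggregate}


@pytest.fixture(scope="session")
def stability_battery():
    """Stability-regime scenario: ~1/5 of types have interior modes."""
    scenario = synthetic.gen_stability_scenario(301)
    dfes, _, _ = pool_by_type(synthetic.gen_scenario_assays(scenario))
    reports, aggregate = dfestats.summarize_all(dfes, seed=302)
    is_mid = np.array(
        [
            (r.from_aa, r.to_aa) in scenario.intermediate_types
            for r in reports.itertuples()
        ]
    )
    return {
        "scenario": scenario,
        "reports": reports,
        "aggregate": aggregate,
        "is_intermediate": is_mid,
    }
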