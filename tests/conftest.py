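import numpy as np
import pandas as pd
import pytest

from heatlagccx.basis import CrossBasisSpec
from heatlagccx.claims import load_cause_groups
from heatlagccx.synth import CauseTruth, SynthConfig, federal_holidays, gen_climate


@pytest.fixture(scope="session")
def spec():
    return CrossBasisSpec()


@pytest.fixture(scope="session")
def cause_groups():
    return load_cause_groups()


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-county study used by structural tests."""
    return SynthConfig(
        n_counties=2, points_per_county=2, years=(2016,),
        causes={"heat_related": CauseTruth(baseline_rate=1.5, or_95v50=1.30)},
        seed=11)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """(county_days, labeled_visits, holidays) for the tiny study."""
    from heatlagccx.pipeline import simulate_study
    return simulate_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_county_days(tiny_config):
    """County-day exposure series only (no visits)."""
    from heatlagccx.exposure import build_county_day_series
    rng = np.random.default_rng(tiny_config.seed)
    pv, weights, _ = gen_climate(tiny_config, rng)
    return build_county_day_series(pv, weights)


def make_matched_pairs(n_discordant_pos, n_discordant_neg, n_concordant=0):
    """1:1 matched-pair strata with one binary covariate.

    ``n_discordant_pos`` pairs have the case exposed and the referent not;
    ``n_discordant_neg`` the reverse; concordant pairs carry no information.
    Returns a strata table in the long format the fitter accepts.
    """
    rows = []
    sid = 0
    base = pd.Timestamp("2016-07-15")

    def add(case_x, ref_x):
        nonlocal sid
        for is_case, x in ((True, case_x), (False, ref_x)):
            rows.append({
                "stratum_id": sid, "county_id": "C0", "case_date": base,
                "date": base + pd.Timedelta(days=0 if is_case else 7),
                "is_case": is_case, "case_count": 1,
                **{f"lag{i}": 50.0 for i in range(6)},
                "rh": 50.0, "holiday": float(x)})
        sid += 1

    for _ in range(n_discordant_pos):
        add(1, 0)
    for _ in range(n_discordant_neg):
        add(0, 1)
    for _ in range(n_concordant):
        add(1, 1)
    return pd.DataFrame(rows)
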