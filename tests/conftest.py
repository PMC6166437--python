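import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from reportratio.model import (  # noqa: E402
    AcasiResponse,
    Cohort,
    PregnancyRecord,
    Respondent,
    ROUND_2002,
    ROUND_2011_2015,
    cm_from_date,
)
from reportratio.simulate import GeneratorConfig  # noqa: E402

#: interview in June 2013 -> standard window Jan 2008 .. Dec 2012
INTERVIEW = cm_from_date(2013, 6)

_DEMO_DEFAULTS = dict(
    age_group="25-34",
    race_ethnicity="white_nl",
    poverty="100-299",
    marital="never_married",
    religiosity="lt_monthly",
)


def make_respondent(
    rid,
    pregnancies=(),
    acasi_birth=0,
    acasi_loss=0,
    acasi_abortion=0,
    round=ROUND_2011_2015,
    interview_month=INTERVIEW,
    **demo,
):
    kwargs = {**_DEMO_DEFAULTS, **demo}
    period = "lifetime" if round == ROUND_2002 else "five_year"
    return Respondent(
        id=rid,
        round=round,
        interview_month=interview_month,
        pregnancies=tuple(pregnancies),
        acasi=AcasiResponse(
            period_kind=period,
            count_birth=acasi_birth,
            count_loss=acasi_loss,
            count_abortion=acasi_abortion,
        ),
        **kwargs,
    )


def preg(outcome, year, month):
    return PregnancyRecord(outcome_raw=outcome, end_month=cm_from_date(year, month))


@pytest.fixture
def hand_cohort():
    """Six women, hand-enumerable: abortion reporters 4 (ACASI) vs 2 (FTF).

    FTF abortion events inside [Jan 2008, Dec 2012]: w1 (2010), w2 (2008).
    w3's abortion is pre-window (2006), w4's history has only a birth,
    w5 reports an abortion in ACASI only, w6 reports nothing anywhere.
    """
    women = [
        make_respondent("w1", [preg("abortion", 2010, 5)], acasi_abortion=1),
        make_respondent("w2", [preg("abortion", 2008, 1), preg("live_birth_vaginal", 2011, 3)],
                        acasi_abortion=2, acasi_birth=1),
        make_respondent("w3", [preg("abortion", 2006, 7)], acasi_abortion=1),
        make_respondent("w4", [preg("live_birth_cesarean", 2012, 12)], acasi_birth=1),
        make_respondent("w5", [], acasi_abortion=1),
        make_respondent("w6", []),
    ]
    return Cohort(round=ROUND_2011_2015, respondents=women)


@pytest.fixture
def faithful_config():
    """Everything disclosed, nothing misdated: modes must agree exactly."""
    return GeneratorConfig(
        n=500,
        seed=7,
        p_ftf={"birth": 1.0, "loss": 1.0, "abortion": 1.0},
        p_acasi={"birth": 1.0, "loss": 1.0, "abortion": 1.0},
        misdate_sd_months=0.0,
        telescope_in_prob=0.0,
        confusion_prob=0.0,
    )
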