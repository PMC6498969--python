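"""Shared fixtures: hand-built rating tables for rule-following participants."""

from __future__ import annotations

import pandas as pd
import pytest

from fuzzydefs.design import StimulusDesign, build_design


def records_for_participant(
    pid: str,
    simple_means: dict[int, int],
    conj_rule,
    disj_rule,
    design: StimulusDesign,
    triple_rule=None,
) -> pd.DataFrame:
    """Ratings table for one participant whose compound ratings follow a rule.

    ``simple_means`` gives integer simple ratings (entered three times so the
    repetition mean equals the value exactly); ``conj_rule(tx, ty)`` and
    ``disj_rule(tx, ty)`` produce the compound ratings from constituent means.
    """
    rows = []
    for age, val in simple_means.items():
        for rep in (1, 2, 3):
            rows.append(dict(participant_id=pid, kind="simple", age1=age, age2=None,
                             age3=None, rating=val, repetition=rep))
    for x, y in design.conjunction_pairs:
        rows.append(dict(participant_id=pid, kind="conjunction2", age1=x, age2=y,
                         age3=None, rating=conj_rule(simple_means[x], simple_means[y]),
                         repetition=1))
    for x, y in design.disjunction_pairs:
        rows.append(dict(participant_id=pid, kind="disjunction", age1=x, age2=y,
                         age3=None, rating=disj_rule(simple_means[x], simple_means[y]),
                         repetition=1))
    if design.triples and triple_rule is not None:
        for a, b, c in design.triples:
            rows.append(dict(participant_id=pid, kind="conjunction3", age1=a, age2=b,
                             age3=c, rating=triple_rule(a, b, c), repetition=1))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def design_exp1() -> StimulusDesign:
    return build_design("experiment-1")


@pytest.fixture(scope="session")
def design_exp2() -> StimulusDesign:
    return build_design("experiment-2")


#: unimodal profile with a single rating peak at 50 and cross-peak ties at
#: ratings 2 and 4 (ties at the floor rating 1 are vacuous and excluded)
EVEN_PROFILE = {15: 1, 25: 2, 30: 2, 33: 2, 37: 2, 40: 4, 45: 4,
                50: 6, 53: 4, 57: 4, 60: 2, 65: 2, 75: 1}
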