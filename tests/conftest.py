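import logging

import numpy as np
import pandas as pd
import pytest

from msrs import (
    Demographics,
    ItemDef,
    Questionnaire,
    SurveyTable,
    default_questionnaire,
    generate,
    paperlike_preset,
)

# Heywood-case warnings are expected noise in bootstrap-heavy tests
logging.getLogger("msrs.factor").setLevel(logging.ERROR)


def make_table(rows, questionnaire=None) -> SurveyTable:
    """Build a SurveyTable from (rater, monkey, item, response) tuples."""
    q = questionnaire or default_questionnaire()
    return SurveyTable(
        pd.DataFrame(rows, columns=["rater_id", "monkey_id", "item_id", "response"]), q
    )


def full_survey(rater, monkey, response=1, n_items=36):
    return [(rater, monkey, i, response) for i in range(1, n_items + 1)]


@pytest.fixture
def plain_questionnaire():
    """36 items, none reverse-keyed."""
    return Questionnaire(tuple(ItemDef(i, f"item {i}", False) for i in range(1, 37)))


@pytest.fixture
def two_survey_table(plain_questionnaire):
    rows = full_survey(1, 1, 2) + full_survey(2, 1, 3)
    return make_table(rows, plain_questionnaire)


@pytest.fixture(scope="session")
def preset_data():
    """One paperlike synthetic dataset shared across tests."""
    config = paperlike_preset(seed=3)
    table, demo, truth = generate(config)
    return config, table, demo, truth


@pytest.fixture
def small_demo():
    return Demographics(pd.DataFrame({
        "monkey_id": [1, 2, 3, 4, 5, 6],
        "age_years": [5.0, 7.5, 12.0, 4.2, 20.0, 9.9],
        "sex": ["female", "female", "male", "female", "female", "male"],
        "rank": ["low", "middle", "high", "low", "unknown", "high"],
        "housing": ["a", "a", "b", "b", "c", "c"],
    }))
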