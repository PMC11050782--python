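import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from gmosr import load_default_schema, load_norm_table
from gmosr.scoresheet import (Assessment, GMCategory, SEQUENCE_ITEM,
                              sequence_from_category)


@pytest.fixture(scope="session")
def schema():
    return load_default_schema()


@pytest.fixture(scope="session")
def table2():
    return load_norm_table("table2")


@pytest.fixture(scope="session")
def table4():
    return load_norm_table("table4")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240413)


def make_assessment(schema, category=GMCategory.NORMAL, fill=2.0,
                    infant_id="A1", **overrides):
    """Conforming assessment with every detail item at ``fill``."""
    items = {k: float(fill) for k in schema.item_keys}
    items[SEQUENCE_ITEM] = float(sequence_from_category(category))
    items.update(overrides)
    return Assessment(infant_id=infant_id, category=category,
                      item_scores=items, country="Austria", sex="F")


def random_conforming_items(schema, category, rng):
    """Random legal item vector respecting the sequence-category coupling."""
    grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
    items = {k: float(rng.choice(grid)) for k in schema.item_keys}
    items[SEQUENCE_ITEM] = float(sequence_from_category(category))
    return items
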