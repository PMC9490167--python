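"""Shared fixtures: tiny hand-built tables and small synthetic samples."""

import numpy as np
import pandas as pd
import pytest

from crossimpute import (ImputerConfig, SurveyTable, SyntheticConfig,
                         VariableSchema, apply_logical_edits, default_ruleset,
                         derive_true_status, encode_missing_as_level,
                         generate_donor_target, numeric_fill_values)
from crossimpute.logical import POSSIBLY_UNDOC, STATUS_COL


def make_table(df: pd.DataFrame, extra_schema=(), provenance="test") -> SurveyTable:
    """Wrap a frame whose columns are id/weight plus declared extras."""
    schema = [VariableSchema("id", "categorical", "id"),
              VariableSchema("weight", "numeric", "weight")]
    schema += list(extra_schema)
    return SurveyTable(data=df, schema=schema, provenance=provenance)


@pytest.fixture
def toy_schema():
    return [
        VariableSchema("id", "categorical", "id"),
        VariableSchema("weight", "numeric", "weight"),
        VariableSchema("color", "categorical", "predictor",
                       levels=("red", "green", "blue")),
        VariableSchema("age", "numeric", "predictor"),
        VariableSchema("flag", "binary", "predictor"),
    ]


@pytest.fixture
def toy_table(toy_schema):
    df = pd.DataFrame({
        "id": ["a", "b", "c"],
        "weight": [1.0, 2.0, 0.5],
        "color": ["red", "blue", "green"],
        "age": [30.0, 41.5, 27.0],
        "flag": [1.0, 0.0, 1.0],
    })
    return SurveyTable(data=df, schema=list(toy_schema))


@pytest.fixture(scope="session")
def small_donor():
    """A ready-to-fit donor pool: edited, truth-labeled, encoded."""
    cfg = SyntheticConfig(n_donor=1500, n_target=1500, seed=42)
    donor, _ = generate_donor_target(cfg)
    rs = default_ruleset()
    d = derive_true_status(apply_logical_edits(donor, rs), rs)
    d = encode_missing_as_level(d, numeric_fill_values(d))
    return d


@pytest.fixture(scope="session")
def small_pool(small_donor):
    return small_donor.subset(
        (small_donor.data[STATUS_COL] == POSSIBLY_UNDOC).to_numpy())


def labeled_pool_table(X: np.ndarray, y: np.ndarray,
                       feature_names=None) -> SurveyTable:
    """Build a possibly-undocumented pool table from a numeric matrix and
    0/1 labels, for testing the imputers on hand-made geometry."""
    from crossimpute.logical import TRUE_DOC, TRUE_UNDOC, TRUTH_COL
    n, p = X.shape
    names = feature_names or [f"x{j}" for j in range(p)]
    df = pd.DataFrame(X, columns=names)
    df["id"] = [f"r{i}" for i in range(n)]
    df["weight"] = 1.0
    df[STATUS_COL] = POSSIBLY_UNDOC
    df[TRUTH_COL] = np.where(np.asarray(y) == 1, TRUE_UNDOC, TRUE_DOC)
    schema = [VariableSchema("id", "categorical", "id"),
              VariableSchema("weight", "numeric", "weight"),
              VariableSchema(STATUS_COL, "categorical", "aux",
                             levels=("doc_logical", "possibly_undoc",
                                     "imputed_doc", "imputed_undoc")),
              VariableSchema(TRUTH_COL, "categorical", "truth_component",
                             levels=(TRUE_DOC, TRUE_UNDOC))]
    schema += [VariableSchema(nm, "numeric", "predictor") for nm in names]
    return SurveyTable(data=df, schema=schema)
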