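"""Shared fixtures: tiny cohorts built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrphewas import Cohort, SnpWeightTable


def make_weights(rows) -> SnpWeightTable:
    return SnpWeightTable(pd.DataFrame(
        rows, columns=["snp_id", "effect_allele", "other_allele", "weight"]))


def make_cohort(dosages: np.ndarray, counted: dict[str, str],
                phenotypes: np.ndarray, outcome_names=None,
                validation=None, hints=None, ids=None) -> Cohort:
    n, p = dosages.shape
    snp_ids = list(counted)
    outcome_names = outcome_names or [f"y{j}" for j in range(phenotypes.shape[1])]
    ids = pd.Index(ids or [f"id{i}" for i in range(n)], name="individual_id")
    meta = pd.DataFrame(
        {"validation_set": validation or [False] * len(outcome_names),
         "declared_type": "auto",
         "transform_hint": hints or ["auto"] * len(outcome_names),
         "role": "outcome"},
        index=pd.Index(outcome_names, name="outcome"))
    return Cohort(
        dosages=pd.DataFrame(dosages.astype(float), index=ids, columns=snp_ids),
        counted_allele=dict(counted),
        phenotypes=pd.DataFrame(phenotypes.astype(float), index=ids,
                                columns=outcome_names),
        outcome_meta=meta)


@pytest.fixture
def three_snp_weights() -> SnpWeightTable:
    return make_weights([("rs1", "A", "G", 0.1), ("rs2", "C", "T", 0.2),
                         ("rs3", "G", "A", 0.05)])


@pytest.fixture
def small_cohort() -> Cohort:
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(5, 2)).astype(float)
    phen = rng.standard_normal((5, 3))
    return make_cohort(dosages, {"rs1": "A", "rs2": "C"}, phen)
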