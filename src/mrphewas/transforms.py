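"""Allele-score construction and outcome transformations.

The weighted allele score is the single instrument of the screen: each SNP's
dosage is oriented to count effect alleles (flipping ``2 - g`` where the file
counts the other allele) and summed with its GWAS weight, so a higher score
predicts a higher exposure. Outcomes are harmonised with a rank-based inverse
normal transform for stage 1, and log / binarise / standardise rules for the
stage-2 IV models, which deliberately use the untransformed-scale variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Cohort, DataError, SnpWeightTable


@dataclass(frozen=True)
class AlleleScore:
    """Per-individual weighted allele score S_i, optionally standardized."""

    values: np.ndarray
    standardized: bool
    snp_ids: tuple[str, ...]
    n_flipped: int

    def __post_init__(self) -> None:
        if self.standardized:
            v = self.values
            if abs(v.mean()) > 1e-10 or abs(v.std() - 1) > 1e-10:
                raise DataError("standardized score fails mean-0/SD-1 contract")


def standardize(x: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (population SD, ddof=0)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DataError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def build_allele_score(cohort: Cohort, weights: SnpWeightTable,
                       subset: Sequence[str] | None = None,
                       standardized: bool = True) -> AlleleScore:
    """Weighted allele score S_i = sum_j w_j d_ij over the chosen SNPs.

    ``d_ij`` is the effect-allele dosage: the stored dosage where the file's
    counted allele equals the weight table's effect allele, else ``2 - g_ij``.
    """
    w = weights if subset is None else weights.subset(subset)
    missing = [s for s in w.snp_ids if s not in cohort.dosages.columns]
    if missing:
        raise DataError(f"SNPs in weights absent from cohort: {missing}")
    raw = np.zeros(cohort.n_individuals)
    n_flipped = 0
    for snp, weight, effect, other in zip(
            w.snp_ids, w.weights, w.table["effect_allele"], w.table["other_allele"]):
        g = cohort.dosages[snp].to_numpy(dtype=float)
        counted = cohort.counted_allele.get(snp)
        if counted == effect:
            d = g
        elif counted == other:
            d = 2.0 - g
            n_flipped += 1
        else:
            raise DataError(
                f"counted allele {counted!r} for {snp} matches neither "
                f"effect ({effect}) nor other ({other}) allele")
        raw = raw + weight * d
    if raw.std() == 0:
        raise DataError("allele score has zero variance")
    values = standardize(raw) if standardized else raw
    return AlleleScore(values=values, standardized=standardized,
                       snp_ids=tuple(w.snp_ids), n_flipped=n_flipped)


class AlleleScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a cohort's dosages to the standardized allele score.

    Parameters
    ----------
    weights : SnpWeightTable
        Effect alleles and per-allele weights.
    subset : sequence of str, optional
        Restrict the score to these SNP ids (e.g. a split-instrument subset).
    standardized : bool
        Return the mean-0/SD-1 score (the default used throughout the screen).
    """

    def __init__(self, weights: SnpWeightTable, subset=None, standardized=True):
        self.weights = weights
        self.subset = subset
        self.standardized = standardized

    def fit(self, cohort: Cohort, y=None):
        self.score_ = build_allele_score(cohort, self.weights,
                                         subset=self.subset,
                                         standardized=self.standardized)
        self.n_flipped_ = self.score_.n_flipped
        return self

    def transform(self, cohort: Cohort) -> np.ndarray:
        return build_allele_score(cohort, self.weights, subset=self.subset,
                                  standardized=self.standardized).values


def _random_tiebreak_ranks(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """1-based ranks with ties broken uniformly at random."""
    n = len(x)
    shuffle = rng.permutation(n)
    order = shuffle[np.argsort(x[shuffle], kind="stable")]
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def inverse_normal_transform(values: np.ndarray, offset: float = 0.0,
                             seed=None) -> np.ndarray:
    """Rank-based inverse normal transform with random tie-breaking.

    Non-missing entries become ``Phi^{-1}((r - offset) / (n - 2*offset + 1))``
    with 1-based ranks r among non-missing values; ties get a uniformly random
    order determined by ``seed``. Missing (NaN) entries stay missing.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    x = values[mask]
    n = len(x)
    if n < 3:
        raise DataError(f"inverse normal transform needs >= 3 values, got {n}")
    if np.all(x == x[0]):
        raise DataError("all values identical: rank order would be purely random")
    rng = np.random.default_rng(seed)
    ranks = _random_tiebreak_ranks(x, rng)
    quantiles = (ranks - offset) / (n - 2 * offset + 1)
    out = np.full(values.shape, np.nan)
    out[mask] = stats.norm.ppf(quantiles)
    return out


class RankInverseNormal(BaseEstimator, TransformerMixin):
    """Column-wise rank-based inverse normal transformer.

    Applies :func:`inverse_normal_transform` to every column of a matrix,
    deriving one tie-break stream per column from ``seed`` so results do not
    depend on column order beyond the column's own index.

    Parameters
    ----------
    offset : float
        Rank offset; 0 gives quantiles r/(n+1), 0.375 the Blom variant.
    seed : int
        Master seed for tie-break randomisation.
    min_nonmissing : int
        Columns with fewer non-missing values are returned as all-NaN.
    """

    def __init__(self, offset: float = 0.0, seed: int = 0,
                 min_nonmissing: int = 3):
        self.offset = offset
        self.seed = seed
        self.min_nonmissing = min_nonmissing

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DataError("expected a 2-D matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape, np.nan)
        for j in range(X.shape[1]):
            col = X[:, j]
            ok = ~np.isnan(col)
            if ok.sum() < self.min_nonmissing or np.all(col[ok] == col[ok][0]):
                continue  # degenerate column: left all-missing, caller skips it
            child = np.random.SeedSequence([int(self.seed), j])
            out[:, j] = inverse_normal_transform(col, offset=self.offset,
                                                 seed=child)
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def prepare_stage2_outcome(values: np.ndarray, hint: str = "auto",
                           min_auto_n: int = 20) -> tuple[np.ndarray, str]:
    """Prepare an outcome for the stage-2 IV model on its original scale.

    ``log``: natural log then standardize (requires positive values);
    ``none``: standardize; ``binarize``: median split into near-equal groups
    (values > median -> 1); ``auto``: log-standardize if right-skewed and
    positive, plain standardize if roughly normal, else binarize.
    Returns the prepared vector (NaN preserved) and its kind.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    x = values[mask]
    if hint == "auto" and len(x) < min_auto_n:
        raise DataError(f"auto transform decision needs >= {min_auto_n} values")

    if hint == "auto":
        skew = stats.skew(x)
        if skew > 1 and np.all(x > 0):
            hint = "log"
        elif abs(skew) <= 1 and len(np.unique(x)) >= 10:
            hint = "none"
        else:
            hint = "binarize"

    out = np.full(values.shape, np.nan)
    if hint == "log":
        if np.any(x <= 0):
            raise DataError("log transform requested but values <= 0 present")
        out[mask] = standardize(np.log(x))
        return out, "continuous"
    if hint == "none":
        out[mask] = standardize(x)
        return out, "continuous"
    if hint == "binarize":
        uniq = np.unique(x)
        if len(uniq) < 2:
            raise DataError("cannot binarize a constant vector")
        if len(uniq) == 2:  # already two-valued: map directly, keep order
            out[mask] = (x == uniq[1]).astype(float)
            return out, "binary"
        med = np.median(x)
        out[mask] = (x > med).astype(float)  # median ties go to the lower group
        return out, "binary"
    raise DataError(f"unknown transform hint {hint!r}")
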