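"""Permutation-based empirical rank p-values for the stage-1 screen.

The Bonferroni adjustment is conservative when outcomes are correlated, so
the screen's ranks are additionally calibrated by permutation: individual
rows of the (already inverse-normal transformed) outcome matrix are permuted
jointly, the screen re-run, and each outcome's permuted rank recorded. The
empirical p for an outcome observed at rank i is the proportion of
permutations in which it achieved rank j <= i. Validation outcomes are
excluded from the ranking entirely.

Permuting the rows jointly preserves the cross-outcome correlation and each
row's missingness pattern; an independent per-outcome shuffle is available
for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import Cohort, DataError, PipelineConfig
from .screen import PhenomeScreen, _seed_int, univariate_robust_screen
from .transforms import AlleleScore


def _rank_pvalues(p: np.ndarray, gamma: np.ndarray,
                  names: np.ndarray) -> np.ndarray:
    """1-based ranks by (p asc, |gamma| desc, name asc); NaN p ranks last."""
    key_p = np.where(np.isnan(p), np.inf, p)
    order = np.lexsort((names, -np.abs(np.nan_to_num(gamma)), key_p))
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def permutation_rank_pvalues(score: AlleleScore | np.ndarray, cohort: Cohort,
                             B: int, seed: int,
                             config: PipelineConfig | None = None,
                             mode: str = "joint",
                             add_one: bool = False) -> pd.DataFrame:
    """Empirical rank p-values over B joint row permutations.

    Returns one row per non-validation outcome with its observed rank and
    ``p_permutation`` = #{b : permuted rank <= observed rank} / B (the
    add-one estimate (count+1)/(B+1) behind ``add_one``). Deterministic
    given ``seed``. ``B = 0`` returns an empty frame.
    """
    if mode not in ("joint", "per_outcome"):
        raise DataError(f"unknown permutation mode {mode!r}")
    config = config or PipelineConfig(rng_seed=seed, n_permutations=B)
    screen = PhenomeScreen(alpha=config.alpha, int_offset=config.int_offset,
                           robust_se_flavor=config.robust_se_flavor,
                           seed=_seed_int(config.child_seed("int")))
    screen.fit(score, cohort)
    return permutation_rank_pvalues_from_screen(
        screen, B=B, seed=seed, mode=mode, add_one=add_one)


def permutation_rank_pvalues_from_screen(screen: PhenomeScreen, B: int,
                                         seed: int, mode: str = "joint",
                                         add_one: bool = False) -> pd.DataFrame:
    """Permutation p-values reusing a fitted screen's frozen INT matrix."""
    res = screen.results_
    keep = (~res["validation_set"]).to_numpy()
    names = res.loc[keep, "outcome"].to_numpy()
    if keep.sum() < 2:
        raise DataError("permutation testing needs at least 2 outcomes")
    if B == 0:
        return pd.DataFrame(columns=["outcome", "observed_rank",
                                     "p_permutation", "B", "seed"])

    Y = screen.int_matrix_[:, keep]
    s = screen.score_
    n = len(s)
    observed = _rank_pvalues(res.loc[keep, "p_value"].to_numpy(),
                             res.loc[keep, "gamma_hat"].to_numpy(), names)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9e3779]))
    counts = np.zeros(keep.sum(), dtype=int)
    for _ in range(B):
        if mode == "joint":
            Yp = Y[rng.permutation(n), :]
        else:
            Yp = np.column_stack([Y[rng.permutation(n), j]
                                  for j in range(Y.shape[1])])
        stat = univariate_robust_screen(s, Yp,
                                        flavor=screen.robust_se_flavor,
                                        min_complete=screen.min_complete)
        perm_ranks = _rank_pvalues(stat["p_value"].to_numpy(),
                                   stat["gamma_hat"].to_numpy(), names)
        counts += perm_ranks <= observed

    p = (counts + 1) / (B + 1) if add_one else counts / B
    return pd.DataFrame({"outcome": names, "observed_rank": observed,
                         "p_permutation": p, "B": B, "seed": seed})
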