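"""Synthetic-cohort generator with known causal structure.

Genotypes are independent Hardy-Weinberg dosages g_ij ~ Binomial(2, maf_j);
an unobserved standard-normal confounder U drives both the exposure and a
subset of outcomes. The exposure is simulated directly on the log scale as
raw score + delta*U + noise, then standardized. Outcome classes encode the
causal diagrams the screen must distinguish:

* ``null``        Y = e                       (no association at all)
* ``causal``      Y = beta*X + lambda*U + e   (true exposure effect)
* ``confounded``  Y = lambda*U + e            (X-Y association via U only)
* ``reverse``     Y = lambda*U + e, then X receives + theta*Y
                  (observational association without exposure->outcome effect)
* ``pleiotropic`` Y = sum_j c_j g_ij + e      (score-outcome path bypassing X)

Binary outcomes threshold the latent Y at its median; missingness is MCAR
per outcome. Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Cohort, DataError, SnpWeightTable
from .transforms import standardize

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative recipe for one outcome."""

    name: str
    klass: str = "null"  # null | causal | confounded | reverse | pleiotropic
    causal_beta: float = 0.0
    confounder_to_outcome: float = 0.0  # lambda
    reverse_theta: float = 0.0
    pleiotropy_snps: tuple[int, ...] = ()  # SNP indices with direct effects
    pleiotropy_effects: tuple[float, ...] = ()  # per-allele direct effects c_j
    missing_rate: float = 0.0
    binary: bool = False
    validation: bool = False

    def __post_init__(self) -> None:
        if self.klass not in ("null", "causal", "confounded", "reverse",
                              "pleiotropic"):
            raise DataError(f"unknown outcome class {self.klass!r}")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must be in [0, 1)")
        if self.klass == "causal" and self.causal_beta == 0:
            raise DataError(f"causal outcome {self.name} needs causal_beta != 0")
        if self.klass == "pleiotropic" and (
                len(self.pleiotropy_snps) == 0
                or len(self.pleiotropy_snps) != len(self.pleiotropy_effects)):
            raise DataError(
                f"pleiotropic outcome {self.name} needs matched SNPs and effects")

    @property
    def true_effect(self) -> float:
        """Causal effect of the standardized exposure on the latent outcome."""
        return self.causal_beta if self.klass == "causal" else 0.0


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the synthetic cohort.

    Defaults put the score at ~2.5% of exposure variance (first-stage F in
    the low hundreds at n ~ 8,000, the scale seen with a 32-SNP adiposity
    score) with moderate confounding of exposure and outcomes.
    """

    n_individuals: int = 2000
    n_snps: int = 32
    maf_range: tuple[float, float] = (0.10, 0.45)
    weight_scale: float = 0.05  # per-allele exposure effect scale (w_j)
    confounder_to_exposure: float = 0.5  # delta
    exposure_noise_sd: float = 1.0
    outcome_specs: tuple[OutcomeSpec, ...] = ()
    seed: int = 0
    exposure_exp_scale: bool = False  # write exp(log-exposure) to exercise log path

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DataError("maf_range must lie within (0, 0.5]")
        names = [s.name for s in self.outcome_specs]
        if len(set(names)) != len(names):
            raise DataError("outcome names must be unique")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for parameter-recovery tests.

    ``exposure_raw_sd`` is the realised SD of the unstandardized log-exposure
    and ``raw_score_var`` the realised variance of the unweighted score; both
    feed closed-form bias calculations (e.g. the OLS estimand under
    confounding, beta + lambda*delta/sd(X_raw) on the standardized scale).
    """

    table: pd.DataFrame  # index outcome; klass, true_beta, pleiotropy_snps
    exposure_raw_sd: float = float("nan")
    raw_score_var: float = float("nan")

    def true_beta(self, outcome: str) -> float:
        return float(self.table.loc[outcome, "true_beta"])


def simulate_cohort(config: SimConfig
                    ) -> tuple[Cohort, SnpWeightTable, np.ndarray, SimTruth]:
    """Generate (cohort, weight table, standardized log-exposure, truth)."""
    specs = config.outcome_specs
    if not specs:
        raise DataError("config has no outcome specs")
    root = np.random.SeedSequence(config.seed)
    ss_geno, ss_conf, ss_expo, ss_out, ss_miss, ss_alle = root.spawn(6)
    rng_g = np.random.default_rng(ss_geno)
    n, p = config.n_individuals, config.n_snps

    mafs = rng_g.uniform(*config.maf_range, size=p)
    G = rng_g.binomial(2, mafs, size=(n, p)).astype(float)  # effect-allele dosage
    weights = config.weight_scale * rng_g.uniform(0.5, 1.5, size=p)
    if np.all(weights == 0) and any(s.klass == "causal" for s in specs):
        raise DataError("all weights zero but a causal outcome is requested")

    U = np.random.default_rng(ss_conf).standard_normal(n)
    raw_score = G @ weights
    rng_x = np.random.default_rng(ss_expo)
    eps_x = config.exposure_noise_sd * rng_x.standard_normal(n)

    rng_y = np.random.default_rng(ss_out)
    latents: dict[str, np.ndarray] = {}
    # reverse-class outcomes exist before the exposure and feed back into it
    x_feedback = np.zeros(n)
    for spec in specs:
        if spec.klass == "reverse":
            y = spec.confounder_to_outcome * U + rng_y.standard_normal(n)
            latents[spec.name] = y
            x_feedback = x_feedback + spec.reverse_theta * y

    x_raw = raw_score + config.confounder_to_exposure * U + x_feedback + eps_x
    exposure = standardize(x_raw)

    for spec in specs:
        if spec.klass == "reverse":
            continue
        e = rng_y.standard_normal(n)
        if spec.klass == "null":
            y = e
        elif spec.klass == "causal":
            y = (spec.causal_beta * exposure
                 + spec.confounder_to_outcome * U + e)
        elif spec.klass == "confounded":
            y = spec.confounder_to_outcome * U + e
        else:  # pleiotropic
            direct = G[:, list(spec.pleiotropy_snps)] @ np.asarray(
                spec.pleiotropy_effects)
            y = direct + e
        latents[spec.name] = y

    rng_m = np.random.default_rng(ss_miss)
    columns = {}
    for spec in specs:
        y = latents[spec.name].copy()
        if spec.binary:
            y = (y > np.median(y)).astype(float)
        if spec.missing_rate > 0:
            mask = rng_m.random(n) < spec.missing_rate
            y[mask] = np.nan
        columns[spec.name] = y

    ids = pd.Index([f"id{i:06d}" for i in range(n)], name="individual_id")
    phen = pd.DataFrame(columns, index=ids)

    rng_a = np.random.default_rng(ss_alle)
    pair_idx = rng_a.integers(0, len(_ALLELE_PAIRS), size=p)
    flip = rng_a.random(p) < 0.5  # half the file columns count the other allele
    snp_ids = [f"rs{1000 + j}" for j in range(p)]
    effect = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    other = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    counted = {snp: (other[j] if flip[j] else effect[j])
               for j, snp in enumerate(snp_ids)}
    stored = np.where(flip[None, :], 2.0 - G, G)
    dosages = pd.DataFrame(stored, index=ids, columns=snp_ids)

    meta = pd.DataFrame(
        {"validation_set": [s.validation for s in specs],
         "declared_type": ["binary" if s.binary else "continuous" for s in specs],
         "transform_hint": ["binarize" if s.binary else "none" for s in specs],
         "role": "outcome"},
        index=pd.Index([s.name for s in specs], name="outcome"))

    weight_table = SnpWeightTable(pd.DataFrame(
        {"snp_id": snp_ids, "effect_allele": effect, "other_allele": other,
         "weight": weights}))
    truth = SimTruth(pd.DataFrame(
        {"klass": [s.klass for s in specs],
         "true_beta": [s.true_effect for s in specs],
         "pleiotropy_snps": [",".join(snp_ids[j] for j in s.pleiotropy_snps)
                             for s in specs]},
        index=pd.Index([s.name for s in specs], name="outcome")),
        exposure_raw_sd=float(x_raw.std()),
        raw_score_var=float(raw_score.var()))
    cohort = Cohort(dosages=dosages, counted_allele=counted,
                    phenotypes=phen, outcome_meta=meta)
    written_exposure = np.exp(x_raw) if config.exposure_exp_scale else exposure
    return cohort, weight_table, written_exposure, truth


def default_paper_shaped_config(seed: int = 0, n_individuals: int = 8121,
                                n_outcomes: int = 172,
                                n_validation: int = 12) -> SimConfig:
    """A cohort shaped like the motivating study: 8,121 individuals, 32
    instrument SNPs, 172 outcomes of which 12 are validation positives, with
    per-outcome missingness spanning 0-65%.

    The 160 "random" outcomes are mostly null with a minority of causal,
    confounded-only, reverse-causal and pleiotropic classes; the validation
    outcomes are causal with larger effects (positive controls).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5e1ec7]))
    n_random = n_outcomes - n_validation
    if n_random < 1:
        raise DataError("n_outcomes must exceed n_validation")
    # class mix: 5% causal, 5% confounded, 2.5% reverse, 2.5% pleiotropic
    # (8 + 8 + 4 + 4 of 160 at the default shape), remainder null
    n_causal = round(0.05 * n_random)
    n_conf = round(0.05 * n_random)
    n_rev = round(0.025 * n_random)
    n_pleio = round(0.025 * n_random)
    classes = (["causal"] * n_causal + ["confounded"] * n_conf
               + ["reverse"] * n_rev + ["pleiotropic"] * n_pleio)
    classes += ["null"] * (n_random - len(classes))
    rng.shuffle(classes)

    specs = []
    for i, klass in enumerate(classes):
        common = dict(name=f"outcome_{i + 1:03d}",
                      missing_rate=float(rng.uniform(0.0, 0.65)),
                      binary=bool(rng.random() < 0.15))
        if klass == "causal":
            specs.append(OutcomeSpec(
                klass="causal",
                causal_beta=float(rng.uniform(0.2, 0.8) * rng.choice([-1, 1])),
                confounder_to_outcome=float(rng.uniform(0.2, 0.8)), **common))
        elif klass == "confounded":
            specs.append(OutcomeSpec(
                klass="confounded",
                confounder_to_outcome=float(rng.uniform(0.3, 1.0)), **common))
        elif klass == "reverse":
            specs.append(OutcomeSpec(
                klass="reverse", reverse_theta=float(rng.uniform(0.05, 0.2)),
                confounder_to_outcome=float(rng.uniform(0.3, 1.0)), **common))
        elif klass == "pleiotropic":
            snps = tuple(int(j) for j in rng.choice(32, size=2, replace=False))
            specs.append(OutcomeSpec(
                klass="pleiotropic", pleiotropy_snps=snps,
                pleiotropy_effects=tuple(rng.uniform(0.03, 0.08, size=2)),
                **common))
        else:
            specs.append(OutcomeSpec(klass="null", **common))
    for i in range(n_validation):
        specs.append(OutcomeSpec(
            name=f"validation_{i + 1:02d}", klass="causal",
            causal_beta=float(rng.uniform(0.4, 1.0) * rng.choice([-1, 1])),
            confounder_to_outcome=float(rng.uniform(0.2, 0.8)),
            missing_rate=float(rng.uniform(0.0, 0.5)),
            binary=bool(rng.random() < 0.15), validation=True))

    return SimConfig(n_individuals=n_individuals, n_snps=32,
                     outcome_specs=tuple(specs), seed=seed)


def null_config(n_individuals: int = 2000, n_outcomes: int = 160,
                seed: int = 0, missing_rate: float = 0.0) -> SimConfig:
    """All-null cohort for calibration studies."""
    specs = tuple(OutcomeSpec(name=f"null_{i + 1:03d}", klass="null",
                              missing_rate=missing_rate)
                  for i in range(n_outcomes))
    return SimConfig(n_individuals=n_individuals, n_snps=8,
                     outcome_specs=specs, seed=seed)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
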