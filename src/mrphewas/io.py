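"""Data model and file IO for the MR-pheWAS pipeline.

All on-disk formats are delimited text (TSV/CSV, auto-detected). Genotypes
may alternatively come from a VCF with a per-sample dosage FORMAT field.
Phenotype missingness is encoded as an empty field or ``NA``; dosage files
are expected to be complete (the intended inputs are imputed dosages).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mrphewas")

_VALID_ALLELES = frozenset("ACGT")
_NA_VALUES = ["", "NA"]
_DOSAGE_TOL = 1e-6


class DataError(ValueError):
    """Invalid or inconsistent input data."""


def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited text file, auto-detecting tab vs comma."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, na_values=_NA_VALUES,
                       keep_default_na=False, **kwargs)


@dataclass(frozen=True)
class SnpWeightTable:
    """Per-SNP effect alleles and weights defining a polygenic allele score.

    Each row carries the per-effect-allele change in the exposure (the GWAS
    effect size ``w_j``) used to weight that SNP's dosage in the score.
    """

    table: pd.DataFrame  # columns: snp_id, effect_allele, other_allele, weight

    def __post_init__(self) -> None:
        t = self.table
        required = ["snp_id", "effect_allele", "other_allele", "weight"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise DataError(f"weight table missing columns: {missing}")
        dup = t["snp_id"][t["snp_id"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate snp_id in weight table: {sorted(set(dup))}")
        for col in ("effect_allele", "other_allele"):
            bad = t[col][~t[col].isin(_VALID_ALLELES)]
            if len(bad):
                raise DataError(f"invalid {col} values: {sorted(set(bad))}")
        same = t[t["effect_allele"] == t["other_allele"]]
        if len(same):
            raise DataError(
                f"effect_allele equals other_allele for: {list(same['snp_id'])}")
        w = pd.to_numeric(t["weight"], errors="coerce")
        if w.isna().any() or not np.isfinite(w).all():
            bad = list(t["snp_id"][~np.isfinite(w.fillna(np.nan))])
            raise DataError(f"non-numeric or non-finite weight for: {bad}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(dtype=float)

    def subset(self, snp_ids: Sequence[str]) -> "SnpWeightTable":
        keep = self.table[self.table["snp_id"].isin(set(snp_ids))]
        absent = set(snp_ids) - set(keep["snp_id"])
        if absent:
            raise DataError(f"SNPs not in weight table: {sorted(absent)}")
        return SnpWeightTable(keep.reset_index(drop=True))

    def drop(self, snp_ids: Sequence[str]) -> "SnpWeightTable":
        keep = self.table[~self.table["snp_id"].isin(set(snp_ids))]
        return SnpWeightTable(keep.reset_index(drop=True))


@dataclass
class Cohort:
    """Aligned genotype dosages and phenotypes for one analysis sample.

    ``dosages`` is individuals x SNPs with values in [0, 2] counting the
    allele declared in ``counted_allele``; ``phenotypes`` is individuals x
    outcomes with NaN marking missing values. Rows of the two frames share
    one individual index.
    """

    dosages: pd.DataFrame
    counted_allele: dict[str, str]
    phenotypes: pd.DataFrame
    outcome_meta: pd.DataFrame  # index: outcome; validation_set, declared_type, transform_hint

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.phenotypes.index):
            raise DataError("dosage and phenotype rows are not aligned")
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size:
            lo, hi = np.nanmin(vals), np.nanmax(vals)
            if lo < -_DOSAGE_TOL or hi > 2 + _DOSAGE_TOL:
                i, j = np.unravel_index(
                    np.nanargmax(np.abs(vals - 1.0)), vals.shape)
                raise DataError(
                    f"dosage outside [0,2] at individual "
                    f"{self.dosages.index[i]!r}, SNP {self.dosages.columns[j]!r}")
        if self.phenotypes.columns.duplicated().any():
            raise DataError("duplicate outcome names")
        missing_meta = set(self.phenotypes.columns) - set(self.outcome_meta.index)
        if missing_meta:
            raise DataError(f"outcomes without metadata: {sorted(missing_meta)}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.phenotypes.index)

    @property
    def n_individuals(self) -> int:
        return len(self.phenotypes.index)

    @property
    def outcome_names(self) -> list[str]:
        return list(self.phenotypes.columns)

    def validation_flags(self) -> pd.Series:
        return self.outcome_meta.loc[self.phenotypes.columns, "validation_set"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level settings; all randomness derives from ``rng_seed``."""

    alpha: float = 0.05
    n_permutations: int = 5000
    rng_seed: int = 0
    bonferroni_m: int | None = None  # None: count non-validation outcomes
    robust_se_flavor: str = "HC1"
    int_offset: float = 0.0
    output_dir: str = "mrphewas_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DataError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_permutations < 0:
            raise DataError("n_permutations must be >= 0")
        if self.robust_se_flavor not in ("HC0", "HC1", "HC3"):
            raise DataError(f"unknown robust SE flavor {self.robust_se_flavor!r}")

    def child_seed(self, *tags: int | str) -> np.random.SeedSequence:
        """Deterministic child seed for a named sub-task."""
        ints = [self.rng_seed] + [
            t if isinstance(t, int)
            else int.from_bytes(hashlib.sha256(t.encode()).digest()[:4], "big")
            for t in tags]
        return np.random.SeedSequence(ints)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {k: d[k] for k in d
                 if k in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def read_snp_weights(path: str | Path) -> SnpWeightTable:
    """Read a SNP weight table (snp_id, effect_allele, other_allele, weight)."""
    t = _read_delimited(path, dtype={"snp_id": str})
    try:
        t["weight"] = pd.to_numeric(t["weight"])
    except (ValueError, KeyError) as exc:
        raise DataError(f"bad weight column in {path}: {exc}") from exc
    return SnpWeightTable(t.reset_index(drop=True))


def write_snp_weights(weights: SnpWeightTable, path: str | Path) -> None:
    weights.table.to_csv(path, sep="\t", index=False)


def _parse_dosage_header(columns: Iterable[str]) -> dict[str, str]:
    counted = {}
    for col in columns:
        if ":" not in col:
            raise DataError(
                f"dosage column {col!r} lacks counted-allele declaration "
                "(expected 'snp_id:allele')")
        snp, allele = col.rsplit(":", 1)
        if allele not in _VALID_ALLELES:
            raise DataError(f"counted allele {allele!r} for SNP {snp!r} invalid")
        counted[snp] = allele
    return counted


def read_dosages(path: str | Path, impute_missing: bool = False
                 ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a dosage TSV: id column + 'snp_id:allele' columns, values in [0,2]."""
    t = _read_delimited(path)
    id_col = t.columns[0]
    t[id_col] = t[id_col].astype(str)
    t = t.set_index(id_col)
    counted = _parse_dosage_header(t.columns)
    t.columns = list(counted)
    t = t.astype(float)
    if t.isna().any().any():
        if not impute_missing:
            cell = np.argwhere(t.isna().to_numpy())[0]
            raise DataError(
                f"missing dosage at individual {t.index[cell[0]]!r}, SNP "
                f"{t.columns[cell[1]]!r}; pass impute_missing=True to mean-impute")
        n = int(t.isna().to_numpy().sum())
        t = t.fillna(t.mean())
        logger.info("mean-imputed %d missing dosage cells", n)
    return t, counted


def read_dosages_vcf(path: str | Path, dosage_field: str = "DS"
                     ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read per-sample dosages from a VCF FORMAT field (counted allele = ALT)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, counted = {}, {}
    for var in vcf:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        ds = np.asarray(var.format(dosage_field), dtype=float).reshape(-1)
        cols[snp] = ds
        counted[snp] = var.ALT[0]
    frame = pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))
    return frame, counted


def read_outcome_meta(path: str | Path) -> pd.DataFrame:
    """Read per-outcome metadata: outcome, validation_set, declared_type, transform_hint."""
    t = _read_delimited(path, dtype=str)
    name_col = t.columns[0]
    t = t.set_index(name_col)
    t.index.name = "outcome"
    if "validation_set" not in t.columns:
        t["validation_set"] = "0"
    t["validation_set"] = (
        t["validation_set"].fillna("0").str.lower()
        .isin({"1", "true", "yes"}))
    for col, default in (("declared_type", "auto"), ("transform_hint", "auto"),
                         ("role", "outcome")):
        if col not in t.columns:
            t[col] = default
        t[col] = t[col].fillna(default)
    return t


def read_cohort(dosage_path: str | Path, phenotype_path: str | Path,
                meta_path: str | Path, vcf: bool = False,
                impute_missing_dosages: bool = False) -> Cohort:
    """Assemble a cohort: inner-join genotypes and phenotypes on individual id.

    Individuals with every outcome missing are dropped (as are outcomes with
    no data at all); both removals are logged.
    """
    if vcf:
        dosages, counted = read_dosages_vcf(dosage_path)
    else:
        dosages, counted = read_dosages(dosage_path,
                                        impute_missing=impute_missing_dosages)
    phen = _read_delimited(phenotype_path)
    id_col = phen.columns[0]
    phen[id_col] = phen[id_col].astype(str)
    phen = phen.set_index(id_col).astype(float)
    meta = read_outcome_meta(meta_path)

    shared = dosages.index.intersection(phen.index)
    if len(shared) == 0:
        raise DataError("no overlapping individual ids between dosages and phenotypes")
    # keep genotype-file order for the retained individuals
    shared = dosages.index[dosages.index.isin(shared)]
    dosages, phen = dosages.loc[shared], phen.loc[shared]

    outcome_cols = [c for c in phen.columns
                    if c not in meta.index or meta.loc[c, "role"] == "outcome"]
    all_missing = phen[outcome_cols].isna().all(axis=1)
    if all_missing.any():
        logger.info("dropped %d individuals with no data for all outcomes",
                    int(all_missing.sum()))
        dosages, phen = dosages[~all_missing], phen[~all_missing]
    empty = [c for c in outcome_cols if phen[c].isna().all()]
    if empty:
        logger.info("dropped %d outcomes with no data: %s", len(empty), empty)
        phen = phen.drop(columns=empty)

    known = [c for c in phen.columns if c in meta.index]
    unknown = [c for c in phen.columns if c not in meta.index]
    if unknown:
        extra = pd.DataFrame(
            {"validation_set": False, "declared_type": "auto",
             "transform_hint": "auto", "role": "outcome"}, index=unknown)
        meta = pd.concat([meta.loc[known], extra])
    return Cohort(dosages=dosages, counted_allele=counted,
                  phenotypes=phen, outcome_meta=meta)


def write_cohort(cohort: Cohort, directory: str | Path,
                 exposure: np.ndarray | None = None,
                 exposure_name: str = "exposure") -> dict[str, Path]:
    """Write the standard cohort file set (dosages, phenotypes, metadata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"dosages": directory / "dosages.tsv",
             "phenotypes": directory / "phenotypes.tsv",
             "meta": directory / "outcome_meta.tsv"}
    dos = cohort.dosages.copy()
    dos.columns = [f"{snp}:{cohort.counted_allele[snp]}" for snp in dos.columns]
    dos.index.name = "individual_id"
    dos.to_csv(paths["dosages"], sep="\t")
    phen = cohort.phenotypes.copy()
    meta = cohort.outcome_meta.copy()
    if exposure is not None:
        phen[exposure_name] = exposure
        meta.loc[exposure_name] = {"validation_set": False,
                                   "declared_type": "continuous",
                                   "transform_hint": "none", "role": "exposure"}
    phen.index.name = "individual_id"
    phen.to_csv(paths["phenotypes"], sep="\t", na_rep="NA",
                float_format="%.10g")
    meta_out = meta.copy()
    meta_out["validation_set"] = meta_out["validation_set"].astype(int)
    meta_out.to_csv(paths["meta"], sep="\t")
    return paths


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV, sorted by rank when present."""
    out = records.copy()
    if "rank" in out.columns and len(out):
        out = out.sort_values("rank", kind="mergesort")
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=_NA_VALUES,
                       keep_default_na=False)
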