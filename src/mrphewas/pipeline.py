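"""End-to-end orchestration of an MR-pheWAS run.

Order of operations: build the allele score, stage-1 screen (Bonferroni,
FDR, permutation p, QQ data, confounder balance when confounders are
supplied), select outcomes with unadjusted p < alpha (validation outcomes
included, as they are followed up too), stage-2 IV models with DWH and
observational comparison, then the over-identification suite (CUE/Hansen
over the individual SNPs and a split-instrument comparison). All outputs
are TSVs plus a JSON manifest; TSV content is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (Cohort, DataError, PipelineConfig, SnpWeightTable, read_cohort,
                 read_snp_weights, write_cohort, write_results,
                 write_snp_weights, _read_delimited)
from .iv import IvEstimate, dwh_test, observational_estimate, tsls_linear, \
    two_stage_logistic
from .overid import cue_gmm, effect_allele_dosages, split_instrument_compare
from .permutation import permutation_rank_pvalues_from_screen
from .screen import PhenomeScreen, _seed_int, confounder_balance
from .simulate import default_paper_shaped_config, simulate_cohort
from .transforms import build_allele_score, prepare_stage2_outcome, standardize

logger = logging.getLogger("mrphewas")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _standardize_with_missing(x: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(x)
    out = np.full(x.shape, np.nan)
    out[ok] = standardize(x[ok])
    return out


def load_run_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DataError("run config must be a YAML mapping")
    return raw


def _load_inputs(raw: Mapping, config: PipelineConfig, outdir: Path):
    """Return (cohort, weights, exposure_raw, sim_truth_or_None, input_paths)."""
    inputs = {}
    if "simulate" in raw:
        sim_block = raw["simulate"] or {}
        sim = default_paper_shaped_config(
            seed=_seed_int(config.child_seed("simulate")),
            n_individuals=int(sim_block.get("n_individuals", 8121)),
            n_outcomes=int(sim_block.get("n_outcomes", 172)),
            n_validation=int(sim_block.get("n_validation", 12)))
        cohort, weights, exposure, truth = simulate_cohort(sim)
        simdir = outdir / "simulated"
        paths = write_cohort(cohort, simdir, exposure=exposure)
        write_snp_weights(weights, simdir / "weights.tsv")
        inputs = {k: str(v) for k, v in paths.items()}
        inputs["weights"] = str(simdir / "weights.tsv")
        return cohort, weights, exposure, truth, inputs

    for key in ("weights", "dosages", "phenotypes", "meta"):
        if key not in raw:
            raise DataError(f"run config missing required key {key!r}")
        inputs[key] = str(raw[key])
    weights = read_snp_weights(raw["weights"])
    cohort = read_cohort(raw["dosages"], raw["phenotypes"], raw["meta"],
                         vcf=bool(raw.get("vcf", False)))
    exposure_name = raw.get("exposure")
    if exposure_name is None:
        roles = cohort.outcome_meta["role"] == "exposure"
        if roles.sum() != 1:
            raise DataError("config must name the exposure column")
        exposure_name = cohort.outcome_meta.index[roles][0]
    if exposure_name not in cohort.phenotypes.columns:
        raise DataError(f"exposure column {exposure_name!r} not found")
    exposure = cohort.phenotypes[exposure_name].to_numpy(dtype=float)
    phen = cohort.phenotypes.drop(columns=[exposure_name])
    meta = cohort.outcome_meta.drop(index=exposure_name, errors="ignore")
    cohort = Cohort(dosages=cohort.dosages, counted_allele=cohort.counted_allele,
                    phenotypes=phen, outcome_meta=meta)
    return cohort, weights, exposure, None, inputs


def _stage2_for_outcome(name: str, values: np.ndarray, hint: str,
                        exposure: np.ndarray, score) -> dict:
    prepared, kind = prepare_stage2_outcome(values, hint=hint)
    if kind == "linear" or kind == "continuous":
        est = tsls_linear(prepared, exposure, score, outcome_name=name)
        est.dwh_p = dwh_test(prepared, exposure, score.values)
        obs = observational_estimate(prepared, exposure, kind="linear")
    else:
        est = two_stage_logistic(prepared, exposure, score, outcome_name=name)
        obs = observational_estimate(prepared, exposure, kind="logistic")
    est.observational = obs
    return {"est": est, "prepared": prepared, "kind": est.kind,
            "transform_applied": hint}


def _iv_row(rank: float, est: IvEstimate, transform: str) -> dict:
    obs = est.observational or {}
    return {"rank": rank, "outcome": est.outcome_name, "kind": est.kind,
            "n": est.n, "iv_estimate": est.estimate, "iv_ci_low": est.ci_low,
            "iv_ci_high": est.ci_high, "iv_p": est.p_value,
            "obs_estimate": obs.get("estimate", np.nan),
            "obs_ci_low": obs.get("ci_low", np.nan),
            "obs_ci_high": obs.get("ci_high", np.nan),
            "obs_p": obs.get("p", np.nan), "dwh_p": est.dwh_p,
            "first_stage_F": est.first_stage_F,
            "transform_applied": transform, "note": est.notes}


def run_mrphewas(config_path: str | Path | None = None,
                 raw_config: Mapping | None = None,
                 **overrides) -> Path:
    """Run the full two-stage screen; returns the results directory."""
    if raw_config is None:
        if config_path is None:
            raise DataError("either a config path or a config mapping is required")
        raw_config = load_run_config(config_path)
    raw = dict(raw_config)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    config = PipelineConfig(
        alpha=float(raw.get("alpha", 0.05)),
        n_permutations=int(raw.get("n_permutations", 5000)),
        rng_seed=int(raw.get("seed", 0)),
        bonferroni_m=raw.get("bonferroni_m"),
        robust_se_flavor=raw.get("robust_se_flavor", "HC1"),
        int_offset=float(raw.get("int_offset", 0.0)),
        output_dir=str(raw.get("output_dir", "mrphewas_out")))

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    t0 = time.time()
    try:
        stage = "inputs"
        cohort, weights, exposure_raw, truth, inputs = _load_inputs(
            raw, config, outdir)
        if bool(raw.get("exposure_log", False)):
            if np.nanmin(exposure_raw) <= 0:
                raise DataError("exposure_log requested but exposure has values <= 0")
            exposure_raw = np.log(exposure_raw)
        exposure = _standardize_with_missing(exposure_raw)

        stage = "allele score"
        score = build_allele_score(cohort, weights)

        stage = "stage-1 screen"
        screen = PhenomeScreen(alpha=config.alpha, int_offset=config.int_offset,
                               robust_se_flavor=config.robust_se_flavor,
                               seed=_seed_int(config.child_seed("int")),
                               bonferroni_m=config.bonferroni_m)
        screen.fit(score, cohort)
        stage1 = screen.results_.copy()

        stage = "permutation"
        if config.n_permutations > 0:
            perm = permutation_rank_pvalues_from_screen(
                screen, B=config.n_permutations,
                seed=_seed_int(config.child_seed("permutation")))
            stage1 = stage1.merge(perm[["outcome", "p_permutation"]],
                                  on="outcome", how="left")
        else:
            stage1["p_permutation"] = np.nan
        cols = ["rank", "outcome", "n", "gamma_hat", "ci_low", "ci_high",
                "p_value", "p_bonferroni", "p_permutation", "validation_set",
                "skipped", "skip_reason"]
        p_stage1 = outdir / "stage1.tsv"
        write_results(stage1[cols], p_stage1)
        written.append(p_stage1)

        stage = "qq data"
        qq = screen.qq_data()
        qq["bonferroni_threshold"] = qq.attrs["bonferroni_threshold"]
        qq.to_csv(outdir / "qq.tsv", sep="\t", index=False,
                  float_format="%.10g")
        written.append(outdir / "qq.tsv")

        balance_rows = 0
        if raw.get("confounders"):
            stage = "confounder balance"
            conf = _read_delimited(raw["confounders"])
            conf = conf.set_index(conf.columns[0])
            conf = conf.loc[conf.index.intersection(cohort.phenotypes.index)]
            conf = conf.reindex(cohort.phenotypes.index)
            bal = confounder_balance(score, exposure, conf)
            bal.to_csv(outdir / "balance.tsv", sep="\t", index=False,
                       na_rep="NA", float_format="%.10g")
            written.append(outdir / "balance.tsv")
            balance_rows = len(bal)

        stage = "stage-2 IV"
        hits = stage1[(stage1["p_value"] < config.alpha)
                      & ~stage1["skipped"]].sort_values("rank")
        if bool(raw.get("skip_stage2", False)):
            hits = hits.iloc[:0]
        iv_rows, overid_rows, split_rows = [], [], []
        Z_snps = effect_allele_dosages(cohort, weights)
        single_snp = raw.get("single_snp")
        if single_snp is None:
            single_snp = weights.table.loc[
                weights.table["weight"].abs().idxmax(), "snp_id"]
        for _, hit in hits.iterrows():
            name = hit["outcome"]
            values = cohort.phenotypes[name].to_numpy(dtype=float)
            hint = cohort.outcome_meta.loc[name, "transform_hint"]
            try:
                res = _stage2_for_outcome(name, values, hint, exposure, score)
            except DataError as exc:
                logger.warning("stage-2 skipped for %s: %s", name, exc)
                iv_rows.append({"rank": hit["rank"], "outcome": name,
                                "kind": "skipped", "note": str(exc)})
                continue
            iv_rows.append(_iv_row(hit["rank"], res["est"],
                                   res["transform_applied"]))

            stage = "over-identification"
            prepared = res["prepared"]
            try:
                ov = cue_gmm(prepared, exposure, Z_snps, outcome_name=name)
                overid_rows.append({
                    "rank": hit["rank"], "outcome": name, "kind": res["kind"],
                    "beta_cue": ov.beta_cue, "se_cue": ov.se_cue,
                    "ci_low": ov.beta_cue - 1.959963984540054 * ov.se_cue,
                    "ci_high": ov.beta_cue + 1.959963984540054 * ov.se_cue,
                    "j_stat": ov.j_stat, "df": ov.df, "hansen_p": ov.p_j,
                    "n": ov.n, "weight_ridged": ov.weight_ridged})
                split = split_instrument_compare(
                    prepared, exposure, cohort, weights, single_snp,
                    kind="linear" if res["kind"] == "linear" else "logistic",
                    outcome_name=name)
                split_rows.append({
                    "rank": hit["rank"], "outcome": name,
                    "single_snp": single_snp,
                    "estimate_single": split.estimate_single.estimate,
                    "single_ci_low": split.estimate_single.ci_low,
                    "single_ci_high": split.estimate_single.ci_high,
                    "single_p": split.estimate_single.p_value,
                    "estimate_rest": split.estimate_rest.estimate,
                    "rest_ci_low": split.estimate_rest.ci_low,
                    "rest_ci_high": split.estimate_rest.ci_high,
                    "rest_p": split.estimate_rest.p_value,
                    "hansen_split_p": split.hansen_split_p})
            except DataError as exc:
                logger.warning("over-identification skipped for %s: %s", name, exc)
            stage = "stage-2 IV"

        iv_cols = ["rank", "outcome", "kind", "n", "iv_estimate", "iv_ci_low",
                   "iv_ci_high", "iv_p", "obs_estimate", "obs_ci_low",
                   "obs_ci_high", "obs_p", "dwh_p", "first_stage_F",
                   "transform_applied", "note"]
        write_results(pd.DataFrame(iv_rows, columns=iv_cols),
                      outdir / "stage2.tsv")
        overid_cols = ["rank", "outcome", "kind", "beta_cue", "se_cue",
                       "ci_low", "ci_high", "j_stat", "df", "hansen_p", "n",
                       "weight_ridged"]
        write_results(pd.DataFrame(overid_rows, columns=overid_cols),
                      outdir / "overid.tsv")
        split_cols = ["rank", "outcome", "single_snp", "estimate_single",
                      "single_ci_low", "single_ci_high", "single_p",
                      "estimate_rest", "rest_ci_low", "rest_ci_high",
                      "rest_p", "hansen_split_p"]
        write_results(pd.DataFrame(split_rows, columns=split_cols),
                      outdir / "split.tsv")
        written += [outdir / "stage2.tsv", outdir / "overid.tsv",
                    outdir / "split.tsv"]

        stage = "manifest"
        manifest = {
            "config": {k: v for k, v in raw.items() if k != "simulate"},
            "simulated": "simulate" in raw,
            "seed": config.rng_seed,
            "alpha": config.alpha,
            "n_permutations": config.n_permutations,
            "versions": {"mrphewas": __version__,
                         "numpy": np.__version__, "pandas": pd.__version__},
            "inputs": {k: {"path": v, "sha256": _checksum(Path(v))}
                       for k, v in inputs.items()},
            "counts": {"individuals": cohort.n_individuals,
                       "outcomes": len(cohort.outcome_names),
                       "stage1_records": len(stage1),
                       "stage1_hits": len(hits),
                       "stage2_records": len(iv_rows),
                       "overid_records": len(overid_rows),
                       "balance_rows": balance_rows},
            "multiplicity": {"m": screen.multiplicity_.m,
                             "k": screen.multiplicity_.k,
                             "expected_by_chance":
                                 screen.multiplicity_.expected_by_chance,
                             "fdr": None if np.isnan(screen.fdr_)
                                    else screen.fdr_},
            "elapsed_seconds": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return outdir
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
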