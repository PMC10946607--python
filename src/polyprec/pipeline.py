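"""End-to-end pipeline: dataset -> scores -> variance partition -> model tables.

Driven by a structured config (YAML or JSON) with sections::

    inputs:        # read an existing dataset ...
      dir: path/to/dataset            # roster.csv, events.csv, offspring.csv
    simulation:    # ... or simulate one (exactly one of the two)
      experiment: FM
      n_het: 20
      n_hom: 10
      params: {p_disp: 0.85, fecundity_mean: 20.0}
    scoring:
      ps_pooling: pooled              # or per_female_mean
      repetitive_convention: total    # or rematings
      order_prestart: exclude         # or from_first_mating
    partition:
      bucket_rule: unique             # or shared_split
      covariate: mate_mean_fecundity  # or group_mean_fecundity
    posthoc_trigger_p: 0.07
    output_dir: out
    seed: 1

Every artefact is written deterministically; a machine-readable run log
records package and library versions, the seed and a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .commonality import CommonalityModel, partition_by_treatment
from .errors import DegenerateInputError, NoDataError, PolyprecError
from .inference import (
    assortative_test,
    fit_order_glm,
    fit_repeat_glm,
    interaction_models,
    median_split,
    order_repeat_correlation,
    pairwise_contrasts,
)
from .records import Dataset, read_dataset, write_dataset
from .scoring import score_dataset
from .simulate import SimulationParams, simulate_experiment

logger = logging.getLogger("polyprec")

__all__ = ["load_config", "run_pipeline"]


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) pipeline config."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PolyprecError(f"config {path} did not parse to a mapping")
    return cfg


def _config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _get_dataset(config: Mapping[str, Any], seed: int | None) -> Dataset:
    if ("inputs" in config) == ("simulation" in config):
        raise PolyprecError("config must have exactly one of 'inputs' or 'simulation'")
    if "inputs" in config:
        inputs = config["inputs"]
        where = inputs["dir"] if "dir" in inputs else inputs
        return read_dataset(where)
    sim = dict(config["simulation"])
    params = SimulationParams(**sim.get("params", {}))
    return simulate_experiment(
        sim.get("experiment", "FM"),
        n_het=int(sim.get("n_het", 20)),
        n_hom=int(sim.get("n_hom", 10)),
        params=params,
        rng=np.random.default_rng(seed),
    )


def run_pipeline(
    config: Mapping[str, Any] | str | Path, seed: int | None = None
) -> dict[str, Any]:
    """Run the full analysis described by ``config``; returns artefact paths
    and in-memory results."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    seed = seed if seed is not None else config.get("seed")
    out_dir = Path(config.get("output_dir", "polyprec_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load data"
    try:
        ds = _get_dataset(config, seed)
        if not ds.vials:
            raise NoDataError("dataset contains zero vials")

        stage = "score"
        scoring_cfg = dict(config.get("scoring", {}))
        scores = score_dataset(
            ds,
            ps_pooling=scoring_cfg.get("ps_pooling", "pooled"),
            repetitive_convention=scoring_cfg.get("repetitive_convention", "total"),
            order_prestart=scoring_cfg.get("order_prestart", "exclude"),
        )
        scores_path = out_dir / "scores.csv"
        scores.to_csv(scores_path, index=False, lineterminator="\n")
        if "simulation" in config:
            write_dataset(ds, out_dir / "dataset")

        stage = "partition"
        part_cfg = dict(config.get("partition", {}))
        covariate = part_cfg.get("covariate", "mate_mean_fecundity")
        bucket_rule = part_cfg.get("bucket_rule", "unique")
        partition = partition_by_treatment(
            scores, bucket_rule=bucket_rule, covariates=(covariate,)
        )
        partition_path = out_dir / "partition.csv"
        partition.to_csv(partition_path, index=False, lineterminator="\n")
        commonality_json: dict[str, Any] = {}
        experiments = (
            sorted(scores["experiment"].dropna().unique())
            if "experiment" in scores.columns
            else ["ALL"]
        )
        results_by_exp = {}
        for exp in experiments:
            sub = scores if exp == "ALL" else scores[scores["experiment"] == exp]
            try:
                res = CommonalityModel(sub, covariates=(covariate,)).fit(bucket_rule)
            except (DegenerateInputError, PolyprecError) as exc:
                logger.warning("commonality for %s skipped: %s", exp, exc)
                continue
            results_by_exp[exp] = res
            commonality_json[exp] = res.to_dict()
        (out_dir / "commonality.json").write_text(
            json.dumps(commonality_json, indent=2, sort_keys=True), encoding="utf-8"
        )

        stage = "fit"
        model_tables = []
        posthoc_p = float(config.get("posthoc_trigger_p", 0.07))
        posthocs = []
        for exp in experiments:
            sub = scores if exp == "ALL" else scores[scores["experiment"] == exp]
            for fitter, label in ((fit_order_glm, "order"), (fit_repeat_glm, "repeat")):
                try:
                    table = fitter(sub, name=f"{label} GLM ({exp})")
                except (DegenerateInputError, NoDataError, PolyprecError) as exc:
                    logger.warning("%s GLM for %s skipped: %s", label, exp, exc)
                    continue
                model_tables.append(table)
                if (table.terms["p"] < posthoc_p).any() and sub["social"].nunique() > 1:
                    response = "order_index" if label == "order" else "repetitive_count"
                    cells = sub.assign(
                        cell=sub["social"] + "/" + sub["focal_size"]
                    )
                    try:
                        ph = pairwise_contrasts(cells, response, "cell")
                        ph.insert(0, "model", f"{label} GLM ({exp})")
                        posthocs.append(ph)
                    except DegenerateInputError:
                        pass
            try:
                inter = interaction_models(sub)
                model_tables.extend(inter.values())
            except (DegenerateInputError, NoDataError) as exc:
                logger.warning("interaction models for %s skipped: %s", exp, exc)
            if exp in ("F", "FM"):
                try:
                    model_tables.append(assortative_test(ds, exp))
                except (DegenerateInputError, NoDataError) as exc:
                    logger.info("assortative test for %s skipped: %s", exp, exc)

        models_txt = "\n\n".join(t.summary() for t in model_tables)
        (out_dir / "models.txt").write_text(models_txt + "\n", encoding="utf-8")
        terms_rows = []
        for t in model_tables:
            tt = t.terms.copy()
            tt.insert(0, "model", t.name)
            tt["family"] = t.family
            tt["dispersion"] = t.dispersion
            terms_rows.append(tt)
        models_csv = (
            pd.concat(terms_rows, ignore_index=True) if terms_rows else pd.DataFrame()
        )
        models_csv.to_csv(out_dir / "models.csv", index=False, lineterminator="\n")
        if posthocs:
            pd.concat(posthocs, ignore_index=True).to_csv(
                out_dir / "posthoc.csv", index=False, lineterminator="\n"
            )

        stage = "median split"
        split = median_split(scores)
        split.to_csv(out_dir / "median_split.csv", index=False, lineterminator="\n")

        stage = "correlation"
        try:
            corr_r, corr_p = order_repeat_correlation(scores)
        except (DegenerateInputError, NoDataError) as exc:
            logger.warning("order/repeat correlation skipped: %s", exc)
            corr_r = corr_p = float("nan")
    except PolyprecError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    runlog = {
        "polyprec": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config_hash": _config_hash(dict(config)),
        "n_vials": len(ds.vials),
        "n_events": int(len(ds.events)),
        "n_offspring_batches": int(len(ds.offspring)),
        "order_repeat_correlation": {"r": corr_r, "p": corr_p},
    }
    (out_dir / "runlog.json").write_text(
        json.dumps(runlog, indent=2, sort_keys=True), encoding="utf-8"
    )
    return {
        "dataset": ds,
        "scores": scores,
        "partition": partition,
        "commonality": results_by_exp,
        "model_tables": model_tables,
        "median_split": split,
        "correlation": (corr_r, corr_p),
        "paths": {
            "scores": scores_path,
            "partition": partition_path,
            "out_dir": out_dir,
        },
        "runlog": runlog,
    }
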