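"""Stage runners tying ingestion, fitting and selection together.

Each runner reads/writes plain TSV/JSON artifacts in an output directory
so stages can be run independently or chained (see :mod:`aadfe.cli`).
All randomness flows from the single configured seed; identical config
plus seed produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dfestats, ingest, selection, synthetic
from .ingest import AMINO_ACIDS, AssayTable, TypeDFE

log = logging.getLogger("aadfe")

__all__ = [
    "ConfigError",
    "DataError",
    "load_config",
    "run_simulate",
    "run_rank",
    "run_fit",
    "run_selection",
]

LONG_TSV = "quantiles_long.tsv"
SUMMARY_TSV = "type_summary.tsv"
REPORTS_TSV = "dfe_reports.tsv"
AGGREGATE_JSON = "aggregate_summary.json"
LAMBDA_TSV = "lambda_matrix.tsv"
MEAN_TSV = "mean_quantile_matrix.tsv"
DYNRANGE_TSV = "dynamic_range_vs_q.tsv"
SELECTION_JSON = "selection_summary.json"


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Unusable input data (CLI exit code 3)."""


def load_config(path) -> dict:
    import yaml

    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if "seed" not in cfg:
        raise ConfigError(f"{path}: 'seed' is required")
    return cfg


def _outdir(config: dict) -> Path:
    out = Path(config.get("output_dir", "aadfe_out"))
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: dict) -> Path:
    """Generate synthetic assay CSVs plus the ground-truth lambda matrix."""
    out = _outdir(config)
    syn = config.get("synthetic", {})
    seed = int(config["seed"])
    regime = syn.get("regime", "fitness")
    n_assays = int(syn.get("n_assays", 20))
    muts = int(syn.get("muts_per_assay", 19_000))
    if regime == "stability":
        scenario = synthetic.gen_stability_scenario(
            seed, n_assays=n_assays, muts_per_assay=muts
        )
    else:
        mean_range = tuple(syn.get("mean_range", synthetic.DEFAULT_MEAN_RANGE))
        scenario = synthetic.SyntheticScenario(
            lambda_star=synthetic.gen_lambda_matrix(seed, mean_range),
            seed=seed,
            n_assays=n_assays,
            muts_per_assay=muts,
        )
    assay_dir = out / "assays"
    assay_dir.mkdir(exist_ok=True)
    for i in range(scenario.n_assays):
        assay = synthetic.gen_assay(scenario, i)
        pd.DataFrame(assay.records, columns=["mutant", "score"]).to_csv(
            assay_dir / f"{assay.assay_id}.csv", index=False, float_format="%.10g"
        )
    scenario.lambda_star.to_tsv(out / "lambda_star.tsv")
    log.info("simulate: wrote %d assays to %s", scenario.n_assays, assay_dir)
    return assay_dir


def _load_assays(config: dict) -> list[AssayTable]:
    rank_cfg = config.get("rank", {})
    input_dir = Path(rank_cfg.get("input_dir", _outdir(config) / "assays"))
    if not input_dir.is_dir():
        raise ConfigError(f"assay input directory not found: {input_dir}")
    paths = sorted(input_dir.glob("*.csv")) + sorted(input_dir.glob("*.tsv"))
    if not paths:
        raise ConfigError(f"no assay files (*.csv, *.tsv) in {input_dir}")
    dialect = rank_cfg.get("dialect", "generic")
    orientation = rank_cfg.get("higher_is_fitter", True)
    try:
        return [
            ingest.read_assay_csv(
                p, dialect=dialect, higher_is_fitter=bool(orientation)
            )
            for p in paths
        ]
    except ValueError as err:
        raise DataError(str(err)) from err


def run_rank(config: dict) -> dict:
    """Rank all assays and pool quantiles by replacement type."""
    out = _outdir(config)
    assays = _load_assays(config)
    dfes, long, dropped = ingest.pool_by_type(assays)
    if long.empty:
        raise DataError("no usable single-missense records in any assay")
    long.to_csv(out / LONG_TSV, sep="\t", index=False, float_format="%.10g")
    summary = (
        long.groupby(["from_aa", "to_aa"], sort=True)["quantile"]
        .agg(n="size", mean_quantile="mean")
        .reset_index()
    )
    summary.to_csv(out / SUMMARY_TSV, sep="\t", index=False, float_format="%.10g")
    n_kept = len(long)
    n_drop = sum(dropped.values())
    log.info(
        "rank: %d assays, %d records retained, %d dropped (%s), %d types",
        len(assays),
        n_kept,
        n_drop,
        dropped or "none",
        len(dfes),
    )
    return dfes


def _load_dfes(config: dict) -> dict:
    out = _outdir(config)
    path = out / LONG_TSV
    if not path.is_file():
        raise ConfigError(f"{path} not found; run the rank stage first")
    long = pd.read_csv(path, sep="\t")
    return {
        (fa, ta): TypeDFE((fa, ta), grp["quantile"].to_numpy())
        for (fa, ta), grp in long.groupby(["from_aa", "to_aa"], sort=True)
    }


def run_fit(config: dict) -> dict:
    """Fit lambda per type and run the full DFE test battery."""
    out = _outdir(config)
    dfes = _load_dfes(config)
    fit_cfg = config.get("fit", {})
    skipped = sorted(p for p, d in dfes.items() if d.n < 4)
    for p in skipped:
        log.warning("fit: type %s->%s has n=%d < 4; split-half test skipped", *p, dfes[p].n)
    reports, aggregate = dfestats.summarize_all(
        dfes,
        seed=int(config["seed"]),
        nbins=int(fit_cfg.get("nbins", 15)),
        alpha=float(fit_cfg.get("alpha", 0.05)),
    )
    reports.to_csv(out / REPORTS_TSV, sep="\t", index=False, float_format="%.10g")
    with open(out / AGGREGATE_JSON, "w") as fh:
        json.dump(aggregate, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lam = selection.LambdaMatrix(
        {
            (r.from_aa, r.to_aa): float(r.lambda_hat)
            for r in reports.itertuples()
            if np.isfinite(r.lambda_hat)
        },
        provenance="fitted",
    )
    lam.to_tsv(out / LAMBDA_TSV)
    mean_frame = pd.DataFrame(
        np.nan, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
    )
    for r in reports.itertuples():
        mean_frame.loc[r.from_aa, r.to_aa] = r.mean_quantile
    mean_frame.index.name = "from_aa"
    mean_frame.to_csv(out / MEAN_TSV, sep="\t", float_format="%.10g")
    log.info(
        "fit: %d types fitted, %d uniform-indistinguishable, fit pass fraction %.3f",
        aggregate["n_types"],
        aggregate["n_uniform_indistinguishable"],
        aggregate["fit_pass_fraction"],
    )
    return aggregate


def run_selection(config: dict) -> dict:
    """Predict exchangeability over a stringency grid, compare to observed U."""
    out = _outdir(config)
    lam_path = out / LAMBDA_TSV
    if not lam_path.is_file():
        raise ConfigError(f"{lam_path} not found; run the fit stage first")
    lm = selection.LambdaMatrix.from_tsv(lam_path)
    sel_cfg = config.get("select", {})
    q_grid = [float(q) for q in sel_cfg.get("q_grid", [0.0, 0.5, 0.9, selection.Q_NEAR_ONE])]
    observed = None
    if sel_cfg.get("observed_u"):
        obs_path = Path(sel_cfg["observed_u"])
        if not obs_path.is_file():
            raise ConfigError(f"observed-U table not found: {obs_path}")
        observed = selection.read_observed_u(obs_path)
    rows = []
    result: dict = {"q_grid": q_grid, "comparisons": []}
    for q in q_grid:
        try:
            pred = selection.predict_U(lm, q)
        except ValueError as err:
            raise DataError(str(err)) from err
        tag = f"{q:.6f}".rstrip("0").rstrip(".").replace(".", "p")
        selection.write_u_table(pred, out / f"predicted_u_q{tag}.tsv")
        row = {"q": q, "dynamic_range_pred": pred.dynamic_range}
        if observed is not None:
            try:
                r, dr_p, dr_o = selection.compare_U(pred, observed)
            except ValueError as err:
                raise DataError(str(err)) from err
            row.update(pearson_r=r, dynamic_range_obs=dr_o)
            result["comparisons"].append({"q": q, "pearson_r": r})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / DYNRANGE_TSV, sep="\t", index=False, float_format="%.10g")
    result["dynamic_range"] = rows
    with open(out / SELECTION_JSON, "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("selection: %d stringency values evaluated", len(q_grid))
    return result
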