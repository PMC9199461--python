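"""End-to-end orchestration: simulate -> QC -> metrics -> fit.

A run is fully described by a :class:`RunConfig`; identical configs
produce byte-identical output bundles.  Every stage writes plain CSV,
and the bundle carries a manifest (config, seed, stage record counts,
file checksums) so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, SimulationConfig
from .design import generate_design
from .inference import bootstrap_ci, effect_tests, endpoint_spec, fit_lmm, prune_interactions, r2_mixed
from .metrics import MODELING_CUTOFF_DOY, compute_tree_metrics
from .qc import MeasurementSchedule, run_qc
from .simulate import read_dataset, simulate_experiment, write_dataset

__all__ = ["RunConfig", "run_pipeline", "summarize_by_treatment", "fit_endpoint_models"]

ENDPOINT_RESPONSES = ("doy_50pct", "total_autumn_photo", "total_rel_carbon_gain")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 0
    out_dir: str = "phenosink_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cutoff_doy: int = MODELING_CUTOFF_DOY
    n_boot: int = 1000
    alpha: float = 0.05
    data_dir: str | None = None  # read observed tables instead of simulating

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def summarize_by_treatment(
    df: pd.DataFrame, value_col: str, by: tuple[str, ...] = ("treatment", "doy")
) -> pd.DataFrame:
    """Per-group mean and standard error (SD / sqrt(n)).

    Groups of size one get an undefined (NaN) SE and are flagged.
    """
    if len(df) == 0:
        raise ValueError("nothing to summarize")
    g = df.groupby(list(by))[value_col]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["se_defined"] = out["n"] > 1
    return out.drop(columns=["sd"])


def fit_endpoint_models(
    metrics_frame: pd.DataFrame, n_boot: int, seed: int, alpha: float = 0.05
) -> dict[str, dict]:
    """Fit the three endpoint models with pruning, tests, R2 and CIs."""
    results = {}
    for i, response in enumerate(ENDPOINT_RESPONSES):
        data = metrics_frame
        if response == "doy_50pct":
            data = data[data["doy_50pct_defined"]]
        spec, prune_log = prune_interactions(endpoint_spec(response), data, alpha=alpha)
        fit = fit_lmm(spec, data)
        fit.pruned_terms = tuple(t for t, _ in prune_log)
        tests = effect_tests(fit, data)
        r2m, r2c = r2_mixed(fit)
        preds = bootstrap_ci(fit, n_sim=n_boot, seed=seed + i) if n_boot > 0 else None
        results[response] = {
            "fit": fit, "tests": tests, "r2_marginal": r2m, "r2_conditional": r2c,
            "predictions": preds, "pruned": prune_log,
        }
    return results


def run_pipeline(run_config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write the output bundle.

    Stages: (1) simulate the experiment (or read observed tables),
    (2) clean the gas-exchange records, (3) derive per-tree metrics,
    (4) fit the endpoint mixed models with bootstrap intervals,
    (5) write treatment-level summaries and a manifest.

    Raises with the stage name on any stage failure.  Returns the
    result bundle (tables, fits, manifest) in memory as well.
    """
    out_dir = run_config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    sim_cfg = run_config.simulation.replace(seed=run_config.seed)

    # -- stage: data ----------------------------------------------------
    try:
        if run_config.data_dir is None:
            design = generate_design(run_config.seed)
            if len(design) == 0:
                raise ConfigError("empty design")
            tables = simulate_experiment(design, sim_cfg)
        else:
            tables = read_dataset(run_config.data_dir)
        write_dataset(tables, out_dir, year=sim_cfg.year, overwrite=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate': {exc}") from exc

    # -- stage: qc ------------------------------------------------------
    try:
        schedule = MeasurementSchedule.from_config(sim_cfg)
        clean, qc_log = run_qc(tables["photosynthesis"], schedule)
        clean.to_csv(os.path.join(out_dir, "photosynthesis_clean.csv"), index=False)
        qc_log.to_csv(os.path.join(out_dir, "qc_log.csv"), index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'qc': {exc}") from exc

    # -- stage: metrics -------------------------------------------------
    try:
        met = compute_tree_metrics(
            clean, tables["counts"], tables["spad"],
            sim_cfg.leaf_removal_1_doy, cutoff_doy=run_config.cutoff_doy,
        )
        frame = met.merge(tables["trees"], on="tree_id").rename(
            columns={"leaf_removal_pct": "leaf_pct", "bud_removal_pct": "bud_pct"}
        )
        frame.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'metrics': {exc}") from exc

    # -- stage: fit -----------------------------------------------------
    try:
        fits = fit_endpoint_models(
            frame, n_boot=run_config.n_boot, seed=run_config.seed, alpha=run_config.alpha
        )
        coef_rows, test_rows, pred_rows = [], [], []
        for response, res in fits.items():
            fit = res["fit"]
            for name in fit.params.index:
                coef_rows.append((response, name, fit.params[name], fit.bse[name],
                                  fit.pvalues[name], res["r2_marginal"],
                                  res["r2_conditional"], fit.converged))
            for term, row in res["tests"].iterrows():
                test_rows.append((response, term, row["statistic"], row["df"], row["p"]))
            if res["predictions"] is not None:
                p = res["predictions"].copy()
                p.attrs = {}  # bootstrap draws are not part of the CSV artifact
                p.insert(0, "response", response)
                pred_rows.append(p)
        pd.DataFrame(coef_rows, columns=["response", "coefficient", "estimate", "se",
                                         "p", "r2_marginal", "r2_conditional",
                                         "converged"]).to_csv(
            os.path.join(out_dir, "coefficients.csv"), index=False)
        pd.DataFrame(test_rows, columns=["response", "term", "statistic", "df", "p"]
                     ).to_csv(os.path.join(out_dir, "tests.csv"), index=False)
        if pred_rows:
            pd.concat(pred_rows, ignore_index=True).to_csv(
                os.path.join(out_dir, "predictions.csv"), index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit': {exc}") from exc

    # -- stage: report --------------------------------------------------
    try:
        spad_summary = summarize_by_treatment(
            tables["spad"].merge(tables["trees"][["tree_id", "treatment"]], on="tree_id"),
            "avg_spad",
        )
        spad_summary.to_csv(os.path.join(out_dir, "spad_by_treatment.csv"), index=False)

        files = sorted(f for f in os.listdir(out_dir) if f.endswith(".csv"))
        manifest = {
            "package_version": __version__,
            "seed": run_config.seed,
            "config": run_config.to_dict(),
            "n_trees": int(tables["trees"].shape[0]),
            "n_photosynthesis_intervals": len(sim_cfg.photosynthesis_doys),
            "n_count_spad_intervals": len(sim_cfg.counts_spad_doys),
            "record_counts": {
                "counts": int(len(tables["counts"])),
                "spad": int(len(tables["spad"])),
                "photosynthesis": int(len(tables["photosynthesis"])),
                "photosynthesis_clean": int(len(clean)),
                "metrics": int(len(frame)),
            },
            "files": {f: _checksum(os.path.join(out_dir, f)) for f in files},
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"stage 'report': {exc}") from exc

    return {"tables": tables, "clean": clean, "qc_log": qc_log, "metrics": frame,
            "fits": fits, "manifest": manifest}


def plot_treatment_series(summary: pd.DataFrame, value_label: str, path: str) -> None:
    """Optional figure: per-treatment means with +/- 1 SE error bars.

    Every figure has a CSV twin (the summary table itself); nothing
    downstream reads pixels.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for treatment, g in summary.groupby("treatment"):
        ax.errorbar(g["doy"], g["mean"], yerr=g["se"], label=treatment, capsize=2)
    ax.set_xlabel("day of year")
    ax.set_ylabel(value_label)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
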