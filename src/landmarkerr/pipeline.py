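"""End-to-end orchestration: read, convert units, measure, QC, and run
the precision / repeatability / difference analyses, writing CSV
reports and a JSON summary."""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .differences import (
    DistanceDifferences,
    percentage_error,
    repeatability_length_correlation,
)
from .distances import QCConfig, distance_table, flag_gross_errors
from .io import LandmarkDataset, convert_units, read_landmark_table
from .precision import LandmarkPrecision
from .reliability import DistanceRepeatability

log = logging.getLogger("landmarkerr")


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    input_path: str | None = None
    dialect: str = "long_csv"
    unit_factors: dict[str, float] = field(default_factory=dict)  # method -> mm per unit
    qc_default_threshold: float = 0.5
    qc_small_threshold: float = 0.3
    qc_small_mean_cutoff: float = 3.0
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100
    use_sides: str = "midline_and_left"
    run_precision: bool = True
    run_repeatability: bool = True
    run_differences: bool = True
    run_correlation: bool = True
    between_pairs: list[list[str]] | None = None  # None -> all method pairs
    strict_qc: bool = False
    output_dir: str = "landmarkerr_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def qc(self) -> QCConfig:
        return QCConfig(
            default_threshold=self.qc_default_threshold,
            small_threshold=self.qc_small_threshold,
            small_mean_cutoff=self.qc_small_mean_cutoff,
        )


def run_pipeline(config: PipelineConfig, dataset: LandmarkDataset | None = None) -> dict:
    """Execute the full analysis on a dataset (read from
    ``config.input_path`` unless passed directly).

    Stage order: read -> unit conversion -> distance extraction + QC ->
    landmark precision -> repeatability (within every method, between
    the requested pairs) -> differences + percentage error ->
    repeatability-length correlation.  Reports are written under
    ``config.output_dir``; the returned dict carries the in-memory
    results keyed by stage.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    logpath = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(logpath, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": []}
    out: dict = {}
    try:
        log.info("landmarkerr %s, seed %d", __version__, config.seed)

        if dataset is None:
            if config.input_path is None:
                raise ValueError("stage read: no input_path and no dataset given")
            log.info("reading %s (%s)", config.input_path, config.dialect)
            dataset = read_landmark_table(config.input_path, dialect=config.dialect)
        summary["stages"].append("read")

        for method, factor in config.unit_factors.items():
            if any(c.units == "voxel" for c in dataset.select(method=method)):
                log.info("converting %s to mm (factor %g)", method, factor)
                dataset = convert_units(dataset, method, factor)
        voxel_methods = sorted({c.method for c in dataset.configurations if c.units == "voxel"})
        if voxel_methods:
            raise ValueError(
                f"stage convert_units: methods {voxel_methods} are in voxel units and "
                "no unit_factors entry was given"
            )
        summary["stages"].append("convert_units")
        out["dataset"] = dataset

        table = distance_table(dataset)
        table.to_csv(os.path.join(config.output_dir, "distances.csv"))
        qc_report = flag_gross_errors(table, config.qc())
        qc_report.to_csv(os.path.join(config.output_dir, "qc_report.csv"))
        log.info("QC: %d gross-error flags", qc_report.n_flags)
        if qc_report.n_flags and config.strict_qc:
            raise ValueError(f"stage qc: {qc_report.n_flags} gross-error flags (strict mode)\n{qc_report}")
        summary["stages"].append("distances+qc")
        summary["qc_flags"] = int(qc_report.n_flags)
        out["table"], out["qc"] = table, qc_report

        methods = dataset.methods
        if config.run_precision:
            out["precision"] = {}
            summary["precision"] = {}
            for m in methods:
                res = LandmarkPrecision(
                    dataset, m, use_sides=config.use_sides,
                    tol=config.gpa_tol, max_iter=config.gpa_max_iter,
                ).fit()
                res.per_landmark.to_csv(
                    os.path.join(config.output_dir, f"precision_{m}.csv"), index=False
                )
                out["precision"][m] = res
                summary["precision"][m] = {
                    "mean_dev_mm": float(res.per_landmark["mean_dev_mm"].mean()),
                    "range_mm": [
                        float(res.per_landmark["mean_dev_mm"].min()),
                        float(res.per_landmark["mean_dev_mm"].max()),
                    ],
                }
                log.info("precision %s: mean deviation %.4f mm", m, summary["precision"][m]["mean_dev_mm"])
            summary["stages"].append("precision")

        pairs = (
            [tuple(p) for p in config.between_pairs]
            if config.between_pairs is not None
            else list(itertools.combinations(methods, 2))
        )

        if config.run_repeatability:
            out["repeatability"] = {}
            summary["repeatability"] = {}
            rep_rows = []
            for key in [((m,)) for m in methods] + pairs:
                res = DistanceRepeatability(table, key).fit()
                out["repeatability"][res.dataset_label] = res
                summary["repeatability"][res.dataset_label] = {
                    "mean_r": res.mean_r, "sd_r": res.sd_r,
                }
                df = res.per_distance.copy()
                df.insert(0, "dataset", res.dataset_label)
                rep_rows.append(df)
                log.info("repeatability %s: mean r %.3f +- %.3f", res.dataset_label, res.mean_r, res.sd_r)
            import pandas as pd

            pd.concat(rep_rows, ignore_index=True).to_csv(
                os.path.join(config.output_dir, "repeatability.csv"), index=False
            )
            summary["stages"].append("repeatability")

        if config.run_differences:
            out["differences"] = {}
            summary["differences"] = {}
            diff_rows = []
            for key in [((m,)) for m in methods] + pairs:
                res = DistanceDifferences(table, key).fit()
                res = percentage_error(res, table, methods=list(key))
                out["differences"][res.pairing_label] = res
                raw_m, raw_s = res.summary_raw
                abs_m, abs_s = res.summary_abs
                pct_m, pct_s = res.summary_pct
                summary["differences"][res.pairing_label] = {
                    "raw": [raw_m, raw_s], "abs": [abs_m, abs_s], "pct": [pct_m, pct_s],
                }
                df = res.per_distance.copy()
                df.insert(0, "pairing", res.pairing_label)
                diff_rows.append(df)
                log.info(
                    "differences %s: raw %+.3f, abs %.3f, %%mean %.1f",
                    res.pairing_label, raw_m, abs_m, pct_m,
                )
            import pandas as pd

            pd.concat(diff_rows, ignore_index=True).to_csv(
                os.path.join(config.output_dir, "differences.csv"), index=False
            )
            summary["stages"].append("differences")

        if config.run_correlation and config.run_repeatability:
            summary["correlation"] = {}
            out["correlation"] = {}
            for a, b in pairs:
                rep = out["repeatability"][f"{a} + {b}"]
                try:
                    corr = repeatability_length_correlation(rep, table, methods=[a, b])
                except ValueError as exc:
                    log.warning("correlation %s + %s skipped: %s", a, b, exc)
                    continue
                out["correlation"][f"{a} + {b}"] = corr
                summary["correlation"][f"{a} + {b}"] = {
                    "r": corr.r, "df": corr.df, "t": corr.t_statistic, "p": corr.p_value,
                }
                log.info("correlation %s + %s: %s", a, b, corr.summary())
            summary["stages"].append("correlation")

        with open(os.path.join(config.output_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        log.info("done: %s", ", ".join(summary["stages"]))
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
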