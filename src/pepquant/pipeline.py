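"""End-to-end orchestration of the label-free peptidomics analysis.

Stage order follows the study workflow: log2 transform (when raw), removal of
pre-specified outlier runs, advisory low-intensity flagging, calibration to
the median reference run, per-peptide run-order drift correction, group
missingness filtering, collapsing of technical replicates, then the four
analysis branches (group-median transform + two-way hierarchical clustering,
PCA, PLS-DA with VIP and jackknife intervals, and the per-peptide factorial
differential table).  Every run writes a JSON manifest with parameters, the
seed and per-stage record counts; identical config and inputs reproduce the
output bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataio import (IntensityMatrix, group_labels, read_design, read_matrix,
                     drop_runs, write_design, write_matrix)
from .differential import analyze_all
from .multivariate import (fit_pca, fit_plsda, group_median_transform,
                           hierarchical_cluster, jackknife_vip,
                           linkage_to_newick)
from .normalize import (calibrate_to_reference, collapse_technical_replicates,
                        correct_run_order, filter_min_matching,
                        flag_outlier_runs, log2_transform)
from .simulate import SimulationConfig, generate_design, simulate_intensities

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "design", "matrix", "out_dir", "span", "min_match_frac",
    "max_missing_per_group", "pre_drop_runs", "post_pca_drop_runs",
    "outlier_k", "n_components_pca", "n_components_plsda", "cv_folds",
    "fdr_alpha", "seed", "plsda_classes", "jackknife", "raw_scale",
}


@dataclass
class PipelineConfig:
    design: str | None = None            # TSV paths; None -> simulate
    matrix: str | None = None
    out_dir: str = "pepquant_out"
    span: float = 0.5
    min_match_frac: float = 0.5
    max_missing_per_group: int = 1
    pre_drop_runs: list = field(default_factory=list)     # e.g. degraded samples
    post_pca_drop_runs: list = field(default_factory=list)  # low-intensity outliers
    outlier_k: float = 3.0
    n_components_pca: int = 2
    n_components_plsda: int = 3
    cv_folds: int = 7
    fdr_alpha: float = 0.05
    seed: int = 0
    plsda_classes: str = "age_treatment"  # or "age", "group"
    jackknife: bool = True
    raw_scale: bool = False               # True if the input matrix is raw intensity

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _class_labels(design: pd.DataFrame, scheme: str) -> pd.Series:
    if scheme == "age":
        lab = design["age"]
    elif scheme == "age_treatment":
        lab = design["age"].str.cat(design["treatment"])
    elif scheme == "group":
        lab = design["age"].str.cat([design["sex"], design["treatment"]])
    else:
        raise ValueError(f"unknown class scheme {scheme!r}")
    return pd.Series(lab.to_numpy(), index=design["run_id"].to_numpy())


def _write_df(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label,
              lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "pepquant",
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": [],
    }

    def log(stage: str, **counts):
        manifest["stages"].append({"stage": stage, **counts})

    try:
        if config.design is None or config.matrix is None:
            sim = SimulationConfig(seed=config.seed)
            design = generate_design(sim)
            matrix, _ = simulate_intensities(sim, design)
            log("simulate", peptides=len(matrix.peptide_ids), runs=len(design))
        else:
            design = read_design(config.design)
            matrix = read_matrix(config.matrix, design,
                                 state=("raw",) if config.raw_scale else ("log2",))
            log("load", peptides=len(matrix.peptide_ids), runs=len(design))

        if matrix.has_state("raw"):
            matrix = log2_transform(matrix)
            log("log2", peptides=len(matrix.peptide_ids))

        if config.pre_drop_runs:
            matrix, design = drop_runs(matrix, design, config.pre_drop_runs)
            log("pre_drop", dropped=len(config.pre_drop_runs), runs=len(design))

        flags = flag_outlier_runs(matrix, k=config.outlier_k)
        log("flag_outliers", flagged=len(flags))
        manifest["flagged_runs"] = [{"run_id": r, "reason": why} for r, why in flags]

        if config.post_pca_drop_runs:
            matrix, design = drop_runs(matrix, design, config.post_pca_drop_runs)
            log("post_pca_drop", dropped=len(config.post_pca_drop_runs),
                runs=len(design))

        matrix, cal_fits = calibrate_to_reference(
            matrix, min_match_frac=config.min_match_frac)
        log("calibrate", runs=len(cal_fits))
        manifest["calibration"] = [
            {"run_id": f.run_id, "slope": f.slope, "intercept": f.intercept,
             "n_shared": f.n_shared} for f in cal_fits]

        matrix, drift_fits = correct_run_order(matrix, design, span=config.span)
        n_uncorrected = sum(not f.corrected for f in drift_fits)
        log("drift_correct", peptides=len(drift_fits), uncorrected=n_uncorrected)

        groups = group_labels(design)
        before = len(matrix.peptide_ids)
        matrix = filter_min_matching(matrix, groups,
                                     config.max_missing_per_group)
        log("filter_min_matching", before=before, after=len(matrix.peptide_ids))

        matrix, design = collapse_technical_replicates(matrix, design)
        log("collapse_replicates", runs=len(design))
        groups = group_labels(design)

        write_matrix(matrix, out / "normalized_matrix.tsv")
        write_design(design, out / "analysis_design.tsv")

        # group-median transform + two-way clustering
        gm = group_median_transform(matrix.values, groups)
        _write_df(gm, out / "group_medians.tsv", "peptide")
        complete = matrix.values.dropna(axis=0)
        if len(complete) >= 2 and complete.shape[1] >= 2:
            trees = hierarchical_cluster(complete, axis="both")
            (out / "clustering_rows.nwk").write_text(
                linkage_to_newick(trees["rows"], complete.index) )
            (out / "clustering_columns.nwk").write_text(
                linkage_to_newick(trees["columns"], complete.columns))
            log("cluster", complete_peptides=len(complete))

        # multivariate models run on complete-case observations x peptides
        X = complete.T.to_numpy()
        pep_ids = list(complete.index)
        run_ids = list(complete.columns)

        pca = fit_pca(X, n_components=config.n_components_pca,
                      cv_folds=config.cv_folds)
        scores = pd.DataFrame(pca.scores_, index=run_ids,
                              columns=[f"C{a+1}" for a in range(pca.scores_.shape[1])])
        scores["t2"] = pca.t2_
        scores["dmodx"] = pca.dmodx_
        _write_df(scores, out / "pca_scores.tsv", "run_id")
        log("pca", r2x_cum=float(pca.r2x_cum_[-1]),
            q2_cum=float(pca.q2_cum_[-1]) if np.isfinite(pca.q2_cum_[-1]) else None)

        classes = _class_labels(design, config.plsda_classes).loc[run_ids]
        pls = fit_plsda(X, classes.to_numpy(),
                        n_components=config.n_components_plsda,
                        cv_folds=config.cv_folds)
        pls_scores = pd.DataFrame(
            pls.x_scores_, index=run_ids,
            columns=[f"t{a+1}" for a in range(pls.x_scores_.shape[1])])
        pls_scores["class"] = classes.to_numpy()
        _write_df(pls_scores, out / "plsda_scores.tsv", "run_id")
        vip_df = pd.DataFrame({"vip": pls.vip_}, index=pep_ids)
        if config.jackknife:
            jk = jackknife_vip(X, classes.to_numpy(),
                               n_components=config.n_components_plsda)
            vip_df["ci_lower"] = jk.lower
            vip_df["ci_upper"] = jk.upper
            vip_df["se"] = jk.se
        _write_df(vip_df, out / "plsda_vip.tsv", "peptide")
        log("plsda", r2y_cum=float(pls.r2y_cum_[-1]),
            q2_cum=float(pls.q2_cum_[-1]) if np.isfinite(pls.q2_cum_[-1]) else None,
            n_vip_gt_1=int(np.sum(pls.vip_ > 1)))

        # per-peptide factorial differential expression
        table = analyze_all(matrix, design, alpha=config.fdr_alpha)
        _write_df(table, out / "differential_table.tsv", "peptide")
        log("differential", peptides=len(table),
            significant=int((table["fdr_p"] < config.fdr_alpha).sum()))
    except Exception as exc:
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
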