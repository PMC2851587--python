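"""Two-step intensity normalization and missingness filtering.

Label-free LC-MS intensities carry run-to-run distortions: global scale
differences between injections and a smooth intensity drift along the run
order.  The pipeline removes them in two steps:

1. *Calibration*: a per-peptide median reference run is built from peptides
   observed in strictly more than half of all runs; each run's observed
   intensities are regressed on the reference (ordinary least squares over the
   shared peptides) and mapped onto the reference scale by inverting the fit.

2. *Drift correction*: for each peptide, a locally weighted linear regression
   (lowess: tricube weights over the nearest ``ceil(span * n_obs)`` observed
   runs, degree 1, no robustness iterations) of intensity on run order is
   subtracted, and the peptide's mean level restored.

Afterwards peptides insufficiently observed (more than ``max_missing`` absent
runs in any experimental group) are dropped, and technical replicates of the
reference sample are collapsed to their per-peptide median.

The transformers follow scikit-learn conventions and operate on runs x
peptides arrays (observations = runs); NaN marks a missing value and is
preserved by every transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .dataio import IntensityMatrix, MatrixError, group_labels

__all__ = [
    "ReferenceRun", "CalibrationFit", "DriftFit",
    "RunCalibrator", "RunOrderCorrector", "GroupMissingFilter",
    "log2_transform", "flag_outlier_runs", "build_reference_run",
    "calibrate_to_reference", "correct_run_order", "filter_min_matching",
    "collapse_technical_replicates", "lowess_fit",
]


@dataclass
class ReferenceRun:
    """Per-peptide median over runs, for well-observed peptides only."""

    values: pd.Series            # peptide -> median log2 intensity
    contributing: pd.Index       # peptides observed in > min_match_frac of runs


@dataclass
class CalibrationFit:
    run_id: str
    slope: float
    intercept: float
    n_shared: int


@dataclass
class DriftFit:
    peptide_id: str
    fitted: pd.Series            # run_id -> fitted smooth value (observed runs)
    span: float
    pre_mean: float
    corrected: bool = True


# ---------------------------------------------------------------------------
# low-level building blocks


def lowess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.5) -> np.ndarray:
    """Locally weighted linear regression evaluated at every x.

    At each point the nearest ``ceil(span * n)`` neighbours (including the
    point itself) enter a weighted least-squares line with tricube weights
    w = (1 - (d/h)^3)^3, h being the largest neighbour distance.  No
    robustness iterations.  x values must be distinct.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    k = max(2, int(np.ceil(span * n)))
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0, None)
        sw = w.sum()
        if sw <= 0:
            fitted[i] = y[idx].mean()
            continue
        xm = np.sum(w * x[idx]) / sw
        ym = np.sum(w * y[idx]) / sw
        sxx = np.sum(w * (x[idx] - xm) ** 2)
        if sxx < 1e-12:
            fitted[i] = ym
        else:
            beta = np.sum(w * (x[idx] - xm) * (y[idx] - ym)) / sxx
            fitted[i] = ym + beta * (x[i] - xm)
    return fitted


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope/intercept of y on x."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ZeroDivisionError("degenerate regressor")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return slope, ym - slope * xm


# ---------------------------------------------------------------------------
# scikit-learn style transformers (X: runs x peptides, NaN = missing)


class RunCalibrator(BaseEstimator, TransformerMixin):
    """Map every run onto the scale of a median reference run.

    fit() builds the reference from peptides observed in strictly more than
    ``min_match_frac`` of runs; transform() regresses each run on the
    reference over their shared peptides (observed = a + b*reference) and
    replaces values by (v - a) / b.  After calibration each run re-regresses
    on the reference with slope 1 and intercept 0.
    """

    def __init__(self, min_match_frac: float = 0.5, min_shared: int = 3):
        self.min_match_frac = min_match_frac
        self.min_shared = min_shared

    def fit(self, X, y=None):
        X = self._as_array(X)
        n_runs = X.shape[0]
        observed_frac = np.mean(~np.isnan(X), axis=0)
        keep = observed_frac > self.min_match_frac
        if not keep.any():
            raise MatrixError(
                f"no peptide observed in more than {self.min_match_frac:.0%} of runs")
        self.reference_ = np.nanmedian(X[:, keep], axis=0)
        self.reference_mask_ = keep
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._as_array(X)
        out = X.copy()
        fits = []
        ref = self.reference_
        for r in range(X.shape[0]):
            row = X[r, self.reference_mask_]
            shared = ~np.isnan(row)
            n_shared = int(shared.sum())
            if n_shared < self.min_shared:
                raise MatrixError(
                    f"run {r} shares only {n_shared} peptides with the reference "
                    f"(need >= {self.min_shared})")
            b, a = _ols_line(ref[shared], row[shared])
            if abs(b) < 1e-6:
                raise MatrixError(f"degenerate calibration slope for run {r}")
            obs = ~np.isnan(X[r])
            out[r, obs] = (X[r, obs] - a) / b
            fits.append((b, a, n_shared))
        self.calibration_ = fits
        return out

    @staticmethod
    def _as_array(X):
        return np.asarray(X, dtype=float)


class RunOrderCorrector(BaseEstimator, TransformerMixin):
    """Remove smooth run-order drift per peptide by lowess.

    The fitted local-linear curve is subtracted from each peptide's observed
    values and the mean of the fitted curve added back, preserving the
    peptide's mean level exactly.  Peptides with fewer than ``min_obs``
    observations are left uncorrected and flagged.
    """

    def __init__(self, span: float = 0.5, min_obs: int = 4):
        self.span = span
        self.min_obs = min_obs

    def fit(self, X, y=None, run_order=None):
        X = np.asarray(X, float)
        self.n_features_in_ = X.shape[1]
        if run_order is None:
            run_order = np.arange(1, X.shape[0] + 1)
        self.run_order_ = np.asarray(run_order, float)
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        out = X.copy()
        order = self.run_order_
        uncorrected = []
        fitted_all = np.full_like(X, np.nan)
        for j in range(X.shape[1]):
            col = X[:, j]
            obs = ~np.isnan(col)
            if obs.sum() < self.min_obs:
                uncorrected.append(j)
                continue
            fit = lowess_fit(order[obs], col[obs], span=self.span)
            fitted_all[obs, j] = fit
            out[obs, j] = col[obs] - fit + fit.mean()
        self.uncorrected_ = uncorrected
        self.fitted_ = fitted_all
        return out


class GroupMissingFilter(BaseEstimator, TransformerMixin):
    """Keep peptides with at most ``max_missing`` absent runs in every group."""

    def __init__(self, max_missing: int = 1):
        self.max_missing = max_missing

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("group labels (y) are required")
        X = np.asarray(X, float)
        groups = np.asarray(y)
        keep = np.ones(X.shape[1], dtype=bool)
        for g in np.unique(groups):
            sel = groups == g
            n_missing = np.sum(np.isnan(X[sel]), axis=0)
            keep &= n_missing <= self.max_missing
        self.support_ = keep
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        X = np.asarray(X, float)
        return X[:, self.support_]


# ---------------------------------------------------------------------------
# IntensityMatrix-level operations (thin wrappers over the transformers)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of raw intensities; missing entries are preserved."""
    matrix.require_state("raw")
    vals = matrix.values
    bad = (vals <= 0) & vals.notna()
    if bad.to_numpy().any():
        cells = [(p, r) for p, r in zip(*np.nonzero(bad.to_numpy()))]
        names = [(vals.index[p], vals.columns[r]) for p, r in cells[:10]]
        raise MatrixError(f"non-positive intensities at {names}")
    return IntensityMatrix(values=np.log2(vals), state=("log2",))


def flag_outlier_runs(matrix: IntensityMatrix, k: float = 3.0) -> list[tuple[str, str]]:
    """Advisory flags for runs of anomalously low overall intensity.

    A run is flagged when its median observed intensity lies more than ``k``
    scaled median-absolute-deviations below the median of run medians.
    """
    matrix.require_state("log2")
    if matrix.values.shape[1] < 4:
        raise MatrixError("need at least 4 runs for robust outlier statistics")
    run_medians = matrix.values.median(axis=0, skipna=True)
    center = run_medians.median()
    mad = stats.median_abs_deviation(run_medians, scale="normal")
    flags = []
    if mad == 0 or not np.isfinite(k):
        return flags
    for run_id, med in run_medians.items():
        if (center - med) / mad > k:
            flags.append((run_id, f"median intensity {med:.3f} is "
                          f"{(center - med) / mad:.1f} robust SDs below cohort"))
    return flags


def build_reference_run(matrix: IntensityMatrix,
                        min_match_frac: float = 0.5) -> ReferenceRun:
    """Median run over peptides matched in strictly > min_match_frac of runs."""
    matrix.require_state("log2")
    cal = RunCalibrator(min_match_frac=min_match_frac).fit(matrix.values.T.to_numpy())
    contributing = matrix.values.index[cal.reference_mask_]
    return ReferenceRun(
        values=pd.Series(cal.reference_, index=contributing, name="reference"),
        contributing=contributing,
    )


def calibrate_to_reference(
    matrix: IntensityMatrix, ref: ReferenceRun | None = None,
    min_match_frac: float = 0.5,
) -> tuple[IntensityMatrix, list[CalibrationFit]]:
    matrix.require_state("log2")
    cal = RunCalibrator(min_match_frac=min_match_frac)
    X = matrix.values.T.to_numpy()
    if ref is None:
        cal.fit(X)
    else:
        mask = matrix.values.index.isin(ref.contributing)
        cal.reference_ = ref.values.reindex(matrix.values.index[mask]).to_numpy()
        cal.reference_mask_ = mask
        cal.n_features_in_ = X.shape[1]
    Xt = cal.transform(X)
    out = pd.DataFrame(Xt.T, index=matrix.values.index, columns=matrix.values.columns)
    fits = [CalibrationFit(run_id=r, slope=b, intercept=a, n_shared=n)
            for r, (b, a, n) in zip(matrix.values.columns, cal.calibration_)]
    return matrix.with_state("calibrated", out), fits


def correct_run_order(
    matrix: IntensityMatrix, design: pd.DataFrame, span: float = 0.5,
    min_obs: int = 4,
) -> tuple[IntensityMatrix, list[DriftFit]]:
    matrix.require_state("calibrated")
    order = design.set_index("run_id").loc[matrix.run_ids, "run_order"].to_numpy(float)
    corr = RunOrderCorrector(span=span, min_obs=min_obs)
    X = matrix.values.T.to_numpy()
    corr.fit(X, run_order=order)
    Xt = corr.transform(X)
    out = pd.DataFrame(Xt.T, index=matrix.values.index, columns=matrix.values.columns)
    fits = []
    uncorrected = set(corr.uncorrected_)
    for j, pep in enumerate(matrix.peptide_ids):
        obs = matrix.values.iloc[j].notna()
        fitted = pd.Series(corr.fitted_[:, j], index=matrix.run_ids)[obs.to_numpy()]
        fits.append(DriftFit(
            peptide_id=pep, fitted=fitted, span=span,
            pre_mean=float(matrix.values.iloc[j][obs].mean()) if obs.any() else np.nan,
            corrected=j not in uncorrected,
        ))
    return matrix.with_state("drift_corrected", out), fits


def filter_min_matching(matrix: IntensityMatrix, groups: pd.Series,
                        max_missing_per_group: int = 1) -> IntensityMatrix:
    """Drop peptides with more than ``max_missing_per_group`` missing runs
    in any experimental group; peptide order is preserved."""
    missing_groups = set(matrix.run_ids) - set(groups.index)
    if missing_groups:
        raise MatrixError(f"runs without group assignment: {sorted(missing_groups)}")
    filt = GroupMissingFilter(max_missing=max_missing_per_group)
    labels = groups.loc[matrix.run_ids].to_numpy()
    filt.fit(matrix.values.T.to_numpy(), y=labels)
    kept = matrix.values.loc[filt.get_support()]
    return matrix.with_state("filtered", kept)


def collapse_technical_replicates(
    matrix: IntensityMatrix, design: pd.DataFrame,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Replace reference-replicate runs by one per-peptide median pseudo-run.

    The pseudo-run has a value wherever at least one replicate observed the
    peptide, and keeps the reference sample's id and factors.
    """
    ref_mask = design["is_reference"].astype(bool)
    if not ref_mask.any():
        raise MatrixError("design has no reference runs to collapse")
    ref_runs = list(design.loc[ref_mask, "run_id"])
    ref_sample = design.loc[ref_mask, "sample_id"].iloc[0]
    median = matrix.values[ref_runs].median(axis=1, skipna=True)

    keep_design = design.loc[~ref_mask].copy()
    first_ref = design.loc[ref_mask].iloc[0].copy()
    first_ref["run_id"] = ref_sample
    pseudo = first_ref.to_frame().T
    new_design = pd.concat([keep_design, pseudo], ignore_index=True)
    new_design = new_design.sort_values("run_order").reset_index(drop=True)
    new_design["run_order"] = np.arange(1, len(new_design) + 1)
    new_design["is_reference"] = new_design["is_reference"].astype(bool)

    vals = matrix.values.drop(columns=ref_runs)
    vals[ref_sample] = median
    vals = vals[list(new_design["run_id"])]
    return matrix.with_state("collapsed", vals), new_design
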