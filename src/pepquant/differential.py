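"""Per-peptide three-way fixed-effects factorial analysis.

Each peptide's log2 intensity y is modelled by the full 2x2x2 factorial

    y = mu + A_i + S_j + T_k + AS_ij + AT_ik + ST_jk + AST_ijk + eps,

with age (ed12/ed17), sex (M/F) and treatment (C/E) as fixed effects under
sum-to-zero coding and eps ~ NID(0, sigma^2).  Marginal (Type III) sums of
squares are computed per term as the residual-SS increase from deleting that
term from the full model; the overall model F-test p-values are adjusted
across peptides by Benjamini-Hochberg; the joint significance of all
interactions is the full-versus-main-effects comparison F (the Wald F for
those coefficients under OLS); fold changes are level-mean differences with
signs ed17-ed12, F-M, E-C; pairwise t-tests between group means use the
model residual variance and the three printed significance tiers
(* p<0.05, ** p<0.01, *** p<0.001).

Designs are near-balanced (the upstream filter allows at most one missing
run per group), and fitting is complete-case per peptide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .dataio import IntensityMatrix, group_labels

__all__ = [
    "FactorialFit", "FactorialAnova", "fit_factorial", "analyze_all",
    "adjust_fdr", "pairwise_t", "significance_tier",
]

_FACTORS = ("age", "sex", "treatment")
_HIGH = {"age": "ed17", "sex": "F", "treatment": "E"}
_TERMS = ("age", "sex", "treatment", "age:sex", "age:treatment",
          "sex:treatment", "age:sex:treatment")


def significance_tier(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _design_matrix(factors: pd.DataFrame) -> np.ndarray:
    """Sum-to-zero coded full factorial design matrix.

    Columns: intercept, age, sex, treatment, age:sex, age:treatment,
    sex:treatment, age:sex:treatment.  The high level (ed17, F, E) codes +1,
    so twice a main-effect coefficient is the level-mean difference on a
    balanced design.
    """
    cols = [np.ones(len(factors))]
    mains = {f: np.where(factors[f].to_numpy() == _HIGH[f], 1.0, -1.0)
             for f in _FACTORS}
    cols += [mains["age"], mains["sex"], mains["treatment"]]
    cols += [mains["age"] * mains["sex"], mains["age"] * mains["treatment"],
             mains["sex"] * mains["treatment"],
             mains["age"] * mains["sex"] * mains["treatment"]]
    return np.column_stack(cols)


def _rss(Xd: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta
    return float(np.sum((y - fitted) ** 2))


@dataclass
class FactorialFit:
    """Effect estimates and test statistics for one peptide."""

    coef: pd.Series                  # sum-to-zero coefficients, term-indexed
    ss_marginal: pd.Series           # Type III SS per term
    term_f: pd.Series
    term_p: pd.Series
    sigma2: float
    df_resid: int
    n_obs: int
    f_overall: float
    p_overall: float
    f_interaction: float
    p_interaction: float
    fold_changes: pd.Series          # age: ed17-ed12; sex: F-M; treatment: E-C
    ls_means: pd.DataFrame           # per factor: low/high least-squares means
    group_means: pd.Series           # observed cell means per group label
    group_counts: pd.Series
    flags: list = field(default_factory=list)


def fit_factorial(y: pd.Series, design: pd.DataFrame) -> FactorialFit:
    """Fit the full 2x2x2 fixed-effects model for one peptide.

    ``y`` is run_id-indexed; missing runs are dropped (complete-case).
    Marginal SS per term come from full-versus-reduced model comparisons.
    """
    factors = design.set_index("run_id").loc[y.index, list(_FACTORS)]
    obs = y.notna().to_numpy()
    yv = y.to_numpy(float)[obs]
    fobs = factors.iloc[obs]
    flags: list[str] = []

    for f in _FACTORS:
        if fobs[f].nunique() < 2:
            flags.append(f"unestimable: factor {f!r} has a single level")
    n = len(yv)
    Xd = _design_matrix(fobs)
    k = Xd.shape[1]
    df_resid = n - np.linalg.matrix_rank(Xd)

    beta, *_ = np.linalg.lstsq(Xd, yv, rcond=None)
    fitted = Xd @ beta
    rss_full = float(np.sum((yv - fitted) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    sigma2 = rss_full / df_resid if df_resid > 0 else np.nan

    ss_marg, term_f, term_p = {}, {}, {}
    for j, term in enumerate(_TERMS, start=1):
        Xr = np.delete(Xd, j, axis=1)
        ss = max(0.0, _rss(Xr, yv) - rss_full)
        ss_marg[term] = ss
        if df_resid > 0 and sigma2 > 0:
            term_f[term] = ss / sigma2
            term_p[term] = float(stats.f.sf(term_f[term], 1, df_resid))
        else:
            term_f[term] = np.nan
            term_p[term] = np.nan

    if df_resid > 0 and sigma2 > 0 and tss > 0:
        f_overall = ((tss - rss_full) / (k - 1)) / sigma2
        p_overall = float(stats.f.sf(f_overall, k - 1, df_resid))
    else:
        f_overall, p_overall = np.nan, np.nan
        if tss == 0:
            flags.append("constant response; p undefined")
        if df_resid <= 0:
            flags.append("zero residual degrees of freedom; statistics undefined")

    # joint interaction Wald F: full vs main-effects-only
    rss_main = _rss(Xd[:, :4], yv)
    if df_resid > 0 and sigma2 > 0:
        f_int = ((rss_main - rss_full) / 4) / sigma2
        p_int = float(stats.f.sf(f_int, 4, df_resid))
    else:
        f_int, p_int = np.nan, np.nan

    # least-squares means: average of predicted cell means over other factors
    cells = list(itertools.product(*[["lo", "hi"]] * 3))
    cell_pred = {}
    for cell in cells:
        row = {f: (_HIGH[f] if lvl == "hi" else
                   {"age": "ed12", "sex": "M", "treatment": "C"}[f])
               for f, lvl in zip(_FACTORS, cell)}
        xr = _design_matrix(pd.DataFrame([row]))
        cell_pred[cell] = float((xr @ beta)[0])
    ls = {}
    fc = {}
    for fi, f in enumerate(_FACTORS):
        hi = np.mean([v for c, v in cell_pred.items() if c[fi] == "hi"])
        lo = np.mean([v for c, v in cell_pred.items() if c[fi] == "lo"])
        ls[f] = {"low": lo, "high": hi}
        fc[f] = hi - lo

    groups = fobs["age"].str.cat([fobs["sex"], fobs["treatment"]])
    gm = pd.Series(yv).groupby(groups.to_numpy()).mean()
    gc = pd.Series(yv).groupby(groups.to_numpy()).size()

    return FactorialFit(
        coef=pd.Series(beta, index=("intercept",) + _TERMS),
        ss_marginal=pd.Series(ss_marg),
        term_f=pd.Series(term_f),
        term_p=pd.Series(term_p),
        sigma2=sigma2,
        df_resid=int(df_resid),
        n_obs=n,
        f_overall=f_overall,
        p_overall=p_overall,
        f_interaction=f_int,
        p_interaction=p_int,
        fold_changes=pd.Series(fc),
        ls_means=pd.DataFrame(ls),
        group_means=gm,
        group_counts=gc,
        flags=flags,
    )


def adjust_fdr(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values ('by' for the
    Benjamini-Yekutieli variant).  NaN entries are passed through."""
    p = np.asarray(pvalues, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        key = {"bh": "fdr_bh", "by": "fdr_by"}[method]
        out[ok] = multipletests(p[ok], method=key)[1]
    return out


def pairwise_t(group_a, group_b, pooled_variance: float | None = None,
               df: int | None = None) -> tuple[float, float, str]:
    """Two-sided t-test between two group means using a supplied (model
    residual) variance, or the within-group pooled variance if omitted."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if pooled_variance is None:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 values per group or a supplied variance")
        df = len(a) + len(b) - 2
        pooled_variance = (np.sum((a - a.mean()) ** 2)
                           + np.sum((b - b.mean()) ** 2)) / df
    if df is None:
        raise ValueError("df must accompany a supplied pooled variance")
    diff = a.mean() - b.mean()
    se2 = pooled_variance * (1 / len(a) + 1 / len(b))
    if se2 == 0:
        if diff == 0:
            return 0.0, 1.0, ""
        return np.inf, np.nan, "degenerate"
    t = diff / np.sqrt(se2)
    p = 2 * float(stats.t.sf(abs(t), df))
    return float(t), p, significance_tier(p)


class FactorialAnova(BaseEstimator):
    """Per-peptide factorial differential analysis over an intensity matrix.

    fit(X, y=None, design=...) consumes runs x peptides values; results_
    holds one row per peptide with FDR-adjusted overall p, fold changes,
    per-term significance tiers and the joint-interaction p.
    """

    def __init__(self, fdr_method: str = "bh", alpha: float = 0.05,
                 all_pairs: bool = False):
        self.fdr_method = fdr_method
        self.alpha = alpha
        self.all_pairs = all_pairs

    def fit(self, X: pd.DataFrame, y=None, design: pd.DataFrame | None = None):
        if design is None:
            raise ValueError("a design table is required")
        fits = {}
        rows = []
        for pep in X.columns:
            f = fit_factorial(X[pep], design)
            fits[pep] = f
            rows.append({
                "peptide": pep,
                "n_obs": f.n_obs,
                "f_overall": f.f_overall,
                "p_overall": f.p_overall,
                "fc_age": f.fold_changes["age"],
                "fc_sex": f.fold_changes["sex"],
                "fc_treatment": f.fold_changes["treatment"],
                "p_age": f.term_p["age"],
                "p_sex": f.term_p["sex"],
                "p_treatment": f.term_p["treatment"],
                "p_interaction": f.p_interaction,
                "flags": ";".join(f.flags),
            })
        table = pd.DataFrame(rows).set_index("peptide")
        table["fdr_p"] = adjust_fdr(table["p_overall"], method=self.fdr_method)
        for term in ("age", "sex", "treatment"):
            table[f"tier_{term}"] = table[f"p_{term}"].map(significance_tier)
        table["tier_interaction"] = table["p_interaction"].map(significance_tier)
        self.fits_ = fits
        self.results_ = table[[
            "n_obs", "f_overall", "p_overall", "fdr_p",
            "fc_age", "fc_sex", "fc_treatment",
            "p_age", "p_sex", "p_treatment", "p_interaction",
            "tier_age", "tier_sex", "tier_treatment", "tier_interaction",
            "flags",
        ]]
        return self

    def pairwise_tests(self, peptide: str) -> pd.DataFrame:
        """t-tests between group means using the peptide's model residual
        variance; within-factor contrasts by default (pairs of groups that
        differ in exactly one factor), all 28 pairs with all_pairs=True."""
        f = self.fits_[peptide]
        labels = list(f.group_means.index)
        rows = []
        for g1, g2 in itertools.combinations(labels, 2):
            # group labels are fixed-width: ed1X + sex + treatment
            n_diff_factors = sum([g1[:4] != g2[:4], g1[4] != g2[4], g1[5] != g2[5]])
            if not self.all_pairs and n_diff_factors != 1:
                continue
            m1, m2 = f.group_means[g1], f.group_means[g2]
            n1, n2 = f.group_counts[g1], f.group_counts[g2]
            se2 = f.sigma2 * (1 / n1 + 1 / n2)
            if se2 > 0 and f.df_resid > 0:
                t = (m1 - m2) / np.sqrt(se2)
                p = 2 * float(stats.t.sf(abs(t), f.df_resid))
            else:
                t, p = np.nan, np.nan
            rows.append({"group_a": g1, "group_b": g2, "diff": m1 - m2,
                         "t": t, "p": p, "tier": significance_tier(p)})
        return pd.DataFrame(rows)


def analyze_all(matrix: IntensityMatrix, design: pd.DataFrame,
                fdr_method: str = "bh", alpha: float = 0.05) -> pd.DataFrame:
    """Differential table across all peptides of a normalized matrix.

    Least-squares means are attached for main effects significant at
    ``alpha`` (marginal-SS F-test per term).
    """
    model = FactorialAnova(fdr_method=fdr_method, alpha=alpha)
    model.fit(matrix.values.T, design=design)
    table = model.results_.copy()
    for term in ("age", "sex", "treatment"):
        lo_col, hi_col = f"lsmean_{term}_low", f"lsmean_{term}_high"
        lo, hi = [], []
        for pep in table.index:
            f = model.fits_[pep]
            if np.isfinite(f.term_p[term]) and f.term_p[term] < alpha:
                lo.append(f.ls_means[term]["low"])
                hi.append(f.ls_means[term]["high"])
            else:
                lo.append(np.nan)
                hi.append(np.nan)
        table[lo_col] = lo
        table[hi_col] = hi
    return table
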