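"""Ecology–shape association and sample-quality statistics.

Covers four analyses that operate on eigenshape scores:

* PGLS — generalized least squares regression of a per-species response
  (e.g. a stable-isotope value in per mil) on shape-axis scores, with residual
  correlation proportional to the Brownian covariance implied by the tree.
* Per-axis one-way ANOVA across clades with Bonferroni correction and Welch
  pairwise post hoc tests.
* Canonical variates analysis with successive-root Wilks' Lambda tests
  (Bartlett's chi-square approximation).
* Measurement-error repeatability R from a one-way ANOVA on replicated
  digitizations: the among-individual share of total variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .phylo import Phylogeny

__all__ = ["PGLSResult", "CVAResult", "RepeatabilityResult", "pgls",
           "anova_per_axis", "cva_wilks", "repeatability"]


@dataclass
class PGLSResult:
    coefficients: pd.DataFrame   # coef, se, t, p per term
    r2_lr: float                 # likelihood-ratio generalized r^2
    r2_gls: float                # GLS sums-of-squares r^2
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int
    logL: float


@dataclass
class CVAResult:
    coefficients: pd.DataFrame   # axes x functions, within-group-normalized
    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    scores: pd.DataFrame         # specimens x functions
    wilks: pd.DataFrame          # function, wilks, chi2, df, p


@dataclass
class RepeatabilityResult:
    axis: str
    MS_among: float
    MS_within: float
    n0: float
    R: float


def pgls(tree: Phylogeny, response: pd.Series, predictors: pd.DataFrame,
         correlation: np.ndarray | None = None) -> PGLSResult:
    """Phylogenetic generalized least squares with a Brownian correlation.

    ``response`` and ``predictors`` are indexed by species and must be
    complete cases (prune beforehand); the species need not cover the whole
    tree — the Brownian covariance of a subset of tips is the corresponding
    submatrix of shared path lengths, scaled by tree depth.  Passing an
    explicit ``correlation`` (e.g. the identity) overrides the tree.
    """
    species = list(response.index)
    if set(species) != set(predictors.index):
        raise ValueError("response and predictors must cover the same species")
    X = predictors.loc[species]
    y = response.loc[species].to_numpy(dtype=float)
    n, m = X.shape
    if n <= m + 1:
        raise ValueError(f"need more species ({n}) than predictors + 1 ({m + 1})")
    _check_rank(X)
    if correlation is None:
        idx = tree.tip_index(species)
        correlation = tree.vcv()[np.ix_(idx, idx)] / tree.depth
    design = sm.add_constant(X.to_numpy(dtype=float))
    fit = sm.GLS(y, design, sigma=correlation).fit()
    null = sm.GLS(y, np.ones((n, 1)), sigma=correlation).fit()
    names = ["intercept"] + list(X.columns)
    coef = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    }, index=names)
    r2_lr = 1.0 - np.exp(-2.0 * (fit.llf - null.llf) / n)
    rss = float(fit.ssr)
    tss = float(null.ssr)
    r2_gls = 1.0 - rss / tss if tss > 0 else np.nan
    return PGLSResult(
        coefficients=coef, r2_lr=float(r2_lr), r2_gls=float(r2_gls),
        fvalue=float(fit.fvalue), f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model), df_resid=int(fit.df_resid), n=n,
        logL=float(fit.llf),
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    bad = []
    kept = np.ones((len(X), 1))
    for j, col in enumerate(X.columns):
        cand = np.column_stack([kept, X.iloc[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept = cand
        else:
            bad.append(col)
    raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def anova_per_axis(scores: pd.DataFrame, groups: pd.Series,
                   axes: list[str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA per shape axis with Bonferroni correction.

    ``groups`` assigns a clade label to every specimen row of ``scores``.
    Adjusted p-values multiply the raw p by the number of axes tested; the
    Welch pairwise post hoc p-values are Bonferroni-corrected by the number
    of group pairs within each axis.  Returns ``(anova_table, posthoc_table)``.
    """
    axes = list(axes) if axes is not None else list(scores.columns)
    g = groups.loc[scores.index]
    levels = sorted(g.unique())
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    sizes = g.value_counts()
    if int((sizes - 1).sum()) < 1:
        raise ValueError("within-group degrees of freedom is zero")
    n_axes = len(axes)
    n_pairs = len(levels) * (len(levels) - 1) // 2
    rows, post = [], []
    for ax in axes:
        samples = [scores.loc[g == lv, ax].to_numpy(dtype=float) for lv in levels]
        F, p = sps.f_oneway(*samples)
        df1 = len(levels) - 1
        df2 = len(g) - len(levels)
        rows.append({"axis": ax, "F": float(F), "df1": df1, "df2": df2,
                     "p": float(p), "p_bonferroni": min(1.0, float(p) * n_axes)})
        for (i, a), (j, b) in combinations(enumerate(levels), 2):
            if len(samples[i]) < 2 or len(samples[j]) < 2:
                continue
            t, pp = sps.ttest_ind(samples[i], samples[j], equal_var=False)
            post.append({"axis": ax, "group1": a, "group2": b,
                         "t": float(t), "p": float(pp),
                         "p_bonferroni": min(1.0, float(pp) * n_pairs)})
    return pd.DataFrame(rows).set_index("axis"), pd.DataFrame(post)


def cva_wilks(scores: pd.DataFrame, groups: pd.Series) -> CVAResult:
    """Canonical variates analysis with Wilks' Lambda significance tests.

    Canonical functions come from the generalized eigenproblem of the
    between-group versus within-group scatter; there are
    ``min(n_groups - 1, n_axes)`` of them.  Coefficients are normalized so
    canonical scores have unit pooled within-group variance (and are
    uncorrelated within groups).  Successive-root Wilks' Lambda tests use
    Bartlett's chi-square approximation with
    ``df = (k - m + 1) * (g - m)`` for the test starting at root ``m``.
    """
    g = groups.loc[scores.index]
    levels = sorted(g.unique())
    ng = len(levels)
    X = scores.to_numpy(dtype=float)
    N, k = X.shape
    if ng < 2:
        raise ValueError("CVA needs at least 2 groups")
    if N <= k + ng:
        raise ValueError("too few specimens for CVA; reduce the number of axes")
    grand = X.mean(axis=0)
    W = np.zeros((k, k))
    B = np.zeros((k, k))
    for lv in levels:
        sub = X[(g == lv).to_numpy()]
        mu = sub.mean(axis=0)
        dev = sub - mu
        W += dev.T @ dev
        B += len(sub) * np.outer(mu - grand, mu - grand)
    try:
        evals, evecs = _geig(B, W)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise np.linalg.LinAlgError(
            "within-group scatter is singular; reduce the number of shape axes"
        ) from exc
    order = np.argsort(evals)[::-1]
    r = min(ng - 1, k)
    lam = np.clip(evals[order][:r], 0, None)
    A = evecs[:, order][:, :r]
    # unit pooled within-group variance for canonical scores
    scale = np.sqrt(np.einsum("ij,jk,ki->i", A.T, W / (N - ng), A))
    A = A / scale
    can_scores = (X - grand) @ A
    func_names = [f"CV{i + 1}" for i in range(r)]
    wilks_rows = []
    for m in range(1, r + 1):
        wl = float(np.prod(1.0 / (1.0 + lam[m - 1:])))
        chi2 = -(N - 1 - (k + ng) / 2.0) * np.log(wl)
        df = (k - m + 1) * (ng - m)
        wilks_rows.append({"function": func_names[m - 1], "wilks": wl,
                           "chi2": float(chi2), "df": df,
                           "p": float(sps.chi2.sf(chi2, df))})
    total = lam.sum()
    return CVAResult(
        coefficients=pd.DataFrame(A, index=scores.columns, columns=func_names),
        eigenvalues=lam,
        variance_pct=100 * lam / total if total > 0 else np.zeros(r),
        scores=pd.DataFrame(can_scores, index=scores.index, columns=func_names),
        wilks=pd.DataFrame(wilks_rows).set_index("function"),
    )


def _geig(B: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generalized symmetric eigenproblem B v = lambda W v."""
    from scipy.linalg import eigh

    return eigh(B, W)


def repeatability(scores: pd.DataFrame, individual_ids: pd.Series
                  ) -> list[RepeatabilityResult]:
    """Measurement-error repeatability per axis from replicated digitizations.

    One-way ANOVA with individuals as groups.  The among-individual variance
    component is ``(MS_among - MS_within) / n0`` with the standard
    unbalanced-design effective replicate count
    ``n0 = (N - sum n_i^2 / N) / (a - 1)``; negative estimates are clamped to
    zero, so ``R = s2_among / (s2_among + s2_within)`` lies in [0, 1].
    """
    ids = individual_ids.loc[scores.index]
    levels = ids.unique()
    a = len(levels)
    if a < 2:
        raise ValueError("repeatability needs at least 2 individuals")
    counts = ids.value_counts()
    if int((counts - 1).sum()) < 1:
        raise ValueError("need replicated measurements for at least one individual")
    N = len(ids)
    n0 = (N - float((counts**2).sum()) / N) / (a - 1)
    out = []
    for ax in scores.columns:
        x = scores[ax].to_numpy(dtype=float)
        grand = x.mean()
        ss_among = 0.0
        ss_within = 0.0
        for lv in levels:
            sub = x[(ids == lv).to_numpy()]
            ss_among += len(sub) * (sub.mean() - grand) ** 2
            ss_within += ((sub - sub.mean()) ** 2).sum()
        ms_among = ss_among / (a - 1)
        ms_within = ss_within / (N - a)
        s2_among = max((ms_among - ms_within) / n0, 0.0)
        denom = s2_among + ms_within
        R = s2_among / denom if denom > 0 else 0.0
        out.append(RepeatabilityResult(axis=str(ax), MS_among=float(ms_among),
                                       MS_within=float(ms_within), n0=float(n0),
                                       R=float(min(max(R, 0.0), 1.0))))
    return out


def repeatability_frame(results: list[RepeatabilityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("axis")
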