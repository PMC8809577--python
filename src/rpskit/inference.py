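"""Inferential statistics for the group analyses.

* :func:`rm_anova` — classical repeated-measures ANOVA for balanced,
  fully-crossed within-participant designs (any number of within
  factors, optionally one between-participants grouping factor).  Each
  within effect is tested against its interaction with participants;
  sphericity is assessed per within effect with Mauchly's test and the
  reported p-value uses Greenhouse-Geisser corrected degrees of freedom
  whenever Mauchly rejects (both corrected and uncorrected results are
  retained).
* :func:`tukey_pairwise` — studentized-range (Tukey HSD) pairwise
  comparisons given cell means and an error term.
* :func:`fit_lmm_emm` — random-intercept linear mixed model for
  optimal-response rates with outcome and experiment as fixed effects,
  estimated marginal means with CIs, Tukey-adjusted pairwise contrasts,
  and maximum-likelihood BICs for Bayes-factor model comparison.
* :func:`bic_bayes_factor` — exp(dBIC/2) Bayes-factor approximation.
* :func:`two_sample_t` — pooled-variance independent-samples t test.

Denominator degrees of freedom for mixed-model Wald tests use the
between-within (inner-outer) partition: effects varying within
participants are tested against N - participants - (within-varying
columns); between effects against participants - 1 - (between columns).
For balanced random-intercept designs this coincides with the
Satterthwaite values reported by dedicated mixed-model tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import helmert


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _subsets(axes):
    return chain.from_iterable(combinations(axes, r)
                               for r in range(len(axes) + 1))


def _keepdims_mean(Y: np.ndarray, keep_axes: tuple[int, ...]) -> np.ndarray:
    drop = tuple(a for a in range(Y.ndim) if a not in keep_axes)
    return Y.mean(axis=drop, keepdims=True) if drop else Y


def _broadcast_ss(eff: np.ndarray, shape: tuple[int, ...]) -> float:
    return float((np.broadcast_to(eff, shape) ** 2).sum())


@dataclass
class SphericityInfo:
    mauchly_w: float
    mauchly_p: float
    epsilon_gg: float


def _pooled_within_cov(Y_sub: np.ndarray, groups: np.ndarray) -> np.ndarray:
    parts = []
    for g in np.unique(groups):
        block = Y_sub[groups == g]
        parts.append(block - block.mean(axis=0))
    resid = np.vstack(parts)
    return resid.T @ resid / (Y_sub.shape[0] - len(np.unique(groups)))


def rm_anova(data: pd.DataFrame, dv: str, within: list[str], subject: str,
             between: str | None = None,
             sphericity_alpha: float = 0.05) -> pd.DataFrame:
    """Repeated-measures ANOVA for a balanced fully-crossed design.

    Parameters
    ----------
    data
        Long-format frame with one observation per subject x within-cell
        (aggregate replicates before calling).
    dv, within, subject, between
        Column names; ``between`` is an optional grouping factor with
        equal group sizes (subjects nested in groups).

    Returns a table with one row per effect: sums of squares, df, F,
    uncorrected p, Mauchly's test, GG epsilon, GG-corrected df and p,
    the conditionally-reported p (GG whenever Mauchly rejects), MSE of
    the error term and partial eta squared.

    Raises on missing or duplicated cells: the classical decomposition
    requires complete data (remove whole participants beforehand, as the
    original analyses did).
    """
    if not within:
        raise ValueError("at least one within factor required")
    cols = [subject] + within + ([between] if between else []) + [dv]
    frame = data[cols].copy()
    if frame[dv].isna().any():
        raise ValueError("missing values in the dependent variable")

    level_lists = [list(pd.unique(frame[f])) for f in within]
    pivot = frame.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="count", fill_value=0)
    if not (pivot.to_numpy() == 1).all():
        raise ValueError("design is not balanced: every subject needs exactly "
                         "one observation per within-factor cell")

    subjects = list(pd.unique(frame[subject]))
    if between is not None:
        group_of = frame.drop_duplicates(subject).set_index(subject)[between]
        groups = list(pd.unique(group_of))
        sizes = group_of.value_counts()
        if sizes.nunique() != 1:
            raise ValueError("between-participant groups must be equal-sized")
        subjects = sorted(subjects, key=lambda s: groups.index(group_of[s]))
        n_groups, per_group = len(groups), int(sizes.iloc[0])
    else:
        n_groups, per_group = 1, len(subjects)
        group_of = None

    # data cube: (group, subject-within-group, within factors...)
    wide = frame.pivot_table(index=subject, columns=within, values=dv)
    order_cols = pd.MultiIndex.from_product(level_lists) if len(within) > 1 \
        else pd.Index(level_lists[0])
    wide = wide.loc[subjects, order_cols]
    Y = wide.to_numpy().reshape(
        [n_groups, per_group] + [len(l) for l in level_lists])
    shape = Y.shape
    G_AX, S_AX = 0, 1
    w_axes = {f: i + 2 for i, f in enumerate(within)}

    def moebius_effect(axes: tuple[int, ...]) -> np.ndarray:
        eff = np.zeros([1] * Y.ndim)
        for sub in _subsets(axes):
            sign = (-1) ** (len(axes) - len(sub))
            eff = eff + sign * _keepdims_mean(Y, tuple(sub))
        return eff

    def nested_error_ss(e_axes: tuple[int, ...]) -> float:
        """SS of effect x subject(group) for within effect spanned by e_axes."""
        eff = np.zeros([1] * Y.ndim)
        for sub in _subsets(e_axes):
            sign = (-1) ** (len(e_axes) - len(sub))
            eff = eff + sign * (_keepdims_mean(Y, tuple(sub) + (G_AX, S_AX))
                                - _keepdims_mean(Y, tuple(sub) + (G_AX,)))
        return _broadcast_ss(eff, shape)

    df_sub_error = n_groups * (per_group - 1)
    ss_subject_error = _broadcast_ss(
        _keepdims_mean(Y, (G_AX, S_AX)) - _keepdims_mean(Y, (G_AX,)), shape)

    rows = []
    if between is not None:
        ss_g = _broadcast_ss(moebius_effect((G_AX,)), shape)
        df_g = n_groups - 1
        f = (ss_g / df_g) / (ss_subject_error / df_sub_error)
        rows.append({
            "effect": between, "SS": ss_g, "df1": df_g,
            "SS_error": ss_subject_error, "df2": df_sub_error,
            "MSE": ss_subject_error / df_sub_error, "F": f,
            "p_uncorrected": float(stats.f.sf(f, df_g, df_sub_error)),
            "mauchly_w": np.nan, "mauchly_p": np.nan, "epsilon_gg": 1.0,
        })

    within_subsets = [c for r in range(1, len(within) + 1)
                      for c in combinations(within, r)]
    for factors in within_subsets:
        e_axes = tuple(w_axes[f] for f in factors)
        levels = [len(level_lists[within.index(f)]) for f in factors]
        df_e = int(np.prod([l - 1 for l in levels]))
        ss_err = nested_error_ss(e_axes)
        df_err = df_e * df_sub_error

        # per-subject means over the effect's cells, for sphericity
        drop = tuple(a for a in range(2, Y.ndim) if a not in e_axes)
        Y_sub = Y.mean(axis=drop) if drop else Y
        Y_sub = Y_sub.reshape(n_groups * per_group, -1)
        group_ids = np.repeat(np.arange(n_groups), per_group)
        sigma = _pooled_within_cov(Y_sub, group_ids)
        sph = _sphericity_from_cov(sigma, levels,
                                   n_groups * per_group - n_groups)

        for include_group in ([False, True] if between is not None else [False]):
            if include_group:
                ss = _broadcast_ss(moebius_effect(e_axes + (G_AX,)), shape)
                df1 = df_e * (n_groups - 1)
                name = f"{between}:" + ":".join(factors)
            else:
                ss = _broadcast_ss(moebius_effect(e_axes), shape)
                df1 = df_e
                name = ":".join(factors)
            # degenerate margins (e.g. compositional proportions whose
            # collapsed means are constant) give 0/0: report NaN
            f = np.nan if ss_err == 0 else (ss / df1) / (ss_err / df_err)
            rows.append({
                "effect": name, "SS": ss, "df1": df1,
                "SS_error": ss_err, "df2": df_err,
                "MSE": ss_err / df_err, "F": f,
                "p_uncorrected": float(stats.f.sf(f, df1, df_err)),
                "mauchly_w": sph.mauchly_w, "mauchly_p": sph.mauchly_p,
                "epsilon_gg": sph.epsilon_gg,
            })

    table = pd.DataFrame(rows)
    table["df1_gg"] = table["df1"] * table["epsilon_gg"]
    table["df2_gg"] = table["df2"] * table["epsilon_gg"]
    table["p_gg"] = stats.f.sf(table["F"], table["df1_gg"], table["df2_gg"])
    corrected = (table["mauchly_p"] < sphericity_alpha).fillna(False)
    table["gg_applied"] = corrected
    table["p"] = np.where(corrected, table["p_gg"], table["p_uncorrected"])
    denom = table["SS"] + table["SS_error"]
    table["partial_eta_sq"] = np.where(denom > 0, table["SS"] / denom, np.nan)
    return table


def _sphericity_from_cov(sigma: np.ndarray, factor_levels: list[int],
                         df_cov: int) -> SphericityInfo:
    d = int(np.prod([l - 1 for l in factor_levels]))
    if d < 2:
        return SphericityInfo(np.nan, 1.0, 1.0)
    C = helmert(factor_levels[0], full=False)
    for l in factor_levels[1:]:
        C = np.kron(C, helmert(l, full=False))
    M = C @ sigma @ C.T
    tr = np.trace(M)
    ss_m = float((M * M).sum())
    if ss_m == 0:  # degenerate effect (constant contrast scores)
        return SphericityInfo(np.nan, np.nan, np.nan)
    eps = float(np.clip(tr ** 2 / (d * ss_m), 1.0 / d, 1.0))
    eigs = np.linalg.eigvalsh(M)
    if (eigs <= 0).any() or df_cov <= d:
        return SphericityInfo(np.nan, np.nan, eps)
    w = float(np.prod(eigs) / (tr / d) ** d)
    # two-term asymptotic expansion of Mauchly's statistic
    n = df_cov
    rho = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * n)
    omega2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * d + 2)
              / (288.0 * d ** 2 * n ** 2 * rho ** 2))
    z = -n * rho * np.log(w)
    f = d * (d + 1) // 2 - 1
    p1 = stats.chi2.sf(z, f)
    p2 = stats.chi2.sf(z, f + 4)
    p = float(p1 + omega2 * (p2 - p1))
    return SphericityInfo(w, p, eps)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def tukey_pairwise(means, mse: float, n_per_mean: int, df_error: float,
                   labels=None) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from cell means and an error term.

    ``q = |mean_i - mean_j| / sqrt(MSE / n)`` referred to the
    studentized-range distribution with ``k`` means and ``df_error``
    degrees of freedom.  At k = 2 this reduces exactly to the unadjusted
    two-sided t test.
    """
    means = np.asarray(means, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least two means")
    labels = list(labels) if labels is not None else list(range(k))
    se = np.sqrt(mse / n_per_mean)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(stats.studentized_range.sf(q, k, df_error)) if np.isfinite(q) \
            else 0.0
        rows.append({"level_1": labels[i], "level_2": labels[j],
                     "diff": diff, "se_diff": se * np.sqrt(2), "q": q,
                     "p_tukey": min(p, 1.0), "significant": p < 0.05})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed model with estimated marginal means
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    bic_full: float       # model with the interaction term (ML fit)
    bic_main: float       # main-effects-only model (ML fit)
    bf_interaction: float  # BF for the interaction model over main effects

    @property
    def bf_main(self) -> float:
        return 1.0 / self.bf_interaction


@dataclass
class LmmResult:
    emms: pd.DataFrame          # estimated marginal means per outcome level
    contrasts: pd.DataFrame     # Tukey-adjusted pairwise outcome contrasts
    anova: pd.DataFrame         # Wald F tests of the fixed terms
    comparison: ModelComparison
    model_result: object        # statsmodels REML fit (main-effects model)


def bic_bayes_factor(bic_null: float, bic_alt: float) -> float:
    """BIC-approximation Bayes factor of the alternative over the null:
    ``exp((BIC_null - BIC_alt) / 2)``."""
    return float(np.exp((bic_null - bic_alt) / 2.0))


def _mixedlm_bic(result) -> float:
    """BIC of an ML-fitted mixed model, counting fixed effects plus
    variance parameters (the convention of mainstream LMM tooling)."""
    k = result.k_fe + result.k_re2 + result.k_vc + 1  # +1 residual variance
    n = result.model.nobs
    return float(-2.0 * result.llf + k * np.log(n))


def fit_lmm_emm(data: pd.DataFrame, dv: str = "optimal_rate",
                outcome: str = "outcome", experiment: str = "experiment",
                subject: str = "participant_id",
                interaction: bool = False) -> LmmResult:
    """Random-intercept mixed model of optimal-response rates.

    Fixed effects: ``outcome`` and ``experiment`` (plus their
    interaction in the full model used only for the Bayes-factor
    comparison); random effect: per-participant intercept, no random
    slopes.  Estimates and EMMs come from the REML fit; both models are
    refitted by maximum likelihood for BIC comparison (required for the
    exp(dBIC/2) approximation to be meaningful).
    """
    import statsmodels.formula.api as smf
    from patsy import dmatrix

    data = data.copy()
    data[experiment] = data[experiment].astype(str)
    f_main = f"{dv} ~ C({outcome}) + C({experiment})"
    f_full = f"{dv} ~ C({outcome}) * C({experiment})"
    formula = f_full if interaction else f_main

    reml = smf.mixedlm(formula, data, groups=data[subject]).fit(reml=True)
    if not reml.converged:
        raise RuntimeError("mixed model did not converge (REML fit)")
    ml_main = smf.mixedlm(f_main, data, groups=data[subject]).fit(reml=False)
    ml_full = smf.mixedlm(f_full, data, groups=data[subject]).fit(reml=False)
    comparison = ModelComparison(
        bic_full=_mixedlm_bic(ml_full), bic_main=_mixedlm_bic(ml_main),
        bf_interaction=bic_bayes_factor(_mixedlm_bic(ml_main),
                                        _mixedlm_bic(ml_full)))

    design_info = reml.model.data.design_info
    fe = reml.fe_params.to_numpy()
    cov_fe = reml.cov_params().iloc[:len(fe), :len(fe)].to_numpy()
    X = np.asarray(reml.model.exog)
    groups_arr = np.asarray(data[subject])
    n_obs, n_subj = X.shape[0], len(np.unique(groups_arr))

    def varies_within(col: np.ndarray) -> bool:
        frame = pd.DataFrame({"g": groups_arr, "x": col})
        return bool((frame.groupby("g")["x"].nunique() > 1).any())

    within_cols = [j for j in range(1, X.shape[1]) if varies_within(X[:, j])]
    df_within = n_obs - n_subj - len(within_cols)
    df_between = n_subj - 1 - (X.shape[1] - 1 - len(within_cols))

    # Wald F tests per fixed term
    anova_rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = list(range(*sl.indices(X.shape[1])))
        L = np.zeros((len(idx), X.shape[1]))
        for r, j in enumerate(idx):
            L[r, j] = 1.0
        est = L @ fe
        vc = L @ cov_fe @ L.T
        fstat = float(est @ np.linalg.solve(vc, est) / len(idx))
        term_within = any(j in within_cols for j in idx)
        df2 = df_within if term_within else df_between
        p = float(stats.f.sf(fstat, len(idx), df2))
        eta = fstat * len(idx) / (fstat * len(idx) + df2)
        anova_rows.append({"term": term, "F": fstat, "df1": len(idx),
                           "df2": df2, "p": p, "partial_eta_sq": eta})
    anova = pd.DataFrame(anova_rows)

    # EMMs for outcome, averaging over experiment levels
    out_levels = list(pd.unique(data[outcome]))
    exp_levels = list(pd.unique(data[experiment]))
    grid = pd.DataFrame([{outcome: o, experiment: e}
                         for o in out_levels for e in exp_levels])
    Xg = np.asarray(dmatrix(design_info, grid, return_type="matrix"))
    emm_rows, Ls = [], {}
    tcrit = stats.t.ppf(0.975, df_within)
    for o in out_levels:
        mask = (grid[outcome] == o).to_numpy()
        L = Xg[mask].mean(axis=0)
        Ls[o] = L
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov_fe @ L))
        emm_rows.append({outcome: o, "emm": est, "se": se,
                         "ci_low": est - tcrit * se,
                         "ci_high": est + tcrit * se, "df": df_within})
    emms = pd.DataFrame(emm_rows)

    k = len(out_levels)
    contrast_rows = []
    for (a, b) in combinations(out_levels, 2):
        L = Ls[a] - Ls[b]
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov_fe @ L))
        q = abs(est) / se * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df_within)) if k > 2 else \
            float(2 * stats.t.sf(abs(est) / se, df_within))
        contrast_rows.append({"level_1": a, "level_2": b, "diff": est,
                              "se_diff": se, "p_tukey": min(p, 1.0),
                              "significant": p < 0.05})
    contrasts = pd.DataFrame(contrast_rows)
    return LmmResult(emms, contrasts, anova, comparison, reml)


# ---------------------------------------------------------------------------
# cross-experiment t test
# ---------------------------------------------------------------------------

def two_sample_t(group1, group2) -> tuple[float, int, float]:
    """Pooled-variance independent-samples t test; returns (t, df, p)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    res = stats.ttest_ind(g1, g2, equal_var=True)
    return float(res.statistic), g1.size + g2.size - 2, float(res.pvalue)
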