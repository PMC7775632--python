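"""Statistical kernel shared by the ASSR and SF pipelines.

Rank tests follow the reporting conventions of the classic desktop packages:
Mann-Whitney U is the exceedance count of the first sample (midrank ties),
Wilcoxon's T is the smaller signed-rank sum, and both report an asymptotic Z
alongside the statistic.  For samples of at most 8 per group the two-sided
p-value comes from exhaustive enumeration of the permutation (resp. sign-flip)
distribution; above that, from the normal approximation with tie-corrected
variance and continuity correction.

The repeated-measures ANOVA supports one between-subject factor and an
arbitrary number of crossed within-subject factors on a balanced design, with
Greenhouse-Geisser epsilon estimated per within effect from the pooled
covariance of orthonormalized contrasts.  Sums of squares are computed by
inclusion-exclusion over margin totals (the classical "uncorrected SS"
decomposition), which makes the conservation property SS_total = sum(SS)
exact by construction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("steadyfield")

__all__ = [
    "GroupComparisonResult",
    "AutismScoreModel",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "fdr_bh",
    "bonferroni",
    "rm_anova_gg",
    "correlation",
    "partial_correlation",
    "hotelling_t2",
    "two_sample_t",
    "cohens_d",
    "partial_eta_squared",
    "autism_score_pca",
]

_EXACT_N = 8  # exhaustive enumeration for rank tests up to this group size


@dataclass
class GroupComparisonResult:
    """One test outcome: statistic, p-values, correction and effect size."""

    test: str
    statistic: float
    p_raw: float
    p_corrected: float | None = None
    correction: str = "none"
    effect_size: tuple | None = None     # (name, value)
    n: tuple | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_corrected):
            if p is not None and not math.isnan(p) and not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} outside [0, 1]")


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U = number of (a, b) pairs with a > b, plus half the ties."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(sample_a, sample_b) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test (exceedance-count convention).

    Exact permutation p-value when both groups have <= 8 observations,
    otherwise normal approximation with tie-corrected variance and
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0

    if max(n1, n2) <= _EXACT_N:
        pooled = np.concatenate([a, b])
        obs_dev = abs(u - mu)
        count = 0
        total = 0
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                count += 1
        p = count / total
        z = np.nan
    else:
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0:
            p, z = 1.0, 0.0          # every observation tied: no evidence
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = 2.0 * sps.norm.sf(z)
    return GroupComparisonResult(
        test="mann-whitney-u",
        statistic=u,
        p_raw=min(p, 1.0) if not math.isnan(p) else p,
        n=(n1, n2),
        effect_size=("rank_biserial", 2.0 * (u - mu) / (n1 * n2)),
        extras={"z": z, "median_a": float(np.median(a)), "median_b": float(np.median(b))},
    )


def wilcoxon_signed_rank(differences) -> GroupComparisonResult:
    """Two-sided Wilcoxon matched-pairs test on paired differences.

    Zero differences are dropped.  T is the smaller of the signed-rank sums;
    Z is the absolute normal-approximation deviate.  Exact sign-flip
    enumeration when <= 8 nonzero differences.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return GroupComparisonResult(
            test="wilcoxon", statistic=math.nan, p_raw=math.nan, n=(d.size,),
            extras={"z": math.nan, "note": "all differences zero"},
        )
    if nonzero.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    n = nonzero.size
    ranks = sps.rankdata(np.abs(nonzero))
    t_plus = float(ranks[nonzero > 0].sum())
    t_minus = float(ranks[nonzero < 0].sum())
    t_stat = min(t_plus, t_minus)
    total = n * (n + 1) / 2.0

    if n <= _EXACT_N:
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w_plus = sum(r for r, s in zip(ranks, signs) if s)
            if min(w_plus, total - w_plus) <= t_stat + 1e-12:
                count += 1
        p = count / 2**n
        mu = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        z = abs(t_plus - mu) / math.sqrt(var) if var > 0 else math.nan
    else:
        mu = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        z = (abs(t_plus - mu) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = 2.0 * sps.norm.sf(z)
    return GroupComparisonResult(
        test="wilcoxon",
        statistic=t_stat,
        p_raw=min(p, 1.0),
        n=(n,),
        extras={"z": z, "t_plus": t_plus, "t_minus": t_minus},
    )


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR over one pooled family.

    Returns ``(reject_mask, adjusted_p)``; NaN entries are never rejected and
    stay NaN in the adjusted vector.
    """
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    reject = np.zeros(flat.size, dtype=bool)
    adj = np.full(flat.size, np.nan)
    if ok.any():
        r, a, *_ = multipletests(flat[ok], alpha=q, method="fdr_bh")
        reject[ok] = r
        adj[ok] = a
    return reject.reshape(p.shape), adj.reshape(p.shape)


def bonferroni(
    p_values, family_size: int | None = None, family_alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bonferroni correction: adjusted p = min(1, p*m), threshold alpha/m."""
    p = np.asarray(p_values, dtype=float)
    m = family_size if family_size is not None else p.size
    if m < 1:
        raise ValueError("family_size must be >= 1")
    adj = np.minimum(p * m, 1.0)
    threshold = family_alpha / m
    return p <= threshold, adj, threshold


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1, levels) orthonormal basis of the contrast space."""
    basis = np.eye(levels) - 1.0 / levels
    q, _ = np.linalg.qr(basis.T)
    return q[:, : levels - 1].T


def _gg_epsilon(y_cells: np.ndarray, groups: np.ndarray, within_levels, subset) -> float:
    """GG epsilon for one within effect from pooled contrast covariance."""
    mats = []
    for i, li in enumerate(within_levels):
        if i in subset:
            mats.append(_orthonormal_contrasts(li))
        else:
            mats.append(np.ones((1, li)) / math.sqrt(li))
    c = mats[0]
    for m_i in mats[1:]:
        c = np.kron(c, m_i)
    z = y_cells.reshape(y_cells.shape[0], -1) @ c.T          # (N, d)
    d = z.shape[1]
    if d == 1:
        return 1.0
    # pool within-group covariance
    resid = np.empty_like(z)
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] = z[sel] - z[sel].mean(axis=0)
    n_groups = np.unique(groups).size
    sigma = resid.T @ resid / (z.shape[0] - n_groups)
    tr = np.trace(sigma)
    tr2 = np.trace(sigma @ sigma)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(min(1.0, max(eps, 1.0 / d)))


def rm_anova_gg(
    data: np.ndarray,
    groups,
    within_names: list[str] | None = None,
    between_name: str = "group",
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA on a balanced cell-means table.

    ``data`` has shape (n_subjects, l1, l2, ...) with one axis per within
    factor; ``groups`` assigns each subject to a level of the between factor.
    Returns a table with F, raw and GG-adjusted p, epsilon and partial
    eta-squared per effect.
    """
    y = np.asarray(data, dtype=float)
    if np.isnan(y).any():
        missing = np.argwhere(np.isnan(y))
        raise ValueError(f"missing cells at indices {missing[:5].tolist()}...")
    groups = np.asarray(groups)
    n_subj = y.shape[0]
    if groups.shape[0] != n_subj:
        raise ValueError("groups length must match the subject axis")
    levels = np.unique(groups)
    if any((groups == g).sum() < 2 for g in levels):
        raise ValueError("need >= 2 subjects per group")
    within_levels = y.shape[1:]
    n_within = len(within_levels)
    names = within_names or [f"W{i + 1}" for i in range(n_within)]
    cells_per_subj = int(np.prod(within_levels)) if n_within else 1

    # margin totals: U(F) = sum over F-margin cells of total^2 / n_obs_per_cell
    g_index = np.searchsorted(levels, groups)
    n_per_group = np.array([(g_index == i).sum() for i in range(levels.size)])
    if np.unique(n_per_group).size > 1 and levels.size > 1:
        pass  # unbalanced between-group sizes are fine for this decomposition

    def u_term(with_subj: bool, with_group: bool, subset: tuple) -> float:
        axes_keep = tuple(i + 1 for i in subset)
        axes_sum = tuple(i + 1 for i in range(n_within) if i not in subset)
        marg = y.sum(axis=axes_sum) if axes_sum else y.copy()
        # marg: (n_subj, levels of subset...)
        flat = marg.reshape(n_subj, -1)
        per_cell_obs = np.prod(
            [within_levels[i] for i in range(n_within) if i not in subset], dtype=float
        ) if n_within else 1.0
        if with_subj:
            return float((flat**2).sum() / per_cell_obs)
        if with_group:
            tot = 0.0
            for i in range(levels.size):
                gsum = flat[g_index == i].sum(axis=0)
                tot += (gsum**2 / (per_cell_obs * n_per_group[i])).sum()
            return float(tot)
        gsum = flat.sum(axis=0)
        return float((gsum**2 / (per_cell_obs * n_subj)).sum())

    rows = []
    ss_total = float(((y - y.mean()) ** 2).sum())

    # between-subject stratum
    u_empty = u_term(False, False, ())
    u_group = u_term(False, True, ())
    u_subj = u_term(True, False, ())
    ss_group = u_group - u_empty
    ss_subj = u_subj - u_group
    df_group = levels.size - 1
    df_subj = n_subj - levels.size
    ms_group = ss_group / df_group if df_group else np.nan
    ms_subj = ss_subj / df_subj
    if df_group:
        f = ms_group / ms_subj
        p = sps.f.sf(f, df_group, df_subj)
        rows.append(
            dict(effect=between_name, F=f, df1=df_group, df2=df_subj, p=p,
                 p_gg=p, gg_epsilon=np.nan, SS=ss_group, SS_error=ss_subj,
                 partial_eta_squared=ss_group / (ss_group + ss_subj))
        )

    accounted = ss_group + ss_subj

    # within-subject strata, one per nonempty subset of within factors
    for r in range(1, n_within + 1):
        for subset in itertools.combinations(range(n_within), r):
            def ie(fn) -> float:
                tot = 0.0
                for rr in range(r + 1):
                    for sub2 in itertools.combinations(subset, rr):
                        tot += (-1) ** (r - rr) * fn(sub2)
                return tot

            ss_eff = ie(lambda s: u_term(False, False, s))
            ss_gx = ie(lambda s: u_term(False, True, s)) - ss_eff
            ss_err = ie(lambda s: u_term(True, False, s)) - ss_eff - ss_gx
            df_eff = int(np.prod([within_levels[i] - 1 for i in subset]))
            df_gx = df_group * df_eff
            df_err = df_subj * df_eff
            ms_err = ss_err / df_err
            eps = _gg_epsilon(y, groups, within_levels, subset)
            label = " x ".join(names[i] for i in subset)

            if ms_err == 0:
                # degenerate: no within-subject error variance for this effect
                ms_err = np.nan
            f_eff = (ss_eff / df_eff) / ms_err
            rows.append(
                dict(effect=label, F=f_eff, df1=df_eff, df2=df_err,
                     p=sps.f.sf(f_eff, df_eff, df_err),
                     p_gg=sps.f.sf(f_eff, eps * df_eff, eps * df_err),
                     gg_epsilon=eps, SS=ss_eff, SS_error=ss_err,
                     partial_eta_squared=ss_eff / (ss_eff + ss_err))
            )
            if df_group:
                f_gx = (ss_gx / df_gx) / ms_err
                rows.append(
                    dict(effect=f"{label} x {between_name}", F=f_gx, df1=df_gx,
                         df2=df_err, p=sps.f.sf(f_gx, df_gx, df_err),
                         p_gg=sps.f.sf(f_gx, eps * df_gx, eps * df_err),
                         gg_epsilon=eps, SS=ss_gx, SS_error=ss_err,
                         partial_eta_squared=ss_gx / (ss_gx + ss_err))
                )
                accounted += ss_gx
            accounted += ss_eff + ss_err

    table = pd.DataFrame(rows)
    table.attrs["ss_total"] = ss_total
    table.attrs["ss_accounted"] = accounted
    return table


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _residualize(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(covariate, v, 1)
    return v - (slope * covariate + intercept)


def correlation(
    x, y, method: str = "pearson", residualize_on=None
) -> GroupComparisonResult:
    """Pearson or Spearman correlation with optional linear detrending.

    When ``residualize_on`` is given, both variables are replaced by their
    residuals from a least-squares linear fit on the covariate (e.g. age)
    before correlating.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if residualize_on is not None:
        cov = np.asarray(residualize_on, dtype=float)
        keep &= ~np.isnan(cov)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        return GroupComparisonResult(
            test=method, statistic=math.nan, p_raw=math.nan, n=(x.size,),
            extras={"note": "zero variance"},
        )
    if residualize_on is not None:
        cov = np.asarray(residualize_on, dtype=float)[keep]
        x = _residualize(x, cov)
        y = _residualize(y, cov)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return GroupComparisonResult(
        test=method, statistic=float(r), p_raw=float(p), n=(x.size,)
    )


def partial_correlation(x, y, controls) -> GroupComparisonResult:
    """Correlation of x and y after regressing both on the control set."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.atleast_2d(np.asarray(controls, dtype=float))
    if c.shape[0] == x.size and c.shape[1] != x.size:
        c = c.T                                    # (k, n)
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(c).any(axis=0))
    x, y, c = x[keep], y[keep], c[:, keep]
    k = c.shape[0]
    n = x.size
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} complete cases, got {n}")
    design = np.column_stack([np.ones(n), c.T])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(f"collinear controls (design rank {rank} < {design.shape[1]})")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if rx.std() <= 1e-10 * max(x.std(), 1e-300) or ry.std() <= 1e-10 * max(
        y.std(), 1e-300
    ):
        return GroupComparisonResult(
            test="partial-correlation", statistic=math.nan, p_raw=math.nan,
            n=(n,), extras={"note": "zero residual variance"},
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparisonResult(
        test="partial-correlation", statistic=r, p_raw=p, n=(n,),
        extras={"df": df, "n_controls": k},
    )


# ---------------------------------------------------------------------------
# Multivariate and effect sizes
# ---------------------------------------------------------------------------

def hotelling_t2(x, y, axis_names=None) -> GroupComparisonResult:
    """Two-sample Hotelling T-squared with F conversion.

    ``x`` and ``y`` are (n_i, p) coordinate samples.  Reports T2, the exact
    F transform with (p, n1+n2-p-1) degrees of freedom, and partial
    eta-squared T2/(T2 + n1 + n2 - 2).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("samples must share dimensionality")
    n1, n2, p_dim = x.shape[0], y.shape[0], x.shape[1]
    if min(n1, n2) < 3:
        raise ValueError("need >= 3 subjects per group")
    d = x.mean(axis=0) - y.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(x.T, ddof=1) + (n2 - 1) * np.cov(y.T, ddof=1)) / (
        n1 + n2 - 2
    )
    s_pooled = np.atleast_2d(s_pooled)
    eigvals = np.linalg.eigvalsh(s_pooled)
    if eigvals.min() <= 1e-12 * max(eigvals.max(), 1.0):
        names = axis_names or [f"axis{i}" for i in range(p_dim)]
        bad = [names[i] for i in np.argsort(np.diag(s_pooled))[:2]]
        raise ValueError(f"singular pooled covariance; near-collinear axes: {bad}")
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s_pooled, d))
    df2 = n1 + n2 - p_dim - 1
    f = t2 * df2 / ((n1 + n2 - 2) * p_dim)
    p = sps.f.sf(f, p_dim, df2)
    return GroupComparisonResult(
        test="hotelling-t2", statistic=t2, p_raw=float(p), n=(n1, n2),
        effect_size=("partial_eta_squared", t2 / (t2 + n1 + n2 - 2)),
        extras={"F": f, "df1": p_dim, "df2": df2},
    )


def cohens_d(sample_a, sample_b) -> float:
    """d = mean difference over pooled SD; NaN when the pooled SD is zero."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = math.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return math.nan
    return float((a.mean() - b.mean()) / pooled)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    return ss_effect / (ss_effect + ss_error)


def two_sample_t(sample_a, sample_b) -> GroupComparisonResult:
    """Pooled-variance two-sample t test with Cohen's d."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparisonResult(
        test="t-test", statistic=float(t), p_raw=float(p), n=(a.size, b.size),
        effect_size=("cohens_d", cohens_d(a, b)),
        extras={"df": a.size + b.size - 2, "mean_a": a.mean(), "mean_b": b.mean()},
    )


# ---------------------------------------------------------------------------
# PCA Autism Score
# ---------------------------------------------------------------------------

@dataclass
class AutismScoreModel:
    """First-principal-component summary of the three autism severity scales."""

    scale_names: list
    means: np.ndarray           # per-scale means used for the z-transform
    sds: np.ndarray
    loadings: np.ndarray        # unit-norm first-PC loading vector
    variance_explained: float
    imputation: str = "mean of the subject's available z-scores"

    def transform(self, table: pd.DataFrame) -> pd.Series:
        """Score new rows with the fitted z-transform and loading vector."""
        z = (table[self.scale_names].to_numpy(dtype=float) - self.means) / self.sds
        row_mean = np.nanmean(z, axis=1, keepdims=True)
        z = np.where(np.isnan(z), row_mean, z)
        return pd.Series(z @ self.loadings, index=table.index, name="autism_score")


def autism_score_pca(
    scale_table: pd.DataFrame,
    scale_names: list | None = None,
) -> tuple[AutismScoreModel, pd.Series]:
    """Fit the PCA 'Autism Score' on a table of severity scale scores.

    Scales are z-transformed; a subject's missing entries are imputed with the
    mean of their available z-scores; subjects with no scales at all are
    dropped.  The first-PC loading vector is oriented so that higher raw
    severity gives a higher score.  Fit on one group's rows only (the ASD
    group in the default workflow); use ``model.transform`` elsewhere.
    """
    names = scale_names or ["srs", "scq", "aq"]
    raw = scale_table[names].to_numpy(dtype=float)
    has_any = ~np.isnan(raw).all(axis=1)
    if (~has_any).any():
        logger.info(
            "autism_score_pca: dropped %d subjects with no scale data", (~has_any).sum()
        )
    raw = raw[has_any]
    if raw.shape[0] < 3:
        raise ValueError("need at least 3 subjects with at least one scale each")
    means = np.nanmean(raw, axis=0)
    sds = np.nanstd(raw, axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("a scale has zero variance")
    z = (raw - means) / sds
    row_mean = np.nanmean(z, axis=1, keepdims=True)
    z = np.where(np.isnan(z), row_mean, z)

    cov = np.cov(z.T, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    loading = eigvecs[:, 0]
    if loading.mean() < 0:                      # higher severity -> higher score
        loading = -loading
    scores = pd.Series(
        z @ loading, index=scale_table.index[has_any], name="autism_score"
    )
    model = AutismScoreModel(
        scale_names=names,
        means=means,
        sds=sds,
        loadings=loading,
        variance_explained=float(eigvals[0] / eigvals.sum()),
    )
    return model, scores
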