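"""Ordinary least squares with the inference used for cis-regulatory models.

Fits are plain Gaussian OLS with an intercept: per-term two-sided t tests,
a model F test against the intercept-only model, adjusted r-squared, and the
Gaussian profile log-likelihood that the nested likelihood-ratio test needs.
Non-nested models are compared with the Davidson-MacKinnon J-test: model B's
fitted values enter model A's design as a single proxy regressor and the
proxy coefficient's t test measures whether B captures signal that A misses.

Numerics go through QR/SVD (numpy lstsq and a thin QR for the covariance);
the cross-product matrix is never inverted explicitly, and rank deficiency
is detected and reported rather than silently regularised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetics_core import GenotypeMatrix

__all__ = [
    "LinearModelFit",
    "ComparisonResult",
    "CollinearityError",
    "fit_ols",
    "lrt_nested",
    "jtest",
    "stars",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient (exactly collinear columns)."""


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class LinearModelFit:
    """A fitted OLS model of a response on variant dosages plus intercept."""

    response_name: str
    variant_ids: list[str]
    sample_ids: list[str]
    n: int
    intercept: float
    coefficients: np.ndarray
    std_errors: np.ndarray  # intercept first, then per-variant
    term_pvalues: np.ndarray  # per-variant, two-sided t
    t_values: np.ndarray  # per-variant
    r2: float
    adj_r2: float
    f_statistic: float
    f_pvalue: float
    rss: float
    loglik: float
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)

    @property
    def p(self) -> int:
        return len(self.variant_ids)

    @property
    def df_resid(self) -> int:
        return self.n - self.p - 1

    def term_table(self) -> pd.DataFrame:
        """Per-term summary: estimate, SE, t, P (intercept first)."""
        terms = ["(intercept)"] + list(self.variant_ids)
        est = np.concatenate(([self.intercept], self.coefficients))
        tvals = np.concatenate(([np.nan], self.t_values))
        pvals = np.concatenate(([np.nan], self.term_pvalues))
        return pd.DataFrame(
            {"term": terms, "estimate": est, "se": self.std_errors,
             "t": tvals, "p": pvals}
        )

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "variants": list(self.variant_ids),
            "n": self.n,
            "intercept": self.intercept,
            "coefficients": dict(zip(self.variant_ids, map(float, self.coefficients))),
            "term_pvalues": dict(zip(self.variant_ids, map(float, self.term_pvalues))),
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "f_pvalue": self.f_pvalue,
            "rss": self.rss,
            "loglik": self.loglik,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Core solver
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming a dependent column set if X is singular."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # walk columns left to right; a column that does not raise the running
    # rank is linearly dependent on those before it
    dependent = []
    prev = 0
    for j in range(1, X.shape[1] + 1):
        cur = np.linalg.matrix_rank(X[:, :j])
        if cur == prev:
            dependent.append(names[j - 1])
        prev = cur
    raise CollinearityError(
        f"design matrix is rank deficient; dependent column(s): {dependent}"
    )


def _ols_core(y: np.ndarray, X: np.ndarray, names: list[str]) -> dict:
    """OLS of y on X (X includes the intercept column). Returns raw pieces."""
    n, k = X.shape
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df_resid = n - k
    # covariance via economic QR: (X'X)^-1 = R^-1 R^-T
    _, R = np.linalg.qr(X)
    Rinv = np.linalg.solve(R, np.eye(k))
    xtx_inv = Rinv @ Rinv.T
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(
            se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta))
        )
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return {
        "beta": beta, "se": se, "t": tvals, "p": pvals,
        "fitted": fitted, "resid": resid, "rss": rss, "df_resid": df_resid,
    }


def design_matrix(
    g: GenotypeMatrix, variant_ids: list[str], y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-case design over the given variants.

    Returns (y_cc, X_cc without intercept, boolean keep-mask over samples).
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != g.n_samples:
        raise ValueError(
            f"response length {y.shape[0]} != {g.n_samples} genotype samples"
        )
    cols = (
        np.column_stack([g.dosage(v) for v in variant_ids])
        if variant_ids
        else np.empty((g.n_samples, 0))
    )
    keep = ~np.isnan(y)
    if cols.shape[1]:
        keep &= ~np.isnan(cols).any(axis=1)
    return y[keep], cols[keep], keep


def fit_ols(
    y,
    g: GenotypeMatrix,
    variant_ids: list[str],
    response_name: str = "y",
) -> LinearModelFit:
    """OLS of a per-sample response on additive dosages of the given variants.

    ``y`` is aligned with ``g.sample_ids`` (array) or matched by index
    (pandas Series).  Samples missing the response or any dosage are dropped
    (complete-case); the retained sample ids are recorded on the fit so model
    comparisons can enforce identical samples.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(g.sample_ids).to_numpy(dtype=float)
    y_cc, X0, keep = design_matrix(g, list(variant_ids), y)
    n, p = X0.shape
    if n <= p + 1:
        raise ValueError(f"n={n} samples insufficient for p={p} predictors")
    X = np.column_stack([np.ones(n), X0])
    core = _ols_core(y_cc, X, ["(intercept)"] + list(variant_ids))

    tss = float(((y_cc - y_cc.mean()) ** 2).sum())
    rss = core["rss"]
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = max(min(r2, 1.0), 0.0 if p == 0 else -np.inf)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if p else 0.0
    if p:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ((tss - rss) / p) / (rss / (n - p - 1)) if rss > 0 else np.inf
        f_p = float(stats.f.sf(f_stat, p, n - p - 1))
    else:
        f_stat, f_p = np.nan, 1.0
    # Gaussian profile log-likelihood with sigma^2 = RSS/n
    loglik = (
        -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0) if rss > 0 else np.inf
    )
    return LinearModelFit(
        response_name=response_name,
        variant_ids=list(variant_ids),
        sample_ids=[s for s, k in zip(g.sample_ids, keep) if k],
        n=n,
        intercept=float(core["beta"][0]),
        coefficients=core["beta"][1:],
        std_errors=core["se"],
        term_pvalues=core["p"][1:],
        t_values=core["t"][1:],
        r2=float(r2),
        adj_r2=float(adj_r2),
        f_statistic=float(f_stat),
        f_pvalue=float(f_p),
        rss=rss,
        loglik=float(loglik),
        fitted=core["fitted"],
        residuals=core["resid"],
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance label: n.s. / * / ** / *** / **** at 0.05/0.01/0.001/0.0001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p value {p} outside [0, 1]")
    for cut, label in STAR_THRESHOLDS:
        if p < cut:
            return label
    return "n.s."


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a nested LRT or one direction of a J-test."""

    kind: str  # "nested_LRT" | "jtest"
    direction: str  # LRT: "small_vs_large"; J-test: name of the model under test
    statistic: float
    df: int | None
    p_value: float
    verdict: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "verdict", stars(self.p_value))


def lrt_nested(small: LinearModelFit, large: LinearModelFit) -> ComparisonResult:
    """Likelihood-ratio test of nested OLS models.

    statistic = 2 (ll_large - ll_small) = n ln(RSS_small / RSS_large),
    referred to chi-square with df = difference in predictor count.
    """
    if set(small.variant_ids) - set(large.variant_ids):
        raise ValueError("models are not nested: small has terms absent from large")
    if small.sample_ids != large.sample_ids:
        raise ValueError("nested comparison requires identical sample sets")
    if small.response_name != large.response_name:
        raise ValueError("nested comparison requires the same response")
    df = large.p - small.p
    if df == 0:
        return ComparisonResult("nested_LRT", "small_vs_large", 0.0, 0, 1.0)
    # a numerically perfect small model leaves nothing to improve
    if small.rss <= 1e-12 * max(1.0, small.n):
        return ComparisonResult("nested_LRT", "small_vs_large", 0.0, df, 1.0)
    if large.rss <= 0:
        statistic = np.inf
    else:
        statistic = small.n * np.log(small.rss / large.rss)
    statistic = max(float(statistic), 0.0)
    p = float(stats.chi2.sf(statistic, df)) if np.isfinite(statistic) else 0.0
    return ComparisonResult("nested_LRT", "small_vs_large", statistic, df, p)


def lrt_f_change(small: LinearModelFit, large: LinearModelFit) -> ComparisonResult:
    """F-change calibration of the same nested comparison (small-sample)."""
    if set(small.variant_ids) - set(large.variant_ids):
        raise ValueError("models are not nested: small has terms absent from large")
    if small.sample_ids != large.sample_ids:
        raise ValueError("nested comparison requires identical sample sets")
    df = large.p - small.p
    if df == 0:
        return ComparisonResult("nested_F", "small_vs_large", 0.0, 0, 1.0)
    df2 = large.df_resid
    f = ((small.rss - large.rss) / df) / (large.rss / df2)
    p = float(stats.f.sf(max(f, 0.0), df, df2))
    return ComparisonResult("nested_F", "small_vs_large", max(float(f), 0.0), df, p)


def jtest(
    y,
    g: GenotypeMatrix,
    predictors_a: list[str],
    predictors_b: list[str],
    name_a: str = "A",
    name_b: str = "B",
) -> tuple[ComparisonResult, ComparisonResult]:
    """Davidson-MacKinnon J-test of two non-nested variant compositions.

    Direction "A" tests model A's adequacy: B is fitted, its fitted values
    enter A's design as a proxy regressor, and the proxy coefficient's
    two-sided t P value is reported (a small P means B captures signal A
    misses).  Both directions are always returned, never averaged.
    Both models are fitted on the common complete-case sample set.
    """
    sa, sb = set(predictors_a), set(predictors_b)
    if sa <= sb or sb <= sa:
        raise ValueError("models are nested; use lrt_nested instead of the J-test")
    if isinstance(y, pd.Series):
        y = y.reindex(g.sample_ids).to_numpy(dtype=float)
    union = list(predictors_a) + [v for v in predictors_b if v not in sa]
    y_cc, X_union, keep = design_matrix(g, union, y)
    n = y_cc.shape[0]
    col = {v: j for j, v in enumerate(union)}

    def base(preds: list[str]) -> np.ndarray:
        return np.column_stack(
            [np.ones(n)] + [X_union[:, col[v]] for v in preds]
        )

    Xa, Xb = base(list(predictors_a)), base(list(predictors_b))
    fit_a = _ols_core(y_cc, Xa, ["(intercept)"] + list(predictors_a))
    fit_b = _ols_core(y_cc, Xb, ["(intercept)"] + list(predictors_b))

    def direction(
        X_base: np.ndarray, names: list[str], proxy: np.ndarray, label: str
    ) -> ComparisonResult:
        # degenerate if the proxy lies in the span of the base design
        resid_norm = np.linalg.norm(
            proxy - X_base @ np.linalg.lstsq(X_base, proxy, rcond=None)[0]
        )
        if resid_norm < 1e-8 * max(np.linalg.norm(proxy), 1.0):
            raise CollinearityError(
                f"J-test degenerate: proxy fitted values are collinear with "
                f"model {label}'s design"
            )
        X_aug = np.column_stack([X_base, proxy])
        core = _ols_core(y_cc, X_aug, names + ["(proxy)"])
        return ComparisonResult(
            "jtest", label, float(core["t"][-1]), None, float(core["p"][-1])
        )

    res_a = direction(
        Xa, ["(intercept)"] + list(predictors_a), fit_b["fitted"], name_a
    )
    res_b = direction(
        Xb, ["(intercept)"] + list(predictors_b), fit_a["fitted"], name_b
    )
    return res_a, res_b


def comparisons_to_tsv(results: list[ComparisonResult], path) -> None:
    pd.DataFrame(
        [
            {
                "kind": r.kind, "direction": r.direction,
                "statistic": r.statistic, "df": r.df,
                "p_value": r.p_value, "verdict": r.verdict,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
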