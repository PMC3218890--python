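"""Haplotype- and allele-level association with expression.

Each haplotype's per-sample copy number (0/1/2) is regressed univariately
against standardized expression; coefficients come with t-based 95%
confidence intervals (n-2 degrees of freedom).  Single-variant association
uses the same machinery on minor-allele dosage.  The squared correlation
between a fitted cis-regulatory model's predictions and a haplotype dosage
measures how much of the model a haplotype captures.

Joint regression on all haplotype dosages is deliberately refused: the
dosages of a complete haplotype set sum to 2 for every diploid sample, so
the joint design with an intercept is exactly rank deficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetics_core import GenotypeMatrix, HaplotypeSet
from .regression_engine import CollinearityError, LinearModelFit

__all__ = [
    "HaplotypeAssociation",
    "ModelHaplotypeCorrelation",
    "haplotype_association",
    "allele_association",
    "model_haplotype_r2",
    "rescale_for_panel",
    "joint_haplotype_regression",
    "associations_to_tsv",
]


@dataclass(frozen=True)
class HaplotypeAssociation:
    """Univariate regression of expression on a 0/1/2 dosage."""

    haplotype_id: str
    dataset: str
    beta: float
    ci_lo: float
    ci_hi: float
    p_value: float
    n: int
    r2: float
    minor_allele: str | None = None  # set for single-variant associations

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.beta <= self.ci_hi):
            raise ValueError("confidence interval must contain the point estimate")


def _univariate(y: np.ndarray, d: np.ndarray, label: str, dataset: str,
                minor_allele: str | None = None,
                conf_level: float = 0.95) -> HaplotypeAssociation:
    ok = ~np.isnan(y) & ~np.isnan(d)
    y, d = y[ok], d[ok]
    n = y.size
    if n < 3:
        raise ValueError(f"{label}: fewer than 3 complete observations")
    if np.ptp(d) == 0:
        raise ValueError(f"{label}: dosage is monomorphic")
    res = stats.linregress(d, y)
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, n - 2)
    half = tcrit * res.stderr
    return HaplotypeAssociation(
        haplotype_id=label,
        dataset=dataset,
        beta=float(res.slope),
        ci_lo=float(res.slope - half),
        ci_hi=float(res.slope + half),
        p_value=float(res.pvalue),
        n=n,
        r2=float(res.rvalue**2),
        minor_allele=minor_allele,
    )


def haplotype_association(
    y, dosage, haplotype_id: str = "hap", dataset: str = "y"
) -> HaplotypeAssociation:
    """Univariate OLS of expression on a haplotype's 0/1/2 copy number.

    ``y`` and ``dosage`` must be aligned per sample (pandas Series are
    aligned on their index).
    """
    if isinstance(y, pd.Series) and isinstance(dosage, pd.Series):
        shared = y.index.intersection(dosage.index)
        y, dosage = y.loc[shared].to_numpy(), dosage.loc[shared].to_numpy()
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if y.shape != dosage.shape:
        raise ValueError("response and dosage must have equal length")
    return _univariate(y, dosage, haplotype_id, dataset)


def allele_association(
    y, g: GenotypeMatrix, variant_id: str, dataset: str = "y"
) -> HaplotypeAssociation:
    """Single-variant association on minor-allele dosage.

    The dosage is oriented to count the minor allele as observed in the
    analysed samples (recorded on the result), so the coefficient sign reads
    as the per-minor-allele-copy effect regardless of ref/alt labelling.
    """
    d = g.dosage(variant_id)
    if isinstance(y, pd.Series):
        y = y.reindex(g.sample_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    meta = g.variant_meta.loc[variant_id]
    freq = np.nanmean(d) / 2.0
    if freq > 0.5:
        d = 2.0 - d
        minor = str(meta["ref"])
    else:
        minor = str(meta["alt"])
    return _univariate(y, d, variant_id, dataset, minor_allele=minor)


@dataclass(frozen=True)
class ModelHaplotypeCorrelation:
    model_id: str
    haplotype_id: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 {self.r2} outside [0, 1]")


def model_haplotype_r2(
    fit: LinearModelFit, dosage, haplotype_id: str = "hap"
) -> ModelHaplotypeCorrelation:
    """Squared correlation between a model's fitted values and a haplotype dosage."""
    if isinstance(dosage, pd.Series):
        dosage = dosage.reindex(fit.sample_ids).to_numpy(dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if dosage.shape[0] != len(fit.sample_ids):
        raise ValueError("dosage must cover exactly the fitted samples")
    if np.isnan(dosage).any():
        raise ValueError("dosage contains missing values over fitted samples")
    if np.ptp(fit.fitted) == 0 or np.ptp(dosage) == 0:
        raise ValueError("undefined correlation: constant fitted values or dosage")
    r = float(np.corrcoef(fit.fitted, dosage)[0, 1])
    name = "+".join(fit.variant_ids) if fit.variant_ids else "(intercept)"
    return ModelHaplotypeCorrelation(name, haplotype_id, min(r * r, 1.0))


def rescale_for_panel(
    associations: list[HaplotypeAssociation],
) -> pd.DataFrame:
    """Display-only rescaling: per dataset, divide by the max |coefficient|.

    CI endpoints scale by the same positive factor, so signs and
    zero-crossing (significance) status are preserved.  Never feed the
    rescaled values back into analysis.
    """
    rows = []
    by_dataset: dict[str, list[HaplotypeAssociation]] = {}
    for a in associations:
        by_dataset.setdefault(a.dataset, []).append(a)
    for dataset, group in by_dataset.items():
        scale = max(abs(a.beta) for a in group)
        if scale == 0:
            warnings.warn(
                f"dataset {dataset}: all coefficients zero; no rescaling",
                stacklevel=2,
            )
            scale = 1.0
        for a in group:
            rows.append(
                {
                    "dataset": dataset,
                    "haplotype": a.haplotype_id,
                    "beta_scaled": a.beta / scale,
                    "ci_lo_scaled": a.ci_lo / scale,
                    "ci_hi_scaled": a.ci_hi / scale,
                    "p_value": a.p_value,
                    "scale": scale,
                }
            )
    return pd.DataFrame(rows)


def joint_haplotype_regression(y, hs: HaplotypeSet, mode: str = "expected"):
    """Detect the degeneracy of joint haplotype-dosage regression.

    Dosages over a complete haplotype set sum to 2 per sample, so the design
    with an intercept is exactly collinear.  This function builds that
    design, verifies the rank deficiency and reports it instead of fitting;
    use univariate haplotype_association per haplotype.
    """
    from .genetics_core import haplotype_dosage

    cols = np.column_stack(
        [haplotype_dosage(hs, h, mode=mode) for h in hs.haplotype_ids]
    )
    X = np.column_stack([np.ones(cols.shape[0]), cols])
    # posterior-expected dosages carry EM round-off; rank to a loose tolerance
    smax = float(np.linalg.svd(X, compute_uv=False)[0])
    rank = int(np.linalg.matrix_rank(X, tol=1e-6 * smax))
    if rank < X.shape[1]:
        raise CollinearityError(
            f"haplotype dosages sum to 2 per sample: joint design with "
            f"intercept has rank {rank} < {X.shape[1]} columns; fit "
            f"per-haplotype univariate models instead"
        )
    raise RuntimeError(
        "joint haplotype design unexpectedly full rank; refusing joint fit "
        "anyway -- use univariate haplotype_association"
    )


def associations_to_tsv(associations: list[HaplotypeAssociation], path) -> None:
    pd.DataFrame(
        [
            {
                "dataset": a.dataset,
                "haplotype": a.haplotype_id,
                "beta": a.beta,
                "ci_lo": a.ci_lo,
                "ci_hi": a.ci_hi,
                "p": a.p_value,
                "n": a.n,
                "minor_allele": a.minor_allele,
            }
            for a in associations
        ]
    ).to_csv(path, sep="\t", index=False)


def forest_plot(associations: list[HaplotypeAssociation], path) -> None:
    """Optional forest-style panel of rescaled coefficients per dataset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = rescale_for_panel(associations)
    datasets = list(dict.fromkeys(table["dataset"]))
    haps = list(dict.fromkeys(table["haplotype"]))
    fig, ax = plt.subplots(figsize=(1.8 * len(datasets) + 2, 4))
    width = 0.8 / max(len(datasets), 1)
    for k, ds in enumerate(datasets):
        sub = table[table["dataset"] == ds].set_index("haplotype").loc[haps]
        x = np.arange(len(haps)) + k * width
        ax.errorbar(
            x, sub["beta_scaled"],
            yerr=[sub["beta_scaled"] - sub["ci_lo_scaled"],
                  sub["ci_hi_scaled"] - sub["beta_scaled"]],
            fmt="o", capsize=2, label=ds,
        )
    ax.axhline(0.0, ls="--", c="grey", lw=0.8)
    ax.set_xticks(np.arange(len(haps)) + 0.4 - width / 2)
    ax.set_xticklabels(haps)
    ax.set_ylabel("rescaled regression coefficient (95% CI)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
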