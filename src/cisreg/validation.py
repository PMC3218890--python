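"""Calibration and validation studies for the statistical machinery.

These routines measure, by simulation, the operating characteristics that
the analysis relies on: agreement of the OLS solver with a brute-force
normal-equation computation, agreement of greedy forward entry with an
exhaustive subset search, type-I error of the nested LRT and of the J-test
under their nulls, J-test power and directionality, recovery of simulated
genotype-explained variance by the selected model, equivalence of the EM
phasing frequencies with a grid-search likelihood maximisation, confidence
interval coverage, and the qualitative patterns of the four-study fixture.

Each routine derives its own child seeds from the seed it is given, so a
single integer reproduces the whole battery.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .association_analysis import (
    haplotype_association,
    model_haplotype_r2,
)
from .expression_core import (
    filter_intron_probes,
    make_composite,
    probe_r2_matrix,
    select_representative_group,
    standardize,
)
from .genetics_core import (
    GenotypeMatrix,
    em_phase,
    haplotype_dosage,
    prune_by_ld,
)
from .model_selection import (
    _exhaustive_best_subset,
    compare_to_best,
    forward_select,
)
from .regression_engine import fit_ols, jtest, lrt_nested
from .synthetic_data import (
    EffectSpec,
    default_haplotype_pool,
    make_four_study_fixture,
    noise_sd_for_h2,
    simulate_expression,
    simulate_genotypes,
)

__all__ = [
    "ols_oracle_max_diff",
    "forward_selection_oracle_agreement",
    "lrt_type1_rate",
    "jtest_type1_rate",
    "jtest_power",
    "h2_recovery",
    "em_vs_grid_max_diff",
    "em_recovery_max_z",
    "ci_coverage",
    "fixture_patterns",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _binomial_genotypes(rng: np.random.Generator, n: int, m: int,
                        maf_lo: float = 0.1, maf_hi: float = 0.5) -> GenotypeMatrix:
    mafs = rng.uniform(maf_lo, maf_hi, size=m)
    while True:
        d = rng.binomial(2, mafs, size=(n, m)).astype(float)
        if (d.std(axis=0) > 0).all():
            break
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=[f"v{j + 1}" for j in range(m)],
        dosages=d,
    )


# ---------------------------------------------------------------------------
# OLS vs normal equations
# ---------------------------------------------------------------------------

def ols_oracle_max_diff(seed: int, n_instances: int = 100) -> float:
    """Max |difference| between fit_ols and explicit normal equations.

    Random designs with n <= 50, p <= 5; compares coefficients (with
    intercept), RSS and adjusted r-squared.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(10, 51))
        p = int(rng.integers(1, 6))
        g = _binomial_genotypes(rng, n, p)
        y = rng.normal(size=n) + g.dosages @ rng.normal(0, 0.5, p)
        fit = fit_ols(y, g, g.variant_ids)
        X = np.column_stack([np.ones(n), g.dosages])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        adj = 1 - (1 - (1 - rss / tss)) * (n - 1) / (n - p - 1)
        worst = max(
            worst,
            float(np.abs(np.concatenate(([fit.intercept], fit.coefficients))
                         - beta).max()),
            abs(fit.rss - rss),
            abs(fit.adj_r2 - adj),
        )
    return worst


# ---------------------------------------------------------------------------
# forward entry vs exhaustive subset search
# ---------------------------------------------------------------------------

def forward_selection_oracle_agreement(
    seed: int, n_panels: int = 50, n: int = 200, m: int = 15
) -> float:
    """Fraction of seeded panels where greedy == exhaustive best subset.

    Panels of m independent variants with up to 3 causal effects drawn from
    (1.0, 0.7, 0.4), unit noise; both procedures use the same alpha rules.
    """
    agree = 0
    for s in _child_seeds(seed, n_panels):
        rng = np.random.default_rng(int(s))
        g = _binomial_genotypes(rng, n, m)
        k = int(rng.integers(1, 4))
        causal = rng.choice(m, size=k, replace=False)
        betas = np.array([1.0, 0.7, 0.4][:k])
        y = rng.normal(size=n)
        for c, b in zip(causal, betas):
            y = y + b * g.dosages[:, c]
        trace = forward_select(y, g)
        oracle = _exhaustive_best_subset(y, g, g.variant_ids, max_size=4)
        agree += sorted(trace.selected) == sorted(oracle)
    return agree / n_panels


# ---------------------------------------------------------------------------
# type-I error of model comparisons
# ---------------------------------------------------------------------------

def lrt_type1_rate(seed: int, reps: int = 2000, n: int = 200,
                   alpha: float = 0.05) -> float:
    """Rejection rate of the 1-df nested LRT when the added column is noise."""
    rejections = 0
    for s in _child_seeds(seed, reps):
        rng = np.random.default_rng(int(s))
        g = _binomial_genotypes(rng, n, 2)
        y = 0.5 * g.dosage("v1") + rng.normal(size=n)
        small = fit_ols(y, g, ["v1"])
        large = fit_ols(y, g, ["v1", "v2"])
        rejections += lrt_nested(small, large).p_value < alpha
    return rejections / reps


def jtest_type1_rate(seed: int, reps: int = 2000, n: int = 200,
                     alpha: float = 0.05) -> float:
    """J-test proxy rejection rate when y is independent of both models."""
    rejections = 0
    for s in _child_seeds(seed, reps):
        rng = np.random.default_rng(int(s))
        g = _binomial_genotypes(rng, n, 2)
        y = rng.normal(size=n)
        res_a, _ = jtest(y, g, ["v1"], ["v2"])
        rejections += res_a.p_value < alpha
    return rejections / reps


def jtest_power(seed: int, reps: int = 500, n: int = 200, h2: float = 0.3,
                alpha: float = 0.01) -> tuple[float, float]:
    """(power, reverse rate) of the J-test when the data follow model A.

    Power: fraction of replicates where B's adequacy is rejected (the
    A-proxy is significant at ``alpha``); reverse: fraction where A's
    adequacy is rejected, which should stay at the nominal rate.
    """
    reject_b = reject_a = 0
    for s in _child_seeds(seed, reps):
        rng = np.random.default_rng(int(s))
        g = _binomial_genotypes(rng, n, 2)
        d = g.dosage("v1")
        beta = np.sqrt(h2 / (1 - h2)) / d.std()
        y = beta * d + rng.normal(size=n)
        res_a, res_b = jtest(y, g, ["v1"], ["v2"])
        reject_b += res_b.p_value < alpha
        reject_a += res_a.p_value < alpha
    return reject_b / reps, reject_a / reps


# ---------------------------------------------------------------------------
# heritability recovery
# ---------------------------------------------------------------------------

def h2_recovery(seed: int, h2: float, n: int = 10_000) -> float:
    """Adjusted r2 of the forward-selected model under a known h2."""
    pool = default_haplotype_pool()
    s1, s2 = _child_seeds(seed, 2)
    g, _ = simulate_genotypes(pool, n, int(s1))
    effects = [("t6", 1.0), ("t3", -0.6)]
    spec = EffectSpec(
        causal_variants=effects,
        noise_sd=noise_sd_for_h2(pool, effects, h2),
        n_probes=1,
        probe_noise_sd=0.0,
        seed=int(s2),
    )
    _, latent = simulate_expression(g, spec)
    kept, _ = prune_by_ld(g, 0.90)
    trace = forward_select(latent, g, candidate_ids=kept)
    return float(trace.final.adj_r2)


# ---------------------------------------------------------------------------
# EM phasing vs grid search
# ---------------------------------------------------------------------------

def _grid_search_2snp_mle(genos: np.ndarray) -> np.ndarray:
    """Likelihood maximisation over the 4-haplotype frequency simplex by
    nested grid search (coarse 0.02, refined 0.002); independent of EM."""
    pairs = {}
    for ga, gb in itertools.product((0, 1, 2), repeat=2):
        compat = []
        for h1 in itertools.product((0, 1), repeat=2):
            for h2 in itertools.product((0, 1), repeat=2):
                if h1[0] + h2[0] == ga and h1[1] + h2[1] == gb and h1 <= h2:
                    compat.append((2 * h1[0] + h1[1], 2 * h2[0] + h2[1]))
        pairs[(ga, gb)] = compat
    counts: dict[tuple, int] = {}
    for row in genos:
        counts[tuple(row)] = counts.get(tuple(row), 0) + 1

    def loglik(f):
        total = 0.0
        for geno, c in counts.items():
            p = sum(f[a] * f[b] * (2.0 if a != b else 1.0) for a, b in pairs[geno])
            if p <= 0:
                return -np.inf
            total += c * np.log(p)
        return total

    def search(center, width, step):
        best, best_ll = None, -np.inf
        grid = np.arange(-width, width + step / 2, step)
        for d1 in grid:
            for d2 in grid:
                for d3 in grid:
                    f = np.array(
                        [center[0] + d1, center[1] + d2, center[2] + d3, 0.0]
                    )
                    f[3] = 1.0 - f[:3].sum()
                    if f.min() < 0:
                        continue
                    v = loglik(f)
                    if v > best_ll:
                        best, best_ll = f, v
        return best

    coarse = search(np.array([0.25, 0.25, 0.25]), 0.25, 0.02)
    fine = search(coarse, 0.02, 0.002)
    return search(fine, 0.002, 0.0002)


def em_vs_grid_max_diff(seed: int, n: int = 200) -> float:
    """Max |EM - grid-search| 2-SNP haplotype frequency difference."""
    from .synthetic_data import HaplotypePool

    pool = HaplotypePool(
        variant_ids=["a", "b"],
        haplotypes=[
            ("00", (0, 0), 0.4), ("01", (0, 1), 0.3),
            ("10", (1, 0), 0.2), ("11", (1, 1), 0.1),
        ],
    )
    g, _ = simulate_genotypes(pool, n, seed)
    hs = em_phase(g, ["a", "b"])
    mle = _grid_search_2snp_mle(g.dosages.astype(int))
    em = np.array(
        [hs.frequencies.get("".join(map(str, h)), 0.0)
         for h in [(0, 0), (0, 1), (1, 0), (1, 1)]]
    )
    assert (np.diff(hs.ll_history) >= -1e-10).all()
    return float(np.abs(em - mle).max())


def em_recovery_max_z(seed: int, n: int = 200) -> float:
    """Max |estimated - true| / SE over the 8-tag, 6-haplotype pool."""
    pool = default_haplotype_pool()
    g, _ = simulate_genotypes(pool, n, seed)
    hs = em_phase(g, pool.tag_variant_ids, name_map=pool.tag_name_map())
    worst = 0.0
    for hid, _, f in pool.haplotypes:
        se = np.sqrt(f * (1 - f) / (2 * n))
        worst = max(worst, abs(hs.frequencies.get(hid, 0.0) - f) / se)
    return worst


# ---------------------------------------------------------------------------
# CI coverage
# ---------------------------------------------------------------------------

def ci_coverage(seed: int, reps: int = 2000, n: int = 200) -> float:
    """Empirical 95% CI coverage of the univariate association under the null."""
    covered = 0
    for s in _child_seeds(seed, reps):
        rng = np.random.default_rng(int(s))
        d = rng.binomial(2, 0.3, n).astype(float)
        if d.std() == 0:
            covered += 1
            continue
        y = rng.normal(size=n)
        res = haplotype_association(y, d)
        covered += res.ci_lo <= 0.0 <= res.ci_hi
    return covered / reps


# ---------------------------------------------------------------------------
# fixture patterns
# ---------------------------------------------------------------------------

def fixture_patterns(seed: int, alpha_entry: float = 0.001) -> dict:
    """Qualitative cross-check / haplotype patterns of the four-study fixture.

    Returns, per pattern, the quantity the assertion is about:
    - exchange_max_inferior_p: smallest "inferior" evidence P of the
      lowest-noise composition on the datasets sharing its causal set
      (large = never significantly inferior);
    - risk_hap_positive_datasets: number of datasets where the risk
      haplotype's CI is entirely above 0;
    - n_haps_positive_everywhere: haplotypes significantly positive in all
      datasets (the risk haplotype should be the only one);
    - decoupled_max_r2: max model-vs-decoupled-haplotype r2 over the
      shared-collection datasets.
    """
    fixture = make_four_study_fixture(seed)
    studies = list(fixture.datasets)
    comps, traces, gsubs = {}, {}, {}
    for st in studies:
        e = standardize(filter_intron_probes(fixture.datasets[st]))
        if e.n_probes >= 2 and st == "K":
            members, _, _ = select_representative_group(probe_r2_matrix(e), 0.5)
        else:
            members = [fixture.signal_probes[st][0]]
        comp = make_composite(e, members, st)
        g = fixture.genotypes_for(st).subset_samples(comp.sample_ids)
        kept, _ = prune_by_ld(g, 0.90, protected=list(fixture.functional_ids))
        traces[st] = forward_select(
            comp.as_series(), g, candidate_ids=kept,
            alpha_entry=alpha_entry, alpha_stay=alpha_entry, response_name=st,
        )
        comps[st], gsubs[st] = comp, g

    sharing = [
        st for st in studies
        if st != "S" and fixture.causal[st] == fixture.causal["S"]
    ]
    min_p = 1.0
    for ds in sharing:
        _, p_inf, degen = compare_to_best(
            traces["S"].selected, traces[ds].selected,
            comps[ds].as_series(), gsubs[ds], "S", ds,
        )
        if degen or not np.isfinite(p_inf):
            p_inf = 0.0
        min_p = min(min_p, p_inf)

    hs = {
        coll: em_phase(g, fixture.tag_variant_ids,
                       name_map=fixture.pool.tag_name_map())
        for coll, g in fixture.genotypes.items()
    }
    positive_everywhere = []
    for hap in sorted(hs["CEU"].haplotype_ids):
        ok = True
        for st in studies:
            h = hs[fixture.study_collection[st]]
            if hap not in h.haplotype_ids:
                ok = False
                break
            d = pd.Series(haplotype_dosage(h, hap, "hard"), index=h.sample_ids)
            y = comps[st].as_series()
            if d.reindex(y.index).nunique() < 2:
                ok = False
                break
            a = haplotype_association(y, d, hap, st)
            if not (a.ci_lo > 0):
                ok = False
                break
        if ok:
            positive_everywhere.append(hap)

    risk = fixture.risk_haplotype
    risk_positive = 0
    for st in studies:
        h = hs[fixture.study_collection[st]]
        d = pd.Series(haplotype_dosage(h, risk, "hard"), index=h.sample_ids)
        a = haplotype_association(comps[st].as_series(), d, risk, st)
        risk_positive += a.ci_lo > 0

    decoupled = fixture.decoupled_haplotype
    dec_r2 = 0.0
    shared_coll = fixture.study_collection["S"]
    for st in studies:
        if fixture.study_collection[st] != shared_coll or not traces[st].selected:
            continue
        h = hs[shared_coll]
        d = pd.Series(haplotype_dosage(h, decoupled, "hard"), index=h.sample_ids)
        corr = model_haplotype_r2(
            traces[st].final, d.reindex(traces[st].final.sample_ids), decoupled
        )
        dec_r2 = max(dec_r2, corr.r2)

    return {
        "best_models": {st: traces[st].selected for st in studies},
        "exchange_min_inferior_p": float(min_p),
        "risk_hap_positive_datasets": int(risk_positive),
        "haps_positive_everywhere": positive_everywhere,
        "decoupled_max_r2": float(dec_r2),
    }
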