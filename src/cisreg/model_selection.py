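"""Forward-entry selection of cis-regulatory variants and model cross-checking.

Variant selection follows the stepwise forward-entry rule: start from the
intercept-only model, at each step add the candidate whose nested
likelihood-ratio improvement P is smallest, stop when no addition improves
the model at ``alpha_entry`` or when a term in the refitted model loses
significance at ``alpha_stay`` (that entry is rolled back).  Selected
compositions are then exchanged across expression datasets: each composition
is refitted on each dataset and compared with that dataset's own best model,
by LRT when one composition nests the other and by the Davidson-MacKinnon
J-test otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics_core import GenotypeMatrix
from .regression_engine import (
    CollinearityError,
    ComparisonResult,
    LinearModelFit,
    fit_ols,
    jtest,
    lrt_nested,
    stars,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionTrace",
    "SelectionStep",
    "CrossCheckCell",
    "CrossCheckGrid",
    "forward_select",
    "evaluate_composition",
    "compare_to_best",
    "cross_check",
    "functional_panel_models",
    "render_best_models_table",
]


@dataclass(frozen=True)
class SelectionStep:
    step: int
    variant_id: str
    improvement_p: float  # LRT P of this addition vs the previous model
    model_f_pvalue: float  # model F P after the addition
    term_pvalues: dict[str, float]  # per-term P after the addition


@dataclass
class SelectionTrace:
    """Record of a forward-entry run: entry events, stop reason, final fit."""

    response_name: str
    steps: list[SelectionStep]
    stop_reason: str  # no_significant_improvement | term_lost_significance | exhausted
    final: LinearModelFit
    alpha_entry: float
    alpha_stay: float
    rolled_back: str | None = None  # variant removed by the stop rule, if any

    @property
    def selected(self) -> list[str]:
        return list(self.final.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "variant_id": s.variant_id,
                    "improvement_p": s.improvement_p,
                    "model_p": s.model_f_pvalue,
                }
                for s in self.steps
            ]
        )


def _entry_order_key(g: GenotypeMatrix):
    pos = g.variant_meta["pos"]

    def key(item):
        variant, lrt_p, t_abs = item
        return (lrt_p, -t_abs, pos.loc[variant], variant)

    return key


def forward_select(
    y,
    g: GenotypeMatrix,
    candidate_ids: list[str] | None = None,
    alpha_entry: float = 0.05,
    alpha_stay: float = 0.05,
    response_name: str = "y",
    on_term_loss: str = "stop",
) -> SelectionTrace:
    """Forward-entry selection over an LD-pruned candidate panel.

    Entry criterion is the nested-LRT P of each candidate addition (for the
    first step this ranks candidates exactly as their univariate association
    P does).  Ties break on smaller P, then larger |t| of the entering term,
    then genomic position, then variant id.  ``on_term_loss`` controls the
    stop rule when a refitted term exceeds ``alpha_stay``: "stop" rolls the
    entry back and ends selection (default); "continue" rolls it back,
    discards that candidate and keeps going.
    """
    if on_term_loss not in ("stop", "continue"):
        raise ValueError("on_term_loss must be 'stop' or 'continue'")
    candidates = list(candidate_ids) if candidate_ids is not None else list(g.variant_ids)
    if isinstance(y, pd.Series):
        y = y.reindex(g.sample_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)

    # one consistent complete-case sample set for the whole selection, so
    # every nested comparison is over identical samples
    keep = ~np.isnan(y)
    for v in candidates:
        keep &= ~np.isnan(g.dosage(v))
    if not keep.all():
        logger.warning(
            "forward selection: dropping %d samples with missing data",
            int((~keep).sum()),
        )
    g_cc = g.subset_samples([s for s, k in zip(g.sample_ids, keep) if k])
    y_cc = y[keep]

    current: list[str] = []
    current_fit = fit_ols(y_cc, g_cc, current, response_name=response_name)
    steps: list[SelectionStep] = []
    remaining = list(candidates)
    stop_reason = "exhausted"
    rolled_back = None

    while remaining:
        if current_fit.rss <= 1e-12 * max(1.0, float(y_cc @ y_cc)):
            stop_reason = "no_significant_improvement"  # perfect fit already
            break
        scored = []
        for v in remaining:
            try:
                fit_v = fit_ols(y_cc, g_cc, current + [v], response_name=response_name)
            except (CollinearityError, ValueError):
                continue  # collinear with current model or too few samples
            lrt = lrt_nested(current_fit, fit_v)
            scored.append((v, lrt.p_value, abs(float(fit_v.t_values[-1]))))
        if not scored:
            stop_reason = "exhausted"
            break
        scored.sort(key=_entry_order_key(g_cc))
        best_v, best_p, _ = scored[0]
        if best_p >= alpha_entry:
            stop_reason = "no_significant_improvement"
            break
        trial = fit_ols(y_cc, g_cc, current + [best_v], response_name=response_name)
        if (trial.term_pvalues >= alpha_stay).any():
            rolled_back = best_v
            if on_term_loss == "stop":
                stop_reason = "term_lost_significance"
                break
            remaining.remove(best_v)
            continue
        current.append(best_v)
        current_fit = trial
        remaining.remove(best_v)
        steps.append(
            SelectionStep(
                step=len(steps) + 1,
                variant_id=best_v,
                improvement_p=best_p,
                model_f_pvalue=trial.f_pvalue,
                term_pvalues=dict(zip(trial.variant_ids, map(float, trial.term_pvalues))),
            )
        )
    return SelectionTrace(
        response_name=response_name,
        steps=steps,
        stop_reason=stop_reason,
        final=current_fit,
        alpha_entry=alpha_entry,
        alpha_stay=alpha_stay,
        rolled_back=rolled_back,
    )


def evaluate_composition(
    variant_ids: list[str], y, g: GenotypeMatrix, response_name: str = "y"
) -> LinearModelFit:
    """Plain refit of a fixed variant composition on a target dataset."""
    for v in variant_ids:
        if v not in g.variant_ids:
            raise KeyError(f"variant not genotyped in target dataset: {v}")
    return fit_ols(y, g, list(variant_ids), response_name=response_name)


# ---------------------------------------------------------------------------
# Cross-check grid
# ---------------------------------------------------------------------------

@dataclass
class CrossCheckCell:
    composition_name: str
    dataset_name: str
    fit: LinearModelFit
    comparison: ComparisonResult | None
    inferior_p: float  # evidence that the proper best beats this composition
    verdict: str
    degenerate: bool = False


@dataclass
class CrossCheckGrid:
    compositions: dict[str, list[str]]
    dataset_names: list[str]
    cells: dict[tuple[str, str], CrossCheckCell] = field(default_factory=dict)

    def verdicts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                ds: {
                    comp: self.cells[(comp, ds)].verdict
                    for comp in self.compositions
                }
                for ds in self.dataset_names
            }
        )

    def neglog10_fit_p(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                ds: {
                    comp: -np.log10(max(self.cells[(comp, ds)].fit.f_pvalue, 1e-300))
                    for comp in self.compositions
                }
                for ds in self.dataset_names
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (comp, ds), cell in self.cells.items():
            rows.append(
                {
                    "composition": comp,
                    "dataset": ds,
                    "fit_p": cell.fit.f_pvalue,
                    "neglog10_fit_p": -np.log10(max(cell.fit.f_pvalue, 1e-300)),
                    "adj_r2": cell.fit.adj_r2,
                    "comparison_kind": cell.comparison.kind if cell.comparison else "self",
                    "inferior_p": cell.inferior_p,
                    "verdict": cell.verdict,
                    "degenerate": cell.degenerate,
                }
            )
        return pd.DataFrame(rows)


def compare_to_best(
    composition: list[str],
    best: list[str],
    y,
    g: GenotypeMatrix,
    comp_name: str = "composition",
    best_name: str = "best",
) -> tuple[ComparisonResult | None, float, bool]:
    """Compare a variant composition against a dataset's proper best model.

    Returns (comparison, inferior_p, degenerate): ``inferior_p`` is the P
    value for the evidence that the proper best model outperforms the
    composition -- the nested LRT P when the composition is a subset of the
    best, the J-test proxy P testing the composition's adequacy when the
    models are non-nested, and 1.0 when the composition contains (or equals)
    the best model, since a superset can never be significantly inferior
    under the LRT in that direction.
    """
    comp_set, best_set = set(composition), set(best)
    if comp_set == best_set:
        return None, 1.0, False
    if best_set <= comp_set:  # composition is a superset: not inferior
        small = fit_ols(y, g, list(best), response_name=best_name)
        large = fit_ols(y, g, list(composition), response_name=best_name)
        return lrt_nested(small, large), 1.0, False
    if comp_set <= best_set:  # composition nested in best: LRT
        small = fit_ols(y, g, list(composition), response_name=comp_name)
        large = fit_ols(y, g, list(best), response_name=comp_name)
        res = lrt_nested(small, large)
        return res, res.p_value, False
    try:
        res_comp, _ = jtest(
            y, g, list(composition), list(best), name_a=comp_name, name_b=best_name
        )
    except CollinearityError:
        return None, float("nan"), True
    return res_comp, res_comp.p_value, False


def cross_check(
    best_models: dict[str, list[str]],
    datasets: dict[str, tuple[np.ndarray, GenotypeMatrix]],
) -> CrossCheckGrid:
    """Exchange best-model compositions across datasets.

    ``best_models`` maps a composition name (its origin dataset) to its
    variant ids; ``datasets`` maps dataset name to (response, genotypes).
    Every composition is refitted on every dataset and compared with the
    dataset's own best model; the diagonal is a self-comparison (n.s.).
    """
    if len(datasets) < 2:
        raise ValueError("cross-check needs at least 2 datasets")
    grid = CrossCheckGrid(
        compositions={k: list(v) for k, v in best_models.items()},
        dataset_names=list(datasets),
    )
    for ds_name, (y, g) in datasets.items():
        proper = best_models[ds_name] if ds_name in best_models else None
        for comp_name, comp in best_models.items():
            fit = evaluate_composition(comp, y, g, response_name=ds_name)
            if proper is None:
                comparison, p_inf, degen = None, float("nan"), False
            else:
                comparison, p_inf, degen = compare_to_best(
                    comp, proper, y, g, comp_name=comp_name, best_name=ds_name
                )
            verdict = "deg." if degen else stars(p_inf) if np.isfinite(p_inf) else "n.s."
            grid.cells[(comp_name, ds_name)] = CrossCheckCell(
                composition_name=comp_name,
                dataset_name=ds_name,
                fit=fit,
                comparison=comparison,
                inferior_p=p_inf,
                verdict=verdict,
                degenerate=degen,
            )
    return grid


# ---------------------------------------------------------------------------
# Functional-polymorphism panels
# ---------------------------------------------------------------------------

def functional_panel_models(
    y,
    g: GenotypeMatrix,
    functional_ids: list[str],
    best_composition: list[str],
    max_size: int = 2,
    dataset_name: str = "y",
) -> pd.DataFrame:
    """Fit every size-1..max_size subset of declared functional variants.

    Each panel model is refitted on the dataset and compared with the proper
    best composition (LRT when nested, J-test otherwise); rows are ranked by
    model F P.
    """
    if max_size not in (1, 2):
        raise ValueError("max_size must be 1 or 2")
    rows = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(functional_ids, size):
            try:
                fit = evaluate_composition(list(combo), y, g, response_name=dataset_name)
            except CollinearityError:
                continue
            comparison, p_inf, degen = compare_to_best(
                list(combo), best_composition, y, g,
                comp_name="+".join(combo), best_name=dataset_name,
            )
            rows.append(
                {
                    "model": "+".join(combo),
                    "size": size,
                    "model_p": fit.f_pvalue,
                    "neglog10_model_p": -np.log10(max(fit.f_pvalue, 1e-300)),
                    "adj_r2": fit.adj_r2,
                    "term_pvalues": ";".join(
                        f"{v}={p:.3g}" for v, p in zip(combo, fit.term_pvalues)
                    ),
                    "vs_best_p": p_inf,
                    "vs_best_verdict": "deg." if degen else stars(p_inf),
                }
            )
    out = pd.DataFrame(rows).sort_values("model_p", kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Validation oracle (never a primary selection path)
# ---------------------------------------------------------------------------

def _exhaustive_best_subset(
    y,
    g: GenotypeMatrix,
    candidate_ids: list[str],
    alpha_entry: float = 0.05,
    alpha_stay: float = 0.05,
    max_size: int = 4,
) -> list[str]:
    """Brute-force cross-check for forward selection on small panels.

    Enumerates every subset up to ``max_size`` under the same alpha rules as
    forward entry, but order-free: a subset is admissible when every term P
    < alpha_stay (and, for a single term, its P < alpha_entry); it is
    terminal when no admissible one-variant extension improves it at
    alpha_entry by the nested LRT.  Among terminal admissible subsets the
    one with the smallest model F P wins (ties: fewer terms, then
    lexicographic ids).  This is a validation oracle for tests and
    calibration runs only -- greedy forward entry is the analysis path.
    """
    from scipy import stats as _stats

    ids = sorted(candidate_ids)
    table: dict[frozenset, LinearModelFit] = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(ids, size):
            try:
                table[frozenset(combo)] = fit_ols(y, g, list(combo))
            except (CollinearityError, ValueError):
                continue

    def admissible(key: frozenset) -> bool:
        fit = table.get(key)
        if fit is None:
            return False
        return bool((fit.term_pvalues < alpha_stay).all()) and (
            len(key) > 1 or fit.f_pvalue < alpha_entry
        )

    def lrt_p(small_key: frozenset, large_key: frozenset) -> float:
        small, large = table[small_key], table[large_key]
        if small.rss <= 1e-12 * small.n:
            return 1.0
        stat = max(small.n * np.log(small.rss / large.rss), 0.0)
        return float(_stats.chi2.sf(stat, len(large_key) - len(small_key)))

    def terminal(key: frozenset) -> bool:
        if len(key) >= max_size:
            return True
        for v in ids:
            if v in key:
                continue
            ext = key | {v}
            if admissible(ext) and lrt_p(key, ext) < alpha_entry:
                return False
        return True

    best: tuple | None = None
    for key, fit in table.items():
        if not admissible(key) or not terminal(key):
            continue
        combo = tuple(sorted(key))
        cand = (fit.f_pvalue, len(key), combo)
        if best is None or cand < best:
            best = cand
    if best is None:
        return []
    return list(best[2])


def render_best_models_table(traces: dict[str, SelectionTrace]) -> str:
    """Text table of best models per dataset: adjusted r2, model P, term Ps.

    Rows are ordered by entry step within each dataset.
    """
    lines = [
        f"{'Data set':<12}{'Adj r2':>8}{'Model P':>12}   "
        f"{'Polymorphism':<16}{'P in model':>12}"
    ]
    for name, trace in traces.items():
        fit = trace.final
        if not fit.variant_ids:
            lines.append(f"{name:<12}{fit.adj_r2:>8.2f}{'-':>12}   {'(none)':<16}")
            continue
        entry_order = [s.variant_id for s in trace.steps]
        term_p = dict(zip(fit.variant_ids, fit.term_pvalues))
        for i, v in enumerate(entry_order):
            head = (
                f"{name:<12}{fit.adj_r2:>8.2f}{fit.f_pvalue:>12.2e}"
                if i == 0
                else f"{'':<12}{'':>8}{'':>12}"
            )
            lines.append(f"{head}   {v:<16}{term_p[v]:>12.2e}")
    return "\n".join(lines)
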