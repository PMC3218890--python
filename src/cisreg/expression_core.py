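"""Expression standardisation, probe correlation, representative-signal selection.

Microarray studies interrogate one gene with several hybridisation probes.
Probes that track the same underlying transcript signal are highly
inter-correlated; probes hitting alternative exons or introns are not.  This
module z-scores each probe, measures pairwise squared Pearson correlation,
selects a representative probe group by greedy agglomeration, averages the
group into a composite signal, and provides classical multidimensional
scaling coordinates for display of the probe correlation structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "CompositeSignal",
    "standardize",
    "filter_intron_probes",
    "probe_r2_matrix",
    "select_representative_group",
    "make_composite",
    "mds_coordinates",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionDataset:
    """Samples x probes expression values with optional probe annotation.

    probe_meta is indexed by probe id with columns ``target`` (feature label)
    and ``targets_intron`` (bool).  ``standardized`` records whether values
    are per-probe z-scores; ``raw`` keeps the pre-standardisation values for
    provenance once standardize() has run.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    probe_meta: pd.DataFrame = None
    standardized: bool = False
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if self.probe_meta is None:
            self.probe_meta = pd.DataFrame(
                {"target": "", "targets_intron": False},
                index=pd.Index(self.probe_ids, name="probe_id"),
            )
        else:
            self.probe_meta = self.probe_meta.loc[self.probe_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def probe(self, probe_id: str) -> np.ndarray:
        try:
            j = self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"unknown probe id: {probe_id}") from None
        return self.values[:, j].copy()


@dataclass
class CompositeSignal:
    """Arithmetic mean of standardized member probes, per sample."""

    name: str
    member_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids, name=self.name)


def standardize(e: ExpressionDataset) -> ExpressionDataset:
    """Transform each probe to mean 0 and sample standard deviation 1.

    Uses the n-1 denominator, so a probe with values (1, 2, 3) maps exactly
    to (-1, 0, 1).  Idempotent; the raw values are retained on the result.
    """
    mean = e.values.mean(axis=0)
    sd = e.values.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = [e.probe_ids[j] for j in zero]
        raise ValueError(f"zero-variance probe(s): {names}")
    z = (e.values - mean) / sd
    return ExpressionDataset(
        sample_ids=list(e.sample_ids),
        probe_ids=list(e.probe_ids),
        values=z,
        probe_meta=e.probe_meta,
        standardized=True,
        raw=e.raw if e.raw is not None else e.values.copy(),
    )


def filter_intron_probes(e: ExpressionDataset) -> ExpressionDataset:
    """Drop probes annotated as targeting introns."""
    keep = [p for p in e.probe_ids if not bool(e.probe_meta.loc[p, "targets_intron"])]
    n_removed = e.n_probes - len(keep)
    if n_removed:
        logger.info("removed %d intron-targeting probes, %d remain", n_removed, len(keep))
    if not keep:
        warnings.warn("all probes target introns; dataset is empty", stacklevel=2)
    idx = [e.probe_ids.index(p) for p in keep]
    return ExpressionDataset(
        sample_ids=list(e.sample_ids),
        probe_ids=keep,
        values=e.values[:, idx],
        probe_meta=e.probe_meta.loc[keep] if keep else e.probe_meta.iloc[:0],
        standardized=e.standardized,
        raw=e.raw[:, idx] if e.raw is not None else None,
    )


def probe_r2_matrix(e: ExpressionDataset, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise squared Pearson correlation between probes (diagonal 1).

    Pairs with fewer than ``min_shared`` jointly observed samples get NaN
    with a warning.  Affine transforms of the raw probe values leave this
    matrix unchanged, so it may be computed before or after standardisation.
    """
    k = e.n_probes
    out = np.ones((k, k))
    vals = e.values
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
            if ok.sum() < min_shared:
                warnings.warn(
                    f"probes {e.probe_ids[i]}/{e.probe_ids[j]}: "
                    f"only {int(ok.sum())} shared samples; r2 undefined",
                    stacklevel=2,
                )
                out[i, j] = out[j, i] = np.nan
                continue
            r = np.corrcoef(vals[ok, i], vals[ok, j])[0, 1]
            out[i, j] = out[j, i] = min(r * r, 1.0)
    return pd.DataFrame(out, index=e.probe_ids, columns=e.probe_ids)


def select_representative_group(
    r2: pd.DataFrame, min_mean_r2: float = 0.5
) -> tuple[list[str], float, list[str]]:
    """Greedy selection of a mutually correlated probe group.

    Greedy agglomeration from a seed pair: repeatedly add the probe with the
    highest mean r2 to the current group, as long as the candidate's mean r2
    to the group and the group's mean pairwise r2 both stay >=
    ``min_mean_r2``.  The greedy run is started from every pair meeting the
    threshold and the maximal group wins (size, then mean r2, then
    lexicographic ids); ties inside a run break lexicographically on probe
    id.  Returns (group ids sorted, achieved mean pairwise r2, excluded
    ids); an empty group if no pair reaches the threshold.
    """
    probes = list(r2.index)
    if len(probes) < 2:
        raise ValueError("need at least 2 probes")
    m = r2.to_numpy()

    def mean_pairwise(idx: list[int]) -> float:
        sub = m[np.ix_(idx, idx)]
        k = len(idx)
        return float((np.nansum(sub) - k) / (k * (k - 1)))

    def grow(seed: list[int]) -> list[int]:
        group = list(seed)
        while True:
            candidates = [c for c in range(len(probes)) if c not in group]
            if not candidates:
                return group
            c = min(candidates, key=lambda c: (-np.nanmean(m[c, group]), probes[c]))
            if (
                np.nanmean(m[c, group]) < min_mean_r2
                or mean_pairwise(group + [c]) < min_mean_r2
            ):
                return group
            group.append(c)

    best_group: list[int] | None = None
    best_key = None
    for i in range(len(probes)):
        for j in range(i + 1, len(probes)):
            if np.isnan(m[i, j]) or m[i, j] < min_mean_r2:
                continue
            group = grow([i, j])
            key = (-len(group), -mean_pairwise(group),
                   tuple(sorted(probes[k] for k in group)))
            if best_key is None or key < best_key:
                best_key, best_group = key, group
    if best_group is None:
        return [], float("nan"), sorted(probes)
    ids = sorted(probes[i] for i in best_group)
    excluded = sorted(set(probes) - set(ids))
    return ids, mean_pairwise(best_group), excluded


def make_composite(
    e: ExpressionDataset, member_ids: list[str], name: str
) -> CompositeSignal:
    """Average standardized member probes into one representative signal."""
    if not member_ids:
        raise ValueError("empty member list")
    if not e.standardized:
        raise ValueError("composite requires standardized input")
    cols = np.column_stack([e.probe(p) for p in member_ids])
    ok = ~np.isnan(cols).any(axis=1)
    if not ok.all():
        excluded = [s for s, keep in zip(e.sample_ids, ok) if not keep]
        warnings.warn(
            f"composite {name}: excluding {len(excluded)} samples with "
            f"missing members: {excluded[:5]}",
            stacklevel=2,
        )
    return CompositeSignal(
        name=name,
        member_ids=list(member_ids),
        sample_ids=[s for s, keep in zip(e.sample_ids, ok) if keep],
        values=cols[ok].mean(axis=1),
    )


def combine_composites(
    composites: list[CompositeSignal], name: str, allow_partial: bool = False
) -> CompositeSignal:
    """Cross-study composite: mean of member composites on shared samples."""
    if not composites:
        raise ValueError("empty member list")
    shared = set(composites[0].sample_ids)
    for c in composites[1:]:
        shared &= set(c.sample_ids)
    union = set().union(*(c.sample_ids for c in composites))
    if shared != union and not allow_partial:
        raise ValueError(
            f"sample ids differ across member composites "
            f"({len(union - shared)} non-shared); pass allow_partial to use "
            f"the intersection"
        )
    order = [s for s in composites[0].sample_ids if s in shared]
    stacked = np.column_stack([c.as_series().loc[order].to_numpy() for c in composites])
    return CompositeSignal(
        name=name,
        member_ids=[c.name for c in composites],
        sample_ids=order,
        values=stacked.mean(axis=1),
    )


def mds_coordinates(r2: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of probes from d = sqrt(1 - r2) distances.

    Display-only: coordinates are defined up to rotation and reflection.
    Perfectly correlated probes coincide at distance 0.
    """
    m = r2.to_numpy(dtype=float)
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("r2 matrix must be symmetric")
    if np.isnan(m).any():
        raise ValueError("r2 matrix must be complete for MDS")
    d2 = np.clip(1.0 - m, 0.0, None)  # squared distances
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    return pd.DataFrame(
        coords, index=r2.index, columns=[f"dim{k + 1}" for k in range(dims)]
    )


def read_expression_tsv(path, probe_meta: pd.DataFrame | None = None) -> ExpressionDataset:
    """Expression TSV with rows = samples, columns = probes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionDataset(
        sample_ids=[str(s) for s in df.index],
        probe_ids=[str(p) for p in df.columns],
        values=df.to_numpy(dtype=float),
        probe_meta=probe_meta,
    )


def write_expression_tsv(e: ExpressionDataset, path) -> None:
    df = pd.DataFrame(e.values, index=e.sample_ids, columns=e.probe_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_probe_meta_tsv(path) -> pd.DataFrame:
    """Probe annotation TSV: probe_id, target, targets_intron."""
    meta = pd.read_csv(path, sep="\t", index_col="probe_id")
    meta["targets_intron"] = meta["targets_intron"].astype(bool)
    return meta
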