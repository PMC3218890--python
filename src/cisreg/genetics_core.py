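"""Genotype data model, linkage disequilibrium, LD pruning and EM haplotype phasing.

Genotypes are held as additive dosages (0/1/2 counts of the alternate allele,
NaN for missing) over samples x variants.  LD is genotypic r-squared -- the
squared Pearson correlation of dosage columns -- which is what collinearity
pruning for regression designs needs and which requires no phase information.

Phasing is Excoffier-Slatkin style expectation-maximisation over the
multinomial haplotype-frequency likelihood under Hardy-Weinberg equilibrium:
each sample's unphased multi-site genotype is explained by the mixture of all
compatible ordered haplotype pairs, haplotype frequencies are iterated to the
maximum-likelihood point, and per-sample diplotypes are read off the final
posteriors.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "HaplotypeSet",
    "LDResult",
    "GenotypeError",
    "LDUndefinedError",
    "PhasingError",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "ld_r2",
    "prune_by_ld",
    "em_phase",
    "haplotype_dosage",
]


class GenotypeError(ValueError):
    """Malformed or unsupported genotype input."""


class LDUndefinedError(ValueError):
    """LD requested for a variant pair where r^2 is undefined (zero variance)."""


class PhasingError(RuntimeError):
    """EM phasing could not be run or did not converge."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x variants additive-dosage matrix with per-variant metadata.

    dosages is float with values in {0, 1, 2} or NaN (missing).
    variant_meta is indexed by variant id with columns
    chrom, pos (1-based), ref, alt, type ("SNP" or "indel").
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    variant_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise GenotypeError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeError("duplicate sample ids")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise GenotypeError("duplicate variant ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0, 2.0))]))
            raise GenotypeError(f"dosages must be 0/1/2 or missing; found {bad[:5]}")
        if self.variant_meta is None:
            self.variant_meta = default_variant_meta(self.variant_ids)
        else:
            self.variant_meta = self.variant_meta.loc[self.variant_ids]
            for chrom, grp in self.variant_meta.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing:
                    raise GenotypeError(
                        f"positions not non-decreasing on chromosome {chrom}"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def dosage(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant (copy)."""
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id: {variant_id}") from None
        return self.dosages[:, j].copy()

    def maf(self, variant_id: str) -> float:
        """Minor-allele frequency from non-missing dosages."""
        d = self.dosage(variant_id)
        d = d[~np.isnan(d)]
        if d.size == 0:
            return float("nan")
        p = d.mean() / 2.0
        return float(min(p, 1.0 - p))

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=list(variant_ids),
            dosages=self.dosages[:, idx].copy(),
            variant_meta=self.variant_meta.loc[list(variant_ids)],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[idx, :].copy(),
            variant_meta=self.variant_meta,
        )


def default_variant_meta(variant_ids: list[str]) -> pd.DataFrame:
    """Placeholder metadata: one chromosome, positions in column order."""
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, len(variant_ids) + 1),
            "ref": "A",
            "alt": "G",
            "type": "SNP",
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read a GenotypeMatrix from a VCF (GT-only subset) or a dosage TSV.

    VCF genotypes are recoded additively: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    ./. -> missing; phase separators ('|' vs '/') are ignored for dosage.
    Multi-allelic records are rejected.
    """
    path = str(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return GenotypeMatrix(
            sample_ids=[str(s) for s in df.index],
            variant_ids=[str(v) for v in df.columns],
            dosages=df.to_numpy(dtype=float),
        )
    if fmt != "vcf":
        raise ValueError(f"unknown genotype format: {fmt!r}")

    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise GenotypeError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variant_ids, rows, meta_rows = [], [], []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise GenotypeError(
                f"multi-allelic site unsupported at record {i} "
                f"({rec.CHROM}:{rec.POS})"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        variant_ids.append(vid)
        rows.append(dos)
        vtype = "SNP" if len(rec.REF) == 1 and len(rec.ALT[0]) == 1 else "indel"
        meta_rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], vtype))
    meta = pd.DataFrame(
        meta_rows,
        columns=["chrom", "pos", "ref", "alt", "type"],
        index=pd.Index(variant_ids, name="variant_id"),
    )
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variant_ids, dosages, meta)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    """Dosage matrix as TSV: rows = samples, columns = variants."""
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.variant_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.0f")


def write_genotypes_vcf(
    g: GenotypeMatrix, path, phased_haplotypes: np.ndarray | None = None
) -> None:
    """Minimal GT-only VCF.

    With phased_haplotypes (n_samples x n_variants x 2 allele array) genotypes
    are written phased ('|'); otherwise unphased ('/') from dosages.
    """
    meta = g.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(g.variant_ids):
            row = meta.loc[vid]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), vid,
                str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT",
            ]
            for i in range(g.n_samples):
                if phased_haplotypes is not None:
                    a, b = phased_haplotypes[i, j]
                    fields.append(f"{int(a)}|{int(b)}")
                else:
                    d = g.dosages[i, j]
                    fields.append(
                        "./." if np.isnan(d) else {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                    )
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDResult:
    variant_a: str
    variant_b: str
    r2: float


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete observations."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise LDUndefinedError("fewer than 2 shared non-missing samples")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise LDUndefinedError("zero dosage variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return min(r * r, 1.0)


def ld_r2(g: GenotypeMatrix, v1: str, v2: str) -> LDResult:
    """Genotypic LD between two variants as squared dosage correlation."""
    return LDResult(v1, v2, _pairwise_r2(g.dosage(v1), g.dosage(v2)))


def prune_by_ld(
    g: GenotypeMatrix,
    threshold: float = 0.90,
    protected: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy LD pruning so that no retained pair has r^2 >= threshold.

    Variants are considered protected-first (never removed), then by
    descending minor-allele frequency with genomic position as tie-break,
    so of a high-LD pair the more informative (higher-MAF) variant is kept.
    Returns the kept ids (in original panel order) and a report mapping each
    removed variant to its retained proxy with their r^2.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    protected = list(protected or [])
    for p in protected:
        if p not in g.variant_ids:
            raise KeyError(f"protected variant not in panel: {p}")

    pos = g.variant_meta["pos"]
    order = protected + sorted(
        (v for v in g.variant_ids if v not in protected),
        key=lambda v: (-(g.maf(v) if np.isfinite(g.maf(v)) else -1.0), pos.loc[v], v),
    )
    kept: list[str] = []
    removed: list[tuple[str, str, float]] = []
    for v in order:
        dv = g.dosage(v)
        proxy, proxy_r2 = None, -1.0
        for k in kept:
            try:
                r2 = _pairwise_r2(dv, g.dosage(k))
            except LDUndefinedError:
                continue
            if r2 >= threshold and r2 > proxy_r2:
                proxy, proxy_r2 = k, r2
        if proxy is None or v in protected:
            kept.append(v)
        else:
            removed.append((v, proxy, proxy_r2))
    report = pd.DataFrame(removed, columns=["removed_id", "kept_id", "r2"])
    kept_ordered = [v for v in g.variant_ids if v in set(kept)]
    logger.info("LD pruning: %d -> %d variants (threshold r2 >= %.2f)",
                g.n_variants, len(kept_ordered), threshold)
    return kept_ordered, report


# ---------------------------------------------------------------------------
# EM haplotype phasing
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    """Estimated haplotype pool over tag variants with per-sample diplotypes.

    haplotypes maps haplotype id -> allele tuple over tag_variant_ids;
    frequencies are the EM maximum-likelihood estimates; diplotypes holds the
    most probable ordered-pair per sample (lexicographic order within pair)
    with its posterior probability; expected_dosages is samples x haplotypes
    with posterior-expected copy numbers in [0, 2].
    """

    tag_variant_ids: list[str]
    sample_ids: list[str]
    haplotypes: dict[str, tuple[int, ...]]
    frequencies: dict[str, float]
    diplotypes: list[tuple[str, str]]
    posteriors: np.ndarray
    expected_dosages: pd.DataFrame
    log_likelihood: float
    ll_history: list[float] = field(default_factory=list)
    n_iterations: int = 0

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        sums = self.expected_dosages.sum(axis=1).to_numpy()
        if not np.allclose(sums, 2.0, atol=1e-6):
            raise ValueError("expected dosages must sum to 2 per sample")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.haplotypes)


def _compatible_pairs(geno: tuple[int, ...]):
    """All unordered haplotype pairs consistent with an unphased genotype."""
    het = [i for i, d in enumerate(geno) if d == 1]
    base = [d // 2 for d in geno]  # 0->0, 2->1 at homozygous sites
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    # fix the first het site's allele on h1 to avoid double-counting
    for assign in itertools.product((0, 1), repeat=len(het) - 1):
        h1, h2 = list(base), list(base)
        alleles = (0,) + assign
        for site, a in zip(het, alleles):
            h1[site] = a
            h2[site] = 1 - a
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_phase(
    g: GenotypeMatrix,
    tag_variant_ids: list[str],
    name_map: dict[tuple[int, ...], str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    max_tags: int = 12,
) -> HaplotypeSet:
    """Haplotype frequencies and diplotypes by EM under Hardy-Weinberg.

    Initial frequencies are uniform over haplotypes compatible with at least
    one observed genotype; the EM iterates until the log-likelihood improves
    by less than ``tol``.  Samples missing any tag genotype are excluded with
    a warning.  ``name_map`` optionally assigns ids (e.g. H1..H6) to known
    allele vectors; unnamed haplotypes are labelled by their allele string.
    """
    if len(tag_variant_ids) > max_tags:
        raise PhasingError(
            f"tag set of {len(tag_variant_ids)} exceeds enumeration bound {max_tags}"
        )
    sub = g.subset_variants(tag_variant_ids)
    complete = ~np.isnan(sub.dosages).any(axis=1)
    if not complete.all():
        dropped = [s for s, ok in zip(sub.sample_ids, complete) if not ok]
        warnings.warn(
            f"excluding {len(dropped)} samples with missing tag genotypes",
            stacklevel=2,
        )
    sample_ids = [s for s, ok in zip(sub.sample_ids, complete) if ok]
    genos = sub.dosages[complete].astype(int)
    n = len(sample_ids)
    if n == 0:
        raise PhasingError("no samples with complete tag genotypes")

    sample_pairs = [_compatible_pairs(tuple(row)) for row in genos]
    hap_pool = sorted({h for pairs in sample_pairs for p in pairs for h in p})
    hap_index = {h: k for k, h in enumerate(hap_pool)}
    H = len(hap_pool)

    # pair arrays per sample for fast E-steps
    pair_idx = [
        np.array([(hap_index[a], hap_index[b]) for a, b in pairs]) for pairs in sample_pairs
    ]
    pair_mult = [
        np.array([2.0 if a != b else 1.0 for a, b in pairs]) for pairs in sample_pairs
    ]

    freq = np.full(H, 1.0 / H)
    ll_history: list[float] = []
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        ll = 0.0
        for i in range(n):
            idx, mult = pair_idx[i], pair_mult[i]
            w = freq[idx[:, 0]] * freq[idx[:, 1]] * mult
            tot = w.sum()
            ll += np.log(tot)
            post = w / tot
            np.add.at(counts, idx[:, 0], post)
            np.add.at(counts, idx[:, 1], post)
        ll_history.append(ll)
        if ll + 1e-12 < prev_ll:
            raise PhasingError(f"log-likelihood decreased at iteration {it}")
        if ll - prev_ll < tol and it > 1:
            break
        prev_ll = ll
        freq = counts / (2.0 * n)
    else:
        raise PhasingError(
            f"EM did not converge in {max_iter} iterations "
            f"(last log-likelihood delta {ll - prev_ll:.3e})"
        )

    def hap_name(h: tuple[int, ...]) -> str:
        if name_map and h in name_map:
            return name_map[h]
        return "".join(map(str, h))

    names = [hap_name(h) for h in hap_pool]
    if len(set(names)) != len(names):
        raise PhasingError("haplotype name collision in name_map")

    diplotypes: list[tuple[str, str]] = []
    best_post = np.zeros(n)
    expected = np.zeros((n, H))
    for i in range(n):
        idx, mult = pair_idx[i], pair_mult[i]
        w = freq[idx[:, 0]] * freq[idx[:, 1]] * mult
        post = w / w.sum()
        np.add.at(expected[i], idx[:, 0], post)
        np.add.at(expected[i], idx[:, 1], post)
        b = int(np.argmax(post))
        a_id, b_id = names[idx[b, 0]], names[idx[b, 1]]
        diplotypes.append(tuple(sorted((a_id, b_id))))
        best_post[i] = post[b]

    freq = freq / freq.sum()
    # drop haplotypes the EM drove to (numerically) zero frequency
    used = {h for pair in diplotypes for h in pair}
    keep = [k for k, name in enumerate(names) if freq[k] > 1e-9 or name in used]
    hap_pool = [hap_pool[k] for k in keep]
    names = [names[k] for k in keep]
    expected = expected[:, keep]
    freq = freq[keep]
    freq = freq / freq.sum()
    return HaplotypeSet(
        tag_variant_ids=list(tag_variant_ids),
        sample_ids=sample_ids,
        haplotypes=dict(zip(names, hap_pool)),
        frequencies=dict(zip(names, freq)),
        diplotypes=diplotypes,
        posteriors=best_post,
        expected_dosages=pd.DataFrame(expected, index=sample_ids, columns=names),
        log_likelihood=ll_history[-1],
        ll_history=ll_history,
        n_iterations=len(ll_history),
    )


def haplotype_dosage(hs: HaplotypeSet, haplotype_id: str, mode: str = "hard") -> np.ndarray:
    """Per-sample copy number of one haplotype.

    hard: copies in the most probable diplotype (0/1/2, the coding used for
    haplotype-trait regression); expected: posterior-expected copies in [0,2].
    """
    if haplotype_id not in hs.haplotypes:
        raise KeyError(f"unknown haplotype id: {haplotype_id}")
    if mode == "expected":
        return hs.expected_dosages[haplotype_id].to_numpy(copy=True)
    if mode != "hard":
        raise ValueError(f"mode must be 'hard' or 'expected', got {mode!r}")
    return np.array(
        [float(sum(h == haplotype_id for h in pair)) for pair in hs.diplotypes]
    )


def write_haplotypes_tsv(hs: HaplotypeSet, path) -> None:
    """Per-sample diplotype table: sample, hap1, hap2, posterior."""
    pd.DataFrame(
        {
            "sample_id": hs.sample_ids,
            "hap1": [p[0] for p in hs.diplotypes],
            "hap2": [p[1] for p in hs.diplotypes],
            "posterior": hs.posteriors,
        }
    ).to_csv(path, sep="\t", index=False)
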