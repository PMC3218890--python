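"""Synthetic haplotype-structured genotypes and expression with known truth.

The generator draws, for each diploid sample, two independent haplotypes
from a pool (Hardy-Weinberg random mating), producing additive dosages with
the block LD structure that haplotype sharing induces.  Expression is a
linear additive function of causal-variant dosages plus Gaussian noise, and
each microarray probe observes that latent signal through its own
independent probe noise.  Everything downstream of the generator -- LD
pruning, forward model selection, phasing, haplotype association -- can
therefore be checked against recorded ground truth.

The default pool has six haplotypes (H1..H6) over eight tag variants plus a
block of extended variants in strong LD with the tags, so that pruning at
r^2 >= 0.90 collapses the panel the way a dense cis region would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_core import ExpressionDataset
from .genetics_core import GenotypeMatrix

__all__ = [
    "HaplotypePool",
    "EffectSpec",
    "GenotypeTruth",
    "FourStudyFixture",
    "simulate_genotypes",
    "simulate_expression",
    "make_four_study_fixture",
    "default_haplotype_pool",
    "genetic_variance",
    "noise_sd_for_h2",
]


# ---------------------------------------------------------------------------
# Pool and effect specifications
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """A pool of haplotypes over an ordered variant panel.

    ``haplotypes`` is a list of (haplotype id, allele vector over
    variant_ids, population frequency); frequencies must sum to 1.
    ``tag_variant_ids`` marks the subset used for phasing and haplotype
    naming (defaults to all variants).
    """

    variant_ids: list[str]
    haplotypes: list[tuple[str, tuple[int, ...], float]]
    tag_variant_ids: list[str] = None
    variant_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        total = sum(f for _, _, f in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total!r}, not 1")
        ids = [h for h, _, _ in self.haplotypes]
        if len(set(ids)) != len(ids):
            raise ValueError("haplotype ids not unique")
        m = len(self.variant_ids)
        for hid, alleles, _ in self.haplotypes:
            if len(alleles) != m:
                raise ValueError(
                    f"haplotype {hid}: allele vector length {len(alleles)} != "
                    f"{m} variants"
                )
        if any(f < 0 for _, _, f in self.haplotypes):
            raise ValueError("negative haplotype frequency")
        if self.tag_variant_ids is None:
            self.tag_variant_ids = list(self.variant_ids)

    @property
    def haplotype_ids(self) -> list[str]:
        return [h for h, _, _ in self.haplotypes]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, _, f in self.haplotypes])

    @property
    def allele_matrix(self) -> np.ndarray:
        """haplotypes x variants 0/1 alleles."""
        return np.array([a for _, a, _ in self.haplotypes], dtype=float)

    def tag_name_map(self) -> dict[tuple[int, ...], str]:
        """Allele vector at the tag variants -> haplotype id (for phasing)."""
        idx = [self.variant_ids.index(t) for t in self.tag_variant_ids]
        return {
            tuple(int(a[i]) for i in idx): hid for hid, a, _ in self.haplotypes
        }


@dataclass
class EffectSpec:
    """Generative additive model for expression.

    ``causal_variants`` lists (variant id, per-dosage-unit effect); the
    latent signal adds Gaussian noise with ``noise_sd``; each of the
    ``n_probes`` probes observes the latent signal through independent
    Gaussian probe noise (``probe_noise_sd`` scalar or per-probe sequence).
    """

    causal_variants: list[tuple[str, float]]
    noise_sd: float
    n_probes: int = 1
    probe_noise_sd: float | tuple[float, ...] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    def probe_noise(self) -> np.ndarray:
        sd = np.broadcast_to(
            np.asarray(self.probe_noise_sd, dtype=float), (self.n_probes,)
        )
        if (sd < 0).any():
            raise ValueError("probe_noise_sd must be >= 0")
        return sd


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTruth:
    """Ground truth recorded by simulate_genotypes."""

    diplotypes: list[tuple[str, str]]  # sorted id pairs per sample
    phased: np.ndarray = field(repr=False)  # n_samples x n_variants x 2 alleles
    haplotype_indices: np.ndarray = field(repr=False)  # n_samples x 2 pool rows


def simulate_genotypes(
    pool: HaplotypePool, n_samples: int, seed: int, sample_prefix: str = "s"
) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Draw two independent pool haplotypes per sample (Hardy-Weinberg).

    Dosage at each variant is the count of the non-reference allele; the
    true haplotype pair is recorded for phasing-recovery checks.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = pool.frequencies
    alleles = pool.allele_matrix
    draws = rng.choice(len(freqs), size=(n_samples, 2), p=freqs)
    phased = np.stack(
        [alleles[draws[:, 0]], alleles[draws[:, 1]]], axis=2
    )  # n x m x 2
    dosages = phased.sum(axis=2)
    ids = pool.haplotype_ids
    diplotypes = [tuple(sorted((ids[a], ids[b]))) for a, b in draws]
    g = GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)],
        variant_ids=list(pool.variant_ids),
        dosages=dosages,
        variant_meta=pool.variant_meta,
    )
    return g, GenotypeTruth(diplotypes, phased, draws)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    genotypes: GenotypeMatrix, spec: EffectSpec
) -> tuple[ExpressionDataset, np.ndarray]:
    """Latent additive signal plus per-probe noise.

    latent_i = sum_v beta_v * dosage_iv + N(0, noise_sd);
    probe_ij = latent_i + N(0, probe_noise_sd_j).
    Returns the probe dataset and the latent signal.
    """
    missing = [v for v, _ in spec.causal_variants if v not in genotypes.variant_ids]
    if missing:
        raise KeyError(f"causal variant(s) not in genotype matrix: {missing}")
    rng = np.random.default_rng(spec.seed)
    n = genotypes.n_samples
    latent = rng.normal(0.0, spec.noise_sd, size=n)
    for v, beta in spec.causal_variants:
        latent = latent + beta * genotypes.dosage(v)
    sds = spec.probe_noise()
    probes = latent[:, None] + rng.normal(0.0, 1.0, size=(n, spec.n_probes)) * sds
    e = ExpressionDataset(
        sample_ids=list(genotypes.sample_ids),
        probe_ids=[f"probe{j + 1:02d}" for j in range(spec.n_probes)],
        values=probes,
    )
    return e, latent


# ---------------------------------------------------------------------------
# Analytic variance helpers (for calibrating noise to a target h^2)
# ---------------------------------------------------------------------------

def genetic_variance(pool: HaplotypePool, effects: list[tuple[str, float]]) -> float:
    """Population variance of the additive genetic value under the pool.

    With random mating the dosage is the sum of two iid haplotype draws, so
    Var(sum_v beta_v d_v) = 2 * Var_hap(sum_v beta_v a_v).
    """
    idx = [pool.variant_ids.index(v) for v, _ in effects]
    betas = np.array([b for _, b in effects])
    score = pool.allele_matrix[:, idx] @ betas  # per-haplotype genetic score
    f = pool.frequencies
    mean = float(score @ f)
    return 2.0 * float(((score - mean) ** 2) @ f)


def noise_sd_for_h2(
    pool: HaplotypePool, effects: list[tuple[str, float]], h2: float
) -> float:
    """Noise standard deviation giving genotype-explained variance h2."""
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must be in (0, 1)")
    vg = genetic_variance(pool, effects)
    return float(np.sqrt(vg * (1.0 - h2) / h2))


# ---------------------------------------------------------------------------
# Default pool: 6 haplotypes over 8 tags plus an LD block of extended variants
# ---------------------------------------------------------------------------

_TAG_ALLELES = {
    #      t1 t2 t3 t4 t5 t6 t7 t8
    "H1": (1, 0, 0, 0, 0, 0, 1, 0),
    "H2": (1, 1, 0, 0, 0, 0, 0, 0),
    "H3": (0, 0, 1, 0, 0, 0, 0, 0),
    "H4": (0, 0, 0, 1, 0, 0, 0, 1),
    "H5": (0, 0, 0, 1, 1, 0, 0, 0),
    "H6": (0, 0, 0, 1, 0, 1, 0, 0),
}
_HAP_FREQS = {"H1": 0.28, "H2": 0.05, "H3": 0.21, "H4": 0.17, "H5": 0.13, "H6": 0.16}

# extra variants riding on haplotype subsets: patterns distinct from every
# tag, and avoiding the causal carriers H3/H6 so they stay clean nulls
_SURVIVOR_PATTERNS = {
    "x1": ("H1", "H4"),
    "x2": ("H2", "H5"),
    "x3": ("H1", "H5"),
    "indel1": ("H2", "H4"),
}


def default_haplotype_pool() -> HaplotypePool:
    """Six-haplotype pool over 8 tags plus 22 extended LD-block variants.

    Eighteen extended variants are exact copies or allele flips of tags
    (r^2 = 1 pairs that LD pruning must collapse); four carry distinct
    haplotype patterns and survive pruning.  One survivor is an indel.
    """
    tags = [f"t{k}" for k in range(1, 9)]
    hap_ids = list(_TAG_ALLELES)

    variant_ids = list(tags)
    columns = {t: [(_TAG_ALLELES[h][j]) for h in hap_ids] for j, t in enumerate(tags)}
    # copies: two per tag; flips of t1 and t4
    for t in tags:
        for c in (1, 2):
            vid = f"{t}_cp{c}"
            variant_ids.append(vid)
            columns[vid] = list(columns[t])
    for t in ("t1", "t4"):
        vid = f"{t}_flip"
        variant_ids.append(vid)
        columns[vid] = [1 - a for a in columns[t]]
    for vid, carriers in _SURVIVOR_PATTERNS.items():
        variant_ids.append(vid)
        columns[vid] = [1 if h in carriers else 0 for h in hap_ids]

    # lay variants along the block: tags early, their copies downstream
    meta = pd.DataFrame(
        {
            "chrom": "7",
            "pos": [1_000 * (i + 1) for i in range(len(variant_ids))],
            "ref": "A",
            "alt": "G",
            "type": "SNP",
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    meta.loc["indel1", ["ref", "alt", "type"]] = ["C", "CGGGG", "indel"]

    haplotypes = [
        (
            h,
            tuple(columns[v][k] for v in variant_ids),
            _HAP_FREQS[h],
        )
        for k, h in enumerate(hap_ids)
    ]
    return HaplotypePool(
        variant_ids=variant_ids,
        haplotypes=haplotypes,
        tag_variant_ids=tags,
        variant_meta=meta,
    )


# ---------------------------------------------------------------------------
# The four-study fixture
# ---------------------------------------------------------------------------

# study layout: (collection, n_samples, n_probes, n_signal_probes), echoing
# four published lymphoblastoid-cell-line expression experiments
_STUDY_LAYOUT = {
    "K": ("CEU", 57, 17, 8),
    "S": ("CEU", 60, 2, 1),
    "C": ("CEU", 58, 1, 1),
    "D": ("asthma", 181, 3, 1),
}
# target genotype-explained variance of each study's latent signal
_STUDY_H2 = {"K": 0.31, "S": 0.80, "C": 0.55, "D": 0.28}
# causal architectures: the three CEU studies share one; the independent
# asthma collection has a partially different one (same lead variant, plus
# an independent contribution from the functional promoter indel)
_CAUSAL = {
    "CEU": [("t6", 1.0), ("t3", -0.6)],
    "asthma": [("t6", 1.0), ("indel1", -0.7)],
}

# probe annotation for the multi-probe study: 8 probes share the signal,
# 7 hit uninformative exonic features, 2 target introns
_K_SIGNAL_TARGETS = [
    "exon2", "exon3", "exon5", "exon6", "exon7", "exon8", "exon9", "utr_pre",
]
_K_JUNK_TARGETS = [
    ("exon1A", False), ("exon1B", False), ("exon1C", False), ("exon4", False),
    ("exon6_v5", False), ("utr_post", False), ("promoter", False),
    ("intron1", True), ("intron3", True),
]


@dataclass
class FourStudyFixture:
    """Four expression studies over two LCL-like collections, with truth."""

    pool: HaplotypePool
    genotypes: dict[str, GenotypeMatrix]  # per collection
    genotype_truth: dict[str, GenotypeTruth]
    datasets: dict[str, ExpressionDataset]  # per study
    latents: dict[str, np.ndarray]
    causal: dict[str, list[tuple[str, float]]]  # per study
    signal_probes: dict[str, list[str]]
    study_collection: dict[str, str]
    risk_haplotype: str = "H6"
    # decoupled from the shared-collection (CEU) causal architecture: H2
    # carries neither t6 nor t3 and is rare enough to track neither
    decoupled_haplotype: str = "H2"
    functional_ids: tuple[str, ...] = ("t6", "t2", "indel1")
    seed: int = 0

    @property
    def tag_variant_ids(self) -> list[str]:
        return list(self.pool.tag_variant_ids)

    def genotypes_for(self, study: str) -> GenotypeMatrix:
        g = self.genotypes[self.study_collection[study]]
        return g.subset_samples(self.datasets[study].sample_ids)


def _probe_meta(targets: list[tuple[str, bool]], probe_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": [t for t, _ in targets],
            "targets_intron": [i for _, i in targets],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def make_four_study_fixture(seed: int) -> FourStudyFixture:
    """Deterministic four-study fixture sharing one CEU-like collection.

    Three studies (57/60/58 samples, 17/2/1 probes) observe the same 60
    CEU-like samples through different probe sets and noise levels; the
    fourth (181 samples, 3 probes) observes an independent collection with a
    partially different causal architecture.  Per-study noise is calibrated
    analytically so the latent genotype-explained variance spans ~0.28-0.80.
    The risk haplotype H6 carries the lead causal variant t6; haplotype H2
    is deliberately decoupled from both causal architectures.
    """
    pool = default_haplotype_pool()
    child = np.random.SeedSequence(seed).generate_state(16) % (2**31)

    g_ceu, truth_ceu = simulate_genotypes(pool, 60, int(child[0]), sample_prefix="ceu")
    g_ast, truth_ast = simulate_genotypes(pool, 181, int(child[1]), sample_prefix="ast")
    genotypes = {"CEU": g_ceu, "asthma": g_ast}
    truths = {"CEU": truth_ceu, "asthma": truth_ast}

    datasets: dict[str, ExpressionDataset] = {}
    latents: dict[str, np.ndarray] = {}
    causal: dict[str, list[tuple[str, float]]] = {}
    signal_probes: dict[str, list[str]] = {}
    study_collection: dict[str, str] = {}

    for k, (study, (collection, n, n_probes, n_signal)) in enumerate(
        _STUDY_LAYOUT.items()
    ):
        effects = _CAUSAL[collection]
        g_sub = genotypes[collection].subset_samples(
            genotypes[collection].sample_ids[:n]
        )
        noise_sd = noise_sd_for_h2(pool, effects, _STUDY_H2[study])
        var_latent = genetic_variance(pool, effects) + noise_sd**2
        n_junk = n_probes - n_signal
        if study == "K":
            # probe noise tuned so signal probes pair at r^2 ~ 0.79
            rho = np.sqrt(0.79)
            probe_sd = float(np.sqrt(var_latent * (1.0 - rho) / rho))
        else:
            probe_sd = 0.15 * float(np.sqrt(var_latent))
        spec = EffectSpec(
            causal_variants=effects,
            noise_sd=noise_sd,
            n_probes=n_signal,
            probe_noise_sd=probe_sd,
            seed=int(child[2 + k]),
        )
        e_signal, latent = simulate_expression(g_sub, spec)
        rng = np.random.default_rng(int(child[8 + k]))
        junk = rng.normal(0.0, 1.0, size=(n, n_junk))
        values = np.column_stack([e_signal.values, junk])
        probe_ids = [f"{study}_p{j + 1:02d}" for j in range(n_probes)]

        if study == "K":
            targets = [(t, False) for t in _K_SIGNAL_TARGETS] + _K_JUNK_TARGETS
        elif study == "S":
            targets = [("utr_pre", False), ("exon1A", False)][:n_probes]
        elif study == "C":
            targets = [("exon9_utr", False)]
        else:  # D
            targets = [("exon9_utr", False), ("exon1A", False), ("exon4", False)]
        meta = _probe_meta(targets, probe_ids)

        datasets[study] = ExpressionDataset(
            sample_ids=list(g_sub.sample_ids),
            probe_ids=probe_ids,
            values=values,
            probe_meta=meta,
        )
        latents[study] = latent
        causal[study] = list(effects)
        signal_probes[study] = probe_ids[:n_signal]
        study_collection[study] = collection

    return FourStudyFixture(
        pool=pool,
        genotypes=genotypes,
        genotype_truth=truths,
        datasets=datasets,
        latents=latents,
        causal=causal,
        signal_probes=signal_probes,
        study_collection=study_collection,
        seed=seed,
    )


def write_truth_json(truth: GenotypeTruth, path) -> None:
    """Ground-truth sidecar: per-sample diplotypes."""
    with open(path, "w") as fh:
        json.dump({"diplotypes": [list(d) for d in truth.diplotypes]}, fh, indent=0)
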