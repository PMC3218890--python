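"""Genotype I/O, LD, pruning and EM phasing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisreg.genetics_core import (
    GenotypeError,
    GenotypeMatrix,
    LDUndefinedError,
    PhasingError,
    em_phase,
    haplotype_dosage,
    ld_r2,
    prune_by_ld,
    read_genotypes,
    write_genotypes_tsv,
    write_genotypes_vcf,
)
from cisreg.synthetic_data import HaplotypePool, simulate_genotypes

from tests.conftest import genotypes_from_dosages

# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

VCF_SMALL = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=7>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
7\t100\trsX\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t./.
7\t200\trsY\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
"""


def test_vcf_additive_coding(tmp_path):
    path = tmp_path / "small.vcf"
    path.write_text(VCF_SMALL)
    g = read_genotypes(path, fmt="vcf")
    assert g.sample_ids == ["a", "b", "c"]
    assert g.variant_ids == ["rsX", "rsY"]
    np.testing.assert_array_equal(g.dosages[:, 1], [0, 1, 2])
    assert g.dosages[0, 0] == 1 and g.dosages[1, 0] == 2
    assert np.isnan(g.dosages[2, 0])
    assert g.variant_meta.loc["rsY", "pos"] == 200


def test_vcf_multiallelic_rejected(tmp_path):
    bad = VCF_SMALL.replace("A\tG", "A\tG,T")
    path = tmp_path / "multi.vcf"
    path.write_text(bad)
    with pytest.raises(GenotypeError, match="multi-allelic"):
        read_genotypes(path, fmt="vcf")


def test_tsv_round_trip(tmp_path, rng):
    from tests.conftest import random_genotypes

    g = random_genotypes(rng, 20, 5)
    path = tmp_path / "g.tsv"
    write_genotypes_tsv(g, path)
    g2 = read_genotypes(path, fmt="tsv")
    assert g2.sample_ids == g.sample_ids
    assert g2.variant_ids == g.variant_ids
    np.testing.assert_array_equal(g2.dosages, g.dosages)


def test_vcf_matches_dosage_tsv(tmp_path, pool):
    """Phased VCF written from truth decodes to the same dosage matrix."""
    g, truth = simulate_genotypes(pool, 25, seed=7)
    vcf = tmp_path / "sim.vcf"
    tsv = tmp_path / "sim.tsv"
    write_genotypes_vcf(g, vcf, phased_haplotypes=truth.phased)
    write_genotypes_tsv(g, tsv)
    g_vcf = read_genotypes(vcf, fmt="vcf")
    g_tsv = read_genotypes(tsv, fmt="tsv")
    np.testing.assert_array_equal(g_vcf.dosages, g_tsv.dosages)
    assert g_vcf.variant_ids == g_tsv.variant_ids


def test_dosage_validation():
    with pytest.raises(GenotypeError, match="0/1/2"):
        genotypes_from_dosages([[0, 3.0], [1, 1]])


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_ld_self_and_flip():
    d = np.array([[0, 0, 2], [1, 1, 1], [2, 2, 0], [1, 1, 1]], dtype=float)
    g = genotypes_from_dosages(d)
    assert ld_r2(g, "v1", "v2").r2 == pytest.approx(1.0)
    assert ld_r2(g, "v1", "v3").r2 == pytest.approx(1.0)  # v3 = 2 - v1


def test_ld_hand_oracle():
    """r^2 of (0,1,2,1) vs (0,1,1,2) from the direct Pearson formula."""
    x = np.array([0.0, 1, 2, 1])
    y = np.array([0.0, 1, 1, 2])
    cov = ((x - x.mean()) * (y - y.mean())).sum()
    expected = cov**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    assert expected == pytest.approx(0.25)
    g = genotypes_from_dosages(np.column_stack([x, y]))
    assert ld_r2(g, "v1", "v2").r2 == pytest.approx(expected, abs=1e-12)


def test_ld_zero_variance_error():
    g = genotypes_from_dosages([[1, 0], [1, 1], [1, 2]])
    with pytest.raises(LDUndefinedError):
        ld_r2(g, "v1", "v2")


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.permutations(range(12)))
def test_ld_invariant_to_labels_and_order(seed, perm):
    """LD r^2 is unchanged by ref/alt swap and by sample reordering."""
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, [0.3, 0.4], size=(12, 2)).astype(float)
    if d.std(axis=0).min() == 0:
        return
    g = genotypes_from_dosages(d)
    base = ld_r2(g, "v1", "v2").r2
    flipped = genotypes_from_dosages(np.column_stack([2 - d[:, 0], d[:, 1]]))
    reordered = genotypes_from_dosages(d[list(perm)])
    assert ld_r2(flipped, "v1", "v2").r2 == pytest.approx(base, abs=1e-12)
    assert ld_r2(reordered, "v1", "v2").r2 == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def test_prune_duplicates_and_independent(rng):
    d0 = rng.binomial(2, 0.4, size=40).astype(float)
    d1 = rng.binomial(2, 0.3, size=40).astype(float)
    g = genotypes_from_dosages(np.column_stack([d0, d0, d1]))
    kept, report = prune_by_ld(g, 0.90)
    assert len(kept) == 2 and "v3" in kept
    assert set(report["removed_id"]) == {"v2"} or set(report["removed_id"]) == {"v1"}

    g_ind = genotypes_from_dosages(
        rng.binomial(2, [0.2, 0.3, 0.5], size=(500, 3)).astype(float)
    )
    kept_ind, rep_ind = prune_by_ld(g_ind, 0.90)
    assert kept_ind == ["v1", "v2", "v3"] and rep_ind.empty


def test_prune_three_perfect_groups(rng):
    """10 variants in 3 perfect-LD groups collapse to 3, report consistent."""
    base = rng.binomial(2, [0.25, 0.35, 0.45], size=(60, 3)).astype(float)
    groups = [0, 0, 0, 0, 1, 1, 1, 2, 2, 2]
    d = np.column_stack([base[:, k] for k in groups])
    g = genotypes_from_dosages(d)
    kept, report = prune_by_ld(g, 0.90)
    assert len(kept) == 3
    kept_groups = [groups[int(v[1:]) - 1] for v in kept]
    assert sorted(kept_groups) == [0, 1, 2]
    for _, row in report.iterrows():
        assert groups[int(row.removed_id[1:]) - 1] == groups[int(row.kept_id[1:]) - 1]
        assert row.r2 >= 0.90


def test_prune_idempotent(pool):
    g, _ = simulate_genotypes(pool, 150, seed=3)
    kept, _ = prune_by_ld(g, 0.90)
    g2 = g.subset_variants(kept)
    kept2, report2 = prune_by_ld(g2, 0.90)
    assert kept2 == kept and report2.empty


def test_prune_protected_kept(pool):
    g, _ = simulate_genotypes(pool, 150, seed=3)
    kept, report = prune_by_ld(g, 0.90, protected=["t6_cp1"])
    assert "t6_cp1" in kept
    assert "t6" not in kept  # its perfect proxy is removed instead
    assert (report[report.removed_id == "t6"].kept_id == "t6_cp1").all()


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------

def two_snp_pool(freqs=(0.4, 0.3, 0.2, 0.1)) -> HaplotypePool:
    haps = [("00", (0, 0)), ("01", (0, 1)), ("10", (1, 0)), ("11", (1, 1))]
    return HaplotypePool(
        variant_ids=["a", "b"],
        haplotypes=[(h, al, f) for (h, al), f in zip(haps, freqs)],
    )


def grid_search_mle(genos: np.ndarray) -> np.ndarray:
    """Brute-force 2-SNP haplotype-frequency MLE over the 3-simplex.

    Coarse 0.02 grid, then 0.002 refinement around the best point; fully
    independent of the EM implementation.
    """
    pairs = {}
    for ga, gb in itertools.product((0, 1, 2), repeat=2):
        compat = []
        for h1 in itertools.product((0, 1), repeat=2):
            for h2 in itertools.product((0, 1), repeat=2):
                if h1[0] + h2[0] == ga and h1[1] + h2[1] == gb and h1 <= h2:
                    compat.append((2 * h1[0] + h1[1], 2 * h2[0] + h2[1]))
        pairs[(ga, gb)] = compat
    counts = {}
    for row in genos:
        counts[tuple(row)] = counts.get(tuple(row), 0) + 1

    def ll(f):
        total = 0.0
        for geno, c in counts.items():
            p = sum(
                f[a] * f[b] * (2.0 if a != b else 1.0) for a, b in pairs[geno]
            )
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
                    f1, f2, f3 = center[0] + d1, center[1] + d2, center[2] + d3
                    f4 = 1.0 - f1 - f2 - f3
                    if min(f1, f2, f3, f4) < 0:
                        continue
                    cand = np.array([f1, f2, f3, f4])
                    v = ll(cand)
                    if v > best_ll:
                        best, best_ll = cand, v
        return best

    coarse = search(np.array([0.25, 0.25, 0.25]), 0.25, 0.02)
    fine = search(coarse, 0.02, 0.002)
    return search(fine, 0.002, 0.0002)


def test_em_matches_grid_search_mle():
    pool = two_snp_pool()
    g, _ = simulate_genotypes(pool, 200, seed=11)
    hs = em_phase(g, ["a", "b"])
    mle = grid_search_mle(g.dosages.astype(int))
    em_freqs = np.array(
        [hs.frequencies.get("".join(map(str, h)), 0.0) for h in
         [(0, 0), (0, 1), (1, 0), (1, 1)]]
    )
    np.testing.assert_allclose(em_freqs, mle, atol=2e-3)
    # log-likelihood monotone across iterations
    diffs = np.diff(hs.ll_history)
    assert (diffs >= -1e-10).all()


def test_em_unambiguous_samples():
    """All-homozygous and single-het samples phase with posterior 1."""
    d = np.array([[2, 2, 0], [0, 0, 0], [2, 1, 0]], dtype=float)
    g = genotypes_from_dosages(d)
    hs = em_phase(g, ["v1", "v2", "v3"])
    np.testing.assert_allclose(hs.posteriors, 1.0)
    assert hs.diplotypes[0] == ("110", "110")
    assert hs.diplotypes[2] == ("100", "110")


def test_em_recovery_6hap(pool):
    """Frequencies within 3 SE of truth; >=95% exact hard diplotypes, n=200."""
    g, truth = simulate_genotypes(pool, 200, seed=5)
    hs = em_phase(g, pool.tag_variant_ids, name_map=pool.tag_name_map())
    n = 200
    for hid, _, f in pool.haplotypes:
        se = np.sqrt(f * (1 - f) / (2 * n))
        assert abs(hs.frequencies.get(hid, 0.0) - f) < 3 * se + 1e-9
    exact = np.mean(
        [hs.diplotypes[i] == truth.diplotypes[i] for i in range(n)]
    )
    assert exact >= 0.95


def test_em_guards():
    g = genotypes_from_dosages(np.ones((4, 13)))
    with pytest.raises(PhasingError, match="enumeration bound"):
        em_phase(g, g.variant_ids)
    g2 = genotypes_from_dosages([[1, np.nan], [0, 1], [2, 0]])
    with pytest.warns(UserWarning, match="missing tag"):
        em_phase(g2, ["v1", "v2"])


def test_haplotype_dosage_modes(pool):
    g, truth = simulate_genotypes(pool, 120, seed=9)
    hs = em_phase(g, pool.tag_variant_ids, name_map=pool.tag_name_map())
    hard = np.column_stack(
        [haplotype_dosage(hs, h, "hard") for h in hs.haplotype_ids]
    )
    exp = np.column_stack(
        [haplotype_dosage(hs, h, "expected") for h in hs.haplotype_ids]
    )
    np.testing.assert_allclose(hard.sum(axis=1), 2.0)
    np.testing.assert_allclose(exp.sum(axis=1), 2.0, atol=1e-6)
    # unambiguous-phase samples: hard dosage equals the generator's truth
    for i, (d1, d2) in enumerate(truth.diplotypes):
        if hs.posteriors[i] > 0.99:
            for hid in (d1, d2):
                expected_count = float((d1 == hid) + (d2 == hid))
                j = hs.haplotype_ids.index(hid)
                assert hard[i, j] == expected_count
    with pytest.raises(KeyError):
        haplotype_dosage(hs, "H99")
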