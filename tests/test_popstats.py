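"""Frequencies, heterozygosity, Weir-Cockerham Fst, permutation p,
Tajima's D, LD, PCA, and allele sharing, each against an independent oracle
or a hand-computed value."""

import math

import numpy as np
import pandas as pd
import pytest

from svpopdiff.core import GenotypeMatrix, PopulationPanel, make_windows
from svpopdiff.popstats import (
    PermutationResult,
    allele_frequencies,
    group_allele_sharing,
    ld_decay_profile,
    ld_pairs,
    ld_r2,
    observed_heterozygosity,
    pca,
    permutation_fst_p,
    persite_permutation_p,
    sliding_tajimas_d,
    site_fst,
    tajimas_d,
    wc_fst_components,
    weighted_fst,
    windowed_fst,
)
from svpopdiff.synthdata import SimConfig, simulate_panel


def _matrix(dosage, chrom=None, starts=None, svtype="DEL"):
    dosage = np.asarray(dosage, dtype=np.int16)
    n_samples, n_sites = dosage.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom or ["1"] * n_sites,
            "start": starts if starts is not None else np.arange(n_sites) * 1_000,
            "end": (starts if starts is not None else np.arange(n_sites) * 1_000) + np.full(n_sites, 100),
            "svtype": [svtype] * n_sites,
            "site_id": [f"{svtype}_{j}" for j in range(n_sites)],
        }
    )
    return GenotypeMatrix(sites, [f"s{i}" for i in range(n_samples)], dosage)


# ---------------------------------------------------------------------------
# frequencies / heterozygosity


class TestFrequencies:
    def test_arithmetic_examples(self):
        freqs = allele_frequencies(np.array([[0], [1], [2]], dtype=np.int16))
        assert freqs[0] == pytest.approx(0.5)
        assert allele_frequencies(np.zeros((4, 1), dtype=np.int16))[0] == 0.0
        assert allele_frequencies(np.full((4, 1), 2, dtype=np.int16))[0] == 1.0

    def test_all_missing_is_nan(self):
        assert math.isnan(allele_frequencies(np.full((3, 1), -1, dtype=np.int16))[0])

    def test_heterozygosity_examples(self):
        het = observed_heterozygosity(np.array([[1], [1], [0], [2]], dtype=np.int16))
        assert het[0] == pytest.approx(0.5)

    def test_hwe_simulation_recovers_expected_het(self, rng):
        # 2pq = 0.5 at p = 0.5
        dosage = rng.binomial(2, 0.5, size=(5_000, 1)).astype(np.int16)
        het = observed_heterozygosity(dosage)[0]
        assert het == pytest.approx(0.5, abs=2 * math.sqrt(0.25 / 5_000) + 0.005)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst


def _wc_oracle(gen_a, gen_b):
    """Independently coded textbook Weir & Cockerham (1984) components for
    one biallelic site and two diploid samples-of-populations, written as a
    direct scalar transliteration."""
    r = 2
    n = [len(gen_a), len(gen_b)]
    p = [sum(gen_a) / (2 * len(gen_a)), sum(gen_b) / (2 * len(gen_b))]
    h = [sum(1 for g in gen_a if g == 1) / len(gen_a),
         sum(1 for g in gen_b if g == 1) / len(gen_b)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_identical_groups_give_near_zero(self):
        # identical frequency 0.5 and het 0.5 in both groups; the estimator
        # is unbiased, so a finite identical sample sits near (slightly
        # below) zero
        block = np.array([0, 1, 1, 2] * 25, dtype=np.int16)  # 100 diploids
        dosage = np.concatenate([block, block])[:, None]
        idx_a, idx_b = np.arange(100), np.arange(100, 200)
        fst = site_fst(dosage, idx_a, idx_b)[0]
        assert fst == pytest.approx(0.0, abs=0.01)
        assert fst <= 0.0

    def test_fixed_difference_gives_one(self):
        dosage = np.array([[2]] * 5 + [[0]] * 5, dtype=np.int16)
        fst = site_fst(dosage, np.arange(5), np.arange(5, 10))[0]
        assert fst == pytest.approx(1.0)

    def test_components_match_scalar_oracle(self, rng):
        """Vectorized components equal the independently coded per-site
        formulas to 1e-10 over random sites and unequal group sizes."""
        n_a, n_b, n_sites = 13, 9, 100
        dosage = rng.integers(0, 3, size=(n_a + n_b, n_sites)).astype(np.int16)
        idx_a, idx_b = np.arange(n_a), np.arange(n_a, n_a + n_b)
        a, b, c = wc_fst_components(dosage, idx_a, idx_b)
        for j in range(n_sites):
            oa, ob, oc = _wc_oracle(dosage[idx_a, j].tolist(), dosage[idx_b, j].tolist())
            assert a[j] == pytest.approx(oa, abs=1e-10)
            assert b[j] == pytest.approx(ob, abs=1e-10)
            assert c[j] == pytest.approx(oc, abs=1e-10)

    def test_single_site_window_equals_site_fst(self):
        dosage = np.array([[2], [2], [1], [0], [0], [1]], dtype=np.int16)
        matrix = _matrix(dosage)
        panel = PopulationPanel(pd.DataFrame({
            "sample": matrix.samples,
            "breed": ["x"] * 6,
            "group": ["A"] * 3 + ["B"] * 3,
        }))
        frame = windowed_fst(matrix, panel, "A", "B", window_size=1_000_000)
        expected = site_fst(dosage, np.arange(3), np.arange(3, 6))[0]
        assert frame["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_window_ratio_of_sums_by_hand(self):
        """A window mixing undifferentiated sites with one fixed-difference
        site gives sum(a)/sum(a+b+c), strictly between the per-site values."""
        same = [0, 1, 1, 2] * 2  # identical in both groups -> a ~ 0
        dosage = np.column_stack([
            np.array(same, dtype=np.int16),
            np.array([2, 2, 2, 2, 0, 0, 0, 0], dtype=np.int16),
        ])
        idx_a, idx_b = np.arange(4), np.arange(4, 8)
        a, b, c = wc_fst_components(dosage, idx_a, idx_b)
        by_hand = (a[0] + a[1]) / (a[0] + b[0] + c[0] + a[1] + b[1] + c[1])
        got = weighted_fst(dosage, idx_a, idx_b)
        assert got == pytest.approx(by_hand, abs=1e-12)
        per_site = site_fst(dosage, idx_a, idx_b)
        assert per_site[0] < got < per_site[1]

    def test_balding_nichols_recovery(self):
        """Genome-wide weighted Fst recovers the Balding-Nichols target
        within +/-0.02 (2 groups x 50 diploids, 2,000 sites)."""
        cfg = SimConfig(
            seed=42,
            group_sizes={"A": 50, "B": 50},
            target_fst=0.1,
            n_snp=2_000,
            n_sv={"DEL": 10},
            n_implant=0,
            ld_rho=0.0,
            missing_rate=0.0,
        )
        snp, _, panel, _ = simulate_panel(cfg)
        gi = panel.group_indices(snp.samples)
        fst = weighted_fst(snp.dosage, gi["A"], gi["B"])
        assert fst == pytest.approx(0.1, abs=0.02)


class TestPermutation:
    def test_closed_form_identity(self):
        res = PermutationResult(observed=0.5, n_perm=10_000, n_exceed=0)
        assert res.p == pytest.approx(1 / 10_001)
        assert res.p * (res.n_perm + 1) - 1 == pytest.approx(res.n_exceed)
        assert PermutationResult(0.5, 100, 100).p == 1.0

    def test_differentiated_groups_get_minimal_p(self):
        rng = np.random.default_rng(5)
        neutral = rng.integers(0, 3, size=(20, 30)).astype(np.int16)
        fixed = np.array([[2]] * 10 + [[0]] * 10, dtype=np.int16)
        dosage = np.hstack([fixed, neutral])
        matrix = _matrix(dosage)
        panel = PopulationPanel(pd.DataFrame({
            "sample": matrix.samples,
            "breed": ["x"] * 20,
            "group": ["A"] * 10 + ["B"] * 10,
        }))
        res = permutation_fst_p(matrix, panel, "A", "B", n_perm=199, seed=1)
        assert res.n_exceed == 0
        assert res.p == pytest.approx(1 / 200)

    def test_persite_p_respects_identity(self, rng):
        dosage = rng.integers(0, 3, size=(16, 20)).astype(np.int16)
        fst, p = persite_permutation_p(dosage, np.arange(8), np.arange(8, 16),
                                       n_perm=99, seed=3)
        ok = ~np.isnan(p)
        n_exceed = p[ok] * 100 - 1
        assert np.allclose(n_exceed, np.round(n_exceed))

    def test_null_p_is_roughly_uniform(self):
        """On exchangeable (panmictic) data the permutation p is approximately
        Uniform(0,1]: over replicates, the fraction with p <= 0.2 stays near
        0.2."""
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            freqs = rng.uniform(0.1, 0.9, size=25)
            dosage = rng.binomial(2, freqs, size=(20, 25)).astype(np.int16)
            matrix = _matrix(dosage)
            panel = PopulationPanel(pd.DataFrame({
                "sample": matrix.samples,
                "breed": ["x"] * 20,
                "group": ["A"] * 10 + ["B"] * 10,
            }))
            res = permutation_fst_p(matrix, panel, "A", "B", n_perm=49,
                                    seed=int(rng.integers(2**31)))
            if res.p <= 0.2:
                hits += 1
        se = math.sqrt(0.2 * 0.8 / n_rep)
        assert abs(hits / n_rep - 0.2) < 3 * se + 0.02


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_oracle(allele_counts, n):
    """Independent Tajima's D from per-site (alt count, chromosomes) pairs."""
    S = sum(1 for k, m in allele_counts if 0 < k < m)
    pi = sum(2 * k * (m - k) / (m * (m - 1)) for k, m in allele_counts if m > 1)
    if S == 0:
        return S, pi, float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return S, pi, D


class TestTajimasD:
    def test_monomorphic_window_is_nan(self):
        S, pi, D = tajimas_d(np.zeros((5, 4), dtype=np.int16))
        assert S == 0 and pi == 0.0 and math.isnan(D)

    def test_two_diploids_one_site(self):
        # n = 4 chromosomes, allele counts 2/2 -> pi = 2*2*2/(4*3) = 2/3, S = 1
        dosage = np.array([[2], [0]], dtype=np.int16)
        S, pi, D = tajimas_d(dosage)
        assert S == 1
        assert pi == pytest.approx(2 / 3)
        oS, opi, oD = _tajima_oracle([(2, 4)], 4)
        assert D == pytest.approx(oD, abs=1e-10)

    def test_matches_oracle_on_random_windows(self, rng):
        """100 random windows agree with the independent formula oracle to
        1e-10 (complete data)."""
        for _ in range(100):
            n_samples = int(rng.integers(2, 12))
            n_sites = int(rng.integers(1, 30))
            dosage = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int16)
            S, pi, D = tajimas_d(dosage)
            n = 2 * n_samples
            counts = [(int(dosage[:, j].sum()), n) for j in range(n_sites)]
            oS, opi, oD = _tajima_oracle(counts, n)
            assert S == oS
            assert pi == pytest.approx(opi, abs=1e-10)
            if math.isnan(oD):
                assert math.isnan(D)
            else:
                assert D == pytest.approx(oD, abs=1e-10)

    def test_neutral_frequency_spectrum_centres_d_near_zero(self, rng):
        """Windows drawn from the neutral 1/k frequency spectrum have mean D
        within 2 s.e. of 0 over 500 windows."""
        n_samples, n_sites, n_windows = 20, 40, 500
        n = 2 * n_samples
        k_values = np.arange(1, n)
        weights = (1.0 / k_values) / np.sum(1.0 / k_values)
        ds = []
        for _ in range(n_windows):
            ks = rng.choice(k_values, size=n_sites, p=weights)
            dosage = np.zeros((n_samples, n_sites), dtype=np.int16)
            for j, k in enumerate(ks):
                chroms = np.zeros(n, dtype=np.int16)
                chroms[rng.choice(n, size=int(k), replace=False)] = 1
                dosage[:, j] = chroms[0::2] + chroms[1::2]
            _, _, D = tajimas_d(dosage)
            if not math.isnan(D):
                ds.append(D)
        ds = np.array(ds)
        se = ds.std(ddof=1) / math.sqrt(len(ds))
        assert abs(ds.mean()) < 2 * se + 0.02


class TestSlidingWindows:
    def _matrix_with(self, n_var):
        dosage = np.tile(np.array([[0], [1], [2], [1]], dtype=np.int16), (1, n_var))
        return _matrix(dosage)

    def test_forty_variants_three_full_windows(self):
        wins = sliding_tajimas_d(self._matrix_with(40))
        assert len(wins) == 3
        assert [w.n_sites for w in wins] == [20, 20, 20]

    def test_twenty_variants_single_window(self):
        wins = sliding_tajimas_d(self._matrix_with(20))
        assert len(wins) == 1

    def test_trailing_partial_kept_when_it_extends_coverage(self):
        # 35 variants: full windows at 0 and 10; trailing 20..34 has 15 >= 10
        wins = sliding_tajimas_d(self._matrix_with(35))
        assert [w.n_sites for w in wins] == [20, 20, 15]

    def test_fewer_than_one_window_warns_single_partial(self, caplog):
        wins = sliding_tajimas_d(self._matrix_with(7))
        assert len(wins) == 1
        assert wins[0].n_sites == 7

    def test_bp_mode_delegates_to_grid(self):
        n_var = 30
        starts = np.arange(n_var) * 100_000  # spans 2.9 Mb
        dosage = np.tile(np.array([[0], [1], [2], [1]], dtype=np.int16), (1, n_var))
        matrix = _matrix(dosage, starts=starts)
        wins = sliding_tajimas_d(matrix, mode="bp", bp_window=1_000_000)
        grid = make_windows({"1": int(starts[-1]) + 101}, 1_000_000)
        assert len(wins) == grid.n_windows
        assert sum(w.n_sites for w in wins) == n_var


# ---------------------------------------------------------------------------
# LD


class TestLd:
    def test_identical_vectors_r2_one(self):
        x = np.array([0, 1, 2, 1, 0], dtype=np.int16)
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal_vectors_r2_zero(self):
        a = np.array([0, 0, 2, 2], dtype=np.int16)
        b = np.array([0, 2, 0, 2], dtype=np.int16)
        assert ld_r2(a, b) == pytest.approx(0.0)

    def test_zero_variance_is_nan(self):
        a = np.array([1, 1, 1, 1], dtype=np.int16)
        b = np.array([0, 1, 2, 0], dtype=np.int16)
        assert math.isnan(ld_r2(a, b))

    def test_matches_corrcoef_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(0, 3, size=30).astype(np.int16)
            y = rng.integers(0, 3, size=30).astype(np.int16)
            if x.var() == 0 or y.var() == 0:
                continue
            assert ld_r2(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_pair_enumeration_matches_brute_force(self, rng):
        n_sites = 40
        starts = np.sort(rng.choice(3_000_000, size=n_sites, replace=False))
        chroms = ["1"] * 25 + ["2"] * 15
        starts = np.concatenate([np.sort(starts[:25]), np.sort(starts[25:])])
        dosage = rng.integers(0, 3, size=(12, n_sites)).astype(np.int16)
        matrix = _matrix(dosage, chrom=chroms, starts=starts)
        pairs = ld_pairs(matrix, max_dist=500_000)
        sites = matrix.sites
        expected = sum(
            1
            for j in range(n_sites)
            for k in range(j + 1, n_sites)
            if sites["chrom"][j] == sites["chrom"][k]
            and abs(int(sites["start"][k]) - int(sites["start"][j])) <= 500_000
        )
        assert len(pairs) == expected

    def test_decay_profile_trend_on_block_ld(self):
        cfg = SimConfig(
            seed=31,
            chrom_lengths={"1": 3_000_000},
            group_sizes={"A": 40},
            target_fst=0.0,
            n_snp=250,
            n_sv={"DEL": 5},
            n_implant=0,
            ld_block_bp=500_000,
            ld_rho=0.9,
            missing_rate=0.0,
        )
        snp, _, _, _ = simulate_panel(cfg)
        prof = ld_decay_profile(snp, max_dist=1_500_000, n_bins=3)
        means = prof["mean_r2"].dropna().to_numpy()
        assert len(means) == 3
        assert means[0] > means[-1]


# ---------------------------------------------------------------------------
# PCA and allele sharing


class TestPca:
    def test_separated_groups_split_on_pc1(self):
        cfg = SimConfig(
            seed=13,
            chrom_lengths={"1": 3_000_000},
            group_sizes={"A": 25, "B": 25},
            target_fst=0.2,
            n_snp=800,
            n_sv={"DEL": 5},
            n_implant=0,
            ld_rho=0.0,
            missing_rate=0.0,
        )
        snp, _, panel, _ = simulate_panel(cfg)
        coords, _ = pca(snp)
        pc1_a = coords[:25, 0]
        pc1_b = coords[25:, 0]
        assert max(pc1_a.min(), pc1_b.min()) > min(pc1_a.max(), pc1_b.max()) or \
               min(pc1_a.max(), pc1_b.max()) < max(pc1_a.min(), pc1_b.min()) or \
               (pc1_a.max() < pc1_b.min() or pc1_b.max() < pc1_a.min())

    def test_duplicate_samples_identical_coordinates(self, rng):
        base = rng.integers(0, 3, size=(5, 60)).astype(np.int16)
        dosage = np.vstack([base, base[0]])
        matrix = _matrix(dosage)
        coords, eigvals = pca(matrix)
        solid = eigvals[: coords.shape[1]] > 1e-6  # skip null-space noise
        assert np.allclose(coords[0, solid], coords[-1, solid], atol=1e-6)

    def test_eigenvalue_sum_equals_trace(self, rng):
        dosage = rng.integers(0, 3, size=(10, 80)).astype(np.int16)
        matrix = _matrix(dosage)
        d = dosage.astype(float)
        p = d.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        z = (d[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
        cov = z @ z.T / poly.sum()
        _, eigvals = pca(matrix)
        assert eigvals.sum() == pytest.approx(np.trace(cov), abs=1e-8)

    def test_sample_order_invariance(self, rng):
        dosage = rng.integers(0, 3, size=(8, 50)).astype(np.int16)
        m1 = _matrix(dosage)
        perm = rng.permutation(8)
        m2 = m1.subset_samples([m1.samples[i] for i in perm])
        c1, e1 = pca(m1)
        c2, e2 = pca(m2)
        assert np.allclose(e1, e2, atol=1e-8)
        assert np.allclose(np.abs(c1[perm, 0]), np.abs(c2[:, 0]), atol=1e-8)

    def test_no_polymorphic_sites_raises(self):
        matrix = _matrix(np.zeros((4, 5), dtype=np.int16))
        with pytest.raises(ValueError):
            pca(matrix)


class TestAlleleSharing:
    def _panel(self, n_per=2):
        samples = [f"s{i}" for i in range(3 * n_per)]
        return PopulationPanel(pd.DataFrame({
            "sample": samples,
            "breed": ["x"] * (3 * n_per),
            "group": ["A"] * n_per + ["B"] * n_per + ["C"] * n_per,
        }))

    def test_pattern_classes(self):
        dosage = np.array(
            [
                # site0: only A; site1: all; site2: A+B; site3: absent
                [1, 1, 1, 0],
                [0, 1, 0, 0],
                [0, 1, 1, 0],
                [0, 1, 1, 0],
                [0, 1, 0, 0],
                [0, 2, 0, 0],
            ],
            dtype=np.int16,
        )
        matrix = _matrix(dosage)
        per_site, per_group = group_allele_sharing(matrix, self._panel())
        assert per_site["class"].tolist() == [
            "specific:A", "shared-all", "shared-2", "absent",
        ]
        rates = per_group.set_index("group")["per_genome_rate"]
        assert rates["A"] == pytest.approx(0.5)  # 1 specific site / 2 genomes
        assert rates["B"] == 0.0

    def test_tallies_match_enumeration_oracle(self, rng):
        dosage = rng.integers(0, 3, size=(6, 60)).astype(np.int16)
        matrix = _matrix(dosage)
        panel = self._panel()
        per_site, _ = group_allele_sharing(matrix, panel)
        for j in range(60):
            present = []
            for g, lo in (("A", 0), ("B", 2), ("C", 4)):
                if (dosage[lo:lo + 2, j] > 0).any():
                    present.append(g)
            expect = {0: "absent", 1: f"specific:{present[0] if present else ''}",
                      2: "shared-2", 3: "shared-all"}[len(present)]
            assert per_site["class"].iloc[j] == expect

    def test_site_order_invariance(self, rng):
        dosage = rng.integers(0, 3, size=(6, 30)).astype(np.int16)
        m1 = _matrix(dosage)
        # same sites presented in reverse start order
        starts = np.arange(30)[::-1] * 1_000
        m2 = _matrix(dosage[:, ::-1], starts=starts[::-1])
        _, g1 = group_allele_sharing(m1, self._panel())
        _, g2 = group_allele_sharing(m2, self._panel())
        pd.testing.assert_frame_equal(g1, g2)
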