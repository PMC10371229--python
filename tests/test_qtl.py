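"""Kinship, factor residualisation, LMM scans, permutations, cis/trans calls."""

import numpy as np
import pandas as pd
import pytest

from musclemap.phenotypes import ProteinMatrix
from musclemap.qtl import (ScanConfig, classify_pqtl, genome_scan,
                           kinship_matrix, permutation_threshold,
                           residualize_factors)
from musclemap.simulate import SimConfig, simulate_genotypes


@pytest.fixture(scope="module")
def geno():
    cfg = SimConfig(n_mice=50, n_chromosomes=3, markers_per_chromosome=25, seed=7)
    return simulate_genotypes(cfg)


def _kinship_bruteforce(G: pd.DataFrame) -> np.ndarray:
    # O(n^2 m) double loop straight from the definition
    X = G.to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    keep = sd > 0
    A = (X[:, keep] - mu[keep]) / sd[keep]
    n, m = A.shape
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = sum(A[i, t] * A[j, t] for t in range(m)) / m
    return K


class TestKinship:
    def test_matches_bruteforce(self, geno):
        G = geno.dosages.iloc[:12, :20]
        assert np.allclose(kinship_matrix(G).to_numpy(), _kinship_bruteforce(G), atol=1e-10)

    def test_duplicate_mice_share_diagonal_entry(self, geno):
        G = geno.dosages.iloc[:10].copy()
        G.iloc[1] = G.iloc[0].to_numpy()
        K = kinship_matrix(G)
        assert K.iloc[0, 1] == pytest.approx(K.iloc[0, 0], rel=1e-12)

    def test_symmetric_psd(self, geno):
        K = kinship_matrix(geno.dosages).to_numpy()
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_monomorphic_errors(self):
        G = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="monomorphic"):
            kinship_matrix(G)


def _pm(values: np.ndarray) -> ProteinMatrix:
    n, p = values.shape
    return ProteinMatrix(
        values=pd.DataFrame(values, index=[f"DO{i}" for i in range(n)],
                            columns=[f"P{j}" for j in range(p)]),
        fraction="pmf",
    )


class TestResidualize:
    def test_k0_is_identity_on_zscores(self, rng):
        v = rng.normal(3, 2, size=(20, 6))
        out = residualize_factors(_pm(v), k=0).values.to_numpy()
        z = (v - v.mean(0)) / v.std(0, ddof=1)
        assert np.allclose(out, z, atol=1e-12)

    def test_rank_one_structure_removed(self, rng):
        f = rng.normal(size=(40, 1))
        load = rng.normal(size=(1, 30))
        v = f @ load + 0.01 * rng.normal(size=(40, 30))
        out = residualize_factors(_pm(v), k=1).values.to_numpy()
        assert out.var() <= 0.01 * 1.0  # z-scored input has unit variance

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError):
            residualize_factors(_pm(rng.normal(size=(5, 3))), k=5)

    def test_missing_values_stay_missing(self, rng):
        v = rng.normal(size=(15, 4))
        v[0, 0] = np.nan
        out = residualize_factors(_pm(v), k=1)
        assert np.isnan(out.values.iloc[0, 0])


def _ols_lod_oracle(y, G, covariates=None):
    """Independent per-marker OLS LOD via explicit residual sums of squares."""
    n = len(y)
    X0 = np.ones((n, 1))
    if covariates is not None:
        X0 = np.hstack([X0, covariates])
    b0, res0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(((y - X0 @ b0) ** 2).sum())
    lods = []
    for j in range(G.shape[1]):
        X1 = np.hstack([X0, G[:, [j]]])
        b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss1 = float(((y - X1 @ b1) ** 2).sum())
        lods.append((n / 2) * np.log10(rss0 / max(rss1, 1e-300)))
    return np.array(lods)


class TestScan:
    def test_no_kinship_equals_ols(self, geno, rng):
        G = geno.dosages
        y = pd.Series(rng.normal(size=len(G)), index=G.index)
        cfg = ScanConfig(use_kinship=False, n_permutations=50)
        scan = genome_scan(y, G, None, None, cfg)
        oracle = _ols_lod_oracle(y.to_numpy(), G.to_numpy())
        assert np.allclose(scan.lod.to_numpy(), oracle, atol=1e-8)

    def test_planted_marker_recovered(self, geno, rng):
        G = geno.dosages
        K = kinship_matrix(G)
        cfg = ScanConfig(n_permutations=50, seed=1)
        hits = 0
        markers = [m for m in G.columns if G[m].std() > 0.3]
        for t in range(10):
            m_star = markers[rng.integers(len(markers))]
            y = 1.0 * G[m_star] + 0.3 * rng.normal(size=len(G))
            scan = genome_scan(pd.Series(y, index=G.index), G, K, None, cfg)
            peak = geno.marker_map.loc[scan.peak_marker]
            truth = geno.marker_map.loc[m_star]
            same_region = (peak["chrom"] == truth["chrom"]
                           and abs(int(peak["pos_bp"]) - int(truth["pos_bp"])) <= 10_000_000)
            hits += same_region
        assert hits >= 9

    def test_lod_affine_invariant(self, geno, rng):
        G = geno.dosages
        K = kinship_matrix(G)
        y = pd.Series(rng.normal(size=len(G)), index=G.index)
        cfg = ScanConfig(n_permutations=50)
        l1 = genome_scan(y, G, K, None, cfg).lod
        l2 = genome_scan(3.0 * y - 7.0, G, K, None, cfg).lod
        assert np.allclose(l1, l2, atol=1e-6)

    def test_lod_nonnegative(self, geno, rng):
        y = pd.Series(rng.normal(size=len(geno.dosages)), index=geno.dosages.index)
        scan = genome_scan(y, geno.dosages, kinship_matrix(geno.dosages), None, ScanConfig())
        assert (scan.lod >= 0).all()


class TestPermutations:
    def test_p_lower_bound_and_monotone_thresholds(self, geno, rng):
        G = geno.dosages
        K = kinship_matrix(G)
        cfg = ScanConfig(n_permutations=100, seed=3)
        # strong but not purely genetic signal (a fully genetic trait would be
        # absorbed into the kinship term -- proximal contamination)
        marker = next(m for m in G.columns if G[m].std() > 0.5)
        y = pd.Series(1.5 * G[marker] + 1.0 * rng.normal(size=len(G)), index=G.index)
        perm = permutation_threshold(y, G, K, None, cfg)
        scan = genome_scan(y, G, K, None, cfg)
        assert perm.p_value(scan.peak_lod) == pytest.approx(1 / 101)
        assert perm.threshold(0.05) >= perm.threshold(0.1)

    def test_refuses_too_few_permutations(self, geno):
        y = pd.Series(np.arange(len(geno.dosages), dtype=float), index=geno.dosages.index)
        with pytest.raises(ValueError, match="20"):
            permutation_threshold(y, geno.dosages, None, None,
                                  ScanConfig(n_permutations=10, use_kinship=False))

    def test_determinism_under_seed(self, geno, rng):
        G = geno.dosages
        y = pd.Series(rng.normal(size=len(G)), index=G.index)
        cfg = ScanConfig(n_permutations=60, seed=11, use_kinship=False)
        a = permutation_threshold(y, G, None, None, cfg)
        b = permutation_threshold(y, G, None, None, cfg)
        assert np.array_equal(a.max_lods, b.max_lods)


class TestClassify:
    MAP = pd.DataFrame({"chrom": ["chr1", "chr2"], "pos_bp": [5_000_000, 5_000_000]},
                       index=pd.Index(["m1", "m2"], name="marker_id"))
    CFG = ScanConfig()

    def test_boundary_distance_inclusive(self):
        # distance exactly 2 Mbp, p between the two alphas -> still cis
        assert classify_pqtl("m1", 0.08, ("chr1", 7_000_000), self.MAP, self.CFG) == "cis"

    def test_two_tier_alpha(self):
        assert classify_pqtl("m2", 0.06, ("chr1", 5_000_000), self.MAP, self.CFG) == "none"
        assert classify_pqtl("m2", 0.04, ("chr1", 5_000_000), self.MAP, self.CFG) == "trans"

    def test_local_but_weak_is_none(self):
        assert classify_pqtl("m1", 0.2, ("chr1", 5_000_000), self.MAP, self.CFG) == "none"

    def test_missing_position_errors(self):
        with pytest.raises(ValueError, match="position"):
            classify_pqtl("m1", 0.01, None, self.MAP, self.CFG)
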