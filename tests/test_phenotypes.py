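"""Matsuda Index, adiposity, presence filtering, normalisation, CV."""

import math

import numpy as np
import pandas as pd
import pytest

from musclemap.phenotypes import (BodyComposition, DomainError, GTTRecord,
                                  ProteinMatrix, adiposity_percent,
                                  coefficient_of_variation,
                                  fraction_enrichment, matsuda_index,
                                  normalise_proteome, presence_filter)


def _record(glucose, insulin, times=None):
    gt = tuple(times) if times else tuple(float(15 * i) for i in range(len(glucose)))
    it = gt[: len(insulin)]
    return GTTRecord("m1", gt, tuple(glucose), it, tuple(insulin))


def _matsuda_oracle(g, i):
    # independently coded one-liner straight from the formula
    return 10000 / math.sqrt(g[0] * i[0] * (sum(g) / len(g)) * (sum(i) / len(i)))


class TestMatsuda:
    def test_worked_example(self):
        rec = _record([100, 100], [10, 10])
        assert matsuda_index(rec) == pytest.approx(10.0, abs=0)

    def test_scale_equivariance(self):
        rec = _record([90, 200, 150, 120], [8, 20])
        doubled = _record([180, 400, 300, 240], [8, 20])
        assert matsuda_index(doubled) == pytest.approx(matsuda_index(rec) / 2, rel=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            g = rng.uniform(3, 30, size=6)
            i = rng.uniform(0.1, 10, size=2)
            rec = _record(g, i)
            assert matsuda_index(rec) == pytest.approx(_matsuda_oracle(g, i), rel=1e-12)

    def test_strictly_decreasing_in_each_concentration(self, rng):
        g = [9.0, 20.0, 15.0, 12.0]
        i = [1.0, 3.0]
        base = matsuda_index(_record(g, i))
        for k in range(len(g)):
            g2 = list(g)
            g2[k] += 1.0
            assert matsuda_index(_record(g2, i)) < base
        for k in range(len(i)):
            i2 = list(i)
            i2[k] += 0.5
            assert matsuda_index(_record(g, i2)) < base

    def test_exclude_baseline_flag(self):
        rec = _record([100, 200], [10, 20])
        full = matsuda_index(rec)
        post = matsuda_index(rec, exclude_baseline_from_mean=True)
        assert post == pytest.approx(10000 / math.sqrt(100 * 10 * 200 * 20), rel=1e-12)
        assert post != full

    def test_rejects_nonpositive_concentrations(self):
        with pytest.raises(DomainError):
            GTTRecord("m1", (0.0, 15.0), (5.0, 0.0), (0.0,), (1.0,))

    def test_record_invariants(self):
        with pytest.raises(DomainError):
            GTTRecord("m1", (0.0, 15.0, 10.0), (5.0, 6.0, 7.0), (0.0,), (1.0,))
        with pytest.raises(DomainError):
            GTTRecord("m1", (5.0, 15.0), (5.0, 6.0), (5.0,), (1.0,))  # no t=0


class TestAdiposity:
    def test_worked_examples(self):
        assert adiposity_percent(BodyComposition("m", 10, 30, 50)) == 20.0
        assert adiposity_percent(BodyComposition("m", 0, 30, 50)) == 0.0

    def test_matches_oracle(self, rng):
        for _ in range(10):
            body = rng.uniform(20, 40)
            fat = rng.uniform(0, 10)
            bc = BodyComposition("m", fat, 0.7 * (body - fat), body)
            assert adiposity_percent(bc) == pytest.approx(100 * fat / body, rel=1e-12)

    def test_mass_invariants(self):
        with pytest.raises(DomainError):
            BodyComposition("m", 30, 30, 50)


def _pm(values: np.ndarray, ids=None) -> ProteinMatrix:
    n, p = values.shape
    return ProteinMatrix(
        values=pd.DataFrame(values, index=[f"DO{i}" for i in range(n)],
                            columns=ids or [f"P{j}" for j in range(p)]),
        fraction="pmf",
    )


class TestPresenceFilter:
    def test_exact_boundary_is_retained(self):
        v = np.ones((4, 2))
        v[:2, 0] = np.nan  # protein 0 observed in exactly 50% of mice
        out = presence_filter(_pm(v), 0.5)
        assert out.protein_ids == ["P0", "P1"]
        out2 = presence_filter(_pm(v), 0.51)
        assert out2.protein_ids == ["P1"]

    def test_fully_observed_identity_and_idempotence(self, rng):
        v = rng.normal(size=(5, 4))
        pm = _pm(v)
        once = presence_filter(pm)
        assert once.values.equals(pm.values)
        v[rng.random(v.shape) < 0.6] = np.nan
        pm2 = _pm(v)
        once = presence_filter(pm2)
        twice = presence_filter(once)
        assert twice.values.equals(once.values)

    def test_matches_counting_oracle(self, rng):
        v = rng.normal(size=(20, 30))
        v[rng.random(v.shape) < 0.5] = np.nan
        kept = presence_filter(_pm(v), 0.5).protein_ids
        expected = [f"P{j}" for j in range(30)
                    if (~np.isnan(v[:, j])).sum() >= 10]
        assert kept == expected


class TestNormalise:
    def test_column_medians_hit_grand_median(self, rng):
        v = rng.normal(10, 3, size=(15, 40))
        v[rng.random(v.shape) < 0.1] = np.nan
        out = normalise_proteome(_pm(v))
        med = out.values.median(axis=1)
        assert np.allclose(med, med.median(), atol=1e-9)

    def test_idempotent_once_centred(self, rng):
        v = rng.normal(size=(6, 20))
        once = normalise_proteome(_pm(v))
        twice = normalise_proteome(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_preserves_within_mouse_rank_order(self, rng):
        v = rng.normal(size=(5, 10))
        out = normalise_proteome(_pm(v))
        for i in range(5):
            assert (np.argsort(v[i]) == np.argsort(out.values.iloc[i].to_numpy())).all()

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(DomainError, match="non-positive"):
            normalise_proteome(_pm(np.array([[1.0, -2.0]])), log_transform=True)

    def test_single_mouse_trivial(self):
        out = normalise_proteome(_pm(np.array([[1.0, 5.0, 3.0]])))
        assert np.allclose(out.values, [[1.0, 5.0, 3.0]])


class TestCV:
    def test_constant_protein_zero(self):
        v = np.log2(np.full((4, 1), 7.0))
        assert coefficient_of_variation(_pm(v))["cv"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_forced_arithmetic(self):
        v = np.log2(np.array([[1.0], [3.0]]))
        cv = coefficient_of_variation(_pm(v))["cv"].iloc[0]
        assert cv == pytest.approx(math.sqrt(2) / 2, rel=1e-12)

    def test_matches_oracle_and_ranking(self, rng):
        lin = rng.lognormal(2, 0.5, size=(12, 8))
        out = coefficient_of_variation(_pm(np.log2(lin)))
        for j in range(8):
            expected = lin[:, j].std(ddof=1) / lin[:, j].mean()
            assert out.loc[f"P{j}", "cv"] == pytest.approx(expected, rel=1e-10)
        assert (out["cv"].diff().dropna() <= 1e-12).all()  # descending


class TestFractionEnrichment:
    def test_identical_fractions_ratio_one(self, rng):
        v = rng.normal(5, 1, size=(6, 10))
        assert fraction_enrichment(_pm(v), _pm(v.copy()), {"P0", "P1"}) == pytest.approx(1.0)

    def test_constructed_twofold(self):
        # one gene-set protein, one background protein, equal sums in PMF
        pmf = _pm(np.log2(np.array([[4.0, 4.0]])))
        mito = _pm(np.log2(np.array([[8.0, 4.0]])))
        ratio = fraction_enrichment(mito, pmf, {"P0"})
        assert ratio == pytest.approx((8 / 12) / (4 / 8), rel=1e-12)

    def test_absent_geneset_errors(self):
        pm = _pm(np.ones((2, 2)))
        with pytest.raises(DomainError):
            fraction_enrichment(pm, pm, {"missing"})
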