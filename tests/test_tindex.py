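"""Texture-index construction and the 2304-combination screen."""

import numpy as np
import pandas as pd
import pytest

from alfapnc.glcm import tfv_names
from alfapnc.scene import planted_tfv_table
from alfapnc.tindex import (FAMILIES, best_per_family, enumerate_pairs, ndti,
                            rank_family, rdti, rti, screen_tis, ti_heatmap)


class TestIndexFormulas:
    def test_basic_arithmetic(self):
        assert ndti(4, 2) == pytest.approx(1 / 3, abs=1e-4)
        assert rdti(6, 3) == pytest.approx(1.0)

    def test_identity_pairs(self):
        for t in (0.5, 1.0, 7.3):
            assert rti(t, t) == pytest.approx(1.0)
            assert ndti(t, t) == pytest.approx(0.0)

    def test_missing_on_bad_denominators(self):
        assert np.isnan(ndti(1.0, -1.0))
        assert np.isnan(rti(1.0, 0.0))
        assert np.isnan(rdti(1.0, -2.0))

    def test_ndti_bounded_and_antisymmetric(self, rng):
        a = rng.uniform(0, 5, 100)
        b = rng.uniform(0.001, 5, 100)
        v = ndti(a, b)
        assert (np.abs(v) <= 1).all()
        assert np.allclose(ndti(b, a), -v, atol=1e-12)

    def test_rti_reciprocal_product_is_one(self, rng):
        a = rng.uniform(0.1, 5, 100)
        b = rng.uniform(0.1, 5, 100)
        assert np.allclose(rti(a, b) * rti(b, a), 1.0, atol=1e-12)


class TestEnumerate:
    def test_48_names_give_2304_ordered_pairs(self):
        pairs = enumerate_pairs(tfv_names())
        assert len(pairs) == 2304

    def test_small_cases_and_self_pairs(self):
        pairs = enumerate_pairs(["a", "b"])
        assert len(pairs) == 4
        assert ("a", "a") in pairs and ("b", "b") in pairs
        big = enumerate_pairs(tfv_names())
        for name in tfv_names():
            assert (name, name) in big


class TestScreen:
    def test_planted_pair_ranks_first(self, rng):
        # clean construction: NDTI(t1, t2) exactly linear in PNC
        n = 48
        pnc = rng.normal(3.3, 0.26, n)
        v = 0.2 * (pnc - pnc.mean()) / pnc.std()
        cols = {name: np.abs(rng.normal(2.0, 0.3, n)) + 0.5 for name in tfv_names()}
        cols["NIR_mean"] = 2.0 * (1 + v)
        cols["B_mean"] = 2.0 * (1 - v)
        df = pd.DataFrame(cols)
        df["PNC"] = pnc
        cat = screen_tis(df)
        top = rank_family(cat, "NDTI").iloc[0]
        assert {top["t1"], top["t2"]} == {"NIR_mean", "B_mean"}
        assert abs(top["r"]) > 0.99

    def test_catalog_counts_and_self_pair_exclusion(self, branching_screening):
        cat = branching_screening.ti_catalog
        for fam in FAMILIES:
            sub = cat[cat["family"] == fam]
            assert len(sub) == 2304
            usable = sub["r"].notna().sum()
            assert 2304 - 48 >= usable >= 2304 - 48 - 200
        # self-pairs are constant series -> never ranked
        ranked = rank_family(cat, "NDTI")
        assert not (ranked["t1"] == ranked["t2"]).any()

    def test_screening_invariant_to_row_order(self):
        df, _ = planted_tfv_table(11)
        cat1 = screen_tis(df)
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        cat2 = screen_tis(shuffled)
        merged = cat1.merge(cat2, on=["family", "t1", "t2"], suffixes=("_a", "_b"))
        assert np.allclose(merged["r_a"].fillna(9), merged["r_b"].fillna(9), atol=1e-12)

    def test_permutation_null_shows_selection_effect(self, rng):
        # with PNC permuted the best of 2304 candidates is still far from 0:
        # the screen's max-|r| is strongly inflated relative to a single
        # pair's null correlation
        df, _ = planted_tfv_table(21)
        single_abs, best_abs = [], []
        for k in range(10):
            perm = df.copy()
            perm["PNC"] = rng.permutation(perm["PNC"].to_numpy())
            cat = screen_tis(perm)
            ranked = rank_family(cat, "NDTI")
            best_abs.append(ranked["abs_r"].iloc[0])
            fixed = cat[(cat["family"] == "NDTI") & (cat["t1"] == "G_var")
                        & (cat["t2"] == "R_ent")]
            single_abs.append(abs(fixed["r"].iloc[0]))
        assert np.median(best_abs) > 0.3
        assert np.median(best_abs) > 2 * np.median(single_abs)

    def test_best_per_family_threshold(self):
        df, (family, t1, t2) = planted_tfv_table(5)
        cat = screen_tis(df)
        best = best_per_family(cat, threshold=0.99)
        assert all(v is None for v in best.values())
        best = best_per_family(cat, threshold=0.5)
        assert best["NDTI"] is not None
        assert abs(best["NDTI"]["r"]) > 0.5


class TestHeatmap:
    def test_matrix_properties(self, branching_screening):
        cat = branching_screening.ti_catalog
        mat = ti_heatmap(cat, "NDTI")
        assert mat.shape == (48, 48)
        assert list(mat.index) == tfv_names()  # band-major order
        vals = mat.to_numpy(dtype=float)
        # antisymmetry of NDTI correlations; diagonal missing
        off = ~np.isnan(vals) & ~np.isnan(vals.T)
        assert np.allclose(vals[off], -vals.T[off], atol=1e-12)
        assert np.isnan(np.diag(vals)).all()

    def test_heatmap_figure_renders(self, branching_screening, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from alfapnc.tindex import plot_ti_heatmap

        out = tmp_path / "ndti.png"
        plot_ti_heatmap(branching_screening.ti_catalog, "NDTI", path=out)
        assert out.stat().st_size > 0

    def test_entries_match_catalog(self, branching_screening):
        cat = branching_screening.ti_catalog
        mat = ti_heatmap(cat, "RTI")
        sub = cat[cat["family"] == "RTI"].head(200)
        for row in sub.itertuples():
            got = mat.loc[row.t1, row.t2]
            if np.isnan(row.r):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(row.r, abs=1e-12)
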