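import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from esgamap import plates
from esgamap.plates import (FormatError, PlateQCError, build_screen_matrix,
                            circular_distance, linkage_mask, mask_linked,
                            normalize_plate, qc_filter, read_colony_table,
                            write_colony_table)


def make_plate(sizes, n_rows=32, n_cols=48, query="q1", replicate=1):
    sizes = np.asarray(sizes, dtype=float)
    rows = np.repeat(np.arange(1, n_rows + 1), n_cols)[: len(sizes)]
    cols = np.tile(np.arange(1, n_cols + 1), n_rows)[: len(sizes)]
    return pd.DataFrame({
        "query": query, "array": [f"a{i}" for i in range(len(sizes))],
        "plate": f"{query}.P01", "row": rows, "col": cols,
        "replicate": replicate, "condition": "rich", "size": sizes,
        "missing_flag": np.isnan(sizes).astype(int),
    })


class TestColonyTableIO:
    def test_single_row_round_trip(self, tmp_path):
        df = make_plate([123.4])
        path = tmp_path / "one.tsv"
        write_colony_table(df, path)
        back = read_colony_table(path)
        assert len(back) == 1
        assert back["size"].iloc[0] == 123.4

    def test_duplicate_key_error_names_lines(self, tmp_path):
        df = pd.concat([make_plate([1.0]), make_plate([2.0])], ignore_index=True)
        path = tmp_path / "dup.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match=r"lines \[2, 3\]"):
            read_colony_table(path)

    def test_missing_flag_consistency_enforced(self, tmp_path):
        df = make_plate([5.0])
        df.loc[0, "missing_flag"] = 1  # size present but flagged missing
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="missing_flag"):
            read_colony_table(path)

    def test_unknown_columns_preserved(self, tmp_path):
        df = make_plate([1.0, 2.0]).assign(extra="x")
        path = tmp_path / "extra.tsv"
        write_colony_table(df, path)
        assert "extra" in read_colony_table(path).columns


class TestNormalizePlate:
    def test_uniform_plate_maps_to_one(self):
        out = normalize_plate(make_plate(np.full(1536, 77.0)))
        assert np.allclose(out["size"], 1.0)

    def test_row_gradient_removed(self):
        rng = np.random.default_rng(0)
        rows = np.repeat(np.arange(1, 33), 48)
        sizes = 100 * (1 + 0.02 * rows) * rng.lognormal(0, 0.03, 1536)
        out = normalize_plate(make_plate(sizes))
        res = stats.linregress(rows, np.log(out["size"].to_numpy()))
        assert abs(res.slope) < 0.002

    def test_edge_inflation_corrected(self):
        rng = np.random.default_rng(1)
        rows = np.repeat(np.arange(1, 33), 48)
        cols = np.tile(np.arange(1, 49), 32)
        edge = (rows == 1) | (rows == 32) | (cols == 1) | (cols == 48)
        sizes = 50 * rng.lognormal(0, 0.03, 1536)
        sizes[edge] *= 1.5
        out = normalize_plate(make_plate(sizes))
        s = out["size"].to_numpy()
        assert abs(np.median(s[edge]) / np.median(s[~edge]) - 1) < 0.02

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        rows = np.repeat(np.arange(1, 33), 48)
        sizes = 10 * np.exp(0.01 * rows) * rng.lognormal(0, 0.1, 1536)
        once = normalize_plate(make_plate(sizes))
        twice = normalize_plate(once)
        a, b = once["size"].to_numpy(), twice["size"].to_numpy()
        assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-12)) < 1e-9

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(3)
        sizes = 20 * rng.lognormal(0, 0.1, 1536)
        base = normalize_plate(make_plate(sizes))["size"].to_numpy()
        scaled = normalize_plate(make_plate(sizes * c))["size"].to_numpy()
        assert np.allclose(base, scaled, rtol=1e-9)

    def test_zero_sizes_stay_zero_and_missing_stays_missing(self):
        sizes = np.full(1536, 30.0)
        sizes[5] = 0.0
        sizes[6] = np.nan
        out = normalize_plate(make_plate(sizes))
        assert out["size"].iloc[5] == 0.0
        assert np.isnan(out["size"].iloc[6])

    def test_mostly_missing_plate_rejected(self):
        sizes = np.full(1536, np.nan)
        sizes[:700] = 10.0
        with pytest.raises(PlateQCError):
            normalize_plate(make_plate(sizes))


class TestQCFilter:
    def _screen(self, rng, r2_noise=None):
        frames = []
        base = rng.lognormal(0, 0.3, 400)
        for rep in (1, 2):
            vals = base * rng.lognormal(0, 0.05, 400) if r2_noise is None or rep == 1 \
                else rng.lognormal(0, 0.3, 400)
            df = make_plate(vals, replicate=rep)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_identical_replicates_kept_with_r_one(self):
        df = pd.concat([make_plate(np.arange(1, 101, dtype=float), replicate=r)
                        for r in (1, 2)], ignore_index=True)
        kept, report = qc_filter(df)
        assert report["decision"].eq("kept").all()
        assert report["r"].iloc[0] == pytest.approx(1.0)
        assert len(kept) == len(df)

    def test_noise_replicate_flagged(self):
        rng = np.random.default_rng(4)
        df = self._screen(rng, r2_noise=True)
        kept, report = qc_filter(df)
        assert report["decision"].iloc[0] == "excluded"
        assert len(kept) == 0

    def test_single_replicate_pinning_failure_set_missing(self):
        rng = np.random.default_rng(5)
        base = np.linspace(0.5, 2.0, 50)  # shared array-level structure
        df = pd.concat(
            [make_plate(base * rng.lognormal(0, 0.02, 50), replicate=r)
             for r in (1, 2, 3)], ignore_index=True)
        # array a7 failed in replicate 2 only
        idx = df[(df["array"] == "a7") & (df["replicate"] == 2)].index
        df.loc[idx, "size"] = 0.01
        kept, report = qc_filter(df, size_floor=0.05)
        cell = kept[(kept["array"] == "a7") & (kept["replicate"] == 2)]
        assert cell["size"].isna().all()


class TestLinkageMask:
    def test_window_zero_masks_only_query(self):
        pos = {"q": 100, "a1": 100_000, "a2": 4_000_000}
        assert mask_linked("q", ["q", "a1", "a2"], pos, window_bp=0) == {"q"}

    def test_within_window_masked(self):
        pos = {"q": 100_000, "a1": 110_000, "a2": 200_000}
        masked = mask_linked("q", ["a1", "a2"], pos, window_bp=30_000)
        assert masked == {"a1"}

    def test_circular_wraparound(self):
        length = plates.CHROMOSOME_BP
        pos = {"q": 1_000, "a1": length - 5_000}
        assert mask_linked("q", ["a1"], pos, window_bp=30_000) == {"a1"}

    @given(st.integers(min_value=0, max_value=10))
    @settings(max_examples=10, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(60)]
        pos = {g: int(rng.integers(0, plates.CHROMOSOME_BP)) for g in genes}
        query = genes[0]
        masked = mask_linked(query, genes, pos, window_bp=30_000)
        brute = {g for g in genes
                 if g == query or circular_distance(pos[query], pos[g]) <= 30_000}
        assert masked == brute

    def test_missing_position_left_unmasked(self):
        masked = mask_linked("q", ["a1"], {"q": 100}, window_bp=30_000)
        assert masked == {"q"} or masked == set()  # self always masked when present
        assert "a1" not in masked


class TestBuildScreenMatrix:
    def test_replicate_mean_and_sd(self):
        df = pd.concat([make_plate([0.9], replicate=1), make_plate([1.1], replicate=2)],
                       ignore_index=True)
        m = build_screen_matrix(df)
        assert m.w[0, 0] == pytest.approx(1.0)
        assert m.sd[0, 0] == pytest.approx(0.14142, rel=1e-3)
        assert m.n_obs[0, 0] == 2

    def test_all_missing_cell_unmeasured(self):
        df = pd.concat([make_plate([np.nan], replicate=r) for r in (1, 2)],
                       ignore_index=True)
        m = build_screen_matrix(df)
        assert m.n_obs[0, 0] == 0
        assert np.isnan(m.w[0, 0])

    def test_matches_brute_force_groupby(self, small_screens):
        df = small_screens["rich"]
        m = build_screen_matrix(df)
        rng = np.random.default_rng(0)
        for _ in range(50):
            q = rng.choice(m.queries)
            a = rng.choice(m.arrays)
            vals = [rec for rec in df[(df["query"] == q) & (df["array"] == a)]["size"]
                    if not np.isnan(rec)]
            i, j = m.queries.index(q), m.arrays.index(a)
            if vals:
                assert m.w[i, j] == pytest.approx(np.mean(vals))
            else:
                assert m.n_obs[i, j] == 0

    def test_masking_removes_but_never_alters(self, small_screens):
        df = small_screens["rich"]
        m0 = build_screen_matrix(df)
        masked_pairs = {(m0.queries[0], m0.arrays[1]), (m0.queries[2], m0.arrays[3])}
        m1 = build_screen_matrix(df, masked_pairs=masked_pairs)
        assert np.isnan(m1.w[0, 1]) and m1.mask[0, 1]
        keep = ~m1.mask
        assert np.array_equal(np.isnan(m0.w[keep]), np.isnan(m1.w[keep]))
        both = keep & np.isfinite(m0.w)
        assert np.array_equal(m0.w[both], m1.w[both])
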