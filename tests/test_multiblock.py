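"""Block maps, Ward lipid clustering (with a brute-force Lance-Williams
oracle), composite block scores, weighting, and the hierarchical model."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from omniblock.data import ValidationError
from omniblock.latent import compute_vip, fit_plsda
from omniblock.multiblock import (
    BlockMap,
    block_scores,
    cluster_lipids,
    fit_hierarchical,
    load_block_map,
    select_blocks,
    weight_blocks,
    write_block_map,
)

from conftest import make_table


def _labels(n):
    return np.array(["a", "b"] * (n // 2))


class TestBlockMap:
    def test_single_block(self):
        bm = BlockMap({"all": ["f1", "f2", "f3"]})
        assert bm.sizes == {"all": 3}

    def test_duplicate_feature_rejected(self):
        with pytest.raises(ValidationError, match="f1"):
            BlockMap({"a": ["f1"], "b": ["f1"]})

    def test_empty_block_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            BlockMap({"a": []})

    def test_roundtrip_and_unassigned(self, tmp_path, rng):
        table = make_table(np.exp(rng.normal(0, 1, (4, 5))))
        bm = BlockMap({"b1": ["f1", "f3"], "b2": ["f2", "f5"]})
        path = write_block_map(bm, tmp_path / "map.tsv")
        loaded, unassigned = load_block_map(path, table)
        assert loaded.blocks == bm.blocks
        assert unassigned == ["f4"]

    def test_unknown_feature_named(self, tmp_path, rng):
        table = make_table(np.ones((2, 2)))
        (tmp_path / "map.tsv").write_text("zzz\tb1\n")
        with pytest.raises(ValidationError, match="zzz"):
            load_block_map(tmp_path / "map.tsv", table)

    def test_double_mapping_rejected(self, tmp_path):
        table = make_table(np.ones((2, 2)))
        (tmp_path / "map.tsv").write_text("f1\tb1\nf1\tb2\n")
        with pytest.raises(ValidationError, match="twice"):
            load_block_map(tmp_path / "map.tsv", table)


def _brute_ward_heights(X):
    """Lance-Williams recursion for Ward on squared Euclidean distances."""
    n = X.shape[0]
    d = {frozenset((i, j)): v**2 for (i, j), v in zip(
        ((i, j) for i in range(n) for j in range(i + 1, n)), pdist(X))}
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    nxt = n
    while len(active) > 1:
        key = min(d, key=lambda k: (d[k], tuple(sorted(k))))
        i, j = sorted(key)
        heights.append(np.sqrt(d[key]))
        ni, nj = sizes[i], sizes[j]
        for k in active - {i, j}:
            nk = sizes[k]
            dik, djk = d[frozenset((i, k))], d[frozenset((j, k))]
            d[frozenset((nxt, k))] = ((ni + nk) * dik + (nj + nk) * djk
                                      - nk * d[key]) / (ni + nj + nk)
        for k in list(d):
            if i in k or j in k:
                del d[k]
        active -= {i, j}
        active.add(nxt)
        sizes[nxt] = ni + nj
        nxt += 1
    return heights


class TestClusterLipids:
    def test_k_one_single_block(self, rng):
        X = rng.standard_normal((10, 6))
        bm = cluster_lipids(X, [f"l{j}" for j in range(6)], k=1)
        assert len(bm.blocks) == 1
        assert sum(bm.sizes.values()) == 6

    def test_planted_two_groups_recovered(self):
        r = np.random.default_rng(4)
        n = 60
        f1, f2 = r.standard_normal(n), r.standard_normal(n)
        cols = [f1 + 0.2 * r.standard_normal(n) for _ in range(4)]
        cols += [f2 + 0.2 * r.standard_normal(n) for _ in range(4)]
        X = np.column_stack([(c - c.mean()) / c.std() for c in cols])
        ids = [f"l{j}" for j in range(8)]
        bm = cluster_lipids(X, ids, k=2)
        members = sorted(tuple(sorted(v)) for v in bm.blocks.values())
        assert members == [tuple(ids[:4]), tuple(ids[4:])]

    def test_merge_heights_non_decreasing_and_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((10, 7))  # 10 features as points
            Z = linkage(X, method="ward")
            assert (np.diff(Z[:, 2]) >= -1e-12).all()
            np.testing.assert_allclose(
                sorted(Z[:, 2]), sorted(_brute_ward_heights(X)), rtol=1e-8
            )

    def test_k_exceeds_features(self, rng):
        with pytest.raises(ValidationError):
            cluster_lipids(rng.standard_normal((5, 3)), ["a", "b", "c"], k=4)


class TestBlockScores:
    def _scaled(self, rng, n, p):
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)
        X /= X.std(axis=0, ddof=1)
        return X

    def test_single_feature_block_is_scaled_column(self, rng):
        n = 40
        X = self._scaled(rng, n, 3)
        y = _labels(n)
        bm = BlockMap({"solo": ["f1"], "rest": ["f2", "f3"]})
        bs = block_scores(X, y, ["f1", "f2", "f3"], bm)
        corr = np.corrcoef(bs.scores["solo"], X[:, 0])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_identical_columns_not_degenerate(self, rng):
        n = 30
        base = rng.standard_normal(n)
        base = (base - base.mean()) / base.std(ddof=1)
        X = np.c_[base, base]
        bs = block_scores(X, _labels(n), ["f1", "f2"], BlockMap({"b": ["f1", "f2"]}))
        corr = np.corrcoef(bs.scores["b"], base)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)

    def test_unit_variance_contract(self, rng):
        X = self._scaled(rng, 50, 12)
        ids = [f"f{j+1}" for j in range(12)]
        bm = BlockMap({"b1": ids[:5], "b2": ids[5:9], "b3": ids[9:]})
        bs = block_scores(X, _labels(50), ids, bm)
        sds = bs.scores.std(ddof=1)
        np.testing.assert_allclose(sds, 1.0, atol=1e-10)


class TestWeighting:
    def _scores(self, rng, sizes):
        n = 30
        frame = pd.DataFrame(
            {b: rng.standard_normal(n) for b in sizes}, index=range(n)
        )
        from omniblock.multiblock import BlockScoreMatrix
        return BlockScoreMatrix(scores=frame, weights={b: 1.0 for b in sizes},
                                sizes=dict(sizes), models={b: None for b in sizes})

    def test_equal_sizes_identity(self, rng):
        bs = self._scores(rng, {"a": 3, "b": 3})
        w = weight_blocks(bs, "sqrt_size")
        assert all(v == pytest.approx(1.0) for v in w.weights.values())
        pd.testing.assert_frame_equal(w.scores, bs.scores)

    def test_sqrt_size_ratio(self, rng):
        bs = self._scores(rng, {"small": 1, "big": 4})
        w = weight_blocks(bs, "sqrt_size")
        assert w.weights["big"] / w.weights["small"] == pytest.approx(2.0)
        total = sum(v**2 for v in w.weights.values())
        assert total == pytest.approx(2.0)  # sum of squares = number of blocks

    def test_none_identity(self, rng):
        bs = self._scores(rng, {"a": 2, "b": 9})
        w = weight_blocks(bs, "none")
        pd.testing.assert_frame_equal(w.scores, bs.scores)


class TestHierarchical:
    def test_informative_block_top_vip(self):
        r = np.random.default_rng(8)
        n = 80
        y = _labels(n)
        yc = (y == "b").astype(float) - 0.5
        ids, cols, blocks = [], [], {}
        for b in range(10):
            for j in range(3):
                fid = f"b{b}_f{j}"
                ids.append(fid)
                sig = 1.5 * yc if b == 0 else 0.0
                col = sig + r.standard_normal(n)
                cols.append((col - col.mean()) / col.std(ddof=1))
                blocks.setdefault(f"block{b}", []).append(fid)
        X = np.column_stack(cols)
        bs = block_scores(X, y, ids, BlockMap(blocks))
        w = weight_blocks(bs, "sqrt_size")
        model, vips = fit_hierarchical(w, y, A=2)
        assert vips.idxmax() == "block0"
        assert vips["block0"] > 1.0

    def test_copy_blocks_equal_vip(self, rng):
        n = 60
        y = _labels(n)
        base = rng.standard_normal((n, 3))
        base -= base.mean(0)
        base /= base.std(0, ddof=1)
        X = np.c_[base, base]
        ids = ["a1", "a2", "a3", "c1", "c2", "c3"]
        bm = BlockMap({"orig": ids[:3], "copy": ids[3:]})
        bs = block_scores(X, y, ids, bm)
        model, vips = fit_hierarchical(weight_blocks(bs, "none"), y, A=1)
        assert vips["orig"] == pytest.approx(vips["copy"], abs=1e-8)

    def test_single_feature_blocks_reduce_to_flat_plsda(self, rng):
        n, p = 50, 6
        X = rng.standard_normal((n, p))
        X -= X.mean(0)
        X /= X.std(0, ddof=1)
        y = _labels(n)
        ids = [f"f{j+1}" for j in range(p)]
        bm = BlockMap({f"s{j}": [ids[j]] for j in range(p)})
        bs = block_scores(X, y, ids, bm)
        w = weight_blocks(bs, "none")
        model, _ = fit_hierarchical(w, y, A=2)
        # block scores are the (sign-aligned) columns themselves, so the
        # hierarchical model is the flat PLS-DA up to column signs
        flat = fit_plsda(X, y, A=2)
        np.testing.assert_allclose(
            np.abs(model.scores), np.abs(flat.scores), atol=1e-8
        )


class TestSelectBlocks:
    def test_planted_block_selected(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(200 + s)
            n = 194
            y = np.array(["a"] * 97 + ["b"] * 97)
            from omniblock.multiblock import BlockScoreMatrix
            yc = (y == "b").astype(float)
            cols = {"effect": yc - 0.5 + r.standard_normal(n)}  # d = 1
            for j in range(9):
                cols[f"null{j}"] = r.standard_normal(n)
            frame = pd.DataFrame(cols)
            bs = BlockScoreMatrix(scores=frame, weights={b: 1.0 for b in cols},
                                  sizes={b: 3 for b in cols},
                                  models={b: None for b in cols})
            model, vips = fit_hierarchical(bs, y, A=1)
            sel = select_blocks(vips, bs, y)
            hits += bool(sel.loc["effect", "selected"])
        assert hits >= 9

    def test_infinite_threshold_empty(self, rng):
        from omniblock.multiblock import BlockScoreMatrix
        n = 40
        y = _labels(n)
        frame = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        bs = BlockScoreMatrix(scores=frame, weights={"a": 1, "b": 1},
                              sizes={"a": 2, "b": 2}, models={"a": None, "b": None})
        model, vips = fit_hierarchical(bs, y, A=1)
        sel = select_blocks(vips, bs, y, vip_threshold=np.inf)
        assert not sel["selected"].any()

    def test_null_false_selection_rate(self):
        false_sel = 0
        total = 0
        for s in range(40):
            r = np.random.default_rng(3000 + s)
            n = 60
            y = _labels(n)
            from omniblock.multiblock import BlockScoreMatrix
            frame = pd.DataFrame({f"b{j}": r.standard_normal(n) for j in range(8)})
            bs = BlockScoreMatrix(scores=frame, weights={c: 1.0 for c in frame},
                                  sizes={c: 2 for c in frame},
                                  models={c: None for c in frame})
            model, vips = fit_hierarchical(bs, y, A=1)
            sel = select_blocks(vips, bs, y, alpha=0.05)
            false_sel += int(sel["selected"].sum())
            total += len(sel)
        assert false_sel / total <= 0.05
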