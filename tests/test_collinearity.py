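import itertools

import numpy as np
import pandas as pd
import pytest

from wgdkit import collinearity as col
from wgdkit.io_formats import HomologyTable, IntegrityError
from tests.conftest import toy_annotation, toy_homology


# ---------------------------------------------------------------------------
# brute-force chain oracle: explicit enumeration of every monotone chain
# ---------------------------------------------------------------------------

def brute_force_best_score(anchors, gap_limit):
    """Maximum total score over all chains strictly increasing in both
    coordinates with max(da, db) - 1 <= gap_limit, by full enumeration."""
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i][0], anchors[i][1]))
    best = 0.0

    def extend(last_idx, score):
        nonlocal best
        best = max(best, score)
        la, lb, _ = anchors[last_idx]
        for j in order:
            a, b, w = anchors[j]
            if a > la and b > lb and max(a - la, b - lb) - 1 <= gap_limit:
                extend(j, score + w)

    for i in order:
        extend(i, anchors[i][2])
    return best


def test_chain_score_equals_exhaustive_enumeration():
    """Windowed DP chain score matches brute-force enumeration on random
    instances of up to 12 anchors."""
    rng = np.random.default_rng(0)
    for _ in range(60):
        n = int(rng.integers(1, 13))
        anchors = [(int(rng.integers(0, 10)), int(rng.integers(0, 10)),
                    float(rng.integers(1, 20))) for _ in range(n)]
        gap = int(rng.integers(0, 6))
        oa = np.array([a for a, _b, _w in anchors])
        ob = np.array([b for _a, b, _w in anchors])
        w = np.array([s for _a, _b, s in anchors])
        _chain, score = col.best_chain(oa, ob, w, gap_limit=gap)
        assert score == pytest.approx(brute_force_best_score(anchors, gap))


def _grid_annotations(n=60):
    a = toy_annotation("A", [(f"a{i}", "c1", 100 * i + 1, 100 * i + 50) for i in range(n)])
    b = toy_annotation("B", [(f"b{i}", "c1", 100 * i + 1, 100 * i + 50) for i in range(n)])
    return a, b


def test_perfect_diagonal_single_block():
    ann_a, ann_b = _grid_annotations()
    hom = toy_homology([(f"a{i}", f"b{i}", 100) for i in range(6)])
    blocks = col.chain_blocks(hom, ann_a, ann_b)
    assert len(blocks) == 1
    assert blocks[0].n_anchors == 6
    assert blocks[0].orientation == "same"


def test_gap_limit_splits_blocks():
    """A 51-gene gap on one axis exceeds the 50-gene limit and splits the
    signal into two blocks; a 50-gene gap does not."""
    ann_a, ann_b = _grid_annotations(120)
    near = [(f"a{i}", f"b{i}", 100) for i in range(5)]
    far = [(f"a{i + 56}", f"b{i + 56}", 100) for i in range(5)]   # gap = 51
    blocks = col.chain_blocks(toy_homology(near + far), ann_a, ann_b)
    assert len(blocks) == 2
    far_ok = [(f"a{i + 55}", f"b{i + 55}", 100) for i in range(5)]  # gap = 50
    blocks = col.chain_blocks(toy_homology(near + far_ok), ann_a, ann_b)
    assert len(blocks) == 1


def test_inverted_orientation_detected():
    ann_a, ann_b = _grid_annotations(30)
    hom = toy_homology([(f"a{i}", f"b{9 - i}", 100) for i in range(6)])
    blocks = col.chain_blocks(hom, ann_a, ann_b)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"
    orders_b = [p.order_b for p in blocks[0].anchors]
    assert orders_b == sorted(orders_b, reverse=True)


def test_blocks_satisfy_invariants_on_simulated_data(clade_small):
    from wgdkit.pipeline import blocks_and_ks
    blocks, _ = blocks_and_ks(clade_small, "V", "X", with_ks=False)
    assert blocks
    for blk in blocks:
        oa = [p.order_a for p in blk.anchors]
        ob = [p.order_b for p in blk.anchors]
        assert oa == sorted(oa) and len(set(oa)) == len(oa)
        if blk.orientation == "same":
            assert ob == sorted(ob) and len(set(ob)) == len(ob)
        else:
            assert ob == sorted(ob, reverse=True)
        steps = zip(blk.anchors, blk.anchors[1:])
        assert all(max(abs(q.order_a - p.order_a), abs(q.order_b - p.order_b)) - 1 <= 50
                   for p, q in steps)
        assert blk.n_anchors >= 5


def test_unknown_gene_id_raises():
    ann_a, ann_b = _grid_annotations(10)
    hom = toy_homology([("a1", "nope", 100)])
    with pytest.raises(IntegrityError):
        col.chain_blocks(hom, ann_a, ann_b)


def test_family_filter_boundary():
    """Single-linkage families of exactly 30 genes survive; 31 are removed."""
    star30 = [("hub", f"m{i}", 100) for i in range(29)]          # 30 genes
    star31 = [("hub2", f"n{i}", 100) for i in range(30)]         # 31 genes
    other = [("x1", "x2", 100)]
    hom = toy_homology(star30 + star31 + other)
    out = col.filter_families(hom, max_family_size=30)
    genes = set(out.pairs["query"]) | set(out.pairs["subject"])
    assert "hub" in genes and "hub2" not in genes
    assert len(out) == 30
    empty = col.filter_families(HomologyTable(out.pairs.iloc[0:0]), 30)
    assert len(empty) == 0


def test_classify_duplicates_precedence():
    ann = toy_annotation("A", [(f"g{i}", "c2", 100 * i + 1, 100 * i + 50)
                               for i in range(30)])
    # g7-g8 adjacent (tandem), g10-g15 proximal (5 apart), g20-g29 dispersed-ish
    hom = toy_homology([("g7", "g8", 100), ("g10", "g15", 100), ("g1", "g25", 100)])
    classes = col.classify_duplicates(ann, hom, blocks=[])
    assert classes["g7"] == classes["g8"] == "tandem"
    assert classes["g10"] == classes["g15"] == "proximal"
    assert classes["g1"] == classes["g25"] == "dispersed"
    assert classes["g3"] == "singleton"
    # a block anchor wins over adjacency
    from wgdkit.collinearity import AnchorPair, ColinearBlock
    blk = ColinearBlock("A", "A", "c2", "c2",
                        [AnchorPair("g7", "g20", 7, 20, 100)], "same", 100.0)
    classes = col.classify_duplicates(ann, hom, blocks=[blk])
    assert classes["g7"] == "WGD"
    assert classes["g8"] == "tandem"


def test_depth_profile_hand_instance():
    """Depths match a hand enumeration on a 12-gene reference."""
    ref = toy_annotation("R", [(f"r{i}", "c1", 100 * i + 1, 100 * i + 50)
                               for i in range(12)])
    from wgdkit.collinearity import AnchorPair, ColinearBlock

    def blk(lo, hi):
        anchors = [AnchorPair(f"r{lo}", "t", lo, 0, 1.0),
                   AnchorPair(f"r{hi}", "t", hi, 1, 1.0)]
        return ColinearBlock("R", "T", "c1", "tc", anchors, "same", 1.0)

    blocks = [blk(0, 5), blk(3, 8), blk(10, 11)]
    prof = col.depth_profile(ref, blocks)
    expected = [1, 1, 1, 2, 2, 2, 1, 1, 1, 0, 1, 1]
    assert list(prof["depth"]) == expected
    assert prof["histogram"] == {0: 1, 1: 8, 2: 3}
    assert prof["modal_ratio"] == (1, 1)
    assert prof["deleted_fraction"] == pytest.approx(100.0 / 12)


def test_depth_profile_no_blocks():
    ref = toy_annotation("R", [("r0", "c1", 1, 50), ("r1", "c1", 100, 150)])
    prof = col.depth_profile(ref, [])
    assert prof["deleted_fraction"] == 100.0
    assert prof["modal_ratio"] == (1, 0)


def test_hit_colors_best_secondary_rest():
    hom = toy_homology([("q", "s1", 300), ("q", "s2", 250), ("q", "s3", 200)])
    ranked = col.hit_colors(hom.pairs)
    by_subject = dict(zip(ranked["subject"], ranked["color"]))
    assert by_subject == {"s1": "red", "s2": "blue", "s3": "grey"}


def test_dotplot_deterministic_and_empty(tmp_path):
    ann_a, ann_b = _grid_annotations(10)
    hom = toy_homology([(f"a{i}", f"b{i}", 100 + i) for i in range(8)])
    p1, p2 = tmp_path / "d1.svg", tmp_path / "d2.svg"
    col.render_dotplot(hom, ann_a, ann_b, p1)
    col.render_dotplot(hom, ann_a, ann_b, p2)
    assert p1.read_bytes() == p2.read_bytes()
    empty = HomologyTable(hom.pairs.iloc[0:0])
    p3 = tmp_path / "empty.svg"
    col.render_dotplot(empty, ann_a, ann_b, p3)
    assert p3.stat().st_size > 0
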