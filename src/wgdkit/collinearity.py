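"""Colinear (synteny) block inference and duplicate-gene classification.

Blocks are maximal-scoring chains of homologous anchor pairs, strictly
monotone in gene rank on both chromosomes (separately for same and inverted
orientation) with a maximal gap between consecutive anchors of 50 genes.
Chain score is the sum of anchor homology scores; an anchor consumed by a
chain is unavailable to later chains of the same orientation on the same
chromosome pair, while a gene may still appear in several blocks overall
(recursive duplications put one gene in many pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, HomologyTable, IntegrityError

GAP_LIMIT = 50      # maximal number of intervening genes between anchors
MIN_ANCHORS = 5     # smallest reported block
MAX_FAMILY_SIZE = 30


@dataclass
class AnchorPair:
    gene_a: str
    gene_b: str
    order_a: int
    order_b: int
    score: float


@dataclass
class ColinearBlock:
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list
    orientation: str            # 'same' | 'inverted'
    score: float
    ks_median: Optional[float] = None
    event: Optional[str] = None  # event/epoch label attached downstream

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        orders = [a.order_a for a in self.anchors]
        return min(orders), max(orders)

    @property
    def span_b(self) -> tuple[int, int]:
        orders = [a.order_b for a in self.anchors]
        return min(orders), max(orders)


# ---------------------------------------------------------------------------
# family filtering
# ---------------------------------------------------------------------------

def filter_families(homology: HomologyTable, max_family_size: int = MAX_FAMILY_SIZE) -> HomologyTable:
    """Drop every pair touching a single-linkage family of more than
    ``max_family_size`` genes (large families confound colinearity)."""
    df = homology.pairs
    if df.empty:
        return HomologyTable(df.copy())
    genes = pd.unique(pd.concat([df["query"], df["subject"]], ignore_index=True))
    index = {g: i for i, g in enumerate(genes)}
    parent = np.arange(len(genes))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    qi = df["query"].map(index).to_numpy()
    si = df["subject"].map(index).to_numpy()
    for a, b in zip(qi, si):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.fromiter((find(i) for i in range(len(genes))), dtype=np.int64)
    sizes = np.bincount(roots, minlength=len(genes))
    ok = (sizes[roots[qi]] <= max_family_size) & (sizes[roots[si]] <= max_family_size)
    return HomologyTable(df[ok].reset_index(drop=True))


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def best_chain(order_a: np.ndarray, order_b: np.ndarray, score: np.ndarray,
               gap_limit: int = GAP_LIMIT) -> tuple[list[int], float]:
    """Maximum-score chain of anchors, strictly increasing in both orders,
    with ``max(|da|, |db|) - 1 <= gap_limit`` between consecutive anchors.

    Returns (indices into the input arrays in chain order, total score).
    Ties in score are broken towards more anchors, then the smaller starting
    ``order_a`` (resolved deterministically by the scan order below).
    """
    n = len(order_a)
    if n == 0:
        return [], 0.0
    idx = np.lexsort((order_b, order_a))
    a = order_a[idx]
    b = order_b[idx]
    w = score[idx]
    best = w.copy()          # best chain score ending at i
    length = np.ones(n, dtype=np.int64)
    prev = np.full(n, -1, dtype=np.int64)
    lo = 0
    for i in range(n):
        # predecessors must satisfy a[j] >= a[i] - gap_limit - 1
        while a[lo] < a[i] - gap_limit - 1:
            lo += 1
        cj = -1
        cs = 0.0
        cl = 0
        for j in range(lo, i):
            if a[j] >= a[i]:
                break
            db = b[i] - b[j]
            if db <= 0 or db - 1 > gap_limit:
                continue
            if best[j] > cs or (best[j] == cs and length[j] > cl):
                cs = best[j]
                cl = length[j]
                cj = j
        if cj >= 0:
            best[i] += cs
            length[i] += cl
            prev[i] = cj
    end = 0
    for i in range(1, n):
        if best[i] > best[end] or (best[i] == best[end] and length[i] > length[end]):
            end = i
    chain = []
    i = end
    while i >= 0:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    return [int(idx[i]) for i in chain], float(best[end])


def _chain_chromosome_pair(anchors: list, genome_a: str, genome_b: str,
                           chrom_a: str, chrom_b: str, gap_limit: int,
                           min_anchors: int) -> list:
    """Repeatedly extract maximal chains for one chromosome pair and
    orientation until no chain reaches ``min_anchors``."""
    blocks = []
    for orientation in ("same", "inverted"):
        available = list(anchors)
        sign = 1 if orientation == "same" else -1
        while True:
            if len(available) < min_anchors:
                break
            oa = np.array([p.order_a for p in available])
            ob = sign * np.array([p.order_b for p in available])
            sc = np.array([p.score for p in available])
            chain, total = best_chain(oa, ob, sc, gap_limit)
            if len(chain) < min_anchors:
                break
            chosen = [available[i] for i in chain]
            blocks.append(ColinearBlock(genome_a, genome_b, chrom_a, chrom_b,
                                        chosen, orientation, total))
            used = set(chain)
            available = [p for i, p in enumerate(available) if i not in used]
    return blocks


def chain_blocks(homology: HomologyTable, annotation_a: GenomeAnnotation,
                 annotation_b: Optional[GenomeAnnotation] = None,
                 gap_limit: int = GAP_LIMIT, min_anchors: int = MIN_ANCHORS) -> list:
    """Infer colinear blocks between two genomes (or within one genome when
    ``annotation_b`` is omitted or identical).

    For intra-genome runs anchors are canonicalized with the lower-ranked
    gene on the a-side and the self diagonal is excluded.
    """
    intra = annotation_b is None or annotation_b.genome_id == annotation_a.genome_id
    annotation_b = annotation_a if intra else annotation_b

    def pos_map(annotation: GenomeAnnotation) -> dict:
        g = annotation.genes
        return dict(zip(g["gene_id"], zip(g["chromosome"], g["order_index"])))

    apos = pos_map(annotation_a)
    bpos = pos_map(annotation_b)

    df = homology.pairs
    per_pair: dict[tuple[str, str], list] = {}
    for g1, g2, score in zip(df["query"], df["subject"], df["alignment_score"]):
        if g1 in apos and g2 in bpos:
            ga, gb = g1, g2
        elif g2 in apos and g1 in bpos:
            ga, gb = g2, g1
        else:
            raise IntegrityError(f"homology pair ({g1}, {g2}) has gene ids "
                                 f"unknown to the annotations")
        ca, oa = apos[ga]
        cb, ob = bpos[gb]
        if intra:
            if ga == gb:
                continue
            if (cb, ob) < (ca, oa):
                ca, oa, cb, ob = cb, ob, ca, oa
                ga, gb = gb, ga
        per_pair.setdefault((ca, cb), []).append(AnchorPair(ga, gb, oa, ob, float(score)))

    blocks: list = []
    for (ca, cb) in sorted(per_pair):
        blocks.extend(_chain_chromosome_pair(per_pair[(ca, cb)], annotation_a.genome_id,
                                             annotation_b.genome_id, ca, cb,
                                             gap_limit, min_anchors))
    return blocks


# ---------------------------------------------------------------------------
# duplicate classification
# ---------------------------------------------------------------------------

def classify_duplicates(annotation: GenomeAnnotation, homology: HomologyTable,
                        blocks: Sequence[ColinearBlock],
                        proximal_window: int = 10) -> pd.Series:
    """Assign every gene one origin class with precedence
    WGD > tandem > proximal > dispersed > singleton."""
    g = annotation.genes
    pos = dict(zip(g["gene_id"], zip(g["chromosome"], g["order_index"])))
    wgd = set()
    for blk in blocks:
        if blk.genome_a == blk.genome_b == annotation.genome_id:
            for p in blk.anchors:
                wgd.add(p.gene_a)
                wgd.add(p.gene_b)
    tandem = set()
    proximal = set()
    homolog = set()
    for g1, g2 in zip(homology.pairs["query"], homology.pairs["subject"]):
        if g1 not in pos or g2 not in pos:
            continue
        homolog.add(g1)
        homolog.add(g2)
        c1, o1 = pos[g1]
        c2, o2 = pos[g2]
        if c1 == c2:
            d = abs(int(o1) - int(o2))
            if d == 1:
                tandem.update((g1, g2))
            elif d <= proximal_window:
                proximal.update((g1, g2))

    def classify(g: str) -> str:
        if g in wgd:
            return "WGD"
        if g in tandem:
            return "tandem"
        if g in proximal:
            return "proximal"
        if g in homolog:
            return "dispersed"
        return "singleton"

    genes = annotation.genes["gene_id"]
    return pd.Series([classify(g) for g in genes], index=genes, name="duplicate_class")


# ---------------------------------------------------------------------------
# orthology depth
# ---------------------------------------------------------------------------

def depth_profile(reference: GenomeAnnotation, blocks: Sequence[ColinearBlock]) -> dict:
    """Per-reference-gene copy depth from target block coverage.

    Depth of a reference gene counts the distinct target block regions whose
    reference-side anchor span covers the gene's order_index (region
    counting: a gene locally deleted in the target but inside a covered
    region still counts as covered).  Returns a dict with ``depth`` (Series
    indexed by gene_id), ``histogram``, ``modal_ratio`` and
    ``deleted_fraction`` (percent of reference genes at depth 0).
    """
    genes = reference.genes
    depth = np.zeros(len(genes), dtype=np.int64)
    by_chrom = {c: sub for c, sub in genes.groupby("chromosome", sort=False)}
    for blk in blocks:
        if blk.genome_a != reference.genome_id:
            continue
        sub = by_chrom.get(blk.chrom_a)
        if sub is None:
            continue
        lo, hi = blk.span_a
        sel = sub.index[(sub["order_index"] >= lo) & (sub["order_index"] <= hi)]
        depth[sel] += 1
    depth_s = pd.Series(depth, index=genes["gene_id"], name="depth")
    hist = depth_s.value_counts().sort_index().to_dict()
    covered = depth_s[depth_s >= 1]
    mode = int(covered.mode().iloc[0]) if len(covered) else 0
    return {
        "depth": depth_s,
        "histogram": hist,
        "modal_ratio": (1, mode),
        "deleted_fraction": float(100.0 * (depth_s == 0).mean()),
    }


# ---------------------------------------------------------------------------
# dot plots
# ---------------------------------------------------------------------------

def hit_colors(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rank hits per query by score: best red, second-best blue, rest grey."""
    if pairs.empty:
        return pairs.assign(color=pd.Series(dtype=str))
    df = pairs.sort_values(["query", "alignment_score", "subject"],
                           ascending=[True, False, True], kind="mergesort").copy()
    rank = df.groupby("query", sort=False).cumcount()
    df["color"] = np.where(rank == 0, "red", np.where(rank == 1, "blue", "grey"))
    return df


def render_dotplot(homology: HomologyTable, annotation_a: GenomeAnnotation,
                   annotation_b: GenomeAnnotation, out_path,
                   blocks: Optional[Sequence[ColinearBlock]] = None) -> None:
    """Render a homology dot plot (SVG): best hit red, second-best blue,
    remaining hits grey; chromosomes laid out in annotation order, axes in Mb;
    optional block outlines. Output is byte-deterministic."""
    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "wgdkit"
    import matplotlib.pyplot as plt

    def layout(annotation: GenomeAnnotation):
        offsets = {}
        total = 0
        for chrom, sub in annotation.genes.groupby("chromosome", sort=False):
            offsets[chrom] = total
            total += int(sub["end"].max())
        return offsets, total

    off_a, tot_a = layout(annotation_a)
    off_b, tot_b = layout(annotation_b)
    amap = annotation_a.genes.set_index("gene_id")
    bmap = annotation_b.genes.set_index("gene_id")

    ranked = hit_colors(homology.pairs)
    colors = []
    xs, ys = [], []
    for row in ranked.itertuples():
        if row.query not in amap.index or row.subject not in bmap.index:
            continue
        ga = amap.loc[row.query]
        gb = bmap.loc[row.subject]
        xs.append((off_a[ga["chromosome"]] + (ga["start"] + ga["end"]) / 2) / 1e6)
        ys.append((off_b[gb["chromosome"]] + (gb["start"] + gb["end"]) / 2) / 1e6)
        colors.append(row.color)

    fig, ax = plt.subplots(figsize=(6, 6))
    if xs:
        ax.scatter(xs, ys, s=2, c=colors, linewidths=0)
    for chrom, off in off_a.items():
        ax.axvline(off / 1e6, color="0.85", lw=0.5)
    for chrom, off in off_b.items():
        ax.axhline(off / 1e6, color="0.85", lw=0.5)
    if blocks:
        import matplotlib.cm as cm
        ks_vals = [b.ks_median for b in blocks if b.ks_median is not None]
        vmax = max(ks_vals) if ks_vals else 1.0
        for blk in blocks:
            sub_a = annotation_a.genes[annotation_a.genes["chromosome"] == blk.chrom_a]
            sub_b = annotation_b.genes[annotation_b.genes["chromosome"] == blk.chrom_b]
            lo_a, hi_a = blk.span_a
            lo_b, hi_b = blk.span_b
            xa = (off_a[blk.chrom_a] + sub_a.iloc[lo_a]["start"]) / 1e6
            xb = (off_a[blk.chrom_a] + sub_a.iloc[hi_a]["end"]) / 1e6
            ya = (off_b[blk.chrom_b] + sub_b.iloc[lo_b]["start"]) / 1e6
            yb = (off_b[blk.chrom_b] + sub_b.iloc[hi_b]["end"]) / 1e6
            color = cm.viridis((blk.ks_median or 0.0) / vmax) if vmax else "black"
            ax.plot([xa, xb, xb, xa, xa], [ya, ya, yb, yb, ya], color=color, lw=0.6)
    ax.set_xlim(0, max(tot_a / 1e6, 1e-3))
    ax.set_ylim(0, max(tot_b / 1e6, 1e-3))
    ax.set_xlabel(f"{annotation_a.genome_id} (Mb)")
    ax.set_ylabel(f"{annotation_b.genome_id} (Mb)")
    fig.savefig(out_path, format="svg", metadata={"Date": None})
    plt.close(fig)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def blocks_to_frame(blocks: Sequence[ColinearBlock]) -> pd.DataFrame:
    rows = []
    for i, blk in enumerate(blocks):
        rows.append({
            "block_id": i,
            "genome_a": blk.genome_a, "genome_b": blk.genome_b,
            "chrom_a": blk.chrom_a, "chrom_b": blk.chrom_b,
            "orientation": blk.orientation, "n_anchors": blk.n_anchors,
            "score": blk.score, "ks_median": blk.ks_median, "event": blk.event,
            "anchors": ";".join(f"{p.gene_a},{p.gene_b},{p.order_a},{p.order_b},{p.score:.6g}"
                                 for p in blk.anchors),
        })
    return pd.DataFrame(rows, columns=["block_id", "genome_a", "genome_b", "chrom_a",
                                       "chrom_b", "orientation", "n_anchors", "score",
                                       "ks_median", "event", "anchors"])


def blocks_from_frame(df: pd.DataFrame) -> list:
    blocks = []
    for row in df.itertuples():
        anchors = []
        if isinstance(row.anchors, str) and row.anchors:
            for part in row.anchors.split(";"):
                ga, gb, oa, ob, sc = part.split(",")
                anchors.append(AnchorPair(ga, gb, int(oa), int(ob), float(sc)))
        ks = None if pd.isna(row.ks_median) else float(row.ks_median)
        ev = None if (not isinstance(row.event, str) and pd.isna(row.event)) else row.event
        blocks.append(ColinearBlock(row.genome_a, row.genome_b, row.chrom_a, row.chrom_b,
                                    anchors, row.orientation, float(row.score), ks, ev))
    return blocks
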