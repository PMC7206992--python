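"""Reference-anchored, event-structured colinear gene tables.

Rows are the reference genome's genes in genome order.  The reference
contributes ``m_ref`` columns (the gene plus its ``m_ref - 1`` intra-genome
paralogs from an older shared polyploidy), and every other genome
contributes ``m_g`` orthologous columns per reference column — e.g. with a
triplicated reference and genomes of multiplicity 1, 3, 4 and 4 the table
has 3 * (1 + 12) = 39 columns.  A cell holds the colinear gene occupying
the expected location, or ``.`` when it was lost or translocated.

Orthologous blocks of one genome are partitioned into ``m_g`` column layers
by interval scheduling on the reference axis (blocks in one layer never
overlap); layers are then grouped into the genome's event hierarchy (e.g.
two A-beta groups of two A-alpha siblings) using the synonymous divergence
between co-row genes of different layers: the layer pairing with the lowest
within-pair Ks corresponds to the youngest shared event.

Loss epochs are read off each row by Dollo parsimony on the hierarchy tree:
every maximal all-missing subtree is one loss event, dated to the epoch of
the edge above the subtree root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .collinearity import ColinearBlock
from .io_formats import MISSING, GenomeAnnotation


class OverflowLayerError(RuntimeError):
    """More mutually overlapping block layers than the schema's multiplicity."""


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# schema & hierarchy
# ---------------------------------------------------------------------------

@dataclass
class HierNode:
    """Node of the per-genome column hierarchy.

    Leaves carry a slot index; internal nodes carry the duplication event
    that separates their children.
    """
    event: Optional[str] = None
    slot: Optional[int] = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def slots(self) -> list[int]:
        if self.is_leaf:
            return [self.slot]
        out = []
        for c in self.children:
            out.extend(c.slots())
        return out


def hierarchy(spec) -> HierNode:
    """Build a HierNode from a nested spec: an int is a leaf slot, a tuple
    ``(event, child, child, ...)`` an internal node."""
    if isinstance(spec, int):
        return HierNode(slot=spec)
    event, *children = spec
    node = HierNode(event=event, children=[hierarchy(c) for c in children])
    if len(node.children) < 2:
        raise SchemaError("internal hierarchy node needs >= 2 children")
    return node


@dataclass
class GenomeSpec:
    genome: str
    multiplicity: int
    hierarchy: HierNode

    def __post_init__(self) -> None:
        slots = sorted(self.hierarchy.slots())
        if slots != list(range(self.multiplicity)):
            raise SchemaError(f"{self.genome}: hierarchy slots {slots} do not cover "
                              f"multiplicity {self.multiplicity}")


@dataclass
class TableSchema:
    reference: str
    m_ref: int
    genomes: list

    @property
    def total_columns(self) -> int:
        return self.m_ref * (1 + sum(g.multiplicity for g in self.genomes))


def paper_schema() -> TableSchema:
    """The five-genome configuration: triplicated reference V, coffee-like C
    (1 column), lettuce-like L (3), carrot-like D (4), coriander-like X (4):
    39 columns in total."""
    return TableSchema(reference="V", m_ref=3, genomes=[
        GenomeSpec("C", 1, hierarchy(0)),
        GenomeSpec("L", 3, hierarchy(("L-wgt", 0, 1, 2))),
        GenomeSpec("D", 4, hierarchy(("A-beta", ("A-alpha", 0, 1), ("A-alpha", 2, 3)))),
        GenomeSpec("X", 4, hierarchy(("A-beta", ("A-alpha", 0, 1), ("A-alpha", 2, 3)))),
    ])


# ---------------------------------------------------------------------------
# block labelling
# ---------------------------------------------------------------------------

def label_blocks_from_homology(blocks: Sequence[ColinearBlock], homology) -> None:
    """Attach to each block the majority divergence-event label of its
    anchors (available on simulated homology tables)."""
    df = homology.pairs
    lut = {}
    for q, s, ev in zip(df["query"], df["subject"], df["event"]):
        lut[(q, s)] = ev
        lut[(s, q)] = ev
    for blk in blocks:
        labels = [lut[(a.gene_a, a.gene_b)] for a in blk.anchors if (a.gene_a, a.gene_b) in lut]
        if labels:
            blk.event = max(set(labels), key=labels.count)


def label_blocks_by_ks(blocks: Sequence[ColinearBlock], boundaries: Sequence[float],
                       events: Sequence[str]) -> None:
    """Assign each block an event label by binning its Ks median:
    ``len(boundaries) + 1 == len(events)``, events ordered by ascending Ks."""
    if len(events) != len(boundaries) + 1:
        raise ValueError("need one more event than boundaries")
    for blk in blocks:
        if blk.ks_median is None:
            blk.event = None
            continue
        i = int(np.searchsorted(boundaries, blk.ks_median))
        blk.event = events[i]


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    schema: TableSchema
    reference_genes: pd.DataFrame        # gene_id, chromosome, order_index
    core: dict                           # genome -> list of m_g dicts {ref_gene: target_gene}
    paralogs: list                       # m_ref - 1 dicts {ref_gene: paralog_gene}
    coverage: dict                       # genome -> slot -> list[(chrom, lo, hi)]

    @property
    def n_columns(self) -> int:
        return self.schema.total_columns

    def row_presence(self, genome: str) -> np.ndarray:
        """Boolean matrix rows x slots for one genome's core columns."""
        spec = next(g for g in self.schema.genomes if g.genome == genome)
        cells = self.core[genome]
        out = np.zeros((len(self.reference_genes), spec.multiplicity), dtype=bool)
        for s in range(spec.multiplicity):
            col = cells[s]
            out[:, s] = [gid in col for gid in self.reference_genes["gene_id"]]
        return out

    def to_frame(self) -> pd.DataFrame:
        """The full table: reference paralog groups side by side."""
        ref_ids = list(self.reference_genes["gene_id"])
        groups = [dict(zip(ref_ids, ref_ids))] + self.paralogs
        data = {}
        for p, ref_map in enumerate(groups):
            prefix = self.schema.reference if p == 0 else f"{self.schema.reference}.p{p}"
            data[prefix] = [ref_map.get(g) for g in ref_ids]
            for spec in self.schema.genomes:
                for s in range(spec.multiplicity):
                    col = self.core[spec.genome][s]
                    data[f"{prefix}|{spec.genome}.{s}"] = [
                        col.get(ref_map.get(g)) if ref_map.get(g) is not None else None
                        for g in ref_ids]
        return pd.DataFrame(data, index=pd.Index(ref_ids, name="row"))


def _schedule_layers(blocks: Sequence[ColinearBlock], m: int, genome: str) -> list[list]:
    """Greedy interval scheduling of blocks into m non-overlapping layers per
    reference chromosome (longest blocks first).

    A block is preferentially placed in a layer already holding blocks from
    the same target chromosome: fragments of one chromosome descend from one
    subgenome, so chromosome continuity keeps layers subgenome-pure.
    """
    layers: list[list] = [[] for _ in range(m)]
    occupied: list[dict] = [dict() for _ in range(m)]   # layer -> chrom -> [(lo, hi)]
    layer_chroms: list[set] = [set() for _ in range(m)]
    for blk in sorted(blocks, key=lambda b: (-b.n_anchors, b.chrom_a, b.span_a)):
        lo, hi = blk.span_a
        free = []
        for li in range(m):
            ivs = occupied[li].setdefault(blk.chrom_a, [])
            if all(hi < a or lo > b for a, b in ivs):
                free.append(li)
        if not free:
            raise OverflowLayerError(
                f"{genome}: more than {m} overlapping block layers at "
                f"{blk.chrom_a}:{lo}-{hi} (mis-grouped events?)")
        same = [li for li in free if blk.chrom_b in layer_chroms[li]]
        li = same[0] if same else free[0]
        occupied[li][blk.chrom_a].append((lo, hi))
        layer_chroms[li].add(blk.chrom_b)
        layers[li].append(blk)
    return layers


def _pair_layers(layers: list, pair_ks: Optional[Mapping], rows: Sequence[str],
                 cells: list) -> list[int]:
    """Order 4 layers so that slots (0,1) and (2,3) are the youngest-event
    sibling pairs, using the median divergence between co-row genes."""
    if pair_ks is None:
        return list(range(len(layers)))
    m = len(layers)
    med = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i + 1, m):
            vals = []
            for r in rows:
                a = cells[i].get(r)
                b = cells[j].get(r)
                if a is not None and b is not None:
                    v = pair_ks.get((a, b), pair_ks.get((b, a)))
                    if v is not None:
                        vals.append(v)
            if vals:
                med[i, j] = med[j, i] = float(np.median(vals))
    best = None
    best_cost = np.inf
    for pairing in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        cost = 0.0
        ok = True
        for a, b in pairing:
            if np.isnan(med[a, b]):
                ok = False
                break
            cost += med[a, b]
        if ok and cost < best_cost:
            best_cost = cost
            best = pairing
    if best is None:
        return list(range(m))
    return [best[0][0], best[0][1], best[1][0], best[1][1]]


def build_event_table(schema: TableSchema, reference: GenomeAnnotation,
                      blocks_by_genome: Mapping[str, Sequence[ColinearBlock]],
                      reference_self_blocks: Sequence[ColinearBlock] = (),
                      ortholog_label: str = "speciation",
                      reference_paralog_label: Optional[str] = None,
                      pair_ks: Optional[Mapping] = None) -> EventTable:
    """Assemble the event table.

    ``blocks_by_genome[g]`` are reference-vs-g blocks; only those labelled
    ``ortholog_label`` (or unlabelled) enter the ortholog columns.
    ``reference_self_blocks`` fill the reference paralog columns (filtered to
    ``reference_paralog_label`` when given).  ``pair_ks`` maps target-genome
    gene pairs to a divergence value used to group 4-fold layers into
    sibling pairs.
    """
    ref_genes = reference.genes[["gene_id", "chromosome", "order_index"]].reset_index(drop=True)
    ref_ids = list(ref_genes["gene_id"])

    core: dict = {}
    coverage: dict = {}
    for spec in schema.genomes:
        blocks = [b for b in blocks_by_genome.get(spec.genome, ())
                  if b.event in (None, ortholog_label)]
        per_chrom: dict[str, list] = {}
        for b in blocks:
            per_chrom.setdefault(b.chrom_a, []).append(b)
        cells: list[dict] = [dict() for _ in range(spec.multiplicity)]
        cover: dict[int, list] = {s: [] for s in range(spec.multiplicity)}
        order_to_gene = {}
        for chrom, sub in ref_genes.groupby("chromosome", sort=False):
            order_to_gene[chrom] = dict(zip(sub["order_index"], sub["gene_id"]))
        for chrom in sorted(per_chrom):
            layers = _schedule_layers(per_chrom[chrom], spec.multiplicity, spec.genome)
            chrom_cells: list[dict] = [dict() for _ in range(spec.multiplicity)]
            for li, layer in enumerate(layers):
                for blk in layer:
                    lo, hi = blk.span_a
                    cover_entry = (chrom, lo, hi)
                    for p in sorted(blk.anchors, key=lambda a: -a.score):
                        rg = order_to_gene[chrom].get(p.order_a)
                        if rg is not None and rg not in chrom_cells[li]:
                            chrom_cells[li][rg] = p.gene_b
                    cover[li].append(cover_entry)
            if spec.multiplicity == 4 and not spec.hierarchy.is_leaf:
                rows_here = [order_to_gene[chrom][o] for o in sorted(order_to_gene[chrom])]
                perm = _pair_layers(layers, pair_ks, rows_here, chrom_cells)
                chrom_cells = [chrom_cells[i] for i in perm]
                reordered = {s: [] for s in range(spec.multiplicity)}
                for new_s, old_s in enumerate(perm):
                    reordered[new_s] = [iv for iv in cover[old_s] if iv[0] == chrom]
                for s in range(spec.multiplicity):
                    cover[s] = [iv for iv in cover[s] if iv[0] != chrom] + reordered[s]
            for s in range(spec.multiplicity):
                cells[s].update(chrom_cells[s])
        core[spec.genome] = cells
        coverage[spec.genome] = cover

    # reference paralog columns from intra-reference blocks
    paralogs: list[dict] = [dict() for _ in range(max(schema.m_ref - 1, 0))]
    if schema.m_ref > 1:
        directed = []
        for b in reference_self_blocks:
            if reference_paralog_label is not None and b.event not in (None, reference_paralog_label):
                continue
            directed.append(b)
        # partner lookup per reference gene, best-scoring first
        partners: dict[str, list] = {}
        for b in directed:
            for p in b.anchors:
                partners.setdefault(p.gene_a, []).append((p.score, p.gene_b))
                partners.setdefault(p.gene_b, []).append((p.score, p.gene_a))
        for g in ref_ids:
            best = sorted(partners.get(g, []), key=lambda t: (-t[0], t[1]))
            seen = set()
            uniq = []
            for _sc, q in best:
                if q not in seen:
                    seen.add(q)
                    uniq.append(q)
            for i in range(schema.m_ref - 1):
                if i < len(uniq):
                    paralogs[i][g] = uniq[i]

    return EventTable(schema=schema, reference_genes=ref_genes, core=core,
                      paralogs=paralogs, coverage=coverage)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def retention_stats(table: EventTable) -> pd.DataFrame:
    """Per-genome distribution of retained orthologous copies per reference
    gene (depth histogram as percentages plus deleted fraction)."""
    rows = []
    for spec in table.schema.genomes:
        presence = table.row_presence(spec.genome)
        depth = presence.sum(axis=1)
        n = len(depth)
        for d in range(spec.multiplicity + 1):
            rows.append({"genome": spec.genome, "depth": d,
                         "count": int((depth == d).sum()),
                         "percent": 100.0 * float((depth == d).mean())})
    df = pd.DataFrame(rows)
    return df


def deleted_fraction(table: EventTable, genome: str) -> float:
    presence = table.row_presence(genome)
    return float(100.0 * (presence.sum(axis=1) == 0).mean())


def classify_loss_epochs(table: EventTable, genome: str) -> dict:
    """Dollo-parsimony loss events per epoch for one genome.

    Returns ``{"events": {epoch: count}, "missing_cells": {epoch: count},
    "per_row": list}`` where each maximal all-missing subtree of the column
    hierarchy counts one loss event in the epoch of its root edge, and
    ``missing_cells`` attributes every missing cell to the epoch of the loss
    event that removed it.
    """
    spec = next(g for g in table.schema.genomes if g.genome == genome)
    presence = table.row_presence(genome)

    def epoch_label(node: HierNode, parent: Optional[HierNode]) -> str:
        if parent is None:
            return (f"before_{node.event}" if node.event else "after_speciation")
        if node.is_leaf:
            return f"after_{parent.event}"
        return f"between_{parent.event}_and_{node.event}"

    events: dict[str, int] = {}
    cells: dict[str, int] = {}
    per_row = []

    def prune(node: HierNode, parent: Optional[HierNode], row: np.ndarray, out: list):
        slots = node.slots()
        if not row[slots].any():
            label = epoch_label(node, parent)
            out.append((label, len(slots)))
            return
        for c in node.children:
            prune(c, node, row, out)

    for r in range(presence.shape[0]):
        out: list = []
        prune(spec.hierarchy, None, presence[r], out)
        per_row.append(out)
        for label, width in out:
            events[label] = events.get(label, 0) + 1
            cells[label] = cells.get(label, 0) + width
    return {"events": events, "missing_cells": cells, "per_row": per_row}


# ---------------------------------------------------------------------------
# serialization & display
# ---------------------------------------------------------------------------

def table_to_tsv(table: EventTable, path) -> None:
    df = table.to_frame()
    df.to_csv(path, sep="\t", na_rep=MISSING)


def render_homology_circles(table: EventTable, out_path) -> None:
    """Concentric-circle view: one ring per table column, a tick per filled
    cell, coloured by the reference chromosome of the row."""
    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "wgdkit"
    import matplotlib.pyplot as plt

    df = table.to_frame()
    n_rows = len(df)
    n_cols = df.shape[1]
    chroms = list(dict.fromkeys(table.reference_genes["chromosome"]))
    cmap = plt.get_cmap("tab20")
    chrom_color = {c: cmap(i % 20) for i, c in enumerate(chroms)}
    fig, ax = plt.subplots(figsize=(8, 8), subplot_kw={"projection": "polar"})
    theta = np.linspace(0, 2 * np.pi, max(n_rows, 1), endpoint=False)
    row_chrom = list(table.reference_genes["chromosome"])
    for ci, col in enumerate(df.columns):
        radius = 1.0 + ci * 0.12
        filled = df[col].notna().to_numpy()
        if n_rows and filled.any():
            colors = [chrom_color[row_chrom[i]] for i in np.flatnonzero(filled)]
            ax.scatter(theta[filled], np.full(int(filled.sum()), radius), s=1,
                       c=colors, marker="|", linewidths=0.4)
    ax.set_yticks([])
    ax.set_xticks([])
    ax.set_title(f"{table.n_columns} homology circles ({table.schema.reference} reference)")
    fig.savefig(out_path, format="svg", metadata={"Date": None})
    plt.close(fig)
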