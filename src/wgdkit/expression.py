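"""Expression divergence between duplicated copies and retention classes.

Works on replicate-averaged FPKM with a +1 pseudocount before log2.  A
duplicate pair is called diverged in a condition when its absolute log2
ratio reaches the fold threshold (default 2-fold), and diverged overall when
that happens in at least one condition.  Subgenome dominance is an exact
binomial test of which copy is higher among diverged pairs, per duplicated
region pair.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .event_table import EventTable
from .io_formats import ExpressionMatrix


class InsufficientDataError(ValueError):
    pass


def _sibling_leaf_pairs(node):
    out = []
    if node.is_leaf:
        return out
    if all(c.is_leaf for c in node.children):
        slots = [c.slot for c in node.children]
        for i in range(len(slots)):
            for j in range(i + 1, len(slots)):
                out.append((node.event, slots[i], slots[j]))
    else:
        # cross-group pairs separated by this (older) event
        left = node.children[0].slots() if node.children else []
        for i, ci in enumerate(node.children):
            for cj in node.children[i + 1:]:
                for a in ci.slots():
                    for b in cj.slots():
                        out.append((node.event, a, b))
        for c in node.children:
            out.extend(_sibling_leaf_pairs(c))
    return out


def pair_divergence(table: EventTable, expression: ExpressionMatrix, genome: str,
                    fold_threshold: float = 2.0) -> dict:
    """Expression divergence of duplicate pairs from the event table.

    Returns ``{"pairs": DataFrame, "per_event": DataFrame}``: one row per
    duplicate pair (sibling columns, both copies present and measured) with
    per-condition log2 ratios and divergence flags, and the fraction of
    diverged pairs per event.
    """
    means = expression.condition_means()
    conditions = list(means.columns)
    if not conditions:
        raise ValueError("expression matrix has no conditions")
    spec = next(g for g in table.schema.genomes if g.genome == genome)
    presence_cells = table.core[genome]
    log_thr = np.log2(fold_threshold)
    rows = []
    ref_ids = list(table.reference_genes["gene_id"])
    chrom_of = dict(zip(table.reference_genes["gene_id"], table.reference_genes["chromosome"]))
    for event, sa, sb in _sibling_leaf_pairs(spec.hierarchy):
        col_a = presence_cells[sa]
        col_b = presence_cells[sb]
        for rg in ref_ids:
            a = col_a.get(rg)
            b = col_b.get(rg)
            if a is None or b is None or a not in means.index or b not in means.index:
                continue
            va = means.loc[a, conditions].to_numpy(dtype=float)
            vb = means.loc[b, conditions].to_numpy(dtype=float)
            ratios = np.log2((va + 1.0) / (vb + 1.0))
            div = np.abs(ratios) >= log_thr
            rows.append({
                "event": event, "slot_a": sa, "slot_b": sb, "ref_gene": rg,
                "region": f"{chrom_of[rg]}:{sa}-{sb}",
                "gene_a": a, "gene_b": b,
                **{f"log2_{c}": r for c, r in zip(conditions, ratios)},
                "n_diverged_conditions": int(div.sum()),
                "diverged": bool(div.any()),
                "higher_copy": ("a" if ratios[np.argmax(np.abs(ratios))] > 0 else "b"),
            })
    pairs = pd.DataFrame(rows)
    if len(pairs):
        per_event = (pairs.groupby("event")["diverged"]
                     .agg(n_pairs="size", n_diverged="sum", fraction="mean").reset_index())
        per_event["fraction"] *= 100.0
    else:
        per_event = pd.DataFrame(columns=["event", "n_pairs", "n_diverged", "fraction"])
    return {"pairs": pairs, "per_event": per_event}


def dominance_test(pairs: pd.DataFrame, min_pairs: int = 10) -> pd.DataFrame:
    """Exact binomial test of higher-copy side among diverged pairs, per
    duplicated region pair (region = reference chromosome x sibling slots).

    Region pairs with fewer than ``min_pairs`` diverged pairs are skipped
    (flagged in the output).
    """
    rows = []
    div = pairs[pairs["diverged"]]
    for region, sub in div.groupby("region", sort=True):
        n = len(sub)
        n_a = int((sub["higher_copy"] == "a").sum())
        if n < min_pairs:
            rows.append({"region": region, "n_diverged": n, "n_first_higher": n_a,
                         "fraction_first_higher": n_a / n if n else float("nan"),
                         "p_value": float("nan"), "skipped": True})
            continue
        p = float(stats.binomtest(n_a, n, 0.5).pvalue)
        rows.append({"region": region, "n_diverged": n, "n_first_higher": n_a,
                     "fraction_first_higher": n_a / n, "p_value": p, "skipped": False})
    return pd.DataFrame(rows)


def one_vs_two_copy_test(table: EventTable, expression: ExpressionMatrix, genome: str,
                         event: Optional[str] = None, min_group: int = 3) -> pd.DataFrame:
    """Welch t-test per condition: log2(FPKM+1) of genes whose duplicate was
    lost (one-copy group) against the per-pair mean of pairs retaining both
    copies."""
    means = expression.condition_means()
    conditions = list(means.columns)
    spec = next(g for g in table.schema.genomes if g.genome == genome)
    cells = table.core[genome]
    def leaf_pairs(node):
        out = []
        if node.is_leaf:
            return out
        if all(c.is_leaf for c in node.children):
            slots = [c.slot for c in node.children]
            for i in range(len(slots)):
                for j in range(i + 1, len(slots)):
                    out.append((node.event, slots[i], slots[j]))
        for c in node.children:
            out.extend(leaf_pairs(c))
        return out

    one_copy: list[str] = []
    two_copy: list[tuple[str, str]] = []
    for ev, sa, sb in leaf_pairs(spec.hierarchy):
        if event is not None and ev != event:
            continue
        for rg in table.reference_genes["gene_id"]:
            a = cells[sa].get(rg)
            b = cells[sb].get(rg)
            if a is not None and b is not None:
                two_copy.append((a, b))
            elif a is not None:
                one_copy.append(a)
            elif b is not None:
                one_copy.append(b)
    one_copy = [g for g in one_copy if g in means.index]
    two_copy = [(a, b) for a, b in two_copy if a in means.index and b in means.index]
    if len(one_copy) < min_group or len(two_copy) < min_group:
        raise InsufficientDataError(
            f"groups too small: {len(one_copy)} one-copy, {len(two_copy)} two-copy")
    rows = []
    for cond in conditions:
        x1 = np.log2(means.loc[one_copy, cond].to_numpy(dtype=float) + 1.0)
        x2 = np.array([
            (np.log2(means.loc[a, cond] + 1.0) + np.log2(means.loc[b, cond] + 1.0)) / 2.0
            for a, b in two_copy])
        t, p = stats.ttest_ind(x1, x2, equal_var=False)
        rows.append({"condition": cond, "n_one_copy": len(x1), "n_two_copy": len(x2),
                     "mean_one_copy": float(x1.mean()), "mean_two_copy": float(x2.mean()),
                     "t": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)
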