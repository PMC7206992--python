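"""Gene-loss run lengths, the geometric deletion model, and retention
profiles along duplicated regions.

Post-polyploidy gene removal proceeds by segmental deletions, so the lengths
of maximal runs of consecutively missing genes inside block-covered regions
should follow (at large) a geometric distribution on support {1, 2, ...}.
The MLE of its parameter is the reciprocal mean run length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_table import EventTable


class InsufficientRunsError(ValueError):
    pass


@dataclass
class DeletionRuns:
    """Maximal missing-gene run lengths per column, along reference order.

    ``lengths`` excludes runs truncated by a covered-interval boundary;
    ``truncated`` holds those separately.
    """
    lengths: list
    truncated: list

    def all_lengths(self) -> list:
        return self.lengths + self.truncated


@dataclass
class GeometricFit:
    p_hat: float
    se: float
    n_runs: int
    observed_fraction_lt10: float       # fraction of runs shorter than 10 genes
    model_fraction_lt10: float          # 1 - (1 - p)^9
    observed_gene_fraction_lt10: float  # fraction of removed genes in such runs
    chi2: float
    chi2_pvalue: float


def _column_runs(presence_by_order: dict, intervals: Sequence[tuple]) -> DeletionRuns:
    lengths: list[int] = []
    truncated: list[int] = []
    for lo, hi in intervals:
        run = 0
        touching_start = False
        for o in range(lo, hi + 1):
            present = presence_by_order.get(o, None)
            if present is None:  # position outside reference gene set
                continue
            if present:
                if run:
                    if touching_start:
                        truncated.append(run)
                    else:
                        lengths.append(run)
                run = 0
                touching_start = False
            else:
                if run == 0:
                    touching_start = o == lo
                run += 1
        if run:
            truncated.append(run)  # reaches the covered-interval edge
    return DeletionRuns(lengths=lengths, truncated=truncated)


def extract_runs(table: EventTable, genome: str) -> DeletionRuns:
    """Missing-gene runs for every column of one genome, counted only inside
    block-covered reference intervals (a run cannot span a region never
    covered by any block of its column)."""
    spec = next(g for g in table.schema.genomes if g.genome == genome)
    ref = table.reference_genes
    lengths: list[int] = []
    truncated: list[int] = []
    for s in range(spec.multiplicity):
        col = table.core[genome][s]
        for chrom, sub in ref.groupby("chromosome", sort=False):
            presence = {int(o): (g in col) for o, g in zip(sub["order_index"], sub["gene_id"])}
            ivs = [(lo, hi) for (c, lo, hi) in table.coverage[genome][s] if c == chrom]
            ivs = _merge_intervals(ivs)
            runs = _column_runs(presence, ivs)
            lengths.extend(runs.lengths)
            truncated.extend(runs.truncated)
    return DeletionRuns(lengths=lengths, truncated=truncated)


def _merge_intervals(ivs):
    ivs = sorted(ivs)
    out = []
    for lo, hi in ivs:
        if out and lo <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def fit_geometric(runs, min_runs: int = 30) -> GeometricFit:
    """MLE fit of Geometric(p) on support {1, 2, ...} to run lengths."""
    lengths = np.asarray(runs.lengths if isinstance(runs, DeletionRuns) else runs, dtype=float)
    n = len(lengths)
    if n < min_runs:
        raise InsufficientRunsError(f"{n} runs < required {min_runs}")
    mean = lengths.mean()
    p = 1.0 / mean
    se = p * np.sqrt((1.0 - p) / n) if p < 1 else 0.0
    obs_lt10 = float((lengths < 10).mean())
    model_lt10 = 1.0 - (1.0 - p) ** 9
    removed = lengths.sum()
    obs_gene_lt10 = float(lengths[lengths < 10].sum() / removed) if removed else float("nan")
    # chi-square goodness of fit over binned lengths (tail pooled)
    kmax = int(min(np.quantile(lengths, 0.99), 30))
    bins = list(range(1, kmax + 1))
    obs_counts = np.array([(lengths == k).sum() for k in bins] + [(lengths > kmax).sum()], dtype=float)
    probs = np.array([p * (1 - p) ** (k - 1) for k in bins] + [(1 - p) ** kmax])
    keep = probs * n >= 1
    if keep.sum() >= 2:
        o = obs_counts[keep]
        e = probs[keep] * n
        chi2 = float(((o - e) ** 2 / e).sum())
        dof = max(int(keep.sum()) - 2, 1)  # one estimated parameter
        pval = float(stats.chi2.sf(chi2, dof))
    else:
        chi2, pval = float("nan"), float("nan")
    return GeometricFit(p_hat=float(p), se=float(se), n_runs=n,
                        observed_fraction_lt10=obs_lt10, model_fraction_lt10=float(model_lt10),
                        observed_gene_fraction_lt10=obs_gene_lt10,
                        chi2=chi2, chi2_pvalue=pval)


# ---------------------------------------------------------------------------
# retention profiles
# ---------------------------------------------------------------------------

def retention_profile(table: EventTable, genome: str, window: int = 30,
                      step: int = 5) -> dict:
    """Sliding-window retention fraction per column plus a paired sign test
    between sibling columns (divergent retention between duplicated regions).

    Returns ``{"profile": DataFrame, "tests": DataFrame}`` where the tests
    compare each sibling column pair of the genome's hierarchy with a
    two-sided sign test over windows.
    """
    spec = next(g for g in table.schema.genomes if g.genome == genome)
    ref = table.reference_genes
    max_len = ref.groupby("chromosome")["order_index"].max().min()
    if window > max_len + 1:
        raise ValueError(f"window {window} larger than shortest chromosome ({max_len + 1} genes)")
    presence = table.row_presence(genome)
    prof_rows = []
    windows_by_slot: dict[int, list] = {s: [] for s in range(spec.multiplicity)}
    for chrom, sub in ref.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        orders = sub["order_index"].to_numpy()
        for start in range(int(orders.min()), int(orders.max()) - window + 2, step):
            sel = idx[(orders >= start) & (orders < start + window)]
            if len(sel) == 0:
                continue
            for s in range(spec.multiplicity):
                cov = _covered(table.coverage[genome][s], chrom, start, start + window - 1)
                if not cov:
                    continue
                frac = float(presence[sel, s].mean())
                prof_rows.append({"chromosome": chrom, "start": start, "slot": s,
                                  "retention": frac})
                windows_by_slot[s].append((chrom, start, frac))
    profile = pd.DataFrame(prof_rows)

    def sibling_pairs(node, parent_event=None):
        out = []
        if node.is_leaf:
            return out
        if all(c.is_leaf for c in node.children):
            slots = [c.slot for c in node.children]
            for i in range(len(slots)):
                for j in range(i + 1, len(slots)):
                    out.append((node.event, slots[i], slots[j]))
        for c in node.children:
            out.extend(sibling_pairs(c, node.event))
        return out

    test_rows = []
    for event, sa, sb in sibling_pairs(spec.hierarchy):
        a = {(c, st): f for c, st, f in windows_by_slot[sa]}
        b = {(c, st): f for c, st, f in windows_by_slot[sb]}
        common = sorted(set(a) & set(b))
        diffs = [a[k] - b[k] for k in common]
        n_pos = sum(1 for d in diffs if d > 0)
        n_neg = sum(1 for d in diffs if d < 0)
        if n_pos + n_neg > 0:
            pval = float(stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue)
        else:
            pval = 1.0
        test_rows.append({"event": event, "slot_a": sa, "slot_b": sb,
                          "n_windows": len(common), "n_a_higher": n_pos,
                          "n_b_higher": n_neg, "p_value": pval})
    return {"profile": profile, "tests": pd.DataFrame(test_rows)}


def _covered(intervals, chrom, lo, hi) -> bool:
    return any(c == chrom and not (hi < a or lo > b) for c, a, b in intervals)
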