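"""Synonymous/nonsynonymous divergence (Ks, Ka) by the Nei-Gojobori method.

The estimator counts synonymous and nonsynonymous sites per codon from the
universal genetic code, averages substitution differences over all minimal
pathways between differing codons (pathways through stop codons excluded),
and applies the Jukes-Cantor multiple-hit correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._codon import UNIVERSAL, CodeTables, encode_cds

MIN_CODONS = 30  # below this an estimate is flagged too_short


@dataclass
class KsEstimate:
    gene_a: str
    gene_b: str
    S: float = float("nan")
    N: float = float("nan")
    Sd: float = float("nan")
    Nd: float = float("nan")
    ps: float = float("nan")
    pn: float = float("nan")
    Ks: float = float("nan")
    Ka: float = float("nan")
    n_codons: int = 0
    status: str = "ok"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def _strip_final_stop(codons: np.ndarray, tables: CodeTables) -> np.ndarray:
    if len(codons) and codons[-1] >= 0 and tables.is_stop[codons[-1]]:
        return codons[:-1]
    return codons


def align_codons(
    cds_a: str,
    cds_b: str,
    tables: CodeTables = UNIVERSAL,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair codons of two coding sequences via protein-level global alignment.

    Returns two equal-length integer codon arrays.  Gap columns, codons
    containing N and final stop codons are dropped.  When both sequences have
    the same length the identity mapping is used directly (a global protein
    alignment of two co-linear CDSs is the identity; skipping it avoids the
    quadratic alignment cost on large simulated batches).
    """
    ca = _strip_final_stop(encode_cds(cds_a), tables)
    cb = _strip_final_stop(encode_cds(cds_b), tables)
    if len(ca) != len(cb):
        # translate; internal stops (should not occur in valid CDS) -> X
        pa = "".join("X" if c < 0 or tables.aa[c] == "*" else tables.aa[c] for c in ca)
        pb = "".join("X" if c < 0 or tables.aa[c] == "*" else tables.aa[c] for c in cb)
        aln = _ALIGNER.align(pa, pb)[0]
        ia: list[int] = []
        ib: list[int] = []
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            ia.extend(range(a0, a1))
            ib.extend(range(b0, b1))
        ca = ca[np.asarray(ia, dtype=np.int64)]
        cb = cb[np.asarray(ib, dtype=np.int64)]
    keep = (ca >= 0) & (cb >= 0)
    keep &= ~(tables.is_stop[np.clip(ca, 0, 63)] | tables.is_stop[np.clip(cb, 0, 63)])
    return ca[keep], cb[keep]


def nei_gojobori(
    codons_a: np.ndarray,
    codons_b: np.ndarray,
    gene_a: str = "a",
    gene_b: str = "b",
    tables: CodeTables = UNIVERSAL,
    min_codons: int = MIN_CODONS,
) -> KsEstimate:
    """Nei-Gojobori (1986) Ks/Ka from paired codon arrays.

    Codon pairs for which every minimal substitution pathway crosses a stop
    codon are dropped from both the site and the difference counts.
    """
    est = KsEstimate(gene_a=gene_a, gene_b=gene_b)
    sd = tables.sd[codons_a, codons_b]
    valid = ~np.isnan(sd)
    a = codons_a[valid]
    b = codons_b[valid]
    est.n_codons = int(len(a))
    if est.n_codons == 0:
        est.status = "too_short"
        return est
    est.S = float((tables.syn_sites[a].sum() + tables.syn_sites[b].sum()) / 2.0)
    est.N = float((tables.nonsyn_sites[a].sum() + tables.nonsyn_sites[b].sum()) / 2.0)
    est.Sd = float(tables.sd[a, b].sum())
    est.Nd = float(tables.nd[a, b].sum())
    if est.n_codons < min_codons:
        est.status = "too_short"
        return est
    if est.S <= 0 or est.N <= 0:
        est.status = "saturated"
        return est
    est.ps = est.Sd / est.S
    est.pn = est.Nd / est.N
    qs = 1.0 - 4.0 * est.ps / 3.0
    qn = 1.0 - 4.0 * est.pn / 3.0
    if qs <= 0 or qn <= 0:
        est.status = "saturated"
        return est
    est.Ks = -0.75 * math.log(qs)
    est.Ka = -0.75 * math.log(qn)
    return est


def ks_pair(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b",
            tables: CodeTables = UNIVERSAL) -> KsEstimate:
    """Convenience: align two CDSs and estimate Ks/Ka."""
    ca, cb = align_codons(cds_a, cds_b, tables)
    return nei_gojobori(ca, cb, gene_a, gene_b, tables)


def ks_table(
    cds: dict,
    pairs: Iterable[tuple[str, str]],
    tables: CodeTables = UNIVERSAL,
) -> pd.DataFrame:
    """Estimate Ks for many gene pairs; returns the standard Ks table."""
    cache: dict[str, np.ndarray] = {}

    def enc(g: str) -> np.ndarray:
        if g not in cache:
            cache[g] = _strip_final_stop(encode_cds(cds[g]), tables)
        return cache[g]

    rows = []
    for ga, gb in pairs:
        ca, cb = enc(ga), enc(gb)
        if len(ca) == len(cb):
            keep = (ca >= 0) & (cb >= 0)
            est = nei_gojobori(ca[keep], cb[keep], ga, gb, tables)
        else:
            est = ks_pair(cds[ga], cds[gb], ga, gb, tables)
        rows.append(est.__dict__)
    return pd.DataFrame(rows)


def block_ks_median(blocks, estimates: pd.DataFrame):
    """Attach the median anchor Ks to each colinear block.

    ``estimates`` is a Ks table (gene_a, gene_b, Ks, status).  Blocks whose
    anchors have no ok-status estimate keep ``ks_median = None``.
    """
    ok = estimates[estimates["status"] == "ok"]
    lut: dict[tuple[str, str], float] = {}
    for ga, gb, ks in zip(ok["gene_a"], ok["gene_b"], ok["Ks"]):
        lut[(ga, gb)] = ks
        lut[(gb, ga)] = ks
    for blk in blocks:
        vals = [lut[(a.gene_a, a.gene_b)] for a in blk.anchors if (a.gene_a, a.gene_b) in lut]
        blk.ks_median = float(np.median(vals)) if vals else None
    return blocks
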