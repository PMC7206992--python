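"""Genetic-code lookup tables shared by the Ks estimator and the sequence simulator.

Codons are encoded as integers in base 4 with A=0, C=1, G=2, T=3, i.e.
``index = 16*a + 4*b + c``.  All tables are built once at import time from the
standard (universal) nuclear code; :func:`build_code_tables` accepts any
Biopython codon table id so a different code can be injected in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}


def codon_str(idx: int) -> str:
    return NT[(idx >> 4) & 3] + NT[(idx >> 2) & 3] + NT[idx & 3]


def codon_index(codon: str) -> int:
    return (NT_INDEX[codon[0]] << 4) | (NT_INDEX[codon[1]] << 2) | NT_INDEX[codon[2]]


@dataclass(frozen=True)
class CodeTables:
    """Precomputed per-codon and per-codon-pair quantities.

    Attributes
    ----------
    aa : array of shape (64,), dtype '<U1'
        Amino acid per codon, ``*`` for stops.
    is_stop : bool array (64,)
    syn_sites : float array (64,)
        Nei-Gojobori synonymous site count per codon (sum over the three
        positions of the fraction of the 3 possible single-nucleotide changes
        that are synonymous; changes to stop codons count as nonsynonymous).
        NaN for stop codons.
    nonsyn_sites : float array (64,)
        ``3 - syn_sites``.
    sd : float array (64, 64)
        Pathway-averaged synonymous difference count between codon pairs.
        Paths through stop codons are excluded; NaN where no valid path
        exists or either codon is a stop.
    nd : float array (64, 64)
        Same for nonsynonymous differences.
    syn_neighbors / nonsyn_neighbors : list of 64 int arrays
        Single-nucleotide neighbours reachable by a synonymous (resp.
        nonsynonymous, non-stop) change.
    """

    aa: np.ndarray
    is_stop: np.ndarray
    syn_sites: np.ndarray
    nonsyn_sites: np.ndarray
    sd: np.ndarray
    nd: np.ndarray
    syn_neighbors: tuple
    nonsyn_neighbors: tuple


def _neighbors(idx: int):
    """Yield (position, neighbour_index) for the 9 single-nt changes."""
    for pos in range(3):
        shift = (2 - pos) * 2
        base = (idx >> shift) & 3
        for b in range(4):
            if b != base:
                yield pos, (idx & ~(3 << shift)) | (b << shift)


def _pair_path_counts(a: int, b: int, aa: np.ndarray) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over all minimal
    substitution pathways from codon ``a`` to codon ``b``.

    Pathways visiting a stop codon at an intermediate step are excluded.
    Returns (nan, nan) if every pathway is excluded.
    """
    diff_pos = [p for p in range(3) if ((a >> ((2 - p) * 2)) & 3) != ((b >> ((2 - p) * 2)) & 3)]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = 0.0
    nonsyn_tot = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = a
        syn = 0
        nonsyn = 0
        ok = True
        for step, pos in enumerate(order):
            shift = (2 - pos) * 2
            target = (b >> shift) & 3
            nxt = (cur & ~(3 << shift)) | (target << shift)
            if aa[nxt] == "*" and step < len(order) - 1:
                ok = False
                break
            if aa[nxt] == "*":  # endpoint is a stop: caller guarantees not
                ok = False
                break
            if aa[nxt] == aa[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        return float("nan"), float("nan")
    return syn_tot / n_paths, nonsyn_tot / n_paths


def build_code_tables(table_id: int = 1) -> CodeTables:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = np.empty(64, dtype="<U1")
    for idx in range(64):
        c = codon_str(idx)
        aa[idx] = "*" if c in table.stop_codons else table.forward_table[c]
    is_stop = aa == "*"

    syn_sites = np.full(64, np.nan)
    syn_nb = []
    nonsyn_nb = []
    for idx in range(64):
        if is_stop[idx]:
            syn_nb.append(np.empty(0, dtype=np.int64))
            nonsyn_nb.append(np.empty(0, dtype=np.int64))
            continue
        s = 0.0
        sn = []
        nn = []
        for _pos, nb in _neighbors(idx):
            if aa[nb] == aa[idx]:
                s += 1.0 / 3.0
                sn.append(nb)
            elif not is_stop[nb]:
                nn.append(nb)
        syn_sites[idx] = s
        syn_nb.append(np.array(sn, dtype=np.int64))
        nonsyn_nb.append(np.array(nn, dtype=np.int64))
    nonsyn_sites = 3.0 - syn_sites

    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for a in range(64):
        if is_stop[a]:
            continue
        for b in range(64):
            if is_stop[b]:
                continue
            s, n = _pair_path_counts(a, b, aa)
            sd[a, b] = s
            nd[a, b] = n
    return CodeTables(
        aa=aa,
        is_stop=is_stop,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        sd=sd,
        nd=nd,
        syn_neighbors=tuple(syn_nb),
        nonsyn_neighbors=tuple(nonsyn_nb),
    )


UNIVERSAL: CodeTables = build_code_tables(1)


def encode_cds(seq: str) -> np.ndarray:
    """Encode a CDS string into codon indices; codons containing anything
    outside ACGT (e.g. N) are encoded as -1."""
    seq = seq.upper()
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        c = seq[3 * i : 3 * i + 3]
        if all(ch in NT_INDEX for ch in c):
            out[i] = codon_index(c)
    return out


def decode_codons(codons: np.ndarray) -> str:
    return "".join(codon_str(int(c)) for c in codons)
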