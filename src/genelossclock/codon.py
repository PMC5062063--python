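"""Genetic-code-11 codon tables and Nei–Gojobori (NG86) counting machinery.

Codons are encoded as integers ``16*a + 4*b + c`` with A,C,G,T -> 0..3.
All NG86 quantities (synonymous/nonsynonymous site fractions per codon,
pathway-averaged difference counts per codon pair) are precomputed into
lookup tables so that pairwise comparisons reduce to vectorized indexing.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import log

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCS)}
GAP_CODON = 64  # sentinel for a gapped / unresolvable codon column

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon index -> one-letter amino acid, '*' for stop
AA_BY_CODON: list[str] = []
for i in range(64):
    codon = NUCS[i >> 4] + NUCS[(i >> 2) & 3] + NUCS[i & 3]
    AA_BY_CODON.append("*" if codon in _TABLE11.stop_codons else _TABLE11.forward_table[codon])

STOP_CODONS = frozenset(i for i in range(64) if AA_BY_CODON[i] == "*")

#: amino acid -> sorted list of codon indices (synonymous family), code 11
FAMILY_BY_AA: dict[str, list[int]] = {}
for i, aa in enumerate(AA_BY_CODON):
    if aa != "*":
        FAMILY_BY_AA.setdefault(aa, []).append(i)


def encode_cds(seq: str) -> np.ndarray:
    """CDS string -> int array of codon indices (must be length % 3 == 0)."""
    if len(seq) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for c, i in NUC_INDEX.items():
        lut[ord(c)] = i
    nt = lut[arr]
    if (nt == 255).any():
        raise ValueError("non-ACGT character in CDS")
    nt = nt.astype(np.int16).reshape(-1, 3)
    return (nt[:, 0] * 16 + nt[:, 1] * 4 + nt[:, 2]).astype(np.int16)


_CODON_STR = np.array(
    [(NUCS[i >> 4] + NUCS[(i >> 2) & 3] + NUCS[i & 3]).encode() for i in range(64)]
    + [b"---"]
)


def decode_codons(codons: np.ndarray) -> str:
    """Codon-index array back to a nucleotide string (64 -> ``---``)."""
    arr = np.asarray(codons, dtype=np.int64)
    return _CODON_STR[arr].tobytes().decode()


def translate_codons(codons: np.ndarray) -> str:
    return "".join(AA_BY_CODON[c] for c in codons)


def _neighbors(codon: int, pos: int):
    """The three codons differing from `codon` at nucleotide position pos."""
    shift = (2 - pos) * 2
    cur = (codon >> shift) & 3
    for alt in range(4):
        if alt != cur:
            yield codon ^ ((cur ^ alt) << shift)


@lru_cache(maxsize=1)
def ng86_site_tables() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon synonymous (S) and nonsynonymous (N) site counts.

    Each of the three positions contributes one site, split by the fraction
    of its non-stop single-nucleotide changes that are synonymous; changes
    to stop codons are ignored. Stop codons themselves get zero sites.
    """
    S = np.zeros(65)
    N = np.zeros(65)
    for codon in range(64):
        if codon in STOP_CODONS:
            continue
        for pos in range(3):
            alts = [a for a in _neighbors(codon, pos) if a not in STOP_CODONS]
            if not alts:
                continue
            syn = sum(AA_BY_CODON[a] == AA_BY_CODON[codon] for a in alts)
            S[codon] += syn / len(alts)
            N[codon] += 1 - syn / len(alts)
    return S, N


@lru_cache(maxsize=1)
def ng86_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """Pathway-averaged synonymous (Sd) and nonsynonymous (Nd) differences.

    For a codon pair differing at d positions, all d! stepwise mutation
    paths are enumerated; paths passing through a stop codon are discarded
    (all paths are kept if every one is blocked). Sd + Nd = d.
    """
    Sd = np.zeros((65, 65))
    Nd = np.zeros((65, 65))
    for a in range(64):
        if a in STOP_CODONS:
            continue
        for b in range(a + 1, 64):
            if b in STOP_CODONS:
                continue
            positions = [p for p in range(3) if ((a >> ((2 - p) * 2)) & 3) != ((b >> ((2 - p) * 2)) & 3)]
            paths = []
            for order in itertools.permutations(positions):
                cur, syn, non, blocked = a, 0.0, 0.0, False
                for pos in order:
                    shift = (2 - pos) * 2
                    nxt = cur ^ ((((cur >> shift) & 3) ^ ((b >> shift) & 3)) << shift)
                    if nxt in STOP_CODONS:
                        blocked = True
                    if AA_BY_CODON[nxt] == AA_BY_CODON[cur] and nxt not in STOP_CODONS and cur not in STOP_CODONS:
                        syn += 1
                    else:
                        non += 1
                    cur = nxt
                paths.append((blocked, syn, non))
            open_paths = [p for p in paths if not p[0]] or paths
            Sd[a, b] = Sd[b, a] = sum(p[1] for p in open_paths) / len(open_paths)
            Nd[a, b] = Nd[b, a] = sum(p[2] for p in open_paths) / len(open_paths)
    return Sd, Nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differing sites."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")
    return -0.75 * log(1 - 4 * p / 3)


#: True for sense codons, False for stops and the gap sentinel
VALID_CODON = np.array([i not in STOP_CODONS for i in range(64)] + [False])


def pairwise_ng86(codons_a: np.ndarray, codons_b: np.ndarray) -> dict:
    """NG86 dN and dS for one aligned codon sequence pair.

    Columns where either sequence is gapped (GAP_CODON) or a stop are
    skipped. Returns dict with S, N, Sd, Nd, pS, pN, dS, dN (dS/dN are NaN
    when the JC correction is undefined).
    """
    S_tab, N_tab = ng86_site_tables()
    Sd_tab, Nd_tab = ng86_diff_tables()
    ok = VALID_CODON[codons_a] & VALID_CODON[codons_b]
    a, b = codons_a[ok], codons_b[ok]
    S = (S_tab[a].sum() + S_tab[b].sum()) / 2.0
    N = (N_tab[a].sum() + N_tab[b].sum()) / 2.0
    Sd = Sd_tab[a, b].sum()
    Nd = Nd_tab[a, b].sum()
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    out = {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN}
    out["dS"] = jukes_cantor(pS) if pS == pS and pS < 0.75 else float("nan")
    out["dN"] = jukes_cantor(pN) if pN == pN and pN < 0.75 else float("nan")
    return out


def ng86_all_pairs(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise NG86 dN and dS matrices for a gap-free codon matrix.

    ``matrix`` is (n_seqs, n_codons) with sense-codon entries only (drop
    gapped/stop columns first). Entries are NaN where the Jukes-Cantor
    correction is undefined. Equivalent to :func:`pairwise_ng86` applied
    to every pair, but vectorized.
    """
    S_tab, N_tab = ng86_site_tables()
    Sd_tab, Nd_tab = ng86_diff_tables()
    A = np.asarray(matrix)
    s_row = S_tab[A].sum(axis=1)
    n_row = N_tab[A].sum(axis=1)
    Sd = Sd_tab[A[:, None, :], A[None, :, :]].sum(axis=2)
    Nd = Nd_tab[A[:, None, :], A[None, :, :]].sum(axis=2)
    S_pair = (s_row[:, None] + s_row[None, :]) / 2.0
    N_pair = (n_row[:, None] + n_row[None, :]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pS = Sd / S_pair
        pN = Nd / N_pair
        dS = np.where(pS < 0.75, -0.75 * np.log(1 - 4 * pS / 3), np.nan)
        dN = np.where(pN < 0.75, -0.75 * np.log(1 - 4 * pN / 3), np.nan)
    return dN, dS
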