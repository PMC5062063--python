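"""Pairwise sequence comparison used throughout the pipeline.

Two engines are provided behind one identity contract
(``identity = 100 * matches / aligned columns``, gapped columns included
in the denominator):

* :func:`align_pair` — affine-gap local alignment (match +5, mismatch -4,
  gap of length L costs 12 + 4*(L-1)), the reference scheme for ortholog
  calls. Backed by Biopython's ``PairwiseAligner``.
* :func:`quick_identity` — a fast path for bulk clustering: a plain
  column-wise comparison when the two sequences have equal length, else a
  unit-cost global alignment (edlib). At the high identities that matter
  for clustering decisions the two engines agree closely.

A k-mer candidate index (:class:`KmerIndex`) avoids all-vs-all alignment:
only sequence pairs sharing at least ``min_shared`` k-mers are aligned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class PairAlignment:
    identity: float  # percent over aligned columns, gaps in denominator
    alignment_length: int  # aligned columns
    shorter_len: int
    longer_len: int

    @property
    def coverage_of_shorter(self) -> float:
        """Fraction of the shorter sequence inside the aligned region."""
        return min(1.0, self.alignment_length / self.shorter_len)


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    # overlap alignment: internal gaps are affine, terminal gaps free
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_internal_gap_score = -gap_open
    aligner.extend_internal_gap_score = -gap_extend
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner

_DNA_ALIGNER = _make_aligner(5.0, -4.0, 12.0, 4.0)


def align_pair(seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None) -> PairAlignment:
    """Best overlap alignment of two DNA sequences under the affine scheme
    (terminal gaps free, so only the overlapping region is scored; identity
    is computed over its columns, internal gaps included).

    Symmetric by construction: the pair is put in canonical order before
    aligning, so ``align_pair(a, b) == align_pair(b, a)`` even when several
    alignments tie on score.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    a, b = sorted((seq_a.upper(), seq_b.upper()))
    alignment = next(iter((aligner or _DNA_ALIGNER).align(a, b)))
    blocks = alignment.aligned
    matches = columns = 0
    if blocks is not None and len(blocks[0]):
        for (a0, a1), (b0, b1) in zip(blocks[0], blocks[1]):
            # aligned blocks are gap-free; columns between blocks are gaps
            matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
            columns += a1 - a0
        # internal gap columns: span minus block columns on each sequence
        span_a = blocks[0][-1][1] - blocks[0][0][0]
        span_b = blocks[1][-1][1] - blocks[1][0][0]
        columns += (span_a - columns) + (span_b - columns)
    identity = 100.0 * float(matches) / columns if columns else 0.0
    return PairAlignment(identity, int(columns), min(len(a), len(b)), max(len(a), len(b)))


def quick_identity(seq_a: str, seq_b: str) -> PairAlignment:
    """Fast unit-cost identity with overlap-style semantics.

    Equal lengths: plain column comparison. Unequal lengths: the shorter
    sequence is aligned inside the longer one (edlib infix mode), so a
    truncated gene scores by its overlapping region rather than being
    charged for terminal gaps — matching :func:`align_pair`'s behavior.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    la, lb = len(seq_a), len(seq_b)
    if la == lb:
        a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
        b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
        matches = int((a == b).sum())
        return PairAlignment(100.0 * matches / la, la, la, la)
    query, target = (seq_a, seq_b) if la < lb else (seq_b, seq_a)
    res = edlib.align(query, target, mode="HW", task="path")
    matches = columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return PairAlignment(100.0 * matches / columns, columns, min(la, lb), max(la, lb))


def batch_identity_equal_length(seqs: list[str]) -> np.ndarray:
    """Pairwise percent-identity matrix for equal-length sequences
    (column-wise comparison, the gap-free global alignment)."""
    n = len(seqs)
    if n == 0:
        return np.zeros((0, 0))
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length")
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
    out = np.zeros((n, n))
    for i in range(n):
        out[i] = (mat == mat[i]).mean(axis=1) * 100.0
    return out


def _kmer_codes(seq: str, k: int, alphabet_bits: int) -> np.ndarray:
    """Integer codes of all k-mers (2 or 5 bits per character)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).astype(np.uint64)
    if len(arr) < k:
        return np.empty(0, dtype=np.uint64)
    if alphabet_bits == 2:  # DNA: A/C/G/T -> 0..3, anything else folded
        code = (arr >> np.uint64(1)) & np.uint64(3)
    else:  # protein: 5 bits of the raw byte
        code = arr & np.uint64(31)
    n_out = len(code) - k + 1
    out = np.zeros(n_out, dtype=np.uint64)
    for i in range(k):  # shift-accumulate beats a windowed multiply here
        out |= code[i : i + n_out] << np.uint64(alphabet_bits * i)
    return out


class KmerIndex:
    """Sampled k-mer index for fast candidate retrieval before alignment.

    K-mers are sampled by content (``code % sample == 0``), which is
    phase-invariant: two homologous sequences sample the same conserved
    k-mers regardless of indel offsets. ``protein=True`` switches to a
    5-bit amino-acid coding with a shorter default k.
    """

    def __init__(
        self,
        sequences: list[str] | None = None,
        k: int | None = None,
        protein: bool = False,
        sample: int | None = None,
    ):
        self.protein = protein
        self.k = k if k is not None else (5 if protein else 14)
        self.sample = sample if sample is not None else (4 if protein else 8)
        self.n = 0
        self._index: dict[int, list[int]] = {}
        for seq in sequences or []:
            self.add(seq)

    def _sampled(self, seq: str) -> np.ndarray:
        codes = _kmer_codes(seq, self.k, 5 if self.protein else 2)
        if self.sample > 1:
            codes = codes[codes % np.uint64(self.sample) == 0]
        return np.unique(codes)

    def add(self, seq: str) -> int:
        idx = self.n
        self.n += 1
        for code in self._sampled(seq).tolist():
            self._index.setdefault(code, []).append(idx)
        return idx

    def candidates(self, seq: str, min_shared: int = 1, relative: float = 0.0) -> list[int]:
        """Indices sharing >= min_shared sampled k-mers, best-first
        (ties broken by index order). With ``relative`` > 0, candidates
        sharing fewer than ``relative * top_count`` k-mers are dropped —
        a cheap way to skip aligning spurious low-overlap hits."""
        from collections import Counter

        flat: list[int] = []
        get = self._index.get
        for code in self._sampled(seq).tolist():
            hit = get(code)
            if hit:
                flat.extend(hit)
        if not flat:
            return []
        counts = Counter(flat)
        floor = max(min_shared, int(relative * max(counts.values())))
        hits = [(c, i) for i, c in counts.items() if c >= floor]
        hits.sort(key=lambda t: (-t[0], t[1]))
        return [i for _, i in hits]
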