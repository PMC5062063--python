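"""Species phylogeny from average nucleotide dissimilarity (AND = 100 - ANI).

ANI between two strains is the unweighted mean percent identity over
qualifying ortholog pairs (>= 30% identity over >= 70% of the shorter
gene, POGO-DB thresholds) restricted to core, non-recombining pangenes;
recombination is screened with a four-gamete test. Trees are built with
canonical Saitou-Nei neighbor joining, rooted with an outgroup that is
then pruned. Deterministic throughout: NJ ties are broken on the
lexicographically smallest cluster-label pair and negative branch-length
estimates are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import KmerIndex, batch_identity_equal_length, quick_identity
from .pangenome import Pangene, Pangenome, StrainGenome, find_orthologs
from .trees import Node, Tree


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # AND percentages, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label.ljust(12) + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text().strip().splitlines()
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows))


# ---------------------------------------------------------------------------
# recombination screen


def four_gamete_pass(alignment: dict[str, str]) -> bool:
    """True iff no pair of biallelic sites shows all four haplotypes.

    `alignment` maps strain -> aligned sequence (equal lengths). Columns
    containing non-ACGT characters are ignored. Alignments with <= 1
    segregating site pass trivially.
    """
    seqs = list(alignment.values())
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("unequal sequence lengths: input is not aligned")
    mat = np.frombuffer("".join(s.upper() for s in seqs).encode(), dtype=np.uint8)
    mat = mat.reshape(len(seqs), -1)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8)).all(axis=0)
    mat = mat[:, valid]
    if mat.shape[1] == 0:
        return True
    # biallelic columns -> boolean minor-allele matrix (vectorized)
    present = np.stack([(mat == c).any(axis=0) for c in b"ACGT"])  # 4 x cols
    biallelic = present.sum(axis=0) == 2
    if biallelic.sum() < 2:
        return True
    sub = mat[:, biallelic]
    B = sub != sub[0]  # strains x sites, binary-coded against row 0's allele
    Bn = ~B
    g11 = (B.T.astype(np.int32) @ B.astype(np.int32)) > 0
    g10 = (B.T.astype(np.int32) @ Bn.astype(np.int32)) > 0
    g01 = (Bn.T.astype(np.int32) @ B.astype(np.int32)) > 0
    g00 = (Bn.T.astype(np.int32) @ Bn.astype(np.int32)) > 0
    four = g11 & g10 & g01 & g00
    np.fill_diagonal(four, False)
    return not bool(four.any())


def filter_nonrecombining(alignments: dict[str, dict[str, str]]) -> list[str]:
    """Subset of pangene ids whose alignments pass the four-gamete screen."""
    return [pid for pid, aln in alignments.items() if four_gamete_pass(aln)]


# ---------------------------------------------------------------------------
# AND matrix


def compute_and_matrix(
    genomes: list[StrainGenome],
    pangenome: Pangenome,
    core_pangenes: list[Pangene] | list[str],
    outgroup: StrainGenome | None = None,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
) -> DistanceMatrix:
    """AND = 100 - ANI over qualifying core-gene ortholog pairs.

    Ingroup pairs use pangene co-membership as the ortholog relation;
    the outgroup (not part of the pangenome) is paired with each strain
    by bidirectional best hits against that strain's core genes.
    """
    if len(genomes) + (outgroup is not None) < 3:
        raise ValueError("need >= 3 genomes")
    core: list[Pangene] = [
        pangenome.pangene(p) if isinstance(p, str) else p for p in core_pangenes
    ]
    strains = [g.strain_id for g in genomes]
    strain_pos = {s: i for i, s in enumerate(strains)}
    labels = strains + ([outgroup.strain_id] if outgroup else [])
    n = len(labels)
    and_vals = np.zeros((n, n))
    m = len(strains)
    ident_sum = np.zeros((m, m))
    ident_cnt = np.zeros((m, m))
    for p in core:
        items = [(s, pangenome.sequences[(s, g)]) for s, g in sorted(p.members.items())]
        by_len: dict[int, list[tuple[str, str]]] = {}
        for s, seq in items:
            by_len.setdefault(len(seq), []).append((s, seq))
        for group in by_len.values():
            if len(group) < 2:
                continue
            ids = batch_identity_equal_length([seq for _, seq in group])
            pos = [strain_pos[s] for s, _ in group]
            qual = ids >= min_identity  # equal length: full coverage
            for ii in range(len(group)):
                for jj in range(ii + 1, len(group)):
                    if qual[ii, jj]:
                        x, y = sorted((pos[ii], pos[jj]))
                        ident_sum[x, y] += ids[ii, jj]
                        ident_cnt[x, y] += 1
        # members of unequal length (split genes etc.): align individually
        if len(by_len) > 1:
            lens = sorted(by_len)
            for li in range(len(lens)):
                for lj in range(li + 1, len(lens)):
                    for sa, qa in by_len[lens[li]]:
                        for sb, qb in by_len[lens[lj]]:
                            aln = quick_identity(qa, qb)
                            if (
                                aln.identity >= min_identity
                                and aln.coverage_of_shorter >= min_coverage
                            ):
                                x, y = strain_pos[sa], strain_pos[sb]
                                ident_sum[min(x, y), max(x, y)] += aln.identity
                                ident_cnt[min(x, y), max(x, y)] += 1
    for i in range(m):
        for j in range(i + 1, m):
            if ident_cnt[i, j] == 0:
                raise ValueError(
                    f"no qualifying orthologs between {strains[i]} and {strains[j]}"
                )
            and_vals[i, j] = and_vals[j, i] = 100.0 - ident_sum[i, j] / ident_cnt[i, j]
    if outgroup is not None:
        o = len(labels) - 1
        # map outgroup genes to core pangenes once (reciprocal best hit
        # against pangene representatives), then score each strain's
        # member against its paired outgroup gene
        rep_seqs = [pangenome.sequences[p.representative] for p in core]
        rep_index = KmerIndex(rep_seqs)
        pangene_hit: dict[int, tuple[str, str, float]] = {}  # core idx -> (gene, seq, ident)
        for gid, seq in outgroup.genes:
            best: tuple[float, int] | None = None
            for slot in rep_index.candidates(seq, relative=0.25)[:5]:
                t = rep_seqs[slot]
                if min(len(seq), len(t)) < (2.0 / 3.0) * max(len(seq), len(t)):
                    continue
                aln = quick_identity(seq, t)
                if aln.identity >= min_identity and aln.coverage_of_shorter >= min_coverage:
                    if best is None or aln.identity > best[0]:
                        best = (aln.identity, slot)
            if best is not None:
                ident, slot = best
                if slot not in pangene_hit or ident > pangene_hit[slot][2]:
                    pangene_hit[slot] = (gid, seq, ident)
        for i, genome in enumerate(genomes):
            idents = []
            for slot, (ogid, oseq, _) in pangene_hit.items():
                p = core[slot]
                if genome.strain_id not in p.members:
                    continue
                member_seq = pangenome.sequences[(genome.strain_id, p.members[genome.strain_id])]
                aln = quick_identity(oseq, member_seq)
                if aln.identity >= min_identity and aln.coverage_of_shorter >= min_coverage:
                    idents.append(aln.identity)
            if not idents:
                raise ValueError(
                    f"no qualifying orthologs between {outgroup.strain_id} and {genome.strain_id}"
                )
            and_vals[i, o] = and_vals[o, i] = 100.0 - float(np.mean(idents))
    return DistanceMatrix(labels, and_vals)


# ---------------------------------------------------------------------------
# neighbor joining


def _nj_unrooted(matrix: DistanceMatrix):
    """Saitou-Nei NJ; returns (adjacency, last node id).

    Adjacency maps node id -> list of (neighbor id, branch length). Each
    cluster carries a canonical name (its smallest member label) used for
    deterministic tie-breaking.
    """
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    D: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            D[frozenset((a, labels[j]))] = float(matrix.values[i, j])
    adj: dict[str, list[tuple[str, float]]] = {l: [] for l in labels}
    canon = {l: l for l in labels}
    active = sorted(labels)
    counter = 0

    def connect(a: str, b: str, length: float) -> None:
        length = max(0.0, length)
        adj.setdefault(a, []).append((b, length))
        adj.setdefault(b, []).append((a, length))

    while len(active) > 3:
        r = len(active)
        R = {a: sum(D[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * D[frozenset((a, b))] - R[a] - R[b]
                key = (q, tuple(sorted((canon[a], canon[b]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = D[frozenset((a, b))]
        la = dab / 2.0 + (R[a] - R[b]) / (2.0 * (r - 2))
        lb = dab - la
        counter += 1
        u = f"I{counter}"
        canon[u] = min(canon[a], canon[b])
        connect(u, a, la)
        connect(u, b, lb)
        for c in active:
            if c not in (a, b):
                D[frozenset((u, c))] = (
                    D[frozenset((a, c))] + D[frozenset((b, c))] - dab
                ) / 2.0
        active = sorted(
            [x for x in active if x not in (a, b)] + [u], key=lambda x: canon[x]
        )
    a, b, c = active
    dab, dac, dbc = (
        D[frozenset((a, b))],
        D[frozenset((a, c))],
        D[frozenset((b, c))],
    )
    counter += 1
    center = f"I{counter}"
    connect(center, a, (dab + dac - dbc) / 2.0)
    connect(center, b, (dab + dbc - dac) / 2.0)
    connect(center, c, (dac + dbc - dab) / 2.0)
    return adj, center


def nj_tree(matrix: DistanceMatrix, outgroup_label: str) -> Tree:
    """Rooted NJ tree: root placed where the outgroup attaches, outgroup
    pruned. Ingroup leaf-to-leaf path lengths equal the NJ estimates."""
    if outgroup_label not in matrix.labels:
        raise ValueError(f"outgroup {outgroup_label!r} not in matrix")
    adj, _ = _nj_unrooted(matrix)
    (attach, _), = adj[outgroup_label]

    def build(node_id: str, parent_id: str | None, parent_node: Node | None, length: float) -> Node:
        node = Node(node_id, length, parent_node)
        for nbr, l in sorted(adj[node_id]):
            if nbr != parent_id and nbr != outgroup_label:
                node.children.append(build(nbr, node_id, node, l))
        return node

    root = build(attach, None, None, 0.0)
    # splice any degree-2 pass-through nodes left by outgroup removal
    def splice(node: Node) -> None:
        for i, child in enumerate(list(node.children)):
            splice(child)
        if node.parent is not None and len(node.children) == 1:
            child = node.children[0]
            child.length += node.length
            child.parent = node.parent
            node.parent.children[node.parent.children.index(node)] = child

    splice(root)
    return Tree(root)


def trimmed_tree(
    matrix: DistanceMatrix, present_strains: list[str], outgroup_label: str
) -> Tree:
    """NJ tree restricted to the strains carrying a pangene (plus the
    outgroup for rooting, pruned afterwards)."""
    present = [s for s in matrix.labels if s in set(present_strains)]
    if len(present) < 3:
        raise ValueError(f"too few taxa for a tree: {len(present)} present strains")
    missing = set(present_strains) - set(matrix.labels)
    if missing:
        raise ValueError(f"strains not in matrix: {sorted(missing)}")
    sub = matrix.submatrix(present + [outgroup_label])
    return nj_tree(sub, outgroup_label)
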