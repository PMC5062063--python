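"""Pangenome construction: ortholog clustering of CDS across strains.

The pangenome of a species is built iteratively: a seeded-random strain
founds the library; every remaining strain's genes are matched to it
(best hit at >= 80% identity, aligned over >= 70% of the shorter gene,
shorter >= 2/3 of the longer) and unmatched genes are appended as new
pangenes. A final self-comparison pass merges pangenes whose
representatives match, removing the dependence on the initial library
choice. Members shorter than 2/3 of a pangene's longest member are then
removed and the pangene is considered absent from those strains. Pangenes
are classified by frequency: core (all strains), near-core (>= 75% but
not all) and accessory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import KmerIndex, PairAlignment, align_pair, quick_identity

DNA = set("ACGT")


@dataclass
class StrainGenome:
    """One strain's CDS collection."""

    strain_id: str
    genes: list[tuple[str, str]]  # (gene_id, CDS nucleotide sequence)
    species_id: str = ""

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene ids in strain {self.strain_id!r}")
        for gid, seq in self.genes:
            if len(seq) < 3 or set(seq.upper()) - DNA:
                raise ValueError(f"invalid CDS for {self.strain_id}/{gid}")

    def __len__(self) -> int:
        return len(self.genes)

    def as_dict(self) -> dict[str, str]:
        return dict(self.genes)


@dataclass
class Pangene:
    pangene_id: str
    members: dict[str, str]  # strain_id -> gene_id
    representative: tuple[str, str]  # (strain_id, gene_id) of longest member
    frequency: float = 0.0
    class_label: str | None = None  # core / near_core / accessory
    removed_members: list[tuple[str, str, str]] = field(default_factory=list)


@dataclass
class Pangenome:
    species_id: str
    strain_ids: list[str]
    pangenes: list[Pangene]
    identity_threshold: float
    sequences: dict[tuple[str, str], str]  # (strain, gene) -> CDS
    threshold_check: tuple[float, bool] | None = None

    def pangene(self, pangene_id: str) -> Pangene:
        return next(p for p in self.pangenes if p.pangene_id == pangene_id)

    def member_seqs(self, pangene: Pangene) -> dict[str, str]:
        return {s: self.sequences[(s, g)] for s, g in sorted(pangene.members.items())}

    def presence_matrix(self) -> pd.DataFrame:
        data = {
            p.pangene_id: [int(s in p.members) for s in self.strain_ids]
            for p in self.pangenes
        }
        return pd.DataFrame(data, index=self.strain_ids).T

    def by_class(self) -> dict[str, list[Pangene]]:
        out: dict[str, list[Pangene]] = {}
        for p in self.pangenes:
            out.setdefault(p.class_label or "unclassified", []).append(p)
        return out


def _scorer_fn(scorer: str):
    if scorer == "fast":
        return quick_identity
    if scorer == "affine":
        return align_pair
    raise ValueError(f"unknown scorer {scorer!r}")


def _passes_rules(aln: PairAlignment, min_identity: float, min_coverage: float) -> bool:
    return (
        aln.identity >= min_identity
        and aln.coverage_of_shorter >= min_coverage
        and aln.shorter_len >= (2.0 / 3.0) * aln.longer_len
    )


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float
    alignment: PairAlignment


def _best_hits(
    queries: list[tuple[str, str]],
    targets: list[tuple[str, str]],
    index: KmerIndex,
    scorer,
    min_identity: float,
    min_coverage: float,
    max_candidates: int = 5,
) -> dict[str, tuple[str, PairAlignment]]:
    """Best qualifying hit in `targets` for each query gene."""
    hits: dict[str, tuple[str, PairAlignment]] = {}
    for gid, seq in queries:
        best: tuple[str, PairAlignment] | None = None
        for t_idx in index.candidates(seq, relative=0.25)[:max_candidates]:
            t_gid, t_seq = targets[t_idx]
            if min(len(seq), len(t_seq)) < (2.0 / 3.0) * max(len(seq), len(t_seq)):
                continue  # cannot pass the length rule; skip the alignment
            aln = scorer(seq, t_seq)
            if not _passes_rules(aln, min_identity, min_coverage):
                continue
            if best is None or (aln.identity, t_gid) > (best[1].identity, best[0]):
                best = (t_gid, aln)
        if best is not None:
            hits[gid] = best
    return hits


def find_orthologs(
    genome_a: StrainGenome,
    genome_b: StrainGenome,
    min_identity: float = 80.0,
    min_coverage: float = 0.70,
    scorer: str = "fast",
    index_b: KmerIndex | None = None,
    index_a: KmerIndex | None = None,
) -> list[OrthologPair]:
    """Bidirectional best hits between two genomes.

    A pair qualifies only if identity >= min_identity, the alignment
    covers >= min_coverage of the shorter gene and the shorter gene is at
    least two-thirds of the longer one.
    """
    if genome_a.strain_id == genome_b.strain_id:
        raise ValueError("find_orthologs needs two distinct genomes")
    fn = _scorer_fn(scorer)
    # relaxed identity floors need a denser, shorter-k index to retrieve
    # diverged candidates (reliable down to ~65% identity)
    sensitive = min_identity < 75.0
    kw = {"k": 10, "sample": 2} if sensitive else {}
    if index_b is None:
        index_b = KmerIndex([s for _, s in genome_b.genes], **kw)
    if index_a is None:
        index_a = KmerIndex([s for _, s in genome_a.genes], **kw)
    ab = _best_hits(genome_a.genes, genome_b.genes, index_b, fn, min_identity, min_coverage)
    ba = _best_hits(genome_b.genes, genome_a.genes, index_a, fn, min_identity, min_coverage)
    pairs = []
    for ga, (gb, aln) in sorted(ab.items()):
        if ba.get(gb, (None,))[0] == ga:
            pairs.append(OrthologPair(ga, gb, aln.identity, aln))
    return pairs


def threshold_check(
    genomes: list[StrainGenome],
    identity_threshold: float = 80.0,
    required_fraction: float = 0.95,
    relaxed_floor: float = 30.0,
    min_coverage: float = 0.70,
    scorer: str = "fast",
) -> tuple[float, bool]:
    """Validate the clustering identity threshold against the species'
    ortholog identity distribution: pass iff >= 95% of all pairwise BBH
    orthologs (found with a relaxed identity floor) are >= 80% identical."""
    if len(genomes) < 2:
        raise ValueError("threshold_check needs >= 2 strains")
    kw = {"k": 10, "sample": 2} if relaxed_floor < 75.0 else {}
    indexes = {g.strain_id: KmerIndex([s for _, s in g.genes], **kw) for g in genomes}
    identities: list[float] = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            pairs = find_orthologs(
                ga, gb, relaxed_floor, min_coverage, scorer,
                index_b=indexes[gb.strain_id], index_a=indexes[ga.strain_id],
            )
            identities.extend(p.identity for p in pairs)
    if not identities:
        raise ValueError("no ortholog pairs found; identity distribution is empty")
    frac = float(np.mean([i >= identity_threshold for i in identities]))
    return frac, frac >= required_fraction


class _LibraryPangene:
    __slots__ = ("members", "member_lens")

    def __init__(self) -> None:
        self.members: dict[str, str] = {}
        self.member_lens: dict[str, int] = {}


def build_pangenome(
    genomes: list[StrainGenome],
    min_identity: float = 80.0,
    min_coverage: float = 0.70,
    seed: int = 0,
    scorer: str = "fast",
    species_id: str | None = None,
    run_threshold_check: bool = False,
) -> Pangenome:
    """Iterative pangenome construction (see module docstring)."""
    if len(genomes) < 2:
        raise ValueError("build_pangenome needs >= 2 genomes")
    strain_ids = [g.strain_id for g in genomes]
    if len(set(strain_ids)) != len(strain_ids):
        raise ValueError("duplicate strain_ids")
    seqs: dict[tuple[str, str], str] = {
        (g.strain_id, gid): seq for g in genomes for gid, seq in g.genes
    }
    fn = _scorer_fn(scorer)
    rng = np.random.default_rng(seed)
    order = list(genomes)
    first = int(rng.integers(len(order)))
    order[0], order[first] = order[first], order[0]

    # library: one entry per pangene; the k-mer index maps to pangene slots
    library: list[_LibraryPangene] = []
    rep_seq: list[str] = []  # current representative sequence per slot
    index = KmerIndex()

    def new_pangene(strain: str, gid: str, seq: str) -> None:
        pg = _LibraryPangene()
        pg.members[strain] = gid
        pg.member_lens[strain] = len(seq)
        library.append(pg)
        rep_seq.append(seq)
        index.add(seq)

    def try_place(strain: str, gid: str, seq: str, skip: set[int]) -> None:
        best_slot, best_aln = -1, None
        for slot in index.candidates(seq, relative=0.25)[:5]:
            if slot in skip:
                continue
            if min(len(seq), len(rep_seq[slot])) < (2.0 / 3.0) * max(len(seq), len(rep_seq[slot])):
                continue
            aln = fn(seq, rep_seq[slot])
            if not _passes_rules(aln, min_identity, min_coverage):
                continue
            if best_aln is None or aln.identity > best_aln.identity:
                best_slot, best_aln = slot, aln
        if best_aln is None:
            new_pangene(strain, gid, seq)
            return
        pg = library[best_slot]
        if strain in pg.members:
            # paralog conflict: keep the higher-identity member
            incumbent_gid = pg.members[strain]
            inc_aln = fn(seqs[(strain, incumbent_gid)], rep_seq[best_slot])
            if best_aln.identity > inc_aln.identity:
                pg.members[strain] = gid
                pg.member_lens[strain] = len(seq)
                try_place(strain, incumbent_gid, seqs[(strain, incumbent_gid)], skip | {best_slot})
            else:
                try_place(strain, gid, seq, skip | {best_slot})
            return
        pg.members[strain] = gid
        pg.member_lens[strain] = len(seq)
        if len(seq) > len(rep_seq[best_slot]):
            rep_seq[best_slot] = seq

    for gid, seq in order[0].genes:
        # the founding strain is still clustered against itself so that
        # intra-strain paralog pairs behave like in later strains
        try_place(order[0].strain_id, gid, seq, set())
    for genome in order[1:]:
        for gid, seq in genome.genes:
            try_place(genome.strain_id, gid, seq, set())

    # self-comparison pass: merge pangene pairs whose representatives match
    parent = list(range(len(library)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for slot in range(len(library)):
        for other in index.candidates(rep_seq[slot], relative=0.25)[:6]:
            if find(other) == find(slot):
                continue
            aln = fn(rep_seq[slot], rep_seq[other])
            if _passes_rules(aln, min_identity, min_coverage):
                a, b = sorted((find(slot), find(other)))
                parent[b] = a

    merged: dict[int, _LibraryPangene] = {}
    strays: list[tuple[str, str]] = []
    for slot, pg in enumerate(library):
        root = find(slot)
        if root not in merged:
            merged[root] = pg
            continue
        target = merged[root]
        for strain, gid in pg.members.items():
            if strain in target.members:
                # keep the member closer to the longer representative
                t_rep = rep_seq[root] if len(rep_seq[root]) >= len(rep_seq[slot]) else rep_seq[slot]
                keep_new = (
                    fn(seqs[(strain, gid)], t_rep).identity
                    > fn(seqs[(strain, target.members[strain])], t_rep).identity
                )
                if keep_new:
                    strays.append((strain, target.members[strain]))
                    target.members[strain] = gid
                    target.member_lens[strain] = pg.member_lens[strain]
                else:
                    strays.append((strain, gid))
            else:
                target.members[strain] = gid
                target.member_lens[strain] = pg.member_lens[strain]
    final = list(merged.values())
    for strain, gid in strays:  # displaced paralogs become singleton pangenes
        pg = _LibraryPangene()
        pg.members[strain] = gid
        pg.member_lens[strain] = len(seqs[(strain, gid)])
        final.append(pg)

    # length correction: drop members < 2/3 of the longest member
    n_strains = len(strain_ids)
    pangenes: list[Pangene] = []
    final.sort(key=lambda pg: min((pg.members[s], s) for s in pg.members))
    for i, pg in enumerate(final):
        longest = max(pg.member_lens.values())
        removed = [
            (s, g, "short")
            for s, g in sorted(pg.members.items())
            if pg.member_lens[s] < (2.0 / 3.0) * longest
        ]
        for s, _, _ in removed:
            del pg.members[s]
            del pg.member_lens[s]
        if not pg.members:  # cannot happen: the longest member survives
            continue
        rep_strain = max(pg.members, key=lambda s: (pg.member_lens[s], pg.members[s]))
        pangenes.append(
            Pangene(
                pangene_id=f"PG{i:05d}",
                members=dict(sorted(pg.members.items())),
                representative=(rep_strain, pg.members[rep_strain]),
                frequency=len(pg.members) / n_strains,
                removed_members=removed,
            )
        )
    pangenome = Pangenome(
        species_id=species_id or (genomes[0].species_id or "species"),
        strain_ids=strain_ids,
        pangenes=pangenes,
        identity_threshold=min_identity,
        sequences=seqs,
    )
    if run_threshold_check:
        pangenome.threshold_check = threshold_check(
            genomes, identity_threshold=min_identity, min_coverage=min_coverage, scorer=scorer
        )
    return pangenome


def classify_pangenes(pangenome: Pangenome, near_core_fraction: float = 0.75) -> Pangenome:
    """Label pangenes core (f = 1), near-core (near_core_fraction <= f < 1,
    boundary inclusive) or accessory (f < near_core_fraction), in place."""
    eps = 1e-12
    for p in pangenome.pangenes:
        if p.frequency >= 1.0 - eps:
            p.class_label = "core"
        elif p.frequency >= near_core_fraction - eps:
            p.class_label = "near_core"
        else:
            p.class_label = "accessory"
    return pangenome


# ---------------------------------------------------------------------------
# TSV input/output


def write_pangenome_tsv(pangenome: Pangenome, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"pangene_id": p.pangene_id, "strain_id": s, "gene_id": g, "class": p.class_label or ""}
        for p in pangenome.pangenes
        for s, g in p.members.items()
    ]
    pd.DataFrame(rows).to_csv(out / "pangenome.tsv", sep="\t", index=False)
    pangenome.presence_matrix().to_csv(out / "presence_absence.tsv", sep="\t")
    removed = [
        {"pangene_id": p.pangene_id, "strain_id": s, "gene_id": g, "reason": r}
        for p in pangenome.pangenes
        for s, g, r in p.removed_members
    ]
    pd.DataFrame(removed, columns=["pangene_id", "strain_id", "gene_id", "reason"]).to_csv(
        out / "removed_members.tsv", sep="\t", index=False
    )
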