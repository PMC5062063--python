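"""Per-pangene evolutionary metrics and their exclusion filters.

Three metrics summarize how expendable a gene looks before it is ever
lost: cross-species conservation (number of species with a hit at >= 40%
normalized identity NI = I*AL/QL), within-species constraint (a single
NG86 counting dN/dS per pangene, kept only when 0.0001 < w <= 2 and the
summed synonymous tree length is >= 0.001), and codon-usage bias (ENC',
Wright's effective number of codons adjusted for background nucleotide
composition; pangenes are dropped when the between-member coefficient of
variation exceeds 10% or any member is shorter than 100 codons). A
Fitch-parsimony ancestral reconstruction provides per-branch synonymous
divergence, averaged over core genes into adS, the clock proxy.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from . import codon as _codon
from .align import KmerIndex, quick_identity
from .codon import GAP_CODON
from .lossmap import BranchProfile
from .trees import Tree


# ---------------------------------------------------------------------------
# normalized identity and cross-species conservation


def normalized_identity(identity: float, alignment_length: float, query_length: float) -> float:
    """NI = I * AL / QL, capped at 100."""
    if query_length <= 0:
        raise ValueError("query length must be positive")
    if not 0 <= identity <= 100:
        raise ValueError("identity must be a percentage")
    if alignment_length <= 0:
        raise ValueError("alignment length must be positive")
    return min(100.0, identity * alignment_length / query_length)


class ReferenceProteinDB:
    """Species-labeled protein database with a k-mer candidate index."""

    def __init__(
        self,
        records: list[tuple[str, str, str]],
        k: int | None = None,
        sample: int | None = None,
    ):
        # records: (species, protein_id, sequence); k/sample tune the
        # candidate index (denser = sensitive to lower identities, slower)
        if not records:
            raise ValueError("empty reference database")
        self.records = records
        self.index = KmerIndex(
            [seq for _, _, seq in records], protein=True, k=k, sample=sample
        )

    def best_ni_per_species(
        self,
        query_protein: str,
        max_candidates: int = 150,
        ni_floor: float = 0.0,
    ) -> dict[str, float]:
        out: dict[str, float] = {}
        ql = len(query_protein)
        cands = self.index.candidates(query_protein, relative=0.05)[:max_candidates]
        for idx in cands:
            species, _, seq = self.records[idx]
            # NI <= 100 * matches / QL <= 100 * min(len) / QL: skip targets
            # that cannot reach the floor
            if ni_floor > 0 and 100.0 * min(ql, len(seq)) / ql < ni_floor:
                continue
            aln = quick_identity(query_protein, seq)
            ni = normalized_identity(aln.identity, aln.alignment_length, ql)
            if ni > out.get(species, -1.0):
                out[species] = ni
        return out


def load_reference_proteins(path) -> list[tuple[str, str, str]]:
    """Read a species-labeled protein FASTA (``species=`` header token)
    into (species, protein_id, sequence) records."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = None
        for token in rec.description.split():
            if token.startswith("species="):
                species = token.split("=", 1)[1]
        if species is None:
            raise ValueError(f"record {rec.id!r} lacks a species= header token")
        records.append((species, rec.id, str(rec.seq)))
    return records


def conservation_count(
    query_protein: str,
    db: ReferenceProteinDB | list[tuple[str, str, str]],
    ni_threshold: float = 40.0,
) -> int:
    """Number of species with >= 1 protein at NI >= threshold (each
    species counted once, however many strains of it hit)."""
    if not isinstance(db, ReferenceProteinDB):
        db = ReferenceProteinDB(db)
    per_species = db.best_ni_per_species(query_protein, ni_floor=ni_threshold)
    return sum(1 for ni in per_species.values() if ni >= ni_threshold)


# ---------------------------------------------------------------------------
# codon-aware multiple alignment


@dataclass
class CodonAlignment:
    """Aligned codon matrix; 64 = gap. Ungapping a row gives its input CDS."""

    rows: dict[str, np.ndarray]
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return 0 if not self.rows else len(next(iter(self.rows.values())))

    def ungapped(self, name: str) -> str:
        row = self.rows[name]
        return _codon.decode_codons(row[row != GAP_CODON])


def _mafft_protein(named_seqs: list[tuple[str, str]]) -> dict[str, str]:
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for i, (_, seq) in enumerate(named_seqs):
                fh.write(f">s{i}\n{seq}\n")
        res = subprocess.run(
            ["mafft", "--auto", "--quiet", "--amino", str(fasta)],
            capture_output=True, text=True, check=True,
        )
    aligned: list[str] = []
    for block in res.stdout.split(">")[1:]:
        lines = block.splitlines()
        aligned.append("".join(lines[1:]))
    return {name: aln for (name, _), aln in zip(named_seqs, aligned)}


def codon_msa(member_cds: dict[str, str]) -> CodonAlignment:
    """Translate / align proteins / back-translate to a codon alignment.

    Sequences with internal stops (genetic code 11) or lengths not a
    multiple of 3 are rejected per-sequence and reported. When all
    surviving proteins have equal length the alignment is gap-free by
    construction; otherwise the protein step runs through mafft.
    """
    rejected: list[tuple[str, str]] = []
    encoded: dict[str, np.ndarray] = {}  # body codons (terminal stop split off)
    tails: dict[str, int | None] = {}
    proteins: dict[str, str] = {}
    for name, cds in member_cds.items():
        try:
            codons = _codon.encode_cds(cds)
        except ValueError as exc:
            rejected.append((name, str(exc)))
            continue
        aa = _codon.translate_codons(codons)
        has_stop = aa.endswith("*")
        body = aa[:-1] if has_stop else aa
        if "*" in body:
            rejected.append((name, "internal stop codon"))
            continue
        encoded[name] = codons[:-1] if has_stop else codons
        tails[name] = int(codons[-1]) if has_stop else None
        proteins[name] = body
    if not encoded:
        return CodonAlignment({}, rejected)
    lengths = {len(p) for p in proteins.values()}
    if len(lengths) == 1:
        rows = {n: c.copy() for n, c in encoded.items()}
    else:
        aligned = _mafft_protein(sorted(proteins.items()))
        rows = {}
        for name, aln in aligned.items():
            src = encoded[name]
            row = np.full(len(aln), GAP_CODON, dtype=np.int16)
            j = 0
            for i, ch in enumerate(aln):
                if ch != "-":
                    row[i] = src[j]
                    j += 1
            if j != len(src):
                raise RuntimeError(f"back-translation mismatch for {name}")
            rows[name] = row
    if any(t is not None for t in tails.values()):  # terminal-stop column
        rows = {
            n: np.append(row, np.int16(tails[n] if tails[n] is not None else GAP_CODON))
            for n, row in rows.items()
        }
    return CodonAlignment(rows, rejected)


# ---------------------------------------------------------------------------
# dN/dS (NG86 counting)


@dataclass
class DnDsResult:
    omega: float | None
    ds_total: float | None
    included: bool
    reason: str = ""
    mean_dn: float | None = None
    mean_ds: float | None = None


def pangene_dnds(
    alignment: CodonAlignment,
    tree: Tree | None = None,
    omega_min: float = 1e-4,
    omega_max: float = 2.0,
    min_ds_total: float = 1e-3,
) -> DnDsResult:
    """A single counting-method dN/dS per pangene.

    Pairwise NG86 with Jukes-Cantor correction; omega is the ratio of the
    mean pairwise dN to the mean pairwise dS. The synonymous tree length
    ds_total comes from a non-negative least-squares fit of pairwise dS to
    the branches of ``tree`` (falling back to the mean pairwise dS when no
    usable tree is given). The inclusion flag applies the variation
    filters omega_min < w <= omega_max and ds_total >= min_ds_total.
    """
    names = sorted(alignment.rows)
    if len(names) < 2:
        return DnDsResult(None, None, False, "fewer than 2 sequences")
    pairs, dn_vals, ds_vals = [], [], []
    # restrict to columns that are sense codons in every sequence (so all
    # pairs are compared over the same sites) and run all pairs at once
    mat = np.stack([alignment.rows[n] for n in names])
    ok = _codon.VALID_CODON[mat].all(axis=0)
    mat = mat[:, ok]
    if mat.shape[1] == 0:
        return DnDsResult(None, None, False, "no comparable codon columns")
    dn_mat, ds_mat = _codon.ng86_all_pairs(mat)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            dn, ds = dn_mat[i, j], ds_mat[i, j]
            if dn == dn and ds == ds:  # not NaN
                pairs.append((a, names[j]))
                dn_vals.append(float(dn))
                ds_vals.append(float(ds))
    if not pairs:
        return DnDsResult(None, None, False, "saturated or empty pairwise distances")
    mean_dn, mean_ds = float(np.mean(dn_vals)), float(np.mean(ds_vals))
    ds_total = _ds_tree_length(pairs, ds_vals, tree) if tree is not None else mean_ds
    if mean_ds == 0.0:
        return DnDsResult(None, ds_total, False, "dS = 0: omega undefined", mean_dn, mean_ds)
    omega = mean_dn / mean_ds
    included = omega_min < omega <= omega_max and ds_total >= min_ds_total
    reason = "" if included else "failed omega/dS-tree-length filter"
    return DnDsResult(omega, ds_total, included, reason, mean_dn, mean_ds)


def _ds_tree_length(pairs, ds_vals, tree: Tree) -> float:
    branches = [n.id for n in tree.branches()]
    col = {b: i for i, b in enumerate(branches)}
    anc: dict[str, set[str]] = {}
    for leaf in tree.leaf_names():
        chain, node = set(), tree.node(leaf)
        while node.parent is not None:
            chain.add(node.id)
            node = node.parent
        anc[leaf] = chain
    rows = []
    for a, b in pairs:
        if a not in anc or b not in anc:
            return float(np.mean(ds_vals))
        on_path = anc[a] ^ anc[b]
        row = np.zeros(len(branches))
        for x in on_path:
            row[col[x]] = 1.0
        rows.append(row)
    A = np.array(rows)
    if A.size == 0 or np.linalg.matrix_rank(A) == 0:
        return float(np.mean(ds_vals))
    x, _ = nnls(A, np.array(ds_vals))
    return float(x.sum())


# ---------------------------------------------------------------------------
# ENC' (composition-adjusted effective number of codons)

_DEGREE_WEIGHT = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}  # code-11 family counts


def background_composition(sequences: list[str]) -> np.ndarray:
    """Nucleotide frequencies (A, C, G, T) over a set of sequences."""
    counts = np.zeros(4)
    for seq in sequences:
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for i, c in enumerate(b"ACGT"):
            counts[i] += int((arr == c).sum())
    if counts.sum() == 0:
        raise ValueError("no ACGT characters in background sequences")
    return counts / counts.sum()


def enc_prime(cds: str | np.ndarray, background: np.ndarray | None = None) -> float:
    """Novembre-style ENC': Wright's formula on composition-adjusted
    homozygosities F' = (chi2 + n - k) / (k * (n - 1)) per synonymous
    family, with expected codon proportions from the background
    nucleotide composition (uniform if omitted). Capped at 61."""
    codons = _codon.encode_cds(cds) if isinstance(cds, str) else np.asarray(cds)
    codons = codons[codons < 64]
    if len(codons) < 3 and isinstance(cds, str):
        raise ValueError("CDS shorter than 3 codons")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background composition must be 4 frequencies summing to 1")
    counts = np.bincount(codons, minlength=64).tolist()
    bg_list = bg.tolist()
    f_by_degree: dict[int, list[float]] = {k: [] for k in _DEGREE_WEIGHT}
    any_usable = False
    for aa, family in _codon.FAMILY_BY_AA.items():
        k = len(family)
        if k == 1:
            continue
        fam_counts = [counts[c] for c in family]
        n = sum(fam_counts)
        if n < 2:
            continue
        any_usable = True
        w = [bg_list[c >> 4] * bg_list[(c >> 2) & 3] * bg_list[c & 3] for c in family]
        w_sum = sum(w)
        chi2 = n * sum(
            (cnt / n - wi / w_sum) ** 2 / (wi / w_sum) for cnt, wi in zip(fam_counts, w)
        )
        f_prime = (chi2 + n - k) / (k * (n - 1))
        f_by_degree[k].append(max(f_prime, 1e-10))
    if not any_usable:
        raise ValueError("every synonymous family has < 2 codons: ENC' undefined")
    f_mean = {k: float(np.mean(v)) for k, v in f_by_degree.items() if v}
    # Wright's missing-degree handling: impute F3 from F2 and F4; any other
    # absent degree falls back to the mean of the observed degrees
    if 3 not in f_mean and 2 in f_mean and 4 in f_mean:
        f_mean[3] = (f_mean[2] + f_mean[4]) / 2.0
    overall = float(np.mean(list(f_mean.values())))
    nc = 2.0
    for k, weight in _DEGREE_WEIGHT.items():
        nc += weight / f_mean.get(k, overall)
    return min(nc, 61.0)


@dataclass
class CodonBiasResult:
    mean: float
    sd: float
    included: bool
    reason: str = ""


def pangene_codon_bias(
    enc_values: list[float],
    member_codon_lengths: list[int],
    max_cv: float = 0.10,
    min_codons: int = 100,
) -> CodonBiasResult:
    """Mean/SD of member ENC' values with the standard exclusions:
    coefficient of variation > 10% or any member < 100 codons."""
    if not enc_values:
        raise ValueError("no ENC' values")
    mean = float(np.mean(enc_values))
    sd = float(np.std(enc_values, ddof=1)) if len(enc_values) > 1 else 0.0
    if any(l < min_codons for l in member_codon_lengths):
        return CodonBiasResult(mean, sd, False, f"member shorter than {min_codons} codons")
    if mean > 0 and sd / mean > max_cv:
        return CodonBiasResult(mean, sd, False, f"ENC' CV > {max_cv:.0%}")
    return CodonBiasResult(mean, sd, True)


# ---------------------------------------------------------------------------
# per-branch synonymous divergence (adS)


def _lowest_set_bit(masks: np.ndarray) -> np.ndarray:
    low = masks & (~masks + np.uint64(1))
    # log2 of a power of two is exact in float64 up to 2^63
    return np.log2(low.astype(np.float64)).astype(np.int16)


def _fitch_states(tree: Tree, leaf_rows: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Fitch parsimony codon states for every node; ties toward the
    parent's state. Columns must be gap-free across all leaves."""
    n_cols = len(next(iter(leaf_rows.values())))
    masks: dict[str, np.ndarray] = {}
    one = np.uint64(1)
    for node in tree.postorder():
        if node.is_leaf:
            masks[node.id] = one << leaf_rows[node.id].astype(np.uint64)
        else:
            acc_and = acc_or = None
            for child in node.children:
                m = masks[child.id]
                acc_and = m if acc_and is None else acc_and & m
                acc_or = m if acc_or is None else acc_or | m
            masks[node.id] = np.where(acc_and != 0, acc_and, acc_or)
    states: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        mask = masks[node.id]
        if node.parent is None:
            states[node.id] = _lowest_set_bit(mask)
        else:
            parent = states[node.parent.id].astype(np.uint64)
            keep = (mask >> parent) & one
            lowest = _lowest_set_bit(mask)
            states[node.id] = np.where(keep == one, parent.astype(np.int16), lowest)
    return states


def branch_ds(
    tree: Tree,
    core_alignments: dict[str, CodonAlignment],
    omega_branch_max: float = 2.0,
) -> list[BranchProfile]:
    """Average synonymous divergence per branch (adS) over core genes.

    Per gene and branch, dS is the pathway-averaged synonymous difference
    count between Fitch-reconstructed endpoint states divided by the NG86
    synonymous site count of the parent sequence. Genes with dS = 0 or
    dN/dS > 2 on a branch are excluded from that branch's average.
    """
    leaves = tree.leaf_names()
    S_tab, N_tab = _codon.ng86_site_tables()
    Sd_tab, Nd_tab = _codon.ng86_diff_tables()
    per_branch: dict[str, list[float]] = {n.id: [] for n in tree.branches()}
    for pid, aln in sorted(core_alignments.items()):
        missing = set(leaves) - set(aln.rows)
        if missing:
            raise ValueError(f"alignment {pid} missing leaves {sorted(missing)}")
        rows = {name: aln.rows[name] for name in leaves}
        ok = np.ones(aln.n_columns, dtype=bool)
        for row in rows.values():
            ok &= row != GAP_CODON
            for stop in _codon.STOP_CODONS:
                ok &= row != stop
        rows = {name: row[ok] for name, row in rows.items()}
        if not rows[leaves[0]].size:
            continue
        states = _fitch_states(tree, rows)
        for node in tree.branches():
            a = states[node.parent.id]
            b = states[node.id]
            syn = float(Sd_tab[a, b].sum())
            non = float(Nd_tab[a, b].sum())
            s_sites = float(S_tab[a].sum())
            if s_sites <= 0:
                continue
            ds = syn / s_sites
            n_sites = float(N_tab[a].sum())
            dn = non / n_sites if n_sites > 0 else 0.0
            if ds == 0.0 or (ds > 0 and dn / ds > omega_branch_max):
                continue
            per_branch[node.id].append(ds)
    profiles = []
    for node in tree.branches():
        vals = per_branch[node.id]
        profiles.append(
            BranchProfile(
                node.id,
                n_losses=0,
                ads=float(np.mean(vals)) if vals else None,
                length=node.length,
                extra={"n_genes": len(vals)},
            )
        )
    return profiles
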