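"""Forward simulation of intra-species genome evolution with gene loss.

Generates the study conditions every downstream stage is tested against:
a pure-birth (Yule) species tree with an outgroup, an ancestral genome
whose genes fall into constraint classes, clocklike class-dependent gene
loss (per-branch loss probability ``1 - exp(-lambda_c * l)``), rare gene
gain by horizontal transfer (brand-new sequences, so they cluster as new
pangenes and populate the rare arm of the U-shaped frequency spectrum),
and codon-level sequence evolution in which synonymous proposals are
always accepted while nonsynonymous proposals are accepted with
probability ``omega_c`` — so the realized dN/dS of a class approaches its
target. Losses are irreversible within the ingroup (Dollo assumption) and
the outgroup experiences substitutions only, keeping rooting clean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import codon as _codon
from .pangenome import StrainGenome
from .trees import Node, Tree

OUTGROUP_ID = "OUT"
HGT_CLASS = "hgt"

ALL_AA = sorted(_codon.FAMILY_BY_AA)


def _default_classes() -> dict[str, int]:
    return {"constrained": 150, "relaxed": 90, "volatile": 60}


@dataclass
class SimConfig:
    """Study conditions for one simulated species.

    Rates are per unit branch length (the units of ``tree_depth``);
    ``subst_rate`` is proposed substitutions per codon per unit length.
    """

    n_strains: int = 20
    n_genes_per_class: dict[str, int] = field(default_factory=_default_classes)
    loss_rate_per_class: dict[str, float] = field(
        default_factory=lambda: {"constrained": 0.3, "relaxed": 2.0, "volatile": 6.0}
    )
    omega_per_class: dict[str, float] = field(
        default_factory=lambda: {"constrained": 0.05, "relaxed": 0.3, "volatile": 0.8}
    )
    codon_bias_per_class: dict[str, float] = field(
        default_factory=lambda: {"constrained": 0.7, "relaxed": 0.4, "volatile": 0.1}
    )
    hgt_rate: float = 100.0
    hgt_omega: float = 1.0
    subst_rate: float = 0.5
    tree_depth: float = 0.05
    gene_length_range: tuple[int, int] = (300, 900)  # codons; >= 100 always
    seed: int = 0
    #: when set, loss may occur only on these branch ids (used e.g. for
    #: non-clocklike negative controls with loss confined to one branch)
    loss_branch_whitelist: list[str] | None = None
    # synthetic cross-species reference proteins (conservation analysis)
    n_ref_species: int = 40
    ref_presence_per_class: dict[str, float] = field(
        default_factory=lambda: {"constrained": 0.7, "relaxed": 0.3, "volatile": 0.1, HGT_CLASS: 0.05}
    )
    ref_divergence: tuple[float, float] = (0.15, 0.55)

    def validate(self) -> None:
        if self.n_strains < 3:
            raise ValueError("n_strains must be >= 3")
        classes = set(self.n_genes_per_class)
        for name, table in [
            ("loss_rate_per_class", self.loss_rate_per_class),
            ("omega_per_class", self.omega_per_class),
            ("codon_bias_per_class", self.codon_bias_per_class),
        ]:
            missing = classes - set(table)
            if missing:
                raise ValueError(f"{name} missing classes {sorted(missing)}")
        rates = (
            [self.hgt_rate, self.subst_rate, self.tree_depth]
            + list(self.loss_rate_per_class.values())
            + list(self.omega_per_class.values())
        )
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        for w in self.codon_bias_per_class.values():
            if not 0 <= w <= 1:
                raise ValueError("codon_bias_per_class values must be in [0, 1]")
        lo, hi = self.gene_length_range
        if lo < 100 or hi < lo:
            raise ValueError("gene_length_range must satisfy 100 <= lo <= hi")


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    tree: Tree  # full tree including the outgroup leaf
    ingroup_tree: Tree
    loss_events: list[tuple[str, str]]  # (gene_id, branch_id)
    gain_events: list[tuple[str, str]]
    gene_class: dict[str, str]
    branch_loss_counts: dict[str, int]
    presence: dict[str, set[str]]  # strain -> gene ids present
    ancestral_proteins: dict[str, str]

    def presence_vector(self, gene_id: str) -> dict[str, bool]:
        return {s: gene_id in genes for s, genes in self.presence.items()}

    def loss_branches(self, gene_id: str) -> set[str]:
        return {b for g, b in self.loss_events if g == gene_id}


# ---------------------------------------------------------------------------
# species tree


def sample_species_tree(n_strains: int, tree_depth: float, seed: int) -> Tree:
    """Pure-birth topology, i.i.d. exponential branch lengths rescaled so
    the mean ingroup root-to-tip depth equals ``tree_depth``, plus an
    outgroup leaf attached above the ingroup root on a longer branch."""
    if n_strains < 3:
        raise ValueError("n_strains must be >= 3")
    if tree_depth <= 0:
        raise ValueError("tree_depth must be > 0")
    rng = np.random.default_rng(seed)
    counter = [0]

    def new_internal() -> Node:
        counter[0] += 1
        return Node(f"N{counter[0]}")

    root = new_internal()
    leaves = [Node("S000", parent=root), Node("S001", parent=root)]
    root.children = list(leaves)
    while len(leaves) < n_strains:
        i = int(rng.integers(len(leaves)))
        old = leaves[i]
        split = new_internal()
        split.parent = old.parent
        old.parent.children[old.parent.children.index(old)] = split
        child = Node(f"S{len(leaves):03d}", parent=split)
        old.parent = split
        split.children = [old, child]
        leaves.append(child)
        leaves.sort(key=lambda n: n.id)
    ingroup = Tree(root)
    for node in ingroup.branches():
        node.length = float(rng.exponential(1.0))
    depths = ingroup.depths()
    mean_depth = float(np.mean([depths[leaf] for leaf in ingroup.leaf_names()]))
    scale = tree_depth / mean_depth
    for node in ingroup.branches():
        node.length *= scale
    # attach outgroup above the ingroup root
    top = Node("ROOT")
    root.parent = top
    root.length = 0.5 * tree_depth
    out = Node(OUTGROUP_ID, 3.0 * tree_depth, parent=top)
    top.children = [root, out]
    return Tree(top)


def ingroup_subtree(tree: Tree, outgroup: str = OUTGROUP_ID) -> Tree:
    """Drop the outgroup leaf; the ingroup root becomes the root."""
    return tree.prune_leaf(outgroup)


# ---------------------------------------------------------------------------
# sequence generation and evolution


def _preferred_codon(aa: str) -> int:
    return _codon.FAMILY_BY_AA[aa][0]


def _sample_gene(rng: np.random.Generator, n_codons: int, bias: float) -> np.ndarray:
    """Codon-index array for a new gene; synonymous usage skewed toward one
    preferred codon per family with mixture weight ``bias``."""
    aas = rng.choice(ALL_AA, size=n_codons)
    out = np.empty(n_codons, dtype=np.int16)
    for i, aa in enumerate(aas):
        fam = _codon.FAMILY_BY_AA[aa]
        if bias > 0 and rng.random() < bias:
            out[i] = fam[0]
        else:
            out[i] = fam[int(rng.integers(len(fam)))]
    return out


def _mutate_gene(
    rng: np.random.Generator, codons: np.ndarray, n_proposals: int, omega: float
) -> np.ndarray:
    """Apply proposed single-nucleotide changes; synonymous accepted,
    stop-creating rejected, nonsynonymous accepted with prob omega."""
    seq = codons.copy()
    n = len(seq)
    aa = _codon.AA_BY_CODON
    for _ in range(n_proposals):
        pos = int(rng.integers(n))
        ntpos = int(rng.integers(3))
        shift = (2 - ntpos) * 2
        cur = int(seq[pos])
        old_nt = (cur >> shift) & 3
        new_nt = int(rng.integers(3))
        if new_nt >= old_nt:
            new_nt += 1
        new = cur ^ ((old_nt ^ new_nt) << shift)
        if new in _codon.STOP_CODONS:
            continue
        if aa[new] == aa[cur]:
            seq[pos] = new
        elif rng.random() < min(1.0, omega):
            seq[pos] = new
    return seq


def evolve_genomes(
    tree: Tree, config: SimConfig
) -> tuple[list[StrainGenome], StrainGenome, SimTruth]:
    """Evolve genomes down ``tree`` (from :func:`sample_species_tree`)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    lo, hi = config.gene_length_range

    gene_class: dict[str, str] = {}
    ancestral: dict[str, np.ndarray] = {}
    for cls, count in config.n_genes_per_class.items():
        bias = config.codon_bias_per_class[cls]
        for i in range(count):
            gid = f"{cls}_g{i:04d}"
            gene_class[gid] = cls
            ancestral[gid] = _sample_gene(rng, int(rng.integers(lo, hi + 1)), bias)

    loss_events: list[tuple[str, str]] = []
    gain_events: list[tuple[str, str]] = []
    branch_counts: dict[str, int] = {n.id: 0 for n in tree.branches()}
    hgt_counter = [0]
    genomes_at_leaf: dict[str, dict[str, np.ndarray]] = {}

    def descend(node: Node, genome: dict[str, np.ndarray]) -> None:
        if node.parent is not None:
            ell = node.length
            genome = dict(genome)
            loss_allowed = (
                config.loss_branch_whitelist is None
                or node.id in config.loss_branch_whitelist
            )
            if node.id != OUTGROUP_ID:
                # clocklike loss, class-dependent rate; HGT genes exempt
                if loss_allowed:
                    for gid in list(genome):
                        cls = gene_class[gid]
                        if cls == HGT_CLASS:
                            continue
                        lam = config.loss_rate_per_class[cls]
                        if lam > 0 and rng.random() < -np.expm1(-lam * ell):
                            del genome[gid]
                            loss_events.append((gid, node.id))
                            branch_counts[node.id] += 1
                # horizontal gains: unrelated new sequences
                for _ in range(rng.poisson(config.hgt_rate * ell)):
                    gid = f"hgt_g{hgt_counter[0]:04d}"
                    hgt_counter[0] += 1
                    gene_class[gid] = HGT_CLASS
                    genome[gid] = _sample_gene(rng, int(rng.integers(lo, hi + 1)), 0.0)
                    gain_events.append((gid, node.id))
            # substitutions
            mu = config.subst_rate
            if mu > 0 and ell > 0:
                for gid, seq in genome.items():
                    n_prop = int(rng.poisson(mu * ell * len(seq)))
                    if n_prop:
                        cls = gene_class[gid]
                        omega = config.hgt_omega if cls == HGT_CLASS else config.omega_per_class[cls]
                        genome[gid] = _mutate_gene(rng, seq, n_prop, omega)
        if node.is_leaf:
            genomes_at_leaf[node.id] = genome
        else:
            for child in node.children:
                descend(child, genome)

    descend(tree.root, ancestral)

    ingroup_ids = sorted(s for s in genomes_at_leaf if s != OUTGROUP_ID)

    def to_strain(strain_id: str) -> StrainGenome:
        genes = [
            (gid, _codon.decode_codons(seq))
            for gid, seq in sorted(genomes_at_leaf[strain_id].items())
        ]
        return StrainGenome(strain_id=strain_id, genes=genes, species_id="sim")

    genomes = [to_strain(s) for s in ingroup_ids]
    outgroup = to_strain(OUTGROUP_ID)
    truth = SimTruth(
        tree=tree,
        ingroup_tree=ingroup_subtree(tree),
        loss_events=loss_events,
        gain_events=gain_events,
        gene_class=gene_class,
        branch_loss_counts=branch_counts,
        presence={s: set(genomes_at_leaf[s]) for s in ingroup_ids},
        ancestral_proteins={g: _codon.translate_codons(seq) for g, seq in ancestral.items()},
    )
    return genomes, outgroup, truth


def simulate(config: SimConfig) -> tuple[list[StrainGenome], StrainGenome, SimTruth]:
    """Convenience wrapper: sample a tree and evolve genomes along it."""
    config.validate()
    tree = sample_species_tree(config.n_strains, config.tree_depth, config.seed)
    return evolve_genomes(tree, config)


# ---------------------------------------------------------------------------
# synthetic reference databases


def reference_protein_db(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> list[tuple[str, str, str]]:
    """Synthetic cross-species protein database for conservation analysis.

    Each ancestral gene is planted, diverged, into a class-dependent number
    of pseudo-species so that more constrained classes are conserved in
    more species. Returns (species_label, protein_id, sequence) records.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    lo, hi = config.ref_divergence
    records: list[tuple[str, str, str]] = []
    species = [f"refsp{i:03d}" for i in range(config.n_ref_species)]
    for gid, protein in sorted(truth.ancestral_proteins.items()):
        p = config.ref_presence_per_class.get(truth.gene_class[gid], 0.05)
        hosts = [sp for sp in species if rng.random() < p]
        for sp in hosts:
            div = rng.uniform(lo, hi)
            aa = np.array(list(protein))
            mask = rng.random(len(aa)) < div
            if mask.any():
                aa[mask] = rng.choice(ALL_AA, size=int(mask.sum()))
            records.append((sp, f"{sp}|{gid}", "".join(aa)))
    return records


DEFAULT_CATEGORY_BY_CLASS = {
    "constrained": [("housekeeping", 0.8), ("metabolism", 0.2)],
    "relaxed": [("metabolism", 0.5), ("transport", 0.5)],
    "volatile": [("defense", 0.5), ("unknown", 0.5)],
    HGT_CLASS: [("unknown", 1.0)],
}


def functional_label_db(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> list[tuple[str, str, str]]:
    """Synthetic functional-category database: (category, label_id, protein)."""
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    records = []
    for gid, protein in sorted(truth.ancestral_proteins.items()):
        choices = DEFAULT_CATEGORY_BY_CLASS.get(truth.gene_class[gid], [("unknown", 1.0)])
        cats, weights = zip(*choices)
        cat = str(rng.choice(cats, p=np.array(weights) / sum(weights)))
        records.append((cat, f"lbl|{gid}", protein))
    return records


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(
    genomes: list[StrainGenome],
    outgroup: StrainGenome,
    truth: SimTruth,
    out_dir: str | Path,
) -> dict:
    """Write FASTA per strain, truth TSVs, Newick trees and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_files = []
    for genome in [*genomes, outgroup]:
        path = out / f"{genome.strain_id}.fasta"
        with open(path, "w") as fh:
            for gid, seq in genome.genes:
                fh.write(f">{gid} strain={genome.strain_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        fasta_files.append(path.name)
    with open(out / "loss_events.tsv", "w") as fh:
        fh.write("gene_id\tbranch_id\n")
        for gid, bid in truth.loss_events:
            fh.write(f"{gid}\t{bid}\n")
    with open(out / "gain_events.tsv", "w") as fh:
        fh.write("gene_id\tbranch_id\n")
        for gid, bid in truth.gain_events:
            fh.write(f"{gid}\t{bid}\n")
    with open(out / "gene_class.tsv", "w") as fh:
        fh.write("gene_id\tclass\n")
        for gid, cls in sorted(truth.gene_class.items()):
            fh.write(f"{gid}\t{cls}\n")
    (out / "tree.nwk").write_text(truth.tree.to_newick() + "\n")
    (out / "ingroup_tree.nwk").write_text(truth.ingroup_tree.to_newick() + "\n")
    manifest = {
        "strains": [g.strain_id for g in genomes],
        "outgroup": outgroup.strain_id,
        "fasta_files": fasta_files,
        "tree": "tree.nwk",
        "ingroup_tree": "ingroup_tree.nwk",
        "truth_tables": ["loss_events.tsv", "gain_events.tsv", "gene_class.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_fixture(fixture_dir: str | Path) -> tuple[list[StrainGenome], StrainGenome, Tree]:
    """Re-read a written fixture (genomes, outgroup, full tree)."""
    src = Path(fixture_dir)
    manifest = json.loads((src / "manifest.json").read_text())

    def read_fasta(strain_id: str) -> StrainGenome:
        genes: list[tuple[str, str]] = []
        gid, chunks = None, []
        with open(src / f"{strain_id}.fasta") as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if gid is not None:
                        genes.append((gid, "".join(chunks)))
                    gid, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if gid is not None:
            genes.append((gid, "".join(chunks)))
        return StrainGenome(strain_id=strain_id, genes=genes, species_id="sim")

    genomes = [read_fasta(s) for s in manifest["strains"]]
    outgroup = read_fasta(manifest["outgroup"])
    tree = Tree.from_newick((src / manifest["tree"]).read_text())
    return genomes, outgroup, tree


def config_to_json(config: SimConfig) -> str:
    return json.dumps(asdict(config), indent=2, sort_keys=True)


def config_from_json(text: str) -> SimConfig:
    data = json.loads(text)
    for key in ("gene_length_range", "ref_divergence"):
        if key in data:
            data[key] = tuple(data[key])
    return SimConfig(**data)
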