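"""End-to-end orchestration: simulate/load -> pangenome -> tree -> loss
mapping -> metrics -> statistics, with one reproducible report.

Every stage writes plain TSV/Newick/JSON artifacts when an output
directory is given, and the report carries the full serialized
configuration, Table-1-shaped summary counts (core / near-core /
single-loss / multiple-loss) and the statistics tables. Identical config
and seed give an identical report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import simulate as _simulate
from . import stats as _stats
from .lossmap import branch_loss_table, dollo_place
from .pangenome import (
    Pangenome,
    StrainGenome,
    build_pangenome,
    classify_pangenes,
    write_pangenome_tsv,
)
from .phylogeny import compute_and_matrix, filter_nonrecombining, nj_tree, trimmed_tree
from .trees import Tree


@dataclass
class RunConfig:
    """All thresholds of the analysis, defaulting to the printed ones."""

    sim: _simulate.SimConfig | None = None
    fixture_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0
    min_identity: float = 80.0
    min_coverage: float = 0.70
    near_core_fraction: float = 0.75
    ni_threshold: float = 40.0
    omega_min: float = 1e-4
    omega_max: float = 2.0
    min_ds_total: float = 1e-3
    enc_max_cv: float = 0.10
    enc_min_codons: int = 100
    ani_min_identity: float = 30.0
    ani_min_coverage: float = 0.70
    run_threshold_check: bool = True
    with_reference_db: bool = True
    compute_metrics: bool = True  # loss mapping only when False
    ads_max_genes: int = 200

    def to_json(self) -> str:
        data = asdict(self)
        return json.dumps(data, indent=2, sort_keys=True, default=list)


@dataclass
class RunReport:
    config: dict
    counts: dict
    threshold_check: dict | None
    fig1_stats: list[dict]
    clock_test: dict | None
    outputs: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage
        self.cause = exc


class PipelineResult:
    """In-memory handles to every intermediate of a run."""

    def __init__(self) -> None:
        self.genomes: list[StrainGenome] = []
        self.outgroup: StrainGenome | None = None
        self.truth = None
        self.pangenome: Pangenome | None = None
        self.matrix = None
        self.tree: Tree | None = None
        self.assignments = []
        self.branch_profiles = []
        self.metric_table: pd.DataFrame | None = None
        self.fig1 = []
        self.clock = None
        self.report: RunReport | None = None


def _presence_vector(pangene, strain_ids) -> dict[str, bool]:
    return {s: s in pangene.members for s in strain_ids}


def run_all(
    config: RunConfig,
    reference_db: list[tuple[str, str, str]] | None = None,
) -> PipelineResult:
    """Execute the full analysis; see module docstring."""
    res = PipelineResult()
    notes: list[str] = []

    # -- stage: input -------------------------------------------------------
    try:
        if config.sim is not None:
            genomes, outgroup, truth = _simulate.simulate(config.sim)
            res.truth = truth
            if reference_db is None and config.with_reference_db:
                reference_db = _simulate.reference_protein_db(truth, config.sim)
        elif config.fixture_dir is not None:
            genomes, outgroup, _ = _simulate.read_fixture(config.fixture_dir)
        else:
            raise ValueError("config needs either sim or fixture_dir")
        res.genomes, res.outgroup = genomes, outgroup
    except Exception as exc:
        raise StageError("input", exc) from exc

    # -- stage: pangenome ---------------------------------------------------
    try:
        pangenome = build_pangenome(
            genomes,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            seed=config.seed,
            run_threshold_check=config.run_threshold_check,
        )
        classify_pangenes(pangenome, config.near_core_fraction)
        res.pangenome = pangenome
    except Exception as exc:
        raise StageError("pangenome", exc) from exc
    by_class = pangenome.by_class()
    core = by_class.get("core", [])
    near_core = by_class.get("near_core", [])

    # -- stage: tree --------------------------------------------------------
    try:
        core_alignments = {
            p.pangene_id: _metrics.codon_msa(pangenome.member_seqs(p)) for p in core
        }
        aligned_str = {
            pid: {s: _decode_row(aln.rows[s]) for s in aln.rows}
            for pid, aln in core_alignments.items()
            if aln.rows
        }
        nonrecomb = filter_nonrecombining(aligned_str)
        matrix = compute_and_matrix(
            genomes,
            pangenome,
            nonrecomb or [p.pangene_id for p in core],
            outgroup=outgroup,
            min_identity=config.ani_min_identity,
            min_coverage=config.ani_min_coverage,
        )
        tree = nj_tree(matrix, outgroup.strain_id)
        res.matrix, res.tree = matrix, tree
        if not nonrecomb:
            notes.append("no core pangene passed the recombination screen; used all core")
    except Exception as exc:
        raise StageError("tree", exc) from exc

    # -- stage: loss mapping ------------------------------------------------
    try:
        assignments = [
            dollo_place(tree, _presence_vector(p, pangenome.strain_ids), p.pangene_id)
            for p in near_core
        ]
        profiles = branch_loss_table(assignments, tree)
        res.assignments, res.branch_profiles = assignments, profiles
    except Exception as exc:
        raise StageError("loss_mapping", exc) from exc

    # -- stage: metrics -----------------------------------------------------
    if config.compute_metrics:
        try:
            metric_rows = _compute_metrics(config, pangenome, matrix, tree, assignments,
                                           core, near_core, reference_db, core_alignments,
                                           nonrecomb, profiles, notes)
            res.metric_table = pd.DataFrame(metric_rows)
        except Exception as exc:
            raise StageError("metrics", exc) from exc

        # -- stage: statistics ----------------------------------------------
        try:
            fig1, clock = _compute_stats(res.metric_table, profiles, notes)
            res.fig1, res.clock = fig1, clock
        except Exception as exc:
            raise StageError("statistics", exc) from exc
    else:
        res.metric_table = pd.DataFrame()
        notes.append("metrics stage disabled by config")

    # -- stage: report ------------------------------------------------------
    loss_class = {a.pangene_id: a.loss_class for a in res.assignments}
    counts = {
        "genomes": len(genomes),
        "pangenes": len(pangenome.pangenes),
        "core": len(core),
        "near_core": len(near_core),
        "accessory": len(by_class.get("accessory", [])),
        "single_loss": sum(1 for c in loss_class.values() if c == "single_loss"),
        "multiple_loss": sum(1 for c in loss_class.values() if c == "multiple_loss"),
        "total_loss_events": sum(a.loss_count for a in res.assignments),
    }
    report = RunReport(
        config=json.loads(config.to_json()),
        counts=counts,
        threshold_check=(
            {"fraction_ge_threshold": pangenome.threshold_check[0],
             "passed": bool(pangenome.threshold_check[1])}
            if pangenome.threshold_check
            else None
        ),
        fig1_stats=[asdict(c) for c in res.fig1],
        clock_test=(
            {"rho": res.clock.rho, "pvalue": res.clock.pvalue, "n_branches": res.clock.n_branches}
            if res.clock
            else None
        ),
        notes=notes,
    )
    res.report = report
    if config.out_dir:
        _write_outputs(config, res)
    return res


def _decode_row(row) -> str:
    from .codon import decode_codons

    return decode_codons(row)


def _compute_metrics(config, pangenome, matrix, tree, assignments, core, near_core,
                     reference_db, core_alignments, nonrecomb, profiles, notes):
    loss_class = {a.pangene_id: a.loss_class for a in assignments}
    refdb = _metrics.ReferenceProteinDB(reference_db) if reference_db else None
    bg_by_strain = {
        s: _metrics.background_composition(
            [seq for (st, _), seq in pangenome.sequences.items() if st == s]
        )
        for s in pangenome.strain_ids
    }
    tree_cache: dict[frozenset, object] = {}
    rows = []
    for p in core + near_core:
        group = "core" if p.class_label == "core" else loss_class.get(p.pangene_id)
        entry = {
            "pangene_id": p.pangene_id,
            "class": p.class_label,
            "group": group,
            "frequency": p.frequency,
        }
        member_seqs = pangenome.member_seqs(p)
        # conservation
        if refdb is not None:
            rep_seq = pangenome.sequences[p.representative]
            try:
                rep_protein = _protein_of(rep_seq)
                entry["n_species"] = _metrics.conservation_count(
                    rep_protein, refdb, config.ni_threshold
                )
            except ValueError:
                entry["n_species"] = None
        # dN/dS on the strains still carrying the gene, trimmed tree
        aln = core_alignments.get(p.pangene_id) or _metrics.codon_msa(member_seqs)
        sub_tree = None
        present = sorted(p.members)
        if len(present) >= 3:
            key = frozenset(present)
            if key not in tree_cache:
                try:
                    tree_cache[key] = (
                        tree
                        if len(present) == len(pangenome.strain_ids)
                        else trimmed_tree(matrix, present, matrix.labels[-1])
                    )
                except ValueError:
                    tree_cache[key] = None
            sub_tree = tree_cache[key]
        dnds = _metrics.pangene_dnds(
            aln, sub_tree, config.omega_min, config.omega_max, config.min_ds_total
        )
        entry.update(
            omega=dnds.omega, ds_total=dnds.ds_total,
            included_omega=dnds.included, omega_reason=dnds.reason,
        )
        # ENC'
        enc_vals, lens = [], []
        for s, seq in member_seqs.items():
            lens.append(len(seq) // 3)
            try:
                enc_vals.append(_metrics.enc_prime(seq, bg_by_strain[s]))
            except ValueError:
                pass
        if enc_vals:
            bias = _metrics.pangene_codon_bias(
                enc_vals, lens, config.enc_max_cv, config.enc_min_codons
            )
            entry.update(
                enc_prime_mean=bias.mean, enc_prime_sd=bias.sd,
                included_enc=bias.included, enc_reason=bias.reason,
            )
        rows.append(entry)
    # per-branch adS over (non-recombining) core genes
    ads_genes = sorted(nonrecomb)[: config.ads_max_genes] or sorted(core_alignments)[: config.ads_max_genes]
    usable = {pid: core_alignments[pid] for pid in ads_genes if core_alignments[pid].rows}
    if usable:
        ads_profiles = _metrics.branch_ds(tree, usable, config.omega_max)
        ads_by_branch = {p.branch_id: p.ads for p in ads_profiles}
        for prof in profiles:
            prof.ads = ads_by_branch.get(prof.branch_id)
    else:
        notes.append("no usable core alignments for adS")
    return rows


def _protein_of(cds: str) -> str:
    from .codon import encode_cds, translate_codons

    aa = translate_codons(encode_cds(cds))
    return aa[:-1] if aa.endswith("*") else aa


def _compute_stats(metric_table: pd.DataFrame, profiles, notes):
    fig1 = []
    clock = None
    if metric_table is None or metric_table.empty or "group" not in metric_table:
        notes.append("no pangenes for statistics")
        return fig1, clock
    df = metric_table[metric_table["group"].notna()]

    def groups_of(col: str, include_col: str | None = None) -> dict[str, list[float]]:
        out: dict[str, list[float]] = {}
        if col not in df:
            return out
        sub = df
        if include_col and include_col in df:
            sub = df[df[include_col].fillna(False).astype(bool)]
        for grp, chunk in sub.groupby("group"):
            vals = chunk[col].dropna().tolist()
            if vals:
                out[grp] = vals
        return out

    for metric, col, inc in [
        ("conservation", "n_species", None),
        ("omega", "omega", "included_omega"),
        ("enc_prime", "enc_prime_mean", "included_enc"),
    ]:
        grps = groups_of(col, inc)
        if len(grps) >= 2:
            fig1.extend(_stats.fig1_comparisons(metric, grps))
        else:
            notes.append(f"not enough groups for {metric} comparisons")
    try:
        clock = _stats.spearman_clock_test(profiles)
    except ValueError as exc:
        notes.append(f"clock test skipped: {exc}")
    return fig1, clock


def _write_outputs(config: RunConfig, res: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pangenome_tsv(res.pangenome, out)
    res.matrix.to_phylip(out / "and_matrix.phylip")
    (out / "species_tree.nwk").write_text(res.tree.to_newick() + "\n")
    pd.DataFrame(
        [
            {
                "pangene_id": a.pangene_id,
                "loss_class": a.loss_class,
                "loss_count": a.loss_count,
                "loss_branches": ",".join(sorted(a.loss_branches)),
            }
            for a in res.assignments
        ]
    ).to_csv(out / "loss_assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"branch_id": p.branch_id, "n_losses": p.n_losses,
             "ads": p.ads, "length": p.length}
            for p in res.branch_profiles
        ]
    ).to_csv(out / "branch_profile.tsv", sep="\t", index=False)
    if res.metric_table is not None:
        res.metric_table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(c) for c in res.fig1]).to_csv(
        out / "fig1_stats.tsv", sep="\t", index=False
    )
    res.report.outputs = {"dir": str(out)}
    (out / "report.json").write_text(res.report.to_json() + "\n")
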