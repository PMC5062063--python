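"""Rank statistics for the gene-loss comparisons.

Three tests drive the analysis: non-paired one-sided Mann-Whitney U for
the core / single-loss / multiple-loss metric comparisons, a one-sided
Spearman rank correlation of per-branch loss counts against adS (the
clocklike-loss test), and a two-tailed Wilcoxon signed-rank test (the
standard paired rank analogue) for per-species functional-category
percentages. Exact small-sample p-values are used where no ties allow
it; otherwise normal/t approximations with tie and continuity
corrections apply.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .align import quick_identity
from .lossmap import BranchProfile

EXACT_MW_LIMIT = 12  # exact enumeration when n_a + n_b <= 12 and no ties
EXACT_WILCOXON_LIMIT = 15
EXACT_SPEARMAN_LIMIT = 8


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    sample_a, sample_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (value for sample_a) and its p-value.

    Exact p by enumeration of labelings when n_a + n_b <= 12 with no
    ties; otherwise normal approximation with tie and continuity
    corrections. ``alternative`` in {"less", "greater", "two-sided"}.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    small = a.size + b.size <= EXACT_MW_LIMIT and not _has_ties(a, b)
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if small else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def paired_signed_rank(values_a, values_b) -> float:
    """Two-tailed Wilcoxon signed-rank p-value over paired vectors.

    Zero differences are dropped; all-zero input returns p = 1. Exact
    null by sign enumeration up to 15 nonzero pairs (ties get average
    ranks), normal approximation beyond.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    diff = diff[diff != 0]
    if diff.size == 0:
        return 1.0
    small = diff.size <= EXACT_WILCOXON_LIMIT
    res = sps.wilcoxon(diff, method="exact" if small else "approx")
    return float(res.pvalue)


@dataclass
class ClockTest:
    rho: float
    pvalue: float
    n_branches: int
    pairs: list[tuple[float, int]] = field(default_factory=list)


def _exact_spearman_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (positive) exact permutation p for Spearman rho."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(ry):
        r = float(np.corrcoef(rx, np.array(perm))[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def spearman_clock_test(branch_profiles: list[BranchProfile]) -> ClockTest:
    """One-sided Spearman test of per-branch loss counts increasing with
    adS. Branches with undefined adS are dropped; exact permutation p for
    <= 8 usable branches, t-approximation beyond."""
    pairs = [(p.ads, p.n_losses) for p in branch_profiles if p.ads is not None]
    if len(pairs) < 4:
        raise ValueError(f"only {len(pairs)} branches with defined adS (need >= 4)")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ClockTest(0.0, 1.0, len(pairs), pairs)
    rho = float(sps.spearmanr(x, y).statistic)
    if len(pairs) <= EXACT_SPEARMAN_LIMIT:
        p = _exact_spearman_greater(x, y)
    else:
        p = float(sps.spearmanr(x, y, alternative="greater").pvalue)
    return ClockTest(rho, p, len(pairs), pairs)


@dataclass
class GroupComparison:
    metric: str
    comparison: str  # e.g. "core_vs_single_loss"
    alternative: str
    U: float
    pvalue: float
    n_a: int
    n_b: int


# the directions the analysis tests by default: conservation and codon
# bias *decrease* with loss count on the metric scale means conservation
# counts fall and ENC' rises; omega (less constraint) rises
FIG1_DIRECTIONS = {
    "conservation": "greater",  # core > single > multiple
    "omega": "less",  # core < single < multiple
    "enc_prime": "less",  # core < single < multiple (lower ENC' = more bias)
}


def fig1_comparisons(
    metric_name: str,
    groups: dict[str, list[float]],
    alternative: str | None = None,
    order: tuple[str, str, str] = ("core", "single_loss", "multiple_loss"),
) -> list[GroupComparison]:
    """The adjacent group comparisons (core vs single, single vs multiple)
    with the metric's default one-sided alternative."""
    alt = alternative or FIG1_DIRECTIONS.get(metric_name, "two-sided")
    out = []
    for a, b in zip(order, order[1:]):
        sa, sb = groups.get(a, []), groups.get(b, [])
        if not sa or not sb:
            continue
        U, p = mann_whitney_u(sa, sb, alternative=alt)
        out.append(GroupComparison(metric_name, f"{a}_vs_{b}", alt, U, p, len(sa), len(sb)))
    return out


# ---------------------------------------------------------------------------
# functional-category enrichment


def assign_labels(
    representatives: dict[str, str],
    label_db: list[tuple[str, str, str]],
    min_identity: float = 70.0,
    min_query_coverage: float = 2.0 / 3.0,
) -> dict[str, str | None]:
    """Category per pangene: best hit in the label database at >= 70%
    identity across >= 2/3 of the query; None when nothing qualifies."""
    if not label_db:
        raise ValueError("empty label database")
    from .align import KmerIndex

    index = KmerIndex([seq for _, _, seq in label_db], protein=True)
    out: dict[str, str | None] = {}
    for pid, query in representatives.items():
        best: tuple[float, str] | None = None
        for idx in index.candidates(query)[:20]:
            cat, _, seq = label_db[idx]
            aln = quick_identity(query, seq)
            # global alignment: the aligned span of the query is the part
            # matched against target residues
            cov = min(1.0, min(len(query), len(seq)) / len(query))
            if aln.identity >= min_identity and cov >= min_query_coverage:
                if best is None or aln.identity > best[0]:
                    best = (aln.identity, cat)
        out[pid] = best[1] if best else None
    return out


def function_enrichment(
    per_species_labels: list[tuple[dict[str, str | None], dict[str, str | None]]],
) -> dict[str, dict]:
    """Per-category paired comparison of core vs near-core label
    percentages across species.

    Input: one (core_labels, near_core_labels) pair of
    pangene -> category maps per species; unlabeled pangenes stay in the
    denominators. Output per category: per-species percentage vectors and
    the two-tailed signed-rank p-value.
    """
    if len(per_species_labels) < 2:
        raise ValueError("paired test needs >= 2 species")
    categories = sorted(
        {
            c
            for core, near in per_species_labels
            for c in list(core.values()) + list(near.values())
            if c is not None
        }
    )
    if not categories:
        raise ValueError("no labels assigned in any species")
    out: dict[str, dict] = {}
    for cat in categories:
        core_pct, near_pct = [], []
        for core, near in per_species_labels:
            core_pct.append(100.0 * sum(v == cat for v in core.values()) / max(1, len(core)))
            near_pct.append(100.0 * sum(v == cat for v in near.values()) / max(1, len(near)))
        out[cat] = {
            "core_pct": core_pct,
            "near_core_pct": near_pct,
            "pvalue": paired_signed_rank(core_pct, near_pct),
            "test": "wilcoxon_signed_rank_two_tailed",
        }
    return out
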