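"""Six-round selection of T-cell-restricted genes.

Starting from a candidate gene list and a corpus of purified T cells, purified
non-T immune cells, healthy tissues and non-T cell lines, the procedure keeps
only genes whose expression is concentrated in T cells:

1. **Immune filter** — drop genes overexpressed by T cells by less than a
   ten-fold margin (3.32 log2) relative to non-T immune cell subsets.
2. **Tissue filter** — same margin requirement against healthy non-lymphoid
   tissues. Genes surviving 1–2 should owe their tissue signal to
   tissue-resident memory T cells rather than parenchyma.
3. **Range filter** — the spread (max − min) of a gene's per-tissue means must
   fall inside a plausible window (2.5–8.5 log2): too flat suggests
   constitutive parenchymal expression everywhere, too wide suggests strong
   parenchymal expression somewhere.
4./5. **Outlier filter, two passes** — per tissue t and gene g, compute
   nl/Tc(g,t) = tissue mean − T-cell mean, and the cohort mean M_nl/Tc(t)
   over all genes still in play. A gene whose deviation above the cohort mean
   exceeds 3.32 log2 in any tissue behaves unlike the rest of the cohort
   (parenchymal expression in that tissue) and is dropped. Because dropping
   genes moves M_nl/Tc, the pass is repeated once on the survivors.
6. **Cell-line filter** — drop genes under-margined (again 3.32 log2) in cell
   lines from at least two distinct parenchymal sources, or in any line of
   immune (non-T) origin: such genes are inducible in activated parenchymal
   or non-T immune cells.

Boundary convention: all comparisons are strict as worded ("less than" /
"greater than" excludes), so a margin exactly at a threshold survives, and
the round-3 window is inclusive at both edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from tcelsig.io import (
    ExpressionMatrix,
    GeneSignature,
    GroupMeanTable,
    SampleAnnotation,
    SampleClass,
    group_means,
)

__all__ = [
    "SelectionConfig",
    "RoundResult",
    "SelectionReport",
    "round1_immune_filter",
    "round2_tissue_filter",
    "round3_range_filter",
    "round45_outlier_filter",
    "round6_cellline_filter",
    "run_selection",
]

TENFOLD_LOG2 = float(np.log2(10))  # = 3.3219...; the published rounds use 3.32


@dataclass
class SelectionConfig:
    """Thresholds and modes of the six selection rounds.

    log2_min_overexpr
        Minimum T-cell-over-background margin, log2 (default 3.32, ten-fold);
        used by rounds 1, 2 and 6.
    range_min, range_max
        Inclusive window for the round-3 max-min tissue range, log2.
    deviation_threshold
        Rounds 4/5 one-sided cutoff on nl/Tc − M_nl/Tc, log2.
    outlier_passes
        Number of outlier passes (2 = the published rounds 4 and 5).
    cellline_min_parenchymal_sources
        Distinct parenchymal source lineages among violating cell lines
        needed to drop a gene in round 6.
    immune_compare_mode
        Round 1: ``"per_group"`` requires the margin against every immune
        subset; ``"pooled"`` against the unweighted mean of subset means.
    tissue_compare_mode
        Round 2: ``"mean_of_tissue_means"`` (default) tests the margin
        against the average tissue; ``"per_tissue"`` against every tissue.
    signature_name
        Name given to the surviving signature.
    """

    log2_min_overexpr: float = 3.32
    range_min: float = 2.5
    range_max: float = 8.5
    deviation_threshold: float = 3.32
    outlier_passes: int = 2
    cellline_min_parenchymal_sources: int = 2
    immune_compare_mode: str = "per_group"
    tissue_compare_mode: str = "mean_of_tissue_means"
    signature_name: str = "signature"

    def __post_init__(self) -> None:
        if self.range_min >= self.range_max:
            raise ValueError("range_min must be < range_max")
        for name in ("log2_min_overexpr", "range_min", "range_max", "deviation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.outlier_passes < 1:
            raise ValueError("outlier_passes must be >= 1")
        if self.immune_compare_mode not in ("per_group", "pooled"):
            raise ValueError(f"bad immune_compare_mode {self.immune_compare_mode!r}")
        if self.tissue_compare_mode not in ("mean_of_tissue_means", "per_tissue"):
            raise ValueError(f"bad tissue_compare_mode {self.tissue_compare_mode!r}")


@dataclass
class RoundResult:
    """Outcome of one selection round: partition plus per-gene diagnostics."""

    round_index: int
    name: str
    kept: list[str]
    excluded: list[str]
    diagnostics: pd.DataFrame  # one row per entering gene, 'decision' column
    skipped: bool = False

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass
class SelectionReport:
    """Full record of a selection run."""

    config: SelectionConfig
    candidates: list[str]
    rounds: list[RoundResult]
    signature: GeneSignature | None
    dropped_missing: list[str] = field(default_factory=list)

    @property
    def excluded_counts(self) -> dict[str, int]:
        return {r.name: r.n_excluded for r in self.rounds}

    @property
    def surviving_genes(self) -> list[str]:
        return list(self.signature.genes) if self.signature else []

    def check_counts(self) -> bool:
        total = sum(r.n_excluded for r in self.rounds) + len(self.surviving_genes)
        return total == len(self.candidates)

    def summary(self) -> str:
        lines = [f"candidates entering selection: {len(self.candidates)}"]
        if self.dropped_missing:
            lines.append(f"dropped (absent from matrix): {len(self.dropped_missing)}")
        for r in self.rounds:
            tag = " (skipped)" if r.skipped else ""
            lines.append(f"  {r.name}: excluded {r.n_excluded}{tag}")
        lines.append(f"surviving genes: {len(self.surviving_genes)}")
        if self.signature:
            lines.append("  " + ", ".join(self.signature.genes))
        return "\n".join(lines)


def _margins(t_ref: pd.Series, means: pd.DataFrame) -> pd.DataFrame:
    """t_ref(g) - mean(g, group): positive = overexpressed by T cells."""
    return means.mul(-1).add(t_ref, axis=0)


def round1_immune_filter(
    stats: GroupMeanTable, config: SelectionConfig, genes: Sequence[str] | None = None
) -> RoundResult:
    """Drop genes with a sub-threshold T-cell margin against immune subsets."""
    if stats.t_ref is None:
        raise ValueError("round 1 requires a T-cell reference (no T_CELL samples)")
    immune = stats.means_of_class(SampleClass.IMMUNE_NON_T)
    if immune.shape[1] == 0:
        raise ValueError("round 1 requires at least one IMMUNE_NON_T group")
    if genes is not None:
        immune = immune.loc[list(genes)]
    t_ref = stats.t_ref.loc[immune.index]
    margins = _margins(t_ref, immune)
    if config.immune_compare_mode == "per_group":
        stat = margins.min(axis=1)
    else:
        stat = t_ref - immune.mean(axis=1)
    excluded_mask = stat < config.log2_min_overexpr
    diag = margins.add_prefix("margin_vs_")
    diag["min_margin" if config.immune_compare_mode == "per_group" else "pooled_margin"] = stat
    diag["decision"] = np.where(excluded_mask, "excluded", "kept")
    return RoundResult(
        round_index=1,
        name="round1_immune",
        kept=list(stat.index[~excluded_mask]),
        excluded=list(stat.index[excluded_mask]),
        diagnostics=diag,
    )


def round2_tissue_filter(
    stats: GroupMeanTable, config: SelectionConfig, genes: Sequence[str] | None = None
) -> RoundResult:
    """Drop genes with a sub-threshold T-cell margin against healthy tissues."""
    if stats.t_ref is None:
        raise ValueError("round 2 requires a T-cell reference")
    tissues = stats.means_of_class(SampleClass.TISSUE)
    if tissues.shape[1] < 2:
        raise ValueError("round 2 requires at least two TISSUE groups")
    if genes is not None:
        tissues = tissues.loc[list(genes)]
    t_ref = stats.t_ref.loc[tissues.index]
    margins = _margins(t_ref, tissues)
    if config.tissue_compare_mode == "mean_of_tissue_means":
        stat = t_ref - tissues.mean(axis=1)
        statname = "margin_vs_mean_tissue"
    else:
        stat = margins.min(axis=1)
        statname = "min_margin"
    excluded_mask = stat < config.log2_min_overexpr
    diag = margins.add_prefix("margin_vs_")
    diag[statname] = stat
    diag["decision"] = np.where(excluded_mask, "excluded", "kept")
    return RoundResult(
        round_index=2,
        name="round2_tissue",
        kept=list(stat.index[~excluded_mask]),
        excluded=list(stat.index[excluded_mask]),
        diagnostics=diag,
    )


def round3_range_filter(
    stats: GroupMeanTable, config: SelectionConfig, genes: Sequence[str] | None = None
) -> RoundResult:
    """Keep genes whose per-tissue mean spread lies inside [range_min, range_max]."""
    tissues = stats.means_of_class(SampleClass.TISSUE)
    if tissues.shape[1] < 2:
        raise ValueError("round 3 requires at least two TISSUE groups")
    if genes is not None:
        tissues = tissues.loc[list(genes)]
    rng = tissues.max(axis=1) - tissues.min(axis=1)
    kept_mask = (rng >= config.range_min) & (rng <= config.range_max)
    diag = pd.DataFrame(
        {
            "tissue_range": rng,
            "decision": np.where(kept_mask, "kept", "excluded"),
        }
    )
    return RoundResult(
        round_index=3,
        name="round3_range",
        kept=list(rng.index[kept_mask]),
        excluded=list(rng.index[~kept_mask]),
        diagnostics=diag,
    )


def round45_outlier_filter(
    stats: GroupMeanTable,
    config: SelectionConfig,
    genes: Sequence[str],
    round_index: int = 4,
) -> RoundResult:
    """One outlier pass: drop genes deviating above the cohort tissue profile.

    nl/Tc(g,t) = tissue mean − t_ref; M_nl/Tc(t) = mean of nl/Tc over the
    genes entering this pass. A gene is excluded iff
    max_t [nl/Tc(g,t) − M_nl/Tc(t)] > deviation_threshold. All exclusions
    within a pass use the pass-entry M_nl/Tc (simultaneous). The test is
    one-sided: constitutive parenchymal expression raises nl/Tc, never
    lowers it.
    """
    if stats.t_ref is None:
        raise ValueError("outlier pass requires a T-cell reference")
    tissues = stats.means_of_class(SampleClass.TISSUE)
    if tissues.shape[1] < 2:
        raise ValueError("outlier pass requires at least two TISSUE groups")
    genes = list(genes)
    if len(genes) < 2:
        warnings.warn(
            f"outlier pass {round_index} skipped: fewer than two genes entering"
        )
        return RoundResult(
            round_index=round_index,
            name=f"round{round_index}_outlier",
            kept=genes,
            excluded=[],
            diagnostics=pd.DataFrame(index=genes),
            skipped=True,
        )
    tissues = tissues.loc[genes]
    nl_tc = tissues.sub(stats.t_ref.loc[genes], axis=0)
    m_nl_tc = nl_tc.mean(axis=0)  # per tissue, frozen at pass entry
    dev = nl_tc.sub(m_nl_tc, axis=1)
    max_dev = dev.max(axis=1)
    sd_dev = dev.std(axis=1, ddof=1)
    excluded_mask = max_dev > config.deviation_threshold
    diag = nl_tc.add_prefix("nl_tc_")
    diag = diag.join(dev.add_prefix("dev_"))
    diag["max_deviation"] = max_dev
    diag["sd_deviation"] = sd_dev
    diag["decision"] = np.where(excluded_mask, "excluded", "kept")
    return RoundResult(
        round_index=round_index,
        name=f"round{round_index}_outlier",
        kept=list(max_dev.index[~excluded_mask]),
        excluded=list(max_dev.index[excluded_mask]),
        diagnostics=diag,
    )


def round6_cellline_filter(
    stats: GroupMeanTable, config: SelectionConfig, genes: Sequence[str] | None = None
) -> RoundResult:
    """Drop genes under-margined in cell lines of >=2 parenchymal sources or immune origin.

    A (gene, line) pair violates when t_ref − line mean < log2_min_overexpr.
    The gene is excluded iff the violating lines span at least
    ``cellline_min_parenchymal_sources`` distinct parenchymal lineages, or
    any violating line has source_lineage ``"immune"``.
    """
    if stats.t_ref is None:
        raise ValueError("round 6 requires a T-cell reference")
    lines = stats.means_of_class(SampleClass.CELL_LINE)
    if lines.shape[1] == 0:
        warnings.warn("round 6 skipped: no cell lines in corpus")
        idx = list(genes) if genes is not None else []
        return RoundResult(
            round_index=6,
            name="round6_cellline",
            kept=idx,
            excluded=[],
            diagnostics=pd.DataFrame(index=idx),
            skipped=True,
        )
    if genes is not None:
        lines = lines.loc[list(genes)]
    t_ref = stats.t_ref.loc[lines.index]
    margins = _margins(t_ref, lines)
    violating = margins < config.log2_min_overexpr

    rows = []
    for g in lines.index:
        viol_lines = [ln for ln in lines.columns if violating.at[g, ln]]
        lineages = [stats.source_lineage.get(ln, "") for ln in viol_lines]
        parenchymal = {lg for lg in lineages if lg and lg != "immune"}
        immune_hit = any(lg == "immune" for lg in lineages)
        excluded = (
            len(parenchymal) >= config.cellline_min_parenchymal_sources or immune_hit
        )
        rows.append(
            {
                "violating_lines": ";".join(viol_lines),
                "violating_lineages": ";".join(lineages),
                "n_parenchymal_sources": len(parenchymal),
                "immune_line_violation": immune_hit,
                "decision": "excluded" if excluded else "kept",
            }
        )
    diag = pd.DataFrame(rows, index=lines.index)
    if diag.empty:
        diag = pd.DataFrame(columns=["decision"])
    excluded_mask = diag["decision"] == "excluded"
    return RoundResult(
        round_index=6,
        name="round6_cellline",
        kept=list(diag.index[~excluded_mask]),
        excluded=list(diag.index[excluded_mask]),
        diagnostics=diag,
    )


def run_selection(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    candidates: GeneSignature,
    config: SelectionConfig | None = None,
    pooling: str = "pooled_samples",
) -> SelectionReport:
    """Run the full six-round procedure on a candidate gene list.

    Candidates absent from the matrix are dropped with a warning; rounds
    whose sample class is missing from the corpus are skipped with a
    warning. An empty survivor set is reported, not raised.
    """
    config = config or SelectionConfig()
    matrix.require_log2()
    present = [g for g in candidates.genes if g in set(matrix.gene_ids)]
    missing = [g for g in candidates.genes if g not in set(matrix.gene_ids)]
    if missing:
        warnings.warn(
            f"{len(missing)} candidate gene(s) absent from matrix, dropped: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    stats = group_means(matrix, annotation, pooling=pooling)
    if stats.t_ref is None:
        raise ValueError("selection requires T_CELL samples in the corpus")

    classes = annotation.classes()
    current = list(present)
    rounds: list[RoundResult] = []

    def _skip(idx: int, name: str, why: str) -> RoundResult:
        warnings.warn(f"{name} skipped: {why}")
        return RoundResult(idx, name, list(current), [], pd.DataFrame(index=current), True)

    if SampleClass.IMMUNE_NON_T in classes:
        rounds.append(round1_immune_filter(stats, config, genes=current))
    else:
        rounds.append(_skip(1, "round1_immune", "no IMMUNE_NON_T samples"))
    current = rounds[-1].kept

    has_tissues = (
        SampleClass.TISSUE in classes
        and len(stats.groups_of_class(SampleClass.TISSUE)) >= 2
    )
    if has_tissues:
        rounds.append(round2_tissue_filter(stats, config, genes=current))
        current = rounds[-1].kept
        rounds.append(round3_range_filter(stats, config, genes=current))
        current = rounds[-1].kept
        for p in range(config.outlier_passes):
            rounds.append(round45_outlier_filter(stats, config, current, round_index=4 + p))
            current = rounds[-1].kept
    else:
        rounds.append(_skip(2, "round2_tissue", "fewer than two TISSUE groups"))
        rounds.append(_skip(3, "round3_range", "fewer than two TISSUE groups"))
        for p in range(config.outlier_passes):
            rounds.append(_skip(4 + p, f"round{4 + p}_outlier", "fewer than two TISSUE groups"))

    if SampleClass.CELL_LINE in classes:
        rounds.append(round6_cellline_filter(stats, config, genes=current))
    else:
        rounds.append(_skip(6, "round6_cellline", "no CELL_LINE samples"))
    current = rounds[-1].kept

    if current:
        signature = GeneSignature(
            name=config.signature_name,
            genes=list(current),
            provenance=f"six-round selection of {len(present)} candidates",
        )
    else:
        warnings.warn("selection left no surviving genes")
        signature = None
    return SelectionReport(
        config=config,
        candidates=present,
        rounds=rounds,
        signature=signature,
        dropped_missing=missing,
    )


def report_to_dict(report: SelectionReport) -> dict:
    """JSON-serializable summary of a selection run (for CLI output)."""
    return {
        "config": asdict(report.config),
        "n_candidates": len(report.candidates),
        "dropped_missing": report.dropped_missing,
        "excluded_counts": report.excluded_counts,
        "surviving_genes": report.surviving_genes,
    }
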