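"""Synthetic corpora with the statistical structure the method assumes.

Three generators, all seeded and reproducible:

* :func:`generate_corpus` — an annotated expression corpus (T-cell subsets,
  non-T immune subsets, healthy tissues, cell lines, tumors) in which tissue
  expression of a planted T-restricted gene is a *linear-scale mixture* of
  the T-cell profile (fraction f, the T-cell content of the tissue) and a
  parenchymal background (1-f), log2-transformed, with Gaussian log-scale
  (i.e. lognormal multiplicative) noise. Alongside the planted signature it
  plants six confounder classes, each engineered to pass every selection
  round before the one it is designed to violate — so per-round exclusion
  attribution is testable.
* :func:`generate_survival_cohort` — exponential survival times whose hazard
  depends on the patient's Tav bin, with uniform censoring.
* :func:`generate_melanoma_cohort` — checkpoint profiles (linear FPKM) half
  of which satisfy all three response-rule criteria by construction, with
  response probability depending on rule status and survival linked to
  response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from tcelsig.io import (
    ExpressionMatrix,
    GeneSignature,
    SampleAnnotation,
    SampleClass,
)
from tcelsig.prognosis import TavBinning
from tcelsig.response import CheckpointProfile

__all__ = [
    "CorpusSpec",
    "PlantedCorpus",
    "generate_corpus",
    "generate_survival_cohort",
    "generate_melanoma_cohort",
]

CONFOUNDER_CLASSES = ("r1", "r2", "r3_low", "r3_high", "r45", "r6")

DEFAULT_TISSUE_FRACTIONS = {
    "brain": 0.002,
    "liver": 0.005,
    "skin": 0.01,
    "lung": 0.02,
    "colon": 0.03,
}

DEFAULT_CONFOUNDERS = {
    "r1": 10,
    "r2": 10,
    "r3_low": 5,
    "r3_high": 5,
    "r45": 10,
    "r6": 10,
}

T_GROUPS = ("T_naive", "T_memory", "T_activated")
IMMUNE_GROUPS = ("B_cell", "dendritic", "granulocyte", "monocyte")
CELL_LINES = {
    "lung_line_1": "lung",
    "lung_line_2": "lung",
    "colon_line_1": "colon",
    "breast_line_1": "breast",
    "bcell_line_1": "immune",
}


@dataclass
class CorpusSpec:
    """Study conditions of the planted corpus.

    n_signature_genes
        Number of planted T-restricted genes (default 10).
    confounders
        Genes per confounder class (defaults sum to 50, one class per
        selection round; the round-3 window gets a too-flat and a too-wide
        class).
    t_cell_mean_log2
        Mean log2 expression of planted genes in T cells (default 10).
    margin
        log2 gap between the T-cell level and the background level of
        planted genes in immune subsets and cell lines (default 7, safely
        above threshold + 6*noise_sd).
    noise_sd
        Per-sample log2 noise SD (default 0.3, lognormal multiplicative).
    tissue_fractions
        T-cell content f per healthy tissue; tissue signal of a planted gene
        is log2(f*2^mu_T + (1-f)*2^background_log2).
    tumor_fractions
        Same, for tumor groups.
    background_log2
        Parenchymal background of planted genes in tissues (log2 linear
        units). ``None`` (default) puts it 4 log2 below the smallest T-cell
        tissue contribution, i.e. negligible against the mixture but
        non-zero; set very low (e.g. -30) for an effectively zero
        background when testing fraction recovery.
    n_per_group
        Samples per group (default 8).
    """

    n_signature_genes: int = 10
    confounders: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CONFOUNDERS))
    t_cell_mean_log2: float = 10.0
    margin: float = 7.0
    noise_sd: float = 0.3
    tissue_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_FRACTIONS)
    )
    tumor_fractions: dict[str, float] = field(
        default_factory=lambda: {"melanoma": 0.08, "neuroblastoma": 0.04}
    )
    background_log2: float | None = None
    n_per_group: int = 8
    threshold: float = 3.32  # selection margin the corpus is designed around

    def __post_init__(self) -> None:
        unknown = set(self.confounders) - set(CONFOUNDER_CLASSES)
        if unknown:
            raise ValueError(f"unknown confounder classes: {sorted(unknown)}")
        fr = list(self.tissue_fractions.values()) + list(self.tumor_fractions.values())
        if any(not (0 < f < 1) for f in fr):
            raise ValueError("tissue/tumor fractions must lie in (0, 1)")
        if len(self.tissue_fractions) < 2:
            raise ValueError("need at least two tissues")
        if self.margin < self.threshold + 6 * self.noise_sd:
            raise ValueError(
                "infeasible spec: margin must be >= threshold + 6*noise_sd "
                "for guaranteed planted recovery"
            )

    def effective_background_log2(self) -> float:
        if self.background_log2 is not None:
            return self.background_log2
        f_min = min(self.tissue_fractions.values())
        return self.t_cell_mean_log2 + np.log2(f_min) - 4.0


@dataclass
class PlantedCorpus:
    """A generated corpus plus its ground truth."""

    matrix: ExpressionMatrix
    annotation: SampleAnnotation
    signature: GeneSignature
    planted_round: dict[str, str]  # confounder gene -> round class it violates
    group_means: pd.DataFrame  # noiseless genes x groups design means


def _mixture_log2(f: float, mu_t: float, bg_log2: float) -> float:
    return float(np.log2(f * 2.0**mu_t + (1.0 - f) * 2.0**bg_log2))


def _design_means(spec: CorpusSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Noiseless per-gene, per-group design means for all planted genes."""
    mu_t = spec.t_cell_mean_log2
    bg = spec.effective_background_log2()
    low = mu_t - spec.margin  # background level in immune subsets / cell lines
    tissues = list(spec.tissue_fractions)
    tumors = list(spec.tumor_fractions)
    groups = (
        list(T_GROUPS) + list(IMMUNE_GROUPS) + tissues + list(CELL_LINES) + tumors
    )

    def baseline() -> dict[str, float]:
        row = {g: mu_t for g in T_GROUPS}
        row.update({g: low for g in IMMUNE_GROUPS})
        row.update(
            {t: _mixture_log2(f, mu_t, bg) for t, f in spec.tissue_fractions.items()}
        )
        row.update({ln: low for ln in CELL_LINES})
        row.update(
            {t: _mixture_log2(f, mu_t, bg) for t, f in spec.tumor_fractions.items()}
        )
        return row

    rows: dict[str, dict[str, float]] = {}
    planted_round: dict[str, str] = {}

    for i in range(spec.n_signature_genes):
        rows[f"SIG{i + 1:03d}"] = baseline()

    counts = {c: spec.confounders.get(c, 0) for c in CONFOUNDER_CLASSES}

    # r1: constitutive in one non-T immune subset (cycled) -> fails round 1.
    for i in range(counts["r1"]):
        gene = f"C1_{i + 1:03d}"
        row = baseline()
        row[IMMUNE_GROUPS[i % len(IMMUNE_GROUPS)]] = mu_t - 1.0
        rows[gene] = row
        planted_round[gene] = "r1"

    # r2: elevated across all tissues (mean margin 2 < threshold) -> fails round 2.
    for i in range(counts["r2"]):
        gene = f"C2_{i + 1:03d}"
        row = baseline()
        offsets = np.linspace(-1.5, 1.5, len(tissues))
        for t, off in zip(tissues, offsets):
            row[t] = mu_t - 2.0 + off
        rows[gene] = row
        planted_round[gene] = "r2"

    # r3_low: uniform moderate tissue expression, range ~0 < range_min.
    for i in range(counts["r3_low"]):
        gene = f"C3L_{i + 1:03d}"
        row = baseline()
        for t in tissues:
            row[t] = mu_t - 4.0
        rows[gene] = row
        planted_round[gene] = "r3_low"

    # r3_high: one near-T tissue against a deep floor, range > range_max.
    for i in range(counts["r3_high"]):
        gene = f"C3H_{i + 1:03d}"
        row = baseline()
        hot = tissues[i % len(tissues)]
        for t in tissues:
            row[t] = mu_t - 0.5 if t == hot else mu_t - 9.5
        rows[gene] = row
        planted_round[gene] = "r3_high"

    # r45: constitutive in exactly one tissue (margin 1) -> outlier deviation.
    for i in range(counts["r45"]):
        gene = f"C45_{i + 1:03d}"
        row = baseline()
        row[tissues[i % len(tissues)]] = mu_t - 1.0
        rows[gene] = row
        planted_round[gene] = "r45"

    # r6: under-margined in cell lines of two parenchymal sources, or in an
    # immune-derived line (alternating), -> fails round 6.
    for i in range(counts["r6"]):
        gene = f"C6_{i + 1:03d}"
        row = baseline()
        if i % 2 == 0:
            row["lung_line_1"] = mu_t - 1.0
            row["colon_line_1"] = mu_t - 1.0
        else:
            row["bcell_line_1"] = mu_t - 1.0
        rows[gene] = row
        planted_round[gene] = "r6"

    means = pd.DataFrame.from_dict(rows, orient="index")[groups]
    return means, planted_round


def generate_corpus(spec: CorpusSpec | None = None, seed: int = 0) -> PlantedCorpus:
    """Generate an annotated expression corpus with planted ground truth.

    Every group receives ``spec.n_per_group`` samples whose values are the
    design mean plus Normal(0, noise_sd) log2 noise. Identical seeds yield
    bit-identical corpora.
    """
    spec = spec or CorpusSpec()
    rng = np.random.default_rng(seed)
    means, planted_round = _design_means(spec)

    group_class: dict[str, SampleClass] = {}
    group_class.update({g: SampleClass.T_CELL for g in T_GROUPS})
    group_class.update({g: SampleClass.IMMUNE_NON_T for g in IMMUNE_GROUPS})
    group_class.update({t: SampleClass.TISSUE for t in spec.tissue_fractions})
    group_class.update({ln: SampleClass.CELL_LINE for ln in CELL_LINES})
    group_class.update({t: SampleClass.TUMOR for t in spec.tumor_fractions})

    sample_ids: list[str] = []
    ann_rows: list[dict] = []
    columns: list[np.ndarray] = []
    for group in means.columns:
        mu = means[group].to_numpy()
        for j in range(spec.n_per_group):
            sid = f"{group}_s{j + 1}"
            sample_ids.append(sid)
            noise = rng.normal(0.0, spec.noise_sd, size=mu.size)
            columns.append(mu + noise)
            ann_rows.append(
                {
                    "sample_id": sid,
                    "class": group_class[group].value,
                    "group": group,
                    "source_lineage": CELL_LINES.get(group, ""),
                }
            )

    values = pd.DataFrame(
        np.column_stack(columns), index=means.index, columns=sample_ids
    )
    matrix = ExpressionMatrix(values, scale="log2")
    annotation = SampleAnnotation(
        pd.DataFrame(ann_rows).set_index("sample_id")
    )
    signature = GeneSignature(
        name="planted",
        genes=[f"SIG{i + 1:03d}" for i in range(spec.n_signature_genes)],
        provenance="planted T-restricted genes of the synthetic corpus",
    )
    return PlantedCorpus(
        matrix=matrix,
        annotation=annotation,
        signature=signature,
        planted_round=planted_round,
        group_means=means,
    )


def generate_survival_cohort(
    n_per_bin: int,
    bin_hazards: Mapping[str, float],
    censor_frac: float = 0.2,
    seed: int = 0,
    binning: TavBinning | None = None,
) -> pd.DataFrame:
    """Survival records with exponential event times whose hazard depends on
    the Tav bin.

    ``bin_hazards`` maps bin labels (see :class:`TavBinning`) to hazards in
    events/day. Each record draws a Tav uniformly inside its bin's interval,
    an exponential event time, and is censored (uniformly before the event)
    with probability ``censor_frac``. Columns: patient_id, time_days, event,
    tav, true_bin.
    """
    if any(h <= 0 for h in bin_hazards.values()):
        raise ValueError("hazards must be > 0")
    if not 0 <= censor_frac <= 1:
        raise ValueError("censor_frac must lie in [0, 1]")
    binning = binning or TavBinning()
    unknown = set(bin_hazards) - set(binning.labels)
    if unknown:
        raise ValueError(f"unknown bin labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    edges = binning.edges
    intervals = {binning.labels[0]: (max(edges[0] - 0.25, 0.0), edges[0])}
    for a, b, lab in zip(edges, edges[1:], binning.labels[1:-1]):
        intervals[lab] = (a, b)
    intervals[binning.labels[-1]] = (edges[-1], edges[-1] + 2.0)

    rows = []
    i = 0
    for label, hazard in bin_hazards.items():
        lo, hi = intervals[label]
        for _ in range(n_per_bin):
            i += 1
            tav = rng.uniform(lo, hi)
            t_event = rng.exponential(1.0 / hazard)
            censored = rng.uniform() < censor_frac
            time = t_event * rng.uniform() if censored else t_event
            rows.append(
                {
                    "patient_id": f"P{i:04d}",
                    "time_days": max(time, 1e-6),
                    "event": not censored,
                    "tav": tav,
                    "true_bin": label,
                }
            )
    return pd.DataFrame(rows)


def generate_melanoma_cohort(
    n: int = 200,
    p_good_respond: float = 0.85,
    p_bad_respond: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Checkpoint profiles half of which satisfy all three response criteria.

    The "good" half is constructed to satisfy the three signature-3 criteria
    (ligand/receptor ratios inside (0.5, 10), Tav-RNAseq > 1, PD-1/Tav >
    0.5); the "bad" half violates exactly one criterion, chosen uniformly.
    Responses are Bernoulli per group (responders split CR/PR); survival is
    exponential with a lower hazard for responders, 20% uniform censoring.
    Columns: patient_id, pd1_fpkm, pdl1_fpkm, pdl2_fpkm, tav_rnaseq,
    response, time_days, event, true_group.
    """
    for p in (p_good_respond, p_bad_respond):
        if not 0 <= p <= 1:
            raise ValueError("response probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_good = n // 2
    rows = []
    for i in range(n):
        good = i < n_good
        tav = rng.uniform(1.5, 4.0)
        pd1 = tav * rng.uniform(0.75, 3.0)
        pdl1 = pd1 * rng.uniform(1.0, 8.0)
        pdl2 = pd1 * rng.uniform(1.0, 8.0)
        if not good:
            violation = rng.integers(3)
            if violation == 0:  # ligand/receptor ratio out of window
                factor = rng.uniform(12.0, 30.0) if rng.uniform() < 0.5 else rng.uniform(0.05, 0.4)
                pdl1 = pd1 * factor
            elif violation == 1:  # under-infiltrated
                tav = rng.uniform(0.1, 0.9)
                pd1 = tav * rng.uniform(0.75, 3.0)
                pdl1 = pd1 * rng.uniform(1.0, 8.0)
                pdl2 = pd1 * rng.uniform(1.0, 8.0)
            else:  # T cells not exhausted: PD-1 low relative to Tav
                pd1 = tav * rng.uniform(0.05, 0.45)
                pdl1 = pd1 * rng.uniform(1.0, 8.0)
                pdl2 = pd1 * rng.uniform(1.0, 8.0)
        p_resp = p_good_respond if good else p_bad_respond
        responded = rng.uniform() < p_resp
        response = ("CR" if rng.uniform() < 0.3 else "PR") if responded else "PD"
        hazard = 1.0 / 2000.0 if responded else 1.0 / 300.0
        t_event = rng.exponential(1.0 / hazard)
        censored = rng.uniform() < 0.2
        time = t_event * rng.uniform() if censored else t_event
        rows.append(
            {
                "patient_id": f"M{i + 1:04d}",
                "pd1_fpkm": pd1,
                "pdl1_fpkm": pdl1,
                "pdl2_fpkm": pdl2,
                "tav_rnaseq": tav,
                "response": response,
                "time_days": max(time, 1e-6),
                "event": not censored,
                "true_group": "good" if good else "bad",
            }
        )
    return pd.DataFrame(rows)


def cohort_to_profiles(cohort: pd.DataFrame) -> list[CheckpointProfile]:
    """Convert a melanoma cohort table to :class:`CheckpointProfile` objects."""
    return [
        CheckpointProfile(
            patient_id=row.patient_id,
            pd1=row.pd1_fpkm,
            pdl1=row.pdl1_fpkm,
            pdl2=row.pdl2_fpkm,
            tav_rnaseq=row.tav_rnaseq,
            response=row.response,
        )
        for row in cohort.itertuples()
    ]
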