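"""T-cell infiltration scores built on a restricted gene signature.

Three scores, all computed over the signature genes of a log2 expression
profile:

* **Ts%** — the tissue's signature mRNA signal as a percentage of the
  purified-T-cell signal. Averaging happens in log2 space (a geometric mean
  of linear ratios), so purified T cells score exactly 100 and a tissue whose
  signature genes sit a uniform d log2 below T cells scores 100 * 2^(-d).
* **Tav** — the arithmetic mean log2 expression of the signature genes;
  platform-specific (Tav-array, Tav-RNAseq), so it is tagged with the
  platform it came from.
* **Ts-l2** — mean log2 difference of signature genes between a tumor sample
  and the matched healthy tissue (HT); 0 means HT-like infiltration, and
  |Ts-l2| <= 0.32 corresponds to the 80-125% band of the HT signal.

On top of the scores: banding of Ts% relative to the mean healthy-tissue
reference, a per-specimen infiltrated/not call against the HT Tav
distribution, platform adaptation of a signature, and quartile concordance
between two score vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tcelsig.io import (
    ExpressionMatrix,
    GeneSignature,
    SampleAnnotation,
    SampleClass,
)

__all__ = [
    "Band",
    "BandConfig",
    "ts_percent",
    "tav",
    "ts_l2",
    "classify_band",
    "call_infiltrated",
    "adapt_signature",
    "quartile_concordance",
    "score_samples",
]


class Band(str, Enum):
    EXTREMELY_LOW = "extremely_low"
    VERY_LOW = "very_low"
    SIMILAR = "similar"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass
class BandConfig:
    """Edges of the Ts% infiltration bands, as fractions of a reference Ts%.

    ``reference_ts`` defaults to 3.0, the mean healthy-tissue Ts% under the
    15-gene signature. The "similar" window is 80-125% of the reference
    (2.4-3.7 at the default), matching the +/-0.32 log2 convention. The
    moderate/high cut (2.5x) and very-low/extremely-low cut (0.4x) have no
    published value; the defaults are this package's choice and are
    configurable.
    """

    reference_ts: float = 3.0
    similar_low_frac: float = 0.8
    similar_high_frac: float = 1.25
    moderate_high_frac: float = 2.5
    extremely_low_frac: float = 0.4

    def __post_init__(self) -> None:
        if not (
            0
            < self.extremely_low_frac
            < self.similar_low_frac
            < self.similar_high_frac
            < self.moderate_high_frac
        ):
            raise ValueError("band fractions must be ordered and positive")
        if self.reference_ts <= 0:
            raise ValueError("reference_ts must be > 0")


def _signature_values(values: pd.Series, signature: GeneSignature) -> pd.Series:
    present = [g for g in signature.genes if g in values.index]
    if not present:
        raise ValueError(
            f"no signature gene of {signature.name!r} present in the profile"
        )
    return values.loc[present]


def ts_percent(
    sample: pd.Series, signature: GeneSignature, t_ref: pd.Series
) -> float:
    """Ts%: signature signal as a percentage of the purified-T-cell signal.

    Ts% = 100 * 2^(mean_g [x(g, sample) - t_ref(g)]) over the signature genes
    present in both profiles (log2 inputs). A profile identical to the T-cell
    reference scores exactly 100.
    """
    present = [
        g for g in signature.genes if g in sample.index and g in t_ref.index
    ]
    if not present:
        raise ValueError("no signature gene shared between sample and T-cell reference")
    diffs = sample.loc[present].to_numpy() - t_ref.loc[present].to_numpy()
    return float(100.0 * 2 ** diffs.mean())


def tav(
    sample: pd.Series, signature: GeneSignature, platform: str = "array"
) -> float:
    """Tav: arithmetic mean log2 expression of the signature genes.

    Platform-specific; the ``platform`` tag is advisory (Tav-array vs
    Tav-RNAseq values are not comparable across platforms).
    """
    vals = _signature_values(sample, signature)
    return float(vals.mean())


def ts_l2(
    tumor: pd.Series, ht_gene_means: pd.Series, signature: GeneSignature
) -> float:
    """Ts-l2: mean log2 difference between a tumor profile and matched HT means."""
    if ht_gene_means is None:
        raise ValueError("Ts-l2 requires a healthy-tissue reference")
    present = [
        g
        for g in signature.genes
        if g in tumor.index and g in ht_gene_means.index
    ]
    if not present:
        raise ValueError("no signature gene shared between tumor and HT reference")
    diffs = tumor.loc[present].to_numpy() - ht_gene_means.loc[present].to_numpy()
    return float(diffs.mean())


def classify_band(ts: float, config: BandConfig | None = None) -> Band:
    """Assign a Ts% value to an infiltration band relative to the HT reference.

    similar = [0.8r, 1.25r]; moderate = (1.25r, 2.5r]; high above;
    very_low = [0.4r, 0.8r); extremely_low below (r = reference Ts%).
    """
    if ts <= 0:
        raise ValueError("Ts% must be > 0")
    config = config or BandConfig()
    r = config.reference_ts
    eps = 1e-9 * r  # guard against float noise in frac*r at the band edges
    if ts < config.extremely_low_frac * r - eps:
        return Band.EXTREMELY_LOW
    if ts < config.similar_low_frac * r - eps:
        return Band.VERY_LOW
    if ts <= config.similar_high_frac * r + eps:
        return Band.SIMILAR
    if ts <= config.moderate_high_frac * r + eps:
        return Band.MODERATE
    return Band.HIGH


def call_infiltrated(
    tumor_tav: float, ht_specimen_tavs: Sequence[float]
) -> bool:
    """True iff the tumor Tav exceeds mean + 1 SD of the HT specimen Tavs.

    The SD is the sample SD (n-1 denominator); the comparison is strict, so
    a tumor exactly at the threshold is not called infiltrated.
    """
    ht = np.asarray(ht_specimen_tavs, dtype=float)
    if ht.size < 2:
        raise ValueError("infiltration call requires at least two HT specimens")
    threshold = ht.mean() + ht.std(ddof=1)
    return bool(tumor_tav > threshold)


def adapt_signature(
    signature: GeneSignature,
    platform_genes: Sequence[str],
    min_genes: int = 8,
) -> GeneSignature:
    """Restrict a signature to the genes measured by a platform.

    Order is preserved. The adapted signature is renamed with the surviving
    gene count (e.g. a 15-gene "signature-H" reduced to 8 genes becomes
    "signature-H8"). Fewer than ``min_genes`` survivors is an error.
    """
    platform = set(platform_genes)
    if not platform:
        raise ValueError("platform gene list is empty")
    kept = [g for g in signature.genes if g in platform]
    missing = [g for g in signature.genes if g not in platform]
    if len(kept) < min_genes:
        raise ValueError(
            f"only {len(kept)} signature gene(s) on platform "
            f"(minimum {min_genes}); missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) of {signature.name!r} absent from platform: "
            f"{missing}"
        )
    k = len(kept)
    if signature.name.endswith("H"):
        name = f"{signature.name}{k}"
    else:
        name = f"{signature.name}-H{k}"
    return GeneSignature(
        name=name,
        genes=kept,
        provenance=f"{signature.name} restricted to {k}/{len(signature)} platform genes",
    )


def quartile_concordance(
    scores_ref: pd.Series, scores_other: pd.Series
) -> dict[str, float]:
    """Top/bottom-quartile overlap between two per-specimen score vectors.

    Specimens are ranked descending; Q1 is the top ceil(n/4) and Q4 the
    bottom ceil(n/4). Ties are broken by stable specimen-id order. Returns
    the percentage of reference-Q1 (resp. Q4) specimens that remain in Q1
    (resp. Q4) under the other score.
    """
    if set(scores_ref.index) != set(scores_other.index):
        raise ValueError("the two score vectors cover different specimen sets")
    n = len(scores_ref)
    if n < 4:
        raise ValueError("quartile concordance requires at least four specimens")
    q = int(np.ceil(n / 4))

    def _quartiles(s: pd.Series) -> tuple[set, set]:
        ranked = s.sort_values(ascending=False, kind="stable")
        return set(ranked.index[:q]), set(ranked.index[-q:])

    ref_q1, ref_q4 = _quartiles(scores_ref)
    oth_q1, oth_q4 = _quartiles(scores_other.loc[scores_ref.index])
    return {
        "q1_overlap_pct": 100.0 * len(ref_q1 & oth_q1) / q,
        "q4_overlap_pct": 100.0 * len(ref_q4 & oth_q4) / q,
    }


def score_samples(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    signature: GeneSignature,
    t_ref: pd.Series,
    ht_group: str | None = None,
    band_config: BandConfig | None = None,
    platform: str = "array",
) -> pd.DataFrame:
    """Score every sample of a matrix: Ts%, Tav, band, and optionally Ts-l2
    and the infiltrated call against a named healthy-tissue group.

    Returns a DataFrame indexed by sample_id with columns ts_percent, tav,
    band and, when ``ht_group`` is given, ts_l2 and infiltrated.
    """
    matrix.require_log2()
    band_config = band_config or BandConfig()
    ann = annotation.restrict_to(matrix.sample_ids)

    ht_means = None
    ht_tavs: list[float] | None = None
    if ht_group is not None:
        ht_samples = list(ann.table.index[ann.table["group"] == ht_group])
        if not ht_samples:
            raise ValueError(f"no samples in HT group {ht_group!r}")
        ht_means = matrix.values[ht_samples].mean(axis=1)
        ht_tavs = [
            tav(matrix.values[s], signature, platform=platform) for s in ht_samples
        ]

    rows = []
    for s in matrix.sample_ids:
        profile = matrix.values[s]
        ts = ts_percent(profile, signature, t_ref)
        row: dict = {
            "sample_id": s,
            "ts_percent": ts,
            "tav": tav(profile, signature, platform=platform),
            "band": classify_band(ts, band_config).value,
        }
        if ht_means is not None:
            row["ts_l2"] = ts_l2(profile, ht_means, signature)
            if len(ht_tavs) >= 2:
                row["infiltrated"] = call_infiltrated(row["tav"], ht_tavs)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
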