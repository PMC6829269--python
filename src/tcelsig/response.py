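"""Checkpoint-expression rules predicting response to anti-PD-1 therapy.

Three nested decision rules classify a melanoma patient as a likely
responder ("good") or non-responder ("bad") from pre-treatment tumor
RNA-seq, using linear-scale FPKM of the checkpoint receptor PD-1 (PDCD1) and
its ligands PD-L1 (CD274) and PD-L2 (PDCD1LG2), plus the Tav-RNAseq
infiltration score (mean log2(FPKM+1) over the signature genes):

* signature-1: 0.5 < PD-L1/PD-1 < 10 and 0.5 < PD-L2/PD-1 < 10
  (the tumor expresses enough, but not too much, ligand per receptor);
* signature-2: 0.5 < PD-L1/PD-1 < 10 and Tav-RNAseq > 1
  (the tumor is T-cell infiltrated);
* signature-3: signature-2 and PD-1/Tav-RNAseq > 0.5
  (the infiltrating T cells express enough PD-1, i.e. look exhausted).

All inequalities are strict. The receptor/ligand ratios use linear FPKM
while Tav-RNAseq is a log2 quantity; the PD-1/Tav ratio deliberately mixes
the two scales, as published. PD-1 = 0 yields "bad" with a warning (the
PD-1-dependent criteria cannot be satisfied), not an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tcelsig.io import GeneSignature

__all__ = [
    "RuleConfig",
    "CheckpointProfile",
    "compute_tav_rnaseq",
    "signature1_call",
    "signature2_call",
    "signature3_call",
    "call_cohort",
    "overall_response_rate",
    "contingency_chi2",
]

GOOD = "good"
BAD = "bad"
RESPONSES = ("CR", "PR", "PD")


@dataclass
class RuleConfig:
    """Thresholds of the three response rules (all strict inequalities)."""

    ratio_low: float = 0.5
    ratio_high: float = 10.0
    tav_min: float = 1.0
    pd1_over_tav_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.ratio_low < self.ratio_high:
            raise ValueError("need 0 < ratio_low < ratio_high")
        if self.tav_min <= 0 or self.pd1_over_tav_min <= 0:
            raise ValueError("tav_min and pd1_over_tav_min must be > 0")


@dataclass
class CheckpointProfile:
    """Checkpoint expression of one patient (linear FPKM) plus Tav-RNAseq."""

    patient_id: str
    pd1: float
    pdl1: float
    pdl2: float
    tav_rnaseq: float
    response: str | None = None  # CR, PR or PD

    def __post_init__(self) -> None:
        for name in ("pd1", "pdl1", "pdl2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (linear FPKM)")
        if not np.isfinite(self.tav_rnaseq):
            raise ValueError("tav_rnaseq must be finite")
        if self.response is not None and self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")


def compute_tav_rnaseq(fpkm: pd.Series, signature: GeneSignature) -> float:
    """Tav-RNAseq: mean log2(FPKM + 1) over the signature genes present."""
    present = [g for g in signature.genes if g in fpkm.index]
    if not present:
        raise ValueError("no signature gene present in the FPKM profile")
    vals = fpkm.loc[present].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("FPKM values must be >= 0")
    return float(np.log2(vals + 1.0).mean())


def _ratio_in_window(num: float, den: float, rules: RuleConfig) -> bool:
    return rules.ratio_low < num / den < rules.ratio_high


def signature1_call(profile: CheckpointProfile, rules: RuleConfig | None = None) -> str:
    """Good iff both PD-L1/PD-1 and PD-L2/PD-1 lie strictly in (ratio_low, ratio_high)."""
    rules = rules or RuleConfig()
    if profile.pd1 == 0:
        warnings.warn(
            f"patient {profile.patient_id}: PD-1 = 0, ligand/receptor ratios "
            "undefined; classified bad"
        )
        return BAD
    ok = _ratio_in_window(profile.pdl1, profile.pd1, rules) and _ratio_in_window(
        profile.pdl2, profile.pd1, rules
    )
    return GOOD if ok else BAD


def signature2_call(profile: CheckpointProfile, rules: RuleConfig | None = None) -> str:
    """Good iff PD-L1/PD-1 lies in the window and Tav-RNAseq > tav_min."""
    rules = rules or RuleConfig()
    if profile.pd1 == 0:
        warnings.warn(
            f"patient {profile.patient_id}: PD-1 = 0, classified bad"
        )
        return BAD
    ok = (
        _ratio_in_window(profile.pdl1, profile.pd1, rules)
        and profile.tav_rnaseq > rules.tav_min
    )
    return GOOD if ok else BAD


def signature3_call(profile: CheckpointProfile, rules: RuleConfig | None = None) -> str:
    """Good iff signature-2 is good and PD-1/Tav-RNAseq > pd1_over_tav_min."""
    rules = rules or RuleConfig()
    if signature2_call(profile, rules) == BAD:
        return BAD
    if profile.tav_rnaseq <= 0:
        warnings.warn(
            f"patient {profile.patient_id}: Tav-RNAseq <= 0, PD-1/Tav ratio "
            "undefined; classified bad"
        )
        return BAD
    ok = profile.pd1 / profile.tav_rnaseq > rules.pd1_over_tav_min
    return GOOD if ok else BAD


_CALLERS = {
    "signature1": signature1_call,
    "signature2": signature2_call,
    "signature3": signature3_call,
}


def call_cohort(
    profiles: Sequence[CheckpointProfile],
    rule: str = "signature3",
    rules: RuleConfig | None = None,
) -> pd.Series:
    """Apply one rule to a cohort; returns good/bad indexed by patient_id."""
    if rule not in _CALLERS:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(_CALLERS)}")
    caller = _CALLERS[rule]
    return pd.Series(
        {p.patient_id: caller(p, rules) for p in profiles}, name=rule
    )


def overall_response_rate(
    calls: pd.Series | Mapping[str, str], responses: pd.Series | Mapping[str, str]
) -> dict[str, float | None]:
    """ORR (% of CR or PR) within the good and the bad group.

    An empty group's ORR is reported as ``None`` (missing), not an error.
    """
    calls = pd.Series(calls)
    responses = pd.Series(responses)
    missing = set(calls.index) - set(responses.index)
    if missing:
        raise ValueError(f"patients without a recorded response: {sorted(missing)}")
    bad_resp = set(responses.loc[calls.index]) - set(RESPONSES)
    if bad_resp:
        raise ValueError(f"unknown response values: {sorted(bad_resp)}")
    out: dict[str, float | None] = {}
    for group in (GOOD, BAD):
        ids = calls.index[calls == group]
        if len(ids) == 0:
            out[group] = None
            continue
        resp = responses.loc[ids]
        out[group] = float(100.0 * resp.isin(("CR", "PR")).mean())
    return out


def contingency_chi2(
    table: Sequence[Sequence[int]] | np.ndarray, correction: bool = False
) -> dict[str, float]:
    """Pearson chi-square on a 2x2 contingency table (1 df).

    No continuity correction by default; ``correction=True`` applies Yates.
    A zero row or column margin is an error (the test is undefined).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer) and not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = sps.chi2_contingency(arr, correction=correction)
    return {"chi2": float(res.statistic), "p_value": float(res.pvalue)}
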