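"""Cognitive staging, CSF pathology stratification, and pseudo-stage ordering.

The cross-sectional cohort is arranged along a disease-severity pseudo-axis:
participants are grouped by cognitive stage (CN -> MCI -> probable AD),
ordered within stage by global cognition (MMSE, descending) or dementia
severity (CDR sum of boxes, ascending), tie-broken by increasing age and
finally by participant id, then distributed evenly into contiguous bins.
The bin index is the "time" axis of the varying-coefficient model.

Pathology strata follow the published CSF cutoffs: amyloid positivity at
Abeta1-42 < 192 pg/mL and tau positivity at p-tau181 > 23 pg/mL; amyloid
positive participants are analysed as a single group (A+) regardless of
tau status, giving the three strata A-T-, A-T+ and A+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ABETA_CUTOFF",
    "PTAU_CUTOFF",
    "OrderedCohort",
    "classify_diagnosis",
    "stratify_pathology",
    "order_participants",
    "bin_participants",
]

ABETA_CUTOFF = 192.0  # pg/mL, CSF Abeta1-42; amyloid positive strictly below
PTAU_CUTOFF = 23.0  # pg/mL, CSF p-tau181; tau positive strictly above

STAGES = ("CN", "MCI", "AD")
PATHOLOGY_GROUPS = ("A-T-", "A-T+", "A+")


@dataclass
class OrderedCohort:
    """Deterministic severity ordering plus bin assignment for one cohort."""

    ids: list[str]  # participant ids in pseudo-stage order
    bins: np.ndarray  # bin index t_k (1..K) aligned with ``ids``
    strategy: str  # "split" (CN/MCI/AD) or "merged" (MCI+AD pooled)
    bin_size: int

    @property
    def n_bins(self) -> int:
        return int(self.bins.max()) if len(self.bins) else 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.ids,
                "order": np.arange(len(self.ids)),
                "bin": self.bins,
            }
        )


def classify_diagnosis(mmse: float, cdr_global: float, cdr_sob: float) -> str:
    """Stage label from MMSE and global CDR; helper for tables lacking one.

    CN: MMSE >= 24 and CDR 0.  MCI: MMSE >= 24 and CDR 0.5.  Probable AD:
    MMSE <= 26 and CDR >= 0.5.  The MCI/AD overlap (MMSE 24-26, CDR 0.5) is
    resolved as MCI, because the dementia label additionally requires a
    clinical judgement that scores alone cannot reproduce.  Combinations
    matching no rule return ``"unclassifiable"`` rather than a silent
    default.
    """
    if not (0 <= mmse <= 30):
        raise ValueError(f"MMSE out of range: {mmse}")
    if cdr_sob < 0:
        raise ValueError(f"CDR-SOB must be non-negative: {cdr_sob}")
    if mmse >= 24 and cdr_global == 0:
        return "CN"
    if mmse >= 24 and cdr_global == 0.5:
        return "MCI"
    if mmse <= 26 and cdr_global >= 0.5:
        return "AD"
    return "unclassifiable"


def stratify_pathology(csf_abeta: float, csf_ptau: float) -> str:
    """A/T stratum from CSF biomarkers (strict inequalities at the cutoffs).

    Amyloid positive participants form one group whatever their tau status.
    """
    if not (csf_abeta > 0 and csf_ptau > 0):
        raise ValueError("CSF values must be positive")
    if csf_abeta < ABETA_CUTOFF:
        return "A+"
    if csf_ptau > PTAU_CUTOFF:
        return "A-T+"
    return "A-T-"


def stratify_table(phenotypes: pd.DataFrame) -> pd.Series:
    """Vectorised stratification; rows with missing CSF become NA (excluded)."""
    out = []
    for _, row in phenotypes.iterrows():
        a, t = row["csf_abeta"], row["csf_ptau"]
        if pd.isna(a) or pd.isna(t):
            out.append(pd.NA)
        else:
            out.append(stratify_pathology(float(a), float(t)))
    return pd.Series(out, index=phenotypes.index, name="pathology")


def _stage_rank(diagnosis: pd.Series, strategy: str) -> pd.Series:
    if strategy == "split":
        ranks = {"CN": 0, "MCI": 1, "AD": 2}
    elif strategy == "merged":
        ranks = {"CN": 0, "MCI": 1, "AD": 1}
    else:
        raise ValueError(f"unknown ordering strategy: {strategy}")
    unknown = set(diagnosis.unique()) - set(ranks)
    if unknown:
        raise ValueError(f"unknown diagnosis labels: {sorted(unknown)}")
    return diagnosis.map(ranks)


def order_participants(records: pd.DataFrame, strategy: str = "split") -> pd.DataFrame:
    """Sort a phenotype table along the pseudo-stage axis.

    Requires columns ``subject_id, diagnosis, mmse, cdr_sob, age``.  CN
    participants are ordered by decreasing MMSE; MCI and dementia (pooled
    when ``strategy="merged"``) by increasing CDR-SOB; remaining ties by
    increasing age, then by id.  Returns a sorted copy with an ``order``
    column; deterministic and idempotent.
    """
    required = {"subject_id", "diagnosis", "mmse", "cdr_sob", "age"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns for ordering: {sorted(missing)}")
    df = records.copy()
    if df.empty:
        df["order"] = pd.Series(dtype=int)
        return df
    stage = _stage_rank(df["diagnosis"], strategy)
    # CN sorts on -MMSE, later stages on CDR-SOB: one ascending severity key.
    severity = np.where(stage == 0, -df["mmse"].to_numpy(float),
                        df["cdr_sob"].to_numpy(float))
    df = df.assign(_stage=stage, _sev=severity)
    df = df.sort_values(
        by=["_stage", "_sev", "age", "subject_id"], kind="mergesort"
    ).drop(columns=["_stage", "_sev"])
    df["order"] = np.arange(len(df))
    return df.reset_index(drop=True)


def bin_sizes(n: int, bin_size: int) -> list[int]:
    """Near-even contiguous partition: K = ceil(n/bin_size), sizes differ <=1.

    The remainder is spread over the leading bins (n=25, bin_size=10 ->
    sizes 9, 8, 8).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if n == 0:
        return []
    k = math.ceil(n / bin_size)
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def bin_participants(
    ordered: pd.DataFrame,
    bin_size: int = 10,
    strategy: str = "split",
) -> OrderedCohort:
    """Assign contiguous near-even bins along an ordered cohort.

    ``ordered`` must carry an ``order`` column (from
    :func:`order_participants`); the bin index 1..K is monotone in the
    order.
    """
    if "order" not in ordered.columns:
        raise ValueError("input is not ordered; run order_participants first")
    df = ordered.sort_values("order")
    sizes = bin_sizes(len(df), bin_size)
    bins = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    return OrderedCohort(
        ids=list(df["subject_id"]),
        bins=bins,
        strategy=strategy,
        bin_size=bin_size,
    )


def order_and_bin(
    records: pd.DataFrame,
    strategy: str = "split",
    bin_size: int = 10,
) -> pd.DataFrame:
    """Convenience: ordered table with ``order`` and ``bin`` columns added."""
    ordered = order_participants(records, strategy=strategy)
    cohort = bin_participants(ordered, bin_size=bin_size, strategy=strategy)
    ordered["bin"] = cohort.bins
    return ordered
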