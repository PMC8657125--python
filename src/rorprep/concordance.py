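"""Agreement statistics between two subtype/score sets on shared samples.

Used to compare risk scores and subtype calls produced from two
preparations of the same tumors (e.g. macrodissected FFPE vs fresh-frozen
bulk tissue) or against a reference assay.  All comparisons run on the
intersection of sample IDs; signed differences are always first argument
minus second.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from rorprep.io import PROLIFERATION_GENES, SUBTYPES, ClinicalTable, ExpressionMatrix
from rorprep.ror import RORResult, categorize_risk

__all__ = [
    "ScoreAgreement",
    "ConfusionMatrix",
    "DiscordanceRecord",
    "score_agreement",
    "subtype_confusion",
    "risk_group_discordance",
    "per_gene_cross_correlation",
    "SUBSET_FILTERS",
]


@dataclasses.dataclass(frozen=True)
class ScoreAgreement:
    """Pairwise score agreement; differences follow the A − B convention."""

    r_squared: float
    mean_abs_diff: float
    signed_diff_min: float
    signed_diff_max: float
    n: int
    diff_convention: str = "A - B"


@dataclasses.dataclass
class ConfusionMatrix:
    """5x5 subtype call counts: rows = set A calls, columns = set B calls."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(index=list(SUBTYPES), columns=list(SUBTYPES),
                                          fill_value=0).astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def concordance(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return self.counts


@dataclasses.dataclass(frozen=True)
class DiscordanceRecord:
    """One sample whose risk category differs between the two score sets."""

    sample_id: str
    category_A: str
    category_B: str
    ror_A: float
    ror_B: float
    signed_diff: float
    subtype_A: str | None = None
    subtype_B: str | None = None


def _as_series(scores, label: str) -> pd.Series:
    if isinstance(scores, RORResult):
        return scores.ror_by_sample()
    s = pd.Series(scores)
    if not np.all(np.isfinite(s.to_numpy(dtype=float))):
        raise ValueError(f"non-finite scores in {label}")
    return s.astype(float)


def _intersect(a: pd.Series, b: pd.Series) -> list:
    shared = [s for s in a.index if s in set(b.index)]
    if len(shared) < len(a) or len(shared) < len(b):
        warnings.warn(
            f"comparison restricted to {len(shared)} shared samples "
            f"(A has {len(a)}, B has {len(b)})", stacklevel=3,
        )
    return shared


def score_agreement(ror_A, ror_B) -> ScoreAgreement:
    """r² (squared Pearson), mean absolute and signed extreme differences.

    Accepts sample-indexed Series or RORResult objects; runs on the
    intersection of sample IDs (at least 3 required).
    """
    a = _as_series(ror_A, "A")
    b = _as_series(ror_B, "B")
    shared = _intersect(a, b)
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared samples, have {len(shared)}")
    av, bv = a[shared].to_numpy(), b[shared].to_numpy()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("zero variance in one score set; r^2 undefined")
    r = stats.pearsonr(av, bv).statistic
    diff = av - bv
    return ScoreAgreement(
        r_squared=float(r ** 2),
        mean_abs_diff=float(np.mean(np.abs(diff))),
        signed_diff_min=float(diff.min()),
        signed_diff_max=float(diff.max()),
        n=len(shared),
    )


def subtype_confusion(calls_A, calls_B) -> ConfusionMatrix:
    """Cross-tabulate two subtype call sets over shared samples."""
    a, b = pd.Series(calls_A), pd.Series(calls_B)
    shared = _intersect(a, b)
    if not shared:
        raise ValueError("no shared samples between the two call sets")
    counts = pd.crosstab(a[shared], b[shared])
    return ConfusionMatrix(counts)


def _eligible_er_pos_her2_neg_pn0(clinical: ClinicalTable) -> list[str]:
    """Samples eligible for clinical risk testing: ER+, HER2−, node-negative."""
    df = clinical.table
    mask = df["nodes"] == "pN0"
    if "er_status" in df.columns:
        mask &= df["er_status"].astype(str).str.lower().isin(["er_pos", "pos", "positive", "1", "true"])
    if "her2_status" in df.columns:
        mask &= ~df["her2_status"].astype(str).str.lower().isin(["pos", "positive", "1", "true"])
    return list(df.loc[mask, "sample_id"])


SUBSET_FILTERS = {
    "all": lambda clinical: list(clinical.samples),
    "er_pos_her2_neg_pn0": _eligible_er_pos_her2_neg_pn0,
}


def risk_group_discordance(
    ror_A: RORResult,
    ror_B: RORResult,
    clinical: ClinicalTable,
    subset: str = "all",
) -> list[DiscordanceRecord]:
    """List samples whose risk category differs between two score sets.

    Records are ordered by signed score difference (A − B), descending.
    Both inputs must have been categorized under the same threshold table.
    ``subset`` names a predefined eligibility filter (``all`` or
    ``er_pos_her2_neg_pn0``).
    """
    if ror_A.category is None or ror_B.category is None:
        raise ValueError("both score sets must be categorized")
    if ror_A.thresholds != ror_B.thresholds:
        raise ValueError("score sets categorized under different threshold tables")
    if subset not in SUBSET_FILTERS:
        raise ValueError(f"unknown subset filter {subset!r}; options: {sorted(SUBSET_FILTERS)}")
    keep = set(SUBSET_FILTERS[subset](clinical))
    cat_a = pd.Series(ror_A.category, index=ror_A.samples)
    cat_b = pd.Series(ror_B.category, index=ror_B.samples)
    sc_a = ror_A.ror_by_sample()
    sc_b = ror_B.ror_by_sample()
    shared = [s for s in _intersect(sc_a, sc_b) if s in keep]
    records = [
        DiscordanceRecord(
            sample_id=s,
            category_A=cat_a[s], category_B=cat_b[s],
            ror_A=float(sc_a[s]), ror_B=float(sc_b[s]),
            signed_diff=float(sc_a[s] - sc_b[s]),
        )
        for s in shared
        if cat_a[s] != cat_b[s]
    ]
    return sorted(records, key=lambda r: -r.signed_diff)


def per_gene_cross_correlation(
    expr_A: ExpressionMatrix,
    expr_B: ExpressionMatrix,
    *,
    flag_threshold: float = 0.75,
) -> pd.DataFrame:
    """Pearson r per shared gene across shared samples of two matrices.

    Zero-variance genes get ``r = NaN`` and are flagged rather than raising;
    proliferation-signature genes are marked so platform effects on the risk
    score's proliferation component are visible at a glance.
    """
    shared_samples = [s for s in expr_A.samples if s in set(expr_B.samples)]
    if len(shared_samples) < 3:
        raise ValueError("need at least 3 shared samples for per-gene correlation")
    shared_genes = [g for g in expr_A.genes if g in set(expr_B.genes)]
    if not shared_genes:
        raise ValueError("no shared genes between the matrices")
    fa = expr_A.to_frame()[shared_samples].loc[shared_genes]
    fb = expr_B.to_frame()[shared_samples].loc[shared_genes]
    rows = []
    for g in shared_genes:
        x, y = fa.loc[g].to_numpy(), fb.loc[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append({
            "gene": g,
            "r": r,
            "flagged": bool(np.isnan(r) or r <= flag_threshold),
            "is_proliferation": g in PROLIFERATION_GENES,
        })
    return pd.DataFrame(rows)
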