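"""Proliferation score, continuous risk-of-recurrence score, risk category.

The continuous score is a fixed linear combination of the sample's Pearson
correlations to the basal-like, HER2-enriched, luminal A and luminal B
centroids, an 18-gene proliferation score, and a binary tumor-size
indicator:

    ROR = 54.7690 * (-0.0067*Basal + 0.4317*HER2 - 0.3172*LumA
                     + 0.4894*LumB + 0.1981*prolif + 0.1133*T + 0.8826)

calibrated to a 0–100 scale (higher = higher risk of distant recurrence).
Risk categories depend on nodal status: node-negative cutoffs are 40/60,
1–3 positive nodes use 15/40, and 4 or more positive nodes are high risk
regardless of score.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from rorprep.io import PROLIFERATION_GENES, ClinicalTable, ExpressionMatrix
from rorprep.subtype import SubtypeResult

__all__ = [
    "RORCoefficients",
    "RiskThresholds",
    "RORResult",
    "proliferation_score",
    "ror_score",
    "categorize_risk",
]

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"


@dataclasses.dataclass(frozen=True)
class RORCoefficients:
    """The published linear-model constants; immutable by construction."""

    scale: float = 54.7690
    c_basal: float = -0.0067
    c_her2: float = 0.4317
    c_luma: float = -0.3172
    c_lumb: float = 0.4894
    c_prolif: float = 0.1981
    c_T: float = 0.1133
    intercept: float = 0.8826


@dataclasses.dataclass(frozen=True)
class RiskThresholds:
    """(lower, upper) category cutoffs per nodal class; pN4plus is always high."""

    pN0: tuple[float, float] = (40.0, 60.0)
    pN1_3: tuple[float, float] = (15.0, 40.0)

    def __post_init__(self) -> None:
        for name in ("pN0", "pN1_3"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} thresholds must satisfy lower < upper")


@dataclasses.dataclass
class RORResult:
    """Per-sample proliferation score, continuous ROR and risk category."""

    samples: list[str]
    prolif: np.ndarray
    ror_continuous: np.ndarray
    T: np.ndarray
    node_class: np.ndarray | None = None
    category: np.ndarray | None = None
    clipped: np.ndarray | None = None
    thresholds: RiskThresholds = dataclasses.field(default_factory=RiskThresholds)

    def __post_init__(self) -> None:
        self.prolif = np.asarray(self.prolif, dtype=float)
        self.ror_continuous = np.asarray(self.ror_continuous, dtype=float)
        self.T = np.asarray(self.T, dtype=int)
        if self.clipped is None:
            self.clipped = (self.ror_continuous < 0) | (self.ror_continuous > 100)

    def ror_by_sample(self) -> pd.Series:
        return pd.Series(self.ror_continuous, index=self.samples, name="ror")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": self.samples,
            "prolif": self.prolif,
            "T": self.T,
            "ror": self.ror_continuous,
            "clipped": self.clipped,
        })
        if self.node_class is not None:
            df["node_class"] = self.node_class
        if self.category is not None:
            df["category"] = self.category
        return df


def proliferation_score(centered: ExpressionMatrix) -> pd.Series:
    """Arithmetic mean of the 18 proliferation genes per sample.

    All 18 genes must be present after alias resolution — a silent mean over
    fewer genes would shift the score scale.
    """
    missing = [g for g in PROLIFERATION_GENES if g not in centered.genes]
    if missing:
        raise ValueError(f"proliferation genes missing from matrix: {missing}")
    sub = centered.subset_genes(list(PROLIFERATION_GENES))
    return pd.Series(sub.values.mean(axis=0), index=centered.samples, name="prolif")


def categorize_risk(
    ror_continuous,
    node_class,
    thresholds: RiskThresholds | None = None,
):
    """Map continuous scores to low / intermediate / high by nodal class.

    Boundary convention (fixed by the published categorized scores):
    low <= lower cutoff < intermediate <= upper cutoff < high.  Four or
    more positive nodes are high risk at any score.  Accepts scalars or
    aligned arrays.
    """
    thresholds = thresholds or RiskThresholds()
    scores = np.atleast_1d(np.asarray(ror_continuous, dtype=float))
    nodes = np.atleast_1d(np.asarray(node_class, dtype=object))
    if nodes.size == 1 and scores.size > 1:
        nodes = np.repeat(nodes, scores.size)
    if not np.all(np.isfinite(scores)):
        raise ValueError("risk categorization needs finite scores")
    out = np.empty(scores.shape, dtype=object)
    for i, (s, n) in enumerate(zip(scores, nodes)):
        if n == "pN4plus":
            out[i] = HIGH
            continue
        try:
            lo, hi = getattr(thresholds, str(n))
        except AttributeError:
            raise ValueError(f"unknown node class {n!r}") from None
        out[i] = LOW if s <= lo else (INTERMEDIATE if s <= hi else HIGH)
    if np.isscalar(ror_continuous) or np.ndim(ror_continuous) == 0:
        return out[0]
    return out


def ror_score(
    subtypes: SubtypeResult,
    prolif: pd.Series,
    clinical: ClinicalTable | None = None,
    coeffs: RORCoefficients | None = None,
    *,
    T: Mapping[str, int] | None = None,
    thresholds: RiskThresholds | None = None,
    categorize: bool = True,
    clip: bool = False,
) -> RORResult:
    """Evaluate the risk-of-recurrence linear model per sample.

    Tumor-size indicators come from ``clinical`` (or an explicit ``T``
    mapping); nodal classes from ``clinical`` drive categorization when
    requested.  By default the raw continuous value is reported with a
    ``clipped`` flag when it falls outside [0, 100]; ``clip`` truncates to
    that range for display parity with the commercial report.
    """
    coeffs = coeffs or RORCoefficients()
    thresholds = thresholds or RiskThresholds()
    samples = list(subtypes.samples)
    corr = subtypes.ror_inputs()
    p = prolif.reindex(samples)
    if p.isna().any():
        raise ValueError("proliferation score missing for some samples")

    if T is not None:
        t_vec = np.array([T[s] for s in samples], dtype=int)
    elif clinical is not None:
        t_vec = np.array([clinical.size_indicator(s) for s in samples], dtype=int)
    else:
        raise ValueError("tumor-size indicator T required (clinical table or T mapping)")

    linear = (
        coeffs.c_basal * corr["Basal"].to_numpy()
        + coeffs.c_her2 * corr["Her2"].to_numpy()
        + coeffs.c_luma * corr["LumA"].to_numpy()
        + coeffs.c_lumb * corr["LumB"].to_numpy()
        + coeffs.c_prolif * p.to_numpy()
        + coeffs.c_T * t_vec
        + coeffs.intercept
    )
    ror = coeffs.scale * linear
    clipped = (ror < 0) | (ror > 100)
    if clip:
        ror = np.clip(ror, 0.0, 100.0)

    node = category = None
    if categorize:
        if clinical is None:
            raise ValueError("node classes required for categorization; pass a clinical table")
        node = np.array([clinical.node_class(s) for s in samples], dtype=object)
        category = categorize_risk(ror, node, thresholds)
    return RORResult(samples, p.to_numpy(), ror, t_vec, node, category, clipped, thresholds)
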