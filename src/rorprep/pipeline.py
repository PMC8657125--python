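"""End-to-end scoring of one cohort: ER call, centering, subtype, risk score."""

from __future__ import annotations

import dataclasses

import pandas as pd

from rorprep.er import ERCall, call_er_status, weighted_center
from rorprep.io import CentroidSet, ClinicalTable, ExpressionMatrix, load_centroids
from rorprep.ror import RiskThresholds, RORResult, proliferation_score, ror_score
from rorprep.subtype import SubtypeResult, assign_subtypes, centroid_correlations

__all__ = ["CohortScores", "score_cohort"]


@dataclasses.dataclass
class CohortScores:
    """All per-cohort pipeline outputs in one place."""

    er: ERCall
    subtypes: SubtypeResult
    ror: RORResult | None

    def to_frame(self) -> pd.DataFrame:
        df = self.subtypes.to_frame()
        if self.ror is not None:
            df = df.merge(self.ror.to_frame(), on="sample_id")
        df["er_status"] = self.er.status
        return df


def score_cohort(
    expr: ExpressionMatrix,
    clinical: ClinicalTable | None = None,
    centroids: CentroidSet | None = None,
    *,
    seed: int = 0,
    er_weight: float = 0.6,
    er_gene: str = "ESR1",
    er_status: pd.Series | None = None,
    thresholds: RiskThresholds | None = None,
    allow_missing: bool = False,
) -> CohortScores:
    """Run the full scoring pipeline on one expression matrix.

    The matrix is centered within its own cohort (each platform is centered
    separately by construction — call once per matrix).  ``er_status``
    overrides the mixture-based ER call with externally determined labels
    (e.g. from IHC).  Risk scores are computed only when a clinical table
    supplies the tumor-size indicator and nodal class.
    """
    if er_status is not None:
        import numpy as np
        status = er_status.reindex(expr.samples).astype(str).to_numpy(dtype=object)
        post = np.where(status == "ER_pos", 1.0, 0.0)
        er = ERCall(list(expr.samples), status, post, threshold=float("nan"), gene=er_gene)
    else:
        er = call_er_status(expr, gene=er_gene, seed=seed)
    centered, _ = weighted_center(expr, er, w=er_weight)
    subtypes = assign_subtypes(
        centroid_correlations(centered, centroids or load_centroids(),
                              allow_missing=allow_missing))
    ror = None
    if clinical is not None:
        prolif = proliferation_score(centered)
        ror = ror_score(subtypes, prolif, clinical, thresholds=thresholds)
    return CohortScores(er, subtypes, ror)
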