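"""Nearest-centroid intrinsic subtyping on the reduced 46-gene panel.

Each centered sample profile is correlated (Pearson) with the five subtype
centroids — basal-like, HER2-enriched, luminal A, luminal B and normal-like —
over the 46 retained genes, and the sample is assigned to the subtype with
the highest correlation.  Every sample receives a call; the runner-up
subtype and the margin (top minus second correlation) quantify how close
the call was.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from rorprep.io import SUBTYPES, CentroidSet, ExpressionMatrix

__all__ = ["SubtypeResult", "centroid_correlations", "assign_subtypes", "pearson_matrix"]


@dataclasses.dataclass
class SubtypeResult:
    """Per-sample centroid correlations and the resulting subtype call.

    ``corr`` columns follow the fixed subtype order (Basal, Her2, LumA,
    LumB, Normal).  The normal-like correlation participates in the call
    but is never an input to the risk score; downstream code reads the
    four risk-score correlations through :meth:`ror_inputs`, which omits
    it by construction.
    """

    samples: list[str]
    corr: np.ndarray                 # n_samples x 5, in SUBTYPES order
    call: np.ndarray | None = None
    runner_up: np.ndarray | None = None
    margin: np.ndarray | None = None
    tie: np.ndarray | None = None
    n_genes_used: int = 46

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (len(self.samples), len(SUBTYPES)):
            raise ValueError("corr must be n_samples x 5")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ValueError("correlations outside [-1, 1]")

    def ror_inputs(self) -> pd.DataFrame:
        """Correlations to the four tumor subtypes (normal-like excluded)."""
        df = pd.DataFrame(self.corr, index=self.samples, columns=list(SUBTYPES))
        return df[["Basal", "Her2", "LumA", "LumB"]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.corr, columns=[f"corr_{s}" for s in SUBTYPES])
        df.insert(0, "sample_id", self.samples)
        if self.call is not None:
            df["call"] = self.call
            df["runner_up"] = self.runner_up
            df["margin"] = self.margin
            df["tie"] = self.tie
        df["n_genes_used"] = self.n_genes_used
        return df


def pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``x`` with each column of ``y``.

    Columns are observations over the same genes.  Raises on zero-variance
    columns of ``x`` (the per-sample profiles); callers guard ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xs = np.sqrt((xc ** 2).sum(axis=0))
    ys = np.sqrt((yc ** 2).sum(axis=0))
    if np.any(ys == 0):
        raise ValueError("zero-variance centroid profile")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(xs, ys)
    return r


def centroid_correlations(
    centered: ExpressionMatrix,
    centroids: CentroidSet,
    *,
    allow_missing: bool = False,
) -> SubtypeResult:
    """Correlate each sample with the five centroids on the 46-gene set.

    With ``allow_missing`` the correlation runs on the intersection of the
    matrix's genes with the 46 retained genes, and the result records how
    many genes were used.
    """
    wanted = centroids.reduced_genes
    present = set(centered.genes)
    genes = [g for g in wanted if g in present] if allow_missing else wanted
    if not allow_missing:
        missing = [g for g in wanted if g not in present]
        if missing:
            raise ValueError(
                f"centered matrix missing {len(missing)} of the 46 retained "
                f"genes: {missing}; pass allow_missing=True to use the intersection"
            )
    if len(genes) < 2:
        raise ValueError("fewer than 2 retained genes available for correlation")
    sub = centered.subset_genes(genes)
    cent_idx = [centroids.genes.index(g) for g in genes]
    cent = centroids.values[cent_idx, :]
    flat = np.ptp(sub.values, axis=0) == 0
    if np.any(flat):
        bad = [s for s, f in zip(sub.samples, flat) if f]
        raise ValueError(
            f"zero variance across the retained genes for sample(s) {bad}; "
            "correlation undefined"
        )
    corr = pearson_matrix(sub.values, cent)
    return SubtypeResult(list(centered.samples), corr, n_genes_used=len(genes))


def assign_subtypes(result: SubtypeResult) -> SubtypeResult:
    """Fill call, runner-up and margin by argmax over the correlations.

    Exact ties go to the earlier subtype in the fixed order (Basal, Her2,
    LumA, LumB, Normal) and are flagged.
    """
    corr = result.corr
    order = np.argsort(-corr, axis=1, kind="stable")  # stable => fixed-order ties
    best = order[:, 0]
    second = order[:, 1]
    subtype_arr = np.array(SUBTYPES, dtype=object)
    result.call = subtype_arr[best]
    result.runner_up = subtype_arr[second]
    result.margin = corr[np.arange(len(best)), best] - corr[np.arange(len(best)), second]
    result.tie = result.margin == 0.0
    return result
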