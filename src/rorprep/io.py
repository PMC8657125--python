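"""Readers, writers and core containers for PAM50 expression data.

Expression matrices are log2-scale, genes x samples, tab-separated with a
``gene`` column first and sample IDs in the header.  Gene symbols are
resolved to canonical HGNC names through a packaged alias map before any
validation, so files written with legacy symbols (``ORC6L``, ``KNTC2``,
``CDCA1``, ...) load transparently.

The packaged centroid file (``data/synthetic_pam50_centroids.tsv``) is a
SYNTHETIC stand-in for the published PAM50 subtype centroids: it has the
same shape and qualitative block structure (proliferation cluster, luminal/ER
cluster, HER2 amplicon, basal keratins, normal-like profile) but its numbers
are constructed, not measured.  Any conforming ``gene, Basal, Her2, LumA,
LumB, Normal`` TSV can be loaded in its place.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PAM50_GENES",
    "REDUCED_EXCLUDED_GENES",
    "PROLIFERATION_GENES",
    "SUBTYPES",
    "GENE_ALIASES",
    "Platform",
    "ExpressionMatrix",
    "CentroidSet",
    "ClinicalTable",
    "resolve_aliases",
    "load_expression_matrix",
    "write_expression_matrix",
    "load_centroids",
    "packaged_centroid_path",
    "load_clinical",
    "load_discordant_reference",
    "write_report",
]

#: The five intrinsic subtypes, in the fixed order used throughout.
SUBTYPES: tuple[str, ...] = ("Basal", "Her2", "LumA", "LumB", "Normal")

#: Canonical HGNC symbols of the 50-gene panel, alphabetical.
PAM50_GENES: tuple[str, ...] = (
    "ACTR3B", "ANLN", "BAG1", "BCL2", "BIRC5", "BLVRA", "CCNB1", "CCNE1",
    "CDC20", "CDC6", "CDH3", "CENPF", "CEP55", "CXXC5", "EGFR", "ERBB2",
    "ESR1", "EXO1", "FGFR4", "FOXA1", "FOXC1", "GPR160", "GRB7", "KIF2C",
    "KRT14", "KRT17", "KRT5", "MAPT", "MDM2", "MELK", "MIA", "MKI67",
    "MLPH", "MMP11", "MYBL2", "MYC", "NAT1", "NDC80", "NUF2", "ORC6",
    "PGR", "PHGDH", "PTTG1", "RRM2", "SFRP1", "SLC39A6", "TMEM45B", "TYMS",
    "UBE2C", "UBE2T",
)

#: Genes dropped from the 50-gene panel for subtype correlation (46 remain).
REDUCED_EXCLUDED_GENES: frozenset[str] = frozenset({"BIRC5", "CCNB1", "GRB7", "MYBL2"})

#: The 18-gene proliferation signature (canonical symbols).
PROLIFERATION_GENES: tuple[str, ...] = (
    "ANLN", "CEP55", "ORC6", "CCNE1", "EXO1", "PTTG1", "CDC20", "KIF2C",
    "RRM2", "CDC6", "NDC80", "TYMS", "NUF2", "MELK", "UBE2C", "CENPF",
    "MKI67", "UBE2T",
)

#: Legacy -> canonical gene symbol map. Identity for canonical symbols.
GENE_ALIASES: Mapping[str, str] = {
    "ORC6L": "ORC6",
    "KNTC2": "NDC80",
    "CDCA1": "NUF2",
    "ERS1": "ESR1",   # common transposition of ESR1
    "MKI-67": "MKI67",
    "C-MYC": "MYC",
    "HER2": "ERBB2",
    "KRT5/6": "KRT5",
}


class Platform(str, enum.Enum):
    """Origin of an expression matrix."""

    nCounter_FFPE = "nCounter_FFPE"
    RNAseq_FF = "RNAseq_FF"
    simulated = "simulated"


def resolve_aliases(genes: Iterable[str]) -> list[str]:
    """Map legacy gene symbols to canonical HGNC names (idempotent)."""
    return [GENE_ALIASES.get(g, g) for g in genes]


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {kind} {lab!r}")
        seen.add(lab)


@dataclasses.dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with a platform tag."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    platform: Platform = Platform.simulated

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        self.platform = Platform(self.platform)
        if len(self.genes) < 2:
            raise ValueError("expression matrix needs at least 2 genes")
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(GENE_ALIASES.get(gene, gene))
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(
            [self.genes[i] for i in idx], self.samples,
            self.values[idx, :], self.platform,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclasses.dataclass
class CentroidSet:
    """Per-subtype mean profiles of the 50-gene panel.

    ``reduced_gene_mask`` marks the 46 genes retained for subtype
    correlation; the four excluded genes are fixed by the assay definition.
    """

    genes: list[str]
    subtypes: tuple[str, ...]
    values: np.ndarray
    reduced_gene_mask: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.subtypes = tuple(self.subtypes)
        self.values = np.asarray(self.values, dtype=float)
        self.reduced_gene_mask = np.asarray(self.reduced_gene_mask, dtype=bool)
        if len(self.genes) != 50:
            raise ValueError(f"centroid set must have exactly 50 genes, got {len(self.genes)}")
        if self.subtypes != SUBTYPES:
            raise ValueError(f"subtypes must be {SUBTYPES}, got {self.subtypes}")
        if self.values.shape != (50, 5):
            raise ValueError(f"centroid values must be 50 x 5, got {self.values.shape}")
        excluded = {g for g, keep in zip(self.genes, self.reduced_gene_mask) if not keep}
        if excluded != set(REDUCED_EXCLUDED_GENES):
            raise ValueError(
                f"reduced mask must exclude exactly {sorted(REDUCED_EXCLUDED_GENES)}, "
                f"excludes {sorted(excluded)}"
            )

    @property
    def reduced_genes(self) -> list[str]:
        return [g for g, keep in zip(self.genes, self.reduced_gene_mask) if keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=list(self.subtypes))


NODE_CLASSES = ("pN0", "pN1_3", "pN4plus")

_NODE_SYNONYMS = {
    "pn0": "pN0", "0": "pN0", "n0": "pN0",
    "pn1_3": "pN1_3", "pn1-3": "pN1_3", "1-3": "pN1_3", "pn1": "pN1_3",
    "pn2": "pN1_3",
    "pn4plus": "pN4plus", "pn4+": "pN4plus", "4+": "pN4plus", "pn3": "pN4plus",
}


def _normalize_node(value) -> str:
    if isinstance(value, (int, np.integer)):
        n = int(value)
        return "pN0" if n == 0 else ("pN1_3" if n <= 3 else "pN4plus")
    key = str(value).strip().lower()
    if key in _NODE_SYNONYMS:
        return _NODE_SYNONYMS[key]
    raise ValueError(f"unrecognized node status {value!r}")


@dataclasses.dataclass
class ClinicalTable:
    """Per-sample clinical covariates used for scoring and comparison.

    ``nodes`` holds the nodal class (pN0 / pN1_3 / pN4plus) that selects the
    risk-category threshold pair; ``size_gt_2cm`` is the tumor-size indicator
    entering the risk score.  Reference assay columns (subtype and integer
    risk score) and receptor statuses are optional.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "nodes", "size_gt_2cm")
    OPTIONAL = ("prosigna_subtype", "prosigna_ror", "er_status", "her2_status")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        _check_unique(list(df["sample_id"].astype(str)), "sample")
        df["sample_id"] = df["sample_id"].astype(str)
        df["nodes"] = [_normalize_node(v) for v in df["nodes"]]
        df["size_gt_2cm"] = df["size_gt_2cm"].astype(bool)
        if "prosigna_ror" in df.columns:
            ok = df["prosigna_ror"].isna() | df["prosigna_ror"].between(0, 100)
            if not ok.all():
                bad = df.loc[~ok, "sample_id"].tolist()
                raise ValueError(f"prosigna_ror outside [0, 100] for samples {bad}")
        self.table = df.set_index("sample_id", drop=False)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def node_class(self, sample: str) -> str:
        return self.table.at[sample, "nodes"]

    def size_indicator(self, sample: str) -> int:
        return int(self.table.at[sample, "size_gt_2cm"])


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str})


def load_expression_matrix(
    path,
    platform: Platform | str,
    *,
    allow_missing: bool = False,
) -> ExpressionMatrix:
    """Load a genes-x-samples TSV, resolving legacy gene symbols.

    When all 50 panel genes are present the rows are reordered to the
    canonical panel order.  Missing panel genes are a hard error unless
    ``allow_missing`` is set, in which case downstream steps work on the
    intersection and record the gene count they used.
    """
    df = _read_tsv(path)
    gene_col = df.columns[0]
    raw_genes = [str(g) for g in df[gene_col]]
    genes = resolve_aliases(raw_genes)
    seen: dict[str, str] = {}
    for raw, canon in zip(raw_genes, genes):
        if canon in seen:
            raise ValueError(
                f"duplicate gene {canon!r} after alias resolution "
                f"(rows {seen[canon]!r} and {raw!r})"
            )
        seen[canon] = raw
    body = df.drop(columns=[gene_col])
    for col in body.columns:
        numeric = pd.to_numeric(body[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ValueError(
                f"non-numeric value {body[col].iloc[row]!r} at gene "
                f"{raw_genes[row]!r}, column {col!r}"
            )
        body[col] = numeric
    values = body.to_numpy(dtype=float)
    samples = [str(s) for s in body.columns]

    present = set(genes)
    missing = [g for g in PAM50_GENES if g not in present]
    if missing and not allow_missing and present & set(PAM50_GENES):
        raise ValueError(
            f"{len(missing)} panel genes missing: {missing}; "
            "pass allow_missing=True to score on the intersection"
        )
    if not missing and len(genes) == 50:
        order = [genes.index(g) for g in PAM50_GENES]
        genes = [genes[i] for i in order]
        values = values[order, :]
    return ExpressionMatrix(genes, samples, values, Platform(platform))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV with 6-decimal values (round-trip safe)."""
    df = matrix.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6f")


def packaged_centroid_path() -> Path:
    """Path of the packaged (synthetic) centroid TSV."""
    return Path(resources.files("rorprep").joinpath("data/synthetic_pam50_centroids.tsv"))


def load_centroids(path=None) -> CentroidSet:
    """Load a ``gene, Basal, Her2, LumA, LumB, Normal`` centroid TSV.

    Defaults to the packaged synthetic centroid set.  Aliases are resolved;
    the gene set must be exactly the 50-gene panel.
    """
    if path is None:
        path = packaged_centroid_path()
    df = _read_tsv(path)
    gene_col = df.columns[0]
    for subtype in SUBTYPES:
        if subtype not in df.columns:
            raise ValueError(f"centroid file missing subtype column {subtype!r}")
    genes = resolve_aliases([str(g) for g in df[gene_col]])
    if sorted(genes) != sorted(PAM50_GENES):
        extra = sorted(set(genes) - set(PAM50_GENES))
        missing = sorted(set(PAM50_GENES) - set(genes))
        raise ValueError(
            f"centroid gene set must be the 50-gene panel after alias "
            f"resolution; missing {missing}, unexpected {extra}"
        )
    order = np.argsort([PAM50_GENES.index(g) for g in genes])
    genes = [genes[i] for i in order]
    values = df[list(SUBTYPES)].to_numpy(dtype=float)[order, :]
    mask = np.array([g not in REDUCED_EXCLUDED_GENES for g in genes])
    return CentroidSet(genes, SUBTYPES, values, mask)


def load_discordant_reference() -> pd.DataFrame:
    """Published risk scores for the 13 cases where the macrodissected-FFPE
    and bulk fresh-frozen preparations disagreed on risk group.

    Columns: sample_id, subtype, prosigna_ror, prosigna_category, ror_macro,
    category_macro, ror_bulk, category_bulk.  Continuous scores are on the
    0-100 scale; categories follow the node-negative 40/60 cutoffs.
    """
    path = resources.files("rorprep").joinpath("data/discordant_ror_reference.tsv")
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def load_clinical(path) -> ClinicalTable:
    """Load a clinical TSV (``sample_id, nodes, size_gt_2cm, ...``)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(df)


def _config_hash(metadata: Mapping) -> str:
    canon = json.dumps(metadata, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report(results, path, format: str = "tsv", *, metadata: Mapping | None = None,
                 seed: int | None = None) -> None:
    """Write a result collection as TSV or JSON.

    ``results`` may be a DataFrame, a list of mappings, or any object with a
    ``to_frame()`` method.  JSON reports embed the package version, a hash of
    the supplied metadata (configuration) and the seed, so a run can be
    reproduced from its report alone.
    """
    from rorprep import __version__

    if hasattr(results, "to_frame"):
        df = results.to_frame()
    elif isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(list(results))
    if df.empty:
        raise ValueError("refusing to write an empty report")
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif format == "json":
        meta = dict(metadata or {})
        payload = {
            "version": __version__,
            "config_hash": _config_hash(meta),
            "config": meta,
            "seed": seed,
            "results": json.loads(df.to_json(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ValueError(f"unknown report format {format!r}")
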