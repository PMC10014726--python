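"""Quality control of CITE-seq antibody-derived tag (ADT) data.

Covers the sequencing-side defined computations of the pipeline: per-cell
quality filters (mitochondrial UMI fraction with tissue-specific ceilings,
minimum detected genes, and an antibody-aggregate ceiling on total ADT
counts), per-antibody minimum background cut-offs on the ADT count
distribution, and the RNA-vs-protein concordance categorization.

Normalization, clustering, integration and annotation are deliberately out
of scope; cluster assignments arrive as plain input columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .flow_model import ConfigError, SchemaError, ValidationError

__all__ = [
    "AdtMatrix",
    "QcThresholds",
    "ConcordanceCategory",
    "ConcordanceCall",
    "read_adt_matrix",
    "write_adt_matrix",
    "filter_cells",
    "adt_min_cutoff",
    "apply_adt_cutoffs",
    "rna_protein_concordance",
]


@dataclass
class AdtMatrix:
    """Sparse cells x antibodies matrix of non-negative integer ADT counts."""

    cells: list[str]
    antibodies: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.antibodies)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.antibodies)} antibodies"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("cell barcodes must be unique")
        if len(set(self.antibodies)) != len(self.antibodies):
            raise ValidationError("antibody names must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("ADT counts must be non-negative")

    def column(self, antibody: str) -> np.ndarray:
        try:
            j = self.antibodies.index(antibody)
        except ValueError:
            raise SchemaError(f"unknown antibody {antibody!r}") from None
        return np.asarray(self.counts[:, j].todense()).ravel()

    def total_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def read_adt_matrix(mtx_path: str | Path, cells_path: str | Path,
                    features_path: str | Path) -> AdtMatrix:
    """Read an ADT matrix from MatrixMarket triplet + name files."""
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    cells = Path(cells_path).read_text().split()
    antibodies = Path(features_path).read_text().split()
    return AdtMatrix(cells=cells, antibodies=antibodies, counts=counts)


def write_adt_matrix(matrix: AdtMatrix, mtx_path: str | Path,
                     cells_path: str | Path, features_path: str | Path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.counts))
    Path(cells_path).write_text("\n".join(matrix.cells) + "\n")
    Path(features_path).write_text("\n".join(matrix.antibodies) + "\n")


# ---------------------------------------------------------------------------
# Per-cell filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Per-cell QC thresholds.

    Mitochondrial ceilings are tissue-specific (enzymatically digested islet
    tissue is filtered harder than mechanically dissociated spleen).  Cells
    whose total ADT count exceeds the ``aggregate_total_adt_quantile`` of
    the dataset are treated as antibody aggregates.
    """

    mito_max_islet: float = 10.0
    mito_max_spleen: float = 20.0
    min_genes: int = 200
    aggregate_total_adt_quantile: float = 0.999

    def __post_init__(self) -> None:
        if min(self.mito_max_islet, self.mito_max_spleen,
               self.min_genes) <= 0:
            raise ConfigError("QC thresholds must be positive")
        if not (0.0 < self.aggregate_total_adt_quantile <= 1.0):
            raise ConfigError("aggregate quantile must lie in (0, 1]")


_MITO_MAX_BY_TISSUE = {"islet": "mito_max_islet", "spleen": "mito_max_spleen"}


def _aggregate_ceiling(total_adt: np.ndarray, quantile: float) -> float:
    """Total-ADT ceiling above which a cell is called an antibody aggregate.

    The ceiling is the ``quantile`` of a robust log-normal fit to the
    per-cell totals (median and scaled MAD on log1p counts).  A fitted
    rather than empirical quantile is used because aggregates sit in the
    extreme tail: an empirical quantile can never flag more than
    ``1 - quantile`` of cells, however many aggregates are present, whereas
    the fitted ceiling is insensitive to the aggregates themselves.  When
    the totals are (near-)constant the fit is degenerate and the empirical
    quantile is used instead.
    """
    from scipy.stats import norm

    log_total = np.log1p(np.asarray(total_adt, dtype=float))
    med = np.median(log_total)
    mad = np.median(np.abs(log_total - med))
    if mad <= 0:
        return float(np.quantile(total_adt, quantile))
    z = norm.ppf(quantile)
    return float(np.expm1(med + z * 1.4826 * mad))


def filter_cells(
    metrics: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-cell keep/drop decisions with recorded reasons.

    ``metrics`` needs columns ``mito_pct`` (percent of UMIs mapped to
    mitochondrial genes), ``n_genes`` (unique genes detected), ``total_adt``
    and ``tissue`` ("islet" or "spleen").  A cell is dropped when its
    mitochondrial fraction exceeds the tissue ceiling, it has fewer than
    ``min_genes`` genes, or its total ADT count lies above the aggregate
    quantile of all cells.  Returns (keep mask, boolean reason table).
    """
    thresholds = thresholds or QcThresholds()
    required = {"mito_pct", "n_genes", "total_adt", "tissue"}
    missing = required - set(metrics.columns)
    if missing:
        raise SchemaError(f"QC metrics missing columns {sorted(missing)}")
    tissues = metrics["tissue"].astype(str).str.lower()
    unknown = set(tissues) - set(_MITO_MAX_BY_TISSUE)
    if unknown:
        raise ConfigError(f"unknown tissue values {sorted(unknown)}")

    mito_ceiling = np.array([
        getattr(thresholds, _MITO_MAX_BY_TISSUE[t]) for t in tissues
    ])
    total_adt = metrics["total_adt"].to_numpy(dtype=float)
    adt_ceiling = _aggregate_ceiling(
        total_adt, thresholds.aggregate_total_adt_quantile)

    reasons = pd.DataFrame({
        "high_mito": metrics["mito_pct"].to_numpy(dtype=float) > mito_ceiling,
        "low_genes": metrics["n_genes"].to_numpy() < thresholds.min_genes,
        "aggregate": total_adt > adt_ceiling,
    }, index=metrics.index)
    keep = ~reasons.any(axis=1).to_numpy()
    return keep, reasons


# ---------------------------------------------------------------------------
# Per-antibody background cut-offs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffParams:
    """Parameters of the ADT minimum cut-off.

    With ``fallback_quantile`` at its default of 1.0, a column whose log1p
    density shows no valley between a background and a signal mode is
    treated as background-only and fully zeroed (threshold = max + 1).
    """

    min_cells: int = 20
    fallback_quantile: float = 1.0
    min_separation: float = 0.5
    min_mode_height_frac: float = 0.01
    grid_size: int = 512


def adt_min_cutoff(
    matrix: AdtMatrix,
    antibody: str,
    method: str = "valley",
    params: CutoffParams | None = None,
) -> tuple[int, np.ndarray]:
    """Minimum background cut-off for one antibody column.

    The threshold is placed at the valley of the log1p-count density
    between background and signal modes; when the column is not bimodal the
    fallback quantile is used.  Counts below the threshold are zeroed,
    counts at or above it are kept unchanged.  Returns
    (threshold, cleaned column).
    """
    from .gating import GatingConfig, kde_valley_split  # local: avoid cycle

    params = params or CutoffParams()
    col = matrix.column(antibody)
    if not np.any(col):
        warnings.warn(f"antibody {antibody!r}: all-zero column, threshold 0",
                      stacklevel=2)
        return 0, col.copy()
    if col.size < params.min_cells:
        raise ValidationError(
            f"antibody {antibody!r}: need >= {params.min_cells} cells"
        )
    if method not in ("valley", "quantile"):
        raise ConfigError(f"unknown cut-off method {method!r}")

    threshold: int | None = None
    if method == "valley":
        cfg = GatingConfig(grid_size=params.grid_size,
                           min_separation=params.min_separation,
                           min_mode_height_frac=params.min_mode_height_frac)
        valley = kde_valley_split(np.log1p(col.astype(float)), cfg)
        if valley is not None:
            threshold = int(np.ceil(np.expm1(valley)))
    if threshold is None:
        q = float(np.quantile(col, params.fallback_quantile))
        threshold = int(np.floor(q)) + 1

    cleaned = np.where(col >= threshold, col, 0)
    return threshold, cleaned


def apply_adt_cutoffs(
    matrix: AdtMatrix,
    method: str = "valley",
    params: CutoffParams | None = None,
    overrides: Mapping[str, int] | None = None,
) -> tuple[AdtMatrix, dict[str, int]]:
    """Apply :func:`adt_min_cutoff` to every antibody column.

    ``overrides`` supplies manual per-antibody thresholds that replace the
    automatic ones.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(matrix.antibodies)
    if unknown:
        raise SchemaError(f"override for unknown antibodies {sorted(unknown)}")
    thresholds: dict[str, int] = {}
    cleaned_cols = []
    for ab in matrix.antibodies:
        if ab in overrides:
            thr = int(overrides[ab])
            col = matrix.column(ab)
            cleaned = np.where(col >= thr, col, 0)
        else:
            thr, cleaned = adt_min_cutoff(matrix, ab, method=method,
                                          params=params)
        thresholds[ab] = thr
        cleaned_cols.append(cleaned)
    counts = sp.csr_matrix(np.column_stack(cleaned_cols))
    return AdtMatrix(cells=list(matrix.cells),
                     antibodies=list(matrix.antibodies),
                     counts=counts), thresholds


# ---------------------------------------------------------------------------
# RNA vs protein concordance
# ---------------------------------------------------------------------------

class ConcordanceCategory(Enum):
    FULL_OVERLAP = "full_overlap"
    PARTIAL_OVERLAP = "partial_overlap"
    NO_OVERLAP = "no_overlap"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class ConcordanceCall:
    antibody: str
    gene: str | None
    rna_clusters: frozenset
    adt_clusters: frozenset
    category: ConcordanceCategory


def rna_protein_concordance(
    rna_pos: pd.DataFrame,
    adt_pos: pd.DataFrame,
    mapping: Mapping[str, str | None],
    pos_fraction_min: float = 0.25,
) -> tuple[list[ConcordanceCall], dict[str, int]]:
    """Categorize each antibody by overlap of RNA+ and protein+ clusters.

    ``rna_pos`` (clusters x genes) and ``adt_pos`` (clusters x antibodies)
    hold positive-cell fractions per cluster.  A cluster is called positive
    when its fraction exceeds ``pos_fraction_min``.  An antibody is a full
    overlap when the RNA+ and ADT+ cluster sets are equal and non-empty, no
    overlap when the sets are disjoint, and a partial overlap otherwise;
    antibodies whose mapping value is None (no RNA counterpart, e.g. protein
    isoforms) are not assessed.  Returns the per-antibody calls and a tally
    per category.
    """
    unknown = set(mapping) - set(adt_pos.columns)
    if unknown:
        raise SchemaError(
            f"mapping references unknown antibodies {sorted(unknown)}")

    calls: list[ConcordanceCall] = []
    for antibody in adt_pos.columns:
        gene = mapping.get(antibody)
        if gene is None:
            calls.append(ConcordanceCall(
                antibody=antibody, gene=None, rna_clusters=frozenset(),
                adt_clusters=frozenset(),
                category=ConcordanceCategory.NOT_ASSESSED))
            continue
        if gene not in rna_pos.columns:
            raise SchemaError(
                f"antibody {antibody!r} maps to unknown gene {gene!r}")
        adt_set = frozenset(
            adt_pos.index[adt_pos[antibody] > pos_fraction_min])
        rna_set = frozenset(rna_pos.index[rna_pos[gene] > pos_fraction_min])
        if rna_set == adt_set and rna_set:
            category = ConcordanceCategory.FULL_OVERLAP
        elif not (rna_set & adt_set):
            category = ConcordanceCategory.NO_OVERLAP
        else:
            category = ConcordanceCategory.PARTIAL_OVERLAP
        calls.append(ConcordanceCall(
            antibody=antibody, gene=gene, rna_clusters=rna_set,
            adt_clusters=adt_set, category=category))

    tally = {cat.value: 0 for cat in ConcordanceCategory}
    for call in calls:
        tally[call.category.value] += 1
    return calls, tally
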