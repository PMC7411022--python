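"""Single-cell EphA2-pathway enrichment score.

Pipeline, in fixed order over a genes x cells matrix of E = log2(TPM + 1):

1. restrict to a user-supplied EphA2-pathway gene list (the original study
   used 71 genes downstream of EphA2 signaling; the list is supplied as
   input, e.g. from the study's supplementary table / accession GSE117872);
2. drop pathway genes whose mean E across all cells is below 1 (kept when
   the mean equals 1 exactly);
3. score each cell as the unweighted mean E over the surviving genes;
4. discard outlier cells with score < 3 (strict) before normalization;
5. divide each cell's score by the mean score of the *primary*-class cells
   of the same patient, so each patient's primary line averages 1 and
   patients with different baseline expression become comparable.

Patients are inferred from line ids of the form ``<patient><class>`` with
class suffix ``p`` (primary), ``m`` (metastatic) or ``pcr`` (cisplatin
resistant) — e.g. HN120p / HN120m / HN120pcr all map to patient HN120 — and
can be overridden with an explicit mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

_LINE_SUFFIX = re.compile(r"^(?P<patient>.+?)(?P<cls>pcr|p|m)$", re.IGNORECASE)
_CLASS_OF_SUFFIX = {"p": "primary", "m": "metastatic", "pcr": "resistant"}


@dataclass
class ExpressionMatrix:
    """genes x cells matrix of E = log2(TPM+1) with cell -> line annotation."""

    values: pd.DataFrame  # index = gene ids, columns = cell ids
    cell_line: pd.Series  # cell id -> line id
    line_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.cell_line.index):
            self.cell_line = self.cell_line.reindex(self.values.columns)
        if self.cell_line.isna().any():
            raise ValueError("every cell needs a line annotation")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("log expression must be non-negative")
        if not self.line_class:
            self.line_class = {
                line: classify_line(line) for line in self.cell_line.unique()
            }

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class EnrichmentResult:
    """Per-cell pathway scores with full filter provenance."""

    cell_scores: pd.Series  # normalized per-cell scores
    raw_cell_scores: pd.Series
    excluded_genes: list[tuple[str, str]]  # (gene, reason)
    discarded_cells: list[tuple[str, str]]
    per_line_means: dict[str, float]  # raw means over kept cells
    normalization_factor: dict[str, float]  # patient -> primary-line mean
    normalized_line_means: dict[str, float]
    patient_of_line: dict[str, str]


def classify_line(line_id: str) -> str:
    m = _LINE_SUFFIX.match(line_id)
    return _CLASS_OF_SUFFIX[m.group("cls").lower()] if m else "primary"


def patient_of(line_id: str) -> str:
    m = _LINE_SUFFIX.match(line_id)
    return m.group("patient") if m else line_id


def to_log_expression(
    tpm: pd.DataFrame,
    cell_line: pd.Series,
    line_class: dict[str, str] | None = None,
    already_log: bool = False,
) -> ExpressionMatrix:
    """E = log2(TPM + 1) elementwise.

    ``already_log=True`` declares that the input is already on the E scale;
    re-transforming such a matrix is refused.
    """
    if already_log:
        raise ValueError(
            "input is flagged as already log2(TPM+1); refusing to transform again"
        )
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return ExpressionMatrix(
        values=np.log2(tpm + 1.0),
        cell_line=cell_line,
        line_class=line_class or {},
    )


def pathway_filter(
    matrix: ExpressionMatrix,
    pathway_gene_ids: list[str],
    min_avg: float = 1.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Restrict to pathway genes with mean E >= ``min_avg`` across all cells.

    Returns the surviving submatrix and the exclusion list with reasons
    ("absent" — not in the matrix; "low_expression" — mean E < min_avg).
    """
    if not pathway_gene_ids:
        raise ValueError("empty pathway gene list")
    excluded: list[tuple[str, str]] = []
    present: list[str] = []
    for g in pathway_gene_ids:
        if g in matrix.values.index:
            present.append(g)
        else:
            excluded.append((g, "absent"))
    kept: list[str] = []
    for g in present:
        if matrix.values.loc[g].mean() >= min_avg:
            kept.append(g)
        else:
            excluded.append((g, "low_expression"))
    if not kept:
        raise ValueError("no pathway genes survive the expression filter")
    return matrix.values.loc[kept], excluded


def cell_scores(submatrix: pd.DataFrame) -> pd.Series:
    """Per-cell pathway score: unweighted mean E over the surviving genes."""
    if submatrix.shape[0] < 1:
        raise ValueError("need at least one gene")
    return submatrix.mean(axis=0)


def discard_low_epha2(
    scores: pd.Series,
    threshold: float = 3.0,
) -> tuple[pd.Series, list[tuple[str, str]]]:
    """Drop outlier cells with score strictly below ``threshold``.

    Applied to the raw (pre-normalization) pathway score by default; callers
    who prefer the alternative reading of the rule can pass the EphA2 gene's
    own expression row as ``scores`` instead.
    """
    low = scores < threshold
    discarded = [(c, f"score {scores[c]:.4g} < {threshold:g}") for c in scores.index[low]]
    kept = scores[~low]
    if kept.empty:
        raise ValueError("all cells discarded as low-score outliers")
    return kept, discarded


def normalize_by_primary(
    scores: pd.Series,
    cell_line: pd.Series,
    line_class: dict[str, str],
    patient_of_line: dict[str, str] | None = None,
) -> tuple[pd.Series, dict[str, float], dict[str, str]]:
    """Divide each cell's score by its patient's primary-line mean score.

    Returns (normalized scores, patient -> factor, line -> patient).  Each
    patient must contribute at least one primary-class cell.
    """
    lines = cell_line.loc[scores.index]
    patients = patient_of_line or {ln: patient_of(ln) for ln in lines.unique()}
    cell_patient = lines.map(patients)
    factors: dict[str, float] = {}
    for patient, cells in scores.groupby(cell_patient):
        primary = cells[lines.loc[cells.index].map(line_class) == "primary"]
        if primary.empty:
            raise ValueError(f"patient {patient} has no primary-class cells")
        factors[patient] = float(primary.mean())
    normalized = scores / cell_patient.map(factors)
    return normalized, factors, patients


def score_pathway(
    matrix: ExpressionMatrix,
    pathway_gene_ids: list[str],
    min_avg: float = 1.0,
    outlier_threshold: float = 3.0,
    patient_of_line: dict[str, str] | None = None,
) -> EnrichmentResult:
    """Run the full enrichment pipeline in its fixed filter order."""
    sub, excluded_genes = pathway_filter(matrix, pathway_gene_ids, min_avg=min_avg)
    raw = cell_scores(sub)
    kept, discarded = discard_low_epha2(raw, threshold=outlier_threshold)
    normalized, factors, patients = normalize_by_primary(
        kept, matrix.cell_line, matrix.line_class, patient_of_line
    )
    lines = matrix.cell_line.loc[kept.index]
    per_line = {ln: float(v.mean()) for ln, v in kept.groupby(lines)}
    norm_line = {ln: float(v.mean()) for ln, v in normalized.groupby(lines)}
    return EnrichmentResult(
        cell_scores=normalized,
        raw_cell_scores=raw,
        excluded_genes=excluded_genes,
        discarded_cells=discarded,
        per_line_means=per_line,
        normalization_factor=factors,
        normalized_line_means=norm_line,
        patient_of_line=patients,
    )


def correlate_scores(
    enrichment_line_means: dict[str, float],
    clustering_line_means: dict[str, float],
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between line-level enrichment and clustering means."""
    common = sorted(set(enrichment_line_means) & set(clustering_line_means))
    if len(common) < 3:
        raise ValueError("need >= 3 lines in common")
    x = np.array([clustering_line_means[c] for c in common])
    y = np.array([enrichment_line_means[c] for c in common])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def load_gene_list(path) -> list[str]:
    """Read a one-gene-id-per-line text file (blank lines and '#' comments ignored)."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
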