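"""Reading, validating and harmonizing per-dataset expression and clinical data.

A *cohort* is one dataset: a gene-centred (or probe-level) expression
matrix aligned to a clinical table.  A *compendium* is an ordered list of
cohorts sharing an Entrez-gene namespace; every query in this package
runs against a compendium.

File formats are deliberately plain: tab-separated UTF-8 text.  An
expression matrix has a feature-id first column and one column per
sample; a clinical table has one row per sample with a controlled
vocabulary for stage, grade, histology and treatment flags.  Clinical
values that cannot be mapped onto the controlled vocabulary degrade to
missing (with a logged warning) rather than aborting integration —
survival analysis tolerates missing covariates, but not silently wrong
ones.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("survpool")


class ValidationError(ValueError):
    """An input violated a structural invariant (duplicate ids, bad counts...)."""


class ParseError(ValueError):
    """A cell or row could not be parsed; the message carries its location."""


#: Columns recognized in a clinical table, in canonical order.
CLINICAL_COLUMNS = [
    "sample_id",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
    "age",
    "figo_stage",
    "grade",
    "histology",
    "residual_tumour",
    "platinum",
    "taxane",
    "neoadjuvant",
    "chemotherapy",
]

_NUMERIC_COLUMNS = {"os_time", "dfs_time", "age"}
_EVENT_COLUMNS = {"os_event", "dfs_event"}
_YESNO_COLUMNS = {"residual_tumour", "platinum", "taxane", "neoadjuvant", "chemotherapy"}

_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}

_HISTOLOGY_MAP = {
    "serous": "serous",
    "ser": "serous",
    "endometrioid": "endometrioid",
    "end": "endometrioid",
}

_YES = {"yes", "y", "true", "1", "1.0"}
_NO = {"no", "n", "false", "0", "0.0"}

#: Months per day / months per year for survival-time unit conversion.
DAYS_PER_MONTH = 30.44
MONTHS_PER_YEAR = 12.0


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated expression matrix (features x samples).

    First column holds feature ids (probe or Entrez gene ids), the header
    row holds sample ids.  Empty cells and ``NA`` become NaN.  Duplicate
    feature or sample ids raise :class:`ValidationError`; a non-numeric
    cell raises :class:`ParseError` naming its row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    _check_unique(raw.index, "feature id", path)
    _check_unique(raw.columns, "sample id", path)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col].to_numpy()
        for i, cell in enumerate(cells):
            cell = cell.strip()
            if cell == "" or cell.upper() == "NA":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{raw.index[i]!r}, sample {col!r}"
                ) from None
    out = pd.DataFrame(values, index=raw.index.copy(), columns=raw.columns.copy())
    validate_expression_matrix(out)
    return out


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix in the tab-separated layout read back by
    :func:`read_expression_matrix` (missing values as empty cells)."""
    expr = expr.copy()
    expr.index.name = "feature_id"
    expr.to_csv(path, sep="\t", na_rep="")


def validate_expression_matrix(expr: pd.DataFrame) -> None:
    """Check the structural invariants of an expression matrix."""
    _check_unique(expr.index, "feature id")
    _check_unique(expr.columns, "sample id")
    values = expr.to_numpy()
    bad = np.isinf(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite expression value at feature {expr.index[i]!r}, "
            f"sample {expr.columns[j]!r}"
        )


def _check_unique(ids, what: str, path: Path | None = None) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()][0]
        where = f"{path}: " if path is not None else ""
        raise ValidationError(f"{where}duplicate {what} {dup!r}")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def read_clinical_table(path: str | Path, time_unit: str = "months") -> pd.DataFrame:
    """Read and harmonize a tab-separated clinical table.

    Parameters
    ----------
    path:
        Tab-separated file; the header must include ``sample_id`` and may
        include any of :data:`CLINICAL_COLUMNS` (matched case-insensitively).
        Unrecognized columns are ignored with a logged warning.
    time_unit:
        Unit the survival-time columns are recorded in: ``"months"``
        (default, stored as-is), ``"days"`` (divided by 30.44) or
        ``"years"`` (multiplied by 12).  All times are stored in months.

    Returns
    -------
    DataFrame indexed by ``sample_id`` with the canonical columns; values
    that cannot be mapped onto the controlled vocabulary are set to
    missing with a logged warning.  An event indicator without a matching
    time is coerced to missing.  A negative time is fatal.
    """
    path = Path(path)
    if time_unit not in ("months", "days", "years"):
        raise ValueError(f"unknown time unit {time_unit!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for col in raw.columns:
        canon = col.strip().lower()
        if canon in CLINICAL_COLUMNS:
            colmap[col] = canon
        else:
            logger.warning("%s: ignoring unrecognized clinical column %r", path, col)
    raw = raw.rename(columns=colmap)[[c for c in CLINICAL_COLUMNS if c in colmap.values()]]
    if "sample_id" not in raw.columns:
        raise ValidationError(f"{path}: clinical table lacks a sample_id column")
    raw["sample_id"] = raw["sample_id"].str.strip()
    _check_unique(raw["sample_id"], "sample id", path)

    out = pd.DataFrame(index=pd.Index(raw["sample_id"], name="sample_id"))
    for col in CLINICAL_COLUMNS[1:]:
        cells = raw[col].to_numpy() if col in raw.columns else np.full(len(raw), "")
        parsed = [
            _parse_clinical_value(col, cell, path, row_no=i + 2)
            for i, cell in enumerate(cells)
        ]
        out[col] = parsed
    for col in _NUMERIC_COLUMNS | _EVENT_COLUMNS | {"figo_stage", "grade"}:
        out[col] = pd.to_numeric(out[col])

    for t in ("os_time", "dfs_time"):
        if time_unit == "days":
            out[t] = out[t] / DAYS_PER_MONTH
        elif time_unit == "years":
            out[t] = out[t] * MONTHS_PER_YEAR
    # event only meaningful alongside its time
    for t, e in (("os_time", "os_event"), ("dfs_time", "dfs_event")):
        orphan = out[e].notna() & out[t].isna()
        if orphan.any():
            logger.warning(
                "%s: %d %s value(s) without %s set to missing", path, orphan.sum(), e, t
            )
            out.loc[orphan, e] = np.nan
    validate_clinical_table(out)
    return out


def _parse_clinical_value(col: str, cell: str, path: Path, row_no: int):
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN", "UNKNOWN", "?"):
        return np.nan
    low = cell.lower()
    if col in _NUMERIC_COLUMNS:
        try:
            value = float(cell)
        except ValueError:
            logger.warning("%s row %d: unparseable %s %r -> missing", path, row_no, col, cell)
            return np.nan
        if col.endswith("_time") and value < 0:
            raise ParseError(f"{path} row {row_no}: negative {col} {value}")
        return value
    if col in _EVENT_COLUMNS:
        if low in _YES:
            return 1.0
        if low in _NO:
            return 0.0
        logger.warning("%s row %d: unparseable %s %r -> missing", path, row_no, col, cell)
        return np.nan
    if col == "figo_stage":
        return _parse_stage(low, path, row_no)
    if col == "grade":
        m = re.fullmatch(r"g?([123])(?:\.0)?", low)
        if m:
            return float(m.group(1))
        logger.warning("%s row %d: unparseable grade %r -> missing", path, row_no, cell)
        return np.nan
    if col == "histology":
        return _HISTOLOGY_MAP.get(low, "other")
    if col in _YESNO_COLUMNS:
        if low in _YES:
            return "yes"
        if low in _NO:
            return "no"
        logger.warning("%s row %d: unparseable %s %r -> missing", path, row_no, col, cell)
        return np.nan
    raise AssertionError(col)


def _parse_stage(low: str, path: Path, row_no: int):
    # Roman (I-IV, substage suffixes like IIIc truncated) or Arabic (1-4).
    m = re.fullmatch(r"(i{1,3}|iv)([abc]?)", low)
    if m:
        return float(_ROMAN[m.group(1)])
    m = re.fullmatch(r"([1-4])(?:\.0)?[abc]?", low)
    if m:
        return float(m.group(1))
    logger.warning("%s row %d: unparseable figo_stage %r -> missing", path, row_no, low)
    return np.nan


def write_clinical_table(clin: pd.DataFrame, path: str | Path) -> None:
    """Write a clinical table readable by :func:`read_clinical_table`
    (times already in months)."""
    out = clin.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="")


def validate_clinical_table(clin: pd.DataFrame) -> None:
    """Check clinical-table invariants: unique samples, non-negative times,
    events only where times are present."""
    _check_unique(clin.index, "sample id")
    for t in ("os_time", "dfs_time"):
        if (clin[t].dropna() < 0).any():
            raise ValidationError(f"negative {t} in clinical table")
    for t, e in (("os_time", "os_event"), ("dfs_time", "dfs_event")):
        if (clin[e].notna() & clin[t].isna()).any():
            raise ValidationError(f"{e} present without {t}")


# ---------------------------------------------------------------------------
# Cohorts and compendia
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """One dataset: expression matrix aligned with its clinical table.

    ``expression`` rows are feature ids — Entrez gene ids once the matrix
    has been gene-centred — and its columns equal ``clinical.index`` in
    the same order.
    """

    dataset_id: str
    platform: str
    expression: pd.DataFrame
    clinical: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Cohort({self.dataset_id!r}, platform={self.platform!r}, "
            f"{self.expression.shape[0]} features x {self.n_samples} samples)"
        )


@dataclass
class Compendium:
    """Ordered collection of cohorts sharing an Entrez-gene namespace."""

    cohorts: list[Cohort] = field(default_factory=list)

    @property
    def gene_universe(self) -> pd.Index:
        universe: pd.Index = pd.Index([], dtype=object)
        for c in self.cohorts:
            universe = universe.union(c.genes)
        return universe

    @property
    def dataset_ids(self) -> list[str]:
        return [c.dataset_id for c in self.cohorts]

    @property
    def n_samples(self) -> int:
        return sum(c.n_samples for c in self.cohorts)

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Compendium({len(self.cohorts)} cohorts, {self.n_samples} samples, "
            f"{len(self.gene_universe)} genes)"
        )


#: Minimum patients for a dataset to enter a compendium (overridable).
MIN_PATIENTS = 50


def assemble_cohort(
    dataset_id: str,
    platform: str,
    expr: pd.DataFrame,
    clin: pd.DataFrame,
    min_patients: int = MIN_PATIENTS,
) -> Cohort:
    """Align an expression matrix with a clinical table into a cohort.

    Samples are restricted to the intersection of the two inputs, ordered
    as in the expression matrix.  Cohorts smaller than ``min_patients``
    are rejected — small series carry too little survival information to
    contribute stable per-dataset cutoffs — unless the threshold is
    lowered explicitly.
    """
    shared = [s for s in expr.columns if s in clin.index]
    if not shared:
        raise ValidationError(
            f"cohort {dataset_id!r}: expression and clinical tables share no samples"
        )
    if len(shared) < min_patients:
        raise ValidationError(
            f"cohort {dataset_id!r}: only {len(shared)} samples with both expression "
            f"and clinical data (minimum {min_patients}); pass min_patients to override"
        )
    expr = expr.loc[:, shared]
    clin = clin.loc[shared]
    has_endpoint = (clin["os_time"].notna() | clin["dfs_time"].notna()).any()
    if not has_endpoint:
        raise ValidationError(f"cohort {dataset_id!r}: no sample has OS or DFS information")
    return Cohort(dataset_id=dataset_id, platform=platform, expression=expr, clinical=clin)


def assemble_compendium(cohorts: list[Cohort]) -> Compendium:
    """Assemble cohorts (kept in the given order) into a compendium."""
    if not cohorts:
        raise ValidationError("a compendium needs at least one cohort")
    _check_unique([c.dataset_id for c in cohorts], "dataset id")
    return Compendium(cohorts=list(cohorts))


# ---------------------------------------------------------------------------
# Manifest-driven assembly
# ---------------------------------------------------------------------------

def load_compendium(
    manifest_path: str | Path,
    min_patients: int | None = None,
) -> Compendium:
    """Build a compendium from a YAML manifest.

    The manifest lists, per dataset: ``id``, ``platform``, paths to the
    expression matrix and clinical table, optionally a ``probe_map`` (in
    which case the matrix is gene-centred on load), a ``time_unit``
    (days|months|years) and a ``quantile_normalize`` flag.  Paths are
    resolved relative to the manifest file.  A top-level ``min_patients``
    key (default 50) applies to every dataset unless overridden by the
    function argument.
    """
    from survpool.centering import (
        collapse_to_genes,
        filter_multimapping,
        quantile_normalize,
        read_probe_gene_map,
    )

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "datasets" not in manifest:
        raise ValidationError(f"{manifest_path}: manifest must contain a 'datasets' list")
    if min_patients is None:
        min_patients = int(manifest.get("min_patients", MIN_PATIENTS))
    base = manifest_path.parent
    cohorts = []
    for entry in manifest["datasets"]:
        expr = read_expression_matrix(base / entry["expression"])
        clin = read_clinical_table(
            base / entry["clinical"], time_unit=entry.get("time_unit", "months")
        )
        if entry.get("quantile_normalize", False):
            expr = quantile_normalize(expr)
        if "probe_map" in entry:
            pmap = filter_multimapping(read_probe_gene_map(base / entry["probe_map"]))
            expr = collapse_to_genes(expr, pmap)
        cohorts.append(
            assemble_cohort(
                str(entry["id"]),
                str(entry.get("platform", "unknown")),
                expr,
                clin,
                min_patients=min_patients,
            )
        )
    return assemble_compendium(cohorts)


def subset_cohort(cohort: Cohort, sample_ids) -> Cohort:
    """Return a cohort restricted to ``sample_ids`` (order preserved)."""
    keep = [s for s in cohort.sample_ids if s in set(sample_ids)]
    return replace(
        cohort,
        expression=cohort.expression.loc[:, keep],
        clinical=cohort.clinical.loc[keep],
    )
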