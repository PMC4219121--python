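"""Per-dataset dichotomization into high/low expression groups.

Expression scales differ wildly across platforms, so a sample is called
"high" or "low" for a gene relative to *its own dataset's* cutoff — the
median (default) or a quartile of the gene's expression within that
dataset.  Because only within-dataset ranks matter, the split is
invariant under any strictly monotone per-dataset transform of the
intensities, which is what makes pooling across platforms meaningful.

Multi-gene queries combine per-gene assignments as "high in every gene
versus the rest".  Clinical filters subset the cohort *before* cutoffs
are computed: the query is defined on the selected population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from survpool.cohorts import Cohort, ValidationError, subset_cohort

logger = logging.getLogger("survpool")

CutoffMethod = Literal["median", "upper_quartile", "lower_quartile"]
_CUTOFF_Q = {"median": 50.0, "upper_quartile": 75.0, "lower_quartile": 25.0}

HIGH, LOW, EXCLUDED = "high", "low", "excluded"


class InsufficientDataError(ValidationError):
    """Too few usable values to compute a cutoff for this dataset/gene."""


def compute_cutoff(values: Sequence[float] | np.ndarray, method: CutoffMethod) -> float:
    """Cutoff of a gene's expression vector: median, 75th or 25th percentile
    of the non-missing values (linear-interpolation percentile definition).

    Raises :class:`InsufficientDataError` below 2 non-missing values; the
    caller is expected to skip the dataset for this gene.
    """
    if method not in _CUTOFF_Q:
        raise ValueError(f"unknown cutoff method {method!r}")
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise InsufficientDataError(
            f"need >=2 non-missing values for a {method} cutoff, have {values.size}"
        )
    return float(np.percentile(values, _CUTOFF_Q[method]))


@dataclass
class GroupAssignment:
    """High/low/excluded labels for one gene (or combined gene set).

    ``labels`` maps sample id -> {high, low, excluded};
    ``per_dataset_cutoffs`` records the cutoff actually used in each
    contributing dataset.
    """

    labels: pd.Series
    gene: str
    method: str
    per_dataset_cutoffs: dict[str, float] = field(default_factory=dict)

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == HIGH]

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == LOW]

    @property
    def excluded(self) -> pd.Index:
        return self.labels.index[self.labels == EXCLUDED]


def assign_groups(
    cohort: Cohort,
    gene: str,
    method: CutoffMethod = "median",
    extremes_only: bool = False,
) -> GroupAssignment:
    """Dichotomize one cohort's samples on one gene.

    Median: high iff value > median, low otherwise (ties at the cutoff go
    to low, so the high group sits strictly above the cutoff).
    Upper quartile: high iff value > Q3, rest low.
    Lower quartile: low iff value < Q1, rest high.
    With ``extremes_only`` the quartile modes keep only the extreme
    quarter on each side (high > Q3, low < Q1, middle excluded).
    Samples with missing expression are excluded.
    """
    if gene not in cohort.expression.index:
        raise KeyError(f"gene {gene!r} not in cohort {cohort.dataset_id!r}")
    values = cohort.expression.loc[gene]
    cutoff = compute_cutoff(values.to_numpy(), method)
    labels = pd.Series(EXCLUDED, index=values.index, dtype=object)
    present = values.notna()
    if extremes_only and method in ("upper_quartile", "lower_quartile"):
        q1 = float(np.percentile(values.dropna(), 25.0))
        q3 = float(np.percentile(values.dropna(), 75.0))
        labels[present & (values > q3)] = HIGH
        labels[present & (values < q1)] = LOW
        cutoff_record = {f"{cohort.dataset_id}": cutoff}
    elif method == "lower_quartile":
        labels[present & (values < cutoff)] = LOW
        labels[present & (values >= cutoff)] = HIGH
        cutoff_record = {cohort.dataset_id: cutoff}
    else:  # median, upper_quartile: tie-to-low
        labels[present & (values > cutoff)] = HIGH
        labels[present & (values <= cutoff)] = LOW
        cutoff_record = {cohort.dataset_id: cutoff}
    return GroupAssignment(
        labels=labels, gene=gene, method=method, per_dataset_cutoffs=cutoff_record
    )


def combine_all_high(assignments: Sequence[GroupAssignment]) -> GroupAssignment:
    """Combine per-gene assignments into "high in all genes" versus the rest.

    A sample is high iff it is high in every input assignment, excluded
    iff excluded in any, low otherwise.  Assignments must cover the same
    sample universe.
    """
    if len(assignments) < 2:
        raise ValidationError("combine_all_high needs at least two assignments")
    universe = assignments[0].labels.index
    for a in assignments[1:]:
        if set(a.labels.index) != set(universe):
            raise ValidationError("assignments cover different sample universes")
    mat = pd.concat([a.labels.reindex(universe) for a in assignments], axis=1)
    all_high = (mat == HIGH).all(axis=1)
    any_excl = (mat == EXCLUDED).any(axis=1)
    labels = pd.Series(LOW, index=universe, dtype=object)
    labels[all_high] = HIGH
    labels[any_excl] = EXCLUDED
    cutoffs: dict[str, float] = {}
    for a in assignments:
        for ds, c in a.per_dataset_cutoffs.items():
            cutoffs[f"{ds}:{a.gene}"] = c
    return GroupAssignment(
        labels=labels,
        gene="+".join(a.gene for a in assignments),
        method=assignments[0].method,
        per_dataset_cutoffs=cutoffs,
    )


@dataclass
class ClinicalFilter:
    """Optional constraints restricting a query to a clinical subpopulation.

    A sample must satisfy every stated constraint; samples missing a
    value for a constrained field are dropped.  The empty filter is a
    no-op.  Age bounds are inclusive.
    """

    age_min: float | None = None
    age_max: float | None = None
    figo_stage: set[int] | None = None
    grade: set[int] | None = None
    histology: set[str] | None = None
    residual_tumour: str | None = None
    platinum: str | None = None
    taxane: str | None = None
    neoadjuvant: str | None = None
    chemotherapy: str | None = None

    def is_empty(self) -> bool:
        return all(getattr(self, f) is None for f in self.__dataclass_fields__)

    def mask(self, clinical: pd.DataFrame) -> pd.Series:
        """Boolean mask over ``clinical``'s rows for samples passing the filter."""
        keep = pd.Series(True, index=clinical.index)
        if self.age_min is not None:
            keep &= clinical["age"].notna() & (clinical["age"] >= self.age_min)
        if self.age_max is not None:
            keep &= clinical["age"].notna() & (clinical["age"] <= self.age_max)
        for col in ("figo_stage", "grade", "histology"):
            allowed = getattr(self, col)
            if allowed is not None:
                keep &= clinical[col].isin(set(allowed))
        for col in ("residual_tumour", "platinum", "taxane", "neoadjuvant", "chemotherapy"):
            wanted = getattr(self, col)
            if wanted is not None:
                keep &= clinical[col] == wanted
        return keep

    @classmethod
    def from_dict(cls, d: dict | None) -> "ClinicalFilter":
        if not d:
            return cls()
        kwargs = dict(d)
        for col in ("figo_stage", "grade", "histology"):
            if col in kwargs and kwargs[col] is not None:
                kwargs[col] = set(kwargs[col])
        return cls(**kwargs)


def filter_samples(cohort: Cohort, clinical_filter: ClinicalFilter) -> Cohort:
    """Restrict a cohort to samples passing the clinical filter."""
    if clinical_filter.is_empty():
        return cohort
    keep = clinical_filter.mask(cohort.clinical)
    if not keep.any():
        logger.info("cohort %s: clinical filter removed every sample", cohort.dataset_id)
    return subset_cohort(cohort, cohort.clinical.index[keep])


@dataclass
class QuerySpec:
    """A fully specified pooled survival query.

    ``genes`` holds one or more Entrez ids; with several genes the
    analysis compares samples high in *all* of them against the rest.
    """

    genes: tuple[str, ...]
    cutoff: CutoffMethod = "median"
    extremes_only: bool = False
    endpoint: Literal["OS", "DFS"] = "OS"
    filters: ClinicalFilter = field(default_factory=ClinicalFilter)
    stratified: bool = False  # dataset-stratified Cox baseline hazards

    def __post_init__(self):
        if isinstance(self.genes, str):
            self.genes = (self.genes,)
        self.genes = tuple(str(g) for g in self.genes)
        if not self.genes:
            raise ValidationError("QuerySpec needs at least one gene")
        if self.endpoint not in ("OS", "DFS"):
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.cutoff not in _CUTOFF_Q:
            raise ValidationError(f"unknown cutoff method {self.cutoff!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "QuerySpec":
        return cls(
            genes=tuple(str(g) for g in d["genes"]),
            cutoff=d.get("cutoff", "median"),
            extremes_only=bool(d.get("extremes_only", False)),
            endpoint=d.get("endpoint", "OS"),
            filters=ClinicalFilter.from_dict(d.get("filters")),
            stratified=bool(d.get("stratified", False)),
        )

    def to_dict(self) -> dict:
        filters = {
            k: (sorted(v) if isinstance(v, set) else v)
            for k, v in vars(self.filters).items()
            if v is not None
        }
        return {
            "genes": list(self.genes),
            "cutoff": self.cutoff,
            "extremes_only": self.extremes_only,
            "endpoint": self.endpoint,
            "filters": filters,
            "stratified": self.stratified,
        }
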