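"""Probe-to-gene centring of expression matrices.

Microarray platforms measure probes, not genes, and every platform has
its own probe vocabulary.  To compare expression across platforms the
matrices are *gene-centred*: probes are mapped to Entrez gene ids,
probes hitting several genes are discarded, and multiple probes for the
same gene are averaged (arithmetically, on the log scale the matrices
are already on).  Optional quantile normalization forces every sample
(column) of a matrix onto the same intensity distribution; it is applied
within one dataset only — cross-dataset effects are absorbed later by
per-dataset dichotomization.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from survpool.cohorts import ParseError, ValidationError, validate_expression_matrix

logger = logging.getLogger("survpool")

#: probe id -> list of Entrez gene ids (possibly empty)
ProbeGeneMap = dict


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a probe annotation map: one ``probe_id<TAB>entrez_id`` pair per
    line (a probe mapping to k genes appears on k lines; a lone probe id
    records a probe with no gene)."""
    path = Path(path)
    entries: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2):
                raise ParseError(f"{path} line {line_no}: expected 1-2 tab-separated fields")
            probe = parts[0].strip()
            if not probe:
                raise ParseError(f"{path} line {line_no}: empty probe id")
            genes = entries.setdefault(probe, [])
            if len(parts) == 2 and parts[1].strip():
                gene = parts[1].strip()
                if gene not in genes:
                    genes.append(gene)
    return entries


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for probe, genes in pmap.items():
            if genes:
                for g in genes:
                    fh.write(f"{probe}\t{g}\n")
            else:
                fh.write(f"{probe}\n")


def filter_multimapping(pmap: ProbeGeneMap) -> ProbeGeneMap:
    """Keep only probes that map to exactly one gene.

    Probes hitting several genes are ambiguous — their signal cannot be
    attributed to one gene — and probes with no mapping carry no gene
    identity; both are dropped.
    """
    kept = {p: list(gs) for p, gs in pmap.items() if len(gs) == 1}
    n_multi = sum(1 for gs in pmap.values() if len(gs) > 1)
    n_unmapped = sum(1 for gs in pmap.values() if len(gs) == 0)
    if n_multi or n_unmapped:
        logger.info(
            "probe map: dropped %d multi-mapping and %d unmapped probes (%d kept)",
            n_multi,
            n_unmapped,
            len(kept),
        )
    return kept


def collapse_to_genes(expr: pd.DataFrame, pmap: ProbeGeneMap) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per Entrez gene.

    ``pmap`` must already be multi-mapping-filtered (every entry a single
    gene).  Each gene's row is the per-sample arithmetic mean over its
    probes' rows, ignoring missing values (a sample missing on every
    probe of a gene stays missing).  Probes absent from the map are
    dropped.
    """
    multi = [p for p, gs in pmap.items() if len(gs) != 1]
    if multi:
        raise ValidationError(
            f"probe map not multi-mapping-filtered: probe {multi[0]!r} maps to "
            f"{len(pmap[multi[0]])} genes; apply filter_multimapping first"
        )
    probes = [p for p in expr.index if p in pmap]
    if not probes:
        raise ValidationError("no expression row appears in the probe map")
    genes = pd.Index([pmap[p][0] for p in probes])
    sub = expr.loc[probes]
    # per-sample mean over each gene's probes, NaN-aware
    collapsed = sub.groupby(genes, sort=True).mean()
    collapsed.index = collapsed.index.astype(str)
    collapsed.index.name = expr.index.name
    return collapsed


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of an expression matrix.

    Every column is forced onto the reference distribution given by the
    row-wise mean of the sorted columns, so after normalization all
    columns share the same value multiset while within-column rank order
    is preserved.  Ties within a column receive the mean of the reference
    values at their rank positions.  Missing entries are excluded from
    ranking and restored as missing; the reference quantiles are then
    evaluated by linear interpolation at each column's own rank grid.

    A single-column matrix is returned unchanged (with a warning): there
    is nothing to normalize against.
    """
    if expr.shape[1] < 2:
        logger.warning("quantile_normalize: single-column matrix returned unchanged")
        return expr.copy()
    values = expr.to_numpy(dtype=float)
    n_rows, n_cols = values.shape
    counts = np.sum(~np.isnan(values), axis=0)
    if (counts < 1).any():
        raise ValidationError("quantile_normalize: a column is entirely missing")

    # Reference distribution on a common grid of n_rows quantiles: each
    # column's empirical quantile function evaluated on that grid, averaged.
    grid = np.linspace(0.0, 1.0, n_rows)
    ref = np.zeros(n_rows)
    for j in range(n_cols):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        if col.size == n_rows:
            ref += col
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    ref /= n_cols

    out = np.full_like(values, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(values[:, j])
        col = values[mask, j]
        m = col.size
        if m == 1:
            out[mask, j] = ref.mean()
            continue
        ref_m = ref if m == n_rows else np.interp(np.linspace(0.0, 1.0, m), grid, ref)
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(m)
        assigned[order] = ref_m
        # tied values share the mean of the reference values at their ranks
        _, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        cnts = np.bincount(inverse)
        out[mask, j] = (sums / cnts)[inverse]
    result = pd.DataFrame(out, index=expr.index.copy(), columns=expr.columns.copy())
    validate_expression_matrix(result)
    return result
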