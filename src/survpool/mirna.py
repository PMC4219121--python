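"""Querying miRNAs through their host genes' expression.

Roughly half of known human miRNAs sit inside introns of protein-coding
genes, and many intronic miRNAs are co-transcribed with their host.
Expression arrays that lack direct miRNA probes can therefore act as a
*surrogate* readout: a miRNA is queried by running the pooled survival
analysis on its host gene.  Because host/miRNA co-expression is far from
universal, surrogacy should be vetted where matched direct miRNA
measurements exist: host-gene rows are correlated against the matched
miRNA rows, correlations are BH-adjusted, and a miRNA is called
"correlated" only with adjusted p < alpha and a positive coefficient.
Queries for unvetted miRNAs still run but carry a caution flag.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from survpool.cohorts import Compendium, ParseError, ValidationError
from survpool.screen import bh_adjust
from survpool.stratify import QuerySpec
from survpool.survival import SurvivalResult, pooled_query

logger = logging.getLogger("survpool")

STATUSES = ("correlated", "not_correlated", "unknown")


@dataclass
class MirnaHostMap:
    """miRNA name -> host Entrez gene id, with optional vetting status."""

    entries: dict[str, str] = field(default_factory=dict)
    vetted: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def status(self, mirna: str) -> str:
        return self.vetted.get(mirna, "unknown")


def load_mirna_host_map(path: str | Path) -> MirnaHostMap:
    """Load a miRNA->host map: ``mirna<TAB>entrez_id[<TAB>status]`` per line.

    Status, when present, must be one of correlated / not_correlated /
    unknown; absent status defaults to unknown.  Duplicate miRNA names
    and malformed Entrez ids are errors (with line numbers).
    """
    path = Path(path)
    entries: dict[str, str] = {}
    vetted: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) not in (2, 3):
                raise ParseError(f"{path} line {line_no}: expected 2-3 tab-separated fields")
            mirna, gene = parts[0], parts[1]
            if mirna in entries:
                raise ValidationError(f"{path} line {line_no}: duplicate miRNA {mirna!r}")
            if not gene or not gene.replace("_", "").isalnum():
                raise ParseError(f"{path} line {line_no}: malformed Entrez id {gene!r}")
            entries[mirna] = gene
            if len(parts) == 3 and parts[2]:
                if parts[2] not in STATUSES:
                    raise ParseError(
                        f"{path} line {line_no}: unknown vetting status {parts[2]!r}"
                    )
                vetted[mirna] = parts[2]
    return MirnaHostMap(entries=entries, vetted=vetted)


@dataclass
class MirnaResult:
    """A pooled survival result obtained through a host-gene surrogate."""

    mirna: str
    host_gene: str
    vetting_status: str
    caution: bool
    result: SurvivalResult

    def to_dict(self) -> dict:
        d = self.result.to_dict()
        d.update(
            mirna=self.mirna,
            host_gene=self.host_gene,
            vetting_status=self.vetting_status,
            caution=self.caution,
        )
        return d


def mirna_query(comp: Compendium, mirna: str, hmap: MirnaHostMap, spec: QuerySpec | None = None, **spec_kwargs) -> MirnaResult:
    """Query a miRNA by delegating to the pooled analysis of its host gene.

    The numbers are exactly those of querying the host gene directly; the
    result additionally carries the miRNA name, host gene, vetting status
    and a caution flag whenever the status is not "correlated".  A miRNA
    absent from the map raises with nearest-name suggestions.
    """
    if mirna not in hmap.entries:
        near = difflib.get_close_matches(mirna, hmap.entries.keys(), n=3, cutoff=0.4)
        hint = f"; did you mean {', '.join(near)}?" if near else ""
        raise KeyError(f"miRNA {mirna!r} not in host-gene map{hint}")
    host = hmap.entries[mirna]
    if spec is None:
        spec = QuerySpec(genes=(host,), **spec_kwargs)
    else:
        spec = QuerySpec(
            genes=(host,),
            cutoff=spec.cutoff,
            extremes_only=spec.extremes_only,
            endpoint=spec.endpoint,
            filters=spec.filters,
            stratified=spec.stratified,
        )
    result = pooled_query(comp, spec)
    status = hmap.status(mirna)
    if status != "correlated":
        logger.warning(
            "miRNA %s: host-gene surrogacy is %s; interpret with caution", mirna, status
        )
    return MirnaResult(
        mirna=mirna,
        host_gene=host,
        vetting_status=status,
        caution=status != "correlated",
        result=result,
    )


def vet_surrogates(
    host_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    hmap: MirnaHostMap,
    alpha: float = 0.05,
    method: str = "spearman",
    min_shared: int = 10,
) -> pd.DataFrame:
    """Vet host-gene surrogacy against matched direct miRNA measurements.

    For every mapped miRNA with a row in ``mirna_expr`` whose host gene
    has a row in ``host_expr``, the two rows are correlated over the
    shared samples (Spearman by default — robust to platform scale —
    or ``method="pearson"``).  P-values are BH-adjusted across all vetted
    pairs; status is "correlated" iff adjusted p < alpha and the
    coefficient is positive.

    Returns a DataFrame (mirna, host_gene, correlation, p_raw,
    p_adjusted, status) with the overall correlated fraction in
    ``df.attrs["fraction_correlated"]``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    shared = [s for s in host_expr.columns if s in set(mirna_expr.columns)]
    if len(shared) < min_shared:
        raise ValidationError(
            f"only {len(shared)} shared samples between host and miRNA matrices "
            f"(minimum {min_shared})"
        )
    rows = []
    for mirna, host in hmap.entries.items():
        if mirna not in mirna_expr.index or host not in host_expr.index:
            continue
        x = host_expr.loc[host, shared].to_numpy(dtype=float)
        y = mirna_expr.loc[mirna, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_shared:
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(x[ok], y[ok])
        else:
            rho, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"mirna": mirna, "host_gene": host, "correlation": float(rho), "p_raw": float(p)})
    if not rows:
        raise ValidationError("no miRNA/host pair present in both matrices")
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
    df["status"] = np.where(
        (df["p_adjusted"] < alpha) & (df["correlation"] > 0),
        "correlated",
        "not_correlated",
    )
    df.attrs["fraction_correlated"] = float((df["status"] == "correlated").mean())
    return df


def apply_vetting(hmap: MirnaHostMap, vetting: pd.DataFrame) -> MirnaHostMap:
    """Return a copy of the map with statuses taken from a vetting table."""
    vetted = dict(hmap.vetted)
    for _, row in vetting.iterrows():
        vetted[row["mirna"]] = row["status"]
    return MirnaHostMap(entries=dict(hmap.entries), vetted=vetted)


def write_vetting_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
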