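"""Seeded multi-platform synthetic compendia with known ground truth.

The generator emulates the structure of a multi-study expression
compendium: several datasets with disjoint probe vocabularies but
overlapping gene content, dataset-specific location and scale, probe
redundancy (one to three probes per gene, plus a fraction of
multi-mapping probes for the filters to catch), sporadically missing
values, exponential survival with planted per-gene effects, independent
exponential censoring tuned to a target rate, and partially missing
clinical covariates.  One dataset carries OS only and one DFS only, to
exercise endpoint-missingness paths.

Effects are planted on the dichotomized scale: for each planted gene,
samples above that dataset's median of the *gene-centred* expression
have their hazard multiplied by exp(log HR).  The generator's truth is
thus in exactly the units the analysis pipeline estimates, making
parameter recovery a direct end-to-end check.  It makes no attempt to
mimic microarray noise physics (no probe-sequence or GC effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from survpool.centering import (
    collapse_to_genes,
    filter_multimapping,
    write_probe_gene_map,
)
from survpool.cohorts import (
    Cohort,
    Compendium,
    ValidationError,
    assemble_cohort,
    assemble_compendium,
    write_clinical_table,
    write_expression_matrix,
)

_PLATFORMS = [
    "synth-chipA",
    "synth-chipB",
    "synth-twocolorC",
    "synth-chipD",
    "synth-chipE",
    "synth-twocolorF",
    "synth-chipG",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic compendium.

    Defaults describe a mid-sized multi-study compendium: five datasets
    of 200 patients, 100 genes, 30% censoring on an exponential baseline
    with mean 40 months (the order of magnitude of ovarian-cancer cohort
    means), probe redundancy of 1-3 probes per gene with 5% of probes
    multi-mapping, and a 60% latently co-expressed miRNA/host fraction.
    """

    seed: int
    n_datasets: int = 5
    samples_per_dataset: int | tuple[int, ...] = 200
    n_genes: int = 100
    planted_effects: dict[str, float] = field(default_factory=dict)
    probes_per_gene: tuple[int, int] = (1, 3)
    multimapping_fraction: float = 0.05
    probe_noise_sd: float = 0.3
    location_shift_range: tuple[float, float] = (5.0, 9.0)
    scale_range: tuple[float, float] = (0.8, 1.5)
    missing_rate: float = 0.01
    censoring_rate: float = 0.3
    baseline_mean_months: float = 40.0
    dfs_baseline_mean_months: float = 30.0
    endpoint_pattern: str = "mixed"  # "mixed": ds0 OS-only, ds1 DFS-only; or "both"
    covariate_missing_rate: float = 0.2
    stage_probs: tuple[float, ...] = (0.05, 0.10, 0.65, 0.20)
    grade_probs: tuple[float, ...] = (0.15, 0.35, 0.50)
    histology_probs: tuple[float, ...] = (0.75, 0.10, 0.15)  # serous/endometrioid/other
    treated_prob: float = 0.7
    n_mirnas: int = 100
    mirna_shared_fraction: float = 0.6
    mirna_noise_sd: float = 0.8

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("SimConfig.seed is mandatory")
        for p in (
            self.multimapping_fraction,
            self.missing_rate,
            self.censoring_rate,
            self.covariate_missing_rate,
            self.mirna_shared_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.censoring_rate > 0.95:
            raise ValidationError("censoring target > 0.95 is infeasible")
        if len(self.planted_effects) > self.n_genes:
            raise ValidationError("more planted effects than genes")
        self.planted_effects = {str(g): float(b) for g, b in self.planted_effects.items()}

    @property
    def gene_ids(self) -> list[str]:
        return [str(10001 + i) for i in range(self.n_genes)]

    def sizes(self) -> list[int]:
        if isinstance(self.samples_per_dataset, int):
            return [self.samples_per_dataset] * self.n_datasets
        sizes = list(self.samples_per_dataset)
        if len(sizes) != self.n_datasets:
            raise ValidationError("samples_per_dataset length != n_datasets")
        return sizes


def truth_table(cfg: SimConfig) -> pd.DataFrame:
    """Planted ground truth: one row per planted gene (log HR) and per
    simulated miRNA (latent-shared flag).  A deterministic function of
    the configuration, independent of any random draw."""
    rows = [
        {"entity": g, "kind": "gene", "log_hr": b, "shared_factor": np.nan}
        for g, b in sorted(cfg.planted_effects.items())
    ]
    n_shared = int(round(cfg.mirna_shared_fraction * cfg.n_mirnas))
    for i in range(cfg.n_mirnas):
        rows.append(
            {
                "entity": f"sim-miR-{i + 1}",
                "kind": "mirna",
                "log_hr": np.nan,
                "shared_factor": float(i < n_shared),
            }
        )
    return pd.DataFrame(rows, columns=["entity", "kind", "log_hr", "shared_factor"])


def _solve_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+h_i) == target."""
    if target <= 0.0:
        return 0.0

    def frac(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    return float(np.exp(brentq(frac, -25.0, 25.0, xtol=1e-12)))


def _draw_survival(rng, hazards: np.ndarray, target_censoring: float):
    t_event = rng.exponential(1.0 / hazards)
    if target_censoring <= 0.0:
        return t_event, np.ones(hazards.size, dtype=int)
    c_rate = _solve_censor_rate(hazards, target_censoring)
    t_cens = rng.exponential(1.0 / c_rate, size=hazards.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _draw_clinical(rng, cfg: SimConfig, sample_ids) -> pd.DataFrame:
    n = len(sample_ids)

    def hide(values):
        values = values.astype(object)
        mask = rng.random(n) < cfg.covariate_missing_rate
        values[mask] = np.nan
        return values

    clin = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clin["age"] = hide(np.round(rng.normal(60.0, 11.0, n), 1))
    clin["figo_stage"] = hide(rng.choice([1, 2, 3, 4], n, p=cfg.stage_probs).astype(float))
    clin["grade"] = hide(rng.choice([1, 2, 3], n, p=cfg.grade_probs).astype(float))
    clin["histology"] = hide(
        rng.choice(["serous", "endometrioid", "other"], n, p=cfg.histology_probs)
    )
    for col in ("residual_tumour", "platinum", "taxane", "neoadjuvant", "chemotherapy"):
        clin[col] = hide(rng.choice(["yes", "no"], n, p=[cfg.treated_prob, 1 - cfg.treated_prob]))
    return clin


def simulate_compendium(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[Compendium, pd.DataFrame]:
    """Generate a compendium (optionally written to disk) plus its truth.

    Returns the in-memory gene-centred :class:`Compendium` — identical to
    what loading the written files through the I/O and gene-centring
    pipeline yields — and the :func:`truth_table`.  With ``out_dir``,
    writes per-dataset probe-level expression, probe map and clinical
    files, a ``manifest.yaml`` and ``truth_table.tsv``; output is
    byte-identical for a fixed configuration.
    """
    master = np.random.SeedSequence(cfg.seed)
    ds_seeds = master.spawn(cfg.n_datasets)
    genes = cfg.gene_ids
    sizes = cfg.sizes()
    betas = np.array([cfg.planted_effects.get(g, 0.0) for g in genes])
    planted_idx = np.nonzero(betas)[0]

    cohorts = []
    manifest_entries = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for d in range(cfg.n_datasets):
        rng = np.random.default_rng(ds_seeds[d])
        ds_id = f"d{d + 1}"
        platform = _PLATFORMS[d % len(_PLATFORMS)]
        n_s = sizes[d]
        sample_ids = [f"{ds_id}_s{j + 1}" for j in range(n_s)]

        latent = rng.standard_normal((cfg.n_genes, n_s))
        shift = rng.uniform(*cfg.location_shift_range)
        scale = rng.uniform(*cfg.scale_range)

        # probe-level rows: 1-3 probes per gene, each latent + probe noise
        n_probes = rng.integers(
            cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1, size=cfg.n_genes
        )
        probe_rows, probe_ids, pmap = [], [], {}
        for i, g in enumerate(genes):
            for k in range(n_probes[i]):
                pid = f"{ds_id}_p{len(probe_ids) + 1}"
                noise = rng.normal(0.0, cfg.probe_noise_sd, n_s)
                probe_rows.append(shift + scale * (latent[i] + noise))
                probe_ids.append(pid)
                pmap[pid] = [g]
        n_mm = int(round(cfg.multimapping_fraction * len(probe_ids)))
        for _ in range(n_mm):
            pid = f"{ds_id}_p{len(probe_ids) + 1}"
            probe_rows.append(shift + scale * rng.standard_normal(n_s))
            probe_ids.append(pid)
            pair = rng.choice(cfg.n_genes, size=2, replace=False)
            pmap[pid] = [genes[pair[0]], genes[pair[1]]]
        probe_mat = np.asarray(probe_rows)
        if cfg.missing_rate > 0:
            probe_mat[rng.random(probe_mat.shape) < cfg.missing_rate] = np.nan
        probe_expr = pd.DataFrame(probe_mat, index=probe_ids, columns=sample_ids)
        probe_expr.index.name = "feature_id"

        gene_expr = collapse_to_genes(probe_expr, filter_multimapping(pmap))

        # planted effects act on the dichotomized gene-centred expression
        log_mult = np.zeros(n_s)
        for i in planted_idx:
            values = gene_expr.loc[genes[i]].to_numpy()
            med = np.nanmedian(values)
            high = np.where(np.isnan(values), False, values > med)
            log_mult += betas[i] * high
        os_haz = np.exp(log_mult) / cfg.baseline_mean_months
        dfs_haz = np.exp(log_mult) / cfg.dfs_baseline_mean_months
        os_time, os_event = _draw_survival(rng, os_haz, cfg.censoring_rate)
        dfs_time, dfs_event = _draw_survival(rng, dfs_haz, cfg.censoring_rate)

        clin = _draw_clinical(rng, cfg, sample_ids)
        clin.insert(0, "os_time", np.round(os_time, 4))
        clin.insert(1, "os_event", os_event.astype(float))
        clin.insert(2, "dfs_time", np.round(dfs_time, 4))
        clin.insert(3, "dfs_event", dfs_event.astype(float))
        if cfg.endpoint_pattern == "mixed" and cfg.n_datasets >= 3:
            if d == 0:
                clin[["dfs_time", "dfs_event"]] = np.nan
            elif d == 1:
                clin[["os_time", "os_event"]] = np.nan
        for col in ("figo_stage", "grade", "os_event", "dfs_event", "age", "os_time", "dfs_time"):
            clin[col] = pd.to_numeric(clin[col])

        cohorts.append(
            assemble_cohort(ds_id, platform, gene_expr, clin, min_patients=1)
        )

        if out_dir is not None:
            write_expression_matrix(probe_expr, out_dir / f"{ds_id}_expression.tsv")
            write_probe_gene_map(pmap, out_dir / f"{ds_id}_probe_map.tsv")
            write_clinical_table(clin, out_dir / f"{ds_id}_clinical.tsv")
            manifest_entries.append(
                {
                    "id": ds_id,
                    "platform": platform,
                    "expression": f"{ds_id}_expression.tsv",
                    "probe_map": f"{ds_id}_probe_map.tsv",
                    "clinical": f"{ds_id}_clinical.tsv",
                    "time_unit": "months",
                }
            )

    truth = truth_table(cfg)
    if out_dir is not None:
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {"min_patients": 1, "datasets": manifest_entries}, fh, sort_keys=False
            )
        truth.to_csv(out_dir / "truth_table.tsv", sep="\t", index=False, na_rep="NA")
    return assemble_compendium(cohorts), truth


def simulate_matched_mirna(cfg: SimConfig, n_samples: int = 200):
    """Matched host-gene / miRNA expression matrices for surrogate vetting.

    The first ``round(mirna_shared_fraction * n_mirnas)`` miRNAs share a
    latent factor with their host gene (both = factor + independent
    noise of sd ``mirna_noise_sd``); the rest are independent of their
    host with matched marginal variance.  Host gene ids continue the
    compendium's Entrez-style numbering; sample ids are shared between
    the two matrices.  Returns (host_expr, mirna_expr, host_map) with
    ``host_map`` a :class:`~survpool.mirna.MirnaHostMap`.
    """
    from survpool.mirna import MirnaHostMap

    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(977,)))
    n = cfg.n_mirnas
    n_shared = int(round(cfg.mirna_shared_fraction * n))
    sample_ids = [f"m_s{j + 1}" for j in range(n_samples)]
    host_ids = [str(50001 + i) for i in range(n)]
    mirna_ids = [f"sim-miR-{i + 1}" for i in range(n)]
    sd = cfg.mirna_noise_sd
    total_sd = np.sqrt(1.0 + sd**2)
    host = np.empty((n, n_samples))
    mirna = np.empty((n, n_samples))
    for i in range(n):
        if i < n_shared:
            f = rng.standard_normal(n_samples)
            host[i] = f + rng.normal(0.0, sd, n_samples)
            mirna[i] = f + rng.normal(0.0, sd, n_samples)
        else:
            host[i] = rng.normal(0.0, total_sd, n_samples)
            mirna[i] = rng.normal(0.0, total_sd, n_samples)
    host_expr = pd.DataFrame(host, index=host_ids, columns=sample_ids)
    host_expr.index.name = "feature_id"
    mirna_expr = pd.DataFrame(mirna, index=mirna_ids, columns=sample_ids)
    mirna_expr.index.name = "feature_id"
    return host_expr, mirna_expr, MirnaHostMap(entries=dict(zip(mirna_ids, host_ids)))
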