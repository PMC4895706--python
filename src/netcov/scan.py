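"""Pathway x marker scan: orchestrates grouping, statistics, permutation
significance and FDR into module results.

A *module* is one (pathway, marker) pair; the scan asks, for every pair,
whether the marker's genotype changes the covariance structure of the
pathway's genes.  Statistics are computed from a pooled per-pathway Gram
or kernel matrix, so permutations only reindex rows and columns.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .covtest import t_from_gram
from .io import ExpressionMatrix, GeneSetCollection, GenotypeMatrix, ModuleResult, results_frame
from .kernel import KernelSpec, kernel_matrix
from .significance import fdr_qvalues, nominal_p, normalize_statistic, permutation_null_gram

__all__ = [
    "ScanConfig",
    "GroupedSamples",
    "SkipSignal",
    "split_by_genotype",
    "scan",
    "scan_report",
    "select_modules",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Scan settings.

    ``min_group_size`` defaults to 10: with ~50/50 splits of a hundred-odd
    segregants this keeps the U-statistic denominators well away from
    their hard floor of 4.  ``min_pathway_genes`` drops pathways with too
    few measured genes to carry covariance signal.  ``fdr_threshold`` is
    the per-method q-value cutoff used by :func:`select_modules`.
    """

    methods: list[KernelSpec] = field(default_factory=lambda: [KernelSpec("linear")])
    B: int = 1000
    min_group_size: int = 10
    min_pathway_genes: int = 3
    fdr_threshold: float = 0.25
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.min_group_size < 4:
            raise ValueError("min_group_size must be at least 4")
        if self.min_pathway_genes < 2:
            raise ValueError("min_pathway_genes must be at least 2")
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.B < 1:
            raise ValueError("need at least one permutation")


@dataclass
class GroupedSamples:
    """Sample indices per genotype class, ordered by ascending code."""

    groups: list[np.ndarray]
    codes: np.ndarray

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)


@dataclass
class SkipSignal:
    reason: str


def split_by_genotype(marker_row: np.ndarray, min_group_size: int) -> GroupedSamples | SkipSignal:
    """Group sample indices by genotype code; missing (NaN) samples are
    dropped.  Returns a skip signal if fewer than two classes remain or
    any class is smaller than ``min_group_size``."""
    row = np.asarray(marker_row, dtype=float)
    present = np.flatnonzero(~np.isnan(row))
    if present.size == 0:
        return SkipSignal("all genotypes missing")
    codes = np.unique(row[present])
    if codes.size < 2:
        return SkipSignal("monomorphic")
    if codes.size > 3:
        return SkipSignal(f"{codes.size} genotype classes (test defined for 2-3)")
    groups = [present[row[present] == c] for c in codes]
    small = [len(g) for g in groups if len(g) < min_group_size]
    if small:
        return SkipSignal(f"genotype class below min_group_size ({min(small)} < {min_group_size})")
    return GroupedSamples(groups=groups, codes=codes)


def module_seed(master_seed: int, pathway: str, marker: str) -> int:
    """Stable per-module RNG substream: adding or reordering modules never
    perturbs another module's permutation null."""
    h = hashlib.sha256(f"{master_seed}|{pathway}|{marker}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ModuleRecord:
    """Pre-FDR scan record for one module under one method."""

    pathway: str
    marker: str
    method: str
    n_groups: int
    group_sizes: tuple[int, ...]
    T: float
    p_nominal: float
    NT: float
    NT_null: np.ndarray


@dataclass
class ScanReport:
    results: list[ModuleResult]
    skipped: list[tuple[str, str, str]]
    n_evaluated: dict[str, int]


def _t_value(K: np.ndarray, groups: list[np.ndarray]) -> float:
    return t_from_gram(K, groups).T


def _scan_pathway(
    pathway: str,
    Xp: np.ndarray,
    geno_rows: np.ndarray,
    marker_ids: list[str],
    cfg: ScanConfig,
) -> tuple[list[ModuleRecord], list[tuple[str, str, str]]]:
    """All (marker, method) records for one pathway; ``Xp`` is samples x
    pathway-genes over the shared samples, ``geno_rows`` markers x shared
    samples."""
    records: list[ModuleRecord] = []
    skipped: list[tuple[str, str, str]] = []
    kernels = {spec.label: kernel_matrix(Xp, Xp, spec) for spec in cfg.methods}
    for m, marker in enumerate(marker_ids):
        grouping = split_by_genotype(geno_rows[m], cfg.min_group_size)
        if isinstance(grouping, SkipSignal):
            skipped.append((pathway, marker, grouping.reason))
            continue
        keep = np.concatenate(grouping.groups)
        labels = np.concatenate(
            [np.full(len(g), c) for g, c in zip(grouping.groups, grouping.codes)]
        )
        seed = module_seed(cfg.seed, pathway, marker)
        for spec in cfg.methods:
            K = kernels[spec.label][np.ix_(keep, keep)]
            local_groups = [
                np.flatnonzero(labels == c) for c in grouping.codes
            ]
            stat = t_from_gram(K, local_groups, method=spec.label)
            null = permutation_null_gram(K, labels, cfg.B, seed, _t_value)
            p = nominal_p(stat.T, null)
            norm = normalize_statistic(stat.T, null)
            records.append(
                ModuleRecord(
                    pathway=pathway,
                    marker=marker,
                    method=spec.label,
                    n_groups=len(local_groups),
                    group_sizes=grouping.sizes,
                    T=stat.T,
                    p_nominal=p,
                    NT=norm.NT_observed,
                    NT_null=norm.NT_null,
                )
            )
    return records, skipped


def scan_report(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    sets: GeneSetCollection,
    cfg: ScanConfig | None = None,
) -> ScanReport:
    """Run the full pathway x marker scan and return results plus skip log
    and evaluation counters."""
    cfg = cfg or ScanConfig()
    if not expr.adjusted:
        logger.warning(
            "expression matrix is not flagged as mean-adjusted; the covariance "
            "test assumes genotype effects on means were removed"
        )
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    shared = sorted(set(expr.sample_ids) & set(geno.sample_ids))
    if len(shared) < 2 * cfg.min_group_size:
        raise ValueError(
            f"{len(shared)} shared samples; need at least 2*min_group_size "
            f"= {2 * cfg.min_group_size}"
        )
    e_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    g_pos = {s: i for i, s in enumerate(geno.sample_ids)}
    e_idx = np.array([e_pos[s] for s in shared])
    g_idx = np.array([g_pos[s] for s in shared])
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    geno_rows = geno.values[:, g_idx]

    jobs = []
    skipped: list[tuple[str, str, str]] = []
    for pathway, genes in sets:
        present = [g for g in genes if g in gene_pos]
        dropped = len(genes) - len(present)
        if dropped:
            logger.info("pathway %s: %d/%d genes not in expression matrix", pathway, dropped, len(genes))
        if len(present) < cfg.min_pathway_genes:
            skipped.append((pathway, "*", f"only {len(present)} measured genes"))
            continue
        rows = np.array([gene_pos[g] for g in present])
        Xp = expr.values[np.ix_(rows, e_idx)].T  # samples x genes
        jobs.append((pathway, Xp))

    if cfg.n_jobs == 1:
        outputs = [
            _scan_pathway(pw, Xp, geno_rows, geno.marker_ids, cfg) for pw, Xp in jobs
        ]
    else:
        outputs = Parallel(n_jobs=cfg.n_jobs)(
            delayed(_scan_pathway)(pw, Xp, geno_rows, geno.marker_ids, cfg)
            for pw, Xp in jobs
        )

    records: list[ModuleRecord] = []
    for recs, skips in outputs:
        records.extend(recs)
        skipped.extend(skips)

    # FDR per method over the pooled null NT distribution
    results: list[ModuleResult] = []
    n_evaluated: dict[str, int] = {}
    for spec in cfg.methods:
        m_recs = [r for r in records if r.method == spec.label]
        n_evaluated[spec.label] = len(m_recs)
        if not m_recs:
            continue
        obs = np.array([r.NT for r in m_recs])
        pooled_null = np.concatenate([r.NT_null for r in m_recs])
        q = fdr_qvalues(obs, pooled_null)
        for r, qv in zip(m_recs, q):
            results.append(
                ModuleResult(
                    pathway=r.pathway,
                    marker=r.marker,
                    method=r.method,
                    n_groups=r.n_groups,
                    group_sizes=r.group_sizes,
                    T=r.T,
                    p_nominal=r.p_nominal,
                    NT=r.NT,
                    fdr_q=float(qv),
                )
            )

    frame = results_frame(results)
    key = {(r.pathway, r.marker, r.method): r for r in results}
    ordered = [
        key[(row.pathway, row.marker, row.method)] for row in frame.itertuples()
    ]
    return ScanReport(results=ordered, skipped=skipped, n_evaluated=n_evaluated)


def scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    sets: GeneSetCollection,
    cfg: ScanConfig | None = None,
) -> list[ModuleResult]:
    """Convenience wrapper returning the sorted module results only."""
    return scan_report(expr, geno, sets, cfg).results


def select_modules(results: list[ModuleResult], fdr_threshold: float) -> list[ModuleResult]:
    """Retain modules with q-value at or below the threshold (NaN q, from
    modules whose NT was undefined, is never selected)."""
    return [r for r in results if not np.isnan(r.fdr_q) and r.fdr_q <= fdr_threshold]
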