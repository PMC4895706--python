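"""Synthetic fixture generators.

These emulate residualized (mean-adjusted) expression with a
genotype-dependent covariance structure and a panel of binary markers, at
the scale of a haploid cross: two genotype classes per marker with roughly
balanced splits.  They do not emulate marker linkage, mean eQTL effects
(data are generated mean-zero), heavy-tailed expression noise, or
overlapping regulatory signals — properties real segregant data have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GeneSetCollection, GenotypeMatrix

__all__ = ["PlantedScanDataset", "make_planted_scan_dataset"]


@dataclass
class PlantedScanDataset:
    expr: ExpressionMatrix
    geno: GenotypeMatrix
    sets: GeneSetCollection
    causal_pathway: str
    causal_marker: str


def make_planted_scan_dataset(
    seed: int,
    n_genes: int = 20,
    n_per_group: int = 60,
    n_pathways: int = 5,
    n_markers: int = 10,
    pathway_size: int = 8,
    rho: float = 0.5,
) -> PlantedScanDataset:
    """A scan fixture with one causal (pathway, marker) module.

    All genes are unit-variance Gaussian.  Under the causal marker's
    reference genotype the causal pathway's genes are independent; under
    the alternate genotype they share a dense exchangeable correlation
    ``rho`` — a covariance shift spread over every pair in the pathway,
    the dense-alternative regime the Frobenius-norm test targets.  The
    remaining markers are independent balanced binary splits carrying no
    expression signal, and the remaining pathways draw their genes from
    the unperturbed pool.
    """
    if pathway_size > n_genes // 2:
        raise ValueError("pathway_size must leave genes for null pathways")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n)]
    markers = [f"M{i:02d}" for i in range(1, n_markers + 1)]
    causal_marker = markers[rng.integers(n_markers)]
    causal_pathway = "PW01"

    # balanced binary genotypes; causal marker defines the covariance groups
    geno_vals = np.empty((n_markers, n), dtype=float)
    base = np.repeat([0.0, 1.0], n_per_group)
    for m in range(n_markers):
        geno_vals[m] = base[rng.permutation(n)]
    causal_codes = geno_vals[markers.index(causal_marker)]

    # expression: independent N(0,1) everywhere except the causal block
    X = rng.standard_normal((n_genes, n))
    block = np.arange(pathway_size)
    Sigma = (1.0 - rho) * np.eye(pathway_size) + rho * np.ones((pathway_size, pathway_size))
    L = np.linalg.cholesky(Sigma)
    alt = np.flatnonzero(causal_codes == 1.0)
    X[np.ix_(block, alt)] = L @ rng.standard_normal((pathway_size, alt.size))

    X -= X.mean(axis=1, keepdims=True)
    expr = ExpressionMatrix(genes, samples, X, adjusted=True)
    geno = GenotypeMatrix(markers, list(samples), geno_vals)

    sets: dict[str, list[str]] = {causal_pathway: [genes[i] for i in block]}
    null_pool = list(range(pathway_size, n_genes))
    for k in range(2, n_pathways + 1):
        chosen = rng.choice(null_pool, size=min(pathway_size, len(null_pool)), replace=False)
        sets[f"PW{k:02d}"] = [genes[i] for i in sorted(chosen)]
    collection = GeneSetCollection(sets, {name: "synthetic" for name in sets})
    return PlantedScanDataset(
        expr=expr,
        geno=geno,
        sets=collection,
        causal_pathway=causal_pathway,
        causal_marker=causal_marker,
    )
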