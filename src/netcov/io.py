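"""Readers, writers and in-memory containers for expression, genotype,
gene-set and result tables.

Canonical on-disk layout is TSV with genes/markers as rows and samples as
columns (the usual eQTL layout); gene sets use the standard GMT format.
Matching between files is by exact string ID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_GENOTYPE = "NA"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {what} IDs: {', '.join(dups)}")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of (log-scale) expression values or residuals.

    ``adjusted`` marks data whose genotype effects on the means have been
    removed and whose rows are centered to mean zero — the state the
    covariance statistics assume.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.adjusted:
            rm = np.abs(self.values.mean(axis=1))
            if self.values.shape[1] and rm.max(initial=0.0) > 1e-8:
                raise ValueError(
                    "adjusted expression must have zero row means "
                    f"(max |mean| = {rm.max():.3g})"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GenotypeMatrix:
    """Marker x sample matrix of discrete genotype codes.

    Codes are small integers (0/1 for haploid or binary markers, 0/1/2 for
    diploid biallelic markers); missing calls are ``nan`` internally and
    ``NA`` on disk.  A marker with more than three distinct non-missing
    classes is invalid — the covariance test is defined for two or three
    genotype groups only.
    """

    marker_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError("genotype values shape does not match IDs")
        _check_unique(self.marker_ids, "marker")
        _check_unique(self.sample_ids, "sample")
        for mid, row in zip(self.marker_ids, self.values):
            obs = row[~np.isnan(row)]
            if obs.size == 0:
                raise ValueError(f"marker {mid!r} has no non-missing genotype")
            if not np.all(obs == np.round(obs)):
                raise ValueError(f"marker {mid!r} has non-integer genotype codes")
            classes = np.unique(obs)
            if classes.size > 3:
                raise ValueError(
                    f"marker {mid!r} has {classes.size} genotype classes "
                    "(at most 3 supported: the test is defined for 2-3 groups)"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), preserving file order."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class ModuleResult:
    """One (pathway, marker) module: test statistic and its significance."""

    pathway: str
    marker: str
    method: str
    n_groups: int
    group_sizes: tuple[int, ...]
    T: float
    p_nominal: float
    NT: float
    fdr_q: float


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (header = sample IDs, first
    column = gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids, "gene")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ValueError(
                f"non-numeric expression value {bad.iloc[0]!r} at "
                f"gene {row!r}, sample {col!r} in {path}"
            ) from None
    return ExpressionMatrix(gene_ids, [str(s) for s in df.columns], values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a marker x sample genotype TSV; missing calls are ``NA``."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_GENOTYPE], keep_default_na=False
    )
    return GenotypeMatrix(
        [str(m) for m in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
    )


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.values, index=geno.marker_ids, columns=geno.sample_ids)
    df.index.name = "marker"
    with np.errstate(invalid="ignore"):
        out = df.map(lambda v: MISSING_GENOTYPE if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are removed (first occurrence kept) with
    a warning; gene IDs absent from any expression matrix are retained here
    (intersection with measured genes happens at scan time).
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields "
                    "(need name, description and at least one gene)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            uniq: list[str] = []
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                uniq.append(g)
            if len(uniq) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} contains duplicate "
                    "genes; duplicates removed",
                    stacklevel=2,
                )
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


RESULT_COLUMNS = [
    "pathway",
    "marker",
    "method",
    "n_groups",
    "group_sizes",
    "T",
    "p_nominal",
    "NT",
    "fdr_q",
]


def results_frame(results: Sequence[ModuleResult]) -> pd.DataFrame:
    """Tabulate module results, sorted by q ascending (ties: NT descending,
    then pathway, marker) for reproducible diffs."""
    rows = [
        {
            "pathway": r.pathway,
            "marker": r.marker,
            "method": r.method,
            "n_groups": r.n_groups,
            "group_sizes": "/".join(str(s) for s in r.group_sizes),
            "T": r.T,
            "p_nominal": r.p_nominal,
            "NT": r.NT,
            "fdr_q": r.fdr_q,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["fdr_q", "NT", "pathway", "marker"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def write_results(results: Sequence[ModuleResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> list[ModuleResult]:
    df = pd.read_csv(path, sep="\t", dtype={"group_sizes": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            ModuleResult(
                pathway=str(row["pathway"]),
                marker=str(row["marker"]),
                method=str(row["method"]),
                n_groups=int(row["n_groups"]),
                group_sizes=tuple(int(s) for s in str(row["group_sizes"]).split("/")),
                T=float(row["T"]),
                p_nominal=float(row["p_nominal"]),
                NT=float(row["NT"]),
                fdr_q=float(row["fdr_q"]),
            )
        )
    return out
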