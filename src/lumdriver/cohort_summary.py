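"""Cohort-level cross-tabulations.

Four summaries over the combined cohort (in-house exomes plus the
literature/COSMIC samples, 37 tumors by default):

* DNA-repair pathway cross-tab — which samples carry SNVs in genes of
  the seven repair mechanisms (BER/NER/MMR/HRR/NHEJ/DDC/TLS);
* truncating-variant summary — per sample, the nonsense/frameshift
  genes with their CCGD-A/B and expression-regulation memberships;
* gene mutation frequency ranking;
* driver-candidate counts per tumor (genes in CGC u CCGD-A u CCGD-B).

The cohort denominator is always an explicit parameter because the
source tables list only affected samples.  Printed percentages round
half-up to one decimal; the unrounded fraction is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import CohortVariants, GeneSet, PathwayMap, PATHWAY_MECHANISMS, normalize_symbol

__all__ = [
    "round_percent",
    "RepairCrosstab",
    "TruncatingSummary",
    "repair_crosstab",
    "repair_crosstab_from_table",
    "truncating_summary",
    "truncating_summary_from_table",
    "gene_frequency",
    "driver_count_per_tumor",
]

TRUNCATING = frozenset({"nonsense", "frameshift"})


def round_percent(fraction: float, decimals: int = 1) -> float:
    """``count/denominator`` as a percentage, rounded half-up."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RepairCrosstab:
    """(sample, gene, mechanism flags, per-sample variant total) rows plus
    the affected-sample tally over the cohort denominator."""

    rows: pd.DataFrame
    n_samples_affected: int
    cohort_size: int
    fraction_affected: float

    @property
    def percent_affected(self) -> float:
        return round_percent(self.fraction_affected)


def repair_crosstab(
    gene_lists: Mapping[str, set[str] | frozenset[str]],
    pmap: PathwayMap,
    cohort_size: int,
    sample_totals: Mapping[str, int] | None = None,
) -> RepairCrosstab:
    """Project per-sample mutated-gene lists onto the DNA-repair map.

    Genes absent from the pathway map never appear in the output; a
    sample counts as affected when at least one of its genes maps.
    """
    rows = []
    affected = set()
    for sample_id in sorted(gene_lists):
        for gene in sorted(gene_lists[sample_id]):
            if gene not in pmap:
                continue
            affected.add(sample_id)
            mechs = pmap[gene]
            row = {"sample_id": sample_id, "gene": gene}
            row.update({m: m in mechs for m in PATHWAY_MECHANISMS})
            row["n_variants_sample"] = (
                sample_totals.get(sample_id) if sample_totals else None
            )
            rows.append(row)
    if cohort_size < len(affected):
        raise ValueError(
            f"cohort_size {cohort_size} smaller than {len(affected)} affected samples"
        )
    columns = ["sample_id", "gene", *PATHWAY_MECHANISMS, "n_variants_sample"]
    return RepairCrosstab(
        rows=pd.DataFrame(rows, columns=columns),
        n_samples_affected=len(affected),
        cohort_size=cohort_size,
        fraction_affected=len(affected) / cohort_size if cohort_size else 0.0,
    )


def repair_crosstab_from_table(table2: pd.DataFrame, pmap: PathwayMap,
                               cohort_size: int) -> RepairCrosstab:
    """Build the cross-tab from the packaged repair-gene fixture."""
    gene_lists: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for row in table2.itertuples(index=False):
        gene_lists.setdefault(row.sample_id, set()).add(normalize_symbol(row.gene))
        totals[row.sample_id] = int(row.n_variants_sample)
    return repair_crosstab(gene_lists, pmap, cohort_size, sample_totals=totals)


@dataclass
class TruncatingSummary:
    """Per-sample truncating genes with database memberships, plus the
    count of samples carrying >= 1 expression-regulation gene."""

    rows: pd.DataFrame
    n_samples_with_expr_gene: int
    cohort_size: int
    fraction: float

    @property
    def percent(self) -> float:
        return round_percent(self.fraction)


def truncating_summary(
    variants: CohortVariants,
    ccgd_a: GeneSet,
    ccgd_b: GeneSet,
    expr_set: GeneSet,
    cohort_size: int,
) -> TruncatingSummary:
    """Per sample, genes hit by nonsense/frameshift variants and their
    CCGD-A/B and expression-regulation subset memberships."""
    per_sample: dict[str, set[str]] = {}
    for r in variants.records:
        if r.consequence in TRUNCATING:
            per_sample.setdefault(r.sample_id, set()).add(normalize_symbol(r.gene))
    rows = []
    n_expr_samples = 0
    for sample_id in sorted(per_sample):
        genes = sorted(per_sample[sample_id])
        in_a = [g for g in genes if g in ccgd_a]
        in_b = [g for g in genes if g in ccgd_b]
        in_expr = [g for g in genes if g in expr_set]
        n_expr_samples += bool(in_expr)
        rows.append(
            {
                "sample_id": sample_id,
                "truncating_genes": ";".join(genes),
                "ccgd_a": ";".join(in_a),
                "ccgd_b": ";".join(in_b),
                "expr_genes": ";".join(in_expr),
            }
        )
    columns = ["sample_id", "truncating_genes", "ccgd_a", "ccgd_b", "expr_genes"]
    return TruncatingSummary(
        rows=pd.DataFrame(rows, columns=columns),
        n_samples_with_expr_gene=n_expr_samples,
        cohort_size=cohort_size,
        fraction=n_expr_samples / cohort_size if cohort_size else 0.0,
    )


def truncating_summary_from_table(table3: pd.DataFrame, cohort_size: int) -> TruncatingSummary:
    """Summarize the packaged truncating-variant fixture.

    Two samples in the source table print only gene counts (their full
    lists were too long to typeset); the fixture carries those counts in
    ``n_truncating``/``n_expr``, so sample-level flags use the counts.
    """
    rows = []
    n_expr_samples = 0
    for row in table3.itertuples(index=False):
        n_expr = int(row.n_expr)
        n_expr_samples += n_expr > 0
        rows.append(
            {
                "sample_id": row.sample_id,
                "truncating_genes": "" if row.truncating_genes == "-" else row.truncating_genes,
                "ccgd_a": "" if row.ccgd_a == "-" else row.ccgd_a,
                "ccgd_b": "" if row.ccgd_b == "-" else row.ccgd_b,
                "expr_genes": "" if row.expr_genes == "-" else row.expr_genes,
            }
        )
    columns = ["sample_id", "truncating_genes", "ccgd_a", "ccgd_b", "expr_genes"]
    return TruncatingSummary(
        rows=pd.DataFrame(rows, columns=columns),
        n_samples_with_expr_gene=n_expr_samples,
        cohort_size=cohort_size,
        fraction=n_expr_samples / cohort_size if cohort_size else 0.0,
    )


def gene_frequency(
    gene_lists: Mapping[str, set[str] | frozenset[str]], cohort_size: int
) -> pd.DataFrame:
    """Per-gene (count, fraction, percent) ranking, descending by count
    then alphabetical."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    counts: dict[str, int] = {}
    for genes in gene_lists.values():
        for g in genes:
            key = normalize_symbol(g)
            counts[key] = counts.get(key, 0) + 1
    ranking = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {
                "gene": g,
                "count": n,
                "fraction": n / cohort_size,
                "percent": round_percent(n / cohort_size),
            }
            for g, n in ranking
        ],
        columns=["gene", "count", "fraction", "percent"],
    )


def driver_count_per_tumor(
    gene_lists: Mapping[str, set[str] | frozenset[str]],
    cgc: GeneSet,
    ccgd_a: GeneSet,
    ccgd_b: GeneSet,
) -> tuple[dict[str, int], dict[str, float]]:
    """Count per sample the mutated genes in CGC u CCGD-A u CCGD-B.

    Returns the per-sample counts and summary statistics (median by the
    even-n midpoint rule, min, max, mean).
    """
    per_sample = {
        sample_id: sum(1 for g in genes if g in cgc or g in ccgd_a or g in ccgd_b)
        for sample_id, genes in gene_lists.items()
    }
    values = np.array(sorted(per_sample.values())) if per_sample else np.array([0])
    stats = {
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
    }
    return per_sample, stats


def write_crosstab_tsv(crosstab: RepairCrosstab, path: str | Path) -> None:
    with open(path, "w") as fh:
        crosstab.rows.to_csv(fh, sep="\t", index=False)
        fh.write(
            f"# samples_affected={crosstab.n_samples_affected}/{crosstab.cohort_size} "
            f"fraction={crosstab.fraction_affected:.6f} percent={crosstab.percent_affected}\n"
        )


def write_truncating_tsv(summary: TruncatingSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        summary.rows.to_csv(fh, sep="\t", index=False)
        fh.write(
            f"# samples_with_expression_gene={summary.n_samples_with_expr_gene}/"
            f"{summary.cohort_size} fraction={summary.fraction:.6f} percent={summary.percent}\n"
        )
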