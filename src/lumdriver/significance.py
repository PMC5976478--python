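"""Background-mutation-rate significance test for recurrently mutated genes.

The null model assumes each patient's non-synonymous mutations fall
independently and uniformly over the coding territory.  For a gene of
coding length ``L`` in a territory of ``T`` base pairs, a patient who
carries ``n_i`` non-synonymous mutations hits the gene at least once
with probability ``1 - (1 - L/T)**n_i``.  The number of patients hit is
then a Poisson-binomial count (a sum of independent, non-identically
distributed Bernoulli trials), whose exact tail is computed by iterative
convolution of the count distribution — suitable for cohorts where
asymptotic approximations would be unreliable.  Gene-level p-values are
corrected with Benjamini–Hochberg step-up q-values and flagged at
FDR < 10 % by default.

An alternative statistic (``statistic="mutations"``) tests the total
deduplicated mutation count in the gene against the convolution of the
per-patient binomial counts instead of the number of patients hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import CohortVariants, normalize_symbol
from .spectrum import DEFAULT_SILENT_CLASSES

__all__ = [
    "SignificanceResult",
    "per_patient_hit_prob",
    "poisson_binomial_tail",
    "bh_fdr",
    "gene_significance",
    "write_significance_tsv",
]


def per_patient_hit_prob(n_i: int, length_bp: int, territory_bp: int) -> float:
    """P(patient with ``n_i`` uniform background mutations hits the gene >= once)."""
    if n_i < 0:
        raise ValueError("n_i must be non-negative")
    if length_bp <= 0 or territory_bp <= 0:
        raise ValueError("lengths must be positive")
    if length_bp > territory_bp:
        raise ValueError(f"gene length {length_bp} exceeds territory {territory_bp}")
    if length_bp == territory_bp:
        return 1.0 if n_i > 0 else 0.0
    return -np.expm1(n_i * np.log1p(-length_bp / territory_bp))


def _count_distribution(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of the Poisson-binomial count by iterative convolution."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """Exact ``P(X >= k)`` for ``X`` a sum of independent Bernoulli(p_i)."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if k < 0 or k > probs.size + 1:
        raise ValueError(f"k={k} outside [0, {probs.size + 1}]")
    if k <= 0:
        return 1.0
    if k > probs.size:
        return 0.0
    pmf = _count_distribution(probs)
    # summing the lower tail and complementing keeps precision when k is small
    return float(min(1.0, max(0.0, 1.0 - pmf[:k].sum())))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SignificanceResult:
    gene: str
    observed_patients: int
    per_patient_probs: list[float]
    p_value: float
    q_value: float
    flagged: bool


def gene_significance(
    cohort: CohortVariants,
    lengths: Mapping[str, int],
    q_threshold: float = 0.10,
    silent_classes: frozenset[str] = DEFAULT_SILENT_CLASSES,
    statistic: str = "patients",
) -> list[SignificanceResult]:
    """Per-gene recurrence significance against the uniform background.

    Each patient's background total ``n_i`` is their own non-synonymous
    load (heterogeneous across patients, homogeneous within).  With the
    default ``statistic="patients"`` the observed value is the number of
    distinct patients carrying >= 1 non-synonymous SNV in the gene;
    ``statistic="mutations"`` tests the positionally deduplicated
    mutation count instead.  Results are sorted by ascending p-value.
    """
    if statistic not in ("patients", "mutations"):
        raise ValueError("statistic must be 'patients' or 'mutations'")
    territory_bp = int(round(cohort.territory_mbp * 1e6))
    nonsilent = [r for r in cohort.records if r.consequence not in silent_classes]
    patients = cohort.sample_ids
    n_by_patient = {s: 0 for s in patients}
    gene_hits: dict[str, set[str]] = {}
    gene_positions: dict[str, set[tuple]] = {}
    for r in nonsilent:
        n_by_patient[r.sample_id] += 1
        key = normalize_symbol(r.gene)
        gene_hits.setdefault(key, set()).add(r.sample_id)
        gene_positions.setdefault(key, set()).add(r.variant_key)

    missing = sorted(g for g in gene_hits if g not in lengths)
    if missing:
        raise KeyError(f"gene(s) missing from the length table: {missing}")

    results = []
    for gene, hit_samples in gene_hits.items():
        length = lengths[gene]
        probs = [
            per_patient_hit_prob(n_by_patient[s], length, territory_bp) for s in patients
        ]
        if statistic == "patients":
            k = len(hit_samples)
            p = poisson_binomial_tail(probs, k)
        else:
            k = len(gene_positions[gene])
            p = _mutation_count_tail(
                [n_by_patient[s] for s in patients], length, territory_bp, k
            )
        results.append(
            SignificanceResult(
                gene=gene,
                observed_patients=len(hit_samples) if statistic == "patients" else k,
                per_patient_probs=probs,
                p_value=p,
                q_value=np.nan,
                flagged=False,
            )
        )
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.flagged = bool(qv < q_threshold)
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results


def _mutation_count_tail(
    n_per_patient: Sequence[int], length_bp: int, territory_bp: int, k: int
) -> float:
    """P(total background mutations in the gene >= k): convolution of the
    per-patient Binomial(n_i, L/T) counts, truncated at k successes."""
    from scipy.stats import binom

    if k <= 0:
        return 1.0
    p_site = length_bp / territory_bp
    # pmf over counts 0..k, with index k holding the folded mass of ">= k";
    # folding after every convolution keeps the tail exact
    pmf = np.zeros(k + 1)
    pmf[0] = 1.0
    for n_i in n_per_patient:
        kk = np.arange(0, min(n_i, k) + 1)
        binom_pmf = binom.pmf(kk, n_i, p_site)
        binom_pmf[-1] += binom.sf(kk[-1], n_i, p_site)
        full = np.convolve(pmf, binom_pmf)
        pmf = full[: k + 1].copy()
        pmf[k] += full[k + 1 :].sum()
    return float(min(1.0, max(0.0, pmf[k])))


def write_significance_tsv(results: Sequence[SignificanceResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "k": r.observed_patients,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "flagged": r.flagged,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
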