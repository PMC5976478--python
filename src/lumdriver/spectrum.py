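"""Substitution-class and 96-trinucleotide-context profiling.

Substitutions are strand-normalized to a pyrimidine reference base
(COSMIC convention): a G>A change with flanks C_G is reported as the
C>T change in the reverse-complemented triplet.  6 pyrimidine classes
x 16 flank combinations give the 96 trinucleotide mutation types.

Also houses the cohort mutation-load/rate statistics and the positional
recurrence collapse (a variant is identified by chrom/pos/ref/alt, so a
substitution seen in several samples counts once as a unique variant).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BASES, CohortVariants, RowValidationError

__all__ = [
    "SUBSTITUTION_CLASSES",
    "ALL_CONTEXTS",
    "DEFAULT_SILENT_CLASSES",
    "SpectrumCounts",
    "LoadStats",
    "RecurrenceSummary",
    "normalize_substitution",
    "build_spectrum",
    "mutation_rate",
    "load_stats",
    "collapse_recurrence",
    "write_spectrum_tsv",
    "write_load_stats_tsv",
    "write_recurrence_tsv",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Consequence classes excluded from the "non-silent" mutation rate.
DEFAULT_SILENT_CLASSES = frozenset({"synonymous", "intron", "utr3", "utr5", "intergenic"})


def normalize_substitution(ref: str, alt: str, flank5: str, flank3: str) -> tuple[str, str]:
    """Classify one substitution into (pyrimidine class, trinucleotide category).

    Returns e.g. ``("C>T", "ACG>ATG")``.  If ``ref`` is a purine the whole
    triplet and the alternate base are reverse-complemented first, so the
    function is invariant under strand flips.
    """
    for name, base in (("ref", ref), ("alt", alt), ("flank5", flank5), ("flank3", flank3)):
        if base not in BASES:
            raise ValueError(f"{name} must be one of A/C/G/T, got {base!r}")
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        flank5, flank3 = _COMPLEMENT[flank3], _COMPLEMENT[flank5]
    class6 = f"{ref}>{alt}"
    category = f"{flank5}{ref}{flank3}>{flank5}{alt}{flank3}"
    return class6, category


def _all_contexts() -> tuple[str, ...]:
    cats = []
    for class6 in SUBSTITUTION_CLASSES:
        ref, alt = class6[0], class6[2]
        for f5 in "ACGT":
            for f3 in "ACGT":
                cats.append(f"{f5}{ref}{f3}>{f5}{alt}{f3}")
    return tuple(cats)


#: The 96 trinucleotide mutation types, in class-major order.
ALL_CONTEXTS = _all_contexts()

_CONTEXT_CLASS = {c: f"{c[1]}>{c[5]}" for c in ALL_CONTEXTS}


@dataclass
class SpectrumCounts:
    """Counts over the 6 substitution classes and 96 trinucleotide types.

    Zero-count categories are retained so the context map always has
    exactly 96 keys and the two count maps sum to the same total.
    """

    class_counts: dict[str, int]
    context_counts: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.context_counts) != set(ALL_CONTEXTS):
            raise ValueError("context_counts must have exactly the 96 canonical keys")
        if sum(self.class_counts.values()) != sum(self.context_counts.values()):
            raise ValueError("class and context totals disagree")

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    def class_fraction(self, class6: str) -> float:
        return self.class_counts[class6] / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(ALL_CONTEXTS),
                "class": [_CONTEXT_CLASS[c] for c in ALL_CONTEXTS],
                "count": [self.context_counts[c] for c in ALL_CONTEXTS],
            }
        )


def build_spectrum(cohort: CohortVariants) -> SpectrumCounts:
    """Tally the cohort into class and 96-context counts (conserving n)."""
    class_counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    context_counts = {c: 0 for c in ALL_CONTEXTS}
    for i, rec in enumerate(cohort.records, start=1):
        try:
            class6, category = normalize_substitution(rec.ref, rec.alt, rec.flank5, rec.flank3)
        except ValueError as exc:
            raise RowValidationError(f"record {i} ({rec.sample_id} {rec.chrom}:{rec.pos}): {exc}")
        class_counts[class6] += 1
        context_counts[category] += 1
    return SpectrumCounts(class_counts=class_counts, context_counts=context_counts)


def mutation_rate(n_snvs: int, territory_mbp: float) -> float:
    """SNVs per megabase pair of surveyed territory."""
    if territory_mbp <= 0:
        raise ValueError("territory_mbp must be positive")
    if n_snvs < 0:
        raise ValueError("n_snvs must be non-negative")
    return n_snvs / territory_mbp


@dataclass
class LoadStats:
    """Per-tumor mutation-load summary plus cohort-level rates per Mbp."""

    per_sample_counts: dict[str, int]
    median: float
    minimum: int
    maximum: int
    mean: float
    total_rate_per_mbp: float
    nonsilent_rate_per_mbp: float


def load_stats(
    cohort: CohortVariants,
    silent_classes: frozenset[str] = DEFAULT_SILENT_CLASSES,
) -> LoadStats:
    """Mutation loads per sample; median is the midpoint of the middle two
    for even sample counts.  Rates are cohort means over the territory."""
    counts = cohort.per_sample_counts()
    if not counts:
        raise ValueError("cohort has no samples")
    values = np.array(sorted(counts.values()))
    n_samples = len(values)
    nonsilent = sum(1 for r in cohort.records if r.consequence not in silent_classes)
    return LoadStats(
        per_sample_counts=counts,
        median=float(np.median(values)),
        minimum=int(values[0]),
        maximum=int(values[-1]),
        mean=float(values.mean()),
        total_rate_per_mbp=mutation_rate(len(cohort.records), cohort.territory_mbp) / n_samples,
        nonsilent_rate_per_mbp=mutation_rate(nonsilent, cohort.territory_mbp) / n_samples,
    )


@dataclass
class RecurrenceSummary:
    """Cross-sample sharing structure of positional variant identities."""

    total_observations: int
    unique_variants: int
    multiplicity_histogram: dict[int, int]

    def __post_init__(self) -> None:
        hist = self.multiplicity_histogram
        if self.total_observations != sum(k * v for k, v in hist.items()):
            raise ValueError("total_observations inconsistent with histogram")
        if self.unique_variants != sum(hist.values()):
            raise ValueError("unique_variants inconsistent with histogram")


def collapse_recurrence(cohort: CohortVariants) -> RecurrenceSummary:
    """Collapse repeated substitutions at the same chromosomal position.

    A variant is keyed by (chrom, pos, ref, alt); the histogram maps the
    number of distinct samples sharing a variant to how many variants show
    that multiplicity.
    """
    carriers: dict[tuple, set[str]] = {}
    for rec in cohort.records:
        carriers.setdefault(rec.variant_key, set()).add(rec.sample_id)
    hist = Counter(len(samples) for samples in carriers.values())
    return RecurrenceSummary(
        total_observations=sum(k * v for k, v in hist.items()),
        unique_variants=len(carriers),
        multiplicity_histogram=dict(sorted(hist.items())),
    )


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------


def write_spectrum_tsv(spectrum: SpectrumCounts, path: str | Path) -> None:
    spectrum.to_frame().to_csv(path, sep="\t", index=False)


def write_load_stats_tsv(stats: LoadStats, path: str | Path) -> None:
    rows = [{"sample_id": s, "n_snvs": n} for s, n in sorted(stats.per_sample_counts.items())]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(
            f"# median={stats.median} min={stats.minimum} max={stats.maximum} "
            f"mean={stats.mean:.4f} total_rate_per_mbp={stats.total_rate_per_mbp:.4f} "
            f"nonsilent_rate_per_mbp={stats.nonsilent_rate_per_mbp:.4f}\n"
        )


def write_recurrence_tsv(summary: RecurrenceSummary, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "n_samples_sharing": list(summary.multiplicity_histogram),
            "n_variants": list(summary.multiplicity_histogram.values()),
        }
    )
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(
            f"# total_observations={summary.total_observations} "
            f"unique_variants={summary.unique_variants}\n"
        )
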