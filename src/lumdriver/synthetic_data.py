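"""Seeded generators for cohorts and evidence tables.

The default parameters emulate the study conditions of an 8-sample
luminal-breast-cancer exome cohort: per-tumor mutation loads confined
to 19-74 SNVs, a C>T-dominated substitution spectrum (39 % of
substitutions), sparse cross-sample recurrence (297 private variants,
five shared by two tumors, one shared by three, i.e. 310 observations
over 303 unique variants) and a 62-Mbp capture territory.  Evidence
fields are drawn independently from categorical priors shaped like the
cohort's evidence table.

A single seeded generator drives each run, so identical parameters and
seed give byte-identical outputs.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    CohortVariants,
    EvidenceRecord,
    FIXTURE_NAMES,
    VariantRecord,
    fixture_path,
)
from .spectrum import SUBSTITUTION_CLASSES, _COMPLEMENT

__all__ = [
    "EvidencePriors",
    "SimulationParams",
    "simulate_cohort",
    "simulate_evidence",
    "simulate_gene_lengths",
    "make_fixtures",
]

_DEFAULT_CONSEQUENCE_PROBS = {
    "missense": 0.28,
    "intergenic": 0.24,
    "utr3": 0.14,
    "intron": 0.14,
    "synonymous": 0.10,
    "utr5": 0.04,
    "splice": 0.02,
    "nonsense": 0.02,
    "other": 0.02,
}


@dataclass(frozen=True)
class EvidencePriors:
    """Categorical parameters for each simulated evidence field."""

    p_cgc: float = 0.12
    rank_probs: dict = field(
        default_factory=lambda: {
            "A": 0.05, "B": 0.12, "C": 0.10, "D": 0.20, "NR": 0.08, "none": 0.45,
        }
    )
    p_domain: float = 0.45
    p_same_bc: float = 0.07
    p_same_other: float = 0.12
    p_freq_high: float = 0.17  # chance the gene-level SNV frequency is >= 1 %
    p_freq_missing: float = 0.02
    fathmm_probs: dict = field(
        default_factory=lambda: {"pathogenic": 0.55, "neutral": 0.40, "missing": 0.05}
    )
    polyphen_probs: dict = field(
        default_factory=lambda: {"deleterious": 0.40, "benign": 0.33, "missing": 0.27}
    )
    sift_probs: dict = field(
        default_factory=lambda: {"not_tolerated": 0.38, "tolerated": 0.45, "missing": 0.17}
    )
    gvgd_probs: dict = field(
        default_factory=lambda: {
            "C0": 0.02, "C15": 0.05, "C25": 0.05, "C35": 0.10,
            "C45": 0.08, "C55": 0.10, "C65": 0.45, "missing": 0.15,
        }
    )
    p_chasm_missing: float = 0.15
    p_km: float = 0.30
    p_literature: float = 0.50

    @classmethod
    def all_negative(cls) -> "EvidencePriors":
        """Every boolean false, every call missing: scores must be 0."""
        return cls(
            p_cgc=0.0,
            rank_probs={"none": 1.0},
            p_domain=0.0,
            p_same_bc=0.0,
            p_same_other=0.0,
            p_freq_high=0.0,
            p_freq_missing=1.0,
            fathmm_probs={"missing": 1.0},
            polyphen_probs={"missing": 1.0},
            sift_probs={"missing": 1.0},
            gvgd_probs={"missing": 1.0},
            p_chasm_missing=1.0,
            p_km=0.0,
            p_literature=0.0,
        )

    @classmethod
    def forced_driver(cls) -> "EvidencePriors":
        """CGC membership plus three guaranteed pathogenic calls."""
        return cls(
            p_cgc=1.0,
            fathmm_probs={"pathogenic": 1.0},
            polyphen_probs={"deleterious": 1.0},
            sift_probs={"not_tolerated": 1.0},
        )


def _check_probs(probs: dict, what: str) -> None:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} must sum to 1 (got {total})")
    if any(p < 0 for p in probs.values()):
        raise ValueError(f"{what} must be non-negative")


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; the defaults are the emulated study conditions."""

    n_samples: int = 8
    load_range: tuple[int, int] = (19, 74)
    ct_fraction: float = 0.39
    class_probs: dict | None = None  # derived from ct_fraction when None
    n_private: int = 297
    n_shared_pairs: int = 5
    n_shared_triples: int = 1
    spike_genes: dict = field(default_factory=dict)  # gene -> n samples hit
    consequence_probs: dict = field(default_factory=lambda: dict(_DEFAULT_CONSEQUENCE_PROBS))
    evidence_priors: EvidencePriors = field(default_factory=EvidencePriors)
    territory_mbp: float = 62.0
    n_genes: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.load_range
        if not 0 <= lo <= hi:
            raise ValueError("load_range must be a non-decreasing non-negative pair")
        _check_probs(self.resolved_class_probs(), "class_probs")
        _check_probs(self.consequence_probs, "consequence_probs")
        if self.n_shared_pairs > 0 and self.n_samples < 2:
            raise ValueError("shared pairs need at least 2 samples")
        if self.n_shared_triples > 0 and self.n_samples < 3:
            raise ValueError("shared triples need at least 3 samples")
        for gene, m in self.spike_genes.items():
            if not 1 <= m <= self.n_samples:
                raise ValueError(f"spike_genes[{gene!r}]={m} infeasible for {self.n_samples} samples")

    def resolved_class_probs(self) -> dict[str, float]:
        if self.class_probs is not None:
            return self.class_probs
        rest = (1.0 - self.ct_fraction) / 5.0
        return {c: (self.ct_fraction if c == "C>T" else rest) for c in SUBSTITUTION_CLASSES}


def _draw_loads(rng: np.random.Generator, params: SimulationParams,
                shared_extra: np.ndarray, spike_extra: np.ndarray) -> np.ndarray:
    """Private counts per sample such that total loads stay in range."""
    lo, hi = params.load_range
    for _ in range(500):
        private = rng.multinomial(params.n_private, [1.0 / params.n_samples] * params.n_samples)
        loads = private + shared_extra + spike_extra
        if params.n_private == 0 or (loads.min() >= lo and loads.max() <= hi):
            return private
    raise ValueError(
        "could not place the requested variants with per-sample loads inside "
        f"load_range={params.load_range}; the sharing structure is infeasible"
    )


def _random_variant(rng: np.random.Generator, params: SimulationParams,
                    pos: int, chrom: str, gene: str,
                    consequence: str | None = None) -> dict:
    class_probs = params.resolved_class_probs()
    classes = list(class_probs)
    class6 = classes[rng.choice(len(classes), p=[class_probs[c] for c in classes])]
    ref, alt = class6[0], class6[2]
    flank5, flank3 = (("ACGT")[i] for i in rng.integers(0, 4, size=2))
    if rng.random() < 0.5:  # present on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        flank5, flank3 = _COMPLEMENT[flank3], _COMPLEMENT[flank5]
    if consequence is None:
        cons_names = list(params.consequence_probs)
        consequence = cons_names[
            rng.choice(len(cons_names), p=[params.consequence_probs[c] for c in cons_names])
        ]
    return dict(
        gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        flank5=flank5, flank3=flank3, consequence=consequence,
    )


def simulate_cohort(params: SimulationParams) -> CohortVariants:
    """Generate a cohort with the configured load, spectrum, sharing and
    spike structure; deterministic under a fixed seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]

    # carrier sets for shared variants, then spiked samples, then loads
    shared_groups = []
    shared_extra = np.zeros(n, dtype=int)
    for size in [2] * params.n_shared_pairs + [3] * params.n_shared_triples:
        members = rng.choice(n, size=size, replace=False)
        shared_groups.append(sorted(int(i) for i in members))
        shared_extra[members] += 1
    spike_targets: list[tuple[str, list[int]]] = []
    spike_extra = np.zeros(n, dtype=int)
    for gene in sorted(params.spike_genes):
        members = sorted(int(i) for i in rng.choice(n, size=params.spike_genes[gene],
                                                    replace=False))
        spike_targets.append((gene, members))
        spike_extra[np.array(members, dtype=int)] += 1
    private = _draw_loads(rng, params, shared_extra, spike_extra)

    n_spike_records = sum(len(m) for _, m in spike_targets)
    n_unique = int(params.n_private) + len(shared_groups) + n_spike_records
    positions = rng.choice(90_000_000, size=n_unique, replace=False) + 2
    chroms = [f"chr{int(c)}" for c in rng.integers(1, 23, size=n_unique)]
    pos_iter = iter(range(n_unique))

    records: list[VariantRecord] = []
    for i, sample in enumerate(sample_ids):
        for _ in range(int(private[i])):
            j = next(pos_iter)
            gene = f"G{int(rng.integers(0, params.n_genes)):04d}"
            records.append(VariantRecord(sample_id=sample, **_random_variant(
                rng, params, int(positions[j]), chroms[j], gene)))
    for members in shared_groups:
        j = next(pos_iter)
        gene = f"G{int(rng.integers(0, params.n_genes)):04d}"
        variant = _random_variant(rng, params, int(positions[j]), chroms[j], gene)
        for i in members:
            records.append(VariantRecord(sample_id=sample_ids[i], **variant))
    for gene, members in spike_targets:
        for i in members:
            j = next(pos_iter)
            records.append(VariantRecord(sample_id=sample_ids[i], **_random_variant(
                rng, params, int(positions[j]), chroms[j], gene, consequence="missense")))
    return CohortVariants(records=records, territory_mbp=params.territory_mbp)


def _draw_cat(rng: np.random.Generator, probs: dict) -> str:
    names = list(probs)
    return names[rng.choice(len(names), p=[probs[k] for k in names])]


def simulate_evidence(cohort: CohortVariants, params: SimulationParams) -> list[EvidenceRecord]:
    """One evidence record per cohort observation, fields independent
    draws from the configured priors.  Seeded off ``params.seed``."""
    if not cohort.records:
        raise ValueError("cohort is empty")
    pri = params.evidence_priors
    rng = np.random.default_rng(params.seed + 1)

    def freq() -> float | None:
        if rng.random() < pri.p_freq_missing:
            return None
        if rng.random() < pri.p_freq_high:
            return float(rng.uniform(0.01, 0.30))
        return float(rng.uniform(0.0, 0.01))

    records = []
    for r in cohort.records:
        rank = _draw_cat(rng, pri.rank_probs)
        fathmm = _draw_cat(rng, pri.fathmm_probs)
        polyphen = _draw_cat(rng, pri.polyphen_probs)
        sift = _draw_cat(rng, pri.sift_probs)
        gvgd = _draw_cat(rng, pri.gvgd_probs)
        chasm = None if rng.random() < pri.p_chasm_missing else float(rng.random())
        records.append(
            EvidenceRecord(
                gene=r.gene,
                sample_id=r.sample_id,
                variant_label=r.protein_change or f"{r.chrom}:{r.pos}{r.ref}>{r.alt}",
                cgc=bool(rng.random() < pri.p_cgc),
                ccgd_ranks=frozenset() if rank == "none" else frozenset({rank}),
                functional_domain=bool(rng.random() < pri.p_domain),
                same_variant_bc=bool(rng.random() < pri.p_same_bc),
                same_variant_other=bool(rng.random() < pri.p_same_other),
                freq_all_cancers=freq(),
                freq_bc=freq(),
                consequence=r.consequence,
                fathmm=None if fathmm == "missing" else fathmm,
                polyphen=None if polyphen == "missing" else polyphen,
                sift=None if sift == "missing" else sift,
                gvgd_class=None if gvgd == "missing" else gvgd,
                chasm_p=chasm,
                km_significant=bool(rng.random() < pri.p_km),
                literature_support=bool(rng.random() < pri.p_literature),
            )
        )
    return records


def simulate_gene_lengths(
    genes: set[str] | list[str], seed: int = 0, mean_bp: int = 1500
) -> dict[str, int]:
    """Plausible coding lengths (log-normal, >= 300 bp) for a gene list."""
    rng = np.random.default_rng(seed)
    ordered = sorted(genes)
    draws = rng.lognormal(mean=np.log(mean_bp), sigma=0.5, size=len(ordered))
    return {g: int(max(300, round(d))) for g, d in zip(ordered, draws)}


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the packaged summary-table and gene-set fixtures into a
    directory; re-runs are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_NAMES:
        dest = out / name
        shutil.copyfile(fixture_path(name), dest)
        written.append(dest)
    return written
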