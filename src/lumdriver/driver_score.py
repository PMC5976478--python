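"""Evidence-based driver-candidate scoring and classification.

Two additive rubrics over the per-variant evidence vector:

* **System 1** (whole-exome cohort): Cancer Gene Census membership 3 pts;
  best mouse-screen (CCGD) rank A/B/C/D -> 2/1.5/1/0.5 pts; named
  functional domain at the site 0.5; gene SNV frequency >= 1 % in all
  cancers and in breast cancer 0.5 each; the same variant previously
  reported in breast or other cancers 0.5 (single bonus, not cumulative);
  truncating consequence (nonsense/frameshift) 1.5; and 1 pt when at
  least 3 of the 5 assessment algorithms (FATHMM, PolyPhen, SIFT,
  Align-GVGD, CHASM) call the variant pathogenic.
* **System 2** (literature/COSMIC cohort): identical except the vote set
  drops Align-GVGD and the vote bonus is two-tier: exactly 2 pathogenic
  calls of 4 -> 0.5 pt, 3 or 4 -> 1 pt.

A variant's label is ``CGC`` when the gene is in the Cancer Gene Census,
else ``PD`` (candidate driver) at score >= 3.5, ``pd`` (possible driver)
at score >= 2, else ``Neutral``.

Pathogenicity votes: FATHMM "pathogenic", PolyPhen "deleterious", SIFT
"not tolerated", Align-GVGD class >= C35, CHASM p < 0.05.  Missing calls
contribute no vote and the vote thresholds are absolute counts, not
fractions of available calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .io_formats import EvidenceRecord, GVGD_CLASSES, normalize_symbol

__all__ = [
    "RubricConfig",
    "DriverScore",
    "DEFAULT_CONFIG",
    "algorithm_votes",
    "score_system1",
    "score_system2",
    "classify",
    "score_table",
    "write_scores_tsv",
]

TRUNCATING_CONSEQUENCES = frozenset({"nonsense", "frameshift"})

SYSTEM1_ALGORITHMS = ("fathmm", "polyphen", "sift", "gvgd", "chasm")
SYSTEM2_ALGORITHMS = ("fathmm", "polyphen", "sift", "chasm")


@dataclass(frozen=True)
class RubricConfig:
    """All weights and thresholds of both scoring systems.

    The defaults are the published rubric; any field can be overridden
    from a YAML mapping via :meth:`from_yaml`.
    """

    w_cgc: float = 3.0
    rank_weights: dict = field(
        default_factory=lambda: {"A": 2.0, "B": 1.5, "C": 1.0, "D": 0.5, "NR": 0.0}
    )
    w_domain: float = 0.5
    w_freq_all: float = 0.5
    w_freq_bc: float = 0.5
    freq_threshold: float = 0.01
    w_same_variant: float = 0.5
    w_truncating: float = 1.5
    gvgd_min_class: str = "C35"
    chasm_alpha: float = 0.05
    w_km: float = 0.0
    w_literature: float = 0.0
    pd_threshold: float = 3.5  # "candidate driver" (PD)
    pd_lower_threshold: float = 2.0  # "possible driver" (pd)

    def __post_init__(self) -> None:
        weights = [self.w_cgc, self.w_domain, self.w_freq_all, self.w_freq_bc,
                   self.w_same_variant, self.w_truncating, self.w_km, self.w_literature,
                   *self.rank_weights.values()]
        if any(w < 0 for w in weights):
            raise ValueError("rubric weights must be non-negative")
        if self.pd_threshold <= self.pd_lower_threshold:
            raise ValueError("PD threshold must exceed the pd threshold")
        if self.gvgd_min_class not in GVGD_CLASSES:
            raise ValueError(f"unknown GV/GD class {self.gvgd_min_class!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RubricConfig":
        overrides = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(overrides) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown rubric field(s) {sorted(unknown)}")
        return replace(cls(), **overrides)


DEFAULT_CONFIG = RubricConfig()


@dataclass
class DriverScore:
    gene: str
    sample_id: str
    variant_label: str
    score: float
    label: str  # CGC | PD | pd | Neutral
    itemized: dict[str, float]

    def __post_init__(self) -> None:
        if abs(self.score - sum(self.itemized.values())) > 1e-9:
            raise ValueError("score must equal the sum of itemized points")


def _pathogenic_call(e: EvidenceRecord, algorithm: str, cfg: RubricConfig) -> bool:
    if algorithm == "fathmm":
        return e.fathmm == "pathogenic"
    if algorithm == "polyphen":
        return e.polyphen == "deleterious"
    if algorithm == "sift":
        return e.sift == "not_tolerated"
    if algorithm == "gvgd":
        if e.gvgd_class is None:
            return False
        return GVGD_CLASSES.index(e.gvgd_class) >= GVGD_CLASSES.index(cfg.gvgd_min_class)
    if algorithm == "chasm":
        return e.chasm_p is not None and e.chasm_p < cfg.chasm_alpha
    raise ValueError(f"unknown algorithm {algorithm!r}")


def algorithm_votes(
    e: EvidenceRecord, cfg: RubricConfig = DEFAULT_CONFIG, system: int = 1
) -> int:
    """Number of pathogenic calls among the system's assessment algorithms."""
    algorithms = SYSTEM1_ALGORITHMS if system == 1 else SYSTEM2_ALGORITHMS
    return sum(_pathogenic_call(e, a, cfg) for a in algorithms)


def classify(score: float, cgc: bool, cfg: RubricConfig = DEFAULT_CONFIG) -> str:
    """CGC if the gene is census-listed, else PD / pd / Neutral by score."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if cgc:
        return "CGC"
    if score >= cfg.pd_threshold:
        return "PD"
    if score >= cfg.pd_lower_threshold:
        return "pd"
    return "Neutral"


def _score_common(e: EvidenceRecord, cfg: RubricConfig) -> dict[str, float]:
    items: dict[str, float] = {}
    items["cgc"] = cfg.w_cgc if e.cgc else 0.0
    best = e.best_ccgd_rank
    items["ccgd"] = cfg.rank_weights.get(best, 0.0) if best else 0.0
    items["domain"] = cfg.w_domain if e.functional_domain else 0.0
    items["freq_all"] = (
        cfg.w_freq_all
        if e.freq_all_cancers is not None and e.freq_all_cancers >= cfg.freq_threshold
        else 0.0
    )
    items["freq_bc"] = (
        cfg.w_freq_bc if e.freq_bc is not None and e.freq_bc >= cfg.freq_threshold else 0.0
    )
    items["same_variant"] = (
        cfg.w_same_variant if (e.same_variant_bc or e.same_variant_other) else 0.0
    )
    items["truncating"] = cfg.w_truncating if e.consequence in TRUNCATING_CONSEQUENCES else 0.0
    items["km"] = cfg.w_km if e.km_significant else 0.0
    items["literature"] = cfg.w_literature if e.literature_support else 0.0
    return items


def _build(e: EvidenceRecord, items: dict[str, float], cfg: RubricConfig) -> DriverScore:
    score = sum(items.values())
    return DriverScore(
        gene=e.gene,
        sample_id=e.sample_id,
        variant_label=e.variant_label,
        score=score,
        label=classify(score, e.cgc, cfg),
        itemized=items,
    )


def score_system1(e: EvidenceRecord, cfg: RubricConfig = DEFAULT_CONFIG) -> DriverScore:
    """Five-algorithm rubric: >= 3 pathogenic calls award 1 point."""
    items = _score_common(e, cfg)
    items["votes"] = 1.0 if algorithm_votes(e, cfg, system=1) >= 3 else 0.0
    return _build(e, items, cfg)


def score_system2(e: EvidenceRecord, cfg: RubricConfig = DEFAULT_CONFIG) -> DriverScore:
    """Four-algorithm rubric: exactly 2 calls -> 0.5 pt, 3 or 4 -> 1 pt."""
    items = _score_common(e, cfg)
    votes = algorithm_votes(e, cfg, system=2)
    items["votes"] = 1.0 if votes >= 3 else (0.5 if votes == 2 else 0.0)
    return _build(e, items, cfg)


def score_table(
    evidence: Iterable[EvidenceRecord],
    system: int = 1,
    cfg: RubricConfig = DEFAULT_CONFIG,
) -> tuple[list[DriverScore], dict[str, int]]:
    """Score every record and count distinct genes per label.

    A gene appearing in several samples (e.g. a recurrent hotspot) is
    counted once, under the label of its highest-scoring row.
    """
    if system not in (1, 2):
        raise ValueError("system must be 1 or 2")
    scorer = score_system1 if system == 1 else score_system2
    scores = [scorer(e, cfg) for e in evidence]
    best_by_gene: dict[str, DriverScore] = {}
    for s in scores:
        key = normalize_symbol(s.gene)
        if key not in best_by_gene or s.score > best_by_gene[key].score:
            best_by_gene[key] = s
    summary = Counter(s.label for s in best_by_gene.values())
    return scores, {lab: summary.get(lab, 0) for lab in ("CGC", "PD", "pd", "Neutral")}


def write_scores_tsv(scores: Sequence[DriverScore], path: str | Path) -> None:
    item_keys = sorted({k for s in scores for k in s.itemized}) if scores else []
    rows = []
    for s in scores:
        row = {
            "sample_id": s.sample_id,
            "gene": s.gene,
            "variant_label": s.variant_label,
        }
        row.update({f"pts_{k}": s.itemized.get(k, 0.0) for k in item_keys})
        row["total"] = s.score
        row["label"] = s.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
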