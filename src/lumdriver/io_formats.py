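"""Readers, writers and domain types for every table the pipeline touches.

All on-disk formats are plain tab-separated text.  Coordinates are 1-based
and fully closed, as in VCF.  Flanking reference bases travel as explicit
columns (``flank5``/``flank3``) so that no reference genome is required;
:func:`fill_flanks_from_fasta` can populate them when a FASTA is available.
Missing evidence is an explicit state (``None``), never silently zero —
the scoring rubric decides its weight.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BASES",
    "CONSEQUENCES",
    "PATHWAY_MECHANISMS",
    "CCGD_RANKS",
    "GVGD_CLASSES",
    "SchemaError",
    "RowValidationError",
    "VariantRecord",
    "CohortVariants",
    "EvidenceRecord",
    "GeneSet",
    "PathwayMap",
    "normalize_symbol",
    "read_variant_table",
    "write_variant_table",
    "read_evidence_table",
    "write_evidence_table",
    "read_vcf",
    "load_gene_set",
    "load_pathway_map",
    "read_gene_lengths",
    "fixture_path",
    "load_table1",
    "load_table1_evidence",
    "load_table2",
    "load_table3",
    "load_packaged_gene_set",
    "load_packaged_pathway_map",
    "fill_flanks_from_fasta",
]

BASES = frozenset("ACGT")

#: Recognised consequence classes for a single-base substitution.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "synonymous",
        "splice",
        "utr3",
        "utr5",
        "intron",
        "intergenic",
        "other",
    }
)

#: DNA-repair mechanisms tracked by the pathway cross-tab: base excision
#: repair, nucleotide excision repair, mismatch repair, homologous
#: recombination repair, non-homologous end joining, DNA-damage checkpoint
#: signalling and translesion synthesis.
PATHWAY_MECHANISMS = ("BER", "NER", "MMR", "HRR", "NHEJ", "DDC", "TLS")

#: Common-insertion-site strength ranks from mouse transposon screens
#: (A = top 10 %, B = top 11-25 %, C = top 26-50 %, D = bottom 50 %,
#: NR = screen reported no rank).
CCGD_RANKS = ("A", "B", "C", "D", "NR")

#: Align-GVGD missense severity classes, ordered least to most severe.
GVGD_CLASSES = ("C0", "C15", "C25", "C35", "C45", "C55", "C65")


class SchemaError(ValueError):
    """A table is missing a mandatory column or uses an unknown token."""


class RowValidationError(ValueError):
    """One or more data rows violate a record invariant."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


def normalize_symbol(symbol: str) -> str:
    """Gene-symbol key: upper-cased, pre-slash token of aliases.

    ``"RBM16/SCAF8"`` and ``"rbm16"`` both key as ``"RBM16"``; the verbatim
    alias is preserved wherever the symbol is stored, only lookups use the
    normalized key.
    """
    return symbol.strip().upper().split("/")[0]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One somatic SNV observation in one sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    flank5: str
    flank3: str
    consequence: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        for name in ("ref", "alt", "flank5", "flank3"):
            base = getattr(self, name)
            if base not in BASES:
                raise RowValidationError(f"{name} must be one of A/C/G/T, got {base!r}")
        if self.ref == self.alt:
            raise RowValidationError(f"ref == alt ({self.ref!r}) is not a substitution")
        if self.pos < 2:
            raise RowValidationError(f"pos must be >= 2 so the 5' flank exists, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise RowValidationError(f"unknown consequence {self.consequence!r}")

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        """Positional identity used for cross-sample recurrence collapse."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortVariants:
    """An ordered collection of SNV observations plus the surveyed territory.

    ``territory_mbp`` defaults to 62, the exome capture footprint in
    megabase pairs; mutation rates are counts divided by this scalar.
    """

    records: list[VariantRecord]
    territory_mbp: float = 62.0

    def __post_init__(self) -> None:
        if self.territory_mbp <= 0:
            raise ValueError("territory_mbp must be positive")

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    def per_sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "gene": r.gene,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "flank5": r.flank5,
                    "flank3": r.flank3,
                    "consequence": r.consequence,
                    "protein_change": r.protein_change or "",
                }
                for r in self.records
            ],
            columns=VARIANT_COLUMNS,
        )


@dataclass
class EvidenceRecord:
    """The per-variant evidence vector the scoring rubrics consume.

    ``None`` marks evidence that was not determined (printed as ``ND``,
    ``-`` or left blank); enum fields use lower-case snake tokens.
    """

    gene: str
    sample_id: str
    variant_label: str = ""
    cgc: bool = False
    ccgd_ranks: frozenset[str] = frozenset()
    functional_domain: bool = False
    same_variant_bc: bool = False
    same_variant_other: bool = False
    freq_all_cancers: float | None = None
    freq_bc: float | None = None
    consequence: str = "missense"
    fathmm: str | None = None  # "pathogenic" | "neutral" | None
    polyphen: str | None = None  # "deleterious" | "benign" | None
    sift: str | None = None  # "not_tolerated" | "tolerated" | None
    gvgd_class: str | None = None  # C0..C65 | None
    chasm_p: float | None = None
    km_significant: bool | None = None
    literature_support: bool | None = None

    def __post_init__(self) -> None:
        bad = set(self.ccgd_ranks) - set(CCGD_RANKS)
        if bad:
            raise RowValidationError(f"unknown CCGD rank(s) {sorted(bad)}")
        for name in ("freq_all_cancers", "freq_bc", "chasm_p"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise RowValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.gvgd_class is not None and self.gvgd_class not in GVGD_CLASSES:
            raise RowValidationError(f"unknown GV/GD class {self.gvgd_class!r}")
        if self.consequence not in CONSEQUENCES:
            raise RowValidationError(f"unknown consequence {self.consequence!r}")

    @property
    def gene_key(self) -> str:
        return normalize_symbol(self.gene)

    @property
    def best_ccgd_rank(self) -> str | None:
        """Highest rank present (A beats B beats C beats D beats NR)."""
        for rank in CCGD_RANKS:
            if rank in self.ccgd_ranks:
                return rank
        return None


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise ValueError("gene set contains an empty symbol")

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._keys

    @property
    def _keys(self) -> frozenset[str]:
        return frozenset(normalize_symbol(g) for g in self.genes)


@dataclass(frozen=True)
class PathwayMap:
    """gene symbol -> subset of the 7 DNA-repair mechanisms."""

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, mechs in self.mapping.items():
            if not mechs:
                raise ValueError(f"gene {gene} maps to an empty mechanism set")
            bad = set(mechs) - set(PATHWAY_MECHANISMS)
            if bad:
                raise SchemaError(f"unknown DNA-repair mechanism token(s) {sorted(bad)}")

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.mapping

    def __getitem__(self, symbol: str) -> frozenset[str]:
        return self.mapping[normalize_symbol(symbol)]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.mapping)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "flank5",
    "flank3",
    "consequence",
    "protein_change",
]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_variant_table(path: str | Path, territory_mbp: float = 62.0) -> CohortVariants:
    """Read a cohort of SNV observations from a headered TSV.

    Rows failing base or consequence validation are rejected together,
    with their 1-based data-row numbers listed in the error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, [c for c in VARIANT_COLUMNS if c != "protein_change"], path)
    records: list[VariantRecord] = []
    errors: list[str] = []
    bad_rows: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                VariantRecord(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    flank5=str(row.flank5),
                    flank3=str(row.flank3),
                    consequence=str(row.consequence),
                    protein_change=(str(row.protein_change) or None)
                    if "protein_change" in df.columns
                    else None,
                )
            )
        except (RowValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
            bad_rows.append(i)
    if errors:
        raise RowValidationError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors), rows=bad_rows
        )
    return CohortVariants(records=records, territory_mbp=territory_mbp)


def write_variant_table(cohort: CohortVariants, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Evidence tables (schema mirrors the cohort's evidence summary table)
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "sample_id",
    "gene",
    "variant_label",
    "cgc",
    "ccgd_ranks",
    "functional_domain",
    "same_variant_bc",
    "same_variant_other",
    "freq_all_cancers",
    "freq_bc",
    "consequence",
    "fathmm",
    "polyphen",
    "sift",
    "gvgd",
    "chasm_p",
    "km_significant",
    "literature",
]

_MISSING_TOKENS = {"", "-", "ND", "NA", "nan"}
_BOOL_TOKENS = {"Yes": True, "No": False, "yes": True, "no": False, "TRUE": True, "FALSE": False}
_FATHMM_TOKENS = {"Pathogenic": "pathogenic", "Neutral": "neutral"}
_POLYPHEN_TOKENS = {"Deleterious": "deleterious", "Benign": "benign"}
_SIFT_TOKENS = {"Not Tolerated": "not_tolerated", "Tolerated": "tolerated"}

_FATHMM_OUT = {v: k for k, v in _FATHMM_TOKENS.items()}
_POLYPHEN_OUT = {v: k for k, v in _POLYPHEN_TOKENS.items()}
_SIFT_OUT = {v: k for k, v in _SIFT_TOKENS.items()}


def _map_token(token: str, table: Mapping[str, object], column: str):
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    if token not in table:
        raise SchemaError(f"unknown token {token!r} in column {column!r}")
    return table[token]


def _parse_float(token: str, column: str) -> float | None:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise SchemaError(f"non-numeric token {token!r} in column {column!r}") from exc


def _parse_ranks(token: str) -> frozenset[str]:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return frozenset()
    ranks = {t.strip().upper() for t in token.split(",") if t.strip()}
    bad = ranks - set(CCGD_RANKS)
    if bad:
        raise SchemaError(f"unknown token(s) {sorted(bad)} in column 'ccgd_ranks'")
    return frozenset(ranks)


def read_evidence_table(path: str | Path) -> list[EvidenceRecord]:
    """Parse an evidence TSV into records; header-keyed, column order free."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, [c for c in EVIDENCE_COLUMNS if c not in ("variant_label",)], path)
    records = []
    for row in df.to_dict(orient="records"):
        records.append(
            EvidenceRecord(
                gene=row["gene"],
                sample_id=str(row["sample_id"]),
                variant_label=row.get("variant_label", ""),
                cgc=bool(_map_token(row["cgc"], _BOOL_TOKENS, "cgc")),
                ccgd_ranks=_parse_ranks(row["ccgd_ranks"]),
                functional_domain=bool(
                    _map_token(row["functional_domain"], _BOOL_TOKENS, "functional_domain")
                ),
                same_variant_bc=bool(
                    _map_token(row["same_variant_bc"], _BOOL_TOKENS, "same_variant_bc")
                ),
                same_variant_other=bool(
                    _map_token(row["same_variant_other"], _BOOL_TOKENS, "same_variant_other")
                ),
                freq_all_cancers=_parse_float(row["freq_all_cancers"], "freq_all_cancers"),
                freq_bc=_parse_float(row["freq_bc"], "freq_bc"),
                consequence=row["consequence"].strip(),
                fathmm=_map_token(row["fathmm"], _FATHMM_TOKENS, "fathmm"),
                polyphen=_map_token(row["polyphen"], _POLYPHEN_TOKENS, "polyphen"),
                sift=_map_token(row["sift"], _SIFT_TOKENS, "sift"),
                gvgd_class=_map_token(
                    row["gvgd"], {c: c for c in GVGD_CLASSES}, "gvgd"
                ),
                chasm_p=_parse_float(row["chasm_p"], "chasm_p"),
                km_significant=_map_token(row["km_significant"], _BOOL_TOKENS, "km_significant"),
                literature_support=_map_token(row["literature"], _BOOL_TOKENS, "literature"),
            )
        )
    return records


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    def fmt_bool(v: bool | None) -> str:
        return "ND" if v is None else ("Yes" if v else "No")

    def fmt_float(v: float | None) -> str:
        return "ND" if v is None else repr(v)

    rows = []
    for e in records:
        rows.append(
            {
                "sample_id": e.sample_id,
                "gene": e.gene,
                "variant_label": e.variant_label,
                "cgc": fmt_bool(e.cgc),
                "ccgd_ranks": ",".join(sorted(e.ccgd_ranks)) or "ND",
                "functional_domain": fmt_bool(e.functional_domain),
                "same_variant_bc": fmt_bool(e.same_variant_bc),
                "same_variant_other": fmt_bool(e.same_variant_other),
                "freq_all_cancers": fmt_float(e.freq_all_cancers),
                "freq_bc": fmt_float(e.freq_bc),
                "consequence": e.consequence,
                "fathmm": _FATHMM_OUT.get(e.fathmm, "ND"),
                "polyphen": _POLYPHEN_OUT.get(e.polyphen, "ND"),
                "sift": _SIFT_OUT.get(e.sift, "ND"),
                "gvgd": e.gvgd_class or "ND",
                "chasm_p": fmt_float(e.chasm_p),
                "km_significant": fmt_bool(e.km_significant),
                "literature": fmt_bool(e.literature_support),
            }
        )
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets, pathway maps, gene lengths
# ---------------------------------------------------------------------------


def load_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """One symbol per line; blank lines and '#' comments ignored; deduplicated."""
    symbols: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        symbols.setdefault(normalize_symbol(token), token.upper())
    return GeneSet(name=name or Path(path).stem, genes=frozenset(symbols.values()))


def load_pathway_map(path: str | Path) -> PathwayMap:
    """TSV with columns ``gene`` and ``mechanisms`` (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["gene", "mechanisms"], path)
    mapping: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        mechs = frozenset(t.strip().upper() for t in row.mechanisms.split(",") if t.strip())
        bad = mechs - set(PATHWAY_MECHANISMS)
        if bad:
            raise SchemaError(f"{path}: unknown DNA-repair mechanism token(s) {sorted(bad)}")
        key = normalize_symbol(row.gene)
        mapping[key] = mapping.get(key, frozenset()) | mechs
    return PathwayMap(mapping=mapping)


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """TSV with columns ``gene`` and ``length_bp`` (coding length)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["gene", "length_bp"], path)
    lengths: dict[str, int] = {}
    for row in df.itertuples(index=False):
        length = int(row.length_bp)
        if length <= 0:
            raise RowValidationError(f"{path}: non-positive length for gene {row.gene}")
        lengths[normalize_symbol(row.gene)] = length
    return lengths


# ---------------------------------------------------------------------------
# Optional VCF reader (SNVs only)
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, territory_mbp: float = 62.0) -> CohortVariants:
    """Minimal VCF 4.x reader restricted to biallelic SNV records.

    The sample id comes from the header's single sample column.  The
    consequence class is read from the INFO key ``CSQCLS`` and the
    trinucleotide context from ``TRICTX`` (three reference bases centred
    on the variant, e.g. ``ACG``).  Indels and multi-allelic records are
    rejected.
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        sample_id = samples[0] if samples else Path(path).stem
        for rec in vcf:
            if len(rec.alleles or ()) != 2:
                raise RowValidationError(
                    f"{path}: record at {rec.chrom}:{rec.pos} is not biallelic"
                )
            ref, alt = rec.alleles
            if len(ref) != 1 or len(alt) != 1:
                raise RowValidationError(
                    f"{path}: record at {rec.chrom}:{rec.pos} is not an SNV"
                )
            info = dict(rec.info)
            ctx = str(info.get("TRICTX", ""))
            if len(ctx) != 3:
                raise SchemaError(
                    f"{path}: record at {rec.chrom}:{rec.pos} lacks a 3-base TRICTX"
                )
            consequence = str(info.get("CSQCLS", "other"))
            records.append(
                VariantRecord(
                    sample_id=sample_id,
                    gene=str(info.get("GENE", "")),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    flank5=ctx[0],
                    flank3=ctx[2],
                    consequence=consequence,
                )
            )
    return CohortVariants(records=records, territory_mbp=territory_mbp)


def fill_flanks_from_fasta(cohort: CohortVariants, fasta_path: str | Path) -> CohortVariants:
    """Return a copy of the cohort with flanks re-read from a reference FASTA."""
    import pysam

    with pysam.FastaFile(str(fasta_path)) as fasta:
        new_records = []
        for r in cohort.records:
            flank5 = fasta.fetch(r.chrom, r.pos - 2, r.pos - 1).upper()
            flank3 = fasta.fetch(r.chrom, r.pos, r.pos + 1).upper()
            new_records.append(replace(r, flank5=flank5, flank3=flank3))
    return CohortVariants(records=new_records, territory_mbp=cohort.territory_mbp)


# ---------------------------------------------------------------------------
# Packaged fixtures (static transcriptions of the cohort's summary tables)
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "table1_evidence.tsv",
    "table2_repair.tsv",
    "table3_truncating.tsv",
    "pathway_map.tsv",
    "geneset_cgc_cohort.txt",
    "geneset_ccgd_a.txt",
    "geneset_ccgd_b.txt",
    "geneset_expression_regulation.txt",
)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(str(importlib.resources.files("lumdriver").joinpath("data", name)))


def load_table1() -> pd.DataFrame:
    """Raw evidence fixture including the printed ``printed_total`` and
    ``printed_label`` columns."""
    return pd.read_csv(fixture_path("table1_evidence.tsv"), sep="\t", dtype=str,
                       keep_default_na=False)


def load_table1_evidence() -> list[EvidenceRecord]:
    return read_evidence_table(fixture_path("table1_evidence.tsv"))


def load_table2() -> pd.DataFrame:
    return pd.read_csv(fixture_path("table2_repair.tsv"), sep="\t", dtype=str,
                       keep_default_na=False)


def load_table3() -> pd.DataFrame:
    return pd.read_csv(fixture_path("table3_truncating.tsv"), sep="\t", dtype=str,
                       keep_default_na=False)


def load_packaged_gene_set(which: str) -> GeneSet:
    """``which`` is one of ``cgc_cohort``, ``ccgd_a``, ``ccgd_b``,
    ``expression_regulation``."""
    return load_gene_set(fixture_path(f"geneset_{which}.txt"), name=which)


def load_packaged_pathway_map() -> PathwayMap:
    return load_pathway_map(fixture_path("pathway_map.tsv"))
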