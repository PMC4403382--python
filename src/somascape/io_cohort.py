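"""Tabular I/O for the cohort tables and the ingest-time variant filters.

Three flat formats are handled: a MAF-like tab-separated somatic mutation
table, SEG-format copy-number segments, and a clinical TSV. Coordinates are
MAF/SEG native (1-based, inclusive); gene models elsewhere in the package
are BED-style 0-based half-open, and converters are explicit.

Variant-level read-depth filters follow the study design they mirror: a
minimum of 14 reads covering the site in the tumour and 8 in the normal,
with indels additionally requiring tumour reference count > 8 and tumour
variant count > 3. "Reads covering a site" is interpreted as the ref+alt
count sum, and the indel reference-count condition is applied on the
tumour side; both readings are logged in output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_CLASSES = frozenset({
    "missense", "nonsense", "splice_site", "frame_shift_indel",
    "in_frame_indel", "silent", "other",
})
NONSILENT_CLASSES = frozenset({
    "missense", "nonsense", "splice_site", "frame_shift_indel",
    "in_frame_indel",
})
_BASES = frozenset("ACGT")

MUTATION_COLUMNS = [
    "case_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
    "t_ref_count", "t_alt_count", "n_ref_count", "n_alt_count", "context3",
]
_MANDATORY = ["case_id", "gene", "chrom", "pos", "ref", "alt", "variant_class"]
_COUNT_COLUMNS = ["t_ref_count", "t_alt_count", "n_ref_count", "n_alt_count"]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_mark", "seg_mean"]
CLINICAL_COLUMNS = [
    "case_id", "survival_months", "event", "smoking", "grade", "stage",
    "node_positive", "histology",
]


class CohortFormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


@dataclass(frozen=True)
class MutationRecord:
    """One filtered somatic call. ``ref``/``alt`` are single bases, with
    '-' marking the empty side of an indel; ``context3`` is the reference
    trinucleotide centred on the site (empty for indels)."""

    case_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    t_ref_count: int = 0
    t_alt_count: int = 0
    n_ref_count: int = 0
    n_alt_count: int = 0
    context3: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for b, name in ((self.ref, "ref"), (self.alt, "alt")):
            if b != "-" and b not in _BASES:
                raise ValueError(f"invalid {name} allele {b!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if len(self.context3) not in (0, 3):
            raise ValueError("context3 must be empty or length 3")
        for c in (self.t_ref_count, self.t_alt_count,
                  self.n_ref_count, self.n_alt_count):
            if c < 0:
                raise ValueError("read counts must be non-negative")

    @property
    def is_indel(self) -> bool:
        return self.ref == "-" or self.alt == "-"

    @property
    def is_snv(self) -> bool:
        return self.ref in _BASES and self.alt in _BASES

    @property
    def is_nonsilent(self) -> bool:
        return self.variant_class in NONSILENT_CLASSES


@dataclass
class MutationCatalog:
    """A set of somatic calls plus the case roster (cases with zero
    mutations stay on the roster so per-case statistics include them)."""

    records: list[MutationRecord] = field(default_factory=list)
    case_roster: list[str] = field(default_factory=list)

    def __post_init__(self):
        roster = set(self.case_roster)
        if len(roster) != len(self.case_roster):
            raise ValueError("duplicate case_id in roster")
        seen = set()
        for r in self.records:
            if r.case_id not in roster:
                raise ValueError(f"record case {r.case_id!r} not in roster")
            key = (r.case_id, r.chrom, r.pos, r.ref, r.alt)
            if key in seen:
                raise ValueError(f"duplicate mutation record {key}")
            seen.add(key)

    def for_case(self, case_id: str) -> list[MutationRecord]:
        if case_id not in self.case_roster:
            raise KeyError(f"unknown case {case_id!r}")
        return [r for r in self.records if r.case_id == case_id]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CNSegment:
    """One segmented copy-number interval (1-based, inclusive)."""

    case_id: str
    chrom: str
    start: int
    end: int
    n_markers: int
    log2_ratio: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start > end ({self.start} > {self.end})")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")


@dataclass(frozen=True)
class ClinicalRecord:
    case_id: str
    survival_months: float
    event: int                    # 1 = death observed, 0 = censored
    smoking: str = "unknown"      # smoker / non-smoker / unknown
    grade: int = 2
    stage: str = "II"
    node_positive: bool = False
    histology: str = "PDA"

    def __post_init__(self):
        if self.survival_months < 0:
            raise ValueError("survival_months must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.smoking not in ("smoker", "non-smoker", "unknown"):
            raise ValueError(f"unknown smoking status {self.smoking!r}")


# ---------------------------------------------------------------------------
# readers / writers


def read_mutations(path, roster: list[str] | None = None) -> MutationCatalog:
    """Read a MAF-like TSV into a :class:`MutationCatalog`.

    The roster defaults to distinct case_ids in file order; a precomputed
    roster (e.g. including mutation-free cases) may be supplied instead.
    Missing count columns default to 0 with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _MANDATORY:
        if col not in df.columns:
            raise CohortFormatError(f"missing mandatory column {col!r}")
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            logger.warning("column %r missing; defaulting to 0", col)
            df[col] = "0"
    if "context3" not in df.columns:
        df["context3"] = ""
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.pos)
        except ValueError:
            raise CohortFormatError(
                f"line {i}: non-integer pos {row.pos!r}") from None
        try:
            records.append(MutationRecord(
                case_id=row.case_id, gene=row.gene, chrom=row.chrom, pos=pos,
                ref=row.ref, alt=row.alt, variant_class=row.variant_class,
                t_ref_count=int(row.t_ref_count), t_alt_count=int(row.t_alt_count),
                n_ref_count=int(row.n_ref_count), n_alt_count=int(row.n_alt_count),
                context3=row.context3))
        except ValueError as exc:
            raise CohortFormatError(f"line {i}: {exc}") from None
    if roster is None:
        roster = list(dict.fromkeys(df["case_id"]))
    return MutationCatalog(records=records, case_roster=list(roster))


def write_mutations(catalog: MutationCatalog, path) -> None:
    """Write a catalog as TSV with a fixed column order; rows are sorted by
    (case, chrom, pos) so output is deterministic."""
    rows = sorted(catalog.records, key=lambda r: (r.case_id, r.chrom, r.pos, r.ref, r.alt))
    df = pd.DataFrame([{c: getattr(r, c) for c in MUTATION_COLUMNS} for r in rows],
                      columns=MUTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[CNSegment]:
    """Read SEG-format copy-number segments (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in SEG_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"missing SEG column {col!r}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segments.append(CNSegment(
                case_id=row.sample, chrom=row.chrom, start=int(row.start),
                end=int(row.end), n_markers=int(row.num_mark),
                log2_ratio=float(row.seg_mean)))
        except ValueError as exc:
            raise CohortFormatError(f"line {i}: {exc}") from None
    return segments


def write_segments(segments: list[CNSegment], path) -> None:
    rows = sorted(segments, key=lambda s: (s.case_id, s.chrom, s.start))
    df = pd.DataFrame(
        [{"sample": s.case_id, "chrom": s.chrom, "start": s.start,
          "end": s.end, "num_mark": s.n_markers, "seg_mean": s.log2_ratio}
         for s in rows], columns=SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    """Read the clinical TSV; duplicate case_ids are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"missing clinical column {col!r}")
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.case_id in seen:
            raise CohortFormatError(f"line {i}: duplicate case_id {row.case_id!r}")
        seen.add(row.case_id)
        try:
            records.append(ClinicalRecord(
                case_id=row.case_id,
                survival_months=float(row.survival_months),
                event=int(row.event), smoking=row.smoking,
                grade=int(row.grade), stage=row.stage,
                node_positive=str(row.node_positive).lower() in ("1", "true"),
                histology=row.histology))
        except ValueError as exc:
            raise CohortFormatError(f"line {i}: {exc}") from None
    return records


def write_clinical(records: list[ClinicalRecord], path) -> None:
    df = pd.DataFrame(
        [{"case_id": r.case_id, "survival_months": r.survival_months,
          "event": r.event, "smoking": r.smoking, "grade": r.grade,
          "stage": r.stage, "node_positive": int(r.node_positive),
          "histology": r.histology} for r in records],
        columns=CLINICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant filters


def apply_variant_filters(catalog: MutationCatalog,
                          min_tumour_depth: int = 14,
                          min_normal_depth: int = 8,
                          indel_min_ref: int = 8,
                          indel_min_alt: int = 3) -> MutationCatalog:
    """Drop calls failing the read-depth filters; the roster is unchanged.

    SNVs require tumour depth >= ``min_tumour_depth`` and normal depth
    >= ``min_normal_depth`` (depth = ref+alt counts). Indels additionally
    require tumour ref count > ``indel_min_ref`` and tumour alt count
    > ``indel_min_alt`` (strict inequalities).
    """
    kept = []
    for r in catalog.records:
        if r.t_ref_count + r.t_alt_count < min_tumour_depth:
            continue
        if r.n_ref_count + r.n_alt_count < min_normal_depth:
            continue
        if r.is_indel and not (r.t_ref_count > indel_min_ref
                               and r.t_alt_count > indel_min_alt):
            continue
        kept.append(r)
    logger.info("variant filters kept %d/%d records "
                "(tumour depth>=%d, normal depth>=%d, indel ref>%d alt>%d)",
                len(kept), len(catalog.records), min_tumour_depth,
                min_normal_depth, indel_min_ref, indel_min_alt)
    return MutationCatalog(records=kept, case_roster=list(catalog.case_roster))
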