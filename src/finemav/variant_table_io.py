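"""Readers for the tab-delimited variant extract and VEP-style annotation.

The variant table is the raw output of a ``bcftools query`` command: one
headerless row per site with columns

    CHROM:POS  ID  REF  ALT  [AA]  [CADD_PHRED]  AF_1 .. AF_n

where the optional AA / CADD_PHRED columns and the population order are
declared by the caller (the extract's shape depends on the upstream query
string, so it cannot be sniffed reliably).  The annotation table is VEP
tabular output: a headered TSV whose first column is ``Location``
(``chrom:start`` or ``chrom:start-end``), used to fill in AA and/or
CADD_PHRED when the VCF lacked them.

Malformed rows are never silently altered: each is counted under a
machine-readable reason code and skipped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, TextIO, Tuple, Union

from finemav.core import VALID_ALLELES

__all__ = [
    "PopulationPanel",
    "VariantRecord",
    "AnnotationRecord",
    "TableLayout",
    "parse_variant_table",
    "parse_vep_annotation",
    "merge_annotations",
    "write_variant_table",
]

# Row-level rejection reason codes.
BAD_COLUMN_COUNT = "BAD_COLUMN_COUNT"
BAD_LOCATION = "BAD_LOCATION"
NOT_SNP = "NOT_SNP"
AF_OUT_OF_RANGE = "AF_OUT_OF_RANGE"
AF_UNPARSABLE = "AF_UNPARSABLE"
BAD_CADD = "BAD_CADD"

MISSING_FIELD_TOKENS = frozenset({"", ".", "-", "NA"})


@dataclass(frozen=True)
class PopulationPanel:
    """Ordered set of population names; fixes n and the AF column order."""

    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("a panel needs at least 2 populations")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"duplicate population names: {self.names}")
        if any(not name for name in self.names):
            raise ValueError("population names must be non-empty")

    @property
    def n(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP row: position, alleles, per-population ALT frequency."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    af_alt: Tuple[float, ...]
    aa: Optional[str] = None
    cadd_phred: Optional[float] = None

    @property
    def location_key(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class AnnotationRecord:
    """AA and/or CADD_PHRED for one genomic location."""

    location_key: str
    aa: Optional[str] = None
    cadd_phred: Optional[float] = None


@dataclass(frozen=True)
class TableLayout:
    """Declares which optional columns the variant extract carries."""

    has_aa: bool = False
    has_cadd: bool = False
    has_header: bool = False

    def n_fields(self, n_pops: int) -> int:
        return 4 + int(self.has_aa) + int(self.has_cadd) + n_pops


def _parse_location(token: str) -> Optional[Tuple[str, int]]:
    """Parse ``chrom:start`` or ``chrom:start-end`` (SNPs only: start == end)."""
    chrom, sep, rest = token.rpartition(":")
    if not sep or not chrom:
        return None
    start, sep, end = rest.partition("-")
    if sep and start != end:
        return None  # multi-base range: not a SNP location
    try:
        pos = int(start)
    except ValueError:
        return None
    if pos < 1:
        return None
    return chrom, pos


def _parse_optional_float(token: str) -> Optional[float]:
    if token in MISSING_FIELD_TOKENS:
        return None
    return float(token)


def parse_variant_table(
    path: Union[str, Path],
    panel: PopulationPanel,
    layout: TableLayout = TableLayout(),
    counters: Optional[Counter] = None,
) -> Iterator[VariantRecord]:
    """Stream validated :class:`VariantRecord` objects from a variant extract.

    Rows are yielded in file order.  Malformed rows are skipped and
    counted in ``counters`` (one key per reason code, plus ``rows_read``
    and ``rows_yielded``); the stream itself never raises on bad rows.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist (fatal: nothing to score).
    """
    if counters is None:
        counters = Counter()
    expected = layout.n_fields(panel.n)
    n_annot = int(layout.has_aa) + int(layout.has_cadd)
    with open(path, "rt", encoding="utf-8") as handle:
        if layout.has_header:
            next(handle, None)
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            counters["rows_read"] += 1
            fields = line.split("\t")
            if len(fields) != expected:
                counters[BAD_COLUMN_COUNT] += 1
                continue
            loc = _parse_location(fields[0])
            if loc is None:
                counters[BAD_LOCATION] += 1
                continue
            chrom, pos = loc
            ref, alt = fields[2].upper(), fields[3].upper()
            if ref == alt or ref not in VALID_ALLELES or alt not in VALID_ALLELES:
                counters[NOT_SNP] += 1
                continue
            aa: Optional[str] = None
            cadd: Optional[float] = None
            cursor = 4
            if layout.has_aa:
                token = fields[cursor]
                aa = None if token in MISSING_FIELD_TOKENS else token
                cursor += 1
            if layout.has_cadd:
                try:
                    cadd = _parse_optional_float(fields[cursor])
                except ValueError:
                    counters[BAD_CADD] += 1
                    continue
                if cadd is not None and cadd < 0:
                    counters[BAD_CADD] += 1
                    continue
                cursor += 1
            try:
                af = tuple(float(tok) for tok in fields[cursor:])
            except ValueError:
                counters[AF_UNPARSABLE] += 1
                continue
            if any(f < 0.0 or f > 1.0 for f in af):
                counters[AF_OUT_OF_RANGE] += 1
                continue
            counters["rows_yielded"] += 1
            yield VariantRecord(
                chrom=chrom, pos=pos, id=fields[1], ref=ref, alt=alt,
                af_alt=af, aa=aa, cadd_phred=cadd,
            )


def write_variant_table(
    records: Iterable[VariantRecord],
    handle: TextIO,
    layout: TableLayout = TableLayout(),
) -> int:
    """Write records back to the variant-extract dialect; returns row count.

    Inverse of :func:`parse_variant_table` for round-trip checks and
    fixture generation.  Frequencies are written with full repr precision
    so a re-parse reproduces the records exactly.
    """
    count = 0
    for rec in records:
        fields = [f"{rec.chrom}:{rec.pos}", rec.id, rec.ref, rec.alt]
        if layout.has_aa:
            fields.append(rec.aa if rec.aa is not None else ".")
        if layout.has_cadd:
            fields.append(repr(rec.cadd_phred) if rec.cadd_phred is not None else ".")
        fields.extend(repr(f) for f in rec.af_alt)
        handle.write("\t".join(fields) + "\n")
        count += 1
    return count


def parse_vep_annotation(
    path: Union[str, Path],
    counters: Optional[Counter] = None,
) -> Dict[str, AnnotationRecord]:
    """Load a VEP-style tabular annotation file into a location-keyed mapping.

    The file must have a header row; the first column is ``Location`` and
    columns named ``AA`` and/or ``CADD_PHRED`` (case-insensitive) supply
    the annotations.  Range-form locations ``c:s-e`` are accepted only
    when ``s == e`` (single-base, i.e. SNPs) and normalize to ``c:s``.
    Duplicate keys keep the first occurrence (deterministic on
    concatenated VEP outputs); later ones are counted as duplicates.
    """
    if counters is None:
        counters = Counter()
    mapping: Dict[str, AnnotationRecord] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        if not header:
            return mapping
        columns = [c.strip().lstrip("#").upper() for c in header.split("\t")]
        try:
            aa_idx: Optional[int] = columns.index("AA")
        except ValueError:
            aa_idx = None
        try:
            cadd_idx: Optional[int] = columns.index("CADD_PHRED")
        except ValueError:
            cadd_idx = None
        if aa_idx is None and cadd_idx is None:
            raise ValueError(
                f"annotation file {path} has neither an AA nor a CADD_PHRED "
                f"column (header: {header!r})"
            )
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            counters["ann_rows_read"] += 1
            fields = line.split("\t")
            loc = _parse_location(fields[0])
            if loc is None:
                counters["ann_" + BAD_LOCATION] += 1
                continue
            key = f"{loc[0]}:{loc[1]}"
            if key in mapping:
                counters["ann_duplicate_key"] += 1
                continue
            aa = None
            if aa_idx is not None and aa_idx < len(fields):
                token = fields[aa_idx]
                aa = None if token in MISSING_FIELD_TOKENS else token
            cadd = None
            if cadd_idx is not None and cadd_idx < len(fields):
                try:
                    cadd = _parse_optional_float(fields[cadd_idx])
                except ValueError:
                    counters["ann_" + BAD_CADD] += 1
                    continue
                if cadd is not None and cadd < 0:
                    counters["ann_" + BAD_CADD] += 1
                    continue
            mapping[key] = AnnotationRecord(location_key=key, aa=aa, cadd_phred=cadd)
    return mapping


def merge_annotations(
    variants: Iterable[VariantRecord],
    ann: Dict[str, AnnotationRecord],
) -> Iterator[VariantRecord]:
    """Fill missing AA / CADD_PHRED fields from the annotation mapping.

    Fields already present in the variant table take precedence and are
    never overwritten; the merge is therefore idempotent.  Variants with
    no matching key pass through unchanged — downstream filter policy
    decides their fate.
    """
    for rec in variants:
        if rec.aa is not None and rec.cadd_phred is not None:
            yield rec
            continue
        hit = ann.get(rec.location_key)
        if hit is None:
            yield rec
            continue
        updates = {}
        if rec.aa is None and hit.aa is not None:
            updates["aa"] = hit.aa
        if rec.cadd_phred is None and hit.cadd_phred is not None:
            updates["cadd_phred"] = hit.cadd_phred
        yield replace(rec, **updates) if updates else rec
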