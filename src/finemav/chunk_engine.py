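"""Streaming pipeline: chunked scoring with bounded working memory.

The variant extract is read as a stream and processed in fixed-size
chunks (default 200,000 lines), so working memory scales with the chunk
size rather than the input size.  Each chunk's score rows are written to
an implementation-private intermediate file; on success the chunks are
concatenated into the final score TSV, the per-population bigWig tracks
are built from it, the log is written, and the intermediates are
deleted.  On any failure, partial outputs are removed (abort-and-clean;
there is no resume).

The annotation mapping, by contrast, is loaded once and held for random
access across chunks — only the variant table is chunked.  A configurable
entry budget guards against annotation files too large to hold; beyond
it the pipeline aborts and advises pre-joining the inputs upstream.
"""

from __future__ import annotations

import datetime
import shutil
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, TypeVar, Union

from finemav import core
from finemav.core import PolarizedSite, Rejection
from finemav.variant_table_io import (
    PopulationPanel,
    TableLayout,
    VariantRecord,
    merge_annotations,
    parse_variant_table,
    parse_vep_annotation,
)
from finemav.writers import (
    ScoreRow,
    format_score_row,
    read_chrom_sizes,
    score_header,
    write_bigwig,
    write_log,
)

__all__ = ["RunConfig", "RunSummary", "iterate_chunks", "run_pipeline", "score_record"]

T = TypeVar("T")

DEFAULT_CHUNK_SIZE = 200_000

#: Reason codes produced at the row-parsing stage (before polarization).
PARSE_REASONS = (
    "BAD_COLUMN_COUNT",
    "BAD_LOCATION",
    "NOT_SNP",
    "AF_OUT_OF_RANGE",
    "AF_UNPARSABLE",
    "BAD_CADD",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; immutable once constructed."""

    panel: PopulationPanel
    variants_path: Union[str, Path]
    chrom_sizes_path: Union[str, Path]
    out_prefix: Union[str, Path]
    annotations_path: Optional[Union[str, Path]] = None
    x: Optional[float] = None  # None -> default_penalty(panel.n)
    chunk_size: int = DEFAULT_CHUNK_SIZE
    layout: TableLayout = TableLayout()
    strict_ancestral: bool = False
    max_annotation_entries: int = 50_000_000
    seed: Optional[int] = None  # fixture generation only; unused by the run

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError(f"chunk_size must be >= 1, got {self.chunk_size}")
        if self.x is not None and self.x <= 1:
            raise ValueError(f"penalty parameter x must exceed 1, got {self.x}")

    @property
    def penalty(self) -> float:
        return self.x if self.x is not None else core.default_penalty(self.panel.n)

    @property
    def scores_path(self) -> Path:
        return Path(f"{self.out_prefix}.scores.tsv")

    @property
    def log_path(self) -> Path:
        return Path(f"{self.out_prefix}.log")

    def bigwig_path(self, pop_name: str) -> Path:
        return Path(f"{self.out_prefix}.{pop_name}.bw")


@dataclass
class RunSummary:
    """Counters for one run; rows_read = sites_scored + sum(rejected)."""

    rows_read: int = 0
    sites_scored: int = 0
    rejected: Dict[str, int] = field(default_factory=dict)
    chunks_processed: int = 0
    started_utc: str = ""
    finished_utc: str = ""


def iterate_chunks(records: Iterable[T], chunk_size: int) -> Iterator[List[T]]:
    """Partition a stream into consecutive blocks of ``chunk_size`` records.

    The concatenation of the blocks equals the input exactly; every block
    except possibly the last has exactly ``chunk_size`` records.  Empty
    input yields no blocks.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    block: List[T] = []
    for record in records:
        block.append(record)
        if len(block) == chunk_size:
            yield block
            block = []
    if block:
        yield block


def score_record(
    rec: VariantRecord,
    x: float,
    *,
    strict_ancestral: bool = False,
) -> Union[ScoreRow, Rejection]:
    """Polarize and score a single annotated variant record."""
    polarized = core.polarize(
        rec.ref, rec.alt, rec.aa, rec.af_alt, strict_ancestral=strict_ancestral
    )
    if isinstance(polarized, Rejection):
        return polarized
    derived, daf = polarized
    site = PolarizedSite(
        chrom=rec.chrom, pos=rec.pos, id=rec.id, ref=rec.ref, alt=rec.alt,
        aa=rec.aa, derived_allele=derived, daf=daf, cadd_phred=rec.cadd_phred,
    )
    scores = core.compute_scores(site, x)
    if isinstance(scores, Rejection):
        return scores
    return ScoreRow(
        chrom=rec.chrom, pos=rec.pos, id=rec.id, ref=rec.ref, alt=rec.alt,
        aa=rec.aa, derived_allele=derived, cadd_phred=rec.cadd_phred,
        daf=daf, dap=scores.dap, finemav=scores.finemav,
    )


def _iter_score_rows(path: Path, n_pops: int) -> Iterator[ScoreRow]:
    """Re-parse the final score TSV (streaming) for bigWig emission."""
    with open(path, "rt", encoding="utf-8") as handle:
        next(handle)  # header
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            daf = tuple(float(f) for f in fields[8:8 + n_pops])
            finemav = tuple(float(f) for f in fields[9 + n_pops:9 + 2 * n_pops])
            yield ScoreRow(
                chrom=fields[0], pos=int(fields[1]), id=fields[2],
                ref=fields[3], alt=fields[4], aa=fields[5],
                derived_allele=fields[6], cadd_phred=float(fields[7]),
                daf=daf, dap=float(fields[8 + n_pops]), finemav=finemav,
            )


def _utcnow() -> str:
    return datetime.datetime.now(datetime.timezone.utc).strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )


def run_pipeline(config: RunConfig) -> RunSummary:
    """Run the full scoring pipeline; returns the counter summary.

    Side effects: writes ``<out_prefix>.scores.tsv``, one
    ``<out_prefix>.<population>.bw`` per population, and
    ``<out_prefix>.log``.  Intermediate per-chunk files live under
    ``<out_prefix>.chunks/`` and are removed on success; on failure all
    partial outputs are removed before the exception propagates.
    """
    summary = RunSummary(started_utc=_utcnow())
    x = config.penalty
    panel = config.panel

    chrom_sizes = read_chrom_sizes(config.chrom_sizes_path)
    if not Path(config.variants_path).exists():
        raise FileNotFoundError(f"variant table not found: {config.variants_path}")

    out_parent = Path(str(config.out_prefix)).parent
    if out_parent and not out_parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out_parent}")

    annotation = {}
    ann_counters: Counter = Counter()
    if config.annotations_path is not None:
        annotation = parse_vep_annotation(config.annotations_path, ann_counters)
        if len(annotation) > config.max_annotation_entries:
            raise RuntimeError(
                f"annotation file holds {len(annotation)} entries, above the "
                f"budget of {config.max_annotation_entries}; pre-join the "
                "annotations into the variant table instead"
            )

    chunk_dir = Path(f"{config.out_prefix}.chunks")
    produced: List[Path] = [config.scores_path]
    try:
        chunk_dir.mkdir(parents=True, exist_ok=True)
        parse_counters: Counter = Counter()
        records: Iterable[VariantRecord] = parse_variant_table(
            config.variants_path, panel, config.layout, parse_counters
        )
        if annotation:
            records = merge_annotations(records, annotation)

        score_rejections: Counter = Counter()
        chunk_paths: List[Path] = []
        for block in iterate_chunks(records, config.chunk_size):
            chunk_path = chunk_dir / f"chunk_{len(chunk_paths):06d}.tsv"
            with open(chunk_path, "wt", encoding="utf-8") as handle:
                for rec in block:
                    result = score_record(
                        rec, x, strict_ancestral=config.strict_ancestral
                    )
                    if isinstance(result, Rejection):
                        score_rejections[result.reason] += 1
                        continue
                    handle.write(format_score_row(result) + "\n")
                    summary.sites_scored += 1
            chunk_paths.append(chunk_path)
            summary.chunks_processed += 1

        # Merge chunk outputs into the final table (pure concatenation:
        # rows were formatted identically regardless of chunking).
        with open(config.scores_path, "wt", encoding="utf-8") as out:
            out.write(score_header(panel.names) + "\n")
            for chunk_path in chunk_paths:
                with open(chunk_path, "rt", encoding="utf-8") as part:
                    shutil.copyfileobj(part, out)

        for i, name in enumerate(panel.names):
            bw_path = config.bigwig_path(name)
            produced.append(bw_path)
            write_bigwig(
                _iter_score_rows(config.scores_path, panel.n),
                i, chrom_sizes, bw_path,
            )

        summary.rows_read = parse_counters["rows_read"]
        for reason in PARSE_REASONS:
            if parse_counters[reason]:
                summary.rejected[reason] = parse_counters[reason]
        for reason, count in score_rejections.items():
            summary.rejected[reason] = summary.rejected.get(reason, 0) + count
        summary.finished_utc = _utcnow()

        try:
            write_log(summary, config, config.log_path)
        except OSError:
            pass  # scores are already on disk; a missing log is non-fatal
    except BaseException:
        for path in produced:
            Path(path).unlink(missing_ok=True)
        shutil.rmtree(chunk_dir, ignore_errors=True)
        raise
    shutil.rmtree(chunk_dir, ignore_errors=True)
    return summary
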