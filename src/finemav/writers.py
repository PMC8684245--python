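"""Output artifacts: score TSV, per-population bigWig tracks, run log.

The TSV is the precision-bearing artifact (reals at 6 significant
digits); bigWig stores float32 per the format, so round-trips through a
track are exact only to ~1e-7 relative.  Each SNP occupies the single
base ``[pos-1, pos)`` in 0-based half-open bigWig coordinates — the only
lossless interval representation for per-SNP scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import pyBigWig

__all__ = [
    "ScoreRow",
    "format_real",
    "score_header",
    "write_scores_tsv",
    "read_chrom_sizes",
    "write_bigwig",
    "write_log",
]


@dataclass(frozen=True)
class ScoreRow:
    """One scored site: identity, intermediates, and the score vector."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    aa: str
    derived_allele: str
    cadd_phred: float
    daf: Tuple[float, ...]
    dap: float
    finemav: Tuple[float, ...]


def format_real(value: float) -> str:
    """Render a real with 6 significant digits, without exponent padding."""
    return f"{value:.6g}"


def score_header(pop_names: Sequence[str]) -> str:
    """TSV header: 9 fixed columns plus DAF and FineMAV per population."""
    cols = ["CHROM", "POS", "ID", "REF", "ALT", "AA", "DERIVED", "CADD_PHRED"]
    cols += [f"DAF_{name}" for name in pop_names]
    cols.append("DAP")
    cols += [f"FINEMAV_{name}" for name in pop_names]
    return "\t".join(cols)


def format_score_row(row: ScoreRow) -> str:
    fields = [
        row.chrom, str(row.pos), row.id, row.ref, row.alt, row.aa,
        row.derived_allele, format_real(row.cadd_phred),
    ]
    fields += [format_real(d) for d in row.daf]
    fields.append(format_real(row.dap))
    fields += [format_real(s) for s in row.finemav]
    return "\t".join(fields)


def write_scores_tsv(
    rows: Iterable[ScoreRow],
    path: Union[str, Path],
    pop_names: Sequence[str],
) -> int:
    """Write the score table; returns the number of site rows written."""
    count = 0
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write(score_header(pop_names) + "\n")
        for row in rows:
            handle.write(format_score_row(row) + "\n")
            count += 1
    return count


def read_chrom_sizes(path: Union[str, Path]) -> Dict[str, int]:
    """Read a two-column (name, length) chromosome-sizes TSV.

    The same format consumed by standard bigWig toolchains
    (``bedGraphToBigWig``, etc.).  Order is preserved: it defines the
    chromosome order of the emitted bigWig headers.
    """
    sizes: Dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed chromosome-sizes line: {line!r}")
            name, length = fields[0], int(fields[1])
            if length < 1:
                raise ValueError(f"non-positive chromosome length for {name}")
            if name in sizes:
                raise ValueError(f"duplicate chromosome in sizes file: {name}")
            sizes[name] = length
    if not sizes:
        raise ValueError(f"chromosome-sizes file {path} is empty")
    return sizes


def write_bigwig(
    rows: Iterable[ScoreRow],
    population_index: int,
    chrom_sizes: Dict[str, int],
    path: Union[str, Path],
) -> int:
    """Write one population's scores as a bigWig track; returns interval count.

    Each site contributes the value ``finemav[population_index]`` on the
    single-base interval ``[pos-1, pos)``.  Input rows may arrive in any
    order; intervals are sorted per chromosome internally (the format
    requires it) without touching the caller's ordering.  Chromosomes
    appear in chromosome-sizes file order.

    Raises
    ------
    ValueError
        If a row's chromosome is absent from ``chrom_sizes``, its
        position exceeds the chromosome length, or two rows share a
        coordinate (overlapping single-base values are ill-defined in
        bigWig and signal an upstream bug in a biallelic-SNP table).
    """
    per_chrom: Dict[str, List[Tuple[int, float]]] = {}
    for row in rows:
        size = chrom_sizes.get(row.chrom)
        if size is None:
            raise ValueError(
                f"chromosome {row.chrom!r} is not in the chromosome-sizes file"
            )
        if row.pos > size:
            raise ValueError(
                f"position {row.chrom}:{row.pos} exceeds chromosome length {size}"
            )
        per_chrom.setdefault(row.chrom, []).append(
            (row.pos - 1, row.finemav[population_index])
        )

    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader([(name, length) for name, length in chrom_sizes.items()])
        count = 0
        for name in chrom_sizes:
            entries = per_chrom.get(name)
            if not entries:
                continue
            entries.sort(key=lambda e: e[0])
            for prev, cur in zip(entries, entries[1:]):
                if prev[0] == cur[0]:
                    raise ValueError(
                        f"duplicate coordinate {name}:{cur[0] + 1} in score "
                        "stream; cannot emit overlapping bigWig values"
                    )
            starts = [start for start, _ in entries]
            bw.addEntries(
                [name] * len(entries),
                starts,
                ends=[start + 1 for start in starts],
                values=[value for _, value in entries],
            )
            count += len(entries)
    finally:
        bw.close()
    return count


def write_log(
    summary: "RunSummary",
    config: "RunConfig",
    path: Union[str, Path],
) -> None:
    """Write the run log: config echo, counters, timestamps.

    Machine-parseable ``key: value`` lines.  Log failure is non-fatal at
    the call site (the scores are already on disk by the time the log is
    written); this function itself just raises on I/O error.
    """
    lines = [
        "# FineMAV run log",
        f"started_utc: {summary.started_utc}",
        f"finished_utc: {summary.finished_utc}",
        f"populations: {','.join(config.panel.names)}",
        f"n_populations: {config.panel.n}",
        f"penalty_x: {format_real(config.penalty)}",
        f"chunk_size: {config.chunk_size}",
        f"strict_ancestral: {config.strict_ancestral}",
        f"variants_path: {config.variants_path}",
        f"annotations_path: {config.annotations_path or '-'}",
        f"chrom_sizes_path: {config.chrom_sizes_path}",
        f"out_prefix: {config.out_prefix}",
        f"chunks_processed: {summary.chunks_processed}",
        f"rows_read: {summary.rows_read}",
        f"sites_scored: {summary.sites_scored}",
    ]
    for reason in sorted(summary.rejected):
        lines.append(f"rejected_{reason}: {summary.rejected[reason]}")
    lines.append(f"rejected_total: {sum(summary.rejected.values())}")
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")
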