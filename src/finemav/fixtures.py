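"""Synthetic, schema-conformant inputs with known ground truth.

The generator targets schema and statistic coverage, not biological
realism: no linkage, demography or selection sweeps are simulated.  It
emits a variant extract, a VEP-style annotation table, a chromosome-sizes
file and a truth table holding, for every site, either the oracle-computed
DAP and score vector or the expected rejection reason.  Everything is
deterministic given the seed, so two runs of the same spec are
byte-identical.

The oracle in this module is a deliberately naive, scalar-loop
re-implementation of polarization and scoring that shares no code with
:mod:`finemav.core`; its independence is what makes the equivalence
tests meaningful.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from finemav.variant_table_io import PopulationPanel

__all__ = ["FixtureSpec", "FixturePaths", "generate_fixture", "oracle_score"]

_BASES = "ACGT"
CHROM_LENGTH = 1_000_000


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    Fractions select site classes; they must sum to at most 1 and the
    remainder becomes clean shared-polymorphism sites (every population
    polymorphic for the derived allele).  Defect fractions are realised
    as exact counts (``int(fraction * n_sites)``) so truth-table
    bookkeeping is integral.
    """

    n_sites: int
    panel: PopulationPanel
    seed: int = 0
    frac_specific: float = 0.2  # derived allele confined to one population
    frac_aa_missing: float = 0.0
    frac_aa_mismatch: float = 0.0
    frac_cadd_missing: float = 0.0
    frac_malformed_af: float = 0.0
    cadd_max: float = 40.0  # CADD_PHRED ~ Uniform[0, cadd_max]
    chroms: Tuple[str, ...] = ("1", "2", "3")

    def __post_init__(self) -> None:
        total = (
            self.frac_specific + self.frac_aa_missing + self.frac_aa_mismatch
            + self.frac_cadd_missing + self.frac_malformed_af
        )
        if total > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {total} > 1")
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")


@dataclass(frozen=True)
class FixturePaths:
    variants: Path
    annotations: Path
    chrom_sizes: Path
    truth: Path


def oracle_score(
    ref: str,
    alt: str,
    aa: Optional[str],
    af_alt: Sequence[float],
    cadd_phred: Optional[float],
    x: float,
    *,
    strict_ancestral: bool = False,
) -> Union[Tuple[float, List[float]], str]:
    """Brute-force per-site scorer used only as a test oracle.

    Returns ``(dap, finemav_vector)`` or a rejection reason string.
    Scalar loops throughout; intentionally independent of finemav.core.
    """
    if aa is None or aa in ("", ".", "-", "N", "n"):
        return "AA_MISSING"
    if strict_ancestral and aa != aa.upper():
        return "AA_LOW_CONFIDENCE"
    if aa.upper() == ref.upper():
        daf = [float(f) for f in af_alt]
    elif aa.upper() == alt.upper():
        daf = [1.0 - float(f) for f in af_alt]
    else:
        return "AA_MISMATCH"
    if cadd_phred is None:
        return "CADD_MISSING"

    d_n = 0.0
    for d in daf:
        d_n = d_n + d
    if d_n == 0.0:
        dap = 0.0
    else:
        dap = 0.0
        for d in daf:
            dap = dap + math.pow(d / d_n, x)
    scores = []
    for d in daf:
        scores.append(dap * d * cadd_phred)
    return dap, scores


def _draw_site_class(spec: FixtureSpec, rng: random.Random) -> List[str]:
    """Assign each site index a class label, with exact defect counts."""
    labels = []
    for name, frac in (
        ("specific", spec.frac_specific),
        ("AA_MISSING", spec.frac_aa_missing),
        ("AA_MISMATCH", spec.frac_aa_mismatch),
        ("CADD_MISSING", spec.frac_cadd_missing),
        ("MALFORMED_AF", spec.frac_malformed_af),
    ):
        labels.extend([name] * int(frac * spec.n_sites))
    labels.extend(["shared"] * (spec.n_sites - len(labels)))
    rng.shuffle(labels)
    return labels


def generate_fixture(
    spec: FixtureSpec,
    out_dir: Union[str, Path],
    x: Optional[float] = None,
) -> FixturePaths:
    """Write the four fixture files into ``out_dir`` and return their paths.

    The variant extract carries no AA/CADD columns (plain
    ``CHROM:POS ID REF ALT AF..`` layout); the annotation table supplies
    AA and CADD_PHRED, except for sites drawn into a defect class.  The
    truth table records the oracle's verdict for every site under the
    penalty ``x`` (default: the recommended value for the panel size).
    """
    from finemav.core import default_penalty  # local import avoids cycle

    if x is None:
        x = default_penalty(spec.panel.n)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = FixturePaths(
        variants=out_dir / "variants.tsv",
        annotations=out_dir / "annotations.tsv",
        chrom_sizes=out_dir / "chrom.sizes",
        truth=out_dir / "truth.tsv",
    )

    rng = random.Random(spec.seed)
    labels = _draw_site_class(spec, rng)
    n = spec.panel.n

    next_pos = {c: 0 for c in spec.chroms}
    with open(paths.variants, "wt", encoding="utf-8") as var_out, \
            open(paths.annotations, "wt", encoding="utf-8") as ann_out, \
            open(paths.truth, "wt", encoding="utf-8") as truth_out:
        ann_out.write("Location\tAA\tCADD_PHRED\n")
        truth_out.write(
            "LOCATION\tID\tEXPECTED\tDAP\t"
            + "\t".join(f"FINEMAV_{p}" for p in spec.panel.names) + "\n"
        )
        for i, label in enumerate(labels):
            chrom = spec.chroms[i % len(spec.chroms)]
            next_pos[chrom] += rng.randint(1, 50)
            pos = next_pos[chrom]
            ref, alt = rng.sample(_BASES, 2)
            cadd: Optional[float] = rng.uniform(0.0, spec.cadd_max)
            aa: Optional[str] = ref if rng.random() < 0.5 else alt

            if label == "specific":
                # Exactly one population carries the derived allele.
                carrier = rng.randrange(n)
                daf = [0.0] * n
                daf[carrier] = rng.uniform(0.05, 1.0)
            else:
                daf = [rng.uniform(0.0, 1.0) for _ in range(n)]
            af_alt = daf if aa == ref else [1.0 - d for d in daf]

            if label == "AA_MISSING":
                aa = None
            elif label == "AA_MISMATCH":
                aa = next(b for b in _BASES if b not in (ref, alt))
            elif label == "CADD_MISSING":
                cadd = None

            location = f"{chrom}:{pos}"
            af_fields = [repr(f) for f in af_alt]
            if label == "MALFORMED_AF":
                af_fields[rng.randrange(n)] = "1.5"
            var_out.write(
                "\t".join([location, f"site{i}", ref, alt] + af_fields) + "\n"
            )
            ann_out.write(
                "\t".join([
                    location,
                    aa if aa is not None else ".",
                    repr(cadd) if cadd is not None else ".",
                ]) + "\n"
            )

            if label == "MALFORMED_AF":
                truth_out.write(f"{location}\tsite{i}\tAF_OUT_OF_RANGE\t.\t"
                                + "\t".join(["."] * n) + "\n")
                continue
            verdict = oracle_score(ref, alt, aa, af_alt, cadd, x)
            if isinstance(verdict, str):
                truth_out.write(f"{location}\tsite{i}\t{verdict}\t.\t"
                                + "\t".join(["."] * n) + "\n")
            else:
                dap, scores = verdict
                truth_out.write(
                    f"{location}\tsite{i}\tSCORED\t{dap!r}\t"
                    + "\t".join(repr(s) for s in scores) + "\n"
                )

    with open(paths.chrom_sizes, "wt", encoding="utf-8") as sizes_out:
        for chrom in spec.chroms:
            sizes_out.write(f"{chrom}\t{CHROM_LENGTH}\n")

    return paths
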