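"""Core statistic: ancestral polarization, derived allele purity, FineMAV.

Pure computational module — no file I/O.  All functions operate on one
site at a time; vectorization across sites lives in the chunk engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

__all__ = [
    "PolarizedSite",
    "SiteScores",
    "Rejection",
    "default_penalty",
    "polarize",
    "compute_dap",
    "compute_scores",
    "VALID_ALLELES",
]

VALID_ALLELES = frozenset("ACGT")

#: Ancestral-allele tokens treated as "no call".
AA_MISSING_TOKENS = frozenset({"", ".", "-", "N", "n"})

#: Recommended minimal penalty parameter x per number of populations n.
#: Determined empirically in prior work; values rounded to two decimals.
PENALTY_DEFAULTS = {2: 4.96, 3: 3.50, 4: 2.98, 5: 2.71, 6: 2.53, 7: 2.41}


@dataclass(frozen=True)
class Rejection:
    """A site excluded from scoring, with a machine-readable reason code."""

    reason: str


# Reason codes used across the pipeline.
AA_MISSING = "AA_MISSING"
AA_MISMATCH = "AA_MISMATCH"
AA_LOW_CONFIDENCE = "AA_LOW_CONFIDENCE"
CADD_MISSING = "CADD_MISSING"


@dataclass(frozen=True)
class PolarizedSite:
    """A site after ancestral polarization: DAF vector plus annotation.

    ``daf[i]`` is the frequency of the derived allele (the allele that is
    not ancestral) in population ``i``.  Identity fields are carried
    through so writers can emit them alongside the scores.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    aa: str
    derived_allele: str
    daf: Tuple[float, ...]
    cadd_phred: Optional[float]


@dataclass(frozen=True)
class SiteScores:
    """DAP and the per-population FineMAV score vector for one site."""

    dap: float
    finemav: Tuple[float, ...]


def default_penalty(n: int) -> float:
    """Return the recommended minimal penalty parameter x for n populations.

    Defaults exist for 2 <= n <= 7.  For larger panels there is no
    published recommendation and the caller must supply x explicitly.

    Parameters
    ----------
    n : int
        Number of populations in the panel.

    Raises
    ------
    ValueError
        If ``n < 2``, or ``n > 7`` (no default available).
    """
    if n < 2:
        raise ValueError(f"at least 2 populations are required, got n={n}")
    try:
        return PENALTY_DEFAULTS[n]
    except KeyError:
        raise ValueError(
            f"no default penalty parameter for n={n} populations; defaults "
            "cover n=2..7 — supply x explicitly (e.g. --penalty)"
        ) from None


def polarize(
    ref: str,
    alt: str,
    aa: Optional[str],
    af_alt: Sequence[float],
    *,
    strict_ancestral: bool = False,
) -> Union[Tuple[str, Tuple[float, ...]], Rejection]:
    """Polarize alternate-allele frequencies into derived allele frequencies.

    If the ancestral allele equals REF, the derived allele is ALT and
    ``daf = af_alt``; if it equals ALT, the derived allele is REF and
    ``daf = 1 - af_alt``.  A lowercase ancestral call (low-confidence
    inference in the Ensembl ancestral-genome FASTA) is accepted by
    default and rejected when ``strict_ancestral`` is set.

    Returns
    -------
    (derived_allele, daf) on success, else a :class:`Rejection` with
    reason ``AA_MISSING``, ``AA_LOW_CONFIDENCE`` or ``AA_MISMATCH``.
    """
    if aa is None or aa in AA_MISSING_TOKENS:
        return Rejection(AA_MISSING)
    if strict_ancestral and not aa.isupper():
        return Rejection(AA_LOW_CONFIDENCE)
    aa_up = aa.upper()
    if aa_up == ref.upper():
        return alt, tuple(float(f) for f in af_alt)
    if aa_up == alt.upper():
        return ref, tuple(1.0 - float(f) for f in af_alt)
    return Rejection(AA_MISMATCH)


def compute_dap(daf: Sequence[float], x: float) -> float:
    """Derived allele purity: ``sum((d_i / d_N) ** x)`` with ``d_N = sum d_i``.

    Frequencies (not counts) feed the shares ``f_i = d_i / d_N`` so that
    unequal population sample sizes do not bias the statistic.  The
    exponent x > 1 penalizes sharing of the derived allele across
    populations: DAP is 1 when exactly one population carries it and
    reaches its minimum ``n ** (1 - x)`` when all shares are equal.

    A site where the derived allele is absent everywhere (``d_N == 0``)
    has no defined share vector; DAP is taken as 0 there, which keeps
    every downstream score at 0 without dropping the site.
    """
    if x <= 1:
        raise ValueError(f"penalty parameter x must exceed 1, got {x}")
    d_n = 0.0
    for d in daf:
        if d < 0.0 or d > 1.0:
            raise ValueError(f"derived allele frequency outside [0, 1]: {d}")
        d_n += d
    if d_n == 0.0:
        return 0.0
    return sum((d / d_n) ** x for d in daf)


def compute_scores(site: PolarizedSite, x: float) -> Union[SiteScores, Rejection]:
    """FineMAV score vector: ``dap * daf_i * cadd_phred`` per population.

    A site without a CADD_PHRED annotation cannot be scored and is
    rejected (``CADD_MISSING``) rather than scored as 0, which would
    conflate "unannotated" with "predicted benign".
    """
    if site.cadd_phred is None:
        return Rejection(CADD_MISSING)
    dap = compute_dap(site.daf, x)
    scale = dap * site.cadd_phred
    return SiteScores(dap=dap, finemav=tuple(scale * d for d in site.daf))
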