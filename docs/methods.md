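# Methods

## Model

FineMAV combines three per-site quantities into one score per
population. Sites are restricted to biallelic SNPs, the only variant
class for which an ancestral state can be assigned unambiguously from
primate alignments. Given the ancestral allele (AA), the alternate
allele frequencies `AF_i` from the VCF are polarized into derived allele
frequencies: `DAF_i = AF_i` when AA = REF (derived = ALT) and
`DAF_i = 1 − AF_i` when AA = ALT (derived = REF). With shares
`f_i = DAF_i / Σ_j DAF_j`, the derived allele purity is
`DAP = Σ_i f_i^x`, and the score for population `i` is
`FineMAV_i = DAP × DAF_i × CADD_PHRED`.

Shares are computed from frequencies, not allele counts, so that
populations of different sample size contribute on the same scale; a
raw-count mode is deliberately not offered. Because
`FineMAV_i / DAF_i = DAP × CADD_PHRED` is constant within a site, one
population's score determines every other population's score given the
DAF vector — the identity the acceptance tests exploit to check the
implementation against published candidate tables without access to the
underlying genotype data.

### Assumptions

- The ancestral-allele call is correct; misassignment flips the DAF
  vector (`d ↔ 1 − d`) and is not detectable downstream.
- AF values describe the same cohort split the user names in
  `--populations`, in the same column order.
- Autosomes and the X chromosome are treated identically (no haploid
  frequency adjustment).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `x` | sharing penalty exponent (dimensionless, > 1) | per-`n` recommended minimum: 4.96, 3.50, 2.98, 2.71, 2.53, 2.41 for n = 2…7 | empirically derived constants from prior work, taken as given; no default exists for n > 7, so `--penalty` becomes mandatory there. Larger user-supplied values sharpen the population-specificity requirement. |
| `chunk_size` | variant-table lines per processing chunk | 200,000 | trades peak memory against per-chunk overhead; results are invariant to it. |
| `strict_ancestral` | reject lowercase (low-confidence) AA calls | off | Ensembl ancestral FASTA encodes inference confidence by case; by default low-confidence calls are used, case-folded. |

## Filter policy and edge cases

- `d_N = 0` (derived allele absent everywhere): the share vector is
  undefined; DAP is set to 0, which forces every score to 0 while
  keeping the site in the output. Sites monomorphic-derived everywhere
  (`DAF_i = 1` for all i) are retained and take the minimum purity
  `n^(1−x)`.
- Missing CADD_PHRED excludes the site (`CADD_MISSING`) rather than
  scoring it 0: a zero would conflate "unannotated" with "predicted
  benign" and silently flatten browser tracks.
- AA missing (`.`, `-`, `N`, empty) or matching neither allele excludes
  the site (`AA_MISSING` / `AA_MISMATCH`).
- Malformed rows (wrong column count, unparsable or out-of-range AF,
  non-SNP alleles, bad coordinates) are rejected at parse time, each
  under its own reason code; `rows_read = sites_scored + Σ rejections`
  holds for every run and is asserted in tests.
- Annotation precedence: values present in the variant extract win over
  the VEP table (the merge only fills gaps and is idempotent). Duplicate
  annotation keys keep the first occurrence — deterministic on
  concatenated VEP outputs — and are counted. Multi-base `Location`
  ranges (`c:s-e`, s ≠ e) are skipped: they denote indels, outside the
  SNP-only contract.

## Streaming design

Only the variant table is chunked; the annotation table must support
random access across chunks and is held in memory once, behind a
configurable entry budget (default 5 × 10⁷) whose overflow aborts with
advice to pre-join the inputs. Each chunk's score rows are formatted
row-at-a-time and written to a private intermediate file; the final TSV
is the header plus the byte concatenation of the intermediates, which
makes chunk invariance exact by construction. bigWig tracks are then
built by re-streaming the final TSV once per population. On success the
intermediates are deleted; on any failure all partial outputs are
removed (abort-and-clean, no resume). Input order is preserved
end-to-end in the TSV; the bigWig writer sorts its own per-chromosome
interval buffer because the format requires sorted intervals, without
reordering the TSV.

Peak memory therefore scales with `chunk_size` (plus the annotation
map and, during bigWig emission, one (start, value) pair per site on
the densest chromosome); it does not grow with the number of chunks.
This is a structural property of the design rather than a measured
bound, and the test suite checks the structural contract (block sizes,
stream conservation, intermediates removed) rather than asserting
hardware-specific RSS numbers.

## Numerical choices

- The TSV is the precision-bearing artifact: reals are rendered with 6
  significant digits (`%.6g`). bigWig stores float32, so track↔TSV
  round-trips are compared at 1e−6 relative, and the measured worst-case
  disagreement is reported by the acceptance script.
- Duplicate coordinates on a chromosome are a fatal error at bigWig
  write time: overlapping single-base values are ill-defined in the
  format, and a biallelic-SNP table should never produce them, so this
  signals an upstream bug rather than something to paper over.
- `x ≤ 1` is rejected everywhere (it would reward rather than penalize
  sharing).
- SNP intervals are written as 0-based half-open `[pos−1, pos)`
  single-base intervals — the only lossless bigWig representation of a
  per-SNP value.

## Synthetic data generator

`finemav.fixtures` generates schema-conformant inputs with known ground
truth: per-population DAF drawn uniformly on [0, 1] (or confined to one
population for "specific" sites), CADD_PHRED uniform on [0, 40] (the
range where almost all observed phred-scaled CADD values live), 20%
population-specific sites by default, synthetic chromosomes of 1 Mb, and
exact counts of requested defect classes (missing AA, mismatched AA,
missing CADD, malformed AF). The truth table holds scores computed by a
deliberately naive scalar-loop oracle that shares no code with the
production path; their agreement (≤ ~1e−15 relative in practice, tested
at 1e−12 over 10,000 random sites) is what the equivalence tests mean.

The generator emulates table schemas and statistic edge cases only: no
linkage disequilibrium, demography or selection sweeps are simulated,
and DAF vectors are independent across populations. Passing tests
therefore validate the arithmetic, the I/O contracts and the filter
bookkeeping on realistic *shapes* of data — they say nothing about
power to detect selection in real cohorts, which depends on the
upstream cohort, filtering and annotation choices.

## Problem sizes

The test suite and acceptance script run at desk scale: fixtures of
1,000–5,000 sites for pipeline-level checks and 10,000 random sites for
oracle equivalence, with chunk sizes {1, 7, 64, 200,000} exercising the
streaming engine. These sizes were chosen to cover every code path
(multiple chunks, partial final chunks, all rejection classes, multiple
chromosomes) while keeping the whole suite in the seconds range; the
statistic itself is embarrassingly per-site, so behaviour does not
change with scale.

## Known limitations

- No VCF/gVCF parsing: the tool consumes the `bcftools query` extract,
  by design, and never computes AF from genotypes.
- Single process; no parallel chunk execution.
- The published recommended penalties stop at n = 7; beyond that the
  user must justify their own `x`.
- Scores carry no significance measure; ranking and thresholding (e.g.
  the 99th-percentile browser line computed by `finemav percentiles`)
  are descriptive.
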