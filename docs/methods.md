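# Methods

## Scope and model

`mirnaome` implements the comparative small-RNA workflow used in
two-condition plant miRNA studies with one sequencing library per
condition. The data model is a **signature table**: unique insert
sequences with per-library raw counts plus the two library totals. All
downstream statistics (TPM, fold changes, the z test) are functions of
this table, so the totals are recomputed after every filter.

## Read processing

Inserts are located by exact anchor matching: the last 7 nt of the 5'
adapter and, after it, the first 7 nt of the 3' adapter; the insert is the
substring strictly between the anchors (first occurrences, which makes
trimming deterministic). Reads missing either anchor, or with nothing
between them, are rejected with a reason code. Collapsed signatures are
kept when they are 18–30 nt, contain no ambiguous characters, and reach
count ≥ 3 in *at least one* library. The count filter is stated in two
slightly different ways in the tradition this pipeline follows ("below 3
in both libraries" removed, vs "more than 3 used"); we implement the
at-least-one-library reading and expose `min_count` so the stricter
interpretation is one flag away. Internally the alphabet is DNA; all
reports emit RNA (U), the miRBase convention.

## Classification

Sequential exclusion fixes category precedence: ncRNA classes
(rRNA/tRNA/snRNA/snoRNA, exact substring match, forward strand by default)
→ known miRNA → novel miRNA → coding sense → coding antisense → other.
The precedence between ncRNA and known miRNA is an interpretation (the
workflow removes ncRNA first); it is configurable only by running matchers
directly. Known-miRNA homology uses an ungapped sliding alignment over all
offsets; unaligned overhang positions count as mismatches, and assignment
requires distance ≤ 4 with ties broken by (distance, reference id) so the
result is stable under reference reordering. Coding matches are exact on
both strands; a signature matching both orientations is tallied in both
but carries sense as its primary category.

## Folding and novel-miRNA calls

The folding engine is a maximum-weight nested base-pairing dynamic program
(Watson–Crick pairs weight 1.0, G:U wobble weight 1.0 by default, minimum
hairpin loop 3 nt, no pseudoknots) with a deterministic traceback that
pairs the 5'-most base with its 3'-most admissible partner. It is *not* a
thermodynamic model: free energies are never reported, and the fold is
used only to test stem-loop criteria. Its exactness is guaranteed by an
enumeration oracle in the test suite (all nested structures, lengths ≤ 14).
The `duplex_pseudo_energy` diagnostic in the target module is likewise a
weighted pair count, not an energy.

Candidate precursors are windows around perfect transcript hits of
unclassified signatures, one per flank configuration (100/20, 20/100,
60/60 nt — chosen to bracket plant precursor geometries where the mature
sits near either end; not a published constant, configurable).
Structural criteria on the folded window: the mature's partners must lie
on one side (not spanning the terminal loop) in antiparallel order
(single stem), with ≤ `max_duplex_mm` = 4 unpaired mature positions,
asymmetric bulges ≤ `max_asym_bulge` = 2, and paired fraction ≥
`min_paired_frac` = 0.60. These encode the community (Jones-Rhoades /
Meyers-style) conventions; the exact thresholds are conventions, not
reproductions of any single published instantiation, and all are
configurable. Dinucleotide-shuffled precursors pass at well under 10%
(tested).

The miRNA\* span is derived from the fold: the partner region of the
mature minus its 2-nt 3' overhang, extended 2 nt at the star's 3' end
(canonical Dicer/DCL geometry); unpaired mature edges are compensated from
the outermost paired anchors, so a 1-nt duplex bulge shifts the star
length by 1. A candidate is **accepted** only when its star sequence is
itself present in the signature table (exact match by default; `star_mm`
relaxes it). Two refinements matter in practice:

- *Dominant arm*: a structurally valid candidate whose duplex partner
  accumulates more reads than itself is the partner's star, not a novel
  miRNA (status `minor_arm`). Without this every sequenced star would be
  re-called as a mature. Consequently acceptance is monotone in star
  evidence at the duplex level: adding star reads never un-calls the
  locus, though arm naming swaps if the star overtakes the mature.
- *One call per mature*: among a mature's windows the best-scoring valid
  precursor is kept; rejected candidates are reported with status
  `no_star` or `bad_structure` rather than dropped.

## Differential test

The two-library z statistic compares tag proportions against the pooled
proportion (see README for the formula); counts enter raw because the
binomial variance model requires counts, and TPM is used only for
reporting and fold changes. Degenerate inputs (both counts zero, pooled
proportion 0 or 1) return z = 0, p = 1 by convention. Significance is
p < 0.01 on the raw p value, mirroring single-library-per-condition
practice; Benjamini–Hochberg is available behind `bh=True` but off by
default. Reported TPMs and fold changes are rounded half-away-from-zero
to one decimal; full precision is kept internally. The test's type-I
error is verified by simulation (3 × 1000 null genes at 200 per million in
10⁶-read libraries; empirical rate within 3 Monte-Carlo SE of α).

## Target scoring

Sites are scored with an explicit miRU/psRNATarget-style penalty scheme —
match 0, G:U 0.5, mismatch 1, bulged base 2, doubled across miRNA
positions 2–13 from the 5' end — with at most one single-nucleotide bulge
on either strand, and reported at penalty ≤ 4.0 (the common plant
convention; configurable). For a bulged site base the doubling is governed
by the miRNA base 5' of the bulge. The scanner is exact: it equals an
exhaustive all-window oracle (tested on transcripts up to ~2 kb). No
claim is made that hit lists match any specific web service.

Hotspot statistics classify each predicted target gene by whether it
produces perfectly matching sRNAs in sense, antisense, or both
orientations, per library; tallies are emitted both inclusive of "both"
(the convention of the published summary table this mirrors) and
exclusive, to avoid ambiguity. `antisense_cognate_fraction` reports, per
library, the fraction of antisense-sRNA-bearing genes that also bear
sense sRNAs.

## Synthetic-study generator

The generator emulates the study design: two libraries whose background
signature lengths follow a configured 18–30 nt distribution with ~95% of
mass in 21–24 nt and a 24-nt mode (the plant siRNA peak); planted hairpin
miRNA genes embedded in transcripts, half "known" (present in the mature
catalogue) and half "novel" (withheld); per-gene abundances in reads per
million with a multiplicative condition effect (fold 1 marks null genes);
star arms sampled at `star_fraction` (default 0.15) of each gene's reads;
background fragments sampled uniformly over reference positions on both
strands; and 1% junk reads without adapters to exercise trimming
rejection.

Hairpins are built analytically, never by folding: the precursor is
`B + M + linker + revcomp(M[:-2]) + revcomp(B)` with a 22-nt random lower
stem B and an A/C-only linker (which cannot pair with itself), so the
maximum-weight structure is the planted stem and the terminal loop is the
mature's last 2 nt plus the linker. The star is
`revcomp(M[:-2]) + revcomp(B)[:2]` — the duplex partner with 2-nt 3'
overhangs on both strands. Ground truth therefore never depends on the
folding engine under test; a consistency test closes the loop by refolding
every planted precursor.

Default scale: 300 transcripts of 0.8–2.5 kb (~0.5 Mb) and 2 × 200k
reads. The reference size is a scaled-down stand-in for an EST
collection chosen to preserve the *sparse* background coverage regime of
real studies (reads ≪ reference positions); with a much smaller
reference, uniform background fragments tile every position so densely
that arbitrary substrings — including spurious "stars" — are sequenced by
coincidence, which real sRNA data do not exhibit. Calibration studies use
a counts-level shortcut (`simulate_tag_counts`, the same multinomial
sampling model with read construction skipped).

What the generator does **not** emulate: sequencing errors, positionally
biased degradation products, isomiR 5'/3' heterogeneity, locus-clustered
siRNA production, and genome-scale references. Passing recovery tests
therefore show the pipeline's logic is correct under the stated sampling
model, not that its thresholds are optimal for any particular real
dataset.

## Numerical and reproducibility choices

- Pair weights are multiples of 0.5, exactly representable in binary, so
  DP scores and penalty sums are exact; traceback ties are broken
  deterministically (5'-most base, 3'-most partner).
- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; fixed seed gives byte-identical FASTQ and output bundles.
  No timestamps are written to any output.
- The pipeline aborts atomically per stage with the stage name; partial
  bundles are not written.
- Problem sizes in the test suite (reduced 6-gene studies, 30k-read
  libraries with abundances scaled so star arms still reach the count
  filter) are the package's own choices for fast, deterministic recovery
  tests; the full default study is exercised once per session.

## Known limitations

- One library per condition: no replicate-aware dispersion modelling (a
  negative-binomial test would be the natural extension).
- The Nussinov-style fold can overpair long windows; specificity comes
  from the duplex-geometry criteria, not from thermodynamics. ViennaRNA
  can serve as an external cross-check but is deliberately not a
  dependency.
- Known-miRNA homology is ungapped; indel isomiRs of catalogue entries
  are matched only through the mismatch budget.
- Target prediction allows at most one bulge and no target-site gaps
  larger than 1 nt, which keeps the scanner exact but excludes rare
  multi-bulge plant sites.
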