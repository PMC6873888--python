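# Methods

`tssmotif` re-implements, as a tested pipeline over synthetic data, the
computational core of a bacterial dRNA-seq transcriptional-architecture
analysis: differential transcription start site (TSS) calling, TSS
classification and 5'UTR statistics, de novo promoter-motif discovery,
Shine-Dalgarno (SD) detection, PWM scanning of upstream regions across
genomes, and TSS-guided start-codon re-annotation.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and the TSV report tables (1-based) convert exactly once at the I/O
boundary; bedGraph is already 0-based half-open. Counts are stored densely
per contig/strand: bacterial genomes are small enough that sparse
structures would only add complexity.

## Differential TSS calling

dRNA-seq compares a library enriched for primary 5' ends (TAP+, 5'-PPP
converted to ligatable 5'-P) with a library of processed 5' ends (TAP-).
At a true TSS the TAP+ 5'-end read-start count exceeds the TAP- count;
elsewhere both follow the local background.

The test models the two counts at a position as independent Poisson
variables, so their difference follows a Skellam distribution. For each
candidate position we estimate null rates (lambda_plus, lambda_minus) as
10%-trimmed means of the counts in a 1000-nt window centred on the
position (the position itself excluded, windows truncated at contig ends),
scale the TAP- rate and count to the TAP+ scale by the ratio of total
library sizes, floor both rates at 1e-3 to avoid degenerate tests, and
compute the one-sided tail probability

    p = P(X - Y >= x_plus - round(x_minus * s)),   X~Poi(l+), Y~Poi(l-).

A position is called when its raw TAP+ count is at least the noise
threshold (default 10) and p <= 1e-3. Candidates on the same strand whose
positions chain together with gaps <= 5 nt (transitive closure) collapse
to the member with the largest TAP+ count, ties broken by the most
upstream position in transcription direction. All three thresholds are the
standard settings of this analysis type and are configurable.

Properties and limitations. The Skellam survival function is delegated to
scipy (verified against a truncated double-Poisson convolution oracle to
<1e-10; degenerate zero-rate cases are handled analytically because the
scipy implementation requires positive rates). Because the null rates are
local background estimates, a strongly *processed* site (equal high counts
in both libraries) can be called when its TAP+ draw stochastically exceeds
its TAP- draw by more than the background scale; with the default
synthetic settings roughly a quarter of processed sites are called. This
locality assumption is intrinsic to the test; detection of processing
sites as a separate class is out of scope. The trimmed mean keeps nearby
true TSSs from inflating the background. No multiple-testing correction is
applied, matching the fixed p-value threshold convention.

## TSS classification and 5'UTR statistics

A TSS is *primary* for a gene when it lies strictly upstream of the gene's
first base at a distance d with 1 <= d <= 250 nt (boundary inclusive);
*internal* when it falls inside a same-strand gene's interval; *antisense*
inside an opposite-strand gene; *orphan* otherwise. A TSS may carry
several labels with respect to different genes and may be primary for more
than one gene. A TSS coinciding with the start codon's first base is
internal by the interval rule (d starts at 1); the 5'UTR length of a
primary assignment is exactly d, so reported UTRs are >= 1.

UTR summaries report the lower median (deterministic for even n), the
fraction below 100 nt, and leaderless transcripts (5'UTR < 10 nt, strict).
The base-preference profile counts bases at positions -5..-1, +1..+5
relative to the TSS (+1 is the TSS base, no position 0), always read on
the transcribed strand, skipping TSSs within 5 nt of a contig edge.

## Motif discovery (ZOOPS EM)

Upstream windows (default 50 nt, ending at the base before the TSS, read
5'->3' on the transcribed strand, truncated at contig edges) are searched
with a zero-or-one-occurrence-per-sequence (ZOOPS) EM:

* Model: each sequence is emitted by a 0-order background (estimated from
  the input composition) except, with prior gamma (initial 0.8, updated
  each M-step, clipped to [1e-4, 1-1e-4]), one width-w window uniform over
  offsets and strands emitted by the motif's position probability matrix.
* E-step: posterior over {no site, site at each offset/strand} per
  sequence; M-step: Dirichlet-regularised PWM update (total pseudocount
  mass 1 per column, spread as the background, i.e. 0.25 per cell under a
  uniform background) and gamma update. The penalised observed-data log
  likelihood is non-decreasing across iterations and is recorded per
  iteration; convergence at relative change < 1e-6 or 200 iterations.
* Seeding: candidate start PWMs (consensus base probability 0.7) come
  from actual sequence windows. Candidates are ranked by the *excess* of
  their anchored k-mer's erasure-weighted count (exact plus discounted
  one-mismatch neighbours; k = min(w, 8), anchors at the window start,
  centre and end) over its 0-order background expectation — in a low-GC
  genome raw counts are dominated by background-typical AT-rich words,
  which score near zero under the excess statistic while planted motif
  instances are pure excess. The shortlist is topped up with random
  windows, then screened by a composition-discounted evidence score (the
  ZOOPS likelihood gain on the data minus the gain on one letter-shuffled
  copy) before short-EM evaluation picks the start that is run to
  convergence. Windows dominated by a single homopolymer run (longer than
  max(3, w/2)) are masked as potential sites throughout; without this the
  EM's global optimum on AT-rich sequences is a degenerate poly-A/T
  motif. After convergence the register is refined by retrying +-1/+-2
  column shifts.
* Width: a geometric ladder (4, 5, 6, 8, 10, 12, 15, 19, 24, 30, 38, 48)
  rather than every width 4..50 (runtime; the ladder covers the widths of
  the planted classes). The winning width per round maximises a
  permutation z-score (below). The winner is then width-optimised in both
  directions: it is refit once after widening by background-padded flanks
  (a ladder width that clips real flanking signal would otherwise leave
  fragments that resurface as separate motifs), and the stronger of the
  original and widened fits is trimmed to the contiguous column block
  maximising total information content minus 0.2 bits per column (maximum
  subarray) and refit at that width. Trimming guards against a single
  wide motif straddling two distinct signals, which would otherwise
  absorb and erase both in one round.
* Multiple motifs: after a motif is accepted, each window's positions are
  probabilistically erased in proportion to its site posterior, and the
  search repeats (up to n_motifs, stopping after 3 consecutive rejected
  rounds). Rejected rounds erase nothing, so a motif misjudged by one
  noisy significance draw can be retried. All randomness is drawn from
  per-(round, width) child generators of the user seed, so results are
  deterministic and one width's computation never perturbs another's.

Significance. The E-value of a motif is a permutation estimate: a
*standardized fit* (fixed seed count, capped iterations, no refinement) is
applied identically to the observed sequences and to letter-shuffled
copies (shuffling preserves each sequence's composition); a Gaussian tail
fitted to the null sample of the fit objective gives the p-value,
multiplied by the number of ladder widths tested. The Gaussian tail makes
E-values far below 1/N_shuffles representable (a perfect planted motif
sits hundreds of null standard deviations out); near the cutoff the
procedure is calibrated by construction because both arms run the same
fit. Motifs are reported when E <= 0.05 and at least 13 sequences are
assigned a site (posterior >= 0.5); both filters are configurable.
`n_sites` is the expected number of sequences with a site (sum of
posteriors); the assigned count is the integer filter quantity.

Shine-Dalgarno search runs the same machinery on the 30 nt upstream of
annotated start codons (n_motifs 10, max width 30), reporting the top
motif and, per gene with a forward-strand site, the spacing between the
match end and the start codon.

## PWM scanning and exact p-values

Log-odds matrices are stored in bits against a 0-order background,
floored at -30 bits for zero-probability cells and quantised to a 1e-3-bit
lattice. The null score distribution of a background sequence of motif
width is then computed exactly by dynamic programming over the integer
lattice, so reported p-values equal exhaustive enumeration of all 4^w
sequences scored with the same public matrix (the quantisation, not an
approximation on top of it, defines the score scale; the induced score
perturbation is at most w/2000 bits). P-values are monotone non-increasing
in the score and lie in (0, 1].

Upstream-region scanning mirrors the cross-genome occurrence analysis: up
to 300 nt upstream of each annotated gene, both strands, hit threshold
p <= 1e-4 (the scanned tool's default output threshold); a gene "has the
motif" when at least one hit passes. Occurrence rates are hits divided by
the number of annotated genes; relative occurrence divides each species'
rate by the reference's (undefined sentinel when the reference rate is
zero). Windows may overlap neighbouring genes by default; an optional flag
truncates them at the nearest flanking gene boundary.

## Start-codon re-annotation

For each gene with a primary TSS (the shortest-5'UTR TSS is the evidence
when there are several), the transcribed strand from the TSS to the
annotated stop codon is scanned for SD matches (PWM hits at p <= 1e-3 on
the mRNA strand only). A candidate start is an ATG/CTG/GTG/TTG codon
9-14 nt downstream of an SD match end, in frame with the annotated stop,
with an ORF of at least 30 codons and no internal stop. Candidates are
ranked by SD score, then spacing closest to 11 nt (the centre of the
conserved band), then ORF length, then position; the best candidate is
compared with the annotated start (status unchanged/proposed/conflict).
The ranking makes an inherently partly-manual procedure deterministic; the
30-codon floor avoids spurious short proposals.

## Synthetic data

The generator plants the architecture the analysis assumes and returns
the full ground truth. Per gene: strand (fair coin), body length
(log-normal, median ~300 codons, clipped to [60, 1000]), a start codon
drawn as ATG/GTG/TTG/CTG with weights 0.78/0.14/0.06/0.02, sense codons
with in-frame stops repaired, and a stop codon (TAA/TAG/TGA at
0.6/0.2/0.2). 5'UTRs are discretised log-normal with median 63 nt and
sigma 0.4, resampled into [10, 250]; an exact 2% of genes are leaderless
with UTR ~ U{1..9} (exact count, so the planted fraction is not itself a
random variable). The SD (consensus AGGAGG, identity 1.0 — the site is
described as highly conserved) is planted at a spacing drawn uniformly
from 9-14 nt where the UTR can contain it; leaderless genes therefore
carry no SD, matching their biology. The +1 base is 90% A/G (45/45).

The promoter catalog defaults to three classes planted at 85% per-position
identity: an extended -10 (TATGNTATAAT, ending 5 nt upstream of the TSS),
a -35/-10 pair (TTGACA-N17-TATAAT, fixed 17-nt spacer of random bases),
and a width-38 interspaced (A/T)G class whose consensus is the canonical
wild-type promoter core of that class (CTGGAGCAGG TTTTGTAGTT GCAGTAACTG
GTTCAATA), ending 6 nt upstream of the TSS. Genes are laid out left to
right with each gene reserving its own regulatory space (UTR + promoter
footprint + 10 nt) on its upstream side plus exponential intergenic slack
(mean 100 nt + 20), so genes never overlap and every planted element fits
its intergenic gap.

Counts: independent Poisson draws per position, strand and library —
background mean 1 (depth), replaced at planted TSSs by (strength,
strength x leakage) with strength 100 and leakage 1/enrichment_ratio
(enrichment 10; the study states no quantitative enrichment factor, so 10
is a documented free choice), and at processed sites (0.3 per gene
expected, strength 50) by one shared mean in both libraries. Optional
internal/antisense TSSs (0.05 per gene each) exercise the classifier.

What the generator does not emulate: read-level artefacts (sequencing
error, mapping bias, non-uniform fragmentation), operon structure and
shared promoters, correlated counts along a transcript, condition
dependence, and RNA secondary structure. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own model
assumptions, not performance on real libraries.

## Verification experiment sizes

The shipped checks use: Skellam accuracy over lambda in {0.1, 1, 5, 20}
and k in [-50, 50]; null calling calibration on a 100-kb empty genome and
recovery on a 200-gene genome; 1000 random gene/TSS configurations for the
classification oracle and strand-mirror property; 1000 genes for the UTR
summary; a width-12/85%-identity motif in 80 of 100 windows and the
three-class recovery on a 200-gene genome; 100 random PWMs of width <= 8
against exhaustive enumeration; three 300-gene genomes with planted
promoter fractions 1.0/0.5/0.05 for relative occurrence; and 200 genes
with +30-nt start shifts for re-annotation. The occurrence experiment uses
gene-specific windows (neighbour truncation, wider intergenic gaps of mean
350 nt) and the scanned genome's composition as PWM background: with
overlapping windows a neighbouring gene's planted promoter lands in an
unplanted gene's window often enough to mask the planted fraction, and the
remaining small positive offsets (~0.02-0.08) are the expected p<=1e-4
false-positive floor of two-strand ~260-nt windows.

## Known limitations

* The ZOOPS search is a local optimiser; which of several true motifs is
  found first, and at which ladder width, varies with the seed. The
  k-mer-ranked seeding, register refinement, width trimming and
  retry-on-rejection make the three-class recovery reliable at the shipped
  problem sizes but do not guarantee global optima.
* Permutation E-values rest on a Gaussian tail beyond the shuffle sample;
  extreme E-values are order-of-magnitude statements, not exact.
* The Skellam test inherits TSSAR-style locality: isolated strong
  processed sites can leak into the TSS list (see above).
* Relative occurrence compares genomes of the same composition model;
  across genomes with very different GC content the fixed PWM background
  would bias rates (the CLI scans each genome with the motif's stored
  background).
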