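# Methods

`cckit` analyses two complementary measurements of transcription-factor DNA
binding in *Saccharomyces cerevisiae*: transposon calling cards (in vivo)
and HT-SELEX (in vitro).  This note records the models, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Calling-card quantification

In a calling-card experiment the factor of interest (here Ste12, whose
pheromone response element has consensus TGAAACA) is fused to the piggyBac
transposase, which integrates a marked transposon at TTAA tetranucleotides
near where the factor is bound.  Insertion junctions are recovered by
inverse PCR and sequenced as read pairs:

* read 1: the 31 nt universal primer `CGTCAATTTTACGCAGACTATCTTTCTAGGG`
  followed by 39 nt of genomic flank;
* read 2: an 8 nt unique molecular identifier (UMI) in positions 1–8.

**Parsing** (`ccparse`) accepts up to 2 substitutions in the primer (no
indels; a 31-mer primer at desk scale does not need gapped matching),
requires a full 39 nt flank, and filters reads with mean phred < 20 or N
bases in flank or UMI — the quality rule is our own concrete choice where
the protocol says only "high quality".  Failures are statuses, not
exceptions, and status counts always sum to the number of input pairs.

**Mapping** is exact-match against an in-memory index of every genomic
39-mer on both strands.  Desk-scale genomes (≤ a few Mb) make this
deterministic and dependency-free; near-matches are deliberately reported
as `unmapped` rather than rescued.  The junction convention — the read-1
flank is the 39 bp 3′ of the TTAA on the event's strand — is an artifact
convention shared by the simulator and parser; the assay itself does not
pin down which side is sequenced, and nothing downstream depends on the
choice.

**UMI collapse** counts distinct UMI strings per (sample, chromosome,
position); exact string identity only.  A 1-mismatch network collapse is
deliberately not applied (UMI errors are not modelled by the generator and
the assay's published processing specifies none).  Collapse is idempotent:
duplicating every read changes nothing.

**Peak calling** replaces a general-purpose ChIP peak caller with a
transparent scan statistic suited to insertion data: 300 bp windows
(stepped by half a window) are scored by the Poisson upper-tail probability
of their UMI total, Benjamini–Hochberg correction runs across all tested
windows, and significant windows (q ≤ 0.05) merge into peaks.  The null
rate deserves care: insertions can only occur at TTAA sites, and TTAAs
cluster by chance, so a per-bp uniform rate over-calls peaks wherever TTAAs
are dense.  When TTAA positions are available the expected UMI count of a
window is therefore `total_UMIs × (TTAAs in window / TTAAs genome-wide)` —
uniform over integration sites, which is the actual null of the assay.  The
per-bp rate `total_UMIs / genome_size × window` remains available as a
fallback for data without a TTAA index and is the form checked against the
closed-form Poisson tail in the tests.

**Gene assignment** links an interval to a gene when its midpoint lies
within 1000 bp 5′ to 200 bp 3′ of the transcription start site (mirrored
for minus-strand genes).  The midpoint rule is our choice between
summit-based and any-overlap assignment.  Multi-gene assignment is
permitted (divergent promoters share upstream regions), so a UMI can be
counted for two genes by design.

**Gene matrices** hold raw distinct-UMI counts per gene × sample; the
normalised view is counts per million of the sample's total UMIs over all
sites (assigned or not), and the log view is log2(cpm + 1).  Replicate
agreement is the Pearson correlation of two samples on the log view.

## Differential binding

Per gene, the fraction of a sample's total UMIs assigned to the gene is
compared between variant and wild-type with a two-sided two-sample
proportion test: chi-square on the 2×2 table with Yates continuity
correction, replaced by Fisher's exact test whenever an expected cell is
below 5.  Sidedness and the exact-vs-asymptotic rule are our declared
choices; the test is symmetric in its arguments, and under a multinomial
null (200 genes, 10⁴ UMIs per sample) its empirical type-I error at
α = 0.05 sits near 0.04.  BH q-values are computed within each variant
across genes, and both raw p and q are reported so callers can threshold
on either.  Gene-set overlaps are plain Venn cardinalities over every
membership pattern.

## Motif analyses

* **7-mer enrichment**: regions (peaks or sites) are widened to 100 bp
  around their midpoint; 7-mers are counted on both strands and compared
  with genome-wide both-strand frequencies, with a pseudocount of 0.5 on
  observed and expected.  A 7-mer and its reverse complement stay separate
  rows.
* **Consensus distances**: distance from each region midpoint to the
  nearest exact consensus match centre (either strand), capped at 1 kb; the
  summary statistic is the fraction within 200 bp.
* **High-count windows**: insertions with distinct-UMI counts at or above
  the 85th percentile (linear interpolation) receive 300 bp windows, which
  are merged into disjoint intervals; the merged window count is the
  normaliser for motif-pair counts.
* **PWM scanning**: known motifs in MEME minimal format are scanned on both
  strands at every offset.  Scores are log2 odds against the
  strand-symmetrised genome base composition, discretised to centibits, and
  each score's p-value is computed *exactly* by dynamic programming over
  the PWM's null score distribution; hits require p ≤ 1e-4 and overlapping
  hit runs keep only their best position.  A small regulariser (1e-4) keeps
  zero-probability PWM cells finite.
* **Motif pairs**: per merged window, each unordered pair of distinct
  motifs present counts once; a motif hitting two distinct positions in one
  window counts once for its self-pair.  Differential pairs across samples
  with replicates are flagged by a two-part filter — log10(mean count) > 1
  and method-of-moments negative-binomial dispersion above a running-median
  dispersion-vs-mean trend — with a per-pair NB Wald test of the sample
  effect as the significance column.  The trend estimator is our choice;
  the filter concept ("more variable than expected at that mean") does not
  define one, and a running median is the simplest robust option.

## HT-SELEX

Pools of 36 nt random-region ligands ("36N") are selected by a purified
factor over five rounds.  `selex` counts k-mers (default k = 10) at every
offset of every ligand, single-strand because ligands are sequenced
stranded, and normalises a round's counts to the random input pool on a
common per-window scale with a symmetric pseudocount of 0.5:

    enrichment = ((out + ½) / total_out) / ((in + ½) / total_in)

The strongly bound set is every k-mer with enrichment ≥ mean + 3 SD
(population SD over all table rows).  If the SD is zero every row ties at
the threshold and all rows are returned with a warning.  Consensus
trajectories report the consensus 7-mer's enrichment per round against the
input pool.

## The synthetic-data generator

`simdata` emulates exactly the statistical structure the analyses assume:

* **Genome**: uniform i.i.d. bases with planted consensus instances at
  recorded coordinates.  No chromatin, nucleosome or base-composition
  structure is modelled, so passing tests certify the statistics, not
  robustness to genomic covariates.
* **Insertions**: a fraction `p_near` of events is factor-directed — a
  planted site is chosen uniformly, then a TTAA within `d_max = 200` bp
  with weight exp(−distance / 75 bp) — and the rest land uniformly over all
  TTAA sites.  The decay kernel reflects that real calling-card insertions
  pile up closest to the bound site rather than uniformly within reach; the
  75 bp scale is a fixed choice giving sub-window localisation.  By default
  only TTAAs with full 39 bp flank clearance are eligible, so every
  simulated event yields a sequenceable read pair.  The standard study
  scenario (200 kb, 40 genes, 12 bound genes, 5000 events, p_near = 0.8)
  plants each bound gene's motif 400 bp upstream of its TSS and guarantees
  a TTAA within 40 bp of the motif — a bound site with no reachable
  integration site would be undetectable by construction.
* **Reads**: exact primer + flank on read 1, UMI + random filler on read 2,
  constant phred 40.  UMIs are uniform over 4⁸ with collisions allowed
  (the real assay's collision floor).  Sequencing errors are not modelled.
* **SELEX**: ligand affinity is a Boltzmann weight exp(s · m) on the best
  consensus match fraction m (any offset, either strand).  Round r pools
  are i.i.d. samples from the exponentially tilted distribution
  ∝ exp(r·s·m) over uniform 36-mers, drawn by rejection sampling.  This
  models selection acting on the real library's effectively infinite
  diversity (~10¹² molecules): distinct surviving ligands share the
  consensus but not their flanks.  Resampling a 20 000-ligand pool
  round-over-round instead lets a few founder clones take over and
  spuriously enriches their private flank k-mers — an artifact of small
  simulated pools, not of the assay.  At s = 0 every pool is uniform.

## Numerical choices and degenerate inputs

* Enrichment pseudocount 0.5 throughout; PWM probability regulariser 1e-4;
  PWM score grid 0.01 bits.
* Peak p-values use the exact Poisson survival function; empty windows get
  p = 1 and enter the BH family.
* Percentiles use linear interpolation; sites tied at the threshold
  qualify.
* Empty event lists, empty region sets and zero-SD enrichment tables return
  empty/complete results rather than raising; zero totals, ragged pools,
  malformed MEME matrices and unpaired FASTQs raise with context.
* All generators are pure functions of their arguments including the seed.

## Problem sizes

The default test and acceptance workloads are sized for a single CPU: a
200 kb genome with 5000 insertions for the calling-card study, 10 000
multinomial replicates for test calibration, and 20 000-ligand SELEX pools
over five rounds, ten seeds.  These sizes give the binomial/Poisson
fluctuations quoted in the tests; scaling any of them up only tightens the
intervals.

## Known limitations

* Exact-match flank mapping cannot place reads carrying sequencing errors;
  on error-free synthetic reads this loses nothing, on real data it would
  undercount.
* The transposase-only control channel is not modelled; a
  control-subtraction hook is out of scope for the current peak caller.
* At selection strength 5 the simulated round-5 SELEX pool is a mixture of
  perfect- and near-consensus ligands, and 10-mers sharing only 5 consensus
  bases are genuinely ~20× enriched (they ride on full-match winners'
  flanks); the mean + 3 SD threshold then admits some of them alongside the
  consensus-containing k-mers.  A purity requirement of ≥ 6 shared
  consensus bases for *every* top k-mer is only met at sharper selection
  (s ≳ 8), where the pool is essentially pure full-match winners.
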