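# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## SSR mining

A locus is a maximal perfect run of an irreducible 2–6 bp unit meeting its
unit-length minimum (di 6, tri 5, tetra 4, penta 4, hexa 3 contiguous
units; mononucleotide runs are never reported).  "Maximal" means the run
cannot be extended by one whole unit on either side; trailing partial
units never inflate the repeat count.  "Irreducible" excludes motifs that
are powers of a shorter unit (ATAT is a di-, not a tetra-nucleotide
motif).  Any non-ACGT base terminates a run.

Overlapping candidate runs of different unit lengths are resolved so a
position belongs to at most one locus: the longest run wins, ties go to
the smaller unit length, remaining ties to the leftmost start.  This also
resolves the rotational ambiguity of a periodic region (a run of (AT)n
can be read one base later as (TA)n): the leftmost phase is reported.
Compound or interrupted SSRs are out of scope — only perfect repeats are
reported, and adjacent loci are never merged.

Motif classes are canonical over cyclic rotation and reverse complement:
the class label is `M/revcomp(M)` where M is the lexicographically
smallest string among all rotations of the motif and of its reverse
complement.  Published SSR catalogues use interchangeable labels for the
same class (AAG/CTT vs GAA/CTT); the lexicographic rule fixes one
deterministic representative.

Coordinates are 0-based half-open internally and 1-based inclusive in all
written tables.  Summary shares are percentages of total loci rounded to
one decimal at report time; density is total sequence length in kb per
SSR, one decimal.  Flank checks deem a locus primer-designable when both
flanks reach `min_flank` (default 50 bp) and locus plus minimal flanks fit
the product-size window (default 100–250 bp, the window used for the
study's marker primers); both are configurable.

## ORF annotation

The CDS is the longest ATG-initiated open reading frame, stop codon
included, over the three forward frames and the three frames of the
reverse complement.  Ties break FORWARD before REVERSE, then smallest
start.  The default acceptance floor is 90 nt (30 codons) — small enough
to classify nearly all real contigs while rejecting spurious two-codon
frames; the synthetic generator and its recovery tests use 300 nt, the
floor at which random-sequence ORFs become rare enough for a clean planted
truth.  Candidates running off the 3′ end without a stop are rejected by
default; `require_stop=False` accepts them for fragmentary assemblies, at
the cost of a biased 3′UTR partition.

Features classify relative to the ORF in its own orientation: entirely
5′ of the CDS → 5′UTR, entirely 3′ → 3′UTR, and any overlap with the CDS
→ CDS (a repeat spanning the start codon counts as coding).  Transcripts
without an accepted ORF leave their features unclassified rather than
forcing a guess.

## SNP characterization

Variant records come from a VCF produced upstream (read mapping and
calling are out of scope).  Multi-allelic lines contribute their first ALT
(the rest are tallied and dropped); indels, MNPs and symbolic alleles are
skipped with reason codes — the marker set is strictly biallelic SNVs.
Zygosity is read from the first sample's GT field when present, else HOM.

Filtering keeps a record iff depth ∈ [min, max] and MQ ≥ threshold, all
bounds inclusive (defaults 20 / 200 / 10, the varFilter settings of the
study's calling step; the source states values, not open/closed bounds, so
inclusivity is a documented package convention and every rejection carries
its reason).  Transitions are A↔G and C↔T; everything else is a
transversion; the Ts/Tv ratio is undefined (reported as such, never 0)
when no transversions are present.  HRM classes partition the unordered
base pairs: I = {C,T} and {A,G}, II = {A,C} and {G,T}, III = {C,G},
IV = {A,T}.

## Diversity

Band scores are 0/1 per (locus, allele) column.  Allele frequencies at a
locus are band-presence counts over total presences at that locus, so
genotypes with no band (null alleles) shrink the denominator instead of
forming an allele class — the band-score representation cannot distinguish
a null allele from failed amplification.  PIC = 1 − Σp² (0 for
monomorphic loci; bounded by 1 − 1/k, with equality at equifrequency).

Jaccard similarity is |x∧y|/|x∨y| on the binary profiles; two all-zero
profiles are defined as identical (similarity 1).  Genotype distances are
1 − Jaccard.  UPGMA merges the closest pair, averaging distances with
cluster-size weights; each internal node sits at half its merge distance,
so the tree is ultrametric by construction, and the newick serialization
carries height differences as branch lengths.  Distance ties break by the
lexicographically smallest pair of minimum tip labels — the tie rule of
the original clustering software is unknown, so determinism is the only
claim.

## Expression

FPKM = 10⁹·C/(N·L).  FC = log₂(treated/control) on FPKM; classification
is by sign alone (an optional |FC| threshold exists but defaults to 0,
matching the source study's rule), with no significance testing — the
study classified purely by fold-change sign and so does the package.  A
zero-control, nonzero-treated transcript is flagged UNDEFINED rather than
patched with a pseudocount (a pseudocount would manufacture a statistic
the rule does not define); both-zero is UNCHANGED at FC 0, and
zero-treated over nonzero control is −∞, hence DOWN.

## HRM genotyping

QC passes a curve iff Ct ≤ 30 (inclusive) and amplification efficiency
> 1.4 (strict), per the quoted instrument protocol operators.
Normalization fits straight baselines to a pre-melt and a post-melt window
(defaults: first and last 2 °C of the grid — the instrument software's
windows are unpublished) and rescales to 100·(F−lower)/(upper−lower),
clipped to [0, 100].

Melting domains are local maxima of the smoothed negative derivative
−dF/dT (centered moving average, default 5 points) with prominence at
least 0.1 of the global maximum and separation ≥ 0.5 °C; these two values
are package defaults standing in for unpublished instrument parameters.
Peak Tm is refined by the vertex of a parabola through the three grid
points around the maximum, which keeps the estimator bias below 0.05 °C at
a 0.1 °C grid.  One domain ⇒ homozygous, two or more ⇒ heterozygous, none
or QC failure ⇒ no call.  Homozygote pair comparison reports
ΔTm = |Tm_a − Tm_b| and, when the SNP bases are supplied, whether ΔTm falls
in the published per-class homozygote ranges (I 0.15–0.51, II 0.03–0.41,
III 0.18–0.35, IV 0.02–0.12 °C) — an annotation, never a filter, since the
classes overlap.

## Synthetic data

All generators are pure functions of their spec including the seed; one
global seed fans out into named substreams by hashing the generator name,
so adding a stage never reshuffles another stage's draws.

*Transcripts* — uniform lengths within a configurable range (default
280–6445 bp, the study's contig range), i.i.d. bases at a set GC fraction
(default 0.42, typical for legume transcripts).  A configurable fraction
(default 0.964, the study's CDS-prediction rate) carries one planted
forward-strand ORF ≥ 300 nt built from stop-free codons, resampled until
it is the unique longest ORF over six frames; the rest have every ≥300 nt
ORF destroyed by writing a stop into its middle codon.  Real UTR/CDS base
composition, splice isoforms and assembly artifacts are not emulated.

*Planted SSRs* — requested motif/count/region mixes are written into
scrubbed transcripts (natural repeats are first mutated away so
recall/precision against truth is exact) by same-length window
replacement.  Insertions never abut each other, are flank-checked to be
maximal and phase-unambiguous, and CDS insertions are screened for
in-frame stops with the planted ORF re-validated after every change.

*Planted SNPs* — positions drawn without replacement outside excluded
intervals; transition with probability `ts_fraction` (default 0.61, the
study's transition share), heterozygous with probability `het_fraction`
(default 17/1845, the study's het rate).  DP ~ U[10, 250] and
MQ ~ U[0, 60] so the default filters have bite on synthetic data.  No
sequencing-error or allele-balance model.

*Counts* — gamma-Poisson (negative binomial) with per-gene mean
`base_mean` (default 100), dispersion 0.1, library-size scaling, and a
planted fold of 4 for up/down genes (the effect size used in the
sign-recovery checks; the study states none).  No gene-length or GC bias.

*Melt curves* — two-state melting: each duplex species melts along a
logistic transition of width 0.3 °C centred on its Tm, mixed by weights,
between sloped linear baselines, plus Gaussian noise as a fraction of
amplitude on a 70–90 °C grid at 0.1 °C.  Genotype-derived specs place
homoduplex Tms at 80 °C + {A: 0, T: 0.3, C: 0.6, G: 0.9} °C — spacing
chosen to sit inside the published sub-degree homozygote ΔTm ranges while
enforcing the nearest-neighbour stability ordering A/A < T/T < C/C < G/G;
only the ordering itself is literature-backed.  Heterozygotes are
four equal-weight species (two homoduplexes, two heteroduplexes depressed
1.5 °C below the lower homoduplex).  Real instrument noise is not
characterized in the source; the default noise settings are placeholders,
not inferences, so passing recovery tests demonstrate algorithmic
correctness under the stated model, not instrument-level performance.

*Allele matrices* — one band per genotype per locus (appropriate for a
self-pollinating crop scored as homozygous lines), drawn from Dirichlet
(α = 5) or equifrequent truth frequencies, with an optional null-allele
rate.  Co-dominant two-band heterozygotes are not modelled.

## Problem sizes and verification

The test suite checks every operation against independent oracles:
a brute-force (start, unit-length) enumerator for the miner (1,000 random
1-kb sequences), a recompute-from-scratch UPGMA plus scipy average-linkage
cophenetic distances (200+ random matrices), per-record re-checks for the
variant filter (10,000 records), closed forms for PIC/FPKM/FC, and planted
truth for ORFs, SSRs, substitution spectra, DEG signs (4-fold, ≥ 99 %
recovery) and HRM zygosity (1,000 curves per genotype at 0.5 % noise,
≥ 99 %).  The acceptance script measures the same quantities at moderate
sizes (300 transcripts, 300 curves per genotype, 50 count replicates),
chosen as comfortably sufficient for the rates and errors it reports.

## Limitations

- The study's dataset-level totals (1621 SSRs, 1844 SNPs, 2306 DEGs, the
  27-genotype dendrogram) derive from unreleased raw reads and band
  scores; only printed composition statistics are reproduced, from the
  printed category counts themselves.
- The source's printed totals disagree internally in places (1844 vs 1845
  SNPs; a 31-locus panel whose allele counts sum to 85 against a printed
  total of 89; loci printed with one allele but nonzero PIC).  Reports
  carry raw computed counts; worked examples use the printed numerators
  and denominators as-is.
- Primer design, read mapping, variant calling and assembly are upstream
  tools; the package only prepares their inputs or consumes their outputs.
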