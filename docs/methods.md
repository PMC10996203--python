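# Methods

This note records the models, defaults and numerical choices behind
`structrip`, and what the synthetic benchmark does and does not establish.

## Synthetic data model

**Genome.** One chromosome carries coding genes (with exon/intron/UTR
structure), single-copy structured ncRNA genes (H/ACA and C/D box snoRNAs,
scaRNAs, miRNAs), `n_rdna_copies` sequence-identical 45S rDNA units
(5′ETS 800, 18S 1200, ITS1 300, 5.8S 160, ITS2 300, 28S 5070, 3′ETS 250 nt)
and identical 5S copies.  The 28S length matches the human residue numbering
scale so positions such as 1776, 2242 and 2388 are meaningful on the
synthetic unit; its six secondary-structure domains are an input table
(I 1–1400, II 1401–2500, III 2501–3150, IV 3151–3650, V 3651–4550,
VI 4551–5070), scaled proportionally if a different 28S length is configured.
Domain boundaries are data, not computation: curating them from a secondary
structure is outside the package's scope.  `intergenic_fraction` defaults to
0.85 — genomes are mostly intergenic, and this keeps the per-nucleotide
density of intergenic background reads realistically low relative to an
expressed transcript (at a low intergenic fraction, background reads pile
onto short ncRNA loci at signal-like densities, which no real genome-scale
experiment shows).

**Libraries.** Two IP and two Input replicates by default (`n_replicates=2`),
single-end 50 nt fragments, unstranded counting.  Per-transcript fragment
counts are negative binomial: Input ~ NB(baseline, α), IP ~ NB(baseline ×
enrichment, α) with shared dispersion α = 0.05 (variance m + αm²).  The
intergenic background entry is an *aggregate* over many independent loci, so
its total is drawn Poisson — giving it a single-transcript dispersion would
hand the library total an unrealistic ±20% swing.  Fragment start positions
are uniform within the transcript except inside enrichment windows, where the
placement density is multiplied by the window factor and renormalized; starts
keep ≥ 16 nt to the transcript 3′ end (library size selection), so no aligned
read falls below the QC length floor.  Reads from the multicopy 45S/5S units
are emitted once per genomic copy with an NH-style multiplicity; all other
reads are unique.  QC-contaminated reads (> 2 N bases; < 16 nt) are appended
to the FASTQ only, at 2%/1% of the library, so the alignment totals still
equal the planted truth counts exactly.  `n_fragments` rescales the baseline
means to a nominal Input depth; with `n_fragments=None` the baselines are
absolute mean fragment counts (the Monte-Carlo contract "baseline 100,
factor 8 ⇒ mean IP count 800" holds on that scale).

**Planted truth (demo defaults).** Baselines are log-normal per class
(coding ~40, snoRNAs ~60, scaRNAs ~50 mean fragments); the background mass is
2.5× the summed transcript mass, because annotated structured RNAs are a
small minority of a mapped library.  The 45S baseline is set to ~3.8% of the
Input library and its planted IP factor to 14; after library-size
renormalization this lands the *observed* IP 45S read fraction near 21% and
the IP/Input fraction ratio near 6 — the values this kind of assay reports —
with the binding window (8×, 28S residues 1776–2242) concentrating ~73% of
45S reads on the 28S.  Thirty H/ACA snoRNAs (factor 6) and five scaRNAs
(factor 4) are enriched; genomic peak sites (60 nt, factor 25, half flagged
with an implanted (CA)₁₀ motif) sit in introns and intergenic space.

**What the generator does not emulate:** sequencing errors beyond
N-contamination, adapters, paired ends, crosslink-induced truncations or
mutations, mappability structure, and transcript splicing in read placement
(reads are placed on gene spans).  Passing tests therefore demonstrate the
*logic* of the stages under a faithful count model, not robustness to
alignment artifacts of real libraries.

## Stage-by-stage choices

**QC.** N-filter (> 2 N) before length filter (< 16 nt); the order is fixed
and the report attributes each removal to the rule that fired first.

**Partition.** Multiplicity is per read id; inconsistent NH across one read's
records is a data-integrity error naming the read.  Multi-mapped reads are
counted once each (best placement), not fractionally, with deterministic
tie-breaking: class priority rRNA > snoRNA > scaRNA > snRNA > tRNA > miRNA >
lincRNA > other, then lexicographic reference id.  Subregion assignment uses
the read midpoint (1-based in reports, matching rRNA residue numbering), so
junction-spanning reads are never double-counted.

**Peak calling.** One defined algorithm: depth-run candidates
(depth ≥ `min_depth`, merged over gaps ≤ `merge_gap`), a permutation
background that re-places the same reads uniformly *on the same reference*
(preserving the per-reference read budget), and density enrichment normalized
by mapped-library sizes with a one-read pseudocount on the Input window.  The
permutation statistic is the maximum single-base depth — the maximum over
windows of any fixed length equals it — so one permutation distribution per
reference serves every candidate, and p = (1 + #{perm ≥ obs})/(n_perm + 1) is
strictly positive and super-uniform under the null (verified by simulation).
Summit = leftmost maximum.  Defaults: min_depth 10, merge gap 10,
200 permutations, α 0.01, min enrichment 3.

**(CA)-repeat scan.** Per-peak maximal (CA)n run length scanning CA/AC/TG/GT
phases; the statistic is the fraction of peaks with a run ≥ 5 units; the null
shuffles non-overlapping dinucleotide tiles of each peak sequence (preserves
tile composition; the Euler-path dinucleotide shuffle was judged out of
proportion for this setting).

**Enrichment.** Only uniquely mapped reads feed FPKM and the IP/Input test;
the FPKM denominator is *all* uniquely mapped fragments of the pooled
condition, not just transcript-assigned ones.  ε = 0.01 pseudo-FPKM
stabilizes fold changes; the expressed floor is Input FPKM ≥ 1.  The test is
two-sided Fisher's exact on pooled replicate counts — exact at toy depth,
with an enumeration oracle in the tests — and raw p is gated (q reported
alongside), since the FC ≥ 2 gate already suppresses null calls far below α.
Ranking for the top-N abundant list uses IP FPKM with ties broken by
transcript id.  Note the known composition effect: enriching a large share of
the library deflates everyone's FPKM fold change; with realistic library
composition the deflation is ~10–15% here.

**28S profiling.** Multi-mapped rDNA reads collapse to one record on the 45S
consensus (copies are identical; profiling is on the unit).  Domain density
is reads·nt⁻¹ per million mapped reads (the normalization is a package
choice, recorded in outputs).  Binding regions: depth ≥ 0.5 × max, 20 nt
merge gap.  Because only read *starts* are enrichment-weighted, coverage at a
planted window ramps over one read length at each edge; recovered regions are
offset ~half a read length rightward of the planted window.  The annotated
methylation residues 2388/2409/2411 lie in domain II but ~150 nt right of the
1776–2242 window, so the containment flags on the demo are negative —
containment is reported, not presumed.

**Differential expression.** Median-of-ratios size factors (factors rescaled
to geometric mean 1).  The per-gene test is deliberately *not* a
negative-binomial GLM: it is Fisher's exact on pooled-by-condition counts
versus pooled totals, labeled as a stand-in in outputs.  It is exactly
calibrated under Poisson sampling and anticonservative under strong
overdispersion; the count-matrix generator default dispersion is 0.01
(typical of well-expressed genes in cell-line RNA-seq), under which the
measured null fraction at FDR < 0.05 stays below 5%.  This is a documented
limitation, not a replacement for a dispersion-modeling test on real data.
FC is the ratio of mean normalized counts with pseudo-mean ε = 0.5;
direction: up iff FC ≥ 2 ∧ FDR < 0.05, down iff FC ≤ 0.5 ∧ FDR < 0.05.

**RTL-P.** Signal model 2^(−Ct) (100% amplification efficiency; efficiency is
a parameter).  Index = ratio(LD)/ratio(HD) with HD as the full-read-through
anchor; MD is reported descriptively.  Under the stall model the noise-free
index is 1 − m·s for methylated fraction m and stall efficiency s (default
0.9); m = 0.5 gives 0.55 exactly.  Condition contrasts are index ratios with
a paired Student's t on replicate-level log indices (ratios are log-normal
under Gaussian Ct noise).  Default Ct noise is 0.1 cycles, the typical
technical precision of SYBR qPCR replicates.  A planted 2-cycle low-dNTP
suppression (m·s = 0.75 vs an unmethylated control) quarters the index.

**Pipeline.** All randomness flows from one global seed through logged
per-stage seeds; outputs are byte-identical across reruns with the same
config.  Wall-clock timings go to a separate `timings.txt` so the report file
itself is deterministic.  The DE stage of the demo runs on a simulated count
matrix over the bundle's genes plus filler genes (1000 total), with 15
planted 4× genes, since the read simulator models IP binding rather than
condition-dependent expression.

## Evaluation sizes

The seeded evaluations (also behind `scripts/acceptance.py`) use: domain-II
localization, 100 runs × 4 libraries × 4k fragments on a compact reference;
snoRNA recovery, 100 runs × 4 × 40k fragments with 30 planted 4× H/ACA
snoRNAs among 174 (planted depth ~55 reads); peak null calibration and
recovery, 100 runs each on a 2 kb reference (800 and 2000 reads; each run
draws its own permutation seed — sharing one permutation sample across runs
would correlate their p-values); DEG calibration, 50 null + 20 planted runs
of a 1000-gene matrix; RTL-P sign structure, 100 runs at n = 3 replicates.
These sizes were chosen so the whole evaluation completes in a few minutes on
one CPU while keeping binomial noise on every rate below ~±5 points.

## Known limitations

- The peak caller is a single well-specified algorithm, not a reimplementation
  of any published caller; zero-truncated regression models are explicitly
  out of scope.
- Class membership of a multi-mapped read comes from the class table and
  annotation intervals, not from covariance-model scans of the sequence.
- The Fisher stand-ins (enrichment and DE) ignore replicate-level dispersion;
  see above.
- The RTL-P index is a package definition (HD-anchored); plots of per-level
  ratios are the primary descriptive output.
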