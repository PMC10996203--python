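# structrip

Analysis toolkit for RNA immunoprecipitation sequencing (RIP-seq) of
**structured RNAs** — the situation where an RNA-binding protein's targets are
not only mRNAs but also ribosomal RNA, snoRNAs and scaRNAs, so the reads that
standard pipelines throw away (multi-mapped rRNA reads) carry the signal.
It is aimed at computational biologists who have IP and Input alignments (or
want a fully synthetic benchmark) and need the complete chain:

1. **QC and read partition** — drop reads with more than 2 N bases, then reads
   shorter than 16 nt; split alignments into uniquely (NH = 1) and multiply
   (NH > 1) mapped reads; assign multi-mapped reads to ncRNA classes and to
   45S rDNA subregions (5′ETS–18S–ITS1–5.8S–ITS2–28S–3′ETS) by read midpoint.
2. **Peak calling** — candidate peaks are maximal runs of IP depth ≥ *d*,
   merged over gaps; the empirical p-value places the same reads uniformly on
   the same reference and asks how often the permutation maximum depth reaches
   the observed peak depth; enrichment is the library-size–normalized density
   ratio IP/(Input + 1 pseudocount).  Peaks are annotated at their summit with
   priority CDS > 5′UTR > 3′UTR > ncRNA-exon > intron > antisense > intergenic,
   and "confident bound genes" are those with a peak in both IP replicates.
   A direct (CA)n-repeat scan against a dinucleotide-shuffled null replaces
   de-novo motif discovery.
3. **Abundance and enrichment** — FPKM = count / (length/10³) / (total/10⁶)
   from uniquely mapped reads; per-transcript IP/Input fold change
   FC = (FPKM_IP + ε)/(FPKM_Input + ε) with a two-sided Fisher's exact test on
   pooled counts; a transcript is *enriched* when FC ≥ 2 and p < 0.05.
   Top-N abundant RNAs, per-class and per-snoRNA-box-type enrichment
   summaries, and hypergeometric gene-set overlap p = P[X ≥ |A∩B|],
   X ~ Hypergeom(N, |A|, |B|), with Benjamini–Hochberg FDR.
4. **28S domain profiling** — per-base depth on the 28S rRNA, density per
   secondary-structure domain (I–VI) in reads·nt⁻¹ per million mapped reads,
   the maximal binding region (depth ≥ 0.5 × max), and containment of
   2′-O-methylation residues (Am2388, Cm2409, Gm2411).
5. **Differential expression** — median-of-ratios size factors, a clearly
   labeled Fisher-on-pooled-counts stand-in test with BH FDR, the threshold
   rule FC ≥ 2 (up) / ≤ 0.5 (down) at FDR < 0.05, and directional overlap of
   DEG sets with bound-gene sets.
6. **RTL-P methylation quantification** — reverse transcription at low dNTP
   stalls at 2′-O-methylated residues, so with FU (read-through) and FD
   (control) amplicons, signal = 2^(−Ct), ratio(level) = FU/FD, and the
   methylation index is ratio(LD)/ratio(HD); condition contrasts use a paired
   Student's t-test on replicate log indices.  2^(−ΔΔCt) utilities included.

A **synthetic-data generator** produces a toy genome (multicopy 45S unit with
identical copies, hence true multi-mapping), GFF3 annotation, class tables,
and IP/Input replicate libraries with negative-binomial count noise and
planted binding structure (per-transcript enrichment factors, an 8× binding
window on 28S domain II at residues 1776–2242, genomic peak sites with
optional (CA)n motifs).  Every stage is therefore testable against a known
truth, deterministically under a seed.

## Worked example

The bundled demo simulates two IP + two Input libraries (~25k Input fragments
each) and runs the full chain on one CPU in a few seconds:

```bash
structrip run --out demo_out --seed 1
```

From `demo_out/run_report.json` (numbers printed by the run above):

- `partition`: multi-mapped read fraction 0.282 in IP_1 vs 0.051 in Input_1 —
  the IP library is loaded with multi-mapped rRNA reads, the Input is not.
- `callpeaks`: 38 peaks in each IP replicate, 35 confident bound genes;
  (CA)-repeat scan z = 7.8, empirical p = 0.0099 against the
  dinucleotide-shuffled null (the planted motif sites are recovered).
- `enrich`: 35 transcripts pass FC ≥ 2 & p < 0.05; the top-100 abundant list
  is dominated by snoRNAs (49 H/ACA + 47 C/D) and scaRNAs (4), mirroring the
  planted truth.
- `profile`: the max-density domain of the 28S is **II**, and the called
  binding region [1801, 2269] recovers the planted window (1776–2242; the
  ~25 nt offset is the read-length ramp of coverage at window edges).
- `de`: 15 up-regulated genes at FC ≥ 2 & FDR < 0.05 (the 15 planted ones),
  6 overlapping the bound-gene set, hypergeometric p = 4.7×10⁻⁶.
- `rtlp`: methylation indices Ctrl 0.572, OE 0.215, KD 0.892 → OE/Ctrl
  contrast 0.376 (p = 0.025, less read-through ⇒ more methylation) and
  KD/Ctrl contrast 1.559 (p = 0.025), the expected sign structure.

Rerunning with the same seed reproduces every output file byte-for-byte
(timings are logged separately in `timings.txt`).

Library use without the CLI:

```python
import numpy as np
from structrip import (GenomeSpec, build_reference, default_truth,
                       LibrarySim, simulate_libraries)

bundle = build_reference(GenomeSpec(seed=5))
truth = default_truth(bundle, rng=np.random.default_rng(12))
sim = simulate_libraries(truth, LibrarySim(n_fragments=25_000, seed=7), bundle)
```

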