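"""Synthetic genome, annotation and IP/Input library generator.

The generator emulates the statistical structure of a UV-crosslinked RNA
immunoprecipitation (RIP-seq) experiment on a cell line: two IP and two
Input replicate libraries, a multicopy 45S rDNA unit (5'ETS-18S-ITS1-5.8S-
ITS2-28S-3'ETS) that makes rRNA reads multi-mapped, single-copy structured
ncRNAs (H/ACA and C/D box snoRNAs, scaRNAs, miRNAs), negative-binomial
fragment-count noise, and planted IP-specific binding: per-transcript
enrichment factors, a binding window on the 28S rRNA, and genomic peak
sites.  Everything is deterministic under a seed, so the downstream stages
can be tested against the planted truth without any deposited data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as srio

BACKGROUND = "__background__"

#: default 45S subregion layout (name, length in nt); 28S length matches the
#: human 28S residue numbering scale so positions like 1776-2242 and 2388 are
#: meaningful on the synthetic unit.
DEFAULT_RDNA_SUBREGIONS: Tuple[Tuple[str, int], ...] = (
    ("5ETS", 800),
    ("18S", 1200),
    ("ITS1", 300),
    ("5.8S", 160),
    ("ITS2", 300),
    ("28S", 5070),
    ("3ETS", 250),
)

#: default 28S secondary-structure domain intervals (1-based closed, local to
#: the 28S).  Domain II contains the planted binding window 1776-2242 and the
#: 2'-O-methylation residues 2388/2409/2411.
DEFAULT_28S_DOMAINS: Tuple[Tuple[str, int, int], ...] = (
    ("I", 1, 1400),
    ("II", 1401, 2500),
    ("III", 2501, 3150),
    ("IV", 3151, 3650),
    ("V", 3651, 4550),
    ("VI", 4551, 5070),
)


class SizingError(ValueError):
    """Feature budget cannot be packed into the genome."""


class TruthLookupError(KeyError):
    """Binding truth references a transcript absent from the reference."""


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the toy genome and its structured-RNA complement."""

    n_coding_genes: int = 40
    gene_length_range: Tuple[int, int] = (1000, 3000)
    exon_count_range: Tuple[int, int] = (1, 4)
    n_rdna_copies: int = 3
    rdna_subregions: Tuple[Tuple[str, int], ...] = DEFAULT_RDNA_SUBREGIONS
    n_5s_copies: int = 3
    n_snorna_haca: int = 100
    n_snorna_cd: int = 74
    n_scarna: int = 10
    n_mirna: int = 10
    #: genomes are mostly intergenic; a high default keeps the per-nt density
    #: of intergenic background reads realistically low relative to expressed
    #: transcripts
    intergenic_fraction: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_coding_genes, self.n_rdna_copies, self.n_5s_copies,
            self.n_snorna_haca, self.n_snorna_cd, self.n_scarna, self.n_mirna,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all feature counts must be >= 0")
        for name, length in self.rdna_subregions:
            if length < 50:
                raise SizingError(f"rDNA subregion {name} shorter than 50 nt ({length})")
        if not 0 <= self.intergenic_fraction < 1:
            raise SizingError(
                "intergenic_fraction must lie in [0, 1): feature lengths must "
                f"fit into the genome (got {self.intergenic_fraction})"
            )
        lo, hi = self.gene_length_range
        if lo < 300 or hi < lo:
            raise SizingError(f"gene_length_range {self.gene_length_range} infeasible")

    @property
    def rdna_unit_length(self) -> int:
        return sum(length for _, length in self.rdna_subregions)


@dataclass
class BindingTruth:
    """Planted protein-RNA binding structure.

    enriched_transcripts maps transcript id -> IP enrichment factor (>= 1);
    rrna_binding_window is (start, end, factor) in 1-based closed 28S-local
    coordinates; peak_sites are genomic (start0, end0, factor, has_motif)
    intervals on the main chromosome; baseline_expression maps transcript id
    (or ``__background__``) -> mean Input fragments.
    """

    enriched_transcripts: Dict[str, float] = field(default_factory=dict)
    rrna_binding_window: Optional[Tuple[int, int, float]] = None
    peak_sites: List[Tuple[int, int, float, bool]] = field(default_factory=list)
    baseline_expression: Dict[str, float] = field(default_factory=dict)
    nb_dispersion: float = 0.05

    def validate(self, bundle: "ReferenceBundle") -> None:
        known = set(bundle.transcripts["transcript_id"])
        for tid in self.enriched_transcripts:
            if tid not in known:
                raise TruthLookupError(f"enriched transcript {tid!r} not in reference")
        for tid, mean in self.baseline_expression.items():
            if tid != BACKGROUND and tid not in known:
                raise TruthLookupError(f"baseline transcript {tid!r} not in reference")
            if mean <= 0:
                raise ValueError(f"baseline mean for {tid!r} must be > 0")
        if any(f < 1 for f in self.enriched_transcripts.values()):
            raise ValueError("enrichment factors must be >= 1")
        if self.rrna_binding_window is not None:
            s, e, f = self.rrna_binding_window
            len_28s = int(bundle.domains["end"].max())
            if not (1 <= s <= e <= len_28s):
                raise ValueError("rrna_binding_window outside the 28S sequence")
            if f < 1:
                raise ValueError("window enrichment factor must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass(frozen=True)
class LibrarySim:
    """Sequencing-library parameters.

    n_fragments, when set, rescales the truth baselines so Input libraries
    average that many fragments; when None the baselines are absolute mean
    fragment counts.  Reads are single-end, unstranded counting downstream.
    """

    n_fragments: Optional[int] = 40_000
    read_length: int = 50
    n_replicates: int = 2
    frac_n_contaminated: float = 0.02
    frac_short: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.read_length < 16:
            raise ValueError("read_length must be >= 16")
        for frac in (self.frac_n_contaminated, self.frac_short):
            if not 0 <= frac <= 1:
                raise ValueError("contamination fractions must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ReferenceBundle:
    """Everything build_reference emits, kept in memory for the pipeline."""

    spec: GenomeSpec
    genome: Dict[str, str]                  # chr1 plus standalone 45S / 5S units
    features: pd.DataFrame                  # GFF-style rows, 0-based half-open
    transcripts: pd.DataFrame               # transcript_id/seqid/start/end/strand/length/class/box_type
    class_table: pd.DataFrame               # transcript_id/class
    rdna_intervals: pd.DataFrame            # name/start/end, 1-based closed on the 45S unit
    domains: pd.DataFrame                   # name/start/end, 1-based closed on the 28S
    rdna_copies: pd.DataFrame               # feature_id/start/end genomic spans of 45S copies
    fives_copies: pd.DataFrame              # genomic spans of 5S copies

    @property
    def ref_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    @property
    def rdna_28s_offset(self) -> int:
        """0-based offset of the 28S within the 45S unit."""
        row = self.rdna_intervals.set_index("name").loc["28S"]
        return int(row["start"]) - 1

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        srio.write_fasta(self.genome, outdir / "genome.fa")
        srio.write_gff3(self.features, outdir / "annotation.gff3")
        srio.write_tsv(self.class_table, outdir / "classes.tsv")
        srio.write_tsv(self.rdna_intervals, outdir / "rdna_intervals.tsv")
        srio.write_tsv(self.domains, outdir / "domains_28s.tsv")
        srio.write_tsv(self.rdna_copies, outdir / "rdna_copies.tsv")
        srio.write_tsv(self.fives_copies, outdir / "5s_copies.tsv")
        srio.write_tsv(self.transcripts, outdir / "transcripts.tsv")
        with open(outdir / "genome_spec.json", "w") as fh:
            json.dump(dataclasses.asdict(self.spec), fh, indent=2, sort_keys=True)


def load_reference(indir: str | Path) -> ReferenceBundle:
    """Reload a reference bundle written by :meth:`ReferenceBundle.save`."""
    indir = Path(indir)
    with open(indir / "genome_spec.json") as fh:
        raw = json.load(fh)
    raw["gene_length_range"] = tuple(raw["gene_length_range"])
    raw["exon_count_range"] = tuple(raw["exon_count_range"])
    raw["rdna_subregions"] = tuple((n, int(l)) for n, l in raw["rdna_subregions"])
    spec = GenomeSpec(**raw)
    return ReferenceBundle(
        spec=spec,
        genome=srio.read_fasta(indir / "genome.fa"),
        features=srio.read_gff3(indir / "annotation.gff3"),
        transcripts=srio.read_tsv(indir / "transcripts.tsv"),
        class_table=srio.read_tsv(indir / "classes.tsv"),
        rdna_intervals=srio.read_tsv(indir / "rdna_intervals.tsv"),
        domains=srio.read_tsv(indir / "domains_28s.tsv"),
        rdna_copies=srio.read_tsv(indir / "rdna_copies.tsv"),
        fives_copies=srio.read_tsv(indir / "5s_copies.tsv"),
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_reference(spec: GenomeSpec) -> ReferenceBundle:
    """Assemble the toy genome, annotation and reference tables.

    45S copies are sequence-identical by construction so reads simulated from
    the unit are genuinely multi-mapped; the same holds for 5S copies.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    lengths_by_class: List[Tuple[str, str, str, int]] = []  # (tid, class, box, length)
    lo, hi = spec.gene_length_range
    for i in range(spec.n_coding_genes):
        lengths_by_class.append(
            (f"GENE{i + 1:04d}", "coding", "none", int(rng.integers(lo, hi + 1)))
        )
    for i in range(spec.n_snorna_haca):
        lengths_by_class.append(
            (f"SNORA{i + 1:04d}", "snoRNA-H/ACA", "H/ACA", int(rng.integers(120, 160)))
        )
    for i in range(spec.n_snorna_cd):
        lengths_by_class.append(
            (f"SNORD{i + 1:04d}", "snoRNA-C/D", "C/D", int(rng.integers(70, 110)))
        )
    for i in range(spec.n_scarna):
        lengths_by_class.append(
            (f"SCARNA{i + 1:04d}", "scaRNA", "none", int(rng.integers(200, 330)))
        )
    for i in range(spec.n_mirna):
        lengths_by_class.append(
            (f"MIR{i + 1:04d}", "miRNA", "none", int(rng.integers(70, 100)))
        )

    unit_len = spec.rdna_unit_length
    total_feature_len = (
        sum(length for *_, length in lengths_by_class)
        + spec.n_rdna_copies * unit_len
        + spec.n_5s_copies * 121
    )
    n_slots = len(lengths_by_class) + spec.n_rdna_copies + spec.n_5s_copies + 1
    spacer = int(
        total_feature_len
        * spec.intergenic_fraction
        / max(1e-9, (1 - spec.intergenic_fraction))
        / max(1, n_slots)
    )
    spacer = max(spacer, 100)

    rdna_unit_seq = _random_seq(rng, unit_len)
    fives_seq = _random_seq(rng, 121)

    chrom_parts: List[str] = []
    features: List[dict] = []
    transcripts: List[dict] = []
    rdna_copy_rows: List[dict] = []
    fives_rows: List[dict] = []
    cursor = 0

    def _push_spacer() -> None:
        nonlocal cursor
        chrom_parts.append(_random_seq(rng, spacer))
        cursor += spacer

    def _add_feature(**kw) -> None:
        features.append(
            {
                "seqid": "chr1", "type": kw["type"], "start": kw["start"],
                "end": kw["end"], "strand": kw["strand"],
                "feature_id": kw["feature_id"], "gene_id": kw["gene_id"],
                "transcript_id": kw.get("transcript_id", ""),
                "biotype": kw.get("biotype", ""),
            }
        )

    _push_spacer()
    for tid, cls, box, length in lengths_by_class:
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = cursor, cursor + length
        chrom_parts.append(_random_seq(rng, length))
        cursor = end
        if cls == "coding":
            biotype = "protein_coding"
            _add_feature(type="gene", start=start, end=end, strand=strand,
                         feature_id=tid, gene_id=tid, transcript_id=tid, biotype=biotype)
            n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
            bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False)) \
                if n_exons > 1 else np.array([], dtype=int)
            edges = np.concatenate(([0], bounds, [length]))
            exons = [(start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                     for k in range(n_exons)]
            for k, (es, ee) in enumerate(exons):
                _add_feature(type="exon", start=es, end=ee, strand=strand,
                             feature_id=f"{tid}.exon{k + 1}", gene_id=tid,
                             transcript_id=tid, biotype=biotype)
            # UTRs at the transcriptional ends, CDS in between (genomic order)
            utr5_len = min(100, exons[0][1] - exons[0][0] - 1)
            utr3_len = min(150, exons[-1][1] - exons[-1][0] - 1)
            if strand == "-":
                utr5_len, utr3_len = utr3_len, utr5_len  # genomic-left is 3' end
                left_type, right_type = "three_prime_UTR", "five_prime_UTR"
            else:
                left_type, right_type = "five_prime_UTR", "three_prime_UTR"
            _add_feature(type=left_type, start=exons[0][0], end=exons[0][0] + utr5_len,
                         strand=strand, feature_id=f"{tid}.utrL", gene_id=tid,
                         transcript_id=tid, biotype=biotype)
            _add_feature(type=right_type, start=exons[-1][1] - utr3_len, end=exons[-1][1],
                         strand=strand, feature_id=f"{tid}.utrR", gene_id=tid,
                         transcript_id=tid, biotype=biotype)
            for k, (es, ee) in enumerate(exons):
                cs = es + (utr5_len if k == 0 else 0)
                ce = ee - (utr3_len if k == len(exons) - 1 else 0)
                if ce > cs:
                    _add_feature(type="CDS", start=cs, end=ce, strand=strand,
                                 feature_id=f"{tid}.cds{k + 1}", gene_id=tid,
                                 transcript_id=tid, biotype=biotype)
        else:
            biotype = cls
            _add_feature(type="gene", start=start, end=end, strand=strand,
                         feature_id=tid, gene_id=tid, transcript_id=tid, biotype=biotype)
            _add_feature(type="noncoding_exon", start=start, end=end, strand=strand,
                         feature_id=f"{tid}.exon1", gene_id=tid,
                         transcript_id=tid, biotype=biotype)
        transcripts.append(
            {"transcript_id": tid, "seqid": "chr1", "start": start, "end": end,
             "strand": strand, "length": length, "class": cls, "box_type": box}
        )
        _push_spacer()

    for i in range(spec.n_rdna_copies):
        start, end = cursor, cursor + unit_len
        chrom_parts.append(rdna_unit_seq)
        cursor = end
        fid = f"45S_copy{i + 1}"
        _add_feature(type="gene", start=start, end=end, strand="+",
                     feature_id=fid, gene_id="45S", transcript_id="45S", biotype="rRNA")
        rdna_copy_rows.append({"feature_id": fid, "start": start, "end": end})
        _push_spacer()
    for i in range(spec.n_5s_copies):
        start, end = cursor, cursor + 121
        chrom_parts.append(fives_seq)
        cursor = end
        fid = f"5S_copy{i + 1}"
        _add_feature(type="gene", start=start, end=end, strand="+",
                     feature_id=fid, gene_id="5S", transcript_id="5S", biotype="rRNA")
        fives_rows.append({"feature_id": fid, "start": start, "end": end})
        _push_spacer()

    chrom = "".join(chrom_parts)
    genome = {"chr1": chrom, "45S": rdna_unit_seq, "5S": fives_seq}

    if spec.n_rdna_copies > 0:
        transcripts.append(
            {"transcript_id": "45S", "seqid": "45S", "start": 0, "end": unit_len,
             "strand": "+", "length": unit_len, "class": "rRNA", "box_type": "none"}
        )
    if spec.n_5s_copies > 0:
        transcripts.append(
            {"transcript_id": "5S", "seqid": "5S", "start": 0, "end": 121,
             "strand": "+", "length": 121, "class": "rRNA", "box_type": "none"}
        )

    transcripts_df = pd.DataFrame(transcripts)
    class_rows = transcripts_df[transcripts_df["class"] != "coding"][["transcript_id", "class"]]
    class_table = class_rows.reset_index(drop=True)

    rdna_rows, pos = [], 0
    for name, length in spec.rdna_subregions:
        rdna_rows.append({"name": name, "start": pos + 1, "end": pos + length})
        pos += length
    rdna_intervals = pd.DataFrame(rdna_rows)

    len_28s = dict(spec.rdna_subregions)["28S"]
    scale = len_28s / 5070
    dom_rows = []
    prev_end = 0
    for name, s, e in DEFAULT_28S_DOMAINS:
        ds = prev_end + 1
        de = len_28s if name == "VI" else int(round(e * scale))
        dom_rows.append({"name": name, "start": ds, "end": de})
        prev_end = de
    domains = pd.DataFrame(dom_rows)

    return ReferenceBundle(
        spec=spec, genome=genome, features=pd.DataFrame(features),
        transcripts=transcripts_df, class_table=class_table,
        rdna_intervals=rdna_intervals, domains=domains,
        rdna_copies=pd.DataFrame(rdna_copy_rows, columns=["feature_id", "start", "end"]),
        fives_copies=pd.DataFrame(fives_rows, columns=["feature_id", "start", "end"]),
    )


def default_truth(bundle: ReferenceBundle, rng: Optional[np.random.Generator] = None,
                  n_enriched_snorna: int = 30, snorna_factor: float = 6.0,
                  n_enriched_scarna: int = 5, scarna_factor: float = 4.0,
                  rdna_factor: float = 14.0,
                  window: Tuple[int, int, float] = (1776, 2242, 8.0),
                  peak_site_factor: float = 25.0,
                  haca_only: bool = True) -> BindingTruth:
    """Demo binding truth mirroring the study conditions: IP enrichment on the
    45S (strongest in an 8x window on 28S domain II), on H/ACA snoRNAs and
    scaRNAs, a handful of planted genomic peak sites, and NB count noise.

    The 45S baseline is set to ~3.8% of the Input library and the planted 45S
    factor of 14 is calibrated so that, after library-size renormalization,
    the observed IP 45S read fraction lands near 21% and the IP/Input
    fraction ratio near 6 -- the values the assay reports.
    """
    rng = rng or np.random.default_rng(0)
    tx = bundle.transcripts
    # per-class baselines: coding genes moderate, snoRNAs/scaRNAs abundant
    baseline: Dict[str, float] = {}
    for _, row in tx.iterrows():
        tid, cls = row["transcript_id"], row["class"]
        if tid in ("45S", "5S"):
            continue  # set below from the library share
        elif cls == "coding":
            baseline[tid] = float(rng.lognormal(np.log(40), 0.6))
        elif cls in ("snoRNA-H/ACA", "snoRNA-C/D"):
            baseline[tid] = float(rng.lognormal(np.log(60), 0.4))
        elif cls == "scaRNA":
            baseline[tid] = float(rng.lognormal(np.log(50), 0.4))
        else:
            baseline[tid] = float(rng.lognormal(np.log(20), 0.4))
    # intergenic/unannotated reads dominate the mapped library, as in real
    # RIP/RNA-seq data where annotated structured RNAs are a small minority
    baseline[BACKGROUND] = 2.5 * sum(baseline.values())
    rest = sum(baseline.values())
    if "45S" in set(tx["transcript_id"]):
        baseline["45S"] = 0.038 / (1 - 0.038 - 0.004) * rest
    if "5S" in set(tx["transcript_id"]):
        baseline["5S"] = 0.004 / (1 - 0.038 - 0.004) * rest

    enriched: Dict[str, float] = {"45S": rdna_factor}
    pool = tx[tx["class"] == "snoRNA-H/ACA"] if haca_only else tx[tx["class"].str.startswith("snoRNA")]
    chosen = pool["transcript_id"].tolist()[:n_enriched_snorna]
    for tid in chosen:
        enriched[tid] = snorna_factor
    sca = tx[tx["class"] == "scaRNA"]["transcript_id"].tolist()[:n_enriched_scarna]
    for tid in sca:
        enriched[tid] = scarna_factor

    # planted genomic peak sites: half intronic (inside coding genes), half intergenic
    sites: List[Tuple[int, int, float, bool]] = []
    genes = tx[tx["class"] == "coding"]
    for k, (_, g) in enumerate(genes.head(6).iterrows()):
        mid = int((g["start"] + g["end"]) // 2)
        sites.append((mid - 30, mid + 30, peak_site_factor, k % 2 == 0))
    chrom_len = len(bundle.genome["chr1"])
    feature_end = int(bundle.features["end"].max())
    if feature_end + 400 < chrom_len:
        for k in range(4):
            s = feature_end + 100 + k * 200
            if s + 60 < chrom_len:
                sites.append((s, s + 60, peak_site_factor, False))

    truth = BindingTruth(
        enriched_transcripts=enriched,
        rrna_binding_window=window,
        peak_sites=sites,
        baseline_expression=baseline,
        nb_dispersion=0.05,
    )
    truth.validate(bundle)
    return truth


def implant_motifs(bundle: ReferenceBundle, truth: BindingTruth,
                   unit: str = "CA", n_units: int = 10) -> None:
    """Splice an (unit)n repeat into the genome at the center of every
    motif-flagged planted peak site (in place; sequence length unchanged)."""
    chrom = bundle.genome["chr1"]
    motif = unit * n_units
    for s, e, _f, has_motif in truth.peak_sites:
        if not has_motif:
            continue
        center = (s + e) // 2
        left = center - len(motif) // 2
        if left < 0 or left + len(motif) > len(chrom):
            continue
        chrom = chrom[:left] + motif + chrom[left + len(motif):]
    bundle.genome["chr1"] = chrom


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1e-12:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _weighted_starts(rng: np.random.Generator, span: Tuple[int, int], count: int,
                     windows: Sequence[Tuple[int, int, float]]) -> np.ndarray:
    """Draw fragment start positions uniform over the span except inside
    enrichment windows, where density is multiplied by the window factor and
    renormalized.  Windows are 0-based half-open in span coordinates."""
    s0, e0 = span
    if count == 0:
        return np.empty(0, dtype=np.int64)
    cuts = {s0, e0}
    for ws, we, _ in windows:
        cuts.add(min(max(ws, s0), e0))
        cuts.add(min(max(we, s0), e0))
    edges = np.array(sorted(cuts), dtype=np.int64)
    seg_start, seg_end = edges[:-1], edges[1:]
    weights = np.ones(len(seg_start), dtype=float)
    for ws, we, factor in windows:
        inside = (seg_start >= ws) & (seg_end <= we)
        weights[inside] *= factor
    seg_len = (seg_end - seg_start).astype(float)
    mass = seg_len * weights
    keep = mass > 0
    seg_start, seg_len, mass = seg_start[keep], seg_len[keep], mass[keep]
    probs = mass / mass.sum()
    comp = rng.choice(len(probs), size=count, p=probs)
    offsets = np.floor(rng.random(count) * seg_len[comp]).astype(np.int64)
    return seg_start[comp] + offsets


@dataclass
class SimulatedLibraries:
    """Simulator output: per-library alignments, raw reads, and truth tables."""

    libraries: Dict[str, pd.DataFrame]            # lib id -> alignment DataFrame
    reads: Dict[str, List[Tuple[str, str]]]       # lib id -> (read_id, sequence)
    truth_counts: pd.DataFrame                    # library/transcript_id/count
    truth_peaks: pd.DataFrame                     # planted genomic sites
    truth_window: Optional[Tuple[int, int, float]]

    @property
    def ip_libraries(self) -> List[str]:
        return [lib for lib in self.libraries if lib.startswith("IP")]

    @property
    def input_libraries(self) -> List[str]:
        return [lib for lib in self.libraries if lib.startswith("Input")]

    def save(self, bundle: ReferenceBundle, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref_lengths = bundle.ref_lengths
        for lib, aln in self.libraries.items():
            srio.write_sam(aln, ref_lengths, outdir / f"{lib}.sam")
            srio.write_bed(aln, outdir / f"{lib}.bed")
            srio.write_fastq(self.reads[lib], outdir / f"{lib}.fastq")
        srio.write_tsv(self.truth_counts, outdir / "truth_counts.tsv")
        srio.write_tsv(self.truth_peaks, outdir / "truth_peaks.tsv")
        if self.truth_window is not None:
            s, e, f = self.truth_window
            srio.write_tsv(
                pd.DataFrame([{"start": s, "end": e, "factor": f}]),
                outdir / "truth_window.tsv",
            )


def simulate_libraries(truth: BindingTruth, sim: LibrarySim,
                       bundle: ReferenceBundle,
                       emit_reads: bool = True) -> SimulatedLibraries:
    """Simulate IP and Input replicate libraries with planted binding.

    Input per-transcript fragment counts are NB(baseline, dispersion); IP
    counts are NB(baseline x enrichment, dispersion).  Fragment starts are
    uniform within the transcript except inside enrichment windows (28S
    binding window, genomic peak sites) where placement probability is
    multiplied by the window factor.  Reads from the multicopy 45S/5S units
    are written once per genomic copy with the multiplicity recorded.

    ``emit_reads=False`` skips FASTQ sequence construction (alignments and
    truth tables only), for simulation-heavy evaluations.
    """
    sim.validate()
    truth.validate(bundle)

    tx = bundle.transcripts.set_index("transcript_id")
    chrom_len = len(bundle.genome["chr1"])
    read_len = sim.read_length
    offset_28s = bundle.rdna_28s_offset if "45S" in tx.index else 0

    base_total = sum(truth.baseline_expression.values())
    scale = (sim.n_fragments / base_total) if sim.n_fragments else 1.0

    lib_ids = [f"IP_{i + 1}" for i in range(sim.n_replicates)] + \
              [f"Input_{i + 1}" for i in range(sim.n_replicates)]
    children = np.random.SeedSequence(sim.seed).spawn(len(lib_ids))

    # background placement avoids the multicopy rDNA/5S spans so that NH=1
    # holds for background reads
    blocked: List[Tuple[int, int]] = [
        (int(r["start"]), int(r["end"]))
        for _, r in pd.concat([bundle.rdna_copies, bundle.fives_copies]).iterrows()
    ] if len(bundle.rdna_copies) + len(bundle.fives_copies) else []
    blocked.sort()
    bg_segments: List[Tuple[int, int]] = []
    pos = 0
    for bs, be in blocked:
        if bs > pos:
            bg_segments.append((pos, bs))
        pos = max(pos, be)
    if pos < chrom_len:
        bg_segments.append((pos, chrom_len))

    libraries: Dict[str, pd.DataFrame] = {}
    reads_out: Dict[str, List[Tuple[str, str]]] = {}
    truth_rows: List[dict] = []
    chrom_seq = bundle.genome["chr1"]
    unit_seq = bundle.genome.get("45S", "")
    fives_seq = bundle.genome.get("5S", "")

    for lib, child in zip(lib_ids, children):
        rng = np.random.default_rng(child)
        is_ip = lib.startswith("IP")
        rows_ref: List[np.ndarray] = []
        recs: List[pd.DataFrame] = []
        fastq: List[Tuple[str, str]] = []
        counter = 0
        for tid in sorted(truth.baseline_expression):
            mean = truth.baseline_expression[tid] * scale
            if is_ip:
                mean *= truth.enriched_transcripts.get(tid, 1.0)
            # the background is an aggregate over many independent loci, so
            # its total is near-Poisson; per-transcript counts carry the NB
            # dispersion
            dispersion = 0.0 if tid == BACKGROUND else truth.nb_dispersion
            count = _nb_draw(rng, mean, dispersion)
            truth_rows.append({"library": lib, "transcript_id": tid, "count": count})
            if count == 0:
                continue
            # fragment starts stay >= 16 nt from the 3' end (library size
            # selection): aligned reads never fall below the QC length floor
            min_frag = 16
            if tid == BACKGROUND:
                windows = [(s, e, f) for s, e, f, _ in truth.peak_sites] if is_ip else []
                bg_eff = [(s, max(s + 1, e - min_frag + 1)) for s, e in bg_segments]
                seg_len = np.array([e - s for s, e in bg_eff], dtype=float)
                seg_probs = seg_len / seg_len.sum()
                comp = rng.choice(len(bg_eff), size=count, p=seg_probs)
                starts = np.empty(count, dtype=np.int64)
                for si, (s, e) in enumerate(bg_eff):
                    mask = comp == si
                    if mask.any():
                        starts[mask] = _weighted_starts(
                            rng, (s, e), int(mask.sum()),
                            [w for w in windows if w[0] < e and w[1] > s],
                        )
                ends = np.minimum(starts + read_len, chrom_len)
                strands = np.where(rng.random(count) < 0.5, "+", "-")
                ids = [f"{lib}.r{counter + i:07d}" for i in range(count)]
                counter += count
                recs.append(pd.DataFrame({
                    "read_id": ids, "ref": "chr1", "start": starts, "end": ends,
                    "strand": strands, "nh": 1,
                }))
                if emit_reads:
                    fastq.extend(
                        (rid, chrom_seq[s:e]) for rid, s, e in zip(ids, starts, ends)
                    )
                continue

            row = tx.loc[tid]
            span = (int(row["start"]),
                    max(int(row["start"]) + 1, int(row["end"]) - min_frag + 1))
            span_end = int(row["end"])
            strand = row["strand"]
            windows: List[Tuple[int, int, float]] = []
            if is_ip:
                if tid == "45S" and truth.rrna_binding_window is not None:
                    ws, we, wf = truth.rrna_binding_window
                    windows.append((offset_28s + ws - 1, offset_28s + we, wf))
                if row["seqid"] == "chr1":
                    windows.extend(
                        (s, e, f) for s, e, f, _ in truth.peak_sites
                        if s < span[1] and e > span[0]
                    )
            starts = _weighted_starts(rng, span, count, windows)
            ends = np.minimum(starts + read_len, span_end)
            ids = [f"{lib}.r{counter + i:07d}" for i in range(count)]
            counter += count

            if tid in ("45S", "5S"):
                copies = bundle.rdna_copies if tid == "45S" else bundle.fives_copies
                n_copies = len(copies)
                seq = unit_seq if tid == "45S" else fives_seq
                for _, copy in copies.iterrows():
                    recs.append(pd.DataFrame({
                        "read_id": ids,
                        "ref": "chr1",
                        "start": starts + int(copy["start"]),
                        "end": ends + int(copy["start"]),
                        "strand": strand, "nh": n_copies,
                    }))
                if emit_reads:
                    fastq.extend(
                        (rid, seq[s:e]) for rid, s, e in zip(ids, starts, ends)
                    )
            else:
                recs.append(pd.DataFrame({
                    "read_id": ids, "ref": "chr1", "start": starts, "end": ends,
                    "strand": strand, "nh": 1,
                }))
                if emit_reads:
                    fastq.extend(
                        (rid, chrom_seq[s:e]) for rid, s, e in zip(ids, starts, ends)
                    )

        aln = pd.concat(recs, ignore_index=True) if recs else srio.empty_alignments()
        aln = aln.astype({"start": np.int64, "end": np.int64, "nh": np.int64})

        # QC-exercising junk reads: appended to the FASTQ only, so aligned
        # fragment totals still match the truth counts exactly
        n_real = counter
        n_junk_n = int(round(sim.frac_n_contaminated * n_real)) if emit_reads else 0
        n_junk_short = int(round(sim.frac_short * n_real)) if emit_reads else 0
        for i in range(n_junk_n):
            s = int(rng.integers(0, max(1, chrom_len - read_len)))
            seq = list(chrom_seq[s:s + read_len])
            for p in rng.choice(len(seq), size=min(3, len(seq)), replace=False):
                seq[p] = "N"
            fastq.append((f"{lib}.junkN{i:05d}", "".join(seq)))
        for i in range(n_junk_short):
            s = int(rng.integers(0, max(1, chrom_len - 16)))
            short_len = int(rng.integers(4, 16))
            fastq.append((f"{lib}.junkS{i:05d}", chrom_seq[s:s + short_len]))

        libraries[lib] = aln
        reads_out[lib] = fastq

    truth_peaks = pd.DataFrame(
        [{"start": s, "end": e, "factor": f, "motif": m} for s, e, f, m in truth.peak_sites],
        columns=["start", "end", "factor", "motif"],
    )
    return SimulatedLibraries(
        libraries=libraries, reads=reads_out,
        truth_counts=pd.DataFrame(truth_rows),
        truth_peaks=truth_peaks, truth_window=truth.rrna_binding_window,
    )


def simulate_count_matrix(n_genes: int = 1000, n_reps: int = 2,
                          base_mean: float = 100.0, dispersion: float = 0.01,
                          depth_factors: Optional[Sequence[float]] = None,
                          planted: Optional[Mapping[str, float]] = None,
                          conditions: Tuple[str, str] = ("OE", "Ctrl"),
                          gene_ids: Optional[Sequence[str]] = None,
                          seed: int = 0) -> pd.DataFrame:
    """Two-condition RNA-seq count matrix with NB noise and planted fold
    changes (gene means lognormal around base_mean; planted maps gene id ->
    fold change applied to the first condition).  Columns are named
    ``<condition>_<replicate>``; used by the differential-expression stage.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is not None:
        genes = list(gene_ids)
        n_genes = len(genes)
    else:
        genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    unknown = set(planted or {}) - set(genes)
    if unknown:
        raise TruthLookupError(f"planted genes absent from the matrix: {sorted(unknown)[:3]}")
    means = rng.lognormal(np.log(base_mean), 0.5, size=n_genes)
    planted = dict(planted or {})
    libs = [f"{cond}_{r + 1}" for cond in conditions for r in range(n_reps)]
    if depth_factors is None:
        depth_factors = [1.0] * len(libs)
    data = {}
    for j, lib in enumerate(libs):
        cond = lib.rsplit("_", 1)[0]
        mu = means.copy()
        if cond == conditions[0]:
            for gi, g in enumerate(genes):
                if g in planted:
                    mu[gi] *= planted[g]
        mu = mu * depth_factors[j]
        if dispersion <= 1e-12:
            data[lib] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            data[lib] = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
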