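"""IP-enriched peak calling, genomic annotation, and (CA)-repeat enrichment.

The caller is a single defined algorithm: candidate peaks are maximal runs of
positions whose IP depth reaches a minimum, merged across small gaps; each
candidate's empirical p-value comes from a permutation background in which
the same number of reads is placed uniformly on the same reference sequence
and the maximum depth is recorded; enrichment is the Input-normalized density
ratio with a one-read pseudocount on the Input window.  Peaks are annotated
to genomic features at the summit with a fixed priority (CDS > 5'UTR > 3'UTR
> ncRNA exon > intron > antisense > intergenic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .rrna_domain_profile import coverage_profile

ANNOTATION_PRIORITY = [
    "CDS", "5UTR", "3UTR", "ncRNA-exon", "intron", "antisense", "intergenic",
]

PEAK_COLUMNS = [
    "ref", "start", "end", "summit", "ip_count", "input_count",
    "enrichment", "p", "strand",
]


@dataclass(frozen=True)
class PeakCallParams:
    min_depth: int = 10
    merge_gap: int = 10
    n_permutations: int = 200
    alpha: float = 0.05
    min_enrichment: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_enrichment < 1:
            raise ValueError("min_enrichment must be >= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def _candidate_runs(depth: np.ndarray, min_depth: int, merge_gap: int
                    ) -> List[Tuple[int, int]]:
    above = depth >= min_depth
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    merged: List[Tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _count_overlapping(starts: np.ndarray, ends: np.ndarray,
                       lo: int, hi: int) -> int:
    """Number of reads overlapping [lo, hi): start < hi and end > lo."""
    return int(np.count_nonzero((starts < hi) & (ends > lo)))


def _permutation_max_depths(rng: np.random.Generator, read_lengths: np.ndarray,
                            ref_length: int, n_permutations: int) -> np.ndarray:
    """Max single-base depth of reads placed uniformly on the reference, per
    permutation (the max over intervals of any length equals this)."""
    maxima = np.empty(n_permutations, dtype=np.int64)
    n = len(read_lengths)
    for k in range(n_permutations):
        starts = rng.integers(0, np.maximum(1, ref_length - read_lengths + 1))
        ends = np.minimum(starts + read_lengths, ref_length)
        diff = np.zeros(ref_length + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        maxima[k] = np.cumsum(diff)[:ref_length].max() if n else 0
    return maxima


def call_peaks(ip_aln: pd.DataFrame, input_aln: pd.DataFrame,
               ref_lengths: Dict[str, int], params: PeakCallParams
               ) -> pd.DataFrame:
    """Call IP-enriched peaks reference by reference.

    Kept peaks satisfy empirical p < alpha and library-size-normalized
    density enrichment >= min_enrichment (Input window gets a one-read
    pseudocount).  Deterministic under params.seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ip_total = max(int(ip_aln["read_id"].nunique()), 1)
    input_total = max(int(input_aln["read_id"].nunique()), 1)
    rows: List[dict] = []
    for ref in sorted(ip_aln["ref"].unique()):
        if ref not in ref_lengths:
            raise KeyError(f"reference {ref!r} absent from the reference set")
        length = int(ref_lengths[ref])
        ip_ref = ip_aln[ip_aln["ref"] == ref]
        in_ref = input_aln[input_aln["ref"] == ref]
        depth = coverage_profile(ip_ref, length)
        candidates = _candidate_runs(depth, params.min_depth, params.merge_gap)
        if not candidates:
            continue
        read_lengths = (ip_ref["end"] - ip_ref["start"]).to_numpy()
        perm_max = _permutation_max_depths(
            rng, read_lengths, length, params.n_permutations
        )
        ip_starts = ip_ref["start"].to_numpy()
        ip_ends = ip_ref["end"].to_numpy()
        in_starts = in_ref["start"].to_numpy()
        in_ends = in_ref["end"].to_numpy()
        for s, e in candidates:
            window = depth[s:e]
            peak_depth = int(window.max())
            summit = s + int(np.argmax(window))  # leftmost maximum
            p = (1 + int(np.count_nonzero(perm_max >= peak_depth))) / (
                params.n_permutations + 1
            )
            ip_count = _count_overlapping(ip_starts, ip_ends, s, e)
            input_count = _count_overlapping(in_starts, in_ends, s, e)
            enrichment = (ip_count / ip_total) / ((input_count + 1) / input_total)
            if p < params.alpha and enrichment >= params.min_enrichment:
                strands = ip_ref[(ip_starts < e) & (ip_ends > s)]["strand"]
                strand = strands.mode().iloc[0] if len(strands) else "."
                rows.append(
                    {"ref": ref, "start": s, "end": e, "summit": summit,
                     "ip_count": ip_count, "input_count": input_count,
                     "enrichment": enrichment, "p": p, "strand": strand}
                )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


class _FeatureIndex:
    """Summit -> category lookup over the annotation feature table."""

    _TYPE_MAP = {
        "CDS": "CDS",
        "five_prime_UTR": "5UTR",
        "three_prime_UTR": "3UTR",
        "noncoding_exon": "ncRNA-exon",
    }

    def __init__(self, features: pd.DataFrame):
        self.features = features

    def categorize(self, seqid: str, pos: int, strand: str) -> Tuple[str, Optional[str]]:
        f = self.features
        hits = f[(f["seqid"] == seqid) & (f["start"] <= pos) & (pos < f["end"])]
        if len(hits) == 0:
            return "intergenic", None
        same = hits if strand == "." else hits[hits["strand"] == strand]
        best: Optional[Tuple[int, str, str]] = None
        for row in same.itertuples(index=False):
            cat = self._TYPE_MAP.get(row.type)
            if cat is None and row.type == "gene":
                cat = "intron"  # inside the gene; exonic hits outrank it
            if cat is None:
                continue
            rank = ANNOTATION_PRIORITY.index(cat)
            if best is None or rank < best[0]:
                best = (rank, cat, row.gene_id)
        if best is not None:
            return best[1], best[2]
        opposite_genes = hits[hits["type"] == "gene"]
        if len(opposite_genes):
            return "antisense", opposite_genes.iloc[0]["gene_id"]
        return "intergenic", None


def annotate_peaks(peaks: pd.DataFrame, features: pd.DataFrame
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each peak exactly one category (evaluated at the summit) and a
    gene id where applicable; also return the category fraction table."""
    index = _FeatureIndex(features)
    cats: List[str] = []
    genes: List[Optional[str]] = []
    for row in peaks.itertuples(index=False):
        cat, gene = index.categorize(row.ref, int(row.summit), row.strand)
        cats.append(cat)
        genes.append(gene)
    annotated = peaks.copy()
    annotated["category"] = cats
    annotated["gene_id"] = genes
    n = max(len(annotated), 1)
    table = pd.DataFrame(
        [
            {"category": cat, "count": int((annotated["category"] == cat).sum()),
             "fraction": int((annotated["category"] == cat).sum()) / n}
            for cat in ANNOTATION_PRIORITY
        ]
    )
    return annotated, table


def confident_bound_genes(peaks_rep1: pd.DataFrame,
                          peaks_rep2: pd.DataFrame) -> Set[str]:
    """Genes with at least one annotated non-intergenic peak in both replicates."""

    def _genes(peaks: pd.DataFrame) -> Set[str]:
        sel = peaks[(peaks["category"] != "intergenic") & peaks["gene_id"].notna()]
        return set(sel["gene_id"])

    return _genes(peaks_rep1) & _genes(peaks_rep2)


def max_ca_run(sequence: str) -> int:
    """Maximal (CA)n run length in dinucleotide units, scanning both strands
    and both phases (CA/AC on the forward strand, TG/GT for the reverse)."""
    seq = sequence.upper()
    best = 0
    for pattern in (_CA_RE, _AC_RE, _TG_RE, _GT_RE):
        for match in pattern.finditer(seq):
            best = max(best, (match.end() - match.start()) // 2)
    return best


_CA_RE = re.compile(r"(?:CA)+")
_AC_RE = re.compile(r"(?:AC)+")
_TG_RE = re.compile(r"(?:TG)+")
_GT_RE = re.compile(r"(?:GT)+")


def _dinucleotide_shuffle(rng: np.random.Generator, seq: str) -> str:
    tiles = [seq[i:i + 2] for i in range(0, len(seq) - 1, 2)]
    tail = seq[len(tiles) * 2:]
    rng.shuffle(tiles)
    return "".join(tiles) + tail


def ca_repeat_enrichment(peak_sequences: Sequence[str], min_run: int = 5,
                         n_shuffles: int = 100, seed: int = 0) -> dict:
    """Test whether peak sequences are enriched for (CA)n repeats.

    Statistic: fraction of peaks containing a run of >= min_run CA units
    (n >= 3 runs are tabulated in the length distribution).  Null: the same
    statistic on dinucleotide-tile-shuffled copies of the peak sequences.
    Returns the run-length distribution, z-score and empirical p.
    """
    if not peak_sequences:
        raise ValueError("no peak sequences supplied")
    rng = np.random.default_rng(seed)
    runs = np.array([max_ca_run(s) for s in peak_sequences])
    observed = float(np.mean(runs >= min_run))
    null_stats = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = [_dinucleotide_shuffle(rng, s) for s in peak_sequences]
        null_stats[k] = np.mean([max_ca_run(s) >= min_run for s in shuffled])
    sd = float(null_stats.std(ddof=1))
    z = (observed - float(null_stats.mean())) / sd if sd > 0 else (
        0.0 if observed == float(null_stats.mean()) else np.inf
    )
    p = (1 + int(np.count_nonzero(null_stats >= observed))) / (n_shuffles + 1)
    lengths, counts = np.unique(runs[runs >= 3], return_counts=True)
    distribution = pd.DataFrame({"run_length": lengths, "n_peaks": counts})
    return {
        "fraction_observed": observed,
        "null_mean": float(null_stats.mean()),
        "null_sd": sd,
        "z": float(z),
        "p": float(p),
        "run_length_distribution": distribution,
    }


def extract_peak_sequences(peaks: pd.DataFrame, genome: Dict[str, str]) -> List[str]:
    seqs = []
    for row in peaks.itertuples(index=False):
        seq = genome.get(row.ref)
        if seq is None or row.end > len(seq) or row.start < 0:
            raise ValueError(f"peak {row.ref}:{row.start}-{row.end} outside the genome")
        seqs.append(seq[int(row.start):int(row.end)])
    return seqs
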