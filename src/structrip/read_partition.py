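"""QC filtering and read partitioning.

Mirrors the first analysis stages of a RIP-seq workflow: raw reads with more
than 2 N bases are discarded, then reads shorter than 16 nt; alignments are
split into uniquely versus multiply mapped read ids; multi-mapped reads are
assigned to structured-RNA classes (rRNA, snoRNA, scaRNA, ...) and reads on
the 45S rDNA unit are partitioned into its subregions (5'ETS, 18S, ITS1,
5.8S, ITS2, 28S, 3'ETS) by read midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic_data import ReferenceBundle

#: deterministic tie-break priority among structured-RNA classes when a
#: multi-mapped read places equally well on several references
CLASS_PRIORITY = [
    "rRNA", "snoRNA", "scaRNA", "snRNA", "tRNA", "miRNA", "lincRNA", "other",
]


class DataIntegrityError(ValueError):
    """Inconsistent multiplicity across the records of one read."""


class ConfigurationError(KeyError):
    """A reference id is missing from the class table."""


class SubregionAssignmentError(ValueError):
    """A read lies outside the 45S unit: the interval table is malformed."""


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_n: int = 0
    n_removed_short: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_n - self.n_removed_short


def qc_filter_reads(reads: Iterable[Tuple[str, str]],
                    max_n: int = 2, min_length: int = 16
                    ) -> Tuple[List[Tuple[str, str]], FilterReport]:
    """Drop reads with more than ``max_n`` N bases, then reads shorter than
    ``min_length`` nt (rule order is fixed: N-filter first)."""
    report = FilterReport()
    kept: List[Tuple[str, str]] = []
    for read_id, seq in reads:
        report.n_input += 1
        if seq.upper().count("N") > max_n:
            report.n_removed_n += 1
            continue
        if len(seq) < min_length:
            report.n_removed_short += 1
            continue
        kept.append((read_id, seq))
    return kept, report


def partition_by_multiplicity(aln: pd.DataFrame
                              ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int]]:
    """Split alignments into uniquely (NH=1) and multiply (NH>1) mapped sets.

    Counting is per read id, not per placement.  Raises DataIntegrityError if
    a read's records disagree on multiplicity.
    """
    if len(aln) == 0:
        return aln.copy(), aln.copy(), {"total": 0, "unique": 0, "multi": 0}
    nh_per_read = aln.groupby("read_id", sort=False)["nh"]
    bad = nh_per_read.nunique() > 1
    if bad.any():
        offender = bad[bad].index[0]
        raise DataIntegrityError(
            f"read {offender!r} has inconsistent multiplicity across its records"
        )
    nh = nh_per_read.first()
    unique_ids = set(nh[nh == 1].index)
    is_unique = aln["read_id"].isin(unique_ids)
    unique = aln[is_unique].reset_index(drop=True)
    multi = aln[~is_unique].reset_index(drop=True)
    counts = {
        "total": int(nh.size),
        "unique": int((nh == 1).sum()),
        "multi": int((nh > 1).sum()),
    }
    return unique, multi, counts


def _base_class(cls: str) -> str:
    """Collapse box-typed snoRNA labels onto the priority vocabulary."""
    if cls.startswith("snoRNA"):
        return "snoRNA"
    return cls if cls in CLASS_PRIORITY else "other"


@dataclass
class ReadClassSummary:
    """Per-library class composition of the multi-mapped read set."""

    library: str
    counts: Dict[str, int] = field(default_factory=dict)
    n_total: int = 0
    n_unique: int = 0
    n_multi: int = 0
    n_unassigned: int = 0

    @property
    def fractions(self) -> Dict[str, float]:
        assigned = sum(self.counts.values())
        if assigned == 0:
            return {}
        return {cls: n / assigned for cls, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame(
            [
                {"library": self.library, "class": cls,
                 "count": n, "fraction": fr.get(cls, 0.0)}
                for cls, n in sorted(self.counts.items())
            ]
        )


def assign_ncrna_class(multi: pd.DataFrame, bundle: ReferenceBundle,
                       class_table: Optional[pd.DataFrame] = None,
                       library: str = "", counts: Optional[Mapping[str, int]] = None
                       ) -> ReadClassSummary:
    """Assign each multi-mapped read to exactly one structured-RNA class.

    Placements may sit directly on a structured reference (id present in the
    class table) or on the genome, in which case the containing annotated
    ncRNA feature supplies the class.  Ties across placements are broken by
    CLASS_PRIORITY, then lexicographically by reference id.  Reads matching
    no structured reference are counted as unassigned.
    """
    class_table = class_table if class_table is not None else bundle.class_table
    cls_by_ref = dict(zip(class_table["transcript_id"], class_table["class"]))
    # every structured reference id must have a class row
    for tid in bundle.class_table["transcript_id"]:
        if tid not in cls_by_ref:
            raise ConfigurationError(f"reference {tid!r} missing from class table")

    # genomic interval lookup for ncRNA features (including rDNA copy spans)
    nc = bundle.transcripts[bundle.transcripts["class"] != "coding"]
    spans: List[Tuple[int, int, str]] = []  # (start, end, transcript_id)
    for _, row in nc.iterrows():
        if row["seqid"] == "chr1":
            spans.append((int(row["start"]), int(row["end"]), row["transcript_id"]))
    for _, row in bundle.rdna_copies.iterrows():
        spans.append((int(row["start"]), int(row["end"]), "45S"))
    for _, row in bundle.fives_copies.iterrows():
        spans.append((int(row["start"]), int(row["end"]), "5S"))
    spans.sort()
    span_starts = np.array([s for s, _, _ in spans], dtype=np.int64)
    span_ends = np.array([e for _, e, _ in spans], dtype=np.int64)
    span_ids = [t for _, _, t in spans]

    summary = ReadClassSummary(library=library)
    if counts:
        summary.n_total = counts.get("total", 0)
        summary.n_unique = counts.get("unique", 0)
        summary.n_multi = counts.get("multi", 0)

    if len(multi) == 0:
        return summary

    # vectorized placement -> transcript id: direct structured-reference hits
    # first, then genomic midpoint containment in ncRNA feature spans
    refs = multi["ref"].to_numpy()
    tid_col = np.where(multi["ref"].isin(cls_by_ref).to_numpy(), refs, "")
    genomic = (tid_col == "") & (refs == "chr1")
    if genomic.any() and len(span_starts):
        mid = ((multi["start"].to_numpy() + multi["end"].to_numpy()) // 2)[genomic]
        idx = np.searchsorted(span_starts, mid, side="right") - 1
        ok = (idx >= 0) & (mid < span_ends[np.clip(idx, 0, len(span_ends) - 1)])
        hits = np.full(mid.shape, "", dtype=object)
        hits[ok] = np.array(span_ids, dtype=object)[idx[ok]]
        tid_col = tid_col.astype(object)
        tid_col[genomic] = hits

    priority = {cls: i for i, cls in enumerate(CLASS_PRIORITY)}
    placed = pd.DataFrame({"read_id": multi["read_id"].to_numpy(), "tid": tid_col})
    placed["cls"] = placed["tid"].map(
        lambda t: _base_class(cls_by_ref[t]) if t else ""
    )
    placed["rank"] = placed["cls"].map(lambda c: priority.get(c, len(priority)) if c else 99)
    best = (
        placed.sort_values(["read_id", "rank", "tid"], kind="mergesort")
        .drop_duplicates(subset="read_id", keep="first")
    )
    assigned = best[best["cls"] != ""]
    summary.counts = assigned["cls"].value_counts().to_dict()
    summary.n_unassigned = int((best["cls"] == "").sum())
    return summary


def collapse_rdna(aln: pd.DataFrame, bundle: ReferenceBundle,
                  unit: str = "45S") -> pd.DataFrame:
    """Collapse multi-mapped rDNA placements to one record per read on the
    single 45S (or 5S) consensus unit, in unit-local coordinates."""
    copies = bundle.rdna_copies if unit == "45S" else bundle.fives_copies
    out: List[pd.DataFrame] = []
    direct = aln[aln["ref"] == unit]
    if len(direct):
        out.append(direct[["read_id", "start", "end", "strand", "nh"]])
    genomic = aln[aln["ref"] == "chr1"]
    if len(genomic) and len(copies):
        starts = genomic["start"].to_numpy()
        ends = genomic["end"].to_numpy()
        for _, copy in copies.iterrows():
            cs, ce = int(copy["start"]), int(copy["end"])
            mask = (starts >= cs) & (ends <= ce)
            if mask.any():
                sub = genomic[mask].copy()
                sub["start"] = sub["start"] - cs
                sub["end"] = sub["end"] - cs
                out.append(sub[["read_id", "start", "end", "strand", "nh"]])
    if not out:
        return pd.DataFrame(columns=["read_id", "start", "end", "strand", "nh"])
    merged = pd.concat(out, ignore_index=True)
    merged = merged.drop_duplicates(subset="read_id", keep="first").reset_index(drop=True)
    merged.insert(1, "ref", unit)
    return merged


def assign_rdna_subregion(unit_reads: pd.DataFrame, rdna_intervals: pd.DataFrame
                          ) -> pd.DataFrame:
    """Assign each 45S-unit read to the subregion containing its midpoint.

    ``rdna_intervals`` holds 1-based closed intervals tiling the unit.
    Returns a table (subregion, count, fraction) in unit order.
    """
    starts1 = rdna_intervals["start"].to_numpy()
    ends1 = rdna_intervals["end"].to_numpy()
    names = rdna_intervals["name"].tolist()
    if len(unit_reads):
        mid0 = ((unit_reads["start"] + unit_reads["end"]) // 2).to_numpy()
        mid1 = mid0 + 1  # to 1-based residue numbering
        idx = np.searchsorted(starts1, mid1, side="right") - 1
        bad = (idx < 0) | (mid1 > ends1[np.clip(idx, 0, len(ends1) - 1)])
        if bad.any():
            pos = int(mid1[bad][0])
            raise SubregionAssignmentError(
                f"read midpoint {pos} outside the 45S unit intervals"
            )
        counts = np.bincount(idx, minlength=len(names))
    else:
        counts = np.zeros(len(names), dtype=int)
    total = counts.sum()
    return pd.DataFrame(
        {
            "subregion": names,
            "count": counts,
            "fraction": counts / total if total else np.zeros(len(names)),
        }
    )


def library_partition_summary(aln: pd.DataFrame, bundle: ReferenceBundle,
                              library: str = "") -> dict:
    """One-call partition of a library: multiplicity split, ncRNA classes of
    the multi set, and 45S subregion fractions.  Returns a plain dict used by
    the pipeline report and TSV writers."""
    unique, multi, counts = partition_by_multiplicity(aln)
    summary = assign_ncrna_class(multi, bundle, library=library, counts=counts)
    unit_reads = collapse_rdna(multi, bundle, unit="45S")
    subregions = assign_rdna_subregion(unit_reads, bundle.rdna_intervals)
    fives = collapse_rdna(multi, bundle, unit="5S")
    return {
        "library": library,
        "counts": counts,
        "class_summary": summary,
        "n_45s_reads": int(unit_reads["read_id"].nunique()) if len(unit_reads) else 0,
        "n_5s_reads": int(fives["read_id"].nunique()) if len(fives) else 0,
        "subregions": subregions,
        "unique": unique,
        "multi": multi,
    }
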