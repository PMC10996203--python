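"""Per-transcript abundance, IP-vs-Input enrichment, and gene-set overlap.

Abundance is FPKM (fragments per kilobase of transcript per million mapped
fragments) computed from uniquely mapped reads.  Enrichment per transcript
uses a two-sided Fisher's exact test on pooled IP/Input counts together with
an FPKM fold change; a transcript is called enriched when fold change >= 2
and p < 0.05 (configurable).  Gene-set overlaps are tested with the
upper-tail hypergeometric distribution, and multiple testing uses the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

EPS_FPKM = 0.01  # pseudo-FPKM for fold-change stability
EXPRESSED_FLOOR = 1.0  # Input FPKM floor defining an "expressed" transcript


class MembershipError(ValueError):
    """A set element lies outside the declared universe."""


def compute_fpkm(count, length, library_total):
    """FPKM = count / (length/1000) / (library_total/1e6); exact arithmetic.

    Vectorized over numpy arrays / pandas Series.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("transcript length must be > 0")
    if library_total <= 0:
        raise ValueError("library total must be > 0")
    return np.asarray(count, dtype=float) / (length / 1e3) / (library_total / 1e6)


def count_reads_per_transcript(unique_aln: pd.DataFrame,
                               transcripts: pd.DataFrame) -> pd.Series:
    """Count uniquely mapped reads per transcript by midpoint containment in
    the transcript span (one count per read id)."""
    counts = pd.Series(0, index=transcripts["transcript_id"], dtype=np.int64)
    if len(unique_aln) == 0:
        return counts
    genomic = transcripts[transcripts["seqid"] == "chr1"].sort_values("start")
    starts = genomic["start"].to_numpy()
    ends = genomic["end"].to_numpy()
    tids = genomic["transcript_id"].to_numpy()
    aln = unique_aln.drop_duplicates(subset="read_id")
    on_chr = aln[aln["ref"] == "chr1"]
    if len(on_chr) and len(starts):
        mid = ((on_chr["start"] + on_chr["end"]) // 2).to_numpy()
        idx = np.searchsorted(starts, mid, side="right") - 1
        ok = (idx >= 0) & (mid < ends[np.clip(idx, 0, len(ends) - 1)])
        hit = pd.Series(tids[idx[ok]]).value_counts()
        counts.loc[hit.index] += hit.to_numpy().astype(np.int64)
    direct = aln[aln["ref"] != "chr1"]
    if len(direct):
        hit = direct["ref"].value_counts()
        shared = hit.index.intersection(counts.index)
        counts.loc[shared] += hit.loc[shared].to_numpy().astype(np.int64)
    return counts


def test_enrichment(ip_count: int, input_count: int,
                    ip_total: int, input_total: int,
                    length: Optional[float] = None,
                    eps: float = EPS_FPKM) -> Tuple[float, float]:
    """Fold change and p-value for one transcript.

    Fold change = (IP FPKM + eps) / (Input FPKM + eps); when length is None a
    length of 1 kb is used (the length cancels between libraries only through
    the pseudocount).  p is the two-sided Fisher's exact probability on the
    2x2 table [[ip, ip_total-ip], [input, input_total-input]].
    """
    if ip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be > 0")
    if ip_count > ip_total or input_count > input_total:
        raise ValueError("count exceeds library total")
    if ip_count == 0 and input_count == 0:
        return 1.0, 1.0
    length = 1000.0 if length is None else length
    fpkm_ip = float(compute_fpkm(ip_count, length, ip_total))
    fpkm_in = float(compute_fpkm(input_count, length, input_total))
    fc = (fpkm_ip + eps) / (fpkm_in + eps)
    table = [[ip_count, ip_total - ip_count], [input_count, input_total - input_count]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return fc, float(p)


def quantify(ip_counts: Mapping[str, pd.Series], input_counts: Mapping[str, pd.Series],
             transcripts: pd.DataFrame, fc_cut: float = 2.0, p_cut: float = 0.05,
             eps: float = EPS_FPKM, expressed_floor: float = EXPRESSED_FLOOR,
             ip_library_total: Optional[int] = None,
             input_library_total: Optional[int] = None) -> pd.DataFrame:
    """Build the per-transcript quantification table (GeneQuant rows).

    ``ip_counts`` / ``input_counts`` map replicate library id -> per-transcript
    read counts.  Replicates are pooled for the Fisher test; per-replicate
    counts are kept as columns.  Library totals are the number of uniquely
    mapped fragments per pooled condition (the FPKM denominator includes
    fragments mapped outside the quantified transcripts); they default to the
    pooled transcript-assigned counts when not given.
    """
    tx = transcripts.set_index("transcript_id")
    out = pd.DataFrame(index=tx.index)
    out["class"] = tx["class"]
    out["box_type"] = tx["box_type"]
    out["length"] = tx["length"]
    ip_pooled = sum(s.reindex(out.index).fillna(0) for s in ip_counts.values())
    in_pooled = sum(s.reindex(out.index).fillna(0) for s in input_counts.values())
    for lib, s in {**ip_counts, **input_counts}.items():
        out[f"count_{lib}"] = s.reindex(out.index).fillna(0).astype(np.int64)
    ip_total = int(ip_library_total) if ip_library_total else int(ip_pooled.sum())
    in_total = int(input_library_total) if input_library_total else int(in_pooled.sum())
    out["ip_count"] = ip_pooled.astype(np.int64)
    out["input_count"] = in_pooled.astype(np.int64)
    out["ip_fpkm"] = compute_fpkm(ip_pooled, out["length"], max(ip_total, 1))
    out["input_fpkm"] = compute_fpkm(in_pooled, out["length"], max(in_total, 1))
    fc = np.empty(len(out))
    pvals = np.empty(len(out))
    for i, (tid, row) in enumerate(out.iterrows()):
        fc[i], pvals[i] = test_enrichment(
            int(row["ip_count"]), int(row["input_count"]),
            ip_total, in_total, length=float(row["length"]), eps=eps,
        )
    out["fold_change"] = fc
    out["p"] = pvals
    out["q"] = bh_adjust(pvals)
    out["expressed"] = out["input_fpkm"] >= expressed_floor
    out["enriched"] = (out["fold_change"] >= fc_cut) & (out["p"] < p_cut)
    return out.reset_index().rename(columns={"index": "transcript_id"})


def top_abundant(quants: pd.DataFrame, n: int = 100,
                 rank_by: str = "ip_fpkm") -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Top-n transcripts by abundance (ties broken by transcript id) plus the
    class composition of that list."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ordered = quants.sort_values(
        [rank_by, "transcript_id"], ascending=[False, True]
    ).head(n)
    composition = (
        ordered.groupby("class").size().rename("count").reset_index()
        .sort_values("class").reset_index(drop=True)
    )
    return ordered.reset_index(drop=True), composition


def class_enrichment_summary(quants: pd.DataFrame) -> pd.DataFrame:
    """Per-class (and per snoRNA box type) counts of expressed and enriched
    transcripts with the enriched fraction; fraction is NA when no transcript
    of the class is expressed."""
    rows = []

    def _summarize(label: str, sub: pd.DataFrame) -> None:
        expressed = sub[sub["expressed"]]
        n_exp = len(expressed)
        n_enr = int(expressed["enriched"].sum())
        rows.append(
            {"group": label, "n_expressed": n_exp, "n_enriched": n_enr,
             "fraction": n_enr / n_exp if n_exp else np.nan}
        )

    for cls, sub in quants.groupby("class"):
        _summarize(cls, sub)
    sno = quants[quants["class"].str.startswith("snoRNA")]
    if len(sno):
        _summarize("snoRNA (all)", sno)
        for box, sub in sno.groupby("box_type"):
            _summarize(f"snoRNA {box}", sub)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    p: float


def hypergeometric_overlap(set_a: Set, set_b: Set, universe: Set) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets:
    p = P[X >= |A n B|] with X ~ Hypergeom(N, |A|, |B|)."""
    universe = set(universe)
    for label, s in (("A", set_a), ("B", set_b)):
        extra = set(s) - universe
        if extra:
            raise MembershipError(
                f"set {label} has {len(extra)} element(s) outside the universe"
            )
    n, a, b = len(universe), len(set_a), len(set_b)
    k = len(set(set_a) & set(set_b))
    p = float(stats.hypergeom.sf(k - 1, n, a, b))
    return OverlapResult(n_a=a, n_b=b, n_overlap=k, universe=n, p=min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
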