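"""Peak caller behaviour, annotation priority, and the (CA)-repeat scan."""

import numpy as np
import pandas as pd
import pytest

from structrip.peak_calling import (
    PeakCallParams, annotate_peaks, ca_repeat_enrichment, call_peaks,
    confident_bound_genes, extract_peak_sequences, max_ca_run,
)


def _uniform_lib(rng, tag, n_reads, ref_len, read_len=50, ref="T"):
    starts = rng.integers(0, ref_len - read_len + 1, size=n_reads)
    return pd.DataFrame({
        "read_id": [f"{tag}{i}" for i in range(n_reads)],
        "ref": ref, "start": starts, "end": starts + read_len,
        "strand": "+", "nh": 1,
    })


def _planted_lib(rng, tag, n_reads, ref_len, site, factor, read_len=50):
    weights = np.ones(ref_len - read_len + 1)
    lo, hi = max(0, site[0]), min(len(weights), site[1])
    weights[lo:hi] *= factor
    starts = rng.choice(len(weights), size=n_reads, p=weights / weights.sum())
    return pd.DataFrame({
        "read_id": [f"{tag}{i}" for i in range(n_reads)],
        "ref": "T", "start": starts, "end": starts + read_len,
        "strand": "+", "nh": 1,
    })


def test_min_depth_above_coverage_gives_no_peaks():
    rng = np.random.default_rng(0)
    ip = _uniform_lib(rng, "i", 100, 2000)
    params = PeakCallParams(min_depth=500, n_permutations=100, seed=0)
    peaks = call_peaks(ip, _uniform_lib(rng, "c", 100, 2000), {"T": 2000}, params)
    assert len(peaks) == 0


def test_planted_site_recovered_with_overlap():
    site = (1000, 1060)
    recovered = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        ip = _planted_lib(rng, "i", 2000, 2000, site, 10.0)
        inp = _uniform_lib(rng, "c", 2000, 2000)
        params = PeakCallParams(min_depth=100, merge_gap=10, n_permutations=200,
                                alpha=0.01, min_enrichment=3.0, seed=seed)
        peaks = call_peaks(ip, inp, {"T": 2000}, params)
        for row in peaks.itertuples(index=False):
            ov = max(0, min(row.end, site[1]) - max(row.start, site[0]))
            if ov and min(ov / (row.end - row.start), ov / 60) >= 0.5:
                recovered += 1
                break
    assert recovered >= 9


def test_peaks_nonoverlapping_and_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    ip = _planted_lib(rng, "i", 2000, 2000, (500, 560), 8.0)
    inp = _uniform_lib(rng, "c", 2000, 2000)
    loose = PeakCallParams(min_depth=60, merge_gap=10, n_permutations=200,
                           alpha=0.20, min_enrichment=1.0, seed=11)
    strict_alpha = PeakCallParams(min_depth=60, merge_gap=10, n_permutations=200,
                                  alpha=0.01, min_enrichment=1.0, seed=11)
    strict_enr = PeakCallParams(min_depth=60, merge_gap=10, n_permutations=200,
                                alpha=0.20, min_enrichment=4.0, seed=11)
    p_loose = call_peaks(ip, inp, {"T": 2000}, loose)
    # merged intervals do not overlap
    sorted_peaks = p_loose.sort_values("start")
    assert (sorted_peaks["start"].to_numpy()[1:]
            >= sorted_peaks["end"].to_numpy()[:-1]).all()
    assert len(call_peaks(ip, inp, {"T": 2000}, strict_alpha)) <= len(p_loose)
    assert len(call_peaks(ip, inp, {"T": 2000}, strict_enr)) <= len(p_loose)


def test_null_pvalues_super_uniform():
    """Under IP == Input uniform placement, candidate p-values are
    super-uniform: P(p <= t) <= t up to binomial noise."""
    pvals = []
    params = PeakCallParams(min_depth=10, merge_gap=10, n_permutations=100,
                            alpha=0.999, min_enrichment=1.0, seed=5)
    for seed in range(60):
        rng = np.random.default_rng(500 + seed)
        ip = _uniform_lib(rng, "i", 800, 2000)
        inp = _uniform_lib(rng, "c", 800, 2000)
        peaks = call_peaks(ip, inp, {"T": 2000}, params)
        pvals.append(peaks["p"].min() if len(peaks) else 1.0)
    pvals = np.array(pvals)
    for t in (0.05, 0.10, 0.20):
        bound = t + 3 * np.sqrt(t * (1 - t) / len(pvals))
        assert (pvals <= t).mean() <= bound, f"anti-conservative at t={t}"


def _features():
    rows = [
        # gene A (+): exon [0,300) with CDS [50,250), UTRs at the ends
        {"seqid": "T", "type": "gene", "start": 0, "end": 300, "strand": "+",
         "feature_id": "A", "gene_id": "A"},
        {"seqid": "T", "type": "exon", "start": 0, "end": 300, "strand": "+",
         "feature_id": "A.e", "gene_id": "A"},
        {"seqid": "T", "type": "five_prime_UTR", "start": 0, "end": 50, "strand": "+",
         "feature_id": "A.u5", "gene_id": "A"},
        {"seqid": "T", "type": "CDS", "start": 50, "end": 250, "strand": "+",
         "feature_id": "A.c", "gene_id": "A"},
        {"seqid": "T", "type": "three_prime_UTR", "start": 250, "end": 300, "strand": "+",
         "feature_id": "A.u3", "gene_id": "A"},
        # gene B (-) overlapping A's CDS region -> antisense candidates
        {"seqid": "T", "type": "gene", "start": 100, "end": 400, "strand": "-",
         "feature_id": "B", "gene_id": "B"},
        # ncRNA gene C (+)
        {"seqid": "T", "type": "gene", "start": 500, "end": 600, "strand": "+",
         "feature_id": "C", "gene_id": "C"},
        {"seqid": "T", "type": "noncoding_exon", "start": 500, "end": 600, "strand": "+",
         "feature_id": "C.e", "gene_id": "C"},
        # gene D (+) with an intronic stretch [700,780) not covered by exons
        {"seqid": "T", "type": "gene", "start": 650, "end": 850, "strand": "+",
         "feature_id": "D", "gene_id": "D"},
        {"seqid": "T", "type": "exon", "start": 650, "end": 700, "strand": "+",
         "feature_id": "D.e1", "gene_id": "D"},
        {"seqid": "T", "type": "exon", "start": 780, "end": 850, "strand": "+",
         "feature_id": "D.e2", "gene_id": "D"},
    ]
    return pd.DataFrame(rows)


def _peak(summit, strand="+"):
    return {"ref": "T", "start": summit - 20, "end": summit + 20, "summit": summit,
            "ip_count": 50, "input_count": 5, "enrichment": 5.0, "p": 0.001,
            "strand": strand}


@pytest.mark.parametrize(
    "summit,strand,category,gene",
    [
        (150, "+", "CDS", "A"),          # CDS wins although antisense to B
        (150, "-", "intron", "B"),       # minus-strand summit: B gene body
        (20, "+", "5UTR", "A"),
        (270, "+", "3UTR", "A"),
        (550, "+", "ncRNA-exon", "C"),
        (730, "+", "intron", "D"),
        (350, "+", "antisense", "B"),    # only opposite-strand gene B here
        (950, "+", "intergenic", None),
    ],
)
def test_annotation_priority(summit, strand, category, gene):
    peaks = pd.DataFrame([_peak(summit, strand)])
    annotated, table = annotate_peaks(peaks, _features())
    assert annotated["category"].iloc[0] == category
    assert annotated["gene_id"].iloc[0] == gene
    assert table["fraction"].sum() == pytest.approx(1.0)


def test_confident_bound_genes_intersection():
    rep1 = pd.DataFrame([
        {**_peak(150), "category": "CDS", "gene_id": "A"},
        {**_peak(550), "category": "ncRNA-exon", "gene_id": "C"},
        {**_peak(950), "category": "intergenic", "gene_id": None},
    ])
    rep2 = pd.DataFrame([
        {**_peak(160), "category": "CDS", "gene_id": "A"},
        {**_peak(960), "category": "intergenic", "gene_id": None},
    ])
    assert confident_bound_genes(rep1, rep2) == {"A"}


def test_max_ca_run_examples():
    assert max_ca_run("TTCACACACATT") == 4
    assert max_ca_run("ACACAC") == 3          # AC phase
    assert max_ca_run("TGTGTGTGTG") == 5      # reverse strand
    assert max_ca_run("GGGG") == 0


def test_ca_enrichment_detects_planted_repeat():
    rng = np.random.default_rng(2)
    bases = np.array(list("ACGT"))
    def rand_seq(n):
        return "".join(bases[rng.integers(0, 4, n)])
    hits = 0
    for seed in range(5):
        peaks = [rand_seq(40) + "CA" * 10 + rand_seq(40) for _ in range(20)]
        peaks += [rand_seq(100) for _ in range(20)]
        res = ca_repeat_enrichment(peaks, min_run=5, n_shuffles=200, seed=seed)
        if res["p"] < 0.01:
            hits += 1
    assert hits == 5


def test_ca_enrichment_null_z_bounded():
    rng = np.random.default_rng(9)
    bases = np.array(list("ACGT"))
    zs = []
    for seed in range(5):
        peaks = ["".join(bases[rng.integers(0, 4, 120)]) for _ in range(30)]
        res = ca_repeat_enrichment(peaks, min_run=4, n_shuffles=100, seed=seed)
        if np.isfinite(res["z"]):
            zs.append(res["z"])
    assert all(abs(z) <= 3 for z in zs)


def test_extract_peak_sequences_bounds():
    genome = {"T": "ACGT" * 100}
    peaks = pd.DataFrame([{"ref": "T", "start": 390, "end": 410}])
    with pytest.raises(ValueError):
        extract_peak_sequences(peaks, genome)
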