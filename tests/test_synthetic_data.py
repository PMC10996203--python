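"""Generator contracts: determinism, planted-truth conservation, NB means."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from structrip.synthetic_data import (
    BACKGROUND, BindingTruth, GenomeSpec, LibrarySim, SizingError,
    TruthLookupError, build_reference, default_truth, load_reference,
    simulate_count_matrix, simulate_libraries,
)


def test_rdna_copies_are_sequence_identical(bundle):
    chrom = bundle.genome["chr1"]
    seqs = {
        chrom[int(r["start"]):int(r["end"])]
        for _, r in bundle.rdna_copies.iterrows()
    }
    assert len(bundle.rdna_copies) == 3
    assert len(seqs) == 1
    assert seqs.pop() == bundle.genome["45S"]


def test_class_table_counts_and_annotation_coverage(bundle):
    sno = bundle.class_table[bundle.class_table["class"].str.startswith("snoRNA")]
    assert len(sno) == 37  # 20 H/ACA + 17 C/D
    annotated = set(bundle.transcripts["transcript_id"])
    assert set(bundle.class_table["transcript_id"]) <= annotated


def test_same_seed_byte_identical_outputs(compact_spec, tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    build_reference(compact_spec).save(d1)
    build_reference(compact_spec).save(d2)
    for name in ("genome.fa", "annotation.gff3", "classes.tsv"):
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name


def test_load_reference_roundtrip(bundle, tmp_path):
    bundle.save(tmp_path / "ref")
    loaded = load_reference(tmp_path / "ref")
    assert loaded.genome["45S"] == bundle.genome["45S"]
    pd.testing.assert_frame_equal(
        loaded.transcripts.reset_index(drop=True),
        bundle.transcripts.reset_index(drop=True),
    )
    assert loaded.rdna_28s_offset == bundle.rdna_28s_offset


def test_infeasible_spec_raises_sizing_error():
    with pytest.raises(SizingError):
        GenomeSpec(intergenic_fraction=1.0).validate()
    with pytest.raises(SizingError):
        GenomeSpec(rdna_subregions=(("5ETS", 40), ("28S", 5070))).validate()


def test_truth_unknown_transcript_rejected(bundle):
    truth = BindingTruth(baseline_expression={"NOPE": 10.0})
    with pytest.raises(TruthLookupError):
        truth.validate(bundle)


def test_truth_counts_match_simulated_fragments(bundle, truth, sim_result):
    """Conservation: per-library truth counts sum to the simulated fragment
    total (junk QC reads live only in the FASTQ)."""
    tc = sim_result.truth_counts
    for lib, aln in sim_result.libraries.items():
        planted_total = int(tc[tc["library"] == lib]["count"].sum())
        assert aln["read_id"].nunique() == planted_total


def test_simulated_reads_stay_inside_reference(bundle, sim_result):
    chrom_len = len(bundle.genome["chr1"])
    for aln in sim_result.libraries.values():
        assert (aln["start"] >= 0).all()
        assert (aln["end"] <= chrom_len).all()
        assert ((aln["end"] - aln["start"]) >= 16).all()


def test_nb_mean_matches_planted_enrichment():
    """Transcript with baseline 100 and IP factor 8: mean simulated IP count
    approaches 800, within 3 standard errors over 200 seeds."""
    spec = GenomeSpec(n_coding_genes=1, gene_length_range=(1500, 1500),
                      n_rdna_copies=0, n_5s_copies=0, n_snorna_haca=0,
                      n_snorna_cd=0, n_scarna=0, n_mirna=0, seed=3)
    b = build_reference(spec)
    tid = b.transcripts["transcript_id"].iloc[0]
    truth = BindingTruth(baseline_expression={tid: 100.0},
                         enriched_transcripts={tid: 8.0}, nb_dispersion=0.05)
    counts = []
    for seed in range(200):
        sim = LibrarySim(n_fragments=None, n_replicates=1,
                         frac_n_contaminated=0.0, frac_short=0.0, seed=seed)
        res = simulate_libraries(truth, sim, b)
        counts.append(res.libraries["IP_1"]["read_id"].nunique())
    counts = np.array(counts)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 800) < 3 * se + 1e-9


def test_null_truth_gives_equal_ip_input_expectation(bundle):
    """All enrichment factors 1: IP and Input totals agree in expectation."""
    base = {tid: 50.0 for tid in bundle.transcripts["transcript_id"]}
    truth = BindingTruth(baseline_expression=base, nb_dispersion=0.05)
    ip_tot, in_tot = [], []
    for seed in range(30):
        res = simulate_libraries(
            truth, LibrarySim(n_fragments=None, n_replicates=1,
                              frac_n_contaminated=0.0, frac_short=0.0,
                              seed=seed), bundle)
        ip_tot.append(res.libraries["IP_1"]["read_id"].nunique())
        in_tot.append(res.libraries["Input_1"]["read_id"].nunique())
    diff = np.mean(ip_tot) - np.mean(in_tot)
    pooled_se = np.sqrt(np.var(ip_tot) / 30 + np.var(in_tot) / 30)
    assert abs(diff) < 4 * pooled_se


def test_window_enrichment_shifts_ip_start_positions(bundle):
    """With an 8x window on 28S[1776, 2242], the fraction of IP 45S reads
    starting inside the window exceeds the Input fraction (20/20 seeds)."""
    truth = default_truth(bundle, rng=np.random.default_rng(12))
    offset = bundle.rdna_28s_offset
    copies = bundle.rdna_copies
    lo = int(copies["start"].iloc[0]) + offset + 1775
    hi = int(copies["start"].iloc[0]) + offset + 2242
    wins = 0
    for seed in range(20):
        res = simulate_libraries(
            truth, LibrarySim(n_fragments=4000, n_replicates=1,
                              frac_n_contaminated=0.0, frac_short=0.0,
                              seed=seed), bundle)

        def frac_in_window(aln):
            first_copy = aln[(aln["nh"] == 3)
                             & (aln["start"] >= int(copies["start"].iloc[0]))
                             & (aln["end"] <= int(copies["end"].iloc[0]))]
            if not len(first_copy):
                return 0.0
            return float(((first_copy["start"] >= lo)
                          & (first_copy["start"] < hi)).mean())

        if frac_in_window(res.libraries["IP_1"]) > frac_in_window(res.libraries["Input_1"]):
            wins += 1
    assert wins >= 19


def test_count_matrix_planted_and_depth_structure():
    planted = {"G00001": 4.0}
    m = simulate_count_matrix(n_genes=200, base_mean=200, dispersion=0.005,
                              planted=planted, seed=9)
    assert list(m.columns) == ["OE_1", "OE_2", "Ctrl_1", "Ctrl_2"]
    ratio = m.loc["G00001", ["OE_1", "OE_2"]].mean() / \
        m.loc["G00001", ["Ctrl_1", "Ctrl_2"]].mean()
    assert 2.5 < ratio < 6.0
    with pytest.raises(TruthLookupError):
        simulate_count_matrix(n_genes=10, planted={"MISSING": 2.0}, seed=0)
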