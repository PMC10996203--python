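"""QC rules, multiplicity partition, class and subregion assignment."""

import numpy as np
import pandas as pd
import pytest

from structrip.read_partition import (
    DataIntegrityError, SubregionAssignmentError, assign_ncrna_class,
    assign_rdna_subregion, collapse_rdna, library_partition_summary,
    partition_by_multiplicity, qc_filter_reads,
)


def _aln(rows):
    return pd.DataFrame(rows, columns=["read_id", "ref", "start", "end", "strand", "nh"])


@pytest.mark.parametrize(
    "seq,kept",
    [
        ("A" * 27 + "NNN", False),   # 30 nt, 3 N -> discarded
        ("A" * 28 + "NN", True),     # exactly 2 N -> kept
        ("A" * 15, False),           # shorter than 16 nt -> dropped
        ("A" * 16, True),            # boundary: 16 nt kept ("less than 16")
    ],
)
def test_qc_single_read_rules(seq, kept):
    out, _ = qc_filter_reads([("r", seq)])
    assert bool(out) is kept


def test_qc_counting_on_constructed_set():
    """7 N-contaminated + 5 short among 100 reads: exactly 88 survive, with
    the removals attributed to the right rule (N-filter applied first)."""
    reads = [(f"n{i}", "A" * 27 + "NNN") for i in range(7)]
    reads += [(f"s{i}", "ACGTACGTAC") for i in range(5)]
    reads += [(f"k{i}", "ACGT" * 10) for i in range(88)]
    kept, report = qc_filter_reads(reads)
    assert len(kept) == 88
    assert report.n_removed_n == 7
    assert report.n_removed_short == 5
    assert report.n_kept == 88


def test_qc_empty_input_is_not_an_error():
    kept, report = qc_filter_reads([])
    assert kept == [] and report.n_input == 0 and report.n_kept == 0


def test_partition_counts_once_per_read():
    aln = _aln([
        ("m1", "chr1", 0, 50, "+", 3),
        ("m1", "chr1", 100, 150, "+", 3),
        ("m1", "chr1", 200, 250, "+", 3),
        ("u1", "chr1", 0, 50, "+", 1),
    ])
    unique, multi, counts = partition_by_multiplicity(aln)
    assert counts == {"total": 2, "unique": 1, "multi": 1}
    assert multi["read_id"].nunique() == 1 and len(multi) == 3


def test_partition_all_unique():
    aln = _aln([(f"r{i}", "chr1", i, i + 30, "+", 1) for i in range(5)])
    unique, multi, counts = partition_by_multiplicity(aln)
    assert counts["multi"] == 0 and counts["unique"] == 5 and len(multi) == 0


def test_partition_inconsistent_multiplicity_raises():
    aln = _aln([("r1", "chr1", 0, 50, "+", 2), ("r1", "chr1", 9, 59, "+", 3)])
    with pytest.raises(DataIntegrityError, match="r1"):
        partition_by_multiplicity(aln)


def test_class_assignment_by_reference_and_priority(bundle):
    sno = bundle.transcripts[bundle.transcripts["class"] == "snoRNA-H/ACA"].iloc[0]
    copies = bundle.rdna_copies
    aln = _aln(
        # placed only on a snoRNA (genomic span) -> snoRNA
        [("a", "chr1", int(sno["start"]), int(sno["start"]) + 40, "+", 2),
         ("a", "chr1", 5, 45, "+", 2)]
        # placed on two identical 45S copies -> rRNA, one count
        + [("b", "chr1", int(c["start"]) + 10, int(c["start"]) + 60, "+", 2)
           for _, c in copies.head(2).iterrows()]
        # direct placement on the standalone unit -> rRNA
        + [("c", "45S", 100, 150, "+", 2), ("c", "5S", 0, 50, "+", 2)]
        # no structured reference -> unassigned
        + [("d", "chr1", 5, 45, "+", 2), ("d", "chr1", 50, 90, "+", 2)]
    )
    summary = assign_ncrna_class(aln, bundle, library="L")
    assert summary.counts == {"snoRNA": 1, "rRNA": 2}
    assert summary.n_unassigned == 1
    fr = summary.fractions
    assert abs(sum(fr.values()) - 1.0) < 1e-9


def test_multi_fraction_matches_planted_rdna_share(bundle):
    """45S carrying ~40% of fragments across 3 identical copies: the
    multi-mapped read fraction recovers 0.40 within sampling error."""
    from structrip.synthetic_data import BindingTruth, LibrarySim, simulate_libraries
    others = [t for t in bundle.transcripts["transcript_id"] if t not in ("45S", "5S")]
    base = {t: 6000.0 / len(others) for t in others}
    base["45S"] = 4000.0
    truth = BindingTruth(baseline_expression=base, nb_dispersion=0.01)
    res = simulate_libraries(
        truth, LibrarySim(n_fragments=None, n_replicates=1,
                          frac_n_contaminated=0.0, frac_short=0.0, seed=4),
        bundle)
    _, _, counts = partition_by_multiplicity(res.libraries["IP_1"])
    frac = counts["multi"] / counts["total"]
    assert abs(frac - 0.4) < 0.03


def test_subregion_midpoint_rule(bundle):
    iv = bundle.rdna_intervals.set_index("name")
    start_its2 = int(iv.loc["ITS2", "start"])  # 1-based
    # read spanning the 5.8S/ITS2 junction with midpoint in ITS2
    junction_read = (start_its2 - 1 - 10, start_its2 - 1 + 30)  # 0-based midpoint +9 into ITS2
    reads = _aln([
        ("a", "45S", int(iv.loc["28S", "start"]) + 5, int(iv.loc["28S", "start"]) + 55, "+", 3),
        ("b", "45S", junction_read[0], junction_read[1], "+", 3),
    ])
    table = assign_rdna_subregion(reads, bundle.rdna_intervals)
    by_name = table.set_index("subregion")
    assert by_name.loc["28S", "count"] == 1
    assert by_name.loc["ITS2", "count"] == 1
    assert abs(table["fraction"].sum() - 1.0) < 1e-9


def test_subregion_read_outside_unit_raises(bundle):
    unit_len = int(bundle.rdna_intervals["end"].max())
    reads = _aln([("x", "45S", unit_len + 5, unit_len + 55, "+", 3)])
    with pytest.raises(SubregionAssignmentError):
        assign_rdna_subregion(reads, bundle.rdna_intervals)


def test_collapse_rdna_unit_local_coordinates(bundle):
    copies = bundle.rdna_copies
    aln = _aln([
        ("r", "chr1", int(c["start"]) + 123, int(c["start"]) + 173, "+", 3)
        for _, c in copies.iterrows()
    ])
    unit = collapse_rdna(aln, bundle)
    assert len(unit) == 1
    assert int(unit["start"].iloc[0]) == 123 and int(unit["end"].iloc[0]) == 173


def test_doubling_library_leaves_fractions_unchanged(bundle, sim_result):
    aln = sim_result.libraries["IP_1"]
    doubled = pd.concat(
        [aln, aln.assign(read_id=aln["read_id"] + "_dup")], ignore_index=True
    )
    s1 = library_partition_summary(aln, bundle, "L")
    s2 = library_partition_summary(doubled, bundle, "L")
    assert s1["class_summary"].fractions == pytest.approx(s2["class_summary"].fractions)
    np.testing.assert_allclose(
        s1["subregions"]["fraction"], s2["subregions"]["fraction"], atol=1e-12
    )
    assert s2["counts"]["total"] == 2 * s1["counts"]["total"]


def test_assigned_fractions_match_truth_composition(bundle, sim_result, truth):
    """On simulated data the recovered 45S read share matches the planted
    expectation within 3x binomial SE."""
    aln = sim_result.libraries["Input_1"]
    summary = library_partition_summary(aln, bundle, "Input_1")
    total = summary["counts"]["total"]
    frac_45s = summary["n_45s_reads"] / total
    base_total = sum(truth.baseline_expression.values())
    expected = truth.baseline_expression["45S"] / base_total
    se = np.sqrt(expected * (1 - expected) / total)
    assert abs(frac_45s - expected) < 3 * se + 0.01
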