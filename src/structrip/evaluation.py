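"""Study-condition evaluations: seeded recovery and calibration experiments.

Each function re-runs a planted-truth simulation through the real pipeline
stages and measures how well the stage recovers the truth (or how well its
error rates are calibrated under the null).  These are the experiments behind
the package's headline numbers; they are deliberately sized to run on one CPU
in a few minutes.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .diff_expression import test_de
from .enrichment_stats import count_reads_per_transcript, quantify
from .peak_calling import PeakCallParams, call_peaks
from .read_partition import collapse_rdna, partition_by_multiplicity
from .rrna_domain_profile import domain_density, extract_28s_profile, max_density_domain
from .rtlp_quant import rtlp_index, simulate_rtlp
from .synthetic_data import (
    BindingTruth, GenomeSpec, LibrarySim, ReferenceBundle, build_reference,
    default_truth, simulate_count_matrix, simulate_libraries,
)


def _run_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _compact_bundle(seed: int = 11) -> ReferenceBundle:
    return build_reference(GenomeSpec(
        n_coding_genes=10, n_snorna_haca=20, n_snorna_cd=17,
        n_scarna=3, n_mirna=3, seed=seed,
    ))


def domain2_recovery(n_runs: int = 100, seed: int = 0,
                     n_fragments: int = 4000) -> Dict[str, float]:
    """Simulate IP/Input with an 8x binding window on 28S[1776, 2242] and
    measure how often domain II is the max-density domain and the IP 45S read
    fraction is at least 3x the Input fraction."""
    bundle = _compact_bundle()
    truth = default_truth(bundle, rng=np.random.default_rng(12))
    len_28s = int(bundle.domains["end"].max())
    offset = bundle.rdna_28s_offset
    n_domain2 = 0
    n_ratio3 = 0
    ratios = []
    ip_fracs = []
    frac_28s = []
    for run_seed in _run_seeds(seed, n_runs):
        sim = LibrarySim(n_fragments=n_fragments, n_replicates=2,
                         frac_n_contaminated=0.0, frac_short=0.0,
                         seed=int(run_seed))
        res = simulate_libraries(truth, sim, bundle, emit_reads=False)
        ip_multi, in_multi = [], []
        ip_total = in_total = ip_45s = in_45s = 0
        for lib, aln in res.libraries.items():
            _, multi, counts = partition_by_multiplicity(aln)
            unit = collapse_rdna(multi, bundle)
            if lib.startswith("IP"):
                ip_multi.append(unit)
                ip_total += counts["total"]
                ip_45s += unit["read_id"].nunique()
            else:
                in_multi.append(unit)
                in_total += counts["total"]
                in_45s += unit["read_id"].nunique()
        ip_units = pd.concat(ip_multi, ignore_index=True)
        in_units = pd.concat(in_multi, ignore_index=True)
        depth_ip = extract_28s_profile(ip_units, offset, len_28s)
        dens = domain_density(depth_ip, bundle.domains, ip_total)
        if max_density_domain(dens) == "II":
            n_domain2 += 1
        ip_frac = ip_45s / max(ip_total, 1)
        in_frac = in_45s / max(in_total, 1)
        ratio = ip_frac / max(in_frac, 1e-12)
        ratios.append(ratio)
        ip_fracs.append(ip_frac)
        if ratio >= 3.0:
            n_ratio3 += 1
        mid28 = ((ip_units["start"] + ip_units["end"]) // 2 + 1).to_numpy()
        row28 = bundle.rdna_intervals.set_index("name").loc["28S"]
        frac_28s.append(
            float(np.mean((mid28 >= int(row28["start"])) & (mid28 <= int(row28["end"]))))
        )
    return {
        "n_runs": n_runs,
        "domain2_rate": n_domain2 / n_runs,
        "ratio3_rate": n_ratio3 / n_runs,
        "both_rate": min(n_domain2, n_ratio3) / n_runs,
        "median_fraction_ratio": float(np.median(ratios)),
        "median_ip_45s_fraction": float(np.median(ip_fracs)),
        "median_28s_fraction_of_45s": float(np.median(frac_28s)),
    }


def snorna_enrichment_recovery(n_runs: int = 50, n_runs_top20: int = 100,
                               seed: int = 0, n_fragments: int = 40000,
                               factor: float = 4.0, n_planted: int = 30
                               ) -> Dict[str, float]:
    """Plant ``n_planted`` enriched H/ACA snoRNAs (IP factor ``factor``) among
    174 expressed snoRNAs and measure recovery at FC >= 2, p < 0.05: planted
    sensitivity, non-planted false-positive rate, and how often the top-20
    most-enriched snoRNAs are purely H/ACA box."""
    bundle = build_reference(GenomeSpec(
        n_coding_genes=20, n_snorna_haca=100, n_snorna_cd=74,
        n_scarna=10, n_mirna=10, seed=21,
    ))
    truth = default_truth(
        bundle, rng=np.random.default_rng(22), n_enriched_snorna=n_planted,
        snorna_factor=factor, n_enriched_scarna=0, haca_only=True,
    )
    planted = {t for t in truth.enriched_transcripts if t.startswith("SNORA")}
    sno_all = set(
        bundle.transcripts[
            bundle.transcripts["class"].str.startswith("snoRNA")
        ]["transcript_id"]
    )
    non_planted = sno_all - planted
    sens, fpr, top20_pure = [], [], []
    n_total = max(n_runs, n_runs_top20)
    for i, run_seed in enumerate(_run_seeds(seed, n_total)):
        sim = LibrarySim(n_fragments=n_fragments, n_replicates=2,
                         frac_n_contaminated=0.0, frac_short=0.0,
                         seed=int(run_seed))
        res = simulate_libraries(truth, sim, bundle, emit_reads=False)
        ip_counts, input_counts = {}, {}
        ip_total = input_total = 0
        for lib, aln in res.libraries.items():
            unique, _, counts_d = partition_by_multiplicity(aln)
            counts = count_reads_per_transcript(unique, bundle.transcripts)
            if lib.startswith("IP"):
                ip_counts[lib] = counts
                ip_total += counts_d["unique"]
            else:
                input_counts[lib] = counts
                input_total += counts_d["unique"]
        quants = quantify(ip_counts, input_counts, bundle.transcripts,
                          ip_library_total=ip_total, input_library_total=input_total)
        flagged = set(quants[quants["enriched"]]["transcript_id"])
        if i < n_runs:
            sens.append(len(flagged & planted) / len(planted))
            fpr.append(len(flagged & non_planted) / len(non_planted))
        sno_enriched = quants[
            quants["enriched"] & quants["class"].str.startswith("snoRNA")
        ].sort_values(["fold_change", "transcript_id"], ascending=[False, True])
        top20 = sno_enriched.head(20)
        top20_pure.append(float((top20["box_type"] == "H/ACA").all() and len(top20) > 0))
    return {
        "n_runs": n_runs,
        "sensitivity": float(np.mean(sens)),
        "false_positive_rate": float(np.mean(fpr)),
        "top20_haca_rate": float(np.mean(top20_pure[:n_runs_top20])),
        "n_expressed_snorna": len(sno_all),
    }


def peak_null_calibration(n_runs: int = 100, seed: int = 0,
                          n_reads: int = 800, ref_length: int = 2000,
                          read_length: int = 50, alpha: float = 0.05
                          ) -> Dict[str, float]:
    """IP and Input drawn from the same uniform model: the fraction of runs
    yielding any peak should not exceed alpha (up to binomial noise)."""
    min_depth = max(5, int(n_reads * read_length / ref_length))
    ref_lengths = {"T": ref_length}
    n_with_peak = 0
    for run_seed in _run_seeds(seed + 1, n_runs):
        rng = np.random.default_rng(int(run_seed))
        # each run gets its own permutation seed: a shared permutation sample
        # would correlate the p-values of all runs
        params = PeakCallParams(min_depth=min_depth, merge_gap=10,
                                n_permutations=200, alpha=alpha,
                                min_enrichment=1.0, seed=int(run_seed) + 1)

        def _uniform_lib(tag: str) -> pd.DataFrame:
            starts = rng.integers(0, ref_length - read_length + 1, size=n_reads)
            return pd.DataFrame({
                "read_id": [f"{tag}{i}" for i in range(n_reads)],
                "ref": "T", "start": starts, "end": starts + read_length,
                "strand": "+", "nh": 1,
            })

        peaks = call_peaks(_uniform_lib("ip"), _uniform_lib("in"), ref_lengths, params)
        if len(peaks):
            n_with_peak += 1
    se = float(np.sqrt(alpha * (1 - alpha) / n_runs))
    return {
        "n_runs": n_runs,
        "fraction_with_peak": n_with_peak / n_runs,
        "alpha": alpha,
        "bound_alpha_plus_3se": alpha + 3 * se,
    }


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0])) if ov else 0.0


def peak_recovery(n_runs: int = 100, seed: int = 0, depth_reads: int = 2000
                  ) -> Dict[str, float]:
    """Plant one 60-nt site (factor 10) on a 2-kb transcript at ~50x coverage
    and measure recovery with >= 50% reciprocal overlap."""
    bundle = build_reference(GenomeSpec(
        n_coding_genes=1, gene_length_range=(2000, 2000), exon_count_range=(1, 1),
        n_rdna_copies=0, n_5s_copies=0, n_snorna_haca=0, n_snorna_cd=0,
        n_scarna=0, n_mirna=0, seed=31,
    ))
    gene = bundle.transcripts.iloc[0]
    mid = int((gene["start"] + gene["end"]) // 2)
    site = (mid - 30, mid + 30)
    truth = BindingTruth(
        baseline_expression={gene["transcript_id"]: float(depth_reads)},
        peak_sites=[(site[0], site[1], 10.0, False)],
        nb_dispersion=0.05,
    )
    n_recovered = 0
    n_single = 0
    for run_seed in _run_seeds(seed + 2, n_runs):
        sim = LibrarySim(n_fragments=None, n_replicates=1,
                         frac_n_contaminated=0.0, frac_short=0.0,
                         seed=int(run_seed))
        params = PeakCallParams(min_depth=100, merge_gap=10, n_permutations=200,
                                alpha=0.01, min_enrichment=3.0,
                                seed=int(run_seed) + 1)
        res = simulate_libraries(truth, sim, bundle, emit_reads=False)
        peaks = call_peaks(res.libraries["IP_1"], res.libraries["Input_1"],
                           bundle.ref_lengths, params)
        overlapping = [
            row for row in peaks.itertuples(index=False)
            if _reciprocal_overlap((int(row.start), int(row.end)), site) >= 0.5
        ]
        if overlapping:
            n_recovered += 1
        if len(overlapping) == 1 and len(peaks) == 1:
            n_single += 1
    return {
        "n_runs": n_runs,
        "recovery_rate": n_recovered / n_runs,
        "single_peak_rate": n_single / n_runs,
    }


def deg_calibration(n_null_runs: int = 50, n_planted_runs: int = 20,
                    seed: int = 0, n_genes: int = 1000,
                    n_planted: int = 50, planted_fc: float = 4.0
                    ) -> Dict[str, float]:
    """Null FDR calibration (fraction of null genes at FDR < 0.05) and
    sensitivity/direction accuracy for planted ``planted_fc``-fold genes."""
    null_fracs = []
    for run_seed in _run_seeds(seed + 3, n_null_runs):
        matrix = simulate_count_matrix(n_genes=n_genes, seed=int(run_seed))
        deg = test_de(matrix, "OE", "Ctrl")
        null_fracs.append(float((deg["fdr"] < 0.05).mean()))
    sens, correct_dir = [], []
    for run_seed in _run_seeds(seed + 4, n_planted_runs):
        genes = [f"G{i + 1:05d}" for i in range(n_genes)]
        planted = {g: planted_fc for g in genes[:n_planted]}
        matrix = simulate_count_matrix(n_genes=n_genes, planted=planted,
                                       seed=int(run_seed))
        deg = test_de(matrix, "OE", "Ctrl")
        hits = deg.loc[list(planted)]
        sens.append(float((hits["direction"] == "up").mean()))
        sig = hits[hits["fdr"] < 0.05]
        correct_dir.append(
            float((sig["direction"] == "up").mean()) if len(sig) else np.nan
        )
    return {
        "null_fdr_fraction": float(np.mean(null_fracs)),
        "sensitivity": float(np.mean(sens)),
        "direction_accuracy": float(np.nanmean(correct_dir)),
    }


def rtlp_sign_structure(n_runs: int = 100, seed: int = 0,
                        noise_sd: float = 0.1) -> Dict[str, float]:
    """Overexpression suppresses low-dNTP read-through (2-cycle shift,
    m*s = 0.75 vs unmethylated control): the OE/Ctrl contrast should be < 1
    with paired-t p < 0.05 at n=3; a knockdown with reduced methylation
    should give a contrast > 1."""
    n_oe_sig = 0
    n_kd_gt1 = 0
    for run_seed in _run_seeds(seed + 5, n_runs):
        oe = simulate_rtlp({"Ctrl": 0.0, "OE": 0.75 / 0.9}, noise_sd=noise_sd,
                           n_replicates=3, seed=int(run_seed))
        res = rtlp_index(oe)
        row = res.contrasts.iloc[0]
        if row["index_ratio"] < 1 and row["p"] < 0.05:
            n_oe_sig += 1
        kd = simulate_rtlp({"Ctrl": 0.5, "KD": 0.1}, noise_sd=noise_sd,
                           n_replicates=3, seed=int(run_seed) + 1)
        if rtlp_index(kd).contrasts.iloc[0]["index_ratio"] > 1:
            n_kd_gt1 += 1
    return {
        "n_runs": n_runs,
        "oe_contrast_significant_rate": n_oe_sig / n_runs,
        "kd_contrast_gt1_rate": n_kd_gt1 / n_runs,
    }
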