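"""End-to-end pipeline: simulate -> partition -> callpeaks -> enrich ->
profile -> de -> rtlp -> report.

A single config (YAML-serializable) drives every stage; all randomness flows
from one global seed through logged per-stage seeds, so a rerun with the same
config reproduces every output file byte-identically.  Wall-clock timings are
written to a separate timings.txt, keeping the report file deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as srio
from .diff_expression import deg_overlap, test_de
from .enrichment_stats import (
    class_enrichment_summary, count_reads_per_transcript, quantify, top_abundant,
)
from .peak_calling import (
    PeakCallParams, annotate_peaks, ca_repeat_enrichment, call_peaks,
    confident_bound_genes, extract_peak_sequences,
)
from .read_partition import library_partition_summary, qc_filter_reads
from .rrna_domain_profile import ModificationSite, profile_28s
from .rtlp_quant import rtlp_index, simulate_rtlp
from .synthetic_data import (
    GenomeSpec, LibrarySim, build_reference, default_truth, implant_motifs,
    simulate_count_matrix, simulate_libraries,
)

logger = logging.getLogger("structrip")

STAGES = ["simulate", "partition", "callpeaks", "enrich", "profile", "de", "rtlp"]


class PreflightError(ValueError):
    """Configuration invalid or referenced inputs missing."""


@dataclass
class PipelineConfig:
    """All stage parameters; defaults mirror the analysis thresholds
    (QC: >2 N bases, <16 nt; enrichment: FC >= 2, p < 0.05; DEG: FC >= 2 or
    <= 0.5, FDR < 0.05; top-N 100)."""

    seed: int = 1
    # synthetic reference / libraries
    genome: dict = field(default_factory=dict)          # GenomeSpec overrides
    library: dict = field(default_factory=dict)         # LibrarySim overrides
    # QC
    qc_max_n: int = 2
    qc_min_length: int = 16
    # peak calling
    peaks: dict = field(default_factory=lambda: {
        "min_depth": 10, "merge_gap": 10, "n_permutations": 200,
        "alpha": 0.01, "min_enrichment": 3.0,
    })
    # enrichment
    fc_cut: float = 2.0
    p_cut: float = 0.05
    top_n: int = 100
    # 28S profiling
    profile_threshold: float = 0.5
    profile_merge_gap: int = 20
    modification_sites: Tuple[Tuple[str, int], ...] = (
        ("Am2388", 2388), ("Cm2409", 2409), ("Gm2411", 2411),
    )
    # differential expression
    de_fc_cut: float = 2.0
    de_fdr_cut: float = 0.05
    de_n_genes: int = 1000
    de_n_planted: int = 15
    de_planted_fc: float = 4.0
    de_dispersion: float = 0.01
    # RTL-P
    rtlp_methylation: dict = field(default_factory=lambda: {
        "Ctrl": 0.5, "OE": 0.85, "KD": 0.2,
    })
    rtlp_noise_sd: float = 0.1
    rtlp_replicates: int = 3
    # optional external inputs (pre-flight checked when set)
    input_files: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.p_cut < 1 or not 0 < self.de_fdr_cut < 1:
            raise PreflightError("significance cut-offs must lie in (0, 1)")
        if self.fc_cut < 1 or self.de_fc_cut < 1:
            raise PreflightError("fold-change cut-offs must be >= 1")
        if not 0 < self.profile_threshold <= 1:
            raise PreflightError("profile threshold must lie in (0, 1]")
        for name, path in self.input_files.items():
            if not Path(path).exists():
                raise PreflightError(f"input file {name!r} not found: {path}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["modification_sites"] = [list(t) for t in self.modification_sites]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "modification_sites" in data:
            data["modification_sites"] = tuple(
                (str(label), int(pos)) for label, pos in data["modification_sites"]
            )
        return cls(**data)


def demo_config(seed: int = 1) -> PipelineConfig:
    """The bundled demo: a compact genome so the full run stays fast."""
    return PipelineConfig(
        seed=seed,
        genome={"n_coding_genes": 30, "n_snorna_haca": 100, "n_snorna_cd": 74,
                "n_scarna": 10, "n_mirna": 10, "n_rdna_copies": 3},
        library={"n_fragments": 25_000, "n_replicates": 2},
    )


def _stage_seeds(seed: int) -> Dict[str, int]:
    rng = np.random.default_rng(seed)
    return {stage: int(rng.integers(0, 2**31 - 1)) for stage in STAGES}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the run report dict.

    Outputs land under ``outdir``; a failure in any stage aborts with the
    failing stage named.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {"config_seed": config.seed, "stage_seeds": seeds, "stages": {}}
    timings: List[Tuple[str, float]] = []

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        spec = GenomeSpec(**{**config.genome, "seed": seeds[stage]})
        bundle = build_reference(spec)
        truth = default_truth(bundle, rng=np.random.default_rng(seeds[stage] + 1))
        implant_motifs(bundle, truth)
        sim = LibrarySim(**{**config.library, "seed": seeds[stage] + 2})
        result = simulate_libraries(truth, sim, bundle)
        ref_dir = outdir / "reference"
        bundle.save(ref_dir)
        result.save(bundle, outdir / "alignments")
        qc_stats = {}
        for lib, reads in result.reads.items():
            kept, rep = qc_filter_reads(
                reads, max_n=config.qc_max_n, min_length=config.qc_min_length
            )
            qc_stats[lib] = {
                "input": rep.n_input, "removed_n": rep.n_removed_n,
                "removed_short": rep.n_removed_short, "kept": rep.n_kept,
            }
        report["stages"][stage] = {
            "n_libraries": len(result.libraries),
            "n_planted_peaks": len(result.truth_peaks),
            "qc": qc_stats,
        }
        timings.append((stage, time.perf_counter() - t0))
        logger.info("simulate: %d libraries", len(result.libraries))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "partition"
    try:
        t0 = time.perf_counter()
        part_dir = outdir / "partition"
        part_dir.mkdir(exist_ok=True)
        partitions = {}
        class_frames, sub_frames = [], []
        for lib, aln in result.libraries.items():
            summary = library_partition_summary(aln, bundle, library=lib)
            partitions[lib] = summary
            class_frames.append(summary["class_summary"].to_frame())
            sub = summary["subregions"].copy()
            sub.insert(0, "library", lib)
            sub_frames.append(sub)
        srio.write_tsv(pd.concat(class_frames, ignore_index=True),
                       part_dir / "ncrna_classes.tsv")
        srio.write_tsv(pd.concat(sub_frames, ignore_index=True),
                       part_dir / "rdna_subregions.tsv")
        report["stages"][stage] = {
            lib: {
                **p["counts"],
                "multi_fraction": p["counts"]["multi"] / max(p["counts"]["total"], 1),
                "n_45s_reads": p["n_45s_reads"], "n_5s_reads": p["n_5s_reads"],
            }
            for lib, p in partitions.items()
        }
        timings.append((stage, time.perf_counter() - t0))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "callpeaks"
    try:
        t0 = time.perf_counter()
        peak_dir = outdir / "peaks"
        peak_dir.mkdir(exist_ok=True)
        params = PeakCallParams(**config.peaks, seed=seeds[stage])
        input_pool = pd.concat(
            [partitions[lib]["unique"] for lib in result.input_libraries],
            ignore_index=True,
        )
        annotated_reps = {}
        for lib in result.ip_libraries:
            peaks = call_peaks(
                partitions[lib]["unique"], input_pool, bundle.ref_lengths, params
            )
            annotated, dist = annotate_peaks(peaks, bundle.features)
            annotated_reps[lib] = annotated
            out = annotated.copy()
            out["score"] = -np.log10(out["p"])
            srio.write_tsv(out, peak_dir / f"peaks_{lib}.tsv")
            srio.write_tsv(dist, peak_dir / f"peak_categories_{lib}.tsv")
        reps = list(annotated_reps.values())
        bound = confident_bound_genes(reps[0], reps[-1]) if reps else set()
        pd.DataFrame({"gene_id": sorted(bound)}).to_csv(
            peak_dir / "bound_genes.tsv", sep="\t", index=False
        )
        motif = None
        if len(reps) and len(reps[0]):
            seqs = extract_peak_sequences(reps[0], bundle.genome)
            motif = ca_repeat_enrichment(seqs, seed=seeds[stage] + 1)
            srio.write_tsv(motif["run_length_distribution"],
                           peak_dir / "ca_repeat_lengths.tsv")
        report["stages"][stage] = {
            "n_peaks": {lib: int(len(p)) for lib, p in annotated_reps.items()},
            "n_bound_genes": len(bound),
            "ca_repeat": {k: motif[k] for k in
                          ("fraction_observed", "z", "p")} if motif else None,
        }
        timings.append((stage, time.perf_counter() - t0))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "enrich"
    try:
        t0 = time.perf_counter()
        enr_dir = outdir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        ip_counts = {
            lib: count_reads_per_transcript(partitions[lib]["unique"], bundle.transcripts)
            for lib in result.ip_libraries
        }
        input_counts = {
            lib: count_reads_per_transcript(partitions[lib]["unique"], bundle.transcripts)
            for lib in result.input_libraries
        }
        quants = quantify(
            ip_counts, input_counts, bundle.transcripts,
            fc_cut=config.fc_cut, p_cut=config.p_cut,
            ip_library_total=sum(
                partitions[lib]["counts"]["unique"] for lib in result.ip_libraries
            ),
            input_library_total=sum(
                partitions[lib]["counts"]["unique"] for lib in result.input_libraries
            ),
        )
        srio.write_tsv(quants, enr_dir / "transcript_quant.tsv")
        top, composition = top_abundant(quants, n=config.top_n)
        srio.write_tsv(top, enr_dir / "top_abundant.tsv")
        srio.write_tsv(composition, enr_dir / "top_abundant_classes.tsv")
        summary = class_enrichment_summary(quants)
        srio.write_tsv(summary, enr_dir / "class_enrichment.tsv")
        report["stages"][stage] = {
            "n_transcripts": int(len(quants)),
            "n_enriched": int(quants["enriched"].sum()),
            "top_n_classes": dict(zip(composition["class"], composition["count"].astype(int))),
        }
        timings.append((stage, time.perf_counter() - t0))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "profile"
    try:
        t0 = time.perf_counter()
        prof_dir = outdir / "profile"
        prof_dir.mkdir(exist_ok=True)
        from .read_partition import collapse_rdna
        ip_units = pd.concat(
            [collapse_rdna(partitions[lib]["multi"], bundle) for lib in result.ip_libraries],
            ignore_index=True,
        )
        input_units = pd.concat(
            [collapse_rdna(partitions[lib]["multi"], bundle) for lib in result.input_libraries],
            ignore_index=True,
        )
        ip_size = sum(partitions[lib]["counts"]["total"] for lib in result.ip_libraries)
        input_size = sum(partitions[lib]["counts"]["total"] for lib in result.input_libraries)
        len_28s = int(bundle.domains["end"].max())
        sites = [ModificationSite("28S", pos, label)
                 for label, pos in config.modification_sites]
        prof = profile_28s(
            ip_units, input_units, bundle.domains, bundle.rdna_28s_offset, len_28s,
            ip_size, input_size, threshold=config.profile_threshold,
            merge_gap=config.profile_merge_gap, sites=sites,
        )
        depth_df = pd.DataFrame({
            "position": np.arange(1, len_28s + 1),
            "depth_ip": prof["depth_ip"], "depth_input": prof["depth_input"],
        })
        srio.write_tsv(depth_df, prof_dir / "depth_28s.tsv")
        srio.write_tsv(prof["density_ip"], prof_dir / "domain_density_ip.tsv")
        srio.write_tsv(prof["density_input"], prof_dir / "domain_density_input.tsv")
        srio.write_tsv(prof["modification_sites"], prof_dir / "modification_sites.tsv")
        pd.DataFrame(prof["binding_regions"], columns=["start", "end"]).to_csv(
            prof_dir / "binding_regions.tsv", sep="\t", index=False
        )
        report["stages"][stage] = {
            "max_domain_ip": prof["max_domain_ip"],
            "max_domain_ratio": prof["max_domain_ratio"],
            "binding_regions": [list(r) for r in prof["binding_regions"]],
            "sites_contained": {
                row["label"]: bool(row["contained"])
                for _, row in prof["modification_sites"].iterrows()
            },
        }
        timings.append((stage, time.perf_counter() - t0))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "de"
    try:
        t0 = time.perf_counter()
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        bundle_genes = bundle.transcripts["transcript_id"].tolist()
        n_filler = max(config.de_n_genes - len(bundle_genes), 0)
        genes = bundle_genes + [f"FILLER{i + 1:05d}" for i in range(n_filler)]
        rng = np.random.default_rng(seeds[stage])
        coding = [g for g in bundle_genes if g.startswith("GENE")]
        n_coding_planted = min(config.de_n_planted // 2, len(coding))
        planted_ids = coding[:n_coding_planted] + [
            f"FILLER{i + 1:05d}" for i in range(config.de_n_planted - n_coding_planted)
        ]
        planted = {g: config.de_planted_fc for g in planted_ids}
        matrix = simulate_count_matrix(
            gene_ids=genes, dispersion=config.de_dispersion,
            planted=planted, seed=seeds[stage] + 1,
        )
        deg = test_de(matrix, "OE", "Ctrl",
                      fc_cut=config.de_fc_cut, fdr_cut=config.de_fdr_cut)
        srio.write_tsv(deg.reset_index(), de_dir / "deg_results.tsv")
        universe = set(genes)
        bound_in_universe = bound & universe
        overlap, breakdown = deg_overlap(deg, bound_in_universe, universe)
        srio.write_tsv(
            pd.DataFrame([{
                "n_deg": overlap.n_a, "n_bound": overlap.n_b,
                "n_overlap": overlap.n_overlap, "universe": overlap.universe,
                "p": overlap.p, **breakdown,
            }]),
            de_dir / "deg_bound_overlap.tsv",
        )
        n_up = int((deg["direction"] == "up").sum())
        n_down = int((deg["direction"] == "down").sum())
        report["stages"][stage] = {
            "n_genes": len(genes), "n_up": n_up, "n_down": n_down,
            "overlap_with_bound": overlap.n_overlap, "overlap_p": overlap.p,
        }
        timings.append((stage, time.perf_counter() - t0))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "rtlp"
    try:
        t0 = time.perf_counter()
        rtlp_dir = outdir / "rtlp"
        rtlp_dir.mkdir(exist_ok=True)
        measurements = simulate_rtlp(
            config.rtlp_methylation, noise_sd=config.rtlp_noise_sd,
            n_replicates=config.rtlp_replicates, seed=seeds[stage],
        )
        srio.write_tsv(measurements, rtlp_dir / "qpcr_ct.tsv")
        res = rtlp_index(measurements, site="Am2388")
        srio.write_tsv(res.contrasts, rtlp_dir / "rtlp_contrasts.tsv")
        srio.write_tsv(
            res.per_level_ratio.reset_index(), rtlp_dir / "rtlp_level_ratios.tsv"
        )
        report["stages"][stage] = {
            "index": {k: float(v) for k, v in sorted(res.index.items())},
            "contrasts": {
                row["contrast"]: {"index_ratio": row["index_ratio"], "p": row["p"]}
                for _, row in res.contrasts.iterrows()
            },
        }
        timings.append((stage, time.perf_counter() - t0))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    with open(outdir / "timings.txt", "w") as fh:
        for name, dt in timings:
            fh.write(f"{name}\t{dt:.3f}s\n")
    config.to_yaml(outdir / "config_used.yaml")
    return report
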