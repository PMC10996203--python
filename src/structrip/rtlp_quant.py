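"""RTL-P quantification of rRNA 2'-O-methylation and delta-delta-Ct utilities.

RTL-P (reverse transcription at low dNTP followed by PCR) exploits the fact
that reverse transcriptase stalls at a 2'-O-methylated residue when dNTPs are
scarce.  Two amplicons are measured by qPCR across dNTP levels: FU (primer
upstream of the site: read-through-dependent) and FD (downstream: read-
through-independent control).  The per-level signal ratio FU/FD drops at low
dNTP (LD) in proportion to methylation; anchoring at high dNTP (HD) gives a
unit-free methylation index

    index = ratio(LD) / ratio(HD),  ratio(level) = signal(FU) / signal(FD),

with signal = 2^-Ct (100% amplification efficiency).  A lower index means
less read-through at low dNTP, i.e. more methylation.  Condition contrasts
(e.g. overexpression vs control) are index ratios with a paired Student's t
test on replicate-level log indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DNTP_LEVELS = ("LD", "MD", "HD")

QPCR_COLUMNS = ["sample", "condition", "amplicon", "dntp_level", "replicate", "ct"]


class CompletenessError(ValueError):
    """Required amplicon/level measurements are missing."""


def ddct(ct_target: float, ct_reference: float,
         ct_target_ctrl: float, ct_reference_ctrl: float) -> float:
    """Relative quantity by the 2^-ddCt method."""
    for ct in (ct_target, ct_reference, ct_target_ctrl, ct_reference_ctrl):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct_val = (ct_target - ct_reference) - (ct_target_ctrl - ct_reference_ctrl)
    return float(2.0 ** (-ddct_val))


def _signal(ct: np.ndarray, efficiency: float = 1.0) -> np.ndarray:
    return (1.0 + efficiency) ** (-np.asarray(ct, dtype=float))


@dataclass
class RtlpResult:
    site: str
    per_level_ratio: pd.DataFrame     # condition x dNTP level FU/FD signal ratio
    index: Dict[str, float]           # condition -> ratio(LD)/ratio(HD)
    replicate_index: pd.DataFrame     # condition x replicate indices
    contrasts: pd.DataFrame           # treated vs Ctrl: ratio of indices + paired t p


def rtlp_index(measurements: pd.DataFrame, site: str = "",
               control: str = "Ctrl", efficiency: float = 1.0) -> RtlpResult:
    """Compute the methylation index per condition and condition contrasts.

    ``measurements`` columns: condition, amplicon in {FU, FD}, dntp_level in
    {LD, MD, HD}, replicate, ct.  FU and FD must be present at LD and HD for
    every condition; MD is reported descriptively when present.
    """
    df = measurements.copy()
    missing = []
    for cond in df["condition"].unique():
        for amp in ("FU", "FD"):
            for level in ("LD", "HD"):
                sel = (df["condition"] == cond) & (df["amplicon"] == amp) \
                    & (df["dntp_level"] == level)
                if not sel.any():
                    missing.append(f"{cond}/{amp}/{level}")
    if missing:
        raise CompletenessError("missing measurements: " + ", ".join(missing))

    df["signal"] = _signal(df["ct"].to_numpy(), efficiency)

    # condition x level mean-signal ratios (replicates averaged on signal scale)
    mean_sig = (
        df.groupby(["condition", "amplicon", "dntp_level"])["signal"].mean().unstack("amplicon")
    )
    ratio = (mean_sig["FU"] / mean_sig["FD"]).unstack("dntp_level")

    index = {
        cond: float(ratio.loc[cond, "LD"] / ratio.loc[cond, "HD"])
        for cond in ratio.index
    }

    # replicate-level indices for the paired test
    rep_sig = (
        df.groupby(["condition", "replicate", "amplicon", "dntp_level"])["signal"]
        .mean().unstack(["amplicon", "dntp_level"])
    )
    rep_index = (
        (rep_sig[("FU", "LD")] / rep_sig[("FD", "LD")])
        / (rep_sig[("FU", "HD")] / rep_sig[("FD", "HD")])
    ).unstack("replicate")

    contrast_rows = []
    if control in index:
        ctrl_logs = np.log(rep_index.loc[control].to_numpy(dtype=float))
        for cond in index:
            if cond == control:
                continue
            logs = np.log(rep_index.loc[cond].to_numpy(dtype=float))
            n = min(len(logs), len(ctrl_logs))
            if n >= 2:
                t, p = stats.ttest_rel(logs[:n], ctrl_logs[:n])
            else:
                t, p = np.nan, np.nan
            contrast_rows.append(
                {"contrast": f"{cond} vs {control}",
                 "index_ratio": index[cond] / index[control],
                 "t": float(t), "p": float(p), "n_pairs": n}
            )
    return RtlpResult(
        site=site,
        per_level_ratio=ratio,
        index=index,
        replicate_index=rep_index,
        contrasts=pd.DataFrame(
            contrast_rows, columns=["contrast", "index_ratio", "t", "p", "n_pairs"]
        ),
    )


def simulate_rtlp(methylation: Dict[str, float], noise_sd: float = 0.1,
                  n_replicates: int = 3, stall_efficiency: float = 0.9,
                  site: str = "Am2388", seed: int = 0) -> pd.DataFrame:
    """Simulate RTL-P qPCR measurements under the stall model.

    ``methylation`` maps condition -> methylated fraction m in [0, 1].  The FU
    amplicon Ct at low dNTP increases by -log2(1 - m*s) cycles for stall
    efficiency s; FD and the high-dNTP level are unaffected.  Gaussian
    replicate noise of ``noise_sd`` cycles is added to every Ct; the noise is
    shared between the paired FU/LD measurements only through the replicate
    structure.  Expected index with no noise: 1 - m*s.
    """
    for cond, m in methylation.items():
        if not 0 <= m <= 1:
            raise ValueError(f"methylation fraction for {cond!r} outside [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base_ct = {"FU": 22.0, "FD": 20.0}
    rows = []
    for cond in sorted(methylation):
        m = methylation[cond]
        stall_shift = -np.log2(max(1e-12, 1.0 - m * stall_efficiency))
        for rep in range(1, n_replicates + 1):
            for level in DNTP_LEVELS:
                for amp in ("FU", "FD"):
                    ct = base_ct[amp]
                    if amp == "FU" and level == "LD":
                        ct += stall_shift
                    if amp == "FU" and level == "MD":
                        ct += 0.5 * stall_shift
                    ct += rng.normal(0.0, noise_sd)
                    rows.append(
                        {"sample": site, "condition": cond, "amplicon": amp,
                         "dntp_level": level, "replicate": rep, "ct": ct}
                    )
    return pd.DataFrame(rows, columns=QPCR_COLUMNS)
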