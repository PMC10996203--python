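"""Per-base coverage and domain-level binding density on the 28S rRNA.

The 28S secondary structure is summarized by six domains (I-VI) given as an
input interval table; the profile stage computes per-base read depth,
library-size-normalized density per domain, the maximal binding region
(bases above a fraction of the maximum depth), and whether annotated
2'-O-methylation residues (e.g. Am2388, Cm2409, Gm2411) fall inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class BoundsError(ValueError):
    """Alignment extends beyond the reference end."""


@dataclass(frozen=True)
class ModificationSite:
    rrna_id: str
    position: int  # 1-based residue
    label: str


def coverage_profile(aln: pd.DataFrame, length: int) -> np.ndarray:
    """Per-base read depth on a single reference (0-based vector of ``length``).

    depth[i] counts reads overlapping base i; alignment order does not matter.
    """
    depth = np.zeros(length + 1, dtype=np.int64)
    if len(aln):
        starts = aln["start"].to_numpy()
        ends = aln["end"].to_numpy()
        if (starts < 0).any() or (ends > length).any():
            raise BoundsError("alignment outside the reference bounds")
        np.add.at(depth, starts, 1)
        np.add.at(depth, ends, -1)
    return np.cumsum(depth)[:length]


def extract_28s_profile(unit_reads: pd.DataFrame, offset_28s: int,
                        len_28s: int) -> np.ndarray:
    """Depth over the 28S portion of 45S-unit-local reads, clipped to the 28S.

    ``offset_28s`` is the 0-based start of the 28S within the unit.
    """
    if len(unit_reads) == 0:
        return np.zeros(len_28s, dtype=np.int64)
    sub = unit_reads.copy()
    sub["start"] = np.clip(sub["start"] - offset_28s, 0, len_28s)
    sub["end"] = np.clip(sub["end"] - offset_28s, 0, len_28s)
    sub = sub[sub["end"] > sub["start"]]
    return coverage_profile(sub, len_28s)


def domain_density(depth: np.ndarray, domains: pd.DataFrame,
                   library_size: int) -> pd.DataFrame:
    """Reads-per-base density per domain, normalized per million mapped reads.

    density(d) = (sum of depth over d) / length(d) / (library_size / 1e6).
    """
    rows = []
    for _, row in domains.iterrows():
        s1, e1 = int(row["start"]), int(row["end"])
        if e1 < s1:
            raise ValueError(f"empty domain interval {row['name']}")
        mass = int(depth[s1 - 1:e1].sum())
        dlen = e1 - s1 + 1
        density = mass / dlen / (library_size / 1e6) if library_size > 0 else np.nan
        rows.append({"domain": row["name"], "start": s1, "end": e1,
                     "length": dlen, "depth_mass": mass, "density": density})
    return pd.DataFrame(rows)


def max_density_domain(density_table: pd.DataFrame) -> Optional[str]:
    """Domain of maximal density; first in table order on ties; None when all
    densities are zero or undefined."""
    dens = density_table["density"].to_numpy(dtype=float)
    if np.all(np.isnan(dens)) or np.nanmax(dens) <= 0:
        return None
    return str(density_table["domain"].iloc[int(np.nanargmax(dens))])


def call_binding_region(depth: np.ndarray, threshold: float = 0.5,
                        merge_gap: int = 20) -> List[Tuple[int, int]]:
    """Maximal runs of bases with depth >= threshold x max depth, merged
    across gaps <= merge_gap nt.  Returns 1-based closed intervals."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    max_depth = depth.max() if len(depth) else 0
    if max_depth <= 0:
        return []
    above = depth >= threshold * max_depth
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = [(int(edges[i]) + 1, int(edges[i + 1])) for i in range(0, len(edges), 2)]
    merged: List[Tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def check_modification_sites(regions: Sequence[Tuple[int, int]],
                             sites: Sequence[ModificationSite]) -> pd.DataFrame:
    """Flag each modification residue as contained in a binding region or not."""
    rows = []
    for site in sites:
        contained = any(s <= site.position <= e for s, e in regions)
        rows.append({"label": site.label, "position": site.position,
                     "contained": contained})
    return pd.DataFrame(rows, columns=["label", "position", "contained"])


def profile_28s(ip_unit_reads: pd.DataFrame, input_unit_reads: pd.DataFrame,
                domains: pd.DataFrame, offset_28s: int, len_28s: int,
                ip_library_size: int, input_library_size: int,
                threshold: float = 0.5, merge_gap: int = 20,
                sites: Sequence[ModificationSite] = ()) -> dict:
    """Full 28S profiling for one IP/Input pair: depth vectors, per-domain
    densities for IP and the IP/Input ratio, max domains, binding regions and
    modification-site containment."""
    depth_ip = extract_28s_profile(ip_unit_reads, offset_28s, len_28s)
    depth_in = extract_28s_profile(input_unit_reads, offset_28s, len_28s)
    dens_ip = domain_density(depth_ip, domains, ip_library_size)
    dens_in = domain_density(depth_in, domains, input_library_size)
    ratio = dens_ip.copy()
    ratio["density"] = dens_ip["density"] / (dens_in["density"] + 1e-9)
    regions = call_binding_region(depth_ip, threshold=threshold, merge_gap=merge_gap)
    return {
        "depth_ip": depth_ip,
        "depth_input": depth_in,
        "density_ip": dens_ip,
        "density_input": dens_in,
        "max_domain_ip": max_density_domain(dens_ip),
        "max_domain_ratio": max_density_domain(ratio),
        "binding_regions": regions,
        "modification_sites": check_modification_sites(regions, sites),
    }
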