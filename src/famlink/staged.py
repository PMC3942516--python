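"""Three-stage linkage workflow: discovery, extension, replication.

Stage 1 (discovery): genome-wide non-parametric scan in the discovery
families; peaks at LOD >= 2.2 (suggestive) define candidate regions as 2-LOD
support intervals.  Externally reported loci (peak marker + LOD or a
standardized Z score converted via LOD = Z²/(2 ln 10)) may be added to the
candidate list; lacking a curve, their interval is a configurable ±flank
around the hg19 anchor of the peak marker.

Stage 2 (extension): each candidate region is retested in the combined
sample restricted to the matching subgroup; LOD >= 2.2 within the interval
is "confirmed-suggestive".

Stage 3 (replication): only regions with genome-wide significant discovery
evidence (LOD >= 3.6) are tested, using exclusively the families not in the
corresponding discovery analysis; the region is "replicated" iff the minimum
pointwise P over interval markers is < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .npl import (
    SIGNIFICANT_LOD,
    SUGGESTIVE_LOD,
    find_peaks,
    linkage_curve,
    lod_to_pvalue,
    support_interval,
    z_to_lod,
)
from .pedigree_core import LinkageDataset
from .sexdiff import stratify_families


@dataclass
class CandidateRegion:
    source: str  # "stage1" or an external report label
    subgroup: str  # ALL / MO / FC
    chromosome: str
    peak_marker: str
    anchor_bp: int
    left_bp: int
    right_bp: int
    discovery_lod: float


def _subgroup_families(dataset: LinkageDataset, subgroup: str) -> list[str]:
    labels = stratify_families(dataset.pedigrees)
    if subgroup == "ALL":
        keep = labels["label"].isin(["MO", "FC"])
    elif subgroup in ("MO", "FC"):
        keep = labels["label"] == subgroup
    else:
        raise ValueError("subgroup must be ALL, MO or FC")
    fams = labels.loc[keep, "family"].tolist()
    if not fams:
        raise ValueError(f"subgroup {subgroup} contains no multiplex families")
    return fams


def run_stage_scan(
    dataset: LinkageDataset,
    subgroup: str = "ALL",
    statistic: str = "s_all",
    chromosomes: list[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Genome-wide scan for one subgroup: per-chromosome curves plus peaks."""
    fams = _subgroup_families(dataset, subgroup)
    chroms = chromosomes or dataset.marker_map.chromosomes()
    curves = {}
    peak_frames = []
    for chrom in chroms:
        curve = linkage_curve(dataset, chrom, statistic, family_ids=fams)
        curves[str(chrom)] = curve
        pk = find_peaks(curve)
        if len(pk):
            pk = pk.assign(subgroup=subgroup)
            peak_frames.append(pk)
    peaks = (
        pd.concat(peak_frames, ignore_index=True)
        if peak_frames
        else pd.DataFrame(columns=["marker", "chrom", "bp", "cM", "LOD", "tier", "subgroup"])
    )
    return curves, peaks


def define_candidate_regions(
    peaks: pd.DataFrame,
    curves: dict[str, pd.DataFrame],
    external_reports: pd.DataFrame | None = None,
    flank_bp: int = 10_000_000,
    suggestive: float = SUGGESTIVE_LOD,
) -> list[CandidateRegion]:
    """Candidate regions from scan peaks and/or externally reported loci.

    external_reports columns: source, subgroup, chrom, marker, bp, score,
    score_type ('LOD' or 'Z').  Z scores are converted with z_to_lod; loci
    below the suggestive threshold are dropped.  External loci get
    [anchor - flank, anchor + flank]; internal peaks get the 2-LOD support
    interval from their curve.
    """
    regions: list[CandidateRegion] = []
    for _, row in peaks.iterrows():
        if row["LOD"] < suggestive:
            continue
        si = support_interval(curves[str(row["chrom"])], row["marker"])
        regions.append(
            CandidateRegion(
                source="stage1",
                subgroup=row.get("subgroup", "ALL"),
                chromosome=str(row["chrom"]),
                peak_marker=row["marker"],
                anchor_bp=int(row["bp"]),
                left_bp=si.left_bp,
                right_bp=si.right_bp,
                discovery_lod=float(row["LOD"]),
            )
        )
    if external_reports is not None:
        for _, row in external_reports.iterrows():
            lod = float(row["score"])
            if str(row["score_type"]).upper() == "Z":
                lod = z_to_lod(lod)
            if lod < suggestive:
                continue
            if pd.isna(row.get("bp")):
                raise ValueError(
                    f"external report {row['marker']!r} has no mappable hg19 anchor"
                )
            anchor = int(row["bp"])
            regions.append(
                CandidateRegion(
                    source=str(row["source"]),
                    subgroup=str(row["subgroup"]),
                    chromosome=str(row["chrom"]),
                    peak_marker=str(row["marker"]),
                    anchor_bp=anchor,
                    left_bp=max(0, anchor - flank_bp),
                    right_bp=anchor + flank_bp,
                    discovery_lod=lod,
                )
            )
    return regions


def _region_curve(
    dataset: LinkageDataset,
    region: CandidateRegion,
    family_ids: list[str],
    statistic: str,
) -> pd.DataFrame:
    curve = linkage_curve(dataset, region.chromosome, statistic, family_ids)
    inside = (curve["bp"] >= region.left_bp) & (curve["bp"] <= region.right_bp)
    if not inside.any():
        raise ValueError(f"no markers inside region around {region.peak_marker}")
    return curve[inside].reset_index(drop=True)


def evaluate_extension(
    combined: LinkageDataset,
    regions: list[CandidateRegion],
    statistic: str = "s_all",
) -> pd.DataFrame:
    """Retest candidate regions in the combined sample (matching subgroup).

    Classification: confirmed-suggestive iff the peak LOD inside the interval
    is >= 2.2 (inclusive), else not-supported.
    """
    rows = []
    for region in regions:
        fams = _subgroup_families(combined, region.subgroup)
        cur = _region_curve(combined, region, fams, statistic)
        k = int(cur["LOD"].idxmax())
        lod = float(cur["LOD"].iloc[k])
        rows.append(
            {
                "source": region.source,
                "subgroup": region.subgroup,
                "chrom": region.chromosome,
                "region_peak": region.peak_marker,
                "extension_peak": cur["marker"].iloc[k],
                "extension_LOD": lod,
                "extension_P": lod_to_pvalue(lod) if lod > 0 else 0.5,
                "classification": (
                    "confirmed-suggestive" if lod >= SUGGESTIVE_LOD else "not-supported"
                ),
            }
        )
    return pd.DataFrame(rows)


def evaluate_replication(
    combined: LinkageDataset,
    region: CandidateRegion,
    discovery_family_ids: list[str],
    statistic: str = "s_all",
    replication_alpha: float = 0.01,
) -> dict:
    """Formal replication in the independent families only.

    Attempted only when the discovery LOD is genome-wide significant
    (>= 3.6); raises otherwise.  Tests linkage restricted to the region using
    the matching subgroup's families that were NOT in the discovery set, and
    declares replication iff the minimum pointwise P across interval markers
    is < replication_alpha (marker-wise, no further multiplicity adjustment).
    """
    if region.discovery_lod < SIGNIFICANT_LOD:
        raise ValueError(
            f"replication requires genome-wide significant discovery LOD "
            f">= {SIGNIFICANT_LOD}; got {region.discovery_lod:.2f}"
        )
    subgroup_fams = _subgroup_families(combined, region.subgroup)
    discovery = set(discovery_family_ids)
    independent = [f for f in subgroup_fams if f not in discovery]
    if not independent:
        raise ValueError("no independent families available for replication")
    if set(subgroup_fams) != (discovery & set(subgroup_fams)) | set(independent):
        raise AssertionError("discovery ∪ independent must cover the combined subgroup")

    cur = _region_curve(combined, region, independent, statistic)
    k = int(cur["P"].idxmin())
    min_p = float(cur["P"].iloc[k])
    return {
        "source": region.source,
        "subgroup": region.subgroup,
        "chrom": region.chromosome,
        "region_peak": region.peak_marker,
        "n_independent_families": len(independent),
        "replication_marker": cur["marker"].iloc[k],
        "replication_min_P": min_p,
        "replication_LOD": float(cur["LOD"].iloc[k]),
        "replicated": bool(min_p < replication_alpha),
        "classification": "replicated" if min_p < replication_alpha else "not-supported",
    }
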