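"""Genotype and sample quality control, platform merging and LD pruning.

Default thresholds reproduce the conventional family-study pipeline: drop
subjects and SNPs with >5% missing data, SNPs violating Hardy–Weinberg at
P < 1e-7 in founders, minor allele frequency < 1%, or >10 Mendelian errors;
prune the linkage marker panel to pairwise r² ≤ 0.1, and count independent
SNPs in a region at r² < 0.3 for regional multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree_core import (
    GenotypeTable,
    Individual,
    LinkageDataset,
    MarkerMap,
    build_dataset,
)


@dataclass
class QCThresholds:
    max_missing_per_snp: float = 0.05
    max_missing_per_individual: float = 0.05
    min_maf: float = 0.01
    hwe_p_floor: float = 1e-7
    max_mendel_errors_per_snp: int = 10
    linkage_prune_r2: float = 0.1
    independence_r2: float = 0.3


@dataclass
class QCReport:
    """Per-filter removal bookkeeping; removals partition the removed sets."""

    removed_individuals: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    removed_markers: dict[str, list[str]] = field(default_factory=dict)
    surviving_individuals: list[tuple[str, str]] = field(default_factory=list)
    surviving_markers: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {f"individuals_removed_{k}": len(v) for k, v in self.removed_individuals.items()}
        out.update({f"markers_removed_{k}": len(v) for k, v in self.removed_markers.items()})
        out["individuals_surviving"] = len(self.surviving_individuals)
        out["markers_surviving"] = len(self.surviving_markers)
        return out


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability is less than or equal to
    the observed one (mid-free two-sided exact test).  Computed in log space
    via lgamma so large founder samples are safe.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_AA + n_Aa  # count of allele A
    n_b = 2 * n_aa + n_Aa
    rare = min(n_a, n_b)

    def log_prob(het: int) -> float:
        # P(het | allele counts) ∝ 2^het * n! / (nAA! nAa! naa!)
        hom_rare = (rare - het) // 2
        hom_common = (max(n_a, n_b) - het) // 2
        return (
            het * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(hom_common + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    mx = max(logs.values())
    total = sum(math.exp(v - mx) for v in logs.values())
    obs = logs[n_Aa]
    p = sum(math.exp(v - mx) for v in logs.values() if v <= obs + 1e-12) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------


def _possible_transmitted(code: np.ndarray) -> set[int]:
    """Alleles a parent genotype can transmit; missing parent can give either."""
    if code[0] < 0:
        return {0, 1}
    return {int(code[0]), int(code[1])}


def _trio_compatible(child: np.ndarray, father: np.ndarray, mother: np.ndarray) -> bool:
    if (child < 0).any():
        return True
    c1, c2 = int(child[0]), int(child[1])
    pf = _possible_transmitted(father)
    pm = _possible_transmitted(mother)
    return (c1 in pf and c2 in pm) or (c2 in pf and c1 in pm)


def mendelian_error_count(dataset: LinkageDataset) -> pd.DataFrame:
    """Per-(marker, family) count of parent–child incompatibilities.

    A trio errs at a marker when the child's genotype cannot be produced by
    any transmission from the recorded parents (missing genotypes are
    marginalized, so duos with one genotyped parent are still checked).
    Returns a long DataFrame: marker, family, errors (>0 rows only) — use
    groupby('marker') for per-SNP totals.
    """
    codes = dataset.genotypes.codes
    markers = dataset.marker_map.markers
    rows = []
    for fid, ped in dataset.pedigrees.items():
        trios = []
        for child in ped.nonfounders:
            try:
                rc = dataset.row_of(fid, child.person_id)
                rf = dataset.row_of(fid, child.father_id)
                rm = dataset.row_of(fid, child.mother_id)
            except KeyError:
                continue
            trios.append((rc, rf, rm))
        if not trios:
            continue
        for m, marker in enumerate(markers):
            errs = sum(
                0 if _trio_compatible(codes[rc, m], codes[rf, m], codes[rm, m]) else 1
                for rc, rf, rm in trios
            )
            if errs:
                rows.append({"marker": marker, "family": fid, "errors": errs})
    return pd.DataFrame(rows, columns=["marker", "family", "errors"])


def _scrub_mendel_errors(dataset: LinkageDataset, errors: pd.DataFrame) -> None:
    """Set offending trio genotypes missing (in place) so markers stay usable."""
    codes = dataset.genotypes.codes
    for _, row in errors.iterrows():
        m = dataset.marker_column(row["marker"])
        ped = dataset.pedigrees[row["family"]]
        for child in ped.nonfounders:
            try:
                rc = dataset.row_of(row["family"], child.person_id)
                rf = dataset.row_of(row["family"], child.father_id)
                rm = dataset.row_of(row["family"], child.mother_id)
            except KeyError:
                continue
            if not _trio_compatible(codes[rc, m], codes[rf, m], codes[rm, m]):
                codes[rc, m] = -1
                codes[rf, m] = -1
                codes[rm, m] = -1


# ---------------------------------------------------------------------------
# The QC filter cascade
# ---------------------------------------------------------------------------


def _rebuild(dataset: LinkageDataset, rows: np.ndarray, cols: np.ndarray) -> LinkageDataset:
    individuals = []
    for r in rows:
        fam = dataset.sample_index["family"].iloc[r]
        individuals.append(dataset.pedigrees[fam].member(dataset.sample_index["person"].iloc[r]))
    codes = dataset.genotypes.codes[np.ix_(rows, cols)].copy()
    syms = [dataset.genotypes.allele_symbols[c] for c in cols]
    keep_markers = [dataset.marker_map.markers[c] for c in cols]
    return build_dataset(individuals, codes, syms, dataset.marker_map.subset(keep_markers))


def founder_genotype_counts(dataset: LinkageDataset) -> np.ndarray:
    """(n_markers, 3) founder counts of genotypes [hom0, het, hom1]."""
    founder_rows = [
        r
        for r in range(dataset.n_individuals)
        if dataset.pedigrees[dataset.sample_index["family"].iloc[r]]
        .member(dataset.sample_index["person"].iloc[r])
        .is_founder
    ]
    sub = dataset.genotypes.codes[founder_rows]  # (f, m, 2)
    nonmiss = (sub >= 0).all(axis=2)
    tot = sub.sum(axis=2)  # 0,1,2 when non-missing
    out = np.zeros((dataset.n_markers, 3), dtype=int)
    for g in (0, 1, 2):
        out[:, g] = ((tot == g) & nonmiss).sum(axis=0)
    return out


def snp_qc_filter(
    dataset: LinkageDataset, thresholds: QCThresholds | None = None
) -> tuple[LinkageDataset, QCReport]:
    """Apply the QC cascade in a fixed, documented order.

    Order: per-individual missingness → per-SNP missingness → HWE (founders)
    → MAF → Mendelian-error cap.  Order matters for the counts; this one
    removes bad samples first so marker statistics are computed on the
    surviving roster.  Mendelian counting scrubs offending trio genotypes to
    missing, so markers under the error cap remain usable.
    """
    thr = thresholds or QCThresholds()
    report = QCReport()

    # individuals over the missingness cut are excluded by blanking their
    # genotypes, not by deleting them: parents must stay in the pedigree for
    # the trio-based checks downstream.  Already-blank individuals carry
    # nothing to exclude, which keeps the filter idempotent.
    miss = dataset.genotypes.missing_mask()
    ind_miss = miss.mean(axis=1)
    bad_ind = (ind_miss > thr.max_missing_per_individual) & (ind_miss < 1.0)
    report.removed_individuals["missingness"] = [
        (dataset.sample_index["family"].iloc[r], dataset.sample_index["person"].iloc[r])
        for r in np.flatnonzero(bad_ind)
    ]
    ds = _rebuild(dataset, np.arange(dataset.n_individuals), np.arange(dataset.n_markers))
    ds.genotypes.codes[np.flatnonzero(bad_ind)] = -1

    markers = np.array(ds.marker_map.markers)
    alive = np.ones(len(markers), dtype=bool)

    # per-SNP missingness over individuals that contribute any data at all
    contributing = ~ds.genotypes.missing_mask().all(axis=1)
    if not contributing.any():
        raise ValueError("no genotyped individuals survive QC")
    snp_miss = ds.genotypes.missing_mask()[contributing].mean(axis=0)
    cut = snp_miss > thr.max_missing_per_snp
    report.removed_markers["missingness"] = list(markers[cut])
    alive &= ~cut

    gcounts = founder_genotype_counts(ds)
    hwe_p = np.ones(len(markers))
    for m in np.flatnonzero(alive):
        if gcounts[m].sum() > 0:
            hwe_p[m] = hwe_exact_p(*gcounts[m])
    cut = alive & (hwe_p < thr.hwe_p_floor)
    report.removed_markers["hwe"] = list(markers[cut])
    alive &= ~cut

    ac = np.stack([2 * gcounts[:, 0] + gcounts[:, 1], 2 * gcounts[:, 2] + gcounts[:, 1]], axis=1)
    tot = ac.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, ac.min(axis=1) / np.maximum(tot, 1), 0.0)
    cut = alive & (maf < thr.min_maf)
    report.removed_markers["maf"] = list(markers[cut])
    alive &= ~cut

    errors = mendelian_error_count(ds)
    if len(errors):
        per_snp = errors.groupby("marker")["errors"].sum()
        bad = set(per_snp.index[per_snp > thr.max_mendel_errors_per_snp])
    else:
        bad = set()
    cut = alive & np.isin(markers, list(bad))
    report.removed_markers["mendel"] = list(markers[cut])
    alive &= ~cut
    if len(errors):
        _scrub_mendel_errors(ds, errors[~errors["marker"].isin(bad)])

    if not alive.any():
        raise ValueError("no markers survive QC")

    out = _rebuild(ds, np.arange(ds.n_individuals), np.flatnonzero(alive))
    excluded = set(report.removed_individuals["missingness"])
    report.surviving_individuals = [
        (out.sample_index["family"].iloc[r], out.sample_index["person"].iloc[r])
        for r in range(out.n_individuals)
        if (out.sample_index["family"].iloc[r], out.sample_index["person"].iloc[r])
        not in excluded
    ]
    report.surviving_markers = out.marker_map.markers
    return out, report


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_datasets(datasets: list[LinkageDataset], mode: str = "union") -> LinkageDataset:
    """Merge platform datasets over samples; marker set by union or intersection.

    Allele coding is harmonized by symbol; a marker typed with disjoint allele
    sets on two platforms raises (strand/coding error).  Union mode leaves a
    sample missing at markers its platform did not type.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    if not datasets:
        raise ValueError("nothing to merge")

    marker_sets = [set(d.marker_map.markers) for d in datasets]
    if mode == "union":
        keep = set().union(*marker_sets)
    else:
        keep = set.intersection(*marker_sets)
    # marker order: first-seen across datasets, map info from first carrier
    ordered: list[str] = []
    map_rows = []
    for d in datasets:
        for _, row in d.marker_map.table.iterrows():
            if row["marker"] in keep and row["marker"] not in ordered:
                ordered.append(row["marker"])
                map_rows.append(row)
    merged_map = MarkerMap(pd.DataFrame(map_rows).reset_index(drop=True))

    # harmonize allele symbol tables
    symtabs: dict[str, list[str]] = {m: [] for m in ordered}
    for d in datasets:
        for j, m in enumerate(d.marker_map.markers):
            if m not in symtabs:
                continue
            tab = symtabs[m]
            for s in d.genotypes.allele_symbols[j]:
                if s not in tab:
                    tab.append(s)
            if len(tab) > 2:
                raise ValueError(
                    f"marker {m!r}: allele coding mismatch across platforms ({tab})"
                )
    individuals: list[Individual] = []
    blocks = []
    for d in datasets:
        block = np.full((d.n_individuals, len(ordered), 2), -1, dtype=np.int8)
        col_of = {m: j for j, m in enumerate(d.marker_map.markers)}
        for k, m in enumerate(ordered):
            j = col_of.get(m)
            if j is None:
                continue
            recode = np.array(
                [symtabs[m].index(s) for s in d.genotypes.allele_symbols[j]] + [0, 0],
                dtype=np.int8,
            )[:2] if d.genotypes.allele_symbols[j] else np.zeros(2, dtype=np.int8)
            src = d.genotypes.codes[:, j, :]
            dst = np.where(src >= 0, recode[np.clip(src, 0, 1)], -1).astype(np.int8)
            block[:, k, :] = dst
        blocks.append(block)
        for r in range(d.n_individuals):
            fam = d.sample_index["family"].iloc[r]
            individuals.append(d.pedigrees[fam].member(d.sample_index["person"].iloc[r]))

    codes = np.concatenate(blocks, axis=0)
    return build_dataset(individuals, codes, [symtabs[m] for m in ordered], merged_map)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _founder_dosages(dataset: LinkageDataset) -> np.ndarray:
    """(n_founders, n_markers) allele-1 dosage with NaN for missing."""
    rows = [
        r
        for r in range(dataset.n_individuals)
        if dataset.pedigrees[dataset.sample_index["family"].iloc[r]]
        .member(dataset.sample_index["person"].iloc[r])
        .is_founder
    ]
    sub = dataset.genotypes.codes[rows].astype(float)
    dose = sub.sum(axis=2)
    dose[(sub < 0).any(axis=2)] = np.nan
    return dose


def _pairwise_r2(dose: np.ndarray, i: int, j: int) -> float:
    """Composite-LD r²: squared Pearson correlation of genotype dosages."""
    ok = ~np.isnan(dose[:, i]) & ~np.isnan(dose[:, j])
    if ok.sum() < 3:
        return 0.0
    x, y = dose[ok, i], dose[ok, j]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _prune_indices(
    dose: np.ndarray, idx: list[int], maf: np.ndarray, r2_threshold: float
) -> set[int]:
    """All-pairs pruning among idx to fixed point; returns removed set.

    Removal rule (deterministic): among offending pairs pick the pair with the
    highest r²; remove the member with the smaller MAF, ties broken toward the
    later marker.
    """
    removed: set[int] = set()
    alive = [i for i in idx]
    r2 = {}
    while True:
        worst = None
        worst_r2 = r2_threshold
        live = [i for i in alive if i not in removed]
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                key = (live[a], live[b])
                if key not in r2:
                    r2[key] = _pairwise_r2(dose, *key)
                if r2[key] > worst_r2:
                    worst_r2 = r2[key]
                    worst = key
        if worst is None:
            return removed
        i, j = worst
        if maf[i] < maf[j]:
            removed.add(i)
        elif maf[j] < maf[i]:
            removed.add(j)
        else:
            removed.add(max(i, j))


def ld_prune(
    dataset: LinkageDataset,
    r2_threshold: float = 0.1,
    window_size: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained marker ids.

    Windows of `window_size` markers advance by `step` along each chromosome;
    within each window, while any retained pair exceeds the r² threshold the
    member of the worst pair with smaller founder MAF (ties: later position)
    is removed.  r² is the squared correlation of founder genotype dosages.
    """
    if not 0 < r2_threshold < 1:
        raise ValueError("r2_threshold must be in (0,1)")
    dose = _founder_dosages(dataset)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dose, axis=0) / 2.0
    maf = np.minimum(np.nan_to_num(p, nan=0.0), 1 - np.nan_to_num(p, nan=0.0))

    removed: set[int] = set()
    tab = dataset.marker_map.table
    for chrom in dataset.marker_map.chromosomes():
        sub = dataset.marker_map.chromosome_markers(chrom)
        cols = [int(tab.index[tab["marker"] == m][0]) for m in sub["marker"]]
        start = 0
        while True:
            window = [c for c in cols[start : start + window_size] if c not in removed]
            removed |= _prune_indices(dose, window, maf, r2_threshold)
            if start + window_size >= len(cols):
                break
            start += step
    return [m for k, m in enumerate(dataset.marker_map.markers) if k not in removed]


def count_independent_snps(
    dataset: LinkageDataset,
    region: tuple[str, int, int],
    r2: float = 0.3,
) -> int:
    """Number of independent SNPs in (chrom, start_bp, end_bp) at pairwise r² < r2.

    Pruning is run with a window spanning the whole region, i.e. exact
    all-pairs independence within the region.
    """
    chrom, start, end = region
    tab = dataset.marker_map.table
    inside = tab[(tab["chrom"] == str(chrom)) & (tab["bp"] >= start) & (tab["bp"] <= end)]
    if inside.empty:
        import warnings

        warnings.warn(f"region {region} contains no markers", stacklevel=2)
        return 0
    sub = dataset.subset_markers(inside["marker"].tolist())
    kept = ld_prune(sub, r2_threshold=r2, window_size=len(inside), step=max(1, len(inside)))
    return len(kept)
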