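"""Exact non-parametric multipoint linkage for nuclear families.

The machinery is the classic affected-relative allele-sharing pipeline:

1.  For each family, the inheritance pattern at a locus is a binary vector v
    with one bit per meiosis (paternal and maternal bit per child) indicating
    which grand-parental allele was transmitted.  Single-marker likelihoods
    P(G | v) are computed by summing over founder allele assignments weighted
    by population allele frequencies.
2.  A hidden-Markov chain over marker positions (Haldane transitions, each
    meiosis independent) gives the exact multipoint posterior over v at every
    marker (forward–backward; nuclear families have at most 4^c states, so
    full enumeration is exact and cheap).
3.  Sharing among affected children is scored with the Whittemore–Halpern
    statistics S_pairs or S_all, standardized per family against the exact
    null (uniform) distribution over inheritance vectors: Z_i = (E[S|data] −
    μ0)/σ0.
4.  Family scores are combined with the Kong–Cox linear model: maximize
    ℓ(δ) = Σ_i log10(1 + δ γ_i Z_i) over δ ≥ 0, with γ_i = 1/√N and δ capped
    so the likelihood stays valid for every attainable family score.  The
    maximized value is the reported LOD; pointwise P comes from the one-sided
    normal tail of Z = √(2 ln10 · LOD).

X-chromosome mode treats males as hemizygous: fathers carry one X allele
passed to every daughter, male meioses contribute no bits, and sharing is
scored over each child's actual X allele origins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .pedigree_core import (
    AFF_AFFECTED,
    SEX_FEMALE,
    SEX_MALE,
    LinkageDataset,
    Pedigree,
    haldane_theta,
)

LN10 = math.log(10.0)

SUGGESTIVE_LOD = 2.2
SIGNIFICANT_LOD = 3.6


# ---------------------------------------------------------------------------
# LOD / Z / P conversions
# ---------------------------------------------------------------------------


def lod_to_pvalue(lod: float | np.ndarray) -> float | np.ndarray:
    """One-sided pointwise P for a Kong–Cox LOD: P = Φ̄(√(2 ln10 · LOD)).

    LOD 0 (the boundary of the one-sided model) maps to P = 0.5.
    """
    arr = np.asarray(lod, dtype=float)
    if (arr < 0).any():
        raise ValueError("LOD must be non-negative")
    p = norm.sf(np.sqrt(2.0 * LN10 * arr))
    return float(p) if np.isscalar(lod) else p


def pvalue_to_lod(p: float | np.ndarray) -> float | np.ndarray:
    """Inverse of lod_to_pvalue for P in (0, 0.5]."""
    arr = np.asarray(p, dtype=float)
    if ((arr <= 0) | (arr > 0.5)).any():
        raise ValueError("P must be in (0, 0.5]")
    z = norm.isf(arr)
    out = z * z / (2.0 * LN10)
    return float(out) if np.isscalar(p) else out


def z_to_lod(z: float | np.ndarray) -> float | np.ndarray:
    """Convert a standardized sharing score to a LOD: LOD = Z²/(2 ln 10)."""
    arr = np.asarray(z, dtype=float)
    out = arr * arr / (2.0 * LN10)
    return float(out) if np.isscalar(z) else out


# ---------------------------------------------------------------------------
# Family inheritance engine
# ---------------------------------------------------------------------------


@dataclass
class FamilyScore:
    """One family's standardized sharing score at one position."""

    family_id: str
    z: float
    z_min: float
    gamma: float = 1.0
    informative: bool = True


def _s_pairs(origins: list[list[tuple]], affected_idx: Sequence[int]) -> float:
    """Σ over affected pairs of the number of alleles shared IBD."""
    total = 0
    for a in range(len(affected_idx)):
        for b in range(a + 1, len(affected_idx)):
            o1 = list(origins[affected_idx[a]])
            o2 = list(origins[affected_idx[b]])
            for o in o1:
                if o in o2:
                    o2.remove(o)
                    total += 1
    return float(total)


def _s_all(origins: list[list[tuple]], affected_idx: Sequence[int]) -> float:
    """Whittemore–Halpern S_all, generalized to hemizygous members.

    Average over all ways h of picking one allele from each affected member of
    Π_i b_i(h)! where b_i counts how often founder allele i appears in h.
    """
    choices = [origins[i] for i in affected_idx]
    total = 0.0
    n_h = 1
    for c in choices:
        n_h *= len(c)
    for pick in product(*choices):
        counts: dict[tuple, int] = {}
        for o in pick:
            counts[o] = counts.get(o, 0) + 1
        term = 1.0
        for b in counts.values():
            term *= math.factorial(b)
        total += term
    return total / n_h


_INDICATOR_CACHE: dict[tuple, dict[tuple, np.ndarray]] = {}


class NuclearFamilyEngine:
    """Exact inheritance-vector computations for one nuclear family.

    Enumerates the full inheritance-vector space (4^c states on autosomes,
    2^c maternal-bit states on X), precomputes sharing scores and their exact
    null moments, and evaluates single-marker likelihoods and multipoint
    posteriors.  No founder-phase reduction is applied: nuclear sib-ship
    state spaces are small enough that full enumeration is exact and fast.
    """

    def __init__(self, pedigree: Pedigree, statistic: str = "s_all", x_chrom: bool = False):
        if not pedigree.is_nuclear:
            raise ValueError(f"family {pedigree.family_id} is not nuclear")
        if statistic not in ("s_all", "s_pairs"):
            raise ValueError("statistic must be 's_all' or 's_pairs'")
        self.pedigree = pedigree
        self.statistic = statistic
        self.x_chrom = x_chrom
        self.father = next(f for f in pedigree.founders if f.sex == SEX_MALE)
        self.mother = next(f for f in pedigree.founders if f.sex == SEX_FEMALE)
        self.children = pedigree.nonfounders
        self.affected_idx = [
            k for k, c in enumerate(self.children) if c.affection == AFF_AFFECTED
        ]
        if len(self.affected_idx) < 2:
            raise ValueError(
                f"family {pedigree.family_id}: sharing statistics need >=2 affected children"
            )
        c = len(self.children)
        if x_chrom:
            self.n_bits = c
            states = np.array(list(product([0, 1], repeat=c)), dtype=np.int8)
            self.mat_bits = states
            self.pat_bits = None
        else:
            self.n_bits = 2 * c
            states = np.array(list(product([0, 1], repeat=2 * c)), dtype=np.int8)
            self.pat_bits = states[:, :c]
            self.mat_bits = states[:, c:]
        self.n_states = states.shape[0]
        self._bit_states = states
        self.scores = self._compute_scores()
        self.mu0 = float(self.scores.mean())
        self.sigma0 = float(self.scores.std())
        if self.sigma0 > 0:
            self.z_min = float((self.scores.min() - self.mu0) / self.sigma0)
        else:
            self.z_min = 0.0
        self._hamming = (
            self._bit_states[:, None, :] != self._bit_states[None, :, :]
        ).sum(axis=2)
        self._founder_assignments = self._enumerate_founders()
        # indicator tensors depend only on family shape (and child sexes on
        # X), not on affection or allele frequencies — share across families
        if x_chrom:
            shape_key = ("x", tuple(ch.sex for ch in self.children))
        else:
            shape_key = ("auto", len(self.children))
        self._emission_cache = _INDICATOR_CACHE.setdefault(shape_key, {})

    # -- structure ----------------------------------------------------------

    def _child_origins(self, s: int) -> list[list[tuple]]:
        """Per child: list of founder-allele origin labels carried at a locus."""
        origins = []
        for k, child in enumerate(self.children):
            if self.x_chrom:
                o = []
                if child.sex == SEX_FEMALE:
                    o.append(("F", 0))  # father's single X
                o.append(("M", int(self.mat_bits[s, k])))
            else:
                o = [("F", int(self.pat_bits[s, k])), ("M", int(self.mat_bits[s, k]))]
            origins.append(o)
        return origins

    def _compute_scores(self) -> np.ndarray:
        fn = _s_pairs if self.statistic == "s_pairs" else _s_all
        return np.array(
            [fn(self._child_origins(s), self.affected_idx) for s in range(self.n_states)]
        )

    def _enumerate_founders(self) -> np.ndarray:
        """(n_assignments, n_founder_alleles) allele index per founder slot.

        Autosome slots: (father0, father1, mother0, mother1).
        X slots: (fatherX, mother0, mother1).
        """
        n_slots = 3 if self.x_chrom else 4
        return np.array(list(product([0, 1], repeat=n_slots)), dtype=np.int8)

    # -- single-marker likelihood -------------------------------------------

    def _indicator_tensor(self, gsum: tuple[int, ...]) -> np.ndarray:
        """(n_assignments, n_states) genotype-compatibility indicator.

        gsum: allele-index sums (0/1/2) per member in order (father, mother,
        children...), -1 for missing.
        """
        key = gsum
        cached = self._emission_cache.get(key)
        if cached is not None:
            return cached
        A = self._founder_assignments
        nA = A.shape[0]
        ind = np.ones((nA, self.n_states), dtype=float)
        gf, gm = gsum[0], gsum[1]
        if self.x_chrom:
            fa = A[:, 0]
            mo = A[:, 1:3]
            if gf >= 0:  # father hemizygous, stored as homozygous diplotype
                ok = (2 * fa == gf)
                ind *= ok[:, None]
            if gm >= 0:
                ind *= (mo.sum(axis=1) == gm)[:, None]
            for k, child in enumerate(self.children):
                g = gsum[2 + k]
                if g < 0:
                    continue
                mat_allele = mo[np.arange(nA)[:, None], self.mat_bits[:, k][None, :]]
                if child.sex == SEX_MALE:
                    ok = 2 * mat_allele == g
                else:
                    ok = fa[:, None] + mat_allele == g
                ind *= ok
        else:
            fa = A[:, 0:2]
            mo = A[:, 2:4]
            if gf >= 0:
                ind *= (fa.sum(axis=1) == gf)[:, None]
            if gm >= 0:
                ind *= (mo.sum(axis=1) == gm)[:, None]
            for k in range(len(self.children)):
                g = gsum[2 + k]
                if g < 0:
                    continue
                pat_allele = fa[np.arange(nA)[:, None], self.pat_bits[:, k][None, :]]
                mat_allele = mo[np.arange(nA)[:, None], self.mat_bits[:, k][None, :]]
                ind *= pat_allele + mat_allele == g
        self._emission_cache[key] = ind
        return ind

    def marker_likelihood(self, gsum: tuple[int, ...], freq1: float) -> np.ndarray:
        """P(G | v) for every inheritance vector at one marker.

        freq1 is the population frequency of allele index 1; founder allele
        assignments are weighted by Π p(allele).
        """
        ind = self._indicator_tensor(tuple(int(g) for g in gsum))
        A = self._founder_assignments.astype(float)
        w = freq1 ** A.sum(axis=1) * (1 - freq1) ** (A.shape[1] - A.sum(axis=1))
        return w @ ind

    # -- multipoint ---------------------------------------------------------

    def multipoint_posterior(
        self, emissions: np.ndarray, thetas: np.ndarray
    ) -> np.ndarray:
        """Forward–backward posterior over vectors at every marker.

        emissions: (n_markers, n_states) single-marker likelihoods;
        thetas: (n_markers-1,) recombination fractions between neighbours.
        Markers where the family is Mendelian-inconsistent (all-zero
        likelihood) are treated as uninformative (uniform emission).
        """
        E = emissions.copy()
        dead = E.sum(axis=1) == 0
        E[dead] = 1.0
        M, S = E.shape
        trans = [
            np.power(th, self._hamming) * np.power(1 - th, self.n_bits - self._hamming)
            for th in thetas
        ]
        fwd = np.empty((M, S))
        f = E[0] / S
        fwd[0] = f / f.sum()
        for k in range(1, M):
            f = (fwd[k - 1] @ trans[k - 1]) * E[k]
            fwd[k] = f / f.sum()
        bwd = np.empty((M, S))
        bwd[M - 1] = 1.0
        for k in range(M - 2, -1, -1):
            b = trans[k] @ (bwd[k + 1] * E[k + 1])
            bwd[k] = b / b.sum()
        post = fwd * bwd
        post /= post.sum(axis=1, keepdims=True)
        return post

    def posterior_z(self, posterior: np.ndarray) -> np.ndarray:
        """Standardized sharing score per position from a posterior matrix."""
        if self.sigma0 == 0:
            return np.zeros(posterior.shape[0])
        return (posterior @ self.scores - self.mu0) / self.sigma0


# module-level spec-shaped wrappers ------------------------------------------


def inheritance_likelihoods(
    pedigree: Pedigree,
    genotype_sums: Sequence[int],
    allele1_freq: float,
    statistic: str = "s_all",
    x_chrom: bool = False,
) -> np.ndarray:
    """P(G | v) over inheritance vectors for one marker.

    genotype_sums: allele-1 dosage (0/1/2, -1 missing) per member in order
    (father, mother, children in pedigree order).
    """
    eng = NuclearFamilyEngine(pedigree, statistic, x_chrom)
    return eng.marker_likelihood(tuple(genotype_sums), allele1_freq)


def sharing_score(
    pedigree: Pedigree,
    state_index: int,
    statistic: str = "s_all",
    x_chrom: bool = False,
) -> float:
    """Sharing score of one inheritance vector (indexed into the engine's grid)."""
    eng = NuclearFamilyEngine(pedigree, statistic, x_chrom)
    return float(eng.scores[state_index])


# ---------------------------------------------------------------------------
# Kong–Cox linear model
# ---------------------------------------------------------------------------


def _delta_max(gam_zmin: np.ndarray) -> float:
    neg = gam_zmin[gam_zmin < 0]
    if len(neg) == 0:
        return 1e6  # no attainable negative score constrains delta
    return float(np.min(-1.0 / neg))


def kong_cox_lod(
    z: np.ndarray,
    z_min: np.ndarray,
    gamma: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Maximize the Kong–Cox linear-model likelihood over δ ≥ 0.

    ℓ(δ) = Σ_i log10(1 + δ γ_i Z_i), maximized on [0, δ_max] where δ_max keeps
    1 + δ γ_i z is positive for every attainable family score z ≥ z_min_i.
    Returns (LOD, δ̂, overall Z = Σ γ_i Z_i).  One-sided: a non-positive
    overall Z gives δ̂ = 0 and LOD = 0.
    """
    z = np.asarray(z, dtype=float)
    z_min = np.asarray(z_min, dtype=float)
    if len(z) == 0:
        raise ValueError("no informative families")
    if gamma is None:
        gamma = np.full(len(z), 1.0 / math.sqrt(len(z)))
    gz = gamma * z
    overall_z = float(gz.sum())
    if overall_z <= 0:
        return 0.0, 0.0, overall_z
    dmax = _delta_max(gamma * z_min) * (1 - 1e-12)

    def neg_ell(d: float) -> float:
        arg = 1.0 + d * gz
        if (arg <= 0).any():
            return np.inf
        return -np.log10(arg).sum()

    res = minimize_scalar(neg_ell, bounds=(0.0, dmax), method="bounded",
                          options={"xatol": 1e-12})
    # the boundary can beat the interior optimum when the likelihood is
    # still rising at delta_max
    cands = [(0.0, 0.0), (float(res.x), -neg_ell(float(res.x)))]
    lb = -neg_ell(dmax)
    if np.isfinite(lb):
        cands.append((dmax, lb))
    dhat, lod = max(cands, key=lambda t: t[1])
    return float(max(lod, 0.0)), float(dhat), overall_z


def kong_cox_lod_batch(
    z: np.ndarray, z_min: np.ndarray, n_iter: int = 80
) -> np.ndarray:
    """Vectorized Kong–Cox LOD for B family-score vectors at once.

    z: (B, N) standardized scores, z_min: (B, N) attainable minima; equal
    weights 1/√N.  Golden-section maximization per row; used by the
    randomization test where thousands of subsets share a structure.
    """
    z = np.asarray(z, dtype=float)
    z_min = np.asarray(z_min, dtype=float)
    B, N = z.shape
    gam = 1.0 / math.sqrt(N)
    gz = gam * z
    gzmin = gam * z_min
    neg = np.where(gzmin < 0, -1.0 / gzmin, np.inf)
    dmax = neg.min(axis=1)
    dmax = np.where(np.isinf(dmax), 1e6, dmax) * (1 - 1e-12)

    def ell(d: np.ndarray) -> np.ndarray:
        arg = 1.0 + d[:, None] * gz
        bad = (arg <= 0).any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(arg > 0, np.log10(np.maximum(arg, 1e-300)), 0.0).sum(axis=1)
        return np.where(bad, -np.inf, val)

    phi = (math.sqrt(5.0) - 1.0) / 2.0
    lo = np.zeros(B)
    hi = dmax.copy()
    for _ in range(n_iter):
        x1 = hi - phi * (hi - lo)
        x2 = lo + phi * (hi - lo)
        take_right = ell(x1) < ell(x2)  # maximum lies right of x1
        lo = np.where(take_right, x1, lo)
        hi = np.where(take_right, hi, x2)
    best = np.maximum(ell((lo + hi) / 2.0), 0.0)
    best = np.maximum(best, np.maximum(ell(dmax), 0.0))  # rising-at-boundary case
    slope = gz.sum(axis=1)  # one-sided model: LOD 0 when sharing not in excess
    return np.where(slope <= 0, 0.0, best)


# ---------------------------------------------------------------------------
# Curves: Z tables and LOD along a chromosome
# ---------------------------------------------------------------------------


def informative_families(dataset: LinkageDataset) -> list[str]:
    """Nuclear families with >=2 genotyped affected children."""
    miss = dataset.genotypes.missing_mask()
    out = []
    for fid, ped in dataset.pedigrees.items():
        if not ped.is_nuclear:
            continue
        n_gen_aff = 0
        for c in ped.affected_children():
            r = dataset.row_of(fid, c.person_id)
            if not miss[r].all():
                n_gen_aff += 1
        if n_gen_aff >= 2:
            out.append(fid)
    return out


@dataclass
class FamilyZTable:
    """Per-family standardized sharing scores along one chromosome.

    The expensive part of a linkage scan.  Z is (n_families, n_markers);
    z_min is per family (structure-determined).  Any subset's Kong–Cox LOD
    curve is then a cheap reduction over rows — the randomization test
    exploits this.
    """

    family_ids: list[str]
    z: np.ndarray
    z_min: np.ndarray
    positions: pd.DataFrame  # marker, chrom, bp, cM

    def lod_curve(self, family_ids: Sequence[str] | None = None) -> pd.DataFrame:
        if family_ids is None:
            rows = np.arange(len(self.family_ids))
        else:
            index = {f: i for i, f in enumerate(self.family_ids)}
            rows = np.array([index[f] for f in family_ids], dtype=int)
        n = len(rows)
        if n == 0:
            raise ValueError("no informative families in selection")
        recs = []
        for m in range(self.z.shape[1]):
            lod, dhat, oz = kong_cox_lod(
                self.z[rows, m], self.z_min[rows]
            )
            recs.append((lod, dhat, oz))
        out = self.positions.copy().reset_index(drop=True)
        out["LOD"] = [r[0] for r in recs]
        out["delta"] = [r[1] for r in recs]
        out["Z"] = [r[2] for r in recs]
        out["P"] = [lod_to_pvalue(l) if l > 0 else 0.5 for l in out["LOD"]]
        return out


def family_z_table(
    dataset: LinkageDataset,
    chromosome: str,
    statistic: str = "s_all",
    family_ids: Sequence[str] | None = None,
) -> FamilyZTable:
    """Compute per-family multipoint Z along one chromosome's marker grid."""
    chrom = str(chromosome)
    x_chrom = chrom.upper() == "X"
    sub = dataset.marker_map.chromosome_markers(chrom)
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chromosome}")
    marker_ids = sub["marker"].tolist()
    cols = [dataset.marker_column(m) for m in marker_ids]
    cm = sub["cM"].to_numpy(dtype=float)
    thetas = haldane_theta(np.diff(cm))
    thetas = np.clip(np.atleast_1d(thetas), 1e-12, 0.5)
    freqs1 = dataset.allele_freqs[cols, 1]

    fams = family_ids if family_ids is not None else informative_families(dataset)
    codes = dataset.genotypes.codes
    z_rows, zmin_rows, kept = [], [], []
    for fid in fams:
        ped = dataset.pedigrees[fid]
        try:
            eng = NuclearFamilyEngine(ped, statistic, x_chrom)
        except ValueError:
            continue
        member_rows = [dataset.row_of(fid, eng.father.person_id),
                       dataset.row_of(fid, eng.mother.person_id)]
        member_rows += [dataset.row_of(fid, c.person_id) for c in eng.children]
        g = codes[member_rows][:, cols, :]  # (members, M, 2)
        gsum = np.where((g >= 0).all(axis=2), g.sum(axis=2), -1)  # (members, M)
        emissions = np.empty((len(cols), eng.n_states))
        for k in range(len(cols)):
            emissions[k] = eng.marker_likelihood(tuple(gsum[:, k]), float(freqs1[k]))
        post = eng.multipoint_posterior(emissions, thetas)
        z_rows.append(eng.posterior_z(post))
        zmin_rows.append(eng.z_min)
        kept.append(fid)
    if not kept:
        raise ValueError("no informative families")
    return FamilyZTable(
        kept,
        np.vstack(z_rows),
        np.array(zmin_rows),
        sub[["marker", "chrom", "bp", "cM"]].reset_index(drop=True),
    )


def linkage_curve(
    dataset: LinkageDataset,
    chromosome: str,
    statistic: str = "s_all",
    family_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Kong–Cox LOD curve along one chromosome.

    Columns: marker, chrom, bp, cM, LOD, delta, Z, P.
    """
    return family_z_table(dataset, chromosome, statistic, family_ids).lod_curve()


# ---------------------------------------------------------------------------
# Peaks and support intervals
# ---------------------------------------------------------------------------


@dataclass
class SupportInterval:
    chromosome: str
    peak_marker: str
    peak_lod: float
    left_marker: str
    right_marker: str
    left_bp: int
    right_bp: int
    left_cM: float
    right_cM: float
    drop: float
    left_at_end: bool
    right_at_end: bool


def find_peaks(
    curve: pd.DataFrame,
    suggestive: float = SUGGESTIVE_LOD,
    significant: float = SIGNIFICANT_LOD,
) -> pd.DataFrame:
    """Local LOD maxima at or above the suggestive threshold, tier-labeled.

    A plateau counts once; its representative marker is the smallest-bp
    position attaining the maximum.  Columns: marker, chrom, bp, cM, LOD, tier.
    """
    cur = curve.sort_values(["cM", "bp"], kind="stable").reset_index(drop=True)
    lod = cur["LOD"].to_numpy()
    n = len(lod)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and lod[j + 1] == lod[i]:
            j += 1
        left_ok = i == 0 or lod[i - 1] < lod[i]
        right_ok = j == n - 1 or lod[j + 1] < lod[i]
        if left_ok and right_ok and lod[i] >= suggestive:
            block = cur.iloc[i : j + 1]
            rep = block.loc[block["bp"].idxmin()]
            peaks.append(
                {
                    "marker": rep["marker"],
                    "chrom": rep["chrom"],
                    "bp": int(rep["bp"]),
                    "cM": float(rep["cM"]),
                    "LOD": float(lod[i]),
                    "tier": "significant" if lod[i] >= significant else "suggestive",
                }
            )
        i = j + 1
    return pd.DataFrame(peaks, columns=["marker", "chrom", "bp", "cM", "LOD", "tier"])


def support_interval(
    curve: pd.DataFrame, peak_marker: str, drop: float = 2.0
) -> SupportInterval:
    """Support interval: walk outward to the first positions where LOD has
    dropped by `drop` from the peak (crossing markers included, so the
    interval is inclusive); the chromosome end is used and flagged when the
    curve never drops."""
    cur = curve.sort_values(["cM", "bp"], kind="stable").reset_index(drop=True)
    idx = cur.index[cur["marker"] == peak_marker]
    if len(idx) != 1:
        raise ValueError(f"peak marker {peak_marker!r} not on curve")
    p = int(idx[0])
    peak_lod = float(cur["LOD"].iloc[p])
    floor = peak_lod - drop
    lod = cur["LOD"].to_numpy()

    left = p
    left_at_end = True
    for i in range(p - 1, -1, -1):
        left = i
        if lod[i] <= floor:
            left_at_end = False
            break
    if p == 0:
        left, left_at_end = 0, True

    right = p
    right_at_end = True
    for i in range(p + 1, len(lod)):
        right = i
        if lod[i] <= floor:
            right_at_end = False
            break
    if p == len(lod) - 1:
        right, right_at_end = len(lod) - 1, True

    lrow, rrow = cur.iloc[left], cur.iloc[right]
    return SupportInterval(
        chromosome=str(cur["chrom"].iloc[p]),
        peak_marker=peak_marker,
        peak_lod=peak_lod,
        left_marker=lrow["marker"],
        right_marker=rrow["marker"],
        left_bp=int(lrow["bp"]),
        right_bp=int(rrow["bp"]),
        left_cM=float(lrow["cM"]),
        right_cM=float(rrow["cM"]),
        drop=drop,
        left_at_end=left_at_end,
        right_at_end=right_at_end,
    )
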