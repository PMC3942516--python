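"""Synthetic multiplex-family cohort generator.

Emulates the statistical structure the linkage analyses assume: nuclear
families with two or more affected children ascertained from a generative
stream, biallelic SNP maps with Haldane (no-interference) recombination,
founders at linkage equilibrium, risk loci acting through sex-specific
penetrance tables, and the observational noise the QC stage must absorb
(missingness, allele-call errors, planted Mendelian violations).

The default configuration mirrors a large multiplex autism cohort:
~1,008 nuclear families with 2–3 children, ascertained for >=2 affected
children and rebalanced to ~60% male-only (MO) / 40% female-containing (FC).

Risk acts only through penetrance, so by default a planted locus produces
allele-sharing (linkage) signal at nearby markers without any
marker-association signal; setting ``typed=True`` on a risk locus exposes the
locus itself as a genotyped marker (perfect LD), creating a TDT-positive
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree_core import (
    AFF_AFFECTED,
    AFF_UNAFFECTED,
    SEX_FEMALE,
    SEX_MALE,
    Individual,
    LinkageDataset,
    MarkerMap,
    build_dataset,
    haldane_theta,
)


@dataclass
class RiskLocus:
    """A disease locus with a sex-specific penetrance table.

    penetrance maps sex ("male"/"female") to a 3-tuple (f0, f1, f2): the
    probability of affection given 0/1/2 copies of the risk allele.  On X,
    hemizygous males use f1 for their single copy.
    """

    chrom: str
    cM: float
    allele_freq: float
    penetrance: dict[str, tuple[float, float, float]]
    typed: bool = False
    name: str = "risk"

    def __post_init__(self) -> None:
        if not 0 < self.allele_freq < 1:
            raise ValueError("risk allele frequency must be in (0,1)")
        for sex, row in self.penetrance.items():
            if len(row) != 3 or any(not 0 <= f <= 1 for f in row):
                raise ValueError(f"penetrance[{sex}] must be three values in [0,1]")


@dataclass
class ChromosomeSpec:
    name: str
    n_markers: int
    spacing_cM: float = 10.0
    freq_range: tuple[float, float] = (0.2, 0.8)
    start_bp: int = 1_000_000
    bp_per_cM: float = 1_000_000.0

    def __post_init__(self) -> None:
        if self.spacing_cM <= 0:
            raise ValueError("marker spacing must be positive")


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic cohort."""

    n_families: int = 1008
    offspring_dist: dict[int, float] = field(default_factory=lambda: {2: 0.6, 3: 0.4})
    chromosomes: list[ChromosomeSpec] = field(
        default_factory=lambda: [ChromosomeSpec("1", n_markers=12, spacing_cM=10.0)]
    )
    risk_loci: list[RiskLocus] = field(default_factory=list)
    baseline_penetrance: float = 0.08
    target_mo_fraction: float | None = 0.60
    missingness: float = 0.0
    genotype_error_rate: float = 0.0
    n_mendel_errors: int = 0
    seed: int = 0
    max_attempt_factor: int = 2000  # abort after n_families * factor draws

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_penetrance <= 1:
            raise ValueError("baseline penetrance must be in [0,1]")
        if self.target_mo_fraction is not None and not 0 < self.target_mo_fraction < 1:
            raise ValueError("target MO fraction must be in (0,1)")
        for r in (self.missingness, self.genotype_error_rate):
            if not 0 <= r <= 1:
                raise ValueError("noise rates must be in [0,1]")
        tot = sum(self.offspring_dist.values())
        if tot <= 0 or any(k < 1 for k in self.offspring_dist):
            raise ValueError("offspring distribution must be over counts >=1")


@dataclass
class SyntheticCohort:
    """A LinkageDataset plus the ground truth needed to score recovery."""

    dataset: LinkageDataset
    config: SimulationConfig
    risk_truth: pd.DataFrame  # chrom, cM, bp, marker (id or ""), allele_freq
    family_labels: pd.DataFrame  # family, label (MO/FC), n_children, n_affected
    risk_dosages: pd.DataFrame  # family, person, locus, dosage
    pre_noise_codes: np.ndarray
    planted_mendel: list[tuple[str, str]]  # (family, marker)
    acceptance_rate: float


# ---------------------------------------------------------------------------
# Locus grids
# ---------------------------------------------------------------------------


@dataclass
class _LocusGrid:
    chrom: str
    cm: np.ndarray  # sorted positions
    freq1: np.ndarray  # allele-1 frequency per locus
    names: list[str]
    is_marker: np.ndarray  # bool; untyped risk loci excluded from dataset
    bp: np.ndarray
    risk_index: dict[int, int]  # grid column -> index into config.risk_loci


def _build_grids(config: SimulationConfig, rng: np.random.Generator) -> list[_LocusGrid]:
    grids = []
    for spec in config.chromosomes:
        cm = np.arange(spec.n_markers) * spec.spacing_cM
        lo, hi = spec.freq_range
        freq = rng.uniform(lo, hi, size=spec.n_markers)
        names = [f"snp{spec.name}_{k + 1}" for k in range(spec.n_markers)]
        is_marker = [True] * spec.n_markers
        risk_cols: list[tuple[float, int]] = []
        rows = list(zip(cm.tolist(), freq.tolist(), names, is_marker, [-1] * len(names)))
        for li, locus in enumerate(config.risk_loci):
            if str(locus.chrom) != spec.name:
                continue
            rows.append((locus.cM, locus.allele_freq, f"{locus.name}{li}", locus.typed, li))
        rows.sort(key=lambda t: t[0])
        cm_all = np.array([r[0] for r in rows])
        bp = (spec.start_bp + cm_all * spec.bp_per_cM).round().astype(np.int64)
        # distinct bp even for co-located loci
        for k in range(1, len(bp)):
            if bp[k] <= bp[k - 1]:
                bp[k] = bp[k - 1] + 1
        grids.append(
            _LocusGrid(
                chrom=spec.name,
                cm=cm_all,
                freq1=np.array([r[1] for r in rows]),
                names=[r[2] for r in rows],
                is_marker=np.array([r[3] for r in rows], dtype=bool),
                bp=bp,
                risk_index={k: r[4] for k, r in enumerate(rows) if r[4] >= 0},
            )
        )
    return grids


# ---------------------------------------------------------------------------
# Generative primitives (vectorized over families)
# ---------------------------------------------------------------------------


def simulate_founder_haplotypes(
    rng: np.random.Generator, freq1: np.ndarray, n_haplotypes: int
) -> np.ndarray:
    """(n_haplotypes, L) founder haplotypes at linkage equilibrium."""
    if ((freq1 <= 0) | (freq1 >= 1)).any():
        raise ValueError("allele frequencies must be in (0,1)")
    return (rng.random((n_haplotypes, len(freq1))) < freq1).astype(np.int8)


def _meiosis_bits(rng: np.random.Generator, shape: tuple, thetas: np.ndarray) -> np.ndarray:
    """Markov meiosis-indicator process: bit flips between loci with prob theta.

    shape is (..., L); thetas has length L-1.
    """
    L = shape[-1]
    flips = np.empty(shape, dtype=np.int8)
    flips[..., 0] = rng.random(shape[:-1]) < 0.5
    if L > 1:
        flips[..., 1:] = rng.random(shape[:-1] + (L - 1,)) < thetas
    return np.cumsum(flips, axis=-1, dtype=np.int64) % 2


def drop_haplotypes(
    parent_haps: np.ndarray, thetas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One meiosis: recombine a (2, L) parental diplotype into a (L,) gamete.

    Crossovers between adjacent loci occur with probability theta (Haldane,
    no interference) — the same transition kernel the linkage HMM assumes.
    """
    bits = _meiosis_bits(rng, (1, parent_haps.shape[1]), thetas)[0]
    return parent_haps[bits, np.arange(parent_haps.shape[1])]


def assign_affection(
    risk_dosages: np.ndarray,
    sexes: np.ndarray,
    risk_loci: list[RiskLocus],
    baseline: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Affection via independent liability channels.

    P(affected) = 1 - (1 - baseline) * prod_l (1 - f_l(g_l, sex)): each risk
    locus and the polygenic/environmental baseline act as independent causes.
    risk_dosages: (..., n_loci); sexes: (...) with 1=male, 0=female.
    """
    p_unaff = np.full(sexes.shape, 1.0 - baseline)
    for li, locus in enumerate(risk_loci):
        fm = np.asarray(locus.penetrance["male"])
        ff = np.asarray(locus.penetrance["female"])
        d = risk_dosages[..., li]
        f = np.where(sexes == 1, fm[d], ff[d])
        p_unaff = p_unaff * (1.0 - f)
    return rng.random(sexes.shape) < (1.0 - p_unaff)


# ---------------------------------------------------------------------------
# Batch family simulation
# ---------------------------------------------------------------------------


def _simulate_chromosome_batch(
    rng: np.random.Generator,
    grid: _LocusGrid,
    n_fam: int,
    max_kids: int,
    child_sex_male: np.ndarray,  # (n_fam, max_kids) bool
) -> dict[str, np.ndarray]:
    """Simulate one chromosome for a batch of nuclear families.

    Returns per-person allele arrays: father/mother (n_fam, 2, L) and child
    paternal/maternal gametes (n_fam, max_kids, L).  On X the father carries a
    single haplotype transmitted intact to daughters; sons receive only the
    maternal gamete (their paternal slot is a copy of the maternal allele so
    hemizygous genotypes are stored as homozygous diplotypes).
    """
    L = len(grid.cm)
    thetas = np.clip(haldane_theta(np.diff(grid.cm)), 1e-9, 0.5)
    is_x = grid.chrom.upper() == "X"

    fat = simulate_founder_haplotypes(rng, grid.freq1, 2 * n_fam).reshape(n_fam, 2, L)
    mot = simulate_founder_haplotypes(rng, grid.freq1, 2 * n_fam).reshape(n_fam, 2, L)

    mat_bits = _meiosis_bits(rng, (n_fam, max_kids, L), thetas)
    m0, m1 = mot[:, 0, :], mot[:, 1, :]
    child_mat = np.where(mat_bits == 0, m0[:, None, :], m1[:, None, :])

    if is_x:
        fat[:, 1, :] = fat[:, 0, :]  # single paternal X
        fx = fat[:, 0, :]
        child_pat = np.where(
            child_sex_male[:, :, None], child_mat, np.broadcast_to(fx[:, None, :], child_mat.shape)
        )
        pat_dose = np.where(child_sex_male[:, :, None], 0, fx[:, None, :])
    else:
        pat_bits = _meiosis_bits(rng, (n_fam, max_kids, L), thetas)
        f0, f1 = fat[:, 0, :], fat[:, 1, :]
        child_pat = np.where(pat_bits == 0, f0[:, None, :], f1[:, None, :])
        pat_dose = child_pat
    return {
        "father": fat,
        "mother": mot,
        "child_pat": child_pat.astype(np.int8),
        "child_mat": child_mat.astype(np.int8),
        "child_pat_dose": pat_dose.astype(np.int8),  # true transmitted count
        "is_x": is_x,
    }


def ascertain_multiplex(
    config: SimulationConfig, rng: np.random.Generator, grids: list[_LocusGrid]
):
    """Draw families until the multiplex (and MO/FC-quota) targets are met.

    Returns (accepted family records, max children per family, acceptance
    rate).  Families with fewer than two affected children are rejected; when
    a target MO fraction is set, accepted multiplex families additionally
    fill MO/FC quotas of round(n*frac) / rest.  Only chromosomes bearing risk
    loci are simulated during the accept/reject stream; risk-free chromosomes
    are filled in afterwards for accepted families only (affection does not
    depend on them, so the joint distribution is unchanged).
    """
    kcounts = np.array(sorted(config.offspring_dist))
    kprobs = np.array([config.offspring_dist[k] for k in kcounts], dtype=float)
    kprobs /= kprobs.sum()
    max_kids = int(kcounts.max())

    risk_chroms = {str(l.chrom) for l in config.risk_loci}
    risk_grids = [g for g in grids if g.chrom in risk_chroms]
    other_grids = [g for g in grids if g.chrom not in risk_chroms]

    if config.target_mo_fraction is None:
        quota = {"MO": None, "FC": None}
    else:
        n_mo = int(round(config.n_families * config.target_mo_fraction))
        quota = {"MO": n_mo, "FC": config.n_families - n_mo}

    got: dict[str, int] = {"MO": 0, "FC": 0}
    keep_rows = []  # per accepted family: dict with sim arrays
    attempts = 0
    accepted_multiplex = 0
    max_attempts = config.n_families * config.max_attempt_factor
    batch = max(2000, config.n_families)

    while sum(got.values()) < config.n_families:
        if attempts >= max_attempts:
            raise RuntimeError(
                "multiplex acceptance rate too low for the requested cohort; "
                "raise penetrances, offspring counts or max_attempt_factor"
            )
        B = min(batch, max_attempts - attempts)
        attempts += B
        n_kids = kcounts[rng.choice(len(kcounts), size=B, p=kprobs)]
        kid_mask = np.arange(max_kids)[None, :] < n_kids[:, None]
        sex_male = rng.random((B, max_kids)) < 0.5

        sims = {g.chrom: _simulate_chromosome_batch(rng, g, B, max_kids, sex_male) for g in risk_grids}
        # risk dosages per child: (B, max_kids, n_loci)
        n_loci = len(config.risk_loci)
        dos = np.zeros((B, max_kids, n_loci), dtype=np.int8)
        for g in risk_grids:
            s = sims[g.chrom]
            for col, li in g.risk_index.items():
                dos[:, :, li] = s["child_pat_dose"][:, :, col] + s["child_mat"][:, :, col]
        aff = assign_affection(
            dos, sex_male.astype(int), config.risk_loci, config.baseline_penetrance, rng
        )
        aff &= kid_mask
        n_aff = aff.sum(axis=1)
        multiplex = n_aff >= 2
        accepted_multiplex += int(multiplex.sum())
        aff_female = (aff & ~sex_male).any(axis=1)
        labels = np.where(aff_female, "FC", "MO")

        for b in np.flatnonzero(multiplex):
            lab = labels[b]
            if quota[lab] is not None and got[lab] >= quota[lab]:
                continue
            if quota[lab] is None and sum(got.values()) >= config.n_families:
                break
            got[lab] += 1
            keep_rows.append(
                {
                    "n_kids": int(n_kids[b]),
                    "sex_male": sex_male[b].copy(),
                    "aff": aff[b].copy(),
                    "dosages": dos[b].copy(),
                    "risk_sims": {
                        c: {k: (v[b].copy() if isinstance(v, np.ndarray) else v) for k, v in s.items()}
                        for c, s in sims.items()
                    },
                }
            )
            if sum(got.values()) >= config.n_families:
                break

    # phase B: simulate risk-free chromosomes only for the accepted families
    n = len(keep_rows)
    sex_all = np.stack([r["sex_male"] for r in keep_rows])
    for g in other_grids:
        s = _simulate_chromosome_batch(rng, g, n, max_kids, sex_all)
        for i, r in enumerate(keep_rows):
            r["risk_sims"][g.chrom] = {
                k: (v[i] if isinstance(v, np.ndarray) else v) for k, v in s.items()
            }
    rate = accepted_multiplex / attempts if attempts else 0.0
    return keep_rows, max_kids, rate


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------


def inject_noise(
    codes: np.ndarray,
    dataset_index: pd.DataFrame,
    marker_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Apply allele-call errors, missingness, and planted Mendelian violations.

    Returns (noisy codes, list of (family, marker) with planted violations).
    Planted violations set one family's parents to opposite homozygotes
    impossible for the child (parents 1/1, affected-child slot 2/2), which the
    Mendelian checker is guaranteed to flag.
    """
    out = codes.copy()
    n, m, _ = out.shape
    if config.genotype_error_rate > 0:
        flip = rng.random(out.shape) < config.genotype_error_rate
        flip &= out >= 0
        out[flip] = 1 - out[flip]
    if config.missingness > 0:
        miss = rng.random((n, m)) < config.missingness
        out[miss] = -1

    planted: list[tuple[str, str]] = []
    if config.n_mendel_errors > 0:
        fams = dataset_index["family"].to_numpy()
        fam_rows: dict[str, np.ndarray] = {}
        for f in pd.unique(fams):
            fam_rows[f] = np.flatnonzero(fams == f)
        fam_list = list(fam_rows)
        for _ in range(config.n_mendel_errors):
            f = fam_list[int(rng.integers(len(fam_list)))]
            rows = fam_rows[f]
            mk = int(rng.integers(m))
            father_r, mother_r = rows[0], rows[1]
            child_r = rows[2 + int(rng.integers(len(rows) - 2))]
            out[father_r, mk] = [0, 0]
            out[mother_r, mk] = [0, 0]
            out[child_r, mk] = [1, 1]
            planted.append((f, marker_ids[mk]))
    return out, planted


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grids = _build_grids(config, rng)
    rows, max_kids, rate = ascertain_multiplex(config, rng, grids)

    # assemble the marker table (typed loci only), individuals and codes
    marker_rows, col_sources = [], []  # col_sources: (chrom, grid_col)
    for g in grids:
        for col in range(len(g.cm)):
            if not g.is_marker[col]:
                continue
            marker_rows.append(
                {"marker": g.names[col], "chrom": g.chrom, "bp": int(g.bp[col]), "cM": float(g.cm[col])}
            )
            col_sources.append((g.chrom, col))
    marker_map = MarkerMap(pd.DataFrame(marker_rows))
    M = len(marker_rows)

    individuals: list[Individual] = []
    code_rows: list[np.ndarray] = []
    fam_label_rows = []
    dosage_rows = []
    for i, r in enumerate(rows):
        fid = f"F{i + 1:04d}"
        nk = r["n_kids"]
        individuals.append(Individual("1", fid, "0", "0", SEX_MALE, AFF_UNAFFECTED))
        individuals.append(Individual("2", fid, "0", "0", SEX_FEMALE, AFF_UNAFFECTED))
        for k in range(nk):
            sex = SEX_MALE if r["sex_male"][k] else SEX_FEMALE
            aff = AFF_AFFECTED if r["aff"][k] else AFF_UNAFFECTED
            individuals.append(Individual(str(3 + k), fid, "1", "2", sex, aff))
        n_aff = int(r["aff"][:nk].sum())
        label = "FC" if (r["aff"][:nk] & ~r["sex_male"][:nk]).any() else "MO"
        fam_label_rows.append(
            {"family": fid, "label": label, "n_children": nk, "n_affected": n_aff}
        )
        for li in range(len(config.risk_loci)):
            for k in range(nk):
                dosage_rows.append(
                    {"family": fid, "person": str(3 + k), "locus": li, "dosage": int(r["dosages"][k, li])}
                )

        # genotype codes per person at typed markers
        fam_codes = np.full((2 + nk, M, 2), -1, dtype=np.int8)
        for j, (chrom, col) in enumerate(col_sources):
            s = r["risk_sims"][chrom]
            fam_codes[0, j] = s["father"][:, col]
            fam_codes[1, j] = s["mother"][:, col]
            for k in range(nk):
                fam_codes[2 + k, j] = (s["child_pat"][k, col], s["child_mat"][k, col])
        code_rows.append(fam_codes)

    codes = np.concatenate(code_rows, axis=0)
    pre_noise = codes.copy()
    sample_index = pd.DataFrame(
        {"family": [p.family_id for p in individuals], "person": [p.person_id for p in individuals]}
    )
    noisy, planted = inject_noise(
        codes, sample_index, [mr["marker"] for mr in marker_rows], config, rng
    )
    allele_symbols = [["1", "2"] for _ in range(M)]
    dataset = build_dataset(individuals, noisy, allele_symbols, marker_map)

    risk_truth = pd.DataFrame(
        [
            {
                "chrom": str(l.chrom),
                "cM": l.cM,
                "bp": int(
                    next(
                        g.bp[c]
                        for g in grids
                        if g.chrom == str(l.chrom)
                        for c, ridx in g.risk_index.items()
                        if ridx == li
                    )
                ),
                "marker": f"{l.name}{li}" if l.typed else "",
                "allele_freq": l.allele_freq,
            }
            for li, l in enumerate(config.risk_loci)
        ],
        columns=["chrom", "cM", "bp", "marker", "allele_freq"],
    )
    return SyntheticCohort(
        dataset=dataset,
        config=config,
        risk_truth=risk_truth,
        family_labels=pd.DataFrame(fam_label_rows),
        risk_dosages=pd.DataFrame(dosage_rows, columns=["family", "person", "locus", "dosage"]),
        pre_noise_codes=pre_noise,
        planted_mendel=planted,
        acceptance_rate=rate,
    )


def write_cohort(cohort: SyntheticCohort, prefix: str) -> None:
    """Write prefix.ped, prefix.map and prefix.truth.tsv."""
    from .pedigree_core import write_ped_map

    write_ped_map(cohort.dataset, f"{prefix}.ped", f"{prefix}.map")
    truth = cohort.family_labels.merge(
        cohort.risk_dosages.pivot_table(
            index="family", values="dosage", aggfunc="sum"
        ).rename(columns={"dosage": "total_risk_dosage"}),
        on="family",
        how="left",
    )
    truth.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)
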