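"""Domain types, PED/MAP I/O, genetic-map arithmetic and pedigree validation.

The universal input to every analysis stage is a :class:`LinkageDataset`:
a set of pedigrees, a biallelic genotype matrix, a genetic marker map and
per-marker founder allele frequencies.  Genotypes are stored as allele-index
pairs (0/1 into the marker's allele-symbol table, -1 for missing), which makes
all downstream arithmetic symbol-free; the original allele symbols are kept so
files round-trip exactly.

Coordinates are 1-based bp (hg19 convention) and sex-averaged cM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

MISSING = "0"

SEX_MALE = "male"
SEX_FEMALE = "female"

AFF_AFFECTED = "affected"
AFF_UNAFFECTED = "unaffected"
AFF_UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Raised for malformed or internally inconsistent pedigree input."""


@dataclass(frozen=True)
class Individual:
    person_id: str
    family_id: str
    father_id: str  # MISSING for founders
    mother_id: str
    sex: str  # SEX_MALE / SEX_FEMALE
    affection: str  # AFF_AFFECTED / AFF_UNAFFECTED / AFF_UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id == MISSING and self.mother_id == MISSING


@dataclass
class Pedigree:
    """One family: an ordered member list plus derived structure."""

    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        ids = [m.person_id for m in self.members]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(
                f"family {self.family_id}: duplicate person_id {dup}"
            )
        self._by_id = {m.person_id: m for m in self.members}
        for m in self.members:
            for pid, want_sex, role in (
                (m.father_id, SEX_MALE, "father"),
                (m.mother_id, SEX_FEMALE, "mother"),
            ):
                if pid == MISSING:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"family {self.family_id}: {role} {pid!r} of "
                        f"{m.person_id!r} not present in family"
                    )
                if parent.sex != want_sex:
                    raise PedigreeError(
                        f"family {self.family_id}: parent sex inconsistency — "
                        f"{role} {pid!r} of {m.person_id!r} has sex {parent.sex}"
                    )
            if (m.father_id == MISSING) != (m.mother_id == MISSING):
                raise PedigreeError(
                    f"family {self.family_id}: {m.person_id!r} has exactly one "
                    "recorded parent; non-founders need both"
                )

    def member(self, person_id: str) -> Individual:
        return self._by_id[person_id]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def has_cycle(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(m.person_id for m in self.members)
        for m in self.members:
            if not m.is_founder:
                g.add_edge(m.father_id, m.person_id)
                g.add_edge(m.mother_id, m.person_id)
        return not nx.is_directed_acyclic_graph(g)

    @property
    def is_nuclear(self) -> bool:
        """True iff exactly one founder couple and >=1 child of that couple."""
        if self.has_cycle():
            return False
        founders = self.founders
        children = self.nonfounders
        if len(founders) != 2 or not children:
            return False
        sexes = {f.sex for f in founders}
        if sexes != {SEX_MALE, SEX_FEMALE}:
            return False
        father = next(f for f in founders if f.sex == SEX_MALE)
        mother = next(f for f in founders if f.sex == SEX_FEMALE)
        return all(
            c.father_id == father.person_id and c.mother_id == mother.person_id
            for c in children
        )

    @property
    def children(self) -> list[Individual]:
        return self.nonfounders

    def affected_children(self) -> list[Individual]:
        return [c for c in self.nonfounders if c.affection == AFF_AFFECTED]


@dataclass
class MarkerMap:
    """Genetic map: one row per marker (marker_id, chromosome, bp, cM).

    Within a chromosome cM must be non-decreasing in bp; marker_ids unique.
    """

    table: pd.DataFrame  # columns: marker, chrom, bp, cM

    def __post_init__(self) -> None:
        need = {"marker", "chrom", "bp", "cM"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(need)}")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))[:5]}")
        self.table = self.table.reset_index(drop=True)
        for chrom, sub in self.table.groupby("chrom", sort=False):
            s = sub.sort_values("bp")
            if (np.diff(s["cM"].to_numpy()) < -1e-9).any():
                raise ValueError(
                    f"chromosome {chrom}: cM not non-decreasing in bp"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chromosome_markers(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == str(chrom)]
        return sub.sort_values(["cM", "bp"], kind="stable")

    def subset(self, marker_ids: Sequence[str]) -> "MarkerMap":
        keep = self.table[self.table["marker"].isin(set(marker_ids))]
        return MarkerMap(keep.copy())


@dataclass
class GenotypeTable:
    """individuals x markers x 2 allele indices (0/1 into symbols, -1 missing)."""

    codes: np.ndarray  # int8, shape (n_ind, n_markers, 2)
    allele_symbols: list[list[str]]  # per marker, <=2 symbols

    def __post_init__(self) -> None:
        if self.codes.ndim != 3 or self.codes.shape[2] != 2:
            raise ValueError("genotype codes must have shape (n, m, 2)")
        if len(self.allele_symbols) != self.codes.shape[1]:
            raise ValueError("allele_symbols length must match marker count")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        """(n_ind, n_markers) bool: genotype missing (either allele)."""
        return (self.codes < 0).any(axis=2)


@dataclass
class LinkageDataset:
    """Pedigrees + genotypes + map + founder allele frequencies."""

    pedigrees: dict[str, Pedigree]
    sample_index: pd.DataFrame  # columns family, person; row order = genotype rows
    genotypes: GenotypeTable
    marker_map: MarkerMap
    allele_freqs: np.ndarray  # (n_markers, 2); freq of allele index 0 and 1
    freq_source: str = "founders"  # or "all_individuals" fallback

    def __post_init__(self) -> None:
        if len(self.sample_index) != self.genotypes.n_individuals:
            raise ValueError("sample_index rows != genotype rows")
        if len(self.marker_map) != self.genotypes.n_markers:
            raise ValueError("map length != genotype marker count")
        f = self.allele_freqs
        if f.shape != (self.genotypes.n_markers, 2):
            raise ValueError("allele_freqs must be (n_markers, 2)")
        ok = (f > 0) & (f < 1)
        sums = f.sum(axis=1)
        if not (np.isclose(sums, 1.0).all() and ok.all()):
            raise ValueError("allele frequencies must lie in (0,1) and sum to 1")
        self._rows = {
            (fam, per): i
            for i, (fam, per) in enumerate(
                zip(self.sample_index["family"], self.sample_index["person"])
            )
        }
        self._marker_cols = {m: j for j, m in enumerate(self.marker_map.markers)}

    @property
    def n_markers(self) -> int:
        return self.genotypes.n_markers

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    def row_of(self, family_id: str, person_id: str) -> int:
        try:
            return self._rows[(family_id, person_id)]
        except KeyError:
            raise KeyError(f"sample ({family_id}, {person_id}) not found") from None

    def marker_column(self, marker_id: str) -> int:
        try:
            return self._marker_cols[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not found") from None

    def subset_markers(self, marker_ids: Sequence[str]) -> "LinkageDataset":
        ids = list(marker_ids)
        cols = [self.marker_column(m) for m in ids]
        gt = GenotypeTable(
            self.genotypes.codes[:, cols, :].copy(),
            [self.genotypes.allele_symbols[c] for c in cols],
        )
        return LinkageDataset(
            self.pedigrees,
            self.sample_index,
            gt,
            self.marker_map.subset(ids),
            self.allele_freqs[cols].copy(),
            self.freq_source,
        )

    def subset_families(self, family_ids: Iterable[str]) -> "LinkageDataset":
        keep = set(family_ids)
        missing = keep - set(self.pedigrees)
        if missing:
            raise KeyError(f"unknown families: {sorted(missing)[:5]}")
        rows = self.sample_index.index[self.sample_index["family"].isin(keep)]
        rows = np.asarray(rows, dtype=int)
        gt = GenotypeTable(
            self.genotypes.codes[rows].copy(), self.genotypes.allele_symbols
        )
        return LinkageDataset(
            {f: p for f, p in self.pedigrees.items() if f in keep},
            self.sample_index.iloc[rows].reset_index(drop=True),
            gt,
            self.marker_map,
            self.allele_freqs,
            self.freq_source,
        )


# ---------------------------------------------------------------------------
# PED/MAP I/O
# ---------------------------------------------------------------------------

_SEX_IN = {"1": SEX_MALE, "2": SEX_FEMALE}
_SEX_OUT = {SEX_MALE: "1", SEX_FEMALE: "2"}
_AFF_IN = {"2": AFF_AFFECTED, "1": AFF_UNAFFECTED, "0": AFF_UNKNOWN, "-9": AFF_UNKNOWN}
_AFF_OUT = {AFF_AFFECTED: "2", AFF_UNAFFECTED: "1", AFF_UNKNOWN: "0"}


def _estimate_allele_freqs(
    codes: np.ndarray, founder_rows: np.ndarray
) -> tuple[np.ndarray, str]:
    """Per-marker frequency of allele index 0/1, counted in founders.

    Markers with no genotyped founder anywhere trigger the flagged fallback of
    counting across all genotyped individuals.  A 0.5-pseudo-allele is added to
    each count so estimated frequencies always lie strictly inside (0,1), which
    keeps monomorphic-in-sample markers usable downstream.
    """
    n_markers = codes.shape[1]

    def counts(rows: np.ndarray) -> np.ndarray:
        sub = codes[rows]  # (r, m, 2)
        c = np.zeros((n_markers, 2))
        c[:, 0] = (sub == 0).sum(axis=(0, 2))
        c[:, 1] = (sub == 1).sum(axis=(0, 2))
        return c

    c = counts(founder_rows)
    source = "founders"
    if (c.sum(axis=1) == 0).any():
        c_all = counts(np.arange(codes.shape[0]))
        empty = c.sum(axis=1) == 0
        c[empty] = c_all[empty]
        source = "founders+all_individuals_fallback"
    c += 0.5
    freqs = c / c.sum(axis=1, keepdims=True)
    return freqs, source


def build_dataset(
    individuals: list[Individual],
    codes: np.ndarray,
    allele_symbols: list[list[str]],
    marker_map: MarkerMap,
) -> LinkageDataset:
    """Assemble a LinkageDataset from parsed parts (shared by load and synth)."""
    fams: dict[str, list[Individual]] = {}
    for ind in individuals:
        fams.setdefault(ind.family_id, []).append(ind)
    pedigrees = {fid: Pedigree(fid, mem) for fid, mem in fams.items()}
    sample_index = pd.DataFrame(
        {
            "family": [i.family_id for i in individuals],
            "person": [i.person_id for i in individuals],
        }
    )
    founder_rows = np.array(
        [k for k, ind in enumerate(individuals) if ind.is_founder], dtype=int
    )
    freqs, source = _estimate_allele_freqs(codes, founder_rows)
    return LinkageDataset(
        pedigrees,
        sample_index,
        GenotypeTable(codes, allele_symbols),
        marker_map,
        freqs,
        source,
    )


def load_map(map_path: str) -> MarkerMap:
    """Read a 4-column MAP file: chrom, marker, cM, bp."""
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 4:
                raise PedigreeError(
                    f"{map_path}:{ln}: expected 4 fields (chrom id cM bp), "
                    f"got {len(toks)}"
                )
            rows.append(
                {
                    "chrom": toks[0],
                    "marker": toks[1],
                    "cM": float(toks[2]),
                    "bp": int(toks[3]),
                }
            )
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]))


def load_ped_map(ped_path: str, map_path: str) -> LinkageDataset:
    """Load whitespace-delimited PED + MAP files into a LinkageDataset.

    PED dialect: FID IID FATHER MOTHER SEX AFF then two allele tokens per
    marker; sex 1=male 2=female; affection 2=affected 1=unaffected 0/-9
    unknown; allele "0" missing.  Errors carry file/line locations.
    """
    marker_map = load_map(map_path)
    n_markers = len(marker_map)

    individuals: list[Individual] = []
    raw_genos: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 6 + 2 * n_markers:
                raise PedigreeError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_markers} fields "
                    f"(6 + 2x{n_markers} markers), got {len(toks)}"
                )
            fid, iid, fa, mo, sex, aff = toks[:6]
            if sex not in _SEX_IN:
                raise PedigreeError(f"{ped_path}:{ln}: bad sex code {sex!r}")
            if aff not in _AFF_IN:
                raise PedigreeError(f"{ped_path}:{ln}: bad affection code {aff!r}")
            individuals.append(
                Individual(iid, fid, fa, mo, _SEX_IN[sex], _AFF_IN[aff])
            )
            raw_genos.append(toks[6:])

    n = len(individuals)
    codes = np.full((n, n_markers, 2), -1, dtype=np.int8)
    allele_symbols: list[list[str]] = [[] for _ in range(n_markers)]
    for m in range(n_markers):
        symtab = allele_symbols[m]
        for i in range(n):
            for a in range(2):
                tok = raw_genos[i][2 * m + a]
                if tok == MISSING:
                    continue
                if tok not in symtab:
                    if len(symtab) >= 2:
                        raise PedigreeError(
                            f"{ped_path}: marker "
                            f"{marker_map.table['marker'][m]!r} has >2 alleles "
                            f"({symtab + [tok]})"
                        )
                    symtab.append(tok)
                codes[i, m, a] = symtab.index(tok)
        # half-missing genotypes are treated as fully missing
        half = (codes[:, m, :] < 0).any(axis=1)
        codes[half, m, :] = -1

    # cycles are not a load error: validate_pedigrees reports them
    return build_dataset(individuals, codes, allele_symbols, marker_map)


def write_ped_map(dataset: LinkageDataset, ped_path: str, map_path: str) -> None:
    """Write the dataset back out in the same PED/MAP dialect load accepts."""
    tab = dataset.marker_map.table
    with open(map_path, "w") as fh:
        for _, row in tab.iterrows():
            fh.write(f"{row['chrom']}\t{row['marker']}\t{row['cM']:g}\t{row['bp']}\n")

    codes = dataset.genotypes.codes
    syms = dataset.genotypes.allele_symbols
    with open(ped_path, "w") as fh:
        for r in range(dataset.n_individuals):
            fam = dataset.sample_index["family"].iloc[r]
            ind = dataset.pedigrees[fam].member(dataset.sample_index["person"].iloc[r])
            out = [
                ind.family_id,
                ind.person_id,
                ind.father_id,
                ind.mother_id,
                _SEX_OUT[ind.sex],
                _AFF_OUT[ind.affection],
            ]
            for m in range(dataset.n_markers):
                for a in range(2):
                    c = codes[r, m, a]
                    out.append(MISSING if c < 0 else syms[m][c])
            fh.write(" ".join(out) + "\n")


# ---------------------------------------------------------------------------
# Genetic-map arithmetic
# ---------------------------------------------------------------------------


def haldane_theta(distance_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: theta = (1 - exp(-2 d)) / 2 with d in Morgans.

    Assumes no crossover interference; theta is in [0, 0.5) and strictly
    increasing in distance.
    """
    d = np.asarray(distance_cM, dtype=float)
    if (d < 0).any():
        raise ValueError("genetic distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(distance_cM) else theta


def interpolate_genetic_position(
    marker_map: MarkerMap, chromosome: str, bp: float | np.ndarray
) -> float | np.ndarray:
    """cM at physical position(s) by linear interpolation between mapped markers.

    Beyond the first/last mapped marker the position is extrapolated as
    constant (the terminal marker's cM) — queries outside the mapped span carry
    no recombination information either way.
    """
    sub = marker_map.chromosome_markers(str(chromosome))
    if len(sub) < 2:
        raise ValueError(
            f"chromosome {chromosome!r} has {len(sub)} mapped markers; need >=2"
        )
    xp = sub["bp"].to_numpy(dtype=float)
    fp = sub["cM"].to_numpy(dtype=float)
    order = np.argsort(xp, kind="stable")
    out = np.interp(np.asarray(bp, dtype=float), xp[order], fp[order])
    return float(out) if np.isscalar(bp) else out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_pedigrees(dataset: LinkageDataset) -> pd.DataFrame:
    """Report-only structural audit of every family.

    Columns: family, n_members, nuclear, cycle, n_affected_children,
    n_genotyped_affected_children, informative, note.  A family is informative
    for multiplex linkage iff nuclear, acyclic, and it has >=2 affected
    children with at least one non-missing genotype each.
    """
    miss = dataset.genotypes.missing_mask()
    rows = []
    for fid, ped in dataset.pedigrees.items():
        cycle = ped.has_cycle()
        nuclear = ped.is_nuclear
        affected = ped.affected_children()
        genotyped_affected = 0
        for c in affected:
            r = dataset.row_of(fid, c.person_id)
            if not miss[r].all():
                genotyped_affected += 1
        informative = nuclear and not cycle and genotyped_affected >= 2
        if cycle:
            note = "cycle in parent-child graph"
        elif not nuclear:
            note = "non-nuclear structure"
        elif genotyped_affected < 2:
            note = "excluded from multiplex linkage (<2 genotyped affected children)"
        else:
            note = ""
        rows.append(
            {
                "family": fid,
                "n_members": len(ped.members),
                "nuclear": nuclear,
                "cycle": cycle,
                "n_affected_children": len(affected),
                "n_genotyped_affected_children": genotyped_affected,
                "informative": informative,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
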