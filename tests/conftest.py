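import numpy as np
import pandas as pd
import pytest

from famlink.pedigree_core import Individual, MarkerMap, Pedigree, build_dataset


def make_nuclear(
    family_id="f1",
    n_children=2,
    affected=(0, 1),
    child_sexes=None,
):
    """A nuclear pedigree with the given affected-child indices."""
    members = [
        Individual("1", family_id, "0", "0", "male", "unaffected"),
        Individual("2", family_id, "0", "0", "female", "unaffected"),
    ]
    sexes = child_sexes or ["male"] * n_children
    for k in range(n_children):
        aff = "affected" if k in affected else "unaffected"
        members.append(Individual(str(3 + k), family_id, "1", "2", sexes[k], aff))
    return Pedigree(family_id, members)


def dataset_from_genotypes(pedigrees, genotype_sums, freqs1, spacing_cM=10.0, chrom="1"):
    """Build a LinkageDataset from per-person allele-1 dosages.

    genotype_sums: dict family_id -> (n_members, n_markers) array of 0/1/2
    dosages (-1 missing), members in pedigree order.  Dosage 1 is stored as
    the het genotype (0,1).
    """
    individuals, code_rows = [], []
    n_markers = len(freqs1)
    for fid, ped in pedigrees.items():
        gs = np.asarray(genotype_sums[fid])
        for i, member in enumerate(ped.members):
            individuals.append(member)
            row = np.full((n_markers, 2), -1, dtype=np.int8)
            for m in range(n_markers):
                g = gs[i, m]
                if g == 0:
                    row[m] = (0, 0)
                elif g == 1:
                    row[m] = (0, 1)
                elif g == 2:
                    row[m] = (1, 1)
            code_rows.append(row)
    codes = np.stack(code_rows)
    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker": [f"m{k + 1}" for k in range(n_markers)],
                "chrom": [chrom] * n_markers,
                "bp": [1_000_000 * (k + 1) for k in range(n_markers)],
                "cM": [spacing_cM * k for k in range(n_markers)],
            }
        )
    )
    ds = build_dataset(individuals, codes, [["1", "2"]] * n_markers, mm)
    # pin allele frequencies to the generative truth rather than tiny-sample counts
    ds.allele_freqs = np.stack([1 - np.asarray(freqs1), np.asarray(freqs1)], axis=1)
    return ds


@pytest.fixture
def sib_pair_pedigree():
    return make_nuclear()


@pytest.fixture
def trio_ped_files(tmp_path):
    """A 2-family, 3-marker PED/MAP pair on disk."""
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text(
        "f1 1 0 0 1 1 1 2 1 1 2 2\n"
        "f1 2 0 0 2 1 1 1 1 2 1 2\n"
        "f1 3 1 2 1 2 1 2 1 1 2 2\n"
        "f2 1 0 0 1 1 2 2 1 1 0 0\n"
        "f2 2 0 0 2 1 1 2 2 2 1 1\n"
        "f2 3 1 2 2 2 1 2 1 2 1 1\n"
        "f2 4 1 2 2 2 2 2 1 2 1 1\n"
    )
    mp.write_text(
        "1 m1 0.0 1000000\n"
        "1 m2 10.0 2000000\n"
        "1 m3 25.0 3500000\n"
    )
    return str(ped), str(mp)
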