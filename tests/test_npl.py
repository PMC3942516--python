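import itertools
import math

import numpy as np
import pandas as pd
import pytest

from famlink.npl import (
    NuclearFamilyEngine,
    find_peaks,
    kong_cox_lod,
    kong_cox_lod_batch,
    linkage_curve,
    lod_to_pvalue,
    pvalue_to_lod,
    support_interval,
    z_to_lod,
)
from famlink.pedigree_core import haldane_theta

from conftest import dataset_from_genotypes, make_nuclear

LN10 = math.log(10)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_marker_likelihood(eng, gsums, p):
    """Sum over founder diplotype assignments, straight from the definition."""
    out = np.zeros(eng.n_states)
    for s in range(eng.n_states):
        tot = 0.0
        for a1, a2, b1, b2 in itertools.product([0, 1], repeat=4):
            w = 1.0
            for a in (a1, a2, b1, b2):
                w *= p if a else 1 - p
            ok = True
            if gsums[0] >= 0 and a1 + a2 != gsums[0]:
                ok = False
            if gsums[1] >= 0 and b1 + b2 != gsums[1]:
                ok = False
            fa, mo = (a1, a2), (b1, b2)
            for k in range(len(eng.children)):
                g = gsums[2 + k]
                if g >= 0 and fa[eng.pat_bits[s, k]] + mo[eng.mat_bits[s, k]] != g:
                    ok = False
            if ok:
                tot += w
        out[s] = tot
    return out


def brute_joint_posterior(eng, emissions, thetas):
    """Joint enumeration over (vectors)^M with explicit transition products."""
    E = emissions.copy()
    E[E.sum(axis=1) == 0] = 1.0
    M, S = E.shape
    H, nb = eng._hamming, eng.n_bits
    marg = [np.zeros(S) for _ in range(M)]
    for combo in itertools.product(range(S), repeat=M):
        w = E[0, combo[0]]
        for k in range(1, M):
            d = H[combo[k - 1], combo[k]]
            w *= thetas[k - 1] ** d * (1 - thetas[k - 1]) ** (nb - d) * E[k, combo[k]]
        for k in range(M):
            marg[k][combo[k]] += w
    tot = marg[0].sum()
    return np.stack([m / tot for m in marg])


def s_pairs_definition(eng, s):
    """IBD sharing summed over affected pairs, from bit equality."""
    tot = 0
    for a, b in itertools.combinations(eng.affected_idx, 2):
        tot += int(eng.pat_bits[s, a] == eng.pat_bits[s, b])
        tot += int(eng.mat_bits[s, a] == eng.mat_bits[s, b])
    return float(tot)


def s_all_definition(eng, s):
    """Whittemore–Halpern collection sum coded directly from its definition."""
    allele_sets = []
    for k in eng.affected_idx:
        allele_sets.append(
            [("F", int(eng.pat_bits[s, k])), ("M", int(eng.mat_bits[s, k]))]
        )
    total = 0.0
    for pick in itertools.product(*allele_sets):
        counts = {}
        for o in pick:
            counts[o] = counts.get(o, 0) + 1
        term = 1.0
        for b in counts.values():
            term *= math.factorial(b)
        total += term
    return total / 2 ** len(eng.affected_idx)


def grid_search_kc(z, z_min, gamma, n=10**6):
    gz = gamma * z
    neg = gamma * z_min
    neg = neg[neg < 0]
    dmax = np.min(-1 / neg) if len(neg) else 1e6
    grid = np.linspace(0, dmax * (1 - 1e-9), n)
    ell = np.log10(1 + grid[:, None] * gz[None, :]).sum(axis=1)
    k = np.argmax(ell)
    return max(ell[k], 0.0), grid[k]


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_children,affected", [(2, (0, 1)), (3, (0, 1, 2)), (3, (0, 2))])
@pytest.mark.parametrize("statistic", ["s_all", "s_pairs"])
class TestOracleEquivalence:
    """Exact agreement with brute-force enumeration on 2–3-child families."""

    def test_marker_likelihood_matches_founder_enumeration(
        self, n_children, affected, statistic
    ):
        ped = make_nuclear("f", n_children, affected)
        eng = NuclearFamilyEngine(ped, statistic)
        rng = np.random.default_rng(42)
        for _ in range(10):
            gs = rng.integers(-1, 3, size=2 + n_children)
            p = rng.uniform(0.1, 0.9)
            got = eng.marker_likelihood(tuple(gs), p)
            want = brute_marker_likelihood(eng, gs, p)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_multipoint_matches_joint_enumeration(self, n_children, affected, statistic):
        ped = make_nuclear("f", n_children, affected)
        eng = NuclearFamilyEngine(ped, statistic)
        rng = np.random.default_rng(1)
        n_markers = 3
        thetas = np.array([0.08, 0.25])
        gs = rng.integers(-1, 3, size=(2 + n_children, n_markers))
        freqs = rng.uniform(0.2, 0.8, n_markers)
        E = np.stack(
            [eng.marker_likelihood(tuple(gs[:, k]), freqs[k]) for k in range(n_markers)]
        )
        post = eng.multipoint_posterior(E, thetas)
        want = brute_joint_posterior(eng, E, thetas)
        np.testing.assert_allclose(post, want, atol=1e-9)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_sharing_scores_match_definitions(self, n_children, affected, statistic):
        ped = make_nuclear("f", n_children, affected)
        eng = NuclearFamilyEngine(ped, statistic)
        oracle = s_pairs_definition if statistic == "s_pairs" else s_all_definition
        for s in range(eng.n_states):
            assert eng.scores[s] == pytest.approx(oracle(eng, s), abs=1e-12)


class TestSharingScores:
    def test_sib_pair_s_pairs_extremes(self):
        eng = NuclearFamilyEngine(make_nuclear(), "s_pairs")
        assert eng.scores.max() == 2.0  # IBD 2
        assert eng.scores.min() == 0.0  # IBD 0

    def test_three_sibs_full_sharing(self):
        eng = NuclearFamilyEngine(make_nuclear(n_children=3, affected=(0, 1, 2)), "s_pairs")
        assert eng.scores.max() == 6.0  # 3 pairs x 2 alleles

    def test_fewer_than_two_affected_rejected(self):
        with pytest.raises(ValueError, match="2 affected"):
            NuclearFamilyEngine(make_nuclear(affected=(0,)), "s_all")


class TestFamilyZ:
    @pytest.mark.parametrize("statistic", ["s_all", "s_pairs"])
    def test_uniform_posterior_gives_zero(self, statistic):
        eng = NuclearFamilyEngine(make_nuclear(), statistic)
        post = np.full((1, eng.n_states), 1 / eng.n_states)
        assert eng.posterior_z(post)[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("statistic", ["s_all", "s_pairs"])
    def test_informative_sib_pair_z_pm_sqrt2(self, statistic):
        """Fully informative sib pair: IBD2 gives +sqrt(2), IBD0 gives -sqrt(2)
        (null IBD distribution 1/4, 1/2, 1/4)."""
        eng = NuclearFamilyEngine(make_nuclear(), statistic)
        ibd2 = [
            s
            for s in range(eng.n_states)
            if eng.pat_bits[s, 0] == eng.pat_bits[s, 1]
            and eng.mat_bits[s, 0] == eng.mat_bits[s, 1]
        ]
        post = np.zeros((1, eng.n_states))
        post[0, ibd2] = 1 / len(ibd2)
        assert eng.posterior_z(post)[0] == pytest.approx(math.sqrt(2), abs=1e-12)
        ibd0 = [
            s
            for s in range(eng.n_states)
            if eng.pat_bits[s, 0] != eng.pat_bits[s, 1]
            and eng.mat_bits[s, 0] != eng.mat_bits[s, 1]
        ]
        post = np.zeros((1, eng.n_states))
        post[0, ibd0] = 1 / len(ibd0)
        assert eng.posterior_z(post)[0] == pytest.approx(-math.sqrt(2), abs=1e-12)
        assert eng.z_min == pytest.approx(-math.sqrt(2), abs=1e-12)


class TestKongCox:
    def test_all_zero_scores(self):
        lod, d, z = kong_cox_lod(np.zeros(4), np.full(4, -1.4))
        assert (lod, d) == (0.0, 0.0)

    def test_negative_overall_z_boundary(self):
        lod, d, z = kong_cox_lod(np.array([-1.0, 0.5]), np.full(2, -1.4))
        assert lod == 0.0 and d == 0.0 and z < 0

    def test_matches_grid_search_oracle(self):
        z = np.array([1.414, 1.414, 0.0, -0.707])
        zmin = np.full(4, -1.414)
        gam = np.full(4, 0.5)
        lod, dhat, _ = kong_cox_lod(z, zmin, gam)
        lod_grid, d_grid = grid_search_kc(z, zmin, gam)
        assert lod == pytest.approx(lod_grid, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_batch_agrees_with_scalar(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        z = rng.normal(0, 1, size=(4, n))
        zmin = -np.abs(rng.uniform(0.5, 2.0, size=(4, n)))
        batch = kong_cox_lod_batch(z, zmin)
        for b in range(4):
            lod, _, _ = kong_cox_lod(z[b], zmin[b])
            assert batch[b] == pytest.approx(lod, abs=1e-8)

    def test_no_informative_family_raises(self):
        with pytest.raises(ValueError):
            kong_cox_lod(np.array([]), np.array([]))


class TestConversions:
    @pytest.mark.parametrize(
        "lod,p",
        [(0.47, 0.0706), (1.47, 4.64e-3), (2.55, 3.05e-4), (1.12, 0.0116), (0.0, 0.5)],
    )
    def test_lod_to_pvalue_reference_pairs(self, lod, p):
        assert lod_to_pvalue(lod) == pytest.approx(p, rel=5e-3)

    def test_round_trip(self):
        for x in np.linspace(0.01, 10, 50):
            assert pvalue_to_lod(lod_to_pvalue(x)) == pytest.approx(x, abs=1e-9)

    def test_z_to_lod(self):
        assert z_to_lod(0) == 0
        assert z_to_lod(1) == pytest.approx(1 / (2 * LN10), abs=1e-6)
        assert z_to_lod(3) == pytest.approx(9 / (2 * LN10), abs=1e-4)

    def test_negative_lod_rejected(self):
        with pytest.raises(ValueError):
            lod_to_pvalue(-0.1)


class TestMultipointInvariants:
    def _informative_dataset(self, flip_alleles=False, reverse=False):
        """Two families, 3 markers, strongly shared genotypes in family 1."""
        peds = {
            "f1": make_nuclear("f1", 2, (0, 1)),
            "f2": make_nuclear("f2", 2, (0, 1)),
        }
        g1 = np.array([[1, 1, 1], [1, 1, 1], [2, 2, 0], [2, 2, 0]])
        g2 = np.array([[1, 0, 1], [0, 1, 2], [1, 1, 2], [0, 0, 1]])
        if flip_alleles:
            g1, g2 = 2 - g1, 2 - g2
        freqs = [0.4, 0.5, 0.6]
        spacing = 10.0
        ds = dataset_from_genotypes({"f1": peds["f1"], "f2": peds["f2"]},
                                    {"f1": g1, "f2": g2}, freqs, spacing)
        if flip_alleles:
            ds.allele_freqs = ds.allele_freqs[:, ::-1].copy()
        if reverse:
            # mirror the chromosome: reverse marker order, cM -> max - cM
            tab = ds.marker_map.table.iloc[::-1].reset_index(drop=True)
            tab["cM"] = tab["cM"].max() - tab["cM"]
            tab["bp"] = np.arange(1, len(tab) + 1) * 1_000_000
            ds.genotypes.codes = ds.genotypes.codes[:, ::-1, :].copy()
            ds.genotypes.allele_symbols = ds.genotypes.allele_symbols[::-1]
            ds.allele_freqs = ds.allele_freqs[::-1].copy()
            from famlink.pedigree_core import MarkerMap

            ds.marker_map = MarkerMap(tab)
            ds._marker_cols = {m: j for j, m in enumerate(ds.marker_map.markers)}
        return ds

    def test_lod_invariant_under_allele_relabeling(self):
        base = linkage_curve(self._informative_dataset(), "1")
        flipped = linkage_curve(self._informative_dataset(flip_alleles=True), "1")
        np.testing.assert_allclose(base["LOD"], flipped["LOD"], atol=1e-10)

    def test_lod_invariant_under_marker_reversal(self):
        base = linkage_curve(self._informative_dataset(), "1")
        rev = linkage_curve(self._informative_dataset(reverse=True), "1")
        np.testing.assert_allclose(
            base["LOD"].to_numpy(), rev["LOD"].to_numpy()[::-1], atol=1e-10
        )

    def test_theta_half_equals_single_point(self):
        """With unlinked markers, the multipoint posterior at each marker
        equals its single-marker posterior."""
        eng = NuclearFamilyEngine(make_nuclear(), "s_all")
        rng = np.random.default_rng(2)
        gs = rng.integers(-1, 3, size=(4, 3))
        E = np.stack([eng.marker_likelihood(tuple(gs[:, k]), 0.5) for k in range(3)])
        E[E.sum(axis=1) == 0] = 1.0
        post = eng.multipoint_posterior(E, np.array([0.5, 0.5]))
        single = E / E.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(post, single, atol=1e-12)

    def test_fully_informative_marker_degenerate_posterior(self):
        """Unambiguous transmissions concentrate the posterior on one vector class."""
        eng = NuclearFamilyEngine(make_nuclear(), "s_all")
        # parents het x het can't be fully informative with 2 alleles; use
        # missing-free hom x het with children resolving the het parent:
        gs = (1, 0, 1, 0)  # father het, mother hom0, child1 het, child2 hom0
        lik = eng.marker_likelihood(gs, 0.5)
        post = lik / lik.sum()
        # paternal bits determined up to global phase; maternal uninformative
        # -> entropy lower than uniform
        assert (post > 0).sum() < eng.n_states


class TestPeaksAndIntervals:
    def _curve(self, lods, spacing=10.0):
        n = len(lods)
        return pd.DataFrame(
            {
                "marker": [f"m{k}" for k in range(n)],
                "chrom": ["1"] * n,
                "bp": np.arange(1, n + 1) * 10**6,
                "cM": np.arange(n) * spacing,
                "LOD": lods,
            }
        )

    def test_suggestive_not_significant(self):
        pk = find_peaks(self._curve([0.1, 1.0, 3.22, 1.0, 0.2]))
        assert len(pk) == 1 and pk["tier"][0] == "suggestive"
        pk2 = find_peaks(self._curve([0.1, 3.7, 0.3]))
        assert pk2["tier"][0] == "significant"

    def test_below_threshold_no_peaks(self):
        assert len(find_peaks(self._curve([0.5, 2.1, 0.4]))) == 0

    def test_multimodal_matches_local_max_oracle(self):
        rng = np.random.default_rng(5)
        lods = np.abs(rng.normal(1.8, 1.0, size=60))
        curve = self._curve(lods)
        got = set(find_peaks(curve)["marker"])
        want = set()
        for i in range(60):
            left = lods[i - 1] if i > 0 else -1
            right = lods[i + 1] if i < 59 else -1
            if lods[i] > left and lods[i] > right and lods[i] >= 2.2:
                want.add(f"m{i}")
        assert got == want

    def test_triangular_interval(self):
        # peak 3.0 at center, flanks cross 1.0 at +-10 cM (2-LOD drop)
        lods = [0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0]
        si = support_interval(self._curve(lods), "m3", drop=2.0)
        assert (si.left_marker, si.right_marker) == ("m1", "m5")
        assert not si.left_at_end and not si.right_at_end

    def test_flat_curve_whole_chromosome_flagged(self):
        si = support_interval(self._curve([3.0] * 5), "m0", drop=2.0)
        assert si.right_at_end and si.right_marker == "m4"

    def test_random_curves_match_linear_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            lods = np.abs(rng.normal(2, 1, size=30))
            p = int(np.argmax(lods))
            curve = self._curve(lods)
            si = support_interval(curve, f"m{p}", drop=2.0)
            floor = lods[p] - 2.0
            left = 0
            for i in range(p - 1, -1, -1):
                if lods[i] <= floor:
                    left = i
                    break
            right = len(lods) - 1
            for i in range(p + 1, len(lods)):
                if lods[i] <= floor:
                    right = i
                    break
            assert si.left_marker == f"m{left}"
            assert si.right_marker == f"m{right}"


class TestXChromosome:
    """Hemizygous X mode: male meioses carry no bits; daughters always share
    the paternal X; sharing operates on actual allele-origin lists."""

    def _x_fam(self, child_sexes):
        return make_nuclear("f", len(child_sexes), tuple(range(len(child_sexes))),
                            child_sexes=list(child_sexes))

    def test_two_sons_share_maternally_only(self):
        eng = NuclearFamilyEngine(self._x_fam(["male", "male"]), "s_pairs", x_chrom=True)
        assert eng.n_states == 4  # maternal bits only
        np.testing.assert_allclose(sorted(eng.scores), [0, 0, 1, 1])
        assert eng.mu0 == pytest.approx(0.5)
        assert eng.z_min == pytest.approx(-1.0)

    def test_two_daughters_always_share_paternal_x(self):
        eng = NuclearFamilyEngine(self._x_fam(["female", "female"]), "s_pairs", x_chrom=True)
        # paternal X shared in every state -> scores 1 + maternal match
        np.testing.assert_allclose(sorted(eng.scores), [1, 1, 2, 2])

    def test_son_daughter_pair(self):
        eng = NuclearFamilyEngine(self._x_fam(["male", "female"]), "s_pairs", x_chrom=True)
        np.testing.assert_allclose(sorted(eng.scores), [0, 0, 1, 1])

    def test_x_scan_recovers_x_linked_locus(self):
        from famlink.synth import ChromosomeSpec, RiskLocus, SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_families=200,
            chromosomes=[ChromosomeSpec("X", 6, 10.0)],
            risk_loci=[
                RiskLocus("X", 25.0, 0.15,
                          {"male": (0.0, 0.85, 0.85), "female": (0.0, 0.0, 0.05)})
            ],
            baseline_penetrance=0.05,
            target_mo_fraction=None,
            seed=5,
        )
        coh = simulate_cohort(cfg)
        cur = linkage_curve(coh.dataset, "X")
        k = int(cur["LOD"].idxmax())
        assert abs(cur["cM"].iloc[k] - 25.0) <= 10.0
        assert cur["LOD"].iloc[k] > 3.6
        # male genotypes are stored as homozygous diplotypes
        codes = coh.dataset.genotypes.codes
        for r in range(coh.dataset.n_individuals):
            fam = coh.dataset.sample_index["family"].iloc[r]
            per = coh.dataset.sample_index["person"].iloc[r]
            ind = coh.dataset.pedigrees[fam].member(per)
            if ind.sex == "male":
                ok = (codes[r, :, 0] == codes[r, :, 1]) | (codes[r] < 0).any(axis=1)
                assert ok.all()
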