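import numpy as np
import pandas as pd
import pytest

from gbspanel.diversity import (
    allele_presence,
    fst_global_from_components,
    haplotype_interval_averages,
    haplotype_length_sample,
    ld_decay,
    maf_spectrum,
    nucleotide_divergence,
    weir_cockerham_fst,
    window_rank_correlation,
)
from gbspanel.matrix import HET, MISSING, GenotypeMatrix, make_sites
from gbspanel.simulate import (
    PanelConfig,
    simulate_block_pair,
    simulate_mosaic_panel,
    simulate_structured_panel,
)


def _sites(n, chrom="1", spacing=1000):
    pos = (np.arange(n) + 1) * spacing
    return make_sites([chrom] * n, pos, ["A"] * n, ["G"] * n)


def _mk(calls, **kw):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        [f"L{i}" for i in range(calls.shape[0])], _sites(calls.shape[1], **kw), calls
    )


class TestMafSpectrum:
    def test_identical_lines_all_monomorphic(self):
        m = _mk(np.tile([0, 2, 0, 2], (5, 1)))
        res = maf_spectrum(m, m.samples)
        assert res["hist"].sum() == 0
        assert res["n_monomorphic"] == 4

    def test_single_minor_homozygote_in_twenty(self):
        calls = np.zeros((20, 1), dtype=np.int8)
        calls[0, 0] = 2
        m = _mk(calls)
        res = maf_spectrum(m, m.samples)
        assert res["maf"][0] == pytest.approx(0.05)

    def test_histogram_matches_brute_force(self, rng, matrix_factory):
        m = matrix_factory(rng, n_samples=15, n_sites=80, het_rate=0.1)
        res = maf_spectrum(m, m.samples)
        edges = res["bin_edges"]
        # naive per-site recount
        mafs = []
        for j in range(m.n_sites):
            col = m.calls[:, j]
            col = col[(col != MISSING) & (col != HET)]
            if len(col) == 0:
                continue
            p = (col == 2).mean()
            f = min(p, 1 - p)
            if f > 0:
                mafs.append(f)
        expect, _ = np.histogram(mafs, bins=edges)
        assert res["hist"].tolist() == expect.tolist()


class TestAllelePresence:
    def test_singleton_carrier_absent_two_present(self):
        calls = np.zeros((5, 2), dtype=np.int8)
        calls[0, 0] = 2  # one carrier of allele2 at site 0
        calls[0, 1] = 2
        calls[1, 1] = HET  # second carrier (het counts) at site 1
        m = _mk(calls)
        pres, _, _ = allele_presence(m, {"g": m.samples})
        assert not pres["g"][0, 1]
        assert pres["g"][1, 1]

    def test_engineered_private_alleles_recovered(self):
        # group A carries allele2 at sites 0-4 only; B at sites 5-9 only;
        # allele1 common everywhere
        calls = np.zeros((8, 10), dtype=np.int8)
        calls[0:2, 0:5] = 2
        calls[4:6, 5:10] = 2
        m = _mk(calls)
        groups = {"A": m.samples[:4], "B": m.samples[4:]}
        pres, summary, shared_pct = allele_presence(m, groups)
        # union: allele1 at all 10 sites + allele2 at 10 sites (5 private to
        # each group) = 20 present alleles; each group carries 15 of them;
        # only the 10 allele1 copies are shared
        pct = summary.set_index("group")["percent_of_union"]
        assert pct["A"] == pytest.approx(100 * 15 / 20)
        assert pct["B"] == pytest.approx(100 * 15 / 20)
        assert shared_pct == pytest.approx(100 * 10 / 20)


class TestWeirCockerham:
    def test_opposite_fixation_gives_theta_one(self):
        a = np.zeros((6, 4), dtype=np.int8)
        b = np.full((6, 4), 2, dtype=np.int8)
        m = _mk(np.vstack([a, b]))
        res = weir_cockerham_fst(m, m.samples[:6], m.samples[6:])
        assert np.allclose(res.theta, 1.0)

    def test_hand_computed_two_by_two_table(self):
        # haploid counts: group A 3/1 for the two alleles, group B 1/3.
        # MSP = 0.5, MSG = 0.25, n_c = 4 -> theta = 0.25 / 1.25 = 0.2
        a = np.array([[2], [2], [2], [0]], dtype=np.int8)
        b = np.array([[0], [0], [0], [2]], dtype=np.int8)
        m = _mk(np.vstack([a, b]))
        res = weir_cockerham_fst(m, m.samples[:4], m.samples[4:])
        assert res.theta[0] == pytest.approx(0.2)

    def test_null_mean_theta_near_zero(self):
        cfg = PanelConfig(
            n_groups=2, samples_per_group=60, n_chromosomes=2,
            sites_per_chromosome=2500, fst_target=0.0,
            residual_het_rate=0.0, error_rate=0.0, seed=21,
        )
        m, labels, _ = simulate_structured_panel(cfg)
        groups = {g: list(labels[labels == g].index) for g in labels.unique()}
        ga, gb = groups.values()
        res = weir_cockerham_fst(m, ga, gb)
        assert abs(res.mean_theta) < 0.005

    @pytest.mark.parametrize("target", [0.06, 0.15])
    def test_drift_parameter_recovered(self, target):
        cfg = PanelConfig(
            n_groups=2, samples_per_group=60, n_chromosomes=2,
            sites_per_chromosome=1500, fst_target=target,
            residual_het_rate=0.0, error_rate=0.0, seed=22,
        )
        m, labels, _ = simulate_structured_panel(cfg)
        groups = {g: list(labels[labels == g].index) for g in labels.unique()}
        ga, gb = groups.values()
        res = weir_cockerham_fst(m, ga, gb)
        # bootstrap CI over sites
        rng = np.random.default_rng(23)
        n = len(res.msp)
        boots = [
            fst_global_from_components(
                res.msp, res.msg, res.nc, rng.integers(0, n, size=n)
            )
            for _ in range(300)
        ]
        lo, hi = np.quantile(boots, [0.005, 0.995])
        assert lo <= target <= hi

    def test_sparse_groups_skipped(self):
        calls = np.array([[0, 0], [MISSING, 2], [2, 0], [2, 2]], dtype=np.int8)
        m = _mk(calls)
        res = weir_cockerham_fst(m, m.samples[:2], m.samples[2:], min_group_n=2)
        assert np.isnan(res.theta[0])  # only 1 called line in group A

    def test_window_average_is_mean_of_per_site_theta(self):
        cfg = PanelConfig(
            n_groups=2, samples_per_group=20, n_chromosomes=1,
            sites_per_chromosome=200, chromosome_length=3_000_000,
            fst_target=0.1, residual_het_rate=0.0, error_rate=0.0, seed=24,
        )
        m, labels, _ = simulate_structured_panel(cfg)
        groups = {g: list(labels[labels == g].index) for g in labels.unique()}
        ga, gb = groups.values()
        res = weir_cockerham_fst(m, ga, gb, window_bp=1_000_000)
        pos = m.sites["pos"].to_numpy()
        for _, row in res.windows.iterrows():
            inwin = (pos >= row["start"]) & (pos <= row["end"])
            expect = np.nanmean(res.theta[inwin])
            assert row["fst"] == pytest.approx(expect, nan_ok=True)


class TestDivergence:
    def test_identical_groups_zero(self):
        base = np.tile([0, 2, 0, 2, 0, 2], (4, 1)).astype(np.int8)
        m = _mk(np.vstack([base, base]))
        res = nucleotide_divergence(m, m.samples[:4], m.samples[4:],
                                    window_bp=10_000, min_joint_sites=2)
        assert np.allclose(res["divergence"], 0.0)

    def test_opposite_fixation_one(self):
        a = np.zeros((3, 6), dtype=np.int8)
        b = np.full((3, 6), 2, dtype=np.int8)
        m = _mk(np.vstack([a, b]))
        res = nucleotide_divergence(m, m.samples[:3], m.samples[3:],
                                    window_bp=10_000, min_joint_sites=2)
        assert np.allclose(res["divergence"], 1.0)

    def test_matches_brute_force_on_toy_window(self, rng):
        calls = rng.choice([0, 2, MISSING], size=(6, 12), p=[0.4, 0.4, 0.2])
        m = _mk(calls.astype(np.int8))
        ga, gb = m.samples[:3], m.samples[3:]
        res = nucleotide_divergence(m, ga, gb, window_bp=10**9, min_joint_sites=1)
        vals = []
        for i in range(3):
            for j in range(3, 6):
                a, b = m.calls[i], m.calls[j]
                ok = (a != MISSING) & (b != MISSING)
                if ok.sum() >= 1:
                    vals.append((a[ok] == b[ok]).mean())
        assert res["divergence"].iloc[0] == pytest.approx(1 - np.mean(vals))

    def test_bounds_and_self_consistency(self, rng, matrix_factory):
        m = matrix_factory(rng, n_samples=10, n_sites=100, het_rate=0.05)
        res = nucleotide_divergence(m, m.samples, m.samples, window_bp=10**9,
                                    min_joint_sites=5)
        d = res["divergence"].dropna()
        assert ((d >= 0) & (d <= 1)).all()


def _enumerate_shared_interval(a, b, f):
    """Exact maximal shared interval around focal f, no forgiveness.

    Independent oracle: scan outward, skipping missing-in-either sites,
    stopping at the first mismatch on each side.
    """
    if a[f] == MISSING or b[f] == MISSING or a[f] != b[f]:
        return None
    n = 1
    for step in (1, -1):
        i = f + step
        while 0 <= i < len(a):
            if a[i] != MISSING and b[i] != MISSING:
                if a[i] != b[i]:
                    break
                n += 1
            i += step
    return n


class TestHaplotypeLength:
    def test_identical_lines_span_whole_chromosome(self):
        base = np.tile([0, 2] * 10, (2, 1)).astype(np.int8)
        m = _mk(base)
        draws = haplotype_length_sample(m, m.samples, 20, seed=1)
        assert (draws["length_sites"] == 20).all()
        assert (draws["length_bp"] == m.sites["pos"].iloc[-1] - m.sites["pos"].iloc[0] + 1).all()

    def test_alternating_mismatch_pattern_governed_by_forgiveness(self):
        # lines differ at every second site (odd indices)
        a = np.zeros(21, dtype=np.int8)
        b = a.copy()
        b[1::2] = 2
        m = _mk(np.stack([a, b]))
        draws = haplotype_length_sample(m, m.samples, 60, seed=2, forgive=1)
        interior = draws[(draws["focal_idx"] > 1) & (draws["focal_idx"] < 19)]
        even = interior[interior["focal_idx"] % 2 == 0]
        odd = interior[interior["focal_idx"] % 2 == 1]
        # even focal: one mismatch forgiven per side, so exactly the focal
        # plus one matching site each side
        assert (even["length_sites"] == 3).all()
        # odd focal: focal mismatch eats the allowance; next mismatch on a
        # side stops it, leaving focal plus one match per side
        assert (odd["length_sites"] == 3).all()

    def test_no_forgiveness_equals_enumeration_oracle(self, rng, matrix_factory):
        m = matrix_factory(rng, n_samples=2, n_sites=20, n_chrom=1,
                           missing_rate=0.2, het_rate=0.1)
        hap = m.haploidized()
        draws = haplotype_length_sample(m, m.samples, 100, seed=3, forgive=0)
        a, b = hap.calls
        for _, row in draws.iterrows():
            expect = _enumerate_shared_interval(a, b, row["focal_idx"])
            if expect is None:  # focal mismatch -> convention: length 1
                assert row["length_sites"] == 1
            else:
                assert row["length_sites"] == expect

    @pytest.mark.parametrize("block", [50, 500])
    def test_block_length_recovered(self, block):
        m = simulate_block_pair(n_sites=20 * block, block_length=block, seed=4)
        draws = haplotype_length_sample(m, m.samples, 300, seed=5)
        assert draws["length_sites"].mean() == pytest.approx(block, rel=0.10)

    def test_group_of_one_rejected(self):
        m = _mk(np.zeros((3, 5), dtype=np.int8))
        with pytest.raises(ValueError, match=">= 2"):
            haplotype_length_sample(m, m.samples[:1], 5)

    def test_pericentromeric_region_has_longer_haplotypes(self):
        m, _ = simulate_mosaic_panel(
            n_lines=20, n_founders=6, n_sites=1500, block_length=30,
            low_recomb_span=(500, 1000), low_recomb_factor=10, seed=6,
        )
        draws = haplotype_length_sample(m, m.samples, 800, seed=7)
        win = haplotype_interval_averages(draws, window_bp=250_000)
        mid = win[(win["start"] >= 500_000) & (win["end"] <= 1_000_000)]
        outer = win[(win["end"] < 500_000) | (win["start"] > 1_000_000)]
        assert mid["mean_length_sites"].mean() > outer["mean_length_sites"].mean()


class TestLdDecay:
    def test_duplicated_columns_give_r2_one_at_their_distance(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([0, 2], size=(40, 3)).astype(np.int8)
        calls[:, 1] = calls[:, 0]  # duplicate pair at distance 1000
        m = _mk(calls, spacing=1000)
        # shift the third site far away so the near bin holds only the pair
        m.sites.loc[2, "pos"] = 10_000
        res = ld_decay(m, m.samples, subsample=40, max_distance=10_000,
                       n_bins=2, log_bins=False, seed=9)
        near = res.iloc[0]
        assert near["n_pairs"] == 1
        assert near["mean"] == pytest.approx(1.0)

    def test_independent_sites_mean_near_sampling_bias(self):
        cfg = PanelConfig(
            n_groups=1, samples_per_group=60, n_chromosomes=1,
            sites_per_chromosome=300, fst_target=0.0,
            residual_het_rate=0.0, error_rate=0.0, seed=10,
        )
        m, _, _ = simulate_structured_panel(cfg)
        res = ld_decay(m, m.samples, subsample=60, max_distance=10_000_000,
                       n_bins=3, seed=11)
        mean_r2 = (res["mean"] * res["n_pairs"]).sum() / res["n_pairs"].sum()
        assert mean_r2 == pytest.approx(1 / 60, rel=0.30)

    def test_seed_reproducible_and_order_invariant(self):
        cfg = PanelConfig(
            n_groups=1, samples_per_group=30, n_chromosomes=1,
            sites_per_chromosome=100, fst_target=0.0,
            residual_het_rate=0.0, error_rate=0.0, seed=12,
        )
        m, _, _ = simulate_structured_panel(cfg)
        a = ld_decay(m, m.samples, subsample=20, seed=13)
        b = ld_decay(m, m.samples, subsample=20, seed=13)
        assert a.equals(b)
        shuffled = m.take_samples(sorted(m.samples, reverse=True))
        # same pairs summarized when no subsampling cuts in
        c = ld_decay(m, m.samples, subsample=30, seed=14)
        d = ld_decay(shuffled, shuffled.samples, subsample=30, seed=15)
        assert np.allclose(c["mean"].to_numpy(), d["mean"].to_numpy(),
                           equal_nan=True)

    def test_mosaic_panel_decays_monotonically(self):
        m, _ = simulate_mosaic_panel(n_lines=40, n_founders=4, n_sites=800,
                                     block_length=50, seed=16)
        res = ld_decay(m, m.samples, subsample=40, max_distance=200_000,
                       n_bins=4, log_bins=False, seed=17)
        means = res["mean"].dropna().to_numpy()
        # strong within-block LD decays to the 1/n sampling floor beyond
        # the block scale
        assert means[0] > 0.1
        assert (means[1:] < 0.05).all()

    def test_no_passing_snps_raises(self):
        m = _mk(np.zeros((10, 5), dtype=np.int8))  # all monomorphic
        with pytest.raises(ValueError, match="pass"):
            ld_decay(m, m.samples)


class TestWindowRankCorrelation:
    def test_identity_gives_rho_squared_one(self):
        a = [1.0, 3.0, 2.0, 5.0]
        rho, rho2 = window_rank_correlation(a, a)
        assert rho == pytest.approx(1.0)
        assert rho2 == pytest.approx(1.0)

    def test_negation_gives_rho_minus_one(self):
        a = np.array([1.0, 3.0, 2.0, 5.0])
        rho, rho2 = window_rank_correlation(a, -a)
        assert rho == pytest.approx(-1.0)
        assert rho2 == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        rho, _ = window_rank_correlation(a, b)
        ra = pd.Series(a).rank()
        rb = pd.Series(b).rank()
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expect)

    def test_fewer_than_three_pairs_undefined(self):
        rho, rho2 = window_rank_correlation([1, 2], [2, 1])
        assert np.isnan(rho) and np.isnan(rho2)

    def test_missing_windows_dropped(self, rng):
        a = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        b = np.array([2.0, 5.0, np.nan, 6.0, 8.0])
        rho, _ = window_rank_correlation(a, b)
        assert rho == pytest.approx(1.0)
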