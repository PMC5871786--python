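"""Hop simulator and admixture builder: conservation, recovery, dilution."""

import numpy as np
import pytest

from hopaudit import (
    GenomicSite,
    GenotypeTruth,
    HopConfig,
    HopauditError,
    MixtureSpec,
    PoolLayout,
    Role,
    SampleMeta,
    build_admixture,
    candidate_calls,
    draw_genotypes,
    simulate_pool,
    synthetic_frequency_table,
    truth_class,
    verify_mixture,
)
from hopaudit.datamodel import BASE_INDEX, PopulationFrequencyTable


def pair_pool_layout(n_individuals, pool_id="p1"):
    metas = []
    for i in range(n_individuals):
        frac = 1.0 / (2 * n_individuals)
        metas.append(SampleMeta(f"I{i}_T", f"I{i}", pool_id, Role.TUMOUR, frac))
        metas.append(SampleMeta(f"I{i}_N", f"I{i}", pool_id, Role.NORMAL, frac))
    return PoolLayout(metas)


def hom_truth(n_sites, individuals, alt_individuals=(), chrom="1"):
    """All-hom-ref truth except ``alt_individuals``, which are hom-alt
    everywhere."""
    sites = [GenomicSite(chrom, 1000 + i, "A", "G") for i in range(n_sites)]
    dosages = {ind: np.full(n_sites, 2 if ind in alt_individuals else 0)
               for ind in individuals}
    return GenotypeTruth(sites, np.zeros(n_sites), dosages)


class TestDrawGenotypes:
    def _table(self, freqs):
        return PopulationFrequencyTable({
            GenomicSite("1", 100 + i, "A", "G"): f for i, f in enumerate(freqs)})

    def test_degenerate_frequencies(self):
        truth = draw_genotypes(self._table([0.0, 1.0]), ["a", "b"], seed=1)
        for ind in ("a", "b"):
            d = {s.pos: x for s, x in zip(truth.sites, truth.dosages[ind])}
            assert d[100] == 0 and d[101] == 2

    def test_hardy_weinberg_mean_dosage(self):
        table = self._table([0.5])
        inds = [f"i{k}" for k in range(10_000)]
        truth = draw_genotypes(table, inds, seed=2)
        mean = np.mean([truth.dosages[i][0] for i in inds])
        assert mean == pytest.approx(1.0, abs=0.02)

    def test_somatic_sites_cohort_absent_and_disjoint(self):
        table = self._table([0.3, 0.0, 0.0, 0.0, 0.6])
        truth = draw_genotypes(table, ["a"], n_somatic_per_tumour=2, seed=3)
        for i, af in truth.somatic["a"].items():
            assert truth.freqs[i] == 0.0
            assert truth.dosages["a"][i] == 0
            assert 0 < af <= 1

    def test_too_few_candidate_sites_rejected(self):
        with pytest.raises(HopauditError, match="cohort-absent"):
            draw_genotypes(self._table([0.3, 0.0]), ["a"],
                           n_somatic_per_tumour=5, seed=1)

    def test_reproducible_under_seed(self):
        table = self._table([0.2, 0.5, 0.8])
        a = draw_genotypes(table, ["x"], seed=11)
        b = draw_genotypes(table, ["x"], seed=11)
        assert np.array_equal(a.dosages["x"], b.dosages["x"])


class TestSimulatePool:
    def test_no_hopping_means_no_foreign_origins(self):
        layout = pair_pool_layout(2)
        truth = hom_truth(50, [m.individual_id for m in layout])
        pus = simulate_pool(truth, layout, HopConfig(hop_rate=0.0, seed=1))
        for sid, pu in pus.items():
            foreign = sum(int(arr.sum()) for o, arr in pu.origin_counts.items()
                          if o != sid)
            assert foreign == 0

    @pytest.mark.parametrize("hop_rate", [0.0, 0.02])
    def test_read_count_conserved_exactly(self, hop_rate):
        layout = pair_pool_layout(3)
        truth = hom_truth(100, [m.individual_id for m in layout])
        cfg = HopConfig(hop_rate=hop_rate, seed=2)
        pus = simulate_pool(truth, layout, cfg)
        total = sum(int(pu.counts.sum()) for pu in pus.values())
        expected = 100 * 3 * (cfg.depth_tumour + cfg.depth_normal)
        assert total == expected

    def test_two_sample_closed_form_hop_fraction(self):
        # Equal two-library pool, source hom-alt, target hom-ref, e = 0:
        # expected alt fraction among target-assigned reads equals h.
        layout = PoolLayout([
            SampleMeta("tgt", "A", "p1", Role.TUMOUR, 0.5),
            SampleMeta("src", "B", "p1", Role.TUMOUR, 0.5),
        ])
        truth = hom_truth(2000, ["A", "B"], alt_individuals=("B",))
        h = 0.01
        pus = simulate_pool(truth, layout,
                            HopConfig(hop_rate=h, error_rate=0.0, seed=3))
        tgt = pus["tgt"]
        alt = int(tgt.counts[:, BASE_INDEX["G"]].sum())
        total = int(tgt.counts.sum())
        se = np.sqrt(h * (1 - h) * total)
        assert abs(alt - h * total) < 3 * se

    def test_hop_rate_recovered_from_origin_tags(self):
        layout = pair_pool_layout(4)
        truth = hom_truth(300, [m.individual_id for m in layout])
        h = 0.02
        pus = simulate_pool(truth, layout, HopConfig(hop_rate=h, seed=4))
        hopped = sum(int(arr.sum()) for sid, pu in pus.items()
                     for o, arr in pu.origin_counts.items() if o != sid)
        total = sum(int(pu.counts.sum()) for pu in pus.values())
        se = np.sqrt(h * (1 - h) * total)
        assert abs(hopped - h * total) < 3 * se

    def test_single_member_pool_with_hopping_rejected(self):
        layout = PoolLayout([SampleMeta("only", "A", "p1", Role.TUMOUR, 1.0)])
        truth = hom_truth(10, ["A"])
        with pytest.raises(HopauditError, match="hop destination"):
            simulate_pool(truth, layout, HopConfig(hop_rate=0.01, seed=1))

    def test_solo_lane_sample_simulated_without_hopping(self):
        layout = PoolLayout([SampleMeta("solo", "A", None, Role.NORMAL)])
        truth = hom_truth(20, ["A"])
        pus = simulate_pool(truth, layout, HopConfig(hop_rate=0.3, seed=1))
        assert set(pus["solo"].origin_counts) == {"solo"}

    def test_contaminant_af_dilutes_with_pool_size(self):
        # Fixed h: a single source's contribution to a hom-ref target drops
        # as the pool grows (each hopped read picks among more destinations).
        h = 0.02
        means = []
        for k in (2, 4, 8):
            metas = [SampleMeta(f"s{j}", f"i{j}", "p1", Role.TUMOUR, 1.0 / k)
                     for j in range(k)]
            layout = PoolLayout(metas)
            truth = hom_truth(600, [f"i{j}" for j in range(k)],
                              alt_individuals=("i1",))
            pus = simulate_pool(truth, layout,
                                HopConfig(hop_rate=h, error_rate=0.0, seed=5))
            tgt = pus["s0"]
            alt_from_src = tgt.origin_counts["s1"][:, BASE_INDEX["G"]]
            depth = tgt.counts.sum(axis=1)
            means.append(float(np.mean(alt_from_src / depth)))
        assert means[0] > means[1] > means[2]


class TestAdmixture:
    def _truth(self, n_sites, individuals, seed=0):
        freq = synthetic_frequency_table(n_sites, seed=seed)
        return draw_genotypes(freq, individuals, seed=seed + 1)

    def test_zero_contamination_is_pure_target(self):
        truth = self._truth(100, ["t"])
        pu = build_admixture(MixtureSpec("t", ()), truth, depth=50, seed=1)
        assert set(pu.origin_counts) == {"t"}
        assert verify_mixture(pu) == {"t": 1.0}

    def test_seven_equal_shares(self):
        shares = tuple((f"c{i}", 0.08 / 7) for i in range(7))
        spec = MixtureSpec("t", shares)
        assert spec.total == pytest.approx(0.08)
        assert shares[0][1] == pytest.approx(0.011428571)

    def test_total_contamination_bounds(self):
        with pytest.raises(HopauditError):
            MixtureSpec("t", (("c", 1.0),))
        with pytest.raises(HopauditError):
            MixtureSpec("t", (("t", 0.1),))
        with pytest.raises(HopauditError):
            MixtureSpec("t", (("c", -0.1),))

    def test_recovered_share_within_binomial_error(self):
        truth = self._truth(2000, ["t", "b"], seed=2)
        spec = MixtureSpec("t", (("b", 0.02),))
        pu = build_admixture(spec, truth, depth=300, seed=3)
        shares = verify_mixture(pu)
        assert sum(shares.values()) == pytest.approx(1.0)
        n = 2000 * 300
        se = np.sqrt(0.02 * 0.98 / n)
        assert shares["b"] == pytest.approx(0.02, abs=3 * se)
        # mean foreign reads per site ~ depth * c = 6
        foreign = pu.origin_counts["b"].sum() / 2000
        assert foreign == pytest.approx(6.0, rel=0.1)

    def test_untagged_pileup_rejected_by_verify(self):
        truth = self._truth(10, ["t"])
        pu = build_admixture(MixtureSpec("t", ()), truth, depth=20, seed=1)
        pu = type(pu)(pu.sample_id, pu.sites, pu.counts, None)
        with pytest.raises(HopauditError, match="origin tags"):
            verify_mixture(pu)

    def test_reproducible_under_seed(self):
        truth = self._truth(50, ["t", "b"], seed=4)
        spec = MixtureSpec("t", (("b", 0.05),))
        a = build_admixture(spec, truth, depth=100, seed=9)
        b = build_admixture(spec, truth, depth=100, seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestTruthAndCalling:
    def test_truth_classes(self):
        layout = PoolLayout([
            SampleMeta("a_T", "a", "p1", Role.TUMOUR, 0.5),
            SampleMeta("b_T", "b", "p1", Role.TUMOUR, 0.5),
        ])
        sites = [GenomicSite("1", 100 + i, "A", "G") for i in range(3)]
        truth = GenotypeTruth(
            sites, np.array([0.5, 0.0, 0.0]),
            {"a": np.array([1, 0, 0]), "b": np.array([0, 0, 0])},
            somatic={"b": {2: 0.4}})
        assert truth_class(truth, layout, "a_T", 0) == "germline"
        assert truth_class(truth, layout, "b_T", 0) == "hop-contaminant"
        assert truth_class(truth, layout, "b_T", 2) == "somatic"
        assert truth_class(truth, layout, "a_T", 2) == "hop-contaminant"
        assert truth_class(truth, layout, "a_T", 1) is None

    def test_candidate_calls_skip_host_germline(self):
        layout = pair_pool_layout(2)
        freq = synthetic_frequency_table(200, 40, seed=6)
        truth = draw_genotypes(freq, ["I0", "I1"], n_somatic_per_tumour=5,
                               seed=7)
        pus = simulate_pool(truth, layout,
                            HopConfig(hop_rate=0.02, error_rate=0.0, seed=8))
        calls = candidate_calls(pus["I0_T"], truth, individual_id="I0")
        dosage = {s: d for s, d in zip(truth.sites, truth.dosages["I0"])}
        assert calls, "expected candidate calls in a hopping pool"
        for call in calls:
            assert dosage[call.site] == 0
            assert call.alt_count >= 3
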