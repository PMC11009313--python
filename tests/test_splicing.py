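"""PSI computation, variability tests, differential event calling and
cryptic classification."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from clipsplice import splicing, synthetic_data
from clipsplice.splicing import Junction, SplicingEvent


class TestComputePsi:
    def test_pure_inclusion_is_one(self):
        assert splicing.compute_psi([[10]], [0])[0] == 1.0

    def test_mean_of_inclusion_junctions(self):
        """Inclusion junctions (20, 40), skipping 10: PSI = 30/40."""
        psi = splicing.compute_psi([[20], [40]], [10])
        assert psi[0] == pytest.approx(0.75)

    def test_zero_support_undefined(self):
        psi = splicing.compute_psi([[0]], [0])
        assert np.isnan(psi[0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            splicing.compute_psi([[-1]], [0])


class TestVariabilityTests:
    def test_identical_vectors_f_one_p_one(self):
        f, p = splicing.f_variance_test([0.2, 0.5, 0.7], [0.2, 0.5, 0.7])
        assert f == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_f_statistic_and_pvalue_match_distribution_oracle(self):
        """var 0.04 vs 0.01 at n=4 gives F=4 and the two-sided F(3,3) tail."""
        case = np.array([0.0, 0.2, 0.4, 0.6])          # var = 0.2^2/... scaled below
        case = case * (0.2 / case.std(ddof=1)) # force sd 0.2
        control = case * 0.5 + 0.3                      # sd 0.1
        f, p = splicing.f_variance_test(case, control)
        assert f == pytest.approx(4.0)
        dist = sps.f(3, 3)
        assert p == pytest.approx(2 * min(dist.cdf(4.0), dist.sf(4.0)))

    def test_zero_control_variance_flagged_and_excluded(self):
        psi_case = np.array([[0.1, 0.5, 0.9], [0.2, 0.4, 0.6], [0.3, 0.5, 0.7]])
        psi_control = np.array([[0.5, 0.5, 0.5], [0.4, 0.5, 0.6], [0.2, 0.5, 0.8]])
        res = splicing.psi_variability_test(psi_case, psi_control)
        assert res.n_excluded_zero_variance == 1
        assert len(res.per_event) == 3

    def test_higher_case_dispersion_detected_globally(self):
        """4x dispersion in the case group rejects the global t test on
        per-event PSI standard deviations."""
        truth = synthetic_data.SimulationTruth(
            seed=31,
            samples=[(f"c{i}", "case") for i in range(3)]
                    + [(f"k{i}", "ctrl") for i in range(3)],
            psi_truth={f"e{i:03d}": {"case": (0.5, 0.1), "ctrl": (0.5, 0.025)}
                       for i in range(200)},
        )
        df = synthetic_data.simulate_junction_counts(truth, depth=100)
        psi = (df.assign(psi=df["inclusion_count"] / 100)
               .pivot_table(index="event_id", columns="sample", values="psi"))
        case_cols = [c for c in psi.columns if c.startswith("c")]
        ctrl_cols = [c for c in psi.columns if c.startswith("k")]
        res = splicing.psi_variability_test(psi[case_cols].to_numpy(),
                                            psi[ctrl_cols].to_numpy())
        assert res.global_p < 0.01
        assert res.per_event["sd_case"].mean() > res.per_event["sd_control"].mean()

    def test_global_p_uniform_under_equal_dispersion(self):
        """Equal dispersions: global t-test p-values over replicate
        simulations pass a KS uniformity check at alpha = 0.01."""
        pvals = []
        for rep in range(60):
            truth = synthetic_data.SimulationTruth(
                seed=1000 + rep,
                samples=[(f"c{i}", "case") for i in range(3)]
                        + [(f"k{i}", "ctrl") for i in range(3)],
                psi_truth={f"e{i:02d}": {"case": (0.5, 0.05), "ctrl": (0.5, 0.05)}
                           for i in range(80)},
            )
            df = synthetic_data.simulate_junction_counts(truth, depth=100)
            psi = (df.assign(psi=df["inclusion_count"] / 100)
                   .pivot_table(index="event_id", columns="sample", values="psi"))
            case_cols = [c for c in psi.columns if c.startswith("c")]
            ctrl_cols = [c for c in psi.columns if c.startswith("k")]
            res = splicing.psi_variability_test(psi[case_cols].to_numpy(),
                                                psi[ctrl_cols].to_numpy())
            pvals.append(res.global_p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def _event(event_id, incl_case, incl_ctrl, depth=100, event_type="SE"):
    incl = np.array(incl_case + incl_ctrl, dtype=float)
    skip = depth - incl
    n = len(incl_case)
    return SplicingEvent(
        event_id=event_id, event_type=event_type,
        inclusion_counts=incl[None, :], skipping_counts=skip,
        samples=[f"s{i}" for i in range(len(incl))],
        conditions=["case"] * n + ["ctrl"] * (len(incl) - n),
    )


class TestDifferentialAse:
    def test_filter_requires_both_significance_and_effect(self):
        """Large shift kept; tiny-delta events excluded by the inclusion-
        difference filter even when statistically significant; null events
        not significant."""
        events = [
            _event("big", [80, 82, 78], [20, 22, 18]),           # delta ~0.6
            _event("tiny", [52, 51, 53], [48, 49, 47], depth=10_000),
            _event("null", [50, 51, 49], [50, 49, 51]),
        ]
        # make 'tiny' significant but small: high depth, delta ~ 0.0003 -> use
        # counts scaled so delta ~0.04
        events[1] = _event("tiny", [5400, 5380, 5420], [5000, 4980, 5020],
                           depth=10_000)
        df = splicing.differential_ase(events, "case", "ctrl").set_index("event_id")
        assert bool(df.loc["big", "significant"])
        assert df.loc["tiny", "p_adj"] < 0.05
        assert abs(df.loc["tiny", "delta_psi"]) < 0.05
        assert not bool(df.loc["tiny", "significant"])
        assert not bool(df.loc["null", "significant"])

    def test_counts_reported_per_event_type(self):
        events = [
            _event("a", [80, 82, 78], [20, 22, 18], event_type="SE"),
            _event("b", [90, 88, 92], [10, 12, 8], event_type="RI"),
            _event("c", [50, 51, 49], [50, 49, 51], event_type="MXE"),
        ]
        df = splicing.differential_ase(events, "case", "ctrl")
        by_type = df.attrs["significant_by_type"]
        assert by_type["SE"] == 1 and by_type["RI"] == 1 and by_type["MXE"] == 0

    def test_power_at_moderate_effect(self):
        """Planted delta-PSI 0.3 at depth 100, 3v3: the filter detects more
        than 80% of events."""
        truth = synthetic_data.SimulationTruth(
            seed=77,
            samples=[(f"c{i}", "case") for i in range(3)]
                    + [(f"k{i}", "ctrl") for i in range(3)],
            psi_truth={f"e{i:03d}": {"case": (0.65, 0.02), "ctrl": (0.35, 0.02)}
                       for i in range(200)},
        )
        df = synthetic_data.simulate_junction_counts(truth, depth=100)
        events = splicing.events_from_count_table(df)
        res = splicing.differential_ase(events, "case", "ctrl")
        assert res["significant"].mean() > 0.8

    def test_null_lrt_calibrated_under_its_sampling_model(self):
        """Under equal PSI distributions with negligible biological
        overdispersion (the LRT's own binomial sampling model), null
        p-values are not anti-conservative beyond sampling noise at any
        probed quantile. (With substantial overdispersion the pooled LRT
        is anti-conservative — a documented limitation, not an invariant.)"""
        truth = synthetic_data.SimulationTruth(
            seed=15,
            samples=[(f"c{i}", "case") for i in range(3)]
                    + [(f"k{i}", "ctrl") for i in range(3)],
            psi_truth={f"e{i:03d}": {"case": (0.5, 0.001), "ctrl": (0.5, 0.001)}
                       for i in range(400)},
        )
        df = synthetic_data.simulate_junction_counts(truth, depth=100)
        events = splicing.events_from_count_table(df)
        res = splicing.differential_ase(events, "case", "ctrl")
        p = res["p"].to_numpy()
        for q in (0.05, 0.1, 0.25, 0.5):
            assert (p <= q).mean() <= q + 3 * np.sqrt(q * (1 - q) / len(p))


class TestClassifyCryptic:
    ANN = [Junction("chr1", 100, 201, "+"), Junction("chr1", 300, 401, "+")]

    def test_fully_annotated_junction(self):
        df = splicing.classify_cryptic([Junction("chr1", 100, 201, "+")], self.ANN)
        assert df.loc[0, "classification"] == "annotated"

    def test_novel_acceptor_is_cryptic(self):
        df = splicing.classify_cryptic([Junction("chr1", 100, 250, "+")], self.ANN)
        assert df.loc[0, "classification"] == "cryptic"
        assert bool(df.loc[0, "annotated_donor"]) and not bool(df.loc[0, "annotated_acceptor"])

    def test_annotated_coordinates_on_other_strand_are_novel(self):
        df = splicing.classify_cryptic([Junction("chr1", 201, 100, "-")], self.ANN)
        assert df.loc[0, "classification"] == "cryptic"

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            splicing.classify_cryptic([Junction("chrX", 100, 201, "+")], self.ANN)

    def test_planted_cryptic_recovered_exactly(self, toy_annotation):
        """Set-membership classification recovers planted unannotated
        junctions with precision = recall = 1."""
        observed = toy_annotation.annotated_junctions + toy_annotation.cryptic_junctions
        df = splicing.classify_cryptic(observed, toy_annotation.annotated_junctions)
        called = {Junction(r.contig, r.donor, r.acceptor, r.strand)
                  for r in df[df["classification"] == "cryptic"].itertuples()}
        assert called == set(toy_annotation.cryptic_junctions)

    def test_permutation_invariance(self, toy_annotation):
        observed = toy_annotation.cryptic_junctions + toy_annotation.annotated_junctions
        a = splicing.classify_cryptic(observed, toy_annotation.annotated_junctions)
        b = splicing.classify_cryptic(list(reversed(observed)),
                                      toy_annotation.annotated_junctions)
        key = ["contig", "donor", "acceptor", "strand"]
        assert (a.sort_values(key).reset_index(drop=True)["classification"]
                == b.sort_values(key).reset_index(drop=True)["classification"]).all()

    def test_junction_transcription_order_enforced(self):
        with pytest.raises(ValueError, match="upstream"):
            Junction("chr1", 300, 200, "+").validate()
        Junction("chr1", 300, 200, "-").validate()  # valid on the minus strand
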