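"""Temporal classifier: forced examples, invariants and oracle agreement."""

import numpy as np
import pytest

from phagetime.io import DEFAULT_PHASE_GROUPING
from phagetime.normalize import total_count_normalize
from phagetime.temporal import (
    PhaseProfile,
    classify_all,
    classify_temporal,
    phase_averages,
)
from tests.conftest import FULL_TIMES, make_counts


def profile(e, m, l, mean=50.0):
    return PhaseProfile("g", e, m, l, mean_infected=mean)


def brute_force_class(avg_e, avg_m, avg_l, mean_infected,
                      min_tgr=10.0, margin_threshold=40.0):
    """Direct nested-conditional re-reading of the classification rule,
    written independently of the implementation."""
    if mean_infected < min_tgr:
        return "excluded"
    top = max(avg_e, avg_m, avg_l)
    pcts = [(a / top) * 100.0 for a in (avg_e, avg_m, avg_l)]
    ranked = sorted(pcts, reverse=True)
    if ranked[0] - ranked[1] < margin_threshold:
        return "constitutive"
    if pcts[0] == 100.0:
        return "early"
    if pcts[1] == 100.0:
        return "middle"
    return "late"


class TestPhaseAverages:
    def test_constant_gene(self):
        counts = make_counts({"g": [99, 10, 10, 10, 10, 10, 10, 10, 10, 10]},
                             FULL_TIMES, normalized=True)
        (prof,) = phase_averages(counts)
        assert prof.averages.tolist() == [10, 10, 10]
        assert prof.pct.tolist() == [100, 100, 100]
        # the 0-min control (99) must not leak into any average
        assert prof.mean_infected == 10

    def test_forced_arithmetic(self):
        counts = make_counts({"g": [0, 40, 60, 20, 20, 20, 0, 0, 0, 0]},
                             FULL_TIMES, normalized=True)
        (prof,) = phase_averages(counts)
        assert prof.averages.tolist() == [50, 20, 0]
        assert prof.pct.tolist() == [100, 40, 0]

    def test_random_matrices_match_brute_force_means(self, rng):
        mat = {f"g{i}": rng.integers(0, 500, 10).tolist() for i in range(30)}
        counts = make_counts(mat, FULL_TIMES, normalized=True)
        profs = {p.gene_id: p for p in phase_averages(counts)}
        groups = {"early": (1, 2), "middle": (3, 4, 5), "late": (6, 7, 8, 9)}
        for gid, row in mat.items():
            for k, (phase, idx) in enumerate(groups.items()):
                expected = sum(row[i] for i in idx) / len(idx)
                assert profs[gid].averages[k] == pytest.approx(expected)

    def test_empty_phase_group_rejected(self):
        counts = make_counts({"g": [1, 2, 3]}, (0, 2, 5), normalized=True)
        with pytest.raises(ValueError, match="middle"):
            phase_averages(counts)


class TestClassifyTemporal:
    @pytest.mark.parametrize(
        "avgs,mean,expected,margin",
        [
            ((50, 50, 50), 50, "constitutive", 0.0),     # flat profile
            ((100, 40, 0), 50, "early", 60.0),           # forced by rule
            ((100, 70, 10), 50, "constitutive", 30.0),   # margin below 40
            ((1, 2, 5), 5, "excluded", None),            # mean TGR below 10
            ((0, 100, 30), 50, "middle", 70.0),
            ((10, 20, 100), 50, "late", 80.0),
            ((100, 100, 10), 50, "constitutive", 0.0),   # two-way top tie
        ],
    )
    def test_forced_examples(self, avgs, mean, expected, margin):
        call = classify_temporal(profile(*avgs, mean=mean))
        assert call.temporal_class == expected
        if margin is not None:
            assert call.margin == pytest.approx(margin)

    def test_margin_exactly_at_threshold_is_regulated(self):
        call = classify_temporal(profile(100, 60, 0))
        assert call.temporal_class == "early" and call.margin == 40

    def test_scale_invariance(self, rng):
        for _ in range(100):
            avgs = rng.uniform(0, 100, 3)
            c = rng.uniform(0.1, 50)
            base = classify_temporal(profile(*avgs, mean=1e6))
            scaled = classify_temporal(profile(*(avgs * c), mean=1e6))
            assert base.temporal_class == scaled.temporal_class

    def test_raising_margin_never_creates_phase_calls(self, rng):
        for _ in range(200):
            avgs = rng.uniform(0, 100, 3)
            lo = classify_temporal(profile(*avgs), margin_threshold=20)
            hi = classify_temporal(profile(*avgs), margin_threshold=60)
            if lo.temporal_class == "constitutive":
                assert hi.temporal_class == "constitutive"

    def test_oracle_agreement_on_random_profiles(self, rng):
        for _ in range(1000):
            avgs = rng.uniform(0, 100, 3)
            if rng.random() < 0.1:   # force exact ties sometimes
                avgs[rng.integers(3)] = avgs[rng.integers(3)]
            mean = rng.uniform(0, 100)
            got = classify_temporal(profile(*avgs, mean=mean)).temporal_class
            want = brute_force_class(*avgs, mean_infected=mean)
            assert got == want


class TestClassifyAll:
    def test_empty_gene_set(self):
        counts = make_counts({}, FULL_TIMES, normalized=True)
        table, summary = classify_all(counts)
        assert len(table) == 0
        assert all(v == 0 for v in summary["class_sizes"].values())

    def test_partition_and_zero_read_report(self):
        counts = make_counts(
            {"a": [0] * 10, "b": [0, 100, 100, 20, 20, 20, 20, 20, 20, 20]},
            FULL_TIMES,
            normalized=True,
        )
        table, summary = classify_all(counts)
        assert sum(summary["class_sizes"].values()) == 2
        assert summary["zero_read_genes"] == ["a"]
        assert table.set_index("gene_id").loc["a", "temporal_class"] == "excluded"

    def test_all_constitutive_poisson_simulation(self):
        # flat profiles in the Poisson limit must be recovered as constitutive
        from phagetime.simulate import HostDEConfig, SimConfig, simulate_infection

        cfg = SimConfig(
            seed=1,
            n_phage_genes=200,
            phage_genome_len=90_000,
            class_proportions={"early": 0, "middle": 0, "late": 0,
                               "constitutive": 1, "excluded": 0},
            dispersion=None,
            n_asrna=0,
            n_intergenic_rna=0,
            emit_coverage=False,
            host_de=HostDEConfig(0, 0, 0, 0, 0.0),
        )
        _f, counts, _iv, truth = simulate_infection(cfg)
        phage = [g for g in counts.gene_ids if counts.organism_of(g) == "phage"]
        infected = [s.sample_id for s in counts.samples if s.time_min > 0]
        norm = total_count_normalize(
            counts.subset_genes(phage).subset_samples(infected), "phage_only"
        )
        table, summary = classify_all(norm)
        frac = summary["class_sizes"]["constitutive"] / len(phage)
        assert frac >= 0.95
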