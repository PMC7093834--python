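"""Simulator: trees, K2P mutagenesis, master elements, planted invasions."""

import numpy as np
import pytest

from temine._dna import revcomp, translate
from temine.annotate import detect_dde, detect_grpr
from temine.divergence import count_site_differences, kimura2p
from temine.simulate import (InvasionEvent, MasterElementConfig,
                             SimulationConfig, SpeciesTree,
                             SubstitutionParams, evolve_sequence,
                             make_master_element, make_species_tree,
                             simulate_invasion)


class TestSpeciesTree:
    def test_two_species_forced_topology(self):
        tree = make_species_tree(2, 435.0, seed=0)
        times = tree.divergence_times()
        assert times.loc["sp01", "sp02"] == pytest.approx(435.0)

    def test_pairwise_times_are_ultrametric_invariants(self):
        tree = make_species_tree(4, 400.0, seed=1)
        times = tree.divergence_times()
        assert np.allclose(times.values, times.values.T)
        assert np.all(np.diag(times.values) == 0)
        off = times.values[np.triu_indices(4, k=1)]
        assert np.all(off > 0) and np.all(off <= 400.0)

    def test_same_seed_same_tree(self):
        t1 = make_species_tree(6, 300.0, seed=7)
        t2 = make_species_tree(6, 300.0, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            make_species_tree(1, 100.0)

    def test_newick_round_trip_preserves_divergence_times(self):
        tree = make_species_tree(5, 350.0, seed=3)
        back = SpeciesTree.from_newick(tree.to_newick())
        a = tree.divergence_times()
        b = back.divergence_times().loc[a.index, a.columns]
        assert np.allclose(a.values, b.values, atol=1e-6)

    def test_mrca_age(self):
        tree = SpeciesTree.from_newick("((a:20,b:20):380,(c:50,d:50):350);")
        assert tree.mrca_age(["a", "b"]) == pytest.approx(20.0)
        assert tree.mrca_age(["a", "c"]) == pytest.approx(400.0)


class TestEvolveSequence:
    def test_zero_rate_is_identity(self, master):
        out = evolve_sequence(master.full_sequence,
                              SubstitutionParams(k_target=0.0))
        assert out == master.full_sequence

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACGTN", SubstitutionParams(k_target=0.1))

    def test_high_kappa_suppresses_transversions(self, rng):
        from temine._dna import random_dna

        seq = random_dna(50_000, rng)
        out = evolve_sequence(
            seq, SubstitutionParams(kappa=100.0, k_target=0.05), rng)
        counts = count_site_differences(seq, out)
        assert counts.q < 0.002
        assert counts.p > 0.03

    def test_k_recovery_against_estimator(self, rng):
        """Mutating to K=0.10 must be recovered by the K2P estimator on the
        truth alignment (mean over replicates within +-0.01)."""
        from temine._dna import random_dna

        seq = random_dna(10_000, rng)
        ks = []
        for _ in range(100):
            out = evolve_sequence(
                seq, SubstitutionParams(kappa=2.0, k_target=0.10), rng)
            ks.append(kimura2p(count_site_differences(seq, out)))
        assert abs(np.mean(ks) - 0.10) < 0.01

    @pytest.mark.parametrize("k_target", [0.01, 0.05, 0.1, 0.3])
    def test_calibration_across_depths(self, k_target, rng):
        from temine._dna import random_dna

        seq = random_dna(5_000, rng)
        ks = [kimura2p(count_site_differences(
            seq, evolve_sequence(
                seq, SubstitutionParams(kappa=2.0, k_target=k_target), rng)))
            for _ in range(50)]
        assert abs(np.mean(ks) - k_target) / k_target < 0.10

    def test_indels_change_length(self, rng):
        from temine._dna import random_dna

        seq = random_dna(5_000, rng)
        out = evolve_sequence(
            seq, SubstitutionParams(k_target=0.01, indel_rate=0.01), rng)
        assert len(out) != len(seq)


class TestMasterElement:
    def test_default_structure(self, master):
        cfg = MasterElementConfig()
        assert cfg.length_range[0] <= len(master.full_sequence) \
            <= cfg.length_range[1]
        assert 304 <= len(master.transposase) <= 350
        assert 13 <= master.tir_length <= 68
        assert master.tir_right == revcomp(master.tir_left)
        assert master.full_sequence.startswith("CAGTC")
        coding = master.full_sequence[master.orf_start:master.orf_end]
        assert translate(coding) == master.transposase + "*"

    def test_triad_is_dd35e_and_detectable(self, master):
        assert master.triad.spacing == 35
        triad = detect_dde(master.transposase)
        assert triad is not None
        assert triad.label == "DD35E"
        assert (triad.d1, triad.d2, triad.e) == (
            master.triad.d1, master.triad.d2, master.triad.e)

    def test_grpr_planted_and_detectable(self, master):
        assert detect_grpr(master.transposase) == master.grpr_position

    def test_zero_tir_rejected(self):
        with pytest.raises(ValueError):
            make_master_element(MasterElementConfig(tir_length=0))

    def test_infeasible_orf_rejected(self):
        with pytest.raises(ValueError):
            make_master_element(MasterElementConfig(total_length=1100,
                                                    transposase_length=350))


class TestSimulateInvasion:
    def _quick(self, seed=0, **kw):
        tree = SpeciesTree.from_newick(
            "((a:20,b:20):380,(c:50,d:50):350);")
        master = make_master_element(MasterElementConfig(seed=seed))
        cfg = SimulationConfig(contig_length=8_000, p_trunc=0.0,
                               indel_rate=0.0, **kw)
        return tree, master, cfg

    def test_age_zero_copies_are_exact_with_tsds(self):
        tree, master, cfg = self._quick()
        events = [InvasionEvent(recipients=("a",), time_ma=0.0, copies=3)]
        genomes, _, truth = simulate_invasion(tree, master, events, cfg,
                                              seed=4)
        assert len(truth) == 3
        for rec in truth:
            assert rec.age_k == 0.0
            contig = genomes[rec.species][rec.contig]
            elem = contig[rec.start:rec.end]
            if rec.strand == "-":
                elem = revcomp(elem)
            assert elem == master.full_sequence
            assert contig[rec.start - 2:rec.start] == "TA"
            assert contig[rec.end:rec.end + 2] == "TA"

    def test_deterministic_under_seed(self):
        tree, master, cfg = self._quick()
        events = [InvasionEvent(recipients=("a", "b"), time_ma=60.0,
                                copies=4)]
        out1 = simulate_invasion(tree, master, events, cfg, seed=9)
        out2 = simulate_invasion(tree, master, events, cfg, seed=9)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]
        assert out1[2].to_frame().equals(out2[2].to_frame())

    def test_zero_copy_species_in_genomes_not_ledger(self):
        tree, master, cfg = self._quick()
        events = [InvasionEvent(recipients=("a",), time_ma=10.0, copies=2)]
        genomes, _, truth = simulate_invasion(tree, master, events, cfg,
                                              seed=1)
        assert set(genomes) == {"a", "b", "c", "d"}
        assert {r.species for r in truth} == {"a"}

    def test_unknown_recipient_rejected(self):
        tree, master, cfg = self._quick()
        events = [InvasionEvent(recipients=("zz",), time_ma=10.0, copies=1)]
        with pytest.raises(KeyError):
            simulate_invasion(tree, master, events, cfg, seed=0)

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            InvasionEvent(recipients=("a",), time_ma=10.0, copies=-1)

    def test_vertical_te_distance_tracks_host_scaled_by_rate_ratio(self):
        """Two species split 20 Ma carrying a vertically inherited element:
        cross-species TE distance ~ 2*te_rate*20, host distance ~ 0.3x."""
        from temine.divergence import k2p_from_pair

        tree, master, cfg = self._quick()
        events = [InvasionEvent(recipients=("a", "b"), time_ma=60.0,
                                copies=3, burst_time_ma=18.0)]
        d_te, d_host = [], []
        for seed in range(6):
            genomes, hosts, truth = simulate_invasion(
                tree, master, events, cfg, seed=seed)
            rec_a = truth.for_species("a")[0]
            rec_b = truth.for_species("b")[0]

            def seq_of(rec):
                s = genomes[rec.species][rec.contig][rec.start:rec.end]
                return revcomp(s) if rec.strand == "-" else s

            d_te.append(k2p_from_pair(seq_of(rec_a), seq_of(rec_b)))
            d_host.append(k2p_from_pair(hosts["a"], hosts["b"]))
        # expected: TE 2*1.4e-3*20 = 0.056 (purifying selection on the
        # active lineage drags it somewhat lower); host 0.3x that rate
        assert 0.02 < np.mean(d_te) < 0.07
        assert np.mean(d_host) == pytest.approx(
            2 * 0.3 * cfg.te_rate * 20.0, rel=0.6)

    def test_ht_te_distance_far_below_host_distance(self):
        from temine.divergence import k2p_from_pair

        tree, master, cfg = self._quick()
        events = [InvasionEvent(recipients=("a", "c"), time_ma=5.0,
                                copies=3, kind="ht", label="ht1")]
        genomes, hosts, truth = simulate_invasion(tree, master, events,
                                                  cfg, seed=3)
        rec_a = truth.for_species("a")[0]
        rec_c = truth.for_species("c")[0]

        def seq_of(rec):
            s = genomes[rec.species][rec.contig][rec.start:rec.end]
            return revcomp(s) if rec.strand == "-" else s

        d_te = k2p_from_pair(seq_of(rec_a), seq_of(rec_c))
        d_host = k2p_from_pair(hosts["a"], hosts["c"])
        assert d_te < 0.05
        assert d_host > 0.2
        assert d_te < 0.25 * d_host

    def test_truth_ledger_coordinates_valid(self):
        tree, master, cfg = self._quick()
        cfg.p_trunc = 0.5
        events = [InvasionEvent(recipients=("a", "b", "c", "d"),
                                time_ma=400.0, copies=5)]
        genomes, _, truth = simulate_invasion(tree, master, events, cfg,
                                              seed=11)
        for rec in truth:
            contig = genomes[rec.species][rec.contig]
            assert 0 <= rec.start < rec.end <= len(contig)
            assert rec.age_k >= 0
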