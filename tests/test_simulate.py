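"""Synthetic-data generator: sequences, states, digestion, determinism."""

import numpy as np
import pytest

from credra.genotoxicity import genotox_table
from credra.methylation import LaneTriplet, MethylationType, classify_band
from credra.simulate import (
    AmpliconSeq,
    SimConfig,
    STATE_TO_TYPE,
    STATES,
    SyntheticTruth,
    assign_states,
    digest_and_band,
    generate_amplicons,
    simulate,
)


def small_cfg(**kw) -> SimConfig:
    defaults = dict(n_primers=2, bands_per_primer=5, doses=(0.0, 20.0), seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


def zero_mutation(doses):
    return {
        "band_loss_prob": {d: 0.0 for d in doses},
        "band_gain_rate": {d: 0.0 for d in doses},
    }


def degenerate_probs(doses, state):
    i = STATES.index(state)
    v = tuple(1.0 if j == i else 0.0 for j in range(4))
    return {d: v for d in doses}


class TestAmplicons:
    def test_exact_site_count_and_registered_offsets(self):
        for k in (1, 3):
            cfg = small_cfg(sites_per_amplicon=k)
            amps = generate_amplicons(cfg, np.random.default_rng(0))
            assert len(amps) == 10
            for a in amps:
                assert a.sequence.count("CCGG") == k
                assert len(a.ccgg_offsets) == k
                for off in a.ccgg_offsets:
                    assert a.sequence[off : off + 4] == "CCGG"
                assert 100 <= len(a.sequence) <= 1000
                assert set(a.sequence) <= set("ACGT")

    def test_deterministic_given_seed(self):
        cfg = small_cfg()
        a1 = generate_amplicons(cfg, np.random.default_rng(5))
        a2 = generate_amplicons(cfg, np.random.default_rng(5))
        assert a1 == a2

    def test_zero_bands_gives_empty_list(self):
        cfg = small_cfg(bands_per_primer=0)
        assert generate_amplicons(cfg, np.random.default_rng(0)) == []

    def test_unregistered_motif_rejected(self):
        with pytest.raises(ValueError):
            AmpliconSeq("P", "b", "ACCGGT" * 20, ())


class TestStates:
    def test_degenerate_distributions(self):
        for state in ("FF", "U"):
            cfg = small_cfg(
                state_probs=degenerate_probs((0.0, 20.0), state),
                **zero_mutation((0.0, 20.0)),
            )
            rng = np.random.default_rng(3)
            amps = generate_amplicons(cfg, rng)
            truth = assign_states(cfg, amps, rng)
            assert all(set(v) == {state} for v in truth.states.values())

    def test_empirical_frequencies_match_configured_vector(self):
        """10,000 site draws per dose stay within 3 binomial SE per state."""
        probs = (0.10, 0.20, 0.30, 0.40)
        cfg = SimConfig(
            n_primers=10,
            bands_per_primer=1000,
            doses=(0.0, 20.0),
            state_probs={0.0: probs, 20.0: probs},
            **zero_mutation((0.0, 20.0)),
            seed=17,
        )
        rng = np.random.default_rng(cfg.seed)
        amps = generate_amplicons(cfg, rng)
        truth = assign_states(cfg, amps, rng)
        draws = [truth.states[("Cu20", a.primer, a.band_id)][0] for a in amps]
        n = len(draws)
        assert n == 10000
        for state, p in zip(STATES, probs):
            freq = draws.count(state) / n
            se = (p * (1 - p) / n) ** 0.5
            assert abs(freq - p) <= 3 * se


class TestDigestion:
    @pytest.mark.parametrize(
        "state, triplet, mtype",
        [
            ("U", (1, 0, 0), MethylationType.I),
            ("HE", (1, 0, 1), MethylationType.II),
            ("IF", (1, 1, 0), MethylationType.III),
            ("FF", (1, 1, 1), MethylationType.IV),
        ],
    )
    def test_single_site_state_reads_out_as_its_type(self, state, triplet, mtype):
        doses = (0.0, 20.0)
        cfg = small_cfg(
            n_primers=1,
            bands_per_primer=1,
            state_probs=degenerate_probs(doses, state),
            **zero_mutation(doses),
        )
        rng = np.random.default_rng(1)
        amps = generate_amplicons(cfg, rng)
        truth = assign_states(cfg, amps, rng)
        m = digest_and_band(truth, amps, cfg)
        key = (amps[0].primer, amps[0].band_id)
        bits = tuple(m.get(key, "Cu20", lane) for lane in ("X", "H", "M"))
        assert bits == triplet
        assert classify_band(LaneTriplet(*bits)) is mtype
        assert STATE_TO_TYPE[state] is mtype

    def test_any_cleavable_site_kills_both_digested_lanes(self):
        """Two sites with states {U, FF}: each enzyme cuts somewhere."""
        doses = (0.0, 20.0)
        cfg = small_cfg(
            n_primers=1, bands_per_primer=1, sites_per_amplicon=2,
            **zero_mutation(doses),
        )
        rng = np.random.default_rng(2)
        amps = generate_amplicons(cfg, rng)
        truth = SyntheticTruth(
            states={
                (cfg.sample_id(d), amps[0].primer, amps[0].band_id): ("U", "FF")
                for d in doses
            }
        )
        m = digest_and_band(truth, amps, cfg)
        key = (amps[0].primer, amps[0].band_id)
        assert m.get(key, "Cu20", "X") == 1
        assert m.get(key, "Cu20", "H") == 0
        assert m.get(key, "Cu20", "M") == 0


class TestPipeline:
    def test_zero_mutation_limit_gives_gts_100(self):
        doses = (0.0, 20.0, 40.0)
        cfg = SimConfig(
            n_primers=3, bands_per_primer=4, doses=doses,
            **zero_mutation(doses), seed=9,
        )
        rng = np.random.default_rng(cfg.seed)
        amps = generate_amplicons(cfg, rng)
        truth = assign_states(cfg, amps, rng)
        m = digest_and_band(truth, amps, cfg)
        for r in genotox_table(m.rapd_view()):
            assert r.gts_percent == 100.0

    def test_simulate_writes_valid_deterministic_artifacts(self, tmp_path):
        from credra.profiles_io import read_band_matrix

        cfg = small_cfg(seed=21)
        p1 = simulate(cfg, tmp_path / "run1")
        p2 = simulate(cfg, tmp_path / "run2")
        for name in ("credra", "rapd", "truth", "amplicons"):
            assert p1[name].exists()
            assert p1[name].read_bytes() == p2[name].read_bytes()
        m = read_band_matrix(p1["credra"])
        assert m.assay == "CREDRA"
        assert read_band_matrix(p1["rapd"]).assay == "RAPD"

    def test_seed_changes_pattern_not_shape(self, tmp_path):
        from credra.profiles_io import read_band_matrix

        doses = (0.0, 20.0)
        base = dict(n_primers=2, bands_per_primer=8, doses=doses, **zero_mutation(doses))
        m1 = read_band_matrix(simulate(SimConfig(**base, seed=1), tmp_path / "a")["credra"])
        m2 = read_band_matrix(simulate(SimConfig(**base, seed=2), tmp_path / "b")["credra"])
        assert m1.presence.shape == m2.presence.shape
        assert not m1.presence.equals(m2.presence)

    def test_classifier_recovers_drawn_state_exactly(self):
        """Single-site, zero-mutation: state -> type is a bijection."""
        doses = (0.0, 20.0, 160.0)
        cfg = SimConfig(
            n_primers=4, bands_per_primer=10, doses=doses,
            **zero_mutation(doses), seed=33,
        )
        rng = np.random.default_rng(cfg.seed)
        amps = generate_amplicons(cfg, rng)
        truth = assign_states(cfg, amps, rng)
        m = digest_and_band(truth, amps, cfg)
        for s in m.samples:
            for a in amps:
                bits = tuple(
                    m.get((a.primer, a.band_id), s.sample_id, lane)
                    for lane in ("X", "H", "M")
                )
                drawn = truth.states[(s.sample_id, a.primer, a.band_id)][0]
                assert classify_band(LaneTriplet(*bits)) is STATE_TO_TYPE[drawn]


class TestConfigValidation:
    def test_state_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_cfg(state_probs={0.0: (0.5, 0.2, 0.2, 0.2), 20.0: (1, 0, 0, 0)})

    def test_missing_dose_entry_rejected(self):
        with pytest.raises(ValueError, match="band_loss_prob"):
            small_cfg(band_loss_prob={0.0: 0.0}, band_gain_rate={0.0: 0.0, 20.0: 0.0})

    def test_exactly_one_control_dose(self):
        with pytest.raises(ValueError, match="dose"):
            SimConfig(doses=(20.0, 40.0))

    def test_default_calibration_needs_known_doses(self):
        with pytest.raises(ValueError, match="reference"):
            SimConfig(doses=(0.0, 33.0))

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = small_cfg(seed=5)
        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        again = SimConfig.from_yaml(p)
        assert again.to_dict() == cfg.to_dict()
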