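"""Unit tests for the capture -> Myc -> division-budget chain and SHM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmat.config import AffinitySite, SimulationConfig
from pcmat.model import (
    LETHAL,
    OK,
    antigen_capture,
    division_budget,
    mutate_chains,
    myc_level,
)


class TestAntigenCapture:
    @pytest.mark.parametrize(
        "affinity,cmax,K,expected",
        [
            (0.0, 1.0, 1.0, 0.0),
            (1.0, 1.0, 1.0, 0.5),  # half-saturation at affinity == K
            (3.0, 2.0, 1.0, 1.5),
            (4.0, 1.0, 4.0, 0.5),
        ],
    )
    def test_values(self, affinity, cmax, K, expected):
        assert antigen_capture(affinity, cmax, K) == pytest.approx(expected)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            antigen_capture(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            antigen_capture(1.0, 1.0, -2.0)
        with pytest.raises(ValueError):
            antigen_capture(-1.0, 1.0, 1.0)

    @given(st.floats(min_value=0.0, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, affinity):
        c = antigen_capture(affinity, 2.0, 3.0)
        assert 0.0 <= c < 2.0
        assert antigen_capture(affinity + 1.0, 2.0, 3.0) > c


class TestMycLevel:
    def test_intercept_and_slope(self):
        assert myc_level(0.0, 0.2, 1.0) == pytest.approx(0.2)
        assert myc_level(2.0, 1.0, 1.0) == pytest.approx(3.0)

    def test_decoupled_control(self):
        # k = 0 is the null used to break the affinity-division coupling
        for captured in (0.0, 0.3, 5.0):
            assert myc_level(captured, 0.7, 0.0) == pytest.approx(0.7)


class TestDivisionBudget:
    def test_deterministic_examples(self):
        assert division_budget(3.0, 1.0, 1.0, mode="deterministic") == 3
        assert division_budget(5.0, 0.0, 1.0, mode="deterministic") == 0
        assert division_budget(1.24, 2.0, 1.0, mode="deterministic") == 2

    def test_poisson_mean(self):
        rng = np.random.default_rng(0)
        draws = [
            division_budget(2.0, 1.0, 1.0, mode="poisson", rng=rng)
            for _ in range(100_000)
        ]
        assert np.mean(draws) == pytest.approx(2.0, abs=0.05)

    def test_cap(self):
        assert division_budget(100.0, 1.0, 1.0, mode="deterministic", cap=6) == 6

    def test_errors(self):
        with pytest.raises(ValueError):
            division_budget(1.0, 1.0, 1.0, mode="bogus")
        with pytest.raises(ValueError):
            division_budget(1.0, 1.0, 1.0, mode="poisson")  # rng required
        with pytest.raises(ValueError):
            division_budget(-1.0, 1.0, 1.0)


def _site_only_config(**kw):
    """Config whose only mutable position is heavy site 33 (W->L, x8)."""
    defaults = dict(
        mutation_rate=1.0,
        affinity_site_table=(AffinitySite("heavy", 33, "W", "L", 8.0),),
        hotspot_weight=1e9,
        site_target_bias=1.0,
        lethal_fraction=0.0,
        deleterious_fraction=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestMutateChains:
    def test_no_mutation_limit(self):
        cfg = SimulationConfig(mutation_rate=0.0)
        rng = np.random.default_rng(0)
        out = mutate_chains("WAY", "KAY", 1.5, cfg, rng)
        assert (out.heavy_seq, out.light_seq) == ("WAY", "KAY")
        assert out.affinity == 1.5
        assert out.fate == OK
        assert out.events == ()

    def test_forced_affinity_site_multiplies(self):
        from pcmat.germline import germline_of

        cfg = _site_only_config()
        heavy = germline_of("IGHV1-72*01")
        light = germline_of("IGKV4-53*01")
        rng = np.random.default_rng(1)
        out = mutate_chains(heavy, light, 3.0, cfg, rng)
        assert ("heavy", 33, "W", "L") in out.events
        assert out.heavy_seq[32] == "L"
        assert out.affinity == pytest.approx(24.0)  # x8, light mutation neutral
        assert out.fate == OK

    def test_germline_untouched_and_lengths_preserved(self):
        from pcmat.germline import germline_of

        cfg = SimulationConfig(mutation_rate=1.0)
        heavy = germline_of("IGHV1-72*01")
        before = heavy
        rng = np.random.default_rng(2)
        out = mutate_chains(heavy, germline_of("IGKV4-53*01"), 1.0, cfg, rng)
        assert germline_of("IGHV1-72*01") == before
        assert len(out.heavy_seq) == len(heavy)

    def test_mutated_fraction_matches_rate(self):
        cfg = SimulationConfig(mutation_rate=0.3, lethal_fraction=0.0,
                               deleterious_fraction=0.0)
        rng = np.random.default_rng(3)
        n = 10_000
        heavy_hits = 0
        for _ in range(n):
            out = mutate_chains("WAYKQ" * 10, "KAYWQ" * 10, 1.0, cfg, rng)
            heavy_hits += any(e[0] == "heavy" for e in out.events)
        assert heavy_hits / n == pytest.approx(0.3, abs=0.02)

    def test_lethal_fraction(self):
        cfg = SimulationConfig(
            mutation_rate=1.0, lethal_fraction=1.0, deleterious_fraction=0.0,
            affinity_site_table=(),  # all substitutions non-designated
        )
        # empty site table is allowed at the model level; only the flagging
        # operation requires a non-empty site set
        rng = np.random.default_rng(4)
        out = mutate_chains("WAYKQ" * 10, "KAYWQ" * 10, 1.0, cfg, rng)
        assert out.fate == LETHAL

    def test_deleterious_factor(self):
        cfg = SimulationConfig(
            mutation_rate=1.0, lethal_fraction=0.0, deleterious_fraction=1.0,
            deleterious_factor=0.7, affinity_site_table=(),
        )
        rng = np.random.default_rng(5)
        out = mutate_chains("WAYKQ" * 10, "KAYWQ" * 10, 1.0, cfg, rng)
        # both chains mutate, each multiplying by 0.7
        n_events = len(out.events)
        assert out.affinity == pytest.approx(0.7 ** n_events)
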