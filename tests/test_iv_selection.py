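"""Instrument selection: p-screen, greedy LD clumping, strength statistics."""

import itertools

import numpy as np
import pytest

from medimr.iv_selection import (
    InstrumentSet,
    LDInfo,
    add_instrument_strength,
    exclude_confounders,
    filter_pvalue,
    instrument_strength,
    ld_clump,
    select_instruments,
)
from medimr.sumstats import ConfigError, InputError

from conftest import make_table


def _row(vid, chrom, pos, p, beta=0.1, se=0.01):
    return (vid, chrom, pos, "A", "G", 0.3, beta, se, p)


class TestFilterPvalue:
    def test_threshold_filters_strictly(self):
        table = make_table(
            [_row("rs1", "1", 1, 2e-6), _row("rs2", "1", 2, 5e-5), _row("rs3", "1", 3, 1e-8)]
        )
        kept = filter_pvalue(table, 1e-5)
        assert list(kept.records["variant_id"]) == ["rs1", "rs3"]  # order preserved

    def test_threshold_one_keeps_all(self):
        table = make_table([_row("rs1", "1", 1, 0.5), _row("rs2", "1", 2, 0.99)])
        assert len(filter_pvalue(table, 1.0)) == 2

    def test_empty_in_empty_out(self):
        table = make_table([_row("rs1", "1", 1, 0.5)])
        assert len(filter_pvalue(table, 1e-10)) == 0


def brute_force_clump(records, ld, r2_max, window_kb):
    """Independent greedy oracle on (vid, chrom, pos, p) tuples."""
    remaining = sorted(records, key=lambda r: (r[3], r[0]))
    retained = []
    while remaining:
        index = remaining.pop(0)
        retained.append(index[0])
        remaining = [
            r for r in remaining
            if not (
                r[1] == index[1]
                and abs(r[2] - index[2]) <= window_kb * 1000
                and ld.get(index[0], r[0]) >= r2_max
            )
        ]
    return retained


class TestLDClump:
    def test_correlated_pair_keeps_best_p(self):
        table = make_table([_row("rs1", "1", 10_000, 1e-8), _row("rs2", "1", 20_000, 1e-6)])
        ld = LDInfo.from_pairs([("rs1", "rs2", 0.5)])
        kept = ld_clump(table, ld, r2_max=0.001, window_kb=500)
        assert list(kept.records["variant_id"]) == ["rs1"]

    def test_outside_window_both_kept(self):
        table = make_table([_row("rs1", "1", 0, 1e-8), _row("rs2", "1", 600_000, 1e-6)])
        ld = LDInfo.from_pairs([("rs1", "rs2", 0.9)])
        assert len(ld_clump(table, ld, window_kb=500)) == 2

    def test_cross_chromosome_never_clumped(self):
        table = make_table([_row("rs1", "1", 1000, 1e-8), _row("rs2", "2", 2000, 1e-6)])
        ld = LDInfo.from_pairs([("rs1", "rs2", 1.0)])
        assert len(ld_clump(table, ld)) == 2

    def test_empty_ld_is_identity(self):
        table = make_table([_row(f"rs{i}", "1", i * 1000, 1e-6 / (i + 1)) for i in range(5)])
        assert set(ld_clump(table, LDInfo()).records["variant_id"]) == set(
            table.records["variant_id"]
        )

    def test_missing_position_errors(self):
        table = make_table([_row("rs1", "1", 1000, 1e-8)])
        table.records.loc[0, "position"] = np.nan
        with pytest.raises(InputError, match="rs1"):
            ld_clump(table, LDInfo())

    def test_matches_brute_force_oracle_on_random_chains(self, rng):
        """Greedy retention equals an independently coded oracle across
        random LD chains, and is invariant to input record order."""
        for trial in range(20):
            n = 6
            recs = [
                (f"rs{i}", "1", int(rng.integers(0, 300_000)), float(rng.uniform(1e-9, 1e-5)))
                for i in range(n)
            ]
            ld = LDInfo()
            for a, b in itertools.combinations(range(n), 2):
                if rng.random() < 0.5:
                    ld.set(f"rs{a}", f"rs{b}", float(rng.uniform(0, 1)))
            expected = brute_force_clump(recs, ld, 0.1, 100)
            table = make_table([_row(v, c, pos, p) for v, c, pos, p in recs])
            got = ld_clump(table, ld, r2_max=0.1, window_kb=100)
            assert list(got.records["variant_id"]) == expected
            # input-order invariance
            perm = rng.permutation(n)
            shuffled = make_table([_row(*recs[i][:3], recs[i][3]) for i in perm])
            got2 = ld_clump(shuffled, ld, r2_max=0.1, window_kb=100)
            assert list(got2.records["variant_id"]) == expected

    def test_retained_pairs_satisfy_thresholds(self, rng):
        n = 8
        recs = [(f"rs{i}", "1", i * 30_000, float(rng.uniform(1e-9, 1e-5))) for i in range(n)]
        ld = LDInfo()
        for a, b in itertools.combinations(range(n), 2):
            ld.set(f"rs{a}", f"rs{b}", float(rng.uniform(0, 0.5)))
        table = make_table([_row(*r[:3], r[3]) for r in recs])
        kept = ld_clump(table, ld, r2_max=0.2, window_kb=100)
        pos = dict(zip(kept.records["variant_id"], kept.records["position"]))
        for a, b in itertools.combinations(pos, 2):
            assert ld.get(a, b) < 0.2 or abs(pos[a] - pos[b]) > 100_000


class TestInstrumentStrength:
    def test_closed_forms_match_hand_arithmetic(self):
        # independent arithmetic: pve = 0.01/(0.01 + 10000*0.0004) = 0.01/4.01
        pve, f, weak = instrument_strength(0.1, 0.02, 10_000)
        pve_hand = 0.01 / (0.01 + 10_000 * 0.02**2)
        f_hand = pve_hand * 9998 / (1 - pve_hand)
        assert pve == pytest.approx(pve_hand, abs=1e-15)
        assert f == pytest.approx(f_hand, abs=1e-10)
        assert pve == pytest.approx(0.002494, abs=5e-7)
        assert f == pytest.approx(24.99, abs=0.01)
        assert not weak

    def test_zero_beta_is_weak(self):
        pve, f, weak = instrument_strength(0.0, 0.02, 10_000)
        assert pve == 0.0 and f == 0.0 and weak

    def test_f_exactly_ten_is_weak(self):
        # this (beta, se, n) evaluates to f_stat == 10.0 in float arithmetic
        pve, f, weak = instrument_strength(0.125, 0.03608439182435161, 12)
        assert f == 10.0
        assert weak  # strict > 10 requirement

    def test_monotonicity_in_beta_and_pve(self):
        pves, fs = [], []
        for beta in (0.05, 0.1, 0.2, 0.4):
            pve, f, _ = instrument_strength(beta, 0.02, 10_000)
            pves.append(pve)
            fs.append(f)
        assert np.all(np.diff(pves) > 0)
        assert np.all(np.diff(fs) > 0)

    def test_eaf_formula_and_missing_eaf_error(self):
        pve, _, _ = instrument_strength(0.1, 0.02, 10_000, eaf=0.3, pve_formula="eaf")
        assert pve == pytest.approx(2 * 0.01 * 0.3 * 0.7)
        with pytest.raises(ConfigError):
            instrument_strength(0.1, 0.02, 10_000, pve_formula="eaf")

    def test_wald_f_formula(self):
        _, f, _ = instrument_strength(0.1, 0.02, 10_000, f_formula="wald")
        assert f == pytest.approx((0.1 / 0.02) ** 2)

    def test_small_n_is_config_error(self):
        with pytest.raises(ConfigError):
            instrument_strength(0.1, 0.02, 2)

    def test_table_level_fallback_n(self):
        table = make_table([_row("rs1", "1", 1, 1e-8)], sample_size=18340)
        table.records["n"] = np.nan
        df = add_instrument_strength(table)
        assert df.at[0, "f_stat"] > 10


class TestExcludeConfounders:
    def _instruments(self):
        table = make_table([_row("rs1", "1", 1, 1e-8), _row("rs2", "1", 900_000, 1e-7)])
        df = add_instrument_strength(table)
        return InstrumentSet("gm1", df)

    def test_listed_variant_removed(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="medimr"):
            kept = exclude_confounders(self._instruments(), [("rs2", "alcohol consumption")])
        assert list(kept.records["variant_id"]) == ["rs1"]
        assert any("rs2" in m and "alcohol" in m for m in caplog.messages)

    def test_empty_exclusions_identity(self):
        inst = self._instruments()
        assert len(exclude_confounders(inst, [])) == 2

    def test_absent_id_ignored(self):
        assert len(exclude_confounders(self._instruments(), [("rs9", "viral hepatitis")])) == 2


def test_select_instruments_cascade(rng):
    """Full selection: significance screen, clumping, weak-instrument drop."""
    rows = [
        _row("rs1", "1", 10_000, 1e-9, beta=0.30),   # strong index
        _row("rs2", "1", 30_000, 1e-7, beta=0.25),   # clumped with rs1
        _row("rs3", "2", 10_000, 1e-8, beta=0.28),   # independent keeper
        _row("rs4", "3", 10_000, 1e-3, beta=0.10),   # fails p threshold
        # reported p passes the screen but beta/se imply F ~ 4: weak
        _row("rs5", "4", 10_000, 5e-6, beta=0.003, se=0.0015),
    ]
    table = make_table(rows, sample_size=18340)
    ld = LDInfo.from_pairs([("rs1", "rs2", 0.9)])
    selected = select_instruments(table, ld, n=18340)
    assert set(selected.records["variant_id"]) == {"rs1", "rs3"}
    assert (selected.records["f_stat"] > 10).all()
    assert selected.provenance["p_threshold"] == 1e-5
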