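"""miRNA proxy, seed matching, degradation model, differential editing."""

import numpy as np
import pandas as pd
import pytest

from editqtl.mirna import (
    MirnaRecord,
    SimScenario,
    degradation_model,
    diff_editing_scan,
    diff_editing_test,
    editing_specific_target,
    normalize_rna,
    proxy_expression,
    revcomp_rna,
    run_scenario,
    seed_match,
    simulate_qtl_panels,
)
from editqtl.qtl import nonlinearity, ols_assoc

MIR = MirnaRecord(name="mir-test", seq="UAGCUUAUCAGACUGAUGUUGA")


def brute_force_seed_scan(target, mirna):
    """Independent sliding-window reimplementation of the site rules."""
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    t = normalize_rna(target)
    m = mirna.seq
    seed7 = "".join(comp[c] for c in m[1:8])[::-1]
    seed6 = "".join(comp[c] for c in m[1:7])[::-1]
    out = []
    for i in range(len(t) - 6):
        w7 = t[i : i + 7]
        if w7 == seed7:
            if i + 7 < len(t) and t[i + 7] == "A":
                out.append(("8mer", i + 1, i + 8))
            else:
                out.append(("7mer-m8", i + 1, i + 7))
        elif t[i : i + 6] == seed6 and i + 6 < len(t) and t[i + 6] == "A":
            out.append(("7mer-A1", i + 1, i + 7))
    return out


class TestProxy:
    def test_single_sample_is_one(self):
        assert proxy_expression([5], [1_000_000])[0] == pytest.approx(1.0)

    def test_rates_arithmetic(self):
        p = proxy_expression([2, 1], [1_000_000, 1_000_000])
        assert np.allclose(p, [1.0, 0.5])

    def test_scale_invariance(self):
        p1 = proxy_expression([3, 7, 2], [1e6, 2e6, 5e5])
        p2 = proxy_expression([6, 14, 4], [2e6, 4e6, 1e6])
        assert np.allclose(p1, p2)

    def test_all_zero_flagged_as_zeros(self):
        assert np.all(proxy_expression([0, 0], [1e6, 1e6]) == 0)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            proxy_expression([1], [0])


class TestSeedMatch:
    def test_8mer_definition(self):
        target = "CCCC" + revcomp_rna(MIR.seq[1:8]) + "A" + "CCCC"
        matches = seed_match(target, MIR)
        assert any(m.match_type == "8mer" and m.start == 5 for m in matches)

    def test_7mer_m8_without_adjacent_a(self):
        target = "CCCC" + revcomp_rna(MIR.seq[1:8]) + "C" + "CCCC"
        matches = seed_match(target, MIR)
        assert [m.match_type for m in matches] == ["7mer-m8"]

    def test_7mer_a1(self):
        target = "CCCC" + revcomp_rna(MIR.seq[1:7]) + "A" + "CCCC"
        matches = seed_match(target, MIR)
        assert [m.match_type for m in matches] == ["7mer-A1"]

    def test_antisense_complement_not_matched(self):
        # the seed itself (not its reverse complement) must not match
        target = "CCCC" + MIR.seq[1:8] + "ACCCC"
        assert seed_match(target, MIR) == []

    def test_t_mapped_to_u(self):
        target = ("CCCC" + revcomp_rna(MIR.seq[1:8]) + "A").replace("U", "T")
        assert any(m.match_type == "8mer" for m in seed_match(target, MIR))

    def test_fuzz_against_bruteforce(self, rng):
        """Scanner equals an independent sliding-window oracle on random
        sequences seeded with occasional true sites."""
        site = revcomp_rna(MIR.seq[1:8]) + "A"
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGU"), size=60))
            if rng.random() < 0.5:
                k = int(rng.integers(0, 50))
                seq = seq[:k] + site + seq[k + len(site):]
            got = [(m.match_type, m.start, m.end) for m in seed_match(seq, MIR)]
            assert got == brute_force_seed_scan(seq, MIR)


class TestEditingSpecificTarget:
    def test_unedited_only_dhfr_pattern(self):
        """Seed complement needs an A at the edited spot: editing destroys it."""
        site8 = revcomp_rna(MIR.seq[1:8]) + "A"
        k = site8.index("A")
        utr = "CCCC" + site8 + "CCCC"
        cls = editing_specific_target(utr, 5 + k, MIR)
        assert cls.version == "unedited"

    def test_edited_only_rpl13_pattern(self):
        """Seed complement needs a G there: only the edited mRNA matches."""
        site8 = revcomp_rna(MIR.seq[1:8]) + "A"
        k = site8.index("G")
        broken = site8[:k] + "A" + site8[k + 1 :]
        utr = "CCCC" + broken + "CCCC"
        cls = editing_specific_target(utr, 5 + k, MIR)
        assert cls.version == "edited"

    def test_match_away_from_site_is_both(self):
        site8 = revcomp_rna(MIR.seq[1:8]) + "A"
        utr = site8 + "CCCCCCCCCCACCCC"
        edit_pos = len(site8) + 11  # the lone A far from the match
        cls = editing_specific_target(utr, edit_pos, MIR)
        assert cls.version == "both"

    def test_no_match_is_neither(self):
        cls = editing_specific_target("CCCCCCACCCCCC", 7, MIR)
        assert cls.version == "neither"

    def test_non_a_reference_rejected(self):
        with pytest.raises(ValueError):
            editing_specific_target("CCCCCCGCCCCCC", 7, MIR)


class TestDegradationModel:
    def test_d_zero_identity(self):
        res = run_scenario(SimScenario((0.1, 0.3, 0.5), d=0.0))
        assert np.allclose(res.phi_observed, [0.1, 0.3, 0.5])
        assert np.allclose(res.expression, 1.0)

    def test_closed_form_unedited(self):
        phi_p, e = degradation_model(0.5, 0.8, "unedited")
        assert e == pytest.approx(0.6)
        assert phi_p == pytest.approx(0.5 / 0.6)

    def test_direction_of_expression_across_genotypes(self):
        res_u = run_scenario(SimScenario((0.1, 0.3, 0.5), d=0.8, target_version="unedited"))
        assert np.allclose(res_u.expression, [0.28, 0.44, 0.60])
        assert np.all(np.diff(res_u.expression) > 0)  # same direction as edQTL
        res_e = run_scenario(SimScenario((0.1, 0.3, 0.5), d=0.8, target_version="edited"))
        assert np.all(np.diff(res_e.expression) < 0)  # opposite direction

    def test_conservation_identity_fuzz(self, rng):
        """Phi' * E equals the surviving edited fraction for either target."""
        phi = rng.random(500)
        d = rng.random(500)
        for i in range(500):
            pp, e = degradation_model(phi[i], d[i], "unedited")
            assert pp * e == pytest.approx(phi[i], rel=1e-12, abs=1e-15)
            pp, e = degradation_model(phi[i], d[i], "edited")
            assert pp * e == pytest.approx((1 - d[i]) * phi[i], rel=1e-12, abs=1e-15)

    def test_phi_prime_monotone_in_phi(self):
        grid = np.linspace(0, 1, 101)
        for target in ("unedited", "edited"):
            pp, _ = degradation_model(grid, 0.8, target)
            assert np.all(np.diff(pp) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            degradation_model(0.5, 1.2)
        with pytest.raises(ValueError):
            degradation_model(1.5, 0.5)
        with pytest.raises(ValueError):
            SimScenario((0.1, 0.2, 0.3), d=-0.1)


class TestQtlPanels:
    def test_d_zero_eqtl_null(self):
        nulls = 0
        for rep in range(20):
            df = simulate_qtl_panels(
                SimScenario((0.1, 0.3, 0.5), d=0.0), rng=rep
            )
            _, _, p, _, _ = ols_assoc(df["expression"], df["dosage"])
            nulls += p > 0.05
        assert nulls >= 17

    def test_d_08_unedited_creates_positive_eqtl_and_shift(self):
        hits = 0
        for rep in range(20):
            df = simulate_qtl_panels(
                SimScenario((0.1, 0.3, 0.5), d=0.8, target_version="unedited"),
                rng=100 + rep,
            )
            slope, _, p, _, _ = ols_assoc(df["expression"], df["dosage"])
            nl = nonlinearity(df["phi"].to_numpy(), df["dosage"].to_numpy())
            hits += (slope > 0) and (p < 0.05) and (nl.shift > 0)
        assert hits >= 19

    def test_d_08_edited_flips_eqtl_sign(self):
        hits = 0
        for rep in range(20):
            df = simulate_qtl_panels(
                SimScenario((0.1, 0.3, 0.5), d=0.8, target_version="edited"),
                rng=200 + rep,
            )
            slope_e, _, _, _, _ = ols_assoc(df["expression"], df["dosage"])
            slope_phi, _, _, _, _ = ols_assoc(df["phi"], df["dosage"])
            hits += np.sign(slope_e) == -np.sign(slope_phi)
        assert hits >= 19


class TestDiffEditing:
    def test_identical_tables_null(self):
        r = diff_editing_test([(20, 100)] * 3, [(20, 100)] * 3)
        assert r.delta_phi == 0.0 and r.p == pytest.approx(1.0)

    def test_strong_change_detected(self):
        r = diff_editing_test([(20, 100)] * 3, [(50, 100)] * 3)
        assert r.delta_phi == pytest.approx(0.30)
        assert r.p < 1e-6

    def test_condition_swap_symmetry(self):
        a = [(20, 100), (25, 100)]
        b = [(35, 100), (40, 100)]
        r1 = diff_editing_test(a, b)
        r2 = diff_editing_test(b, a)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)
        assert r1.delta_phi == pytest.approx(-r2.delta_phi)

    def test_zero_reads_untestable(self):
        r = diff_editing_test([(0, 0)], [(5, 10)])
        assert r.status == "untestable"

    def test_effect_size_gate_blocks_small_delta(self):
        """A 4% shift at enormous depth: tiny p but below the 5% gate."""
        table = pd.DataFrame(
            {
                "site": ["s"] * 6,
                "condition": ["control"] * 3 + ["experiment"] * 3,
                "g": [2000, 2000, 2000, 2400, 2400, 2400],
                "n": [10000] * 6,
            }
        )
        out = diff_editing_scan(table)
        assert out.iloc[0]["delta_phi"] == pytest.approx(0.04)
        assert out.iloc[0]["q"] < 0.05
        assert not bool(out.iloc[0]["significant"])

    def test_scan_gates_and_fdr(self):
        rows = []
        for k, (pc, pe) in enumerate([(0.2, 0.2), (0.2, 0.45), (0.3, 0.3)]):
            for ci, (cond, pp) in enumerate((("control", pc), ("experiment", pe))):
                r = np.random.default_rng(10 * k + ci)
                for rep in range(3):
                    g = r.binomial(200, pp)
                    rows.append((f"s{k}", cond, g, 200))
        table = pd.DataFrame(rows, columns=["site", "condition", "g", "n"])
        out = diff_editing_scan(table)
        sig = set(out[out["significant"]]["site"])
        assert sig == {"s1"}
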