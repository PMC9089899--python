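"""UPD caller: evidence assembly oracles, the four decision gates, mode
assignment, nomenclature, gate monotonicity, and parameter recovery over a
mixed scenario panel."""
import numpy as np
import pytest

from updtrio.classify import classify_all
from updtrio.roh import ROHRun, detect_roh
from updtrio.simulate import UPDSegmentSpec
from updtrio.upd import (
    UPDCallConfig,
    call_all,
    call_upd,
    format_upd_nomenclature,
    match_roh_to_parent,
    parse_upd_nomenclature,
    summarize_evidence,
)

from conftest import CHR6_LEN, THREE_CHROMS, full_chr6_spec, make_trio_sim


def fit_calls(sim, config=UPDCallConfig()):
    trio = sim.trio
    codes, _ = classify_all(trio)
    runs = {s: detect_roh(trio.sites, trio.gt(s)) for s in trio.samples}
    evidence = summarize_evidence(
        trio, codes, runs["child"], runs["mother"], runs["father"],
        dict(sim.config.chrom_lengths),
    )
    return evidence, call_all(evidence, config)


class TestEvidence:
    def test_null_trio_has_no_informative_sites(self):
        sim = make_trio_sim(seed=51)
        evidence, calls = fit_calls(sim)
        assert calls == []
        for ev in evidence.values():
            assert ev.n_mat == 0 and ev.n_pat == 0

    def test_full_isodisomy_match_fraction_is_one(self):
        sim = make_trio_sim(seed=52, upd=[full_chr6_spec()])
        evidence, _ = fit_calls(sim)
        ev = evidence["6"]
        assert len(ev.run_matches) >= 1
        for rm in ev.run_matches:
            assert rm.mother_match == pytest.approx(1.0)
            assert rm.father_match < 1.0

    def test_summary_matches_brute_force_recount(self):
        sim = make_trio_sim(seed=53, upd=[
            UPDSegmentSpec("6", 30_000_000, 90_000_000, "mother", "isodisomy")
        ])
        trio = sim.trio
        codes, _ = classify_all(trio)
        runs = {s: detect_roh(trio.sites, trio.gt(s)) for s in trio.samples}
        evidence = summarize_evidence(
            trio, codes, runs["child"], runs["mother"], runs["father"]
        )
        from updtrio.classify import MATERNAL_INFORMATIVE

        mask = trio.chrom_mask("6")
        pos = trio.sites.loc[mask, "pos"].to_numpy()
        mat = np.isin(codes[mask], [int(c) for c in MATERNAL_INFORMATIVE])
        inside = np.zeros(len(pos), dtype=bool)
        for r in runs["child"]:
            if r.chrom == "6":
                inside |= (pos >= r.start_bp) & (pos <= r.end_bp)
        ev = evidence["6"]
        assert ev.mat_inside == int(np.sum(mat & inside))
        assert ev.mat_outside == int(np.sum(mat & ~inside))

    def test_match_on_all_missing_run_raises(self):
        pos = np.array([10, 20, 30])
        run = ROHRun("1", 10, 30, 3, 0)
        with pytest.raises(ValueError, match="no usable"):
            match_roh_to_parent(np.array([-1, -1, -1]), np.array([0, 0, 0]), pos, run)

    def test_match_fraction_counts_carried_alleles(self):
        pos = np.array([10, 20, 30, 40])
        run = ROHRun("1", 10, 40, 4, 0)
        child = np.array([2, 2, 0, 1])  # het excluded
        parent = np.array([1, 0, 0, 2])  # carries child allele at sites 1 and 3
        assert match_roh_to_parent(child, parent, pos, run) == pytest.approx(2 / 3)


class TestCallGates:
    def test_gates_match_independent_reevaluation(self):
        config = UPDCallConfig()
        for seed, upd in [(61, [full_chr6_spec()]), (62, []),
                          (63, [full_chr6_spec(mode="heterodisomy")])]:
            sim = make_trio_sim(seed=seed, upd=upd, error_rate=0.002)
            evidence, calls = fit_calls(sim, config)
            for chrom, ev in evidence.items():
                # rule-by-rule oracle of the four gates
                parent = "maternal" if ev.n_mat >= ev.n_pat else "paternal"
                n_win = max(ev.n_mat, ev.n_pat)
                a = n_win >= config.min_informative
                b = n_win / (ev.n_mat + ev.n_pat) >= config.laterality_ratio if (ev.n_mat + ev.n_pat) else False
                c = all(
                    (rm.mother_match if parent == "maternal" else rm.father_match)
                    >= config.match_threshold
                    for rm in ev.run_matches
                )
                d = True
                for r in ev.child_runs:
                    overlap = 0
                    for o in ev.mother_runs + ev.father_runs:
                        lo, hi = max(r.start_bp, o.start_bp), min(r.end_bp, o.end_bp)
                        overlap += max(0, hi - lo + 1)
                    if overlap / r.span_bp > config.parental_overlap_max:
                        d = False
                expected = a and b and c and d
                got = any(cl.chrom == chrom for cl in calls)
                assert got == expected, (seed, chrom)

    def test_no_call_is_a_value(self):
        sim = make_trio_sim(seed=64)
        evidence, _ = fit_calls(sim)
        assert call_upd(evidence["1"]) is None

    def test_consanguinity_guard_suppresses_call(self):
        sim = make_trio_sim(seed=65, upd=[full_chr6_spec()])
        evidence, _ = fit_calls(sim)
        ev = evidence["6"]
        # plant a co-located maternal ROH: autozygosity explains the child run
        ev.mother_runs = list(ev.child_runs)
        assert call_upd(ev) is None

    def test_gate_monotonicity(self):
        """Raising min_informative or match_threshold never creates a call."""
        scenarios = [
            (71, [full_chr6_spec()]),
            (72, [UPDSegmentSpec("6", 30_000_000, 90_000_000, "mother", "isodisomy")]),
            (73, []),
            (74, [full_chr6_spec(parent="father", mode="heterodisomy")]),
        ]
        for seed, upd in scenarios:
            sim = make_trio_sim(seed=seed, error_rate=0.002, upd=upd)
            evidence, _ = fit_calls(sim)
            loose = {c.chrom for c in call_all(evidence, UPDCallConfig(
                min_informative=5, match_threshold=0.9))}
            tight = {c.chrom for c in call_all(evidence, UPDCallConfig(
                min_informative=30, match_threshold=0.995))}
            assert tight <= loose


class TestModesAndRecovery:
    def test_scenario_panel_recovery(self):
        """>= 95% correct (chromosome, parent) over 21 mixed-scenario seeds;
        zero false calls on the null trios."""
        kinds = ["null", "iso_mat", "iso_pat", "het_mat", "het_pat", "seg_mat", "seg_pat"]
        expected_mode = {"iso": "isodisomy", "het": "heterodisomy", "seg": "segmental"}
        hits = 0
        for seed in range(21):
            kind = kinds[seed % len(kinds)]
            upd = []
            if kind != "null":
                parent = "mother" if kind.endswith("mat") else "father"
                if kind.startswith("seg"):
                    upd = [UPDSegmentSpec("6", 30_000_000, 80_000_000, parent, "isodisomy")]
                else:
                    mode = "isodisomy" if kind.startswith("iso") else "heterodisomy"
                    upd = [UPDSegmentSpec("6", 1, CHR6_LEN, parent, mode)]
            sim = make_trio_sim(seed=seed, error_rate=0.002, missing_rate=0.002, upd=upd)
            _, calls = fit_calls(sim)
            if kind == "null":
                assert calls == [], f"false call on null trio, seed {seed}"
                hits += 1
            else:
                want_parent = "maternal" if kind.endswith("mat") else "paternal"
                good = (
                    len(calls) == 1
                    and calls[0].chrom == "6"
                    and calls[0].parent_of_origin == want_parent
                )
                hits += good
                if good:
                    assert calls[0].mode == expected_mode[kind[:3]]
        assert hits / 21 >= 0.95

    def test_no_false_calls_at_higher_error(self):
        for seed in range(5):
            sim = make_trio_sim(seed=500 + seed, error_rate=0.005)
            _, calls = fit_calls(sim)
            assert calls == []

    def test_laterality_exclusive_by_construction(self):
        sim = make_trio_sim(seed=81, upd=[full_chr6_spec()])
        _, calls = fit_calls(sim)
        by_chrom = {}
        for c in calls:
            assert by_chrom.setdefault(c.chrom, c.parent_of_origin) == c.parent_of_origin
        assert len(calls) == len({c.chrom for c in calls})


class TestNomenclature:
    def test_family_verdict_renders(self, family6_report):
        calls = family6_report.upd_calls
        assert [c.nomenclature for c in calls] == ["upd(6)mat"]

    def test_template_and_round_trip(self):
        sim = make_trio_sim(seed=82, upd=[full_chr6_spec(parent="father")])
        _, calls = fit_calls(sim)
        (call,) = calls
        s = format_upd_nomenclature(call)
        assert s == "upd(6)pat"
        assert parse_upd_nomenclature(s) == ("6", "paternal")
        assert parse_upd_nomenclature("upd(15)pat") == ("15", "paternal")
        with pytest.raises(ValueError):
            parse_upd_nomenclature("upd6mat")
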