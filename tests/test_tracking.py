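import math

import numpy as np
import pytest

from gdrep import (
    Clonotype,
    LongitudinalSimConfig,
    PhaseSchedule,
    Repertoire,
    SimConfig,
    category_composition,
    classify_clones,
    intersection_counts,
    neo_frequency_series,
    normalized_shannon_series,
    simulate_longitudinal,
    subsample,
)
from gdrep.tracking import DEFAULT_SCHEDULE


def _rep(tp, pairs, subject="P1"):
    clones = [Clonotype(cdr3, "TRDV1", "TRDJ1", "TRD", n) for cdr3, n in pairs]
    return Repertoire(
        sample_id=f"{subject}_{tp}", clonotypes=clones, subject_id=subject,
        timepoint=tp, chain="TRD",
    )


SCHEDULE3 = PhaseSchedule(
    subject_id="P1",
    timepoints=["T1", "T2", "T3"],
    phases={"T1": "baseline", "T2": "TKI", "T3": "PD1"},
)


class TestSchedule:
    def test_first_timepoint_must_be_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            PhaseSchedule("P", ["T1", "T2"], {"T1": "TKI", "T2": "baseline"})

    def test_every_timepoint_needs_a_phase(self):
        with pytest.raises(ValueError, match="T2"):
            PhaseSchedule("P", ["T1", "T2"], {"T1": "baseline"})


class TestClassification:
    def test_label_rules(self):
        reps = {
            "T1": _rep("T1", [("CAAAF", 5)]),
            "T2": _rep("T2", [("CAAAF", 4), ("CBBBF", 3)]),
            "T3": _rep("T3", [("CAAAF", 2), ("CBBBF", 1), ("CCCCF", 6)]),
        }
        trajs = {t.key[2]: t for t in classify_clones(reps, SCHEDULE3)}
        assert trajs["CAAAF"].label == "PreExisted"
        assert trajs["CBBBF"].label == "TA"
        assert trajs["CCCCF"].label == "PA"
        assert trajs["CBBBF"].first_detected == "T2"

    def test_ra_label_on_default_schedule(self):
        reps = {t: _rep(t, [("CAAAF", 5)]) for t in DEFAULT_SCHEDULE.timepoints}
        reps["T5"] = _rep("T5", [("CAAAF", 5), ("CRRRF", 2)])
        reps["T6"] = _rep("T6", [("CAAAF", 5), ("CRRRF", 1)])
        trajs = {t.key[2]: t for t in classify_clones(reps, DEFAULT_SCHEDULE)}
        assert trajs["CRRRF"].label == "RA"

    def test_baseline_only_clone_is_preexisted(self):
        reps = {
            "T1": _rep("T1", [("CAAAF", 5)]),
            "T2": _rep("T2", [("CBBBF", 3)]),
            "T3": _rep("T3", [("CBBBF", 3)]),
        }
        trajs = {t.key[2]: t for t in classify_clones(reps, SCHEDULE3)}
        assert trajs["CAAAF"].label == "PreExisted"
        assert trajs["CAAAF"].counts["T2"] == 0

    def test_unknown_timepoint_rejected(self):
        reps = {"T9": _rep("T9", [("CAAAF", 1)])}
        with pytest.raises(ValueError, match="T9"):
            classify_clones(reps, SCHEDULE3)

    def test_label_partition_and_stability(self):
        cfg = LongitudinalSimConfig(
            base=SimConfig(n_clones=200, total_reads=50_000, seed=13), noise="none"
        )
        reps, _ = simulate_longitudinal(cfg)
        trajs = classify_clones(reps, cfg.schedule)
        assert all(t.label in ("PreExisted", "TA", "RA", "PA") for t in trajs)
        # appending later timepoints never relabels earlier clones
        partial = {t: reps[t] for t in ["T1", "T2", "T3"]}
        early = {t.key: t.label for t in classify_clones(partial, cfg.schedule)}
        full = {t.key: t.label for t in classify_clones(reps, cfg.schedule)}
        assert all(full[k] == v for k, v in early.items())

    def test_noise_free_planted_recovery_exact(self):
        cfg = LongitudinalSimConfig(
            base=SimConfig(n_clones=300, total_reads=100_000, seed=17), noise="none"
        )
        reps, truth = simulate_longitudinal(cfg)
        got = {t.key: t.label for t in classify_clones(reps, cfg.schedule)}
        planted = {
            (r.v_gene, r.j_gene, r.cdr3_aa): r.label for r in truth.itertuples()
        }
        assert got == planted  # precision = recall = 1 for every label

    def test_subsampled_recall_for_frequent_clones(self):
        cfg = LongitudinalSimConfig(
            base=SimConfig(n_clones=300, total_reads=100_000, seed=19), noise="none"
        )
        reps, truth = simulate_longitudinal(cfg)
        planted = {
            (r.v_gene, r.j_gene, r.cdr3_aa): (r.label, r.emerged_at)
            for r in truth.itertuples()
        }
        thin = {
            t: subsample(rep, depth=10_000, seed=100 + i)
            for i, (t, rep) in enumerate(reps.items())
        }
        got = {t.key: t.label for t in classify_clones(thin, cfg.schedule)}
        eligible = [
            k for k, (label, emerged) in planted.items()
            if reps[emerged].frequencies[
                [c.key for c in reps[emerged].clonotypes].index(k)
            ] >= 1e-3
        ]
        hits = sum(got.get(k) == planted[k][0] for k in eligible)
        assert hits / len(eligible) >= 0.9


class TestSeriesAndComposition:
    def test_single_neo_clone_series(self):
        reps = {
            "T1": _rep("T1", [("CAAAF", 98)]),
            "T2": _rep("T2", [("CAAAF", 98), ("CBBBF", 2)]),
            "T3": _rep("T3", [("CAAAF", 98), ("CBBBF", 2)]),
        }
        trajs = classify_clones(reps, SCHEDULE3)
        series = neo_frequency_series(trajs).set_index("timepoint")
        assert series.loc["T1", "n"] == 0
        assert math.isnan(series.loc["T1", "mean"])
        assert series.loc["T2", "mean"] == pytest.approx(0.02)

    def test_two_clone_mean_and_se(self):
        reps = {
            "T1": _rep("T1", [("CAAAF", 90)]),
            "T2": _rep("T2", [("CAAAF", 90), ("CBBBF", 6), ("CCCCF", 4)]),
            "T3": _rep("T3", [("CAAAF", 90), ("CBBBF", 6), ("CCCCF", 4)]),
        }
        trajs = classify_clones(reps, SCHEDULE3)
        series = neo_frequency_series(trajs).set_index("timepoint")
        assert series.loc["T2", "mean"] == pytest.approx(0.05)
        sd = np.std([0.06, 0.04], ddof=1)
        assert series.loc["T2", "se"] == pytest.approx(sd / math.sqrt(2))

    def test_planted_surge_dominates(self):
        cfg = LongitudinalSimConfig(
            base=SimConfig(n_clones=300, total_reads=100_000, seed=23),
            emergence={"TKI": (20, (1e-4, 3e-4)), "radio": (20, (1e-4, 3e-4)),
                       "PD1": (30, (5e-3, 1e-2))},
            noise="none",
        )
        reps, _ = simulate_longitudinal(cfg)
        trajs = classify_clones(reps, cfg.schedule)
        series = neo_frequency_series(trajs).set_index("timepoint")["mean"]
        assert series["T6"] > series[:"T5"].dropna().max()

    def test_composition_all_preexisted_at_baseline(self):
        reps = {
            "T1": _rep("T1", [("CAAAF", 5), ("CBBBF", 5)]),
            "T2": _rep("T2", [("CAAAF", 5), ("CCCCF", 5)]),
            "T3": _rep("T3", [("CAAAF", 5)]),
        }
        trajs = classify_clones(reps, SCHEDULE3)
        comp = category_composition(trajs)
        t1 = comp[comp.timepoint == "T1"]
        assert list(t1.label) == ["PreExisted"]
        assert t1.share.iloc[0] == 1.0
        for t in ("T2", "T3"):
            assert comp[comp.timepoint == t].share.sum() == pytest.approx(1.0)

    def test_planted_composition_recovered(self):
        cfg = LongitudinalSimConfig(
            base=SimConfig(n_clones=100, total_reads=50_000, seed=29), noise="none"
        )
        reps, truth = simulate_longitudinal(cfg)
        trajs = classify_clones(reps, cfg.schedule)
        comp = category_composition(trajs)
        t6 = comp[comp.timepoint == "T6"].set_index("label")["clones"]
        # persistence=1 and noise-free: everything planted is still present
        assert t6["PreExisted"] == 100
        assert t6["TA"] == truth.label.value_counts()["TA"]
        assert t6["PA"] == truth.label.value_counts()["PA"]


class TestIntersections:
    def test_exclusive_patterns_and_marginals(self):
        reps = {
            "T1": _rep("T1", [("CXXXF", 1), ("CYYYF", 1)]),
            "T2": _rep("T2", [("CYYYF", 1)]),
            "T3": _rep("T3", [("CZZZF", 1)]),
        }
        trajs = classify_clones(reps, SCHEDULE3)
        patterns, marginals = intersection_counts(trajs)
        assert patterns[("T1",)] == 1
        assert patterns[("T1", "T2")] == 1
        assert patterns[("T3",)] == 1
        assert marginals == {"T1": 2, "T2": 1, "T3": 1}

    def test_identical_repertoires_single_pattern(self):
        reps = {t: _rep(t, [("CAAAF", 3), ("CBBBF", 2)]) for t in ("T1", "T2", "T3")}
        patterns, _ = intersection_counts(classify_clones(reps, SCHEDULE3))
        assert patterns == {("T1", "T2", "T3"): 2}

    def test_matches_bitmap_oracle(self):
        cfg = LongitudinalSimConfig(
            base=SimConfig(n_clones=150, total_reads=20_000, seed=31),
            persistence=0.7,
        )
        reps, _ = simulate_longitudinal(cfg)
        trajs = classify_clones(reps, cfg.schedule)
        patterns, marginals = intersection_counts(trajs)
        # brute-force per-clone presence bitmaps over the raw repertoires
        tps = cfg.schedule.timepoints
        presence: dict = {}
        for t in tps:
            for c in reps[t].clonotypes:
                presence.setdefault(c.key, set()).add(t)
        expected: dict = {}
        for key, seen in presence.items():
            pat = tuple(t for t in tps if t in seen)
            expected[pat] = expected.get(pat, 0) + 1
        assert patterns == expected
        for t in tps:
            assert marginals[t] == sum(1 for s in presence.values() if t in s)


class TestNormalizedShannonSeries:
    def test_uniform_gives_one(self):
        reps = {t: _rep(t, [(f"C{ch}F", 5) for ch in "ABCD"]) for t in ("T1", "T2", "T3")}
        series = normalized_shannon_series(reps, SCHEDULE3, expanded_only=False)
        assert np.allclose(series.values, 1.0)

    def test_single_clone_undefined(self):
        reps = {
            "T1": _rep("T1", [("CAAAF", 5)]),
            "T2": _rep("T2", [("CAAAF", 5)]),
            "T3": _rep("T3", [("CAAAF", 5)]),
        }
        series = normalized_shannon_series(reps, SCHEDULE3, expanded_only=False)
        assert series.isna().all()

    def test_matches_diversity_profile(self):
        from gdrep import diversity_profile

        cfg = LongitudinalSimConfig(
            base=SimConfig(n_clones=120, total_reads=30_000, seed=37), noise="none"
        )
        reps, _ = simulate_longitudinal(cfg)
        series = normalized_shannon_series(reps, cfg.schedule, expanded_only=False)
        for t, rep in reps.items():
            prof = diversity_profile(rep)
            assert series[t] == pytest.approx(1 - prof.clonality, abs=1e-9)
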