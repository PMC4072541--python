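"""Reference patterns, gain/loss classification, tallies, sweep, recurrence."""

from __future__ import annotations

import numpy as np
import pytest

from credive.divergence import (
    DivergenceCall,
    build_reference_pattern,
    classify_transgene,
    recurrent_gains,
    sweep_curve,
    tally,
)
from credive.expression import ScoringPolicy, summarize_dataset
from credive.synthetic import ExpressionSimConfig, PlantedEvent, simulate_expression_dataset

from conftest import make_summary


def both(v, n=25):
    return {"st1": (v, n), "st2": (v, n)}


class TestReferencePattern:
    def test_inclusion_threshold(self):
        summary = make_summary(
            "g1", "C_elegans",
            {
                "A": ("frequency", 0.95, both(0.95)),
                "B": ("frequency", 0.20, both(0.20)),
            },
        )
        ref = build_reference_pattern(summary)
        assert ref.entries["A"].in_pattern
        assert not ref.entries["B"].in_pattern
        assert ref.complexity == 1

    def test_include_override_forces_membership_and_is_flagged(self):
        summary = make_summary(
            "g1", "C_elegans", {"B": ("frequency", 0.20, both(0.20))}
        )
        ref = build_reference_pattern(
            summary, overrides=[{"gene": "g1", "cell": "B", "action": "include"}]
        )
        assert ref.entries["B"].in_pattern
        assert ref.entries["B"].override == "include"

    def test_counted_class_in_pattern_when_median_positive(self):
        summary = make_summary(
            "g1", "C_elegans",
            {"VNC": ("median", 11.0, both(11.0)), "D": ("median", 0.0, both(0.0))},
        )
        ref = build_reference_pattern(summary)
        assert ref.entries["VNC"].in_pattern
        assert not ref.entries["D"].in_pattern


def reference(cells):
    return build_reference_pattern(make_summary("g1", "C_elegans", cells))


class TestClassifyTransgene:
    def test_strict_loss_and_gain_by_definition(self):
        ref = reference({"A": ("frequency", 0.9, both(0.9))})
        het = make_summary(
            "g1", "C_briggsae",
            {
                "A": ("frequency", 0.0, both(0.0)),
                "B": ("frequency", 0.8, both(0.8)),
            },
        )
        calls = {c.label: c for c in classify_transgene(het, ref)}
        assert calls["A"].call == "loss_strict"
        assert calls["B"].call == "gain"
        assert calls["B"].n_strains_supporting == 2

    def test_single_strain_gain_is_demoted(self):
        ref = reference({"A": ("frequency", 0.9, both(0.9))})
        het = make_summary(
            "g1", "C_briggsae",
            {
                "A": ("frequency", 0.9, both(0.9)),
                "B": ("frequency", 0.4, {"st1": (0.8, 25), "st2": (0.0, 25)}),
            },
        )
        calls = {c.label: c for c in classify_transgene(het, ref)}
        assert calls["B"].call == "conserved"
        assert calls["B"].demoted
        assert "gain" in calls["B"].note

    def test_reduction_between_strict_and_half_reference(self):
        ref = reference({"A": ("frequency", 0.9, both(0.9))})
        het = make_summary("g1", "C_briggsae", {"A": ("frequency", 0.3, both(0.3))})
        (call,) = classify_transgene(het, ref)
        assert call.call == "reduction"

    def test_counted_class_median_rules(self):
        ref = reference({"VNC": ("median", 12.0, both(12.0))})
        zero = make_summary("g1", "sp", {"VNC": ("median", 0.0, both(0.0))})
        reduced = make_summary("g1", "sp", {"VNC": ("median", 4.0, both(4.0))})
        kept = make_summary("g1", "sp", {"VNC": ("median", 11.0, both(11.0))})
        assert classify_transgene(zero, ref)[0].call == "loss_strict"
        assert classify_transgene(reduced, ref)[0].call == "reduction"
        assert classify_transgene(kept, ref)[0].call == "conserved"

    def test_unscored_reference_cell_reported(self):
        ref = reference({"A": ("frequency", 0.9, both(0.9))})
        het = make_summary("g1", "sp", {"B": ("frequency", 0.0, both(0.0))})
        calls = {c.label: c for c in classify_transgene(het, ref)}
        assert calls["A"].call == "unscored"

    def test_gene_mismatch_rejected(self):
        ref = reference({"A": ("frequency", 0.9, both(0.9))})
        het = make_summary("g2", "sp", {"A": ("frequency", 0.9, both(0.9))})
        with pytest.raises(ValueError, match="gene mismatch"):
            classify_transgene(het, ref)

    def test_no_cell_gets_both_gain_and_loss(self):
        obs, _ = simulate_expression_dataset(_planted_cfg(seed=3, noise=0.4))
        calls = _classify_all(obs)
        for (gene, sp), group in _group_by_transgene(calls).items():
            by_label = {}
            for c in group:
                by_label.setdefault(c.label, set()).add(c.call)
            for label, cs in by_label.items():
                assert not ({"gain"} & cs and {"loss_strict", "reduction"} & cs)

    def test_relaxed_strain_filter_is_superset(self):
        obs, _ = simulate_expression_dataset(_planted_cfg(seed=9, noise=0.5))
        strict_calls = _classify_all(obs, ScoringPolicy(consistency_min_strains=2))
        loose_calls = _classify_all(obs, ScoringPolicy(consistency_min_strains=1))

        def events(calls):
            return {
                (c.gene, c.cre_species, c.label, c.call)
                for c in calls
                if c.call in ("gain", "loss_strict", "reduction")
            }

        assert events(strict_calls) <= events(loose_calls)

    def test_zero_noise_calls_match_planted_truth_exactly(self):
        cfg = _planted_cfg(seed=21, noise=0.0)
        obs, truth = simulate_expression_dataset(cfg)
        calls = _classify_all(obs)
        called = {
            (c.cre_species, c.label): c.call
            for c in calls
            if c.call in ("gain", "loss_strict", "reduction")
        }
        expected = {}
        for (gene, sp), events in truth.planted_events.items():
            for ev in events:
                name = {"gain": "gain", "loss": "loss_strict", "reduction": "reduction"}[ev.event]
                expected[(sp, ev.cell)] = name
        assert called == expected


def _planted_cfg(seed: int, noise: float) -> ExpressionSimConfig:
    from credive.synthetic import study_ontology

    onto = study_ontology()
    return ExpressionSimConfig(
        gene_id="g1",
        ontology=onto,
        reference_pattern={"AVAL": 0.9, "RMED": 0.9, "RIS": 0.9, "DVB": 0.9},
        per_species_edits={
            "C_briggsae": [
                PlantedEvent("CEPDL", "gain", 0.8),
                PlantedEvent("RIS", "loss", 0.0),
            ],
            "C_remanei": [PlantedEvent("DVB", "reduction", 0.25)],
        },
        n_strains=2,
        n_individuals_per_strain=25,
        strain_noise=noise,
        seed=seed,
    )


def _classify_all(obs, policy: ScoringPolicy | None = None):
    from credive.synthetic import study_ontology

    onto = study_ontology()
    summaries = summarize_dataset(obs, onto)
    policy = policy or ScoringPolicy()
    refs = {}
    calls = []
    for key, s in summaries.items():
        if key[1] == "C_elegans":
            refs[key[0]] = build_reference_pattern(s, policy)
    for key, s in summaries.items():
        if key[1] != "C_elegans":
            calls.extend(classify_transgene(s, refs[key[0]], policy))
    return calls


def _group_by_transgene(calls):
    out = {}
    for c in calls:
        out.setdefault((c.gene, c.cre_species), []).append(c)
    return out


def _call(gene, sp, label, call, ref, obs, in_pattern, stat="frequency"):
    return DivergenceCall(
        gene=gene, cre_species=sp, host_species="C_elegans", label=label,
        stat=stat, call=call, ref_value=ref, obs_value=obs,
        n_strains_supporting=2, in_reference_pattern=in_pattern,
    )


class TestTally:
    def test_basic_counts(self):
        calls = [
            _call("g1", "sp", "A", "gain", 0.0, 0.8, False),
            _call("g1", "sp", "B", "gain", 0.0, 0.6, False),
            _call("g1", "sp", "C", "loss_strict", 0.9, 0.0, True),
        ]
        report = tally(calls)
        assert (report.n_gains, report.n_losses_strict, report.n_losses_liberal) == (2, 1, 1)

    def test_reduction_raises_liberal_only(self):
        calls = [
            _call("g1", "sp", "C", "loss_strict", 0.9, 0.0, True),
            _call("g1", "sp", "D", "reduction", 0.9, 0.3, True),
        ]
        report = tally(calls)
        assert report.n_losses_strict == 1
        assert report.n_losses_liberal == 2

    def test_order_invariance_and_restriction(self):
        calls = [
            _call("g1", "spA", "A", "gain", 0.0, 0.8, False),
            _call("g2", "spB", "B", "gain", 0.0, 0.8, False),
            _call("g2", "spB", "C", "loss_strict", 0.9, 0.0, True),
        ]
        full = tally(calls)
        rev = tally(calls[::-1])
        assert (full.n_gains, full.n_losses_strict) == (rev.n_gains, rev.n_losses_strict)
        restricted = tally(calls, gene_universe=["g2"])
        assert restricted.n_gains <= full.n_gains
        assert restricted.n_losses_strict <= full.n_losses_strict
        assert (restricted.n_gains, restricted.n_losses_strict) == (1, 1)


class TestSweepCurve:
    def test_no_losses_dominance_holds_everywhere(self):
        calls = [
            _call("g1", "sp", c, "gain", 0.0, f, False)
            for c, f in (("A", 0.2), ("B", 0.5), ("C", 0.9))
        ]
        curve = sweep_curve(calls)
        assert curve.dominant
        assert curve.n_losses_above.sum() == 0

    def test_equal_multisets_give_equal_counts(self):
        freqs = [0.2, 0.5, 0.9]
        calls = [
            _call("g1", "sp", f"G{i}", "gain", 0.0, f, False)
            for i, f in enumerate(freqs)
        ] + [
            _call("g1", "sp", f"L{i}", "loss_strict", 1.0, 1.0 - f, True)
            for i, f in enumerate(freqs)
        ]
        curve = sweep_curve(calls)
        assert np.array_equal(curve.n_gains_above, curve.n_losses_above)
        assert curve.dominant  # ties count as dominance (>=)

    def test_counts_match_direct_counting_oracle(self):
        rng = np.random.default_rng(44)
        gains = rng.random(20)
        losses = rng.random(8)
        calls = [
            _call("g1", "sp", f"G{i}", "gain", 0.0, f, False)
            for i, f in enumerate(gains)
        ] + [
            _call("g1", "sp", f"L{i}", "loss_strict", 1.0, 1.0 - f, True)
            for i, f in enumerate(losses)
        ]
        curve = sweep_curve(calls)
        for t, ng, nl in zip(curve.thresholds, curve.n_gains_above, curve.n_losses_above):
            assert ng == (gains > t).sum()
            assert nl == (losses > t).sum()
        expected_dom = all(
            (gains > t).sum() >= (losses > t).sum()
            for t in np.concatenate(([0.0], gains, losses))
            if t < 1.0
        )
        assert curve.dominant == expected_dom

    def test_counted_classes_are_excluded(self):
        calls = [
            _call("g1", "sp", "VNC", "loss_strict", 12.0, 0.0, True, stat="median"),
            _call("g1", "sp", "A", "gain", 0.0, 0.5, False),
        ]
        curve = sweep_curve(calls)
        assert len(curve.loss_freqs) == 0
        assert len(curve.gain_freqs) == 1


class TestRecurrentGains:
    def test_shared_cell_collects_supporters(self):
        calls = [
            _call("g1", "spA", "HSNs", "gain", 0.0, 0.5, False),
            _call("g1", "spB", "HSNs", "gain", 0.0, 0.6, False),
            _call("g2", "spA", "HSNs", "gain", 0.0, 0.7, False),
            _call("g2", "spA", "CEP", "gain", 0.0, 0.7, False),
        ]
        recur = recurrent_gains(calls)
        assert recur[0][0] == "HSNs"
        assert len(recur[0][1]) == 3
        assert all(cell != "CEP" for cell, _ in recur)

    def test_unique_gains_give_empty_list(self):
        calls = [
            _call("g1", "spA", "A", "gain", 0.0, 0.5, False),
            _call("g1", "spB", "B", "gain", 0.0, 0.5, False),
        ]
        assert recurrent_gains(calls) == []

    def test_same_cre_twice_counts_once(self):
        calls = [
            _call("g1", "spA", "A", "gain", 0.0, 0.5, False),
            _call("g1", "spA", "A", "gain", 0.0, 0.6, False),
        ]
        assert recurrent_gains(calls) == []
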