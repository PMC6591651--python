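"""Heterozygosity-map assembly, recurrent-artifact flagging and burden
counting."""

import numpy as np
import pandas as pd
import pytest

from biallelic import (
    ArtifactSet,
    HeterozygosityMap,
    ModelConfig,
    build_map,
    classify_pileup,
    count_het_sites,
    flag_artifacts,
    het_burdens,
    maps_to_frame,
    simulate_pileup,
)
from biallelic.hetmap import EMPTY_ARTIFACTS
from biallelic.pileup_io import TranscriptPileup


def _map_from_calls(sample, calls_by_pos, gene="G"):
    positions = sorted(calls_by_pos)
    table = pd.DataFrame(
        {
            "pos": positions,
            "ref_fraction": [0.5] * len(positions),
            "call": [calls_by_pos[p] for p in positions],
            "depth_used": [50] * len(positions),
        }
    )
    return HeterozygosityMap(sample=sample, gene=gene, table=table)


def _sheet(samples_cohorts, sex="male"):
    return pd.DataFrame(
        [(s, c, sex) for s, c in samples_cohorts], columns=["sample", "cohort", "sex"]
    )


class TestBuildMap:
    def test_rows_align_with_calls(self, silenced_scenario):
        pileups, _ = simulate_pileup(silenced_scenario)
        tp = pileups[0]
        report = classify_pileup(tp, ModelConfig(), error_rate=0.0)
        m = build_map(tp, report)
        assert len(m) == len(tp)
        assert np.all(m.table["ref_fraction"] == 1.0)
        assert len(m.het_positions()) == 0

    def test_sample_mismatch_rejected(self, silenced_scenario):
        pileups, _ = simulate_pileup(silenced_scenario)
        report = classify_pileup(pileups[0], ModelConfig(), error_rate=0.0)
        with pytest.raises(ValueError, match="calls are for"):
            build_map(pileups[1], report)

    def test_empty_pileup_gives_empty_map(self):
        tp = TranscriptPileup("s", "g", np.array([], int), np.array([], "U1"),
                              np.zeros((0, 4), int))
        m = build_map(tp, classify_pileup(tp, ModelConfig(), 0.0))
        assert len(m) == 0


class TestFlagArtifacts:
    def test_consistent_position_not_flagged(self):
        maps = [_map_from_calls(f"s{i}", {10: "hom_ref"}) for i in range(4)]
        sheet = _sheet([("s0", "a"), ("s1", "a"), ("s2", "b"), ("s3", "b")])
        art = flag_artifacts(maps, sheet)
        assert art.flagged == frozenset()

    def test_all_three_classes_in_each_cohort_flagged(self):
        calls = ["hom_ref", "het", "hom_alt"]
        maps = [_map_from_calls(f"a{i}", {10: c}) for i, c in enumerate(calls)]
        maps += [_map_from_calls(f"b{i}", {10: c}) for i, c in enumerate(calls)]
        sheet = _sheet([(f"a{i}", "a") for i in range(3)] + [(f"b{i}", "b") for i in range(3)])
        art = flag_artifacts(maps, sheet)
        assert art.flagged == frozenset({10})
        assert set(art.evidence["cohort"]) == {"a", "b"}

    def test_inconsistency_in_one_cohort_only_not_flagged(self):
        calls = ["hom_ref", "het", "hom_alt"]
        maps = [_map_from_calls(f"a{i}", {10: c}) for i, c in enumerate(calls)]
        maps += [_map_from_calls(f"b{i}", {10: "hom_ref"}) for i in range(3)]
        sheet = _sheet([(f"a{i}", "a") for i in range(3)] + [(f"b{i}", "b") for i in range(3)])
        assert flag_artifacts(maps, sheet).flagged == frozenset()

    def test_female_het_against_male_hom_not_flagged(self):
        """A genuinely heterozygous female does not make a position an
        artifact: her cohort never shows all three classes."""
        maps = [_map_from_calls("m1", {5: "hom_ref"}), _map_from_calls("m2", {5: "hom_ref"}),
                _map_from_calls("f1", {5: "het"}),
                _map_from_calls("c1", {5: "hom_ref"}), _map_from_calls("c2", {5: "hom_ref"})]
        sheet = pd.DataFrame(
            [("m1", "case", "male"), ("m2", "case", "male"), ("f1", "case", "female"),
             ("c1", "ctrl", "male"), ("c2", "ctrl", "male")],
            columns=["sample", "cohort", "sex"],
        )
        assert flag_artifacts(maps, sheet).flagged == frozenset()

    def test_majority_rule(self):
        # 3 of 4 samples disagree with the modal call in each cohort
        maps = [_map_from_calls(f"a{i}", {3: c}) for i, c in
                enumerate(["hom_ref", "het", "het", "hom_alt"])]
        maps += [_map_from_calls(f"b{i}", {3: c}) for i, c in
                 enumerate(["hom_ref", "hom_ref", "het", "hom_alt"])]
        sheet = _sheet([(f"a{i}", "a") for i in range(4)] + [(f"b{i}", "b") for i in range(4)])
        art = flag_artifacts(maps, sheet, rule="majority", majority_frac=0.5)
        assert art.flagged == frozenset({3})
        # under the default all-three-classes rule it is also flagged here
        assert flag_artifacts(maps, sheet).flagged == frozenset({3})

    def test_single_cohort_rejected(self):
        maps = [_map_from_calls("s1", {1: "het"}), _map_from_calls("s2", {1: "het"})]
        sheet = _sheet([("s1", "only"), ("s2", "only")])
        with pytest.raises(ValueError, match="2 cohorts"):
            flag_artifacts(maps, sheet)

    def test_removing_a_sample_never_adds_a_flag(self):
        """Flag monotonicity under the all-three-classes rule."""
        rng = np.random.default_rng(4)
        classes = np.array(["hom_ref", "het", "hom_alt"])
        samples = [(f"a{i}", "a") for i in range(5)] + [(f"b{i}", "b") for i in range(5)]
        maps = [
            _map_from_calls(s, {p: classes[rng.integers(3)] for p in (1, 2, 3)})
            for s, _ in samples
        ]
        sheet = _sheet(samples)
        full = flag_artifacts(maps, sheet).flagged
        for drop in range(len(maps)):
            reduced = [m for i, m in enumerate(maps) if i != drop]
            sub = flag_artifacts(reduced, sheet).flagged
            assert sub <= full


class TestCounting:
    def test_zero_het_calls(self):
        m = _map_from_calls("s", {1: "hom_ref", 2: "no_call"})
        assert count_het_sites(m) == 0

    def test_all_het_calls_flagged_counts_zero(self):
        m = _map_from_calls("s", {1: "het", 2: "het", 3: "het"})
        art = ArtifactSet(gene="G", flagged=frozenset({1, 2, 3}), rule="all_classes")
        assert count_het_sites(m, art) == 0
        assert count_het_sites(m, EMPTY_ARTIFACTS) == 3

    def test_count_monotone_in_artifact_set(self):
        m = _map_from_calls("s", {1: "het", 2: "het", 3: "hom_ref", 4: "het"})
        small = ArtifactSet(gene="G", flagged=frozenset({1}), rule="all_classes")
        large = ArtifactSet(gene="G", flagged=frozenset({1, 4}), rule="all_classes")
        assert count_het_sites(m, small) >= count_het_sites(m, large)

    def test_burden_table_and_map_frame(self):
        maps = [_map_from_calls("s1", {1: "het", 2: "hom_ref"}),
                _map_from_calls("s2", {1: "het", 2: "het"})]
        burdens = het_burdens(maps).set_index("sample")["het_sites"]
        assert burdens.to_dict() == {"s1": 1, "s2": 2}
        frame = maps_to_frame(maps, EMPTY_ARTIFACTS)
        assert list(frame.columns) == ["sample", "gene", "pos", "ref_fraction",
                                       "call", "depth_used", "flagged"]
        assert not frame["flagged"].any()
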