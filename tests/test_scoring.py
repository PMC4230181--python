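"""Frequency-metric tests: worked examples, hand counts, invariances."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_nucleus

from nucassoc.errors import (
    AmbiguousPloidyError,
    AnnotationError,
    CohesionUndefinedError,
    SchemaError,
    UnscorableError,
)
from nucassoc.rsd import point_signal_config
from nucassoc.scoring import (
    FrequencySummary,
    association_frequency,
    cohesion_frequency,
    elongation_frequency,
    nuclei_to_table,
    outloop_frequency,
    read_scored_nuclei,
    separation_frequency,
    write_scored_nuclei,
)
from nucassoc.synthetic import PopulationParams, gen_nuclei_population, gen_segment_annotation


class TestReadScoredNuclei:
    def test_empty_table(self):
        empty = pd.DataFrame(
            columns=["nucleus_id", "ploidy", "tissue", "probe_id",
                     "homolog_index", "signal_count", "positions", "flags"]
        )
        assert read_scored_nuclei(empty) == []

    def test_groups_rows_per_nucleus(self):
        rows = []
        for i in range(3):
            for probe in ("A", "B"):
                rows.append(
                    dict(nucleus_id=f"n{i}", ploidy="2C", tissue="leaf",
                         probe_id=probe, homolog_index="", signal_count=1,
                         positions="", flags="")
                )
        nuclei = read_scored_nuclei(pd.DataFrame(rows))
        assert len(nuclei) == 3
        assert all(len(n.observations) == 2 for n in nuclei)

    def test_duplicate_triple_rejected(self):
        row = dict(nucleus_id="n1", ploidy="2C", tissue="leaf", probe_id="A",
                   homolog_index="", signal_count=1, positions="", flags="")
        with pytest.raises(SchemaError, match="duplicate"):
            read_scored_nuclei(pd.DataFrame([row, row]))

    def test_unknown_ploidy_rejected(self):
        row = dict(nucleus_id="n1", ploidy="3C", tissue="leaf", probe_id="A",
                   homolog_index="", signal_count=1, positions="", flags="")
        with pytest.raises(SchemaError, match="ploidy"):
            read_scored_nuclei(pd.DataFrame([row]))

    def test_position_count_mismatch_rejected(self):
        row = dict(nucleus_id="n1", ploidy="2C", tissue="leaf", probe_id="A",
                   homolog_index="", signal_count=2, positions="1;2", flags="")
        with pytest.raises(SchemaError, match="line 2"):
            read_scored_nuclei(pd.DataFrame([row]))

    @pytest.mark.parametrize("ploidy", ["2C", "4C"])
    def test_generator_output_round_trips_losslessly(self, tmp_path, ploidy):
        table = gen_nuclei_population(
            PopulationParams(n_nuclei=40, ploidy_label=ploidy, seed=5)
        )
        nuclei = read_scored_nuclei(table)
        path = tmp_path / "nuclei.tsv"
        write_scored_nuclei(nuclei, path)
        again = read_scored_nuclei(path)
        assert again == nuclei


class TestAssociationFrequency:
    def test_worked_example_trans_2C(self, flagged_association_population):
        # 27 associated of 200 scored nuclei, as reported for the
        # F28P5/T29H11 trans pair in 2C leaf nuclei
        s = association_frequency(flagged_association_population, "A", "B")
        assert (s.k, s.n) == (27, 200)
        assert s.percent_display == 13.5

    def test_worked_example_trans_4C(self):
        nuclei = [
            make_nucleus(
                f"n{i}",
                [{"probe_id": "A",
                  "flags": ("associated_with:B",) if i < 20 else ()},
                 {"probe_id": "B"}],
                ploidy="4C",
            )
            for i in range(90)
        ]
        s = association_frequency(nuclei, "A", "B")
        assert s.percent_display == 22.2

    def test_no_flags_means_zero_percent(self):
        nuclei = [
            make_nucleus(f"n{i}", [{"probe_id": "A"}, {"probe_id": "B"}])
            for i in range(50)
        ]
        s = association_frequency(nuclei, "A", "B")
        assert s.percent == 0.0

    def test_flags_and_positions_modes_agree(self):
        """Generator flags derive from the same distance threshold."""
        cfg = point_signal_config()
        table = gen_nuclei_population(
            PopulationParams(n_nuclei=300, p_assoc=0.3, p_elongation=0.0,
                             p_outloop=0.0, geometry=cfg, seed=8)
        )
        nuclei = read_scored_nuclei(table)
        by_flags = association_frequency(nuclei, "F28P5", "T29H11")
        by_dist = association_frequency(
            nuclei, "F28P5", "T29H11",
            distance_threshold=cfg.association_threshold,
        )
        assert (by_flags.k, by_flags.n) == (by_dist.k, by_dist.n)

    def test_row_permutation_invariance(self):
        table = gen_nuclei_population(PopulationParams(n_nuclei=60, seed=4))
        shuffled = table.sample(frac=1.0, random_state=0)
        a = association_frequency(read_scored_nuclei(table), "F28P5", "T29H11")
        b = association_frequency(read_scored_nuclei(shuffled), "F28P5", "T29H11")
        assert (a.k, a.n) == (b.k, b.n)

    def test_unscorable_without_flags_or_positions(self):
        nuclei = [make_nucleus("n1", [{"probe_id": "A"}, {"probe_id": "B"}])]
        with pytest.raises(UnscorableError):
            association_frequency(nuclei, "A", "B", distance_threshold=0.5)

    def test_missing_probe_raises(self):
        nuclei = [make_nucleus("n1", [{"probe_id": "A"}])]
        with pytest.raises(UnscorableError):
            association_frequency(nuclei, "A", "B")


class TestElongationFrequency:
    def test_worked_example_F16M2(self):
        # 48 of 200 2C nuclei with >2 signals: the 24.0% subtelomeric case
        nuclei = [
            make_nucleus(f"n{i}", [{"probe_id": "F16M2",
                                    "signal_count": 3 if i < 48 else 2}])
            for i in range(200)
        ]
        s = elongation_frequency(nuclei, "F16M2")
        assert (s.k, s.n, s.percent_display) == (48, 200, 24.0)

    def test_boundary_two_signals_not_elongated(self):
        nuclei = [make_nucleus("n1", [{"probe_id": "A", "signal_count": 2}])]
        assert elongation_frequency(nuclei, "A").k == 0

    def test_4C_threshold_is_four(self):
        nuclei = [
            make_nucleus("n1", [{"probe_id": "A", "signal_count": 4}], ploidy="4C"),
            make_nucleus("n2", [{"probe_id": "A", "signal_count": 5}], ploidy="4C"),
        ]
        assert elongation_frequency(nuclei, "A").k == 1

    def test_counts_summed_across_homolog_rows(self):
        nuclei = [
            make_nucleus("n1", [
                {"probe_id": "A", "homolog_index": 1, "signal_count": 2},
                {"probe_id": "A", "homolog_index": 2, "signal_count": 1},
            ])
        ]
        assert elongation_frequency(nuclei, "A").k == 1  # 3 > 2

    def test_mixed_ploidy_rejected(self):
        nuclei = [
            make_nucleus("n1", [{"probe_id": "A"}], ploidy="2C"),
            make_nucleus("n2", [{"probe_id": "A"}], ploidy="4C"),
        ]
        with pytest.raises(AmbiguousPloidyError):
            elongation_frequency(nuclei, "A")


class TestCohesionFrequency:
    @staticmethod
    def _homolog_population(n_cohesive, n_total, probe="T20O10"):
        nuclei = []
        for i in range(0, n_total, 2):
            probes = []
            for hom in (1, 2):
                idx = i + hom - 1
                if idx >= n_total:
                    break
                probes.append({
                    "probe_id": probe,
                    "homolog_index": hom,
                    "signal_count": 1 if idx < n_cohesive else 2,
                })
            nuclei.append(make_nucleus(f"n{i}", probes, ploidy="4C"))
        return nuclei

    def test_worked_example_T20O10(self):
        # 50 of 86 homologues fused: the 58.1% 4C leaf value
        s = cohesion_frequency(self._homolog_population(50, 86), "T20O10")
        assert (s.k, s.n, s.percent_display) == (50, 86, 58.1)

    def test_all_fused_is_100(self):
        s = cohesion_frequency(self._homolog_population(10, 10), "T20O10")
        assert s.percent == 100.0

    def test_hand_count_on_random_fixture(self):
        rng = np.random.default_rng(0)
        fused = rng.random(60) < 0.4
        nuclei = self._homolog_population(0, 0)
        nuclei = []
        for i in range(30):
            probes = [
                {"probe_id": "P", "homolog_index": h + 1,
                 "signal_count": 1 if fused[2 * i + h] else 2}
                for h in range(2)
            ]
            nuclei.append(make_nucleus(f"n{i}", probes, ploidy="4C"))
        s = cohesion_frequency(nuclei, "P")
        assert s.k == int(fused.sum()) and s.n == 60

    def test_2C_input_rejected(self):
        nuclei = [make_nucleus("n1", [{"probe_id": "P", "homolog_index": 1}])]
        with pytest.raises(CohesionUndefinedError):
            cohesion_frequency(nuclei, "P")


class TestSeparationFrequency:
    @staticmethod
    def _pair_population(n_sep, n_total):
        nuclei = []
        for i in range(n_total):
            flags = ("separated_from_adjacent",) if i < n_sep else ()
            nuclei.append(
                make_nucleus(
                    f"n{i}",
                    [{"probe_id": "T25K16", "homolog_index": 1, "flags": flags},
                     {"probe_id": "F6F3", "homolog_index": 1}],
                    ploidy="4C",
                )
            )
        return nuclei

    def test_none_separated_is_zero(self):
        s = separation_frequency(self._pair_population(0, 20), ("T25K16", "F6F3"))
        assert s.percent == 0.0

    def test_worked_example_subtelomeric_2C(self):
        # 23 of 40 homologues apart: the 57.5% subtelomere case
        s = separation_frequency(self._pair_population(23, 40), ("T25K16", "F6F3"))
        assert (s.k, s.n, s.percent_display) == (23, 40, 57.5)

    def test_annotation_gate(self):
        bed = gen_segment_annotation(
            {"Chr1": 1_000_000},
            [("Chr1", 0, 100_000, "T25K16"),
             ("Chr1", 90_000, 100_000, "F6F3"),
             ("Chr1", 500_000, 50_000, "FARAWAY")],
        )
        nuclei = self._pair_population(1, 5)
        s = separation_frequency(nuclei, ("T25K16", "F6F3"), annotation=bed)
        assert s.n == 5
        with pytest.raises(AnnotationError):
            separation_frequency(nuclei, ("T25K16", "FARAWAY"), annotation=bed)

    def test_positional_mode_hand_count(self):
        nuclei = [
            make_nucleus(
                f"n{i}",
                [{"probe_id": "A", "homolog_index": 1,
                  "positions": ((0.0, 0.0),)},
                 {"probe_id": "B", "homolog_index": 1,
                  "positions": ((float(i), 0.0),)}],
            )
            for i in range(4)
        ]
        s = separation_frequency(nuclei, ("A", "B"), distance_threshold=1.5)
        assert (s.k, s.n) == (2, 4)  # distances 2 and 3 exceed 1.5


class TestOutloopFrequency:
    def test_all_flagged_is_100(self):
        nuclei = [
            make_nucleus(f"n{i}", [{"probe_id": "A", "flags": ("outside_CT",)}])
            for i in range(10)
        ]
        assert outloop_frequency(nuclei, "A").percent == 100.0

    def test_worked_example_arithmetic(self):
        nuclei = [
            make_nucleus(
                f"n{i}",
                [{"probe_id": "A",
                  "flags": ("outside_CT",) if i < 2 else ("cohesive",)}],
            )
            for i in range(150)
        ]
        s = outloop_frequency(nuclei, "A", territory_probe="CT1top")
        assert (s.k, s.n, s.percent_display) == (2, 150, 1.3)

    def test_unflagged_table_unscorable(self):
        nuclei = [make_nucleus("n1", [{"probe_id": "A"}])]
        with pytest.raises(UnscorableError):
            outloop_frequency(nuclei, "A")


class TestFrequencySummary:
    def test_invariants(self):
        s = FrequencySummary("m", 1, 3)
        assert 0.0 <= s.percent <= 100.0
        with pytest.raises(ValueError):
            FrequencySummary("m", 4, 3)

    def test_display_rounding_half_up(self):
        assert FrequencySummary("m", 1, 16).percent_display == 6.3  # 6.25 -> 6.3
        assert FrequencySummary("m", 27, 200).percent_display == 13.5
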