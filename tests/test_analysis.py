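import numpy as np
import pandas as pd
import pytest

from emsyn.analysis import (
    area_stats_by_type,
    bouton_multiplicity,
    corrected_area,
    intersynapse_intervals,
    laminar_profile,
    pf_pc_conditional_connectivity,
    synapse_density,
)
from emsyn.core import CellType, CellTypeMap, SegmentationVolume


def table_from(rows):
    defaults = {
        "synapse_id": 0,
        "contact_id": 0,
        "pre_seg": 1,
        "post_seg": 2,
        "pre_type": "PF",
        "post_type": "PC",
        "synapse_class": "EXCITATORY",
        "vc_id": 0,
        "distance": 1.0,
        "area_um2": 0.3,
        "loc_x": 0,
        "loc_y": 0,
        "loc_z": 0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestCorrectedArea:
    def test_typical_overestimation_worked_example(self):
        assert round(corrected_area(0.29, 0.20), 2) == 0.24

    def test_zero_fraction_is_identity(self):
        assert corrected_area(0.5, 0.0) == 0.5

    def test_algebraic_round_trip(self):
        before, fraction = 0.8, 0.35
        after = corrected_area(before, fraction)
        assert (before - after) / after == pytest.approx(fraction)

    def test_fraction_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            corrected_area(0.3, -1.0)


class TestAreaStats:
    def test_single_synapse(self):
        stats = area_stats_by_type(table_from([{"area_um2": 0.42}]))
        assert stats["by_pair"]["PF-PC"]["median_um2"] == pytest.approx(0.42)
        assert stats["total_area_um2"] == pytest.approx(0.42)

    def test_median_and_total_of_three(self):
        stats = area_stats_by_type(
            table_from([{"area_um2": a, "synapse_id": i} for i, a in enumerate([1.0, 2.0, 3.0])])
        )
        assert stats["by_pair"]["PF-PC"]["median_um2"] == 2.0
        assert stats["by_pair"]["PF-PC"]["total_um2"] == 6.0

    def test_class_totals_conserve_overall_total(self):
        rows = [
            {"area_um2": 0.2, "pre_type": "PF", "post_type": "PC"},
            {"area_um2": 0.4, "pre_type": "CF", "post_type": "PC"},
            {"area_um2": 1.1, "pre_type": "IN", "post_type": "PC", "synapse_class": "INHIBITORY"},
        ]
        stats = area_stats_by_type(table_from(rows))
        class_total = sum(v["total_um2"] for v in stats["by_class"].values())
        pair_total = sum(v["total_um2"] for v in stats["by_pair"].values())
        assert class_total == pytest.approx(stats["total_area_um2"])
        assert pair_total == pytest.approx(stats["total_area_um2"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            area_stats_by_type(table_from([]))


class TestDensity:
    def test_counts_over_volume(self):
        table = table_from([{"pre_type": "CF", "synapse_id": i} for i in range(8)])
        dens = synapse_density(table, 1757.0)
        assert dens["CF-PC"] == pytest.approx(8 / 1757.0)

    def test_empty_table(self):
        assert synapse_density(table_from([]), 100.0) == {}

    def test_doubling_volume_halves_density(self):
        table = table_from([{"synapse_id": i} for i in range(10)])
        d1 = synapse_density(table, 50.0)
        d2 = synapse_density(table, 100.0)
        assert d1["PF-PC"] == pytest.approx(2 * d2["PF-PC"])

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            synapse_density(table_from([]), 0.0)


class TestBoutons:
    def test_grouped_histogram(self):
        vc_ids = [0, 0, 0, 1, 1, 2, 3]  # groups of 3, 2, 1, 1
        table = table_from([{"vc_id": v, "synapse_id": i} for i, v in enumerate(vc_ids)])
        hist, frac = bouton_multiplicity(table)
        assert hist == {1: 2, 2: 1, 3: 1}
        assert frac == pytest.approx(0.5)

    def test_all_single_synapse_boutons(self):
        table = table_from([{"vc_id": i, "synapse_id": i} for i in range(5)])
        hist, frac = bouton_multiplicity(table)
        assert frac == 0.0 and sum(hist.values()) == 5

    def test_histogram_mass_equals_bouton_count(self):
        rng = np.random.default_rng(0)
        vc_ids = rng.integers(0, 20, size=60)
        table = table_from([{"vc_id": int(v), "synapse_id": i} for i, v in enumerate(vc_ids)])
        hist, frac = bouton_multiplicity(table)
        assert sum(hist.values()) == len(np.unique(vc_ids))
        assert 0.0 <= frac <= 1.0


class TestLaminarProfile:
    def test_uniform_slab_median_ties_lower(self):
        labels = np.zeros((4, 4, 16), dtype=np.int32)
        labels[:, :, 0:10] = 1  # PC occupying slices 0..9 uniformly
        labels[labels == 0] = 2
        seg = SegmentationVolume(labels)
        types = CellTypeMap({1: CellType.PC, 2: CellType.PF})
        prof = laminar_profile(seg, types)
        assert prof["fragments"][1]["median_slice"] == 4
        assert prof["fragments"][1]["median_um"] == pytest.approx(4 * 0.05)

    def test_two_slabs_hundred_slices_apart(self):
        labels = np.zeros((4, 4, 120), dtype=np.int32)
        labels[:, :, 0:5] = 1
        labels[:, :, 100:105] = 2
        labels[labels == 0] = 3
        seg = SegmentationVolume(labels)
        types = CellTypeMap({1: CellType.PC, 2: CellType.PC, 3: CellType.PF})
        prof = laminar_profile(seg, types)
        assert prof["adjacent_distances_um"] == [pytest.approx(5.0)]

    def test_profile_counts_conserve_fragment_volume(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 4, size=(6, 6, 10)).astype(np.int32)
        seg = SegmentationVolume(labels)
        types = CellTypeMap({i: CellType.PC for i in (1, 2, 3)})
        prof = laminar_profile(seg, types)
        for seg_id, frag in prof["fragments"].items():
            assert frag["z_counts"].sum() == (labels == seg_id).sum()

    def test_no_target_fragment_rejected(self):
        seg = SegmentationVolume(np.ones((3, 3, 3), dtype=np.int32))
        with pytest.raises(ValueError):
            laminar_profile(seg, CellTypeMap({1: CellType.PF}))


class TestIntervals:
    def test_two_synapses_hundred_slices_apart(self):
        table = table_from(
            [{"loc_z": 0, "synapse_id": 0}, {"loc_z": 100, "synapse_id": 1}]
        )
        assert intersynapse_intervals(table) == [pytest.approx(5.0)]

    def test_single_synapse_contributes_nothing(self):
        assert intersynapse_intervals(table_from([{"loc_z": 10}])) == []

    def test_row_order_irrelevant(self):
        rows = [
            {"loc_z": z, "synapse_id": i, "pre_seg": 1 + (i % 2)}
            for i, z in enumerate([40, 0, 90, 10, 60, 30])
        ]
        rng = np.random.default_rng(2)
        t1 = table_from(rows)
        t2 = table_from([rows[i] for i in rng.permutation(len(rows))])
        assert sorted(intersynapse_intervals(t1)) == pytest.approx(
            sorted(intersynapse_intervals(t2))
        )


class TestConditionalConnectivity:
    def _table_from_incidence(self, incidence, pcs):
        rows = []
        for pf, row in enumerate(incidence):
            for j, connected in enumerate(row):
                if connected:
                    rows.append(
                        {"pre_seg": 100 + pf, "post_seg": pcs[j], "synapse_id": len(rows)}
                    )
        return table_from(rows)

    def test_full_connectivity_gives_probability_one(self):
        pcs = [1, 2, 3]
        incidence = [[1, 1, 1]] * 4
        out = pf_pc_conditional_connectivity(self._table_from_incidence(incidence, pcs), pcs)
        assert (out["mean"] == 1.0).all()

    def test_hand_built_incidence_matches_enumeration(self):
        pcs = [1, 2, 3]
        incidence = [
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
            [1, 0, 0],
            [0, 1, 0],
        ]
        out = pf_pc_conditional_connectivity(self._table_from_incidence(incidence, pcs), pcs)
        # exhaustive: k=1: m=0: PFs on PC1 {0,1,3}; also PC2 {0} -> 1/3
        #                  m=1: PFs on PC2 {0,2,4}; also PC3 {2} -> 1/3
        # k=2: m=0: PFs on PC1 {0,1,3}; also PC3 {1} -> 1/3
        by_k = {int(r.k): r for r in out.itertuples(index=False)}
        assert by_k[1].mean == pytest.approx(np.mean([1 / 3, 1 / 3]))
        assert by_k[2].mean == pytest.approx(1 / 3)
        assert by_k[1].n_m == 2 and by_k[2].n_m == 1

    def test_independent_random_connectivity_is_flat(self):
        rng = np.random.default_rng(3)
        p = 0.3
        pcs = list(range(1, 7))
        incidence = (rng.random((600, 6)) < p).astype(int)
        out = pf_pc_conditional_connectivity(
            self._table_from_incidence(incidence.tolist(), pcs), pcs
        )
        assert np.allclose(out["mean"], p, atol=0.07)

    def test_fewer_than_two_pcs_gives_empty_result(self):
        out = pf_pc_conditional_connectivity(table_from([{}]), [1])
        assert out.empty

    def test_multiplicity_ignored(self):
        pcs = [1, 2]
        rows = [
            {"pre_seg": 100, "post_seg": 1, "synapse_id": 0},
            {"pre_seg": 100, "post_seg": 1, "synapse_id": 1},  # duplicate synapse
            {"pre_seg": 100, "post_seg": 2, "synapse_id": 2},
        ]
        out = pf_pc_conditional_connectivity(table_from(rows), pcs)
        assert out.loc[out["k"] == 1, "mean"].iloc[0] == 1.0
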