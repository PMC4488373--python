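"""Occurrence filtering, survey absences, KDE bias and pseudoabsence draws."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from streamsdm.labels import (LabelSet, assign_presences, build_replicates,
                              default_kde_bandwidth, derive_absences, draw_pseudoabsences,
                              kde_bias_surface)
from streamsdm.units import SampleUnitGrid, StreamNetwork


@pytest.fixture
def stream_and_grid():
    net = StreamNetwork([LineString([(0, 500), (2000, 500)])])
    ids = {(r, c) for r in range(5) for c in range(10)}
    grid = SampleUnitGrid((0.0, 1000.0), 200.0, 5, 10, ids)
    return net, grid


def _records(rows):
    return pd.DataFrame(rows, columns=["x", "y", "year", "accuracy_m", "source"])


class TestAssignPresences:
    def test_far_from_stream_excluded(self, stream_and_grid):
        net, grid = stream_and_grid
        recs = _records([(100, 700, 2010, 30.0, "t")])  # 200 m from the stream
        assert assign_presences(recs, net, grid) == set()

    def test_poor_accuracy_excluded_unknown_retained(self, stream_and_grid):
        net, grid = stream_and_grid
        recs = _records([
            (100, 510, 2010, 200.0, "t"),   # documented accuracy > 160 m
            (500, 510, 2010, np.nan, "t"),  # unknown accuracy stays
        ])
        got = assign_presences(recs, net, grid)
        assert got == {grid.uid((2, 2))}

    def test_date_window_excludes_old_records(self, stream_and_grid):
        net, grid = stream_and_grid
        recs = _records([(100, 510, 2003, 30.0, "t"), (500, 510, 2010, 30.0, "t")])
        got = assign_presences(recs, net, grid, date_window=(2005, 2013))
        assert got == {grid.uid((2, 2))}
        assert assign_presences(recs, net, grid) == {grid.uid((2, 0)), grid.uid((2, 2))}

    def test_duplicates_collapse_to_one_unit(self, stream_and_grid):
        net, grid = stream_and_grid
        recs = _records([(100, 510, 2010, 30.0, "t"), (120, 520, 2011, 30.0, "t")])
        assert len(assign_presences(recs, net, grid)) == 1


class TestDeriveAbsences:
    def _surveys(self, rows):
        return pd.DataFrame(rows, columns=["unit_id", "n_night_surveys",
                                           "n_day_surveys", "detected"])

    def test_enough_night_effort_without_detection(self):
        s = self._surveys([(1, 8, 0, False)])
        assert derive_absences(s, set()) == {1}

    def test_below_both_thresholds_unlabeled(self):
        s = self._surveys([(1, 7, 4, False)])
        assert derive_absences(s, set()) == set()

    def test_presence_overrides_qualifying_absence(self):
        s = self._surveys([(1, 10, 6, False)])
        assert derive_absences(s, {1}) == set()

    def test_any_detection_blocks_absence(self):
        s = self._surveys([(2, 5, 0, False), (2, 5, 0, True)])
        assert derive_absences(s, set()) == set()

    def test_effort_accumulates_across_records(self):
        s = self._surveys([(3, 4, 0, False), (3, 4, 0, False)])
        assert derive_absences(s, set()) == {3}


class TestKdeBias:
    def test_single_presence_monotone_decay(self, full_lattice):
        """Weights fall off monotonically with distance from a single
        presence (checked away from the lattice edge, where the
        coverage correction is locally constant)."""
        center = full_lattice.uid((10, 10))
        bw = 400.0
        bias = kde_bias_surface({center}, full_lattice, bw)
        interior = [u for u in full_lattice.uids
                    if 4 <= full_lattice.rc(u)[0] <= 15 and 4 <= full_lattice.rc(u)[1] <= 15]
        pts = full_lattice.centers(interior)
        cx, cy = full_lattice.center((10, 10))
        d = np.hypot(cx - pts[:, 0], cy - pts[:, 1])
        w = bias.weights.loc[interior].to_numpy()
        order = np.argsort(d)
        # strictly decreasing with distance; equidistant units agree up
        # to the (slightly asymmetric) coverage correction
        for i in range(len(order) - 1):
            a, b = order[i], order[i + 1]
            if d[b] > d[a] + 1e-9:
                assert w[b] < w[a]
            else:
                assert w[b] == pytest.approx(w[a], rel=0.05)

    def test_uniform_presences_give_near_uniform_weights(self, full_lattice):
        bias = kde_bias_surface(set(full_lattice.uids), full_lattice,
                                bandwidth_m=full_lattice.ncols * 200.0 / 4)
        w = bias.weights
        assert w.max() / w.min() < 1.5

    def test_weights_sum_to_one(self, full_lattice):
        bias = kde_bias_surface({full_lattice.uid((3, 4))}, full_lattice, 300.0)
        assert bias.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_presences_rejected(self, full_lattice):
        with pytest.raises(ValueError):
            kde_bias_surface(set(), full_lattice, 300.0)

    def test_default_bandwidth_scales_with_spacing(self, full_lattice):
        pres = {full_lattice.uid((r, c)) for r in (0, 5, 10) for c in (0, 5, 10)}
        bw = default_kde_bandwidth(pres, full_lattice)
        assert bw == pytest.approx(2 * 5 * 200.0)


class TestDrawPseudoabsences:
    def test_drawing_all_candidates(self, full_lattice):
        bias = kde_bias_surface({full_lattice.uid((0, 0))}, full_lattice, 2000.0)
        cands = set(full_lattice.uids[:50])
        assert draw_pseudoabsences(cands, bias, 50, 0) == cands

    def test_zero_weight_units_never_drawn(self, full_lattice):
        w = pd.Series(0.0, index=full_lattice.uids)
        w.iloc[:100] = 1.0 / 100
        from streamsdm.labels import BiasSurface

        bias = BiasSurface(w, 500.0)
        dead = set(full_lattice.uids[100:])
        cands = set(full_lattice.uids)
        for seed in range(1000):
            assert not (draw_pseudoabsences(cands, bias, 5, seed) & dead)

    def test_inclusion_frequency_tracks_weight(self, full_lattice):
        """Over many seeds, how often a unit is drawn correlates with its
        bias weight (10 of 200 drawn per seed)."""
        pres = {full_lattice.uid((10, 10))}
        bias = kde_bias_surface(pres, full_lattice, 800.0)
        cands = full_lattice.uids[:200]
        counts = pd.Series(0.0, index=cands)
        for seed in range(5000):
            for u in draw_pseudoabsences(set(cands), bias, 10, seed):
                counts.loc[u] += 1
        w = bias.weights.reindex(cands)
        r = np.corrcoef(counts.to_numpy(), w.to_numpy())[0, 1]
        assert r > 0.95

    def test_oversized_request_rejected(self, full_lattice):
        bias = kde_bias_surface({full_lattice.uid((0, 0))}, full_lattice, 500.0)
        with pytest.raises(ValueError, match="candidates"):
            draw_pseudoabsences(set(full_lattice.uids[:10]), bias, 11, 0)


class TestBuildReplicates:
    def test_balance_arithmetic_at_field_scale(self):
        """791 presences and 89 verified absences need 702 pseudoabsences."""
        n = 50
        ids = {(r, c) for r in range(n) for c in range(n)}
        grid = SampleUnitGrid((0.0, n * 200.0), 200.0, n, n, ids)
        uids = grid.uids
        labels = LabelSet(set(uids[:791]), set(uids[791:880]), "current")
        bias = kde_bias_surface(labels.presence_units, grid, 2000.0)
        reps = build_replicates(labels, bias, grid, n_replicates=2, seed=1)
        for ts in reps:
            src = ts.rows["label_source"].value_counts()
            assert src["presence"] == 791
            assert src["absence"] == 89
            assert src["pseudoabsence"] == 702
            assert (ts.rows["label"] == 1).sum() == (ts.rows["label"] == 0).sum()
            pseudo = set(ts.rows.loc[ts.rows["label_source"] == "pseudoabsence", "unit_id"])
            assert not pseudo & labels.presence_units
            assert not pseudo & labels.absence_units

    def test_no_absence_model_balances_with_pseudoabsences(self, full_lattice):
        pres = set(full_lattice.uids[:100])
        labels = LabelSet(pres, set(), "potential")
        bias = kde_bias_surface(pres, full_lattice, 1500.0)
        reps = build_replicates(labels, bias, full_lattice, n_replicates=3, seed=0)
        for ts in reps:
            assert (ts.rows["label_source"] == "pseudoabsence").sum() == 100

    def test_replicates_share_labels_differ_in_pseudoabsences(self, full_lattice):
        pres = set(full_lattice.uids[:60])
        labels = LabelSet(pres, set(), "potential")
        bias = kde_bias_surface(pres, full_lattice, 1500.0)
        reps = build_replicates(labels, bias, full_lattice, n_replicates=10, seed=7)
        pseudo_sets = []
        for ts in reps:
            assert set(ts.rows.loc[ts.rows["label"] == 1, "unit_id"]) == pres
            pseudo_sets.append(frozenset(
                ts.rows.loc[ts.rows["label_source"] == "pseudoabsence", "unit_id"]))
        distinct_pairs = sum(a != b for i, a in enumerate(pseudo_sets)
                             for b in pseudo_sets[i + 1:])
        assert distinct_pairs >= 44  # >= 9 of 10 replicates pairwise distinct

    def test_bias_matching_concentration(self, full_lattice, rng):
        """Pseudoabsences concentrate where sampling effort concentrated,
        within 10 percentage points of the presences' concentration."""
        n = full_lattice.nrows
        west = [(r, c) for r in range(n) for c in range(n // 2)]
        east = [(r, c) for r in range(n) for c in range(n // 2, n)]
        pres = {full_lattice.uid(tuple(rc)) for rc in
                [west[i] for i in rng.choice(len(west), 80, replace=False)]} | \
               {full_lattice.uid(tuple(rc)) for rc in
                [east[i] for i in rng.choice(len(east), 20, replace=False)]}
        pres_frac = np.mean([full_lattice.rc(u)[1] < n // 2 for u in pres])
        cands = set(full_lattice.uids) - pres
        bias = kde_bias_surface(pres, full_lattice,
                                default_kde_bandwidth(pres, full_lattice), candidates=cands)
        hits = []
        for seed in range(200):
            drawn = draw_pseudoabsences(cands, bias, 10, seed)  # 2,000 draws total
            hits.extend(full_lattice.rc(u)[1] < n // 2 for u in drawn)
        assert np.mean(hits) == pytest.approx(pres_frac, abs=0.10)
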