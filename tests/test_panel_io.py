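import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyndag import (BinaryPanel, DEFAULT_ITEMS, DataError, EmptyTableError,
                    ItemSpec, ConfigurationError, SchemaError, SymptomPanel,
                    TransitionTable, build_transition_table, dichotomize,
                    read_panel, write_panel)

ITEM_NAMES = [it.name for it in DEFAULT_ITEMS]


def _long_df(n_participants=2, n_waves=5, rating=3):
    rows = []
    for p in range(n_participants):
        for w in range(1, n_waves + 1):
            for item in ITEM_NAMES:
                rows.append({"participant": f"S{p}", "wave": w,
                             "item": item, "rating": rating if item.startswith("P") or item.startswith("G") else 1})
    return pd.DataFrame(rows)


def _make_binary(values_by_participant, items=None):
    """values_by_participant: {pid: {wave: row or None}} with None = missing
    interview."""
    if items is None:
        first_row = next(r for d in values_by_participant.values()
                         for r in d.values() if r is not None)
        items = tuple(ItemSpec(f"V{k + 1}", "SIM", 0, 1)
                      for k in range(len(first_row)))
    n = len(items)
    waves = max(max(d) for d in values_by_participant.values())
    idx = pd.MultiIndex.from_product(
        [list(values_by_participant), range(1, waves + 1)],
        names=["participant", "wave"])
    arr = np.full((len(idx), n), np.nan)
    for k, (p, w) in enumerate(idx):
        row = values_by_participant[p].get(w)
        if row is not None:
            arr[k] = row
    df = pd.DataFrame(arr, index=idx, columns=[it.name for it in items])
    return BinaryPanel(items=items, values=df)


class TestReadPanel:
    def test_long_roundtrip_counts(self, tmp_path):
        path = tmp_path / "panel.csv"
        _long_df().to_csv(path, index=False)
        panel = read_panel(path)
        assert panel.values.size == 2 * 5 * 12
        assert panel.n_waves == 5
        assert panel.item_names == ITEM_NAMES

    def test_wide_missing_item_is_schema_error(self, tmp_path):
        path = tmp_path / "panel.csv"
        df = _long_df().pivot(index=["participant", "wave"], columns="item",
                              values="rating").reset_index()
        df = df.drop(columns=["P6"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="P6"):
            read_panel(path)

    def test_out_of_range_rating_reports_location(self, tmp_path):
        df = _long_df()
        df.loc[(df["item"] == "P3") & (df["wave"] == 2)
               & (df["participant"] == "S1"), "rating"] = 9
        path = tmp_path / "panel.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DataError, match=r"P3.*S1.*wave=2"):
            read_panel(path)

    def test_duplicate_measurement_rejected(self, tmp_path):
        df = _long_df()
        df = pd.concat([df, df.iloc[[0]]])
        path = tmp_path / "panel.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DataError, match="duplicate"):
            read_panel(path)

    def test_missing_encoded_as_na_or_empty(self, tmp_path):
        df = _long_df()
        df.loc[0, "rating"] = np.nan
        path = tmp_path / "panel.csv"
        df.to_csv(path, index=False, na_rep="NA")
        panel = read_panel(path)
        assert np.isnan(panel.values.iloc[0, 0])

    def test_write_read_roundtrip(self, tmp_path):
        path = tmp_path / "panel.csv"
        _long_df().to_csv(path, index=False)
        panel = read_panel(path)
        for fmt in ("wide", "long"):
            out = tmp_path / f"out_{fmt}.csv"
            write_panel(panel, out, fmt=fmt)
            back = read_panel(out)
            pd.testing.assert_frame_equal(panel.values, back.values)


class TestDichotomize:
    @pytest.mark.parametrize("item,rating,expected", [
        ("P1", 4, 1.0),   # at the PANSS cutoff -> present
        ("P1", 3, 0.0),   # below -> absent
        ("P1", 7, 1.0),
        ("CDSS1", 2, 1.0),  # CDSS moderate -> present
        ("CDSS1", 1, 0.0),
    ])
    def test_thresholds(self, item, rating, expected):
        idx = pd.MultiIndex.from_tuples([("a", 1), ("a", 2)],
                                        names=["participant", "wave"])
        data = {it.name: [it.low, it.low] for it in DEFAULT_ITEMS}
        data[item] = [rating, np.nan]
        panel = SymptomPanel(items=DEFAULT_ITEMS,
                             values=pd.DataFrame(data, index=idx))
        binary = dichotomize(panel)
        assert binary.values[item].iloc[0] == expected
        assert np.isnan(binary.values[item].iloc[1])  # missing preserved

    def test_missing_threshold_is_configuration_error(self):
        idx = pd.MultiIndex.from_tuples([("a", 1)],
                                        names=["participant", "wave"])
        data = {it.name: [it.low] for it in DEFAULT_ITEMS}
        panel = SymptomPanel(items=DEFAULT_ITEMS,
                             values=pd.DataFrame(data, index=idx))
        with pytest.raises(ConfigurationError, match="CDSS"):
            dichotomize(panel, thresholds={"PANSS": 4})

    def test_idempotent_on_binary_with_threshold_one(self):
        rng = np.random.default_rng(3)
        vals = {f"V{k}": rng.integers(0, 2, 6).astype(float) for k in range(3)}
        idx = pd.MultiIndex.from_product([["a", "b"], [1, 2, 3]],
                                         names=["participant", "wave"])
        items = tuple(ItemSpec(f"V{k}", "SIM", 0, 1) for k in range(3))
        panel = SymptomPanel(items=items, values=pd.DataFrame(vals, index=idx))
        once = dichotomize(panel, thresholds={"SIM": 1})
        twice = dichotomize(SymptomPanel(items=items, values=once.values),
                            thresholds={"SIM": 1})
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestTransitionTable:
    @pytest.mark.parametrize("observed,expected_rows", [
        ({1, 2, 3, 4, 5}, 4),   # complete at all five waves -> four pairs
        ({1, 2, 4}, 1),          # only the 1-2 pair is adjacent and complete
        ({3}, 0),
        ({1, 3, 5}, 0),
    ])
    def test_rows_per_participant(self, observed, expected_rows):
        waves = {w: ([1, 0] if w in observed else None) for w in range(1, 6)}
        other = {w: [0, 0] for w in range(1, 6)}
        panel = _make_binary({"a": waves, "b": other})
        table = build_transition_table(panel)
        assert (table.data["participant"] == "a").sum() == expected_rows
        assert (table.data["participant"] == "b").sum() == 4

    def test_item_level_missingness_drops_pair(self):
        waves = {w: [0, 0] for w in range(1, 4)}
        waves[2] = [0, np.nan]  # one missing item invalidates both pairs
        panel = _make_binary({"a": waves})
        with pytest.raises(EmptyTableError, match="per pair"):
            build_transition_table(panel)

    def test_row_count_matches_bruteforce_recount(self):
        rng = np.random.default_rng(42)
        panels = {}
        for p in range(30):
            waves = {}
            for w in range(1, 6):
                if rng.random() < 0.75:
                    row = rng.integers(0, 2, 4).astype(float)
                    if rng.random() < 0.1:
                        row[rng.integers(4)] = np.nan
                    waves[w] = row
                else:
                    waves[w] = None
            panels[f"S{p}"] = waves
        panel = _make_binary(panels)
        table = build_transition_table(panel)
        expected = 0
        for waves in panels.values():
            for w in range(1, 5):
                a, b = waves.get(w), waves.get(w + 1)
                if a is not None and b is not None \
                        and not np.isnan(a).any() and not np.isnan(b).any():
                    expected += 1
        assert table.n_rows == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(
        st.lists(st.one_of(st.none(),
                           st.lists(st.sampled_from([0.0, 1.0, np.nan]),
                                    min_size=2, max_size=2)),
                 min_size=2, max_size=5),
        min_size=1, max_size=6))
    def test_row_count_property_over_arbitrary_missingness(self, grids):
        panels = {f"S{k}": {w + 1: row for w, row in enumerate(waves)}
                  for k, waves in enumerate(grids)}
        expected = 0
        for waves in panels.values():
            ws = sorted(waves)
            for w in ws[:-1]:
                a, b = waves.get(w), waves.get(w + 1)
                if a is not None and b is not None \
                        and not np.isnan(a).any() and not np.isnan(b).any():
                    expected += 1
        panel = _make_binary(panels, items=tuple(
            ItemSpec(f"V{k + 1}", "SIM", 0, 1) for k in range(2)))
        if expected == 0:
            with pytest.raises(EmptyTableError):
                build_transition_table(panel)
        else:
            assert build_transition_table(panel).n_rows == expected

    def test_invariant_to_participant_order(self):
        rng = np.random.default_rng(5)
        pan = {f"S{p}": {w: rng.integers(0, 2, 3).astype(float)
                         for w in range(1, 4)} for p in range(6)}
        t1 = build_transition_table(_make_binary(pan))
        shuffled = dict(reversed(list(pan.items())))
        t2 = build_transition_table(_make_binary(shuffled))
        a = t1.data.sort_values(["participant", "pair"]).reset_index(drop=True)
        b = t2.data.sort_values(["participant", "pair"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        table = TransitionTable.from_arrays(rng.integers(0, 2, (10, 3)),
                                            rng.integers(0, 2, (10, 3)))
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = TransitionTable.read_csv(path)
        assert back.var_names == table.var_names
        np.testing.assert_array_equal(back.X0, table.X0)
        np.testing.assert_array_equal(back.X1, table.X1)
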