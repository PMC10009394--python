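"""Symptom panel input, dichotomization and the transition table.

The analysis consumes a participant x wave x item panel of ordinal symptom
ratings.  Ratings are dichotomized per instrument (PANSS items are coded
present when rated at least 4, i.e. clearly present at moderate severity;
CDSS items, scored 0-3, default to a cutpoint of 2) and the binary panel is
stacked into a *transition table*: one row per (participant, adjacent wave
pair) with complete data on both waves.  Participants observed at several
adjacent pairs contribute one row per pair; rows are treated as exchangeable
observations of a stationary transition process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A declared item is missing or the schema is inconsistent."""


class DataError(ValueError):
    """Ratings are out of range, duplicated or otherwise malformed."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (thresholds, hyperparameters...)."""


class EmptyTableError(ValueError):
    """No participant has complete data on any adjacent wave pair."""


@dataclass(frozen=True)
class ItemSpec:
    """One symptom item: name, instrument and admissible rating range."""

    name: str
    instrument: str  # "PANSS" | "CDSS"
    low: int
    high: int
    label: str = ""


#: The 12 network variables: nine PANSS items (rated 1-7) and three CDSS
#: items (rated 0-3).
DEFAULT_ITEMS: tuple[ItemSpec, ...] = (
    ItemSpec("P1", "PANSS", 1, 7, "delusions"),
    ItemSpec("P3", "PANSS", 1, 7, "hallucinations"),
    ItemSpec("P4", "PANSS", 1, 7, "excitement"),
    ItemSpec("P5", "PANSS", 1, 7, "grandiosity"),
    ItemSpec("P6", "PANSS", 1, 7, "suspiciousness"),
    ItemSpec("P7", "PANSS", 1, 7, "hostility"),
    ItemSpec("G2", "PANSS", 1, 7, "anxiety"),
    ItemSpec("G11", "PANSS", 1, 7, "poor_attention"),
    ItemSpec("G14", "PANSS", 1, 7, "poor_impulse_control"),
    ItemSpec("CDSS1", "CDSS", 0, 3, "depressed_mood"),
    ItemSpec("CDSS2", "CDSS", 0, 3, "hopelessness"),
    ItemSpec("CDSS3", "CDSS", 0, 3, "self_depreciation"),
)

#: Dichotomization cutpoints per instrument: value >= cut maps to 1.
DEFAULT_THRESHOLDS: dict[str, int] = {"PANSS": 4, "CDSS": 2}


def _validate_axes(values: pd.DataFrame, items: tuple[ItemSpec, ...]) -> None:
    names = [it.name for it in items]
    if len(set(names)) != len(names):
        raise SchemaError("item names must be unique")
    if list(values.columns) != names:
        raise SchemaError("panel columns do not match declared items")
    waves = sorted(values.index.get_level_values("wave").unique())
    if waves != list(range(1, len(waves) + 1)):
        raise DataError(f"wave indices must be consecutive from 1, got {waves}")


@dataclass
class SymptomPanel:
    """Ordinal ratings on a full participant x wave grid.

    ``values`` has a (participant, wave) MultiIndex covering every
    participant at every wave (missing interviews are NaN rows) and one
    float column per item, NaN encoding a missing rating.
    """

    items: tuple[ItemSpec, ...]
    values: pd.DataFrame

    def __post_init__(self):
        self.items = tuple(self.items)
        _validate_axes(self.values, self.items)
        for it in self.items:
            col = self.values[it.name]
            bad = col.notna() & ((col < it.low) | (col > it.high))
            if bad.any():
                part, wave = bad[bad].index[0]
                raise DataError(
                    f"rating {col[bad].iloc[0]:g} for item {it.name} out of range "
                    f"[{it.low}, {it.high}] at participant={part!r}, wave={wave}"
                )

    @property
    def participants(self) -> list:
        return list(self.values.index.get_level_values("participant").unique())

    @property
    def n_waves(self) -> int:
        return int(self.values.index.get_level_values("wave").max())

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]


@dataclass
class BinaryPanel:
    """Same axes as :class:`SymptomPanel` with values in {0, 1, NaN}."""

    items: tuple[ItemSpec, ...]
    values: pd.DataFrame

    def __post_init__(self):
        self.items = tuple(self.items)
        _validate_axes(self.values, self.items)
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
        if not ok.all():
            raise DataError("binary panel contains values other than 0/1/missing")

    participants = SymptomPanel.participants
    n_waves = SymptomPanel.n_waves
    item_names = SymptomPanel.item_names


def _full_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Reindex to the full participant x wave product, keeping first-seen
    participant order."""
    parts = df.index.get_level_values("participant").unique()
    waves = range(1, int(df.index.get_level_values("wave").max()) + 1)
    idx = pd.MultiIndex.from_product([parts, waves], names=["participant", "wave"])
    return df.reindex(idx)


def read_panel(path, items: tuple[ItemSpec, ...] = DEFAULT_ITEMS,
               fmt: str | None = None) -> SymptomPanel:
    """Read a symptom panel from CSV.

    Two dialects are accepted:

    * long — columns ``participant, wave, item, rating``
    * wide — columns ``participant, wave, <item>, <item>, ...``

    ``fmt`` may force ``"long"`` or ``"wide"``; by default the dialect is
    sniffed from the header.  Missing ratings are empty fields or ``NA``.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    cols = set(df.columns)
    if not {"participant", "wave"} <= cols:
        raise SchemaError("panel file must have 'participant' and 'wave' columns")
    if fmt is None:
        fmt = "long" if {"item", "rating"} <= cols else "wide"

    names = [it.name for it in items]
    if fmt == "long":
        if not {"item", "rating"} <= cols:
            raise SchemaError("long format requires 'item' and 'rating' columns")
        seen = set(df["item"].unique())
        missing = [n for n in names if n not in seen]
        if missing:
            raise SchemaError(f"declared items absent from file: {missing}")
        unknown = seen - set(names)
        if unknown:
            raise SchemaError(f"undeclared items present in file: {sorted(unknown)}")
        dup = df.duplicated(subset=["participant", "wave", "item"])
        if dup.any():
            r = df[dup].iloc[0]
            raise DataError(
                f"duplicate rating for participant={r['participant']!r}, "
                f"wave={r['wave']}, item={r['item']}"
            )
        wide = df.pivot(index=["participant", "wave"], columns="item",
                        values="rating")
        wide = wide.reindex(columns=names)
    elif fmt == "wide":
        missing = [n for n in names if n not in cols]
        if missing:
            raise SchemaError(f"declared items absent from file: {missing}")
        dup = df.duplicated(subset=["participant", "wave"])
        if dup.any():
            r = df[dup].iloc[0]
            raise DataError(
                f"duplicate row for participant={r['participant']!r}, wave={r['wave']}"
            )
        wide = df.set_index(["participant", "wave"])[names]
    else:
        raise ValueError(f"unknown panel format {fmt!r}")

    wide.columns.name = None
    try:
        wide = wide.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"unparseable rating value: {exc}") from exc
    wide = _full_grid(wide.sort_index())
    return SymptomPanel(items=tuple(items), values=wide)


def write_panel(panel: SymptomPanel | BinaryPanel, path, fmt: str = "wide") -> None:
    """Write a panel back to CSV in the long or wide dialect, dropping
    fully-missing interview rows."""
    vals = panel.values
    observed = vals.notna().any(axis=1)
    out = vals[observed].reset_index()
    if fmt == "wide":
        out.to_csv(path, index=False)
    elif fmt == "long":
        long = out.melt(id_vars=["participant", "wave"], var_name="item",
                        value_name="rating").dropna(subset=["rating"])
        long.sort_values(["participant", "wave", "item"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown panel format {fmt!r}")


def dichotomize(panel: SymptomPanel,
                thresholds: dict[str, float] | None = None) -> BinaryPanel:
    """Map ordinal ratings to presence/absence.

    ``thresholds`` maps instrument (or item name, which takes precedence)
    to a cutpoint; rating >= cutpoint -> 1, below -> 0, missing stays
    missing.  Defaults: PANSS >= 4, CDSS >= 2.
    """
    thr = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    out = {}
    for it in panel.items:
        cut = thr.get(it.name, thr.get(it.instrument))
        if cut is None:
            raise ConfigurationError(
                f"no dichotomization threshold for item {it.name} "
                f"(instrument {it.instrument})"
            )
        col = panel.values[it.name]
        out[it.name] = (col >= cut).astype(float).where(col.notna())
    binary_items = tuple(
        ItemSpec(it.name, it.instrument, 0, 1, it.label) for it in panel.items
    )
    return BinaryPanel(items=binary_items, values=pd.DataFrame(out, index=panel.values.index))


@dataclass
class TransitionTable:
    """Stacked adjacent-wave pairs, complete by construction.

    ``data`` holds one row per (participant, pair index p) with columns
    ``participant, pair, <v>_t0 ..., <v>_t1 ...``; pair ``p`` pairs wave
    ``p`` with wave ``p + 1``.
    """

    var_names: list[str]
    data: pd.DataFrame

    def __post_init__(self):
        expected = (["participant", "pair"]
                    + [f"{v}_t0" for v in self.var_names]
                    + [f"{v}_t1" for v in self.var_names])
        if list(self.data.columns) != expected:
            raise DataError("transition table columns inconsistent with var_names")
        if self.data[expected[2:]].isna().any().any():
            raise DataError("transition table must have no missing values")

    @property
    def n(self) -> int:
        return len(self.var_names)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def X0(self) -> np.ndarray:
        """Slice-1 values, shape (rows, n), uint8."""
        return self.data[[f"{v}_t0" for v in self.var_names]].to_numpy(dtype=np.uint8)

    @property
    def X1(self) -> np.ndarray:
        """Slice-2 values, shape (rows, n), uint8."""
        return self.data[[f"{v}_t1" for v in self.var_names]].to_numpy(dtype=np.uint8)

    @classmethod
    def from_arrays(cls, X0, X1, var_names=None, participants=None,
                    pairs=None) -> "TransitionTable":
        X0 = np.asarray(X0, dtype=np.uint8)
        X1 = np.asarray(X1, dtype=np.uint8)
        if X0.shape != X1.shape or X0.ndim != 2:
            raise DataError("X0 and X1 must be equal-shape 2-d arrays")
        rows, n = X0.shape
        if var_names is None:
            var_names = [f"V{j + 1}" for j in range(n)]
        if participants is None:
            participants = [f"r{i}" for i in range(rows)]
        if pairs is None:
            pairs = np.ones(rows, dtype=int)
        df = pd.DataFrame({"participant": list(participants), "pair": list(pairs)})
        for j, v in enumerate(var_names):
            df[f"{v}_t0"] = X0[:, j]
        for j, v in enumerate(var_names):
            df[f"{v}_t1"] = X1[:, j]
        return cls(var_names=list(var_names), data=df)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        for c in out.columns[2:]:
            out[c] = out[c].astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TransitionTable":
        df = pd.read_csv(path)
        t0 = [c for c in df.columns if c.endswith("_t0")]
        var_names = [c[:-3] for c in t0]
        return cls(var_names=var_names, data=df)


def build_transition_table(panel: BinaryPanel) -> TransitionTable:
    """Stack every adjacent wave pair with complete data on both waves.

    A participant contributes row ``p`` iff all ``2n`` values at waves
    ``p`` and ``p + 1`` are observed; rows are sorted by (participant
    first-seen order, pair index).
    """
    T = panel.n_waves
    if T < 2:
        raise DataError("at least two waves are required")
    names = panel.item_names
    parts = panel.participants
    n = len(names)
    arr = panel.values.to_numpy(dtype=float).reshape(len(parts), T, n)
    complete = ~np.isnan(arr).any(axis=2)  # (participants, waves)

    rows_part, rows_pair, rows_x0, rows_x1 = [], [], [], []
    for pi, part in enumerate(parts):
        for p in range(T - 1):
            if complete[pi, p] and complete[pi, p + 1]:
                rows_part.append(part)
                rows_pair.append(p + 1)
                rows_x0.append(arr[pi, p])
                rows_x1.append(arr[pi, p + 1])
    if not rows_part:
        per_pair = {
            p + 1: int((complete[:, p] & complete[:, p + 1]).sum())
            for p in range(T - 1)
        }
        raise EmptyTableError(
            f"no participant has complete data on any adjacent wave pair "
            f"(complete rows per pair: {per_pair})"
        )
    X0 = np.asarray(rows_x0, dtype=np.uint8)
    X1 = np.asarray(rows_x1, dtype=np.uint8)
    return TransitionTable.from_arrays(X0, X1, var_names=names,
                                       participants=rows_part, pairs=rows_pair)
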