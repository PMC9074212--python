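"""Variable schema, crash records and dataset I/O.

The unit of analysis is a motor vehicle crash (MVC) attended by an emergency
ambulance.  Each crash carries a Medical Priority Dispatch System (MPDS)
Protocol 29 dispatch code, a set of categorical crash characteristics that a
bystander could report over the phone (road surface, rollover, anyone
trapped, ...), optional clinical fields used to derive the outcome, and a
binary outcome label: whether a lights-and-sirens (L&S) ambulance response
was needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .labelling import ClinicalProfile

#: Reserved category label for an absent value.  Missing values float as a
#: category of their own during tree growth.
MISSING = "__missing__"

KINDS = ("dichotomous", "nominal", "ordinal", "continuous")


class SchemaError(ValueError):
    """A record or file does not conform to the declared variable schema."""


@dataclass
class VariableSpec:
    """Declaration of one predictor variable.

    Parameters
    ----------
    name:
        Column identifier.
    kind:
        ``dichotomous``, ``nominal``, ``ordinal`` or ``continuous``.
        Ordinal categories carry their order in ``categories``.
    categories:
        Ordered list of category labels.  For a continuous variable this is
        empty until :meth:`fit_bins` derives equal-frequency bins.
    missing_label:
        Reserved label for absent values; never listed in ``categories``.
    bins:
        Number of equal-frequency bins for a continuous variable.
    bin_edges:
        Fitted bin edges (continuous only); present after :meth:`fit_bins`.
    """

    name: str
    kind: str
    categories: list[str] = field(default_factory=list)
    missing_label: str = MISSING
    bins: int = 10
    bin_edges: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if len(set(self.categories)) != len(self.categories):
            raise SchemaError(f"duplicate category labels in variable {self.name!r}")
        if self.missing_label in self.categories:
            raise SchemaError(f"missing label shadows a category in {self.name!r}")
        if self.kind == "continuous" and self.bins < 2:
            raise SchemaError(f"continuous variable {self.name!r} needs >= 2 bins")

    @property
    def is_binned(self) -> bool:
        return self.kind != "continuous" or self.bin_edges is not None

    def fit_bins(self, values: Sequence[float]) -> None:
        """Derive equal-frequency bins from observed raw values.

        CHAID needs categorical predictors, so continuous variables are
        discretised once at load time; the fitted edges are kept on the spec
        so the same binning applies to later records.
        """
        if self.kind != "continuous":
            raise SchemaError(f"{self.name!r} is not continuous")
        arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
        if arr.size == 0:
            raise SchemaError(f"no observed values to bin for {self.name!r}")
        qs = np.linspace(0.0, 1.0, self.bins + 1)
        edges = np.unique(np.quantile(arr, qs))
        if edges.size < 2:  # constant column: single degenerate bin
            edges = np.array([edges[0], edges[0]])
        self.bin_edges = [float(e) for e in edges]
        self.categories = [
            f"[{self.bin_edges[i]:g}, {self.bin_edges[i + 1]:g}{')' if i < len(edges) - 2 else ']'}"
            for i in range(len(self.bin_edges) - 1)
        ]

    def bin_value(self, value: Optional[float]) -> str:
        """Map a raw continuous value to its fitted bin label."""
        if self.bin_edges is None:
            raise SchemaError(f"continuous variable {self.name!r} has no fitted bins")
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return self.missing_label
        idx = int(np.searchsorted(self.bin_edges, value, side="right")) - 1
        idx = min(max(idx, 0), len(self.categories) - 1)
        return self.categories[idx]

    def validate_value(self, value: str) -> bool:
        return value == self.missing_label or value in self.categories


@dataclass
class CrashRecord:
    """One MVC: dispatch code, crash characteristics, optional clinical data."""

    mpds_code: str
    features: dict[str, str] = field(default_factory=dict)
    clinical: Optional[ClinicalProfile] = None
    label: Optional[int] = None


class Dataset:
    """A schema plus a list of conforming crash records.

    Internally the features are also held as a :class:`pandas.DataFrame` of
    category strings (one column per variable, plus ``mpds_code`` and
    ``label``), which is what the tree grower consumes.
    """

    MPDS = "mpds_code"
    LABEL = "label"

    def __init__(self, schema: Sequence[VariableSpec], records: Iterable[CrashRecord],
                 validate: bool = True):
        self.schema = list(schema)
        self.records = list(records)
        self._by_name = {v.name: v for v in self.schema}
        if len(self._by_name) != len(self.schema):
            raise SchemaError("duplicate variable names in schema")
        if validate:
            self._validate()
        self._frame: Optional[pd.DataFrame] = None

    def _validate(self) -> None:
        mpds = self._by_name.get(self.MPDS)
        for i, rec in enumerate(self.records):
            if mpds is not None and not mpds.validate_value(rec.mpds_code):
                raise SchemaError(
                    f"record {i}: unknown MPDS code {rec.mpds_code!r}; "
                    f"valid Protocol 29 codes are {mpds.categories}"
                )
            for name, value in rec.features.items():
                spec = self._by_name.get(name)
                if spec is None:
                    raise SchemaError(f"record {i}: undeclared variable {name!r}")
                if spec.kind == "continuous":
                    continue  # raw values binned in from_frame / read_dataset
                if not spec.validate_value(value):
                    raise SchemaError(
                        f"record {i}: value {value!r} not a declared category of {name!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CrashRecord]:
        return iter(self.records)

    def variable(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    @property
    def labelled(self) -> bool:
        return all(r.label is not None for r in self.records)

    def frame(self) -> pd.DataFrame:
        """Feature matrix as category strings; label column may hold NaN."""
        if self._frame is None:
            cols: dict[str, list] = {self.MPDS: [r.mpds_code for r in self.records]}
            for spec in self.schema:
                if spec.name == self.MPDS:
                    continue
                cols[spec.name] = [
                    r.features.get(spec.name, spec.missing_label) for r in self.records
                ]
            cols[self.LABEL] = [r.label for r in self.records]
            self._frame = pd.DataFrame(cols)
        return self._frame

    def labels(self) -> np.ndarray:
        if not self.labelled:
            raise ValueError("dataset has unlabelled records")
        return np.array([r.label for r in self.records], dtype=np.int64)

    def with_labels(self, labels: Sequence[int]) -> "Dataset":
        if len(labels) != len(self.records):
            raise ValueError("label vector length mismatch")
        recs = [
            CrashRecord(r.mpds_code, dict(r.features), r.clinical, int(lab))
            for r, lab in zip(self.records, labels)
        ]
        return Dataset(self.schema, recs, validate=False)


# ---------------------------------------------------------------------------
# The study's variable schema

def mpds_protocol29_codes() -> list[str]:
    from .fixtures import load_table2_fixture

    return [row.category for row in load_table2_fixture().rows]


def table1_schema(time_bins: int = 10) -> list[VariableSpec]:
    """The study's predictor schema: MPDS code plus crash characteristics.

    Dichotomous/nominal category labels follow the marginal tables; the
    posted speed limit is ordinal over Perth's mandated 50-110 km/h zones and
    time of day is continuous (binned equal-frequency at load time).
    """
    dichotomous = {
        "accident_type": ["Intersection", "Midblock"],
        "airbag_deployed": ["Any airbag deployed", "No airbag deployed"],
        "anyone_ejected": ["Anyone ejected", "No one ejected"],
        "anyone_not_ambulant": ["Anyone not ambulant", "Everyone ambulant"],
        "anyone_trapped": ["Anyone trapped", "No one trapped"],
        "child": ["Anyone aged <= 12 years", "Everyone aged >= 13 years"],
        "older": ["Any aged >= 75 years", "Everyone aged <= 74 years"],
        "raining": ["Raining", "Clear"],
        "road_alignment": ["Curve", "Straight"],
        "road_surface": ["Sealed", "Unsealed"],
        "rollover": ["Any vehicle rolled", "No vehicle rolled"],
        "single_v_multi_vehicle": ["Single vehicle", "2 or more vehicles"],
        "vulnerable_road_user": ["Vulnerable", "Motor vehicle occupant"],
    }
    nominal = {
        "atmosphere": ["Clear", "Dust/Smoke", "Fog/Mist", "Fog/smoke/dust",
                       "Overcast", "Raining"],
        "day_of_week": ["Sunday", "Monday", "Tuesday", "Wednesday", "Thursday",
                        "Friday", "Saturday"],
        "lighting": ["Daylight", "Dawn/Dusk", "Dark - street lights on",
                     "Dark - street lights off", "Dark - street lights not provided"],
        "road_grade": ["Level", "Crest of hill", "Slope"],
        "traffic_control": ["Traffic lights", "Stop sign", "Give way sign",
                            "Zebra crossing", "Railway crossing", "School crossing",
                            "No signal or control"],
        "type_of_intersection": ["4-way", "3-way (T-junction)", "Roundabout",
                                 "Bridge", "Rail Crossing", "Driveway"],
    }
    schema = [VariableSpec(Dataset.MPDS, "nominal", mpds_protocol29_codes())]
    for name, cats in dichotomous.items():
        schema.append(VariableSpec(name, "dichotomous", cats))
    for name, cats in nominal.items():
        schema.append(VariableSpec(name, "nominal", cats))
    schema.append(VariableSpec("speed_limit", "ordinal",
                               ["50", "60", "70", "80", "90", "100", "110"]))
    schema.append(VariableSpec("time_of_day", "continuous", bins=time_bins))
    return schema


# ---------------------------------------------------------------------------
# Schema JSON round-trip

def schema_to_json(schema: Sequence[VariableSpec], path: str | Path) -> None:
    payload = [
        {
            "name": v.name, "kind": v.kind, "categories": v.categories,
            "missing_label": v.missing_label, "bins": v.bins, "bin_edges": v.bin_edges,
        }
        for v in schema
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def schema_from_json(path: str | Path) -> list[VariableSpec]:
    payload = json.loads(Path(path).read_text())
    return [VariableSpec(**entry) for entry in payload]


# ---------------------------------------------------------------------------
# CSV I/O

def _parse_time(value: str) -> float:
    """'hh:mm' -> minutes after midnight; plain numbers pass through."""
    if ":" in value:
        hh, mm = value.split(":")
        return int(hh) * 60 + int(mm)
    return float(value)


def from_frame(df: pd.DataFrame, schema: Sequence[VariableSpec],
               unknown: str = "error") -> Dataset:
    """Build a Dataset from a raw DataFrame of strings.

    Continuous columns are parsed numerically and binned equal-frequency
    (fitting edges if the spec has none).  ``unknown`` controls how an
    undeclared category value is handled: ``"error"`` raises a
    :class:`SchemaError` naming the row and column, ``"missing"`` maps it to
    the missing label.
    """
    if unknown not in ("error", "missing"):
        raise ValueError("unknown must be 'error' or 'missing'")
    by_name = {v.name: v for v in schema}
    if Dataset.MPDS not in by_name:
        raise SchemaError("schema must declare the MPDS code variable")
    df = df.copy()

    for spec in schema:
        if spec.name not in df.columns:
            df[spec.name] = spec.missing_label
            continue
        col = df[spec.name]
        if spec.kind == "continuous":
            observed = {
                str(v).strip() for v in col
                if not pd.isna(v) and str(v).strip() not in ("", spec.missing_label)
            }
            if spec.categories and observed <= set(spec.categories):
                # already-binned column (e.g. a written dataset read back)
                df[spec.name] = [
                    spec.missing_label
                    if pd.isna(v) or str(v).strip() in ("", spec.missing_label)
                    else str(v).strip()
                    for v in col
                ]
                continue
            raw = [
                None if (pd.isna(v) or str(v).strip() in ("", spec.missing_label))
                else _parse_time(str(v).strip())
                for v in col
            ]
            if spec.bin_edges is None:
                spec.fit_bins([v for v in raw if v is not None])
            df[spec.name] = [spec.bin_value(v) for v in raw]
        else:
            values = col.astype("object").where(~pd.isna(col), spec.missing_label)
            values = values.map(lambda v: str(v).strip() or spec.missing_label)
            bad = values[~values.map(spec.validate_value)]
            if len(bad):
                if unknown == "error":
                    row = bad.index[0]
                    hint = ""
                    if spec.name == Dataset.MPDS:
                        hint = f"; valid Protocol 29 codes: {', '.join(spec.categories)}"
                    raise SchemaError(
                        f"row {row}, column {spec.name!r}: "
                        f"{bad.iloc[0]!r} is not a declared category{hint}"
                    )
                values[bad.index] = spec.missing_label
            df[spec.name] = values

    # clinical columns: 'priority_ls', 'any_death' (0/1) plus any 'ind_<name>'
    # indicator-flag columns build a ClinicalProfile per row
    clinical: list[Optional[ClinicalProfile]] = [None] * len(df)
    if "priority_ls" in df.columns and "any_death" in df.columns:
        def _bool(v):
            return None if pd.isna(v) or str(v).strip() == "" else bool(int(float(v)))

        flag_cols = [c for c in df.columns if c.startswith("ind_")]
        for i in range(len(df)):
            flags = {}
            for c in flag_cols:
                b = _bool(df[c].iloc[i])
                if b is not None:
                    flags[c[len("ind_"):]] = b
            clinical[i] = ClinicalProfile(
                from_scene_priority_ls=_bool(df["priority_ls"].iloc[i]),
                any_death=_bool(df["any_death"].iloc[i]),
                indicator_flags=flags,
            )

    labels: list[Optional[int]] = [None] * len(df)
    if Dataset.LABEL in df.columns:
        for i, v in enumerate(df[Dataset.LABEL]):
            if pd.isna(v) or str(v).strip() == "":
                continue
            labels[i] = int(float(v))
            if labels[i] not in (0, 1):
                raise SchemaError(f"row {df.index[i]}: label must be 0 or 1")

    records = []
    feature_names = [v.name for v in schema if v.name != Dataset.MPDS]
    cols = {n: [str(v) for v in df[n].to_numpy(dtype=object)] for n in feature_names}
    mpds_col = [str(v) for v in df[Dataset.MPDS].to_numpy(dtype=object)]
    for i in range(len(df)):
        records.append(CrashRecord(
            mpds_code=mpds_col[i],
            features={n: cols[n][i] for n in feature_names},
            clinical=clinical[i],
            label=labels[i],
        ))
    return Dataset(schema, records)


def read_dataset(path: str | Path, schema: Sequence[VariableSpec],
                 unknown: str = "error") -> Dataset:
    """Read a crash dataset from a UTF-8 CSV with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return from_frame(df, schema, unknown=unknown)


def write_dataset(data: Dataset, path: str | Path) -> None:
    """Write a dataset to CSV; read_dataset on the result round-trips."""
    df = data.frame().copy()
    if not data.labelled:
        df[Dataset.LABEL] = ["" if v is None else v for v in df[Dataset.LABEL]]
    df.to_csv(path, index=False)
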