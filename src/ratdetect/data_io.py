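"""Tabular and geometric I/O for the detection-parameter pipeline.

All coordinates are planar metres in an arbitrary local Cartesian frame
(x = easting, y = northing); nights are 0-based integer sampling occasions.
CSV files are comma-separated UTF-8 with a header row and '.' decimals, so
that synthetic fixtures round-trip byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape, mapping

DEVICE_TYPES = ("baitstation", "chewcard", "waxtag")


class DataFormatError(ValueError):
    """A file does not conform to the documented CSV/GeoJSON schema."""


class DataConsistencyError(ValueError):
    """Records are individually well-formed but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Study area


@dataclass(frozen=True)
class StudyArea:
    """A single closed polygon delimiting the management area.

    The ring must be simple (non-self-intersecting) and enclose a strictly
    positive area. Only the exterior ring is used; interior rings are
    rejected at read time.
    """

    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise DataFormatError("study-area ring must be simple with area > 0")
        if len(self.polygon.interiors) > 0:
            raise DataFormatError("interior rings are not supported")

    @property
    def area_ha(self) -> float:
        return self.polygon.area / 1e4

    @classmethod
    def square(cls, hectares: float) -> "StudyArea":
        """Axis-aligned square of the requested area, anchored at the origin.

        Stands in for a real management polygon so that no GIS data is
        required anywhere in the pipeline.
        """
        if not hectares > 0:
            raise ValueError(f"hectares must be > 0, got {hectares}")
        side = float(np.sqrt(hectares * 1e4))
        return cls(Polygon([(0, 0), (side, 0), (side, side), (0, side)]))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "StudyArea":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        if obj.get("type") != "Polygon":
            raise DataFormatError(f"expected a GeoJSON Polygon, got {obj.get('type')!r}")
        if len(obj.get("coordinates", [])) > 1:
            raise DataFormatError("polygons with interior rings are not supported")
        return cls(shape(obj))

    def to_geojson(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(mapping(self.polygon), fh)


def square_area(hectares: float) -> StudyArea:
    """Convenience wrapper for :meth:`StudyArea.square`."""
    return StudyArea.square(hectares)


# ---------------------------------------------------------------------------
# Internal CSV helpers


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path, dtype=float) -> np.ndarray:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & ~df[col].isna() | df[col].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataFormatError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r} "
            f"at data row {row}"
        )
    return out.to_numpy(dtype=dtype)


# ---------------------------------------------------------------------------
# Telemetry


@dataclass
class TelemetryTable:
    """Per-rat VHF location fixes: rat_id, sex (male=0 / female=1), night, x, y."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.empty:
            raise DataFormatError("telemetry table is empty")
        if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise DataFormatError("telemetry coordinates must be finite")
        if not df["sex"].isin([0, 1]).all():
            raise DataFormatError("sex must be coded male=0 / female=1")
        per_rat = df.groupby("rat_id")["sex"].nunique()
        if (per_rat > 1).any():
            bad = per_rat[per_rat > 1].index.tolist()
            raise DataConsistencyError(f"sex differs within rat_id(s) {bad}")

    @property
    def rat_ids(self) -> list[str]:
        return sorted(self.df["rat_id"].unique())

    def sexes(self) -> pd.Series:
        """Sex per rat_id (constant within a rat by construction)."""
        return self.df.groupby("rat_id")["sex"].first()


def read_telemetry(path: str | Path) -> TelemetryTable:
    df = pd.read_csv(path, dtype={"rat_id": str})
    _require_columns(df, ["rat_id", "sex", "night", "x", "y"], path)
    out = pd.DataFrame(
        {
            "rat_id": df["rat_id"].astype(str),
            "sex": _numeric(df, "sex", path, dtype=int),
            "night": _numeric(df, "night", path, dtype=int),
            "x": _numeric(df, "x", path),
            "y": _numeric(df, "y", path),
        }
    )
    return TelemetryTable(out)


def write_telemetry(tel: TelemetryTable, path: str | Path) -> None:
    tel.df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Devices


def _parse_nights(spec: str, path="<devices>") -> frozenset[int]:
    """Parse an availability field: ';'-separated tokens, each "a" or "a-b"."""
    nights: set[int] = set()
    for tok in str(spec).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        if "-" in tok:
            try:
                a, b = tok.split("-")
                a, b = int(a), int(b)
            except ValueError as exc:
                raise DataFormatError(f"{path}: bad night range {tok!r}") from exc
            if b < a:
                raise DataFormatError(f"{path}: empty night range {tok!r}")
            nights.update(range(a, b + 1))
        else:
            try:
                nights.add(int(tok))
            except ValueError as exc:
                raise DataFormatError(f"{path}: bad night token {tok!r}") from exc
    if not nights:
        raise DataFormatError(f"{path}: empty availability {spec!r}")
    return frozenset(nights)


def _format_nights(nights: frozenset[int]) -> str:
    """Canonical compact encoding (sorted, maximal inclusive ranges)."""
    seq = sorted(nights)
    parts: list[str] = []
    start = prev = seq[0]
    for n in seq[1:] + [None]:  # type: ignore[list-item]
        if n is not None and n == prev + 1:
            prev = n
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        if n is not None:
            start = prev = n
    return ";".join(parts)


@dataclass
class DeviceTable:
    """Deployed devices: device_id, device_type, x, y and nightly availability."""

    df: pd.DataFrame
    availability: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        if df["device_id"].duplicated().any():
            dup = df.loc[df["device_id"].duplicated(), "device_id"].tolist()
            raise DataConsistencyError(f"duplicate device_id(s) {dup}")
        bad = set(df["device_type"]) - set(DEVICE_TYPES)
        if bad:
            raise DataFormatError(f"unknown device_type(s) {sorted(bad)}")
        missing = set(df["device_id"]) - set(self.availability)
        if missing:
            raise DataConsistencyError(f"no availability for device(s) {sorted(missing)}")

    @property
    def device_ids(self) -> list[str]:
        return self.df["device_id"].tolist()


def read_devices(path: str | Path) -> DeviceTable:
    df = pd.read_csv(path, dtype={"device_id": str, "device_type": str, "nights": str})
    _require_columns(df, ["device_id", "device_type", "x", "y", "nights"], path)
    avail = {
        str(r.device_id): _parse_nights(r.nights, path) for r in df.itertuples()
    }
    out = pd.DataFrame(
        {
            "device_id": df["device_id"].astype(str),
            "device_type": df["device_type"].astype(str),
            "x": _numeric(df, "x", path),
            "y": _numeric(df, "y", path),
        }
    )
    return DeviceTable(out, avail)


def write_devices(dev: DeviceTable, path: str | Path) -> None:
    df = dev.df.copy()
    df["nights"] = [_format_nights(dev.availability[d]) for d in df["device_id"]]
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Encounter / interaction logs


@dataclass
class EncounterLog:
    """Nightly binary encounter outcomes per (rat, device, night)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        key = self.df[["rat_id", "device_id", "night"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].to_records(index=False).tolist()
            raise DataConsistencyError(
                f"multiple encounter records for (rat, device, night) {dup[:5]}"
            )
        if not self.df["encountered"].isin([0, 1]).all():
            raise DataFormatError("encountered must be 0/1")

    def validate_against(self, devices: DeviceTable) -> None:
        known = set(devices.device_ids)
        unknown = set(self.df["device_id"]) - known
        if unknown:
            raise DataConsistencyError(f"encounters reference unknown device(s) {sorted(unknown)}")
        bad = [
            (r.rat_id, r.device_id, r.night)
            for r in self.df.itertuples()
            if r.night not in devices.availability[r.device_id]
        ]
        if bad:
            raise DataConsistencyError(
                f"encounters on nights outside device availability: {bad[:5]}"
            )


@dataclass
class InteractionLog:
    """Nightly binary interaction outcomes for encountered (rat, device, night)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.df["interacted"].isin([0, 1]).all():
            raise DataFormatError("interacted must be 0/1")

    def validate_against(self, encounters: EncounterLog) -> None:
        enc = encounters.df
        encountered = set(
            map(tuple, enc.loc[enc["encountered"] == 1, ["rat_id", "device_id", "night"]].to_numpy())
        )
        bad = [
            (r.rat_id, r.device_id, r.night)
            for r in self.df.itertuples()
            if (r.rat_id, r.device_id, r.night) not in encountered
        ]
        if bad:
            raise DataConsistencyError(
                f"interaction records without a matching encounter: {bad[:5]}"
            )


def read_encounters(path: str | Path, devices: DeviceTable | None = None) -> EncounterLog:
    df = pd.read_csv(path, dtype={"rat_id": str, "device_id": str})
    _require_columns(df, ["rat_id", "device_id", "night", "encountered"], path)
    out = pd.DataFrame(
        {
            "rat_id": df["rat_id"].astype(str),
            "device_id": df["device_id"].astype(str),
            "night": _numeric(df, "night", path, dtype=int),
            "encountered": _numeric(df, "encountered", path, dtype=int),
        }
    )
    log = EncounterLog(out)
    if devices is not None:
        log.validate_against(devices)
    return log


def read_interactions(path: str | Path, encounters: EncounterLog | None = None) -> InteractionLog:
    df = pd.read_csv(path, dtype={"rat_id": str, "device_id": str})
    _require_columns(df, ["rat_id", "device_id", "night", "interacted"], path)
    out = pd.DataFrame(
        {
            "rat_id": df["rat_id"].astype(str),
            "device_id": df["device_id"].astype(str),
            "night": _numeric(df, "night", path, dtype=int),
            "interacted": _numeric(df, "interacted", path, dtype=int),
        }
    )
    log = InteractionLog(out)
    if encounters is not None:
        log.validate_against(encounters)
    return log


def write_encounters(log: EncounterLog, path: str | Path) -> None:
    log.df.to_csv(path, index=False)


def write_interactions(log: InteractionLog, path: str | Path) -> None:
    log.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Seed plus free-form scenario parameters forwarded to the other modules."""

    seed: int
    out_dir: str = "."
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"seed": self.seed, "out_dir": self.out_dir, "params": self.params}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(seed=int(obj["seed"]), out_dir=obj.get("out_dir", "."), params=obj.get("params", {}))
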