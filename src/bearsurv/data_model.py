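"""Domain types and I/O for aerial line-transect bear surveys.

Distances are one-sided perpendicular meters (the aerial protocol searches a
single side of the aircraft), transect lengths are kilometers, areas are km².
The covered strip per transect is therefore ``length × (w − c)`` with no
factor of two.
"""
from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "History",
    "Method",
    "Transect",
    "Detection",
    "SurveyDataset",
    "AbundanceEstimate",
    "read_survey",
    "write_survey",
    "read_config",
    "left_truncate",
    "covered_area",
]


class History(enum.Enum):
    """Double-observer capture history for a detected group."""

    PILOT_ONLY = "P"
    OBSERVER_ONLY = "O"
    BOTH = "B"


class Method(enum.Enum):
    """Which estimator produced an abundance estimate."""

    MRDS_BC = "MRDS_BC"
    CDS = "CDS"
    CDS_INFORMED = "CDS_INFORMED"
    OPEN_SUPERPOP = "OPEN_SUPERPOP"


@dataclass(frozen=True)
class Transect:
    id: str
    date: dt.date
    length_km: float

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValueError(f"transect {self.id!r}: length must be > 0, got {self.length_km}")


@dataclass(frozen=True)
class Detection:
    transect_id: str
    distance_m: float
    group_size: int
    history: History | None = None

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError(f"detection on {self.transect_id!r}: negative distance {self.distance_m}")
        if self.group_size < 1:
            raise ValueError(f"detection on {self.transect_id!r}: group_size must be ≥ 1, got {self.group_size}")


@dataclass(frozen=True)
class SurveyDataset:
    """Transects, detections, and the truncation geometry shared by all estimators.

    ``left_trunc_c_m`` records how much has already been cut from the left;
    detection distances are stored on the shifted scale, so they live in
    ``[0, truncation_w_m − left_trunc_c_m)``.
    """

    transects: tuple[Transect, ...]
    detections: tuple[Detection, ...]
    truncation_w_m: float
    study_area_km2: float
    left_trunc_c_m: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "transects", tuple(self.transects))
        object.__setattr__(self, "detections", tuple(self.detections))
        if self.truncation_w_m <= 0:
            raise ValueError(f"truncation_w_m must be > 0, got {self.truncation_w_m}")
        if self.study_area_km2 <= 0:
            raise ValueError(f"study_area_km2 must be > 0, got {self.study_area_km2}")
        if not 0 <= self.left_trunc_c_m < self.truncation_w_m:
            raise ValueError("left_trunc_c_m must lie in [0, truncation_w_m)")
        ids = [t.id for t in self.transects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transect ids: {dupes}")
        known = set(ids)
        w_eff = self.strip_width_m
        for k, d in enumerate(self.detections):
            if d.transect_id not in known:
                raise ValueError(f"detection {k}: unknown transect {d.transect_id!r}")
            if d.distance_m > w_eff:
                raise ValueError(
                    f"detection {k}: distance {d.distance_m} exceeds effective width {w_eff}"
                )

    @property
    def strip_width_m(self) -> float:
        """Effective one-sided strip width w − c in meters."""
        return self.truncation_w_m - self.left_trunc_c_m

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    def distances(self) -> np.ndarray:
        return np.array([d.distance_m for d in self.detections], dtype=float)

    def group_sizes(self) -> np.ndarray:
        return np.array([d.group_size for d in self.detections], dtype=int)

    def total_length_km(self) -> float:
        return float(sum(t.length_km for t in self.transects))

    def dates(self) -> list[dt.date]:
        return sorted({t.date for t in self.transects})


@dataclass(frozen=True)
class AbundanceEstimate:
    """Point estimate with a 95% interval (CI or CrI) and CV, in bears."""

    n_hat: float
    lo: float
    hi: float
    cv: float
    method: Method
    prior: str | None = None
    extras: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (self.lo <= self.n_hat <= self.hi):
            raise ValueError(f"interval must bracket the point estimate: {self.lo}, {self.n_hat}, {self.hi}")
        if self.cv < 0:
            raise ValueError("cv must be ≥ 0")

    def to_dict(self) -> dict:
        out = {"N_hat": self.n_hat, "lo": self.lo, "hi": self.hi, "cv": self.cv,
               "method": self.method.value}
        if self.prior is not None:
            out["prior"] = self.prior
        out.update(self.extras)
        return out


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON run-configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


_TRANSECT_COLS = ["transect_id", "date", "length_km"]
_DETECTION_COLS = ["transect_id", "distance_m", "group_size", "history"]


def read_survey(transect_path: str | Path, detection_path: str | Path, config: dict) -> SurveyDataset:
    """Read and validate the transect and detection CSV files.

    ``config`` must provide ``truncation_w_m`` and ``study_area_km2``.
    Malformed rows are rejected with messages naming the 1-based data row.
    """
    tdf = pd.read_csv(transect_path, dtype={"transect_id": str})
    missing = [c for c in _TRANSECT_COLS if c not in tdf.columns]
    if missing:
        raise ValueError(f"{transect_path}: missing columns {missing}")
    ddf = pd.read_csv(detection_path, dtype={"transect_id": str})
    missing = [c for c in _DETECTION_COLS if c not in ddf.columns]
    if missing:
        raise ValueError(f"{detection_path}: missing columns {missing}")

    transects = []
    for row_no, row in enumerate(tdf.itertuples(index=False), start=1):
        try:
            transects.append(
                Transect(id=str(row.transect_id),
                         date=dt.date.fromisoformat(str(row.date)),
                         length_km=float(row.length_km))
            )
        except ValueError as exc:
            raise ValueError(f"{transect_path} row {row_no}: {exc}") from exc

    detections = []
    for row_no, row in enumerate(ddf.itertuples(index=False), start=1):
        hist_raw = row.history
        if pd.isna(hist_raw) or str(hist_raw).strip() == "":
            hist = None
        else:
            try:
                hist = History(str(hist_raw).strip())
            except ValueError:
                raise ValueError(
                    f"{detection_path} row {row_no}: history must be one of P/O/B, got {hist_raw!r}"
                ) from None
        try:
            detections.append(
                Detection(transect_id=str(row.transect_id),
                          distance_m=float(row.distance_m),
                          group_size=int(row.group_size),
                          history=hist)
            )
        except ValueError as exc:
            raise ValueError(f"{detection_path} row {row_no}: {exc}") from exc

    return SurveyDataset(
        transects=tuple(transects),
        detections=tuple(detections),
        truncation_w_m=float(config["truncation_w_m"]),
        study_area_km2=float(config["study_area_km2"]),
        left_trunc_c_m=float(config.get("left_trunc_c_m", 0.0)),
    )


def write_survey(dataset: SurveyDataset, transect_path: str | Path, detection_path: str | Path) -> None:
    """Write the dataset back to the two-CSV interchange format."""
    pd.DataFrame(
        {"transect_id": [t.id for t in dataset.transects],
         "date": [t.date.isoformat() for t in dataset.transects],
         "length_km": [repr(t.length_km) for t in dataset.transects]}
    ).to_csv(transect_path, index=False)
    pd.DataFrame(
        {"transect_id": [d.transect_id for d in dataset.detections],
         "distance_m": [repr(d.distance_m) for d in dataset.detections],
         "group_size": [d.group_size for d in dataset.detections],
         "history": [d.history.value if d.history is not None else "" for d in dataset.detections]}
    ).to_csv(detection_path, index=False)


def left_truncate(dataset: SurveyDataset, c: float) -> SurveyDataset:
    """Left-truncate at distance ``c`` and shift so the retained interval is [0, w − c).

    Detections with distance < c are dropped; a detection exactly at c is
    retained at shifted distance 0 (half-open convention). Transects are
    unchanged. Truncation at the apex of a humped composite detection curve
    leaves a monotone-declining distance distribution suitable for a
    half-normal fit.
    """
    if not 0 <= c < dataset.strip_width_m:
        raise ValueError(f"c must lie in [0, {dataset.strip_width_m}), got {c}")
    if c == 0:
        return dataset
    kept = tuple(
        replace(d, distance_m=d.distance_m - c)
        for d in dataset.detections
        if d.distance_m >= c
    )
    return SurveyDataset(
        transects=dataset.transects,
        detections=kept,
        truncation_w_m=dataset.truncation_w_m,
        study_area_km2=dataset.study_area_km2,
        left_trunc_c_m=dataset.left_trunc_c_m + c,
    )


def covered_area(dataset: SurveyDataset) -> float:
    """Total one-sided covered strip area in km²: Σ_j L_j × (w − c).

    Overlapping strips are not de-duplicated (surveyed area may exceed the
    study area under repeated coverage); the design-based scaling treats each
    strip as an independent sample of density.
    """
    return dataset.total_length_km() * dataset.strip_width_m / 1000.0
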