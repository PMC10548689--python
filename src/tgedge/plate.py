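"""Plate-level data containers for fluorogenic thrombin-generation runs.

A run consists of a set of wells on a microtiter plate: *sample* wells in
which plasma generates thrombin that cleaves a fluorogenic substrate, and
*calibrator* wells in which a thrombin--alpha2-macroglobulin complex of
known, constant substrate-cleaving activity is read out under the same
substrate and optical conditions.  Every sample condition must be paired
with at least one calibrator well group so that fluorescence artifacts
(inner filter effect, substrate consumption) can be corrected against the
calibrator.

All times are stored in minutes; fluorescence in relative fluorescence
units (RFU); concentrations in nM (enzymes) and uM (substrate/fluorophore).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ROLE_SAMPLE = "sample"
ROLE_CALIBRATOR = "calibrator"
_ROLES = (ROLE_SAMPLE, ROLE_CALIBRATOR)

__all__ = [
    "ConditionMeta",
    "Well",
    "Plate",
    "ROLE_SAMPLE",
    "ROLE_CALIBRATOR",
]


@dataclass
class ConditionMeta:
    """Per-condition assay metadata.

    Parameters
    ----------
    fviii_level : float
        Factor VIII level in IU/mL (0 for severe hemophilia A plasma,
        1 for plasma normalized by FVIII supplementation).
    amc_spike : float
        Free AMC fluorophore spiked into the well before the run, in uM
        of final fluorophore-equivalent concentration.  Used to force a
        baseline inner filter effect.
    substrate_total : float
        Initial ZGGR-AMC fluorogenic substrate concentration S0, uM.
    afc_substrate : float
        ZGGR-AFC substrate concentration, uM.  Uncleaved AFC substrate
        bleeds a constant baseline into the AMC recording channel.
    kcat : float
        Substrate turnover number, 1/min (per enzyme molecule).
    Km : float
        Michaelis constant of the substrate, uM.
    calibrator_activity : float
        Assigned calibrator activity E_cal, nM thrombin-equivalent.
    sampling_interval : float
        Recording cadence, seconds.
    duration : float
        Record length, minutes.
    label : str
        Free-text condition label; wells sharing a label share a
        calibrator group.
    """

    fviii_level: float = 1.0
    amc_spike: float = 0.0
    substrate_total: float = 416.0
    afc_substrate: float = 0.0
    kcat: float = 60.0
    Km: float = 200.0
    calibrator_activity: float = 100.0
    sampling_interval: float = 30.0
    duration: float = 60.0
    label: str = ""

    # numeric fields serialized to / parsed from plate file headers
    NUMERIC_FIELDS = (
        "fviii_level",
        "amc_spike",
        "substrate_total",
        "afc_substrate",
        "kcat",
        "Km",
        "calibrator_activity",
        "sampling_interval",
        "duration",
    )

    def validate(self) -> None:
        if not np.isfinite(
            [getattr(self, f) for f in self.NUMERIC_FIELDS]
        ).all():
            raise ValueError("non-finite condition parameter")
        if self.substrate_total < 0:
            raise ValueError("substrate_total must be >= 0")
        if self.amc_spike < 0:
            raise ValueError("amc_spike must be >= 0")
        if self.afc_substrate < 0:
            raise ValueError("afc_substrate must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.kcat < 0:
            raise ValueError("kcat must be >= 0")
        if self.kcat > 0 and self.Km <= 0:
            raise ValueError("Km must be > 0 when kcat > 0")

    def time_grid(self) -> np.ndarray:
        """Recording time grid in minutes, starting at t=0."""
        self.validate()
        dt = self.sampling_interval / 60.0
        n = int(round(self.duration / dt)) + 1
        return np.arange(n) * dt

    def with_(self, **kwargs) -> "ConditionMeta":
        return replace(self, **kwargs)


@dataclass
class Well:
    """A single well's fluorescence time series."""

    well_id: str
    role: str
    condition: ConditionMeta
    times: np.ndarray  # minutes, strictly increasing
    rfu: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)

    def validate(self, min_points: int = 8) -> None:
        if self.role not in _ROLES:
            raise ValueError(
                f"well {self.well_id!r}: role must be one of {_ROLES}"
            )
        if self.times.shape != self.rfu.shape:
            raise ValueError(
                f"well {self.well_id!r}: ragged series "
                f"({self.times.size} times vs {self.rfu.size} rfu)"
            )
        if self.times.size < min_points:
            raise ValueError(
                f"well {self.well_id!r}: needs >= {min_points} points, "
                f"got {self.times.size}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"well {self.well_id!r}: times are not strictly increasing"
            )
        if not np.isfinite(self.rfu).all():
            raise ValueError(f"well {self.well_id!r}: non-finite RFU values")


@dataclass
class Plate:
    """A collection of wells with sample-to-calibrator pairing.

    ``pairing`` maps a condition label to the well ids of its calibrator
    group.  ``truth`` optionally retains the simulator's per-well ground
    truth (synthetic plates only) keyed by well id.
    """

    wells: list[Well] = field(default_factory=list)
    pairing: dict[str, list[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    truth: dict[str, "object"] = field(default_factory=dict)

    def well(self, well_id: str) -> Well:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def sample_wells(self, label: str | None = None) -> list[Well]:
        return [
            w
            for w in self.wells
            if w.role == ROLE_SAMPLE
            and (label is None or w.condition.label == label)
        ]

    def calibrator_wells(self, label: str | None = None) -> list[Well]:
        if label is not None and label in self.pairing:
            ids = set(self.pairing[label])
            return [w for w in self.wells if w.well_id in ids]
        return [
            w
            for w in self.wells
            if w.role == ROLE_CALIBRATOR
            and (label is None or w.condition.label == label)
        ]

    def condition_labels(self) -> list[str]:
        """Sample condition labels in first-appearance order."""
        seen: list[str] = []
        for w in self.wells:
            if w.role == ROLE_SAMPLE and w.condition.label not in seen:
                seen.append(w.condition.label)
        return seen

    def validate(self) -> None:
        ids = [w.well_id for w in self.wells]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicated well_id: {sorted(dup)}")
        for w in self.wells:
            w.validate()
        for label in self.condition_labels():
            cal = self.calibrator_wells(label)
            if not cal:
                raise ValueError(
                    f"condition {label!r} has no paired calibrator well"
                )
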