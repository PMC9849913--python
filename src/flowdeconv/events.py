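"""Core containers: per-event cytometry tables and sample metadata.

Every stage of the pipeline speaks in :class:`EventTable` (a thin wrapper
around a pandas DataFrame holding the five measured channels) and
:class:`SampleMeta` (who the sample is: culture type, medium, replicate,
timepoint, and the volumetric acquisition settings needed for absolute
counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical channel order used throughout the package.
CHANNELS = ("FSC-H", "SSC-H", "GFP-H", "mCherry-H", "SYTO-H")

#: The four community members.
SPECIES = ("Bo", "Bf", "Bt", "Bv")

#: Optional column carrying the generating population of each synthetic event
#: ("Bo"/"Bf"/"Bt"/"Bv"/"debris"). Ignored by all estimators; used only to
#: score recovery against ground truth.
TRUE_LABEL_COLUMN = "true_label"

MONOCULTURE_TYPES = tuple(f"mono:{sp}" for sp in SPECIES)
CULTURE_TYPES = MONOCULTURE_TYPES + ("co", "sterile")


class MissingChannelError(KeyError):
    """Raised when an input table lacks one of the five required channels."""


@dataclass
class EventTable:
    """Per-event five-channel intensities for one cytometry sample.

    ``data`` must contain all columns in :data:`CHANNELS`; extra columns
    (e.g. ground-truth labels from the simulator) are carried along untouched.
    """

    data: pd.DataFrame
    sample_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise MissingChannelError(
                f"event table {self.sample_id!r} lacks channel(s): {', '.join(missing)}"
            )
        mat = self.data[list(CHANNELS)].to_numpy(dtype=float)
        if mat.size and not np.isfinite(mat).all():
            raise ValueError(f"non-finite intensities in sample {self.sample_id!r}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def channel_matrix(self) -> np.ndarray:
        """Events as an (n, 5) float array in canonical channel order."""
        return self.data[list(CHANNELS)].to_numpy(dtype=float)

    def take(self, index) -> "EventTable":
        """Row-subset preserving all columns (positional indices)."""
        return EventTable(self.data.iloc[np.asarray(index)].reset_index(drop=True),
                          sample_id=self.sample_id)


@dataclass(frozen=True)
class SampleMeta:
    """Identity and acquisition settings of one sample.

    acquisition_volume_ul: volume injected into the cytometer (µl); the
    instrument records events for exactly this volume, so retained event
    counts convert to cells/ml by ``count / volume_ml * dilution_factor``.
    dilution_factor: fold-dilution applied before acquisition (the study
    diluted all samples 5-fold).
    """

    sample_id: str
    culture_type: str  # mono:Bo / mono:Bf / mono:Bt / mono:Bv / co / sterile
    medium: str
    substrate_class: str  # simple / complex / control
    replicate: int = 1
    timepoint: float = 24.0  # hours
    acquisition_volume_ul: float = 3.0
    dilution_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.culture_type not in CULTURE_TYPES:
            raise ValueError(f"unknown culture_type {self.culture_type!r}")
        if self.acquisition_volume_ul <= 0:
            raise ValueError("acquisition volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")

    @property
    def species(self) -> str | None:
        """The seeded species for monocultures, else None."""
        if self.culture_type.startswith("mono:"):
            return self.culture_type.split(":", 1)[1]
        return None

    def with_(self, **kw) -> "SampleMeta":
        return replace(self, **kw)
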