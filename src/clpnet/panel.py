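"""Two-wave symptom panel container.

The panel holds 14 DASS-21 items per wave (7 depression, 7 anxiety, each on a
0-3 Likert scale), the covariates age and gender, and a per-participant
follow-up status.  Deceased participants keep their wave-1 record but have no
wave-2 data; by convention their wave-2 items are *not* treated as missing
values to be imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEPRESSION_NODES = [f"D{i}" for i in range(1, 8)]
ANXIETY_NODES = [f"A{i}" for i in range(1, 8)]
NODE_LABELS = DEPRESSION_NODES + ANXIETY_NODES
N_NODES = len(NODE_LABELS)

#: community membership of each symptom node
COMMUNITY = {**{d: "depression" for d in DEPRESSION_NODES},
             **{a: "anxiety" for a in ANXIETY_NODES}}

STATUS_LEVELS = ("complete", "dropout", "deceased")

# wide-CSV column names, e.g. d1_t1 ... a7_t1, d1_t2 ... a7_t2
WAVE1_COLUMNS = [f"{lbl.lower()}_t1" for lbl in NODE_LABELS]
WAVE2_COLUMNS = [f"{lbl.lower()}_t2" for lbl in NODE_LABELS]


@dataclass
class PanelDataset:
    """Participants x (wave-1 items, wave-2 items, covariates).

    Items are stored as float arrays with NaN marking missing cells; observed
    values are integers in {0, 1, 2, 3}.
    """

    ids: np.ndarray
    wave1_items: np.ndarray            # (n, 14) float, NaN = missing
    wave2_items: np.ndarray            # (n, 14) float, NaN = missing
    age: np.ndarray                    # (n,) float, years
    gender: np.ndarray                 # (n,) int, 0 = male, 1 = female
    status: np.ndarray = field(default=None)  # (n,) str in STATUS_LEVELS

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.status is None:
            self.status = np.array(["complete"] * n, dtype=object)
        for name in ("wave1_items", "wave2_items"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (n, N_NODES):
                raise ValueError(f"{name} must have shape ({n}, {N_NODES})")
            setattr(self, name, mat)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=int)
        self.status = np.asarray(self.status, dtype=object)
        self._validate_items()
        bad = set(self.status) - set(STATUS_LEVELS)
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        dead = self.status == "deceased"
        if dead.any() and not np.isnan(self.wave2_items[dead]).all():
            raise ValueError("deceased rows must have fully missing wave-2 items")

    def _validate_items(self) -> None:
        for name in ("wave1_items", "wave2_items"):
            mat = getattr(self, name)
            obs = mat[~np.isnan(mat)]
            if obs.size and (np.any(obs != np.round(obs)) or obs.min() < 0 or obs.max() > 3):
                raise ValueError(f"{name}: observed values must be integers in [0, 3]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray) -> "PanelDataset":
        """Row subset / resample (used by the bootstrap machinery)."""
        return PanelDataset(
            ids=self.ids[index],
            wave1_items=self.wave1_items[index],
            wave2_items=self.wave2_items[index],
            age=self.age[index],
            gender=self.gender[index],
            status=self.status[index],
        )

    def non_deceased(self) -> "PanelDataset":
        return self.subset(np.flatnonzero(self.status != "deceased"))

    def has_missing(self) -> bool:
        return bool(np.isnan(self.wave1_items).any() or np.isnan(self.wave2_items).any())

    def to_frame(self) -> pd.DataFrame:
        """Wide table: id, age, gender, status, d1_t1..a7_t1, d1_t2..a7_t2."""
        df = pd.DataFrame({"id": self.ids, "age": self.age,
                           "gender": np.where(self.gender == 1, "female", "male"),
                           "status": self.status})
        for j, col in enumerate(WAVE1_COLUMNS):
            df[col] = self.wave1_items[:, j]
        for j, col in enumerate(WAVE2_COLUMNS):
            df[col] = self.wave2_items[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def equals(self, other: "PanelDataset") -> bool:
        return (
            np.array_equal(self.ids, other.ids)
            and np.allclose(self.wave1_items, other.wave1_items, equal_nan=True)
            and np.allclose(self.wave2_items, other.wave2_items, equal_nan=True)
            and np.allclose(self.age, other.age)
            and np.array_equal(self.gender, other.gender)
            and np.array_equal(self.status, other.status)
        )
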