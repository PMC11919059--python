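"""DASS-21 panel ingestion, subscale scoring, prevalence and attrition checks.

Each 7-item subscale total is the item sum doubled (range 0-42).  The
screening cutoffs for "mild or above" are 10 for depression and 8 for
anxiety; totals below the cutoff are classed as normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import (N_NODES, PanelDataset, STATUS_LEVELS,
                    WAVE1_COLUMNS, WAVE2_COLUMNS)

DEPRESSION_CUTOFF = 10
ANXIETY_CUTOFF = 8
_CUTOFFS = {"depression": DEPRESSION_CUTOFF, "anxiety": ANXIETY_CUTOFF}
_SLICES = {"depression": slice(0, 7), "anxiety": slice(7, 14)}

DEFAULT_SCHEMA = {
    "id": "id",
    "age": "age",
    "gender": "gender",
    "status": "status",
    "wave1_items": WAVE1_COLUMNS,
    "wave2_items": WAVE2_COLUMNS,
}


class SchemaError(ValueError):
    """A required column is absent from the input file."""


class PanelValidationError(ValueError):
    """An item cell is non-integer or out of the 0-3 range."""


@dataclass
class DassScore:
    depression_total: int
    anxiety_total: int

    @property
    def depression_flag(self) -> str:
        return "mild_or_above" if self.depression_total >= DEPRESSION_CUTOFF else "normal"

    @property
    def anxiety_flag(self) -> str:
        return "mild_or_above" if self.anxiety_total >= ANXIETY_CUTOFF else "normal"


@dataclass
class AttritionResult:
    variable: str
    t_statistic: float
    p_value: float
    group_means: tuple  # (completers, dropouts)


def score_dass(items_7, subscale: str) -> DassScore:
    """Score one 7-item subscale: total = 2 * sum, flagged at the cutoff.

    Scoring happens after imputation, so missing items are an error.
    """
    if subscale not in _CUTOFFS:
        raise ValueError("subscale must be 'depression' or 'anxiety'")
    items = np.asarray(items_7, dtype=float)
    if items.shape != (7,):
        raise ValueError("expected exactly 7 items")
    if np.isnan(items).any():
        raise ValueError("missing items: score after imputation")
    if np.any(items != np.round(items)) or items.min() < 0 or items.max() > 3:
        raise ValueError("items must be integers in [0, 3]")
    total = int(2 * items.sum())
    if subscale == "depression":
        return DassScore(depression_total=total, anxiety_total=0)
    return DassScore(depression_total=0, anxiety_total=total)


def subscale_totals(items: np.ndarray, subscale: str) -> np.ndarray:
    """Vectorized totals (2 * item sum) for all rows; NaN where incomplete."""
    block = items[:, _SLICES[subscale]]
    return 2.0 * block.sum(axis=1)  # NaN propagates for incomplete rows


def prevalence(dataset: PanelDataset, wave: int, subscale: str) -> float:
    """Fraction of participants at or above the mild cutoff.

    Wave 2 excludes deceased participants from the denominator.  Rows whose
    subscale items are incomplete are excluded (score after imputation to
    include everyone).
    """
    if wave not in (1, 2):
        raise ValueError("wave must be 1 or 2")
    ds = dataset.non_deceased() if wave == 2 else dataset
    items = ds.wave1_items if wave == 1 else ds.wave2_items
    totals = subscale_totals(items, subscale)
    totals = totals[~np.isnan(totals)]
    if totals.size == 0:
        raise ValueError("empty denominator: no scorable participants")
    return float(np.mean(totals >= _CUTOFFS[subscale]))


def descriptives(dataset: PanelDataset) -> pd.DataFrame:
    """Mean (SD) and prevalence per subscale and wave, after exclusions."""
    rows = []
    for wave in (1, 2):
        ds = dataset.non_deceased() if wave == 2 else dataset
        items = ds.wave1_items if wave == 1 else ds.wave2_items
        for subscale in ("depression", "anxiety"):
            totals = subscale_totals(items, subscale)
            totals = totals[~np.isnan(totals)]
            rows.append({
                "subscale": subscale, "wave": wave, "n": totals.size,
                "mean": float(np.mean(totals)) if totals.size else np.nan,
                "sd": float(np.std(totals, ddof=1)) if totals.size > 1 else np.nan,
                "prevalence": float(np.mean(totals >= _CUTOFFS[subscale])) if totals.size else np.nan,
            })
    return pd.DataFrame(rows)


def read_panel(path, schema_config: dict | None = None) -> PanelDataset:
    """Read and validate a wide panel CSV.

    ``schema_config`` maps roles to column names (see ``DEFAULT_SCHEMA``),
    which is how externally deposited cohort files with different headers are
    ingested.  Empty cells are missing; item values outside {0,1,2,3} raise a
    validation error naming the offending cell.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)
    df = pd.read_csv(path)
    required = ([schema["id"], schema["age"], schema["gender"]]
                + list(schema["wave1_items"]) + list(schema["wave2_items"]))
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")

    def _items(cols, label):
        mat = np.full((len(df), N_NODES), np.nan)
        for j, col in enumerate(cols):
            vals = pd.to_numeric(df[col], errors="coerce")
            raw_blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
            bad_parse = vals.isna() & ~raw_blank
            obs = vals.dropna()
            bad_range = obs[(obs < 0) | (obs > 3) | (obs != np.round(obs))]
            if bad_parse.any():
                row = int(np.flatnonzero(bad_parse)[0])
                raise PanelValidationError(f"non-numeric value in {label} column '{col}', row {row}")
            if len(bad_range):
                row = int(bad_range.index[0])
                raise PanelValidationError(
                    f"out-of-range item value {bad_range.iloc[0]!r} in column '{col}', row {row}")
            mat[:, j] = vals.to_numpy()
        return mat

    wave1 = _items(schema["wave1_items"], "wave-1")
    wave2 = _items(schema["wave2_items"], "wave-2")
    gender_raw = df[schema["gender"]]
    if gender_raw.dtype == object:
        gender = gender_raw.str.strip().str.lower().map({"male": 0, "m": 0, "0": 0,
                                                         "female": 1, "f": 1, "1": 1})
        if gender.isna().any():
            raise PanelValidationError("unrecognized gender labels")
        gender = gender.to_numpy(dtype=int)
    else:
        gender = gender_raw.to_numpy(dtype=int)
    if schema["status"] in df.columns:
        status = df[schema["status"]].fillna("complete").to_numpy(dtype=object)
    else:
        status = np.array(["complete"] * len(df), dtype=object)
    unknown = set(status) - set(STATUS_LEVELS)
    if unknown:
        raise PanelValidationError(f"unknown status values: {sorted(unknown)}")
    return PanelDataset(
        ids=df[schema["id"]].to_numpy(),
        wave1_items=wave1, wave2_items=wave2,
        age=df[schema["age"]].to_numpy(dtype=float),
        gender=gender, status=status,
    )


def attrition_ttest(dataset: PanelDataset) -> list[AttritionResult]:
    """Welch t-tests comparing completers with wave-2 dropouts on baseline
    depression, baseline anxiety and age.

    Baseline totals use rows with complete wave-1 subscale items (attrition is
    assessed before imputation).  Deceased participants are excluded.
    """
    ds = dataset.non_deceased()
    completer = ds.status == "complete"
    dropout = ds.status == "dropout"
    if completer.sum() < 2 or dropout.sum() < 2:
        raise ValueError("both completer and dropout groups need at least 2 members")
    results = []
    variables = {
        "baseline_depression": subscale_totals(ds.wave1_items, "depression"),
        "baseline_anxiety": subscale_totals(ds.wave1_items, "anxiety"),
        "age": ds.age,
    }
    for name, values in variables.items():
        a = values[completer & ~np.isnan(values)]
        b = values[dropout & ~np.isnan(values)]
        if a.size < 2 or b.size < 2:
            raise ValueError(f"group too small for variable {name}")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        results.append(AttritionResult(
            variable=name, t_statistic=float(t), p_value=float(p),
            group_means=(float(a.mean()), float(b.mean())),
        ))
    return results
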