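"""Cohort CSV dialect and structured configuration files.

One row per neonate per timepoint.  Mandatory columns: ``id``, ``group``
(``pos``/``neg`` blood culture) and ``timepoint`` (``48h``/``24h``/``0h``),
followed by either the eight 0/1 indicator columns (indicator dialect) or
the ten raw observation columns (raw dialect).  Files are RFC-4180 CSV,
UTF-8, header row mandatory.  Rows with missing values are rejected with a
logged reason — the package never imputes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .scoring import (
    INDICATORS,
    RawObservation,
    ThresholdConfig,
    compute_sps,
    derive_indicators,
)
from .simulate import TIMEPOINTS, SimulationConfig, derivation_config, validation_config

logger = logging.getLogger("neosps")

META_COLUMNS = ("id", "group", "timepoint")
RAW_COLUMNS = (
    "temperature",
    "feeding_change",
    "platelet_count",
    "glucose_change",
    "crp",
    "crt",
    "hypotension",
    "o2_requirement_increase",
    "apnea",
    "mech_vent_new_or_changed",
)
GROUPS = ("pos", "neg")

PRESETS = {"derivation2010": derivation_config, "validation2017": validation_config}


def _check_meta(frame: pd.DataFrame, where: str) -> None:
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{where}: missing mandatory columns {missing}")
    bad_group = set(frame["group"].unique()) - set(GROUPS)
    if bad_group:
        raise SchemaError(f"{where}: column 'group' contains invalid values {sorted(bad_group)}")
    bad_tp = set(frame["timepoint"].unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise SchemaError(f"{where}: column 'timepoint' contains invalid values {sorted(bad_tp)}")


def read_cohort(path, thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Read a cohort CSV in either dialect and return a scored tidy frame.

    Raw-dialect files are dichotomised with ``thresholds`` (defaults apply
    when omitted).  Rows with any missing value in a required column are
    dropped, each with a logged reason.  The returned frame always carries
    the indicator columns and a ``score`` column.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    where = path.name
    _check_meta(frame, where)

    has_ind = all(c in frame.columns for c in INDICATORS)
    has_raw = all(c in frame.columns for c in RAW_COLUMNS)
    if not has_ind and not has_raw:
        raise SchemaError(
            f"{where}: expected either the {len(INDICATORS)} indicator columns "
            f"{list(INDICATORS)} or the {len(RAW_COLUMNS)} raw columns {list(RAW_COLUMNS)}"
        )
    required = list(META_COLUMNS) + list(INDICATORS if has_ind else RAW_COLUMNS)
    incomplete = frame[required].isna().any(axis=1)
    if incomplete.any():
        for idx in frame.index[incomplete]:
            cols = [c for c in required if pd.isna(frame.at[idx, c])]
            logger.warning("%s: dropping row %d (id=%r): missing %s",
                           where, idx, frame.at[idx, "id"], cols)
        frame = frame[~incomplete].copy()
    if len(frame) == 0:
        raise SchemaError(f"{where}: no complete rows")

    if has_ind:
        for col in INDICATORS:
            vals = set(pd.unique(frame[col]))
            if not vals <= {0, 1, True, False}:
                raise SchemaError(
                    f"{where}: indicator column {col!r} must be 0/1, found {sorted(vals)[:5]}"
                )
            frame[col] = frame[col].astype(int)
    else:
        cfg = thresholds or ThresholdConfig()
        derived = {c: [] for c in INDICATORS}
        for idx, row in frame.iterrows():
            try:
                raw = RawObservation(
                    temperature=float(row["temperature"]),
                    feeding_change=float(row["feeding_change"]),
                    platelet_count=float(row["platelet_count"]),
                    glucose_change=float(row["glucose_change"]),
                    crp=float(row["crp"]),
                    crt=float(row["crt"]),
                    hypotension=bool(row["hypotension"]),
                    o2_requirement_increase=bool(row["o2_requirement_increase"]),
                    apnea=bool(row["apnea"]),
                    mech_vent_new_or_changed=bool(row["mech_vent_new_or_changed"]),
                )
            except ValidationError as exc:
                raise SchemaError(f"{where}: row {idx} (id={row['id']!r}): {exc}") from exc
            ind = derive_indicators(raw, cfg)
            for c in INDICATORS:
                derived[c].append(int(getattr(ind, c)))
        frame = frame.drop(columns=list(RAW_COLUMNS))
        for c in INDICATORS:
            frame[c] = derived[c]

    frame["score"] = frame[list(INDICATORS)].sum(axis=1).astype(int)
    return frame.reset_index(drop=True)


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort frame as CSV (UTF-8, header row, no index)."""
    frame.to_csv(path, index=False)


def load_threshold_config(path) -> ThresholdConfig:
    """Load dichotomisation thresholds from a YAML mapping of overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: threshold config must be a mapping")
    known = set(ThresholdConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown threshold keys {sorted(unknown)}")
    return ThresholdConfig(**data)


def load_simulation_config(path, seed: int | None = None) -> SimulationConfig:
    """Load a simulation config from YAML.

    Either a full specification (``n_pos``, ``n_neg``, ``prevalence`` nested
    group -> timepoint -> indicator, optional ``rho``/``persistence``/
    ``seed``/``demographics``) or a packaged preset referenced as
    ``base: derivation2010`` / ``base: validation2017`` with overrides.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: simulation config must be a mapping")
    if seed is not None:
        data["seed"] = seed
    base = data.pop("base", None)
    try:
        if base is not None:
            if base not in PRESETS:
                raise SchemaError(
                    f"{path}: unknown base {base!r}; available: {sorted(PRESETS)}"
                )
            return PRESETS[base](**data)
        return SimulationConfig(**data)
    except (TypeError, ValidationError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
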