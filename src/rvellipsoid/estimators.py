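"""Ellipsoid-model right-ventricular volume estimators.

The right ventricle is idealised as a quarter-ellipsoid with semi-axes
``r1`` (basilar width direction), ``r2`` (base-to-apex length) and ``r3``
(half the perpendicular diameter), so its volume is ``pi/3 * r1 * r2 * r3``.
Two 2-D echocardiographic formulas recover this volume:

* area-based (AEM):   ``V = 2/3 * CSA * d``  where ``CSA = pi*r1*r2/4``
* linear-based (LEM): ``V = pi/6 * w * l * d`` where ``w = r1``, ``l = r2``

with ``d = 2*r3`` the perpendicular diameter.  The planimetric inputs can be
taken from the right parasternal long-axis four-chamber view (RPL) or the
left apical four-chamber view (A4C); the diameter from the left apical
two-chamber view (A2C) or the right parasternal short-axis basilar view
(RPS).  Crossing these choices yields eight estimator variants, e.g.
``AEM_A4C-RPS``.

Units: linear measurements in cm, areas in cm^2, volumes in cm^3 which are
reported as mL (the identity is exact in these units).  Missing measurements
propagate as NaN; negative magnitudes are rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Distinguished label of the 3-D reference method.
REFERENCE_LABEL = "RT3D"

#: Exact header of the per-dog measurement CSV (one row per dog x session x phase).
MEASUREMENT_COLUMNS = [
    "dog_id",
    "group",
    "body_weight_kg",
    "session",
    "phase",
    "csa_rpl_cm2",
    "csa_a4c_cm2",
    "w_rpl_cm",
    "l_rpl_cm",
    "w_a4c_cm",
    "l_a4c_cm",
    "d_a2c_cm",
    "d_rps_cm",
    "v_rt3d_ml",
]

#: Header of the long-format volume table.
VOLUME_COLUMNS = ["dog_id", "session", "phase", "method", "volume_ml", "indexed_ml_per_kg"]

PHASES = ("ED", "ES")
GROUPS = ("normal", "PS", "PH", "TVD", "TVDegen", "other")

_FORMULAS = ("AEM", "LEM")
_RV_VIEWS = ("RPL", "A4C")
_D_VIEWS = ("A2C", "RPS")


@dataclass(frozen=True)
class MethodVariant:
    """One of the eight ellipsoid estimator variants.

    ``formula`` selects area-based (AEM) or linear-based (LEM); ``rv_view``
    is the view supplying area/width/length; ``d_view`` the view supplying
    the perpendicular diameter.
    """

    formula: str
    rv_view: str
    d_view: str

    def __post_init__(self) -> None:
        if self.formula not in _FORMULAS:
            raise ValueError(f"formula must be one of {_FORMULAS}, got {self.formula!r}")
        if self.rv_view not in _RV_VIEWS:
            raise ValueError(f"rv_view must be one of {_RV_VIEWS}, got {self.rv_view!r}")
        if self.d_view not in _D_VIEWS:
            raise ValueError(f"d_view must be one of {_D_VIEWS}, got {self.d_view!r}")

    @property
    def label(self) -> str:
        """Conventional label, e.g. ``AEM_A4C-RPS``."""
        return f"{self.formula}_{self.rv_view}-{self.d_view}"

    @classmethod
    def from_label(cls, label: str) -> "MethodVariant":
        try:
            formula, views = label.split("_")
            rv_view, d_view = views.split("-")
        except ValueError as exc:
            raise ValueError(f"unparseable method label {label!r}") from exc
        return cls(formula, rv_view, d_view)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def all_variants() -> list[MethodVariant]:
    """The eight ellipsoid variants in canonical order (AEM before LEM,
    RPL before A4C, A2C before RPS)."""
    return [MethodVariant(f, rv, d) for f, rv, d in product(_FORMULAS, _RV_VIEWS, _D_VIEWS)]


ALL_METHOD_LABELS = [v.label for v in all_variants()] + [REFERENCE_LABEL]


def _check_nonnegative(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError(f"{name} must be nonnegative")


def aem_volume(csa, d):
    """Area-based ellipsoid volume ``(2/3) * csa * d`` in mL.

    Parameters are the RV long-axis cross-sectional area (cm^2) and the
    perpendicular diameter (cm).  NaN inputs yield NaN; negative inputs
    raise ``ValueError``.
    """
    _check_nonnegative("csa", csa)
    _check_nonnegative("d", d)
    return (2.0 / 3.0) * np.multiply(csa, d)


def lem_volume(w, l, d):
    """Linear-based ellipsoid volume ``(pi/6) * w * l * d`` in mL.

    ``w`` is the RV basilar width, ``l`` the base-to-apex length and ``d``
    the perpendicular diameter, all in cm.
    """
    _check_nonnegative("w", w)
    _check_nonnegative("l", l)
    _check_nonnegative("d", d)
    return (math.pi / 6.0) * np.multiply(np.multiply(w, l), d)


def index_volume(volume, body_weight):
    """Body-weight-indexed volume in mL/kg; ``body_weight`` must be > 0 kg."""
    bw = np.asarray(body_weight, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body_weight must be strictly positive")
    return np.divide(volume, body_weight)


def average_cycles(values: Sequence[float]) -> float:
    """Arithmetic mean of per-cycle measurements.

    Measurement protocols average each quantity over 3-5 cardiac cycles;
    other lengths are accepted but logged as a protocol deviation.
    """
    values = list(values)
    if len(values) == 0:
        raise ValueError("cannot average an empty list of cycles")
    if not 3 <= len(values) <= 5:
        logger.warning("protocol deviation: %d cycles averaged (expected 3-5)", len(values))
    return float(np.mean(values))


# -- per-variant input column mapping ---------------------------------------

def _variant_inputs(variant: MethodVariant) -> list[str]:
    d_col = f"d_{variant.d_view.lower()}_cm"
    if variant.formula == "AEM":
        return [f"csa_{variant.rv_view.lower()}_cm2", d_col]
    return [f"w_{variant.rv_view.lower()}_cm", f"l_{variant.rv_view.lower()}_cm", d_col]


def variant_volume(variant: MethodVariant, row) -> float:
    """Volume (mL) of one variant from a measurement row (mapping-like);
    NaN if any required measurement is missing."""
    cols = _variant_inputs(variant)
    vals = [row[c] for c in cols]
    if any(pd.isna(v) for v in vals):
        return float("nan")
    if variant.formula == "AEM":
        return float(aem_volume(*vals))
    return float(lem_volume(*vals))


def compute_all_variants(measurements: pd.DataFrame, dropna: bool = True) -> pd.DataFrame:
    """Long-format volume table for all eight variants plus the reference.

    One output row per (dog, session, phase, method) whose inputs are all
    present; rows whose inputs are missing are dropped (``dropna=True``,
    the default, matching pairwise-complete-case analysis) or kept as NaN.
    A completeness summary (rows per method) is logged.

    Columns: ``dog_id, session, phase, method, volume_ml, indexed_ml_per_kg``.
    """
    validate_measurements(measurements)
    records = []
    variants = all_variants()
    for _, row in measurements.iterrows():
        bw = row["body_weight_kg"]
        for variant in variants:
            vol = variant_volume(variant, row)
            records.append((row["dog_id"], row["session"], row["phase"], variant.label, vol, vol / bw))
        ref = row["v_rt3d_ml"]
        ref = float(ref) if not pd.isna(ref) else float("nan")
        records.append((row["dog_id"], row["session"], row["phase"], REFERENCE_LABEL, ref, ref / bw))
    out = pd.DataFrame.from_records(records, columns=VOLUME_COLUMNS)
    if dropna:
        n_missing = int(out["volume_ml"].isna().sum())
        if n_missing:
            logger.info("dropping %d method rows with missing inputs", n_missing)
        out = out.dropna(subset=["volume_ml"]).reset_index(drop=True)
    counts = out.dropna(subset=["volume_ml"]).groupby("method").size()
    logger.info("completeness (rows per method): %s", counts.to_dict())
    return out


class SchemaError(ValueError):
    """Raised when an input table does not match the published CSV schema."""


def validate_measurements(df: pd.DataFrame) -> None:
    """Validate a measurement table against the schema and its invariants.

    Checks: required columns, positive body weight, nonnegative magnitudes,
    phases in {ED, ES}, and at most one row per (dog_id, session, phase).
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError("measurement table is empty")
    if not df["phase"].isin(PHASES).all():
        bad = sorted(set(df["phase"]) - set(PHASES))
        raise SchemaError(f"invalid phase value(s): {bad}")
    if (df["body_weight_kg"] <= 0).any():
        raise SchemaError("body_weight_kg must be strictly positive")
    numeric = [c for c in MEASUREMENT_COLUMNS if c.endswith(("_cm", "_cm2", "_ml"))]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise SchemaError(f"negative value(s) in column {col}")
    dup = df.duplicated(subset=["dog_id", "session", "phase"])
    if dup.any():
        raise SchemaError("duplicate (dog_id, session, phase) rows")
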