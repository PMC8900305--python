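"""Ejaculate quality control as applied at bull semen collection stations.

An ejaculate is unsuitable for artificial insemination when it contains
fewer than 300 million sperm per mL, less than 70% motile sperm, more than
10% morphologically abnormal sperm, or less than 1 mL of semen.  The
inequalities are strict on the failure side, so records exactly at a
threshold pass.  Anomaly burden may arrive as a percentage or as the
station's 0–3 score (0: none/very few, 1: <10%, 2: 10–30%, 3: >30%);
score ≥ 2 is the only mapping consistent with ">10% abnormal".

Concentration is canonicalized to million sperm per mL internally;
tables reporting 10⁹ sperm per mL are converted on read (×1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EjaculateRecord",
    "QCThresholds",
    "classify_ejaculate",
    "find_affected_bulls",
    "summarize_semen",
    "read_ejaculate_table",
    "write_ejaculate_table",
    "parse_bounded_value",
    "MONTHS_TO_DAYS",
    "AFFECTED_BULL_EJACULATES",
]

logger = logging.getLogger(__name__)

#: Mean calendar month length in days, used when only ages in months exist.
MONTHS_TO_DAYS: float = 30.44


def parse_bounded_value(value) -> tuple[float, bool]:
    """Parse a numeric field that may carry a bound marker like ``<1``.

    A value recorded as "<x" is imputed as x/2; the second element of the
    return flags that imputation so report layers can mark it.
    """
    if isinstance(value, str):
        v = value.strip()
        if v.startswith("<"):
            return float(v[1:]) / 2.0, True
        if v.startswith(">"):
            return float(v[1:]), True
        return float(v), False
    return float(value), False


@dataclass
class EjaculateRecord:
    """One semen collection from one bull.

    ``concentration`` is in million sperm per mL.  Abnormality may be
    given as a percentage (``abnormal_pct``) and/or the 0–3 anomaly score
    (``anomaly_score``); at least one is needed for QC.
    """

    bull: str
    age_days: float
    volume_ml: float
    concentration: float
    motile_pct: float
    abnormal_pct: float | None = None
    anomaly_score: int | None = None
    viable_pct: float | None = None
    imputed_fields: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.volume_ml < 0:
            raise ValueError("volume must be >= 0")
        for name in ("motile_pct", "abnormal_pct", "viable_pct"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.anomaly_score is not None and self.anomaly_score not in (0, 1, 2, 3):
            raise ValueError(f"anomaly score {self.anomaly_score} not in 0..3")


@dataclass
class QCThresholds:
    """Station rejection rules; defaults are the routine-processing rules."""

    min_concentration: float = 300.0  # million sperm per mL
    min_motile: float = 70.0  # percent
    max_abnormal: float = 10.0  # percent
    min_volume: float = 1.0  # mL

    def __post_init__(self) -> None:
        for f in ("min_concentration", "min_motile", "max_abnormal", "min_volume"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def classify_ejaculate(
    rec: EjaculateRecord, thr: QCThresholds | None = None
) -> tuple[bool, list[str]]:
    """Apply the rejection rules; returns (passes, reasons-for-failure).

    Failure requires strictly crossing a threshold; boundary values pass.
    Abnormality uses the percentage when present, else the score (≥ 2
    fails).  A record with neither raises ValueError.
    """
    thr = thr or QCThresholds()
    reasons: list[str] = []
    if rec.concentration < thr.min_concentration:
        reasons.append("concentration")
    if rec.motile_pct < thr.min_motile:
        reasons.append("motility")
    if rec.abnormal_pct is not None:
        if rec.abnormal_pct > thr.max_abnormal:
            reasons.append("abnormality")
    elif rec.anomaly_score is not None:
        if rec.anomaly_score >= 2:
            reasons.append("abnormality")
    else:
        raise ValueError(
            f"record for bull {rec.bull!r} has neither abnormal_pct nor "
            "anomaly_score"
        )
    if rec.volume_ml < thr.min_volume:
        reasons.append("volume")
    return (not reasons, reasons)


def find_affected_bulls(
    records: list[EjaculateRecord],
    age_window: tuple[float, float] = (330.0, 550.0),
    min_ejaculates: int = 5,
    thr: QCThresholds | None = None,
) -> list[str]:
    """Bulls whose every ejaculate in the age window fails quality control.

    Restricts to collections at ages within ``age_window`` (days,
    inclusive), requires at least ``min_ejaculates`` such records per bull,
    and returns the bulls for which every one fails.
    """
    lo, hi = age_window
    per_bull: dict[str, list[EjaculateRecord]] = {}
    for r in records:
        if lo <= r.age_days <= hi:
            per_bull.setdefault(r.bull, []).append(r)
    affected = []
    for bull, recs in per_bull.items():
        if len(recs) < min_ejaculates:
            continue
        if all(not classify_ejaculate(r, thr)[0] for r in recs):
            affected.append(bull)
    return sorted(affected)


def summarize_semen(records: list[EjaculateRecord]) -> pd.DataFrame:
    """Mean and sample (n−1) standard deviation per semen parameter.

    Rounding happens only at the report layer; values here are full
    precision.  With a single record the sd is reported as NaN.
    """
    if not records:
        raise ValueError("no records to summarize")
    fields = {
        "volume_ml": [r.volume_ml for r in records],
        "concentration": [r.concentration for r in records],
        "motile_pct": [r.motile_pct for r in records],
        "abnormal_pct": [r.abnormal_pct for r in records
                         if r.abnormal_pct is not None],
        "viable_pct": [r.viable_pct for r in records
                       if r.viable_pct is not None],
    }
    rows = []
    for name, vals in fields.items():
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
        rows.append((name, arr.size, float(arr.mean()), sd))
    return pd.DataFrame(rows, columns=["parameter", "n", "mean", "sd"]
                        ).set_index("parameter")


# ---------------------------------------------------------------------------
# Tab-separated interchange
# ---------------------------------------------------------------------------

_COLUMNS = ["bull", "age_days", "volume_ml", "concentration", "motile_pct",
            "abnormal_pct", "anomaly_score", "viable_pct"]


def write_ejaculate_table(records: list[EjaculateRecord], path: str | Path
                          ) -> None:
    rows = [[r.bull, r.age_days, r.volume_ml, r.concentration, r.motile_pct,
             r.abnormal_pct, r.anomaly_score, r.viable_pct] for r in records]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ejaculate_table(
    path: str | Path, concentration_unit: str = "million_per_ml"
) -> list[EjaculateRecord]:
    """Read an ejaculate table; rows missing mandatory fields are skipped
    with a warning.  ``concentration_unit`` may be ``million_per_ml`` or
    ``1e9_per_ml`` (converted ×1000 on read).  Bounded entries like "<1"
    are imputed at half the bound and flagged in ``imputed_fields``.
    """
    if concentration_unit not in ("million_per_ml", "1e9_per_ml"):
        raise ValueError(f"unknown concentration unit {concentration_unit!r}")
    scale = 1000.0 if concentration_unit == "1e9_per_ml" else 1.0
    df = pd.read_csv(path, sep="\t", dtype=str)
    records: list[EjaculateRecord] = []
    for i, row in df.iterrows():
        try:
            imputed: list[str] = []

            def grab(col: str, optional: bool = False):
                raw = row.get(col)
                if raw is None or (isinstance(raw, float) and pd.isna(raw)) \
                        or (isinstance(raw, str) and raw.strip() in ("", "na")):
                    if optional:
                        return None
                    raise ValueError(f"missing {col}")
                v, was_bounded = parse_bounded_value(raw)
                if was_bounded:
                    imputed.append(col)
                return v

            score = grab("anomaly_score", optional=True)
            records.append(EjaculateRecord(
                bull=str(row["bull"]),
                age_days=grab("age_days"),
                volume_ml=grab("volume_ml"),
                concentration=grab("concentration") * scale,
                motile_pct=grab("motile_pct"),
                abnormal_pct=grab("abnormal_pct", optional=True),
                anomaly_score=int(score) if score is not None else None,
                viable_pct=grab("viable_pct", optional=True),
                imputed_fields=imputed,
            ))
        except (ValueError, KeyError) as exc:
            logger.warning("skipping row %d of %s: %s", i, path, exc)
    return records


def _rec(bull, months, vol, conc_1e9, abnormal, motile, viable):
    motile_v, motile_imp = parse_bounded_value(motile)
    return EjaculateRecord(
        bull=bull, age_days=months * MONTHS_TO_DAYS, volume_ml=vol,
        concentration=conc_1e9 * 1000.0, motile_pct=motile_v,
        abnormal_pct=abnormal, viable_pct=viable,
        imputed_fields=["motile_pct"] if motile_imp else [],
    )


#: Published semen analyses of the bull homozygous for the QRICH2
#: frameshift: seven ejaculates collected at 14, 16, 17 and 20 months
#: (volume in mL, concentration in 10⁹/mL converted to million/mL,
#: major-defect %, motile %, viable % where analysed).  The six
#: collections from 16 months onward are the standard summary set.
AFFECTED_BULL_EJACULATES: list[EjaculateRecord] = [
    _rec("hom_bull", 14, 5.0, 0.031, 97.3, 0, None),
    _rec("hom_bull", 16, 4.0, 0.187, 99.6, "<1", None),
    _rec("hom_bull", 16, 5.0, 0.115, 97.9, "<1", None),
    _rec("hom_bull", 17, 2.8, 0.160, 100.0, 0, 12.0),
    _rec("hom_bull", 17, 3.0, 0.088, 98.7, "<1", 10.8),
    _rec("hom_bull", 20, 4.5, 0.214, 99.2, 0, 4.2),
    _rec("hom_bull", 20, 4.5, 0.360, 99.3, "<1", 10.4),
]
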