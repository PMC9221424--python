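"""WBC-normalized enumeration: counts, blood volume, events/mL, frequencies.

Rare-event counts are meaningful only relative to the amount of blood
actually examined, which varies per test. The analyzed volume is recovered
from the number of white blood cells the assay detected on the slides divided
by the hematology-analyzer WBC concentration (cells/mL); rates are then
count / volume, and frequencies are percentages of the rare total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CELL_CLASSES, LEV_CLASSES, RARE_CLASSES


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (2 d.p. internal, 1 d.p. in reports)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample assay metadata.

    ``wbc_per_ml`` is the hematology-analyzer WBC concentration in blood
    (cells/mL); ``wbcs_detected`` is the nucleated common-cell count the assay
    found across the test's slides.
    """

    sample_id: str
    cohort: str                 # "UTUC" | "ND"
    wbc_per_ml: float
    slides_per_test: int = 2
    wbcs_detected: float = 0.0

    def __post_init__(self) -> None:
        if self.wbc_per_ml <= 0:
            raise ValueError("WBC concentration must be positive")
        if self.slides_per_test < 1:
            raise ValueError("slides_per_test must be >= 1")


def blood_volume_analyzed(wbcs_detected: float, wbc_per_ml: float) -> float:
    """mL of blood examined: detected WBCs / WBC concentration."""
    if wbcs_detected <= 0 or wbc_per_ml <= 0:
        raise ValueError("wbcs_detected and wbc_per_ml must be positive")
    return wbcs_detected / wbc_per_ml


def events_per_ml(counts: dict[str, float], volume_ml: float) -> dict[str, float]:
    """Per-category rates = count / analyzed volume."""
    if volume_ml <= 0:
        raise ValueError("analyzed volume must be positive")
    return {k: v / volume_ml for k, v in counts.items()}


def category_frequencies(counts: dict[str, float]) -> dict[str, float]:
    """Percentage of the rare total per category; absent if the total is 0.

    Only categories present in ``counts`` contribute; frequencies sum to 100
    over represented categories.
    """
    total = float(sum(counts.values()))
    if total <= 0:
        return {}
    return {k: 100.0 * v / total for k, v in counts.items()}


@dataclass
class SampleEnumeration:
    """Per-sample rare-event enumeration: counts, volume, rates, frequencies."""

    meta: SampleMeta
    counts: dict[str, int]
    volume_ml: float
    rates: dict[str, float] = field(init=False)
    frequencies: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be nonnegative")
        self.rates = events_per_ml(self.counts, self.volume_ml)
        self.frequencies = category_frequencies(self.counts)

    @property
    def total_cells(self) -> int:
        return int(sum(self.counts.get(c.value, 0) for c in CELL_CLASSES))

    @property
    def total_levs(self) -> int:
        return int(sum(self.counts.get(c.value, 0) for c in LEV_CLASSES))

    @property
    def total(self) -> int:
        return self.total_cells + self.total_levs

    def rate_of(self, key: str) -> float:
        if key == "total_cells":
            return self.total_cells / self.volume_ml
        if key == "total_levs":
            return self.total_levs / self.volume_ml
        if key == "total":
            return self.total / self.volume_ml
        return self.rates.get(key, 0.0)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.meta.sample_id,
            "cohort": self.meta.cohort,
            "wbc_per_ml": self.meta.wbc_per_ml,
            "slides_per_test": self.meta.slides_per_test,
            "wbcs_detected": self.meta.wbcs_detected,
            "volume_ml": self.volume_ml,
            "counts": {k: int(v) for k, v in self.counts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleEnumeration":
        meta = SampleMeta(
            sample_id=d["sample_id"], cohort=d["cohort"],
            wbc_per_ml=d["wbc_per_ml"], slides_per_test=d["slides_per_test"],
            wbcs_detected=d["wbcs_detected"])
        return cls(meta=meta, counts=dict(d["counts"]), volume_ml=d["volume_ml"])


def enumerate_sample(classified: pd.DataFrame, meta: SampleMeta) -> SampleEnumeration:
    """Build a :class:`SampleEnumeration` from a classified-event table.

    Only rows classified into one of the 12 rare categories and passing the
    per-frame LEV filter (column ``passed_frame_filter``, if present) are
    counted. The analyzed volume comes from the sample metadata.
    """
    df = classified
    if "passed_frame_filter" in df.columns:
        df = df[df["passed_frame_filter"].fillna(True)]
    rare_names = {c.value for c in RARE_CLASSES}
    counted = df[df["event_class"].isin(rare_names)]
    counts = {c.value: int((counted["event_class"] == c.value).sum())
              for c in RARE_CLASSES}
    volume = blood_volume_analyzed(meta.wbcs_detected, meta.wbc_per_ml)
    return SampleEnumeration(meta=meta, counts=counts, volume_ml=volume)


def save_enumerations(samples: list[SampleEnumeration], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in samples], indent=1))


def load_enumerations(path: str | Path) -> list[SampleEnumeration]:
    return [SampleEnumeration.from_dict(d)
            for d in json.loads(Path(path).read_text())]


def rates_table(samples: list[SampleEnumeration]) -> pd.DataFrame:
    """One row per sample: cohort, per-category events/mL and totals."""
    rows = []
    for s in samples:
        row = {"sample_id": s.meta.sample_id, "cohort": s.meta.cohort,
               "volume_ml": s.volume_ml}
        for c in RARE_CLASSES:
            row[c.value] = s.rates.get(c.value, 0.0)
        row["total_cells"] = s.rate_of("total_cells")
        row["total_levs"] = s.rate_of("total_levs")
        row["total"] = s.rate_of("total")
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(samples: list[SampleEnumeration]) -> pd.DataFrame:
    """Median / range / mean events-per-mL and detection prevalence per
    category and cohort.

    The median uses the midpoint-of-middle-two convention for even n;
    prevalence is the percentage of samples with at least one event of the
    category.
    """
    if not samples:
        raise ValueError("cohort_summary requires at least one sample")
    keys = [c.value for c in RARE_CLASSES] + ["total_cells", "total_levs", "total"]
    rows = []
    for cohort in sorted({s.meta.cohort for s in samples}):
        grp = [s for s in samples if s.meta.cohort == cohort]
        for key in keys:
            vals = np.array([s.rate_of(key) for s in grp])
            if key in ("total_cells", "total_levs", "total"):
                n_pos = sum(1 for s in grp if getattr(s, key) > 0)
            else:
                n_pos = sum(1 for s in grp if s.counts.get(key, 0) > 0)
            rows.append({
                "cohort": cohort, "category": key, "n_samples": len(grp),
                "median": float(np.median(vals)),
                "min": float(vals.min()), "max": float(vals.max()),
                "mean": float(vals.mean()),
                "n_detected": n_pos,
                "prevalence_pct": round_half_up(100.0 * n_pos / len(grp), 2),
            })
    return pd.DataFrame(rows)


def proximity_split(n_free_floating: int, n_cell_proximal: int) -> dict[str, float]:
    """LEV free-floating vs cell-proximal percentages (1 d.p., half-up)."""
    total = n_free_floating + n_cell_proximal
    if total <= 0:
        return {}
    return {
        "free_floating_pct": round_half_up(100.0 * n_free_floating / total, 1),
        "cell_proximal_pct": round_half_up(100.0 * n_cell_proximal / total, 1),
    }
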