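"""Prevalence tables and the closed-form xenograft formulas.

Small, exact arithmetic: cohort prevalence as a percentage rounded
half-away-from-zero to one decimal (matching how such tables are
printed), ellipsoid tumor volume V = 0.52 a² b, and tumor growth
inhibition TGI = [1 − (Ti − T0)/(Vi − V0)] × 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

__all__ = [
    "PrevalenceRecord",
    "prevalence",
    "prevalence_table",
    "read_counts_table",
    "tumor_volume",
    "tumor_growth_inhibition",
]


@dataclass(frozen=True)
class PrevalenceRecord:
    cancer_type: str
    n_total: int
    n_positive: int
    frequency: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_total):
            raise ValueError(
                f"{self.cancer_type}: need 0 <= n_positive <= n_total, "
                f"got {self.n_positive}/{self.n_total}"
            )


def prevalence(n_positive: int, n_total: int) -> float:
    """Percentage of positives, rounded half-away-from-zero to 1 decimal."""
    n_positive, n_total = int(n_positive), int(n_total)
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_positive <= n_total):
        raise ValueError("need 0 <= n_positive <= n_total")
    pct = Decimal(100 * n_positive) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns cancer_type, n_total, n_positive."""
    df = pd.read_csv(path, sep="\t")
    missing = {"cancer_type", "n_total", "n_positive"} - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def prevalence_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-row frequencies from a counts table."""
    records = [
        PrevalenceRecord(
            cancer_type=str(row.cancer_type),
            n_total=int(row.n_total),
            n_positive=int(row.n_positive),
            frequency=prevalence(int(row.n_positive), int(row.n_total)),
        )
        for row in counts.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "cancer_type": [r.cancer_type for r in records],
            "n_total": [r.n_total for r in records],
            "n_positive": [r.n_positive for r in records],
            "frequency": [r.frequency for r in records],
        }
    )


def tumor_volume(a: float, b: float) -> float:
    """Ellipsoid xenograft volume V = 0.52 a² b (a, b in mm; V in mm³).

    ``a`` is the minimal and ``b`` the maximal diameter.
    """
    if a < 0 or b < 0:
        raise ValueError("diameters must be non-negative")
    if a > b:
        raise ValueError("a is the minimal diameter; expected a <= b")
    return 0.52 * (a ** 2) * b


def tumor_growth_inhibition(Ti: float, T0: float, Vi: float, V0: float) -> float:
    """TGI (%) = [1 − (Ti − T0)/(Vi − V0)] × 100.

    Ti/T0 are mean treated volumes at endpoint/start, Vi/V0 the vehicle
    means.  Scale-invariant under common rescaling of all four volumes.
    """
    if Vi == V0:
        raise ZeroDivisionError("vehicle group did not change volume (Vi == V0)")
    return (1.0 - (Ti - T0) / (Vi - V0)) * 100.0
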