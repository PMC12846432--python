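"""Chemical-durability indices for insecticide-treated nets.

Net pieces are assayed for active-ingredient content (g/kg) before and
after washing; two indices summarise wash durability:

* retention          100 * Cn / C0            (overall fraction kept)
* wash-resistance    100 * (Cn / C0)^(1/n)    (per-wash geometric retention)

where C0 is the unwashed content, Cn the content after n standardised
washes (n = 20 in the WHO protocol).  Content can be converted to a
surface dose (mg/m^2) from the fabric weight, and checked against the
manufacturer's declared content with the WHO +/-25% tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "ChemMeasure",
    "retention_pct",
    "wash_resistance_index",
    "content_per_area",
    "within_tolerance",
    "durability_table",
]

DEFAULT_WASHES = 20


@dataclass(frozen=True)
class ChemMeasure:
    """One content measurement of an analyte on a net product."""

    product: str
    analyte: str  # e.g. 'alpha-cypermethrin' or 'PBO'
    content_g_per_kg: float
    washes: int  # 0 or the standardised wash count
    phase: str  # 'before' or 'after' the hut trial
    fabric_weight_g_per_m2: float | None = None

    def __post_init__(self) -> None:
        if self.content_g_per_kg < 0:
            raise ValueError("content must be non-negative")
        if self.fabric_weight_g_per_m2 is not None and self.fabric_weight_g_per_m2 <= 0:
            raise ValueError("fabric weight must be positive")


def retention_pct(c0: float, cn: float) -> float:
    """Overall retention 100 * cn / c0 after the full wash series."""
    if c0 <= 0:
        raise ValueError("unwashed content c0 must be positive")
    if cn < 0:
        raise ValueError("washed content cn must be non-negative")
    return 100.0 * cn / c0


def wash_resistance_index(c0: float, cn: float, n: int = DEFAULT_WASHES) -> float:
    """Per-wash geometric retention 100 * (cn/c0)^(1/n).

    The index is the constant per-wash retention that would produce the
    observed overall loss over n washes; 100% means no loss.
    """
    if c0 <= 0:
        raise ValueError("unwashed content c0 must be positive")
    if n < 1:
        raise ValueError("wash count n must be >= 1")
    if cn <= 0:
        raise ValueError(
            "washed content cn must be positive (a zero content drives the index to zero "
            "and the per-wash log-loss to infinity)"
        )
    return 100.0 * (cn / c0) ** (1.0 / n)


def content_per_area(content_g_per_kg: float, fabric_weight_g_per_m2: float) -> float:
    """Convert g/kg content into a surface dose in mg/m^2.

    (g analyte / kg fabric) x (g fabric / m^2) = mg analyte / m^2.
    """
    if content_g_per_kg < 0:
        raise ValueError("content must be non-negative")
    if fabric_weight_g_per_m2 <= 0:
        raise ValueError("fabric weight must be positive")
    return content_g_per_kg * fabric_weight_g_per_m2


def within_tolerance(measured: float, declared: float, tol: float = 0.25) -> bool:
    """WHO content check: |measured - declared| / declared <= tol."""
    if declared <= 0:
        raise ValueError("declared content must be positive")
    return abs(measured - declared) / declared <= tol


def durability_table(measures: Iterable[ChemMeasure], n_washes: int = DEFAULT_WASHES) -> pd.DataFrame:
    """Retention and wash-resistance index per product/analyte/phase.

    Expects, for each (product, analyte, phase), an unwashed (washes=0)
    and a washed (washes=n) measurement; incomplete pairs are skipped.
    """
    frame = pd.DataFrame(
        {
            "product": m.product,
            "analyte": m.analyte,
            "phase": m.phase,
            "washes": m.washes,
            "content": m.content_g_per_kg,
        }
        for m in measures
    )
    rows = []
    for (product, analyte, phase), grp in frame.groupby(
        ["product", "analyte", "phase"], sort=False
    ):
        by_wash = grp.set_index("washes")["content"]
        if 0 not in by_wash.index or n_washes not in by_wash.index:
            continue
        c0, cn = float(by_wash[0]), float(by_wash[n_washes])
        rows.append(
            {
                "product": product,
                "analyte": analyte,
                "phase": phase,
                "content_0w_g_per_kg": c0,
                f"content_{n_washes}w_g_per_kg": cn,
                "retention_pct": retention_pct(c0, cn),
                "wash_resistance_index_pct": wash_resistance_index(c0, cn, n_washes),
            }
        )
    return pd.DataFrame(rows)
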