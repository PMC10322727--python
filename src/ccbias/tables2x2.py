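"""Exact 2x2 contingency-table utilities: sensitivity, specificity, odds ratio.

Convention: the reference standard (the study's binary outcome) indexes the
columns, the index test (the proxy) indexes the rows, so

* tp = proxy positive & reference positive,  fn = proxy negative & reference positive
* tn = proxy negative & reference negative,  fp = proxy positive & reference negative

Percent rendering is half-up to one decimal to match how diagnostic-accuracy
tables are printed; the raw proportions are always available at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


@dataclass(frozen=True)
class TwoByTwo:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


def percent_1dp(p: float) -> float:
    """Proportion -> percent, rounded half-up to 1 decimal (report parity)."""
    return float(Decimal(repr(100.0 * p)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def sensitivity(t: TwoByTwo) -> float:
    """P(proxy positive | reference positive) = tp / (tp + fn)."""
    if t.tp + t.fn == 0:
        raise ZeroDivisionError("no reference-positive records: sensitivity undefined")
    return t.tp / (t.tp + t.fn)


def specificity(t: TwoByTwo) -> float:
    """P(proxy negative | reference negative) = tn / (tn + fp)."""
    if t.tn + t.fp == 0:
        raise ZeroDivisionError("no reference-negative records: specificity undefined")
    return t.tn / (t.tn + t.fp)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    log_se: float
    corrected: bool

    @property
    def log_odds_ratio(self) -> float:
        return math.log(self.odds_ratio)


def odds_ratio(t: TwoByTwo, continuity_correction: bool = False) -> OddsRatioResult:
    """Cross-product odds ratio (tp*tn)/(fp*fn) with the Woolf log-scale SE.

    A zero cell raises unless ``continuity_correction`` adds 0.5 to every cell
    (flagged in the result, never silent).
    """
    cells = [t.tp, t.tn, t.fp, t.fn]
    corrected = False
    if any(c == 0 for c in cells):
        if not continuity_correction:
            raise ZeroDivisionError("zero cell: enable continuity_correction for a finite OR")
        cells = [c + 0.5 for c in cells]
        corrected = True
    tp, tn, fp, fn = cells
    return OddsRatioResult(
        odds_ratio=(tp * tn) / (fp * fn),
        log_se=math.sqrt(1 / tp + 1 / tn + 1 / fp + 1 / fn),
        corrected=corrected,
    )


# Cross-tabulations of the proxy depression measures from primary-care records
# against the study interview diagnosis, with the printed accuracy figures
# (percent, 1 decimal) they must reproduce.
TABLE3_FIXTURES: dict[str, dict] = {
    "current": {
        "table": TwoByTwo(tn=3012, fp=72, fn=199, tp=71),
        "sensitivity_pct": 26.3,
        "specificity_pct": 97.7,
    },
    "future": {
        "table": TwoByTwo(tn=2500, fp=640, fn=126, tp=156),
        "sensitivity_pct": 55.3,
        "specificity_pct": 79.6,
    },
    "historical": {
        "table": TwoByTwo(tn=3233, fp=127, fn=217, tp=64),
        "sensitivity_pct": 22.8,
        "specificity_pct": 96.2,
    },
}


def check_fixture_accuracy() -> list[dict]:
    """Recompute sensitivity/specificity for every packaged fixture.

    Returns one record per (measure, metric) with computed and expected
    percents and an ``ok`` flag; used by the ``table3-check`` CLI subcommand.
    """
    out = []
    for name, fx in TABLE3_FIXTURES.items():
        t = fx["table"]
        for metric, fun in (("sensitivity", sensitivity), ("specificity", specificity)):
            computed = percent_1dp(fun(t))
            expected = fx[f"{metric}_pct"]
            out.append({
                "measure": name,
                "metric": metric,
                "computed_pct": computed,
                "expected_pct": expected,
                "ok": computed == expected,
            })
    return out
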