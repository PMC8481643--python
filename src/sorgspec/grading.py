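"""Composition formulas and food/feed/fuel grading of sorghum grains.

Cellulose, hemicellulose and lignin come from two-stage acid hydrolysis with
the standard anhydro-corrections: cellulose = 0.9 x glucose, hemicellulose =
0.88 x (xylose + arabinose), lignin = acid-soluble + acid-insoluble.  Grains
are then routed by a threshold decision table on tannin, hemicellulose and
starch (g kg^-1): high-tannin, high-hemicellulose grain goes to fuel; low
tannin with high hemicellulose suits both feed and fuel; low tannin and
hemicellulose with starch >= 650 g kg^-1 is food grain, below that feed.
"""

from __future__ import annotations

from dataclasses import dataclass

GRADE_LABELS = ("food", "feed", "fuel", "feed_fuel")


@dataclass(frozen=True)
class GradingRules:
    """Threshold set for the decision table (g kg^-1); all boundaries are >=."""

    tannin_fuel_threshold: float = 15.0
    hemicellulose_fuel_threshold: float = 50.0
    starch_food_threshold: float = 650.0

    def __post_init__(self):
        if min(self.tannin_fuel_threshold, self.hemicellulose_fuel_threshold,
               self.starch_food_threshold) <= 0:
            raise ValueError("grading thresholds must be > 0")


def nrel_composition(
    glucose: float,
    xylose: float,
    arabinose: float,
    acid_soluble_lignin: float,
    acid_insoluble_lignin: float,
) -> tuple[float, float, float]:
    """Structural composition (cellulose, hemicellulose, lignin) in g kg^-1.

    Applies the anhydro correction factors 0.9 (hexose) and 0.88 (pentoses,
    applied to the xylose + arabinose sum) and sums the two lignin fractions.
    """
    inputs = (glucose, xylose, arabinose, acid_soluble_lignin, acid_insoluble_lignin)
    if any(v < 0 for v in inputs):
        raise ValueError("hydrolysis inputs must be >= 0")
    cellulose = 0.9 * glucose
    hemicellulose = 0.88 * (xylose + arabinose)
    lignin = acid_soluble_lignin + acid_insoluble_lignin
    return cellulose, hemicellulose, lignin


def grade_sample(
    tannin: float,
    hemicellulose: float,
    starch: float,
    rules: GradingRules | None = None,
) -> str:
    """Assign exactly one of food / feed / fuel / feed_fuel.

    Decision table (thresholds from ``rules``, boundaries inclusive):
    tannin >= 15 -> fuel (regardless of hemicellulose; the high-tannin,
    low-hemicellulose corner is conservatively routed to fuel);
    tannin < 15 and hemicellulose >= 50 -> feed_fuel;
    otherwise starch >= 650 -> food, else feed.
    """
    if min(tannin, hemicellulose, starch) < 0:
        raise ValueError("concentrations must be >= 0")
    rules = rules or GradingRules()
    if tannin >= rules.tannin_fuel_threshold:
        return "fuel"
    if hemicellulose >= rules.hemicellulose_fuel_threshold:
        return "feed_fuel"
    if starch >= rules.starch_food_threshold:
        return "food"
    return "feed"
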