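"""Allele-fraction statistics for heterozygous call QC.

A germline heterozygote should show a ~1:1 ratio of reference and
alternate reads.  Two per-call statistics quantify departure from that
ideal:

* ``alt_fraction`` — alternate reads / total reads.  This is the quantity
  the acceptance windows are defined on (a het is accepted when its
  alternate fraction lies in a symmetric window around 50%).
* ``balance_ratio`` — 100 x min/max of the two allele counts.  This is the
  "how balanced are the two alleles" formulation (15/20 reads -> 75%); it
  is a deterministic function of ``alt_fraction`` and is provided because
  both formulations are in routine lab use.

The window optimizer finds the tightest symmetric window around 50% that
retains every supplied (true) call — the narrowest allele-fraction
acceptance band achieving 100% sensitivity on a truth cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_CEILING, ROUND_FLOOR, Decimal
from typing import Iterable, List, Sequence, Tuple, Union

from .models import NoCoverageError, PpglValError, VariantCall

#: tolerance for window-membership comparisons, absorbing float noise in
#: quantities like 9/30*100 (= 30 minus one ulp)
_EPS = 1e-9


def alt_fraction(ref_reads: int, alt_reads: int) -> float:
    """Alternate-allele read fraction, ``alt / (ref + alt)``, unrounded."""
    total = ref_reads + alt_reads
    if total <= 0:
        raise NoCoverageError("cannot compute allele fraction with zero total reads")
    return alt_reads / total


def balance_ratio(ref_reads: int, alt_reads: int) -> float:
    """Allele-balance percentage: 100 x min/max of the two allele counts."""
    hi = max(ref_reads, alt_reads)
    lo = min(ref_reads, alt_reads)
    if hi <= 0:
        raise NoCoverageError("cannot compute balance ratio with zero reads")
    return 100.0 * lo / hi


@dataclass(frozen=True)
class AfrWindow:
    """An allele-fraction acceptance window in percent, bounds inclusive."""

    lower_pct: float
    upper_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_pct <= self.upper_pct <= 100.0):
            raise PpglValError(
                f"invalid window [{self.lower_pct}, {self.upper_pct}]"
            )

    @property
    def symmetric(self) -> bool:
        """True when the window is symmetric around 50% (to 0.1% precision)."""
        return abs(self.lower_pct + self.upper_pct - 100.0) < 0.05

    def contains_fraction(self, fraction: float) -> bool:
        """True iff ``fraction`` (in [0,1]) lies inside the window, inclusive.

        The exclusion rule is strict (< lower or > upper), so a fraction
        sitting exactly on a bound is retained.
        """
        pct = 100.0 * fraction
        return self.lower_pct - _EPS <= pct <= self.upper_pct + _EPS

    def as_dict(self) -> dict:
        return {
            "lower_pct": self.lower_pct,
            "upper_pct": self.upper_pct,
            "symmetric": self.symmetric,
        }

    def __str__(self) -> str:  # "30-70" / "44.8-55.2"
        def fmt(x: float) -> str:
            return f"{x:g}"

        return f"{fmt(self.lower_pct)}-{fmt(self.upper_pct)}"


@dataclass(frozen=True)
class AfrAssessment:
    """Per-call allele-fraction summary used by reports and the AFR filter."""

    call: VariantCall
    alt_fraction_pct: float
    balance_ratio_pct: float
    deviation_pct: float  # |alt_fraction_pct - 50|


def assess(call: VariantCall) -> AfrAssessment:
    f = alt_fraction(call.ref_reads, call.alt_reads)
    return AfrAssessment(
        call=call,
        alt_fraction_pct=100.0 * f,
        balance_ratio_pct=balance_ratio(call.ref_reads, call.alt_reads),
        deviation_pct=abs(100.0 * f - 50.0),
    )


def in_window(item: Union[AfrAssessment, VariantCall, float], window: AfrWindow) -> bool:
    """Window membership for an assessment, a call, or a raw fraction in [0,1]."""
    if isinstance(item, AfrAssessment):
        frac = item.alt_fraction_pct / 100.0
    elif isinstance(item, VariantCall):
        frac = alt_fraction(item.ref_reads, item.alt_reads)
    else:
        frac = float(item)
    return window.contains_fraction(frac)


_STEPS = {"integer": Decimal("1"), "one_decimal": Decimal("0.1")}


def _round_outward(lower: float, upper: float, rounding: str) -> Tuple[float, float]:
    """Floor/ceil the bounds at the reporting precision so the window can
    only widen, never excluding the binding call."""
    try:
        step = _STEPS[rounding]
    except KeyError:
        raise PpglValError(f"unknown rounding mode {rounding!r}") from None
    # snap away float noise (e.g. 44.800000000000004) before quantizing
    lo = Decimal(repr(round(lower, 7))).quantize(step, rounding=ROUND_FLOOR)
    hi = Decimal(repr(round(upper, 7))).quantize(step, rounding=ROUND_CEILING)
    return float(lo), float(hi)


def max_deviation(calls: Sequence[VariantCall]) -> float:
    """Largest |alt_fraction - 0.5| over the calls (a fraction, not percent)."""
    if not calls:
        raise PpglValError("maximum deviation undefined for an empty call set")
    return max(abs(alt_fraction(c.ref_reads, c.alt_reads) - 0.5) for c in calls)


def binding_calls(calls: Sequence[VariantCall]) -> List[VariantCall]:
    """All calls achieving the maximum deviation, in input order."""
    d = max_deviation(calls)
    out = []
    for c in calls:
        if abs(abs(alt_fraction(c.ref_reads, c.alt_reads) - 0.5) - d) < _EPS:
            out.append(c)
    return out


def tightest_symmetric_window(
    calls: Iterable[VariantCall], rounding: str = "one_decimal"
) -> AfrWindow:
    """Narrowest symmetric window [50-d, 50+d] (percent) containing every call.

    ``d`` is the maximum |alt_fraction - 50%| over the calls; the bounds are
    then rounded outward (floor/ceil) to the requested precision
    (``"integer"`` or ``"one_decimal"``) so every input call remains inside
    the reported window.
    """
    calls = list(calls)
    if not calls:
        raise PpglValError("tightest window undefined for an empty call set")
    d = 100.0 * max_deviation(calls)
    lo, hi = _round_outward(50.0 - d, 50.0 + d, rounding)
    return AfrWindow(max(lo, 0.0), min(hi, 100.0))
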