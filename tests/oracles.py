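"""Independent brute-force oracles the interval algorithms are checked against."""

from collections import defaultdict

from polypharm.supply_diary import PrescriptionRecord, days_supply


def day_stack_covered(fills: list[tuple[int, int]]) -> set[int]:
    """Day-by-day supply simulation for one (patient, class) stream.

    Each fill banks its whole days-of-supply on its dispensing day; every
    day on which the bank is non-empty is a covered day and consumes one
    day of supply.  Early refills therefore queue behind the current
    supply — the behaviour the shift-on-overlap interval rule encodes.

    *fills* is a list of ``(dispense_day, supply_days)`` pairs.
    """
    by_day: dict[int, int] = defaultdict(int)
    for day, supply in fills:
        by_day[day] += supply
    covered: set[int] = set()
    bank = 0
    day = min(by_day)
    last_dispense = max(by_day)
    while day <= last_dispense or bank > 0:
        bank += by_day.get(day, 0)
        if bank > 0:
            covered.add(day)
            bank -= 1
        day += 1
    return covered


def diary_covered_sets(
    records: list[PrescriptionRecord], rounding: str = "round"
) -> dict[str, set[int]]:
    """Per-class covered-day sets for one patient, via the day-stack oracle."""
    per_class: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for r in records:
        per_class[r.atc4].append(
            (r.dispense_day, days_supply(r.n_packages, r.ddd_per_package, rounding))
        )
    return {atc4: day_stack_covered(fills) for atc4, fills in per_class.items()}


def daywise_window_counts(
    covered: dict[str, set[int]], bounds: list[tuple[int, int]]
) -> list[int]:
    """Distinct classes with >=1 covered day per window, counted day by day."""
    counts = []
    for lo, hi in bounds:
        window_days = set(range(lo, hi))
        counts.append(sum(1 for days in covered.values() if days & window_days))
    return counts


def odds_ratio_2x2(exposed, outcome) -> float:
    """Closed-form cross-product odds ratio from two boolean sequences."""
    a = b = c = d = 0
    for e, o in zip(exposed, outcome, strict=True):
        if e and o:
            a += 1
        elif e:
            b += 1
        elif o:
            c += 1
        else:
            d += 1
    return (a * d) / (b * c)
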