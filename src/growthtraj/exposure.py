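"""Drug-exposure episodes, prescribed amounts, and adherence.

Prescriptions are dated fills with a days-supply; a fill covers the closed
whole-day interval [start, start + days_supply - 1] under the assumption
that medication is taken as dispensed.  An exposure episode for a drug
class runs from initiation until the first impermissible refill gap: up to
30 uncovered days are allowed during September-May, and up to 121 days for
any gap touching June-August (structured summer treatment interruptions).
When a longer gap occurs the patient is considered to have discontinued on
the last covered day before the gap.

Supply accounting follows pharmacy-claims conventions: the prescribed
amount of one drug at one dose is the sum of fill lengths (early refills
stockpile), the class total sums the per-dose amounts but caps total
between-stream overlap at 90 days, and the medication possession ratio
(MPR) is supply over episode length, capped at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

__all__ = [
    "PrescriptionRecord",
    "ExposureEpisode",
    "ExposureMetrics",
    "gap_allowance",
    "build_episodes",
    "prescribed_amount_per_dose",
    "total_prescribed_amount",
    "mpr",
    "episode_metrics",
]

#: Allowable uncovered days between fills, by season.
GAP_ALLOWANCE_SCHOOL_YEAR = 30
GAP_ALLOWANCE_SUMMER = 121
SUMMER_MONTHS = (6, 7, 8)

ONE_DAY = timedelta(days=1)


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_name: str
    drug_class: str  # guanfacine | stimulant | atomoxetine | other
    dose_label: str
    start_date: date
    days_supply: int

    def __post_init__(self):
        if self.days_supply < 1:
            raise ValueError("days_supply must be >= 1")

    @property
    def end_date(self) -> date:
        """Last covered day (closed interval)."""
        return self.start_date + timedelta(days=self.days_supply - 1)


@dataclass(frozen=True)
class ExposureEpisode:
    patient_id: str
    drug_classes: frozenset
    start_date: date
    discontinuation_date: date
    prescriptions: tuple = field(default_factory=tuple)

    @property
    def length_days(self) -> int:
        return (self.discontinuation_date - self.start_date).days + 1


@dataclass(frozen=True)
class ExposureMetrics:
    prescribed_amount_days: int
    episode_length_days: int
    mpr: float


def gap_allowance(gap_start: date, gap_end: date) -> int:
    """Allowable length for the uncovered interval [gap_start, gap_end].

    121 days if the gap touches any June-August day (drug holidays anchor
    to the school vacation), else 30.
    """
    if gap_end < gap_start:
        raise ValueError("empty gap interval")
    for year in range(gap_start.year, gap_end.year + 1):
        summer_start = date(year, 6, 1)
        summer_end = date(year, 8, 31)
        if gap_start <= summer_end and gap_end >= summer_start:
            return GAP_ALLOWANCE_SUMMER
    return GAP_ALLOWANCE_SCHOOL_YEAR


def _merge_coverage(prescriptions) -> list[tuple[date, date]]:
    """Union of closed coverage intervals; back-to-back fills (next start =
    previous end + 1) merge into one block."""
    intervals = sorted((rx.start_date, rx.end_date) for rx in prescriptions)
    merged: list[list[date]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1] + ONE_DAY:
            if end > merged[-1][1]:
                merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def build_episodes(prescriptions, drug_class: str, from_date: date) -> list[ExposureEpisode]:
    """Exposure episodes for one drug class, beginning at/after ``from_date``.

    Coverage blocks separated by a gap within the seasonal allowance belong
    to the same episode; a longer gap terminates the episode on the last
    covered day before it.  Blocks ending before ``from_date`` are ignored
    (they belong to exposure prior to the anchor date).
    """
    rxs = [rx for rx in prescriptions if rx.drug_class == drug_class]
    if not rxs:
        return []
    blocks = [b for b in _merge_coverage(rxs) if b[1] >= from_date]
    if not blocks:
        return []
    patient_id = rxs[0].patient_id

    episodes: list[ExposureEpisode] = []
    ep_start = max(blocks[0][0], from_date)
    ep_end = blocks[0][1]
    for start, end in blocks[1:]:
        gap_start = ep_end + ONE_DAY
        gap_end = start - ONE_DAY
        gap_days = (gap_end - gap_start).days + 1
        if gap_days > gap_allowance(gap_start, gap_end):
            episodes.append(_make_episode(patient_id, drug_class, ep_start, ep_end, rxs))
            ep_start = start
        ep_end = end
    episodes.append(_make_episode(patient_id, drug_class, ep_start, ep_end, rxs))
    return episodes


def _make_episode(patient_id, drug_class, start, end, rxs) -> ExposureEpisode:
    members = tuple(
        rx for rx in sorted(rxs, key=lambda r: (r.start_date, r.drug_name, r.dose_label))
        if rx.start_date <= end and rx.end_date >= start
    )
    return ExposureEpisode(
        patient_id=patient_id,
        drug_classes=frozenset([drug_class]),
        start_date=start,
        discontinuation_date=end,
        prescriptions=members,
    )


def _clipped_days(rx_start: date, rx_end: date, window: tuple[date, date]) -> int:
    lo = max(rx_start, window[0])
    hi = min(rx_end, window[1])
    return max(0, (hi - lo).days + 1)


def prescribed_amount_per_dose(prescriptions, window: tuple[date, date]) -> int:
    """Supply days for one drug at one dose within a window: sum of fill
    lengths clipped to the window, overlaps between fills not merged
    (an early refill still dispenses a full supply)."""
    return sum(_clipped_days(rx.start_date, rx.end_date, window) for rx in prescriptions)


def total_prescribed_amount(prescriptions, window: tuple[date, date]) -> int:
    """Class-level supply days within a window, with overlap between
    different drug/dose streams capped at 90 days.

    With ``c(d)`` the number of distinct drug+dose streams covering day
    ``d`` (each stream's coverage taken as the union of its fills), the
    between-stream overlap is ``O = sum_d max(0, c(d) - 1)``; the result is
    the raw supply total ``T`` minus ``max(0, O - 90)``.
    """
    streams: dict[tuple[str, str], list] = {}
    for rx in prescriptions:
        streams.setdefault((rx.drug_name, rx.dose_label), []).append(rx)

    total_supply = 0
    stream_union_days = 0
    all_blocks = []
    for rxs in streams.values():
        total_supply += prescribed_amount_per_dose(rxs, window)
        for s, e in _merge_coverage(rxs):
            days = _clipped_days(s, e, window)
            if days:
                stream_union_days += days
                all_blocks.append((max(s, window[0]), min(e, window[1])))

    # days covered by at least one stream
    covered_any = 0
    for s, e in _merge_intervals(all_blocks):
        covered_any += (e - s).days + 1

    overlap = stream_union_days - covered_any
    return total_supply - max(0, overlap - 90)


def _merge_intervals(intervals: list[tuple[date, date]]) -> list[tuple[date, date]]:
    merged: list[list[date]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + ONE_DAY:
            if end > merged[-1][1]:
                merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def mpr(prescribed_amount_days: int, episode_length_days: int) -> float:
    """Medication possession ratio: supply over episode length, capped at 1."""
    if episode_length_days < 1:
        raise ValueError("episode_length_days must be >= 1")
    return min(1.0, prescribed_amount_days / episode_length_days)


def episode_metrics(prescriptions, episode: ExposureEpisode) -> ExposureMetrics:
    """Prescribed amount and MPR for a class episode, evaluated over the
    episode window."""
    drug_class = next(iter(episode.drug_classes))
    rxs = [rx for rx in prescriptions if rx.drug_class == drug_class]
    window = (episode.start_date, episode.discontinuation_date)
    amount = total_prescribed_amount(rxs, window)
    return ExposureMetrics(
        prescribed_amount_days=amount,
        episode_length_days=episode.length_days,
        mpr=mpr(amount, episode.length_days),
    )
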