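"""Splice-event statistics.

Caller-specific confidence filtering, cross-caller merging, event-type
composition, knowledge-base-normalized detection rates, proximal-exon
bias of alternative last exons, and reading-frame (frameshift)
enrichment.  An alternative segment whose length is not a multiple of 3
shifts the reading frame when included/excluded, so transcripts carrying
it are candidates for degradation by nonsense-mediated decay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import chi2_contingency, fisher_exact, hypergeom

from .io_formats import EventCallRecord

logger = logging.getLogger(__name__)


@dataclass
class EventSet:
    """A named collection of event ids with provenance."""

    name: str
    event_ids: tuple[str, ...]
    condition: str = ""
    direction: str = ""  # increasing | decreasing | ""
    callers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.event_ids)) != len(self.event_ids):
            raise ValueError(f"event set {self.name!r}: duplicate ids")

    def __len__(self) -> int:
        return len(self.event_ids)


@dataclass(frozen=True)
class FrameClass:
    """Reading-frame consequence of one event's alternative segment."""

    event_id: str
    alt_segment_length: int
    frameshift: bool

    @classmethod
    def of(cls, event: EventCallRecord) -> "FrameClass":
        length = event.alt_length
        return cls(event_id=event.event_id, alt_segment_length=length,
                   frameshift=length % 3 != 0)


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------

#: minimum |ΔΨ| for a call to count as responsive (both callers)
MIN_DELTA_PSI = 0.1
#: minimum Bayes factor for misolike calls
MIN_BAYES_FACTOR = 10.0
#: minimum MV[|ΔΨ|] at 0.95 for vastlike calls
MIN_MV_DPSI = 0.1


def filter_calls(records: Sequence[EventCallRecord], caller: str) -> list[EventCallRecord]:
    """Keep confidently changed events, by the caller's own confidence scale.

    misolike: |ΔΨ| ≥ 0.1 and Bayes factor ≥ 10.  vastlike: MV[|ΔΨ|] at
    0.95 ≥ 0.1 (the ΔΨ requirement is implied by the MV statistic).
    """
    kept = []
    for r in records:
        if r.caller != caller:
            continue
        if caller == "misolike":
            ok = abs(r.delta_psi) >= MIN_DELTA_PSI and r.confidence >= MIN_BAYES_FACTOR
        elif caller == "vastlike":
            ok = r.confidence >= MIN_MV_DPSI
        else:
            raise ValueError(f"unknown caller {caller!r}")
        if ok:
            kept.append(r)
    logger.info("filter_calls[%s]: %d of %d retained", caller, len(kept), len(records))
    return kept


def _dedup_key(event: EventCallRecord) -> tuple:
    return (event.event_type, event.coords.chrom, event.coords.strand, event.alt_segment)


@dataclass
class MergedEvent:
    """One event after cross-caller deduplication."""

    event_id: str
    event_type: str
    record: EventCallRecord  # misolike record preferred on collision
    callers: tuple[str, ...]


def merge_callers(
    misolike: Sequence[EventCallRecord], vastlike: Sequence[EventCallRecord]
) -> list[MergedEvent]:
    """Merge the two callers' events, removing repeated events.

    Duplicates are detected by the exact (type, chrom, strand,
    alternative-segment interval) key; on a collision the misolike
    record's Ψ values are retained and the provenance lists both callers.
    Idempotent and order-invariant over each caller's list.
    """
    by_key: dict[tuple, MergedEvent] = {}
    for rec in sorted(misolike, key=lambda r: r.event_id):
        key = _dedup_key(rec)
        if key not in by_key:
            by_key[key] = MergedEvent(rec.event_id, rec.event_type, rec, ("misolike",))
    for rec in sorted(vastlike, key=lambda r: r.event_id):
        key = _dedup_key(rec)
        if key in by_key:
            prior = by_key[key]
            if "vastlike" not in prior.callers:
                prior.callers = tuple(sorted(set(prior.callers) | {"vastlike"}))
        else:
            by_key[key] = MergedEvent(rec.event_id, rec.event_type, rec, ("vastlike",))
    return list(by_key.values())


# ---------------------------------------------------------------------------
# composition and detection rates
# ---------------------------------------------------------------------------


def type_composition(
    events: Sequence[MergedEvent] | Sequence[EventCallRecord],
) -> dict[str, float]:
    """Per-type proportions of an event set (sums to 1)."""
    if not events:
        raise ValueError("empty event set")
    counts: dict[str, int] = {}
    for e in events:
        counts[e.event_type] = counts.get(e.event_type, 0) + 1
    total = len(events)
    return {t: c / total for t, c in sorted(counts.items())}


def normalize_by_knowledge_base(
    detected: Mapping[str, int], annotated: Mapping[str, int]
) -> dict[str, float]:
    """Detection rate per event type: detected / annotated in the knowledge base."""
    rates = {}
    for etype, n_det in detected.items():
        n_ann = annotated.get(etype, 0)
        if n_ann <= 0:
            raise ValueError(f"event type {etype!r}: no annotated count")
        if n_det > n_ann:
            raise ValueError(f"event type {etype!r}: detected {n_det} > annotated {n_ann}")
        rates[etype] = n_det / n_ann
    return rates


# ---------------------------------------------------------------------------
# frameshift enrichment
# ---------------------------------------------------------------------------


def frameshift_enrichment(
    positive_frameshift: Sequence[bool], background_frameshift: Sequence[bool]
) -> tuple[list[list[int]], float]:
    """One-tailed Fisher's exact test for frameshift over-representation.

    Compares the fraction of frame-shifting events (alternative-segment
    length not a multiple of 3) in a monotone set against the background
    of all annotated events of the same type outside the set.  Returns
    the 2×2 table [[pos_shift, pos_inframe], [bg_shift, bg_inframe]] and
    the upper-tail (enrichment) p-value.
    """
    if not positive_frameshift or not background_frameshift:
        raise ValueError("both event sets must be non-empty")
    a = sum(bool(x) for x in positive_frameshift)
    b = len(positive_frameshift) - a
    c = sum(bool(x) for x in background_frameshift)
    d = len(background_frameshift) - c
    table = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("frameshift_enrichment: degenerate margin, p set to 1")
        return table, 1.0
    p = float(fisher_exact(table, alternative="greater")[1])
    return table, p


def fisher_one_tailed(table: Sequence[Sequence[int]]) -> float:
    """Upper-tail Fisher p as an explicit hypergeometric tail.

    For table [[a, b], [c, d]], p = P(X ≥ a) with
    X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b).
    """
    (a, b), (c, d) = table
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


# ---------------------------------------------------------------------------
# ALE proximal bias
# ---------------------------------------------------------------------------


def ale_is_proximal(event: EventCallRecord) -> bool:
    """Whether the selected last exon is the 5′-most (proximal) candidate.

    Candidates are the ``alt`` (selected) and ``other_last`` segments; the
    proximal one is 5′-most in transcript orientation, i.e. lowest start
    on the plus strand and highest start on the minus strand.
    """
    if event.event_type != "ALE":
        raise ValueError(f"event {event.event_id} is not ALE")
    alt = event.coords.segment("alt")
    other = event.coords.segment("other_last")
    if event.coords.strand == "+":
        return alt[0] < other[0]
    return alt[0] > other[0]


def ale_proximal_bias(
    increasing_proximal: Sequence[bool], decreasing_proximal: Sequence[bool]
) -> tuple[float, float]:
    """Chi-square test (no continuity correction) for proximal-exon bias.

    Contingency: (proximal/distal) × (increasing/decreasing).  A cell
    with expected count < 1 only triggers a warning; the statistic and p
    are still returned.
    """
    a = sum(bool(x) for x in increasing_proximal)
    b = len(increasing_proximal) - a
    c = sum(bool(x) for x in decreasing_proximal)
    d = len(decreasing_proximal) - c
    table = [[a, b], [c, d]]
    if min(a + b, c + d) == 0:
        raise ValueError("both directions need ALE events")
    if min(a + c, b + d) == 0:
        warnings.warn("ale_proximal_bias: one exon class absent, p = 1")
        return 0.0, 1.0
    stat, p, _, expected = chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warnings.warn("ale_proximal_bias: expected cell count < 1")
    return float(stat), float(p)
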