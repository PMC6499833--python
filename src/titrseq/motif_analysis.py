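"""Region-decomposed RBP motif enrichment.

Splice events are decomposed into transcript-oriented regions (for a
skipped exon: the three exons plus 300-nt windows at the start and end of
both flanking introns; for a retained intron: the two exons plus 300-nt
windows at the intron's start and end).  Each RBP motif is turned into a
log-odds scanner against the empirical background base composition, and
a window counts as a hit when its score exceeds 80% of the motif's
maximum achievable score.  Hits of all motifs sharing an RBP are merged,
hit counts are normalized by region length, and positive events are
compared against length-bin-matched background events with a
Mann–Whitney U test, Benjamini–Hochberg correction and a ±25% effect
filter.  Positional hit densities relative to splice junctions resolve
where around the junction a motif concentrates.

Only the sense strand of the transcript is scanned: these are RNA-binding
motifs and the substrate is single-stranded RNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import EventCallRecord, PWMRecord, RNA_ALPHABET

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: intronic window size flanking splice sites, nt
INTRON_WINDOW = 300
#: fraction of the maximum achievable score a window must exceed to be a hit
HIT_FRACTION = 0.8
#: pseudocount added to PWM probabilities before log-odds
PSEUDOCOUNT = 1e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# background model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackgroundModel:
    """Background A/C/G/U frequencies the log-odds scores are taken against."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if any(q <= 0 for q in self.freqs):
            raise ValueError("background frequencies must be positive")


def estimate_background(sequences: Mapping[str, str] | Sequence[str]) -> BackgroundModel:
    """Empirical base frequencies with add-one smoothing."""
    seqs = sequences.values() if isinstance(sequences, Mapping) else sequences
    counts = np.ones(4)  # add-one smoothing
    total = 0
    for seq in seqs:
        total += len(seq)
        for base, idx in _BASE_INDEX.items():
            counts[idx] += seq.count(base)
    if total == 0:
        raise ValueError("cannot estimate background from empty input")
    freqs = counts / counts.sum()
    return BackgroundModel(freqs=tuple(float(q) for q in freqs))


# ---------------------------------------------------------------------------
# motif scoring and scanning
# ---------------------------------------------------------------------------


@dataclass
class ScoredMotif:
    """A PWM converted to a log-odds scanner with a fixed hit threshold.

    ``log_odds[i, b] = log2((p[i, b] + ε) / q_b)``; the maximum achievable
    window score is the sum of per-position maxima, and a window is a hit
    when its score is strictly above ``hit_fraction`` × max_score.
    """

    motif_id: str
    rbp_names: tuple[str, ...]
    log_odds: np.ndarray  # L × 4, bits
    max_score: float
    hit_threshold: float

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]


def score_motif(
    pwm: PWMRecord,
    background: BackgroundModel,
    pseudocount: float = PSEUDOCOUNT,
    hit_fraction: float = HIT_FRACTION,
) -> ScoredMotif:
    """Build the log-odds matrix and the 80%-of-maximum hit threshold."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    q = np.asarray(background.freqs)
    w = np.log2((pwm.probs + pseudocount) / q[None, :])
    max_score = float(w.max(axis=1).sum())
    return ScoredMotif(
        motif_id=pwm.motif_id,
        rbp_names=pwm.rbp_names,
        log_odds=w,
        max_score=max_score,
        hit_threshold=hit_fraction * max_score,
    )


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.intp)
    except KeyError:
        for pos, base in enumerate(sequence):
            if base not in _BASE_INDEX:
                raise ValueError(
                    f"non-A/C/G/U character {base!r} at position {pos}"
                ) from None
        raise


def scan_hits(motif: ScoredMotif, sequence: str) -> list[int]:
    """All window offsets whose log-odds sum exceeds the hit threshold.

    Overlapping hits are all counted; a sequence shorter than the motif
    yields no hits.
    """
    L = motif.length
    if len(sequence) < L:
        return []
    idx = _encode(sequence)
    n_windows = len(sequence) - L + 1
    # per-position scores gathered once, then summed over sliding windows
    pos_scores = motif.log_odds[np.arange(L)[None, :], idx[np.arange(n_windows)[:, None] + np.arange(L)[None, :]]]
    scores = pos_scores.sum(axis=1)
    return [int(i) for i in np.flatnonzero(scores > motif.hit_threshold)]


# ---------------------------------------------------------------------------
# RBP grouping
# ---------------------------------------------------------------------------


def group_by_rbp(motifs: Sequence[ScoredMotif]) -> dict[str, list[ScoredMotif]]:
    """Cluster motifs by shared RBP; a motif with k names joins k groups."""
    groups: dict[str, list[ScoredMotif]] = {}
    for m in motifs:
        for name in m.rbp_names:
            groups.setdefault(name, []).append(m)
    return {k: groups[k] for k in sorted(groups)}


def group_hit_count(group: Sequence[ScoredMotif], sequence: str) -> int:
    """Merged hit count of a group on one sequence.

    Hits are merged as distinct (position, motif) pairs, so two motifs of
    the same RBP hitting the same offset both count.
    """
    return sum(len(scan_hits(m, sequence)) for m in group)


# ---------------------------------------------------------------------------
# region decomposition
# ---------------------------------------------------------------------------


@dataclass
class EventRegions:
    """Transcript-oriented region sequences of one event."""

    event_id: str
    regions: dict[str, str]


def _intron_windows(start: int, end: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Start/end 300-nt windows of an intron, truncated at the midpoint."""
    length = end - start
    w = min(INTRON_WINDOW, length // 2) if length < 2 * INTRON_WINDOW else INTRON_WINDOW
    return (start, start + w), (end - w, end)


def region_windows(event: EventCallRecord) -> dict[str, tuple[int, int]]:
    """Genomic [start, end) intervals of the event's scannable regions.

    Region names are transcript-oriented (``exon_5p`` is the exon 5′ of
    the alternative segment); for a minus-strand event the 5′ exon is the
    genomically rightmost segment.  For introns shorter than 600 nt the
    start and end windows are truncated at the intron midpoint so they
    never overlap.
    """
    coords = event.coords
    strand = coords.strand
    if event.event_type == "SE":
        up_ex = coords.segment("upstream_exon")
        up_in = coords.segment("upstream_intron")
        alt = coords.segment("alt")
        dn_in = coords.segment("downstream_intron")
        dn_ex = coords.segment("downstream_exon")
        up_start, up_end = _intron_windows(*up_in)
        dn_start, dn_end = _intron_windows(*dn_in)
        if strand == "+":
            return {
                "exon_5p": up_ex,
                "alt_exon": alt,
                "exon_3p": dn_ex,
                "intron5p_start": up_start,
                "intron5p_end": up_end,
                "intron3p_start": dn_start,
                "intron3p_end": dn_end,
            }
        # minus strand: transcript runs right→left; the 5′ intron is the
        # genomically downstream one and its transcript-start is its
        # genomic end window
        return {
            "exon_5p": dn_ex,
            "alt_exon": alt,
            "exon_3p": up_ex,
            "intron5p_start": dn_end,
            "intron5p_end": dn_start,
            "intron3p_start": up_end,
            "intron3p_end": up_start,
        }
    if event.event_type == "RI":
        up_ex = coords.segment("upstream_exon")
        alt = coords.segment("alt")
        dn_ex = coords.segment("downstream_exon")
        w_start, w_end = _intron_windows(*alt)
        if strand == "+":
            return {
                "exon_5p": up_ex,
                "exon_3p": dn_ex,
                "intron_start": w_start,
                "intron_end": w_end,
            }
        return {
            "exon_5p": dn_ex,
            "exon_3p": up_ex,
            "intron_start": w_end,
            "intron_end": w_start,
        }
    raise ValueError(f"region decomposition defined for SE and RI, not {event.event_type}")


def decompose_regions(event: EventCallRecord, sequences: Mapping[str, str]) -> EventRegions:
    """Extract transcript-oriented region sequences from the genome store."""
    chrom_seq = sequences[event.coords.chrom]
    out = {}
    for name, (start, end) in region_windows(event).items():
        if start < 0 or end > len(chrom_seq):
            raise ValueError(
                f"event {event.event_id}: region {name} [{start},{end}) outside chromosome"
            )
        seq = chrom_seq[start:end]
        if event.coords.strand == "-":
            seq = reverse_complement(seq)
        out[name] = seq
    return EventRegions(event_id=event.event_id, regions=out)


# ---------------------------------------------------------------------------
# length-binned negative sampling
# ---------------------------------------------------------------------------


def sample_background(
    positive_lengths: Mapping[str, float],
    pool_lengths: Mapping[str, float],
    n_per_pos: int = 10,
    n_bins: int = 10,
    seed: int = 0,
) -> list[str]:
    """Length-matched negative sample: ``n_per_pos`` negatives per positive.

    Positives and pool are binned together into quantile bins of length;
    each positive draws its negatives without replacement from its own
    bin, falling back to replacement (logged) only when the bin is
    exhausted.  Deterministic given the seed.
    """
    if not positive_lengths or not pool_lengths:
        raise ValueError("positives and background pool must be non-empty")
    rng = np.random.default_rng(seed)
    all_lengths = np.array(list(positive_lengths.values()) + list(pool_lengths.values()))
    qs = np.quantile(all_lengths, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)[1:-1]  # interior edges; degenerate quantiles collapse

    def bin_of(length: float) -> int:
        return int(np.searchsorted(edges, length, side="right"))

    pool_by_bin: dict[int, list[str]] = {}
    for eid in sorted(pool_lengths):
        pool_by_bin.setdefault(bin_of(pool_lengths[eid]), []).append(eid)

    chosen: list[str] = []
    for eid in sorted(positive_lengths):
        b = bin_of(positive_lengths[eid])
        bucket = pool_by_bin.get(b)
        if not bucket:
            # no negatives of comparable length: widen to the whole pool
            logger.info("sample_background: bin %d empty for %s, using full pool", b, eid)
            bucket = sorted(pool_lengths)
        if len(bucket) >= n_per_pos:
            picks = rng.choice(len(bucket), size=n_per_pos, replace=False)
        else:
            logger.info("sample_background: bin exhausted for %s, sampling with replacement", eid)
            picks = rng.choice(len(bucket), size=n_per_pos, replace=True)
        chosen.extend(bucket[i] for i in picks)
    return chosen


# ---------------------------------------------------------------------------
# Mann–Whitney enrichment test
# ---------------------------------------------------------------------------


@dataclass
class MotifEnrichmentResult:
    """One (RBP group × region × direction) enrichment test."""

    rbp_group: str
    region: str
    direction: str
    u_statistic: float
    p_value: float
    q_value: float = math.nan
    mean_rate_positive: float = math.nan
    mean_rate_background: float = math.nan
    effect: str = "none"  # enriched | depleted | none


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def motif_enrichment_test(
    rates: Mapping[tuple[str, str, str], tuple[Sequence[float], Sequence[float]]],
    effect_min_ratio: float = 1.25,
) -> list[MotifEnrichmentResult]:
    """Mann–Whitney tests over (group × region × direction) hit-rate vectors.

    ``rates`` maps each key to (positive_rates, background_rates), both
    already normalized by region length.  BH correction runs across the
    full table; an effect is called only when the positive/background
    mean-rate ratio is at least 25% above or below 1.
    """
    results: list[MotifEnrichmentResult] = []
    for (group, region, direction), (pos, neg) in sorted(rates.items()):
        pos = np.asarray(pos, dtype=float)
        neg = np.asarray(neg, dtype=float)
        if pos.size == 0 or neg.size == 0:
            raise ValueError(f"{group}/{region}/{direction}: empty rate vector")
        if not pos.any() and not neg.any():
            u, p = float(pos.size * neg.size / 2.0), 1.0
        else:
            u, p = mann_whitney(pos, neg)
        results.append(
            MotifEnrichmentResult(
                rbp_group=group,
                region=region,
                direction=direction,
                u_statistic=u,
                p_value=p,
                mean_rate_positive=float(pos.mean()),
                mean_rate_background=float(neg.mean()),
            )
        )
    if results:
        qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_value = float(q)
            mb = r.mean_rate_background
            ratio = math.inf if mb == 0 and r.mean_rate_positive > 0 else (
                r.mean_rate_positive / mb if mb > 0 else 1.0
            )
            if ratio >= effect_min_ratio:
                r.effect = "enriched"
            elif ratio <= 1.0 / effect_min_ratio:
                r.effect = "depleted"
    return results


def region_hit_rates(
    groups: Mapping[str, Sequence[ScoredMotif]],
    positive_regions: Sequence[EventRegions],
    background_regions: Sequence[EventRegions],
    direction: str,
) -> dict[tuple[str, str, str], tuple[list[float], list[float]]]:
    """Length-normalized merged hit rates per (group, region, direction)."""
    region_names = sorted({n for er in positive_regions for n in er.regions})
    out: dict[tuple[str, str, str], tuple[list[float], list[float]]] = {}
    for gname, motifs in groups.items():
        for rname in region_names:
            pos_rates = [
                group_hit_count(motifs, er.regions[rname]) / max(len(er.regions[rname]), 1)
                for er in positive_regions
                if rname in er.regions
            ]
            neg_rates = [
                group_hit_count(motifs, er.regions[rname]) / max(len(er.regions[rname]), 1)
                for er in background_regions
                if rname in er.regions
            ]
            if pos_rates and neg_rates:
                out[(gname, rname, direction)] = (pos_rates, neg_rates)
    return out


# ---------------------------------------------------------------------------
# positional density around junctions
# ---------------------------------------------------------------------------

#: junction name → (segment whose boundary defines it, use transcript-5′ edge?)
SE_JUNCTIONS = ("alt_start", "alt_end")


@dataclass
class PositionalDensity:
    """Per-offset normalized hit rate around a junction, ±window nt."""

    rbp_group: str
    junction: str
    offsets: np.ndarray  # [-window, window)
    rate_positive: np.ndarray
    rate_background: np.ndarray


def _junction_genomic_pos(event: EventCallRecord, junction: str) -> int:
    """Genomic coordinate of the named skipped-exon junction."""
    alt = event.coords.segment("alt")
    plus = event.coords.strand == "+"
    if junction == "alt_start":  # 5′ end of the skipped exon in transcript orientation
        return alt[0] if plus else alt[1]
    if junction == "alt_end":
        return alt[1] if plus else alt[0]
    raise ValueError(f"unknown junction {junction!r}")


def _junction_window_seq(
    event: EventCallRecord, sequences: Mapping[str, str], junction: str, window: int
) -> str | None:
    chrom_seq = sequences[event.coords.chrom]
    pos = _junction_genomic_pos(event, junction)
    if event.coords.strand == "+":
        start, end = pos - window, pos + window
        if start < 0 or end > len(chrom_seq):
            return None
        return chrom_seq[start:end]
    start, end = pos - window, pos + window
    if start < 0 or end > len(chrom_seq):
        return None
    return reverse_complement(chrom_seq[start:end])


def positional_density(
    group_name: str,
    motifs: Sequence[ScoredMotif],
    positive_events: Sequence[EventCallRecord],
    background_events: Sequence[EventCallRecord],
    sequences: Mapping[str, str],
    junction: str,
    window: int = 200,
) -> PositionalDensity:
    """Hit-start frequency per offset in [−window, window) around a junction.

    The rate at an offset is the fraction of contributing events with a
    merged group hit starting at that offset (transcript orientation;
    offset 0 is the junction itself).
    """
    offsets = np.arange(-window, window)

    def profile(events: Sequence[EventCallRecord]) -> np.ndarray:
        counts = np.zeros(2 * window)
        contributing = 0
        for ev in events:
            seq = _junction_window_seq(ev, sequences, junction, window)
            if seq is None:
                continue
            contributing += 1
            seen = np.zeros(2 * window, dtype=bool)
            for m in motifs:
                for h in scan_hits(m, seq):
                    seen[h] = True
            counts += seen
        return counts / contributing if contributing else counts

    return PositionalDensity(
        rbp_group=group_name,
        junction=junction,
        offsets=offsets,
        rate_positive=profile(positive_events),
        rate_background=profile(background_events),
    )
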