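"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a graded-inhibition experiment: a control plus a
handful of increasing inhibitor concentrations, features whose abundance
(or inclusion ratio Ψ) responds monotonically up, monotonically down, or
not at all, splice events with controllable type and reading-frame
composition, and event-anchored sequences with RBP motif instances planted
at controlled densities in chosen regions.  Every output is a pure
function of (config, seed), which gives each downstream stage a
no-download parameter-recovery test surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    EventCallRecord,
    EventCoords,
    ExpressionTable,
    GeneSetCollection,
    PWMRecord,
    TranscriptAnnotation,
    write_event_calls,
    write_expression_table,
    write_fasta,
    write_gmt,
    write_pwm_cisbp,
    write_transcript_annotation,
)

RNA = ("A", "C", "G", "U")

#: Default dose ladder in μM (control first).
DEFAULT_DOSES = (0.0, 0.5, 2.0, 5.0, 10.0)

#: Default splice-type mix, skewed toward skipped exons as in real
#: knowledge bases, with first/last-exon and retained-intron classes next.
DEFAULT_EVENT_MIX = {
    "SE": 0.40,
    "AFE": 0.15,
    "ALE": 0.15,
    "RI": 0.10,
    "A3SS": 0.08,
    "A5SS": 0.07,
    "MXE": 0.03,
    "TandemUTR": 0.02,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with realistic defaults.

    ``noise_sd`` is the standard deviation of the Gaussian in log space
    for FPKM values (multiplicative log-normal noise, so non-negativity is
    structural) and of the logit-space Gaussian for Ψ profiles.
    ``effect_size`` is the max/min fold change of planted monotone mean
    profiles.  Motif plant densities are expected instances per kb of
    region per event.
    """

    seed: int = 0
    doses: tuple[float, ...] = DEFAULT_DOSES
    n_features: int = 200
    frac_increasing: float = 0.15
    frac_decreasing: float = 0.15
    effect_size: float = 2.0
    noise_sd: float = 0.1
    # isoforms / NMD
    max_isoforms: int = 3
    frac_nmd_genes: float = 0.3
    frac_nmd_increasing: float = 0.5
    # events
    n_events: int = 300
    event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    frac_frameshift_pos: float = 0.8
    frac_frameshift_bg: float = 2.0 / 3.0
    intron_length: int = 800
    exon_length: int = 150
    # sequences / motifs
    motif_plant_density_pos: float = 6.0
    motif_plant_density_bg: float = 2.0
    motif_plant_regions: tuple[str, ...] = ("intron5p_start",)
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # gene sets
    n_gene_sets: int = 20
    gene_set_size: tuple[int, int] = (10, 40)

    def __post_init__(self) -> None:
        if len(self.doses) < 3:
            raise ValueError("need at least 3 dose levels")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.frac_increasing + self.frac_decreasing > 1:
            raise ValueError("frac_increasing + frac_decreasing must be ≤ 1")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if any(q < 0 for q in self.base_freqs):
            raise ValueError("base_freqs must be non-negative")
        if self.motif_plant_density_pos < 0 or self.motif_plant_density_bg < 0:
            raise ValueError("plant densities must be ≥ 0")
        total = sum(self.event_mix.values())
        if total <= 0:
            raise ValueError("event_mix must have positive mass")
        self.event_mix = {k: v / total for k, v in self.event_mix.items()}

    @property
    def dose_labels(self) -> tuple[str, ...]:
        return tuple("DMSO" if d == 0 else f"{d:g}uM" for d in self.doses)

    @property
    def n_doses(self) -> int:
        return len(self.doses)


@dataclass
class GroundTruth:
    """Planted truth for every generated feature/event."""

    labels: dict[str, str]  # id → increasing | decreasing | null
    clean: pd.DataFrame | None = None  # noise-free mean profiles
    frameshift: dict[str, bool] = field(default_factory=dict)
    ale_proximal: dict[str, bool] = field(default_factory=dict)
    nmd_increasing: list[str] = field(default_factory=list)
    planted_instances: list[dict] = field(default_factory=list)
    planting_skips: list[dict] = field(default_factory=list)


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _monotone_profile(base: float, effect: float, n: int, direction: str) -> np.ndarray:
    """Noise-free geometric ramp with max/min exactly `effect`."""
    ramp = base * effect ** (np.arange(n) / (n - 1))
    return ramp if direction == "increasing" else ramp[::-1]


# ---------------------------------------------------------------------------
# gene expression
# ---------------------------------------------------------------------------


def gen_expression(config: SimulationConfig) -> tuple[ExpressionTable, GroundTruth]:
    """Generate a gene FPKM table with planted monotone dose responses."""
    rng = _rng(config, 1)
    n = config.n_features
    n_up = int(round(n * config.frac_increasing))
    n_down = int(round(n * config.frac_decreasing))
    labels_arr = ["increasing"] * n_up + ["decreasing"] * n_down + ["null"] * (n - n_up - n_down)
    labels_arr = [labels_arr[i] for i in rng.permutation(n)]

    ids = [f"G{i:05d}" for i in range(n)]
    base = np.exp(rng.uniform(np.log(2.0), np.log(100.0), size=n))
    clean = np.empty((n, config.n_doses))
    for i, lab in enumerate(labels_arr):
        if lab == "null":
            clean[i] = base[i]
        else:
            clean[i] = _monotone_profile(base[i], config.effect_size, config.n_doses, lab)

    noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else 0.0
    values = clean * np.exp(noise)

    data = pd.DataFrame(values, index=ids, columns=list(config.dose_labels))
    table = ExpressionTable(data=data, dose_values=config.doses, feature_kind="gene")
    truth = GroundTruth(
        labels=dict(zip(ids, labels_arr)),
        clean=pd.DataFrame(clean, index=ids, columns=list(config.dose_labels)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# isoforms with NMD flags
# ---------------------------------------------------------------------------


def gen_isoforms_with_nmd(
    config: SimulationConfig, expression: ExpressionTable, truth: GroundTruth
) -> tuple[ExpressionTable, TranscriptAnnotation, GroundTruth]:
    """Split each gene into 1–3 isoforms; a designated subset of NMD-flagged
    isoforms has an inclusion ratio (isoform/gene) that increases with dose.

    Noise-free isoform profiles sum exactly to the gene's noise-free
    profile; independent multiplicative noise is then applied per isoform.
    """
    rng = _rng(config, 2)
    clean_genes = truth.clean
    if clean_genes is None:
        raise ValueError("gene ground truth with clean profiles required")

    iso_ids: list[str] = []
    iso_gene: list[str] = []
    iso_nmd: list[bool] = []
    clean_rows: list[np.ndarray] = []
    nmd_increasing: list[str] = []
    iso_labels: dict[str, str] = {}
    n_doses = config.n_doses

    for gid in expression.feature_ids:
        gene_clean = clean_genes.loc[gid].to_numpy()
        k = int(rng.integers(1, config.max_isoforms + 1))
        has_nmd = k >= 2 and rng.random() < config.frac_nmd_genes
        tids = [f"{gid}.T{j+1}" for j in range(k)]

        if has_nmd:
            nmd_idx = 0
            ramp_up = rng.random() < config.frac_nmd_increasing
            if ramp_up:
                # inclusion ratio rises geometrically from psi0 with the
                # configured fold change, capped below 0.9
                psi0 = rng.uniform(0.08, 0.9 / config.effect_size)
                psi = _monotone_profile(psi0, config.effect_size, n_doses, "increasing")
                nmd_increasing.append(tids[0])
            else:
                psi = np.full(n_doses, rng.uniform(0.08, 0.5))
            rest = np.asarray(rng.dirichlet(np.ones(k - 1)))
            fracs = np.empty((k, n_doses))
            fracs[0] = psi
            fracs[1:] = rest[:, None] * (1.0 - psi)[None, :]
        else:
            nmd_idx = -1
            w = np.asarray(rng.dirichlet(np.ones(k)))
            fracs = np.repeat(w[:, None], n_doses, axis=1)

        for j, tid in enumerate(tids):
            iso_ids.append(tid)
            iso_gene.append(gid)
            iso_nmd.append(j == nmd_idx)
            clean_rows.append(fracs[j] * gene_clean)
            if j == nmd_idx and tid in nmd_increasing:
                iso_labels[tid] = "increasing"
            else:
                iso_labels[tid] = "null"

    clean = np.vstack(clean_rows)
    noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 else 0.0
    values = clean * np.exp(noise)

    data = pd.DataFrame(values, index=iso_ids, columns=list(config.dose_labels))
    table = ExpressionTable(
        data=data,
        dose_values=config.doses,
        feature_kind="isoform",
        gene_ids=pd.Series(iso_gene, index=iso_ids, name="gene_id"),
    )
    annot = TranscriptAnnotation(
        gene_of=dict(zip(iso_ids, iso_gene)), is_nmd=dict(zip(iso_ids, iso_nmd))
    )
    iso_truth = GroundTruth(
        labels=iso_labels,
        clean=pd.DataFrame(clean, index=iso_ids, columns=list(config.dose_labels)),
        nmd_increasing=nmd_increasing,
    )
    return table, annot, iso_truth


# ---------------------------------------------------------------------------
# splice events
# ---------------------------------------------------------------------------


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_alt_length(rng: np.random.Generator, frameshift: bool) -> int:
    base = int(rng.integers(20, 100)) * 3  # in-frame anchor, 60–297 nt
    if frameshift:
        return base + int(rng.integers(1, 3))
    return base


def gen_events(config: SimulationConfig) -> tuple[list[EventCallRecord], GroundTruth]:
    """Generate splice-event calls along one synthetic chromosome.

    Events are laid out left to right with 1 kb spacers.  Alternative
    segment lengths are drawn so the out-of-frame fraction equals
    ``frac_frameshift_pos`` among planted-monotone events and
    ``frac_frameshift_bg`` among the rest.  Ψ profiles are planted
    monotone/null analogously to the expression generator, with
    logit-space Gaussian noise so values stay in (0, 1).
    """
    rng = _rng(config, 3)
    n = config.n_events
    n_up = int(round(n * config.frac_increasing))
    n_down = int(round(n * config.frac_decreasing))
    labels_arr = ["increasing"] * n_up + ["decreasing"] * n_down + ["null"] * (n - n_up - n_down)
    labels_arr = [labels_arr[i] for i in rng.permutation(n)]

    types = list(config.event_mix)
    type_p = np.array([config.event_mix[t] for t in types])
    n_doses = config.n_doses

    records: list[EventCallRecord] = []
    truth = GroundTruth(labels={})
    cursor = 1000  # leading spacer
    chrom = "chrS"

    for i in range(n):
        eid = f"EV{i:05d}"
        label = labels_arr[i]
        etype = types[int(rng.choice(len(types), p=type_p))]
        frameshift = rng.random() < (
            config.frac_frameshift_pos if label != "null" else config.frac_frameshift_bg
        )
        alt_len = _draw_alt_length(rng, frameshift)
        strand = "+" if rng.random() < 0.5 else "-"

        exl, inl = config.exon_length, config.intron_length
        segs: list[tuple[str, int, int]] = []
        pos = cursor

        def add(name: str, length: int) -> None:
            nonlocal pos
            segs.append((name, pos, pos + length))
            pos += length

        if etype == "RI":
            add("upstream_exon", exl)
            add("alt", alt_len)
            add("downstream_exon", exl)
        elif etype == "ALE":
            # two candidate last exons; "alt" is the selected one
            add("upstream_exon", exl)
            add("spacer_intron", inl)
            first_is_alt = rng.random() < 0.5
            add("alt" if first_is_alt else "other_last", alt_len if first_is_alt else exl)
            add("mid_intron", inl)
            add("other_last" if first_is_alt else "alt", exl if first_is_alt else alt_len)
            # proximal = 5'-most candidate in transcript orientation
            if strand == "+":
                truth.ale_proximal[eid] = first_is_alt
            else:
                truth.ale_proximal[eid] = not first_is_alt
        else:
            add("upstream_exon", exl)
            add("upstream_intron", inl)
            add("alt", alt_len)
            add("downstream_intron", inl)
            add("downstream_exon", exl)

        cursor = pos + 1000  # 1 kb spacer

        if label == "null":
            center = rng.uniform(0.2, 0.8)
            mean_psi = np.full(n_doses, center)
        else:
            ramp = np.linspace(_logit(np.array([0.2]))[0], _logit(np.array([0.8]))[0], n_doses)
            mean_psi = _sigmoid(ramp if label == "increasing" else ramp[::-1])
        if config.noise_sd > 0:
            psi = _sigmoid(_logit(mean_psi) + rng.normal(0, config.noise_sd, n_doses))
        else:
            psi = mean_psi

        caller = "misolike" if rng.random() < 0.5 else "vastlike"
        delta = float(psi[-1] - psi[0])
        if label == "null":
            # mostly below the caller confidence cut
            conf = float(rng.uniform(0.0, 8.0)) if caller == "misolike" else float(rng.uniform(0, 0.08))
        else:
            conf = float(rng.uniform(12.0, 40.0)) if caller == "misolike" else float(rng.uniform(0.15, 0.6))

        coords = EventCoords(chrom=chrom, strand=strand, segments=tuple(segs))
        records.append(
            EventCallRecord(
                event_id=eid,
                caller=caller,
                event_type=etype,
                psi={lab: float(p) for lab, p in zip(config.dose_labels, psi)},
                delta_psi=delta,
                confidence=conf,
                coords=coords,
            )
        )
        truth.labels[eid] = label
        truth.frameshift[eid] = frameshift

    return records, truth


# ---------------------------------------------------------------------------
# sequences with planted motifs
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sample_motif_instance(rng: np.random.Generator, pwm: PWMRecord) -> str:
    """Draw one instance from the PWM (per-position categorical draw)."""
    return "".join(RNA[int(rng.choice(4, p=row / row.sum()))] for row in pwm.probs)


def gen_sequences_with_motifs(
    config: SimulationConfig,
    events: Sequence[EventCallRecord],
    truth: GroundTruth,
    pwms: Sequence[PWMRecord],
    planted_motif: str | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Build the synthetic chromosome and plant PWM instances.

    Background sequence is i.i.d. at ``base_freqs``.  In each scannable
    region of each SE event, instances of the planted motif are placed as
    Poisson(density × region_length / 1000), where density is
    ``motif_plant_density_pos`` for (monotone event, designated region)
    pairs and ``motif_plant_density_bg`` otherwise.  Instances are written
    in transcript orientation (reverse-complemented onto minus-strand
    genomic sequence).  Every planted instance and every skip (region
    shorter than the motif) is logged in the returned ground truth.
    """
    from .motif_analysis import region_windows  # genomic region layout

    rng = _rng(config, 4)
    length = max(e.coords.segments[-1][2] for e in events) + 1000
    freqs = np.asarray(config.base_freqs)
    chrom_arr = rng.choice(np.array(list(RNA)), size=length, p=freqs)

    pwm = next((p for p in pwms if p.motif_id == planted_motif), pwms[0])
    for event in events:
        if event.event_type != "SE":
            continue
        positive = truth.labels.get(event.event_id, "null") != "null"
        strand = event.coords.strand
        for region, (start, end) in region_windows(event).items():
            density = (
                config.motif_plant_density_pos
                if positive and region in config.motif_plant_regions
                else config.motif_plant_density_bg
            )
            if density == 0:
                continue
            span = end - start
            if span < pwm.length:
                truth.planting_skips.append(
                    {"event_id": event.event_id, "region": region, "length": span}
                )
                continue
            n_inst = rng.poisson(density * span / 1000.0)
            for _ in range(n_inst):
                inst = sample_motif_instance(rng, pwm)
                offset = int(rng.integers(0, span - pwm.length + 1))
                gpos = start + offset
                genomic = inst if strand == "+" else _revcomp(inst)
                chrom_arr[gpos : gpos + pwm.length] = list(genomic)
                truth.planted_instances.append(
                    {
                        "event_id": event.event_id,
                        "region": region,
                        "position": gpos,
                        "motif_id": pwm.motif_id,
                    }
                )

    chrom = events[0].coords.chrom if events else "chrS"
    return {chrom: "".join(chrom_arr)}, truth


# ---------------------------------------------------------------------------
# PWMs and gene sets for the bundle
# ---------------------------------------------------------------------------


def gen_pwms(config: SimulationConfig, n_motifs: int = 6, length: int = 7) -> list[PWMRecord]:
    """Informative synthetic PWMs, one RBP per motif (RBP1, RBP2, ...)."""
    rng = _rng(config, 5)
    records = []
    for m in range(n_motifs):
        probs = np.full((length, 4), 0.05)
        for i in range(length):
            probs[i, int(rng.integers(0, 4))] = 0.85
        records.append(
            PWMRecord(motif_id=f"M{m+1:03d}", rbp_names=(f"RBP{m+1}",), probs=probs)
        )
    return records


def gen_gene_sets(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[GeneSetCollection, str]:
    """Random gene sets plus one set enriched for the increasing genes."""
    rng = _rng(config, 6)
    genes = sorted(truth.labels)
    increasing = [g for g in genes if truth.labels[g] == "increasing"]
    sets: dict[str, frozenset[str]] = {}
    lo, hi = config.gene_set_size
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets[f"SET{i+1:03d}"] = frozenset(members)
    # planted set: mostly increasing genes with a sprinkle of others
    n_pos = min(len(increasing), max(lo, 15))
    pos = list(rng.choice(increasing, size=n_pos, replace=False))
    pad = list(rng.choice(genes, size=5, replace=False))
    planted = "SET_PLANTED"
    sets[planted] = frozenset(pos + pad)
    return GeneSetCollection(sets=sets, universe=frozenset(genes)), planted


# ---------------------------------------------------------------------------
# full input bundle
# ---------------------------------------------------------------------------


def write_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the complete synthetic input bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes, gene_truth = gen_expression(config)
    isoforms, annot, iso_truth = gen_isoforms_with_nmd(config, genes, gene_truth)
    events, event_truth = gen_events(config)
    pwms = gen_pwms(config)
    seqs, event_truth = gen_sequences_with_motifs(config, events, event_truth, pwms)
    gene_sets, planted_set = gen_gene_sets(config, gene_truth)

    paths = {
        "genes": out / "genes.tsv",
        "isoforms": out / "isoforms.tsv",
        "annotation": out / "annotation.tsv",
        "events_miso": out / "events_misolike.tsv",
        "events_vast": out / "events_vastlike.tsv",
        "fasta": out / "genome.fa",
        "pwms": out / "pwms.txt",
        "rbp_map": out / "rbp_map.tsv",
        "gmt": out / "gene_sets.gmt",
        "truth": out / "ground_truth.json",
    }
    write_expression_table(genes, paths["genes"])
    write_expression_table(isoforms, paths["isoforms"])
    write_transcript_annotation(annot, paths["annotation"])
    miso = [e for e in events if e.caller == "misolike"]
    vast = [e for e in events if e.caller == "vastlike"]
    if miso:
        write_event_calls(miso, paths["events_miso"])
    if vast:
        write_event_calls(vast, paths["events_vast"])
    write_fasta(seqs, paths["fasta"])
    write_pwm_cisbp(pwms, paths["pwms"], paths["rbp_map"])
    write_gmt(gene_sets, paths["gmt"])

    truth_doc = {
        "config": {k: v for k, v in asdict(config).items()},
        "gene_labels": gene_truth.labels,
        "isoform_labels": iso_truth.labels,
        "nmd_increasing": iso_truth.nmd_increasing,
        "event_labels": event_truth.labels,
        "frameshift": event_truth.frameshift,
        "ale_proximal": event_truth.ale_proximal,
        "planted_instances": event_truth.planted_instances,
        "planted_gene_set": planted_set,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, default=list)
    return paths
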