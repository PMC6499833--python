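"""Readers, writers and validated in-memory domain types.

Every external representation the pipeline touches (expression TSVs,
event-call TSVs, CIS-BP RNA PWM text, FASTA, GMT gene sets) is parsed here
into a validated domain object so downstream modules never see raw files.

Conventions
-----------
* Genomic coordinates are 0-based half-open throughout.
* Dose labels carry both a string label and a numeric concentration in μM;
  columns are ordered by the numeric value and the control ("DMSO"/"0")
  maps to 0.
* Sequences are upper-cased on read; for motif work DNA is normalized to
  the RNA alphabet (T→U) because CIS-BP RNA matrices are defined over
  A/C/G/U.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = ("A", "C", "G", "U")

EVENT_TYPES = ("SE", "RI", "A3SS", "A5SS", "AFE", "ALE", "MXE", "TandemUTR", "MIC")
CALLERS = ("misolike", "vastlike")


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


# ---------------------------------------------------------------------------
# dose labels
# ---------------------------------------------------------------------------

_DOSE_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*(?:u|μ|µ)?M?\s*$", re.IGNORECASE)


def parse_dose_label(label: str) -> float:
    """Map a concentration column label to numeric μM; control is 0."""
    s = str(label).strip()
    if s.upper() in {"DMSO", "CTRL", "CONTROL", "UNTREATED"}:
        return 0.0
    m = _DOSE_RE.match(s)
    if m is None:
        raise FormatError(f"cannot parse dose label {label!r} as a concentration")
    return float(m.group(1))


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Features × ordered doses abundance matrix on the FPKM scale.

    ``data`` has feature ids as the index and the original dose labels as
    columns, ordered by increasing numeric dose.  For isoform tables
    ``gene_ids`` maps every isoform to its parent gene.
    """

    data: pd.DataFrame
    dose_values: tuple[float, ...]
    feature_kind: str  # "gene" | "isoform"
    gene_ids: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "isoform"):
            raise FormatError(f"feature_kind must be gene|isoform, got {self.feature_kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if len(self.dose_values) != self.data.shape[1]:
            raise FormatError("dose_values length does not match number of columns")
        if any(b <= a for a, b in zip(self.dose_values, self.dose_values[1:])):
            raise FormatError("dose values must be strictly increasing")
        vals = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite value at feature {self.data.index[r]!r}, dose {self.data.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative value {vals[r, c]} at feature {self.data.index[r]!r}, "
                f"dose {self.data.columns[c]!r}"
            )
        if self.feature_kind == "isoform":
            if self.gene_ids is None:
                raise FormatError("isoform table requires gene_ids")
            if not self.data.index.equals(self.gene_ids.index):
                raise FormatError("gene_ids index must match feature index")

    @property
    def dose_labels(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.data.columns)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)


def read_expression_table(path: str | Path, feature_kind: str) -> ExpressionTable:
    """Read a TSV expression table (feature_id [gene_id] dose columns...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected feature_id plus dose columns")
    df = df.set_index(df.columns[0])
    gene_ids = None
    if feature_kind == "isoform":
        if df.shape[1] < 2:
            raise FormatError(f"{path}: isoform table needs a gene_id column")
        gene_ids = df.iloc[:, 0].rename("gene_id")
        df = df.iloc[:, 1:]
    doses = sorted((parse_dose_label(c), c) for c in df.columns)
    if len({d for d, _ in doses}) != len(doses):
        raise FormatError(f"{path}: duplicate numeric dose among columns")
    df = df[[c for _, c in doses]]
    try:
        data = df.astype(float)
    except ValueError as exc:
        # locate the offending cell for the error report
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
                ) from exc
        raise
    return ExpressionTable(
        data=data,
        dose_values=tuple(d for d, _ in doses),
        feature_kind=feature_kind,
        gene_ids=gene_ids,
    )


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.data.copy()
    if table.feature_kind == "isoform":
        out.insert(0, "gene_id", table.gene_ids)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transcript annotation
# ---------------------------------------------------------------------------


@dataclass
class TranscriptAnnotation:
    """transcript → gene mapping with an NMD-biotype flag per transcript."""

    gene_of: dict[str, str]
    is_nmd: dict[str, bool]

    def __post_init__(self) -> None:
        if set(self.gene_of) != set(self.is_nmd):
            raise FormatError("annotation transcript sets inconsistent")

    def nmd_transcripts(self) -> list[str]:
        return [t for t, flag in self.is_nmd.items() if flag]


def read_transcript_annotation(path: str | Path) -> TranscriptAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "gene_id", "is_nmd"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation needs columns {sorted(required)}")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise FormatError(f"{path}: transcript {dup!r} mapped more than once")
    flags = df["is_nmd"].str.lower().map({"true": True, "1": True, "false": False, "0": False})
    if flags.isna().any():
        raise FormatError(f"{path}: is_nmd must be true/false or 0/1")
    return TranscriptAnnotation(
        gene_of=dict(zip(df["transcript_id"], df["gene_id"])),
        is_nmd=dict(zip(df["transcript_id"], flags)),
    )


def write_transcript_annotation(annot: TranscriptAnnotation, path: str | Path) -> None:
    rows = [
        {"transcript_id": t, "gene_id": g, "is_nmd": str(annot.is_nmd[t]).lower()}
        for t, g in annot.gene_of.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# splice-event calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventCoords:
    """Named genomic segments of one splice event (0-based half-open).

    Segment names are in genomic order terms (``upstream`` = lower
    coordinate); 5′/3′ roles are resolved by strand via :meth:`role`.
    """

    chrom: str
    strand: str
    segments: tuple[tuple[str, int, int], ...]  # (name, start, end), genomic order

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for name, start, end in self.segments:
            if not 0 <= start < end:
                raise FormatError(f"segment {name}: invalid interval [{start},{end})")
            if start < prev_end:
                raise FormatError(f"segment {name}: intervals overlap or are unordered")
            prev_end = end

    def segment(self, name: str) -> tuple[int, int]:
        for n, s, e in self.segments:
            if n == name:
                return (s, e)
        raise KeyError(name)

    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.segments)

    def role(self, prime5: bool) -> tuple[str, ...]:
        """Segment names ordered 5′→3′ in transcript orientation."""
        order = self.segments if self.strand == "+" else tuple(reversed(self.segments))
        names = tuple(n for n, _, _ in order)
        return names if prime5 else tuple(reversed(names))


@dataclass
class EventCallRecord:
    """One alternative-splicing event call with per-dose Ψ and confidence.

    ``confidence`` semantics are keyed by caller: a Bayes factor for
    misolike records, MV[|ΔΨ|] at 0.95 for vastlike records.
    """

    event_id: str
    caller: str
    event_type: str
    psi: dict[str, float]  # dose label → Ψ
    delta_psi: float
    confidence: float
    coords: EventCoords

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise FormatError(f"unknown caller {self.caller!r}")
        if self.event_type not in EVENT_TYPES:
            raise FormatError(f"unknown event type {self.event_type!r}")
        for label, value in self.psi.items():
            if not 0.0 <= value <= 1.0:
                raise FormatError(
                    f"event {self.event_id}: psi {value} at dose {label!r} outside [0,1]"
                )

    @property
    def alt_segment(self) -> tuple[int, int]:
        """Interval of the alternative segment (skipped exon, retained intron...)."""
        return self.coords.segment("alt")

    @property
    def alt_length(self) -> int:
        s, e = self.alt_segment
        return e - s


def _format_segments(coords: EventCoords) -> str:
    return ";".join(f"{n}:{s}-{e}" for n, s, e in coords.segments)


def _parse_segments(text: str) -> tuple[tuple[str, int, int], ...]:
    out = []
    for part in text.split(";"):
        name, _, iv = part.partition(":")
        start, _, end = iv.partition("-")
        out.append((name, int(start), int(end)))
    return tuple(out)


def read_event_calls(path: str | Path, caller: str) -> list[EventCallRecord]:
    """Read the frozen event-call TSV dialect for one caller."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = {"event_id", "type", "chrom", "strand", "segments", "delta_psi", "confidence"}
    if not fixed.issubset(df.columns):
        raise FormatError(f"{path}: event table needs columns {sorted(fixed)}")
    psi_cols = [c for c in df.columns if c.startswith("psi_")]
    records = []
    for _, row in df.iterrows():
        coords = EventCoords(
            chrom=row["chrom"], strand=row["strand"], segments=_parse_segments(row["segments"])
        )
        psi = {c[4:]: float(row[c]) for c in psi_cols}
        records.append(
            EventCallRecord(
                event_id=row["event_id"],
                caller=caller,
                event_type=row["type"],
                psi=psi,
                delta_psi=float(row["delta_psi"]),
                confidence=float(row["confidence"]),
                coords=coords,
            )
        )
    return records


def write_event_calls(records: Sequence[EventCallRecord], path: str | Path) -> None:
    if not records:
        raise FormatError("refusing to write an empty event table")
    labels = sorted(records[0].psi, key=parse_dose_label)
    rows = []
    for r in records:
        row = {
            "event_id": r.event_id,
            "type": r.event_type,
            "chrom": r.coords.chrom,
            "strand": r.coords.strand,
            "segments": _format_segments(r.coords),
        }
        for lab in labels:
            row[f"psi_{lab}"] = repr(r.psi[lab])
        row["delta_psi"] = repr(r.delta_psi)
        row["confidence"] = repr(r.confidence)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWMs (CIS-BP RNA dialect)
# ---------------------------------------------------------------------------


@dataclass
class PWMRecord:
    """Position probability matrix over (A, C, G, U) with RBP attribution."""

    motif_id: str
    rbp_names: tuple[str, ...]
    probs: np.ndarray  # L × 4

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise FormatError(f"motif {self.motif_id}: PWM must be L×4 with L ≥ 1")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"motif {self.motif_id}: row {bad} sums to {sums[bad]:.6f}, not 1"
            )
        if not self.rbp_names:
            raise FormatError(f"motif {self.motif_id}: no RBP name attached")

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def read_pwm_cisbp(
    path: str | Path, rbp_map: Mapping[str, Sequence[str]] | str | Path
) -> list[PWMRecord]:
    """Read CIS-BP RNA PWM text (one or more motifs per file).

    Multi-motif files delimit motifs with ``Motif <id>`` lines; a file
    holding a single bare matrix takes its motif id from the file stem.
    Rows whose probabilities sum within 1e-3 of 1 are renormalized.
    """
    if not isinstance(rbp_map, Mapping):
        mdf = pd.read_csv(rbp_map, sep="\t", dtype=str)
        if not {"motif_id", "rbp_name"}.issubset(mdf.columns):
            raise FormatError("rbp map needs columns motif_id, rbp_name")
        mapping: dict[str, list[str]] = {}
        for _, row in mdf.iterrows():
            mapping.setdefault(row["motif_id"], []).append(row["rbp_name"])
    else:
        mapping = {k: list(v) for k, v in rbp_map.items()}

    path = Path(path)
    blocks: list[tuple[str, list[list[float]]]] = []
    current_id: str | None = None
    current_rows: list[list[float]] = []
    col_order: list[int] | None = None

    def flush() -> None:
        nonlocal current_rows
        if current_rows:
            blocks.append((current_id or path.stem, current_rows))
            current_rows = []

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fields[0].lower() == "motif":
            flush()
            current_id = fields[1]
            col_order = None
            continue
        if fields[0].lower() == "pos":
            bases = [b.upper().replace("T", "U") for b in fields[1:]]
            unknown = set(bases) - set(RNA_ALPHABET)
            if unknown:
                raise FormatError(f"{path}: unknown base column(s) {sorted(unknown)}")
            if sorted(bases) != sorted(RNA_ALPHABET):
                raise FormatError(f"{path}: header must list A C G U, got {bases}")
            col_order = [bases.index(b) for b in RNA_ALPHABET]
            continue
        if col_order is None:
            raise FormatError(f"{path}: matrix row before 'Pos A C G U' header")
        vals = [float(v) for v in fields[1:]]
        if len(vals) != 4:
            raise FormatError(f"{path}: expected 4 probabilities per row, got {len(vals)}")
        row = [vals[i] for i in col_order]
        total = sum(row)
        if abs(total - 1.0) > 1e-3:
            raise FormatError(f"{path}: PWM row sums to {total:.4f}, outside tolerance")
        blocks_row = [v / total for v in row]
        current_rows.append(blocks_row)
    flush()

    records = []
    for motif_id, rows in blocks:
        names = tuple(mapping.get(motif_id, ()))
        if not names:
            raise FormatError(f"motif {motif_id}: missing from RBP map")
        records.append(PWMRecord(motif_id=motif_id, rbp_names=names, probs=np.array(rows)))
    if not records:
        raise FormatError(f"{path}: no motifs found")
    return records


def write_pwm_cisbp(
    records: Sequence[PWMRecord], pwm_path: str | Path, map_path: str | Path
) -> None:
    with open(pwm_path, "w") as fh:
        for rec in records:
            fh.write(f"Motif\t{rec.motif_id}\n")
            fh.write("Pos\tA\tC\tG\tU\n")
            for i, row in enumerate(rec.probs, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    rows = [
        {"motif_id": rec.motif_id, "rbp_name": name}
        for rec in records
        for name in rec.rbp_names
    ]
    pd.DataFrame(rows).to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / GMT
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, rna: bool = True) -> dict[str, str]:
    """Read FASTA to an id → sequence dict (upper-cased; T→U when rna)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rna:
            seq = seq.replace("T", "U")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        seqs[rec.id] = seq
    if not seqs:
        raise FormatError(f"{path}: no sequences")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a new universe, dropping emptied sets."""
        uni = frozenset(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = members & uni
            if inter:
                kept[name] = frozenset(inter)
        return GeneSetCollection(sets=kept, universe=uni)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3 or not any(f for f in fields[2:]):
            raise FormatError(f"{path}:{lineno}: GMT line has no members")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(f for f in fields[2:] if f)
    universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# generic results tables + manifest
# ---------------------------------------------------------------------------


def write_results_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named DataFrames as TSVs with deterministic column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


def write_manifest(out_dir: str | Path, **entries) -> Path:
    p = Path(out_dir) / "manifest.json"
    with open(p, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return p
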