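"""End-to-end study orchestration.

A single run config (YAML) names the input files for each condition
(cell line × compound) and the per-stage parameters; ``run_condition``
executes normalize → filter → cluster → label → events → motifs →
enrichment for one condition and ``run_study`` adds cross-condition
overlap and direction-concordance summaries.  Every output table carries
a provenance header (package version, seed, stage parameters) and reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .dose_response import (
    ClusteringConfig,
    DoseProfileMatrix,
    cluster_profiles,
    compute_nmd_inclusion,
    filter_features,
    monotone_feature_sets,
    overlap_conditions,
    upper_quartile_normalize,
)
from .io_formats import (
    read_event_calls,
    read_expression_table,
    read_fasta,
    read_gmt,
    read_pwm_cisbp,
    read_transcript_annotation,
    write_manifest,
)
from .motif_analysis import (
    decompose_regions,
    estimate_background,
    group_by_rbp,
    motif_enrichment_test,
    region_hit_rates,
    sample_background,
    score_motif,
)
from .set_enrichment import build_enrichment_map, hypergeom_enrich
from .splice_events import (
    FrameClass,
    ale_is_proximal,
    ale_proximal_bias,
    filter_calls,
    frameshift_enrichment,
    merge_callers,
    type_composition,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and per-stage parameter blocks for a study run."""

    conditions: dict[str, dict[str, str]]  # condition name → input paths
    out_dir: str
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {"respond": True, "events": True, "motifs": True, "enrich": True}
    )
    clustering: dict[str, Any] = field(default_factory=dict)
    motifs: dict[str, Any] = field(default_factory=dict)
    enrich: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cfg = cls(
            conditions=doc["conditions"],
            out_dir=doc["out_dir"],
            seed=int(doc.get("seed", 0)),
        )
        cfg.stages.update(doc.get("stages", {}))
        cfg.clustering.update(doc.get("clustering", {}))
        cfg.motifs.update(doc.get("motifs", {}))
        cfg.enrich.update(doc.get("enrich", {}))
        for name, paths in cfg.conditions.items():
            for key, p in paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"condition {name!r}: {key} path {p} does not exist")
        return cfg

    def clustering_config(self) -> ClusteringConfig:
        return ClusteringConfig(**self.clustering)


def _provenance(config: RunConfig, stage: str, params: Mapping[str, Any]) -> str:
    blob = json.dumps(params, sort_keys=True, default=str)
    return (
        f"# titrseq v{__version__} stage={stage} seed={config.seed} "
        f"params={blob}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, stage: str, params: Mapping) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config, stage, params))
        df.to_csv(fh, sep="\t", index=False)


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """An error raised by one named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_condition(config: RunConfig, condition: str) -> dict[str, Any]:
    """Run all enabled stages for one condition; returns the result bundle."""
    paths = config.conditions[condition]
    out = Path(config.out_dir) / condition
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"condition": condition}
    ccfg = config.clustering_config()

    # ----- respond: normalize → filter → cluster → label ------------------
    if config.stages.get("respond", True):
        try:
            genes = upper_quartile_normalize(read_expression_table(paths["genes"], "gene"))
            gmatrix = filter_features(DoseProfileMatrix.from_expression(genes))
            gclusters = cluster_profiles(gmatrix, ccfg)
            gsets = monotone_feature_sets(gclusters)
            bundle["gene_clusters"] = gclusters
            bundle["gene_monotone"] = gsets

            rows = [
                {
                    "cluster_id": c.cluster_id,
                    "n_members": len(c.members),
                    "monotonic_label": c.monotonic_label,
                    "members": ",".join(c.members),
                    "consensus": ",".join(f"{v:.6f}" for v in c.consensus_profile),
                }
                for c in gclusters
            ]
            _write_tsv(pd.DataFrame(rows), out / "gene_clusters.tsv", config, "respond",
                       {"power": ccfg.resolve_power("fpkm"), "cut_height": ccfg.cut_height,
                        "min_module_size": ccfg.min_module_size})

            if "isoforms" in paths and "annotation" in paths:
                isoforms = upper_quartile_normalize(
                    read_expression_table(paths["isoforms"], "isoform")
                )
                annot = read_transcript_annotation(paths["annotation"])
                inclusion = compute_nmd_inclusion(isoforms, genes, annot)
                if inclusion.data.shape[0] >= 3:
                    iclusters = cluster_profiles(inclusion, ccfg)
                    bundle["nmd_clusters"] = iclusters
                    bundle["nmd_monotone"] = monotone_feature_sets(iclusters)
                    rows = [
                        {
                            "cluster_id": c.cluster_id,
                            "n_members": len(c.members),
                            "monotonic_label": c.monotonic_label,
                            "members": ",".join(c.members),
                        }
                        for c in iclusters
                    ]
                    _write_tsv(pd.DataFrame(rows), out / "nmd_clusters.tsv", config, "respond",
                               {"power": ccfg.resolve_power("inclusion_ratio")})
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            raise StageError("respond", exc) from exc

    # ----- events: filter → merge → monotone Ψ sets → statistics ----------
    merged = []
    all_events = []  # knowledge base: every annotated event, pre-filter
    event_sets: dict[str, set[str]] = {"increasing": set(), "decreasing": set()}
    if config.stages.get("events", True):
        try:
            raw_miso = read_event_calls(paths["events_miso"], "misolike") \
                if "events_miso" in paths else []
            raw_vast = read_event_calls(paths["events_vast"], "vastlike") \
                if "events_vast" in paths else []
            all_events = raw_miso + raw_vast
            miso = filter_calls(raw_miso, "misolike")
            vast = filter_calls(raw_vast, "vastlike")
            merged = merge_callers(miso, vast)
            bundle["merged_events"] = merged

            if merged:
                order = _dose_order(merged[0].record.psi)
                psi_df = pd.DataFrame(
                    {m.event_id: [m.record.psi[lab] for lab in order] for m in merged}
                ).T
                doses = tuple(_dose_values(merged[0].record.psi))
                psi_df.columns = order
                pmatrix = DoseProfileMatrix(
                    data=psi_df, dose_values=doses, value_kind="psi"
                )
                eclusters = cluster_profiles(pmatrix, ccfg)
                event_sets = monotone_feature_sets(eclusters)
                bundle["event_clusters"] = eclusters
                bundle["event_monotone"] = event_sets

                by_id = {m.event_id: m for m in merged}
                stats: dict[str, Any] = {}
                for direction, ids in event_sets.items():
                    members = [by_id[i] for i in sorted(ids)]
                    if members:
                        stats[f"composition_{direction}"] = type_composition(members)
                for direction, ids in event_sets.items():
                    for etype in ("SE", "RI"):
                        pos = [FrameClass.of(by_id[i].record).frameshift
                               for i in sorted(ids) if by_id[i].event_type == etype]
                        bg = [FrameClass.of(m.record).frameshift for m in merged
                              if m.event_type == etype and m.event_id not in ids]
                        if pos and bg:
                            table, p = frameshift_enrichment(pos, bg)
                            stats[f"frameshift_{etype}_{direction}"] = {"table": table, "p": p}
                inc_prox = [ale_is_proximal(by_id[i].record)
                            for i in sorted(event_sets["increasing"])
                            if by_id[i].event_type == "ALE"]
                dec_prox = [ale_is_proximal(by_id[i].record)
                            for i in sorted(event_sets["decreasing"])
                            if by_id[i].event_type == "ALE"]
                if inc_prox and dec_prox:
                    stat, p = ale_proximal_bias(inc_prox, dec_prox)
                    stats["ale_proximal_bias"] = {"chi2": stat, "p": p}
                bundle["event_stats"] = stats
                with open(out / "event_stats.json", "w") as fh:
                    json.dump(stats, fh, indent=2, sort_keys=True)

                rows = [
                    {"event_id": m.event_id, "type": m.event_type,
                     "callers": "+".join(m.callers),
                     "direction": next((d for d, s in event_sets.items()
                                        if m.event_id in s), "none")}
                    for m in merged
                ]
                _write_tsv(pd.DataFrame(rows), out / "merged_events.tsv", config, "events", {})
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("events", exc) from exc

    # ----- motifs ----------------------------------------------------------
    if config.stages.get("motifs", True):
        try:
            required = ("fasta", "pwms", "rbp_map")
            missing = [k for k in required if k not in paths]
            if missing:
                raise FileNotFoundError(f"missing input(s) {missing} for motif stage")
            seqs = read_fasta(paths["fasta"])
            pwms = read_pwm_cisbp(paths["pwms"], paths["rbp_map"])
            background = estimate_background(seqs)
            pcount = float(config.motifs.get("pseudocount", 1e-3))
            scored = [score_motif(p, background, pseudocount=pcount) for p in pwms]
            groups = group_by_rbp(scored)

            se_by_id = {m.event_id: m.record for m in merged if m.event_type == "SE"}
            # background pool: all annotated SE events outside every monotone set
            monotone_ids = set().union(*event_sets.values()) if event_sets else set()
            pool_records = {e.event_id: e for e in all_events
                            if e.event_type == "SE" and e.event_id not in monotone_ids}
            results = []
            for direction in ("increasing", "decreasing"):
                pos_ids = sorted(i for i in event_sets.get(direction, set()) if i in se_by_id)
                pool_ids = sorted(pool_records)
                if not pos_ids or not pool_ids:
                    continue
                pos_len = {i: se_by_id[i].alt_length for i in pos_ids}
                pool_len = {i: pool_records[i].alt_length for i in pool_ids}
                neg_ids = sample_background(
                    pos_len, pool_len,
                    n_per_pos=int(config.motifs.get("neg_ratio", 10)),
                    n_bins=int(config.motifs.get("bins", 10)),
                    seed=config.seed,
                )
                pos_regions = [decompose_regions(se_by_id[i], seqs) for i in pos_ids]
                neg_regions = [decompose_regions(pool_records[i], seqs) for i in neg_ids]
                rates = region_hit_rates(groups, pos_regions, neg_regions, direction)
                results.extend(motif_enrichment_test(rates))
            bundle["motif_results"] = results
            if results:
                rows = [
                    {"rbp_group": r.rbp_group, "region": r.region, "direction": r.direction,
                     "U": r.u_statistic, "p": r.p_value, "q": r.q_value,
                     "rate_positive": r.mean_rate_positive,
                     "rate_background": r.mean_rate_background, "effect": r.effect}
                    for r in results
                ]
                _write_tsv(pd.DataFrame(rows), out / "motif_enrichment.tsv", config, "motifs",
                           {"pseudocount": pcount})
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("motifs", exc) from exc

    # ----- enrich -----------------------------------------------------------
    if config.stages.get("enrich", True) and "gmt" in paths and "gene_monotone" in bundle:
        try:
            gene_sets = read_gmt(paths["gmt"])
            universe = set(bundle["gene_clusters"][0].members)
            for c in bundle["gene_clusters"]:
                universe.update(c.members)
            all_results = []
            for direction in ("increasing", "decreasing"):
                ident = bundle["gene_monotone"].get(direction, set())
                if not ident:
                    continue
                res = hypergeom_enrich(ident, gene_sets, universe=universe, direction=direction)
                all_results.extend(res)
            emap = build_enrichment_map(
                all_results,
                fdr_cutoff=float(config.enrich.get("fdr", 0.01)),
                p_cutoff=float(config.enrich.get("p", 0.005)),
                jaccard_cutoff=float(config.enrich.get("jaccard", 0.25)),
            )
            bundle["enrichment"] = all_results
            bundle["enrichment_map"] = emap
            rows = [
                {"set_name": r.set_name, "direction": r.direction, "k": r.overlap,
                 "K": r.set_size, "n": r.identified_size, "N": r.universe_size,
                 "p": r.p_value, "q": r.q_value, "score": r.odds_ratio_score,
                 "cluster": emap.clusters.get(r.set_name, 0)}
                for r in all_results
            ]
            _write_tsv(pd.DataFrame(rows), out / "gene_set_enrichment.tsv", config, "enrich",
                       {"fdr": config.enrich.get("fdr", 0.01)})
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc

    return bundle


def _dose_order(psi: Mapping[str, float]) -> list[str]:
    from .io_formats import parse_dose_label

    return sorted(psi, key=parse_dose_label)


def _dose_values(psi: Mapping[str, float]) -> list[float]:
    from .io_formats import parse_dose_label

    return sorted(parse_dose_label(k) for k in psi)


def run_study(config: RunConfig) -> dict[str, Any]:
    """Run every condition, then cross-condition overlaps and concordance."""
    bundles = {name: run_condition(config, name) for name in sorted(config.conditions)}
    out = Path(config.out_dir)
    study: dict[str, Any] = {"bundles": bundles}

    directions: dict[str, dict[str, set[str]]] = {}
    for name, bundle in bundles.items():
        sets = bundle.get("event_monotone") or bundle.get("gene_monotone") or {}
        directions[name] = {d: set(s) for d, s in sets.items()}

    if len(bundles) >= 2:
        for direction in ("increasing", "decreasing"):
            per_cond = {n: d.get(direction, set()) for n, d in directions.items()}
            summary = overlap_conditions(per_cond)
            study[f"overlap_{direction}"] = summary
            rows = [
                {"conditions": "+".join(sorted(k)), "count": len(v)}
                for k, v in sorted(summary.exclusive.items(), key=lambda kv: sorted(kv[0]))
            ]
            rows.append({"conditions": "UNION", "count": summary.union_size})
            _write_tsv(pd.DataFrame(rows), out / f"overlap_{direction}.tsv", config, "study", {})

        # direction concordance over events shared by condition pairs
        conc_rows = []
        names = sorted(bundles)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                label_a = {e: d for d, s in directions[a].items() for e in s}
                label_b = {e: d for d, s in directions[b].items() for e in s}
                shared = set(label_a) & set(label_b)
                agree = sum(label_a[e] == label_b[e] for e in shared)
                conc_rows.append(
                    {"condition_a": a, "condition_b": b, "n_shared": len(shared),
                     "concordance": agree / len(shared) if shared else float("nan")}
                )
        study["concordance"] = conc_rows
        _write_tsv(pd.DataFrame(conc_rows), out / "concordance.tsv", config, "study", {})

    hashes = {
        f"{name}:{key}": _file_sha256(p)
        for name, paths in sorted(config.conditions.items())
        for key, p in sorted(paths.items())
    }
    write_manifest(out, version=__version__, seed=config.seed, input_hashes=hashes,
                   stages=config.stages, clustering=config.clustering)
    return study
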