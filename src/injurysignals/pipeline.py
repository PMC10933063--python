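"""End-to-end orchestration: preprocess -> importance -> categorize -> network.

One YAML-serializable config drives the whole run; every threshold of the
method (DF support 10, top-300 candidate cut, phi floor 0.05, pair support
10) is a named parameter defaulting to its standard value.  A manifest
records the config echo, an input digest and per-stage row counts, and a
re-run with identical config and input reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import categorize as cat
from . import importance as imp
from . import network as net
from . import preprocess as pre

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str
    output_dir: str
    study_years: list[int] | None = None  # None: infer from data
    tokenizer: str = "default"
    min_df: int = 10
    top_k: int = 300
    missing_year_policy: str = "zero"
    acceleration_variant: str = "first_difference"
    sd_variant: str = "population"
    stoplist: dict[str, list[str]] = field(default_factory=dict)
    egos: list[str] | None = None  # None: hazardous-categorized terms
    phi_threshold: float = 0.05
    min_cooccurrence: int = 10
    filter_order: str = "ego_then_phi"
    louvain_resolution: float = 1.0
    louvain_weighted: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise pre.ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations, one per broken field rule (empty = valid)."""
    v: list[str] = []
    if not config.input_path:
        v.append("input_path: required")
    if not config.output_dir:
        v.append("output_dir: required")
    if config.min_df < 1:
        v.append(f"min_df: must be >= 1, got {config.min_df}")
    if config.top_k < 1:
        v.append(f"top_k: must be >= 1, got {config.top_k}")
    if config.missing_year_policy not in ("zero", "observed"):
        v.append(f"missing_year_policy: unknown value {config.missing_year_policy!r}")
    if config.acceleration_variant not in ("first_difference", "second_difference"):
        v.append(f"acceleration_variant: unknown value {config.acceleration_variant!r}")
    if config.sd_variant not in ("population", "sample"):
        v.append(f"sd_variant: unknown value {config.sd_variant!r}")
    if not 0 <= config.phi_threshold <= 1:
        v.append(f"phi_threshold: must lie in [0, 1], got {config.phi_threshold}")
    if config.min_cooccurrence < 0:
        v.append(f"min_cooccurrence: must be >= 0, got {config.min_cooccurrence}")
    if config.filter_order not in ("ego_then_phi", "phi_then_ego"):
        v.append(f"filter_order: unknown value {config.filter_order!r}")
    if config.louvain_resolution <= 0:
        v.append(f"louvain_resolution: must be > 0, got {config.louvain_resolution}")
    if config.study_years is not None and config.study_years:
        ys = sorted(config.study_years)
        if ys != list(range(ys[0], ys[-1] + 1)):
            v.append("study_years: must be contiguous")
    bad_classes = set(config.stoplist) - {"time", "person", "body_site"}
    if bad_classes:
        v.append(f"stoplist: unknown classes {sorted(bad_classes)}")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the run manifest.

    Stages run in order; a failure aborts with the stage name attached and
    the manifest (written regardless) marks the run incomplete.
    """
    violations = validate_config(config)
    if violations:
        raise pre.ConfigurationError("invalid config: " + "; ".join(violations))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_path = Path(config.input_path)
    if not input_path.exists():
        raise pre.PipelineError(f"input file not found: {input_path}")

    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "input_sha256": _sha256(input_path),
        "stages": {},
        "complete": False,
    }
    manifest_path = out_dir / "manifest.json"

    def finish_stage(name: str, **counts: Any) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    try:
        stage = "preprocess"
        records = pre.read_records(input_path)
        matrices = pre.build_matrix(records, config.tokenizer)
        if config.study_years:
            matrices = [m for m in matrices if m.year in set(config.study_years)]
            if not matrices:
                raise pre.PipelineError("no records within the configured study years")
        years = [m.year for m in matrices]
        downsized = [pre.downsize(m, config.min_df) for m in matrices]
        vocabulary = pre.union_terms(downsized)
        pre.write_matrix_summary(downsized, out_dir / "term_summary.csv")
        finish_stage(stage, n_records=len(records), n_years=len(years),
                     n_terms=len(vocabulary))

        stage = "importance"
        weights = [w for m in downsized for w in imp.yearly_tfidf(m)]
        candidates = imp.select_candidates(
            weights, k=config.top_k,
            missing_year_policy=config.missing_year_policy,  # type: ignore[arg-type]
            study_years=years,
        )
        imp.write_candidate_table(candidates, out_dir / "candidates.csv", years)
        finish_stage(stage, n_weights=len(weights), n_candidates=len(candidates))

        stage = "categorize"
        trajectories = cat.build_trajectories(downsized, [c.term for c in candidates])
        stoplist = cat.Stoplist.from_dict(config.stoplist)
        assessments = cat.assess_keywords(
            trajectories, years, stoplist,
            acceleration_variant=config.acceleration_variant,  # type: ignore[arg-type]
            sd_variant=config.sd_variant,  # type: ignore[arg-type]
        )
        cat.write_assessments(assessments, out_dir / "assessments.csv")
        cat.write_category_summary(assessments, out_dir / "category_summary.csv")
        by_cat: dict[str, int] = {}
        for a in assessments:
            if not a.excluded:
                by_cat[a.category] = by_cat.get(a.category, 0) + 1
        finish_stage(stage, n_assessed=len(assessments),
                     n_excluded=sum(a.excluded for a in assessments), **by_cat)

        stage = "network"
        egos = config.egos or sorted(
            a.term for a in assessments if a.category == "hazardous" and not a.excluded
        )
        if not egos:
            raise pre.PipelineError("no ego terms: nothing categorized hazardous "
                                    "and no explicit ego list configured")
        sub = net.select_subcorpus(records, egos, config.tokenizer)
        vocab, incidence = net.binary_incidence(sub, config.tokenizer, config.min_df)
        graph = net.build_graph(
            vocab, incidence, egos,
            phi_threshold=config.phi_threshold,
            min_cooccurrence=config.min_cooccurrence,
            filter_order=config.filter_order,  # type: ignore[arg-type]
        )
        partition = net.louvain_communities(
            graph, seed=config.seed, resolution=config.louvain_resolution,
            weight="phi" if config.louvain_weighted else None,
        )
        nodes_table, _ = net.degree_report(graph, partition)
        net.write_edge_list(graph, out_dir / "network_edges.csv")
        net.write_graphml(graph, out_dir / "network.graphml")
        net.write_communities(nodes_table, out_dir / "communities.csv")
        net.write_summary(graph, partition, out_dir / "network_summary.json")
        finish_stage(stage, n_subcorpus=len(sub), n_nodes=graph.n_nodes,
                     n_edges=graph.n_edges,
                     n_communities=partition.n_communities,
                     modularity=round(partition.modularity, 6))

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise pre.PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
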