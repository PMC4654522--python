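"""End-to-end orchestration: configuration, staged execution, run manifest.

``run_all`` executes quantify -> identification sets/Venn -> annotation
tallies -> network integration -> expression validation, writing each stage's
machine-readable outputs plus a manifest recording the tool version,
parameters, input checksums and per-stage counts.  Outputs contain no
timestamps, so rerunning on identical inputs and configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import parse_blast_tabular, read_annotation_map, tally_categories, write_tally
from .design import read_design
from .expression_validation import concordance, read_ct_table, rev
from .network_integration import (
    NetworkConfig,
    build_network,
    link_pathways,
    read_pathway_db,
    select_candidates,
    tissue_subnetwork,
)
from .profile_analysis import (
    cluster_profiles,
    regulation_patterns,
    stage_venn,
    tissue_specific_sets,
)
from .quant_io import filter_by_fdr, identification_sets, read_quant_table
from .ratio_quant import (
    comparison_count_table,
    compute_sample_ratios,
    study_comparisons,
    write_comparisons,
)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    quant_table: str
    design: str
    out_dir: str
    annotation_map: str | None = None
    blast_tabular: str | None = None
    ko_pathway: str | None = None
    ko_edges: str | None = None
    ko_compound: str | None = None
    pathway_desc: str | None = None
    ct_table: str | None = None
    protein_fdr_max: float = 0.05
    peptide_fdr_max: float = 0.05
    up_min: float = 1.5
    down_max: float = 0.67
    fold_min: float = 5.0
    e_value_max: float = 1e-05
    ct_spread_max: float = 0.5
    reference_gene: str = "actin"
    calibrator_sample: str = "N1"
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    contrasts: tuple[str, ...] | None = None
    pattern_mode: str = "intersection"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.protein_fdr_max <= 1.0 and 0.0 <= self.peptide_fdr_max <= 1.0):
            raise ConfigError("FDR thresholds must lie in [0, 1]")
        if not (0.0 < self.down_max < 1.0 < self.up_min):
            raise ConfigError("need 0 < down_max < 1 < up_min")
        if self.fold_min <= 1.0:
            raise ConfigError("fold_min must be > 1")
        if self.e_value_max <= 0:
            raise ConfigError("e_value_max must be positive")
        if self.ct_spread_max <= 0:
            raise ConfigError("ct_spread_max must be positive")
        if self.pattern_mode not in ("intersection", "union"):
            raise ConfigError(f"unknown pattern mode {self.pattern_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["contrasts"] is not None:
            d["contrasts"] = list(d["contrasts"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, Mapping):
            raise ConfigError(f"{path}: config is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if doc.get("contrasts") is not None:
            doc = dict(doc)
            doc["contrasts"] = tuple(doc["contrasts"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "itraqpipe",
        "version": __version__,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "inputs": {},
        "stages": {},
    }
    for key in ("quant_table", "design", "annotation_map", "blast_tabular",
                "ko_pathway", "ko_edges", "ko_compound", "ct_table"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = _sha256(Path(p))

    # ---- quantify ----
    stage = "quantify"
    try:
        design = read_design(config.design)
        records = read_quant_table(config.quant_table, design)
        filtered = filter_by_fdr(records, config.protein_fdr_max, config.peptide_fdr_max)
        matrix = compute_sample_ratios(filtered, design)
        matrix.write(out / "ratio_matrix.tsv")
        comparisons = study_comparisons(matrix, config.up_min, config.down_max)
        write_comparisons(comparisons, out / "comparisons.tsv")
        counts = comparison_count_table(comparisons)
        counts.to_csv(out / "comparison_counts.tsv", sep="\t", index=False,
                      lineterminator="\n")
        manifest["stages"][stage] = {
            "n_records": len(records),
            "n_after_fdr": len(filtered),
            "n_proteins": len(matrix.proteins),
            "outputs": ["ratio_matrix.tsv", "comparisons.tsv", "comparison_counts.tsv"],
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- identification sets, Venn, tissue specificity ----
    stage = "venn"
    try:
        sets = identification_sets(filtered, design)
        sets.summary().to_csv(out / "identification_summary.tsv", sep="\t",
                              index=False, lineterminator="\n")
        venn_frames = []
        for tissue in sets.tissues():
            v = stage_venn(sets, tissue)
            df = v.to_frame()
            df.insert(0, "tissue", tissue)
            venn_frames.append(df)
        pd.concat(venn_frames, ignore_index=True).to_csv(
            out / "venn_cells.tsv", sep="\t", index=False, lineterminator="\n"
        )
        p_only, e_only, shared = tissue_specific_sets(sets)
        pd.DataFrame(
            {
                "set": ["pericarp_only", "endosperm_only", "shared"],
                "count": [len(p_only), len(e_only), len(shared)],
            }
        ).to_csv(out / "tissue_specific.tsv", sep="\t", index=False,
                 lineterminator="\n")
        manifest["stages"][stage] = {
            "per_stage_sizes": {f"{t}:{s}": n for (t, s), n in sorted(sets.sizes().items())},
            "nonredundant": len(sets.overall_union()),
            "outputs": ["identification_summary.tsv", "venn_cells.tsv", "tissue_specific.tsv"],
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- expression patterns + clustering ----
    stage = "profiles"
    try:
        patterns = regulation_patterns(comparisons, mode=config.pattern_mode)
        patterns.to_frame().to_csv(out / "regulation_patterns.tsv", sep="\t",
                                   index=False, lineterminator="\n")
        info: dict = {"outputs": ["regulation_patterns.tsv"]}
        try:
            tree = cluster_profiles(matrix, config.cluster_metric, config.cluster_linkage)
            tree.write(out / "cluster_tree.newick", matrix.log2(),
                       out / "clustered_matrix.tsv")
            info["outputs"] += ["cluster_tree.newick", "clustered_matrix.tsv"]
            info["n_clustered"] = len(tree.leaves)
            info["n_excluded"] = len(tree.excluded)
        except ValueError as e:
            info["clustering_skipped"] = str(e)
        manifest["stages"][stage] = info
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- annotation tallies ----
    if config.annotation_map:
        stage = "annotate"
        try:
            amap = read_annotation_map(config.annotation_map)
            universe = sets.overall_union()
            outputs = []
            for scheme in ("go:biological_process", "go:molecular_function",
                           "go:cellular_component", "cog"):
                tally = tally_categories(amap, universe, scheme)
                name = f"tally_{scheme.replace(':', '_')}.tsv"
                write_tally(tally, out / name, scheme)
                outputs.append(name)
            manifest["stages"][stage] = {"outputs": outputs}
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    # ---- network integration ----
    if config.blast_tabular and config.ko_pathway:
        stage = "network"
        try:
            ko = parse_blast_tabular(config.blast_tabular, config.e_value_max)
            db = read_pathway_db(
                config.ko_pathway, config.ko_edges, config.ko_compound,
                config.pathway_desc,
            )
            net_config = NetworkConfig(
                fold_min=config.fold_min, contrasts=config.contrasts
            )
            selection = select_candidates(matrix, net_config)
            selection.count_table().to_csv(
                out / "candidate_counts.tsv", sep="\t", index=False,
                lineterminator="\n",
            )
            network = build_network(selection, ko, db)
            network.write_edge_list(out / "network_edges.tsv")
            network.write_graphml(out / "network.graphml")
            ranked = link_pathways(network)
            pd.DataFrame(ranked, columns=["pathway", "description", "n_proteins"]).to_csv(
                out / "pathway_ranking.tsv", sep="\t", index=False,
                lineterminator="\n",
            )
            tissue_counts = {}
            for tissue in ("pericarp", "endosperm"):
                sub = tissue_subnetwork(network, tissue)
                sub.write_edge_list(out / f"network_{tissue}_edges.tsv")
                tissue_counts[tissue] = len(sub.study_proteins())
            manifest["stages"][stage] = {
                "n_candidates": len(selection.candidates),
                "n_study_proteins": len(network.study_proteins()),
                "n_unmapped": len(network.unmapped),
                "n_pathways": len(ranked),
                "tissue_proteins": tissue_counts,
                "outputs": [
                    "candidate_counts.tsv", "network_edges.tsv", "network.graphml",
                    "pathway_ranking.tsv", "network_pericarp_edges.tsv",
                    "network_endosperm_edges.tsv",
                ],
            }
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    # ---- expression validation ----
    if config.ct_table:
        stage = "validate"
        try:
            ct = read_ct_table(config.ct_table, config.reference_gene,
                               config.calibrator_sample)
            rev_result = rev(ct, max_spread=config.ct_spread_max)
            rev_result.write(out / "rev.tsv")
            profile = rev_result.rev_profile()
            ratio_df = matrix.dataframe()
            shared_genes = [g for g in profile.index if g in set(ratio_df.index)]
            info: dict = {"n_genes": len(profile.index), "outputs": ["rev.tsv"]}
            if shared_genes:
                report = concordance(profile, ratio_df, design, flat_fold=config.up_min)
                report.intervals.to_csv(out / "concordance.tsv", sep="\t",
                                        index=False, lineterminator="\n")
                info["outputs"].append("concordance.tsv")
                info["fraction_concordant"] = report.fraction_concordant
            manifest["stages"][stage] = info
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    # ---- manifest with output checksums ----
    checksums = {}
    for st in manifest["stages"].values():
        for name in st.get("outputs", []):
            checksums[name] = _sha256(out / name)
    manifest["output_checksums"] = checksums
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
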