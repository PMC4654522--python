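"""High-fold-change candidate selection and KEGG-orthology network integration.

Candidates are proteins whose expression differs by at least ``fold_min``
(default 5) in any configured contrast; contrasts are differences of log2
ratios, so "5-fold" means |log2 r_a - log2 r_b| >= log2(5).  Candidates are
mapped to KEGG orthology (KO) via BLAST best hits and embedded into a typed
graph together with KO-KO relation edges and KO-compound edges read from
KEGG-style flat link files (offline; the live API is never touched).

A study protein and its KO are modelled as one merged node carrying both
identities (the protein stands in the KO's graph position); explicit
protein-KO relation edges appear only between distinct proteins that map to
the same KO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .annotation import KoAssignment
from .design import SampleDesign
from .ratio_quant import RatioMatrix

FOLD_MIN_DEFAULT = 5.0

NODE_STUDY_PROTEIN = "study_protein"
NODE_ORTHOLOG = "ortholog"
NODE_COMPOUND = "compound"

EDGE_PROTEIN_KO = "protein_ko_relation"
EDGE_KO_KO = "ko_ko_interaction"
EDGE_KO_COMPOUND = "ko_compound"


class NetworkError(ValueError):
    pass


def default_contrasts(design: SampleDesign) -> tuple[str, ...]:
    """5 single contrasts vs the control sample plus all 15 unordered pairs.

    Single contrasts are labelled by the sample alone (``"N6"`` means N6 vs
    control); double contrasts as ``"Na/Nb"``.
    """
    sids = design.sample_ids()
    control = design.control_sample
    singles = tuple(s for s in sids if s != control)
    pairs = []
    for i, a in enumerate(sids):
        for b in sids[i + 1 :]:
            pairs.append(f"{b}/{a}")
    return singles + tuple(pairs)


@dataclass
class NetworkConfig:
    fold_min: float = FOLD_MIN_DEFAULT
    contrasts: tuple[str, ...] | None = None  # None -> default_contrasts(design)
    log_base: float = 2.0
    fold_space: str = "log"  # "log" (|delta log2| >= log2 fold_min) or "linear"

    def __post_init__(self) -> None:
        if self.fold_min <= 1.0:
            raise NetworkError("fold_min must be > 1")
        if self.fold_space not in ("log", "linear"):
            raise NetworkError(f"unknown fold_space {self.fold_space!r}")


@dataclass
class Candidate:
    accession: str
    gene_model: str
    contrasts: tuple[str, ...]  # contrasts that triggered inclusion
    tissues: frozenset[str]  # tissue provenance of the triggering contrasts


@dataclass
class CandidateSelection:
    candidates: dict[str, Candidate]
    contrast_counts: dict[str, int]
    config: NetworkConfig

    def accessions(self) -> frozenset[str]:
        return frozenset(self.candidates)

    def count_table(self) -> pd.DataFrame:
        rows = [
            {"contrast": c, "n_proteins": n}
            for c, n in sorted(
                self.contrast_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows)


def _contrast_samples(contrast: str, control: str) -> tuple[str, str]:
    if "/" in contrast:
        a, b = contrast.split("/")
        return a, b
    return contrast, control


def contrast_tissue(contrast: str, design: SampleDesign) -> str | None:
    """Tissue label of a contrast, or None for cross-tissue pairs.

    A single contrast (sample vs control) is labelled by the sample's own
    tissue, the control acting as a neutral reference; a pair contrast is
    labelled only when both samples share a tissue.
    """
    a, b = _contrast_samples(contrast, design.control_sample)
    ta = design.tissue_of(a)
    if "/" not in contrast:
        return ta
    tb = design.tissue_of(b)
    return ta if ta == tb else None


def select_candidates(
    matrix: RatioMatrix, config: NetworkConfig | None = None
) -> CandidateSelection:
    """Select proteins exceeding the fold-change criterion in any contrast.

    Returns the union of qualifying proteins plus a per-contrast count table.
    A protein's tissue provenance is the set of ``contrast_tissue`` labels of
    its triggering contrasts; proteins triggered only by cross-tissue pairs
    carry no tissue label and belong to the whole network but to neither
    tissue subnetwork.
    """
    config = config or NetworkConfig()
    contrasts = config.contrasts or default_contrasts(matrix.design)
    log2 = matrix.log2()
    threshold = math.log(config.fold_min, config.log_base)
    control = matrix.design.control_sample

    hits: dict[str, list[str]] = {}
    contrast_counts: dict[str, int] = {}
    for contrast in contrasts:
        a, b = _contrast_samples(contrast, control)
        if config.fold_space == "log":
            delta = (log2[a] - log2[b]).abs()
            qualifying = delta.index[delta >= threshold]
        else:
            ratio = matrix.dataframe()
            lin = (ratio[a] - ratio[b]).abs()
            qualifying = lin.index[lin >= config.fold_min]
        contrast_counts[contrast] = len(qualifying)
        for acc in qualifying:
            hits.setdefault(acc, []).append(contrast)

    candidates: dict[str, Candidate] = {}
    for acc in sorted(hits):
        trig = tuple(hits[acc])
        tissues: set[str] = set()
        for contrast in trig:
            t = contrast_tissue(contrast, matrix.design)
            if t is not None:
                tissues.add(t)
        candidates[acc] = Candidate(
            accession=acc,
            gene_model=matrix.gene_models.get(acc, acc),
            contrasts=trig,
            tissues=frozenset(tissues),
        )
    return CandidateSelection(
        candidates=candidates, contrast_counts=contrast_counts, config=config
    )


# ---------------------------------------------------------------------- #
# pathway reference database (KEGG-style flat link files)


@dataclass
class PathwayDB:
    ko_pathway: dict[str, frozenset[str]] = field(default_factory=dict)
    pathway_desc: dict[str, str] = field(default_factory=dict)
    ko_edges: frozenset[frozenset[str]] = field(default_factory=frozenset)
    ko_compounds: dict[str, frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for e in self.ko_edges:
            if len(e) != 2:
                raise NetworkError(f"KO-KO edge must join two distinct KOs: {set(e)}")
        for ko, compounds in self.ko_compounds.items():
            if ko in compounds:
                raise NetworkError(f"KO {ko} listed as its own compound")

    def ko_neighbors(self, ko: str) -> frozenset[str]:
        out = set()
        for e in self.ko_edges:
            if ko in e:
                out |= set(e) - {ko}
        return frozenset(out)

    def declared_kos(self) -> frozenset[str]:
        kos = set(self.ko_pathway)
        for e in self.ko_edges:
            kos |= set(e)
        kos |= set(self.ko_compounds)
        return frozenset(kos)


def _strip_prefix(token: str) -> str:
    return token.split(":", 1)[1] if ":" in token else token


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise NetworkError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def read_pathway_db(
    ko_pathway_path: str | Path,
    ko_edges_path: str | Path | None = None,
    ko_compound_path: str | Path | None = None,
    pathway_desc_path: str | Path | None = None,
) -> PathwayDB:
    """Assemble a PathwayDB from two-column KEGG link-style flat files.

    Lines look like ``ko:K01778<TAB>path:ko00290``; prefixes before ':' are
    tolerated and stripped for KO/compound tokens, pathway ids keep their
    ``path:`` form.
    """
    ko_pathway: dict[str, set[str]] = {}
    for ko, pw in _read_pairs(ko_pathway_path):
        pw_id = pw if pw.startswith("path:") else f"path:{_strip_prefix(pw)}"
        ko_pathway.setdefault(_strip_prefix(ko), set()).add(pw_id)

    edges: set[frozenset[str]] = set()
    if ko_edges_path is not None:
        for a, b in _read_pairs(ko_edges_path):
            ka, kb = _strip_prefix(a), _strip_prefix(b)
            if ka == kb:
                raise NetworkError(f"self-loop KO edge {ka}")
            edges.add(frozenset((ka, kb)))

    compounds: dict[str, set[str]] = {}
    if ko_compound_path is not None:
        for ko, cpd in _read_pairs(ko_compound_path):
            compounds.setdefault(_strip_prefix(ko), set()).add(_strip_prefix(cpd))

    desc: dict[str, str] = {}
    if pathway_desc_path is not None:
        for pw, d in _read_pairs(pathway_desc_path):
            pw_id = pw if pw.startswith("path:") else f"path:{_strip_prefix(pw)}"
            desc[pw_id] = d

    db = PathwayDB(
        ko_pathway={k: frozenset(v) for k, v in ko_pathway.items()},
        pathway_desc=desc,
        ko_edges=frozenset(edges),
        ko_compounds={k: frozenset(v) for k, v in compounds.items()},
    )
    db.validate()
    return db


def write_pathway_db(db: PathwayDB, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ko_pathway": out_dir / "ko_pathway.tsv",
        "ko_edges": out_dir / "ko_edges.tsv",
        "ko_compound": out_dir / "ko_compound.tsv",
        "pathway_desc": out_dir / "pathway_desc.tsv",
    }
    with open(paths["ko_pathway"], "w") as fh:
        for ko in sorted(db.ko_pathway):
            for pw in sorted(db.ko_pathway[ko]):
                fh.write(f"ko:{ko}\t{pw}\n")
    with open(paths["ko_edges"], "w") as fh:
        for e in sorted(tuple(sorted(e)) for e in db.ko_edges):
            fh.write(f"ko:{e[0]}\tko:{e[1]}\n")
    with open(paths["ko_compound"], "w") as fh:
        for ko in sorted(db.ko_compounds):
            for cpd in sorted(db.ko_compounds[ko]):
                fh.write(f"ko:{ko}\tcpd:{cpd}\n")
    with open(paths["pathway_desc"], "w") as fh:
        for pw in sorted(db.pathway_desc):
            fh.write(f"{pw}\t{db.pathway_desc[pw]}\n")
    return paths


# ---------------------------------------------------------------------- #
# the integrated typed network


@dataclass
class IntegratedNetwork:
    graph: nx.Graph
    unmapped: tuple[str, ...]  # candidate accessions without a KO assignment
    selection: CandidateSelection | None = None
    ko: KoAssignment | None = None
    db: PathwayDB | None = None

    def study_proteins(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["type"] == NODE_STUDY_PROTEIN
        )

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["type"] == node_type)

    def ko_of(self, protein: str) -> str:
        d = self.graph.nodes[protein]
        if d["type"] != NODE_STUDY_PROTEIN:
            raise KeyError(f"{protein!r} is not a study protein node")
        return d["ko"]

    def candidate_kos(self) -> frozenset[str]:
        return frozenset(
            d["ko"]
            for _, d in self.graph.nodes(data=True)
            if d["type"] == NODE_STUDY_PROTEIN
        )

    # ---- serialization (byte-stable: sorted nodes/edges) ----

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for a, b, d in sorted(self.graph.edges(data=True)):
            a2, b2 = sorted((a, b))
            rows.append(
                {
                    "source": a2,
                    "target": b2,
                    "edge_type": d["type"],
                    "source_type": self.graph.nodes[a2]["type"],
                    "target_type": self.graph.nodes[b2]["type"],
                }
            )
        rows.sort(key=lambda r: (r["source"], r["target"], r["edge_type"]))
        return pd.DataFrame(
            rows, columns=["source", "target", "edge_type", "source_type", "target_type"]
        )

    def write_edge_list(self, path: str | Path) -> None:
        from . import __version__

        lines = [f"# itraqpipe integrated network v{__version__}"]
        Path(path).write_text(
            "\n".join(lines)
            + "\n"
            + self.edge_list().to_csv(sep="\t", index=False, lineterminator="\n")
        )

    def write_graphml(self, path: str | Path) -> None:
        # rebuild with sorted insertion so the XML is byte-stable
        g = nx.Graph()
        for n in sorted(self.graph.nodes):
            attrs = {
                k: v for k, v in self.graph.nodes[n].items() if isinstance(v, (str, int, float))
            }
            g.add_node(n, **attrs)
        for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
            g.add_edge(a, b, type=self.graph.edges[a, b]["type"])
        nx.write_graphml(g, path)


def build_network(
    selection: CandidateSelection | Iterable[str],
    ko: KoAssignment,
    db: PathwayDB,
    gene_models: Mapping[str, str] | None = None,
) -> IntegratedNetwork:
    """Embed candidate proteins into the KO relation/compound graph.

    Candidates without a KO assignment are excluded and listed as unmapped.
    Node and edge insertion is sorted, so serialization is stable under any
    input order.
    """
    db.validate()
    if isinstance(selection, CandidateSelection):
        cand_map = selection.candidates
        sel = selection
    else:
        cand_map = {
            acc: Candidate(
                accession=acc,
                gene_model=(gene_models or {}).get(acc, acc),
                contrasts=(),
                tissues=frozenset(),
            )
            for acc in selection
        }
        sel = None

    # KO -> proteins standing on that KO node
    ko_to_proteins: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for acc in sorted(cand_map):
        k = ko.ko(cand_map[acc].gene_model)
        if k is None:
            unmapped.append(acc)
        else:
            ko_to_proteins.setdefault(k, []).append(acc)

    g = nx.Graph()

    def protein_nodes_for(k: str) -> list[str]:
        return ko_to_proteins.get(k, [])

    def ensure_ko_node(k: str) -> list[str]:
        """Nodes representing KO k: its study proteins if any, else one ortholog node."""
        prots = protein_nodes_for(k)
        if prots:
            for acc in prots:
                if acc not in g:
                    c = cand_map[acc]
                    g.add_node(
                        acc,
                        type=NODE_STUDY_PROTEIN,
                        ko=k,
                        gene_model=c.gene_model,
                        tissues=",".join(sorted(c.tissues)),
                        contrasts=",".join(c.contrasts),
                    )
            return prots
        node = f"ko:{k}"
        if node not in g:
            g.add_node(node, type=NODE_ORTHOLOG, ko=k)
        return [node]

    candidate_kos = sorted(ko_to_proteins)
    for k in candidate_kos:
        nodes = ensure_ko_node(k)
        # distinct proteins sharing a KO are linked by protein_ko_relation edges
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                g.add_edge(a, b, type=EDGE_PROTEIN_KO)

    # expand the KO interaction neighbourhood to depth 2, so first- and
    # second-degree interaction partners of every study protein are present
    frontier = set(candidate_kos)
    expanded: set[str] = set()
    for _depth in range(2):
        next_frontier: set[str] = set()
        for k in sorted(frontier):
            if k in expanded:
                continue
            expanded.add(k)
            nodes = ensure_ko_node(k)
            for neighbor in sorted(db.ko_neighbors(k)):
                for a in nodes:
                    for b in ensure_ko_node(neighbor):
                        if a != b:
                            g.add_edge(a, b, type=EDGE_KO_KO)
                next_frontier.add(neighbor)
        frontier = next_frontier - expanded

    # compounds attach to every KO represented in the graph, neighbours included
    represented = sorted(
        {d["ko"] for _, d in g.nodes(data=True) if "ko" in d}
    )
    for k in represented:
        for cpd in sorted(db.ko_compounds.get(k, ())):
            cnode = f"cpd:{cpd}"
            if cnode not in g:
                g.add_node(cnode, type=NODE_COMPOUND)
            for a in ensure_ko_node(k):
                g.add_edge(a, cnode, type=EDGE_KO_COMPOUND)

    return IntegratedNetwork(
        graph=g, unmapped=tuple(unmapped), selection=sel, ko=ko, db=db
    )


def link_pathways(
    network_or_kos: IntegratedNetwork | Iterable[str],
    db: PathwayDB | None = None,
    ko_of_protein: Mapping[str, str] | None = None,
) -> list[tuple[str, str, int]]:
    """Rank pathways by the number of distinct candidate proteins linking to them.

    Given an IntegratedNetwork, each study protein contributes through its KO;
    given a bare KO iterable, each KO counts as one protein.  Returns
    (pathway id, description, protein count) sorted by descending count then
    pathway id.
    """
    if isinstance(network_or_kos, IntegratedNetwork):
        net = network_or_kos
        db = db or net.db
        if db is None:
            raise NetworkError("a PathwayDB is required")
        protein_ko = {p: net.ko_of(p) for p in net.study_proteins()}
    else:
        if db is None:
            raise NetworkError("a PathwayDB is required")
        protein_ko = {k: k for k in network_or_kos}
        if ko_of_protein:
            protein_ko = dict(ko_of_protein)

    counts: dict[str, set[str]] = {}
    for protein, k in protein_ko.items():
        for pw in db.ko_pathway.get(k, ()):
            counts.setdefault(pw, set()).add(protein)
    ranked = sorted(counts.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(pw, db.pathway_desc.get(pw, ""), len(members)) for pw, members in ranked]


def degree_profile(
    network: IntegratedNetwork, protein: str
) -> tuple[frozenset[str], frozenset[str]]:
    """First- and second-degree interaction neighbourhoods of a study protein.

    Traverses KO-KO interaction edges only: first degree is the set of nodes
    adjacent to the protein's node; second degree is nodes adjacent to those,
    excluding the focal node and all first-degree nodes.  The two sets are
    disjoint by construction.
    """
    g = network.graph
    if protein not in g or g.nodes[protein]["type"] != NODE_STUDY_PROTEIN:
        raise KeyError(f"unknown study protein {protein!r}")

    def interaction_neighbors(node: str) -> set[str]:
        return {
            m for m in g.neighbors(node) if g.edges[node, m]["type"] == EDGE_KO_KO
        }

    first = interaction_neighbors(protein)
    second: set[str] = set()
    for n in first:
        second |= interaction_neighbors(n)
    second -= first
    second.discard(protein)
    return frozenset(first), frozenset(second)


def tissue_subnetwork(network: IntegratedNetwork, tissue: str) -> IntegratedNetwork:
    """Rebuild the network over study proteins whose candidacy arose in a tissue."""
    from .design import TISSUES

    if tissue not in TISSUES:
        raise NetworkError(f"unknown tissue {tissue!r}")
    if network.selection is None or network.ko is None or network.db is None:
        raise NetworkError("network lacks the selection/ko/db needed to re-link")
    sub = {
        acc: cand
        for acc, cand in network.selection.candidates.items()
        if tissue in cand.tissues
    }
    selection = CandidateSelection(
        candidates=sub,
        contrast_counts=network.selection.contrast_counts,
        config=network.selection.config,
    )
    return build_network(selection, network.ko, network.db)
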