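"""Case-to-normal ratios, two-sigma differential flags and pathway activation.

The pathway activation strength (PAS) of a pathway p in a case sample is

    PAS_p = sum_n ARR_np * BTIF_n * lg(CNR_n)

where CNR_n is the case-to-normal ratio of gene n (case expression over the
geometric mean of the control samples), lg is log10, ARR_np is the gene's
activator/repressor role in the pathway (+1 activator, -1 repressor, +/-0.5
weak, 0 unknown), and BTIF_n is a boolean flag marking the gene as
differentially expressed.  The flag uses the two-sigma rule: a gene is
differential when its case expression falls outside mean +/- 2 sd of the
control samples (sample standard deviation, n-1).

Positive PAS means over-activation relative to the controls, negative means
under-activation; genes that are not flagged contribute nothing.  Pathway
edges (activation/inhibition) are carried for network rendering only — the
score itself is node-role based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_ARR = {-1.0, -0.5, 0.0, 0.5, 1.0}
VALID_EDGE_KINDS = {"activation", "inhibition"}
EDGE_COLORS = {"activation": "green", "inhibition": "red"}


class PathwayError(ValueError):
    """Raised for malformed pathway definitions."""


@dataclass(frozen=True)
class PathwayDefinition:
    """One pathway: gene roles plus directed interaction edges."""

    pathway_id: str
    nodes: dict[str, float]  # gene_id -> activator/repressor role (ARR)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise PathwayError(f"pathway {self.pathway_id!r} has no nodes")
        bad_arr = {g: a for g, a in self.nodes.items() if a not in VALID_ARR}
        if bad_arr:
            raise PathwayError(
                f"pathway {self.pathway_id!r}: invalid role values {bad_arr}"
            )
        if all(a == 0 for a in self.nodes.values()):
            raise PathwayError(
                f"pathway {self.pathway_id!r} has no node with a non-zero role"
            )
        for src, tgt, kind in self.edges:
            if kind not in VALID_EDGE_KINDS:
                raise PathwayError(f"edge kind {kind!r} not in {VALID_EDGE_KINDS}")
            for endpoint in (src, tgt):
                if endpoint not in self.nodes:
                    raise PathwayError(
                        f"edge endpoint {endpoint!r} is not a declared node "
                        f"of pathway {self.pathway_id!r}"
                    )

    @property
    def genes(self) -> list[str]:
        return list(self.nodes)


def load_pathway(path) -> PathwayDefinition:
    """Load and validate a pathway YAML file.

    Schema::

        pathway_id: token
        nodes: [{gene: token, arr: -1|-0.5|0|0.5|1}, ...]
        edges: [{from: token, to: token, kind: activation|inhibition}, ...]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "pathway_id" not in raw or "nodes" not in raw:
        raise PathwayError(f"{path}: expected mapping with pathway_id and nodes")
    nodes: dict[str, float] = {}
    for entry in raw["nodes"]:
        gene = str(entry["gene"])
        if gene in nodes:
            raise PathwayError(f"{path}: duplicate gene {gene!r}")
        nodes[gene] = float(entry["arr"])
    edges = [
        (str(e["from"]), str(e["to"]), str(e["kind"]))
        for e in raw.get("edges", []) or []
    ]
    return PathwayDefinition(str(raw["pathway_id"]), nodes, edges)


def load_pathway_dir(path) -> list[PathwayDefinition]:
    files = sorted(Path(path).glob("*.yaml")) + sorted(Path(path).glob("*.yml"))
    if not files:
        raise PathwayError(f"no pathway YAML files found under {path}")
    return [load_pathway(f) for f in files]


# ---------------------------------------------------------------------------
# CNR and differential flags


def compute_cnr(
    expr: pd.DataFrame, case: str, controls: list[str]
) -> pd.Series:
    """Case-to-normal ratio per gene: case / geometric mean of controls."""
    if not controls:
        raise ValueError("control sample list is empty")
    if case in controls:
        raise ValueError(f"case sample {case!r} also appears in controls")
    ctrl = expr[list(controls)].to_numpy(dtype=float)
    if (ctrl <= 0).any() or (expr[case] <= 0).any():
        raise ValueError("expression must be positive for CNR (apply signal floor)")
    normal = np.exp(np.log(ctrl).mean(axis=1))
    cnr = expr[case].to_numpy(dtype=float) / normal
    return pd.Series(cnr, index=expr.index, name=case)


def flag_two_sigma(
    expr: pd.DataFrame, case: str, controls: list[str]
) -> pd.Series:
    """Two-sigma differential expression flags against a control group.

    A gene is flagged when its case expression lies strictly outside
    mean +/- 2 sd of the control samples.  At least two control samples are
    required for the sample standard deviation to exist; the study design
    uses five biological control replicates.
    """
    if len(controls) < 2:
        raise ValueError(
            "two-sigma rule needs >=2 control samples "
            f"(got {len(controls)}): sample standard deviation is undefined"
        )
    ctrl = expr[list(controls)]
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    case_vals = expr[case]
    flags = (case_vals < mean - 2 * sd) | (case_vals > mean + 2 * sd)
    return flags.rename(case)


# ---------------------------------------------------------------------------
# PAS


@dataclass(frozen=True)
class PASResult:
    pathway_id: str
    sample_id: str
    pas: float
    per_gene_terms: dict[str, float]

    def __post_init__(self) -> None:
        assert math.isclose(
            self.pas, sum(self.per_gene_terms.values()), abs_tol=1e-9
        )


def compute_pas(
    cnr: pd.Series, flags: pd.Series, pathway: PathwayDefinition
) -> PASResult:
    """Score one pathway for one case sample.

    Pathway genes absent from the expression data contribute zero and are
    logged; a pathway with no overlap at all scores 0 with a warning.
    """
    if (cnr <= 0).any():
        raise ValueError("CNR values must be positive")
    terms: dict[str, float] = {}
    n_present = 0
    for gene, arr in pathway.nodes.items():
        if gene not in cnr.index:
            logger.info(
                "pathway %s gene %s absent from expression data; contributes 0",
                pathway.pathway_id, gene,
            )
            terms[gene] = 0.0
            continue
        n_present += 1
        flagged = bool(flags.get(gene, False))
        terms[gene] = arr * float(flagged) * math.log10(float(cnr[gene])) if flagged else 0.0
    if n_present == 0:
        logger.warning(
            "pathway %s shares no genes with the expression data; PAS = 0",
            pathway.pathway_id,
        )
    sample = str(cnr.name) if cnr.name is not None else ""
    return PASResult(pathway.pathway_id, sample, float(sum(terms.values())), terms)


def pas_timecourse(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    pathways: list[PathwayDefinition],
    per_week_controls: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PAS of every drug sample against its matched naive controls.

    For each (cell line, week) the naive samples of that week form the
    control group of every drug sample of the same cell line and week (the
    matched-control design; ``per_week_controls=False`` pools all naive
    samples of the cell line instead).  Weeks without controls are skipped
    with a warning.

    Returns ``(scores, dispersion)``: per-sample PAS rows
    (pathway_id, sample_id, cell_line, drug, week, pas) and the per-week
    spread of PAS across drug samples (pathway_id, cell_line, week, pas_sd,
    population standard deviation).
    """
    rows = []
    for cell_line, block in meta.groupby("cell_line", sort=False):
        naive = block[block["drug"] == "naive"]
        cases = block[block["drug"] != "naive"]
        for week, week_cases in cases.groupby("week", sort=True):
            if per_week_controls:
                controls = naive[naive["week"] == week]["sample_id"].tolist()
            else:
                controls = naive["sample_id"].tolist()
            controls = [s for s in controls if s in expr.columns]
            if len(controls) < 2:
                logger.warning(
                    "skipping %s week %s: no matched control samples", cell_line, week
                )
                continue
            for sample in week_cases["sample_id"]:
                if sample not in expr.columns:
                    continue
                cnr = compute_cnr(expr, sample, controls)
                flags = flag_two_sigma(expr, sample, controls)
                for pw in pathways:
                    res = compute_pas(cnr, flags, pw)
                    rows.append(
                        {
                            "pathway_id": pw.pathway_id,
                            "sample_id": sample,
                            "cell_line": cell_line,
                            "drug": week_cases.loc[
                                week_cases["sample_id"] == sample, "drug"
                            ].iloc[0],
                            "week": int(week),
                            "pas": res.pas,
                        }
                    )
    scores = pd.DataFrame(
        rows, columns=["pathway_id", "sample_id", "cell_line", "drug", "week", "pas"]
    )
    if len(scores):
        dispersion = (
            scores.groupby(["pathway_id", "cell_line", "week"])["pas"]
            .std(ddof=0)
            .rename("pas_sd")
            .reset_index()
        )
    else:
        dispersion = pd.DataFrame(columns=["pathway_id", "cell_line", "week", "pas_sd"])
    return scores, dispersion


# ---------------------------------------------------------------------------
# Network export


def build_network(
    pathway: PathwayDefinition, cnr: pd.Series | None = None, pas: float | None = None
) -> nx.DiGraph:
    """Pathway topology as a directed graph with rendering attributes.

    Node attribute ``log_cnr`` is log10(CNR) clamped to [-1, +1] (color
    depth); nodes without a CNR value render neutral (0).  Edges carry
    ``kind`` and the conventional color (activation green, inhibition red).
    """
    g = nx.DiGraph(pathway_id=pathway.pathway_id)
    if pas is not None:
        g.graph["pas"] = float(pas)
    for gene, arr in pathway.nodes.items():
        if cnr is not None and gene in cnr.index and cnr[gene] > 0:
            depth = float(np.clip(math.log10(float(cnr[gene])), -1.0, 1.0))
        else:
            if cnr is not None:
                logger.info("no CNR for node %s; rendering neutral", gene)
            depth = 0.0
        g.add_node(gene, arr=float(arr), log_cnr=depth)
    for src, tgt, kind in pathway.edges:
        g.add_edge(src, tgt, kind=kind, color=EDGE_COLORS[kind])
    return g


def export_network(
    pathway: PathwayDefinition,
    cnr: pd.Series | None,
    graphml_path,
    dot_path=None,
    pas: float | None = None,
) -> nx.DiGraph:
    """Write the pathway network as GraphML (and optionally DOT)."""
    g = build_network(pathway, cnr, pas)
    nx.write_graphml(g, graphml_path)
    if dot_path is not None:
        write_dot(g, dot_path)
    return g


def write_dot(g: nx.DiGraph, path) -> None:
    """Minimal Graphviz DOT writer (node fill from log_cnr, edge colors)."""
    lines = [f'digraph "{g.graph.get("pathway_id", "pathway")}" {{']
    if "pas" in g.graph:
        lines.append(f'  label="PAS = {g.graph["pas"]:.3f}";')
    for node, data in g.nodes(data=True):
        lines.append(
            f'  "{node}" [log_cnr={data["log_cnr"]:.4f}, arr={data["arr"]:g}];'
        )
    for src, tgt, data in g.edges(data=True):
        lines.append(f'  "{src}" -> "{tgt}" [color={data["color"]}, kind="{data["kind"]}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pas_table(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")
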