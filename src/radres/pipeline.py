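"""End-to-end orchestration: simulate/ingest -> normalize -> PAS -> IC50 -> foci.

``run_all`` produces a report bundle in the output directory:

* ``ic50_table.tsv``    — IC50 time course with percent changes vs baseline
* ``pas.tsv``/``pas_dispersion.tsv`` — pathway activation per drug sample and
  its per-week spread across drugs
* ``networks/*.graphml`` (+ ``.dot``) — pathway graphs, node color depth from
  log10 CNR, at the earliest culturing week
* ``foci_summary.tsv``/``foci_tests.tsv`` — hierarchical focus-count
  summaries and Student t-tests of each drug lineage against naive cells
* ``manifest.json``     — package version, config hash, seed, output list

A stage failure renames the bundle's outputs with a ``.partial`` suffix and
re-raises, so an interrupted run is never mistaken for a complete one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dose_response import fit_ic50, read_plates, resistance_table
from .expression import (
    normalize_pipeline,
    read_metadata,
    read_probe_table,
    write_expression,
    write_metadata,
)
from .foci import (
    CONDITION_KEYS,
    compare,
    read_foci,
    reduction_table,
    summarize,
    write_summary,
)
from .pathways import (
    compute_cnr,
    export_network,
    load_pathway_dir,
    pas_timecourse,
    write_pas_table,
)
from .simulate import SyntheticConfig, atm_pathway, write_simulation

logger = logging.getLogger(__name__)


def _config_hash(cfg) -> str:
    if dataclasses.is_dataclass(cfg):
        payload = {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if not isinstance(v, (bytes,))
        }
    else:
        payload = cfg
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_all(
    outdir,
    simulate_cfg: SyntheticConfig | None = None,
    probes_path=None,
    meta_path=None,
    plates_path=None,
    foci_path=None,
    pathway_dir=None,
    per_week_controls: bool = True,
) -> dict:
    """Run every pipeline stage and write the report bundle.

    Inputs are either simulated (``simulate_cfg``) or read from the given
    paths; both modes share all downstream stages.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    try:
        return _run_all(
            outdir, outputs, simulate_cfg, probes_path, meta_path,
            plates_path, foci_path, pathway_dir, per_week_controls,
        )
    except Exception:
        for path in outputs:
            if path.exists():
                path.rename(path.with_name(path.name + ".partial"))
        raise


def _run_all(
    outdir, outputs, simulate_cfg, probes_path, meta_path,
    plates_path, foci_path, pathway_dir, per_week_controls,
):
    if simulate_cfg is not None:
        sim_dir = outdir / "simulated"
        paths = write_simulation(simulate_cfg, sim_dir)
        probes_path, meta_path = paths["probes"], paths["meta"]
        plates_path, foci_path = paths["plates"], paths["foci"]
    if probes_path is None or meta_path is None:
        raise ValueError("need probe and metadata inputs (or a simulation config)")
    if pathway_dir is not None:
        pathway_dir = Path(pathway_dir)
        if not pathway_dir.exists():
            raise FileNotFoundError(f"pathway directory not found: {pathway_dir}")
        pathways = load_pathway_dir(pathway_dir)
    else:
        pathways = [atm_pathway()]

    # stage 1: expression
    logger.info("stage 1: probe collapse + quantile normalization")
    table = read_probe_table(probes_path)
    meta = read_metadata(meta_path)
    expr = normalize_pipeline(table, meta)
    expr_path = outdir / "expression.tsv"
    write_expression(expr, expr_path)
    write_metadata(meta, outdir / "meta.tsv")
    outputs += [expr_path, outdir / "meta.tsv"]

    # stage 2: PAS time course + networks
    logger.info("stage 2: CNR / PAS scoring over %d pathway(s)", len(pathways))
    scores, dispersion = pas_timecourse(expr, meta, pathways, per_week_controls)
    write_pas_table(scores, outdir / "pas.tsv")
    write_pas_table(dispersion, outdir / "pas_dispersion.tsv")
    outputs += [outdir / "pas.tsv", outdir / "pas_dispersion.tsv"]
    net_dir = outdir / "networks"
    net_dir.mkdir(exist_ok=True)
    if len(scores):
        first_week = int(scores["week"].min())
        early = scores[scores["week"] == first_week]
        for _, row in early.iterrows():
            controls = meta[
                (meta["cell_line"] == row["cell_line"])
                & (meta["drug"] == "naive")
                & (meta["week"] == first_week)
            ]["sample_id"].tolist()
            cnr = compute_cnr(expr, row["sample_id"], controls)
            pw = next(p for p in pathways if p.pathway_id == row["pathway_id"])
            stem = f"{row['pathway_id']}_{row['cell_line']}_{row['drug']}_w{first_week:02d}"
            export_network(
                pw, cnr, net_dir / f"{stem}.graphml", net_dir / f"{stem}.dot",
                pas=row["pas"],
            )
            outputs += [net_dir / f"{stem}.graphml", net_dir / f"{stem}.dot"]

    # stage 3: IC50 table
    if plates_path is not None:
        logger.info("stage 3: dose-response fits")
        plates = read_plates(plates_path)
        estimates = {
            (p.cell_line, p.drug, p.week): fit_ic50(p) for p in plates
        }
        ic50_table = resistance_table(estimates)
        ic50_table.to_csv(outdir / "ic50_table.tsv", sep="\t", index=False)
        outputs.append(outdir / "ic50_table.tsv")
    else:
        ic50_table = None

    # stage 4: foci summaries + tests
    if foci_path is not None:
        logger.info("stage 4: foci statistics")
        ds = read_foci(foci_path)
        summaries = pd.concat(
            [summarize(ds, m) for m in ("h2ax", "patm")], ignore_index=True
        )
        write_summary(summaries, outdir / "foci_summary.tsv")
        outputs.append(outdir / "foci_summary.tsv")
        tests = _foci_tests(ds)
        tests.to_csv(outdir / "foci_tests.tsv", sep="\t", index=False, float_format="%.6g")
        outputs.append(outdir / "foci_tests.tsv")
        reductions = pd.concat(
            [reduction_table(summarize(ds, m)) for m in ("h2ax", "patm")],
            ignore_index=True,
        )
        reductions.to_csv(
            outdir / "foci_reduction.tsv", sep="\t", index=False, float_format="%.6g"
        )
        outputs.append(outdir / "foci_reduction.tsv")
    else:
        summaries = None

    manifest = {
        "package": "radres",
        "version": __version__,
        "seed": getattr(simulate_cfg, "seed", None),
        "config_hash": _config_hash(simulate_cfg) if simulate_cfg else None,
        "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _write_summary_md(outdir, ic50_table, summaries)
    return manifest


def _foci_tests(ds: pd.DataFrame) -> pd.DataFrame:
    """Each drug lineage vs the matched naive condition, both markers."""
    rows = []
    conditions = ds[CONDITION_KEYS].drop_duplicates()
    for _, cond in conditions.iterrows():
        if cond["lineage"] == "naive":
            continue
        naive_cond = cond.to_dict() | {"lineage": "naive"}
        match = conditions
        for k, v in naive_cond.items():
            match = match[match[k] == v]
        if not len(match):
            continue
        for marker in ("h2ax", "patm"):
            res = compare(ds, cond.to_dict(), naive_cond, marker)
            rows.append(
                cond.to_dict()
                | {"marker": marker, "t": res.t, "df": res.df, "p": res.p}
            )
    return pd.DataFrame(rows)


def _write_summary_md(outdir: Path, ic50_table, foci_summary) -> None:
    lines = ["# Pipeline report", ""]
    if ic50_table is not None:
        lines += ["## IC50 time course", "", "```", ic50_table.to_string(index=False), "```", ""]
    if foci_summary is not None:
        lines += ["## Foci summaries", "", "```", foci_summary.to_string(index=False), "```", ""]
    (outdir / "summary.md").write_text("\n".join(lines))


def load_run_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
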