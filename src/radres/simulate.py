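"""Study-shaped synthetic data: probe tables, MTT plates and foci datasets.

The generator emulates the design of a 20-week drug-adaptation experiment:
two cell lines grown on five kinase-inhibitor drugs, expression profiled on
custom chips (6020 probes for 3706 gene transcripts) every four weeks with
five naive biological replicates per time point as controls, quadruplicate
MTT dose-response plates over the standard 8-point concentration series, and
immunofluorescence focus counts (200 cells x 3 experiments per condition)
for the gammaH2AX and pATM double-strand-break markers.

Everything is a pure function of (config, seed).  The packaged calibration
file carries the study-scale defaults: drug panel and concentrations, the
measured IC50 time-course used as plate truth, per-condition focus-count
means, and the expression effect scenario in which the DNA-repair pathway is
activated by tyrosine-kinase inhibitors in one cell line only, with an
effect amplitude that decays over the culturing weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dose_response import DoseResponsePlate, four_pl
from .foci import FOCI_COLUMNS
from .pathways import PathwayDefinition, load_pathway

_FIXTURES = resources.files("radres") / "fixtures"

CENSOR_MARK = ">=50"
NOT_DETECTED_MARK = "ND"
NOT_SIGNIFICANT_MARK = "NS"


def load_calibration() -> dict:
    """The packaged study-scale calibration (deep-copied, safe to mutate)."""
    with (_FIXTURES / "calibration.yaml").open() as fh:
        return yaml.safe_load(fh)


def atm_pathway() -> PathwayDefinition:
    """The packaged curated DNA-repair (ATM) pathway fixture."""
    return load_pathway(str(_FIXTURES / "atm_pathway.yaml"))


def fixture_path(name: str) -> str:
    return str(_FIXTURES / name)


@dataclass
class PathwayEffect:
    """Signed expression shift of one pathway's genes for one drug class."""

    cell_line: str
    drug_class: str
    pathway: str
    magnitude: float  # log10 fold change at week 0, before decay
    decay: float  # per-week exponential decay rate of the magnitude
    drug_jitter_sd: float = 0.3  # lognormal sd of the per-(drug, week) multiplier


@dataclass
class SyntheticConfig:
    """Full description of one synthetic study; seed determines all output."""

    seed: int
    cell_lines: list[str]
    drugs: list[str]
    drug_classes: dict[str, list[str]]
    weeks: list[int]
    n_control_reps: int
    n_genes: int
    n_probes: int
    pathways: list[PathwayDefinition]
    pathway_effects: list[PathwayEffect]
    ic50_table: dict[str, dict[str, dict[int, float | str]]]
    foci_means: dict[str, dict[str, dict[str, list[float]]]]
    plate_concentrations: list[float]
    probe_cv: float = 0.10
    od_cv: float = 0.05
    experiment_cv: float = 0.05
    hill: float = 1.2
    viability_floor: float = 2.0
    viability_ceiling: float = 100.0
    censored_true_ic50: float = 120.0
    n_cells: int = 200
    n_experiments: int = 3
    baseline_log10_mean: float = 2.0
    baseline_log10_sd: float = 0.5
    od_control_mean: float = 1.0
    od_blank: float = 0.05
    effect_scale: float = 1.0  # global multiplier on pathway effects (0 = null data)

    def __post_init__(self) -> None:
        if self.n_probes < self.n_genes:
            raise ValueError("n_probes must be >= n_genes")
        if any(e.decay < 0 for e in self.pathway_effects):
            raise ValueError("decay rates must be >= 0")
        known = set(self.gene_ids())
        for eff in self.pathway_effects:
            pw = self._pathway(eff.pathway)
            missing = [g for g in pw.genes if g not in known]
            if missing:
                raise ValueError(
                    f"pathway effect {eff.pathway!r} references genes outside "
                    f"the simulated universe: {missing}"
                )

    @classmethod
    def from_calibration(cls, seed: int, **overrides) -> "SyntheticConfig":
        cal = load_calibration()
        noise = cal["noise"]
        cfg = cls(
            seed=seed,
            cell_lines=list(cal["cell_lines"]),
            drugs=list(cal["drugs"]),
            drug_classes={k: list(v) for k, v in cal["drug_classes"].items()},
            weeks=list(cal["weeks"]),
            n_control_reps=int(cal["n_control_reps"]),
            n_genes=int(cal["n_genes"]),
            n_probes=int(cal["n_probes"]),
            pathways=[atm_pathway()],
            pathway_effects=[PathwayEffect(**e) for e in cal["pathway_effects"]],
            ic50_table=cal["ic50_table_uM"],
            foci_means=cal["foci_means"],
            plate_concentrations=[float(c) for c in cal["plate_concentrations_uM"]],
            probe_cv=float(noise["probe_cv"]),
            od_cv=float(noise["od_cv"]),
            experiment_cv=float(noise["experiment_cv"]),
            hill=float(cal["hill_default"]),
            viability_floor=float(cal["viability_floor"]),
            viability_ceiling=float(cal["viability_ceiling"]),
            censored_true_ic50=float(cal["censored_true_ic50_uM"]),
            n_cells=int(cal["n_cells_per_experiment"]),
            n_experiments=int(cal["n_experiments"]),
        )
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise TypeError(f"unknown config field {key!r}")
            setattr(cfg, key, value)
        cfg.__post_init__()
        return cfg

    # -- helpers ----------------------------------------------------------
    def _pathway(self, pathway_id: str) -> PathwayDefinition:
        for pw in self.pathways:
            if pw.pathway_id == pathway_id:
                return pw
        raise ValueError(f"unknown pathway {pathway_id!r}")

    def drug_class_of(self, drug: str) -> str | None:
        for cls_name, members in self.drug_classes.items():
            if drug in members:
                return cls_name
        return None

    def gene_ids(self) -> list[str]:
        """Gene universe: pathway genes first, then filler transcripts."""
        pathway_genes = sorted({g for pw in self.pathways for g in pw.genes})
        if len(pathway_genes) > self.n_genes:
            raise ValueError("n_genes smaller than the pathway gene count")
        filler = [f"G{i:05d}" for i in range(self.n_genes - len(pathway_genes))]
        return pathway_genes + filler

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


# ---------------------------------------------------------------------------
# Expression


def gen_expression(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a probe signal table and its sample metadata sidecar.

    Per cell line, each week gets ``n_control_reps`` naive replicate samples
    plus one sample per drug.  Gene expression is lognormal around a
    per-gene baseline; drug samples shift pathway-member genes by
    sign(arr) * magnitude * exp(-decay * week) log10 units with a per-drug
    lognormal jitter; every probe carries multiplicative replicate noise.
    """
    rng = cfg._rng(0)
    genes = np.array(cfg.gene_ids())
    n_genes = len(genes)
    baseline = rng.normal(cfg.baseline_log10_mean, cfg.baseline_log10_sd, n_genes)

    # probe layout: first (n_probes - n_genes) genes carry 2 probes, rest 1
    n_extra = cfg.n_probes - n_genes
    probes_per_gene = np.where(np.arange(n_genes) < n_extra, 2, 1)
    gene_of_probe = np.repeat(np.arange(n_genes), probes_per_gene)
    probe_ids = np.array([f"P{i:06d}" for i in range(cfg.n_probes)])

    gene_index = {g: i for i, g in enumerate(genes)}
    samples: list[tuple[str, str, str, int]] = []  # (sample_id, cell_line, drug, week)
    deltas: list[np.ndarray] = []
    sigma_probe = np.sqrt(np.log1p(cfg.probe_cv ** 2))
    for cell_line in cfg.cell_lines:
        for week in cfg.weeks:
            for rep in range(1, cfg.n_control_reps + 1):
                samples.append(
                    (f"{cell_line}_naive_w{week:02d}_r{rep}", cell_line, "naive", week)
                )
                deltas.append(np.zeros(n_genes))
            for drug in cfg.drugs:
                delta = np.zeros(n_genes)
                drug_cls = cfg.drug_class_of(drug)
                for eff in cfg.pathway_effects:
                    # jitter drawn unconditionally to keep the rng stream
                    # aligned across scenario variants of the same seed
                    jitter = rng.lognormal(0.0, eff.drug_jitter_sd)
                    if eff.cell_line != cell_line or eff.drug_class != drug_cls:
                        continue
                    pw = cfg._pathway(eff.pathway)
                    amp = cfg.effect_scale * eff.magnitude * np.exp(-eff.decay * week)
                    for g, arr in pw.nodes.items():
                        if arr != 0:
                            delta[gene_index[g]] += np.sign(arr) * amp * jitter
                samples.append((f"{cell_line}_{drug}_w{week:02d}", cell_line, drug, week))
                deltas.append(delta)

    records = []
    for (sample_id, _, _, _), delta in zip(samples, deltas):
        expr = 10.0 ** (baseline + delta)
        noise = rng.lognormal(0.0, sigma_probe, cfg.n_probes)
        signal = expr[gene_of_probe] * noise
        records.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "gene_id": genes[gene_of_probe],
                    "sample_id": sample_id,
                    "signal": signal,
                }
            )
        )
    table = pd.concat(records, ignore_index=True)
    meta = pd.DataFrame(
        samples, columns=["sample_id", "cell_line", "drug", "week"]
    ).set_index("sample_id", drop=False)
    return table, meta


# ---------------------------------------------------------------------------
# Dose-response plates


def _true_ic50(cfg: SyntheticConfig, entry: float | str) -> float | None:
    if isinstance(entry, str):
        if entry.startswith(">="):
            return cfg.censored_true_ic50
        return None  # ND / NS: no plate measured
    return float(entry)


def gen_plates(cfg: SyntheticConfig) -> list[DoseResponsePlate]:
    """Simulate quadruplicate MTT plates from the IC50 truth profile.

    Censored truth entries (">=50") produce plates whose viability stays
    high through the top tested dose; "ND"/"NS" entries produce no plate.
    """
    rng = cfg._rng(1)
    concs = [c for c in cfg.plate_concentrations if c > 0]
    span = cfg.od_control_mean - cfg.od_blank
    plates = []
    for cell_line in cfg.cell_lines:
        for drug in cfg.drugs:
            week_map = cfg.ic50_table.get(cell_line, {}).get(drug, {})
            for week in sorted(week_map):
                truth = _true_ic50(cfg, week_map[week])
                if truth is None:
                    continue
                viab = four_pl(
                    concs, cfg.viability_floor, cfg.viability_ceiling, truth, cfg.hill
                )
                od_true = cfg.od_blank + span * viab / 100.0
                od = od_true[:, None] + rng.normal(0.0, cfg.od_cv * span, (len(concs), 4))
                od_control = cfg.od_control_mean + rng.normal(0.0, cfg.od_cv * span, 4)
                plates.append(
                    DoseResponsePlate(
                        cell_line=cell_line,
                        drug=drug,
                        week=int(week),
                        concentrations=list(concs),
                        od=od,
                        od_blank=cfg.od_blank,
                        od_control=list(od_control),
                    )
                )
    return plates


def plates_to_frame(plates: list[DoseResponsePlate]) -> pd.DataFrame:
    """Long-format plate table (0 uM rows are the control wells)."""
    rows = []
    for p in plates:
        for rep, od in enumerate(p.od_control, start=1):
            rows.append((p.cell_line, p.drug, p.week, 0.0, rep, od, p.od_blank))
        for conc, well_row in zip(p.concentrations, p.od):
            for rep, od in enumerate(well_row, start=1):
                rows.append((p.cell_line, p.drug, p.week, conc, rep, od, p.od_blank))
    return pd.DataFrame(
        rows,
        columns=["cell_line", "drug", "week", "concentration_uM", "replicate", "od", "od_blank"],
    )


# ---------------------------------------------------------------------------
# Foci


def gen_foci(cfg: SyntheticConfig) -> pd.DataFrame:
    """Simulate per-cell focus counts for every condition.

    Counts are Poisson around the condition mean times a lognormal
    between-experiment multiplier (one multiplier per condition x
    experiment, shared by both markers).  Washout conditions reuse the
    corresponding means: the emulated scenario keeps the adaptation after
    drug removal.
    """
    rng = cfg._rng(2)
    sigma_exp = np.sqrt(np.log1p(cfg.experiment_cv ** 2))
    rows = []
    for cell_line in cfg.cell_lines:
        lineages = cfg.foci_means.get(cell_line, {})
        for lineage in lineages:
            for irradiated in (False, True):
                key = "irr" if irradiated else "spont"
                h2ax_mean, patm_mean = (float(v) for v in lineages[lineage][key])
                for washout in (False, True):
                    for exp_id in range(1, cfg.n_experiments + 1):
                        mult = rng.lognormal(0.0, sigma_exp) if sigma_exp > 0 else 1.0
                        h2ax = rng.poisson(h2ax_mean * mult, cfg.n_cells)
                        patm = rng.poisson(patm_mean * mult, cfg.n_cells)
                        for i in range(cfg.n_cells):
                            rows.append(
                                (cell_line, lineage, irradiated, washout,
                                 exp_id, i + 1, int(h2ax[i]), int(patm[i]))
                            )
    return pd.DataFrame(rows, columns=FOCI_COLUMNS)


# ---------------------------------------------------------------------------
# Bundle writer


def write_simulation(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate and write probes.tsv, meta.tsv, plates.tsv and foci.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, meta = gen_expression(cfg)
    paths = {
        "probes": outdir / "probes.tsv",
        "meta": outdir / "meta.tsv",
        "plates": outdir / "plates.tsv",
        "foci": outdir / "foci.tsv",
    }
    table.to_csv(paths["probes"], sep="\t", index=False, float_format="%.6g")
    meta.reset_index(drop=True).to_csv(paths["meta"], sep="\t", index=False)
    plates_to_frame(gen_plates(cfg)).to_csv(
        paths["plates"], sep="\t", index=False, float_format="%.6g"
    )
    gen_foci(cfg).to_csv(paths["foci"], sep="\t", index=False)
    return paths
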