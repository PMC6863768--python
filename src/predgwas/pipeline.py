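"""End-to-end orchestration: simulate/load -> binarize -> associate -> saturate.

A run is described by one declarative :class:`PipelineConfig` (buildable
from a YAML file) holding either input paths or a simulation recipe, plus
the screen cutoffs, binarization settings, saturation grid, and a seed.
Every stage writes its table under the output directory, so each number in
the final report can be recomputed from persisted intermediates; identical
config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .association import HitSummary, ScreenConfig, compare_category_profiles, run_association
from .binarize import binarize_panel, predatory_breadth
from .containers import UNASSIGNED
from .errors import ConfigError, InsufficientAnnotationError, PredGwasError
from .io import (
    read_annotation_table,
    read_phenotype_table,
    read_roary_presence_absence,
    write_annotation_table,
    write_association_table,
    write_phenotype_table,
    write_roary_presence_absence,
    write_traits_table,
)
from .saturation import (
    fit_power_law,
    predict_required_genomes,
    subsample_gene_counts,
)
from .simulate import (
    PlantedGene,
    SimulationConfig,
    simulate_cog_annotations,
    simulate_pangenome,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one full pipeline run."""

    outdir: str
    seed: int = 0
    # exactly one of (matrix_path & phenotype_path) or simulation
    matrix_path: str | None = None
    phenotype_path: str | None = None
    annotation_path: str | None = None
    simulation: SimulationConfig | None = None
    simulate_annotations: bool = False
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    fraction: float = 1 / 3
    tie_rule: str = "demote"
    saturation_grid: tuple[int, ...] = ()
    saturation_reps: int = 20
    saturation_targets: tuple[float, ...] = (100.0, 10.0)

    def __post_init__(self) -> None:
        has_paths = self.matrix_path is not None or self.phenotype_path is not None
        has_sim = self.simulation is not None
        if has_paths and has_sim:
            raise ConfigError("supply input paths or a simulation recipe, not both")
        if not has_paths and not has_sim:
            raise ConfigError("supply either input paths or a simulation recipe")
        if has_paths and (self.matrix_path is None or self.phenotype_path is None):
            raise ConfigError("both matrix_path and phenotype_path are required")
        if self.simulate_annotations and not has_sim:
            raise ConfigError("simulate_annotations requires a simulation recipe")

    def echo(self) -> dict[str, Any]:
        """JSON/YAML-safe dictionary of the full configuration."""
        sim = None
        if self.simulation is not None:
            sim = asdict(self.simulation)
            sim.pop("accessory_prevalence_sampler", None)
            sim["prey_ids"] = list(sim["prey_ids"])
            sim["baseline_mm"] = dict(sim["baseline_mm"])
            sim["planted_genes"] = [
                {**g, "affected_prey": list(g["affected_prey"])}
                for g in sim["planted_genes"]
            ]
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "matrix_path": self.matrix_path,
            "phenotype_path": self.phenotype_path,
            "annotation_path": self.annotation_path,
            "simulation": sim,
            "simulate_annotations": self.simulate_annotations,
            "screen": asdict(self.screen),
            "fraction": self.fraction,
            "tie_rule": self.tie_rule,
            "saturation_grid": list(self.saturation_grid),
            "saturation_reps": self.saturation_reps,
            "saturation_targets": list(self.saturation_targets),
        }


def simulation_config_from_dict(spec: dict[str, Any], seed: int) -> SimulationConfig:
    """Build a simulation recipe from flat YAML keys.

    Recognized keys (with defaults): ``n_strains`` 29, ``n_core`` 100,
    ``n_accessory`` 600, ``n_prey`` 10, ``baseline_mm`` 20, ``noise_sd_mm``
    1, ``effect_mm`` 10, ``carriage_fraction`` 1/3, ``genes_per_prey`` 1.
    One planted gene (per ``genes_per_prey``) is created per prey, each
    affecting only its own prey.
    """
    known = {
        "n_strains", "n_core", "n_accessory", "n_prey", "baseline_mm",
        "noise_sd_mm", "effect_mm", "carriage_fraction", "genes_per_prey",
    }
    unknown = set(spec) - known
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    n_prey = int(spec.get("n_prey", 10))
    prey_ids = tuple(f"prey_{i + 1:02d}" for i in range(n_prey))
    genes_per_prey = int(spec.get("genes_per_prey", 1))
    planted = []
    for prey in prey_ids:
        for j in range(genes_per_prey):
            suffix = "" if genes_per_prey == 1 else f"_{j + 1}"
            planted.append(
                PlantedGene(
                    cluster_id=f"planted_{prey}{suffix}",
                    carriage_fraction=float(spec.get("carriage_fraction", 1 / 3)),
                    affected_prey=(prey,),
                    effect_mm=float(spec.get("effect_mm", 10.0)),
                )
            )
    baseline = float(spec.get("baseline_mm", 20.0))
    return SimulationConfig(
        n_strains=int(spec.get("n_strains", 29)),
        n_core=int(spec.get("n_core", 100)),
        n_accessory=int(spec.get("n_accessory", 600)),
        prey_ids=prey_ids,
        planted_genes=tuple(planted),
        baseline_mm={p: baseline for p in prey_ids},
        noise_sd_mm=float(spec.get("noise_sd_mm", 1.0)),
        seed=seed,
    )


def load_config(path, seed_override: int | None = None) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    seed = int(raw.get("seed", 0)) if seed_override is None else int(seed_override)
    screen_spec = raw.get("screen", {}) or {}
    screen = ScreenConfig(
        p_cutoff=float(screen_spec.get("p_cutoff", 0.05)),
        sensitivity_cutoff_pct=float(screen_spec.get("sensitivity_cutoff_pct", 70.0)),
        specificity_cutoff_pct=float(screen_spec.get("specificity_cutoff_pct", 80.0)),
    )
    sim = None
    if "simulation" in raw and raw["simulation"] is not None:
        sim = simulation_config_from_dict(dict(raw["simulation"]), seed)
    inputs = raw.get("inputs", {}) or {}
    sat = raw.get("saturation", {}) or {}
    return PipelineConfig(
        outdir=str(raw.get("outdir", "pipeline_out")),
        seed=seed,
        matrix_path=inputs.get("matrix"),
        phenotype_path=inputs.get("phenotypes"),
        annotation_path=inputs.get("annotations"),
        simulation=sim,
        simulate_annotations=bool(raw.get("simulate_annotations", False)),
        screen=screen,
        fraction=float(raw.get("fraction", 1 / 3)),
        tie_rule=str(raw.get("tie_rule", "demote")),
        saturation_grid=tuple(int(g) for g in sat.get("grid", ())),
        saturation_reps=int(sat.get("reps", 20)),
        saturation_targets=tuple(float(t) for t in sat.get("targets", (100.0, 10.0))),
    )


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    per_prey_hit_counts: dict[str, int]
    pairwise_overlap: dict[str, dict[str, int]]
    genes_by_prey_count: dict[int, int]
    total_unique_hits: int
    predatory_breadth: list[dict[str, Any]]
    category_profile: dict[str, float] | None
    saturation: dict[str, Any] | None
    version: str
    seed: int
    config: dict[str, Any]

    def to_json(self) -> str:
        payload = asdict(self)
        payload["genes_by_prey_count"] = {
            str(k): v for k, v in self.genes_by_prey_count.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


class StageError(PredGwasError):
    """An error tagged with the pipeline stage that raised it."""


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except PredGwasError as exc:
        raise StageError(f"[{name}] {exc}") from exc


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages, persisting every intermediate under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump(config.echo(), sort_keys=True)
    )

    # --- stage: inputs -----------------------------------------------------
    annotation: dict[str, str] | None = None
    if config.simulation is not None:
        dataset = _stage("simulate", simulate_pangenome, config.simulation)
        matrix, panel = dataset.matrix, dataset.phenotypes
        write_roary_presence_absence(matrix, outdir / "matrix.csv")
        write_phenotype_table(panel, outdir / "phenotypes.tsv")
        with open(outdir / "truth.tsv", "w") as handle:
            handle.write("cluster_id\taffected_prey\teffect_mm\tcarriage_fraction\n")
            for gene in dataset.truth:
                handle.write(
                    f"{gene.cluster_id}\t{','.join(gene.affected_prey)}\t"
                    f"{gene.effect_mm:.12g}\t{gene.carriage_fraction:.12g}\n"
                )
        if config.simulate_annotations:
            annotation, _ = simulate_cog_annotations(
                matrix.cluster_ids, seed=config.seed + 1
            )
            write_annotation_table(annotation, outdir / "annotations.tsv")
    else:
        matrix = _stage("read-matrix", read_roary_presence_absence, config.matrix_path)
        panel = _stage("read-phenotypes", read_phenotype_table, config.phenotype_path)
        if config.annotation_path is not None:
            annotation = _stage(
                "read-annotations", read_annotation_table, config.annotation_path
            )
    logger.info(
        "inputs: %d clusters x %d strains, %d prey",
        matrix.n_clusters, matrix.n_strains, len(panel.prey_ids),
    )

    # --- stage: binarize ---------------------------------------------------
    labels = _stage("binarize", binarize_panel, panel, config.fraction, config.tie_rule)
    write_traits_table(labels, outdir / "traits.csv")
    breadth = predatory_breadth(labels)
    breadth.to_csv(outdir / "predatory_breadth.csv", index=False)

    # --- stage: associate --------------------------------------------------
    records, summary = _stage("associate", run_association, matrix, labels, config.screen)
    write_association_table(records, outdir / "associations.csv")
    _write_summary_tables(summary, outdir)

    # --- stage: category profile -------------------------------------------
    category_profile = None
    if annotation is not None:
        all_hits = set().union(*summary.per_prey_hits.values()) if summary.per_prey_hits else set()
        hit_categories = {g: annotation.get(g, UNASSIGNED) for g in all_hits}
        background = _background_frequencies(annotation)
        try:
            chi2, p = compare_category_profiles(hit_categories, background)
            category_profile = {"chi_square": chi2, "p_value": p}
        except (InsufficientAnnotationError, PredGwasError) as exc:
            logger.warning("category profile comparison skipped: %s", exc)

    # --- stage: saturate ---------------------------------------------------
    saturation = None
    if config.saturation_grid:
        curve = _stage(
            "saturate",
            subsample_gene_counts,
            matrix,
            panel,
            list(config.saturation_grid),
            config.saturation_reps,
            config.seed + 2,
            config.fraction,
            config.tie_rule,
            config.screen,
        )
        with open(outdir / "saturation_curve.tsv", "w") as handle:
            handle.write("genomes\tmean_hits\treplicate_hits\n")
            for g, mean in zip(curve.genome_counts, curve.mean_hits):
                reps = ",".join(str(c) for c in curve.replicate_hits[g])
                handle.write(f"{g}\t{mean:.12g}\t{reps}\n")
        fit = _stage("saturate", fit_power_law, curve)
        predictions = {
            f"{target:g}": predict_required_genomes(fit, target)
            for target in config.saturation_targets
        } if fit.exponent < 0 else {}
        saturation = {
            "genome_counts": curve.genome_counts,
            "mean_hits": curve.mean_hits,
            "coefficient": fit.coefficient,
            "exponent": fit.exponent,
            "r_squared": fit.r_squared,
            "required_genomes": predictions,
        }
        (outdir / "power_law_fit.json").write_text(
            json.dumps(saturation, indent=2, sort_keys=True) + "\n"
        )

    report = RunReport(
        per_prey_hit_counts={p: len(h) for p, h in summary.per_prey_hits.items()},
        pairwise_overlap={
            p: {q: int(summary.pairwise_overlap.at[p, q]) for q in summary.pairwise_overlap.columns}
            for p in summary.pairwise_overlap.index
        },
        genes_by_prey_count=summary.genes_by_prey_count,
        total_unique_hits=summary.total_unique_hits,
        predatory_breadth=breadth.to_dict(orient="records"),
        category_profile=category_profile,
        saturation=saturation,
        version=__version__,
        seed=config.seed,
        config=config.echo(),
    )
    (outdir / "report.json").write_text(report.to_json())
    (outdir / "report.txt").write_text(_human_summary(report))
    return report


def _background_frequencies(annotation: dict[str, str]) -> dict[str, float]:
    """COG-letter proportions across all annotated clusters (the parent-genome profile)."""
    counts: dict[str, int] = {}
    for cats in annotation.values():
        if cats == UNASSIGNED:
            continue
        for letter in cats:
            counts[letter] = counts.get(letter, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise InsufficientAnnotationError("no annotated clusters in the background")
    return {letter: n / total for letter, n in counts.items()}


def _write_summary_tables(summary: HitSummary, outdir: Path) -> None:
    with open(outdir / "per_prey_hits.tsv", "w") as handle:
        handle.write("prey\tn_hits\thits\n")
        for prey in summary.per_prey_hits:
            hits = sorted(summary.per_prey_hits[prey])
            handle.write(f"{prey}\t{len(hits)}\t{','.join(hits)}\n")
    summary.pairwise_overlap.to_csv(outdir / "overlap.tsv", sep="\t")
    with open(outdir / "genes_by_prey_count.tsv", "w") as handle:
        handle.write("n_prey\tn_genes\n")
        for k, v in summary.genes_by_prey_count.items():
            handle.write(f"{k}\t{v}\n")


def _human_summary(report: RunReport) -> str:
    lines = [
        f"predgwas v{report.version} (seed {report.seed})",
        "",
        "Hits per prey:",
    ]
    for prey, n in report.per_prey_hit_counts.items():
        lines.append(f"  {prey}: {n}")
    lines.append(f"Total unique screen-passing genes: {report.total_unique_hits}")
    lines.append("Genes by number of prey hit:")
    for k, v in report.genes_by_prey_count.items():
        lines.append(f"  {k} prey: {v} genes")
    if report.predatory_breadth:
        top = report.predatory_breadth[0]
        lines.append(
            f"Broadest predator: {top['strain_id']} "
            f"({top['n_superior']}/{top['n_prey']} prey)"
        )
    if report.category_profile is not None:
        lines.append(
            "COG profile vs background: chi2 = "
            f"{report.category_profile['chi_square']:.3f}, "
            f"p = {report.category_profile['p_value']:.4f}"
        )
    if report.saturation is not None:
        lines.append(
            "Saturation power law: hits(G) = "
            f"{report.saturation['coefficient']:.1f} * G^{report.saturation['exponent']:.3f}"
            f" (R^2 = {report.saturation['r_squared']:.3f})"
        )
        for target, g in report.saturation["required_genomes"].items():
            lines.append(f"  <= {target} candidates requires {g} genomes")
    return "\n".join(lines) + "\n"
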