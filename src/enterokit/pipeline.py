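"""Config-driven end-to-end analysis: preprocess → frequency classes →
alpha diversity → beta distances → ordination + permutation tests →
enterotyping → phenotype associations.

The YAML config (:class:`PipelineConfig`, unknown keys rejected) either
points at a count table / metadata / optional newick tree on disk, or asks
for a synthetic cohort. One master seed deterministically spawns an
independent child seed per stage, so adding or re-ordering stages never
perturbs earlier stages' randomness. The run writes per-stage TSV
artifacts and a JSON report validated against a pydantic schema.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import alpha as alpha_mod
from . import association as assoc_mod
from . import distance as dist_mod
from . import enterotype as ent_mod
from . import io as io_mod
from . import ordination as ord_mod
from . import preprocess as prep_mod
from . import synth as synth_mod

logger = logging.getLogger(__name__)

_STAGES = (
    "synth", "rarefy", "tree", "nmds", "permanova", "anosim", "contingency",
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticInput(_Strict):
    n_samples: int = 483
    n_taxa: int = 171
    concentration_scale: float = 50.0
    effects: Literal["default", "none"] = "default"
    spec_yaml: Optional[str] = None  # full CohortSpec YAML overrides the above
    with_tree: bool = True


class FileInput(_Strict):
    table: str
    metadata: str
    tree: Optional[str] = None
    orientation: Literal["samples_as_rows", "taxa_as_rows"] = "samples_as_rows"


class FilterParams(_Strict):
    min_total: float = 5
    min_samples: int = 2
    min_rel_abund: float = 0.001


class EnterotypeParams(_Strict):
    top_n: int = 35
    k_min: int = 2
    k_max: int = 9
    pseudocount: float = 1e-6


class OrdinationParams(_Strict):
    metric: str = "jsd"
    n_starts: int = 4
    n_permutations: int = 999


class PipelineConfig(_Strict):
    """Everything a run needs; serialisable to/from YAML."""

    input: Optional[FileInput] = None
    synthetic: Optional[SyntheticInput] = None
    rarefaction_depth: int = 2000
    filter: FilterParams = FilterParams()
    distance_metrics: list[str] = ["jsd", "braycurtis", "jaccard"]
    enterotype: EnterotypeParams = EnterotypeParams()
    ordination: OrdinationParams = OrdinationParams()
    phenotypes: list[str] = []
    association_method: Literal["ttest", "kw"] = "ttest"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


class PhenotypeReport(_Strict):
    alpha_tests: dict[str, dict[str, float]]
    beta_tests: dict[str, dict[str, float]]
    contingency: dict[str, float]
    n_association_tests: int
    n_significant_q05: int


class EnterotypeReport(_Strict):
    best_k: int
    silhouette: float
    cluster_sizes: dict[str, int]
    driver_taxa: dict[str, dict[str, Any]]
    medoid_ids: list[str]
    ch_curve: dict[str, float]
    weak_structure: bool


class Report(_Strict):
    """Schema of the machine-readable run report."""

    seed: int
    n_samples_input: int
    n_samples_retained: int
    dropped_samples: list[str]
    n_taxa_input: int
    n_taxa_retained: int
    frequency_classes: dict[str, int]
    nmds_stress: float
    enterotype: EnterotypeReport
    phenotypes: dict[str, PhenotypeReport]


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _load_inputs(config: PipelineConfig, seeds: dict[str, int]):
    if (config.input is None) == (config.synthetic is None):
        raise ValueError("config must set exactly one of 'input' and 'synthetic'")
    if config.input is not None:
        table = io_mod.read_abundance_tsv(config.input.table, config.input.orientation)
        meta = io_mod.read_metadata_tsv(config.input.metadata)
        table, meta = io_mod.align_samples(table, meta)
        tree = io_mod.read_newick(config.input.tree) if config.input.tree else None
        return table, meta, tree
    syn = config.synthetic
    if syn.spec_yaml:
        spec = synth_mod.CohortSpec.from_yaml(syn.spec_yaml)
    else:
        spec = synth_mod.default_cohort_spec(
            n_samples=syn.n_samples,
            n_taxa=syn.n_taxa,
            concentration_scale=syn.concentration_scale,
            seed=seeds["synth"],
        )
    effects = synth_mod.default_planted_effects() if syn.effects == "default" else []
    table, meta, _ = synth_mod.generate_cohort(spec, effects)
    tree = synth_mod.generate_tree(spec.taxon_names, seed=seeds["tree"]) if syn.with_tree else None
    return table, meta, tree


def run_pipeline(config: PipelineConfig, outdir, force: bool = False) -> dict:
    """Execute every stage, write artifacts + ``report.json``, return the report."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s ...", name)

            def __exit__(self_, *exc):
                dt = time.perf_counter() - self_.t0
                timings[name] = dt
                logger.info("stage %s done in %.2fs", name, dt)

        return _T()

    with timed("load"):
        table, meta, tree = _load_inputs(config, seeds)
    n_input = table.shape[0]

    for phen in config.phenotypes:
        if phen not in meta.columns:
            raise KeyError(f"phenotype column {phen!r} missing from metadata")

    with timed("preprocess"):
        rarefied, dropped = prep_mod.rarefy(
            table, depth=config.rarefaction_depth, seed=seeds["rarefy"]
        )
        filtered = prep_mod.filter_rare_features(
            rarefied,
            min_total=config.filter.min_total,
            min_samples=config.filter.min_samples,
            min_rel_abund=config.filter.min_rel_abund,
        )
        rel = prep_mod.to_relative(filtered)
        meta = meta.loc[filtered.index]
        io_mod.write_abundance_tsv(filtered, outdir / "filtered_counts.tsv")
        rel.to_csv(outdir / "relative_abundance.tsv", sep="\t", index_label="sample_id")

    with timed("frequency_classes"):
        freq = prep_mod.classify_detection_rate(filtered)
        freq.table.to_csv(outdir / "frequency_classes.tsv", sep="\t")

    with timed("alpha"):
        alpha = alpha_mod.alpha_diversity(filtered)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")

    with timed("distances"):
        matrices: dict[str, Any] = {}
        for metric in config.distance_metrics:
            needs_tree = metric.startswith("unifrac")
            if needs_tree and tree is None:
                raise ValueError(f"metric {metric!r} requires a tree input")
            dm = dist_mod.pairwise(rel, metric, tree=tree)
            matrices[metric] = dm
            io_mod.write_distance_tsv(dm, outdir / f"distance_{metric}.tsv")

    with timed("ordination"):
        ord_metric = config.ordination.metric
        if ord_metric not in matrices:
            matrices[ord_metric] = dist_mod.pairwise(rel, ord_metric, tree=tree)
        ordn = ord_mod.nmds(
            matrices[ord_metric],
            n_starts=config.ordination.n_starts,
            seed=seeds["nmds"],
        )
        ordn.coordinates.to_csv(outdir / "nmds.tsv", sep="\t", index_label="sample_id")

    with timed("enterotype"):
        result = ent_mod.enterotype_pipeline(
            rel,
            k_min=config.enterotype.k_min,
            k_max=config.enterotype.k_max,
            top_n=config.enterotype.top_n,
            pseudocount=config.enterotype.pseudocount,
        )
        result.labels.to_csv(outdir / "enterotype_labels.tsv", sep="\t")
        result.ch_curve.to_frame().to_csv(outdir / "ch_curve.tsv", sep="\t")

    with timed("association"):
        assoc_input = assoc_mod.prevalence_abundance_filter(rel)
        phen_reports: dict[str, dict] = {}
        for i, phen in enumerate(config.phenotypes):
            atests = alpha_mod.compare_alpha(alpha, meta, phen)
            beta_tests = {}
            for metric, dm in matrices.items():
                groups = meta.loc[list(dm.ids), phen]
                ok = groups.notna()
                dsub = dm.filter([i for i, keep in zip(dm.ids, ok) if keep])
                perm = ord_mod.permanova(
                    dsub, groups[ok].to_numpy(),
                    n_permutations=config.ordination.n_permutations,
                    seed=seeds["permanova"] + i,
                )
                ano = ord_mod.anosim(
                    dsub, groups[ok].to_numpy(),
                    n_permutations=config.ordination.n_permutations,
                    seed=seeds["anosim"] + i,
                )
                beta_tests[metric] = {
                    "pseudo_F": perm.statistic, "permanova_p": perm.p_value,
                    "anosim_R": ano.statistic, "anosim_p": ano.p_value,
                }
            chi2, chi_p = assoc_mod.enterotype_phenotype_independence(
                result.labels, meta, phen, seed=seeds["contingency"] + i
            )
            tests = assoc_mod.group_tests(
                assoc_input, meta, phen, method=config.association_method
            )
            tests.to_csv(outdir / f"association_{phen}.tsv", sep="\t", index=False)
            phen_reports[phen] = {
                "alpha_tests": {
                    m: {"H": float(r["H"]), "p_value": float(r["p_value"])}
                    for m, r in atests.iterrows()
                },
                "beta_tests": beta_tests,
                "contingency": {"chi2": chi2, "p_value": chi_p},
                "n_association_tests": int(len(tests)),
                "n_significant_q05": int((tests["q_value"] < 0.05).sum()),
            }

    report = Report(
        seed=config.seed,
        n_samples_input=n_input,
        n_samples_retained=int(filtered.shape[0]),
        dropped_samples=list(dropped),
        n_taxa_input=int(table.shape[1]),
        n_taxa_retained=int(filtered.shape[1]),
        frequency_classes=freq.class_counts,
        nmds_stress=float(ordn.stress),
        enterotype=result.summary(),
        phenotypes=phen_reports,
    )
    payload = report.model_dump()
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload


__all__ = ["PipelineConfig", "Report", "run_pipeline"]
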