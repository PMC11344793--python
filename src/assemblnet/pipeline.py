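"""End-to-end orchestration: filter -> null fit -> calibrate -> cluster ->
combine -> metrics -> redundancy -> classify -> auxotrophy.

A :class:`RunConfig` collects the input paths and the method's thresholds
(margin filters 5/5, minimum co-occurrence 5, target FPR 1e-4, 1000 null
matrices, 100 runs, consensus support 10, terminal-edge support 70, phylo
tolerances 0.05/0.1, genome-size tolerance 20%, size-class threshold 5).
``run_pipeline`` executes the stages in order, persists every stage's
outputs as TSV/JSON/GraphML in the output directory, and writes a manifest
recording the effective configuration, the per-stage seeds and the SHA-256
of every artifact, so a rerun with the same config and seed is verifiable as
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblage_metrics, clustering, io_model, pathways, redundancy
from .errors import AssemblnetError, UnannotatableAssemblage
from .model import AssemblyNetworkModel

log = logging.getLogger("assemblnet")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    occurrence: str
    annotations: str
    genome_pathways: str | None = None
    species_distances: str | None = None
    species_to_genus: str | None = None
    genus_distances: str | None = None
    cost_table: str | None = None
    pathway_amino_acids: str | None = None
    out_dir: str = "assemblnet_run"
    seed: int = 0
    min_genera_per_sample: int = 5
    min_samples_per_genus: int = 5
    min_cooccurrence: int = 5
    target_fpr: float = 1e-4
    n_null: int = 1000
    n_runs: int = 100
    min_support: int = 10
    consensus_support: int = 70
    phylo_tolerance: float = 0.05
    classify_phylo_tolerance: float = 0.1
    size_rel_tolerance: float = 0.2
    size_threshold: int = 5
    n_random_classify: int = 1000
    alpha: float = 0.05
    exclude_amino_acids: tuple[str, ...] = ("Trp",)

    def __post_init__(self) -> None:
        for name in (
            "min_genera_per_sample", "min_samples_per_genus", "min_cooccurrence",
            "target_fpr", "n_null", "n_runs", "min_support", "consensus_support",
            "phylo_tolerance", "classify_phylo_tolerance", "size_rel_tolerance",
            "size_threshold",
        ):
            if not getattr(self, name) > 0:
                raise AssemblnetError(f"config threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "exclude_amino_acids" in data:
            data["exclude_amino_acids"] = tuple(data["exclude_amino_acids"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def dominant_subtype(
    table: io_model.OccurrenceTable,
    annotations: list[io_model.SampleAnnotation],
    taxa: frozenset[str],
) -> str | None:
    """The environment subtype where an assemblage's members most often
    co-occur (falling back to where any member occurs)."""
    sub_of = {a.sample_id: a.env_subtype for a in annotations}
    rows = [table.genus_index(g) for g in taxa if g in table.genus_ids]
    if len(rows) != len(taxa):
        return None
    joint = table.X[rows].min(axis=0)
    cols = np.flatnonzero(joint)
    if cols.size == 0:
        cols = np.flatnonzero(table.X[rows].max(axis=0))
    counts: dict[str, int] = {}
    for a in cols:
        sub = sub_of.get(table.sample_ids[a])
        if sub:
            counts[sub] = counts.get(sub, 0) + 1
    if not counts:
        return None
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def genus_subtype_pool(
    table: io_model.OccurrenceTable, annotations: list[io_model.SampleAnnotation]
) -> dict[str, set[str]]:
    """Each genus mapped to every subtype in which it was observed."""
    sub_of = {a.sample_id: a.env_subtype for a in annotations}
    pool: dict[str, set[str]] = {}
    for g, row in zip(table.genus_ids, table.X):
        pool[g] = {
            sub_of[table.sample_ids[a]]
            for a in np.flatnonzero(row)
            if table.sample_ids[a] in sub_of
        }
    return pool


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
    }
    stage = "setup"
    try:
        # ---- network inference ------------------------------------------
        stage = "filter+fit+cluster"
        log.info("stage %s", stage)
        model = AssemblyNetworkModel.from_tsv(
            config.occurrence,
            config.annotations,
            min_genera_per_sample=config.min_genera_per_sample,
            min_samples_per_genus=config.min_samples_per_genus,
            n_null=config.n_null,
            target_fpr=config.target_fpr,
            n_runs=config.n_runs,
            min_support=config.min_support,
            min_cooccurrence=config.min_cooccurrence,
        )
        res = model.fit(seed=config.seed)
        manifest["stages"].append(stage)
        io_model.write_occurrence_table(model.table, out / "filtered_occurrence.tsv")
        for env, calib in res.calibrations.items():
            calib.save(out / f"calibration_{env}.json")
        res.network.write_graphml(out / "network.graphml")
        res.network.write_tsv(out / "network_nodes.tsv", out / "network_edges.tsv")
        (out / "summary.txt").write_text(res.summary() + "\n", encoding="utf-8")

        profiles = distances = None
        if config.genome_pathways:
            stage = "metrics"
            log.info("stage %s", stage)
            genomes = io_model.read_genome_pathways(config.genome_pathways)
            profiles = io_model.genus_profiles(genomes)
            if config.genus_distances:
                distances = io_model.read_distance_matrix(config.genus_distances)
            elif config.species_distances and config.species_to_genus:
                smat = io_model.read_distance_matrix(config.species_distances)
                s2g = dict(
                    pd.read_csv(config.species_to_genus, sep="\t", dtype=str)
                    .iloc[:, :2]
                    .itertuples(index=False, name=None)
                )
                distances = io_model.genus_distances(smat, s2g)
            summaries = {}
            for taxa in res.assemblages():
                try:
                    summaries[taxa] = assemblage_metrics.summarize_assemblage(
                        taxa, profiles, distances
                    )
                except UnannotatableAssemblage as exc:
                    log.info("skipping assemblage: %s", exc)
            assemblage_metrics.summaries_to_frame(summaries.values()).to_csv(
                out / "assemblage_summaries.tsv", sep="\t", index=False
            )
            manifest["stages"].append(stage)

            stage = "redundancy"
            log.info("stage %s", stage)
            pool = genus_subtype_pool(model.table, model.annotations)
            subs = {
                taxa: dominant_subtype(model.table, model.annotations, taxa)
                for taxa in summaries
            }
            groups: dict[str, list] = {"real_single_env": [], "real_multi_env": []}
            for taxa, s in summaries.items():
                key = (
                    "real_multi_env"
                    if res.network.multi_environment(taxa)
                    else "real_single_env"
                )
                groups[key].append(s)
            rseed = np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % 2**31
            for kind in redundancy._KINDS:
                constraint = redundancy.RandomAssemblageConstraint(
                    kind,
                    phylo_tolerance=config.phylo_tolerance,
                    size_rel_tolerance=config.size_rel_tolerance,
                )
                groups[kind] = redundancy.random_summaries(
                    [(s, subs[t]) for t, s in summaries.items() if subs[t]],
                    constraint,
                    pool,
                    profiles,
                    distances,
                    seed=int(rseed),
                )
            report = redundancy.redundancy_report(groups, alpha=config.alpha)
            report.to_csv(out / "redundancy_report.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)

            stage = "classify"
            log.info("stage %s", stage)
            terminals = clustering.consensus_terminals(
                res.network, config.consensus_support
            )
            term_subs = {
                t: dominant_subtype(model.table, model.annotations, t)
                for t in terminals
            }
            cseed = np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % 2**31
            classifications = pathways.classify_network(
                {t: s for t, s in term_subs.items() if s},
                profiles,
                distances,
                pool,
                n_random=config.n_random_classify,
                phylo_tolerance=config.classify_phylo_tolerance,
                seed=int(cseed),
            )
            pathways.classifications_to_frame(classifications).to_csv(
                out / "pathway_classifications.tsv", sep="\t", index=False
            )
            pathways.size_class_comparison(
                classifications, config.size_threshold
            ).to_csv(out / "size_class_comparison.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)

            if config.pathway_amino_acids and config.cost_table:
                stage = "auxotrophy"
                log.info("stage %s", stage)
                p2a = dict(
                    pd.read_csv(config.pathway_amino_acids, sep="\t", dtype=str)
                    .iloc[:, :2]
                    .itertuples(index=False, name=None)
                )
                costs = io_model.read_cost_table(config.cost_table)
                records = pathways.auxotrophy_records(
                    classifications, p2a, costs, min_size=config.size_threshold
                )
                rows = []
                if len(records) >= 3:
                    for label, excl in (
                        ("all", ()),
                        ("excluding_" + "_".join(config.exclude_amino_acids),
                         config.exclude_amino_acids),
                    ):
                        try:
                            fit = pathways.cost_regression(records, exclude=excl)
                            rows.append(
                                dict(model=label, slope=fit.slope,
                                     intercept=fit.intercept, r_squared=fit.r_squared,
                                     p_value=fit.p_value, n=fit.n)
                            )
                        except AssemblnetError as exc:
                            log.info("regression %s skipped: %s", label, exc)
                pd.DataFrame(
                    [(r.amino_acid, r.mean_auxotroph_fraction, r.cost) for r in records],
                    columns=["amino_acid", "mean_auxotroph_fraction", "cost"],
                ).to_csv(out / "auxotrophy_records.tsv", sep="\t", index=False)
                pd.DataFrame(rows).to_csv(
                    out / "auxotrophy_regression.tsv", sep="\t", index=False
                )
                manifest["stages"].append(stage)
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name not in ("manifest.json", "run.log"):
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
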