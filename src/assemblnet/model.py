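"""Model/Results front end for the network-inference pipeline.

:class:`AssemblyNetworkModel` is constructed from an occurrence table and its
sample annotations; :meth:`AssemblyNetworkModel.fit` runs the per-environment
null-model fits, score calibrations and stochastic clustering ensembles, and
returns an :class:`AssemblyNetworkResults` carrying the consensus network,
the per-environment calibrations and diagnostics, with a ``summary()`` table
in the style of statistical modelling packages.

Example
-------
>>> from assemblnet import synthetic
>>> from assemblnet.model import AssemblyNetworkModel
>>> table, ann = synthetic.generate_null_occurrences(40, 120, seed=7)
>>> res = AssemblyNetworkModel(table, ann, n_null=50, n_runs=20).fit(seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import clustering, null_model
from .errors import InvariantError
from .io_model import (
    OccurrenceTable,
    SampleAnnotation,
    filter_occurrence_table,
    read_occurrence_table,
)

__all__ = ["AssemblyNetworkModel", "AssemblyNetworkResults"]


class AssemblyNetworkModel:
    """Agglomerative co-occurrence network model for binary occurrence data.

    Parameters
    ----------
    table
        Binary genus x sample occurrence table (will be margin-filtered).
    annotations
        Environmental annotations; samples without one are dropped with a
        warning.
    min_genera_per_sample, min_samples_per_genus
        Margin filters applied to the input (both default to 5).
    n_null
        Fixed-margin null matrices per environment for score calibration.
    target_fpr
        Null false-positive-rate target for the significance cutoff.
    n_runs
        Independent clustering runs per environment.
    min_support
        Consensus support below which nodes and edges are discarded.
    min_cooccurrence
        Pairs must co-occur in strictly more samples than this to merge.
    """

    def __init__(
        self,
        table: OccurrenceTable,
        annotations: Iterable[SampleAnnotation],
        min_genera_per_sample: int = 5,
        min_samples_per_genus: int = 5,
        n_null: int = 1000,
        target_fpr: float = 1e-4,
        n_runs: int = 100,
        min_support: int = 10,
        min_cooccurrence: int = 5,
    ) -> None:
        annotations = list(annotations)
        annotated = {a.sample_id for a in annotations}
        missing = [s for s in table.sample_ids if s not in annotated]
        if missing:
            warnings.warn(
                f"dropping {len(missing)} unannotated samples", stacklevel=2
            )
            table = table.subset_samples([s for s in table.sample_ids if s in annotated])
        self.table = filter_occurrence_table(
            table, min_genera_per_sample, min_samples_per_genus
        )
        keep = set(self.table.sample_ids)
        self.annotations = [a for a in annotations if a.sample_id in keep]
        self.n_null = n_null
        self.target_fpr = target_fpr
        self.n_runs = n_runs
        self.min_support = min_support
        self.min_cooccurrence = min_cooccurrence

    @classmethod
    def from_tsv(cls, occurrence_path, annotation_path, **kwargs) -> "AssemblyNetworkModel":
        table, ann = read_occurrence_table(occurrence_path, annotation_path)
        return cls(table, ann, **kwargs)

    def environments(self) -> dict[str, list[str]]:
        """Samples grouped by environment type."""
        out: dict[str, list[str]] = {}
        for a in self.annotations:
            out.setdefault(a.env_type, []).append(a.sample_id)
        return out

    def fit(self, seed: int = 0) -> "AssemblyNetworkResults":
        """Run the full inference: per-environment null fit, calibration,
        clustering ensemble, and cross-environment consensus."""
        root = np.random.SeedSequence(seed)
        env_tables: dict[str, OccurrenceTable] = {}
        env_pi: dict[str, null_model.ProbabilityMatrix] = {}
        env_calib: dict[str, null_model.ScoreCalibration] = {}
        runs: dict[str, list[clustering.AssemblyNetwork]] = {}
        for env, samples in sorted(self.environments().items()):
            ens_seed, run_seed = root.spawn(2)
            sub = self.table.subset_samples(samples)
            # genera never seen in this environment contribute nothing here
            present = [g for g, row in zip(sub.genus_ids, sub.X) if row.any()]
            if len(present) < 2 or len(samples) < 2:
                continue
            sub = sub.subset_genera(present)
            pi = null_model.fit_environment_probabilities(sub, self.annotations)
            ensemble = null_model.sample_null_matrices(
                sub, n=self.n_null, seed=np.random.default_rng(ens_seed)
            )
            calib = null_model.calibrate_scores(
                sub, pi, ensemble, target_fpr=self.target_fpr
            )
            env_tables[env] = sub
            env_pi[env] = pi
            env_calib[env] = calib
            runs[env] = clustering.run_ensemble(
                sub,
                pi,
                calib,
                n_runs=self.n_runs,
                base_seed=int(run_seed.generate_state(1)[0] % (2**31)),
                min_cooccurrence=self.min_cooccurrence,
                environment=env,
            )
        network = clustering.combine_runs(runs, min_support=self.min_support)
        return AssemblyNetworkResults(
            model=self,
            seed=seed,
            network=network,
            calibrations=env_calib,
            probabilities=env_pi,
            env_tables=env_tables,
        )


@dataclass
class AssemblyNetworkResults:
    """Fitted consensus network and per-environment diagnostics."""

    model: AssemblyNetworkModel
    seed: int
    network: clustering.CombinedNetwork
    calibrations: Mapping[str, null_model.ScoreCalibration]
    probabilities: Mapping[str, null_model.ProbabilityMatrix]
    env_tables: Mapping[str, OccurrenceTable]

    def assemblages(self) -> list[frozenset[str]]:
        return self.network.assemblages()

    def terminals(self, min_edge_support: int = 70) -> set[frozenset[str]]:
        return clustering.consensus_terminals(self.network, min_edge_support)

    def genera(self) -> set[str]:
        return set().union(*self.network.node_support) if self.network.node_support else set()

    def size_distribution(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for k in self.network.node_support:
            out[len(k)] = out.get(len(k), 0) + 1
        return dict(sorted(out.items()))

    def summary(self) -> str:
        n_nodes = len(self.network.node_support)
        n_edges = len(self.network.edge_support)
        n_ass = len(self.assemblages())
        multi = sum(self.network.multi_environment(k) for k in self.network.node_support)
        lines = [
            "      Agglomerative co-occurrence network",
            "=" * 52,
            f"genera (input, filtered)   {len(self.model.table.genus_ids):>10d}",
            f"samples (filtered)         {len(self.model.table.sample_ids):>10d}",
            f"environments               {len(self.env_tables):>10d}",
            f"runs per environment       {self.model.n_runs:>10d}",
            f"null matrices / target FPR {self.model.n_null:>6d} / {self.model.target_fpr:g}",
            "-" * 52,
            f"nodes (support >= {self.model.min_support:<3d})     {n_nodes:>10d}",
            f"edges (support >= {self.model.min_support:<3d})     {n_edges:>10d}",
            f"assemblages (size >= 2)    {n_ass:>10d}",
            f"multi-environment nodes    {multi:>10d}",
            "-" * 52,
            "assemblage size distribution:",
        ]
        for size, cnt in self.size_distribution().items():
            lines.append(f"    size {size:>2d}  {cnt:>6d}")
        lines.append("-" * 52)
        for env, calib in sorted(self.calibrations.items()):
            lines.append(
                f"    {env}: z cutoff {calib.z_cutoff:.3f} "
                f"({calib.n_null_scores} null scores)"
            )
        return "\n".join(lines)
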