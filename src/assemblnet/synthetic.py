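"""Seeded synthetic-data generators with known ground truth.

These emulate the statistical structure of cross-study occurrence databases:
sparse binary genus x sample matrices with heavy-tailed genus occupancies and
per-sample richness effects, a nested environment hierarchy, optionally
planted (and conditionally planted) co-occurring taxon sets, genus core
genomes with planted redundant/specific/missing pathway structure, and
species-level phylogenetic distances.  Every generator is bit-reproducible
under a fixed seed and emits the ground truth needed to score recovery.

They do **not** emulate abundance information, study-level batch effects, or
16S read-level noise; see the methods note for what passing tests do and do
not show about real data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvariantError
from .io_model import (
    DistanceMatrix,
    GenomePathwayTable,
    OccurrenceTable,
    SampleAnnotation,
)

__all__ = [
    "PlantSpec",
    "generate_null_occurrences",
    "plant_assemblages",
    "generate_pathway_universe",
    "generate_phylo_distances",
]


@dataclass
class PlantSpec:
    """A set of taxa planted to co-occur excessively in one subtype.

    ``co_occurrence_boost`` multiplies the independent-expectation joint
    occurrence probability.  ``conditional_partner_map`` plants the same
    focal taxon with different partners in different subtypes, e.g.
    ``{"A": {"sub1": {"B"}, "sub2": {"C"}}}``.
    """

    taxa: frozenset[str] = frozenset()
    env_subtype: str = ""
    co_occurrence_boost: float = 1.0
    conditional_partner_map: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.co_occurrence_boost < 1:
            raise InvariantError("co_occurrence_boost must be >= 1")
        self.taxa = frozenset(self.taxa)

    def joint_plants(self) -> list[tuple[frozenset[str], str]]:
        """Expand into (taxa set, subtype) joint-plant instructions."""
        out = []
        if self.taxa and self.env_subtype:
            out.append((self.taxa, self.env_subtype))
        for focal, by_sub in self.conditional_partner_map.items():
            for sub, partners in by_sub.items():
                out.append((frozenset({focal}) | frozenset(partners), sub))
        return out


def _default_layout(n_samples: int) -> dict[str, dict[str, int]]:
    return {"env1": {"sub1": n_samples}}


def generate_null_occurrences(
    n_genera: int,
    n_samples: int = 300,
    occupancy_shape: tuple[float, float] = (0.7, 4.0),
    richness_shape: tuple[float, float] = (5.0, 5.0),
    env_layout: Mapping[str, Mapping[str, int]] | None = None,
    seed: int = 0,
    return_targets: bool = False,
):
    """Interaction-free occurrence matrix from a margin-product model.

    Genus occupancy propensities are Beta(*occupancy_shape*) (heavy-tailed by
    default: most genera rare, a few cosmopolitan); each sample gets a
    Beta(*richness_shape*) richness effect normalized to mean 1.  Cells are
    independent Bernoulli with probability ``clip(u_i * v_a, 0, 1)``, so by
    construction no pair of genera co-occurs more than their margins imply.
    """
    if n_genera < 1 or n_samples < 1:
        raise InvariantError("counts must be >= 1")
    if min(occupancy_shape) <= 0 or min(richness_shape) <= 0:
        raise InvariantError("Beta shape parameters must be > 0")
    rng = np.random.default_rng(seed)
    layout = env_layout if env_layout is not None else _default_layout(n_samples)
    annotations: list[SampleAnnotation] = []
    for env, subs in layout.items():
        for sub, count in subs.items():
            for _ in range(count):
                sid = f"s{len(annotations):05d}"
                annotations.append(SampleAnnotation(sid, env, sub))
    M = len(annotations)
    u = rng.beta(*occupancy_shape, size=n_genera)
    v = rng.beta(*richness_shape, size=M)
    v = v / v.mean()
    p = np.clip(u[:, None] * v[None, :], 0.0, 1.0)
    X = (rng.random((n_genera, M)) < p).astype(np.uint8)
    genera = [f"g{i:04d}" for i in range(n_genera)]
    table = OccurrenceTable(genera, [a.sample_id for a in annotations], X)
    if return_targets:
        return table, annotations, (u, v)
    return table, annotations


def plant_assemblages(
    base: OccurrenceTable,
    annotations: Iterable[SampleAnnotation],
    plants: Sequence[PlantSpec],
    seed: int = 0,
) -> tuple[OccurrenceTable, list[dict]]:
    """Re-draw member presences so planted taxa co-occur excessively.

    Within each plant's subtype samples, all members are jointly forced
    present with extra probability ``q = clip((boost - 1) * prod(member
    marginal frequencies), 0, 1)``, so ``boost = 1`` leaves the table
    untouched.  Margins are approximately preserved by removing, for each
    member, as many of its presences from un-forced samples as were added.
    Returns the new table and a ground-truth record per joint plant.
    """
    rng = np.random.default_rng(seed)
    ann = list(annotations)
    sub_samples: dict[str, np.ndarray] = {}
    col = {s: a for a, s in enumerate(base.sample_ids)}
    for a in ann:
        sub_samples.setdefault(a.env_subtype, []).append(col[a.sample_id])
    sub_samples = {k: np.asarray(v) for k, v in sub_samples.items()}
    X = base.X.copy()
    gidx = {g: i for i, g in enumerate(base.genus_ids)}
    truth: list[dict] = []
    forced_cols: set[int] = set()
    for spec in plants:
        for taxa, subtype in spec.joint_plants():
            missing = sorted(set(taxa) - set(gidx))
            if missing:
                raise InvariantError(f"plant taxa absent from table: {missing}")
            if subtype not in sub_samples:
                raise InvariantError(f"unknown env_subtype {subtype!r}")
            cols = sub_samples[subtype]
            rows = [gidx[g] for g in sorted(taxa)]
            freqs = base.X[rows][:, cols].mean(axis=1)
            baseline = float(np.prod(freqs))
            q = (spec.co_occurrence_boost - 1.0) * baseline
            if q > 1.0:
                warnings.warn(
                    f"boost {spec.co_occurrence_boost} not realizable for "
                    f"{sorted(taxa)} (achieved joint rate ~1.0)",
                    stacklevel=2,
                )
            q = min(q, 1.0)
            if baseline == 0.0 and spec.co_occurrence_boost > 1:
                warnings.warn(
                    f"plant {sorted(taxa)} has zero baseline joint frequency in "
                    f"{subtype}; boost has no effect",
                    stacklevel=2,
                )
            force = cols[rng.random(cols.size) < q]
            forced_cols.update(force.tolist())
            for r in rows:
                added = int((X[r, force] == 0).sum())
                X[r, force] = 1
                if added:  # best-effort margin compensation
                    removable = np.array(
                        [
                            a
                            for a in np.flatnonzero(X[r])
                            if a not in forced_cols
                        ]
                    )
                    if removable.size:
                        drop = rng.choice(
                            removable, size=min(added, removable.size), replace=False
                        )
                        X[r, drop] = 0
            truth.append(
                dict(
                    taxa=taxa,
                    env_subtype=subtype,
                    boost=spec.co_occurrence_boost,
                    extra_joint_probability=q,
                    n_forced_samples=int(force.size),
                )
            )
    return OccurrenceTable(list(base.genus_ids), list(base.sample_ids), X), truth


def generate_pathway_universe(
    genera: Sequence[str],
    n_pathways: int = 150,
    core_size_range: tuple[int, int] = (15, 40),
    planted: Mapping[tuple[frozenset[str], str], str] | None = None,
    n_genomes_range: tuple[int, int] = (1, 5),
    noise_rate: float = 2.0,
    seed: int = 0,
) -> tuple[list[GenomePathwayTable], dict]:
    """Genome pathway tables with planted redundant/specific/missing roles.

    Each genus receives a core drawn from a shared pathway universe with
    popularity-weighted sampling (core sizes within ``core_size_range``),
    plus 1-5 genomes carrying the core and genome-private noise pathways.
    Planted roles are realized in the cores:

    * ``redundant`` — carried by every assemblage member, rare (5%) in the
      background pool;
    * ``specific`` — carried by exactly one member, common (90%) in the pool;
    * ``missing`` — carried by no member, common (90%) in the pool.

    Returns the genome tables and a ground-truth dict with keys ``roles``
    ((assemblage, pathway) -> role) and ``cores`` (genus -> intended core).
    """
    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    pw_names = [f"p{t:04d}" for t in range(n_pathways)]
    planted_pw = sorted({p for (_, p) in planted})
    unknown = [p for p in planted_pw if p not in pw_names]
    if unknown:
        raise InvariantError(f"planted pathways outside universe: {unknown}")

    # forced per-genus inclusion/exclusion from the planted roles
    force_in: dict[str, set[str]] = {g: set() for g in genera}
    force_out: dict[str, set[str]] = {g: set() for g in genera}
    background_common: set[str] = set()
    background_rare: set[str] = set()
    for (taxa, p), role in planted.items():
        taxa = frozenset(taxa)
        members = sorted(taxa)
        bad = sorted(taxa - set(genera))
        if bad:
            raise InvariantError(f"planted assemblage members not in pool: {bad}")
        if role == "redundant":
            background_rare.add(p)
            for g in members:
                force_in[g].add(p)
        elif role == "specific":
            background_common.add(p)
            carrier = members[int(rng.integers(len(members)))]
            force_in[carrier].add(p)
            for g in members:
                if g != carrier:
                    force_out[g].add(p)
        elif role == "missing":
            background_common.add(p)
            for g in members:
                force_out[g].add(p)
        else:
            raise InvariantError(f"unknown planted role {role!r}")
    for g in genera:
        clash = force_in[g] & force_out[g]
        if clash:
            raise InvariantError(
                f"inconsistent plants: {sorted(clash)} both required and forbidden in {g}"
            )

    free_pw = [p for p in pw_names if p not in planted_pw]
    popularity = rng.uniform(0.05, 1.0, size=len(free_pw))
    popularity /= popularity.sum()
    genomes: list[GenomePathwayTable] = []
    cores: dict[str, frozenset[str]] = {}
    for g in genera:
        target = int(rng.integers(core_size_range[0], core_size_range[1] + 1))
        target = min(target, len(free_pw))
        core = set(
            np.asarray(free_pw)[
                rng.choice(len(free_pw), size=target, replace=False, p=popularity)
            ]
        )
        for p in planted_pw:
            if p in force_in[g]:
                core.add(p)
            elif p in force_out[g]:
                pass
            else:
                b = 0.9 if p in background_common else 0.05
                if rng.random() < b:
                    core.add(p)
        cores[g] = frozenset(core)
        k = int(rng.integers(n_genomes_range[0], n_genomes_range[1] + 1))
        for t in range(k):
            n_noise = int(rng.poisson(noise_rate))
            noise = {f"noise-{g}-{t}-{u}" for u in range(n_noise)}
            genomes.append(
                GenomePathwayTable(f"{g}-genome{t}", g, frozenset(core) | noise)
            )
    truth = {
        "roles": {(frozenset(t), p): r for (t, p), r in planted.items()},
        "cores": cores,
    }
    return genomes, truth


def generate_phylo_distances(
    genera: Sequence[str],
    n_species_per_genus: tuple[int, int] = (1, 4),
    seed: int = 0,
    within_scale: float = 0.03,
) -> tuple[DistanceMatrix, dict[str, str]]:
    """Species-level distances with coherent genus structure.

    Genera are embedded at random points of a latent trait space; distances
    between species of different genera follow their genera's separation
    (mean ~0.25 substitutions/site) with small jitter, while congeneric
    species are within ``within_scale`` of each other, so within-genus
    distances are smaller than between-genus ones on average.
    """
    if n_species_per_genus[0] < 1:
        raise InvariantError("need at least one species per genus")
    rng = np.random.default_rng(seed)
    G = len(genera)
    pts = rng.normal(size=(G, 8))
    base = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    off = base[np.triu_indices(G, k=1)]
    if off.size:
        base = base * (0.25 / off.mean())
    species: list[str] = []
    s2g: dict[str, str] = {}
    gof: list[int] = []
    for gi, g in enumerate(genera):
        k = int(rng.integers(n_species_per_genus[0], n_species_per_genus[1] + 1))
        for t in range(k):
            sp = f"{g}-sp{t}"
            species.append(sp)
            s2g[sp] = g
            gof.append(gi)
    n = len(species)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if gof[i] == gof[j]:
            d = rng.uniform(0.0, within_scale)
        else:
            d = max(
                base[gof[i], gof[j]] + rng.uniform(-0.01, 0.01), within_scale
            )
        D[i, j] = D[j, i] = d
    return DistanceMatrix(species, D), s2g
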