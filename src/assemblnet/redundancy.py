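"""Constrained random assemblages and the real-vs-random redundancy report.

Observed assemblages are compared against four classes of random assemblages
of the same size:

* ``fully_random`` — genera drawn from the whole pool (1000 replicates);
* ``same_environment`` — genera drawn from the reference assemblage's
  environment subtype (100 replicates);
* ``env_and_phylo`` — same subtype, and mean pairwise phylogenetic distance
  within ``phylo_tolerance`` (default 0.05 substitutions/site) of the
  reference (100 replicates);
* ``env_and_genome_size`` — same subtype, and mean core pathways per genus
  within ``size_rel_tolerance`` (default 20%) of the reference (100
  replicates).

Distributions of the three per-assemblage metrics are compared between
groups with two-sided Mann-Whitney U tests, Benjamini-Hochberg corrected
within each (metric, assemblage size) family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .assemblage_metrics import AssemblageSummary, summarize_assemblage
from .errors import InfeasibleConstraint, InvariantError
from .io_model import DistanceMatrix, GenusPathwayProfile

__all__ = [
    "RandomAssemblageConstraint",
    "sample_random_assemblage",
    "random_summaries",
    "redundancy_report",
]

_KINDS = ("fully_random", "same_environment", "env_and_phylo", "env_and_genome_size")
METRICS = ("mean_functional_distance", "mean_phylo_distance", "mean_pathways_per_genus")


@dataclass
class RandomAssemblageConstraint:
    kind: str
    n_replicates: int | None = None
    phylo_tolerance: float = 0.05
    size_rel_tolerance: float = 0.20
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvariantError(f"unknown constraint kind {self.kind!r}")
        if self.n_replicates is None:
            self.n_replicates = 1000 if self.kind == "fully_random" else 100
        if self.phylo_tolerance <= 0 or self.size_rel_tolerance <= 0:
            raise InvariantError("tolerances must be > 0")


def _pool_subtypes(pool: Mapping[str, object], genus: str) -> set[str]:
    subs = pool[genus]
    return {subs} if isinstance(subs, str) else set(subs)


def _mean_pairwise(distances: DistanceMatrix, members: Sequence[str]) -> float:
    idx = [distances.labels.index(g) for g in members]
    sub = distances.D[np.ix_(idx, idx)]
    return float(sub[np.triu_indices(len(idx), k=1)].mean())


def sample_random_assemblage(
    size: int,
    constraint: RandomAssemblageConstraint,
    reference: AssemblageSummary | None,
    pool: Mapping[str, str],
    profiles: Mapping[str, GenusPathwayProfile],
    distances: DistanceMatrix,
    seed: int | np.random.Generator = 0,
    reference_env_subtype: str | None = None,
) -> frozenset[str]:
    """Draw one random assemblage honouring the constraint, by rejection
    sampling without replacement.

    ``pool`` maps each candidate genus to the environment subtype(s) in which
    it was observed (a single label or a collection).  For the
    environmentally constrained kinds the candidate pool is restricted to
    genera observed in ``reference_env_subtype``.  Raises
    :class:`InfeasibleConstraint` when ``max_attempts`` draws all fail the
    acceptance test.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if constraint.kind == "fully_random":
        candidates = sorted(pool)
    else:
        if reference_env_subtype is None:
            raise InvariantError("environment-constrained sampling needs the reference subtype")
        candidates = sorted(
            g for g in pool if reference_env_subtype in _pool_subtypes(pool, g)
        )
    if len(candidates) < size:
        raise InfeasibleConstraint(
            f"pool of {len(candidates)} genera cannot produce assemblages of size {size}",
            attempts=0,
        )
    if len(candidates) == size:
        members = candidates
        if _accept(members, constraint, reference, profiles, distances):
            return frozenset(members)
        raise InfeasibleConstraint("the only possible assemblage fails the constraint", 1)
    for attempt in range(1, constraint.max_attempts + 1):
        members = [candidates[t] for t in rng.choice(len(candidates), size=size, replace=False)]
        if _accept(members, constraint, reference, profiles, distances):
            return frozenset(members)
    raise InfeasibleConstraint(
        f"no valid assemblage after {constraint.max_attempts} attempts "
        f"(kind={constraint.kind}, size={size})",
        attempts=constraint.max_attempts,
    )


def _accept(
    members: Sequence[str],
    constraint: RandomAssemblageConstraint,
    reference: AssemblageSummary | None,
    profiles: Mapping[str, GenusPathwayProfile],
    distances: DistanceMatrix,
) -> bool:
    if constraint.kind in ("fully_random", "same_environment"):
        return True
    if reference is None:
        raise InvariantError(f"{constraint.kind} sampling needs a reference summary")
    if constraint.kind == "env_and_phylo":
        if any(g not in distances.labels for g in members):
            return False
        return (
            abs(_mean_pairwise(distances, members) - reference.mean_phylo_distance)
            <= constraint.phylo_tolerance
        )
    # env_and_genome_size
    if any(g not in profiles for g in members):
        return False
    mean_pw = float(np.mean([len(profiles[g].core_pathways) for g in members]))
    return (
        abs(mean_pw - reference.mean_pathways_per_genus)
        <= constraint.size_rel_tolerance * reference.mean_pathways_per_genus
    )


def random_summaries(
    real: Iterable[tuple[AssemblageSummary, str]],
    constraint: RandomAssemblageConstraint,
    pool: Mapping[str, str],
    profiles: Mapping[str, GenusPathwayProfile],
    distances: DistanceMatrix,
    seed: int = 0,
) -> list[AssemblageSummary]:
    """Summaries of ``n_replicates`` random counterparts for every real
    assemblage.  ``real`` yields (summary, env_subtype) pairs.  Infeasible
    references are skipped with a warning."""
    rng = np.random.default_rng(seed)
    out: list[AssemblageSummary] = []
    for ref, subtype in real:
        try:
            for _ in range(constraint.n_replicates):
                members = sample_random_assemblage(
                    ref.size, constraint, ref, pool, profiles, distances,
                    seed=rng, reference_env_subtype=subtype,
                )
                out.append(summarize_assemblage(members, profiles, distances))
        except InfeasibleConstraint as exc:
            warnings.warn(
                f"skipping reference {sorted(ref.taxa)}: {exc}", stacklevel=2
            )
    return out


def redundancy_report(
    groups: Mapping[str, Sequence[AssemblageSummary]],
    alpha: float = 0.05,
    sizes: Iterable[int] = range(2, 13),
) -> pd.DataFrame:
    """Size-stratified pairwise group comparisons of the three metrics.

    ``groups`` maps a group label (e.g. ``real_single_env``,
    ``real_multi_env``, ``fully_random`` ...) to its assemblage summaries.
    For every assemblage size and metric, every pair of groups with at least
    two observations each is compared with a two-sided Mann-Whitney U test;
    Benjamini-Hochberg correction is applied within each (metric, size)
    family.  Pairs with fewer observations are reported as not testable.
    """
    rows = []
    for sz in sizes:
        by_group = {
            name: [s for s in ss if s.size == sz] for name, ss in groups.items()
        }
        for metric in METRICS:
            fam = []
            for ga, gb in itertools.combinations(sorted(by_group), 2):
                xa = [getattr(s, metric) for s in by_group[ga]]
                xb = [getattr(s, metric) for s in by_group[gb]]
                if len(xa) < 2 or len(xb) < 2:
                    rows.append(
                        dict(size=sz, metric=metric, group_a=ga, group_b=gb,
                             n_a=len(xa), n_b=len(xb), U=np.nan, p_raw=np.nan,
                             p_adj=np.nan, significant=False, testable=False)
                    )
                    continue
                method = "exact" if max(len(xa), len(xb)) < 20 else "asymptotic"
                try:
                    U, p = mannwhitneyu(xa, xb, alternative="two-sided", method=method)
                except ValueError:  # exact method refuses ties
                    U, p = mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
                fam.append(
                    dict(size=sz, metric=metric, group_a=ga, group_b=gb,
                         n_a=len(xa), n_b=len(xb), U=float(U), p_raw=float(p),
                         testable=True)
                )
            if fam:
                adj = multipletests([r["p_raw"] for r in fam], method="fdr_bh")[1]
                for r, pa in zip(fam, adj):
                    r["p_adj"] = float(pa)
                    r["significant"] = bool(pa <= alpha)
                rows.extend(fam)
    cols = ["size", "metric", "group_a", "group_b", "n_a", "n_b", "U",
            "p_raw", "p_adj", "significant", "testable"]
    return pd.DataFrame(rows, columns=cols)
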