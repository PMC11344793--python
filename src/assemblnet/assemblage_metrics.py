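"""Per-assemblage functional and phylogenetic summary statistics.

An assemblage's functional redundancy is read off the average pairwise
Jaccard dissimilarity between its members' core pathway sets (low distance =
high redundancy); its phylogenetic cohesion off the average pairwise
genus-level distance (substitutions per site); and the average number of
core pathways per genus serves as a proxy for genome size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvariantError, UnannotatableAssemblage
from .io_model import DistanceMatrix, GenusPathwayProfile

__all__ = ["AssemblageSummary", "functional_distance", "summarize_assemblage"]


@dataclass
class AssemblageSummary:
    taxa: frozenset[str]
    mean_functional_distance: float
    mean_phylo_distance: float
    mean_pathways_per_genus: float
    union_pathways: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.taxa)


def functional_distance(u: GenusPathwayProfile, v: GenusPathwayProfile) -> float:
    """Jaccard dissimilarity (1 - Jaccard index) between two core pathway
    sets.  Undefined when both sets are empty."""
    a, b = u.core_pathways, v.core_pathways
    union = a | b
    if not union:
        raise InvariantError(
            f"Jaccard distance undefined: both {u.genus} and {v.genus} have empty cores"
        )
    return 1.0 - len(a & b) / len(union)


def summarize_assemblage(
    taxa: Iterable[str],
    profiles: Mapping[str, GenusPathwayProfile],
    distances: DistanceMatrix,
) -> AssemblageSummary:
    """All-against-all pairwise summaries of an assemblage.

    Raises :class:`UnannotatableAssemblage` when a member lacks a pathway
    profile or a distance entry; callers skip such assemblages rather than
    crash.
    """
    members = sorted(set(taxa))
    if len(members) < 2:
        raise InvariantError("assemblage summaries need at least two genera")
    missing = [g for g in members if g not in profiles or g not in distances.labels]
    if missing:
        raise UnannotatableAssemblage(
            f"members without annotation: {missing}"
        )
    pairs = list(itertools.combinations(members, 2))
    fd = float(
        np.mean([functional_distance(profiles[a], profiles[b]) for a, b in pairs])
    )
    idx = [distances.labels.index(g) for g in members]
    sub = distances.D[np.ix_(idx, idx)]
    pd_ = float(sub[np.triu_indices(len(members), k=1)].mean())
    sizes = [len(profiles[g].core_pathways) for g in members]
    union = frozenset().union(*(profiles[g].core_pathways for g in members))
    return AssemblageSummary(
        taxa=frozenset(members),
        mean_functional_distance=fd,
        mean_phylo_distance=pd_,
        mean_pathways_per_genus=float(np.mean(sizes)),
        union_pathways=union,
    )


def summaries_to_frame(summaries: Iterable[AssemblageSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                "|".join(sorted(s.taxa)),
                s.size,
                s.mean_functional_distance,
                s.mean_phylo_distance,
                s.mean_pathways_per_genus,
                len(s.union_pathways),
            )
            for s in summaries
        ],
        columns=[
            "taxa",
            "size",
            "mean_functional_distance",
            "mean_phylo_distance",
            "mean_pathways_per_genus",
            "n_union_pathways",
        ],
    )
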