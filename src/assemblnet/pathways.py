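"""Per-pathway selection signals in consensus assemblages.

For each terminal assemblage of the highly supported consensus network, the
prevalence P of every metabolic pathway (how many of the S members carry it
in their core genome) is compared to its prevalence in 1000 environmentally
and phylogenetically matched random assemblages:

* **Redundant** — carried by at least two members, and more prevalent than
  in 95% of the random assemblages (a capability selected by the habitat and
  seldom shared);
* **Specific** — present in the assemblage, but less prevalent than in 95%
  of the random assemblages (a candidate shared "public good");
* **Missing** — absent from the assemblage although present in 95% of the
  random assemblages (not needed, or selected against, in that habitat);
* **Unclassified** otherwise.  Ties with the random distribution favour
  Unclassified (conservative one-sided empirical test).

``1 - P/S`` is the fraction of members that cannot synthesize the pathway's
product themselves — for amino-acid biosynthesis pathways, the auxotroph
fraction regressed against biosynthetic cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
import statsmodels.api as sm

from .errors import InfeasibleConstraint, InvariantError
from .io_model import AminoAcidCostTable, DistanceMatrix, GenusPathwayProfile
from .redundancy import RandomAssemblageConstraint, sample_random_assemblage

__all__ = [
    "PathwayClassification",
    "AuxotrophyRecord",
    "classify_pathway",
    "classify_network",
    "auxotroph_fraction",
    "auxotrophy_records",
    "size_class_comparison",
    "cost_regression",
]

CALLS = ("Redundant", "Specific", "Missing", "Unclassified")


@dataclass
class PathwayClassification:
    assemblage: frozenset[str]
    pathway: str
    prevalence_real: int  # P
    assemblage_size: int  # S
    call: str
    quantile: float  # fraction of random assemblages with prevalence < P

    def __post_init__(self) -> None:
        P, S = self.prevalence_real, self.assemblage_size
        if not 0 <= P <= S:
            raise InvariantError(f"prevalence {P} outside [0, {S}]")


@dataclass
class AuxotrophyRecord:
    amino_acid: str
    mean_auxotroph_fraction: float
    cost: float

    def __post_init__(self) -> None:
        if not 0 <= self.mean_auxotroph_fraction <= 1:
            raise InvariantError("auxotroph fraction outside [0,1]")


def classify_pathway(P: int, S: int, random_prevalences: Sequence[int]) -> str:
    """Classify one pathway in one assemblage against the random-prevalence
    distribution (strict inequality against at least 95% of replicates)."""
    r = np.asarray(random_prevalences)
    if r.size == 0:
        raise InvariantError("empty random prevalence distribution")
    if not 0 <= P <= S:
        raise InvariantError(f"prevalence {P} outside [0, {S}]")
    frac_below = float((r < P).mean())
    frac_above = float((r > P).mean())
    if P >= 2 and frac_below >= 0.95:
        return "Redundant"
    if P >= 1 and frac_above >= 0.95:
        return "Specific"
    if P == 0 and float((r >= 1).mean()) >= 0.95:
        return "Missing"
    return "Unclassified"


def classify_network(
    terminals: Mapping[frozenset[str], str] | Iterable[tuple[frozenset[str], str]],
    profiles: Mapping[str, GenusPathwayProfile],
    distances: DistanceMatrix,
    pool: Mapping[str, str],
    summaries: Mapping[frozenset[str], "object"] | None = None,
    n_random: int = 1000,
    phylo_tolerance: float = 0.1,
    seed: int = 0,
) -> list[PathwayClassification]:
    """Classify every (terminal assemblage, pathway) pair.

    ``terminals`` maps each terminal assemblage (taxa set) to its environment
    subtype; random counterparts are drawn from that subtype with mean
    pairwise phylogenetic distance within ``phylo_tolerance`` of the real
    assemblage (the tolerance is relaxed relative to the redundancy report to
    keep enough valid random assemblages).  The pathway universe is the union
    of all core pathways in the pool.  Assemblages for which no valid random
    counterparts can be drawn are skipped with a warning.
    """
    from .assemblage_metrics import summarize_assemblage

    if not isinstance(terminals, Mapping):
        terminals = dict(terminals)
    rng = np.random.default_rng(seed)
    universe = sorted(set().union(*(p.core_pathways for p in profiles.values())))
    pw_idx = {p: t for t, p in enumerate(universe)}
    genus_list = sorted(profiles)
    g_idx = {g: i for i, g in enumerate(genus_list)}
    ind = np.zeros((len(genus_list), len(universe)), dtype=np.int16)
    for g, prof in profiles.items():
        for p in prof.core_pathways:
            ind[g_idx[g], pw_idx[p]] = 1

    constraint = RandomAssemblageConstraint(
        "env_and_phylo", n_replicates=n_random, phylo_tolerance=phylo_tolerance
    )
    out: list[PathwayClassification] = []
    for taxa, subtype in terminals.items():
        members = sorted(taxa)
        if any(g not in profiles or g not in distances.labels for g in members):
            warnings.warn(f"skipping unannotatable assemblage {members}", stacklevel=2)
            continue
        ref = summarize_assemblage(members, profiles, distances)
        try:
            randoms = [
                sample_random_assemblage(
                    ref.size, constraint, ref, pool, profiles, distances,
                    seed=rng, reference_env_subtype=subtype,
                )
                for _ in range(n_random)
            ]
        except InfeasibleConstraint as exc:
            warnings.warn(f"skipping assemblage {members}: {exc}", stacklevel=2)
            continue
        rand_prev = np.stack(
            [ind[[g_idx[g] for g in rs]].sum(axis=0) for rs in randoms]
        )  # (n_random, n_pathways)
        real_prev = ind[[g_idx[g] for g in members]].sum(axis=0)
        S = len(members)
        for p, t in pw_idx.items():
            P = int(real_prev[t])
            r = rand_prev[:, t]
            out.append(
                PathwayClassification(
                    assemblage=frozenset(members),
                    pathway=p,
                    prevalence_real=P,
                    assemblage_size=S,
                    call=classify_pathway(P, S, r),
                    quantile=float((r < P).mean()),
                )
            )
    return out


def classifications_to_frame(classifications: Iterable[PathwayClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                "|".join(sorted(c.assemblage)),
                c.pathway,
                c.prevalence_real,
                c.assemblage_size,
                c.call,
                c.quantile,
            )
            for c in classifications
        ],
        columns=["assemblage", "pathway", "P", "S", "call", "quantile"],
    )


def auxotroph_fraction(P: int, S: int) -> float:
    """Fraction of assemblage members lacking a pathway: ``1 - P/S``."""
    if S < 1:
        raise InvariantError("assemblage size must be >= 1")
    if not 0 <= P <= S:
        raise InvariantError(f"prevalence {P} outside [0, {S}]")
    return 1.0 - P / S


def auxotrophy_records(
    classifications: Iterable[PathwayClassification],
    pathway_to_amino_acid: Mapping[str, str],
    costs: AminoAcidCostTable,
    min_size: int = 5,
) -> list[AuxotrophyRecord]:
    """Mean auxotroph fraction per amino acid over large assemblages.

    ``pathway_to_amino_acid`` maps amino-acid biosynthesis pathway labels to
    the amino acid they produce.  Only assemblages with at least ``min_size``
    members contribute.
    """
    fracs: dict[str, list[float]] = {}
    for c in classifications:
        aa = pathway_to_amino_acid.get(c.pathway)
        if aa is None or c.assemblage_size < min_size:
            continue
        fracs.setdefault(aa, []).append(
            auxotroph_fraction(c.prevalence_real, c.assemblage_size)
        )
    return [
        AuxotrophyRecord(aa, float(np.mean(v)), costs.costs[aa])
        for aa, v in sorted(fracs.items())
        if aa in costs.costs
    ]


def size_class_comparison(
    classifications: Iterable[PathwayClassification],
    size_threshold: int = 5,
) -> pd.DataFrame:
    """Average pathways per genome in small vs large assemblages, overall and
    restricted to each call class.

    For each assemblage the per-genome average restricted to a call class is
    ``sum(P over pathways with that call) / S``.  Small (< threshold) and
    large (>= threshold) groups are compared with a two-sided Wilcoxon
    rank-sum test; degenerate groups are flagged not testable.
    """
    per_ass: dict[frozenset[str], dict] = {}
    for c in classifications:
        d = per_ass.setdefault(
            c.assemblage, {"S": c.assemblage_size, "total": 0.0, **{k: 0.0 for k in CALLS}}
        )
        d["total"] += c.prevalence_real
        d[c.call] += c.prevalence_real
    rows = []
    for cls in ("total",) + CALLS[:3]:
        small = [d[cls] / d["S"] for d in per_ass.values() if d["S"] < size_threshold]
        large = [d[cls] / d["S"] for d in per_ass.values() if d["S"] >= size_threshold]
        testable = len(small) >= 2 and len(large) >= 2
        if testable:
            U, p = mannwhitneyu(small, large, alternative="two-sided")
        else:
            U, p = np.nan, np.nan
        rows.append(
            dict(
                call_class=cls,
                n_small=len(small),
                n_large=len(large),
                mean_small=float(np.mean(small)) if small else np.nan,
                mean_large=float(np.mean(large)) if large else np.nan,
                U=float(U) if testable else np.nan,
                p=float(p) if testable else np.nan,
                testable=testable,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class CostRegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided test of zero slope
    slope_stderr: float
    n: int


def cost_regression(
    records: Iterable[AuxotrophyRecord],
    exclude: Iterable[str] = (),
) -> CostRegressionResult:
    """Ordinary least squares of mean auxotroph fraction on biosynthetic
    cost, optionally excluding amino acids (e.g. tryptophan, whose tight
    regulation decouples its auxotroph prevalence from raw cost)."""
    excl = set(exclude)
    kept = [r for r in records if r.amino_acid not in excl]
    if len(kept) < 3:
        raise InvariantError(f"need >= 3 records after exclusion, got {len(kept)}")
    x = np.array([r.cost for r in kept])
    y = np.array([r.mean_auxotroph_fraction for r in kept])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return CostRegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        slope_stderr=float(fit.bse[1]),
        n=len(kept),
    )
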