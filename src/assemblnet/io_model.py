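"""Typed data model and TSV readers/writers.

The package works on binary genus x sample occurrence tables annotated with a
two-level environmental hierarchy (environment type, e.g. ``marine water``,
and the finer environment subtype, e.g. ``river``), genome-level metabolic
pathway tables aggregated to genus core genomes, phylogenetic distance
matrices in substitutions per site, and amino-acid biosynthetic cost tables.

All tabular interchange is tab-delimited UTF-8 text with a header row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTableError, InvariantError, ParseError

__all__ = [
    "OccurrenceTable",
    "SampleAnnotation",
    "GenomePathwayTable",
    "GenusPathwayProfile",
    "DistanceMatrix",
    "AminoAcidCostTable",
    "read_occurrence_table",
    "write_occurrence_table",
    "read_annotations",
    "write_annotations",
    "filter_occurrence_table",
    "read_genome_pathways",
    "core_pathways",
    "read_distance_matrix",
    "write_distance_matrix",
    "genus_distances",
    "read_cost_table",
    "akashi_gojobori_costs",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if list(labels).count(x) > 1})
        raise InvariantError(f"duplicate {what} labels: {dupes[:5]}")


@dataclass
class OccurrenceTable:
    """Binary genus x sample presence/absence matrix.

    ``X[i, a]`` is 1 when genus ``genus_ids[i]`` was observed in sample
    ``sample_ids[a]`` and 0 otherwise.
    """

    genus_ids: list[str]
    sample_ids: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.shape != (len(self.genus_ids), len(self.sample_ids)):
            raise InvariantError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genus_ids)} genera x {len(self.sample_ids)} samples"
            )
        _check_unique(self.genus_ids, "genus")
        _check_unique(self.sample_ids, "sample")
        if not np.isin(self.X, (0, 1)).all():
            i, a = np.argwhere(~np.isin(self.X, (0, 1)))[0]
            raise InvariantError(
                f"non-binary entry at ({self.genus_ids[i]},{self.sample_ids[a]})"
            )
        self.X = self.X.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def genus_index(self, genus: str) -> int:
        return self.genus_ids.index(genus)

    def row(self, genus: str) -> np.ndarray:
        return self.X[self.genus_ids.index(genus)]

    def subset_samples(self, keep: Sequence[str]) -> "OccurrenceTable":
        pos = {s: a for a, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return OccurrenceTable(list(self.genus_ids), list(keep), self.X[:, idx])

    def subset_genera(self, keep: Sequence[str]) -> "OccurrenceTable":
        pos = {g: i for i, g in enumerate(self.genus_ids)}
        idx = [pos[g] for g in keep]
        return OccurrenceTable(list(keep), list(self.sample_ids), self.X[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.genus_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleAnnotation:
    """Environmental annotation of one sample.

    ``env_subtype`` is the finest environmental classification and is nested
    within ``env_type`` (one subtype never spans two types).
    """

    sample_id: str
    env_type: str
    env_subtype: str


@dataclass
class GenomePathwayTable:
    """Metabolic pathways predicted for a single sequenced genome."""

    genome_id: str
    genus: str
    pathways: frozenset[str]
    pathway_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pathways = frozenset(self.pathways)
        if not self.pathways:
            raise InvariantError(f"genome {self.genome_id} has an empty pathway set")


@dataclass(frozen=True)
class GenusPathwayProfile:
    """Core genome of a genus in the pathway sense: the pathways predicted in
    every available genome of that genus."""

    genus: str
    core_pathways: frozenset[str]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix (substitutions per site)."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        _check_unique(self.labels, "distance-matrix")
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise InvariantError(f"distance matrix shape {self.D.shape} != ({n},{n})")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise InvariantError("distance matrix is not symmetric")
        if (self.D < 0).any():
            raise InvariantError("negative distances")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise InvariantError("non-zero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.D[i, j])


@dataclass
class AminoAcidCostTable:
    """Per-amino-acid biosynthetic cost (high-energy phosphate bonds)."""

    costs: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.costs) > 20:
            raise InvariantError("more than 20 amino acids in cost table")
        for aa, c in self.costs.items():
            if not c > 0:
                raise InvariantError(f"non-positive cost for {aa}")


# ---------------------------------------------------------------------------
# occurrence tables


def read_occurrence_table(
    path, annotation_path=None
) -> tuple[OccurrenceTable, list[SampleAnnotation]]:
    """Read a binary occurrence TSV (rows genera, columns samples) and,
    optionally, its sample annotation TSV.

    Dense form: header row of sample ids, first column genus ids, 0/1 cells.
    Sparse triplet form (detected by a ``genus\\tsample`` header) lists one
    ``genus<TAB>sample<TAB>1`` row per occurrence.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] == ["genus", "sample"]:
        trip = pd.read_csv(path, sep="\t", dtype=str)
        genera = list(dict.fromkeys(trip["genus"]))
        samples = list(dict.fromkeys(trip["sample"]))
        X = np.zeros((len(genera), len(samples)), dtype=np.uint8)
        gi = {g: i for i, g in enumerate(genera)}
        si = {s: a for a, s in enumerate(samples)}
        for _, r in trip.iterrows():
            X[gi[r["genus"]], si[r["sample"]]] = 1
        table = OccurrenceTable(genera, samples, X)
    else:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
        genera = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
        vals = np.empty(df.shape, dtype=np.uint8)
        for i, g in enumerate(genera):
            for a, s in enumerate(samples):
                cell = df.iat[i, a]
                if cell not in ("0", "1"):
                    raise ParseError(f"non-binary cell '{cell}' at ({g},{s})")
                vals[i, a] = int(cell)
        table = OccurrenceTable(genera, samples, vals)

    annotations: list[SampleAnnotation] = []
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
        annotated = {a.sample_id for a in annotations}
        missing = [s for s in table.sample_ids if s not in annotated]
        if missing:
            import warnings

            warnings.warn(
                f"{len(missing)} samples lack environmental annotation and will "
                f"be excluded from network building: {missing[:5]}...",
                stacklevel=2,
            )
    return table, annotations


def write_occurrence_table(table: OccurrenceTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_annotations(path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "env_type", "env_subtype"}
    if not required.issubset(df.columns):
        raise ParseError(f"annotation file must have columns {sorted(required)}")
    anns = [
        SampleAnnotation(r.sample_id, r.env_type, r.env_subtype)
        for r in df.itertuples()
    ]
    _check_unique([a.sample_id for a in anns], "annotated sample")
    by_sub: dict[str, str] = {}
    for a in anns:
        if by_sub.setdefault(a.env_subtype, a.env_type) != a.env_type:
            raise InvariantError(
                f"env_subtype {a.env_subtype!r} appears under two env_types"
            )
    return anns


def write_annotations(annotations: Iterable[SampleAnnotation], path) -> None:
    pd.DataFrame(
        [(a.sample_id, a.env_type, a.env_subtype) for a in annotations],
        columns=["sample_id", "env_type", "env_subtype"],
    ).to_csv(path, sep="\t", index=False)


def filter_occurrence_table(
    table: OccurrenceTable,
    min_genera_per_sample: int = 5,
    min_samples_per_genus: int = 5,
    iterate: bool = True,
) -> OccurrenceTable:
    """Drop sparse samples and genera.

    Samples with fewer than ``min_genera_per_sample`` genera and genera present
    in fewer than ``min_samples_per_genus`` samples are excluded.  By default
    the two rules are applied alternately until a fixed point is reached, so
    the returned table satisfies both constraints simultaneously; with
    ``iterate=False`` each rule is applied once against the original margins.
    """
    if min_genera_per_sample < 1 or min_samples_per_genus < 1:
        raise InvariantError("filter thresholds must be >= 1")
    X = table.X.astype(np.int64)
    gmask = np.ones(X.shape[0], dtype=bool)
    smask = np.ones(X.shape[1], dtype=bool)
    while True:
        sub = X[np.ix_(gmask, smask)]
        bad_g = sub.sum(axis=1) < min_samples_per_genus
        bad_s = sub.sum(axis=0) < min_genera_per_sample
        if not bad_g.any() and not bad_s.any():
            break
        gmask[np.flatnonzero(gmask)[bad_g]] = False
        smask[np.flatnonzero(smask)[bad_s]] = False
        if not iterate:
            break
    if not gmask.any() or not smask.any():
        raise EmptyTableError("empty after filtering")
    return OccurrenceTable(
        [g for g, m in zip(table.genus_ids, gmask) if m],
        [s for s, m in zip(table.sample_ids, smask) if m],
        table.X[np.ix_(gmask, smask)],
    )


# ---------------------------------------------------------------------------
# pathways


def read_genome_pathways(path) -> list[GenomePathwayTable]:
    """Read a genome x pathway TSV with columns genome_id, genus, pathway and
    optionally pathway_class (one row per genome-pathway pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "genus", "pathway"}
    if not required.issubset(df.columns):
        raise ParseError(f"genome pathway file must have columns {sorted(required)}")
    has_class = "pathway_class" in df.columns
    out: list[GenomePathwayTable] = []
    for gid, grp in df.groupby("genome_id", sort=False):
        genera = grp["genus"].unique()
        if len(genera) != 1:
            raise InvariantError(f"genome {gid} maps to several genera: {genera}")
        classes = (
            dict(zip(grp["pathway"], grp["pathway_class"])) if has_class else {}
        )
        out.append(GenomePathwayTable(str(gid), str(genera[0]), set(grp["pathway"]), classes))
    return out


def core_pathways(genomes: Iterable[GenomePathwayTable], genus: str) -> GenusPathwayProfile:
    """Core genome of ``genus``: intersection of its genomes' pathway sets."""
    sets = [g.pathways for g in genomes if g.genus == genus]
    if not sets:
        raise InvariantError(f"no genomes for genus {genus!r}")
    core = frozenset.intersection(*sets)
    return GenusPathwayProfile(genus, core)


def genus_profiles(genomes: Iterable[GenomePathwayTable]) -> dict[str, GenusPathwayProfile]:
    """Core profiles for every genus present in a genome collection."""
    genomes = list(genomes)
    return {
        genus: core_pathways(genomes, genus)
        for genus in dict.fromkeys(g.genus for g in genomes)
    }


# ---------------------------------------------------------------------------
# distances


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError("distance matrix rows and columns differ")
    return DistanceMatrix([str(x) for x in df.index], df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.D, index=dm.labels, columns=dm.labels).to_csv(path, sep="\t")


def genus_distances(
    species_matrix: DistanceMatrix, species_to_genus: Mapping[str, str]
) -> DistanceMatrix:
    """Aggregate a species-level distance matrix to genus level.

    The distance between two genera is the median over all cross pairs of
    their member species' distances; the diagonal is forced to zero.
    """
    missing = sorted(set(species_to_genus) - set(species_matrix.labels))
    if missing:
        raise InvariantError(f"species absent from distance matrix: {missing}")
    genera = list(dict.fromkeys(species_to_genus.values()))
    members = {
        g: [species_matrix.labels.index(s) for s, h in species_to_genus.items() if h == g]
        for g in genera
    }
    n = len(genera)
    D = np.zeros((n, n))
    for (i, g), (j, h) in itertools.combinations(enumerate(genera), 2):
        cross = species_matrix.D[np.ix_(members[g], members[h])]
        D[i, j] = D[j, i] = float(np.median(cross))
    return DistanceMatrix(genera, D)


# ---------------------------------------------------------------------------
# amino-acid costs

# Biosynthetic cost of each amino acid in high-energy phosphate bonds per
# molecule (Akashi & Gojobori-type opportunity costs, E. coli, aerobic).
_AA_COSTS = {
    "Ala": 11.7, "Arg": 27.3, "Asn": 14.7, "Asp": 12.7, "Cys": 24.7,
    "Gln": 16.3, "Glu": 15.3, "Gly": 11.7, "His": 38.3, "Ile": 32.3,
    "Leu": 27.3, "Lys": 30.3, "Met": 34.3, "Phe": 52.0, "Pro": 20.3,
    "Ser": 11.7, "Thr": 18.7, "Trp": 74.3, "Tyr": 50.0, "Val": 23.3,
}


def akashi_gojobori_costs() -> AminoAcidCostTable:
    """The standard published 20-amino-acid biosynthetic cost table."""
    return AminoAcidCostTable(dict(_AA_COSTS))


def read_cost_table(path) -> AminoAcidCostTable:
    df = pd.read_csv(path, sep="\t", dtype={"amino_acid": str, "cost": float})
    required = {"amino_acid", "cost"}
    if not required.issubset(df.columns):
        raise ParseError(f"cost table must have columns {sorted(required)}")
    return AminoAcidCostTable(dict(zip(df["amino_acid"], df["cost"])))
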