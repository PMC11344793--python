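"""Ground-truth guarantees of the synthetic-data generators."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from assemblnet.errors import InvariantError
from assemblnet.io_model import genus_profiles
from assemblnet.synthetic import (
    PlantSpec,
    generate_null_occurrences,
    generate_pathway_universe,
    generate_phylo_distances,
    plant_assemblages,
)


class TestNullOccurrences:
    def test_determinism(self):
        a, _ = generate_null_occurrences(30, 50, seed=9)
        b, _ = generate_null_occurrences(30, 50, seed=9)
        assert (a.X == b.X).all()

    def test_saturated_occupancy_gives_all_ones(self):
        t, _ = generate_null_occurrences(
            10, 20, occupancy_shape=(1e6, 1e-6), richness_shape=(1e6, 1e-6), seed=0
        )
        assert (t.X == 1).all()

    def test_margins_track_targets(self):
        t, _, (u, v) = generate_null_occurrences(
            200, 500, seed=1, return_targets=True
        )
        rho_rows = spearmanr(t.X.sum(axis=1), u).statistic
        rho_cols = spearmanr(t.X.sum(axis=0), v).statistic
        assert rho_rows > 0.9
        assert rho_cols > 0.5  # column effects are weaker by construction

    def test_env_layout_annotations(self):
        layout = {"e1": {"a": 5, "b": 3}, "e2": {"c": 2}}
        t, ann = generate_null_occurrences(5, env_layout=layout, seed=2)
        assert len(ann) == 10 == len(t.sample_ids)
        assert sum(a.env_type == "e1" for a in ann) == 8

    def test_invalid_shape_rejected(self):
        with pytest.raises(InvariantError):
            generate_null_occurrences(5, 5, occupancy_shape=(0, 1))


@pytest.fixture(scope="module")
def base():
    layout = {"envA": {"sub1": 150, "sub2": 150}}
    return generate_null_occurrences(60, env_layout=layout, seed=3)


class TestPlanting:
    def _members(self, table, cols, k, exclude=(), lo=0.05, hi=0.12):
        f = table.X[:, cols].mean(axis=1)
        return [
            g
            for g, fr in zip(table.genus_ids, f)
            if lo < fr < hi and g not in exclude
        ][:k]

    def test_boost_one_is_identity(self, base):
        table, ann = base
        pair = self._members(table, slice(0, 150), 2)
        out, _ = plant_assemblages(
            table, ann, [PlantSpec(frozenset(pair), "sub1", 1.0)], seed=4
        )
        assert (out.X == table.X).all()

    def test_boost_elevates_cooccurrence_beyond_null(self, base):
        table, ann = base
        pair = self._members(table, slice(0, 150), 2)
        out, truth = plant_assemblages(
            table, ann, [PlantSpec(frozenset(pair), "sub1", 50)], seed=5
        )
        i, j = out.genus_index(pair[0]), out.genus_index(pair[1])
        sub1 = slice(0, 150)
        n = int((out.X[i, sub1] & out.X[j, sub1]).sum())
        fi = out.X[i, sub1].mean()
        fj = out.X[j, sub1].mean()
        mean0 = 150 * fi * fj
        sd0 = np.sqrt(150 * fi * fj * (1 - fi * fj))
        assert n > mean0 + 5 * sd0
        assert truth[0]["n_forced_samples"] > 0

    def test_conditional_plant_is_subtype_specific(self, base):
        table, ann = base
        a = self._members(table, slice(0, 300), 1)
        b = self._members(table, slice(0, 150), 1, exclude=a)
        c = self._members(table, slice(150, 300), 1, exclude=a + b)
        spec = PlantSpec(
            conditional_partner_map={a[0]: {"sub1": {b[0]}, "sub2": {c[0]}}},
            co_occurrence_boost=50,
        )
        out, _ = plant_assemblages(table, ann, [spec], seed=6)
        ia, ic = out.genus_index(a[0]), out.genus_index(c[0])
        def joint(rows, cols):
            return int((out.X[rows[0], cols] & out.X[rows[1], cols]).sum())
        base_joint = int(
            (table.X[ia, :150] & table.X[ic, :150]).sum()
        )
        # (A, C) co-occurrence is elevated in sub2 but not in sub1
        assert joint((ia, ic), slice(150, 300)) >= 10
        assert joint((ia, ic), slice(0, 150)) <= base_joint + 3

    def test_unknown_taxon_rejected(self, base):
        table, ann = base
        with pytest.raises(InvariantError, match="absent"):
            plant_assemblages(
                table, ann, [PlantSpec(frozenset({"nope"}), "sub1", 2)], seed=0
            )


class TestPathwayUniverse:
    def test_no_plants_means_no_roles(self):
        genomes, truth = generate_pathway_universe(["a", "b"], seed=0)
        assert truth["roles"] == {}
        assert {g.genus for g in genomes} == {"a", "b"}

    def test_planted_roles_realized_in_cores(self):
        genera = [f"g{i}" for i in range(30)]
        members = frozenset(genera[:5])
        planted = {
            (members, "p0001"): "redundant",
            (members, "p0002"): "specific",
            (members, "p0003"): "missing",
        }
        genomes, truth = generate_pathway_universe(genera, planted=planted, seed=1)
        profiles = genus_profiles(genomes)
        red = [g for g in members if "p0001" in profiles[g].core_pathways]
        spec = [g for g in members if "p0002" in profiles[g].core_pathways]
        mis = [g for g in members if "p0003" in profiles[g].core_pathways]
        assert set(red) == set(members)
        assert len(spec) == 1
        assert mis == []
        background = [g for g in genera if g not in members]
        common = np.mean(["p0003" in profiles[g].core_pathways for g in background])
        rare = np.mean(["p0001" in profiles[g].core_pathways for g in background])
        assert common >= 0.8
        assert rare <= 0.2

    def test_emitted_cores_match_profiles(self):
        genera = [f"g{i}" for i in range(10)]
        genomes, truth = generate_pathway_universe(
            genera, n_genomes_range=(2, 4), seed=2
        )
        profiles = genus_profiles(genomes)
        for g in genera:
            assert truth["cores"][g] == profiles[g].core_pathways

    def test_inconsistent_plant_rejected(self):
        genera = ["a", "b"]
        planted = {
            (frozenset(genera), "p0001"): "redundant",
            (frozenset(genera), "p0001"): "missing",
        }
        # same key overwrites -> construct the clash across assemblages
        planted = {
            (frozenset({"a", "b"}), "p0001"): "redundant",
            (frozenset({"b"}), "p0001"): "missing",
        }
        with pytest.raises(InvariantError, match="inconsistent"):
            generate_pathway_universe(genera, planted=planted, seed=0)


class TestPhyloDistances:
    def test_matrix_invariants_and_determinism(self):
        genera = [f"g{i}" for i in range(8)]
        a, map_a = generate_phylo_distances(genera, seed=3)
        b, map_b = generate_phylo_distances(genera, seed=3)
        assert np.allclose(a.D, a.D.T)
        assert np.allclose(np.diag(a.D), 0)
        assert (a.D >= 0).all()
        assert np.allclose(a.D, b.D) and map_a == map_b

    def test_within_genus_smaller_than_between(self):
        genera = [f"g{i}" for i in range(10)]
        dm, s2g = generate_phylo_distances(genera, n_species_per_genus=(2, 3), seed=4)
        within, between = [], []
        labels = dm.labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                (within if s2g[labels[i]] == s2g[labels[j]] else between).append(
                    dm.D[i, j]
                )
        assert np.mean(within) < np.mean(between)

    def test_single_genus(self):
        dm, s2g = generate_phylo_distances(["only"], seed=5)
        assert set(s2g.values()) == {"only"}
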