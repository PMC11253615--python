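import numpy as np
import pandas as pd
import pytest

from guildscope.core_io import GenomeAnnotation, ValidationError
from guildscope.functional_contrast import (
    arg_vf_summary,
    carrier_contrast,
    copy_number_contrast,
    ko_ordination,
    modules_present,
    unique_modules,
)
from guildscope.guild_detect import GuildAssignment


def _annotation(gene_copies, ko=None):
    ids = list(gene_copies.index)
    n = len(ids)
    return GenomeAnnotation(
        tuple(ids),
        gene_copies,
        np.zeros(n, int),
        np.zeros(n, int),
        ko if ko is not None else pd.DataFrame(index=ids),
    )


def _assign(n1, n2):
    ids = [f"A{k}" for k in range(n1)] + [f"B{k}" for k in range(n2)]
    labels = ["guild1"] * n1 + ["guild2"] * n2
    return GuildAssignment(tuple(ids), tuple(labels)), ids


class TestCarrierContrast:
    def test_butyrate_gene_paper_table(self):
        ga, ids = _assign(34, 20)
        copies = pd.DataFrame(
            {"but": [1] * 14 + [0] * 20 + [2, 1] + [0] * 18}, index=ids
        )
        table, (odds, p) = carrier_contrast(_annotation(copies), ga, "but")
        assert (table.carriers_a, table.total_a) == (14, 34)
        assert (table.carriers_b, table.total_b) == (2, 20)
        assert round(p, 3) == 0.029

    def test_no_carriers_p_one(self):
        ga, ids = _assign(5, 5)
        copies = pd.DataFrame({"x": [0] * 10}, index=ids)
        with pytest.warns(UserWarning):
            _, (_, p) = carrier_contrast(_annotation(copies), ga, "x")
        assert p == 1.0

    def test_unknown_gene_lists_valid_names(self):
        ga, ids = _assign(3, 3)
        copies = pd.DataFrame({"but": [1] * 6}, index=ids)
        with pytest.raises(ValidationError, match="but"):
            carrier_contrast(_annotation(copies), ga, "nope")

    def test_margins_equal_guild_sizes(self, small_cohort):
        m, meta, ann, truth = small_cohort
        ids = list(truth.signal_genomes)
        ga = GuildAssignment(tuple(ids), tuple(truth.roles[g] for g in ids))
        table, _ = carrier_contrast(ann, ga, "but")
        assert table.total_a == len(ga.members("guild1"))
        assert table.total_b == len(ga.members("guild2"))

    def test_synthetic_rates_within_binomial_ci(self):
        from guildscope.synthetic_data import SimulationSpec, simulate_community

        hits1 = hits2 = n1 = n2 = 0
        for seed in range(10):
            _, _, ann, truth = simulate_community(SimulationSpec(n_background=5), seed)
            ids = list(truth.signal_genomes)
            ga = GuildAssignment(tuple(ids), tuple(truth.roles[g] for g in ids))
            t, _ = carrier_contrast(ann, ga, "but")
            hits1 += t.carriers_a
            hits2 += t.carriers_b
            n1 += t.total_a
            n2 += t.total_b
        p1, p2 = 14 / 34, 2 / 20
        for hits, n, p in ((hits1, n1, p1), (hits2, n2, p2)):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(hits - n * p) <= 3 * sd


class TestCopyNumberContrast:
    def test_identical_distributions_p_one(self):
        ga, ids = _assign(4, 4)
        copies = pd.DataFrame({"but": [1, 2, 1, 2, 2, 1, 2, 1]}, index=ids)
        _, (u, p) = copy_number_contrast(_annotation(copies), ga, "but")
        assert p == 1.0

    def test_fully_separated_exact_p(self):
        ga, ids = _assign(5, 5)
        copies = pd.DataFrame({"but": [2] * 5 + [0] * 5}, index=ids)
        _, (u, p) = copy_number_contrast(_annotation(copies), ga, "but")
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_direction_matches_configured_rates(self, small_cohort):
        m, meta, ann, truth = small_cohort
        ids = list(truth.signal_genomes)
        ga = GuildAssignment(tuple(ids), tuple(truth.roles[g] for g in ids))
        copies, _ = copy_number_contrast(ann, ga, "pct")
        assert copies["guild1"].mean() > copies["guild2"].mean()


class TestUniqueModules:
    def test_single_ko_module_unique_to_guild2(self):
        ga, ids = _assign(3, 3)
        ko = pd.DataFrame({"K1": [0, 0, 0, 1, 0, 1]}, index=ids)
        gene = pd.DataFrame(index=ids)
        ann = _annotation(gene, ko)
        out = unique_modules(ann, ga, {"M1": {"K1"}})
        assert out["unique_guild2"] == {"M1"}
        assert out["unique_guild1"] == set()

    def test_split_module_absent_per_genome_rule(self):
        ga, ids = _assign(3, 3)
        # K1 and K2 in different guild-1 genomes: full completeness fails
        ko = pd.DataFrame(
            {"K1": [1, 0, 0, 0, 0, 0], "K2": [0, 1, 0, 0, 0, 0]}, index=ids
        )
        ann = _annotation(pd.DataFrame(index=ids), ko)
        present = modules_present(ann, ga.members("guild1"), {"M": {"K1", "K2"}})
        assert present == set()

    def test_partial_completeness(self):
        ga, ids = _assign(3, 3)
        ko = pd.DataFrame(
            {"K1": [1, 0, 0, 0, 0, 0], "K2": [0, 1, 0, 0, 0, 0]}, index=ids
        )
        ann = _annotation(pd.DataFrame(index=ids), ko)
        present = modules_present(
            ann, ga.members("guild1"), {"M": {"K1", "K2"}}, completeness=0.5
        )
        assert present == {"M"}

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        ga, ids = _assign(4, 4)
        ko = pd.DataFrame(
            rng.integers(0, 2, (8, 6)), index=ids,
            columns=[f"K{k}" for k in range(6)],
        )
        ann = _annotation(pd.DataFrame(index=ids), ko)
        catalog = {f"M{k}": {f"K{k}", f"K{(k + 1) % 6}"} for k in range(6)}
        out = unique_modules(ann, ga, catalog)
        assert not (out["unique_guild1"] & out["unique_guild2"])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        ga, ids = _assign(5, 4)
        kos = [f"K{k}" for k in range(8)]
        ko = pd.DataFrame(rng.integers(0, 3, (9, 8)), index=ids, columns=kos)
        ann = _annotation(pd.DataFrame(index=ids), ko)
        catalog = {
            f"M{j}": set(rng.choice(kos, rng.integers(1, 4), replace=False))
            for j in range(10)
        }
        out = unique_modules(ann, ga, catalog)
        # oracle: per-module scan over genomes
        def oracle(members):
            present = set()
            for mod, need in catalog.items():
                for g in members:
                    if all(ko.loc[g, k] >= 1 for k in need):
                        present.add(mod)
                        break
            return present

        o1, o2 = oracle(ga.members("guild1")), oracle(ga.members("guild2"))
        assert out["unique_guild1"] == o1 - o2
        assert out["unique_guild2"] == o2 - o1

    def test_empty_catalog_rejected(self):
        ga, ids = _assign(3, 3)
        ann = _annotation(pd.DataFrame(index=ids), pd.DataFrame(index=ids))
        with pytest.raises(ValidationError):
            unique_modules(ann, ga, {})


class TestKoOrdination:
    def test_disjoint_ko_sets_separate(self):
        rng = np.random.default_rng(2)
        ga, ids = _assign(6, 6)
        ko = np.zeros((12, 10))
        ko[:6, :5] = rng.integers(3, 6, (6, 5))
        ko[6:, 5:] = rng.integers(3, 6, (6, 5))
        ann = _annotation(
            pd.DataFrame(index=ids),
            pd.DataFrame(ko, index=ids, columns=[f"K{k}" for k in range(10)]),
        )
        ordination, perm = ko_ordination(ann, ga, n_permutations=199, seed=0)
        assert perm.r_squared > 0.5
        assert perm.p <= 0.01

    def test_shuffled_profiles_null(self):
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(20):
            ga, ids = _assign(6, 6)
            ko = pd.DataFrame(
                rng.integers(0, 4, (12, 8)), index=ids,
                columns=[f"K{k}" for k in range(8)],
            )
            ann = _annotation(pd.DataFrame(index=ids), ko)
            _, perm = ko_ordination(ann, ga, n_permutations=99, seed=rep)
            ps.append(perm.p)
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.25

    def test_duplicated_genome_zero_distance(self):
        ga, ids = _assign(3, 3)
        ko = pd.DataFrame(
            [[1, 2]] * 2 + [[3, 1]] + [[0, 4]] * 3, index=ids, columns=["K1", "K2"]
        )
        ann = _annotation(pd.DataFrame(index=ids), ko)
        from guildscope.transforms_distance import euclidean

        d = euclidean(ko.to_numpy(float), ids)
        assert d.values[0, 1] == 0.0


class TestArgVf:
    def test_guild2_biased_burden(self, small_cohort):
        _, _, ann, truth = small_cohort
        ids = list(truth.signal_genomes)
        ga = GuildAssignment(tuple(ids), tuple(truth.roles[g] for g in ids))
        summary = arg_vf_summary(ann, ga)
        assert summary.loc["guild2", "vf_total"] > summary.loc["guild1", "vf_total"]
        assert summary.loc["guild1", "n_genomes"] == len(ga.members("guild1"))
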