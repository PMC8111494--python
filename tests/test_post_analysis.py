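import numpy as np
import pytest

from complexmap import (
    ComplexSet,
    age_group_zscores,
    enrichment_with_shuffled_fdr,
    generate_planted_complexes,
    nonredundant_set,
    promiscuous_proteins,
    subcomplex_index,
)
from complexmap.post_analysis import read_gmt, shuffle_complex_memberships


def cs(*groups, tiers=None):
    return ComplexSet([frozenset(g) for g in groups], tiers=tiers)


class TestSubcomplexIndex:
    def test_subset_is_one(self):
        assert subcomplex_index({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_half_overlap(self):
        assert subcomplex_index({1, 2, 3, 4}, {3, 4, 5, 6}) == 0.5

    def test_disjoint_zero(self):
        assert subcomplex_index({"a"}, {"b"}) == 0.0

    def test_asymmetric(self):
        a, b = {"a", "b"}, {"a", "b", "c", "d"}
        assert subcomplex_index(a, b) != subcomplex_index(b, a)

    def test_empty_a_errors(self):
        with pytest.raises(ValueError):
            subcomplex_index(set(), {"a"})


class TestNonredundantSet:
    def test_duplicates_keep_one(self):
        out = nonredundant_set(cs("abc", "abc"))
        assert len(out) == 1

    def test_nested_keeps_first_ranked(self):
        out = nonredundant_set(cs("abcdef", "abc"))
        assert out.complexes == [frozenset("abcdef")]

    def test_disjoint_all_kept(self):
        out = nonredundant_set(cs("abc", "def", "ghi"))
        assert len(out) == 3

    def test_tier_order_respected(self):
        # lower-tier big complex loses to higher-tier small one it overlaps
        inp = cs("abcd", "abcz", tiers=["Medium", "ExtremelyHigh"])
        out = nonredundant_set(inp)
        assert frozenset("abcz") in out.complexes
        assert frozenset("abcd") not in out.complexes

    def test_output_mutually_nonredundant(self, rng):
        from conftest import random_complexes

        comp = random_complexes(rng, 20, universe=30)
        out = nonredundant_set(comp, sc_cutoff=0.5)
        for i in range(len(out)):
            for j in range(len(out)):
                if i != j:
                    assert subcomplex_index(out[i], out[j]) < 0.5

    def test_symmetric_mode_can_empty_redundant_groups(self):
        out = nonredundant_set(cs("abc", "abd"), method="symmetric")
        assert len(out) == 0  # mutual SC = 2/3 >= 0.5 both ways


class TestPromiscuousProteins:
    def test_single_membership_excluded(self):
        assert promiscuous_proteins(cs("abc", "def")) == {}

    def test_double_membership_counted(self):
        assert promiscuous_proteins(cs("abc", "ade")) == {"a": 2}

    def test_no_overlap_world_empty(self):
        world = generate_planted_complexes(10, (3, 5), 0.0, 10, seed=61)
        nonred = nonredundant_set(world.complexes)
        assert promiscuous_proteins(nonred) == {}


class TestAgeZscores:
    def test_null_draw_unbiased_z(self):
        # under the null (promiscuous set is itself a random draw from the
        # same pool) each group's z is ~standard normal, so the *signed*
        # mean over seeds shrinks toward 0 while |z| per seed stays ~0.8
        proteins = [f"p{i}" for i in range(200)]
        ages = {p: ["old", "mid", "young", "ancient"][i % 4]
                for i, p in enumerate(proteins)}
        zs = []
        for seed in range(20):
            rng2 = np.random.default_rng(seed)
            prom = set(rng2.choice(proteins, 30, replace=False).tolist())
            bg = set(proteins) - prom
            df = age_group_zscores(prom, bg, ages, n_resamples=300, seed=seed)
            zs.extend(df["zscore"].dropna().tolist())
        assert abs(np.mean(zs)) < 0.5

    def test_planted_enrichment_detected(self):
        old = [f"o{i}" for i in range(60)]
        young = [f"y{i}" for i in range(60)]
        ages = {p: "old" for p in old} | {p: "young" for p in young}
        prom = set(old[:20])  # promiscuous all old
        bg = set(old[20:]) | set(young)
        df = age_group_zscores(prom, bg, ages, n_resamples=500, seed=1)
        z = dict(zip(df["age_group"], df["zscore"]))
        assert z["old"] > 3
        assert z["young"] < -3

    def test_deterministic_given_seed(self):
        proteins = [f"p{i}" for i in range(50)]
        ages = {p: "a" if i < 25 else "b" for i, p in enumerate(proteins)}
        prom, bg = set(proteins[:10]), set(proteins[10:])
        d1 = age_group_zscores(prom, bg, ages, n_resamples=100, seed=3)
        d2 = age_group_zscores(prom, bg, ages, n_resamples=100, seed=3)
        assert (d1["zscore"] == d2["zscore"]).all()

    def test_background_too_small_rejected(self):
        with pytest.raises(ValueError):
            age_group_zscores({"a", "b"}, {"c"}, {}, 10, 0)


class TestShuffledComplexes:
    def test_shuffle_preserves_sizes_and_memberships(self, rng):
        world = generate_planted_complexes(8, (3, 6), 0.3, 0, seed=62)
        orig = world.complexes
        shuf = shuffle_complex_memberships(orig, rng)
        assert sorted(len(c) for c in shuf) == sorted(len(c) for c in orig)

        def counts(csx):
            out = {}
            for c in csx:
                for p in c:
                    out[p] = out.get(p, 0) + 1
            return out

        assert counts(shuf) == counts(orig)


class TestEnrichment:
    def make_world(self, seed=63):
        world = generate_planted_complexes(8, (4, 6), 0.0, 40, seed=seed)
        return world

    def test_matching_annotation_is_most_significant(self):
        world = self.make_world()
        background = set(world.proteome)
        annotations = {f"term{i}": set(c) for i, c in enumerate(world.complexes)}
        res = enrichment_with_shuffled_fdr(
            world.complexes, annotations, background, n_shuffles=5, seed=1
        )
        # each complex's own term should be its best hit and enriched
        best = res.table.loc[res.table.groupby("complex_id")["p_value"].idxmin()]
        assert (best["term"] == [f"term{i}" for i in best["complex_id"]]).all()
        assert res.n_enriched_complexes == len(world.complexes)

    def test_random_annotations_rarely_flagged(self):
        world = self.make_world(seed=64)
        background = set(world.proteome)
        rng = np.random.default_rng(5)
        prots = sorted(background)
        annotations = {
            f"rand{i}": set(rng.choice(prots, 6, replace=False).tolist())
            for i in range(10)
        }
        res = enrichment_with_shuffled_fdr(
            world.complexes, annotations, background, n_shuffles=10, seed=2
        )
        assert res.n_enriched_complexes / res.n_complexes <= 0.25

    def test_bh_mode(self):
        world = self.make_world(seed=65)
        background = set(world.proteome)
        annotations = {"t0": set(world.complexes[0])}
        res = enrichment_with_shuffled_fdr(
            world.complexes, annotations, background, method="bh"
        )
        assert res.table.loc[res.table["complex_id"] == 0, "enriched"].any()

    def test_term_outside_background_skipped(self):
        world = self.make_world(seed=66)
        background = set(world.proteome)
        annotations = {"alien": {"NOT_A_PROTEIN"}}
        with pytest.warns(UserWarning, match="skipping"):
            res = enrichment_with_shuffled_fdr(
                world.complexes, annotations, background, n_shuffles=2, seed=0
            )
        assert res.table.empty

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "anno.gmt"
        p.write_text("t1\tdesc\ta\tb\tc\nt2\tdesc\td\te\n")
        gmt = read_gmt(p)
        assert gmt == {"t1": {"a", "b", "c"}, "t2": {"d", "e"}}
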