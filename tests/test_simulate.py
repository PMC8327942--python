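"""Forward simulator: generational cycle operations and their invariants."""

import numpy as np
import pytest
from scipy import stats

from conflictsim.protocol import build_regime
from conflictsim.simulate import (
    FEMALE, MALE, MatingEvent, Roster, ShortfallError, SimulationError,
    apply_infertility, form_matings, init_population, line_rng, migrate,
    produce_offspring, run_line, select_breeders,
)


def _tiny_roster(n_females, n_males, loci=4, kinship=None):
    """Hand-built single-deme roster of unrelated adults."""
    n = n_females + n_males
    rng = np.random.default_rng(0)
    return Roster(
        line_id="tiny", generation=0,
        ids=np.arange(n, dtype=np.int64),
        sex=np.array([FEMALE] * n_females + [MALE] * n_males, dtype=np.int8),
        deme=np.zeros(n, dtype=np.int32),
        dam=np.full(n, -1, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64),
        is_migrant=np.zeros(n, bool),
        genotypes=rng.integers(0, 2, (n, loci, 2), dtype=np.int8),
        kinship=np.eye(n) * 0.5 if kinship is None else kinship,
        F=np.zeros(n),
    )


class TestInitPopulation:
    def test_structured_layout(self, structured_poly, rng):
        roster = init_population(structured_poly, "L1", rng)
        assert len(roster) == 50
        for d in range(5):
            in_deme = roster.deme == d
            assert in_deme.sum() == 10
            assert (roster.sex[in_deme] == FEMALE).sum() == 5
            assert (roster.sex[in_deme] == MALE).sum() == 5

    def test_founders_not_inbred(self, unstructured_mono, rng):
        roster = init_population(unstructured_mono, "L1", rng)
        assert np.all(roster.F == 0)
        assert np.all(roster.dam == -1)

    def test_founder_allele_frequency(self, rng):
        # 100 allele copies per locus: per-locus SE is 0.05, so the mean
        # over 200 loci has SE 0.05/sqrt(200)
        cfg = build_regime("monogamy", False, {"neutral_loci": 200})
        roster = init_population(cfg, "L1", rng)
        p = roster.allele_freqs()
        assert abs(p.mean() - 0.5) < 4 * 0.05 / np.sqrt(200)
        assert p.std() == pytest.approx(0.05, rel=0.35)


class TestMigrate:
    def test_every_deme_gets_one_pair(self, structured_poly, rng):
        roster = init_population(structured_poly, "L1", rng)
        home = roster.deme.copy()
        roster = migrate(roster, structured_poly, rng)
        for d in range(5):
            imm = roster.is_migrant & (roster.deme == d)
            assert imm.sum() == 2
            assert (roster.sex[imm] == FEMALE).sum() == 1
            assert (roster.sex[imm] == MALE).sum() == 1
            # immigrants arrive from a single other deme
            assert len(set(home[imm])) == 1
            assert home[imm][0] != d

    def test_realized_migrant_fraction(self, structured_poly, rng):
        roster = migrate(init_population(structured_poly, "L1", rng),
                         structured_poly, rng)
        for d in range(5):
            in_deme = roster.deme == d
            assert in_deme.sum() == 10
            assert roster.is_migrant[in_deme].mean() == pytest.approx(0.2)

    def test_unstructured_is_misuse(self, unstructured_poly, rng):
        roster = init_population(unstructured_poly, "L1", rng)
        with pytest.raises(SimulationError):
            migrate(roster, unstructured_poly, rng)

    def test_no_pair_stays_home(self, structured_poly, rng):
        # derangement property, checked over several draws
        for k in range(20):
            r = np.random.default_rng(k)
            roster = init_population(structured_poly, "L1", r)
            home = roster.deme.copy()
            roster = migrate(roster, structured_poly, r)
            moved = roster.is_migrant
            assert np.all(roster.deme[moved] != home[moved])


class TestFormMatings:
    def test_monogamy_perfect_matching(self, unstructured_mono, rng):
        roster = init_population(unstructured_mono, "L1", rng)
        events = form_matings(roster, unstructured_mono, rng)
        assert len(events) == 25
        males = [ev.male_ids[0] for ev in events]
        assert len(set(males)) == 25
        assert all(len(ev.male_ids) == 1 for ev in events)

    def test_polygamy_mate_slot_range(self, unstructured_poly, rng):
        roster = init_population(unstructured_poly, "L1", rng)
        events = form_matings(roster, unstructured_poly, rng)
        slots = sum(len(ev.male_ids) for ev in events)
        assert 50 <= slots <= 75

    def test_polygamy_distinct_mates_within_deme(self, rng):
        cfg = build_regime("polygamy", True, {"mates_per_female": (3, 3)})
        roster = init_population(cfg, "L1", rng)
        events = form_matings(roster, cfg, rng)
        for ev in events:
            assert len(ev.male_ids) == 3
            assert len(set(ev.male_ids)) == 3
            mate_demes = roster.deme[list(ev.male_indices)]
            assert np.all(mate_demes == ev.deme)

    def test_empty_sex_raises(self, rng):
        roster = _tiny_roster(3, 0)
        cfg = build_regime("polygamy", False,
                           {"females_per_deme": 3, "males_per_deme": 1,
                            "mates_per_female": (1, 1)})
        with pytest.raises(ShortfallError):
            form_matings(roster, cfg, rng)


class TestApplyInfertility:
    def test_edge_rates(self, unstructured_poly, rng):
        roster = init_population(unstructured_poly, "L1", rng)
        events = form_matings(roster, unstructured_poly, rng)
        all_fertile = apply_infertility(events, 0.0, rng)
        assert all(all(ev.fertile) for ev in all_fertile)
        none_fertile = apply_infertility(events, 1.0, rng)
        assert all(not any(ev.fertile) for ev in none_fertile)
        assert all(ev.paternity_shares == (0.0,) * len(ev.male_ids)
                   for ev in none_fertile)

    def test_rate_outside_unit_interval(self, rng):
        with pytest.raises(ValueError):
            apply_infertility([], 1.2, rng)

    def test_binomial_rate(self, rng):
        # 10,000 pairings at 3%: infertile count within the binomial 99%
        # interval
        events = [MatingEvent(female_id=i, male_ids=(10_000 + i,),
                              female_index=0, male_indices=(0,), deme=0)
                  for i in range(10_000)]
        flagged = apply_infertility(events, 0.03, rng)
        n_infertile = sum(not ev.fertile[0] for ev in flagged)
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.03)
        assert lo <= n_infertile <= hi

    def test_shares_renormalized_over_fertile(self, rng):
        ev = MatingEvent(female_id=0, male_ids=(1, 2, 3), female_index=0,
                         male_indices=(1, 2, 3), deme=0,
                         fertile=(True, False, True))
        from conflictsim.simulate import _shares
        from conflictsim.protocol import build_regime
        shares = _shares(ev, build_regime("polygamy", False))
        assert shares == (0.5, 0.0, 0.5)


class TestProduceOffspring:
    def test_bean_quota(self, unstructured_mono, rng):
        roster = init_population(unstructured_mono, "L1", rng)
        events = form_matings(roster, unstructured_mono, rng)
        events = apply_infertility(events, 0.0, rng)
        pool = produce_offspring(events, unstructured_mono, roster, rng)
        assert len(pool) == 150

    def test_full_sib_offspring_inbreeding(self, rng):
        # two full sibs (shared dam and sire, unrelated grandparents) have
        # kinship 1/4, so their offspring's F is 0.25
        K = np.array([[0.5, 0.25], [0.25, 0.5]])
        roster = _tiny_roster(1, 1, kinship=K)
        cfg = build_regime("monogamy", False,
                           {"females_per_deme": 1, "males_per_deme": 1,
                            "beans_per_line": 10, "fecundity_mean": 30.0})
        events = apply_infertility(form_matings(roster, cfg, rng), 0.0, rng)
        pool = produce_offspring(events, cfg, roster, rng)
        assert np.allclose(pool.F, 0.25)

    def test_paternity_shares_binomial(self, rng):
        roster = _tiny_roster(1, 2)
        ev = MatingEvent(female_id=0, male_ids=(1, 2), female_index=0,
                         male_indices=(1, 2), deme=0)
        cfg = build_regime(
            "polygamy", False,
            {"females_per_deme": 1, "males_per_deme": 2,
             "mates_per_female": (2, 2), "beans_per_line": 10_000,
             "fecundity_mean": 11_000.0})
        pool = produce_offspring([ev], cfg, roster, rng)
        n_sire1 = int((pool.sire == roster.ids[1]).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.5)
        assert lo <= n_sire1 <= hi

    def test_shortfall_when_pool_too_small(self, rng):
        roster = _tiny_roster(1, 1)
        cfg = build_regime("monogamy", False,
                           {"females_per_deme": 1, "males_per_deme": 1,
                            "beans_per_line": 150, "fecundity_mean": 5.0})
        events = apply_infertility(form_matings(roster, cfg, rng), 0.0, rng)
        with pytest.raises(ShortfallError):
            produce_offspring(events, cfg, roster, rng)


class TestSelectBreeders:
    def test_forced_sample_is_identity(self, unstructured_mono, rng):
        pool = _tiny_roster(25, 25)
        selected = select_breeders(pool, unstructured_mono, rng)
        assert set(selected.ids) == set(pool.ids)

    def test_shortfall_on_missing_sex(self, structured_poly, rng):
        pool = _tiny_roster(30, 30)   # every member in deme 0
        with pytest.raises(ShortfallError):
            select_breeders(pool, structured_poly, rng)


class TestRunLine:
    def test_seeded_determinism(self, structured_poly):
        a = run_line(structured_poly, "SPoly-1", 7, n_generations=4)
        b = run_line(structured_poly, "SPoly-1", 7, n_generations=4)
        assert a.to_frame().equals(b.to_frame())
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.allele_freqs, b.allele_freqs))

    def test_census_constancy(self, unstructured_mono):
        log = run_line(unstructured_mono, "NSMono-1", 3, n_generations=10)
        for s in log.stats:
            assert s.n_breeders == 50
            assert s.n_females == 25
            assert s.n_males == 25

    def test_family_sizes_account_for_all_breeders(self, unstructured_poly):
        log = run_line(unstructured_poly, "NSPoly-1", 11, n_generations=5)
        for s in log.stats[1:]:
            # 25 dams and 25 sires each parent exactly 50 selected breeders
            assert s.kbar_f * 25 == pytest.approx(50)
            assert s.kbar_m * 25 == pytest.approx(50)

    def test_pedigree_export(self, unstructured_mono):
        log = run_line(unstructured_mono, "NSMono-1", 3, n_generations=2,
                       full_pedigree=True)
        ped = log.pedigree_frame()
        assert len(ped) == 50 * 3
        assert set(ped.columns) >= {"id", "sex", "deme", "dam_id", "sire_id",
                                    "generation", "F_ped"}

    def test_allele_frequency_martingale(self):
        # drift is directionless: over replicates the mean per-locus
        # frequency change from founders to generation 1 is ~0
        cfg = build_regime("monogamy", False, {"neutral_loci": 50})
        deltas = []
        for r in range(200):
            log = run_line(cfg, "NSMono-1", np.random.SeedSequence([5, r]),
                           n_generations=1)
            deltas.append(log.allele_freqs[1] - log.allele_freqs[0])
        deltas = np.concatenate(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se

    def test_heterozygosity_declines(self, unstructured_mono):
        # expected H loss per generation ~ 1/(2Ne); check the direction
        # over a replicate average
        hs = []
        for r in range(30):
            log = run_line(unstructured_mono, "NSMono-1",
                           np.random.SeedSequence([9, r]), n_generations=8)
            hs.append([s.mean_heterozygosity for s in log.stats])
        h = np.mean(hs, axis=0)
        assert h[-1] < h[0]
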