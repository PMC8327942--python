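"""Forward Monte Carlo simulation of one selection line's generational cycle.

Each generation mirrors the husbandry protocol exactly: virgin breeders are
(optionally) migrated between demes, mated according to the regime's mating
system, a fraction of pairings may be infertile, females lay one egg per
bean, 150 inoculated beans are sampled per line, and the next generation's
virgin breeders are drawn at random from the emerging adults.

Pedigree inbreeding is propagated exactly through a kinship matrix over the
current breeders (an offspring's F equals the kinship of its parents), and
neutral biallelic loci are transmitted by Mendelian segregation so that
drift can be measured from allele frequencies.

The roster is stored as a structure of arrays for speed; :class:`Individual`
offers a per-animal view for export and inspection.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .protocol import MONOGAMY, RegimeConfig

FEMALE, MALE = 0, 1
FOUNDER = -1  # parent id marker for generation-0 individuals


class SimulationError(RuntimeError):
    """Base class for simulator failures."""


class ShortfallError(SimulationError):
    """Too few offspring (or offspring of one sex) to continue the line."""

    def __init__(self, message: str, line_id: str | None = None,
                 generation: int | None = None):
        super().__init__(message)
        self.line_id = line_id
        self.generation = generation


@dataclass(frozen=True)
class Individual:
    """Per-animal view of a roster row (export / inspection only)."""

    id: int
    sex: str
    line_id: str
    deme: int
    dam_id: int
    sire_id: int
    generation: int
    F_ped: float
    is_migrant: bool


@dataclass
class Roster:
    """One generation's breeders as parallel arrays.

    ``kinship`` is the pedigree kinship (coancestry) matrix among members,
    relative to the unrelated founders; ``F`` is each member's pedigree
    inbreeding coefficient (the kinship of its parents).
    """

    line_id: str
    generation: int
    ids: np.ndarray          # (N,) int64, unique within a run
    sex: np.ndarray          # (N,) int8, 0=F 1=M
    deme: np.ndarray         # (N,) int32
    dam: np.ndarray          # (N,) int64, FOUNDER for generation 0
    sire: np.ndarray         # (N,) int64
    is_migrant: np.ndarray   # (N,) bool
    genotypes: np.ndarray    # (N, L, 2) int8 allele codes {0, 1}
    kinship: np.ndarray      # (N, N) float64
    F: np.ndarray            # (N,) float64

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_females(self) -> int:
        return int(np.sum(self.sex == FEMALE))

    @property
    def n_males(self) -> int:
        return int(np.sum(self.sex == MALE))

    def allele_freqs(self) -> np.ndarray:
        """Per-locus frequency of allele 1 across all members."""
        return self.genotypes.mean(axis=(0, 2))

    def individuals(self) -> Iterator[Individual]:
        for i in range(len(self)):
            yield Individual(
                id=int(self.ids[i]),
                sex="F" if self.sex[i] == FEMALE else "M",
                line_id=self.line_id,
                deme=int(self.deme[i]),
                dam_id=int(self.dam[i]),
                sire_id=int(self.sire[i]),
                generation=self.generation,
                F_ped=float(self.F[i]),
                is_migrant=bool(self.is_migrant[i]),
            )


@dataclass
class MatingEvent:
    """One female's matings for the current generation.

    ``male_ids`` is ordered (mating order matters under last-male paternity
    precedence); ``fertile`` flags each pairing; ``paternity_shares`` are
    the per-male siring probabilities, summing to 1 over fertile mates and
    empty when no mate is fertile.
    """

    female_id: int
    male_ids: tuple[int, ...]
    female_index: int                  # row in the breeder roster
    male_indices: tuple[int, ...]
    deme: int
    fertile: tuple[bool, ...] = ()
    paternity_shares: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.fertile:
            self.fertile = tuple(True for _ in self.male_ids)
        if not self.paternity_shares:
            n = len(self.male_ids)
            self.paternity_shares = tuple(1.0 / n for _ in range(n))

    @property
    def n_fertile(self) -> int:
        return sum(self.fertile)


@dataclass
class GenerationStats:
    """Generation-level summary row of a :class:`PedigreeLog`."""

    generation: int
    n_breeders: int
    n_females: int
    n_males: int
    mean_F: float
    mean_heterozygosity: float      # mean over loci of 2p(1-p)
    kbar_f: float = np.nan          # mean selected offspring per dam
    vk_f: float = np.nan
    kbar_m: float = np.nan
    vk_m: float = np.nan
    n_mating_events: int = 0
    n_infertile_pairings: int = 0
    pool_size: int = 0              # eggs laid before bean sampling


@dataclass
class PedigreeLog:
    """Per-generation record of one simulated line."""

    line_id: str
    config: RegimeConfig
    seed_entropy: tuple[int, ...]
    stats: list[GenerationStats] = field(default_factory=list)
    allele_freqs: list[np.ndarray] = field(default_factory=list)
    pedigree: list[Individual] = field(default_factory=list)

    @property
    def n_generations(self) -> int:
        return len(self.stats) - 1

    def mean_F(self, generation: int) -> float:
        return self.stats[generation].mean_F

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(s) for s in self.stats])
        df.insert(0, "line_id", self.line_id)
        return df

    def pedigree_frame(self) -> pd.DataFrame:
        if not self.pedigree:
            raise ValueError("run_line(..., full_pedigree=True) required for "
                             "a pedigree export")
        return pd.DataFrame([vars(i) for i in self.pedigree])


# ---------------------------------------------------------------------------
# RNG plumbing

def line_rng(seed, line_id: str) -> np.random.Generator:
    """A named-stream generator derived from (master seed, line_id)."""
    if isinstance(seed, np.random.SeedSequence):
        entropy = list(np.atleast_1d(seed.entropy)) + list(seed.spawn_key)
    else:
        entropy = [int(seed)]
    entropy.append(zlib.crc32(line_id.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _seed_entropy(seed, line_id: str) -> tuple[int, ...]:
    if isinstance(seed, np.random.SeedSequence):
        base = tuple(int(v) for v in np.atleast_1d(seed.entropy))
    else:
        base = (int(seed),)
    return base + (zlib.crc32(line_id.encode()),)


# ---------------------------------------------------------------------------
# Generational cycle operations

def init_population(config: RegimeConfig, line_id: str,
                    rng: np.random.Generator) -> Roster:
    """Unrelated founders filled to the config's per-deme sex counts.

    Genotypes are drawn per locus at allele frequency 0.5 under random
    union of gametes; founders carry F = 0 and no parents.
    """
    per_deme = config.females_per_deme + config.males_per_deme
    n = config.census_size
    sex = np.tile(
        np.r_[np.full(config.females_per_deme, FEMALE, dtype=np.int8),
              np.full(config.males_per_deme, MALE, dtype=np.int8)],
        config.n_demes)
    deme = np.repeat(np.arange(config.n_demes, dtype=np.int32), per_deme)
    genotypes = rng.integers(0, 2, size=(n, config.neutral_loci, 2), dtype=np.int8)
    kinship = np.eye(n) * 0.5  # self-kinship of a non-inbred individual
    return Roster(
        line_id=line_id, generation=0,
        ids=np.arange(n, dtype=np.int64),
        sex=sex, deme=deme,
        dam=np.full(n, FOUNDER, dtype=np.int64),
        sire=np.full(n, FOUNDER, dtype=np.int64),
        is_migrant=np.zeros(n, dtype=bool),
        genotypes=genotypes, kinship=kinship,
        F=np.zeros(n),
    )


def migrate(roster: Roster, config: RegimeConfig,
            rng: np.random.Generator) -> Roster:
    """Relocate one (or ``migrant_pairs_per_deme``) male-female pair(s)
    out of every deme along a uniformly sampled derangement of demes.

    Every deme therefore receives exactly its quota of immigrant pairs from
    a single other deme, no pair stays home, and deme sizes and sex ratios
    are unchanged.  Relocated individuals are flagged ``is_migrant``.
    """
    if not config.structured:
        raise SimulationError("migrate() requires a structured (multi-deme) config")
    k = config.migrant_pairs_per_deme
    deme = roster.deme.copy()
    is_migrant = np.zeros(len(roster), dtype=bool)
    if k == 0:
        roster.deme = deme
        roster.is_migrant = is_migrant
        return roster

    # uniform derangement by rejection: no deme keeps its own migrants
    n_demes = config.n_demes
    while True:
        target = rng.permutation(n_demes)
        if not np.any(target == np.arange(n_demes)):
            break

    for d in range(n_demes):
        for sex_code in (FEMALE, MALE):
            residents = np.flatnonzero((deme == d) & (roster.sex == sex_code)
                                       & ~is_migrant)
            if len(residents) < k:
                raise ShortfallError(
                    f"deme {d} holds {len(residents)} residents of sex "
                    f"{sex_code}, fewer than {k} migrants required",
                    line_id=roster.line_id, generation=roster.generation)
            chosen = rng.choice(residents, size=k, replace=False)
            deme[chosen] = target[d]
            is_migrant[chosen] = True
    roster.deme = deme
    roster.is_migrant = is_migrant
    return roster


def form_matings(roster: Roster, config: RegimeConfig,
                 rng: np.random.Generator) -> list[MatingEvent]:
    """Pair every female with mates from her own deme.

    Monogamy: a uniformly random perfect matching of females to males
    within each deme.  Polygamy: each female draws ``m`` distinct males
    uniformly from her deme, with ``m`` uniform over the configured
    inclusive range; males may serve several females.
    """
    events: list[MatingEvent] = []
    lo, hi = config.mates_per_female
    for d in range(config.n_demes):
        females = np.flatnonzero((roster.deme == d) & (roster.sex == FEMALE))
        males = np.flatnonzero((roster.deme == d) & (roster.sex == MALE))
        if len(females) == 0 or len(males) == 0:
            raise ShortfallError(f"deme {d} lacks one sex entirely",
                                 line_id=roster.line_id,
                                 generation=roster.generation)
        if config.mating_system == MONOGAMY:
            if len(females) != len(males):
                raise ShortfallError(
                    f"monogamy needs equal sex counts in deme {d} "
                    f"({len(females)}F vs {len(males)}M)",
                    line_id=roster.line_id, generation=roster.generation)
            partners = rng.permutation(males)
            for f_idx, m_idx in zip(females, partners):
                events.append(MatingEvent(
                    female_id=int(roster.ids[f_idx]),
                    male_ids=(int(roster.ids[m_idx]),),
                    female_index=int(f_idx), male_indices=(int(m_idx),),
                    deme=d))
        else:
            for f_idx in females:
                m = int(rng.integers(lo, hi + 1))
                mates = rng.choice(males, size=m, replace=False)
                events.append(MatingEvent(
                    female_id=int(roster.ids[f_idx]),
                    male_ids=tuple(int(roster.ids[i]) for i in mates),
                    female_index=int(f_idx),
                    male_indices=tuple(int(i) for i in mates),
                    deme=d))
    return events


def _shares(event: MatingEvent, config: RegimeConfig) -> tuple[float, ...]:
    """Paternity shares over the event's fertile mates."""
    fertile_idx = [i for i, ok in enumerate(event.fertile) if ok]
    n = len(fertile_idx)
    shares = [0.0] * len(event.male_ids)
    if n == 0:
        return tuple(shares)
    if config.paternity_mode == "last_male" and n > 1:
        last = fertile_idx[-1]
        rest = (1.0 - config.last_male_share) / (n - 1)
        for i in fertile_idx:
            shares[i] = config.last_male_share if i == last else rest
    else:
        for i in fertile_idx:
            shares[i] = 1.0 / n
    return tuple(shares)


def apply_infertility(events: Sequence[MatingEvent], rate: float,
                      rng: np.random.Generator,
                      config: RegimeConfig | None = None) -> list[MatingEvent]:
    """Flag each female-male pairing independently infertile with
    probability ``rate`` and renormalize paternity shares over fertile
    mates.  Events with no fertile mate contribute no offspring."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("infertility rate must lie in [0, 1]")
    out = []
    for ev in events:
        if rate == 0.0:
            fertile = tuple(True for _ in ev.male_ids)
        else:
            fertile = tuple(bool(v) for v in rng.random(len(ev.male_ids)) >= rate)
        new = MatingEvent(female_id=ev.female_id, male_ids=ev.male_ids,
                          female_index=ev.female_index,
                          male_indices=ev.male_indices, deme=ev.deme,
                          fertile=fertile)
        new.paternity_shares = _shares(
            new, config if config is not None else _EQUAL_SHARES)
        out.append(new)
    return out


class _EqualShares:
    paternity_mode = "equal"
    last_male_share = 0.5


_EQUAL_SHARES = _EqualShares()


def produce_offspring(events: Sequence[MatingEvent], config: RegimeConfig,
                      roster: Roster, rng: np.random.Generator,
                      next_ids_start: int = 0) -> Roster:
    """Lay eggs, sample beans, and rear the emerging adults.

    Each female with at least one fertile mate lays a Poisson
    (``fecundity_mean``) number of eggs, one per bean; the bean supply is
    downsampled uniformly without replacement to ``beans_per_line``, and
    every sampled bean yields one adult with sex 50:50, Mendelian genotype,
    and pedigree F equal to its parents' kinship.  Offspring emerge in
    their dam's deme.

    Each deme is a physically separate container, so under subdivision the
    bean quota is split evenly across demes (150 per line = 30 per deme for
    the default layout) and each deme's beans are sampled from its own
    females' eggs.
    """
    fertile_events = [ev for ev in events if ev.n_fertile > 0]
    counts = rng.poisson(config.fecundity_mean, size=len(fertile_events))
    pool_size = int(counts.sum())

    # per-deme bean quotas (even split, remainder to the first demes)
    base, rem = divmod(config.beans_per_line, config.n_demes)
    quotas = np.full(config.n_demes, base, dtype=int)
    quotas[:rem] += 1

    ev_deme = np.array([ev.deme for ev in fertile_events], dtype=int)
    dam_events = np.empty(config.beans_per_line, dtype=int)
    pos = 0
    for d in range(config.n_demes):
        members = np.flatnonzero(ev_deme == d)
        deme_counts = counts[members]
        deme_pool = int(deme_counts.sum())
        if deme_pool < quotas[d]:
            raise ShortfallError(
                f"line {roster.line_id}: deme {d} laid {deme_pool} eggs, "
                f"cannot fill {quotas[d]} beans at generation "
                f"{roster.generation + 1}",
                line_id=roster.line_id, generation=roster.generation + 1)
        # sample bean slots from the deme's egg multiset; eggs are
        # exchangeable within a female, so only the dam composition matters
        owner = np.repeat(members, deme_counts)
        sampled = rng.choice(deme_pool, size=quotas[d], replace=False)
        dam_events[pos:pos + quotas[d]] = owner[sampled]
        pos += quotas[d]

    n = config.beans_per_line
    dam_idx = np.empty(n, dtype=np.int64)
    sire_idx = np.empty(n, dtype=np.int64)
    for j, e in enumerate(dam_events):
        ev = fertile_events[e]
        dam_idx[j] = ev.female_index
        shares = np.asarray(ev.paternity_shares)
        choice = rng.choice(len(ev.male_indices), p=shares)
        sire_idx[j] = ev.male_indices[choice]

    L = roster.genotypes.shape[1]
    loci = np.arange(L)
    pick_d = rng.integers(0, 2, size=(n, L))
    pick_s = rng.integers(0, 2, size=(n, L))
    geno = np.empty((n, L, 2), dtype=np.int8)
    geno[:, :, 0] = roster.genotypes[dam_idx[:, None], loci[None, :], pick_d]
    geno[:, :, 1] = roster.genotypes[sire_idx[:, None], loci[None, :], pick_s]

    K = roster.kinship
    F_off = K[dam_idx, sire_idx]
    k_off = 0.25 * (K[np.ix_(dam_idx, dam_idx)] + K[np.ix_(dam_idx, sire_idx)]
                    + K[np.ix_(sire_idx, dam_idx)] + K[np.ix_(sire_idx, sire_idx)])
    np.fill_diagonal(k_off, 0.5 * (1.0 + F_off))

    pool = Roster(
        line_id=roster.line_id, generation=roster.generation + 1,
        ids=next_ids_start + np.arange(n, dtype=np.int64),
        sex=rng.integers(0, 2, size=n).astype(np.int8),
        deme=roster.deme[dam_idx].copy(),
        dam=roster.ids[dam_idx].copy(),
        sire=roster.ids[sire_idx].copy(),
        is_migrant=np.zeros(n, dtype=bool),
        genotypes=geno, kinship=k_off, F=F_off,
    )
    pool.pool_size = pool_size  # type: ignore[attr-defined]
    return pool


def select_breeders(pool: Roster, config: RegimeConfig,
                    rng: np.random.Generator) -> Roster:
    """Uniform random sample without replacement filling each deme's
    per-sex breeder quota from that deme's emerged adults."""
    chosen: list[np.ndarray] = []
    for d in range(config.n_demes):
        for sex_code, need in ((FEMALE, config.females_per_deme),
                               (MALE, config.males_per_deme)):
            avail = np.flatnonzero((pool.deme == d) & (pool.sex == sex_code))
            if len(avail) < need:
                raise ShortfallError(
                    f"deme {d} emerged only {len(avail)} adults of sex "
                    f"{sex_code}, {need} breeders required",
                    line_id=pool.line_id, generation=pool.generation)
            chosen.append(rng.choice(avail, size=need, replace=False))
    idx = np.concatenate(chosen)
    return Roster(
        line_id=pool.line_id, generation=pool.generation,
        ids=pool.ids[idx], sex=pool.sex[idx], deme=pool.deme[idx],
        dam=pool.dam[idx], sire=pool.sire[idx],
        is_migrant=pool.is_migrant[idx],
        genotypes=pool.genotypes[idx],
        kinship=pool.kinship[np.ix_(idx, idx)],
        F=pool.F[idx],
    )


def _family_stats(parent_ids: np.ndarray,
                  selected_parent_of: np.ndarray) -> tuple[float, float]:
    """Mean and variance of selected-offspring counts per candidate parent."""
    counts = np.array([(selected_parent_of == pid).sum() for pid in parent_ids],
                      dtype=float)
    return float(counts.mean()), float(counts.var(ddof=0))


def _log_generation(log: PedigreeLog, roster: Roster, **extra) -> None:
    p = roster.allele_freqs()
    het = float(np.mean(2.0 * p * (1.0 - p)))
    log.stats.append(GenerationStats(
        generation=roster.generation, n_breeders=len(roster),
        n_females=roster.n_females, n_males=roster.n_males,
        mean_F=float(roster.F.mean()), mean_heterozygosity=het, **extra))
    log.allele_freqs.append(p)


def run_line(config: RegimeConfig, line_id: str, seed,
             n_generations: int | None = None,
             full_pedigree: bool = False) -> PedigreeLog:
    """Run one line's full propagation protocol for ``n_generations``.

    The run is a pure function of ``(config, line_id, seed)``: the same
    inputs reproduce a bit-identical log.
    """
    gens = config.n_generations if n_generations is None else int(n_generations)
    rng = line_rng(seed, line_id)
    log = PedigreeLog(line_id=line_id, config=config,
                      seed_entropy=_seed_entropy(seed, line_id))
    roster = init_population(config, line_id, rng)
    _log_generation(log, roster)
    if full_pedigree:
        log.pedigree.extend(roster.individuals())

    next_id = len(roster)
    for _ in range(gens):
        if config.structured:
            roster = migrate(roster, config, rng)
        events = form_matings(roster, config, rng)
        events = apply_infertility(events, config.infertility_rate, rng, config)
        n_infertile = sum(len(ev.fertile) - ev.n_fertile for ev in events)
        pool = produce_offspring(events, config, roster, rng,
                                 next_ids_start=next_id)
        next_id += len(pool)
        breeders = select_breeders(pool, config, rng)

        dams = roster.ids[roster.sex == FEMALE]
        sires = roster.ids[roster.sex == MALE]
        kbar_f, vk_f = _family_stats(dams, breeders.dam)
        kbar_m, vk_m = _family_stats(sires, breeders.sire)
        roster = breeders
        _log_generation(log, roster, kbar_f=kbar_f, vk_f=vk_f,
                        kbar_m=kbar_m, vk_m=vk_m,
                        n_mating_events=len(events),
                        n_infertile_pairings=n_infertile,
                        pool_size=getattr(pool, "pool_size", 0))
        if full_pedigree:
            log.pedigree.extend(roster.individuals())
    return log


__all__ = [
    "FEMALE", "MALE", "FOUNDER",
    "SimulationError", "ShortfallError",
    "Individual", "Roster", "MatingEvent", "GenerationStats", "PedigreeLog",
    "line_rng", "init_population", "migrate", "form_matings",
    "apply_infertility", "produce_offspring", "select_breeders", "run_line",
]
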