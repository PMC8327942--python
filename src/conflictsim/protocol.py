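"""Experimental-design configuration for the 2x2 selection experiment.

The design crosses two mating systems (enforced monogamy vs. polygamy) with
two levels of spatial structure (a single panmictic population vs. a
metapopulation of five demes exchanging one male-female migrant pair per
deme per generation).  Every selection line carries 50 breeders (25 females,
25 males); under subdivision these are split into five demes of 5+5, which
fixes the per-deme migration rate at 2/10 = 20%.

Configurations are immutable after validation, so a simulation run is a pure
function of ``(config, seed)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from typing import Any, Iterable, Mapping

import yaml

MONOGAMY = "monogamy"
POLYGAMY = "polygamy"

#: Canonical regime labels: (mating_system, structured).
REGIME_LABELS: dict[str, tuple[str, bool]] = {
    "NSPoly": (POLYGAMY, False),
    "SPoly": (POLYGAMY, True),
    "NSMono": (MONOGAMY, False),
    "SMono": (MONOGAMY, True),
}


class ConfigError(ValueError):
    """A breeding-design configuration violates an invariant."""


@dataclass(frozen=True)
class RegimeConfig:
    """Full breeding-design parameters for one selection regime.

    Attributes
    ----------
    mating_system:
        ``"monogamy"`` (each female paired with one male) or ``"polygamy"``
        (each female mates a random number of distinct males from her deme).
    structured:
        Whether the line is subdivided into demes with migration.
    n_demes, females_per_deme, males_per_deme:
        Deme layout; census size is ``n_demes * (females + males)``.
    migrant_pairs_per_deme:
        Male-female pairs relocated out of (and into) every deme each
        generation; 1 pair in a 5+5 deme imposes a 20% migration rate.
    mates_per_female:
        Inclusive integer range of mate numbers per female under polygamy;
        forced to ``(1, 1)`` under monogamy.
    infertility_rate:
        Per-pairing probability that a mating leaves no offspring.
    beans_per_line:
        Oviposition substrate sampled per line per generation (one egg per
        bean; each bean yields one emerging adult).
    fecundity_mean:
        Mean of the Poisson egg count per female with at least one fertile
        mate.  Only its relative variance matters after bean downsampling.
    paternity_mode:
        ``"equal"`` shares among a female's fertile mates, or
        ``"last_male"`` precedence with ``last_male_share`` to the final mate.
    """

    mating_system: str
    structured: bool
    n_demes: int
    females_per_deme: int
    males_per_deme: int
    migrant_pairs_per_deme: int
    mates_per_female: tuple[int, int] = (1, 1)
    infertility_rate: float = 0.0
    beans_per_line: int = 150
    n_generations: int = 10
    neutral_loci: int = 100
    fecundity_mean: float = 40.0
    paternity_mode: str = "equal"
    last_male_share: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "mates_per_female",
                           tuple(int(v) for v in self.mates_per_female))
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.mating_system not in (MONOGAMY, POLYGAMY):
            raise ConfigError(f"unknown mating_system {self.mating_system!r}")
        if self.n_demes < 1:
            raise ConfigError("n_demes must be a positive integer")
        if self.females_per_deme < 1 or self.males_per_deme < 1:
            raise ConfigError("each deme must hold at least one breeder of each sex")
        if self.structured != (self.n_demes > 1):
            raise ConfigError(
                "structured=true requires n_demes > 1 and vice versa "
                f"(got structured={self.structured}, n_demes={self.n_demes})")
        if self.migrant_pairs_per_deme < 0:
            raise ConfigError("migrant_pairs_per_deme must be non-negative")
        if self.n_demes == 1 and self.migrant_pairs_per_deme != 0:
            raise ConfigError("migrant_pairs_per_deme must be 0 for an undivided line")
        if self.migrant_pairs_per_deme > min(self.females_per_deme, self.males_per_deme):
            raise ConfigError(
                "migrant_pairs_per_deme exceeds the per-deme count of a sex")
        lo, hi = self.mates_per_female
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid mates_per_female range {self.mates_per_female}")
        if self.mating_system == MONOGAMY and (lo, hi) != (1, 1):
            raise ConfigError("monogamy forces mates_per_female = (1, 1)")
        if hi > self.males_per_deme:
            raise ConfigError(
                "mates_per_female upper bound exceeds males available in a deme")
        if not 0.0 <= self.infertility_rate <= 1.0:
            raise ConfigError("infertility_rate must lie in [0, 1]")
        if self.beans_per_line < 1 or self.n_generations < 1 or self.neutral_loci < 1:
            raise ConfigError("beans_per_line, n_generations and neutral_loci must be positive")
        if self.fecundity_mean <= 0:
            raise ConfigError("fecundity_mean must be positive")
        if self.paternity_mode not in ("equal", "last_male"):
            raise ConfigError(f"unknown paternity_mode {self.paternity_mode!r}")
        if not 0.0 <= self.last_male_share <= 1.0:
            raise ConfigError("last_male_share must lie in [0, 1]")

    # -- derived quantities ---------------------------------------------
    @property
    def census_size(self) -> int:
        return self.n_demes * (self.females_per_deme + self.males_per_deme)

    @property
    def migration_rate(self) -> float:
        """Realized per-deme migrant fraction (0 for undivided lines)."""
        if not self.structured:
            return 0.0
        return (2 * self.migrant_pairs_per_deme
                / (self.females_per_deme + self.males_per_deme))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["mates_per_female"] = list(self.mates_per_female)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RegimeConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def fingerprint(self) -> str:
        """Content hash, independent of key ordering in any source file."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ExperimentDesign:
    """An ordered collection of selection lines with their regime configs."""

    lines: tuple[tuple[str, RegimeConfig], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lines", tuple((str(i), c) for i, c in self.lines))
        ids = [i for i, _ in self.lines]
        if len(ids) != len(set(ids)):
            raise ConfigError("line_ids must be unique")
        if not ids:
            raise ConfigError("a design needs at least one line")

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)

    def regime_of(self, line_id: str) -> RegimeConfig:
        for lid, cfg in self.lines:
            if lid == line_id:
                return cfg
        raise KeyError(line_id)

    def to_dict(self) -> dict[str, Any]:
        return {"lines": [{"line_id": lid, **cfg.to_dict()} for lid, cfg in self.lines]}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ExperimentDesign":
        unknown = set(data) - {"lines"}
        if unknown:
            raise ConfigError(f"unknown design keys: {sorted(unknown)}")
        lines = []
        for entry in data["lines"]:
            entry = dict(entry)
            lid = entry.pop("line_id")
            lines.append((lid, RegimeConfig.from_dict(entry)))
        return cls(lines=tuple(lines))

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Builders

#: Documented infertility scenario: observed rates stay below 3% in all lines.
INFERTILITY_SCENARIO_RATE = 0.03


def build_regime(mating_system: str, structured: bool,
                 overrides: Mapping[str, Any] | None = None) -> RegimeConfig:
    """Build one regime with the study's default layout.

    Unstructured lines hold a single population of 25 females + 25 males;
    structured lines hold 5 demes of 5+5 exchanging one migrant pair per
    deme.  Polygamy defaults to 2-3 mates per female.
    """
    if structured:
        base: dict[str, Any] = dict(n_demes=5, females_per_deme=5,
                                    males_per_deme=5, migrant_pairs_per_deme=1)
    else:
        base = dict(n_demes=1, females_per_deme=25, males_per_deme=25,
                    migrant_pairs_per_deme=0)
    base.update(mating_system=mating_system, structured=structured)
    base["mates_per_female"] = (1, 1) if mating_system == MONOGAMY else (2, 3)
    if overrides:
        known = {f.name for f in fields(RegimeConfig)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"unknown override keys: {sorted(unknown)}")
        base.update(overrides)
    return RegimeConfig(**base)


def build_default_design() -> ExperimentDesign:
    """The full 2x2 design: 4 replicate lines per regime, 16 lines total."""
    lines = []
    for label in ("NSPoly", "SPoly", "NSMono", "SMono"):
        ms, structured = REGIME_LABELS[label]
        cfg = build_regime(ms, structured)
        for rep in range(1, 5):
            lines.append((f"{label}-{rep}", cfg))
    return ExperimentDesign(lines=tuple(lines))


def regime_label(config: RegimeConfig) -> str:
    """Map a config back onto the regime nomenclature (NSPoly, SMono, ...)."""
    for label, (ms, structured) in REGIME_LABELS.items():
        if config.mating_system == ms and config.structured == structured:
            return label
    return f"{config.mating_system}-{'S' if config.structured else 'NS'}"


# ---------------------------------------------------------------------------
# Plain-text round trip

def design_to_yaml(design: ExperimentDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


def design_from_yaml(path) -> ExperimentDesign:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ExperimentDesign.from_dict(data)


__all__ = [
    "MONOGAMY", "POLYGAMY", "REGIME_LABELS", "INFERTILITY_SCENARIO_RATE",
    "ConfigError", "RegimeConfig", "ExperimentDesign",
    "build_regime", "build_default_design", "regime_label",
    "design_to_yaml", "design_from_yaml", "replace",
]
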