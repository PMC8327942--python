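"""Effective population size estimators for the breeding protocol.

Four routes to Ne are provided, all standard in the experimental-evolution
literature:

``sex_ratio``
    4 Nm Nf / (Nm + Nf) from breeder counts alone.
``family_size_variance``
    Per-sex Ne = (n k̄ − 1) / (k̄ − 1 + Vk / k̄) from the realized mean and
    variance of family sizes, the two sexes combined as an unequal-sex-ratio
    harmonic mean.
``pedigree_inbreeding``
    Ne = 1 / (2 ΔF) with ΔF the per-generation rate of increase of mean
    pedigree inbreeding, measured against a burn-in baseline.
``temporal_allele_frequency``
    Ne = t / (2 F̄c) from the standardized variance of neutral allele
    frequency change, Fc = (p0 − pt)² / (p̄ (1 − p̄)), p̄ = (p0 + pt)/2.
    No sampling corrections are applied: the simulator observes true census
    frequencies.

The Monte Carlo driver replays the full line-propagation protocol per
replicate and summarizes each estimator by its median and 2.5–97.5
percentile interval, which is robust to the heavy right tail of Ne
estimates (a replicate with almost no drift yields a huge or infinite Ne).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .protocol import RegimeConfig, regime_label
from .simulate import PedigreeLog, ShortfallError, run_line

_FLOOR = 1e-12

SEX_RATIO = "sex_ratio"
FAMILY_SIZE = "family_size_variance"
INBREEDING = "pedigree_inbreeding"
TEMPORAL = "temporal_allele_frequency"
METHODS = (SEX_RATIO, FAMILY_SIZE, INBREEDING, TEMPORAL)


@dataclass(frozen=True)
class NeEstimate:
    """One effective-size estimate with its provenance."""

    method: str
    value: float                       # may be math.inf when no drift is seen
    ci: tuple[float, float] | None = None
    regime: str | None = None
    replicates: int | None = None
    generations: int | None = None
    infertility_rate: float = 0.0

    def __post_init__(self):
        if not (self.value > 0):
            raise ValueError("Ne estimate must be positive (or infinite)")
        if self.ci is not None and not (self.ci[0] <= self.value <= self.ci[1]):
            raise ValueError("percentile CI must contain the point estimate")

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.value)


# ---------------------------------------------------------------------------
# Closed forms

def ne_sex_ratio(n_males: int, n_females: int) -> float:
    """Unequal-sex-ratio effective size, 4 Nm Nf / (Nm + Nf)."""
    if n_males < 1 or n_females < 1:
        raise ValueError("both sexes need at least one breeder")
    return 4.0 * n_males * n_females / (n_males + n_females)


def ne_family_size(n: int, k_bar: float, v_k: float) -> float:
    """Per-sex family-size-variance effective size (n k̄ − 1)/(k̄ − 1 + Vk/k̄).

    Equalized families (Vk = 0) give ≈ 2n; Poisson families (Vk = k̄) give
    ≈ n.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if k_bar <= 0:
        raise ValueError("mean family size must be positive")
    if v_k < 0:
        raise ValueError("family-size variance cannot be negative")
    denom = k_bar - 1.0 + v_k / k_bar
    if denom <= _FLOOR:
        return float("inf")
    return (n * k_bar - 1.0) / denom


def combine_sexes(ne_f: float, ne_m: float) -> float:
    """Combine per-sex effective sizes: 4 NeF NeM / (NeF + NeM)."""
    if ne_f <= 0 or ne_m <= 0:
        raise ValueError("per-sex Ne must be positive")
    if np.isinf(ne_f) and np.isinf(ne_m):
        return float("inf")
    return 4.0 * ne_f * ne_m / (ne_f + ne_m)


# ---------------------------------------------------------------------------
# Pedigree- and frequency-based estimators

def default_burn_in(config: RegimeConfig) -> int:
    """Burn-in (baseline generation) for the inbreeding-rate estimator.

    Undivided lines only need one generation to discount the artificially
    non-inbred founders.  Subdivided lines additionally show a fast initial
    rise of mean pedigree F while within-deme coancestry approaches its
    migration-drift quasi-equilibrium; only after that mixing phase does F
    grow at the metapopulation rate that defines the regime's Ne.  The
    baseline is therefore placed one migrant residence time into the run,
    ceil(1/m) generations for migration rate m.
    """
    if not config.structured or config.migration_rate == 0:
        return 1
    return int(np.ceil(1.0 / config.migration_rate))


def ne_from_inbreeding(log: PedigreeLog, burn_in: int | None = None) -> float:
    """Inbreeding effective size 1/(2 ΔF) from a pedigree log.

    ΔF is the per-generation rate such that (1 − F) decays geometrically
    from the burn-in baseline: ΔF = 1 − ((1 − F_T)/(1 − F_b))^(1/(T − b)).
    ``burn_in=None`` resolves via :func:`default_burn_in` (one generation
    for undivided lines, the migration mixing time for subdivided ones).
    """
    if burn_in is None:
        burn_in = default_burn_in(log.config)
    T = log.n_generations
    if T < burn_in + 2:
        raise ValueError(f"log spans {T} generations; need at least {burn_in + 2}")
    F_b = log.mean_F(burn_in)
    F_T = log.mean_F(T)
    ratio = (1.0 - F_T) / (1.0 - F_b)
    dF = 1.0 - ratio ** (1.0 / (T - burn_in))
    if dF <= _FLOOR:
        return float("inf")
    return 1.0 / (2.0 * dF)


def ne_temporal(p0: np.ndarray, pt: np.ndarray, t: int) -> float:
    """Temporal (drift-variance) effective size t/(2 F̄c).

    Loci fixed at both time points carry no drift information and are
    dropped; an all-fixed input is degenerate.
    """
    p0 = np.asarray(p0, dtype=float)
    pt = np.asarray(pt, dtype=float)
    if p0.shape != pt.shape:
        raise ValueError("frequency vectors must have equal length")
    if t < 1:
        raise ValueError("t must be at least one generation")
    p_bar = 0.5 * (p0 + pt)
    denom = p_bar * (1.0 - p_bar)
    keep = denom > 0
    if not np.any(keep):
        raise ValueError("all loci fixed: temporal estimator undefined")
    fc = ((p0 - pt) ** 2)[keep] / denom[keep]
    f_bar = float(fc.mean())
    if f_bar <= _FLOOR:
        return float("inf")
    return t / (2.0 * f_bar)


def _family_size_ne(log: PedigreeLog) -> float:
    """Per-replicate family-size Ne: per-generation combined estimates
    averaged over the log's generations."""
    cfg = log.config
    nf = cfg.n_demes * cfg.females_per_deme
    nm = cfg.n_demes * cfg.males_per_deme
    vals = []
    for s in log.stats[1:]:
        ne_f = ne_family_size(nf, s.kbar_f, s.vk_f)
        ne_m = ne_family_size(nm, s.kbar_m, s.vk_m)
        vals.append(combine_sexes(ne_f, ne_m))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Monte Carlo drivers

def _percentile_summary(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    # order statistics only: heavy-tailed Ne replicates may be infinite,
    # and interpolating between two infinities is undefined
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5],
                                method="inverted_cdf")
    return float(med), (float(lo), float(hi))


def monte_carlo_ne(config: RegimeConfig, replicates: int, generations: int,
                   seed, burn_in: int | None = None, label: str | None = None,
                   on_shortfall: str = "raise") -> dict[str, NeEstimate]:
    """Replay the propagation protocol ``replicates`` times and estimate Ne
    by every method, summarized as median and 2.5–97.5 percentile CI.

    ``on_shortfall="summarize"`` counts replicates that could not complete
    (e.g. infertility so high that the bean quota cannot be filled) instead
    of raising; the counts are attached to the returned mapping under the
    ``"_failures"`` key of its ``attrs``-style companion, accessible via
    ``result["_n_failed"]`` when any occurred.
    """
    if replicates < 2:
        raise ValueError("at least 2 replicates are required for a CI")
    if on_shortfall not in ("raise", "summarize"):
        raise ValueError("on_shortfall must be 'raise' or 'summarize'")
    if burn_in is None:
        burn_in = default_burn_in(config)
    if generations < burn_in + 2:
        raise ValueError(f"{generations} generations leave no room after a "
                         f"burn-in of {burn_in}")
    label = label or regime_label(config)
    per_method: dict[str, list[float]] = {FAMILY_SIZE: [], INBREEDING: [],
                                          TEMPORAL: []}
    n_failed = 0
    for r in range(replicates):
        rep_seed = np.random.SeedSequence(
            [int(s) for s in np.atleast_1d(getattr(seed, "entropy", seed))] + [r])
        try:
            log = run_line(config, label, rep_seed, n_generations=generations)
        except ShortfallError:
            if on_shortfall == "raise":
                raise
            n_failed += 1
            continue
        per_method[INBREEDING].append(ne_from_inbreeding(log, burn_in=burn_in))
        # drift variance has no founder transient, so the temporal estimator
        # uses the founder frequencies as its baseline
        p0 = log.allele_freqs[0]
        pt = log.allele_freqs[-1]
        per_method[TEMPORAL].append(ne_temporal(p0, pt, generations))
        per_method[FAMILY_SIZE].append(_family_size_ne(log))

    completed = replicates - n_failed
    out: dict[str, NeEstimate] = {}
    nf = config.n_demes * config.females_per_deme
    nm = config.n_demes * config.males_per_deme
    out[SEX_RATIO] = NeEstimate(
        method=SEX_RATIO, value=ne_sex_ratio(nm, nf), ci=None, regime=label,
        replicates=completed, generations=generations,
        infertility_rate=config.infertility_rate)
    for method, vals in per_method.items():
        if not vals:
            continue
        med, ci = _percentile_summary(np.asarray(vals))
        out[method] = NeEstimate(
            method=method, value=med, ci=ci, regime=label,
            replicates=completed, generations=generations,
            infertility_rate=config.infertility_rate)
    if n_failed:
        out["_n_failed"] = n_failed  # type: ignore[assignment]
    return out


def infertility_scenario(config: RegimeConfig, rates: Sequence[float],
                         replicates: int, seed, generations: int | None = None,
                         burn_in: int = 1) -> pd.DataFrame:
    """Evaluate ``monte_carlo_ne`` at each infertility rate.

    Under monogamy an infertile pairing removes the pair outright, so Ne is
    expected to be non-increasing in the rate.  Replicates that cannot
    complete (extreme rates) are summarized in the ``n_failed`` column, not
    raised.
    """
    for rate in rates:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"infertility rate {rate} outside [0, 1]")
    gens = generations if generations is not None else config.n_generations
    rows = []
    for rate in rates:
        cfg = replace(config, infertility_rate=float(rate))
        res = monte_carlo_ne(cfg, replicates, gens, seed, burn_in=burn_in,
                             on_shortfall="summarize")
        n_failed = res.pop("_n_failed", 0)
        for method, est in res.items():
            rows.append({
                "regime": est.regime, "method": method, "rate": rate,
                "median": est.value,
                "ci_low": est.ci[0] if est.ci else np.nan,
                "ci_high": est.ci[1] if est.ci else np.nan,
                "replicates": est.replicates, "n_failed": n_failed,
            })
        if not res:
            rows.append({"regime": regime_label(cfg), "method": "none",
                         "rate": rate, "median": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "replicates": 0,
                         "n_failed": n_failed})
    return pd.DataFrame(rows)


def estimates_to_frame(results: dict[str, dict[str, NeEstimate]]) -> pd.DataFrame:
    """Flatten {regime: {method: NeEstimate}} into a tidy table."""
    rows = []
    for regime, by_method in results.items():
        for method, est in by_method.items():
            if method.startswith("_"):
                continue
            rows.append({
                "regime": regime, "method": method, "rate": est.infertility_rate,
                "median": est.value,
                "ci_low": est.ci[0] if est.ci else np.nan,
                "ci_high": est.ci[1] if est.ci else np.nan,
                "replicates": est.replicates,
            })
    return pd.DataFrame(rows)


__all__ = [
    "SEX_RATIO", "FAMILY_SIZE", "INBREEDING", "TEMPORAL", "METHODS",
    "NeEstimate", "ne_sex_ratio", "ne_family_size", "combine_sexes",
    "ne_from_inbreeding", "ne_temporal", "monte_carlo_ne",
    "infertility_scenario", "estimates_to_frame",
]
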