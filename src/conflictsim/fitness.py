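"""Synthetic assay-level female fitness records.

Generates per-female longevity / lifetime-reproductive-success (LRS)
records with the statistical structure the study's mixed models assume:
fixed effects of the 2x2 selection regimes (including a monogamy-polygamy
by structure reversal interaction), by-line random intercepts (and
optionally random body-size slopes), mean-centered covariate effects, and
a residual correlation between longevity and LRS expressing the cost of
reproduction.

The preset fixed-effect vectors equal the published per-assay coefficient
tables (reference coding: monogamy and "no structure" are the reference
levels, covariates centered).  LRS coefficients live on the scale the
analyses used (the squared-count transform is exposed as an optional
response transform and is off by default, since back-transforming printed
coefficients is ambiguous); LRS values are rounded, floored Gaussians, not
an explicit count model.

Records are emitted as a tidy DataFrame with one row per assayed female;
covariates are stored raw (uncentered) — centering belongs to the analysis
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .protocol import ExperimentDesign, build_default_design

#: Columns of a FitnessRecord row, in output order.
RECORD_COLUMNS = [
    "line_id", "mating_system", "structured", "female_id", "assay",
    "longevity", "LRS", "body_size", "male_body_size", "age_at_entry",
    "n_matings", "generation",
]


@dataclass(frozen=True)
class FitnessRecord:
    """One assayed female's row (schema mirror of the tidy output)."""

    line_id: str
    mating_system: str
    structured: bool
    female_id: str
    assay: str
    longevity: float
    LRS: float | None
    body_size: float
    male_body_size: float | None
    age_at_entry: float
    n_matings: int
    generation: int


@dataclass(frozen=True)
class CovariateDistributions:
    """Raw covariate distributions for record generation.

    Elytron lengths are in mm (females ~2 mm, the slightly smaller tester
    males ~1.85 mm); ages in days since adult emergence.
    """

    body_size_mean: float = 2.00
    body_size_sd: float = 0.08
    male_body_size_mean: float = 1.85
    male_body_size_sd: float = 0.08
    age_low: int = 1
    age_high: int = 3
    mating_opportunity_p: float = 0.9   # per-day realized-mating probability


@dataclass(frozen=True)
class GenerativeModel:
    """Generative model for one response of one assay.

    ``beta`` maps term names to fixed-effect coefficients on reference
    coding with centered covariates; recognized terms are ``intercept``,
    ``mating_system`` (polygamy indicator), ``structure`` (subdivided
    indicator), ``interaction``, ``body_size``, ``male_body_size``,
    ``age``, ``n_matings``, ``generation`` (indicator of the later assay
    generation), and treatment-by-size terms ``ms_x_body_size``,
    ``st_x_body_size``, ``ms_x_male_body_size``, ``st_x_male_body_size``.
    Cross-trait coefficients printed in the tables (longevity on LRS and
    vice versa) are not generative: the trait association is induced by
    ``trade_off_rho`` instead.
    """

    response: str                       # "longevity" | "LRS"
    assay: str                          # no_conflict | low | medium | extreme
    beta: Mapping[str, float]
    sd_line_intercept: float
    sd_residual: float
    sd_line_slopes: Mapping[str, float] = field(default_factory=dict)
    trade_off_rho: float = -0.3
    covariates: CovariateDistributions = CovariateDistributions()
    companion: "GenerativeModel | None" = None
    lrs_squared_transform: bool = False
    default_n_per_line: int = 10
    generations: tuple[int, ...] = (0,)
    #: per-line female counts assigned to each assay generation; None means
    #: all females share the single generation label
    generation_split: tuple[int, ...] | None = None
    matings_opportunities: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.sd_residual < 0:
            raise ValueError("residual SD cannot be negative")
        if not -1.0 < self.trade_off_rho <= 0.0:
            raise ValueError("trade_off_rho must lie in (-1, 0] (cost of "
                             "reproduction acts against longevity)")
        if self.sd_line_intercept < 0 or any(v < 0 for v in self.sd_line_slopes.values()):
            raise ValueError("random-effect SDs must be non-negative")

    def null(self) -> "GenerativeModel":
        """Copy with all treatment coefficients zeroed (random structure,
        covariate effects and residual correlation retained)."""
        drop = {"mating_system", "structure", "interaction",
                "ms_x_body_size", "st_x_body_size",
                "ms_x_male_body_size", "st_x_male_body_size"}
        beta = {k: (0.0 if k in drop else v) for k, v in self.beta.items()}
        comp = self.companion.null() if self.companion is not None else None
        return replace(self, beta=beta, companion=comp)


# ---------------------------------------------------------------------------
# Published coefficient presets

def _medium_model() -> GenerativeModel:
    # female resistance under variable mating rates; longevity only
    # (females had no oviposition substrate, so no LRS is recorded)
    return GenerativeModel(
        response="longevity", assay="medium",
        beta={
            "intercept": 24.15,
            "mating_system": 2.01,
            "structure": 2.17,
            "generation": 2.21,
            "age": -0.07,
            "n_matings": -0.38,
            "body_size": 30.14,
            "interaction": -3.90,
            "ms_x_body_size": -11.90,
            "st_x_body_size": -0.58,
        },
        sd_line_intercept=2.4, sd_residual=4.0,
        sd_line_slopes={"body_size": 0.0},
        trade_off_rho=0.0,
        default_n_per_line=17,
        generations=(12, 30), generation_split=(7, 10),
        matings_opportunities={12: 12, 30: 10},
    )


def _low_models() -> dict[str, GenerativeModel]:
    lrs_harm = GenerativeModel(
        response="LRS", assay="low",
        beta={
            "intercept": 3205.43, "mating_system": -146.83,
            "structure": -223.80, "body_size": 965.45,
            "male_body_size": 3970.13, "interaction": 451.58,
            "ms_x_body_size": 2351.27, "ms_x_male_body_size": -2478.79,
            "st_x_body_size": -369.27, "st_x_male_body_size": 2982.37,
        },
        sd_line_intercept=320.0, sd_residual=900.0,
        default_n_per_line=10, generations=(32,),
    )
    harm = GenerativeModel(
        response="longevity", assay="low",
        beta={
            "intercept": 8.11, "mating_system": 0.18, "structure": 0.25,
            "body_size": 2.78, "male_body_size": -0.21,
            "interaction": -0.16, "ms_x_body_size": 2.66,
            "ms_x_male_body_size": -1.13, "st_x_body_size": -1.37,
            "st_x_male_body_size": 1.57,
        },
        sd_line_intercept=0.81, sd_residual=2.0,
        companion=lrs_harm, default_n_per_line=10, generations=(32,),
    )
    lrs_res = GenerativeModel(
        response="LRS", assay="low",
        beta={
            "intercept": 4441.01, "mating_system": -197.31,
            "structure": 251.45, "body_size": 5660.15,
            "male_body_size": -2366.07, "interaction": 1040.18,
            "ms_x_body_size": -3573.76, "ms_x_male_body_size": 3442.93,
            "st_x_body_size": 1999.97, "st_x_male_body_size": 517.87,
        },
        sd_line_intercept=444.0, sd_residual=900.0,
        default_n_per_line=10, generations=(32,),
    )
    resistance = GenerativeModel(
        response="longevity", assay="low",
        beta={
            "intercept": 9.17, "mating_system": 0.43, "structure": 0.40,
            "body_size": 5.49, "male_body_size": -1.17,
            "interaction": 0.00, "ms_x_body_size": -0.25,
            "ms_x_male_body_size": 0.75, "st_x_body_size": -0.14,
            "st_x_male_body_size": 3.07,
        },
        sd_line_intercept=0.92, sd_residual=2.0,
        companion=lrs_res, default_n_per_line=10, generations=(32,),
    )
    return {"low_harm": harm, "low_resistance": resistance}


def _extreme_models() -> dict[str, GenerativeModel]:
    lrs_harm = GenerativeModel(
        response="LRS", assay="extreme",
        beta={
            "intercept": 2927.53, "mating_system": -233.94,
            "structure": -531.21, "body_size": 1604.67,
            "age": -748.73, "interaction": 1017.32,
            "ms_x_body_size": 1687.08, "st_x_body_size": 1569.93,
        },
        sd_line_intercept=300.0, sd_residual=800.0,
        default_n_per_line=10, generations=(47,),
    )
    harm = GenerativeModel(
        response="longevity", assay="extreme",
        beta={
            "intercept": 7.76, "mating_system": 0.02, "structure": 0.69,
            "body_size": 3.46, "age": 1.12, "interaction": -0.67,
            "ms_x_body_size": -1.95, "st_x_body_size": 2.38,
        },
        sd_line_intercept=0.78, sd_residual=2.0,
        companion=lrs_harm, default_n_per_line=10, generations=(47,),
    )
    lrs_res = GenerativeModel(
        response="LRS", assay="extreme",
        beta={
            "intercept": 5121.78, "mating_system": 221.99,
            "structure": -250.28, "body_size": 6980.48,
            "age": -387.54, "interaction": 675.48,
            "ms_x_body_size": 5382.78, "st_x_body_size": 2969.26,
        },
        sd_line_intercept=512.0, sd_residual=800.0,
        default_n_per_line=10, generations=(47,),
    )
    resistance = GenerativeModel(
        response="longevity", assay="extreme",
        beta={
            "intercept": 7.56, "mating_system": -0.08, "structure": -0.03,
            "body_size": 0.03, "age": 0.92, "interaction": 0.51,
            "ms_x_body_size": -1.90, "st_x_body_size": 4.95,
        },
        sd_line_intercept=0.76, sd_residual=2.0,
        companion=lrs_res, default_n_per_line=10, generations=(47,),
    )
    return {"extreme_harm": harm, "extreme_resistance": resistance}


def default_models() -> dict[str, GenerativeModel]:
    """Preset generative models keyed by assay variant.

    ``medium`` carries the variable-mating-rate longevity coefficients;
    ``low_*`` and ``extreme_*`` pair a longevity model with an LRS
    companion (``_harm``: tester females with focal males; ``_resistance``:
    focal females with tester males).  ``no_conflict`` is a null-structured
    virgin-longevity preset: the regimes did not diverge in baseline
    longevity, which was shaped by body size only.
    """
    models = {
        "no_conflict": GenerativeModel(
            response="longevity", assay="no_conflict",
            beta={"intercept": 11.0, "mating_system": 0.0, "structure": 0.0,
                  "interaction": 0.0, "body_size": 3.0},
            sd_line_intercept=0.5, sd_residual=1.5,
            default_n_per_line=30, generations=(43,),
        ),
        "medium": _medium_model(),
    }
    models.update(_low_models())
    models.update(_extreme_models())
    return models


# ---------------------------------------------------------------------------
# Generation

def _eta(model: GenerativeModel, ms: float, st: float, bs_c: np.ndarray,
         mbs_c: np.ndarray, age_c: np.ndarray, mat_c: np.ndarray,
         gen_ind: np.ndarray) -> np.ndarray:
    b = model.beta
    g = lambda k: b.get(k, 0.0)
    return (g("intercept")
            + g("mating_system") * ms + g("structure") * st
            + g("interaction") * ms * st
            + g("body_size") * bs_c + g("male_body_size") * mbs_c
            + g("age") * age_c + g("n_matings") * mat_c
            + g("generation") * gen_ind
            + g("ms_x_body_size") * ms * bs_c
            + g("st_x_body_size") * st * bs_c
            + g("ms_x_male_body_size") * ms * mbs_c
            + g("st_x_male_body_size") * st * mbs_c)


def generate_assay(model: GenerativeModel,
                   design: ExperimentDesign | None = None,
                   n_per_line: int | Sequence[int] | None = None,
                   seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Draw one synthetic assay dataset as a tidy DataFrame.

    Line random intercepts (and any random slopes) are drawn from their
    SDs; covariates from their raw distributions; the linear predictor
    applies the coefficient vector to treatment indicators and
    population-centered covariates, so the stored raw covariates remain
    uncentered.  When the model has an LRS/longevity companion, the two
    responses' residuals are drawn jointly with correlation
    ``trade_off_rho``.  LRS is floored at zero and rounded.
    """
    design = design if design is not None else build_default_design()
    if n_per_line is None:
        n_per_line = model.default_n_per_line
    if np.isscalar(n_per_line):
        counts = [int(n_per_line)] * len(design)
    else:
        counts = [int(v) for v in n_per_line]
        if len(counts) != len(design):
            raise ValueError("n_per_line sequence must match the number of lines")
    if min(counts) < 1:
        raise ValueError("n_per_line must be at least 1")

    rng = np.random.default_rng(seed)
    cov = model.covariates
    models = [model] + ([model.companion] if model.companion is not None else [])

    # joint residual covariance over the 1 or 2 responses
    sds = np.array([m.sd_residual for m in models])
    corr = np.eye(len(models))
    if len(models) == 2:
        corr[0, 1] = corr[1, 0] = model.trade_off_rho
    res_cov = corr * np.outer(sds, sds)

    line_int = {m.response: rng.normal(0.0, m.sd_line_intercept, size=len(design))
                for m in models}
    line_slope = {
        m.response: {c: rng.normal(0.0, sd, size=len(design))
                     for c, sd in m.sd_line_slopes.items()}
        for m in models}

    rows = []
    for j, ((line_id, cfg), n) in enumerate(zip(design, counts)):
        ms = 1.0 if cfg.mating_system == "polygamy" else 0.0
        st = 1.0 if cfg.structured else 0.0

        body = rng.normal(cov.body_size_mean, cov.body_size_sd, size=n)
        male_body = rng.normal(cov.male_body_size_mean, cov.male_body_size_sd,
                               size=n)
        age = rng.integers(cov.age_low, cov.age_high + 1, size=n).astype(float)

        if model.generation_split is not None:
            gens = np.concatenate([
                np.full(k, g) for k, g in zip(model.generation_split,
                                              model.generations)])
            gens = np.resize(gens, n)
        else:
            gens = np.full(n, model.generations[0])
        gen_ind = (gens == max(model.generations)).astype(float) \
            if len(model.generations) > 1 else np.zeros(n)

        opp = np.array([model.matings_opportunities.get(int(g), 1) for g in gens])
        matings = rng.binomial(opp, cov.mating_opportunity_p)

        # population-centered covariates so the intercept keeps its
        # printed meaning; stored values stay raw
        bs_c = body - cov.body_size_mean
        mbs_c = male_body - cov.male_body_size_mean
        age_c = age - 0.5 * (cov.age_low + cov.age_high)
        mat_c = matings - opp * cov.mating_opportunity_p

        eps = rng.multivariate_normal(np.zeros(len(models)), res_cov, size=n)
        values: dict[str, np.ndarray] = {}
        for k, m in enumerate(models):
            eta = _eta(m, ms, st, bs_c, mbs_c, age_c, mat_c, gen_ind)
            eta = eta + line_int[m.response][j]
            for c, dev in line_slope[m.response].items():
                base = {"body_size": bs_c, "male_body_size": mbs_c}[c]
                eta = eta + dev[j] * base
            y = eta + eps[:, k]
            if m.response == "LRS":
                y = np.maximum(0.0, np.round(y))
                if m.lrs_squared_transform:
                    y = np.round(np.sqrt(y)) ** 2
            else:
                y = np.maximum(y, 0.1)
            values[m.response] = y

        has_lrs = "LRS" in values
        for i in range(n):
            rows.append({
                "line_id": line_id,
                "mating_system": cfg.mating_system,
                "structured": cfg.structured,
                "female_id": f"{line_id}-F{i + 1}",
                "assay": model.assay,
                "longevity": float(values["longevity"][i]) if "longevity" in values else np.nan,
                "LRS": float(values["LRS"][i]) if has_lrs else np.nan,
                "body_size": float(body[i]),
                "male_body_size": float(male_body[i]),
                "age_at_entry": float(age[i]),
                "n_matings": int(matings[i]),
                "generation": int(gens[i]),
            })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def generate_null(model: GenerativeModel,
                  design: ExperimentDesign | None = None,
                  n_per_line: int | Sequence[int] | None = None,
                  seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """As :func:`generate_assay` with all treatment effects zeroed; the
    random structure, covariate effects and residual correlation remain.
    Used for type-I-error calibration of the analysis design."""
    return generate_assay(model.null(), design=design, n_per_line=n_per_line,
                          seed=seed)


def settings_sidecar(model: GenerativeModel) -> dict:
    """JSON-serializable description of a generator run's settings."""
    def encode(m: GenerativeModel | None):
        if m is None:
            return None
        return {
            "response": m.response, "assay": m.assay, "beta": dict(m.beta),
            "sd_line_intercept": m.sd_line_intercept,
            "sd_line_slopes": dict(m.sd_line_slopes),
            "sd_residual": m.sd_residual, "trade_off_rho": m.trade_off_rho,
            "lrs_squared_transform": m.lrs_squared_transform,
            "companion": encode(m.companion),
        }
    return encode(model)


__all__ = [
    "RECORD_COLUMNS", "FitnessRecord", "CovariateDistributions",
    "GenerativeModel", "default_models", "generate_assay", "generate_null",
    "settings_sidecar",
]
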