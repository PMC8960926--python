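"""Synthetic breast-cancer cohort generator.

Generates per-patient records whose group-conditional distributions match the
published cohort summaries: LN-metastasis prevalence 174/619, BI-RADS and
stiff-rim frequencies per LN group, and median/IQR of all 17 quantitative SWE
parameters per LN group.  Each SWE parameter is modeled as a log-normal
calibrated in closed form from its median and quartiles; within-patient
dependence across the 16 region statistics is induced by a one-factor
Gaussian copula with correlation ``copula_rho`` (E_ratio is drawn
independently from its own calibrated log-normal).

Draw order (fixed, so a seed fully determines the cohort): LN status, BI-RADS,
stiff rim, T stage, location, age, tumor size, the SWE latent block
(factor + noise), resampling draws for ordering violations, then E_ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import fixtures
from .cohort import (
    BIRADS_LEVELS,
    CANONICAL_COLUMNS,
    LOCATION_LEVELS,
    REGIONS,
    SWE_COLUMNS,
    T_STAGE_LEVELS,
    CohortTable,
)

__all__ = [
    "LogNormalSpec",
    "SyntheticConfig",
    "lognormal_from_quartiles",
    "default_config",
    "generate_cohort",
    "validate_against_summaries",
    "SummaryReport",
    "save_config",
    "load_config",
]

_Z75 = float(norm.ppf(0.75))

#: Age and tumor size (mm): mean, SD, admissible range from the study cohort.
_AGE = (52.16, 11.21, 22.0, 91.0)
_TUMOR_SIZE = (20.99, 9.04, 4.7, 89.0)


@dataclass(frozen=True)
class LogNormalSpec:
    """Median and quartiles of a positive-valued feature (kPa or unitless)."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (0 < self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"require 0 < q1 <= median <= q3, got ({self.q1}, {self.median}, {self.q3})"
            )


def lognormal_from_quartiles(spec: LogNormalSpec) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the log-normal matching the spec's quartiles.

    Closed form: mu = ln(median); sigma = ln(q3/q1) / (2 z_0.75).  The
    calibrated distribution reproduces the median and both quartiles exactly.
    """
    mu = float(np.log(spec.median))
    sigma = float(np.log(spec.q3 / spec.q1) / (2.0 * _Z75))
    return mu, sigma


def _default_swe_specs() -> dict:
    return {
        group: {
            feat: LogNormalSpec(*vals)
            for feat, vals in fixtures.SWE_MEDIAN_IQR[group].items()
        }
        for group in ("negative", "positive")
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Group-conditional distribution parameters for cohort simulation."""

    n: int
    seed: int = 0
    prevalence: float = fixtures.N_POSITIVE / fixtures.N_TOTAL
    birads_probs: dict = field(
        default_factory=lambda: {
            "negative": tuple(fixtures.BIRADS_BY_LN[:, 0] / fixtures.N_NEGATIVE),
            "positive": tuple(fixtures.BIRADS_BY_LN[:, 1] / fixtures.N_POSITIVE),
        }
    )
    stiff_rim_prob: dict = field(
        default_factory=lambda: {
            "negative": fixtures.STIFF_RIM_2X2[0, 0] / fixtures.N_NEGATIVE,
            "positive": fixtures.STIFF_RIM_2X2[0, 1] / fixtures.N_POSITIVE,
        }
    )
    swe_specs: dict = field(default_factory=_default_swe_specs)
    copula_rho: float = 0.7

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        if not (0.0 <= self.copula_rho < 1.0):
            raise ValueError("copula_rho must lie in [0, 1)")
        for group in ("negative", "positive"):
            probs = np.asarray(self.birads_probs[group], dtype=float)
            if probs.size != len(BIRADS_LEVELS) or abs(probs.sum() - 1.0) > 1e-12:
                raise ValueError(f"birads_probs[{group}] must sum to 1")
            if not (0.0 <= self.stiff_rim_prob[group] <= 1.0):
                raise ValueError(f"stiff_rim_prob[{group}] out of [0, 1]")
            specs = self.swe_specs[group]
            missing = set(SWE_COLUMNS + ("e_ratio",)) - set(specs)
            if missing:
                raise ValueError(f"swe_specs[{group}] missing {sorted(missing)}")
            for spec in specs.values():
                if not isinstance(spec, LogNormalSpec):
                    raise ValueError("swe_specs values must be LogNormalSpec")


def default_config(n: int, seed: int = 0, **overrides) -> SyntheticConfig:
    """Configuration calibrated to the published cohort summaries."""
    return replace(SyntheticConfig(n=n, seed=seed), **overrides)


def _sample_categorical(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs), u, side="right").clip(0, probs.size - 1)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a reproducible synthetic cohort under ``config``.

    After sampling, any record violating e_min <= e_mean <= e_max in some
    region has its whole SWE block redrawn (up to 1000 attempts); surviving
    violations — vanishingly rare under the default calibration — are repaired
    by sorting the three values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return CohortTable(pd.DataFrame(columns=list(CANONICAL_COLUMNS)),
                           provenance="synthetic(empty)", _validated=True)

    positive = rng.random(n) < config.prevalence
    groups = np.where(positive, "positive", "negative")

    birads_idx = np.empty(n, dtype=int)
    u = rng.random(n)
    for group in ("negative", "positive"):
        mask = groups == group
        probs = np.asarray(config.birads_probs[group], dtype=float)
        birads_idx[mask] = _sample_categorical(u[mask], probs)
    birads = np.asarray(BIRADS_LEVELS)[birads_idx]

    u = rng.random(n)
    p_rim = np.where(
        positive, config.stiff_rim_prob["positive"], config.stiff_rim_prob["negative"]
    )
    stiff_rim = np.where(u < p_rim, "present", "absent")

    # Group-independent clinical covariates (the study found no LN association).
    t_probs = fixtures.T_STAGE_BY_LN.sum(axis=1) / fixtures.N_TOTAL
    t_stage = np.asarray(T_STAGE_LEVELS)[_sample_categorical(rng.random(n), t_probs)]
    loc_probs = fixtures.LOCATION_BY_LN.sum(axis=1) / fixtures.N_TOTAL
    location = np.asarray(LOCATION_LEVELS)[_sample_categorical(rng.random(n), loc_probs)]
    age = np.clip(_AGE[0] + _AGE[1] * rng.standard_normal(n), _AGE[2], _AGE[3])
    size = np.clip(
        _TUMOR_SIZE[0] + _TUMOR_SIZE[1] * rng.standard_normal(n),
        _TUMOR_SIZE[2],
        _TUMOR_SIZE[3],
    )

    # Calibrated log-scale parameters per group, aligned with SWE_COLUMNS.
    mus = {}
    sigmas = {}
    for group in ("negative", "positive"):
        ms = [lognormal_from_quartiles(config.swe_specs[group][c]) for c in SWE_COLUMNS]
        mus[group] = np.array([m for m, _ in ms])
        sigmas[group] = np.array([s for _, s in ms])
    mu_mat = np.where(positive[:, None], mus["positive"], mus["negative"])
    sigma_mat = np.where(positive[:, None], sigmas["positive"], sigmas["negative"])

    rho = config.copula_rho
    k = len(SWE_COLUMNS)

    def draw_block(m: int) -> np.ndarray:
        factor = rng.standard_normal((m, 1))
        noise = rng.standard_normal((m, k))
        return np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise

    z = draw_block(n)
    swe = np.exp(mu_mat + sigma_mat * z)

    col_idx = {c: i for i, c in enumerate(SWE_COLUMNS)}

    def violations(block: np.ndarray) -> np.ndarray:
        bad = np.zeros(block.shape[0], dtype=bool)
        for region in REGIONS:
            emin = block[:, col_idx[f"{region}_emin"]]
            emean = block[:, col_idx[f"{region}_emean"]]
            emax = block[:, col_idx[f"{region}_emax"]]
            bad |= ~((emin <= emean) & (emean <= emax))
        return bad

    bad = violations(swe)
    attempts = 0
    while bad.any() and attempts < 1000:
        idx = np.flatnonzero(bad)
        z_new = draw_block(idx.size)
        swe[idx] = np.exp(mu_mat[idx] + sigma_mat[idx] * z_new)
        bad = violations(swe)
        attempts += 1
    if bad.any():  # last resort: sort the three order-constrained values
        for region in REGIONS:
            cols = [col_idx[f"{region}_{s}"] for s in ("emin", "emean", "emax")]
            sub = swe[np.ix_(np.flatnonzero(bad), cols)]
            swe[np.ix_(np.flatnonzero(bad), cols)] = np.sort(sub, axis=1)

    mu_r = np.empty(n)
    sigma_r = np.empty(n)
    for group in ("negative", "positive"):
        m, s = lognormal_from_quartiles(config.swe_specs[group]["e_ratio"])
        mask = groups == group
        mu_r[mask] = m
        sigma_r[mask] = s
    e_ratio = np.exp(mu_r + sigma_r * rng.standard_normal(n))

    width = max(6, len(str(n)))
    frame = pd.DataFrame(
        {
            "patient_id": [f"S{i:0{width}d}" for i in range(1, n + 1)],
            "ln_status": groups,
            "age": np.round(age, 1),
            "tumor_size_mm": np.round(size, 1),
            "t_stage": t_stage,
            "location": location,
            "birads": birads,
            "stiff_rim": stiff_rim,
            "e_ratio": e_ratio,
        }
    )
    for j, col in enumerate(SWE_COLUMNS):
        frame[col] = swe[:, j]
    frame = frame.reindex(columns=list(CANONICAL_COLUMNS))
    return CohortTable(frame, provenance=f"synthetic(seed={config.seed}, n={n})",
                       _validated=True)


@dataclass
class SummaryReport:
    """Deviation of a cohort's summaries from configured targets."""

    frame: pd.DataFrame
    tolerance: float

    @property
    def flags(self) -> pd.DataFrame:
        return self.frame[self.frame["flagged"]]

    @property
    def ok(self) -> bool:
        return not bool(self.frame["flagged"].any())

    def to_text(self) -> str:
        lines = [f"summary check (tolerance {self.tolerance:g})"]
        for _, row in self.frame.iterrows():
            mark = "FLAG" if row["flagged"] else "ok"
            lines.append(
                f"  [{mark}] {row['group']:>8s} {row['quantity']:<22s} "
                f"expected {row['expected']:.4g} observed {row['observed']:.4g}"
            )
        return "\n".join(lines)


def validate_against_summaries(
    cohort, config: SyntheticConfig, tolerance: float = 0.05
) -> SummaryReport:
    """Compare a cohort's empirical summaries with the configured targets.

    Quantitative features are checked on relative deviation of the median;
    prevalence, stiff-rim, and BI-RADS frequencies on absolute deviation.
    Raises on an empty cohort or one lacking the SWE columns.
    """
    frame = cohort.frame if isinstance(cohort, CohortTable) else pd.DataFrame(cohort)
    if len(frame) == 0:
        raise ValueError("cannot summarize an empty cohort")
    missing = set(SWE_COLUMNS + ("e_ratio", "ln_status", "birads", "stiff_rim")) - set(
        frame.columns
    )
    if missing or frame[list(SWE_COLUMNS)].isna().all().all():
        raise ValueError(f"not a full cohort: missing columns {sorted(missing) or 'SWE values'}")

    rows = []

    def add(group, quantity, expected, observed, relative):
        dev = abs(observed - expected) / (abs(expected) if relative else 1.0)
        rows.append(
            {
                "group": group,
                "quantity": quantity,
                "expected": expected,
                "observed": observed,
                "deviation": dev,
                "flagged": bool(dev > tolerance),
            }
        )

    prev = float((frame["ln_status"] == "positive").mean())
    add("all", "prevalence", config.prevalence, prev, relative=False)
    for group in ("negative", "positive"):
        sub = frame[frame["ln_status"] == group]
        if len(sub) == 0:
            continue
        add(
            group,
            "stiff_rim_present",
            float(config.stiff_rim_prob[group]),
            float((sub["stiff_rim"] == "present").mean()),
            relative=False,
        )
        for lev, p_exp in zip(BIRADS_LEVELS, config.birads_probs[group]):
            add(
                group,
                f"birads_{lev}",
                float(p_exp),
                float((sub["birads"] == lev).mean()),
                relative=False,
            )
        for col in SWE_COLUMNS + ("e_ratio",):
            spec = config.swe_specs[group][col]
            add(group, f"{col}_median", spec.median,
                float(np.median(sub[col])), relative=True)
    return SummaryReport(pd.DataFrame(rows), tolerance)


# ---------------------------------------------------------------------------
# Flat key-value serialization (CLI-friendly)
# ---------------------------------------------------------------------------

def save_config(config: SyntheticConfig, path) -> Path:
    """Write the config as a flat ``key = value`` text file."""
    lines = [
        f"n = {config.n}",
        f"seed = {config.seed}",
        f"prevalence = {config.prevalence!r}",
        f"copula_rho = {config.copula_rho!r}",
    ]
    for group in ("negative", "positive"):
        probs = ",".join(repr(float(p)) for p in config.birads_probs[group])
        lines.append(f"birads_probs.{group} = {probs}")
        lines.append(f"stiff_rim_prob.{group} = {float(config.stiff_rim_prob[group])!r}")
        for feat, spec in config.swe_specs[group].items():
            lines.append(
                f"swe.{group}.{feat} = {spec.median!r},{spec.q1!r},{spec.q3!r}"
            )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_config(path) -> SyntheticConfig:
    """Read a config written by :func:`save_config`."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    birads = {}
    rim = {}
    swe: dict[str, dict[str, LogNormalSpec]] = {"negative": {}, "positive": {}}
    for key, value in kv.items():
        if key.startswith("birads_probs."):
            birads[key.split(".", 1)[1]] = tuple(float(x) for x in value.split(","))
        elif key.startswith("stiff_rim_prob."):
            rim[key.split(".", 1)[1]] = float(value)
        elif key.startswith("swe."):
            _, group, feat = key.split(".", 2)
            med, q1, q3 = (float(x) for x in value.split(","))
            swe[group][feat] = LogNormalSpec(med, q1, q3)
    config = SyntheticConfig(
        n=int(kv["n"]),
        seed=int(kv["seed"]),
        prevalence=float(kv["prevalence"]),
        copula_rho=float(kv["copula_rho"]),
        birads_probs=birads,
        stiff_rim_prob=rim,
        swe_specs=swe,
    )
    config.validate()
    return config
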