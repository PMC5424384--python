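"""Logistic-normal synthetic cohort generator.

Emulates the statistical structure the analysis assumes: four-part
24-h movement compositions (sleep, ST, LPA, MVPA) drawn logistic-normally
— multivariate normal in ilr space around group-specific compositional
means, with a covariance derived from a target pairwise variation matrix
— and outcomes generated from the linear model

    y = b0 + beta . ilr(x) + gamma . covariates + eps,   eps ~ N(0, sigma^2).

Default parameters emulate a cohort of 169 nine-to-ten-year-olds from a
low-income English community (15 underweight / 115 normal-weight / 39
overweight-obese), with MVPA a small slice (~26 min) of the day and the
deprivation distribution concentrated in the most deprived deciles.
Default ilr effect vectors are calibrated so that the predicted 15-min
substitution differences around the full-sample mean match the published
reference grid for that cohort (least squares over the twelve ordered
pairs); they are fixture defaults for testing the pipeline, not claims
about any study's true coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import (
    DEFAULT_PARTS,
    MINUTES_PER_DAY,
    Composition,
    CompositionError,
    SequentialBinaryPartition,
    close,
    ilr,
    variation_to_lr_covariance,
)
from .reallocation import Reallocation, reallocate

__all__ = [
    "SyntheticConfig",
    "default_config",
    "generate_compositions",
    "generate_records",
    "make_fixture",
    "calibrate_ilr_effects",
    "GROUP_MEAN_MINUTES",
    "TARGET_VARIATION",
    "DIFF_TARGETS_15MIN",
]

#: Group compositional means in minutes (sleep, ST, LPA, MVPA); the study
#: conditions the generator emulates.
GROUP_MEAN_MINUTES: dict[str, tuple[float, float, float, float]] = {
    "all": (548.6, 510.3, 354.8, 26.4),
    "underweight": (546.0, 488.1, 370.9, 35.0),
    "normal-weight": (545.6, 509.3, 356.2, 28.9),
    "overweight/obese": (557.1, 520.9, 343.9, 18.1),
}

#: Target pairwise log-ratio variation matrix (part order sleep, ST,
#: LPA, MVPA): sleep, ST and LPA are tightly co-dependent (<0.08) while
#: MVPA varies most relative to everything else.
TARGET_VARIATION = np.array([
    [0.000, 0.030, 0.036, 0.281],
    [0.030, 0.000, 0.079, 0.442],
    [0.036, 0.079, 0.000, 0.235],
    [0.281, 0.442, 0.235, 0.000],
])

#: Reference predicted differences for 15-min substitutions around the
#: full-sample mean, keyed (donor, receiver); used only to calibrate the
#: generator's default ilr effect vectors.  ``vo2peak`` entries are from
#: the fatness-adjusted fitness model and calibrate the direct (zBMI-held
#: -constant) composition effect on fitness.
DIFF_TARGETS_15MIN: dict[str, dict[tuple[str, str], float]] = {
    "zbmi": {
        ("st", "sleep"): 0.05, ("lpa", "sleep"): -0.01, ("mvpa", "sleep"): 0.88,
        ("sleep", "st"): -0.05, ("lpa", "st"): -0.06, ("mvpa", "st"): 0.83,
        ("sleep", "lpa"): 0.01, ("st", "lpa"): 0.06, ("mvpa", "lpa"): 0.89,
        ("sleep", "mvpa"): -0.48, ("st", "mvpa"): -0.43, ("lpa", "mvpa"): -0.49,
    },
    "whtr_pct": {
        ("st", "sleep"): 0.1, ("lpa", "sleep"): -0.4, ("mvpa", "sleep"): 5.1,
        ("sleep", "st"): -0.1, ("lpa", "st"): -0.5, ("mvpa", "st"): 5.0,
        ("sleep", "lpa"): 0.3, ("st", "lpa"): 0.4, ("mvpa", "lpa"): 5.5,
        ("sleep", "mvpa"): -2.8, ("st", "mvpa"): -2.7, ("lpa", "mvpa"): -3.1,
    },
    "vo2peak": {
        ("st", "sleep"): 0.0, ("lpa", "sleep"): -0.0, ("mvpa", "sleep"): -2.4,
        ("sleep", "st"): 0.0, ("lpa", "st"): -0.0, ("mvpa", "st"): -2.4,
        ("sleep", "lpa"): 0.0, ("st", "lpa"): 0.0, ("mvpa", "lpa"): -2.4,
        ("sleep", "mvpa"): 1.3, ("st", "mvpa"): 1.3, ("lpa", "mvpa"): 1.3,
    },
}

_DEFAULT_SEED = 20170510


def calibrate_ilr_effects(targets: Mapping[tuple[str, str], float],
                          mean_minutes: Sequence[float],
                          sbp: SequentialBinaryPartition,
                          minutes: float = 15.0) -> np.ndarray:
    """Solve for ilr coefficients reproducing a substitution-difference grid.

    Under a linear-in-ilr model, difference = beta . (ilr(C') - ilr(C));
    with twelve ordered pairs and D-1 unknowns the least-squares solution
    recovers beta nearly exactly when the grid itself came from such a
    model (residual is rounding noise).
    """
    baseline = close(np.asarray(mean_minutes, float), parts=sbp.parts)
    z0 = ilr(baseline, sbp).values
    rows, d = [], []
    for (donor, receiver), diff in targets.items():
        moved = reallocate(baseline, Reallocation(donor, receiver, minutes))
        rows.append(ilr(moved, sbp).values - z0)
        d.append(diff)
    beta, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(d), rcond=None)
    return beta


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort generator.

    ``beta`` holds the direct ilr effect vectors per outcome (under
    ``basis``); ``gamma`` the covariate effects; ``sigma`` the residual
    standard deviations.  ``gamma_zbmi_on_vo2`` couples fitness to
    fatness so the zBMI-adjusted fitness model is meaningful.
    """

    parts: tuple[str, ...] = DEFAULT_PARTS
    kappa: float = MINUTES_PER_DAY
    n_per_group: dict[str, int] = field(default_factory=lambda: {
        "underweight": 15, "normal-weight": 115, "overweight/obese": 39})
    group_means: dict[str, np.ndarray] = field(default_factory=dict)
    ilr_cov: np.ndarray | None = None
    beta: dict[str, np.ndarray] = field(default_factory=dict)
    gamma: dict[str, dict[str, float]] = field(default_factory=dict)
    imd_effects: dict[str, np.ndarray] = field(default_factory=dict)
    gamma_zbmi_on_vo2: float = -1.5
    intercept: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=lambda: {
        "zbmi": 1.23, "whtr_pct": 6.15, "vo2peak": 3.12})
    sex_p_girl: float = 0.5
    age_mean: float = 10.3
    age_sd: float = 0.3
    imd_probs: tuple[float, ...] = (
        0.40, 0.23, 0.22, 0.04, 0.03, 0.03, 0.02, 0.03, 0.0, 0.0)
    height_mean: float = 141.2
    height_sd: float = 6.2
    seed: int = _DEFAULT_SEED

    @property
    def basis(self) -> SequentialBinaryPartition:
        return SequentialBinaryPartition.pivot(self.parts)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.sigma)

    def validate(self) -> "SyntheticConfig":
        D = len(self.parts)
        for g, m in self.group_means.items():
            m = np.asarray(m, float)
            if m.shape != (D,) or np.any(m <= 0):
                raise CompositionError(f"group {g!r}: mean must be {D} positive minutes")
        if self.ilr_cov is not None:
            S = np.asarray(self.ilr_cov, float)
            if S.shape != (D - 1, D - 1) or not np.allclose(S, S.T, atol=1e-10):
                raise CompositionError("ilr covariance must be symmetric (D-1)x(D-1)")
            eig = np.linalg.eigvalsh(S)
            if eig.min() < -1e-10:
                raise CompositionError(
                    f"ilr covariance is not positive semidefinite (min eig {eig.min():.3g})")
        for o, s in self.sigma.items():
            if s < 0:
                raise CompositionError(f"sigma[{o!r}] must be >= 0")
        p = np.asarray(self.imd_probs, float)
        if p.min() < 0 or not np.isclose(p.sum(), 1.0):
            raise CompositionError("imd_probs must be nonnegative and sum to 1")
        if not 0 <= self.sex_p_girl <= 1:
            raise CompositionError("sex_p_girl must be a probability")
        for grp in self.n_per_group:
            if grp not in self.group_means:
                raise CompositionError(f"no compositional mean for group {grp!r}")
        return self

    def to_dict(self) -> dict:
        return {
            "parts": list(self.parts), "kappa": self.kappa,
            "n_per_group": dict(self.n_per_group),
            "group_means": {g: list(np.asarray(m, float))
                            for g, m in self.group_means.items()},
            "ilr_cov": np.asarray(self.ilr_cov, float).tolist(),
            "beta": {o: list(map(float, b)) for o, b in self.beta.items()},
            "gamma": {o: dict(g) for o, g in self.gamma.items()},
            "imd_effects": {o: list(map(float, e))
                            for o, e in self.imd_effects.items()},
            "gamma_zbmi_on_vo2": self.gamma_zbmi_on_vo2,
            "intercept": dict(self.intercept), "sigma": dict(self.sigma),
            "sex_p_girl": self.sex_p_girl, "age_mean": self.age_mean,
            "age_sd": self.age_sd, "imd_probs": list(self.imd_probs),
            "height_mean": self.height_mean, "height_sd": self.height_sd,
            "seed": self.seed,
        }


def default_config(seed: int = _DEFAULT_SEED) -> SyntheticConfig:
    """Study-condition defaults: group means, variation-matrix-derived ilr
    covariance, calibrated ilr effects, plausible covariate effects."""
    cfg = SyntheticConfig(seed=seed)
    cfg.group_means = {g: np.asarray(m, float)
                       for g, m in GROUP_MEAN_MINUTES.items() if g != "all"}
    sbp = cfg.basis
    cfg.ilr_cov = variation_to_lr_covariance(TARGET_VARIATION, sbp)
    cfg.beta = {o: calibrate_ilr_effects(t, GROUP_MEAN_MINUTES["all"], sbp)
                for o, t in DIFF_TARGETS_15MIN.items()}
    # modest covariate effects (girl vs boy reference; age in years,
    # centred at the cohort mean; deprivation decile as a shallow gradient)
    cfg.gamma = {
        "zbmi": {"sex_girl": -0.15, "age": 0.8},
        "whtr_pct": {"sex_girl": 1.2, "age": 2.0},
        "vo2peak": {"sex_girl": -0.3, "age": 0.6},
    }
    deciles = np.arange(10)
    cfg.imd_effects = {
        "zbmi": -0.04 * deciles,
        "whtr_pct": -0.15 * deciles,
        "vo2peak": 0.25 * deciles,
    }
    # anchor outcome levels near realistic cohort means at the mean
    # composition and covariate distribution
    anchors = {"zbmi": 0.43, "whtr_pct": 46.0, "vo2peak": 47.0}
    z_all = ilr(close(GROUP_MEAN_MINUTES["all"], parts=cfg.parts), sbp).values
    p = np.asarray(cfg.imd_probs)
    for o, target in anchors.items():
        expected = (cfg.beta[o] @ z_all
                    + cfg.gamma[o]["sex_girl"] * cfg.sex_p_girl
                    + cfg.gamma[o]["age"] * cfg.age_mean
                    + float(p @ cfg.imd_effects[o]))
        if o == "vo2peak":
            expected += cfg.gamma_zbmi_on_vo2 * anchors["zbmi"]
        cfg.intercept[o] = target - expected
    return cfg.validate()


def generate_compositions(cfg: SyntheticConfig, group: str,
                          n: int | None = None,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` compositions for one group, closed to ``cfg.kappa``.

    Logistic-normal: ilr coordinates are multivariate normal around the
    group mean's coordinates with covariance ``cfg.ilr_cov``; rows are
    strictly positive by construction.
    """
    cfg.validate()
    if group not in cfg.group_means:
        raise KeyError(f"unknown group {group!r}; groups: {list(cfg.group_means)}")
    if n is None:
        n = cfg.n_per_group.get(group)
        if n is None:
            raise KeyError(f"no sample size configured for group {group!r}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sbp = cfg.basis
    mu = ilr(close(cfg.group_means[group], cfg.kappa, cfg.parts), sbp).values
    Z = rng.multivariate_normal(mu, np.asarray(cfg.ilr_cov, float), size=n,
                                method="svd")
    raw = np.exp(Z @ sbp.contrast_matrix.T)
    return raw * (cfg.kappa / raw.sum(axis=1, keepdims=True))


def generate_records(cfg: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a full participant table.

    Columns: id, the four part durations (minutes), sex, age,
    imd_decile, weight_status, height_cm, waist_cm, and the outcomes
    zbmi, whtr_pct, vo2peak.  Waist is derived from the generated %WHtR
    and height so that 100*waist/height reproduces whtr_pct exactly.
    The weight-status label is the generating group.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sbp = cfg.basis
    frames = []
    for group, n in cfg.n_per_group.items():
        X = generate_compositions(cfg, group, n, rng)
        frames.append(pd.DataFrame(X, columns=list(cfg.parts)).assign(weight_status=group))
    df = pd.concat(frames, ignore_index=True)
    n_total = len(df)
    df.insert(0, "id", [f"P{i + 1:04d}" for i in range(n_total)])

    df["sex"] = np.where(rng.random(n_total) < cfg.sex_p_girl, "girl", "boy")
    df["age"] = rng.normal(cfg.age_mean, cfg.age_sd, n_total)
    df["imd_decile"] = rng.choice(np.arange(1, 11), size=n_total,
                                  p=np.asarray(cfg.imd_probs))
    df["height_cm"] = rng.normal(cfg.height_mean, cfg.height_sd, n_total)

    Z = np.log(df[list(cfg.parts)].to_numpy()) @ sbp.contrast_matrix
    girl = (df["sex"] == "girl").to_numpy(float)
    imd_idx = df["imd_decile"].to_numpy() - 1

    def linear(outcome: str) -> np.ndarray:
        return (cfg.intercept.get(outcome, 0.0)
                + Z @ cfg.beta[outcome]
                + cfg.gamma[outcome]["sex_girl"] * girl
                + cfg.gamma[outcome]["age"] * df["age"].to_numpy()
                + np.asarray(cfg.imd_effects[outcome])[imd_idx])

    df["zbmi"] = linear("zbmi") + rng.normal(0, cfg.sigma["zbmi"], n_total)
    df["whtr_pct"] = linear("whtr_pct") + rng.normal(0, cfg.sigma["whtr_pct"], n_total)
    df["vo2peak"] = (linear("vo2peak")
                     + cfg.gamma_zbmi_on_vo2 * df["zbmi"].to_numpy()
                     + rng.normal(0, cfg.sigma["vo2peak"], n_total))
    df["waist_cm"] = df["whtr_pct"] * df["height_cm"] / 100.0
    return df


def make_fixture(cfg: SyntheticConfig | None = None,
                 path: str | Path = ".") -> tuple[Path, Path]:
    """Write a seeded dataset plus a truth file for tests.

    ``data.csv`` uses the pipeline's input column names (``sleep_min``,
    ``st_min``, ...); ``truth.json`` records every generator parameter
    so parameter-recovery tests can compare estimates to truth.
    Byte-stable for a fixed config.
    """
    cfg = cfg if cfg is not None else default_config()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = generate_records(cfg)
    out = df.rename(columns={p: f"{p}_min" for p in cfg.parts})
    data_path = path / "data.csv"
    out.to_csv(data_path, index=False, float_format="%.10g", lineterminator="\n")
    truth_path = path / "truth.json"
    truth_path.write_text(json.dumps(cfg.to_dict(), indent=1, sort_keys=True) + "\n")
    return data_path, truth_path
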