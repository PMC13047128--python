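"""Synthetic PPMI-like panels with known time-varying mediation structure.

The generator is the simplest data-generating process consistent with a
linear time-varying-coefficient mediation model: for subject i at visit k
with normalized time t = k/(K-1),

    X_ik  ~ rounded truncated AR(1) Gaussian           (exposure, RBDSQ)
    M_ik  = a0 + alpha(t) X_ik + gamma_M' C_i + u_i^M + eps  (per mediator)
    Y_ik  = b0 + beta1(t) M1_ik + beta2(t) M2_ik + tau(t) X_ik
            + gamma_Y' C_i + u_i^Y + eps'

with baseline-fixed categorical covariates C_i, independent subject random
intercepts u_i, and Gaussian residuals.  With clipping on, emitted scores
are rounded and truncated to their scale ranges.  The true indirect effect
of mediator j at time t is the product of the configured paths,
alpha_j(t) * beta_j(t), available analytically via :func:`true_effects`.

Default paths are affine and increasing in t, so the indirect effect of each
mediator roughly doubles between t = 0.25 and t = 0.75 — the qualitative
regime in which mediation strengthens with disease duration.  Default
covariate marginals follow PPMI-like demographics (about 65% male, about 75%
over 65, predominantly White).

Per-subject random streams are spawned deterministically from the master
seed, so increasing ``n_subjects`` extends the cohort without reshuffling
existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from longmed.data_model import (
    COVARIATE_COLUMNS,
    DEFAULT_N_VISITS,
    SCALE_RANGES,
    CohortPanel,
    normalize_time,
)

MEDIATORS = ("gds15", "moca")

TimeFn = Callable[[np.ndarray], np.ndarray]


def _affine(a: float, b: float) -> TimeFn:
    """a + b*t as a vectorized function of normalized time."""

    def fn(t):
        return a + b * np.asarray(t, dtype=float)

    return fn


#: PPMI-like marginal frequencies for the baseline covariates
DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.3472, "male": 0.6528},
    "age_band": {"<56": 0.0326, "56-65": 0.2196, ">65": 0.7478},
    "edu_band": {"<13": 0.2226, "13-23": 0.7656, ">23": 0.0118},
    "race": {"White": 0.9614, "Black": 0.0059, "Asian": 0.0148, "other": 0.0179},
    "family_history": {"first-degree": 0.2166, "non-first-degree": 0.1691, "none": 0.6143},
    "duration_band": {"<5": 0.1602, "5-10": 0.2433, ">10": 0.5967},
}

#: modest covariate effects so adjustment is exercised but never dominant
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "gds15": {"sex=female": 0.4},
    "moca": {"edu_band=13-23": 0.5, "edu_band=>23": 1.0},
    "updrs2": {"sex=male": 0.8, "age_band=>65": 0.6},
}


@dataclass(frozen=True)
class ExposureModel:
    """Rounded truncated Gaussian RBDSQ with AR(1) within-subject dependence."""

    mean: float = 5.0
    sd: float = 2.5
    rho: float = 0.7  # latent autocorrelation between adjacent visits


@dataclass(frozen=True)
class DGPConfig:
    """Full specification of the synthetic data-generating process.

    ``alpha_fns``/``beta_fns`` map each mediator column to its exposure->
    mediator and mediator->outcome path as a function of normalized time;
    ``tau_fn`` is the direct exposure->outcome path.  SDs are on the raw
    score scale.
    """

    n_subjects: int = 337
    n_visits: int = DEFAULT_N_VISITS
    alpha_fns: dict[str, TimeFn] = field(
        default_factory=lambda: {
            "gds15": _affine(0.20, 0.20),
            "moca": _affine(-0.15, -0.25),
        }
    )
    beta_fns: dict[str, TimeFn] = field(
        default_factory=lambda: {
            "gds15": _affine(0.30, 0.30),
            "moca": _affine(-0.25, -0.35),
        }
    )
    tau_fn: TimeFn = field(default_factory=lambda: _affine(0.5, 0.3))
    intercepts: dict[str, float] = field(
        default_factory=lambda: {"gds15": 2.5, "moca": 26.5, "updrs2": 13.6}
    )
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()
        }
    )
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()
        }
    )
    random_effect_sd: dict[str, float] = field(
        default_factory=lambda: {"gds15": 1.0, "moca": 1.0, "updrs2": 2.0}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"gds15": 1.8, "moca": 2.0, "updrs2": 3.0}
    )
    exposure_model: ExposureModel = ExposureModel()
    clipping: bool = True
    dropout_rate: float = 0.0  # per-visit MAR dropout hazard, off by default
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_visits < 2:
            raise ValueError("need n_subjects >= 2 and n_visits >= 2")
        for d in (self.random_effect_sd, self.noise_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for m in MEDIATORS:
            if m not in self.alpha_fns or m not in self.beta_fns:
                raise ValueError(f"missing path function for mediator {m!r}")

    def with_(self, **kwargs) -> "DGPConfig":
        """Convenience copy-with-overrides."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrueEffectCurves:
    """Analytic effect curves implied by a configuration (no sampling)."""

    t_grid: np.ndarray
    ie_true: dict[str, np.ndarray]  # per mediator, alpha(t) * beta(t)
    de_true: np.ndarray  # tau(t)


def true_effects(config: DGPConfig, t_grid: Sequence[float]) -> TrueEffectCurves:
    """Pointwise product of the configured paths on a time grid."""
    config.validate()
    t = np.asarray(t_grid, dtype=float)
    if t.size and (t.min() < 0 or t.max() > 1):
        raise ValueError("t_grid values must lie in [0, 1]")
    ie = {
        m: np.asarray(config.alpha_fns[m](t)) * np.asarray(config.beta_fns[m](t))
        for m in MEDIATORS
    }
    return TrueEffectCurves(t_grid=t, ie_true=ie, de_true=np.asarray(config.tau_fn(t)))


def _draw_covariates(rng: np.random.Generator, marginals) -> dict[str, str]:
    row = {}
    for col in COVARIATE_COLUMNS:
        levels = list(marginals[col])
        probs = np.array([marginals[col][l] for l in levels], dtype=float)
        probs = probs / probs.sum()
        row[col] = levels[rng.choice(len(levels), p=probs)]
    return row


def _covariate_shift(effects: dict[str, float], cov: dict[str, str]) -> float:
    total = 0.0
    for key, eff in effects.items():
        col, _, level = key.partition("=")
        if cov[col] == level:
            total += eff
    return total


def _clip_round(x: np.ndarray, column: str, clipping: bool) -> np.ndarray:
    if not clipping:
        return x
    lo, hi = SCALE_RANGES[column]
    return np.clip(np.round(x), lo, hi)


def simulate_cohort(config: DGPConfig) -> CohortPanel:
    """Draw one panel from the configured process.

    Fully reproducible from ``config.seed``; subject i always receives the
    i-th spawned random stream.
    """
    config.validate()
    K = config.n_visits
    t = normalize_time(np.arange(K), K)
    alpha = {m: np.asarray(config.alpha_fns[m](t), dtype=float) for m in MEDIATORS}
    beta = {m: np.asarray(config.beta_fns[m](t), dtype=float) for m in MEDIATORS}
    tau = np.asarray(config.tau_fn(t), dtype=float)
    em = config.exposure_model

    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    records: list[dict] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cov = _draw_covariates(rng, config.covariate_marginals)
        u = {
            eq: rng.normal(0.0, config.random_effect_sd[eq])
            for eq in ("gds15", "moca", "updrs2")
        }

        # latent AR(1) exposure process
        z = np.empty(K)
        z[0] = rng.normal()
        innov = rng.normal(size=K - 1)
        for k in range(1, K):
            z[k] = em.rho * z[k - 1] + np.sqrt(1 - em.rho**2) * innov[k - 1]
        x = _clip_round(em.mean + em.sd * z, "rbdsq", True)  # scores always valid

        eps = {
            eq: rng.normal(0.0, config.noise_sd[eq], size=K)
            for eq in ("gds15", "moca", "updrs2")
        }
        med_vals = {}
        for m in MEDIATORS:
            raw = (
                config.intercepts[m]
                + alpha[m] * x
                + _covariate_shift(config.covariate_effects.get(m, {}), cov)
                + u[m]
                + eps[m]
            )
            med_vals[m] = _clip_round(raw, m, config.clipping)
        y_raw = (
            config.intercepts["updrs2"]
            + beta["gds15"] * med_vals["gds15"]
            + beta["moca"] * med_vals["moca"]
            + tau * x
            + _covariate_shift(config.covariate_effects.get("updrs2", {}), cov)
            + u["updrs2"]
            + eps["updrs2"]
        )
        y = _clip_round(y_raw, "updrs2", config.clipping)

        n_keep = K
        if config.dropout_rate > 0:
            stay = rng.random(K - 1) >= config.dropout_rate
            n_keep = 1 + int(np.argmin(stay)) if not stay.all() else K
        for k in range(n_keep):
            rec = {
                "subject_id": f"S{i:05d}",
                "visit": k,
                "rbdsq": x[k],
                "gds15": med_vals["gds15"][k],
                "moca": med_vals["moca"][k],
                "updrs2": y[k],
            }
            rec.update(cov)
            records.append(rec)

    df = pd.DataFrame.from_records(records)
    return CohortPanel(df, n_visits=K)


def simulate_linear_toy(
    n_subjects: int,
    a: float,
    b: float,
    c: float,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> CohortPanel:
    """Single-visit linear-Gaussian toy with one mediator.

    X ~ N(6, 2), M1 = 2 + a X + eps, Y = 1 + b M1 + c X + eps', no clipping.
    The unit-exposure-contrast effects have closed forms: TE = c + a*b,
    DE = c, IE = a*b.  Intended for validating the g-formula engine against
    product-of-coefficients arithmetic; the moca column is filled with a
    constant and takes no part in the toy.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(6.0, 2.0, size=n_subjects)
    m1 = 2.0 + a * x + rng.normal(0.0, noise_sd, size=n_subjects)
    y = 1.0 + b * m1 + c * x + rng.normal(0.0, noise_sd, size=n_subjects)
    df = pd.DataFrame(
        {
            "subject_id": [f"L{i:06d}" for i in range(n_subjects)],
            "visit": 0,
            "rbdsq": x,
            "gds15": m1,
            "moca": 0.0,
            "updrs2": y,
            "sex": "female",
            "age_band": "<56",
            "edu_band": "<13",
            "race": "White",
            "family_history": "none",
            "duration_band": "<5",
        }
    )
    return CohortPanel(df, n_visits=1)


# --------------------------------------------------------------------------
# Discrete toys: binary X, M1, M2, Y over 1-2 visits, with retained CPTs so
# the g-formula can be enumerated exactly.
# --------------------------------------------------------------------------


def _check_cpt(name: str, table: np.ndarray, n_parents: int) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.shape != (2,) * (n_parents + 1):
        raise ValueError(
            f"CPT {name!r} must have shape {(2,) * (n_parents + 1)}, "
            f"got {table.shape}"
        )
    sums = table.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ValueError(f"CPT {name!r} rows do not sum to 1")
    if np.any(table < -1e-12):
        raise ValueError(f"CPT {name!r} has negative probabilities")
    return table


@dataclass(frozen=True)
class ToyCPTs:
    """Conditional probability tables of a binary two-mediator toy.

    Structure (last axis = outcome value 0/1):

    * ``px[k]``: P(X_k), shape (2,)
    * ``pm1[0]``: P(M1_0 | X_0), shape (2, 2)
    * ``pm2[0]``: P(M2_0 | X_0, M1_0), shape (2, 2, 2)
    * ``pm1[1]``: P(M1_1 | X_1, M1_0), shape (2, 2, 2)       (if 2 visits)
    * ``pm2[1]``: P(M2_1 | X_1, M1_1, M2_0), shape (2, 2, 2, 2)
    * ``py``: P(Y | X_last, M1_last, M2_last), shape (2, 2, 2, 2)
    """

    px: tuple[np.ndarray, ...]
    pm1: tuple[np.ndarray, ...]
    pm2: tuple[np.ndarray, ...]
    py: np.ndarray

    def __post_init__(self):
        K = self.n_visits
        if K not in (1, 2):
            raise ValueError("toy supports 1 or 2 visits")
        if not (len(self.pm1) == len(self.pm2) == K):
            raise ValueError("px, pm1, pm2 must have one table per visit")
        px = tuple(_check_cpt(f"px[{k}]", p, 0) for k, p in enumerate(self.px))
        pm1 = [_check_cpt("pm1[0]", self.pm1[0], 1)]
        pm2 = [_check_cpt("pm2[0]", self.pm2[0], 2)]
        if K == 2:
            pm1.append(_check_cpt("pm1[1]", self.pm1[1], 2))
            pm2.append(_check_cpt("pm2[1]", self.pm2[1], 3))
        py = _check_cpt("py", self.py, 3)
        object.__setattr__(self, "px", px)
        object.__setattr__(self, "pm1", tuple(pm1))
        object.__setattr__(self, "pm2", tuple(pm2))
        object.__setattr__(self, "py", py)

    @property
    def n_visits(self) -> int:
        return len(self.px)


def random_toy_cpts(seed: int, n_visits: int = 2) -> ToyCPTs:
    """A seeded random toy, useful for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)

    def rand_cpt(n_parents):
        p1 = rng.uniform(0.1, 0.9, size=(2,) * n_parents)
        return np.stack([1 - p1, p1], axis=-1)

    px = tuple(rand_cpt(0) for _ in range(n_visits))
    pm1 = [rand_cpt(1)] + ([rand_cpt(2)] if n_visits == 2 else [])
    pm2 = [rand_cpt(2)] + ([rand_cpt(3)] if n_visits == 2 else [])
    return ToyCPTs(px=px, pm1=tuple(pm1), pm2=tuple(pm2), py=rand_cpt(3))


def simulate_toy_discrete(
    n_subjects: int, cpts: ToyCPTs, seed: int
) -> tuple[CohortPanel, ToyCPTs]:
    """Sample a binary panel exactly from the CPTs.

    Binary values are stored directly in the score columns (all within their
    scale ranges); covariates are filled with a constant reference level.
    The CPTs are returned alongside the panel so the exact g-formula can be
    enumerated.
    """
    rng = np.random.default_rng(seed)
    K = cpts.n_visits
    n = n_subjects

    def bern(p):
        return (rng.random(p.shape) < p).astype(int)

    x = np.empty((n, K), dtype=int)
    m1 = np.empty((n, K), dtype=int)
    m2 = np.empty((n, K), dtype=int)
    for k in range(K):
        x[:, k] = bern(np.full(n, cpts.px[k][1]))
        if k == 0:
            m1[:, 0] = bern(cpts.pm1[0][x[:, 0], 1])
            m2[:, 0] = bern(cpts.pm2[0][x[:, 0], m1[:, 0], 1])
        else:
            m1[:, 1] = bern(cpts.pm1[1][x[:, 1], m1[:, 0], 1])
            m2[:, 1] = bern(cpts.pm2[1][x[:, 1], m1[:, 1], m2[:, 0], 1])
    y_last = bern(cpts.py[x[:, -1], m1[:, -1], m2[:, -1], 1])

    y = np.zeros((n, K), dtype=int)
    y[:, K - 1] = y_last
    ids = np.repeat([f"T{i:06d}" for i in range(n)], K)
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "visit": np.tile(np.arange(K), n),
            "rbdsq": x.ravel(),
            "gds15": m1.ravel(),
            "moca": m2.ravel(),
            "updrs2": y.ravel(),
            "sex": "female",
            "age_band": "<56",
            "edu_band": "<13",
            "race": "White",
            "family_history": "none",
            "duration_band": "<5",
        }
    )
    return CohortPanel(df, n_visits=K), cpts
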