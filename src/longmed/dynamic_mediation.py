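"""Bayesian dynamic (time-varying-coefficient) mediation for one mediator.

Model
-----
For subject i at visit time t (min–max normalized to [0, 1]), with exposure
X, a single mediator M, outcome Y, and baseline covariate dummies C_i:

    M_it = a0(t) + alpha(t) X_it + gamma_M' C_i + u_i^M + eps_it^M
    Y_it = b0(t) + beta(t) M_it + tau(t) X_it + gamma_Y' C_i + u_i^Y + eps_it^Y

alpha(t) is the time-varying exposure->mediator path, beta(t) the mediator->
outcome path adjusted for exposure, tau(t) the direct path.  Each
time-varying coefficient is a linear combination of basis functions of t
(cubic B-spline with 5 degrees of freedom by default; a linear-in-t basis is
available for small samples).  u_i are independent subject random
intercepts; residuals are Gaussian.  The time-t indirect effect is the
product of paths, IE(t) = alpha(t) * beta(t), summarized by its posterior
mean, SD and equal-tailed 95% credible interval.

Inference
---------
The two equations are conditionally independent given the data, and with
Gaussian priors on coefficients and inverse-gamma priors on variances every
full conditional is available in closed form, so each equation is sampled by
a block Gibbs sampler (coefficients | rest, random intercepts | rest,
variances | rest).  Multiple chains with overdispersed starts support
split-R-hat and ESS diagnostics (via arviz).

By default X, M and Y are z-scored before fitting, so coefficient priors of
unit scale are weakly informative and IE(t) is reported on the standardized
scale; the raw-score scale is an exact rescaling by sd(Y)/sd(X).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from longmed.data_model import CohortPanel, complete_case_filter

__all__ = [
    "BasisSpec",
    "Priors",
    "DynMedSpec",
    "PosteriorDraws",
    "IndirectEffectSummary",
    "ConvergenceReport",
    "fit_dynamic_mediation",
    "indirect_effect_curve",
    "diagnose",
]


class FitError(ValueError):
    """The model cannot be fit on this panel (degenerate design etc.)."""


@dataclass(frozen=True)
class BasisSpec:
    """Basis for the time-varying coefficients.

    ``kind`` is ``"bspline"`` (cubic, ``df`` functions on [0, 1]) or
    ``"linear"`` (intercept + slope in t, df fixed at 2).
    """

    kind: str = "bspline"
    df: int = 5

    def n_funcs(self) -> int:
        return 2 if self.kind == "linear" else self.df

    def matrix(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < 0 or t.max() > 1):
            raise ValueError("basis evaluated outside [0, 1]")
        if self.kind == "linear":
            return np.column_stack([np.ones_like(t), t])
        if self.kind != "bspline":
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.df < 4:
            raise ValueError("cubic B-spline basis needs df >= 4")
        k = 3
        interior = np.linspace(0.0, 1.0, self.df - k + 1)[1:-1]
        knots = np.concatenate([[0.0] * (k + 1), interior, [1.0] * (k + 1)])
        # design_matrix drops the right endpoint from the last interval;
        # nudge t=1 inside to keep the basis well defined there
        tt = np.minimum(t, 1.0 - 1e-12)
        return BSpline.design_matrix(tt, knots, k).toarray()


@dataclass(frozen=True)
class Priors:
    """Weakly informative conjugate priors (on standardized data).

    Coefficients: Normal(0, coef_scale^2).  Residual and random-intercept
    variances: InverseGamma(shape, rate).
    """

    coef_scale: float = 1.0
    resid_shape: float = 2.0
    resid_rate: float = 1.0
    ranef_shape: float = 2.0
    ranef_rate: float = 0.5


@dataclass(frozen=True)
class DynMedSpec:
    """Configuration of a single-mediator dynamic mediation fit."""

    mediator: str = "gds15"
    basis: BasisSpec = BasisSpec()
    priors: Priors = Priors()
    n_iter: int = 10_000
    n_warmup: int = 5_000
    n_chains: int = 4
    seed: int = 0
    standardize: bool = True

    def validate(self) -> None:
        if self.mediator not in ("gds15", "moca"):
            raise ValueError("mediator must be 'gds15' or 'moca'")
        if not (self.n_iter > self.n_warmup >= 0):
            raise ValueError("need n_iter > n_warmup >= 0")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of every model parameter.

    Weight blocks have shape (chain, draw, n_basis); scalars (chain, draw).
    ``scale`` holds the standard deviations used for z-scoring (all 1.0 when
    fitting on the raw scale).
    """

    spec: DynMedSpec
    params: dict[str, np.ndarray]
    param_labels: dict[str, list[str]]
    scale: dict[str, float]
    data_hash: str
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        sig = self.params["sigma_m"]
        return sig.shape[0] * sig.shape[1]

    def curve_draws(self, block: str, t_grid: Sequence[float]) -> np.ndarray:
        """Evaluate a time-varying coefficient per draw; (n_draws, n_t)."""
        B = self.spec.basis.matrix(np.asarray(t_grid, dtype=float))
        w = self.params[block]
        flat = w.reshape(-1, w.shape[-1])
        return flat @ B.T

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(posterior=self.params)


@dataclass(frozen=True)
class IndirectEffectSummary:
    """Posterior summary of IE(t) = alpha(t) * beta(t) at a single time."""

    t: float
    ie_mean: float
    ie_sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-R-hat and ESS per scalar parameter, with trouble flags."""

    table: pd.DataFrame  # columns: parameter, rhat, ess, flagged
    rhat_threshold: float
    ess_threshold: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "parameter"])

    @property
    def ok(self) -> bool:
        return not self.table["flagged"].any()


from longmed._design import dummy_design as _dummy_design


def _gibbs_equation(
    y: np.ndarray,
    Z: np.ndarray,
    subj: np.ndarray,
    n_subjects: int,
    priors: Priors,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Block Gibbs for one mixed linear equation y = Z w + u_subj + eps.

    The coefficient block is collapsed: w is drawn from its conditional
    given only the variances, with the random intercepts integrated out
    (their covariance contribution is a rank-one term per subject), which
    removes the strong posterior correlation between between-subject
    covariate effects and the intercepts.  u_i, sigma^2 and sigma_u^2 then
    follow their standard conjugate conditionals.  Returns retained draws of
    w, sigma (residual SD) and sigma_u (random-intercept SD).
    """
    n, p = Z.shape
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    prior_prec = np.full(p, 1.0 / priors.coef_scale**2)
    n_per_subj = np.bincount(subj, minlength=n_subjects).astype(float)
    # per-subject column sums of Z and of y, for the collapsed update
    S = np.zeros((n_subjects, p))
    np.add.at(S, subj, Z)
    s_y = np.bincount(subj, weights=y, minlength=n_subjects)

    w = rng.normal(0.0, priors.coef_scale, size=p)  # overdispersed start
    u = np.zeros(n_subjects)
    sigma2 = float(np.var(y)) or 1.0
    sigma_u2 = 0.5 * sigma2 + 1e-6

    keep = n_iter - n_warmup
    out_w = np.empty((keep, p))
    out_sigma = np.empty(keep)
    out_sigma_u = np.empty(keep)

    for it in range(n_iter):
        # coefficients | variances (random intercepts marginalized out):
        # y ~ N(Zw, sigma2 I + sigma_u2 * block(J)), whose inverse is
        # (I - J * sigma_u2/(sigma2 + n_i sigma_u2)) / sigma2 per subject
        c = sigma_u2 / (sigma2 * (sigma2 + n_per_subj * sigma_u2))
        A = ZtZ / sigma2 - S.T @ (S * c[:, None]) + np.diag(prior_prec)
        b = Zty / sigma2 - S.T @ (c * s_y)
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
        w = mean + np.linalg.solve(L.T, rng.normal(size=p))

        # random intercepts | w, variances
        resid = y - Z @ w
        sums = s_y - S @ w
        var_u = 1.0 / (n_per_subj / sigma2 + 1.0 / sigma_u2)
        u = var_u * sums / sigma2 + np.sqrt(var_u) * rng.normal(size=n_subjects)

        # variances | rest
        e = resid - u[subj]
        sigma2 = 1.0 / rng.gamma(
            priors.resid_shape + 0.5 * n, 1.0 / (priors.resid_rate + 0.5 * e @ e)
        )
        sigma_u2 = 1.0 / rng.gamma(
            priors.ranef_shape + 0.5 * n_subjects,
            1.0 / (priors.ranef_rate + 0.5 * u @ u),
        )

        if it >= n_warmup:
            j = it - n_warmup
            out_w[j] = w
            out_sigma[j] = np.sqrt(sigma2)
            out_sigma_u[j] = np.sqrt(sigma_u2)

    return {"w": out_w, "sigma": out_sigma, "sigma_u": out_sigma_u}


def fit_dynamic_mediation(panel: CohortPanel, spec: DynMedSpec) -> PosteriorDraws:
    """Sample the joint posterior of the two-equation dynamic mediation model.

    Complete cases only; reproducible from ``spec.seed``.  A convergence
    pre-check (split-R-hat > 1.05 on any parameter) attaches a warning to the
    returned draws rather than failing.
    """
    spec.validate()
    panel, _ = complete_case_filter(panel)
    df = panel.df.sort_values(["subject_id", "visit"]).reset_index(drop=True)

    x = df["rbdsq"].to_numpy(float)
    m = df[spec.mediator].to_numpy(float)
    y = df["updrs2"].to_numpy(float)
    if np.std(x) == 0:
        raise FitError("degenerate design: exposure is constant")
    if np.std(m) == 0:
        raise FitError("degenerate design: mediator is constant")

    scale = {"x": 1.0, "m": 1.0, "y": 1.0}
    if spec.standardize:
        scale = {"x": float(np.std(x)), "m": float(np.std(m)), "y": float(np.std(y))}
        x = (x - x.mean()) / scale["x"]
        m = (m - m.mean()) / scale["m"]
        y = (y - y.mean()) / scale["y"]

    t = df["visit"].to_numpy() / (panel.n_visits - 1)
    B = spec.basis.matrix(t)
    nb = spec.basis.n_funcs()
    D, dummy_labels = _dummy_design(df)

    subj_codes, _ = pd.factorize(df["subject_id"], sort=True)
    n_subjects = int(subj_codes.max()) + 1

    Z_m = np.hstack([B, B * x[:, None], D])
    Z_y = np.hstack([B, B * m[:, None], B * x[:, None], D])

    h = hashlib.sha256(
        np.ascontiguousarray(np.column_stack([t, x, m, y])).tobytes()
    ).hexdigest()[:16]

    seeds = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_chains)
    chains_m, chains_y = [], []
    for c in range(spec.n_chains):
        rng_m = np.random.default_rng(seeds[2 * c])
        rng_y = np.random.default_rng(seeds[2 * c + 1])
        chains_m.append(
            _gibbs_equation(m, Z_m, subj_codes, n_subjects, spec.priors,
                            spec.n_iter, spec.n_warmup, rng_m)
        )
        chains_y.append(
            _gibbs_equation(y, Z_y, subj_codes, n_subjects, spec.priors,
                            spec.n_iter, spec.n_warmup, rng_y)
        )

    def stack(chains, key):
        return np.stack([c[key] for c in chains])

    w_m = stack(chains_m, "w")
    w_y = stack(chains_y, "w")
    nd = len(dummy_labels)
    params = {
        "a0_w": w_m[:, :, :nb],
        "alpha_w": w_m[:, :, nb : 2 * nb],
        "gamma_m": w_m[:, :, 2 * nb :],
        "b0_w": w_y[:, :, :nb],
        "beta_w": w_y[:, :, nb : 2 * nb],
        "tau_w": w_y[:, :, 2 * nb : 3 * nb],
        "gamma_y": w_y[:, :, 3 * nb :],
        "sigma_m": stack(chains_m, "sigma"),
        "sigma_u_m": stack(chains_m, "sigma_u"),
        "sigma_y": stack(chains_y, "sigma"),
        "sigma_u_y": stack(chains_y, "sigma_u"),
    }
    labels = {
        "a0_w": [f"a0_w[{i}]" for i in range(nb)],
        "alpha_w": [f"alpha_w[{i}]" for i in range(nb)],
        "beta_w": [f"beta_w[{i}]" for i in range(nb)],
        "tau_w": [f"tau_w[{i}]" for i in range(nb)],
        "b0_w": [f"b0_w[{i}]" for i in range(nb)],
        "gamma_m": [f"gamma_m[{l}]" for l in dummy_labels],
        "gamma_y": [f"gamma_y[{l}]" for l in dummy_labels],
    }

    draws = PosteriorDraws(
        spec=spec, params=params, param_labels=labels, scale=scale, data_hash=h
    )
    report = diagnose(draws)
    if not report.ok:
        msg = (
            "convergence flags on: " + ", ".join(report.flagged[:8])
            + ("..." if len(report.flagged) > 8 else "")
        )
        draws.warnings.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return draws


def indirect_effect_curve(
    draws: PosteriorDraws,
    t_grid: Sequence[float],
    scale: str | None = None,
) -> list[IndirectEffectSummary]:
    """Posterior mean/SD and equal-tailed 95% credible band of IE(t).

    ``scale`` selects the reporting scale: ``None`` keeps the fitting scale,
    ``"raw"`` converts a standardized fit back to raw score units (multiply
    by sd(Y)/sd(X)), ``"standardized"`` asserts the fit was standardized.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    alpha = draws.curve_draws("alpha_w", t_grid)
    beta = draws.curve_draws("beta_w", t_grid)
    ie = alpha * beta  # per-draw product of paths

    factor = 1.0
    if scale == "raw":
        factor = draws.scale["y"] / draws.scale["x"]
    elif scale == "standardized":
        if draws.scale["x"] == draws.scale["y"] == 1.0 and not draws.spec.standardize:
            raise ValueError("fit was not standardized")
    elif scale is not None:
        raise ValueError(f"unknown scale {scale!r}")
    ie = ie * factor

    lo, hi = np.percentile(ie, [2.5, 97.5], axis=0)
    return [
        IndirectEffectSummary(
            t=float(tv),
            ie_mean=float(ie[:, j].mean()),
            ie_sd=float(ie[:, j].std(ddof=1)),
            ci_low=float(lo[j]),
            ci_high=float(hi[j]),
        )
        for j, tv in enumerate(t_grid)
    ]


def curve_frame(
    draws: PosteriorDraws, t_grid: Sequence[float], scale: str | None = None
) -> pd.DataFrame:
    """The IE(t) summary as a tidy frame (t, ie_mean, ie_sd, ci_low, ci_high)."""
    rows = indirect_effect_curve(draws, t_grid, scale=scale)
    return pd.DataFrame(
        {
            "t": [r.t for r in rows],
            "ie_mean": [r.ie_mean for r in rows],
            "ie_sd": [r.ie_sd for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
        }
    )


def diagnose(
    draws: PosteriorDraws,
    rhat_threshold: float = 1.05,
    ess_threshold: float = 400.0,
) -> ConvergenceReport:
    """Split-R-hat and bulk ESS for every scalar parameter.

    Degenerate (constant) chains yield undefined R-hat; those parameters are
    flagged rather than crashing.
    """
    n_chains = draws.params["sigma_m"].shape[0]
    if n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz warns on constant chains
        for block, arr in draws.params.items():
            if arr.ndim == 2:
                arr = arr[:, :, None]
                names = [block]
            else:
                names = draws.param_labels.get(
                    block, [f"{block}[{i}]" for i in range(arr.shape[-1])]
                )
            ds = az.convert_to_dataset(arr)
            rhats = np.atleast_1d(np.asarray(az.rhat(ds)["x"]))
            esss = np.atleast_1d(np.asarray(az.ess(ds)["x"]))
            for j, name in enumerate(names):
                if np.allclose(arr[:, :, j].std(axis=1), 0):
                    rows.append((name, np.nan, np.nan, True))
                    continue
                rhat, ess = float(rhats[j]), float(esss[j])
                flagged = (
                    (not np.isfinite(rhat)) or rhat > rhat_threshold
                    or ess < ess_threshold
                )
                rows.append((name, rhat, ess, bool(flagged)))
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged"])
    return ConvergenceReport(table, rhat_threshold, ess_threshold)


def trace_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-chain draw series in long format, for trace plotting/export."""
    recs = []
    for block, arr in draws.params.items():
        if arr.ndim == 2:
            arr = arr[:, :, None]
            names = [block]
        else:
            names = draws.param_labels.get(
                block, [f"{block}[{i}]" for i in range(arr.shape[-1])]
            )
        n_chains, n_draws, _ = arr.shape
        for j, name in enumerate(names):
            for c in range(n_chains):
                recs.append(
                    pd.DataFrame(
                        {
                            "parameter": name,
                            "chain": c,
                            "draw": np.arange(n_draws),
                            "value": arr[c, :, j],
                        }
                    )
                )
    return pd.concat(recs, ignore_index=True)
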