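"""Sample-size-weighted Bayesian linear regression via adaptive Metropolis.

The question asked of the data: does plasma C-peptide rise with the
smoothed predicted-minus-observed EBCM at the same time after diagnosis?
Each paired observation carries the reporting study's sample size n_i; the
likelihood is Gaussian with per-point variance sigma^2 / w_i, where
w_i = n_i / sum(n) are normalized sample-size weights and sigma^2 is
profiled at its conditional maximum on every evaluation (an empirical-Bayes
plug-in rather than a prior on the variance).  The prior on (slope,
intercept) is flat and improper; the Gaussian distribution mentioned
alongside the sampler is the random-walk *proposal*, whose scale is adapted
to a target acceptance fraction of 0.4 and then frozen.

Three chains start overdispersed around the weighted-least-squares solution
(+/- 4 standard errors), convergence is declared when the Gelman-Rubin
potential scale reduction factor drops below 1.1 for both parameters on
doubling windows, and at least 100,000 post-convergence steps per chain are
pooled.  The headline statistic is P(slope > 0), the fraction of pooled
slope samples above zero; values above 0.95 are declared significant.

Under this likelihood and flat prior the slope marginal is analytically a
Student-t centered at the WLS estimate (n - 2 df, classical WLS scale);
the sampler is checked against that closed form in the test suite, never
replaced by it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .residuals import PairedObservation

__all__ = [
    "RegressionData",
    "MCMCConfig",
    "MetropolisChain",
    "ConvergenceError",
    "log_likelihood",
    "make_loglik",
    "wls_fit",
    "metropolis_chain",
    "gelman_rubin",
    "run_regression",
    "posterior_summary",
    "WeightedBayesLinearModel",
    "BayesRegressionResults",
]


class ConvergenceError(RuntimeError):
    """Raised when PSRF never drops below threshold within the step budget."""


@dataclass(frozen=True)
class RegressionData:
    """Paired observations ready for the weighted regression.

    Weights are the study sample sizes; the likelihood normalizes them to
    ``w_i = n_i / sum(n)`` (their scale is absorbed by the profiled
    variance).
    """

    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray  # raw sample sizes
    y_se: np.ndarray | None = None
    weight_mode: str = "sample_size"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "weights", w)
        if not (x.size == y.size == w.size):
            raise ValueError("x, y, weights must have equal length")
        if x.size < 3:
            raise ValueError(f"need >=3 paired observations, got {x.size}")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("x and y must be finite")

    @classmethod
    def from_pairs(cls, pairs: Sequence[PairedObservation]) -> "RegressionData":
        return cls(
            x=np.array([p.x for p in pairs]),
            y=np.array([p.y for p in pairs]),
            weights=np.array([p.weight for p in pairs]),
            y_se=np.array([p.y_se for p in pairs]),
        )

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def normalized_weights(self) -> np.ndarray:
        return self.weights / self.weights.sum()


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_steps`` counts post-convergence samples per chain; adaptation and
    burn-in are on top of it.  ``target_acceptance`` is the acceptance
    fraction the proposal scale is tuned to (0.4), frozen once the batch
    acceptance stabilizes within +/-0.05.
    """

    n_chains: int = 3
    n_steps: int = 100_000
    target_acceptance: float = 0.4
    adapt_steps: int = 30_000
    adapt_batch: int = 500
    seed: int = 0
    psrf_threshold: float = 1.1
    init_window: int = 1_000
    max_convergence_steps: int = 200_000

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not (0.0 < self.target_acceptance < 1.0):
            raise ValueError("target_acceptance must lie in (0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class MetropolisChain:
    """Post-adaptation output of one random-walk Metropolis chain."""

    samples: np.ndarray  # (n_steps, d)
    acceptance_fraction: float
    proposal_scale: float
    n_adapt_steps: int


# -- likelihood ---------------------------------------------------------------


def make_loglik(
    data: RegressionData, use_se: bool = False
) -> Callable[[np.ndarray], float]:
    """Build an O(1)-per-call log-likelihood from precomputed moments.

    The weighted residual sum of squares is a quadratic in (slope,
    intercept), so six weighted moments suffice.  Default: variance
    sigma^2 / w_i with sigma^2 profiled (floored at 1e-12 so exactly
    collinear data does not produce -inf at the optimum).  With
    ``use_se`` the per-point variances are the reported SE_i^2, fixed.
    """
    x, y = data.x, data.y
    if use_se:
        if data.y_se is None or np.any(data.y_se <= 0):
            raise ValueError("use_se requires positive y_se for every pair")
        w = 1.0 / data.y_se**2
        const = -0.5 * float(np.sum(np.log(2.0 * math.pi / w)))
        profiled = False
    else:
        w = data.normalized_weights
        const = 0.5 * float(np.sum(np.log(w)))
        profiled = True
    n = x.size
    sw = float(w.sum())
    sx = float(w @ x)
    sy = float(w @ y)
    sxx = float(w @ (x * x))
    sxy = float(w @ (x * y))
    syy = float(w @ (y * y))

    def loglik(theta) -> float:
        slope = float(theta[0])
        intercept = float(theta[1])
        rss = (
            syy
            - 2.0 * slope * sxy
            - 2.0 * intercept * sy
            + slope * slope * sxx
            + 2.0 * slope * intercept * sx
            + intercept * intercept * sw
        )
        if profiled:
            sigma2 = max(rss / n, 1e-12)
            return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0) + const
        return const - 0.5 * max(rss, 0.0)

    return loglik


def log_likelihood(slope: float, intercept: float, data: RegressionData) -> float:
    """Weighted Gaussian log-likelihood with profiled variance (see module doc)."""
    if not (math.isfinite(slope) and math.isfinite(intercept)):
        raise ValueError("slope and intercept must be finite")
    return make_loglik(data)((slope, intercept))


def wls_fit(
    data: RegressionData, use_se: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form weighted least squares.

    Returns ``(theta, cov)`` with ``theta = [slope, intercept]`` and the
    classical covariance ``sigma_hat^2 (X'WX)^{-1}``, ``sigma_hat^2 =
    RSS_w/(n-2)``.
    """
    w = (1.0 / data.y_se**2) if use_se else data.normalized_weights
    x, y = data.x, data.y
    a = np.array(
        [[float(w @ (x * x)), float(w @ x)], [float(w @ x), float(w.sum())]]
    )
    rhs = np.array([float(w @ (x * y)), float(w @ y)])
    theta = np.linalg.solve(a, rhs)
    resid = y - theta[0] * x - theta[1]
    dof = max(data.n - 2, 1)
    sigma2 = float(w @ resid**2) / dof
    cov = sigma2 * np.linalg.inv(a)
    return theta, cov


# -- sampler ------------------------------------------------------------------


class _ChainState:
    """One random-walk Metropolis chain with batch-adaptive proposal scale.

    The proposal is an isotropic-in-scaled-coordinates Gaussian,
    ``theta' = theta + scale * proposal_sd * z``.  During adaptation the
    log-scale moves by ``gain_b * (acc_batch - target)`` with a decaying
    gain; the scale freezes once two consecutive batch acceptance fractions
    sit within 0.03 of the target (or the adaptation budget runs out).
    Post-freeze samples only are ever reported.
    """

    def __init__(
        self,
        loglik: Callable[[np.ndarray], float],
        init: np.ndarray,
        proposal_sd: np.ndarray,
        config: MCMCConfig,
        chain_seed: int,
    ) -> None:
        self.loglik = loglik
        self.theta = np.array(init, dtype=float)
        self.proposal_sd = np.array(proposal_sd, dtype=float)
        if np.any(self.proposal_sd <= 0):
            raise ValueError("proposal_sd must be positive componentwise")
        self.lp = float(loglik(self.theta))
        if not math.isfinite(self.lp):
            raise ValueError(
                f"log-likelihood is not finite at the initial point {self.theta}"
            )
        self.config = config
        self.rng = np.random.default_rng(chain_seed)
        self.scale = 1.0
        self.n_adapt_steps = 0
        self._adapted = False

    def _run(self, n: int, record: bool) -> tuple[np.ndarray | None, int]:
        d = self.theta.size
        steps = self.rng.standard_normal((n, d)) * (self.scale * self.proposal_sd)
        logu = np.log(self.rng.random(n))
        samples = np.empty((n, d)) if record else None
        theta, lp, ll = self.theta, self.lp, self.loglik
        accepted = 0
        for i in range(n):
            cand = theta + steps[i]
            lp_cand = ll(cand)
            if logu[i] <= lp_cand - lp:
                theta, lp = cand, lp_cand
                accepted += 1
            if record:
                samples[i] = theta
        self.theta, self.lp = theta, lp
        return samples, accepted

    def adapt(self) -> None:
        cfg = self.config
        target = cfg.target_acceptance
        streak = 0
        batch_index = 0
        while self.n_adapt_steps < cfg.adapt_steps:
            _, accepted = self._run(cfg.adapt_batch, record=False)
            self.n_adapt_steps += cfg.adapt_batch
            frac = accepted / cfg.adapt_batch
            if abs(frac - target) <= 0.03:
                streak += 1
                if streak >= 2 and batch_index >= 3:
                    break
            else:
                streak = 0
                gain = 2.0 / math.sqrt(1.0 + batch_index)
                self.scale *= math.exp(gain * (frac - target))
            batch_index += 1
        self._adapted = True

    def sample(self, n: int) -> tuple[np.ndarray, float]:
        """Draw ``n`` post-adaptation samples; returns (samples, acceptance)."""
        if not self._adapted:
            self.adapt()
        samples, accepted = self._run(n, record=True)
        return samples, accepted / n


def metropolis_chain(
    loglik: Callable[[np.ndarray], float],
    init,
    proposal_sd,
    config: MCMCConfig | None = None,
    chain_seed: int = 0,
) -> MetropolisChain:
    """Run one adaptive random-walk Metropolis chain.

    ``loglik`` maps a parameter vector to a log density (flat improper
    prior: the posterior is the likelihood).  The proposal scale is adapted
    toward ``config.target_acceptance`` and frozen; only the
    ``config.n_steps`` frozen-scale samples are returned, with the
    acceptance fraction measured over exactly those steps.
    """
    config = config or MCMCConfig()
    state = _ChainState(loglik, np.atleast_1d(init), np.atleast_1d(proposal_sd),
                        config, chain_seed)
    state.adapt()
    samples, acc = state.sample(config.n_steps)
    return MetropolisChain(
        samples=samples,
        acceptance_fraction=acc,
        proposal_scale=state.scale,
        n_adapt_steps=state.n_adapt_steps,
    )


def gelman_rubin(chains: Sequence[np.ndarray]) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``PSRF = sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain
    variance and B = n * variance of the chain means (both with ddof=1).
    Identical duplicated chains give the floor ``sqrt((n-1)/n)``.
    """
    arrs = [np.atleast_2d(np.asarray(c, dtype=float).T).T for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least 2 chains")
    n = arrs[0].shape[0]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("chains must have equal shapes")
    if n < 10:
        raise ValueError("chains too short for a meaningful PSRF (need n >= 10)")
    stacked = np.stack(arrs)  # (m, n, d)
    within = stacked.var(axis=1, ddof=1).mean(axis=0)
    if np.any(within <= 0):
        raise ValueError("degenerate chains: zero within-chain variance")
    between = n * stacked.mean(axis=1).var(axis=0, ddof=1)
    var_hat = (n - 1) / n * within + between / n
    return np.sqrt(var_hat / within)


# -- model/results objects ----------------------------------------------------


@dataclass(frozen=True)
class BayesRegressionResults:
    """Posterior over (slope, intercept) with sampler diagnostics.

    ``slope_samples``/``intercept_samples`` hold the post-convergence
    samples per chain; pooled views and the headline P(slope > 0) are
    derived properties.
    """

    slope_samples: tuple[np.ndarray, ...]
    intercept_samples: tuple[np.ndarray, ...]
    acceptance_fraction: tuple[float, ...]
    psrf: np.ndarray  # per parameter (slope, intercept)
    wls_params: np.ndarray  # [slope, intercept]
    wls_cov: np.ndarray
    n_burn_in: int
    config: MCMCConfig
    data: RegressionData = field(repr=False)

    @property
    def pooled_slope(self) -> np.ndarray:
        return np.concatenate(self.slope_samples)

    @property
    def pooled_intercept(self) -> np.ndarray:
        return np.concatenate(self.intercept_samples)

    @property
    def p_slope_positive(self) -> float:
        return float(np.mean(self.pooled_slope > 0.0))

    @property
    def significant(self) -> bool:
        """True when P(slope > 0) exceeds the 0.95 significance bar."""
        return self.p_slope_positive > 0.95

    @property
    def slope_intercept_correlation(self) -> float:
        return float(np.corrcoef(self.pooled_slope, self.pooled_intercept)[0, 1])

    @property
    def params(self) -> np.ndarray:
        """Posterior means, ``[slope, intercept]``."""
        return np.array(
            [self.pooled_slope.mean(), self.pooled_intercept.mean()]
        )

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = 100.0 * np.array([(1 - level) / 2, 1 - (1 - level) / 2])
        return np.array(
            [
                np.percentile(self.pooled_slope, q),
                np.percentile(self.pooled_intercept, q),
            ]
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Weighted Bayesian linear regression (adaptive Metropolis)",
            "=" * 58,
            f"pairs: {self.data.n}   chains: {len(self.slope_samples)}   "
            f"steps/chain (post-convergence): {self.slope_samples[0].size}",
            f"burn-in discarded per chain: {self.n_burn_in}",
            "",
            "            mean        95% interval          PSRF",
            f"slope      {self.params[0]: .5f}  [{ci[0,0]: .5f}, {ci[0,1]: .5f}]  "
            f"{self.psrf[0]:.4f}",
            f"intercept  {self.params[1]: .5f}  [{ci[1,0]: .5f}, {ci[1,1]: .5f}]  "
            f"{self.psrf[1]:.4f}",
            "",
            f"acceptance fractions: "
            + ", ".join(f"{a:.3f}" for a in self.acceptance_fraction),
            f"P(slope > 0) = {self.p_slope_positive:.4f}"
            + ("  (significant at 0.95)" if self.significant else ""),
            f"slope-intercept correlation: {self.slope_intercept_correlation:+.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable summary (samples excluded)."""
        ci = self.conf_int()
        return {
            "slope_mean": float(self.params[0]),
            "intercept_mean": float(self.params[1]),
            "slope_ci95": [float(ci[0, 0]), float(ci[0, 1])],
            "intercept_ci95": [float(ci[1, 0]), float(ci[1, 1])],
            "psrf": [float(v) for v in self.psrf],
            "acceptance_fraction": [float(a) for a in self.acceptance_fraction],
            "p_slope_positive": self.p_slope_positive,
            "significant": self.significant,
            "slope_intercept_correlation": self.slope_intercept_correlation,
            "n_steps_per_chain": int(self.slope_samples[0].size),
            "n_burn_in": int(self.n_burn_in),
            "seed": int(self.config.seed),
        }

    # -- plots (Fig 4-style) -------------------------------------------------

    def plot_trace(self, path=None):
        """Trace of slope and intercept per chain."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
        for name, ax, per_chain in zip(
            ("slope", "intercept"),
            axes,
            (self.slope_samples, self.intercept_samples),
        ):
            for i, chain in enumerate(per_chain):
                ax.plot(chain, lw=0.3, label=f"chain {i + 1}")
            ax.set_ylabel(name)
        axes[-1].set_xlabel("MCMC step (post-convergence)")
        axes[0].legend(loc="upper right", fontsize=8)
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def plot_joint(self, path=None, bins: int = 120):
        """2-D histogram of the pooled (slope, intercept) posterior."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5.5, 5))
        ax.hist2d(self.pooled_slope, self.pooled_intercept, bins=bins, cmap="viridis")
        ax.set_xlabel("slope")
        ax.set_ylabel("intercept")
        ax.set_title(
            f"r = {self.slope_intercept_correlation:+.3f},  "
            f"P(slope>0) = {self.p_slope_positive:.4f}"
        )
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class WeightedBayesLinearModel:
    """Statsmodels-style front end: data in, ``fit()`` out.

    >>> model = WeightedBayesLinearModel.from_pairs(pairs)
    >>> res = model.fit(MCMCConfig(seed=42))
    >>> print(res.summary())
    """

    def __init__(self, y, x, weights, y_se=None) -> None:
        self.data = RegressionData(x=x, y=y, weights=weights, y_se=y_se)

    @classmethod
    def from_pairs(cls, pairs: Sequence[PairedObservation]) -> "WeightedBayesLinearModel":
        obj = cls.__new__(cls)
        obj.data = RegressionData.from_pairs(pairs)
        return obj

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, y: str = "y", x: str = "x", weights: str = "weight"
    ) -> "WeightedBayesLinearModel":
        return cls(
            df[y].to_numpy(float), df[x].to_numpy(float), df[weights].to_numpy(float)
        )

    def fit(
        self, config: MCMCConfig | None = None, use_se: bool = False
    ) -> BayesRegressionResults:
        return run_regression(self.data, config, use_se=use_se)


def run_regression(
    data: RegressionData,
    config: MCMCConfig | None = None,
    use_se: bool = False,
) -> BayesRegressionResults:
    """Full pipeline: adapt, converge (PSRF on doubling windows), pool.

    Chains start at the WLS solution offset by (-1, 0, +1) x 4 standard
    errors; chain seeds are ``config.seed + 1 + chain_index``.  Burn-in is
    everything before the first doubling window whose second half has PSRF
    below threshold for both parameters; ``config.n_steps`` fresh samples
    per chain are then pooled.
    """
    config = config or MCMCConfig()
    loglik = make_loglik(data, use_se=use_se)
    theta_wls, cov = wls_fit(data, use_se=use_se)
    se = np.sqrt(np.diag(cov))
    se = np.where(se > 0, se, 1e-6)

    offsets = (-1.0, 0.0, 1.0)
    states = []
    for i in range(config.n_chains):
        init = theta_wls + offsets[i % 3] * 4.0 * se
        states.append(
            _ChainState(loglik, init, se, config, chain_seed=config.seed + 1 + i)
        )
    for s in states:
        s.adapt()

    # convergence on doubling windows: PSRF of the second half of history
    window = config.init_window
    history: list[list[np.ndarray]] = [[] for _ in states]
    total = 0
    psrf = None
    while True:
        for h, s in zip(history, states):
            block, _ = s.sample(window)
            h.append(block)
        total += window
        joined = [np.concatenate(h) for h in history]
        half = [j[total // 2 :] for j in joined]
        psrf = gelman_rubin(half)
        if np.all(psrf < config.psrf_threshold):
            break
        window *= 2
        if total + window > config.max_convergence_steps:
            raise ConvergenceError(
                f"PSRF {psrf} still above {config.psrf_threshold} after "
                f"{total} steps/chain (budget {config.max_convergence_steps}); "
                "the posterior may be multimodal or the proposal badly scaled"
            )

    samples, acc = [], []
    for s in states:
        block, a = s.sample(config.n_steps)
        samples.append(block)
        acc.append(a)

    final_psrf = gelman_rubin(samples)
    return BayesRegressionResults(
        slope_samples=tuple(b[:, 0] for b in samples),
        intercept_samples=tuple(b[:, 1] for b in samples),
        acceptance_fraction=tuple(acc),
        psrf=final_psrf,
        wls_params=theta_wls,
        wls_cov=cov,
        n_burn_in=total,
        config=config,
        data=data,
    )


def posterior_summary(post: BayesRegressionResults) -> pd.DataFrame:
    """Summary table: mean, central 95% interval and PSRF per parameter.

    Scalar diagnostics (acceptance fractions, P(slope>0), slope-intercept
    correlation) are attached in ``DataFrame.attrs``.
    """
    ci = post.conf_int()
    df = pd.DataFrame(
        {
            "mean": post.params,
            "ci_2.5%": ci[:, 0],
            "ci_97.5%": ci[:, 1],
            "psrf": post.psrf,
        },
        index=["slope", "intercept"],
    )
    df.attrs.update(
        {
            "acceptance_fraction": list(post.acceptance_fraction),
            "p_slope_positive": post.p_slope_positive,
            "slope_intercept_correlation": post.slope_intercept_correlation,
        }
    )
    return df
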