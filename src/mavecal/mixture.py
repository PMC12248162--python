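"""Multi-sample two-component skew-normal mixture fit by constrained EM.

A functional assay's score distribution is modeled with two shared
skew-normal components — functionally abnormal and functionally normal —
mixed with sample-specific weights.  The labeled samples are the P/LP
clinical controls (``P``), the B/LB controls (``B``), a gnomAD reference
sample (``G``) and, when the assay reports them, synonymous variants
(``S``).  Sample ``i`` has density

    p_i(s) = w_i * SN(s; theta_a) + (1 - w_i) * SN(s; theta_n).

The EM algorithm augments each observation with the half-normal latent
variable of the constructive skew-normal representation; the M-step updates
the alternate parameters (mu, Delta, Gamma) of each component by pooling
responsibilities across all samples, and each sample's weight by the mean
abnormal responsibility within the sample.

Throughout the optimization the component density ratio
SN(s; theta_a) / SN(s; theta_n) is kept non-increasing in the score over
the observed range (lower scores mean more functionally abnormal).  With
w_P > w_B this is sufficient for the local positive likelihood ratio — and
hence the posterior probability of pathogenicity — to be monotone in the
score.  The constraint is re-imposed after every component update by a
binary search between the last feasible parameters and the proposed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfcx, logsumexp
from sklearn.cluster import KMeans

from .distributions import (
    AlternateParams,
    SkewNormalParams,
    alternate_to_canonical,
    canonical_to_alternate,
    sn_logpdf,
    sn_pdf,
)

__all__ = [
    "SampleSet",
    "MixtureFit",
    "DegenerateDataError",
    "ConstraintError",
    "mixture_pdf",
    "mixture_logpdf",
    "constraint_grid",
    "ratio_is_monotone",
    "enforce_monotone_ratio",
    "initialize",
    "em_step",
    "loglikelihood",
    "fit",
]

SAMPLE_KEYS = ("P", "B", "G", "S")

#: number of grid points for the monotone density-ratio check
GRID_POINTS = 512
#: fractional padding added on either side of the observed score range
GRID_PADDING = 0.05
#: numerical slack when testing for a non-increasing log density ratio
RATIO_TOL = 1e-12
#: bisection steps in the constraint projection
BISECTION_STEPS = 50


class DegenerateDataError(ValueError):
    """Raised when the observations cannot support a two-component fit."""


class ConstraintError(RuntimeError):
    """Raised when the density-ratio constraint cannot be restored."""


@dataclass
class SampleSet:
    """Labeled assay score samples used to fit the mixture.

    P/LP, B/LB and reference (gnomAD) scores are mandatory; synonymous
    scores are optional and, when present, enter the likelihood exactly
    like the other samples.
    """

    scores_plp: np.ndarray
    scores_blb: np.ndarray
    scores_ref: np.ndarray
    scores_syn: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores_plp = np.asarray(self.scores_plp, dtype=float).ravel()
        self.scores_blb = np.asarray(self.scores_blb, dtype=float).ravel()
        self.scores_ref = np.asarray(self.scores_ref, dtype=float).ravel()
        if self.scores_syn is not None:
            self.scores_syn = np.asarray(self.scores_syn, dtype=float).ravel()
            if self.scores_syn.size == 0:
                self.scores_syn = None
        for name, arr in self.items():
            if arr.size == 0:
                raise DegenerateDataError(f"sample {name!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"sample {name!r} contains non-finite scores")

    def items(self) -> list[tuple[str, np.ndarray]]:
        out = [("P", self.scores_plp), ("B", self.scores_blb), ("G", self.scores_ref)]
        if self.scores_syn is not None:
            out.append(("S", self.scores_syn))
        return out

    def pooled(self) -> np.ndarray:
        return np.concatenate([a for _, a in self.items()])

    def score_range(self) -> tuple[float, float]:
        pooled = self.pooled()
        return float(pooled.min()), float(pooled.max())


@dataclass
class MixtureFit:
    """Result of the constrained EM fit."""

    theta_abnormal: SkewNormalParams
    theta_normal: SkewNormalParams
    weight_abnormal_per_sample: dict[str, float]
    log_likelihood: float
    converged: bool
    n_iterations: int
    score_range: tuple[float, float]
    ll_trace: list[float] = field(default_factory=list)
    projection_trace: list[bool] = field(default_factory=list)


# ---------------------------------------------------------------------------
# densities


def mixture_pdf(
    s,
    weight: float,
    theta_abnormal: SkewNormalParams,
    theta_normal: SkewNormalParams,
):
    """Two-component mixture density w*SN(s; a) + (1-w)*SN(s; n)."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"mixture weight must lie in [0, 1], got {weight}")
    return weight * sn_pdf(s, theta_abnormal) + (1.0 - weight) * sn_pdf(s, theta_normal)


def mixture_logpdf(
    s,
    weight: float,
    theta_abnormal: SkewNormalParams,
    theta_normal: SkewNormalParams,
):
    """Log mixture density via log-sum-exp (safe for extreme tails)."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"mixture weight must lie in [0, 1], got {weight}")
    la = sn_logpdf(s, *theta_abnormal.as_tuple())
    ln = sn_logpdf(s, *theta_normal.as_tuple())
    with np.errstate(divide="ignore"):
        stacked = np.stack([la + np.log(weight), ln + np.log1p(-weight)])
    return logsumexp(stacked, axis=0)


# ---------------------------------------------------------------------------
# monotone density-ratio constraint


def constraint_grid(score_range: tuple[float, float], n: int = GRID_POINTS) -> np.ndarray:
    """Evaluation grid for the ratio check: the observed range plus padding."""
    lo, hi = score_range
    span = hi - lo
    if span <= 0:
        raise DegenerateDataError("observed score range has zero width")
    return np.linspace(lo - GRID_PADDING * span, hi + GRID_PADDING * span, n)


def ratio_is_monotone(
    theta_abnormal: SkewNormalParams,
    theta_normal: SkewNormalParams,
    grid: np.ndarray,
    tol: float = RATIO_TOL,
) -> bool:
    """True when SN(s; a)/SN(s; n) is non-increasing over ``grid``."""
    log_ratio = sn_logpdf(grid, *theta_abnormal.as_tuple()) - sn_logpdf(
        grid, *theta_normal.as_tuple()
    )
    return bool(np.all(np.diff(log_ratio) <= tol))


def _interpolate_alt(a: AlternateParams, b: AlternateParams, t: float) -> AlternateParams:
    return AlternateParams(
        location=(1 - t) * a.location + t * b.location,
        delta=(1 - t) * a.delta + t * b.delta,
        gamma=(1 - t) * a.gamma + t * b.gamma,
    )


def _project_component(
    proposed: AlternateParams,
    feasible: AlternateParams,
    other: SkewNormalParams,
    grid: np.ndarray,
    updating_abnormal: bool,
) -> tuple[AlternateParams, bool]:
    """Binary-search the largest feasible step toward ``proposed``.

    The full (mu, Delta, Gamma) vector of the component being updated is
    interpolated between its last feasible value (step 0, known feasible)
    and the M-step proposal (step 1); the other component stays fixed.
    Returns the accepted parameters and whether the projection truncated
    the update.
    """

    def pair(alt: AlternateParams):
        cano = alternate_to_canonical(alt)
        return (cano, other) if updating_abnormal else (other, cano)

    if ratio_is_monotone(*pair(proposed), grid):
        return proposed, False
    lo, hi = 0.0, 1.0
    for _ in range(BISECTION_STEPS):
        mid = 0.5 * (lo + hi)
        if ratio_is_monotone(*pair(_interpolate_alt(feasible, proposed, mid)), grid):
            lo = mid
        else:
            hi = mid
    accepted = _interpolate_alt(feasible, proposed, lo)
    if not ratio_is_monotone(*pair(accepted), grid):  # pragma: no cover - lo=0 is feasible
        raise ConstraintError("density-ratio constraint infeasible at the anchor point")
    return accepted, True


def enforce_monotone_ratio(
    theta_abnormal: SkewNormalParams,
    theta_normal: SkewNormalParams,
    score_range: tuple[float, float],
    feasible: tuple[SkewNormalParams, SkewNormalParams] | None = None,
    max_separation_steps: int = 1000,
) -> tuple[SkewNormalParams, SkewNormalParams]:
    """Return a parameter pair satisfying the monotone density-ratio constraint.

    If ``feasible`` is supplied, the abnormal component is pulled back
    toward it by binary search.  Otherwise a feasible anchor is built by
    moving the component locations apart (abnormal down, normal up) until
    the ratio is monotone on the grid, and the proposal is then pulled
    toward that anchor.
    """
    grid = constraint_grid(score_range)
    if ratio_is_monotone(theta_abnormal, theta_normal, grid):
        return theta_abnormal, theta_normal
    if feasible is None:
        feasible = _separate_until_feasible(
            theta_abnormal, theta_normal, score_range, max_separation_steps
        )
    if not ratio_is_monotone(*feasible, grid):
        raise ConstraintError("supplied anchor pair violates the density-ratio constraint")
    alt_a, alt_n = map(canonical_to_alternate, (theta_abnormal, theta_normal))
    anchor_a, anchor_n = map(canonical_to_alternate, feasible)
    lo, hi = 0.0, 1.0
    for _ in range(BISECTION_STEPS):
        mid = 0.5 * (lo + hi)
        cand = (
            alternate_to_canonical(_interpolate_alt(anchor_a, alt_a, mid)),
            alternate_to_canonical(_interpolate_alt(anchor_n, alt_n, mid)),
        )
        if ratio_is_monotone(*cand, grid):
            lo = mid
        else:
            hi = mid
    return (
        alternate_to_canonical(_interpolate_alt(anchor_a, alt_a, lo)),
        alternate_to_canonical(_interpolate_alt(anchor_n, alt_n, lo)),
    )


def _separate_until_feasible(
    theta_a: SkewNormalParams,
    theta_n: SkewNormalParams,
    score_range: tuple[float, float],
    max_steps: int,
) -> tuple[SkewNormalParams, SkewNormalParams]:
    """Move component locations in opposing directions until the ratio is monotone."""
    grid = constraint_grid(score_range)
    span = score_range[1] - score_range[0]
    step = 0.05 * span
    a, n = theta_a, theta_n
    for _ in range(max_steps):
        if ratio_is_monotone(a, n, grid):
            return a, n
        a = replace(a, location=a.location - step)
        n = replace(n, location=n.location + step)
    raise ConstraintError(
        "could not reach a feasible initialization by separating component locations"
    )


# ---------------------------------------------------------------------------
# EM machinery


def _truncated_moments(s: np.ndarray, alt: AlternateParams) -> tuple[np.ndarray, np.ndarray]:
    """Posterior moments E[T | s], E[T^2 | s] of the half-normal latent variable.

    Given s = mu + Delta*T + sqrt(Gamma)*U, the conditional law of T is a
    normal with mean m = Delta*(s - mu)/(Delta^2 + Gamma) and variance
    v = Gamma/(Delta^2 + Gamma), truncated to (0, inf).  The inverse-Mills
    ratio is computed through erfcx for stability far in the tails.
    """
    tau2 = alt.delta**2 + alt.gamma
    v = alt.gamma / tau2
    sd = math.sqrt(v)
    m = alt.delta * (s - alt.location) / tau2
    a = m / sd
    hazard = math.sqrt(2.0 / math.pi) / erfcx(-a / math.sqrt(2.0))  # phi(a)/Phi(a)
    e_t = m + sd * hazard
    e_t2 = m * m + v + m * sd * hazard
    return e_t, e_t2


def _mstep_component(
    s: np.ndarray,
    resp: np.ndarray,
    e_t: np.ndarray,
    e_t2: np.ndarray,
    old: AlternateParams,
    gamma_floor: float,
) -> AlternateParams:
    """Closed-form maximizer of the expected complete-data log-likelihood.

    The location update uses the old Delta; Delta then uses the new
    location, and Gamma uses both new values.
    """
    total = resp.sum()
    mu = float(np.dot(resp, s - old.delta * e_t) / total)
    num = float(np.dot(resp, (s - mu) * e_t))
    den = float(np.dot(resp, e_t2))
    delta = num / den
    r = s - mu
    gamma = float(np.dot(resp, r * r - 2.0 * delta * r * e_t + delta * delta * e_t2) / total)
    return AlternateParams(location=mu, delta=delta, gamma=max(gamma, gamma_floor))


@dataclass
class _EMState:
    alt_a: AlternateParams
    alt_n: AlternateParams
    weights: dict[str, float]

    @property
    def theta_a(self) -> SkewNormalParams:
        return alternate_to_canonical(self.alt_a)

    @property
    def theta_n(self) -> SkewNormalParams:
        return alternate_to_canonical(self.alt_n)


def loglikelihood(state_or_fit, samples: SampleSet) -> float:
    """Observed-data log-likelihood of the multi-sample mixture."""
    if isinstance(state_or_fit, MixtureFit):
        theta_a = state_or_fit.theta_abnormal
        theta_n = state_or_fit.theta_normal
        weights = state_or_fit.weight_abnormal_per_sample
    else:
        theta_a, theta_n = state_or_fit.theta_a, state_or_fit.theta_n
        weights = state_or_fit.weights
    total = 0.0
    for key, arr in samples.items():
        total += float(mixture_logpdf(arr, weights[key], theta_a, theta_n).sum())
    return total


def _responsibilities(state: _EMState, samples: SampleSet):
    """Per-observation abnormal responsibilities and the current log-likelihood."""
    theta_a, theta_n = state.theta_a, state.theta_n
    resp, ll = {}, 0.0
    for key, arr in samples.items():
        w = state.weights[key]
        la = sn_logpdf(arr, *theta_a.as_tuple())
        ln = sn_logpdf(arr, *theta_n.as_tuple())
        with np.errstate(divide="ignore"):
            la = la + np.log(w)
            ln = ln + np.log1p(-w)
        lse = np.logaddexp(la, ln)
        resp[key] = np.exp(la - lse)
        ll += float(lse.sum())
    return resp, ll


def em_step(
    state: _EMState,
    samples: SampleSet,
    grid: np.ndarray,
    gamma_floor: float,
) -> tuple[_EMState, float, bool]:
    """One constrained EM iteration.

    Returns the new state, the log-likelihood of the *incoming* state (a
    byproduct of the E-step), and whether a constraint projection
    truncated either component update.  When a projection activates, the
    updated component is kept only if it does not lower the observed-data
    log-likelihood; otherwise it is reverted, which preserves monotone
    ascent.

    A component whose pooled responsibility mass vanishes (every sample
    weight at a boundary) is frozen rather than updated, so degenerate
    single-component configurations are exact fixed points.
    """
    resp, _ = _responsibilities(state, samples)
    s_all = samples.pooled()
    resp_a = np.concatenate([resp[key] for key, _ in samples.items()])
    resp_n = 1.0 - resp_a

    projected = False
    current = state

    for comp, comp_resp in (("a", resp_a), ("n", resp_n)):
        mass = comp_resp.sum()
        if mass <= 1e-12:
            continue  # frozen component: no data assigned to it
        old_alt = current.alt_a if comp == "a" else current.alt_n
        e_t, e_t2 = _truncated_moments(s_all, old_alt)
        proposal = _mstep_component(s_all, comp_resp, e_t, e_t2, old_alt, gamma_floor)
        other = current.theta_n if comp == "a" else current.theta_a
        accepted, was_projected = _project_component(
            proposal, old_alt, other, grid, updating_abnormal=(comp == "a")
        )
        candidate = (
            replace(current, alt_a=accepted) if comp == "a" else replace(current, alt_n=accepted)
        )
        if was_projected:
            # ascent is guaranteed only for the full M-step proposal; verify
            # the clipped update and revert it if the likelihood would drop
            projected = True
            if loglikelihood(candidate, samples) < loglikelihood(current, samples) - 1e-10:
                candidate = current
        current = candidate

    new_weights = {key: float(resp[key].mean()) for key, _ in samples.items()}
    current = replace(current, weights=new_weights)
    _, ll_new = _responsibilities(current, samples)
    return current, ll_new, projected


# ---------------------------------------------------------------------------
# initialization and the fitting driver


def initialize(samples: SampleSet, seed) -> _EMState:
    """K-means (K=2) initialization with randomized small skews.

    Per-cluster Gaussian fits give the locations and scales; the skew of
    each component is drawn from Uniform(-0.25, 0.25).  The component with
    the lower location is labeled abnormal.  Initial sample weights are
    the per-sample fractions of observations assigned to the abnormal
    cluster, kept away from the absorbing boundaries.  Locations are then
    moved apart until the density-ratio constraint holds on the observed
    range.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pooled = samples.pooled()
    if pooled.size < 4:
        raise DegenerateDataError("need at least 4 pooled observations")
    if np.unique(pooled).size < 2:
        raise DegenerateDataError("all observations are identical")
    lo, hi = samples.score_range()
    span = hi - lo

    km_seed = int(rng.integers(0, 2**31 - 1))
    km = KMeans(n_clusters=2, n_init=10, random_state=km_seed)
    assignments = km.fit_predict(pooled.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)  # lower-location cluster first -> abnormal
    params = []
    for cluster in order:
        members = pooled[assignments == cluster]
        mean = float(members.mean()) if members.size else float(centers[cluster])
        scale = float(members.std(ddof=1)) if members.size > 1 else 0.0
        scale = max(scale, 0.05 * span)
        skew = float(rng.uniform(-0.25, 0.25))
        # moment-matching: place the location so the component's implied
        # mean equals the cluster mean given the drawn skew (the skew-normal
        # likelihood is nearly flat along the mean-preserving location/skew
        # ridge, so anchoring the mean is what the data actually determine)
        delta_unit = skew / math.sqrt(1.0 + skew * skew)
        loc = mean - scale * delta_unit * math.sqrt(2.0 / math.pi)
        params.append(SkewNormalParams(location=loc, scale=scale, skew=skew))
    theta_a, theta_n = _separate_until_feasible(params[0], params[1], (lo, hi), 1000)

    abnormal_cluster = order[0]
    weights = {}
    for key, arr in samples.items():
        frac = float(np.mean(km.predict(arr.reshape(-1, 1)) == abnormal_cluster))
        weights[key] = min(max(frac, 0.05), 0.95)
    return _EMState(
        alt_a=canonical_to_alternate(theta_a),
        alt_n=canonical_to_alternate(theta_n),
        weights=weights,
    )


def fit(
    samples: SampleSet,
    n_restarts: int = 100,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureFit:
    """Fit the constrained mixture, keeping the best of ``n_restarts`` runs.

    Restart ``r`` is seeded deterministically with ``seed + r``; EM stops
    when the relative log-likelihood change falls below ``tol`` or after
    ``max_iter`` iterations.  The returned fit carries the winning
    restart's per-iteration log-likelihood trace and projection flags.
    """
    pooled = samples.pooled()
    if np.unique(pooled).size < 2:
        raise DegenerateDataError("fewer than 2 distinct score values")
    lo, hi = samples.score_range()
    grid = constraint_grid((lo, hi))
    gamma_floor = 1e-12 * float(pooled.var() + 1.0)

    best: MixtureFit | None = None
    for r in range(n_restarts):
        state = initialize(samples, (seed + r) % 2**31)
        _, ll_prev = _responsibilities(state, samples)
        trace = [ll_prev]
        proj_trace: list[bool] = []
        converged = False
        iterations = 0
        for iterations in range(1, max_iter + 1):
            state, ll_new, projected = em_step(state, samples, grid, gamma_floor)
            trace.append(ll_new)
            proj_trace.append(projected)
            if abs(ll_new - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
                converged = True
                ll_prev = ll_new
                break
            ll_prev = ll_new
        candidate = MixtureFit(
            theta_abnormal=state.theta_a,
            theta_normal=state.theta_n,
            weight_abnormal_per_sample=dict(state.weights),
            log_likelihood=ll_prev,
            converged=converged,
            n_iterations=iterations,
            score_range=(lo, hi),
            ll_trace=trace,
            projection_trace=proj_trace,
        )
        if best is None or candidate.log_likelihood > best.log_likelihood:
            best = candidate
    assert best is not None
    return best
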