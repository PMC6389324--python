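"""Maximum-likelihood DFE estimation from paired unfolded SFS.

Poisson random field machinery: expected SFS entries from the sojourn
density of a selected allele, a Gamma distribution of deleterious fitness
effects (optionally plus an exponential beneficial class), per-frequency
nuisance multipliers r_i shared by the synonymous and nonsynonymous
spectra, and alpha / omega_a / omega_na with likelihood-profile confidence
intervals (log-likelihood within two units of its maximum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, special, stats

from .polymorphism import SFSPair

__all__ = [
    "DFEModel",
    "DFEFit",
    "ProfileCI",
    "fixation_factor",
    "sojourn_density",
    "expected_sfs_entry",
    "expected_sfs",
    "gamma_grid",
    "fit",
    "alpha_omega",
    "profile_ci",
]

GL_ORDER = 64  # Gauss-Legendre order for the frequency integral
GAMMA_GRID = 100  # quantile-grid size for the Gamma DFE integral


# ---------------------------------------------------------------------------
# PRF primitives
# ---------------------------------------------------------------------------


def fixation_factor(S):
    """Fixation rate of a mutation with scaled coefficient S, relative to
    neutral: S / (1 - exp(-S)), with the continuity value 1 at S = 0."""
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    small = np.abs(S) < 1e-8
    neg = (S < 0) & ~small
    pos = (S > 0) & ~small
    out[small] = 1.0 + S[small] / 2.0
    # S<0: S/(1-e^{-S}) = S e^{S}/(e^{S}-1) = -S e^{S}/(-expm1(S)) — no overflow
    out[neg] = S[neg] * np.exp(S[neg]) / np.expm1(S[neg])
    out[pos] = S[pos] / (-np.expm1(-S[pos]))
    return out if out.ndim else float(out)


def _sojourn_ratio(S: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(1 - e^{-S(1-x)}) / (1 - e^{-S}) for S[:,None] against x[None,:].

    Evaluated in overflow-safe branches; the S -> 0 limit is (1 - x).
    """
    S = np.atleast_1d(np.asarray(S, dtype=float))[:, None]
    x = np.asarray(x, dtype=float)[None, :]
    out = np.empty(np.broadcast_shapes(S.shape, x.shape))
    small = np.broadcast_to(np.abs(S) < 1e-10, out.shape)
    neg = np.broadcast_to(S < 0, out.shape) & ~small
    pos = ~small & ~neg
    xs = np.broadcast_to(x, out.shape)
    Ss = np.broadcast_to(S, out.shape)
    out[small] = 1.0 - xs[small]
    # S<0: multiply through by e^{S}: (e^{Sx} - e^{S}) / (1 - e^{S})
    sn, xn = Ss[neg], xs[neg]
    out[neg] = (np.exp(sn * xn) - np.exp(sn)) / (-np.expm1(sn))
    sp, xp = Ss[pos], xs[pos]
    out[pos] = np.expm1(-sp * (1.0 - xp)) / np.expm1(-sp)
    return out


def sojourn_density(S, x):
    """PRF sojourn density H(S, x); H(0, x) = 1/x by continuity."""
    x = np.asarray(x, dtype=float)
    ratio = _sojourn_ratio(S, x)
    out = ratio / (x * (1.0 - x))[None, :]
    return out if np.ndim(S) else out[0]


@lru_cache(maxsize=32)
def _quadrature(n: int, order: int = GL_ORDER):
    """GL nodes/weights on (0,1) and the binomial sampling matrix B[i-1,g]."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    i = np.arange(1, n)[:, None]
    logb = (
        special.gammaln(n + 1)
        - special.gammaln(i + 1)
        - special.gammaln(n - i + 1)
        + i * np.log(x)[None, :]
        + (n - i) * np.log1p(-x)[None, :]
    )
    return x, w, np.exp(logb)


def expected_sfs(S, n: int, order: int = GL_ORDER) -> np.ndarray:
    """Expected SFS shape for one or more selection coefficients.

    Returns, for each S, the vector over derived counts i=1..n-1 of
    integral_0^1 H(S,x) C(n,i) x^i (1-x)^(n-i) dx (equal to 1/i at S=0).
    Shape (len(S), n-1), or (n-1,) for scalar S.
    """
    x, w, B = _quadrature(n, order)
    H = sojourn_density(np.atleast_1d(S), x)  # (k, G)
    out = (H * w[None, :]) @ B.T
    return out if np.ndim(S) else out[0]


def expected_sfs_entry(S: float, i: int, n: int, order: int = GL_ORDER) -> float:
    """Single expected SFS entry (up to the theta*L scale)."""
    if not 1 <= i <= n - 1:
        raise ValueError("i must be in [1, n-1]")
    return float(expected_sfs(float(S), n, order)[i - 1])


def gamma_grid(shape: float, mean: float, k: int = GAMMA_GRID) -> np.ndarray:
    """Quantile-midpoint discretisation of a Gamma(shape, mean) magnitude."""
    q = (np.arange(k) + 0.5) / k
    return stats.gamma.ppf(q, shape, scale=mean / shape)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class DFEModel:
    """Deleterious-Gamma DFE, optionally with an exponential beneficial class.

    ``shape``/``s_mean`` parameterise the Gamma of |S| for deleterious
    mutations; GammaExpo adds a proportion ``p_pos`` of beneficial mutations
    with exponentially distributed advantage of mean ``s_pos``.
    """

    name: str  # "GammaZero" | "GammaExpo"
    shape: float = 0.5
    s_mean: float = 100.0
    p_pos: float = 0.0
    s_pos: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("GammaZero", "GammaExpo"):
            raise ValueError(f"unknown DFE model {self.name!r}")
        if self.name == "GammaZero" and self.p_pos != 0.0:
            raise ValueError("GammaZero has no beneficial class")

    def nonsyn_expected_sfs(self, n: int, k: int = GAMMA_GRID) -> np.ndarray:
        """DFE-integrated expected nonsyn SFS shape (neutral would be 1/i)."""
        s = gamma_grid(self.shape, self.s_mean, k)
        ent = expected_sfs(-s, n).mean(axis=0)
        if self.p_pos > 0:
            spos = _expo_grid(self.s_pos, k)
            ent_pos = expected_sfs(spos, n).mean(axis=0)
            ent = (1.0 - self.p_pos) * ent + self.p_pos * ent_pos
        return ent

    def omega_na(self, k: int = GAMMA_GRID) -> float:
        """Expected dN/dS contributed by the deleterious class."""
        s = gamma_grid(self.shape, self.s_mean, k)
        return float((1.0 - self.p_pos) * np.mean(fixation_factor(-s)))


def _expo_grid(mean: float, k: int = GAMMA_GRID) -> np.ndarray:
    q = (np.arange(k) + 0.5) / k
    return stats.expon.ppf(q, scale=mean)


@dataclass
class ProfileCI:
    low: float
    high: float
    low_bounded: bool = False  # True when the contour hit a search bound
    high_bounded: bool = False

    def __iter__(self):
        return iter((self.low, self.high))


@dataclass
class DFEFit:
    model: DFEModel
    sfs: SFSPair
    theta: float
    r: np.ndarray  # nuisance multipliers, r[0] == 1 by construction
    loglik: float
    converged: bool
    alpha: float | None = None
    omega_a: float | None = None
    omega_na: float | None = None
    ci: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _poisson_ll(counts: np.ndarray, means: np.ndarray) -> float:
    # constant log(k!) terms dropped
    return float(np.sum(special.xlogy(counts, means) - means))


def _sfs_loglik_profiled(sfs: SFSPair, nonsyn_entries: np.ndarray):
    """SFS log-likelihood with theta and r_i profiled out analytically.

    For each frequency class the product a_i = r_i * theta has closed-form
    MLE (S_i + N_i) / (L_syn/i + L_nonsyn * e_i) because r_i multiplies the
    synonymous and nonsynonymous means identically.
    """
    n = sfs.n
    i = np.arange(1, n)
    neutral = 1.0 / i
    denom = sfs.L_syn * neutral + sfs.L_nonsyn * nonsyn_entries
    tot = sfs.syn_sfs + sfs.nonsyn_sfs
    a = np.where(denom > 0, tot / denom, 0.0)
    m_s = a * sfs.L_syn * neutral
    m_n = a * sfs.L_nonsyn * nonsyn_entries
    ll = _poisson_ll(sfs.syn_sfs, m_s) + _poisson_ll(sfs.nonsyn_sfs, m_n)
    return ll, a


_BOUNDS = {
    "log_shape": (math.log(0.01), math.log(50.0)),
    "log_smean": (math.log(1e-3), math.log(1e7)),
    "p_pos": (0.0, 0.99),
    "log_spos": (math.log(1e-2), math.log(1e4)),
}


def _unpack(vec: np.ndarray, name: str) -> DFEModel:
    if name == "GammaZero":
        return DFEModel(name, shape=math.exp(vec[0]), s_mean=math.exp(vec[1]))
    return DFEModel(
        name,
        shape=math.exp(vec[0]),
        s_mean=math.exp(vec[1]),
        p_pos=float(vec[2]),
        s_pos=math.exp(vec[3]),
    )


def _pack(model: DFEModel) -> np.ndarray:
    v = [math.log(model.shape), math.log(model.s_mean)]
    if model.name == "GammaExpo":
        v += [model.p_pos, math.log(model.s_pos)]
    return np.array(v)


def _param_bounds(name: str):
    b = [_BOUNDS["log_shape"], _BOUNDS["log_smean"]]
    if name == "GammaExpo":
        b += [_BOUNDS["p_pos"], _BOUNDS["log_spos"]]
    return b


def fit(
    sfs: SFSPair,
    model: str | DFEModel = "GammaZero",
    n_starts: int = 5,
    seed: int = 0,
    with_alpha: bool = True,
) -> DFEFit:
    """Fit a DFE to a syn/nonsyn SFS pair by Poisson maximum likelihood.

    theta and the r_i multipliers are profiled analytically; the DFE shape
    parameters are optimised by bounded quasi-Newton from ``n_starts``
    seeded starting points.
    """
    name = model if isinstance(model, str) else model.name
    rng = np.random.default_rng(seed)

    def negll(vec):
        m = _unpack(vec, name)
        ll, _ = _sfs_loglik_profiled(sfs, m.nonsyn_expected_sfs(sfs.n))
        return -ll if np.isfinite(ll) else 1e12

    bounds = _param_bounds(name)
    starts = [_pack(DFEModel(name, shape=0.4, s_mean=500.0))]
    if isinstance(model, DFEModel):
        starts.insert(0, _pack(model))
    if name == "GammaExpo":
        # include the GammaZero optimum as a start to guarantee nesting
        gz = fit(sfs, "GammaZero", n_starts=n_starts, seed=seed, with_alpha=False)
        starts.insert(
            0,
            _pack(
                DFEModel(
                    "GammaExpo",
                    shape=gz.model.shape,
                    s_mean=gz.model.s_mean,
                    p_pos=0.0,
                    s_pos=1.0,
                )
            ),
        )
    while len(starts) < n_starts:
        v = np.array([b[0] + rng.random() * (b[1] - b[0]) for b in bounds])
        starts.append(v)

    best = None
    ok = False
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-10}
        )
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    fitted = _unpack(best.x, name)
    ll, a = _sfs_loglik_profiled(sfs, fitted.nonsyn_expected_sfs(sfs.n))
    theta = float(a[0])
    r = a / theta if theta > 0 else np.full_like(a, np.nan)
    out = DFEFit(fitted, sfs, theta, r, ll, ok)
    if with_alpha and sfs.D_syn > 0:
        out.alpha, out.omega_a, out.omega_na = alpha_omega(
            out, sfs.D_syn, sfs.D_nonsyn, sfs.L_syn, sfs.L_nonsyn
        )
    return out


def alpha_omega(
    fit_: DFEFit,
    D_syn: float,
    D_nonsyn: float,
    L_syn: float,
    L_nonsyn: float,
) -> tuple[float, float, float]:
    """alpha, omega_a, omega_na from a fitted DFE plus divergence counts.

    omega_na is the dN/dS expected under the fitted deleterious DFE; the
    excess of the observed dN/dS over it is attributed to adaptation, so
    omega_a + omega_na = observed dN/dS exactly.
    """
    if D_syn <= 0:
        raise ValueError("alpha undefined without synonymous divergence")
    dnds = (D_nonsyn / L_nonsyn) / (D_syn / L_syn)
    if dnds <= 0:
        raise ValueError("alpha undefined when observed dN/dS is zero")
    omega_na = fit_.model.omega_na()
    alpha = 1.0 - omega_na / dnds
    omega_a = dnds - omega_na
    return alpha, omega_a, omega_na


# ---------------------------------------------------------------------------
# Likelihood-profile confidence intervals
# ---------------------------------------------------------------------------


def _divergence_ll(omega_na: float, omega_a: float, sfs: SFSPair) -> float:
    """Divergence Poisson terms with the branch mutation rate profiled out.

    Expected counts: D_syn ~ d*L_syn, D_nonsyn ~ d*L_nonsyn*(omega_na +
    omega_a); the free rate d has closed-form MLE.
    """
    w = omega_na + omega_a
    if w <= 0:
        return -np.inf
    Ds, Dn = sfs.D_syn, sfs.D_nonsyn
    d = (Ds + Dn) / (sfs.L_syn + sfs.L_nonsyn * w)
    return _poisson_ll(
        np.array([Ds, Dn]), np.array([d * sfs.L_syn, d * sfs.L_nonsyn * w])
    )


def _profile_loglik(value: float, target: str, fit_: DFEFit) -> float:
    """max over DFE params of [SFS loglik + divergence loglik] at fixed target."""
    sfs = fit_.sfs
    name = fit_.model.name
    bounds = _param_bounds(name)

    def negll(vec):
        m = _unpack(vec, name)
        ll, _ = _sfs_loglik_profiled(sfs, m.nonsyn_expected_sfs(sfs.n))
        w_na = m.omega_na()
        if target == "omega_a":
            w_a = value
        else:  # alpha: omega_a = alpha/(1-alpha) * omega_na
            if value >= 1.0:
                return np.inf
            w_a = value / (1.0 - value) * w_na
        dll = _divergence_ll(w_na, w_a, sfs)
        out = ll + dll
        return -out if np.isfinite(out) else 1e12

    best = np.inf
    for x0 in (_pack(fit_.model), _pack(DFEModel(name, shape=0.4, s_mean=500.0))):
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-10}
        )
        best = min(best, res.fun)
    return -best


def profile_ci(
    fit_: DFEFit, target: str = "alpha", delta: float = 2.0
) -> ProfileCI:
    """CI bounds where the profile log-likelihood drops ``delta`` units.

    The likelihood is the SFS likelihood plus Poisson divergence terms in
    which omega_a enters the expected nonsynonymous substitution count.
    """
    if target not in ("alpha", "omega_a"):
        raise ValueError("target must be 'alpha' or 'omega_a'")
    if fit_.alpha is None:
        raise ValueError("fit carries no divergence counts; cannot profile")
    v0 = fit_.alpha if target == "alpha" else fit_.omega_a
    dnds = (fit_.sfs.D_nonsyn / fit_.sfs.L_nonsyn) / (
        fit_.sfs.D_syn / fit_.sfs.L_syn
    )
    ll0 = _profile_loglik(v0, target, fit_)
    crit = ll0 - delta

    if target == "alpha":
        lo_lim, hi_lim = -20.0, 1.0 - 1e-9
        step0 = 0.05
    else:
        lo_lim, hi_lim = -1.0 + 1e-9, v0 + max(10.0 * dnds, 1.0)
        step0 = max(0.05 * dnds, 0.01)

    def g(v):
        return _profile_loglik(v, target, fit_) - crit

    def search(direction: int):
        step = step0
        prev = v0
        for _ in range(60):
            v = v0 + direction * step
            v = min(max(v, lo_lim), hi_lim)
            if g(v) < 0:
                return optimize.brentq(g, *sorted((prev, v)), xtol=1e-4), False
            if v in (lo_lim, hi_lim):
                return v, True
            prev = v
            step *= 2.0
        return v, True

    low, low_b = search(-1)
    high, high_b = search(+1)
    return ProfileCI(float(low), float(high), low_b, high_b)
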