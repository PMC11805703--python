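"""Multivariate Cholesky twin decomposition: genetic and environmental correlations.

For k traits the additive-genetic and unique-environmental (optionally also
shared-environmental) cross-trait covariances are parametrized by
lower-triangular loading matrices, Sigma_X = T_X T_X', which keeps every
component covariance positive semi-definite by construction.  The expected
2k x 2k covariance of a twin pair (twin1 traits stacked before twin2 traits)
in zygosity group z is

    [[ Sigma,                    kappa_A(z) Sigma_A + kappa_C(z) Sigma_C ],
     [ symmetric,                Sigma                                   ]]

with Sigma = Sigma_A (+ Sigma_C) + Sigma_E, kappa_A = 1 (MZ) / 0.5 (DZ) and
kappa_C = 1.  Standardizing a component covariance gives the component
correlation matrices r_A (and r_C) and r_E; standardizing the total gives the
model-implied phenotypic correlations.  The likelihood is multivariate-normal
FIML over missingness patterns.

Although the Cholesky factors depend on trait order, the implied covariances
(and hence all correlations) are order-invariant, so trait order is purely a
reporting convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _fiml
from .twin_univariate import GROUP_ZYGOSITY, GROUPS, KAPPA


@dataclass
class MultiTraitPairData:
    """Pairs x (2k) trait matrix for one group: twin1's k traits, then twin2's."""

    group: str
    data: np.ndarray
    trait_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        self.trait_labels = tuple(self.trait_labels)
        self.data = np.asarray(self.data, dtype=float)
        k = len(self.trait_labels)
        if self.data.ndim != 2 or self.data.shape[1] != 2 * k:
            raise ValueError(
                f"data must be n x {2 * k} (twin1 traits then twin2 traits)"
            )

    @property
    def k(self) -> int:
        return len(self.trait_labels)

    @property
    def zygosity(self) -> str:
        return GROUP_ZYGOSITY[self.group]


def multitrait_from_table(
    traits: pd.DataFrame, trait_labels, include_os: bool = False
) -> list[MultiTraitPairData]:
    """Per-group pair matrices for several traits from a per-individual table."""
    from .twin_univariate import assign_group

    trait_labels = tuple(trait_labels)
    t = traits.copy()
    t["group"] = assign_group(t)
    out = []
    for g in GROUPS:
        if g == "DZOS" and not include_os:
            continue
        sub = t[t["group"] == g]
        if len(sub) == 0:
            continue
        blocks = []
        for order in (1, 2):
            side = sub[sub["birth_order"] == order].set_index("pair_id")
            blocks.append(side[list(trait_labels)])
        pair_ids = sorted(set(sub["pair_id"]))
        mat = np.full((len(pair_ids), 2 * len(trait_labels)), np.nan)
        for j, block in enumerate(blocks):
            block = block.reindex(pair_ids)
            mat[:, j * len(trait_labels):(j + 1) * len(trait_labels)] = (
                block.to_numpy()
            )
        out.append(MultiTraitPairData(group=g, data=mat, trait_labels=trait_labels))
    if not out:
        raise ValueError("no twin groups could be built from the table")
    return out


def _tril_indices(k: int):
    return np.tril_indices(k)


def _fingerprint(groups: list[MultiTraitPairData]) -> str:
    h = hashlib.sha256()
    for g in sorted(groups, key=lambda x: x.group):
        h.update(g.group.encode())
        h.update(np.ascontiguousarray(np.nan_to_num(g.data, nan=-9e99)).tobytes())
    return h.hexdigest()


@dataclass
class CholeskyFit:
    trait_labels: tuple[str, ...]
    components: tuple[str, ...]
    paths: dict[str, np.ndarray]           # component -> lower-triangular T_X
    means: np.ndarray
    minus2LL: float
    n_free_params: int
    converged: bool
    fingerprint: str
    ci: dict = field(default_factory=dict)
    _theta: np.ndarray | None = None
    _patterns: dict | None = None

    @property
    def k(self) -> int:
        return len(self.trait_labels)

    def component_cov(self, component: str) -> np.ndarray:
        t = self.paths[component]
        return t @ t.T

    @property
    def sigma_total(self) -> np.ndarray:
        return sum(self.component_cov(x) for x in self.components)

    @property
    def AIC(self) -> float:
        return self.minus2LL + 2 * self.n_free_params


def _pack(means: np.ndarray, tris: dict[str, np.ndarray], components) -> np.ndarray:
    k = len(means)
    rows, cols = _tril_indices(k)
    parts = [means] + [tris[x][rows, cols] for x in components]
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, k: int, components):
    rows, cols = _tril_indices(k)
    m = theta[:k]
    tris = {}
    off = k
    npar = len(rows)
    for x in components:
        t = np.zeros((k, k))
        t[rows, cols] = theta[off:off + npar]
        tris[x] = t
        off += npar
    return m, tris


def _expected_cov(tris: dict[str, np.ndarray], zygosity: str, components):
    covs = {x: tris[x] @ tris[x].T for x in components}
    sigma = sum(covs.values())
    cross = sum(KAPPA[x][zygosity] * covs[x] for x in components)
    top = np.hstack([sigma, cross])
    bot = np.hstack([cross.T, sigma])
    return np.vstack([top, bot])


def _neg2ll(theta, k, components, patterns_by_group) -> float:
    m, tris = _unpack(theta, k, components)
    mu = np.concatenate([m, m])
    total = 0.0
    for group, patterns in patterns_by_group.items():
        cov = _expected_cov(tris, GROUP_ZYGOSITY[group], components)
        total += _fiml.neg2ll(patterns, mu, cov)
    return total


_LOG_2PI = float(np.log(2.0 * np.pi))


def _neg2ll_and_grad(theta, k, components, patterns_by_group):
    """Objective and analytic gradient of the FIML -2LL.

    Per pattern, d(-2LL)/dSigma_obs = n G - G M G and d(-2LL)/dmu_obs =
    -2 G (t - n mu_obs) with G the observed-block precision and M the
    mu-centered second-moment matrix; the chain rule maps the 2k x 2k
    weight matrix W onto each Cholesky factor as (W11 + W22 + kappa (W12 +
    W21) + transpose) T_X, restricted to the lower triangle.
    """
    m, tris = _unpack(theta, k, components)
    mu = np.concatenate([m, m])
    covs = {x: tris[x] @ tris[x].T for x in components}
    total = 0.0
    grad_m = np.zeros(k)
    b_acc = {x: np.zeros((k, k)) for x in components}
    for group, patterns in patterns_by_group.items():
        zyg = GROUP_ZYGOSITY[group]
        sigma = sum(covs.values())
        cross = sum(KAPPA[x][zyg] * covs[x] for x in components)
        cov = np.vstack(
            [np.hstack([sigma, cross]), np.hstack([cross.T, sigma])]
        )
        w = np.zeros((2 * k, 2 * k))
        gmu = np.zeros(2 * k)
        for p in patterns:
            idx = p.idx
            s = cov[np.ix_(idx, idx)]
            sign, logdet = np.linalg.slogdet(s)
            if sign <= 0 or not np.isfinite(logdet):
                return np.inf, np.full_like(theta, np.nan)
            g = np.linalg.inv(s)
            mo = mu[idx]
            mm = (
                p.outer
                - np.outer(p.total, mo)
                - np.outer(mo, p.total)
                + p.n * np.outer(mo, mo)
            )
            total += p.n * (len(idx) * _LOG_2PI + logdet) + float(np.sum(g * mm))
            w[np.ix_(idx, idx)] += p.n * g - g @ mm @ g
            gmu[idx] += -2.0 * (g @ (p.total - p.n * mo))
        grad_m += gmu[:k] + gmu[k:]
        w11, w22 = w[:k, :k], w[k:, k:]
        w12, w21 = w[:k, k:], w[k:, :k]
        for x in components:
            kx = KAPPA[x][zyg]
            b_acc[x] += w11 + w22 + kx * (w12 + w21)
    rows, cols = _tril_indices(k)
    parts = [grad_m]
    for x in components:
        gx = (b_acc[x] + b_acc[x].T) @ tris[x]
        parts.append(gx[rows, cols])
    return float(total), np.concatenate(parts)


def _psd_project(s: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    s = (s + s.T) / 2.0
    w, v = np.linalg.eigh(s)
    w = np.clip(w, floor, None)
    return v @ np.diag(w) @ v.T


def _moment_start(groups: list[MultiTraitPairData], components) -> tuple[np.ndarray, dict]:
    """Start values from cross-twin moment matrices (2(C_MZ - C_DZ) etc.)."""
    k = groups[0].k
    within = []
    cross = {"MZ": [], "DZ": []}
    means = []
    for g in groups:
        d = g.data
        for j in (0, 1):
            block = d[:, j * k:(j + 1) * k]
            means.append(np.nanmean(block, axis=0))
        df = pd.DataFrame(d)
        c = df.cov(min_periods=2).to_numpy()
        if np.isnan(c).any():
            continue
        within.append((c[:k, :k] + c[k:, k:]) / 2.0)
        cross[g.zygosity].append((c[:k, k:] + c[k:, :k].T) / 2.0)
    mean = np.nanmean(np.array(means), axis=0)
    s_w = np.mean(within, axis=0)
    tris = {}
    if cross["MZ"] and cross["DZ"] and "A" in components:
        c_mz = np.mean(cross["MZ"], axis=0)
        c_dz = np.mean(cross["DZ"], axis=0)
        sig_a = _psd_project(2.0 * (c_mz - c_dz))
        if "C" in components:
            sig_c = _psd_project(2.0 * c_dz - c_mz)
        else:
            sig_c = np.zeros((k, k))
    else:
        sig_a = _psd_project(0.5 * s_w)
        sig_c = _psd_project(0.1 * s_w) if "C" in components else np.zeros((k, k))
    sig_e = _psd_project(s_w - sig_a - sig_c, floor=1e-3)
    sig = {"A": sig_a, "C": sig_c, "E": sig_e}
    for x in components:
        tris[x] = np.linalg.cholesky(_psd_project(sig[x], floor=1e-4))
    return mean, tris


def fit_cholesky(
    groups: list[MultiTraitPairData],
    components=("A", "E"),
    n_restarts: int = 3,
    polish: bool = True,
) -> CholeskyFit:
    """FIML fit of the Cholesky model over the supplied twin groups.

    Per-sex analyses are obtained by passing only that sex's MZ and DZ groups
    (see :func:`fit_cholesky_by_sex`); all supplied groups share one set of
    means and loading matrices.
    """
    components = tuple(x for x in ("A", "C", "E") if x in components)
    if "E" not in components:
        raise ValueError("the unique-environment component E is mandatory")
    k = groups[0].k
    if any(g.k != k for g in groups):
        raise ValueError("all groups must carry the same traits")
    zygs = {g.zygosity for g in groups}
    if "A" in components and len(zygs) < 2:
        raise ValueError("A is not identified without both MZ and DZ groups")

    patterns_by_group = {}
    for g in groups:
        pats = _fiml.compress(g.data)
        if pats:
            patterns_by_group[g.group] = pats
    if not patterns_by_group:
        raise ValueError("all groups are empty")

    mean0, tris0 = _moment_start(groups, components)
    theta0 = _pack(mean0, tris0, components)

    def obj(theta):
        return _neg2ll(theta, k, components, patterns_by_group)

    def obj_grad(theta):
        return _neg2ll_and_grad(theta, k, components, patterns_by_group)

    rng = np.random.default_rng(0)
    best = None
    start = theta0
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(obj_grad, start, jac=True, method="BFGS",
                                options={"gtol": 1e-9, "maxiter": 4000})
        if polish and len(theta0) <= 9:
            res = optimize.minimize(
                obj, res.x, method="Nelder-Mead",
                options={"maxiter": 20000, "xatol": 1e-11, "fatol": 1e-13},
            )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
        if best is not None and np.isfinite(best.fun):
            break
        start = theta0 * (1.0 + 0.2 * rng.standard_normal(len(theta0)))
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Cholesky fit did not converge")

    m, tris = _unpack(best.x, k, components)
    # canonicalize: flip factor signs so diagonals are non-negative
    for x in components:
        t = tris[x]
        for j in range(k):
            if t[j, j] < 0:
                t[:, j] *= -1.0
    return CholeskyFit(
        trait_labels=groups[0].trait_labels,
        components=components,
        paths={x: tris[x] for x in components},
        means=m,
        minus2LL=float(best.fun),
        n_free_params=len(best.x),
        converged=True,
        fingerprint=_fingerprint(groups),
        _theta=_pack(m, tris, components),
        _patterns=patterns_by_group,
    )


def fit_cholesky_by_sex(
    groups: list[MultiTraitPairData], components=("A", "E"), **kwargs
) -> dict[str, CholeskyFit]:
    """Separate Cholesky fits per sex from same-sex MZ + DZ groups."""
    out = {}
    for sex, labels in (("M", ("MZM", "DZM")), ("F", ("MZF", "DZF"))):
        sub = [g for g in groups if g.group in labels]
        if len({g.zygosity for g in sub}) == 2:
            out[sex] = fit_cholesky(sub, components=components, **kwargs)
    if not out:
        raise ValueError("neither sex has both MZ and DZ groups")
    return out


# ---------------------------------------------------------------------------
# derived quantities

def _cov_to_corr(sigma: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(sigma))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sigma / np.outer(d, d)
    r[~np.isfinite(r)] = np.nan
    if np.isfinite(r).all():
        np.fill_diagonal(r, 1.0)
    return r


def derive_correlations(fit: CholeskyFit) -> dict[str, np.ndarray]:
    """Component correlation matrices r_A (r_C) r_E plus phenotypic r.

    r_X[i, j] = Sigma_X[i, j] / sqrt(Sigma_X[i, i] Sigma_X[j, j]); a zero
    component variance leaves the trait's correlations NaN (undefined).
    """
    if not fit.converged:
        raise ValueError("correlations require a converged fit")
    out = {f"r_{x}": _cov_to_corr(fit.component_cov(x)) for x in fit.components}
    out["r_phenotypic"] = _cov_to_corr(fit.sigma_total)
    return out


def correlation_ci(
    fit: CholeskyFit,
    component: str,
    i: int,
    j: int,
    level: float = 0.95,
    method: str = "profile",
) -> tuple[float, float, str]:
    """CI for one correlation entry; profile likelihood or delta method.

    ``component`` is "A", "C", "E" or "phenotypic".  Returns (lower, upper,
    method_used); the delta method is the labeled fallback when profiling
    fails to bracket.
    """
    def corr_fn(theta):
        _, tris = _unpack(theta, fit.k, fit.components)
        if component == "phenotypic":
            sig = sum(t @ t.T for t in tris.values())
        else:
            t = tris[component]
            sig = t @ t.T
        return sig[i, j] / np.sqrt(sig[i, i] * sig[j, j])

    theta_hat = fit._theta
    r_hat = corr_fn(theta_hat)

    if method == "profile":
        crit = fit.minus2LL + stats.chi2.ppf(level, 1)

        def profile_min(r0):
            res = optimize.minimize(
                lambda th: min(_neg2ll(th, fit.k, fit.components, fit._patterns), 1e12),
                theta_hat,
                method="SLSQP",
                constraints=[{"type": "eq", "fun": lambda th: corr_fn(th) - r0}],
                options={"maxiter": 300, "ftol": 1e-9},
            )
            return float(res.fun)

        def g(r0):
            return profile_min(r0) - crit

        try:
            eps = 1e-6
            lo = -1 + eps if g(-1 + eps) > 0 else None
            hi = 1 - eps if g(1 - eps) > 0 else None
            lower = (
                float(optimize.brentq(g, -1 + eps, r_hat, xtol=1e-4))
                if lo is not None else -1.0
            )
            upper = (
                float(optimize.brentq(g, r_hat, 1 - eps, xtol=1e-4))
                if hi is not None else 1.0
            )
            return lower, upper, "profile"
        except Exception:  # noqa: BLE001 - fall through to delta method
            pass

    # delta method on the Fisher-z scale
    grad = optimize.approx_fprime(theta_hat, corr_fn, 1e-5)
    hess = _numeric_hessian(
        lambda th: 0.5 * _neg2ll(th, fit.k, fit.components, fit._patterns), theta_hat
    )
    try:
        cov_theta = np.linalg.pinv(hess)
        var_r = float(grad @ cov_theta @ grad)
    except np.linalg.LinAlgError:
        var_r = np.nan
    if not np.isfinite(var_r) or var_r < 0:
        return -1.0, 1.0, "delta (unstable)"
    z = np.arctanh(np.clip(r_hat, -1 + 1e-12, 1 - 1e-12))
    se_z = np.sqrt(var_r) / max(1.0 - r_hat**2, 1e-12)
    q = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - q * se_z)), float(np.tanh(z + q * se_z)), "delta"


def _numeric_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.zeros((n, n))
    f0 = f(x)
    for a in range(n):
        for b in range(a, n):
            xa = x.copy(); xa[a] += h; xa[b] += h
            xb = x.copy(); xb[a] += h
            xc = x.copy(); xc[b] += h
            hess[a, b] = hess[b, a] = (f(xa) - f(xb) - f(xc) + f0) / h**2
    return hess


def decompose_phenotypic_correlation(
    fit: CholeskyFit, i: int, j: int
) -> dict[str, float]:
    """Component shares of one cross-trait covariance.

    contribution_X = Sigma_X[i, j] / Sigma[i, j]; the shares sum to 1.  A
    phenotypic covariance near zero leaves the decomposition undefined.
    """
    if i == j:
        raise ValueError("decomposition is defined for distinct traits")
    sigma = fit.sigma_total
    denom = sigma[i, j]
    scale = np.sqrt(sigma[i, i] * sigma[j, j])
    if abs(denom) < 1e-10 * scale:
        raise ValueError(
            f"phenotypic covariance of traits {i} and {j} is ~0; "
            "contribution shares are undefined"
        )
    return {x: float(fit.component_cov(x)[i, j] / denom) for x in fit.components}
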