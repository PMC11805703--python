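"""Univariate twin variance decomposition by full-information maximum likelihood.

The classical twin design contrasts monozygotic (MZ) pairs, whose additive
genetic (A) latents correlate 1, with dizygotic (DZ) pairs, where they
correlate 0.5.  Shared environment (C) correlates 1 in both, dominance (D)
1 vs 0.25, and unique environment (E) 0.  A trait's expected 2x2 within-pair
covariance in a zygosity group is assembled from path coefficients:

    var    = a^2 + c^2 (or d^2) + e^2
    cross  = kappa_A a a' + kappa_C c c' (or kappa_D d d')

with primes marking the co-twin's (possibly sex-specific) paths, so
opposite-sex DZ pairs contribute 0.5 * a_M * a_F to the cross-twin covariance.
The likelihood is bivariate-normal FIML over five zygosity-by-sex groups
(MZM, MZF, DZM, DZF, DZOS), evaluated per missingness pattern, so pairs with
one missing co-twin still contribute.

Sex-limitation modes:
  * ``sex_specific`` (full model): means and all paths free per sex;
  * ``common`` (no sex-specific differences): everything equated across sexes;
  * ``equal_a`` (no sex-specific genetic effects): the genetic path equated,
    means and the other paths free per sex.

Path signs are not identified; reported paths are absolute values and all
inference is on the standardized variance shares (a2 + c2|d2 + e2 = 1 per
sex), with profile-likelihood confidence intervals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _fiml

GROUPS = ("MZM", "MZF", "DZM", "DZF", "DZOS")
GROUP_ZYGOSITY = {"MZM": "MZ", "MZF": "MZ", "DZM": "DZ", "DZF": "DZ", "DZOS": "DZ"}
GROUP_SEXES = {
    "MZM": ("M", "M"),
    "MZF": ("F", "F"),
    "DZM": ("M", "M"),
    "DZF": ("F", "F"),
    "DZOS": ("M", "F"),
}
KAPPA = {
    "A": {"MZ": 1.0, "DZ": 0.5},
    "C": {"MZ": 1.0, "DZ": 1.0},
    "D": {"MZ": 1.0, "DZ": 0.25},
    "E": {"MZ": 0.0, "DZ": 0.0},
}
SEX_MODES = ("common", "sex_specific", "equal_a")


# ---------------------------------------------------------------------------
# data containers

@dataclass
class TwinGroupData:
    """Pairs-by-2 trait matrix for one zygosity-by-sex group (NaN = missing)."""

    group: str
    pairs: np.ndarray
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)

    @property
    def zygosity(self) -> str:
        return GROUP_ZYGOSITY[self.group]

    @property
    def sexes(self) -> tuple[str, str]:
        return GROUP_SEXES[self.group]

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def assign_group(traits: pd.DataFrame) -> pd.Series:
    """Zygosity-by-sex group label per row of a per-individual trait table."""
    pair_sex = traits.groupby("pair_id")["sex"].agg(lambda s: "".join(sorted(set(s))))
    mixed = traits["pair_id"].map(pair_sex) == "FM"
    zyg = traits["zygosity"].astype(str)
    if (mixed & (zyg == "MZ")).any():
        raise ValueError("MZ pairs must be same-sex")
    out = np.where(mixed, "DZOS", zyg + traits["sex"].astype(str))
    return pd.Series(out, index=traits.index, name="group")


def twin_groups_from_table(
    traits: pd.DataFrame, trait: str, include_os: bool = True
) -> list[TwinGroupData]:
    """Build per-group pair matrices from a per-individual trait table.

    Requires columns pair_id, birth_order, sex, zygosity and the trait column;
    twin1/twin2 are ordered by birth order.
    """
    t = traits.copy()
    t["group"] = assign_group(t)
    out = []
    for g in GROUPS:
        if g == "DZOS" and not include_os:
            continue
        sub = t[t["group"] == g]
        if len(sub) == 0:
            continue
        wide = sub.pivot_table(
            index="pair_id", columns="birth_order", values=trait, aggfunc="first",
            dropna=False,
        ).reindex(columns=[1, 2])
        if g == "DZOS":
            # order columns male first to match GROUP_SEXES, not birth order
            sex_map = sub.pivot_table(
                index="pair_id", columns="birth_order", values="sex", aggfunc="first"
            ).reindex(columns=[1, 2])
            vals = wide.to_numpy()
            swap = (sex_map[1] == "F").to_numpy()
            vals[swap] = vals[swap][:, ::-1]
            out.append(TwinGroupData(group=g, pairs=vals, trait=trait))
        else:
            out.append(TwinGroupData(group=g, pairs=wide.to_numpy(), trait=trait))
    if not out:
        raise ValueError("no twin groups could be built from the table")
    return out


def data_fingerprint(groups: list[TwinGroupData]) -> str:
    h = hashlib.sha256()
    for g in sorted(groups, key=lambda x: x.group):
        h.update(g.group.encode())
        arr = np.nan_to_num(g.pairs, nan=-9e99)
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# model specification and parameter layout

@dataclass(frozen=True)
class ModelSpec:
    """Variance components and sex-limitation mode of a twin model."""

    components: str = "ACE"          # subset of "ACDE"; E mandatory
    sex_mode: str = "sex_specific"   # common | sex_specific | equal_a

    def __post_init__(self) -> None:
        comps = set(self.components)
        if not comps <= set("ACDE"):
            raise ValueError(f"unknown components in {self.components!r}")
        if "E" not in comps:
            raise ValueError("the unique-environment component E is mandatory")
        if {"C", "D"} <= comps:
            raise ValueError("C and D cannot be estimated simultaneously")
        if self.sex_mode not in SEX_MODES:
            raise ValueError(f"sex_mode must be one of {SEX_MODES}")
        # canonical ordering A, C, D, E
        object.__setattr__(
            self, "components", "".join(x for x in "ACDE" if x in comps)
        )

    @property
    def label(self) -> str:
        return f"{self.components}/{self.sex_mode}"


class _Layout:
    """Maps a flat parameter vector to per-sex means and paths."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        names: list[str] = []
        if spec.sex_mode == "common":
            names.append("mu")
        else:
            names += ["mu_M", "mu_F"]
        for comp in spec.components:
            if spec.sex_mode == "common" or (spec.sex_mode == "equal_a" and comp == "A"):
                names.append(comp.lower())
            else:
                names += [f"{comp.lower()}_M", f"{comp.lower()}_F"]
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def unpack(self, theta: np.ndarray):
        spec = self.spec
        if spec.sex_mode == "common":
            means = {"M": theta[self.index["mu"]], "F": theta[self.index["mu"]]}
        else:
            means = {"M": theta[self.index["mu_M"]], "F": theta[self.index["mu_F"]]}
        paths: dict[str, dict[str, float]] = {}
        for comp in spec.components:
            c = comp.lower()
            if c in self.index:
                v = theta[self.index[c]]
                paths[comp] = {"M": v, "F": v}
            else:
                paths[comp] = {
                    "M": theta[self.index[f"{c}_M"]],
                    "F": theta[self.index[f"{c}_F"]],
                }
        return means, paths


def _group_moments(means, paths, group: str):
    zyg = GROUP_ZYGOSITY[group]
    s1, s2 = GROUP_SEXES[group]
    mu = np.array([means[s1], means[s2]])
    v1 = sum(paths[x][s1] ** 2 for x in paths)
    v2 = sum(paths[x][s2] ** 2 for x in paths)
    cross = sum(KAPPA[x][zyg] * paths[x][s1] * paths[x][s2] for x in paths)
    sigma = np.array([[v1, cross], [cross, v2]])
    return mu, sigma


# ---------------------------------------------------------------------------
# saturated model

@dataclass
class GroupSaturated:
    group: str
    mean: np.ndarray
    cov: np.ndarray
    n_pairs: int
    minus2ll: float
    degenerate: bool = False

    @property
    def correlation(self) -> float:
        v1, v2 = self.cov[0, 0], self.cov[1, 1]
        if v1 <= 0 or v2 <= 0:
            return np.nan
        return float(self.cov[0, 1] / np.sqrt(v1 * v2))


@dataclass
class SaturatedFit:
    groups: dict[str, GroupSaturated]
    minus2LL: float
    n_free_params: int
    fingerprint: str
    label: str = "saturated"
    converged: bool = True

    @property
    def AIC(self) -> float:
        return self.minus2LL + 2 * self.n_free_params


def _closed_form_saturated(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Complete-data saturated MLE and -2LL: n (2 log 2pi + log det S + 2)."""
    n = x.shape[0]
    mu = x.mean(axis=0)
    xc = x - mu
    s = xc.T @ xc / n
    sign, logdet = np.linalg.slogdet(s)
    degenerate = sign <= 0 or not np.isfinite(logdet)
    m2ll = np.inf if degenerate else n * (2.0 * np.log(2.0 * np.pi) + logdet + 2.0)
    return mu, s, float(m2ll), degenerate


def _numeric_saturated(patterns) -> tuple[np.ndarray, np.ndarray, float, bool]:
    def build(theta):
        mu = theta[:2]
        sd = np.exp(theta[2:4])
        rho = np.tanh(theta[4])
        cov = np.array(
            [[sd[0] ** 2, rho * sd[0] * sd[1]], [rho * sd[0] * sd[1], sd[1] ** 2]]
        )
        return mu, cov

    def obj(theta):
        mu, cov = build(theta)
        return _fiml.neg2ll(patterns, mu, cov)

    # moment start from whatever is observed
    start = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
    m1 = [p for p in patterns if 0 in p.idx]
    m2 = [p for p in patterns if 1 in p.idx]
    if m1:
        tot = sum(p.total[list(p.idx).index(0)] for p in m1)
        n = sum(p.n for p in m1)
        start[0] = tot / n
    if m2:
        tot = sum(p.total[list(p.idx).index(1)] for p in m2)
        n = sum(p.n for p in m2)
        start[1] = tot / n
    res = optimize.minimize(obj, start, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
    res = optimize.minimize(obj, res.x, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
    mu, cov = build(res.x)
    return mu, cov, float(res.fun), abs(np.tanh(res.x[4])) > 1 - 1e-9


def fit_saturated(groups: list[TwinGroupData]) -> SaturatedFit:
    """Free means/variances/covariance per group; FIML under missingness.

    For complete data the MLE is the sample moments and the -2LL its closed
    form.  Groups with no observations are dropped with a warning flag; a
    singular within-group covariance (e.g. twin1 identical to twin2) is
    flagged degenerate, not an error.
    """
    out: dict[str, GroupSaturated] = {}
    total = 0.0
    for g in groups:
        patterns = _fiml.compress(g.pairs)
        if not patterns:
            continue
        complete = [p for p in patterns if len(p.idx) == 2]
        if len(patterns) == 1 and complete:
            x = g.pairs[~np.isnan(g.pairs).any(axis=1)]
            mu, cov, m2ll, degen = _closed_form_saturated(x)
        else:
            mu, cov, m2ll, degen = _numeric_saturated(patterns)
        out[g.group] = GroupSaturated(
            group=g.group, mean=mu, cov=cov, n_pairs=g.n_pairs,
            minus2ll=m2ll, degenerate=degen,
        )
        total += m2ll
    if not out:
        raise ValueError("no groups with observations")
    return SaturatedFit(
        groups=out,
        minus2LL=float(total),
        n_free_params=5 * len(out),
        fingerprint=data_fingerprint(groups),
    )


def fit_constrained_saturated(groups: list[TwinGroupData]) -> SaturatedFit:
    """Saturated model with means and variances equated across co-twins.

    Three free parameters per group (mu, sigma, rho); this is the 'twin model
    assumptions' constraint tested against the full saturated model.
    """
    out: dict[str, GroupSaturated] = {}
    total = 0.0
    for g in groups:
        patterns = _fiml.compress(g.pairs)
        if not patterns:
            continue

        def build(theta):
            mu = np.array([theta[0], theta[0]])
            v = np.exp(2 * theta[1])
            rho = np.tanh(theta[2])
            return mu, np.array([[v, rho * v], [rho * v, v]])

        def obj(theta):
            mu, cov = build(theta)
            return _fiml.neg2ll(patterns, mu, cov)

        vals = g.pairs[~np.isnan(g.pairs)]
        start = np.array([vals.mean(), np.log(max(vals.std(), 1e-6)), 0.2])
        res = optimize.minimize(obj, start, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        mu, cov = build(res.x)
        out[g.group] = GroupSaturated(
            group=g.group, mean=mu, cov=cov, n_pairs=g.n_pairs,
            minus2ll=float(res.fun),
        )
        total += float(res.fun)
    return SaturatedFit(
        groups=out,
        minus2LL=float(total),
        n_free_params=3 * len(out),
        fingerprint=data_fingerprint(groups),
        label="saturated (equal means/variances)",
    )


# ---------------------------------------------------------------------------
# variance-component models

@dataclass
class VarianceComponentsResult:
    spec: ModelSpec
    paths: dict[str, dict[str, float]]       # component -> sex -> |path|
    means: dict[str, float]
    variances: dict[str, float]              # total variance per sex
    shares: dict[str, dict[str, float]]      # sex -> component -> standardized share
    minus2LL: float
    n_free_params: int
    converged: bool
    fingerprint: str
    ci: dict = field(default_factory=dict)   # (component, sex) -> ProfileCI
    _theta: np.ndarray | None = None
    _layout: _Layout | None = None
    _patterns: dict | None = None

    @property
    def AIC(self) -> float:
        return self.minus2LL + 2 * self.n_free_params

    @property
    def label(self) -> str:
        return self.spec.label

    def share(self, component: str, sex: str = "M") -> float:
        return self.shares[sex][component]

    def heritability(self, sex: str = "M") -> float:
        """h^2 = Va / V, the standardized additive-genetic share."""
        return self.shares[sex].get("A", 0.0)


def _neg2ll_theta(theta, layout: _Layout, patterns_by_group: dict) -> float:
    means, paths = layout.unpack(theta)
    total = 0.0
    for group, patterns in patterns_by_group.items():
        mu, sigma = _group_moments(means, paths, group)
        total += _fiml.neg2ll(patterns, mu, sigma)
    return total


def moment_estimates(groups: list[TwinGroupData]) -> dict:
    """Falconer-style moment summary: pooled rMZ, rDZ, mean and variance.

    Used for start values and as an independent oracle for AE fits:
    a2 = 2 (rMZ - rDZ), e2 = 1 - rMZ, projected onto [0, 1].
    """
    corrs = {"MZ": [], "DZ": []}
    vals = {"M": [], "F": []}
    for g in groups:
        x = g.pairs[~np.isnan(g.pairs).any(axis=1)]
        if x.shape[0] >= 3 and g.group != "DZOS":
            r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
            if np.isfinite(r):
                corrs[g.zygosity].append((r, x.shape[0]))
        s1, s2 = g.sexes
        vals[s1].append(g.pairs[:, 0])
        vals[s2].append(g.pairs[:, 1])

    def pooled(pairs):
        if not pairs:
            return np.nan
        w = np.array([n for _, n in pairs], dtype=float)
        r = np.array([r for r, _ in pairs])
        return float(np.sum(w * r) / np.sum(w))

    rmz, rdz = pooled(corrs["MZ"]), pooled(corrs["DZ"])
    out = {"rMZ": rmz, "rDZ": rdz}
    for s in ("M", "F"):
        v = np.concatenate(vals[s]) if vals[s] else np.array([])
        v = v[~np.isnan(v)]
        out[f"mean_{s}"] = float(v.mean()) if v.size else 0.0
        out[f"var_{s}"] = float(v.var(ddof=1)) if v.size > 1 else 1.0
    if np.isfinite(rmz) and np.isfinite(rdz):
        a2 = float(np.clip(2.0 * (rmz - rdz), 0.02, 0.95))
        c2 = float(np.clip(2.0 * rdz - rmz, 0.02, 0.95))
        d2 = float(np.clip(2.0 * (2.0 * rdz - rmz) * -1.0, 0.02, 0.95))
    else:
        a2, c2, d2 = 0.4, 0.2, 0.2
    out["a2"], out["c2"], out["d2"] = a2, c2, d2
    return out


def _start_theta(layout: _Layout, groups: list[TwinGroupData]) -> np.ndarray:
    m = moment_estimates(groups)
    comps = layout.spec.components
    shares = {}
    raw = {"A": m["a2"], "C": m["c2"], "D": m["d2"], "E": 0.0}
    used = sum(raw[x] for x in comps if x != "E")
    used = min(used, 0.9)
    scale = used / max(sum(raw[x] for x in comps if x != "E"), 1e-9)
    for x in comps:
        if x != "E":
            shares[x] = raw[x] * scale
    shares["E"] = 1.0 - sum(shares.get(x, 0.0) for x in comps if x != "E")
    theta = np.zeros(len(layout))
    for name, i in layout.index.items():
        if name == "mu":
            theta[i] = 0.5 * (m["mean_M"] + m["mean_F"])
        elif name.startswith("mu_"):
            theta[i] = m[f"mean_{name[-1]}"]
        else:
            comp = name[0].upper()
            if name[-1] in ("M", "F") and "_" in name:
                v = m[f"var_{name[-1]}"]
            else:
                v = 0.5 * (m["var_M"] + m["var_F"])
            theta[i] = np.sqrt(max(shares[comp], 1e-3) * v)
    return theta


def fit_variance_components(
    groups: list[TwinGroupData],
    spec: ModelSpec,
    n_restarts: int = 5,
    polish: bool = True,
    rng: np.random.Generator | None = None,
) -> VarianceComponentsResult:
    """Maximum-likelihood fit of an ACE/ADE-family model over twin groups."""
    needs_zyg = any(x in spec.components for x in "ACD")
    zygs = {GROUP_ZYGOSITY[g.group] for g in groups}
    if needs_zyg and len(zygs) < 2:
        raise ValueError(
            "A and C/D are not identified without both MZ and DZ groups"
        )
    patterns_by_group = {}
    for g in groups:
        pats = _fiml.compress(g.pairs)
        if not pats:
            continue
        patterns_by_group[g.group] = pats
    if not patterns_by_group:
        raise ValueError("all groups are empty or all-missing")

    layout = _Layout(spec)
    theta0 = _start_theta(layout, groups)
    rng = rng or np.random.default_rng(0)

    def obj(theta):
        return _neg2ll_theta(theta, layout, patterns_by_group)

    best = None
    start = theta0
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(obj, start, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 2000})
        if polish:
            res = optimize.minimize(
                obj, res.x, method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
            )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
        if best is not None and np.isfinite(best.fun):
            break
        start = theta0 * (1.0 + 0.3 * rng.standard_normal(len(theta0))) + 0.01
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"variance-component fit did not converge for {spec.label}"
        )

    theta = best.x
    means, paths = layout.unpack(theta)
    variances = {
        s: float(sum(paths[x][s] ** 2 for x in paths)) for s in ("M", "F")
    }
    shares = {
        s: {x: float(paths[x][s] ** 2 / variances[s]) for x in spec.components}
        for s in ("M", "F")
    }
    return VarianceComponentsResult(
        spec=spec,
        paths={x: {s: abs(float(paths[x][s])) for s in ("M", "F")} for x in paths},
        means={s: float(means[s]) for s in ("M", "F")},
        variances=variances,
        shares=shares,
        minus2LL=float(best.fun),
        n_free_params=len(layout),
        converged=True,
        fingerprint=data_fingerprint(groups),
        _theta=theta,
        _layout=layout,
        _patterns=patterns_by_group,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals

@dataclass
class ProfileCI:
    lower: float
    upper: float
    lower_at_boundary: bool = False
    upper_at_boundary: bool = False
    level: float = 0.95

    def __iter__(self):
        return iter((self.lower, self.upper))


def _profile_min(result: VarianceComponentsResult, component: str, sex: str,
                 s0: float) -> float:
    """min -2LL subject to share(component, sex) = s0.

    When the profiled stratum's paths are separate parameters (common and
    sex_specific modes) the constraint is imposed by reparametrizing that
    stratum as (log total variance, remaining-share logits); under equal_a
    the genetic path is shared across strata and SLSQP with an equality
    constraint is used instead.
    """
    layout = result._layout
    spec = result.spec
    theta_hat = result._theta
    patterns = result._patterns
    comps = spec.components
    others = [x for x in comps if x != component]

    def stratum_names(mode_sex):
        if spec.sex_mode == "common":
            return {x: x.lower() for x in comps}
        return {x: f"{x.lower()}_{mode_sex}" for x in comps}

    names = stratum_names(sex)
    reparam_ok = all(n in layout.index for n in names.values())

    if reparam_ok:
        strat_idx = [layout.index[n] for n in names.values()]
        free_idx = [i for i in range(len(layout)) if i not in strat_idx]
        v_hat = result.variances[sex]
        sh = result.shares[sex]
        rem = max(1.0 - s0, 1e-12)
        # stick-breaking logits for the non-profiled components
        logits0 = []
        tail = sum(sh[x] for x in others)
        for x in others[:-1]:
            p = sh[x] / max(tail, 1e-12)
            logits0.append(np.log(p / max(1.0 - p, 1e-12)))
            tail -= sh[x]
        z0 = np.concatenate([theta_hat[free_idx], [np.log(max(v_hat, 1e-12))],
                             logits0])

        def expand(z):
            theta = np.array(theta_hat, dtype=float)
            theta[free_idx] = z[: len(free_idx)]
            v = np.exp(z[len(free_idx)])
            logits = z[len(free_idx) + 1:]
            rem_share = rem
            shares = {component: s0}
            for j, x in enumerate(others[:-1]):
                p = 1.0 / (1.0 + np.exp(-logits[j]))
                shares[x] = rem_share * p
                rem_share *= 1.0 - p
            shares[others[-1]] = rem_share
            for x in comps:
                theta[layout.index[names[x]]] = np.sqrt(max(shares[x], 0.0) * v)
            return theta

        def obj(z):
            return _neg2ll_theta(expand(z), layout, patterns)

        res = optimize.minimize(obj, z0, method="BFGS",
                                options={"gtol": 1e-7, "maxiter": 1000})
        fun = float(res.fun)
        # BFGS "precision loss" near a tight optimum is fine; only a
        # non-finite value warrants the derivative-free fallback
        if not np.isfinite(fun):
            res2 = optimize.minimize(obj, z0, method="Nelder-Mead",
                                     options={"maxiter": 2000, "xatol": 1e-9,
                                              "fatol": 1e-10})
            fun = float(res2.fun)
        return fun

    # equal_a (shared genetic path): constrained optimization
    def share_fn(theta):
        _, paths = layout.unpack(theta)
        v = sum(paths[x][sex] ** 2 for x in paths)
        return paths[component][sex] ** 2 / v - s0

    def obj(theta):
        val = _neg2ll_theta(theta, layout, patterns)
        return val if np.isfinite(val) else 1e12

    # start at the MLE rescaled toward the constraint
    res = optimize.minimize(
        obj, theta_hat, method="SLSQP",
        constraints=[{"type": "eq", "fun": share_fn}],
        options={"maxiter": 500, "ftol": 1e-10},
    )
    return float(res.fun)


def profile_ci(
    result: VarianceComponentsResult,
    parameter: tuple[str, str] | str,
    level: float = 0.95,
    xtol: float = 2e-4,
) -> ProfileCI:
    """Profile-likelihood CI for a standardized variance share.

    ``parameter`` is (component, sex), e.g. ("A", "M"); a bare component
    string profiles the common/male share.  Bounds are where -2LL rises by
    the chi-square(1) quantile above the minimum, found by root-bracketing on
    the share scale with nuisance parameters re-optimized at every step;
    bounds not bracketed inside (0, 1) are reported at the boundary with a
    flag.
    """
    if isinstance(parameter, str):
        parameter = (parameter, "M")
    component, sex = parameter
    if component not in result.spec.components:
        raise ValueError(f"component {component!r} not in model {result.spec.label}")
    crit = result.minus2LL + stats.chi2.ppf(level, 1)
    s_hat = result.shares[sex][component]
    eps = 1e-7

    def g(s):
        return _profile_min(result, component, sex, s) - crit

    lower, upper = 0.0, 1.0
    lower_b = upper_b = False
    if s_hat <= eps:
        lower_b = True
    elif g(eps) < 0:
        lower, lower_b = 0.0, True
    else:
        lower = float(optimize.brentq(g, eps, s_hat, xtol=xtol))
    if s_hat >= 1 - eps:
        upper_b = True
    elif g(1 - eps) < 0:
        upper, upper_b = 1.0, True
    else:
        upper = float(optimize.brentq(g, s_hat, 1 - eps, xtol=xtol))
    ci = ProfileCI(lower=max(lower, 0.0), upper=min(upper, 1.0),
                   lower_at_boundary=lower_b, upper_at_boundary=upper_b,
                   level=level)
    result.ci[(component, sex)] = ci
    return ci


# ---------------------------------------------------------------------------
# model comparison

@dataclass
class ModelComparison:
    table: pd.DataFrame
    reference: str
    selected: str
    alpha: float = 0.05


def _lrt_p(delta_2ll: float, delta_df: int, boundary: str = "naive") -> float:
    delta_2ll = max(delta_2ll, 0.0)
    if delta_df <= 0:
        return 1.0 if delta_2ll <= 1e-4 else 0.0
    if boundary == "mixture" and delta_df == 1:
        # 50:50 mixture of chi2_0 and chi2_1 for a variance tested at zero
        return 0.5 * stats.chi2.sf(delta_2ll, 1) if delta_2ll > 0 else 1.0
    return float(stats.chi2.sf(delta_2ll, delta_df))


def compare_models(
    fits: list, reference, alpha: float = 0.05, boundary: str = "naive",
    tol: float = 1e-4,
) -> ModelComparison:
    """Likelihood-ratio comparison table against a reference model.

    All fits must be on identical data (checked by fingerprint).  Selection:
    the most parsimonious model not significantly worse than the reference at
    ``alpha`` (AIC breaks ties).  ``boundary='mixture'`` applies the
    conservative 50:50 chi-square mixture to single-df comparisons.
    """
    fp = reference.fingerprint
    for f in fits:
        if f.fingerprint != fp:
            raise ValueError(
                "model comparison requires fits on identical data "
                "(data fingerprints differ)"
            )
    rows = []
    all_fits = [reference] + [f for f in fits if f is not reference]
    for f in all_fits:
        d2 = f.minus2LL - reference.minus2LL
        ddf = reference.n_free_params - f.n_free_params
        if f is not reference and d2 < -tol:
            raise ValueError(
                f"model {f.label!r} has better likelihood than its declared "
                f"reference ({d2:.4g}); nesting is wrong or the reference "
                f"did not converge"
            )
        p = 1.0 if f is reference else _lrt_p(d2, ddf, boundary)
        rows.append(
            {
                "model": f.label,
                "minus2LL": f.minus2LL,
                "n_params": f.n_free_params,
                "delta_minus2LL": max(d2, 0.0) if f is not reference else 0.0,
                "delta_df": ddf if f is not reference else 0,
                "p": p,
                "AIC": f.AIC,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["p"] >= alpha]
    pick = ok.sort_values(["n_params", "AIC"]).iloc[0] if len(ok) else table.iloc[0]
    return ModelComparison(
        table=table, reference=reference.label, selected=str(pick["model"]),
        alpha=alpha,
    )


def test_assumptions(groups: list[TwinGroupData], alpha: float = 0.05) -> ModelComparison:
    """Twin-model assumption tests against the saturated model.

    Compares (i) the saturated model with means/variances equated across
    co-twins and (ii) the full sex-specific ACE model to the free saturated
    model.  Violations (p < alpha) are reported, not fatal: downstream
    modeling proceeds regardless, mirroring standard practice.
    """
    sat = fit_saturated(groups)
    constrained = fit_constrained_saturated(groups)
    ace = fit_variance_components(groups, ModelSpec("ACE", "sex_specific"))
    return compare_models([constrained, ace], sat, alpha=alpha)
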