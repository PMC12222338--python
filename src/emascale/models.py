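"""Group inference for scale differences in within-person statistics.

Each within-person statistic (one value per participant x item) is modeled
with a distributional regression: fixed effects of response scale (Likert
baseline), item valence (effects coded, negative = +1) and their
interaction on *every* distributional parameter — location, dispersion,
and boundary inflation where the family has them.  Families:

* ``zoib``   — zero-/one-inflated beta for statistics bounded in [0, 1]
  (within-person means, SDs, RMSSDs, missing proportions, mean absolute
  correlations; inflation parts switchable per outcome),
* ``gaussian``  — for unbounded-ish statistics (skewness, lag-1
  autocorrelation, initial elevation), with the log-variance modeled,
* ``lognormal`` — for survey durations.

Three inference backends share one model definition:

* ``mcmc``          — adaptive Metropolis-within-Gibbs over fixed effects,
  crossed random intercepts (participant, item) and their SDs; weakly
  informative priors; rhat/ess diagnostics via arviz,
* ``map_laplace``   — penalized ML on the fixed effects plus a Gaussian
  (Laplace) approximation,
* ``cluster_bootstrap`` — fixed-effects ML refit on participant resamples,
  yielding draw-like replicates.

Estimated marginal means condition random effects at zero and average the
response-scale expectation over the two valence levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

logger = logging.getLogger("emascale")

_LINK_EPS = 1e-12


def _expit(x):
    return special.expit(x)


def _logit(p):
    return special.logit(np.clip(p, _LINK_EPS, 1 - _LINK_EPS))


# ---------------------------------------------------------------------------
# densities


def zoib_logpdf(y, mu, phi, pi0=0.0, pi1=0.0):
    """Log density of the zero-/one-inflated beta mixture.

    Point mass ``pi0`` at 0, ``pi1`` at 1, and weight 1-pi0-pi1 on a
    Beta(mu*phi, (1-mu)*phi) interior (mean/precision parameterization).
    Scalars or broadcastable arrays; requires pi0 + pi1 < 1.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("zoib responses must lie in [0, 1]")
    mu, phi, pi0, pi1 = (np.asarray(v, dtype=float) for v in (mu, phi, pi0, pi1))
    if np.any(pi0 + pi1 >= 1):
        raise ValueError("pi0 + pi1 must be < 1")
    a = mu * phi
    b = (1.0 - mu) * phi
    with np.errstate(divide="ignore", invalid="ignore"):
        interior = (
            np.log1p(-(pi0 + pi1))
            + special.gammaln(a + b)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
        out = np.where(y == 0.0, np.log(pi0), np.where(y == 1.0, np.log(pi1), interior))
    return float(out) if out.ndim == 0 else out


def hdi(draws, mass: float = 0.90) -> tuple[float, float]:
    """Shortest contiguous interval holding ``mass`` of the sorted draws.

    The arg-min window is noisy when the density is symmetric (the width
    profile has a flat valley), so the endpoints of all windows within
    0.5% of the minimal width are averaged; for clearly skewed densities
    the valley is one-sided and the averaging is inert.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    window = int(np.ceil(mass * n))
    if n < 100 or window >= n:
        if n < 100:
            raise ValueError(f"need >= 100 draws for an HDI, got {n}")
        return float(x[0]), float(x[-1])
    widths = x[window - 1 :] - x[: n - window + 1]
    wmin = float(widths.min())
    if wmin == 0.0:
        i = int(np.argmin(widths))
        return float(x[i]), float(x[i + window - 1])
    near = widths <= wmin * 1.005
    return float(x[: n - window + 1][near].mean()), float(x[window - 1 :][near].mean())


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Family and structure of one group model.

    ``family``: zoib | gaussian | lognormal.  ``zero_inflation`` /
    ``one_inflation`` switch the boundary point masses of the zoib family
    (one-inflation is meant for the missing-proportion outcome).
    ``valence_effects`` adds the effects-coded valence main effect and the
    scale x valence interaction (off for survey-level outcomes such as
    duration).  ``random_effects`` selects crossed random intercepts on
    the location parameter (mcmc backend only).  Priors are weakly
    informative normals on the link scales and half-normals for the
    random-effect SDs.
    """

    family: str = "zoib"
    zero_inflation: bool | None = None  # default: True for zoib, off otherwise
    one_inflation: bool = False
    valence_effects: bool = True
    random_effects: tuple[str, ...] = ("participant", "item")
    prior_scale: float = 2.5
    re_sd_prior_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("zoib", "gaussian", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.zero_inflation is None:
            self.zero_inflation = self.family == "zoib"
        if self.family != "zoib" and (self.zero_inflation or self.one_inflation):
            raise ValueError("inflation parts only apply to the zoib family")

    @property
    def param_blocks(self) -> list[str]:
        blocks = ["mu", "disp"]
        if self.zero_inflation:
            blocks.append("pi0")
        if self.one_inflation:
            blocks.append("pi1")
        return blocks


@dataclass
class PosteriorDraws:
    """Named draws of fixed effects (and RE SDs) with diagnostics."""

    draws: dict
    backend: str
    spec: ModelSpec
    design_columns: list[str]
    diagnostics: pd.DataFrame | None = None
    converged: bool = True
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    def stack(self, names: list[str]) -> np.ndarray:
        return np.column_stack([self.draws[n] for n in names])


# ---------------------------------------------------------------------------
# design and likelihood


def build_design(groups: np.ndarray, valences: np.ndarray | None, valence_effects: bool) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: Likert is the baseline, valence effects coded.

    ``groups`` holds 'likert'/'vas' labels; ``valences`` 'positive'/'negative'
    labels (negative coded +1, positive -1 so the intercept is the average
    across valences).
    """
    scale = (np.asarray(groups) == "vas").astype(float)
    cols = [np.ones_like(scale), scale]
    names = ["intercept", "scale_vas"]
    if valence_effects:
        if valences is None:
            raise ValueError("valence_effects requested but no valence labels given")
        val = np.where(np.asarray(valences) == "negative", 1.0, -1.0)
        cols += [val, scale * val]
        names += ["valence", "scale_x_valence"]
    return np.column_stack(cols), names


class _GroupModel:
    """Internal likelihood/gradient engine shared by all backends."""

    def __init__(self, y, X, spec: ModelSpec, pid_idx=None, iid_idx=None, n_p=0, n_i=0):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.spec = spec
        self.p = self.X.shape[1]
        self.pid_idx = pid_idx
        self.iid_idx = iid_idx
        self.n_p = n_p
        self.n_i = n_i
        self.is0 = self.y == 0.0
        self.is1 = self.y == 1.0
        self.interior = ~(self.is0 | self.is1)
        if spec.family == "zoib":
            if np.any(self.is0) and not spec.zero_inflation:
                raise ValueError("data contain exact zeros but zero_inflation is off")
            if np.any(self.is1) and not spec.one_inflation:
                raise ValueError("data contain exact ones but one_inflation is off")
            self._logy = np.where(self.interior, np.log(np.where(self.interior, self.y, 0.5)), 0.0)
            self._log1my = np.where(self.interior, np.log1p(-np.where(self.interior, self.y, 0.5)), 0.0)
        elif spec.family == "lognormal":
            if np.any(self.y <= 0):
                raise ValueError("lognormal requires strictly positive responses")
            self._logy = np.log(self.y)

    # -- fixed-effects parameter vector: concatenated beta blocks ----------

    @property
    def n_beta(self) -> int:
        return self.p * len(self.spec.param_blocks)

    def split_beta(self, beta: np.ndarray) -> dict:
        out = {}
        for k, name in enumerate(self.spec.param_blocks):
            out[name] = beta[k * self.p : (k + 1) * self.p]
        return out

    def _linpreds(self, beta: np.ndarray, z_offset=0.0) -> dict:
        b = self.split_beta(beta)
        eta = {name: self.X @ b[name] for name in b}
        eta["mu"] = eta["mu"] + z_offset
        return eta

    def loglik_rows(self, beta: np.ndarray, z_offset=0.0) -> np.ndarray:
        eta = self._linpreds(beta, z_offset)
        fam = self.spec.family
        if fam == "zoib":
            mu = _expit(eta["mu"])
            phi = np.exp(eta["disp"])
            pi0 = _expit(eta["pi0"]) if "pi0" in eta else 0.0
            pi1 = _expit(eta["pi1"]) if "pi1" in eta else 0.0
            mu = np.clip(mu, _LINK_EPS, 1 - _LINK_EPS)
            a = mu * phi
            b_ = (1.0 - mu) * phi
            # the two inflation logits are independent, so guard the corner
            # where their probabilities sum past 1
            pi_sum = np.clip(np.broadcast_to(pi0 + pi1, self.y.shape), 0.0, 1 - _LINK_EPS)
            interior = (
                np.log1p(-pi_sum)
                + special.gammaln(a + b_)
                - special.gammaln(a)
                - special.gammaln(b_)
                + (a - 1.0) * self._logy
                + (b_ - 1.0) * self._log1my
            )
            with np.errstate(divide="ignore"):
                ll = np.where(
                    self.is0,
                    np.log(np.broadcast_to(pi0, self.y.shape)) if self.spec.zero_inflation else -np.inf,
                    np.where(
                        self.is1,
                        np.log(np.broadcast_to(pi1, self.y.shape)) if self.spec.one_inflation else -np.inf,
                        interior,
                    ),
                )
            return ll
        mu = eta["mu"]
        log_sigma = eta["disp"]
        target = self._logy if fam == "lognormal" else self.y
        ll = -0.918938533204672670 - log_sigma - 0.5 * ((target - mu) / np.exp(log_sigma)) ** 2
        if fam == "lognormal":
            ll = ll - self._logy
        return ll

    def grad_beta(self, beta: np.ndarray) -> np.ndarray:
        """Analytic gradient of the total fixed-effects log likelihood."""
        eta = self._linpreds(beta)
        fam = self.spec.family
        grads = []
        if fam == "zoib":
            mu = np.clip(_expit(eta["mu"]), _LINK_EPS, 1 - _LINK_EPS)
            phi = np.exp(eta["disp"])
            pi0 = _expit(eta["pi0"]) if "pi0" in eta else np.zeros_like(mu)
            pi1 = _expit(eta["pi1"]) if "pi1" in eta else np.zeros_like(mu)
            a = mu * phi
            b_ = (1.0 - mu) * phi
            dig_a = special.digamma(a)
            dig_b = special.digamma(b_)
            dig_ab = special.digamma(a + b_)
            inter = self.interior.astype(float)
            # d ll / d eta_mu = inter * phi * mu(1-mu) * (digamma(b)-digamma(a)+log y - log(1-y))
            dmu = inter * phi * mu * (1 - mu) * (dig_b - dig_a + self._logy - self._log1my)
            grads.append(self.X.T @ dmu)
            dphi = inter * phi * (
                dig_ab - mu * dig_a - (1 - mu) * dig_b + mu * self._logy + (1 - mu) * self._log1my
            )
            grads.append(self.X.T @ dphi)
            one_minus = np.clip(1.0 - pi0 - pi1, _LINK_EPS, None)
            if self.spec.zero_inflation:
                d = np.where(self.is0, (1 - pi0), 0.0) - inter * pi0 * (1 - pi0) / one_minus
                grads.append(self.X.T @ d)
            if self.spec.one_inflation:
                d = np.where(self.is1, (1 - pi1), 0.0) - inter * pi1 * (1 - pi1) / one_minus
                grads.append(self.X.T @ d)
            return np.concatenate(grads)
        mu = eta["mu"]
        sigma = np.exp(eta["disp"])
        target = self._logy if fam == "lognormal" else self.y
        resid = (target - mu) / sigma
        grads.append(self.X.T @ (resid / sigma))
        grads.append(self.X.T @ (resid**2 - 1.0))
        return np.concatenate(grads)


def _ml_fit(model: _GroupModel, ridge_scale: float = 5.0, x0: np.ndarray | None = None):
    """Penalized ML on the fixed effects (weak N(0, ridge_scale^2) ridge)."""

    lam = 1.0 / (2.0 * ridge_scale**2)

    def negloglik(beta):
        ll = model.loglik_rows(beta)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -(ll.sum() - lam * np.dot(beta, beta))

    def grad(beta):
        return -(model.grad_beta(beta) - 2.0 * lam * beta)

    if x0 is None:
        x0 = _init_beta(model)
    res = optimize.minimize(negloglik, x0, jac=grad, method="L-BFGS-B")
    return res


def _init_beta(model: _GroupModel) -> np.ndarray:
    """Moment-based starting values for the link-scale intercepts."""
    y = model.y
    spec = model.spec
    x0 = np.zeros(model.n_beta)
    if spec.family == "zoib":
        interior = y[model.interior]
        m = float(np.mean(interior)) if len(interior) else 0.5
        v = float(np.var(interior)) if len(interior) > 1 else 0.01
        v = max(v, 1e-4)
        phi0 = max(m * (1 - m) / v - 1.0, 0.5)
        x0[0] = _logit(m)
        x0[model.p] = np.log(phi0)
        k = 2
        if spec.zero_inflation:
            x0[k * model.p] = _logit(max(np.mean(model.is0), 1e-3))
            k += 1
        if spec.one_inflation:
            x0[k * model.p] = _logit(max(np.mean(model.is1), 1e-3))
    else:
        target = model._logy if spec.family == "lognormal" else y
        x0[0] = float(np.mean(target))
        x0[model.p] = float(np.log(max(np.std(target), 1e-3)))
    return x0


# ---------------------------------------------------------------------------
# backends


def _prepare(stat_table: pd.DataFrame, outcome: str, spec: ModelSpec, min_pairs: int = 20):
    """Extract the response column, dropping undefined/ineligible rows."""
    df = stat_table.copy()
    if outcome in ("rmssd", "ar1") and "n_pairs" in df.columns:
        df = df[df["n_pairs"] >= min_pairs]
    df = df.dropna(subset=[outcome])
    n_dropped = len(stat_table) - len(df)
    y = df[outcome].to_numpy(dtype=float)
    X, names = build_design(
        df["group"].to_numpy(),
        df["valence"].to_numpy() if spec.valence_effects and "valence" in df.columns else None,
        spec.valence_effects,
    )
    pids = pd.Categorical(df["participant_id"])
    iids = pd.Categorical(df["item"]) if "item" in df.columns else None
    return df, y, X, names, pids, iids, n_dropped


def fit_group_model(
    stat_table: pd.DataFrame,
    outcome: str,
    spec: ModelSpec | None = None,
    backend: str = "mcmc",
    seed: int = 0,
    chains: int = 3,
    warmup: int = 1000,
    draws: int = 1000,
    thin: int = 4,
    B: int = 2000,
    min_pairs: int = 20,
) -> PosteriorDraws:
    """Fit one outcome's group model and return draw-like replicates.

    ``stat_table`` needs columns participant_id, group, item, valence and
    the outcome.  Non-finite and lag-ineligible rows are dropped (counts
    recorded).  Backends: ``mcmc`` (default sizes: 3 chains, 1000 warmup,
    1000 retained each), ``map_laplace``, ``cluster_bootstrap``.
    """
    spec = spec or ModelSpec()
    df, y, X, names, pids, iids, n_dropped = _prepare(stat_table, outcome, spec, min_pairs)
    groups_per = df.groupby("group")["participant_id"].nunique()
    if (groups_per < 2).any() or len(groups_per) < 2:
        raise ValueError("need >= 2 participants per group")
    if n_dropped:
        logger.info("fit_group_model(%s): dropped %d undefined/ineligible rows", outcome, n_dropped)
    if spec.zero_inflation and not np.any(y == 0.0):
        logger.warning("fit_group_model(%s): no exact zeros; zero-inflation is prior-dominated", outcome)

    if backend == "cluster_bootstrap":
        result = _fit_bootstrap(df, y, X, names, spec, outcome, B=B, seed=seed)
    elif backend == "map_laplace":
        result = _fit_laplace(y, X, names, spec, seed=seed, n_draws=max(draws * chains, 2000))
    elif backend == "mcmc":
        result = _fit_mcmc(y, X, names, spec, pids, iids, seed=seed, chains=chains, warmup=warmup, draws=draws, thin=thin)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    result.n_dropped = n_dropped
    return result


def _fit_laplace(y, X, names, spec, seed=0, n_draws=3000) -> PosteriorDraws:
    model = _GroupModel(y, X, spec)
    res = _ml_fit(model)
    beta = res.x
    # dense Hessian by central differences of the analytic gradient
    n = len(beta)
    H = np.zeros((n, n))
    h = 1e-5
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        H[:, j] = (model.grad_beta(beta + e) - model.grad_beta(beta - e)) / (2 * h)
    H = -(H + H.T) / 2.0
    try:
        cov = np.linalg.inv(H)
        cov = (cov + cov.T) / 2.0
        evals, evecs = np.linalg.eigh(cov)
        cov = (evecs * np.clip(evals, 1e-10, None)) @ evecs.T
    except np.linalg.LinAlgError:
        cov = np.diag(np.full(n, 1e-4))
    rng = np.random.default_rng(seed)
    sample = rng.multivariate_normal(beta, cov, size=n_draws, method="eigh")
    draw_dict = _name_beta_draws(sample, spec, names)
    return PosteriorDraws(draw_dict, "map_laplace", spec, names, meta={"mode": beta, "converged_opt": bool(res.success)})


def _fit_bootstrap(df, y, X, names, spec, outcome, B=2000, seed=0) -> PosteriorDraws:
    model = _GroupModel(y, X, spec)
    full = _ml_fit(model)
    rng = np.random.default_rng(seed)
    pid_arr = df["participant_id"].to_numpy()
    group_of = df.groupby("participant_id")["group"].first()
    pids_by_group = {g: group_of[group_of == g].index.to_numpy() for g in ("likert", "vas")}
    row_idx_by_pid = {p: np.flatnonzero(pid_arr == p) for p in group_of.index}

    reps = []
    n_failed = 0
    for _ in range(B):
        rows = []
        for g, pids in pids_by_group.items():
            for p in pids[rng.integers(0, len(pids), size=len(pids))]:
                rows.append(row_idx_by_pid[p])
        rows = np.concatenate(rows)
        sub = _GroupModel(y[rows], X[rows], spec)
        try:
            res = _ml_fit(sub, x0=full.x)
            if not np.all(np.isfinite(res.x)):
                raise FloatingPointError
            reps.append(res.x)
        except (FloatingPointError, ValueError):
            n_failed += 1
    if n_failed:
        logger.warning("cluster bootstrap: %d/%d replicates failed", n_failed, B)
    sample = np.array(reps)
    draw_dict = _name_beta_draws(sample, spec, names)
    return PosteriorDraws(
        draw_dict, "cluster_bootstrap", spec, names,
        meta={"point": full.x, "n_failed": n_failed},
    )


def _name_beta_draws(sample: np.ndarray, spec: ModelSpec, names: list[str]) -> dict:
    p = len(names)
    out = {}
    for k, block in enumerate(spec.param_blocks):
        for j, nm in enumerate(names):
            out[f"b_{block}[{nm}]"] = sample[:, k * p + j]
    return out


# -- MCMC backend -----------------------------------------------------------


def _fit_mcmc(y, X, names, spec, pids, iids, seed=0, chains=3, warmup=1000, draws=1000, thin=4) -> PosteriorDraws:
    import arviz as az

    use_p = "participant" in spec.random_effects
    use_i = "item" in spec.random_effects and iids is not None
    pid_idx = np.asarray(pids.codes) if use_p else None
    iid_idx = np.asarray(iids.codes) if use_i else None
    n_p = len(pids.categories) if use_p else 0
    n_i = len(iids.categories) if use_i else 0
    model = _GroupModel(y, X, spec, pid_idx, iid_idx, n_p, n_i)
    ml = _ml_fit(model)

    # per-cluster covariate values, for the interweaving moves: a fixed
    # effect that is constant within clusters trades off against the mean
    # of that cluster's random intercepts, so we resample the shared shift
    # from its exact (Gaussian) conditional to break the ridge
    sweeps = []
    col = {nm: k for k, nm in enumerate(names)}
    if use_p:
        sweeps.append(("p", col["intercept"], np.ones(n_p)))
        grp = np.zeros(n_p)
        grp[pid_idx] = X[:, col["scale_vas"]]
        sweeps.append(("p", col["scale_vas"], grp))
    if use_i:
        sweeps.append(("i", col["intercept"], np.ones(n_i)))
        if "valence" in col:
            vi = np.zeros(n_i)
            vi[iid_idx] = X[:, col["valence"]]
            sweeps.append(("i", col["valence"], vi))

    rng_master = np.random.default_rng(seed)
    chain_draws = []
    for c in range(chains):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        chain_draws.append(_run_chain(model, ml.x, spec, rng, warmup, draws, sweeps, thin))

    names_out = list(chain_draws[0].keys())
    stacked = {k: np.stack([cd[k] for cd in chain_draws]) for k in names_out}  # (chains, draws)
    diag_rows = []
    for k, arr in stacked.items():
        diag_rows.append(
            {
                "param": k,
                "rhat": float(az.rhat(arr)),
                "ess_bulk": float(az.ess(arr)),
                "ess_tail": float(az.ess(arr, method="tail")),
            }
        )
    diagnostics = pd.DataFrame(diag_rows).set_index("param")
    converged = bool((diagnostics["rhat"] < 1.02).all() and (diagnostics[["ess_bulk", "ess_tail"]] > 500).all().all())
    if not converged:
        logger.warning("mcmc backend: convergence diagnostics outside thresholds (rhat<1.02, ess>500)")
    flat = {k: arr.reshape(-1) for k, arr in stacked.items()}
    return PosteriorDraws(flat, "mcmc", spec, names, diagnostics=diagnostics, converged=converged)


def _run_chain(model: _GroupModel, beta_init, spec, rng, warmup, draws, sweeps=(), thin: int = 1) -> dict:
    n_beta = model.n_beta
    beta = beta_init + rng.normal(0, 0.05, size=n_beta)
    z_p = np.zeros(model.n_p)
    z_i = np.zeros(model.n_i)
    log_sd_p = np.log(0.2) if model.n_p else None
    log_sd_i = np.log(0.2) if model.n_i else None
    prior_var = spec.prior_scale**2

    def z_offset():
        off = 0.0
        if model.n_p:
            off = off + z_p[model.pid_idx]
        if model.n_i:
            off = off + z_i[model.iid_idx]
        return off

    rows = model.loglik_rows(beta, z_offset())
    total = rows.sum()

    s_beta = np.full(n_beta, 0.05)
    s_zp, s_zi, s_sdp, s_sdi = 0.2, 0.2, 0.3, 0.3

    out = {f"{k}": np.empty(draws) for k in _beta_names_internal(spec, model.p)}
    if model.n_p:
        out["sd_participant"] = np.empty(draws)
    if model.n_i:
        out["sd_item"] = np.empty(draws)

    def adapt(s, acc, it, target=0.44):
        return s * np.exp((acc - target) / (1 + it * 0.02) ** 0.6 * 0.5)

    n_iter = warmup + draws * thin
    for it in range(n_iter):
        adapting = it < warmup
        # fixed effects, elementwise random-walk
        for j in range(n_beta):
            prop = beta.copy()
            prop[j] += rng.normal(0, s_beta[j])
            rows_p = model.loglik_rows(prop, z_offset())
            tp = rows_p.sum()
            lr = (tp - total) + (beta[j] ** 2 - prop[j] ** 2) / (2 * prior_var)
            acc = np.log(rng.random()) < lr
            if acc:
                beta, rows, total = prop, rows_p, tp
            if adapting:
                s_beta[j] = adapt(s_beta[j], float(acc), it)
        # participant intercepts, vectorized elementwise
        if model.n_p:
            z_prop = z_p + rng.normal(0, s_zp, size=model.n_p)
            off_prop = z_prop[model.pid_idx] + (z_i[model.iid_idx] if model.n_i else 0.0)
            rows_p = model.loglik_rows(beta, off_prop)
            cur_by = np.bincount(model.pid_idx, weights=rows, minlength=model.n_p)
            prop_by = np.bincount(model.pid_idx, weights=rows_p, minlength=model.n_p)
            sd2 = np.exp(2 * log_sd_p)
            lr = (prop_by - cur_by) + (z_p**2 - z_prop**2) / (2 * sd2)
            acc = np.log(rng.random(model.n_p)) < lr
            z_p = np.where(acc, z_prop, z_p)
            accepted_rows = acc[model.pid_idx]
            rows = np.where(accepted_rows, rows_p, rows)
            # mixed acceptance invalidates cached rows where both z_p and z_i enter;
            # recompute exactly to avoid drift
            rows = model.loglik_rows(beta, z_offset())
            total = rows.sum()
            if adapting:
                s_zp = adapt(s_zp, float(acc.mean()), it)
            # RE sd: depends only on z and hyperprior
            lsd_prop = log_sd_p + rng.normal(0, s_sdp)
            lr = _re_sd_logpost(z_p, lsd_prop, spec.re_sd_prior_scale) - _re_sd_logpost(z_p, log_sd_p, spec.re_sd_prior_scale)
            acc_s = np.log(rng.random()) < lr
            if acc_s:
                log_sd_p = lsd_prop
            if adapting:
                s_sdp = adapt(s_sdp, float(acc_s), it)
        # item intercepts
        if model.n_i:
            z_prop = z_i + rng.normal(0, s_zi, size=model.n_i)
            off_prop = z_prop[model.iid_idx] + (z_p[model.pid_idx] if model.n_p else 0.0)
            rows_p = model.loglik_rows(beta, off_prop)
            cur_by = np.bincount(model.iid_idx, weights=rows, minlength=model.n_i)
            prop_by = np.bincount(model.iid_idx, weights=rows_p, minlength=model.n_i)
            sd2 = np.exp(2 * log_sd_i)
            lr = (prop_by - cur_by) + (z_i**2 - z_prop**2) / (2 * sd2)
            acc = np.log(rng.random(model.n_i)) < lr
            z_i = np.where(acc, z_prop, z_i)
            rows = model.loglik_rows(beta, z_offset())
            total = rows.sum()
            if adapting:
                s_zi = adapt(s_zi, float(acc.mean()), it)
            lsd_prop = log_sd_i + rng.normal(0, s_sdi)
            lr = _re_sd_logpost(z_i, lsd_prop, spec.re_sd_prior_scale) - _re_sd_logpost(z_i, log_sd_i, spec.re_sd_prior_scale)
            acc_s = np.log(rng.random()) < lr
            if acc_s:
                log_sd_i = lsd_prop
            if adapting:
                s_sdi = adapt(s_sdi, float(acc_s), it)
        # interweaving: exchange a shared shift between each cluster-constant
        # coefficient and its random-intercept block (likelihood-invariant,
        # exact Gaussian conditional under the priors)
        for block, j, w in sweeps:
            if block == "p":
                z, sd = z_p, np.exp(log_sd_p)
            else:
                z, sd = z_i, np.exp(log_sd_i)
            prec = (w @ w) / sd**2 + 1.0 / prior_var
            mean = ((w @ z) / sd**2 - beta[j] / prior_var) / prec
            delta = rng.normal(mean, 1.0 / np.sqrt(prec))
            beta[j] += delta
            if block == "p":
                z_p = z_p - delta * w
            else:
                z_i = z_i - delta * w
        if not adapting and (it - warmup) % thin == thin - 1:
            d = (it - warmup) // thin
            for j, nm in enumerate(_beta_names_internal(spec, model.p)):
                out[nm][d] = beta[j]
            if model.n_p:
                out["sd_participant"][d] = np.exp(log_sd_p)
            if model.n_i:
                out["sd_item"][d] = np.exp(log_sd_i)
    return out


def _beta_names_internal(spec: ModelSpec, p: int) -> list[str]:
    base = ["intercept", "scale_vas", "valence", "scale_x_valence"][:p]
    return [f"b_{block}[{nm}]" for block in spec.param_blocks for nm in base]


def _re_sd_logpost(z, log_sd, prior_scale):
    sd = np.exp(log_sd)
    return (
        -len(z) * log_sd
        - np.sum(z**2) / (2 * sd**2)
        - sd**2 / (2 * prior_scale**2)
        + log_sd  # Jacobian of the log transform (half-normal prior on sd)
    )


# ---------------------------------------------------------------------------
# estimated marginal means


@dataclass
class EMMSummary:
    """Median and 90% HDI of the EMM per group plus their difference."""

    table: pd.DataFrame  # rows: likert, vas, difference
    outcome: str = ""
    quantity: str = "mean"


def emm_draws(post: PosteriorDraws, group: str, quantity: str = "mean") -> np.ndarray:
    """Per-draw estimated marginal response for one group.

    Conditions random effects at zero and averages the response-scale
    expectation over the two valence levels (effects coding).  ``quantity``:
    'mean' (response expectation; zoib: (1-pi0-pi1)*mu + pi1; lognormal:
    exp(location) i.e. the median), 'variance' (response variance), or
    'pi0'/'pi1' (inflation probabilities, zoib only).
    """
    spec = post.spec
    names = post.design_columns
    scale = 1.0 if group == "vas" else 0.0
    valence_levels = [1.0, -1.0] if "valence" in names else [0.0]

    def design_point(v):
        x = {"intercept": 1.0, "scale_vas": scale, "valence": v, "scale_x_valence": scale * v}
        return np.array([x[nm] for nm in names])

    acc = None
    for v in valence_levels:
        x = design_point(v)
        eta = {}
        for block in spec.param_blocks:
            try:
                cols = [post.draws[f"b_{block}[{nm}]"] for nm in names]
            except KeyError as exc:
                raise ValueError(f"draws missing parameter {exc}") from exc
            eta[block] = np.column_stack(cols) @ x
        if spec.family == "zoib":
            mu = _expit(eta["mu"])
            phi = np.exp(eta["disp"])
            pi0 = _expit(eta["pi0"]) if "pi0" in eta else 0.0
            pi1 = _expit(eta["pi1"]) if "pi1" in eta else 0.0
            if quantity == "mean":
                val = (1.0 - pi0 - pi1) * mu + pi1
            elif quantity == "variance":
                val = mu * (1.0 - mu) / (1.0 + phi)
            elif quantity == "pi0":
                val = pi0 if np.ndim(pi0) else np.full(post.n_draws, pi0)
            elif quantity == "pi1":
                val = pi1 if np.ndim(pi1) else np.full(post.n_draws, pi1)
            else:
                raise ValueError(f"unknown quantity {quantity!r}")
        elif spec.family == "gaussian":
            if quantity == "mean":
                val = eta["mu"]
            elif quantity == "variance":
                val = np.exp(2 * eta["disp"])
            else:
                raise ValueError(f"quantity {quantity!r} undefined for gaussian family")
        else:  # lognormal: report the median response exp(location)
            if quantity == "mean":
                val = np.exp(eta["mu"])
            elif quantity == "variance":
                s2 = np.exp(2 * eta["disp"])
                val = (np.exp(s2) - 1.0) * np.exp(2 * eta["mu"] + s2)
            else:
                raise ValueError(f"quantity {quantity!r} undefined for lognormal family")
        acc = val if acc is None else acc + val
    return acc / len(valence_levels)


def emm_summary(post: PosteriorDraws, outcome: str = "", quantity: str = "mean", mass: float = 0.90) -> EMMSummary:
    """EMM medians with 90% HDIs for both groups and the VAS-Likert gap."""
    lik = emm_draws(post, "likert", quantity)
    vas = emm_draws(post, "vas", quantity)
    diff = vas - lik
    rows = []
    for name, d in (("likert", lik), ("vas", vas), ("difference", diff)):
        lo, hi = hdi(d, mass)
        rows.append({"component": name, "median": float(np.median(d)), "hdi_low": lo, "hdi_high": hi})
    return EMMSummary(pd.DataFrame(rows).set_index("component"), outcome=outcome, quantity=quantity)


# ---------------------------------------------------------------------------
# criterion correlations


@dataclass
class CriterionResult:
    """Per-item correlations with a baseline criterion, by group."""

    per_item: pd.DataFrame  # rows item x group with r
    avg_abs: pd.DataFrame  # per group: median/HDI of avg |r| replicates
    difference: pd.DataFrame  # VAS - Likert avg |r|: median/HDI
    criterion: str = ""


def criterion_correlations(
    item_means: pd.DataFrame,
    criteria: pd.Series,
    groups: pd.Series,
    B: int = 2000,
    seed: int = 0,
    mass: float = 0.90,
) -> CriterionResult:
    """Correlate per-person item means with one baseline criterion, by group.

    ``item_means``: participants x items; ``criteria``: one score per
    participant; ``groups``: 'likert'/'vas' per participant.  Within each
    group both sides are z-scored, so each item's regression slope equals
    the Pearson r.  Uncertainty by participant-level bootstrap; the
    difference column is avg|r|_VAS - avg|r|_Likert per replicate.
    """
    common = item_means.index.intersection(criteria.dropna().index)
    item_means = item_means.loc[common]
    criteria = criteria.loc[common]
    groups = groups.loc[common]
    rng = np.random.default_rng(seed)

    def group_r(idx) -> np.ndarray:
        xm = item_means.loc[idx].to_numpy(dtype=float)
        c = criteria.loc[idx].to_numpy(dtype=float)
        if np.std(c) == 0 or len(idx) < 3:
            return np.full(item_means.shape[1], np.nan)
        zc = (c - c.mean()) / c.std(ddof=0)
        zm = (xm - xm.mean(axis=0)) / np.where(xm.std(axis=0, ddof=0) == 0, np.nan, xm.std(axis=0, ddof=0))
        return (zm * zc[:, None]).mean(axis=0)

    idx_by_group = {g: groups[groups == g].index.to_numpy() for g in ("likert", "vas")}
    for g, idx in idx_by_group.items():
        if len(idx) < 3:
            raise ValueError(f"group {g} has fewer than 3 participants with criterion scores")

    obs = {g: group_r(idx) for g, idx in idx_by_group.items()}
    per_item = pd.DataFrame(obs, index=item_means.columns)

    reps = {g: np.empty(B) for g in idx_by_group}
    for b in range(B):
        for g, idx in idx_by_group.items():
            draw = idx[rng.integers(0, len(idx), size=len(idx))]
            r = group_r(draw)
            ok = np.isfinite(r)
            reps[g][b] = np.mean(np.abs(r[ok])) if ok.any() else np.nan
    diff = reps["vas"] - reps["likert"]

    def summarize(x):
        ok = x[np.isfinite(x)]
        if len(ok) < 100:
            return {"median": np.nan, "hdi_low": np.nan, "hdi_high": np.nan}
        lo, hi = hdi(ok, mass)
        return {"median": float(np.median(ok)), "hdi_low": lo, "hdi_high": hi}

    def observed_avg(r):
        ok = np.isfinite(r)
        return float(np.mean(np.abs(r[ok]))) if ok.any() else np.nan

    avg_abs = pd.DataFrame(
        {g: {**summarize(reps[g]), "observed": observed_avg(obs[g])} for g in reps}
    ).T
    difference = pd.DataFrame([summarize(diff)], index=["vas_minus_likert"])
    return CriterionResult(per_item, avg_abs, difference)
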