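"""Hierarchical ordered logistic model with cyclist-specific thresholds.

The flat cumulative-logit model assumes one set of attention thresholds
for everyone.  Here the thresholds of cyclist ``j`` on trial ``i`` are

    gamma_kj = gamma_k + sum_q alpha_q z_qij + B_j,

a common shift of both cut points by the trial's eye-movement covariates
(lane-fixation share, pupil-diameter CV) plus a zero-mean cyclist random
effect ``B_j ~ Normal(0, 1/tau)``.  Category probabilities follow the
usual differenced logistic CDFs with linear predictor
``theta_ij = sum_p beta_p x_pij``.

Estimation is Bayesian: vague Normal(0, 10^3) priors on ``gamma_k``,
``beta_p`` and ``alpha_q`` and a Gamma(0.01, 0.01) prior on the
precision ``tau``.  The sampler is Metropolis-within-Gibbs —
adaptive random-walk Metropolis updates for the fixed effects and the
``B_j`` block (per-cyclist acceptance, exploiting the factorized
likelihood) and a conjugate Gibbs draw for ``tau`` given ``B``:
``tau | B ~ Gamma(a0 + J/2, b0 + sum B_j^2 / 2)``.

Point summaries are posterior means with posterior SDs; Wald-style
statistics ``(mean/SD)^2`` are included for report parity with the flat
model's table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ologit import ModelSpec, build_design, cumlogit_logprobs, wald_inference

__all__ = [
    "HierData",
    "HierParams",
    "Priors",
    "HierFit",
    "prepare_hier_data",
    "hier_loglik",
    "fit_hier_mcmc",
    "threshold_for_cyclist",
    "predict_category_hier",
]


@dataclass(frozen=True)
class Priors:
    """Vague BUGS-style priors: Normal(0, sigma^2) on the fixed effects,
    Gamma(shape, rate) on the random-effect precision."""

    fixed_var: float = 1e3
    tau_shape: float = 0.01
    tau_rate: float = 0.01


@dataclass
class HierData:
    """Model-ready arrays extracted from a trial table."""

    y: np.ndarray            # 1-based levels
    X: np.ndarray            # (n, P) factor dummies
    Z: np.ndarray            # (n, Q) threshold covariates
    groups: np.ndarray       # (n,) 0-based cyclist codes
    cyclists: np.ndarray     # original cyclist labels, index = code
    x_names: list
    z_names: list
    K: int

    @property
    def J(self) -> int:
        return len(self.cyclists)


def prepare_hier_data(trials: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> HierData:
    y, X, names = build_design(trials, spec)
    missing = [c for c in spec.covariates if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks threshold covariates: {missing}")
    Z = trials[list(spec.covariates)].to_numpy(dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("threshold covariates contain missing values")
    codes, cyclists = pd.factorize(trials[spec.group_col], sort=True)
    if len(cyclists) < 2:
        raise ValueError("hierarchical model needs at least two cyclists")
    return HierData(y=y, X=X, Z=Z, groups=codes, cyclists=np.asarray(cyclists),
                    x_names=names, z_names=list(spec.covariates), K=int(y.max()))


@dataclass
class HierParams:
    gamma: np.ndarray        # (K-1,), strictly increasing
    beta: np.ndarray         # (P,)
    alpha: np.ndarray        # (Q,)
    b: np.ndarray            # (J,)
    tau: float


def _trial_logprobs(params: HierParams, data: HierData) -> np.ndarray:
    shift = data.Z @ params.alpha + params.b[data.groups]
    eta = data.X @ params.beta if data.X.shape[1] else np.zeros(len(data.y))
    gammas = params.gamma[None, :] + shift[:, None]
    return cumlogit_logprobs(gammas, eta)


def hier_loglik(params: HierParams, data: HierData) -> float:
    """Log-likelihood of the trial levels under the hierarchical model.

    Returns ``-inf`` (rather than raising) when a category probability
    underflows to zero after differencing, so samplers can reject.
    """
    if not np.all(np.diff(params.gamma) > 0):
        return -np.inf
    lp = _trial_logprobs(params, data)
    picked = lp[np.arange(len(data.y)), data.y - 1]
    if not np.isfinite(picked).all():
        return -np.inf
    return float(picked.sum())


def _loglik_by_cyclist(params: HierParams, data: HierData) -> np.ndarray:
    lp = _trial_logprobs(params, data)
    picked = lp[np.arange(len(data.y)), data.y - 1]
    picked = np.where(np.isfinite(picked), picked, -np.inf)
    out = np.full(data.J, 0.0)
    np.add.at(out, data.groups, picked)
    return out


@dataclass
class HierFit:
    draws: dict                     # name -> (n_chains, n_draws[, dim]) arrays
    data: HierData
    spec: ModelSpec
    priors: Priors
    accept_rates: dict
    n_warmup: int
    seed: int

    def _flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    @property
    def param_names(self) -> list:
        names = [f"threshold[{k+1}]" for k in range(self.data.K - 1)]
        names += self.data.x_names + self.data.z_names + ["tau"]
        return names

    def _stacked(self) -> tuple[np.ndarray, list]:
        cols = [self._flat("gamma"), self._flat("beta"), self._flat("alpha"),
                self._flat("tau")[:, None]]
        return np.concatenate(cols, axis=1), self.param_names

    def posterior_mean(self) -> HierParams:
        return HierParams(
            gamma=self._flat("gamma").mean(axis=0),
            beta=self._flat("beta").mean(axis=0),
            alpha=self._flat("alpha").mean(axis=0),
            b=self._flat("b").mean(axis=0),
            tau=float(self._flat("tau").mean()),
        )

    def summary(self) -> pd.DataFrame:
        """Posterior means/SDs with 95% intervals, Wald-style parity
        statistics, and (when >1 chain) split-chain R-hat and ESS."""
        mat, names = self._stacked()
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        lo, hi = np.quantile(mat, [0.025, 0.975], axis=0)
        tab = wald_inference(mean, sd)
        tab.index = names
        tab = tab.rename(columns={"ci_lower": "norm_ci_lower",
                                  "ci_upper": "norm_ci_upper"})
        tab["q2.5"] = lo
        tab["q97.5"] = hi
        diag = self.diagnostics()
        tab["rhat"] = diag["rhat"].reindex(names).to_numpy()
        tab["ess"] = diag["ess"].reindex(names).to_numpy()
        return tab

    def diagnostics(self) -> pd.DataFrame:
        import arviz as az

        mat_names = self.param_names
        post = {
            "gamma": self.draws["gamma"],
            "beta": self.draws["beta"],
            "alpha": self.draws["alpha"],
            "tau": self.draws["tau"],
        }
        idata = az.from_dict(posterior=post)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rows = {}
        k = self.data.K - 1
        for i in range(k):
            rows[mat_names[i]] = (float(rhat["gamma"][i]), float(ess["gamma"][i]))
        for i, nm in enumerate(self.data.x_names):
            rows[nm] = (float(rhat["beta"][i]), float(ess["beta"][i]))
        for i, nm in enumerate(self.data.z_names):
            rows[nm] = (float(rhat["alpha"][i]), float(ess["alpha"][i]))
        rows["tau"] = (float(rhat["tau"]), float(ess["tau"]))
        out = pd.DataFrame(rows, index=["rhat", "ess"]).T
        bad = out[out["rhat"] > 1.1]
        if len(bad):
            warnings.warn(f"chains may not have converged: R-hat > 1.1 for "
                          f"{list(bad.index)}")
        return out

    def draws_frame(self) -> pd.DataFrame:
        """One row per retained draw (all chains stacked)."""
        mat, names = self._stacked()
        df = pd.DataFrame(mat, columns=names)
        b = self._flat("b")
        for i, c in enumerate(self.data.cyclists):
            df[f"B[{c}]"] = b[:, i]
        return df


def fit_hier_mcmc(
    trials: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    n_iter: int = 5000,
    n_warmup: int = 5000,
    seed: int = 0,
    n_chains: int = 4,
    priors: Priors = Priors(),
    target_accept: float = 0.35,
) -> HierFit:
    """Posterior sampling for the hierarchical ordered logistic model.

    Runs ``n_chains`` independent chains (seeded by spawning from
    ``seed``) of ``n_warmup`` adaptation iterations followed by
    ``n_iter`` retained iterations.  Step sizes adapt toward
    ``target_accept`` (mid 0.25-0.45 band) during warmup only, keeping
    the retained chain Markovian.  Fully reproducible given
    ``(seed, n_chains)``.
    """
    data = prepare_hier_data(trials, spec)
    if len(np.unique(data.y)) < 2:
        raise ValueError("degenerate response: all trials in one category")
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = [_run_chain(data, priors, n_iter, n_warmup,
                         np.random.default_rng(s), target_accept)
              for s in seeds]
    draws = {k: np.stack([c[0][k] for c in chains]) for k in chains[0][0]}
    acc = {k: float(np.mean([c[1][k] for c in chains])) for k in chains[0][1]}
    return HierFit(draws=draws, data=data, spec=spec, priors=priors,
                   accept_rates=acc, n_warmup=n_warmup, seed=seed)


def _draw_tau(b: np.ndarray, priors: Priors, rng: np.random.Generator) -> float:
    """Conjugate Gibbs draw: tau | B ~ Gamma(a0 + J/2, b0 + sum(B^2)/2)."""
    shape = priors.tau_shape + len(b) / 2.0
    rate = priors.tau_rate + float(b @ b) / 2.0
    return float(rng.gamma(shape, 1.0 / rate))


def _run_chain(data, priors, n_iter, n_warmup, rng, target_accept):
    km1, P, Q, J = data.K - 1, data.X.shape[1], data.Z.shape[1], data.J
    xbar = data.X.mean(axis=0) if P else np.empty(0)
    zbar = data.Z.mean(axis=0)
    # empirical cumulative-logit start for the thresholds, centred on the
    # mean covariate shift so the initial likelihood is finite and sane
    counts = np.bincount(data.y, minlength=data.K + 1)[1:]
    cum = np.clip(np.cumsum(counts)[:-1] / len(data.y), 0.01, 0.99)
    g0 = np.log(cum / (1 - cum))
    state = HierParams(
        gamma=g0.astype(float), beta=np.zeros(P), alpha=np.zeros(Q),
        b=np.zeros(J), tau=1.0,
    )
    fixed_var = priors.fixed_var

    names = ([("gamma", k) for k in range(km1)]
             + [("beta", p) for p in range(P)]
             + [("alpha", q) for q in range(Q)])
    # translation moves along the weakly identified ridges: shift a
    # coefficient and compensate both thresholds so the likelihood only
    # feels the centred part of the covariate
    trans = ([("t_beta", p) for p in range(P)]
             + [("t_alpha", q) for q in range(Q)] + [("t_b", 0)])
    steps = {nm: 0.2 for nm in names} | {nm: 0.3 for nm in trans}
    step_b = 0.3
    acc_ct = {nm: 0 for nm in names + trans} | {"b": 0}
    prop_ct = {nm: 0 for nm in names + trans} | {"b": 0}
    win_acc = {nm: 0 for nm in names + trans} | {"b": 0}
    win_n = 50

    cur_ll = hier_loglik(state, data)
    if not np.isfinite(cur_ll):
        raise RuntimeError("initial state has zero likelihood")

    total = n_warmup + n_iter
    out = {
        "gamma": np.empty((n_iter, km1)), "beta": np.empty((n_iter, P)),
        "alpha": np.empty((n_iter, Q)), "b": np.empty((n_iter, J)),
        "tau": np.empty(n_iter),
    }

    def vec(name):
        return getattr(state, name)

    for it in range(total):
        for nm in names:
            block, idx = nm
            arr = vec(block)
            old = arr[idx]
            new = old + steps[nm] * rng.normal()
            arr[idx] = new
            if block == "gamma" and not np.all(np.diff(state.gamma) > 0):
                arr[idx] = old  # outside the ordered support
                prop_ct[nm] += 1
                continue
            new_ll = hier_loglik(state, data)
            dprior = (old * old - new * new) / (2.0 * fixed_var)
            if np.log(rng.random()) < (new_ll - cur_ll + dprior):
                cur_ll = new_ll
                acc_ct[nm] += 1
                win_acc[nm] += 1
            else:
                arr[idx] = old
            prop_ct[nm] += 1

        # random-effect block: per-cyclist accept, likelihood factorizes
        ll_j = _loglik_by_cyclist(state, data)
        b_old = state.b.copy()
        state.b = b_old + step_b * rng.normal(size=J)
        ll_j_new = _loglik_by_cyclist(state, data)
        dprior = state.tau * (b_old**2 - state.b**2) / 2.0
        accept = np.log(rng.random(J)) < (ll_j_new - ll_j + dprior)
        state.b = np.where(accept, state.b, b_old)
        cur_ll = hier_loglik(state, data)
        acc_ct["b"] += int(accept.sum())
        win_acc["b"] += int(accept.sum())
        prop_ct["b"] += J

        # ridge translation moves
        for nm in trans:
            kind, idx = nm
            delta = steps[nm] * rng.normal()
            g_old = state.gamma.copy()
            if kind == "t_b":
                # gamma -> gamma - delta, B -> B + delta: likelihood exact-
                # invariant, only the priors move
                b_old2 = state.b
                g_new = g_old - delta
                dlp = ((g_old**2 - g_new**2).sum() / (2.0 * fixed_var)
                       - state.tau / 2.0
                       * float(((b_old2 + delta) ** 2 - b_old2**2).sum()))
                if np.log(rng.random()) < dlp:
                    state.gamma = g_new
                    state.b = b_old2 + delta
                    acc_ct[nm] += 1
                    win_acc[nm] += 1
                prop_ct[nm] += 1
                continue
            if kind == "t_beta":
                arr, mean = state.beta, xbar[idx]
                g_new = g_old + delta * mean
            else:
                arr, mean = state.alpha, zbar[idx]
                g_new = g_old - delta * mean
            old = arr[idx]
            arr[idx] = old + delta
            state.gamma = g_new
            new_ll = hier_loglik(state, data)
            dprior = ((old**2 - arr[idx] ** 2) / (2.0 * fixed_var)
                      + (g_old**2 - g_new**2).sum() / (2.0 * fixed_var))
            if np.log(rng.random()) < (new_ll - cur_ll + dprior):
                cur_ll = new_ll
                acc_ct[nm] += 1
                win_acc[nm] += 1
            else:
                arr[idx] = old
                state.gamma = g_old
            prop_ct[nm] += 1

        # conjugate Gibbs update for tau | B
        state.tau = _draw_tau(state.b, priors, rng)

        if it < n_warmup and (it + 1) % win_n == 0:
            for nm in names + trans:
                rate = win_acc[nm] / win_n
                steps[nm] = float(np.clip(
                    steps[nm] * np.exp(rate - target_accept), 1e-3, 10.0))
                win_acc[nm] = 0
            rate_b = win_acc["b"] / (win_n * J)
            step_b = float(np.clip(step_b * np.exp(rate_b - target_accept),
                                   1e-3, 10.0))
            win_acc["b"] = 0

        if it >= n_warmup:
            i = it - n_warmup
            out["gamma"][i] = state.gamma
            out["beta"][i] = state.beta
            out["alpha"][i] = state.alpha
            out["b"][i] = state.b
            out["tau"][i] = state.tau

    acc = {"/".join(map(str, nm)): acc_ct[nm] / prop_ct[nm]
           for nm in names + trans}
    acc["b"] = acc_ct["b"] / prop_ct["b"]
    return out, acc


def threshold_for_cyclist(fit: HierFit, cyclist, z) -> pd.DataFrame:
    """Posterior summary of cyclist ``j``'s thresholds at covariates ``z``.

    Per draw, ``gamma_kj = gamma_k + z @ alpha + B_j``; the spacing
    between adjacent thresholds is the common-shift invariant (identical
    in every draw to the spacing of the base thresholds).
    """
    idx = np.flatnonzero(fit.data.cyclists == cyclist)
    if len(idx) == 0:
        raise KeyError(f"cyclist {cyclist!r} not in fit")
    j = int(idx[0])
    z = np.asarray(z, dtype=float)
    g = fit._flat("gamma")
    shift = fit._flat("alpha") @ z + fit._flat("b")[:, j]
    gkj = g + shift[:, None]
    lo, hi = np.quantile(gkj, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {"mean": gkj.mean(axis=0), "sd": gkj.std(axis=0, ddof=1),
         "q2.5": lo, "q97.5": hi},
        index=[f"threshold[{k+1}]" for k in range(gkj.shape[1])],
    )


def predict_category_hier(fit: HierFit, trials: pd.DataFrame):
    """Plug-in modal prediction at the posterior means.

    Trials of cyclists present in the fit use their posterior-mean
    ``B_j``; unseen cyclists fall back to ``B_j = 0`` with a warning.
    Returns ``(levels, probs)``.
    """
    pm = fit.posterior_mean()
    y, X, names = build_design(trials, fit.spec)
    if names != fit.data.x_names:
        raise ValueError(f"factor levels {names} do not match fit "
                         f"{fit.data.x_names}")
    Z = trials[list(fit.spec.covariates)].to_numpy(dtype=float)
    code = pd.Series(np.arange(fit.data.J), index=fit.data.cyclists)
    labels = trials[fit.spec.group_col]
    known = labels.isin(code.index).to_numpy()
    if not known.all():
        warnings.warn("unseen cyclist(s): random effect set to 0")
    b = np.zeros(len(trials))
    b[known] = pm.b[code[labels[known]].to_numpy()]
    shift = Z @ pm.alpha + b
    eta = X @ pm.beta if X.shape[1] else np.zeros(len(trials))
    gammas = pm.gamma[None, :] + shift[:, None]
    probs = np.exp(cumlogit_logprobs(gammas, eta))
    return probs.argmax(axis=1) + 1, probs
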