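"""The ensemble of individual analysis strategies.

Each strategy S pairs an optional treatment (propensity) model with an
adjustment mechanism (inverse probability weighting, 1:1 caliper matching,
propensity-score stratification) or an outcome model (Cox regression with
main effects or all two-way interactions, penalised Cox, parametric
Weibull, random forest or gradient boosting on the pseudo-outcome scale).
Every fitted strategy exposes

* ``predict(X, t)``  — predictions m̂_S(t, x) on the pseudo-outcome scale,
  used for cross-validated scoring against the pseudo-observations;
* ``counterfactuals(X)`` — m̂_S(0, x) and m̂_S(1, x) for every patient;
* ``ate(...)`` — the strategy's average-treatment-effect estimate, a
  contrast of the counterfactual means on the configured estimand scale.

ML outcome models regress pseudo-observations (a continuous, complete-data
target) rather than the raw censored times, so that all strategies are
comparable on one prediction scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from .survival import estimand_from_means

__all__ = [
    "StrategySpec",
    "PairwiseData",
    "FittedStrategy",
    "StrategyFailedError",
    "BalanceReport",
    "fit_propensity",
    "fit_strategy",
    "balance_report",
    "default_roster",
    "reduced_roster",
]

logger = logging.getLogger(__name__)

TREATMENT_MODELS = (
    "none", "logistic", "logistic_stepwise", "logistic_penalised",
    "random_forest", "gradient_boosting",
)
ADJUSTMENTS = ("none", "ipw", "matching", "stratification")
OUTCOME_MODELS = (
    "none", "arm_means", "cox_main_effects", "cox_two_way", "penalised_cox",
    "parametric_survival", "random_forest", "gradient_boosting",
)

PS_CLIP = (0.01, 0.99)


class StrategyFailedError(RuntimeError):
    """A strategy did not converge; it is dropped from averaging."""


@dataclass
class StrategySpec:
    name: str
    treatment_model: str = "none"
    adjustment: str = "none"
    outcome_model: str = "none"
    per_arm: bool = False
    hyperparameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.treatment_model not in TREATMENT_MODELS:
            raise ValueError(f"{self.name}: unknown treatment_model {self.treatment_model!r}")
        if self.adjustment not in ADJUSTMENTS:
            raise ValueError(f"{self.name}: unknown adjustment {self.adjustment!r}")
        if self.outcome_model not in OUTCOME_MODELS:
            raise ValueError(f"{self.name}: unknown outcome_model {self.outcome_model!r}")
        if self.treatment_model == "none" and self.outcome_model == "none":
            raise ValueError(f"{self.name}: need a treatment or an outcome model")
        if self.adjustment != "none" and self.treatment_model == "none":
            raise ValueError(f"{self.name}: adjustment requires a treatment model")
        if self.adjustment != "none" and self.outcome_model not in ("none", "arm_means"):
            raise ValueError(
                f"{self.name}: propensity adjustment combined with a non-trivial "
                "outcome model is not supported"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PairwiseData:
    """Two-arm analysis slice: covariates, 0/1 treatment, pseudo-outcomes."""

    X: pd.DataFrame
    treatment: np.ndarray
    pseudo: np.ndarray
    time: np.ndarray
    event: np.ndarray
    functional: str = "cumhaz"
    t0: float = 3.2

    def __post_init__(self) -> None:
        self.treatment = np.asarray(self.treatment, dtype=int)
        self.pseudo = np.asarray(self.pseudo, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.X = self.X.reset_index(drop=True)
        self.X.attrs = {}

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "PairwiseData":
        idx = np.asarray(idx)
        return PairwiseData(
            X=self.X.iloc[idx],
            treatment=self.treatment[idx],
            pseudo=self.pseudo[idx],
            time=self.time[idx],
            event=self.event[idx],
            functional=self.functional,
            t0=self.t0,
        )


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def design_matrix(X: pd.DataFrame, interactions: bool = False) -> pd.DataFrame:
    """One-hot (reference-coded) model matrix, optionally with all pairwise
    products of its columns (no self-products)."""
    M = pd.get_dummies(X, drop_first=True).astype(float)
    # drop constant columns: they carry no information and break some fits
    keep = M.columns[M.std(axis=0) > 0]
    M = M[keep]
    if interactions:
        cols = list(M.columns)
        inter = {}
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                inter[f"{a}:{b}"] = M[a].to_numpy() * M[b].to_numpy()
        if inter:
            I = pd.DataFrame(inter, index=M.index)
            I = I.loc[:, I.std(axis=0) > 0]
            M = pd.concat([M, I], axis=1)
    return M


def _standardize(M: pd.DataFrame):
    mu = M.mean(axis=0)
    sd = M.std(axis=0).replace(0.0, 1.0)
    return (M - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# Propensity models
# ---------------------------------------------------------------------------

class PropensityModel:
    """Fitted treatment model producing scores e(x) in (0,1)."""

    def __init__(self, kind, predictor, columns):
        self.kind = kind
        self._predictor = predictor
        self.columns = columns

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        M = design_matrix(X).reindex(columns=self.columns, fill_value=0.0)
        return np.clip(self._predictor(M), *PS_CLIP)


def fit_propensity(
    model: str,
    X: pd.DataFrame,
    treatment: np.ndarray,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> PropensityModel:
    """Fit the requested treatment model on a two-arm slice.

    Stepwise logistic uses forward selection with likelihood-ratio entry /
    stay thresholds (default 0.05/0.05); penalised logistic uses an
    elastic-net with internally cross-validated penalty; tree ensembles use
    the given seed.  Degenerate fits fall back to the treated fraction.
    """
    hp = hyperparameters or {}
    treatment = np.asarray(treatment, dtype=int)
    M = design_matrix(X)
    frac = float(np.mean(treatment))

    if M.shape[1] == 0 or frac in (0.0, 1.0):
        return PropensityModel(model, lambda Mn: np.full(len(Mn), frac), M.columns)

    if model == "logistic":
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(penalty=None, max_iter=5000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(M.to_numpy(), treatment)
        return PropensityModel(
            model, lambda Mn: clf.predict_proba(Mn.to_numpy())[:, 1], M.columns
        )

    if model == "logistic_stepwise":
        cols = _forward_stepwise(M, treatment, hp.get("slentry", 0.05), hp.get("slstay", 0.05))
        from sklearn.linear_model import LogisticRegression

        if not cols:
            return PropensityModel(model, lambda Mn: np.full(len(Mn), frac), M.columns)
        clf = LogisticRegression(penalty=None, max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(M[cols].to_numpy(), treatment)
        sel = list(cols)
        return PropensityModel(
            model, lambda Mn: clf.predict_proba(Mn[sel].to_numpy())[:, 1], M.columns
        )

    if model == "logistic_penalised":
        from sklearn.linear_model import LogisticRegressionCV

        S, mu, sd = _standardize(M)
        clf = LogisticRegressionCV(
            Cs=hp.get("Cs", 8),
            cv=hp.get("cv", 5),
            penalty="elasticnet",
            solver="saga",
            l1_ratios=[hp.get("l1_ratio", 0.5)],
            max_iter=hp.get("max_iter", 500),
            tol=1e-3,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(S.to_numpy(), treatment)
        cols, mu_, sd_ = M.columns, mu, sd
        return PropensityModel(
            model,
            lambda Mn: clf.predict_proba(((Mn - mu_) / sd_).to_numpy())[:, 1],
            cols,
        )

    if model == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200),
            min_samples_leaf=hp.get("min_samples_leaf", 25),
            random_state=seed,
            n_jobs=1,
        )
        clf.fit(M.to_numpy(), treatment)
        return PropensityModel(
            model, lambda Mn: clf.predict_proba(Mn.to_numpy())[:, 1], M.columns
        )

    if model == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingClassifier

        clf = GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 2),
            learning_rate=hp.get("learning_rate", 0.1),
            random_state=seed,
        )
        clf.fit(M.to_numpy(), treatment)
        return PropensityModel(
            model, lambda Mn: clf.predict_proba(Mn.to_numpy())[:, 1], M.columns
        )

    raise ValueError(f"unknown treatment model {model!r}")


def _forward_stepwise(M: pd.DataFrame, y: np.ndarray, slentry: float, slstay: float) -> list:
    """Forward selection by likelihood-ratio test, with a stay check."""
    import statsmodels.api as sm
    from scipy import stats

    def loglik(cols):
        Xd = sm.add_constant(M[cols].to_numpy()) if cols else np.ones((len(M), 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            return res.llf
        except Exception:  # noqa: BLE001 - separation etc.
            return None

    selected: list[str] = []
    ll_cur = loglik(selected)
    remaining = list(M.columns)
    while remaining:
        best, best_ll, best_p = None, None, 1.0
        for c in remaining:
            ll = loglik(selected + [c])
            if ll is None or ll_cur is None:
                continue
            p = stats.chi2.sf(2.0 * max(ll - ll_cur, 0.0), df=1)
            if p < best_p:
                best, best_ll, best_p = c, ll, p
        if best is None or best_p >= slentry:
            break
        selected.append(best)
        remaining.remove(best)
        ll_cur = best_ll
        # stay check: drop any term whose removal is no longer significant
        for c in list(selected[:-1]):
            rest = [s for s in selected if s != c]
            ll_rest = loglik(rest)
            if ll_rest is not None and stats.chi2.sf(2.0 * max(ll_cur - ll_rest, 0.0), 1) >= slstay:
                selected.remove(c)
                remaining.append(c)
                ll_cur = ll_rest
    return selected


# ---------------------------------------------------------------------------
# Fitted strategies
# ---------------------------------------------------------------------------

class FittedStrategy:
    """Uniform surface over all strategy families."""

    def __init__(self, spec, predictor, propensity=None, info=None):
        self.spec = spec
        self._predictor = predictor  # callable (X, t) -> values
        self.propensity = propensity
        self.info = info or {}

    def predict(self, X: pd.DataFrame, t: np.ndarray) -> np.ndarray:
        return self._predictor(X, np.asarray(t, dtype=int))

    def counterfactuals(self, X: pd.DataFrame):
        n = len(X)
        return (
            self._predictor(X, np.zeros(n, dtype=int)),
            self._predictor(X, np.ones(n, dtype=int)),
        )

    def ate(self, X: pd.DataFrame, functional: str) -> float:
        """Contrast of counterfactual means on the estimand scale.

        For the cumulative-hazard functional, per-patient predictions are
        marginalised on the survival scale (g-formula standardisation,
        S̄_t = mean_x exp(−m̂(t,x))) before the −log ratio, so that outcome
        models target the same marginal restricted hazard ratio as the
        Kaplan-Meier-based strategies; for constant predictions the two
        computations coincide.
        """
        m0, m1 = self.counterfactuals(X)
        if functional == "cumhaz":
            s0 = float(np.clip(np.mean(np.exp(-np.asarray(m0))), 1e-12, 1 - 1e-12))
            s1 = float(np.clip(np.mean(np.exp(-np.asarray(m1))), 1e-12, 1 - 1e-12))
            return float(np.log(s1) / np.log(s0))
        return estimand_from_means(float(np.mean(m0)), float(np.mean(m1)), functional)


def _hajek_means(pseudo, treatment, weights):
    mus = []
    for t in (0, 1):
        m = treatment == t
        if weights[m].sum() <= 0 or m.sum() == 0:
            raise StrategyFailedError("empty arm after weighting")
        mus.append(float(np.sum(weights[m] * pseudo[m]) / np.sum(weights[m])))
    return mus


def _const_predictor(mu0, mu1):
    return lambda X, t: np.where(np.asarray(t) == 1, mu1, mu0).astype(float)


def ipw_ate(data: PairwiseData, scores: np.ndarray, spec: StrategySpec) -> FittedStrategy:
    """Hájek (normalised) inverse-probability-of-treatment weighting.

    ATE weights w = T/e + (1−T)/(1−e), truncated at their 99th percentile.
    """
    e = np.clip(scores, *PS_CLIP)
    w = np.where(data.treatment == 1, 1.0 / e, 1.0 / (1.0 - e))
    cap = np.quantile(w, 0.99)
    n_trunc = int(np.sum(w > cap))
    if n_trunc:
        logger.info("%s: truncated %d extreme IPW weights at %.3g", spec.name, n_trunc, cap)
    w = np.minimum(w, cap)
    mu0, mu1 = _hajek_means(data.pseudo, data.treatment, w)
    return FittedStrategy(
        spec, _const_predictor(mu0, mu1), propensity=e, info={"weights_truncated": n_trunc}
    )


def stratified_ate(
    data: PairwiseData, prop_model: PropensityModel, spec: StrategySpec, n_strata: int = 5
) -> FittedStrategy:
    """Propensity-score stratification with quantile strata.

    Within-stratum arm contrasts are combined with stratum-size (ATE)
    weights; strata lacking one arm are merged with their neighbour.
    """
    scores = prop_model.scores(data.X)
    qs = np.quantile(scores, np.linspace(0, 1, n_strata + 1)[1:-1])
    bounds = np.unique(qs)
    strata = np.searchsorted(bounds, scores, side="right")
    n_s = len(bounds) + 1
    if n_s < 2 and n_strata > 1:
        # constant scores: a single stratum, the unadjusted contrast
        logger.info("%s: constant propensity scores; single stratum", spec.name)

    # merge strata missing an arm into their lower neighbour
    groups = list(range(n_s))
    merged = True
    while merged:
        merged = False
        for g in sorted(set(groups)):
            m = np.isin(strata, [i for i in range(n_s) if groups[i] == g])
            if m.sum() == 0:
                continue
            if len(np.unique(data.treatment[m])) < 2:
                neighbours = [h for h in sorted(set(groups)) if h != g]
                if not neighbours:
                    raise StrategyFailedError("no stratum contains both arms")
                tgt = max([h for h in neighbours if h < g], default=min(neighbours))
                for i in range(n_s):
                    if groups[i] == g:
                        groups[i] = tgt
                logger.info("%s: merged single-arm stratum %d into %d", spec.name, g, tgt)
                merged = True
                break

    labels = sorted(set(groups))
    if len(labels) < 1:
        raise StrategyFailedError("stratification produced no usable strata")
    means = {}
    sizes = {}
    for g in list(labels):
        m = np.isin(strata, [i for i in range(n_s) if groups[i] == g])
        if m.sum() == 0:
            labels.remove(g)
            continue
        mu0 = float(np.mean(data.pseudo[m & (data.treatment == 0)]))
        mu1 = float(np.mean(data.pseudo[m & (data.treatment == 1)]))
        means[g] = (mu0, mu1)
        sizes[g] = int(m.sum())

    # any stratum index whose group ended up empty maps to the nearest kept one
    groups = [
        g if g in means else min(means, key=lambda kk: abs(kk - i))
        for i, g in enumerate(groups)
    ]
    group_of = np.asarray(groups)

    def predictor(Xn, t):
        s = np.searchsorted(bounds, prop_model.scores(Xn), side="right")
        g = group_of[s]
        out = np.empty(len(Xn))
        for gg in labels:
            mm = g == gg
            if mm.any():
                out[mm] = np.where(np.asarray(t)[mm] == 1, means[gg][1], means[gg][0])
        return out

    return FittedStrategy(
        spec, predictor, propensity=np.clip(scores, *PS_CLIP),
        info={"n_strata_used": len(labels)},
    )


def matched_ate(
    data: PairwiseData, scores: np.ndarray, spec: StrategySpec, seed: int = 0
) -> FittedStrategy:
    """1:1 nearest-neighbour matching on the logit propensity score.

    Caliper 0.2·SD(logit score), without replacement, treated processed in
    seeded random order.  The ATE is the arm contrast within the matched set.
    """
    e = np.clip(scores, *PS_CLIP)
    logit = special.logit(e)
    sd = float(np.std(logit))
    caliper = 0.2 * sd if sd > 0 else np.inf
    rng = np.random.default_rng(seed)
    t_idx = np.flatnonzero(data.treatment == 1)
    c_idx = np.flatnonzero(data.treatment == 0)
    if len(t_idx) == 0 or len(c_idx) == 0:
        raise StrategyFailedError("matching requires both arms")
    order = rng.permutation(len(t_idx))
    c_order = np.argsort(logit[c_idx], kind="stable")
    keys = logit[c_idx][c_order]
    ids = c_idx[c_order]
    used = np.zeros(len(keys), dtype=bool)
    pairs = []
    unmatched = 0
    for ti in t_idx[order]:
        target = logit[ti]
        pos = int(np.searchsorted(keys, target))
        left, right = pos - 1, pos
        while left >= 0 and used[left]:
            left -= 1
        while right < len(keys) and used[right]:
            right += 1
        best, best_d = None, np.inf
        if left >= 0 and abs(keys[left] - target) < best_d:
            best, best_d = left, abs(keys[left] - target)
        if right < len(keys) and abs(keys[right] - target) < best_d:
            best, best_d = right, abs(keys[right] - target)
        if best is not None and best_d <= caliper:
            used[best] = True
            pairs.append((ti, int(ids[best])))
        else:
            unmatched += 1
    if not pairs:
        raise StrategyFailedError("no matches within caliper")
    if unmatched:
        logger.info("%s: %d treated left unmatched by the caliper", spec.name, unmatched)
    mu1 = float(np.mean(data.pseudo[[a for a, _ in pairs]]))
    mu0 = float(np.mean(data.pseudo[[b for _, b in pairs]]))
    return FittedStrategy(
        spec, _const_predictor(mu0, mu1), propensity=e,
        info={"n_pairs": len(pairs), "n_unmatched_treated": unmatched, "caliper": caliper},
    )


# ---------------------------------------------------------------------------
# Outcome models
# ---------------------------------------------------------------------------

def _functional_from_cumhaz(H: np.ndarray, functional: str):
    """Convert a per-patient cumulative hazard at t0 (or a survival curve)
    to the pseudo-outcome scale."""
    if functional == "cumhaz":
        return np.maximum(H, 1e-10)
    if functional == "binary":
        return 1.0 - np.exp(-H)
    raise ValueError(functional)


def _cox_strategy(data: PairwiseData, spec: StrategySpec, seed: int) -> FittedStrategy:
    from lifelines import CoxPHFitter

    interactions = spec.outcome_model == "cox_two_way"
    penal = spec.hyperparameters.get(
        "penalizer", 0.1 if spec.outcome_model == "penalised_cox" else 1e-8
    )
    tx_inter = spec.hyperparameters.get("treatment_interactions", True)

    def build(M, t=None):
        out = M.copy()
        if t is not None:
            out["_tx"] = np.asarray(t, dtype=float)
            if interactions and tx_inter:
                for c in M.columns:
                    out[f"_tx:{c}"] = out["_tx"].to_numpy() * M[c].to_numpy()
        return out

    def fit_one(idx, with_tx):
        M = design_matrix(data.X.iloc[idx], interactions=interactions)
        df = build(M, data.treatment[idx] if with_tx else None)
        df["_time"] = data.time[idx]
        df["_event"] = data.event[idx]
        cph = CoxPHFitter(penalizer=penal)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # noqa: BLE001
            raise StrategyFailedError(f"{spec.name}: Cox fit failed ({exc})") from exc
        return cph, M.columns

    def make_eval(cph, cols, with_tx):
        bch = cph.baseline_cumulative_hazard_.iloc[:, 0]
        grid, h0 = bch.index.to_numpy(float), bch.to_numpy(float)
        j0 = np.searchsorted(grid, data.t0, side="right") - 1
        H0_t0 = h0[j0] if j0 >= 0 else 0.0

        def ev(Xn, t):
            M = design_matrix(Xn, interactions=interactions).reindex(
                columns=cols, fill_value=0.0
            )
            df = build(M, t if with_tx else None)
            lp = cph.predict_log_partial_hazard(df).to_numpy()
            if data.functional == "rmst":
                # integrate exp(-H0(t)·e^lp) stepwise to t0
                knots = np.concatenate(([0.0], grid[(grid > 0) & (grid < data.t0)], [data.t0]))
                knots = np.unique(knots)
                jj = np.searchsorted(grid, knots[:-1], side="right") - 1
                h_seg = np.where(jj >= 0, h0[np.clip(jj, 0, len(h0) - 1)], 0.0)
                seg = np.diff(knots)
                out = np.zeros(len(M))
                for s in range(0, len(M), 512):
                    e = min(s + 512, len(M))
                    out[s:e] = np.sum(
                        seg[None, :] * np.exp(-h_seg[None, :] * np.exp(lp[s:e, None])),
                        axis=1,
                    )
                return out
            H = H0_t0 * np.exp(lp)
            return _functional_from_cumhaz(H, data.functional)

        return ev

    if spec.per_arm:
        evals = {}
        for t in (0, 1):
            idx = np.flatnonzero(data.treatment == t)
            cph, cols = fit_one(idx, with_tx=False)
            evals[t] = make_eval(cph, cols, with_tx=False)

        def predictor(Xn, t):
            t = np.asarray(t, dtype=int)
            out = np.empty(len(Xn))
            for tt in (0, 1):
                m = t == tt
                if m.any():
                    out[m] = evals[tt](Xn.iloc[np.flatnonzero(m)], None)
            return out

        return FittedStrategy(spec, predictor)

    cph, cols = fit_one(np.arange(len(data)), with_tx=True)
    ev = make_eval(cph, cols, with_tx=True)
    return FittedStrategy(spec, lambda Xn, t: ev(Xn, np.asarray(t, dtype=float)))


def _weibull_strategy(data: PairwiseData, spec: StrategySpec) -> FittedStrategy:
    from lifelines import WeibullAFTFitter

    def fit_one(idx, with_tx):
        M = design_matrix(data.X.iloc[idx])
        df = M.copy()
        if with_tx:
            df["_tx"] = data.treatment[idx].astype(float)
        df["_time"] = np.maximum(data.time[idx], 1e-6)
        df["_event"] = data.event[idx]
        aft = WeibullAFTFitter(penalizer=spec.hyperparameters.get("penalizer", 1e-6))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aft.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # noqa: BLE001
            raise StrategyFailedError(f"{spec.name}: Weibull fit failed ({exc})") from exc
        return aft, M.columns

    def make_eval(aft, cols, with_tx):
        def ev(Xn, t):
            M = design_matrix(Xn).reindex(columns=cols, fill_value=0.0)
            df = M.copy()
            if with_tx:
                df["_tx"] = np.asarray(t, dtype=float)
            params = aft.params_
            rho = float(np.exp(params.loc[("rho_", "Intercept")]))
            lam_cols = params.loc["lambda_"]
            lp = np.full(len(df), float(lam_cols.get("Intercept", 0.0)))
            for c in df.columns:
                if c in lam_cols.index:
                    lp += float(lam_cols[c]) * df[c].to_numpy(float)
            lam = np.exp(lp)
            H = (data.t0 / lam) ** rho
            if data.functional == "rmst":
                k = 1.0 / rho
                c = lam ** (-rho)
                return (
                    special.gamma(k)
                    * special.gammainc(k, c * data.t0**rho)
                    / (rho * c**k)
                )
            return _functional_from_cumhaz(H, data.functional)

        return ev

    if spec.per_arm:
        evals = {}
        for t in (0, 1):
            idx = np.flatnonzero(data.treatment == t)
            aft, cols = fit_one(idx, with_tx=False)
            evals[t] = make_eval(aft, cols, with_tx=False)

        def predictor(Xn, t):
            t = np.asarray(t, dtype=int)
            out = np.empty(len(Xn))
            for tt in (0, 1):
                m = t == tt
                if m.any():
                    out[m] = evals[tt](Xn.iloc[np.flatnonzero(m)], None)
            return out

        return FittedStrategy(spec, predictor)

    aft, cols = fit_one(np.arange(len(data)), with_tx=True)
    ev = make_eval(aft, cols, with_tx=True)
    return FittedStrategy(spec, lambda Xn, t: ev(Xn, t))


def _ml_outcome_strategy(data: PairwiseData, spec: StrategySpec, seed: int) -> FittedStrategy:
    from sklearn.ensemble import (
        GradientBoostingRegressor,
        RandomForestRegressor,
    )

    hp = spec.hyperparameters

    def make_model():
        if spec.outcome_model == "random_forest":
            return RandomForestRegressor(
                n_estimators=hp.get("n_estimators", 200),
                min_samples_leaf=hp.get("min_samples_leaf", 25),
                random_state=seed,
                n_jobs=1,
            )
        return GradientBoostingRegressor(
            n_estimators=hp.get("n_estimators", 100),
            max_depth=hp.get("max_depth", 2),
            learning_rate=hp.get("learning_rate", 0.1),
            random_state=seed,
        )

    if spec.per_arm:
        models = {}
        cols = design_matrix(data.X).columns
        for t in (0, 1):
            idx = np.flatnonzero(data.treatment == t)
            M = design_matrix(data.X.iloc[idx]).reindex(columns=cols, fill_value=0.0)
            mdl = make_model()
            mdl.fit(M.to_numpy(), data.pseudo[idx])
            models[t] = mdl

        def predictor(Xn, t):
            M = design_matrix(Xn).reindex(columns=cols, fill_value=0.0).to_numpy()
            t = np.asarray(t, dtype=int)
            out = np.empty(len(M))
            for tt in (0, 1):
                m = t == tt
                if m.any():
                    out[m] = models[tt].predict(M[m])
            return out

        return FittedStrategy(spec, predictor)

    cols = design_matrix(data.X).columns
    M = design_matrix(data.X).reindex(columns=cols, fill_value=0.0)
    Z = np.column_stack([M.to_numpy(), data.treatment.astype(float)])
    mdl = make_model()
    mdl.fit(Z, data.pseudo)

    def predictor(Xn, t):
        Mn = design_matrix(Xn).reindex(columns=cols, fill_value=0.0).to_numpy()
        Zn = np.column_stack([Mn, np.asarray(t, dtype=float)])
        return mdl.predict(Zn)

    return FittedStrategy(spec, predictor)


def _arm_means_strategy(data: PairwiseData, spec: StrategySpec) -> FittedStrategy:
    mu0 = float(np.mean(data.pseudo[data.treatment == 0]))
    mu1 = float(np.mean(data.pseudo[data.treatment == 1]))
    return FittedStrategy(spec, _const_predictor(mu0, mu1))


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def fit_strategy(spec: StrategySpec, data: PairwiseData, seed: int = 0) -> FittedStrategy:
    """Fit one analysis strategy on a two-arm slice.

    Raises :class:`StrategyFailedError` on non-convergence; the averaging
    engine drops and logs failed strategies.
    """
    spec.validate()
    if len(np.unique(data.treatment)) < 2:
        raise StrategyFailedError(f"{spec.name}: both arms required")

    if spec.adjustment != "none":
        prop = fit_propensity(
            spec.treatment_model, data.X, data.treatment, seed, spec.hyperparameters
        )
        if spec.adjustment == "ipw":
            return ipw_ate(data, prop.scores(data.X), spec)
        if spec.adjustment == "matching":
            return matched_ate(data, prop.scores(data.X), spec, seed=seed)
        return stratified_ate(
            data, prop, spec, n_strata=spec.hyperparameters.get("n_strata", 5)
        )

    om = spec.outcome_model
    if om == "arm_means":
        return _arm_means_strategy(data, spec)
    if om in ("cox_main_effects", "cox_two_way", "penalised_cox"):
        return _cox_strategy(data, spec, seed)
    if om == "parametric_survival":
        return _weibull_strategy(data, spec)
    if om in ("random_forest", "gradient_boosting"):
        return _ml_outcome_strategy(data, spec, seed)
    raise ValueError(f"{spec.name}: nothing to fit")


def strategy_ate(fs: FittedStrategy, data: PairwiseData) -> float:
    """ATE of a fitted strategy on the configured estimand scale."""
    return fs.ate(data.X, data.functional)


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    table: pd.DataFrame  # covariate, smd, variance_ratio, flags
    asam: float

    def out_of_range(self) -> pd.DataFrame:
        return self.table[self.table["flag_smd"] | self.table["flag_vr"]]


def balance_report(
    X: pd.DataFrame,
    treatment: np.ndarray,
    weights: np.ndarray | None = None,
    smd_limit: float = 0.25,
    vr_limits: tuple = (0.5, 2.0),
) -> BalanceReport:
    """Standardised differences and variance ratios per covariate.

    Continuous: d = (x̄₁−x̄₀)/√((s₁²+s₀²)/2); binary (and one-hot levels):
    d = (p₁−p₀)/√((p₁(1−p₁)+p₀(1−p₀))/2).  Acceptable ranges: |d| < 0.25,
    variance ratio in [0.5, 2.0].  ASAM is the mean |d|.
    """
    treatment = np.asarray(treatment, dtype=int)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    M = pd.get_dummies(X).astype(float)  # all levels for categorical balance
    binary = {
        c: set(np.unique(M[c].to_numpy())) <= {0.0, 1.0} for c in M.columns
    }

    rows = []
    for c in M.columns:
        x = M[c].to_numpy()
        stats = {}
        for t in (0, 1):
            m = treatment == t
            wm = w[m]
            mu = float(np.sum(wm * x[m]) / np.sum(wm))
            if binary[c]:
                var = mu * (1.0 - mu)
            else:
                var = float(np.sum(wm * (x[m] - mu) ** 2) / np.sum(wm))
            stats[t] = (mu, var)
        (mu0, v0), (mu1, v1) = stats[0], stats[1]
        pooled = np.sqrt((v0 + v1) / 2.0)
        if pooled == 0.0:
            d = 0.0 if np.isclose(mu0, mu1) else np.inf
        else:
            d = (mu1 - mu0) / pooled
        vr = v1 / v0 if v0 > 0 else np.inf
        rows.append(
            {
                "covariate": c,
                "smd": d,
                "variance_ratio": vr,
                "flag_smd": not abs(d) < smd_limit,
                "flag_vr": not vr_limits[0] <= vr <= vr_limits[1],
            }
        )
    table = pd.DataFrame(rows)
    finite = table["smd"].replace([np.inf, -np.inf], np.nan).dropna()
    asam = float(finite.abs().mean()) if len(finite) else 0.0
    return BalanceReport(table=table, asam=asam)


# ---------------------------------------------------------------------------
# Rosters
# ---------------------------------------------------------------------------

def default_roster() -> list:
    """The full strategy set: propensity mechanisms crossed with treatment
    models, plus direct outcome regressions."""
    return [
        StrategySpec("unadjusted", outcome_model="arm_means"),
        StrategySpec("ipw_logistic", "logistic", "ipw"),
        StrategySpec("ipw_logistic_stepwise", "logistic_stepwise", "ipw"),
        StrategySpec("ipw_logistic_penalised", "logistic_penalised", "ipw"),
        StrategySpec("ipw_random_forest", "random_forest", "ipw"),
        StrategySpec("ipw_gradient_boosting", "gradient_boosting", "ipw"),
        StrategySpec("match_logistic", "logistic", "matching"),
        StrategySpec("strat_logistic", "logistic", "stratification"),
        StrategySpec("cox_main_effects", outcome_model="cox_main_effects"),
        StrategySpec("cox_two_way", outcome_model="cox_two_way"),
        StrategySpec("cox_penalised", outcome_model="penalised_cox"),
        StrategySpec("weibull_per_arm", outcome_model="parametric_survival", per_arm=True),
        StrategySpec("rf_outcome", outcome_model="random_forest"),
        StrategySpec("gbm_outcome", outcome_model="gradient_boosting"),
    ]


def reduced_roster() -> list:
    """Small roster for simulation studies: unadjusted contrast, IPW with
    plain logistic scores, Cox main effects, gradient-boosted outcome."""
    return [
        StrategySpec("unadjusted", outcome_model="arm_means"),
        StrategySpec("ipw_logistic", "logistic", "ipw"),
        StrategySpec("cox_main_effects", outcome_model="cox_main_effects"),
        StrategySpec("gbm_outcome", outcome_model="gradient_boosting"),
    ]
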