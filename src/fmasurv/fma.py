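"""Frequentist model averaging of causal treatment-effect estimators.

Every analysis strategy S in the roster produces an ATE estimate and
cross-validated factual predictions m̂_S^(−i)(T_i, x_i).  Its support from
the data is scored by the cross-validated mean squared prediction error

    CvMSPE(S) = (N₀+N₁)⁻¹ [ Σ_{i∈arm0} (Y_i − m̂_S^(−i)(0,x_i))²
                          + Σ_{i∈arm1} (Y_i − m̂_S^(−i)(1,x_i))² ],

with Y_i the (pseudo-)outcome.  Larger CvMSPE means poorer support and a
smaller weight.  The default weight map is a scaled softmax,

    w_S ∝ exp(−N·(CvMSPE_S − min CvMSPE)/(2·min CvMSPE)),

which degenerates to best-model selection as N grows and to uniform
weights under ties; inverse-CvMSPE and top-1 rules are selectable.  The
FMA estimate is the weighted mean of strategy ATEs (on the log scale for
ratio estimands) and its confidence interval comes from a percentile
bootstrap that re-runs the whole pipeline — pseudo-observations,
cross-validation, weights — on each within-arm resample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .survival import pseudo_observations, estimand_from_means
from .strategies import (
    PairwiseData,
    StrategySpec,
    StrategyFailedError,
    fit_strategy,
    strategy_ate,
    default_roster,
)

__all__ = [
    "AnalysisConfig",
    "StrategyScore",
    "FMAResult",
    "crossval_factual_predictions",
    "cvmspe",
    "fma_weights",
    "fma_estimate",
    "bootstrap_ci",
    "run_pairwise_analysis",
    "report_forest",
]

logger = logging.getLogger(__name__)

_RATIO_ESTIMANDS = ("rhr", "odds_ratio")
_FUNCTIONAL_OF = {"rmst_diff": "rmst", "rhr": "cumhaz", "odds_ratio": "binary"}
_NON_COVARIATE_COLUMNS = {"patient_id", "arm", "time_years", "event", "censor_reason"}


@dataclass
class AnalysisConfig:
    reference_arm: str
    comparator_arm: str
    estimand: str = "rhr"  # rmst_diff | rhr | odds_ratio
    t0: float = 3.2
    n_folds: int = 10
    n_bootstrap: int = 500
    seed: int = 0
    strategy_roster: list = field(default_factory=default_roster)
    weight_rule: str = "scaled_softmax"  # | inverse | best
    pseudo_method: str = "jackknife"  # | covariate_adjusted
    covariate_columns: list | None = None  # default: all non-identifier columns
    bootstrap_max_failure_rate: float = 0.20

    def __post_init__(self) -> None:
        self.strategy_roster = [
            StrategySpec(**s) if isinstance(s, dict) else s for s in self.strategy_roster
        ]

    def validate(self) -> None:
        if self.estimand not in _FUNCTIONAL_OF:
            raise ValueError(f"unknown estimand {self.estimand!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        if self.reference_arm == self.comparator_arm:
            raise ValueError("reference and comparator arms must differ")
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")
        for s in self.strategy_roster:
            s.validate()

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StrategyScore:
    name: str
    cvmspe: float
    weight: float
    ate: float
    converged: bool = True
    failure: str | None = None


@dataclass
class FMAResult:
    estimand: str
    t0: float
    fma_ate: float
    best_model_ate: float
    best_model: str
    ci_lower: float | None
    ci_upper: float | None
    per_strategy: list
    n0: int
    n1: int
    reference_arm: str
    comparator_arm: str
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_strategy"] = [asdict(s) if not isinstance(s, dict) else s for s in self.per_strategy]
        return d

    def to_json(self, path=None, **kw) -> str:
        payload = {"schema_version": 1, **self.to_dict()}
        text = json.dumps(payload, sort_keys=True, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Cross-validated scoring
# ---------------------------------------------------------------------------

def crossval_factual_predictions(
    spec: StrategySpec, data: PairwiseData, n_folds: int, seed: int,
    fold_seed: int | None = None,
) -> np.ndarray:
    """Out-of-fold factual predictions m̂_S^(−i)(T_i, x_i).

    Folds are stratified by arm; within each fold the strategy — both its
    treatment and outcome components — is refit on the complement and
    evaluated on the held-out patients under their factual arm.  K-fold
    approximates the leave-one-out superscript; pass n_folds = n for exact
    leave-one-out on small samples.  ``fold_seed`` fixes the partition
    separately from the model seed so that competing strategies can be
    scored on identical folds (a paired comparison).
    """
    from sklearn.model_selection import StratifiedKFold

    n = len(data)
    n_folds = min(n_folds, int(np.bincount(data.treatment).min()))
    if n_folds < 2:
        raise ValueError("not enough patients per arm for cross-validation")
    fold_seed = seed if fold_seed is None else fold_seed
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    preds = np.full(n, np.nan)
    for train, test in skf.split(np.zeros(n), data.treatment):
        fs = fit_strategy(spec, data.subset(train), seed=seed)
        preds[test] = fs.predict(data.X.iloc[test], data.treatment[test])
    if np.any(np.isnan(preds)):
        raise StrategyFailedError(f"{spec.name}: missing out-of-fold predictions")
    return preds


def cvmspe(pseudo: np.ndarray, factual_predictions: np.ndarray, treatment=None) -> float:
    """Cross-validated mean squared prediction error of factual predictions."""
    pseudo = np.asarray(pseudo, dtype=float)
    preds = np.asarray(factual_predictions, dtype=float)
    if pseudo.shape != preds.shape:
        raise ValueError("pseudo-outcomes and predictions must align")
    return float(np.mean((pseudo - preds) ** 2))


# ---------------------------------------------------------------------------
# Weights and averaging
# ---------------------------------------------------------------------------

def fma_weights(scores, n_total: int, rule: str = "scaled_softmax") -> np.ndarray:
    """Support weights from CvMSPE scores: nonnegative, summing to 1,
    monotone non-increasing in CvMSPE."""
    c = np.asarray(scores, dtype=float)
    if c.size == 0:
        raise ValueError("empty strategy roster")
    if np.any(~np.isfinite(c)) or np.any(c < 0):
        raise ValueError("CvMSPE scores must be finite and nonnegative")
    cmin = float(c.min())
    if rule == "best":
        w = (c == cmin).astype(float)
    elif rule == "inverse":
        if cmin == 0:
            w = (c == 0).astype(float)
        else:
            w = 1.0 / c
    elif rule == "scaled_softmax":
        if cmin == 0:
            w = (c == 0).astype(float)
        else:
            z = -n_total * (c - cmin) / (2.0 * cmin)
            w = np.exp(np.maximum(z, -700.0))
    else:
        raise ValueError(f"unknown weight rule {rule!r}")
    return w / w.sum()


def fma_estimate(ates, weights, estimand: str):
    """Weighted mean of strategy ATEs; ratio estimands on the log scale.

    Returns (fma_ate, best_model_index is the caller's concern)."""
    ates = np.asarray(ates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if ates.size == 0:
        raise ValueError("no converged strategies to average")
    if estimand in _RATIO_ESTIMANDS:
        return float(np.exp(np.sum(weights * np.log(ates))))
    return float(np.sum(weights * ates))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _prepare_pairwise(cohort: pd.DataFrame, config: AnalysisConfig) -> PairwiseData:
    from .cohort import impute_region

    sub = cohort[cohort["arm"].isin([config.reference_arm, config.comparator_arm])]
    for arm in (config.reference_arm, config.comparator_arm):
        if not (sub["arm"] == arm).any():
            raise ValueError(f"arm {arm!r} not present in cohort")
    if "region" in sub.columns:
        sub = impute_region(sub)
    treatment = (sub["arm"] == config.comparator_arm).astype(int).to_numpy()
    if config.covariate_columns is None:
        covs = [c for c in sub.columns if c not in _NON_COVARIATE_COLUMNS]
    else:
        covs = [c for c in config.covariate_columns if c in sub.columns]
    X = sub[covs].reset_index(drop=True)
    time = sub["time_years"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=int)
    functional = _FUNCTIONAL_OF[config.estimand]

    if functional == "binary":
        known = ((event == 1) & (time <= config.t0)) | (time >= config.t0)
        X, treatment = X.iloc[np.flatnonzero(known)], treatment[known]
        time, event = time[known], event[known]

    data = PairwiseData(
        X=X, treatment=treatment, pseudo=np.zeros(len(X)),
        time=time, event=event, functional=functional, t0=config.t0,
    )
    data.pseudo = _pseudo_by_arm(data, config)
    return data


def _pseudo_by_arm(data: PairwiseData, config: AnalysisConfig) -> np.ndarray:
    """Pseudo-observations computed within each arm so that each arm's
    pseudo mean equals its own KM functional."""
    out = np.empty(len(data))
    for t in (0, 1):
        m = data.treatment == t
        pv = pseudo_observations(
            data.time[m],
            data.event[m],
            functional=data.functional,
            t0=config.t0,
            method=config.pseudo_method,
            covariates=data.X.iloc[np.flatnonzero(m)] if config.pseudo_method == "covariate_adjusted" else None,
        )
        out[m] = pv.values
    return out


def _score_roster(data: PairwiseData, config: AnalysisConfig, seed: int):
    """Fit + cross-validate every strategy; returns per-strategy records."""
    records = []
    for k, spec in enumerate(config.strategy_roster):
        s_seed = (seed + 104729 * (k + 1)) % (2**31 - 1)
        try:
            fs = fit_strategy(spec, data, seed=s_seed)
            ate = strategy_ate(fs, data)
            preds = crossval_factual_predictions(
                spec, data, config.n_folds, s_seed, fold_seed=seed % (2**31 - 1)
            )
            score = cvmspe(data.pseudo, preds)
            records.append(
                {"spec": spec, "ate": ate, "cvmspe": score, "converged": True, "failure": None}
            )
        except (StrategyFailedError, np.linalg.LinAlgError) as exc:
            logger.warning("strategy %s failed: %s", spec.name, exc)
            records.append(
                {"spec": spec, "ate": np.nan, "cvmspe": np.nan, "converged": False,
                 "failure": str(exc)}
            )
    return records


def _combine(records, n_total: int, config: AnalysisConfig):
    ok = [r for r in records if r["converged"]]
    if not ok:
        raise RuntimeError("all strategies failed")
    w = fma_weights([r["cvmspe"] for r in ok], n_total, config.weight_rule)
    fma = fma_estimate([r["ate"] for r in ok], w, config.estimand)
    best = min(ok, key=lambda r: r["cvmspe"])
    wi = iter(w)
    scores = [
        StrategyScore(
            name=r["spec"].name,
            cvmspe=float(r["cvmspe"]) if r["converged"] else float("nan"),
            weight=float(next(wi)) if r["converged"] else 0.0,
            ate=float(r["ate"]) if r["converged"] else float("nan"),
            converged=r["converged"],
            failure=r["failure"],
        )
        for r in records
    ]
    return fma, best, scores


def _pipeline_estimate(data: PairwiseData, config: AnalysisConfig, seed: int) -> float:
    records = _score_roster(data, config, seed)
    fma, _, _ = _combine(records, len(data), config)
    return fma


def bootstrap_ci(
    data: PairwiseData, config: AnalysisConfig, seed: int | None = None
) -> tuple:
    """95% percentile-bootstrap interval for the FMA estimate.

    Patients are resampled with replacement within each arm (conditional on
    N₀, N₁) and the entire pipeline — pseudo-observations, strategy fits,
    cross-validation, weights — is re-run per replicate.  Percentiles are
    taken on the log scale for ratio estimands.  Aborts if more than
    ``config.bootstrap_max_failure_rate`` of replicates fail.
    """
    if config.n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1 for a bootstrap CI")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    idx0 = np.flatnonzero(data.treatment == 0)
    idx1 = np.flatnonzero(data.treatment == 1)
    draws = []
    failures = 0
    for b in range(config.n_bootstrap):
        take = np.concatenate(
            [rng.choice(idx0, size=len(idx0)), rng.choice(idx1, size=len(idx1))]
        )
        rep = data.subset(take)
        try:
            rep.pseudo = _pseudo_by_arm(rep, config)
            draws.append(_pipeline_estimate(rep, config, seed=(seed + b + 1) % (2**31 - 1)))
        except Exception as exc:  # noqa: BLE001 - replicate-level failure
            failures += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
    if failures > config.bootstrap_max_failure_rate * config.n_bootstrap:
        raise RuntimeError(
            f"bootstrap failure rate {failures}/{config.n_bootstrap} exceeds "
            f"{config.bootstrap_max_failure_rate:.0%}"
        )
    draws = np.asarray(draws, dtype=float)
    if config.estimand in _RATIO_ESTIMANDS:
        lo, hi = np.percentile(np.log(draws), [2.5, 97.5])
        return float(np.exp(lo)), float(np.exp(hi))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(lo), float(hi)


def run_pairwise_analysis(cohort: pd.DataFrame, config: AnalysisConfig) -> FMAResult:
    """Full FMA analysis of one treatment pair on one outcome.

    Slices the two arms, imputes region, builds pseudo-observations on the
    estimand's functional scale, scores every roster strategy by CvMSPE,
    and combines their ATEs with support weights.  A percentile-bootstrap
    CI is attached when ``config.n_bootstrap > 0``.
    """
    config.validate()
    data = _prepare_pairwise(cohort, config)
    records = _score_roster(data, config, config.seed)
    fma, best, scores = _combine(records, len(data), config)

    ci_lo = ci_hi = None
    if config.n_bootstrap > 0:
        ci_lo, ci_hi = bootstrap_ci(data, config)

    n1 = int(data.treatment.sum())
    return FMAResult(
        estimand=config.estimand,
        t0=config.t0,
        fma_ate=fma,
        best_model_ate=float(best["ate"]),
        best_model=best["spec"].name,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        per_strategy=scores,
        n0=len(data) - n1,
        n1=n1,
        reference_arm=config.reference_arm,
        comparator_arm=config.comparator_arm,
        metadata={
            "seed": config.seed,
            "n_folds": config.n_folds,
            "n_bootstrap": config.n_bootstrap,
            "weight_rule": config.weight_rule,
            "pseudo_method": config.pseudo_method,
            "ratio_log_scale": config.estimand in _RATIO_ESTIMANDS,
        },
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_forest(results: list, outcome_names: list | None = None) -> pd.DataFrame:
    """Forest-plot table: one row per comparison/outcome with the FMA
    estimate, CI, best model and arm sizes, plus per-strategy rows usable
    to reproduce a full model-combination forest plot."""
    if not results:
        raise ValueError("no results to report")
    outcome_names = outcome_names or [f"outcome_{i}" for i in range(len(results))]
    rows = []
    for name, res in zip(outcome_names, results):
        failed = [s.name for s in res.per_strategy if not s.converged]
        rows.append(
            {
                "outcome": name,
                "comparison": f"{res.comparator_arm} vs {res.reference_arm}",
                "estimand": res.estimand,
                "estimate": res.fma_ate,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "best_model": res.best_model,
                "best_model_estimate": res.best_model_ate,
                "n0": res.n0,
                "n1": res.n1,
                "failed_strategies": ";".join(failed),
            }
        )
    return pd.DataFrame(rows)


def strategy_table(result: FMAResult) -> pd.DataFrame:
    """Per-strategy estimates, CvMSPE and weights for one comparison."""
    return pd.DataFrame(
        [
            {"strategy": s.name, "ate": s.ate, "cvmspe": s.cvmspe,
             "weight": s.weight, "converged": s.converged, "failure": s.failure}
            for s in result.per_strategy
        ]
    )
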