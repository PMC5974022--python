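"""Consensus hepatic-encephalopathy (HE) risk feature ranking.

Features are mean-centred to unit variance and the binary HE outcome is
modelled four ways: plain logistic regression (per-feature by default, since
the reported coefficient/odds-ratio pairs are per-row transforms), stability-
selection randomized lasso (selection frequency in [0, 1]), elastic-net
penalized logistic regression, and an SGD-trained logistic-loss classifier.
Logistic coefficients are converted to odds ratios with the base-2 transform
OR = 2**beta, and a consensus sign is assigned when every non-zero signed
coefficient agrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV, SGDClassifier

from fmnet._utils import child_seeds, write_table


def standardize(features: pd.DataFrame) -> pd.DataFrame:
    """Mean-centre each column to population (ddof=0) unit variance.

    Constant columns are dropped with a warning; the transform is idempotent.
    """
    f = features.astype(float)
    sd = f.std(axis=0, ddof=0)
    const = sd == 0
    if const.all():
        raise ValueError("all feature columns are constant")
    if const.any():
        warnings.warn(f"dropping constant columns: {list(f.columns[const])}", stacklevel=2)
        f = f.loc[:, ~const]
        sd = sd[~const]
    return (f - f.mean(axis=0)) / sd


def odds_ratio_from_beta(beta: float) -> float:
    """OR = 2**beta (the base-2 convention of the consensus report)."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(2.0**beta)


@dataclass
class ConsensusConfig:
    """Hyperparameters of the four-model consensus fit."""

    n_subsamples: int = 200        # stability-selection resamples B
    subsample_fraction: float = 0.5
    weakness: float = 0.5          # random per-feature penalty down-weighting
    # L1 strength: None -> largest C whose full-data fit selects at most
    # ~sqrt(m/2) features. A cross-validated C is useless here: under a null
    # it picks a weak penalty that selects everything, so every selection
    # frequency saturates at 1 and the score loses its meaning.
    l1_C: float | None = None
    elastic_l1_ratio: float = 0.5
    elastic_C: float | None = None  # None -> internal CV
    sgd_max_iter: int = 1000
    cv_folds: int = 3
    joint_logistic: bool = False   # per-feature beta by default
    selection_tol: float = 1e-6


@dataclass
class RiskFeatureReport:
    """Per-feature consensus record mirroring the published column order."""

    df: pd.DataFrame  # logistic_beta, odds_ratio, randomized_lasso_score,
    #                   elastic_net_coef, sgd_coef, consensus_sign
    seed: int
    config: ConsensusConfig = field(default_factory=ConsensusConfig)

    def write(self, path) -> None:
        write_table(self.df, path, [f"seed={self.seed}"])


def _logistic_betas(x: np.ndarray, y: np.ndarray, joint: bool) -> np.ndarray:
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500)
    if joint:
        model.fit(x, y)
        return model.coef_.ravel().copy()
    betas = np.empty(x.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation can stop lbfgs early
        for j in range(x.shape[1]):
            model.fit(x[:, [j]], y)
            betas[j] = model.coef_[0, 0]
    return betas


def _choose_C(x: np.ndarray, y: np.ndarray, cfg: ConsensusConfig) -> float:
    """Largest C (weakest penalty) whose full-data L1 fit keeps at most
    ~sqrt(m/2) features, so subsampled fits select a sparse, comparable set."""
    m = x.shape[1]
    target = max(2, int(np.ceil(np.sqrt(m / 2))))
    chosen = None
    model = LogisticRegression(penalty="l1", solver="liblinear", max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for C in np.logspace(-2, 1, 16):
            model.set_params(C=C)
            model.fit(x, y)
            if (np.abs(model.coef_) > 1e-6).sum() <= target:
                chosen = float(C)
            elif chosen is not None:
                break
    return chosen if chosen is not None else 1e-2


def _randomized_lasso(
    x: np.ndarray, y: np.ndarray, cfg: ConsensusConfig, seed: int
) -> np.ndarray:
    """Stability selection: selection frequency of each feature across
    subsampled, randomly penalty-rescaled L1 logistic fits."""
    n, m = x.shape
    rng = np.random.default_rng(seed)
    C = cfg.l1_C if cfg.l1_C is not None else _choose_C(x, y, cfg)
    size = max(10, int(round(cfg.subsample_fraction * n)))
    hits = np.zeros(m)
    fitted = 0
    model = LogisticRegression(
        penalty="l1", C=C, solver="liblinear", max_iter=200
    )
    for _ in range(cfg.n_subsamples):
        for _attempt in range(20):
            idx = rng.choice(n, size=size, replace=False)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            continue
        # random penalty rescaling: scaling column j by w_j in {weakness, 1}
        # is equivalent to penalizing coefficient j by 1/w_j
        w = np.where(rng.random(m) < 0.5, cfg.weakness, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x[idx] * w, y[idx])
        hits += np.abs(model.coef_.ravel()) > cfg.selection_tol
        fitted += 1
    if fitted == 0:
        raise ValueError("no subsample contained both classes")
    return hits / fitted


def _elastic_net(x: np.ndarray, y: np.ndarray, cfg: ConsensusConfig, seed: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cfg.elastic_C is None:
            model = LogisticRegressionCV(
                Cs=np.logspace(-2, 1, 4),
                penalty="elasticnet",
                solver="saga",
                l1_ratios=[cfg.elastic_l1_ratio],
                cv=cfg.cv_folds,
                random_state=seed,
                max_iter=2000,
            )
        else:
            model = LogisticRegression(
                penalty="elasticnet",
                solver="saga",
                C=cfg.elastic_C,
                l1_ratio=cfg.elastic_l1_ratio,
                max_iter=2000,
            )
        model.fit(x, y)
    return model.coef_.ravel().copy()


def _consensus_sign(row: pd.Series, tol: float = 1e-9) -> int:
    signs = {
        int(np.sign(v))
        for v in (row["logistic_beta"], row["elastic_net_coef"], row["sgd_coef"])
        if abs(v) > tol
    }
    if len(signs) == 1:
        return signs.pop()
    return 0


def fit_consensus(
    features: pd.DataFrame,
    he_labels: pd.Series | np.ndarray,
    seed: int = 0,
    config: ConsensusConfig | None = None,
) -> RiskFeatureReport:
    """Fit the four models and assemble the consensus report.

    ``features`` must already be standardized (see :func:`standardize`);
    labels must contain both classes. All stochastic parts (subsampling,
    penalty randomization, SGD shuffling, CV splits) derive from ``seed``.
    """
    cfg = config or ConsensusConfig()
    x = features.to_numpy(dtype=float)
    y = np.asarray(he_labels, dtype=int).ravel()
    if x.shape[0] != len(y):
        raise ValueError("features and labels differ in length")
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if len(np.unique(y)) != 2:
        raise ValueError("both HE classes must be present")
    if not np.allclose(x.mean(axis=0), 0, atol=1e-6) or not np.allclose(
        x.std(axis=0), 1, atol=1e-3
    ):
        raise ValueError("features must be standardized first (see standardize())")

    s_rl, s_en, s_sgd, s_cv = child_seeds(seed, 4)
    betas = _logistic_betas(x, y, cfg.joint_logistic)
    rl = _randomized_lasso(x, y, cfg, s_rl)
    en = _elastic_net(x, y, cfg, s_en)
    sgd = SGDClassifier(
        loss="log_loss",
        penalty="l2",
        max_iter=cfg.sgd_max_iter,
        tol=1e-4,
        random_state=s_sgd,
        shuffle=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sgd.fit(x, y)
    df = pd.DataFrame(
        {
            "logistic_beta": betas,
            "odds_ratio": [odds_ratio_from_beta(b) for b in betas],
            "randomized_lasso_score": rl,
            "elastic_net_coef": en,
            "sgd_coef": sgd.coef_.ravel(),
        },
        index=features.columns,
    )
    df["consensus_sign"] = [int(_consensus_sign(row)) for _, row in df.iterrows()]
    return RiskFeatureReport(df=df, seed=seed, config=cfg)


def select_he_features(
    report: RiskFeatureReport,
    min_lasso_score: float = 0.0,
    require_consensus: bool = True,
) -> pd.DataFrame:
    """Filter and rank the report into the final risk table.

    Default criteria: non-zero consensus sign and a randomized-lasso score
    strictly above ``min_lasso_score``. Rows are sorted by |logistic beta|
    and annotated with the percentage risk change (OR - 1) * 100.
    """
    df = report.df.copy()
    keep = df["randomized_lasso_score"] > min_lasso_score
    if require_consensus:
        keep &= df["consensus_sign"] != 0
    out = df.loc[keep].copy()
    out["risk_change_pct"] = (out["odds_ratio"] - 1.0) * 100.0
    return out.reindex(out["logistic_beta"].abs().sort_values(ascending=False).index)
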