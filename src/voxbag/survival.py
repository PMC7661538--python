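"""Survival validation: Cox-Lasso hazard scores, Harrell's C-index with
paired bootstrap, model comparison and Kaplan-Meier stratification.

The validation protocol: the cohort is divided ``n_splits`` times into
train/validation parts with a stratified shuffle on the event indicator.
On each training part, every aggregation strategy gets its own z-scaler
(and, for the bag-of-visual-words model, its own dictionary) and an
L1-penalized Cox model whose penalty is chosen by inner cross-validation.
Hazard scores are predicted on the held-out part and the C-index is
computed on ``n_boot`` bootstrap resamples of the held-out patients; the
same resamples are used for every model so that model differences are
paired. 5 splits x 1000 bootstraps yield 5000 C-index estimates per model,
summarized by their mean and percentile 95% CI.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_fit_apply",
    "CoxLassoHazard",
    "c_index",
    "run_validation",
    "km_stratify",
    "ValidationResult",
    "KMResult",
]


def zscore_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, StandardScaler]:
    """z-score both tables with the mean/SD estimated on the training table.

    Zero-variance columns pass through as zeros (with a warning).
    """
    if list(train.columns) != list(test.columns):
        raise ValueError("train/test column mismatch")
    if train.empty:
        raise ValueError("empty training table")
    scaler = StandardScaler().fit(train.values)
    if np.any(train.values.std(axis=0) == 0):
        warnings.warn("constant descriptor column(s); passed through as zeros")
    return scaler.transform(train.values), scaler.transform(test.values), scaler


def _breslow_partial_loglik(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a set of risk scores."""
    order = np.argsort(time)
    s, t, e = scores[order], time[order], event[order]
    # risk set of patient i: all j with t_j >= t_i -> suffix logsumexp
    rev = s[::-1]
    m = rev.max()
    lse = np.log(np.cumsum(np.exp(rev - m))) + m
    suffix_lse = lse[::-1]
    # handle ties in time: risk set uses t_j >= t_i, so for tied times use the
    # first index with that time
    first_idx = np.searchsorted(t, t, side="left")
    ll = float(np.sum((s - suffix_lse[first_idx])[e == 1]))
    return ll


class CoxLassoHazard(BaseEstimator):
    """L1-penalized Cox proportional-hazards model with inner-CV penalty
    selection; predicts the linear hazard score HS = x'beta.

    The lasso path is fit with scikit-survival's Coxnet; the penalty is the
    path value maximizing the held-out Breslow partial likelihood summed
    over ``cv`` stratified folds of the training data. An all-zero
    coefficient vector at the selected penalty is a valid (constant-score)
    model, flagged via ``is_null_``.
    """

    def __init__(
        self,
        cv: int = 5,
        n_alphas: int = 50,
        alpha_min_ratio: float = 0.01,
        l1_ratio: float = 1.0,
        random_state: int | None = 0,
    ):
        self.cv = cv
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.l1_ratio = l1_ratio
        self.random_state = random_state

    def _make_path_model(self, alphas=None):
        kw = dict(
            l1_ratio=self.l1_ratio,
            fit_baseline_model=False,
            max_iter=100000,
            tol=1e-7,
        )
        if alphas is None:
            kw.update(n_alphas=self.n_alphas, alpha_min_ratio=self.alpha_min_ratio)
        else:
            kw.update(alphas=alphas)
        return CoxnetSurvivalAnalysis(**kw)

    def fit(self, X, y):
        """X: (n, p) standardized descriptors; y: structured survival array
        (or (time, event) tuple)."""
        X = np.asarray(X, dtype=np.float64)
        if isinstance(y, tuple):
            y = Surv.from_arrays(event=np.asarray(y[1]).astype(bool), time=y[0])
        event = y[y.dtype.names[0]].astype(bool)
        time = y[y.dtype.names[1]].astype(float)
        if event.sum() < 2:
            raise ValueError("need at least 2 events to fit a Cox model")
        path = self._make_path_model().fit(X, y)
        alphas = np.asarray(path.alphas_)
        n_folds = min(self.cv, int(event.sum()))
        if n_folds >= 2 and len(alphas) > 1:
            skf = StratifiedKFold(
                n_splits=n_folds, shuffle=True, random_state=self.random_state
            )
            cv_ll = np.zeros(len(alphas))
            valid = np.ones(len(alphas), dtype=bool)
            for tr, te in skf.split(X, event):
                if event[tr].sum() < 2 or event[te].sum() < 1:
                    continue
                try:
                    m = self._make_path_model(alphas=list(alphas)).fit(X[tr], y[tr])
                except Exception:  # degenerate fold; skip
                    continue
                # coxnet may truncate the requested path; match by value
                fold_alphas = np.asarray(m.alphas_)
                scores = X[te] @ m.coef_
                for a, alpha in enumerate(alphas):
                    (hits,) = np.where(np.isclose(fold_alphas, alpha, rtol=1e-8))
                    if len(hits) == 0:
                        valid[a] = False
                        continue
                    cv_ll[a] += _breslow_partial_loglik(
                        scores[:, hits[0]], time[te], event[te]
                    )
            best = int(np.argmax(np.where(valid, cv_ll, -np.inf)))
        else:
            best = len(alphas) - 1
        self.alpha_ = float(alphas[best])
        self.alphas_ = alphas
        final = self._make_path_model(alphas=[self.alpha_]).fit(X, y)
        self.coef_ = np.asarray(final.coef_).ravel()
        self.is_null_ = not np.any(self.coef_ != 0)
        if self.is_null_:
            logger.info("Cox-Lasso selected the null model (all coefficients zero)")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_


def c_index(scores, time, event) -> float:
    """Harrell's concordance index.

    Comparable pairs: the patient with the shorter time has event = 1 and
    times are strictly ordered (equal times are incomparable). A pair is
    concordant when the shorter-time patient has the higher score; score
    ties count 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    t_i = time[:, None]
    comparable = (t_i < time[None, :]) & event[:, None]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    s_i = scores[:, None]
    conc = (s_i > scores[None, :]) & comparable
    ties = (s_i == scores[None, :]) & comparable
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


@dataclass
class ValidationResult:
    """Bootstrap C-index estimates for every model, plus comparisons."""

    estimates: dict[str, np.ndarray]  # strategy -> (n_splits, n_boot)
    split_test_ids: list[list[str]]
    seed: int | None
    n_redrawn: int = 0
    null_model_fits: dict[str, int] = field(default_factory=dict)

    @property
    def strategies(self) -> list[str]:
        return list(self.estimates)

    def pooled(self, strategy: str) -> np.ndarray:
        return self.estimates[strategy].ravel()

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.strategies:
            vals = self.pooled(s)
            lo, hi = np.percentile(vals, [2.5, 97.5])
            rows.append(
                dict(model=s, mean_c_index=vals.mean(), ci_low=lo, ci_high=hi,
                     n_estimates=vals.size)
            )
        return pd.DataFrame(rows).set_index("model")

    def compare(self, a: str, b: str) -> dict[str, float]:
        """Paired bootstrap difference a - b over the pooled estimates."""
        d = self.pooled(a) - self.pooled(b)
        lo, hi = np.percentile(d, [2.5, 97.5])
        p = 2.0 * min((d <= 0).mean(), (d >= 0).mean())
        return dict(
            mean_diff=float(d.mean()), ci_low=float(lo), ci_high=float(hi),
            p_value=float(min(1.0, p)),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "split_test_ids": self.split_test_ids,
            "estimates": {k: v.tolist() for k, v in self.estimates.items()},
            "summary": self.summary().reset_index().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload))


def _bootstrap_indices(rng, n, time, event, n_boot, max_redraw=100):
    """Resample test indices with replacement; redraw resamples that have no
    comparable pair. Returns (indices (n_boot, n), n_redrawn)."""
    out = np.empty((n_boot, n), dtype=np.int64)
    n_redrawn = 0
    for b in range(n_boot):
        for attempt in range(max_redraw + 1):
            idx = rng.integers(0, n, size=n)
            t, e = time[idx], event[idx]
            comparable = ((t[:, None] < t[None, :]) & (e[:, None] == 1)).any()
            if comparable:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a resample with comparable pairs")
        out[b] = idx
    return out, n_redrawn


def run_validation(
    tables: dict[str, pd.DataFrame],
    survival: pd.DataFrame,
    stacks: dict[str, "object"] | None = None,
    n_splits: int = 5,
    test_fraction: float = 0.2,
    n_boot: int = 1000,
    bovw_words: int = 50,
    bovw_kwargs: dict | None = None,
    cox_kwargs: dict | None = None,
    seed: int | None = 0,
) -> ValidationResult:
    """Run the full multi-model validation protocol.

    Parameters
    ----------
    tables : per-strategy patient x feature descriptor tables (indexed by
        patient id) for the precomputed strategies (classical, mean, var,
        mean_var, volume).
    survival : DataFrame with columns patient_id, time, event.
    stacks : per-patient voxel feature stacks; when given, a "bovw" model is
        added whose dictionary is refit on every training fold.
    """
    surv = survival.set_index("patient_id") if "patient_id" in survival else survival
    ids = list(surv.index)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if np.any(time <= 0) or not set(np.unique(event)) <= {0, 1}:
        raise ValueError("survival table needs positive times and 0/1 events")
    for name, tab in tables.items():
        if set(tab.index) != set(ids):
            raise ValueError(f"table {name!r} does not cover the cohort")
    strategies = list(tables)
    if stacks is not None:
        missing = set(ids) - set(stacks)
        if missing:
            raise ValueError(f"stacks missing for patients: {sorted(missing)[:5]}...")
        strategies.append("bovw")

    ss = np.random.SeedSequence(seed)
    split_seed, boot_seed, dict_seed, cox_seed = [
        int(np.random.default_rng(c).integers(0, 2**31 - 1)) for c in ss.spawn(4)
    ]
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=split_seed
    )
    estimates = {s: np.zeros((n_splits, n_boot)) for s in strategies}
    split_test_ids = []
    n_redrawn_total = 0
    null_fits = {s: 0 for s in strategies}
    bovw_kwargs = dict(bovw_kwargs or {})
    cox_kwargs = dict(cox_kwargs or {})

    for si, (tr, te) in enumerate(splitter.split(np.zeros(len(ids)), event)):
        tr_ids = [ids[i] for i in tr]
        te_ids = [ids[i] for i in te]
        split_test_ids.append(te_ids)
        y_tr = Surv.from_arrays(event=event[tr].astype(bool), time=time[tr])
        test_scores = {}
        for strat in strategies:
            if strat == "bovw":
                from .aggregation import BagOfVisualWords

                dictionary = BagOfVisualWords(
                    n_words=bovw_words,
                    random_state=dict_seed + si,
                    **bovw_kwargs,
                ).fit([stacks[p] for p in tr_ids])
                Xtr_raw = dictionary.transform([stacks[p] for p in tr_ids])
                Xte_raw = dictionary.transform([stacks[p] for p in te_ids])
                cols = [f"word_{i}" for i in range(bovw_words)]
                train_tab = pd.DataFrame(Xtr_raw, index=tr_ids, columns=cols)
                test_tab = pd.DataFrame(Xte_raw, index=te_ids, columns=cols)
            else:
                train_tab = tables[strat].loc[tr_ids]
                test_tab = tables[strat].loc[te_ids]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Xtr, Xte, _ = zscore_fit_apply(train_tab, test_tab)
            model = CoxLassoHazard(random_state=cox_seed + si, **cox_kwargs).fit(
                Xtr, y_tr
            )
            if model.is_null_:
                null_fits[strat] += 1
            test_scores[strat] = model.predict(Xte)
        rng = np.random.default_rng(np.random.SeedSequence([boot_seed, si]))
        boot_idx, n_redrawn = _bootstrap_indices(
            rng, len(te), time[te], event[te], n_boot
        )
        n_redrawn_total += n_redrawn
        t_te, e_te = time[te], event[te]
        for b in range(n_boot):
            idx = boot_idx[b]
            for strat in strategies:
                estimates[strat][si, b] = c_index(
                    test_scores[strat][idx], t_te[idx], e_te[idx]
                )
    return ValidationResult(
        estimates=estimates,
        split_test_ids=split_test_ids,
        seed=seed,
        n_redrawn=n_redrawn_total,
        null_model_fits=null_fits,
    )


@dataclass
class KMResult:
    low_risk: np.ndarray  # boolean mask
    statistic: float
    p_value: float
    curves: dict[str, pd.DataFrame]


def km_stratify(scores, time, event) -> KMResult:
    """Median hazard-score split + Kaplan-Meier curves + log-rank test.

    Patients with HS <= median go to the low-risk group (ties to low risk).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    scores = np.asarray(scores, dtype=np.float64)
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event).astype(int)
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 patients to stratify")
    med = float(np.median(scores))
    low = scores <= med
    if low.all() or not low.any():
        raise ValueError("all hazard scores identical; cannot stratify")
    res = logrank_test(time[low], time[~low], event[low], event[~low])
    curves = {}
    for name, mask in (("low_risk", low), ("high_risk", ~low)):
        km = KaplanMeierFitter().fit(time[mask], event[mask])
        curves[name] = km.survival_function_.rename(
            columns={km.survival_function_.columns[0]: "S"}
        )
    return KMResult(
        low_risk=low,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
    )
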