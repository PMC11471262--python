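"""Scikit-learn style estimators.

``CoupledMotifCFG`` is a binary classifier over RNA sequences for one
search pattern: ``fit(X, y)`` trains the coupled model discriminatively
(y=1 marks motif-bearing sequences), ``predict_proba`` returns the motif
probability P(y=1|x), and ``decision_function`` the log-odds
``log Z+ - log Z-``.  ``MotifDiscovery`` runs the full workflow over a
set of candidate patterns: K-fold enrichment-score ranking followed by a
final retrain of the best pattern.

``X`` is a sequence of RNA strings (unaligned, any lengths); both
estimators follow get_params/set_params conventions and compose with
sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .coupled import coupled_charts
from .energy import EnergyParams, default_energy_params
from .pattern import default_pattern_set, parse_pattern
from .profile import build_profile_model
from .training import (
    MotifFit,
    TrainConfig,
    enrichment_score,
    scores_for,
    select_motif,
    train,
)

__all__ = ["CoupledMotifCFG", "MotifDiscovery"]


def _check_X(X):
    xs = list(X)
    if not xs or not all(isinstance(s, str) for s in xs):
        raise ValueError("X must be a non-empty sequence of RNA strings")
    return xs


def _check_y(y, n):
    y = np.asarray(y)
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0, 1])) or len(classes) != 2:
        raise ValueError("y must contain both classes 0 and 1")
    return y.astype(int)


class CoupledMotifCFG(BaseEstimator, ClassifierMixin):
    """Coupled profile-CFG / energy-model motif classifier for one pattern.

    Parameters
    ----------
    pattern:
        Search pattern text (modified dot-bracket, e.g. ``"*(.(*))*"``).
    W, min_hairpin:
        Structure-ensemble constraints (maximal pair span; minimum
        hairpin loop size).
    omega:
        Fixed self-transition log-weight (not trained).
    lam_init:
        Initial coupling scale; kept non-negative during training.
    c_theta, c_lam:
        L2 regularization strengths.
    learning_rate, batch_size, n_epochs, patience, validation_fraction:
        Adam SGD schedule; ``validation_fraction > 0`` holds out part of
        the training data for early stopping.
    sim_negative_ratio:
        Dinucleotide-shuffled copies of positives mixed into the
        negative stream each epoch, as a fraction of the positive count.
    energy_params:
        Optional :class:`EnergyParams`; default is the shipped table
        with the given ``W``/``min_hairpin``.
    random_state:
        Seed controlling initialization, batching and shuffles.

    Attributes (after fit)
    ----------------------
    model_ : ProfileModel          trained parameters
    theta_loop_, theta_pair_, theta_bg_ : ndarray
    lam_ : float                   trained coupling scale
    objective_trace_ : list        per-epoch objective values
    n_iter_ : int                  epochs actually run
    enrichment_score_ : float      AUROC on the early-stopping split
    """

    def __init__(
        self,
        pattern: str = "*(...)*",
        W: int = 50,
        min_hairpin: int = 3,
        omega: float = -1.0,
        lam_init: float = 1.0,
        c_theta: float = 0.01,
        c_lam: float = 0.001,
        learning_rate: float = 0.02,
        batch_size: int = 16,
        n_epochs: int = 50,
        patience: int = 5,
        validation_fraction: float = 0.2,
        sim_negative_ratio: float = 1.0,
        energy_params: EnergyParams | None = None,
        random_state: int | None = None,
    ):
        self.pattern = pattern
        self.W = W
        self.min_hairpin = min_hairpin
        self.omega = omega
        self.lam_init = lam_init
        self.c_theta = c_theta
        self.c_lam = c_lam
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.sim_negative_ratio = sim_negative_ratio
        self.energy_params = energy_params
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _params(self) -> EnergyParams:
        if self.energy_params is not None:
            return self.energy_params
        return default_energy_params(W=self.W, min_hairpin=self.min_hairpin)

    def _config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.n_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            c_theta=self.c_theta,
            c_lam=self.c_lam,
            seed=0 if self.random_state is None else int(self.random_state),
            sim_negative_ratio=self.sim_negative_ratio,
            patience=self.patience,
            validation_fraction=self.validation_fraction,
        )

    def fit(self, X, y):
        X = _check_X(X)
        y = _check_y(y, len(X))
        cfg = self._config()
        params = self._params()
        pat = parse_pattern(self.pattern)
        rng = np.random.default_rng(cfg.seed)
        pos = [x for x, yy in zip(X, y) if yy == 1]
        neg = [x for x, yy in zip(X, y) if yy == 0]

        pv = nv = None
        if cfg.validation_fraction > 0 and cfg.patience > 0:
            n_pv = max(1, int(len(pos) * cfg.validation_fraction))
            n_nv = max(1, int(len(neg) * cfg.validation_fraction))
            if len(pos) > n_pv and len(neg) > n_nv:
                pidx = rng.permutation(len(pos))
                nidx = rng.permutation(len(neg))
                pv = [pos[i] for i in pidx[:n_pv]]
                pos = [pos[i] for i in pidx[n_pv:]]
                nv = [neg[i] for i in nidx[:n_nv]]
                neg = [neg[i] for i in nidx[n_nv:]]

        m0 = build_profile_model(
            pat, init="jitter", seed=cfg.seed,
            omega=self.omega, lam=self.lam_init,
        )
        fit = train(m0, pos, neg, cfg, params, Xpos_val=pv, Xneg_val=nv)
        self.model_ = fit.model
        self.fit_ = fit
        self.theta_loop_ = fit.model.theta_loop
        self.theta_pair_ = fit.model.theta_pair
        self.theta_bg_ = fit.model.theta_bg
        self.lam_ = fit.model.lam
        self.objective_trace_ = fit.objective_trace
        self.n_iter_ = len(fit.objective_trace)
        self.enrichment_score_ = fit.enrichment_score
        self.classes_ = np.array([0, 1])
        return self

    def _charts(self, X, want_counts=False):
        params = self._params()
        return [coupled_charts(x, self.model_, params, want_counts) for x in _check_X(X)]

    def predict_proba(self, X):
        p = np.array([c.prob for c in self._charts(X)])
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        out = []
        for c in self._charts(X):
            out.append(c.logZ_plus - c.logZ_minus)
        return np.array(out)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def position_posterior(self, X, kind: str = "motif"):
        """Per-position motif-membership posteriors, one array per input."""
        return [c.position_posterior(kind) for c in self._charts(X, want_counts=True)]

    def pair_posterior(self, X):
        """Base-pair posterior matrix per input sequence."""
        return [c.pair_posterior() for c in self._charts(X, want_counts=True)]

    def enrichment(self, Xpos, Xneg):
        return enrichment_score(self.model_, Xpos, Xneg, self._params())


class MotifDiscovery(BaseEstimator, ClassifierMixin):
    """Full motif-discovery workflow over a candidate pattern set.

    K-fold cross-validated enrichment-score ranking of every pattern,
    then a final retrain of the winner on the complete data.

    Attributes (after fit): ``ranking_`` (list of (pattern text, mean
    ES)), ``best_pattern_``, ``best_fit_`` (a :class:`MotifFit`) and
    ``best_estimator_`` (a fitted :class:`CoupledMotifCFG` view).
    """

    def __init__(
        self,
        patterns=None,
        cv: int = 5,
        W: int = 50,
        min_hairpin: int = 3,
        omega: float = -1.0,
        c_theta: float = 0.01,
        c_lam: float = 0.001,
        learning_rate: float = 0.02,
        batch_size: int = 16,
        n_epochs: int = 50,
        patience: int = 5,
        sim_negative_ratio: float = 1.0,
        energy_params: EnergyParams | None = None,
        random_state: int | None = None,
    ):
        self.patterns = patterns
        self.cv = cv
        self.W = W
        self.min_hairpin = min_hairpin
        self.omega = omega
        self.c_theta = c_theta
        self.c_lam = c_lam
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.patience = patience
        self.sim_negative_ratio = sim_negative_ratio
        self.energy_params = energy_params
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_X(X)
        y = _check_y(y, len(X))
        pats = self.patterns
        if pats is None:
            pats = [p.text for p in default_pattern_set()]
        params = self.energy_params or default_energy_params(
            W=self.W, min_hairpin=self.min_hairpin
        )
        cfg = TrainConfig(
            k_folds=self.cv,
            epochs=self.n_epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            c_theta=self.c_theta,
            c_lam=self.c_lam,
            seed=0 if self.random_state is None else int(self.random_state),
            sim_negative_ratio=self.sim_negative_ratio,
            patience=self.patience,
        )
        pos = [x for x, yy in zip(X, y) if yy == 1]
        neg = [x for x, yy in zip(X, y) if yy == 0]
        ranked, best = select_motif(pats, pos, neg, cfg, params)
        self.ranking_ = [(f.pattern.text, f.enrichment_score) for f in ranked]
        self.ranked_fits_ = ranked
        self.best_fit_ = best
        self.best_pattern_ = best.pattern.text
        est = CoupledMotifCFG(
            pattern=best.pattern.text, W=self.W, min_hairpin=self.min_hairpin,
            omega=self.omega, energy_params=self.energy_params,
            random_state=self.random_state,
        )
        est.model_ = best.model
        est.classes_ = np.array([0, 1])
        self.best_estimator_ = est
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)

    def predict(self, X):
        return self.best_estimator_.predict(X)

    def decision_function(self, X):
        return self.best_estimator_.decision_function(X)
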