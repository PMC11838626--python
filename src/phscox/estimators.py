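"""scikit-learn style estimators wrapping the Cox lasso machinery.

Two estimators cover the two ways the solver is used:

* :class:`PenalizedCoxPH` — an L1-penalized Cox fit at one fixed
  penalty, all features in memory;
* :class:`BasilCoxLasso` — the full batch-screening path over a
  genotype matrix (in-memory array or :class:`~phscox.genotypes.GenotypeStore`),
  with the internal train/validation/test split and validation-based
  model selection.

Both follow the scikit-learn contract: parameters in ``__init__``,
``fit`` returning self, fitted attributes with trailing underscores,
``get_params``/``set_params`` inherited from ``BaseEstimator``. Survival
outcomes ``y`` are accepted as a structured array with event/time
fields (the scikit-survival convention) or as an (n, 2) array of
``[time, status]`` columns.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import basil as _basil
from .coxph import fit_penalized, make_cox_data
from .evaluation import c_index
from .genotypes import GenotypeStore, impute_and_standardize, qc_filter

__all__ = ["PenalizedCoxPH", "BasilCoxLasso", "unpack_survival"]


def unpack_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """(time, status) from a structured survival array or (n, 2) array."""
    y = np.asarray(y)
    if y.dtype.names:
        names = list(y.dtype.names)
        ev_name = next(n for n in names if y[n].dtype.kind == "b" or "event" in n or "status" in n)
        t_name = next(n for n in names if n != ev_name)
        return y[t_name].astype(float), y[ev_name].astype(float)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(float)
    raise ValueError("y must be a structured (event, time) array or an (n, 2) [time, status] array")


class PenalizedCoxPH(BaseEstimator):
    """Lasso-penalized Cox proportional-hazards model at a fixed penalty.

    Minimizes -l(b)/n + alpha*||b||_1 with l the Breslow partial
    log-likelihood; optional ``covariates`` passed to :meth:`fit` enter
    unpenalized. ``predict`` returns the linear predictor (log relative
    hazard), and ``score`` the concordance index.

    Parameters
    ----------
    alpha : float
        Penalty level (mean-log-likelihood scaling).
    tol, max_iter : solver controls, see
        :func:`phscox.coxph.fit_penalized`.
    """

    def __init__(self, alpha: float = 0.01, tol: float = 1e-7, max_iter: int = 100):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=np.float64)
        time, status = unpack_survival(y)
        data = make_cox_data(time, status, X_pen=X, X_unpen=covariates)
        fit = fit_penalized(data, self.alpha, tol=self.tol, max_iter=self.max_iter)
        self.coef_ = fit.beta_pen
        self.covariate_coef_ = fit.beta_unpen
        self.objective_ = fit.objective
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, covariates=None) -> np.ndarray:
        eta = np.asarray(X, dtype=np.float64) @ self.coef_
        if covariates is not None and self.covariate_coef_.size:
            eta = eta + np.asarray(covariates, dtype=np.float64) @ self.covariate_coef_
        return eta

    def score(self, X, y, covariates=None) -> float:
        time, status = unpack_survival(y)
        return c_index(self.predict(X, covariates), time, status)


class BasilCoxLasso(BaseEstimator):
    """Batch-screening lasso Cox path with validation-based selection.

    ``fit`` partitions the rows into train/validation/test at the
    configured fractions, builds the verified lasso path by batch
    screening, and selects the penalty maximizing validation
    concordance. For ndarray input, features are standardized on the
    training split (constant columns dropped); a
    :class:`~phscox.genotypes.GenotypeStore` additionally passes QC
    (missing rate, MAF) first.

    Attributes after fit include ``path_`` (the verified
    :class:`~phscox.basil.LassoPath`), ``model_`` (the selected
    :class:`~phscox.basil.PHSModel`), ``coef_`` (dense per-SD weights on
    the input variant axis) and the split row indices
    ``train_rows_`` / ``val_rows_`` / ``test_rows_``.
    """

    def __init__(
        self,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        batch_screen_size: int = 1000,
        max_basil_iter: int = 50,
        split_fractions: tuple = (0.70, 0.10, 0.20),
        split_seed: int = 0,
        early_stop_patience: int = 2,
        tol: float = 1e-7,
        max_iter: int = 100,
        kkt_tol: float = 1e-5,
        max_missing: float = 0.10,
        min_maf: float = 0.001,
        verbose: bool = False,
    ):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.batch_screen_size = batch_screen_size
        self.max_basil_iter = max_basil_iter
        self.split_fractions = split_fractions
        self.split_seed = split_seed
        self.early_stop_patience = early_stop_patience
        self.tol = tol
        self.max_iter = max_iter
        self.kkt_tol = kkt_tol
        self.max_missing = max_missing
        self.min_maf = min_maf
        self.verbose = verbose

    def _config(self) -> _basil.BasilConfig:
        return _basil.BasilConfig(
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            batch_screen_size=self.batch_screen_size,
            max_basil_iter=self.max_basil_iter,
            split_fractions=tuple(self.split_fractions),
            split_seed=self.split_seed,
            early_stop_patience=self.early_stop_patience,
            tol=self.tol,
            max_iter=self.max_iter,
            kkt_tol=self.kkt_tol,
        )

    def fit(self, X, y, covariates=None, covariate_names=None):
        time, status = unpack_survival(y)
        config = self._config()
        n = time.shape[0]
        splits = _basil.make_split(n, config, status=status)
        train = splits[0]
        for attr in ("qc_kept_", "stats_"):
            if hasattr(self, attr):
                delattr(self, attr)

        if isinstance(X, GenotypeStore):
            if X.n_individuals != n:
                raise ValueError("genotype store rows do not match y")
            kept = qc_filter(X, max_missing=self.max_missing, min_maf=self.min_maf)
            stats = impute_and_standardize(X, kept, train)
            source = _basil.GenotypeSource(X, stats)
            self.qc_kept_ = kept
            self.stats_ = stats
            person_ids = X.sample_ids
            n_input = X.n_variants
        elif isinstance(X, (_basil.GenotypeSource, _basil.ArraySource)):
            source = X
            person_ids = np.array([f"row_{i}" for i in range(n)])
            n_input = source.n_variants
        else:
            X = np.asarray(X, dtype=np.float64)
            if X.shape[0] != n:
                raise ValueError("X rows do not match y")
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0)
            keep = sd > 0
            source = _basil.ArraySource((X[:, keep] - mu[keep]) / sd[keep])
            source.variant_ids = np.array([f"var_{j}" for j in np.flatnonzero(keep)])
            source.means = mu[keep]
            source.sds = sd[keep]
            self.stats_ = None
            person_ids = np.array([f"row_{i}" for i in range(n)])
            n_input = X.shape[1]

        cov = None if covariates is None else np.asarray(covariates, dtype=np.float64)
        path, splits = _basil.basil_fit(
            time, status, cov, source, config, splits=splits, verbose=self.verbose
        )
        model = _basil.select_model(
            path,
            source,
            train_person_ids=person_ids[train],
            covariate_names=covariate_names,
        )
        self.source_ = source
        self.path_ = path
        self.model_ = model
        self.train_rows_, self.val_rows_, self.test_rows_ = splits
        self.lambda_ = model.selected_lambda
        self.covariate_coef_ = model.covariate_betas
        # dense weights on the input variant axis, mapped back through any
        # QC / constant-column filtering
        coef = np.zeros(n_input)
        id_to_pos = {v: i for i, v in enumerate(np.asarray(source.variant_ids))}
        for vid, b in zip(model.variant_ids, model.betas):
            coef[self._input_position(vid, id_to_pos)] = b
        self.coef_ = coef
        self.n_features_in_ = n_input
        return self

    def _input_position(self, vid, id_to_pos) -> int:
        if hasattr(self, "qc_kept_") and self.stats_ is not None:
            return int(self.stats_.variant_indices[id_to_pos[vid]])
        name = str(vid)
        if name.startswith("var_"):
            return int(name.split("_", 1)[1])
        return int(id_to_pos[vid])

    def predict(self, X, covariates=None) -> np.ndarray:
        """Full linear predictor (PHS + covariate contribution) for new rows."""
        eta = self.predict_phs(X)
        if covariates is not None and self.covariate_coef_.size:
            eta = eta + np.asarray(covariates, dtype=np.float64) @ self.covariate_coef_
        return eta

    def predict_phs(self, X) -> np.ndarray:
        """Variant-only polygenic hazard score on the training scale."""
        from .evaluation import compute_phs

        if isinstance(X, GenotypeStore):
            return compute_phs(X, self.model_).phs
        X = np.asarray(X, dtype=np.float64)
        m = self.model_
        pos = np.array([self._model_column(v) for v in m.variant_ids], dtype=np.int64)
        if pos.size == 0:
            return np.zeros(X.shape[0])
        return ((X[:, pos] - m.mean) / m.sd) @ m.betas

    def _model_column(self, vid) -> int:
        name = str(vid)
        if name.startswith("var_"):
            return int(name.split("_", 1)[1])
        raise ValueError("array prediction requires models fitted on array input")

    def score(self, X, y, covariates=None) -> float:
        time, status = unpack_survival(y)
        return c_index(self.predict(X, covariates), time, status)
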