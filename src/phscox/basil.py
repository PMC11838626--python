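"""Batch-screening iterative lasso over the full regularization path.

Fitting an L1-penalized Cox model over 10^5-10^6 variants is feasible
because the lasso solution is sparse: at any penalty level only a small
set of variants can be active. The batch-screening iterative lasso
(BASIL) exploits this by never materializing the full design matrix.
It maintains an ever-growing candidate subset; at each penalty level it

1. solves the penalized problem on the subset (warm-started),
2. evaluates the full-data score at the solution, streamed in column
   batches, and checks the lasso optimality (KKT) conditions over ALL
   variants: every excluded variant must have gradient magnitude at
   most lambda,
3. on a violation, adds the top ``batch_screen_size`` excluded variants
   by absolute gradient and re-solves, so every reported penalty level
   satisfies full-data KKT,
4. scores the verified solution by concordance on the validation split
   and stops extending the path once the validation C-index has
   stopped improving for ``early_stop_patience`` consecutive levels.

The data enter through a 70/10/20 train/validation/test split; the
model reported downstream is the one maximizing validation concordance
(ties broken toward the sparser, larger-lambda model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .coxph import CoxData, CoxFit, _breslow, fit_cox_newton, fit_penalized, make_cox_data
from .evaluation import c_index
from .genotypes import GenotypeStore, StandardizationStats, standardized_block

__all__ = [
    "BasilConfig",
    "LassoPath",
    "PHSModel",
    "GenotypeSource",
    "ArraySource",
    "make_split",
    "compute_lambda_max",
    "basil_fit",
    "select_model",
]


@dataclass
class BasilConfig:
    """Knobs of the path algorithm.

    ``max_basil_iter`` caps the number of screening augmentations (the
    outer iterations of the batch-screening loop); the defaults mirror
    glmnet-family conventions for the grid (100 log-spaced penalties
    down to lambda_max/100).
    """

    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    batch_screen_size: int = 1000
    max_basil_iter: int = 50
    split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    split_seed: int = 0
    early_stop_patience: int = 2
    tol: float = 1e-7
    max_iter: int = 100
    kkt_tol: float = 1e-5

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.split_fractions) < 0:
            raise ValueError("split fractions must be non-negative")
        for name in ("n_lambda", "batch_screen_size", "max_basil_iter", "early_stop_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


# ----------------------------------------------------------------------
# column sources: how the solver sees the (standardized) variant matrix
# ----------------------------------------------------------------------
class GenotypeSource:
    """Standardized, batched view of a GenotypeStore after QC."""

    def __init__(self, store: GenotypeStore, stats: StandardizationStats):
        self.store = store
        self.stats = stats
        self.n_variants = len(stats.variant_indices)
        self.variant_ids = store.variants["id"].to_numpy()[stats.variant_indices]
        self.effect_alleles = store.variants["a1"].to_numpy()[stats.variant_indices]
        self.means = stats.mean
        self.sds = stats.sd
        self.batch_size = store.batch_size

    def get(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        return standardized_block(self.store, self.stats, cols, rows)


class ArraySource:
    """In-memory feature matrix already on the model scale."""

    def __init__(self, X: np.ndarray, variant_ids=None, batch_size: int = 1000):
        self.X = np.asarray(X, dtype=np.float64)
        self.n_variants = self.X.shape[1]
        self.variant_ids = (
            np.asarray(variant_ids)
            if variant_ids is not None
            else np.array([f"var_{j}" for j in range(self.n_variants)])
        )
        self.effect_alleles = np.array(["A"] * self.n_variants)
        self.means = np.zeros(self.n_variants)
        self.sds = np.ones(self.n_variants)
        self.batch_size = batch_size

    def get(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        return self.X[np.ix_(np.asarray(rows), np.asarray(cols))]


def _stream_abs_gradient(source, rows: np.ndarray, u: np.ndarray, n: int) -> np.ndarray:
    """|d mean-loglik / d beta_j| for every variant, in column batches."""
    g = np.empty(source.n_variants)
    bs = source.batch_size
    for start in range(0, source.n_variants, bs):
        cols = np.arange(start, min(start + bs, source.n_variants))
        g[cols] = np.abs(source.get(cols, rows).T @ u) / n
    return g


# ----------------------------------------------------------------------
# split and grid
# ----------------------------------------------------------------------
def make_split(n: int, config: BasilConfig, status: np.ndarray | None = None):
    """Random disjoint, exhaustive train/validation/test row partition."""
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(n)
    f_tr, f_va, _ = config.split_fractions
    n_tr = int(round(f_tr * n))
    n_va = int(round(f_va * n))
    train = np.sort(perm[:n_tr])
    val = np.sort(perm[n_tr : n_tr + n_va])
    test = np.sort(perm[n_tr + n_va :])
    if status is not None:
        for part, nm in ((train, "train"), (val, "validation"), (test, "test")):
            if part.size and status[part].sum() == 0:
                raise ValueError(f"{nm} split contains zero events")
    return train, val, test


def compute_lambda_max(
    data: CoxData, source, rows: np.ndarray, config: BasilConfig
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Smallest penalty with an all-zero variant solution, plus the grid.

    lambda_max is the largest absolute gradient of the mean partial
    log-likelihood over penalized variants, evaluated at beta_pen = 0
    with the unpenalized covariates at their optimum. Returns
    (lambda_max, grid, |gradient| per variant, covariate betas).
    """
    cov_fit = fit_cox_newton(data)
    eta = data.X_unpen @ cov_fit.beta if data.p_unpen else np.zeros(data.n)
    _, u, _ = _breslow(data, eta)
    g_abs = _stream_abs_gradient(source, rows, u, data.n)
    lam_max = float(g_abs.max())
    grid = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)
    return lam_max, grid, g_abs, cov_fit.beta


# ----------------------------------------------------------------------
# path containers
# ----------------------------------------------------------------------
@dataclass
class LassoPath:
    """The verified regularization path.

    ``coefficients`` is a CSR matrix (one row per reported lambda, one
    column per QC-passing variant); every reported row passed the
    full-variant-set KKT check. Two validation concordances are logged:
    the full linear predictor (variants + covariates; used for model
    selection) and the genetic component alone.
    """

    lambda_grid: np.ndarray
    coefficients: sp.csr_matrix
    covariate_coefficients: np.ndarray  # (n_lambda, q)
    validation_c_index: np.ndarray
    validation_c_index_genetic: np.ndarray
    active_counts: np.ndarray
    kkt_verified: np.ndarray
    n_basil_iter: int = 0
    subset_size: int = 0
    covariate_names: list = field(default_factory=list)
    early_stopped: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.lambda_grid) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.lambda_grid)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "active_count": self.active_counts,
                "validation_c_index": self.validation_c_index,
                "validation_c_index_genetic": self.validation_c_index_genetic,
                "kkt_verified": self.kkt_verified,
            }
        )

    def coefficients_long(self, variant_ids: np.ndarray) -> pd.DataFrame:
        coo = self.coefficients.tocoo()
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid[coo.row],
                "variant_id": np.asarray(variant_ids)[coo.col],
                "beta": coo.data,
            }
        )


@dataclass
class PHSModel:
    """Selected variant set with log-hazard weights: the PHS definition.

    ``betas`` are per-SD log-hazard weights; scoring a person applies
    the training-split standardization (``mean``/``sd``) to their
    dosages of each variant. Covariate weights are carried for the full
    linear predictor but the polygenic hazard score itself is the
    variant-only component.
    """

    selected_lambda: float
    variant_ids: np.ndarray
    effect_alleles: np.ndarray
    betas: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    covariate_names: list
    covariate_betas: np.ndarray
    train_person_ids: np.ndarray
    validation_c_index: float = np.nan

    def __post_init__(self):
        k = len(self.variant_ids)
        if not (len(self.betas) == len(self.mean) == len(self.sd) == k):
            raise ValueError("inconsistent model arrays")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")

    @property
    def n_active(self) -> int:
        return len(self.variant_ids)

    def to_tsv(self, path) -> None:
        var = pd.DataFrame(
            {
                "term_type": "variant",
                "id": self.variant_ids,
                "effect_allele": self.effect_alleles,
                "beta": self.betas,
                "mean": self.mean,
                "sd": self.sd,
            }
        )
        cov = pd.DataFrame(
            {
                "term_type": "covariate",
                "id": self.covariate_names,
                "effect_allele": "",
                "beta": self.covariate_betas,
                "mean": 0.0,
                "sd": 1.0,
            }
        )
        meta = pd.DataFrame(
            {
                "term_type": "meta",
                "id": ["selected_lambda", "validation_c_index"],
                "effect_allele": "",
                "beta": [self.selected_lambda, self.validation_c_index],
                "mean": 0.0,
                "sd": 1.0,
            }
        )
        pd.concat([meta, var, cov]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, train_person_ids=None) -> "PHSModel":
        df = pd.read_csv(path, sep="\t")
        meta = df[df["term_type"] == "meta"].set_index("id")["beta"]
        var = df[df["term_type"] == "variant"]
        cov = df[df["term_type"] == "covariate"]
        return cls(
            selected_lambda=float(meta["selected_lambda"]),
            variant_ids=var["id"].to_numpy(),
            effect_alleles=var["effect_allele"].to_numpy(),
            betas=var["beta"].to_numpy(),
            mean=var["mean"].to_numpy(),
            sd=var["sd"].to_numpy(),
            covariate_names=cov["id"].tolist(),
            covariate_betas=cov["beta"].to_numpy(),
            train_person_ids=(
                np.asarray(train_person_ids) if train_person_ids is not None else np.empty(0)
            ),
            validation_c_index=float(meta["validation_c_index"]),
        )


# ----------------------------------------------------------------------
# the driver
# ----------------------------------------------------------------------
def basil_fit(
    y: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None,
    source,
    config: BasilConfig,
    splits=None,
    lambda_grid: np.ndarray | None = None,
    verbose: bool = False,
) -> tuple[LassoPath, tuple]:
    """Fit the verified lasso path by batch screening.

    ``source`` provides standardized variant columns (GenotypeSource or
    ArraySource); ``covariates`` is the unpenalized (n, q) block. Rows
    are partitioned internally unless ``splits`` (train, val, test row
    indices) is given. Returns the path and the splits used.
    """
    y = np.asarray(y, dtype=np.float64)
    status = np.asarray(status, dtype=np.float64)
    n = y.shape[0]
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if splits is None:
        splits = make_split(n, config, status=status)
    train, val, _ = splits

    y_tr, s_tr, cov_tr = y[train], status[train], cov[train]
    y_va, s_va, cov_va = y[val], status[val], cov[val]
    n_tr = train.size

    null_data = make_cox_data(y_tr, s_tr, X_unpen=cov_tr)
    lam_max, grid, g_abs, cov_beta0 = compute_lambda_max(null_data, source, train, config)
    if lambda_grid is not None:
        grid = np.asarray(lambda_grid, dtype=np.float64)

    # initial screen: top batch by absolute score at the null
    k0 = min(config.batch_screen_size, source.n_variants)
    subset = list(np.argsort(g_abs, kind="stable")[::-1][:k0])
    in_subset = np.zeros(source.n_variants, dtype=bool)
    in_subset[subset] = True
    X_sub_tr = source.get(np.array(subset), train)
    X_sub_va = source.get(np.array(subset), val)

    beta = np.zeros(len(subset))
    warm = CoxFit(beta, cov_beta0.copy(), lam_max, np.nan, 0, True)
    data_tr = make_cox_data(y_tr, s_tr, X_pen=X_sub_tr, X_unpen=cov_tr)

    rows_lam, rows_coefs, rows_cov = [], [], []
    rows_c, rows_cg, rows_active, rows_kkt = [], [], [], []
    n_basil_iter = 0
    best_c = -np.inf
    stale = 0
    early_stopped = False
    budget_exhausted = False

    for lam in grid:
        verified = False
        fit = warm
        while not verified:
            fit = fit_penalized(
                data_tr, lam, warm_start=warm, tol=config.tol, max_iter=config.max_iter
            )
            eta_tr = X_sub_tr @ fit.beta_pen + (cov_tr @ fit.beta_unpen if cov.shape[1] else 0.0)
            _, u, _ = _breslow(data_tr, eta_tr)
            g_abs = _stream_abs_gradient(source, train, u, n_tr)
            g_abs[in_subset] = 0.0  # subset features satisfy KKT via the fitter
            violators = g_abs > lam + config.kkt_tol
            if not violators.any():
                verified = True
                break
            if n_basil_iter >= config.max_basil_iter:
                budget_exhausted = True
                warnings.warn(
                    "screening budget exhausted before full KKT verification; "
                    "returning the partial path"
                )
                break
            n_basil_iter += 1
            # add the strongest excluded variants (all violators first)
            order = np.argsort(g_abs, kind="stable")[::-1]
            add = [j for j in order[: config.batch_screen_size] if g_abs[j] > 0.0]
            for j in sorted(set(add) | set(np.flatnonzero(violators))):
                subset.append(j)
                in_subset[j] = True
            new = np.array(subset[X_sub_tr.shape[1] :])
            X_sub_tr = np.hstack([X_sub_tr, source.get(new, train)])
            X_sub_va = np.hstack([X_sub_va, source.get(new, val)])
            data_tr = make_cox_data(y_tr, s_tr, X_pen=X_sub_tr, X_unpen=cov_tr)
            pad = np.zeros(len(subset))
            pad[: fit.beta_pen.size] = fit.beta_pen
            warm = CoxFit(pad, fit.beta_unpen, lam, np.nan, 0, True)
            if verbose:
                print(f"  screen: lambda={lam:.5g} subset={len(subset)}")
        if budget_exhausted and not verified:
            break
        warm = fit

        eta_va_gen = X_sub_va @ fit.beta_pen
        eta_va = eta_va_gen + (cov_va @ fit.beta_unpen if cov.shape[1] else 0.0)
        c_full = c_index(eta_va, y_va, s_va)
        c_gen = c_index(eta_va_gen, y_va, s_va)

        rows_lam.append(lam)
        local_support = np.flatnonzero(fit.beta_pen)
        rows_coefs.append(
            (np.array(subset)[local_support], fit.beta_pen[local_support])
        )
        rows_cov.append(fit.beta_unpen.copy())
        rows_c.append(c_full)
        rows_cg.append(c_gen)
        rows_active.append(local_support.size)
        rows_kkt.append(True)
        if verbose:
            print(
                f"lambda={lam:.5g} active={local_support.size} "
                f"val C={c_full:.4f} (genetic {c_gen:.4f})"
            )

        if c_full > best_c + 1e-12:
            best_c = c_full
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                early_stopped = True
                break

    m = len(rows_lam)
    indptr = np.zeros(m + 1, dtype=np.int64)
    cols, vals = [], []
    for i, (cc, vv) in enumerate(rows_coefs):
        indptr[i + 1] = indptr[i] + len(cc)
        cols.append(cc)
        vals.append(vv)
    coef = sp.csr_matrix(
        (
            np.concatenate(vals) if vals else np.empty(0),
            np.concatenate(cols) if cols else np.empty(0, dtype=np.int64),
            indptr,
        ),
        shape=(m, source.n_variants),
    )
    path = LassoPath(
        lambda_grid=np.array(rows_lam),
        coefficients=coef,
        covariate_coefficients=np.array(rows_cov) if rows_cov else np.empty((0, cov.shape[1])),
        validation_c_index=np.array(rows_c),
        validation_c_index_genetic=np.array(rows_cg),
        active_counts=np.array(rows_active, dtype=np.int64),
        kkt_verified=np.array(rows_kkt, dtype=bool),
        n_basil_iter=n_basil_iter,
        subset_size=len(subset),
        early_stopped=early_stopped,
    )
    return path, splits


def select_model(
    path: LassoPath,
    source,
    train_person_ids=None,
    covariate_names=None,
) -> PHSModel:
    """Pick the penalty maximizing validation concordance.

    Ties are broken toward the larger penalty (the sparser model), which
    is the first index of the maximum on the decreasing grid.
    """
    if len(path) == 0:
        raise ValueError("empty path")
    best = int(np.argmax(path.validation_c_index))
    row = path.coefficients.getrow(best).tocoo()
    pos = row.col
    q = path.covariate_coefficients.shape[1]
    return PHSModel(
        selected_lambda=float(path.lambda_grid[best]),
        variant_ids=np.asarray(source.variant_ids)[pos],
        effect_alleles=np.asarray(source.effect_alleles)[pos],
        betas=row.data,
        mean=np.asarray(source.means)[pos],
        sd=np.asarray(source.sds)[pos],
        covariate_names=list(covariate_names) if covariate_names else [f"cov_{i}" for i in range(q)],
        covariate_betas=path.covariate_coefficients[best],
        train_person_ids=(
            np.asarray(train_person_ids) if train_person_ids is not None else np.empty(0)
        ),
        validation_c_index=float(path.validation_c_index[best]),
    )
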