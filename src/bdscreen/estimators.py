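"""scikit-learn style estimator front end for the deconvolution models.

``SubpopulationDeconvolution`` wraps the multistart maximum-likelihood
machinery in a ``BaseEstimator`` so fits compose with scikit-learn idioms
(``get_params``/``set_params``, cloning, grid search over ``method`` or
``n_populations``).  ``X`` may be a ``ScreenDataset`` or a long-format
DataFrame with columns ``time, dose, replicate, cell_count`` (time-0 rows
carry the known seeding count).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import inference
from .dose_response import hill
from .moments import total_mean_vector
from .simulate import ScreenDataset

__all__ = ["SubpopulationDeconvolution"]


class SubpopulationDeconvolution(BaseEstimator):
    """Deconvolve bulk drug-screen counts into clonal subpopulations.

    Parameters
    ----------
    method : {"live_cell", "end_points", "phenopop"}, default="live_cell"
        Likelihood used: time-correlated multivariate Gaussian, independent
        birth-death Gaussian approximation, or deterministic growth with
        two noise levels.
    n_populations : int, default=2
        Number of clones fitted.
    bounds : str or FitBounds, default="table4"
        Feasible box for the optimizer.
    n_restarts : int, default=20
        Latin-hypercube multistart budget.
    random_state : int or Generator, optional
        Controls the starting points; fits are reproducible given data and
        seed.

    Attributes
    ----------
    result_ : FitResult with the full fit record.
    params_ : fitted parameter set, clones in ascending half-effect dose.
    fractions_, gr50_ : per-clone initial fractions and GR50 doses.
    loglik_, aic_, bic_ : fit quality measures.
    converged_ : whether any restart reported convergence.
    """

    def __init__(
        self,
        method: str = "live_cell",
        n_populations: int = 2,
        bounds="table4",
        n_restarts: int = 20,
        random_state=None,
    ):
        self.method = method
        self.n_populations = n_populations
        self.bounds = bounds
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _as_dataset(self, X) -> ScreenDataset:
        if isinstance(X, ScreenDataset):
            return X
        if isinstance(X, pd.DataFrame):
            from .io import dataset_from_frame

            assay = "live_cell" if self.method == "live_cell" else "end_point"
            return dataset_from_frame(X, assay=assay)
        raise TypeError(
            "X must be a ScreenDataset or a long-format DataFrame with "
            "columns time,dose,replicate,cell_count"
        )

    def fit(self, X, y=None):
        data = self._as_dataset(X)
        self.result_ = inference.fit(
            data,
            method=self.method,
            S=self.n_populations,
            bounds=self.bounds,
            n_restarts=self.n_restarts,
            rng=self.random_state,
        )
        self.params_ = self.result_.theta_hat
        self.fractions_ = np.asarray(self.result_.fractions)
        self.gr50_ = np.asarray(self.result_.gr50)
        self.loglik_ = self.result_.loglik
        self.aic_ = self.result_.aic
        self.bic_ = self.result_.bic
        self.converged_ = self.result_.converged
        self.design_ = data.design
        return self

    def score(self, X, y=None) -> float:
        """Log-likelihood of ``X`` under the fitted parameters."""
        check_is_fitted(self, "params_")
        data = self._as_dataset(X)
        return inference._loglik_fn(self.method)(self.params_, data)

    def predict(self, X) -> np.ndarray:
        """Expected total cell count for each (time, dose) row of ``X``.

        ``X`` is a DataFrame with ``time`` and ``dose`` columns (other
        columns ignored); the fitted mean growth curve is evaluated
        row-wise using the seeding count of the training design.
        """
        check_is_fitted(self, "params_")
        frame = pd.DataFrame(X)
        n = self.design_.n_initial
        out = np.empty(len(frame))
        t = frame["time"].to_numpy(dtype=float)
        d = frame["dose"].to_numpy(dtype=float)
        if self.method == "phenopop":
            th = self.params_
            mean = np.zeros_like(t)
            for p_i, a_i, h_i in zip(th.fractions, th.alphas, th.hills):
                mean += p_i * np.exp(t * (a_i + np.log(hill(d, h_i))))
            out = n * mean
        else:
            for i, (ti, di) in enumerate(zip(t, d)):
                if ti == 0.0:
                    out[i] = n
                else:
                    out[i] = total_mean_vector(self.params_, [ti], di, n)[0]
        return out

    def bootstrap(self, X, n_boot: int = 100, refit_restarts: int = 3):
        """Percentile bootstrap CIs around the fitted estimate."""
        data = self._as_dataset(X)
        return inference.bootstrap_cis(
            data,
            method=self.method,
            S=self.n_populations,
            n_boot=n_boot,
            bounds=self.bounds,
            n_restarts=self.n_restarts,
            refit_restarts=refit_restarts,
            rng=self.random_state,
        )
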