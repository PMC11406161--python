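"""scikit-learn-style estimator wrapping the hierarchical model.

``PhyloGLMMRegressor`` follows the sklearn estimator contract
(``get_params``/``set_params``, ``fit``/``predict``, fitted attributes with
trailing underscores) so the Bayesian mixed model composes with sklearn
tooling; the module-level :func:`ewlphylo.hmodel.fit_hmc` and friends are
thin functional entry points over the same engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import hmodel
from .phylocov import CorrelationMatrix
from .prep import CodingConfig, ModelFrame

_COVARIATE_COLUMNS = [
    "time_min",
    "water",
    "temp_c",
    "temp_centered",
    "ln_svl_centered",
    "species",
    "frog",
    "housing",
    "date",
]


class PhyloGLMMRegressor(BaseEstimator, RegressorMixin):
    """Bayesian phylogenetic longitudinal mixed model of ln body mass.

    Parameters
    ----------
    phylogeny:
        Species correlation matrix (``CorrelationMatrix``).  Required unless
        ``fixed_covariance`` is passed to :meth:`fit`.
    priors:
        ``PriorSpec``; defaults to :func:`ewlphylo.hmodel.default_priors`.
    mode:
        ``"nested"`` (time kernel within individuals, phylogeny through the
        species random effect) or ``"composite"``.
    chains, warmup, samples, seed:
        HMC settings; desk-scale defaults (4 x 1000/1000).

    Attributes (after ``fit``)
    ----------
    draws_ : PosteriorDraws
    summary_ : list[EffectSummary]
    coef_ : ndarray of the 19 posterior-mean fixed effects
    diagnostics_ : DataFrame with R-hat / ESS / MCSE per parameter
    """

    def __init__(
        self,
        phylogeny: CorrelationMatrix | None = None,
        priors=None,
        mode: str = "nested",
        chains: int = 4,
        warmup: int = 1000,
        samples: int = 1000,
        seed: int = 0,
        reference_lag: float = 20.0,
        max_leapfrog: int = 16,
    ):
        self.phylogeny = phylogeny
        self.priors = priors
        self.mode = mode
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.seed = seed
        self.reference_lag = reference_lag
        self.max_leapfrog = max_leapfrog

    def _to_frame(self, X, y) -> ModelFrame:
        if isinstance(X, ModelFrame):
            return X
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a ModelFrame or a pandas DataFrame")
        if y is None:
            raise ValueError("y (ln mass) is required when X is a plain DataFrame")
        missing = [c for c in _COVARIATE_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"X missing covariate columns {missing}")
        data = X.copy()
        data["ln_mass"] = np.asarray(y, dtype=float)
        if "status" not in data:
            data["status"] = "observed"
        return ModelFrame(data=data, coding=CodingConfig())

    def fit(self, X, y=None, fixed_covariance: np.ndarray | None = None):
        frame = self._to_frame(X, y)
        priors = self.priors
        if priors is None and fixed_covariance is None:
            priors = hmodel.default_priors(frame)
        self.frame_ = frame
        self.draws_ = hmodel._fit_hmc_engine(
            frame,
            self.phylogeny,
            priors,
            chains=self.chains,
            warmup=self.warmup,
            samples=self.samples,
            seed=self.seed,
            mode=self.mode,
            reference_lag=self.reference_lag,
            fixed_covariance=fixed_covariance,
            max_leapfrog=self.max_leapfrog,
        )
        self.summary_ = hmodel.summarize_posterior(self.draws_)
        self.coef_ = np.array(
            [
                np.mean(self.draws_.get(n))
                for n in hmodel.COEFFICIENT_NAMES
                if n in self.draws_.names
            ]
        )
        self.diagnostics_ = self.draws_.diagnostics()
        self.n_features_in_ = len(hmodel.COEFFICIENT_NAMES)
        return self

    def predict(self, X, y=None) -> np.ndarray:
        """Posterior-mean fixed-effect prediction of ln mass."""
        if not hasattr(self, "draws_"):
            raise AttributeError("estimator is not fitted")
        frame = X if isinstance(X, ModelFrame) else self._to_frame(X, np.zeros(len(X)))
        Xd, names = hmodel.design_matrix(frame)
        beta = np.array([np.mean(self.draws_.get(n)) for n in names])
        return Xd @ beta

    def score(self, X, y=None):
        """R^2 of the posterior-mean prediction of ln mass."""
        frame = X if isinstance(X, ModelFrame) else self._to_frame(X, y)
        yy = frame.data["ln_mass"].to_numpy(float)
        pred = self.predict(frame)
        ss_res = np.sum((yy - pred) ** 2)
        ss_tot = np.sum((yy - yy.mean()) ** 2)
        return 1.0 - ss_res / ss_tot
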