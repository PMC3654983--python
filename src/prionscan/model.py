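"""Scikit-learn-style estimator facade over the scanning pipeline.

:class:`PrionScanner` is a one-class-style detector: ``fit`` learns the
amino-acid propensity table from positive (prion-domain) training sequences
against a background composition, ``decision_function`` returns each
sequence's best-window score in bits, and ``predict`` applies the calibrated
cutoff.  It composes with sklearn's ``clone``/``get_params`` machinery; the
module-level functions in :mod:`prionscan.scan` remain the workhorses.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import proline as _proline
from . import propensity as _propensity
from . import scan as _scan


def _residues(x) -> str:
    return x.residues if hasattr(x, "residues") else str(x).upper()


class PrionScanner(BaseEstimator):
    """Sliding-window detector of Q/N-rich prion-forming domains.

    Parameters
    ----------
    window_length : int
        Length of the scored window (residues).
    cutoff : float
        Decision threshold in bits; ``predict`` calls a sequence positive
        when its best window reaches it.
    pseudocount : float
        Jeffreys-style smoothing added per residue when estimating training
        frequencies; 0 gives raw maximum likelihood (and possibly infinite
        potentials).
    background : array-like of shape (20,), optional
        Background frequencies; the frozen Swiss-Prot composition if None.
    proline_model : ProlineDistanceModel, optional
        Proline spacing correction; the shipped default model if None.
    ambiguity_policy : {"zero", "skip"}
        Treatment of windows containing ambiguity letters.

    Attributes
    ----------
    table_ : PropensityTable
        The fitted log-odds potentials.
    proline_model_ : ProlineDistanceModel
        The spacing model in use.
    n_training_sequences_ : int
    """

    def __init__(
        self,
        window_length: int = 60,
        cutoff: float = 50.0,
        pseudocount: float = 0.5,
        background=None,
        proline_model=None,
        ambiguity_policy: str = "zero",
    ):
        self.window_length = window_length
        self.cutoff = cutoff
        self.pseudocount = pseudocount
        self.background = background
        self.proline_model = proline_model
        self.ambiguity_policy = ambiguity_policy

    # -- sklearn plumbing ---------------------------------------------------

    def _config(self, mode: str = "max") -> _scan.ScanConfig:
        return _scan.ScanConfig(
            window_length=self.window_length,
            cutoff=self.cutoff,
            mode=mode,
            ambiguity_policy=self.ambiguity_policy,
        )

    def fit(self, X: Iterable, y=None) -> "PrionScanner":
        """Learn the propensity table from positive training sequences.

        ``X`` is a sequence of residue strings or ``SequenceRecord``s.  With
        a binary ``y``, only the positive examples are used for training
        (the model is compositional and one-class).
        """
        X = list(X)
        if y is not None:
            y = np.asarray(y)
            X = [x for x, yi in zip(X, y) if yi]
        if not X:
            raise ValueError("fit requires at least one positive training sequence")
        bg = None if self.background is None else np.asarray(self.background, float)
        self.table_ = _propensity.train_table(
            X, background=bg, pseudocount=self.pseudocount
        )
        self.proline_model_ = (
            self.proline_model if self.proline_model is not None
            else _proline.default_model()
        )
        self.n_training_sequences_ = len(X)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise ValueError("this PrionScanner instance is not fitted yet")

    def decision_function(self, X: Iterable) -> np.ndarray:
        """Best-window score in bits per sequence (-inf if too short)."""
        self._check_fitted()
        cfg = self._config()
        return np.array(
            [
                _scan.best_score(x, self.table_, self.proline_model_, cfg)
                for x in X
            ]
        )

    score_samples = decision_function

    def predict(self, X: Iterable) -> np.ndarray:
        """Boolean prion-domain call at the configured cutoff."""
        return self.decision_function(X) >= self.cutoff

    def scan(self, X: Iterable, mode: str = "max") -> list:
        """Full predictions (ScoredWindow lists) over a collection."""
        self._check_fitted()
        return _scan.scan_proteome(
            X, self.table_, self.proline_model_, self._config(mode)
        )


def builtin_scanner(**params) -> PrionScanner:
    """A scanner wired to the shipped propensity table (no fitting needed)."""
    est = PrionScanner(**params)
    est.table_ = _propensity.builtin_table()
    est.proline_model_ = (
        est.proline_model if est.proline_model is not None else _proline.default_model()
    )
    est.n_training_sequences_ = 0
    return est
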