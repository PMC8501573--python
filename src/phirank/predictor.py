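"""Scikit-learn-style estimator for ranked-list host prediction.

``RboHostPredictor`` is the package's main entry point: fit it on the
candidate hosts' ranked lists, then transform virus ranked lists into a score
matrix or predict each virus's top-scoring host set.  It follows the
scikit-learn estimator contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``fit``/``transform``/``predict``), so
it composes with sklearn model-selection utilities.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .ranklists import RankedList
from .rbo import DEFAULT_P, RboParams
from .scoring import ScoreMatrix, score_all

__all__ = ["RboHostPredictor"]


class RboHostPredictor(BaseEstimator):
    """Predict phage hosts by rank-biased overlap of ranked lists.

    Parameters
    ----------
    p : float, default 0.75
        Persistence parameter of the rank-biased overlap; weight on rank d
        decays geometrically as p**(d-1).  The default places ~98.6% of the
        weight on the first ten ranks.
    normalize : bool, default True
        Divide the truncated overlap sum by ``1 - p**n`` so identical lists
        score exactly 1.
    workers : int, default 1
        Parallel workers for matrix computation.

    Attributes
    ----------
    host_ids_ : tuple of str
        Host identifiers, in fit order.
    host_lists_ : tuple of RankedList
        The fitted host ranked lists.

    Examples
    --------
    >>> from phirank.ranklists import RankedList
    >>> hosts = [RankedList("hostA", ({"spA"}, {"spB"}))]
    >>> viruses = [RankedList("phi1", ({"spA"}, {"spB"}))]
    >>> RboHostPredictor().fit(hosts).predict(viruses)
    [frozenset({'hostA'})]
    """

    def __init__(
        self,
        p: float = DEFAULT_P,
        normalize: bool = True,
        workers: int = 1,
    ) -> None:
        self.p = p
        self.normalize = normalize
        self.workers = workers

    def _params(self) -> RboParams:
        return RboParams(p=self.p, normalize=self.normalize)

    @staticmethod
    def _as_lists(
        X: Mapping[str, RankedList] | Sequence[RankedList],
    ) -> list[RankedList]:
        items = list(X.values()) if isinstance(X, Mapping) else list(X)
        for item in items:
            if not isinstance(item, RankedList):
                raise TypeError(
                    f"expected RankedList inputs, got {type(item).__name__}"
                )
        return items

    def fit(
        self,
        X: Mapping[str, RankedList] | Sequence[RankedList],
        y: object = None,
    ) -> "RboHostPredictor":
        """Store the candidate hosts' ranked lists.

        ``X`` is a mapping or sequence of :class:`RankedList`, one per
        candidate host; ``y`` is ignored (present for API compatibility).
        """
        self._params()  # validate p early
        hosts = self._as_lists(X)
        ids = [h.query_id for h in hosts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate host ids")
        if not hosts:
            raise ValueError("at least one host ranked list is required")
        self.host_ids_ = tuple(ids)
        self.host_lists_ = tuple(hosts)
        return self

    def transform(
        self, X: Mapping[str, RankedList] | Sequence[RankedList]
    ) -> ScoreMatrix:
        """Score matrix of the given virus lists against the fitted hosts."""
        self._check_fitted()
        return score_all(
            self._as_lists(X),
            self.host_lists_,
            self._params(),
            workers=self.workers,
        )

    def predict(
        self, X: Mapping[str, RankedList] | Sequence[RankedList]
    ) -> list[frozenset[str]]:
        """Top-scoring host set per virus (all hosts tied at the maximum)."""
        matrix = self.transform(X)
        out: list[frozenset[str]] = []
        for row in matrix.scores:
            top = row.max()
            out.append(
                frozenset(
                    h for h, s in zip(matrix.host_ids, row) if s == top
                )
            )
        return out

    def predict_scores(
        self, X: Mapping[str, RankedList] | Sequence[RankedList]
    ) -> np.ndarray:
        """Raw score array (viruses x hosts), column order ``host_ids_``."""
        return self.transform(X).scores

    def _check_fitted(self) -> None:
        if not hasattr(self, "host_lists_"):
            raise RuntimeError(
                "RboHostPredictor is not fitted; call fit(host_lists) first"
            )
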