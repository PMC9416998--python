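"""scikit-learn transformers over the graphlet counters.

:class:`GraphletVectorizer` turns a list of ego networks (or plain typed
graphs with per-graph focal nodes) into a numeric feature matrix, one row
per network, so graphlet features compose with sklearn pipelines and
model selection.  Like sklearn's text vectorizers it consumes raw domain
objects rather than arrays; for the keyed colored/heterogeneous kinds the
column vocabulary is fixed at ``fit`` time from the observed keys.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import counters as _c
from .graph import EgoNetwork, GraphError, TypedGraph

__all__ = ["GraphletVectorizer", "KINDS"]

KINDS = ("gdv", "tye-gdv", "tye-dv", "colored", "hetero")


class GraphletVectorizer(TransformerMixin, BaseEstimator):
    """Extract per-ego graphlet feature vectors as a matrix.

    Parameters
    ----------
    kind : {"gdv", "tye-gdv", "tye-dv", "colored", "hetero"}
        Which counter family to apply.
    include_sentinel : bool, default False
        Whether untyped (sentinel) edges get their own column/key.  The
        default matches the egocentric survey setting where only
        ego-alter ties are typed.

    Attributes
    ----------
    feature_names_ : list of str
        Deterministically ordered output column names.
    vocabulary_ : dict, only for keyed kinds
        Maps ``(orbit, type-key)`` to column position.
    n_features_ : int
        Number of output columns.
    """

    def __init__(self, kind: str = "gdv", include_sentinel: bool = False):
        self.kind = kind
        self.include_sentinel = include_sentinel

    # -- helpers ------------------------------------------------------
    @staticmethod
    def _as_ego(x) -> EgoNetwork:
        if isinstance(x, EgoNetwork):
            return x
        network = getattr(x, "network", None)
        if isinstance(network, EgoNetwork):
            return network
        raise GraphError(
            f"expected EgoNetwork (or an object with a .network EgoNetwork), got {type(x).__name__}"
        )

    def _count_one(self, net: EgoNetwork):
        g, ego = net.graph, net.ego
        if self.kind == "gdv":
            return _c.count_gdv(g, [ego], mode="egocentric")[ego]
        if self.kind == "tye-gdv":
            return _c.count_tye_egdv(net, include_sentinel=self.include_sentinel)
        if self.kind == "tye-dv":
            return _c.count_tye_dv(g, [ego], include_sentinel=self.include_sentinel)[ego]
        if self.kind == "colored":
            return _c.count_colored_gdv(
                g, [ego], mode="egocentric", include_sentinel=self.include_sentinel
            )[ego]
        if self.kind == "hetero":
            return _c.count_hetero_gdv(
                g, [ego], mode="egocentric", include_sentinel=self.include_sentinel
            )[ego]
        raise GraphError(f"unknown kind {self.kind!r}; pick one of {KINDS}")

    # -- sklearn API --------------------------------------------------
    def fit(self, X, y=None):
        nets = [self._as_ego(x) for x in X]
        if not nets:
            raise GraphError("cannot fit on an empty collection")
        registries = {net.graph.registry for net in nets}
        if len(registries) > 1:
            raise GraphError("all networks must share one type registry")
        self.registry_ = nets[0].graph.registry

        if self.kind in ("colored", "hetero"):
            keys = set()
            for net in nets:
                res = self._count_one(net)
                for o, d in enumerate(res.by_orbit):
                    keys.update((o, k) for k in d)
            vocab = sorted(keys)
            self.vocabulary_ = {ok: i for i, ok in enumerate(vocab)}
            self.feature_names_ = [
                f"g{o}_k{'|'.join(map(str, k))}" for o, k in vocab
            ]
        else:
            first = self._count_one(nets[0])
            self.feature_names_ = list(first.flat_labels())
            self.vocabulary_ = None
        self.n_features_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise GraphError("GraphletVectorizer is not fitted yet")
        nets = [self._as_ego(x) for x in X]
        rows = np.zeros((len(nets), self.n_features_), dtype=np.int64)
        for i, net in enumerate(nets):
            res = self._count_one(net)
            if self.kind in ("colored", "hetero"):
                for o, d in enumerate(res.by_orbit):
                    for key, c in d.items():
                        col = self.vocabulary_.get((o, key))
                        if col is not None:  # unseen keys are dropped
                            rows[i, col] = c
            else:
                flat = res.flatten()
                if len(flat) != self.n_features_:
                    raise GraphError("inconsistent vector width across networks")
                rows[i] = flat
        return rows

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
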