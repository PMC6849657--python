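"""scikit-learn estimator facade over the pipeline stages.

``ConnectomeFeatureExtractor`` is a transformer mapping a list of
gray-matter volumes to the 93-column feature matrix;
``OversamplingClassifier`` wraps any of the four classifier families (or an
arbitrary estimator) with in-fit random minority oversampling.  Both follow
sklearn conventions (get_params/set_params, fitted attributes with trailing
underscores) and compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .atlas import AtlasDefinition, bundled_atlas
from .features import extract_features
from .models import FAMILIES, derive_seed, make_classifier, oversample_minority
from .volume import GrayMatterVolume

__all__ = ["ConnectomeFeatureExtractor", "OversamplingClassifier"]


class ConnectomeFeatureExtractor(TransformerMixin, BaseEstimator):
    """Volumes → 93 connectome features (90 regional efficiencies + brain
    volume + network size + mean degree).

    Parameters mirror the pipeline stages: the gray-matter floor for node
    retention, the threshold method/parameter for binarization, the number
    of vector permutations for the false-positive-rate calibration, and the
    optional rotation-invariant cube similarity.  ``atlas=None`` selects the
    bundled synthetic 90-region atlas sized to the first volume seen.
    """

    def __init__(
        self,
        min_gm: float = 0.1,
        threshold_method: str = "permutation_fpr",
        threshold_param: float = 0.05,
        n_permutations: int = 20,
        rotation_invariant: bool = False,
        atlas: AtlasDefinition | None = None,
        random_state: int | None = None,
    ):
        self.min_gm = min_gm
        self.threshold_method = threshold_method
        self.threshold_param = threshold_param
        self.n_permutations = n_permutations
        self.rotation_invariant = rotation_invariant
        self.atlas = atlas
        self.random_state = random_state

    def _volumes(self, X) -> list[GrayMatterVolume]:
        vols = list(X)
        if not vols or not all(isinstance(v, GrayMatterVolume) for v in vols):
            raise TypeError("X must be a non-empty sequence of GrayMatterVolume")
        return vols

    def fit(self, X, y=None):
        vols = self._volumes(X)
        self.atlas_ = self.atlas if self.atlas is not None else bundled_atlas(vols[0].shape)
        self.n_features_out_ = 93
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "atlas_")
        vols = self._volumes(X)
        rows = []
        for i, vol in enumerate(vols):
            seed = (
                None
                if self.random_state is None
                else derive_seed(self.random_state, "extract", vol.subject_id, i)
            )
            rows.append(
                extract_features(
                    vol,
                    self.atlas_,
                    min_gm=self.min_gm,
                    threshold_method=self.threshold_method,
                    threshold_param=self.threshold_param,
                    n_permutations=self.n_permutations,
                    rotation_invariant=self.rotation_invariant,
                    seed=seed,
                )
            )
        index = [v.subject_id for v in vols]
        return pd.DataFrame(rows, index=index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "atlas_")
        from .features import core_feature_names

        return np.asarray(core_feature_names(self.atlas_), dtype=object)


class OversamplingClassifier(ClassifierMixin, BaseEstimator):
    """Classifier wrapper that balances classes by random minority
    oversampling at fit time, then delegates to the base estimator.

    ``estimator`` is a family name (one of {families}) or any sklearn
    classifier instance.
    """.format(families=FAMILIES)

    def __init__(
        self,
        estimator: str = "random_forest",
        random_state: int | None = None,
        n_trees: int = 1000,
    ):
        self.estimator = estimator
        self.random_state = random_state
        self.n_trees = n_trees

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        Xb, yb, _ = oversample_minority(X, y, self.random_state)
        if isinstance(self.estimator, str):
            self.estimator_ = make_classifier(
                self.estimator, X.shape[1], self.random_state, self.n_trees
            )
        else:
            from sklearn.base import clone

            self.estimator_ = clone(self.estimator)
        self.estimator_.fit(Xb, yb)
        self.classes_ = self.estimator_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(np.asarray(X, dtype=float))
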