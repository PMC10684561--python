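"""Cosine-similarity item networks from Likert rating tables.

Each questionnaire item is represented by its vector of responses across
participants; the association between two items is the cosine of the
angle between their response vectors.  Because Likert responses are
non-negative, cosine similarity lies in [0, 1]: 1 for items that always
co-occur (parallel vectors), 0 for items that never do.

Two coding modes are supported.  ``raw`` uses the 1..L Likert values
directly and is the default: it uses all the information in the ratings.
``binarized`` first recodes each response as an endorsement indicator
(rating >= threshold), which treats the similarity strictly as a
co-occurrence probability.  Note that with all-positive vectors cosine
similarity has a high floor driven by shared means; the structure of
interest lives in the upper tail of the similarity distribution, which
is what the TMFG filter extracts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine
from sklearn.utils.validation import check_array


class CosineSimilarity(TransformerMixin, BaseEstimator):
    """Transform a participants x items rating matrix into an items x items
    cosine-similarity matrix.

    Parameters
    ----------
    mode : {"raw", "binarized"}
        ``raw`` uses Likert values as-is; ``binarized`` recodes each value
        as ``value >= threshold`` before computing cosines.
    threshold : int
        Endorsement cutoff for ``binarized`` mode (default 4 on a 1-5 scale).

    Attributes
    ----------
    n_items_ : int
        Number of items seen in fit.
    """

    def __init__(self, mode: str = "raw", threshold: int = 4):
        self.mode = mode
        self.threshold = threshold

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("cosine similarity requires >= 2 participants")
        if self.mode not in ("raw", "binarized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.n_items_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("rating matrix contains missing values")
        if self.mode == "binarized":
            X = (X >= self.threshold).astype(float)
        vecs = X.T  # one row per item
        norms = np.linalg.norm(vecs, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} item vector(s) are all-zero; "
                          "their similarities are set to 0", stacklevel=2)
        sim = _sk_cosine(vecs)
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0
        sim = (sim + sim.T) / 2.0  # symmetrize away float asymmetry
        np.clip(sim, 0.0, 1.0, out=sim)
        np.fill_diagonal(sim, np.where(zero, 0.0, 1.0))
        return sim


def cosine_similarity_matrix(ratings, mode: str = "raw", threshold: int = 4) -> pd.DataFrame:
    """Item x item cosine-similarity matrix as a labeled DataFrame.

    ``ratings`` may be a RatingsTable, a participants x items DataFrame,
    or a 2-D array.  The condition label, when available, is attached as
    ``result.attrs["condition"]``.
    """
    condition = None
    if hasattr(ratings, "data") and hasattr(ratings, "condition"):  # RatingsTable
        condition = ratings.condition
        frame = ratings.data
    elif isinstance(ratings, pd.DataFrame):
        frame = ratings
    else:
        frame = pd.DataFrame(np.asarray(ratings))
    est = CosineSimilarity(mode=mode, threshold=threshold)
    sim = est.fit(frame.to_numpy(dtype=float)).transform(frame.to_numpy(dtype=float))
    out = pd.DataFrame(sim, index=frame.columns, columns=frame.columns)
    out.attrs["condition"] = condition
    out.attrs["mode"] = mode
    return out
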