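"""General cognitive ability (g) as the first unrotated principal component.

Each cohort's battery of cognitive subtests is reduced to a single score:
tests are standardized, the first eigenvector of their correlation matrix
gives the loadings, and the projection — re-standardized to unit variance
— is g.  The sign is fixed so the loadings sum positive (higher g =
better average performance); timed tests, where smaller is better, should
be log-transformed but not negated, since the loading absorbs direction.
The proportion of battery variance explained by g is lambda_1 / K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TestSpec:
    """One battery entry: output name, source columns, transform tag.

    ``transform`` is ``"identity"`` (single column passed through) or
    ``"log_mean_time"`` (log of the mean of the source time columns, the
    convention for repeated timed trail-making-style tests).
    """

    name: str
    columns: tuple
    transform: str = "identity"


def preprocess_tests(
    raw: pd.DataFrame, specs: list[TestSpec]
) -> tuple[pd.DataFrame, int]:
    """Apply per-test transforms and listwise-delete incomplete rows.

    Returns the battery (one column per test plus ``iid`` if present) and
    the number of deleted rows.
    """
    out = pd.DataFrame(index=raw.index)
    if "iid" in raw.columns:
        out["iid"] = raw["iid"]
    for spec in specs:
        cols = raw[list(spec.columns)]
        if spec.transform == "identity":
            if len(spec.columns) != 1:
                raise ValueError(f"identity transform takes one column: {spec.name}")
            out[spec.name] = cols.iloc[:, 0]
        elif spec.transform == "log_mean_time":
            mean_time = cols.mean(axis=1)
            if (mean_time.dropna() <= 0).any():
                raise ValueError(
                    f"non-positive time under log transform for test {spec.name}"
                )
            out[spec.name] = np.log(mean_time)
        else:
            raise ValueError(f"unknown transform {spec.transform!r}")
    complete = out.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    return out[complete].reset_index(drop=True), n_dropped


class GScorePCA:
    """First-unrotated-PC scorer for a cognitive battery.

    Fitted attributes: ``loadings_`` (per-test weights on the correlation
    matrix's first eigenvector, sign-fixed so they sum positive),
    ``proportion_variance_`` (lambda_1 / K), ``means_`` and ``scales_``
    used for standardization.  ``transform`` returns g standardized to
    unit variance over the fitted sample.
    """

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, scores: np.ndarray | pd.DataFrame, y=None):
        X = np.asarray(scores, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need at least two tests")
        if X.shape[0] < 3:
            raise ValueError("need at least three complete individuals")
        if np.isnan(X).any():
            raise ValueError("battery contains missing values; preprocess first")
        self.means_ = X.mean(axis=0)
        self.scales_ = X.std(axis=0)
        if np.any(self.scales_ == 0):
            raise ValueError("constant test column (zero variance)")
        Z = (X - self.means_) / self.scales_
        corr = np.corrcoef(Z, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        lead = eigvecs[:, -1]
        if lead.sum() < 0:
            lead = -lead
        self.loadings_ = lead
        self.proportion_variance_ = float(eigvals[-1] / X.shape[1])
        raw = Z @ lead
        self._g_scale = raw.std()
        return self

    def transform(self, scores: np.ndarray | pd.DataFrame) -> np.ndarray:
        Z = (np.asarray(scores, dtype=float) - self.means_) / self.scales_
        return (Z @ self.loadings_) / self._g_scale

    def fit_transform(self, scores, y=None) -> np.ndarray:
        return self.fit(scores).transform(scores)


@dataclass
class GScore:
    """Standardized g values with the loadings that produced them."""

    g: np.ndarray
    proportion_variance_explained: float
    loadings: np.ndarray
    iids: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        iids = self.iids if self.iids is not None else np.arange(len(self.g))
        return pd.DataFrame({"iid": iids, "g": self.g})

    def loadings_frame(self, test_names) -> pd.DataFrame:
        return pd.DataFrame({"test": list(test_names), "loading": self.loadings})


def derive_g(battery: pd.DataFrame) -> GScore:
    """g from a complete battery table (non-test column ``iid`` allowed)."""
    iids = battery["iid"].to_numpy() if "iid" in battery.columns else None
    tests = battery.drop(columns=["iid"], errors="ignore")
    model = GScorePCA().fit(tests)
    return GScore(
        g=model.transform(tests),
        proportion_variance_explained=model.proportion_variance_,
        loadings=model.loadings_,
        iids=iids,
    )
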