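"""Monte-Carlo Shapley attribution by permutation sampling.

The Shapley value of feature i for a prediction f(x) relative to a
baseline b is the average, over orderings of the features, of the change
in f when feature i switches from its baseline to its observed value
given the features before it in the ordering have already switched.
Sampling random orderings gives an unbiased estimate; because each
sampled ordering telescopes from f(b) to f(x), the per-subject
attributions sum exactly to f(x) - f(b) (the efficiency axiom holds for
the estimator, not just in expectation).

The default baseline is the train-split median vector (a single
background point); a k-sample background averages attributions over
several baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AttributionReport", "shapley_attribution"]


@dataclass
class AttributionReport:
    """Per-subject, per-feature Shapley estimates."""

    values: pd.DataFrame            # subjects x features
    baseline_prediction: float
    predictions: pd.Series
    mc_se: pd.DataFrame             # Monte-Carlo standard errors
    n_samples: int

    def ranking(self) -> pd.Series:
        """Features ordered by global importance (mean |value|)."""
        return self.values.abs().mean().sort_values(ascending=False)

    def efficiency_gap(self) -> pd.Series:
        """Per-subject |sum(attributions) - (prediction - baseline)|."""
        return (self.values.sum(axis=1)
                - (self.predictions - self.baseline_prediction)).abs()


def shapley_attribution(predict, x: pd.DataFrame,
                        background: np.ndarray | pd.Series | pd.DataFrame,
                        n_samples: int = 200,
                        seed: int = 0) -> AttributionReport:
    """Permutation-sampling Shapley estimates for each row of ``x``.

    Parameters
    ----------
    predict
        Callable mapping an (n, p) array to a 1-d score (e.g. the positive-
        class probability).
    x
        Subjects x features frame to explain.
    background
        Baseline vector (single reference) or frame of reference rows;
        with several rows attributions are averaged over them.
    n_samples
        Permutations sampled per (subject, background) pair.  Fewer than
        2x the feature count triggers a high-variance warning.
    """
    feats = list(x.columns)
    p = len(feats)
    if n_samples < 2 * p:
        warnings.warn(f"n_samples={n_samples} < 2x feature count ({p}); "
                      "Monte-Carlo variance will be high", RuntimeWarning)
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[1] != p:
        raise ValueError("background and x have different feature counts")
    rng = np.random.default_rng(seed)
    xv = x.to_numpy(dtype=float)
    n = xv.shape[0]

    phi = np.zeros((n, p))
    phi_sq = np.zeros((n, p))
    base_pred = float(np.mean(predict(bg)))
    for b in bg:
        for _ in range(n_samples):
            order = rng.permutation(p)
            cur = np.tile(b, (n, 1))
            prev = predict(cur)
            for j in order:
                cur[:, j] = xv[:, j]
                new = predict(cur)
                contrib = new - prev
                phi[:, j] += contrib
                phi_sq[:, j] += contrib ** 2
                prev = new
    total = len(bg) * n_samples
    phi /= total
    var = phi_sq / total - phi ** 2
    se = np.sqrt(np.clip(var, 0, None) / total)

    preds = predict(xv)
    return AttributionReport(
        values=pd.DataFrame(phi, index=x.index, columns=feats),
        baseline_prediction=base_pred,
        predictions=pd.Series(np.asarray(preds, dtype=float), index=x.index),
        mc_se=pd.DataFrame(se, index=x.index, columns=feats),
        n_samples=n_samples)
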