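"""Model-agnostic Shapley attributions by permutation sampling.

For a sample x the coalition value is v(S) = E_b[f(x_S, b_{S^c})], the
model output with features in S taken from x and the rest from a background
(reference) row b, averaged over the background set.  Walking a random
feature permutation from the empty to the full coalition and crediting each
feature its marginal gain gives attributions that telescope exactly to
f(x) - base_value for every permutation, so the local-accuracy identity
base + sum(phi) = f(x) holds to floating-point precision regardless of the
number of permutations; averaging permutations only reduces the variance of
the per-feature split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Attribution", "shapley_attributions", "summary_ranking",
           "plot_summary"]


@dataclass
class Attribution:
    """Per-sample, per-feature Shapley values for a model's probability output."""

    values: np.ndarray          # (n_samples, n_features)
    base_value: float           # mean model output over the background set
    model_outputs: np.ndarray   # (n_samples,) f(x) for each explained sample
    feature_names: list[str]
    samples: np.ndarray         # the explained feature matrix

    def local_accuracy_error(self) -> np.ndarray:
        """|base + sum(phi) - f(x)| per sample; ~0 by construction."""
        return np.abs(self.base_value + self.values.sum(axis=1)
                      - self.model_outputs)


def shapley_attributions(predict: Callable[[np.ndarray], np.ndarray],
                         background: np.ndarray, samples: np.ndarray,
                         feature_names: Sequence[str] | None = None,
                         n_permutations: int = 10, seed: int = 0) -> Attribution:
    """Permutation-sampling Shapley estimates for each row of ``samples``.

    ``predict`` maps an (n, d) array to n scalar outputs (e.g. class-1
    probability).  ``background`` supplies the reference distribution from
    the training fold.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("empty background set")
    n_samples, d = samples.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(d)]
    rng = np.random.default_rng(seed)
    # antithetic sampling: every permutation is paired with its reverse,
    # which cancels first-order order effects (and makes d = 2 exact)
    perms = []
    for _ in range(max(1, n_permutations // 2)):
        p = rng.permutation(d)
        perms.extend([p, p[::-1]])
    n_walks = len(perms)

    base = float(predict(background).mean())
    n_bg = background.shape[0]
    values = np.zeros((n_samples, d))
    for s in range(n_samples):
        x = samples[s]
        for perm in perms:
            # coalition k uses x for perm[:k]; stack all d+1 coalitions so
            # the model is called once per permutation
            coal = np.tile(background, (d + 1, 1, 1))
            for k in range(1, d + 1):
                coal[k:, :, perm[k - 1]] = x[perm[k - 1]]
            v = predict(coal.reshape(-1, d)).reshape(d + 1, n_bg).mean(axis=1)
            values[s, perm] += np.diff(v) / n_walks
    outputs = predict(samples)
    return Attribution(values=values, base_value=base, model_outputs=outputs,
                       feature_names=list(feature_names), samples=samples)


def summary_ranking(attribution: Attribution) -> pd.DataFrame:
    """Features ordered by mean |Shapley value| across samples, descending."""
    mean_abs = np.abs(attribution.values).mean(axis=0)
    df = pd.DataFrame({"feature": attribution.feature_names,
                       "mean_abs_shap": mean_abs})
    return df.sort_values("mean_abs_shap", ascending=False,
                          kind="stable").reset_index(drop=True)


def plot_summary(attribution: Attribution, path: str | None = None,
                 max_features: int = 20):
    """Beeswarm-style summary: one jittered row per feature, colored by
    the (standardized) feature value, most important on top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranking = summary_ranking(attribution).head(max_features)
    order = [attribution.feature_names.index(f) for f in ranking["feature"]]
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(order) + 1.5))
    for row, idx in enumerate(reversed(order)):
        phi = attribution.values[:, idx]
        feat = attribution.samples[:, idx]
        spread = feat.std()
        color = (feat - feat.mean()) / spread if spread > 0 else np.zeros_like(feat)
        y = row + rng.uniform(-0.25, 0.25, phi.size)
        ax.scatter(phi, y, c=np.clip(color, -2, 2), cmap="coolwarm",
                   s=14, alpha=0.8)
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(list(reversed(ranking["feature"].tolist())), fontsize=7)
    ax.set_xlabel("Shapley value (impact on P(low quality))")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
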