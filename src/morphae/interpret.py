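"""Shapley-value feature attribution and population mean-|SHAP| rankings.

A prediction f(x) is decomposed as base_value + sum_i phi_i, where phi_i is
feature i's Shapley value: its average marginal contribution over feature
coalitions.  Absent features are marginalized against a fixed background
sample (marginal-expectation convention), so the coalition value is

    v(S) = mean_{b in background} f(x_S joined with b_{not S})

Two estimators are provided:

* ``exact_enumeration`` — averages over all 2^(m-1) coalitions per feature;
  feasible for m <= 12 and exact (local accuracy, symmetry and the dummy
  axiom hold to machine precision);
* ``sampling`` — averages marginal contributions along random feature
  permutations; unbiased for the same estimand, and the per-permutation
  telescoping sum keeps local accuracy exact up to background averaging.

The population importance statistic is the mean of |phi_i| over subjects,
ranked descending (ties broken lexicographically by feature name); subgroup
rankings recompute it per covariate level.  Attributions are computed on
the standardized-outcome scale of the fitted models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import CohortTable

__all__ = [
    "shapley_attribution",
    "population_importance",
    "subgroup_importance",
    "ShapReport",
    "select_background",
]

_MAX_EXACT_FEATURES = 12


def select_background(X_train: np.ndarray, size: int = 100, seed: int = 0) -> np.ndarray:
    """Seeded subsample of the training features used as the reference set."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    n = X_train.shape[0]
    if n == 0:
        raise ValueError("empty background source")
    if size >= n:
        return X_train.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=size, replace=False)
    return X_train[idx]


def _coalition_values_exact(predict_fn, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """v(S) for every coalition mask 0..2^m-1, background-marginalized."""
    B, m = background.shape
    values = np.empty(2**m)
    # chunk masks so the stacked prediction batch stays modest
    chunk = max(1, 2**16 // max(B, 1))
    bits = 1 << np.arange(m)
    for start in range(0, 2**m, chunk):
        masks = np.arange(start, min(start + chunk, 2**m))
        ind = ((masks[:, None] & bits[None, :]) > 0).astype(float)  # (n_masks, m)
        data = background[None, :, :] * (1.0 - ind[:, None, :]) + x[None, None, :] * ind[:, None, :]
        preds = np.asarray(predict_fn(data.reshape(-1, m)), dtype=float).reshape(len(masks), B)
        values[masks] = preds.mean(axis=1)
    return values


def _exact_shapley(predict_fn, background: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    B, m = background.shape
    if m > _MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration is limited to {_MAX_EXACT_FEATURES} features (got {m}); "
            "use estimator='sampling'"
        )
    v = _coalition_values_exact(predict_fn, background, x)
    masks = np.arange(2**m)
    sizes = np.array([bin(mask).count("1") for mask in masks])
    fact = [math.factorial(i) for i in range(m + 1)]
    weights = np.array([fact[s] * fact[m - 1 - s] / fact[m] if s < m else 0.0 for s in range(m + 1)])
    phi = np.zeros(m)
    for i in range(m):
        bit = 1 << i
        without = masks[(masks & bit) == 0]
        phi[i] = np.sum(weights[sizes[without]] * (v[without | bit] - v[without]))
    return phi, float(v[0])


def _sampling_shapley(
    predict_fn,
    background: np.ndarray,
    x: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling estimator; common value function as exact."""
    B, m = background.shape
    phi = np.zeros(m)
    base = float(np.mean(np.asarray(predict_fn(background), dtype=float)))
    for _ in range(n_permutations):
        perm = rng.permutation(m)
        # indicator of x-features present after each of the m+1 steps
        ind = np.zeros((m + 1, m))
        for t, j in enumerate(perm):
            ind[t + 1 :, j] = 1.0
        data = background[None, :, :] * (1.0 - ind[:, None, :]) + x[None, None, :] * ind[:, None, :]
        preds = np.asarray(predict_fn(data.reshape(-1, m)), dtype=float).reshape(m + 1, B)
        v = preds.mean(axis=1)
        phi[perm] += v[1:] - v[:-1]
    return phi / n_permutations, base


def shapley_attribution(
    predict_fn,
    background: np.ndarray,
    instance: np.ndarray,
    estimator: str = "exact_enumeration",
    n_permutations: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-feature Shapley attributions and the base value for one instance.

    ``predict_fn`` maps an (n, m) array to n scalar predictions.  Returns
    ``(phi, base_value)`` with ``base_value + phi.sum()`` equal to the
    model's background-averaged prediction at ``instance`` (exactly for
    enumeration, and exactly up to the shared background for sampling).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(instance, dtype=float).ravel()
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    if background.shape[1] != x.size:
        raise ValueError(f"instance has {x.size} features but background has {background.shape[1]}")
    if estimator == "exact_enumeration":
        return _exact_shapley(predict_fn, background, x)
    if estimator == "sampling":
        rng = np.random.default_rng(seed)
        return _sampling_shapley(predict_fn, background, x, n_permutations, rng)
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class ShapReport:
    """Per-subject attributions plus the population mean-|SHAP| ranking."""

    subject_ids: list[str]
    feature_names: list[str]
    attributions: np.ndarray  # (n_subjects, n_features)
    base_value: float
    estimator: str
    n_coalition_samples: int
    background_size: int
    seed: int
    mean_abs_shap: np.ndarray = field(init=False)
    ranking: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.mean_abs_shap = np.mean(np.abs(self.attributions), axis=0)
        order = sorted(
            range(len(self.feature_names)),
            key=lambda j: (-self.mean_abs_shap[j], self.feature_names[j]),
        )
        self.ranking = [self.feature_names[j] for j in order]

    def top_k(self, k: int) -> list[tuple[str, float]]:
        if k > len(self.feature_names):
            raise ValueError(f"k={k} exceeds the {len(self.feature_names)} available features")
        by_name = dict(zip(self.feature_names, self.mean_abs_shap))
        return [(name, float(by_name[name])) for name in self.ranking[:k]]

    def to_csv(self, path: str) -> None:
        frame = pd.DataFrame(self.attributions, columns=self.feature_names)
        frame.insert(0, "subject_id", self.subject_ids)
        frame.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "base_value": self.base_value,
                    "estimator": self.estimator,
                    "n_coalition_samples": self.n_coalition_samples,
                    "background_size": self.background_size,
                    "seed": self.seed,
                    "mean_abs_shap": dict(zip(self.feature_names, map(float, self.mean_abs_shap))),
                    "ranking": self.ranking,
                },
                fh,
                indent=1,
            )


def population_importance(
    predict_fn,
    X_subjects: np.ndarray,
    feature_names: list[str],
    background: np.ndarray,
    subject_ids: list[str] | None = None,
    estimator: str = "sampling",
    n_permutations: int = 20,
    seed: int = 0,
) -> ShapReport:
    """Attribute every subject and rank features by population mean |phi|.

    Permutations are redrawn per subject from a seeded stream, so the report
    is deterministic for a fixed seed.
    """
    X_subjects = np.atleast_2d(np.asarray(X_subjects, dtype=float))
    if X_subjects.shape[0] == 0:
        raise ValueError("empty subject set")
    if X_subjects.shape[1] != len(feature_names):
        raise ValueError("feature_names does not match the subject matrix width")
    rng = np.random.default_rng(seed)
    attribs = np.empty_like(X_subjects)
    base = float(np.mean(np.asarray(predict_fn(np.atleast_2d(background)), dtype=float)))
    for i, x in enumerate(X_subjects):
        try:
            if estimator == "exact_enumeration":
                attribs[i], _ = _exact_shapley(predict_fn, np.atleast_2d(background), x)
            elif estimator == "sampling":
                attribs[i], _ = _sampling_shapley(
                    predict_fn, np.atleast_2d(background), x, n_permutations, rng
                )
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
        except ValueError:
            raise
        except Exception as err:  # attach the subject for debugging
            sid = subject_ids[i] if subject_ids else str(i)
            raise RuntimeError(f"attribution failed for subject {sid}: {err}") from err
    ids = list(subject_ids) if subject_ids is not None else [str(i) for i in range(len(X_subjects))]
    return ShapReport(
        ids, list(feature_names), attribs, base, estimator,
        n_permutations if estimator == "sampling" else 2 ** len(feature_names),
        int(np.atleast_2d(background).shape[0]), seed,
    )


def subgroup_importance(
    predict_fn,
    cohort: CohortTable,
    background: np.ndarray,
    covariate: str = "sex",
    top_k: int = 10,
    estimator: str = "sampling",
    n_permutations: int = 20,
    seed: int = 0,
) -> tuple[dict[str, ShapReport], int]:
    """Per-covariate-level rankings plus the top-k overlap count."""
    if covariate not in cohort.frame.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    if top_k > cohort.n_features:
        raise ValueError(f"top_k={top_k} exceeds the {cohort.n_features} features")
    reports: dict[str, ShapReport] = {}
    for g in sorted(cohort.frame[covariate].unique()):
        mask = (cohort.frame[covariate] == g).to_numpy()
        sub = cohort.subset(mask)
        reports[str(g)] = population_importance(
            predict_fn, sub.features, cohort.feature_names, background,
            subject_ids=list(sub.subject_ids), estimator=estimator,
            n_permutations=n_permutations, seed=seed,
        )
    groups = list(reports)
    overlap = top_k
    if len(groups) >= 2:
        sets = [set(reports[g].ranking[:top_k]) for g in groups[:2]]
        overlap = len(sets[0] & sets[1])
    return reports, overlap


def format_topk_table(report: ShapReport, k: int = 10, title: str = "") -> str:
    lines = [title] if title else []
    lines.append(f"{'feature':<40}{'mean |SHAP|':>14}")
    for name, val in report.top_k(k):
        lines.append(f"{name:<40}{val:>14.4f}")
    return "\n".join(lines)
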