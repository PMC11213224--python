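"""Metrics, bootstrap uncertainty, subgroup evaluation, PCC comparison.

Performance is summarized by MSE on the original outcome scale and by the
Pearson correlation (PCC) between predicted and true scores.  Uncertainty
comes from resampling subjects with replacement (default 100 resamples);
the "+/-" of a report row is the bootstrap SD of the metric, with a
percentile 95% CI carried alongside.

Two subgroup PCCs are compared with the two-sample statistic

    t = (r1 - r2) / sqrt(s1^2/n1 + s2^2/n2)

with a two-sided p-value from a standard normal.  In the textbook
two-sample t-test s_i is the *subject-level* SD, whose division by
sqrt(n_i) yields the standard error of the group statistic.  The bootstrap
SD of a group's PCC already estimates that standard error directly, so
when groups are passed as EvalRows the comparison uses
s_i = sqrt(n_i) * bootstrapSD(r_i), making the denominator the proper
SE of r1 - r2.  (Substituting the bootstrap SD for s_i unconverted would
divide an SE by sqrt(n) a second time and reject almost always under the
null; callers supplying raw (r, s, n) tuples get the formula applied to
their s verbatim and own this choice.)  The standard Fisher-z two-sample
comparison is available as ``method="fisher_z"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mse",
    "pcc",
    "bootstrap_eval",
    "subgroup_eval",
    "compare_pcc",
    "EvalRow",
    "PccComparison",
    "evaluate_predictions",
    "format_performance_table",
]


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared prediction error, (1/N) sum (y - yhat)^2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError(f"length mismatch or empty input: {y_true.shape} vs {y_pred.shape}")
    return float(np.mean((y_true - y_pred) ** 2))


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("pcc needs two equal-length vectors of length >= 3")
    da, db = a - a.mean(), b - b.mean()
    denom = math.sqrt(float(np.sum(da * da)) * float(np.sum(db * db)))
    if denom == 0:
        raise ValueError("pcc undefined for a constant input")
    return float(np.sum(da * db) / denom)


@dataclass
class EvalRow:
    """Point and bootstrap summaries of one model x split x subgroup cell."""

    model: str
    split: str
    subgroup: str  # all / male / female
    n: int
    mse_point: float
    pcc_point: float
    mse_boot_mean: float
    mse_boot_sd: float
    pcc_boot_mean: float
    pcc_boot_sd: float
    mse_ci95: tuple[float, float]
    pcc_ci95: tuple[float, float]
    n_boot: int
    boot_seed: int
    n_skipped_resamples: int = 0


def bootstrap_eval(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    model: str = "model",
    split: str = "test",
    subgroup: str = "all",
) -> EvalRow:
    """Bootstrap-the-subjects uncertainty for MSE and PCC.

    Resamples with constant y_true (PCC undefined) are skipped and counted.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = y_true.size
    if n < 10:
        raise ValueError("bootstrap_eval needs at least 10 subjects")
    rng = np.random.default_rng(seed)
    mses, pccs = [], []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yt, yp = y_true[idx], y_pred[idx]
        mses.append(mse(yt, yp))
        try:
            pccs.append(pcc(yt, yp))
        except ValueError:
            skipped += 1
    mses_a = np.asarray(mses)
    pccs_a = np.asarray(pccs) if pccs else np.asarray([float("nan")])
    return EvalRow(
        model=model,
        split=split,
        subgroup=subgroup,
        n=n,
        mse_point=mse(y_true, y_pred),
        pcc_point=pcc(y_true, y_pred),
        mse_boot_mean=float(mses_a.mean()),
        mse_boot_sd=float(mses_a.std(ddof=1)) if n_boot > 1 else 0.0,
        pcc_boot_mean=float(pccs_a.mean()),
        pcc_boot_sd=float(pccs_a.std(ddof=1)) if len(pccs) > 1 else 0.0,
        mse_ci95=(float(np.percentile(mses_a, 2.5)), float(np.percentile(mses_a, 97.5))),
        pcc_ci95=(float(np.percentile(pccs_a, 2.5)), float(np.percentile(pccs_a, 97.5))),
        n_boot=n_boot,
        boot_seed=seed,
        n_skipped_resamples=skipped,
    )


def subgroup_eval(
    predictions: pd.DataFrame,
    covariate: str = "sex",
    n_boot: int = 100,
    seed: int = 0,
    model: str = "model",
    split: str = "test",
) -> dict[str, EvalRow]:
    """Per-subgroup bootstrap evaluation of a prediction table.

    ``predictions`` needs columns y_true, y_pred and the covariate.  Groups
    with fewer than 10 subjects are omitted.
    """
    if covariate not in predictions.columns:
        raise ValueError(f"unknown covariate column {covariate!r}")
    rows: dict[str, EvalRow] = {}
    for g, sub in predictions.groupby(covariate, sort=True):
        if len(sub) < 10:
            continue
        rows[str(g)] = bootstrap_eval(
            sub["y_true"].to_numpy(), sub["y_pred"].to_numpy(),
            n_boot=n_boot, seed=seed, model=model, split=split, subgroup=str(g),
        )
    return rows


@dataclass
class PccComparison:
    """Two-group PCC difference statistic."""

    r1: float
    r2: float
    s1: float
    s2: float
    n1: int
    n2: int
    t: float
    p: float
    method: str


def compare_pcc(
    group1: EvalRow | tuple[float, float, int],
    group2: EvalRow | tuple[float, float, int],
    method: str = "paper",
) -> PccComparison:
    """Compare two subgroup PCCs.

    ``method="paper"`` uses t = (r1-r2)/sqrt(s1^2/n1 + s2^2/n2) with a
    two-sided normal p-value.  An EvalRow group contributes
    s_i = sqrt(n_i) * (bootstrap SD of its PCC), so that s_i^2/n_i is the
    squared SE of r_i (see module docstring); a raw (r, s, n) tuple is
    substituted verbatim.  ``method="fisher_z"`` uses the standard
    two-sample comparison of Fisher-transformed correlations,
    z = (z1-z2)/sqrt(1/(n1-3)+1/(n2-3)) (s_i unused).
    """

    def unpack(g):
        if isinstance(g, EvalRow):
            return g.pcc_point, g.pcc_boot_sd * math.sqrt(g.n), g.n
        return g

    r1, s1, n1 = unpack(group1)
    r2, s2, n2 = unpack(group2)
    if n1 < 3 or n2 < 3:
        raise ValueError("both groups need n >= 3")
    if method == "paper":
        if s1 <= 0 or s2 <= 0:
            raise ValueError("degenerate bootstrap: group PCC SD is zero")
        t = (r1 - r2) / math.sqrt(s1**2 / n1 + s2**2 / n2)
    elif method == "fisher_z":
        if n1 < 4 or n2 < 4:
            raise ValueError("fisher_z needs n >= 4 in both groups")
        z1, z2 = math.atanh(r1), math.atanh(r2)
        t = (z1 - z2) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = 2.0 * float(stats.norm.sf(abs(t)))
    return PccComparison(r1, r2, s1, s2, n1, n2, float(t), p, method)


# ---------------------------------------------------------------- reporting


def evaluate_predictions(
    predictions: pd.DataFrame, n_boot: int = 100, seed: int = 0
) -> list[EvalRow]:
    """Full report: every model x split, overall and per sex where present."""
    rows: list[EvalRow] = []
    for (model, split), sub in predictions.groupby(["model", "split"], sort=True):
        rows.append(
            bootstrap_eval(
                sub["y_true"].to_numpy(), sub["y_pred"].to_numpy(),
                n_boot=n_boot, seed=seed, model=str(model), split=str(split),
            )
        )
        if "sex" in sub.columns:
            rows.extend(
                subgroup_eval(sub, "sex", n_boot=n_boot, seed=seed, model=str(model), split=str(split)).values()
            )
    return rows


def rows_to_frame(rows: list[EvalRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        d = asdict(r)
        d["mse_ci95_lo"], d["mse_ci95_hi"] = d.pop("mse_ci95")
        d["pcc_ci95_lo"], d["pcc_ci95_hi"] = d.pop("pcc_ci95")
        recs.append(d)
    return pd.DataFrame(recs)


def format_performance_table(rows: list[EvalRow]) -> str:
    """Text table: model x split with 'point +/- bootstrap SD' cells."""
    models = sorted({r.model for r in rows})
    splits = [s for s in ("train", "val", "test") if any(r.split == s for r in rows)]
    by = {(r.model, r.split): r for r in rows if r.subgroup == "all"}
    lines = [f"{'model':<18}" + "".join(f"{s + ' PCC':>18}{s + ' MSE':>20}" for s in splits)]
    for m in models:
        cells = []
        for s in splits:
            r = by.get((m, s))
            if r is None:
                cells.append(f"{'—':>18}{'—':>20}")
            else:
                cells.append(
                    f"{r.pcc_point:8.3f} ±{r.pcc_boot_sd:5.3f} {r.mse_point:10.3f} ±{r.mse_boot_sd:6.3f}"
                )
        lines.append(f"{m:<18}" + "".join(cells))
    return "\n".join(lines)


def save_report(rows: list[EvalRow], csv_path: str, json_path: str | None = None) -> None:
    frame = rows_to_frame(rows)
    frame.to_csv(csv_path, index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1)
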