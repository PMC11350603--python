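"""Counting metrics and comparison-report arithmetic.

Counts are read off a density map by plain summation (the integral of the
density), kept real-valued — no rounding — before the error metrics:

    MAE  = mean_i |P_i - G_i|
    RMSE = sqrt(mean_i (P_i - G_i)^2)

The comparison report reproduces the percentage-reduction and absolute-
difference narrative around published benchmark tables:
reduction = 100 (baseline - improved) / baseline, printed to two decimals
with round-half-up.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .density_maps import DensityMap

__all__ = ["EvalResult", "count_from_density", "compute_metrics",
           "percent_reduction", "round_half_up", "load_benchmark_table",
           "comparison_report"]


@dataclass
class EvalResult:
    per_image: list            # (image_id, predicted P_i, ground truth G_i)
    mae: float
    rmse: float


def count_from_density(density: DensityMap | np.ndarray) -> float:
    """Predicted count = sum over the density grid."""
    values = density.values if isinstance(density, DensityMap) else np.asarray(density)
    return float(values.sum())


def compute_metrics(pairs) -> EvalResult:
    """MAE and RMSE over (predicted, ground-truth) count pairs.

    Accepts (P, G) pairs or (image_id, P, G) triples.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot compute metrics over an empty list")
    per_image = []
    for item in pairs:
        if len(item) == 2:
            per_image.append((None, float(item[0]), float(item[1])))
        else:
            per_image.append((item[0], float(item[1]), float(item[2])))
    err = np.array([p - g for _, p, g in per_image])
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    return EvalResult(per_image=per_image, mae=mae, rmse=rmse)


def round_half_up(x: float, decimals: int = 2) -> float:
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent_reduction(baseline: float, improved: float) -> float:
    """100 (baseline - improved) / baseline, two decimals, round-half-up."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round_half_up(100.0 * (baseline - improved) / baseline)


def load_benchmark_table(name: str) -> pd.DataFrame:
    """Load a bundled benchmark table (columns: model, setting, mae, rmse).

    Bundled tables: 'fully_supervised', 'semi_supervised', 'ablation'.
    """
    path = resources.files("shootcount").joinpath(f"tables/{name}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def _lookup(table: pd.DataFrame, model: str, setting: str | None, metric: str) -> float:
    rows = table[table["model"] == model]
    if setting is not None:
        rows = rows[rows["setting"] == setting]
    if len(rows) != 1:
        raise KeyError(f"row not found (or ambiguous): model={model!r} setting={setting!r}")
    return float(rows.iloc[0][metric])


def comparison_report(table: pd.DataFrame, comparisons) -> pd.DataFrame:
    """Compute reductions/differences between table rows.

    ``comparisons`` is an iterable of dicts with keys
    ``baseline_model, baseline_setting, improved_model, improved_setting,
    metric, kind`` where kind is 'reduction' (percent) or 'difference'
    (absolute, two decimals).  Returns a DataFrame; missing rows raise.
    """
    records = []
    for cmp_spec in comparisons:
        metric = cmp_spec["metric"]
        base = _lookup(table, cmp_spec["baseline_model"],
                       cmp_spec.get("baseline_setting"), metric)
        improved = _lookup(table, cmp_spec["improved_model"],
                           cmp_spec.get("improved_setting"), metric)
        if cmp_spec.get("kind", "reduction") == "reduction":
            value = percent_reduction(base, improved)
        else:
            value = round_half_up(abs(improved - base))
        records.append({**cmp_spec, "baseline_value": base,
                        "improved_value": improved, "value": value})
    return pd.DataFrame(records)
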