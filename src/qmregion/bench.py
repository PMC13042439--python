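"""Model-vs-reference comparison tables and rank agreement with experiment.

Deviation tables reproduce the convention of reporting each QM-region
model's value with its signed deviation (model - reference) from the all-QM
reference in parentheses; rank agreement between computed binding energies
and experimental activities (e.g. pIC50) uses Spearman or Kendall rank
correlation with average-rank tie handling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DeviationTable", "ActivitySeries", "model_comparison", "rank_agreement"]

#: Marker for a label a model did not report.
GAP = float("nan")


@dataclass
class DeviationTable:
    values: pd.DataFrame       # rows: labels; columns: models
    deviations: pd.DataFrame   # model - reference, same shape
    reference: str
    units: str = ""

    def to_tsv(self, path=None) -> str:
        merged = pd.concat(
            {"value": self.values, "deviation": self.deviations}, axis=1
        )
        merged.columns = [f"{m}_{k}" for k, m in merged.columns]
        buf = io.StringIO()
        merged.to_csv(buf, sep="\t", float_format="%.10g")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        """Aligned report: value with the deviation in parentheses beneath."""
        models = list(self.values.columns)
        width = max(12, *(len(m) + 2 for m in models))
        lines = ["".join(["label".ljust(12)] + [m.rjust(width) for m in models])]
        for label in self.values.index:
            vals = "".join(
                ["" .ljust(0)]
                + [f"{self.values.at[label, m]:.2f}".rjust(width) for m in models]
            )
            devs = "".join(
                f"({self.deviations.at[label, m]:+.2f})".rjust(width)
                if m != self.reference and np.isfinite(self.deviations.at[label, m])
                else "".rjust(width)
                for m in models
            )
            lines.append(str(label).ljust(12) + vals)
            lines.append(" " * 12 + devs)
        if self.units:
            lines.append(f"[{self.units}]")
        return "\n".join(lines)


def model_comparison(
    values: dict[str, dict[str, float]],
    reference_model: str,
    units: str = "",
) -> DeviationTable:
    """Signed deviations of each model from the reference, per label.

    ``values`` maps model name -> {label: value}.  The reference model must
    report every label appearing anywhere; a label missing for another
    model shows an explicit gap (NaN), never a silent omission.
    """
    if reference_model not in values:
        raise KeyError(f"reference model {reference_model!r} not in values")
    labels: list[str] = []
    for m in values:
        for lab in values[m]:
            if lab not in labels:
                labels.append(lab)
    missing_ref = [lab for lab in labels if lab not in values[reference_model]]
    if missing_ref:
        raise ValueError(
            f"reference model lacks labels {missing_ref}"
        )
    models = list(values)
    vals = pd.DataFrame(
        [[values[m].get(lab, GAP) for m in models] for lab in labels],
        index=labels,
        columns=models,
        dtype=float,
    )
    devs = vals.sub(vals[reference_model], axis=0)
    return DeviationTable(values=vals, deviations=devs, reference=reference_model, units=units)


@dataclass
class ActivitySeries:
    labels: list[str]
    activities: list[float]     # experimental, e.g. pIC50
    computed: list[float]       # e.g. binding energies, kcal/mol

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.activities) == len(self.computed)):
            raise ValueError("labels, activities and computed lengths differ")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")


def rank_agreement(series: ActivitySeries, method: str = "spearman") -> float:
    """Rank correlation between computed and experimental values in [-1, 1]."""
    if len(series.labels) < 3:
        raise ValueError("need at least 3 points for a rank coefficient")
    x = np.asarray(series.activities, float)
    y = np.asarray(series.computed, float)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values in activity series")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant column: rank coefficient undefined")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
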