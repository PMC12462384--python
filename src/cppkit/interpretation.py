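"""Interpretability reports: top importances, per-block contributions,
class frequency/mean ratios, the pI vs net-charge table, and
misclassification distribution summaries.

All outputs are tidy tables (DataFrames), pure functions of their inputs,
so reports are reproducible and testable headless; plotting is left to the
caller.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._tables import GROUP_ALIASES
from .errors import (
    CppkitError,
    LengthMismatchError,
    MissingFeatureError,
    SingleClassError,
    UnmappedFeatureError,
)
from .matrix import FeatureMatrix
from .selection import SelectionReport

__all__ = [
    "block_map",
    "display_name",
    "top_importances",
    "block_contributions",
    "class_ratio",
    "physchem_scatter",
    "misclassification_profile",
]

_PHYSCHEM = {"isoelectric_point", "net_charge", "gravy", "hydrophobicity", "mass"}
_ATOMIC = {"normnC", "normnH", "normnN", "normnO", "normnS"}


def block_map(names: list[str]) -> dict[str, str]:
    """Assign every feature name to its descriptor block, mechanically from
    the ``BLOCK_subscript`` naming scheme."""
    mapping: dict[str, str] = {}
    for name in names:
        if name.startswith("AAC_"):
            mapping[name] = "AAC"
        elif name.startswith("DPC_"):
            mapping[name] = "dipeptides"
        elif name.startswith("TPC_"):
            mapping[name] = "tripeptides"
        elif name.startswith("CKSAAGP_"):
            mapping[name] = "CKSAAGP"
        elif name in _PHYSCHEM:
            mapping[name] = "physicochemical"
        elif name in _ATOMIC:
            mapping[name] = "atomic"
        elif name == "length":
            mapping[name] = "length"
        else:
            raise UnmappedFeatureError(f"cannot assign {name!r} to a block")
    return mapping


def display_name(name: str) -> str:
    """Report-facing alias: group-pair features collapse the two hydrophobic
    groups to 'H' (e.g. ``CKSAAGP_k1_ALI.PC`` -> ``k1 H_PC``)."""
    if not name.startswith("CKSAAGP_"):
        return name
    _, gap, pair = name.split("_", 2)
    g1, g2 = pair.split(".")
    return f"{gap} {GROUP_ALIASES.get(g1, g1)}_{GROUP_ALIASES.get(g2, g2)}"


def top_importances(report: SelectionReport, k: int = 20) -> pd.DataFrame:
    """The k highest-importance features, descending, alphabetical tie-break."""
    if not report.importances:
        raise CppkitError("selection report has no importances")
    items = sorted(report.importances.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(items):
        warnings.warn(
            f"requested top {k} but only {len(items)} features have importances",
            stacklevel=2,
        )
        k = len(items)
    top = items[:k]
    return pd.DataFrame(
        {
            "feature": [n for n, _ in top],
            "display": [display_name(n) for n, _ in top],
            "importance": [v for _, v in top],
        }
    )


def block_contributions(
    report: SelectionReport, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Sum of normalized importances per descriptor block (totals 1)."""
    if not report.importances:
        raise CppkitError("selection report has no importances")
    names = list(report.importances)
    mapping = mapping if mapping is not None else block_map(names)
    missing = [n for n in names if n not in mapping]
    if missing:
        raise UnmappedFeatureError(f"unmapped features: {missing[:5]}")
    sums: dict[str, float] = {}
    for name, value in report.importances.items():
        sums[mapping[name]] = sums.get(mapping[name], 0.0) + value
    frame = pd.DataFrame(
        {"block": list(sums), "contribution": list(sums.values())}
    ).sort_values("contribution", ascending=False, ignore_index=True)
    return frame


def _class_rows(m: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if m.labels is None:
        raise SingleClassError("matrix carries no labels")
    pos = m.labels == 1
    neg = m.labels == 0
    if not pos.any() or not neg.any():
        raise SingleClassError("both classes must be non-empty")
    return pos, neg


def class_ratio(m: FeatureMatrix, features: list[str]) -> pd.DataFrame:
    """Per-feature ratio mean(positive rows) / mean(negative rows).

    A zero denominator flags the ratio as undefined (NaN + flag); no epsilon
    fudging.
    """
    pos, neg = _class_rows(m)
    rows = []
    for name in features:
        column = m.column(name)
        mean_pos = float(column[pos].mean())
        mean_neg = float(column[neg].mean())
        undefined = mean_neg == 0.0
        rows.append(
            {
                "feature": name,
                "mean_positive": mean_pos,
                "mean_negative": mean_neg,
                "ratio": np.nan if undefined else mean_pos / mean_neg,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)


def physchem_scatter(m: FeatureMatrix) -> pd.DataFrame:
    """Tidy (id, isoelectric_point, net_charge, label) table for the classic
    pI-vs-charge scatter; the pH 7 vertical reference marks the cationic
    boundary."""
    for required in ("isoelectric_point", "net_charge"):
        if required not in m.names:
            raise MissingFeatureError(f"matrix lacks {required!r}")
    frame = pd.DataFrame(
        {
            "id": m.ids,
            "isoelectric_point": m.column("isoelectric_point"),
            "net_charge": m.column("net_charge"),
        }
    )
    if m.labels is not None:
        frame["label"] = m.labels
    return frame


def misclassification_profile(
    m: FeatureMatrix,
    truth,
    predicted,
    features: list[str],
) -> pd.DataFrame:
    """Five-number summaries of each feature across the four truth x
    predicted cells.

    Empty cells (e.g. no false positives under a perfect classifier) appear
    with ``n = 0`` and NaN quartiles, explicitly flagged.
    """
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != (m.n_rows,) or predicted.shape != (m.n_rows,):
        raise LengthMismatchError("truth/predicted must align with matrix rows")
    rows = []
    for name in features:
        column = m.column(name)
        for t in (0, 1):
            for p in (0, 1):
                cell = column[(truth == t) & (predicted == p)]
                if cell.size:
                    q = np.percentile(cell, [0, 25, 50, 75, 100])
                else:
                    q = [np.nan] * 5
                rows.append(
                    {
                        "feature": name,
                        "truth": t,
                        "predicted": p,
                        "n": int(cell.size),
                        "empty": cell.size == 0,
                        "min": q[0],
                        "q1": q[1],
                        "median": q[2],
                        "q3": q[3],
                        "max": q[4],
                    }
                )
    return pd.DataFrame(rows)
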