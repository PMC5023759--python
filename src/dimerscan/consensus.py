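"""Normalization and consensus ranking of interface classes.

Two consensus methods rank the interface classes of a scored dimer
population:

* **value averaging** — per class, the mean normalized score of its
  members among the top-N dimers (N = 100 by default), combined over the
  four parameters as an unweighted mean;
* **frequency** — per parameter, the fraction of the top-N dimers that
  belong to each class, combined as the mean of the four per-parameter
  frequencies.

Normalization maps each parameter affinely to [0, 1] oriented so that 1
is better: energies are best at their minimum, interface area at its
maximum.  A "class top members" variant (per-class means over each
class's own best-N members) is available through ``per_class=True``; the
global-top-N reading is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import PARAMETERS

#: orientation of each scoring parameter: True if larger raw value is better
LARGER_IS_BETTER = {
    "interface_score": False,
    "interface_area": True,
    "dg_bind": False,
    "hbond_energy": False,
}


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        row = {"pose_id": r.pose_id, "class": r.class_label}
        for p in PARAMETERS:
            row[p] = getattr(r, p)
            if r.normalized and p in r.normalized:
                row[f"norm_{p}"] = r.normalized[p]
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_scores(records) -> pd.DataFrame:
    """Affine [0, 1] normalization of the four parameters, 1 = better.

    A parameter that is constant across the population carries no ranking
    information and is set to 0.5 everywhere.
    """
    df = records_to_frame(records)
    if len(df) < 2:
        raise ValueError("need at least 2 records to normalize")
    for p in PARAMETERS:
        vals = df[p].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-12:
            norm = np.full(len(vals), 0.5)
        elif LARGER_IS_BETTER[p]:
            norm = (vals - lo) / (hi - lo)
        else:
            norm = (hi - vals) / (hi - lo)
        df[f"norm_{p}"] = norm
    if not isinstance(records, pd.DataFrame):
        for r, (_, row) in zip(records, df.iterrows()):
            r.normalized = {p: float(row[f"norm_{p}"]) for p in PARAMETERS}
    return df


@dataclass
class ConsensusResult:
    """Per-class scores and rankings under one consensus method."""

    method: str                 # "values" or "frequency"
    top_n: int
    per_parameter: pd.DataFrame  # index: class, columns: parameters
    combined: pd.Series          # index: class
    ranking: list[str]           # classes, best first

    def rank_of(self, label: str) -> int:
        """1-based rank of a class (raises if the class never occurs)."""
        return self.ranking.index(label) + 1


def _require_normalized(df: pd.DataFrame) -> None:
    missing = [p for p in PARAMETERS if f"norm_{p}" not in df.columns]
    if missing:
        raise ValueError(f"records not normalized (missing {missing})")


def _top_subset(df: pd.DataFrame, column: str, top_n: int) -> pd.DataFrame:
    ordered = df.sort_values([column, "pose_id"], ascending=[False, True],
                             kind="mergesort")
    return ordered.head(top_n)


def consensus_by_values(records, top_n: int = 100,
                        per_class: bool = False) -> ConsensusResult:
    """Value-averaging consensus over the top-N dimers.

    Per parameter, classes are scored by the mean normalized value of
    their members within the global top-N (classes absent from the top-N
    score 0).  The combined consensus applies the same rule to the
    unweighted mean of the four normalized parameters.  With
    ``per_class=True`` the mean is instead taken over each class's own
    best ``top_n`` members.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = records_to_frame(records)
    _require_normalized(df)
    classes = sorted(df["class"].unique())
    df = df.copy()
    df["norm_combined"] = df[[f"norm_{p}" for p in PARAMETERS]].mean(axis=1)

    def class_means(column: str) -> pd.Series:
        if per_class:
            means = {c: _top_subset(df[df["class"] == c], column, top_n)[column].mean()
                     for c in classes}
            return pd.Series(means)
        sub = _top_subset(df, column, top_n)
        means = sub.groupby("class")[column].mean()
        return means.reindex(classes, fill_value=0.0)

    per_param = pd.DataFrame({p: class_means(f"norm_{p}") for p in PARAMETERS})
    combined = class_means("norm_combined")
    ranking = sorted(classes, key=lambda c: (-combined[c], c))
    return ConsensusResult("values", top_n, per_param, combined, ranking)


def consensus_by_frequency(records, top_n: int = 100) -> ConsensusResult:
    """Frequency consensus: class shares among the top-N per parameter.

    The per-parameter frequencies over classes each sum to 1; the combined
    score is their mean.  Ties are broken by the combined value consensus,
    then by label order.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = records_to_frame(records)
    _require_normalized(df)
    classes = sorted(df["class"].unique())

    def class_freq(column: str) -> pd.Series:
        sub = _top_subset(df, column, top_n)
        freq = sub["class"].value_counts() / len(sub)
        return freq.reindex(classes, fill_value=0.0)

    per_param = pd.DataFrame({p: class_freq(f"norm_{p}") for p in PARAMETERS})
    combined = per_param.mean(axis=1)
    value_combined = consensus_by_values(df, top_n=top_n).combined
    ranking = sorted(classes, key=lambda c: (-combined[c], -value_combined[c], c))
    return ConsensusResult("frequency", top_n, per_param, combined, ranking)


def rank_report(result: ConsensusResult, k: int = 3) -> pd.DataFrame:
    """Top-k class labels per parameter and for the combined consensus.

    One row per scoring parameter plus a combined row; columns
    ``rank1..rankk``.  If fewer classes exist than ``k``, rows are
    truncated without padding.
    """
    rows = []
    n_classes = len(result.ranking)
    kk = min(k, n_classes)
    for p in list(PARAMETERS) + ["combined"]:
        series = result.combined if p == "combined" else result.per_parameter[p]
        order = sorted(series.index, key=lambda c: (-series[c], c))[:kk]
        rows.append({"method": result.method, "parameter": p,
                     **{f"rank{i + 1}": lab for i, lab in enumerate(order)}})
    return pd.DataFrame(rows)


def report_to_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
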