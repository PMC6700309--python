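"""Treatment-vs-control percent differences and a permutation screen.

Summarises harvest tables into the trial's headline statistics: per-harvest,
average and cumulative percent differences of each amended treatment against
the unamended control, for dry and fresh aboveground biomass.

Significance screening uses a subject-level permutation test instead of
repeated-measures mixed models: each subject's harvest series is collapsed
to its total biomass, and treatment labels are permuted across subjects.
This is deliberately a lightweight substitute for REML factorial ANOVA —
exact under exchangeability of subjects, assumption-free about the noise
distribution, and adequate as a screen on balanced factorial designs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trial import combo_label

__all__ = [
    "MATTER_COLUMNS",
    "label_records",
    "percent_diff_per_harvest",
    "average_percent_diff",
    "cumulative_percent_diff",
    "EffectTable",
    "build_effect_table",
    "PermutationResult",
    "permutation_factorial_test",
]

MATTER_COLUMNS = {"dry": "dry_g", "fresh": "fresh_g"}


def _matter_col(matter_type: str) -> str:
    try:
        return MATTER_COLUMNS[matter_type]
    except KeyError:
        raise ValueError(f"matter_type must be 'dry' or 'fresh', got {matter_type!r}")


def label_records(records: pd.DataFrame) -> pd.Series:
    """Treatment label ('control', 'B', 'B+F', ...) for every record row."""
    return records.apply(
        lambda r: combo_label(bool(r["biochar"]), bool(r["fertilizer"]),
                              bool(r["inoculant"])),
        axis=1,
    )


def _harvest_means(records: pd.DataFrame, label: str, col: str) -> pd.Series:
    labels = label_records(records)
    sub = records.loc[labels == label]
    if sub.empty:
        kind = "control (reference)" if label == "control" else f"treatment {label!r}"
        raise ValueError(f"no records for {kind}")
    means = sub.groupby("harvest_index")[col].mean()
    expected = sorted(records["harvest_index"].unique())
    missing = [h for h in expected if h not in means.index]
    if missing:
        raise ValueError(f"{label!r} has empty harvest cells: {missing}")
    return means.reindex(expected)


def percent_diff_per_harvest(
    records: pd.DataFrame, treatment: str, matter_type: str = "dry"
) -> pd.Series:
    """100 x (mean_T(h) - mean_C(h)) / mean_C(h) for each harvest h."""
    col = _matter_col(matter_type)
    mean_t = _harvest_means(records, treatment, col)
    mean_c = _harvest_means(records, "control", col)
    out = 100.0 * (mean_t - mean_c) / mean_c
    out.name = treatment
    return out


def average_percent_diff(
    records: pd.DataFrame, treatment: str, matter_type: str = "dry"
) -> float:
    """Arithmetic mean of the per-harvest percent differences."""
    return float(percent_diff_per_harvest(records, treatment, matter_type).mean())


def cumulative_percent_diff(
    records: pd.DataFrame, treatment: str, matter_type: str = "dry"
) -> float:
    """Percent difference of biomass summed over all harvests.

    100 x (sum_h mean_T(h) - sum_h mean_C(h)) / sum_h mean_C(h); under a
    balanced design this equals the per-subject-total version, but summing
    harvest means is robust to unequal replicate counts.
    """
    col = _matter_col(matter_type)
    mean_t = _harvest_means(records, treatment, col)
    mean_c = _harvest_means(records, "control", col)
    return float(100.0 * (mean_t.sum() - mean_c.sum()) / mean_c.sum())


@dataclass(frozen=True)
class EffectTable:
    """Per-harvest / average / cumulative percent differences vs control.

    ``per_harvest`` is harvests x treatments; ``average`` and ``cumulative``
    are per-treatment Series.  The control column is absent by construction.
    """

    matter_type: str
    per_harvest: pd.DataFrame
    average: pd.Series
    cumulative: pd.Series

    @property
    def treatments(self) -> list[str]:
        return list(self.per_harvest.columns)

    def to_frame(self) -> pd.DataFrame:
        """Rows = harvest indices + 'average' + 'cumulative'; cols = treatments."""
        out = self.per_harvest.copy()
        out.index = out.index.astype(str)
        out.loc["average"] = self.average
        out.loc["cumulative"] = self.cumulative
        out.index.name = "harvest"
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_effect_table(
    records: pd.DataFrame, matter_type: str = "dry"
) -> EffectTable:
    """Assemble the full percent-difference table for one matter type."""
    _matter_col(matter_type)
    labels = label_records(records)
    treatments = [t for t in labels.unique() if t != "control"]
    treatments.sort(key=lambda t: (len(t.split("+")), t))
    cols = {
        t: percent_diff_per_harvest(records, t, matter_type) for t in treatments
    }
    per_harvest = pd.DataFrame(cols)
    average = per_harvest.mean(axis=0)
    cumulative = pd.Series(
        {t: cumulative_percent_diff(records, t, matter_type) for t in treatments}
    ).reindex(treatments)
    return EffectTable(matter_type=matter_type, per_harvest=per_harvest,
                       average=average, cumulative=cumulative)


@dataclass(frozen=True)
class PermutationResult:
    label: str
    observed: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_permutations + 1) - 1e-12

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _subject_totals(records: pd.DataFrame, matter_type: str):
    col = _matter_col(matter_type)
    grouped = records.groupby("subject_id")
    totals = grouped[col].sum()
    flags = grouped[["biochar", "fertilizer", "inoculant"]].first().astype(bool)
    return totals.to_numpy(float), flags


def _factor_stat(totals: np.ndarray, on: np.ndarray) -> float:
    return abs(totals[on].mean() - totals[~on].mean())


def permutation_factorial_test(
    records: pd.DataFrame,
    factor_or_interaction: str,
    n_permutations: int = 999,
    seed: int = 0,
    matter_type: str = "dry",
) -> PermutationResult:
    """Permutation test on subject totals for a factor or 2-way interaction.

    For a main factor the statistic is |difference of mean subject totals
    between the two factor levels|; for an interaction ``"a:b"`` it is the
    interaction contrast of cell means |m11 - m10 - m01 + m00|.  Treatment
    labels are permuted across subjects, keeping each subject's harvest
    series intact.  p = (1 + #{perm >= obs}) / (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    totals, flags = _subject_totals(records, matter_type)
    n = totals.size

    parts = factor_or_interaction.split(":")
    for p in parts:
        if p not in flags.columns:
            raise ValueError(f"unknown factor {p!r}")
    if len(parts) not in (1, 2):
        raise ValueError("only main factors and 2-way interactions supported")

    if len(parts) == 1:
        on = flags[parts[0]].to_numpy()
        if on.sum() < 2 or (~on).sum() < 2:
            raise ValueError(f"fewer than 2 subjects per level of {parts[0]!r}")

        def stat(t: np.ndarray) -> float:
            return _factor_stat(t, on)

    else:
        a = flags[parts[0]].to_numpy()
        b = flags[parts[1]].to_numpy()
        cells = [a & b, a & ~b, ~a & b, ~a & ~b]
        if any(c.sum() < 2 for c in cells):
            raise ValueError("fewer than 2 subjects in an interaction cell")

        def stat(t: np.ndarray) -> float:
            m11, m10, m01, m00 = (t[c].mean() for c in cells)
            return abs(m11 - m10 - m01 + m00)

    observed = stat(totals)
    rng = np.random.default_rng(seed)
    # permuting totals against fixed labels == permuting labels across subjects
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = stat(totals[rng.permutation(n)])
    exceed = int(np.sum(perm >= observed - 1e-12))
    p_value = (1.0 + exceed) / (n_permutations + 1.0)
    return PermutationResult(
        label=factor_or_interaction,
        observed=float(observed),
        p_value=float(p_value),
        n_permutations=n_permutations,
    )
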