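"""Fold-change / significance filtering of quantitative proteomics ratios.

Input is a long-format table of per-protein, per-group replicate ratios to a
common reference channel (iTRAQ-style).  For a contrast (case vs control)
each protein gets a mean ratio, a log2 fold change and a two-sided t-test
p-value computed on log2-transformed replicate ratios (ratios are
multiplicative, so the test belongs on the log scale).  The deregulation
filter keeps proteins with at least a 1.5-fold difference (|log2 FC| >=
0.585) and p <= 0.05 by default; either threshold can be changed and the
significance arm can be switched off to reproduce fold-change-only counts.

List intersection across named candidate lists (key regulators, deregulated
sets from different contrasts) yields the common candidate together with a
Venn-style membership summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QuantTable",
    "DEList",
    "VennSummary",
    "log2_fold_change",
    "test_contrast",
    "select_deregulated",
    "intersect_lists",
]

REQUIRED_COLUMNS = ("protein_id", "group", "replicate", "ratio")


@dataclass
class QuantTable:
    """Long-format protein quantitation table.

    Columns: ``protein_id``, ``group``, ``replicate``, ``ratio`` (strictly
    positive ratio to the reference channel).
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"quant table missing column(s): {missing}")
        if (self.data["ratio"] <= 0).any():
            raise ValueError("ratios must be strictly positive")

    @classmethod
    def from_tsv(cls, path) -> "QuantTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @property
    def proteins(self) -> list:
        return sorted(self.data["protein_id"].unique())

    @property
    def groups(self) -> list:
        return sorted(self.data["group"].unique())

    def ratios(self, protein, group) -> np.ndarray:
        sel = self.data[(self.data["protein_id"] == protein)
                        & (self.data["group"] == group)]
        return sel["ratio"].to_numpy(dtype=float)


def log2_fold_change(ratio: float) -> float:
    """Base-2 log of a (strictly positive) abundance ratio."""
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return math.log2(ratio)


def test_contrast(case_reps, control_reps, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value on log2-transformed ratios.

    Student's equal-variance form by default, matching the classical t-test
    used for iTRAQ group comparisons; ``equal_var=False`` switches to
    Welch's unequal-variance form.  With fewer than 2 replicates on either side the
    p-value is undefined and NaN is returned.  Two identical, zero-variance
    groups give p = 1; zero variance with different means gives p = 0.
    """
    case = np.log2(np.asarray(case_reps, dtype=float))
    ctrl = np.log2(np.asarray(control_reps, dtype=float))
    if len(case) < 2 or len(ctrl) < 2:
        return float("nan")
    if case.var(ddof=1) == 0.0 and ctrl.var(ddof=1) == 0.0:
        return 1.0 if case.mean() == ctrl.mean() else 0.0
    return float(stats.ttest_ind(case, ctrl, equal_var=equal_var).pvalue)


@dataclass
class DEList:
    """Deregulated proteins selected for one contrast."""

    contrast: tuple[str, str]
    table: pd.DataFrame          # all proteins with mean_ratio, log2_fc, p, selected, direction
    fc_threshold: float
    p_threshold: float | None
    require_both: bool
    n_up: int = 0
    n_down: int = 0

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    @property
    def proteins(self) -> list:
        return sorted(self.selected["protein_id"])

    def __len__(self) -> int:
        return int(self.table["selected"].sum())


def select_deregulated(
    table: QuantTable,
    contrast: tuple[str, str],
    fc_threshold: float = 1.5,
    p_threshold: float | None = 0.05,
    require_both: bool = True,
    equal_var: bool = True,
    adjust: str | None = None,
) -> DEList:
    """Apply the deregulation filter to one contrast of a quant table.

    ``contrast`` is ``(case_group, control_group)``.  The mean ratio is the
    ratio of group means of the replicate ratios; the fold-change criterion
    is ``|log2 FC| >= log2(fc_threshold)``; significance is a two-sided
    t-test on log2 ratios at ``p <= p_threshold``.  With
    ``require_both=False`` (or ``p_threshold=None``) the filter is
    fold-change-only.  ``adjust="bh"`` adds a Benjamini–Hochberg adjusted
    column ``p_adj`` (reported alongside; selection still uses raw p, as in
    the raw-p filtering this pipeline mirrors).

    Direction is "up" when log2 FC >= +log2(fc_threshold), "down" when
    <= -log2(fc_threshold).
    """
    case_g, ctrl_g = contrast
    groups = set(table.data["group"])
    for g in (case_g, ctrl_g):
        if g not in groups:
            raise KeyError(f"group {g!r} not present in quant table")

    wide = {
        g: table.data[table.data["group"] == g]
            .pivot_table(index="protein_id", columns="replicate",
                         values="ratio", aggfunc="first")
        for g in (case_g, ctrl_g)
    }
    proteins = wide[case_g].index.intersection(wide[ctrl_g].index)
    case = np.log2(wide[case_g].loc[proteins].to_numpy(dtype=float))
    ctrl = np.log2(wide[ctrl_g].loc[proteins].to_numpy(dtype=float))

    mean_ratio = (2.0 ** np.nanmean(case, axis=1)) / (2.0 ** np.nanmean(ctrl, axis=1))
    log2_fc = np.log2(mean_ratio)

    n_case = np.sum(~np.isnan(case), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var,
                            nan_policy="omit").pvalue
    p = np.asarray(p, dtype=float)
    # zero-variance degenerate cases, and under-replicated rows -> undefined
    p[np.isnan(p) & (n_case >= 2) & (n_ctrl >= 2)] = 1.0
    p[(n_case < 2) | (n_ctrl < 2)] = np.nan

    out = pd.DataFrame(
        {
            "protein_id": proteins,
            "mean_ratio": mean_ratio,
            "log2_fc": log2_fc,
            "p": p,
            "p_undefined": np.isnan(p),
        }
    ).reset_index(drop=True)
    if adjust == "bh":
        valid = ~out["p"].isna()
        padj = np.full(len(out), np.nan)
        if valid.any():
            padj[valid.to_numpy()] = stats.false_discovery_control(
                out.loc[valid, "p"].to_numpy(), method="bh"
            )
        out["p_adj"] = padj

    lfc_cut = math.log2(fc_threshold)
    passes_fc = out["log2_fc"].abs() >= lfc_cut
    if p_threshold is None or not require_both:
        selected = passes_fc
    else:
        selected = passes_fc & (out["p"] <= p_threshold) & ~out["p_undefined"]
    out["selected"] = selected
    direction = np.where(out["log2_fc"] >= lfc_cut, "up",
                         np.where(out["log2_fc"] <= -lfc_cut, "down", ""))
    out["direction"] = np.where(selected, direction, "")

    n_up = int(((out["direction"] == "up") & selected).sum())
    n_down = int(((out["direction"] == "down") & selected).sum())
    return DEList(
        contrast=(case_g, ctrl_g),
        table=out,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold if require_both else None,
        require_both=require_both,
        n_up=n_up,
        n_down=n_down,
    )


@dataclass
class VennSummary:
    """Intersection of named candidate lists with membership counts."""

    common: set
    membership: pd.DataFrame      # element, n_lists, lists
    pairwise: pd.DataFrame        # list_a, list_b, overlap
    list_names: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "lists": {name: int((self.membership["lists"].str.contains(
                name, regex=False)).sum()) for name in self.list_names},
            "common": sorted(map(str, self.common)),
            "n_common": len(self.common),
        }


def intersect_lists(named_lists: Mapping[str, Iterable]) -> VennSummary:
    """Intersect >= 2 named protein lists.

    Returns the exact intersection across all lists, per-element membership
    counts (the Venn summary) and a pairwise overlap table.
    """
    if len(named_lists) < 2:
        raise ValueError("need at least 2 lists to intersect")
    sets = {name: set(v) for name, v in named_lists.items()}
    for name, s in sets.items():
        if not s:
            raise ValueError(f"list {name!r} is empty")
    names = list(sets)
    common = set.intersection(*sets.values())

    all_elements = sorted(set.union(*sets.values()), key=str)
    membership = pd.DataFrame(
        {
            "element": all_elements,
            "n_lists": [sum(e in sets[n] for n in names) for e in all_elements],
            "lists": [";".join(n for n in names if e in sets[n])
                      for e in all_elements],
        }
    ).sort_values(["n_lists", "element"], ascending=[False, True]).reset_index(drop=True)

    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({"list_a": a, "list_b": b,
                         "overlap": len(sets[a] & sets[b])})
    pairwise = pd.DataFrame(rows)
    return VennSummary(common=common, membership=membership,
                       pairwise=pairwise, list_names=names)


def read_protein_list(path) -> list[str]:
    """One protein identifier per line; '#' comments and blanks ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
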