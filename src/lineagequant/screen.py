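"""Two-stage RNAi-screen statistics.

Stage 1 compares every clone's background-subtracted germline-blastomere
(P2) intensities against the empty-vector control with a two-sample
Student t-test at a small n; stage-1 hits are retested at a larger n.
The retest replaces formal multiple-testing correction: a null clone
must clear two independent tests to become a final hit, which sharply
reduces false discoveries at matched per-test alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ScreenTable", "normalize_to_control", "call_hits"]

REQUIRED_COLUMNS = ("clone", "stage", "embryo", "p2_mean", "camera_bg")


@dataclass(frozen=True)
class ScreenTable:
    """Tidy per-embryo screen measurements plus the control clone id."""

    data: pd.DataFrame
    control_clone: str = "control"

    def __post_init__(self):
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"screen table missing columns {sorted(missing)}")
        for stage in self.data["stage"].unique():
            sub = self.data[self.data["stage"] == stage]
            if self.control_clone not in set(sub["clone"]):
                raise ValueError(f"control clone absent from stage {stage}")
        counts = self.data.groupby(["stage", "clone"]).size()
        if (counts < 1).any():
            raise ValueError("every clone needs at least one embryo")

    def stage(self, stage: int) -> pd.DataFrame:
        sub = self.data[self.data["stage"] == stage]
        if sub.empty:
            raise ValueError(f"no stage-{stage} rows")
        return sub

    def net(self, stage: int) -> pd.DataFrame:
        """Per-embryo background-subtracted values for one stage."""
        sub = self.stage(stage).copy()
        sub["net"] = sub["p2_mean"] - sub["camera_bg"]
        return sub


def normalize_to_control(table: ScreenTable, stage: int) -> pd.DataFrame:
    """Per-embryo (P2 - bg) values divided by the control-clone mean.

    Returns the stage's rows with a ``normalized`` column; the control
    clone's normalized mean is 1 by construction.
    """
    sub = table.net(stage)
    ctrl_mean = sub.loc[sub["clone"] == table.control_clone, "net"].mean()
    if ctrl_mean <= 0:
        raise ValueError("control mean <= 0: cannot normalize")
    sub["normalized"] = sub["net"] / ctrl_mean
    return sub


def _two_sample_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return float(res.pvalue)


def call_hits(table: ScreenTable, alpha: float = 0.05,
              min_n_stage1: int = 5, min_n_stage2: int = 11,
              test: str = "student", correction: str | None = None) -> pd.DataFrame:
    """Two-stage hit calling against the control clone.

    Per stage, each clone is compared with the control by a two-tailed
    two-sample t-test (pooled-variance Student by default, ``test=
    "welch"`` for unequal variances).  Stage 2 is evaluated only for
    stage-1 hits.  Clones below the per-stage minimum n are flagged, not
    dropped.  ``correction="bh"`` applies Benjamini-Hochberg within each
    stage (off by default; the two-stage retest is the false-positive
    control).

    Returns one row per clone: p-values, hit calls and low-n flags.
    """
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    s1 = table.net(1)
    ctrl1 = s1.loc[s1["clone"] == table.control_clone, "net"].to_numpy()
    clones = [c for c in s1["clone"].unique() if c != table.control_clone]
    rows = {}
    p1s = []
    for clone in clones:
        vals = s1.loc[s1["clone"] == clone, "net"].to_numpy()
        p = _two_sample_p(vals, ctrl1, test)
        rows[clone] = {"clone": clone, "n1": len(vals), "p1": p,
                       "low_n1": len(vals) < min_n_stage1}
        p1s.append(p)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(p1s, alpha=alpha, method="fdr_bh")[1]
        for clone, p in zip(clones, adj):
            rows[clone]["p1"] = float(p)
    for clone in clones:
        p = rows[clone]["p1"]
        rows[clone]["stage1_hit"] = bool(np.isfinite(p) and p < alpha)

    has_stage2 = 2 in set(table.data["stage"].unique())
    if has_stage2:
        s2 = table.net(2)
        ctrl2 = s2.loc[s2["clone"] == table.control_clone, "net"].to_numpy()
    p2s, retested = [], []
    for clone in clones:
        r = rows[clone]
        if not (has_stage2 and r["stage1_hit"]):
            r.update(n2=0, p2=float("nan"), low_n2=False, stage2_hit=False)
            continue
        vals = s2.loc[s2["clone"] == clone, "net"].to_numpy()
        p = _two_sample_p(vals, ctrl2, test)
        r.update(n2=len(vals), p2=p, low_n2=len(vals) < min_n_stage2)
        retested.append(clone)
        p2s.append(p)
    if correction == "bh" and retested:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(p2s, alpha=alpha, method="fdr_bh")[1]
        for clone, p in zip(retested, adj):
            rows[clone]["p2"] = float(p)
    for clone in retested:
        p = rows[clone]["p2"]
        rows[clone]["stage2_hit"] = bool(np.isfinite(p) and p < alpha)
    return pd.DataFrame(rows.values()).set_index("clone")
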