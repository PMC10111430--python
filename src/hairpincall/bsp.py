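"""Clone-level targeted bisulfite (BSP) statistics.

BSP amplifies a bisulfite-converted region, clones the products and Sanger
sequences individual clones, so each clone reports a binary methylation
state at every cytosine in the amplicon. This module computes per-site
clone frequencies, compares conditions with a chi-square goodness-of-fit
test, and contrasts candidate sites across datasets with one-way ANOVA and
Tukey HSD.

The goodness-of-fit construction: the observed condition's methylated /
unmethylated clone counts are tested against expected counts derived from
the reference condition's frequency (expected methylated = N_obs * p_ref).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CloneMatrix",
    "read_clone_table",
    "per_site_frequency",
    "combined_frequency",
    "chisq_gof_condition",
    "anova_tukey_site_comparison",
    "lollipop_plot",
]


@dataclass
class CloneMatrix:
    """Clones x cytosine-positions binary methylation states for one condition."""

    condition: str
    positions: Sequence[int]
    states: np.ndarray  # shape (n_clones, n_positions), values 0/1
    contexts: Sequence[str] = field(default_factory=list)
    amplicon: tuple | None = None  # (chrom, start, end, strand)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.positions):
            raise ValueError("states must be clones x positions")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary")
        pos = list(self.positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_clones(self) -> int:
        return self.states.shape[0]

    def counts_at(self, position: int) -> tuple[int, int]:
        """(methylated clones, total clones) at a position."""
        idx = list(self.positions).index(position)
        return int(self.states[:, idx].sum()), self.n_clones


def read_clone_table(path) -> dict[str, CloneMatrix]:
    """Read a long-format clone TSV: clone_id, condition, position, state.

    Returns one CloneMatrix per condition. Every clone must report every
    position of its condition.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "condition", "position", "state"}
    if not required.issubset(df.columns):
        raise ValueError(f"clone table needs columns {sorted(required)}")
    out = {}
    for cond, sub in df.groupby("condition"):
        wide = sub.pivot(index="clone_id", columns="position", values="state")
        if wide.isna().any().any():
            raise ValueError(f"condition {cond!r}: missing states for some clones")
        positions = sorted(wide.columns)
        out[cond] = CloneMatrix(
            condition=str(cond),
            positions=positions,
            states=wide[positions].to_numpy(dtype=int),
        )
    return out


def per_site_frequency(matrix: CloneMatrix) -> pd.DataFrame:
    """Per-position (meth_clones, total_clones, percent)."""
    if matrix.n_clones < 1:
        raise ValueError("need at least one clone")
    meth = matrix.states.sum(axis=0)
    return pd.DataFrame({
        "position": list(matrix.positions),
        "meth_clones": meth,
        "total_clones": matrix.n_clones,
        "percent": 100.0 * meth / matrix.n_clones,
    })


def combined_frequency(matrices: Sequence[CloneMatrix], position: int) -> float:
    """Pooled percent methylated clones at one position across conditions."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to pool")
    meth = total = 0
    for m in matrices:
        if position not in list(m.positions):
            raise KeyError(f"position {position} absent in condition {m.condition!r}")
        k, n = m.counts_at(position)
        meth += k
        total += n
    return 100.0 * meth / total


def chisq_gof_condition(
    reference: tuple[int, int], observed: tuple[int, int]
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of observed counts against a reference frequency.

    ``reference`` and ``observed`` are (methylated clones, total clones).
    Expected methylated = observed total x reference proportion; chi2 summed
    over the methylated and unmethylated cells, 1 df, no continuity
    correction. Returns (chi2, df, p).
    """
    ref_k, ref_n = reference
    obs_k, obs_n = observed
    if ref_n < 1 or obs_n < 1:
        raise ValueError("totals must be >= 1")
    p_ref = ref_k / ref_n
    if not 0.0 < p_ref < 1.0:
        raise ValueError("reference proportion must lie strictly in (0, 1)")
    expected = np.array([obs_n * p_ref, obs_n * (1.0 - p_ref)])
    if np.any(expected == 0):
        raise ValueError("zero expected cell count")
    observed_cells = np.array([obs_k, obs_n - obs_k], dtype=float)
    chi2 = float(((observed_cells - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p


def anova_tukey_site_comparison(
    ratios: Mapping[str, Sequence[float]] | pd.DataFrame,
    alpha: float = 0.05,
):
    """One-way ANOVA across sites plus Tukey HSD pairwise comparisons.

    ``ratios`` maps each site label to its per-dataset methylation ratios
    (the datasets are treated as independent observations). Sites with
    fewer than two observations are excluded with a warning. Returns
    (F, p, tukey_frame) where tukey_frame has columns group1, group2,
    meandiff, p_adj, reject.
    """
    import warnings

    if isinstance(ratios, pd.DataFrame):
        groups = {str(c): ratios[c].dropna().to_list() for c in ratios.columns}
    else:
        groups = {str(k): [v for v in vals if v == v] for k, vals in ratios.items()}
    usable = {}
    for name, vals in groups.items():
        if len(vals) < 2:
            warnings.warn(f"site {name!r} has < 2 observations; excluded")
            continue
        usable[name] = np.asarray(vals, dtype=float)
    if len(usable) < 2:
        raise ValueError("need at least two sites with >= 2 observations")
    names = list(usable)
    samples = [usable[n] for n in names]
    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(usable[n]) for n in names])
    degenerate = np.ptp(values) == 0
    if degenerate:
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*samples)
        f_stat, p_val = float(f_stat), float(p_val)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if degenerate:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        tukey_df = pd.DataFrame({
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": 0.0, "p_adj": 1.0, "reject": False,
        })
    else:
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=[c.replace("-", "_") for c in res.summary().data[0]]
        )[["group1", "group2", "meandiff", "p_adj", "reject"]]
        tukey_df["p_adj"] = np.asarray(res.pvalues, dtype=float)
        tukey_df["reject"] = np.asarray(res.reject, dtype=bool)
    return f_stat, p_val, tukey_df


def lollipop_plot(matrix: CloneMatrix, ax=None, target: int | None = None):
    """Minimal lollipop-style rendering: one row per clone, filled = methylated."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.2 * matrix.n_clones + 1))
    xs = np.arange(len(matrix.positions))
    for i in range(matrix.n_clones):
        ax.plot(xs, np.full_like(xs, i), color="0.8", lw=0.5, zorder=1)
        meth = matrix.states[i].astype(bool)
        ax.scatter(xs[~meth], np.full((~meth).sum(), i), facecolors="white",
                   edgecolors="black", s=14, zorder=2)
        ax.scatter(xs[meth], np.full(meth.sum(), i), color="black", s=14, zorder=2)
    if target is not None and target in list(matrix.positions):
        ax.axvline(list(matrix.positions).index(target), color="red", alpha=0.3)
    ax.set_xticks(xs)
    ax.set_xticklabels(matrix.positions, rotation=90, fontsize=6)
    ax.set_ylabel("clone")
    ax.set_title(matrix.condition)
    return ax
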