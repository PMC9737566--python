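"""Group summaries and nonparametric between-group comparison.

Seed descriptor samples are routinely non-normal, so between-group
comparison is rank-based throughout: an omnibus Kruskal–Wallis test over
the k groups, followed by the Campbell–Skillings stepwise step-down
search for homogeneous subsets, reported as a compact letter display
(groups sharing a letter do not differ significantly).

The step-down procedure orders groups by mean rank and tests contiguous
subsets in a closed fashion: the full set is tested at level alpha; each
rejected subset of size p is split into its two maximal contiguous
subsets of size p-1, which are tested — after re-ranking the data within
the subset, the defining feature of the procedure — at the adjusted level

    alpha_p = 1 - (1 - alpha)**((p - 1) / (k - 1)),   p < k.

Published descriptions of the procedure differ in the adjustment; the
formula above (the Ryan–Einot–Gabriel–Welsch-style level, which Campbell
and Skillings recommend for their step-down scheme) is the default, and
an unadjusted variant (``adjust='none'``) is available for sensitivity
checks.  Accepted subsets are the homogeneous subsets; they are
contiguous in mean-rank order by construction.

The comparison is packaged statsmodels-style: build a
:class:`SeedGroupComparison` from a tidy descriptor table, call
:meth:`~SeedGroupComparison.fit`, and read the resulting letter table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "coefficient_of_variation",
    "kruskal_wallis",
    "kruskal_wallis_exact",
    "campbell_skillings",
    "GroupComparison",
    "summarize",
    "SeedGroupComparison",
    "SeedGroupComparisonResults",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = ["A", "P", "AR", "C", "R", "S"]


def coefficient_of_variation(values) -> float:
    """CV = sample standard deviation / mean * 100 (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean * 100.0)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    ``groups`` is a sequence of value sequences (>= 2 groups, each
    non-empty).  All values identical across groups is not an error:
    it returns ``(0.0, 1.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _h_statistic(pooled_ranks: np.ndarray, sizes: list[int],
                 tie_factor: float) -> float:
    n = len(pooled_ranks)
    h = 0.0
    start = 0
    for s in sizes:
        h += pooled_ranks[start:start + s].sum() ** 2 / s
        start += s
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def kruskal_wallis_exact(groups, max_n: int = 12) -> tuple[float, float]:
    """H with an exact permutation p-value (small samples only).

    Enumerates every distinct assignment of the pooled observations to
    the group sizes and counts the fraction with ``H >= H_observed``.
    Limited to ``sum(n_i) <= max_n`` to keep enumeration tractable.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    if n > max_n:
        raise ValueError(f"exact permutation limited to n <= {max_n}")
    h_obs, _ = kruskal_wallis(groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum() / (n**3 - n))

    def assignments(indices, sizes):
        if len(sizes) == 1:
            yield (tuple(indices),)
            return
        for chosen in combinations(indices, sizes[0]):
            rest = [i for i in indices if i not in chosen]
            for tail in assignments(rest, sizes[1:]):
                yield (chosen,) + tail

    n_ge, n_tot = 0, 0
    for parts in assignments(list(range(n)), sizes):
        perm = np.concatenate([ranks[list(part)] for part in parts])
        h = _h_statistic(perm, sizes, tie)
        n_tot += 1
        if h >= h_obs - 1e-12:
            n_ge += 1
    return h_obs, n_ge / n_tot


@dataclass
class GroupComparison:
    """Result of one descriptor's k-group nonparametric comparison."""

    descriptor: str
    groups: list[str]                  # in mean-rank order
    n: dict[str, int]
    mean: dict[str, float]
    cv: dict[str, float]
    h: float
    p: float
    alpha: float
    subsets: list[tuple[str, ...]]     # maximal homogeneous subsets
    letters: dict[str, str]
    subset_tests: list[dict] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        """Omnibus test rejected at alpha."""
        return self.p < self.alpha

    def cell(self, group: str, fmt: str = "{mean:.3g} ({cv:.1f}) {letters}") -> str:
        return fmt.format(mean=self.mean[group], cv=self.cv[group],
                          letters=self.letters[group])


def _stepdown_alpha(p: int, k: int, alpha: float, adjust: str) -> float:
    if p >= k or adjust == "none":
        return alpha
    return 1.0 - (1.0 - alpha) ** ((p - 1) / (k - 1))


def campbell_skillings(groups: dict, alpha: float = 0.05,
                       adjust: str = "stepdown",
                       descriptor: str = "") -> GroupComparison:
    """Step-down homogeneous subsets and compact letters for k groups.

    ``groups`` maps group name to its sample.  Groups are ordered by mean
    global midrank; contiguous subsets are tested by Kruskal–Wallis on
    the subset's own data (implicitly re-ranked) at the step-down level;
    accepted subsets, reduced to the maximal ones, become the homogeneous
    subsets from which letters are assigned left to right.
    """
    if adjust not in ("stepdown", "none"):
        raise ValueError("adjust must be 'stepdown' or 'none'")
    names = list(groups)
    data = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g in names:
        if data[g].size == 0:
            raise ValueError(f"empty group {g!r}")
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate([data[g] for g in names])
    ranks = sps.rankdata(pooled)
    mean_rank, start = {}, 0
    for g in names:
        mean_rank[g] = ranks[start:start + data[g].size].mean()
        start += data[g].size
    order = sorted(names, key=lambda g: mean_rank[g])
    k = len(order)
    h_full, p_full = kruskal_wallis([data[g] for g in order])

    accepted: list[tuple[int, ...]] = []
    tests: list[dict] = []
    seen: set[tuple[int, ...]] = set()

    def covered(idx: tuple[int, ...]) -> bool:
        return any(set(idx) <= set(a) for a in accepted)

    def step(idx: tuple[int, ...]) -> None:
        if idx in seen or covered(idx):
            return
        seen.add(idx)
        if len(idx) == 1:
            accepted.append(idx)
            return
        a_p = _stepdown_alpha(len(idx), k, alpha, adjust)
        h, p = kruskal_wallis([data[order[i]] for i in idx])
        tests.append({"subset": [order[i] for i in idx], "H": h, "p": p,
                      "alpha_p": a_p, "rejected": bool(p < a_p)})
        if p < a_p:
            step(idx[:-1])
            step(idx[1:])
        else:
            accepted.append(idx)

    step(tuple(range(k)))
    # keep maximal accepted subsets only
    maximal = [a for a in accepted
               if not any(set(a) < set(b) for b in accepted)]
    maximal.sort(key=lambda a: (a[0], -len(a)))
    letters = {g: "" for g in order}
    for letter, subset in zip("abcdefghijklmnopqrstuvwxyz", maximal):
        for i in subset:
            letters[order[i]] += letter
    return GroupComparison(
        descriptor=descriptor,
        groups=order,
        n={g: int(data[g].size) for g in order},
        mean={g: float(data[g].mean()) for g in order},
        cv={g: coefficient_of_variation(data[g]) if data[g].size > 1 else 0.0
            for g in order},
        h=h_full,
        p=p_full,
        alpha=alpha,
        subsets=[tuple(order[i] for i in a) for a in maximal],
        letters=letters,
        subset_tests=tests,
    )


def summarize(descriptors: pd.DataFrame, view: str | None = None,
              by: str = "species") -> pd.DataFrame:
    """Study-level summary per descriptor: mean, SD, CV, extreme species.

    ``descriptors`` is the tidy per-seed table (columns ``species``,
    ``view``, the descriptor columns).  Mean/SD/CV are over individual
    seeds; min and max are over per-``by`` means, with the argmin/argmax
    label reported alongside.
    """
    if descriptors.empty:
        raise ValueError("empty descriptor table")
    df = descriptors if view is None else descriptors[descriptors["view"] == view]
    if df.empty:
        raise ValueError(f"no rows for view {view!r}")
    cols = [c for c in DESCRIPTOR_COLUMNS if c in df.columns]
    per_unit = df.groupby(by)[cols].mean()
    out = []
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        out.append({
            "descriptor": c,
            "n": len(v),
            "mean": v.mean(),
            "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
            "cv": coefficient_of_variation(v) if len(v) > 1 else 0.0,
            "min": per_unit[c].min(),
            "min_" + by: per_unit[c].idxmin(),
            "max": per_unit[c].max(),
            "max_" + by: per_unit[c].idxmax(),
        })
    return pd.DataFrame(out).set_index("descriptor")


# ---------------------------------------------------------------------------
# Model/Results wrapper


class SeedGroupComparison:
    """Between-group comparison model over a tidy descriptor table.

    Parameters
    ----------
    data : DataFrame
        One row per seed (or per average silhouette) with a group column
        and descriptor columns.
    descriptors : sequence of str
        Descriptor columns to compare (default all present among A, P,
        AR, C, R, S).
    group_col : str
        Column holding the group labels.
    alpha : float
        Significance level for the omnibus and step-down tests.
    adjust : {'stepdown', 'none'}
        Step-down level adjustment variant.
    """

    def __init__(self, data: pd.DataFrame, descriptors=None,
                 group_col: str = "group", alpha: float = 0.05,
                 adjust: str = "stepdown"):
        if data.empty:
            raise ValueError("empty data table")
        if group_col not in data.columns:
            raise ValueError(f"missing group column {group_col!r}")
        self.data = data
        self.group_col = group_col
        self.descriptors = list(descriptors) if descriptors is not None else \
            [c for c in DESCRIPTOR_COLUMNS if c in data.columns]
        missing = [c for c in self.descriptors if c not in data.columns]
        if missing:
            raise ValueError(f"missing descriptor columns {missing}")
        self.alpha = alpha
        self.adjust = adjust

    @classmethod
    def from_records(cls, records, view: str, **kwargs) -> "SeedGroupComparison":
        rows = [r.as_row() for r in records if r.view == view]
        return cls(pd.DataFrame(rows), **kwargs)

    def fit(self) -> "SeedGroupComparisonResults":
        comparisons = {}
        for c in self.descriptors:
            groups = {
                g: sub[c].to_numpy(dtype=float)
                for g, sub in self.data.groupby(self.group_col, sort=False)
            }
            comparisons[c] = campbell_skillings(
                groups, alpha=self.alpha, adjust=self.adjust, descriptor=c)
        return SeedGroupComparisonResults(self, comparisons)


class SeedGroupComparisonResults:
    """Fitted group comparison: letters, subsets and summary tables."""

    def __init__(self, model: SeedGroupComparison,
                 comparisons: dict[str, GroupComparison]):
        self.model = model
        self.comparisons = comparisons

    @property
    def excluded(self) -> list[str]:
        """Descriptors whose omnibus test found no group differences.

        These are reported but carry a single shared letter; in a
        classical write-up they would be dropped from further analysis.
        """
        return [c for c, comp in self.comparisons.items() if not comp.significant]

    def letters(self, descriptor: str) -> dict[str, str]:
        return self.comparisons[descriptor].letters

    def table(self) -> pd.DataFrame:
        """Wide letter table: rows = groups, cells = 'mean (CV) letters'."""
        groups = sorted({g for c in self.comparisons.values() for g in c.groups})
        data = {
            c: {g: comp.cell(g) for g in comp.groups}
            for c, comp in self.comparisons.items()
        }
        return pd.DataFrame(data).reindex(groups)

    def tidy(self) -> pd.DataFrame:
        """Long-format results, one row per descriptor x group."""
        rows = []
        for c, comp in self.comparisons.items():
            for g in comp.groups:
                rows.append({
                    "descriptor": c, "group": g, "n": comp.n[g],
                    "mean": comp.mean[g], "cv": comp.cv[g],
                    "letters": comp.letters[g],
                    "H": comp.h, "p": comp.p, "alpha": comp.alpha,
                })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            c: {
                "H": comp.h, "p": comp.p, "alpha": comp.alpha,
                "groups": comp.groups,
                "subsets": [list(s) for s in comp.subsets],
                "letters": comp.letters,
                "tests": comp.subset_tests,
            }
            for c, comp in self.comparisons.items()
        }

    def summary(self) -> str:
        lines = [
            "Seed group comparison (Kruskal-Wallis + step-down letters)",
            "=" * 60,
            f"alpha = {self.model.alpha}, adjustment = {self.model.adjust}",
            "",
            self.table().to_string(),
        ]
        if self.excluded:
            lines += ["", "no significant omnibus differences for: "
                          + ", ".join(self.excluded)]
        return "\n".join(lines)
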