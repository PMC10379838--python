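"""Haplotype frequency tables, the M ratio statistic, and regional tests.

The M statistic summarizes the balance of the two predominant haplotypes of
a group:

    M = (count_A - count_B) / (count_A + count_B)

with A the focal and B the contrast haplotype (for the soybean looper COI
marker, A = C1035/T1272 and B = T1035/C1272). M is -1..1, antisymmetric
under swapping A and B, and invariant to scaling both counts — it measures
proportion, not abundance, which is what makes it comparable across
collections of different size.

Regional comparisons take collection-level M values (one value per pooled
state x year collection), map each state to a side of a two-region scheme
(East/West across the Appalachians, or Gulf-bordering South vs migratory
North), and compare the sides by unpaired two-tailed t-test. Within-state
haplotype count distributions are compared by chi-square against uniform
and by one-way ANOVA with Tukey HSD across haplotype classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataQualityError, UndefinedStatisticError, ValidationError

FOCAL_HAPLOTYPE = "C1035/T1272"
CONTRAST_HAPLOTYPE = "T1035/C1272"

EAST_STATES = ("FL", "GA", "SC", "NC", "VA")
WEST_STATES = ("TX", "LA", "MS", "KS", "TN", "AL")
NORTH_STATES = ("KS", "TN", "VA", "NC", "SC")
SOUTH_STATES = ("TX", "LA", "MS", "GA", "FL", "AL")


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome with its group summaries."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    groups: dict = field(default_factory=dict)  # label -> (n, mean, sd)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    def summary(self) -> str:
        df = self.df if np.isscalar(self.df) else tuple(round(d, 2) for d in self.df)
        lines = [f"{self.name}: statistic={self.statistic:.4f} df={df} "
                 f"p={self.p_value:.4f}"]
        for label, (n, mean, sd) in self.groups.items():
            lines.append(f"  {label}: n={n} mean={mean:.2f} sd={sd:.2f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class MResult:
    """Collection-level M value with its defining counts."""

    group: tuple  # e.g. (state, year) or (collection_id,)
    state: str
    count_a: int
    count_b: int
    m: float


@dataclass
class FrequencyTable:
    """Per-group haplotype counts (wide) with an ``n_resolved`` column."""

    grouping: str
    counts: pd.DataFrame  # index = group key, columns = haplotype labels

    @property
    def n_resolved(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.n_resolved, axis=0)


@dataclass(frozen=True)
class RegionScheme:
    """A two-sided grouping of states, with explicit exclusions."""

    name: str
    mapping: dict  # state -> side label
    excluded: frozenset = frozenset({"PR"})

    @property
    def sides(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.mapping.values()))

    @classmethod
    def east_west(cls) -> "RegionScheme":
        m = {s: "East" for s in EAST_STATES}
        m.update({s: "West" for s in WEST_STATES})
        return cls("East/West", m)

    @classmethod
    def north_south(cls) -> "RegionScheme":
        m = {s: "North" for s in NORTH_STATES}
        m.update({s: "South" for s in SOUTH_STATES})
        return cls("North/South", m)


# ---------------------------------------------------------------------------

def calls_to_frame(calls, records) -> pd.DataFrame:
    """Join haplotype calls with specimen metadata into a tidy frame."""
    meta = {r.specimen_id: r for r in records}
    rows = []
    for c in calls:
        r = meta.get(c.specimen_id)
        if r is None:
            raise ValidationError(f"call for unknown specimen {c.specimen_id!r}")
        rows.append({"specimen_id": c.specimen_id,
                     "collection_id": r.collection_id, "state": r.state,
                     "year": r.year, "segment": c.segment,
                     "label": c.label, "status": c.status})
    return pd.DataFrame(rows)


_GROUP_KEYS = {
    "collection": ["collection_id"],
    "state_year": ["state", "year"],
    "state": ["state"],
}


def frequency_table(calls_frame: pd.DataFrame,
                    grouping: str = "state_year") -> FrequencyTable:
    """Count resolved haplotype calls per group.

    Only ``status == "resolved"`` calls are counted; groups whose calls are
    all unresolved are omitted with a warning.
    """
    if grouping not in _GROUP_KEYS:
        raise ValidationError(f"unknown grouping {grouping!r}")
    keys = _GROUP_KEYS[grouping]
    resolved = calls_frame[calls_frame["status"] == "resolved"]
    if resolved.empty:
        raise DataQualityError("no resolved haplotype calls")
    all_groups = set(map(tuple, calls_frame[keys].drop_duplicates().values))
    kept_groups = set(map(tuple, resolved[keys].drop_duplicates().values))
    dropped = all_groups - kept_groups
    if dropped:
        warnings.warn(f"groups with zero resolved calls omitted: "
                      f"{sorted(dropped)}")
    counts = (resolved.groupby(keys + ["label"]).size()
              .unstack(fill_value=0).sort_index())
    counts.columns.name = None
    return FrequencyTable(grouping=grouping, counts=counts)


def m_statistic(count_a: float, count_b: float) -> float:
    """M = (A - B) / (A + B); undefined when both counts are zero."""
    if count_a < 0 or count_b < 0:
        raise ValidationError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        raise UndefinedStatisticError("M undefined: both counts are zero")
    return (count_a - count_b) / total


def m_results(table: FrequencyTable, focal: str = FOCAL_HAPLOTYPE,
              contrast: str = CONTRAST_HAPLOTYPE) -> list[MResult]:
    """Collection-level M per group; both-zero groups dropped with a warning."""
    out = []
    for key, row in table.counts.iterrows():
        key_t = key if isinstance(key, tuple) else (key,)
        a = int(row.get(focal, 0))
        b = int(row.get(contrast, 0))
        if a + b == 0:
            warnings.warn(f"group {key_t}: no {focal} or {contrast} calls; "
                          "dropped from M analysis")
            continue
        state = key_t[0] if table.grouping in ("state_year", "state") else None
        out.append(MResult(group=key_t, state=state, count_a=a, count_b=b,
                           m=m_statistic(a, b)))
    return out


# ---------------------------------------------------------------------------
# tests

def _group_summary(values) -> tuple[int, float, float]:
    v = np.asarray(values, dtype=float)
    return len(v), float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


def chi_square_uniform(counts) -> TestResult:
    """Pearson chi-square of observed counts against equal expectations."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 1 or len(obs) < 2:
        raise ValidationError("need a 1-d vector of at least 2 counts")
    if (obs < 0).any() or obs.sum() == 0:
        raise ValidationError("counts must be non-negative with positive sum")
    stat, p = stats.chisquare(obs)
    return TestResult("chi_square_uniform", float(stat), len(obs) - 1,
                      float(p), extra={"n": int(obs.sum())})


def two_sample_t(a, b, variant: str = "pooled") -> TestResult:
    """Unpaired two-tailed t-test (classic pooled-variance or Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(
        f"two_sample_t[{variant}]", float(res.statistic), float(res.df),
        float(res.pvalue),
        groups={"a": _group_summary(a), "b": _group_summary(b)})


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA with effect size r^2 = SSB/SST."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValidationError("need >=2 groups with n >= 2 each")
    allv = np.concatenate(gs)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ss_within == 0:
        raise DataQualityError("zero within-group variance: F undefined")
    f, p = stats.f_oneway(*gs)
    k, n = len(gs), len(allv)
    return TestResult(
        "one_way_anova", float(f), (k - 1, n - k), float(p),
        groups={str(i): _group_summary(g) for i, g in enumerate(gs)},
        extra={"r2": float(ss_between / (ss_between + ss_within))})


@dataclass(frozen=True)
class TukeyResult:
    pairwise: pd.DataFrame  # group_i, group_j, diff, p_value, reject
    letters: dict  # label -> letter string
    alpha: float


def _compact_letter_display(labels, means, reject) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different. Columns start
    as one all-group set and are split for each rejected pair; redundant
    (subset) columns are absorbed. Letters are assigned in order of
    decreasing group mean.
    """
    order = sorted(range(len(labels)), key=lambda i: -means[i])
    cols = [set(range(len(labels)))]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if not reject[i][j]:
                continue
            for col in [c for c in cols if i in c and j in c]:
                cols.remove(col)
                for new in (col - {i}, col - {j}):
                    if not any(new <= c for c in cols):
                        cols.append(new)
    cols.sort(key=lambda c: min(order.index(i) for i in c))
    letters = {lab: "" for lab in labels}
    for letter_i, col in enumerate(cols):
        ch = chr(ord("a") + letter_i)
        for i in sorted(col, key=order.index):
            letters[labels[i]] += ch
    return letters


def tukey_hsd(groups, alpha: float = 0.05, labels=None) -> TukeyResult:
    """Tukey HSD pairwise comparisons with a compact letter display."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValidationError("need >=2 groups with n >= 2 each")
    if labels is None:
        labels = [str(i) for i in range(len(gs))]
    res = stats.tukey_hsd(*gs)
    rows = []
    k = len(gs)
    reject = [[False] * k for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            p = float(res.pvalue[i, j])
            reject[i][j] = reject[j][i] = p < alpha
            rows.append({"group_i": labels[i], "group_j": labels[j],
                         "diff": float(gs[i].mean() - gs[j].mean()),
                         "p_value": p, "reject": p < alpha})
    letters = _compact_letter_display(labels, [g.mean() for g in gs], reject)
    return TukeyResult(pairwise=pd.DataFrame(rows), letters=letters,
                       alpha=alpha)


def plot_state_pies(table: FrequencyTable, path,
                    colors: dict | None = None) -> None:
    """One pie per group showing its haplotype composition (PNG/SVG/PDF).

    A quick visual analogue of per-state haplotype-proportion maps; layout
    is a simple grid, not a geographic projection.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freqs = table.frequencies()
    labels = list(freqs.columns)
    if colors is None:
        cmap = plt.get_cmap("tab10")
        colors = {lab: cmap(i % 10) for i, lab in enumerate(labels)}
    n = len(freqs)
    ncol = min(4, n)
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow),
                             squeeze=False)
    for ax in axes.flat:
        ax.axis("off")
    for ax, (key, row) in zip(axes.flat, freqs.iterrows()):
        vals = [row[lab] for lab in labels]
        ax.pie(vals, colors=[colors[lab] for lab in labels])
        name = "/".join(map(str, key)) if isinstance(key, tuple) else str(key)
        ax.set_title(f"{name} (n={int(table.n_resolved.loc[key])})",
                     fontsize=9)
    fig.legend(labels, loc="lower center", ncol=min(4, len(labels)),
               fontsize=8)
    fig.tight_layout(rect=(0, 0.06, 1, 1))
    fig.savefig(path)
    plt.close(fig)


def regional_compare(m_values: list[MResult], scheme: RegionScheme,
                     variant: str = "pooled") -> TestResult:
    """Compare collection-level M values between a scheme's two sides."""
    sides: dict[str, list[float]] = {s: [] for s in scheme.sides}
    for mr in m_values:
        state = mr.state if mr.state is not None else mr.group[0]
        if state in scheme.excluded:
            continue
        side = scheme.mapping.get(state)
        if side is None:
            raise ValidationError(
                f"state {state!r} neither mapped nor excluded in scheme "
                f"{scheme.name!r}")
        sides[side].append(mr.m)
    short = [s for s, v in sides.items() if len(v) < 2]
    if short:
        raise DataQualityError(
            f"scheme {scheme.name!r}: fewer than 2 groups on side(s) {short}")
    s1, s2 = scheme.sides
    res = two_sample_t(sides[s1], sides[s2], variant=variant)
    return TestResult(
        f"regional[{scheme.name},{variant}]", res.statistic, res.df,
        res.p_value,
        groups={s1: _group_summary(sides[s1]), s2: _group_summary(sides[s2])},
        extra={"scheme": scheme.name})
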