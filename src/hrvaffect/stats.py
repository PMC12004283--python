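"""Nonparametric statistical layer: Wilcoxon contrasts with Bonferroni control.

The sampling unit defaults to normalized window-level values pooled across
the subjects of a group (e.g. 17 healthy subjects x 6 acquaintance videos =
102 values per feature), which is consistent with effect sizes reported as
r = |Z| / sqrt(N) at window-level N; per-subject condition means are
available via ``unit="subject"``.

Within-group condition contrasts use the Wilcoxon signed-rank test (windows
paired by protocol position within subject); between-group contrasts use the
rank-sum (Mann-Whitney) test.  Both report a normal-approximation Z with
mid-rank ties and no continuity correction, signed by the direction of the
median difference, with exact small-sample p-values substituted
automatically.  Bonferroni correction is applied over the family of the 12
features within each contrast.

The layer is presented statsmodels-style: build an
:class:`AffectContrastModel` from the normalized long table, call ``fit()``,
and read the :class:`AffectContrastResults` (records, significance matrix,
``summary()``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import CONDITIONS, FEATURE_NAMES

__all__ = [
    "shapiro_wilk_screen", "paired_wilcoxon", "ranksum_wilcoxon",
    "bonferroni", "effect_size_r", "demographics_t_test",
    "build_results_table", "ComparisonResult",
    "AffectContrastModel", "AffectContrastResults", "CONTRAST_ORDER",
]

#: exact-p thresholds (informative sample size)
SIGNED_RANK_EXACT_N = 25
RANKSUM_EXACT_N = 30

#: the nine contrast columns of the results matrix, in reporting order
CONTRAST_ORDER = (
    "HC:acq-vs-str", "UWS:acq-vs-str", "MCS:acq-vs-str",
    "HC-vs-MCS:acq", "HC-vs-MCS:str",
    "HC-vs-UWS:acq", "HC-vs-UWS:str",
    "HC-vs-DOC:acq", "HC-vs-DOC:str",
)


# --------------------------------------------------------------------------
# Elementary tests
# --------------------------------------------------------------------------

def shapiro_wilk_screen(values: np.ndarray, alpha: float = 0.05
                        ) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality screen: ``(W, p, normal?)``.

    Advisory only — the analysis always proceeds nonparametrically, the
    screen documents why.
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000 (got {values.size})")
    w, p = sstats.shapiro(values)
    return float(w), float(p), bool(p >= alpha)


def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by convolution over doubled mid-ranks.

    Enumerates the null distribution of W+ = sum of |d|-ranks with positive
    sign under independent equiprobable signs; mid-ranks make the
    distribution exact in the presence of ties (zero differences must
    already be dropped).
    """
    ranks = sstats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)          # doubled ranks are integers
    w2 = int(np.rint(2 * np.sum(ranks[d > 0])))
    coef = np.zeros(r2.sum() + 1)
    coef[0] = 1.0
    length = 1
    for r in r2:
        coef[r:length + r] += coef[:length]
        length += r
    total = coef.sum()
    p_ge = coef[w2:].sum() / total
    p_le = coef[: w2 + 1].sum() / total
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples: ``(Z, p)``.

    Zero differences are dropped; |d| ties take mid-ranks; Z uses the
    tie-corrected normal approximation without continuity correction and is
    signed by the direction of the median difference.  For up to
    ``SIGNED_RANK_EXACT_N`` informative pairs the p-value comes from the
    exact null distribution instead of the approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d_all = x - y
    d = d_all[d_all != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0  # degenerate: all pairs identical
    if n < 6:
        raise ValueError(f"need at least 6 informative pairs (got {n})")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= np.sum(counts ** 3 - counts) / 48.0
    z0 = (w_plus - mean) / np.sqrt(var)
    if n <= SIGNED_RANK_EXACT_N:
        p = _signed_rank_exact_p(d)
    else:
        p = float(2.0 * sstats.norm.sf(abs(z0)))
    md = float(np.median(d_all))
    sign = np.sign(md) if md != 0 else (np.sign(z0) or 1.0)
    return float(sign * abs(z0)), min(p, 1.0)


def ranksum_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Rank-sum (Mann-Whitney) test on independent samples: ``(Z, p)``.

    Mid-rank ties, tie-corrected normal-approximation Z without continuity
    correction, signed by the direction of the median difference; exact p
    for tie-free samples with combined size up to ``RANKSUM_EXACT_N``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 4 or n2 < 4:
        raise ValueError(f"need at least 4 observations per group (got {n1}, {n2})")
    nn = n1 + n2
    combined = np.concatenate([a, b])
    ranks = sstats.rankdata(combined)
    u1 = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (nn * (nn - 1))
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0  # all observations identical
    z0 = (u1 - mu) / np.sqrt(var)
    if nn <= RANKSUM_EXACT_N and counts.max() == 1:
        p = float(sstats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="exact").pvalue)
    else:
        p = float(2.0 * sstats.norm.sf(abs(z0)))
    md = float(np.median(a) - np.median(b))
    sign = np.sign(md) if md != 0 else (np.sign(z0) or 1.0)
    return float(sign * abs(z0)), min(p, 1.0)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Order-preserving Bonferroni correction: ``min(1, m * p)`` per value."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = max(1, p.size)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return [float(min(1.0, m * v)) if np.isfinite(v) else float("nan") for v in p]


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = |Z| / sqrt(N)."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    return float(abs(z) / np.sqrt(n_total))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    descriptives: dict
    degenerate: bool = False


def demographics_t_test(ages_a: np.ndarray, ages_b: np.ndarray) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance) on ages.

    Descriptives report both SD conventions (population n and sample n-1)
    since demographic tables are printed under either.
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")

    def describe(x):
        return {"n": int(x.size), "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)), "sd_pop": float(np.std(x, ddof=0))}

    desc = {"a": describe(a), "b": describe(b)}
    pooled_var = (np.var(a, ddof=1) * (a.size - 1)
                  + np.var(b, ddof=1) * (b.size - 1)) / (a.size + b.size - 2)
    if pooled_var == 0:
        equal = np.mean(a) == np.mean(b)
        return TTestResult(t=0.0 if equal else float("inf"),
                           p=1.0 if equal else 0.0,
                           descriptives=desc, degenerate=True)
    t, p = sstats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), p=float(p), descriptives=desc)


# --------------------------------------------------------------------------
# Comparison records and the results matrix
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    """One feature x one contrast, with everything a results row reports."""

    feature: str
    contrast: str
    n1: int
    n2: int
    mdn1: float
    mdn2: float
    statistic: float          # signed Z
    p_raw: float
    p_corrected: float
    r: float
    significant: bool

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "feature", "contrast", "n1", "n2", "mdn1", "mdn2",
            "statistic", "p_raw", "p_corrected", "r", "significant")}


def build_results_table(comparisons: list[ComparisonResult],
                        markers: tuple[str, str] = ("***", "–")) -> pd.DataFrame:
    """Feature x contrast matrix of significance markers.

    Rows follow the canonical feature order, columns the canonical contrast
    order (restricted to contrasts present); the full records are attached
    under ``df.attrs["records"]`` keyed by (feature, contrast).
    """
    if not comparisons:
        return pd.DataFrame()
    present = [c for c in CONTRAST_ORDER
               if any(r.contrast == c for r in comparisons)]
    extra = sorted({r.contrast for r in comparisons} - set(present))
    cols = present + extra
    sig_marker, ns_marker = markers
    table = pd.DataFrame(ns_marker, index=list(FEATURE_NAMES), columns=cols)
    records: dict[tuple[str, str], ComparisonResult] = {}
    for rec in comparisons:
        records[(rec.feature, rec.contrast)] = rec
        if rec.feature in table.index and rec.contrast in table.columns:
            table.loc[rec.feature, rec.contrast] = \
                sig_marker if rec.significant else ns_marker
    table.attrs["records"] = records
    return table


# --------------------------------------------------------------------------
# Model / Results objects
# --------------------------------------------------------------------------

class AffectContrastModel:
    """Wilcoxon/Bonferroni contrast model over normalized HRV values.

    Parameters
    ----------
    data : DataFrame
        Long table with columns ``subject_id, group, window_id, condition,
        feature, value`` (the output of :func:`hrvaffect.pipeline.run_cohort`).
    alpha : float
        Family-wise significance level after correction.
    family_size : int
        Bonferroni family (default: the 12 features within one contrast).
    unit : {"window", "subject"}
        Sampling unit: pooled window-level values (default) or per-subject
        condition means.
    """

    REQUIRED = ("subject_id", "group", "condition", "feature", "value")

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05,
                 family_size: int = len(FEATURE_NAMES), unit: str = "window"):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns: {missing}")
        if unit not in ("window", "subject"):
            raise ValueError("unit must be 'window' or 'subject'")
        if unit == "window" and "window_id" not in data.columns:
            raise ValueError("window-level analysis requires a window_id column")
        self.data = data.copy()
        self.alpha = float(alpha)
        self.family_size = int(family_size)
        self.unit = unit

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "AffectContrastModel":
        return cls(data, **kwargs)

    # -- data access -------------------------------------------------------

    def _group_mask(self, group: str) -> pd.Series:
        if group == "DOC":
            return self.data["group"].isin(["MCS", "UWS"])
        return self.data["group"] == group

    def _condition_values(self, group: str, condition: str, feature: str
                          ) -> np.ndarray:
        df = self.data[self._group_mask(group)
                       & (self.data["condition"] == condition)
                       & (self.data["feature"] == feature)]
        if self.unit == "subject":
            return df.groupby("subject_id", observed=True)["value"].mean().to_numpy()
        return df["value"].to_numpy()

    def _paired_values(self, group: str, feature: str
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Acquaintance/stranger values paired by protocol position within
        subject, pooled across the group's subjects."""
        df = self.data[self._group_mask(group)
                       & (self.data["feature"] == feature)]
        if self.unit == "subject":
            wide = df.groupby(["subject_id", "condition"], observed=True)[
                "value"].mean().unstack("condition").dropna()
            return (wide[CONDITIONS[0]].to_numpy(),
                    wide[CONDITIONS[1]].to_numpy())
        xs, ys = [], []
        for _, sub in df.groupby("subject_id", observed=True):
            acq = sub[sub["condition"] == CONDITIONS[0]].sort_values(
                "window_id")["value"].to_numpy()
            strg = sub[sub["condition"] == CONDITIONS[1]].sort_values(
                "window_id")["value"].to_numpy()
            m = min(acq.size, strg.size)
            xs.append(acq[:m])
            ys.append(strg[:m])
        if not xs:
            return np.array([]), np.array([])
        return np.concatenate(xs), np.concatenate(ys)

    # -- fitting -----------------------------------------------------------

    def _one_comparison(self, feature: str, contrast: str,
                        x: np.ndarray, y: np.ndarray, paired: bool
                        ) -> ComparisonResult:
        nan = float("nan")
        mdn1 = float(np.median(x)) if x.size else nan
        mdn2 = float(np.median(y)) if y.size else nan
        try:
            if paired:
                z, p = paired_wilcoxon(x, y)
            else:
                z, p = ranksum_wilcoxon(x, y)
        except ValueError:
            return ComparisonResult(feature, contrast, x.size, y.size,
                                    mdn1, mdn2, nan, nan, nan, nan, False)
        p_corr = bonferroni([p], m=self.family_size)[0]
        r = effect_size_r(z, x.size + y.size) if x.size + y.size >= 2 else nan
        return ComparisonResult(feature, contrast, x.size, y.size, mdn1, mdn2,
                                z, p, p_corr, r, bool(p_corr < self.alpha))

    def fit(self) -> "AffectContrastResults":
        """Run the nine contrasts x twelve features and package the results."""
        acq, strg = CONDITIONS
        comparisons: list[ComparisonResult] = []
        for feature in FEATURE_NAMES:
            for group in ("HC", "UWS", "MCS"):
                x, y = self._paired_values(group, feature)
                comparisons.append(self._one_comparison(
                    feature, f"{group}:acq-vs-str", x, y, paired=True))
            for other in ("MCS", "UWS", "DOC"):
                for cond, tag in ((acq, "acq"), (strg, "str")):
                    x = self._condition_values("HC", cond, feature)
                    y = self._condition_values(other, cond, feature)
                    comparisons.append(self._one_comparison(
                        feature, f"HC-vs-{other}:{tag}", x, y, paired=False))
        return AffectContrastResults(model=self, comparisons=comparisons)


@dataclass
class AffectContrastResults:
    """Fitted contrast results: records, tables, and a printable summary."""

    model: AffectContrastModel
    comparisons: list[ComparisonResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """All comparisons as a long DataFrame."""
        return pd.DataFrame([c.as_dict() for c in self.comparisons])

    def significance_matrix(self, markers: tuple[str, str] = ("***", "–")
                            ) -> pd.DataFrame:
        return build_results_table(self.comparisons, markers=markers)

    def get(self, feature: str, contrast: str) -> ComparisonResult | None:
        for c in self.comparisons:
            if c.feature == feature and c.contrast == contrast:
                return c
        return None

    def summary(self) -> str:
        """Human-readable summary: significance matrix plus key statistics."""
        mat = self.significance_matrix()
        lines = [
            "Nonparametric HRV contrasts "
            f"(alpha={self.model.alpha}, Bonferroni m={self.model.family_size}, "
            f"unit={self.model.unit})",
            "", mat.to_string(), "",
            "Significant cells (feature, contrast, Mdn1 vs Mdn2, Z, p_corr, r):",
        ]
        any_sig = False
        for c in self.comparisons:
            if c.significant:
                any_sig = True
                lines.append(
                    f"  {c.feature:9s} {c.contrast:16s} "
                    f"Mdn {c.mdn1:8.3f} vs {c.mdn2:8.3f}  "
                    f"Z={c.statistic:6.2f}  p={c.p_corrected:.4g}  r={c.r:.2f}")
        if not any_sig:
            lines.append("  (none)")
        return "\n".join(lines)

    def plot_matrix(self, ax=None):
        """Heat map of the significance matrix (1 = significant)."""
        import matplotlib.pyplot as plt

        mat = self.significance_matrix(markers=("1", "0")).astype(int)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        ax.imshow(mat.to_numpy(), cmap="Greys", vmin=0, vmax=1, aspect="auto")
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(mat.shape[0]), mat.index)
        ax.set_title("Significant contrasts after Bonferroni correction")
        return ax
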