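"""Method-agreement and clinical-correlation statistics.

The statistical layer used to compare two quantification methods and to
relate clot composition to CT attenuation:

* Bland-Altman agreement — bias (mean of paired differences), sample SD,
  and 95% limits of agreement at bias ± 1.96·SD;
* Spearman rank correlation with mid-rank ties and the usual two-sided t
  approximation, t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 df;
* Pearson chi-squared on contingency tables (no continuity correction by
  default);
* the hyperdense artery sign (HAS) rule: mean clot attenuation ≥ 50 HU on
  non-contrast CT is HAS-positive.

``agreement_report`` ties these together over per-clot composition tables
from two methods plus a clinical table, the analysis applied to a cohort of
quantified clots.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from clotquant.quantify import ClotCategory, categorize_percentages

HAS_THRESHOLD_HU = 50.0
CATEGORY_ORDER = (ClotCategory.RBC_RICH, ClotCategory.MIXED, ClotCategory.FIBRIN_RICH)
COMPONENTS = ("pct_rbc", "pct_wbc", "pct_fibrin")


def has_flag(mean_hu: float) -> bool:
    """Hyperdense artery sign: positive iff mean attenuation >= 50 HU."""
    if not math.isfinite(mean_hu):
        raise ValueError(f"mean_hu must be finite, got {mean_hu}")
    return mean_hu >= HAS_THRESHOLD_HU


@dataclass(frozen=True)
class ClinicalRecord:
    clot_id: str
    mean_hu: float
    max_hu: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_hu):
            raise ValueError("mean_hu must be finite")

    @property
    def has_positive(self) -> bool:
        return has_flag(self.mean_hu)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    points: tuple = ()  # (average, difference) pairs for plotting

    def __post_init__(self) -> None:
        assert abs((self.loa_high - self.loa_low) - 2 * 1.96 * self.sd) <= 1e-9 * max(1.0, self.sd)


@dataclass(frozen=True)
class RankCorrelationResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    observed: tuple
    expected: tuple


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements, differences a − b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and the same length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    points = tuple(zip(((a + b) / 2.0).tolist(), diff.tolist()))
    return BlandAltmanResult(
        bias=bias, sd=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n=len(a), points=points,
    )


def spearman(x, y, exact: bool = False) -> RankCorrelationResult:
    """Spearman rank correlation with mid-rank ties.

    p is two-sided from the t approximation on n−2 df (ρ = ±1 gives p = 0);
    ``exact=True`` switches to the permutation distribution (n ≤ 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only for n <= 10")
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return RankCorrelationResult(rho=rho, p=count / total, n=n)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return RankCorrelationResult(rho=rho, p=float(p), n=n)


def pearson_chi2(observed, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-squared test of independence on an r×c table.

    Expected counts are the product of margins over the grand total;
    Yates continuity correction (2×2 only) is off by default.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("observed must be an r x c table with r, c >= 2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("observed must hold non-negative integer counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - expected)
    if correction and obs.shape == (2, 2):
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(
        statistic=statistic, df=df, p=p,
        observed=tuple(map(tuple, obs.astype(int).tolist())),
        expected=tuple(map(tuple, expected.tolist())),
    )


def composition_has_table(
    categories: list[ClotCategory], flags: list[bool]
) -> tuple[np.ndarray, np.ndarray]:
    """Tally clots into a 3×2 table (rows RBC-rich / mixed / fibrin-rich,
    columns HAS+ / HAS−) and the collapsed 2×2 (RBC-rich vs other)."""
    if len(categories) != len(flags):
        raise ValueError("categories and flags must have the same length")
    table = np.zeros((3, 2), dtype=int)
    for cat, flag in zip(categories, flags):
        table[CATEGORY_ORDER.index(cat), 0 if flag else 1] += 1
    collapsed = np.vstack([table[0], table[1] + table[2]])
    return table, collapsed


# ---------------------------------------------------------------------------
# Tables and the combined report
# ---------------------------------------------------------------------------

def load_composition_table(path: str, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-clot composition table from CSV or XLSX.

    ``column_map`` maps source column names to the canonical columns
    (clot_id, pct_rbc, pct_wbc, pct_fibrin[, category]) so spreadsheets
    with arbitrary headers can be imported. A missing category column is
    derived from the >=60% rule.
    """
    if path.lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"clot_id", "pct_rbc", "pct_wbc", "pct_fibrin"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} (use a column map)")
    df = df.copy()
    df["clot_id"] = df["clot_id"].astype(str)
    if "category" not in df.columns:
        df["category"] = [
            categorize_percentages(r, f).value for r, f in zip(df["pct_rbc"], df["pct_fibrin"])
        ]
    return df


def load_clinical_table(path: str, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read the per-clot clinical table (clot_id, mean_hu[, max_hu])."""
    if path.lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"clot_id", "mean_hu"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} (use a column map)")
    df = df.copy()
    df["clot_id"] = df["clot_id"].astype(str)
    df["has_positive"] = [has_flag(v) for v in df["mean_hu"]]
    return df


@dataclass
class AgreementReport:
    """All cross-method and clinical statistics for one clot cohort."""

    n_clots: int
    pooled_spearman: RankCorrelationResult
    bland_altman: BlandAltmanResult
    rbc_vs_hu: dict[str, RankCorrelationResult]
    has_3x2: dict[str, ChiSquareResult]
    has_2x2: dict[str, ChiSquareResult]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        # drop the (long) Bland-Altman point list from the JSON summary
        d["bland_altman"] = {k: v for k, v in d["bland_altman"].items() if k != "points"}
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        ba = self.bland_altman
        lines = [
            f"Clots analyzed: {self.n_clots}",
            (
                f"Method agreement (pooled over components, n={self.pooled_spearman.n}): "
                f"rho={self.pooled_spearman.rho:.3f}, p={self.pooled_spearman.p:.3g}"
            ),
            (
                f"Bland-Altman (method A - method B): bias={ba.bias:.2f}, SD={ba.sd:.2f}, "
                f"LoA [{ba.loa_low:.1f}, {ba.loa_high:.1f}]"
            ),
        ]
        for method, res in self.rbc_vs_hu.items():
            lines.append(f"{method}: %RBC vs mean HU rho={res.rho:.3f}, p={res.p:.3g}")
        for method, res in self.has_3x2.items():
            lines.append(
                f"{method}: composition x HAS X2({res.df})={res.statistic:.3f}, p={res.p:.3g}"
            )
        for method, res in self.has_2x2.items():
            lines.append(
                f"{method}: RBC-rich x HAS X2({res.df})={res.statistic:.3f}, p={res.p:.3g}"
            )
        lines.extend(self.notes)
        return "\n".join(lines)


def agreement_report(
    method_a: pd.DataFrame,
    method_b: pd.DataFrame,
    clinical: pd.DataFrame,
    names: tuple[str, str] = ("method_a", "method_b"),
) -> AgreementReport:
    """Compare two per-clot composition tables and relate them to CT density.

    Joins on clot_id and computes: pooled per-component Spearman between
    methods (n = clots × 3 components), Bland-Altman on the pooled pairs
    (differences A − B), per-method Spearman of %RBC vs mean HU, and
    per-method chi-squared of the 3×2 and collapsed 2×2 HAS tables. Row
    order of the inputs does not matter.
    """
    a = method_a.set_index("clot_id").sort_index()
    b = method_b.set_index("clot_id").sort_index()
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 clots common to both methods, got {len(common)}")
    a = a.loc[common]
    b = b.loc[common]
    pooled_a = np.concatenate([a[c].to_numpy(dtype=float) for c in COMPONENTS])
    pooled_b = np.concatenate([b[c].to_numpy(dtype=float) for c in COMPONENTS])
    pooled_rho = spearman(pooled_a, pooled_b)
    ba = bland_altman(pooled_a, pooled_b)

    clin = clinical.set_index("clot_id")
    notes: list[str] = []
    rbc_vs_hu: dict[str, RankCorrelationResult] = {}
    has_3x2: dict[str, ChiSquareResult] = {}
    has_2x2: dict[str, ChiSquareResult] = {}
    clin_common = common.intersection(clin.index)
    if len(clin_common) >= 3:
        hu = clin.loc[clin_common, "mean_hu"].to_numpy(dtype=float)
        flags = [has_flag(v) for v in hu]
        for name, tab in zip(names, (a, b)):
            sub = tab.loc[clin_common]
            rbc_vs_hu[name] = spearman(sub["pct_rbc"].to_numpy(dtype=float), hu)
            cats = [ClotCategory(c) for c in sub["category"]]
            t3, t2 = composition_has_table(cats, flags)
            for label, t, sink in (("3x2", t3, has_3x2), ("2x2", t2, has_2x2)):
                try:
                    sink[name] = pearson_chi2(t)
                except ValueError as exc:
                    notes.append(f"{name} {label} HAS table not testable: {exc}")
    else:
        notes.append("fewer than 3 clots with clinical data; HU statistics skipped")
    return AgreementReport(
        n_clots=len(common),
        pooled_spearman=pooled_rho,
        bland_altman=ba,
        rbc_vs_hu=rbc_vs_hu,
        has_3x2=has_3x2,
        has_2x2=has_2x2,
        notes=notes,
    )
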