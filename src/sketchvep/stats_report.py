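"""Group-level statistics and report generation.

Within-subject comparisons across SNR conditions: one-way
repeated-measures ANOVA with classic eta-squared, Bonferroni-corrected
paired t-tests with paired Cohen's d and normal-approximation 95%
confidence intervals, Spearman correlation between preference and
latency differences, and Shapiro-Wilk normality checks.  Results are
gathered into a machine-readable JSON report plus TSV tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """One statistical test with its effect size."""

    name: str
    statistic: float
    df: tuple[float, ...] | None
    p_value: float
    effect_size: float | None = None
    effect_size_label: str | None = None
    ci95: tuple[float, float] | None = None
    correction: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        if self.ci95 is not None and self.ci95[0] > self.ci95[1]:
            raise ValueError("CI lower bound exceeds upper bound")


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    """participant x condition grid; raises naming missing cells."""
    wide = table.pivot(index="participant", columns="condition", values="value")
    if wide.isna().any().any():
        missing = [
            f"({p}, {c})" for p in wide.index for c in wide.columns
            if pd.isna(wide.loc[p, c])
        ]
        raise ValueError(f"incomplete participant x condition grid; "
                         f"missing cells: {', '.join(missing)}")
    return wide


def compute_preference(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant preference for the higher-SNR compound.

    ``responses`` needs columns participant, afc_high_snr and
    chose_higher (from the 2AFC table); the result is a long table
    (participant, condition = higher SNR level, value = fraction chosen).
    """
    if responses["chose_higher"].isna().any():
        raise ValueError("every 2AFC trial needs a recorded choice")
    pref = (
        responses.groupby(["participant", "afc_high_snr"], observed=True)
        ["chose_higher"].mean().reset_index()
    )
    pref.columns = ["participant", "condition", "value"]
    return pref


def rm_anova(table: pd.DataFrame) -> TestResult:
    """One-way repeated-measures ANOVA over conditions.

    F and p come from :func:`pingouin.rm_anova`; eta-squared is the
    classic SS_condition / SS_total (subject variability included in the
    denominator), computed from the sums of squares directly.
    """
    import pingouin as pg

    wide = _pivot(table)
    n, k = wide.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 participants")
    x = wide.to_numpy()
    ss_total = float(((x - x.mean()) ** 2).sum())
    ss_cond = float(n * ((x.mean(axis=0) - x.mean()) ** 2).sum())
    df = (float(k - 1), float((k - 1) * (n - 1)))
    if ss_cond <= 1e-12 * max(ss_total, 1.0):
        # no condition effect at all; F-ratio degenerates to 0/0
        return TestResult(name="rm_anova", statistic=0.0, df=df, p_value=1.0,
                          effect_size=0.0, effect_size_label="eta_squared")
    aov = pg.rm_anova(data=table, dv="value", within="condition",
                      subject="participant", detailed=True)
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return TestResult(
        name="rm_anova",
        statistic=float(aov.loc[0, "F"]),
        df=(float(aov.loc[0, "DF"]), float(aov.loc[1, "DF"])),
        p_value=float(aov.loc[0, p_col]),
        effect_size=ss_cond / ss_total if ss_total > 0 else 0.0,
        effect_size_label="eta_squared",
    )


def paired_cohens_d(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float], str | None]:
    """Paired Cohen's d (difference-score sd) with a normal-approx 95% CI.

    d = mean(x - y) / sd(x - y); se(d) ~= sqrt(1/n + d^2 / (2n)).
    Zero-variance differences give d = 0 with a flag.
    """
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0, (0.0, 0.0), "zero-variance differences"
    d = diff.mean() / sd
    se = math.sqrt(1 / n + d**2 / (2 * n))
    return d, (d - 1.96 * se, d + 1.96 * se), None


def pairwise_tests(table: pd.DataFrame) -> list[TestResult]:
    """Bonferroni-corrected paired t-tests over all condition pairs."""
    wide = _pivot(table)
    if len(wide) < 2:
        raise ValueError("need at least 2 paired observations")
    pairs = list(combinations(wide.columns, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        if np.ptp(x - y) == 0 and (x - y)[0] == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sps.ttest_rel(x, y)
        d, ci, note = paired_cohens_d(x, y)
        results.append(TestResult(
            name=f"t_{a}_vs_{b}",
            statistic=float(t_stat),
            df=(float(len(wide) - 1),),
            p_value=min(1.0, m * float(p)),
            effect_size=d,
            effect_size_label="cohens_d",
            ci95=ci,
            correction=f"bonferroni(m={m})",
            note=note,
        ))
    return results


def correlate(x: np.ndarray, y: np.ndarray, name: str = "spearman") -> TestResult:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(name=name, statistic=math.nan, df=None,
                          p_value=math.nan, note="constant input vector")
    r, p = sps.spearmanr(x, y)
    return TestResult(name=name, statistic=float(r), df=(float(len(x) - 2),),
                      p_value=float(p))


def shapiro_by_condition(table: pd.DataFrame) -> dict[str, TestResult]:
    """Shapiro-Wilk normality per condition."""
    out = {}
    for cond, grp in table.groupby("condition", observed=True):
        w, p = sps.shapiro(grp["value"])
        out[str(cond)] = TestResult(name=f"shapiro_{cond}", statistic=float(w),
                                    df=None, p_value=float(p))
    return out


REPORT_SCHEMA = {
    "type": "object",
    "required": ["condition_means", "anova", "pairwise", "normality",
                 "correlations"],
    "properties": {
        "condition_means": {"type": "object"},
        "anova": {"type": ["object", "null"]},
        "pairwise": {"type": "array"},
        "normality": {"type": "object"},
        "correlations": {"type": "array"},
    },
}


def _result_dict(r: TestResult) -> dict:
    d = asdict(r)
    d["df"] = list(r.df) if r.df is not None else None
    d["ci95"] = list(r.ci95) if r.ci95 is not None else None
    return d


def analyze_measure(table: pd.DataFrame) -> dict:
    """Condition means +/- sem, normality, RM-ANOVA and pairwise tests.

    Sections that need more data than the table holds (within-subject
    tests want >= 3 participants and >= 2 conditions) are reported as
    null rather than raising, so partial cohorts still yield a report.
    """
    wide = _pivot(table)
    n, k = wide.shape
    means = {
        str(c): {
            "mean": float(wide[c].mean()),
            "sem": float(wide[c].std(ddof=1) / math.sqrt(len(wide))),
            "n": int(len(wide)),
        }
        for c in wide.columns
    }
    enough = n >= 3 and k >= 2
    return {
        "condition_means": means,
        "normality": {k_: _result_dict(v)
                      for k_, v in shapiro_by_condition(table).items()},
        "anova": _result_dict(rm_anova(table)) if enough else None,
        "pairwise": ([_result_dict(r) for r in pairwise_tests(table)]
                     if enough else []),
    }


def build_report(
    sections: dict[str, pd.DataFrame],
    correlations: list[TestResult] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble the full statistical report.

    ``sections`` maps a measure name (e.g. ``c1_latency_s`` or
    ``preference``) to its long-format table (participant, condition,
    value).  Writes ``report.json`` and one TSV per section when
    ``out_dir`` is given; empty input produces a valid report with empty
    sections.
    """
    report: dict = {"schema": REPORT_SCHEMA, "measures": {},
                    "correlations": [_result_dict(r) for r in (correlations or [])]}
    for name, table in sections.items():
        report["measures"][name] = (
            analyze_measure(table) if len(table) else
            {"condition_means": {}, "normality": {}, "anova": None,
             "pairwise": []}
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        for name, table in sections.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return report
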