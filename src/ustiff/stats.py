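"""Group statistics and report tables for mass comparisons.

Mass types are compared pairwise (cancer vs cyst, cancer vs fibroadenoma,
cyst vs fibroadenoma) within strata of size class x filtering, on the mass
stiffness index and on stiffness-texture homogeneity.  The t-test is the
Welch unequal-variance form; frequency contrasts use the Pearson chi-squared
test without continuity correction.  Per-group spread is summarized by the
5th-95th percentile interval of the per-mass values.  Raw p-values are
always reported; the 0.05 threshold only sets a significance flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05
_PAIR_ORDER = [("cancer", "cyst"), ("cancer", "fibroadenoma"), ("cyst", "fibroadenoma")]


def welch_t_test(xs, ys):
    """Welch's unequal-variance t-test.

    Returns
    -------
    (t, df, p) : floats
        Test statistic, Welch-Satterthwaite degrees of freedom, and the
        two-sided p-value.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.size < 2 or ys.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise ValueError("non-finite observations")
    res = sps.ttest_ind(xs, ys, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_squared(table):
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction; df = (r - 1)(c - 1).  Zero row or column
    margins are rejected.
    """
    table = np.asarray(table, float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("need a 2-D table of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: chi-squared undefined")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def percentile_interval_5_95(xs):
    """(5th, 95th) percentile of the values, linear interpolation."""
    xs = np.asarray(xs, float)
    if xs.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = np.percentile(xs, [5.0, 95.0])
    return float(lo), float(hi)


@dataclass
class GroupComparison:
    """One pairwise contrast within a (size class, filtering) stratum."""

    group_a: str
    group_b: str
    metric: str
    size_class: str
    filtered: bool
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    t: float
    df: float
    t_p: float
    significant: bool
    chi2_p: float | None = None


def compare_mass_groups(records, metrics=("stiffness_index", "homogeneity")):
    """All pairwise mass-type contrasts per (size class x filtered) stratum.

    ``records`` is a list of :class:`~ustiff.massmetrics.MassRecord`.  Strata
    or pairs with fewer than 2 masses per group are skipped with a log entry.
    Also attaches a chi-squared p-value on hard-majority frequencies
    (share of masses whose modal stiffness class is hard) where defined.
    """
    if len(records) == 0:
        raise ValueError("no mass records")
    df = pd.DataFrame(
        {
            "histology": [r.histology for r in records],
            "size_class": [r.size_class for r in records],
            "filtered": [r.filtered for r in records],
            "stiffness_index": [r.stiffness_index for r in records],
            "homogeneity": [r.homogeneity for r in records],
            "pct_hard": [r.pct_hard for r in records],
        }
    )
    out: list[GroupComparison] = []
    for (size_class, filtered), stratum in df.groupby(["size_class", "filtered"], sort=True):
        for a, b in _PAIR_ORDER:
            for metric in metrics:
                xs = stratum.loc[stratum.histology == a, metric].dropna().to_numpy()
                ys = stratum.loc[stratum.histology == b, metric].dropna().to_numpy()
                if xs.size < 2 or ys.size < 2:
                    log.info(
                        "skipping %s vs %s on %s (%s, filtered=%s): group too small",
                        a, b, metric, size_class, filtered,
                    )
                    continue
                t, dof, p = welch_t_test(xs, ys)
                chi2_p = None
                if metric == "stiffness_index":
                    hard_a = stratum.loc[stratum.histology == a, "pct_hard"] > 50.0
                    hard_b = stratum.loc[stratum.histology == b, "pct_hard"] > 50.0
                    counts = np.array(
                        [
                            [hard_a.sum(), (~hard_a).sum()],
                            [hard_b.sum(), (~hard_b).sum()],
                        ]
                    )
                    if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
                        chi2_p = chi_squared(counts)[2]
                out.append(
                    GroupComparison(
                        group_a=a,
                        group_b=b,
                        metric=metric,
                        size_class=size_class,
                        filtered=bool(filtered),
                        n_a=int(xs.size),
                        n_b=int(ys.size),
                        mean_a=float(xs.mean()),
                        mean_b=float(ys.mean()),
                        interval_a=percentile_interval_5_95(xs),
                        interval_b=percentile_interval_5_95(ys),
                        t=t,
                        df=dof,
                        t_p=p,
                        significant=p < ALPHA,
                        chi2_p=chi2_p,
                    )
                )
    return out


def comparisons_frame(comparisons) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "size_class": c.size_class,
                "filtered": c.filtered,
                "metric": c.metric,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "p5_a": c.interval_a[0],
                "p95_a": c.interval_a[1],
                "p5_b": c.interval_b[0],
                "p95_b": c.interval_b[1],
                "t": c.t,
                "df": c.df,
                "t_p": c.t_p,
                "chi2_p": c.chi2_p,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows)


def records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "breast_id": r.breast_id,
            "histology": r.histology,
            "filtered": r.filtered,
            "size_class": r.size_class,
            "equivalent_diameter_cm": r.equivalent_diameter_cm,
            "stiffness_index": r.stiffness_index,
            "pct_soft": r.pct_soft,
            "pct_intermediate": r.pct_intermediate,
            "pct_hard": r.pct_hard,
            "homogeneity": r.homogeneity,
            "area_mm2": r.area_mm2,
        }
        row.update({f"pct_{k}": v for k, v in r.component_pcts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def mass_group_distributions(records) -> pd.DataFrame:
    """Mean six-component percentage per (histology, size class, filtered).

    The per-mass six-way pixel distributions averaged within each mass
    group - the data behind a grouped six-bar chart per stratum.
    """
    df = records_frame(records)
    comp_cols = [c for c in df.columns if c.startswith("pct_") and c.count("_") >= 2]
    if not comp_cols:
        raise ValueError("records carry no component percentages")
    return (
        df.groupby(["size_class", "filtered", "histology"], sort=True)[comp_cols]
        .mean()
        .reset_index()
    )


def render_reports(volumes: pd.DataFrame | None, records, comparisons, outdir) -> dict:
    """Write the CSV report bundle; returns {name: path}.

    Emits the component-volume table, per-mass records, pairwise group
    comparisons, and the per-group six-component distributions, all with
    deterministic row ordering.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if volumes is not None:
        p = outdir / "component_volumes.csv"
        volumes.to_csv(p)
        written["component_volumes"] = p
    if records:
        p = outdir / "mass_records.csv"
        records_frame(records).to_csv(p, index=False)
        written["mass_records"] = p
        p = outdir / "mass_group_distributions.csv"
        mass_group_distributions(records).to_csv(p, index=False)
        written["mass_group_distributions"] = p
    if comparisons:
        p = outdir / "group_comparisons.csv"
        comparisons_frame(comparisons).to_csv(p, index=False)
        written["group_comparisons"] = p
    return written
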