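"""Statistical battery comparing clinical, simulated and estimated TVDTs.

The analyses mirror a reader-study evaluation of a growth-simulation
pipeline: Shapiro-Wilk normality per data set, Friedman reproducibility
across repeated measurement sessions, Anderson-Darling family selection,
two-sample Kolmogorov-Smirnov plus Wilcoxon signed-rank pairwise
comparisons, median difference with IQR per session, ordinary
least-squares regression of measured versus true size per screening
round, and a fast-versus-slow growth-class error comparison by two-sample
t-test.  All tests are reported individually at the 0.05 level with no
multiple-testing correction.

Conventions: quantiles (and hence the IQR) use linear interpolation;
sentinel (non-growing) TVDT estimates are excluded pairwise with the
exclusion count reported; zero differences are dropped from the Wilcoxon
signed-rank statistic, with the count reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from tvdtsim.distribution import ClinicalFit, fit_distribution, select_family

ALPHA = 0.05


# ---------------------------------------------------------------------------
# individual tests
# ---------------------------------------------------------------------------

def normality(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError(f"need at least 3 finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) data")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def reproducibility(sessions) -> tuple[float, float]:
    """Friedman chi-square test over paired measurement sessions.

    Identical sessions carry no evidence of a difference and are reported
    as (0, 1).
    """
    arrays = [np.asarray(s, dtype=float) for s in sessions]
    if len(arrays) < 2:
        raise ValueError("need at least 2 sessions")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("sessions must have equal lengths")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        return 0.0, 1.0
    res = stats.friedmanchisquare(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PairComparison:
    """KS (and, when paired, Wilcoxon signed-rank) comparison of two sets."""

    ks_statistic: float
    ks_pvalue: float
    wilcoxon_statistic: float | None = None
    wilcoxon_pvalue: float | None = None
    n_x: int = 0
    n_y: int = 0
    n_excluded: int = 0  # sentinel-valued entries removed (pairwise if paired)
    n_zero_diff: int = 0  # zero differences dropped by the signed-rank test
    degenerate: bool = False  # no non-zero differences: reported as no-difference


def compare_pair(x, y, paired: bool = False) -> PairComparison:
    """Two-sample KS test, plus Wilcoxon signed-rank when ``paired``.

    NaN entries (sentinel TVDTs) are excluded — pairwise for paired data —
    and counted.  The exact small-sample KS computation is used where
    scipy supports it.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if paired:
        if xa.size != ya.size:
            raise ValueError("paired comparison requires equal lengths")
        keep = np.isfinite(xa) & np.isfinite(ya)
        n_excl = int(xa.size - keep.sum())
        xa, ya = xa[keep], ya[keep]
    else:
        n_excl = int((~np.isfinite(xa)).sum() + (~np.isfinite(ya)).sum())
        xa, ya = xa[np.isfinite(xa)], ya[np.isfinite(ya)]
    if min(xa.size, ya.size) < 5:
        raise ValueError("need at least 5 usable values per sample")

    ks = stats.ks_2samp(xa, ya, method="auto")
    result = dict(
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_x=int(xa.size),
        n_y=int(ya.size),
        n_excluded=n_excl,
    )
    if paired:
        diff = ya - xa
        n_zero = int((diff == 0).sum())
        result["n_zero_diff"] = n_zero
        if np.all(diff == 0):
            result.update(
                wilcoxon_statistic=0.0, wilcoxon_pvalue=1.0, degenerate=True
            )
        else:
            w = stats.wilcoxon(xa, ya, zero_method="wilcox")
            result.update(
                wilcoxon_statistic=float(w.statistic),
                wilcoxon_pvalue=float(w.pvalue),
            )
    return PairComparison(**result)


def median_difference(assigned, estimated) -> tuple[float, float, int]:
    """Median and IQR (days) of per-patient differences assigned - estimated.

    Sentinel (NaN) estimates are excluded pairwise; returns
    (median, iqr, n_excluded).  Quantiles use linear interpolation.
    """
    a = np.asarray(assigned, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.size != e.size:
        raise ValueError("paired lists required")
    keep = np.isfinite(a) & np.isfinite(e)
    n_excl = int(a.size - keep.sum())
    diff = a[keep] - e[keep]
    if diff.size == 0:
        raise ValueError("no usable pairs after sentinel exclusion")
    q25, q50, q75 = np.percentile(diff, [25, 50, 75])
    return float(q50), float(q75 - q25), n_excl


def regress_sizes(true_sizes, measured_sizes) -> tuple[float, float, float]:
    """OLS fit of measured on true size: (slope, intercept, R^2)."""
    x = np.asarray(true_sizes, dtype=float)
    y = np.asarray(measured_sizes, dtype=float)
    if x.size != y.size:
        raise ValueError("paired lists required")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in true sizes")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass(frozen=True)
class GrowthClassResult:
    """Fast/slow quartile split of assigned TVDTs with error comparison."""

    fast_ids: list
    slow_ids: list
    fast_errors: list  # |est - assigned| / assigned, fast class
    slow_errors: list
    t_statistic: float
    p_value: float
    degenerate: bool = False


def growth_class_analysis(assigned, estimated, ids=None) -> GrowthClassResult:
    """Compare TVDT estimation error between fast- and slow-growing tumors.

    Fast = lowest quartile of assigned TVDT, slow = highest quartile, each
    floor(n/4) members (rank ties broken by id).  The per-patient absolute
    relative error |estimated - assigned| / assigned is compared between
    classes with a two-sample t-test.
    """
    a = np.asarray(assigned, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.size != e.size:
        raise ValueError("paired lists required")
    if a.size < 8:
        raise ValueError(f"need at least 8 patients, got {a.size}")
    id_arr = np.arange(1, a.size + 1) if ids is None else np.asarray(ids)
    keep = np.isfinite(a) & np.isfinite(e)
    a, e, id_arr = a[keep], e[keep], id_arr[keep]
    k = a.size // 4
    if k < 2:
        raise ValueError("quartile classes need at least 2 members each")
    order = np.lexsort((id_arr, a))  # TVDT ascending, ties by id
    fast, slow = order[:k], order[-k:]
    err = np.abs(e - a) / a
    fe, se = err[fast], err[slow]
    if np.ptp(fe) == 0 and np.ptp(se) == 0 and fe[0] == se[0]:
        return GrowthClassResult(
            fast_ids=list(id_arr[fast]),
            slow_ids=list(id_arr[slow]),
            fast_errors=list(fe),
            slow_errors=list(se),
            t_statistic=0.0,
            p_value=1.0,
            degenerate=True,
        )
    t = stats.ttest_ind(fe, se)
    return GrowthClassResult(
        fast_ids=list(id_arr[fast]),
        slow_ids=list(id_arr[slow]),
        fast_errors=list(fe),
        slow_errors=list(se),
        t_statistic=float(t.statistic),
        p_value=float(t.pvalue),
    )


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Machine-readable results of the full statistical battery."""

    alpha: float
    normality: dict = field(default_factory=dict)
    family_selection: list = field(default_factory=list)
    reproducibility: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)
    median_diff: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)
    growth_class: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_report(
    cohort,
    estimates: pd.DataFrame,
    measurements=None,
    clinical_values=None,
    fit: ClinicalFit | None = None,
    *,
    alpha: float = ALPHA,
    family_bootstrap: int = 1000,
    seed=None,
) -> EvaluationReport:
    """Run the full battery over a measured cohort.

    Parameters
    ----------
    cohort : list of VirtualPatient
    estimates : frame with columns patient_id, session, tvdt_est_days, status
        (the output of ``observer.estimate_cohort_tvdt``)
    measurements : optional list of MeasurementRecord, enables the
        reproducibility (Friedman) and size-regression analyses
    clinical_values : optional raw clinical TVDTs (days); enables the
        clinical-arm comparisons and AD family selection on clinical data
    fit : the clinical fit used for sampling; a reference sample of
        cohort size is drawn from it for fit-versus-data comparisons
    """
    rng = np.random.default_rng(seed)
    report = EvaluationReport(alpha=alpha)

    assigned = np.array([p.tvdt for p in cohort])
    ids = np.array([p.id for p in cohort])
    sessions = sorted(estimates["session"].unique())
    est_by_session = {
        s: (
            estimates[estimates["session"] == s]
            .set_index("patient_id")["tvdt_est_days"]
            .reindex(ids)
            .to_numpy()
        )
        for s in sessions
    }
    est_mean = np.nanmean(np.vstack(list(est_by_session.values())), axis=0)

    # --- normality ---------------------------------------------------------
    datasets = {"simulated": assigned}
    for s in sessions:
        datasets[f"estimated_session_{s}"] = est_by_session[s]
    if clinical_values is not None:
        datasets["clinical"] = np.asarray(clinical_values, dtype=float)
    for name, values in datasets.items():
        v = values[np.isfinite(values)]
        stat, p = normality(v)
        report.normality[name] = {"statistic": stat, "pvalue": p, "n": int(v.size)}

    # --- family selection --------------------------------------------------
    fam_data = (
        np.asarray(clinical_values, dtype=float)
        if clinical_values is not None
        else assigned
    )
    fam = select_family(
        fam_data, n_bootstrap=family_bootstrap, seed=rng.integers(2**31)
    )
    report.family_selection = [
        {
            "family": r.family,
            "ad_statistic": r.ad_statistic,
            "pvalue": r.p_value,
            "mean": r.fit.mean,
            "sd": r.fit.sd,
        }
        for r in fam
    ]

    # --- reproducibility & regression (need raw size measurements) ---------
    if measurements is not None:
        true_size = {(p.id, 1): p.d_round1 for p in cohort}
        true_size.update({(p.id, 2): p.d_round2 for p in cohort})
        for rnd in (1, 2):
            per_session = {
                s: {
                    r.patient_id: r.mean_size
                    for r in measurements
                    if r.session == s and r.round == rnd
                }
                for s in sessions
            }
            stacked = [
                [per_session[s][pid] for pid in ids] for s in sessions
            ]
            stat, p = reproducibility(stacked)
            report.reproducibility[f"round_{rnd}"] = {"statistic": stat, "pvalue": p}
            truth = [true_size[(pid, rnd)] for s in sessions for pid in ids]
            meas = [per_session[s][pid] for s in sessions for pid in ids]
            slope, intercept, r2 = regress_sizes(truth, meas)
            report.regression[f"round_{rnd}"] = {
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
            }

    # --- pairwise comparisons ----------------------------------------------
    def _record(name, comp: PairComparison):
        report.pairwise[name] = {
            "ks_statistic": comp.ks_statistic,
            "ks_pvalue": comp.ks_pvalue,
            "wilcoxon_statistic": comp.wilcoxon_statistic,
            "wilcoxon_pvalue": comp.wilcoxon_pvalue,
            "n_excluded": comp.n_excluded,
            "degenerate": comp.degenerate,
        }

    if fit is not None:
        ref = fit.frozen.rvs(size=assigned.size, random_state=rng)
        _record("simulated_vs_clinical_fit", compare_pair(assigned, ref))
        if clinical_values is not None:
            _record(
                "clinical_vs_clinical_fit",
                compare_pair(clinical_values, fit.frozen.rvs(
                    size=len(clinical_values), random_state=rng)),
            )
    for s in sessions:
        _record(
            f"simulated_vs_estimated_session_{s}",
            compare_pair(assigned, est_by_session[s], paired=True),
        )
        if clinical_values is not None:
            _record(
                f"clinical_vs_estimated_session_{s}",
                compare_pair(clinical_values, est_by_session[s]),
            )

    # --- median difference per session --------------------------------------
    for s in sessions:
        med, iqr, n_excl = median_difference(assigned, est_by_session[s])
        report.median_diff[f"session_{s}"] = {
            "median_days": med,
            "iqr_days": iqr,
            "n_excluded": n_excl,
        }

    # --- growth classes ------------------------------------------------------
    gc = growth_class_analysis(assigned, est_mean, ids=ids)
    report.growth_class = {
        "fast_ids": [int(i) for i in gc.fast_ids],
        "slow_ids": [int(i) for i in gc.slow_ids],
        "fast_mean_abs_rel_error": float(np.mean(gc.fast_errors)),
        "slow_mean_abs_rel_error": float(np.mean(gc.slow_errors)),
        "t_statistic": gc.t_statistic,
        "pvalue": gc.p_value,
        "degenerate": gc.degenerate,
    }

    report.meta = {"n_patients": int(len(cohort)), "n_sessions": len(sessions)}
    return report


def render_plots(
    report: EvaluationReport,
    cohort,
    estimates: pd.DataFrame,
    out_dir,
    clinical_values=None,
    fit: ClinicalFit | None = None,
) -> list[str]:
    """Histograms with fitted densities, a density overlay, and the
    measured-vs-true regression panels.  Returns the written file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    assigned = np.array([p.tvdt for p in cohort])
    arms = {"simulated": assigned}
    if clinical_values is not None:
        arms["clinical"] = np.asarray(clinical_values, dtype=float)
    est = estimates["tvdt_est_days"].to_numpy()
    arms["estimated"] = est[np.isfinite(est)]

    grid = np.linspace(1, max(a.max() for a in arms.values()) * 1.1, 400)
    fig, ax = plt.subplots()
    for name, values in arms.items():
        f = fit_distribution(values[values > 0], "gamma")
        ax.plot(grid, f.frozen.pdf(grid), label=f"{name} fit")
    if fit is not None:
        ax.plot(grid, fit.frozen.pdf(grid), "k--", label="clinical fit")
    ax.set_xlabel("TVDT (days)")
    ax.set_ylabel("density")
    ax.legend()
    path = out / "tvdt_density_overlay.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    for name, values in arms.items():
        fig, ax = plt.subplots()
        ax.hist(values, bins=15, density=True, alpha=0.6)
        f = fit_distribution(values[values > 0], "gamma")
        ax.plot(grid, f.frozen.pdf(grid), "r-")
        ax.set_xlabel("TVDT (days)")
        ax.set_title(f"{name} TVDTs (n={values.size})")
        path = out / f"hist_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
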