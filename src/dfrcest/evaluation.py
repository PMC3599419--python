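"""Measured-versus-estimated agreement in non-parametric style.

Agreement between clinically measured dFRC and a method's estimates is
summarised by the trend correlation coefficient R² (squared Pearson
correlation of the pooled pairs, with the ordinary-least-squares trend line
reported alongside) and by non-parametric error statistics -- median, IQR,
minimum and maximum of (estimated - measured), pooled and per PEEP level.
Overestimation is positive by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DfrcError

__all__ = [
    "AgreementReport",
    "compute_agreement",
    "rank_methods",
    "cohort_pairs",
    "plot_agreement",
    "plot_error_boxplot",
]


def _error_stats(errors: np.ndarray) -> dict:
    q25, q75 = np.percentile(errors, [25.0, 75.0])
    return {
        "median": float(np.median(errors)),
        "iqr": float(q75 - q25),
        "min": float(errors.min()),
        "max": float(errors.max()),
        "n": int(errors.size),
    }


@dataclass
class AgreementReport:
    """Agreement of one method's estimates with measured dFRC."""

    method: str
    n_pairs: int
    r_squared: Optional[float]
    r_squared_reason: Optional[str]
    slope: Optional[float]
    intercept: Optional[float]
    errors: dict                  # pooled error statistics, L
    per_peep: dict                # PEEP level -> error statistics
    cohort: Optional[str] = None
    flags: tuple = ()

    def summary(self) -> str:
        r2 = "undefined" if self.r_squared is None else f"{self.r_squared:.3f}"
        lines = [
            f"Agreement report: {self.method}"
            + (f" [{self.cohort}]" if self.cohort else ""),
            f"  pairs           {self.n_pairs}",
            f"  trend R^2       {r2}"
            + (f" ({self.r_squared_reason})" if self.r_squared_reason else ""),
        ]
        if self.slope is not None:
            lines.append(f"  trend line      est = {self.slope:.3f} * meas "
                         f"{self.intercept:+.3f} L")
        e = self.errors
        lines.append(f"  error (est-meas, L)  median {e['median']:+.3f}  "
                     f"IQR {e['iqr']:.3f}  min {e['min']:+.3f}  max {e['max']:+.3f}")
        for peep in sorted(self.per_peep):
            pe = self.per_peep[peep]
            lines.append(f"    PEEP {peep:g}: median {pe['median']:+.3f}  "
                         f"IQR {pe['iqr']:.3f}  n {pe['n']}")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


def _as_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
    else:
        df = pd.DataFrame(list(pairs), columns=["measured", "estimated", "peep"])
    missing = {"measured", "estimated", "peep"} - set(df.columns)
    if missing:
        raise DfrcError(f"pairs lack columns {sorted(missing)}")
    return df


def compute_agreement(pairs, method: str = "",
                      cohort: Optional[str] = None) -> AgreementReport:
    """Agreement statistics from (measured, estimated, peep) pairs.

    R² and the trend line require at least two pairs with non-zero variance
    on both axes; otherwise R² is reported as absent with a reason while the
    error statistics are still produced.  Per-PEEP groups use exact PEEP
    (level) equality.
    """
    df = _as_frame(pairs)
    if df.empty:
        raise DfrcError("no (measured, estimated) pairs")
    meas = df["measured"].to_numpy(dtype=float)
    est = df["estimated"].to_numpy(dtype=float)
    errors = est - meas

    r2 = slope = intercept = None
    reason = None
    if meas.size < 2:
        reason = "fewer than 2 pairs"
    elif np.var(meas) == 0:
        reason = "zero variance in measured values"
    elif np.var(est) == 0:
        reason = "zero variance in estimated values"
    else:
        r = np.corrcoef(meas, est)[0, 1]
        r2 = float(r * r)
        b, a = np.polyfit(meas, est, 1)
        slope, intercept = float(b), float(a)

    per_peep = {
        float(p): _error_stats(grp["estimated"].to_numpy() - grp["measured"].to_numpy())
        for p, grp in df.groupby("peep")
    }
    return AgreementReport(method=method, n_pairs=int(meas.size), r_squared=r2,
                           r_squared_reason=reason, slope=slope, intercept=intercept,
                           errors=_error_stats(errors), per_peep=per_peep,
                           cohort=cohort)


def rank_methods(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    """Methods ranked by pooled R², descending; ties broken by method name.

    When reports carry cohort labels, per-cohort R² columns are emitted
    next to the overall column (reports with ``cohort=None`` are treated
    as overall).
    """
    if len(reports) < 2:
        raise DfrcError("ranking needs at least 2 reports")
    rows = {}
    for rep in reports:
        col = rep.cohort or "overall"
        rows.setdefault(rep.method, {})[col] = rep.r_squared
    df = pd.DataFrame.from_dict(rows, orient="index")
    cohort_cols = sorted(c for c in df.columns if c != "overall")
    cols = cohort_cols + (["overall"] if "overall" in df.columns else [])
    df = df[cols]
    sort_col = "overall" if "overall" in df.columns else cols[-1]
    # descending R^2, ties broken by method name ascending
    order = sorted(df.index, key=lambda m: (-(df.loc[m, sort_col]
                                             if pd.notna(df.loc[m, sort_col]) else -np.inf), m))
    df = df.loc[order]
    df.index.name = "method"
    return df


def cohort_pairs(cohort, method: str, ssmb_table=None, sssb_table=None,
                 policy: str = "refuse", pairing: str = "consecutive",
                 against: str = "measured") -> pd.DataFrame:
    """Pooled (measured, estimated, peep) pairs for a cohort and method.

    ``against='measured'`` scores estimates against the clinically measured
    dFRC; ``'truth'`` against the simulator's ground truth when present.
    """
    from .estimators import estimate_dataset  # local: avoid import cycle

    records = []
    for pat in cohort:
        ests = estimate_dataset(pat, method, ssmb_table=ssmb_table,
                                sssb_table=sssb_table, policy=policy,
                                pairing=pairing)
        for est in ests:
            step = pat.step_at(est.peep)
            if against == "truth":
                ref = (pat.true_dfrc or {}).get(step.level)
            else:
                ref = step.measured_dfrc
            if ref is None:
                continue
            records.append({"patient_id": pat.patient_id, "peep": est.peep,
                            "measured": ref, "estimated": est.value})
    return pd.DataFrame.from_records(
        records, columns=["patient_id", "peep", "measured", "estimated"])


# ---------------------------------------------------------------------------
# Plots (display-only truncation; statistics are never truncated)


def plot_agreement(report: AgreementReport, pairs, ax=None):
    """Scatter of measured vs estimated dFRC with the fitted trend line."""
    import matplotlib.pyplot as plt

    df = _as_frame(pairs)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(df["measured"], df["estimated"], s=18, alpha=0.7)
    if report.slope is not None:
        xs = np.linspace(df["measured"].min(), df["measured"].max(), 2)
        label = f"$R^2$ = {report.r_squared:.3f}"
        ax.plot(xs, report.slope * xs + report.intercept, "k-", label=label)
        ax.legend()
    lim = max(df["measured"].max(), df["estimated"].max())
    ax.plot([0, lim], [0, lim], ":", color="grey", lw=1)
    ax.set_xlabel("measured dFRC [L]")
    ax.set_ylabel(f"estimated dFRC [L] ({report.method})")
    return ax


def plot_error_boxplot(pairs, truncate: float = 1.0, ax=None):
    """Per-PEEP box plots of estimation error; errors beyond ±truncate L are
    clipped for display only."""
    import matplotlib.pyplot as plt

    df = _as_frame(pairs)
    if ax is None:
        _, ax = plt.subplots()
    groups = sorted(df["peep"].unique())
    data = [(df.loc[df["peep"] == p, "estimated"]
             - df.loc[df["peep"] == p, "measured"]).to_numpy() for p in groups]
    ax.boxplot(data, tick_labels=[f"{p:g}" for p in groups])
    if truncate is not None:
        ax.set_ylim(-truncate, truncate)
    ax.axhline(0.0, color="grey", lw=1, ls=":")
    ax.set_xlabel("PEEP [cmH2O]")
    ax.set_ylabel("estimated - measured dFRC [L]")
    return ax
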