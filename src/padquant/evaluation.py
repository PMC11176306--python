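"""Method comparison: Δsignal-ratio discrimination and ranking.

Sensitivity alone does not tell whether an assay can distinguish two
nearby concentrations — the signal uncertainties matter just as much. The
discrimination statistic used here is the *Δsignal ratio*: the absolute
difference of the fitted signals at two similar concentrations divided by
the average of their 95% confidence half-widths,

    ratio = |y(c_high) - y(c_low)| / ((u_low + u_high) / 2).

A ratio well above 1 means the two concentrations are resolvable by that
data-treatment method; near or below 1 they are not.

:class:`MethodComparison` is the study-level model object: it takes the
zone × method signal table, fits a calibration per method, evaluates the
Δsignal ratio at a user-chosen concentration pair, and ranks the usable
methods. High sensitivity, small sensitivity error, low LOD and a high
Δsignal ratio are the desirable directions; the default ranking orders by
Δsignal ratio (descending) with LOD and sensitivity error as tie-breaks —
a pragmatic default, not a universal rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationResults, LinearCalibration, PredictedSignal
from .exceptions import (
    ConfigurationError,
    ExtrapolationWarning,
    InfiniteRatioWarning,
    InsufficientDataError,
    SingularDesignError,
)
from .signal_methods import METHODS, METHOD_IDS

__all__ = [
    "ConcentrationPair",
    "DeltaSignalRatioResult",
    "MethodComparison",
    "MethodComparisonResults",
    "delta_signal_ratio",
    "ratio_from_values",
    "build_comparison",
    "rank_methods",
    "render_report",
]

EM_DASH_CELL = "–––"  # mirrors the dash convention for unusable methods

#: columns of the comparison table, in output order
COMPARISON_COLUMNS = [
    "method_id", "label", "slope", "slope_se", "sensitivity_error_pct",
    "lod", "r2", "n", "usable",
    "s_low", "u_low", "s_high", "u_high", "delta_signal", "ratio",
    "rank", "notes",
]


@dataclass
class ConcentrationPair:
    """Two nearby concentrations whose discriminability is under test."""

    c_low: float
    c_high: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.c_low < self.c_high:
            raise ConfigurationError(
                f"concentration pair must satisfy c_low < c_high, got {self.c_low}, {self.c_high}"
            )


@dataclass
class DeltaSignalRatioResult:
    """Fitted signals ± 95% half-widths at a pair and their Δsignal ratio."""

    method_id: int | None
    s_low: float
    u_low: float
    s_high: float
    u_high: float
    delta_signal: float
    ratio: float

    @property
    def ratio_2dp(self) -> float:
        """Display rounding used in reports; computations keep full precision."""
        return round(self.ratio, 2)


def ratio_from_values(
    s_low: float, u_low: float, s_high: float, u_high: float, method_id: int | None = None
) -> DeltaSignalRatioResult:
    """Δsignal ratio from plain numbers (signal ± half-width at each level)."""
    if u_low < 0 or u_high < 0:
        raise ConfigurationError("uncertainties must be >= 0")
    delta = abs(s_high - s_low)
    denom = (u_low + u_high) / 2.0
    if denom == 0:
        if delta == 0:
            ratio = 0.0
        else:
            warnings.warn(
                "both uncertainties are zero; Δsignal ratio reported as inf",
                InfiniteRatioWarning,
                stacklevel=2,
            )
            ratio = math.inf
    else:
        ratio = delta / denom
    return DeltaSignalRatioResult(
        method_id=method_id,
        s_low=s_low, u_low=u_low, s_high=s_high, u_high=u_high,
        delta_signal=delta, ratio=ratio,
    )


def delta_signal_ratio(
    low: PredictedSignal, high: PredictedSignal, method_id: int | None = None
) -> DeltaSignalRatioResult:
    """Δsignal ratio of two fitted signals with confidence half-widths."""
    return ratio_from_values(
        low.value, low.ci_half_width, high.value, high.ci_half_width, method_id=method_id
    )


# ---------------------------------------------------------------------------
# study-level model
# ---------------------------------------------------------------------------

class MethodComparison:
    """Compare all data-treatment methods on one calibration dataset.

    Parameters
    ----------
    signal_table
        Output of :func:`padquant.signal_methods.compute_all_signals`:
        one row per zone with a ``concentration`` column and one column
        per method (``m01_R`` … ``m19_logprod``).
    pair
        The two similar concentrations whose discriminability is scored.
    alpha
        Significance level of the slope t-test deciding usability.
    lod_k
        Multiplier of the LOD formula (3.3 by default; 3 for the
        stricter classical variant).
    use_blank_sd
        When true (default) and the table contains >= 3 zero-concentration
        rows, each method's LOD uses the SD of its blank signals as sigma;
        otherwise the residual SD of the fit.
    """

    def __init__(
        self,
        signal_table: pd.DataFrame,
        pair: ConcentrationPair,
        *,
        alpha: float = 0.05,
        lod_k: float = 3.3,
        use_blank_sd: bool = True,
    ) -> None:
        if "concentration" not in signal_table.columns:
            raise ConfigurationError("signal table lacks a 'concentration' column")
        self.signal_table = signal_table
        self.pair = pair
        self.alpha = alpha
        self.lod_k = lod_k
        self.use_blank_sd = use_blank_sd
        self.method_columns = [
            c for c in signal_table.columns
            if any(METHODS[i].column == c for i in METHOD_IDS)
        ]
        if not self.method_columns:
            raise ConfigurationError("signal table contains no method columns")

    def fit(self) -> "MethodComparisonResults":
        table = self.signal_table
        conc = table["concentration"].astype(float)
        c_min, c_max = float(conc.min()), float(conc.max())
        extrapolating = self.pair.c_low < c_min or self.pair.c_high > c_max
        if extrapolating:
            warnings.warn(
                f"concentration pair ({self.pair.c_low}, {self.pair.c_high}) lies outside "
                f"the calibrated range [{c_min}, {c_max}]",
                ExtrapolationWarning,
                stacklevel=2,
            )

        rows: list[dict[str, object]] = []
        calibs: dict[int, CalibrationResults] = {}
        for col in self.method_columns:
            spec = next(METHODS[i] for i in METHOD_IDS if METHODS[i].column == col)
            row: dict[str, object] = {
                "method_id": spec.method_id,
                "label": spec.label,
                "usable": False,
                "rank": np.nan,
                "notes": "",
            }
            y = table[col].astype(float)
            finite = np.isfinite(y) & np.isfinite(conc)
            blanks = y[finite & (conc == 0)]
            blank_sd = float(blanks.std(ddof=1)) if len(blanks) >= 3 else None
            try:
                model = LinearCalibration(
                    conc[finite].to_numpy(), y[finite].to_numpy(),
                    method_id=spec.method_id, label=spec.label, unit=self.pair.unit,
                )
                res = model.fit(
                    alpha=self.alpha,
                    lod_k=self.lod_k,
                    blank_sd=blank_sd if self.use_blank_sd else None,
                    n_blank=len(blanks),
                )
            except (InsufficientDataError, SingularDesignError) as exc:
                row["notes"] = str(exc)
                rows.append(row)
                continue
            calibs[spec.method_id] = res
            row.update(
                slope=res.slope, slope_se=res.slope_se,
                sensitivity_error_pct=res.sensitivity_error_pct,
                lod=res.lod, r2=res.r2, n=res.n, usable=res.usable,
            )
            if res.usable:
                dsr = delta_signal_ratio(
                    res.predict(self.pair.c_low),
                    res.predict(self.pair.c_high),
                    method_id=spec.method_id,
                )
                row.update(
                    s_low=dsr.s_low, u_low=dsr.u_low,
                    s_high=dsr.s_high, u_high=dsr.u_high,
                    delta_signal=dsr.delta_signal, ratio=dsr.ratio,
                )
            else:
                row["notes"] = "slope not significant at alpha"
            if extrapolating:
                row["notes"] = (row["notes"] + "; " if row["notes"] else "") + "extrapolated pair"
            rows.append(row)

        df = pd.DataFrame(rows).reindex(columns=COMPARISON_COLUMNS)
        df = rank_methods(df)
        return MethodComparisonResults(
            table=df,
            calibrations=calibs,
            pair=self.pair,
            settings={
                "alpha": self.alpha,
                "lod_k": self.lod_k,
                "use_blank_sd": self.use_blank_sd,
            },
        )


def build_comparison(
    calibs: Mapping[int, CalibrationResults] | Sequence[CalibrationResults],
    pair: ConcentrationPair,
) -> pd.DataFrame:
    """Comparison table straight from pre-fitted calibrations.

    One row per method; unusable methods keep their identification but
    carry missing metrics, mirroring the dash cells of a printed table.
    """
    if not isinstance(calibs, Mapping):
        calibs = {c.method_id: c for c in calibs}
    rows = []
    for method_id in sorted(calibs):
        res = calibs[method_id]
        row: dict[str, object] = {
            "method_id": method_id,
            "label": res.label or (METHODS[method_id].label if method_id in METHODS else ""),
            "slope": res.slope, "slope_se": res.slope_se,
            "sensitivity_error_pct": res.sensitivity_error_pct,
            "lod": res.lod, "r2": res.r2, "n": res.n,
            "usable": res.usable, "rank": np.nan, "notes": "",
        }
        if res.usable:
            dsr = delta_signal_ratio(
                res.predict(pair.c_low), res.predict(pair.c_high), method_id=method_id
            )
            row.update(
                s_low=dsr.s_low, u_low=dsr.u_low, s_high=dsr.s_high, u_high=dsr.u_high,
                delta_signal=dsr.delta_signal, ratio=dsr.ratio,
            )
        rows.append(row)
    df = pd.DataFrame(rows).reindex(columns=COMPARISON_COLUMNS)
    return rank_methods(df)


def rank_methods(
    rows: pd.DataFrame, policy: str = "ratio", weights: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Assign ranks to the usable methods; unusable rows carry no rank.

    ``ratio`` policy (default): sort by Δsignal ratio descending, ties
    broken by lower LOD, then lower sensitivity error; stable, so equal
    rows keep their input order. ``weighted`` policy: rank by a weighted
    sum of min-max-normalised ratio, −LOD and −sensitivity error.
    """
    df = rows.copy()
    df["rank"] = np.nan
    rankable = df[df["usable"].fillna(False).astype(bool) & df["ratio"].notna()]
    if rankable.empty:
        return df
    if policy == "ratio":
        ordered = rankable.sort_values(
            by=["ratio", "lod", "sensitivity_error_pct"],
            ascending=[False, True, True],
            kind="mergesort",
        )
    elif policy == "weighted":
        w = {"ratio": 1.0, "lod": 1.0, "sensitivity_error_pct": 1.0}
        if weights:
            w.update(weights)

        def norm(s: pd.Series, invert: bool) -> pd.Series:
            span = s.max() - s.min()
            z = (s - s.min()) / span if span > 0 else s * 0.0
            return 1.0 - z if invert else z

        score = (
            w["ratio"] * norm(rankable["ratio"], invert=False)
            + w["lod"] * norm(rankable["lod"], invert=True)
            + w["sensitivity_error_pct"] * norm(rankable["sensitivity_error_pct"], invert=True)
        )
        ordered = rankable.loc[score.sort_values(ascending=False, kind="mergesort").index]
    else:
        raise ConfigurationError(f"unknown ranking policy {policy!r}")
    df.loc[ordered.index, "rank"] = np.arange(1, len(ordered) + 1, dtype=float)
    return df


@dataclass
class MethodComparisonResults:
    """Fitted comparison study: per-method metrics, calibrations and ranks."""

    table: pd.DataFrame
    calibrations: dict[int, CalibrationResults]
    pair: ConcentrationPair
    settings: dict[str, object]

    @property
    def ranking(self) -> list[int]:
        """Method ids of the usable methods, best first."""
        ranked = self.table[self.table["rank"].notna()].sort_values("rank")
        return [int(m) for m in ranked["method_id"]]

    @property
    def best(self) -> int | None:
        r = self.ranking
        return r[0] if r else None

    def summary(self) -> str:
        return render_report_text(self.table, self.pair, self.settings)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def plot_ranking(self, ax=None):
        """Bar chart of the Δsignal ratio for the ranked methods."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ranked = self.table[self.table["rank"].notna()].sort_values("rank")
        ax.bar([str(int(m)) for m in ranked["method_id"]], ranked["ratio"])
        ax.axhline(1.0, color="grey", ls="--", lw=1)
        ax.set_xlabel("method id")
        ax.set_ylabel("Δsignal ratio")
        return ax


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt(value: object, nd: int = 2) -> str:
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return EM_DASH_CELL
    try:
        if pd.isna(value):
            return EM_DASH_CELL
    except TypeError:
        pass
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{float(value):.{nd}f}"


def render_report_text(
    table: pd.DataFrame, pair: ConcentrationPair, settings: Mapping[str, object]
) -> str:
    """Human-readable two-section report (figures of merit, discrimination).

    Numbers are displayed at 2 decimal places; full precision lives in the
    CSV written alongside. Deterministic: same inputs, same bytes.
    """
    unit = f" {pair.unit}" if pair.unit else ""
    lines = [
        "padquant method comparison report",
        "=================================",
        f"# settings: alpha={settings.get('alpha')} lod_k={settings.get('lod_k')} "
        "log_base=10 ci=mean-response",
        f"# concentration pair: {pair.c_low}{unit} vs {pair.c_high}{unit}",
        "",
        "Figures of merit per method",
        "---------------------------",
        f"{'id':>3} {'method':<18} {'sensitivity':>14} {'+/-SE':>10} "
        f"{'err%':>7} {'LOD':>9} {'R2':>6} {'usable':>6}",
    ]
    for _, r in table.sort_values("method_id").iterrows():
        usable = bool(r["usable"]) if pd.notna(r["usable"]) else False
        lines.append(
            f"{int(r['method_id']):>3} {str(r['label']):<18} "
            f"{_fmt(r['slope'], 4):>14} {_fmt(r['slope_se'], 4):>10} "
            f"{_fmt(r['sensitivity_error_pct']):>7} {_fmt(r['lod']):>9} "
            f"{_fmt(r['r2']):>6} {'yes' if usable else EM_DASH_CELL:>6}"
        )
    lines += [
        "",
        f"Discrimination at {pair.c_low} vs {pair.c_high}{unit}",
        "-----------------------------------------",
        f"{'id':>3} {'method':<18} {'low':>16} {'high':>16} {'dSignal':>9} "
        f"{'ratio':>7} {'rank':>5}",
    ]
    for _, r in table.sort_values("method_id").iterrows():
        if pd.notna(r.get("ratio")):
            low = f"{_fmt(r['s_low'])} +/- {_fmt(r['u_low'])}"
            high = f"{_fmt(r['s_high'])} +/- {_fmt(r['u_high'])}"
            rank = _fmt(r["rank"], 0)
        else:
            low = high = rank = EM_DASH_CELL
        lines.append(
            f"{int(r['method_id']):>3} {str(r['label']):<18} {low:>16} {high:>16} "
            f"{_fmt(r.get('delta_signal')):>9} {_fmt(r.get('ratio')):>7} {rank:>5}"
        )
    lines.append("")
    return "\n".join(lines)


def render_report(
    results: MethodComparisonResults,
    out_dir: str | Path,
    stem: str = "comparison",
) -> tuple[Path, Path]:
    """Write the full-precision CSV and the 2-dp text report; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    txt_path = out_dir / f"{stem}_report.txt"
    results.to_csv(csv_path)
    txt_path.write_text(results.summary(), encoding="utf-8")
    return csv_path, txt_path
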