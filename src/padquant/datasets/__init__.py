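"""Bundled reference datasets for the worked examples and regression tests.

Two small tables of published reference values for the model assays —
bromothymol blue (BTB, mg/L) and the zinc(II)–xylenol orange complex
(mmol/L) — read from µPAD scans with all nineteen data-treatment methods:

* :func:`load_reference_calibrations` — per-method calibration summaries
  (sensitivity ± SE, the reported sensitivity error in %, the reported
  LOD). Methods with no analytically meaningful response carry empty
  cells.
* :func:`load_reference_fitted_signals` — fitted signals ± 95% confidence
  half-widths at two similar concentrations per analyte (60/65 mg/L BTB,
  0.30/0.35 mmol/L Zn), with the reported Δsignal ratio.

These are *results-level* fixtures (the raw scans are not shipped); they
exercise the figure-of-merit and Δsignal-ratio arithmetic end to end.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_calibrations", "load_reference_fitted_signals"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_reference_calibrations() -> pd.DataFrame:
    """Columns: analyte, method_id, label, slope, slope_se,
    sens_error_pct_printed, lod_printed, conc_unit."""
    return _read("reference_calibrations.csv")


def load_reference_fitted_signals() -> pd.DataFrame:
    """Columns: analyte, method_id, label, c_low, c_high, conc_unit,
    s_low, u_low, s_high, u_high, ratio_printed."""
    return _read("reference_fitted_signals.csv")
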