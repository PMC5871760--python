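"""ChIP-qPCR quantification.

Each plate carries, per amplicon, a dilution series of the input chromatin
from which a standard curve Ct = a + b*log10(quantity) is fitted; IP and
IgG-control Ct values are interpolated on that curve, scaled to percent of
input, and the IgG percent is subtracted from each sample.

Quantities live on an arbitrary per-plate scale anchored by the input
dilution series (undiluted input = 1); ``input_fraction`` is the fraction
of the IP chromatin that the undiluted input standard represents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrRun",
    "fit_standard_curve",
    "percent_input",
    "subtract_igg",
    "quantify_run",
]

SAMPLE_KINDS = ("standard", "IP", "IgG")


@dataclass
class StandardCurve:
    """Least-squares line Ct = intercept + slope * log10(quantity)."""

    amplicon: str
    slope: float
    intercept: float
    r_squared: float
    ct_min: float
    ct_max: float
    efficiency: float = field(init=False)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        # slope of -3.3219 (perfect doubling) gives efficiency 1.0
        self.efficiency = 10.0 ** (-1.0 / self.slope) - 1.0

    def quantity(self, ct: float) -> float:
        """Invert the curve: quantity at a measured Ct."""
        if not (self.ct_min - 3.0) <= ct <= (self.ct_max + 3.0):
            warnings.warn(
                f"{self.amplicon}: Ct {ct:.2f} outside standard range "
                f"[{self.ct_min:.2f}, {self.ct_max:.2f}] (extrapolation)"
            )
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass
class QpcrRun:
    """Plate measurements: (amplicon, sample_kind, dilution, Ct) rows.

    ``dilution`` is the standard's dilution factor relative to undiluted
    input (NaN for IP/IgG rows); ``input_fraction`` is the input-vs-IP
    chromatin fraction used for the percent scale.
    """

    measurements: pd.DataFrame
    input_fraction: float

    def __post_init__(self) -> None:
        required = {"amplicon", "sample_kind", "dilution", "ct"}
        if not required <= set(self.measurements.columns):
            raise ValueError(f"measurements need columns {sorted(required)}")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")
        unknown = set(self.measurements["sample_kind"]) - set(SAMPLE_KINDS)
        if unknown:
            raise ValueError(f"unknown sample kinds: {sorted(unknown)}")
        if (self.measurements["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")


def fit_standard_curve(standards, amplicon: str = "") -> StandardCurve:
    """Fit the log-linear standard curve to (quantity, Ct) points.

    Requires >= 3 distinct quantities.  Warns when the implied efficiency
    leaves [0.8, 1.1] or r^2 < 0.98 — the fit is still returned since the
    procedure sets no hard QC thresholds.
    """
    pts = [(float(q), float(ct)) for q, ct in standards]
    if len(pts) < 3:
        raise ValueError("need at least 3 standard points")
    q = np.array([p[0] for p in pts])
    ct = np.array([p[1] for p in pts])
    if len(np.unique(q)) < 3:
        raise ValueError("need at least 3 distinct quantities")
    if (q <= 0).any():
        raise ValueError("quantities must be positive")
    res = stats.linregress(np.log10(q), ct)
    curve = StandardCurve(
        amplicon=amplicon,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ct_min=float(ct.min()),
        ct_max=float(ct.max()),
    )
    if not 0.8 <= curve.efficiency <= 1.1:
        warnings.warn(
            f"{amplicon}: amplification efficiency {curve.efficiency:.2f} "
            "outside [0.8, 1.1]"
        )
    if curve.r_squared < 0.98:
        warnings.warn(f"{amplicon}: standard-curve r^2 {curve.r_squared:.3f} < 0.98")
    return curve


def percent_input(
    ip_ct: float,
    curve: StandardCurve,
    input_fraction: float,
    quantity_unit: float = 1.0,
) -> float:
    """Percent of input chromatin recovered in the IP.

    ``quantity_unit`` is the quantity assigned to the undiluted input
    standard (1 on the per-plate scale); that standard represents
    ``input_fraction`` of the IP chromatin, so
    percent = 100 * q_IP / (quantity_unit / input_fraction).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    q_ip = curve.quantity(ip_ct)
    return 100.0 * q_ip / (quantity_unit / input_fraction)


def subtract_igg(sample_percent: float, igg_percent: float) -> tuple[float, bool]:
    """Sample %-input minus IgG-control %-input; negatives kept, flagged."""
    diff = sample_percent - igg_percent
    return diff, diff < 0


def quantify_run(run: QpcrRun) -> pd.DataFrame:
    """Per-amplicon standard-curve fit, %-input and IgG subtraction.

    Returns one row per amplicon with the fitted slope/efficiency, IP and
    IgG %-input, the IgG-subtracted value and a negative-value flag.
    Amplicons lacking an IgG control raise.
    """
    rows = []
    for amplicon, grp in run.measurements.groupby("amplicon", sort=False):
        std = grp[grp["sample_kind"] == "standard"]
        curve = fit_standard_curve(
            list(zip(std["dilution"], std["ct"])), amplicon=amplicon
        )
        ips = grp.loc[grp["sample_kind"] == "IP", "ct"]
        iggs = grp.loc[grp["sample_kind"] == "IgG", "ct"]
        if ips.empty:
            continue
        if iggs.empty:
            raise ValueError(f"{amplicon}: no IgG control measurement")
        ip_pct = percent_input(float(ips.mean()), curve, run.input_fraction)
        igg_pct = percent_input(float(iggs.mean()), curve, run.input_fraction)
        value, flagged = subtract_igg(ip_pct, igg_pct)
        rows.append(
            {
                "amplicon": amplicon,
                "slope": curve.slope,
                "efficiency": curve.efficiency,
                "r_squared": curve.r_squared,
                "ip_percent_input": ip_pct,
                "igg_percent_input": igg_pct,
                "specific_percent_input": value,
                "negative_flag": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("amplicon")
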