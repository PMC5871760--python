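"""Reporter-assay summary statistics.

Covers the fluctuation-style readouts used to score AID activity:
rifampicin-resistance mutation frequency in E. coli (median Rif-R cfu per
1e9 Amp-R cells over independent cultures), IgM-loss and CSR percentages
(background-subtracted, normalised to the wild-type construct),
competitive-growth GFP+/GFP- ratios, and the imaging-derived
nuclear-signal fraction and gammaH2AX foci threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluctuationExperiment",
    "FluctuationResult",
    "rifR_frequency",
    "normalize_to_reference",
    "background_subtracted_percent",
    "competitive_growth",
    "nuclear_fraction",
    "foci_positive_fraction",
]


@dataclass
class FluctuationExperiment:
    """Per-culture Rif-R and Amp-R colony counts for one construct."""

    construct: str
    cultures: list[tuple[int, int]]  # (rifR_cfu, ampR_cfu)
    experiment_id: str = "exp1"
    dilution_rifR: float = 1.0  # plating dilution factors multiply raw cfu
    dilution_ampR: float = 1.0

    def __post_init__(self) -> None:
        for rif, amp in self.cultures:
            if rif < 0 or amp < 0:
                raise ValueError("negative colony counts")
            if amp == 0:
                raise ValueError("zero Amp-R cfu; frequency undefined")


@dataclass
class FluctuationResult:
    construct: str
    experiment_id: str
    frequencies: list[float]  # per culture, per 1e9 Amp-R cells
    median: float = field(init=False)

    def __post_init__(self) -> None:
        self.median = float(np.median(self.frequencies))


def rifR_frequency(exp: FluctuationExperiment) -> FluctuationResult:
    """Per-culture Rif-R frequency per 1e9 Amp-R cells and their median.

    freq_i = rifR_i / ampR_i * 1e9, after applying plating dilutions; even
    culture numbers take the mean of the two central order statistics.
    """
    freqs = [
        (rif * exp.dilution_rifR) / (amp * exp.dilution_ampR) * 1e9
        for rif, amp in exp.cultures
    ]
    return FluctuationResult(exp.construct, exp.experiment_id, freqs)


def normalize_to_reference(
    summaries: pd.DataFrame, reference_label: str
) -> pd.DataFrame:
    """Normalise per-construct statistics to a reference construct.

    ``summaries`` has columns construct, experiment, value (one row per
    construct per experiment, e.g. the median Rif-R frequency or median
    IgM-loss).  Within each experiment every value is divided by the
    reference construct's value; the cross-experiment mean of normalised
    values is reported per construct.
    """
    required = {"construct", "experiment", "value"}
    if not required <= set(summaries.columns):
        raise ValueError(f"summaries needs columns {sorted(required)}")
    normalized = []
    for exp_id, grp in summaries.groupby("experiment"):
        ref = grp.loc[grp["construct"] == reference_label, "value"]
        if ref.empty:
            raise ValueError(f"reference {reference_label!r} missing in {exp_id}")
        ref_val = float(ref.iloc[0])
        if ref_val == 0:
            raise ValueError(f"reference statistic is 0 in {exp_id}")
        g = grp.copy()
        g["normalized"] = g["value"] / ref_val
        normalized.append(g)
    norm = pd.concat(normalized)
    out = norm.groupby("construct").agg(
        mean_normalized=("normalized", "mean"),
        n_experiments=("normalized", "size"),
    )
    return out


def background_subtracted_percent(
    pct_positive: float, pct_background: float
) -> tuple[float, bool]:
    """Observed minus background %, floored at 0 (flag when floored)."""
    for p in (pct_positive, pct_background):
        if not 0 <= p <= 100:
            raise ValueError("percentages must be in [0, 100]")
    diff = pct_positive - pct_background
    if diff < 0:
        return 0.0, True
    return diff, False


def competitive_growth(ratios, mode: str = "relative_day0") -> np.ndarray:
    """Normalise a GFP+/GFP- ratio time series to day 0 or to its maximum."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 timepoints")
    if mode == "relative_day0":
        norm = r[0]
    elif mode == "relative_max":
        norm = r.max()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if norm == 0:
        raise ValueError("zero normaliser")
    return r / norm


def nuclear_fraction(nuclear_signal: float, total_signal: float) -> float:
    """Percent of total signal that is nuclear: 100 * nuclear / total."""
    if total_signal <= 0:
        raise ValueError("total signal must be positive")
    if not 0 <= nuclear_signal <= total_signal:
        raise ValueError("nuclear signal must be within [0, total]")
    return 100.0 * nuclear_signal / total_signal


def foci_positive_fraction(foci_counts, k: int = 5) -> float:
    """Percent of cells with at least ``k`` foci per nucleus."""
    counts = np.asarray(foci_counts)
    if counts.size == 0:
        raise ValueError("empty foci counts")
    if (counts < 0).any():
        raise ValueError("negative foci counts")
    return 100.0 * float(np.mean(counts >= k))
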