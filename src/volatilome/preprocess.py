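"""Raw peak-table reduction: ppbV conversion, blank-based noise filter,
correlation-based isotopologue filter.

The conversion follows the standard proton-transfer-reaction relation: the
analyte number density is ``[R] = I_RH+ / (I_H3O+ * k * t)`` and the volume
mixing ratio is ``[R] / N_air * 1e9`` ppbV, with the air number density taken
from the drift-tube pressure and temperature. With a single average rate
constant the concentrations of all compounds are linearly related, so every
downstream statistic is invariant to the (instrument-specific) reaction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import PeakTable, label_to_mz

#: Boltzmann constant, J/K
K_B = 1.380649e-23


@dataclass
class InstrumentConfig:
    """Drift-tube conditions for the counts -> ppbV conversion."""

    rate_constant: float = 2.0e-9  # cm^3 s^-1, average proton-transfer rate
    reaction_time: float = 1.0e-4  # s; instrument-specific, global linear scale only
    drift_pressure: float = 2.8    # mbar
    drift_temperature: float = 383.15  # K (110 degC)
    drift_voltage: float = 530.0   # V, metadata only
    e_over_n: float = 140.0        # Td, metadata only

    def validate(self) -> "InstrumentConfig":
        for name in ("rate_constant", "reaction_time", "drift_pressure", "drift_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid instrument config: {name} must be > 0")
        return self

    @property
    def air_number_density(self) -> float:
        """N_air in cm^-3 from the ideal-gas law at drift conditions."""
        pressure_pa = self.drift_pressure * 100.0
        return pressure_pa / (K_B * self.drift_temperature) * 1e-6


@dataclass
class FilterConfig:
    blank_alpha: float = 0.05
    blank_test: Literal["rank-sum", "t-test"] = "rank-sum"
    corr_threshold: float = 0.99
    corr_keep_rule: Literal["lower-mz", "higher-signal"] = "lower-mz"

    def validate(self) -> "FilterConfig":
        if not (0.0 < self.blank_alpha < 1.0):
            raise ValueError("invalid filter config: blank_alpha must be in (0, 1)")
        if not (0.0 < self.corr_threshold < 1.0):
            raise ValueError("invalid filter config: corr_threshold must be in (0, 1)")
        if self.blank_test not in ("rank-sum", "t-test"):
            raise ValueError(f"invalid filter config: unknown blank_test {self.blank_test!r}")
        if self.corr_keep_rule not in ("lower-mz", "higher-signal"):
            raise ValueError(
                f"invalid filter config: unknown corr_keep_rule {self.corr_keep_rule!r}")
        return self


@dataclass
class FilterReport:
    """Per-peak filtering provenance.

    ``frame`` has one row per input peak with columns ``removed_by`` (``blank`` |
    ``correlation`` | ``none``), ``blank_p``, ``corr_partner`` and ``corr_r``.
    """

    frame: pd.DataFrame = field(repr=False)

    REMOVED_BY = ("blank", "correlation", "none")

    def __post_init__(self) -> None:
        bad = set(self.frame["removed_by"]) - set(self.REMOVED_BY)
        if bad:
            raise ValueError(f"unknown removal reasons: {sorted(bad)}")
        if self.frame.index.duplicated().any():
            raise ValueError("a peak appears more than once in the filter report")

    @property
    def retained(self) -> list[str]:
        return list(self.frame.index[self.frame["removed_by"] == "none"])

    def removed(self, reason: str) -> list[str]:
        return list(self.frame.index[self.frame["removed_by"] == reason])

    def counts(self) -> dict[str, int]:
        c = self.frame["removed_by"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in self.REMOVED_BY}

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "peak", out.index)
        out.to_csv(path, sep="\t", index=False)


def combine_reports(first: FilterReport, second: FilterReport) -> FilterReport:
    """Merge sequential stage reports; a peak removed in the first stage keeps
    that provenance, survivors take the second stage's verdict."""
    frame = first.frame.copy()
    for peak, row in second.frame.iterrows():
        if peak not in frame.index:
            raise ValueError(f"second report covers unknown peak {peak}")
        if row["removed_by"] != "none":
            frame.loc[peak, "removed_by"] = row["removed_by"]
        for col in ("blank_p", "corr_partner", "corr_r"):
            if pd.notna(row.get(col)):
                frame.loc[peak, col] = row[col]
    return FilterReport(frame)


def _empty_report(peaks: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"removed_by": "none", "blank_p": np.nan, "corr_partner": pd.NA, "corr_r": np.nan},
        index=pd.Index(peaks, name="peak"),
    )


# -- operations ---------------------------------------------------------------


def counts_to_ppbv(count_table: PeakTable, primary_ion_counts: pd.Series,
                   cfg: InstrumentConfig | None = None) -> PeakTable:
    """Convert raw ion count rates to headspace concentrations in ppbV."""
    cfg = (cfg or InstrumentConfig()).validate()
    if count_table.units != "counts":
        raise ValueError(f"expected a counts table, got units {count_table.units!r}")
    if (count_table.data.to_numpy() < 0).any():
        raise ValueError("negative ion counts in table")
    primary = primary_ion_counts.reindex(count_table.data.index)
    if primary.isna().any():
        missing = list(primary.index[primary.isna()])
        raise ValueError(f"no primary ion counts for samples: {missing}")
    bad = primary[primary <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive primary ion signal for samples: {list(bad.index)}")
    density = count_table.data.div(primary, axis=0) / (cfg.rate_constant * cfg.reaction_time)
    ppbv = density / cfg.air_number_density * 1e9
    return PeakTable(ppbv, units="ppbV")


def blank_filter(table: PeakTable, meta: pd.DataFrame,
                 cfg: FilterConfig | None = None) -> tuple[PeakTable, FilterReport]:
    """Drop peaks not significantly higher in cultures than in blank vials.

    A peak is retained iff a one-sided test (cultures > blanks) rejects at
    ``blank_alpha``; no multiplicity correction is applied. Column order of
    survivors is preserved.
    """
    cfg = (cfg or FilterConfig()).validate()
    meta = meta.loc[table.data.index]
    blank_ids = meta.index[meta["role"] == "blank"]
    sample_ids = meta.index[meta["role"] == "sample"]
    if len(blank_ids) < 2:
        raise ValueError(
            "fewer than 2 blank samples present; to run without blanks, skip "
            "the blank-filter stage explicitly")
    report = _empty_report(table.peaks)
    blanks = table.data.loc[blank_ids]
    samples = table.data.loc[sample_ids]
    for peak in table.peaks:
        x = samples[peak].to_numpy()
        y = blanks[peak].to_numpy()
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0  # identical constant in both groups: nothing above blank
        elif cfg.blank_test == "rank-sum":
            p = float(sps.mannwhitneyu(x, y, alternative="greater").pvalue)
        else:
            p = float(sps.ttest_ind(x, y, alternative="greater", equal_var=False).pvalue)
        report.loc[peak, "blank_p"] = p
        if p >= cfg.blank_alpha:
            report.loc[peak, "removed_by"] = "blank"
    rep = FilterReport(report)
    return table.subset_peaks(rep.retained), rep


def correlation_filter(table: PeakTable,
                       cfg: FilterConfig | None = None) -> tuple[PeakTable, FilterReport]:
    """Greedy removal of near-perfectly correlated peaks (isotopologues).

    Peaks are visited in the keep-rule order (default ascending m/z, so the
    lighter monoisotopic parent survives); a peak is removed if its |Pearson r|
    with any already-kept peak exceeds the threshold (strict inequality).
    Constant columns have undefined r, which is treated as 0.
    """
    cfg = (cfg or FilterConfig()).validate()
    if table.data.shape[0] < 3:
        raise ValueError("correlation filter needs at least 3 samples")
    peaks = table.peaks
    if cfg.corr_keep_rule == "lower-mz":
        order = sorted(peaks, key=lambda c: (label_to_mz(c), c))
    else:
        means = table.data.mean(axis=0)
        order = sorted(peaks, key=lambda c: (-means[c], c))

    x = table.data.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    norms = np.sqrt((x ** 2).sum(axis=0))
    constant = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(constant[None, :], 0.0, x / np.where(norms == 0, 1.0, norms)[None, :])
    col = {p: k for k, p in enumerate(peaks)}

    report = _empty_report(peaks)
    kept_idx: list[int] = []
    kept_labels: list[str] = []
    for peak in order:
        k = col[peak]
        if kept_idx:
            r = z[:, kept_idx].T @ z[:, k]  # Pearson r against every kept peak
            worst = int(np.argmax(np.abs(r)))
            # strict inequality with a tiny slack so |r| == threshold keeps both
            if np.abs(r[worst]) > cfg.corr_threshold + 1e-12:
                report.loc[peak, "removed_by"] = "correlation"
                report.loc[peak, "corr_partner"] = kept_labels[worst]
                report.loc[peak, "corr_r"] = float(r[worst])
                continue
        kept_idx.append(k)
        kept_labels.append(peak)
    rep = FilterReport(report)
    return table.subset_peaks(rep.retained), rep


def preprocess(table: PeakTable, meta: pd.DataFrame, cfg: FilterConfig | None = None,
               skip_blank: bool = False,
               skip_corr: bool = False) -> tuple[PeakTable, FilterReport]:
    """Blank filter then correlation filter, with a combined provenance report."""
    cfg = (cfg or FilterConfig()).validate()
    if skip_blank:
        blank_rep = FilterReport(_empty_report(table.peaks))
        reduced = table
    else:
        reduced, blank_rep = blank_filter(table, meta, cfg)
    if skip_corr:
        corr_rep = FilterReport(_empty_report(reduced.peaks))
    else:
        reduced, corr_rep = correlation_filter(reduced, cfg)
    return reduced, combine_reports(blank_rep, corr_rep)
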