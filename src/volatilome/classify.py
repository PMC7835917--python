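"""Species-discriminating peak classification.

The mining procedure works on ratios to the per-sample mean concentration: a
peak is a *candidate* if at least one strain has every technical replicate above
ratio 1; candidates whose above-ratio fraction is at least 60% within every
species are *generally increased*; candidates above ratio 1 in more than half of
the technical replications of only one or a few species are *species-specific*;
anything else stays *unclassified*. Because everything is ratio-based, the
classification is invariant to any global rescaling of the concentration table.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import PeakTable, label_to_mz

GENERAL = "general"
SPECIFIC = "species-specific"
UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationConfig:
    ratio_threshold: float = 1.0
    general_fraction: float = 0.60   # share of within-species measurements above threshold
    specific_fraction: float = 0.50  # share of a species' technical replications, strict >
    max_specific_species: int = 3    # operationalizes "one or a few" species
    #: enforce the "only" in "above ratio in >50% of the replications of only one
    #: or a few species": the enriched set must also account for more than
    #: ``specific_fraction`` of all the peak's above-threshold measurements
    require_confinement: bool = True

    def validate(self) -> "ClassificationConfig":
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")
        for name in ("general_fraction", "specific_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.max_specific_species < 1:
            raise ValueError("max_specific_species must be >= 1")
        return self


@dataclass
class PeakClassification:
    """Per-peak classes with the supporting per-species above-ratio fractions."""

    #: per peak: candidate flag, class, enriched species (comma-joined, may be "")
    frame: pd.DataFrame = field(repr=False)
    #: species x peaks matrix of above-threshold fractions
    fractions: pd.DataFrame = field(repr=False)

    def peaks_in_class(self, cls: str) -> list[str]:
        return list(self.frame.index[self.frame["class"] == cls])

    @property
    def candidates(self) -> list[str]:
        return list(self.frame.index[self.frame["candidate"]])

    def enriched_species(self, peak: str) -> tuple[str, ...]:
        raw = self.frame.loc[peak, "enriched_species"]
        return tuple(raw.split(",")) if raw else ()

    def tallies(self) -> dict[str, int]:
        return {
            "candidates": int(self.frame["candidate"].sum()),
            "general": len(self.peaks_in_class(GENERAL)),
            "species_specific": len(self.peaks_in_class(SPECIFIC)),
            "unclassified_candidates": int(
                (self.frame["candidate"] & (self.frame["class"] == UNCLASSIFIED)).sum()),
        }

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "peak", out.index)
        out.to_csv(path, sep="\t", index=False)


# -- operations ---------------------------------------------------------------


def ratio_normalize(table: PeakTable) -> PeakTable:
    """Divide every measurement by the mean peak concentration of its sample, so
    each row of the result has mean exactly 1."""
    row_mean = table.data.mean(axis=1)
    bad = row_mean[row_mean <= 0]
    if len(bad):
        raise ValueError(f"sample rows with non-positive mean: {list(bad.index)}")
    return PeakTable(table.data.div(row_mean, axis=0), units="ratio")


def select_candidates(ratios: PeakTable, meta: pd.DataFrame,
                      cfg: ClassificationConfig | None = None) -> list[str]:
    """Peaks above the ratio threshold in *all* technical replicates of at least
    one strain."""
    cfg = (cfg or ClassificationConfig()).validate()
    meta = meta.loc[ratios.data.index]
    cultures = meta.index[meta["role"] == "sample"]
    above = ratios.data.loc[cultures] > cfg.ratio_threshold
    per_strain = above.groupby(meta.loc[cultures, "strain"]).all()
    mask = per_strain.any(axis=0)
    return [p for p in ratios.peaks if mask[p]]


def species_fractions(ratios: PeakTable, meta: pd.DataFrame,
                      cfg: ClassificationConfig | None = None) -> pd.DataFrame:
    """Species x peaks matrix: fraction of the species' measurements (all
    technical replicates of all strains) above the ratio threshold."""
    cfg = (cfg or ClassificationConfig()).validate()
    meta = meta.loc[ratios.data.index]
    cultures = meta.index[meta["role"] == "sample"]
    above = ratios.data.loc[cultures] > cfg.ratio_threshold
    return above.groupby(meta.loc[cultures, "species"]).mean()


def classify_peaks(ratios: PeakTable, meta: pd.DataFrame,
                   candidates: Sequence[str] | None = None,
                   cfg: ClassificationConfig | None = None) -> PeakClassification:
    """Partition candidate peaks into generally increased, species-specific and
    unclassified.

    General: above-threshold fraction >= ``general_fraction`` in every species.
    Species-specific: the set of species with fraction > ``specific_fraction``
    has between 1 and ``max_specific_species`` members and (with
    ``require_confinement``) collects more than ``specific_fraction`` of all the
    peak's above-threshold measurements, so that occurrences are genuinely
    confined to those species. Candidates meeting neither rule, and
    non-candidates, are unclassified.
    """
    cfg = (cfg or ClassificationConfig()).validate()
    if candidates is None:
        candidates = select_candidates(ratios, meta, cfg)
    unknown = set(candidates) - set(ratios.peaks)
    if unknown:
        raise ValueError(f"candidates not present in ratio table: {sorted(unknown)}")
    meta_aligned = meta.loc[ratios.data.index]
    cultures = meta_aligned.index[meta_aligned["role"] == "sample"]
    above = ratios.data.loc[cultures] > cfg.ratio_threshold
    species_of = meta_aligned.loc[cultures, "species"]
    counts = above.groupby(species_of).sum()
    sizes = species_of.value_counts()
    frac = counts.div(sizes, axis=0).sort_index()

    rows = []
    cand = set(candidates)
    for peak in ratios.peaks:
        cls, enriched = UNCLASSIFIED, ()
        if peak in cand:
            f = frac[peak]
            if (f >= cfg.general_fraction).all():
                cls = GENERAL
            else:
                over = tuple(sorted(f.index[f > cfg.specific_fraction]))
                if 1 <= len(over) <= cfg.max_specific_species:
                    confined = True
                    if cfg.require_confinement:
                        total_above = counts[peak].sum()
                        in_set = counts.loc[list(over), peak].sum()
                        confined = total_above > 0 and in_set / total_above > cfg.specific_fraction
                    if confined:
                        cls, enriched = SPECIFIC, over
        rows.append({"peak": peak, "candidate": peak in cand, "class": cls,
                     "enriched_species": ",".join(enriched)})
    frame = pd.DataFrame(rows).set_index("peak")
    return PeakClassification(frame=frame, fractions=frac)


# -- annotation ---------------------------------------------------------------

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a (protonated) sum formula string; the
    charge-carrying proton does not change the count."""
    f = formula.strip()
    if f.lower().startswith("isotope of"):
        f = f[len("isotope of"):].strip()
    f = f.rstrip("+-")
    total = 0
    pos = 0
    for m in _ELEMENT_RE.finditer(f):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if m.group(1) == "C":
            total += int(m.group(2) or 1)
    if pos != len(f):
        raise ValueError(f"cannot parse formula {formula!r}")
    return total


def load_reference_annotations() -> pd.DataFrame:
    """Packaged reference table of tentatively identified peaks (m/z, protonated
    sum formula, tentative name)."""
    with importlib.resources.files("volatilome.data").joinpath("known_peaks.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def annotate(peaks: Sequence[str] | Sequence[float],
             reference: pd.DataFrame | None = None,
             tol: float = 0.005) -> pd.DataFrame:
    """Nearest-mass annotation of peaks against a reference table.

    ``peaks`` may be ``ms<mz>`` labels or plain m/z values. Peaks with no
    reference mass within ``tol`` Th are annotated as unknown with no carbon
    count. Returns one row per peak: mz, formula, name, carbon_count.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if reference is None:
        reference = load_reference_annotations()
    for col in ("mz", "formula", "name"):
        if col not in reference.columns:
            raise ValueError(f"reference table is missing column {col!r}")
    ref_mz = reference["mz"].to_numpy(dtype=float)
    rows = []
    for peak in peaks:
        mz = label_to_mz(peak) if isinstance(peak, str) else float(peak)
        delta = np.abs(ref_mz - mz)
        k = int(np.argmin(delta)) if len(delta) else -1
        if k >= 0 and delta[k] <= tol:
            formula = str(reference["formula"].iloc[k])
            rows.append({"peak": str(peak), "mz": mz, "formula": formula,
                         "name": str(reference["name"].iloc[k]),
                         "carbon_count": carbon_count(formula)})
        else:
            rows.append({"peak": str(peak), "mz": mz, "formula": None,
                         "name": "unknown", "carbon_count": None})
    return pd.DataFrame(rows).set_index("peak")


# -- class contrast -----------------------------------------------------------


@dataclass
class ClassContrast:
    """Mass and carbon-count comparison between general and specific peaks."""

    median_mz_general: float
    median_mz_specific: float
    mass_p: float
    median_carbon_general: float | None
    median_carbon_specific: float | None
    carbon_p: float | None
    n_general: int
    n_specific: int


def compare_classes(cls: PeakClassification,
                    annotation: pd.DataFrame | None = None) -> ClassContrast:
    """Two-sided rank-sum contrasts of m/z (always) and carbon count (where
    annotated) between generally increased and species-specific peaks."""
    general = cls.peaks_in_class(GENERAL)
    specific = cls.peaks_in_class(SPECIFIC)
    if not general or not specific:
        raise ValueError("both classes must be non-empty for a contrast")
    mz_g = np.array([label_to_mz(p) for p in general])
    mz_s = np.array([label_to_mz(p) for p in specific])
    mass_p = float(sps.mannwhitneyu(mz_g, mz_s, alternative="two-sided").pvalue)

    carbon_g = carbon_s = None
    carbon_p = None
    if annotation is not None:
        cc = annotation["carbon_count"]
        g = cc.reindex(general).dropna().astype(float).to_numpy()
        s = cc.reindex(specific).dropna().astype(float).to_numpy()
        if len(g) and len(s):
            carbon_g, carbon_s = float(np.median(g)), float(np.median(s))
            carbon_p = float(sps.mannwhitneyu(g, s, alternative="two-sided").pvalue)
    return ClassContrast(
        median_mz_general=float(np.median(mz_g)),
        median_mz_specific=float(np.median(mz_s)),
        mass_p=mass_p,
        median_carbon_general=carbon_g,
        median_carbon_specific=carbon_s,
        carbon_p=carbon_p,
        n_general=len(general),
        n_specific=len(specific),
    )


def species_peak_matrix(ratios: PeakTable, meta: pd.DataFrame,
                        peaks: Sequence[str] | None = None) -> pd.DataFrame:
    """Species x peaks matrix of median ratios (heatmap-style export)."""
    meta = meta.loc[ratios.data.index]
    cultures = meta.index[meta["role"] == "sample"]
    data = ratios.data.loc[cultures, list(peaks) if peaks is not None else ratios.peaks]
    return data.groupby(meta.loc[cultures, "species"]).median()
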