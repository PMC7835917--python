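"""Synthetic PTR-ToF-MS datasets with the statistical structure the analysis assumes.

The generator emulates a standardized culture design: ``n_species`` species, a
handful of strains per species as biological replicates, three technical
replicate vials per strain, plus blank control vials. Peak concentrations are
log-normal at baseline; a few peaks are generally elevated across all species; a
few peaks are enriched 100-1000-fold in a single species; noise channels are
sparse sub-detection-limit spikes drawn identically in cultures and blanks; and
a fraction of signal peaks get an isotopologue twin column correlated with its
parent at |r| > 0.99. Machine-readable ground truth is emitted alongside so every
downstream filtering, testing and classification stage can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (DistanceMatrix, PeakTable, label_to_mz, peak_label,
                         validate_meta, write_meta_tsv)
from .dendro import Dendrogram, Node

#: mass shift of a 13C isotopologue relative to its monoisotopic parent (Th)
C13_SHIFT = 1.00336

# Noise channels: sparse spikes around the detection limit. Zero-inflation keeps
# the channel exchangeable between cultures and blanks while making rank-sum
# p-values heavily discrete (never spuriously "above blank").
NOISE_SPIKE_PROB = 0.15
NOISE_LOG_MEAN = math.log(0.05)
NOISE_LOG_SD = 1.0

#: blank background of a real signal channel, as a fraction of its baseline
BLANK_BACKGROUND = 0.01
BLANK_LOG_SD = 0.3

# Species-specific peaks sit at trace level in most species and at an ordinary
# signal level (median ~10 ppbV) in their enriched species, so the realized fold
# between the enriched species and the rest equals the drawn enrichment factor.
SPECIFIC_LEVEL_LOG_MEAN = math.log(10.0)
SPECIFIC_LEVEL_LOG_SD = 0.3

# m/z windows echoing the observation that broadly shared VOCs are lighter
# (median ~61 Th) than species-specific ones (median ~93 Th).
GENERAL_MZ_WINDOW = (47.0, 75.0)
SPECIFIC_MZ_WINDOW = (77.0, 109.0)

#: relative scatter of the isotopologue abundance scalar between strains/blanks
ISOTOPOLOGUE_JITTER = 0.005

# Biological and technical variability are split into a dominant per-culture
# scalar (overall emission intensity: growth vigor, colony size, headspace
# equilibration) and a smaller peak-specific component (regulation of single
# pathways). The split keeps the stated total CV per peak while reflecting that
# most replicate-to-replicate variation in headspace fingerprints is a common
# intensity factor; the peak-specific share keeps distinct peak columns well
# away from the isotopologue correlation threshold.
BIO_PEAK_SHARE = 0.4
TECH_PEAK_SHARE = 0.3

# Species-specific compounds are under their own pathway regulation and show
# high within-species heterogeneity, so their between-strain variation gets an
# extra independent log-normal factor on top of the common intensity scalar.
SPECIFIC_STRAIN_LOG_SD = 0.4

_SITES = [f"site{i}" for i in range(1, 7)]


@dataclass
class SyntheticSpec:
    """Parameters of the emulated study design; defaults follow the real one."""

    n_species: int = 13
    strains_per_species: int = 5
    tech_reps: int = 3
    n_signal_peaks: int = 139
    n_noise_peaks: int = 264
    n_blanks: int = 6
    n_specific_peaks_per_species: int = 2
    specific_effect_range: tuple[float, float] = (100.0, 1000.0)
    n_general_peaks: int = 14
    general_effect: float = 5.0
    baseline_log_mean: float = math.log(2.0)
    baseline_log_sd: float = 0.8
    biological_cv: float = 0.5
    technical_cv: float = 0.15
    isotopologue_fraction: float = 0.1
    mz_range: tuple[float, float] = (28.0, 300.0)
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        for name in ("n_species", "strains_per_species", "tech_reps", "n_signal_peaks",
                     "n_specific_peaks_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid spec: {name} must be >= 1")
        for name in ("n_noise_peaks", "n_blanks", "n_general_peaks"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid spec: {name} must be >= 0")
        lo, hi = self.specific_effect_range
        if not (1.0 < lo <= hi):
            raise ValueError("invalid spec: specific_effect_range lower bound must be > 1")
        if self.general_effect <= 1.0:
            raise ValueError("invalid spec: general_effect must be > 1")
        if not (0.0 <= self.isotopologue_fraction < 1.0):
            raise ValueError("invalid spec: isotopologue_fraction must be in [0, 1)")
        if self.technical_cv < 0 or self.biological_cv <= 0:
            raise ValueError("invalid spec: technical_cv/biological_cv must be nonnegative")
        if self.technical_cv >= self.biological_cv:
            raise ValueError("invalid spec: technical_cv must be < biological_cv")
        if self.mz_range[0] >= self.mz_range[1] or self.mz_range[0] <= 0:
            raise ValueError("invalid spec: mz_range must be an increasing positive interval")
        n_twin = round(self.isotopologue_fraction * self.n_signal_peaks)
        n_independent = self.n_signal_peaks - n_twin
        needed = self.n_general_peaks + self.n_species * self.n_specific_peaks_per_species
        if n_independent < needed:
            raise ValueError(
                "invalid spec: n_signal_peaks leaves too few independent peaks "
                f"({n_independent}) for {needed} general+specific peaks")
        return self

    @property
    def n_cultures(self) -> int:
        return self.n_species * self.strains_per_species * self.tech_reps

    def species_names(self) -> list[str]:
        width = max(2, len(str(self.n_species)))
        return [f"sp{i + 1:0{width}d}" for i in range(self.n_species)]


@dataclass
class GroundTruth:
    """What the generator actually injected, keyed by peak label."""

    #: "noise" | "signal" | "isotopologue-of:<parent label>"
    peak_class: dict[str, str]
    #: species-specific enrichments: peak -> {species: fold}
    specific: dict[str, dict[str, float]]
    #: peaks elevated by a common fold in every species
    general_peaks: list[str]
    #: fold applied to the general peaks
    general_effect: float
    #: expected strain-level concentration (baseline x species fold x strain effect)
    strain_baseline: pd.DataFrame = field(repr=False)

    def noise_peaks(self) -> list[str]:
        return [p for p, c in self.peak_class.items() if c == "noise"]

    def signal_peaks(self) -> list[str]:
        """All non-noise peaks, including isotopologue twins."""
        return [p for p, c in self.peak_class.items() if c != "noise"]

    def twin_peaks(self) -> dict[str, str]:
        """Isotopologue columns mapped to their parent peak."""
        return {p: c.split(":", 1)[1] for p, c in self.peak_class.items()
                if c.startswith("isotopologue-of:")}

    def independent_signal_peaks(self) -> list[str]:
        return [p for p, c in self.peak_class.items() if c == "signal"]

    def flat_peaks(self) -> list[str]:
        """Signal peaks with no general or species-specific enrichment."""
        enriched = set(self.general_peaks) | set(self.specific)
        return [p for p in self.independent_signal_peaks() if p not in enriched]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peak_class": self.peak_class,
            "specific": self.specific,
            "general_peaks": self.general_peaks,
            "general_effect": self.general_effect,
            "strain_baseline": {
                "index": list(self.strain_baseline.index),
                "columns": list(self.strain_baseline.columns),
                "values": self.strain_baseline.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def read_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        sb = payload["strain_baseline"]
        return cls(
            peak_class=payload["peak_class"],
            specific={p: {s: float(f) for s, f in m.items()}
                      for p, m in payload["specific"].items()},
            general_peaks=list(payload["general_peaks"]),
            general_effect=float(payload["general_effect"]),
            strain_baseline=pd.DataFrame(
                np.asarray(sb["values"], dtype=float),
                index=sb["index"], columns=sb["columns"]),
        )


def _unique_mz(rng: np.random.Generator, n: int, window: tuple[float, float],
               taken: set[float]) -> list[float]:
    out: list[float] = []
    while len(out) < n:
        mz = round(float(rng.uniform(*window)), 4)
        if mz not in taken:
            taken.add(mz)
            out.append(mz)
    return out


def generate_dataset(spec: SyntheticSpec) -> tuple[PeakTable, pd.DataFrame, GroundTruth]:
    """Draw one complete dataset (concentration table, metadata, ground truth).

    Culture concentrations follow
    ``baseline_j * species_fold(j, species(i)) * strain_effect * exp(N(0, technical_cv))``;
    noise channels are drawn identically in cultures and blanks; isotopologue
    twins are a scaled copy of their parent column with a small per-strain
    jitter. Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    species = spec.species_names()

    n_twin = round(spec.isotopologue_fraction * spec.n_signal_peaks)
    n_ind = spec.n_signal_peaks - n_twin
    n_specific = spec.n_species * spec.n_specific_peaks_per_species
    n_flat = n_ind - spec.n_general_peaks - n_specific

    # --- peak identities and m/z ------------------------------------------
    taken: set[float] = set()
    specific_mz = _unique_mz(rng, n_specific, SPECIFIC_MZ_WINDOW, taken)
    general_mz = _unique_mz(rng, spec.n_general_peaks, GENERAL_MZ_WINDOW, taken)
    flat_mz = _unique_mz(rng, n_flat, spec.mz_range, taken)
    noise_mz = _unique_mz(rng, spec.n_noise_peaks, spec.mz_range, taken)

    specific_labels = [peak_label(m) for m in specific_mz]
    general_labels = [peak_label(m) for m in general_mz]
    flat_labels = [peak_label(m) for m in flat_mz]
    noise_labels = [peak_label(m) for m in noise_mz]
    ind_labels = specific_labels + general_labels + flat_labels

    # isotopologue twins: a 13C-shifted copy of a randomly chosen parent
    parents = list(rng.choice(np.array(ind_labels), size=n_twin, replace=False))
    twin_labels: list[str] = []
    twin_parent: dict[str, str] = {}
    for parent in parents:
        mz = round(label_to_mz(parent) + C13_SHIFT, 4)
        while mz in taken:
            mz = round(mz + 1e-4, 4)
        taken.add(mz)
        lab = peak_label(mz)
        twin_labels.append(lab)
        twin_parent[lab] = parent

    # --- baselines and species folds --------------------------------------
    n_strains = spec.n_species * spec.strains_per_species
    strain_ids = [f"{sp}s{k + 1}" for sp in species for k in range(spec.strains_per_species)]
    strain_species = np.repeat(np.arange(spec.n_species), spec.strains_per_species)

    baseline = np.empty(len(ind_labels))
    fold = np.ones((spec.n_species, len(ind_labels)))
    specific_map: dict[str, dict[str, float]] = {}

    lo, hi = spec.specific_effect_range
    for j, lab in enumerate(specific_labels):
        sp_idx = j // spec.n_specific_peaks_per_species
        level = math.exp(rng.normal(SPECIFIC_LEVEL_LOG_MEAN, SPECIFIC_LEVEL_LOG_SD))
        f = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        baseline[j] = level / f
        fold[sp_idx, j] = f
        specific_map[lab] = {species[sp_idx]: f}
    off = len(specific_labels)
    baseline[off:off + spec.n_general_peaks] = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_general_peaks))
    fold[:, off:off + spec.n_general_peaks] = spec.general_effect
    off += spec.n_general_peaks
    baseline[off:] = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, n_flat))

    sigma_bio_peak = BIO_PEAK_SHARE * spec.biological_cv
    sigma_bio_scalar = spec.biological_cv * math.sqrt(1.0 - BIO_PEAK_SHARE ** 2)
    strain_scalar = np.exp(rng.normal(0.0, sigma_bio_scalar, n_strains))
    strain_peak = np.exp(rng.normal(0.0, sigma_bio_peak, (n_strains, len(ind_labels))))
    strain_peak[:, :len(specific_labels)] *= np.exp(
        rng.normal(0.0, SPECIFIC_STRAIN_LOG_SD, (n_strains, len(specific_labels))))
    strain_effect = strain_scalar[:, None] * strain_peak
    strain_expected = baseline[None, :] * fold[strain_species, :] * strain_effect

    # --- culture rows ------------------------------------------------------
    n_cultures = spec.n_cultures
    sample_strain = np.repeat(np.arange(n_strains), spec.tech_reps)
    sample_ids = [f"{strain_ids[s]}r{r + 1}"
                  for s in range(n_strains) for r in range(spec.tech_reps)]
    sigma_tech_peak = TECH_PEAK_SHARE * spec.technical_cv
    sigma_tech_scalar = spec.technical_cv * math.sqrt(1.0 - TECH_PEAK_SHARE ** 2)
    if spec.technical_cv > 0:
        vial_scalar = np.exp(rng.normal(0.0, sigma_tech_scalar, n_cultures))
        tech = (vial_scalar[:, None]
                * np.exp(rng.normal(0.0, sigma_tech_peak, (n_cultures, len(ind_labels)))))
    else:
        vial_scalar = np.ones(n_cultures)
        tech = np.ones((n_cultures, len(ind_labels)))
    cultures_signal = strain_expected[sample_strain, :] * tech

    # noise channels: one sparse draw per strain, shared by its technical reps
    def noise_draw(shape: tuple[int, ...]) -> np.ndarray:
        spikes = rng.random(shape) < NOISE_SPIKE_PROB
        mags = np.exp(rng.normal(NOISE_LOG_MEAN, NOISE_LOG_SD, shape))
        return np.where(spikes, mags, 0.0)

    noise_strain = noise_draw((n_strains, spec.n_noise_peaks))
    if spec.technical_cv > 0:
        tech_noise = (vial_scalar[:, None] * np.exp(
            rng.normal(0.0, sigma_tech_peak, (n_cultures, spec.n_noise_peaks))))
    else:
        tech_noise = np.ones((n_cultures, spec.n_noise_peaks))
    cultures_noise = noise_strain[sample_strain, :] * tech_noise

    # --- blanks ------------------------------------------------------------
    blank_ids = [f"blank{i + 1:02d}" for i in range(spec.n_blanks)]
    blanks_signal = (BLANK_BACKGROUND * baseline[None, :]
                     * np.exp(rng.normal(0.0, BLANK_LOG_SD, (spec.n_blanks, len(ind_labels)))))
    blanks_noise = noise_draw((spec.n_blanks, spec.n_noise_peaks))

    # --- isotopologue twins ------------------------------------------------
    scalar = rng.uniform(0.02, 0.15, n_twin)
    jitter_strain = 1.0 + rng.normal(0.0, ISOTOPOLOGUE_JITTER, (n_strains, n_twin))
    jitter_blank = 1.0 + rng.normal(0.0, ISOTOPOLOGUE_JITTER, (spec.n_blanks, n_twin))
    parent_idx = np.array([ind_labels.index(twin_parent[t]) for t in twin_labels])
    cultures_twin = (cultures_signal[:, parent_idx] * scalar[None, :]
                     * jitter_strain[sample_strain, :])
    blanks_twin = blanks_signal[:, parent_idx] * scalar[None, :] * jitter_blank

    # --- assemble ----------------------------------------------------------
    labels = ind_labels + twin_labels + noise_labels
    values = np.vstack([
        np.hstack([cultures_signal, cultures_twin, cultures_noise]),
        np.hstack([blanks_signal, blanks_twin, blanks_noise]),
    ])
    df = pd.DataFrame(values, index=sample_ids + blank_ids, columns=labels)
    df = df.loc[:, sorted(df.columns, key=label_to_mz)]
    df.index.name = "sample"
    table = PeakTable(df, units="ppbV")

    # --- metadata ----------------------------------------------------------
    strain_site = rng.choice(_SITES, n_strains)
    strain_season = rng.choice(["snowcover", "exposed"], n_strains)
    strain_matrix = rng.choice(["soil", "meshbag"], n_strains)
    rows = []
    for i, sid in enumerate(sample_ids):
        s = sample_strain[i]
        rows.append({
            "sample": sid, "role": "sample",
            "species": species[strain_species[s]], "strain": strain_ids[s],
            "replicate": i % spec.tech_reps + 1,
            "location": strain_site[s], "season": strain_season[s],
            "matrix": strain_matrix[s],
        })
    for bid in blank_ids:
        rows.append({"sample": bid, "role": "blank", "species": "none",
                     "strain": "none", "replicate": 0, "location": "none",
                     "season": "none", "matrix": "none"})
    meta = pd.DataFrame(rows).set_index("sample")
    validate_meta(meta, table)

    peak_class = {lab: "signal" for lab in ind_labels}
    peak_class.update({t: f"isotopologue-of:{p}" for t, p in twin_parent.items()})
    peak_class.update({lab: "noise" for lab in noise_labels})
    truth = GroundTruth(
        peak_class=peak_class,
        specific=specific_map,
        general_peaks=list(general_labels),
        general_effect=spec.general_effect,
        strain_baseline=pd.DataFrame(strain_expected, index=strain_ids, columns=ind_labels),
    )
    return table, meta, truth


# -- sequence-side distances --------------------------------------------------


def random_ultrametric_tree(labels: Iterable[str], rng: np.random.Generator) -> Dendrogram:
    """Random binary ultrametric tree: repeated uniform pair merges at strictly
    increasing heights (uniform increments keep merge heights well separated)."""
    clusters: list[Node] = [Node(0.0, label=str(l)) for l in labels]
    if len(clusters) < 2:
        raise ValueError("need at least two labels")
    h = 0.0
    while len(clusters) > 1:
        h += float(rng.uniform(0.25, 0.75))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = Node(h, children=(clusters[i], clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return Dendrogram(clusters[0])


#: within-species strain distance on the sequence side (well below tree heights)
WITHIN_SPECIES_DISTANCE = 0.02


@dataclass
class SpeciesDistances:
    """Strain-level sequence-side distances plus the generating species tree."""

    distances: DistanceMatrix
    tree: Dendrogram


def generate_species_distances(spec: SyntheticSpec, noise_sd: float = 0.0,
                               seed: int | None = None,
                               tree: Dendrogram | None = None) -> SpeciesDistances:
    """Strain-level distance matrix structured by a random ultrametric species
    tree; at ``noise_sd=0`` the matrix is exactly ultrametric."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    species = spec.species_names()
    if tree is None:
        tree = random_ultrametric_tree(species, rng)
    coph = tree.cophenetic().reorder(species)

    strain_ids = [f"{sp}s{k + 1}" for sp in species for k in range(spec.strains_per_species)]
    strain_species = np.repeat(np.arange(spec.n_species), spec.strains_per_species)
    n = len(strain_ids)
    d = coph.values[np.ix_(strain_species, strain_species)].copy()
    same = strain_species[:, None] == strain_species[None, :]
    d[same] = WITHIN_SPECIES_DISTANCE
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, (n, n))
        noise = (noise + noise.T) / 2.0
        d = np.clip(d + noise, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return SpeciesDistances(DistanceMatrix(strain_ids, d), tree)


def strain_meta(spec: SyntheticSpec) -> pd.DataFrame:
    """Minimal strain-level metadata (strain id -> species) for species-median
    collapsing of a strain-level distance matrix."""
    species = spec.species_names()
    rows = [{"sample": f"{sp}s{k + 1}", "species": sp}
            for sp in species for k in range(spec.strains_per_species)]
    return pd.DataFrame(rows).set_index("sample")


def _embed_cophenetic(coph: DistanceMatrix) -> np.ndarray:
    """Classical MDS coordinates whose pairwise Euclidean distances reproduce an
    ultrametric cophenetic matrix exactly (ultrametrics are Euclidean-embeddable)."""
    d2 = coph.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    keep = w > 1e-9
    return v[:, keep] * np.sqrt(w[keep])[None, :]


def generate_tree_structured_dataset(
        spec: SyntheticSpec, tree: Dendrogram | None = None, noise_sd: float = 0.0,
        seed: int | None = None) -> tuple[PeakTable, pd.DataFrame, Dendrogram]:
    """Volatilome table whose species-level Euclidean structure follows a species
    tree: species mean profiles are placed at coordinates realizing the tree's
    cophenetic distances, plus iid cell noise of sd ``noise_sd``.

    At ``noise_sd=0`` the sample-level Euclidean distances between two species'
    cultures equal their cophenetic distance exactly, so average clustering on
    the species-median matrix reproduces the generating topology.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    species = spec.species_names()
    if tree is None:
        tree = random_ultrametric_tree(species, rng)
    coph = tree.cophenetic().reorder(species)
    coords = _embed_cophenetic(coph)

    n_peaks = max(spec.n_signal_peaks, coords.shape[1])
    profiles = np.full((spec.n_species, n_peaks), 2.0)
    offset = 1.0 + float(np.abs(coords).max())
    profiles[:, :coords.shape[1]] = coords + offset

    taken: set[float] = set()
    mz = _unique_mz(rng, n_peaks, spec.mz_range, taken)
    labels = [peak_label(m) for m in mz]

    strain_ids = [f"{sp}s{k + 1}" for sp in species for k in range(spec.strains_per_species)]
    strain_species = np.repeat(np.arange(spec.n_species), spec.strains_per_species)
    sample_strain = np.repeat(np.arange(len(strain_ids)), spec.tech_reps)
    sample_ids = [f"{strain_ids[s]}r{r + 1}"
                  for s in range(len(strain_ids)) for r in range(spec.tech_reps)]
    values = profiles[strain_species[sample_strain], :]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    df = pd.DataFrame(values, index=sample_ids, columns=labels)
    df = df.loc[:, sorted(df.columns, key=lambda c: float(c[2:]))]
    df.index.name = "sample"
    meta = pd.DataFrame({
        "sample": sample_ids, "role": "sample",
        "species": [species[strain_species[s]] for s in sample_strain],
        "strain": [strain_ids[s] for s in sample_strain],
        "replicate": [i % spec.tech_reps + 1 for i in range(len(sample_ids))],
        "location": "site1", "season": "exposed", "matrix": "soil",
    }).set_index("sample")
    return PeakTable(df, units="ppbV"), meta, tree


# -- serialization ------------------------------------------------------------


def write_dataset(outdir: str | Path, table: PeakTable, meta: pd.DataFrame,
                  truth: GroundTruth | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_tsv(outdir / "peaks.tsv")
    write_meta_tsv(meta, outdir / "meta.tsv")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")


def spec_from_dict(payload: dict) -> SyntheticSpec:
    known = {f for f in SyntheticSpec.__dataclass_fields__}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown synthetic-spec fields: {sorted(unknown)}")
    payload = dict(payload)
    for key in ("specific_effect_range", "mz_range"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SyntheticSpec(**payload).validate()
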