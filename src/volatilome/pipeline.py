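"""End-to-end orchestration: simulate -> preprocess -> stats -> classify -> dendro.

A single :class:`RunConfig` (typically loaded from YAML) drives every stage; one
global seed fans out to deterministic per-stage sub-seeds, so disabling a stage
does not perturb later stages' randomness. Each stage logs one structured line
and contributes to a machine-readable :class:`RunReport` written as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as cl
from . import dendro as dd
from . import preprocess as pp
from . import stats as st
from . import synthdata as sd
from .containers import DistanceMatrix, PeakTable, read_meta_tsv

log = logging.getLogger("volatilome")

_STAGES = ("simulate", "preprocess", "stats", "classify", "dendro")
_DEFAULT_FACTORS = ("species", "location", "season", "matrix", "replicate")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    #: stage toggles; simulate off means peaks/meta are read from the paths below
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES})
    peaks_path: str | None = None
    meta_path: str | None = None
    peaks_units: str = "ppbV"
    primary_ions_path: str | None = None
    seq_distances_path: str | None = None
    alignment_path: str | None = None
    annotations_path: str | None = None
    permanova_factors: tuple[str, ...] = _DEFAULT_FACTORS
    skip_blank_filter: bool = False
    skip_corr_filter: bool = False
    synthetic: sd.SyntheticSpec = field(default_factory=sd.SyntheticSpec)
    instrument: pp.InstrumentConfig = field(default_factory=pp.InstrumentConfig)
    filters: pp.FilterConfig = field(default_factory=pp.FilterConfig)
    stats: st.StatsConfig = field(default_factory=st.StatsConfig)
    classification: cl.ClassificationConfig = field(default_factory=cl.ClassificationConfig)

    def validate(self) -> "RunConfig":
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages in config: {sorted(unknown)}")
        for s in _STAGES:
            self.stages.setdefault(s, True)
        if not self.stages["simulate"]:
            for name in ("peaks_path", "meta_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"simulation disabled but {name} not given")
                if not Path(path).exists():
                    raise ValueError(f"{name} does not exist: {path}")
        for name in ("primary_ions_path", "seq_distances_path", "alignment_path",
                     "annotations_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{name} does not exist: {path}")
        self.synthetic.validate()
        self.instrument.validate()
        self.filters.validate()
        self.stats.validate()
        self.classification.validate()
        return self

    def stage_seed(self, stage: str) -> int:
        """Deterministic sub-seed per stage, independent of which stages run."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        kwargs: dict = {}
        if "synthetic" in payload:
            kwargs["synthetic"] = sd.spec_from_dict(payload.pop("synthetic"))
        for key, builder in (("instrument", pp.InstrumentConfig),
                             ("filters", pp.FilterConfig),
                             ("stats", st.StatsConfig),
                             ("classification", cl.ClassificationConfig)):
            if key in payload:
                section = payload.pop(key)
                known = set(builder.__dataclass_fields__)
                unknown = set(section) - known
                if unknown:
                    raise ValueError(f"unknown {key} fields: {sorted(unknown)}")
                kwargs[key] = builder(**section)
        if "permanova_factors" in payload:
            payload["permanova_factors"] = tuple(payload["permanova_factors"])
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs.update(payload)
        return cls(**kwargs).validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_line(stage: str, **info) -> None:
    msg = f"[{stage}] " + " ".join(f"{k}={v}" for k, v in info.items())
    log.info(msg)
    print(msg, file=sys.stderr)


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order and return the run report (also
    written to ``<outdir>/report.json``). Any stage failure raises
    :class:`StageError` naming the stage."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    report: dict = {
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "wallclock_s": {},
    }

    table: PeakTable | None = None
    meta: pd.DataFrame | None = None
    truth: sd.GroundTruth | None = None
    try:
        # --- simulate ------------------------------------------------------
        t0 = time.perf_counter()
        stage = "simulate"
        try:
            if cfg.stages[stage]:
                spec = dataclasses.replace(cfg.synthetic, seed=cfg.stage_seed(stage))
                table, meta, truth = sd.generate_dataset(spec)
                sd.write_dataset(outdir, table, meta, truth)
                report["stages"][stage] = {
                    "enabled": True,
                    "n_cultures": int((meta["role"] == "sample").sum()),
                    "n_blanks": int((meta["role"] == "blank").sum()),
                    "n_peaks": len(table.peaks),
                    "checksums": {p.name: _sha256(p) for p in
                                  (outdir / "peaks.tsv", outdir / "meta.tsv")},
                }
                _stage_line(stage, samples=len(table.sample_ids), peaks=len(table.peaks))
            else:
                table = PeakTable.read_tsv(cfg.peaks_path, units=cfg.peaks_units)
                meta = read_meta_tsv(cfg.meta_path)
                meta = meta.loc[table.data.index]
                if table.units == "counts":
                    ions = pd.read_csv(cfg.primary_ions_path, sep="\t")
                    ions = ions.set_index(ions.columns[0]).iloc[:, 0]
                    table = pp.counts_to_ppbv(table, ions, cfg.instrument)
                report["stages"][stage] = {
                    "enabled": False,
                    "checksums": {Path(cfg.peaks_path).name: _sha256(Path(cfg.peaks_path))},
                }
                _stage_line(stage, loaded=len(table.sample_ids), peaks=len(table.peaks))
        except Exception as exc:
            raise StageError(stage, exc) from exc
        report["wallclock_s"][stage] = round(time.perf_counter() - t0, 3)

        # --- preprocess ----------------------------------------------------
        t0 = time.perf_counter()
        stage = "preprocess"
        n_in = len(table.peaks)
        try:
            if cfg.stages[stage]:
                filtered, fr = pp.preprocess(table, meta, cfg.filters,
                                             skip_blank=cfg.skip_blank_filter,
                                             skip_corr=cfg.skip_corr_filter)
                fr.to_tsv(outdir / "filter_report.tsv")
                filtered.to_tsv(outdir / "peaks_filtered.tsv")
                counts = fr.counts()
                report["stages"][stage] = {
                    "enabled": True, "n_peaks_in": n_in,
                    "removed_by_blank": counts["blank"],
                    "removed_by_correlation": counts["correlation"],
                    "retained": counts["none"],
                }
                _stage_line(stage, **report["stages"][stage])
                table = filtered
            else:
                report["stages"][stage] = {"enabled": False, "n_peaks_in": n_in,
                                           "removed_by_blank": 0,
                                           "removed_by_correlation": 0,
                                           "retained": n_in}
        except Exception as exc:
            raise StageError(stage, exc) from exc
        report["wallclock_s"][stage] = round(time.perf_counter() - t0, 3)

        cultures = meta.index[meta["role"] == "sample"]
        culture_table = table.subset_samples(list(cultures))
        culture_meta = meta.loc[cultures]

        seq_dist: DistanceMatrix | None = None
        if cfg.seq_distances_path is not None:
            seq_dist = DistanceMatrix.read_tsv(cfg.seq_distances_path)
        elif cfg.alignment_path is not None:
            seq_dist = dd.p_distance(cfg.alignment_path)

        # --- stats ---------------------------------------------------------
        t0 = time.perf_counter()
        stage = "stats"
        try:
            if cfg.stages[stage]:
                scfg = dataclasses.replace(cfg.stats, seed=cfg.stage_seed(stage))
                d = st.euclidean_distances(culture_table)
                perm = {}
                for factor in cfg.permanova_factors:
                    if factor not in culture_meta.columns:
                        continue
                    if culture_meta[factor].nunique() < 2:
                        continue
                    res = st.permanova(d, culture_meta[factor], scfg)
                    perm[factor] = {"pseudo_F": res.pseudo_f, "R2": res.r2, "p": res.p}
                wb = {}
                u, p = st.within_between_test(d, culture_meta, level="species")
                wb["species"] = {"U": u, "p": p}
                u, p = st.within_between_test(d, culture_meta,
                                              level="strain-within-species")
                wb["technical"] = {"U": u, "p": p}
                screen = st.univariate_screen(culture_table, culture_meta)
                screen.reset_index().to_csv(outdir / "peak_tests.tsv", sep="\t",
                                            index=False)
                stats_report = {
                    "enabled": True,
                    "permanova": perm,
                    "within_between": wb,
                    "n_peaks_tested": int(len(screen)),
                    "n_significant_kruskal": int((screen["kruskal_p"]
                                                  < scfg.alpha).sum()),
                }
                if seq_dist is not None:
                    meta_for_seq = culture_meta.drop_duplicates("strain").set_index("strain")
                    vol_species = dd.median_species_distance(d, culture_meta)
                    seq_species = dd.median_species_distance(
                        seq_dist, meta_for_seq)
                    common = [s for s in vol_species.ids if s in seq_species.ids]
                    r, mp = st.mantel(vol_species.reorder(common),
                                      seq_species.reorder(common), scfg)
                    stats_report["mantel"] = {"r": r, "p": mp}
                report["stages"][stage] = stats_report
                _stage_line(stage, factors=len(perm),
                            significant=stats_report["n_significant_kruskal"],
                            total=stats_report["n_peaks_tested"])
            else:
                report["stages"][stage] = {"enabled": False}
        except Exception as exc:
            raise StageError(stage, exc) from exc
        report["wallclock_s"][stage] = round(time.perf_counter() - t0, 3)

        # --- classify ------------------------------------------------------
        t0 = time.perf_counter()
        stage = "classify"
        try:
            if cfg.stages[stage]:
                ratios = cl.ratio_normalize(culture_table)
                result = cl.classify_peaks(ratios, culture_meta, cfg=cfg.classification)
                result.to_tsv(outdir / "classification.tsv")
                matrix = cl.species_peak_matrix(ratios, culture_meta,
                                                peaks=result.candidates)
                matrix.to_csv(outdir / "species_peak_ratios.tsv", sep="\t")
                reference = (pd.read_csv(cfg.annotations_path, sep="\t")
                             if cfg.annotations_path else None)
                ann = cl.annotate(result.frame.index, reference=reference)
                stage_report: dict = {"enabled": True, **result.tallies()}
                if result.peaks_in_class(cl.GENERAL) and result.peaks_in_class(cl.SPECIFIC):
                    contrast = cl.compare_classes(result, ann)
                    stage_report["class_contrast"] = {
                        "median_mz_general": contrast.median_mz_general,
                        "median_mz_specific": contrast.median_mz_specific,
                        "mass_p": contrast.mass_p,
                    }
                report["stages"][stage] = stage_report
                _stage_line(stage, **result.tallies())
            else:
                report["stages"][stage] = {"enabled": False}
        except Exception as exc:
            raise StageError(stage, exc) from exc
        report["wallclock_s"][stage] = round(time.perf_counter() - t0, 3)

        # --- dendro --------------------------------------------------------
        t0 = time.perf_counter()
        stage = "dendro"
        try:
            if cfg.stages[stage]:
                d = st.euclidean_distances(culture_table)
                vol_species = dd.median_species_distance(d, culture_meta)
                vol_tree = dd.upgma(vol_species)
                vol_tree.write_newick(outdir / "volatilome_dendrogram.nwk")
                stage_report = {"enabled": True}
                if seq_dist is not None:
                    meta_for_seq = culture_meta.drop_duplicates("strain").set_index("strain")
                    seq_species = dd.median_species_distance(seq_dist, meta_for_seq)
                    common = sorted(set(vol_species.ids) & set(seq_species.ids))
                    seq_tree = dd.upgma(seq_species.reorder(common))
                    seq_tree.write_newick(outdir / "sequence_dendrogram.nwk")
                    comp = dd.compare_trees(dd.upgma(vol_species.reorder(common)),
                                            seq_tree)
                    stage_report.update({"rf": comp.rf,
                                         "normalized_rf": comp.normalized_rf,
                                         "cophenetic_r": comp.cophenetic_r})
                report["stages"][stage] = stage_report
                _stage_line(stage, species=len(vol_species.ids))
            else:
                report["stages"][stage] = {"enabled": False}
        except Exception as exc:
            raise StageError(stage, exc) from exc
        report["wallclock_s"][stage] = round(time.perf_counter() - t0, 3)
    finally:
        log.removeHandler(handler)
        handler.close()

    validate_report(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


# -- report schema ------------------------------------------------------------


def load_report_schema() -> dict:
    import importlib.resources

    path = importlib.resources.files("volatilome.data").joinpath("run_report.schema.json")
    return json.loads(path.read_text())


_TYPES = {"object": dict, "string": str, "integer": int, "number": (int, float),
          "boolean": bool, "array": list}


def _check(node, schema: dict, where: str) -> None:
    expected = schema.get("type")
    if expected is not None and not isinstance(node, _TYPES[expected]):
        raise ValueError(f"report schema violation at {where}: "
                         f"expected {expected}, got {type(node).__name__}")
    if expected == "boolean" or not isinstance(node, dict):
        return
    for key in schema.get("required", []):
        if key not in node:
            raise ValueError(f"report schema violation at {where}: missing {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in node:
            _check(node[key], sub, f"{where}.{key}")


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Check a run report against the shipped schema (required keys + types)."""
    _check(report, schema or load_report_schema(), "report")
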