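"""Mine the filtered table for generally increased and species-specific peaks.

Concentrations are divided by each sample's mean peak concentration; candidates
must exceed ratio 1 in all technical replicates of at least one strain; the 60%
rule separates generally increased peaks from species-specific ones (above
ratio in >50% of only one or a few species' replications). Calls are scored
against the generator's ground truth and the mass contrast between the two
classes is reported.
"""

import argparse
import json
from pathlib import Path

from volatilome import PeakTable
from volatilome import classify as cl
from volatilome import synthdata as sd
from volatilome.containers import read_meta_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--peaks", type=Path, default=Path("results/peaks_filtered.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = PeakTable.read_tsv(args.peaks)
    meta = read_meta_tsv(args.data / "meta.tsv").loc[table.data.index]
    cultures = list(meta.index[meta["role"] == "sample"])
    ratios = cl.ratio_normalize(table.subset_samples(cultures))
    result = cl.classify_peaks(ratios, meta.loc[cultures])
    tallies = result.tallies()
    print(f"{tallies['candidates']} candidate peaks -> {tallies['general']} general, "
          f"{tallies['species_specific']} species-specific, "
          f"{tallies['unclassified_candidates']} unclassified")

    args.out.mkdir(parents=True, exist_ok=True)
    result.to_tsv(args.out / "classification.tsv")
    cl.species_peak_matrix(ratios, meta.loc[cultures],
                           peaks=result.candidates).to_csv(
        args.out / "species_peak_ratios.tsv", sep="\t")

    summary: dict = dict(tallies)
    truth_file = args.data / "ground_truth.json"
    if truth_file.exists():
        truth = sd.GroundTruth.read_json(truth_file)
        called = set(result.peaks_in_class(cl.SPECIFIC))
        want = set(truth.specific)
        tp = len(called & want)
        summary["specific_precision"] = tp / max(len(called), 1)
        summary["specific_recall"] = tp / len(want)
        print(f"species-specific calls vs ground truth: precision "
              f"{summary['specific_precision']:.3f}, recall "
              f"{summary['specific_recall']:.3f}")

    ann = cl.annotate(result.frame.index)
    if result.peaks_in_class(cl.GENERAL) and result.peaks_in_class(cl.SPECIFIC):
        contrast = cl.compare_classes(result, ann)
        summary["median_mz_general"] = contrast.median_mz_general
        summary["median_mz_specific"] = contrast.median_mz_specific
        summary["mass_contrast_p"] = contrast.mass_p
        print(f"mass contrast: general median {contrast.median_mz_general:.2f} Th "
              f"vs specific median {contrast.median_mz_specific:.2f} Th "
              f"(rank-sum p = {contrast.mass_p:.3g})")
    (args.out / "classification_summary.json").write_text(
        json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
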