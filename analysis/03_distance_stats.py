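"""Distance-based and per-peak statistics on the filtered volatilomes.

Euclidean distances between samples; one-factor PERMANOVA (999 permutations)
for species and the nuisance factors; rank-sum tests that within-species and
within-strain (technical) distances are smaller than their between-group
counterparts; Kruskal-Wallis/ANOVA screens per peak.
"""

import argparse
import json
from pathlib import Path

from volatilome import PeakTable
from volatilome import stats as st
from volatilome.containers import read_meta_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--peaks", type=Path, default=Path("results/peaks_filtered.tsv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = PeakTable.read_tsv(args.peaks)
    meta = read_meta_tsv(args.data / "meta.tsv").loc[table.data.index]
    cultures = list(meta.index[meta["role"] == "sample"])
    table = table.subset_samples(cultures)
    meta = meta.loc[cultures]

    d = st.euclidean_distances(table)
    cfg = st.StatsConfig(n_permutations=999, seed=args.seed)
    omnibus = {}
    for factor in ("species", "location", "season", "matrix", "replicate"):
        res = st.permanova(d, meta[factor], cfg)
        omnibus[factor] = {"pseudo_F": res.pseudo_f, "R2": res.r2, "p": res.p}
        print(f"PERMANOVA {factor:9s}: R2 = {res.r2:.3f}, p = {res.p:.4g}")

    u, p = st.within_between_test(d, meta, level="species")
    omnibus["within_between_species"] = {"U": u, "p": p}
    print(f"within-species < between-species distances: p = {p:.3g}")
    u, p = st.within_between_test(d, meta, level="strain-within-species")
    omnibus["technical_vs_biological"] = {"U": u, "p": p}
    print(f"technical < biological replicate distances: p = {p:.3g}")

    screen = st.univariate_screen(table, meta)
    n_sig = int((screen["kruskal_p"] < cfg.alpha).sum())
    print(f"per-peak Kruskal-Wallis: {n_sig}/{len(screen)} peaks differ between "
          "species at alpha 0.05")

    args.out.mkdir(parents=True, exist_ok=True)
    screen.reset_index().to_csv(args.out / "peak_tests.tsv", sep="\t", index=False)
    d.to_tsv(args.out / "sample_distances.tsv")
    (args.out / "omnibus_stats.json").write_text(json.dumps(omnibus, indent=2))


if __name__ == "__main__":
    main()
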