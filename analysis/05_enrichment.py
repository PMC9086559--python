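"""GSEA over the mRNA fold-change ranking.

Builds the logFC ranking from the full mRNA DE table, assembles a
planted-top gene set and a size-matched random control, and runs the
weighted-KS permutation test with the |NES| > 2 and p < 0.05 call.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cernaforge import io as cio
from cernaforge.enrichment import gsea


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--set-size", type=int, default=50)
    args = ap.parse_args()
    out = args.results / "05_gsea"
    out.mkdir(parents=True, exist_ok=True)

    de = pd.read_csv(args.results / "02_de" / "de_mrna_full.tsv", sep="\t",
                     index_col=0)
    ranking = de["logFC"].sort_values(ascending=False, kind="stable")
    truth = json.loads((args.results / "01_inputs" / "truth.json").read_text())
    planted_up = [f for f, d in truth["de_features"]
                  if f in ranking.index and d == "up"]
    planted_up = sorted(planted_up, key=lambda f: -ranking[f])[:args.set_size]
    rng = np.random.default_rng(args.seed)
    random_set = set(rng.choice(ranking.index.to_numpy(), size=args.set_size,
                                replace=False))
    sets = {"PLANTED_UP": set(planted_up), "RANDOM_CONTROL": random_set}
    cio.write_gmt(sets, out / "gene_sets.gmt")

    results = gsea(ranking, sets, n_perm=args.n_perm, seed=args.seed + 1)
    tab = pd.DataFrame([(r.set_id, r.es, r.nes, r.p, r.significant)
                        for r in results],
                       columns=["set_id", "es", "nes", "p", "significant"])
    cio.write_table(tab, out / "gsea.tsv", index=False)
    for r in results:
        print(f"{r.set_id}: ES {r.es:.3f}, NES {r.nes:.2f}, p {r.p:.4g} "
              f"-> {'significant' if r.significant else 'not significant'}")


if __name__ == "__main__":
    main()
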