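"""Assemble the circRNA-miRNA-mRNA ceRNA network.

Joins circRNA-miRNA and miRNA-mRNA site tables on shared miRNAs,
keeps pairs with concordant tumor/normal directions and a summed
best-site energy below -90 kcal/mol, and exports the triple table plus
GraphML/SIF networks to results/04_network/.  Precision/recall against
the planted triples is printed.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cernaforge import io as cio
from cernaforge.expression import DEResult
from cernaforge.mirtarget import Alignment, TargetHit
from cernaforge.network import build_cerna, triples_table


def _de_results(path: Path) -> list[DEResult]:
    out = []
    for row in pd.read_csv(path, sep="\t").itertuples():
        r = DEResult(row.feature_id, row.logFC, row.p, row.adj_p)
        r.direction = row.direction
        out.append(r)
    return out


def _hits(df: pd.DataFrame) -> list[TargetHit]:
    return [TargetHit(r.mirna_id, r.target_id, r.score, r.energy, r.start, r.end,
                      Alignment("", "", "", r.start, r.end, []))
            for r in df.itertuples()]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--energy-sum-max", type=float, default=-90.0)
    args = ap.parse_args()
    out = args.results / "04_network"
    out.mkdir(parents=True, exist_ok=True)

    circ_de = _de_results(args.results / "02_de" / "de_circ_called.tsv")
    mrna_de = _de_results(args.results / "02_de" / "de_mrna_called.tsv")
    hits = pd.read_csv(args.results / "03_scan" / "target_hits.tsv", sep="\t")
    net, triples = build_cerna(circ_de, mrna_de,
                               _hits(hits[hits.target_class == "circRNA"]),
                               _hits(hits[hits.target_class == "mRNA"]),
                               energy_sum_max=args.energy_sum_max)
    cio.write_table(triples_table(triples), out / "cerna_triples.tsv", index=False)
    cio.write_graphml(net.graph, out / "cerna_network.graphml")
    cio.write_sif(net.graph, out / "cerna_network.sif")

    truth = json.loads((args.results / "01_inputs" / "truth.json").read_text())
    planted = {tuple(t) for t in truth["planted_triples"]}
    found = {(t.circ_id, t.mir_id, t.mrna_id) for t in triples}
    prec = len(found & planted) / len(found) if found else float("nan")
    rec = len(found & planted) / len(planted) if planted else float("nan")
    print(f"network: {len(net.nodes_of_kind('circRNA'))} circRNAs, "
          f"{len(net.nodes_of_kind('miRNA'))} miRNAs, "
          f"{len(net.nodes_of_kind('mRNA'))} mRNAs, {len(triples)} triples")
    print(f"vs planted truth: precision {prec:.3f}, recall {rec:.3f}")


if __name__ == "__main__":
    main()
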