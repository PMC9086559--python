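"""Synthesize the study inputs with planted ground truth.

Emits paired tumor/normal count matrices (mRNA: 8 pairs, circRNA: 4
pairs), miRNA/circRNA/mRNA sequence sets with planted binding sites, a
PPI edge list with a planted clique, and a TARGET-like survival cohort,
all under results/01_inputs/, together with truth.json recording what
was planted.  Downstream scripts work only from these files.
"""

import argparse
import json
from pathlib import Path

from cernaforge import io as cio
from cernaforge.pipeline import PipelineConfig, synthesize_inputs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    data = synthesize_inputs(cfg)
    out = args.results / "01_inputs"
    out.mkdir(parents=True, exist_ok=True)

    cio.write_counts(data.mrna_counts, out / "mrna_counts.tsv")
    cio.write_counts(data.circ_counts, out / "circ_counts.tsv")
    data.mrna_counts.lib_sizes.rename("lib_size").to_csv(
        out / "mrna_lib_sizes.tsv", sep="\t")
    data.circ_counts.lib_sizes.rename("lib_size").to_csv(
        out / "circ_lib_sizes.tsv", sep="\t")
    cio.write_fasta(data.mirnas, out / "mirnas.fa")
    cio.write_fasta(data.circ_seqs, out / "circ_seqs.fa")
    cio.write_fasta(data.mrna_seqs, out / "mrna_seqs.fa")
    cio.write_edges(data.ppi_edges, out / "ppi_edges.tsv")
    cio.write_table(data.survival, out / "survival.tsv", index=False)

    truth = {
        "seed": args.seed,
        "de_features": sorted(list(x) for x in data.truth.de_features),
        "planted_sites": data.truth.planted_sites,
        "planted_triples": data.truth.planted_triples,
        "planted_cliques": [sorted(c) for c in data.truth.planted_cliques],
        "prognostic_betas": data.truth.prognostic_betas,
        "hub_candidates": data.hub_candidates,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    print(f"wrote inputs to {out}")
    print(f"  mRNA counts: {data.mrna_counts.values.shape}, "
          f"circRNA counts: {data.circ_counts.values.shape}")
    print(f"  planted DE features: {len(data.truth.de_features)}, "
          f"planted triples: {len(data.truth.planted_triples)}")
    print(f"  PPI: {len(data.ppi_edges)} edges, clique "
          f"{sorted(data.truth.planted_cliques[0])}")
    print(f"  survival cohort: {len(data.survival)} patients, "
          f"prognostic genes {sorted(data.truth.prognostic_betas)}")


if __name__ == "__main__":
    main()
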