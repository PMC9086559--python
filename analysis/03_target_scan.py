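"""miRanda-style target scan over the differential sequences.

Scans every miRNA against the sequences of called DE circRNAs and
DE mRNAs, keeping sites with alignment score > 140 and duplex energy
< -20 kcal/mol, and writes the hit table to results/03_scan/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cernaforge import io as cio
from cernaforge.mirtarget import scan_targets


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-score", type=float, default=140.0)
    ap.add_argument("--max-energy", type=float, default=-20.0)
    args = ap.parse_args()
    inputs = args.results / "01_inputs"
    de_dir = args.results / "02_de"
    out = args.results / "03_scan"
    out.mkdir(parents=True, exist_ok=True)

    mirnas = cio.read_fasta(inputs / "mirnas.fa")
    circ_called = set(pd.read_csv(de_dir / "de_circ_called.tsv", sep="\t")["feature_id"])
    mrna_called = set(pd.read_csv(de_dir / "de_mrna_called.tsv", sep="\t")["feature_id"])
    circ_seqs = {k: v for k, v in cio.read_fasta(inputs / "circ_seqs.fa").items()
                 if k in circ_called}
    mrna_seqs = {k: v for k, v in cio.read_fasta(inputs / "mrna_seqs.fa").items()
                 if k in mrna_called}

    rows = []
    for cls, targets in (("circRNA", circ_seqs), ("mRNA", mrna_seqs)):
        for h in scan_targets(mirnas, targets, args.min_score, args.max_energy):
            rows.append((h.mirna_id, h.target_id, cls, h.score, h.energy,
                         h.target_start, h.target_end))
    hits = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class",
                                       "score", "energy", "start", "end"])
    cio.write_table(hits, out / "target_hits.tsv", index=False)
    print(f"scanned {len(mirnas)} miRNAs against {len(circ_seqs)} DE circRNAs "
          f"and {len(mrna_seqs)} DE mRNAs")
    print(f"{(hits.target_class == 'circRNA').sum()} circRNA sites and "
          f"{(hits.target_class == 'mRNA').sum()} mRNA sites passed both screens")


if __name__ == "__main__":
    main()
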