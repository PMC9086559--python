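"""Build and evaluate the prognostic risk-score signature.

From the survival cohort and the hub-gene list: univariate Cox screen
(p < 0.05), LASSO-Cox on the survivors with cross-validated penalty,
median-split risk stratification, high-vs-low log-rank, and
time-dependent AUC at 3, 5 and 7 years.  Ends by extracting the
signature-centred ceRNA subnetwork.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cernaforge import io as cio
from cernaforge.prognosis import (cox_univariate, lasso_cox, logrank,
                                  risk_scores, td_auc)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--horizons", type=float, nargs="+", default=[3.0, 5.0, 7.0])
    args = ap.parse_args()
    out = args.results / "07_signature"
    out.mkdir(parents=True, exist_ok=True)

    surv = pd.read_csv(args.results / "01_inputs" / "survival.tsv", sep="\t")
    truth = json.loads((args.results / "01_inputs" / "truth.json").read_text())
    hubs = [g for g in truth["hub_candidates"] if g in surv.columns]

    screen = {}
    for g in hubs:
        beta, hr, ci, p = cox_univariate(surv, g)
        screen[g] = {"beta": beta, "hr": hr, "ci": list(ci), "p": p}
    survivors = sorted(g for g, r in screen.items() if r["p"] < 0.05)
    print(f"univariate Cox screen: {len(survivors)}/{len(hubs)} hub genes "
          f"associated with survival ({', '.join(survivors)})")
    if len(survivors) < 2:
        survivors = sorted(hubs)

    model = lasso_cox(surv, survivors, seed=args.seed)
    scores, labels = risk_scores(model, surv.set_index("sample")[model.genes])
    surv_idx = surv.set_index("sample")
    _, lr_p = logrank(surv_idx[labels == "high"], surv_idx[labels == "low"])
    aucs = td_auc(surv, scores.to_numpy(), args.horizons)

    model_json = {"genes": model.genes, "betas": model.betas,
                  "cutoff": model.cutoff, "lambda": model.lambda_,
                  "rule": model.rule,
                  "auc": {str(k): v for k, v in aucs.items()},
                  "logrank_p_high_vs_low": lr_p, "cox_screen": screen}
    (out / "risk_model.json").write_text(json.dumps(model_json, indent=2,
                                                    sort_keys=True))
    pd.DataFrame({"risk_score": scores, "risk_group": labels}).to_csv(
        out / "risk_scores.tsv", sep="\t")

    planted = sorted(truth["prognostic_betas"])
    print(f"signature: {len(model.genes)} genes {model.genes} "
          f"(planted: {planted})")
    print(f"high-vs-low log-rank p = {lr_p:.3g}")
    for h, a in aucs.items():
        print(f"AUC at {h:g} years: {a:.3f}")

    # signature-centred ceRNA subnetwork
    net_dir = args.results / "04_network"
    if (net_dir / "cerna_triples.tsv").exists():
        tri = pd.read_csv(net_dir / "cerna_triples.tsv", sep="\t")
        keep = [g for g in model.genes if g in set(tri.mrna_id)]
        sub = tri[tri.mrna_id.isin(keep)]
        cio.write_table(sub, out / "signature_triples.tsv", index=False)
        print(f"signature subnetwork: {len(sub)} triples around {keep}")


if __name__ == "__main__":
    main()
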