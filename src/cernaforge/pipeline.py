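"""End-to-end orchestration of the ceRNA inference chain.

Stages, in order: synthesize (or load) inputs -> differential expression
for circRNAs and mRNAs -> miRNA target scan over the differential
sequences -> ceRNA network assembly -> GSEA over the mRNA ranking -> PPI
hub ranking -> survival signature (univariate Cox screen, LASSO-Cox,
risk stratification, time-dependent AUC) -> signature subnetwork.  Every
stage writes its table to the run directory so any stage can be re-run
from the previous stage's on-disk output, and a manifest records
parameters and input hashes.  All randomness derives from the single
config seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as expr
from . import io as cio
from . import mirtarget as mt
from . import network as net
from . import prognosis as prog
from . import synth
from .errors import InvalidArgumentError


@dataclass
class SynthesisConfig:
    """Scenario scale; defaults mirror the targeted study design scaled to
    desk size: 8 tumor/normal pairs for mRNA and 4 for circRNA counts, a
    TARGET-like independent survival cohort of 136 patients."""

    n_mrna: int = 1500
    n_circ: int = 240
    n_pairs_mrna: int = 8
    n_pairs_circ: int = 4
    frac_de_mrna: float = 0.10
    frac_de_circ: float = 0.15
    fc_de: float = 6.0
    dispersion: float = 0.1
    n_mirna: int = 10
    n_triple_pairs: int = 6
    mirs_per_pair: int = 2
    n_decoy_circ: int = 8
    n_decoy_mrna: int = 12
    n_ppi_nodes: int = 100
    ppi_noise_edges: int = 60
    clique_size: int = 6


@dataclass
class SurvivalConfig:
    n_patients: int = 136
    n_prognostic: int = 3
    beta: float = 1.0
    censor_rate: float = 0.3
    horizons: tuple[float, ...] = (3.0, 5.0, 7.0)
    n_folds: int = 5
    lasso_rule: str = "min"
    cox_screen_alpha: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    min_score: float = 140.0
    max_energy: float = -20.0
    energy_sum_max: float = -90.0
    min_abs_logfc: float = 2.0
    alpha: float = 0.05
    circ_use_adjusted: bool = False   # circRNA screen: |FC| > 2 and raw p < 0.05
    mrna_use_adjusted: bool = True    # mRNA screen: |logFC| > 2 and adjusted p < 0.05
    k_hubs: int = 10
    n_perm: int = 1000
    gsea_set_size: int = 50
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    survival: SurvivalConfig | None = field(default_factory=SurvivalConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = SynthesisConfig(**raw.pop("synthesis", {}))
        surv_raw = raw.pop("survival", "default")
        if surv_raw is None:
            surv = None
        elif surv_raw == "default":
            surv = SurvivalConfig()
        else:
            if "horizons" in surv_raw:
                surv_raw["horizons"] = tuple(surv_raw["horizons"])
            surv = SurvivalConfig(**surv_raw)
        return cls(synthesis=syn, survival=surv, **raw)


def _child_seed(seed: int, stage: int) -> int:
    return int((seed * 1_000_003 + stage * 7919) % (2**31 - 1))


# ------------------------------------------------------------ synthesis

@dataclass
class ScenarioData:
    """Everything one pipeline run consumes, plus the planted truth."""

    mrna_counts: expr.ExprMatrix
    circ_counts: expr.ExprMatrix
    mirnas: dict[str, str]
    circ_seqs: dict[str, str]
    mrna_seqs: dict[str, str]
    ppi_edges: list[tuple[str, str]]
    hub_candidates: list[str]
    survival: pd.DataFrame | None
    truth: synth.SyntheticTruth


def synthesize_inputs(cfg: PipelineConfig) -> ScenarioData:
    """Build a coherent synthetic study with planted signal at every stage.

    Planted ceRNA pairs share ``mirs_per_pair`` miRNAs with perfect
    (reverse-complement) sites on both molecules and concordant planted
    fold-changes.  Two decoy pair families exercise the filters: a
    discordant pair (sites present, opposite directions) and a
    single-miRNA pair (concordant but too little binding energy to pass
    the energy-sum screen).  Truth lists only the genuinely planted
    triples.
    """
    s = cfg.synthesis
    seed = cfg.seed
    rng = np.random.default_rng(_child_seed(seed, 0))

    # --- counts ------------------------------------------------------
    mrna_ids = [f"GENE{i + 1:04d}" for i in range(s.n_mrna)]
    circ_ids = []
    seen = set()
    while len(circ_ids) < s.n_circ:
        chrom = f"chr{rng.integers(1, 23)}"
        start = int(rng.integers(10_000, 100_000_000))
        cid = cio.format_circ_id(chrom, start, start + int(rng.integers(500, 50_000)))
        if cid not in seen:
            seen.add(cid)
            circ_ids.append(cid)

    mrna_libs = list(rng.integers(15_000_000, 25_000_000, size=2 * s.n_pairs_mrna))
    circ_libs = list(rng.integers(400_000_000, 600_000_000, size=2 * s.n_pairs_circ))
    mrna_counts, mrna_truth = synth.gen_count_matrix(
        s.n_mrna, s.n_pairs_mrna, s.frac_de_mrna, s.fc_de, s.dispersion,
        mrna_libs, _child_seed(seed, 1), feature_ids=mrna_ids)
    circ_counts, circ_truth = synth.gen_count_matrix(
        s.n_circ, s.n_pairs_circ, s.frac_de_circ, s.fc_de, s.dispersion,
        circ_libs, _child_seed(seed, 2), feature_ids=circ_ids)

    def _by_distinctness(counts: expr.ExprMatrix, truth_de, min_realized: float = 2.3):
        """Planted features ranked for network planting: realized log2
        fold-change comfortably past the screen (the planted decoys and
        triple members stand in for the study's most distinctly expressed
        transcripts), strongest and most abundant first."""
        norm = counts.values.to_numpy() / counts.lib_sizes.to_numpy()[None, :]
        n = norm.shape[1] // 2
        mean_ref = norm[:, :n].mean(axis=1)
        mean_test = norm[:, n:].mean(axis=1)
        realized = np.log2((mean_test + 1e-12) / (mean_ref + 1e-12))
        realized = pd.Series(realized, index=counts.feature_ids)
        abundance = pd.Series(norm.mean(axis=1), index=counts.feature_ids)
        out = {"up": [], "down": []}
        for d in ("up", "down"):
            sign = 1 if d == "up" else -1
            ids = [f for f, dd in truth_de if dd == d
                   and sign * realized[f] >= min_realized]
            out[d] = sorted(ids, key=lambda f: -abundance[f])
        return out

    de_mrna = _by_distinctness(mrna_counts, mrna_truth.de_features)
    de_circ = _by_distinctness(circ_counts, circ_truth.de_features)

    # --- planted triples and decoys ----------------------------------
    mir_ids = [f"miR-{i + 1:03d}" for i in range(s.n_mirna)]
    n_pairs = s.n_triple_pairs
    half = n_pairs // 2
    pair_dirs = ["up"] * (n_pairs - half) + ["down"] * half
    planted_pairs = []  # (circ, mrna, direction, [mirs])
    used_circ: set[str] = set()
    used_mrna: set[str] = set()
    # the last three miRNAs are reserved for the decoy pairs so no decoy
    # shares binding partners with a planted pair
    pool = mir_ids[:s.n_mirna - 3]
    if len(pool) < s.mirs_per_pair:
        raise InvalidArgumentError("n_mirna too small for mirs_per_pair plus decoys")
    for i, d in enumerate(pair_dirs):
        circ = next(c for c in de_circ[d] if c not in used_circ)
        mrna = next(m for m in de_mrna[d] if m not in used_mrna)
        used_circ.add(circ)
        used_mrna.add(mrna)
        mirs = [pool[(s.mirs_per_pair * i + k) % len(pool)]
                for k in range(s.mirs_per_pair)]
        planted_pairs.append((circ, mrna, d, mirs))
    # two same-direction pairs sharing a full miRNA set would create
    # unplanted triples that legitimately pass every filter
    for i, (_, _, di, mi) in enumerate(planted_pairs):
        for _, _, dj, mj in planted_pairs[i + 1:]:
            if di == dj and len(set(mi) & set(mj)) >= 2:
                raise InvalidArgumentError(
                    "miRNA pool too small: concordant planted pairs share 2+ miRNAs")

    # decoy 1: discordant directions, full binding
    disc_circ = next(c for c in de_circ["up"] if c not in used_circ)
    disc_mrna = next(m for m in de_mrna["down"] if m not in used_mrna)
    used_circ.add(disc_circ)
    used_mrna.add(disc_mrna)
    disc_mirs = mir_ids[s.n_mirna - 3:s.n_mirna - 3 + s.mirs_per_pair]
    # decoy 2: concordant but only one shared miRNA (energy sum too weak)
    weak_circ = next(c for c in de_circ["up"] if c not in used_circ)
    weak_mrna = next(m for m in de_mrna["up"] if m not in used_mrna)
    used_circ.add(weak_circ)
    used_mrna.add(weak_mrna)
    weak_mir = mir_ids[-1]

    site_plan: list[tuple[str, str, int]] = []
    for circ, mrna, _, mirs in planted_pairs:
        for mir in mirs:
            site_plan.append((mir, circ, 1))
            site_plan.append((mir, mrna, 1))
    for mir in disc_mirs:
        site_plan.append((mir, disc_circ, 1))
        site_plan.append((mir, disc_mrna, 1))
    site_plan.append((weak_mir, weak_circ, 1))
    site_plan.append((weak_mir, weak_mrna, 1))

    extra_circ = [c for c in de_circ["up"] + de_circ["down"]
                  if c not in used_circ][:s.n_decoy_circ]
    seq_circ_ids = sorted({p[0] for p in planted_pairs} | {disc_circ, weak_circ}
                          | set(extra_circ))
    seq_mrna_ids = sorted({p[1] for p in planted_pairs} | {disc_mrna, weak_mrna})
    extra_mrna = [m for m in de_mrna["up"] + de_mrna["down"]
                  if m not in used_mrna][:s.n_decoy_mrna]
    seq_mrna_ids = sorted(set(seq_mrna_ids) | set(extra_mrna))

    # the weak decoy's miRNA is drawn into an energy band where one perfect
    # site per molecule passes the per-site screen (< -20) but a single
    # shared miRNA cannot reach the pair-level energy sum (2e > -90)
    rng_weak = np.random.default_rng(_child_seed(seed, 10))
    alphabet = np.array(list("ACGU"))
    for _ in range(10_000):
        cand = "".join(rng_weak.choice(alphabet, size=22))
        if -44.0 < mt.perfect_duplex_energy(cand) < -24.0:
            weak_seq = cand
            break
    else:
        raise InvalidArgumentError("could not draw a weak-binding decoy miRNA")

    mirnas, circ_seqs, mrna_seqs, seq_truth = synth.gen_sequences(
        s.n_mirna, len(seq_circ_ids), len(seq_mrna_ids), site_plan,
        _child_seed(seed, 3), mirna_len=22,
        circ_ids=seq_circ_ids, mrna_ids=seq_mrna_ids, mirna_ids=mir_ids,
        mirna_seqs={weak_mir: weak_seq})

    truth = synth.SyntheticTruth(seed=seed)
    truth.de_features = mrna_truth.de_features | circ_truth.de_features
    truth.planted_sites = seq_truth.planted_sites
    for circ, mrna, _, mirs in planted_pairs:
        for mir in mirs:
            truth.planted_triples.append((circ, mir, mrna))
    truth.planted_triples.sort()

    # --- PPI over network-candidate mRNAs ----------------------------
    hub_candidates = sorted({p[1] for p in planted_pairs})
    while len(hub_candidates) < s.clique_size:
        hub_candidates.append(next(m for m in seq_mrna_ids if m not in hub_candidates))
    clique = set(hub_candidates[:s.clique_size])
    ppi_nodes = sorted(set(seq_mrna_ids)
                       | set(de_mrna["up"][:s.n_ppi_nodes // 2])
                       | set(de_mrna["down"][:s.n_ppi_nodes // 2]))[:s.n_ppi_nodes]
    ppi_nodes = sorted(set(ppi_nodes) | clique)
    ppi_edges, ppi_truth = synth.gen_ppi(ppi_nodes, [clique], s.ppi_noise_edges,
                                         _child_seed(seed, 4))
    truth.planted_cliques = ppi_truth.planted_cliques

    # --- survival cohort ---------------------------------------------
    surv_df = None
    survival_genes = hub_candidates
    if cfg.survival is not None:
        sv = cfg.survival
        genes = sorted(clique)
        extra = [m for m in seq_mrna_ids if m not in genes]
        genes = genes + extra[:max(0, 10 - len(genes))]
        rng_s = np.random.default_rng(_child_seed(seed, 5))
        expr_df = pd.DataFrame(rng_s.standard_normal((sv.n_patients, len(genes))),
                               columns=genes)
        prognostic = sorted(clique)[:sv.n_prognostic]
        betas = {g: sv.beta for g in prognostic}
        surv_df = synth.gen_survival(sv.n_patients, betas, expr_df, sv.censor_rate,
                                     _child_seed(seed, 6))
        truth.prognostic_betas = betas
        survival_genes = genes

    return ScenarioData(mrna_counts, circ_counts, mirnas, circ_seqs, mrna_seqs,
                        ppi_edges, sorted(set(survival_genes)), surv_df, truth)


# --------------------------------------------------------------- run_all

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full chain; returns the truth-vs-output report dict.

    Artifacts land in ``out_dir``: input tables, per-stage TSVs, network
    exports (GraphML + SIF), the risk-model JSON, a manifest, and
    ``report.json`` comparing results against the planted truth.
    """
    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    data = synthesize_inputs(config)

    # persist inputs so each stage is re-runnable from disk
    cio.write_counts(data.mrna_counts, out / "inputs" / "mrna_counts.tsv")
    cio.write_counts(data.circ_counts, out / "inputs" / "circ_counts.tsv")
    cio.write_fasta(data.mirnas, out / "inputs" / "mirnas.fa")
    cio.write_fasta(data.circ_seqs, out / "inputs" / "circ_seqs.fa")
    cio.write_fasta(data.mrna_seqs, out / "inputs" / "mrna_seqs.fa")
    cio.write_edges(data.ppi_edges, out / "inputs" / "ppi_edges.tsv")
    if data.survival is not None:
        cio.write_table(data.survival, out / "inputs" / "survival.tsv", index=False)

    report: dict = {"seed": config.seed, "stages_completed": []}

    # --- differential expression -------------------------------------
    n_mrna_pairs = len(data.mrna_counts.sample_ids) // 2
    mrna_groups = ["N"] * n_mrna_pairs + ["T"] * n_mrna_pairs
    mrna_res = expr.de_test(data.mrna_counts, mrna_groups, reference="N")
    mrna_de = expr.call_de(mrna_res, config.min_abs_logfc, config.alpha,
                           use_adjusted=config.mrna_use_adjusted)
    n_circ_pairs = len(data.circ_counts.sample_ids) // 2
    circ_groups = ["N"] * n_circ_pairs + ["T"] * n_circ_pairs
    circ_res = expr.de_test(data.circ_counts, circ_groups, reference="N")
    circ_de = expr.call_de(circ_res, config.min_abs_logfc, config.alpha,
                           use_adjusted=config.circ_use_adjusted)
    cio.write_table(expr.de_table(mrna_res), out / "de_mrna.tsv")
    cio.write_table(expr.de_table(circ_res), out / "de_circ.tsv")

    planted_mrna = {f for f, _ in data.truth.de_features if f.startswith("GENE")}
    called_mrna = {r.feature_id for r in mrna_de}
    report["de"] = {
        "n_de_mrna": len(mrna_de), "n_de_circ": len(circ_de),
        "mrna_sensitivity": len(called_mrna & planted_mrna) / max(1, len(planted_mrna)),
        "mrna_false_calls": len(called_mrna - planted_mrna) / max(1, len(called_mrna)),
    }
    report["stages_completed"].append("de")

    # --- target scan --------------------------------------------------
    circ_de_ids = {r.feature_id for r in circ_de}
    mrna_de_ids = {r.feature_id for r in mrna_de}
    circ_targets = {k: v for k, v in data.circ_seqs.items() if k in circ_de_ids}
    mrna_targets = {k: v for k, v in data.mrna_seqs.items() if k in mrna_de_ids}
    circ_hits = mt.scan_targets(data.mirnas, circ_targets,
                                config.min_score, config.max_energy)
    mrna_hits = mt.scan_targets(data.mirnas, mrna_targets,
                                config.min_score, config.max_energy)
    hits_df = pd.DataFrame(
        [(h.mirna_id, h.target_id, h.score, h.energy, h.target_start, h.target_end)
         for h in circ_hits + mrna_hits],
        columns=["mirna_id", "target_id", "score", "energy", "start", "end"])
    cio.write_table(hits_df, out / "target_hits.tsv", index=False)
    report["scan"] = {"n_circ_hits": len(circ_hits), "n_mrna_hits": len(mrna_hits)}
    report["stages_completed"].append("scan")

    # --- ceRNA network ------------------------------------------------
    cerna, triples = net.build_cerna(circ_de, mrna_de, circ_hits, mrna_hits,
                                     energy_sum_max=config.energy_sum_max)
    cio.write_table(net.triples_table(triples), out / "cerna_triples.tsv", index=False)
    cio.write_graphml(cerna.graph, out / "cerna_network.graphml")
    cio.write_sif(cerna.graph, out / "cerna_network.sif")
    found = {(t.circ_id, t.mir_id, t.mrna_id) for t in triples}
    planted = set(data.truth.planted_triples)
    report["cerna"] = {
        "n_triples": len(found),
        "n_circ": len(cerna.nodes_of_kind("circRNA")),
        "n_mirna": len(cerna.nodes_of_kind("miRNA")),
        "n_mrna": len(cerna.nodes_of_kind("mRNA")),
        "precision": len(found & planted) / len(found) if found else float("nan"),
        "recall": len(found & planted) / len(planted) if planted else float("nan"),
    }
    report["stages_completed"].append("cerna")

    # --- GSEA ---------------------------------------------------------
    ranking = pd.Series({r.feature_id: r.logFC for r in mrna_res}).sort_values(
        ascending=False, kind="stable")
    planted_up = sorted(f for f, d in data.truth.de_features
                        if f.startswith("GENE") and d == "up")
    planted_up = sorted(planted_up, key=lambda f: -ranking.get(f, 0))[:config.gsea_set_size]
    rng_sets = np.random.default_rng(_child_seed(config.seed, 7))
    random_set = set(rng_sets.choice(ranking.index.to_numpy(), size=config.gsea_set_size,
                                     replace=False))
    gene_sets = {"PLANTED_UP": set(planted_up), "RANDOM_CONTROL": random_set}
    cio.write_gmt(gene_sets, out / "gene_sets.gmt")
    gsea_res = enr.gsea(ranking, gene_sets, n_perm=config.n_perm,
                        seed=_child_seed(config.seed, 8))
    cio.write_table(pd.DataFrame(
        [(r.set_id, r.es, r.nes, r.p, r.significant) for r in gsea_res],
        columns=["set_id", "es", "nes", "p", "significant"]),
        out / "gsea.tsv", index=False)
    report["gsea"] = {r.set_id: {"es": r.es, "nes": r.nes, "p": r.p,
                                 "significant": r.significant} for r in gsea_res}
    report["stages_completed"].append("gsea")

    # --- PPI hubs -----------------------------------------------------
    scores = net.mcc_scores(data.ppi_edges)
    hubs = net.top_hubs(scores, k=config.k_hubs)
    cio.write_table(pd.DataFrame([(s.gene_id, s.mcc, s.rank) for s in scores],
                                 columns=["gene_id", "mcc", "rank"]),
                    out / "hub_scores.tsv", index=False)
    clique = data.truth.planted_cliques[0] if data.truth.planted_cliques else set()
    report["hubs"] = {"top": hubs,
                      "clique_recovered": len(set(hubs) & clique) / len(clique)
                      if clique else float("nan")}
    report["stages_completed"].append("hubs")

    if data.survival is None or config.survival is None:
        report["notice"] = ("no survival block in config: pipeline stopped after "
                            "the hub stage")
        _finish(out, config, report)
        return report

    # --- survival signature -------------------------------------------
    sv = config.survival
    surv = data.survival
    hub_genes = [g for g in data.hub_candidates if g in surv.columns]
    screen = {}
    for g in hub_genes:
        b, hr, ci, p = prog.cox_univariate(surv, g)
        screen[g] = {"beta": b, "hr": hr, "ci": ci, "p": p}
    survivors = sorted(g for g, r in screen.items() if r["p"] < sv.cox_screen_alpha)
    if len(survivors) < 2:
        warnings.warn("fewer than two genes passed the Cox screen; using all hubs")
        survivors = sorted(hub_genes)
    model = prog.lasso_cox(surv, survivors, n_folds=sv.n_folds,
                           seed=_child_seed(config.seed, 9), rule=sv.lasso_rule)
    scores_s, labels = prog.risk_scores(model, surv.set_index("sample")[model.genes]
                                        if model.genes else surv.set_index("sample"))
    surv_idx = surv.set_index("sample")
    hi, lo = surv_idx[labels == "high"], surv_idx[labels == "low"]
    if len(hi) and len(lo):
        _, lr_p = prog.logrank(hi, lo)
    else:
        lr_p = float("nan")
    model.auc = prog.td_auc(surv, scores_s.to_numpy() if model.genes
                            else np.zeros(len(surv)), list(sv.horizons))
    model_json = {"genes": model.genes, "betas": model.betas, "cutoff": model.cutoff,
                  "lambda": model.lambda_, "rule": model.rule,
                  "auc": {str(k): v for k, v in model.auc.items()},
                  "logrank_p_high_vs_low": lr_p,
                  "cox_screen": screen}
    (out / "risk_model.json").write_text(
        json.dumps(model_json, indent=2, sort_keys=True, default=_json_default))
    pd.DataFrame({"risk_score": scores_s, "risk_group": labels}).to_csv(
        out / "risk_scores.tsv", sep="\t")
    report["signature"] = {
        "genes": model.genes,
        "planted": sorted(data.truth.prognostic_betas),
        "planted_recovered": sorted(set(model.genes)
                                    & set(data.truth.prognostic_betas)),
        "auc": {str(k): v for k, v in model.auc.items()},
        "logrank_p": lr_p,
    }
    report["stages_completed"].append("signature")

    # --- signature subnetwork ----------------------------------------
    keep = [g for g in model.genes if g in set(cerna.nodes_of_kind("mRNA"))]
    sub = net.subnetwork(cerna, keep)
    cio.write_graphml(sub.graph, out / "signature_subnetwork.graphml")
    cio.write_table(net.triples_table(sub.triples), out / "signature_triples.tsv",
                    index=False)
    report["subnetwork"] = {"n_triples": len(sub.triples), "mrnas": keep}
    report["stages_completed"].append("subnetwork")

    _finish(out, config, report)
    return report


def _finish(out: Path, config: PipelineConfig, report: dict) -> None:
    manifest = {
        "config": asdict(config),
        "inputs": {p.name: _sha256(p) for p in sorted((out / "inputs").glob("*"))},
        "outputs": sorted(p.name for p in out.glob("*") if p.is_file()),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default))
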