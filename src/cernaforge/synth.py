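"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study design the pipeline targets: paired
tumor/normal RNA-seq count matrices with planted fold-changes (negative
binomial, since the downstream exact-style count test assumes a
gamma-Poisson model), RNA sequence sets with planted miRNA binding sites
(exact reverse complements embedded at known positions), a protein-protein
interaction graph with planted cliques, and survival times whose hazard is
driven by planted gene coefficients.  Each generator takes one integer
seed and is byte-identical across re-runs with the same arguments
(NumPy PCG64 via ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidArgumentError
from .expression import ExprMatrix

RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp_rna(seq: str) -> str:
    """Reverse complement on the RNA alphabet (A<->U, C<->G)."""
    return seq.translate(RNA_COMPLEMENT)[::-1]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    Every id listed here exists in the corresponding emitted dataset; the
    seed fully determines all outputs.
    """

    seed: int
    de_features: set[tuple[str, str]] = field(default_factory=set)  # (id, "up"/"down")
    planted_sites: list[tuple[str, str, int]] = field(default_factory=list)  # (mir, target, 1-based start)
    planted_triples: list[tuple[str, str, str]] = field(default_factory=list)  # (circ, mir, mrna)
    planted_cliques: list[set[str]] = field(default_factory=list)
    prognostic_betas: dict[str, float] = field(default_factory=dict)


# ------------------------------------------------------------- count matrix

def gen_count_matrix(n_features: int, n_pairs: int, frac_de: float, fc_de: float,
                     dispersion: float, lib_sizes: list[int], seed: int,
                     feature_ids: list[str] | None = None,
                     base_mean: float = 100.0,
                     group_prefixes: tuple[str, str] = ("N", "T"),
                     ) -> tuple[ExprMatrix, SyntheticTruth]:
    """Paired two-group negative-binomial counts with planted fold-changes.

    Samples are ordered ``N1..Nk, T1..Tk`` (reference group first) and
    ``lib_sizes`` follows that order.  Exactly ``round(frac_de *
    n_features)`` features are planted differential with mean ratio
    ``fc_de`` between groups, direction split ~50/50 at random.  Count
    means scale with library size; ``dispersion`` is the NB dispersion
    alpha (variance mu + alpha*mu^2; 0 gives Poisson).
    """
    if n_pairs < 2:
        raise InvalidArgumentError("n_pairs must be >= 2")
    if not 0 <= frac_de <= 1:
        raise InvalidArgumentError("frac_de must be in [0, 1]")
    if fc_de < 1:
        raise InvalidArgumentError("fc_de must be >= 1")
    if dispersion < 0:
        raise InvalidArgumentError("dispersion must be >= 0")
    if len(lib_sizes) != 2 * n_pairs:
        raise InvalidArgumentError("lib_sizes must have length 2 * n_pairs")
    if any(l <= 0 for l in lib_sizes):
        raise InvalidArgumentError("library sizes must be positive")

    rng = np.random.default_rng(seed)
    if feature_ids is None:
        feature_ids = [f"G{i + 1:05d}" for i in range(n_features)]
    elif len(feature_ids) != n_features:
        raise InvalidArgumentError("feature_ids length must equal n_features")

    sample_ids = ([f"{group_prefixes[0]}{i + 1}" for i in range(n_pairs)]
                  + [f"{group_prefixes[1]}{i + 1}" for i in range(n_pairs)])
    lib = np.asarray(lib_sizes, dtype=float)

    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_features)
    n_de = round(frac_de * n_features)
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    up = rng.random(n_de) < 0.5

    # symmetric split of the fold-change keeps overall abundance comparable
    effect = np.ones((n_features, 2))  # columns: reference group, test group
    effect[de_idx[up], 1] = np.sqrt(fc_de)
    effect[de_idx[up], 0] = 1.0 / np.sqrt(fc_de)
    effect[de_idx[~up], 1] = 1.0 / np.sqrt(fc_de)
    effect[de_idx[~up], 0] = np.sqrt(fc_de)

    depth = lib / lib.mean()
    group_col = np.array([0] * n_pairs + [1] * n_pairs)
    mu = base[:, None] * effect[:, group_col] * depth[None, :]
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    truth = SyntheticTruth(seed=seed)
    for k, i in enumerate(de_idx):
        truth.de_features.add((feature_ids[i], "up" if up[k] else "down"))

    mat = ExprMatrix(pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
                     kind="count", lib_sizes=pd.Series(lib, index=sample_ids))
    return mat, truth


# --------------------------------------------------------------- sequences

def gen_sequences(n_mirna: int, n_circ: int, n_mrna: int,
                  site_plan: list[tuple[str, str, int]], seed: int,
                  mirna_len: int = 22,
                  circ_len_range: tuple[int, int] = (300, 1200),
                  mrna_len_range: tuple[int, int] = (400, 2000),
                  circ_ids: list[str] | None = None,
                  mrna_ids: list[str] | None = None,
                  mirna_ids: list[str] | None = None,
                  mirna_seqs: dict[str, str] | None = None,
                  ) -> tuple[dict[str, str], dict[str, str], dict[str, str], SyntheticTruth]:
    """RNA sequence sets with planted miRNA binding sites.

    Returns (mirnas, circs, mrnas, truth).  Background sequence is uniform
    over A/C/G/U; each planned site embeds the exact reverse complement of
    the full miRNA at a recorded 1-based position, non-overlapping with
    other planted sites on the same target.  circRNA ids default to
    circBase-style ``chrN:start-end`` spans.
    """
    if not 19 <= mirna_len <= 24:
        raise InvalidArgumentError("miRNA length must be in 19..24")
    for lo, hi in (circ_len_range, mrna_len_range):
        if not 200 <= lo <= hi <= 3000:
            raise InvalidArgumentError("target lengths must lie in 200..3000")

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))

    def rand_seq(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length))

    if mirna_ids is None:
        mirna_ids = [f"miR-{i + 1:03d}" for i in range(n_mirna)]
    if circ_ids is None:
        circ_ids = []
        for i in range(n_circ):
            chrom = f"chr{rng.integers(1, 23)}"
            start = int(rng.integers(10_000, 100_000_000))
            end = start + int(rng.integers(500, 50_000))
            circ_ids.append(f"{chrom}:{start}-{end}")
    if mrna_ids is None:
        mrna_ids = [f"MRNA{i + 1:04d}" for i in range(n_mrna)]

    mirnas = {mid: rand_seq(mirna_len) for mid in mirna_ids}
    if mirna_seqs:
        for mid, seq in mirna_seqs.items():
            if mid not in mirnas:
                raise InvalidArgumentError(f"unknown miRNA id in mirna_seqs: {mid!r}")
            if len(seq) != mirna_len or any(c not in "ACGU" for c in seq):
                raise InvalidArgumentError(f"fixed miRNA {mid!r} must be RNA of length {mirna_len}")
            mirnas[mid] = seq
    lengths: dict[str, int] = {}
    targets: dict[str, str] = {}
    for cid in circ_ids:
        lengths[cid] = int(rng.integers(circ_len_range[0], circ_len_range[1] + 1))
    for mid in mrna_ids:
        lengths[mid] = int(rng.integers(mrna_len_range[0], mrna_len_range[1] + 1))
    for tid, L in lengths.items():
        targets[tid] = rand_seq(L)

    truth = SyntheticTruth(seed=seed)
    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in targets}
    for mir_id, target_id, n_sites in site_plan:
        if mir_id not in mirnas:
            raise InvalidArgumentError(f"unknown miRNA id in site plan: {mir_id!r}")
        if target_id not in targets:
            raise InvalidArgumentError(f"unknown target id in site plan: {target_id!r}")
        site = revcomp_rna(mirnas[mir_id])
        L, sl = lengths[target_id], len(site)
        if n_sites * sl > L:
            raise InvalidArgumentError(
                f"{n_sites} sites of length {sl} cannot fit target {target_id!r} (len {L})")
        seq = list(targets[target_id])
        placed = 0
        attempts = 0
        while placed < n_sites:
            attempts += 1
            if attempts > 10_000:
                raise InvalidArgumentError(
                    f"could not place {n_sites} non-overlapping sites on {target_id!r}")
            start0 = int(rng.integers(0, L - sl + 1))  # 0-based
            if any(start0 < e and start0 + sl > s for s, e in occupied[target_id]):
                continue
            seq[start0:start0 + sl] = site
            occupied[target_id].append((start0, start0 + sl))
            truth.planted_sites.append((mir_id, target_id, start0 + 1))
            placed += 1
        targets[target_id] = "".join(seq)

    circs = {cid: targets[cid] for cid in circ_ids}
    mrnas = {mid: targets[mid] for mid in mrna_ids}
    return mirnas, circs, mrnas, truth


# ---------------------------------------------------------------- survival

def gen_survival(n_patients: int, betas: dict[str, float], expr: pd.DataFrame,
                 censor_rate: float, seed: int,
                 baseline_hazard: float = np.log(2) / 5.0) -> pd.DataFrame:
    """Exponential survival times with hazard exp(sum beta * x).

    ``expr`` is patients x genes (all beta keys must be columns).  Event
    times are exponential with rate ``baseline_hazard * exp(linear
    predictor)``; independent Uniform(0, c) censoring with c root-found so
    the expected censoring fraction matches ``censor_rate``.  Returns a
    table with columns (sample, time, event) followed by the expression
    covariates.
    """
    if not 0 <= censor_rate < 1:
        raise InvalidArgumentError("censor_rate must be in [0, 1)")
    missing = [g for g in betas if g not in expr.columns]
    if missing:
        raise InvalidArgumentError(f"beta genes missing from expression: {missing}")
    if len(expr) != n_patients:
        raise InvalidArgumentError("expr must have one row per patient")

    rng = np.random.default_rng(seed)
    lp = np.zeros(n_patients)
    for gene, beta in betas.items():
        lp += beta * expr[gene].to_numpy(dtype=float)
    rates = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rates)

    if censor_rate == 0:
        time, event = t_event, np.ones(n_patients, dtype=int)
    else:
        def expected_censoring(c: float) -> float:
            # P(C < T | rate) with C ~ U(0, c), T ~ Exp(rate)
            x = rates * c
            return float(np.mean((1.0 - np.exp(-x)) / x))

        lo, hi = 1e-9, 1.0
        while expected_censoring(hi) > censor_rate and hi < 1e9:
            hi *= 2.0
        c_max = brentq(lambda c: expected_censoring(c) - censor_rate, lo, hi)
        t_cens = rng.uniform(0.0, c_max, size=n_patients)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    out = pd.DataFrame({"sample": [f"P{i + 1:04d}" for i in range(n_patients)],
                        "time": time, "event": event})
    for col in expr.columns:
        out[col] = expr[col].to_numpy()
    return out


# --------------------------------------------------------------------- PPI

def gen_ppi(nodes: list[str], planted_cliques: list[set[str]], noise_edges: int,
            seed: int) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Undirected simple PPI edge list with planted cliques plus noise.

    All within-clique edges are present; ``noise_edges`` additional edges
    are sampled uniformly from the remaining non-edges (no duplicates, no
    self-loops).
    """
    node_set = set(nodes)
    if len(node_set) != len(nodes):
        raise InvalidArgumentError("duplicate node ids")
    for clique in planted_cliques:
        if len(clique) < 2:
            raise InvalidArgumentError("planted clique must have >= 2 nodes")
        if not clique <= node_set:
            raise InvalidArgumentError(f"clique nodes not in node list: {sorted(clique - node_set)}")

    rng = np.random.default_rng(seed)
    edges: set[tuple[str, str]] = set()
    for clique in planted_cliques:
        members = sorted(clique)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.add((members[i], members[j]))

    order = sorted(nodes)
    candidates = [(order[i], order[j])
                  for i in range(len(order)) for j in range(i + 1, len(order))
                  if (order[i], order[j]) not in edges]
    if noise_edges > len(candidates):
        raise InvalidArgumentError(
            f"requested {noise_edges} noise edges but only {len(candidates)} non-edges exist")
    idx = rng.choice(len(candidates), size=noise_edges, replace=False)
    for k in sorted(idx):
        edges.add(candidates[k])

    truth = SyntheticTruth(seed=seed, planted_cliques=[set(c) for c in planted_cliques])
    return sorted(edges), truth
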