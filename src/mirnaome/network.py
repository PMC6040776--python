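"""Breed-DE miRNA / breed-DE mRNA pairing, bipartite network and hubs,
plus binomial-test term overrepresentation for target genes.

Pairing follows three conjunctive steps: (1) a miRNA that is breed-DE at
any stage is paired with its predicted targets when the Spearman rank
correlation of their 5-stage expression trajectories is below -0.5 in at
least one breed (negative co-trend); (2) the mRNA member must itself be
breed-DE; (3) surviving pairs become the edges of a bipartite interaction
network in which nodes of degree >= 5 (inclusive) are flagged hubs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binom, rankdata

from .annotate import revcomp

DEFAULT_RHO = -0.5
HUB_DEGREE = 5
SEED_START, SEED_END = 1, 8  # miRNA positions 2-8, 0-based half-open


# ---------------------------------------------------------------------------
# target prediction stand-in
# ---------------------------------------------------------------------------


def seed_match_targets(
    mirna_seqs: Mapping[str, str], utr_seqs: Mapping[str, str]
) -> pd.DataFrame:
    """Predict pairs by exact seed-site matching.

    A (miRNA, mRNA) pair is predicted when the reverse complement of the
    miRNA seed (positions 2-8, a 7-mer) occurs in the mRNA 3'UTR; every
    match offset is reported. RNA input (U) is accepted and treated as T.
    """
    rows = []
    for mir_id in sorted(mirna_seqs):
        seq = mirna_seqs[mir_id].upper().replace("U", "T")
        if len(seq) < SEED_END:
            raise ValueError(f"{mir_id}: miRNA shorter than 8 nt")
        site = revcomp(seq[SEED_START:SEED_END])
        for gene_id in sorted(utr_seqs):
            utr = utr_seqs[gene_id].upper().replace("U", "T")
            positions = []
            p = utr.find(site)
            while p != -1:
                positions.append(p)
                p = utr.find(site, p + 1)
            if positions:
                rows.append(
                    {
                        "mirna_id": mir_id,
                        "mrna_id": gene_id,
                        "site": site,
                        "positions": positions,
                    }
                )
    return pd.DataFrame(rows, columns=["mirna_id", "mrna_id", "site", "positions"])


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def spearman_rho(a, b) -> float | None:
    """Spearman rank correlation: Pearson on average ranks (ties get their
    mean rank). Returns None when either vector is constant (undefined)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    ra, rb = rankdata(a), rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


@dataclass
class MiRTargetPair:
    """A candidate miRNA-target pair with its per-breed trajectory rho."""

    mirna_id: str
    mrna_id: str
    predicted: bool
    rho: dict[str, float | None]
    de_stages: tuple[int, ...]
    passes_pairing: bool


def pair_breed_de(
    breed_de_mirnas: Mapping[int, set[str]],
    predicted_pairs: Iterable[tuple[str, str]],
    mirna_traj: Mapping[str, pd.DataFrame],
    mrna_traj: Mapping[str, pd.DataFrame],
    rho_threshold: float = DEFAULT_RHO,
) -> list[MiRTargetPair]:
    """Step 1 of the pairing: breed-DE miRNA + predicted target + negative
    trajectory correlation in at least one breed.

    ``mirna_traj`` / ``mrna_traj`` map breed -> (id x stage) expression
    trajectory tables. Pairs whose trajectories are missing are skipped with
    a warning; pairs with undefined (constant-vector) rho are excluded.
    """
    import warnings

    de_union: dict[str, list[int]] = {}
    for stage, ids in breed_de_mirnas.items():
        for mir in ids:
            de_union.setdefault(mir, []).append(int(stage))

    out = []
    for mir, gene in sorted(set(predicted_pairs)):
        stages = tuple(sorted(de_union.get(mir, ())))
        if not stages:
            continue
        rho: dict[str, float | None] = {}
        missing = False
        for breed in sorted(mirna_traj):
            mt, gt = mirna_traj[breed], mrna_traj.get(breed)
            if gt is None or mir not in mt.index or gene not in gt.index:
                missing = True
                break
            rho[breed] = spearman_rho(mt.loc[mir], gt.loc[gene])
        if missing:
            warnings.warn(
                f"missing trajectory for pair ({mir}, {gene}); skipped",
                stacklevel=2,
            )
            continue
        passes = any(
            r is not None and r < rho_threshold for r in rho.values()
        )
        out.append(
            MiRTargetPair(
                mirna_id=mir,
                mrna_id=gene,
                predicted=True,
                rho=rho,
                de_stages=stages,
                passes_pairing=passes,
            )
        )
    return out


def intersect_breed_de_mrna(
    pairs: list[MiRTargetPair], breed_de_mrnas: set[str]
) -> list[MiRTargetPair]:
    """Step 2: keep passing pairs whose mRNA is itself breed-DE."""
    return [
        p
        for p in pairs
        if p.passes_pairing and p.mrna_id in breed_de_mrnas
    ]


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def build_network(
    pairs: list[MiRTargetPair], hub_degree: int = HUB_DEGREE
) -> nx.Graph:
    """Bipartite miRNA-mRNA graph with degree and hub (degree >= cutoff,
    inclusive) node attributes. Pairs are deduplicated on (miRNA, mRNA)."""
    g = nx.Graph()
    for p in pairs:
        g.add_node(p.mirna_id, kind="miRNA")
        g.add_node(p.mrna_id, kind="mRNA")
        g.add_edge(p.mirna_id, p.mrna_id)
    for node in g.nodes:
        degree = g.degree[node]
        g.nodes[node]["degree"] = degree
        g.nodes[node]["hub"] = degree >= hub_degree
    return g


def degree_table(network: nx.Graph) -> pd.DataFrame:
    """Degree-ranked node table with kind and hub flag."""
    rows = [
        {
            "node": n,
            "kind": d["kind"],
            "degree": d["degree"],
            "hub": d["hub"],
        }
        for n, d in network.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node", "kind", "degree", "hub"])
    return df.sort_values(
        ["degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)


def export_network(network: nx.Graph, sif_path, graphml_path=None) -> None:
    """Write the network as SIF (one edge per line, relation "targets") and
    optionally GraphML with the node attributes."""
    sif_path = Path(sif_path)
    lines = []
    for a, b in sorted(network.edges):
        if network.nodes[a]["kind"] != "miRNA":
            a, b = b, a
        lines.append(f"{a}\ttargets\t{b}")
    sif_path.write_text("\n".join(lines) + ("\n" if lines else ""))
    if graphml_path is not None:
        nx.write_graphml(network, graphml_path)


# ---------------------------------------------------------------------------
# term overrepresentation
# ---------------------------------------------------------------------------


def binomial_overrepresentation(
    target_genes: set[str],
    annotation: Mapping[str, set[str]],
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided binomial overrepresentation of annotation terms.

    With n = |target set|, k = targets annotated to the term and q = term
    share of the universe, the p-value is P(X >= k | n, q); terms with
    p < alpha are flagged enriched. The universe defaults to the union of
    all annotated genes.
    """
    if universe is None:
        universe = set().union(*annotation.values()) if annotation else set()
    if not universe:
        raise ValueError("empty annotation universe")
    stray = target_genes - universe
    if stray:
        raise ValueError(f"target genes outside the universe: {sorted(stray)[:5]}")
    n = len(target_genes)
    rows = []
    for term in sorted(annotation):
        genes = annotation[term] & universe
        k = len(target_genes & genes)
        q = len(genes) / len(universe)
        p = float(binom.sf(k - 1, n, q)) if k > 0 else 1.0
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "term_genes": len(genes),
                "universe": len(universe),
                "q": q,
                "p_value": p,
                "enriched": bool(p < alpha and k > 0),
            }
        )
    return pd.DataFrame(rows).sort_values("p_value").reset_index(drop=True)
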