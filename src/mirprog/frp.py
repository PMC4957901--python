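"""Functional regulatory program (FRP) mining.

The genes of a regulatory network, annotated with functional terms, form
a boolean gene x term incidence.  A maximal biclique of that incidence is
a term set together with the complete set of genes carrying all of those
terms, such that neither side can grow without breaking completeness —
equivalently, a closed itemset over terms with its supporting gene set.
Mining uses an LCM-style depth-first enumeration with closure checking
(terms are few relative to genes, so the search runs over term space).
Mined bicliques are tested for over-representation against a whole-genome
background, de-duplicated by a silhouette criterion on a Jaccard
term-profile distance, and finally turned into FRPs by attaching every
miRNA with a network edge into the biclique's gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enrichment import bh_fdr, hypergeom_upper_tail

logger = logging.getLogger(__name__)


@dataclass
class IncidenceMatrix:
    """Boolean gene x term membership restricted to network genes."""

    genes: list[str]
    terms: list[str]
    cells: np.ndarray  # bool, shape (len(genes), len(terms))

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if self.cells.shape != (len(self.genes), len(self.terms)):
            raise ValueError("cells shape does not match gene/term lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.genes, columns=self.terms)


@dataclass
class MaximalBiclique:
    """A closed term itemset with its full supporting gene set."""

    gene_ids: frozenset
    term_ids: frozenset
    support: int
    p_value: float | None = None
    fdr: float | None = None
    silhouette: float | None = None

    def sort_key(self):
        return (-self.support, tuple(sorted(self.term_ids)))


@dataclass
class FRP:
    """A maximal biclique plus the miRNAs that regulate its genes."""

    biclique: MaximalBiclique
    mirna_ids: frozenset = field(default_factory=frozenset)

    @property
    def flagged_no_regulators(self) -> bool:
        return len(self.mirna_ids) == 0


def build_incidence(network_genes, annotations) -> IncidenceMatrix:
    """Gene x term incidence over annotated network genes.

    Rows are network genes with at least one annotation; columns are terms
    hitting at least one network gene.
    """
    net = set(network_genes)
    term_hits = {
        t: set(g) & net for t, g in annotations.items() if set(g) & net
    }
    genes = sorted({g for hits in term_hits.values() for g in hits})
    terms = sorted(term_hits)
    if not genes:
        logger.warning("no annotated genes in network; incidence is empty")
        return IncidenceMatrix([], [], np.zeros((0, 0), dtype=bool))
    gene_idx = {g: i for i, g in enumerate(genes)}
    cells = np.zeros((len(genes), len(terms)), dtype=bool)
    for j, t in enumerate(terms):
        for g in term_hits[t]:
            cells[gene_idx[g], j] = True
    return IncidenceMatrix(genes, terms, cells)


def mine_closed_itemsets(
    incidence: IncidenceMatrix,
    min_support: int,
    min_itemset_size: int = 1,
) -> list[MaximalBiclique]:
    """All closed term itemsets with support >= ``min_support``.

    Depth-first prefix-preserving closure extension (LCM): each closed
    itemset is generated exactly once, from the extension item that is the
    smallest new item of its closure.  Output is deterministic, sorted by
    (-support, lexicographic term tuple).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    n_genes, n_terms = incidence.cells.shape
    if n_genes == 0 or n_terms == 0:
        return []
    cols = incidence.cells  # (genes, terms)
    genes = np.array(incidence.genes)
    results: list[MaximalBiclique] = []

    def closure_of(mask: np.ndarray) -> np.ndarray:
        # terms annotated to every supporting gene
        return cols[mask].all(axis=0)

    def emit(term_mask: np.ndarray, gene_mask: np.ndarray) -> None:
        terms = frozenset(map(str, np.array(incidence.terms)[term_mask]))
        if len(terms) < min_itemset_size:
            return
        results.append(
            MaximalBiclique(
                gene_ids=frozenset(map(str, genes[gene_mask])),
                term_ids=terms,
                support=int(gene_mask.sum()),
            )
        )

    def expand(term_mask: np.ndarray, gene_mask: np.ndarray, last: int) -> None:
        for j in range(last + 1, n_terms):
            if term_mask[j]:
                continue
            new_genes = gene_mask & cols[:, j]
            if int(new_genes.sum()) < min_support:
                continue
            new_closure = closure_of(new_genes)
            # prefix test: closure may not add items before j beyond current
            if np.any(new_closure[:j] & ~term_mask[:j]):
                continue
            emit(new_closure, new_genes)
            expand(new_closure, new_genes, j)

    # no itemset can have support above the total gene count
    if n_genes >= min_support:
        root_genes = np.ones(n_genes, dtype=bool)
        root_closure = closure_of(root_genes)
        if root_closure.any():
            emit(root_closure, root_genes)
        expand(root_closure, root_genes, -1)
    results.sort(key=MaximalBiclique.sort_key)
    return results


def mb_significance(
    mbs: list[MaximalBiclique],
    input_genes,
    background_annotations,
    background_genes,
    fdr_cutoff: float = 0.05,
    significant_only: bool = True,
) -> list[MaximalBiclique]:
    """Hypergeometric significance of each biclique against a background.

    For a biclique with term set S, the test asks whether the network's
    gene set is enriched in genes co-annotated with all of S: k is the
    biclique support, n the network genes inside the background, K the
    background genes carrying all terms of S, N the background size.
    BH-FDR is computed across bicliques; with ``significant_only`` the
    list is restricted to fdr < ``fdr_cutoff``.
    """
    if not mbs:
        return []
    background = set(background_genes)
    n = len(set(input_genes) & background)
    N = len(background)
    term_sets = {t: set(g) & background for t, g in background_annotations.items()}
    ks, Ks = [], []
    for mb in mbs:
        co = None
        for t in mb.term_ids:
            hits = term_sets.get(t, set())
            co = hits.copy() if co is None else co & hits
        K = len(co) if co is not None else 0
        if K == 0:
            raise ValueError(
                f"biclique terms {sorted(mb.term_ids)} have no co-annotated "
                "background genes; background inconsistent with incidence"
            )
        ks.append(min(mb.support, n, K))
        if mb.support > min(n, K):
            logger.warning(
                "biclique support %d exceeds min(n=%d, K=%d); clipped",
                mb.support, n, K,
            )
        Ks.append(K)
    p = hypergeom_upper_tail(np.array(ks), np.array(Ks), n, N)
    p = np.atleast_1d(p)
    q = bh_fdr(p)
    out = [
        replace(mb, p_value=float(pi), fdr=float(qi))
        for mb, pi, qi in zip(mbs, p, q)
    ]
    if significant_only:
        out = [mb for mb in out if mb.fdr < fdr_cutoff]
    return out


def _jaccard_distance_matrix(cells: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Jaccard over gene rows of a boolean incidence."""
    x = cells.astype(float)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 1.0)
    return 1.0 - jac


def silhouette_scores(
    mbs: list[MaximalBiclique],
    incidence: IncidenceMatrix,
) -> list[MaximalBiclique]:
    """Silhouette of each biclique under a Jaccard term-profile distance.

    Genes are points, their term profiles (rows of the incidence) define
    the distance d = 1 - Jaccard, and each biclique acts as a cluster.  A
    member gene's own-cluster distance a is the mean distance to the other
    members (0 for a singleton); its neighbor distance b is the smallest
    mean distance to another biclique's members (the gene itself excluded
    if it also belongs there).  The biclique silhouette is the mean of
    (b - a) / max(a, b) over its members.  With a single biclique the
    score is undefined (None) and the biclique is retained.
    """
    if not mbs:
        return []
    if len(mbs) == 1:
        return [replace(mbs[0], silhouette=None)]
    gene_idx = {g: i for i, g in enumerate(incidence.genes)}
    dist = _jaccard_distance_matrix(incidence.cells)
    members = [np.array(sorted(gene_idx[g] for g in mb.gene_ids)) for mb in mbs]
    out = []
    for ci, mb in enumerate(mbs):
        own = members[ci]
        scores = []
        for g in own:
            if len(own) > 1:
                a = dist[g, own[own != g]].mean()
            else:
                a = 0.0
            b = np.inf
            for cj, other in enumerate(members):
                if cj == ci:
                    continue
                pts = other[other != g]
                if len(pts) == 0:
                    continue
                b = min(b, dist[g, pts].mean())
            if not np.isfinite(b):
                continue
            denom = max(a, b)
            scores.append((b - a) / denom if denom > 0 else 0.0)
        out.append(replace(mb, silhouette=float(np.mean(scores)) if scores else None))
    return out


def select_min_support(
    incidence: IncidenceMatrix,
    candidate_supports,
    min_itemset_size: int = 1,
) -> int:
    """Smallest support maximizing the mean biclique silhouette.

    Each candidate support is mined and silhouette-scored; the candidate
    with the highest mean silhouette wins, ties and undefined scores
    resolving toward the smaller support.
    """
    candidates = sorted(set(candidate_supports))
    if not candidates:
        raise ValueError("candidate support list is empty")
    best = None
    diagnostics = {}
    for s in candidates:
        mbs = silhouette_scores(mine_closed_itemsets(incidence, s, min_itemset_size), incidence)
        defined = [mb.silhouette for mb in mbs if mb.silhouette is not None]
        diagnostics[s] = (len(mbs), len(defined))
        if not mbs:
            continue
        score = float(np.mean(defined)) if defined else float("-inf")
        if best is None or score > best[0]:
            best = (score, s)
    if best is None:
        raise ValueError(f"no candidate support yields bicliques: {diagnostics}")
    return best[1]


def assemble_frps(mbs: list[MaximalBiclique], edges: pd.DataFrame) -> list[FRP]:
    """Attach to each biclique every miRNA with an edge into its genes."""
    by_gene: dict[str, set] = {}
    for mirna, gene in zip(edges["mirna"], edges["gene"]):
        by_gene.setdefault(gene, set()).add(mirna)
    frps = []
    for mb in mbs:
        mirnas = frozenset().union(*(by_gene.get(g, set()) for g in mb.gene_ids)) if mb.gene_ids else frozenset()
        frp = FRP(biclique=mb, mirna_ids=frozenset(mirnas))
        if frp.flagged_no_regulators:
            logger.warning(
                "biclique %s has no regulator with a network edge",
                sorted(mb.term_ids),
            )
        frps.append(frp)
    return frps


def frp_table(frps: list[FRP]) -> pd.DataFrame:
    """Flatten FRPs to a report DataFrame (one row per program)."""
    rows = []
    for i, frp in enumerate(frps):
        mb = frp.biclique
        rows.append(
            {
                "frp_id": f"frp{i + 1:03d}",
                "genes": ";".join(sorted(mb.gene_ids)),
                "terms": ";".join(sorted(mb.term_ids)),
                "support": mb.support,
                "p_value": mb.p_value,
                "fdr": mb.fdr,
                "silhouette": mb.silhouette,
                "mirnas": ";".join(sorted(frp.mirna_ids)),
                "no_regulators": frp.flagged_no_regulators,
            }
        )
    return pd.DataFrame(rows)
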