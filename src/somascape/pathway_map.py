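"""Oncoprint matrices (gene- and pathway-level) and the analyses over
them: alteration frequencies, Pearson correlation between pathways,
mutual exclusivity, and unsupervised Random-Forest + PAM clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier

from .cnv_landscape import AMP, DEL
from .io_cohort import MutationCatalog
from .stats_survival import hypergeom_tail

logger = logging.getLogger(__name__)

ALTERATION_TYPES = ("mutation", "amp", "del")


@dataclass
class PathwayDefinition:
    """A named gene set; each member lists which alteration types qualify
    (nonsilent mutation, amplification, deletion)."""

    name: str
    members: dict[str, set[str]]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")
        for gene, kinds in self.members.items():
            bad = set(kinds) - set(ALTERATION_TYPES)
            if bad:
                raise ValueError(f"pathway {self.name!r}, gene {gene!r}: "
                                 f"unknown alteration types {bad}")


@dataclass
class AlterationMatrix:
    """Binary cases×items matrix (items are genes or pathways)."""

    binary: pd.DataFrame
    item_type: str = "gene"
    #: per-alteration-type binary matrices (gene matrices only)
    by_type: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self):
        vals = self.binary.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("alteration matrix entries must be 0/1")

    def frequencies(self) -> pd.Series:
        return self.binary.mean(axis=0)


def load_pathways(path=None) -> list[PathwayDefinition]:
    """Load pathway definitions from YAML (bundled defaults if no path)."""
    if path is None:
        ref = resources.files("somascape.data").joinpath("pathways.yaml")
        with resources.as_file(ref) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defs = []
    for name, members in raw.items():
        defs.append(PathwayDefinition(
            name=name,
            members={g: set(kinds) for g, kinds in members.items()}))
    return defs


def gene_alteration_matrix(catalog: MutationCatalog,
                           cn_calls: pd.DataFrame | None = None,
                           qualifying_cn: tuple[str, ...] = (AMP, DEL),
                           ) -> AlterationMatrix:
    """Binary case×gene matrix: 1 iff the case has a nonsilent mutation in
    the gene or a qualifying copy-number call.

    ``cn_calls`` is a cases×genes {amp,del,neutral} frame sharing the
    catalog's roster; pass None for a mutation-only matrix.
    """
    roster = list(catalog.case_roster)
    if cn_calls is not None:
        missing = set(cn_calls.index) - set(roster)
        if missing or set(roster) - set(cn_calls.index):
            raise ValueError("mutation catalog and CN calls must share one "
                             "case roster")
    mut_genes = sorted({r.gene for r in catalog.records if r.is_nonsilent})
    cn_genes = list(cn_calls.columns) if cn_calls is not None else []
    genes = sorted(set(mut_genes) | set(cn_genes))
    mut = pd.DataFrame(0, index=roster, columns=genes, dtype=int)
    for r in catalog.records:
        if r.is_nonsilent:
            mut.loc[r.case_id, r.gene] = 1
    amp = pd.DataFrame(0, index=roster, columns=genes, dtype=int)
    dele = pd.DataFrame(0, index=roster, columns=genes, dtype=int)
    if cn_calls is not None:
        aligned = cn_calls.loc[roster]
        amp.loc[:, cn_genes] = (aligned == AMP).astype(int)
        dele.loc[:, cn_genes] = (aligned == DEL).astype(int)
    combined = mut.copy()
    if AMP in qualifying_cn:
        combined |= amp
    if DEL in qualifying_cn:
        combined |= dele
    return AlterationMatrix(binary=combined, item_type="gene",
                            by_type={"mutation": mut, "amp": amp, "del": dele})


def pathway_alteration_matrix(gene_matrix: AlterationMatrix,
                              defs: list[PathwayDefinition],
                              ) -> tuple[AlterationMatrix, pd.Series]:
    """Case×pathway matrix (1 iff any member gene is altered with a
    qualifying type) and per-pathway frequencies.

    Member genes absent from the gene matrix are skipped with a warning;
    a pathway left empty after skipping is an error.
    """
    if not gene_matrix.by_type:
        raise ValueError("gene matrix must carry per-type matrices")
    known = set(gene_matrix.binary.columns)
    cols = {}
    for d in defs:
        hit = np.zeros(len(gene_matrix.binary.index), dtype=int)
        used = 0
        for gene, kinds in d.members.items():
            if gene not in known:
                warnings.warn(f"pathway {d.name!r}: gene {gene!r} not in the "
                              "gene matrix; skipped")
                continue
            used += 1
            for kind in kinds:
                hit |= gene_matrix.by_type[kind][gene].to_numpy()
        if used == 0:
            raise ValueError(f"pathway {d.name!r} has no usable members")
        cols[d.name] = hit
    binary = pd.DataFrame(cols, index=gene_matrix.binary.index)
    mat = AlterationMatrix(binary=binary, item_type="pathway")
    return mat, mat.frequencies()


def pathway_correlation(matrix: AlterationMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation between binary item columns; constant
    columns are excluded with a warning."""
    df = matrix.binary
    if len(df.index) < 2:
        raise ValueError("need at least 2 cases")
    keep = df.columns[df.std() > 0]
    dropped = set(df.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant columns excluded from correlation: "
                      f"{sorted(dropped)}")
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant columns")
    corr = df[keep].corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def mutual_exclusivity_test(gene_matrix: AlterationMatrix, gene_a: str,
                            gene_b: str) -> tuple[int, float]:
    """Lower-tail hypergeometric test for co-occurrence of two genes.

    Returns (observed co-occurrence count, P(X <= observed) under the
    hypergeometric null); small p means more exclusive than chance.
    """
    df = gene_matrix.binary
    for g in (gene_a, gene_b):
        if g not in df.columns:
            raise KeyError(f"gene {g!r} not in alteration matrix")
    n = len(df.index)
    a = df[gene_a].to_numpy().astype(bool)
    b = df[gene_b].to_numpy().astype(bool)
    K, n_b = int(a.sum()), int(b.sum())
    x = int((a & b).sum())
    p = hypergeom_tail(x, K=K, N=n, n=n_b, side="le")
    return x, p


# ---------------------------------------------------------------------------
# unsupervised Random-Forest dissimilarity + PAM


def rf_dissimilarity(matrix: pd.DataFrame, n_trees: int = 500,
                     seed: int = 0) -> np.ndarray:
    """Unsupervised RF dissimilarity by the synthetic-contrast trick.

    Real rows are labelled 1 and a column-wise permuted copy 0; a forest
    is trained on the contrast; the proximity of two real rows is their
    co-leaf frequency over trees, and dissimilarity = 1 − proximity.
    """
    X = np.asarray(matrix, dtype=float)
    if np.all(X == X[0]):
        raise ValueError("constant matrix: no contrast to learn")
    rng = np.random.default_rng(seed)
    synth = np.column_stack([rng.permutation(X[:, j])
                             for j in range(X.shape[1])])
    data = np.vstack([X, synth])
    y = np.r_[np.ones(len(X)), np.zeros(len(synth))]
    forest = RandomForestClassifier(n_estimators=n_trees,
                                    random_state=int(rng.integers(2**31)))
    forest.fit(data, y)
    leaves = forest.apply(X)  # real rows only
    prox = np.zeros((len(X), len(X)))
    for t in range(leaves.shape[1]):
        same = leaves[:, t][:, None] == leaves[:, t][None, :]
        prox += same
    prox /= leaves.shape[1]
    return 1.0 - prox


def pam(dissimilarity: np.ndarray, k: int) -> tuple[np.ndarray, list[int]]:
    """Partitioning around medoids (classic build + swap).

    Returns (labels as medoid indices per point, medoid list). Fully
    deterministic: build greedily minimizes total dissimilarity; swap
    applies the best-improving (medoid, non-medoid) exchange until none
    improves.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if k < 1 or k > n:
        raise ValueError("k out of range")
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = [np.maximum(current - D[:, c], 0).sum() if c not in medoids
                 else -np.inf for c in range(n)]
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost = c
                    best_swap = (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            medoids = sorted(medoids)
            improved = True
    meds = np.asarray(medoids)
    labels = meds[np.argmin(D[:, meds], axis=1)]
    labels[meds] = meds
    return labels, medoids


def rf_pam_cluster(matrix: AlterationMatrix, k: int, n_trees: int = 500,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Cluster cases by RF dissimilarity + PAM.

    Returns (per-case medoid labels, the dissimilarity matrix).
    """
    df = matrix.binary
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(df.index) < 2 * k:
        raise ValueError("need at least 2k cases")
    D = rf_dissimilarity(df, n_trees=n_trees, seed=seed)
    labels, _ = pam(D, k)
    return labels, D
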