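"""Gene-level copy number: projection from segments, calling, recurrence
and locus-survival scans.

Segments arrive 1-based inclusive (SEG convention) and gene models are
BED-style 0-based half-open; conversion happens here. The recurrence scan
is a deliberately simplified amplitude-times-frequency statistic (a
G-score) with a within-chromosome circular-permutation null — it preserves
the logic of peak-finding tools like GISTIC without reimplementing them,
and is not claimed to be equivalent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io_cohort import CNSegment, ClinicalRecord
from .stats_survival import bh_fdr, cox_univariate, logrank_test

logger = logging.getLogger(__name__)

NEUTRAL, AMP, DEL = "neutral", "amp", "del"


@dataclass(frozen=True)
class CallThresholds:
    """Log2-ratio cut-offs: ±0.3 for low-level, ±0.9 for high-level events
    (the usual log2 calling conventions)."""

    amp_high: float = 0.9
    del_high: float = -0.9
    amp_low: float = 0.3
    del_low: float = -0.3

    def __post_init__(self):
        if not (self.del_high < self.del_low < 0 < self.amp_low < self.amp_high):
            raise ValueError("thresholds must satisfy del_high < del_low < 0 "
                             "< amp_low < amp_high")


@dataclass
class GeneModel:
    """gene -> (chrom, start, end), 0-based half-open."""

    spans: dict[str, tuple[str, int, int]]

    def __post_init__(self):
        for g, (_, start, end) in self.spans.items():
            if start >= end:
                raise ValueError(f"gene {g}: start must be < end")

    def genes_by_position(self) -> list[str]:
        return sorted(self.spans, key=lambda g: (self.spans[g][0],
                                                 self.spans[g][1]))


@dataclass
class GeneCNMatrix:
    """Cases×genes log2 ratios plus a per-cell coverage flag."""

    values: pd.DataFrame
    covered: pd.DataFrame

    @property
    def cases(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def read_gene_model_bed(path) -> GeneModel:
    """Read a 4-column BED (chrom, start, end, gene) into a GeneModel."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "gene"],
                     dtype={"chrom": str, "gene": str})
    spans = {}
    for row in df.itertuples(index=False):
        if row.gene in spans:
            raise ValueError(f"duplicate gene {row.gene!r} in BED")
        spans[row.gene] = (row.chrom, int(row.start), int(row.end))
    return GeneModel(spans=spans)


def load_gene_model(path=None) -> GeneModel:
    """The bundled minimal gene model (approximate hg19 spans of the
    recurrently altered genes), or a user-supplied BED."""
    if path is not None:
        return read_gene_model_bed(path)
    ref = resources.files("somascape.data").joinpath("genes.bed")
    with resources.as_file(ref) as p:
        return read_gene_model_bed(p)


def segments_to_gene_matrix(segments: list[CNSegment],
                            gene_model: GeneModel) -> GeneCNMatrix:
    """Project per-case segments onto genes.

    Each cell is the overlap-length-weighted mean of segment log2 ratios
    over the gene span; genes untouched by any segment get 0 with the
    coverage flag false (kept dense for clustering). Overlapping segments
    within one case are an error.
    """
    cases = list(dict.fromkeys(s.case_id for s in segments))
    genes = gene_model.genes_by_position()
    values = pd.DataFrame(0.0, index=cases, columns=genes)
    covered = pd.DataFrame(False, index=cases, columns=genes)
    by_case_chrom: dict[tuple[str, str], list[CNSegment]] = {}
    for s in segments:
        by_case_chrom.setdefault((s.case_id, s.chrom), []).append(s)
    for (case, chrom), segs in by_case_chrom.items():
        segs.sort(key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping segments for case {case} on chr{chrom}: "
                    f"[{prev.start},{prev.end}] and [{cur.start},{cur.end}]")
    for gene in genes:
        chrom, gstart, gend = gene_model.spans[gene]
        for case in cases:
            segs = by_case_chrom.get((case, chrom))
            if not segs:
                continue
            weight = total = 0.0
            for s in segs:
                ov = min(gend, s.end) - max(gstart, s.start - 1)
                if ov > 0:
                    weight += ov
                    total += ov * s.log2_ratio
            if weight > 0:
                values.loc[case, gene] = total / weight
                covered.loc[case, gene] = True
    return GeneCNMatrix(values=values, covered=covered)


def call_gene_alterations(matrix: GeneCNMatrix,
                          thresholds: CallThresholds = CallThresholds(),
                          stringency: str = "low") -> pd.DataFrame:
    """Call {amp, del, neutral} per cell at the chosen stringency;
    uncovered cells are neutral."""
    if stringency == "high":
        amp_t, del_t = thresholds.amp_high, thresholds.del_high
    elif stringency == "low":
        amp_t, del_t = thresholds.amp_low, thresholds.del_low
    else:
        raise ValueError("stringency must be 'high' or 'low'")
    calls = pd.DataFrame(NEUTRAL, index=matrix.values.index,
                         columns=matrix.values.columns)
    calls[(matrix.values >= amp_t) & matrix.covered] = AMP
    calls[(matrix.values <= del_t) & matrix.covered] = DEL
    return calls


def cnv_complexity(calls: pd.DataFrame) -> pd.Series:
    """Per-case fraction of genes with a non-neutral call."""
    return (calls != NEUTRAL).mean(axis=1)


def recurrence_scan(matrix: GeneCNMatrix, gene_model: GeneModel,
                    thresholds: CallThresholds = CallThresholds(),
                    n_perm: int = 500, seed: int = 0) -> pd.DataFrame:
    """Per-gene recurrence G-scores with a circular-permutation null.

    G-score (amp) = Σ_cases max(0, x − amp_low); analogously for
    deletions with −x. The null circularly shifts each case's gene-ordered
    profile independently within each chromosome, preserving amplitude
    structure while decoupling position. Empirical p values use the
    (1+B)/(n_perm+1) convention; q is Benjamini-Hochberg per direction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = [g for g in matrix.genes]
    chrom_of = {g: gene_model.spans[g][0] for g in genes}
    chrom_blocks: dict[str, list[int]] = {}
    for j, g in enumerate(genes):
        chrom_blocks.setdefault(chrom_of[g], []).append(j)
    usable: list[int] = []
    for chrom, cols in chrom_blocks.items():
        if len(cols) < 2:
            warnings.warn(f"chromosome {chrom} has a single modelled gene; "
                          "excluded from the permutation scan")
        else:
            usable.extend(cols)
    X = matrix.values.to_numpy()

    def gscores(arr):
        amp = np.maximum(0.0, arr - thresholds.amp_low).sum(axis=0)
        dele = np.maximum(0.0, -arr - (-thresholds.del_low)).sum(axis=0)
        return amp, dele

    amp_obs, del_obs = gscores(X)
    amp_ge = np.zeros(X.shape[1])
    del_ge = np.zeros(X.shape[1])
    blocks = [cols for cols in chrom_blocks.values() if len(cols) >= 2]
    for _ in range(n_perm):
        Xp = X.copy()
        for cols in blocks:
            m = len(cols)
            shifts = rng.integers(0, m, size=X.shape[0])
            block = X[:, cols]
            rows = np.arange(X.shape[0])[:, None]
            offsets = (np.arange(m)[None, :] - shifts[:, None]) % m
            Xp[:, cols] = block[rows, offsets]
        amp_p, del_p = gscores(Xp)
        amp_ge += amp_p >= amp_obs
        del_ge += del_p >= del_obs
    out = pd.DataFrame(index=matrix.genes)
    out["amp_gscore"] = amp_obs
    out["del_gscore"] = del_obs
    out["tested"] = [j in set(usable) for j in range(len(genes))]
    amp_pv = (1 + amp_ge) / (n_perm + 1)
    del_pv = (1 + del_ge) / (n_perm + 1)
    out["amp_p"] = amp_pv
    out["del_p"] = del_pv
    tested = out["tested"].to_numpy()
    out["amp_q"] = np.nan
    out["del_q"] = np.nan
    if tested.any():
        out.loc[tested, "amp_q"] = bh_fdr(amp_pv[tested])
        out.loc[tested, "del_q"] = bh_fdr(del_pv[tested])
    return out


def locus_survival_scan(calls: pd.DataFrame, clinical: list[ClinicalRecord],
                        loci: list[str],
                        min_arm: int = 2) -> pd.DataFrame:
    """Altered-vs-not survival association per locus (gene).

    Reports log-rank p, univariate Cox HR and BH q across the tested loci;
    loci with an arm smaller than ``min_arm`` are reported untested.
    """
    clin = {c.case_id: c for c in clinical}
    cases = [c for c in calls.index if c in clin]
    times = np.array([clin[c].survival_months for c in cases])
    events = np.array([clin[c].event for c in cases], dtype=bool)
    rows = []
    for locus in loci:
        if locus not in calls.columns:
            rows.append((locus, False, np.nan, np.nan, np.nan, 0))
            continue
        altered = (calls.loc[cases, locus] != NEUTRAL).to_numpy()
        n_alt = int(altered.sum())
        if n_alt < min_arm or (len(cases) - n_alt) < min_arm:
            rows.append((locus, False, np.nan, np.nan, np.nan, n_alt))
            continue
        try:
            _, lr_p = logrank_test(times[altered], events[altered],
                                   times[~altered], events[~altered])
        except ValueError:
            rows.append((locus, False, np.nan, np.nan, np.nan, n_alt))
            continue
        cox = cox_univariate(times, events, altered.astype(float))
        rows.append((locus, True, lr_p, cox.hr, cox.p, n_alt))
    out = pd.DataFrame(rows, columns=["locus", "tested", "logrank_p", "hr",
                                      "cox_p", "n_altered"]).set_index("locus")
    out["q"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "logrank_p"].to_numpy())
    return out
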