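"""Mutation spectra, signature enrichment, burden and gene recurrence.

Single-base substitutions are classified into the six pyrimidine-collapsed
classes (C>A, C>G, C>T, T>A, T>C, T>G), optionally refined by the 16
flanking trinucleotide contexts into the standard 96-channel spectrum.
Purine-reference calls are reverse-complemented before classification, so
e.g. a G>T transversion and its C>A complement land in the same channel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .io_cohort import MutationCatalog
from .stats_survival import hypergeom_tail, students_t

CLASS6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: canonical channel order: class-major, then 5' base, then 3' base
CONTEXTS96 = tuple(
    f"{five}[{cls}]{three}"
    for cls in CLASS6 for five in _BASES for three in _BASES
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def classify_substitution(ref: str, alt: str, context3: str) -> tuple[str, str]:
    """Collapse a single-base substitution onto the pyrimidine strand.

    Returns ``(class6, context96)``, e.g. ``("C>T", "A[C>T]G")``. Purine
    references are reverse-complemented (alleles and context) first.
    """
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref == alt")
    if len(context3) != 3 or any(b not in _BASES for b in context3):
        raise ValueError(f"context3 must be a 3-mer over ACGT, got {context3!r}")
    if context3[1] != ref:
        raise ValueError(
            f"context central base {context3[1]!r} does not match ref {ref!r}")
    if ref in "AG":
        ref, alt = revcomp(ref), revcomp(alt)
        context3 = revcomp(context3)
    cls = f"{ref}>{alt}"
    return cls, f"{context3[0]}[{cls}]{context3[2]}"


@dataclass
class SpectrumVector:
    """Normalized mutation spectrum at 6- or 96-channel resolution."""

    resolution: int
    values: np.ndarray
    n_mutations: int

    def __post_init__(self):
        if self.resolution not in (6, 96):
            raise ValueError("resolution must be 6 or 96")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.resolution,):
            raise ValueError("values length must equal resolution")


def _spectrum_counts(records, resolution: int) -> np.ndarray:
    counts = np.zeros(resolution)
    for r in records:
        if not (r.is_snv and len(r.context3) == 3):
            continue
        cls, ctx = classify_substitution(r.ref, r.alt, r.context3)
        if resolution == 6:
            counts[CLASS6.index(cls)] += 1
        else:
            counts[CONTEXTS96.index(ctx)] += 1
    return counts


def case_spectrum(catalog: MutationCatalog, case_id: str,
                  resolution: int = 6) -> SpectrumVector:
    """Per-case spectrum over SNVs with known context (silent included:
    spectra describe the mutational process, not its coding consequence)."""
    counts = _spectrum_counts(catalog.for_case(case_id), resolution)
    n = int(counts.sum())
    values = counts / n if n > 0 else counts
    return SpectrumVector(resolution=resolution, values=values, n_mutations=n)


def _pattern_matches(pattern: str, trimer: str) -> bool:
    return all(base in IUPAC[p] for p, base in zip(pattern, trimer))


def context_fraction(catalog: MutationCatalog, case_ids, class6: str,
                     pattern: str) -> float:
    """Fraction of the group's ``class6`` mutations whose collapsed context
    matches an IUPAC 3-mer pattern (e.g. T>C at "CTG", C>T/C>G at "TCW")."""
    if class6 not in CLASS6:
        raise ValueError(f"unknown class {class6!r}")
    if len(pattern) != 3 or any(p not in IUPAC for p in pattern.upper()):
        raise ValueError(f"invalid IUPAC pattern {pattern!r}")
    pattern = pattern.upper()
    if class6[0] not in IUPAC[pattern[1]]:
        raise ValueError(
            f"pattern central base {pattern[1]!r} incompatible with {class6}")
    case_ids = set(case_ids)
    total = hits = 0
    for r in catalog.records:
        if r.case_id not in case_ids or not (r.is_snv and len(r.context3) == 3):
            continue
        cls, ctx = classify_substitution(r.ref, r.alt, r.context3)
        if cls != class6:
            continue
        total += 1
        if _pattern_matches(pattern, ctx[0] + cls[0] + ctx[-1]):
            hits += 1
    return hits / total if total else 0.0


def uniform_context_background() -> dict[str, float]:
    """Uniform background over the 32 pyrimidine-centred trinucleotides —
    the generator's truth for synthetic cohorts drawn without sequence
    composition bias."""
    trimers = [f"{a}{c}{b}" for c in "CT" for a in _BASES for b in _BASES]
    return {t: 1.0 / len(trimers) for t in trimers}


def apobec_enrichment(catalog: MutationCatalog, case_ids,
                      background: dict[str, float]) -> float:
    """TCW fold-enrichment score for APOBEC-type mutagenesis.

    score = [ (C>T + C>G at TCW) / (all C>T + C>G mutations) ]
          / [ background TCW frequency / background C-context frequency ]

    The numerator ratio is computed within the APOBEC substitution classes
    (C>T, C>G) so the score is 1-centred under a context-uniform null
    regardless of the class composition. 0 with no APOBEC-class mutations
    at all (degenerate input, flagged with a warning).
    """
    if not background:
        raise ValueError("background trinucleotide frequencies required")
    bg = {}
    for trimer, f in background.items():
        if trimer[1] in "AG":
            trimer = revcomp(trimer)
        bg[trimer] = bg.get(trimer, 0.0) + f
    bg_c = sum(f for t, f in bg.items() if t[1] == "C")
    bg_tcw = sum(f for t, f in bg.items()
                 if t[1] == "C" and t[0] == "T" and t[2] in "AT")
    if bg_c <= 0 or bg_tcw <= 0:
        raise ValueError("background must give C and TCW contexts positive mass")
    case_ids = set(case_ids)
    n_c = n_tcw = 0
    for r in catalog.records:
        if r.case_id not in case_ids or not (r.is_snv and len(r.context3) == 3):
            continue
        cls, ctx = classify_substitution(r.ref, r.alt, r.context3)
        if cls not in ("C>T", "C>G"):
            continue
        n_c += 1
        if ctx[0] == "T" and ctx[-1] in "AT":
            n_tcw += 1
    if n_c == 0:
        warnings.warn("no C>T/C>G mutations in group; APOBEC score degenerate")
        return 0.0
    return (n_tcw / n_c) / (bg_tcw / bg_c)


def compare_group_spectra(catalog: MutationCatalog, group_a_ids, group_b_ids,
                          resolution: int = 6):
    """Per-class two-sample Student's t on per-case spectrum fractions.

    Returns ``{class: (t, p)}``. Classes with zero variance in both groups
    and equal means get (0, 1) by convention.
    """
    group_a_ids, group_b_ids = list(group_a_ids), list(group_b_ids)
    if len(group_a_ids) < 2 or len(group_b_ids) < 2:
        raise ValueError("each group needs at least 2 cases")
    channels = CLASS6 if resolution == 6 else CONTEXTS96
    spec_a = np.array([case_spectrum(catalog, c, resolution).values
                       for c in group_a_ids])
    spec_b = np.array([case_spectrum(catalog, c, resolution).values
                       for c in group_b_ids])
    return {ch: students_t(spec_a[:, j], spec_b[:, j])
            for j, ch in enumerate(channels)}


def cluster_spectra(spectra: list[SpectrumVector], n_clusters: int):
    """Agglomerative (complete-linkage, Euclidean) clustering of spectra.

    Returns ``(labels, linkage_matrix)``; labels are 1-based cluster ids.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 cases to cluster")
    X = np.array([s.values for s in spectra])
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


def nonsilent_burden(catalog: MutationCatalog) -> dict[str, int]:
    """Per-case count of nonsilent (protein-altering) mutations, with
    zero-mutation roster cases included."""
    counts = {c: 0 for c in catalog.case_roster}
    for r in catalog.records:
        if r.is_nonsilent:
            counts[r.case_id] += 1
    return counts


def mutator_enrichment(burdens: dict[str, int],
                       lesion_flags: dict[str, bool]) -> tuple[int, float]:
    """Hypergeometric enrichment of mutator-gene lesions in the top burden
    quartile.

    The top quartile is the ceil(n/4) highest-burden cases, ties broken by
    roster order. Returns (overlap count, upper-tail hypergeometric p).
    """
    cases = list(burdens)
    if set(lesion_flags) != set(cases):
        raise ValueError("lesion flags must cover exactly the burden roster")
    n = len(cases)
    if n == 0:
        raise ValueError("empty roster")
    if len(set(burdens.values())) == 1:
        warnings.warn("all burdens equal; top quartile is arbitrary (roster order)")
    q = math.ceil(n / 4)
    ranked = sorted(range(n), key=lambda i: (-burdens[cases[i]], i))
    top = {cases[i] for i in ranked[:q]}
    K = sum(bool(v) for v in lesion_flags.values())
    overlap = sum(lesion_flags[c] for c in top)
    p = hypergeom_tail(overlap, K=K, N=n, n=q, side="ge")
    return overlap, p


def significant_gene_filter(per_gene: dict[str, tuple[int, float]],
                            n_cases: int,
                            min_count: int = 4,
                            p_cutoff: float = 0.05) -> list[str]:
    """Post-filter for significance-ranked genes: keep genes with at least
    ``min_count`` nonsilent mutations and p < ``p_cutoff``, sorted by p."""
    kept = [(p, g) for g, (count, p) in per_gene.items()
            if count >= min_count and p < p_cutoff]
    return [g for p, g in sorted(kept)]
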