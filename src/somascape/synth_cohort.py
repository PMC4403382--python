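"""Synthetic PDA-like cohort generator.

Generates the three cohort tables (somatic mutation catalog, copy-number
segments, clinical outcomes) with the statistical structure the downstream
analyses assume, so the whole pipeline is testable without protected
sequencing data:

* per-case nonsilent burden from a log-normal, with a latent mismatch-
  repair "mutator" fraction carrying a burden multiplier;
* driver genes drawn independently by configured marginal probabilities,
  except mutual-exclusivity groups (e.g. KRAS/BRAF/PIK3CA) where at most
  one member is drawn per case — exclusivity is a hard constraint here so
  tests of the exclusivity statistic have measurable power;
* trinucleotide mutation contexts drawn from per-etiology signature
  mixtures (ageing-like C>T, smoking-like C>A, mismatch-repair-like T>C
  at CTG), unconditionally on genomic position (no reference genome);
* diploid-noise segment profiles overwritten by sampled focal events at
  configured loci (CDKN2A/SMAD4 deletions, MYC/CCND1 amplifications);
* survival from an exponential proportional-hazards model with
  independent uniform censoring. The packaged profile states the target
  *cohort* median; the baseline (reference-covariate) hazard is
  calibrated at generation time so the marginal cohort median matches it
  given the configured covariate mix and hazard ratios.

Every draw flows through one ``numpy`` Generator, so a (profile, seed)
pair reproduces the cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq

from .cnv_landscape import GeneModel, load_gene_model
from .io_cohort import (CNSegment, ClinicalRecord, MutationCatalog,
                        MutationRecord)
from .spectra_burden import CLASS6, revcomp

# approximate hg19 autosome lengths (bp)
CHROM_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}
_AUTOSOMES = list(CHROM_LENGTHS)

_BASES = "ACGT"

#: fixed hotspot lesions for the canonical drivers (chrom, pos, ref, alt,
#: context); any other driver gets a signature-drawn lesion in its span
HOTSPOTS = {
    "KRAS": ("12", 25_398_284, "C", "T", "GCC"),
    "BRAF": ("7", 140_453_136, "A", "T", "CAC"),   # V600E
    "PIK3CA": ("3", 178_952_085, "A", "G", "CAT"),
    "GNAS": ("20", 57_484_420, "C", "T", "GCG"),
}

_NONSILENT_CLASS_P = {
    "missense": 0.78, "nonsense": 0.08, "splice_site": 0.05,
    "frame_shift_indel": 0.06, "in_frame_indel": 0.03,
}


def _context96(cls_idx: int, ctx_idx: int) -> tuple[str, str]:
    cls = CLASS6[cls_idx]
    five = _BASES[ctx_idx // 4]
    three = _BASES[ctx_idx % 4]
    return cls, f"{five}{cls[0]}{three}"


def builtin_signature(name: str) -> np.ndarray:
    """Parametric 96-channel signatures used by the packaged profiles.

    ``aging``  — C>T dominated, boosted at NpCpG contexts (deamination);
    ``smoking`` — C>A dominated (tobacco-type transversions);
    ``mmr``    — T>C dominated with mass concentrated at CTG contexts
    (mismatch-repair deficiency); ``uniform`` — flat over all channels.
    """
    class_w = {
        "aging":   [0.08, 0.07, 0.55, 0.08, 0.16, 0.06],
        "smoking": [0.50, 0.07, 0.20, 0.08, 0.10, 0.05],
        "mmr":     [0.05, 0.04, 0.25, 0.05, 0.55, 0.06],
        "uniform": [1 / 6] * 6,
    }
    if name not in class_w:
        raise ValueError(f"unknown builtin signature {name!r}")
    vec = np.zeros(96)
    for ci, cw in enumerate(class_w[name]):
        ctx_w = np.ones(16)
        if name == "aging" and CLASS6[ci] == "C>T":
            ctx_w[np.arange(16) % 4 == _BASES.index("G")] = 6.0
        if name == "mmr" and CLASS6[ci] == "T>C":
            ctx_w[:] = 0.3 / 15
            ctx_w[_BASES.index("C") * 4 + _BASES.index("G")] = 0.7
        ctx_w = ctx_w / ctx_w.sum()
        vec[ci * 16:(ci + 1) * 16] = cw * ctx_w
    return vec / vec.sum()


@dataclass
class BurdenModel:
    """Cohort-wide mean nonsilent count, log-normal dispersion, and the
    latent mutator fraction with its burden multiplier. The base log-normal
    mean is derived so the *cohort* expectation equals ``mean_count``."""

    mean_count: float = 67.0
    log_sd: float = 0.5
    mutator_multiplier: float = 10.0
    mutator_prob: float = 0.03

    def __post_init__(self):
        if self.mean_count <= 0 or self.log_sd <= 0:
            raise ValueError("mean_count and log_sd must be positive")
        if not 0 <= self.mutator_prob <= 1:
            raise ValueError("mutator_prob must be in [0, 1]")

    @property
    def base_mean(self) -> float:
        return self.mean_count / (1 - self.mutator_prob
                                  + self.mutator_prob * self.mutator_multiplier)


@dataclass
class CNVLocus:
    name: str
    gene: str
    kind: str              # amp | del
    prob: float
    mean: float
    sd: float
    flank: int = 250_000   # focal event extends this far beyond the gene

    def __post_init__(self):
        if self.kind not in ("amp", "del"):
            raise ValueError("locus kind must be 'amp' or 'del'")
        if not 0 <= self.prob <= 1:
            raise ValueError(f"locus {self.name}: prob outside [0, 1]")


@dataclass
class SurvivalModel:
    """Exponential proportional-hazards outcome model.

    Exactly one of ``baseline_median`` (median at reference covariates,
    m0) or ``cohort_median`` (target marginal median, from which m0 is
    back-calculated given the covariate mix) must be set.
    """

    log_hr: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.3
    baseline_median: float | None = None
    cohort_median: float | None = None

    def __post_init__(self):
        if (self.baseline_median is None) == (self.cohort_median is None):
            raise ValueError("set exactly one of baseline_median / cohort_median")
        for m in (self.baseline_median, self.cohort_median):
            if m is not None and m <= 0:
                raise ValueError("median months must be > 0")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")

    def resolved_baseline(self, covariate_probs: dict[str, float]) -> float:
        """Baseline median m0; calibrated from the cohort median when
        needed, by inverting the marginal survival mixture over the
        (independent) covariate distribution."""
        if self.baseline_median is not None:
            return self.baseline_median
        names = list(self.log_hr)
        probs = [covariate_probs[n] for n in names]
        combos = []
        for mask in range(2 ** len(names)):
            p = 1.0
            hr = 1.0
            for j, nm in enumerate(names):
                on = (mask >> j) & 1
                p *= probs[j] if on else 1 - probs[j]
                hr *= math.exp(self.log_hr[nm]) if on else 1.0
            combos.append((p, hr))

        def marginal_surv_minus_half(u):
            return sum(p * math.exp(-hr * u) for p, hr in combos) - 0.5

        u_star = brentq(marginal_surv_minus_half, 1e-9, 50.0)
        h0 = u_star / self.cohort_median
        return math.log(2) / h0


def _censor_horizon(h0: float, rate: float) -> float:
    """Upper bound of the uniform censoring window giving the requested
    expected censoring fraction under an exponential(h0) event time."""
    if rate <= 0:
        return math.inf

    def frac(u):  # P(censored) with C ~ U(0, u/h0)
        return (1 - math.exp(-u)) / u - rate

    u = brentq(frac, 1e-9, 1e6)
    return u / h0


def draw_survival(covariates: dict[str, float], model: SurvivalModel,
                  seed) -> tuple[float, int]:
    """One (time_months, event) draw: exponential with hazard
    h0·exp(Σ β·x), h0 = ln2/m0, under independent uniform censoring."""
    if model.baseline_median is None:
        raise ValueError("survival model baseline must be resolved first")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    m0 = model.baseline_median
    h0 = math.log(2) / m0
    h = h0 * math.exp(sum(model.log_hr.get(k, 0.0) * v
                          for k, v in covariates.items()))
    t = rng.exponential(1.0 / h)
    if model.censoring_rate >= 1:
        return float(rng.uniform(0, m0)), 0
    if model.censoring_rate <= 0:
        return float(t), 1
    c = rng.uniform(0, _censor_horizon(h0, model.censoring_rate))
    return (float(t), 1) if t <= c else (float(c), 0)


def draw_contexts(distribution, n: int, seed) -> list[tuple[str, str]]:
    """i.i.d. draws of (class6, context3) from a 96-channel distribution."""
    p = np.asarray(distribution, dtype=float)
    if p.shape != (96,):
        raise ValueError("distribution must have 96 entries")
    if np.any(p < 0):
        raise ValueError("negative signature weights")
    if abs(p.sum() - 1) > 1e-9:
        raise ValueError("distribution must sum to 1")
    if n == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.choice(96, size=n, p=p)
    return [_context96(i // 16, i % 16) for i in idx]


@dataclass
class CohortProfile:
    """Generative configuration for a synthetic cohort."""

    n_cases: int = 109
    case_prefix: str = "PDA"
    histology_probs: dict[str, float] = field(default_factory=lambda: {"PDA": 1.0})
    smoking_probs: dict[str, float] = field(
        default_factory=lambda: {"smoker": 0.3, "non-smoker": 0.6, "unknown": 0.1})
    grade_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.70, 3: 0.25})
    stage_probs: dict[str, float] = field(default_factory=lambda: {"II": 1.0})
    node_positive_prob: float = 0.65
    gene_mutation_probs: dict[str, float] = field(default_factory=dict)
    exclusivity_groups: list[dict[str, float]] = field(default_factory=list)
    mutator_genes: list[str] = field(default_factory=lambda: ["MLH1", "MSH2", "MSH6"])
    burden_model: BurdenModel = field(default_factory=BurdenModel)
    silent_fraction: float = 0.25
    signatures: dict[str, np.ndarray] = field(
        default_factory=lambda: {n: builtin_signature(n)
                                 for n in ("aging", "smoking", "mmr")})
    etiology_mixtures: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"baseline": {"aging": 1.0},
                                 "smoker": {"smoking": 0.6, "aging": 0.4},
                                 "mutator": {"mmr": 0.7, "aging": 0.3}})
    cnv_loci: list[CNVLocus] = field(default_factory=list)
    noise_sd: float = 0.1
    survival_model: SurvivalModel = field(
        default_factory=lambda: SurvivalModel(baseline_median=21.0))
    n_passenger_genes: int = 2000

    def __post_init__(self):
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        for name, probs in (("histology_probs", self.histology_probs),
                            ("smoking_probs", self.smoking_probs),
                            ("grade_probs", self.grade_probs),
                            ("stage_probs", self.stage_probs)):
            vals = list(probs.values())
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name}: probability outside [0, 1]")
            if abs(sum(vals) - 1) > 1e-9:
                raise ValueError(f"{name}: probabilities must sum to 1")
        for g, p in self.gene_mutation_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"gene {g}: probability outside [0, 1]")
        for grp in self.exclusivity_groups:
            if any(not 0 <= w <= 1 for w in grp.values()):
                raise ValueError("exclusivity weight outside [0, 1]")
            if sum(grp.values()) > 1 + 1e-9:
                raise ValueError("exclusivity group weights exceed 1")
        if not 0 <= self.silent_fraction < 1:
            raise ValueError("silent_fraction must be in [0, 1)")
        for lab, mix in self.etiology_mixtures.items():
            if abs(sum(mix.values()) - 1) > 1e-9:
                raise ValueError(f"etiology mixture {lab!r} must sum to 1")
            for sig in mix:
                if sig not in self.signatures:
                    raise ValueError(f"mixture {lab!r} references unknown "
                                     f"signature {sig!r}")

    def etiology_signature(self, label: str) -> np.ndarray:
        mix = self.etiology_mixtures[label]
        vec = sum(w * self.signatures[s] for s, w in mix.items())
        return vec / vec.sum()

    def covariate_probs(self) -> dict[str, float]:
        """Marginal probabilities of the survival covariates (assumed
        independent), resolved from the profile's own configuration."""
        out = {}
        for name in self.survival_model.log_hr:
            if name == "smoker":
                out[name] = self.smoking_probs.get("smoker", 0.0)
            elif name.startswith("grade"):
                out[name] = self.grade_probs.get(int(name[5:]), 0.0)
            elif name.endswith(("_amp", "_del")):
                locus_name = name[:-4]
                locus = next((l for l in self.cnv_loci if l.name == locus_name),
                             None)
                if locus is None:
                    raise ValueError(f"survival covariate {name!r} references "
                                     "an unknown CNV locus")
                out[name] = locus.prob
            else:
                raise ValueError(f"cannot resolve covariate {name!r}")
        return out


@dataclass
class SyntheticCohort:
    catalog: MutationCatalog
    segments: list[CNSegment]
    clinical: list[ClinicalRecord]
    truth: dict


def load_profile(path=None) -> CohortProfile:
    """Load a YAML cohort profile; the packaged 109-case PDA profile
    (``pda109``) when no path is given."""
    if path is None:
        ref = resources.files("somascape.data").joinpath("pda109.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    sigs = {}
    for name, spec in raw.get("signatures", {}).items():
        sigs[name] = (builtin_signature(name) if spec == "builtin"
                      else np.asarray(spec, dtype=float))
    sm_raw = dict(raw["survival_model"])
    sm = SurvivalModel(
        log_hr=dict(sm_raw.get("log_hr", {})),
        censoring_rate=float(sm_raw.get("censoring_rate", 0.3)),
        baseline_median=sm_raw.get("baseline_median_months"),
        cohort_median=sm_raw.get("cohort_median_months"))
    return CohortProfile(
        n_cases=int(raw["n_cases"]),
        case_prefix=raw.get("case_prefix", "PDA"),
        histology_probs=dict(raw["histology_probs"]),
        smoking_probs=dict(raw["smoking_probs"]),
        grade_probs={int(k): float(v) for k, v in raw["grade_probs"].items()},
        stage_probs=dict(raw["stage_probs"]),
        node_positive_prob=float(raw["node_positive_prob"]),
        gene_mutation_probs=dict(raw["gene_mutation_probs"]),
        exclusivity_groups=[dict(g) for g in raw.get("exclusivity_groups", [])],
        mutator_genes=list(raw.get("mutator_genes", [])),
        burden_model=BurdenModel(**raw["burden_model"]),
        silent_fraction=float(raw.get("silent_fraction", 0.25)),
        signatures=sigs or None or {n: builtin_signature(n)
                                    for n in ("aging", "smoking", "mmr")},
        etiology_mixtures={k: dict(v)
                           for k, v in raw["etiology_mixtures"].items()},
        cnv_loci=[CNVLocus(**l) for l in raw.get("cnv_loci", [])],
        noise_sd=float(raw.get("noise_sd", 0.1)),
        survival_model=sm,
    )


def _snv_counts(rng) -> tuple[int, int, int, int]:
    return (int(rng.poisson(25) + 10), int(rng.poisson(12) + 4),
            int(rng.poisson(30) + 8), 0)


def _indel_counts(rng) -> tuple[int, int, int, int]:
    return (int(rng.poisson(20) + 9), int(rng.poisson(8) + 4),
            int(rng.poisson(30) + 8), 0)


def _case_segments(rng, case_id: str, events: list[tuple[CNVLocus, float]],
                   gene_model: GeneModel, noise_sd: float) -> list[CNSegment]:
    """Diploid-noise baseline split into ~50 Mb chunks, overwritten by the
    sampled focal events."""
    by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in _AUTOSOMES}
    for locus, amplitude in events:
        chrom, gstart, gend = gene_model.spans[locus.gene]
        if chrom not in by_chrom:
            continue
        start = max(1, gstart + 1 - locus.flank)
        end = min(CHROM_LENGTHS[chrom], gend + locus.flank)
        by_chrom[chrom].append((start, end, amplitude))
    segments = []
    for chrom in _AUTOSOMES:
        length = CHROM_LENGTHS[chrom]
        evs = sorted(by_chrom[chrom])
        # drop any event overlapping its predecessor (loci are expected to
        # be disjoint; this keeps the per-case profile valid regardless)
        cleaned = []
        for ev in evs:
            if cleaned and ev[0] <= cleaned[-1][1]:
                continue
            cleaned.append(ev)
        cursor = 1
        pieces: list[tuple[int, int, float | None]] = []
        for start, end, amp in cleaned:
            if start > cursor:
                pieces.append((cursor, start - 1, None))
            pieces.append((start, end, amp))
            cursor = end + 1
        if cursor <= length:
            pieces.append((cursor, length, None))
        for start, end, amp in pieces:
            if amp is not None:
                segments.append(CNSegment(
                    case_id=case_id, chrom=chrom, start=start, end=end,
                    n_markers=max(1, (end - start) // 5000),
                    log2_ratio=round(float(amp), 4)))
                continue
            # split baseline gaps into ~50 Mb chunks with independent noise
            n_chunks = max(1, round((end - start + 1) / 50_000_000))
            bounds = np.linspace(start, end + 1, n_chunks + 1).astype(int)
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                if hi <= lo:
                    continue
                segments.append(CNSegment(
                    case_id=case_id, chrom=chrom, start=int(lo), end=int(hi - 1),
                    n_markers=max(1, (hi - lo) // 10_000),
                    log2_ratio=round(float(rng.normal(0, noise_sd)), 4)))
    return segments


def generate_cohort(profile: CohortProfile, seed: int,
                    gene_model: GeneModel | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort, deterministically in (profile, seed)."""
    rng = np.random.default_rng(seed)
    gene_model = gene_model or load_gene_model()
    n = profile.n_cases
    ids = [f"{profile.case_prefix}_{i + 1:04d}" for i in range(n)]

    bm = profile.burden_model
    mutator = rng.random(n) < bm.mutator_prob
    smoking = rng.choice(list(profile.smoking_probs), size=n,
                         p=list(profile.smoking_probs.values())) if n else np.array([])
    histology = rng.choice(list(profile.histology_probs), size=n,
                           p=list(profile.histology_probs.values())) if n else np.array([])
    grades = rng.choice(list(profile.grade_probs), size=n,
                        p=list(profile.grade_probs.values())) if n else np.array([])
    stages = rng.choice(list(profile.stage_probs), size=n,
                        p=list(profile.stage_probs.values())) if n else np.array([])
    node_pos = rng.random(n) < profile.node_positive_prob

    # copy-number events
    cnv_events: list[list[tuple[CNVLocus, float]]] = [[] for _ in range(n)]
    locus_hit: dict[str, np.ndarray] = {}
    for locus in profile.cnv_loci:
        hit = rng.random(n) < locus.prob
        amps = rng.normal(locus.mean, locus.sd, size=n)
        locus_hit[locus.name] = hit
        for i in np.nonzero(hit)[0]:
            cnv_events[i].append((locus, float(amps[i])))

    # driver mutations: exclusivity groups then independent genes
    driver_genes: list[list[str]] = [[] for _ in range(n)]
    for grp in profile.exclusivity_groups:
        genes = list(grp)
        weights = list(grp.values())
        choices = rng.choice(len(genes) + 1, size=n,
                             p=weights + [1 - sum(weights)]) if n else []
        for i, c in enumerate(choices):
            if c < len(genes):
                driver_genes[i].append(genes[c])
    for gene, p in profile.gene_mutation_probs.items():
        hit = rng.random(n) < p
        for i in np.nonzero(hit)[0]:
            driver_genes[i].append(gene)
    for i in np.nonzero(mutator)[0]:
        mmr_gene = profile.mutator_genes[int(rng.integers(len(profile.mutator_genes)))]
        if mmr_gene not in driver_genes[i]:
            driver_genes[i].append(mmr_gene)

    # burden
    mu = math.log(bm.base_mean) - bm.log_sd ** 2 / 2
    burden = rng.lognormal(mu, bm.log_sd, size=n)
    burden[mutator] *= bm.mutator_multiplier
    burden = np.maximum(np.rint(burden).astype(int), 1)

    etiology = np.where(mutator, "mutator",
                        np.where(smoking == "smoker", "smoker", "baseline")) \
        if n else np.array([])

    nonsil_classes = list(_NONSILENT_CLASS_P)
    nonsil_p = list(_NONSILENT_CLASS_P.values())

    records: list[MutationRecord] = []
    for i in range(n):
        case = ids[i]
        sig = profile.etiology_signature(str(etiology[i]))
        seen_keys: set[tuple] = set()

        def add_record(**kw):
            key = (kw["chrom"], kw["pos"], kw["ref"], kw["alt"])
            if key in seen_keys:
                return False
            seen_keys.add(key)
            records.append(MutationRecord(case_id=case, **kw))
            return True

        n_driver = 0
        for gene in driver_genes[i]:
            if gene in HOTSPOTS:
                chrom, pos, ref, alt, ctx = HOTSPOTS[gene]
                t_r, t_a, n_r, n_a = _snv_counts(rng)
                add_record(gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                           variant_class="missense", t_ref_count=t_r,
                           t_alt_count=t_a, n_ref_count=n_r, n_alt_count=n_a,
                           context3=ctx)
                n_driver += 1
                continue
            chrom, gstart, gend = gene_model.spans.get(
                gene, (rng.choice(_AUTOSOMES), 0, 0))
            if gend > gstart:
                pos = int(rng.integers(gstart + 1, gend + 1))
            else:
                pos = int(rng.integers(1, CHROM_LENGTHS[str(chrom)]))
            vclass = nonsil_classes[rng.choice(len(nonsil_classes), p=nonsil_p)]
            if vclass.endswith("indel"):
                t_r, t_a, n_r, n_a = _indel_counts(rng)
                ref, alt = (str(rng.choice(list(_BASES))), "-")
                ctx = ""
            else:
                (cls, ctx), = draw_contexts(sig, 1, rng)
                ref, alt = ctx[1], cls[2]
                if rng.random() < 0.5:   # report on the purine strand
                    ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
                t_r, t_a, n_r, n_a = _snv_counts(rng)
            add_record(gene=gene, chrom=str(chrom), pos=pos, ref=ref, alt=alt,
                       variant_class=vclass, t_ref_count=t_r, t_alt_count=t_a,
                       n_ref_count=n_r, n_alt_count=n_a, context3=ctx)
            n_driver += 1

        n_pass = max(0, int(burden[i]) - n_driver)
        n_silent = int(rng.poisson(
            burden[i] * profile.silent_fraction / (1 - profile.silent_fraction)))
        vclasses = [nonsil_classes[j] for j in
                    rng.choice(len(nonsil_classes), size=n_pass, p=nonsil_p)]
        vclasses += ["silent"] * n_silent
        n_snv = sum(not vc.endswith("indel") for vc in vclasses)
        drawn = iter(draw_contexts(sig, n_snv, rng))
        for vc in vclasses:
            gene = f"PGENE{int(rng.integers(profile.n_passenger_genes)):04d}"
            chrom = str(rng.choice(_AUTOSOMES))
            pos = int(rng.integers(1, CHROM_LENGTHS[chrom]))
            if vc.endswith("indel"):
                t_r, t_a, n_r, n_a = _indel_counts(rng)
                add_record(gene=gene, chrom=chrom, pos=pos,
                           ref=str(rng.choice(list(_BASES))), alt="-",
                           variant_class=vc, t_ref_count=t_r, t_alt_count=t_a,
                           n_ref_count=n_r, n_alt_count=n_a, context3="")
            else:
                cls, ctx = next(drawn)
                ref, alt = ctx[1], cls[2]
                if rng.random() < 0.5:   # report on the purine strand
                    ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
                t_r, t_a, n_r, n_a = _snv_counts(rng)
                add_record(gene=gene, chrom=chrom, pos=pos, ref=ref,
                           alt=alt, variant_class=vc, t_ref_count=t_r,
                           t_alt_count=t_a, n_ref_count=n_r, n_alt_count=n_a,
                           context3=ctx)

    catalog = MutationCatalog(records=records, case_roster=ids)

    # segments
    segments: list[CNSegment] = []
    for i in range(n):
        segments.extend(_case_segments(rng, ids[i], cnv_events[i], gene_model,
                                       profile.noise_sd))

    # survival
    sm = profile.survival_model
    resolved = SurvivalModel(
        log_hr=dict(sm.log_hr), censoring_rate=sm.censoring_rate,
        baseline_median=sm.resolved_baseline(profile.covariate_probs()))
    clinical: list[ClinicalRecord] = []
    covariate_truth = []
    for i in range(n):
        cov = {}
        for name in sm.log_hr:
            if name == "smoker":
                cov[name] = float(smoking[i] == "smoker")
            elif name.startswith("grade"):
                cov[name] = float(int(grades[i]) == int(name[5:]))
            elif name.endswith(("_amp", "_del")):
                cov[name] = float(locus_hit[name[:-4]][i])
        t, ev = draw_survival(cov, resolved, rng)
        covariate_truth.append(cov)
        clinical.append(ClinicalRecord(
            case_id=ids[i], survival_months=round(t, 3), event=ev,
            smoking=str(smoking[i]), grade=int(grades[i]), stage=str(stages[i]),
            node_positive=bool(node_pos[i]), histology=str(histology[i])))

    truth = {
        "mutator": {ids[i]: bool(mutator[i]) for i in range(n)},
        "etiology": {ids[i]: str(etiology[i]) for i in range(n)},
        "drivers": {ids[i]: list(driver_genes[i]) for i in range(n)},
        "cnv_events": {ids[i]: [loc.name for loc, _ in cnv_events[i]]
                       for i in range(n)},
        "covariates": {ids[i]: covariate_truth[i] for i in range(n)},
        "baseline_median_months": resolved.baseline_median,
        "log_hr": dict(sm.log_hr),
        "burden_base_mean": bm.base_mean,
    }
    return SyntheticCohort(catalog=catalog, segments=segments,
                           clinical=clinical, truth=truth)
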