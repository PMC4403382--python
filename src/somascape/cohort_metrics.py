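"""Cohort-level summary metrics: the end-to-end quantities the pipeline
reports for a cohort (driver frequencies, burden, pathway frequencies,
copy-number call rates, median survival).

These run the full stack — catalog → gene/pathway matrices, segments →
gene-level calls, clinical → Kaplan-Meier — and are what the worked
examples and regression benchmarks aggregate over seeds.
"""

from __future__ import annotations

import numpy as np

from . import cnv_landscape as cnv
from . import pathway_map as pm
from . import spectra_burden as sb
from . import stats_survival as ss
from .synth_cohort import SyntheticCohort


def cohort_summary(cohort: SyntheticCohort,
                   gene_model: cnv.GeneModel | None = None,
                   pathway_defs: list[pm.PathwayDefinition] | None = None,
                   ) -> dict[str, float]:
    """Measured end-to-end summary of one cohort.

    Frequencies are fractions in [0, 1]; ``km_median_months`` may be NaN
    when the survival curve never reaches 0.5.
    """
    gene_model = gene_model or cnv.load_gene_model()
    pathway_defs = pathway_defs or pm.load_pathways()
    catalog = cohort.catalog
    n = len(catalog.case_roster)

    matrix = cnv.segments_to_gene_matrix(cohort.segments, gene_model)
    calls = cnv.call_gene_alterations(matrix)
    calls = calls.reindex(catalog.case_roster, fill_value=cnv.NEUTRAL)
    gene_mat = pm.gene_alteration_matrix(catalog, calls)
    mut = gene_mat.by_type["mutation"]
    _, pw_freqs = pm.pathway_alteration_matrix(gene_mat, pathway_defs)

    def mut_freq(gene):
        return float(mut[gene].mean()) if gene in mut.columns else 0.0

    burdens = sb.nonsilent_burden(catalog)
    fit = ss.km_fit([c.survival_months for c in cohort.clinical],
                    [c.event for c in cohort.clinical])
    med = ss.km_median(fit)

    both = 0
    if "KRAS" in mut.columns and "BRAF" in mut.columns:
        # mutation-level co-occurrence: the exclusivity statement concerns
        # the mutations themselves, not incidental copy-number noise calls
        both = int(((mut["KRAS"] > 0) & (mut["BRAF"] > 0)).sum())
    return {
        "n_cases": n,
        "kras_mut_freq": mut_freq("KRAS"),
        "braf_mut_freq": mut_freq("BRAF"),
        "kras_braf_co_occurrence": both,
        "flg_mut_freq": mut_freq("FLG"),
        "mean_nonsilent_burden": float(np.mean(list(burdens.values()))),
        "cdkn2a_del_freq": float((calls["CDKN2A"] == cnv.DEL).mean())
        if "CDKN2A" in calls.columns else 0.0,
        "swi_snf_pathway_freq": float(pw_freqs.get("SWI_SNF", 0.0)),
        "dna_repair_pathway_freq": float(pw_freqs.get("DNA_repair", 0.0)),
        "km_median_months": float(med) if med is not None else float("nan"),
    }
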