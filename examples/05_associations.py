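"""Phenotype associations: deconfounding, mass correlation, and comparing
two dependent correlations.

A cohort is generated with one phenotype tied to cluster-level synchrony,
one tied to the voxel-SD scale, nulls, a shared confound, and missing
entries.  Both sides are residualized on the confound, every (measure,
variable) pair is correlated with pairwise-complete data, and the
dependent-correlation test asks whether a variable binds differently to
the two cluster amplitudes.
"""

import numpy as np

from rsnamp.assoc import compare_dependent_correlations, deconfound, mass_correlate
from rsnamp.clusters import amplitude_covariation, cluster_amplitude, ward_cluster
from rsnamp.decompose import measure_table, network_amplitude, spatial_regress
from rsnamp.synthcohort import ConfoundSpec, PhenotypeSpec, SimConfig, simulate_cohort

cfg = SimConfig(
    n_voxels=200,
    n_networks=6,
    n_timepoints=250,
    n_subjects=300,
    phenotype_spec=(
        PhenotypeSpec("sys_bp", "cardiovascular", effect_synchrony=-0.8,
                      cluster=0, missing_rate=0.05),
        PhenotypeSpec("body_fat", "body_composition", effect_voxel_sd=0.6,
                      cluster=1),
        PhenotypeSpec("tea_intake", "lifestyle"),  # null
    ),
    confound_spec=(ConfoundSpec("site", effect_phenotype=0.4),),
    seed=21,
)
cohort = simulate_cohort(cfg)

amp = np.array([network_amplitude(spatial_regress(r, cohort.maps))
                for r in cohort.runs])
table = measure_table(amp, "network_amplitude", cohort.maps.network_labels)
cr = ward_cluster(amplitude_covariation(table), n_clusters=2)
clusters = cluster_amplitude(table, cr)
clusters.columns = ["cluster_a", "cluster_b"]

clusters_dc = deconfound(clusters, cohort.confounds)
pheno_dc = deconfound(cohort.phenotypes, cohort.confounds)

assoc = mass_correlate(clusters_dc, pheno_dc)
print(assoc[["measure", "variable", "n", "r", "p", "sig_bonferroni"]]
      .round(4).to_string(index=False))

res = compare_dependent_correlations(
    clusters_dc["cluster_a"], clusters_dc["cluster_b"], pheno_dc["sys_bp"]
)
print(
    f"\nsys_bp: r with cluster_a = {res.r1:+.3f}, with cluster_b = {res.r2:+.3f}, "
    f"p_diff = {res.p_diff:.2e}"
)
print(
    "The planted blood-pressure effect targets one cluster's synchrony, so "
    "its correlation differs significantly between the two cluster amplitudes; "
    "the null variable is flagged by neither."
)
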